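"""Fast per-read taxonomic classification: k-mer naive Bayes with bootstrap
confidence, in the style of the RDP classifier.

The model indexes, per reference taxon, the set of distinct k-mers (default
k=8) of its reference sequences and their reverse complements. A read is
scored against every taxon by the naive-Bayes log joint of its distinct
k-mers; confidence is estimated by bootstrap resampling of ceil(V/8) k-mers
(V = distinct k-mers in the read) and reported per rank as the fraction of
resamples whose winner shares the best taxon's lineage down to that rank.
The assignment is truncated at the deepest rank reaching the confidence
cutoff (default 0.8).

Word prior:       P(w)   = (n(w) + 0.5) / (N + 1)   over N taxa
Taxon conditional P(w|t) = (m(w) + P(w)) / (M_t + 1)
with m(w) in {0,1} flagging presence among taxon t's references and M_t the
number of references backing t.

This per-read classifier drives real-time saturation monitoring; the final
high-accuracy abundance re-estimation is an external tool whose output table
is ingested by :func:`load_external_profile`.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    RANKS,
    SPECIES_RANK,
    TABLE_RANKS,
    AbundanceProfile,
    Kingdom,
    LineageRecord,
)

__all__ = [
    "LineageRecord",
    "ClassifierModel",
    "TaxonAssignment",
    "build_kmer_model",
    "classify_read",
    "profile_sample",
    "load_external_profile",
    "read_seed",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _kmer_ids(bases: str, k: int) -> np.ndarray:
    """Distinct k-mer integer codes of ``bases`` (k-mers containing non-ACGT
    characters are skipped)."""
    codes = _CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    ok = np.ones(n, dtype=bool)
    for off in range(k):
        ok &= valid[off : off + n]
    if not ok.any():
        return np.empty(0, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    for off in range(k):
        ids = ids * 4 + codes[off : off + n]
    return np.unique(ids[ok])


_RC_BASE = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC_BASE)[::-1]


@dataclass
class ClassifierModel:
    """Naive-Bayes k-mer model over a set of reference lineages.

    ``log_cond`` is the dense (T, 4^k) matrix of log P(w|t); taxa are sorted
    by tax_id so that index order doubles as the lexicographic tie-break.
    """

    k: int
    taxa: list[LineageRecord]
    log_cond: np.ndarray
    n_bootstrap: int = 100
    min_conf: float = 0.8

    tax_index: dict[str, int] = field(init=False)
    lineages: dict[str, LineageRecord] = field(init=False)
    _prefix_cache: dict = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.tax_index = {t.tax_id: i for i, t in enumerate(self.taxa)}
        self.lineages = {t.tax_id: t for t in self.taxa}
        if len(self.tax_index) != len(self.taxa):
            raise ValueError("tax_ids must be unique within a model")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def save(self, path: Path | str) -> None:
        """Persist as an .npz archive (lineage table + log-conditional matrix)."""
        lineage_rows = [
            "\t".join([t.tax_id, t.kingdom.value, str(int(t.uncertain)), *t.ranks])
            for t in self.taxa
        ]
        np.savez_compressed(
            path,
            k=np.int64(self.k),
            n_bootstrap=np.int64(self.n_bootstrap),
            min_conf=np.float64(self.min_conf),
            log_cond=self.log_cond,
            lineages=np.array(lineage_rows),
        )

    @classmethod
    def load(cls, path: Path | str) -> "ClassifierModel":
        with np.load(path, allow_pickle=False) as z:
            taxa = []
            for row in z["lineages"]:
                tax_id, kingdom, uncertain, *ranks = str(row).split("\t")
                taxa.append(
                    LineageRecord(tax_id, tuple(ranks), Kingdom(kingdom), bool(int(uncertain)))
                )
            return cls(
                k=int(z["k"]),
                taxa=taxa,
                log_cond=z["log_cond"],
                n_bootstrap=int(z["n_bootstrap"]),
                min_conf=float(z["min_conf"]),
            )


@dataclass(frozen=True)
class TaxonAssignment:
    read_id: str
    best_taxon: str  # tax_id or "unassigned"
    confidences: tuple[float, ...] = ()  # superkingdom..species (7 values)
    assigned_rank: Optional[int] = None  # deepest rank with conf >= min_conf
    tie: bool = False
    reason: Optional[str] = None

    @property
    def is_assigned(self) -> bool:
        return self.best_taxon != "unassigned" and self.assigned_rank is not None


def build_kmer_model(
    db: Sequence[tuple[LineageRecord, str | Sequence[str]]],
    k: int = 8,
    seed: int = 0,
    n_bootstrap: int = 100,
    min_conf: float = 0.8,
    index_revcomp: bool = True,
) -> ClassifierModel:
    """Build the k-mer presence model from (lineage, reference(s)) pairs.

    Multiple entries may share a tax_id; each contributes one reference.
    Reverse-complement k-mers are indexed too so that orientation mistakes
    upstream degrade scores gracefully rather than catastrophically.
    """
    if not db:
        raise ValueError("empty reference database")
    if not (4 <= k <= 12):
        raise ValueError("k must be in [4, 12]")

    grouped: dict[str, tuple[LineageRecord, list[str]]] = {}
    for lineage, refs in db:
        seqs = [refs] if isinstance(refs, str) else list(refs)
        rec = grouped.setdefault(lineage.tax_id, (lineage, []))
        rec[1].extend(seqs)
    taxa = [grouped[t][0] for t in sorted(grouped)]

    n_words = 4**k
    presence = np.zeros((len(taxa), n_words), dtype=bool)
    ref_counts = np.zeros(len(taxa), dtype=np.int64)
    for i, t in enumerate(taxa):
        seqs = grouped[t.tax_id][1]
        ref_counts[i] = len(seqs)
        for seq in seqs:
            seq = seq.upper().replace("N", "")
            presence[i, _kmer_ids(seq, k)] = True
            if index_revcomp:
                presence[i, _kmer_ids(_revcomp(seq), k)] = True

    n_taxa = len(taxa)
    prior = (presence.sum(axis=0) + 0.5) / (n_taxa + 1)  # P(w)
    log_cond = np.log(
        (presence + prior[None, :]) / (ref_counts[:, None] + 1)
    ).astype(np.float32)
    return ClassifierModel(
        k=k, taxa=taxa, log_cond=log_cond, n_bootstrap=n_bootstrap, min_conf=min_conf
    )


def read_seed(global_seed: int, read_id: str) -> int:
    """Stable per-read RNG seed; independent of processing order."""
    return (int(global_seed) ^ zlib.crc32(read_id.encode())) & 0x7FFFFFFF


def classify_read(
    model: ClassifierModel,
    bases: str,
    seed: int = 0,
    read_id: str = "",
) -> TaxonAssignment:
    """Classify one read; deterministic given (model, bases, seed)."""
    if len(bases) < model.k:
        return TaxonAssignment(read_id, "unassigned", reason="shorter than k")
    kmers = _kmer_ids(bases, model.k)
    V = kmers.size
    if V == 0:
        return TaxonAssignment(read_id, "unassigned", reason="no valid k-mers")

    S = model.log_cond[:, kmers]  # (T, V)
    totals = S.sum(axis=1)
    best = int(np.argmax(totals))  # ties -> first = lexicographically smallest tax_id
    tie = bool(np.sum(totals == totals[best]) > 1)

    # bootstrap: draws of ceil(V/8) k-mers with replacement
    B = model.n_bootstrap
    d = math.ceil(V / 8)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, V, size=(B, d))
    counts = np.bincount(
        (idx + (np.arange(B)[:, None] * V)).ravel(), minlength=B * V
    ).reshape(B, V)
    draw_scores = S @ counts.T.astype(np.float32)  # (T, B)
    winners = np.argmax(draw_scores, axis=0)

    best_lineage = model.taxa[best]
    prefixes = model._prefix_cache.get(best)
    if prefixes is None:
        prefixes = np.array(
            [
                [model.taxa[t].prefix(r) == best_lineage.prefix(r) for r in range(7)]
                for t in range(model.n_taxa)
            ],
            dtype=bool,
        )
        model._prefix_cache[best] = prefixes
    confidences = prefixes[winners].mean(axis=0)
    assigned_rank: Optional[int] = None
    for r in range(6, -1, -1):
        if confidences[r] >= model.min_conf:
            assigned_rank = r
            break
    return TaxonAssignment(
        read_id=read_id,
        best_taxon=best_lineage.tax_id,
        confidences=tuple(float(c) for c in confidences),
        assigned_rank=assigned_rank,
        tie=tie,
    )


def profile_sample(
    assignments: Sequence[TaxonAssignment],
    model: ClassifierModel,
    sample_id: str = "",
    kingdom: Kingdom | None = None,
) -> AbundanceProfile:
    """Aggregate read assignments into an abundance profile.

    Reads whose confidence never reached the cutoff (or that failed outright)
    are pooled as unassigned; all others count at their assigned rank, so a
    genus-confident read contributes to genus and above and appears as
    ``unclassified-below-genus`` at species rank.
    """
    if kingdom is None:
        kingdom = model.taxa[0].kingdom if model.taxa else Kingdom.bacteria
    profile = AbundanceProfile(sample_id=sample_id, kingdom=kingdom)
    for a in assignments:
        if not a.is_assigned:
            profile.unassigned += 1
            continue
        profile.counts[(a.best_taxon, a.assigned_rank)] += 1
        profile.lineages.setdefault(a.best_taxon, model.lineages[a.best_taxon])
    return profile


def load_external_profile(
    tsv: Path | str,
    kingdom: Kingdom,
    sample_id: str = "",
    tolerance: float = 0.05,
) -> AbundanceProfile:
    """Ingest an externally produced abundance table (Emu-style dialect).

    Requires ``tax_id`` and ``abundance`` columns plus any subset of the rank
    columns; abundances are renormalised to sum to 1 over assigned taxa (a
    warning is emitted when the raw sum deviates by more than rounding
    noise). Read counts are reconstructed from an ``estimated counts`` column
    when present, otherwise scaled to a nominal total.
    """
    import warnings

    df = pd.read_csv(tsv, sep="\t", dtype={"tax_id": str}, keep_default_na=False)
    missing = {"tax_id", "abundance"} - set(df.columns)
    if missing:
        raise ValueError(f"external profile missing columns: {sorted(missing)}")
    df = df[df["tax_id"] != "unassigned"].copy()
    total = float(pd.to_numeric(df["abundance"]).sum())
    if total <= 0:
        raise ValueError("external profile has no positive abundances")
    if abs(total - 1.0) > 1e-6:
        if abs(total - 1.0) > tolerance:
            raise ValueError(f"abundances sum to {total:.4f}, outside tolerance")
        warnings.warn(f"abundances sum to {total:.4f}; renormalising to 1")
    counts_col = next(
        (c for c in df.columns if c.replace("_", " ") == "estimated counts"), None
    )
    profile = AbundanceProfile(sample_id=sample_id, kingdom=kingdom)
    nominal_total = 1_000_000
    for _, row in df.iterrows():
        ranks = tuple(str(row.get(r, "")) for r in TABLE_RANKS) + ("",)
        lineage = LineageRecord(str(row["tax_id"]), ranks, kingdom)
        names = [lineage.name_at(i) for i in range(7)]
        rank = max((i for i, n in enumerate(names) if n), default=SPECIES_RANK)
        reads = (
            int(round(float(row[counts_col])))
            if counts_col
            else int(round(float(row["abundance"]) / total * nominal_total))
        )
        profile.counts[(lineage.tax_id, rank)] += reads
        profile.lineages.setdefault(lineage.tax_id, lineage)
    return profile
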