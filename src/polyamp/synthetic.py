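"""Synthetic multi-kingdom nanopore-like runs with complete ground truth.

The generator emulates the study conditions of a 3:1 molar 16S:ITS ensemble
run: bimodal read lengths (bacterial references ~1,450 nt, fungal ~550 nt,
±10% jitter), ~5% per-base error split over substitutions/insertions/
deletions, a barcode plate with subject wells plus a two-strain positive
control for each kingdom (bacterial parts 1:4, fungal 2.7:1), near-empty
negative controls, and batch writes of 4,000 reads per FASTQ file under a
``fastq_pass/<barcode>/`` tree.

Quality strings are emitted so that the arithmetic-mean-phred filter is
meaningful — erroneous bases draw low phred values — rather than modelling
basecaller calibration. Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Kingdom, LineageRecord, Role, SampleSheet, SampleSheetEntry
from .segregate import IUPAC, PrimerSet, default_primer_sets, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _kmer_set(seq: str, k: int = 8) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# ---------------------------------------------------------------------------
# Reference databases
# ---------------------------------------------------------------------------


@dataclass
class ReferenceDB:
    """Synthetic reference sequences with lineages, one entry per taxon
    (duplicated-lineage fungal entries excepted, mirroring real UNITE input)."""

    bacteria: list[tuple[LineageRecord, str]]
    fungi: list[tuple[LineageRecord, str]]
    n_unique_fungal_lineages: int

    def references(self, kingdom: Kingdom) -> list[tuple[LineageRecord, str]]:
        return self.bacteria if kingdom == Kingdom.bacteria else self.fungi

    def unite_fasta(self) -> str:
        """Fungal references as a UNITE-style annotated FASTA."""
        out = []
        for i, (lin, seq) in enumerate(self.fungi, start=1):
            ranks7 = lin.ranks[:7]
            prefixes = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
            lineage = ";".join(
                f"{p}{name.replace(' ', '_')}" for p, name in zip(prefixes, ranks7)
            )
            out.append(f">SYN{i:06d}|{lineage}\n{seq}\n")
        return "".join(out)

    def write_unite_fasta(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(self.unite_fasta())
        return path


def _lineage(kingdom: Kingdom, idx: int, species: str, genus: str) -> tuple[str, ...]:
    tag = "Bact" if kingdom == Kingdom.bacteria else "Fun"
    sk = "Bacteria" if kingdom == Kingdom.bacteria else "Fungi"
    return (
        sk,
        f"{tag}phylum{idx % 4}",
        f"{tag}class{idx % 6}",
        f"{tag}order{idx % 8}",
        f"{tag}family{idx % 12}",
        genus,
        species,
        "",
    )


def make_reference_db(
    n_bact: int,
    n_fungi: int,
    len_bact: int = 1450,
    len_fungi: int = 550,
    seed: int = 0,
    length_jitter: float = 0.10,
    n_duplicate_lineages: int = 0,
    unidentified_frac: float = 0.0,
    max_jaccard: float = 0.5,
    max_tries: int = 50,
) -> ReferenceDB:
    """Random references with controlled pairwise 8-mer divergence.

    Sequences are accepted only while every pairwise 8-mer Jaccard stays
    below ``max_jaccard`` (random sequences of these lengths satisfy this
    essentially always; the rejection loop guards degenerate settings).
    ``n_duplicate_lineages`` extra fungal entries reuse an existing lineage
    with a fresh sequence; ``unidentified_frac`` of fungal lineages carry
    placeholder genus/species names.
    """
    if n_bact < 1 or n_fungi < 1:
        raise ValueError("need at least one taxon per kingdom")
    rng = np.random.default_rng(seed)
    kmer_sets: list[set] = []

    def draw_seq(target_len: int) -> str:
        lo = int(round(target_len * (1 - length_jitter)))
        hi = int(round(target_len * (1 + length_jitter)))
        for _ in range(max_tries):
            length = int(rng.integers(lo, hi + 1))
            seq = _decode(rng.integers(0, 4, size=length).astype(np.uint8))
            ks = _kmer_set(seq)
            if all(
                len(ks & other) / max(len(ks | other), 1) < max_jaccard
                for other in kmer_sets
            ):
                kmer_sets.append(ks)
                return seq
        raise RuntimeError(
            "could not reach the k-mer divergence target; use longer sequences"
        )

    bacteria = []
    for i in range(n_bact):
        genus = f"Bactgenus{i}"
        species = f"{genus} species{i}"
        lin = LineageRecord(f"B{i + 1}", _lineage(Kingdom.bacteria, i, species, genus),
                            Kingdom.bacteria)
        bacteria.append((lin, draw_seq(len_bact)))

    fungi = []
    n_placeholder = int(round(unidentified_frac * n_fungi))
    for i in range(n_fungi):
        if i < n_fungi - n_placeholder:
            genus = f"Fungenus{i}"
            species = f"{genus} species{i}"
            uncertain = False
        else:
            genus, species, uncertain = "unidentified", "unidentified", True
        lin = LineageRecord(f"F{i + 1}", _lineage(Kingdom.fungi, i, species, genus),
                            Kingdom.fungi, uncertain)
        fungi.append((lin, draw_seq(len_fungi)))
    unique_lineages = len({lin.ranks[:7] for lin, _ in fungi})
    for j in range(n_duplicate_lineages):
        src, _ = fungi[j % n_fungi]
        dup = LineageRecord(f"F{n_fungi + j + 1}", src.ranks, Kingdom.fungi, src.uncertain)
        fungi.append((dup, draw_seq(len_fungi)))

    return ReferenceDB(bacteria, fungi, n_unique_fungal_lineages=unique_lineages)


# ---------------------------------------------------------------------------
# Error model and single-read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Per-base corruption and quality emission.

    Default rates sum to 0.05 — the ~95% median read accuracy regime.
    Correct bases draw phred around ``q_correct``; erroneous bases (including
    inserted ones) around ``q_error``; deletions leave no trace.
    """

    substitution: float = 0.03
    insertion: float = 0.01
    deletion: float = 0.01
    q_correct: float = 25.0
    q_error: float = 8.0
    q_jitter: float = 3.0

    def __post_init__(self) -> None:
        rates = (self.substitution, self.insertion, self.deletion)
        if any(not (0 <= r < 1) for r in rates) or sum(rates) >= 1:
            raise ValueError("error rates must lie in [0, 1) and sum below 1")

    @property
    def total_rate(self) -> float:
        return self.substitution + self.insertion + self.deletion


ZERO_ERROR = ErrorModel(0.0, 0.0, 0.0)


def _concretize_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC[c][int(rng.integers(0, len(IUPAC[c])))] if len(IUPAC[c]) > 1 else c
        for c in primer
    )


@dataclass(frozen=True)
class SimulatedRead:
    bases: str
    quals: tuple[int, ...]
    flipped: bool
    insert: str  # error-free insert between the primers


def simulate_read(
    reference: str,
    primer_set: PrimerSet,
    err: ErrorModel,
    rng: np.random.Generator,
    flip_prob: float = 0.5,
) -> SimulatedRead:
    """One amplicon read: fwd primer + insert + rc(rev primer), randomly
    flipped, corrupted by the error model, with error-aware qualities."""
    fwd = _concretize_primer(primer_set.forward, rng)
    rev = _concretize_primer(primer_set.reverse, rng)
    amplicon = fwd + reference + reverse_complement(rev)
    codes = np.frombuffer(amplicon.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[codes]
    L = codes.size

    u = rng.random(L)
    del_mask = u < err.deletion
    sub_mask = (u >= err.deletion) & (u < err.deletion + err.substitution)
    ins_mask = rng.random(L) < err.insertion
    keep = ~del_mask

    mutated = codes.copy()
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        mutated[sub_mask] = (mutated[sub_mask] + shift) % 4

    counts = ins_mask.astype(np.int64) + keep.astype(np.int64)
    total = int(counts.sum())
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    out = np.zeros(total, dtype=np.uint8)
    is_err = np.zeros(total, dtype=bool)
    ins_pos = starts[ins_mask]
    out[ins_pos] = rng.integers(0, 4, size=ins_pos.size)
    is_err[ins_pos] = True
    base_pos = (starts + ins_mask.astype(np.int64))[keep]
    out[base_pos] = mutated[keep]
    is_err[base_pos] = sub_mask[keep]

    quals = rng.normal(err.q_correct, err.q_jitter, size=total)
    n_err = int(is_err.sum())
    if n_err:
        quals[is_err] = rng.normal(err.q_error, err.q_jitter, size=n_err)
    quals = np.clip(np.rint(quals), 2, 41).astype(np.int64)

    flipped = bool(rng.random() < flip_prob)
    if flipped:
        out = 3 - out[::-1]
        quals = quals[::-1]
    return SimulatedRead(_decode(out), tuple(int(q) for q in quals), flipped, reference)


# ---------------------------------------------------------------------------
# Whole-run simulation
# ---------------------------------------------------------------------------


@dataclass
class BarcodeCommunity:
    """One barcode's true community: kingdom mix and taxon abundances."""

    its_fraction: float
    bacteria: dict[str, float]  # tax_id -> probability, sums to 1
    fungi: dict[str, float]
    read_scale: float = 1.0

    def __post_init__(self) -> None:
        for vec in (self.bacteria, self.fungi):
            if vec:
                total = sum(vec.values())
                if abs(total - 1.0) > 1e-9:
                    for k in vec:
                        vec[k] /= total
        if not (0 <= self.its_fraction <= 1):
            raise ValueError("its_fraction must lie in [0, 1]")


@dataclass
class CommunitySpec:
    communities: dict[str, BarcodeCommunity]

    @classmethod
    def from_sheet(
        cls,
        sheet: SampleSheet,
        db: ReferenceDB,
        seed: int = 0,
        its_fraction: float = 0.25,
        sigma: float = 1.0,
        pc_bact_parts: tuple[float, float] = (1.0, 4.0),
        pc_fungi_parts: tuple[float, float] = (2.7, 1.0),
        nc_scale: float = 0.005,
    ) -> "CommunitySpec":
        """Study-condition defaults: 25% ITS molar fraction (3:1 spike),
        log-normal subject communities, bacterial PC 1:4, fungal PC 2.7:1,
        near-empty negative controls."""
        rng = np.random.default_rng(seed)
        bact_ids = [lin.tax_id for lin, _ in db.bacteria]
        fun_ids = [lin.tax_id for lin, _ in db.fungi]
        communities: dict[str, BarcodeCommunity] = {}
        for entry in sheet.entries:
            if entry.role == Role.positive_control:
                bact = dict(zip(bact_ids[:2], pc_bact_parts))
                fung = dict(zip(fun_ids[:2], pc_fungi_parts))
                communities[entry.barcode] = BarcodeCommunity(
                    its_fraction, bact, fung
                )
            elif entry.role in (Role.negative_control, Role.ncp):
                bact = {t: 1.0 for t in bact_ids[:3]}
                fung = {t: 1.0 for t in fun_ids[:3]}
                communities[entry.barcode] = BarcodeCommunity(
                    its_fraction, bact, fung, read_scale=nc_scale
                )
            else:
                w_b = rng.lognormal(0.0, sigma, size=len(bact_ids))
                w_f = rng.lognormal(0.0, sigma, size=len(fun_ids))
                communities[entry.barcode] = BarcodeCommunity(
                    its_fraction,
                    dict(zip(bact_ids, w_b / w_b.sum())),
                    dict(zip(fun_ids, w_f / w_f.sum())),
                )
        return cls(communities)


@dataclass
class GroundTruth:
    """Per-read and per-barcode truth of a simulated run."""

    reads: pd.DataFrame  # read_id, barcode, kingdom, tax_id, batch, flipped
    abundances: pd.DataFrame  # barcode, kingdom, tax_id, reads

    def kingdom_counts(self, barcode: str) -> dict[str, int]:
        sub = self.reads[self.reads["barcode"] == barcode]
        return sub["kingdom"].value_counts().to_dict()

    def taxon_counts(self, barcode: str, kingdom: Kingdom) -> dict[str, int]:
        sub = self.abundances[
            (self.abundances["barcode"] == barcode)
            & (self.abundances["kingdom"] == kingdom.value)
        ]
        return dict(zip(sub["tax_id"], sub["reads"]))

    def dominant_taxon(self, barcode: str, kingdom: Kingdom) -> Optional[str]:
        counts = self.taxon_counts(barcode, kingdom)
        return max(counts, key=counts.get) if counts else None


def default_plate(
    n_subjects: int = 9,
    pc_bact_parts: tuple[float, float] = (1.0, 4.0),
    pc_fungi_parts: tuple[float, float] = (2.7, 1.0),
    pc_bact_names: tuple[str, str] = ("Bactgenus0 species0", "Bactgenus1 species1"),
    pc_fungi_names: tuple[str, str] = ("Fungenus0 species0", "Fungenus1 species1"),
) -> SampleSheet:
    """A scaled-down plate: subjects + one PC, one NC, one NCP."""
    entries = [
        SampleSheetEntry(f"barcode{i + 1:02d}", f"S{i + 1}", Role.subject)
        for i in range(n_subjects)
    ]
    pc_bc = f"barcode{n_subjects + 1:02d}"
    entries.append(SampleSheetEntry(pc_bc, "PC", Role.positive_control))
    entries.append(
        SampleSheetEntry(f"barcode{n_subjects + 2:02d}", "NC", Role.negative_control)
    )
    entries.append(SampleSheetEntry(f"barcode{n_subjects + 3:02d}", "NCP", Role.ncp))
    ratios = {
        pc_bc: {
            pc_bact_names[0]: pc_bact_parts[0],
            pc_bact_names[1]: pc_bact_parts[1],
        }
    }
    return SampleSheet(entries=entries, expected_ratios=ratios)


def simulate_run(
    sheet: SampleSheet,
    spec: CommunitySpec,
    db: ReferenceDB,
    reads_per_barcode: int,
    out_dir: Path | str,
    batch_size: int = 4000,
    seed: int = 0,
    err: ErrorModel = ErrorModel(),
    primer_sets: Sequence[PrimerSet] | None = None,
) -> GroundTruth:
    """Write a MinKNOW-style run directory plus ground-truth manifests.

    Per barcode: read count = reads_per_barcode × the community's read
    scale; kingdoms drawn from the ITS molar fraction, taxa from the
    abundance vector; reads written as gzipped FASTQ in ``batch_size``
    chunks (last file short) in a stable order.
    """
    if primer_sets is None:
        primer_sets = default_primer_sets()
    psets = {p.kingdom: p for p in primer_sets}
    refs = {
        Kingdom.bacteria: dict((lin.tax_id, seq) for lin, seq in db.bacteria),
        Kingdom.fungi: dict((lin.tax_id, seq) for lin, seq in db.fungi),
    }
    out_dir = Path(out_dir)
    truth_rows = []
    abundance_rows: dict[tuple[str, str, str], int] = {}

    for bc_idx, entry in enumerate(sheet.entries):
        barcode = entry.barcode
        if barcode not in spec.communities:
            raise ValueError(f"community spec does not cover {barcode}")
        comm = spec.communities[barcode]
        rng = np.random.default_rng([seed, bc_idx])
        n_reads = int(round(reads_per_barcode * comm.read_scale))
        bc_dir = out_dir / "fastq_pass" / barcode
        bc_dir.mkdir(parents=True, exist_ok=True)

        kingdoms = np.where(
            rng.random(n_reads) < comm.its_fraction, "fungi", "bacteria"
        )
        taxa_choices = {}
        for kd_name, vec in (("bacteria", comm.bacteria), ("fungi", comm.fungi)):
            ids = list(vec)
            probs = np.array([vec[t] for t in ids])
            n_kd = int((kingdoms == kd_name).sum())
            taxa_choices[kd_name] = iter(
                rng.choice(ids, size=n_kd, p=probs / probs.sum())
            ) if n_kd else iter([])

        batch_no, handle = 0, None
        for i in range(n_reads):
            if i % batch_size == 0:
                if handle is not None:
                    handle.close()
                handle = gzip.open(
                    bc_dir / f"{barcode}_batch{batch_no:04d}.fastq.gz", "wt"
                )
                batch_no += 1
            kd_name = str(kingdoms[i])
            kingdom = Kingdom(kd_name)
            tax_id = str(next(taxa_choices[kd_name]))
            sim = simulate_read(refs[kingdom][tax_id], psets[kingdom], err, rng)
            read_id = f"{barcode}-{i:06d}"
            qual_str = "".join(chr(q + 33) for q in sim.quals)
            handle.write(f"@{read_id} barcode={barcode}\n{sim.bases}\n+\n{qual_str}\n")
            truth_rows.append(
                {
                    "read_id": read_id,
                    "barcode": barcode,
                    "kingdom": kd_name,
                    "tax_id": tax_id,
                    "batch": batch_no - 1,
                    "flipped": sim.flipped,
                }
            )
            key = (barcode, kd_name, tax_id)
            abundance_rows[key] = abundance_rows.get(key, 0) + 1
        if handle is not None:
            handle.close()

    reads_df = pd.DataFrame(
        truth_rows,
        columns=["read_id", "barcode", "kingdom", "tax_id", "batch", "flipped"],
    )
    ab_df = pd.DataFrame(
        [
            {"barcode": bc, "kingdom": kd, "tax_id": t, "reads": n}
            for (bc, kd, t), n in sorted(abundance_rows.items())
        ]
    )
    reads_df.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    ab_df.to_csv(out_dir / "truth_abundance.tsv", sep="\t", index=False)
    return GroundTruth(reads=reads_df, abundances=ab_df)
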