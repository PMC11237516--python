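"""Readers and writers for FASTQ batches, sample sheets and abundance tables.

Every downstream stage consumes the types defined here. The FASTQ reader is a
streaming generator emulating the way nanopore run software deposits
demultiplexed "pass" reads in fixed-size batches, one directory per barcode.
Quality strings are decoded as phred+33; no auto-detection is attempted.
"""

from __future__ import annotations

import gzip
import io as _stdio
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: Canonical rank order used throughout; the trailing slot holds an optional
#: strain/infra-species label and is left empty for most references.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)
#: Ranks serialised in tabular output (strain excluded).
TABLE_RANKS: tuple[str, ...] = RANKS[:7]

SPECIES_RANK = RANKS.index("species")
GENUS_RANK = RANKS.index("genus")


class Role(str, Enum):
    """Sample role on the 96-well plate."""

    subject = "subject"
    positive_control = "positive_control"
    negative_control = "negative_control"
    ncp = "ncp"


class Kingdom(str, Enum):
    bacteria = "bacteria"
    fungi = "fungi"


@dataclass(frozen=True)
class Read:
    """One sequencing read with phred+33-decoded qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    barcode: str = "unclassified"
    batch_index: int = 0

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 93):
            raise ValueError(f"read {self.read_id}: phred scores outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        """Arithmetic mean of per-base phred scores (FastQC-style)."""
        return float(np.mean(self.quals)) if self.quals else 0.0


@dataclass
class ReadBatch:
    """A contiguous batch of reads sharing a barcode (one arrival window)."""

    reads: list[Read]
    batch_index: int
    barcode: str

    def __post_init__(self) -> None:
        for r in self.reads:
            if r.barcode != self.barcode or r.batch_index != self.batch_index:
                raise ValueError("all reads in a batch must share barcode and batch_index")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class SampleSheetEntry:
    barcode: str
    sample_id: str
    role: Role


@dataclass
class SampleSheet:
    """Barcode → sample mapping with optional control mix ratios.

    ``expected_ratios`` maps a control barcode to an *ordered* mapping of
    taxon name → expected molar part, e.g. ``{"Msmeg": 1, "Ecoli": 4}`` for a
    two-strain mock mixed 1:4.
    """

    entries: list[SampleSheetEntry]
    expected_ratios: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        barcodes = [e.barcode for e in self.entries]
        if len(set(barcodes)) != len(barcodes):
            dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
            raise ValueError(f"duplicate barcodes in sample sheet: {dupes}")
        if len(self.entries) > 96:
            raise ValueError("sample sheet exceeds 96 entries")

    @property
    def barcodes(self) -> list[str]:
        return [e.barcode for e in self.entries]

    def role_of(self, barcode: str) -> Role:
        for e in self.entries:
            if e.barcode == barcode:
                return e.role
        raise KeyError(barcode)

    def barcodes_with_role(self, *roles: Role) -> list[str]:
        return [e.barcode for e in self.entries if e.role in roles]

    @property
    def subject_barcodes(self) -> list[str]:
        """Barcodes counted toward the run-stop majority (controls excluded)."""
        return self.barcodes_with_role(Role.subject)


@dataclass(frozen=True)
class LineageRecord:
    """An 8-rank taxonomy path with a stable identifier.

    ``ranks`` runs superkingdom → strain; unknown ranks are empty strings.
    ``uncertain`` flags placeholder names (``unidentified``, ``*_sp`` …) kept
    verbatim from the source database.
    """

    tax_id: str
    ranks: tuple[str, ...]
    kingdom: Kingdom
    uncertain: bool = False

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks, got {len(self.ranks)}")

    def name_at(self, rank: int | str) -> str:
        idx = RANKS.index(rank) if isinstance(rank, str) else rank
        return self.ranks[idx]

    def prefix(self, rank: int) -> tuple[str, ...]:
        """Lineage truncated at ``rank`` (inclusive), for ancestry comparison."""
        return self.ranks[: rank + 1]

    @property
    def species(self) -> str:
        return self.ranks[SPECIES_RANK]


@dataclass
class AbundanceProfile:
    """Per-sample, per-kingdom taxon read counts with derived proportions.

    Counts are keyed by ``(tax_id, assigned_rank)`` so that reads confident
    only to, say, genus are distinguishable from species-level assignments of
    the same reference taxon.
    """

    sample_id: str
    kingdom: Kingdom
    counts: Counter = field(default_factory=Counter)  # (tax_id, rank_idx) -> reads
    lineages: dict[str, LineageRecord] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total_reads(self) -> int:
        return self.total_assigned + self.unassigned

    def counts_at_rank(self, rank: int | str) -> dict[str, int]:
        """Aggregate counts at ``rank``.

        A read assigned at rank ``a`` contributes to every rank ≤ ``a`` under
        its lineage name there; at deeper ranks it is pooled under
        ``"unclassified-below-<rank a>"``.
        """
        r = RANKS.index(rank) if isinstance(rank, str) else rank
        out: Counter = Counter()
        for (tax_id, ar), n in self.counts.items():
            if ar >= r:
                name = self.lineages[tax_id].name_at(r) or "unclassified"
                out[name] += n
            else:
                out[f"unclassified-below-{RANKS[ar]}"] += n
        return dict(out)

    def species_counts(self, include_unclassified: bool = False) -> dict[str, int]:
        sc = self.counts_at_rank(SPECIES_RANK)
        if not include_unclassified:
            sc = {k: v for k, v in sc.items() if not k.startswith("unclassified")}
        return sc

    def relative_abundances(self) -> dict[tuple[str, int], float]:
        """Proportions over assigned taxa plus the unassigned pool."""
        total = self.total_reads
        if total == 0:
            return {}
        return {key: n / total for key, n in self.counts.items()}

    def merged_with(self, other: "AbundanceProfile") -> "AbundanceProfile":
        if other.kingdom != self.kingdom:
            raise ValueError("cannot merge profiles across kingdoms")
        merged = AbundanceProfile(
            sample_id=self.sample_id,
            kingdom=self.kingdom,
            counts=self.counts + other.counts,
            lineages={**self.lineages, **other.lineages},
            unassigned=self.unassigned + other.unassigned,
        )
        return merged


# ---------------------------------------------------------------------------
# FASTQ streaming
# ---------------------------------------------------------------------------


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return _stdio.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def barcode_of_path(path: Path, layout: str = "dir") -> str | None:
    """Barcode for a FASTQ file under the MinKNOW layout (parent directory)."""
    if layout == "dir":
        name = path.parent.name
        if name.startswith("barcode") or name == "unclassified":
            return name
    return None


def _barcode_from_header(title: str) -> str:
    for token in title.split():
        if token.startswith("barcode="):
            return token.split("=", 1)[1]
    return "unclassified"


def read_fastq_batches(
    paths: Sequence[Path | str],
    batch_size: int,
    layout: str = "dir",
) -> Iterator[ReadBatch]:
    """Stream reads from FASTQ(.gz) files as fixed-size per-barcode batches.

    Batches are yielded in file order; a batch is flushed early when the
    barcode changes between consecutive records, and the final batch may be
    short. Memory use is proportional to ``batch_size``. With
    ``layout="dir"`` the barcode is the parent directory name; with
    ``layout="flat"`` it is parsed from a ``barcode=NN`` header token
    (defaulting to ``unclassified``).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    buffer: list[Read] = []
    buf_barcode: str | None = None
    batch_counters: Counter = Counter()

    def flush() -> ReadBatch:
        nonlocal buffer, buf_barcode
        idx = batch_counters[buf_barcode]
        batch_counters[buf_barcode] += 1
        batch = ReadBatch(
            reads=[
                Read(r.read_id, r.bases, r.quals, buf_barcode, idx) for r in buffer
            ],
            batch_index=idx,
            barcode=buf_barcode,
        )
        buffer = []
        return batch

    for path in map(Path, paths):
        dir_barcode = barcode_of_path(path, layout)
        with _open_text(path) as handle:
            record_no = 0
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    record_no += 1
                    if len(seq) != len(qual):
                        raise ValueError("sequence/quality length mismatch")
                    barcode = dir_barcode or _barcode_from_header(title)
                    if buf_barcode is not None and barcode != buf_barcode and buffer:
                        yield flush()
                    buf_barcode = barcode
                    quals = tuple(ord(c) - 33 for c in qual)
                    buffer.append(Read(title.split()[0], seq, quals, barcode, 0))
                    if len(buffer) >= batch_size:
                        yield flush()
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record in {path} near record {record_no + 1}: {exc}"
                ) from exc
    if buffer:
        yield flush()


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


def _parse_ratio(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in text.split(","):
        name, _, value = part.partition(":")
        if not value:
            raise ValueError(f"malformed expected_ratio entry {part!r}")
        out[name.strip()] = float(value)
    return out


def parse_sample_sheet(path: Path | str) -> SampleSheet:
    """Parse a tab-separated sample sheet.

    Columns: ``barcode``, ``sample_id``, ``role`` and optionally
    ``expected_ratio`` formatted ``name:part,name:part`` for control wells.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"barcode", "sample_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    entries: list[SampleSheetEntry] = []
    ratios: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        try:
            role = Role(row["role"])
        except ValueError:
            raise ValueError(f"unknown role {row['role']!r} for {row['barcode']}") from None
        entries.append(SampleSheetEntry(row["barcode"], row["sample_id"], role))
        if "expected_ratio" in df.columns and row["expected_ratio"]:
            ratios[row["barcode"]] = _parse_ratio(row["expected_ratio"])
    return SampleSheet(entries=entries, expected_ratios=ratios)


def write_sample_sheet(sheet: SampleSheet, path: Path | str) -> None:
    rows = []
    for e in sheet.entries:
        ratio = sheet.expected_ratios.get(e.barcode, {})
        rows.append(
            {
                "barcode": e.barcode,
                "sample_id": e.sample_id,
                "role": e.role.value,
                "expected_ratio": ",".join(f"{k}:{v:g}" for k, v in ratio.items()),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "sample_id",
    "kingdom",
    "tax_id",
    *TABLE_RANKS,
    "reads",
    "rel_abundance",
]


def write_abundance_table(
    profiles: Iterable[AbundanceProfile], out: Path | str
) -> None:
    """Write profiles as a tab-separated table, one row per (sample, kingdom,
    taxon) plus one ``unassigned`` row per (sample, kingdom).

    Lineage columns are filled down to each row's assigned rank only, so the
    deepest non-empty rank column encodes the assignment depth on read-back.
    ``rel_abundance`` sums to 1 per (sample, kingdom) across assigned rows
    plus the unassigned row.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    rows = []
    for p in profiles:
        total = p.total_reads
        for (tax_id, ar), n in sorted(p.counts.items()):
            lineage = p.lineages[tax_id]
            names = {
                rank: (lineage.name_at(i) if i <= ar else "")
                for i, rank in enumerate(TABLE_RANKS)
            }
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "kingdom": p.kingdom.value,
                    "tax_id": tax_id,
                    **names,
                    "reads": n,
                    "rel_abundance": round(n / total, 6) if total else 0.0,
                }
            )
        rows.append(
            {
                "sample_id": p.sample_id,
                "kingdom": p.kingdom.value,
                "tax_id": "unassigned",
                **{rank: "" for rank in TABLE_RANKS},
                "reads": p.unassigned,
                "rel_abundance": round(p.unassigned / total, 6) if total else 1.0,
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(out, sep="\t", index=False)


def read_abundance_table(path: Path | str) -> list[AbundanceProfile]:
    """Inverse of :func:`write_abundance_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"tax_id": str}, keep_default_na=False)
    profiles: dict[tuple[str, str], AbundanceProfile] = {}
    for _, row in df.iterrows():
        key = (row["sample_id"], row["kingdom"])
        if key not in profiles:
            profiles[key] = AbundanceProfile(row["sample_id"], Kingdom(row["kingdom"]))
        p = profiles[key]
        if row["tax_id"] == "unassigned":
            p.unassigned = int(row["reads"])
            continue
        names = [str(row[rank]) for rank in TABLE_RANKS]
        assigned_rank = max(i for i, n in enumerate(names) if n) if any(names) else 0
        ranks = tuple(names) + ("",)
        kingdom = p.kingdom
        p.lineages.setdefault(
            row["tax_id"], LineageRecord(row["tax_id"], ranks, kingdom)
        )
        p.counts[(row["tax_id"], assigned_rank)] += int(row["reads"])
    return list(profiles.values())
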