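"""Build a classification database from a UNITE-style annotated FASTA.

UNITE releases carry millions of full-length ITS sequences whose FASTA
headers embed a rank-prefixed lineage string
(``k__Fungi;p__…;c__…;o__…;f__…;g__…;s__…``). This module parses those
headers, dereplicates the collection down to unique 7-rank lineages with
deterministic tax_ids, keeps a capped list of representative sequences per
lineage, and exports both the internal classifier-model input and an
Emu-compatible database (taxonomy.tsv + species_taxid.fasta).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .io import Kingdom, LineageRecord

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
#: lineage rank order in the exported taxonomy table (species-first dialect)
_EMU_COLUMNS = (
    "tax_id",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)

_PLACEHOLDER_MARKERS = ("unidentified", "incertae sedis")


@dataclass(frozen=True)
class UniteEntry:
    accession: str
    lineage_string: str
    sequence: str


def _is_placeholder(name: str) -> bool:
    low = name.lower()
    if any(marker in low for marker in _PLACEHOLDER_MARKERS):
        return True
    return low.endswith(" sp") or low.endswith(" sp.")


def parse_unite_header(header: str) -> tuple[str, LineageRecord]:
    """Split a UNITE FASTA header into accession and lineage.

    The lineage segment is the ``|``-separated field containing ``k__``;
    rank prefixes are stripped and underscores converted to spaces.
    Placeholder names (``unidentified``, ``*_sp``, ``Incertae sedis``
    variants) are preserved verbatim but flag the record as uncertain.
    tax_id is left empty here — dereplication assigns it.
    """
    fields = header.lstrip(">").strip().split("|")
    lineage_field = next((f for f in fields if "k__" in f), None)
    if lineage_field is None:
        raise ValueError(f"no k__-prefixed lineage segment in header: {header!r}")
    accession = next((f for f in fields if f is not lineage_field and f), "")

    parts = [p.strip() for p in lineage_field.split(";") if p.strip()]
    names: list[str] = []
    for i, prefix in enumerate(_RANK_PREFIXES):
        match = next((p for p in parts if p.startswith(prefix)), None)
        if match is None:
            if i == 0:
                raise ValueError(f"lineage lacks k__ prefix: {header!r}")
            names.append("")
            continue
        names.append(match[len(prefix):].replace("_", " ").strip())
    uncertain = any(_is_placeholder(n) for n in names if n)
    ranks = tuple(names) + ("",)  # strain slot empty
    return accession, LineageRecord("", ranks, Kingdom.fungi, uncertain)


def iter_unite_fasta(path: Path | str) -> Iterator[UniteEntry]:
    """Stream (accession, lineage, sequence) entries from a FASTA(.gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        header: str | None = None
        chunks: list[str] = []
        for line in handle:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    yield _make_entry(header, chunks)
                header, chunks = line, []
            elif line:
                chunks.append(line)
        if header is not None:
            yield _make_entry(header, chunks)


def _make_entry(header: str, chunks: list[str]) -> UniteEntry:
    accession, lineage = parse_unite_header(header)
    lineage_field = next(f for f in header.lstrip(">").split("|") if "k__" in f)
    return UniteEntry(accession, lineage_field, "".join(chunks).upper())


@dataclass
class DereplicationResult:
    lineages: list[LineageRecord]                 # tax_id assigned, sorted
    representatives: dict[str, list[str]]         # tax_id -> sequences, longest first
    n_input_sequences: int
    n_unique_lineages: int


def dereplicate_lineages(
    entries: Iterable[UniteEntry], max_representatives: int = 10
) -> DereplicationResult:
    """Collapse entries to unique 7-rank lineages.

    Lineage identity is the exact normalized rank tuple; tax_ids are assigned
    1-based over the sorted lineage tuples, so the numbering is a pure
    function of the lineage *set* (input order never matters). Up to
    ``max_representatives`` sequences are retained per lineage, longest
    first (ties by sequence string for determinism).
    """
    by_lineage: dict[tuple[str, ...], list[str]] = {}
    uncertain_flags: dict[tuple[str, ...], bool] = {}
    n_input = 0
    for entry in entries:
        _, record = parse_unite_header(f">{entry.accession}|{entry.lineage_string}")
        n_input += 1
        key = record.ranks[:7]
        by_lineage.setdefault(key, []).append(entry.sequence)
        uncertain_flags[key] = record.uncertain

    lineages: list[LineageRecord] = []
    representatives: dict[str, list[str]] = {}
    for i, key in enumerate(sorted(by_lineage), start=1):
        tax_id = str(i)
        lineages.append(
            LineageRecord(tax_id, key + ("",), Kingdom.fungi, uncertain_flags[key])
        )
        seqs = sorted(by_lineage[key], key=lambda s: (-len(s), s))
        representatives[tax_id] = seqs[:max_representatives]
    return DereplicationResult(
        lineages=lineages,
        representatives=representatives,
        n_input_sequences=n_input,
        n_unique_lineages=len(lineages),
    )


def export_emu_db(
    lineages: Sequence[LineageRecord],
    representatives: dict[str, list[str]],
    out_dir: Path | str,
) -> tuple[Path, Path]:
    """Write taxonomy.tsv + species_taxid.fasta in the Emu dialect.

    taxonomy.tsv is species-first after tax_id; empty ranks are preserved as
    empty fields. FASTA headers are ``tax_id:serial``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tax_path = out_dir / "taxonomy.tsv"
    fasta_path = out_dir / "species_taxid.fasta"
    with open(tax_path, "w") as out:
        out.write("\t".join(_EMU_COLUMNS) + "\n")
        for lin in lineages:
            row = [lin.tax_id] + [lin.name_at(rank) for rank in _EMU_COLUMNS[1:]]
            out.write("\t".join(row) + "\n")
    with open(fasta_path, "w") as out:
        for lin in lineages:
            for serial, seq in enumerate(representatives.get(lin.tax_id, []), start=1):
                out.write(f">{lin.tax_id}:{serial}\n{seq}\n")
    return tax_path, fasta_path


def load_emu_db(out_dir: Path | str) -> tuple[list[LineageRecord], dict[str, list[str]]]:
    """Read back an exported database (round-trip counterpart of export)."""
    import pandas as pd

    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "taxonomy.tsv", sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != _EMU_COLUMNS:
        raise ValueError(f"unexpected taxonomy.tsv columns: {list(df.columns)}")
    lineages = []
    for _, row in df.iterrows():
        names = {rank: row[rank] for rank in _EMU_COLUMNS[1:]}
        ranks = (
            names["superkingdom"], names["phylum"], names["class"], names["order"],
            names["family"], names["genus"], names["species"], "",
        )
        uncertain = any(_is_placeholder(n) for n in ranks if n)
        lineages.append(LineageRecord(row["tax_id"], ranks, Kingdom.fungi, uncertain))
    representatives: dict[str, list[str]] = {}
    header = None
    chunks: list[str] = []
    with open(out_dir / "species_taxid.fasta") as handle:
        for line in handle:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    representatives.setdefault(header, []).append("".join(chunks))
                header, chunks = line[1:].split(":")[0], []
            elif line:
                chunks.append(line)
        if header is not None:
            representatives.setdefault(header, []).append("".join(chunks))
    return lineages, representatives


def build_from_fasta(
    fasta: Path | str, out_dir: Path | str, max_representatives: int = 10
) -> DereplicationResult:
    """End-to-end database build: parse, dereplicate, export, report."""
    result = dereplicate_lineages(iter_unite_fasta(fasta), max_representatives)
    export_emu_db(result.lineages, result.representatives, out_dir)
    report = Path(out_dir) / "build_report.tsv"
    with open(report, "w") as out:
        out.write("metric\tvalue\n")
        out.write(f"input_sequences\t{result.n_input_sequences}\n")
        out.write(f"unique_lineages\t{result.n_unique_lineages}\n")
    return result
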