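"""Post-run analytics: abundance summaries, control conformity, negative-
control contamination screening and the resource-effectiveness calculator.

Control conformity compares the read ratio of a two-strain mock community
against its known input molar parts, at species level and after rolling
genus-level ("<Genus> sp.") assignments into their strain. Ratios are
printed "x:1" / "1:x" at two decimals, half-up, with the orientation of the
expected mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import GENUS_RANK, RANKS, AbundanceProfile, Kingdom


def _round2(x: float) -> str:
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_ratio(left: float, right: float) -> str:
    """Normalise a pair of counts so the smaller side reads 1, keeping the
    left/right orientation: (34718, 10423) → "3.33:1"; swapped → "1:3.33"."""
    if left <= 0 or right <= 0:
        raise ValueError("ratio requires positive counts on both sides")
    if left >= right:
        return f"{_round2(left / right)}:1"
    return f"1:{_round2(right / left)}"


@dataclass
class ConformityReport:
    barcode: str
    kingdom: Kingdom
    expected_parts: dict[str, float]
    species_counts: dict[str, int]
    rollup_counts: dict[str, int]
    species_ratio: str
    rollup_ratio: Optional[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for taxon, part in self.expected_parts.items():
            rows.append(
                {
                    "barcode": self.barcode,
                    "kingdom": self.kingdom.value,
                    "taxon": taxon,
                    "expected_part": part,
                    "species_reads": self.species_counts.get(taxon, 0),
                    "rollup_reads": self.rollup_counts.get(taxon, 0),
                    "species_ratio": self.species_ratio,
                    "rollup_ratio": self.rollup_ratio or "",
                }
            )
        return pd.DataFrame(rows)


def control_conformity(
    profile: AbundanceProfile,
    expected: Mapping[str, float],
    rollup_names: Mapping[str, str] | None = None,
    extra_counts: Mapping[str, int] | None = None,
) -> ConformityReport:
    """Conformity of a two-strain positive control with its input parts.

    ``expected`` maps the two species names to molar parts, in the
    orientation the ratio should be printed (first-listed name on the left).
    ``rollup_names`` maps genus-level assignment labels (e.g.
    "Trichophyton sp.") to the species they roll into; ``extra_counts`` lets
    externally tabulated genus-level reads be added instead.
    """
    if len(expected) != 2:
        raise ValueError("expected mapping must contain exactly 2 taxa")
    species_counts_all = profile.species_counts(include_unclassified=True)
    names = list(expected)
    counts = {name: species_counts_all.get(name, 0) for name in names}
    if all(c == 0 for c in counts.values()):
        raise ValueError("no reads assigned to either expected control taxon")

    rollup = dict(counts)
    genus_counts = profile.counts_at_rank(GENUS_RANK)
    if rollup_names:
        for label, species in rollup_names.items():
            if species not in rollup:
                continue
            # genus-level reads carry the genus name; species-level reads
            # already counted above must not be double-added
            genus = label.replace(" sp.", "").replace(" sp", "")
            genus_level_only = genus_counts.get(genus, 0) - sum(
                n for s, n in species_counts_all.items()
                if profile_species_genus(s) == genus
            )
            rollup[species] += max(genus_level_only, 0)
    if extra_counts:
        for species, extra in extra_counts.items():
            if species in rollup:
                rollup[species] += extra

    left, right = names
    species_ratio = format_ratio(counts[left], counts[right])
    rollup_ratio = (
        format_ratio(rollup[left], rollup[right])
        if rollup != counts
        else species_ratio
    )
    return ConformityReport(
        barcode=profile.sample_id,
        kingdom=profile.kingdom,
        expected_parts=dict(expected),
        species_counts=counts,
        rollup_counts=rollup,
        species_ratio=species_ratio,
        rollup_ratio=rollup_ratio,
    )


def profile_species_genus(species_name: str) -> str:
    """Genus token of a binomial species name."""
    return species_name.split(" ")[0] if species_name else ""


# ---------------------------------------------------------------------------
# Abundance summaries
# ---------------------------------------------------------------------------


def top_taxa_table(
    profiles: Sequence[AbundanceProfile],
    rank: str = "species",
    top_n: int = 10,
    denominator: str = "assigned",
) -> pd.DataFrame:
    """Per-sample relative proportions of the top-N taxa at ``rank``.

    Taxa are ranked by cumulative reads across samples (ties alphabetical).
    ``denominator`` selects "assigned" (reads assigned at any rank) or
    "total" (assigned + unassigned) as the proportion base; both views are
    legitimate and differ when many reads fail the confidence cutoff.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    per_sample: dict[str, dict[str, int]] = {}
    denominators: dict[str, int] = {}
    cumulative: dict[str, int] = {}
    for p in profiles:
        counts = {
            k: v
            for k, v in p.counts_at_rank(rank).items()
            if not k.startswith("unclassified")
        }
        per_sample[p.sample_id] = counts
        denominators[p.sample_id] = (
            p.total_assigned if denominator == "assigned" else p.total_reads
        )
        for taxon, n in counts.items():
            cumulative[taxon] = cumulative.get(taxon, 0) + n
    ranked = sorted(cumulative.items(), key=lambda t: (-t[1], t[0]))[:top_n]
    rows = []
    for taxon, cum in ranked:
        row: dict[str, object] = {"taxon": taxon, "rank": rank, "cumulative_reads": cum}
        for sample_id in sorted(per_sample):
            denom = denominators[sample_id]
            row[sample_id] = (
                per_sample[sample_id].get(taxon, 0) / denom if denom else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def lineage_export(
    profiles: Sequence[AbundanceProfile],
    min_prop: float = 0.0001,
    rank: str = "genus",
) -> pd.DataFrame:
    """Lineage table of taxa reaching ``min_prop`` of assigned reads overall
    (default 0.01%), the input a cladogram renderer consumes."""
    cumulative: dict[str, int] = {}
    lineage_of: dict[str, tuple[str, ...]] = {}
    total = 0
    r = RANKS.index(rank)
    for p in profiles:
        total += p.total_assigned
        for (tax_id, ar), n in p.counts.items():
            if ar < r:
                continue
            lin = p.lineages[tax_id]
            name = lin.name_at(r) or "unclassified"
            cumulative[name] = cumulative.get(name, 0) + n
            lineage_of.setdefault(name, lin.prefix(r))
    rows = [
        {
            "taxon": name,
            "reads": n,
            "proportion": n / total,
            "lineage": ";".join(lineage_of[name]),
        }
        for name, n in sorted(cumulative.items(), key=lambda t: (-t[1], t[0]))
        if total and n / total >= min_prop
    ]
    return pd.DataFrame(rows)


def contamination_screen(
    nc_profiles: Sequence[AbundanceProfile],
    sample_profiles: Sequence[AbundanceProfile],
    dominance_threshold: float = 0.01,
) -> pd.DataFrame:
    """Overlap between negative-control taxa and the sample communities.

    Each taxon seen in a negative control is listed with its NC read count
    and flagged when it is also dominant (relative abundance ≥ threshold of
    assigned reads) in at least one sample — the pattern that distinguishes
    true members from reagent contaminants.
    """
    if not nc_profiles:
        raise ValueError("at least one negative-control profile is required")
    dominant_in: dict[str, list[str]] = {}
    for p in sample_profiles:
        denom = p.total_assigned
        if not denom:
            continue
        for name, n in p.species_counts().items():
            if n / denom >= dominance_threshold:
                dominant_in.setdefault(name, []).append(p.sample_id)
    rows = []
    for p in nc_profiles:
        for name, n in sorted(p.species_counts().items()):
            samples = dominant_in.get(name, [])
            rows.append(
                {
                    "nc_sample": p.sample_id,
                    "kingdom": p.kingdom.value,
                    "taxon": name,
                    "nc_reads": n,
                    "flagged": bool(samples),
                    "dominant_in": ",".join(sorted(samples)),
                }
            )
        rows.append(
            {
                "nc_sample": p.sample_id,
                "kingdom": p.kingdom.value,
                "taxon": "__total__",
                "nc_reads": p.total_reads,
                "flagged": False,
                "dominant_in": "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["nc_sample", "kingdom", "taxon", "nc_reads", "flagged", "dominant_in"],
    )


# ---------------------------------------------------------------------------
# Resource-effectiveness calculator
# ---------------------------------------------------------------------------


@dataclass
class ResourceTable:
    """Quantified savings of ensembling A amplicon types and pooling negative
    controls (2 sequenced out of N maintained)."""

    n_amplicon_types: int
    n_negative_controls: int
    ensembling_fraction: float       # 1/A of per-kingdom reagents & flow cells
    negative_control_fraction: float  # 2/N of control sequencing slots
    input_scale: float
    spike_fractions: dict[str, float]   # unrounded, sum to 1
    spike_percent_display: dict[str, int]  # rounded for display

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "ensembling_fraction", "value": self.ensembling_fraction,
             "display": f"1/{self.n_amplicon_types} ({self.ensembling_fraction:.0%})"},
            {"quantity": "negative_control_fraction",
             "value": self.negative_control_fraction,
             "display": f"2/{self.n_negative_controls} (~{self.negative_control_fraction:.0%})"},
            {"quantity": "input_scale", "value": self.input_scale,
             "display": f"{self.input_scale:g}"},
        ]
        for name, frac in self.spike_fractions.items():
            rows.append(
                {"quantity": f"spike_{name}", "value": frac,
                 "display": f"{self.spike_percent_display[name]}%"}
            )
        return pd.DataFrame(rows)


def resource_calculator(
    A: int,
    N: int,
    input_scale: float = 1.0,
    molar_amounts: Mapping[str, float] | None = None,
) -> ResourceTable:
    """Resource fractions for an A-amplicon ensemble with N negative controls.

    Ensembling uses 1/A of per-amplicon reagents and flow cells; the pooled
    negative-control strategy sequences 2 of N maintained controls (one pool,
    one individual). Spike percentages split the pool by molar amount.
    """
    if A < 1 or N < 1:
        raise ValueError("A and N must be >= 1")
    molar_amounts = dict(molar_amounts or {})
    if any(v <= 0 for v in molar_amounts.values()):
        raise ValueError("molar amounts must be positive")
    total = sum(molar_amounts.values())
    fractions = {k: v / total for k, v in molar_amounts.items()} if total else {}
    display = {k: int(Decimal(repr(100 * f)).quantize(0, rounding=ROUND_HALF_UP))
               for k, f in fractions.items()}
    return ResourceTable(
        n_amplicon_types=A,
        n_negative_controls=N,
        ensembling_fraction=1.0 / A,
        negative_control_fraction=2.0 / N,
        input_scale=input_scale,
        spike_fractions=fractions,
        spike_percent_display=display,
    )
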