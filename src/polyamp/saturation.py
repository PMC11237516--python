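"""Analytic rarefaction, Chao1 extrapolation and the windowed run-stop rule.

Species saturation per barcode and kingdom is monitored on accumulation
windows — one window per batch of newly written reads ("pore-scan"). For a
count vector (n_1, …, n_S) with n = Σ n_i the classical analytic rarefaction

    E[S(m)] = S_obs − Σ_i C(n − n_i, m) / C(n, m)

gives the expected richness of an m-read subsample (computed in log-space);
the bias-corrected Chao1 estimator

    Ŝ = S_obs + f1 (f1 − 1) / (2 (f2 + 1))

(f1 singletons, f2 doubletons) anchors the extrapolation beyond n. A sample
is saturated when, over the last W windows, observed richness grew by at
most eps_abs species and the Chao1 asymptote by at most a fraction eps_rel;
the run-stop recommendation fires when a majority of eligible (non-control)
barcodes is saturated for both kingdoms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .io import AbundanceProfile, Kingdom


@dataclass(frozen=True)
class CountVector:
    """Multiset of per-species read counts."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts):
            raise ValueError("species counts must be positive")

    @classmethod
    def from_counts(cls, counts: Iterable[int]) -> "CountVector":
        return cls(tuple(int(c) for c in counts))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "CountVector":
        return cls.from_counts(v for v in mapping.values() if v > 0)

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def f1(self) -> int:
        return sum(1 for c in self.counts if c == 1)

    @property
    def f2(self) -> int:
        return sum(1 for c in self.counts if c == 2)


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(cv: CountVector, m: int) -> float:
    """Expected species richness of an m-read random subsample (m ≤ n)."""
    n = cv.n
    if not (1 <= m <= n):
        raise ValueError(f"m must be in [1, n={n}]; use extrapolate for m > n")
    counts = np.asarray(cv.counts, dtype=np.float64)
    keep = (n - counts) >= m  # species that can be entirely missed
    if not keep.any():
        return float(cv.s_obs)
    nn = n - counts[keep]
    log_terms = _log_comb(nn, m) - _log_comb(float(n), m)
    return float(cv.s_obs - np.exp(log_terms).sum())


def chao1(cv: CountVector) -> float:
    """Bias-corrected Chao1 asymptotic richness estimate."""
    if cv.n < 1:
        raise ValueError("chao1 requires at least one read")
    f1, f2 = cv.f1, cv.f2
    if f1 == 0:
        return float(cv.s_obs)
    return float(cv.s_obs + f1 * (f1 - 1) / (2 * (f2 + 1)))


def extrapolate(cv: CountVector, m: int) -> float:
    """Expected richness at a sample size m > n (Chao1-anchored)."""
    n = cv.n
    if m <= n:
        raise ValueError("extrapolate requires m > n; use rarefy otherwise")
    f1 = cv.f1
    if f1 == 0:
        return float(cv.s_obs)
    m_star = m - n
    f0_hat = chao1(cv) - cv.s_obs
    return float(
        cv.s_obs + f0_hat * (1.0 - (1.0 - f1 / (n * f0_hat + f1)) ** m_star)
    )


@dataclass
class RarefactionCurve:
    grid: tuple[int, ...]
    expected_richness: tuple[float, ...]
    extrapolated: tuple[bool, ...]


def rarefaction_curve(cv: CountVector, grid: Sequence[int]) -> RarefactionCurve:
    """Interpolated + extrapolated richness curve over ``grid`` sample sizes."""
    grid = tuple(sorted(int(m) for m in grid))
    values, flags = [], []
    for m in grid:
        if m <= cv.n:
            values.append(rarefy(cv, m))
            flags.append(False)
        else:
            values.append(extrapolate(cv, m))
            flags.append(True)
    return RarefactionCurve(grid, tuple(values), tuple(flags))


class SaturationStatus(str, Enum):
    saturated = "saturated"
    gaining = "gaining"
    insufficient_reads = "insufficient_reads"


@dataclass(frozen=True)
class SaturationParams:
    """Thresholds of the windowed stop rule (all configurable, all logged)."""

    window_span: int = 3       # W consecutive accumulation windows
    min_reads: int = 500       # below this a barcode is not yet assessable
    epsilon_abs: float = 1.0   # tolerated new species over the window span
    epsilon_rel: float = 0.01  # tolerated relative Chao1 asymptote gain
    majority_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.window_span < 2:
            raise ValueError("window_span must be >= 2")
        if not (0 < self.majority_frac <= 1):
            raise ValueError("majority_frac must be in (0, 1]")


@dataclass
class AccumulationState:
    """Windowed per-barcode, per-kingdom richness history."""

    barcode: str
    kingdom: Kingdom
    species_counts: Counter = field(default_factory=Counter)
    s_obs_history: list[int] = field(default_factory=list)
    chao1_history: list[float] = field(default_factory=list)
    reads_history: list[int] = field(default_factory=list)

    @property
    def windows_seen(self) -> int:
        return len(self.s_obs_history)

    @property
    def cumulative_reads(self) -> int:
        return self.reads_history[-1] if self.reads_history else 0

    @property
    def count_vector(self) -> CountVector:
        return CountVector.from_mapping(self.species_counts)


def update_accumulation(
    state: AccumulationState, batch_profile: AbundanceProfile
) -> AccumulationState:
    """Merge one batch's species counts into the cumulative state and append
    a new window to the histories. An empty batch repeats the last values."""
    if batch_profile.kingdom != state.kingdom:
        raise ValueError("batch kingdom does not match accumulation state")
    state.species_counts.update(batch_profile.species_counts())
    batch_reads = batch_profile.total_reads
    cum_reads = state.cumulative_reads + batch_reads
    cv = state.count_vector
    if cv.s_obs:
        state.s_obs_history.append(cv.s_obs)
        state.chao1_history.append(chao1(cv))
    else:
        state.s_obs_history.append(0)
        state.chao1_history.append(0.0)
    state.reads_history.append(cum_reads)
    return state


def is_saturated(
    state: AccumulationState, params: SaturationParams = SaturationParams()
) -> SaturationStatus:
    """Windowed decision: saturated iff over the last W windows richness grew
    by ≤ epsilon_abs species and the Chao1 asymptote by ≤ epsilon_rel."""
    if state.cumulative_reads < params.min_reads:
        return SaturationStatus.insufficient_reads
    W = params.window_span
    if state.windows_seen < W:
        return SaturationStatus.gaining
    delta_s = state.s_obs_history[-1] - state.s_obs_history[-W]
    chao_then = state.chao1_history[-W]
    chao_now = state.chao1_history[-1]
    rel_gain = (chao_now - chao_then) / chao_then if chao_then > 0 else 0.0
    if delta_s <= params.epsilon_abs and rel_gain <= params.epsilon_rel:
        return SaturationStatus.saturated
    return SaturationStatus.gaining


@dataclass
class StopDecision:
    stop: bool
    fraction_saturated: float
    per_barcode: dict[str, dict[Kingdom, SaturationStatus]]
    least_accumulated: list[tuple[str, int]]  # (barcode, cumulative reads) ascending


def stop_recommendation(
    states: Sequence[AccumulationState],
    params: SaturationParams = SaturationParams(),
    eligible_barcodes: Optional[Sequence[str]] = None,
    n_least: int = 5,
) -> StopDecision:
    """Run-level stop rule over all barcodes.

    Stop iff the fraction of eligible barcodes saturated for *both* kingdoms
    reaches majority_frac; controls are excluded by passing the subject
    barcodes as ``eligible_barcodes``. The report lists the barcodes with the
    fewest accumulated reads, the ones that gate the decision in practice.
    """
    per_barcode: dict[str, dict[Kingdom, SaturationStatus]] = {}
    reads_per_barcode: Counter = Counter()
    for st in states:
        per_barcode.setdefault(st.barcode, {})[st.kingdom] = is_saturated(st, params)
        reads_per_barcode[st.barcode] += st.cumulative_reads
    eligible = (
        list(eligible_barcodes) if eligible_barcodes is not None else sorted(per_barcode)
    )
    n_sat = sum(
        1
        for bc in eligible
        if per_barcode.get(bc)
        and all(
            s == SaturationStatus.saturated for s in per_barcode[bc].values()
        )
        and len(per_barcode[bc]) >= 1
    )
    frac = n_sat / len(eligible) if eligible else 0.0
    least = sorted(
        ((bc, reads_per_barcode.get(bc, 0)) for bc in eligible), key=lambda t: (t[1], t[0])
    )[:n_least]
    return StopDecision(
        stop=frac >= params.majority_frac,
        fraction_saturated=frac,
        per_barcode=per_barcode,
        least_accumulated=least,
    )
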