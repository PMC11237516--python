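"""Kingdom segregation by degenerate-primer matching, trimming and filtering.

A multi-kingdom amplicon pool mixes ~1.5 kb bacterial 16S amplicons
(27F/1492R) and ~0.6 kb fungal ITS amplicons (ITS1/ITS4) in one library.
Each read is assigned to a kingdom by locating the primers at the read ends
with a semi-global edit-distance alignment in which IUPAC degenerate codes
match any base of their set at zero cost. Matched primers are trimmed off and
the retained insert passes length, tail-truncation and mean-quality filters.

The matcher is exact: it minimises unit-cost edit distance with the primer
fully aligned, breaking ties by smaller start and then shorter span. The
inner dynamic program is JIT-compiled with numba when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .io import Kingdom, Read

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@lru_cache(maxsize=1024)
def _rc_cached(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: Default primer panel: full-length 16S (27F/1492R) and the inner nested
#: ITS pair (ITS1/ITS4) that flanks the sequenced fungal amplicon.
PRIMER_16S_FWD = "AGRGTTYGATYMTGGCTCAG"   # 27F
PRIMER_16S_REV = "CGGYTACCTTGTTACGACTT"   # 1492R
PRIMER_ITS_FWD = "TCCGTAGGTGAACCTGCGG"    # ITS1
PRIMER_ITS_REV = "TCCTCCGCTTATTGATATGC"   # ITS4


@dataclass(frozen=True)
class PrimerSet:
    name: str
    forward: str
    reverse: str
    kingdom: Kingdom

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if not primer:
                raise ValueError("primers must be non-empty")
            bad = set(primer) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC characters in primer: {sorted(bad)}")


def default_primer_sets() -> list[PrimerSet]:
    return [
        PrimerSet("16S", PRIMER_16S_FWD, PRIMER_16S_REV, Kingdom.bacteria),
        PrimerSet("ITS", PRIMER_ITS_FWD, PRIMER_ITS_REV, Kingdom.fungi),
    ]


class Orientation(str, Enum):
    fwd_at_5p = "fwd_at_5p"
    rc_rev_at_3p = "rc_rev_at_3p"


class RejectReason(str, Enum):
    no_primer = "no_primer"
    conflict = "conflict"
    too_short = "too_short"
    too_long = "too_long"
    low_quality = "low_quality"


class Verdict(str, Enum):
    amplicon_16S = "amplicon_16S"
    amplicon_ITS = "amplicon_ITS"
    unassigned = "unassigned"


@dataclass(frozen=True)
class PrimerHit:
    primer_name: str
    orientation: Orientation
    start: int
    end: int
    edit_distance: int


@dataclass(frozen=True)
class KingdomCall:
    read_id: str
    verdict: Verdict
    hits: tuple[PrimerHit, ...] = ()
    trim_span: Optional[tuple[int, int]] = None
    reject_reason: Optional[RejectReason] = None
    flipped: bool = False  # True when the reverse primer leads the raw read

    @property
    def kingdom(self) -> Optional[Kingdom]:
        return {
            Verdict.amplicon_16S: Kingdom.bacteria,
            Verdict.amplicon_ITS: Kingdom.fungi,
        }.get(self.verdict)


@dataclass(frozen=True)
class FilterParams:
    """Length/quality filters applied to the trimmed insert.

    Defaults follow the workflow's post-basecalling preprocessing: retain
    200–3,500 nt, truncate 3' tails to 1,550 nt, require arithmetic mean
    phred ≥ 20.
    """

    min_len: int = 200
    max_len: int = 3500
    trunc_len: int = 1550
    min_mean_q: float = 20.0
    max_err_frac: float = 0.2
    search_window: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.trunc_len <= 0 or self.min_mean_q < 0:
            raise ValueError("trunc_len must be positive and min_mean_q >= 0")
        if not (0 <= self.max_err_frac < 0.5):
            raise ValueError("max_err_frac must be in [0, 0.5)")

    def max_err_for(self, primer: str) -> int:
        return math.ceil(self.max_err_frac * len(primer))


@dataclass(frozen=True)
class ProcessedRead:
    """A retained read: trimmed insert in forward-primer-first orientation."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    barcode: str
    kingdom: Kingdom
    mean_quality: float


# ---------------------------------------------------------------------------
# Semi-global IUPAC edit-distance matching
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 4, dtype=np.uint8)  # 4 == "other"
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@lru_cache(maxsize=256)
def _primer_match_table(primer: str) -> np.ndarray:
    """(len(primer), 5) boolean table: row i true for base codes matched."""
    table = np.zeros((len(primer), 5), dtype=bool)
    for i, code in enumerate(primer):
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC character {code!r} in primer")
        for b in IUPAC[code]:
            table[i, _BASE_CODE[ord(b)]] = True
        if code == "N":
            table[i, 4] = True  # N in the primer also matches an N base call
    return table


def _dp_python(sub: np.ndarray) -> tuple[int, int, int]:
    m, n = sub.shape
    INF = 10**9
    dist = np.zeros(n + 1, dtype=np.int64)
    start = np.arange(n + 1, dtype=np.int64)
    for i in range(m):
        ndist = np.empty(n + 1, dtype=np.int64)
        nstart = np.empty(n + 1, dtype=np.int64)
        ndist[0] = i + 1
        nstart[0] = 0
        for j in range(1, n + 1):
            best = dist[j - 1] + sub[i, j - 1]
            bs = start[j - 1]
            d = dist[j] + 1
            if d < best or (d == best and start[j] < bs):
                best, bs = d, start[j]
            d = ndist[j - 1] + 1
            if d < best or (d == best and nstart[j - 1] < bs):
                best, bs = d, nstart[j - 1]
            ndist[j] = best
            nstart[j] = bs
        dist, start = ndist, nstart
    j_best, d_best, s_best = -1, INF, INF
    for j in range(n + 1):
        if dist[j] < d_best:
            d_best, s_best, j_best = dist[j], start[j], j
        elif dist[j] == d_best and start[j] < s_best:
            s_best, j_best = start[j], j
        # equal distance and equal minimal start: keep the earlier (shorter) end
    return int(d_best), int(s_best), int(j_best)


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _dp_core = njit(cache=True)(_dp_python)
except Exception:  # pragma: no cover
    _dp_core = _dp_python


def match_primer(
    bases: str,
    primer: str,
    max_err: int,
    window: tuple[int, int] | None = None,
    orientation: Orientation = Orientation.fwd_at_5p,
    primer_name: str = "",
) -> Optional[PrimerHit]:
    """Best semi-global alignment of ``primer`` within ``bases[window]``.

    The primer must align end-to-end against a read substring; IUPAC codes in
    the primer match every base of their set at zero cost. Returns the hit
    with minimal edit distance (ties: smaller start, then shorter span), or
    ``None`` if the minimum exceeds ``max_err``.
    """
    lo, hi = window if window is not None else (0, len(bases))
    if not (0 <= lo <= hi <= len(bases)):
        raise ValueError(f"window {window} outside read bounds [0, {len(bases)}]")
    table = _primer_match_table(primer)
    text = _BASE_CODE[np.frombuffer(bases[lo:hi].encode("ascii"), dtype=np.uint8)]
    if text.size == 0:
        return None
    sub = (~table[:, text]).astype(np.int64)
    d, s, e = _dp_core(sub)
    if d > max_err:
        return None
    return PrimerHit(primer_name or primer, orientation, lo + s, lo + e, d)


# ---------------------------------------------------------------------------
# Kingdom assignment
# ---------------------------------------------------------------------------


def _search_set(
    bases: str, pset: PrimerSet, params: FilterParams
) -> tuple[list[PrimerHit], list[PrimerHit]]:
    """Hits for one primer set, split into forward- and flipped-orientation
    evidence on the raw read.

    Forward orientation: forward primer at the 5' window, reverse-complement
    of the reverse primer at the 3' window. A flipped read shows the reverse
    primer at 5' and the reverse-complement of the forward primer at 3'.
    """
    L = len(bases)
    w = params.search_window
    fwd_hits: list[PrimerHit] = []
    flip_hits: list[PrimerHit] = []
    searches = [
        (pset.forward, (0, min(L, w + len(pset.forward))), Orientation.fwd_at_5p,
         f"{pset.name}-fwd", fwd_hits),
        (_rc_cached(pset.reverse),
         (max(0, L - w - len(pset.reverse)), L), Orientation.rc_rev_at_3p,
         f"{pset.name}-rev", fwd_hits),
        (pset.reverse, (0, min(L, w + len(pset.reverse))), Orientation.fwd_at_5p,
         f"{pset.name}-rev", flip_hits),
        (_rc_cached(pset.forward),
         (max(0, L - w - len(pset.forward)), L), Orientation.rc_rev_at_3p,
         f"{pset.name}-fwd", flip_hits),
    ]
    for primer, window, orient, name, sink in searches:
        max_err = params.max_err_for(primer)
        hit = match_primer(bases, primer, max_err, window, orient, name)
        if hit is not None:
            sink.append(hit)
    return fwd_hits, flip_hits


def assign_kingdom(
    read: Read,
    primer_sets: Sequence[PrimerSet] | None = None,
    params: FilterParams = FilterParams(),
) -> KingdomCall:
    """Segregate one read into 16S / ITS / unassigned by primer evidence.

    A primer set supports the read if at least one of its primers hits within
    its error budget. A unique supporting set decides the verdict; when
    several support, the set with more distinct primer hits wins, ties broken
    by lower total edit distance and otherwise reported as a conflict.
    """
    if primer_sets is None:
        primer_sets = default_primer_sets()
    if not primer_sets:
        raise ValueError("primer_sets must be non-empty")

    per_set: list[tuple[PrimerSet, list[PrimerHit], bool]] = []
    for pset in primer_sets:
        fwd_hits, flip_hits = _search_set(read.bases, pset, params)
        # orientation with more hits, ties by lower total edit distance
        fkey = (len(fwd_hits), -sum(h.edit_distance for h in fwd_hits))
        rkey = (len(flip_hits), -sum(h.edit_distance for h in flip_hits))
        hits, flipped = (fwd_hits, False) if fkey >= rkey else (flip_hits, True)
        if hits:
            per_set.append((pset, hits, flipped))

    if not per_set:
        return KingdomCall(read.read_id, Verdict.unassigned,
                           reject_reason=RejectReason.no_primer)
    if len(per_set) > 1:
        per_set.sort(
            key=lambda t: (-len(t[1]), sum(h.edit_distance for h in t[1]))
        )
        (s0, h0, _), (s1, h1, _) = per_set[0], per_set[1]
        if len(h0) == len(h1) and (
            sum(h.edit_distance for h in h0) == sum(h.edit_distance for h in h1)
        ):
            return KingdomCall(
                read.read_id,
                Verdict.unassigned,
                hits=tuple(h0 + h1),
                reject_reason=RejectReason.conflict,
            )
    pset, hits, flipped = per_set[0]

    trim_start = max((h.end for h in hits if h.orientation == Orientation.fwd_at_5p),
                     default=0)
    trim_end = min((h.start for h in hits if h.orientation == Orientation.rc_rev_at_3p),
                   default=len(read))
    trim_end = max(trim_end, trim_start)
    verdict = (
        Verdict.amplicon_16S if pset.kingdom == Kingdom.bacteria else Verdict.amplicon_ITS
    )
    return KingdomCall(
        read.read_id,
        verdict,
        hits=tuple(hits),
        trim_span=(trim_start, trim_end),
        flipped=flipped,
    )


def trim_and_filter(
    read: Read,
    call: KingdomCall,
    params: FilterParams = FilterParams(),
) -> ProcessedRead | KingdomCall:
    """Cut to the insert, canonicalise orientation and apply filters.

    Order: (1) cut to trim_span, (2) length gate [min_len, max_len],
    (3) truncate the 3' tail (forward-primer-proximal end kept) to trunc_len,
    (4) arithmetic mean phred gate. Returns the retained ProcessedRead or a
    KingdomCall carrying the rejection reason.
    """
    if call.verdict == Verdict.unassigned:
        raise ValueError("trim_and_filter requires an assigned read")
    start, end = call.trim_span
    bases = read.bases[start:end]
    quals = read.quals[start:end]
    if call.flipped:
        bases = reverse_complement(bases)
        quals = quals[::-1]
    if len(bases) < params.min_len:
        return replace(call, verdict=Verdict.unassigned,
                       reject_reason=RejectReason.too_short)
    if len(bases) > params.max_len:
        return replace(call, verdict=Verdict.unassigned,
                       reject_reason=RejectReason.too_long)
    if len(bases) > params.trunc_len:
        bases = bases[: params.trunc_len]
        quals = quals[: params.trunc_len]
    mean_q = float(np.mean(quals))
    if mean_q < params.min_mean_q:
        return replace(call, verdict=Verdict.unassigned,
                       reject_reason=RejectReason.low_quality)
    return ProcessedRead(
        read_id=read.read_id,
        bases=bases,
        quals=tuple(quals),
        barcode=read.barcode,
        kingdom=call.kingdom,
        mean_quality=mean_q,
    )


def load_primer_tsv(path) -> list[PrimerSet]:
    """Primer panel from a TSV with columns name, kingdom, forward, reverse."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PrimerSet(row["name"], row["forward"], row["reverse"], Kingdom(row["kingdom"]))
        for _, row in df.iterrows()
    ]
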