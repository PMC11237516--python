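"""Independent brute-force oracles shared by unit and acceptance tests."""

from polyamp.segregate import IUPAC


def lev_iupac(primer: str, text: str) -> int:
    """Plain Levenshtein DP; IUPAC codes in the primer match free."""
    m, n = len(primer), len(text)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        allowed = IUPAC[primer[i - 1]]
        for j in range(1, n + 1):
            cost = 0 if text[j - 1] in allowed else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[n]


def brute_force_match(bases: str, primer: str, max_err: int):
    """Exhaustive enumeration over all read substrings; ties resolved by
    (distance, start, span) lexicographic order."""
    best = None
    for s in range(len(bases) + 1):
        for e in range(s, len(bases) + 1):
            key = (lev_iupac(primer, bases[s:e]), s, e - s)
            if best is None or key < best:
                best = key
    d, s, span = best
    return None if d > max_err else (d, s, s + span)
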