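"""Independent reference implementations used only to check the package.

Each oracle is written as plainly as possible (pure-Python loops, tuple
maxima, explicit enumeration) and stays independent of the code paths it
validates.
"""

from __future__ import annotations

from functools import lru_cache

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


def align_oracle(a: str, b: str) -> tuple[float, int]:
    """(score, identities) of an optimal global alignment, match +1,
    mismatch 0, gap -0.5, end gaps free; among co-optimal alignments the
    highest identity count is reported. Plain tuple-valued DP."""
    n, m = len(a), len(b)
    NEG = (float("-inf"), 0)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[float, int]:
        # best (score, identities) of an alignment of a[:i] and b[:j] whose
        # leading gaps are free (any prefix of either may hang unaligned)
        if i == 0 or j == 0:
            return (0.0, 0)
        options = [(0.0, 0)]  # treat a[:i] / b[:j] entirely as leading gap
        s, ident = best(i - 1, j - 1)
        match = a[i - 1] == b[j - 1] and a[i - 1] in CANONICAL
        options.append((s + (1.0 if match else 0.0), ident + (1 if match else 0)))
        s, ident = best(i - 1, j)
        options.append((s - 0.5, ident))
        s, ident = best(i, j - 1)
        options.append((s - 0.5, ident))
        return max(options)

    # free trailing gaps: any suffix of either sequence may hang unaligned
    out = max(best(i, m) for i in range(n + 1))
    out = max(out, max(best(n, j) for j in range(m + 1)))
    best.cache_clear()
    return out


def scan_oracle(sequence: str, notation: str) -> list[tuple[int, int, str]]:
    """All overlapping motif occurrences by naive token-by-token matching.
    Returns (start, end, matched) with 1-based inclusive coordinates."""
    # expand the notation into per-position checks
    checks: list[str | None] = []  # residue letter, or None for wildcard
    i = 0
    while i < len(notation):
        c = notation[i]
        if c == "x":
            if i + 1 < len(notation) and notation[i + 1] == "(":
                close = notation.index(")", i)
                checks.extend([None] * int(notation[i + 2 : close]))
                i = close + 1
            else:
                checks.append(None)
                i += 1
        else:
            checks.append(c)
            i += 1
    span = len(checks)
    hits = []
    for start in range(len(sequence) - span + 1):
        window = sequence[start : start + span]
        ok = all(c is None or c == r for c, r in zip(checks, window))
        if ok:
            hits.append((start + 1, start + span, window))
    return hits


def percentile_oracle(raw: float, background: list[float]) -> float:
    count = 0
    for b in background:
        if b > raw:
            count += 1
    return 100.0 * count / len(background)


def pareto_oracle(points: dict[str, tuple[float, ...]]) -> set[str]:
    """Non-dominated ids under joint minimization, by exhaustive comparison."""
    front = set()
    for pid, p in points.items():
        dominated = False
        for qid, q in points.items():
            if qid == pid:
                continue
            if all(qk <= pk for qk, pk in zip(q, p)) and any(
                qk < pk for qk, pk in zip(q, p)
            ):
                dominated = True
                break
        if not dominated:
            front.add(pid)
    return front


def best_frame_oracle(weights, window: str) -> tuple[float, int]:
    """Best 9-mer frame of a 15-mer by explicit enumeration of all 7 frames."""
    best_score, best_off = None, None
    for off in range(7):
        core = window[off : off + 9]
        score = sum(weights[p][CANONICAL.index(core[p])] for p in range(9))
        if best_score is None or score > best_score:
            best_score, best_off = score, off
    return best_score, best_off
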