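"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a pipeline quantity by the most direct route —
full-matrix dynamic programming, exhaustive enumeration, sliding-window
scanning — with no code shared with the package internals it checks.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def naive_local_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                      gap_open: float = -5.0, gap_extend: float = -2.0) -> float:
    """Full-matrix affine-gap Smith-Waterman score (Gotoh, O(nm) loops).

    The first position of a gap scores ``gap_open``, each further position
    ``gap_extend``.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def brute_longest_orf(seq: str) -> tuple[int, int, int] | None:
    """Enumerate every ATG in every forward frame and scan to its in-frame stop.

    Returns ``(aa_length, start, frame)`` of the best ORF under the same
    tie-break (longest, then leftmost start, then lowest frame), or None.
    """
    stops = {"TAA", "TAG", "TGA"}
    calls = []
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos:pos + 3] in stops:
                calls.append(((pos - start) // 3, start, start % 3))
                break
    if not calls:
        return None
    return max(calls, key=lambda c: (c[0], -c[1], -c[2]))


def brute_bh(p_values: list[float]) -> list[float]:
    """BH adjusted p-values by scanning every candidate rejection level.

    The adjusted value of p_i is the smallest level alpha (drawn from the
    finite set of step-up cutoffs) at which the BH *procedure* rejects i.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    candidate_alphas = sorted({min(1.0, m * p_values[i] / (r + 1))
                               for r, i in enumerate(order)} | {1.0})

    def rejected_at(alpha: float) -> set[int]:
        # the 1e-12 guards the float round-trip p -> alpha=m*p/r -> r*alpha/m
        k = 0
        for r, i in enumerate(order, start=1):
            if p_values[i] <= r * alpha / m + 1e-12:
                k = r
        return {order[r] for r in range(k)}

    adjusted = [1.0] * m
    for i in range(m):
        for alpha in candidate_alphas:
            if i in rejected_at(alpha):
                adjusted[i] = alpha
                break
    return adjusted


def scan_occurrences(haystack: str, needle: str) -> list[int]:
    """Sliding-window exact substring scan."""
    return [i for i in range(len(haystack) - len(needle) + 1)
            if haystack[i:i + len(needle)] == needle]


def brute_positional(t_start: int, t_end: int, t_strand: str,
                     genes: list[tuple[str, int, int, str]]) -> str:
    """Positional label by testing every (transcript, gene) pair directly.

    ``genes`` are (gene_id, start, end, strand) on the transcript's
    chromosome; intervals half-open.
    """
    overlapping = [(gid, s, e, st) for gid, s, e, st in genes
                   if min(t_end, e) - max(t_start, s) > 0]
    if not overlapping:
        return "intergenic"
    same = [g for g in overlapping if g[3] == t_strand]
    if not same:
        return "antisense"
    if any(s <= t_start and t_end <= e for _, s, e, _ in same):
        return "intragenic"
    return "overlapping"
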