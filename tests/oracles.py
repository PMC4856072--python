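"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation's code paths: direct
enumeration, full dynamic programming, and position-set arithmetic.
"""

from itertools import combinations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHA = str(_B62.alphabet)


def sub_score(a: str, b: str) -> float:
    if a not in _B62_ALPHA:
        a = "X"
    if b not in _B62_ALPHA:
        b = "X"
    return float(_B62[a, b])


def gotoh_local_score(a: str, b: str, open_cost: float = 12.0,
                      extend_cost: float = 1.0) -> float:
    """Full-matrix affine local alignment score (gap of length k costs
    ``open_cost + (k-1) * extend_cost``)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + sub_score(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_stop_to_stop(sequence: str, stop_codons: set) -> set:
    """All circular maximal stop-to-stop segments as (start0, n_codons).

    A segment opens at position p (0-based) when the circular codon three
    bases upstream is a stop and the codon at p is not; it extends codon by
    codon until the next stop.  Openings with no stop within one genome
    length are discarded (the cap rule).
    """
    L = len(sequence)

    def codon(p):
        return "".join(sequence[(p + k) % L] for k in range(3))

    segments = set()
    for p in range(L):
        if codon((p - 3) % L) not in stop_codons or codon(p) in stop_codons:
            continue
        n = 0
        q = p
        while n <= L // 3:
            if codon(q) in stop_codons:
                break
            n += 1
            q = (q + 3) % L
        else:
            continue
        if codon(q) in stop_codons and n <= L // 3:
            segments.add((p, n))
    return segments


def rotations_equal(a: tuple, b: tuple) -> bool:
    if len(a) != len(b):
        return False
    return any(b == a[i:] + a[:i] for i in range(max(1, len(a))))


def min_trna_deletion(order_a: list, order_b: list, trnas: list,
                      max_k: int = 3):
    """Exhaustive minimal deletion-set search over *all* tRNA subsets."""
    for k in range(max_k + 1):
        for sub in combinations(sorted(trnas), k):
            drop = set(sub)
            ra = tuple(x for x in order_a if x not in drop)
            rb = tuple(x for x in order_b if x not in drop)
            if rotations_equal(ra, rb):
                return k, drop
    return max_k + 1, None


def kd_segments_by_position_union(protein: str, kd: dict, window: int,
                                  threshold: float) -> list:
    """Transmembrane segments as maximal runs of the union of hit windows."""
    n = len(protein)
    vals = [kd.get(c, 0.0) for c in protein.upper()]
    covered = set()
    for i in range(n - window + 1):
        if sum(vals[i : i + window]) / window >= threshold - 1e-9:
            covered.update(range(i, i + window))
    if not covered:
        return []
    segs = []
    pos = sorted(covered)
    s = prev = pos[0]
    for p in pos[1:]:
        if p == prev + 1:
            prev = p
        else:
            segs.append((s + 1, prev + 1))
            s = prev = p
    segs.append((s + 1, prev + 1))
    return segs
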