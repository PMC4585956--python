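"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration, exact rational arithmetic, all-pairs scans) and share no code
with the implementation paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def brute_force_longest_orf(sequence: str):
    """Enumerate every ATG in every frame of both strands; return the
    (frame, start, aa_length, has_stop) of the maximal ORF with ties broken
    by frame order then start."""
    seq = sequence.upper()
    best = ("+1", 0, 0, False)
    for frame in ("+1", "+2", "+3", "-1", "-2", "-3"):
        s = seq if frame[0] == "+" else revcomp(seq)
        offset = int(frame[1]) - 1
        limit = offset + ((len(s) - offset) // 3) * 3 if len(s) >= offset else offset
        for start in range(offset, max(limit - 2, offset), 3):
            if s[start : start + 3] != "ATG":
                continue
            aa = None
            has_stop = False
            for k in range(start + 3, limit, 3):
                if s[k : k + 3] in _STOPS:
                    aa = (k - start) // 3
                    has_stop = True
                    break
            if aa is None:
                aa = (limit - start) // 3
            if aa > best[2]:
                best = (frame, start, aa, has_stop)
    return best


def hypergeom_upper_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact rational tail summation."""
    total = Fraction(0)
    denom = comb(N, n)
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(total)


def nearest_gene_all_pairs(linc_span, gene_spans):
    """(index, gap) of the nearest gene by half-open gap distance; ties to
    the gene with the smaller start."""
    best = None
    for i, g in enumerate(gene_spans):
        gap = max(0, max(linc_span[0], g[0]) - min(linc_span[1], g[1]))
        if best is None or gap < best[1] or (gap == best[1] and g[0] < gene_spans[best[0]][0]):
            best = (i, gap)
    return best


def set_overlap_counts(sets: dict):
    """Pairwise and all-way intersection sizes by direct set algebra."""
    names = list(sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairwise[(a, b)] = len(set(sets[a]) & set(sets[b]))
    all_way = len(set.intersection(*(set(v) for v in sets.values())))
    return pairwise, all_way
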