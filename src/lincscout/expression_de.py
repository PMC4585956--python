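"""RPKM quantification and the weighted beta-binomial count test.

The two-group test follows the weighted proportions construction of
Baggerly et al. (2003): per library the proportion ``p_i = x_i / n_i`` is
treated as beta-distributed around a group proportion with binomial
sampling on top. Libraries are weighted by ``w_i ~ n_i / (1 + phi * n_i)``
where ``phi`` is a method-of-moments estimate of the between-library
overdispersion (floored at 0, where the weights reduce to ``w_i ~ n_i``
and the statistic collapses to the classical two-proportion z on pooled
counts). The statistic ``t = (pA - pB) / sqrt(VA + VB)`` is referred to a
t distribution with Welch-Satterthwaite degrees of freedom (floored at 1).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, DEResult, TranscriptModel

_TINY = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def compute_rpkm(counts: CountMatrix, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``RPKM = 1e9 * C / (N * L)`` with C the count, N the library's total
    mapped reads and L the transcript length in bp; exact per cell.
    """
    L = np.array([lengths[t] for t in counts.transcript_ids], dtype=float)
    if (L <= 0).any():
        bad = [t for t, l in zip(counts.transcript_ids, L) if l <= 0]
        raise ValueError(f"non-positive transcript lengths: {bad[:5]}")
    N = counts.totals
    if (N <= 0).any():
        raise ValueError("library totals must be positive")
    values = 1e9 * counts.counts.to_numpy(dtype=float) / (N[None, :] * L[:, None])
    return pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)


# ---------------------------------------------------------------------------
# Baggerly's weighted beta-binomial test
# ---------------------------------------------------------------------------

def _moment_terms(x: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Contribution of one group to the method-of-moments overdispersion.

    Returns ``(s_scaled, denom)`` where ``s_scaled = S / (p0 q0) - (K - 1)``
    with ``S`` the size-weighted squared deviation of library proportions
    about the pooled proportion, and ``denom`` its expectation multiplier
    for phi. Single-library groups contribute nothing (both terms 0).
    """
    k = len(x)
    if k == 1:
        return 0.0, 0.0
    p = x / n
    n_sum = n.sum()
    p0 = float((n * p).sum() / n_sum)
    pq0 = p0 * (1.0 - p0)
    if pq0 <= 0:
        return 0.0, 0.0
    s = float((n * (p - p0) ** 2).sum())
    denom = float(n_sum - (n**2).sum() / n_sum)
    return s / pq0 - (k - 1), denom


def _group_estimate(x: np.ndarray, n: np.ndarray, phi: float) -> tuple[float, float, float]:
    """Weight-optimal group proportion, its variance, and residual df.

    With the overdispersion floored at 0 the weights reduce to ``w ~ n``
    (pooled proportion, binomial variance). A single-library group uses
    pure binomial variance.
    """
    k = len(x)
    if k == 1:
        p = x[0] / n[0]
        return p, p * (1.0 - p) / n[0], 1.0
    p = x / n
    w = n / (1.0 + phi * n)
    w_sum = w.sum()
    p_hat = float((w * p).sum() / w_sum)
    var = p_hat * (1.0 - p_hat) / w_sum
    return p_hat, var, float(k - 1)


def baggerly_test(
    counts_a: Sequence[int],
    totals_a: Sequence[int],
    counts_b: Sequence[int],
    totals_b: Sequence[int],
) -> tuple[float, float]:
    """Two-sided weighted beta-binomial test of equal group proportions.

    The between-library overdispersion ``phi`` is a single method-of-moments
    estimate pooled over both groups' residuals (floored at 0); each group
    proportion is the weight-optimal estimate under that dispersion.
    Returns ``(statistic, p_value)`` with the statistic oriented as
    ``A - B``. Single-library groups fall back to pure binomial variance.
    """
    xa = np.asarray(counts_a, dtype=float)
    na = np.asarray(totals_a, dtype=float)
    xb = np.asarray(counts_b, dtype=float)
    nb = np.asarray(totals_b, dtype=float)
    for x, n, label in ((xa, na, "A"), (xb, nb, "B")):
        if x.size == 0:
            raise ValueError(f"group {label} has no libraries")
        if (n <= 0).any():
            raise ValueError(f"group {label} has non-positive library totals")
        if (x > n).any():
            raise ValueError(f"group {label} has counts exceeding totals")
        if (x < 0).any():
            raise ValueError(f"group {label} has negative counts")
    sa, da = _moment_terms(xa, na)
    sb, db = _moment_terms(xb, nb)
    phi = max(0.0, (sa + sb) / (da + db)) if (da + db) > 0 else 0.0
    pa, va, dfa = _group_estimate(xa, na, phi)
    pb, vb, dfb = _group_estimate(xb, nb, phi)
    v = va + vb
    if v <= 0:
        return 0.0, 1.0
    t = (pa - pb) / np.sqrt(v)
    denom = (va**2) / dfa + (vb**2) / dfb
    df = (v**2) / denom if denom > 0 else dfa + dfb
    df = max(df, 1.0)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(max(p, _TINY), 1.0))


# ---------------------------------------------------------------------------
# Differential-expression call
# ---------------------------------------------------------------------------

def call_de(
    transcript_ids: Sequence[str],
    counts: CountMatrix,
    rpkm: pd.DataFrame,
    contrast: tuple[str, str],
    fc_threshold: float = 4.0,
    alpha: float = 0.05,
    min_reads: int = 10,
    pseudocount: float = 0.1,
) -> list[DEResult]:
    """Call differential expression for one contrast ``(group_A, group_B)``.

    Fold change is ``(mean RPKM_B + eps) / (mean RPKM_A + eps)`` with
    ``eps = 0.1``; a transcript is DE iff ``max(fc, 1/fc) > fc_threshold``,
    the count-test p-value is below ``alpha``, and at least one library in
    either group has ``count >= min_reads``. Direction ``up`` means higher
    in group B. A Benjamini-Hochberg q-value over the tested set is
    attached for information; it does not enter the call.
    """
    group_a, group_b = contrast
    cols_a = counts.columns_for_group(group_a)
    cols_b = counts.columns_for_group(group_b)
    totals_a = counts.totals_for_group(group_a)
    totals_b = counts.totals_for_group(group_b)
    results: list[DEResult] = []
    for tid in transcript_ids:
        row = counts.counts.loc[tid]
        xa = row[cols_a].to_numpy(dtype=float)
        xb = row[cols_b].to_numpy(dtype=float)
        stat, p = baggerly_test(xa, totals_a, xb, totals_b)
        mean_a = float(rpkm.loc[tid, cols_a].mean())
        mean_b = float(rpkm.loc[tid, cols_b].mean())
        fc = (mean_b + pseudocount) / (mean_a + pseudocount)
        ratio = max(fc, 1.0 / fc)
        passes_reads = bool(max(xa.max(), xb.max()) >= min_reads)
        results.append(
            DEResult(
                transcript_id=tid,
                contrast=(group_a, group_b),
                mean_rpkm_a=mean_a,
                mean_rpkm_b=mean_b,
                fold_change=fc,
                direction="up" if fc >= 1.0 else "down",
                statistic=stat,
                p_value=p,
                passes_reads_rule=passes_reads,
                is_de=bool(ratio > fc_threshold and p < alpha and passes_reads),
            )
        )
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def de_results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "contrast": f"{r.contrast[0]}_vs_{r.contrast[1]}",
                "mean_rpkm_a": r.mean_rpkm_a,
                "mean_rpkm_b": r.mean_rpkm_b,
                "fold_change": r.fold_change,
                "log2_fold_change": float(np.log2(r.fold_change)),
                "direction": r.direction,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "neg_log10_p": float(-np.log10(r.p_value)),
                "passes_reads_rule": r.passes_reads_rule,
                "is_de": r.is_de,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Overlap summaries across contrasts
# ---------------------------------------------------------------------------

class OverlapSummary:
    """Up/down tallies per contrast and intersections of DE id sets."""

    def __init__(
        self,
        per_contrast: dict[str, tuple[int, int, int]],
        de_ids: dict[str, set[str]],
        pairwise: dict[tuple[str, str], int],
        all_way: int,
    ):
        self.per_contrast = per_contrast
        self.de_ids = de_ids
        self.pairwise = pairwise
        self.all_way = all_way


def summarize_overlaps(de_sets: Mapping[str, object]) -> OverlapSummary:
    """Summarize DE sets across contrasts.

    ``de_sets`` maps contrast name to either a list of :class:`DEResult`
    (up/down tallies use directions) or a plain set of DE transcript ids
    (tallies report 0 up/down splits).
    """
    if not de_sets:
        raise ValueError("at least one contrast is required")
    ids: dict[str, set[str]] = {}
    per_contrast: dict[str, tuple[int, int, int]] = {}
    for name, value in de_sets.items():
        value_list = list(value) if not isinstance(value, (set, frozenset)) else value
        if value_list and isinstance(next(iter(value_list)), DEResult):
            de = [r for r in value_list if r.is_de]
            ids[name] = {r.transcript_id for r in de}
            n_up = sum(1 for r in de if r.direction == "up")
            per_contrast[name] = (len(de), n_up, len(de) - n_up)
        else:
            ids[name] = set(value_list)
            per_contrast[name] = (len(ids[name]), None, None)  # directions unknown
    names = list(ids)
    pairwise = {
        (a, b): len(ids[a] & ids[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    all_way = len(set.intersection(*ids.values())) if names else 0
    return OverlapSummary(per_contrast, ids, pairwise, all_way)


def catalog_lengths(catalog: Iterable[TranscriptModel]) -> dict[str, int]:
    return {t.transcript_id: t.length for t in catalog}
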