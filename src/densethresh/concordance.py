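"""Matched concordance index (mC) and set-bootstrap score comparison.

The matched concordance index adapts the concordance index / AUC to matched
case-control data: within each matched set the case's risk score is compared
with each of its controls' (ties credited 0.5), and the per-set fractions
are averaged.  mC = 0.5 means no discrimination within sets; 1.0 means the
case outscores every control in every set.

Two scores are compared with a nonparametric bootstrap that resamples
*matched sets* with replacement — the set is the sampling unit, which
preserves the matched design — and counts how often the mC difference
crosses zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MCResult", "BootstrapComparison", "matched_concordance",
           "per_set_concordance", "bootstrap_mc_difference", "bootstrap_mc_ci"]


@dataclass(frozen=True)
class MCResult:
    mc: float
    per_set: np.ndarray
    n_sets: int


@dataclass(frozen=True)
class BootstrapComparison:
    delta_observed: float  # mC(scores2) − mC(scores1)
    replicates: int
    p_two_sided: float
    seed: int
    delta_mean: float
    delta_q025: float
    delta_q975: float


def per_set_concordance(set_id, is_case, scores) -> tuple[np.ndarray, np.ndarray]:
    """Per-set concordance fractions, ordered by first appearance of set_id.

    For a set with case score ``c`` and control scores ``u_j``:
    ``(#{u_j < c} + 0.5·#{u_j = c}) / m``.
    """
    set_id = np.asarray(set_id)
    is_case = np.asarray(is_case, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("all scores must be finite")
    order = np.argsort(set_id, kind="stable")
    set_id, is_case, scores = set_id[order], is_case[order], scores[order]
    starts = np.flatnonzero(np.r_[True, set_id[1:] != set_id[:-1]])
    counts = np.diff(np.r_[starts, set_id.size])
    n_cases = np.add.reduceat(is_case.astype(int), starts)
    if np.any(n_cases != 1):
        bad = set_id[starts[np.flatnonzero(n_cases != 1)[0]]]
        raise ValueError(f"set {bad!r} does not have exactly one case")
    case_score = np.zeros(starts.size)
    case_score[np.repeat(np.arange(starts.size), counts)[is_case]] = scores[is_case]
    grp = np.repeat(np.arange(starts.size), counts)
    c = case_score[grp]
    below = np.add.reduceat((~is_case) & (scores < c), starts)
    tied = np.add.reduceat((~is_case) & (scores == c), starts)
    m = counts - 1
    return (below + 0.5 * tied) / m, set_id[starts]


def matched_concordance(set_id, is_case, scores) -> MCResult:
    """Matched concordance index: unweighted mean of per-set concordances."""
    per_set, _ = per_set_concordance(set_id, is_case, scores)
    return MCResult(mc=float(per_set.mean()), per_set=per_set, n_sets=per_set.size)


def bootstrap_mc_difference(
    set_id, is_case, scores1, scores2, B: int = 10000, seed: int = 0
) -> BootstrapComparison:
    """Two-sided set-bootstrap p-value for ΔmC = mC(scores2) − mC(scores1).

    Sets are resampled with replacement ``B`` times; each replicate's Δ* is
    the mean over resampled per-set concordance differences.  The p-value is
    ``2·min((1+#{Δ*≤0})/(B+1), (1+#{Δ*≥0})/(B+1))`` capped at 1 (add-one
    Monte-Carlo correction, so p is never exactly 0).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    c1, _ = per_set_concordance(set_id, is_case, scores1)
    c2, _ = per_set_concordance(set_id, is_case, scores2)
    n = c1.size
    if n < 2:
        raise ValueError("bootstrap comparison needs at least 2 sets")
    d = c2 - c1
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    deltas = d[idx].mean(axis=1)
    p_lo = (1 + np.count_nonzero(deltas <= 0)) / (B + 1)
    p_hi = (1 + np.count_nonzero(deltas >= 0)) / (B + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return BootstrapComparison(
        delta_observed=float(d.mean()),
        replicates=B,
        p_two_sided=float(p),
        seed=seed,
        delta_mean=float(deltas.mean()),
        delta_q025=float(np.quantile(deltas, 0.025)),
        delta_q975=float(np.quantile(deltas, 0.975)),
    )


def bootstrap_mc_ci(set_id, is_case, scores, B: int = 10000, seed: int = 0):
    """Percentile (2.5, 97.5) set-bootstrap confidence interval for mC."""
    per_set, _ = per_set_concordance(set_id, is_case, scores)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, per_set.size, size=(B, per_set.size))
    mcs = per_set[idx].mean(axis=1)
    return float(np.quantile(mcs, 0.025)), float(np.quantile(mcs, 0.975))
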