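"""ROC curves, AUC, and the paired DeLong comparison of two scores.

The per-cycle question: does the oocyte-side score (PTOS) predict clinical
pregnancy better than the embryo-side score (mean grade of the transferred
embryos)?  Both scores are computed on the same cycles, so the AUCs are
correlated and are compared with DeLong's paired test using structural
components.

All estimators accept per-cycle frequency weights (weight = number of
embryos transferred reproduces the study's "weighted ROC"): a cycle with
integer weight w contributes exactly as w identical unweighted cycles, in
the AUC, the structural-component variances (denominator sum(w) - 1) and
the paired covariance.

AUC is computed as the weighted pairwise concordance (Mann-Whitney with
ties counting 1/2), which equals the trapezoidal area under the empirical
ROC curve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .oocyte_scoring import ValidationError

__all__ = [
    "RocInput",
    "RocResult",
    "RocComparison",
    "compute_auc",
    "compare_auc_paired",
    "roc_curve_points",
    "auc_trapezoid",
    "restrict_good_quality",
    "plot_roc_comparison",
]


@dataclass(frozen=True)
class RocInput:
    """Per-cycle scores, binary outcomes and positive frequency weights."""

    scores: np.ndarray
    outcomes: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_arrays(cls, scores, outcomes, weights=None) -> "RocInput":
        s = np.asarray(scores, dtype=float)
        y = np.asarray(outcomes)
        y = y.astype(bool) if y.dtype != bool else y
        w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
        if not (s.shape == y.shape == w.shape) or s.ndim != 1:
            raise ValidationError("scores, outcomes and weights must be equal-length 1-d")
        if np.any(w <= 0):
            raise ValidationError("weights must be strictly positive")
        if not (y.any() and (~y).any()):
            raise ValidationError("both outcome classes must be present for an AUC")
        return cls(s, y, w)


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class RocComparison:
    """Paired AUC comparison: DeLong z-test on auc_a - auc_b."""

    auc_a: float
    auc_b: float
    se_a: float
    se_b: float
    covariance: float
    z: float
    p: float


def _components(pos_scores, neg_scores, neg_weights):
    """Structural components V10 for each positive score: the weighted
    proportion of negatives it beats (ties count 1/2)."""
    # vectorized over the (n_pos, n_neg) comparison matrix; cohorts are small
    psi = (pos_scores[:, None] > neg_scores[None, :]).astype(float)
    psi += 0.5 * (pos_scores[:, None] == neg_scores[None, :])
    return psi @ neg_weights / neg_weights.sum()


def _split(inp: RocInput):
    pos = inp.outcomes
    return (inp.scores[pos], inp.weights[pos], inp.scores[~pos], inp.weights[~pos])


def _wvar(values, weights, mean):
    """Frequency-weighted sample variance, denominator sum(w) - 1.

    A class with total weight <= 1 carries no variance information; its
    structural-component variance is reported as 0.
    """
    w_total = weights.sum()
    if w_total <= 1.0:
        return 0.0
    return float(weights @ (values - mean) ** 2 / (w_total - 1.0))


def compute_auc(inp: RocInput) -> RocResult:
    """Weighted concordance AUC with the DeLong structural-component SE."""
    xs, wx, ys, wy = _split(inp)
    v10 = _components(xs, ys, wy)
    v01 = 1.0 - _components(ys, xs, wx)
    auc = float(wx @ v10 / wx.sum())
    s10 = _wvar(v10, wx, auc)
    s01 = _wvar(v01, wy, auc)
    var = s10 / wx.sum() + s01 / wy.sum()
    return RocResult(auc=auc, se=float(np.sqrt(max(var, 0.0))), n_pos=xs.size, n_neg=ys.size)


def compare_auc_paired(input_a: RocInput, input_b: RocInput) -> RocComparison:
    """DeLong paired z-test of two AUCs measured on the same cycles.

    Requires identical outcomes and weights (the scores differ). Two-sided
    p against the standard normal; identical scores give z = 0, p = 1.
    """
    if not (
        np.array_equal(input_a.outcomes, input_b.outcomes)
        and np.array_equal(input_a.weights, input_b.weights)
    ):
        raise ValidationError("paired comparison requires identical cycles, outcomes, weights")
    pos = input_a.outcomes
    wx, wy = input_a.weights[pos], input_a.weights[~pos]

    res_a = compute_auc(input_a)
    res_b = compute_auc(input_b)
    v10_a = _components(input_a.scores[pos], input_a.scores[~pos], wy)
    v10_b = _components(input_b.scores[pos], input_b.scores[~pos], wy)
    v01_a = 1.0 - _components(input_a.scores[~pos], input_a.scores[pos], wx)
    v01_b = 1.0 - _components(input_b.scores[~pos], input_b.scores[pos], wx)

    s10_ab = float(wx @ ((v10_a - res_a.auc) * (v10_b - res_b.auc)) / (wx.sum() - 1.0))
    s01_ab = float(wy @ ((v01_a - res_a.auc) * (v01_b - res_b.auc)) / (wy.sum() - 1.0))
    cov = s10_ab / wx.sum() + s01_ab / wy.sum()

    var_diff = res_a.se**2 + res_b.se**2 - 2.0 * cov
    diff = res_a.auc - res_b.auc
    if var_diff <= 0:
        z = 0.0 if abs(diff) < 1e-12 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z)))) if np.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return RocComparison(
        auc_a=res_a.auc, auc_b=res_b.auc, se_a=res_a.se, se_b=res_b.se,
        covariance=cov, z=float(z), p=p,
    )


def roc_curve_points(inp: RocInput) -> pd.DataFrame:
    """Empirical (weighted) ROC curve: one point per distinct threshold,
    thresholds descending, starting at (0, 0) and ending at (1, 1)."""
    order = np.argsort(-inp.scores, kind="stable")
    s, y, w = inp.scores[order], inp.outcomes[order], inp.weights[order]
    w_pos_total = w[y].sum()
    w_neg_total = w[~y].sum()
    tp = np.cumsum(np.where(y, w, 0.0))
    fp = np.cumsum(np.where(~y, w, 0.0))
    last = np.r_[s[1:] != s[:-1], True]  # last index of each tied block
    tpr = np.r_[0.0, tp[last] / w_pos_total]
    fpr = np.r_[0.0, fp[last] / w_neg_total]
    thresholds = np.r_[np.inf, s[last]]
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})


def auc_trapezoid(inp: RocInput) -> float:
    """Trapezoidal area under the empirical ROC curve (equals the
    concordance AUC; kept as an independent code path)."""
    pts = roc_curve_points(inp)
    return float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))


def restrict_good_quality(
    cycles: pd.DataFrame, embryos: pd.DataFrame, mode: str = "any"
) -> pd.DataFrame:
    """Keep cycles whose transferred embryos are good quality (grade >= 4).

    mode='any': at least one transferred embryo graded >= 4 (default);
    mode='all': every transferred embryo graded >= 4.
    """
    if mode not in {"any", "all"}:
        raise ValidationError(f"mode must be 'any' or 'all', got {mode!r}")
    transferred = embryos[embryos["transferred"].astype(bool)]
    good = transferred.assign(good=transferred["grade"] >= 4).groupby("patient_id")["good"]
    flag = good.any() if mode == "any" else good.all()
    keep = flag[flag].index
    return cycles[cycles["patient_id"].isin(keep)].reset_index(drop=True)


def plot_roc_comparison(input_a: RocInput, input_b: RocInput, path,
                        label_a="oocyte score (PTOS)", label_b="embryo grade"):
    """Both ROC curves on one axis, AUCs in the legend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for inp, label in ((input_a, label_a), (input_b, label_b)):
        pts = roc_curve_points(inp)
        res = compute_auc(inp)
        ax.plot(pts["fpr"], pts["tpr"], drawstyle="steps-post",
                label=f"{label} (AUC {res.auc:.3f} ± {res.se:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
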