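"""Inferential statistics for biomarker evaluation.

DeLong ROC analysis (AUC with structural-component standard error, Wald CI,
paired AUC comparison), Youden-index optimal cutpoints, the nonparametric
two-sample / matched-pair / k-group tests used for group comparisons,
Holm-Sidak step-down multiplicity adjustment, Spearman correlation and
univariate logistic predictive accuracy.

The AUC is the Mann-Whitney estimator with ties counted 1/2; its variance is
estimated from the DeLong placement values, and 95% CIs are Wald intervals
on the AUC scale clipped to [0, 1].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocResult",
    "TestResult",
    "roc_delong",
    "compare_paired_auc",
    "youden_optimal",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "kruskal_wallis_dunn",
    "holm_sidak",
    "spearman",
    "logistic_accuracy",
]


@dataclass
class RocResult:
    """ROC analysis of one score against a binary label.

    ``direction == "greater"`` means higher scores indicate the positive
    class (rule: score >= threshold => positive); ``"less"`` means the rule is
    score <= threshold => positive.
    """

    auc: float
    se_auc: float
    ci95: tuple[float, float]
    direction: str
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int
    p_value: float  # two-sided test of AUC = 0.5

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.direction in ("greater", "less")


@dataclass
class TestResult:
    """Outcome of a hypothesis test with optional per-group summaries."""

    statistic_name: str
    statistic_value: float
    p_value: float
    tails: str
    n: tuple[int, ...]
    effect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"invalid p-value {self.p_value}")


def _validate_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D arrays")
    if np.any(np.isnan(scores)):
        raise ValueError("missing scores are not allowed")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    y = labels == uniq.max() if uniq.dtype.kind in "biuf" else labels == uniq[-1]
    return scores, y.astype(bool)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values V10 (per positive), V01 (per negative)."""
    # psi(x, y) = 1 if x > y, 0.5 if x == y, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def roc_delong(
    scores: Sequence[float],
    labels: Sequence,
    direction: Optional[str] = None,
) -> RocResult:
    """Empirical AUC with DeLong standard error and Youden-optimal cutpoint.

    Direction is auto-detected (chosen so AUC >= 0.5) unless given.  The
    p-value is the two-sided normal test of AUC = 0.5; with perfect
    separation the DeLong SE is 0 and the p-value degenerates to 0.
    """
    scores, y = _validate_binary(scores, labels)
    pos, neg = scores[y], scores[~y]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 subjects per class")
    auc_greater, _, _ = _placements(pos, neg)
    if direction is None:
        direction = "greater" if auc_greater >= 0.5 else "less"
    elif direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    s = scores if direction == "greater" else -scores
    auc, v10, v01 = _placements(s[y], s[~y])
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    se = math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    threshold, sens, spec, acc = youden_optimal(scores, labels, direction=direction)
    return RocResult(
        auc=auc,
        se_auc=se,
        ci95=ci,
        direction=direction,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        n_pos=int(len(pos)),
        n_neg=int(len(neg)),
        p_value=min(p, 1.0),
    )


def compare_paired_auc(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence
) -> tuple[float, float, float]:
    """DeLong comparison of two correlated AUCs measured on the same subjects.

    Returns (delta_auc, se_delta, two-sided p).  Each AUC is oriented
    "greater"; callers comparing mixed-direction markers should negate the
    relevant score first.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    _, y = _validate_binary(a, labels)
    auc_a, v10_a, v01_a = _placements(a[y], a[~y])
    auc_b, v10_b, v01_b = _placements(b[y], b[~y])
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (
        s10[0, 0] / m + s01[0, 0] / n
        + s10[1, 1] / m + s01[1, 1] / n
        - 2.0 * (s10[0, 1] / m + s01[0, 1] / n)
    )
    delta = auc_a - auc_b
    se = math.sqrt(max(var, 0.0))
    if se == 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = 2.0 * sps.norm.sf(abs(delta / se))
    return float(delta), float(se), float(min(p, 1.0))


def youden_optimal(
    scores: Sequence[float],
    labels: Sequence,
    direction: Optional[str] = None,
) -> tuple[float, float, float, float]:
    """Prevalence-independent optimal cutpoint maximising J = sens + spec - 1.

    Candidate thresholds are midpoints between consecutive sorted unique
    scores plus +-inf; ties in J resolve to the smallest threshold.  Returns
    (threshold, sensitivity, specificity, accuracy) with accuracy evaluated
    at the chosen threshold.
    """
    scores, y = _validate_binary(scores, labels)
    if direction is None:
        direction = "greater" if _placements(scores[y], scores[~y])[0] >= 0.5 else "less"
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    best = (-np.inf, np.inf)  # (J, threshold)
    out = None
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    for t in candidates:
        pred = scores >= t if direction == "greater" else scores <= t
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        j = sens + spec - 1.0
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t < best[1]):
            best = (j, t)
            acc = float((pred == y).mean())
            out = (float(t), sens, spec, acc)
    assert out is not None
    return out


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], tails: str = "two"
) -> TestResult:
    """Mann-Whitney U test for two independent groups.

    Reports the min(U_x, U_y) convention.  The p-value is exact (full
    enumeration) for n_x + n_y <= 12 without ties, otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    exact = no_ties and (len(x) + len(y) <= 12)
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided" if tails == "two" else "two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    u_x = float(res.statistic)
    u_y = len(x) * len(y) - u_x
    p = float(res.pvalue)
    if tails == "one":
        p = p / 2.0
    return TestResult(
        statistic_name="U",
        statistic_value=min(u_x, u_y),
        p_value=min(p, 1.0),
        tails=tails,
        n=(len(x), len(y)),
        effect={
            "median_x": float(np.median(x)),
            "median_y": float(np.median(y)),
            "method": "exact" if exact else "asymptotic",
        },
    )


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], tails: str = "one"
) -> TestResult:
    """Wilcoxon signed-rank test for matched pairs (default one-tailed).

    Zero differences are dropped (count recorded).  One-tailed tests take the
    tail in the direction of the observed rank sum; p is exact for n <= 12
    without tied |differences|, otherwise a normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("matched samples must have equal length")
    d = x - y
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    n = len(d)
    if n <= 12:
        # exact null distribution of W+ by enumerating all 2^n sign patterns
        # (handles tied |differences|, which the textbook tables do not)
        patterns = (
            np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        ) & 1
        w_all = patterns @ ranks
        p_greater = float(np.mean(w_all >= w_pos - 1e-12))
        p_less = float(np.mean(w_all <= w_pos + 1e-12))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z_greater = (w_pos - 0.5 - mean) / math.sqrt(var)
        z_less = (w_pos + 0.5 - mean) / math.sqrt(var)
        p_greater = float(sps.norm.sf(z_greater))
        p_less = float(sps.norm.cdf(z_less))
        method = "normal-approximation"
    if tails == "one":
        # tail in the direction of the observed rank sum
        p = p_greater if w_pos >= w_neg else p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return TestResult(
        statistic_name="W",
        statistic_value=min(w_pos, w_neg),
        p_value=min(p, 1.0),
        tails=tails,
        n=(n,),
        effect={"n_zero_dropped": n_zero, "w_pos": w_pos, "w_neg": w_neg,
                "method": method},
    )


def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]],
) -> tuple[TestResult, list[dict]]:
    """Tie-corrected Kruskal-Wallis H test with Dunn post hoc comparisons.

    Dunn z statistics use the pooled mid-ranks with tie correction; pairwise
    two-sided p-values are Holm-Sidak adjusted.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    result = TestResult(
        statistic_name="H",
        statistic_value=float(h),
        p_value=float(p),
        tails="two",
        n=tuple(len(g) for g in groups),
    )
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        float(ranks[bounds[i]:bounds[i + 1]].mean()) for i in range(len(groups))
    ]
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    raw = []
    pairs = list(itertools.combinations(range(len(groups)), 2))
    for i, j in pairs:
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var) if var > 0 else 0.0
        raw.append(2.0 * sps.norm.sf(abs(z)))
    adjusted = holm_sidak(raw)
    table = [
        {
            "groups": (i, j),
            "mean_rank_diff": mean_ranks[i] - mean_ranks[j],
            "z": (mean_ranks[i] - mean_ranks[j])
            / math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j])),
            "p_raw": p_raw,
            "p_adjusted": p_adj,
        }
        for (i, j), p_raw, p_adj in zip(pairs, raw, adjusted)
    ]
    return result, table


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sorted ascending, adjusted_(i) = 1 - (1 - p_(i))^(m - i) for 0-based i,
    then a running maximum enforces monotonicity.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    out = np.empty(m)
    out[order] = np.minimum(adjusted_sorted, 1.0)
    return out


def spearman(x: Sequence[float], y: Sequence[float], tails: str = "two") -> TestResult:
    """Spearman rank correlation (two-tailed by default).

    rho is the Pearson correlation of mid-ranks; the p-value uses the exact
    permutation distribution for n <= 8 and the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector; rank correlation undefined")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        r_all = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(r_all) >= abs(rho) - 1e-12))
        if tails == "one":
            p = p / 2.0
        method = "exact-permutation"
    else:
        res = sps.spearmanr(x, y, alternative="two-sided" if tails == "two" else "greater")
        p = float(res.pvalue)
        method = "t-approximation"
    return TestResult(
        statistic_name="rho",
        statistic_value=rho,
        p_value=min(float(p), 1.0),
        tails=tails,
        n=(n,),
        effect={"method": method},
    )


def logistic_accuracy(
    score: Sequence[float], labels: Sequence
) -> tuple[float, float, float, bool]:
    """Univariate logistic regression and its in-sample predictive accuracy.

    Fits P(positive) = expit(intercept + slope*score) by maximum likelihood
    (IRLS/Newton, tol 1e-8, 100 iterations); accuracy is the fraction
    correctly classified at predicted probability >= 0.5.  Complete
    separation is detected beforehand: the flag is set, the accuracy of the
    separating rule (1.0) is returned, and the coefficients are the (diverged)
    final iterates.

    Returns (intercept, slope, predictive_accuracy, separation_flag).
    """
    import statsmodels.api as sm

    score, y = _validate_binary(score, labels)
    pos, neg = score[y], score[~y]
    separated = (pos.min() > neg.max()) or (pos.max() < neg.min())
    exog = sm.add_constant(score)
    model = sm.Logit(y.astype(float), exog)
    import warnings as _warnings

    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=100, tol=1e-8)
        intercept, slope = (float(v) for v in fit.params)
        prob = np.asarray(fit.predict(exog))
    except Exception:
        if not separated:
            raise RuntimeError("logistic fit failed to converge without separation")
        # fall back to the separating rule
        intercept, slope = math.nan, math.inf if pos.min() > neg.max() else -math.inf
        prob = (score > (pos.min() + neg.max()) / 2).astype(float)
        if pos.max() < neg.min():
            prob = 1.0 - prob
    accuracy = float(((prob >= 0.5) == y).mean())
    return intercept, slope, accuracy, bool(separated)
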