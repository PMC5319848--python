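"""Statistical procedures for sarcomere morphometry and muscle physiology.

Covers: ordinary least-squares TFL~SL regression and ANCOVA-style
between-group comparison of slope / elevation / intercept; normality- and
variance-gated two-group testing (Student's t vs Mann-Whitney); per-segment
variance profiling with F-tests; the Hill fit of force-pCa curves; and the
small arithmetic of cardiac volumetric indices and fractional wall
thickening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps

__all__ = [
    "RegressionFit",
    "RegressionComparison",
    "GroupComparison",
    "ForcePCaCurve",
    "ForcePCaFit",
    "fit_linear",
    "compare_regressions",
    "gate_and_test",
    "variance_profile",
    "fit_force_pca",
    "hill_force",
    "cardiac_indices",
    "fractional_wall_thickening",
]


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with the slope-vs-zero test."""

    slope: float
    intercept: float
    residual_sd: float
    n: int
    slope_se: float
    p_slope_nonzero: float
    group: str = ""

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_linear(x, y, group: str = "") -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x`` with a slope t-test.

    Residual SD uses ``n - 2`` degrees of freedom. Requires at least three
    points and non-constant ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope is not identifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(model.ssr / (x.size - 2)))
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        residual_sd=resid_sd,
        n=int(x.size),
        slope_se=float(model.bse[1]),
        p_slope_nonzero=float(model.pvalues[1]),
        group=group,
    )


@dataclass(frozen=True)
class RegressionComparison:
    """ANCOVA-style comparison of two group regressions.

    ``p_slope`` tests slope equality via the group-by-x interaction in a
    pooled model. ``p_elevation`` tests the vertical offset between the
    groups under a common slope (the classical elevation test), and is
    meaningful when the slopes are not distinguishably different.
    ``p_intercept`` tests the intercept difference at x = 0 in the full
    interaction model.
    """

    fit_a: RegressionFit
    fit_b: RegressionFit
    slope_diff: float
    p_slope: float
    elevation_diff: float
    p_elevation: float
    intercept_diff: float
    p_intercept: float


def compare_regressions(x_a, y_a, x_b, y_b,
                        labels: tuple[str, str] = ("a", "b")) -> RegressionComparison:
    """Compare two linear regressions for slope, elevation and intercept.

    Slope equality is tested through the interaction term of the pooled
    model ``y ~ x + g + x:g``; the elevation (common-slope offset) through
    the group term of ``y ~ x + g``; the intercept difference through the
    group term of the full interaction model. Results are symmetric in group
    order up to the sign of the differences.
    """
    fit_a = fit_linear(x_a, y_a, labels[0])
    fit_b = fit_linear(x_b, y_b, labels[1])
    x = np.concatenate([np.asarray(x_a, float), np.asarray(x_b, float)])
    y = np.concatenate([np.asarray(y_a, float), np.asarray(y_b, float)])
    g = np.concatenate([np.zeros(len(np.atleast_1d(x_a))),
                        np.ones(len(np.atleast_1d(x_b)))])
    design = np.column_stack([np.ones_like(x), x, g, x * g])
    full = sm.OLS(y, design).fit()
    common = sm.OLS(y, design[:, :3]).fit()
    return RegressionComparison(
        fit_a=fit_a,
        fit_b=fit_b,
        slope_diff=fit_b.slope - fit_a.slope,
        p_slope=float(full.pvalues[3]),
        elevation_diff=float(common.params[2]),
        p_elevation=float(common.pvalues[2]),
        intercept_diff=fit_b.intercept - fit_a.intercept,
        p_intercept=float(full.pvalues[2]),
    )


# ---------------------------------------------------------------------------
# gated two-group testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a two-group comparison, with the gate decisions logged."""

    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str
    gates: dict = field(default_factory=dict)


def f_test_variances(a, b) -> tuple[float, float]:
    """Two-sided F-test for equality of variances of two samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if vb == 0 and va == 0:
        return 1.0, 1.0
    if vb == 0 or va == 0:
        return np.inf, 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))


def gate_and_test(a, b, alpha_gate: float = 0.05, n_comparisons: int = 1) -> GroupComparison:
    """Two-group test with normality and variance-equality gates.

    Both samples are screened with the Shapiro-Wilk test and their variances
    with a two-sided F-test, each at ``alpha_gate``. When all three gates
    pass, an unpaired two-tailed Student's t-test is used; otherwise a
    two-tailed Mann-Whitney U. The gate decisions travel with the result.
    ``n_comparisons`` applies a Bonferroni factor for use inside families of
    tests.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    identical_a = np.ptp(a) == 0
    identical_b = np.ptp(b) == 0
    sw_a = 0.0 if identical_a else float(sps.shapiro(a).pvalue)
    sw_b = 0.0 if identical_b else float(sps.shapiro(b).pvalue)
    f_stat, f_p = f_test_variances(a, b)
    gates = {
        "shapiro_p_a": sw_a, "shapiro_p_b": sw_b,
        "f_statistic": f_stat, "f_p": f_p,
        "normal_a": sw_a > alpha_gate, "normal_b": sw_b > alpha_gate,
        "equal_variance": f_p > alpha_gate,
    }
    if gates["normal_a"] and gates["normal_b"] and gates["equal_variance"]:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        name = "student_t"
    else:
        if identical_a and identical_b and a[0] == b[0]:
            stat, p = 0.0, 1.0  # degenerate: all observations identical
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    p_adj = min(float(p) * n_comparisons, 1.0)
    label = f"bonferroni_x{n_comparisons}" if n_comparisons > 1 else "none"
    return GroupComparison(name, float(stat), float(p), p_adj, label, gates)


def variance_profile(data: pd.DataFrame, group_col: str = "group",
                     segment_col: str = "segment",
                     value_col: str = "value") -> tuple[pd.DataFrame, GroupComparison]:
    """Per-segment SD comparison between two groups, plus a pooled F-test.

    Expects tidy data with one row per observation. For each segment the two
    groups' SDs are compared by a two-sided F-test; the pooled comparison
    uses the within-segment pooled variances of each group (degrees of
    freedom summed across segments), asking whether one group is more
    variable overall.
    """
    groups = list(dict.fromkeys(data[group_col]))
    if len(groups) != 2:
        raise ValueError("variance_profile expects exactly 2 groups")
    ga, gb = groups
    rows = []
    ss = {ga: 0.0, gb: 0.0}
    df = {ga: 0, gb: 0}
    for seg, sub in data.groupby(segment_col, sort=False):
        a = sub.loc[sub[group_col] == ga, value_col].to_numpy(float)
        b = sub.loc[sub[group_col] == gb, value_col].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"segment {seg!r} needs >=2 values per group")
        f_stat, f_p = f_test_variances(a, b)
        rows.append({segment_col: seg, f"sd_{ga}": float(np.std(a, ddof=1)),
                     f"sd_{gb}": float(np.std(b, ddof=1)),
                     "f_statistic": f_stat, "p": f_p})
        ss[ga] += float(np.sum((a - a.mean()) ** 2))
        ss[gb] += float(np.sum((b - b.mean()) ** 2))
        df[ga] += a.size - 1
        df[gb] += b.size - 1
    pooled_f = (ss[ga] / df[ga]) / (ss[gb] / df[gb])
    pooled_p = 2.0 * min(sps.f.cdf(pooled_f, df[ga], df[gb]),
                         sps.f.sf(pooled_f, df[ga], df[gb]))
    pooled = GroupComparison("pooled_f", float(pooled_f), float(min(pooled_p, 1.0)),
                             float(min(pooled_p, 1.0)), "none",
                             {"df": (df[ga], df[gb])})
    return pd.DataFrame(rows), pooled


# ---------------------------------------------------------------------------
# force-pCa
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForcePCaCurve:
    """(pCa, total force) measurements with the passive-force baseline.

    ``pca`` is conventionally recorded in descending pCa (ascending [Ca2+]).
    ``force`` is total force; the relaxing-solution passive force must be
    subtracted before fitting Ca2+ sensitivity.
    """

    pca: np.ndarray
    force: np.ndarray
    passive_force: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pca", np.asarray(self.pca, dtype=float))
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        if self.pca.size != self.force.size:
            raise ValueError("pca and force must have equal length")

    @property
    def active_force(self) -> np.ndarray:
        return self.force - self.passive_force

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pca": self.pca, "force": self.force,
                             "passive_force": self.passive_force})


@dataclass(frozen=True)
class ForcePCaFit:
    """Hill fit of active force vs pCa: pCa50, Hill coefficient, F_max."""

    pca50: float
    n_hill: float
    f_max: float
    passive: float
    rss: float


def hill_force(pca, pca50: float, n_hill: float, f_max: float):
    """Hill curve in pCa units: ``F = f_max / (1 + 10^(n (pCa - pCa50)))``.

    Monotonically increasing with [Ca2+] (decreasing pCa); half-maximal at
    ``pca == pca50``.
    """
    return f_max / (1.0 + 10.0 ** (n_hill * (np.asarray(pca, float) - pca50)))


def fit_force_pca(curve: ForcePCaCurve) -> ForcePCaFit:
    """Fit Ca2+ sensitivity of force by nonlinear least squares.

    Passive force is subtracted first; the active force is then fit to the
    Hill form with initial values pCa50 = 6.0, n_H = 2.0 and
    f_max = max(active). A warning is issued when the measured pCa range does
    not bracket the fitted midpoint (the pCa50 is then an extrapolation).
    """
    if curve.pca.size < 5:
        raise ValueError("need at least 5 pCa points spanning the transition")
    active = curve.active_force
    p0 = (6.0, 2.0, float(active.max()))
    try:
        popt, _ = optimize.curve_fit(
            hill_force, curve.pca, active, p0=p0,
            bounds=([4.0, 1e-6, 1e-12], [8.0, 20.0, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        resid = active - hill_force(curve.pca, *p0)
        raise RuntimeError(
            f"Hill fit failed to converge; initial residual SS "
            f"{float(np.sum(resid ** 2)):.4g}") from exc
    pca50, n_hill, f_max = map(float, popt)
    rss = float(np.sum((active - hill_force(curve.pca, *popt)) ** 2))
    if not (curve.pca.min() <= pca50 <= curve.pca.max()):
        warnings.warn("pCa grid does not span the fitted midpoint; pCa50 is "
                      "extrapolated", stacklevel=2)
    return ForcePCaFit(pca50, n_hill, f_max, float(curve.passive_force), rss)


# ---------------------------------------------------------------------------
# cardiac arithmetic
# ---------------------------------------------------------------------------


def cardiac_indices(edv: float, esv: float, hr: float) -> dict[str, float]:
    """Stroke volume (ul), ejection fraction (%) and cardiac output (ul/min)
    from end-diastolic/end-systolic volumes (ul) and heart rate (1/min).
    ``edv == esv`` is permitted (a degenerate beat with zero stroke)."""
    if not (edv >= esv >= 0) or edv <= 0:
        raise ValueError("need edv >= esv >= 0 and edv > 0")
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    sv = edv - esv
    return {"sv": sv, "ef": 100.0 * sv / edv, "co": sv * hr}


def fractional_wall_thickening(wt_ed, wt_es) -> np.ndarray:
    """Percent systolic wall thickening per segment:
    ``fWT = 100 (wt_es - wt_ed) / wt_ed``; segment order is preserved."""
    wt_ed = np.atleast_1d(np.asarray(wt_ed, dtype=float))
    wt_es = np.atleast_1d(np.asarray(wt_es, dtype=float))
    if np.any(wt_ed <= 0):
        raise ValueError("end-diastolic wall thickness must be positive")
    return 100.0 * (wt_es - wt_ed) / wt_ed
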