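"""Titin isoform quantification from gel densitometry and qPCR Ct tables.

Cardiac titin comes in two isoform classes: the short, stiff N2B and the
longer, compliant N2BA (which additionally carries the N2A element and a
longer PEVK spring). Their ratio sets passive myocardial stiffness and
shifts from N2BA- to N2B-dominant over postnatal development. Two
quantifications are implemented:

* **Gel densitometry** — a lane profile from agarose-strengthened SDS-PAGE
  carries two bands; the smaller N2B isoform migrates farther. After linear
  baseline subtraction the bands are fit as Gaussians and %N2B is the
  analytic N2B area over the total titin area.
* **qPCR element index** — under the transcript-mixture model (every titin
  transcript carries the N2B element, only N2BA transcripts carry the N2A
  element), ``fraction_N2BA = efficiency^-(Ct_N2A - Ct_N2B)`` and
  ``%N2B = 100 (1 - fraction_N2BA)``. The index is a relative measure: it
  tracks the N2BA-to-N2B transition but does not calibrate absolute copy
  numbers. Standard 2^-ddCt fold changes are provided alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .stats import gate_and_test

logger = logging.getLogger(__name__)

__all__ = [
    "GelLane",
    "CtRecord",
    "IsoformMeasurement",
    "TransitionResult",
    "subtract_baseline",
    "quantify_lane",
    "ddct_fold_change",
    "pct_n2b_from_ct",
    "transition_series",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GelLane:
    """One gel lane's densitometry profile.

    ``profile`` is optical density sampled along the migration axis
    (arbitrary migration units, increasing = farther migration);
    ``spacing`` is the sample step in those units.
    """

    profile: np.ndarray
    spacing: float = 1.0
    lane_id: str = ""
    group: str = ""
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "profile", np.asarray(self.profile, dtype=float))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.profile.size < 20:
            raise ValueError("lane needs at least 20 samples")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.profile.size) * self.spacing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"migration": self.positions, "od": self.profile})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, lane_id: str = "",
                   group: str = "") -> "GelLane":
        pos = np.asarray(frame["migration"], dtype=float)
        return cls(np.asarray(frame["od"], dtype=float),
                   float(np.median(np.diff(pos))), lane_id, group)


@dataclass(frozen=True)
class CtRecord:
    """A single qPCR observation."""

    sample_id: str
    target: str
    ct: float
    replicate: int = 0
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and not self.ct > 0:
            raise ValueError("ct must be positive when not censored")


@dataclass(frozen=True)
class IsoformMeasurement:
    """%N2B of total titin for one sample, with provenance."""

    sample_id: str
    pct_n2b: float
    method: str  # "gel" | "qpcr"
    stage: str = ""
    group: str = ""
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and not 0.0 <= self.pct_n2b <= 100.0:
            raise ValueError("pct_n2b must lie in [0, 100]")

    @property
    def pct_n2ba(self) -> float:
        return 100.0 - self.pct_n2b


# ---------------------------------------------------------------------------
# gel densitometry
# ---------------------------------------------------------------------------


def _dominant_bands(lane: GelLane, expected_bands: int) -> np.ndarray:
    """Indices of the most prominent peaks, sorted by position."""
    prof = lane.profile
    rng = float(prof.max() - prof.min())
    if rng == 0:
        return np.empty(0, dtype=int)
    idx, props = signal.find_peaks(prof, prominence=0.02 * rng)
    if idx.size == 0:
        return idx
    order = np.argsort(props["prominences"])[::-1][:expected_bands]
    return np.sort(idx[order])


def subtract_baseline(lane: GelLane) -> GelLane:
    """Remove a linear baseline anchored at the minima flanking the bands.

    The band region is located from the dominant peaks; the minima of the
    profile on either side of that region define two anchor points, the line
    through them is subtracted and negative residuals are clipped to zero.
    Adding any constant or linear ramp to a lane therefore leaves downstream
    band areas unchanged.
    """
    prof = lane.profile
    idx = _dominant_bands(lane, expected_bands=2)
    if idx.size == 0:
        # band-free lane: anchor at the minima of each half
        left_end = prof.size // 2
        right_start = prof.size // 2
    else:
        # half-width beyond the outer peaks where the bands have decayed
        span = max(int(0.5 * (idx[-1] - idx[0])), 5) if idx.size > 1 else 10
        left_end = max(idx[0] - span, 1)
        right_start = min(idx[-1] + span, prof.size - 1)
    i0 = int(np.argmin(prof[:left_end]))
    i1 = int(right_start + np.argmin(prof[right_start:]))
    x = np.arange(prof.size, dtype=float)
    if i1 == i0:
        baseline = np.full_like(prof, prof[i0])
    else:
        slope = (prof[i1] - prof[i0]) / (i1 - i0)
        baseline = prof[i0] + slope * (x - i0)
    corrected = np.clip(prof - baseline, 0.0, None)
    return replace(lane, profile=corrected, baseline_subtracted=True)


def _two_gaussians(x, a1, c1, s1, a2, c2, s2, floor):
    # the constant floor absorbs the positive-mean residual that baseline
    # clipping leaves in band-free stretches; band areas stay analytic
    return (a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - c2) / s2) ** 2) + floor)


def quantify_lane(lane: GelLane, expected_bands: int = 2) -> IsoformMeasurement:
    """%N2B of total titin from a baseline-subtracted two-band lane.

    The two dominant bands are fit as Gaussians (initialised at the detected
    peaks); band identity is by migration order alone — the farther-migrating
    band is N2B. Areas are analytic (``amplitude * sigma * sqrt(2 pi)``) and
    ``pct_n2b = 100 A_N2B / (A_N2B + A_N2BA)``, so %N2B and %N2BA sum to 100
    exactly and the result is invariant to lane-wide intensity scaling.
    Fewer than two detectable bands yields a censored measurement with a
    warning (merged bands cannot be apportioned).
    """
    if not lane.baseline_subtracted:
        lane = subtract_baseline(lane)
    idx = _dominant_bands(lane, expected_bands)
    if idx.size < 2:
        warnings.warn(f"lane {lane.lane_id!r}: fewer than 2 bands detected; "
                      "censored result", stacklevel=2)
        return IsoformMeasurement(lane.lane_id, float("nan"), "gel",
                                  group=lane.group, censored=True)
    x = lane.positions
    prof = lane.profile
    sep = abs(x[idx[-1]] - x[idx[0]])
    sigma0 = max(sep / 6.0, lane.spacing)
    p0 = [prof[idx[0]], x[idx[0]], sigma0, prof[idx[-1]], x[idx[-1]], sigma0,
          0.0]
    lower = [0.0, x[0], lane.spacing / 10.0] * 2 + [0.0]
    upper = [np.inf, x[-1], x[-1] - x[0]] * 2 + [np.inf]
    popt, _ = optimize.curve_fit(_two_gaussians, x, prof, p0=p0,
                                 bounds=(lower, upper), maxfev=20000)
    a1, c1, s1, a2, c2, s2, _floor = popt
    area1 = a1 * s1 * np.sqrt(2.0 * np.pi)
    area2 = a2 * s2 * np.sqrt(2.0 * np.pi)
    # farther migration = larger coordinate = N2B
    area_n2b, area_n2ba = (area1, area2) if c1 > c2 else (area2, area1)
    pct = 100.0 * area_n2b / (area_n2b + area_n2ba)
    return IsoformMeasurement(lane.lane_id, float(pct), "gel", group=lane.group)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def _ct_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame([r.__dict__ for r in records])
    if "censored" not in frame:
        frame["censored"] = frame["ct"].isna()
    return frame


def _mean_ct(frame: pd.DataFrame) -> pd.DataFrame:
    """Replicates averaged on the Ct (log) scale, consistent with the ddCt
    derivation; a sample/target is censored when any replicate is."""
    grouped = frame.groupby(["sample_id", "target"], sort=False)
    out = grouped.agg(ct=("ct", "mean"), censored=("censored", "any"))
    return out.reset_index()


def ddct_fold_change(records, target: str, reference_gene: str,
                     control_samples) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``fold = 2^-((Ct_t,s - Ct_ref,s) - mean_control(Ct_t,c - Ct_ref,c))``,
    with technical replicates averaged on the Ct scale first. Samples with a
    censored Ct for either gene are excluded (logged). The mean fold change
    of the control group's own dCt is exactly 1 by construction.

    ``records`` may be a tidy DataFrame (columns sample_id, target,
    replicate, ct[, censored]) or a sequence of :class:`CtRecord`.
    """
    frame = _mean_ct(_ct_frame(records))
    control_samples = set(control_samples)
    wide = frame.pivot(index="sample_id", columns="target", values="ct")
    cens = frame.pivot(index="sample_id", columns="target", values="censored")
    for gene in (target, reference_gene):
        if gene not in wide:
            raise ValueError(f"missing Ct values for {gene!r}")
    usable = ~(cens[target].fillna(True) | cens[reference_gene].fillna(True))
    dropped = wide.index[~usable]
    if len(dropped):
        logger.info("ddct_fold_change: excluded censored sample(s) %s",
                    list(dropped))
    wide = wide[usable]
    dct = wide[target] - wide[reference_gene]
    control_idx = [s for s in wide.index if s in control_samples]
    if not control_idx:
        raise ValueError("no usable control samples")
    ddct = dct - dct.loc[control_idx].mean()
    return pd.DataFrame({
        "sample_id": wide.index,
        "dct": dct.to_numpy(float),
        "ddct": ddct.to_numpy(float),
        "fold_change": np.power(2.0, -ddct.to_numpy(float)),
        "is_control": [s in control_samples for s in wide.index],
    }).reset_index(drop=True)


def pct_n2b_from_ct(records, efficiency: float = 2.0,
                    noise_floor_cycles: float = 0.5) -> list[IsoformMeasurement]:
    """%N2B of total titin from N2B-/N2A-element Cts, per sample.

    Under the transcript-mixture model, the N2A-element template is the
    N2BA fraction of the N2B-element template, so
    ``fraction_N2BA = efficiency^-(Ct_N2A - Ct_N2B)`` (clipped into [0, 1])
    and ``pct_n2b = 100 (1 - fraction_N2BA)``. The reference gene cancels and
    adding any constant to both titin Cts changes nothing. A censored N2A
    Ct (template absent) maps to 100% N2B. ``Ct_N2A < Ct_N2B`` beyond the
    technical noise floor violates the model (the N2A element cannot exceed
    total titin) and is clipped to 0% N2B with a warning.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    frame = _mean_ct(_ct_frame(records))
    out = []
    for sample, sub in frame.groupby("sample_id", sort=False):
        by_target = sub.set_index("target")
        for t in ("N2B_element", "N2A_element"):
            if t not in by_target.index:
                raise ValueError(f"sample {sample!r} lacks target {t!r}")
        if bool(by_target.loc["N2B_element", "censored"]):
            warnings.warn(f"sample {sample!r}: censored N2B-element Ct; "
                          "cannot quantify", stacklevel=2)
            out.append(IsoformMeasurement(str(sample), float("nan"), "qpcr",
                                          censored=True))
            continue
        if bool(by_target.loc["N2A_element", "censored"]):
            out.append(IsoformMeasurement(str(sample), 100.0, "qpcr"))
            continue
        dct = float(by_target.loc["N2A_element", "ct"]
                    - by_target.loc["N2B_element", "ct"])
        if dct < -noise_floor_cycles:
            warnings.warn(f"sample {sample!r}: Ct_N2A below Ct_N2B beyond "
                          "the noise floor; model violation, clipped to 0% "
                          "N2B", stacklevel=2)
        frac_n2ba = float(np.clip(efficiency ** (-dct), 0.0, 1.0))
        out.append(IsoformMeasurement(str(sample), 100.0 * (1.0 - frac_n2ba),
                                      "qpcr"))
    return out


# ---------------------------------------------------------------------------
# developmental transition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionResult:
    """Per-stage genotype comparison of the isoform transition."""

    summary: pd.DataFrame          # stage x genotype means +/- SEM
    tests: pd.DataFrame            # per-stage test, p_raw, p_bonferroni
    earliest_divergence: str | None


def transition_series(measurements: pd.DataFrame, stage_order: list[str] | None = None,
                      value_col: str = "pct_n2b", alpha: float = 0.05,
                      ) -> TransitionResult:
    """Track a two-genotype isoform transition across developmental stages.

    Expects tidy data with columns ``stage``, ``genotype`` and
    ``value_col``. Stages are compared between the two genotypes with the
    normality/variance-gated two-group test; Bonferroni correction uses the
    number of tested stages as the family size. The earliest divergence is
    the first stage (in ``stage_order``) whose corrected p falls below
    ``alpha``. Stages with fewer than two samples in either genotype are
    excluded from testing but retained in the summary of means.
    """
    genotypes = list(dict.fromkeys(measurements["genotype"]))
    if len(genotypes) != 2:
        raise ValueError("transition_series expects exactly 2 genotypes")
    stages = stage_order or list(dict.fromkeys(measurements["stage"]))
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    ga, gb = genotypes
    summary_rows, testable = [], []
    for stage in stages:
        sub = measurements[measurements["stage"] == stage]
        a = sub.loc[sub["genotype"] == ga, value_col].to_numpy(float)
        b = sub.loc[sub["genotype"] == gb, value_col].to_numpy(float)
        for g, v in ((ga, a), (gb, b)):
            summary_rows.append({
                "stage": stage, "genotype": g, "n": int(v.size),
                "mean": float(np.mean(v)) if v.size else float("nan"),
                "sem": float(np.std(v, ddof=1) / np.sqrt(v.size))
                        if v.size > 1 else float("nan")})
        if a.size >= 2 and b.size >= 2:
            testable.append((stage, a, b))
        else:
            logger.info("transition_series: stage %r excluded from testing "
                        "(n<2 in a genotype)", stage)
    n_family = len(testable)
    test_rows = []
    earliest = None
    for stage, a, b in testable:
        # the gate needs n>=3; with exactly 2 samples fall back to Student's t
        if min(a.size, b.size) >= 3:
            cmp_ = gate_and_test(a, b, n_comparisons=n_family)
            test, p_raw, p_adj = cmp_.test, cmp_.p_raw, cmp_.p_adjusted
        else:
            from scipy import stats as sps
            _, p_raw = sps.ttest_ind(a, b, equal_var=True)
            test, p_adj = "student_t", min(float(p_raw) * n_family, 1.0)
        test_rows.append({"stage": stage, "test": test,
                          "p_raw": float(p_raw), "p_bonferroni": float(p_adj)})
        if earliest is None and p_adj < alpha:
            earliest = stage
    return TransitionResult(pd.DataFrame(summary_rows),
                            pd.DataFrame(test_rows), earliest)
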