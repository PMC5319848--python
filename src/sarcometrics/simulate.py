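"""Synthetic generators for every input the measurement pipeline consumes.

The centrepiece is a forward optical model of immunostained striated muscle:
a myofibril is a strictly increasing sequence of Z-disc positions with a
per-sarcomere thin-filament length (TFL). Thin filaments extend from each
Z-disc toward the sarcomere centre, so phalloidin intensity is the filament
coverage count (0, 1 or 2 per position): sarcomeres with SL > 2 TFL show a
phalloidin-dark H band of width SL - 2 TFL, while SL < 2 TFL produces a
double-coverage bright overlap band of width 2 TFL - SL — the banding logic
used to phenotype short sarcomeres. Point-like epitopes (alpha-actinin and
myomesin lines, Tmod1 pointed ends, titin exon epitopes) are rendered as
Gaussian-blurred impulses. Everything is blurred with a Gaussian PSF, offset
by a baseline and degraded with additive Gaussian noise (adequate for
high-SNR fixed-tissue confocal imaging, and it keeps the oracles analytic).

Also here: population generators with the linear TFL~SL structure, two-band
titin gel lanes, qPCR Ct tables under the transcript-mixture model, Hill
force-pCa curves, postnatal isoform-transition series and per-segment wall
thickening tables. All randomness flows through explicit seeds or
``numpy.random.Generator`` instances — never global state.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .isoform import GelLane
from .morphometry import IntensityProfile
from .stats import ForcePCaCurve

__all__ = [
    "CHANNELS",
    "SarcomereGroundTruth",
    "OpticalModelParams",
    "PopulationSpec",
    "QpcrTruth",
    "simulate_profile",
    "simulate_image",
    "simulate_population",
    "simulate_gel_lane",
    "simulate_ct_table",
    "simulate_force_pca",
    "simulate_transition_series",
    "simulate_wall_thickening",
    "truth_table",
]

#: Channels the optical model can render.
CHANNELS = ("phalloidin", "alpha_actinin", "tmod1", "myomesin",
            "titin_ex49", "titin_ex224")

#: Physical lower bound (um) for sarcomere-length draws; below the
#: myofilament minimum (the shortest length observed in tissue is ~1.18 um).
SL_TRUNCATION_UM = 0.8

_ISOFORM_CLASSES = ("N2B-dominant", "N2BA-dominant", "mixed")

#: Scaling of the SL-dependent epitope placement slope by titin isoform
#: class: the N2B spring region barely extends, the N2BA region is the
#: reference, a mixed population sits in between.
_EPITOPE_SLOPE_SCALE = {"N2BA-dominant": 1.0, "mixed": 0.75, "N2B-dominant": 0.5}


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SarcomereGroundTruth:
    """Ground truth for one myofibril: Z-disc positions, SL and TFL per
    sarcomere, and the titin isoform class driving epitope placement.

    ``z_positions`` (um) are strictly increasing; ``sl_values[i]`` equals
    ``z_positions[i+1] - z_positions[i]``; each TFL is positive and below its
    sarcomere's SL (thin filaments may still reach past mid-sarcomere, which
    is exactly the overlap-band phenotype).
    """

    z_positions: np.ndarray
    tfl_values: np.ndarray
    isoform_class: str = "mixed"
    cell_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_positions",
                           np.asarray(self.z_positions, dtype=float))
        object.__setattr__(self, "tfl_values",
                           np.asarray(self.tfl_values, dtype=float))
        z = self.z_positions
        if z.size < 2:
            raise ValueError("need at least 2 Z-disc positions")
        if not np.all(np.diff(z) > 0):
            raise ValueError("z_positions must be strictly increasing")
        sl = np.diff(z)
        if self.tfl_values.size != sl.size:
            raise ValueError("one TFL per sarcomere required")
        if np.any(self.tfl_values <= 0):
            raise ValueError("all TFL values must be positive")
        if np.any(self.tfl_values >= sl):
            raise ValueError("TFL must be below the sarcomere's SL")
        if self.isoform_class not in _ISOFORM_CLASSES:
            raise ValueError(f"isoform_class must be one of {_ISOFORM_CLASSES}")

    @property
    def sl_values(self) -> np.ndarray:
        return np.diff(self.z_positions)

    @property
    def n_sarcomeres(self) -> int:
        return self.z_positions.size - 1

    @classmethod
    def from_sl_tfl(cls, sl_values, tfl_values, cell_id: str = "",
                    isoform_class: str = "mixed",
                    origin: float = 0.0) -> "SarcomereGroundTruth":
        z = origin + np.concatenate([[0.0], np.cumsum(np.asarray(sl_values, float))])
        return cls(z, tfl_values, isoform_class, cell_id)


@dataclass(frozen=True)
class OpticalModelParams:
    """Imaging parameters of the forward model.

    Defaults emulate confocal imaging of ~1 um banding: 0.05 um pixels and a
    0.10 um lateral PSF sigma. Amplitudes are arbitrary fluorescence units;
    ``epitope_offsets`` maps a titin epitope channel to the linear placement
    law ``offset = c + s * (SL - 2.0)`` (um from the Z-disc, per flank).
    """

    pixel_size: float = 0.05
    psf_sigma: float = 0.10
    z_amplitude: float = 1.0
    thin_amplitude: float = 0.5
    epitope_amplitude: float = 1.0
    baseline: float = 0.1
    noise_sd: float = 0.0
    epitope_offsets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"titin_ex49": (0.10, 0.05),
                                 "titin_ex224": (0.25, 0.15)})

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be non-negative")
        for name in ("z_amplitude", "thin_amplitude", "epitope_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PopulationSpec:
    """Generating distribution of a cell population.

    Per cell, a cell-level mean SL is drawn as ``Normal(sl_mean,
    cell_sl_sd)``; per sarcomere, SL ~ ``Normal(cell_mean, sl_sd)`` truncated
    above 0.8 um; TFL follows the linear law ``tfl_slope * SL +
    tfl_intercept + Normal(0, tfl_noise_sd)`` truncated into ``(0, SL)``.
    A fraction ``affected_fraction`` of cells instead draws SL from the
    shortened distribution ``Normal(affected_sl_mean, affected_sl_sd)`` and
    is labelled N2B-dominant, emulating the patchy short-sarcomere phenotype.
    """

    n_cells: int
    sl_mean: float
    sl_sd: float
    tfl_slope: float
    tfl_intercept: float
    tfl_noise_sd: float
    n_sarcomeres: int = 10
    cell_sl_sd: float = 0.0
    affected_fraction: float = 0.0
    affected_sl_mean: float | None = None
    affected_sl_sd: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_sarcomeres < 1:
            raise ValueError("n_cells and n_sarcomeres must be positive")
        if self.sl_sd < 0 or self.cell_sl_sd < 0 or self.tfl_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class QpcrTruth:
    """Ground truth of a titin isoform qPCR sample.

    ``pct_n2b`` is the percentage of titin transcripts that are N2B;
    ``efficiency`` the per-cycle amplification factor (2 = perfect doubling);
    ``ct_ref`` the reference-gene Ct; replicate Cts are jittered with
    ``tech_noise_sd`` cycles of technical noise.
    """

    pct_n2b: float
    ct_ref: float = 20.0
    efficiency: float = 2.0
    tech_noise_sd: float = 0.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_n2b <= 100.0:
            raise ValueError("pct_n2b must lie in [0, 100]")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must lie in (1, 2]")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.tech_noise_sd < 0:
            raise ValueError("tech_noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# analytic optical field
# ---------------------------------------------------------------------------


def _gaussian_impulses(x: np.ndarray, centers: np.ndarray, amplitude: float,
                       sigma: float) -> np.ndarray:
    """PSF-blurred unit-height impulses on a regular ascending grid;
    exact nearest-sample deltas when sigma == 0."""
    out = np.zeros_like(x)
    if amplitude == 0 or centers.size == 0:
        return out
    step = float(x[1] - x[0]) if x.size > 1 else 1.0
    if sigma == 0:
        idx = np.clip(np.round((centers - x[0]) / step).astype(int),
                      0, x.size - 1)
        np.add.at(out, idx, amplitude)
        return out
    half = int(np.ceil(6.0 * sigma / step))  # 6-sigma support window
    for c in centers:
        i0 = int(np.clip(np.floor((c - x[0]) / step) - half, 0, x.size))
        i1 = int(np.clip(i0 + 2 * half + 1, 0, x.size))
        xs = x[i0:i1]
        out[i0:i1] += amplitude * np.exp(-0.5 * ((xs - c) / sigma) ** 2)
    return out


def _box_coverage(x: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                  sigma: float) -> np.ndarray:
    """Sum of unit boxcars [lo_i, hi_i] convolved with a Gaussian PSF."""
    out = np.zeros_like(x)
    if sigma == 0:
        for a, b in zip(lo, hi):
            out += ((x >= a) & (x < b)).astype(float)
        return out
    s = sigma * np.sqrt(2.0)
    for a, b in zip(lo, hi):
        out += 0.5 * (erf((x - a) / s) - erf((x - b) / s))
    return out


def _epitope_centers(truth: SarcomereGroundTruth, channel: str,
                     optics: OpticalModelParams) -> np.ndarray:
    """Titin epitope positions: z +/- (c + s (SL - 2.0)) per flank, with the
    SL-slope scaled by isoform class (the N2B spring region barely extends).
    Each Z uses the SL of the sarcomere on the relevant flank."""
    c, s = optics.epitope_offsets[channel]
    s = s * _EPITOPE_SLOPE_SCALE[truth.isoform_class]
    z = truth.z_positions
    sl = truth.sl_values
    centers = []
    for i, zi in enumerate(z):
        if i > 0:  # left flank uses the sarcomere to the left
            centers.append(zi - (c + s * (sl[i - 1] - 2.0)))
        if i < sl.size:  # right flank uses the sarcomere to the right
            centers.append(zi + (c + s * (sl[i] - 2.0)))
    return np.asarray(centers, dtype=float)


def channel_field(truth: SarcomereGroundTruth, optics: OpticalModelParams,
                  channel: str, x_um: np.ndarray) -> np.ndarray:
    """Noiseless fluorescence of one channel at arbitrary positions (um).

    phalloidin: thin-filament coverage count (filaments span ``[z, z+TFL]``
    rightward and ``[z-TFL, z]`` leftward of each Z) times the thin-filament
    amplitude, plus a Z-localised boost; alpha_actinin / myomesin:
    PSF-blurred impulses at Z / M positions; tmod1: impulses at the pointed
    ends ``z +/- TFL``; titin epitopes: impulses at the class- and
    SL-dependent spring-region offsets. Baseline included, noise not.
    """
    x = np.asarray(x_um, dtype=float)
    z = truth.z_positions
    tfl = truth.tfl_values
    sigma = optics.psf_sigma
    if channel == "phalloidin":
        lo = np.concatenate([z[:-1], z[1:] - tfl])
        hi = np.concatenate([z[:-1] + tfl, z[1:]])
        cov = _box_coverage(x, lo, hi, sigma)
        boost = _gaussian_impulses(x, z, optics.z_amplitude, sigma)
        return optics.baseline + optics.thin_amplitude * cov + boost
    if channel == "alpha_actinin":
        return optics.baseline + _gaussian_impulses(
            x, z, optics.z_amplitude, sigma)
    if channel == "myomesin":
        m = 0.5 * (z[:-1] + z[1:])
        return optics.baseline + _gaussian_impulses(
            x, m, optics.z_amplitude, sigma)
    if channel == "tmod1":
        ends = np.concatenate([z[:-1] + tfl, z[1:] - tfl])
        return optics.baseline + _gaussian_impulses(
            x, ends, optics.epitope_amplitude, sigma)
    if channel in ("titin_ex49", "titin_ex224"):
        centers = _epitope_centers(truth, channel, optics)
        return optics.baseline + _gaussian_impulses(
            x, centers, optics.epitope_amplitude, sigma)
    raise ValueError(f"unknown channel {channel!r}; choose from {CHANNELS}")


# ---------------------------------------------------------------------------
# profile / image synthesis
# ---------------------------------------------------------------------------


def simulate_profile(truth: SarcomereGroundTruth, optics: OpticalModelParams,
                     channels: Sequence[str] = ("phalloidin", "alpha_actinin"),
                     rng: np.random.Generator | int | None = None,
                     margin_um: float | None = None) -> dict[str, IntensityProfile]:
    """Render 1D intensity profiles of a myofibril, one per channel.

    The sampling grid extends past the outermost Z-discs by ``margin_um``
    (default: the largest TFL plus four PSF sigmas) at ``pixel_size``
    spacing; positions are recorded relative to the first sample, with the
    first Z-disc at ``margin_um``. Deterministic for a given ``rng`` seed.
    """
    if truth.n_sarcomeres < 3:
        raise ValueError("myofibril shorter than 3 sarcomeres is too short "
                         "for downstream measurement")
    bad = [c for c in channels if c not in CHANNELS]
    if bad:
        raise ValueError(f"unknown channel(s) {bad}; choose from {CHANNELS}")
    gen = _as_rng(rng)
    if margin_um is None:
        margin_um = float(truth.tfl_values.max()) + 4.0 * optics.psf_sigma + 0.2
    x = np.arange(truth.z_positions[0] - margin_um,
                  truth.z_positions[-1] + margin_um + optics.pixel_size / 2,
                  optics.pixel_size)
    out = {}
    for channel in channels:
        values = channel_field(truth, optics, channel, x)
        if optics.noise_sd > 0:
            values = values + gen.normal(0.0, optics.noise_sd, x.size)
        out[channel] = IntensityProfile(values, optics.pixel_size,
                                        channel, (float(x[0]), 0.0, 0.0))
    return out


def simulate_image(truths: Sequence[SarcomereGroundTruth],
                   optics: OpticalModelParams, orientation_deg: float = 0.0,
                   size_px: int | tuple[int, int] = (256, 256),
                   rng: np.random.Generator | int | None = None,
                   channels: Sequence[str] = ("phalloidin", "alpha_actinin"),
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a multi-channel 2D image of one or more myofibrils.

    Each myofibril's 1D pattern is extruded laterally into a horizontal band
    (bands stacked top to bottom share the image height equally) and the
    whole pattern is rotated so that the striation normal points along
    ``orientation_deg`` (normalised into [0, 180)). Patterns are centred in
    the image. Returns a ``(n_channels, h, w)`` float32 stack (TIFF-writable,
    one page per channel) and the ground-truth table.
    """
    truths = list(truths)
    if not truths:
        raise ValueError("empty population: nothing to render")
    gen = _as_rng(rng)
    h, w = (size_px, size_px) if isinstance(size_px, int) else size_px
    min_extent = 3 * min(float(t.sl_values.mean()) for t in truths)
    if min(h, w) * optics.pixel_size < min_extent:
        raise ValueError("image too small to contain 3 striation periods")
    theta = np.radians(orientation_deg % 180.0)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    t_px = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    u_px = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    band = np.clip(((u_px + h / 2.0) // (h / len(truths))).astype(int),
                   0, len(truths) - 1)
    stack = np.empty((len(channels), h, w), dtype=np.float32)
    for ci, channel in enumerate(channels):
        plane = np.zeros((h, w), dtype=float)
        for bi, truth in enumerate(truths):
            mask = band == bi
            center = 0.5 * (truth.z_positions[0] + truth.z_positions[-1])
            t_um = t_px[mask] * optics.pixel_size + center
            # evaluate the analytic field once on a fine regular grid and
            # interpolate onto the rotated coordinates; quarter-pixel
            # sampling keeps the interpolation error far below the noise
            step = optics.pixel_size / 4.0
            x_fine = np.arange(t_um.min() - step, t_um.max() + 2 * step, step)
            field = channel_field(truth, optics, channel, x_fine)
            plane[mask] = np.interp(t_um, x_fine, field)
        if optics.noise_sd > 0:
            plane = plane + gen.normal(0.0, optics.noise_sd, plane.shape)
        stack[ci] = plane.astype(np.float32)
    return stack, truth_table(truths)


def truth_table(truths: Sequence[SarcomereGroundTruth]) -> pd.DataFrame:
    """Tidy ground-truth table: cell_id, sarcomere_index, sl_um, tfl_um."""
    rows = []
    for t in truths:
        for i, (sl, tfl) in enumerate(zip(t.sl_values, t.tfl_values)):
            rows.append({"cell_id": t.cell_id, "sarcomere_index": i,
                         "sl_um": float(sl), "tfl_um": float(tfl),
                         "isoform_class": t.isoform_class})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population generator
# ---------------------------------------------------------------------------


def _truncated_normal(gen: np.random.Generator, mean, sd: float, lower: float,
                      upper: float = np.inf, max_tries: int = 1000) -> np.ndarray:
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    draws = gen.normal(mean, sd)
    for _ in range(max_tries):
        bad = (draws <= lower) | (draws >= upper)
        if not bad.any():
            return draws
        draws = np.where(bad, gen.normal(mean, sd), draws)
    raise RuntimeError("truncated sampling failed to converge")


def simulate_population(spec: PopulationSpec,
                        rng: np.random.Generator | int | None = None,
                        ) -> list[SarcomereGroundTruth]:
    """Draw a population of myofibril ground truths from a PopulationSpec.

    Bit-reproducible under a fixed seed (``spec.seed`` is used when no
    ``rng`` is passed). Raises when the requested TFL law is degenerate,
    i.e. when more than half of the raw TFL draws land at or above their
    sarcomere's SL.
    """
    gen = _as_rng(spec.seed if rng is None else rng)
    cells: list[SarcomereGroundTruth] = []
    n_tfl_violations = 0
    n_tfl_draws = 0
    affected_flags = gen.random(spec.n_cells) < spec.affected_fraction
    for ci in range(spec.n_cells):
        if affected_flags[ci]:
            mean = spec.affected_sl_mean if spec.affected_sl_mean is not None \
                else spec.sl_mean - 0.3
            sd = spec.affected_sl_sd if spec.affected_sl_sd is not None \
                else spec.sl_sd
            iso = "N2B-dominant"
        else:
            mean, sd, iso = spec.sl_mean, spec.sl_sd, "mixed"
        cell_mean = mean if spec.cell_sl_sd == 0 else \
            float(_truncated_normal(gen, mean, spec.cell_sl_sd,
                                    SL_TRUNCATION_UM)[0])
        sl = _truncated_normal(gen, np.full(spec.n_sarcomeres, cell_mean),
                               sd, SL_TRUNCATION_UM) if sd > 0 else \
            np.full(spec.n_sarcomeres, cell_mean)
        tfl_mean = spec.tfl_slope * sl + spec.tfl_intercept
        raw = gen.normal(tfl_mean, spec.tfl_noise_sd) if spec.tfl_noise_sd > 0 \
            else tfl_mean.copy()
        n_tfl_draws += raw.size
        n_tfl_violations += int(np.sum((raw <= 0) | (raw >= sl)))
        bad = (raw <= 0) | (raw >= sl)
        tries = 0
        while bad.any():
            tries += 1
            if tries > 1000 or spec.tfl_noise_sd == 0:
                raw = np.where(bad, np.clip(raw, 1e-3, sl - 1e-3), raw)
                break
            raw = np.where(bad, gen.normal(tfl_mean, spec.tfl_noise_sd), raw)
            bad = (raw <= 0) | (raw >= sl)
        cells.append(SarcomereGroundTruth.from_sl_tfl(
            sl, raw, cell_id=f"cell_{ci:04d}", isoform_class=iso))
    if n_tfl_violations > 0.5 * n_tfl_draws:
        raise ValueError("degenerate spec: TFL >= SL in more than half of "
                         "the draws")
    return cells


# ---------------------------------------------------------------------------
# gel / qPCR / force generators
# ---------------------------------------------------------------------------


def simulate_gel_lane(pct_n2b: float, band_centers: tuple[float, float] = (70.0, 50.0),
                      band_sigmas: tuple[float, float] = (3.0, 3.0),
                      total_area: float = 1000.0, baseline_slope: float = 0.0,
                      baseline_offset: float = 0.0, noise_sd: float = 0.0,
                      migration_max: float = 120.0, n_samples: int = 241,
                      rng: np.random.Generator | int | None = None,
                      lane_id: str = "", group: str = "") -> GelLane:
    """Synthesise a two-band titin gel densitometry profile.

    ``band_centers`` are (N2B, N2BA) positions on the migration axis — the
    smaller N2B isoform migrates farther, so its centre must be the larger
    coordinate. Band areas split ``total_area`` according to ``pct_n2b``;
    a linear baseline and additive Gaussian noise complete the lane. Bands
    closer than twice the widest sigma are generated with a warning (they
    will not be resolvable downstream).
    """
    if not 0.0 <= pct_n2b <= 100.0:
        raise ValueError("pct_n2b must lie in [0, 100]")
    c_n2b, c_n2ba = band_centers
    if c_n2b == c_n2ba:
        raise ValueError("band centers must be distinct")
    if c_n2b < c_n2ba:
        raise ValueError("N2B migrates farther: its centre must be the "
                         "larger migration coordinate")
    if abs(c_n2b - c_n2ba) < 2.0 * max(band_sigmas):
        warnings.warn("band separation below 2 sigma: bands will be "
                      "unresolvable", stacklevel=2)
    gen = _as_rng(rng)
    x = np.linspace(0.0, migration_max, n_samples)
    a_n2b = total_area * pct_n2b / 100.0
    a_n2ba = total_area * (1.0 - pct_n2b / 100.0)
    od = np.zeros_like(x)
    for area, center, sigma in ((a_n2b, c_n2b, band_sigmas[0]),
                                (a_n2ba, c_n2ba, band_sigmas[1])):
        od += area / (sigma * np.sqrt(2.0 * np.pi)) * \
            np.exp(-0.5 * ((x - center) / sigma) ** 2)
    od += baseline_offset + baseline_slope * x
    if noise_sd > 0:
        od = od + gen.normal(0.0, noise_sd, x.size)
    return GelLane(profile=od, spacing=float(x[1] - x[0]), lane_id=lane_id,
                   group=group)


def simulate_ct_table(truth: QpcrTruth,
                      targets: Sequence[str] = ("N2B_element", "N2A_element",
                                                "reference"),
                      sample_id: str = "S1", ct_n2b_base: float = 19.0,
                      rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Generate a qPCR Ct table under the titin transcript-mixture model.

    All titin transcripts carry the N2B element while only N2BA transcripts
    carry the N2A element, so the N2A template is a ``1 - pct_n2b/100``
    fraction of the N2B template and
    ``Ct_N2A - Ct_N2B = -log_eff(1 - pct_n2b / 100)``. The reference gene
    sits at ``ct_ref``. At ``pct_n2b == 100`` the N2A template is absent and
    its Ct is emitted censored (flagged undetermined) rather than infinite.
    Technical replicates are jittered by ``tech_noise_sd`` cycles.
    """
    gen = _as_rng(rng)
    frac_n2ba = 1.0 - truth.pct_n2b / 100.0
    ct_by_target = {"N2B_element": ct_n2b_base, "reference": truth.ct_ref}
    if frac_n2ba > 0:
        ct_by_target["N2A_element"] = ct_n2b_base - \
            np.log(frac_n2ba) / np.log(truth.efficiency)
    else:
        ct_by_target["N2A_element"] = None  # template absent
    rows = []
    for target in targets:
        if target not in ct_by_target:
            raise ValueError(f"unknown target {target!r}")
        base = ct_by_target[target]
        for rep in range(truth.replicates):
            if base is None:
                rows.append({"sample_id": sample_id, "target": target,
                             "replicate": rep, "ct": np.nan, "censored": True})
            else:
                ct = base + (gen.normal(0.0, truth.tech_noise_sd)
                             if truth.tech_noise_sd > 0 else 0.0)
                rows.append({"sample_id": sample_id, "target": target,
                             "replicate": rep, "ct": float(ct),
                             "censored": False})
    return pd.DataFrame(rows)


def simulate_force_pca(pca50: float, n_hill: float, f_max: float,
                       passive_force: float, pca_grid: Sequence[float],
                       noise_sd: float = 0.0,
                       rng: np.random.Generator | int | None = None) -> ForcePCaCurve:
    """Hill-shaped total force over a descending pCa grid.

    ``total = passive + f_max / (1 + 10^(n (pCa - pCa50))) + noise``; the
    grid must be descending in pCa (ascending [Ca2+]), the convention in
    which skinned-fibre activation series are recorded.
    """
    if n_hill <= 0:
        raise ValueError("Hill coefficient must be positive")
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    grid = np.asarray(pca_grid, dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) < 0):
        raise ValueError("pca_grid must be descending in pCa")
    gen = _as_rng(rng)
    active = f_max / (1.0 + 10.0 ** (n_hill * (grid - pca50)))
    total = passive_force + active
    if noise_sd > 0:
        total = total + gen.normal(0.0, noise_sd, grid.size)
    return ForcePCaCurve(grid, total, passive_force)


# ---------------------------------------------------------------------------
# developmental series / physiology tables
# ---------------------------------------------------------------------------


def simulate_transition_series(stages: Sequence[str],
                               genotype_pcts: Mapping[str, Sequence[float]],
                               n_per_stage: int = 4, noise_sd: float = 3.0,
                               rng: np.random.Generator | int | None = None,
                               ) -> pd.DataFrame:
    """Per-stage %N2B samples for several genotypes (postnatal transition).

    ``genotype_pcts`` maps genotype to the true %N2B trajectory over
    ``stages``; each stage yields ``n_per_stage`` biological samples with
    Gaussian scatter, clipped into [0, 100].
    """
    gen = _as_rng(rng)
    rows = []
    for genotype, pcts in genotype_pcts.items():
        if len(pcts) != len(stages):
            raise ValueError("one true %N2B per stage required")
        for stage, pct in zip(stages, pcts):
            draws = np.clip(gen.normal(pct, noise_sd, n_per_stage), 0.0, 100.0)
            for si, v in enumerate(draws):
                rows.append({"stage": stage, "genotype": genotype,
                             "sample": f"{genotype}_{stage}_{si}",
                             "pct_n2b": float(v)})
    return pd.DataFrame(rows)


def simulate_wall_thickening(segment_means: Mapping[str, Mapping[str, float]],
                             segment_sds: Mapping[str, Mapping[str, float]],
                             n_per_segment: int = 8,
                             rng: np.random.Generator | int | None = None,
                             ) -> pd.DataFrame:
    """Tidy per-segment fractional wall thickening values per group.

    ``segment_means[group][segment]`` / ``segment_sds[group][segment]`` give
    the generating Normal for each cell of the design.
    """
    gen = _as_rng(rng)
    rows = []
    for group, means in segment_means.items():
        for segment, mu in means.items():
            sd = segment_sds[group][segment]
            for v in gen.normal(mu, sd, n_per_segment):
                rows.append({"group": group, "segment": segment,
                             "value": float(v)})
    return pd.DataFrame(rows)
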