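"""Quantification of morphogen intensity profiles along the neural tube.

Raw inputs are fluorescence intensity traces measured from the ventral to
the dorsal midline (1-micron steps) with a per-section mesoderm background
value.  The pipeline subtracts background, stages sections by their total
dorsoventral (DV) length, bins cohorts by stage and relative position,
spline-smooths the binned curves, locates the source/target boundary at
the intensity peak, fits an exponential gradient C(x) = C0 * exp(-x / lambda)
dorsal to the boundary, regresses amplitude and decay length on tissue
size, and stereotypes the ventral Shh time courses into linear ramps for
the pathway model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import CubicSpline

__all__ = [
    "GradientProfile",
    "ExponentialFit",
    "StereotypedFit",
    "LinearCalibration",
    "TrendResult",
    "subtract_background",
    "stage_by_dv_length",
    "bin_profiles",
    "smooth_spline",
    "locate_source_boundary",
    "boxcar_smooth",
    "fit_exponential",
    "trend_vs_size",
    "band_timecourse",
    "build_ramps_from_profiles",
    "stereotype_timecourse",
    "profiles_to_frame",
    "profiles_from_frame",
]

PROFILE_COLUMNS = (
    "embryo_id",
    "section_id",
    "channel",
    "dv_length_um",
    "position_um",
    "intensity_au",
    "background_au",
)


@dataclass(frozen=True)
class GradientProfile:
    """One intensity trace along the DV axis of a single section.

    Positions are microns from the ventral midline (strictly increasing);
    ``dv_length`` is the total DV neural-tube length of the section and
    must reach at least the last measured position.
    """

    positions: np.ndarray
    intensity: np.ndarray
    background: float
    dv_length: float
    channel: str = "Shh"
    embryo_id: str = ""
    section_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, float))
        if self.positions.shape != self.intensity.shape:
            raise ValueError("positions and intensity must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.dv_length < self.positions[-1]:
            raise ValueError("dv_length must cover the measured positions")
        if self.background < 0:
            raise ValueError("background must be >= 0")

    @property
    def relative_positions(self) -> np.ndarray:
        return self.positions / self.dv_length


@dataclass(frozen=True)
class ExponentialFit:
    """Result of fitting C(x) = C0 * exp(-x / lambda) dorsal to the source.

    ``x`` is distance from the source boundary; ``r_squared`` is computed
    on the fitted points.
    """

    C0: float
    lam: float
    r_squared: float
    boundary_position: float
    n_points: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"decay length must be positive, got {self.lam}")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    def __call__(self, x_from_boundary: np.ndarray) -> np.ndarray:
        return self.C0 * np.exp(-np.asarray(x_from_boundary, float) / self.lam)


@dataclass(frozen=True)
class StereotypedFit:
    """Linear fit of a band-averaged Shh time course, used to build ramps."""

    position_band: tuple[float, float]  # fractions of DV length
    slope: float  # a.u. per h
    intercept: float  # a.u. at t = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")

    @property
    def zero_crossing(self) -> float:
        """Time at which the extrapolated line reaches zero intensity."""
        if self.slope == 0:
            raise ValueError("zero slope has no zero-crossing")
        return -self.intercept / self.slope


@dataclass(frozen=True)
class LinearCalibration:
    """Linear somite-stage <-> DV-length relation, fitted from a cohort."""

    slope: float  # stage units per micron
    intercept: float
    length_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("degenerate calibration: zero slope")

    @classmethod
    def fit(
        cls, dv_lengths: Sequence[float], stages: Sequence[float]
    ) -> "LinearCalibration":
        x = np.asarray(dv_lengths, float)
        y = np.asarray(stages, float)
        if len(x) < 2:
            raise ValueError("calibration needs at least 2 points")
        slope, intercept = np.polyfit(x, y, 1)
        return cls(float(slope), float(intercept), (float(x.min()), float(x.max())))

    def stage(self, dv_length: float) -> float:
        return self.slope * dv_length + self.intercept

    def dv_length(self, stage: float) -> float:
        return (stage - self.intercept) / self.slope

    def in_range(self, dv_length) -> np.ndarray:
        lo, hi = self.length_range
        return (np.asarray(dv_length) >= lo) & (np.asarray(dv_length) <= hi)


def subtract_background(profile: GradientProfile) -> GradientProfile:
    """Subtract the per-section background, clamping at zero."""
    cleaned = np.maximum(profile.intensity - profile.background, 0.0)
    return replace(profile, intensity=cleaned, background=0.0)


def stage_by_dv_length(
    dv_length: float, calibration: LinearCalibration
) -> tuple[float, bool]:
    """Somite-stage estimate for a section, plus an extrapolation flag.

    The flag is True when ``dv_length`` falls outside the range the
    calibration was fitted on.
    """
    extrapolated = not bool(np.all(calibration.in_range(dv_length)))
    return calibration.stage(dv_length), extrapolated


def bin_profiles(
    profiles: Iterable[GradientProfile],
    stage_bin_width: float = 40.0,
    n_position_bins: int = 10,
) -> pd.DataFrame:
    """Bin a cohort by developmental stage and relative DV position.

    Stage bins are ``stage_bin_width`` microns of total DV length (the
    staging proxy); position bins cover equal fractions (default 10%) of
    each section's own DV length.  Per (stage bin, position bin) the mean
    intensity and its Student-t 95% confidence interval across sections
    are reported; bins backed by a single section get an undefined (NaN)
    interval.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to bin")
    rows = []
    edges = np.linspace(0.0, 1.0, n_position_bins + 1)
    for prof in profiles:
        rel = prof.relative_positions
        idx = np.clip(np.searchsorted(edges, rel, side="right") - 1, 0, n_position_bins - 1)
        for b in range(n_position_bins):
            mask = idx == b
            if not mask.any():
                continue
            rows.append(
                {
                    "stage_bin": int(prof.dv_length // stage_bin_width),
                    "position_bin": b,
                    "section_mean": float(prof.intensity[mask].mean()),
                    "dv_length_um": prof.dv_length,
                }
            )
    per_section = pd.DataFrame(rows)
    out = []
    for (sb, pb), grp in per_section.groupby(["stage_bin", "position_bin"]):
        vals = grp["section_mean"].to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        if n > 1:
            half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        else:
            half = np.nan
        out.append(
            {
                "stage_bin": sb,
                "stage_dv_length_um": (sb + 0.5) * stage_bin_width,
                "position_bin": pb,
                "position_frac": (edges[pb] + edges[pb + 1]) / 2,
                "mean": mean,
                "ci_lo": mean - half,
                "ci_hi": mean + half,
                "n": n,
            }
        )
    return pd.DataFrame(out).sort_values(["stage_bin", "position_bin"]).reset_index(
        drop=True
    )


def smooth_spline(
    x: Sequence[float], y: Sequence[float], step: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline interpolation through bin means on a fine grid.

    Uses a not-a-knot cubic spline (the classic interpolating 'spline')
    evaluated every ``step`` microns; the curve passes exactly through the
    knots.  With fewer than 4 knots a linear interpolation is used and a
    warning emitted.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    grid = np.arange(x[0], x[-1] + 0.5 * step, step)
    if len(x) < 4:
        warnings.warn(
            f"only {len(x)} knots; falling back to linear interpolation",
            RuntimeWarning,
            stacklevel=2,
        )
        return grid, np.interp(grid, x, y)
    return grid, CubicSpline(x, y)(grid)


def boxcar_smooth(y: Sequence[float], window_um: int = 7) -> np.ndarray:
    """Moving-average smoothing on the 1-um grid (for boundary detection)."""
    y = np.asarray(y, float)
    if window_um <= 1:
        return y
    kernel = np.ones(window_um) / window_um
    return np.convolve(y, kernel, mode="same")


def locate_source_boundary(
    positions: Sequence[float], intensity: Sequence[float]
) -> float:
    """Position of maximum intensity: the source/target-tissue boundary.

    Expects an already-smoothed profile (raw traces should go through
    :func:`boxcar_smooth` or :func:`smooth_spline` first, so an isolated
    noise spike cannot masquerade as the source).  Ties are broken toward
    the ventral-most (smallest) position.  An all-zero profile has no
    boundary and raises.
    """
    positions = np.asarray(positions, float)
    intensity = np.asarray(intensity, float)
    if np.all(intensity == 0):
        raise ValueError("all-zero profile has no source boundary")
    return float(positions[int(np.argmax(intensity))])


def fit_exponential(
    profile: GradientProfile,
    boundary: float | None = None,
    dorsal_cutoff_frac: float = 0.5,
    tail_lambdas: float = 3.0,
) -> ExponentialFit:
    """Nonlinear least-squares fit of C(x) = C0 * exp(-x / lambda).

    ``x`` is distance dorsal to the source boundary (ventral-of-peak points
    are excluded).  The fit window ends at ``dorsal_cutoff_frac`` of the DV
    length; after a log-linear initialisation on the positive points it is
    further limited to ``tail_lambdas`` initial decay lengths past the
    boundary, so that the far tail — which carries no gradient information
    once the signal is lost in background — cannot distort the fit.
    Requires at least 5 positive-intensity points dorsal to the boundary.
    """
    if boundary is None:
        # coarse peak on a smoothed trace (noise-spike proof), then snap to
        # the raw maximum inside the smoothing window (exact when noiseless)
        coarse = locate_source_boundary(
            profile.positions, boxcar_smooth(profile.intensity)
        )
        near = np.abs(profile.positions - coarse) <= 3.5
        local = np.where(near)[0]
        boundary = float(
            profile.positions[local[np.argmax(profile.intensity[local])]]
        )
    x_all = profile.positions
    y_all = profile.intensity
    cutoff = dorsal_cutoff_frac * profile.dv_length
    sel = (x_all >= boundary) & (x_all <= cutoff)
    x = x_all[sel] - boundary
    y = y_all[sel]
    pos = y > 0
    if pos.sum() < 5:
        raise ValueError(
            f"need >= 5 positive points dorsal to the boundary, got {int(pos.sum())}"
        )
    # log-linear initialisation on the positive points
    slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
    lam0 = -1.0 / slope if slope < 0 else profile.dv_length
    c0 = float(np.exp(intercept))
    if lam0 > 0:
        window = x <= tail_lambdas * lam0
        if window.sum() >= 5:
            x, y = x[window], y[window]

    def resid(theta):
        return theta[0] * np.exp(-x / theta[1]) - y

    fit = optimize.least_squares(
        resid,
        x0=[max(c0, y.max(), 1e-12), max(lam0, 1e-6)],
        bounds=([0.0, 1e-9], [np.inf, np.inf]),
    )
    if not fit.success:
        raise RuntimeError(f"exponential fit did not converge: {fit.message}")
    C0, lam = fit.x
    ss_res = float(np.sum(fit.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExponentialFit(
        C0=float(C0),
        lam=float(lam),
        r_squared=r2,
        boundary_position=float(boundary),
        n_points=len(x),
    )


@dataclass(frozen=True)
class TrendResult:
    """OLS regression of a fitted gradient quantity on tissue size."""

    quantity: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.norm.ppf(0.5 + level / 2) * self.slope_stderr
        return self.slope - half, self.slope + half


def trend_vs_size(
    fits: Sequence[ExponentialFit], dv_lengths: Sequence[float]
) -> dict[str, TrendResult]:
    """Regress amplitude C0 and decay length lambda on DV length (OLS)."""
    if len(fits) != len(dv_lengths):
        raise ValueError("fits and dv_lengths must align")
    if len(fits) < 3:
        raise ValueError("need at least 3 fits for a trend")
    x = np.asarray(dv_lengths, float)
    if np.allclose(x, x[0]):
        raise ValueError("constant regressor: all sections have equal DV length")
    out = {}
    for name, vals in (
        ("C0", np.array([f.C0 for f in fits])),
        ("lambda", np.array([f.lam for f in fits])),
    ):
        res = stats.linregress(x, vals)
        out[name] = TrendResult(
            quantity=name,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            p_value=float(res.pvalue),
            slope_stderr=float(res.stderr),
        )
    return out


def stereotype_timecourse(
    band_series: pd.DataFrame,
    calibration: LinearCalibration | None = None,
    hours_per_stage: float = 1.5,
    bands: tuple[tuple[float, float], ...] = ((0.0, 0.1), (0.1, 0.2)),
) -> tuple[StereotypedFit, ...]:
    """Linear fits of the ventral Shh time courses for ramp construction.

    ``band_series`` needs columns ``band_lo``, ``band_hi``, ``mean`` and
    either ``time_h`` directly or ``dv_length_um`` (converted to hours via
    the stage calibration and ``hours_per_stage``, the development time per
    somite).  Each requested band needs at least 3 time points and an
    increasing trend; a non-positive fitted slope raises, since a
    non-increasing course cannot be extrapolated back to a zero-crossing.
    """
    df = band_series.copy()
    if "time_h" not in df.columns:
        if calibration is None:
            raise ValueError("need a stage calibration to convert size to time")
        df["time_h"] = calibration.stage(df["dv_length_um"]) * hours_per_stage
    fits = []
    for lo, hi in bands:
        grp = df[(np.isclose(df["band_lo"], lo)) & (np.isclose(df["band_hi"], hi))]
        if len(grp) < 3:
            raise ValueError(f"band {lo}-{hi}: need >= 3 stages, got {len(grp)}")
        slope, intercept = np.polyfit(grp["time_h"], grp["mean"], 1)
        if slope <= 0:
            raise ValueError(
                f"band {lo}-{hi}: Shh time course is not increasing (slope={slope:.3g})"
            )
        fits.append(
            StereotypedFit(position_band=(lo, hi), slope=float(slope), intercept=float(intercept))
        )
    return tuple(fits)


def band_timecourse(
    binned: pd.DataFrame,
    bands: tuple[tuple[float, float], ...] = ((0.0, 0.1), (0.1, 0.2)),
) -> pd.DataFrame:
    """Extract per-stage band means from :func:`bin_profiles` output.

    Returns one row per (band, stage bin) with columns ``band_lo``,
    ``band_hi``, ``dv_length_um`` (stage-bin centre) and ``mean``, ready
    for :func:`stereotype_timecourse`.
    """
    n_bins = int(binned["position_bin"].max()) + 1
    rows = []
    for lo, hi in bands:
        b = int(round(lo * n_bins))
        grp = binned[binned["position_bin"] == b]
        for _, r in grp.iterrows():
            rows.append(
                {
                    "band_lo": lo,
                    "band_hi": hi,
                    "dv_length_um": r["stage_dv_length_um"],
                    "mean": r["mean"],
                }
            )
    return pd.DataFrame(rows)


def build_ramps_from_profiles(
    profiles: Iterable[GradientProfile],
    calibration: LinearCalibration | None = None,
    hours_per_stage: float = 1.5,
    stage_bin_width: float = 40.0,
    ramp_max_dv_um: float = 240.0,
):
    """Full stereotyping chain: profiles -> binned bands -> linear fits ->
    normalized ramp inputs.

    The ventral-most band (0-10% DV) becomes signal 1 (peak 2.0), the
    10-20% band signal 2 (peak 1.0).  Only stages up to ``ramp_max_dv_um``
    of DV length enter the linear fits: the ramps idealize the early
    patterning window in which ligand levels at both ventral bands still
    rise; at later stages the 10-20% band slides dorsally past the
    gradient and its course saturates, where a linear extrapolation back
    to zero is no longer meaningful.  Without an explicit stage
    calibration a nominal 10 um-per-somite law is assumed.
    """
    from .stimulation_protocols import build_ramp_inputs

    cleaned = [subtract_background(p) for p in profiles]
    binned = bin_profiles(cleaned, stage_bin_width=stage_bin_width)
    binned = binned[binned["stage_dv_length_um"] <= ramp_max_dv_um]
    series = band_timecourse(binned)
    if calibration is None:
        calibration = LinearCalibration(slope=0.1, intercept=0.0)
    stereo = stereotype_timecourse(
        series, calibration=calibration, hours_per_stage=hours_per_stage
    )
    sig1, sig2 = build_ramp_inputs(stereo[0], stereo[1])
    return sig1, sig2, stereo


def profiles_to_frame(profiles: Iterable[GradientProfile]) -> pd.DataFrame:
    """Long-format table with one row per measured position."""
    rows = []
    for p in profiles:
        rows.append(
            pd.DataFrame(
                {
                    "embryo_id": p.embryo_id,
                    "section_id": p.section_id,
                    "channel": p.channel,
                    "dv_length_um": p.dv_length,
                    "position_um": p.positions,
                    "intensity_au": p.intensity,
                    "background_au": p.background,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def profiles_from_frame(df: pd.DataFrame) -> list[GradientProfile]:
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    out = []
    for (emb, sec, ch), grp in df.groupby(
        ["embryo_id", "section_id", "channel"], sort=True
    ):
        grp = grp.sort_values("position_um")
        out.append(
            GradientProfile(
                positions=grp["position_um"].to_numpy(),
                intensity=grp["intensity_au"].to_numpy(),
                background=float(grp["background_au"].iloc[0]),
                dv_length=float(grp["dv_length_um"].iloc[0]),
                channel=str(ch),
                embryo_id=str(emb),
                section_id=str(sec),
            )
        )
    return out
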