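"""Synthetic cohorts with the statistical structure of the measured data.

The generator emulates the features the analysis pipeline assumes in real
neural-tube sections: an exponential Shh gradient whose decay length is
roughly constant across development (mean 19.6 um, SD 4.2 um) while the
amplitude grows linearly with tissue size over a more than 10-fold range
(amplitude-size correlation near R^2 = 0.8); a fluorescence peak offset
5-13 um from the ventral midline with a smooth ventral shoulder; a
linear somite-stage / DV-length staging law; additive background plus
additive and multiplicative measurement noise.  Every draw records its
ground truth so recovery tests never peek at the pipeline under test.

It also produces adapting (rise-peak-decline) reporter time courses used
to exercise the metric and stereotyping code.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gradient_quant import GradientProfile

__all__ = [
    "CohortSpec",
    "generate_profile",
    "generate_cohort",
    "generate_adapting_timecourse",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generating law for a synthetic cohort of sectioned embryos.

    Amplitudes follow ``C0 = (amp_slope * dv + amp_intercept) * exp(eta)``
    with log-normal residual ``eta ~ N(0, amp_log_sd^2)``: the mean law is
    the linear size dependence of the measured gradient, and the
    multiplicative residual keeps amplitudes positive at small sizes while
    landing the amplitude-size correlation near R^2 = 0.8 at the default
    ``amp_log_sd``.  Decay lengths are normal, truncated at zero.  Additive
    noise is quoted as a fraction of the largest expected amplitude in the
    cohort (one imaging session, one intensity scale).
    """

    n_embryos: int = 60
    dv_length_range: tuple[float, float] = (80.0, 400.0)  # um, ~E8.5-E10.5
    # staging law: somite stage = dv_length / stage_slope + noise
    stage_slope: float = 10.0  # um per somite
    stage_intercept: float = 0.0
    stage_noise_sd: float = 1.0  # somites
    # gradient shape
    lambda_mean: float = 19.6  # um
    lambda_sd: float = 4.2  # um
    amp_slope: float = 3.5  # a.u. per um
    amp_intercept: float = -175.0  # a.u.; >10-fold growth over the size range
    amp_log_sd: float = 0.22  # log-normal residual, targets R^2 ~ 0.8
    peak_offset_range: tuple[float, float] = (5.0, 13.0)  # um
    rise_width: float = 4.0  # um, ventral half-Gaussian shoulder
    # background and noise
    background_level: float = 30.0  # a.u.
    background_sd: float = 5.0
    additive_noise_frac: float = 0.02  # of the cohort-max expected amplitude
    multiplicative_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "stage_noise_sd",
            "lambda_sd",
            "amp_log_sd",
            "background_sd",
            "additive_noise_frac",
            "multiplicative_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lambda_mean <= 0:
            raise ValueError("lambda_mean must be positive")
        lo, hi = self.dv_length_range
        if not 0 < lo < hi:
            raise ValueError("invalid dv_length_range")

    @property
    def max_expected_amplitude(self) -> float:
        return self.amp_slope * self.dv_length_range[1] + self.amp_intercept

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        d = json.loads(Path(path).read_text())
        for k in ("dv_length_range", "peak_offset_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Redraw until above ``lo``; degenerate sd returns the mean."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    raise RuntimeError("truncated normal rejection failed; check spec")


def generate_profile(
    spec: CohortSpec,
    rng: np.random.Generator,
    dv_length: float | None = None,
    embryo_id: str = "e0",
    section_id: str = "s0",
) -> tuple[GradientProfile, dict]:
    """One synthetic section: intensity trace plus its ground truth.

    The noiseless signal is ``C0 * exp(-(x - x_peak)/lambda)`` dorsal to
    the peak and a half-Gaussian shoulder (width ``rise_width``) ventral to
    it, with constant background; multiplicative then additive Gaussian
    noise is applied on the 1-um grid.
    """
    if dv_length is None:
        dv_length = float(rng.uniform(*spec.dv_length_range))
    lam = _truncated_normal(rng, spec.lambda_mean, spec.lambda_sd, 0.0)
    mean_amp = spec.amp_slope * dv_length + spec.amp_intercept
    if mean_amp <= 0:
        raise ValueError(
            "amplitude law non-positive at this size; adjust amp_slope/intercept"
        )
    c0 = mean_amp * float(np.exp(rng.normal(0.0, spec.amp_log_sd)))
    # the source/target boundary shifts dorsally as the floor plate grows,
    # so the peak offset tracks tube size within its observed range
    p_lo, p_hi = spec.peak_offset_range
    lo, hi = spec.dv_length_range
    frac = (dv_length - lo) / (hi - lo)
    # snapped to the 1-um measurement grid so the recorded truth is exactly
    # realizable by the sampled profile
    x_peak = float(
        np.round(
            np.clip(p_lo + frac * (p_hi - p_lo) + rng.uniform(-1.5, 1.5), p_lo, p_hi)
        )
    )
    background = max(float(rng.normal(spec.background_level, spec.background_sd)), 0.0)
    stage = (
        dv_length / spec.stage_slope
        + spec.stage_intercept
        + rng.normal(0.0, spec.stage_noise_sd)
    )

    x = np.arange(0.0, np.floor(dv_length) + 0.5, 1.0)
    signal = np.where(
        x >= x_peak,
        c0 * np.exp(-(x - x_peak) / lam),
        c0 * np.exp(-((x - x_peak) ** 2) / (2.0 * spec.rise_width**2)),
    )
    add_sd = spec.additive_noise_frac * spec.max_expected_amplitude
    noisy = (
        signal * (1.0 + spec.multiplicative_cv * rng.standard_normal(x.shape))
        + background
        + add_sd * rng.standard_normal(x.shape)
    )
    profile = GradientProfile(
        positions=x,
        intensity=np.maximum(noisy, 0.0),
        background=background,
        dv_length=dv_length,
        channel="Shh",
        embryo_id=embryo_id,
        section_id=section_id,
    )
    truth = {
        "embryo_id": embryo_id,
        "section_id": section_id,
        "dv_length_um": dv_length,
        "C0": c0,
        "lambda_um": lam,
        "peak_um": x_peak,
        "background_au": background,
        "somite_stage": float(stage),
    }
    return profile, truth


def generate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator = 0
) -> tuple[list[GradientProfile], pd.DataFrame]:
    """A cohort of one section per embryo, sizes spanning the spec range.

    DV lengths are evenly spread (with jitter) across the range so the
    amplitude law realises its full, more than 10-fold dynamic range.
    Returns the profiles and a truth table with one row per profile.
    """
    if spec.n_embryos < 3:
        raise ValueError("a cohort needs at least 3 embryos")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = spec.dv_length_range
    centers = np.linspace(lo, hi, spec.n_embryos)
    jitter = (hi - lo) / (2.0 * spec.n_embryos)
    profiles, truths = [], []
    for i, c in enumerate(centers):
        dv = float(np.clip(c + rng.uniform(-jitter, jitter), lo, hi))
        prof, truth = generate_profile(
            spec, rng, dv_length=dv, embryo_id=f"e{i:03d}", section_id="s0"
        )
        profiles.append(prof)
        truths.append(truth)
    return profiles, pd.DataFrame(truths)


def generate_adapting_timecourse(
    basal: float,
    peak: float,
    peak_time: float,
    adapted_level: float,
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
    settle_time: float = 40.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth rise-peak-decline curve with prescribed landmarks.

    Rises (half-cosine) from ``basal`` to ``peak`` at ``peak_time``, eases
    back to ``adapted_level`` by ``settle_time`` and stays there, so the
    peak and the late-window mean equal the stated landmarks exactly in
    the noiseless case.  Gaussian noise of ``noise_sd`` is added pointwise.
    """
    if not (peak > adapted_level > 0 and basal > 0 and peak > basal):
        raise ValueError("landmarks must satisfy peak > adapted_level > 0, peak > basal > 0")
    if not (0 < peak_time < settle_time):
        raise ValueError("need 0 < peak_time < settle_time")
    if grid is None:
        grid = np.arange(0.0, 70.0 + 0.25, 0.5)
    t = np.asarray(grid, float)
    y = np.empty_like(t)
    rising = t <= peak_time
    y[rising] = basal + (peak - basal) * 0.5 * (
        1 - np.cos(np.pi * t[rising] / peak_time)
    )
    falling = (t > peak_time) & (t < settle_time)
    phase = (t[falling] - peak_time) / (settle_time - peak_time)
    y[falling] = adapted_level + (peak - adapted_level) * 0.5 * (
        1 + np.cos(np.pi * phase)
    )
    y[t >= settle_time] = adapted_level
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + noise_sd * rng.standard_normal(t.shape)
    return t, y


def write_cohort(spec: CohortSpec, seed: int, out_dir) -> tuple[Path, Path]:
    """Write profiles.csv and truth.csv for a seeded cohort."""
    from .gradient_quant import profiles_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles, truth = generate_cohort(spec, seed)
    p_path = out / "profiles.csv"
    t_path = out / "truth.csv"
    profiles_to_frame(profiles).to_csv(p_path, index=False)
    truth.to_csv(t_path, index=False)
    return p_path, t_path
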