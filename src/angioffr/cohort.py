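"""Synthetic coronary cohort generator.

Per-patient angiographic data behind published angio-FFR validation studies
is rarely deposited, so this module generates vessels, hemodynamic
measurements, wire-FFR references and rendered angiogram stills with the
statistical structure of a typical intermediate-stenosis cohort: percent
diameter stenosis 45.7 +/- 11.0%, reference diameter 3.25 +/- 0.56 mm,
resting MAP 93.9 +/- 7.0 mmHg, contrast velocity 14.2 +/- 5.9 cm/s, ~10%
tandem-lesion arteries.  Wire FFR is the forward model's FFR plus Gaussian
noise (default SD 0.03, the order of repeat-measurement variability of the
pressure wire itself) — so parameter-recovery tests exercise inversion and
calibration, not model validity.

Every draw flows from a single integer seed; identical configs give
field-for-field identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError
from .flow import FlowMeasurement, HyperemiaModel
from .geometry import (
    CenterlineProfile,
    detect_stenoses,
    reference_diameter,
    resample_profile,
)
from .pressure import CaseData, FluidProperties, compute_ffr
from .segmentation import AngiogramImage

__all__ = [
    "CohortConfig",
    "RenderConfig",
    "SyntheticCase",
    "generate_cohort",
    "render_angiogram",
]

_REJECTION_CAP = 1000


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level distribution parameters (all means/SDs per the defaults)."""

    n_cases: int = 100
    pct_ds_mean: float = 45.7
    pct_ds_sd: float = 11.0
    pct_ds_bounds: tuple[float, float] = (10.0, 90.0)
    d_ref_mean: float = 3.25       # mm
    d_ref_sd: float = 0.56
    d_ref_min: float = 2.0         # inclusion criterion: reference >= 2 mm
    map_mean: float = 93.9         # mmHg
    map_sd: float = 7.0
    map_bounds: tuple[float, float] = (60.0, 130.0)
    velocity_mean: float = 14.2    # cm/s
    velocity_sd: float = 5.9
    velocity_min: float = 2.0      # cm/s; TFC unusable below
    lesion_length_range: tuple[float, float] = (6.0, 20.0)  # mm
    vessel_length_range: tuple[float, float] = (60.0, 100.0)  # mm
    taper_frac: float = 0.10       # proximal-to-distal healthy taper
    tandem_prob: float = 0.102
    bifurcation_prob: float = 0.25
    wire_noise_sd: float = 0.03    # FFR units
    fps: float = 15.0              # advocated cine frame rate
    profile_step: float = 0.1      # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ConfigurationError("n_cases must be non-negative")
        for name in ("pct_ds_sd", "d_ref_sd", "map_sd", "velocity_sd", "wire_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("tandem_prob", "bifurcation_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCase:
    """One generated vessel with its measurements, truth and wire reference."""

    case_id: str
    profile: CenterlineProfile
    flow: FlowMeasurement
    map_rest: float
    wire_ffr: float
    truth: dict[str, Any]
    bifurcation: bool = False

    def to_case_data(self, entry_frac: float = 0.10, exit_frac: float = 0.05,
                     merge_gap: float = 2.0) -> CaseData:
        """Re-detect lesions on the profile and package for batch physics."""
        d_ref = reference_diameter(self.profile)
        lesions = detect_stenoses(self.profile, d_ref, entry_frac, exit_frac, merge_gap)
        return CaseData(
            profile=self.profile,
            lesions=tuple(lesions),
            flow=self.flow,
            map_rest=self.map_rest,
            wire_ffr=self.wire_ffr,
            case_id=self.case_id,
        )


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf) -> float:
    if sd == 0:
        if not (low <= mean <= high):
            raise ConfigurationError("degenerate draw outside truncation bounds")
        return float(mean)
    for _ in range(_REJECTION_CAP):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    raise ConfigurationError(
        f"rejection-sampling cap hit for N({mean}, {sd}) on [{low}, {high}]"
    )


def _build_profile(cfg: CohortConfig, d_ref: float, lesions: list[dict]) -> CenterlineProfile:
    """Smooth linear-taper healthy vessel with Gaussian diameter dips.

    Each lesion dict has keys pct_ds, center, length; the dip multiplier is
    ``1 - depth * exp(-(s-c)^2 / (2 sigma^2))`` with sigma = length/6, so the
    diameter at the dip center is exactly ``(1 - pct_ds/100)`` of healthy.
    """
    length = lesions[0]["vessel_length"]
    s = np.arange(0.0, length + cfg.profile_step / 2, cfg.profile_step)
    healthy = d_ref * (1.0 + cfg.taper_frac / 2.0) - d_ref * cfg.taper_frac * s / length
    mult = np.ones_like(s)
    for les in lesions:
        sigma = les["length"] / 6.0
        mult *= 1.0 - (les["pct_ds"] / 100.0) * np.exp(
            -((s - les["center"]) ** 2) / (2.0 * sigma**2)
        )
    return CenterlineProfile(s=s, d=healthy * mult)


def _case_truth_ffr(profile, flow, map_rest, hyperemia, fluid, kt):
    d_ref = reference_diameter(profile)
    lesions = detect_stenoses(profile, d_ref)
    sol = compute_ffr(profile, lesions, flow, map_rest, hyperemia, fluid, kt)
    return sol, lesions


def generate_cohort(
    config: CohortConfig,
    hyperemia: HyperemiaModel = HyperemiaModel(),
    fluid: FluidProperties = FluidProperties(),
    kt: float = 1.52,
) -> list[SyntheticCase]:
    """Draw a deterministic synthetic cohort from the configured distributions.

    Wire FFR is the forward pipeline's FFR (profile -> detected lesions ->
    TFC flow -> pressure solution) plus N(0, wire_noise_sd), clipped to
    (0, 1]; with zero noise the pipeline reproduces each case's wire value
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    cases: list[SyntheticCase] = []
    for i in range(config.n_cases):
        for _attempt in range(_REJECTION_CAP):
            case = _draw_case(rng, config, hyperemia, fluid, kt, i)
            if case is not None:
                cases.append(case)
                break
        else:
            raise ConfigurationError(
                "rejection-sampling cap hit: configuration yields only "
                "supra-physiologic cases"
            )
    return cases


_MIN_MODEL_FFR = 0.02  # reject draws whose modelled losses rival Pa itself


def _draw_case(rng, config, hyperemia, fluid, kt, i):
    d_ref = _truncated_normal(rng, config.d_ref_mean, config.d_ref_sd,
                              config.d_ref_min, config.d_ref_mean + 4 * config.d_ref_sd)
    primary_ds = _truncated_normal(rng, config.pct_ds_mean, config.pct_ds_sd,
                                   *config.pct_ds_bounds)
    map_rest = _truncated_normal(rng, config.map_mean, config.map_sd,
                                 *config.map_bounds)
    velocity = _truncated_normal(  # cm/s -> mm/s below
        rng, config.velocity_mean, config.velocity_sd,
        config.velocity_min, config.velocity_mean + 4 * config.velocity_sd
    ) * 10.0
    vessel_length = rng.uniform(*config.vessel_length_range)
    n_lesions = 1
    if rng.uniform() < config.tandem_prob:
        n_lesions = int(rng.integers(2, 4))  # tandem arteries carry 2-3 lesions
    lesion_specs = []
    lo, hi = config.lesion_length_range
    # one slot per lesion inside the mid 60% of the vessel guarantees
    # non-overlapping dips for any draw
    span_lo, span_hi = 0.2 * vessel_length, 0.8 * vessel_length
    slot = (span_hi - span_lo) / n_lesions
    for j in range(n_lesions):
        ds = primary_ds if j == 0 else rng.uniform(min(15.0, primary_ds), primary_ds)
        length = rng.uniform(lo, min(hi, max(lo, 0.6 * slot)))
        center = span_lo + (j + rng.uniform(0.35, 0.65)) * slot
        lesion_specs.append(
            {
                "pct_ds": ds,
                "center": center,
                "length": length,
                "vessel_length": vessel_length,
            }
        )
    profile = _build_profile(config, d_ref, lesion_specs)
    transit = vessel_length / velocity  # s
    frame_count = max(2, int(round(transit * config.fps)))
    flow = FlowMeasurement.from_profile(profile, frame_count, config.fps)
    sol, lesions = _case_truth_ffr(profile, flow, map_rest, hyperemia, fluid, kt)
    if not np.isfinite(sol.ffr) or sol.ffr < _MIN_MODEL_FFR:
        return None  # supra-physiologic draw; caller redraws
    # unit draw scaled afterwards: the rng stream (hence the vessels) is
    # identical across noise settings for a given seed
    noise = rng.normal(0.0, 1.0) * config.wire_noise_sd
    wire = float(np.clip(sol.ffr + noise, 1e-6, 1.0))
    return SyntheticCase(
        case_id=f"case_{i:04d}",
        profile=profile,
        flow=flow,
        map_rest=map_rest,
        wire_ffr=wire,
        bifurcation=bool(rng.uniform() < config.bifurcation_prob),
        truth={
            "d_ref": d_ref,
            "lesions": lesion_specs,
            "pct_ds": primary_ds,
            "velocity_mm_s": velocity,
            "q_rest": flow.q_rest,
            "model_ffr": sol.ffr,
            "detected_pct_ds": max((l.pct_ds for l in lesions), default=0.0),
            "n_lesions": n_lesions,
        },
    )


# ---------------------------------------------------------------------------
# angiogram rendering


@dataclass(frozen=True)
class RenderConfig:
    """How synthetic vessels are rasterized into angiogram stills.

    The lumen silhouette is drawn at uniform opacity (dark vessel on a
    brighter background) so the half-height edge of the blurred image
    coincides with the true lumen border; blur and additive Gaussian noise
    emulate the imaging chain.
    """

    pixel_spacing: float = 0.2   # mm/px
    blur_sigma_px: float = 1.0
    noise_sd: float = 0.0        # intensity units
    background: float = 200.0
    vessel_contrast: float = 120.0
    margin_mm: float = 5.0
    max_canvas_px: int = 4096
    supersample: int = 4
    seed: int = 0


def render_angiogram(
    profile: CenterlineProfile,
    config: RenderConfig = RenderConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[AngiogramImage, dict[str, Any]]:
    """Rasterize an axisymmetric profile as a horizontal dark vessel.

    Returns the image plus a ground-truth dict with the rendered centerline
    row, the arc origin column and the per-column true diameters.  Raises
    when the vessel (plus margins) exceeds the configured canvas.
    """
    sp = config.pixel_spacing
    margin_px = config.margin_mm / sp
    width = int(np.ceil(profile.length / sp + 2 * margin_px))
    height = int(np.ceil((profile.d.max() + 2 * config.margin_mm) / sp))
    width, height = max(width, 64), max(height, 64)
    if width > config.max_canvas_px or height > config.max_canvas_px:
        raise DomainError(
            f"vessel needs a {height}x{width} canvas, exceeding "
            f"{config.max_canvas_px} px"
        )
    ss = config.supersample
    y0 = height / 2.0 - 0.5  # centerline row (pixel centers at integers)
    x0 = margin_px
    # supersampled coverage mask of the lumen silhouette
    cols = (np.arange(width * ss) + 0.5) / ss - 0.5
    rows = (np.arange(height * ss) + 0.5) / ss - 0.5
    s_of_col = (cols - x0) * sp + profile.s[0]
    r_mm = np.interp(s_of_col, profile.s, profile.d) / 2.0
    inside_col = (s_of_col >= profile.s[0]) & (s_of_col <= profile.s[-1])
    half_width_px = np.where(inside_col, r_mm / sp, -1.0)
    mask = np.abs(rows[:, None] - y0) <= half_width_px[None, :]
    coverage = mask.reshape(height, ss, width, ss).mean(axis=(1, 3))
    img = config.background - config.vessel_contrast * coverage
    if config.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, config.blur_sigma_px)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    image = AngiogramImage(pixels=img, pixel_spacing=sp, polarity="dark")
    truth = {
        "centerline_row": y0,
        "origin_col": x0,
        "s_of_col": s_of_col[::ss][:width],
        "profile": profile,
    }
    return image, truth
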