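"""Stenosis pressure-loss physics and the angiographic FFR computation.

The trans-stenotic pressure drop is modelled with the classical quadratic
pressure-flow relationship

    dp = k1 * Q + k2 * Q**2          (vascular resistance R = k1 + k2 * Q)

where the linear coefficient ``k1`` carries viscous friction losses and the
quadratic coefficient ``k2`` carries turbulent jet-expansion (separation)
losses distal to a stenosis.  The viscous part is realized as a Poiseuille
integral over the full axisymmetric diameter profile,

    k1 = int 128 mu / (pi d(s)^4) ds ,

which reduces exactly to 128*mu*L/(pi*D^4) for a uniform tube and handles
tapering automatically.  The expansion part follows the Young-Tsai form per
lesion,

    k2 = kt * rho * (A0/A1 - 1)^2 / (2 * A0^2) ,

with ``A0``/``A1`` the reference and minimal cross-sectional areas and the
empirical separation constant ``kt`` (default 1.52).  The inertial term is
dropped (dU/dt = 0) because FFR is a ratio of time-averaged pressures.

FFR is then ``Pd / Pa`` at simulated hyperemia, with
``Pd = Pa_hyp - dp_total`` evaluated at the hyperemic flow.

All internal physics is in SI; mmHg and mL/s appear only at the interface
(1 mmHg = 133.322 Pa, 1 mL/s = 1e-6 m^3/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, SingularGeometryError
from .flow import FlowMeasurement, HyperemiaModel, simulate_hyperemia
from .geometry import CenterlineProfile, StenosisSegment, resample_profile

__all__ = [
    "PA_PER_MMHG",
    "FluidProperties",
    "LossCoefficients",
    "PressureSolution",
    "CaseData",
    "CalibrationResult",
    "viscous_coefficient_k1",
    "lumped_viscous_k1",
    "expansion_coefficient_k2",
    "vascular_resistance",
    "pressure_drop",
    "compute_ffr",
    "calibrate_kfold",
]

PA_PER_MMHG = 133.322
M3S_PER_MLS = 1e-6

DEFAULT_RESAMPLE_STEP = 0.1  # mm; sub-pixel relative to angiographic resolution


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as a Newtonian fluid: viscosity mu (Pa s), density rho (kg/m^3)."""

    mu: float = 0.0035
    rho: float = 1050.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ConfigurationError("mu and rho must be positive")


@dataclass(frozen=True)
class LossCoefficients:
    """Quadratic-law coefficients in interface units.

    k1 : mmHg s / mL   (viscous, linear in flow)
    k2 : mmHg s^2/mL^2 (expansion, quadratic in flow)
    kv, kt, ku : the dimensionless Young-Tsai shape constants; ``ku`` is
    carried for completeness but unused under the steady-flow assumption.
    """

    k1: float
    k2: float
    kv: float | None = None
    kt: float = 1.52
    ku: float = 1.2

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ConfigurationError("k1 and k2 must be non-negative")
        if self.kt <= 0:
            raise ConfigurationError("kt must be positive")


def viscous_coefficient_k1(
    profile: CenterlineProfile,
    fluid: FluidProperties = FluidProperties(),
    resample_step: float | None = DEFAULT_RESAMPLE_STEP,
) -> float:
    """Poiseuille viscous coefficient of a profile, in mmHg s/mL.

    ``k1 = int 128 mu / (pi d^4) ds`` by the trapezoidal rule on the
    (optionally resampled) profile, evaluated in SI and converted.
    """
    if resample_step is not None and profile.length > resample_step:
        profile = resample_profile(profile, resample_step)
    s_m = profile.s * 1e-3
    d_m = profile.d * 1e-3
    integrand = 128.0 * fluid.mu / (np.pi * d_m**4)  # Pa s / m^4
    k1_si = float(np.trapezoid(integrand, s_m))  # Pa s / m^3
    return k1_si * M3S_PER_MLS / PA_PER_MMHG


def lumped_viscous_k1(
    lesion: StenosisSegment,
    fluid: FluidProperties = FluidProperties(),
    kv: float | None = None,
) -> float:
    """Lumped per-lesion viscous coefficient, for cross-checks.

    Uses the classical lumped form ``dp_v = kv * mu / D0 * U`` with
    ``U = Q/A0``, i.e. ``k1 = kv * mu / (D0 * A0)``.  When ``kv`` is not
    supplied, the Poiseuille-equivalent value for a tube of the lesion's
    minimal diameter and length is used,
    ``kv = 32 * (L / D1) * (A0 / A1)^2``.
    """
    d0 = lesion.d_ref * 1e-3
    a0 = lesion.A0 * 1e-6
    if kv is None:
        kv = 32.0 * (lesion.L / lesion.mld) * (lesion.A0 / lesion.A1) ** 2
    k1_si = kv * fluid.mu / (d0 * a0)
    return k1_si * M3S_PER_MLS / PA_PER_MMHG


def expansion_coefficient_k2(
    lesion: StenosisSegment,
    fluid: FluidProperties = FluidProperties(),
    kt: float = 1.52,
) -> float:
    """Young-Tsai expansion coefficient of one lesion, in mmHg s^2/mL^2.

    ``k2 = kt * rho * (A0/A1 - 1)^2 / (2 A0^2)`` with U taken as the
    reference-section velocity Q/A0.
    """
    if lesion.A1 <= 0:
        raise SingularGeometryError("lesion minimal area is zero")
    a0 = lesion.A0 * 1e-6  # m^2
    ratio = lesion.A0 / lesion.A1
    k2_si = kt * fluid.rho * (ratio - 1.0) ** 2 / (2.0 * a0**2)  # Pa s^2 / m^6
    return k2_si * M3S_PER_MLS**2 / PA_PER_MMHG


def vascular_resistance(coeffs: LossCoefficients, q: float) -> float:
    """R(Q) = k1 + k2*Q in mmHg s/mL; reduces to k1 in the Poiseuille limit."""
    if q < 0:
        raise DomainError("flow must be non-negative")
    return coeffs.k1 + coeffs.k2 * q


def pressure_drop(coeffs: LossCoefficients, q: float) -> float:
    """dp(Q) = k1*Q + k2*Q^2 in mmHg; identically R(Q)*Q."""
    if q < 0:
        raise DomainError("flow must be non-negative")
    return coeffs.k1 * q + coeffs.k2 * q * q


@dataclass(frozen=True)
class LesionLosses:
    """Per-lesion pressure-drop breakdown at the evaluated hyperemic flow."""

    lesion: StenosisSegment
    k2: float
    dp_expansion: float
    dp_viscous: float  # Poiseuille loss over the lesion's own span


@dataclass(frozen=True)
class PressureSolution:
    """Result of one FFR computation.

    ``ffr`` is ``Pd / Pa_hyp`` and is NaN (with a diagnostic in
    ``warnings``) when the modelled losses exceed the driving pressure.
    """

    pa_hyp: float
    q_hyp: float
    dp_viscous: float
    dp_expansion: float
    dp_total: float
    pd: float
    ffr: float
    per_lesion: tuple[LesionLosses, ...] = ()
    warnings: tuple[str, ...] = ()


def compute_ffr(
    profile: CenterlineProfile,
    lesions: Sequence[StenosisSegment],
    flow: FlowMeasurement,
    map_rest: float,
    hyperemia: HyperemiaModel = HyperemiaModel(),
    fluid: FluidProperties = FluidProperties(),
    kt: float = 1.52,
    resample_step: float | None = DEFAULT_RESAMPLE_STEP,
) -> PressureSolution:
    """Full geometry + flow -> pressure solution at simulated hyperemia.

    The viscous drop is the Poiseuille integral over the whole profile at
    the hyperemic flow; the expansion drop is the sum of the per-lesion
    Young-Tsai losses (tandem lesions add).  ``Pd = Pa_hyp - dp_total`` and
    ``ffr = Pd / Pa_hyp``.
    """
    worst_ds = max((l.pct_ds for l in lesions), default=None)
    q_hyp, pa_hyp = simulate_hyperemia(flow.q_rest, map_rest, hyperemia, worst_ds)
    k1 = viscous_coefficient_k1(profile, fluid, resample_step)
    dp_visc = k1 * q_hyp
    per_lesion = []
    dp_exp = 0.0
    for lesion in lesions:
        k2 = expansion_coefficient_k2(lesion, fluid, kt)
        dp_l = k2 * q_hyp * q_hyp
        dp_exp += dp_l
        s0 = max(lesion.s_start, float(profile.s[0]))
        s1 = min(lesion.s_end, float(profile.s[-1]))
        k1_seg = viscous_coefficient_k1(profile.subprofile(s0, s1), fluid, resample_step)
        per_lesion.append(
            LesionLosses(lesion=lesion, k2=k2, dp_expansion=dp_l, dp_viscous=k1_seg * q_hyp)
        )
    dp_total = dp_visc + dp_exp
    pd = pa_hyp - dp_total
    notes: list[str] = []
    if pd <= 0:
        notes.append(
            "supra-physiologic loss: modelled pressure drop "
            f"({dp_total:.1f} mmHg) exceeds hyperemic Pa ({pa_hyp:.1f} mmHg); "
            "ffr undefined"
        )
        ffr = float("nan")
    else:
        ffr = pd / pa_hyp
    return PressureSolution(
        pa_hyp=pa_hyp,
        q_hyp=q_hyp,
        dp_viscous=dp_visc,
        dp_expansion=dp_exp,
        dp_total=dp_total,
        pd=pd,
        ffr=ffr,
        per_lesion=tuple(per_lesion),
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------------------
# k-fold calibration of the hyperemia/separation constants against wire FFR


@dataclass(frozen=True)
class CaseData:
    """One case's inputs for batch FFR computation and calibration."""

    profile: CenterlineProfile
    lesions: tuple[StenosisSegment, ...]
    flow: FlowMeasurement
    map_rest: float
    wire_ffr: float | None = None
    case_id: str = ""


@dataclass(frozen=True)
class CalibrationResult:
    """Grid optimum over all data plus per-held-out-fold error summaries."""

    params: Mapping[str, float]
    fold_bias: np.ndarray
    fold_sd: np.ndarray
    fold_rmse: np.ndarray
    grids: Mapping[str, np.ndarray] = field(default_factory=dict)

    @property
    def cv_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))


DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "flow_factor": np.round(np.arange(1.5, 3.0 + 1e-9, 0.05), 10),
    "kt": np.round(np.arange(0.8, 2.4 + 1e-9, 0.05), 10),
}


def _case_constants(
    cases: Sequence[CaseData],
    hyperemia: HyperemiaModel,
    fluid: FluidProperties,
    resample_step: float | None,
):
    """Per-case constants making FFR(flow_factor, kt) a cheap closed form."""
    k1 = np.array([viscous_coefficient_k1(c.profile, fluid, resample_step) for c in cases])
    k2_unit = np.array(
        [
            sum(expansion_coefficient_k2(l, fluid, kt=1.0) for l in c.lesions)
            for c in cases
        ]
    )
    q_rest = np.array([c.flow.q_rest for c in cases])
    pa = hyperemia.pa_slope * np.array([c.map_rest for c in cases]) + hyperemia.pa_intercept
    wire = np.array([np.nan if c.wire_ffr is None else c.wire_ffr for c in cases])
    return k1, k2_unit, q_rest, pa, wire


def _ffr_grid(k1, k2_unit, q_rest, pa, flow_factor: float, kt: float) -> np.ndarray:
    q = flow_factor * q_rest
    dp = k1 * q + kt * k2_unit * q * q
    return (pa - dp) / pa


def calibrate_kfold(
    cases: Sequence[CaseData],
    tunable: Iterable[str] = ("flow_factor",),
    k: int = 5,
    seed: int = 0,
    grids: Mapping[str, np.ndarray] | None = None,
    hyperemia: HyperemiaModel = HyperemiaModel(),
    fluid: FluidProperties = FluidProperties(),
    kt: float = 1.52,
    resample_step: float | None = DEFAULT_RESAMPLE_STEP,
) -> CalibrationResult:
    """Seeded k-fold grid calibration of model constants against wire FFR.

    Cases are shuffled deterministically by ``seed`` and split into ``k``
    folds.  Per fold, the tunable constants are grid-searched on the
    training folds to minimize the mean squared (FFR - wire FFR); bias, SD
    and RMSE of the held-out fold are recorded.  The returned ``params``
    are the grid optimum refit on all data.
    """
    tunable = tuple(tunable)
    if not tunable:
        raise ConfigurationError("tunable must name at least one constant")
    unknown = set(tunable) - {"flow_factor", "kt"}
    if unknown:
        raise ConfigurationError(f"unknown tunable constants: {sorted(unknown)}")
    n = len(cases)
    if not (2 <= k <= n):
        raise ConfigurationError(f"need 2 <= k <= n cases, got k={k}, n={n}")
    if any(c.wire_ffr is None for c in cases):
        raise ConfigurationError("all cases need a wire_ffr for calibration")
    use_grids = {name: np.asarray((grids or {}).get(name, DEFAULT_GRIDS[name]), float)
                 for name in tunable}

    k1, k2_unit, q_rest, pa, wire = _case_constants(cases, hyperemia, fluid, resample_step)

    f_grid = use_grids.get("flow_factor", np.array([hyperemia.flow_factor]))
    kt_grid = use_grids.get("kt", np.array([kt]))

    # precompute the FFR of every case under every grid combination
    ffr_cube = np.empty((len(f_grid), len(kt_grid), n))
    for i, f in enumerate(f_grid):
        for j, kt_v in enumerate(kt_grid):
            ffr_cube[i, j] = _ffr_grid(k1, k2_unit, q_rest, pa, f, kt_v)

    def best(idx: np.ndarray) -> tuple[int, int]:
        err = ffr_cube[:, :, idx] - wire[idx]
        mse = np.mean(err * err, axis=2)
        flat = int(np.argmin(mse))
        return flat // mse.shape[1], flat % mse.shape[1]

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    bias, sd, rmse = [], [], []
    for held in folds:
        train = np.setdiff1d(order, held)
        i, j = best(train)
        resid = ffr_cube[i, j, held] - wire[held]
        bias.append(float(np.mean(resid)))
        sd.append(float(np.std(resid, ddof=1)) if len(held) > 1 else 0.0)
        rmse.append(float(np.sqrt(np.mean(resid * resid))))
    i, j = best(np.arange(n))
    params = {}
    if "flow_factor" in tunable:
        params["flow_factor"] = float(f_grid[i])
    if "kt" in tunable:
        params["kt"] = float(kt_grid[j])
    return CalibrationResult(
        params=params,
        fold_bias=np.array(bias),
        fold_sd=np.array(sd),
        fold_rmse=np.array(rmse),
        grids=use_grids,
    )
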