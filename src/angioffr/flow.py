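"""Coronary flow kinematics from the TIMI frame count, and simulated hyperemia.

The TIMI frame count (TFC) is the number of cine frames the contrast bolus
needs to traverse a measured centerline length; with the acquisition frame
rate it yields the contrast (taken as blood) velocity.  Combined with the
axisymmetric vessel volume this gives the resting volumetric flow
``Q = V / t_transit``.  Maximal hyperemia — clinically induced with
adenosine, here simulated — is modelled by a linear regression of hyperemic
mean arterial pressure on resting MAP and a multiplicative coronary
flow-reserve factor on resting flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError
from .geometry import CenterlineProfile, axisymmetric_volume

__all__ = [
    "FlowMeasurement",
    "HyperemiaModel",
    "contrast_velocity",
    "resting_flow",
    "simulate_hyperemia",
]


def contrast_velocity(path_length: float, frame_count: float, fps: float) -> float:
    """Contrast (blood) velocity in mm/s from the TIMI frame count.

    ``U = path_length * fps / frame_count`` with ``path_length`` in mm.
    """
    if path_length <= 0 or frame_count <= 0 or fps <= 0:
        raise DomainError("path_length, frame_count and fps must all be positive")
    return path_length * fps / frame_count


def resting_flow(volume_mm3: float, transit_time_s: float) -> float:
    """Resting volumetric flow in mL/s: vessel volume over bolus transit time."""
    if volume_mm3 <= 0 or transit_time_s <= 0:
        raise DomainError("volume and transit time must be positive")
    return volume_mm3 / transit_time_s / 1000.0  # 1000 mm^3 = 1 mL


@dataclass(frozen=True)
class FlowMeasurement:
    """Resting flow state of one vessel derived from a TIMI frame count.

    ``dU/dt`` is fixed at zero: FFR is a ratio of time-averaged pressures,
    so the inertial loss term never contributes.
    """

    frame_count: float
    fps: float
    path_length: float  # mm traversed by the contrast bolus
    q_rest: float       # mL/s
    du_dt: float = 0.0  # mm/s^2, steady-state assumption

    def __post_init__(self) -> None:
        if self.frame_count <= 0 or self.fps <= 0 or self.path_length <= 0:
            raise DomainError("frame_count, fps and path_length must be positive")
        if self.q_rest <= 0:
            raise DomainError("q_rest must be positive")

    @property
    def transit_time(self) -> float:
        """Bolus transit time in seconds, ``frame_count / fps``."""
        return self.frame_count / self.fps

    @property
    def velocity(self) -> float:
        """Contrast velocity in mm/s."""
        return contrast_velocity(self.path_length, self.frame_count, self.fps)

    @classmethod
    def from_profile(
        cls,
        profile: CenterlineProfile,
        frame_count: float,
        fps: float,
        path_length: float | None = None,
    ) -> "FlowMeasurement":
        """Build the measurement with Q from the profile's axisymmetric volume."""
        if path_length is None:
            path_length = profile.length
        volume = axisymmetric_volume(profile)
        q = resting_flow(volume, frame_count / fps)
        return cls(frame_count=frame_count, fps=fps, path_length=path_length, q_rest=q)


@dataclass(frozen=True)
class HyperemiaModel:
    """Resting-to-hyperemic state map.

    pa_slope, pa_intercept
        Hyperemic proximal pressure regression
        ``Pa_hyp = pa_slope * MAP_rest + pa_intercept`` (mmHg).  Defaults
        encode the ~10% MAP decline under intravenous adenosine.
    flow_factor
        Hyperemic-to-resting flow ratio (coronary flow reserve); default 2.0.
    severity_attenuation
        When True, the effective flow factor falls linearly to 1.0 as the
        worst percent diameter stenosis approaches 90% (Gould-type
        flow-reserve blunting).  Off by default.
    """

    pa_slope: float = 0.90
    pa_intercept: float = 0.0
    flow_factor: float = 2.0
    severity_attenuation: bool = False

    def __post_init__(self) -> None:
        if self.pa_slope <= 0:
            raise ConfigurationError("pa_slope must be positive")
        if self.flow_factor < 1:
            raise ConfigurationError("flow_factor must be >= 1")

    def effective_flow_factor(self, pct_ds: float | None = None) -> float:
        if not self.severity_attenuation or pct_ds is None:
            return self.flow_factor
        frac = min(max(pct_ds, 0.0), 90.0) / 90.0
        return self.flow_factor - (self.flow_factor - 1.0) * frac


def simulate_hyperemia(
    q_rest: float,
    map_rest: float,
    model: HyperemiaModel,
    pct_ds: float | None = None,
) -> tuple[float, float]:
    """Map a resting state to simulated maximal hyperemia.

    Returns ``(q_hyp, pa_hyp)`` in (mL/s, mmHg).
    """
    if q_rest <= 0:
        raise DomainError("q_rest must be positive")
    if not (30.0 <= map_rest <= 200.0):
        warnings.warn(
            f"resting MAP {map_rest} mmHg outside the physiologic 30-200 range",
            stacklevel=2,
        )
    pa_hyp = model.pa_slope * map_rest + model.pa_intercept
    q_hyp = model.effective_flow_factor(pct_ds) * q_rest
    return q_hyp, pa_hyp
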