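"""Axisymmetric vessel geometry from 2-D angiographic contours.

A single-view angiogram yields a lumen-diameter profile ``d(s)`` along the
vessel centerline.  Under the axisymmetric assumption every cross-section is
a circle of the locally measured diameter, so the profile fully determines
cross-sectional areas and the vessel volume — the geometric substrate for
the pressure-loss physics in :mod:`angioffr.pressure`.

Stenosis detection follows standard quantitative coronary angiography (QCA)
practice: a "healthy" reference diameter is interpolated by a robust line
fit over the profile (iteratively excluding diseased samples), lesions are
maximal runs where the lumen falls a configurable fraction below that
reference, and severity is the percent diameter stenosis
``%DS = 100 * (1 - MLD / Dref)`` at the minimal lumen diameter (MLD).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateFitError, DomainError, ProfileValidationError

__all__ = [
    "CenterlineProfile",
    "StenosisSegment",
    "resample_profile",
    "reference_diameter",
    "detect_stenoses",
    "percent_diameter_stenosis",
    "axisymmetric_volume",
    "read_profile",
    "write_profile",
]


@dataclass(frozen=True)
class CenterlineProfile:
    """Sampled arc-length / lumen-diameter description of one coronary segment.

    Parameters
    ----------
    s : array of float
        Arc position along the centerline in mm, strictly increasing,
        0 conventionally at the proximal end.
    d : array of float
        Lumen diameter at each ``s`` in mm; all strictly positive.
    case_id : str
        Opaque case label carried through the pipeline.
    pixel_spacing : float or None
        mm per pixel when the profile was extracted from an image.
    """

    s: np.ndarray
    d: np.ndarray
    case_id: str = ""
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "d", d)
        if s.ndim != 1 or d.ndim != 1 or len(s) != len(d):
            raise ProfileValidationError("s and d must be 1-D arrays of equal length")
        if len(s) < 2:
            raise ProfileValidationError("a profile needs at least 2 samples")
        if not np.all(np.diff(s) > 0):
            raise ProfileValidationError("arc positions s must be strictly increasing")
        if not np.all(d > 0):
            raise ProfileValidationError("all lumen diameters must be positive")

    @property
    def length(self) -> float:
        """Total arc length ``s[-1] - s[0]`` in mm."""
        return float(self.s[-1] - self.s[0])

    @property
    def n_samples(self) -> int:
        return len(self.s)

    def subprofile(self, s_start: float, s_end: float) -> "CenterlineProfile":
        """Profile restricted to ``[s_start, s_end]`` (endpoints interpolated)."""
        if not (self.s[0] <= s_start < s_end <= self.s[-1]):
            raise DomainError("subprofile bounds outside the sampled range")
        inside = (self.s > s_start) & (self.s < s_end)
        s = np.concatenate(([s_start], self.s[inside], [s_end]))
        d = np.interp(s, self.s, self.d)
        return replace(self, s=s, d=d)


@dataclass(frozen=True)
class StenosisSegment:
    """One detected lesion on a centerline profile.

    ``A0``/``A1`` are the reference and minimal circular cross-sectional
    areas (mm^2) entering the expansion-loss term; ``L`` is the lesion
    length (mm) and ``pct_ds`` the percent diameter stenosis.
    """

    s_start: float
    s_end: float
    s_mld: float
    mld: float
    d_ref: float
    A0: float = field(init=False)
    A1: float = field(init=False)
    L: float = field(init=False)
    pct_ds: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.mld <= self.d_ref):
            raise DomainError(
                f"need 0 < mld <= d_ref, got mld={self.mld}, d_ref={self.d_ref}"
            )
        if not (self.s_start <= self.s_mld <= self.s_end) or self.s_start >= self.s_end:
            raise DomainError("lesion bounds must satisfy s_start <= s_mld <= s_end")
        object.__setattr__(self, "A0", np.pi * self.d_ref**2 / 4.0)
        object.__setattr__(self, "A1", np.pi * self.mld**2 / 4.0)
        object.__setattr__(self, "L", self.s_end - self.s_start)
        object.__setattr__(
            self, "pct_ds", percent_diameter_stenosis(self.mld, self.d_ref)
        )


def percent_diameter_stenosis(mld: float, d_ref: float) -> float:
    """Percent diameter stenosis, ``100 * (1 - mld / d_ref)``."""
    if not (0 < mld <= d_ref):
        raise DomainError(f"need 0 < mld <= d_ref, got mld={mld}, d_ref={d_ref}")
    return 100.0 * (1.0 - mld / d_ref)


def resample_profile(profile: CenterlineProfile, step: float) -> CenterlineProfile:
    """Uniformly resample a profile at ``step`` mm with linear interpolation.

    The returned grid spans ``[s[0], s[-1]]``; both endpoints are preserved
    (the final interval may be shorter than ``step`` when the total length
    is not an exact multiple).
    """
    if step <= 0 or step > profile.length:
        raise DomainError(f"step must be in (0, total length], got {step}")
    s0, s1 = float(profile.s[0]), float(profile.s[-1])
    n = int(np.floor((s1 - s0) / step + 1e-12))
    s = s0 + step * np.arange(n + 1)
    if s[-1] < s1 - 1e-9 * max(1.0, abs(s1)):
        s = np.append(s, s1)
    else:
        s[-1] = s1
    d = np.interp(s, profile.s, profile.d)
    return replace(profile, s=s, d=d)


def reference_diameter(
    profile: CenterlineProfile,
    exclusion_frac: float = 0.10,
    max_iter: int = 10,
) -> np.ndarray:
    """Healthy-taper reference diameter by iteratively reweighted line fit.

    Fits ``d = a*s + b`` to all samples, excludes samples more than
    ``exclusion_frac`` below the fitted line (putative diseased samples),
    refits on the survivors and repeats until the exclusion set is stable
    or ``max_iter`` is reached.  Returns the fitted line evaluated at every
    sample; the fit may sit above or below individual diameters.
    """
    if not (0 <= exclusion_frac < 1):
        raise DomainError("exclusion_frac must be in [0, 1)")
    s, d = profile.s, profile.d
    keep = np.ones(len(s), dtype=bool)
    coef = None
    for _ in range(max_iter):
        if keep.sum() < 2:
            raise DegenerateFitError(
                "fewer than 2 samples survive exclusion; cannot fit reference"
            )
        coef = np.polyfit(s[keep], d[keep], 1)
        fit = np.polyval(coef, s)
        new_keep = d >= (1.0 - exclusion_frac) * fit
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    if keep.sum() < 2:
        raise DegenerateFitError("fewer than 2 samples survive exclusion")
    return np.polyval(coef, s)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def detect_stenoses(
    profile: CenterlineProfile,
    d_ref: np.ndarray,
    entry_frac: float = 0.10,
    exit_frac: float = 0.05,
    merge_gap: float = 2.0,
    reference_mode: str = "interpolated",
) -> list[StenosisSegment]:
    """Detect discrete stenoses against an interpolated reference diameter.

    A lesion core is a maximal run of samples with
    ``d < (1 - entry_frac) * d_ref``.  Cores whose arc-length gap is below
    ``merge_gap`` mm are merged into one tandem-component lesion.  Each
    lesion's bounds are then extended outward to the first sample where
    ``d >= (1 - exit_frac) * d_ref`` (or the profile end).  Lesions are
    returned ordered proximal to distal; the list is empty when no sample
    breaches the entry criterion.

    ``reference_mode`` selects the lesion's reference diameter: the robust
    line fit evaluated at the MLD location (``"interpolated"``, default,
    robust to catheter-adjacent artifacts) or the mean measured diameter of
    the segment proximal to the lesion (``"proximal_mean"``).
    """
    if reference_mode not in ("interpolated", "proximal_mean"):
        raise DomainError("reference_mode must be 'interpolated' or 'proximal_mean'")
    d_ref = np.asarray(d_ref, dtype=float)
    if d_ref.shape != profile.d.shape:
        raise ProfileValidationError("d_ref must have the profile's shape")
    if not (0 < entry_frac < 1) or not (0 <= exit_frac <= entry_frac):
        raise DomainError("need 0 < entry_frac < 1 and 0 <= exit_frac <= entry_frac")
    s, d = profile.s, profile.d
    cores = _runs(d < (1.0 - entry_frac) * d_ref)
    if not cores:
        return []
    # merge cores separated by less than merge_gap (tandem components)
    merged: list[list[int]] = []
    for i0, i1 in cores:
        if merged and s[i0] - s[merged[-1][1]] < merge_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    exit_ok = d >= (1.0 - exit_frac) * d_ref
    bounds: list[list[int]] = []
    for i0, i1 in merged:
        j0 = 0
        for j in range(i0 - 1, -1, -1):
            if exit_ok[j]:
                j0 = j
                break
        j1 = len(s) - 1
        for j in range(i1 + 1, len(s)):
            if exit_ok[j]:
                j1 = j
                break
        if bounds and j0 <= bounds[-1][1]:
            bounds[-1][1] = j1  # extension overlapped the previous lesion
        else:
            bounds.append([j0, j1])
    segments = []
    for j0, j1 in bounds:
        k = j0 + int(np.argmin(d[j0 : j1 + 1]))
        if reference_mode == "proximal_mean" and j0 > 0:
            ref_val = float(np.mean(d[:j0]))
        else:
            ref_val = float(d_ref[k])
        segments.append(
            StenosisSegment(
                s_start=float(s[j0]),
                s_end=float(s[j1]),
                s_mld=float(s[k]),
                mld=float(d[k]),
                d_ref=float(max(ref_val, d[k])),
            )
        )
    return segments


def axisymmetric_volume(profile: CenterlineProfile) -> float:
    """Vessel volume in mm^3, ``V = \\int pi d(s)^2 / 4 ds`` (trapezoidal)."""
    return float(np.trapezoid(np.pi * profile.d**2 / 4.0, profile.s))


# ---------------------------------------------------------------------------
# profile file round-trip: two-column delimited text, header "s_mm,d_mm"


def read_profile(
    path: str | Path | io.TextIOBase,
    case_id: str | None = None,
    pixel_spacing: float | None = None,
) -> CenterlineProfile:
    """Read a profile file (header ``s_mm,d_mm``) with row-numbered diagnostics."""
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "r")
        close = True
        if case_id is None:
            case_id = Path(path).stem
    else:
        fh = path
    try:
        header = fh.readline().strip()
        cols = [c.strip().lower() for c in header.split(",")]
        if cols[:2] != ["s_mm", "d_mm"]:
            raise ProfileValidationError(
                f"row 1: expected header 's_mm,d_mm', got {header!r}"
            )
        s_vals, d_vals = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ProfileValidationError(f"row {lineno}: expected 2 columns")
            try:
                s_v, d_v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ProfileValidationError(f"row {lineno}: non-numeric value") from exc
            if d_v <= 0:
                raise ProfileValidationError(f"row {lineno}: diameter must be > 0")
            if s_vals and s_v <= s_vals[-1]:
                raise ProfileValidationError(
                    f"row {lineno}: arc position not strictly increasing"
                )
            s_vals.append(s_v)
            d_vals.append(d_v)
    finally:
        if close:
            fh.close()
    if len(s_vals) < 2:
        raise ProfileValidationError("profile file has fewer than 2 samples")
    return CenterlineProfile(
        s=np.array(s_vals), d=np.array(d_vals),
        case_id=case_id or "", pixel_spacing=pixel_spacing,
    )


def write_profile(profile: CenterlineProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("s_mm,d_mm\n")
        for s_v, d_v in zip(profile.s, profile.d):
            fh.write(f"{s_v:.6f},{d_v:.6f}\n")
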