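"""Post-deflection mechanics: cantilever spring model and tissue geometry.

Engineered cardiac tissues are suspended between two flexible PDMS posts
that act as integrated force sensors: tissue contraction bends the posts,
and the tip deflection, tracked over time, is converted to force through a
linear spring constant.  The spring constant may be supplied directly
(calibrated) or computed from post geometry with the Euler-Bernoulli
cantilever formula ``k = 3 E I / L^3`` with ``I = pi r^4 / 4``.

Sign convention: positive deflection points toward the tissue midline,
i.e. contraction produces positive force.  Deflections are referenced to
the post position at the time of tissue fabrication, so the resting
(inter-twitch) force is a diastolic-tone proxy rather than zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PostGeometry",
    "PostSpec",
    "DeflectionTrace",
    "ForceTrace",
    "TissueGeometry",
    "spring_constant",
    "deflection_to_force",
    "force_to_deflection",
    "developed_stress",
]


class ParameterError(ValueError):
    """Invalid physical parameter (non-positive stiffness, size, ...)."""


class DataError(ValueError):
    """Invalid data (non-finite samples, non-uniform time grid, ...)."""


@dataclass(frozen=True)
class PostGeometry:
    """Cantilever post geometry.

    Parameters
    ----------
    elastic_modulus_mpa : float
        Young's modulus of the post material in MPa (PDMS is ~1-3 MPa).
    length_mm : float
        Post length from base to tissue attachment, mm.
    radius_mm : float
        Post radius, mm (circular cross-section).
    """

    elastic_modulus_mpa: float
    length_mm: float
    radius_mm: float

    def __post_init__(self) -> None:
        for name in ("elastic_modulus_mpa", "length_mm", "radius_mm"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")


def spring_constant(geometry: PostGeometry) -> float:
    """Cantilever tip stiffness ``k = 3 E I / L^3`` in uN/um.

    ``I = pi r^4 / 4`` for a circular section.  With E in MPa (= N/mm^2)
    and lengths in mm the raw result is in N/mm; multiplied by 1000 to
    express it in uN/um (1 N/mm = 1000 uN/um... note 1 N = 1e6 uN and
    1 mm = 1e3 um, so 1 N/mm = 1e3 uN/um).
    """
    second_moment = math.pi * geometry.radius_mm**4 / 4.0  # mm^4
    k_n_per_mm = 3.0 * geometry.elastic_modulus_mpa * second_moment / geometry.length_mm**3
    return k_n_per_mm * 1e3


@dataclass(frozen=True)
class PostSpec:
    """Post stiffness, either direct or derived from geometry.

    ``lever_correction`` is an optional multiplicative factor applied to
    the spring constant to account for the tissue attaching below the
    tracked tip; default 1 (no correction).
    """

    spring_constant_un_per_um: Optional[float] = None
    geometry: Optional[PostGeometry] = None
    lever_correction: float = 1.0

    def __post_init__(self) -> None:
        if self.spring_constant_un_per_um is None and self.geometry is None:
            raise ParameterError("provide spring_constant_un_per_um or geometry")
        if self.spring_constant_un_per_um is not None and self.spring_constant_un_per_um <= 0:
            raise ParameterError("spring constant must be positive")
        if self.lever_correction <= 0:
            raise ParameterError("lever_correction must be positive")

    @property
    def k(self) -> float:
        """Effective spring constant in uN/um."""
        base = (
            self.spring_constant_un_per_um
            if self.spring_constant_un_per_um is not None
            else spring_constant(self.geometry)
        )
        return base * self.lever_correction


def _check_uniform(time_s: np.ndarray) -> float:
    """Validate a uniform time grid; return the sampling rate in Hz."""
    if time_s.ndim != 1 or time_s.size < 2:
        raise DataError("time grid needs at least two samples")
    dt = np.diff(time_s)
    if not np.all(np.isfinite(dt)) or dt[0] <= 0:
        raise DataError("time grid must be finite and increasing")
    if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
        raise DataError("time grid is not uniform")
    return 1.0 / dt[0]


@dataclass
class DeflectionTrace:
    """Post tip deflection versus time.

    ``deflection_um`` is signed, positive toward the tissue midline, and
    referenced to the post position at tissue fabrication.
    """

    time_s: np.ndarray
    deflection_um: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.deflection_um = np.asarray(self.deflection_um, dtype=float)
        if self.time_s.shape != self.deflection_um.shape:
            raise DataError("time and deflection must have equal length")
        self.sampling_rate = _check_uniform(self.time_s)
        bad = np.flatnonzero(~np.isfinite(self.deflection_um))
        if bad.size:
            raise DataError(f"non-finite deflection at sample index {bad[0]}")


@dataclass
class ForceTrace:
    """Force versus time on a uniform grid, with provenance of the spring
    constant used (``metadata['k_un_per_um']`` when converted)."""

    time_s: np.ndarray
    force_un: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_un = np.asarray(self.force_un, dtype=float)
        if self.time_s.shape != self.force_un.shape:
            raise DataError("time and force must have equal length")
        self.sampling_rate = _check_uniform(self.time_s)
        bad = np.flatnonzero(~np.isfinite(self.force_un))
        if bad.size:
            raise DataError(f"non-finite force at sample index {bad[0]}")

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def deflection_to_force(trace: DeflectionTrace, post: PostSpec) -> ForceTrace:
    """Convert deflection to force elementwise: ``F_i = k * delta_i``."""
    k = post.k
    meta = dict(trace.metadata)
    meta["k_un_per_um"] = k
    return ForceTrace(time_s=trace.time_s.copy(), force_un=k * trace.deflection_um, metadata=meta)


def force_to_deflection(trace: ForceTrace, post: PostSpec) -> DeflectionTrace:
    """Inverse of :func:`deflection_to_force` (exact up to rounding)."""
    k = post.k
    meta = {key: val for key, val in trace.metadata.items() if key != "k_un_per_um"}
    return DeflectionTrace(time_s=trace.time_s.copy(), deflection_um=trace.force_un / k, metadata=meta)


@dataclass(frozen=True)
class TissueGeometry:
    """Tissue diameter and derived circular cross-sectional area.

    A single diameter measurement implies an axisymmetric cross-section,
    so ``CSA = pi d^2 / 4``.
    """

    diameter_mm: float

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ParameterError("diameter must be positive")

    @property
    def cross_sectional_area_mm2(self) -> float:
        return math.pi * self.diameter_mm**2 / 4.0


def developed_stress(developed_force_un: float, geometry: TissueGeometry) -> float:
    """Developed stress in uN/mm^2: developed force over cross-sectional area."""
    csa = geometry.cross_sectional_area_mm2
    if csa <= 0:
        raise ParameterError("cross-sectional area must be positive")
    return developed_force_un / csa
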