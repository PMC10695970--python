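"""Geometric optics of blazed oblique plane microscopy.

Oblique plane microscopes (OPM) excite and collect through a single primary
objective, which produces a tilted intermediate image plane.  Re-imaging that
plane with a tertiary objective loses every emission direction that falls
outside the tertiary acceptance cone; the loss becomes total once the
numerical aperture drops to half the refractive index.  A blazed fiber-optic
faceplate, cut at an angle matched to the incoming cone, removes this
constraint by transferring the intensity distribution regardless of tilt.

This module implements the two quantitative pieces of that argument:

* :func:`blaze_coupling_angle` — the faceplate cut angle that couples a cone
  arriving at the intermediate-plane angle ``theta`` into fibers of index
  ``n_core``.
* :func:`remote_refocus_efficiency` — the solid-angle fraction of a uniform
  emission cone captured by a tilted acceptance cone (conventional remote
  refocusing, no faceplate).

Angles are degrees at the API boundary and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "OpticalConfig",
    "blaze_coupling_angle",
    "remote_refocus_efficiency",
    "check_pitch_nyquist",
    "efficiency_vs_na_table",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of a (blazed) OPM configuration.

    Parameters
    ----------
    phi : float
        Oblique light-sheet angle in the sample, degrees.
    theta : float
        Tilt of the intermediate image plane, degrees.
    n1, n2, n_core : float
        Refractive indices at the sample, the intermediate image space and
        the faceplate fiber core.
    na1, na2, na3 : float
        Numerical apertures of the primary, secondary and tertiary
        objectives.
    magnification : float
        Magnification from sample to faceplate surface.
    fiber_pitch : float
        Faceplate fiber pitch in μm.
    """

    phi: float = 33.0
    theta: float = 27.0
    n1: float = 1.33
    n2: float = 1.0
    n_core: float = 1.81
    na1: float = 0.8
    na2: float = 0.45
    na3: float = 0.45
    magnification: float = 1.6
    fiber_pitch: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 < self.theta <= 90.0:
            raise ValueError(f"theta must lie in (0, 90] deg, got {self.theta}")
        if not self.n_core > self.n2 > 0.0:
            raise ValueError("indices must satisfy n_core > n2 > 0")
        for na, n, label in [
            (self.na1, self.n1, "na1/n1"),
            (self.na2, self.n2, "na2/n2"),
        ]:
            if not 0.0 < na <= n:
                raise ValueError(f"{label}: need 0 < NA <= n, got {na}/{n}")


def blaze_coupling_angle(theta: float, n2: float, n_core: float) -> float:
    """Faceplate cut angle α (deg) for optimal coupling.

    The mean incidence direction of the cone arriving at the tilted
    intermediate plane makes an angle ``90° − theta`` with the plane normal;
    refraction into the fiber core gives ``α = arcsin(cos(θ)·n2/n_core)``.

    Raises
    ------
    ValueError
        If ``cos(theta)·n2/n_core`` falls outside ``[0, 1]`` (no real
        refraction angle).
    """
    arg = np.cos(np.deg2rad(theta)) * n2 / n_core
    if not 0.0 <= arg <= 1.0:
        raise ValueError(
            f"cos(theta)*n2/n_core = {arg:.4g} outside [0, 1]; no valid coupling angle"
        )
    return float(np.rad2deg(np.arcsin(arg)))


def _cap_overlap_fraction(beta_e: float, beta_a: float, gamma: float) -> float:
    """Fraction of the spherical cap of half-angle ``beta_e`` (about +z)
    covered by a cap of half-angle ``beta_a`` whose axis is tilted by
    ``gamma``.  All angles in radians."""
    if beta_e <= 0.0:
        return 1.0 if gamma <= beta_a else 0.0
    # nested / disjoint cases are exact
    if gamma + beta_e <= beta_a:
        return 1.0
    if gamma >= beta_e + beta_a:
        return 0.0

    cos_a, cos_g, sin_g = np.cos(beta_a), np.cos(gamma), np.sin(gamma)

    def azimuth_fraction(psi: float) -> float:
        # directions at polar angle psi from the emission axis: fraction of
        # the azimuth circle lying inside the tilted acceptance cone
        sin_p, cos_p = np.sin(psi), np.cos(psi)
        if sin_p * sin_g < 1e-15:
            return 1.0 if cos_p * cos_g >= cos_a else 0.0
        c = (cos_a - cos_p * cos_g) / (sin_p * sin_g)
        if c <= -1.0:
            return 1.0
        if c >= 1.0:
            return 0.0
        return np.arccos(c) / np.pi

    num, _ = quad(lambda p: azimuth_fraction(p) * np.sin(p), 0.0, beta_e, limit=200)
    den = 1.0 - np.cos(beta_e)
    return float(min(max(num * 2.0 * np.pi / (2.0 * np.pi * den), 0.0), 1.0))


def remote_refocus_efficiency(
    na2: float, n2: float, na3: float, n3: float, tilt: float
) -> float:
    """Geometric light efficiency of conventional remote refocusing.

    The emission leaving the secondary objective fills a cone of half-angle
    ``arcsin(na2/n2)``; the tertiary objective accepts a cone of half-angle
    ``arcsin(na3/n3)`` whose axis is tilted by ``tilt`` degrees.  The
    efficiency is the solid-angle fraction of the emission cone falling
    inside the acceptance cone, assuming uniform intensity over directions
    (no apodization).

    Returns a fraction in ``[0, 1]``.
    """
    for na, n, label in [(na2, n2, "na2/n2"), (na3, n3, "na3/n3")]:
        if not 0.0 < na <= n:
            raise ValueError(f"{label}: need 0 < NA <= n, got {na}/{n}")
    if not 0.0 <= tilt <= 90.0:
        raise ValueError(f"tilt must lie in [0, 90] deg, got {tilt}")
    beta_e = float(np.arcsin(na2 / n2))
    beta_a = float(np.arcsin(na3 / n3))
    return _cap_overlap_fraction(beta_e, beta_a, float(np.deg2rad(tilt)))


def check_pitch_nyquist(pitch: float, magnification: float, feature: float) -> bool:
    """True iff the faceplate fiber pitch samples a feature of size
    ``feature`` μm (at the sample) at the Nyquist limit: ``p ≤ M·r/2``."""
    if pitch <= 0 or magnification <= 0 or feature <= 0:
        raise ValueError("pitch, magnification and feature must be positive")
    return pitch <= magnification * feature / 2.0


def efficiency_vs_na_table(
    n: float = 1.0, n_points: int = 25, na_min: float = 0.05
) -> list[dict[str, float]]:
    """Efficiency of conventional remote refocusing vs objective NA.

    Matched secondary/tertiary cones (``na2 = na3 = NA``) in a medium of
    index ``n``; the tilt is the complement of the cone half-angle, which is
    the worst-case tilt of the intermediate plane for an oblique plane at
    grazing incidence.  The efficiency falls to zero as ``NA/n → 0.5``.
    """
    rows = []
    for na in np.linspace(na_min, n * 0.999, n_points):
        half = np.rad2deg(np.arcsin(na / n))
        tilt = 90.0 - half
        eff = remote_refocus_efficiency(na, n, na, n, min(tilt, 90.0))
        rows.append({"na": float(na), "na_over_n": float(na / n), "efficiency": eff})
    return rows
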