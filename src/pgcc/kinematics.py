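"""Compton-scattering kinematics for two- and three-interaction camera events.

A gamma ray that Compton scatters in the first stage of a Compton camera and
is absorbed (or scatters again) in the second stage constrains its emission
point to the surface of a *cone of origin*: apex at the first interaction,
axis through the first two interactions, and half-angle given by the Compton
scattering formula evaluated with the incident energy and the first energy
deposit.

Units: energies in MeV, positions in cm, angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ELECTRON_REST_ENERGY_MEV",
    "PAIR_PRODUCTION_THRESHOLD_MEV",
    "KinematicallyForbiddenError",
    "DegenerateGeometryError",
    "ConeOfOrigin",
    "compton_scatter_angle",
    "compton_cosine",
    "scattered_energy",
    "ds_initial_energy",
    "geometric_angle",
    "ts_initial_energy",
    "cone_from_event",
]

#: Electron rest energy m_e c^2 [MeV].
ELECTRON_REST_ENERGY_MEV: float = 0.511

#: Threshold for e+/e- pair production, 2 m_e c^2 [MeV].
PAIR_PRODUCTION_THRESHOLD_MEV: float = 1.022


class KinematicallyForbiddenError(ValueError):
    """The requested energy split admits no real Compton scattering angle.

    Raised when |cos(theta)| > 1; callers are expected to drop such events
    from reconstruction rather than clamp the angle.
    """


class DegenerateGeometryError(ValueError):
    """Interaction positions coincide (or are collinear where forbidden)."""


def compton_cosine(e_incident: float, e_deposited: float) -> float:
    """Cosine of the Compton scattering angle for a given energy split.

    ``cos(theta) = 1 - m_e c^2 * (1/E' - 1/E)`` with ``E' = E - e_deposited``
    the scattered-photon energy.  May lie outside [-1, 1] for unphysical
    splits; see :func:`compton_scatter_angle` for the validated version.
    """
    e_incident = float(e_incident)
    e_deposited = float(e_deposited)
    if not (0.0 < e_deposited < e_incident):
        raise ValueError(
            f"require 0 < e_deposited < e_incident, got {e_deposited!r}, {e_incident!r}"
        )
    e_scattered = e_incident - e_deposited
    return 1.0 - ELECTRON_REST_ENERGY_MEV * (1.0 / e_scattered - 1.0 / e_incident)


def compton_scatter_angle(e_incident: float, e_deposited: float) -> float:
    """Compton scattering angle [rad] for incident energy and first deposit.

    Parameters
    ----------
    e_incident : float
        Incident photon energy [MeV].
    e_deposited : float
        Energy transferred to the electron in the scatter [MeV]; must satisfy
        ``0 < e_deposited < e_incident``.

    Raises
    ------
    KinematicallyForbiddenError
        If the implied cosine falls outside [-1, 1].  Such events cannot come
        from a single Compton scatter at this incident energy and must be
        discarded by the caller.
    """
    c = compton_cosine(e_incident, e_deposited)
    if c < -1.0 or c > 1.0:
        raise KinematicallyForbiddenError(
            f"cos(theta) = {c:.6g} outside [-1, 1] for "
            f"E={e_incident:.6g} MeV, deposit={e_deposited:.6g} MeV"
        )
    return float(np.arccos(c))


def scattered_energy(e_incident: float, theta: float) -> float:
    """Scattered-photon energy after a Compton scatter through ``theta``."""
    k = e_incident / ELECTRON_REST_ENERGY_MEV
    return e_incident / (1.0 + k * (1.0 - np.cos(theta)))


def ds_initial_energy(e1: float, e2: float) -> float:
    """Initial-energy estimate for a double-scatter event: the deposit sum."""
    if e1 <= 0 or e2 <= 0:
        raise ValueError(f"deposits must be positive, got {e1!r}, {e2!r}")
    return float(e1) + float(e2)


def geometric_angle(p1, p2, p3) -> float:
    """Angle [rad] between track legs (p1 -> p2) and (p2 -> p3).

    This is the direction *change* of the photon at the second interaction,
    i.e. the geometric scattering angle there.  Not symmetric under swapping
    p1 and p3 in general.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    u = p2 - p1
    v = p3 - p2
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("coincident interaction positions")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(c))


def ts_initial_energy(event=None, *, energies=None, positions=None) -> float:
    """Incident energy of a triple-scatter event by gamma-ray tracking.

    Uses the three-interaction redundancy: the scattering angle at the second
    interaction is known geometrically, so the photon energy entering the
    second interaction follows from Compton kinematics alone,

        E_2 = e2/2 + sqrt((e2/2)^2 + e2 * m_e c^2 / (1 - cos(theta2))),

    and the incident energy is ``E_0 = e1 + E_2``.  No assumption about full
    absorption at the third interaction is needed.

    Accepts either an event-like object with ``energies`` (length >= 3) and
    ``positions`` ((3, 3) array, rows = interactions), or the two keyword
    arrays directly.  The first three interactions in the *assumed* order are
    used.

    Raises
    ------
    DegenerateGeometryError
        If theta2 = 0 (collinear track: the formula diverges) or positions
        coincide.
    """
    if event is not None:
        energies = np.asarray(event.energies, dtype=float)
        positions = np.asarray(event.positions, dtype=float)
    else:
        energies = np.asarray(energies, dtype=float)
        positions = np.asarray(positions, dtype=float)
    if energies.shape[0] < 3 or positions.shape[0] < 3:
        raise ValueError("triple-scatter estimate requires 3 interactions")
    e1, e2 = float(energies[0]), float(energies[1])
    theta2 = geometric_angle(positions[0], positions[1], positions[2])
    one_minus_cos = 1.0 - np.cos(theta2)
    if one_minus_cos <= 1e-12:
        raise DegenerateGeometryError("theta2 = 0: tracking formula diverges")
    half = e2 / 2.0
    e_in2 = half + np.sqrt(half**2 + e2 * ELECTRON_REST_ENERGY_MEV / one_minus_cos)
    return float(e1 + e_in2)


@dataclass(frozen=True)
class ConeOfOrigin:
    """Locus of possible emission points of a recorded photon.

    Attributes
    ----------
    apex : ndarray, shape (3,)
        First interaction position [cm].
    axis : ndarray, shape (3,)
        Unit vector from the second interaction toward the first, pointing
        out of the camera into the imaging space.
    half_angle : float
        Compton scattering angle [rad], in (0, pi).
    event_energy : float
        Initial-energy estimate used to open the cone [MeV].
    """

    apex: np.ndarray
    axis: np.ndarray
    half_angle: float
    event_energy: float

    def __post_init__(self):
        apex = np.asarray(self.apex, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        if not (np.isfinite(apex).all() and np.isfinite(axis).all()):
            raise ValueError("non-finite cone geometry")
        n = np.linalg.norm(axis)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"axis must be unit length, |axis| = {n}")
        if not (0.0 < self.half_angle < np.pi):
            raise ValueError(f"half_angle must lie in (0, pi), got {self.half_angle}")
        object.__setattr__(self, "apex", apex)
        object.__setattr__(self, "axis", axis)


def cone_from_event(event, energy_estimate: float) -> ConeOfOrigin:
    """Cone of origin from the first two interactions of an event.

    The apex sits at the first interaction, the axis points from the second
    interaction toward the first (into the imaging space), and the opening
    half-angle is the Compton angle for ``energy_estimate`` with the first
    deposit transferred to the electron.

    Raises
    ------
    KinematicallyForbiddenError
        If the first deposit is incompatible with a single Compton scatter at
        ``energy_estimate`` — the event should be dropped from reconstruction.
    """
    energies = np.asarray(event.energies, dtype=float)
    positions = np.asarray(event.positions, dtype=float)
    if energies.shape[0] < 2:
        raise ValueError("cone requires at least two interactions")
    e1 = float(energies[0])
    if e1 >= energy_estimate:
        raise KinematicallyForbiddenError(
            f"first deposit {e1:.6g} MeV >= energy estimate {energy_estimate:.6g} MeV"
        )
    p1, p2 = positions[0], positions[1]
    d = p1 - p2
    n = np.linalg.norm(d)
    if n == 0.0:
        raise DegenerateGeometryError("first two interactions coincide")
    theta = compton_scatter_angle(energy_estimate, e1)
    if theta <= 0.0:
        raise KinematicallyForbiddenError("zero scattering angle gives an empty cone")
    return ConeOfOrigin(apex=p1, axis=d / n, half_angle=theta, event_energy=float(energy_estimate))
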