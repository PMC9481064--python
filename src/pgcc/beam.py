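"""Pencil-beam prompt-gamma emission model.

Coordinates: the proton beam travels along +z with z = 0 at the target
entrance; y is vertical (camera below the beam); x is lateral.  Prompt
gammas are emitted from a line source along the beam axis whose depth
profile mimics proton dose: a slowly rising plateau followed by a sharp
sigmoid distal falloff at the beam range.  Emission energies come from the
discrete line spectrum of the target activation: 718 keV, 2.0 MeV and
4.44 MeV carbon de-excitation lines, the 2.22 MeV hydrogen neutron-capture
line, and a 511 keV annihilation component.

The per-proton yield of detectable prompt gammas and the relative line
intensities are model assumptions (documented in the methods note), not
measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MU_TO_PROTONS", "BeamModel", "sample_emission"]

#: Monitor-unit calibration of the delivery system at 150 MeV [protons/MU].
MU_TO_PROTONS: float = 3.668e6

#: Default relative line intensities (energy MeV, weight); assumption.
DEFAULT_EMISSION_LINES: tuple[tuple[float, float], ...] = (
    (0.511, 0.10),
    (0.718, 0.15),
    (2.000, 0.20),
    (2.220, 0.25),
    (4.440, 0.30),
)


@dataclass
class BeamModel:
    """A 150 MeV-class proton pencil beam irradiating a plastic target."""

    nominal_range: float = 15.6          # cm, depth of the distal falloff
    range_shift: float = 0.0             # cm, imposed shift (e.g. -0.3, -0.5)
    lateral_sigma: float = 0.4           # cm, pencil-beam lateral spread
    dose_rate_kMU_per_min: float = 20.0  # clinical dose rate
    mu_to_protons: float = MU_TO_PROTONS
    # Detectable prompt gammas emitted per proton.  Not a measured quantity:
    # chosen once so that the false-event fractions the readout produces at
    # the two clinical dose rates match measured reference detection rates
    # for this camera class (~20% of doubles false at 20 kMU/min, ~50% at
    # 180 kMU/min); see the methods note.
    pg_yield_per_proton: float = 0.07
    emission_lines: tuple[tuple[float, float], ...] = DEFAULT_EMISSION_LINES
    plateau_floor: float = 0.45          # entrance emission density relative to peak
    bragg_amplitude: float = 0.55        # height of the pre-range emission peak
    bragg_width: float = 0.7             # cm, width of the emission peak
    bragg_offset: float = 0.4            # cm, peak position upstream of the range
    falloff_width: float = 0.10          # cm, sigmoid scale of the distal falloff

    def __post_init__(self):
        if self.dose_rate_kMU_per_min <= 0 or self.lateral_sigma <= 0:
            raise ValueError("physical beam parameters must be positive")
        if not all(w > 0 for _, w in self.emission_lines):
            raise ValueError("emission line intensities must be positive")

    @property
    def range(self) -> float:
        """Effective beam range [cm] including any imposed shift."""
        return self.nominal_range + self.range_shift

    @property
    def protons_per_second(self) -> float:
        return self.dose_rate_kMU_per_min * 1e3 * self.mu_to_protons / 60.0

    @property
    def emission_rate(self) -> float:
        """Detectable prompt gammas emitted per second."""
        return self.protons_per_second * self.pg_yield_per_proton

    def depth_pdf(self, z: np.ndarray) -> np.ndarray:
        """Unnormalized emission density vs depth [cm].

        Dose-like shape: an entrance plateau, a pronounced emission peak
        just upstream of the range (the Bragg-peak correlate), and a sharp
        sigmoid distal falloff at the range.
        """
        z = np.asarray(z, dtype=float)
        r = self.range
        peak = self.bragg_amplitude * np.exp(
            -0.5 * ((z - (r - self.bragg_offset)) / self.bragg_width) ** 2
        )
        falloff = 1.0 / (1.0 + np.exp((z - r) / self.falloff_width))
        return np.where(z < 0, 0.0, (self.plateau_floor + peak) * falloff)


def sample_emission(beam: BeamModel, n: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ``n`` prompt-gamma emissions from the beam.

    Returns
    -------
    origins : (n, 3) float array [cm]
        Emission points: depth sampled from the beam's emission profile,
        laterally blurred by ``lateral_sigma`` in x and y.
    energies : (n,) float array [MeV]
        Drawn from the discrete line spectrum.
    times : (n,) float array [microseconds]
        Uniform over the wall-clock span implied by the emission rate,
        i.e. the order statistics of a Poisson stream with ``n`` arrivals.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(rng)
    # inverse-CDF sampling of the depth profile on a fine grid
    zg = np.linspace(0.0, beam.range + 12.0 * beam.falloff_width, 4096)
    pdf = beam.depth_pdf(zg)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    z = np.interp(rng.random(n), cdf, zg)
    xy = rng.normal(0.0, beam.lateral_sigma, size=(n, 2))
    origins = np.column_stack([xy[:, 0], xy[:, 1], z])

    lines = np.array([e for e, _ in beam.emission_lines])
    weights = np.array([w for _, w in beam.emission_lines], dtype=float)
    energies = lines[rng.choice(lines.size, size=n, p=weights / weights.sum())]

    span_us = n / beam.emission_rate * 1e6
    times = np.sort(rng.random(n)) * span_us
    return origins, energies, times
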