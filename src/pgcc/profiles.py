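"""Depth/crossfield profiles and range-verification statistics.

The depth profile is the integral of the three pixel rows nearest the beam
axis (x = 0) in the central coronal (XZ) plane, as a function of depth z.
From it come the range metrics: the depth of the profile maximum (PGmax)
and the distal depths where the profile first falls to 80% (PG80) and 60%
(PG60) of the maximum, linearly interpolated between voxel centers.  Image
quality is quantified by the contrast-to-noise ratio

    CNR = |S_peak - S_distal| / sigma_distal,

with S_peak the mean profile value within +-2 cm of PGmax and
S_distal/sigma_distal the mean and standard deviation over the 21-25 cm
depth region beyond the proton range.  Replicate-to-replicate uncertainty
is summarized by five-number summaries (Tukey inclusive-median quartiles)
and the inter-quartile range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recon import PGImage

__all__ = [
    "DepthProfile",
    "RangeMetrics",
    "NoCrossingError",
    "depth_profile",
    "crossfield_profile",
    "pg_falloff",
    "cnr",
    "range_metrics",
    "five_number_summary",
    "shift_summary",
]


class NoCrossingError(ValueError):
    """The profile never falls below the requested fraction distal to its max."""


@dataclass
class DepthProfile:
    """1D profile on a regular coordinate axis [cm]."""

    coords: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        assert self.coords.shape == self.values.shape
        d = np.diff(self.coords)
        assert (d > 0).all(), "profile coordinates must be strictly increasing"

    def normalized(self) -> "DepthProfile":
        m = self.values.max()
        return DepthProfile(self.coords, self.values / m if m > 0 else self.values)


@dataclass
class RangeMetrics:
    pgmax_depth: float
    pg80_depth: float | None
    pg60_depth: float | None
    cnr: float | None


def depth_profile(image: PGImage, n_rows: int = 3) -> DepthProfile:
    """Sum of the ``n_rows`` x-slices nearest the beam axis vs depth z.

    Evaluated in the central XZ plane (the y pixel row nearest y = 0).
    """
    g = image.grid
    if g.nx < n_rows:
        raise ValueError(f"grid has {g.nx} x-slices, need {n_rows}")
    xi = g.central_rows("x", n_rows)
    yi = g.central_rows("y", 1)[0]
    values = image.data[xi, yi, :].sum(axis=0)
    return DepthProfile(g.axis_centers("z"), values)


def crossfield_profile(image: PGImage, depth: float = 10.0, n_cols: int = 3) -> DepthProfile:
    """Lateral (x) profile: sum of ``n_cols`` depth columns about ``depth``.

    Evaluated in the central XZ plane, mirroring the depth profile but
    integrating over the z pixels nearest the requested depth.
    """
    g = image.grid
    if g.nz < n_cols:
        raise ValueError(f"grid has {g.nz} z-pixels, need {n_cols}")
    zc = g.axis_centers("z")
    zi = np.sort(np.argsort(np.abs(zc - depth), kind="stable")[:n_cols])
    yi = g.central_rows("y", 1)[0]
    values = image.data[:, yi, zi].sum(axis=1)
    return DepthProfile(g.axis_centers("x"), values)


def pg_falloff(profile: DepthProfile, frac: float) -> float:
    """Distal depth [cm] where the profile first falls below ``frac`` of max.

    Linear interpolation between the voxel centers bracketing the crossing;
    scale-invariant.  Raises :class:`NoCrossingError` when the profile never
    drops below the threshold beyond its maximum (the typical failure mode
    of high-background images).
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    v = profile.values
    z = profile.coords
    imax = int(v.argmax())
    vmax = v[imax]
    if vmax <= 0:
        raise NoCrossingError("profile has no positive maximum")
    thresh = frac * vmax
    below = np.where(v[imax:] < thresh)[0]
    if below.size == 0:
        raise NoCrossingError(f"profile never falls below {frac:.0%} of max distally")
    j = imax + below[0]
    # interpolate between (j-1, j); j > imax because v[imax] >= thresh
    z0, z1 = z[j - 1], z[j]
    v0, v1 = v[j - 1], v[j]
    return float(z0 + (z1 - z0) * (v0 - thresh) / (v0 - v1))


def cnr(
    profile: DepthProfile,
    peak_halfwidth: float = 2.0,
    distal_lo: float = 21.0,
    distal_hi: float = 25.0,
) -> float:
    """Contrast-to-noise ratio of a depth profile.

    Signal is the mean within ``peak_halfwidth`` of the profile maximum;
    noise statistics come from the distal window (default 21-25 cm), which
    the profile must cover.  Invariant under adding a constant offset.
    """
    z = profile.coords
    v = profile.values
    if z[0] > distal_lo or z[-1] < distal_hi:
        raise ValueError("profile does not cover the distal noise window")
    zmax = z[int(v.argmax())]
    peak = v[(z >= zmax - peak_halfwidth) & (z <= zmax + peak_halfwidth)]
    distal = v[(z >= distal_lo) & (z <= distal_hi)]
    sigma = distal.std(ddof=1)
    if sigma == 0:
        raise ValueError("zero variance in the distal noise region")
    return float(abs(peak.mean() - distal.mean()) / sigma)


def range_metrics(profile: DepthProfile, with_cnr: bool = True) -> RangeMetrics:
    """PGmax/PG80/PG60 depths and (optionally) the CNR of one profile.

    PG80/PG60 are None when no distal crossing exists.
    """
    z = profile.coords
    pgmax = float(z[int(profile.values.argmax())])
    out = {}
    for frac, key in ((0.8, "pg80"), (0.6, "pg60")):
        try:
            out[key] = pg_falloff(profile, frac)
        except NoCrossingError:
            out[key] = None
    c = None
    if with_cnr:
        try:
            c = cnr(profile)
        except ValueError:
            c = None
    return RangeMetrics(pgmax_depth=pgmax, pg80_depth=out["pg80"],
                        pg60_depth=out["pg60"], cnr=c)


def five_number_summary(values) -> dict:
    """Min, Q1, median, Q3, max and IQR with Tukey (inclusive-median) quartiles."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError("need at least two values")
    n = v.size
    med = float(np.median(v))
    half = (n + 1) // 2  # inclusive of the median point for odd n
    q1 = float(np.median(v[:half]))
    q3 = float(np.median(v[n - half:]))
    return {"min": float(v[0]), "q1": q1, "median": med, "q3": q3,
            "max": float(v[-1]), "iqr": q3 - q1}


def shift_summary(metric_values: dict, reference: str) -> dict:
    """Five-number summaries per condition, plus shifts vs a reference.

    ``metric_values`` maps condition name -> sequence of replicate metric
    values (e.g. PG60 depths from five independent reconstructions).
    Shifts are each condition's median minus the reference condition's
    median.
    """
    if reference not in metric_values:
        raise KeyError(f"reference condition {reference!r} missing")
    summaries = {k: five_number_summary(v) for k, v in metric_values.items()}
    ref_med = summaries[reference]["median"]
    for k, s in summaries.items():
        s["median_shift"] = s["median"] - ref_med
    return summaries
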