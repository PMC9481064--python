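"""Two-stage pixelated CZT camera geometry.

The camera sits below the beam axis: beam along +z at (x, y) = (0, 0), with
the top face of the first detection stage 30 cm below the axis.  Each stage
holds 8 modules in a 2 (x) x 4 (z) layout; each module holds a 2 x 2 array
of CZT crystals.  Stage-1 crystals are 2.0 x 1.0 x 2.0 cm (x, y, z), stage-2
crystals 2.0 x 1.5 x 2.0 cm.  Crystals within a module are separated by
0.25 cm, modules by 1.0 cm, and the two stages by a 2.5 cm gap.

Crystal anodes are on the lower (-y) face; readout order within a trigger
window follows proximity to the anode plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CameraGeometry"]


@dataclass
class CameraGeometry:
    n_stages: int = 2
    modules_per_stage: int = 8
    crystals_per_module: int = 4
    stage1_crystal_size: tuple[float, float, float] = (2.0, 1.0, 2.0)
    stage2_crystal_size: tuple[float, float, float] = (2.0, 1.5, 2.0)
    intra_module_gap: float = 0.25    # cm, between crystals in a module
    inter_module_gap: float = 1.0     # cm, between modules
    stage_separation: float = 2.5     # cm, between stage-1 bottom and stage-2 top
    beam_to_detector_top: float = 30.0  # cm, beam axis to stage-1 top face
    z_center: float = 15.6            # cm, camera center depth (under the isocenter)
    # derived, filled in __post_init__
    crystal_lo: np.ndarray = field(init=False, repr=False)
    crystal_hi: np.ndarray = field(init=False, repr=False)
    crystal_module: np.ndarray = field(init=False, repr=False)
    crystal_index: np.ndarray = field(init=False, repr=False)
    anode_y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        lo, hi, mod, cry = [], [], [], []
        # modules laid out 2 (x) x 4 (z), same footprint for both stages
        module_pitch_x = self._module_width() + self.inter_module_gap
        module_pitch_z = self._module_width() + self.inter_module_gap
        mx = (np.arange(2) - 0.5) * module_pitch_x
        mz = (np.arange(4) - 1.5) * module_pitch_z + self.z_center
        for stage in range(self.n_stages):
            size = np.array(
                self.stage1_crystal_size if stage == 0 else self.stage2_crystal_size
            )
            y_top = -self.beam_to_detector_top if stage == 0 else (
                -self.beam_to_detector_top
                - self.stage1_crystal_size[1]
                - self.stage_separation
            )
            y_lo, y_hi = y_top - size[1], y_top
            m = 0
            for iz in range(4):
                for ix in range(2):
                    # 2x2 crystals inside the module
                    off = (size[0] + self.intra_module_gap) / 2.0
                    c = 0
                    for cz in (-off, off):
                        for cx in (-off, off):
                            cen = np.array([mx[ix] + cx, 0.0, mz[iz] + cz])
                            lo.append([cen[0] - size[0] / 2, y_lo, cen[2] - size[2] / 2])
                            hi.append([cen[0] + size[0] / 2, y_hi, cen[2] + size[2] / 2])
                            mod.append(stage * self.modules_per_stage + m)
                            cry.append(c)
                            c += 1
                    m += 1
        self.crystal_lo = np.array(lo)
        self.crystal_hi = np.array(hi)
        self.crystal_module = np.array(mod, dtype=np.int16)
        self.crystal_index = np.array(cry, dtype=np.int8)
        self.anode_y = self.crystal_lo[:, 1].copy()  # anode on the -y face
        self._validate()

    def _module_width(self) -> float:
        # both stages share the 2.0 cm crystal footprint in x and z
        return 2 * 2.0 + self.intra_module_gap

    def _validate(self):
        n = self.n_crystals
        lo, hi = self.crystal_lo, self.crystal_hi
        assert (hi > lo).all(), "degenerate crystal boxes"
        # pairwise non-overlap
        for i in range(n):
            sep = (hi[i] <= lo + 1e-12) | (lo[i] >= hi - 1e-12)
            sep[i] = True
            assert sep.any(axis=1).all(), "crystals overlap"
        # (module, crystal) map is bijective
        keys = set(zip(self.crystal_module.tolist(), self.crystal_index.tolist()))
        assert len(keys) == n, "module/crystal index map not bijective"

    @property
    def n_crystals(self) -> int:
        return self.crystal_lo.shape[0]

    @property
    def n_modules(self) -> int:
        return self.n_stages * self.modules_per_stage

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned box enclosing all crystals."""
        return self.crystal_lo.min(axis=0), self.crystal_hi.max(axis=0)

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Crystal index containing each point, or -1 if in no crystal."""
        pts = np.atleast_2d(points)
        inside = (
            (pts[:, None, :] >= self.crystal_lo[None, :, :] - 1e-9)
            & (pts[:, None, :] <= self.crystal_hi[None, :, :] + 1e-9)
        ).all(axis=2)
        out = np.where(inside.any(axis=1), inside.argmax(axis=1), -1)
        return out if points.ndim == 2 else out[0]

    def anode_distance(self, crystal: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance [cm] from interaction height y to the crystal anode plane."""
        return np.asarray(y) - self.anode_y[np.asarray(crystal)]
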