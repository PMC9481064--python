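"""Cone backprojection against a brute-force oracle, plus selection rules."""

import numpy as np
import pytest

from pgcc.events import EventLabels, ListModeDataset
from pgcc.kinematics import ConeOfOrigin, compton_scatter_angle, scattered_energy
from pgcc.recon import (
    EnergyWindow,
    ImageGrid,
    backproject,
    cone_sigmas,
    event_cones,
    reconstruct,
    select_by_energy,
)


def _random_cones(n, rng):
    cones = []
    for _ in range(n):
        apex = rng.uniform(-3, 3, 3)
        axis = rng.normal(0, 1, 3)
        axis /= np.linalg.norm(axis)
        cones.append(ConeOfOrigin(apex=apex, axis=axis,
                                  half_angle=rng.uniform(0.2, 2.5),
                                  event_energy=2.0))
    return cones


def _brute_force(cones, grid, sigmas, exponent):
    """Per-voxel, per-event angular deviation computed with plain loops."""
    out = np.zeros(grid.shape)
    xs, ys, zs = (grid.axis_centers(a) for a in "xyz")
    for c, s in zip(cones, sigmas):
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                for k, z in enumerate(zs):
                    v = np.array([x, y, z]) - c.apex
                    r = np.linalg.norm(v)
                    if r == 0:
                        continue
                    ang = np.arccos(np.clip(v @ c.axis / r, -1, 1))
                    delta = (ang - c.half_angle) / s
                    out[i, j, k] += s ** (-exponent) / np.sqrt(2 * np.pi) * np.exp(
                        -0.5 * delta**2)
    return out


@pytest.fixture()
def small_grid():
    return ImageGrid(nx=8, ny=8, nz=8, dx=1.0, dy=1.0, dz=1.0,
                     x0=-4.0, y0=-4.0, z0=-4.0)


class TestBackprojection:
    def test_matches_brute_force_oracle(self, small_grid, rng):
        cones = _random_cones(10, rng)
        sigmas = rng.uniform(0.02, 0.3, 10)
        for exponent in (1.0, 3.0):
            img = backproject(cones, small_grid, sigmas, weight_exponent=exponent)
            oracle = _brute_force(cones, small_grid, sigmas, exponent)
            assert np.allclose(img, oracle, rtol=1e-10, atol=1e-12)

    def test_scalar_sigma_matches_uniform_array(self, small_grid, rng):
        cones = _random_cones(5, rng)
        a = backproject(cones, small_grid, 0.1)
        b = backproject(cones, small_grid, np.full(5, 0.1))
        assert np.allclose(a, b)

    def test_empty_event_list_gives_zero_image(self, small_grid):
        assert (backproject([], small_grid, 0.1) == 0).all()

    def test_linearity_under_duplication(self, small_grid, rng):
        cones = _random_cones(4, rng)
        one = backproject(cones, small_grid, 0.1)
        two = backproject(cones + cones, small_grid, 0.1)
        assert np.allclose(two, 2 * one)

    def test_event_order_invariance(self, small_grid, rng):
        cones = _random_cones(6, rng)
        a = backproject(cones, small_grid, 0.15)
        b = backproject(cones[::-1], small_grid, 0.15)
        assert np.allclose(a, b)

    def test_chunking_does_not_change_result(self, small_grid, rng):
        cones = _random_cones(7, rng)
        sig = rng.uniform(0.05, 0.2, 7)
        a = backproject(cones, small_grid, sig)
        b = backproject(cones, small_grid, sig, chunk_voxels=13, chunk_events=2)
        assert np.allclose(a, b)

    def test_invalid_sigma_rejected(self, small_grid, rng):
        with pytest.raises(ValueError):
            backproject(_random_cones(2, rng), small_grid, -0.1)
        with pytest.raises(ValueError):
            backproject(_random_cones(2, rng), small_grid, np.array([0.1, 0.1, 0.1]))


def _ds_dataset(rows):
    """rows: (e1, e2, p1, p2) double-scatter events."""
    n = len(rows)
    energies = np.zeros((n, 3))
    positions = np.zeros((n, 3, 3))
    for i, (e1, e2, p1, p2) in enumerate(rows):
        energies[i, :2] = (e1, e2)
        positions[i, 0], positions[i, 1] = p1, p2
    return ListModeDataset(
        np.full(n, 2, dtype=np.int8), energies, positions,
        np.zeros(n, np.int16), np.full((n, 3), 0, np.int8), np.zeros(n),
    )


class TestSelection:
    def test_window_membership_examples(self):
        data = _ds_dataset([
            (2.00, 2.44, [0, -30, 0], [0, -31, 0]),   # sum 4.44
            (1.00, 0.50, [0, -30, 0], [0, -31, 0]),   # sum 1.50
        ])
        kept44 = select_by_energy(data, EnergyWindow(4.0, 4.5))
        assert len(kept44) == 1 and kept44.energies[0, 0] == 2.00
        kept20 = select_by_energy(data, EnergyWindow(2.0, 4.5))
        assert len(kept20) == 1 and kept20.energies[0, 0] == 2.00

    def test_nested_windows_monotone(self, clean_dataset):
        wide = select_by_energy(clean_dataset, EnergyWindow(0.6, 4.5))
        mid = select_by_energy(clean_dataset, EnergyWindow(2.0, 4.5))
        narrow = select_by_energy(clean_dataset, EnergyWindow(4.0, 4.5))
        assert len(narrow) <= len(mid) <= len(wide)

    def test_forbidden_cones_dropped_and_counted(self):
        # second event: first deposit beyond the Compton edge for its sum
        data = _ds_dataset([
            (1.0, 1.22, [0, -30, 0], [0, -31, 0.5]),
            (2.1, 0.12, [0, -30, 0], [0, -31, 0.5]),
        ])
        cones, sigmas, dropped = event_cones(data)
        assert len(cones) == 1
        assert dropped == 1
        assert sigmas.shape == (1,)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            EnergyWindow(3.0, 2.0)


class TestReconstruct:
    def test_single_noiseless_event_peaks_at_emission_point(self):
        # build a kinematically exact double whose cone passes through the
        # emission point; the containing voxel must rank in the top intensity
        emission = np.array([0.0, 0.0, 0.5])
        p1 = np.array([0.2, -5.0, 0.3])
        d_in = p1 - emission
        d_in /= np.linalg.norm(d_in)
        e0, theta = 2.22, 0.5
        e1 = e0 - scattered_energy(e0, theta)
        perp = np.cross(d_in, [1.0, 0, 0])
        perp /= np.linalg.norm(perp)
        d_out = np.cos(theta) * d_in + np.sin(theta) * perp
        p2 = p1 + 1.2 * d_out
        data = _ds_dataset([(e1, e0 - e1, p1, p2)])
        grid = ImageGrid(nx=20, ny=20, nz=20, dx=0.25, dy=0.25, dz=0.25,
                         x0=-2.5, y0=-2.5, z0=-2.0)
        img = reconstruct(data, grid, EnergyWindow(0.6, 4.5), kernel_sigma=0.05)
        idx = tuple(int(np.argmin(np.abs(grid.axis_centers(a) - emission[i])))
                    for i, a in enumerate("xyz"))
        # the emission voxel sits on the cone band: its intensity is within
        # voxel-discretization of the band maximum, far above the off-band
        # background that fills most of the grid
        assert img.data[idx] >= 0.5 * img.data.max()
        assert np.median(img.data) < 0.05 * img.data.max()

    def test_cone_sigma_shrinks_with_lever_arm(self):
        near = _ds_dataset([(1.0, 1.0, [0, -30, 0], [0, -30.3, 0])])
        far = _ds_dataset([(1.0, 1.0, [0, -30, 0], [0, -32.5, 0.5])])
        assert cone_sigmas(near)[0] > cone_sigmas(far)[0]

    def test_grid_geometry(self):
        g = ImageGrid()
        assert g.shape == (60, 256, 256)
        assert g.extents == pytest.approx((18.0, 51.2, 51.2))
        slab = g.profile_slab()
        assert slab.shape == (3, 1, 256)
        # slab x rows are the three nearest the beam axis
        assert np.abs(slab.axis_centers("x")).max() <= 0.5
        assert np.allclose(slab.axis_centers("z"), g.axis_centers("z"))
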