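"""Trigger readout: grouping, pileup labeling, cuts and mis-ordering."""

import numpy as np
import pytest

from pgcc.beam import BeamModel
from pgcc.events import EventCategory
from pgcc.readout import ReadoutModel, readout
from pgcc.simulate import SimulationConfig, simulate
from pgcc.transport import InteractionBatch


def _batch(geometry, entries):
    """Build an InteractionBatch from (photon, crystal, dy_above_anode, energy, chrono)."""
    photon, crystal, pos, energy, chrono = [], [], [], [], []
    for ph, cr, dy, e, ch in entries:
        lo, hi = geometry.crystal_lo[cr], geometry.crystal_hi[cr]
        p = (lo + hi) / 2.0
        p[1] = lo[1] + dy
        photon.append(ph)
        crystal.append(cr)
        pos.append(p)
        energy.append(e)
        chrono.append(ch)
    return InteractionBatch(
        photon=np.array(photon), crystal=np.array(crystal),
        module=geometry.crystal_module[np.array(crystal)],
        position=np.array(pos), energy=np.array(energy),
        chrono=np.array(chrono, dtype=np.int8),
    )


def _quiet_readout():
    # no measurement blur so crafted deposits survive the cuts exactly
    return ReadoutModel(energy_resolution_frac_662=1e-9, position_sigma=1e-9)


class TestGrouping:
    def test_double_to_triple_labeling(self, geometry):
        # a true double plus an unrelated single in the same module and window
        c0 = 0
        siblings = np.where(geometry.crystal_module == geometry.crystal_module[c0])[0]
        batch = _batch(geometry, [
            (0, c0, 0.9, 1.0, 0),          # photon 0, far from anode, first
            (0, siblings[1], 0.1, 0.8, 1),  # photon 0, near anode, second
            (1, siblings[2], 0.5, 0.3, 0),  # unrelated single scatter
        ])
        times = np.array([10.0, 10.0])      # photons 0 and 1 share the window
        data = readout(batch, times, _quiet_readout(), geometry,
                       np.random.default_rng(0))
        assert len(data) == 1
        lab = data.labels
        assert lab.category[0] == EventCategory.D_TO_T
        # recorded order is anode proximity: slots are (near, mid, far)
        # -> embedded pair is recorded slots {0, 2}, chronologically (2, 0)
        assert set(lab.ds_pair[0]) == {0, 2}
        assert tuple(lab.order[0, :2]) == (2, 0)

    def test_anode_proximity_misorders_true_double(self, geometry):
        c0 = 0
        sib = np.where(geometry.crystal_module == geometry.crystal_module[c0])[0][1]
        batch = _batch(geometry, [
            (0, c0, 0.9, 1.0, 0),   # chronologically first, far from anode
            (0, sib, 0.1, 0.8, 1),  # second, near anode -> read out first
        ])
        data = readout(batch, np.array([5.0]), _quiet_readout(), geometry,
                       np.random.default_rng(0))
        assert len(data) == 1
        assert data.labels.category[0] == EventCategory.TRUE_DS
        assert tuple(data.labels.order[0, :2]) == (1, 0)   # mis-ordered
        assert data.energies[0, 0] == pytest.approx(0.8, abs=1e-3)

    def test_threshold_and_max_energy_cuts(self, geometry):
        c0 = 0
        sib = np.where(geometry.crystal_module == geometry.crystal_module[c0])[0][1]
        # sub-threshold partner reduces the pair to a dropped single
        b1 = _batch(geometry, [(0, c0, 0.5, 1.0, 0), (0, sib, 0.2, 0.02, 1)])
        d1 = readout(b1, np.array([5.0]), _quiet_readout(), geometry,
                     np.random.default_rng(0))
        assert len(d1) == 0
        assert d1.provenance["readout_counters"]["singles_dropped"] == 1
        # a 2.8 MeV single interaction vetoes the whole event
        b2 = _batch(geometry, [(0, c0, 0.5, 2.8, 0), (0, sib, 0.2, 1.0, 1)])
        d2 = readout(b2, np.array([5.0]), _quiet_readout(), geometry,
                     np.random.default_rng(0))
        assert len(d2) == 0
        assert d2.provenance["readout_counters"]["over_max_energy_dropped"] == 1

    def test_separate_windows_do_not_pile_up(self, geometry):
        c0 = 0
        sib = np.where(geometry.crystal_module == geometry.crystal_module[c0])[0][1]
        batch = _batch(geometry, [
            (0, c0, 0.5, 1.0, 0), (0, sib, 0.2, 0.8, 1),   # true double at t=5
            (1, c0, 0.5, 0.5, 0),                          # single at t=50
        ])
        data = readout(batch, np.array([5.0, 50.0]), _quiet_readout(), geometry,
                       np.random.default_rng(0))
        assert len(data) == 1
        assert data.labels.category[0] == EventCategory.TRUE_DS


class TestPileupTrends:
    def test_no_pileup_at_vanishing_rate(self, clean_dataset):
        cat = clean_dataset.labels.category
        frac_bad = np.isin(cat, [EventCategory.FALSE_DS, EventCategory.FALSE_TS,
                                 EventCategory.D_TO_T]).mean()
        assert frac_bad < 0.05

    def test_false_fraction_monotone_in_dose_rate(self):
        fracs = []
        for rate in (2.0, 40.0, 180.0):
            cfg = SimulationConfig(beam=BeamModel(dose_rate_kMU_per_min=rate),
                                   n_emissions=2_000_000, seed=42)
            d = simulate(cfg)
            cat = d.labels.category
            fracs.append(np.isin(cat, [EventCategory.FALSE_DS,
                                       EventCategory.FALSE_TS,
                                       EventCategory.D_TO_T]).mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_usable_fraction_falls_with_dose_rate(self, clean_dataset, pileup_dataset):
        def usable(d):
            cat = d.labels.category
            return np.isin(cat, [EventCategory.TRUE_DS, EventCategory.TRUE_TS,
                                 EventCategory.D_TO_T]).mean()
        assert usable(pileup_dataset) < usable(clean_dataset)

    def test_recorded_positions_inside_crystals(self, pileup_dataset, geometry):
        for i in range(0, len(pileup_dataset), 97):
            ev = pileup_dataset[i]
            located = geometry.locate(ev.positions)
            assert (located >= 0).all()

    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(beam=BeamModel(dose_rate_kMU_per_min=180.0),
                               n_emissions=1_000_000, seed=77)
        a, b = simulate(cfg), simulate(cfg)
        assert len(a) == len(b)
        assert np.array_equal(a.energies, b.energies)
        assert np.array_equal(a.labels.category, b.labels.category)
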