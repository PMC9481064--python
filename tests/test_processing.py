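"""Label-driven event cleanup and detection-rate bookkeeping."""

import numpy as np
import pytest

from pgcc.events import EventCategory, EventLabels, ListModeDataset
from pgcc.processing import ProcessingSummary, process, summarize_rates


def _dataset(rows):
    """rows: list of (n_int, energies(3,), category, order, pair)."""
    n = len(rows)
    if n == 0:
        labels = EventLabels(np.empty(0, np.int8), np.empty((0, 3), np.int8),
                             np.empty((0, 2), np.int8))
        return ListModeDataset(
            np.empty(0, np.int8), np.empty((0, 3)), np.empty((0, 3, 3)),
            np.empty(0, np.int16), np.empty((0, 3), np.int8), np.empty(0),
            labels=labels,
        )
    n_int = np.array([r[0] for r in rows], dtype=np.int8)
    energies = np.array([r[1] for r in rows], dtype=float)
    positions = np.zeros((n, 3, 3))
    rng = np.random.default_rng(0)
    for i, r in enumerate(rows):
        positions[i, :r[0]] = rng.normal(0, 1, (r[0], 3))
    cat = np.array([r[2] for r in rows], dtype=np.int8)
    order = np.full((n, 3), -1, dtype=np.int8)
    pair = np.full((n, 2), -1, dtype=np.int8)
    for i, r in enumerate(rows):
        order[i, : len(r[3])] = r[3]
        if r[4] is not None:
            pair[i] = r[4]
    labels = EventLabels(cat, order, pair)
    return ListModeDataset(
        n_int, energies, positions, np.zeros(n, dtype=np.int16),
        np.where(np.arange(3)[None, :] < n_int[:, None], 0, -1).astype(np.int8),
        np.arange(n, dtype=float), labels=labels,
    )


@pytest.fixture()
def mixed():
    return _dataset([
        (2, [1.0, 0.5, 0.0], EventCategory.TRUE_DS, (0, 1), None),   # CO double
        (2, [0.7, 0.9, 0.0], EventCategory.TRUE_DS, (1, 0), None),   # MO double
        (3, [0.2, 0.3, 0.4], EventCategory.FALSE_TS, (), None),      # false triple
        (3, [1.1, 0.6, 0.2], EventCategory.D_TO_T, (2, 0), (0, 2)),  # recoverable
    ])


def test_four_step_procedure(mixed):
    out = process(mixed, mixed.labels)
    # false removed; CO + re-ordered MO + recovered double = 3 events
    assert len(out) == 3
    assert (out.labels.category != EventCategory.FALSE_TS).all()
    assert (out.labels.category != EventCategory.FALSE_DS).all()
    # MO double re-ordered: recorded (0.7, 0.9) with order (1,0) -> (0.9, 0.7)
    assert np.allclose(out.energies[1, :2], [0.9, 0.7])
    # D-to-T reduced to its embedded double in chronological order (slots 2, 0)
    assert out.n_interactions[2] == 2
    assert np.allclose(out.energies[2, :2], [0.2, 1.1])
    assert out.energies[2, 2] == 0.0


def test_all_false_input_empties(mixed):
    labels = EventLabels(
        np.full(4, EventCategory.FALSE_DS, dtype=np.int8),
        np.full((4, 3), -1, dtype=np.int8),
        np.full((4, 2), -1, dtype=np.int8),
    )
    assert len(process(mixed, labels)) == 0


def test_mo_reorder_is_exact_permutation(mixed):
    out = process(mixed, mixed.labels)
    assert np.allclose(sorted(out.energies[1, :2]), sorted(mixed.energies[1, :2]))
    assert (out.labels.order[1, :2] == [0, 1]).all()   # now chronological


def test_label_mismatch_rejected(mixed):
    with pytest.raises(ValueError):
        process(mixed, mixed.labels.subset([0, 1]))


def test_conservation_with_truth_labels(pileup_dataset):
    out = process(pileup_dataset, pileup_dataset.labels)
    cat = pileup_dataset.labels.category
    n_true = np.isin(cat, [EventCategory.TRUE_DS, EventCategory.TRUE_TS,
                           EventCategory.D_TO_T]).sum()
    n_false = np.isin(cat, [EventCategory.FALSE_DS, EventCategory.FALSE_TS]).sum()
    assert len(out) == n_true
    assert len(pileup_dataset) - len(out) == n_false


class TestRates:
    def test_summarize_counts(self, mixed):
        s = summarize_rates(mixed, mixed.labels, protons_delivered=1e6)
        assert s.counts["ds_total"] == 2
        assert s.counts["ts_total"] == 2
        assert s.counts["ds_true_co"] == 1
        assert s.counts["ds_true_mo"] == 1
        assert s.counts["d_to_t"] == 1
        assert s.counts["ts_false"] == 1
        assert s.usable_rate == pytest.approx(3 / 1e6)
        assert s.raw_total_rate == pytest.approx(4 / 1e6)

    def test_zero_events(self):
        empty = _dataset([])
        s = summarize_rates(empty, empty.labels, protons_delivered=10.0)
        assert s.raw_total_rate == 0.0
        assert s.usable_rate == 0.0

    def test_zero_protons_rejected(self, mixed):
        with pytest.raises(ValueError):
            summarize_rates(mixed, mixed.labels, protons_delivered=0.0)

    def test_reference_rate_table_arithmetic(self):
        # detection-rate bookkeeping on the reference per-proton rates
        low = ProcessingSummary.from_rates({
            "ds_total": 90.04e-6, "ts_total": 20.31e-6,
            "ds_true_co": 35.39e-6, "ds_true_mo": 35.62e-6, "ds_false": 19.03e-6,
            "ts_true_co": 2.35e-6, "ts_true_mo": 11.71e-6,
            "d_to_t": 5.8e-6, "ts_false": 0.45e-6,
        })
        high = ProcessingSummary.from_rates({
            "ds_total": 17.76e-6, "ts_total": 7.92e-6,
            "ds_true_co": 4.01e-6, "ds_true_mo": 4.03e-6, "ds_false": 9.72e-6,
            "ts_true_co": 0.33e-6, "ts_true_mo": 1.74e-6,
            "d_to_t": 4.58e-6, "ts_false": 1.27e-6,
        })
        assert low.raw_total_rate == pytest.approx(1.1035e-4, rel=1e-3)
        assert high.raw_total_rate == pytest.approx(2.568e-5, rel=1e-3)
        assert low.raw_total_rate / high.raw_total_rate == pytest.approx(4.3, abs=0.05)
        assert low.usable_rate == pytest.approx(9.087e-5, rel=1e-3)
        assert high.usable_rate == pytest.approx(1.469e-5, rel=1e-3)
        # at the highest dose rate only ~17% of raw events are correctly ordered
        assert high.co_fraction_of_raw == pytest.approx(0.169, abs=0.001)
        # while usable events after processing exceed 55% of the raw data
        assert high.usable_fraction_of_raw > 0.55
        # at the lowest rate ~42% of usable events are correctly ordered
        assert low.co_fraction_of_usable == pytest.approx(0.415, abs=0.002)
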