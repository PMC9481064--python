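"""Turning raw list-mode data into the processed dataset used for imaging.

The classifier's label for each event drives a four-step procedure:

1. decide whether the event is a true double, false double, true triple,
   false triple, or a double-in-triple;
2. true events keep all interactions, re-ordered into the predicted
   chronological order;
3. double-in-triple events are reduced to the embedded double — the
   predicted pair in its predicted order, the unrelated third interaction
   removed;
4. false events are removed outright.

:func:`summarize_rates` computes the per-proton detection-rate bookkeeping
(raw and usable rates, correctly-ordered and usable fractions) from any
combination of labels — simulation ground truth or classifier predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventCategory, EventLabels, ListModeDataset

__all__ = ["process", "ProcessingSummary", "summarize_rates"]


def process(events: ListModeDataset, labels: EventLabels) -> ListModeDataset:
    """Apply the label-driven cleanup; returns the processed dataset.

    Events come out in their input order (stably); interactions inside each
    surviving event are permuted into the label's chronological order.
    Events whose predicted order later turns out kinematically inconsistent
    are still emitted — the reconstructor drops them at cone construction.
    """
    if len(events) != len(labels):
        raise ValueError("labels must align 1:1 with events")
    cat = labels.category
    keep = (cat != EventCategory.FALSE_DS) & (cat != EventCategory.FALSE_TS)
    idx = np.where(keep)[0]

    out = events.subset(idx)
    lab = labels.subset(idx)
    n = len(out)
    n_int = out.n_interactions.copy()
    energies = out.energies.copy()
    positions = out.positions.copy()
    crystals = out.crystals.copy()

    for j in range(n):
        c = lab.category[j]
        if c == EventCategory.D_TO_T:
            first, second = lab.order[j, :2]
            sel = np.array([first, second])
            n_int[j] = 2
        elif c == EventCategory.TRUE_TS:
            sel = lab.order[j, :3].astype(int)
        else:  # TRUE_DS
            sel = lab.order[j, :2].astype(int)
        k = sel.size
        energies[j, :k] = out.energies[j, sel]
        positions[j, :k] = out.positions[j, sel]
        crystals[j, :k] = out.crystals[j, sel]
        if k == 2:
            energies[j, 2] = 0.0
            positions[j, 2] = 0.0
            crystals[j, 2] = -1

    prov = dict(events.provenance)
    prov["processed"] = True
    # processed events are chronologically ordered by construction
    identity = np.tile(np.array([0, 1, 2], dtype=np.int8), (n, 1))
    identity[n_int == 2, 2] = -1
    out_labels = EventLabels(
        category=np.where(
            lab.category == EventCategory.D_TO_T, EventCategory.TRUE_DS, lab.category
        ).astype(np.int8),
        order=identity,
        ds_pair=np.full((n, 2), -1, dtype=np.int8),
    )
    return ListModeDataset(
        n_int, energies, positions, out.module, crystals, out.timestamp,
        labels=out_labels, provenance=prov,
    )


@dataclass
class ProcessingSummary:
    """Detection-rate bookkeeping for one measurement (rates per proton)."""

    protons_delivered: float
    counts: dict = field(default_factory=dict)

    @property
    def rates(self) -> dict:
        return {k: v / self.protons_delivered for k, v in self.counts.items()}

    # ---- derived quantities ------------------------------------------------
    @property
    def raw_total_rate(self) -> float:
        r = self.rates
        return r["ds_total"] + r["ts_total"]

    @property
    def usable_rate(self) -> float:
        """True doubles + true triples + doubles recovered from D-to-T."""
        r = self.rates
        return r["ds_true_co"] + r["ds_true_mo"] + r["ts_true_co"] + r["ts_true_mo"] + r["d_to_t"]

    @property
    def co_fraction_of_raw(self) -> float:
        """Correctly-ordered true events as a fraction of all raw events."""
        r = self.rates
        return (r["ds_true_co"] + r["ts_true_co"]) / self.raw_total_rate

    @property
    def co_fraction_of_usable(self) -> float:
        """Correctly-ordered true events as a fraction of usable events."""
        r = self.rates
        return (r["ds_true_co"] + r["ts_true_co"]) / self.usable_rate

    @property
    def usable_fraction_of_raw(self) -> float:
        return self.usable_rate / self.raw_total_rate

    def to_dict(self) -> dict:
        return {
            "protons_delivered": self.protons_delivered,
            "counts": dict(self.counts),
            "rates": self.rates,
            "raw_total_rate": self.raw_total_rate,
            "usable_rate": self.usable_rate,
            "co_fraction_of_raw": self.co_fraction_of_raw,
            "co_fraction_of_usable": self.co_fraction_of_usable,
            "usable_fraction_of_raw": self.usable_fraction_of_raw,
        }

    @classmethod
    def from_rates(cls, rates_per_proton: dict, protons_delivered: float = 1.0
                   ) -> "ProcessingSummary":
        """Build a summary directly from per-proton category rates.

        Useful for bookkeeping arithmetic on reference rate tables, where
        only rates (not raw counts) are available.  Expected keys:
        ``ds_true_co, ds_true_mo, ds_false, ts_true_co, ts_true_mo,
        d_to_t, ts_false`` (missing keys default to 0); the ``ds_total`` /
        ``ts_total`` aggregates are derived if absent.
        """
        r = {k: rates_per_proton.get(k, 0.0) for k in (
            "ds_true_co", "ds_true_mo", "ds_false",
            "ts_true_co", "ts_true_mo", "d_to_t", "ts_false")}
        r.setdefault("ds_total", 0.0)
        r["ds_total"] = rates_per_proton.get(
            "ds_total", r["ds_true_co"] + r["ds_true_mo"] + r["ds_false"])
        r["ts_total"] = rates_per_proton.get(
            "ts_total", r["ts_true_co"] + r["ts_true_mo"] + r["d_to_t"] + r["ts_false"])
        counts = {k: v * protons_delivered for k, v in r.items()}
        return cls(protons_delivered=protons_delivered, counts=counts)


def summarize_rates(
    raw: ListModeDataset,
    labels: EventLabels,
    protons_delivered: float,
    processed: ListModeDataset | None = None,
) -> ProcessingSummary:
    """Category counts and per-proton rates for a measurement.

    ``labels`` may be simulation ground truth (simulator validation) or
    classifier predictions (pipeline mode); the summary is the same shape
    either way.  An event is correctly ordered (CO) when its label's order
    is the identity — i.e. the recorded order needs no fixing.
    """
    if protons_delivered <= 0:
        raise ValueError("protons_delivered must be positive")
    if len(labels) != len(raw):
        raise ValueError("labels must align 1:1 with events")
    cat = labels.category
    is_ds = raw.n_interactions == 2
    co2 = (labels.order[:, 0] == 0) & (labels.order[:, 1] == 1)
    co3 = co2 & (labels.order[:, 2] == 2)
    counts = {
        "ds_total": int(is_ds.sum()),
        "ts_total": int((~is_ds).sum()),
        "ds_true_co": int(((cat == EventCategory.TRUE_DS) & co2).sum()),
        "ds_true_mo": int(((cat == EventCategory.TRUE_DS) & ~co2).sum()),
        "ds_false": int((cat == EventCategory.FALSE_DS).sum()),
        "ts_true_co": int(((cat == EventCategory.TRUE_TS) & co3).sum()),
        "ts_true_mo": int(((cat == EventCategory.TRUE_TS) & ~co3).sum()),
        "d_to_t": int((cat == EventCategory.D_TO_T).sum()),
        "ts_false": int((cat == EventCategory.FALSE_TS).sum()),
    }
    if processed is not None:
        counts["processed_total"] = int(len(processed))
    return ProcessingSummary(protons_delivered=float(protons_delivered), counts=counts)
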