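"""Module-level trigger readout: grouping, pileup, blurring and labeling.

Each detector module triggers independently: the first interaction opens a
charge-collection window (1.5 us); every above-threshold interaction in the
same module inside that window is read out as one *event*, after which the
module is dead for the pixel-reset time (4 us).  Interactions are recorded
in order of proximity to the crystal anode (the -y face), not chronological
order — the origin of mis-ordered events.  When interactions from more than
one photon share a window the event is false (or double-in-triple when a
true double rides along with an unrelated single).

Recorded energies and positions carry Gaussian measurement blur; events
with a single interaction or with four or more interactions are counted and
discarded; any event with a single recorded deposit above 2.7 MeV is
excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import (
    DT_VARIANTS,
    EventCategory,
    EventLabels,
    ListModeDataset,
    TS_PERMUTATIONS,
)
from .geometry import CameraGeometry
from .transport import InteractionBatch

__all__ = ["ReadoutModel", "readout", "shuffle_for_training"]


@dataclass
class ReadoutModel:
    trigger_window: float = 1.5            # us, charge collection window
    pixel_reset: float = 4.0               # us, dead time after a readout
    energy_threshold: float = 0.050        # MeV, per-interaction trigger threshold
    single_interaction_max: float = 2.7    # MeV, exclusion limit per interaction
    energy_resolution_frac_662: float = 0.005  # FWHM/E at 662 keV
    position_sigma: float = 0.03           # cm, per-axis position blur

    def __post_init__(self):
        if self.trigger_window <= 0:
            raise ValueError("trigger window must be positive")
        if self.energy_threshold >= self.single_interaction_max:
            raise ValueError("threshold must lie below the exclusion limit")

    def energy_sigma(self, energy: np.ndarray) -> np.ndarray:
        """Stochastic resolution: FWHM scaling as sqrt(E) from the 662 keV point."""
        fwhm = self.energy_resolution_frac_662 * 0.662 * np.sqrt(
            np.asarray(energy, dtype=float) / 0.662
        )
        return fwhm / 2.3548200450309493


def readout(
    interactions: InteractionBatch,
    times: np.ndarray,
    readout_model: ReadoutModel,
    geometry: CameraGeometry,
    rng,
    provenance: dict | None = None,
) -> ListModeDataset:
    """Group a stream of interactions into labeled 2-/3-interaction events.

    Parameters
    ----------
    interactions : InteractionBatch
        True interactions with photon identity and chronological order.
    times : (n_photons,) array [us]
        Emission time of each photon; all interactions of a photon share its
        timestamp (transit times are ~ns, far below the window length).
    """
    rng = np.random.default_rng(rng)
    rm = readout_model
    n_int = len(interactions)
    counters = {
        "interactions_total": int(n_int),
        "interactions_below_threshold": 0,
        "interactions_in_reset": 0,
        "singles_dropped": 0,
        "ge4_dropped": 0,
        "over_max_energy_dropped": 0,
    }

    # measurement blur
    e_rec = interactions.energy + rng.normal(0.0, 1.0, n_int) * rm.energy_sigma(
        interactions.energy
    )
    e_rec = np.maximum(e_rec, 1e-6)
    p_rec = interactions.position + rng.normal(0.0, rm.position_sigma, (n_int, 3))
    # clip back into the host crystal so recorded positions stay physical
    lo = geometry.crystal_lo[interactions.crystal]
    hi = geometry.crystal_hi[interactions.crystal]
    p_rec = np.clip(p_rec, lo + 1e-6, hi - 1e-6)

    above = e_rec >= rm.energy_threshold
    counters["interactions_below_threshold"] = int((~above).sum())

    t_int = times[interactions.photon]
    anode_d = geometry.anode_distance(interactions.crystal, p_rec[:, 1])

    ev_n, ev_e, ev_p, ev_mod, ev_cry, ev_t = [], [], [], [], [], []
    lab_cat, lab_order, lab_pair = [], [], []

    keep = np.where(above)[0]
    order_t = keep[np.argsort(t_int[keep], kind="stable")]
    mod_of = interactions.module[order_t]

    for m in range(geometry.n_modules):
        sel = order_t[mod_of == m]
        if sel.size == 0:
            continue
        t = t_int[sel]
        i = 0
        nsel = sel.size
        while i < nsel:
            t0 = t[i]
            j = int(np.searchsorted(t, t0 + rm.trigger_window, side="left"))
            group = sel[i:j]
            # interactions arriving during the reset are lost
            k = int(np.searchsorted(t, t0 + rm.trigger_window + rm.pixel_reset, side="left"))
            counters["interactions_in_reset"] += k - j
            i = k

            size = group.size
            if size == 1:
                counters["singles_dropped"] += 1
                continue
            if size >= 4:
                counters["ge4_dropped"] += 1
                continue
            ge = e_rec[group]
            if (ge > rm.single_interaction_max).any():
                counters["over_max_energy_dropped"] += 1
                continue

            # recorded order: closest to the anode reads out first
            rec = group[np.argsort(anode_d[group], kind="stable")]
            cat, order, pair = _label_group(interactions, rec)

            e3 = np.zeros(3)
            p3 = np.zeros((3, 3))
            c3 = np.full(3, -1, dtype=np.int8)
            e3[:size] = e_rec[rec]
            p3[:size] = p_rec[rec]
            c3[:size] = geometry.crystal_index[interactions.crystal[rec]]
            ev_n.append(size)
            ev_e.append(e3)
            ev_p.append(p3)
            ev_mod.append(m)
            ev_cry.append(c3)
            ev_t.append(t0)
            lab_cat.append(cat)
            o3 = np.full(3, -1, dtype=np.int8)
            o3[: len(order)] = order
            lab_order.append(o3)
            pr = np.full(2, -1, dtype=np.int8)
            if pair is not None:
                pr[:] = pair
            lab_pair.append(pr)

    prov = dict(provenance or {})
    prov["readout_counters"] = counters
    if not ev_n:
        return ListModeDataset(
            np.empty(0, np.int8), np.empty((0, 3)), np.empty((0, 3, 3)),
            np.empty(0, np.int16), np.empty((0, 3), np.int8), np.empty(0),
            labels=EventLabels(
                np.empty(0, np.int8), np.empty((0, 3), np.int8), np.empty((0, 2), np.int8)
            ),
            provenance=prov,
        )
    return ListModeDataset(
        np.array(ev_n, np.int8),
        np.array(ev_e),
        np.array(ev_p),
        np.array(ev_mod, np.int16),
        np.array(ev_cry, np.int8),
        np.array(ev_t),
        labels=EventLabels(np.array(lab_cat, np.int8), np.array(lab_order), np.array(lab_pair)),
        provenance=prov,
    )


def _label_group(interactions: InteractionBatch, rec: np.ndarray):
    """Ground-truth label of a recorded group (indices in recorded order)."""
    photons = interactions.photon[rec]
    chrono = interactions.chrono[rec]
    size = rec.size
    if size == 2:
        if photons[0] == photons[1]:
            order = tuple(np.argsort(chrono, kind="stable"))
            return EventCategory.TRUE_DS, order, None
        return EventCategory.FALSE_DS, (), None
    # triples
    uniq, counts = np.unique(photons, return_counts=True)
    if uniq.size == 1:
        order = tuple(np.argsort(chrono, kind="stable"))
        return EventCategory.TRUE_TS, order, None
    if uniq.size == 2:
        # a true double plus one unrelated single
        pair_photon = uniq[counts == 2][0]
        slots = np.where(photons == pair_photon)[0]
        first, second = slots[np.argsort(chrono[slots], kind="stable")]
        return EventCategory.D_TO_T, (int(first), int(second)), (int(slots[0]), int(slots[1]))
    return EventCategory.FALSE_TS, (), None


def shuffle_for_training(data: ListModeDataset, rng) -> ListModeDataset:
    """Impose the training-set ordering balance on a labeled dataset.

    After shuffling, the recorded interaction orders are exactly balanced:

    * true doubles — half (+-1) correctly ordered, half swapped;
    * true triples — the six possible recorded orderings equally represented
      (+-1), so one sixth retain the correct order;
    * double-in-triple events — the six variants (which recorded pair is the
      embedded double x its order) equally represented (+-1).

    False events keep their recorded order.  Labels are rewritten so that
    ``order`` always maps recorded slots back to chronological order.
    """
    if data.labels is None:
        raise ValueError("shuffling requires ground-truth labels")
    rng = np.random.default_rng(rng)
    out = data.subset(np.arange(len(data)))
    labels = out.labels
    cat = labels.category
    n = len(out)
    # P[i] = slot permutation to apply: new slot s holds old slot P[i, s]
    P = np.tile(np.arange(3), (n, 1))

    # --- true doubles: exact half/half split over final orderings
    ds = np.where(cat == EventCategory.TRUE_DS)[0]
    if ds.size:
        tgt_mo = _balanced_choices(ds.size, 2, rng).astype(bool)  # True -> mis-ordered
        tgt_first = np.where(tgt_mo, 1, 0)  # final order label starts with this slot
        need_swap = labels.order[ds, 0] != tgt_first
        P[ds[need_swap], 0] = 1
        P[ds[need_swap], 1] = 0
        labels.order[ds, 0] = tgt_first
        labels.order[ds, 1] = 1 - tgt_first

    # --- true triples: equal sixths over the six final orderings
    ts = np.where(cat == EventCategory.TRUE_TS)[0]
    if ts.size:
        assign = _balanced_choices(ts.size, 6, rng)
        for i, a in zip(ts, assign):
            tau = np.array(TS_PERMUTATIONS[a])
            sigma = labels.order[i, :3].astype(int)
            P[i] = _perm_to_target(sigma, tau)
            labels.order[i, :3] = tau

    # --- double-in-triple: equal sixths over the six variants
    dt = np.where(cat == EventCategory.D_TO_T)[0]
    if dt.size:
        assign = _balanced_choices(dt.size, 6, rng)
        for i, a in zip(dt, assign):
            f_new, s_new = DT_VARIANTS[a]
            o_new = 3 - f_new - s_new
            f_old, s_old = labels.order[i, :2].astype(int)
            o_old = 3 - f_old - s_old
            perm = np.empty(3, dtype=int)
            perm[f_new], perm[s_new], perm[o_new] = f_old, s_old, o_old
            P[i] = perm
            labels.order[i, :2] = (f_new, s_new)
            labels.ds_pair[i] = sorted((f_new, s_new))

    rows = np.arange(n)[:, None]
    out.energies = out.energies[rows, P]
    out.positions = out.positions[rows, P, :]
    out.crystals = out.crystals[rows, P]

    prov = dict(out.provenance)
    prov["training_shuffle"] = True
    out.provenance = prov
    return out


def _balanced_choices(n: int, k: int, rng) -> np.ndarray:
    """n assignments over k options, as equal as possible, in random order."""
    base = np.tile(np.arange(k), n // k + 1)[:n]
    return base[rng.permutation(n)]


def _perm_to_target(sigma: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Slot permutation turning an event with order ``sigma`` into order ``tau``.

    With "new slot s holds old slot perm[s]" semantics, the order label
    transforms as ``new_order = argsort(perm)[old_order]``; solving for perm
    gives ``perm = argsort(tau[argsort(sigma)])``.
    """
    inv = tau[np.argsort(sigma)]
    return np.argsort(inv)
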