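"""List-mode event containers and the 16-class event-type scheme.

A recorded *event* is the group of 2 or 3 energy depositions (interactions)
read out from one detector module within one trigger window.  Events carry a
recorded interaction order (set by anode proximity in the readout, not by
physics), and — in simulation — a ground-truth label saying what the event
really is and in which order its interactions actually occurred.

Label taxonomy
--------------
* ``TRUE_DS`` / ``TRUE_TS`` — all interactions from one photon; ``order``
  is the permutation of recorded slots that restores chronological order.
* ``FALSE_DS`` / ``FALSE_TS`` — every interaction from a distinct photon
  (pure pileup); no meaningful order.
* ``D_TO_T`` — a true double-scatter plus one unrelated single scatter
  recorded together as a triple; ``ds_pair`` identifies the recorded slots
  of the true pair and ``order`` its chronological order.

The merged classification scheme has 16 classes: 3 for doubles
(correct order, swapped order, false) and 13 for triples (6 true orderings,
6 double-in-triple variants = 3 pair choices x 2 orders, and false).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "EventCategory",
    "EventLabels",
    "Event",
    "ListModeDataset",
    "N_CLASSES",
    "DS_CLASSES",
    "TS_CLASSES",
    "TS_PERMUTATIONS",
    "DT_VARIANTS",
    "label_to_class",
    "class_to_label",
    "class_mask_for_size",
]


class EventCategory(IntEnum):
    TRUE_DS = 0
    FALSE_DS = 1
    TRUE_TS = 2
    FALSE_TS = 3
    D_TO_T = 4


#: The six orderings of a recorded triple, lexicographic.
TS_PERMUTATIONS: tuple[tuple[int, int, int], ...] = tuple(itertools.permutations((0, 1, 2)))

#: Double-in-triple variants: (recorded slots of the true pair, chronological order).
DT_VARIANTS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1),
)

N_CLASSES = 16
#: Class indices reachable by a 2-interaction event.
DS_CLASSES = np.array([0, 1, 2])
#: Class indices reachable by a 3-interaction event.
TS_CLASSES = np.arange(3, 16)

_TS_PERM_RANK = {p: i for i, p in enumerate(TS_PERMUTATIONS)}
_DT_RANK = {v: i for i, v in enumerate(DT_VARIANTS)}


def label_to_class(category: int, order, ds_pair=None) -> int:
    """Map a ground-truth label to its merged-scheme class index."""
    cat = EventCategory(category)
    if cat == EventCategory.TRUE_DS:
        return 0 if tuple(order[:2]) == (0, 1) else 1
    if cat == EventCategory.FALSE_DS:
        return 2
    if cat == EventCategory.TRUE_TS:
        return 3 + _TS_PERM_RANK[tuple(order[:3])]
    if cat == EventCategory.D_TO_T:
        return 9 + _DT_RANK[tuple(order[:2])]
    return 15  # FALSE_TS


def class_to_label(class_index: int) -> tuple[EventCategory, tuple[int, ...], tuple[int, ...] | None]:
    """Inverse of :func:`label_to_class`: (category, order, ds_pair)."""
    c = int(class_index)
    if c == 0:
        return EventCategory.TRUE_DS, (0, 1), None
    if c == 1:
        return EventCategory.TRUE_DS, (1, 0), None
    if c == 2:
        return EventCategory.FALSE_DS, (), None
    if 3 <= c <= 8:
        return EventCategory.TRUE_TS, TS_PERMUTATIONS[c - 3], None
    if 9 <= c <= 14:
        order = DT_VARIANTS[c - 9]
        return EventCategory.D_TO_T, order, tuple(sorted(order))
    if c == 15:
        return EventCategory.FALSE_TS, (), None
    raise ValueError(f"class index {c} outside 0..15")


def class_mask_for_size(n_interactions: np.ndarray) -> np.ndarray:
    """Boolean (N, 16) mask of classes structurally reachable per event."""
    n = np.asarray(n_interactions)
    mask = np.zeros((n.shape[0], N_CLASSES), dtype=bool)
    mask[:, :3] = (n == 2)[:, None]
    mask[:, 3:] = (n == 3)[:, None]
    return mask


@dataclass
class EventLabels:
    """Ground-truth (or predicted) labels aligned 1:1 with a dataset.

    ``order`` rows are padded with -1 beyond the label's own length;
    ``ds_pair`` rows are (-1, -1) except for D-to-T events.
    """

    category: np.ndarray          # (N,) int8, EventCategory values
    order: np.ndarray             # (N, 3) int8, -1 padded
    ds_pair: np.ndarray           # (N, 2) int8, -1 padded

    def __post_init__(self):
        self.category = np.asarray(self.category, dtype=np.int8)
        self.order = np.asarray(self.order, dtype=np.int8)
        self.ds_pair = np.asarray(self.ds_pair, dtype=np.int8)
        n = self.category.shape[0]
        assert self.order.shape == (n, 3) and self.ds_pair.shape == (n, 2)

    def __len__(self) -> int:
        return self.category.shape[0]

    def class_indices(self) -> np.ndarray:
        """(N,) int array of merged-scheme class indices."""
        out = np.empty(len(self), dtype=np.int64)
        for i in range(len(self)):
            out[i] = label_to_class(self.category[i], self.order[i], self.ds_pair[i])
        return out

    @classmethod
    def from_class_indices(cls, class_indices, n_interactions) -> "EventLabels":
        ci = np.asarray(class_indices)
        n = ci.shape[0]
        category = np.empty(n, dtype=np.int8)
        order = np.full((n, 3), -1, dtype=np.int8)
        ds_pair = np.full((n, 2), -1, dtype=np.int8)
        for i, c in enumerate(ci):
            cat, o, pair = class_to_label(c)
            category[i] = cat
            order[i, : len(o)] = o
            if pair is not None:
                ds_pair[i] = pair
        return cls(category, order, ds_pair)

    def subset(self, index) -> "EventLabels":
        return EventLabels(self.category[index], self.order[index], self.ds_pair[index])


@dataclass(frozen=True)
class Event:
    """Per-event view: arrays trimmed to the event's interaction count."""

    energies: np.ndarray     # (n,) MeV
    positions: np.ndarray    # (n, 3) cm
    module: int
    crystals: np.ndarray     # (n,) crystal index within module
    timestamp: float         # microseconds from run start

    @property
    def n_interactions(self) -> int:
        return self.energies.shape[0]


@dataclass
class ListModeDataset:
    """Struct-of-arrays container for 2- and 3-interaction list-mode events.

    Third-interaction slots are zero-filled (energies/positions) or -1
    (crystal indices) for double-scatter events.
    """

    n_interactions: np.ndarray   # (N,) int8 in {2, 3}
    energies: np.ndarray         # (N, 3) MeV
    positions: np.ndarray        # (N, 3, 3) cm
    module: np.ndarray           # (N,) int16
    crystals: np.ndarray         # (N, 3) int8, -1 padded
    timestamp: np.ndarray        # (N,) float64 microseconds
    labels: EventLabels | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_interactions = np.asarray(self.n_interactions, dtype=np.int8)
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.module = np.asarray(self.module, dtype=np.int16)
        self.crystals = np.asarray(self.crystals, dtype=np.int8)
        self.timestamp = np.asarray(self.timestamp, dtype=np.float64)
        n = len(self)
        assert self.energies.shape == (n, 3)
        assert self.positions.shape == (n, 3, 3)
        if self.labels is not None:
            assert len(self.labels) == n, "labels must align 1:1 with events"

    def __len__(self) -> int:
        return self.n_interactions.shape[0]

    def __getitem__(self, i: int) -> Event:
        k = int(self.n_interactions[i])
        return Event(
            energies=self.energies[i, :k].copy(),
            positions=self.positions[i, :k].copy(),
            module=int(self.module[i]),
            crystals=self.crystals[i, :k].copy(),
            timestamp=float(self.timestamp[i]),
        )

    def subset(self, index) -> "ListModeDataset":
        return ListModeDataset(
            self.n_interactions[index],
            self.energies[index],
            self.positions[index],
            self.module[index],
            self.crystals[index],
            self.timestamp[index],
            labels=self.labels.subset(index) if self.labels is not None else None,
            provenance=dict(self.provenance),
        )

    def features(self) -> np.ndarray:
        """(N, 12) feature matrix: (e, x, y, z) per interaction slot.

        Double-scatter events have their third-slot columns identically
        zero, which downstream consumers use to infer event size.
        """
        X = np.concatenate(
            [self.energies[:, :, None], self.positions], axis=2
        )  # (N, 3, 4)
        return X.reshape(len(self), 12)

    @staticmethod
    def concatenate(parts: list["ListModeDataset"]) -> "ListModeDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        labels = None
        if all(p.labels is not None for p in parts):
            labels = EventLabels(
                np.concatenate([p.labels.category for p in parts]),
                np.concatenate([p.labels.order for p in parts]),
                np.concatenate([p.labels.ds_pair for p in parts]),
            )
        return ListModeDataset(
            np.concatenate([p.n_interactions for p in parts]),
            np.concatenate([p.energies for p in parts]),
            np.concatenate([p.positions for p in parts]),
            np.concatenate([p.module for p in parts]),
            np.concatenate([p.crystals for p in parts]),
            np.concatenate([p.timestamp for p in parts]),
            labels=labels,
            provenance=dict(parts[0].provenance),
        )
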