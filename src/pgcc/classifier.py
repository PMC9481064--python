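"""Event-type and interaction-order classification of camera events.

The classifier is a deep fully-connected residual network over the 12-value
feature vector ``(e1, x1, y1, z1, e2, x2, y2, z2, e3, x3, y3, z3)`` —
deposited energy [MeV] and position [cm] of up to three interactions,
third-slot columns zero-filled for double-scatter events.  One merged
16-class softmax covers every situation the readout can produce (see
:mod:`pgcc.events`); classes that are structurally impossible for an
event's size are masked out of the softmax.

:class:`ComptonEventClassifier` follows the scikit-learn estimator
contract (``fit``/``predict``/``predict_proba``, ``get_params``, fitted
attributes with trailing underscores) and therefore composes with sklearn
model selection; :func:`train` / :func:`predict_labels` / :func:`evaluate`
wrap it for list-mode datasets.

A kinematics-only baseline (:func:`kinematics_baseline_classes`) chooses
the interaction ordering minimizing Compton-consistency violations; it is
the yardstick the learned model must beat.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._mlp import ResidualMLP, masked_log_softmax
from .events import (
    EventLabels,
    ListModeDataset,
    N_CLASSES,
    TS_PERMUTATIONS,
    class_mask_for_size,
)
from .kinematics import ELECTRON_REST_ENERGY_MEV, ts_initial_energy, DegenerateGeometryError

__all__ = [
    "ComptonEventClassifier",
    "train",
    "predict_labels",
    "evaluate",
    "kinematics_baseline_classes",
]


def _mask_from_features(X: np.ndarray) -> np.ndarray:
    """Infer per-event reachable classes from the zero-filled third slot."""
    is_ds = (X[:, 8:12] == 0.0).all(axis=1)
    n_int = np.where(is_ds, 2, 3)
    return class_mask_for_size(n_int)


# ---------------------------------------------------------------------------
# physics-informed internal featurization

_LINES = np.array([0.511, 0.718, 2.0, 2.22, 4.44])   # known emission lines [MeV]
_ZGRID = np.linspace(-5.0, 30.0, 71)                  # beam-axis probe depths [cm]


def _cone_block(e_f, p_f, p_s, E0):
    """Per-hypothesis cone descriptors, vectorized over events.

    Treats ``p_f`` as the first interaction of a photon of energy ``E0``
    depositing ``e_f`` there and proceeding toward ``p_s``.  Returns the
    Compton cosine (clipped), opening angle, kinematic violation magnitude,
    the cone's best angular agreement with the beam axis and the depth at
    which it occurs, and the first-deposit fraction.
    """
    E0 = np.maximum(E0, 1e-9)
    e_sc = np.maximum(E0 - e_f, 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 1.0 - ELECTRON_REST_ENERGY_MEV * (1.0 / e_sc - 1.0 / E0)
    viol = np.maximum(np.abs(c) - 1.0, 0.0)
    cc = np.clip(c, -1.0, 1.0)
    th = np.arccos(cc)
    axis = p_f - p_s
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    axis = axis / np.maximum(norm, 1e-9)
    beam = np.zeros((_ZGRID.size, 3))
    beam[:, 2] = _ZGRID
    u = beam[None, :, :] - p_f[:, None, :]
    u = u / np.maximum(np.linalg.norm(u, axis=2, keepdims=True), 1e-9)
    gam = np.arccos(np.clip(np.einsum("nzc,nc->nz", u, axis), -1.0, 1.0))
    dev = np.abs(gam - th[:, None])
    k = dev.argmin(axis=1)
    rows = np.arange(k.size)
    return np.column_stack([cc, th, viol, dev[rows, k], _ZGRID[k], e_f / E0])


def _ts_tracking_energy(e2, p1, p2, p3):
    """Vectorized three-interaction tracking energy of the photon at p2."""
    u = p2 - p1
    v = p3 - p2
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos2 = np.einsum("nc,nc->n", u, v) / np.maximum(nu * nv, 1e-12)
    omc = np.maximum(1.0 - np.clip(cos2, -1.0, 1.0), 1e-9)
    half = e2 / 2.0
    return half + np.sqrt(half**2 + e2 * ELECTRON_REST_ENERGY_MEV / omc)


def augment_features(X: np.ndarray) -> np.ndarray:
    """Physics-informed expansion of the 12-value event feature vector.

    Deterministic derived quantities a Compton-kinematics practitioner
    would compute by hand: per-ordering initial-energy estimates (deposit
    sum and nearest-emission-line hypotheses), Compton-cosine validity,
    cone-versus-beam-axis agreement, tracking energies for triple
    orderings, embedded-pair descriptors for the double-in-triple
    hypotheses, pairwise distances and stage flags.  Purely a function of
    the input features — no labels, no randomness.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    e = X[:, 0::4]                       # (N, 3) deposits
    p = X.reshape(n, 3, 4)[:, :, 1:]     # (N, 3, 3) positions
    is_ts = ~(X[:, 8:12] == 0.0).all(axis=1)

    blocks = [X]
    # double hypotheses on the first two slots, both orders, two E0 choices
    sum2 = e[:, 0] + e[:, 1]
    line2 = _LINES[np.abs(sum2[:, None] - _LINES[None, :]).argmin(axis=1)]
    for E0 in (sum2, line2):
        blocks.append(_cone_block(e[:, 0], p[:, 0], p[:, 1], E0))
        blocks.append(_cone_block(e[:, 1], p[:, 1], p[:, 0], E0))
    blocks.append((sum2 - line2)[:, None])

    # triple-ordering hypotheses (zeroed for doubles)
    sum3 = e.sum(axis=1)
    line3 = _LINES[np.abs(sum3[:, None] - _LINES[None, :]).argmin(axis=1)]
    ts_blocks = []
    for perm in TS_PERMUTATIONS:
        a, b, c = perm
        E2 = _ts_tracking_energy(e[:, b], p[:, a], p[:, b], p[:, c])
        E0 = e[:, a] + E2
        blk = _cone_block(e[:, a], p[:, a], p[:, b], E0)
        edge = 2 * E2**2 / (ELECTRON_REST_ENERGY_MEV + 2 * E2)
        ts_blocks.append(np.column_stack([E0, blk, np.maximum(e[:, b] - edge, 0.0)]))
    # embedded-pair (double-in-triple) hypotheses: each unordered pair as a DS
    for i, j in ((0, 1), (0, 2), (1, 2)):
        s = e[:, i] + e[:, j]
        ts_blocks.append(_cone_block(e[:, i], p[:, i], p[:, j], s))
        ts_blocks.append(_cone_block(e[:, j], p[:, j], p[:, i], s))
    ts_part = np.hstack(ts_blocks)
    ts_part[~is_ts] = 0.0
    blocks.append(ts_part)
    blocks.append(np.where(is_ts, sum3 - line3, 0.0)[:, None])

    d01 = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    d02 = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    d12 = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    stage2 = (p[:, :, 1] < -32.0).astype(float)      # stage-2 flag per slot
    stage2[~is_ts, 2] = 0.0
    blocks.append(np.column_stack([d01, d02 * is_ts, d12 * is_ts,
                                   np.abs(e[:, 0] - e[:, 1])]))
    blocks.append(stage2)
    return np.hstack(blocks)


class ComptonEventClassifier(ClassifierMixin, BaseEstimator):
    """Residual fully-connected network over 12-value event features.

    Parameters
    ----------
    hidden_layers : int
        Number of equal-width hidden layers (desk-scale default; the
        architecture is depth-configurable).
    width : int
        Hidden layer width.
    leaky_slope : float
        Negative-side slope of the leaky-ReLU activation.
    skip_period : int
        Identity residual skip added every this many hidden layers.
    epochs, batch_size, learning_rate : training schedule (Adam).
    validation_fraction : float
        Fraction of ``fit`` data held out for per-epoch validation
        (the standard 80/20 split by default).
    random_state : int
        Seeds initialization, the train/validation split and batch
        shuffling; fits are bit-reproducible.
    """

    def __init__(self, hidden_layers=10, width=64, leaky_slope=0.01, skip_period=2,
                 epochs=30, batch_size=256, learning_rate=1e-3, lr_halving_epochs=12,
                 features="physics", validation_fraction=0.2, random_state=0):
        self.hidden_layers = hidden_layers
        self.width = width
        self.leaky_slope = leaky_slope
        self.skip_period = skip_period
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_halving_epochs = lr_halving_epochs
        self.features = features
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _featurize(self, X):
        if self.features == "physics":
            return augment_features(X)
        if self.features == "raw":
            return np.asarray(X, dtype=float)
        raise ValueError(f"unknown feature mode {self.features!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = y.astype(np.int64)
        if X.shape[1] != 12:
            raise ValueError("expected 12 features per event")
        if np.unique(y).size < 2:
            raise ValueError("degenerate single-class training data")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.validation_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        Xf = self._featurize(X)
        # standardization fitted on training rows only and stored with the model
        mu = Xf[tr_idx].mean(axis=0)
        sd = Xf[tr_idx].std(axis=0)
        sd[sd == 0] = 1.0
        self.scaler_mean_, self.scaler_scale_ = mu, sd

        Xs = (Xf - mu) / sd
        mask = _mask_from_features(X)
        net = ResidualMLP(Xf.shape[1], N_CLASSES, width=self.width,
                          n_hidden=self.hidden_layers,
                          leaky_slope=self.leaky_slope,
                          skip_period=self.skip_period, rng=rng)

        history = {"loss": [], "val_accuracy": []}
        bs = int(self.batch_size)
        for epoch in range(int(self.epochs)):
            lr = self.learning_rate * 0.5 ** (epoch // int(self.lr_halving_epochs))
            order = tr_idx[rng.permutation(tr_idx.size)]
            losses = []
            for s in range(0, order.size, bs):
                b = order[s:s + bs]
                loss, grads = net.loss_and_grads(Xs[b], y[b], mask[b])
                net.adam_step(grads, lr)
                losses.append(loss)
            pv = self._predict_net(net, Xs[val_idx], mask[val_idx])
            history["loss"].append(float(np.mean(losses)))
            history["val_accuracy"].append(float((pv == y[val_idx]).mean()))

        self.net_ = net
        self.classes_ = np.arange(N_CLASSES)
        self.n_features_in_ = 12
        self.n_features_internal_ = int(Xf.shape[1])
        self.history_ = history
        self.validation_report_ = evaluate(
            EventLabels.from_class_indices(self._predict_net(net, Xs[val_idx], mask[val_idx]),
                                           np.where(mask[val_idx][:, 0], 2, 3)),
            EventLabels.from_class_indices(y[val_idx], np.where(mask[val_idx][:, 0], 2, 3)),
        )
        return self

    @staticmethod
    def _predict_net(net, Xs, mask):
        logits = net.forward(Xs)
        logits = np.where(mask, logits, -np.inf)
        return logits.argmax(axis=1)

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X)
        Xs = (self._featurize(X) - self.scaler_mean_) / self.scaler_scale_
        mask = _mask_from_features(X)
        return np.exp(masked_log_softmax(self.net_.forward(Xs), mask))

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X)
        Xs = (self._featurize(X) - self.scaler_mean_) / self.scaler_scale_
        return self._predict_net(self.net_, Xs, _mask_from_features(X))

    # ---- single-file serialization --------------------------------------
    def save(self, path):
        check_is_fitted(self, "net_")
        meta, params = self.net_.state_dict()
        blob = {"config": self.get_params(), "net_meta": meta}
        np.savez(path, __meta__=np.frombuffer(json.dumps(blob).encode(), dtype=np.uint8),
                 scaler_mean=self.scaler_mean_, scaler_scale=self.scaler_scale_, **params)

    @classmethod
    def load(cls, path) -> "ComptonEventClassifier":
        with np.load(path) as f:
            blob = json.loads(bytes(f["__meta__"]).decode())
            clf = cls(**blob["config"])
            clf.scaler_mean_ = f["scaler_mean"]
            clf.scaler_scale_ = f["scaler_scale"]
            params = {k: f[k] for k in f.files
                      if k not in ("__meta__", "scaler_mean", "scaler_scale")}
        clf.net_ = ResidualMLP.from_state(blob["net_meta"], params)
        clf.classes_ = np.arange(N_CLASSES)
        clf.n_features_in_ = 12
        return clf


# ---------------------------------------------------------------------------
# list-mode dataset wrappers

def train(data: ListModeDataset, **params) -> tuple[ComptonEventClassifier, dict]:
    """Fit a classifier on a labeled (and training-shuffled) dataset.

    Returns the fitted estimator and a training report with per-epoch loss,
    per-epoch validation accuracy and the final per-category validation
    accuracy table.
    """
    if data.labels is None:
        raise ValueError("training requires labels")
    clf = ComptonEventClassifier(**params)
    clf.fit(data.features(), data.labels.class_indices())
    report = {"history": clf.history_, "validation": clf.validation_report_}
    return clf, report


def predict_labels(data: ListModeDataset, clf: ComptonEventClassifier) -> EventLabels:
    """Predicted event labels, one per event; softmax argmax with size mask."""
    ci = clf.predict(data.features())
    return EventLabels.from_class_indices(ci, data.n_interactions)


def evaluate(predicted: EventLabels, truth: EventLabels) -> dict:
    """Per-category accuracy table.

    DS accuracy groups doubles into {true correctly-ordered, true
    mis-ordered, false}; TS accuracy groups triples into {true (any
    ordering), false, double-in-triple}; ``ordering_accuracy`` requires the
    exact class (type and full ordering) to match.
    """
    if len(predicted) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    pc = predicted.class_indices()
    tc = truth.class_indices()
    is_ds = tc < 3
    out = {"n_events": int(len(truth))}

    def acc(mask, group):
        if not mask.any():
            return float("nan")
        return float((group(pc[mask]) == group(tc[mask])).mean())

    ts_group = np.zeros(N_CLASSES, dtype=int)
    ts_group[3:9] = 0   # true TS, any ordering
    ts_group[9:15] = 1  # double-in-triple
    ts_group[15] = 2    # false
    out["ds_accuracy"] = acc(is_ds, lambda c: c)
    out["ts_accuracy"] = acc(~is_ds, lambda c: ts_group[c])
    out["ordering_accuracy"] = float((pc == tc).mean())
    out["confusion_counts"] = _confusion(tc, pc)
    return out


def _confusion(tc, pc) -> dict:
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (tc, pc), 1)
    return {"matrix": cm.tolist()}


# ---------------------------------------------------------------------------
# kinematics-only baseline

def _ds_violation(e_first: float, e_second: float) -> float:
    """How far the implied Compton cosine falls outside [-1, 1] (0 = consistent)."""
    e0 = e_first + e_second
    e_sc = e0 - e_first
    c = 1.0 - ELECTRON_REST_ENERGY_MEV * (1.0 / e_sc - 1.0 / e0)
    return max(0.0, abs(c) - 1.0)


def kinematics_baseline_classes(data: ListModeDataset) -> np.ndarray:
    """Classical ordering baseline: minimize Compton-consistency violation.

    Doubles: pick the ordering whose first deposit is kinematically allowed
    under the sum-energy estimate (ties keep the recorded order).  Triples:
    for each of the six orderings estimate the initial energy by gamma-ray
    tracking and score the kinematic feasibility of the implied first and
    second scatters; pick the least-violating ordering.  The baseline has no
    notion of false or double-in-triple events — every event is assumed true,
    which is exactly the blind spot the learned classifier addresses.
    """
    out = np.empty(len(data), dtype=np.int64)
    for i in range(len(data)):
        ev = data[i]
        e = ev.energies
        p = ev.positions
        if ev.n_interactions == 2:
            v01 = _ds_violation(e[0], e[1])
            v10 = _ds_violation(e[1], e[0])
            out[i] = 0 if v01 <= v10 else 1
            continue
        best, best_v = 0, np.inf
        for r, perm in enumerate(TS_PERMUTATIONS):
            ep = e[list(perm)]
            pp = p[list(perm)]
            try:
                e0 = ts_initial_energy(energies=ep, positions=pp)
            except DegenerateGeometryError:
                continue
            v = _ds_violation(ep[0], e0 - ep[0])
            e1_in = e0 - ep[0]
            # second-scatter deposit must respect the Compton edge
            edge = 2 * e1_in**2 / (ELECTRON_REST_ENERGY_MEV + 2 * e1_in)
            v += max(0.0, ep[1] - edge)
            if v < best_v:
                best_v, best = v, r
        out[i] = 3 + best
    return out
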