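"""Performer identification from single-keystroke phase trajectories.

The classification chain mirrors a movement-biometrics workflow: the
portions of the velocity and acceleration curves that separate performers
(the functional-ANOVA mask) are concatenated into feature vectors,
compressed by PCA to the smallest number of components explaining >= 95% of
the variance, and fed to a small two-hidden-layer feed-forward network (10
and 20 tanh units, softmax output) trained with resilient backpropagation
(Rprop).  Accuracy is estimated by five repeats of stratified 10-fold
cross-validation, with bagging (majority vote over networks trained on
bootstrap resamples of each training fold) inside every fold.

PCA is fitted inside each training fold and applied to its test fold, so no
test information leaks into the representation; ``pca_on_all_data=True``
reproduces the leakier variant where components are fitted once on
everything.  All randomness (fold shuffling, bootstrap draws, weight
initialization) derives from a single seed through separate child streams,
so reports are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierReport", "RpropNetwork",
    "build_feature_vectors", "pca_reduce", "train_network", "bagged_crossvalidate",
]


def build_feature_vectors(trajectories, fanova_mask) -> np.ndarray:
    """Stack masked velocity and acceleration samples into feature rows.

    Each trajectory contributes its velocity values at the masked grid
    points followed by its acceleration values at those points; columns are
    then standardized to mean 0, sd 1.  An empty mask is an error (use a
    lower alpha level to obtain a nonempty significant portion).
    """
    mask = np.asarray(fanova_mask, bool)
    if not mask.any():
        raise ValueError("empty functional-ANOVA mask: no grid points separate the "
                         "groups; try a lower alpha level")
    X = np.stack([np.concatenate([t.velocity[mask], t.acceleration[mask]])
                  for t in trajectories])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def pca_reduce(X: np.ndarray, variance_threshold: float = 0.95):
    """Project onto the smallest number of PCs reaching the variance threshold.

    Returns (scores, loadings, variance_fractions) where scores is
    (n, k), loadings (k, p) and variance_fractions the full spectrum.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constant feature matrix has no principal components")
    pca = PCA()
    scores_full = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(frac), variance_threshold) + 1)
    k = min(k, len(frac))
    return scores_full[:, :k], pca.components_[:k], frac


class RpropNetwork:
    """Two-hidden-layer tanh network trained with resilient backpropagation.

    Classic Rprop with weight-backtracking is applied to the full-batch
    cross-entropy gradient: each weight keeps its own step size, multiplied
    by eta+ = 1.2 when the gradient keeps its sign and by eta- = 0.5 when
    it flips (undoing the last step), clipped to [1e-6, 50].  Training
    stops early when validation loss stops improving.
    """

    ETA_PLUS, ETA_MINUS = 1.2, 0.5
    DELTA0, DELTA_MIN, DELTA_MAX = 0.1, 1e-6, 50.0

    def __init__(self, n_in: int, n_classes: int, hidden=(10, 20), seed=None):
        rng = np.random.default_rng(seed)
        sizes = [n_in, *hidden, n_classes]
        self.weights = []
        self.biases = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(a)
            self.weights.append(rng.uniform(-bound, bound, size=(a, b)))
            self.biases.append(np.zeros(b))
        self.classes_: np.ndarray | None = None

    # --- forward / backward ---

    def _forward(self, X):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            h = np.tanh(z) if i < len(self.weights) - 1 else z
            acts.append(h)
        # softmax on the final linear layer
        z = acts[-1] - acts[-1].max(axis=1, keepdims=True)
        e = np.exp(z)
        acts[-1] = e / e.sum(axis=1, keepdims=True)
        return acts

    def predict_proba(self, X) -> np.ndarray:
        return self._forward(np.asarray(X, float))[-1]

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def _loss_and_grads(self, X, T):
        acts = self._forward(X)
        P = acts[-1]
        n = len(X)
        loss = -np.sum(T * np.log(np.clip(P, 1e-12, None))) / n
        delta = (P - T) / n
        gW, gb = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            gW.append(acts[i].T @ delta)
            gb.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (1.0 - acts[i] ** 2)
        return loss, gW[::-1], gb[::-1]

    # --- training ---

    def fit(self, X, y, max_epochs: int = 300, val_fraction: float = 0.15,
            patience: int = 30, seed=None):
        """Train on (X, y); deterministic for a fixed network + ``seed``.

        A random ``val_fraction`` of the rows (at least one per class when
        possible) is held out for early stopping; training runs at most
        ``max_epochs`` full-batch Rprop steps and restores the weights of
        the best validation epoch.
        """
        X = np.asarray(X, float)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        yi = np.searchsorted(self.classes_, y)
        T = np.eye(len(self.classes_))[yi]

        rng = np.random.default_rng(seed)
        n = len(X)
        n_val = int(round(val_fraction * n))
        if n_val >= 2 and n - n_val >= len(self.classes_):
            order = rng.permutation(n)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            if len(np.unique(yi[tr_idx])) < len(self.classes_):
                val_idx, tr_idx = np.array([], int), np.arange(n)
        else:
            val_idx, tr_idx = np.array([], int), np.arange(n)
        Xt, Tt = X[tr_idx], T[tr_idx]
        Xv, Tv = X[val_idx], T[val_idx]

        params = self.weights + self.biases
        steps = [np.full_like(p, self.DELTA0) for p in params]
        prev_grads = [np.zeros_like(p) for p in params]
        prev_update = [np.zeros_like(p) for p in params]
        best_loss, best_state, since_best = np.inf, None, 0
        self.loss_curve_ = []
        for _ in range(max_epochs):
            loss, gW, gb = self._loss_and_grads(Xt, Tt)
            self.loss_curve_.append(loss)
            grads = gW + gb
            for p, g, st, pg, pu in zip(params, grads, steps, prev_grads, prev_update):
                sign = pg * g
                inc, dec = sign > 0, sign < 0
                st[inc] = np.minimum(st[inc] * self.ETA_PLUS, self.DELTA_MAX)
                st[dec] = np.maximum(st[dec] * self.ETA_MINUS, self.DELTA_MIN)
                update = -np.sign(g) * st
                update[dec] = -pu[dec]  # backtrack the flipped weights
                g = g.copy()
                g[dec] = 0.0
                p += update
                pg[...] = g
                pu[...] = update
            if len(Xv):
                vl, *_ = self._loss_and_grads(Xv, Tv)
            else:
                vl = loss
            if vl < best_loss - 1e-9:
                best_loss, since_best = vl, 0
                best_state = [p.copy() for p in params]
            else:
                since_best += 1
                if since_best >= patience:
                    break
        if best_state is not None:
            for p, b in zip(params, best_state):
                p[...] = b
        return self


def train_network(features, labels, hidden=(10, 20), seed=None,
                  max_epochs: int = 300) -> RpropNetwork:
    """Train one Rprop network on the full feature matrix (seeded)."""
    X = np.asarray(features, float)
    classes = np.unique(labels)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_seed, fit_seed = ss.spawn(2)
    net = RpropNetwork(X.shape[1], len(classes), hidden=hidden, seed=init_seed)
    net.fit(X, labels, max_epochs=max_epochs, seed=fit_seed)
    return net


@dataclass
class ClassifierReport:
    """Cross-validated performer-identification results."""

    accuracy: float                      # mean over CV repeats
    accuracy_per_repeat: list[float]
    per_class_accuracy: dict[str, float]
    confusion_counts: pd.DataFrame       # actual x classified
    confusion_pct: pd.DataFrame          # rows sum to 100
    chance: float
    n_classes: int
    folds: int
    repeats: int
    bags: int
    seed: int | None
    fold_assignments: pd.DataFrame = field(repr=False, default=None)


def _bootstrap_indices(rng, y, n) -> np.ndarray:
    """Bootstrap resample keeping every class represented."""
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) == len(np.unique(y)):
            return idx
    raise RuntimeError("could not draw a bootstrap sample containing all classes")


def bagged_crossvalidate(
    features, labels,
    folds: int = 10, repeats: int = 5, bags: int = 15,
    hidden=(10, 20), seed=None,
    pca_threshold: float | None = 0.95,
    pca_on_all_data: bool = False,
    max_epochs: int = 300,
) -> ClassifierReport:
    """Repeated stratified k-fold CV of the bagged Rprop classifier.

    For each of ``repeats`` shuffles, the rows are split into ``folds``
    stratified folds; each fold is predicted by majority vote of ``bags``
    networks trained on bootstrap resamples of the remaining folds.
    Accuracy is the mean over repeats of the overall proportion correct;
    the confusion matrix accumulates over all repeats.

    ``pca_threshold`` (if not None) compresses features to the PCs reaching
    that cumulative variance, fitted on the training part of every fold —
    or once on everything when ``pca_on_all_data`` is set.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 classes")
    if len(X) < folds:
        raise ValueError("fewer samples than folds")
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise ValueError(f"stratification impossible: class {counts.idxmin()!r} has "
                         f"{counts.min()} samples for {folds} folds")
    ss = np.random.SeedSequence(seed)
    fold_ss, bag_ss = ss.spawn(2)
    fold_seeds = fold_ss.generate_state(repeats)
    bag_children = iter(bag_ss.spawn(repeats * folds * bags))

    if pca_on_all_data and pca_threshold is not None:
        scores, _, _ = pca_reduce(X, pca_threshold)
        X_all = scores
    else:
        X_all = X

    conf = np.zeros((k, k), int)
    acc_repeat = []
    assignment_rows = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(fold_seeds[r] % (2**31)))
        pred = np.empty(len(y), dtype=object)
        for fold_no, (tr, te) in enumerate(skf.split(X_all, y)):
            if len(np.unique(y[tr])) < k:
                raise ValueError("a class is absent from a training split")
            if pca_threshold is not None and not pca_on_all_data:
                Xtr_s, loadings, _ = pca_reduce(X_all[tr], pca_threshold)
                center = X_all[tr].mean(axis=0)
                Xtr, Xte = Xtr_s, (X_all[te] - center) @ loadings.T
            else:
                Xtr, Xte = X_all[tr], X_all[te]
            votes = np.zeros((len(te), k), int)
            for _ in range(bags):
                child = next(bag_children)
                boot_seed, net_seed = child.spawn(2)
                rng = np.random.default_rng(boot_seed)
                bi = _bootstrap_indices(rng, y[tr], len(tr))
                net = train_network(Xtr[bi], y[tr][bi], hidden=hidden,
                                    seed=net_seed, max_epochs=max_epochs)
                p = net.predict(Xte)
                votes[np.arange(len(te)), np.searchsorted(classes, p)] += 1
            pred[te] = classes[np.argmax(votes, axis=1)]
            for t in te:
                assignment_rows.append({"repeat": r, "fold": fold_no, "row": int(t)})
        acc_repeat.append(float(np.mean(pred == y)))
        for a, p in zip(y, pred):
            conf[np.searchsorted(classes, a), np.searchsorted(classes, p)] += 1

    conf_df = pd.DataFrame(conf, index=classes, columns=classes)
    with np.errstate(invalid="ignore"):
        pct = conf / conf.sum(axis=1, keepdims=True) * 100.0
    per_class = {str(c): float(conf[i, i] / conf[i].sum()) for i, c in enumerate(classes)}
    return ClassifierReport(
        accuracy=float(np.mean(acc_repeat)),
        accuracy_per_repeat=acc_repeat,
        per_class_accuracy=per_class,
        confusion_counts=conf_df,
        confusion_pct=pd.DataFrame(pct, index=classes, columns=classes),
        chance=1.0 / k,
        n_classes=k,
        folds=folds,
        repeats=repeats,
        bags=bags,
        seed=seed,
        fold_assignments=pd.DataFrame(assignment_rows),
    )
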