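"""Linear separation of ranked pair differences.

A single-layer perceptron with sigmoid output — equivalently logistic
regression *without* an intercept — is trained by full-batch gradient
descent on pair-difference feature vectors. The intercept is omitted on
purpose: the separating hyperplane must pass through the origin so that
swapping a pair (v, w) -> (w, v) negates both the feature and the decision,
and its normal vector is then exactly the Taylor-coefficient vector of the
fitness approximation.

Every training set is antisymmetrically augmented with (-diff, -label)
before fitting, which makes the column means exactly zero; features are
then whitened (Cholesky factor of their covariance) and the learned
weights mapped back to the raw feature scale, so the reported hyperplane
normal lives in the original lifted-feature coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .feature_space import FitnessCoefficients, RankedPair

__all__ = [
    "SeparatorModel",
    "EvalReport",
    "train_separator",
    "classify_pair",
    "evaluate",
    "cross_val_accuracy",
    "nearest_neighbor_baseline",
    "extract_coefficients",
]

DEFAULT_HYPER = {"lr": 0.1, "epochs": 2000, "l2": 1e-6, "seed": 0}

_PROB_CLIP = 1e-12


@dataclass
class SeparatorModel:
    """Origin-through separating hyperplane over a lifted feature basis."""

    weights: np.ndarray  # raw-scale hyperplane normal
    n: int
    k: int
    loss_curve: np.ndarray = field(repr=False, default=None)
    hyper: dict = field(default_factory=dict)

    def decision(self, diffs: np.ndarray) -> np.ndarray:
        diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
        if diffs.shape[1] != self.weights.size:
            raise ValueError(
                f"feature length {diffs.shape[1]} does not match model "
                f"dimension {self.weights.size}")
        return diffs @ self.weights

    def to_json(self) -> str:
        return json.dumps({
            "n": self.n, "k": self.k,
            "weights": self.weights.tolist(),
            "hyper": self.hyper,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SeparatorModel":
        obj = json.loads(text)
        return cls(np.asarray(obj["weights"], dtype=float),
                   n=obj["n"], k=obj["k"], hyper=obj.get("hyper", {}))


@dataclass(frozen=True)
class EvalReport:
    """Hold-out metrics of a pair classifier."""

    accuracy: float
    logloss: float
    cv_accuracy: float
    confusion: dict  # {"tp": ..., "tn": ..., "fp": ..., "fn": ...}


def _pair_matrix(pairs: list[RankedPair]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([p.diff for p in pairs], dtype=float)
    y = np.array([p.label for p in pairs], dtype=float)
    return X, y


def train_separator(pairs: list[RankedPair] | "RankedDataset",
                    hyper: dict | None = None) -> SeparatorModel:
    """Fit the no-intercept logistic separator by full-batch gradient descent.

    Accepts a list of training pairs or a RankedDataset (whose train split
    is used). Minimizes the mean logistic loss, L2-regularized in the
    whitened feature gauge, over the antisymmetrically augmented set. A
    step that would increase the loss triggers a momentum restart and
    step-size backtracking, so the recorded loss curve is non-increasing;
    the fit is deterministic for fixed inputs.
    """
    if hasattr(pairs, "train_pairs"):
        dataset = pairs
        pairs = dataset.train_pairs
        n, k = dataset.n, dataset.k
    else:
        n = k = None
    hp = dict(DEFAULT_HYPER)
    if hyper:
        hp.update(hyper)
    X, y = _pair_matrix(pairs)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training pairs")
    if not np.any(np.abs(X) > 0):
        raise ValueError("all pair-difference vectors are zero; nothing to fit")

    # antisymmetric augmentation guarantees both labels and zero column means
    Xa = np.vstack([X, -X])
    ya = np.concatenate([y, -y])
    # lifted feature columns are strongly correlated (condition numbers in
    # the thousands); whitening instead of per-column scaling keeps plain
    # gradient descent convergent in a few hundred steps
    cov = Xa.T @ Xa / Xa.shape[0]
    jitter = 1e-12 * np.trace(cov) / cov.shape[0]
    chol = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
    Xs = np.linalg.solve(chol, Xa.T).T

    w = np.zeros(Xs.shape[1])
    lr, l2 = float(hp["lr"]), float(hp["l2"])
    losses = []

    def loss_of(wv: np.ndarray) -> float:
        margins = ya * (Xs @ wv)
        return float(np.mean(np.logaddexp(0.0, -margins)) + 0.5 * l2 * wv @ wv)

    def grad_of(wv: np.ndarray) -> np.ndarray:
        margins = ya * (Xs @ wv)
        sig = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))
        return -(Xs * (ya * sig)[:, None]).mean(axis=0) + l2 * wv

    # Full-batch gradient descent with Nesterov momentum; a monotone
    # restart (drop momentum, backtrack the step) whenever a step would
    # increase the loss keeps the recorded curve non-increasing while
    # coping with the strong correlation between lifted feature columns.
    current = loss_of(w)
    y_acc, t_acc = w.copy(), 1.0
    for _ in range(int(hp["epochs"])):
        w_new = y_acc - lr * grad_of(y_acc)
        new = loss_of(w_new)
        if new > current:
            while True:  # plain backtracked gradient step from w
                w_new = w - lr * grad_of(w)
                new = loss_of(w_new)
                if new <= current or lr < 1e-12:
                    break
                lr *= 0.5
            t_acc = 1.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc * t_acc))
        y_acc = w_new + ((t_acc - 1.0) / t_next) * (w_new - w)
        w, current, t_acc = w_new, new, t_next
        lr *= 1.02
        losses.append(current)
        if not np.isfinite(current):
            raise ArithmeticError(
                f"training loss became non-finite at epoch {len(losses)}; "
                f"|w|={np.linalg.norm(w):g}")

    if n is None:
        # infer a linear basis when trained on a bare pair list
        n, k = X.shape[1], 1
    return SeparatorModel(weights=np.linalg.solve(chol.T, w), n=n, k=k,
                          loss_curve=np.asarray(losses), hyper=hp)


def classify_pair(model: SeparatorModel, diff: np.ndarray) -> tuple[int, float]:
    """Predicted order and probability that the first strategy is better.

    The on-hyperplane tie sign(0) maps to +1 by convention.
    """
    score = float(model.decision(diff)[0])
    label = 1 if score >= 0 else -1
    prob = float(1.0 / (1.0 + np.exp(-np.clip(score, -500, 500))))
    return label, prob


def _accuracy_logloss(model: SeparatorModel,
                      pairs: list[RankedPair]) -> tuple[float, float, dict]:
    X, y = _pair_matrix(pairs)
    scores = model.decision(X)
    pred = np.where(scores >= 0, 1.0, -1.0)
    acc = float(np.mean(pred == y))
    p_first = 1.0 / (1.0 + np.exp(-np.clip(scores, -500, 500)))
    p_true = np.where(y > 0, p_first, 1.0 - p_first)
    p_true = np.clip(p_true, _PROB_CLIP, 1.0 - _PROB_CLIP)
    logloss = float(-np.mean(np.log(p_true)))
    conf = {
        "tp": int(np.sum((pred > 0) & (y > 0))),
        "tn": int(np.sum((pred < 0) & (y < 0))),
        "fp": int(np.sum((pred > 0) & (y < 0))),
        "fn": int(np.sum((pred < 0) & (y > 0))),
    }
    return acc, logloss, conf


def cross_val_accuracy(pairs: list[RankedPair], hyper: dict | None = None,
                       n_folds: int = 5, seed: int = 0) -> float:
    """Mean k-fold accuracy of seeded separator refits on ``pairs``."""
    if len(pairs) < n_folds:
        raise ValueError(f"need at least {n_folds} pairs for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    folds = np.array_split(perm, n_folds)
    accs = []
    for f in folds:
        test = [pairs[i] for i in f]
        train = [pairs[i] for i in np.setdiff1d(perm, f)]
        model = train_separator(train, hyper)
        acc, _, _ = _accuracy_logloss(model, test)
        accs.append(acc)
    return float(np.mean(accs))


def evaluate(model: SeparatorModel, pairs: list[RankedPair],
             cv_pairs: list[RankedPair] | None = None,
             n_folds: int = 5, seed: int = 0,
             hyper: dict | None = None) -> EvalReport:
    """Hold-out accuracy and log-loss, plus k-fold CV accuracy.

    CV refits the separator on ``cv_pairs`` (default: the evaluation pairs)
    with seeded folds; log-loss uses the natural logarithm with
    probabilities clipped to [1e-12, 1 - 1e-12].
    """
    if not pairs:
        raise ValueError("empty evaluation set")
    acc, logloss, conf = _accuracy_logloss(model, pairs)
    cv = cross_val_accuracy(cv_pairs if cv_pairs is not None else pairs,
                            hyper or model.hyper, n_folds, seed)
    return EvalReport(accuracy=acc, logloss=logloss, cv_accuracy=cv,
                      confusion=conf)


def nearest_neighbor_baseline(dataset, k_nn: int = 1,
                              n_folds: int = 5, seed: int = 0) -> EvalReport:
    """k-NN classification of pair differences on the dataset's split.

    The comparison baseline: Euclidean k-NN on the (antisymmetrically
    augmented, variance-scaled) training differences, evaluated on the test
    split exactly like the separator.
    """
    Xtr, ytr = _pair_matrix(dataset.train_pairs)
    Xte, yte = _pair_matrix(dataset.test_pairs)
    if k_nn < 1 or k_nn > 2 * Xtr.shape[0]:
        raise ValueError(f"k_nn={k_nn} out of range for {Xtr.shape[0]} training pairs")
    Xa = np.vstack([Xtr, -Xtr])
    ya = np.concatenate([ytr, -ytr])
    scale = Xa.std(axis=0)
    scale[scale == 0] = 1.0

    knn = KNeighborsClassifier(n_neighbors=k_nn)
    knn.fit(Xa / scale, ya)
    pred = knn.predict(Xte / scale)
    acc = float(np.mean(pred == yte))
    proba = knn.predict_proba(Xte / scale)
    p_first = proba[:, list(knn.classes_).index(1.0)]
    p_true = np.where(yte > 0, p_first, 1.0 - p_first)
    p_true = np.clip(p_true, _PROB_CLIP, 1.0 - _PROB_CLIP)
    logloss = float(-np.mean(np.log(p_true)))

    # seeded k-fold CV of the k-NN itself on the pooled pairs
    pairs = dataset.pairs
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    folds = np.array_split(perm, n_folds)
    accs = []
    for f in folds:
        tr = np.setdiff1d(perm, f)
        Xf, yf = _pair_matrix([pairs[i] for i in tr])
        Xfa, yfa = np.vstack([Xf, -Xf]), np.concatenate([yf, -yf])
        sc = Xfa.std(axis=0)
        sc[sc == 0] = 1.0
        m = KNeighborsClassifier(n_neighbors=min(k_nn, 2 * Xf.shape[0]))
        m.fit(Xfa / sc, yfa)
        Xv, yv = _pair_matrix([pairs[i] for i in f])
        accs.append(float(np.mean(m.predict(Xv / sc) == yv)))
    conf = {
        "tp": int(np.sum((pred > 0) & (yte > 0))),
        "tn": int(np.sum((pred < 0) & (yte < 0))),
        "fp": int(np.sum((pred > 0) & (yte < 0))),
        "fn": int(np.sum((pred < 0) & (yte > 0))),
    }
    return EvalReport(accuracy=acc, logloss=logloss,
                      cv_accuracy=float(np.mean(accs)), confusion=conf)


def extract_coefficients(model: SeparatorModel, convention: str = "unit",
                         match_index: int = 0,
                         match_value: float = 1.0) -> FitnessCoefficients:
    """Read the fitness Taylor coefficients off the hyperplane normal.

    convention "unit": L2-normalized with a non-negative M1 coefficient.
    convention "match": rescale so the coefficient at ``match_index``
    equals ``match_value`` (for comparison against published values).
    """
    w = np.asarray(model.weights, dtype=float)
    if not np.any(w != 0):
        raise ZeroDivisionError("zero weight vector: the separator is degenerate")
    if convention == "unit":
        return FitnessCoefficients(w, model.n, model.k, "raw").unit()
    if convention == "match":
        if w[match_index] == 0:
            raise ZeroDivisionError(
                f"cannot match: weight {match_index} is zero")
        return FitnessCoefficients(w * (match_value / w[match_index]),
                                   model.n, model.k, "match")
    raise ValueError(f"unknown normalization convention {convention!r}")
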