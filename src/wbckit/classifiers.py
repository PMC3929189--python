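"""Three classifiers over 20-feature white-blood-cell vectors.

* **MLP** — a 20 x 12 x 10 x 5 multilayer perceptron with logistic hidden
  activations, trained by backpropagation (scikit-learn is the fitting
  engine; inference is a self-contained forward pass over the stored
  weights, so saved models need nothing but this module).
* **RBF-SVM** — a radial-basis-function kernel support vector machine,
  one-vs-one multiclass; inference replays libsvm's pairwise voting over
  the stored support vectors and dual coefficients.
* **HRCNN** — a hyperrectangular composite neural network.  Each hidden
  node j holds per-feature weight pairs (M_ji, m_ji) and fires on input x
  when

      net_j(x) = sum_i f((M_ji - x_i)(x_i - m_ji)) - n  >=  0,
      f(y) = 1 if y >= 0 else 0,

  i.e. exactly when m_ji <= x_i <= M_ji for every feature: the node is an
  axis-aligned box.  The class output Out(x) = f(sum_j Out_j(x) - eta)
  with eta in (0, 1) fires iff at least one box contains x.  Training is
  a sequential covering algorithm that, on consistently labeled data,
  always reaches 100% training accuracy; the learned weights read out as
  crisp If-Then interval rules.

The five class labels are the leukocyte types of a differential count:
lymphocyte, monocyte, basophil, eosinophil, neutrophil.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASS_LABELS", "Hyperrectangle", "HRCNNModel", "TrainedClassifier",
    "hrcnn_hidden", "hrcnn_output", "hrcnn_train", "hrcnn_rules",
    "parse_rules", "mlp_train", "svm_train", "hrcnn_classifier",
    "predict", "evaluate",
    "save_classifier", "load_classifier",
]

CLASS_LABELS = ("lymphocyte", "monocyte", "basophil", "eosinophil", "neutrophil")


# --------------------------------------------------------------------------
# HRCNN
# --------------------------------------------------------------------------

@dataclass
class Hyperrectangle:
    """Axis-aligned box: per-feature lower bounds m and upper bounds M."""

    m: np.ndarray
    M: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=np.float64).ravel()
        self.M = np.asarray(self.M, dtype=np.float64).ravel()
        if self.m.shape != self.M.shape:
            raise ValueError("m and M must have equal length")
        if np.any(self.m > self.M):
            raise ValueError("every lower bound must be <= its upper bound")

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=np.float64).ravel()
        return bool(np.all((self.m <= x) & (x <= self.M)))


@dataclass
class HRCNNModel:
    """Per-class sets of hyperrectangles plus the firing threshold eta.

    ``feature_scaling`` holds per-feature (offset, range) pairs fitted on
    the training data; boxes are stored in original feature units and the
    scaling only normalizes the distance/volume tie-breaks at inference.
    """

    boxes: dict            # class label -> list[Hyperrectangle]
    eta: float = 0.5
    feature_scaling: tuple = None     # (offset array, range array)
    classes: tuple = CLASS_LABELS

    def __post_init__(self):
        if not (0.0 < self.eta < 1.0):
            raise ValueError("eta must lie in (0, 1)")

    @property
    def n_features(self) -> int:
        for bs in self.boxes.values():
            if bs:
                return bs[0].m.size
        return 0


def hrcnn_hidden(x, h: Hyperrectangle) -> int:
    """Output of one hidden node, computed literally from its net input.

    Returns f(net(x)) with net(x) = sum_i f((M_i - x_i)(x_i - m_i)) - n,
    which is 1 exactly when x lies inside the box [m, M].
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size != h.m.size:
        raise ValueError(f"expected {h.m.size} features, got {x.size}")
    terms = (h.M - x) * (x - h.m)
    net = np.count_nonzero(terms >= 0) - x.size
    return 1 if net >= 0 else 0


def hrcnn_output(x, model: HRCNNModel, cls) -> int:
    """Class-network output: 1 iff sum of hidden outputs exceeds eta.

    Since hidden outputs are binary and eta is in (0, 1), this fires iff
    at least one of the class's boxes contains x.
    """
    if cls not in model.boxes:
        raise ValueError(f"unknown class {cls!r}")
    total = sum(hrcnn_hidden(x, h) for h in model.boxes[cls])
    return 1 if total - model.eta >= 0 else 0


def _check_consistent(X: np.ndarray, y: np.ndarray) -> None:
    order = np.lexsort(X.T)
    xs, ys = X[order], y[order]
    same = np.all(xs[1:] == xs[:-1], axis=1)
    if np.any(same & (ys[1:] != ys[:-1])):
        raise ValueError("inconsistent data: identical vectors with different labels")


def hrcnn_train(X, y, eta: float = 0.5, seed=None, shuffle: bool = False) -> HRCNNModel:
    """Train per-class hyperrectangle sets by sequential covering.

    For each class the training points are visited in input order (or a
    seed-controlled shuffle).  A point already inside one of the class's
    boxes is skipped; otherwise each existing box is tried in turn for a
    minimal expansion to include the point, accepted iff the expanded box
    contains no point of any other class; if no expansion is admissible a
    new degenerate box is started at the point.  Every training point
    ends up covered by a box of its own class and no box ever contains an
    opposite-class point, so training accuracy on consistent data is
    always 100%.

    Raises
    ------
    ValueError
        If identical vectors carry different labels.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (N, n) with one label per row")
    _check_consistent(X, y)

    classes = tuple(dict.fromkeys(y.tolist()))      # first-appearance order
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_span = np.where(hi > lo, hi - lo, 1.0)

    boxes: dict = {c: [] for c in classes}
    rng = np.random.default_rng(seed)
    for c in classes:
        idx = np.flatnonzero(y == c)
        if shuffle:
            idx = rng.permutation(idx)
        others = X[y != c]
        for i in idx:
            p = X[i]
            if any(b.contains(p) for b in boxes[c]):
                continue
            placed = False
            for b in boxes[c]:
                new_m = np.minimum(b.m, p)
                new_M = np.maximum(b.M, p)
                if others.size:
                    inside = np.all((others >= new_m) & (others <= new_M), axis=1)
                    if inside.any():
                        continue
                b.m, b.M = new_m, new_M
                placed = True
                break
            if not placed:
                boxes[c].append(Hyperrectangle(m=p.copy(), M=p.copy()))
    return HRCNNModel(boxes=boxes, eta=eta, feature_scaling=(lo, rng_span),
                      classes=classes)


def _hrcnn_predict_one(model: HRCNNModel, x: np.ndarray):
    x = np.asarray(x, dtype=np.float64).ravel()
    off, span = (model.feature_scaling if model.feature_scaling is not None
                 else (np.zeros(x.size), np.ones(x.size)))
    fired = []          # (class, box) pairs containing x
    for c in model.classes:
        for b in model.boxes.get(c, []):
            if b.contains(x):
                fired.append((c, b))
    if len(fired) == 1:
        return fired[0][0]
    if fired:
        # most specific rule: smallest normalized box volume
        def vol(cb):
            return float(np.prod((cb[1].M - cb[1].m) / span))
        return min(fired, key=vol)[0]
    # nothing fired: nearest box by normalized distance to its surface
    best, best_d = None, np.inf
    for c in model.classes:
        for b in model.boxes.get(c, []):
            gap = np.maximum(np.maximum(b.m - x, x - b.M), 0.0) / span
            d = float(gap @ gap)
            if d < best_d:
                best, best_d = c, d
    return best


def hrcnn_rules(model: HRCNNModel, feature_names=None) -> str:
    """Render the trained boxes as crisp If-Then rules (one per box).

    The interval bounds are the synaptic weight pairs (m_ji, M_ji)
    verbatim, at full precision.  A commented header preserves eta and
    the tie-break scaling so the text round-trips through
    :func:`parse_rules` to a model with identical predictions.
    """
    n = model.n_features
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(n)]
    lines = [f"# HRCNN rules: eta={model.eta!r}"]
    if model.feature_scaling is not None:
        off, span = model.feature_scaling
        lines.append("# scaling-offset: " + json.dumps(list(map(float, off))))
        lines.append("# scaling-range: " + json.dumps(list(map(float, span))))
    lines.append("# features: " + json.dumps(names))
    k = 1
    for c in model.classes:
        for b in model.boxes.get(c, []):
            conds = " AND ".join(
                f"{names[i]} in [{float(b.m[i])!r}, {float(b.M[i])!r}]"
                for i in range(b.m.size))
            lines.append(f"Rule {k}: IF {conds} THEN {c}")
            k += 1
    return "\n".join(lines) + "\n"


_RULE_RE = re.compile(r"^Rule \d+: IF (.+) THEN (\S+)$")
_COND_RE = re.compile(r"\S+ in \[([^,\]]+), ([^\]]+)\]")


def parse_rules(text: str) -> HRCNNModel:
    """Rebuild an HRCNN model from its If-Then rule listing."""
    eta, off, span = 0.5, None, None
    boxes: dict = {}
    order: list = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "eta=" in line:
                eta = float(line.split("eta=")[1])
            elif line.startswith("# scaling-offset:"):
                off = np.array(json.loads(line.split(":", 1)[1]))
            elif line.startswith("# scaling-range:"):
                span = np.array(json.loads(line.split(":", 1)[1]))
            continue
        mobj = _RULE_RE.match(line)
        if not mobj:
            raise ValueError(f"unparseable rule line: {line!r}")
        conds, cls = mobj.groups()
        bounds = _COND_RE.findall(conds)
        m = np.array([float(a) for a, _ in bounds])
        M = np.array([float(b) for _, b in bounds])
        if cls not in boxes:
            boxes[cls] = []
            order.append(cls)
        boxes[cls].append(Hyperrectangle(m=m, M=M))
    scaling = (off, span) if off is not None and span is not None else None
    return HRCNNModel(boxes=boxes, eta=eta, feature_scaling=scaling,
                      classes=tuple(order))


# --------------------------------------------------------------------------
# Trained-classifier wrapper (MLP / SVM / HRCNN)
# --------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A fitted classifier with self-contained inference.

    ``params`` stores plain arrays (weights, support vectors, boxes...)
    so models serialize to JSON and predict without the fitting engine.
    """

    kind: str                       # "mlp" | "svm" | "hrcnn"
    classes: tuple
    params: dict
    scaler: tuple = None            # (mean, std) for z-scored inputs
    training_report: dict = field(default_factory=dict)
    hrcnn: HRCNNModel = None

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.kind == "hrcnn":
            return np.array([_hrcnn_predict_one(self.hrcnn, x) for x in X])
        if self.scaler is not None:
            mean, std = self.scaler
            X = (X - mean) / std
        if self.kind == "mlp":
            return self._predict_mlp(X)
        if self.kind == "svm":
            return self._predict_svm(X)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def _predict_mlp(self, X: np.ndarray) -> np.ndarray:
        a = X
        weights, biases = self.params["weights"], self.params["biases"]
        for W, b in zip(weights[:-1], biases[:-1]):
            a = 1.0 / (1.0 + np.exp(-(a @ W + b)))       # logistic hidden
        out = a @ weights[-1] + biases[-1]
        labels = np.asarray(self.classes, dtype=object)
        if out.shape[1] == 1:                # binary head: single logit
            return labels[(out[:, 0] > 0).astype(int)]
        return labels[np.argmax(out, axis=1)]            # argmax readout

    def _predict_svm(self, X: np.ndarray) -> np.ndarray:
        sv = self.params["support_vectors"]
        dual = self.params["dual_coef"]
        intercept = self.params["intercept"]
        n_support = self.params["n_support"]
        gamma = self.params["gamma"]
        starts = np.concatenate([[0], np.cumsum(n_support)])
        d2 = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-gamma * d2)                          # (N, n_SV)
        nc = len(self.classes)
        labels = np.asarray(self.classes, dtype=object)
        if nc == 2:
            # scikit-learn flips the stored binary decision: positive
            # values map onto classes_[1]
            dec = K @ dual[0] + intercept[0]
            return labels[(dec > 0).astype(int)]
        votes = np.zeros((X.shape[0], nc), dtype=int)
        p = 0
        for i in range(nc):
            for j in range(i + 1, nc):
                si, sj = slice(starts[i], starts[i + 1]), slice(starts[j], starts[j + 1])
                dec = (K[:, si] @ dual[j - 1, si] + K[:, sj] @ dual[i, sj]
                       + intercept[p])
                votes[:, i] += dec > 0
                votes[:, j] += dec <= 0
                p += 1
        return labels[np.argmax(votes, axis=1)]


def _class_report(y_true, y_pred) -> dict:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    per_class = {}
    for c in dict.fromkeys(y_true.tolist()):
        sel = y_true == c
        per_class[str(c)] = float(np.mean(y_pred[sel] == c))
    return {"overall": float(np.mean(y_pred == y_true)), "per_class": per_class}


def mlp_train(X, y, seed: int = 0, epochs: int = 400,
              learning_rate: float = 1e-2) -> TrainedClassifier:
    """Backpropagation-train the 20 x 12 x 10 x 5 perceptron.

    Inputs are z-scored on the training data; hidden layers use logistic
    activations; training runs for at most ``epochs`` passes.  With a
    fixed seed the fitted weights, and hence all predictions, are
    deterministic.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPClassifier

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("MLP training needs at least two classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std
    net = MLPClassifier(hidden_layer_sizes=(12, 10), activation="logistic",
                        solver="adam", learning_rate_init=learning_rate,
                        max_iter=epochs, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Xs, y)
    clf = TrainedClassifier(
        kind="mlp", classes=tuple(net.classes_.tolist()),
        params={"weights": [w.copy() for w in net.coefs_],
                "biases": [b.copy() for b in net.intercepts_]},
        scaler=(mean, std))
    clf.training_report = _class_report(y, clf.predict(X))
    return clf


def svm_train(X, y, kernel_gamma="scale", C: float = 10.0,
              seed: int = 0) -> TrainedClassifier:
    """Fit a one-vs-one RBF-kernel support vector machine.

    The number of radial basis functions and their centers follow from
    the fitted support vectors.  Inputs are z-scored on the training
    data; the stored model reports its support-vector count.
    """
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("SVM training needs at least two classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std
    svc = SVC(kernel="rbf", gamma=kernel_gamma, C=C, random_state=seed)
    svc.fit(Xs, y)
    clf = TrainedClassifier(
        kind="svm", classes=tuple(svc.classes_.tolist()),
        params={"support_vectors": svc.support_vectors_.copy(),
                "dual_coef": svc.dual_coef_.copy(),
                "intercept": svc.intercept_.copy(),
                "n_support": svc.n_support_.copy(),
                "support_indices": svc.support_.copy(),
                "gamma": float(svc._gamma)},
        scaler=(mean, std))
    clf.training_report = _class_report(y, clf.predict(X))
    clf.training_report["n_support_vectors"] = int(svc.n_support_.sum())
    return clf


def hrcnn_classifier(model: HRCNNModel, X=None, y=None) -> TrainedClassifier:
    """Wrap an HRCNN model in the common classifier interface."""
    clf = TrainedClassifier(kind="hrcnn", classes=tuple(model.classes),
                            params={}, hrcnn=model)
    if X is not None and y is not None:
        clf.training_report = _class_report(y, clf.predict(X))
    return clf


def predict(classifier: TrainedClassifier, x):
    """Predict the class label for one 20-feature vector."""
    x = np.asarray(x, dtype=np.float64).ravel()
    return classifier.predict(x[None, :])[0]


def evaluate(classifier: TrainedClassifier, X, y) -> dict:
    """Per-class and overall accuracy of a classifier on labeled data."""
    return _class_report(y, classifier.predict(X))


# --------------------------------------------------------------------------
# JSON serialization
# --------------------------------------------------------------------------

def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def save_classifier(clf: TrainedClassifier, path) -> None:
    """Serialize a trained classifier (any kind) to JSON."""
    doc = {"kind": clf.kind, "classes": list(clf.classes),
           "params": _to_jsonable(clf.params),
           "scaler": _to_jsonable(clf.scaler),
           "training_report": _to_jsonable(clf.training_report)}
    if clf.kind == "hrcnn":
        m = clf.hrcnn
        doc["hrcnn"] = {
            "eta": m.eta,
            "classes": list(m.classes),
            "feature_scaling": _to_jsonable(m.feature_scaling),
            "boxes": {str(c): [[b.m.tolist(), b.M.tolist()]
                               for b in m.boxes[c]] for c in m.classes},
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_classifier(path) -> TrainedClassifier:
    """Load a classifier written by :func:`save_classifier`."""
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc["kind"]
    params = doc.get("params", {})
    if kind == "mlp":
        params = {"weights": [np.array(w) for w in params["weights"]],
                  "biases": [np.array(b) for b in params["biases"]]}
    elif kind == "svm":
        params = {"support_vectors": np.array(params["support_vectors"]),
                  "dual_coef": np.array(params["dual_coef"]),
                  "intercept": np.array(params["intercept"]),
                  "n_support": np.array(params["n_support"], dtype=int),
                  "support_indices": np.array(params.get("support_indices", []),
                                              dtype=int),
                  "gamma": float(params["gamma"])}
    scaler = doc.get("scaler")
    if scaler is not None:
        scaler = (np.array(scaler[0]), np.array(scaler[1]))
    clf = TrainedClassifier(kind=kind, classes=tuple(doc["classes"]),
                            params=params, scaler=scaler,
                            training_report=doc.get("training_report", {}))
    if kind == "hrcnn":
        h = doc["hrcnn"]
        scaling = h.get("feature_scaling")
        if scaling is not None:
            scaling = (np.array(scaling[0]), np.array(scaling[1]))
        boxes = {c: [Hyperrectangle(m=np.array(m), M=np.array(M))
                     for m, M in bs] for c, bs in h["boxes"].items()}
        clf.hrcnn = HRCNNModel(boxes=boxes, eta=h["eta"],
                               feature_scaling=scaling,
                               classes=tuple(h["classes"]))
        clf.scaler = None
    return clf
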