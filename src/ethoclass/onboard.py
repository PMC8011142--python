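"""Compact model export and microcontroller-style prediction engines.

A tracker that classifies behaviour on-board stores only the minimal
parameter structure of a trained model — support vectors, dense weight
matrices, or flat tree-node arrays — and runs prediction with plain
loops over plain arrays. The four engines here (RBF-SVM one-vs-one
voting, dense ANN forward pass, forest tree-traversal voting, boosted
margin summation) depend on nothing but numpy and can be transcribed to
embedded C verbatim; the training backends serve only as the source of
the exported parameters and as the oracle the engines are tested
against.

Conventions shared by all engines: tree traversal goes left when
feature < threshold (strictly; the exporter converts scikit-learn's
``<=`` convention exactly via ``nextafter``), and every tie — SVM
votes, forest votes, ANN/boost argmax — resolves to the alphabetically
first class label.

The module also carries the deployment arithmetic: model storage bytes,
the raw-ACC-to-behaviour-code compression ratio, and how many days of
behaviour fit in a given memory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .io import ValidationError
from .classify import TrainedClassifier

__all__ = [
    "CompactSvm",
    "CompactAnn",
    "CompactForest",
    "CompactBoost",
    "StorageReport",
    "export_compact",
    "predict_compact",
    "predict_compact_svm",
    "predict_compact_ann",
    "predict_compact_forest",
    "predict_compact_boost",
    "model_storage_bytes",
    "compression_ratio",
    "storage_days",
    "save_compact_json",
    "load_compact_json",
]

#: flat tree-node array columns: feature index (-1 for a leaf), threshold
#: (or leaf value/class), left child, right child, leaf payload
_LEAF = -1


def _scale_input(f: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (np.asarray(f, dtype=float) - center) / scale


@dataclass
class CompactSvm:
    """RBF-SVM parameters for one-vs-one on-board voting.

    ``sv`` holds all support vectors in the scaled feature space,
    ``coefs`` the (n_classes-1, n_sv) dual coefficients, ``rho`` one
    intercept per unordered class pair in (0,1), (0,2), ..., (1,2), ...
    order, and ``n_sv`` the per-class support-vector counts.
    """

    sv: np.ndarray
    coefs: np.ndarray
    rho: np.ndarray
    n_sv: np.ndarray
    gamma: float
    x_center: np.ndarray
    x_scale: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.class_labels)
        if int(self.n_sv.sum()) != len(self.sv):
            raise ValidationError("support-vector counts do not sum to rows of sv")
        if len(self.rho) != k * (k - 1) // 2:
            raise ValidationError("need one rho per unordered class pair")

    def to_dict(self) -> dict:
        return {
            "kind": "svm",
            "sv": self.sv.tolist(),
            "coefs": self.coefs.tolist(),
            "rho": self.rho.tolist(),
            "n_sv": self.n_sv.tolist(),
            "gamma": self.gamma,
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "class_labels": list(self.class_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompactSvm":
        return cls(
            sv=np.array(d["sv"], dtype=float),
            coefs=np.array(d["coefs"], dtype=float),
            rho=np.array(d["rho"], dtype=float),
            n_sv=np.array(d["n_sv"], dtype=int),
            gamma=float(d["gamma"]),
            x_center=np.array(d["x_center"], dtype=float),
            x_scale=np.array(d["x_scale"], dtype=float),
            class_labels=tuple(d["class_labels"]),
        )


@dataclass
class CompactAnn:
    """Dense single-hidden-layer network: logistic hidden, softmax output."""

    w1: np.ndarray  # (n_features, size)
    b1: np.ndarray
    w2: np.ndarray  # (size, n_classes)
    b2: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.w1.shape[1] != self.w2.shape[0]:
            raise ValidationError("layer shapes do not chain input→hidden→output")
        if self.w2.shape[1] != len(self.class_labels):
            raise ValidationError("output width must equal the class count")

    def to_dict(self) -> dict:
        return {
            "kind": "ann",
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "class_labels": list(self.class_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompactAnn":
        return cls(
            w1=np.array(d["w1"], dtype=float), b1=np.array(d["b1"], dtype=float),
            w2=np.array(d["w2"], dtype=float), b2=np.array(d["b2"], dtype=float),
            x_center=np.array(d["x_center"], dtype=float),
            x_scale=np.array(d["x_scale"], dtype=float),
            class_labels=tuple(d["class_labels"]),
        )


def _check_tree(nodes: np.ndarray, leaf_payload_classes: int | None) -> None:
    """Structural check: proper binary topology, valid children and leaves."""
    n = len(nodes)
    seen = set()
    stack = [0]
    while stack:
        i = stack.pop()
        if i in seen:
            raise ValidationError(f"cycle through node {i}")
        seen.add(i)
        feat, _, left, right, payload = nodes[i]
        if int(feat) == _LEAF:
            if leaf_payload_classes is not None and not (
                0 <= int(payload) < leaf_payload_classes
            ):
                raise ValidationError(f"leaf node {i} carries invalid class {payload}")
            continue
        for child in (int(left), int(right)):
            if not 0 <= child < n:
                raise ValidationError(f"node {i} has out-of-range child {child}")
            stack.append(child)


@dataclass
class CompactForest:
    """Flat node arrays for tree-traversal majority voting.

    Each tree is an (n_nodes, 5) array of
    (feature, threshold, left, right, leaf_class); internal nodes have
    feature >= 0 and branch left when feature value < threshold.
    """

    trees: list[np.ndarray]
    class_labels: tuple[str, ...]

    @property
    def ntree(self) -> int:
        return len(self.trees)

    def validate(self) -> None:
        for t in self.trees:
            _check_tree(t, len(self.class_labels))

    def to_dict(self) -> dict:
        return {
            "kind": "forest",
            "trees": [t.tolist() for t in self.trees],
            "class_labels": list(self.class_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompactForest":
        return cls(
            trees=[np.array(t, dtype=float) for t in d["trees"]],
            class_labels=tuple(d["class_labels"]),
        )


@dataclass
class CompactBoost:
    """Boosted trees grouped round-major: tree i scores class i mod n_classes.

    Leaves carry additive margin scores; class margins start at
    ``base_margin`` and prediction is the argmax of the summed margins
    (softmax is monotone in the margin, so it is omitted — raw margins
    stay inspectable).
    """

    trees: list[np.ndarray]
    nrounds: int
    class_labels: tuple[str, ...]
    base_margin: float = 0.0

    def __post_init__(self) -> None:
        if len(self.trees) != self.nrounds * len(self.class_labels):
            raise ValidationError(
                f"tree count {len(self.trees)} != nrounds {self.nrounds} x "
                f"{len(self.class_labels)} classes"
            )

    def validate(self) -> None:
        for t in self.trees:
            _check_tree(t, None)

    def to_dict(self) -> dict:
        return {
            "kind": "boost",
            "trees": [t.tolist() for t in self.trees],
            "nrounds": self.nrounds,
            "base_margin": self.base_margin,
            "class_labels": list(self.class_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompactBoost":
        return cls(
            trees=[np.array(t, dtype=float) for t in d["trees"]],
            nrounds=int(d["nrounds"]),
            base_margin=float(d["base_margin"]),
            class_labels=tuple(d["class_labels"]),
        )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_compact(model: TrainedClassifier):
    """Export a trained SVM/ANN/RF/XGBoost model to its compact structure.

    The result is self-contained (feature scaling and class labels
    included) and serialises to auditable JSON. LDA and DT have no
    on-board engine here and are rejected.
    """
    if model.method not in ("svm", "ann", "rf", "xgboost"):
        raise ValidationError(
            f"no compact on-board engine for method {model.method!r}"
        )
    backend = model.backend
    if not hasattr(backend, "classes_"):
        raise ValidationError("model backend looks untrained")
    labels = model.class_labels

    if model.method == "svm":
        center, scale = model.scaler
        return CompactSvm(
            sv=np.array(backend.support_vectors_, dtype=float),
            coefs=np.array(backend.dual_coef_, dtype=float),
            rho=np.array(backend.intercept_, dtype=float),
            n_sv=np.array(backend.n_support_, dtype=int),
            gamma=float(getattr(backend, "_gamma", backend.gamma)),
            x_center=np.array(center, dtype=float),
            x_scale=np.array(scale, dtype=float),
            class_labels=labels,
        )

    if model.method == "ann":
        center, scale = model.scaler
        w1, w2 = backend.coefs_
        b1, b2 = backend.intercepts_
        return CompactAnn(
            w1=np.array(w1, dtype=float), b1=np.array(b1, dtype=float),
            w2=np.array(w2, dtype=float), b2=np.array(b2, dtype=float),
            x_center=np.array(center, dtype=float),
            x_scale=np.array(scale, dtype=float),
            class_labels=labels,
        )

    if model.method == "rf":
        trees = []
        for est in backend.estimators_:
            t = est.tree_
            nodes = np.zeros((t.node_count, 5))
            leaf_cls = t.value.squeeze(1).argmax(axis=1)
            for i in range(t.node_count):
                if t.children_left[i] == -1:
                    nodes[i] = (_LEAF, 0.0, -1, -1, leaf_cls[i])
                else:
                    # sklearn branches left on <=; nextafter makes the
                    # strict-< convention float-exact
                    nodes[i] = (
                        t.feature[i],
                        np.nextafter(t.threshold[i], np.inf),
                        t.children_left[i],
                        t.children_right[i],
                        0.0,
                    )
            trees.append(nodes)
        return CompactForest(trees=trees, class_labels=labels)

    # xgboost: parse the per-tree text dump into flat node arrays
    booster = backend.get_booster()
    dumps = booster.get_dump(dump_format="json")
    cfg = json.loads(booster.save_config())
    base = float(cfg["learner"]["learner_model_param"]["base_score"])
    trees = []
    for d in dumps:
        flat: dict[int, tuple] = {}

        def walk(node: dict) -> None:
            nid = node["nodeid"]
            if "leaf" in node:
                flat[nid] = (_LEAF, 0.0, -1, -1, node["leaf"])
            else:
                flat[nid] = (
                    int(node["split"][1:]),
                    node["split_condition"],  # xgboost already branches left on <
                    node["yes"],
                    node["no"],
                    0.0,
                )
                for child in node["children"]:
                    walk(child)

        walk(json.loads(d))
        nodes = np.zeros((max(flat) + 1, 5))
        for nid, row in flat.items():
            nodes[nid] = row
        trees.append(nodes)
    nrounds = len(dumps) // len(labels)
    return CompactBoost(
        trees=trees, nrounds=nrounds, class_labels=labels, base_margin=base
    )


# ---------------------------------------------------------------------------
# scratch prediction engines
# ---------------------------------------------------------------------------

def _alphabetical_argmax(scores: np.ndarray, labels: tuple[str, ...]) -> str:
    # labels are stored sorted; argmax returns the first (alphabetically
    # first) maximiser
    return labels[int(np.argmax(scores))]


def svm_votes(m: CompactSvm, f: np.ndarray) -> np.ndarray:
    """One-vs-one vote counts per class for a single feature vector."""
    f = np.asarray(f, dtype=float)
    if f.shape != (m.sv.shape[1],):
        raise ValidationError(
            f"feature vector has {f.shape} values, model expects {m.sv.shape[1]}"
        )
    x = _scale_input(f, m.x_center, m.x_scale)
    kern = np.exp(-m.gamma * ((x - m.sv) ** 2).sum(axis=1))
    starts = np.concatenate([[0], np.cumsum(m.n_sv)])
    k = len(m.class_labels)
    votes = np.zeros(k, dtype=int)
    p = 0
    for i in range(k):
        for j in range(i + 1, k):
            dec = (
                kern[starts[i]:starts[i + 1]] @ m.coefs[j - 1, starts[i]:starts[i + 1]]
                + kern[starts[j]:starts[j + 1]] @ m.coefs[i, starts[j]:starts[j + 1]]
                + m.rho[p]
            )
            votes[i if dec > 0 else j] += 1
            p += 1
    return votes


def predict_compact_svm(m: CompactSvm, f: np.ndarray) -> str:
    """RBF-SVM one-vs-one voting; vote ties resolve alphabetically."""
    return _alphabetical_argmax(svm_votes(m, f), m.class_labels)


def ann_softmax(m: CompactAnn, f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (m.w1.shape[0],):
        raise ValidationError(
            f"feature vector has {f.shape} values, model expects {m.w1.shape[0]}"
        )
    x = _scale_input(f, m.x_center, m.x_scale)
    hidden = 1.0 / (1.0 + np.exp(-(x @ m.w1 + m.b1)))
    out = hidden @ m.w2 + m.b2
    e = np.exp(out - out.max())
    return e / e.sum()


def predict_compact_ann(m: CompactAnn, f: np.ndarray) -> str:
    """Dense forward pass: logistic hidden layer, softmax output, argmax."""
    return _alphabetical_argmax(ann_softmax(m, f), m.class_labels)


def _traverse(nodes: np.ndarray, f: np.ndarray) -> float:
    i = 0
    hops = 0
    while True:
        feat, thr, left, right, payload = nodes[i]
        if int(feat) == _LEAF:
            return payload
        if not 0 <= int(feat) < len(f):
            raise ValidationError(f"node references feature {int(feat)} "
                                  f"but only {len(f)} provided")
        # feature values compare in single precision, as a microcontroller
        # (and both training backends) would hold them
        i = int(left) if np.float32(f[int(feat)]) < thr else int(right)
        hops += 1
        if hops > len(nodes):
            raise ValidationError("malformed tree: traversal does not terminate")


def forest_votes(m: CompactForest, f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    votes = np.zeros(len(m.class_labels), dtype=int)
    for tree in m.trees:
        votes[int(_traverse(tree, f))] += 1
    return votes


def predict_compact_forest(m: CompactForest, f: np.ndarray) -> str:
    """Traverse every tree and majority-vote the leaf classes."""
    return _alphabetical_argmax(forest_votes(m, f), m.class_labels)


def boost_margins(m: CompactBoost, f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    k = len(m.class_labels)
    margins = np.full(k, m.base_margin, dtype=float)
    for i, tree in enumerate(m.trees):
        margins[i % k] += _traverse(tree, f)
    return margins


def predict_compact_boost(m: CompactBoost, f: np.ndarray) -> str:
    """Sum each class's leaf scores over all rounds; argmax of the margins."""
    return _alphabetical_argmax(boost_margins(m, f), m.class_labels)


_ENGINES = {
    CompactSvm: predict_compact_svm,
    CompactAnn: predict_compact_ann,
    CompactForest: predict_compact_forest,
    CompactBoost: predict_compact_boost,
}


def predict_compact(m, X: np.ndarray) -> np.ndarray:
    """Run the matching scratch engine over rows of a feature matrix."""
    engine = _ENGINES[type(m)]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([engine(m, row) for row in X], dtype=object)


# ---------------------------------------------------------------------------
# storage and deployment accounting
# ---------------------------------------------------------------------------

@dataclass
class StorageReport:
    """Bytes per model component; ``value_bytes`` is the stored value width."""

    components: dict[str, int]
    value_bytes: int

    @property
    def total_bytes(self) -> int:
        return sum(self.components.values())

    @property
    def total_kb(self) -> float:
        return self.total_bytes / 1000.0


def model_storage_bytes(m, value_bytes: int = 4) -> StorageReport:
    """On-board storage for a compact model.

    SVM storage scales with the support-vector count, ANN with the
    weight count, forest and boost with the total node count (each node
    stores a feature index, a threshold or leaf payload, and two child
    references).
    """
    if isinstance(m, CompactSvm):
        comps = {
            "support_vectors": m.sv.size * value_bytes,
            "coefs": m.coefs.size * value_bytes,
            "rho": m.rho.size * value_bytes,
            "x_scale": (m.x_center.size + m.x_scale.size) * value_bytes,
        }
    elif isinstance(m, CompactAnn):
        comps = {
            "weights": (m.w1.size + m.w2.size) * value_bytes,
            "biases": (m.b1.size + m.b2.size) * value_bytes,
            "x_scale": (m.x_center.size + m.x_scale.size) * value_bytes,
        }
    elif isinstance(m, (CompactForest, CompactBoost)):
        n_nodes = sum(len(t) for t in m.trees)
        comps = {"tree_nodes": n_nodes * 4 * value_bytes}
    else:
        raise ValidationError(f"not a compact model: {type(m).__name__}")
    return StorageReport(components=comps, value_bytes=value_bytes)


def compression_ratio(
    samples_per_bout: int,
    axes: int = 3,
    value_bytes: int = 2,
    label_bytes: int = 1,
) -> float:
    """Raw-ACC-bytes to behaviour-code-bytes compression of on-board classification.

    A 40-record triaxial bout at 2 bytes per value against a 1-byte
    behaviour code compresses 240:1.
    """
    if min(samples_per_bout, axes, value_bytes, label_bytes) <= 0:
        raise ValidationError("all inputs must be positive")
    return float(
        Fraction(samples_per_bout * axes * value_bytes, label_bytes)
    )


def storage_days(
    memory_bytes: int, bout_seconds: float, label_bytes: int = 1
) -> int:
    """Whole days of behaviour codes that fit in ``memory_bytes`` of memory.

    One ``label_bytes`` code is stored per bout, 86400/bout_seconds
    bouts per day (timestamps excluded); 1 MiB at one 3.8-s bout code
    per bout holds 46 days.
    """
    if memory_bytes <= 0 or bout_seconds <= 0 or label_bytes <= 0:
        raise ValidationError("all inputs must be positive")
    per_day = Fraction(label_bytes) * Fraction(86400) / Fraction(str(bout_seconds))
    return math.floor(Fraction(memory_bytes) / per_day)


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

_KINDS = {"svm": CompactSvm, "ann": CompactAnn, "forest": CompactForest,
          "boost": CompactBoost}


def save_compact_json(m, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(m.to_dict(), fh)


def load_compact_json(path: str | Path):
    with open(path) as fh:
        d = json.load(fh)
    return _KINDS[d["kind"]].from_dict(d)
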