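"""The eight ON/OFF classifier configurations and their training.

Four shallow models (CART tree capped at 129 splits with Gini impurity,
quadratic discriminant, linear-kernel SVM, KNN with k = 21 and city-block
distance) and four small dense networks:

=====  ==========================================================
DNN1   BN -> 32 ReLU -> 32 ReLU -> 32 ReLU -> 1 sigmoid (Nadam)
DNN2   BN -> 32 ReLU -> 32 ReLU -> 1 sigmoid           (Nadam)
DNN3   BN -> 32 Tanh -> 32 ReLU -> 1 sigmoid           (Nadam)
DNN4   BN -> 32 ReLU -> 1 sigmoid                      (RMSProp)
=====  ==========================================================

Scale-sensitive shallow models (QD, SVM, KNN) are z-scored with
training-set statistics; the networks rely on their batch-norm input
layer.  All decision functions return a probability-like score in [0, 1]
for the positive class (pre-Levodopa, OFF).  Training uses a stratified
4-fold split, holding out one fold for early stopping / validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._utils import MUSCULAR_FEATURES, derive_rng
from .metrics import POSITIVE
from .nn import BN_EPS, DenseNet, train_dense

FAMILIES = ("tree", "qd", "svm", "knn", "dnn1", "dnn2", "dnn3", "dnn4")

_DNN_TOPOLOGY = {
    "dnn1": (((32, 32, 32), ("relu", "relu", "relu")), "nadam"),
    "dnn2": (((32, 32), ("relu", "relu")), "nadam"),
    "dnn3": (((32, 32), ("tanh", "relu")), "nadam"),
    "dnn4": (((32,), ("relu",)), "rmsprop"),
}


@dataclass
class ModelSpec:
    family: str
    tree_max_splits: int = 129
    knn_k: int = 21
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    n_folds: int = 4
    features: tuple = MUSCULAR_FEATURES

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def is_dnn(self) -> bool:
        return self.family.startswith("dnn")


@dataclass
class TrainedModel:
    spec: ModelSpec
    net: DenseNet | None = None
    sk_model: object = None
    scaler: StandardScaler | None = None
    seed: int | None = None
    history: dict = field(default_factory=dict)

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Probability-like score in [0, 1] for the positive (pre/OFF) class."""
        x = np.asarray(x, dtype=float)
        if self.spec.is_dnn:
            return self.net.forward(x)
        xs = self.scaler.transform(x) if self.scaler is not None else x
        if isinstance(self.sk_model, SVC):
            return expit(self.sk_model.decision_function(xs))
        pos_col = list(self.sk_model.classes_).index(1)
        return self.sk_model.predict_proba(xs)[:, pos_col]


def _labels_to_binary(labels) -> np.ndarray:
    return (np.asarray(labels) == POSITIVE).astype(int)


def train(spec: ModelSpec, table: pd.DataFrame, seed: int) -> TrainedModel:
    """Fit one model configuration on a labelled stride-feature table."""
    missing = [c for c in spec.features if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns {missing}")
    x = table[list(spec.features)].to_numpy(dtype=float)
    y = _labels_to_binary(table["condition"])
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both conditions")
    if spec.family == "knn" and spec.knn_k > len(x):
        raise ValueError(f"k = {spec.knn_k} exceeds {len(x)} training rows")

    if spec.is_dnn:
        (hidden, acts), optimizer = _DNN_TOPOLOGY[spec.family]
        rng = derive_rng(seed, "train", spec.family)
        skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        train_idx, val_idx = next(iter(skf.split(x, y)))
        net = DenseNet.initialized(x.shape[1], hidden, acts, rng)
        history = train_dense(
            net, x[train_idx], y[train_idx], x[val_idx], y[val_idx],
            optimizer=optimizer, lr=spec.lr, batch_size=spec.batch_size,
            max_epochs=spec.max_epochs, patience=spec.patience, rng=rng,
        )
        return TrainedModel(spec=spec, net=net, seed=seed, history=history)

    scaler = None
    xs = x
    if spec.family in ("qd", "svm", "knn"):
        scaler = StandardScaler().fit(x)
        xs = scaler.transform(x)
    rs = int(derive_rng(seed, "train", spec.family).integers(2 ** 31))
    if spec.family == "tree":
        model = DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=spec.tree_max_splits + 1, random_state=rs)
    elif spec.family == "qd":
        model = QuadraticDiscriminantAnalysis(reg_param=1e-6, store_covariance=True)
    elif spec.family == "svm":
        model = SVC(kernel="linear", random_state=rs)
    elif spec.family == "knn":
        model = KNeighborsClassifier(n_neighbors=spec.knn_k, metric="cityblock",
                                     weights="uniform")
    model.fit(xs, y)
    return TrainedModel(spec=spec, sk_model=model, scaler=scaler, seed=seed)


def forward_dense(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Pure forward pass of a dense model: sigmoid(dense chain(batchnorm(x)))."""
    if not model.spec.is_dnn:
        raise ValueError("forward_dense requires a dense NN model")
    return model.net.forward(x)


def predict_table(model: TrainedModel, table: pd.DataFrame,
                  threshold: float = 0.5) -> pd.DataFrame:
    """Per-row scores and hard labels (NN threshold 0.5; shallow native rule)."""
    out = table.copy()
    if len(table) == 0:
        out["score"] = np.array([], dtype=float)
        out["predicted"] = np.array([], dtype=object)
        return out
    x = table[list(model.spec.features)].to_numpy(dtype=float)
    s = model.scores(x)
    out["score"] = s
    if model.spec.is_dnn:
        hard = s >= threshold
    else:
        xs = model.scaler.transform(x) if model.scaler is not None else x
        hard = model.sk_model.predict(xs) == 1
    out["predicted"] = np.where(hard, "pre", "post")
    return out


# ---------------------------------------------------------------------------
# complexity accounting

def complexity(model: TrainedModel) -> dict:
    """Parameter, MACC and memory accounting under a documented convention.

    Dense layer in -> out: in*out multiply-accumulates plus out bias
    accumulates; batch-norm: 2 ops per input (scale and shift after folding
    the statistics); activations are counted separately as non-MACC ops.
    ROM is 4 bytes per parameter (float32); RAM is 4 bytes per slot of the
    widest pair of consecutive activation buffers plus input and output.
    """
    if not model.spec.is_dnn:
        n_params = None
        if model.sk_model is not None and hasattr(model.sk_model, "coef_"):
            n_params = int(model.sk_model.coef_.size) + 1
        return {"family": model.spec.family, "n_params": n_params,
                "counting_convention": "parameter count only for shallow models"}
    net = model.net
    sizes = [net.n_inputs, *net.hidden, 1]
    macc_dense = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
    macc_bn = 2 * net.n_inputs
    act_ops = sum(net.hidden) + 1          # hidden activations + output sigmoid
    n_params = net.n_params()
    live = max(a + b for a, b in zip(sizes[:-1], sizes[1:]))
    return {
        "family": model.spec.family,
        "n_params": n_params,
        "macc_count": macc_dense + macc_bn,
        "macc_dense": macc_dense,
        "macc_batchnorm": macc_bn,
        "activation_ops": act_ops,
        "rom_bytes": 4 * n_params,
        "ram_bytes": 4 * (live + net.n_inputs + 1),
        "counting_convention": "dense in*out + out bias; batch-norm 2/input; "
                               "activations non-MACC",
    }


# ---------------------------------------------------------------------------
# serialization (dense models)

def save_model(model: TrainedModel, path: str | Path) -> None:
    if not model.spec.is_dnn:
        raise ValueError("only dense models serialize to JSON")
    net = model.net
    doc = {
        "family": model.spec.family,
        "features": list(model.spec.features),
        "seed": model.seed,
        "hidden": list(net.hidden),
        "activations": list(net.activations),
        "bn": {
            "gamma": net.gamma.tolist(), "beta": net.beta.tolist(),
            "mean": net.run_mean.tolist(), "var": net.run_var.tolist(),
            "eps": BN_EPS,
        },
        "weights": [w.tolist() for w in net.weights],   # row-major (in, out)
        "biases": [b.tolist() for b in net.biases],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    spec = ModelSpec(family=doc["family"], features=tuple(doc["features"]))
    net = DenseNet(n_inputs=len(doc["features"]), hidden=tuple(doc["hidden"]),
                   activations=tuple(doc["activations"]))
    net.gamma = np.asarray(doc["bn"]["gamma"])
    net.beta = np.asarray(doc["bn"]["beta"])
    net.run_mean = np.asarray(doc["bn"]["mean"])
    net.run_var = np.asarray(doc["bn"]["var"])
    net.weights = [np.asarray(w) for w in doc["weights"]]
    net.biases = [np.asarray(b) for b in doc["biases"]]
    return TrainedModel(spec=spec, net=net, seed=doc.get("seed"))
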