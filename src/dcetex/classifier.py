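"""Voxelwise malignancy classification with a small feedforward network.

Balanced training and verification voxel sets are sampled from a
radiologist (or phantom ground-truth) lesion mask and from surrounding
body tissue.  A one-hidden-layer network (15 tanh units, one linear
output unit) is trained on the per-voxel texture feature vectors by
full-batch gradient descent with momentum, minimizing the mean squared
error against 0/1 labels; the verification set drives early stopping so
the network is not overtrained.  The network output is clipped to
[0, 1] and thresholded to obtain binary malignancy masks; the default
threshold sweep is 39%, 49%, 59%, 69%, 78%, 88% and 98%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ClassifierConfig",
    "TrainingSet",
    "NNModel",
    "build_training_and_verification_sets",
    "train_nn",
    "predict_scores",
    "threshold_scores",
]

DEFAULT_THRESHOLDS = (0.39, 0.49, 0.59, 0.69, 0.78, 0.88, 0.98)


@dataclass
class ClassifierConfig:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    hidden_units: int = 15
    max_epochs: int = 1500
    patience: int = 100
    learning_rate: float = 0.05
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        if np.any(t <= 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")


@dataclass
class TrainingSet:
    """Sampled voxel coordinates with feature vectors and binary labels."""

    coords: np.ndarray   # (n, 3) int
    features: np.ndarray  # (n, F)
    labels: np.ndarray   # (n,) in {0, 1}
    seed: int

    def __post_init__(self) -> None:
        n_pos = int(self.labels.sum())
        if abs(2 * n_pos - self.labels.size) > 1:
            raise ValueError("labels must be balanced to within one voxel")

    def __len__(self) -> int:
        return self.labels.size


def _sample_coords(rng: np.random.Generator, mask: np.ndarray, n: int) -> np.ndarray:
    coords = np.argwhere(mask)
    if coords.shape[0] < n:
        raise ValueError(f"need {n} voxels but mask holds {coords.shape[0]}")
    sel = rng.choice(coords.shape[0], size=n, replace=False)
    return coords[np.sort(sel)]


def _split_half(rng: np.random.Generator, coords: np.ndarray):
    """Random disjoint halves; the first (training) gets the odd voxel."""
    n = coords.shape[0]
    perm = rng.permutation(n)
    n_ver = n // 2
    return coords[perm[n_ver:]], coords[perm[:n_ver]]


def build_training_and_verification_sets(
    lesion_mask: np.ndarray,
    body_mask: np.ndarray,
    validity_mask: np.ndarray,
    feature_stack: np.ndarray,
    seed: int,
    benign_mask: np.ndarray | None = None,
) -> tuple[TrainingSet, TrainingSet]:
    """Balanced, disjoint training and verification voxel sets.

    Half of the lesion-marked voxels are sampled as positives and the
    same number of negatives is drawn from body tissue (within the
    texture validity region, outside the lesion).  The pooled sample is
    split in half into disjoint training and verification sets,
    stratified by label so both sets stay balanced; set sizes differ by
    at most one voxel.  Fully reproducible from ``seed``.

    If ``benign_mask`` is given, half of the benign-marked voxels
    (capped at the positive count) are placed among the negatives with
    target 0, displacing random body voxels.
    """
    lesion = np.asarray(lesion_mask, bool)
    body = np.asarray(body_mask, bool)
    valid = np.asarray(validity_mask, bool)
    rng = np.random.default_rng(seed)

    pos_pool = lesion & body & valid
    L = int(pos_pool.sum())
    if L == 0:
        raise ValueError("lesion mask holds no usable voxels")
    n_pos = (L + 1) // 2
    pos = _sample_coords(rng, pos_pool, n_pos)

    neg_pool = body & valid & ~lesion
    neg_parts = []
    n_body = n_pos
    if benign_mask is not None:
        ben_pool = np.asarray(benign_mask, bool) & neg_pool
        B = int(ben_pool.sum())
        n_ben = min((B + 1) // 2, n_pos)
        if n_ben:
            ben = _sample_coords(rng, ben_pool, n_ben)
            neg_parts.append(ben)
            neg_pool = neg_pool & ~np.asarray(benign_mask, bool)
            n_body -= n_ben
    if n_body:
        neg_parts.append(_sample_coords(rng, neg_pool, n_body))
    neg = np.concatenate(neg_parts) if neg_parts else np.empty((0, 3), int)

    pos_tr, pos_ver = _split_half(rng, pos)
    neg_tr, neg_ver = _split_half(rng, neg)
    # keep |train| - |verify| <= 1 when both classes have an odd count
    if pos.shape[0] % 2 and neg.shape[0] % 2:
        neg_ver = np.concatenate([neg_ver, neg_tr[-1:]])
        neg_tr = neg_tr[:-1]

    def make(coords_pos, coords_neg):
        coords = np.concatenate([coords_pos, coords_neg])
        labels = np.concatenate(
            [np.ones(coords_pos.shape[0]), np.zeros(coords_neg.shape[0])]
        )
        perm = rng.permutation(coords.shape[0])
        coords, labels = coords[perm], labels[perm]
        feats = feature_stack[coords[:, 0], coords[:, 1], coords[:, 2]]
        return TrainingSet(coords, feats, labels, seed)

    return make(pos_tr, neg_tr), make(pos_ver, neg_ver)


@dataclass
class NNModel:
    """One-hidden-layer feedforward regressor with per-feature scaler."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    kept_features: np.ndarray           # indices of non-constant features
    dropped_features: np.ndarray
    history: dict = field(default_factory=dict)  # {"train_mse": [...], "verify_mse": [...]}

    @property
    def input_dim(self) -> int:
        return self.mean.size

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Scores in [0, 1] for (n, F) raw feature rows."""
        X = np.asarray(features, float)
        if X.shape[-1] != self.input_dim:
            raise ValueError(
                f"feature dimension {X.shape[-1]} does not match model ({self.input_dim})"
            )
        Xs = (X[:, self.kept_features] - self.mean[self.kept_features]) / self.sd[
            self.kept_features
        ]
        out = np.tanh(Xs @ self.W1 + self.b1) @ self.W2 + self.b2
        return np.clip(out[:, 0], 0.0, 1.0)

    def to_json(self) -> str:
        payload = {
            k: np.asarray(getattr(self, k)).tolist()
            for k in ("W1", "b1", "W2", "b2", "mean", "sd", "kept_features", "dropped_features")
        }
        payload["history"] = {k: list(map(float, v)) for k, v in self.history.items()}
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "NNModel":
        d = json.loads(text)
        arrays = {
            k: np.asarray(d[k]) for k in ("W1", "b1", "W2", "b2", "mean", "sd")
        }
        return cls(
            **arrays,
            kept_features=np.asarray(d["kept_features"], int),
            dropped_features=np.asarray(d["dropped_features"], int),
            history=d.get("history", {}),
        )


def _check_finite(X: np.ndarray, feature_names=None) -> None:
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        j = int(bad[0, 1])
        name = feature_names[j] if feature_names is not None else f"feature {j}"
        raise ValueError(f"non-finite value in {name}")


def train_nn(
    train: TrainingSet,
    verify: TrainingSet,
    config: ClassifierConfig | None = None,
    feature_names=None,
) -> NNModel:
    """Train the network, early-stopping on the verification MSE.

    Features are z-scored with training-set statistics (zero-variance
    features are dropped and recorded).  Full-batch gradient descent
    with momentum minimizes the MSE; when the verification MSE has not
    improved for ``patience`` epochs training stops and the
    best-verification weights are restored.  Deterministic per seed.
    """
    config = config or ClassifierConfig()
    if len(train) == 0 or len(verify) == 0:
        raise ValueError("training and verification sets must be non-empty")
    X, y = np.asarray(train.features, float), train.labels.astype(float)
    Xv, yv = np.asarray(verify.features, float), verify.labels.astype(float)
    _check_finite(X, feature_names)
    _check_finite(Xv, feature_names)

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    dropped = np.flatnonzero(sd == 0)
    sd_safe = np.where(sd > 0, sd, 1.0)

    Xs = (X[:, kept] - mean[kept]) / sd_safe[kept]
    Xvs = (Xv[:, kept] - mean[kept]) / sd_safe[kept]
    n, F = Xs.shape
    H = config.hidden_units
    rng = np.random.default_rng(config.seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(F), (F, H))
    b1 = np.zeros(H)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(H), (H, 1))
    b2 = np.zeros(1)
    vel = [np.zeros_like(p) for p in (W1, b1, W2, b2)]

    y2 = y[:, None]
    best = None
    best_mse = np.inf
    since_best = 0
    hist_tr, hist_ver = [], []
    for _ in range(config.max_epochs):
        a1 = np.tanh(Xs @ W1 + b1)
        out = a1 @ W2 + b2
        err = out - y2
        hist_tr.append(float(np.mean(err**2)))

        g_out = 2.0 * err / n
        gW2 = a1.T @ g_out
        gb2 = g_out.sum(axis=0)
        g_a1 = g_out @ W2.T * (1.0 - a1**2)
        gW1 = Xs.T @ g_a1
        gb1 = g_a1.sum(axis=0)
        params = [W1, b1, W2, b2]
        for p, v, g in zip(params, vel, (gW1, gb1, gW2, gb2)):
            v *= config.momentum
            v -= config.learning_rate * g
            p += v

        ver_out = np.tanh(Xvs @ W1 + b1) @ W2 + b2
        ver_mse = float(np.mean((ver_out[:, 0] - yv) ** 2))
        hist_ver.append(ver_mse)
        if ver_mse < best_mse - 1e-12:
            best_mse = ver_mse
            best = [p.copy() for p in (W1, b1, W2, b2)]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    W1, b1, W2, b2 = best if best is not None else (W1, b1, W2, b2)
    return NNModel(
        W1, b1, W2, b2, mean, sd_safe, kept, dropped,
        history={"train_mse": hist_tr, "verify_mse": hist_ver},
    )


def predict_scores(
    model: NNModel,
    feature_stack: np.ndarray,
    body_mask: np.ndarray,
    validity_mask: np.ndarray,
) -> np.ndarray:
    """Voxelwise malignancy scores in [0, 1]; 0 outside body & validity."""
    body = np.asarray(body_mask, bool)
    valid = np.asarray(validity_mask, bool)
    scores = np.zeros(body.shape)
    eval_mask = body & valid
    feats = feature_stack[eval_mask]
    if feats.size:
        scores[eval_mask] = model.forward(feats)
    return scores


def threshold_scores(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binary malignancy mask: score >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(scores) >= threshold
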