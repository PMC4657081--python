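"""Cost-sensitive boosting with balanced undersampling.

The trainer builds T base classifiers M_1 ... M_T, each fit on exactly k
positives and k negatives (k = positive-class size), so no base learner
ever sees the class imbalance.  Sample weights start at C_P/|V| for
positives and C_N/|V| for negatives with C_P >= C_N, biasing the ensemble
toward recovering real pre-miRNAs.  Each iteration:

1. M_t classifies the full sample set V; its error rate is
   phi_t = 1 - G_m(M_t on V), clamped into (0, 0.5).
2. theta_t = phi_t / (1 - phi_t); correctly classified samples have their
   weight multiplied by theta_t (< 1) while misclassified samples keep
   theirs, so weight accumulates on hard samples.  Weights are then
   renormalized to constant total mass (selection probabilities are
   scale-free, and unnormalized weights underflow over hundreds of
   iterations).
3. The next balanced subset takes all k positives plus k negatives drawn
   without replacement proportionally to current weights, and M_{t+1} is
   fit on it with the current weights passed as per-sample importance.

Prediction is a weighted vote: instance t contributes log(1/theta_t), so
low-error instances dominate; a sample is called positive when the
positive vote mass reaches half the total (ties resolve positive,
consistent with the cost asymmetry).
"""

from __future__ import annotations

import base64
import hashlib
import json
import logging
import math
import pickle
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

from .errors import BalanceContractError, DimensionError, LabelError
from .metrics import confusion, g_mean, se_sp
from .resampling import select_initial_negatives, select_negatives_by_weight
from .similarity import MinMaxParams

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

#: Default base learner: RBF-kernel SVM with unit regularization.  The
#: kernel width uses the variance-aware 1/(n Var(X)) heuristic: features
#: are min-max compressed into [0,1] before fitting, where a plain 1/n
#: width leaves the kernel nearly constant across the data.
DEFAULT_BASE_LEARNER_PARAMS: Dict[str, object] = {
    "C": 1.0,
    "kernel": "rbf",
    "gamma": "scale",
}


@dataclass
class TrainingConfig:
    """Knobs of the boosting trainer.

    C_P / C_N are the misclassification costs seeding the initial weights
    (defaults 1 and 0.6); T is the number of boosting iterations (default
    300); phi_epsilon clamps the per-instance error rate away from the
    degenerate ends of theta = phi/(1-phi).  ``use_sample_weights``
    controls whether current weights also enter the base-learner fit as
    per-sample importance (they always drive negative selection).
    """

    C_P: float = 1.0
    C_N: float = 0.6
    T: int = 300
    phi_epsilon: float = 1e-6
    base_learner_params: Dict[str, object] = field(
        default_factory=lambda: dict(DEFAULT_BASE_LEARNER_PARAMS)
    )
    use_sample_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (self.C_P >= self.C_N > 0):
            raise ValueError(f"require C_P >= C_N > 0, got {self.C_P}, {self.C_N}")
        if self.T < 1:
            raise ValueError(f"require T >= 1, got {self.T}")
        if not (0 < self.phi_epsilon < 0.5):
            raise ValueError(f"phi_epsilon must lie in (0, 0.5)")

    def to_dict(self) -> dict:
        return {
            "C_P": self.C_P, "C_N": self.C_N, "T": self.T,
            "phi_epsilon": self.phi_epsilon,
            "base_learner_params": self.base_learner_params,
            "use_sample_weights": self.use_sample_weights,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        return cls(**d)


@dataclass
class WeightedSampleSet:
    """Feature matrix with binary labels (1 = real pre-miRNA) and
    optional evolving per-sample weights."""

    features: np.ndarray
    labels: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise DimensionError("features must be a 2-D matrix")
        if self.labels.shape[0] != self.features.shape[0]:
            raise LabelError(
                f"{self.labels.shape[0]} labels for {self.features.shape[0]} rows"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise LabelError("labels must be 0/1")
        self.labels = self.labels.astype(int)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape[0] != self.labels.shape[0]:
                raise DimensionError("weights length mismatch")
            if (self.weights <= 0).any():
                raise ValueError("weights must be strictly positive")

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == 0).sum())


@dataclass
class BaseInstance:
    """One trained balanced classifier with its boosting bookkeeping."""

    learner: object  # fit/predict contract
    phi: float
    theta: float
    vote_weight: float
    training_indices: List[int]


def init_weights(labels: Sequence[int], C_P: float, C_N: float) -> np.ndarray:
    """Initial weights: C_P/|V| per positive, C_N/|V| per negative."""
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise LabelError("labels must be 0/1")
    n = y.shape[0]
    if n < 2 or (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise LabelError("need at least one sample of each class")
    return np.where(y == 1, C_P / n, C_N / n).astype(float)


def error_rate(
    learner, X: np.ndarray, y: Sequence[int], phi_epsilon: float = 1e-6
) -> float:
    """phi_t = 1 - G_m of the instance over the full sample set, clamped
    into [phi_epsilon, 0.5 - phi_epsilon]."""
    phi, _ = _error_stats(learner, X, np.asarray(y), phi_epsilon)
    return phi


def _error_stats(
    learner, X: np.ndarray, y: np.ndarray, phi_epsilon: float
) -> Tuple[float, dict]:
    pred = np.asarray(learner.predict(X)).astype(int)
    se, sp = se_sp(confusion(y, pred))
    gm = g_mean(se, sp)
    phi = min(max(1.0 - gm, phi_epsilon), 0.5 - phi_epsilon)
    return phi, {"SE": se, "SP": sp, "Gm": gm, "pred": pred}


def theta_from_phi(phi: float) -> float:
    """theta = phi / (1 - phi); caller must clamp phi into (0, 0.5) first."""
    if not (0.0 < phi < 0.5):
        raise ValueError(f"phi={phi} outside (0, 0.5); clamp before calling")
    return phi / (1.0 - phi)


def update_weights(
    weights: np.ndarray,
    y_true: Sequence[int],
    y_pred: Sequence[int],
    theta: float,
) -> np.ndarray:
    """w_i <- w_i * theta^(1 - |p(x_i) - y_i|), then renormalize.

    Correct samples shrink by the factor theta < 1; misclassified samples
    are untouched before renormalization, so weight concentrates on them.
    Renormalization preserves the total mass (a numerical safeguard;
    relative weights, hence selection probabilities, are unaffected).
    """
    w = np.asarray(weights, dtype=float)
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if not (w.shape == yt.shape == yp.shape):
        raise DimensionError("weights/labels/predictions lengths differ")
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta={theta} outside (0, 1)")
    updated = np.where(yt == yp, w * theta, w)
    return updated * (w.sum() / updated.sum())


def make_base_learner(params: Dict[str, object], seed: int) -> SVC:
    return SVC(random_state=seed, **params)


def train_instance(
    features: np.ndarray,
    labels: Sequence[int],
    sample_weights: Optional[np.ndarray],
    params: Dict[str, object],
    seed: int,
    learner_factory: Optional[Callable[[Dict[str, object], int], object]] = None,
):
    """Fit one balanced base classifier; the balance contract is enforced."""
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos != n_neg or n_pos == 0:
        raise BalanceContractError(
            f"base learner requires k positives and k negatives, "
            f"got {n_pos} vs {n_neg}"
        )
    factory = learner_factory or make_base_learner
    learner = factory(params, seed)
    if sample_weights is not None:
        w = np.asarray(sample_weights, dtype=float)
        # rescale to mean 1: relative importance is what matters, and the
        # absolute scale would otherwise multiply into the SVM's C
        learner.fit(features, y, sample_weight=w * (w.shape[0] / w.sum()))
    else:
        learner.fit(features, y)
    return learner


@dataclass
class EnsembleModel:
    """The deployable classifier: T weighted-vote base instances plus the
    scaling learned on the training features."""

    instances: List[BaseInstance]
    config: TrainingConfig
    scaler: MinMaxParams
    feature_names: List[str]
    training_log: List[dict] = field(default_factory=list)

    def predict(self, features: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Labels and normalized positive-vote scores for a raw feature
        matrix (scaling is applied internally)."""
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise DimensionError(
                f"expected (*, {len(self.feature_names)}) features, got {X.shape}"
            )
        Xs = self.scaler.transform(X)
        total = sum(inst.vote_weight for inst in self.instances)
        pos_mass = np.zeros(X.shape[0])
        for inst in self.instances:
            pred = np.asarray(inst.learner.predict(Xs)).astype(int)
            pos_mass += inst.vote_weight * (pred == 1)
        scores = pos_mass / total
        labels = (pos_mass >= total / 2.0).astype(int)  # tie -> positive
        return labels, scores

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "scaler": self.scaler.to_dict(),
            "feature_names": self.feature_names,
            "instances": [
                {
                    "phi": inst.phi,
                    "theta": inst.theta,
                    "vote_weight": inst.vote_weight,
                    "training_indices": inst.training_indices,
                    "learner": base64.b64encode(
                        pickle.dumps(inst.learner)
                    ).decode("ascii"),
                }
                for inst in self.instances
            ],
            "training_log": self.training_log,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {d.get('schema_version')!r}")
        return cls(
            instances=[
                BaseInstance(
                    learner=pickle.loads(base64.b64decode(e["learner"])),
                    phi=e["phi"],
                    theta=e["theta"],
                    vote_weight=e["vote_weight"],
                    training_indices=list(e["training_indices"]),
                )
                for e in d["instances"]
            ],
            config=TrainingConfig.from_dict(d["config"]),
            scaler=MinMaxParams.from_dict(d["scaler"]),
            feature_names=list(d["feature_names"]),
            training_log=list(d.get("training_log", [])),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _indices_digest(indices: Sequence[int]) -> str:
    return hashlib.sha256(
        ",".join(str(i) for i in indices).encode()
    ).hexdigest()[:16]


def train_ensemble(
    data: WeightedSampleSet,
    config: TrainingConfig,
    feature_names: Optional[List[str]] = None,
    learner_factory: Optional[Callable[[Dict[str, object], int], object]] = None,
) -> EnsembleModel:
    """Run the full boosting loop and return the trained ensemble.

    ``data.features`` is raw (unscaled); min-max scaling is fit here and
    stored in the model.  The per-iteration log records phi_t, theta_t,
    the vote weight, SE/SP/G_m of M_t on V and a digest of the balanced
    subset used to train M_t.
    """
    y = data.labels
    n_pos, n_neg = data.n_pos, data.n_neg
    if n_pos == 0 or n_neg == 0:
        raise LabelError("both classes must be present")
    if n_neg < n_pos:
        logger.warning(
            "fewer negatives (%d) than positives (%d); the method targets "
            "majority-negative imbalance", n_neg, n_pos
        )
    names = feature_names or [f"f{i}" for i in range(data.features.shape[1])]
    scaler = MinMaxParams.fit(data.features)
    Xs = scaler.transform(data.features)
    pos_idx = np.where(y == 1)[0]
    neg_idx = np.where(y == 0)[0]
    k = n_pos

    weights = init_weights(y, config.C_P, config.C_N)

    def seed_at(t: int) -> int:
        return (config.seed + t) % (2**31)

    sel = select_initial_negatives(Xs[neg_idx], k, seed_at(0))
    train_idx = np.concatenate([pos_idx, neg_idx[sel.indices]])
    learner = train_instance(
        Xs[train_idx], y[train_idx],
        weights[train_idx] if config.use_sample_weights else None,
        config.base_learner_params, seed_at(0), learner_factory,
    )

    instances: List[BaseInstance] = []
    log: List[dict] = []
    for t in range(1, config.T + 1):
        phi, stats = _error_stats(learner, Xs, y, config.phi_epsilon)
        theta = theta_from_phi(phi)
        vote_weight = math.log(1.0 / theta)
        instances.append(
            BaseInstance(learner, phi, theta, vote_weight,
                         [int(i) for i in train_idx])
        )
        log.append({
            "t": t, "phi": phi, "theta": theta, "vote_weight": vote_weight,
            "SE": stats["SE"], "SP": stats["SP"], "Gm": stats["Gm"],
            "indices_digest": _indices_digest(train_idx),
        })
        logger.info(
            "iteration %d: phi=%.4f theta=%.4f Gm=%.4f", t, phi, theta,
            stats["Gm"],
        )
        if t == config.T:
            break
        weights = update_weights(weights, y, stats["pred"], theta)
        sel = select_negatives_by_weight(weights[neg_idx], k, seed_at(t))
        train_idx = np.concatenate([pos_idx, neg_idx[sel.indices]])
        learner = train_instance(
            Xs[train_idx], y[train_idx],
            weights[train_idx] if config.use_sample_weights else None,
            config.base_learner_params, seed_at(t), learner_factory,
        )

    return EnsembleModel(
        instances=instances,
        config=config,
        scaler=scaler,
        feature_names=names,
        training_log=log,
    )
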