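"""Merging stretches into LTR candidates with a linear classifier.

Each pair of consecutive same-direction stretches is described by 10
features (sizes, gap, height difference, repeat-score statistics of the
stretches and the gap, and a same-repetitive-region flag).  A linear
model trained by stochastic gradient descent decides whether the pair
fuses; chains of accepted pairs fuse transitively.  Single stretches that
merge with nothing still become candidates; anything shorter than 200 bp
(the minimum LTR size) is discarded.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import RandomizedSearchCV

from .intervals import Interval
from .merger import Stretch
from .repeat_profile import RepeatProfile

MIN_CANDIDATE_LENGTH = 200
N_FEATURES = 10


@dataclass
class LtrCandidate:
    """A proposed single LTR: hull of one or more fused stretches."""

    interval: Interval
    direction: str
    height: float
    stretches: List[Stretch] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.interval)


def featurize(first: Stretch, second: Stretch, profile: RepeatProfile, sequence_id: str) -> np.ndarray:
    """The 10 features of a consecutive stretch pair, in order."""
    if second.interval.start < first.interval.end:
        raise ValueError("stretches overlap")
    if first.direction != second.direction:
        raise ValueError("stretch pair must share a direction")
    red = profile.score_vector(sequence_id)

    def window(iv: Interval) -> np.ndarray:
        return red[min(iv.start, red.size) : min(iv.end, red.size)]

    def nz_median(v: np.ndarray) -> float:
        nz = v[v > 0]
        return float(np.median(nz)) if nz.size else 0.0

    w1, w2 = window(first.interval), window(second.interval)
    gap_iv = Interval(first.interval.end, second.interval.start)
    wg = window(gap_iv)
    regions = profile.regions[sequence_id]
    same_region = 0.0
    for r in regions:
        if r.overlaps(first.interval) and r.overlaps(second.interval):
            same_region = 1.0
            break
    return np.array(
        [
            first.size,
            second.size,
            len(gap_iv),
            abs(first.height - second.height),
            abs(nz_median(w1) - nz_median(w2)),
            abs(float(w1.mean() if w1.size else 0.0) - float(w2.mean() if w2.size else 0.0)),
            float(w1.mean()) if w1.size else 0.0,
            float(w2.mean()) if w2.size else 0.0,
            float(wg.mean()) if wg.size else 0.0,
            same_region,
        ],
        dtype=np.float64,
    )


@dataclass
class MergeModel:
    """Linear decision rule with the standardization constants baked in.

    f10 is binary and never standardized.
    """

    weights: np.ndarray  # shape (10,)
    bias: float
    feature_means: np.ndarray  # shape (9,)
    feature_sds: np.ndarray  # shape (9,)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.feature_means = np.asarray(self.feature_means, dtype=np.float64)
        self.feature_sds = np.asarray(self.feature_sds, dtype=np.float64)
        if self.weights.shape != (N_FEATURES,):
            raise ValueError("expected exactly 10 weights")
        if self.feature_means.shape != (9,) or self.feature_sds.shape != (9,):
            raise ValueError("standardization constants cover f1..f9 only")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        z = x.copy()
        sds = np.where(self.feature_sds > 0, self.feature_sds, 1.0)
        z[:, :9] = (x[:, :9] - self.feature_means) / sds
        return z

    def decision(self, x: np.ndarray) -> np.ndarray:
        return self.standardize(x) @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.decision(x) > 0.0

    def accepts(self, features: np.ndarray) -> bool:
        return bool(self.predict(features)[0])

    def save(self, path: str) -> None:
        payload = {
            "format": "ltrscout-merge-model",
            "version": 1,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "MergeModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "ltrscout-merge-model":
            raise ValueError(f"{path} is not a merge-model file")
        return cls(
            weights=np.array(payload["weights"]),
            bias=float(payload["bias"]),
            feature_means=np.array(payload["feature_means"]),
            feature_sds=np.array(payload["feature_sds"]),
            metadata=payload.get("metadata", {}),
        )


def constant_model(accept: bool) -> MergeModel:
    """Degenerate model that accepts or rejects every pair (testing aid)."""
    bias = 1.0 if accept else -1.0
    return MergeModel(
        weights=np.zeros(N_FEATURES),
        bias=bias,
        feature_means=np.zeros(9),
        feature_sds=np.ones(9),
        metadata={"constant": accept},
    )


def train_model(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_search_iterations: int = 40,
) -> Tuple[MergeModel, Dict[str, float]]:
    """Train the pair-merge classifier.

    70/20/10 train/validation/test split; f1..f9 standardized with
    training-set statistics; SGD hyperparameters found by random search
    with 10-fold cross validation; the model with the best validation F1
    is kept, test metrics are reported, and the final model is refit on
    the entire (re-standardized) dataset.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ValueError("features must be (n, 10)")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(seed)
    n = features.shape[0]
    order = rng.permutation(n)
    n_train = int(0.7 * n)
    n_val = int(0.2 * n)
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]

    means = features[idx_train, :9].mean(axis=0)
    sds = features[idx_train, :9].std(axis=0)
    scaler = MergeModel(np.zeros(N_FEATURES), 0.0, means, sds)
    z_train = scaler.standardize(features[idx_train])
    z_val = scaler.standardize(features[idx_val])
    z_test = scaler.standardize(features[idx_test])

    param_space = {
        "loss": ["hinge", "log_loss"],
        "alpha": np.logspace(-6, -1, 30),
        "penalty": ["l2", "l1", "elasticnet"],
        "class_weight": [None, "balanced"],
    }
    search = RandomizedSearchCV(
        SGDClassifier(max_iter=2000, tol=1e-4, random_state=int(seed) & 0x7FFFFFFF),
        param_space,
        n_iter=n_search_iterations,
        cv=10,
        scoring="f1",
        random_state=int(seed) & 0x7FFFFFFF,
        n_jobs=1,
    )
    search.fit(z_train, labels[idx_train])

    # keep the candidate with the best validation F1 (re-fitting the top
    # parameter settings found by the search)
    ranked = np.argsort(-np.asarray(search.cv_results_["mean_test_score"]))
    best_clf, best_val_f1 = None, -1.0
    for r in ranked[:5]:
        params = search.cv_results_["params"][r]
        clf = SGDClassifier(
            max_iter=2000, tol=1e-4, random_state=int(seed) & 0x7FFFFFFF, **params
        )
        clf.fit(z_train, labels[idx_train])
        val_f1 = f1_score(labels[idx_val], clf.predict(z_val)) if idx_val.size else 0.0
        if val_f1 > best_val_f1:
            best_clf, best_val_f1 = clf, val_f1

    pred_test = best_clf.predict(z_test) if idx_test.size else np.empty(0, dtype=int)
    metrics = {
        "validation_f1": float(best_val_f1),
        "test_recall": float(recall_score(labels[idx_test], pred_test)) if idx_test.size else float("nan"),
        "test_precision": float(precision_score(labels[idx_test], pred_test, zero_division=0)) if idx_test.size else float("nan"),
        "test_f1": float(f1_score(labels[idx_test], pred_test)) if idx_test.size else float("nan"),
    }

    # final refit on the entire dataset with rescaled statistics
    means_all = features[:, :9].mean(axis=0)
    sds_all = features[:, :9].std(axis=0)
    scaler_all = MergeModel(np.zeros(N_FEATURES), 0.0, means_all, sds_all)
    final_params = {k: best_clf.get_params()[k] for k in param_space}
    final = SGDClassifier(max_iter=2000, tol=1e-4, random_state=int(seed) & 0x7FFFFFFF, **final_params)
    final.fit(scaler_all.standardize(features), labels)

    model = MergeModel(
        weights=final.coef_.ravel(),
        bias=float(final.intercept_[0]),
        feature_means=means_all,
        feature_sds=sds_all,
        metadata={"params": {k: (v if not isinstance(v, np.floating) else float(v)) for k, v in final_params.items()}, "metrics": metrics, "n_examples": int(n)},
    )
    return model, metrics


MAX_MERGE_GAP = 300  # a within-LTR gap is tiny (mean 16.3 bp); pairs further
# apart than this cannot belong to one LTR regardless of the model's vote


def assemble_candidates(
    stretches: Sequence[Stretch],
    model: MergeModel,
    profile: RepeatProfile,
    sequence_id: str,
    max_merge_gap: int = MAX_MERGE_GAP,
) -> List[LtrCandidate]:
    """Chain-merge consecutive stretch pairs the model accepts.

    Transitive: if (s1,s2) and (s2,s3) are both accepted all three fuse.
    Candidates shorter than 200 bp are discarded.
    """
    stretches = sorted(stretches, key=lambda s: s.interval.start)
    out: List[LtrCandidate] = []
    group: List[Stretch] = []

    def flush() -> None:
        if not group:
            return
        iv = group[0].interval
        pooled = [s.pooled for s in group]
        for s in group[1:]:
            iv = iv.hull(s.interval)
        scores = np.concatenate(pooled)
        cand = LtrCandidate(
            interval=iv,
            direction=group[0].direction,
            height=float(np.median(scores[scores > 0])) if np.any(scores > 0) else 0.0,
            stretches=list(group),
        )
        if cand.size >= MIN_CANDIDATE_LENGTH:
            out.append(cand)

    for s in stretches:
        if (
            group
            and s.interval.start - group[-1].interval.end <= max_merge_gap
            and model.accepts(featurize(group[-1], s, profile, sequence_id))
        ):
            group.append(s)
        else:
            flush()
            group = [s]
    flush()
    return out
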