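"""Gradient-boosted classification of the 15-feature table and exact Shapley
attribution.

The classifier is an XGBoost binary model (thalassemic = positive class)
evaluated with sensitivity, specificity, accuracy, F1 and a rank-statistic
AUC.  Attribution uses exact Shapley values of the interventional marginal
expectation: the value of a coalition S is the mean model output over a
background sample with the instance's values spliced in on S.  With 15
features the 2^15 = 32768 coalitions are enumerated outright, so no sampling
approximation is involved; attributions are in the model's margin (log-odds)
units and satisfy the efficiency axiom exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import rankdata

from .errors import ParameterError, ValidationError
from .features2d import FEATURE_COLUMNS, single_cell_features
from .holography import PhaseMap
from .segmentation import augment_rotate

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "thal"

DEFAULT_HYPERPARAMS = {
    "max_depth": 3,
    "n_estimators": 200,
    "learning_rate": 0.1,
    "objective": "binary:logistic",
    "tree_method": "hist",
    "n_jobs": 1,
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Group-aware random partition of a feature table.

    All rows sharing ``grouping_key`` (augmented copies of one physical cell)
    land in the same partition, preventing near-duplicate leakage.
    """

    ratios: tuple[float, ...]
    grouping_key: str = "cell_id"
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.ratios), 1.0):
            raise ValidationError(f"ratios must sum to 1, got {self.ratios}")
        if any(r <= 0 for r in self.ratios):
            raise ValidationError("all ratios must be positive")


@dataclass
class EvalMetrics:
    """Confusion-derived classification metrics plus AUC."""

    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float | None
    confusion: dict[str, int]

    @classmethod
    def from_counts(
        cls, tp: int, fn: int, tn: int, fp: int, auc: float | None = None
    ) -> "EvalMetrics":
        total = tp + fn + tn + fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        acc = (tp + tn) / total if total else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        return cls(
            sensitivity=sens,
            specificity=spec,
            accuracy=acc,
            f1=f1,
            auc=auc,
            confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        )

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": self.confusion,
        }


@dataclass
class ShapleyResult:
    """Exact Shapley attributions for a set of instances."""

    attributions: np.ndarray  # instances x features, margin units
    base_value: float
    feature_names: list[str]
    importance: np.ndarray = field(init=False)  # mean |attribution| per feature
    ranking: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.attributions = np.asarray(self.attributions, dtype=float)
        self.importance = np.abs(self.attributions).mean(axis=0)
        self.ranking = global_importance(self)


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def split_dataset(table: pd.DataFrame, plan: SplitPlan) -> list[pd.DataFrame]:
    """Randomly assign whole groups to partitions in the plan's proportions."""
    if plan.grouping_key not in table.columns:
        raise ValidationError(f"grouping key {plan.grouping_key!r} not in table")
    groups = table[plan.grouping_key].unique()
    n_groups = len(groups)
    targets = [r * n_groups for r in plan.ratios]
    counts = [int(np.floor(t)) for t in targets]
    # distribute the remainder by largest fractional part
    rem = n_groups - sum(counts)
    order = np.argsort([t - int(np.floor(t)) for t in targets])[::-1]
    for k in order[:rem]:
        counts[k] += 1
    if any(c == 0 for c in counts):
        raise ValidationError(
            "a partition would receive no groups; too few groups for these ratios"
        )
    rng = np.random.default_rng(plan.seed)
    shuffled = groups[rng.permutation(n_groups)]
    parts: list[pd.DataFrame] = []
    start = 0
    for c in counts:
        chosen = set(shuffled[start : start + c])
        part = table[table[plan.grouping_key].isin(chosen)].reset_index(drop=True)
        parts.append(part)
        start += c
        if "class" in table.columns:
            logger.info(
                "split partition: %d groups, class counts %s",
                c,
                part["class"].value_counts().to_dict(),
            )
    return parts


@dataclass
class CellImage:
    """A per-cell phase crop with its mask, used for rotation augmentation."""

    cell_id: int
    cell_class: str
    phase: np.ndarray
    mask: np.ndarray
    pixel_size: float


def balance_by_rotation(
    records: list[CellImage],
    rng_seed: int = 0,
    minority_class: str | None = None,
) -> list[CellImage]:
    """Equalise class counts by appending random-angle rotated minority copies.

    Copies inherit the source cell's id (the grouping key), so augmented
    near-duplicates can never straddle a train/test split.
    """
    counts: dict[str, int] = {}
    for r in records:
        counts[r.cell_class] = counts.get(r.cell_class, 0) + 1
    if len(counts) < 2:
        return list(records)
    if minority_class is None:
        minority_class = min(counts, key=counts.get)
    deficit = max(counts.values()) - counts[minority_class]
    if deficit <= 0:
        return list(records)
    rng = np.random.default_rng(rng_seed)
    pool = [r for r in records if r.cell_class == minority_class]
    out = list(records)
    for k in range(deficit):
        src = pool[k % len(pool)]
        angle = float(rng.uniform(0.0, 360.0))
        img, msk = augment_rotate(src.phase, src.mask, angle)
        out.append(
            CellImage(src.cell_id, src.cell_class, img, msk, src.pixel_size)
        )
    return out


def features_from_records(
    records: list[CellImage], glcm_levels: int = 32
) -> pd.DataFrame:
    """15-feature table for a list of per-cell images (one row per record)."""
    rows = []
    for r in records:
        p = PhaseMap(r.phase, pixel_size=r.pixel_size, provenance="synthetic")
        row: dict[str, object] = {"cell_id": r.cell_id, "class": r.cell_class}
        row.update(single_cell_features(p, r.mask, glcm_levels=glcm_levels))
        rows.append(row)
    return pd.DataFrame(rows, columns=["cell_id", "class"] + FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def train_classifier(
    train_table: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> xgb.XGBClassifier:
    """Fit the gradient-boosted tree classifier on the 15 feature columns."""
    y = (train_table["class"] == POSITIVE_CLASS).astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("training table must contain both classes")
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    model = xgb.XGBClassifier(random_state=seed, **params)
    model.fit(train_table[FEATURE_COLUMNS].to_numpy(), y)
    return model


def save_model(model: xgb.XGBClassifier, out_dir: str | Path, seed: int = 0) -> Path:
    """Persist the booster plus a JSON sidecar of hyperparameters and seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_path = out_dir / "model.ubj"
    # newer scikit-learn drops the _estimator_type attribute the xgboost
    # sklearn wrapper expects when serialising; restore it explicitly
    model._estimator_type = "classifier"
    model.save_model(model_path)
    sidecar = {
        "hyperparams": {k: model.get_params().get(k) for k in DEFAULT_HYPERPARAMS},
        "seed": seed,
        "feature_columns": FEATURE_COLUMNS,
    }
    (out_dir / "model.json").write_text(json.dumps(sidecar, indent=2))
    return model_path


def load_model(model_dir: str | Path) -> xgb.XGBClassifier:
    model = xgb.XGBClassifier()
    model._estimator_type = "classifier"
    model.load_model(Path(model_dir) / "model.ubj")
    return model


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    npos = int(y.sum())
    nneg = int((~y).sum())
    if npos == 0 or nneg == 0:
        raise ValidationError("AUC requires both classes")
    r = rankdata(scores)
    return float((r[y].sum() - npos * (npos + 1) / 2) / (npos * nneg))


def evaluate(
    model: xgb.XGBClassifier,
    test_table: pd.DataFrame,
    positive_class: str = POSITIVE_CLASS,
    threshold: float = 0.5,
) -> EvalMetrics:
    """Confusion metrics at the 0.5 operating point plus rank-statistic AUC."""
    if len(test_table) == 0:
        raise ValidationError("test table is empty")
    y = (test_table["class"] == positive_class).to_numpy()
    scores = model.predict_proba(test_table[FEATURE_COLUMNS].to_numpy())[:, 1]
    pred = scores >= threshold
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    if y.all() or not y.any():
        logger.warning("evaluate: one-class test set; AUC reported missing")
        auc = None
    else:
        auc = rank_auc(scores, y)
    return EvalMetrics.from_counts(tp, fn, tn, fp, auc=auc)


def xgb_margin_fn(model: xgb.XGBClassifier):
    """Model function returning raw margin (log-odds) scores."""

    def fn(X: np.ndarray) -> np.ndarray:
        return model.predict(np.asarray(X, dtype=float), output_margin=True)

    return fn


# ---------------------------------------------------------------------------
# exact Shapley attribution
# ---------------------------------------------------------------------------

def shapley_exact(
    model_fn,
    instances: np.ndarray,
    background: np.ndarray,
    feature_names: list[str] | None = None,
    max_features: int = 16,
    coalition_chunk: int = 4096,
) -> ShapleyResult:
    """Exact Shapley values by full coalition enumeration.

    For instance x and feature i,

        phi_i = sum_{S subset of features \\ {i}} |S|! (M-|S|-1)! / M!
                * (v(S + {i}) - v(S)),

    with the interventional marginal value v(S) = mean over background rows b
    of ``model_fn`` applied to the hybrid vector taking x on S and b elsewhere.
    All 2^M coalitions are enumerated (feasible for M <= ``max_features``);
    the coalition axis is processed in chunks to bound memory.
    """
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValidationError("background must be non-empty")
    M = instances.shape[1]
    if background.shape[1] != M:
        raise ValidationError("instances and background disagree on feature count")
    if M > max_features:
        raise ParameterError(
            f"{M} features would require 2^{M} = {2 ** M} coalition evaluations; "
            f"limit is max_features = {max_features}"
        )
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(M)]

    n_coal = 1 << M
    bits = np.arange(M)
    coal_ids = np.arange(n_coal)
    member = ((coal_ids[:, None] >> bits[None, :]) & 1).astype(bool)  # n_coal x M
    sizes = member.sum(axis=1)
    fact = np.array([math.factorial(k) for k in range(M + 1)], dtype=float)
    weights = fact[sizes] * fact[M - sizes - 1] / fact[M]  # weight for S of |S|, i not in S
    B = background.shape[0]

    attributions = np.zeros((instances.shape[0], M))
    base_value = float(np.mean(model_fn(background)))
    for n, x in enumerate(instances):
        v = np.empty(n_coal)
        for start in range(0, n_coal, coalition_chunk):
            mm = member[start : start + coalition_chunk]
            hybrid = np.where(
                mm[:, None, :], x[None, None, :], background[None, :, :]
            ).reshape(-1, M)
            v[start : start + mm.shape[0]] = model_fn(hybrid).reshape(-1, B).mean(axis=1)
        for i in range(M):
            without = ~member[:, i]
            idx = coal_ids[without]
            attributions[n, i] = np.sum(
                weights[idx] * (v[idx | (1 << i)] - v[idx])
            )
    return ShapleyResult(attributions, base_value, list(feature_names))


def global_importance(s: ShapleyResult) -> list[str]:
    """Features sorted by mean absolute attribution, descending.

    Ties are broken by feature-name order (and logged).
    """
    imp = np.abs(s.attributions).mean(axis=0)
    order = sorted(range(len(imp)), key=lambda i: (-imp[i], s.feature_names[i]))
    vals = imp[order]
    if len(vals) > 1 and np.any(np.diff(vals) == 0):
        logger.info("global_importance: ties broken by feature-name order")
    return [s.feature_names[i] for i in order]
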