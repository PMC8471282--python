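"""Model assembly and evaluation: feature matrices per model, SMOTE class
balancing, 30 stratified holdout partitions, pooled-covariance LDA, and
classification metrics with preterm as the positive class.

The six model compositions and their dimensionalities:

=========  ==========================  ==========  ====
acronym    EHG feature groups          obstetric    dim
=========  ==========================  ==========  ====
En_SFS     SampEn, FuzEn, SpEn         no            18
En_ALL     all five entropies          no            30
Linear     linear                      yes           65
LNL        linear + non-linear         yes          113
LEn_ALL    linear + entropies          yes           95
LNLEn_ALL  linear + NL + entropies     yes          143
=========  ==========================  ==========  ====

Following the study design this package reproduces, SMOTE is applied to
the whole dataset *before* partitioning.  That places synthetic
neighbors of test rows in the training set and inflates test metrics;
the methodologically clean alternative (SMOTE on the training split
only) is available via ``smote_placement="train-only"``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from . import complexity as cx
from . import entropy as ent
from . import linear as lin
from .preprocess import CHANNELS, MISSING
from .stats import TestResult, friedman_test, ranksum_test

logger = logging.getLogger(__name__)

TERM, PRETERM = "term", "preterm"
POSITIVE_CLASS = PRETERM

MODEL_ACRONYMS = ("En_SFS", "En_ALL", "Linear", "LNL", "LEn_ALL", "LNLEn_ALL")
_MODEL_GROUPS = {
    "En_SFS": (("En_SFS",), False),
    "En_ALL": (("En_ALL",), False),
    "Linear": (("Linear",), True),
    "LNL": (("Linear", "NL"), True),
    "LEn_ALL": (("Linear", "En_ALL"), True),
    "LNLEn_ALL": (("Linear", "NL", "En_ALL"), True),
}
EXPECTED_DIMS = {"En_SFS": 18, "En_ALL": 30, "Linear": 65, "LNL": 113,
                 "LEn_ALL": 95, "LNLEn_ALL": 143}


@dataclass
class FeatureTable:
    """records x named features, with labels and per-row provenance."""

    X: pd.DataFrame
    labels: pd.Series
    provenance: np.ndarray

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature columns")
        if len(self.X) != len(self.labels):
            raise ValueError("labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.X)

    def class_counts(self) -> dict:
        return self.labels.value_counts().to_dict()


@dataclass(frozen=True)
class ModelSpec:
    """Feature-group composition of one prediction model."""

    acronym: str

    def __post_init__(self) -> None:
        if self.acronym not in _MODEL_GROUPS:
            raise ValueError(f"unknown model acronym {self.acronym!r}")

    @property
    def groups(self) -> tuple:
        return _MODEL_GROUPS[self.acronym][0]

    @property
    def include_obstetric(self) -> bool:
        return _MODEL_GROUPS[self.acronym][1]

    @property
    def expected_dim(self) -> int:
        return EXPECTED_DIMS[self.acronym]

    def columns(self) -> list:
        """Expand the groups over 3 channels (and 2 bands where applicable)."""
        from .features import OBSTETRIC_COLUMNS

        per_channel: list = []
        if "Linear" in self.groups:
            per_channel += lin.linear_feature_names()
        if "NL" in self.groups:
            for band in ("WBW", "FWH"):
                per_channel += [f"{f}_{band}"
                                for f in cx.complexity_feature_names()]
        ent_set = None
        if "En_ALL" in self.groups:
            ent_set = ent.ESTIMATORS
        elif "En_SFS" in self.groups:
            ent_set = ("SampEn", "FuzEn", "SpEn")
        if ent_set:
            for band in ("WBW", "FWH"):
                per_channel += [f"{e}_{band}" for e in ent_set]
        cols = [f"{name}_{ch}" for ch in CHANNELS for name in per_channel]
        if self.include_obstetric:
            cols += list(OBSTETRIC_COLUMNS)
        return cols


def build_feature_matrix(table: FeatureTable, spec: ModelSpec) -> FeatureTable:
    """Select the model's columns from a full feature table and impute.

    Missing values are median-imputed per column (logged); the resulting
    column count equals the model's expected dimensionality.
    """
    cols = spec.columns()
    missing_cols = [c for c in cols if c not in table.X.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks columns: {missing_cols}")
    X = table.X[cols].copy()
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        logger.warning("imputing %d missing value(s) with column medians",
                       n_missing)
        X = X.fillna(X.median())
        X = X.fillna(0.0)  # columns that are entirely missing
    assert X.shape[1] == spec.expected_dim
    return FeatureTable(X=X, labels=table.labels.copy(),
                        provenance=table.provenance.copy())


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_balance(table: FeatureTable, k: int = 5,
                  seed: int = 0) -> FeatureTable:
    """Oversample the minority class to the majority count (SMOTE, k=5).

    Each synthetic row is x + u * (x_nn - x) with u ~ Uniform(0, 1) and
    x_nn one of x's k nearest minority neighbors (Euclidean distance on
    z-scored features).  Synthetic rows are flagged in provenance.
    Already-balanced input is returned unchanged.
    """
    counts = table.labels.value_counts()
    if len(counts) != 2:
        raise ValueError("need exactly two classes")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return table
    min_mask = (table.labels == minority).to_numpy()
    Xmin = table.X.loc[min_mask].to_numpy(dtype=float)
    if Xmin.shape[0] <= k:
        raise ValueError(
            f"minority class has {Xmin.shape[0]} rows; needs > k={k} "
            f"(use a smaller k)")
    mu = table.X.to_numpy(dtype=float).mean(axis=0)
    sd = table.X.to_numpy(dtype=float).std(axis=0)
    sd[sd == 0] = 1.0
    Zmin = (Xmin - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Zmin)
    _, idx = nn.kneighbors(Zmin)
    neighbors = idx[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    parents = rng.integers(0, Xmin.shape[0], size=n_needed)
    picks = rng.integers(0, k, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    synth = Xmin[parents] + u[:, None] * (
        Xmin[neighbors[parents, picks]] - Xmin[parents])
    synth_df = pd.DataFrame(synth, columns=table.X.columns,
                            index=[f"smote_{i}" for i in range(n_needed)])
    X = pd.concat([table.X, synth_df])
    labels = pd.concat([table.labels,
                        pd.Series([minority] * n_needed, index=synth_df.index,
                                  name=table.labels.name)])
    provenance = np.concatenate([table.provenance,
                                 np.array(["synthetic_smote"] * n_needed)])
    return FeatureTable(X=X, labels=labels, provenance=provenance)


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

@dataclass
class PartitionSet:
    """Stratified random train/validation/test thirds, reused across models."""

    partitions: list  # list of (train_idx, val_idx, test_idx) arrays
    seed: int

    def __len__(self) -> int:
        return len(self.partitions)

    def digest(self) -> str:
        h = hashlib.sha256()
        for tr, va, te in self.partitions:
            for a in (tr, va, te):
                h.update(np.asarray(a, dtype=np.int64).tobytes())
        return h.hexdigest()


def _largest_remainder_thirds(n: int) -> list:
    base = [n // 3] * 3
    rema = n - 3 * (n // 3)
    for i in range(rema):
        base[i] += 1
    return base


def make_partitions(table: FeatureTable, n_partitions: int = 30,
                    seed: int = 0) -> PartitionSet:
    """Independent stratified 1/3-1/3-1/3 random splits (largest-remainder
    rounding for odd class counts).  Deterministic given seed."""
    labels = table.labels.to_numpy()
    rng = np.random.default_rng(seed)
    class_idx = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
    for c, idx in class_idx.items():
        if idx.size < 6:
            raise ValueError(f"class {c!r} too small to stratify ({idx.size})")
    partitions = []
    for _ in range(n_partitions):
        split = [[], [], []]
        for idx in class_idx.values():
            perm = rng.permutation(idx)
            sizes = _largest_remainder_thirds(idx.size)
            pos = 0
            for s in range(3):
                split[s].append(perm[pos:pos + sizes[s]])
                pos += sizes[s]
        partitions.append(tuple(np.sort(np.concatenate(parts))
                                for parts in split))
    return PartitionSet(partitions=partitions, seed=seed)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Pooled-covariance linear discriminant with diagonal shrinkage."""

    classes: np.ndarray
    means: np.ndarray          # (2, d)
    priors: np.ndarray         # (2,)
    weights: np.ndarray        # (d,)
    bias: float
    mu: np.ndarray             # standardization mean (d,)
    sd: np.ndarray             # standardization sd (d,)

    def scores(self, X) -> np.ndarray:
        """Continuous discriminant score; > 0 favors the positive class."""
        Z = (np.asarray(X, dtype=float) - self.mu) / self.sd
        return Z @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        s = self.scores(X)
        return np.where(s > 0, self.classes[1], self.classes[0])


def lda_fit(X, y, shrinkage_scale: float = 1e-6) -> LDAModel:
    """Fit pooled-covariance LDA with priors from class frequencies.

    Features are z-scored with training statistics; the pooled
    within-class covariance gets ``shrinkage_scale * trace/dim`` added
    to its diagonal so it is always invertible.  The second class in
    sorted order (``preterm`` before ``term`` reversed — the positive
    class is placed last) receives positive scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("lda_fit requires exactly two classes in training")
    # place the positive (preterm) class last when present
    if POSITIVE_CLASS in classes:
        classes = np.array([c for c in classes if c != POSITIVE_CLASS]
                           + [POSITIVE_CLASS])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    d = Z.shape[1]
    means, covs, ns = [], [], []
    for c in classes:
        Zc = Z[y == c]
        means.append(Zc.mean(axis=0))
        covs.append((Zc - Zc.mean(axis=0)).T @ (Zc - Zc.mean(axis=0)))
        ns.append(Zc.shape[0])
    pooled = (covs[0] + covs[1]) / (ns[0] + ns[1] - 2)
    eps = shrinkage_scale * np.trace(pooled) / d
    pooled = pooled + np.eye(d) * max(eps, shrinkage_scale)
    priors = np.array(ns, dtype=float) / sum(ns)
    diff = means[1] - means[0]
    w = np.linalg.solve(pooled, diff)
    bias = float(-0.5 * (means[1] + means[0]) @ w
                 + math_log_ratio(priors[1], priors[0]))
    return LDAModel(classes=classes, means=np.array(means), priors=priors,
                    weights=w, bias=bias, mu=mu, sd=sd)


def math_log_ratio(a: float, b: float) -> float:
    return float(np.log(a) - np.log(b))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

METRIC_NAMES = ("F1", "Accuracy", "Sensitivity", "Specificity", "PPV",
                "NPV", "AUC")


def classification_metrics(y_true, y_pred, scores=None) -> dict:
    """Confusion-matrix metrics in percent, preterm = positive class.

    AUC comes from trapezoidal integration of the ROC over the
    continuous scores.  Undefined ratios return the missing sentinel.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    pos = y_true == POSITIVE_CLASS
    pred_pos = y_pred == POSITIVE_CLASS
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else MISSING

    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    acc = ratio(tp + tn, tp + fn + tn + fp)
    if np.isnan(se) or np.isnan(ppv) or (se + ppv) == 0:
        f1 = MISSING
    else:
        f1 = 2.0 * ppv * se / (ppv + se)
    if scores is not None and np.unique(y_true).size == 2:
        auc = 100.0 * float(roc_auc_score(pos.astype(int),
                                          np.asarray(scores, dtype=float)))
    else:
        auc = MISSING
    return {"F1": f1, "Accuracy": acc, "Sensitivity": se, "Specificity": sp,
            "PPV": ppv, "NPV": npv, "AUC": auc}


@dataclass
class MetricsReport:
    """Per-partition and aggregate metrics for one model."""

    per_partition: dict          # split -> DataFrame (n_partitions x metrics)
    partition_digest: str = ""

    def aggregate(self, split: str = "test") -> pd.DataFrame:
        df = self.per_partition[split]
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})

    def mean(self, metric: str = "F1", split: str = "test") -> float:
        return float(self.per_partition[split][metric].mean())


def evaluate_model(table: FeatureTable, partitions: PartitionSet,
                   mask=None) -> MetricsReport:
    """Fit LDA per partition and report train/validation/test metrics.

    ``mask`` restricts the feature columns (boolean array, column names,
    or None for all).
    """
    X_all = _masked_matrix(table, mask)
    if X_all.shape[1] == 0:
        raise ValueError("empty feature mask")
    y = table.labels.to_numpy()
    rows = {"train": [], "validation": [], "test": []}
    for tr, va, te in partitions.partitions:
        model = lda_fit(X_all[tr], y[tr])
        for split, idx in (("train", tr), ("validation", va), ("test", te)):
            scores = model.scores(X_all[idx])
            preds = model.predict(X_all[idx])
            rows[split].append(classification_metrics(y[idx], preds, scores))
    per = {s: pd.DataFrame(r, columns=list(METRIC_NAMES))
           for s, r in rows.items()}
    return MetricsReport(per_partition=per,
                         partition_digest=partitions.digest())


def _masked_matrix(table: FeatureTable, mask) -> np.ndarray:
    if mask is None:
        return table.X.to_numpy(dtype=float)
    mask_arr = np.asarray(mask)
    if mask_arr.dtype == bool:
        return table.X.to_numpy(dtype=float)[:, mask_arr]
    return table.X[list(mask)].to_numpy(dtype=float)


@dataclass
class ModelComparison:
    friedman: dict               # metric -> TestResult
    pairwise: dict               # metric -> DataFrame of p-values


def compare_models(reports: dict, split: str = "test",
                   alpha: float = 0.05) -> ModelComparison:
    """Friedman across models per metric plus pairwise rank-sum tests.

    All reports must share the same PartitionSet (checked by digest).
    """
    names = list(reports)
    digests = {reports[n].partition_digest for n in names}
    if len(digests) > 1:
        raise ValueError("reports were computed on different partition sets")
    n_parts = {len(reports[n].per_partition[split]) for n in names}
    if len(n_parts) > 1:
        raise ValueError("mismatched partition counts")
    friedman: dict = {}
    pairwise: dict = {}
    for metric in METRIC_NAMES:
        matrix = np.vstack([
            reports[n].per_partition[split][metric].to_numpy() for n in names])
        if len(names) >= 2:
            friedman[metric] = friedman_test(matrix)
        p = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                         columns=names)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    res = ranksum_test(matrix[i], matrix[j])
                    p.iloc[i, j] = p.iloc[j, i] = res.p_value
        pairwise[metric] = p
    return ModelComparison(friedman=friedman, pairwise=pairwise)


def balance_and_partition(table: FeatureTable, k: int = 5,
                          n_partitions: int = 30, seed: int = 0,
                          smote_placement: str = "pre"):
    """SMOTE-balance then partition (the study's order of operations).

    ``smote_placement="pre"`` (default) balances the full table before
    the holdout splits are drawn.  ``"train-only"`` returns the original
    table with partitions over it; SMOTE is then applied within each
    training split by :func:`evaluate_model_train_smote`.
    """
    if smote_placement not in ("pre", "train-only"):
        raise ValueError("smote_placement must be 'pre' or 'train-only'")
    if smote_placement == "pre":
        balanced = smote_balance(table, k=k, seed=seed)
        parts = make_partitions(balanced, n_partitions, seed=seed + 1)
        return balanced, parts
    parts = make_partitions(table, n_partitions, seed=seed + 1)
    return table, parts


def evaluate_model_train_smote(table: FeatureTable, partitions: PartitionSet,
                               mask=None, k: int = 5,
                               seed: int = 0) -> MetricsReport:
    """Leakage-free variant: SMOTE applied inside each training split."""
    y = table.labels.to_numpy()
    rows = {"train": [], "validation": [], "test": []}
    for p_i, (tr, va, te) in enumerate(partitions.partitions):
        sub = FeatureTable(X=table.X.iloc[tr].reset_index(drop=True),
                           labels=table.labels.iloc[tr].reset_index(drop=True),
                           provenance=table.provenance[tr])
        counts = sub.labels.value_counts()
        if counts.min() > k:
            sub = smote_balance(sub, k=k, seed=seed + p_i)
        Xtr = _masked_matrix(sub, mask)
        model = lda_fit(Xtr, sub.labels.to_numpy())
        X_all = _masked_matrix(table, mask)
        rows["train"].append(classification_metrics(
            sub.labels.to_numpy(), model.predict(Xtr), model.scores(Xtr)))
        for split, idx in (("validation", va), ("test", te)):
            scores = model.scores(X_all[idx])
            preds = model.predict(X_all[idx])
            rows[split].append(classification_metrics(y[idx], preds, scores))
    per = {s: pd.DataFrame(r, columns=list(METRIC_NAMES))
           for s, r in rows.items()}
    return MetricsReport(per_partition=per,
                         partition_digest=partitions.digest())
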