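"""Random-forest classification, thresholding and validation.

The classifier follows the published configuration: 40 trees, 5 candidate
predictors per split, minimum leaf population 2, bag fraction 0.7 and a
3,010-node cap per tree, trained on an 80/20 stratified split of labelled
points over the 11 predictor layers.  Per-pixel probabilities are vote
fractions — the share of trees classifying the pixel as GDE — and the
binary map codes GDE as 1 and non-GDE as 2, using either the default 50%
likelihood threshold or a dynamic threshold that maximises validation
accuracy over a 0.00-1.00 sweep.

The ensemble itself is scikit-learn's random forest; the node cap maps to
a leaf cap of ceil(max_nodes / 2) because a binary tree with L leaves has
2L - 1 nodes.  Split criterion is Gini impurity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .predictors import LAYER_ORDER, PredictorStack
from .raster_core import RasterGrid, RasterError

GDE, NONGDE = "GDE", "NONGDE"

#: binary map codes (deposited-data convention)
CODE_GDE, CODE_NONGDE = 1.0, 2.0

DEFAULT_THRESHOLD = 0.5


class ValidationError(ValueError):
    """Contract violation in training/validation inputs."""


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (defaults are the published tuning)."""

    n_trees: int = 40
    vars_per_split: int = 5
    min_leaf: int = 2
    bag_fraction: float = 0.7
    max_nodes: int = 3010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if not 1 <= self.vars_per_split <= len(LAYER_ORDER):
            raise ValidationError(
                f"vars_per_split must be in [1, {len(LAYER_ORDER)}]"
            )
        if not 0 < self.bag_fraction <= 1:
            raise ValidationError("bag_fraction must be in (0, 1]")


PAPER_RF_CONFIG = RFConfig()


@dataclass
class TrainedModel:
    """A fitted ensemble plus its training diagnostics."""

    forest: RandomForestClassifier
    layer_order: tuple[str, ...]
    config: RFConfig
    oob_error: float
    feature_importances: dict[str, float]
    n_dropped: int = 0  # training points lost to nodata predictors

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)

    def _gde_index(self) -> int:
        return list(self.forest.classes_).index(GDE)

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting GDE for each row of ``X``.

        This is the probabilistic (MULTIPROBABILITY-style) output: each
        tree casts one vote, its majority class at the reached leaf.
        """
        gde_idx = self._gde_index()
        votes = np.zeros(len(X))
        for tree in self.forest.estimators_:
            votes += (np.argmax(tree.predict_proba(X), axis=1) == gde_idx)
        return votes / self.n_trees


@dataclass
class ValidationReport:
    """Confusion counts and the derived rates; NaN marks undefined ratios."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    threshold: float | None = None
    context: str = ""

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "threshold": self.threshold,
            "context": self.context,
        }


@dataclass
class GDEMap:
    """Paired probability/binary layers and the threshold that linked them."""

    probability: RasterGrid
    binary: RasterGrid
    threshold: float


# ---------------------------------------------------------------------------
# label consensus
# ---------------------------------------------------------------------------

def consensus_labels(species_flags: pd.DataFrame) -> pd.DataFrame:
    """Classify species by cross-region consensus.

    A species is a GDE when two or more regions flag it as a phreatophyte,
    a non-GDE when three or more flag it as not one, and unlabelled
    (excluded from the output) otherwise.  GDE consensus takes precedence
    if both rules fire.  Input columns: species, region, flag in
    {phreatophyte, not_phreatophyte}, unique per (species, region).
    """
    df = species_flags.drop_duplicates()
    conflicts = df.groupby(["species", "region"])["flag"].nunique()
    if (conflicts > 1).any():
        sp, rg = conflicts[conflicts > 1].index[0]
        raise ValidationError(f"conflicting flags for species {sp!r} in region {rg!r}")
    counts = (
        df.groupby("species")["flag"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["phreatophyte", "not_phreatophyte"], fill_value=0)
    )
    labels = np.where(
        counts["phreatophyte"] >= 2, GDE,
        np.where(counts["not_phreatophyte"] >= 3, NONGDE, ""),
    )
    out = pd.DataFrame({"species": counts.index, "label": labels})
    return out[out["label"] != ""].reset_index(drop=True)


# ---------------------------------------------------------------------------
# splitting and training
# ---------------------------------------------------------------------------

def split_train_test(
    points: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-label disjoint split; deterministic per seed."""
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label, grp in points.groupby("label", sort=True):
        n = len(grp)
        if n < 2:
            raise ValidationError(f"class {label!r} has < 2 points")
        perm = rng.permutation(grp.index.to_numpy())
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = points.loc[np.concatenate(train_idx)].reset_index(drop=True)
    test = points.loc[np.concatenate(test_idx)].reset_index(drop=True)
    return train, test


def _design_matrix(points: pd.DataFrame, stack: PredictorStack
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    X = stack.sample_at(points["lon"].to_numpy(), points["lat"].to_numpy())
    y = points["label"].to_numpy()
    keep = ~np.isnan(X).any(axis=1)
    return X[keep], y[keep], int((~keep).sum())


def train_rf(train: pd.DataFrame, stack: PredictorStack,
             config: RFConfig = PAPER_RF_CONFIG) -> TrainedModel:
    """Fit the bagged tree ensemble on predictor values at labelled points.

    Points with any nodata predictor are dropped (the count is kept on the
    returned model).  Out-of-bag error is estimated from samples left out
    of each tree's bootstrap draw.
    """
    X, y, n_dropped = _design_matrix(train, stack)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    max_leaves = math.ceil(config.max_nodes / 2)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.vars_per_split,
        min_samples_leaf=config.min_leaf,
        max_leaf_nodes=max_leaves,
        max_samples=None if config.bag_fraction >= 1.0 else config.bag_fraction,
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # small ensembles can leave a few samples with no OOB vote
        warnings.simplefilter("ignore", UserWarning)
        forest.fit(X, y)
    importances = dict(zip(LAYER_ORDER, map(float, forest.feature_importances_)))
    return TrainedModel(
        forest=forest,
        layer_order=tuple(LAYER_ORDER),
        config=config,
        oob_error=float(1.0 - forest.oob_score_),
        feature_importances=importances,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# prediction, thresholding, metrics
# ---------------------------------------------------------------------------

def predict_probability(model: TrainedModel, stack: PredictorStack,
                        extent: RasterGrid) -> RasterGrid:
    """GDE vote-fraction per extent pixel; nodata elsewhere."""
    if tuple(stack.names) != tuple(model.layer_order):
        raise ValidationError(
            f"layer-order mismatch: model expects {model.layer_order}, "
            f"stack has {stack.names}"
        )
    ref = stack.grid
    cube = stack.as_array()
    in_extent = extent.values == 1.0
    complete = ~np.isnan(cube).any(axis=0)
    ok = in_extent & complete
    out = np.full(ref.shape, ref.nodata)
    if ok.any():
        X = cube[:, ok].T
        out[ok] = model.vote_fractions(X)
    return ref.with_values(out, layer_name="gde_probability")


def score_points(model: TrainedModel, stack: PredictorStack,
                 points: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Vote fractions at point locations; points with nodata predictors drop."""
    X = stack.sample_at(points["lon"].to_numpy(), points["lat"].to_numpy())
    keep = ~np.isnan(X).any(axis=1)
    return model.vote_fractions(X[keep]), points[keep].reset_index(drop=True)


def dynamic_threshold(probability, validation: pd.DataFrame,
                      scores: np.ndarray | None = None) -> float:
    """Threshold from {0.00, 0.01, ..., 1.00} maximising validation accuracy.

    ``probability`` may be a probability raster (scores are then sampled
    at the validation points) or ignored when ``scores`` provides the
    per-point probabilities directly.  Ties go to the smallest threshold.
    """
    labels = validation["label"].to_numpy()
    if len(set(labels)) < 2:
        raise ValidationError("dynamic thresholding needs both classes present")
    if scores is None:
        if not isinstance(probability, RasterGrid):
            raise ValidationError("supply a probability raster or explicit scores")
        row, col = probability.lonlat_to_rowcol(
            validation["lon"].to_numpy(), validation["lat"].to_numpy()
        )
        scores = probability.values[row, col]
        valid = scores != probability.nodata
        scores, labels = scores[valid], labels[valid]
    scores = np.asarray(scores, float)
    truth_gde = labels == GDE
    best_t, best_acc = 0.0, -1.0
    for i in range(101):
        t = i / 100.0
        pred_gde = scores >= t
        acc = float(np.mean(pred_gde == truth_gde))
        if acc > best_acc + 1e-12:
            best_acc, best_t = acc, t
    return best_t


def binarize(probability: RasterGrid, threshold: float = DEFAULT_THRESHOLD) -> GDEMap:
    """Probability >= threshold -> GDE (1), else non-GDE (2); nodata preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0,1], got {threshold}")
    valid = probability.valid_mask()
    binary = np.where(
        valid,
        np.where(probability.values >= threshold, CODE_GDE, CODE_NONGDE),
        probability.nodata,
    )
    return GDEMap(
        probability=probability,
        binary=probability.with_values(binary, layer_name="gde_binary"),
        threshold=threshold,
    )


def confusion_metrics(predicted: Sequence[str], truth: Sequence[str],
                      threshold: float | None = None,
                      context: str = "") -> ValidationReport:
    """2x2 confusion counts with accuracy, precision and recall.

    GDE is the positive class; zero-denominator ratios come out NaN.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValidationError(
            f"length mismatch: {predicted.shape} predicted vs {truth.shape} truth"
        )
    for arr, name in ((predicted, "predicted"), (truth, "truth")):
        bad = set(arr) - {GDE, NONGDE}
        if bad:
            raise ValidationError(f"{name} labels outside {{GDE, NONGDE}}: {bad}")
    tp = int(np.sum((predicted == GDE) & (truth == GDE)))
    fp = int(np.sum((predicted == GDE) & (truth == NONGDE)))
    fn = int(np.sum((predicted == NONGDE) & (truth == GDE)))
    tn = int(np.sum((predicted == NONGDE) & (truth == NONGDE)))
    total = tp + fp + fn + tn

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return ValidationReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=ratio(tp + tn, total),
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
        threshold=threshold,
        context=context,
    )


def validate_points(model: TrainedModel, stack: PredictorStack,
                    points: pd.DataFrame,
                    threshold: float = DEFAULT_THRESHOLD,
                    context: str = "") -> ValidationReport:
    """Score points, threshold, and report confusion metrics."""
    scores, kept = score_points(model, stack, points)
    predicted = np.where(scores >= threshold, GDE, NONGDE)
    return confusion_metrics(predicted, kept["label"].to_numpy(),
                             threshold=threshold, context=context)


def regional_cv(points: pd.DataFrame, stack: PredictorStack,
                holdout_region: str,
                config: RFConfig = PAPER_RF_CONFIG,
                threshold: float = DEFAULT_THRESHOLD) -> ValidationReport:
    """Train with one region held out entirely; validate inside it."""
    held = points[points["region"] == holdout_region]
    rest = points[points["region"] != holdout_region]
    if held.empty:
        raise ValidationError(f"holdout region {holdout_region!r} has no points")
    model = train_rf(rest, stack, config)
    return validate_points(model, stack, held, threshold=threshold,
                           context=f"holdout:{holdout_region}")


# ---------------------------------------------------------------------------
# distribution overlap
# ---------------------------------------------------------------------------

def overlap_index(sample_a, sample_b) -> float:
    """Histogram estimate of the distribution overlap integral min(f_a, f_b).

    Shared bins span the pooled range with the Freedman-Diaconis bin count
    of the pooled sample; the statistic is the summed per-bin minimum of
    the two relative frequencies, 0 for disjoint samples and 1 for
    identical ones.  Symmetric in its arguments.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 10 or len(b) < 10:
        raise ValidationError("overlap_index needs n >= 10 per sample")
    pooled = np.concatenate([a, b])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi == lo:
        if np.all(a == lo) and np.all(b == lo):
            return 1.0
        raise ValidationError("degenerate zero-spread pooled sample")
    q75, q25 = np.percentile(pooled, [75, 25])
    width = 2.0 * (q75 - q25) / len(pooled) ** (1.0 / 3.0)
    if width <= 0:
        n_bins = max(1, int(math.ceil(math.sqrt(len(pooled)))))
    else:
        n_bins = max(1, int(math.ceil((hi - lo) / width)))
    ha, _ = np.histogram(a, bins=n_bins, range=(lo, hi))
    hb, _ = np.histogram(b, bins=n_bins, range=(lo, hi))
    return float(np.minimum(ha / len(a), hb / len(b)).sum())


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def tune_hyperparameters(points: pd.DataFrame, stack: PredictorStack,
                         grid: Iterable[RFConfig], seed: int = 0) -> RFConfig:
    """Exhaustive search maximising held-out accuracy on an internal split.

    Ties prefer fewer trees, then fewer variables per split.
    """
    configs = list(grid)
    if not configs:
        raise ValidationError("hyperparameter grid is empty")
    train, test = split_train_test(points, seed=seed)
    results = []
    for cfg in configs:
        cfg_seeded = replace(cfg, seed=seed)
        model = train_rf(train, stack, cfg_seeded)
        report = validate_points(model, stack, test)
        results.append((cfg, report.accuracy))
    best_acc = max(acc for _, acc in results)
    tied = [cfg for cfg, acc in results if acc >= best_acc - 1e-12]
    tied.sort(key=lambda c: (c.n_trees, c.vars_per_split))
    return tied[0]
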