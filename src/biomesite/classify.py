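"""Cross-validated Random-Forest body-site classification with calibration.

The framework mirrors standard practice for cross-study microbiome
classification: relative-abundance features, stratified 5-fold outer
cross-validation with a stratified 4-fold inner grid search (number of
trees x max-features multiplier of sqrt(p)), class weights inverse to
class frequency, macro-F1 objective, and per-class isotonic calibration
of the forest's probabilities fitted on out-of-fold scores.  Evaluation
utilities cover per-class/macro F1 (optionally study-inverse weighted),
row-normalized confusion matrices, mixture-detection AUC, F1-optimal
decision-threshold tables over mixture grids, deliberately biased sample
subsets, study-wise learning curves, and feature-importance overlap
between models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .mixtures import MixedEvalSet, MixtureSpec, build_mixture_grid
from .otu_table import OtuTable, SampleMeta

__all__ = ["CvPlan", "HyperGrid", "TrainedModel", "MetricsReport",
           "ThresholdTable", "make_cv_plan", "train_model", "predict_proba",
           "f1_report", "study_weights", "confusion", "mixture_auc",
           "optimize_thresholds", "biased_subset", "learning_curve_by_study",
           "feature_importance_overlap"]

logger = logging.getLogger(__name__)


@dataclass
class CvPlan:
    outer_k: int
    inner_k: int
    assignments: dict  # sample id -> outer fold index

    def fold_ids(self, fold: int) -> tuple[list, list]:
        """(train ids, validation ids) for one outer fold."""
        train = [s for s, f in self.assignments.items() if f != fold]
        valid = [s for s, f in self.assignments.items() if f == fold]
        return train, valid


@dataclass
class HyperGrid:
    """Forest size and max-features multipliers applied to sqrt(n_features)."""

    n_trees: tuple = (500, 1000, 2000)
    max_features_multipliers: tuple = (0.5, 1.0, 2.0)

    def validate(self) -> None:
        if not self.n_trees or not self.max_features_multipliers:
            raise ValueError("hyperparameter grid must be non-empty")
        if any(m <= 0 for m in self.max_features_multipliers):
            raise ValueError("max_features multipliers must be > 0")

    def points(self):
        for t in self.n_trees:
            for m in self.max_features_multipliers:
                yield int(t), float(m)


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    calibrators: dict                  # class label -> IsotonicRegression
    feature_ids: list
    classes: list
    hyperparameters: dict
    importances: pd.Series             # impurity-based, sums to 1

    def importance_map(self) -> dict:
        return self.importances.to_dict()


@dataclass
class MetricsReport:
    per_class_f1: dict
    mean_f1: float
    confusion: pd.DataFrame
    weighted_f1: float | None = None
    auc_by_spec: dict = field(default_factory=dict)


@dataclass
class ThresholdTable:
    """(target site, background site, fraction) -> decision threshold."""

    thresholds: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.thresholds)

    def get(self, target: str, background: str, fraction: float) -> float:
        return self.thresholds[(target, background, fraction)]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"target_site": t, "background_site": b, "fraction": f,
                 "threshold": thr}
                for (t, b, f), thr in sorted(self.thresholds.items())]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def make_cv_plan(meta: SampleMeta, outer_k: int = 5, inner_k: int = 4,
                 seed: int = 0) -> CvPlan:
    """Stratified outer split keeping per-fold site proportions constant."""
    sample_ids = list(meta.frame.index)
    sites = meta.frame["body_site"].to_numpy()
    counts = pd.Series(sites).value_counts()
    too_small = counts[counts < outer_k]
    if len(too_small):
        raise ValueError(
            f"class {too_small.index[0]!r} has {too_small.iloc[0]} samples, "
            f"fewer than outer_k={outer_k}")
    skf = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    assignments: dict = {}
    for fold, (_, valid_idx) in enumerate(skf.split(np.zeros(len(sample_ids)), sites)):
        for i in valid_idx:
            assignments[sample_ids[i]] = fold
    return CvPlan(outer_k=outer_k, inner_k=inner_k, assignments=assignments)


def _max_features(multiplier: float, n_features: int) -> int:
    return max(1, int(round(multiplier * np.sqrt(n_features))))


def _forest(n_trees: int, multiplier: float, n_features: int, seed: int,
            n_jobs: int = 1) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=_max_features(multiplier, n_features),
        class_weight="balanced",
        random_state=seed,
        n_jobs=n_jobs,
    )


def train_model(rel_abund: pd.DataFrame, labels, grid: HyperGrid | None = None,
                inner_k: int = 4, seed: int = 0, n_jobs: int = 1) -> TrainedModel:
    """Grid-searched, class-weighted forest with isotonic calibration.

    ``rel_abund`` is OTUs x samples; ``labels`` aligns with its columns.
    Every grid point is scored by macro-F1 over a stratified ``inner_k``-fold
    cross-validation; the best point is refit on all the data and one
    isotonic calibrator per class is fitted on the inner out-of-fold
    probabilities of the winning configuration.
    """
    grid = HyperGrid() if grid is None else grid
    grid.validate()
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    counts = pd.Series(y).value_counts()
    if counts.min() < inner_k:
        raise ValueError(
            f"class {counts.idxmin()!r} has fewer than inner_k={inner_k} samples")
    X = rel_abund.to_numpy().T
    feature_ids = [str(i) for i in rel_abund.index]
    p = X.shape[1]

    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best = None
    oof_best = None
    for n_trees, mult in grid.points():
        oof = np.zeros((len(y), len(classes)))
        f1s = []
        for tr, va in splits:
            clf = _forest(n_trees, mult, p, seed, n_jobs)
            clf.fit(X[tr], y[tr])
            proba = clf.predict_proba(X[va])
            # align fold class order to global class order
            for ci, c in enumerate(clf.classes_):
                oof[va, classes.index(c)] = proba[:, ci]
            pred = clf.classes_[np.argmax(proba, axis=1)]
            f1s.append(f1_score(y[va], pred, labels=classes, average="macro",
                                zero_division=0))
        score = float(np.mean(f1s))
        key = (score, -n_trees, -mult)  # prefer smaller models on exact ties
        if best is None or key > best[0]:
            best = (key, (n_trees, mult), score)
            oof_best = oof

    (_, (n_trees, mult), inner_score) = best
    forest = _forest(n_trees, mult, p, seed, n_jobs)
    forest.fit(X, y)

    calibrators = {}
    for ci, c in enumerate(classes):
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(oof_best[:, ci], (y == c).astype(float))
        calibrators[c] = iso

    imp = forest.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    return TrainedModel(
        forest=forest, calibrators=calibrators, feature_ids=feature_ids,
        classes=classes,
        hyperparameters={"n_trees": n_trees, "max_features_multiplier": mult,
                         "inner_macro_f1": inner_score},
        importances=pd.Series(imp, index=feature_ids),
    )


def _align_features(model: TrainedModel, rel_abund: pd.DataFrame) -> np.ndarray:
    present = [f for f in model.feature_ids if f in rel_abund.index]
    if not present:
        raise ValueError("no overlapping features between model and table")
    extra = set(map(str, rel_abund.index)) - set(model.feature_ids)
    if extra:
        logger.warning("dropping %d features unknown to the model", len(extra))
    aligned = pd.DataFrame(0.0, index=model.feature_ids, columns=rel_abund.columns)
    aligned.loc[present] = rel_abund.loc[present].to_numpy()
    return aligned.to_numpy().T


def predict_proba(model: TrainedModel, rel_abund: pd.DataFrame) -> pd.DataFrame:
    """Calibrated, renormalized class probabilities (samples x classes)."""
    X = _align_features(model, rel_abund)
    raw = model.forest.predict_proba(X)
    order = [list(model.forest.classes_).index(c) for c in model.classes]
    raw = raw[:, order]
    # isotonic fits are weakly monotone (flat segments tie distinct raw
    # scores); an infinitesimal raw-score component keeps the ranking strict
    # so threshold-free metrics are unchanged by calibration
    cal = np.column_stack([model.calibrators[c].predict(raw[:, i])
                           for i, c in enumerate(model.classes)])
    cal = cal + 1e-9 * raw
    sums = cal.sum(axis=1, keepdims=True)
    flat = np.full_like(cal, 1.0 / cal.shape[1])
    cal = np.where(sums > 0, cal / np.where(sums == 0, 1.0, sums), flat)
    return pd.DataFrame(cal, index=rel_abund.columns, columns=model.classes)


def predict_labels(model: TrainedModel, rel_abund: pd.DataFrame) -> np.ndarray:
    proba = predict_proba(model, rel_abund)
    return proba.columns.to_numpy()[np.argmax(proba.to_numpy(), axis=1)]


# ---------------------------------------------------------------------------
# Metrics

def confusion(predicted, true, classes=None) -> pd.DataFrame:
    """Row-normalized confusion matrix (rows = true classes)."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if classes is None:
        classes = sorted(set(true) | set(predicted))
    mat = pd.DataFrame(0.0, index=classes, columns=classes)
    for t, p in zip(true, predicted):
        mat.loc[t, p] += 1
    sums = mat.sum(axis=1)
    for c in classes:
        if sums[c] > 0:
            mat.loc[c] /= sums[c]
    return mat


def f1_report(predicted, true, sample_weights=None,
              classes=None) -> MetricsReport:
    """Per-class and macro F1 + row-normalized confusion matrix.

    When ``sample_weights`` are given (e.g., study-inverse weights), the
    precision/recall counts underlying each per-class F1 are weighted;
    the mean is always the unweighted average over classes.
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    if classes is None:
        classes = sorted(set(true) | set(predicted))
    unknown = (set(predicted) | set(true)) - set(classes)
    if unknown:
        raise ValueError(f"label outside class set: {sorted(unknown)[0]!r}")
    per_class = f1_score(true, predicted, labels=classes, average=None,
                         sample_weight=sample_weights, zero_division=0)
    per_class_f1 = {c: float(v) for c, v in zip(classes, per_class)}
    mean_f1 = float(np.mean(per_class))
    weighted = mean_f1 if sample_weights is not None else None
    return MetricsReport(per_class_f1=per_class_f1, mean_f1=mean_f1,
                         confusion=confusion(predicted, true, classes),
                         weighted_f1=weighted)


def study_weights(meta: SampleMeta) -> pd.Series:
    """w_i = 1 / (number of samples in sample i's study); sums to n_studies."""
    sizes = meta.frame["study_id"].value_counts()
    return meta.frame["study_id"].map(lambda s: 1.0 / sizes[s]).rename("weight")


def mixture_auc(model: TrainedModel, eval_set: MixedEvalSet,
                validation: OtuTable) -> float:
    """AUC of the target-class probability: mixed positives vs unmixed negatives.

    Ties count one half (Mann-Whitney convention).
    """
    spec = eval_set.spec
    if not eval_set.positives or not eval_set.negatives:
        raise ValueError("mixture AUC undefined: empty positives or negatives")
    pos_counts = np.column_stack([p.counts for p in eval_set.positives])
    pos_rel = pd.DataFrame(pos_counts / pos_counts.sum(axis=0, keepdims=True),
                           index=validation.otu_ids,
                           columns=[f"mix{i}" for i in range(len(eval_set.positives))])
    neg = validation.select_samples(eval_set.negatives)
    neg_rel = pd.DataFrame(neg.counts / neg.counts.sum(axis=0, keepdims=True),
                           index=neg.otu_ids, columns=neg.sample_ids)
    scores_pos = predict_proba(model, pos_rel)[spec.target_site].to_numpy()
    scores_neg = predict_proba(model, neg_rel)[spec.target_site].to_numpy()
    y = np.concatenate([np.ones_like(scores_pos), np.zeros_like(scores_neg)])
    s = np.concatenate([scores_pos, scores_neg])
    return float(roc_auc_score(y, s))


def _best_f1_threshold(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Threshold (predict positive iff score >= t) maximizing binary F1.

    Candidates are all observed scores plus midpoints between adjacent
    distinct scores; among maximizers the highest threshold wins.
    """
    scores = np.sort(np.unique(np.concatenate([scores_pos, scores_neg])))
    mids = (scores[:-1] + scores[1:]) / 2.0 if scores.size > 1 else np.array([])
    candidates = np.concatenate([scores, mids])
    best_t, best_f1 = None, -1.0
    for t in np.sort(candidates):
        tp = float(np.sum(scores_pos >= t))
        fp = float(np.sum(scores_neg >= t))
        fn = float(np.sum(scores_pos < t))
        denom = 2 * tp + fp + fn
        f1 = (2 * tp / denom) if denom > 0 else 0.0
        if f1 >= best_f1:  # >= : ties broken toward the higher threshold
            best_f1, best_t = f1, float(t)
    return best_t


def optimize_thresholds(model: TrainedModel, eval_sets: list[MixedEvalSet],
                        training: OtuTable) -> ThresholdTable:
    """F1-optimal decision threshold per (target, background, fraction).

    The eval sets must be built from training-fold samples only: the
    forest and calibrators are never refit on mixtures, only the
    threshold is adjusted.
    """
    table = ThresholdTable()
    for es in eval_sets:
        if not es.positives:
            raise ValueError(f"spec {es.spec} has no positive mixtures")
        spec = es.spec
        pos_counts = np.column_stack([p.counts for p in es.positives])
        pos_rel = pd.DataFrame(pos_counts / pos_counts.sum(axis=0, keepdims=True),
                               index=training.otu_ids,
                               columns=[f"mix{i}" for i in range(len(es.positives))])
        neg = training.select_samples(es.negatives)
        neg_rel = pd.DataFrame(neg.counts / neg.counts.sum(axis=0, keepdims=True),
                               index=neg.otu_ids, columns=neg.sample_ids)
        sp = predict_proba(model, pos_rel)[spec.target_site].to_numpy()
        sn = predict_proba(model, neg_rel)[spec.target_site].to_numpy()
        table.thresholds[(spec.target_site, spec.background_site,
                          spec.fraction)] = _best_f1_threshold(sp, sn)
    return table


def build_threshold_table(model: TrainedModel, training: OtuTable,
                          meta: SampleMeta, fractions=None,
                          seed: int = 0) -> ThresholdTable:
    """Full grid: every ordered site pair x every fraction."""
    from .mixtures import default_fraction_grid
    fractions = default_fraction_grid() if fractions is None else fractions
    meta = meta.align(training)
    sites = sorted(pd.unique(meta.frame["body_site"]))
    specs = [MixtureSpec(t, b, f) for t in sites for b in sites if b != t
             for f in fractions]
    rng = np.random.default_rng(seed)
    eval_sets = build_mixture_grid(training, meta, specs, rng)
    return optimize_thresholds(model, eval_sets, training)


# ---------------------------------------------------------------------------
# Study-structure utilities

def biased_subset(meta: SampleMeta, bias_site: str, ratio: float = 0.1,
                  seed: int = 0) -> list:
    """All samples of one site plus a 10%-sized down-sample of every other."""
    sites = meta.frame["body_site"]
    if bias_site not in set(sites):
        raise ValueError(f"bias site {bias_site!r} not present")
    rng = np.random.default_rng(seed)
    bias_ids = list(meta.frame.index[sites == bias_site])
    quota = int(round(ratio * len(bias_ids)))
    out = list(bias_ids)
    for site in sorted(set(sites) - {bias_site}):
        ids = list(meta.frame.index[sites == site])
        if len(ids) <= quota:
            if len(ids) < quota:
                logger.warning("site %r smaller than quota %d; kept whole",
                               site, quota)
            out.extend(ids)
        else:
            pick = rng.choice(len(ids), size=quota, replace=False)
            out.extend(ids[i] for i in sorted(pick))
    return out


def learning_curve_by_study(rel_abund: pd.DataFrame, meta: SampleMeta,
                            heldout_rel: pd.DataFrame, heldout_meta: SampleMeta,
                            grid: HyperGrid | None = None, inner_k: int = 4,
                            seed: int = 0) -> pd.DataFrame:
    """Train on cumulative study sets (largest first, rest shuffled).

    Each point adds one study; the model is refit and scored on the fixed
    held-out set with both the unweighted macro-F1 and the
    study-inverse-weighted macro-F1.
    """
    meta_frame = meta.frame.loc[list(rel_abund.columns)]
    sizes = meta_frame["study_id"].value_counts()
    if len(sizes) < 2:
        raise ValueError("learning curve needs at least 2 studies")
    rng = np.random.default_rng(seed)
    rest = [s for s in sizes.index if s != sizes.index[0]]
    order = [sizes.index[0]] + list(rng.permutation(rest))
    w_all = study_weights(SampleMeta(heldout_meta.frame))
    rows = []
    included: list = []
    for study in order:
        included.append(study)
        ids = list(meta_frame.index[meta_frame["study_id"].isin(included)])
        sub = rel_abund[ids]
        labels = meta_frame.loc[ids, "body_site"].to_numpy()
        try:
            model = train_model(sub, labels, grid=grid, inner_k=inner_k, seed=seed)
        except ValueError:  # a class not yet covered by enough samples
            rows.append({"n_studies": len(included), "n_samples": len(ids),
                         "mean_f1": np.nan, "weighted_f1": np.nan})
            continue
        pred = predict_labels(model, heldout_rel)
        true = heldout_meta.frame.loc[list(heldout_rel.columns), "body_site"].to_numpy()
        classes = sorted(set(true))
        mean_f1 = float(np.mean(f1_score(true, pred, labels=classes,
                                         average=None, zero_division=0)))
        w = w_all.loc[list(heldout_rel.columns)].to_numpy()
        weighted_f1 = float(np.mean(f1_score(true, pred, labels=classes,
                                             average=None, sample_weight=w,
                                             zero_division=0)))
        rows.append({"n_studies": len(included), "n_samples": len(ids),
                     "mean_f1": mean_f1, "weighted_f1": weighted_f1})
    return pd.DataFrame(rows)


def feature_importance_overlap(model_a: TrainedModel, model_b: TrainedModel):
    """Overlap of predictive features (importance > 0) and their rank agreement.

    Returns (shared count, a-only count, b-only count, Spearman rho over
    the intersection; rho is None when undefined).
    """
    ia = model_a.importances
    ib = model_b.importances
    if set(ia.index) != set(ib.index):
        raise ValueError("models must share a feature universe")
    pa = set(ia.index[ia > 0])
    pb = set(ib.index[ib > 0])
    shared = sorted(pa & pb)
    rho = None
    if len(shared) >= 2:
        r = spearmanr(ia.loc[shared], ib.loc[shared]).statistic
        rho = None if np.isnan(r) else float(r)
    return len(shared), len(pa - pb), len(pb - pa), rho
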