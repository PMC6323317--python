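"""Three-stage stacked-generalization model for CPR classification.

Stage I trains three binary base models (random forest, extremely
randomized trees, gradient-boosted trees) per track — CPI pairs and CPI
triplets in parallel — to score whether a candidate belongs to any
evaluated CPR group.  Training-set scores are strictly out-of-fold: the
data are split into 10 disjoint stratified folds and each row is scored by
the model that never saw it; test rows are scored by averaging the 10 fold
models.  Scores are rank-normalized to [0, 1] and appended as meta-features.

Stage II trains six multiclass base models per track (the stage-I families
plus logistic regression, linear discriminant analysis and Gaussian naive
Bayes) over {CPR:3, 4, 5, 6, 9, other} on the augmented matrices.  Each
base model contributes its six class scores and its argmax class.  When a
pair spawned several triplets (multiple interaction words), the triplet
whose best evaluated-class score is highest represents the pair.

Stage III combines the original pair features with both tracks' stage-II
outputs and fits logistic regression, random forest, extremely randomized
trees and gradient boosting; class scores are averaged over the four and
the argmax is the final prediction.  Pairs predicted "other" emit nothing.

Out-of-fold bookkeeping (fold assignment per row) is retained so leakage
can be audited.  All randomness flows from one seed; fixed seeds give
byte-identical predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from xgboost import XGBClassifier

from cpimine.features import FeatureMatrix

OTHER = 0  # internal encoding of the non-evaluated "other" class
EVALUATED_CPR = (3, 4, 5, 6, 9)
CLASSES = (3, 4, 5, 6, 9, OTHER)

STAGE1_FAMILIES = ("rf", "et", "xgb")
STAGE2_FAMILIES = ("rf", "et", "xgb", "lr", "lda", "nb")
STAGE3_FAMILIES = ("lr", "rf", "et", "xgb")


@dataclass(frozen=True)
class StackerConfig:
    """Fold counts, learner sizes and interpretation switches."""

    n_folds: int = 10
    seed: int = 0
    n_estimators: int = 100
    xgb_estimators: int = 60
    use_stage1: bool = True        #: feed stage-I meta-features into stage II
    six_stage2: bool = True        #: six stage-II families (False: lr/lda/nb only)
    rank_normalized: bool = True   #: rank-transform stage-I scores (False: raw)
    triplet_selection: str = "max_eval"  #: or "one_minus_other"

    def stage2_families(self) -> tuple[str, ...]:
        return STAGE2_FAMILIES if self.six_stage2 else ("lr", "lda", "nb")


def _sub_seed(seed: int, *tags: str) -> int:
    h = seed & 0x7FFFFFFF
    for t in tags:
        for ch in t:
            h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def make_learner(family: str, seed: int, cfg: StackerConfig):
    """Instantiate one base learner family with deterministic seeding."""
    if family == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.n_estimators, random_state=seed, n_jobs=1,
            min_samples_leaf=2,
        )
    if family == "et":
        return ExtraTreesClassifier(
            n_estimators=cfg.n_estimators, random_state=seed, n_jobs=1,
            min_samples_leaf=2,
        )
    if family == "xgb":
        return XGBClassifier(
            n_estimators=cfg.xgb_estimators, max_depth=4, learning_rate=0.3,
            subsample=0.9, colsample_bytree=0.9, random_state=seed, n_jobs=1,
            verbosity=0, tree_method="hist", eval_metric="logloss",
        )
    if family == "lr":
        return LogisticRegression(max_iter=2000, C=1.0, random_state=seed)
    if family == "lda":
        return LinearDiscriminantAnalysis()
    if family == "nb":
        return GaussianNB()
    raise ValueError(f"unknown learner family {family!r}")


#: randomized-search distributions per family (lists are sampled uniformly)
DEFAULT_DISTRIBUTIONS: dict[str, dict[str, list]] = {
    "rf": {"n_estimators": [50, 100, 200, 400], "max_depth": [None, 6, 10, 16],
           "min_samples_leaf": [1, 2, 4, 8], "max_features": ["sqrt", 0.5, None]},
    "et": {"n_estimators": [50, 100, 200, 400], "max_depth": [None, 6, 10, 16],
           "min_samples_leaf": [1, 2, 4, 8], "max_features": ["sqrt", 0.5, None]},
    "xgb": {"n_estimators": [30, 60, 120, 250], "max_depth": [3, 4, 6, 8],
            "learning_rate": [0.05, 0.1, 0.3], "subsample": [0.7, 0.9, 1.0]},
    "lr": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "lda": {"solver": ["svd", "lsqr"]},
    "nb": {"var_smoothing": [1e-11, 1e-9, 1e-7]},
}


# ---------------------------------------------------------------------------
# Out-of-fold machinery
# ---------------------------------------------------------------------------

@dataclass
class OOFResult:
    """Out-of-fold probabilities with the fold bookkeeping for audits."""

    oof: np.ndarray                 # (n, n_classes)
    classes: np.ndarray             # class values, sorted
    fold_models: list
    fold_of_row: np.ndarray         # fold index that held out each row
    n_folds: int


class StratificationError(ValueError):
    pass


def _align_proba(proba: np.ndarray, model_classes, classes: np.ndarray) -> np.ndarray:
    out = np.zeros((proba.shape[0], len(classes)))
    pos = {c: j for j, c in enumerate(classes)}
    for j, c in enumerate(model_classes):
        out[:, pos[int(c)]] = proba[:, j]
    return out


def oof_scores(
    X: np.ndarray,
    y: np.ndarray,
    learner_factory: Callable[[], object],
    n_folds: int = 10,
    seed: int = 0,
) -> OOFResult:
    """Stratified out-of-fold class probabilities plus the k fold models.

    Each row's score comes from the model whose training folds excluded the
    row.  If the rarest class has fewer members than ``n_folds`` the fold
    count falls back to that member count (stratification fallback, with a
    warning); a class with fewer than 2 rows is an error because it cannot
    appear in both a training and a holdout fold.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        rare = classes[counts.argmin()]
        raise StratificationError(
            f"class {rare} has {counts.min()} row(s); at least 2 are needed "
            "for out-of-fold scoring — merge or drop it, or add data"
        )
    k = min(n_folds, int(counts.min()))
    if k < n_folds:
        warnings.warn(
            f"rarest class has {counts.min()} rows; using {k} folds instead of {n_folds}",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.zeros((len(y), len(classes)))
    fold_of_row = np.full(len(y), -1, dtype=int)
    models = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        m = learner_factory()
        m.fit(X[tr], y[tr])
        oof[te] = _align_proba(m.predict_proba(X[te]), m.classes_, classes)
        fold_of_row[te] = f
        models.append(m)
    return OOFResult(oof, classes, models, fold_of_row, k)


def predict_meta(X: np.ndarray, fold_models: Sequence, classes: np.ndarray) -> np.ndarray:
    """Average the fold models' class probabilities for unseen rows."""
    if not fold_models:
        raise ValueError("no fold models")
    acc = np.zeros((X.shape[0], len(classes)))
    for m in fold_models:
        acc += _align_proba(m.predict_proba(X), m.classes_, classes)
    return acc / len(fold_models)


def rank_normalize(scores: np.ndarray) -> np.ndarray:
    """Empirical-rank transform onto [0, 1]: (rank - 1) / (n - 1).

    Ties receive average ranks; order-preserving; a single score maps to
    0.5 (an all-tie vector likewise).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        return scores.copy()
    if n == 1:
        return np.array([0.5])
    return (rankdata(scores, method="average") - 1.0) / (n - 1.0)


# ---------------------------------------------------------------------------
# Stage blocks
# ---------------------------------------------------------------------------

def _binary_positive(oof: OOFResult) -> np.ndarray:
    pos = {int(c): j for j, c in enumerate(oof.classes)}
    return oof.oof[:, pos[1]]


def _stage2_block_names(families: Sequence[str], prefix: str) -> list[str]:
    names = []
    for fam in families:
        names += [f"{prefix}_{fam}_c{c}" for c in CLASSES]
        names += [f"{prefix}_{fam}_pred={c}" for c in CLASSES]
    return names


def _stage2_block(scores_by_family: dict[str, np.ndarray], families: Sequence[str],
                  prefix: str) -> FeatureMatrix:
    """Per base model: six class scores plus a one-hot of the argmax class."""
    n = next(iter(scores_by_family.values())).shape[0]
    cols, mats = [], []
    for fam in families:
        proba = scores_by_family[fam]
        onehot = np.zeros((n, len(CLASSES)))
        if n:
            onehot[np.arange(n), proba.argmax(axis=1)] = 1.0
        cols += [f"{prefix}_{fam}_c{c}" for c in CLASSES]
        cols += [f"{prefix}_{fam}_pred={c}" for c in CLASSES]
        mats += [proba, onehot]
    return FeatureMatrix(cols, np.hstack(mats) if mats else np.zeros((n, 0)))


def select_best_triplet(
    scores: np.ndarray,
    positions: Sequence[int],
    words: Sequence[str],
    mode: str = "max_eval",
) -> int:
    """Index of the representative triplet among one pair's triplet rows.

    ``scores`` is (n_triplets, 6) mean class scores over base models.  The
    winner maximizes the best evaluated-class score (or ``1 - other`` score
    with mode="one_minus_other"); ties break by earliest interaction-word
    position, then lexicographically smallest word.
    """
    if scores.shape[0] == 0:
        raise ValueError("select_best_triplet requires at least one triplet row")
    eval_cols = [CLASSES.index(c) for c in EVALUATED_CPR]
    if mode == "max_eval":
        key_score = scores[:, eval_cols].max(axis=1)
    elif mode == "one_minus_other":
        key_score = 1.0 - scores[:, CLASSES.index(OTHER)]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    order = sorted(
        range(scores.shape[0]),
        key=lambda i: (-key_score[i], positions[i], words[i]),
    )
    return order[0]


# ---------------------------------------------------------------------------
# The stacked model
# ---------------------------------------------------------------------------

def encode_six_class(labels: Sequence[int]) -> np.ndarray:
    """Map CPR labels 1-10 to the model's class space {3,4,5,6,9,other=0}."""
    arr = np.asarray(labels, dtype=int)
    return np.where(np.isin(arr, EVALUATED_CPR), arr, OTHER)


def _to_class_index(y6: np.ndarray) -> np.ndarray:
    """Index-encode the six-class target (base learners require 0..K-1)."""
    lut = {c: i for i, c in enumerate(CLASSES)}
    return np.array([lut[int(v)] for v in y6], dtype=int)


@dataclass
class _TrackArtifacts:
    stage1: dict[str, OOFResult] = field(default_factory=dict)
    stage2: dict[str, OOFResult] = field(default_factory=dict)
    registry: list[str] = field(default_factory=list)       # base features
    aug_registry: list[str] = field(default_factory=list)   # + stage-I meta


@dataclass
class StackedModel:
    """Fitted three-stage artifacts for both tracks, with registries and seeds."""

    config: StackerConfig
    tracks: dict[str, _TrackArtifacts] = field(default_factory=dict)
    stage3_models: dict[str, object] = field(default_factory=dict)
    stage3_registry: list[str] = field(default_factory=list)
    classes: tuple = CLASSES

    # ---------------- fitting ----------------

    @classmethod
    def fit(
        cls,
        pair_X: FeatureMatrix,
        pair_labels: Sequence[int],
        trip_X: FeatureMatrix,
        trip_labels: Sequence[int],
        trip_pair_index: Sequence[int],
        trip_positions: Sequence[int],
        trip_words: Sequence[str],
        config: StackerConfig = StackerConfig(),
    ) -> "StackedModel":
        """Fit stages I-III on labeled pair and triplet matrices.

        ``trip_pair_index`` maps each triplet row to its pair row;
        ``trip_positions``/``trip_words`` carry the interaction-word token
        index and surface for deterministic tie-breaking.
        """
        cfg = config
        model = cls(config=cfg)
        y6 = {"pair": encode_six_class(pair_labels), "triplet": encode_six_class(trip_labels)}
        mats = {"pair": pair_X, "triplet": trip_X}
        s2_oof_blocks: dict[str, FeatureMatrix] = {}

        for track in ("pair", "triplet"):
            art = _TrackArtifacts(registry=list(mats[track].columns))
            X = mats[track].values
            y_bin = (y6[track] != OTHER).astype(int)

            aug_cols, aug_vals = list(mats[track].columns), [X]
            if cfg.use_stage1:
                if len(np.unique(y_bin)) < 2:
                    raise StratificationError(
                        f"stage-I target degenerate on the {track} track: "
                        "all candidates share one binary label"
                    )
                for fam in STAGE1_FAMILIES:
                    seed = _sub_seed(cfg.seed, "s1", track, fam)
                    res = oof_scores(X, y_bin, lambda: make_learner(fam, seed, cfg),
                                     cfg.n_folds, seed)
                    art.stage1[fam] = res
                    score = _binary_positive(res)
                    if cfg.rank_normalized:
                        score = rank_normalize(score)
                    aug_cols.append(f"meta1_{fam}")
                    aug_vals.append(score[:, None])
            art.aug_registry = aug_cols
            Xa = np.hstack(aug_vals)

            y_idx = _to_class_index(y6[track])
            s2_scores: dict[str, np.ndarray] = {}
            for fam in cfg.stage2_families():
                seed = _sub_seed(cfg.seed, "s2", track, fam)
                res = oof_scores(Xa, y_idx, lambda: make_learner(fam, seed, cfg),
                                 cfg.n_folds, seed)
                art.stage2[fam] = res
                s2_scores[fam] = _align_proba(res.oof, res.classes, np.arange(len(CLASSES)))
            s2_oof_blocks[track] = _stage2_block(s2_scores, cfg.stage2_families(), f"s2_{track}")
            model.tracks[track] = art

        combined = cls._combine_stage3(
            model, pair_X, s2_oof_blocks["pair"], s2_oof_blocks["triplet"],
            np.asarray(trip_pair_index, int), list(trip_positions), list(trip_words),
        )
        model.stage3_registry = combined.columns
        y_idx = _to_class_index(y6["pair"])
        for fam in STAGE3_FAMILIES:
            seed = _sub_seed(cfg.seed, "s3", fam)
            m = make_learner(fam, seed, cfg)
            m.fit(combined.values, y_idx)
            model.stage3_models[fam] = m
        return model

    # ---------------- shared stage-III assembly ----------------

    def _combine_stage3(
        self,
        pair_X: FeatureMatrix,
        pair_block: FeatureMatrix,
        trip_block: FeatureMatrix,
        trip_pair_index: np.ndarray,
        trip_positions: list[int],
        trip_words: list[str],
    ) -> FeatureMatrix:
        """Original pair features + pair stage-II block + selected triplet
        stage-II block + a no-triplet indicator."""
        cfg = self.config
        fams = cfg.stage2_families()
        n_pairs = pair_X.n_rows
        sel_block = np.zeros((n_pairs, len(trip_block.columns)))
        missing = np.ones((n_pairs, 1))
        score_cols = {
            fam: [trip_block.columns.index(f"s2_triplet_{fam}_c{c}") for c in CLASSES]
            for fam in fams
        }
        by_pair: dict[int, list[int]] = {}
        for t, p in enumerate(trip_pair_index):
            by_pair.setdefault(int(p), []).append(t)
        for p, rows in by_pair.items():
            mean_scores = np.zeros((len(rows), len(CLASSES)))
            for fam in fams:
                mean_scores += trip_block.values[np.ix_(rows, score_cols[fam])]
            mean_scores /= len(fams)
            best = select_best_triplet(
                mean_scores,
                [trip_positions[r] for r in rows],
                [trip_words[r] for r in rows],
                cfg.triplet_selection,
            )
            sel_block[p] = trip_block.values[rows[best]]
            missing[p, 0] = 0.0
        cols = (list(pair_X.columns) + list(pair_block.columns)
                + [f"sel_{c}" for c in trip_block.columns] + ["no_triplet"])
        vals = np.hstack([pair_X.values, pair_block.values, sel_block, missing])
        return FeatureMatrix(cols, vals)

    # ---------------- prediction ----------------

    def _track_stage2_scores(self, track: str, X: FeatureMatrix) -> dict[str, np.ndarray]:
        """Stage-II class scores for new rows of one track (fold-averaged)."""
        art = self.tracks[track]
        if list(X.columns) != art.registry:
            raise ValueError(f"{track} feature registry mismatch at predict time")
        cfg = self.config
        vals = [X.values]
        if cfg.use_stage1:
            for fam in STAGE1_FAMILIES:
                res = art.stage1[fam]
                proba = predict_meta(X.values, res.fold_models, res.classes)
                score = proba[:, list(res.classes).index(1)]
                if cfg.rank_normalized:
                    score = rank_normalize(score)
                vals.append(score[:, None])
        Xa = np.hstack(vals)
        out = {}
        for fam in cfg.stage2_families():
            res = art.stage2[fam]
            proba = predict_meta(Xa, res.fold_models, res.classes)
            out[fam] = _align_proba(proba, res.classes, np.arange(len(CLASSES)))
        return out

    def predict(
        self,
        pair_X: FeatureMatrix,
        trip_X: FeatureMatrix,
        trip_pair_index: Sequence[int],
        trip_positions: Sequence[int],
        trip_words: Sequence[str],
    ) -> dict[str, np.ndarray]:
        """Final per-pair class and score, plus per-stage diagnostics.

        Returns ``classes`` (values in {3,4,5,6,9,0}; 0 = other), ``scores``
        (the winning class's averaged stage-III score), ``class_scores``
        (n_pairs x 6), and the stage-II argmax per track
        (``stage2_pair``/``stage2_triplet``, the latter after triplet
        selection; pairs with no triplet fall back to "other").
        """
        cfg = self.config
        s2_pair = self._track_stage2_scores("pair", pair_X)
        s2_trip = self._track_stage2_scores("triplet", trip_X)
        pair_block = _stage2_block(s2_pair, cfg.stage2_families(), "s2_pair")
        trip_block = _stage2_block(s2_trip, cfg.stage2_families(), "s2_triplet")
        combined = self._combine_stage3(
            pair_X, pair_block, trip_block,
            np.asarray(trip_pair_index, int), list(trip_positions), list(trip_words),
        )
        if combined.columns != self.stage3_registry:
            raise ValueError("stage-III registry mismatch at predict time")
        acc = np.zeros((pair_X.n_rows, len(CLASSES)))
        for fam in STAGE3_FAMILIES:
            m = self.stage3_models[fam]
            acc += _align_proba(m.predict_proba(combined.values), m.classes_,
                                np.arange(len(CLASSES)))
        acc /= len(STAGE3_FAMILIES)
        idx = acc.argmax(axis=1)
        classes = np.array([CLASSES[i] for i in idx])

        fams = cfg.stage2_families()
        mean_pair = sum(s2_pair[f] for f in fams) / len(fams)
        stage2_pair = np.array([CLASSES[i] for i in mean_pair.argmax(axis=1)])
        stage2_trip = np.full(pair_X.n_rows, OTHER)
        by_pair: dict[int, list[int]] = {}
        for t, p in enumerate(np.asarray(trip_pair_index, int)):
            by_pair.setdefault(int(p), []).append(t)
        mean_trip = sum(s2_trip[f] for f in fams) / len(fams)
        for p, rows in by_pair.items():
            best = select_best_triplet(
                mean_trip[rows],
                [list(trip_positions)[r] for r in rows],
                [list(trip_words)[r] for r in rows],
                cfg.triplet_selection,
            )
            stage2_trip[p] = CLASSES[mean_trip[rows[best]].argmax()]
        return {
            "classes": classes,
            "scores": acc[np.arange(len(idx)), idx],
            "class_scores": acc,
            "stage2_pair": stage2_pair,
            "stage2_triplet": stage2_trip,
        }

    # ---------------- persistence ----------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model bundle to one file."""
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "StackedModel":
        model = joblib.load(Path(path))
        if not isinstance(model, StackedModel):
            raise TypeError(f"{path} does not contain a StackedModel bundle")
        return model


# ---------------------------------------------------------------------------
# Hyper-parameter search and feature selection
# ---------------------------------------------------------------------------

def _cv_f1(estimator, X: np.ndarray, y: np.ndarray, cv: int, seed: int) -> float:
    """Mean CV F1: binary F1 for two-class targets, micro over the evaluated
    classes otherwise (the "other" class is excluded from the average).

    Labels may be CPR values or already index-encoded; they are re-encoded
    to 0..K-1 internally for learner compatibility.
    """
    y = np.asarray(y)
    uniq, counts = np.unique(y, return_counts=True)
    binary = len(uniq) == 2 and set(uniq) <= {0, 1}
    y_enc = np.searchsorted(uniq, y)
    eval_enc = [int(np.searchsorted(uniq, c)) for c in EVALUATED_CPR if c in uniq]
    k = min(cv, int(counts.min()))
    if k < 2:
        raise StratificationError("a class has fewer than 2 rows; cannot cross-validate")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y_enc):
        m = clone(estimator)
        m.fit(X[tr], y_enc[tr])
        pred = m.predict(X[te])
        if binary:
            scores.append(_sk_f1(y_enc[te], pred, zero_division=0))
        else:
            labels = eval_enc or list(range(len(uniq)))
            scores.append(_sk_f1(y_enc[te], pred, labels=labels, average="micro",
                                 zero_division=0))
    return float(np.mean(scores))


def randomized_search(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    n_settings: int = 10,
    cv: int = 3,
    seed: int = 0,
    distributions: dict[str, list] | None = None,
    config: StackerConfig = StackerConfig(),
) -> tuple[dict, float]:
    """Randomized hyper-parameter search: ``n_settings`` draws, k-fold CV.

    Returns (best parameter setting, its mean CV F1); deterministic under a
    fixed seed, first-drawn wins ties.
    """
    if n_settings < 1:
        raise ValueError("n_settings must be >= 1")
    dist = distributions if distributions is not None else DEFAULT_DISTRIBUTIONS[family]
    sampler = ParameterSampler(dist, n_iter=min(n_settings, _n_grid(dist)),
                               random_state=seed)
    best_params, best_score = None, -np.inf
    for params in sampler:
        est = make_learner(family, _sub_seed(seed, "rs", family), config)
        est.set_params(**params)
        score = _cv_f1(est, X, y, cv, seed)
        if score > best_score:
            best_params, best_score = params, score
    return best_params, best_score


def _n_grid(dist: dict[str, list]) -> int:
    n = 1
    for v in dist.values():
        n *= len(v)
    return n


def rfe_select(
    family: str,
    X: FeatureMatrix,
    y: np.ndarray,
    cv: int = 3,
    seed: int = 0,
    step: int = 1,
    config: StackerConfig = StackerConfig(),
) -> list[str]:
    """Recursive feature elimination with cross-validation.

    Recursively drops the least-important features (by impurity importance
    or coefficient magnitude) and keeps the subset size with the best mean
    CV F1.  Returns the selected column names.  Learners without
    importances (naive Bayes, plain LDA) are rejected with a pointer to a
    tree or linear surrogate.
    """
    est = make_learner(family, _sub_seed(seed, "rfe", family), config)
    if not (hasattr(est, "feature_importances_") or hasattr(est, "coef_")
            or family in ("rf", "et", "xgb", "lr")):
        raise ValueError(
            f"{family} exposes no importances/coefficients; run RFE with a "
            "surrogate such as 'rf' or 'lr' and reuse the selected columns"
        )
    if len(X.columns) < 2:
        return list(X.columns)  # nothing to eliminate
    y = np.asarray(y)
    uniq = np.unique(y)
    binary = len(uniq) == 2 and set(uniq) <= {0, 1}
    y_enc = np.searchsorted(uniq, y)
    if binary:
        scoring = "f1"
    else:
        from sklearn.metrics import make_scorer

        labels = [int(np.searchsorted(uniq, c)) for c in EVALUATED_CPR if c in uniq]
        scoring = make_scorer(_sk_f1, labels=labels or list(range(len(uniq))),
                              average="micro", zero_division=0)
    selector = RFECV(
        est, step=step, scoring=scoring,
        cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
        min_features_to_select=1, n_jobs=1,
    )
    selector.fit(X.values, y_enc)
    return [c for c, keep in zip(X.columns, selector.support_) if keep]
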