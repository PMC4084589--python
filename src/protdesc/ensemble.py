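"""Per-descriptor SVM training and weighted-sum-rule fusion.

Every descriptor table trains its own radial-basis SVM: features are
linearly normalized to [0, 1] using the training rows only, and the cost /
kernel-width hyperparameters are chosen by an internal cross-validated grid
search that never sees the test rows.  Classifier scores (class-posterior
estimates by default, so heterogeneous SVMs are commensurable) are combined
by the weighted sum rule.  The FUS1 / FUS2 recipes fix the component list
and weights used across every dataset:

    FUS1 = 2*AAS(AC) + 2*PSSM(SAN) + 4*PSSM(PP) + PSSM(LHF_G) + PSSM(BGR)
           + PSSM(TGR) + SMR(PP) + SMR(BGR)
    FUS2 = FUS1 + 2*DM(LPQ_G)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

#: cost grid 2^-5 .. 2^15 in powers of 4
DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))
#: kernel-width grid 2^-15 .. 2^3 in powers of 4
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))


# ---------------------------------------------------------------------------
# [0,1] normalization learned from training rows only

@dataclass
class NormalizerState:
    """Per-column min and max learned from the training rows."""

    col_min: np.ndarray
    col_max: np.ndarray


def fit_normalizer(train: np.ndarray) -> NormalizerState:
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("cannot fit a normalizer on an empty table")
    return NormalizerState(col_min=train.min(axis=0),
                           col_max=train.max(axis=0))


def apply_normalizer(state: NormalizerState, table: np.ndarray) -> np.ndarray:
    """Map columns to [0, 1] by the training range; out-of-range test
    values are clipped, constant training columns map to 0."""
    table = np.asarray(table, dtype=float)
    span = state.col_max - state.col_min
    out = np.zeros_like(table)
    ok = span > 0
    out[:, ok] = (table[:, ok] - state.col_min[ok]) / span[ok]
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# single-descriptor SVM

@dataclass
class TrainedScorer:
    """One descriptor's normalizer + tuned SVM.

    ``calibration_ok`` records whether the internal Platt calibration agrees
    with the decision rule on the training data; when it does not (a known
    failure mode of the sigmoid fit on near-degenerate margins), scoring
    falls back to a softmax of the one-vs-all decision values, which keeps
    the ranking of the margin classifier on a common [0, 1] scale.
    """

    normalizer: NormalizerState
    model: SVC
    classes: np.ndarray
    best_params: dict
    use_probabilities: bool
    calibration_ok: bool = True


def _softmax_scores(model: SVC, x: np.ndarray) -> np.ndarray:
    df = model.decision_function(x)
    if df.ndim == 1:
        df = np.column_stack([-df, df])
    df = df - df.max(axis=1, keepdims=True)
    e = np.exp(df)
    return e / e.sum(axis=1, keepdims=True)


def train_classifier(train: np.ndarray, labels, seed: int = 0, *,
                     c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                     n_folds: int = 5, use_probabilities: bool = True
                     ) -> TrainedScorer:
    """Fit a radial-basis SVM on one descriptor table.

    The [0,1] normalizer and the grid search (ties broken toward the
    smallest cost, then the smallest width) use the training rows only;
    multiclass problems are handled one-versus-all.
    """
    train = np.asarray(train, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    norm = fit_normalizer(train)
    x = apply_normalizer(norm, train)
    folds = min(n_folds, int(np.bincount(
        np.searchsorted(classes, labels)).min()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True,
                         random_state=seed)
    # dict order (C outer, gamma inner, both ascending) makes GridSearchCV's
    # first-best tie-break pick the smallest cost then the smallest width
    search = GridSearchCV(
        SVC(kernel="rbf", decision_function_shape="ovr", random_state=seed),
        {"C": list(c_grid), "gamma": list(gamma_grid)},
        cv=cv, scoring="accuracy", n_jobs=None)
    search.fit(x, labels)
    model = SVC(kernel="rbf", probability=use_probabilities,
                decision_function_shape="ovr", random_state=seed,
                **search.best_params_)
    import warnings
    with warnings.catch_warnings():
        # sklearn 1.9 deprecation chatter for SVC(probability=True); the
        # Platt-scaled posteriors are exactly what the sum rule consumes
        warnings.filterwarnings("ignore", category=FutureWarning)
        model.fit(x, labels)
    calibration_ok = True
    if use_probabilities:
        proba_pred = model.classes_[np.argmax(model.predict_proba(x),
                                              axis=1)]
        calibration_ok = bool(
            (proba_pred == model.predict(x)).mean() >= 0.95)
    return TrainedScorer(normalizer=norm, model=model, classes=classes,
                         best_params=dict(search.best_params_),
                         use_probabilities=use_probabilities,
                         calibration_ok=calibration_ok)


def predict_scores(scorer: TrainedScorer, table: np.ndarray) -> np.ndarray:
    """Per-class score matrix (samples x classes, columns in sorted class
    order): posterior estimates by default, raw one-vs-all decision values
    when the scorer was trained with ``use_probabilities=False``."""
    table = np.asarray(table, dtype=float)
    if table.shape[1] != len(scorer.normalizer.col_min):
        raise ValueError(
            f"feature dimension {table.shape[1]} does not match the "
            f"trained descriptor ({len(scorer.normalizer.col_min)})")
    x = apply_normalizer(scorer.normalizer, table)
    if scorer.use_probabilities:
        if scorer.calibration_ok:
            return scorer.model.predict_proba(x)
        return _softmax_scores(scorer.model, x)
    df = scorer.model.decision_function(x)
    if df.ndim == 1:  # binary: one margin, expand to per-class columns
        return np.column_stack([-df, df])
    return df


# ---------------------------------------------------------------------------
# weighted sum rule

def weighted_sum_fusion(score_matrices, weights=None) -> np.ndarray:
    """Elementwise weighted sum of per-class score matrices."""
    mats = [np.asarray(m, dtype=float) for m in score_matrices]
    if not mats:
        raise ValueError("no score matrices to fuse")
    if weights is None:
        weights = np.ones(len(mats))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(mats):
        raise ValueError("one weight per score matrix required")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("score matrices must share one shape")
    return sum(w * m for w, m in zip(weights, mats))


@dataclass
class FusedScorer:
    """A pool of trained scorers with their per-descriptor feature tables
    keyed by component name."""

    scorers: list[TrainedScorer]
    weights: np.ndarray

    def predict(self, tables) -> np.ndarray:
        scores = [predict_scores(s, t) for s, t in zip(self.scorers, tables)]
        return weighted_sum_fusion(scores, self.weights)


def compute_property_tables(records, descriptor_op, properties
                            ) -> list[np.ndarray]:
    """One feature table per property: rows are records, columns the
    descriptor ``descriptor_op(record, property)``."""
    return [np.vstack([np.asarray(descriptor_op(r, d)) for r in records])
            for d in properties]


def property_ensemble(tables, labels, seed: int = 0,
                      **svm_kwargs) -> FusedScorer:
    """One classifier per physicochemical property on that property's
    descriptor table (one table per property, e.g. from
    :func:`compute_property_tables`), fused with unit weights."""
    tables = list(tables)
    if not tables:
        raise ValueError("property ensemble needs at least one property")
    scorers = [train_classifier(tab, labels, seed=seed, **svm_kwargs)
               for tab in tables]
    return FusedScorer(scorers=scorers, weights=np.ones(len(scorers)))


# ---------------------------------------------------------------------------
# ensemble recipes

@dataclass
class EnsembleSpec:
    """An ordered list of (representation, descriptor, weight) components
    for weighted-sum-rule fusion."""

    name: str
    components: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(w > 0 for _, _, w in self.components):
            raise ValueError("ensemble needs at least one positive weight")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.components])


def build_fus1() -> EnsembleSpec:
    """The 8-component FUS1 recipe with weights (2,2,4,1,1,1,1,1)."""
    return EnsembleSpec("FUS1", [
        ("AAS", "AC", 2.0),
        ("PSSM", "SAN", 2.0),
        ("PSSM", "PP", 4.0),
        ("PSSM", "LHF_G", 1.0),
        ("PSSM", "BGR", 1.0),
        ("PSSM", "TGR", 1.0),
        ("SMR", "PP", 1.0),
        ("SMR", "BGR", 1.0),
    ])


def build_fus2(have_backbone: bool = True) -> EnsembleSpec:
    """FUS2 = FUS1 + 2 x DM(LPQ_G); requires backbone coordinates."""
    if not have_backbone:
        raise ValueError("FUS2 includes a distance-matrix component and "
                         "needs backbone coordinates")
    spec = build_fus1()
    return EnsembleSpec("FUS2", spec.components + [("DM", "LPQ_G", 2.0)])


def build_ng_fusion() -> EnsembleSpec:
    """The five reduced-alphabet n-gram classifiers fused with weights
    (1, 1, 1, 0.5, 0.25) in A1..A5 order."""
    weights = (1.0, 1.0, 1.0, 0.5, 0.25)
    return EnsembleSpec("NG", [("AAS", f"NG_A{i + 1}", w)
                               for i, w in enumerate(weights)])
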