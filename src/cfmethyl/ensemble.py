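"""Split-ensemble penalized logistic-regression cancer classifier.

The classifier is an average of many (by default 1000) L1-penalized logistic
models.  The training set is repeatedly split 50/50 into a model-building
half and a model-validation half; each building half fits one component
(penalty strength chosen by internal cross-validation restricted to the
building samples), and each training sample's final score is the mean of the
probabilities it received whenever it sat in a validation half.  A decision
cutoff is then frozen at the training specificity closest to a target
(default 95%).  Held-out samples are scored by *all* components and their
mean is compared to the frozen cutoff.

Each component scores a sample with the logistic transform

    P = 1 / (1 + exp(-(sum_i M_i * X_i + B)))

over the modeled regions' AMF values X_i.  The orientation is
cancer-positive: larger linear predictor means larger P means cancer.  (An
equivalent published form writes the logistic of the negated predictor; the
two differ only by a global sign flip of (M, B).)

Regions with a missing AMF in any training sample are dropped before
modeling, so every component sees a complete matrix; at prediction time a
missing modeled region is a hard error rather than an imputation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from ._rng import substream, substream_seed

__all__ = [
    "EnsembleConfig", "EnsembleComponent", "EnsembleModel",
    "drop_incomplete_regions", "make_splits", "fit_component", "score",
    "fit_ensemble", "choose_cutoff", "apply_ensemble", "model_checksum",
]

CANCER_GROUPS = ("pre_dx", "post_dx")


@dataclass
class EnsembleConfig:
    """Training configuration.

    ``penalty_grid`` holds L1 penalty *strengths* (lambda), log-spaced
    1e-1..1e4 by default; internally converted to scikit-learn's inverse
    regularization C = 1/lambda.  For ~100 training samples over bounded
    [0, 1] features, strengths below 0.1 are effectively unpenalized, so the
    grid bottoms out there.  ``base_learner`` may be ``logistic_regression``
    (L1, liblinear) or ``linear_discriminant``.
    """

    n_iter: int = 1000
    penalty_grid: tuple[float, ...] = tuple(np.logspace(-1, 4, 10))
    cv_folds: int = 5
    stratified_splits: bool = True
    base_learner: str = "logistic_regression"
    target_specificity: float = 0.95
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.base_learner not in ("logistic_regression", "linear_discriminant"):
            raise ValueError(f"unknown base_learner {self.base_learner!r}")
        if not 0.0 < self.target_specificity < 1.0:
            raise ValueError("target_specificity must be in (0, 1)")

    def config_hash(self) -> str:
        blob = json.dumps({
            "n_iter": self.n_iter,
            "penalty_grid": [float(c) for c in self.penalty_grid],
            "cv_folds": self.cv_folds,
            "stratified_splits": self.stratified_splits,
            "base_learner": self.base_learner,
            "target_specificity": self.target_specificity,
            "max_iter": self.max_iter,
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class EnsembleComponent:
    coef: np.ndarray        # one linear coefficient per modeled region
    intercept: float
    penalty: float | None   # chosen L1 strength (None for LDA)
    split_index: int


@dataclass
class EnsembleModel:
    """Frozen ensemble: region order, components, split plan, cutoff."""

    region_ids: list[str]
    components: list[EnsembleComponent]
    split_plan: list[tuple[list[int], list[int]]]   # (build, validation) indices
    train_sample_ids: list[str]
    cutoff: float
    base_learner: str
    seed: int
    config_hash: str = ""

    def to_json(self) -> str:
        comps = []
        for c in self.components:
            nz = np.flatnonzero(c.coef)
            comps.append({
                "coef": {int(i): float(c.coef[i]) for i in nz},
                "intercept": float(c.intercept),
                "penalty": None if c.penalty is None else float(c.penalty),
                "split_index": c.split_index,
            })
        return json.dumps({
            "region_ids": self.region_ids,
            "n_regions": len(self.region_ids),
            "components": comps,
            "split_plan": [[list(map(int, b)), list(map(int, v))] for b, v in self.split_plan],
            "train_sample_ids": self.train_sample_ids,
            "cutoff": float(self.cutoff),
            "base_learner": self.base_learner,
            "seed": int(self.seed),
            "config_hash": self.config_hash,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        d = json.loads(text)
        n = d["n_regions"]
        comps = []
        for c in d["components"]:
            coef = np.zeros(n)
            for i, v in c["coef"].items():
                coef[int(i)] = v
            comps.append(EnsembleComponent(coef, c["intercept"], c["penalty"], c["split_index"]))
        return cls(d["region_ids"], comps,
                   [(b, v) for b, v in d["split_plan"]],
                   d["train_sample_ids"], d["cutoff"], d["base_learner"],
                   d["seed"], d.get("config_hash", ""))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def model_checksum(model: EnsembleModel) -> str:
    """SHA-256 over the canonical JSON serialization of the frozen model."""
    return hashlib.sha256(model.to_json().encode()).hexdigest()


# ---------------------------------------------------------------------------


def drop_incomplete_regions(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the regions with no MISSING value in any provided sample."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty AMF matrix")
    out = matrix.dropna(axis=0)
    if out.shape[0] == 0:
        raise ValueError("all regions have missing values; nothing to model")
    return out


def make_splits(train_ids: list[str], y: np.ndarray, n_iter: int, seed: int,
                stratified: bool = True) -> list[tuple[list[int], list[int]]]:
    """Plan of ``n_iter`` 50/50 splits into building/validation halves.

    Returns index pairs into ``train_ids``.  Stratified splits keep both
    classes on both sides; half sizes differ by at most one.
    """
    y = np.asarray(y)
    n = len(train_ids)
    if n < 4:
        raise ValueError("need at least 4 training samples")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training set")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    rng = substream(seed, "split")
    plan = []
    for it in range(n_iter):
        if stratified:
            build: list[int] = []
            # alternate ceil/floor across classes so halves differ by <= 1
            for k, cls in enumerate(classes):
                idx = np.flatnonzero(y == cls)
                perm = rng.permutation(idx)
                take = (len(idx) + (1 if k % 2 == 0 else 0)) // 2
                build.extend(perm[:take])
            build_set = set(build)
        else:
            perm = rng.permutation(n)
            build_set = set(perm[: n // 2])
        b = sorted(build_set)
        v = sorted(set(range(n)) - build_set)
        plan.append((b, v))
    return plan


def fit_component(X_build: np.ndarray, y_build: np.ndarray, cfg: EnsembleConfig,
                  split_index: int = 0) -> EnsembleComponent:
    """Fit one ensemble component on a model-building half.

    Logistic components use an L1 penalty whose strength is chosen by
    stratified cross-validation restricted to the building samples
    (scikit-learn's LogisticRegressionCV with the liblinear solver).
    """
    y_build = np.asarray(y_build)
    if len(np.unique(y_build)) < 2:
        raise ValueError("model-building set contains a single class")
    if np.isnan(X_build).any():
        raise ValueError("MISSING values in model-building matrix")
    rs = substream_seed(cfg.seed, f"cv:{split_index}") % (2**32 - 1)

    if cfg.base_learner == "linear_discriminant":
        lda = LinearDiscriminantAnalysis()
        lda.fit(X_build, y_build)
        return EnsembleComponent(lda.coef_.ravel().copy(), float(lda.intercept_[0]),
                                 None, split_index)

    n_folds = int(min(cfg.cv_folds, np.bincount(y_build.astype(int)).min()))
    n_folds = max(n_folds, 2)
    # Ascending C = strongest penalty first, so CV-score ties resolve to the
    # most parsimonious model.  The grid search runs at liblinear's standard
    # iteration budget; only the kept component must be fully converged.
    Cs = sorted(1.0 / lam for lam in cfg.penalty_grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search = LogisticRegressionCV(
            Cs=Cs, l1_ratios=[1.0], solver="liblinear", scoring="accuracy",
            cv=StratifiedKFold(n_folds, shuffle=True, random_state=rs),
            max_iter=100, refit=False, random_state=rs,
            intercept_scaling=100.0,   # keep the L1 penalty off the intercept
        )
        search.fit(X_build, y_build)
    C_chosen = float(np.atleast_1d(search.C_)[0])
    for max_iter in (cfg.max_iter, cfg.max_iter * 10):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(C=C_chosen, l1_ratio=1.0, solver="liblinear",
                                     max_iter=max_iter, random_state=rs,
                                     intercept_scaling=100.0)
            clf.fit(X_build, y_build)
        if int(np.max(clf.n_iter_)) < max_iter:
            break
    else:
        raise RuntimeError("logistic component failed to converge after retry")
    return EnsembleComponent(clf.coef_.ravel().copy(), float(clf.intercept_[0]),
                             1.0 / C_chosen, split_index)


def score(component: EnsembleComponent, x: np.ndarray) -> float:
    """Probability of cancer for one complete AMF vector."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("MISSING value in AMF vector passed to score()")
    if x.shape[0] != component.coef.shape[0]:
        raise ValueError("AMF vector length does not match component coefficients")
    return float(expit(x @ component.coef + component.intercept))


def _component_scores(component: EnsembleComponent, X: np.ndarray) -> np.ndarray:
    return expit(X @ component.coef + component.intercept)


def choose_cutoff(healthy_train_scores, target_specificity: float = 0.95) -> float:
    """Decision cutoff achieving training specificity closest to the target.

    Candidates are midpoints between adjacent distinct sorted healthy scores
    plus one candidate below the minimum and one above the maximum; achieved
    specificity is the fraction of healthy scores strictly below the
    candidate.  Ties on |specificity - target| break toward higher
    specificity.
    """
    s = np.asarray(list(healthy_train_scores), dtype=float)
    if s.size == 0:
        raise ValueError("no healthy training scores")
    u = np.unique(s)
    candidates = [u[0] / 2.0 if u[0] > 0 else u[0] - 1e-9]
    candidates.extend((u[:-1] + u[1:]) / 2.0)
    candidates.append((u[-1] + 1.0) / 2.0 if u[-1] < 1 else u[-1] + 1e-9)
    best = None
    for c in candidates:
        spec = float(np.mean(s < c))
        key = (abs(spec - target_specificity), -spec)
        if best is None or key < best[0]:
            best = (key, c)
    return float(best[1])


def _labels_from_meta(meta: pd.DataFrame) -> np.ndarray:
    return meta["group"].isin(CANCER_GROUPS).to_numpy().astype(int)


def fit_ensemble(train_matrix: pd.DataFrame, train_meta: pd.DataFrame,
                 cfg: EnsembleConfig | None = None,
                 y: np.ndarray | None = None
                 ) -> tuple[EnsembleModel, pd.DataFrame]:
    """Train and freeze the full ensemble on the training set.

    Returns the frozen model and the training score records (sample_id,
    final_score, n_components, call).  ``y`` overrides the labels derived
    from ``train_meta`` (used by permutation controls); the healthy class for
    the cutoff is always y == 0.
    """
    cfg = cfg or EnsembleConfig()
    ids = train_meta["sample_id"].tolist()
    missing_cols = [s for s in ids if s not in train_matrix.columns]
    if missing_cols:
        raise KeyError(f"training samples absent from AMF matrix: {missing_cols[:5]}")
    matrix = drop_incomplete_regions(train_matrix[ids])
    if y is None:
        y = _labels_from_meta(train_meta)
    y = np.asarray(y, dtype=int)

    plan = make_splits(ids, y, cfg.n_iter, cfg.seed, cfg.stratified_splits)
    X = matrix.to_numpy().T          # samples x regions
    n = len(ids)
    sums = np.zeros(n)
    hits = np.zeros(n, dtype=int)
    components = []
    for k, (b, v) in enumerate(plan):
        comp = fit_component(X[b], y[b], cfg, split_index=k)
        components.append(comp)
        sums[v] += _component_scores(comp, X[v])
        hits[v] += 1
    if (hits == 0).any():
        never = [ids[i] for i in np.flatnonzero(hits == 0)]
        raise RuntimeError(f"samples never appeared in any validation set: {never}")
    final = sums / hits
    cutoff = choose_cutoff(final[y == 0], cfg.target_specificity)

    model = EnsembleModel(
        region_ids=matrix.index.tolist(), components=components, split_plan=plan,
        train_sample_ids=ids, cutoff=cutoff, base_learner=cfg.base_learner,
        seed=cfg.seed, config_hash=cfg.config_hash(),
    )
    records = pd.DataFrame({
        "sample_id": ids,
        "final_score": final,
        "n_components": hits,
        "call": np.where(final >= cutoff, "cancer", "healthy"),
    })
    return model, records


def apply_ensemble(model: EnsembleModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Score every sample in ``matrix`` with all components of a frozen model.

    Every modeled region must be present and non-missing for every sample;
    calls use score >= cutoff (a score exactly at the cutoff is a cancer
    call).
    """
    absent = [r for r in model.region_ids if r not in matrix.index]
    if absent:
        raise KeyError(f"modeled regions absent from matrix: {absent[:5]}")
    sub = matrix.loc[model.region_ids]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()][0]
        region = sub.index[sub[bad].isna()][0]
        raise ValueError(f"MISSING AMF for modeled region {region} in sample {bad}")
    X = sub.to_numpy().T
    scores = np.mean([_component_scores(c, X) for c in model.components], axis=0)
    return pd.DataFrame({
        "sample_id": list(sub.columns),
        "final_score": scores,
        "n_components": len(model.components),
        "call": np.where(scores >= model.cutoff, "cancer", "healthy"),
    })
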