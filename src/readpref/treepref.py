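"""Gradient-boosted-trees preference model with cross-validated deviance R².

The nonlinear counterpart of the log-linear model (MART: multiple
additive regression trees).  The pipeline, per cross-validation fold:

1. genes are randomly partitioned into folds (5 by default);
2. in each training gene, each count is divided by the gene's mean count
   N_i/L_i to give an empirical preference; zero counts are first
   replaced by a small number (0.5) so the logarithm exists;
3. the log of these preferences is the regression target;
4. a gradient-boosted tree ensemble (squared-error loss, depth 10,
   shrinkage 0.06, 2000 trees) is trained on the one-hot window features,
   with per-row weights N_i/L_i — targets from highly expressed genes
   have smaller variance and get heavier weights;
5. the trained ensemble predicts log preferences a_j on the test genes;
6. each test gene's expression level is set to its closed-form Poisson
   MLE nu = log(sum n_j / sum e^{a_j});
7. the Poisson deviance of the test counts against mu_j = e^{nu + a_j}
   and the null deviance are accumulated;
8. the pooled cross-validation R² is 1 - sum(d) / sum(d0) over folds.

The ensemble backend is xgboost with plain-least-squares settings (no L2
penalty, histogram splitter, single thread for determinism).
``interaction_depth`` follows R gbm's semantics — the number of splits
per tree, so a tree has ``interaction_depth + 1`` terminal nodes — grown
best-first (``max_leaves``), together with gbm's default minimum node
size of ~10 observations (``min_node_weight``, applied to weights
rescaled to mean 1).  Small trees are what keep 2000 boosting rounds
from memorizing the sampling noise of the log-count targets; fully-grown
depth-10 trees overfit badly at moderate sample sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb

from .context import ContextConfig, TrainingSet, build_training_set, encode, encode_region
from .countdata import GeneCounts
from .poislin import NEG_INF, null_deviance, poisson_deviance


@dataclass(frozen=True)
class BoostParams:
    """Boosting hyperparameters.

    ``interaction_depth`` is the number of splits per tree (gbm
    semantics: a tree has interaction_depth + 1 leaves).
    ``min_node_weight`` is the minimum total (mean-normalized) row weight
    per leaf — the analog of gbm's 10-observation minimum node size.
    """

    interaction_depth: int = 10
    shrinkage: float = 0.06
    n_trees: int = 2000
    subsample_fraction: float = 0.5
    min_node_weight: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction_depth < 1 or self.n_trees < 1:
            raise ValueError("interaction_depth and n_trees must be >= 1")
        if self.shrinkage <= 0:
            raise ValueError("shrinkage must be positive")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.min_node_weight < 0:
            raise ValueError("min_node_weight must be >= 0")


def make_targets(
    gene: GeneCounts, zero_replacement: float = 0.5
) -> tuple[np.ndarray, float]:
    """Log-preference targets and the gene's regression weight.

    target_j = log(max(n_j, zero_replacement) / (N/L)); the weight N/L is
    shared by all rows of the gene.
    """
    if gene.N == 0:
        raise ValueError(f"{gene.gene_id}: cannot form targets with no reads")
    mean = gene.N / gene.L
    n = np.asarray(gene.counts, dtype=np.float64)
    targets = np.log(np.maximum(n, zero_replacement) / mean)
    return targets, mean


def build_boost_training_set(
    genes: list[GeneCounts],
    cfg: ContextConfig,
    zero_replacement: float = 0.5,
) -> TrainingSet:
    """Training set with log-preference targets and N/L weights attached.

    Genes with no reads are excluded with a warning.
    """
    usable = []
    for g in genes:
        if g.N == 0:
            warnings.warn(f"{g.gene_id}: no reads, excluded from boosting")
        else:
            usable.append(g)
    ts = build_training_set(usable, cfg, weight_mode="N_over_L")
    ts.targets = np.concatenate(
        [make_targets(g, zero_replacement)[0] for g in usable]
    ) if usable else np.zeros(0)
    return ts


@dataclass
class BoostPrefModel:
    """Trained tree ensemble predicting log preference from window features."""

    booster: xgb.XGBRegressor
    cfg: ContextConfig
    params: BoostParams
    n_rows: int
    weight_scheme: str = "N_over_L"

    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        return self.booster.predict(X).astype(np.float64)


def fit_boost(ts: TrainingSet, params: BoostParams) -> BoostPrefModel:
    """Weighted squared-error gradient tree boosting on encoded windows."""
    if ts.targets is None:
        raise ValueError("training set has no log-preference targets")
    if ts.n_rows < 1:
        raise ValueError("empty training set")
    if not np.all(np.isfinite(ts.targets)):
        raise ValueError("non-finite targets")
    reg = xgb.XGBRegressor(
        objective="reg:squarederror",
        n_estimators=params.n_trees,
        grow_policy="lossguide",
        max_leaves=params.interaction_depth + 1,
        max_depth=0,
        learning_rate=params.shrinkage,
        subsample=params.subsample_fraction,
        tree_method="hist",
        reg_lambda=0.0,
        reg_alpha=0.0,
        min_child_weight=params.min_node_weight,
        n_jobs=1,
        random_state=params.seed,
    )
    # weights enter relative to their mean so min_node_weight counts
    # "typical observations"; WLS fits are invariant to the rescaling
    w = ts.weights
    if w.size and w.mean() > 0:
        w = w / w.mean()
    reg.fit(ts.X, ts.targets, sample_weight=w)
    return BoostPrefModel(
        booster=reg, cfg=ts.cfg, params=params, n_rows=ts.n_rows
    )


def predict_log_pref(model: BoostPrefModel, windows) -> np.ndarray:
    """Ensemble log preference for a list of window strings."""
    rows = [encode(w, model.cfg) for w in windows]
    X = np.vstack(rows) if rows else np.zeros((0, 3 * model.cfg.K))
    return model.predict_encoded(X)


def predict_gene_log_pref(model: BoostPrefModel, gene: GeneCounts) -> np.ndarray:
    """Log preference at every region position of a gene."""
    return model.predict_encoded(encode_region(gene, model.cfg))


def predict_pref(
    model: BoostPrefModel, gene: GeneCounts, normalize: bool = False
) -> np.ndarray:
    """Per-position preference e^{a_j}; optionally rescaled to mean 1."""
    pref = np.exp(predict_gene_log_pref(model, gene))
    if normalize:
        pref = pref / pref.mean()
    return pref


def mle_expression(counts, log_prefs) -> float:
    """Closed-form Poisson MLE of a gene's log expression level.

    nu = log(sum_j n_j / sum_j e^{a_j}); by construction
    sum_j e^{nu + a_j} = sum_j n_j.  Returns -inf for a gene with no reads.
    """
    n = np.asarray(counts, dtype=np.float64)
    a = np.asarray(log_prefs, dtype=np.float64)
    if n.shape != a.shape or n.size == 0:
        raise ValueError("counts and log_prefs must be matching nonempty arrays")
    if not np.all(np.isfinite(a)):
        raise ValueError("log preferences must be finite")
    total = n.sum()
    if total == 0:
        return NEG_INF
    return float(math.log(total) - math.log(np.exp(a).sum()))


@dataclass
class CvResult:
    """Gene-level cross-validation outcome for the boosted model."""

    fold_of: dict[str, int]
    d: np.ndarray  # per-fold model deviance
    d0: np.ndarray  # per-fold null deviance
    params: BoostParams
    cfg: ContextConfig
    n_folds: int
    seed: int

    @property
    def r2_per_fold(self) -> np.ndarray:
        return 1.0 - self.d / self.d0

    @property
    def cv_r2(self) -> float:
        """Pooled cross-validation R² = 1 - sum(d)/sum(d0)."""
        return float(1.0 - self.d.sum() / self.d0.sum())


def assign_folds(gene_ids, n_folds: int, seed: int) -> dict[str, int]:
    """Seeded random fold assignment, stable under gene input order.

    Sorted gene ids are shuffled with the seeded RNG and dealt round-robin
    into folds, so the same id set and seed always give the same split.
    """
    ids = sorted(gene_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return {ids[p]: i % n_folds for i, p in enumerate(perm)}


def cv_r2(
    genes: list[GeneCounts],
    cfg: ContextConfig,
    params: BoostParams,
    n_folds: int = 5,
    seed: int = 0,
    zero_replacement: float = 0.5,
) -> CvResult:
    """Gene-level cross-validated deviance R² of the boosted model."""
    # sorted so the result is invariant to the caller's gene order
    usable = sorted((g for g in genes if g.N > 0), key=lambda g: g.gene_id)
    for g in genes:
        if g.N == 0:
            warnings.warn(f"{g.gene_id}: no reads, excluded from cross-validation")
    if len(usable) < n_folds:
        raise ValueError(f"need at least {n_folds} genes with reads")
    fold_of = assign_folds([g.gene_id for g in usable], n_folds, seed)
    d = np.zeros(n_folds)
    d0 = np.zeros(n_folds)
    for fold in range(n_folds):
        train = [g for g in usable if fold_of[g.gene_id] != fold]
        test = [g for g in usable if fold_of[g.gene_id] == fold]
        if not test:
            continue
        ts = build_boost_training_set(train, cfg, zero_replacement)
        model = fit_boost(ts, params)
        for g in test:
            a = predict_gene_log_pref(model, g)
            nu = mle_expression(g.counts, a)
            mu = np.exp(nu + a)
            d[fold] += poisson_deviance(g.counts, mu)
        d0[fold] += null_deviance(test)
    return CvResult(
        fold_of=fold_of, d=d, d0=d0, params=params, cfg=cfg,
        n_folds=n_folds, seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization: versioned JSON container embedding the backend's own format

_FORMAT = "readpref-boost-model"
_VERSION = 1


def save_boost_model(model: BoostPrefModel, path) -> None:
    import json
    import tempfile, os

    with tempfile.NamedTemporaryFile("r", suffix=".json", delete=False) as tmp:
        tmp_path = tmp.name
    try:
        model.booster.get_booster().save_model(tmp_path)
        with open(tmp_path) as fh:
            booster_json = fh.read()
    finally:
        os.unlink(tmp_path)
    payload = {
        "format": _FORMAT,
        "version": _VERSION,
        "cfg": {"w_up": model.cfg.w_up, "w_down": model.cfg.w_down},
        "params": {
            "interaction_depth": model.params.interaction_depth,
            "shrinkage": model.params.shrinkage,
            "n_trees": model.params.n_trees,
            "subsample_fraction": model.params.subsample_fraction,
            "min_node_weight": model.params.min_node_weight,
            "seed": model.params.seed,
        },
        "feature_names": model.cfg.feature_names(),
        "n_rows": model.n_rows,
        "weight_scheme": model.weight_scheme,
        "booster": booster_json,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_boost_model(path) -> BoostPrefModel:
    import json
    import tempfile, os

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a readpref boost model file")
    cfg = ContextConfig(**payload["cfg"])
    if payload["feature_names"] != cfg.feature_names():
        raise ValueError(f"{path}: feature column order mismatch")
    params = BoostParams(**payload["params"])
    reg = xgb.XGBRegressor()
    with tempfile.NamedTemporaryFile("w", suffix=".json", delete=False) as tmp:
        tmp.write(payload["booster"])
        tmp_path = tmp.name
    try:
        booster = xgb.Booster()
        booster.load_model(tmp_path)
        reg._Booster = booster
    finally:
        os.unlink(tmp_path)
    return BoostPrefModel(
        booster=reg,
        cfg=cfg,
        params=params,
        n_rows=payload["n_rows"],
        weight_scheme=payload["weight_scheme"],
    )
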