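"""Poisson log-linear preference model fitted by alternating offset regression.

The model for the count at position j of gene i is

    n_ij ~ Poisson(mu_ij),
    log mu_ij = nu_i + alpha + sum_k sum_{h in {A,C,G}} beta_kh I(b_ijk = h),

with nu_i = log(mu_i) the gene's log expression level and the double sum a
log-linear function of the K-base window around the position.  alpha and
the gene levels are confounded; the operational convention keeps alpha
inside the preference and lets the expression update set each nu_i.

Fitting alternates two exact conditional maximizations:

1. initialize nu_i = log(N_i / L_i);
2. with nu fixed as known offsets, fit the Poisson regression by IRLS to
   get (alpha, beta) — the conditional MLE;
3. update nu_i = log(N_i / W_i), where W_i = sum_j exp(alpha + x_ij' beta)
   is the gene's sum of sequencing preferences — the conditional MLE of
   nu_i, which makes the fitted total sum_j mu_ij equal N_i exactly;
4. repeat from 2 until the deviance decreases by less than rel_tol
   (default 1%).

Each half-step maximizes the same joint likelihood, so the deviance
trajectory is non-increasing and the procedure converges to the joint
MLE; a direct Poisson GLM with gene-indicator columns reaches the same
deviance.

Goodness of fit is the deviance R² = 1 - d/d0, where d0 is the deviance
of the null model with a uniform preference within each gene
(mu_ij = N_i/L_i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .context import ContextConfig, TrainingSet, build_training_set, encode, encode_region
from .countdata import GeneCounts

NEG_INF = float("-inf")


def poisson_deviance(y, mu, weights=None) -> float:
    """Poisson GLM deviance 2 * sum[y log(y/mu) - (y - mu)].

    The y log y term is taken as 0 at y = 0.  This is the deviance that
    standard GLM software reports, and it is always >= 0.
    """
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have the same shape")
    if (mu <= 0).any():
        raise ValueError("fitted means must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    contrib = 2.0 * (term - (y - mu))
    if weights is not None:
        contrib = contrib * np.asarray(weights, dtype=np.float64)
    return float(max(contrib.sum(), 0.0))


def null_deviance(genes: list[GeneCounts]) -> float:
    """Deviance of the uniform-preference model mu_ij = N_i / L_i.

    A gene with no reads fits its all-zero counts exactly and contributes 0.
    """
    d0 = 0.0
    for g in genes:
        if g.N == 0:
            continue
        mu = np.full(g.L, g.N / g.L)
        d0 += poisson_deviance(g.counts, mu)
    return d0


@dataclass
class OffsetGlmFit:
    alpha: float
    beta: np.ndarray
    se_alpha: float
    se_beta: np.ndarray
    deviance: float
    converged: bool


def fit_offset_glm(ts: TrainingSet) -> OffsetGlmFit:
    """Poisson regression of counts on context features with fixed offsets.

    The per-row offsets (the current nu_i) enter the linear predictor with
    coefficient 1; IRLS maximizes the Poisson likelihood over (alpha, beta).
    Row weights act as replication counts, so duplicating a row is
    equivalent to doubling its weight.
    """
    n, p = ts.X.shape
    if n < p + 1:
        raise ValueError(f"need at least 3K+1 = {p + 1} rows, got {n}")
    if not np.all(np.isfinite(ts.offsets)):
        raise ValueError("offsets must be finite")
    X1 = np.column_stack([np.ones(n), ts.X])
    kwargs = {}
    if not np.all(ts.weights == 1.0):
        kwargs["freq_weights"] = ts.weights
    model = sm.GLM(ts.y, X1, family=sm.families.Poisson(), offset=ts.offsets, **kwargs)
    res = model.fit(maxiter=200, tol=1e-10)
    converged = bool(getattr(res, "converged", True))
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(params)):
        raise RuntimeError(
            f"offset GLM failed to converge (last deviance {res.deviance:.6g})"
        )
    return OffsetGlmFit(
        alpha=float(params[0]),
        beta=params[1:].copy(),
        se_alpha=float(bse[0]),
        se_beta=bse[1:].copy(),
        deviance=float(res.deviance),
        converged=converged,
    )


def update_expression(
    genes: list[GeneCounts],
    alpha: float,
    beta: np.ndarray,
    cfg: ContextConfig,
) -> np.ndarray:
    """Conditional MLE of the log expression levels given (alpha, beta).

    nu_i = log(N_i / W_i) with W_i = sum_j exp(alpha + x_ij' beta), the
    gene's sum of sequencing preferences.  By construction
    exp(nu_i) * W_i = N_i, i.e. fitted totals match observed totals.
    Genes with N_i = 0 get a -inf sentinel.
    """
    nu = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g.N == 0:
            nu[i] = NEG_INF
            continue
        eta = alpha + encode_region(g, cfg) @ beta
        W = np.exp(eta).sum()
        nu[i] = math.log(g.N / W)
    return nu


@dataclass
class FitDiagnostics:
    deviance_trajectory: np.ndarray
    d: float
    d0: float
    r2: float
    se_alpha: float
    se: np.ndarray
    n_iterations: int
    converged: bool


@dataclass
class LinearPrefModel:
    """Fitted log-linear preference model.

    ``beta`` follows the ContextConfig feature-column order
    (offset, base A/C/G); T is the reference level.  ``nu`` maps training
    gene ids to their fitted log expression levels.
    """

    alpha: float
    beta: np.ndarray
    cfg: ContextConfig
    nu: dict[str, float]
    diagnostics: FitDiagnostics | None = field(default=None, repr=False)

    def coefficient(self, offset: int, base: str) -> float:
        """beta_{offset, base}; base T returns 0 (reference level)."""
        if base == "T":
            return 0.0
        names = self.cfg.feature_names()
        return float(self.beta[names.index(f"pos{offset}:{base}")])


def fit_linear_pref(
    genes: list[GeneCounts],
    cfg: ContextConfig,
    rel_tol: float = 0.01,
    max_iter: int = 50,
) -> LinearPrefModel:
    """Fit the Poisson log-linear preference model by alternating updates.

    Stops when the relative decrease of the model deviance between outer
    iterations falls below ``rel_tol`` (default: 1%), or after
    ``max_iter`` outer iterations (flagged, not fatal).  Genes with no
    reads are excluded from fitting.
    """
    fit_genes = [g for g in genes if g.N > 0]
    if len(fit_genes) < 2:
        raise ValueError("need at least 2 genes with reads")
    ts = build_training_set(fit_genes, cfg, weight_mode="uniform")
    N = np.array([g.N for g in fit_genes], dtype=np.float64)
    L = np.array([g.L for g in fit_genes], dtype=np.float64)
    nu = np.log(N / L)  # step 1
    trajectory: list[float] = []
    converged = False
    fit: OffsetGlmFit | None = None
    for _ in range(max_iter):
        ts.offsets = nu[ts.gene_index]
        fit = fit_offset_glm(ts)  # step 2
        eta = fit.alpha + ts.X @ fit.beta
        # step 3: per-gene SSP and expression update
        W = np.bincount(ts.gene_index, weights=np.exp(eta), minlength=len(fit_genes))
        nu = np.log(N / W)
        mu = np.exp(nu[ts.gene_index] + eta)
        d = poisson_deviance(ts.y, mu)
        if trajectory and trajectory[-1] > 0:
            if (trajectory[-1] - d) / trajectory[-1] < rel_tol:  # step 4
                trajectory.append(d)
                converged = True
                break
        trajectory.append(d)
    assert fit is not None
    traj = np.asarray(trajectory)
    if np.any(np.diff(traj) > 1e-8 * max(traj[0], 1.0)):
        raise RuntimeError("deviance increased across outer iterations")
    d = float(traj[-1])
    d0 = null_deviance(fit_genes)
    diagnostics = FitDiagnostics(
        deviance_trajectory=traj,
        d=d,
        d0=d0,
        r2=1.0 - d / d0 if d0 > 0 else 0.0,
        se_alpha=fit.se_alpha,
        se=fit.se_beta,
        n_iterations=len(traj),
        converged=converged,
    )
    return LinearPrefModel(
        alpha=fit.alpha,
        beta=fit.beta,
        cfg=cfg,
        nu={g.gene_id: float(v) for g, v in zip(fit_genes, nu)},
        diagnostics=diagnostics,
    )


def predict_log_pref(model: LinearPrefModel, windows) -> np.ndarray:
    """Unnormalized log preference alpha + x' beta for each window."""
    rows = [encode(w, model.cfg) for w in windows]
    X = np.vstack(rows) if rows else np.zeros((0, 3 * model.cfg.K))
    return model.alpha + X @ model.beta


def predict_gene_log_pref(model: LinearPrefModel, gene: GeneCounts) -> np.ndarray:
    """Log preference at every region position of a gene."""
    return model.alpha + encode_region(gene, model.cfg) @ model.beta


def normalized_preferences(
    model: LinearPrefModel, genes: list[GeneCounts]
) -> tuple[list[np.ndarray], float]:
    """Preferences rescaled to mean 1 over all positions of ``genes``.

    Returns per-gene preference arrays and the corpus scale that was
    divided out.  With this normalization the SSP of a region under a
    uniform model equals its length, making SSP directly comparable to L.
    """
    raw = [np.exp(predict_gene_log_pref(model, g)) for g in genes]
    total = sum(p.sum() for p in raw)
    n = sum(p.size for p in raw)
    scale = total / n
    return [p / scale for p in raw], float(scale)


# ---------------------------------------------------------------------------
# serialization: versioned plain-text container

_MAGIC = "#readpref-linear-model\tv1"


def save_linear_model(model: LinearPrefModel, path) -> None:
    """Write the model as a versioned TSV container (bit-exact round trip)."""
    names = model.cfg.feature_names()
    se = model.diagnostics.se if model.diagnostics is not None else None
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"w_up\t{model.cfg.w_up}\n")
        fh.write(f"w_down\t{model.cfg.w_down}\n")
        fh.write(f"alpha\t{model.alpha!r}\n")
        fh.write("[beta]\n")
        for i, name in enumerate(names):
            s = repr(float(se[i])) if se is not None else "NA"
            fh.write(f"{name}\t{float(model.beta[i])!r}\t{s}\n")
        fh.write("[nu]\n")
        for gid, v in model.nu.items():
            fh.write(f"{gid}\t{v!r}\n")


def load_linear_model(path) -> LinearPrefModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a readpref linear model file")
    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("["):
        key, val = lines[i].split("\t")
        header[key] = val
        i += 1
    cfg = ContextConfig(w_up=int(header["w_up"]), w_down=int(header["w_down"]))
    alpha = float(header["alpha"])
    if lines[i] != "[beta]":
        raise ValueError("expected [beta] section")
    i += 1
    names = cfg.feature_names()
    beta = np.empty(len(names))
    se = np.full(len(names), np.nan)
    for k, name in enumerate(names):
        fields = lines[i].split("\t")
        if fields[0] != name:
            raise ValueError(f"feature column mismatch: {fields[0]} != {name}")
        beta[k] = float(fields[1])
        if fields[2] != "NA":
            se[k] = float(fields[2])
        i += 1
    nu: dict[str, float] = {}
    if i < len(lines) and lines[i] == "[nu]":
        i += 1
        while i < len(lines) and lines[i]:
            gid, v = lines[i].split("\t")
            nu[gid] = float(v)
            i += 1
    return LinearPrefModel(alpha=alpha, beta=beta, cfg=cfg, nu=nu)


def export_coefficients(model: LinearPrefModel, path) -> None:
    """Coefficient TSV (offset, base, beta, se) for plotting/inspection."""
    se = model.diagnostics.se if model.diagnostics is not None else None
    with open(path, "w") as fh:
        fh.write("offset\tbase\tbeta\tse\n")
        for i, name in enumerate(model.cfg.feature_names()):
            pos, base = name.removeprefix("pos").split(":")
            s = f"{se[i]:.6g}" if se is not None else "NA"
            fh.write(f"{pos}\t{base}\t{model.beta[i]:.8g}\t{s}\n")
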