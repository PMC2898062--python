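"""Preference-corrected expression estimators and the isoform MLE.

The sum of sequencing preferences (SSP) of a region plays the role of an
effective length: under the uniform model every preference is 1 and the
SSP equals the region length L.  The corrected expression estimate for a
single-isoform gene divides the total read count by the SSP instead of L.
The fold change max(p, 1/p), with p = SSP/L the region's mean preference
(preferences normalized to corpus mean 1), quantifies how much the
correction matters; it is 1 when the correction is immaterial and grows
for short regions where local preference variation has not been smoothed
out by summation.

For multi-isoform genes the exon counts n_e are modeled as Poisson with
mean sum_t theta_t * s_{e,t}, where s_{e,t} is the SSP of exon e within
isoform t (0 when the exon is absent) — the preference-aware version of
"mean count proportional to exon length".  The log-likelihood is concave
in the abundances theta, and a multiplicative EM update converges
monotonically to the maximizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .countdata import GeneCounts


def region_ssp(prefs) -> float:
    """Sum of sequencing preferences over a set of positions."""
    p = np.asarray(prefs, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty position set")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite preferences")
    return float(p.sum())


def junction_positions(
    site: int, read_length: int, transcript_length: int | None = None
) -> np.ndarray:
    """Read-start positions whose reads span an exon-exon boundary.

    The boundary sits between positions site-1 and site of the
    concatenated (intron-free) transcript.  A read of length R starting at
    j covers positions [j, j+R); it spans the boundary iff
    j in [site-R+1, site-1], giving R-1 positions.  Positions that fall
    outside the transcript (or cannot host a full-length read) are
    trimmed with a warning.
    """
    if read_length < 2:
        raise ValueError("read_length must be >= 2 to span a boundary")
    lo, hi = site - read_length + 1, site - 1
    positions = np.arange(lo, hi + 1)
    keep = positions >= 0
    if transcript_length is not None:
        keep &= positions <= transcript_length - read_length
    if not keep.all():
        warnings.warn(
            f"junction at {site}: {int((~keep).sum())} read-start positions "
            "outside the transcript were trimmed"
        )
    return positions[keep]


def fold_change(ssp: float, L: float) -> float:
    """max(p, 1/p) for the region's mean preference p = ssp / L.

    Equals the ratio of the larger to the smaller of the corrected (N/SSP)
    and uniform (N/L) expression estimates, and is always >= 1.
    """
    if ssp <= 0 or L <= 0:
        raise ValueError("ssp and L must be positive")
    p = ssp / L
    return float(max(p, 1.0 / p))


@dataclass
class ExpressionEstimate:
    """Uniform vs SSP-corrected expression estimates for one region."""

    gene_id: str
    N: int
    L: int
    ssp: float
    est_uniform: float
    est_ssp: float
    fold_change: float
    rpkm: float | None = None


def estimate_gene(gene: GeneCounts, prefs) -> ExpressionEstimate:
    """Expression estimates for a gene given corpus-normalized preferences.

    ``prefs`` must cover the region positions and already be normalized to
    corpus mean 1, so SSP is on the same scale as L.
    """
    p = np.asarray(prefs, dtype=np.float64)
    if p.shape != (gene.L,):
        raise ValueError(
            f"{gene.gene_id}: {p.size} preferences for region length {gene.L}"
        )
    ssp = region_ssp(p)
    if gene.N == 0:
        return ExpressionEstimate(
            gene_id=gene.gene_id, N=0, L=gene.L, ssp=ssp,
            est_uniform=0.0, est_ssp=0.0, fold_change=1.0, rpkm=gene.rpkm,
        )
    return ExpressionEstimate(
        gene_id=gene.gene_id,
        N=gene.N,
        L=gene.L,
        ssp=ssp,
        est_uniform=gene.N / gene.L,
        est_ssp=gene.N / ssp,
        fold_change=fold_change(ssp, gene.L),
        rpkm=gene.rpkm,
    )


@dataclass
class IsoformSet:
    """Exon-level observations for one multi-isoform gene.

    ``ssp[e, t]`` is the SSP of exon e within isoform t, 0 when isoform t
    does not contain exon e.  Exon SSPs may be isoform-specific: near a
    junction the window sequence (and hence the preference) depends on
    which exons are joined, and exon lengths themselves can differ between
    isoforms.  ``counts[e]`` is the observed read count of exon e.
    """

    exon_ids: list[str]
    isoform_ids: list[str]
    ssp: np.ndarray  # (n_exons, n_isoforms)
    counts: np.ndarray  # (n_exons,)

    def __post_init__(self) -> None:
        self.ssp = np.asarray(self.ssp, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        E, T = len(self.exon_ids), len(self.isoform_ids)
        if self.ssp.shape != (E, T):
            raise ValueError(f"ssp must be ({E}, {T})")
        if self.counts.shape != (E,):
            raise ValueError(f"counts must have {E} entries")
        if (self.ssp < 0).any() or (self.counts < 0).any():
            raise ValueError("ssp and counts must be non-negative")
        if (self.ssp.sum(axis=0) <= 0).any():
            raise ValueError("every isoform must contain at least one exon")
        if (self.ssp.sum(axis=1) <= 0).any():
            raise ValueError("every exon must belong to at least one isoform")


@dataclass
class IsoformEstimate:
    theta: np.ndarray
    shares: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    identifiable: bool
    isoform_ids: list[str] = field(default_factory=list)


def _poisson_loglik(n: np.ndarray, lam: np.ndarray) -> float:
    # constant terms (log n!) dropped
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > 0, n * np.log(np.where(lam > 0, lam, 1.0)), 0.0)
    if np.any((lam == 0) & (n > 0)):
        return float("-inf")
    return float((term - lam).sum())


def isoform_mle(
    iso: IsoformSet, tol: float = 1e-10, max_iter: int = 100_000
) -> IsoformEstimate:
    """Maximum-likelihood isoform abundances by multiplicative EM.

    Maximizes sum_e [n_e log(sum_t theta_t s_{e,t}) - sum_t theta_t s_{e,t}]
    over theta >= 0.  The update

        theta_t <- theta_t * (sum_e n_e s_{e,t} / lambda_e) / sum_e s_{e,t}

    is the EM step for the complete-data model in which each exon's reads
    are attributed to isoforms; the likelihood is concave so the fixed
    point is a global maximizer.  Rank deficiency of the incidence
    structure is flagged (a maximizer is still returned, but theta is not
    unique; the fitted exon means are).
    """
    S = iso.ssp
    n = iso.counts
    T = S.shape[1]
    col_tot = S.sum(axis=0)
    theta = np.full(T, n.sum() / max(S.sum(), 1e-300))
    if n.sum() == 0:
        return IsoformEstimate(
            theta=np.zeros(T), shares=np.zeros(T), log_likelihood=0.0,
            n_iterations=0, converged=True,
            identifiable=np.linalg.matrix_rank(S) == T,
            isoform_ids=list(iso.isoform_ids),
        )
    ll_prev = _poisson_loglik(n, S @ theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = S @ theta
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(lam > 0, n / np.where(lam > 0, lam, 1.0), 0.0)
        new_theta = theta * (S.T @ ratio) / col_tot
        ll = _poisson_loglik(n, S @ new_theta)
        if ll < ll_prev - 1e-9 * max(abs(ll_prev), 1.0):
            raise RuntimeError("EM log-likelihood decreased")
        # parameter-change criterion: the log-likelihood flattens long
        # before theta settles, so it is too loose a stopping rule
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        ll_prev = ll
        if delta <= tol * max(theta.max(), 1e-300):
            converged = True
            break
    total = theta.sum()
    shares = theta / total if total > 0 else np.zeros(T)
    identifiable = bool(np.linalg.matrix_rank(S) == T)
    if not identifiable:
        warnings.warn("isoform structure is rank-deficient; theta is not unique")
    return IsoformEstimate(
        theta=theta,
        shares=shares,
        log_likelihood=ll_prev,
        n_iterations=it,
        converged=converged,
        identifiable=identifiable,
        isoform_ids=list(iso.isoform_ids),
    )


def isoform_kkt_residual(iso: IsoformSet, theta: np.ndarray) -> float:
    """Max violation of the KKT conditions at theta (0 at an exact optimum).

    grad_t = sum_e s_{e,t} (n_e/lambda_e - 1) must be ~0 where theta_t > 0
    and <= 0 where theta_t = 0.
    """
    lam = iso.ssp @ theta
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lam > 0, iso.counts / np.where(lam > 0, lam, 1.0), 0.0)
    grad = iso.ssp.T @ (ratio - 1.0)
    active = theta > 1e-12 * max(theta.max(), 1.0)
    resid = np.abs(grad[active]) if active.any() else np.zeros(0)
    slack = np.maximum(grad[~active], 0.0)
    parts = np.concatenate([resid, slack]) if slack.size else resid
    return float(parts.max()) if parts.size else 0.0
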