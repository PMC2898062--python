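"""Synthetic transcripts, ground-truth preferences, and Poisson counts.

The generator reproduces the generative model assumed throughout the
package: position j of gene i receives a read-start count

    n_ij ~ Poisson(mu_ij),    mu_ij = exp(nu_i + a_ij),

where nu_i is the log expression level of gene i and a_ij is the log
sequencing preference determined by the local sequence around position j.
Counts at different positions are independent, so at constant mu the
variance-to-mean ratio of simulated counts is 1 — any overdispersion in a
simulated gene comes entirely from heterogeneous mu_ij, exactly as the
model asserts for real data.

Sequences carry explicit flanks on both sides of the analyzed region so
that context windows never run off the sequence (mirroring the UTR+100 nt
truncation, which guarantees real sequence beyond the region).  Each gene
draws from its own RNG stream derived from (seed, gene index): generating
a subset of genes yields the same sequences and counts for those genes.

Expression levels are drawn log-uniform: nu_i ~ Uniform(ln 5, ln 500) by
default — a ~100-fold dynamic range with per-position mean counts whose
median (~50) puts the variance-to-mean ratios of heterogeneous-rate
genes in the tens-to-hundreds range observed for the most highly
expressed genes in real sequencing runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .context import ContextConfig, encode_region
from .countdata import GeneCounts

_EXPR_LO = math.log(5.0)
_EXPR_HI = math.log(500.0)


@dataclass(frozen=True)
class LinearPreference:
    """A planted log-linear preference: a_ij = alpha + sum_k beta[k, base]."""

    alpha: float
    beta: np.ndarray  # length 3K, column order as ContextConfig.feature_names
    cfg: ContextConfig

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.shape != (3 * self.cfg.K,):
            raise ValueError(f"beta must have 3K = {3 * self.cfg.K} entries")
        if not np.all(np.isfinite(beta)) or not math.isfinite(self.alpha):
            raise ValueError("non-finite preference parameters")
        object.__setattr__(self, "beta", beta)

    def log_pref(self, gene: GeneCounts) -> np.ndarray:
        return self.alpha + encode_region(gene, self.cfg) @ self.beta


#: A custom preference maps (full_sequence, region_start, region_length) to
#: a length-L array of per-position log preferences.
CustomPreference = Callable[[str, int, int], np.ndarray]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    region_length_range is inclusive on both ends; regions below 100 nt
    are rejected at configuration time because such genes are discarded by
    the extraction filter and never reach the models.
    """

    n_genes: int
    region_length_range: tuple[int, int] = (200, 2000)
    flank_length: int = 100
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    expression_log_range: tuple[float, float] = (_EXPR_LO, _EXPR_HI)
    preference_spec: LinearPreference | CustomPreference | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        lo, hi = self.region_length_range
        if lo < 100 or hi < lo:
            raise ValueError("region lengths must satisfy 100 <= min <= max")
        comp = np.asarray(self.base_composition, dtype=np.float64)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-12:
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if isinstance(self.preference_spec, LinearPreference):
            c = self.preference_spec.cfg
            if self.flank_length < max(c.w_up, c.w_down):
                raise ValueError(
                    "flank_length must cover the preference window "
                    f"(need >= {max(c.w_up, c.w_down)})"
                )
        if self.flank_length < 0:
            raise ValueError("flank_length must be >= 0")


@dataclass
class Transcript:
    gene_id: str
    sequence: str
    region_start: int
    region_end: int


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset: mu_ij = exp(nu_i + a_ij)."""

    nu: np.ndarray  # per-gene log expression
    log_pref: list[np.ndarray]  # per-gene a_ij, length L_i each
    mu: list[np.ndarray]  # per-gene Poisson rates
    preference_spec: LinearPreference | CustomPreference | None


def _gene_rng(seed: int, gene_index: int, stream: int) -> np.random.Generator:
    # independent substreams per (gene, purpose); stable under subsetting
    return np.random.default_rng([seed, gene_index, stream])


def gen_transcripts(cfg: SimConfig) -> list[Transcript]:
    """Draw i.i.d. transcript sequences with explicit flanks.

    Each gene's region length is uniform over region_length_range and its
    sequence (region plus both flanks) is i.i.d. from base_composition.
    """
    comp = np.asarray(cfg.base_composition, dtype=np.float64)
    lo, hi = cfg.region_length_range
    out = []
    bases = np.array(list("ACGT"))
    for i in range(cfg.n_genes):
        rng = _gene_rng(cfg.seed, i, 0)
        L = int(rng.integers(lo, hi + 1))
        total = L + 2 * cfg.flank_length
        seq = "".join(bases[rng.choice(4, size=total, p=comp)])
        out.append(
            Transcript(
                gene_id=f"g{i:04d}",
                sequence=seq,
                region_start=cfg.flank_length,
                region_end=cfg.flank_length + L,
            )
        )
    return out


def gen_truth(cfg: SimConfig, transcripts: Sequence[Transcript]) -> SimTruth:
    """Draw nu_i and evaluate the planted preference for every position."""
    nus, log_prefs, mus = [], [], []
    lo, hi = cfg.expression_log_range
    for i, t in enumerate(transcripts):
        rng = _gene_rng(cfg.seed, i, 1)
        nu = float(rng.uniform(lo, hi))
        L = t.region_end - t.region_start
        spec = cfg.preference_spec
        if spec is None:
            a = np.zeros(L)
        elif isinstance(spec, LinearPreference):
            g = GeneCounts(t.gene_id, t.sequence, t.region_start, t.region_end,
                           np.zeros(L, dtype=np.int64))
            a = spec.log_pref(g)
        else:
            a = np.asarray(spec(t.sequence, t.region_start, L), dtype=np.float64)
            if a.shape != (L,):
                raise ValueError("custom preference must return one value per position")
        mu = np.exp(nu + a)
        if not np.all(np.isfinite(mu)):
            raise ValueError(f"non-finite Poisson rate for gene {t.gene_id}")
        nus.append(nu)
        log_prefs.append(a)
        mus.append(mu)
    return SimTruth(
        nu=np.asarray(nus),
        log_pref=log_prefs,
        mu=mus,
        preference_spec=cfg.preference_spec,
    )


def gen_counts(
    transcripts: Sequence[Transcript], truth: SimTruth, seed: int
) -> list[GeneCounts]:
    """Independent Poisson counts n_ij ~ Poisson(mu_ij) for every position."""
    if len(truth.mu) != len(transcripts):
        raise ValueError("truth does not cover all transcripts")
    genes = []
    for i, t in enumerate(transcripts):
        mu = truth.mu[i]
        L = t.region_end - t.region_start
        if mu.shape != (L,):
            raise ValueError(f"truth does not cover every position of {t.gene_id}")
        if not np.all(np.isfinite(mu)):
            raise ValueError(f"non-finite rate for gene {t.gene_id}")
        rng = _gene_rng(seed, i, 2)
        counts = rng.poisson(mu)
        genes.append(
            GeneCounts(t.gene_id, t.sequence, t.region_start, t.region_end, counts)
        )
    return genes


def simulate_dataset(cfg: SimConfig) -> tuple[list[GeneCounts], SimTruth]:
    """Convenience: transcripts + truth + counts in one call."""
    transcripts = gen_transcripts(cfg)
    truth = gen_truth(cfg, transcripts)
    return gen_counts(transcripts, truth, cfg.seed), truth


def gen_reads(gene: GeneCounts, read_length: int) -> list[str]:
    """Emit n_ij copies of the read starting at each region position.

    The inverse of toy read-start counting: on a region whose k-mers are
    all distinct, counting these reads recovers the counts exactly.
    Positions too close to the region end to host a full-length read must
    have zero counts.
    """
    region = gene.region_sequence
    if read_length < 1 or read_length > len(region):
        raise ValueError(f"read_length {read_length} not in [1, {len(region)}]")
    reads: list[str] = []
    for j, n in enumerate(gene.counts):
        if n == 0:
            continue
        if j + read_length > len(region):
            raise ValueError(
                f"{gene.gene_id}: position {j} has counts but cannot host a "
                f"read of length {read_length}"
            )
        reads.extend([region[j : j + read_length]] * int(n))
    return reads
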