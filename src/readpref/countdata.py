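"""Position-level read-start count data: extraction, filtering, diagnostics.

The unit of data is one gene's analyzed region: for each position j the
count n_ij of reads whose alignment starts there.  Regions are obtained
from transcripts by truncating both UTRs plus a further 100 nt (guarding
against annotation ambiguity and boundary bias), discarding regions
shorter than 100 nt, and keeping the top genes by RPKM — highly expressed
genes carry nearly all the usable signal about sequencing preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GeneCounts:
    """One gene's analyzed region with per-position read-start counts.

    ``region_start``/``region_end`` are a 0-based half-open interval into
    ``full_sequence``; ``counts[j]`` is the number of reads starting at
    region position j (0-based).  The sequence outside the region (the
    flanks) is retained so context windows never run out of bounds.
    """

    gene_id: str
    full_sequence: str
    region_start: int
    region_end: int
    counts: np.ndarray
    rpkm: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.region_start < 0 or self.region_end > len(self.full_sequence):
            raise ValueError(
                f"{self.gene_id}: region [{self.region_start}, {self.region_end}) "
                f"outside sequence of length {len(self.full_sequence)}"
            )
        if self.L < 1:
            raise ValueError(f"{self.gene_id}: empty region")
        if len(self.counts) != self.L:
            raise ValueError(
                f"{self.gene_id}: {len(self.counts)} counts for region length {self.L}"
            )
        if (self.counts < 0).any():
            raise ValueError(f"{self.gene_id}: negative count")

    @property
    def L(self) -> int:
        """Region length L_i in nucleotides."""
        return self.region_end - self.region_start

    @property
    def N(self) -> int:
        """Total reads N_i across the region."""
        return int(self.counts.sum())

    @property
    def region_sequence(self) -> str:
        return self.full_sequence[self.region_start : self.region_end]


def count_read_starts(region_sequence: str, reads) -> np.ndarray:
    """Count reads whose unique exact match starts at each region position.

    A read matching the region at two or more positions is discarded
    (multi-mapping); its potential start positions keep structural zeros.
    The count vector has one entry per region position — positions within
    a read length of the region end can never host a start and are
    trailing zeros.

    Parameters
    ----------
    region_sequence : str
        A/C/G/T region to count against.
    reads : iterable of str
        Read multiset; all reads must share one length <= region length.
    """
    L = len(region_sequence)
    if L == 0:
        raise ValueError("empty region")
    from .context import sequence_codes  # validates alphabet

    sequence_codes(region_sequence)
    counts = np.zeros(L, dtype=np.int64)
    reads = list(reads)
    if not reads:
        return counts
    read_len = len(reads[0])
    if read_len == 0:
        raise ValueError("empty read")
    if read_len > L:
        raise ValueError(f"read length {read_len} exceeds region length {L}")
    multiplicity: dict[str, int] = {}
    for r in reads:
        if len(r) != read_len:
            raise ValueError("reads of mixed lengths")
        sequence_codes(r)
        multiplicity[r] = multiplicity.get(r, 0) + 1
    for read, m in multiplicity.items():
        hits = _match_positions(region_sequence, read)
        if len(hits) == 1:
            counts[hits[0]] += m
    return counts


def _match_positions(region: str, read: str) -> list[int]:
    """All (overlapping) exact-match start positions of read in region."""
    hits, start = [], 0
    while True:
        pos = region.find(read, start)
        if pos < 0:
            return hits
        hits.append(pos)
        start = pos + 1


def truncate_region(
    full_sequence: str,
    utr5_len: int,
    utr3_len: int,
    pad: int = 100,
    min_len: int = 100,
) -> tuple[int, int] | None:
    """Trim UTRs plus ``pad`` extra nucleotides from both transcript ends.

    Returns the analyzed region as a 0-based half-open interval, or None
    when the remaining region is shorter than ``min_len`` (the gene is
    discarded).
    """
    if utr5_len < 0 or utr3_len < 0 or pad < 0:
        raise ValueError("UTR and pad lengths must be non-negative")
    start = utr5_len + pad
    end = len(full_sequence) - utr3_len - pad
    if end - start < min_len:
        return None
    return (start, end)


def rpkm(N: float, L: float, total_mapped: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if L <= 0 or total_mapped <= 0:
        raise ValueError("L and total_mapped must be positive")
    return N / (L / 1_000.0) / (total_mapped / 1_000_000.0)


def select_top_genes(genes: list[GeneCounts], k: int = 100) -> list[GeneCounts]:
    """The k genes with the highest RPKM (ties broken by gene_id).

    If fewer than k genes are supplied, all are returned (still sorted).
    """
    for g in genes:
        if g.rpkm is None:
            raise ValueError(f"{g.gene_id}: rpkm not set")
    ranked = sorted(genes, key=lambda g: (-g.rpkm, g.gene_id))
    return ranked[:k]


def variance_to_mean(counts) -> float:
    """Fano factor: sample variance (ddof=1) over sample mean.

    Equals 1 in expectation for Poisson counts with a constant rate;
    values well above 1 signal overdispersion.
    """
    c = np.asarray(counts, dtype=np.float64)
    if c.size == 0:
        raise ValueError("empty counts")
    m = c.mean()
    if m == 0:
        raise ValueError("variance-to-mean undefined for all-zero counts")
    if c.size < 2:
        raise ValueError("need at least two counts")
    return float(c.var(ddof=1) / m)
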