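"""Local-sequence windows around read-start positions and their encoding.

A read starting at transcript position ``j`` is surrounded by a window of
``w_up`` nucleotides upstream of its first base (offsets ``-w_up .. -1``)
and ``w_down`` nucleotides from the first base onward (offsets
``0 .. w_down-1``), ``K = w_up + w_down`` bases in total.  Each window
position contributes three 0/1 indicator features, one per base A/C/G;
base T is the reference level and encodes as all zeros.  A window of
length K therefore yields a 3K-dimensional feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .countdata import GeneCounts

#: Non-reference bases, in feature-column order.
BASES = ("A", "C", "G")

# byte -> code, A=0 C=1 G=2 T=3, -1 for anything else
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def sequence_codes(sequence: str) -> np.ndarray:
    """Map an A/C/G/T string to integer codes (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes < 0).any():
        bad = sequence[int(np.argmax(codes < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


@dataclass(frozen=True)
class ContextConfig:
    """Geometry of the local-sequence window relative to a read's first base.

    Parameters
    ----------
    w_up : int
        Nucleotides upstream of the first base of the read (offsets
        ``-w_up .. -1``).
    w_down : int
        Nucleotides from the first base of the read onward (offsets
        ``0 .. w_down-1``); must be at least 1 so offset 0, the read's
        first base, is always included.
    """

    w_up: int
    w_down: int

    def __post_init__(self) -> None:
        if self.w_up < 0:
            raise ValueError("w_up must be >= 0")
        if self.w_down < 1:
            raise ValueError("w_down must be >= 1")

    @property
    def K(self) -> int:
        """Window length in nucleotides."""
        return self.w_up + self.w_down

    @property
    def offsets(self) -> np.ndarray:
        """Window offsets relative to the read's first base."""
        return np.arange(-self.w_up, self.w_down)

    def feature_names(self) -> list[str]:
        """Column names ``pos{offset}:{base}`` in normative order."""
        return [f"pos{o}:{b}" for o in self.offsets for b in BASES]


def extract_window(
    full_sequence: str, region_start: int, j: int, cfg: ContextConfig
) -> str:
    """Window of length K around read-start position ``j`` of the region.

    ``j`` is 0-based within the analyzed region; offset 0 of the returned
    window is the read's first base.  Raises if the window runs off the
    sequence — callers must guarantee flanks.
    """
    lo = region_start + j - cfg.w_up
    hi = region_start + j + cfg.w_down
    if lo < 0 or hi > len(full_sequence):
        raise IndexError(
            f"window [{lo}, {hi}) out of bounds for sequence of "
            f"length {len(full_sequence)} (position {j})"
        )
    return full_sequence[lo:hi]


def encode(window: str, cfg: ContextConfig) -> np.ndarray:
    """One-hot encode a window into 3K indicator features.

    Column order is (offset, base) with bases A, C, G; T is the reference
    level and contributes all zeros at its position.
    """
    if len(window) != cfg.K:
        raise ValueError(f"window length {len(window)} != K = {cfg.K}")
    codes = sequence_codes(window)
    x = np.zeros(3 * cfg.K, dtype=np.float64)
    k = np.flatnonzero(codes < 3)
    x[3 * k + codes[k]] = 1.0
    return x


def decode(encoding: np.ndarray, cfg: ContextConfig) -> str:
    """Invert :func:`encode` (exists because encode is injective)."""
    enc = np.asarray(encoding, dtype=np.float64).reshape(cfg.K, 3)
    bases = []
    for row in enc:
        hot = np.flatnonzero(row == 1.0)
        if hot.size == 0:
            bases.append("T")
        elif hot.size == 1:
            bases.append(BASES[hot[0]])
        else:
            raise ValueError("invalid one-hot row with multiple set bits")
    return "".join(bases)


@dataclass
class TrainingSet:
    """Encoded per-position regression inputs over a set of genes.

    Rows are ordered (gene order, then position).  ``offsets`` holds the
    per-row log expression level used as the Poisson regression offset
    (zero until a fit assigns it); ``weights`` are all 1 (uniform) or
    gene-level N_i/L_i.  ``targets`` is filled by the boosting stage with
    log-preference responses.
    """

    X: np.ndarray
    y: np.ndarray
    gene_index: np.ndarray
    gene_ids: list[str]
    offsets: np.ndarray
    weights: np.ndarray
    cfg: ContextConfig
    targets: np.ndarray | None = field(default=None)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def feature_names(self) -> list[str]:
        return self.cfg.feature_names()


def encode_region(gene: GeneCounts, cfg: ContextConfig) -> np.ndarray:
    """Encode every read-start position of a gene's region: (L, 3K) matrix."""
    seq_codes = sequence_codes(gene.full_sequence)
    L = gene.L
    lo = gene.region_start - cfg.w_up
    hi = gene.region_start + (L - 1) + cfg.w_down
    if lo < 0 or hi > len(seq_codes):
        raise IndexError(
            f"gene {gene.gene_id}: context window needs sequence indices "
            f"[{lo}, {hi}) but sequence has length {len(seq_codes)}"
        )
    # (L, K) base codes for all windows at once
    idx = gene.region_start + np.arange(L)[:, None] + cfg.offsets[None, :]
    b = seq_codes[idx]
    X = np.zeros((L, 3 * cfg.K), dtype=np.float64)
    rows, ks = np.nonzero(b < 3)
    X[rows, 3 * ks + b[rows, ks]] = 1.0
    return X


def build_training_set(
    genes: list[GeneCounts],
    cfg: ContextConfig,
    weight_mode: str = "uniform",
) -> TrainingSet:
    """Assemble the per-position design matrix over a list of genes.

    weight_mode "uniform" gives every row weight 1; "N_over_L" gives all
    rows of gene i the weight N_i/L_i (higher expression, lower variance
    of its empirical log preferences).
    """
    if weight_mode not in ("uniform", "N_over_L"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    blocks, ys, gidx, ws = [], [], [], []
    for i, g in enumerate(genes):
        try:
            blocks.append(encode_region(g, cfg))
        except IndexError as err:
            raise IndexError(f"while encoding gene {g.gene_id}: {err}") from err
        ys.append(np.asarray(g.counts, dtype=np.float64))
        gidx.append(np.full(g.L, i, dtype=np.int64))
        w = 1.0 if weight_mode == "uniform" else g.N / g.L
        ws.append(np.full(g.L, w, dtype=np.float64))
    n = 3 * cfg.K
    X = np.vstack(blocks) if blocks else np.zeros((0, n))
    return TrainingSet(
        X=X,
        y=np.concatenate(ys) if ys else np.zeros(0),
        gene_index=np.concatenate(gidx) if gidx else np.zeros(0, dtype=np.int64),
        gene_ids=[g.gene_id for g in genes],
        offsets=np.zeros(X.shape[0]),
        weights=np.concatenate(ws) if ws else np.zeros(0),
        cfg=cfg,
    )
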