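"""Shared file formats: FASTA transcripts, counts TSV, truth TSV, manifests.

Conventions
-----------
* Coordinates are 0-based half-open everywhere in memory; FASTA
  description lines annotate the analyzed region 1-based inclusive
  (``region=start-end``) for human readability.
* Counts travel as TSV with columns gene_id, position, count; positions
  are 0-based and contiguous within each gene.
* Output files start with ``#`` comment lines naming the tool version and
  the producing command; readers skip ``#`` lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .countdata import GeneCounts
from .simulate import SimTruth, Transcript

_VALID = set("ACGTN")
_REGION_RE = re.compile(r"region=(\d+)-(\d+)")


@dataclass
class FastaRecord:
    id: str
    description: str
    sequence: str


def _clean_sequence(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"record {record_id}: characters outside ACGTN: {sorted(bad)}"
        )
    return s


def read_fasta(path) -> list[FastaRecord]:
    """Parse FASTA; sequences are uppercased and U is mapped to T."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append(FastaRecord(rec.id, desc, _clean_sequence(str(rec.seq), rec.id)))
    return out


def write_fasta(path, transcripts: list[Transcript]) -> None:
    """Write transcripts with the analyzed region annotated 1-based inclusive."""
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=t.gene_id,
            description=f"region={t.region_start + 1}-{t.region_end}",
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def parse_region(description: str, seq_len: int) -> tuple[int, int]:
    """Region interval from a description line; whole sequence if absent."""
    m = _REGION_RE.search(description)
    if m is None:
        return (0, seq_len)
    start1, end1 = int(m.group(1)), int(m.group(2))
    if not (1 <= start1 <= end1 <= seq_len):
        raise ValueError(f"region {start1}-{end1} outside sequence of length {seq_len}")
    return (start1 - 1, end1)


def _header_lines(command: str | None) -> str:
    lines = [f"# readpref {__version__}"]
    if command:
        lines.append(f"# command: {command}")
    return "\n".join(lines) + "\n"


def write_counts(path, genes: list[GeneCounts], command: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(command))
        fh.write("gene_id\tposition\tcount\n")
        for g in genes:
            for j, c in enumerate(g.counts):
                fh.write(f"{g.gene_id}\t{j}\t{int(c)}\n")


def read_counts(path) -> dict[str, np.ndarray]:
    """Counts TSV -> per-gene count arrays, validating contiguity.

    Positions must be 0-based, contiguous from 0, without duplicates, and
    counts non-negative; violations name the offending gene and position.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    required = {"gene_id", "position", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts file must have columns {sorted(required)}")
    out: dict[str, np.ndarray] = {}
    for gid, sub in df.groupby("gene_id", sort=False):
        pos = sub["position"].to_numpy()
        counts = sub["count"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, counts = pos[order], counts[order]
        dup = np.flatnonzero(np.diff(pos) == 0)
        if dup.size:
            raise ValueError(f"gene {gid}: duplicate position {int(pos[dup[0]])}")
        expected = np.arange(len(pos))
        if not np.array_equal(pos, expected):
            missing = int(np.setdiff1d(expected, pos)[0])
            raise ValueError(f"gene {gid}: positions not contiguous (missing {missing})")
        if (counts < 0).any():
            j = int(pos[np.argmax(counts < 0)])
            raise ValueError(f"gene {gid}: negative count at position {j}")
        out[gid] = counts.astype(np.int64)
    return out


def load_genes(fasta_path, counts_path) -> list[GeneCounts]:
    """Join a transcript FASTA with a counts TSV into GeneCounts objects."""
    records = {r.id: r for r in read_fasta(fasta_path)}
    counts = read_counts(counts_path)
    genes = []
    for gid, c in counts.items():
        if gid not in records:
            raise ValueError(f"gene {gid} in counts but not in FASTA")
        rec = records[gid]
        start, end = parse_region(rec.description, len(rec.sequence))
        if end - start != len(c):
            raise ValueError(
                f"gene {gid}: region length {end - start} != {len(c)} counts"
            )
        genes.append(GeneCounts(gid, rec.sequence, start, end, c))
    return genes


def write_truth(path, transcripts: list[Transcript], truth: SimTruth,
                command: str | None = None) -> None:
    """Ground-truth TSV: per-position nu, log preference, and Poisson rate."""
    with open(path, "w") as fh:
        fh.write(_header_lines(command))
        fh.write("gene_id\tposition\tnu\tlog_pref\tmu\n")
        for i, t in enumerate(transcripts):
            nu = truth.nu[i]
            for j, (a, mu) in enumerate(zip(truth.log_pref[i], truth.mu[i])):
                fh.write(f"{t.gene_id}\t{j}\t{nu!r}\t{a!r}\t{mu!r}\n")


def write_preferences(path, gene_ids, positions, log_prefs,
                      command: str | None = None) -> None:
    """Per-position preference TSV (gene_id, position, log_pref, pref)."""
    with open(path, "w") as fh:
        fh.write(_header_lines(command))
        fh.write("gene_id\tposition\tlog_pref\tpref\n")
        for gid, j, a in zip(gene_ids, positions, log_prefs):
            fh.write(f"{gid}\t{j}\t{a:.8g}\t{np.exp(a):.8g}\n")


def write_expression(path, estimates, command: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(command))
        fh.write("gene_id\tN\tL\tssp\test_uniform\test_ssp\tfold_change\trpkm\n")
        for e in estimates:
            rp = f"{e.rpkm:.6g}" if e.rpkm is not None else "NA"
            fh.write(
                f"{e.gene_id}\t{e.N}\t{e.L}\t{e.ssp:.8g}\t{e.est_uniform:.8g}"
                f"\t{e.est_ssp:.8g}\t{e.fold_change:.8g}\t{rp}\n"
            )
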