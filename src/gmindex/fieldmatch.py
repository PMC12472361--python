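"""Mapping field contigs onto reference transcripts via identity hits.

Field metatranscriptome assemblies contain contigs from the whole
community; the contigs belonging to the organism of interest are recognized
by nucleotide similarity against its reference transcript set.  This module
consumes a precomputed BLAST tabular (outfmt 6) hit table -- it never runs
BLAST itself -- applies the retention thresholds (percent identity >= 98,
e-value <= 1e-50 by default), reduces to one best hit per contig, and
collapses contig abundances onto reference transcript IDs.

The study's final manual curation step (hand-picking marker transcripts
from the filtered hit list) is not algorithmically reproducible; only the
stated quantitative filters are implemented.  An optional exclusion list
lets users remove transcripts rejected by any external verification step.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix
from .synthetic import BLAST_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 98.0
DEFAULT_MAX_EVALUE = 1e-50
#: stricter e-value cutoff used in the study's hit-funnel summary table
STRICT_MAX_EVALUE = 1e-66

_NUMERIC = {
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
}


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular (outfmt 6) file.

    Comment lines starting with ``#`` are skipped; scientific-notation
    e-values are parsed as floats.  A row with the wrong column count raises
    an error naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BLAST tabular file not found: {path}")
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                row = [parts[0], parts[1]] + [
                    _NUMERIC[col](parts[i]) for i, col in enumerate(BLAST_COLUMNS[2:], start=2)
                ]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed value ({exc})") from None
            rows.append(row)
    return pd.DataFrame(rows, columns=list(BLAST_COLUMNS))


def write_blast_tab(hits: pd.DataFrame, path: str | Path) -> None:
    """Write hits as 12-column outfmt-6 TSV (no header, as BLAST emits)."""
    hits.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def _validate_hits(hits: pd.DataFrame) -> None:
    missing = set(BLAST_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    pid = hits["pident"].to_numpy(dtype=float)
    if np.any((pid < 0) | (pid > 100)):
        raise ValueError("percent identity outside [0, 100]")
    ev = hits["evalue"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ev)) or np.any(ev < 0):
        raise ValueError("e-values must be finite and nonnegative")


def filter_hits(
    hits: pd.DataFrame,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> pd.DataFrame:
    """Retain confident hits and reduce to the best hit per contig.

    A hit survives iff ``pident >= min_identity`` and
    ``evalue <= max_evalue``.  When a contig retains several hits, only the
    best is kept; ties break deterministically by highest bit score, then
    highest identity, then lexicographically smallest subject ID.
    Idempotent: filtering an already-filtered table is a no-op.
    """
    _validate_hits(hits)
    kept = hits[(hits["pident"] >= min_identity) & (hits["evalue"] <= max_evalue)]
    logger.info("hit filter: %d in, %d pass thresholds", len(hits), len(kept))
    kept = kept.sort_values(
        ["qseqid", "bitscore", "pident", "sseqid"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = kept.drop_duplicates("qseqid", keep="first").reset_index(drop=True)
    logger.info("hit filter: %d best-per-contig retained", len(best))
    return best


def map_to_reference(
    retained: pd.DataFrame,
    field: CountMatrix,
    exclude: set[str] | None = None,
) -> CountMatrix:
    """Collapse field contig abundances onto reference transcript IDs.

    Abundances of all contigs assigned to the same reference transcript are
    summed per sample (fragmented assemblies of one gene contribute all
    their reads).  ``exclude`` removes reference transcripts rejected by an
    external verification step.
    """
    if exclude:
        retained = retained[~retained["sseqid"].isin(exclude)]
    if retained.empty:
        logger.warning("no retained hits; returning empty field table")
        return CountMatrix(
            pd.DataFrame(index=pd.Index([], name="transcript_id"), columns=field.values.columns, dtype=float),
            field.samples.copy(),
        )
    missing = [q for q in retained["qseqid"] if q not in field.values.index]
    if missing:
        raise ValueError(f"contigs absent from field matrix: {sorted(set(missing))}")
    assignment = retained.set_index("qseqid")["sseqid"]
    sub = field.values.loc[assignment.index]
    summed = sub.groupby(assignment).sum()
    summed = summed.sort_index()
    summed.index.name = "transcript_id"
    return CountMatrix(summed, field.samples.copy())
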