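"""Transcript-by-sample abundance tables and their on-disk TSV form.

The :class:`CountMatrix` is the currency of the whole pipeline: laboratory
stress experiments, synthetic field metatranscriptomes and reference-mapped
field tables all travel through it.  It wraps a pandas DataFrame of
nonnegative abundances (rows = transcripts, columns = samples) together with
per-sample metadata (condition, site, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("control", "cold", "desiccated", "field")

#: Fixed float dialect for all TSV output; 9 significant digits keeps
#: round-trips byte-stable across runs.
FLOAT_FMT = "%.9g"


class CountMatrixError(ValueError):
    """Raised on malformed abundance tables or metadata."""


@dataclass
class CountMatrix:
    """Transcripts x samples abundance table with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by transcript ID with one column per sample ID.
        Entries are nonnegative abundances (raw counts, fpkm or relative
        abundances -- the pipeline does not care which, only ratios and
        per-column normalizations are ever taken).
    samples
        DataFrame indexed by sample ID with columns ``condition``, ``site``
        and ``replicate``; one row per column of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                {
                    "condition": ["field"] * self.values.shape[1],
                    "site": [""] * self.values.shape[1],
                    "replicate": range(1, self.values.shape[1] + 1),
                },
                index=self.values.columns,
            )
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate transcript IDs: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate sample IDs: {dups}")
        if (v.to_numpy() < 0).any():
            raise CountMatrixError("negative abundance values")
        missing = v.columns.difference(self.samples.index)
        if len(missing):
            raise CountMatrixError(f"samples without metadata: {missing.tolist()}")
        extra = self.samples.index.difference(v.columns)
        if len(extra):
            raise CountMatrixError(f"metadata without samples: {extra.tolist()}")
        if "condition" not in self.samples.columns:
            raise CountMatrixError("sample metadata lacks a 'condition' column")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise CountMatrixError(f"unknown conditions: {sorted(bad)}")
        # keep metadata rows aligned with the value columns
        self.samples = self.samples.loc[v.columns]

    # -- convenience ---------------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def condition_samples(self, condition: str) -> list[str]:
        """Sample IDs whose metadata condition equals ``condition``."""
        mask = self.samples["condition"] == condition
        return self.samples.index[mask].tolist()

    def condition_means(self, condition: str) -> pd.Series:
        """Per-transcript mean abundance over the replicates of a condition."""
        cols = self.condition_samples(condition)
        if not cols:
            raise CountMatrixError(f"no samples with condition {condition!r}")
        return self.values[cols].mean(axis=1)

    def subset_transcripts(self, ids) -> "CountMatrix":
        ids = list(ids)
        missing = [t for t in ids if t not in self.values.index]
        if missing:
            raise CountMatrixError(f"transcripts absent from matrix: {missing}")
        return CountMatrix(self.values.loc[ids].copy(), self.samples.copy())

    def subset_samples(self, ids) -> "CountMatrix":
        ids = list(ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise CountMatrixError(f"samples absent from matrix: {missing}")
        return CountMatrix(self.values[ids].copy(), self.samples.loc[ids].copy())


def normalize_relative(matrix: CountMatrix) -> CountMatrix:
    """Scale each sample to relative abundances (columns sum to one).

    Mirrors the study design of normalizing transcript counts to the total
    number of reads assigned to the organism of interest within each sample,
    so downstream ratios compare like with like across libraries of very
    different depth.

    Raises
    ------
    CountMatrixError
        If any sample has zero total abundance (relative abundance would be
        undefined); the error names the offending sample(s).
    """
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise CountMatrixError(f"all-zero samples cannot be normalized: {zero}")
    return CountMatrix(matrix.values / totals, matrix.samples.copy())


# -- TSV I/O ----------------------------------------------------------------


def read_counts(path: str | Path, metadata_path: str | Path | None = None) -> CountMatrix:
    """Read a count table (and optional sample metadata) from TSV.

    The count TSV has ``transcript_id`` as its first column and one column
    per sample.  The metadata TSV has columns ``sample_id``, ``condition``,
    ``site``, ``replicate``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    first = raw.columns[0]
    if raw[first].duplicated().any():
        dups = raw[first][raw[first].duplicated()].tolist()
        raise CountMatrixError(f"duplicate transcript IDs in {path}: {dups}")
    values = raw.set_index(first)
    values.index.name = "transcript_id"
    samples = None
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        if not metadata_path.exists():
            raise FileNotFoundError(f"sample metadata not found: {metadata_path}")
        samples = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
        samples = samples.set_index("sample_id")
    return CountMatrix(values, samples)


def write_counts(matrix: CountMatrix, path: str | Path, metadata_path: str | Path | None = None) -> None:
    """Write a CountMatrix (and optionally its metadata) as TSV."""
    out = matrix.values.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if metadata_path is not None:
        meta = matrix.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")
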