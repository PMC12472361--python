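"""Stress-marker classification and the per-stressor marker catalog.

Laboratory stress transcriptomes (control vs cold, control vs desiccation)
are screened for regulated transcripts with a deliberately lightweight
classifier: log2 ratio of condition mean abundances, a Welch two-sample
t-test on log2(CPM + 1), and Benjamini-Hochberg FDR control across all
transcripts tested per stressor.  A transcript is called regulated when it
clears all three printed thresholds simultaneously: fold change > 2,
p < 0.05, FDR < 0.05.

This is not a reimplementation of a full count-model DE package (edgeR,
DESeq2); those model count dispersion explicitly.  Users who prefer such
output can load a precomputed table with :func:`read_regulation_table`.
The catalog step then keeps only transcripts regulated by exactly one
stressor (dual-regulated transcripts are recorded separately) and attaches
the constantly expressed set used as ratio denominators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .countmatrix import CountMatrix, normalize_relative

logger = logging.getLogger(__name__)

STRESSORS = ("cold", "desiccation")
#: condition label in sample metadata for each stressor
STRESS_CONDITION = {"cold": "cold", "desiccation": "desiccated"}

REGULATION_COLUMNS = ("stressor", "log2_fold_change", "p_value", "fdr", "class")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for calling a transcript regulated.

    ``fold_change`` is on the linear scale (a transcript must change more
    than this factor in either direction), ``p_value`` and ``fdr`` are the
    raw Welch-test and Benjamini-Hochberg cutoffs, and both must be cleared.
    ``pseudocount`` is added to mean CPM in the fold-change ratio only, to
    keep ratios finite for transcripts absent from one condition.
    """

    fold_change: float = 2.0
    p_value: float = 0.05
    fdr: float = 0.05
    pseudocount: float = 0.5
    stability_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise ValueError("fold_change threshold must exceed 1")
        for name in ("p_value", "fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} threshold must lie in (0, 1)")


def _cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: per-sample relative abundance x 1e6."""
    rel = normalize_relative(matrix)
    return rel.values * 1e6


def classify_regulation(
    lab: CountMatrix,
    stressor: str,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Classify every transcript as up/down/not regulated under one stressor.

    Parameters
    ----------
    lab
        Laboratory count matrix with ``control`` replicates and replicates
        of the stressor's condition (``cold`` or ``desiccated``).
    stressor
        ``"cold"`` or ``"desiccation"``.
    thresholds
        Decision thresholds; defaults to fold change > 2, p < 0.05,
        FDR < 0.05.

    Returns
    -------
    DataFrame indexed by transcript ID with columns ``stressor``,
    ``log2_fold_change``, ``p_value``, ``fdr`` and ``class``
    (``up`` / ``down`` / ``not_regulated``).
    """
    if stressor not in STRESSORS:
        raise ValueError(f"unknown stressor {stressor!r}; expected one of {STRESSORS}")
    thresholds = thresholds or Thresholds()
    if lab.values.empty:
        raise ValueError("empty count matrix")
    ctrl = lab.condition_samples("control")
    stress = lab.condition_samples(STRESS_CONDITION[stressor])
    if len(ctrl) < 2 or len(stress) < 2:
        raise ValueError(
            f"need >=2 replicates per condition, got {len(ctrl)} control and "
            f"{len(stress)} {STRESS_CONDITION[stressor]}"
        )

    cpm = _cpm(lab)
    eps = thresholds.pseudocount
    mean_ctrl = cpm[ctrl].mean(axis=1)
    mean_stress = cpm[stress].mean(axis=1)
    log2fc = np.log2((mean_stress + eps) / (mean_ctrl + eps))

    log_cpm = np.log2(cpm + 1.0)
    with warnings.catch_warnings():
        # near-identical replicate groups trip scipy's precision warning;
        # the resulting NaN p-values are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(
            log_cpm[stress], log_cpm[ctrl], axis=1, equal_var=False
        )
    # zero variance in both groups yields NaN; identical groups are not evidence
    pvals = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    lfc_cut = np.log2(thresholds.fold_change)
    significant = (pvals < thresholds.p_value) & (fdr < thresholds.fdr)
    cls = np.where(
        significant & (log2fc > lfc_cut),
        "up",
        np.where(significant & (log2fc < -lfc_cut), "down", "not_regulated"),
    )
    return pd.DataFrame(
        {
            "stressor": stressor,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "class": cls,
        },
        index=lab.values.index,
    )


def read_regulation_table(path: str | Path, stressor: str, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Load a precomputed differential-expression table (e.g. edgeR output).

    The TSV must carry ``transcript_id``, ``log2_fold_change``, ``p_value``
    and ``fdr`` columns; the regulation class is (re)assigned from the
    thresholds so the catalog logic is identical for both classifier paths.
    """
    thresholds = thresholds or Thresholds()
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "log2_fold_change", "p_value", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"regulation table {path} lacks columns: {sorted(missing)}")
    df = df.set_index("transcript_id")
    lfc_cut = np.log2(thresholds.fold_change)
    significant = (df["p_value"] < thresholds.p_value) & (df["fdr"] < thresholds.fdr)
    df["stressor"] = stressor
    df["class"] = np.where(
        significant & (df["log2_fold_change"] > lfc_cut),
        "up",
        np.where(significant & (df["log2_fold_change"] < -lfc_cut), "down", "not_regulated"),
    )
    return df[list(REGULATION_COLUMNS)]


def find_constant(
    records_cold: pd.DataFrame,
    records_des: pd.DataFrame,
    lab: CountMatrix,
    stability_threshold: float = 0.5,
) -> set[str]:
    """Transcripts suitable as constantly expressed ratio denominators.

    A transcript qualifies when it is not regulated under either stressor,
    its |log2 fold change| stays below ``stability_threshold`` under both,
    and it has nonzero mean abundance in every lab condition (a denominator
    that vanishes in some condition is useless for ratio bounds).
    """
    shared = records_cold.index.intersection(records_des.index)
    flat = (
        (records_cold.loc[shared, "class"] == "not_regulated")
        & (records_des.loc[shared, "class"] == "not_regulated")
        & (records_cold.loc[shared, "log2_fold_change"].abs() < stability_threshold)
        & (records_des.loc[shared, "log2_fold_change"].abs() < stability_threshold)
    )
    candidates = set(shared[flat])
    conditions = sorted(set(lab.samples["condition"]))
    for cond in conditions:
        means = lab.condition_means(cond)
        candidates &= set(means.index[means > 0])
    return candidates


@dataclass
class StressorMarkers:
    """Single-stressor marker sets: regulated (with direction) and constant."""

    regulated: dict[str, str]  # transcript_id -> "up" | "down"
    constant: set[str]


@dataclass
class MarkerCatalog:
    """Per-stressor marker sets plus the dual-regulated remainder.

    ``stressors`` maps each stressor to the transcripts regulated by that
    stressor ONLY (with direction) and the constantly expressed set used as
    denominators.  ``dual`` holds transcripts regulated by both stressors;
    they are excluded from ratio pairs but re-enter the whole-profile
    clustering comparison (dataset 2).
    """

    stressors: dict[str, StressorMarkers]
    dual: dict[str, dict[str, str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def regulated_ids(self, stressor: str) -> list[str]:
        return sorted(self.stressors[stressor].regulated)

    def constant_ids(self, stressor: str) -> list[str]:
        return sorted(self.stressors[stressor].constant)

    def direction(self, stressor: str, transcript_id: str) -> str:
        return self.stressors[stressor].regulated[transcript_id]

    def dual_ids(self) -> list[str]:
        return sorted(self.dual)

    def validate(self) -> None:
        dual = set(self.dual)
        specific = {s: set(m.regulated) for s, m in self.stressors.items()}
        for s, ids in specific.items():
            if ids & dual:
                raise ValueError(f"dual transcripts listed as {s}-specific: {sorted(ids & dual)}")
        for s, m in self.stressors.items():
            bad = m.constant & (set().union(*specific.values()) | dual)
            if bad:
                raise ValueError(f"constant set overlaps regulated/dual transcripts: {sorted(bad)}")


def _regulated_directions(records: pd.DataFrame) -> dict[str, str]:
    mask = records["class"].isin(["up", "down"])
    return dict(records.loc[mask, "class"])


def build_catalog(
    records_cold: pd.DataFrame,
    records_des: pd.DataFrame,
    constant_ids: set[str],
    provenance: dict | None = None,
) -> MarkerCatalog:
    """Partition regulated transcripts into stressor-specific and dual sets.

    Only transcripts regulated by exactly one stressor become ratio markers;
    the intersection of both regulated sets is kept as ``dual``.  Raises if
    the constant set intersects any regulated set (the sets must partition).
    """
    cold = _regulated_directions(records_cold)
    des = _regulated_directions(records_des)
    dual_ids = set(cold) & set(des)
    overlap = constant_ids & (set(cold) | set(des))
    if overlap:
        raise ValueError(f"constant_ids overlap regulated transcripts: {sorted(overlap)}")
    catalog = MarkerCatalog(
        stressors={
            "cold": StressorMarkers(
                regulated={t: d for t, d in cold.items() if t not in dual_ids},
                constant=set(constant_ids),
            ),
            "desiccation": StressorMarkers(
                regulated={t: d for t, d in des.items() if t not in dual_ids},
                constant=set(constant_ids),
            ),
        },
        dual={t: {"cold": cold[t], "desiccation": des[t]} for t in sorted(dual_ids)},
        provenance=provenance or {},
    )
    catalog.validate()
    logger.info(
        "catalog: %d cold-specific, %d desiccation-specific, %d dual, %d constant",
        len(catalog.stressors["cold"].regulated),
        len(catalog.stressors["desiccation"].regulated),
        len(catalog.dual),
        len(constant_ids),
    )
    return catalog


def summarize_regulation(records: pd.DataFrame | list[pd.DataFrame]) -> pd.DataFrame:
    """Tabulate up/down-regulated transcript counts per stressor."""
    if isinstance(records, pd.DataFrame):
        records = [records]
    frames = [r for r in records if len(r)]
    if not frames:
        return pd.DataFrame(columns=["up", "down"]).rename_axis("stressor")
    combined = pd.concat(frames)
    table = (
        combined[combined["class"].isin(["up", "down"])]
        .groupby(["stressor", "class"])
        .size()
        .unstack(fill_value=0)
    )
    for col in ("up", "down"):
        if col not in table.columns:
            table[col] = 0
    present = combined["stressor"].unique()
    table = table.reindex(present, fill_value=0)[["up", "down"]]
    table.columns.name = None
    return table.rename_axis("stressor")
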