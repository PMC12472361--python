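"""Gene marker indices: min-max normalized expression ratios.

A marker pair couples one stress-regulated transcript ``r`` with one
constantly expressed transcript ``c``.  Within any sample, the ratio
``X = abundance(r) / abundance(c)`` is insensitive to sequencing depth.
The lab experiment pins down the ratio's dynamic range: ``X_min`` is the
ratio under control conditions, ``X_max`` under the stress treatment.  A
field sample's ratio ``X_i`` is then expressed as a percentage of the
lab effect:

    GMI_i = (X_i - X_min) / (X_max - X_min) * 100

so 0 means "field looks like the lab control", 100 "like the lab stress
treatment", and values outside [0, 100] flag expression beyond either lab
endpoint.  The same formula handles down-regulated markers (X_max < X_min)
without modification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix
from .markers import MarkerCatalog, STRESS_CONDITION

logger = logging.getLogger(__name__)

#: minimal |x_max - x_min| for a pair to be usable (degeneracy guard)
DEFAULT_DELTA = 1e-9

CATEGORIES = ("below_range", "q1", "q2", "q3", "q4", "above_range")


@dataclass(frozen=True)
class MarkerPair:
    """One (regulated, constant) transcript pair with its lab ratio bounds."""

    pair_index: int
    regulated_id: str
    constant_id: str
    stressor: str
    direction: str  # up | down
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        for name in ("x_min", "x_max"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.x_min == self.x_max:
            raise ValueError("degenerate pair: x_min == x_max")


@dataclass(frozen=True)
class GMIRecord:
    """One marker-index evaluation: pair x field sample."""

    pair_index: int
    regulated_id: str
    constant_id: str
    sample_id: str
    x_i: float
    gmi: float
    category: str


def enumerate_pairs(catalog: MarkerCatalog, stressor: str) -> list[tuple[str, str]]:
    """Full Cartesian product of regulated x constant transcripts.

    Returns all candidate (regulated_id, constant_id) pairs in a fixed
    (sorted) order; the count is |regulated| * |constant|.
    """
    regulated = catalog.regulated_ids(stressor)
    constant = catalog.constant_ids(stressor)
    return [(r, c) for r in regulated for c in constant]


def compute_pair_bounds(
    lab_normalized: CountMatrix,
    catalog: MarkerCatalog,
    stressor: str,
    delta: float = DEFAULT_DELTA,
) -> list[MarkerPair]:
    """Derive lab ratio bounds for every enumerated marker pair.

    Replicate aggregation is mean-then-ratio: ``x_min`` is the ratio of the
    control-replicate mean abundances of the regulated and constant
    transcripts, ``x_max`` the same under the stress condition.  Pairs with
    a zero denominator or |x_max - x_min| < ``delta`` are dropped with a
    logged reason.
    """
    condition = STRESS_CONDITION[stressor]
    ctrl_mean = lab_normalized.condition_means("control")
    stress_mean = lab_normalized.condition_means(condition)

    pairs: list[MarkerPair] = []
    dropped = 0
    for idx, (r, c) in enumerate(enumerate_pairs(catalog, stressor)):
        c_ctrl, c_stress = ctrl_mean.get(c, 0.0), stress_mean.get(c, 0.0)
        r_ctrl, r_stress = ctrl_mean.get(r, 0.0), stress_mean.get(r, 0.0)
        if c_ctrl == 0 or c_stress == 0:
            logger.info("pair (%s, %s) dropped: zero constant-transcript mean", r, c)
            dropped += 1
            continue
        if r_ctrl == 0 or r_stress == 0:
            logger.info("pair (%s, %s) dropped: zero regulated-transcript mean", r, c)
            dropped += 1
            continue
        x_min = r_ctrl / c_ctrl
        x_max = r_stress / c_stress
        if abs(x_max - x_min) < delta:
            logger.info("pair (%s, %s) dropped: degenerate bounds", r, c)
            dropped += 1
            continue
        pairs.append(
            MarkerPair(
                pair_index=idx,
                regulated_id=r,
                constant_id=c,
                stressor=stressor,
                direction=catalog.direction(stressor, r),
                x_min=x_min,
                x_max=x_max,
            )
        )
    if dropped:
        logger.info("%s: %d pairs dropped, %d usable", stressor, dropped, len(pairs))
    return pairs


def categorize(gmi: float) -> str:
    """Bin a GMI value: out-of-range flags or in-range quartile."""
    if gmi < 0:
        return "below_range"
    if gmi > 100:
        return "above_range"
    if gmi < 25:
        return "q1"
    if gmi < 50:
        return "q2"
    if gmi < 75:
        return "q3"
    return "q4"


def compute_gmi(
    pair: MarkerPair, field_normalized: CountMatrix, sample_id: str
) -> GMIRecord | None:
    """Evaluate one marker pair in one field sample.

    Returns ``None`` (with a logged reason) when either transcript is
    absent from the field table or the constant transcript's abundance is
    zero in the sample; no pseudocount is applied, which preserves exact
    invariance of the index to per-sample scaling.
    """
    values = field_normalized.values
    for tid, role in ((pair.regulated_id, "regulated"), (pair.constant_id, "constant")):
        if tid not in values.index:
            logger.info(
                "pair %d sample %s skipped: %s transcript %s absent from field table",
                pair.pair_index, sample_id, role, tid,
            )
            return None
    denom = values.at[pair.constant_id, sample_id]
    if denom == 0:
        logger.info(
            "pair %d sample %s skipped: constant transcript %s has zero abundance",
            pair.pair_index, sample_id, pair.constant_id,
        )
        return None
    x_i = values.at[pair.regulated_id, sample_id] / denom
    gmi = (x_i - pair.x_min) / (pair.x_max - pair.x_min) * 100.0
    return GMIRecord(
        pair_index=pair.pair_index,
        regulated_id=pair.regulated_id,
        constant_id=pair.constant_id,
        sample_id=sample_id,
        x_i=x_i,
        gmi=gmi,
        category=categorize(gmi),
    )


def compute_gmi_table(
    pairs: list[MarkerPair], field_normalized: CountMatrix
) -> pd.DataFrame:
    """Evaluate all pairs across all field samples.

    Returns one row per successful (pair, sample) evaluation with the same
    columns as :class:`GMIRecord`; skipped evaluations are logged.
    """
    records = []
    for sample_id in field_normalized.sample_ids:
        for pair in pairs:
            rec = compute_gmi(pair, field_normalized, sample_id)
            if rec is not None:
                records.append(rec)
    return pd.DataFrame([r.__dict__ for r in records], columns=[
        "pair_index", "regulated_id", "constant_id", "sample_id", "x_i", "gmi", "category",
    ])


@dataclass
class GMISummary:
    """Distributional summary of a set of GMI evaluations.

    ``in range`` means GMI in [0, 100]: the field ratio falls between the
    lab control and stress endpoints.  ``transcript_in_range_freq`` counts,
    per regulated transcript, how often its pairs landed in range -- a
    reliability screen for individual markers.
    """

    n_total: int
    n_in_range: int
    n_below: int
    n_above: int
    category_counts: dict[str, int]
    in_range_mean: float
    in_range_sd: float
    transcript_in_range_freq: dict[str, int]

    @property
    def fraction_in_range(self) -> float:
        return self.n_in_range / self.n_total

    @property
    def fraction_out_of_range(self) -> float:
        return (self.n_below + self.n_above) / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_in_range": self.n_in_range,
            "n_below": self.n_below,
            "n_above": self.n_above,
            "fraction_in_range": self.fraction_in_range,
            "fraction_out_of_range": self.fraction_out_of_range,
            "category_counts": self.category_counts,
            "in_range_mean": self.in_range_mean,
            "in_range_sd": self.in_range_sd,
            "transcript_in_range_freq": self.transcript_in_range_freq,
        }


def summarize_gmi(records: pd.DataFrame) -> GMISummary:
    """Summarize a GMI record table (out-of-range split, in-range mean/SD)."""
    if records.empty:
        raise ValueError("no GMI records to summarize")
    gmi = records["gmi"].to_numpy()
    in_range = (gmi >= 0) & (gmi <= 100)
    counts = {cat: int((records["category"] == cat).sum()) for cat in CATEGORIES}
    in_vals = gmi[in_range]
    freq = (
        records.loc[in_range]
        .groupby("regulated_id")
        .size()
        .astype(int)
        .to_dict()
    )
    return GMISummary(
        n_total=len(records),
        n_in_range=int(in_range.sum()),
        n_below=counts["below_range"],
        n_above=counts["above_range"],
        category_counts=counts,
        in_range_mean=float(np.mean(in_vals)) if len(in_vals) else float("nan"),
        in_range_sd=float(np.std(in_vals, ddof=1)) if len(in_vals) > 1 else float("nan"),
        transcript_in_range_freq=freq,
    )


def pairs_to_frame(pairs: list[MarkerPair]) -> pd.DataFrame:
    """Tabulate marker pairs for TSV output."""
    return pd.DataFrame(
        [p.__dict__ for p in pairs],
        columns=["pair_index", "regulated_id", "constant_id", "stressor", "direction", "x_min", "x_max"],
    )
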