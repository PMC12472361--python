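"""Synthetic laboratory and field data with known ground truth.

The generator stands in for the sequencing stages of the original study
design: replicated lab stress experiments (control / cold / desiccated),
field metatranscriptome replicates drawn at a known latent stress fraction,
and a BLAST-style identity-hit table linking field contigs to reference
transcripts.  Because the truth (which transcripts are regulated, by how
much, and how stressed each field sample is) is known exactly, every
downstream stage -- classifier, catalog, hit filtering, marker-index
computation, clustering -- can be validated quantitatively.

Counts follow a negative-binomial model: a transcript with expected count
``mu`` in a sample is drawn with variance ``mu + phi * mu**2`` where
``phi`` is the scenario's overdispersion (``phi = 0`` degenerates to
Poisson).  Field samples interpolate expected abundances arithmetically
between the control and stress expectations, ``(1 - s) * E[control] +
s * E[stress]``, which makes the marker-pair ratio linear in ``s`` whenever
the denominator transcript is constant -- the analytic basis of the
index-recovery tests.

All randomness stems from one scenario seed.  Sub-streams are derived with
numpy ``SeedSequence(seed, spawn_key=(k,))`` using fixed keys (0 = lab,
1 = field cold, 2 = field desiccation, 3 = identity hits), so adding a new
simulator never perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix
from .markers import MarkerCatalog, StressorMarkers

_STREAM_LAB = 0
_STREAM_FIELD = {"cold": 1, "desiccation": 2}
_STREAM_HITS = 3

LABEL_CLASSES = ("up_cold", "down_cold", "up_des", "down_des", "dual", "constant", "background")


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic experiment.

    Defaults emulate the study conditions: three replicates per lab
    condition, regulated transcripts with fold changes well above the
    detection threshold of 2, roughly a third of each stressor's regulated
    set shared with the other stressor, and one field replicate per latent
    stress level.
    """

    n_transcripts: int = 2000
    n_up_cold: int = 60
    n_down_cold: int = 60
    n_up_des: int = 60
    n_down_des: int = 60
    overlap_fraction: float = 1 / 3
    n_constant: int = 100
    fold_change_range: tuple[float, float] = (4.0, 8.0)
    baseline_mean_range: tuple[float, float] = (20.0, 500.0)
    dispersion: float = 0.05
    n_replicates_per_condition: int = 3
    field_stress_levels: tuple[float, ...] = (0.25, 0.5, 0.75)
    library_size_range: tuple[float, float] = (1e6, 2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_transcripts,
            self.n_up_cold,
            self.n_down_cold,
            self.n_up_des,
            self.n_down_des,
            self.n_constant,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all transcript counts must be nonnegative")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if self.fold_change_range[0] <= 2:
            raise ValueError(
                "fold_change_range lower bound must exceed 2 (the detection "
                "threshold); smaller true effects make the truth unlearnable"
            )
        if self.fold_change_range[0] > self.fold_change_range[1]:
            raise ValueError("fold_change_range must be (low, high)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if any(not 0 <= s <= 1 for s in self.field_stress_levels):
            raise ValueError("field stress levels must lie in [0, 1]")
        if self.n_labelled + self.n_dual > self.n_transcripts:
            raise ValueError("labelled transcripts exceed n_transcripts")

    @property
    def n_dual(self) -> int:
        """Dual-regulated transcript count implied by overlap_fraction.

        ``overlap_fraction`` is the share of each stressor's full regulated
        set that is also regulated by the other stressor, so with S
        single-stressor transcripts per stressor the dual count d solves
        d / (S + d) = overlap_fraction.
        """
        single = min(
            self.n_up_cold + self.n_down_cold, self.n_up_des + self.n_down_des
        )
        f = self.overlap_fraction
        return int(round(f / (1 - f) * single))

    @property
    def n_labelled(self) -> int:
        return (
            self.n_up_cold
            + self.n_down_cold
            + self.n_up_des
            + self.n_down_des
            + self.n_constant
        )


@dataclass
class TruthLabels:
    """Ground truth of a synthetic experiment.

    ``labels`` maps every transcript to exactly one class; ``fold_changes``
    holds the true multiplicative factor applied per stressor (1.0 means
    unaffected, values < 1 mean down-regulation); ``expected_means`` carries
    each transcript's expected abundance (arbitrary expression units, before
    library-size scaling) per lab condition, the quantity the field
    interpolation operates on.
    """

    labels: pd.Series
    fold_changes: pd.DataFrame  # columns: cold, desiccation
    expected_means: pd.DataFrame  # columns: control, cold, desiccated

    def ids_with_label(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def direction(self, transcript_id: str, stressor: str) -> str:
        fc = self.fold_changes.loc[transcript_id, stressor]
        if fc > 1:
            return "up"
        if fc < 1:
            return "down"
        return "none"


def _rng(scenario_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario_seed, spawn_key=(stream,)))


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draw with variance mu + phi * mu^2 (Poisson if phi=0)."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / phi
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def _assign_truth(scenario: SyntheticScenario, rng: np.random.Generator) -> TruthLabels:
    n = scenario.n_transcripts
    ids = [f"T{i:06d}" for i in range(n)]
    labels = pd.Series("background", index=pd.Index(ids, name="transcript_id"))
    fc = pd.DataFrame(1.0, index=labels.index, columns=["cold", "desiccation"])

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        block = ids[cursor : cursor + k]
        cursor += k
        return block

    def draw_fc(k: int) -> np.ndarray:
        lo, hi = scenario.fold_change_range
        return rng.uniform(lo, hi, size=k)

    for label, stressor, up in [
        ("up_cold", "cold", True),
        ("down_cold", "cold", False),
        ("up_des", "desiccation", True),
        ("down_des", "desiccation", False),
    ]:
        k = getattr(scenario, f"n_{label}")
        block = take(k)
        labels[block] = label
        f = draw_fc(k)
        fc.loc[block, stressor] = f if up else 1.0 / f

    dual = take(scenario.n_dual)
    labels[dual] = "dual"
    for stressor in ("cold", "desiccation"):
        f = draw_fc(len(dual))
        up = rng.random(len(dual)) < 0.5
        fc.loc[dual, stressor] = np.where(up, f, 1.0 / f)

    constant = take(scenario.n_constant)
    labels[constant] = "constant"

    lo, hi = scenario.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    expected = pd.DataFrame(
        {
            "control": baseline,
            "cold": baseline * fc["cold"].to_numpy(),
            "desiccated": baseline * fc["desiccation"].to_numpy(),
        },
        index=labels.index,
    )
    return TruthLabels(labels=labels, fold_changes=fc, expected_means=expected)


def _sample_counts(
    rng: np.random.Generator,
    expected: np.ndarray,
    library_size: float,
    phi: float,
) -> np.ndarray:
    mu = expected / expected.sum() * library_size
    return _draw_counts(rng, mu, phi)


def simulate_lab_experiment(scenario: SyntheticScenario) -> tuple[CountMatrix, TruthLabels]:
    """Simulate the replicated lab stress experiment.

    Returns a count matrix with conditions control / cold / desiccated at
    ``n_replicates_per_condition`` each, and the ground-truth labels.
    Identical scenarios (including seed) give identical output.
    """
    rng = _rng(scenario.seed, _STREAM_LAB)
    truth = _assign_truth(scenario, rng)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for condition in ("control", "cold", "desiccated"):
        profile = truth.expected_means[condition].to_numpy()
        for rep in range(1, scenario.n_replicates_per_condition + 1):
            lib = rng.uniform(*scenario.library_size_range)
            sample_id = f"lab_{condition}_{rep}"
            columns[sample_id] = _sample_counts(rng, profile, lib, scenario.dispersion)
            meta_rows.append((sample_id, condition, "lab", rep))

    values = pd.DataFrame(columns, index=truth.labels.index, dtype=float)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "site", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(values, samples), truth


def expected_field_means(truth: TruthLabels, stressor: str, s: float) -> pd.Series:
    """Expected field abundance profile at latent stress fraction ``s``.

    Linear interpolation between the control and stress expectations; used
    by the field simulator and directly testable for linearity in ``s``.
    """
    if not 0 <= s <= 1:
        raise ValueError(f"stress fraction must lie in [0, 1], got {s}")
    condition = {"cold": "cold", "desiccation": "desiccated"}[stressor]
    ctrl = truth.expected_means["control"]
    stress = truth.expected_means[condition]
    return (1 - s) * ctrl + s * stress


def simulate_field_samples(
    scenario: SyntheticScenario,
    lab: CountMatrix,
    truth: TruthLabels,
    stressor: str,
    site: str = "site1",
) -> CountMatrix:
    """Simulate field replicates at the scenario's latent stress levels.

    One sample is drawn per entry of ``field_stress_levels``; a level of 0
    reproduces the lab control expectations, 1 the lab stress expectations.
    """
    if stressor not in _STREAM_FIELD:
        raise ValueError(f"unknown stressor {stressor!r}")
    missing = {"control", {"cold": "cold", "desiccation": "desiccated"}[stressor]} - set(
        lab.samples["condition"]
    )
    if missing:
        raise ValueError(f"lab matrix lacks conditions: {sorted(missing)}")
    rng = _rng(scenario.seed, _STREAM_FIELD[stressor])
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for rep, s in enumerate(scenario.field_stress_levels, start=1):
        profile = expected_field_means(truth, stressor, s).to_numpy()
        lib = rng.uniform(*scenario.library_size_range)
        sample_id = f"field_{site}_{stressor}_{rep}"
        columns[sample_id] = _sample_counts(rng, profile, lib, scenario.dispersion)
        meta_rows.append((sample_id, "field", site, rep))
    values = pd.DataFrame(columns, index=truth.labels.index, dtype=float)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "site", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(values, samples)


BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def simulate_identity_hits(
    truth: TruthLabels, n_decoys: int, seed: int
) -> pd.DataFrame:
    """Fabricate a BLAST tabular hit table for field contigs.

    Every truth transcript receives one confident hit (identity uniform in
    [98, 100], e-value <= 1e-60) from a contig named ``contig_<id>``.
    Decoys alternate between low-identity hits (identity in [80, 98)) and
    high-identity hits with e-values above the retention threshold, so the
    default filter keeps exactly the truth hits.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_HITS,)))
    ids = truth.labels.index.tolist()
    rows = []

    def hit_row(qseqid, sseqid, pident, evalue):
        length = int(rng.integers(300, 2000))
        mismatch = int(round(length * (100 - pident) / 100))
        bitscore = float(np.round(rng.uniform(200, 2000), 1))
        return (
            qseqid,
            sseqid,
            round(pident, 3),
            length,
            mismatch,
            0,
            1,
            length,
            1,
            length,
            evalue,
            bitscore,
        )

    for tid in ids:
        pident = rng.uniform(98.0, 100.0)
        evalue = 10.0 ** (-rng.uniform(60.0, 180.0))
        rows.append(hit_row(f"contig_{tid}", tid, pident, evalue))
    for k in range(n_decoys):
        subject = ids[int(rng.integers(len(ids)))]
        if k % 2 == 0:
            pident = rng.uniform(80.0, 97.99)
            evalue = 10.0 ** (-rng.uniform(60.0, 120.0))
        else:
            pident = rng.uniform(98.0, 100.0)
            evalue = 10.0 ** (-rng.uniform(10.0, 49.5))
        rows.append(hit_row(f"decoy_{k:05d}", subject, pident, evalue))
    return pd.DataFrame(rows, columns=list(BLAST_COLUMNS))


def scenario_from_dict(d: dict) -> SyntheticScenario:
    """Build a scenario from a plain dict (e.g. parsed YAML config)."""
    kwargs = dict(d)
    for key in ("fold_change_range", "baseline_mean_range", "library_size_range", "field_stress_levels"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticScenario(**kwargs)


def scenario_to_dict(scenario: SyntheticScenario) -> dict:
    d = asdict(scenario)
    for key, value in d.items():
        if isinstance(value, tuple):
            d[key] = list(value)
    return d


# -- printed-table fixture ---------------------------------------------------


def make_table4_fixture(site: str = "site1") -> tuple[MarkerCatalog, CountMatrix]:
    """Deterministic catalog + lab counts sized like the published field study.

    The returned catalog mirrors the study's per-site marker counts: for
    cold stress, 13 constantly expressed transcripts with 11 regulated ones
    at site 1 (10 at site 3); for desiccation, 12 constant and 8 regulated
    at either site.  The accompanying noise-free count matrix (three
    replicates per condition) yields well-separated, non-degenerate ratio
    bounds for every pair, so the full Cartesian pair enumeration survives
    degeneracy filtering: 143 pairs (site 1, cold), 130 (site 3, cold) and
    96 (desiccation).
    """
    if site not in ("site1", "site3"):
        raise ValueError(f"unknown site {site!r}; expected 'site1' or 'site3'")
    n_reg_cold = 11 if site == "site1" else 10
    sizes = {
        "cold": {"regulated": n_reg_cold, "constant": 13},
        "desiccation": {"regulated": 8, "constant": 12},
    }

    regulated: dict[str, dict[str, str]] = {}
    constant: dict[str, set[str]] = {}
    values: dict[str, dict[str, float]] = {}
    fold = 4.0

    for stressor, prefix_reg, prefix_const in (
        ("cold", "CR", "CC"),
        ("desiccation", "DR", "DC"),
    ):
        condition = {"cold": "cold", "desiccation": "desiccated"}[stressor]
        regulated[stressor] = {}
        for j in range(sizes[stressor]["regulated"]):
            tid = f"{prefix_reg}{j + 1:02d}"
            direction = "up" if j % 2 == 0 else "down"
            regulated[stressor][tid] = direction
            base = 10.0 + j
            stressed = base * fold if direction == "up" else base / fold
            values[tid] = {"control": base, "cold": base, "desiccated": base}
            values[tid][condition] = stressed
        constant[stressor] = set()
        for j in range(sizes[stressor]["constant"]):
            tid = f"{prefix_const}{j + 1:02d}"
            constant[stressor].add(tid)
            level = 50.0 + 3.0 * j
            values[tid] = {"control": level, "cold": level, "desiccated": level}

    catalog = MarkerCatalog(
        stressors={
            s: StressorMarkers(regulated=regulated[s], constant=constant[s])
            for s in ("cold", "desiccation")
        },
        provenance={"source": "published per-site marker counts", "site": site},
    )
    catalog.validate()

    columns: dict[str, list[float]] = {}
    meta_rows = []
    tids = sorted(values)
    for condition in ("control", "cold", "desiccated"):
        for rep in range(1, 4):
            sample_id = f"lab_{condition}_{rep}"
            columns[sample_id] = [values[t][condition] for t in tids]
            meta_rows.append((sample_id, condition, "lab", rep))
    matrix = CountMatrix(
        pd.DataFrame(columns, index=pd.Index(tids, name="transcript_id")),
        pd.DataFrame(meta_rows, columns=["sample_id", "condition", "site", "replicate"]).set_index("sample_id"),
    )
    return catalog, matrix


def write_truth(truth: TruthLabels, path: str | Path) -> None:
    """Write truth labels and fold changes as one TSV."""
    out = pd.DataFrame(
        {
            "label": truth.labels,
            "fold_change_cold": truth.fold_changes["cold"],
            "fold_change_desiccation": truth.fold_changes["desiccation"],
        }
    )
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", float_format="%.9g")
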