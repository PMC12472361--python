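"""End-to-end pipeline: configuration, orchestration and output files.

``run_pipeline`` chains the stages -- (optionally) simulate, classify
regulation, build the marker catalog, filter identity hits and map field
contigs, derive ratio bounds, evaluate marker indices, assemble datasets 1
and 2 and run the clustering/SIMPROF comparison -- and writes every
intermediate table as TSV plus a provenance manifest.  Identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .countmatrix import CountMatrix, FLOAT_FMT, normalize_relative, read_counts, write_counts
from .markers import (
    MarkerCatalog,
    StressorMarkers,
    Thresholds,
    build_catalog,
    classify_regulation,
    find_constant,
    summarize_regulation,
)
from .fieldmatch import (
    DEFAULT_MAX_EVALUE,
    DEFAULT_MIN_IDENTITY,
    filter_hits,
    map_to_reference,
    read_blast_tab,
    write_blast_tab,
)
from .gmi import compute_pair_bounds, compute_gmi_table, pairs_to_frame, summarize_gmi
from .cluster import DatasetSpec, build_dataset, render_newick, simprof
from .synthetic import (
    SyntheticScenario,
    scenario_from_dict,
    scenario_to_dict,
    simulate_field_samples,
    simulate_identity_hits,
    simulate_lab_experiment,
    write_truth,
)
from . import __version__

logger = logging.getLogger(__name__)

STRESSORS = ("cold", "desiccation")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``scenario`` (synthetic mode) or the four input paths
    (``lab_counts`` ... ``blast_hits``) must be provided.  Thresholds
    default to the published values: identity >= 98%, e-value <= 1e-50,
    fold change > 2, p < 0.05, FDR < 0.05.
    """

    out_dir: str = "gmindex_out"
    seed: int = 0
    scenario: dict | None = None
    n_decoys: int = 100
    lab_counts: str | None = None
    lab_metadata: str | None = None
    field_counts: str | None = None
    field_metadata: str | None = None
    blast_hits: str | None = None
    min_identity: float = DEFAULT_MIN_IDENTITY
    max_evalue: float = DEFAULT_MAX_EVALUE
    fold_change: float = 2.0
    p_value: float = 0.05
    fdr: float = 0.05
    stability_threshold: float = 0.5
    pseudocount: float = 0.5
    delta: float = 1e-9
    alpha: float = 0.05
    n_expected: int = 999
    n_simulated: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> Thresholds:
        return Thresholds(
            fold_change=self.fold_change,
            p_value=self.p_value,
            fdr=self.fdr,
            pseudocount=self.pseudocount,
            stability_threshold=self.stability_threshold,
        )


def write_catalog(catalog: MarkerCatalog, path: str | Path) -> None:
    rows = []
    for stressor in sorted(catalog.stressors):
        m = catalog.stressors[stressor]
        for tid in sorted(m.regulated):
            rows.append((tid, "regulated", stressor, m.regulated[tid]))
        for tid in sorted(m.constant):
            rows.append((tid, "constant", stressor, ""))
    for tid in catalog.dual_ids():
        for stressor, direction in sorted(catalog.dual[tid].items()):
            rows.append((tid, "dual", stressor, direction))
    pd.DataFrame(rows, columns=["transcript_id", "role", "stressor", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path: str | Path) -> MarkerCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    stressors = {}
    for stressor in sorted(df["stressor"].unique()):
        sub = df[df["stressor"] == stressor]
        regulated = dict(
            zip(sub.loc[sub["role"] == "regulated", "transcript_id"],
                sub.loc[sub["role"] == "regulated", "direction"])
        )
        constant = set(sub.loc[sub["role"] == "constant", "transcript_id"])
        stressors[stressor] = StressorMarkers(regulated=regulated, constant=constant)
    dual: dict[str, dict[str, str]] = {}
    for _, row in df[df["role"] == "dual"].iterrows():
        dual.setdefault(row["transcript_id"], {})[row["stressor"]] = row["direction"]
    catalog = MarkerCatalog(stressors=stressors, dual=dual)
    catalog.validate()
    return catalog


class StageError(RuntimeError):
    """Pipeline failure carrying the stage name and underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, exc) from exc
        return wrapper
    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig, out: Path):
    """Simulate or read the lab matrix, field matrix and hit table."""
    if config.scenario is not None:
        scenario_kwargs = dict(config.scenario)
        scenario_kwargs.setdefault("seed", config.seed)
        scenario = scenario_from_dict(scenario_kwargs)
        lab, truth = simulate_lab_experiment(scenario)
        fields = [
            simulate_field_samples(scenario, lab, truth, stressor)
            for stressor in STRESSORS
        ]
        field = CountMatrix(
            pd.concat([f.values for f in fields], axis=1),
            pd.concat([f.samples for f in fields]),
        )
        # field contigs carry assembly-style names distinct from reference IDs
        field.values.index = pd.Index(
            [f"contig_{t}" for t in field.values.index], name="transcript_id"
        )
        hits = simulate_identity_hits(truth, config.n_decoys, scenario.seed)
        write_counts(lab, out / "lab_counts.tsv", out / "lab_metadata.tsv")
        write_counts(field, out / "field_counts.tsv", out / "field_metadata.tsv")
        write_blast_tab(hits, out / "identity_hits.tsv")
        write_truth(truth, out / "truth.tsv")
        return lab, field, hits
    for name in ("lab_counts", "lab_metadata", "field_counts", "field_metadata", "blast_hits"):
        value = getattr(config, name)
        if value is None:
            raise ValueError(f"config needs either 'scenario' or the {name!r} path")
        if not Path(value).exists():
            raise FileNotFoundError(f"{name} file not found: {value}")
    lab = read_counts(config.lab_counts, config.lab_metadata)
    field = read_counts(config.field_counts, config.field_metadata)
    hits = read_blast_tab(config.blast_hits)
    return lab, field, hits


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write results under ``config.out_dir``.

    Returns a dict of the in-memory results keyed by stage, for
    programmatic use; the on-disk outputs are the authoritative record.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds()

    lab, field, hits = _load_inputs(config, out)

    @_stage("classify")
    def _classify():
        records = {s: classify_regulation(lab, s, thresholds) for s in STRESSORS}
        for s, rec in records.items():
            rec.to_csv(out / f"regulation_{s}.tsv", sep="\t", float_format=FLOAT_FMT)
        summarize_regulation(list(records.values())).to_csv(
            out / "regulation_summary.tsv", sep="\t"
        )
        return records

    records = _classify()

    @_stage("catalog")
    def _catalog():
        constant = find_constant(
            records["cold"], records["desiccation"], lab, config.stability_threshold
        )
        catalog = build_catalog(
            records["cold"],
            records["desiccation"],
            constant,
            provenance={"thresholds": asdict(thresholds)},
        )
        write_catalog(catalog, out / "catalog.tsv")
        return catalog

    catalog = _catalog()

    @_stage("match")
    def _match():
        retained = filter_hits(hits, config.min_identity, config.max_evalue)
        table = map_to_reference(retained, field)
        write_counts(table, out / "field_mapped.tsv")
        return table

    field_table = _match()

    @_stage("gmi")
    def _gmi():
        lab_norm = normalize_relative(lab)
        field_norm = normalize_relative(field_table)
        results = {}
        summaries = {}
        for stressor in STRESSORS:
            pairs = compute_pair_bounds(lab_norm, catalog, stressor, config.delta)
            pairs_to_frame(pairs).to_csv(
                out / f"pairs_{stressor}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
            )
            table = compute_gmi_table(pairs, field_norm)
            table.to_csv(
                out / f"gmi_records_{stressor}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
            )
            results[stressor] = {"pairs": pairs, "records": table}
            if len(table):
                summaries[stressor] = summarize_gmi(table).as_dict()
        with open(out / "gmi_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
        return results

    gmi_results = _gmi()

    @_stage("cluster")
    def _cluster():
        field_norm = normalize_relative(field_table)
        out_clusters = {}
        for stressor in STRESSORS:
            for variant in ("dataset1", "dataset2"):
                spec = DatasetSpec(variant=variant, stressor=stressor)
                try:
                    dataset = build_dataset(catalog, field_norm, lab, spec)
                except ValueError as exc:
                    logger.warning("skipping %s/%s: %s", stressor, variant, exc)
                    continue
                result = simprof(
                    dataset,
                    alpha=config.alpha,
                    n_expected=config.n_expected,
                    n_simulated=config.n_simulated,
                    seed=config.seed,
                )
                name = f"{stressor}_{variant}"
                (out / f"dendrogram_{name}.nwk").write_text(
                    render_newick(result.dendrogram, result) + "\n", encoding="utf-8"
                )
                result.node_table.to_csv(
                    out / f"simprof_{name}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
                )
                out_clusters[name] = result
        return out_clusters

    cluster_results = _cluster()

    manifest = {
        "tool": "gmindex",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "lab": lab,
        "field": field,
        "records": records,
        "catalog": catalog,
        "field_table": field_table,
        "gmi": gmi_results,
        "clusters": cluster_results,
    }


def simulate_to_dir(scenario: SyntheticScenario, out_dir: str | Path, n_decoys: int = 100) -> None:
    """Write a full synthetic input set (lab, field, truth, hits) as TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lab, truth = simulate_lab_experiment(scenario)
    write_counts(lab, out / "lab_counts.tsv", out / "lab_metadata.tsv")
    fields = [simulate_field_samples(scenario, lab, truth, s) for s in STRESSORS]
    field = CountMatrix(
        pd.concat([f.values for f in fields], axis=1),
        pd.concat([f.samples for f in fields]),
    )
    field.values.index = pd.Index(
        [f"contig_{t}" for t in field.values.index], name="transcript_id"
    )
    write_counts(field, out / "field_counts.tsv", out / "field_metadata.tsv")
    write_truth(truth, out / "truth.tsv")
    write_blast_tab(
        simulate_identity_hits(truth, n_decoys, scenario.seed), out / "identity_hits.tsv"
    )
    with open(out / "scenario.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)
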