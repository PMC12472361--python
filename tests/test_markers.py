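import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gmindex import (
    Thresholds,
    build_catalog,
    classify_regulation,
    find_constant,
    read_regulation_table,
    summarize_regulation,
)

from conftest import make_matrix


def lab_with_target(ctrl_vals, stress_vals, n_background=1000, background_level=100.0):
    """One target transcript plus flat no-effect background, control vs cold."""
    n = len(ctrl_vals)
    transcripts = ["target"] + [f"bg{i}" for i in range(n_background)]
    columns = {}
    conditions = {}
    for j in range(n):
        sid = f"ctrl{j}"
        columns[sid] = [ctrl_vals[j]] + [background_level] * n_background
        conditions[sid] = "control"
    for j in range(n):
        sid = f"cold{j}"
        columns[sid] = [stress_vals[j]] + [background_level] * n_background
        conditions[sid] = "cold"
    return make_matrix(columns, transcripts, conditions)


def independent_welch_bh_oracle(lab, stressor_condition="cold"):
    """Brute-force re-derivation of the classifier's statistics.

    Uses plain per-transcript loops over scipy's Welch test and a single
    statsmodels BH call, independent of the vectorized implementation path.
    """
    totals = lab.values.sum(axis=0)
    cpm = lab.values / totals * 1e6
    ctrl = lab.condition_samples("control")
    stress = lab.condition_samples(stressor_condition)
    rows = {}
    pvals = []
    for tid in lab.transcript_ids:
        a = np.log2(cpm.loc[tid, stress].to_numpy(dtype=float) + 1)
        b = np.log2(cpm.loc[tid, ctrl].to_numpy(dtype=float) + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(p):
            p = 1.0
        lfc = np.log2((cpm.loc[tid, stress].mean() + 0.5) / (cpm.loc[tid, ctrl].mean() + 0.5))
        rows[tid] = (lfc, p)
        pvals.append(p)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = {}
    for (tid, (lfc, p)), q in zip(rows.items(), fdr):
        if p < 0.05 and q < 0.05 and lfc > 1:
            cls = "up"
        elif p < 0.05 and q < 0.05 and lfc < -1:
            cls = "down"
        else:
            cls = "not_regulated"
        out[tid] = (lfc, p, q, cls)
    return out


class TestClassifyRegulation:
    def test_flat_transcript_not_regulated(self):
        lab = lab_with_target([10, 10, 10], [10, 10, 10], n_background=5)
        rec = classify_regulation(lab, "cold")
        assert rec.loc["target", "class"] == "not_regulated"
        assert rec.loc["target", "log2_fold_change"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "ctrl, stress",
        [
            ([10, 10, 10], [50, 48, 52]),
            ([10, 10, 10, 10, 10], [50, 48, 52, 49, 51]),
        ],
    )
    def test_statistics_match_independent_oracle(self, ctrl, stress):
        """Every statistic (log2FC, p, FDR, class) of a fivefold-increase
        transcript among 1000 flat ones agrees with an independently coded
        per-transcript Welch+BH oracle."""
        lab = lab_with_target(ctrl, stress, n_background=1000)
        rec = classify_regulation(lab, "cold")
        oracle = independent_welch_bh_oracle(lab)
        for tid in ["target", "bg0", "bg500"]:
            lfc, p, q, cls = oracle[tid]
            assert rec.loc[tid, "log2_fold_change"] == pytest.approx(lfc, rel=1e-9)
            assert rec.loc[tid, "p_value"] == pytest.approx(p, rel=1e-9)
            assert rec.loc[tid, "fdr"] == pytest.approx(q, rel=1e-9)
            assert rec.loc[tid, "class"] == cls

    def test_fivefold_increase_called_up(self):
        """A 10 -> 50 transcript among 1000 no-effect background transcripts
        clears all three thresholds (fold change > 2, p < 0.05, FDR < 0.05)
        and is classified up."""
        lab = lab_with_target([10, 10, 10], [50, 48, 52], n_background=1000)
        rec = classify_regulation(lab, "cold")
        assert rec.loc["target", "class"] == "up"
        assert rec.loc["target", "log2_fold_change"] > 1

    def test_direction_matches_truth_on_low_noise_data(self, low_noise_lab):
        _, lab, truth = low_noise_lab
        for stressor, up_label, down_label in [
            ("cold", "up_cold", "down_cold"),
            ("desiccation", "up_des", "down_des"),
        ]:
            rec = classify_regulation(lab, stressor)
            assert (rec.loc[truth.ids_with_label(up_label), "class"] == "up").all()
            assert (rec.loc[truth.ids_with_label(down_label), "class"] == "down").all()
            assert (rec.loc[truth.ids_with_label("constant"), "class"] == "not_regulated").all()

    def test_bh_adjustment_is_monotone_in_p(self, low_noise_lab):
        _, lab, _ = low_noise_lab
        rec = classify_regulation(lab, "cold").sort_values("p_value")
        assert (np.diff(rec["fdr"].to_numpy()) >= -1e-12).all()

    def test_too_few_replicates_rejected(self):
        lab = make_matrix(
            {"c1": [1], "k1": [2], "k2": [3]},
            ["tA"],
            {"c1": "control", "k1": "cold", "k2": "cold"},
        )
        with pytest.raises(ValueError, match="replicates"):
            classify_regulation(lab, "cold")

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(fold_change=0.5)
        with pytest.raises(ValueError):
            Thresholds(p_value=1.5)


class TestFindConstant:
    def make_records(self, entries):
        frames = {}
        for stressor in ("cold", "desiccation"):
            rows = []
            for tid, (lfc_c, cls_c, lfc_d, cls_d) in entries.items():
                lfc, cls = (lfc_c, cls_c) if stressor == "cold" else (lfc_d, cls_d)
                rows.append((tid, stressor, lfc, 0.5, 0.5, cls))
            frames[stressor] = pd.DataFrame(
                rows,
                columns=["transcript_id", "stressor", "log2_fold_change", "p_value", "fdr", "class"],
            ).set_index("transcript_id")
        return frames["cold"], frames["desiccation"]

    def test_rules(self):
        entries = {
            "flat": (0.1, "not_regulated", -0.1, "not_regulated"),
            "cold_up": (2.0, "up", 0.0, "not_regulated"),
            "wobbly": (0.45, "not_regulated", 0.8, "not_regulated"),
            "zero_in_des": (0.0, "not_regulated", 0.0, "not_regulated"),
        }
        rc, rd = self.make_records(entries)
        lab = make_matrix(
            {
                "c1": [10, 10, 10, 10], "c2": [10, 10, 10, 10],
                "k1": [10, 40, 10, 10], "k2": [10, 40, 10, 10],
                "d1": [10, 10, 15, 0], "d2": [10, 10, 18, 0],
            },
            ["flat", "cold_up", "wobbly", "zero_in_des"],
            {"c1": "control", "c2": "control", "k1": "cold", "k2": "cold",
             "d1": "desiccated", "d2": "desiccated"},
        )
        constant = find_constant(rc, rd, lab, stability_threshold=0.5)
        assert constant == {"flat"}


class TestBuildCatalog:
    def records(self, regulated: dict[str, str], stressor: str):
        rows = [
            (tid, stressor, 2.0 if d == "up" else -2.0, 0.001, 0.001, d)
            for tid, d in regulated.items()
        ]
        return pd.DataFrame(
            rows, columns=["transcript_id", "stressor", "log2_fold_change", "p_value", "fdr", "class"]
        ).set_index("transcript_id")

    def test_set_algebra(self):
        rc = self.records({"A": "up", "B": "down", "C": "up"}, "cold")
        rd = self.records({"B": "up", "D": "down"}, "desiccation")
        cat = build_catalog(rc, rd, {"H1", "H2"})
        assert set(cat.stressors["cold"].regulated) == {"A", "C"}
        assert set(cat.stressors["desiccation"].regulated) == {"D"}
        assert set(cat.dual) == {"B"}
        assert cat.dual["B"] == {"cold": "down", "desiccation": "up"}

    def test_worked_overlap_numbers(self):
        """22 cold-regulated and 22 desiccation-regulated sharing 11 leave
        exactly 11 cold-specific markers."""
        shared = {f"S{i}": "up" for i in range(11)}
        rc = self.records({**shared, **{f"C{i}": "up" for i in range(11)}}, "cold")
        rd = self.records({**shared, **{f"D{i}": "down" for i in range(11)}}, "desiccation")
        cat = build_catalog(rc, rd, set())
        assert len(cat.stressors["cold"].regulated) == 11
        assert len(cat.stressors["desiccation"].regulated) == 11
        assert len(cat.dual) == 11

    def test_specificity_partition(self):
        rc = self.records({"A": "up", "B": "down", "C": "up"}, "cold")
        rd = self.records({"B": "up", "D": "down", "E": "up"}, "desiccation")
        cat = build_catalog(rc, rd, set())
        cold = set(cat.stressors["cold"].regulated)
        des = set(cat.stressors["desiccation"].regulated)
        dual = set(cat.dual)
        assert cold | des | dual == {"A", "B", "C", "D", "E"}
        assert not (cold & des) and not (cold & dual) and not (des & dual)

    def test_empty_inputs_give_empty_catalog(self):
        empty = self.records({}, "cold")
        cat = build_catalog(empty, self.records({}, "desiccation"), set())
        assert not cat.stressors["cold"].regulated
        assert not cat.dual

    def test_constant_overlap_rejected(self):
        rc = self.records({"A": "up"}, "cold")
        rd = self.records({}, "desiccation")
        with pytest.raises(ValueError, match="overlap"):
            build_catalog(rc, rd, {"A"})


class TestSummaries:
    def test_counts_per_stressor(self):
        rows = [("a", "cold", 2, 0.01, 0.01, "up"), ("b", "cold", -2, 0.01, 0.01, "down"),
                ("c", "cold", 0, 0.9, 0.9, "not_regulated"), ("d", "desiccation", 3, 0.01, 0.01, "up")]
        rec = pd.DataFrame(rows, columns=["transcript_id", "stressor", "log2_fold_change",
                                          "p_value", "fdr", "class"]).set_index("transcript_id")
        table = summarize_regulation(rec)
        assert table.loc["cold", "up"] == 1 and table.loc["cold", "down"] == 1
        assert table.loc["desiccation", "up"] == 1 and table.loc["desiccation", "down"] == 0

    def test_no_regulated_transcripts_all_zero(self):
        rec = pd.DataFrame(
            [("a", "cold", 0.0, 0.9, 0.9, "not_regulated")],
            columns=["transcript_id", "stressor", "log2_fold_change", "p_value", "fdr", "class"],
        ).set_index("transcript_id")
        table = summarize_regulation(rec)
        assert table.loc["cold"].sum() == 0

    def test_single_stressor_only(self):
        rec = pd.DataFrame(
            [("a", "cold", 2.0, 0.01, 0.01, "up")],
            columns=["transcript_id", "stressor", "log2_fold_change", "p_value", "fdr", "class"],
        ).set_index("transcript_id")
        table = summarize_regulation(rec)
        assert "desiccation" not in table.index

    def test_end_to_end_counts_match_truth(self, low_noise_lab):
        _, lab, truth = low_noise_lab
        rec = classify_regulation(lab, "cold")
        table = summarize_regulation(rec)
        n_dual_up = sum(
            truth.direction(t, "cold") == "up" for t in truth.ids_with_label("dual")
        )
        assert table.loc["cold", "up"] == len(truth.ids_with_label("up_cold")) + n_dual_up


def test_precomputed_table_path(tmp_path):
    """A DE table from an external tool yields the same catalog logic."""
    path = tmp_path / "de.tsv"
    pd.DataFrame(
        {
            "transcript_id": ["A", "B"],
            "log2_fold_change": [2.5, 0.2],
            "p_value": [0.001, 0.5],
            "fdr": [0.01, 0.7],
        }
    ).to_csv(path, sep="\t", index=False)
    rec = read_regulation_table(path, "cold")
    assert rec.loc["A", "class"] == "up"
    assert rec.loc["B", "class"] == "not_regulated"
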