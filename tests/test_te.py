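"""Expression filter, log-CPM, contrast model and nested-F selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regulonmap.te import (TEModelFit, filter_expressed, fit_te_model,
                           log_transform, nested_f_selection, rna_only_model)


def _meta(n_reps=5):
    rows = []
    for assay in ("RPF", "RNA"):
        for strain in ("WT", "mutant"):
            for r in range(1, n_reps + 1):
                rows.append((f"{strain}_{assay}_r{r}", strain, assay, r))
    return pd.DataFrame(rows, columns=["library_id", "strain", "assay",
                                       "replicate"]).set_index("library_id")


def _counts_from_log2(log2_means: dict, meta: pd.DataFrame, genes) -> tuple:
    """Deterministic count matrices realizing exact per-cell log2 levels.

    A large constant ballast gene keeps library totals nearly equal so the
    CPM normalization does not absorb the planted shifts.
    """
    all_genes = list(genes) + ["_ballast"]
    rpf_cols, rna_cols = {}, {}
    for lib, row in meta.iterrows():
        target = rpf_cols if row["assay"] == "RPF" else rna_cols
        target[lib] = [
            int(round(2.0 ** log2_means.get((g, row["assay"], row["strain"]), 22.0)))
            for g in all_genes
        ]
    rpf = pd.DataFrame(rpf_cols, index=all_genes)
    rna = pd.DataFrame(rna_cols, index=all_genes)
    return rpf, rna


class TestFilterExpressed:
    def test_literal_rule_keeps_gene_low_in_one_assay(self):
        rpf = pd.DataFrame({"a": [20, 0], "b": [20, 0]}, index=["g1", "g2"])
        rna = pd.DataFrame({"c": [3, 0], "d": [3, 0]}, index=["g1", "g2"])
        kept = filter_expressed(rpf, rna, min_mean=15, mode="both")
        assert "g1" in kept and "g2" not in kept

    def test_either_rule_removes_it(self):
        rpf = pd.DataFrame({"a": [20]}, index=["g1"])
        rna = pd.DataFrame({"c": [3]}, index=["g1"])
        assert len(filter_expressed(rpf, rna, mode="either")) == 0

    def test_toy_set_matches_rule_oracle(self, rng):
        genes = [f"g{i}" for i in range(6)]
        rpf = pd.DataFrame(rng.integers(0, 40, (6, 4)), index=genes)
        rna = pd.DataFrame(rng.integers(0, 40, (6, 4)), index=genes)
        kept = set(filter_expressed(rpf, rna, min_mean=15))
        oracle = {g for g in genes
                  if not (rpf.loc[g].mean() < 15 and rna.loc[g].mean() < 15)}
        assert kept == oracle

    def test_disjoint_gene_sets_error(self):
        with pytest.raises(ValueError):
            filter_expressed(pd.DataFrame(index=["a"]), pd.DataFrame(index=["b"]))


class TestLogTransform:
    def test_zero_count_in_million_library(self):
        counts = pd.DataFrame({"lib": [0, 10**6 - 0]}, index=["g0", "g1"])
        val = log_transform(counts).loc["g0", "lib"]
        assert val == pytest.approx(np.log2(0.5 * 1e6 / (10**6 + 1)), abs=1e-9)

    def test_thousand_in_million(self):
        counts = pd.DataFrame({"lib": [1000, 10**6 - 1000]}, index=["g", "rest"])
        val = log_transform(counts).loc["g", "lib"]
        assert val == pytest.approx(np.log2(1000.5 / (1e6 + 1) * 1e6), abs=1e-9)

    def test_depth_doubling_cancels_up_to_pseudocount(self):
        counts = pd.DataFrame({"lib": [1000, 4000]}, index=["g", "rest"])
        doubled = counts * 2
        d = (log_transform(doubled) - log_transform(counts)).abs().max().max()
        assert d < 2e-3  # only the pseudocount term remains


class TestFitTEModel:
    def test_all_samples_equal_gives_zero_contrasts(self):
        meta = _meta()
        genes = ["g"]
        levels = {("g", a, s): 10.0 for a in ("RPF", "RNA") for s in ("WT", "mutant")}
        rpf, rna = _counts_from_log2(levels, meta, genes)
        fit = fit_te_model(rpf, rna, meta, moderation=False)
        row = fit.table.loc["g"]
        assert row["log2fc_rpf"] == pytest.approx(0.0, abs=1e-9)
        assert row["log2fc_rna"] == pytest.approx(0.0, abs=1e-9)
        assert row["F"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_rpf_shift_gives_te_shift(self):
        meta = _meta()
        levels = {("g", "RPF", "WT"): 10.0, ("g", "RPF", "mutant"): 11.0,
                  ("g", "RNA", "WT"): 10.0, ("g", "RNA", "mutant"): 10.0}
        rpf, rna = _counts_from_log2(levels, meta, ["g"])
        row = fit_te_model(rpf, rna, meta, moderation=False).table.loc["g"]
        assert row["log2fc_rpf"] == pytest.approx(1.0, abs=0.01)
        assert row["log2fc_rna"] == pytest.approx(0.0, abs=0.01)
        assert row["log2fc_te"] == pytest.approx(1.0, abs=0.01)

    def test_equal_shift_cancels_in_te(self):
        meta = _meta()
        levels = {("g", "RPF", "WT"): 10.0, ("g", "RPF", "mutant"): 11.0,
                  ("g", "RNA", "WT"): 10.0, ("g", "RNA", "mutant"): 11.0}
        rpf, rna = _counts_from_log2(levels, meta, ["g"])
        row = fit_te_model(rpf, rna, meta, moderation=False).table.loc["g"]
        assert row["log2fc_te"] == pytest.approx(0.0, abs=0.01)

    def test_te_linear_identity_machine_precision(self, rng):
        meta = _meta()
        genes = [f"g{i}" for i in range(100)]
        rpf = pd.DataFrame(rng.integers(10, 5000, (100, 10)), index=genes,
                           columns=meta.index[meta["assay"] == "RPF"])
        rna = pd.DataFrame(rng.integers(10, 5000, (100, 10)), index=genes,
                           columns=meta.index[meta["assay"] == "RNA"])
        table = fit_te_model(rpf, rna, meta).table
        np.testing.assert_allclose(
            table["log2fc_te"], table["log2fc_rpf"] - table["log2fc_rna"],
            atol=1e-12)

    def test_missing_design_cell_errors(self):
        meta = _meta().iloc[:12]  # drops mutant RNA replicates
        rpf = pd.DataFrame(1, index=["g"], columns=meta.index)
        with pytest.raises(ValueError, match="cell"):
            fit_te_model(rpf, rpf.copy(), meta)


def test_unmoderated_t_equals_classical_two_sample_t(rng):
    """The RNA-only model without moderation is the classical t on log-CPM."""
    rows = [(f"{s}_RNA_r{r}", s, "RNA", r)
            for s in ("WT", "mutant") for r in range(1, 5)]
    meta = pd.DataFrame(rows, columns=["library_id", "strain", "assay",
                                       "replicate"]).set_index("library_id")
    rna = pd.DataFrame(rng.integers(100, 5000, (30, 8)),
                       index=[f"g{i}" for i in range(30)], columns=meta.index)
    out = rna_only_model(rna, meta, min_mean=0, moderation=False)
    expr = np.log2((rna + 0.5) / (rna.sum(axis=0) + 1.0) * 1e6)
    wt = expr[[l for l in meta.index if l.startswith("WT")]]
    mut = expr[[l for l in meta.index if l.startswith("mutant")]]
    for g in rna.index[:10]:
        ref = stats.ttest_ind(mut.loc[g], wt.loc[g])
        assert out.loc[g, "t"] == pytest.approx(ref.statistic, rel=1e-9)
        assert out.loc[g, "p"] == pytest.approx(ref.pvalue, rel=1e-9)


class TestNestedF:
    def _fit_with_stats(self, tstats_by_gene, n_reps=5, s2=1.0):
        """Construct a TEModelFit carrying prescribed contrast t statistics."""
        sigma = np.array([[0.4, 0.0, 0.4], [0.0, 0.4, -0.4], [0.4, -0.4, 0.8]])
        rows = {}
        for g, ts in tstats_by_gene.items():
            est = [t * np.sqrt(sigma[i, i] * s2) for i, t in enumerate(ts)]
            sinv = np.linalg.inv(sigma[:2, :2])
            quad = np.array(est[:2]) @ sinv @ np.array(est[:2])
            F = quad / (2 * s2)
            rows[g] = {
                "log2fc_rpf": est[0], "log2fc_rna": est[1], "log2fc_te": est[2],
                "t_rpf": ts[0], "t_rna": ts[1], "t_te": ts[2],
                "F": F, "p_F": stats.f.sf(F, 2, 16), "s2": s2, "s2_post": s2,
            }
        table = pd.DataFrame(rows).T
        return TEModelFit(table=table, sigma=sigma, df_resid=16, d0=0,
                          df_total=16)

    def test_gene_failing_f_selects_nothing(self):
        fit = self._fit_with_stats({"null": (0.5, 0.2, 0.3)})
        out = nested_f_selection(fit)
        assert out.loc["null", "significant_contrasts"] == ""

    def test_descent_selects_strong_contrasts_only(self):
        fit = self._fit_with_stats({"g": (10.0, 0.1, 9.9),
                                    "null": (0.1, 0.2, 0.1)})
        out = nested_f_selection(fit, lfc=0.5)
        assert out.loc["g", "significant_contrasts"] == "RPF,TE"

    def test_lfc_gate_blocks_small_effects(self):
        # strong t but tiny fold change (small s2 makes t large)
        fit = self._fit_with_stats({"g": (12.0, 0.1, 11.9)}, s2=1e-4)
        out = nested_f_selection(fit, lfc=0.5)
        assert out.loc["g", "significant_contrasts"] == ""


class TestRnaOnly:
    def test_planted_fold_changes_recovered(self, rng):
        rows = [(f"{s}_RNA_r{r}", s, "RNA", r)
                for s in ("WT", "mutant") for r in range(1, 6)]
        meta = pd.DataFrame(rows, columns=["library_id", "strain", "assay",
                                           "replicate"]).set_index("library_id")
        n = 300
        mu = rng.uniform(100, 2000, n)
        genes = [f"g{i}" for i in range(n)]
        affected = set(genes[:30])
        cols = {}
        for lib, row in meta.iterrows():
            fc = np.where([g in affected for g in genes],
                          2.0 if row["strain"] == "mutant" else 1.0, 1.0)
            cols[lib] = rng.poisson(mu * fc)
        rna = pd.DataFrame(cols, index=genes)
        out = rna_only_model(rna, meta, min_mean=15)
        hits = set(out.index[out["significant"]])
        recall = len(hits & affected) / len(affected)
        assert recall >= 0.9
        assert (out.loc[sorted(hits & affected), "log2fc_rna"] > 0).all()
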