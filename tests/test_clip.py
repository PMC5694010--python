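"""Peak calling, per-peak counting, NB enrichment test, feature annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regulonmap.annotation import Gene, GenomeAnnotation
from regulonmap.clip import (annotate_peaks, call_candidate_peaks,
                             count_reads_per_peak, coverage_from_positions,
                             read_peaks_bed, write_peaks_bed)
from regulonmap.clip import test_peak_enrichment as nb_peak_test  # noqa: N813


def _clip_meta(n=4):
    rows = []
    for cond, assay, strain in (("tagged", "CLIP_tagged", "mutant"),
                                ("untagged", "CLIP_untagged", "WT")):
        for r in range(1, n + 1):
            rows.append((f"{cond}_r{r}", strain, assay, r))
    return pd.DataFrame(rows, columns=["library_id", "strain", "assay",
                                       "replicate"]).set_index("library_id")


class TestPeakCaller:
    def test_flat_zero_coverage_no_peaks(self):
        assert len(call_candidate_peaks({"chr": np.zeros(1000)})) == 0

    def test_single_block_called_exactly(self):
        cov = np.ones(1000)
        cov[300:500] = 50
        peaks = call_candidate_peaks({"chr": cov}, min_cov=10, min_len=20)
        assert len(peaks) == 1
        assert (peaks.iloc[0]["start"], peaks.iloc[0]["end"]) == (300, 500)

    def test_nearby_blocks_merged(self):
        cov = np.zeros(1000)
        cov[100:150] = 20
        cov[155:200] = 20  # gap of 5 < merge_gap 10
        peaks = call_candidate_peaks({"chr": cov}, min_cov=10, merge_gap=10)
        assert len(peaks) == 1
        assert (peaks.iloc[0]["start"], peaks.iloc[0]["end"]) == (100, 200)

    def test_short_runs_dropped(self):
        cov = np.zeros(1000)
        cov[100:110] = 99
        assert len(call_candidate_peaks({"chr": cov}, min_len=20,
                                        merge_gap=5)) == 0

    def test_scaling_above_threshold_and_idempotence(self):
        cov = np.zeros(500)
        cov[50:100] = 30
        cov[200:260] = 12
        p1 = call_candidate_peaks({"chr": cov}, min_cov=10)
        p2 = call_candidate_peaks({"chr": cov * 3}, min_cov=10)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(p1, call_candidate_peaks({"chr": cov},
                                                               min_cov=10))


class TestCounting:
    def test_no_reads_zero_matrix(self):
        peaks = pd.DataFrame([("chr", 10, 50)], columns=["contig", "start", "end"],
                             index=["p0"])
        rp = pd.DataFrame(columns=["library_id", "contig", "position"])
        counts = count_reads_per_peak(peaks, rp)
        assert counts.shape[1] == 0 or (counts.to_numpy() == 0).all()

    def test_inside_and_outside_reads(self, rng):
        peaks = pd.DataFrame([("chr", 100, 200)],
                             columns=["contig", "start", "end"], index=["p0"])
        inside = rng.integers(100, 200, 100)
        outside = rng.integers(300, 400, 5)
        rp = pd.DataFrame({
            "library_id": "lib1",
            "contig": "chr",
            "position": np.concatenate([inside, outside]),
        })
        counts = count_reads_per_peak(peaks, rp)
        assert counts.loc["p0", "lib1"] == 100

    def test_overlapping_user_peaks_warn_and_double_count(self):
        peaks = pd.DataFrame([("chr", 100, 200), ("chr", 150, 250)],
                             columns=["contig", "start", "end"],
                             index=["p0", "p1"])
        rp = pd.DataFrame({"library_id": ["l"], "contig": ["chr"],
                           "position": [175]})
        with pytest.warns(UserWarning, match="overlapping"):
            counts = count_reads_per_peak(peaks, rp)
        assert counts.loc["p0", "l"] == 1 and counts.loc["p1", "l"] == 1


class TestEnrichmentTest:
    def test_identical_conditions_not_significant(self):
        meta = _clip_meta()
        counts = pd.DataFrame(
            {lib: [100, 200, 50] for lib in meta.index},
            index=["p0", "p1", "p2"])
        out = nb_peak_test(counts, meta)
        assert np.allclose(out["log2fc"], 0.0, atol=1e-6)
        assert not out["significant"].any()

    def test_all_zero_peak_excluded(self):
        meta = _clip_meta()
        counts = pd.DataFrame({lib: [0, 100] for lib in meta.index},
                              index=["pz", "p1"])
        out = nb_peak_test(counts, meta)
        assert out.loc["pz", "reason"] == "all_zero"

    def test_poisson_limit_matches_exact_ratio_test(self):
        """At dispersion 0 the Wald p is within 2x of the exact binomial p."""
        meta = _clip_meta(2)
        bg = {f"bg{i}": [100] * 4 for i in range(5)}  # equal-size libraries
        counts = pd.DataFrame(
            {"tagged_r1": [30], "tagged_r2": [32],
             "untagged_r1": [18], "untagged_r2": [20]},
            index=["p0"])
        counts = pd.concat([counts,
                            pd.DataFrame(bg, index=counts.columns).T])
        out = nb_peak_test(counts, meta, dispersion=0.0)
        t_sum, u_sum = 30 + 32, 18 + 20
        exact = stats.binomtest(t_sum, t_sum + u_sum, 0.5).pvalue
        ratio = out.loc["p0", "p"] / exact
        assert 0.5 < ratio < 2.0

    def test_planted_enrichment_detected(self, rng):
        meta = _clip_meta(5)
        n_bg = 30
        mu_bg = rng.uniform(50, 200, n_bg)
        rows = {}
        for lib, row in meta.iterrows():
            lam = np.concatenate([[800 if row["assay"] == "CLIP_tagged" else 100],
                                  mu_bg])
            rows[lib] = rng.poisson(lam)
        counts = pd.DataFrame(rows, index=["planted"] + [f"bg{i}" for i in
                                                         range(n_bg)])
        out = nb_peak_test(counts, meta)
        assert out.loc["planted", "significant"]
        assert out.loc["planted", "log2fc"] == pytest.approx(3.0, abs=0.5)


class TestAnnotatePeaks:
    def test_peak_in_first60_of_plus_cds(self, toy_annotation):
        peaks = pd.DataFrame([("chr", 130, 170)],
                             columns=["contig", "start", "end"], index=["p"])
        out = annotate_peaks(peaks, toy_annotation)
        assert "CDS_first60" in out.loc["p", "labels"]
        assert "CDS_deep" not in out.loc["p", "labels"]

    def test_minus_strand_first60_is_high_end(self, toy_annotation):
        # geneC: CDS (1000, 1300) on '-': first 60 nt are (1240, 1300)
        peaks = pd.DataFrame([("chr", 1250, 1290)],
                             columns=["contig", "start", "end"], index=["p"])
        labels = annotate_peaks(peaks, toy_annotation).loc["p", "labels"]
        assert "CDS_first60" in labels and "CDS_last60_near_stop" not in labels

    def test_whole_gene_peak_multi_label(self, toy_annotation):
        peaks = pd.DataFrame([("chr", 100, 450)],
                             columns=["contig", "start", "end"], index=["p"])
        labels = set(annotate_peaks(peaks, toy_annotation).loc["p", "labels"]
                     .split(","))
        assert {"UTR5", "CDS_first60", "CDS_last60_near_stop", "UTR3",
                "TSS"} <= labels

    def test_intergenic_is_exclusive(self, toy_annotation):
        peaks = pd.DataFrame([("chr", 1850, 1950)],
                             columns=["contig", "start", "end"], index=["p"])
        labels = annotate_peaks(peaks, toy_annotation).loc["p", "labels"]
        assert labels == "intergenic"

    def test_downstream_operon_flag(self, toy_annotation):
        # near geneA stop and into geneB (same operon)
        peaks = pd.DataFrame([("chr", 400, 520)],
                             columns=["contig", "start", "end"], index=["p"])
        out = annotate_peaks(peaks, toy_annotation)
        assert out.loc["p", "downstream_gene_in_operon"]

    def test_random_peaks_match_interval_oracle(self, rng):
        genes = {}
        cursor = 200
        for i in range(30):
            u5, cds_len, u3 = 20, 300, 30
            gid = f"g{i}"
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                genes[gid] = Gene(gid, "chr", "+", (cursor + u5, cursor + u5 + cds_len),
                                  (cursor, cursor + u5),
                                  (cursor + u5 + cds_len, cursor + u5 + cds_len + u3))
            else:
                genes[gid] = Gene(gid, "chr", "-", (cursor + u3, cursor + u3 + cds_len),
                                  (cursor + u3 + cds_len, cursor + u3 + cds_len + u5),
                                  (cursor, cursor + u3))
            cursor += u5 + cds_len + u3 + int(rng.integers(50, 150))
        ann = GenomeAnnotation(contigs={"chr": cursor + 500}, genes=genes)
        ann.validate()
        starts = rng.integers(0, cursor, 300)
        peaks = pd.DataFrame({"contig": "chr", "start": starts,
                              "end": starts + rng.integers(20, 120, 300)})
        peaks.index = [f"p{i}" for i in range(300)]
        out = annotate_peaks(peaks, ann)

        def oracle_labels(s, e):
            nts = set(range(s, e))
            labels = set()
            for g in genes.values():
                if nts & set(range(*g.utr5)):
                    labels.add("UTR5")
                if nts & set(range(*g.utr3)):
                    labels.add("UTR3")
                cds_nts = list(range(*g.cds))
                if g.strand == "-":
                    cds_nts = cds_nts[::-1]  # codon order
                first = set(cds_nts[:60])
                last = set(cds_nts[-60:])
                deep = set(cds_nts[60:-60])
                if nts & first:
                    labels.add("CDS_first60")
                if nts & last:
                    labels.add("CDS_last60_near_stop")
                if nts & deep:
                    labels.add("CDS_deep")
            return labels or {"intergenic"}

        for pid, pk in peaks.iterrows():
            expected = oracle_labels(int(pk["start"]), int(pk["end"]))
            assert set(out.loc[pid, "labels"].split(",")) == expected, pid


def test_bed_round_trip(tmp_path):
    peaks = pd.DataFrame([("chr", 100, 200), ("chr", 500, 640)],
                         columns=["contig", "start", "end"],
                         index=["pk0", "pk1"])
    peaks["strand"] = "."
    write_peaks_bed(peaks, tmp_path / "p.bed")
    back = read_peaks_bed(str(tmp_path / "p.bed"))
    assert list(back.index) == ["pk0", "pk1"]
    assert list(back["start"]) == [100, 500]
    assert list(back["end"]) == [200, 640]
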