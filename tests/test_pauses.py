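"""Occupancy profiles, pause calling, replicate consensus and co-localization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regulonmap.pauses import (PauseSite, build_profiles, compare_pause_strength,
                               consensus_pauses, detect_pauses,
                               pause_peak_enrichment)


class TestBuildProfiles:
    def test_point_mass_and_conservation(self, toy_annotation):
        rp = pd.DataFrame({"library_id": ["lib1"] * 10, "gene_id": ["geneA"] * 10,
                           "offset": [99] * 10})
        profiles, dropped = build_profiles(rp, toy_annotation)
        prof = profiles[("geneA", "lib1")]
        assert prof[99] == 10 and prof.sum() == 10 and dropped == 0

    def test_out_of_cds_reads_dropped_and_counted(self, toy_annotation):
        rp = pd.DataFrame({"library_id": ["l"] * 3, "gene_id": ["geneA"] * 3,
                           "offset": [0, 299, 300]})  # CDS length 300
        profiles, dropped = build_profiles(rp, toy_annotation)
        assert dropped == 1
        assert profiles[("geneA", "l")].sum() == 2

    def test_unknown_gene_errors(self, toy_annotation):
        rp = pd.DataFrame({"library_id": ["l"], "gene_id": ["ghost"], "offset": [5]})
        with pytest.raises(KeyError, match="ghost"):
            build_profiles(rp, toy_annotation)


class TestDetectPauses:
    def test_uniform_profile_has_no_pauses(self):
        assert detect_pauses(np.full(300, 5.0)) == []

    def test_worked_single_spike_profile(self):
        """Trimmed length 240, one position at 50, remainder 2 -> one pause."""
        profile = np.full(300, 2.0)
        profile[150] = 50.0
        sites = detect_pauses(profile, gene_id="g", trim=30, fold=10)
        assert len(sites) == 1
        assert sites[0].position == 150
        assert sites[0].fold == pytest.approx(50.0 / ((239 * 2 + 50) / 240))

    def test_matches_bruteforce_oracle_on_random_profiles(self, rng):
        for _ in range(200):
            length = int(rng.integers(61, 400))
            profile = rng.poisson(3.0, length).astype(float)
            profile[rng.integers(0, length, 3)] += rng.integers(0, 200)
            got = {s.position for s in detect_pauses(profile, trim=30, fold=10)}
            trimmed = profile[30:length - 30]
            mean = trimmed.mean()
            oracle = {30 + i for i, v in enumerate(trimmed)
                      if mean > 0 and v > 10 * mean}
            assert got == oracle

    def test_raising_fold_threshold_never_adds_pauses(self, rng):
        profile = rng.poisson(2.0, 300).astype(float)
        profile[100] = 80
        prev = None
        for fold in (5, 10, 20, 40):
            now = {s.position for s in detect_pauses(profile, fold=fold)}
            if prev is not None:
                assert now <= prev
            prev = now

    def test_short_cds_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_pauses(np.ones(60), trim=30)


class TestConsensus:
    def _sets(self):
        a = PauseSite("g1", 100, 20.0)
        b = PauseSite("g1", 200, 15.0)
        c = PauseSite("g2", 50, 30.0)
        return [
            [a, b, c],
            [a, b],
            [a, b, c],
            [a, c],
            [a],
        ]

    def test_full_support_retained(self):
        out = consensus_pauses(self._sets(), min_reps=4)
        by_key = {(p.gene_id, p.position): p for p in out}
        assert by_key[("g1", 100)].support == 5

    def test_three_of_five_dropped_at_default(self):
        out = consensus_pauses(self._sets(), min_reps=4)
        keys = {(p.gene_id, p.position) for p in out}
        assert ("g1", 200) not in keys  # support 3
        assert ("g2", 50) not in keys   # support 3

    def test_matches_intersection_count_oracle(self):
        sets = self._sets()
        for min_reps in (1, 2, 3, 4, 5):
            out = {(p.gene_id, p.position)
                   for p in consensus_pauses(sets, min_reps=min_reps)}
            counts: dict = {}
            for s in sets:
                for p in s:
                    counts[(p.gene_id, p.position)] = counts.get(
                        (p.gene_id, p.position), 0) + 1
            oracle = {k for k, v in counts.items() if v >= min_reps}
            assert out == oracle

    def test_min_reps_one_is_union_and_n_is_intersection(self):
        sets = self._sets()
        union = {(p.gene_id, p.position) for s in sets for p in s}
        inter = set.intersection(*[{(p.gene_id, p.position) for p in s}
                                   for s in sets])
        got1 = {(p.gene_id, p.position) for p in consensus_pauses(sets, min_reps=1)}
        got5 = {(p.gene_id, p.position) for p in consensus_pauses(sets, min_reps=5)}
        assert got1 == union and got5 == inter

    def test_min_reps_above_n_errors(self):
        with pytest.raises(ValueError, match="min_reps"):
            consensus_pauses(self._sets(), min_reps=6)


class TestPausePeakEnrichment:
    def test_chi2_on_fixed_table_matches_hand_computation(self):
        table = np.array([[30, 970], [50, 3950]])
        chi2, p, _, exp = stats.chi2_contingency(table, correction=False)
        # closed-form Pearson statistic computed independently
        n = table.sum()
        hand = 0.0
        for i in range(2):
            for j in range(2):
                e = table[i].sum() * table[:, j].sum() / n
                hand += (table[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(hand, abs=1e-9)
        assert hand == pytest.approx(15.5614837, abs=1e-6)

    def test_proportional_table_gives_zero_chi2(self):
        table = np.array([[10, 990], [40, 3960]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_planted_colocalization_detected(self, sim_annotation, rng):
        ann, _ = sim_annotation
        genes = [g for g in ann.genes.values() if g.cds_length > 200]
        peaks = pd.DataFrame(
            [(g.contig, g.cds[0] + 60, g.cds[0] + 120) for g in genes[:10]],
            columns=["contig", "start", "end"])
        pauses = []
        for g in genes:
            lo, hi = 30, g.cds_length - 30
            for _ in range(6):
                pos = int(rng.integers(lo, hi))
                pauses.append(PauseSite(g.gene_id, pos, 15.0))
        # plant extra pauses inside the peak windows of the first genes
        for g in genes[:10]:
            for _ in range(6):
                off = int(rng.integers(60, 120)) if g.strand == "+" else int(
                    rng.integers(g.cds_length - 120, g.cds_length - 60))
                pauses.append(PauseSite(g.gene_id, off, 15.0))
        res = pause_peak_enrichment(pauses, peaks, ann,
                                    genes=[g.gene_id for g in genes])
        assert res["fold"] > 1.5
        assert res["p"] < 0.05

    def test_no_peak_overlap_is_error(self, toy_annotation):
        peaks = pd.DataFrame([("chr", 1900, 1950)],
                             columns=["contig", "start", "end"])
        with pytest.raises(ValueError, match="inside"):
            pause_peak_enrichment([PauseSite("geneA", 100, 12.0)], peaks,
                                  toy_annotation, genes=["geneA"], flank=0)


class TestPauseStrength:
    def test_identical_sets_give_zero_t(self):
        pauses = [PauseSite("g", 100, 15.0), PauseSite("g", 200, 18.0),
                  PauseSite("g", 250, 21.0)]
        res = compare_pause_strength(pauses, list(pauses))
        assert res["t"] == pytest.approx(0.0, abs=1e-12)

    def test_shifted_folds_detected(self, rng):
        wt = [PauseSite("g", i, f) for i, f in
              enumerate(rng.normal(15, 2, 60).clip(10.5))]
        mut = [PauseSite("g", i, f) for i, f in
               enumerate(rng.normal(22.5, 3, 60).clip(10.5))]
        res = compare_pause_strength(wt, mut)
        assert res["p"] < 0.05 and res["t"] > 0

    def test_too_few_pauses_skips(self):
        res = compare_pause_strength([PauseSite("g", 1, 12.0)], [])
        assert "skipped" in res
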