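"""Simulation-based validation experiments for every pipeline stage.

Each function generates a synthetic dataset with known ground truth,
runs the corresponding analysis exactly as the pipeline would, and
returns summary recovery/calibration metrics.  They are used by the
test suite and by scripts/acceptance.py, so the numbers reported there
are always recomputed from scratch.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .clip import (annotate_peaks, call_candidate_peaks, count_reads_per_peak,
                   test_peak_enrichment, coverage_from_positions)
from .decay import run_decay_analysis
from .integrate import assign_peaks_to_genes, classify_regulation
from .pauses import (PauseSite, _in_intervals, _merged_peak_intervals,
                     build_profiles, consensus_pauses, detect_pauses,
                     pause_peak_enrichment)
from .simulate import (generate_annotation, make_truth,
                       simulate_clip_experiment, simulate_decay_experiment,
                       simulate_ribo_experiment)
from .te import (filter_expressed, fit_te_model, nested_f_selection,
                 rna_only_model)

__all__ = [
    "decay_halflife_recovery",
    "stability_experiment",
    "te_null_calibration",
    "te_effect_recovery",
    "pause_recovery",
    "pause_colocalization",
    "clip_experiment",
    "end_to_end_agreement",
]


def _decay_truth(rng, n_genes, hl_range=(1.0, 20.0)):
    genes = [f"g{i}" for i in range(n_genes)]
    hl = pd.Series(np.exp(rng.uniform(*np.log(hl_range), n_genes)), index=genes)
    n0 = pd.Series(np.exp(rng.uniform(np.log(100), np.log(2000), n_genes)),
                   index=genes)
    spikes = pd.Series(np.exp(rng.uniform(np.log(50), np.log(5000), 25)),
                       index=[f"spike{i}" for i in range(25)])
    return hl, n0, spikes


def decay_halflife_recovery(seed: int, noise: float = 0.0, depth: int = 1_000_000,
                            n_genes: int = 1000, n_replicates: int = 2) -> dict:
    """Median absolute relative error of fitted vs true half-lives."""
    rng = np.random.default_rng(seed)
    hl, n0, spikes = _decay_truth(rng, n_genes)
    counts, meta = simulate_decay_experiment(
        hl, n0, spikes, n_replicates=n_replicates, depth=depth, noise=noise,
        rng=rng)
    fits, _ = run_decay_analysis(counts, meta, list(spikes.index))
    kept = fits[fits["passed"] & np.isfinite(fits["half_life"])]
    est = kept.groupby("gene_id")["half_life"].mean()
    err = np.abs(est / hl.loc[est.index] - 1.0)
    return {"median_rel_err": float(err.median()), "n": int(len(est))}


def stability_experiment(seed: int, planted_frac: float = 0.0,
                         fold: float = 2.0, n_genes: int = 1000,
                         depth: int = 300_000, n_replicates: int = 3) -> dict:
    """Differential-stability null calibration / planted-change recovery."""
    rng = np.random.default_rng(seed)
    hl_wt, n0, spikes = _decay_truth(rng, n_genes, hl_range=(1.5, 15.0))
    hl_mut = hl_wt.copy()
    planted: set = set()
    if planted_frac > 0:
        idx = rng.choice(n_genes, int(round(planted_frac * n_genes)),
                         replace=False)
        direction = rng.choice([1.0 / fold, fold], size=idx.size)
        hl_mut.iloc[idx] = hl_wt.iloc[idx] * direction
        planted = set(hl_wt.index[idx])
    frames, metas = [], []
    for strain, hl in (("WT", hl_wt), ("mutant", hl_mut)):
        c, m = simulate_decay_experiment(hl, n0, spikes,
                                         n_replicates=n_replicates,
                                         depth=depth, strain=strain, rng=rng)
        frames.append(c)
        metas.append(m)
    _, diff = run_decay_analysis(pd.concat(frames, axis=1), pd.concat(metas),
                                 list(spikes.index))
    sig = set(diff.index[diff["significant"]])
    out = {
        "n_tested": int(len(diff)),
        "frac_q05": float((diff["q"] < 0.05).mean()),
    }
    if planted:
        out["recall"] = len(sig & planted) / len(planted)
        out["empirical_fdr"] = len(sig - planted) / max(len(sig), 1)
    return out


def _ribo_meta_free_annotation():
    # a minimal annotation; gene-level TE experiments ignore positions
    ann, _ = generate_annotation(0, n_genes=1, contig_length=10_000)
    return ann


def _planted_effects(rng, n_genes, n_affected, effect_size=1.0):
    genes = [f"g{i}" for i in range(n_genes)]
    eff = pd.DataFrame(0.0, index=genes,
                       columns=["log2fc_rpf", "log2fc_rna", "log2fc_te"])
    aff = rng.choice(n_genes, n_affected, replace=False)
    third = n_affected // 3
    eff.iloc[aff[:third], 0] = effect_size * rng.choice([-1, 1], third)
    eff.iloc[aff[third:2 * third], 1] = effect_size * rng.choice([-1, 1], third)
    both = aff[2 * third:]
    eff.iloc[both, 0] = effect_size * rng.choice([-1, 1], len(both))
    eff.iloc[both, 1] = eff.iloc[both, 0]
    eff["log2fc_te"] = eff["log2fc_rpf"] - eff["log2fc_rna"]
    return eff, [genes[i] for i in aff]


def te_null_calibration(seed: int, n_genes: int = 1000,
                        n_replicates: int = 5, dispersion: float = 0.05) -> dict:
    """Fraction of null genes with raw joint-F p < 0.05 (nominal 0.05)."""
    rng = np.random.default_rng(seed)
    ann = _ribo_meta_free_annotation()
    eff, _ = _planted_effects(rng, n_genes, 0)
    base = pd.Series(np.exp(rng.uniform(np.log(50), np.log(2000), n_genes)),
                     index=eff.index)
    rpf, rna, meta, _ = simulate_ribo_experiment(
        eff, base, ann, n_replicates=n_replicates, dispersion=dispersion,
        profile_genes=[], rng=rng)
    fit = fit_te_model(rpf, rna, meta)
    return {"frac_p05": float((fit.table["p_F"] < 0.05).mean()),
            "n": int(n_genes)}


def te_effect_recovery(seed: int, n_genes: int = 1000, n_affected: int = 100,
                       n_replicates: int = 5, dispersion: float = 0.05) -> dict:
    """Recovery of planted 1-log2 contrasts: accuracy and q<0.05 FDR."""
    rng = np.random.default_rng(seed)
    ann = _ribo_meta_free_annotation()
    eff, affected = _planted_effects(rng, n_genes, n_affected)
    base = pd.Series(np.exp(rng.uniform(np.log(50), np.log(2000), n_genes)),
                     index=eff.index)
    rpf, rna, meta, _ = simulate_ribo_experiment(
        eff, base, ann, n_replicates=n_replicates, dispersion=dispersion,
        profile_genes=[], rng=rng)
    fit = fit_te_model(rpf, rna, meta)
    table = nested_f_selection(fit)
    errs = []
    for g in affected:
        for c in ("rpf", "rna", "te"):
            if eff.loc[g, f"log2fc_{c}"] != 0:
                errs.append(abs(table.loc[g, f"log2fc_{c}"]
                                - eff.loc[g, f"log2fc_{c}"]))
    errs = np.array(errs)
    sig = set(table.index[table["significant_contrasts"] != ""])
    affected_set = set(affected)
    return {
        "frac_within_02": float((errs <= 0.2).mean()),
        "median_abs_err": float(np.median(errs)),
        "empirical_fdr": len(sig - affected_set) / max(len(sig), 1),
        "recall": len(sig & affected_set) / len(affected_set),
        "n_affected_contrasts": int(len(errs)),
    }


def pause_recovery(seed: int, n_genes: int = 50, pause_fold: float = 25.0,
                   base_mean: float = 2000.0, n_replicates: int = 5,
                   min_reps: int = 4) -> dict:
    """Recall of planted pause sites after the replicate-consensus rule."""
    rng = np.random.default_rng(seed)
    ann, _ = generate_annotation(seed, n_genes=n_genes, contig_length=250_000)
    genes = list(ann.genes)
    rows = []
    for g in genes:
        length = ann.genes[g].cds_length
        if length > 100:
            rows.append((g, int(rng.integers(30, length - 30)), pause_fold))
    pauses = pd.DataFrame(rows, columns=["gene_id", "position", "fold"])
    eff = pd.DataFrame(0.0, index=genes,
                       columns=["log2fc_rpf", "log2fc_rna", "log2fc_te"])
    _, _, meta, pos = simulate_ribo_experiment(
        eff, pd.Series(base_mean, index=genes), ann, pauses=pauses,
        n_replicates=n_replicates, dispersion=0.05, rng=rng)
    profiles, _ = build_profiles(pos, ann)
    per_rep = []
    for lib in [l for l in meta.index if l.startswith("WT_RPF")]:
        sites = []
        for (g, l), prof in profiles.items():
            if l == lib and len(prof) >= 61:
                sites.extend(detect_pauses(prof, gene_id=g))
        per_rep.append(sites)
    consensus = consensus_pauses(per_rep, min_reps=min_reps)
    got = {(p.gene_id, p.position) for p in consensus}
    truth = {(r.gene_id, int(r.position)) for r in pauses.itertuples()}
    return {"recall": len(got & truth) / len(truth),
            "n_planted": len(truth), "n_extra": len(got - truth)}


def pause_colocalization(seed: int, n_pauses: int = 500, n_peaks: int = 50,
                         density: float = 2.0, n_null_repeats: int = 0) -> dict:
    """Planted 2x pause density near peaks: fold estimate and chi-square p.

    With ``n_null_repeats`` > 0 also reports the type-I error rate of the
    test under uniform pause placement.
    """
    rng = np.random.default_rng(seed)
    ann, _ = generate_annotation(seed, n_genes=100, contig_length=400_000)
    genes = [g for g in ann.genes.values() if g.cds_length > 160]
    gids = [g.gene_id for g in genes]
    chosen = rng.choice(len(genes), n_peaks, replace=False)
    peaks = pd.DataFrame(
        [(genes[i].contig, genes[i].cds[0] + 80, genes[i].cds[0] + 140)
         for i in chosen],
        columns=["contig", "start", "end"])
    merged = _merged_peak_intervals(peaks, 30)
    candidates, inside = [], []
    for g in genes:
        ivs = merged.get(g.contig, np.empty((0, 2), dtype=int))
        for off in range(30, g.cds_length - 30):
            candidates.append((g.gene_id, off))
            inside.append(_in_intervals(g.cds_offset_to_genomic(off), ivs))
    inside = np.array(inside)

    def draw(rel_density):
        w = np.where(inside, rel_density, 1.0)
        idx = rng.choice(len(candidates), n_pauses, replace=False, p=w / w.sum())
        return [PauseSite(candidates[i][0], candidates[i][1], 15.0) for i in idx]

    res = pause_peak_enrichment(draw(density), peaks, ann, genes=gids)
    out = {"fold": res["fold"], "p": res["p"]}
    if n_null_repeats:
        hits = 0
        for _ in range(n_null_repeats):
            r = pause_peak_enrichment(draw(1.0), peaks, ann, genes=gids)
            hits += r["p"] < 0.05
        out["null_type1"] = hits / n_null_repeats
    return out


def clip_experiment(seed: int, planted: bool = True, n_genes: int = 150,
                    enrichment: float = 8.0, depth: int = 110_000,
                    null_depth: int = 400_000) -> dict:
    """Planted-peak detection (or null false-discovery control) for CLIP.

    Planted mode: low background coverage so candidate peaks are the
    enriched windows; reports the detection rate of planted peaks and
    their log2 enrichment estimates.  Null mode: no peaks, higher depth
    so whole transcripts become candidates; reports the q < 0.05
    fraction.
    """
    rng = np.random.default_rng(seed)
    ann, _ = generate_annotation(seed, n_genes=n_genes, contig_length=400_000)
    truth = make_truth(ann, seed=seed, frac_peak_genes=0.12,
                       peak_enrichment=enrichment)
    peaks = truth.peaks if planted else truth.peaks.iloc[:0]
    pos, meta = simulate_clip_experiment(
        ann, peaks, n_replicates=5,
        depth=depth if planted else null_depth, rng=rng)
    tagged = meta.index[meta["assay"] == "CLIP_tagged"]
    cov = coverage_from_positions(pos, ann.contigs, libraries=tagged)
    cands = call_candidate_peaks(cov)
    counts = count_reads_per_peak(cands, pos)
    totals = pos.groupby("library_id")["count"].sum()
    res = test_peak_enrichment(counts, meta, library_totals=totals)
    if not planted:
        return {"n_candidates": int(len(cands)),
                "frac_q05": float((res["q"] < 0.05).mean())}
    detected, fcs = 0, []
    for _, pk in peaks.iterrows():
        hit = cands[(cands["start"] < pk["end"]) & (cands["end"] > pk["start"])]
        sig = [pid for pid in hit.index if res.loc[pid, "significant"]]
        detected += bool(sig)
        fcs.extend(res.loc[sig, "log2fc"])
    fcs = np.array(fcs)
    return {
        "n_planted": int(len(peaks)),
        "detection_rate": detected / len(peaks),
        "median_log2fc": float(np.median(fcs)) if fcs.size else np.nan,
        "frac_log2fc_within_05_of_3": float((np.abs(fcs - 3.0) <= 0.5).mean())
        if fcs.size else np.nan,
    }


def end_to_end_agreement(seed: int, n_genes: int = 60) -> dict:
    """Noiseless simulate -> all stages -> integrate; truth agreement.

    Counts are set to their exact expectations (no sampling), so every
    layer should recover exactly the planted effects and the
    direct/indirect/binding_only/none classification should match the
    simulation truth for every gene.
    """
    rng = np.random.default_rng(seed)
    ann, _ = generate_annotation(seed, n_genes=n_genes, contig_length=250_000)
    truth = make_truth(ann, seed=seed)

    frames, metas = [], []
    for strain in ("WT", "mutant"):
        c, m = simulate_decay_experiment(
            truth.half_life[strain], truth.base_mean * 10,
            truth.spike_abundance, n_replicates=3, depth=500_000,
            strain=strain, noiseless=True, rng=rng)
        frames.append(c)
        metas.append(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance replicate guard
        _, stab = run_decay_analysis(pd.concat(frames, axis=1),
                                     pd.concat(metas),
                                     list(truth.spike_abundance.index))

    rpf, rna, rmeta, _ = simulate_ribo_experiment(
        truth.effects, truth.base_mean, ann, pauses=truth.pauses,
        n_replicates=5, noiseless=True, profile_genes=[], rng=rng)
    keep = filter_expressed(rpf, rna)
    te_tab = nested_f_selection(fit_te_model(rpf.loc[keep], rna.loc[keep], rmeta))
    rna_tab = rna_only_model(rna, rmeta)

    cpos, cmeta = simulate_clip_experiment(ann, truth.peaks, n_replicates=5,
                                           depth=400_000, noiseless=True, rng=rng)
    tagged = cmeta.index[cmeta["assay"] == "CLIP_tagged"]
    cov = coverage_from_positions(cpos, ann.contigs, libraries=tagged)
    cands = call_candidate_peaks(cov)
    counts = count_reads_per_peak(cands, cpos)
    totals = cpos.groupby("library_id")["count"].sum()
    res = test_peak_enrichment(counts, cmeta, library_totals=totals)
    sig = cands.join(res)
    sig = sig[sig["significant"].fillna(False)]
    gene_peaks = {g: v for g, v in
                  assign_peaks_to_genes(annotate_peaks(sig, ann), ann).items()
                  if g in ann.genes}
    calls = classify_regulation(te_tab, rna_tab, stab, gene_peaks)

    peak_genes = set(truth.peaks["gene_id"])
    agree = 0
    for g in ann.genes:
        any_eff = bool((truth.effects.loc[g].abs() > 0).any()) or abs(
            np.log2(truth.half_life.loc[g, "mutant"]
                    / truth.half_life.loc[g, "WT"])) > 0.5
        has_peak = g in peak_genes
        expected = ("direct" if has_peak and any_eff else
                    "indirect" if any_eff else
                    "binding_only" if has_peak else "none")
        got = calls.loc[g, "classification"] if g in calls.index else "none"
        agree += got == expected
    return {"agreement": agree / len(ann.genes), "n_genes": int(len(ann.genes))}
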