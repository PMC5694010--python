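"""Spike-in normalized RNA decay analysis.

After transcription arrest (rifampicin), each transcript decays roughly
exponentially, so its log abundance falls linearly with time and the
half-life is t1/2 = -ln2 / slope.  Sequencing only measures fractions of
a library, so raw counts are first put back on an absolute scale using
exogenous spike-in RNAs whose true abundance is constant across the time
course: for each timepoint library T_n versus its time-zero library T_0,

    k_i = (ERCC_n,i / ERCC_0,i) / (Total_n / Total_0)

per spike i, and the library normalization factor k is the geometric
mean of k_i over the most abundant spikes (default 25).  Dividing raw
counts by k cancels the shrinking total-mRNA denominator.

Note the printed k is invariant to uniform library-depth scaling, so an
optional pre-step rescales libraries to equal totals before normalizing
(default on); this makes half-life recovery well-posed when depths vary.

Differential stability between strains is a per-gene two-sample t test on
replicate half-lives with Benjamini-Hochberg control and a fold-change
gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DecayFit",
    "spike_normalization_factor",
    "normalize_counts",
    "fit_decay",
    "filter_fits",
    "differential_stability",
    "run_decay_analysis",
]

_TINY_P = np.finfo(float).tiny


@dataclass
class DecayFit:
    gene_id: str
    strain: str
    replicate: int
    slope: float          # per minute, natural-log scale
    intercept: float
    r2: float
    t0_count: float       # raw reads at time zero
    half_life: float      # minutes; +inf when slope >= 0
    n_points: int
    failed: bool = False
    reason: str = ""


def spike_normalization_factor(
    spikes_n: pd.Series,
    spikes_0: pd.Series,
    total_n: float,
    total_0: float,
    top_k: int = 25,
    min_usable: int = 10,
) -> float:
    """Geometric-mean spike normalization factor k for one library pair.

    Spikes are ranked by abundance in the time-zero library; the `top_k`
    most abundant with nonzero counts in both libraries contribute
    k_i = (ERCC_n,i/ERCC_0,i)/(Total_n/Total_0).  Spikes with zero T_n
    counts are dropped with a warning; fewer than `min_usable` remaining
    is an error.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    common = spikes_0.index.intersection(spikes_n.index)
    ranked = spikes_0.loc[common]
    ranked = ranked[ranked > 0].sort_values(ascending=False)
    if len(ranked) < top_k:
        raise ValueError(
            f"only {len(ranked)} spikes with nonzero T_0 counts; need {top_k}"
        )
    chosen = ranked.index[:top_k]
    num = spikes_n.loc[chosen].to_numpy(float)
    den = spikes_0.loc[chosen].to_numpy(float)
    keep = num > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} spike(s) with zero T_n counts",
            stacklevel=2,
        )
    num, den = num[keep], den[keep]
    if len(num) < min_usable:
        raise ValueError(
            f"only {len(num)} usable spikes after zero-drop (minimum {min_usable})"
        )
    k_i = (num / den) / (total_n / total_0)
    return float(np.exp(np.mean(np.log(k_i))))


def normalize_counts(raw: pd.Series | np.ndarray, k: float):
    """Divide raw counts by the normalization factor k (> 0 required)."""
    if k <= 0:
        raise ValueError("normalization factor k must be positive")
    return raw / k


def fit_decay(
    y: np.ndarray,
    timepoints: np.ndarray,
    gene_id: str = "",
    strain: str = "",
    replicate: int = 0,
    t0_count: float = np.nan,
    pseudocount: float = 0.0,
) -> DecayFit:
    """Semi-log OLS of one normalized decay series.

    ln(y + pseudocount) is regressed on time; points with y <= 0 after the
    pseudocount are dropped.  Fewer than 3 usable points marks the fit
    failed (reason code) instead of raising.  half_life = -ln2/slope for
    negative slopes, +inf otherwise.
    """
    y = np.asarray(y, dtype=float) + pseudocount
    t = np.asarray(timepoints, dtype=float)
    mask = y > 0
    n = int(mask.sum())
    if np.isnan(t0_count):
        t0_count = float(y[np.argmin(t)]) - pseudocount
    if n < 3:
        return DecayFit(gene_id, strain, replicate, np.nan, np.nan, np.nan,
                        t0_count, np.nan, n, failed=True, reason="too_few_points")
    res = stats.linregress(t[mask], np.log(y[mask]))
    slope = float(res.slope)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    half_life = -np.log(2.0) / slope if slope < 0 else float("inf")
    return DecayFit(gene_id, strain, replicate, slope, float(res.intercept),
                    r2, t0_count, half_life, n)


def fits_to_frame(fits: list[DecayFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])


def filter_fits(
    fits: pd.DataFrame,
    min_t0: float = 50,
    min_r2: float = 0.7,
    mode: str = "or",
) -> pd.DataFrame:
    """Apply the starting-count and regression-quality filters.

    A fit is retained iff t0_count >= min_t0 AND r2 >= min_r2 (boundaries
    inclusive).  ``mode="or"`` excludes on either failure (default);
    ``mode="and"`` excludes only when both fail, the literal reading of
    the published rule.  Excluded fits keep reason codes.
    """
    out = fits.copy()
    low_t0 = out["t0_count"] < min_t0
    low_r2 = (out["r2"] < min_r2) | out["r2"].isna()
    failed = out["failed"].astype(bool)
    if mode == "or":
        excluded = low_t0 | low_r2
    elif mode == "and":
        excluded = low_t0 & low_r2
    else:
        raise ValueError("mode must be 'or' or 'and'")
    excluded = excluded | failed
    reasons = []
    for lt, lr, fl, old in zip(low_t0, low_r2, failed, out["reason"]):
        codes = [old] if old else []
        if lt:
            codes.append("low_t0")
        if lr and not fl:
            codes.append("low_r2")
        reasons.append(",".join(codes))
    out["reason"] = reasons
    out["passed"] = ~excluded
    return out


def _ttest(a: np.ndarray, b: np.ndarray, kind: str) -> tuple[float, float]:
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means; p set to tiny", stacklevel=2)
        return np.inf if np.mean(a) > np.mean(b) else -np.inf, _TINY_P
    res = stats.ttest_ind(a, b, equal_var=(kind == "student"))
    return float(res.statistic), float(res.pvalue)


def differential_stability(
    halflives_wt: pd.DataFrame,
    halflives_mut: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 0.5,
    ttest: str = "student",
) -> pd.DataFrame:
    """Per-gene two-sample t test on replicate half-lives, BH-corrected.

    Inputs are genes x replicates tables of finite half-lives (one per
    strain); genes need >= 2 finite replicates in both strains.  A gene is
    significant when q < `fdr` and |log2(mutant/WT mean half-life)| >
    `lfc`.
    """
    genes = halflives_wt.index.intersection(halflives_mut.index)
    rows = []
    for g in genes:
        a = halflives_mut.loc[g].to_numpy(float)
        b = halflives_wt.loc[g].to_numpy(float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = _ttest(a, b, ttest)
        rows.append((g, float(np.mean(b)), float(np.mean(a)),
                     float(np.log2(np.mean(a) / np.mean(b))), t, p))
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "half_life_WT", "half_life_mutant",
                 "log2_ratio", "t", "p"],
    ).set_index("gene_id")
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    out["significant"] = (out["q"] < fdr) & (out["log2_ratio"].abs() > lfc)
    return out


def run_decay_analysis(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    spike_ids,
    timepoints=None,
    top_k: int = 25,
    min_usable: int = 10,
    min_t0: float = 50,
    min_r2: float = 0.7,
    filter_mode: str = "or",
    pseudocount: float = 0.0,
    equal_depth: bool = True,
    fdr: float = 0.05,
    lfc: float = 0.5,
    ttest: str = "student",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full decay pipeline: normalize, fit, filter, test between strains.

    Expects DECAY libraries covering one or more (strain, replicate) time
    courses each containing a t=0 library.  Returns (per-replicate fits,
    differential-stability table).
    """
    spike_ids = [s for s in spike_ids if s in counts.index]
    gene_ids = [g for g in counts.index if g not in set(spike_ids)]
    decay_meta = meta[meta["assay"] == "DECAY"]
    work = counts[decay_meta.index].astype(float)
    if equal_depth:
        totals = work.sum(axis=0)
        work = work * (totals.mean() / totals)

    fits: list[DecayFit] = []
    for (strain, rep), group in decay_meta.groupby(["strain", "replicate"]):
        group = group.sort_values("timepoint")
        tps = group["timepoint"].to_numpy(float)
        if timepoints is not None:
            keep = np.isin(tps, np.asarray(timepoints, float))
            group, tps = group[keep], tps[keep]
        if 0.0 not in tps:
            raise ValueError(f"time course ({strain}, rep {rep}) lacks a t=0 library")
        lib0 = group.index[np.argmin(tps)]
        norm = pd.DataFrame(index=work.index)
        for lib, t in zip(group.index, tps):
            k = spike_normalization_factor(
                work.loc[spike_ids, lib], work.loc[spike_ids, lib0],
                work[lib].sum(), work[lib0].sum(),
                top_k=top_k, min_usable=min_usable,
            )
            norm[lib] = normalize_counts(work[lib], k)
        raw_t0 = counts.loc[gene_ids, lib0].to_numpy(float)
        for gi, g in enumerate(gene_ids):
            fits.append(
                fit_decay(
                    norm.loc[g, group.index].to_numpy(), tps,
                    gene_id=g, strain=strain, replicate=int(rep),
                    t0_count=raw_t0[gi], pseudocount=pseudocount,
                )
            )
    fit_frame = filter_fits(fits_to_frame(fits), min_t0=min_t0, min_r2=min_r2,
                            mode=filter_mode)
    kept = fit_frame[fit_frame["passed"] & np.isfinite(fit_frame["half_life"])]
    tables = {
        strain: kept[kept["strain"] == strain]
        .pivot(index="gene_id", columns="replicate", values="half_life")
        .dropna()
        for strain in ("WT", "mutant")
    }
    common = tables["WT"].index.intersection(tables["mutant"].index)
    diff = differential_stability(
        tables["WT"].loc[common], tables["mutant"].loc[common],
        fdr=fdr, lfc=lfc, ttest=ttest,
    )
    return fit_frame, diff
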