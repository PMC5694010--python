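"""Ribosome pause-site detection and peak co-localization statistics.

A pause is a CDS position whose ribosome footprint occupancy exceeds a
fold threshold (default 10x) over the mean occupancy of the trimmed CDS;
the first and last 30 nt are trimmed so initiating/terminating ribosomes
are not counted as pauses.  Pauses are called per replicate and only
those shared by a minimum number of replicates (default 4) are kept.
Co-localization of pauses with binding peaks (extended by a 30-nt flank)
is tested with a two-sided Pearson chi-square on the 2x2 table of
pause/non-pause nucleotides inside/outside peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation

__all__ = [
    "PauseSite",
    "build_profiles",
    "detect_pauses",
    "consensus_pauses",
    "pause_peak_enrichment",
    "compare_pause_strength",
]


@dataclass(frozen=True)
class PauseSite:
    gene_id: str
    position: int      # nt from CDS start, 0-based, within the trimmed region
    fold: float        # occupancy over the trimmed-CDS mean
    support: int = 1


def build_profiles(
    read_positions: pd.DataFrame,
    annotation: GenomeAnnotation,
) -> tuple[dict[tuple[str, str], np.ndarray], int]:
    """Per-(gene, library) occupancy vectors from a read-position table.

    `read_positions` has columns (library_id, gene_id, offset[, count]);
    offsets are nt from the start codon.  Reads with offsets outside the
    CDS are dropped and counted; an unknown gene is an error.  Total
    profile mass equals the number of assigned reads.
    """
    profiles: dict[tuple[str, str], np.ndarray] = {}
    dropped = 0
    has_count = "count" in read_positions.columns
    for row in read_positions.itertuples(index=False):
        gene = annotation.genes.get(row.gene_id)
        if gene is None:
            raise KeyError(f"gene {row.gene_id} absent from annotation")
        length = gene.cds_length
        offset = int(row.offset)
        weight = int(row.count) if has_count else 1
        if not 0 <= offset < length:
            dropped += weight
            continue
        key = (row.gene_id, row.library_id)
        if key not in profiles:
            profiles[key] = np.zeros(length, dtype=np.int64)
        profiles[key][offset] += weight
    return profiles, dropped


def detect_pauses(
    profile: np.ndarray,
    gene_id: str = "",
    trim: int = 30,
    fold: float = 10.0,
) -> list[PauseSite]:
    """Positions with occupancy > `fold` x the trimmed-CDS mean.

    The mean is taken over all trimmed positions including zeros; a
    zero-mean (empty) profile yields no pauses.  A CDS shorter than
    2*trim + 1 cannot be scanned and raises ValueError (callers skip such
    genes with a reason code).
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) < 2 * trim + 1:
        raise ValueError(f"CDS shorter than {2 * trim + 1} nt cannot be scanned")
    trimmed = profile[trim:len(profile) - trim]
    mean = trimmed.mean()
    if mean == 0:
        return []
    hits = np.nonzero(trimmed > fold * mean)[0]
    return [
        PauseSite(gene_id, int(trim + i), float(trimmed[i] / mean)) for i in hits
    ]


def consensus_pauses(
    per_replicate: dict | list,
    min_reps: int = 4,
    tolerance: int = 0,
) -> list[PauseSite]:
    """Pauses shared by at least `min_reps` replicates of one strain.

    Sharing means identical (gene, position) by default; with
    ``tolerance=w`` positions within w nt (greedy chaining per gene) are
    treated as the same site.  The reported fold is the mean over
    supporting replicates; the reported position the supporting median.
    """
    if isinstance(per_replicate, dict):
        replicate_sets = list(per_replicate.values())
    else:
        replicate_sets = list(per_replicate)
    if min_reps > len(replicate_sets):
        raise ValueError(
            f"min_reps={min_reps} exceeds {len(replicate_sets)} replicates"
        )
    records: list[tuple[str, int, float, int]] = []
    for rep_idx, sites in enumerate(replicate_sets):
        for s in sites:
            records.append((s.gene_id, s.position, s.fold, rep_idx))
    out: list[PauseSite] = []
    frame = pd.DataFrame(records, columns=["gene_id", "position", "fold", "rep"])
    for gid, grp in frame.groupby("gene_id", sort=True):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        breaks = np.nonzero(np.diff(positions) > tolerance)[0] + 1
        for cluster in np.split(np.arange(len(grp)), breaks):
            sub = grp.iloc[cluster]
            support = sub["rep"].nunique()
            if support >= min_reps:
                out.append(
                    PauseSite(
                        gid,
                        int(np.median(sub["position"])),
                        float(sub["fold"].mean()),
                        int(support),
                    )
                )
    return out


def _merged_peak_intervals(peaks: pd.DataFrame, flank: int) -> dict[str, np.ndarray]:
    """Flank-extended, merged peak intervals per contig, as (n, 2) arrays."""
    merged: dict[str, np.ndarray] = {}
    for contig, grp in peaks.groupby("contig"):
        ivs = np.sort(
            np.column_stack(
                [grp["start"].to_numpy() - flank, grp["end"].to_numpy() + flank]
            ),
            axis=0,
        )
        keep: list[list[int]] = []
        for s, e in ivs:
            if keep and s <= keep[-1][1]:
                keep[-1][1] = max(keep[-1][1], e)
            else:
                keep.append([int(s), int(e)])
        merged[contig] = np.array(keep, dtype=int)
    return merged


def _in_intervals(pos: int, ivs: np.ndarray) -> bool:
    if ivs.size == 0:
        return False
    i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
    return i >= 0 and pos < ivs[i, 1]


def pause_peak_enrichment(
    pauses: list[PauseSite] | pd.DataFrame,
    peaks: pd.DataFrame,
    annotation: GenomeAnnotation,
    genes: list[str] | None = None,
    flank: int = 30,
    trim: int = 30,
    correction: bool = False,
) -> dict:
    """Chi-square test of pause density inside vs outside extended peaks.

    The universe is every trimmed-CDS nucleotide of the analyzed genes
    (in genome coordinates); peaks are extended by `flank` nt on both
    sides and merged.  Returns the 2x2 table, the per-nucleotide fold
    enrichment, chi2 and p (Pearson, no continuity correction by
    default).
    """
    if isinstance(pauses, pd.DataFrame):
        pauses = [
            PauseSite(r.gene_id, int(r.position), float(r.fold),
                      int(getattr(r, "support", 1)))
            for r in pauses.itertuples(index=False)
        ]
    if genes is None:
        genes = sorted({p.gene_id for p in pauses})
    merged = _merged_peak_intervals(peaks, flank)

    nt_inside = nt_outside = 0
    for gid in genes:
        g = annotation.genes[gid]
        if g.cds_length < 2 * trim + 1:
            continue
        lo, hi = g.cds[0] + trim, g.cds[1] - trim  # strand-symmetric trim
        ivs = merged.get(g.contig, np.empty((0, 2), dtype=int))
        inside = 0
        for s, e in ivs:
            inside += max(0, min(hi, e) - max(lo, s))
        nt_inside += inside
        nt_outside += (hi - lo) - inside
    if nt_inside == 0:
        raise ValueError("no trimmed-CDS nucleotides fall inside extended peaks")

    p_inside = p_outside = 0
    for p in pauses:
        g = annotation.genes[p.gene_id]
        pos = g.cds_offset_to_genomic(p.position)
        ivs = merged.get(g.contig, np.empty((0, 2), dtype=int))
        if _in_intervals(pos, ivs):
            p_inside += 1
        else:
            p_outside += 1

    table = np.array(
        [[p_inside, nt_inside - p_inside], [p_outside, nt_outside - p_outside]]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, pval = 0.0, 1.0
    else:
        chi2, pval, _, _ = stats.chi2_contingency(table, correction=correction)
    rate_in = p_inside / nt_inside
    rate_out = p_outside / nt_outside if nt_outside else np.nan
    return {
        "table": table,
        "fold": rate_in / rate_out if rate_out else float("inf"),
        "chi2": float(chi2),
        "p": float(pval),
        "nt_inside": nt_inside,
        "nt_outside": nt_outside,
    }


def compare_pause_strength(
    pauses_wt: list[PauseSite],
    pauses_mut: list[PauseSite],
    annotation: GenomeAnnotation | None = None,
    peaks: pd.DataFrame | None = None,
    scope: str = "all",
    flank: int = 30,
    trim: int = 30,
    genes: list[str] | None = None,
) -> dict:
    """Two-sided t test on pause fold occupancies between strains.

    With ``scope="near_peaks"`` only pauses whose genomic position lies
    within a peak +/- `flank` nt are compared (requires annotation and
    peaks).  Also reports pause frequency per kb of trimmed CDS when the
    analyzed gene set is given.
    """
    if scope not in ("all", "near_peaks"):
        raise ValueError("scope must be 'all' or 'near_peaks'")
    wt, mut = list(pauses_wt), list(pauses_mut)
    if scope == "near_peaks":
        if annotation is None or peaks is None:
            raise ValueError("near_peaks scope needs annotation and peaks")
        merged = _merged_peak_intervals(peaks, flank)

        def near(p: PauseSite) -> bool:
            g = annotation.genes[p.gene_id]
            ivs = merged.get(g.contig, np.empty((0, 2), dtype=int))
            return _in_intervals(g.cds_offset_to_genomic(p.position), ivs)

        wt = [p for p in wt if near(p)]
        mut = [p for p in mut if near(p)]

    result: dict = {"n_WT": len(wt), "n_mutant": len(mut), "scope": scope}
    if len(wt) < 2 or len(mut) < 2:
        result.update(t=np.nan, p=np.nan, skipped="fewer than 2 pauses in a group")
        return result
    folds_wt = np.array([p.fold for p in wt])
    folds_mut = np.array([p.fold for p in mut])
    res = stats.ttest_ind(folds_mut, folds_wt)
    result.update(
        t=float(res.statistic), p=float(res.pvalue),
        mean_fold_WT=float(folds_wt.mean()), mean_fold_mutant=float(folds_mut.mean()),
    )
    if annotation is not None and genes is not None:
        kb = sum(
            max(annotation.genes[g].cds_length - 2 * trim, 0) for g in genes
        ) / 1000.0
        if kb > 0:
            result["pauses_per_kb_WT"] = len(wt) / kb
            result["pauses_per_kb_mutant"] = len(mut) / kb
    return result
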