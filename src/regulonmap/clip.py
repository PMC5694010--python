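"""CLIP peak calling, enrichment testing and feature annotation.

Candidate peaks are maximal runs of merged tagged-library coverage above
a threshold (runs closer than a gap are merged, short runs dropped).
Per-peak counts from tagged and untagged libraries are then compared
with a negative-binomial Wald test: library-size factors by
median-of-ratios, per-peak dispersions by method of moments shrunk
toward a mean-dispersion trend, and Benjamini-Hochberg control across
peaks; a peak is significantly bound when q < 0.05 with positive
enrichment.  Annotation places each peak against 5'UTR / CDS / 3'UTR /
ncRNA / TSS / terminator features, with the first and last 60 nt of each
CDS distinguished because binding there acts on initiation or on
downstream operon genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation

__all__ = [
    "coverage_from_positions",
    "call_candidate_peaks",
    "count_reads_per_peak",
    "test_peak_enrichment",
    "annotate_peaks",
    "read_peaks_bed",
    "write_peaks_bed",
    "PEAK_LABELS",
]

PEAK_LABELS = (
    "CDS_first60", "CDS_deep", "CDS_last60_near_stop",
    "UTR5", "UTR3", "ncRNA", "TSS", "terminator", "intergenic",
)


def coverage_from_positions(
    read_positions: pd.DataFrame,
    contig_lengths: dict[str, int],
    libraries=None,
    dedup: bool = False,
) -> dict[str, np.ndarray]:
    """Summed per-nucleotide coverage over the selected libraries.

    ``dedup=True`` collapses duplicate reads at one position within one
    library to a single read before summing.
    """
    cov = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
    rp = read_positions
    if libraries is not None:
        rp = rp[rp["library_id"].isin(set(libraries))]
    weights = rp["count"].to_numpy() if "count" in rp.columns else np.ones(len(rp), int)
    if dedup:
        weights = np.minimum(weights, 1)
    for contig, idx in rp.groupby("contig").groups.items():
        pos = rp.loc[idx, "position"].to_numpy(int)
        np.add.at(cov[contig], pos, weights[rp.index.get_indexer(idx)])
    return cov


def call_candidate_peaks(
    coverage: dict[str, np.ndarray],
    min_cov: int = 10,
    min_len: int = 20,
    merge_gap: int = 10,
) -> pd.DataFrame:
    """Threshold/merge peak caller on merged coverage.

    Maximal runs with coverage >= `min_cov` are found per contig; runs
    separated by fewer than `merge_gap` nucleotides are merged; merged
    runs shorter than `min_len` are dropped.  Deterministic, and
    invariant to coverage rescaling that preserves threshold crossings.
    """
    rows = []
    for contig in sorted(coverage):
        above = np.asarray(coverage[contig]) >= min_cov
        if not above.any():
            continue
        padded = np.concatenate([[0], above.astype(np.int8), [0]])
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        merged: list[list[int]] = []
        for s, e in zip(run_starts, run_ends):
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s >= min_len:
                rows.append((contig, s, e))
    out = pd.DataFrame(rows, columns=["contig", "start", "end"])
    out.index = [f"peak{i:04d}" for i in range(len(out))]
    return out


def count_reads_per_peak(
    peaks: pd.DataFrame,
    read_positions: pd.DataFrame,
    dedup: bool = False,
) -> pd.DataFrame:
    """Integer peaks x libraries counts of reads falling inside each peak.

    A read is assigned to every peak containing its position; caller
    output is disjoint, but overlapping user-supplied peaks trigger a
    warning and ambiguous reads count in all of them.
    """
    libs = sorted(read_positions["library_id"].unique())
    counts = pd.DataFrame(0, index=peaks.index, columns=libs, dtype=np.int64)
    for contig, pk in peaks.groupby("contig", sort=False):
        pk = pk.iloc[np.argsort(pk["start"].to_numpy())]
        starts, ends = pk["start"].to_numpy(), pk["end"].to_numpy()
        overlapping = bool((starts[1:] < ends[:-1]).any())
        if overlapping:
            warnings.warn("overlapping peaks: ambiguous reads counted in all",
                          stacklevel=2)
        rp = read_positions[read_positions["contig"] == contig]
        pos = rp["position"].to_numpy(int)
        w = rp["count"].to_numpy(int) if "count" in rp.columns else np.ones(len(rp), int)
        if dedup:
            w = np.minimum(w, 1)
        lib_codes = pd.Categorical(rp["library_id"], categories=libs).codes
        if not overlapping:
            # disjoint sorted peaks: one searchsorted lookup per read
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
            mat = np.zeros((len(pk), len(libs)), dtype=np.int64)
            np.add.at(mat, (idx[inside], lib_codes[inside]), w[inside])
            counts.loc[pk.index, :] += mat
        else:
            for j, (pid, s, e) in enumerate(zip(pk.index, starts, ends)):
                inside = (pos >= s) & (pos < e)
                row = np.zeros(len(libs), dtype=np.int64)
                np.add.at(row, lib_codes[inside], w[inside])
                counts.loc[pid] += row
    return counts


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (total-count fallback)."""
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 1:
        logref = np.log(counts[positive]).mean(axis=1)
        sf = np.exp(np.median(np.log(counts[positive]) - logref[:, None], axis=0))
    else:
        totals = counts.sum(axis=0).astype(float)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def _moment_dispersions(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-peak method-of-moments NB dispersion pooled within groups."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += var - mu
        den += mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(phi, 0.0, None)


def test_peak_enrichment(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    fdr: float = 0.05,
    dispersion: float | None = None,
    library_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Tagged-vs-untagged NB Wald test per peak.

    `meta` assigns each library to CLIP_tagged or CLIP_untagged (>= 2
    replicates each).  Per-peak dispersions are method-of-moments
    estimates shrunk halfway toward a fitted a0 + a1/mu trend; passing
    `dispersion` overrides estimation (0 gives the exact Poisson limit).
    Size factors are median-of-ratios over the peak counts by default;
    when the candidate set is dominated by genuinely bound regions that
    estimator absorbs the enrichment, so `library_totals` (all mapped
    reads per library) can be supplied instead.  Significant peaks have
    q < `fdr` AND log2FC > 0.
    """
    tagged = [l for l in counts.columns if meta.loc[l, "assay"] == "CLIP_tagged"]
    untag = [l for l in counts.columns if meta.loc[l, "assay"] == "CLIP_untagged"]
    if len(tagged) < 2 or len(untag) < 2:
        raise ValueError("need >= 2 replicates per condition")
    order = untag + tagged
    y = counts[order].to_numpy(float)
    keep = y.sum(axis=1) > 0
    if library_totals is not None:
        t = library_totals.loc[order].to_numpy(float)
        sf = t / np.exp(np.mean(np.log(t)))
    else:
        sf = _size_factors(y[keep] if keep.any() else y)
    norm = y / sf

    n_un = len(untag)
    groups = [np.arange(n_un), np.arange(n_un, len(order))]
    if dispersion is None:
        phi_mom = _moment_dispersions(norm, groups)
        mu = norm.mean(axis=1)
        # trend phi(mu) = a0 + a1/mu fitted by least squares on raw estimates
        ok = keep & (mu > 0)
        if ok.sum() >= 3:
            X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
            coef, *_ = np.linalg.lstsq(X, phi_mom[ok], rcond=None)
            trend = np.clip(coef[0] + coef[1] / np.maximum(mu, 1e-8), 0.0, None)
        else:
            trend = np.full(len(mu), phi_mom[ok].mean() if ok.any() else 0.0)
        phi = 0.5 * phi_mom + 0.5 * trend
    else:
        phi = np.full(y.shape[0], float(dispersion))

    design = np.column_stack(
        [np.ones(len(order)), np.r_[np.zeros(n_un), np.ones(len(tagged))]]
    )
    offset = np.log(sf)
    rows = []
    for i, pid in enumerate(counts.index):
        if not keep[i]:
            rows.append((pid, np.nan, np.nan, np.nan, "all_zero"))
            continue
        fam = (
            sm.families.Poisson()
            if phi[i] < 1e-8
            else sm.families.NegativeBinomial(alpha=float(phi[i]))
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y[i], design, family=fam, offset=offset).fit()
            b, se = res.params[1], res.bse[1]
            z = b / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((pid, b / np.log(2.0), float(z), float(p), ""))
        except Exception as exc:  # non-convergence on degenerate counts
            rows.append((pid, np.nan, np.nan, np.nan, f"fit_failed:{exc}"))
    out = pd.DataFrame(
        rows, columns=["peak_id", "log2fc", "wald_z", "p", "reason"]
    ).set_index("peak_id")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["significant"] = (out["q"] < fdr) & (out["log2fc"] > 0)
    return out


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def annotate_peaks(
    peaks: pd.DataFrame,
    annotation: GenomeAnnotation,
    window_cds: int = 60,
    tss_window: int = 0,
) -> pd.DataFrame:
    """Attach every applicable feature label to each peak.

    CDS windows are measured from the start/stop codon in the gene's
    orientation; a peak overlapping nothing is `intergenic`.  The
    downstream-operon flag marks near-stop peaks that also overlap the
    next gene of the same operon.  Returns the peaks with `labels`
    (comma-joined), `genes` (overlapped transcripts) and
    `downstream_gene_in_operon` columns.
    """
    label_col, gene_col, flag_col = [], [], []
    for _, pk in peaks.iterrows():
        contig, s, e = pk["contig"], int(pk["start"]), int(pk["end"])
        if contig not in annotation.contigs:
            raise ValueError(f"peak contig {contig} not in annotation")
        labels: set[str] = set()
        genes_hit: list[str] = []
        near_stop_genes: list[str] = []
        for g in annotation.genes.values():
            if g.contig != contig:
                continue
            if _overlap(s, e, *g.transcript) > 0:
                genes_hit.append(g.gene_id)
            if g.utr5 is not None and _overlap(s, e, *g.utr5) > 0:
                labels.add("UTR5")
            if g.utr3 is not None and _overlap(s, e, *g.utr3) > 0:
                labels.add("UTR3")
            c0, c1 = g.cds
            if _overlap(s, e, c0, c1) == 0:
                continue
            w = min(window_cds, c1 - c0)
            if g.strand == "+":
                first = (c0, c0 + w)
                last = (c1 - w, c1)
            else:
                first = (c1 - w, c1)
                last = (c0, c0 + w)
            if _overlap(s, e, *first) > 0:
                labels.add("CDS_first60")
            if _overlap(s, e, *last) > 0:
                labels.add("CDS_last60_near_stop")
                near_stop_genes.append(g.gene_id)
            deep_lo, deep_hi = c0 + w, c1 - w
            if deep_hi > deep_lo and _overlap(s, e, deep_lo, deep_hi) > 0:
                labels.add("CDS_deep")
        for nc in annotation.ncrnas.values():
            if nc.contig == contig and _overlap(s, e, *nc.interval) > 0:
                labels.add("ncRNA")
                genes_hit.append(nc.ncrna_id)
        for tc, pos in annotation.tss:
            if tc == contig and s - tss_window <= pos < e + tss_window:
                labels.add("TSS")
        for tc, t0, t1 in annotation.terminators:
            if tc == contig and _overlap(s, e, t0, t1) > 0:
                labels.add("terminator")
        flag = False
        for gid in near_stop_genes:
            nxt = annotation.next_in_operon(gid)
            if nxt is not None and _overlap(s, e, *annotation.genes[nxt].transcript) > 0:
                flag = True
        if not labels:
            labels.add("intergenic")
        label_col.append(",".join(sorted(labels)))
        gene_col.append(",".join(genes_hit))
        flag_col.append(flag)
    out = peaks.copy()
    out["labels"] = label_col
    out["genes"] = gene_col
    out["downstream_gene_in_operon"] = flag_col
    return out


def read_peaks_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 fields")
            name = fields[3] if len(fields) > 3 else f"peak{lineno:04d}"
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((fields[0], int(fields[1]), int(fields[2]), name, strand))
    out = pd.DataFrame(rows, columns=["contig", "start", "end", "name", "strand"])
    return out.set_index("name")


def write_peaks_bed(peaks: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for pid, pk in peaks.iterrows():
            strand = pk.get("strand", ".")
            fh.write(
                f"{pk['contig']}\t{int(pk['start'])}\t{int(pk['end'])}\t{pid}\t0\t{strand}\n"
            )
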