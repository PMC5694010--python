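"""Gene-wise linear modeling of translation, RNA abundance and TE.

Paired ribosome-profiling (RPF) and RNA-seq counts from two strains are
log-CPM transformed and fit gene-by-gene with a cell-means model over the
2 assays x 2 strains design.  Three contrasts are tested:

    translation:  RPF_mutant - RPF_WT
    abundance:    RNA_mutant - RNA_WT
    TE:           (RPF_mutant - RPF_WT) - (RNA_mutant - RNA_WT)

The TE contrast is the interaction: the part of a translation change not
explained by the RNA change; the three contrasts span a rank-2 space, so
the joint F uses 2 numerator degrees of freedom.  Residual variances are
optionally moderated by empirical-Bayes shrinkage toward a pooled prior
(posterior s2 = (d0*s0^2 + d*s2)/(d0 + d), with d0 and s0^2 estimated by
method of moments on the gene-wise variances), giving moderated t
statistics with d0 + d degrees of freedom.  Gene-level significance uses
the joint F with Benjamini-Hochberg correction; within significant genes
a nested-F descent picks the contrasts that drive the signal, gated by a
fold-change threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_expressed",
    "log_transform",
    "moderate_variances",
    "fit_te_model",
    "nested_f_selection",
    "rna_only_model",
    "TEModelFit",
]

CONTRASTS = ("RPF", "RNA", "TE")
# cell order: (RPF, WT), (RPF, mutant), (RNA, WT), (RNA, mutant)
_CELLS = (("RPF", "WT"), ("RPF", "mutant"), ("RNA", "WT"), ("RNA", "mutant"))
_C = np.array(
    [
        [-1.0, 1.0, 0.0, 0.0],   # RPF contrast
        [0.0, 0.0, -1.0, 1.0],   # RNA contrast
        [-1.0, 1.0, 1.0, -1.0],  # TE = RPF - RNA
    ]
)


def filter_expressed(
    rpf: pd.DataFrame,
    rna: pd.DataFrame,
    min_mean: float = 15,
    mode: str = "both",
) -> pd.Index:
    """Genes passing the mean-expression filter.

    ``mode="both"`` (literal rule): a gene is removed only when its mean
    count per sample is below `min_mean` in BOTH the RPF and RNA matrices.
    ``mode="either"``: removed when below in either.
    """
    common = rpf.index.intersection(rna.index)
    if len(common) == 0:
        raise ValueError("no shared gene ids between RPF and RNA matrices")
    low_rpf = rpf.loc[common].mean(axis=1) < min_mean
    low_rna = rna.loc[common].mean(axis=1) < min_mean
    if mode == "both":
        removed = low_rpf & low_rna
    elif mode == "either":
        removed = low_rpf | low_rna
    else:
        raise ValueError("mode must be 'both' or 'either'")
    return common[~removed]


def log_transform(counts: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """log2 counts per million with a 0.5 pseudocount.

    value = log2((count + 0.5) / (library_total + 1) * 1e6); the +1 on the
    total keeps the transformed values bounded for empty libraries.
    """
    totals = counts.sum(axis=0).astype(float)
    return np.log2((counts + 0.5) / (totals + 1.0) * 1e6)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene-wise residual variances.

    Under the hierarchical model s2_g ~ s0^2 * F(df, d0), the prior
    degrees of freedom d0 and prior variance s0^2 are solved from the
    first two moments of the observed s2.  Returns (posterior s2, d0,
    s0^2); an underdispersed ensemble gives d0 = inf (complete shrinkage
    to the mean variance).
    """
    s2 = np.asarray(s2, dtype=float)
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    if m <= 0:
        return s2, 0.0, 0.0
    r = v / m**2
    if r * df <= 2.0:
        d0, s02 = np.inf, m
        post = np.full_like(s2, m)
    else:
        d0 = (2.0 * df - 4.0 + 4.0 * r * df) / (r * df - 2.0)
        s02 = m * (d0 - 2.0) / d0 if d0 > 2 else m
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


@dataclass
class TEModelFit:
    """Per-gene contrast estimates plus the shared design geometry."""

    table: pd.DataFrame
    sigma: np.ndarray      # 3x3 unit-variance covariance of the contrasts
    df_resid: float
    d0: float
    df_total: float


def _cell_columns(meta: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    cells: dict[tuple[str, str], list[str]] = {c: [] for c in _CELLS}
    for lib, row in meta.iterrows():
        key = (row["assay"], row["strain"])
        if key in cells:
            cells[key].append(lib)
    return cells


def fit_te_model(
    rpf: pd.DataFrame,
    rna: pd.DataFrame,
    meta: pd.DataFrame,
    moderation: bool = True,
) -> TEModelFit:
    """Fit the cell-means model and the three contrasts for every gene.

    Expects RPF and RNA count matrices over the same genes and a metadata
    table assigning each library to a (assay, strain) cell with >= 2
    replicates.  Counts are log-CPM transformed internally.
    """
    genes = rpf.index.intersection(rna.index)
    expr = pd.concat([log_transform(rpf.loc[genes]), log_transform(rna.loc[genes])], axis=1)
    cells = _cell_columns(meta)
    for key, libs in cells.items():
        if len(libs) < 2:
            raise ValueError(f"design cell {key} has {len(libs)} replicates; need >= 2")
    n_per_cell = np.array([len(cells[c]) for c in _CELLS], dtype=float)
    n_total = int(n_per_cell.sum())
    df_resid = float(n_total - 4)
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    means = np.column_stack(
        [expr[cells[c]].mean(axis=1).to_numpy() for c in _CELLS]
    )  # genes x 4
    rss = np.zeros(len(genes))
    for j, c in enumerate(_CELLS):
        block = expr[cells[c]].to_numpy()
        rss += ((block - means[:, [j]]) ** 2).sum(axis=1)
    s2 = rss / df_resid

    if moderation:
        s2_post, d0, _s02 = moderate_variances(s2, df_resid)
    else:
        s2_post, d0 = s2, 0.0
    s2_post = np.maximum(s2_post, 1e-300)  # degenerate noiseless input
    df_total = df_resid + (d0 if np.isfinite(d0) else np.inf)

    sigma = _C @ np.diag(1.0 / n_per_cell) @ _C.T
    est = means @ _C.T  # genes x 3 contrast estimates

    table = pd.DataFrame(index=genes)
    tdist = stats.norm if np.isinf(df_total) else stats.t(df_total)
    for i, name in enumerate(CONTRASTS):
        se = np.sqrt(sigma[i, i] * s2_post)
        t = est[:, i] / se
        table[f"log2fc_{name.lower()}"] = est[:, i]
        table[f"t_{name.lower()}"] = t
        table[f"p_{name.lower()}"] = 2.0 * tdist.sf(np.abs(t))

    # joint F over the rank-2 space spanned by the RPF and RNA contrasts
    sigma2 = sigma[:2, :2]
    sinv = np.linalg.inv(sigma2)
    quad = np.einsum("gi,ij,gj->g", est[:, :2], sinv, est[:, :2])
    rank = 2
    F = quad / (rank * s2_post)
    table["F"] = F
    fden = df_total if np.isfinite(df_total) else 1e9
    table["p_F"] = stats.f.sf(F, rank, fden)
    table["s2"] = s2
    table["s2_post"] = s2_post
    return TEModelFit(table=table, sigma=sigma, df_resid=df_resid, d0=d0,
                      df_total=df_total)


def _subset_f(est: np.ndarray, idx: list[int], sigma: np.ndarray, s2: float
              ) -> tuple[float, int]:
    sub = sigma[np.ix_(idx, idx)]
    rank = int(np.linalg.matrix_rank(sub))
    c = est[idx]
    quad = float(c @ np.linalg.pinv(sub) @ c)
    return quad / (rank * s2), rank


def nested_f_selection(
    fit: TEModelFit,
    fdr: float = 0.05,
    lfc: float = 0.5,
) -> pd.DataFrame:
    """Gene-level BH on the joint F, then per-gene nested-F contrast choice.

    For genes whose adjusted F p-value passes `fdr`, contrasts are moved
    into the selected set in decreasing |t| order for as long as the F
    statistic recomputed over the not-yet-selected contrasts (with its
    rank as numerator df) still exceeds the gene's critical F.  Selected
    contrasts must additionally pass |log2FC| > `lfc`.  Returns the table
    with q_F and significant_contrasts columns added.
    """
    table = fit.table.copy()
    table["q_F"] = multipletests(table["p_F"], method="fdr_bh")[1] if len(table) else []
    passing = table["q_F"] < fdr
    # within a BH-passing gene, contrasts are peeled against the nominal
    # critical F (per numerator rank) rather than the genome-wide threshold
    fden = fit.df_total if np.isfinite(fit.df_total) else 1e9
    crit = {r: stats.f.isf(fdr, r, fden) for r in (1, 2)}

    selections = []
    names = [f"log2fc_{c.lower()}" for c in CONTRASTS]
    tnames = [f"t_{c.lower()}" for c in CONTRASTS]
    for g, row in table.iterrows():
        if not passing.loc[g]:
            selections.append("")
            continue
        est = row[names].to_numpy(float)
        tvals = np.abs(row[tnames].to_numpy(float))
        s2 = float(row["s2_post"])
        remaining = list(np.argsort(-tvals))
        selected: list[int] = []
        while remaining:
            f_rem, rank = _subset_f(est, remaining, fit.sigma, s2)
            if f_rem <= crit[rank]:
                break
            selected.append(remaining.pop(0))
        chosen = [
            CONTRASTS[i] for i in selected if abs(est[i]) > lfc
        ]
        selections.append(",".join(chosen))
    table["significant_contrasts"] = selections
    return table


def rna_only_model(
    rna: pd.DataFrame,
    meta: pd.DataFrame,
    min_mean: float = 15,
    fdr: float = 0.05,
    lfc: float = 0.5,
    moderation: bool = True,
) -> pd.DataFrame:
    """Two-group moderated comparison of RNA abundance (all gene biotypes).

    Genes with mean count >= `min_mean` per RNA sample are log-CPM
    transformed and tested for a mutant-vs-WT difference with a moderated
    t; BH across genes; significant iff q < `fdr` and |log2FC| > `lfc`.
    """
    rna_meta = meta[meta["assay"] == "RNA"]
    counts = rna[rna_meta.index]
    keep = counts.mean(axis=1) >= min_mean
    counts = counts[keep]
    expr = log_transform(counts)
    wt_libs = rna_meta.index[rna_meta["strain"] == "WT"]
    mut_libs = rna_meta.index[rna_meta["strain"] == "mutant"]
    if len(wt_libs) < 2 or len(mut_libs) < 2:
        raise ValueError("need >= 2 replicates per strain")
    n1, n2 = len(wt_libs), len(mut_libs)
    df_resid = float(n1 + n2 - 2)
    m_wt = expr[wt_libs].mean(axis=1).to_numpy()
    m_mut = expr[mut_libs].mean(axis=1).to_numpy()
    rss = (
        ((expr[wt_libs].to_numpy() - m_wt[:, None]) ** 2).sum(axis=1)
        + ((expr[mut_libs].to_numpy() - m_mut[:, None]) ** 2).sum(axis=1)
    )
    s2 = rss / df_resid
    if moderation:
        s2_post, d0, _ = moderate_variances(s2, df_resid)
    else:
        s2_post, d0 = s2, 0.0
    s2_post = np.maximum(s2_post, 1e-300)
    df_total = df_resid + (d0 if np.isfinite(d0) else np.inf)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    est = m_mut - m_wt
    t = est / se
    tdist = stats.norm if np.isinf(df_total) else stats.t(df_total)
    p = 2.0 * tdist.sf(np.abs(t))
    out = pd.DataFrame(
        {"log2fc_rna": est, "t": t, "p": p}, index=counts.index
    )
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["significant"] = (out["q"] < fdr) & (out["log2fc_rna"].abs() > lfc)
    return out
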