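"""Integration of CLIP, TE, abundance and stability layers per gene.

A gene's regulation is classified by whether significant expression
changes coincide with a binding peak on its transcript:

* direct       - has a peak AND at least one significant layer,
* indirect     - no peak but at least one significant layer,
* binding_only - a peak with no significant expression change,
* none         - neither.

Sign convention: a significant increase in the mutant means the
regulator represses that layer in the wild type (and vice versa).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

__all__ = ["assign_peaks_to_genes", "classify_regulation", "summarize", "LAYERS"]

LAYERS = ("RPF", "RNA", "TE", "stability")


def _overlap(a0, a1, b0, b1) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    annotation: GenomeAnnotation,
    mode: str = "transcript",
) -> dict[str, list[str]]:
    """Map each gene (and ncRNA) to the peaks overlapping it.

    ``mode="transcript"`` (default) counts a peak anywhere from the 5'UTR
    through the 3'UTR; ``mode="utr5_first60"`` restricts association to
    the 5'UTR plus the first 60 CDS nt, where initiation-blocking binding
    acts.  A peak may map to several genes; intergenic peaks map to none.
    """
    out: dict[str, list[str]] = {}
    for pid, pk in peaks.iterrows():
        contig, s, e = pk["contig"], int(pk["start"]), int(pk["end"])
        for g in annotation.genes.values():
            if g.contig != contig:
                continue
            if mode == "transcript":
                hit = _overlap(s, e, *g.transcript) > 0
            elif mode == "utr5_first60":
                w = min(60, g.cds_length)
                if g.strand == "+":
                    window = (g.cds[0], g.cds[0] + w)
                else:
                    window = (g.cds[1] - w, g.cds[1])
                hit = _overlap(s, e, *window) > 0 or (
                    g.utr5 is not None and _overlap(s, e, *g.utr5) > 0
                )
            else:
                raise ValueError("mode must be 'transcript' or 'utr5_first60'")
            if hit:
                out.setdefault(g.gene_id, []).append(pid)
        for nc in annotation.ncrnas.values():
            if nc.contig == contig and _overlap(s, e, *nc.interval) > 0:
                out.setdefault(nc.ncrna_id, []).append(pid)
    return out


def _direction(sig: bool, log2fc: float) -> str:
    if not sig or not np.isfinite(log2fc):
        return "ns"
    return "up_in_mutant" if log2fc > 0 else "down_in_mutant"


def _effect(direction: str) -> str:
    # significant increase in the mutant => the regulator represses in WT
    return {"up_in_mutant": "represses", "down_in_mutant": "activates"}.get(
        direction, "none"
    )


def classify_regulation(
    te_results: pd.DataFrame | None,
    rna_only_results: pd.DataFrame | None,
    stability_results: pd.DataFrame | None,
    gene_peaks: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-gene regulation calls from the three analysis layers + peaks.

    Inputs are the per-gene output tables of the TE model (with a
    `significant_contrasts` column), the RNA-only model and the
    differential-stability analysis; any may be None (treated as ns).
    Genes are outer-joined; duplicated gene rows are an error.
    """
    for tab, name in ((te_results, "te"), (rna_only_results, "rna"),
                      (stability_results, "stability")):
        if tab is not None and tab.index.duplicated().any():
            raise ValueError(f"duplicate gene rows in {name} results")
    genes: set[str] = set(gene_peaks)
    for tab in (te_results, rna_only_results, stability_results):
        if tab is not None:
            genes |= set(tab.index)
    rows = []
    for g in sorted(genes):
        dirs = {}
        if te_results is not None and g in te_results.index:
            row = te_results.loc[g]
            chosen = set(str(row.get("significant_contrasts", "")).split(","))
            dirs["RPF"] = _direction("RPF" in chosen, row.get("log2fc_rpf", np.nan))
            dirs["TE"] = _direction("TE" in chosen, row.get("log2fc_te", np.nan))
        else:
            dirs["RPF"] = dirs["TE"] = "ns"
        if rna_only_results is not None and g in rna_only_results.index:
            row = rna_only_results.loc[g]
            dirs["RNA"] = _direction(bool(row["significant"]), row["log2fc_rna"])
        else:
            dirs["RNA"] = "ns"
        if stability_results is not None and g in stability_results.index:
            row = stability_results.loc[g]
            dirs["stability"] = _direction(bool(row["significant"]), row["log2_ratio"])
        else:
            dirs["stability"] = "ns"
        has_peak = bool(gene_peaks.get(g))
        any_sig = any(v != "ns" for v in dirs.values())
        if has_peak and any_sig:
            cls = "direct"
        elif any_sig:
            cls = "indirect"
        elif has_peak:
            cls = "binding_only"
        else:
            cls = "none"
        rows.append(
            {
                "gene_id": g,
                **{f"dir_{k}": v for k, v in dirs.items()},
                **{f"effect_{k}": _effect(v) for k, v in dirs.items()},
                "has_clip_peak": has_peak,
                "peaks": ",".join(gene_peaks.get(g, [])),
                "classification": cls,
            }
        )
    if not rows:
        cols = ([f"dir_{k}" for k in LAYERS] + [f"effect_{k}" for k in LAYERS]
                + ["has_clip_peak", "peaks", "classification"])
        return pd.DataFrame(columns=cols, index=pd.Index([], name="gene_id"))
    return pd.DataFrame(rows).set_index("gene_id")


def summarize(calls: pd.DataFrame, annotated_peaks: pd.DataFrame | None = None) -> dict:
    """Venn-style overlap counts, peak-localization fractions and tallies.

    The Venn partitions genes significant in >= 1 method across the three
    methods (TE model = RPF or TE contrast, RNA abundance, stability);
    localization fractions are computed over peak-label instances
    (multi-labelled peaks contribute to several categories).
    """
    sets = {
        "te_model": set(
            calls.index[(calls["dir_RPF"] != "ns") | (calls["dir_TE"] != "ns")]
        ),
        "rna": set(calls.index[calls["dir_RNA"] != "ns"]),
        "stability": set(calls.index[calls["dir_stability"] != "ns"]),
    }
    universe = sets["te_model"] | sets["rna"] | sets["stability"]
    venn = {}
    names = list(sets)
    for mask in range(1, 8):
        members = [names[i] for i in range(3) if mask >> i & 1]
        cell = set(universe)
        for i, nm in enumerate(names):
            cell &= sets[nm] if mask >> i & 1 else (universe - sets[nm])
        venn["&".join(members)] = len(cell)
    summary: dict = {
        "venn": venn,
        "n_significant_any": len(universe),
        "classification_counts": calls["classification"].value_counts().to_dict(),
        "effects": {
            layer: calls[f"effect_{layer}"].value_counts().to_dict()
            for layer in LAYERS
        },
    }
    if annotated_peaks is not None and len(annotated_peaks):
        label_counts: dict[str, int] = {}
        for labels in annotated_peaks["labels"]:
            for lab in str(labels).split(","):
                label_counts[lab] = label_counts.get(lab, 0) + 1
        total = sum(label_counts.values())
        summary["peak_localization_counts"] = label_counts
        summary["peak_localization_fractions"] = {
            k: v / total for k, v in label_counts.items()
        }
        summary["n_peaks"] = int(len(annotated_peaks))
        summary["n_downstream_operon"] = int(
            annotated_peaks["downstream_gene_in_operon"].sum()
        )
    return summary
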