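"""Synthetic data with the statistical structure the analysis assumes.

Four generators mirror the four experimental layers:

* an annotated genome (genes with UTRs/CDS, operons, TSS, terminators,
  ncRNAs, and a random sequence),
* rifampicin decay time-courses: per-gene exponential decay sampled
  compositionally (multinomial over genes + constant spike-ins), because
  sequencing observes fractions — exactly the regime the spike-in
  normalization is designed to invert,
* paired ribosome-profiling / RNA-seq counts for two strains with planted
  log2 effects on translation, RNA abundance and their interaction (TE),
  plus per-CDS ribosome occupancy profiles with planted pause positions,
* CLIP libraries for a tagged protein and an untagged control, with
  planted motif-bearing binding peaks enriching the tagged coverage.

Every generator takes an explicit numpy Generator (or seed) and emits a
ground-truth table sufficient to score the downstream stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, NcRNA
from .motifs import iupac_regex

__all__ = [
    "SimulationTruth",
    "generate_annotation",
    "simulate_decay_experiment",
    "simulate_ribo_experiment",
    "simulate_clip_experiment",
    "make_truth",
]


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset."""

    half_life: pd.DataFrame            # genes x {WT, mutant}, minutes
    effects: pd.DataFrame              # genes x {log2fc_rpf, log2fc_rna, log2fc_te}
    spike_abundance: pd.Series         # spike id -> relative molecule count
    pauses: pd.DataFrame               # gene_id, position (nt from start codon), fold
    peaks: pd.DataFrame                # contig, start, end, strand, enrichment, gene_id
    dispersion: float = 0.05
    seed: int = 0
    base_mean: pd.Series | None = field(default=None)

    def validate(self) -> None:
        if (self.half_life.to_numpy() <= 0).any():
            raise ValueError("half-lives must be positive")
        te = self.effects["log2fc_rpf"] - self.effects["log2fc_rna"]
        if not np.allclose(te, self.effects["log2fc_te"]):
            raise ValueError("log2fc_te must equal log2fc_rpf - log2fc_rna")
        if (self.spike_abundance <= 0).any():
            raise ValueError("spike abundances must be strictly positive")
        if len(self.peaks) and (self.peaks["enrichment"] < 1).any():
            raise ValueError("peak enrichment factors must be >= 1")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _scrub_motif(seq: list[str], pattern: re.Pattern, width: int,
                 rng: np.random.Generator, max_rounds: int = 50) -> None:
    """Re-draw any window matching `pattern` until the sequence is motif-free."""
    for _ in range(max_rounds):
        text = "".join(seq)
        hits = [m.start() for m in pattern.finditer(text)]
        if not hits:
            return
        for start in hits:
            for i in range(start, min(start + width, len(seq))):
                seq[i] = "ACGT"[rng.integers(0, 4)]
    raise RuntimeError("could not scrub motif from background sequence")


def generate_annotation(
    seed,
    n_genes: int = 50,
    n_operons: int = 5,
    contig_length: int = 200_000,
    utr_length_range: tuple[int, int] = (20, 80),
    cds_length_range: tuple[int, int] = (300, 1500),
    n_ncrnas: int = 3,
    contig_name: str = "chr",
    motif_free: bool = False,
    motif: str = "AUGGAUG",
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Place non-overlapping genes with UTRs on a random contig.

    Returns the annotation and a {contig: sequence} dict.  With
    ``motif_free=True`` the background sequence is rejected-resampled so it
    contains no occurrence of ``motif`` (used to make motif-enrichment
    tests clean).
    """
    rng = _rng(seed)
    if min(utr_length_range) <= 0 or min(cds_length_range) <= 0:
        raise ValueError("lengths must be positive")
    genes: dict[str, Gene] = {}
    operons: list[list[str]] = []
    tss: list[tuple[str, int]] = []
    terminators: list[tuple[str, int, int]] = []
    ncrnas: dict[str, NcRNA] = {}

    # operon layout: first genes grouped consecutively, 2-3 genes each
    op_sizes = []
    remaining = n_genes
    for _ in range(n_operons):
        size = int(rng.integers(2, 4))
        if remaining - size < 0:
            break
        op_sizes.append(size)
        remaining -= size

    cursor = int(rng.integers(100, 300))
    placed = 0
    op_iter = iter(op_sizes)
    current_op: list[str] = []
    op_size = next(op_iter, 0)
    op_strand = "+"
    while placed < n_genes:
        gid = f"gene{placed:04d}"
        in_operon = len(current_op) < op_size
        strand = op_strand if in_operon and current_op else ("+" if rng.random() < 0.5 else "-")
        if in_operon and not current_op:
            op_strand = strand
        u5 = int(rng.integers(*utr_length_range))
        u3 = int(rng.integers(*utr_length_range))
        cds_len = int(rng.integers(*cds_length_range))
        cds_len -= cds_len % 3
        span = u5 + cds_len + u3
        if cursor + span > contig_length:
            raise ValueError(
                f"{n_genes} genes do not fit in contig of length {contig_length}"
            )
        if strand == "+":
            utr5 = (cursor, cursor + u5)
            cds = (cursor + u5, cursor + u5 + cds_len)
            utr3 = (cds[1], cds[1] + u3)
            tss_pos = utr5[0]
            term = (utr3[1], min(utr3[1] + 20, contig_length))
        else:
            utr3 = (cursor, cursor + u3)
            cds = (cursor + u3, cursor + u3 + cds_len)
            utr5 = (cds[1], cds[1] + u5)
            tss_pos = utr5[1] - 1
            term = (max(cursor - 20, 0), cursor)
        genes[gid] = Gene(gid, contig_name, strand, cds=cds, utr5=utr5, utr3=utr3)
        if in_operon:
            current_op.append(gid)
            if len(current_op) == op_size:
                operons.append(current_op)
                current_op = []
                op_size = next(op_iter, 0)
        # TSS for solo genes and operon leaders; terminator after each unit
        if not in_operon or len(genes) == 1 or (current_op and len(current_op) == 1):
            tss.append((contig_name, tss_pos))
        terminators.append((contig_name, term[0], term[1]))
        gap = int(rng.integers(30, 120)) if in_operon and current_op else int(rng.integers(200, 500))
        cursor += span + gap
        placed += 1

    for i in range(n_ncrnas):
        length = int(rng.integers(60, 150))
        if cursor + length + 100 > contig_length:
            break
        ncrnas[f"ncrna{i:03d}"] = NcRNA(
            f"ncrna{i:03d}", contig_name, "+", (cursor, cursor + length)
        )
        cursor += length + int(rng.integers(200, 400))

    ann = GenomeAnnotation(
        contigs={contig_name: contig_length},
        genes=genes,
        operons=operons,
        tss=tss,
        terminators=terminators,
        ncrnas=ncrnas,
    )
    ann.validate()
    seq = list(_random_seq(rng, contig_length))
    if motif_free:
        _scrub_motif(seq, iupac_regex(motif), len(motif), rng)
    return ann, {contig_name: "".join(seq)}


def simulate_decay_experiment(
    half_lives: pd.Series,
    init_abundance: pd.Series,
    spike_abundance: pd.Series,
    timepoints=(0.0, 2.5, 5.0, 10.0, 15.0),
    n_replicates: int = 3,
    depth: int = 2_000_000,
    noise: float = 0.0,
    strain: str = "WT",
    noiseless: bool = False,
    rng=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compositional sampling of an exponential-decay time course.

    Gene molecules decay as N_g(t) = N_g(0) * 2^(-t/h_g); spike molecules
    stay constant.  Each library draws `depth` reads multinomially from the
    joint gene+spike composition at its timepoint; `noise` > 0 adds
    extra-Poisson variability through a per-gene gamma factor with
    variance `noise` (mean 1).

    Returns (counts, meta); spike rows are the index entries of
    `spike_abundance`.
    """
    rng = _rng(rng)
    if (half_lives <= 0).any():
        raise ValueError("half-lives must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    genes = list(half_lives.index)
    spikes = list(spike_abundance.index)
    n0 = init_abundance.reindex(genes).to_numpy(float)
    h = half_lives.to_numpy(float)
    s = spike_abundance.to_numpy(float)
    cols: dict[str, np.ndarray] = {}
    rows_meta = []
    for rep in range(1, n_replicates + 1):
        for t in timepoints:
            molecules = np.concatenate([n0 * 2.0 ** (-t / h), s])
            if noise > 0:
                molecules = molecules * rng.gamma(1.0 / noise, noise, size=molecules.size)
            p = molecules / molecules.sum()
            lib = f"{strain}_decay_t{t:g}_r{rep}"
            cols[lib] = (
                np.rint(depth * p).astype(np.int64) if noiseless
                else rng.multinomial(depth, p)
            )
            rows_meta.append((lib, strain, "DECAY", float(t), rep))
    counts = pd.DataFrame(cols, index=genes + spikes)
    meta = pd.DataFrame(
        rows_meta, columns=["library_id", "strain", "assay", "timepoint", "replicate"]
    ).set_index("library_id")
    return counts, meta


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_ribo_experiment(
    effects: pd.DataFrame,
    base_mean: pd.Series,
    annotation: GenomeAnnotation,
    pauses: pd.DataFrame | None = None,
    n_replicates: int = 5,
    dispersion: float = 0.05,
    profile_genes=None,
    noiseless: bool = False,
    rng=0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired RPF/RNA counts for WT and mutant, plus occupancy profiles.

    Gene counts follow a negative binomial with strain/assay mean
    mu_g * 2^effect (effects apply to the mutant only).  RPF reads of
    genes in `profile_genes` are additionally placed along the CDS:
    uniformly, except planted pause positions whose local rate is
    multiplied by the pause fold.

    Returns (rpf_counts, rna_counts, meta, read_positions) where
    read_positions is a long table (library, gene_id, offset, count).
    """
    rng = _rng(rng)
    genes = list(effects.index)
    mu = base_mean.reindex(genes).to_numpy(float)
    pauses = pauses if pauses is not None else pd.DataFrame(
        columns=["gene_id", "position", "fold"]
    )
    if profile_genes is None:
        profile_genes = genes
    profile_genes = [g for g in profile_genes if g in annotation.genes]
    pause_by_gene: dict[str, list[tuple[int, float]]] = {}
    for _, row in pauses.iterrows():
        pause_by_gene.setdefault(row["gene_id"], []).append(
            (int(row["position"]), float(row["fold"]))
        )

    rpf_cols, rna_cols, meta_rows, pos_rows = {}, {}, [], []
    for strain in ("WT", "mutant"):
        fc_rpf = effects["log2fc_rpf"].to_numpy(float) if strain == "mutant" else 0.0
        fc_rna = effects["log2fc_rna"].to_numpy(float) if strain == "mutant" else 0.0
        for rep in range(1, n_replicates + 1):
            rpf_lib = f"{strain}_RPF_r{rep}"
            rna_lib = f"{strain}_RNA_r{rep}"
            if noiseless:
                if dispersion < 0:
                    raise ValueError("dispersion must be >= 0")
                rpf_counts = np.rint(mu * 2.0 ** fc_rpf).astype(np.int64)
                rna_counts = np.rint(mu * 2.0 ** fc_rna).astype(np.int64)
            else:
                rpf_counts = _nb_draw(rng, mu * 2.0 ** fc_rpf, dispersion)
                rna_counts = _nb_draw(rng, mu * 2.0 ** fc_rna, dispersion)
            rpf_cols[rpf_lib] = rpf_counts
            rna_cols[rna_lib] = rna_counts
            meta_rows.append((rpf_lib, strain, "RPF", np.nan, rep))
            meta_rows.append((rna_lib, strain, "RNA", np.nan, rep))
            for gi, g in enumerate(genes):
                if g not in profile_genes:
                    continue
                length = annotation.genes[g].cds_length
                total = int(rpf_counts[gi])
                if total == 0:
                    continue
                w = np.ones(length)
                for pos, fold in pause_by_gene.get(g, []):
                    w[pos] *= fold
                if noiseless:
                    placed = np.rint(total * w / w.sum()).astype(np.int64)
                else:
                    placed = rng.multinomial(total, w / w.sum())
                nz = np.nonzero(placed)[0]
                pos_rows.extend(
                    (rpf_lib, g, int(o), int(placed[o])) for o in nz
                )
    rpf = pd.DataFrame(rpf_cols, index=genes)
    rna = pd.DataFrame(rna_cols, index=genes)
    meta = pd.DataFrame(
        meta_rows, columns=["library_id", "strain", "assay", "timepoint", "replicate"]
    ).set_index("library_id")
    read_positions = pd.DataFrame(
        pos_rows, columns=["library_id", "gene_id", "offset", "count"]
    )
    return rpf, rna, meta, read_positions


def simulate_clip_experiment(
    annotation: GenomeAnnotation,
    peaks: pd.DataFrame,
    n_replicates: int = 5,
    depth: int = 300_000,
    noiseless: bool = False,
    rng=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tagged/untagged CLIP read positions over the transcribed genome.

    Background reads fall uniformly over transcribed nucleotides in both
    conditions; inside each planted peak interval the tagged-library rate
    is multiplied by that peak's enrichment factor.

    Returns (read_positions, meta) with read_positions a long table
    (library, contig, position, count).
    """
    rng = _rng(rng)
    if len(peaks) and (peaks["enrichment"] < 1).any():
        raise ValueError("peak enrichment factors must be >= 1 (peaks are enrichments)")
    masks = {}
    for contig, length in annotation.contigs.items():
        mask = np.zeros(length, dtype=float)
        for g in annotation.genes.values():
            if g.contig == contig:
                mask[slice(*g.transcript)] = 1.0
        for nc in annotation.ncrnas.values():
            if nc.contig == contig:
                mask[slice(*nc.interval)] = 1.0
        masks[contig] = mask

    pos_rows, meta_rows = [], []
    for condition, assay in (("tagged", "CLIP_tagged"), ("untagged", "CLIP_untagged")):
        weights = {c: m.copy() for c, m in masks.items()}
        if condition == "tagged":
            for _, pk in peaks.iterrows():
                w = weights[pk["contig"]]
                s, e = int(pk["start"]), int(pk["end"])
                w[s:e] *= float(pk["enrichment"])
        flat = np.concatenate([weights[c] for c in sorted(weights)])
        offsets = {}
        off = 0
        for c in sorted(weights):
            offsets[c] = off
            off += len(weights[c])
        p = flat / flat.sum()
        for rep in range(1, n_replicates + 1):
            strain = "mutant" if condition == "tagged" else "WT"
            lib = f"{condition}_r{rep}"
            draw = (
                np.rint(depth * p).astype(np.int64) if noiseless
                else rng.multinomial(depth, p)
            )
            nz = np.nonzero(draw)[0]
            for c in sorted(weights):
                lo, hi = offsets[c], offsets[c] + len(weights[c])
                sel = nz[(nz >= lo) & (nz < hi)]
                pos_rows.extend(
                    (lib, c, int(i - lo), int(draw[i])) for i in sel
                )
            meta_rows.append((lib, strain, assay, np.nan, rep))
    read_positions = pd.DataFrame(
        pos_rows, columns=["library_id", "contig", "position", "count"]
    )
    meta = pd.DataFrame(
        meta_rows, columns=["library_id", "strain", "assay", "timepoint", "replicate"]
    ).set_index("library_id")
    return read_positions, meta


def plant_motifs(sequences: dict[str, str], peaks: pd.DataFrame,
                 motif: str = "AUGGAUG") -> dict[str, str]:
    """Write the DNA form of `motif` at the center of each planted peak."""
    dna = motif.upper().replace("U", "T")
    out = {c: list(s) for c, s in sequences.items()}
    for _, pk in peaks.iterrows():
        center = (int(pk["start"]) + int(pk["end"])) // 2 - len(dna) // 2
        seq = out[pk["contig"]]
        seq[center:center + len(dna)] = list(dna)
    return {c: "".join(s) for c, s in out.items()}


def make_truth(
    annotation: GenomeAnnotation,
    seed: int = 0,
    frac_stability_change: float = 0.1,
    stability_fold: float = 2.0,
    frac_te_affected: float = 0.1,
    effect_size: float = 1.0,
    n_spikes: int = 25,
    frac_paused: float = 0.2,
    pause_fold: float = 25.0,
    frac_peak_genes: float = 0.3,
    peak_enrichment: float = 8.0,
    peak_length: int = 60,
    dispersion: float = 0.05,
    trim: int = 30,
) -> SimulationTruth:
    """Draw a coherent ground truth over the genes of `annotation`.

    Affected gene sets for stability, RPF/RNA/TE effects, pauses and
    binding peaks are drawn independently; planted effects are +/-
    `effect_size` log2 units, stability changes are a `stability_fold`
    half-life ratio, and peaks are `peak_length`-nt windows at CDS starts.
    """
    rng = np.random.default_rng(seed)
    genes = list(annotation.genes)
    n = len(genes)

    wt_hl = np.exp(rng.uniform(np.log(1.5), np.log(15.0), size=n))
    mut_hl = wt_hl.copy()
    stab_idx = rng.choice(n, size=int(round(frac_stability_change * n)), replace=False)
    signs = rng.choice([-1.0, 1.0], size=stab_idx.size)
    mut_hl[stab_idx] = wt_hl[stab_idx] * stability_fold ** signs
    half_life = pd.DataFrame({"WT": wt_hl, "mutant": mut_hl}, index=genes)

    fc_rpf = np.zeros(n)
    fc_rna = np.zeros(n)
    n_aff = int(round(frac_te_affected * n))
    aff = rng.choice(n, size=min(3 * n_aff, n), replace=False)
    third = len(aff) // 3
    # three planted classes: RPF-only, RNA-only (cancels in TE), both-shifted
    fc_rpf[aff[:third]] = effect_size * rng.choice([-1, 1], size=third)
    fc_rna[aff[third:2 * third]] = effect_size * rng.choice([-1, 1], size=third)
    both = aff[2 * third:]
    fc_rpf[both] = effect_size * rng.choice([-1, 1], size=len(both))
    fc_rna[both] = fc_rpf[both]
    effects = pd.DataFrame(
        {"log2fc_rpf": fc_rpf, "log2fc_rna": fc_rna, "log2fc_te": fc_rpf - fc_rna},
        index=genes,
    )

    spike_abundance = pd.Series(
        np.exp(rng.uniform(np.log(50), np.log(5000), size=n_spikes)),
        index=[f"spike{i:03d}" for i in range(n_spikes)],
    )

    pause_rows = []
    for gid in rng.choice(genes, size=int(round(frac_paused * n)), replace=False):
        length = annotation.genes[gid].cds_length
        if length <= 2 * trim + 1:
            continue
        pos = int(rng.integers(trim, length - trim))
        pause_rows.append((gid, pos, pause_fold))
    pauses = pd.DataFrame(pause_rows, columns=["gene_id", "position", "fold"])

    peak_rows = []
    for gid in rng.choice(genes, size=int(round(frac_peak_genes * n)), replace=False):
        g = annotation.genes[gid]
        # window over the start-codon region, where the regulator binds
        if g.strand == "+":
            s = max(g.transcript[0], g.cds[0] - peak_length // 2)
            e = min(g.transcript[1], s + peak_length)
        else:
            e = min(g.transcript[1], g.cds[1] + peak_length // 2)
            s = max(g.transcript[0], e - peak_length)
        peak_rows.append((g.contig, s, e, g.strand, peak_enrichment, gid))
    peaks = pd.DataFrame(
        peak_rows, columns=["contig", "start", "end", "strand", "enrichment", "gene_id"]
    )

    base_mean = pd.Series(
        np.exp(rng.uniform(np.log(50), np.log(2000), size=n)), index=genes
    )
    truth = SimulationTruth(
        half_life=half_life,
        effects=effects,
        spike_abundance=spike_abundance,
        pauses=pauses,
        peaks=peaks,
        dispersion=dispersion,
        seed=seed,
        base_mean=base_mean,
    )
    truth.validate()
    return truth
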