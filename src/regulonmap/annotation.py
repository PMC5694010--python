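"""Genome annotation model and GFF3/BED input-output.

The internal coordinate convention is 0-based half-open everywhere;
conversion to 1-based inclusive GFF3 happens only at the file boundary.
A gene is a 5'UTR / CDS / 3'UTR triple on one strand (UTRs optional),
optionally grouped into operons.  Transcription start sites, intrinsic
terminators and non-coding RNAs are carried as separate feature sets so
binding peaks can be annotated against all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Gene",
    "NcRNA",
    "GenomeAnnotation",
    "AnnotationError",
    "ParseError",
    "read_annotation",
    "write_gff3",
    "write_bed",
]

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """An annotation violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line."""


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str
    cds: Interval
    utr5: Interval | None = None
    utr3: Interval | None = None
    coding: bool = True

    @property
    def transcript(self) -> Interval:
        """Full transcript span (5'UTR through 3'UTR), half-open."""
        parts = [p for p in (self.utr5, self.cds, self.utr3) if p is not None]
        return (min(p[0] for p in parts), max(p[1] for p in parts))

    @property
    def cds_length(self) -> int:
        return self.cds[1] - self.cds[0]

    def cds_offset_to_genomic(self, offset: int) -> int:
        """Genomic coordinate of a 0-based offset from the start codon."""
        if not 0 <= offset < self.cds_length:
            raise ValueError(f"offset {offset} outside CDS of {self.gene_id}")
        if self.strand == "+":
            return self.cds[0] + offset
        return self.cds[1] - 1 - offset


@dataclass
class NcRNA:
    ncrna_id: str
    contig: str
    strand: str
    interval: Interval


@dataclass
class GenomeAnnotation:
    contigs: dict[str, int]
    genes: dict[str, Gene] = field(default_factory=dict)
    operons: list[list[str]] = field(default_factory=list)
    tss: list[tuple[str, int]] = field(default_factory=list)
    terminators: list[tuple[str, int, int]] = field(default_factory=list)
    ncrnas: dict[str, NcRNA] = field(default_factory=dict)

    def validate(self) -> None:
        """Check every structural invariant; raise AnnotationError on failure."""
        bad_frame: list[str] = []
        seen_in_operon: set[str] = set()
        for ops in self.operons:
            for gid in ops:
                if gid in seen_in_operon:
                    raise AnnotationError(f"gene {gid} in more than one operon")
                if gid not in self.genes:
                    raise AnnotationError(f"operon references unknown gene {gid}")
                seen_in_operon.add(gid)
        for gene in self.genes.values():
            if gene.contig not in self.contigs:
                raise AnnotationError(f"{gene.gene_id}: unknown contig {gene.contig}")
            clen = self.contigs[gene.contig]
            for iv in (gene.utr5, gene.cds, gene.utr3):
                if iv is None:
                    continue
                s, e = iv
                if not (0 <= s < e <= clen):
                    raise AnnotationError(
                        f"{gene.gene_id}: interval ({s}, {e}) outside [0, {clen})"
                    )
            if gene.strand not in "+-":
                raise AnnotationError(f"{gene.gene_id}: bad strand {gene.strand!r}")
            if gene.coding and gene.cds_length % 3 != 0:
                bad_frame.append(gene.gene_id)
            # UTRs must abut the CDS in the gene's orientation
            if gene.utr5 is not None:
                ok = (gene.utr5[1] == gene.cds[0]) if gene.strand == "+" else (
                    gene.utr5[0] == gene.cds[1]
                )
                if not ok:
                    raise AnnotationError(f"{gene.gene_id}: 5'UTR not adjacent to CDS")
            if gene.utr3 is not None:
                ok = (gene.utr3[0] == gene.cds[1]) if gene.strand == "+" else (
                    gene.utr3[1] == gene.cds[0]
                )
                if not ok:
                    raise AnnotationError(f"{gene.gene_id}: 3'UTR not adjacent to CDS")
        if bad_frame:
            raise AnnotationError(
                "CDS length not divisible by 3 for: " + ", ".join(sorted(bad_frame))
            )
        for nc in self.ncrnas.values():
            if nc.ncrna_id in self.genes:
                raise AnnotationError(f"id {nc.ncrna_id} used by both gene and ncRNA")

    def operon_of(self, gene_id: str) -> list[str] | None:
        for ops in self.operons:
            if gene_id in ops:
                return ops
        return None

    def next_in_operon(self, gene_id: str) -> str | None:
        """The gene transcribed immediately after `gene_id` in its operon."""
        ops = self.operon_of(gene_id)
        if ops is None:
            return None
        i = ops.index(gene_id)
        return ops[i + 1] if i + 1 < len(ops) else None


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"attribute without '=': {chunk!r}")
        key, val = chunk.split("=", 1)
        out[key] = val
    return out


def _read_gff3(path: str) -> GenomeAnnotation:
    contigs: dict[str, int] = {}
    genes: dict[str, Gene] = {}
    gene_parts: dict[str, dict[str, Interval]] = {}
    gene_operon: dict[str, tuple[str, int]] = {}
    noncoding: set[str] = set()
    ann = GenomeAnnotation(contigs=contigs, genes=genes)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                try:
                    _, name, _start, end = line.split()
                    contigs[name] = int(end)
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad sequence-region: {exc}")
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 tab-separated fields")
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
                attrs = _parse_attributes(attr_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}")
            iv = (start1 - 1, end1)  # GFF3 1-based inclusive -> half-open
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"line {lineno}: gene without ID attribute")
                if gid in genes:
                    raise ParseError(f"line {lineno}: duplicate gene id {gid}")
                genes[gid] = Gene(gid, contig, strand, cds=iv)
                gene_parts[gid] = {}
                if attrs.get("biotype") == "noncoding":
                    noncoding.add(gid)
                if "operon" in attrs:
                    gene_operon[gid] = (attrs["operon"], int(attrs.get("operon_index", 0)))
            elif ftype in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"line {lineno}: {ftype} without Parent")
                gene_parts.setdefault(parent, {})[ftype] = iv
            elif ftype == "ncRNA":
                ncid = attrs.get("ID")
                if ncid is None:
                    raise ParseError(f"line {lineno}: ncRNA without ID")
                ann.ncrnas[ncid] = NcRNA(ncid, contig, strand, iv)
            elif ftype == "TSS":
                ann.tss.append((contig, iv[0]))
            elif ftype == "terminator":
                ann.terminators.append((contig, iv[0], iv[1]))
            # unknown feature types are ignored
    for gid, parts in gene_parts.items():
        if gid not in genes:
            raise ParseError(f"feature Parent={gid} has no gene line")
        g = genes[gid]
        if "CDS" in parts:
            g.cds = parts["CDS"]
        g.utr5 = parts.get("five_prime_UTR")
        g.utr3 = parts.get("three_prime_UTR")
        g.coding = gid not in noncoding
    # reconstruct operons from (name, index) attributes
    by_op: dict[str, list[tuple[int, str]]] = {}
    for gid, (opname, idx) in gene_operon.items():
        by_op.setdefault(opname, []).append((idx, gid))
    ann.operons = [[gid for _, gid in sorted(v)] for _, v in sorted(by_op.items())]
    for name in {g.contig for g in genes.values()}:
        contigs.setdefault(name, max(g.transcript[1] for g in genes.values() if g.contig == name))
    ann.validate()
    return ann


def _read_bed(path: str) -> GenomeAnnotation:
    """BED6: each record becomes a gene whose CDS is the whole interval."""
    contigs: dict[str, int] = {}
    genes: dict[str, Gene] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: BED6 needs 6 fields")
            contig, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}")
            if name in genes:
                raise ParseError(f"line {lineno}: duplicate gene id {name}")
            genes[name] = Gene(name, contig, strand, cds=(start, end))
            contigs[contig] = max(contigs.get(contig, 0), end)
    ann = GenomeAnnotation(contigs=contigs, genes=genes)
    ann.validate()
    return ann


def read_annotation(path: str) -> GenomeAnnotation:
    """Read a GFF3 or BED6 annotation into internal half-open coordinates.

    Format is chosen by extension (.gff/.gff3 vs .bed); anything else is
    tried as GFF3 first.
    """
    lower = str(path).lower()
    if lower.endswith(".bed"):
        return _read_bed(path)
    return _read_gff3(path)


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(ann: GenomeAnnotation, path: str, source: str = "regulonmap") -> None:
    ann.validate()
    op_of: dict[str, tuple[str, int]] = {}
    for oi, ops in enumerate(ann.operons):
        for gi, gid in enumerate(ops):
            op_of[gid] = (f"operon{oi:04d}", gi)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in ann.contigs.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")

        def emit(contig, ftype, iv, strand, attrs):
            fh.write(
                f"{contig}\t{source}\t{ftype}\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t.\t"
                f"{_fmt_attrs(attrs)}\n"
            )

        for g in ann.genes.values():
            attrs = {"ID": g.gene_id}
            if not g.coding:
                attrs["biotype"] = "noncoding"
            if g.gene_id in op_of:
                opname, idx = op_of[g.gene_id]
                attrs["operon"] = opname
                attrs["operon_index"] = str(idx)
            emit(g.contig, "gene", g.transcript, g.strand, attrs)
            if g.utr5 is not None:
                emit(g.contig, "five_prime_UTR", g.utr5, g.strand, {"Parent": g.gene_id})
            emit(g.contig, "CDS", g.cds, g.strand, {"Parent": g.gene_id})
            if g.utr3 is not None:
                emit(g.contig, "three_prime_UTR", g.utr3, g.strand, {"Parent": g.gene_id})
        for nc in ann.ncrnas.values():
            emit(nc.contig, "ncRNA", nc.interval, nc.strand, {"ID": nc.ncrna_id})
        for contig, pos in ann.tss:
            emit(contig, "TSS", (pos, pos + 1), "+", {"ID": f"tss_{contig}_{pos}"})
        for contig, s, e in ann.terminators:
            emit(contig, "terminator", (s, e), "+", {"ID": f"term_{contig}_{s}"})


def write_bed(ann: GenomeAnnotation, path: str) -> None:
    """Write gene CDS intervals as BED6 (already half-open: no conversion)."""
    with open(path, "w") as fh:
        for g in ann.genes.values():
            fh.write(
                f"{g.contig}\t{g.cds[0]}\t{g.cds[1]}\t{g.gene_id}\t0\t{g.strand}\n"
            )
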