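"""IUPAC consensus-motif scanning and enrichment testing.

The default motif is the 7-mer AUGGAUG core recognized by CsrA-family
regulators (GGA presented in a stem-loop); an extended SELEX consensus
RUACARGGAUGU is selectable.  Sequences are scanned on the given strand
(peaks are strand-resolved transcripts) with T/U treated as equivalent.
"""

from __future__ import annotations

import re

import numpy as np
from scipy import stats

__all__ = ["iupac_regex", "scan_motif", "motif_enrichment", "CORE_MOTIF", "EXTENDED_MOTIF"]

CORE_MOTIF = "AUGGAUG"
EXTENDED_MOTIF = "RUACARGGAUGU"

# IUPAC nucleotide codes over the DNA alphabet (U normalized to T)
_IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC string into a lookahead regex allowing overlaps."""
    body = []
    for ch in _normalize(motif):
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in motif {motif!r}")
        allowed = _IUPAC[ch]
        body.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile(f"(?={''.join(body)})")


def scan_motif(sequences: dict[str, str] | list[str], motif: str = CORE_MOTIF
               ) -> dict[str, list[int]]:
    """All 0-based match start positions of `motif` in each sequence.

    Overlapping matches are reported; DNA and RNA alphabets are
    interchangeable (T equivalent to U).  Input may be a {name: seq}
    mapping or a list (names become the indices).
    """
    if not isinstance(sequences, dict):
        sequences = {str(i): s for i, s in enumerate(sequences)}
    pat = iupac_regex(motif)
    return {
        name: [m.start() for m in pat.finditer(_normalize(seq))]
        for name, seq in sequences.items()
    }


def motif_enrichment(
    peak_sequences,
    background_sequences,
    motif: str = CORE_MOTIF,
    correction: bool = False,
) -> dict:
    """Chi-square test of motif-start frequency in peaks versus background.

    Builds the 2x2 table of (motif-match starts, non-match scannable
    positions) x (peaks, background) and applies a two-sided Pearson
    chi-square (Yates correction off by default).  Returns frequencies,
    the fold ratio, the table, chi2 and p.
    """
    m = len(motif)

    def tally(seqs) -> tuple[int, int]:
        hits = scan_motif(seqs, motif)
        seqs = seqs if isinstance(seqs, dict) else {str(i): s for i, s in enumerate(seqs)}
        matches = sum(len(v) for v in hits.values())
        scannable = sum(max(len(s) - m + 1, 0) for s in seqs.values())
        return matches, scannable

    pk_hits, pk_pos = tally(peak_sequences)
    bg_hits, bg_pos = tally(background_sequences)
    if pk_pos == 0 or bg_pos == 0:
        raise ValueError("no scannable positions in one of the sequence sets")
    table = np.array([[pk_hits, pk_pos - pk_hits], [bg_hits, bg_pos - bg_hits]])
    if table[:, 0].sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    freq_pk = pk_hits / pk_pos
    freq_bg = bg_hits / bg_pos
    return {
        "freq_peaks": freq_pk,
        "freq_background": freq_bg,
        "fold": freq_pk / freq_bg if freq_bg > 0 else float("inf"),
        "table": table,
        "chi2": float(chi2),
        "p": float(p),
    }
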