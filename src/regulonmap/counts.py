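"""Count-matrix and sample-metadata tables.

Counts are a genes x libraries pandas DataFrame of non-negative integers;
metadata is a libraries-indexed DataFrame with strain / assay / timepoint /
replicate columns.  Validation enforces the contracts every downstream
stage assumes (integer counts, unique ids, known assay labels, timepoints
present exactly for decay libraries).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ASSAYS",
    "CountsError",
    "validate_counts",
    "validate_meta",
    "read_counts",
    "write_counts",
]

ASSAYS = frozenset({"RPF", "RNA", "CLIP_tagged", "CLIP_untagged", "DECAY"})
STRAINS = frozenset({"WT", "mutant"})


class CountsError(ValueError):
    pass


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise CountsError(f"duplicate gene ids: {dupes}")
    if counts.columns.duplicated().any():
        raise CountsError("duplicate library ids")
    values = counts.to_numpy()
    try:
        as_int = counts.astype("int64")
    except (ValueError, TypeError) as exc:
        raise CountsError(f"counts must be integers: {exc}")
    if not (as_int.to_numpy() == values).all():
        raise CountsError("counts must be integers (found fractional values)")
    if (as_int.to_numpy() < 0).any():
        raise CountsError("counts must be non-negative")
    return as_int


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"strain", "assay", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise CountsError(f"metadata missing columns: {sorted(missing)}")
    if meta.index.duplicated().any():
        raise CountsError("duplicate library ids in metadata")
    unknown = set(meta["assay"]) - ASSAYS
    if unknown:
        raise CountsError(f"unknown assay labels: {sorted(unknown)}")
    unknown_strain = set(meta["strain"]) - STRAINS
    if unknown_strain:
        raise CountsError(f"unknown strain labels: {sorted(unknown_strain)}")
    if "timepoint" not in meta.columns:
        meta = meta.assign(timepoint=float("nan"))
    is_decay = meta["assay"] == "DECAY"
    if meta.loc[is_decay, "timepoint"].isna().any():
        raise CountsError("DECAY libraries must carry a timepoint")
    if meta.loc[~is_decay, "timepoint"].notna().any():
        raise CountsError("timepoint only allowed for DECAY libraries")
    key = meta[["strain", "assay", "timepoint", "replicate"]].astype(str)
    if key.duplicated().any():
        raise CountsError("(strain, assay, timepoint, replicate) not unique")
    return meta


def read_counts(path: str, meta_path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a counts TSV (gene rows, library columns) and its metadata TSV.

    Returns (counts, meta) with counts columns restricted to, and ordered
    like, the metadata index.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    counts = validate_counts(counts)
    meta = validate_meta(meta)
    missing = set(meta.index) - set(counts.columns)
    if missing:
        raise CountsError(f"libraries in metadata but not counts: {sorted(missing)}")
    return counts[list(meta.index)], meta


def write_counts(counts: pd.DataFrame, path: str, meta: pd.DataFrame | None = None,
                 meta_path: str | None = None) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")
    if meta is not None and meta_path is not None:
        out = meta.copy()
        out.to_csv(meta_path, sep="\t", index_label="library_id")
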