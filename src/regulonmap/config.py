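"""Flat key/value configuration with the analysis defaults.

Every threshold used anywhere in the pipeline is a named key here, so a
run is fully described by (config, seed).  The file format is flat YAML
(`key: value` per line); unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import yaml

DEFAULTS: dict = {
    # decay / stability
    "decay_timepoints": [0.0, 2.5, 5.0, 10.0, 15.0],  # min after rifampicin
    "spike_top_k": 25,            # spikes for the normalization factor
    "spike_min_usable": 10,       # minimum spikes after zero-drop
    "decay_min_t0": 50,           # starting-read-count filter
    "decay_min_r2": 0.7,          # regression-quality filter
    "decay_filter_mode": "or",    # "or": exclude if either fails; "and": both
    "decay_pseudocount": 0.0,     # optional +0.5 on the decay series
    "decay_equal_depth": True,    # rescale libraries to equal totals first
    "decay_fdr": 0.05,
    "decay_lfc": 0.5,             # |log2 half-life ratio| gate
    "decay_ttest": "student",     # or "welch"
    # translation / TE
    "te_min_mean": 15,            # counts/sample expression filter
    "te_filter_mode": "both",     # removed iff below threshold in BOTH assays
    "te_fdr": 0.05,
    "te_lfc": 0.5,
    "te_moderation": True,
    # pausing
    "pause_trim": 30,             # nt trimmed from each CDS end
    "pause_fold": 10.0,           # occupancy fold over trimmed-CDS mean
    "pause_min_reps": 4,          # replicate-consensus threshold
    "pause_position_tolerance": 0,
    "pause_flank": 30,            # nt around peaks for co-localization
    "read_assignment": "center",  # read-to-position rule
    # CLIP peaks
    "peak_min_cov": 10,
    "peak_min_len": 20,
    "peak_merge_gap": 10,
    "clip_fdr": 0.05,
    "clip_dedup": False,
    "motif": "AUGGAUG",
    "chi2_correction": False,
    # integration
    "peak_association": "transcript",  # or "utr5_first60"
}


class ConfigError(ValueError):
    pass


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config must be a flat key: value mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update(overrides)
    return cfg


def write_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=None)
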