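"""Strict TOML run configuration.

A run config is a TOML document with the sections below; unknown sections
or keys are rejected so a typo cannot silently fall back to a default.
Every random operation takes an explicit seed, either per-section or via
the CLI ``--seed`` override.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .errors import ConfigError

#: section -> allowed keys
SCHEMA: dict[str, set[str]] = {
    "system": {"kind", "dim", "k", "a", "b", "n_beads", "helix_bias", "omega"},
    "sampler": {
        "dt", "T_sim", "friction", "n_steps", "sample_every", "seed",
        "wall_stiffness", "burn_in",
    },
    "protocol": {
        "T_seed", "T_reset", "T_target", "extension_rule", "max_iterations",
        "flatness_threshold", "degree", "n_bins", "n_traj", "margin_frac",
    },
    "reweight": {"T_tags", "n_resample", "seed"},
    "analysis": {
        "ligand_chain", "receptor_chain", "cutoff", "support_threshold",
        "bound_thresholds", "pmf_binwidth", "density_spacing",
    },
    "synthetic": {
        "n_models", "model_jitter_sigma", "n_conformations", "pose_weights",
        "helix_propensity", "marker_anchor_sigma", "seed",
    },
    "io": {"out_dir"},
}


def load_config(path) -> dict:
    """Parse and validate a TOML run config against the strict schema."""
    text = Path(path).read_text()
    try:
        doc = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML in {path}: {exc}") from exc
    for section, body in doc.items():
        if section not in SCHEMA:
            raise ConfigError(
                f"unknown section [{section}]; expected one of {sorted(SCHEMA)}"
            )
        if not isinstance(body, dict):
            raise ConfigError(f"section [{section}] must be a table")
        unknown = set(body) - SCHEMA[section]
        if unknown:
            raise ConfigError(
                f"unknown keys {sorted(unknown)} in [{section}]; "
                f"allowed: {sorted(SCHEMA[section])}"
            )
    return doc
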