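"""Run configuration: a flat YAML file of key/value overrides."""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml


@dataclass
class Config:
    # genotype file dialect: "wide" (<locus>_1/<locus>_2) or "slash" (a/b)
    dialect: str = "wide"
    # alignment column stripping: "complete" or "pairwise"
    strip_mode: str = "complete"
    # allele frequencies for likelihoods: "empirical" or "uniform_minimal"
    freq_mode: str = "empirical"
    # dyadic kinship
    n_sims: int = 10_000
    tie_alpha: float = 0.05
    fold_po_to_fs: bool = True
    # parsimony search
    exact_cap: int = 12
    mismatch_budget: int = 0
    # marker diagnostics
    unbiased_he: bool = True
    exclusion_form: str = "parent_pair"
    hwe_mc_reps: int = 100_000
    # simulator
    n_adult_reference: int = 81
    seed: int = 0


def load_config(path=None, **overrides) -> Config:
    cfg = Config()
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(Config)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k, v in data.items():
        setattr(cfg, k, v)
    return cfg
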