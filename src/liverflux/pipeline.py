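"""End-to-end orchestration: simulate/load -> score -> call -> concord.

A :class:`RunConfig` (usually read from a YAML file) names the inputs —
either files in the package's TSV dialects or the synthetic generators —
and every stage parameter. :func:`run_all` executes the chain and writes
all output tables plus a manifest recording the config hash, seed and
library versions; re-running an identical config reproduces identical
files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .concordance import accuracy_summary, compare, read_pathway_map, write_report
from .constraints import read_bounds_tsv
from .errors import ValidationError
from .metabolomics import BootstrapConfig, call_directions, read_counts_tsv
from .netmodel import load_model
from .synthetic import (
    CountSimSpec,
    ToyNetworkSpec,
    make_ms_counts,
    make_toy_liver_network,
    write_truth_tsv,
)
from .metabolomics import write_counts_tsv
from .timbr import run_timbr


@dataclass
class RunConfig:
    """All knobs of one analysis run. File paths may be None to simulate."""

    out_dir: str
    seed: Optional[int] = None
    # network inputs (None -> toy generator)
    model_path: Optional[str] = None
    bounds_path: Optional[str] = None
    early_condition: str = "early_5-7h"
    late_condition: str = "late_10-13h"
    scored_metabolites: Optional[List[str]] = None
    pathway_path: Optional[str] = None
    # counts input (None -> count simulator driven by the toy truth table)
    counts_path: Optional[str] = None
    # stage parameters
    v_opt_fraction: float = 0.9
    v_opt_mode: str = "shared"
    weights_path: Optional[str] = None
    B: int = 100_000
    ci_level: float = 0.99
    estimator: str = "paired_ratio"
    impute_scope: str = "per_study"
    sim_n_metabolites: int = 50
    sim_noise_sigma: float = 0.3
    sim_missing_rate: float = 0.1
    sim_planted_fc_elevated: float = 2.0
    sim_planted_fc_depressed: float = 0.5
    overall_alternative: str = "greater"
    pathway_alternative: str = "two_sided"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValidationError("config must set out_dir")
        return cls(**raw)

    def validate(self) -> None:
        stochastic = self.counts_path is None or self.B > 0
        if stochastic and self.seed is None:
            raise ValidationError(
                "a seed is required: the run simulates counts and/or bootstraps"
            )
        for path in (
            self.model_path, self.bounds_path, self.counts_path,
            self.pathway_path, self.weights_path,
        ):
            if path is not None and not os.path.exists(path):
                raise ValidationError(f"input path does not exist: {path}")


def _config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(asdict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode("utf8")).hexdigest()


def _read_weights(path: Optional[str]) -> Optional[Dict[str, float]]:
    if path is None:
        return None
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["reaction_id", "weight"]:
        raise ValidationError(f"{path}: expected columns reaction_id, weight")
    return dict(zip(df["reaction_id"], df["weight"].astype(float)))


def run_all(cfg: RunConfig) -> Dict[str, object]:
    """Execute the full chain; returns the summary dict written to disk."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)

    # --- network stage ----------------------------------------------------
    if cfg.model_path is None:
        toy = make_toy_liver_network(ToyNetworkSpec())
        model, cb_early, cb_late = toy.model, toy.cb_early, toy.cb_late
        scored = cfg.scored_metabolites or toy.scored_metabolites
        pathway_map = dict(toy.pathway_map)
        truths = toy.truths
    else:
        model = load_model(cfg.model_path)
        if cfg.bounds_path is None:
            raise ValidationError("bounds_path is required with model_path")
        conditions = read_bounds_tsv(cfg.bounds_path)
        try:
            cb_early = conditions[cfg.early_condition]
            cb_late = conditions[cfg.late_condition]
        except KeyError as missing:
            raise ValidationError(
                f"bounds file lacks condition {missing}; has {sorted(conditions)}"
            ) from None
        scored = cfg.scored_metabolites
        pathway_map = read_pathway_map(cfg.pathway_path) if cfg.pathway_path else {}
        truths = {}

    scores = run_timbr(
        model, cb_early, cb_late,
        metabolites=scored,
        v_opt_fraction=cfg.v_opt_fraction,
        weights=_read_weights(cfg.weights_path),
        v_opt_mode=cfg.v_opt_mode,
    )
    scores.to_tsv(os.path.join(cfg.out_dir, "scores.tsv"))

    # --- metabolomics stage ------------------------------------------------
    if cfg.counts_path is None:
        planted = {}
        for met, direction in truths.items():
            planted[met] = (
                cfg.sim_planted_fc_elevated
                if direction == "elevated"
                else cfg.sim_planted_fc_depressed
            )
        sim = CountSimSpec(
            n_metabolites=max(cfg.sim_n_metabolites, len(planted)),
            planted_fc=planted,
            noise_sigma=cfg.sim_noise_sigma,
            missing_rate=cfg.sim_missing_rate,
            seed=cfg.seed,
        )
        studies, truth_table = make_ms_counts(sim)
        write_counts_tsv(studies, os.path.join(cfg.out_dir, "counts.tsv"))
        write_truth_tsv(truth_table, os.path.join(cfg.out_dir, "counts_truth.tsv"))
    else:
        studies = read_counts_tsv(cfg.counts_path)

    calls = call_directions(
        studies,
        BootstrapConfig(
            B=cfg.B, ci_level=cfg.ci_level, seed=cfg.seed,
            estimator=cfg.estimator, impute_scope=cfg.impute_scope,
        ),
    )
    calls.to_csv(os.path.join(cfg.out_dir, "calls.tsv"), sep="\t", index=False)

    # --- concordance stage --------------------------------------------------
    report = compare(scores, calls, pathway_map)
    write_report(report, os.path.join(cfg.out_dir, "concordance.tsv"))
    summary = accuracy_summary(
        report, cfg.overall_alternative, cfg.pathway_alternative
    )
    summary["unmapped"] = report.unmapped
    with open(os.path.join(cfg.out_dir, "concordance_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    manifest = {
        "config": asdict(cfg),
        "config_sha256": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "liverflux": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return summary
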