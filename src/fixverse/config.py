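"""YAML run configuration.

A single file with sections ``synthetic``, ``cleaning_catalog``,
``filters``, ``outliers``, ``models``, ``permutation`` and ``io``. Every
section is optional; omitted sections fall back to the replication
defaults (the shipped 14-entry cleaning catalog, filter levels 0/3/5, the
seven outlier rules, all three model families, 500 permutations).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from fixverse.cleaning import (
    CleaningConfig,
    MergeStage,
    RunMergeStage,
    TemporalStage,
    build_catalog,
)
from fixverse.modeling import FAMILIES
from fixverse.multiverse import Catalog, default_outlier_rules
from fixverse.preprocessing import OutlierRule
from fixverse.synthetic import SyntheticConfig


def load_run_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return parse_run_config(raw)


def parse_run_config(raw: dict) -> dict:
    synthetic = SyntheticConfig(**raw.get("synthetic", {}))
    if "cleaning_catalog" in raw:
        cleaning = [_parse_cleaning(entry) for entry in raw["cleaning_catalog"]]
    else:
        cleaning = build_catalog()
    filters = tuple(raw.get("filters", (0, 3, 5)))
    if "outliers" in raw:
        outliers = tuple(
            OutlierRule(o["scope"], float(o.get("k_sd", float("nan"))))
            for o in raw["outliers"]
        )
    else:
        outliers = default_outlier_rules()
    models = tuple(raw.get("models", FAMILIES))
    perm = raw.get("permutation", {})
    catalog = Catalog(
        cleaning_configs=cleaning,
        filter_levels=filters,
        outlier_rules=outliers,
        model_families=models,
        significance_alpha=float(raw.get("alpha", 0.05)),
    )
    return {
        "synthetic": synthetic,
        "catalog": catalog,
        "n_perm": int(perm.get("n_perm", 500)),
        "perm_seed": int(perm.get("seed", 0)),
        "io": raw.get("io", {}),
    }


def _parse_cleaning(entry: dict) -> CleaningConfig:
    def stage(key, cls, **defaults):
        block = dict(defaults)
        block.update(entry.get(key, {}))
        return cls(**block)

    return CleaningConfig(
        config_id=entry["config_id"],
        stage1=stage("stage1", MergeStage, enabled=True, max_dur_ms=80.0,
                     max_dist_deg=0.5),
        stage2=stage("stage2", MergeStage, enabled=True, max_dur_ms=40.0,
                     max_dist_deg=1.25),
        stage3=stage("stage3", RunMergeStage, enabled=True, max_dur_ms=140.0),
        stage4=stage("stage4", TemporalStage, enabled=True, min_dur_ms=140.0,
                     max_dur_ms=800.0),
        delete_outside_ia=bool(entry.get("delete_outside_ia", False)),
    )


def dump_config(config: SyntheticConfig) -> dict:
    return dataclasses.asdict(config)
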