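"""Universe enumeration, pipeline execution, and permutation inference.

A *universe* is one path through the garden of forking paths: a cleaning
configuration, a minimum-fixation trial filter, an outlier rule, and a
model family. Every universe executes the same fixed pipeline order:
cleaning -> trial filter -> SFD extraction -> outlier removal -> model fit.

The engine exploits two structural facts for speed without changing any
result: (i) universes sharing a (cleaning, filter, outlier) prefix share
their observation table, and (ii) condition labels are an item property
that no cleaning/filtering/extraction step reads, so label permutations
commute with those stages. Equivalence with the naive one-universe-at-a-time
execution is covered by tests.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from fixverse.cleaning import CleaningConfig, apply_cleaning, build_catalog
from fixverse.io import TrialSet
from fixverse.modeling import FAMILIES, ModelResult, ModelSpec, fit_model
from fixverse.preprocessing import (
    OutlierRule,
    extract_sfd,
    filter_trials,
    remove_outliers,
)


@dataclass(frozen=True)
class UniverseSpec:
    cleaning_id: str
    min_fixations: int
    outlier: OutlierRule
    model: ModelSpec

    @property
    def label(self) -> str:
        return (
            f"{self.cleaning_id}|minfix{self.min_fixations}"
            f"|{self.outlier.label}|{self.model.family}"
        )


@dataclass
class UniverseResult:
    spec: UniverseSpec
    model_result: ModelResult
    n_obs_removed_vs_baseline: int
    dataset_fingerprint: str


@dataclass
class MultiverseResult:
    """Specification curve: universes ordered ascending by effect size."""

    universes: list[UniverseResult]
    n_significant: int
    n_nonconverged: int
    dashboard: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, u in enumerate(self.universes, start=1):
            m = u.model_result
            rows.append(
                {
                    "rank": rank,
                    "cleaning_id": u.spec.cleaning_id,
                    "min_fixations": u.spec.min_fixations,
                    "outlier": u.spec.outlier.label,
                    "family": u.spec.model.family,
                    "beta_freq": m.beta_freq,
                    "se_beta": m.se_beta,
                    "p_value": m.p_value,
                    "significant": m.significant,
                    "converged": m.converged,
                    "effect_ms": m.effect_ms,
                    "n_obs": m.n_obs,
                    "n_obs_removed_vs_baseline": u.n_obs_removed_vs_baseline,
                    "fingerprint": u.dataset_fingerprint,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PermutationResult:
    empirical_count: int
    null_counts: list[int]
    p_add_one: float
    p_bound: float
    bound_holds: bool
    n_perm: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "empirical_count": self.empirical_count,
            "null_counts": list(self.null_counts),
            "p_add_one": self.p_add_one,
            "p_bound": self.p_bound,
            "bound_holds": self.bound_holds,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


@dataclass
class Catalog:
    """The factor levels spanning the multiverse."""

    cleaning_configs: list[CleaningConfig]
    filter_levels: tuple[int, ...] = (0, 3, 5)
    outlier_rules: tuple[OutlierRule, ...] = ()
    model_families: tuple[str, ...] = FAMILIES
    significance_alpha: float = 0.05


def default_outlier_rules() -> tuple[OutlierRule, ...]:
    rules = [OutlierRule("none")]
    for scope in ("grand", "subject", "subject_condition"):
        for k in (2.5, 3.0):
            rules.append(OutlierRule(scope, k))
    return tuple(rules)


def default_catalog() -> Catalog:
    """Full replication catalog: 14 cleaning configs x 3 filters x 7 outlier
    rules x 3 model families = 882 universes."""
    return Catalog(
        cleaning_configs=build_catalog(),
        filter_levels=(0, 3, 5),
        outlier_rules=default_outlier_rules(),
        model_families=FAMILIES,
    )


def enumerate_universes(catalog: Catalog) -> list[UniverseSpec]:
    """Cartesian product of the catalog's levels, in deterministic order
    (cleaning, filter, outlier, model), with redundant duplicates collapsed.

    A ``none``-scope outlier rule ignores its SD criterion, so multiple
    ``none`` entries (e.g. one per k) would denote the same universe; they
    are collapsed to a single level.
    """
    if not catalog.cleaning_configs:
        raise ValueError("catalog has no cleaning configurations")
    if not catalog.filter_levels:
        raise ValueError("catalog has no trial-filter levels")
    if not catalog.outlier_rules:
        raise ValueError("catalog has no outlier rules")
    if not catalog.model_families:
        raise ValueError("catalog has no model families")
    seen, rules = set(), []
    for rule in catalog.outlier_rules:
        key = rule.label
        if key not in seen:
            seen.add(key)
            rules.append(rule)
    return [
        UniverseSpec(
            cleaning_id=c.config_id,
            min_fixations=f,
            outlier=r,
            model=ModelSpec(m, catalog.significance_alpha),
        )
        for c, f, r, m in itertools.product(
            catalog.cleaning_configs, catalog.filter_levels, rules,
            catalog.model_families,
        )
    ]


def count_total_models(n_universes: int, n_permutations: int) -> int:
    """Total mixed-model fits: each universe once on the empirical data and
    once per label-shuffled replicate."""
    return n_universes * (1 + n_permutations)


def observation_fingerprint(obs: pd.DataFrame) -> str:
    """Digest of an observation table; equal iff the tables are identical."""
    canon = obs.sort_values(["subject_id", "item_id"], kind="mergesort")
    payload = "\n".join(
        f"{r.subject_id}\t{r.item_id}\t{r.condition}\t{r.sfd_ms:.6f}"
        for r in canon.itertuples(index=False)
    )
    return hashlib.sha256(payload.encode()).hexdigest()


# --------------------------------------------------------------------------
# pipeline execution with shared-prefix caching


class PipelineCache:
    """Memoizes the label-independent pipeline stages of one trial set."""

    def __init__(self, ts: TrialSet, cleaning_map: dict[str, CleaningConfig]):
        if ts.items is None or "target_ia_index" not in ts.items.columns:
            raise ValueError("trial set needs an items table with target_ia_index")
        self.ts = ts
        self.cleaning_map = cleaning_map
        self._cleaned: dict[str, TrialSet] = {}
        self._obs: dict[tuple[str, int], pd.DataFrame] = {}

    def cleaned(self, cleaning_id: str) -> TrialSet:
        if cleaning_id not in self._cleaned:
            config = self.cleaning_map[cleaning_id]
            self._cleaned[cleaning_id], _ = apply_cleaning(self.ts, config)
        return self._cleaned[cleaning_id]

    def observations(self, cleaning_id: str, min_fixations: int) -> pd.DataFrame:
        """SFD table (without condition labels) after cleaning + trial filter."""
        key = (cleaning_id, min_fixations)
        if key not in self._obs:
            filtered = filter_trials(self.cleaned(cleaning_id), min_fixations)
            self._obs[key] = extract_sfd(
                filtered, targets=self.ts.items, with_condition=False
            )
        return self._obs[key]


def _attach_condition(obs: pd.DataFrame, items: pd.DataFrame) -> pd.DataFrame:
    cond = items.set_index("item_id")["condition"]
    out = obs.copy()
    out["condition"] = out["item_id"].map(cond)
    return out[["subject_id", "item_id", "condition", "sfd_ms"]]


def _nonconverged_result(spec: UniverseSpec, n_obs: int) -> ModelResult:
    nan = float("nan")
    return ModelResult(
        family=spec.model.family, beta_freq=nan, se_beta=nan, stat=nan,
        p_value=nan, significant=False, converged=False, n_obs=n_obs,
        intercept=nan, effect_ms=None,
    )


def _safe_fit(obs: pd.DataFrame, spec: UniverseSpec) -> ModelResult:
    try:
        return fit_model(obs, spec.model)
    except Exception:
        return _nonconverged_result(spec, len(obs))


def run_universe(
    ts: TrialSet,
    spec: UniverseSpec,
    cleaning_map: dict[str, CleaningConfig] | None = None,
    baseline_n_obs: int | None = None,
) -> UniverseResult:
    """Execute one universe's full pipeline on a trial set.

    ``baseline_n_obs`` is the observation count of the no-cleaning /
    no-filter / no-outlier baseline; computed from ``ts`` when omitted.
    Model errors are captured as non-converged results, never raised.
    """
    if cleaning_map is None:
        cleaning_map = {c.config_id: c for c in build_catalog()}
    if baseline_n_obs is None:
        baseline_n_obs = len(extract_sfd(ts))
    cleaned, _ = apply_cleaning(ts, cleaning_map[spec.cleaning_id])
    filtered = filter_trials(cleaned, spec.min_fixations)
    obs = extract_sfd(filtered, targets=ts.items)
    obs = remove_outliers(obs, spec.outlier)
    fingerprint = observation_fingerprint(obs)
    result = _safe_fit(obs, spec)
    return UniverseResult(
        spec=spec,
        model_result=result,
        n_obs_removed_vs_baseline=baseline_n_obs - len(obs),
        dataset_fingerprint=fingerprint,
    )


def _curve_order(results: list[UniverseResult]) -> list[UniverseResult]:
    def key(pair):
        idx, r = pair
        eff = r.model_result.effect_ms
        missing = eff is None or not np.isfinite(eff)
        return (missing, eff if not missing else 0.0, idx)

    return [r for _, r in sorted(enumerate(results), key=key)]


def _build_dashboard(results: list[UniverseResult]) -> pd.DataFrame:
    levels: list[tuple[str, str]] = []
    for attr, values in (
        ("cleaning", sorted({r.spec.cleaning_id for r in results})),
        ("min_fixations", sorted({r.spec.min_fixations for r in results})),
        ("outlier", sorted({r.spec.outlier.label for r in results})),
        ("model", sorted({r.spec.model.family for r in results})),
    ):
        levels.extend((attr, str(v)) for v in values)
    mat = np.zeros((len(levels), len(results)), dtype=int)
    index = {lv: i for i, lv in enumerate(levels)}
    for j, r in enumerate(results):
        mat[index[("cleaning", r.spec.cleaning_id)], j] = 1
        mat[index[("min_fixations", str(r.spec.min_fixations))], j] = 1
        mat[index[("outlier", r.spec.outlier.label)], j] = 1
        mat[index[("model", r.spec.model.family)], j] = 1
    return pd.DataFrame(
        mat,
        index=pd.MultiIndex.from_tuples(levels, names=["decision", "level"]),
        columns=[f"u{j + 1}" for j in range(len(results))],
    )


def run_multiverse(
    ts: TrialSet,
    specs: list[UniverseSpec],
    cleaning_configs: list[CleaningConfig] | None = None,
    n_jobs: int = 1,
    cache: PipelineCache | None = None,
    items_override: pd.DataFrame | None = None,
) -> MultiverseResult:
    """Execute every universe and assemble the specification curve.

    The result is identical for any ``n_jobs``: the data pipeline is
    memoized on shared prefixes and model fits are reassembled in spec
    order. ``items_override`` substitutes an item table with different
    condition labels (used by the permutation test) without invalidating
    the label-independent caches.
    """
    if not specs:
        raise ValueError("no universes to run")
    cleaning_map = {
        c.config_id: c for c in (cleaning_configs or build_catalog())
    }
    if cache is None:
        cache = PipelineCache(ts, cleaning_map)
    items = items_override if items_override is not None else ts.items

    baseline_raw = extract_sfd(ts, targets=ts.items, with_condition=False)
    baseline_n_obs = len(baseline_raw)

    # one observation table per (cleaning, filter, outlier) prefix
    tables: dict[tuple, tuple[pd.DataFrame, str]] = {}
    for spec in specs:
        key = (spec.cleaning_id, spec.min_fixations, spec.outlier.label)
        if key not in tables:
            obs = _attach_condition(
                cache.observations(spec.cleaning_id, spec.min_fixations), items
            )
            obs = remove_outliers(obs, spec.outlier)
            tables[key] = (obs, observation_fingerprint(obs))

    def task(spec):
        obs, _ = tables[(spec.cleaning_id, spec.min_fixations, spec.outlier.label)]
        return _safe_fit(obs, spec)

    if n_jobs == 1:
        fits = [task(spec) for spec in specs]
    else:
        fits = Parallel(n_jobs=n_jobs, backend="threading")(
            delayed(task)(spec) for spec in specs
        )

    results = []
    for spec, fit in zip(specs, fits):
        obs, fingerprint = tables[
            (spec.cleaning_id, spec.min_fixations, spec.outlier.label)
        ]
        results.append(
            UniverseResult(
                spec=spec,
                model_result=fit,
                n_obs_removed_vs_baseline=baseline_n_obs - len(obs),
                dataset_fingerprint=fingerprint,
            )
        )
    ordered = _curve_order(results)
    n_sig = sum(r.model_result.significant for r in ordered)
    n_nc = sum(not r.model_result.converged for r in ordered)
    return MultiverseResult(
        universes=ordered,
        n_significant=n_sig,
        n_nonconverged=n_nc,
        dashboard=_build_dashboard(ordered),
    )


# --------------------------------------------------------------------------
# permutation inference


def permute_labels(ts: TrialSet, rng: np.random.Generator) -> TrialSet:
    """Shuffle the item -> condition map uniformly at random.

    Labels are permuted as a block across items, preserving the condition
    balance; every fixation row inherits its item's new label.
    """
    if ts.items is None:
        raise ValueError("trial set has no items table to permute")
    items = permute_item_labels(ts.items, rng)
    cond = items.set_index("item_id")["condition"]
    fx = ts.fixations.copy()
    fx["condition"] = fx["item_id"].map(cond)
    return TrialSet(fixations=fx, items=items, geometry=ts.geometry)


def permute_item_labels(
    items: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    out = items.copy()
    labels = out["condition"].to_numpy()
    out["condition"] = labels[rng.permutation(len(labels))]
    return out


def paper_style_p_bound(n_perm: int) -> float:
    """The p-value bound quoted when no shuffled multiverse reaches the
    empirical significant-universe count: ``1 / n_perm``."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return 1.0 / n_perm


def permutation_test(
    ts: TrialSet,
    specs: list[UniverseSpec],
    cleaning_configs: list[CleaningConfig] | None = None,
    n_perm: int = 500,
    seed: int = 0,
    n_jobs: int = 1,
) -> tuple[MultiverseResult, PermutationResult]:
    """Label-permutation test of the multiverse's significant-universe count.

    Runs the empirical multiverse, then ``n_perm`` multiverses on trial sets
    whose item condition labels were shuffled. Reports the add-one estimate
    ``p = (1 + #{null >= empirical}) / (1 + n_perm)`` plus the paper-style
    bound ``1/n_perm`` (flagged as holding when no null count reaches the
    empirical count).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cleaning_map_list = cleaning_configs or build_catalog()
    cleaning_map = {c.config_id: c for c in cleaning_map_list}
    cache = PipelineCache(ts, cleaning_map)
    empirical = run_multiverse(
        ts, specs, cleaning_configs=cleaning_map_list, n_jobs=n_jobs, cache=cache
    )
    rng = np.random.default_rng(seed)
    null_counts = []
    for _ in range(n_perm):
        items_b = permute_item_labels(ts.items, rng)
        mv_b = run_multiverse(
            ts,
            specs,
            cleaning_configs=cleaning_map_list,
            n_jobs=n_jobs,
            cache=cache,
            items_override=items_b,
        )
        null_counts.append(mv_b.n_significant)
    exceed = sum(c >= empirical.n_significant for c in null_counts)
    perm_result = PermutationResult(
        empirical_count=empirical.n_significant,
        null_counts=null_counts,
        p_add_one=(1 + exceed) / (1 + n_perm),
        p_bound=paper_style_p_bound(n_perm),
        bound_holds=(exceed == 0),
        n_perm=n_perm,
        seed=seed,
    )
    return empirical, perm_result
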