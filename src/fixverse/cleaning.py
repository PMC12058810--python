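"""The four-stage fixation cleaning function, fully parameterized.

Stage 1 merges fixations shorter than 80 ms into a strictly longer fixation
within 0.5 deg; stage 2 does the same at 40 ms / 1.25 deg; stage 3 collapses
runs of >= 3 consecutive sub-140 ms fixations sharing one interest area into
a single fixation; stage 4 removes fixations shorter than 140 ms or longer
than 800 ms (strict inequalities throughout). An optional final step deletes
fixations outside every interest area (off by default). Each threshold and
enable flag is a parameter, so a catalog of variant configurations can be
enumerated (:func:`build_catalog`).

Merging conventions (documented, covered by tests):

* candidates are the *temporally adjacent* neighbors only;
* tie-break when both neighbors are eligible: nearer wins, then longer,
  then the preceding one;
* the host keeps its position and interest area and gains the absorbed
  duration (stages 1-2); stage-3 runs, having no host, get the summed
  duration at the duration-weighted centroid, placed at the run's start;
* a short fixation with no eligible neighbor is left in place — removal is
  stage 4's job.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fixverse.io import Geometry, TrialSet
from fixverse.synthetic import Trial


@dataclass(frozen=True)
class MergeStage:
    enabled: bool = True
    max_dur_ms: float = 80.0
    max_dist_deg: float = 0.5

    def __post_init__(self):
        if self.max_dur_ms <= 0 or self.max_dist_deg <= 0:
            raise ValueError("merge-stage thresholds must be > 0")


@dataclass(frozen=True)
class RunMergeStage:
    enabled: bool = True
    max_dur_ms: float = 140.0

    def __post_init__(self):
        if self.max_dur_ms <= 0:
            raise ValueError("stage-3 threshold must be > 0")


@dataclass(frozen=True)
class TemporalStage:
    enabled: bool = True
    min_dur_ms: float = 140.0
    max_dur_ms: float = 800.0

    def __post_init__(self):
        if self.min_dur_ms <= 0:
            raise ValueError("stage-4 min must be > 0")
        if self.min_dur_ms >= self.max_dur_ms:
            raise ValueError("stage-4 min must be < max")


@dataclass(frozen=True)
class CleaningConfig:
    """One cleaning-function configuration (one catalog row)."""

    config_id: str = "standard"
    stage1: MergeStage = field(default_factory=lambda: MergeStage(True, 80.0, 0.5))
    stage2: MergeStage = field(default_factory=lambda: MergeStage(True, 40.0, 1.25))
    stage3: RunMergeStage = field(default_factory=RunMergeStage)
    stage4: TemporalStage = field(default_factory=TemporalStage)
    delete_outside_ia: bool = False


@dataclass
class CleaningStats:
    n_fixations_before: int = 0
    n_fixations_after: int = 0
    merges_stage1: int = 0
    merges_stage2: int = 0
    runs_merged_stage3: int = 0
    removed_stage4: int = 0
    removed_outside_ia: int = 0
    n_observations_removed_vs_baseline: int | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_catalog() -> list[CleaningConfig]:
    """The 14-entry cleaning-configuration catalog.

    A standard all-defaults configuration, an all-off ("no cleaning")
    configuration, each stage switched off individually, variations of each
    stage's thresholds, and the outside-interest-area deletion switched on.
    """
    std = CleaningConfig()
    off = MergeStage(enabled=False)

    def cfg(config_id, **kw):
        return dataclasses.replace(std, config_id=config_id, **kw)

    return [
        std,
        cfg(
            "no_cleaning",
            stage1=off,
            stage2=MergeStage(False, 40.0, 1.25),
            stage3=RunMergeStage(enabled=False),
            stage4=TemporalStage(enabled=False),
        ),
        cfg("stage1_off", stage1=off),
        cfg("stage2_off", stage2=MergeStage(False, 40.0, 1.25)),
        cfg("stage3_off", stage3=RunMergeStage(enabled=False)),
        cfg("stage4_off", stage4=TemporalStage(enabled=False)),
        cfg("stage1_dur60", stage1=MergeStage(True, 60.0, 0.5)),
        cfg("stage1_dist1deg", stage1=MergeStage(True, 80.0, 1.0)),
        cfg("stage2_dur60", stage2=MergeStage(True, 60.0, 1.25)),
        cfg("stage2_dist2deg", stage2=MergeStage(True, 40.0, 2.0)),
        cfg("stage3_dur100", stage3=RunMergeStage(True, 100.0)),
        cfg("stage4_min80_max800", stage4=TemporalStage(True, 80.0, 800.0)),
        cfg("stage4_min140_max600", stage4=TemporalStage(True, 140.0, 600.0)),
        cfg("delete_outside_ia", delete_outside_ia=True),
    ]


def catalog_by_id(catalog: list[CleaningConfig] | None = None) -> dict[str, CleaningConfig]:
    return {c.config_id: c for c in (catalog if catalog is not None else build_catalog())}


# --------------------------------------------------------------------------
# per-trial stage engines


def merge_pass(
    trial: Trial, max_dur_ms: float, max_dist_deg: float, geometry: Geometry
) -> tuple[Trial, int]:
    """Shared engine for stages 1 and 2.

    Scans left to right, repeatedly, until a full pass makes no change: each
    fixation shorter than ``max_dur_ms`` whose temporally adjacent
    neighbor(s) are strictly longer and lie within ``max_dist_deg``
    (Euclidean) is absorbed into the chosen neighbor. Returns the trial and
    the number of merges performed.
    """
    if len(trial) == 0:
        return trial, 0
    max_dist_px = geometry.deg_to_px(max_dist_deg)
    x = list(trial.x)
    y = list(trial.y)
    dur = list(trial.dur)
    ia = list(trial.ia)
    n_merges = 0
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(dur):
            if dur[i] >= max_dur_ms:
                i += 1
                continue
            host = _choose_host(x, y, dur, i, max_dist_px)
            if host is None:
                i += 1
                continue
            dur[host] += dur[i]
            for arr in (x, y, dur, ia):
                del arr[i]
            n_merges += 1
            changed = True
            # stay at i: the next fixation shifted into this slot
    return (
        Trial(np.asarray(x), np.asarray(y), np.asarray(dur), np.asarray(ia)),
        n_merges,
    )


def _choose_host(x, y, dur, i, max_dist_px):
    """Eligible neighbor of fixation i; tie-break nearer > longer > preceding."""
    cands = []
    for j in (i - 1, i + 1):
        if 0 <= j < len(dur) and dur[j] > dur[i]:
            d = float(np.hypot(x[j] - x[i], y[j] - y[i]))
            if d <= max_dist_px:
                cands.append((d, -dur[j], 0 if j < i else 1, j))
    if not cands:
        return None
    return min(cands)[3]


def merge_ia_runs(trial: Trial, max_dur_ms: float) -> tuple[Trial, int]:
    """Stage 3: collapse maximal runs of >= 3 consecutive short fixations
    sharing one (non-missing) interest area into a single fixation.

    The merged fixation carries the summed duration, the duration-weighted
    mean position, and the shared interest area, at the run's first slot.
    """
    n = len(trial)
    if n == 0:
        return trial, 0
    x, y, dur, ia = trial.x, trial.y, trial.dur, trial.ia
    out_x, out_y, out_dur, out_ia = [], [], [], []
    n_runs = 0
    i = 0
    while i < n:
        j = i
        if not np.isnan(ia[i]) and dur[i] < max_dur_ms:
            while (
                j + 1 < n
                and not np.isnan(ia[j + 1])
                and ia[j + 1] == ia[i]
                and dur[j + 1] < max_dur_ms
            ):
                j += 1
        if j - i + 1 >= 3:
            w = dur[i : j + 1]
            total = float(w.sum())
            out_x.append(float(np.dot(w, x[i : j + 1]) / total))
            out_y.append(float(np.dot(w, y[i : j + 1]) / total))
            out_dur.append(total)
            out_ia.append(ia[i])
            n_runs += 1
            i = j + 1
        else:
            out_x.append(x[i])
            out_y.append(y[i])
            out_dur.append(dur[i])
            out_ia.append(ia[i])
            i += 1
    return (
        Trial(np.asarray(out_x), np.asarray(out_y), np.asarray(out_dur),
              np.asarray(out_ia)),
        n_runs,
    )


def temporal_filter(
    trial: Trial, min_dur_ms: float, max_dur_ms: float
) -> tuple[Trial, int]:
    """Stage 4: drop fixations with duration < min or > max (boundaries kept)."""
    keep = (trial.dur >= min_dur_ms) & (trial.dur <= max_dur_ms)
    removed = int((~keep).sum())
    return Trial(trial.x[keep], trial.y[keep], trial.dur[keep], trial.ia[keep]), removed


def delete_outside_ia(trial: Trial) -> tuple[Trial, int]:
    keep = ~np.isnan(trial.ia)
    removed = int((~keep).sum())
    return Trial(trial.x[keep], trial.y[keep], trial.dur[keep], trial.ia[keep]), removed


def clean_trial(
    trial: Trial, config: CleaningConfig, geometry: Geometry,
    stats: CleaningStats | None = None,
) -> Trial:
    """Apply the enabled stages, in fixed order 1 -> 2 -> 3 -> 4 -> outside-IA."""
    if config.stage1.enabled:
        trial, k = merge_pass(
            trial, config.stage1.max_dur_ms, config.stage1.max_dist_deg, geometry
        )
        if stats:
            stats.merges_stage1 += k
    if config.stage2.enabled:
        trial, k = merge_pass(
            trial, config.stage2.max_dur_ms, config.stage2.max_dist_deg, geometry
        )
        if stats:
            stats.merges_stage2 += k
    if config.stage3.enabled:
        trial, k = merge_ia_runs(trial, config.stage3.max_dur_ms)
        if stats:
            stats.runs_merged_stage3 += k
    if config.stage4.enabled:
        trial, k = temporal_filter(
            trial, config.stage4.min_dur_ms, config.stage4.max_dur_ms
        )
        if stats:
            stats.removed_stage4 += k
    if config.delete_outside_ia:
        trial, k = delete_outside_ia(trial)
        if stats:
            stats.removed_outside_ia += k
    return trial


# --------------------------------------------------------------------------
# trial-set level


def _iter_trials(fx: pd.DataFrame):
    """Yield (key_rows, Trial) per (subject, trial), preserving order."""
    x = fx["x_px"].to_numpy()
    y = fx["y_px"].to_numpy()
    dur = fx["duration_ms"].to_numpy()
    ia = fx["ia_index"].to_numpy(dtype=float, na_value=np.nan)
    keys = (fx["subject_id"].astype(str) + "\x00" + fx["trial_id"].astype(str)).to_numpy()
    bounds = np.flatnonzero(np.r_[True, keys[1:] != keys[:-1], True])
    for s, e in zip(bounds[:-1], bounds[1:]):
        yield s, Trial(x[s:e], y[s:e], dur[s:e], ia[s:e])


def apply_cleaning(
    ts: TrialSet, config: CleaningConfig
) -> tuple[TrialSet, CleaningStats]:
    """Clean every trial of a trial set; returns the cleaned set and tallies.

    With all stages disabled the output equals the input (the "no cleaning"
    dataset) and all stage counters are zero.
    """
    fx = ts.fixations
    stats = CleaningStats(n_fixations_before=len(fx))
    if fx.empty:
        stats.n_fixations_after = 0
        return ts.copy(), stats

    meta_cols = ["subject_id", "trial_id", "item_id", "condition"]
    rows_meta, out = [], {"x": [], "y": [], "dur": [], "ia": [], "fix_index": []}
    meta = fx[meta_cols]
    for start, trial in _iter_trials(fx):
        cleaned = clean_trial(trial, config, ts.geometry, stats)
        k = len(cleaned)
        if k == 0:
            continue
        rows_meta.append((start, k))
        out["x"].append(cleaned.x)
        out["y"].append(cleaned.y)
        out["dur"].append(cleaned.dur)
        out["ia"].append(cleaned.ia)
        out["fix_index"].append(np.arange(1, k + 1))

    if not rows_meta:
        cleaned_fx = fx.iloc[0:0].copy()
    else:
        rep = np.repeat(
            [s for s, _ in rows_meta], [k for _, k in rows_meta]
        )
        meta_rep = meta.iloc[rep].reset_index(drop=True)
        ia_vals = np.concatenate(out["ia"])
        cleaned_fx = meta_rep.assign(
            fix_index=np.concatenate(out["fix_index"]).astype(int),
            x_px=np.concatenate(out["x"]),
            y_px=np.concatenate(out["y"]),
            duration_ms=np.concatenate(out["dur"]),
            ia_index=pd.array(
                [None if np.isnan(v) else int(v) for v in ia_vals], dtype="Int64"
            ),
        )[fx.columns.tolist()]
    stats.n_fixations_after = len(cleaned_fx)
    return TrialSet(fixations=cleaned_fx, items=ts.items, geometry=ts.geometry), stats


def datasets_identical(a: TrialSet, b: TrialSet) -> bool:
    """True iff every trial has the same fixation sequence (position,
    duration, interest area) in both trial sets."""
    fa = a.fixations.sort_values(
        ["subject_id", "trial_id", "fix_index"], kind="mergesort"
    ).reset_index(drop=True)
    fb = b.fixations.sort_values(
        ["subject_id", "trial_id", "fix_index"], kind="mergesort"
    ).reset_index(drop=True)
    if len(fa) != len(fb):
        return False
    cols = ["subject_id", "trial_id", "fix_index", "x_px", "y_px",
            "duration_ms", "ia_index"]
    return fa[cols].equals(fb[cols])
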