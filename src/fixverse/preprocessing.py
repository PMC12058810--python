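"""Trial filtering, single-fixation-duration extraction, outlier trimming.

Pipeline order is fixed: cleaning -> trial filter -> SFD extraction ->
outlier removal (cleaning proceeds from the lowest level of the data to the
highest).

The single fixation duration (SFD) of a trial's target word is defined via
first pass: the maximal run of consecutive fixations inside the target
interest area, starting at the first entry into it and ending at the first
fixation elsewhere. An observation is emitted iff that run has length
exactly one. Rereading after leaving the target does not retroactively
disqualify an SFD.

Outlier trimming operates on the SFD observation table: an observation is
removed iff ``|sfd - m| > k * s`` where ``(m, s)`` are the mean and sample
SD (n-1 denominator) of the reference cell implied by the rule's scope —
all observations (``grand``), the subject's observations (``subject``), or
the subject-by-condition cell (``subject_condition``). Trimming is one-shot
(reference statistics computed once, no iteration); cells with fewer than
two observations or zero SD pass through untrimmed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fixverse.io import TrialSet

OBSERVATION_COLUMNS = ["subject_id", "item_id", "condition", "sfd_ms"]

OUTLIER_SCOPES = ("none", "grand", "subject", "subject_condition")


@dataclass(frozen=True)
class OutlierRule:
    scope: str = "none"
    k_sd: float = float("nan")

    def __post_init__(self):
        if self.scope not in OUTLIER_SCOPES:
            raise ValueError(f"unknown outlier scope {self.scope!r}")
        if self.scope != "none" and not self.k_sd > 0:
            raise ValueError("k_sd must be > 0 for a non-none scope")

    @property
    def label(self) -> str:
        if self.scope == "none":
            return "none"
        return f"{self.scope}_{self.k_sd:g}sd"


def filter_trials(ts: TrialSet, min_fixations: int) -> TrialSet:
    """Drop trials whose fixation count is <= ``min_fixations``.

    A threshold of 3 keeps only trials with *more than* 3 fixations,
    matching the "> 3 fixations" inclusion rule; 0 keeps everything.
    """
    if min_fixations < 0:
        raise ValueError("min_fixations must be >= 0")
    fx = ts.fixations
    if fx.empty or min_fixations == 0:
        return ts.copy()
    counts = fx.groupby(["subject_id", "trial_id"], sort=False)["fix_index"].transform(
        "size"
    )
    return TrialSet(
        fixations=fx[counts > min_fixations].reset_index(drop=True),
        items=ts.items,
        geometry=ts.geometry,
    )


def extract_sfd(
    ts: TrialSet, targets: pd.DataFrame | None = None, with_condition: bool = True
) -> pd.DataFrame:
    """Emit at most one SFD observation per trial (see module docstring).

    ``targets`` maps ``item_id`` to ``target_ia_index``; defaults to
    ``ts.items``. With ``with_condition=False`` the condition column is
    omitted (useful when labels are attached later, e.g. after permutation).
    """
    if targets is None:
        targets = ts.items
    if targets is None or "target_ia_index" not in targets.columns:
        raise ValueError("no target_ia_index available for SFD extraction")
    target_map = dict(
        zip(targets["item_id"].astype(int), targets["target_ia_index"].astype(int))
    )
    fx = ts.fixations
    subjects, item_ids, conds, sfds = [], [], [], []
    if not fx.empty:
        ia = fx["ia_index"].to_numpy(dtype=float, na_value=np.nan)
        dur = fx["duration_ms"].to_numpy()
        keys = (
            fx["subject_id"].astype(str) + "\x00" + fx["trial_id"].astype(str)
        ).to_numpy()
        bounds = np.flatnonzero(np.r_[True, keys[1:] != keys[:-1], True])
        subj_col = fx["subject_id"].to_numpy()
        item_col = fx["item_id"].to_numpy()
        cond_col = fx["condition"].to_numpy()
        for s, e in zip(bounds[:-1], bounds[1:]):
            item = int(item_col[s])
            try:
                target = target_map[item]
            except KeyError:
                raise ValueError(f"item {item} has no target_ia_index") from None
            seg = ia[s:e]
            on_target = np.flatnonzero(seg == target)
            if on_target.size == 0:
                continue
            first = on_target[0]
            run_len = 1
            while first + run_len < len(seg) and seg[first + run_len] == target:
                run_len += 1
            if run_len != 1:
                continue
            subjects.append(subj_col[s])
            item_ids.append(item)
            conds.append(cond_col[s])
            sfds.append(dur[s + first])
    obs = pd.DataFrame(
        {
            "subject_id": np.asarray(subjects, dtype=object),
            "item_id": np.asarray(item_ids, dtype=int),
            "condition": np.asarray(conds, dtype=object),
            "sfd_ms": np.asarray(sfds, dtype=float),
        }
    )
    if not with_condition:
        obs = obs.drop(columns=["condition"])
    return obs


def remove_outliers(obs: pd.DataFrame, rule: OutlierRule) -> pd.DataFrame:
    """Trim observations outside ``mean +/- k_sd * SD`` of their reference cell."""
    if rule.scope == "none" or obs.empty:
        return obs.copy()
    if rule.scope == "grand":
        group_cols = None
    elif rule.scope == "subject":
        group_cols = ["subject_id"]
    else:
        group_cols = ["subject_id", "condition"]
    v = obs["sfd_ms"]
    if group_cols is None:
        m, s = v.mean(), v.std(ddof=1)
        if len(obs) < 2 or not s > 0:
            return obs.copy()
        keep = (v - m).abs() <= rule.k_sd * s
    else:
        g = obs.groupby(group_cols, sort=False)["sfd_ms"]
        m = g.transform("mean")
        s = g.transform("std")
        n = g.transform("size")
        keep = ((v - m).abs() <= rule.k_sd * s) | (n < 2) | ~(s > 0)
    return obs[keep].reset_index(drop=True)
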