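"""Specification-curve tables, dashboards, removal-vs-effect panels, plots.

All quantities are computed into plain tables; the plotting layer only
renders tables and never computes anything new.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from fixverse.multiverse import MultiverseResult


def specification_curve_table(mv: MultiverseResult) -> pd.DataFrame:
    """Universes sorted ascending by effect size with a significance class.

    Classes: ``significant``, ``nonsignificant``, ``nonconverged`` (whose
    effect slot is empty). Ties are broken by spec order (already encoded in
    the multiverse's universe ordering).
    """
    if not mv.universes:
        raise ValueError("empty multiverse")
    rows = []
    for rank, u in enumerate(mv.universes, start=1):
        m = u.model_result
        if not m.converged:
            cls, eff = "nonconverged", np.nan
        elif m.significant:
            cls, eff = "significant", m.effect_ms
        else:
            cls, eff = "nonsignificant", m.effect_ms
        rows.append(
            {
                "rank": rank,
                "universe": u.spec.label,
                "effect_ms": eff,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


def dashboard_table(mv: MultiverseResult) -> pd.DataFrame:
    """Binary matrix: one row per (decision point, level), one column per
    universe in curve order; 1 iff the universe uses that level."""
    if not mv.universes:
        raise ValueError("empty multiverse")
    return mv.dashboard.copy()


def removal_vs_effect_table(mv: MultiverseResult) -> pd.DataFrame:
    """Per (cleaning config, model family): the (observations removed,
    effect) points of each universe plus a least-squares slope per panel
    (orientation only)."""
    pts = []
    for u in mv.universes:
        m = u.model_result
        if not m.converged:
            continue
        pts.append(
            {
                "cleaning_id": u.spec.cleaning_id,
                "family": u.spec.model.family,
                "n_obs_removed": u.n_obs_removed_vs_baseline,
                "effect_ms": m.effect_ms,
            }
        )
    df = pd.DataFrame(pts)
    if df.empty:
        return df.assign(slope=pd.Series(dtype=float))
    slopes = {}
    for key, grp in df.groupby(["cleaning_id", "family"]):
        x = grp["n_obs_removed"].to_numpy(dtype=float)
        y = grp["effect_ms"].to_numpy(dtype=float)
        if len(grp) >= 2 and np.ptp(x) > 0:
            slopes[key] = float(np.polyfit(x, y, 1)[0])
        else:
            slopes[key] = np.nan
    df["slope"] = [slopes[(c, f)] for c, f in zip(df["cleaning_id"], df["family"])]
    return df


def relative_spread_pct(min_effect_ms: float, max_effect_ms: float) -> float:
    """Share of the maximal effect attributable to pipeline choice:
    ``(max - min) / max * 100``."""
    if max_effect_ms == 0:
        raise ValueError("max effect must be nonzero")
    return (max_effect_ms - min_effect_ms) / max_effect_ms * 100.0


# --------------------------------------------------------------------------
# plots (render tables only)


def plot_specification_curve(curve: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "significant": "#1f77b4",
        "nonsignificant": "#d62728",
        "nonconverged": "#7f7f7f",
    }
    fig, ax = plt.subplots(figsize=(9, 3.5))
    for cls, grp in curve.groupby("class"):
        ax.scatter(grp["rank"], grp["effect_ms"], s=8, label=cls,
                   color=colors.get(cls, "black"))
    ax.set_xlabel("universe (ordered by effect size)")
    ax.set_ylabel("frequency effect (ms)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dashboard(dashboard: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(9, 0.25 * len(dashboard) + 1.0)
    )
    ax.imshow(dashboard.to_numpy(), aspect="auto", cmap="Greys",
              interpolation="nearest")
    ax.set_yticks(range(len(dashboard)))
    ax.set_yticklabels(
        [f"{d}: {l}" for d, l in dashboard.index], fontsize=6
    )
    ax.set_xlabel("universe (curve order)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_removal_vs_effect(table: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cleanings = sorted(table["cleaning_id"].unique())
    families = sorted(table["family"].unique())
    nrows, ncols = len(cleanings), max(len(families), 1)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3 * ncols, 2 * nrows), squeeze=False
    )
    for i, c in enumerate(cleanings):
        for j, f in enumerate(families):
            ax = axes[i][j]
            grp = table[(table["cleaning_id"] == c) & (table["family"] == f)]
            ax.scatter(grp["n_obs_removed"], grp["effect_ms"], s=6)
            if len(grp) >= 2:
                x = grp["n_obs_removed"].to_numpy(dtype=float)
                slope = grp["slope"].iloc[0]
                if np.isfinite(slope) and np.ptp(x) > 0:
                    y0 = grp["effect_ms"].mean() + slope * (x - x.mean())
                    ax.plot(x, y0, lw=0.8, color="gray")
            ax.set_title(f"{c} / {f}", fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
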