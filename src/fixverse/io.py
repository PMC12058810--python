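"""Fixation-report and interest-area table I/O.

The on-disk dialect is tab-delimited UTF-8 text with a ``.`` decimal
separator. Two tables are used throughout:

Fixation report (one row per fixation)::

    subject_id  trial_id  item_id  condition  fix_index  x_px  y_px  duration_ms  ia_index

Interest-area table (one row per word box, half-open ``[min, max)`` bounds)::

    item_id  ia_index  x_min_px  x_max_px  y_min_px  y_max_px

``ia_index`` is 1-based; a fixation outside every box carries an empty
``ia_index`` field (never 0). Rows are ordered by (subject, trial,
fix_index) and floats are serialized at fixed precision, so equal trial
sets produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FIXATION_COLUMNS = [
    "subject_id",
    "trial_id",
    "item_id",
    "condition",
    "fix_index",
    "x_px",
    "y_px",
    "duration_ms",
    "ia_index",
]

IA_COLUMNS = ["item_id", "ia_index", "x_min_px", "x_max_px", "y_min_px", "y_max_px"]

#: Common EyeLink Data Viewer fixation-report column names mapped onto the
#: canonical schema (used when ``dialect="permissive"``).
COLUMN_ALIASES = {
    "RECORDING_SESSION_LABEL": "subject_id",
    "TRIAL_INDEX": "trial_id",
    "CURRENT_FIX_X": "x_px",
    "CURRENT_FIX_Y": "y_px",
    "CURRENT_FIX_DURATION": "duration_ms",
    "CURRENT_FIX_INDEX": "fix_index",
    "CURRENT_FIX_INTEREST_AREA_INDEX": "ia_index",
}

CONDITIONS = ("high", "low")


class SchemaError(ValueError):
    """A required column is missing or a field cannot be parsed."""


class IntegrityError(ValueError):
    """Structurally invalid data (duplicates, overlaps, dangling references)."""


@dataclass(frozen=True)
class Geometry:
    """Screen geometry used to convert degree thresholds to pixels."""

    pixels_per_degree: float = 40.0
    screen_width_px: float = 1920.0
    screen_height_px: float = 1080.0

    def deg_to_px(self, deg: float) -> float:
        return deg * self.pixels_per_degree


@dataclass
class TrialSet:
    """A fixation table plus item metadata and screen geometry.

    ``fixations`` holds one row per fixation with the canonical columns;
    ``items`` (optional) holds one row per stimulus item, at minimum
    ``item_id``/``condition`` and, when produced by the generator,
    ``target_ia_index`` and the stimulus statistics.
    """

    fixations: pd.DataFrame
    items: pd.DataFrame | None = None
    geometry: Geometry = field(default_factory=Geometry)

    def n_trials(self) -> int:
        if self.fixations.empty:
            return 0
        return self.fixations.groupby(["subject_id", "trial_id"], sort=False).ngroups

    def copy(self) -> "TrialSet":
        return TrialSet(
            fixations=self.fixations.copy(),
            items=None if self.items is None else self.items.copy(),
            geometry=self.geometry,
        )


def _canonical_fixations(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["trial_id"] = df["trial_id"].astype(str)
    df["item_id"] = df["item_id"].astype(int)
    df["condition"] = df["condition"].astype(str)
    df["fix_index"] = df["fix_index"].astype(int)
    for col in ("x_px", "y_px", "duration_ms"):
        df[col] = df[col].astype(float)
    df["ia_index"] = df["ia_index"].astype("Int64")
    return df[FIXATION_COLUMNS]


def validate_trialset(ts: TrialSet) -> None:
    """Raise on schema or integrity violations; silent when valid."""
    df = ts.fixations
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"fixation table missing columns: {missing}")
    if df.empty:
        return
    if (df["duration_ms"] <= 0).any():
        bad = df.index[df["duration_ms"] <= 0][0]
        raise IntegrityError(f"non-positive duration at row {bad}")
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unknown condition labels: {sorted(bad_cond)}")
    dup = df.duplicated(subset=["subject_id", "trial_id", "fix_index"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise IntegrityError(
            "duplicate (subject, trial, fix_index): "
            f"({row['subject_id']}, {row['trial_id']}, {row['fix_index']})"
        )
    for (subj, trial), grp in df.groupby(["subject_id", "trial_id"], sort=False):
        idx = grp["fix_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise IntegrityError(
                f"fix_index not contiguous from 1 in trial ({subj}, {trial})"
            )


def read_fixation_report(
    path: str | Path,
    dialect: str = "canonical",
    renumber: bool = False,
    geometry: Geometry | None = None,
) -> TrialSet:
    """Read a fixation report TSV into a validated :class:`TrialSet`.

    Parameters
    ----------
    dialect
        ``"canonical"`` requires the documented column names;
        ``"permissive"`` additionally maps Data Viewer aliases.
    renumber
        When true, ``fix_index`` is rewritten as 1..n per trial in file
        order instead of being validated.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "permissive":
        df = df.rename(columns=COLUMN_ALIASES)
    elif dialect != "canonical":
        raise ValueError(f"unknown dialect: {dialect!r}")
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")

    def _numeric(col: str, caster):
        out = []
        for lineno, raw in enumerate(df[col].to_numpy(), start=2):
            try:
                out.append(caster(raw))
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path.name}, line {lineno}: cannot parse {col}={raw!r}"
                ) from None
        return out

    parsed = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "trial_id": df["trial_id"],
            "item_id": _numeric("item_id", int),
            "condition": df["condition"],
            "fix_index": _numeric("fix_index", int),
            "x_px": _numeric("x_px", float),
            "y_px": _numeric("y_px", float),
            "duration_ms": _numeric("duration_ms", float),
            "ia_index": pd.array(
                [int(v) if v != "" else None for v in df["ia_index"]], dtype="Int64"
            ),
        }
    )
    if renumber:
        parsed["fix_index"] = (
            parsed.groupby(["subject_id", "trial_id"], sort=False).cumcount() + 1
        )
    ts = TrialSet(
        fixations=_canonical_fixations(parsed),
        geometry=geometry or Geometry(),
    )
    validate_trialset(ts)
    return ts


_FLOAT_FMT = "{:.3f}"


def write_fixation_report(ts: TrialSet, path: str | Path) -> None:
    """Write a fixation report deterministically (byte-identical for equal sets)."""
    df = _canonical_fixations(ts.fixations) if not ts.fixations.empty else None
    path = Path(path)
    lines = ["\t".join(FIXATION_COLUMNS)]
    if df is not None:
        df = df.sort_values(
            ["subject_id", "trial_id", "fix_index"], kind="mergesort"
        )
        for row in df.itertuples(index=False):
            ia = "" if pd.isna(row.ia_index) else str(int(row.ia_index))
            lines.append(
                "\t".join(
                    [
                        row.subject_id,
                        row.trial_id,
                        str(row.item_id),
                        row.condition,
                        str(row.fix_index),
                        _FLOAT_FMT.format(row.x_px),
                        _FLOAT_FMT.format(row.y_px),
                        _FLOAT_FMT.format(row.duration_ms),
                        ia,
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_interest_areas(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in IA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    df = df[IA_COLUMNS].copy()
    df["item_id"] = df["item_id"].astype(int)
    df["ia_index"] = df["ia_index"].astype(int)
    for c in IA_COLUMNS[2:]:
        df[c] = df[c].astype(float)
    _validate_ia(df)
    return df


def write_interest_areas(ia: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    ia = ia.sort_values(["item_id", "ia_index"], kind="mergesort")
    lines = ["\t".join(IA_COLUMNS)]
    for row in ia.itertuples(index=False):
        lines.append(
            "\t".join(
                [str(int(row.item_id)), str(int(row.ia_index))]
                + [
                    _FLOAT_FMT.format(getattr(row, c))
                    for c in IA_COLUMNS[2:]
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _validate_ia(ia: pd.DataFrame) -> None:
    if (ia["x_min_px"] >= ia["x_max_px"]).any():
        raise IntegrityError("interest area with x_min >= x_max")
    for item_id, grp in ia.groupby("item_id"):
        boxes = grp[["x_min_px", "x_max_px", "y_min_px", "y_max_px"]].to_numpy()
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                overlap_x = a[0] < b[1] and b[0] < a[1]
                overlap_y = a[2] < b[3] and b[2] < a[3]
                if overlap_x and overlap_y:
                    raise IntegrityError(
                        f"overlapping interest areas in item {item_id}"
                    )


def assign_interest_areas(ts: TrialSet, ia: pd.DataFrame) -> TrialSet:
    """Set each fixation's ``ia_index`` to the unique box containing it.

    Boxes are half-open ``[min, max)`` in both axes; a point on the shared
    boundary of word *k* and word *k+1* therefore belongs to *k+1*. Fixations
    outside every box get a missing ``ia_index``. Idempotent.
    """
    _validate_ia(ia)
    fx = ts.fixations
    missing_items = set(fx["item_id"].unique()) - set(ia["item_id"].unique())
    if missing_items:
        raise IntegrityError(f"items without interest areas: {sorted(missing_items)}")
    out = fx.copy()
    assigned = np.full(len(fx), np.nan)
    x = fx["x_px"].to_numpy()
    y = fx["y_px"].to_numpy()
    item = fx["item_id"].to_numpy()
    for item_id, grp in ia.groupby("item_id"):
        sel = np.flatnonzero(item == item_id)
        if sel.size == 0:
            continue
        for row in grp.itertuples(index=False):
            inside = (
                (x[sel] >= row.x_min_px)
                & (x[sel] < row.x_max_px)
                & (y[sel] >= row.y_min_px)
                & (y[sel] < row.y_max_px)
            )
            assigned[sel[inside]] = row.ia_index
    out["ia_index"] = pd.array(
        [None if np.isnan(v) else int(v) for v in assigned], dtype="Int64"
    )
    return TrialSet(fixations=out, items=ts.items, geometry=ts.geometry)
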