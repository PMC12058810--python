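"""Synthetic sentence-reading datasets with controllable artifacts.

Generates fixation-level data with the structure the downstream analysis
assumes: 1 target word per single-line sentence in a high- vs. low-frequency
condition, ex-Gaussian single-fixation durations with crossed subject and
item random intercepts, a condition effect loading on both the mean (``mu``)
and the exponential tail (``tau``) of the target's duration distribution,
and injected artifact fixations (very short fixations near or far from a
longer host, overly long fixations, near-empty trials).

The reading model itself (skipping, regressions, landing sites) is a
deliberately simple invention: it only needs to yield realistic single
fixation availability and interest-area-resolvable positions.

Randomness is split hierarchically (stimuli / intercepts / per-subject trial
streams), so adding subjects does not reshuffle item-level draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from fixverse.io import Geometry, TrialSet

LINE_Y_PX = 300.0
LINE_HALF_HEIGHT_PX = 20.0
TEXT_X0_PX = 100.0


@dataclass(frozen=True)
class StimulusItem:
    """One sentence with a single target word."""

    item_id: int
    condition: str  # "high" | "low"
    target_ia_index: int
    word_lengths: tuple[int, ...]
    zipf_target: float

    def __post_init__(self):
        if self.condition not in ("high", "low"):
            raise ValueError(f"bad condition {self.condition!r}")
        if not 1 <= self.target_ia_index <= len(self.word_lengths):
            raise ValueError("target_ia_index out of range")

    @property
    def n_words(self) -> int:
        return len(self.word_lengths)

    @property
    def target_length(self) -> int:
        return self.word_lengths[self.target_ia_index - 1]


@dataclass(frozen=True)
class SyntheticConfig:
    n_subjects: int = 100
    n_items: int = 78
    # baseline ex-Gaussian for single fixation durations (ms)
    exgauss_mu_ms: float = 180.0
    exgauss_sigma_ms: float = 40.0
    exgauss_tau_ms: float = 60.0
    # frequency effect added to the low-frequency target's mu and tau
    effect_mu_ms: float = 10.0
    effect_tau_ms: float = 5.0
    sd_subject_ms: float = 20.0
    sd_item_ms: float = 10.0
    p_skip_base: float = 0.35
    artifact_short_rate: float = 0.0
    artifact_long_rate: float = 0.0
    sparse_trial_rate: float = 0.0
    min_duration_floor_ms: float = 21.0
    pixels_per_degree: float = 40.0
    char_width_px: float = 12.0
    # printed stimulus statistics (Zipf frequency and target word length)
    zipf_high_mean: float = 5.28
    zipf_high_sd: float = 0.36
    zipf_low_mean: float = 3.22
    zipf_low_sd: float = 0.43
    target_len_mean: float = 5.4
    target_len_sd: float = 0.87
    target_len_min: int = 4
    target_len_max: int = 9
    seed: int = 0

    def __post_init__(self):
        if self.n_items % 2 != 0:
            raise ValueError(
                "n_items must be even: conditions are counterbalanced half/half"
            )
        for name in ("sd_subject_ms", "sd_item_ms", "exgauss_tau_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.exgauss_sigma_ms <= 0:
            raise ValueError("exgauss_sigma_ms must be > 0")
        for name in ("artifact_short_rate", "artifact_long_rate",
                     "sparse_trial_rate", "p_skip_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be > 0")

    @property
    def geometry(self) -> Geometry:
        return Geometry(pixels_per_degree=self.pixels_per_degree)


@dataclass
class Trial:
    """One trial's fixation sequence as parallel arrays (ia may be NaN)."""

    x: np.ndarray
    y: np.ndarray
    dur: np.ndarray
    ia: np.ndarray

    def __len__(self) -> int:
        return len(self.dur)

    def copy(self) -> "Trial":
        return Trial(self.x.copy(), self.y.copy(), self.dur.copy(), self.ia.copy())


# --------------------------------------------------------------------------
# stimulus generation


def _calibrate_int_sample(
    draws: np.ndarray,
    mean_target: float,
    sd_target: float,
    lo: int,
    hi: int,
    max_iter: int = 4000,
) -> np.ndarray:
    """Adjust integer draws in [lo, hi] until the sample mean rounds (1 dp)
    to ``mean_target`` and the sample SD rounds (2 dp) to ``sd_target``.

    Greedy local search over single-element moves (to fix the sum) and
    mean-preserving +1/-1 pair moves (to tune the spread). Returns the best
    configuration found if the exact rounding is unreachable within budget.
    """
    x = draws.astype(int).copy()
    n = len(x)

    def mean_ok(v):
        return round(float(np.mean(v)), 1) == round(mean_target, 1)

    def sd_ok(v):
        return round(float(np.std(v, ddof=1)), 2) == round(sd_target, 2)

    # phase 1: walk the sum to round(mean_target * n)
    target_sum = int(round(mean_target * n))
    for _ in range(max_iter):
        diff = target_sum - int(x.sum())
        if diff == 0:
            break
        step = 1 if diff > 0 else -1
        # move the element whose change best helps the SD as a tiebreak
        movable = np.flatnonzero((x + step >= lo) & (x + step <= hi))
        best, best_loss = None, math.inf
        m = x.mean()
        for i in movable:
            # moving toward the mean shrinks SS, away grows it
            loss = abs(
                np.std(np.concatenate([x[:i], [x[i] + step], x[i + 1:]]), ddof=1)
                - sd_target
            )
            if loss < best_loss:
                best, best_loss = i, loss
        if best is None:
            break
        x[best] += step

    # phase 2: mean-preserving pair moves until SD rounds correctly
    for _ in range(max_iter):
        if mean_ok(x) and sd_ok(x):
            return x
        sd_now = float(np.std(x, ddof=1))
        widen = sd_now < sd_target
        order = np.argsort(x)
        moved = False
        # widen: push the largest up and the smallest down; narrow: inverse
        ups = order[::-1] if widen else order
        downs = order if widen else order[::-1]
        for i in ups:
            if x[i] + 1 > hi:
                continue
            for j in downs:
                if j == i or x[j] - 1 < lo:
                    continue
                trial = x.copy()
                trial[i] += 1
                trial[j] -= 1
                new_sd = float(np.std(trial, ddof=1))
                if abs(new_sd - sd_target) < abs(sd_now - sd_target) or (
                    mean_ok(trial) and sd_ok(trial)
                ):
                    x = trial
                    moved = True
                    break
            if moved:
                break
        if not moved:
            break
    return x


def generate_stimuli(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[StimulusItem]:
    """Create ``n_items`` counterbalanced items calibrated to the configured
    stimulus statistics.

    Exactly half the items are high frequency. Per condition, Zipf values are
    drawn then affinely recentered so the sample mean/SD (ddof=1) equal the
    configured values; target word lengths are integers whose sample mean and
    SD round to the configured values.
    """
    if config.n_items % 2 != 0:
        raise ValueError("n_items must be even (counterbalanced conditions)")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_items
    half = n // 2

    lengths_raw = np.clip(
        np.round(rng.normal(config.target_len_mean, config.target_len_sd, n)),
        config.target_len_min,
        config.target_len_max,
    )
    lengths = _calibrate_int_sample(
        lengths_raw,
        config.target_len_mean,
        config.target_len_sd,
        config.target_len_min,
        config.target_len_max,
    )

    def _zipf(mean, sd, k):
        if k < 2:
            return np.full(k, mean)
        z = rng.normal(size=k)
        z = (z - z.mean()) / z.std(ddof=1)
        return mean + sd * z

    zipf = np.empty(n)
    cond = np.array(["high"] * half + ["low"] * half)
    perm = rng.permutation(n)
    cond = cond[perm]
    zipf[cond == "high"] = _zipf(config.zipf_high_mean, config.zipf_high_sd, half)
    zipf[cond == "low"] = _zipf(config.zipf_low_mean, config.zipf_low_sd, half)

    items = []
    for i in range(n):
        n_words = int(rng.integers(7, 12))
        target_pos = int(rng.integers(3, n_words))  # never first two, never last
        word_lengths = rng.integers(2, 9, size=n_words)
        word_lengths[target_pos - 1] = lengths[i]
        items.append(
            StimulusItem(
                item_id=i + 1,
                condition=str(cond[i]),
                target_ia_index=target_pos,
                word_lengths=tuple(int(w) for w in word_lengths),
                zipf_target=float(zipf[i]),
            )
        )
    return items


def word_boxes(item: StimulusItem, config: SyntheticConfig) -> np.ndarray:
    """Pixel bounds per word: rows (x_min, x_max, y_min, y_max), half-open.

    Each word box spans the word's letters plus its trailing space, so the
    boxes tile the line with no gaps.
    """
    cw = config.char_width_px
    boxes = np.empty((item.n_words, 4))
    x = TEXT_X0_PX
    for w, length in enumerate(item.word_lengths):
        width = (length + 1) * cw
        boxes[w] = (x, x + width, LINE_Y_PX - LINE_HALF_HEIGHT_PX,
                    LINE_Y_PX + LINE_HALF_HEIGHT_PX)
        x += width
    return boxes


def interest_areas_table(
    items: list[StimulusItem], config: SyntheticConfig
) -> pd.DataFrame:
    rows = []
    for item in items:
        for w, box in enumerate(word_boxes(item, config), start=1):
            rows.append((item.item_id, w, *box))
    return pd.DataFrame(
        rows,
        columns=["item_id", "ia_index", "x_min_px", "x_max_px", "y_min_px", "y_max_px"],
    )


def stimuli_table(items: list[StimulusItem]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item_id": [it.item_id for it in items],
            "condition": [it.condition for it in items],
            "target_ia_index": [it.target_ia_index for it in items],
            "n_words": [it.n_words for it in items],
            "target_length": [it.target_length for it in items],
            "zipf_target": [it.zipf_target for it in items],
        }
    )


# --------------------------------------------------------------------------
# trial generation


def _p_skip(length: int, base: float) -> float:
    return min(0.95, base * math.exp(-(length - 2) / 2.5))


P_REFIX_PER_LETTER = 0.022
P_REGRESSION = 0.08


def generate_trial(
    subject_id: str,
    item: StimulusItem,
    effects: tuple[float, float],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> Trial:
    """Simulate one trial's fixation sequence (artifact-free).

    The eyes proceed left to right with length-dependent word skipping,
    occasional refixations and one-word regressions. Durations are
    ex-Gaussian with the subject/item intercepts added to ``mu``; the
    low-frequency target additionally receives ``effect_mu_ms`` on ``mu``
    and ``effect_tau_ms`` on ``tau``. Durations are floored at
    ``min_duration_floor_ms``.
    """
    subj_int, item_int = effects
    n_words = item.n_words
    boxes = word_boxes(item, config)
    target = item.target_ia_index
    is_low = item.condition == "low"

    u = rng.random(4 * n_words + 8)  # decision stream for the word walk
    ui = 0
    fix_words: list[int] = []
    w = 1
    while w <= n_words:
        length = item.word_lengths[w - 1]
        if w != 1 and u[ui] < _p_skip(length, config.p_skip_base):
            ui += 1
            w += 1
            continue
        ui += 1
        fix_words.append(w)
        # refixation of the current word
        if u[ui] < P_REFIX_PER_LETTER * length:
            fix_words.append(w)
        ui += 1
        # one-word regression before moving on
        if w > 1 and u[ui] < P_REGRESSION:
            fix_words.append(w - 1)
            fix_words.append(w)
        ui += 1
        w += 1
    if not fix_words:
        fix_words = [1]

    k = len(fix_words)
    words = np.asarray(fix_words)
    lo_target = is_low & (words == target)
    mu = config.exgauss_mu_ms + subj_int + item_int + np.where(
        lo_target, config.effect_mu_ms, 0.0
    )
    tau = config.exgauss_tau_ms + np.where(lo_target, config.effect_tau_ms, 0.0)
    dur = rng.normal(mu, config.exgauss_sigma_ms)
    # exponential tail; standard_exponential scaled per-fixation by tau
    dur = dur + rng.standard_exponential(k) * tau
    dur = np.maximum(dur, config.min_duration_floor_ms)

    xmin = boxes[words - 1, 0]
    xmax = boxes[words - 1, 1]
    centers = (xmin + xmax) / 2.0
    x = centers + rng.normal(0.0, 0.15 * (xmax - xmin), size=k)
    x = np.clip(x, xmin + 0.5, xmax - 0.5)
    y = np.clip(
        LINE_Y_PX + rng.normal(0.0, 4.0, size=k),
        LINE_Y_PX - LINE_HALF_HEIGHT_PX + 0.5,
        LINE_Y_PX + LINE_HALF_HEIGHT_PX - 0.5,
    )
    return Trial(x=x, y=y, dur=dur, ia=words.astype(float))


def inject_artifacts(
    trial: Trial,
    config: SyntheticConfig,
    rng: np.random.Generator,
    _force_near: bool | None = None,
) -> Trial:
    """Optionally add artifact fixations to a trial.

    With ``artifact_short_rate``, a 20-79 ms fixation is inserted next to a
    host fixation — within 0.5 deg of the host half the time, 0.6-3 deg away
    otherwise. With ``artifact_long_rate``, one fixation's duration is
    inflated to 801-2000 ms. With ``sparse_trial_rate``, the trial is
    truncated to 1-3 fixations. No-op when all rates are zero.
    """
    if len(trial) == 0:
        return trial
    out = trial.copy()
    ppd = config.pixels_per_degree

    if rng.random() < config.artifact_short_rate:
        host = int(rng.integers(0, len(out)))
        dur = rng.uniform(20.0, 79.0)
        near = (rng.random() < 0.5) if _force_near is None else _force_near
        if near:
            dist = rng.uniform(0.05, 0.45) * ppd
        else:
            dist = rng.uniform(0.6, 3.0) * ppd
        angle = rng.uniform(0.0, 2.0 * math.pi)
        x = out.x[host] + dist * math.cos(angle)
        y = out.y[host] + dist * math.sin(angle)
        side = host + (1 if rng.random() < 0.5 else 0)
        out = Trial(
            x=np.insert(out.x, side, x),
            y=np.insert(out.y, side, y),
            dur=np.insert(out.dur, side, dur),
            ia=np.insert(out.ia, side, np.nan),
        )

    if rng.random() < config.artifact_long_rate:
        i = int(rng.integers(0, len(out)))
        out.dur[i] = rng.uniform(801.0, 2000.0)

    if rng.random() < config.sparse_trial_rate:
        keep = int(rng.integers(1, 4))
        out = Trial(
            x=out.x[:keep], y=out.y[:keep], dur=out.dur[:keep], ia=out.ia[:keep]
        )
    return out


# --------------------------------------------------------------------------
# dataset assembly


def generate_dataset(
    config: SyntheticConfig, seed: int | None = None
) -> TrialSet:
    """Generate the full ``n_subjects`` x ``n_items`` trial set.

    Reproducible from ``(config, seed)``; ``seed`` defaults to
    ``config.seed``. Stimuli, intercepts and per-subject trial streams are
    seeded independently.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    s = config.seed
    items = generate_stimuli(config)
    rng_subj = np.random.default_rng(np.random.SeedSequence([s, 1]))
    rng_item = np.random.default_rng(np.random.SeedSequence([s, 2]))
    subj_ints = rng_subj.normal(0.0, config.sd_subject_ms, config.n_subjects)
    item_ints = rng_item.normal(0.0, config.sd_item_ms, config.n_items)

    cols: dict[str, list] = {c: [] for c in (
        "subject_id", "trial_id", "item_id", "condition", "fix_index",
        "x_px", "y_px", "duration_ms", "ia_index")}
    for si in range(config.n_subjects):
        subject_id = f"s{si + 1:03d}"
        rng = np.random.default_rng(np.random.SeedSequence([s, 3, si]))
        for item in items:
            trial = generate_trial(
                subject_id, item, (subj_ints[si], item_ints[item.item_id - 1]),
                config, rng,
            )
            trial = inject_artifacts(trial, config, rng)
            k = len(trial)
            cols["subject_id"].append(np.full(k, subject_id, dtype=object))
            cols["trial_id"].append(
                np.full(k, f"{subject_id}_i{item.item_id:03d}", dtype=object)
            )
            cols["item_id"].append(np.full(k, item.item_id))
            cols["condition"].append(np.full(k, item.condition, dtype=object))
            cols["fix_index"].append(np.arange(1, k + 1))
            cols["x_px"].append(trial.x)
            cols["y_px"].append(trial.y)
            cols["duration_ms"].append(trial.dur)
            cols["ia_index"].append(trial.ia)

    fx = pd.DataFrame({c: np.concatenate(v) for c, v in cols.items()})
    fx["item_id"] = fx["item_id"].astype(int)
    fx["fix_index"] = fx["fix_index"].astype(int)
    ia_float = fx.pop("ia_index").to_numpy(dtype=float)
    fx["ia_index"] = pd.array(
        [None if np.isnan(v) else int(v) for v in ia_float], dtype="Int64"
    )
    return TrialSet(
        fixations=fx,
        items=stimuli_table(items),
        geometry=config.geometry,
    )
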