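import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fixverse.cleaning import (
    CleaningConfig,
    MergeStage,
    RunMergeStage,
    TemporalStage,
    apply_cleaning,
    build_catalog,
    clean_trial,
    datasets_identical,
    delete_outside_ia,
    merge_ia_runs,
    merge_pass,
    temporal_filter,
)
from fixverse.io import Geometry
from fixverse.synthetic import Trial

from conftest import make_trial

GEOM = Geometry(pixels_per_degree=40.0)


# ---------------------------------------------------------------------------
# independent reference implementations (plain lists of dicts, rule applied
# literally, one event at a time)


def oracle_merge(trial, max_dur, max_dist_px):
    fx = [
        {"x": x, "y": y, "dur": d, "ia": i}
        for x, y, d, i in zip(trial.x, trial.y, trial.dur, trial.ia)
    ]
    while True:
        event = None
        for i, f in enumerate(fx):
            if f["dur"] >= max_dur:
                continue
            options = []
            for j in (i - 1, i + 1):
                if 0 <= j < len(fx) and fx[j]["dur"] > f["dur"]:
                    d = math.hypot(fx[j]["x"] - f["x"], fx[j]["y"] - f["y"])
                    if d <= max_dist_px:
                        options.append((d, -fx[j]["dur"], 0 if j < i else 1, j))
            if options:
                event = (i, min(options)[3])
                break
        if event is None:
            break
        i, host = event
        fx[host]["dur"] += fx[i]["dur"]
        del fx[i]
    return fx


def oracle_ia_runs(trial, max_dur):
    fx = [
        {"x": x, "y": y, "dur": d, "ia": i}
        for x, y, d, i in zip(trial.x, trial.y, trial.dur, trial.ia)
    ]
    out = []
    i = 0
    while i < len(fx):
        run = [fx[i]]
        if not math.isnan(fx[i]["ia"]) and fx[i]["dur"] < max_dur:
            j = i + 1
            while (
                j < len(fx)
                and not math.isnan(fx[j]["ia"])
                and fx[j]["ia"] == fx[i]["ia"]
                and fx[j]["dur"] < max_dur
            ):
                run.append(fx[j])
                j += 1
        if len(run) >= 3:
            total = sum(f["dur"] for f in run)
            out.append(
                {
                    "x": sum(f["x"] * f["dur"] for f in run) / total,
                    "y": sum(f["y"] * f["dur"] for f in run) / total,
                    "dur": total,
                    "ia": run[0]["ia"],
                }
            )
            i += len(run)
        else:
            out.append(fx[i])
            i += 1
    return out


def oracle_temporal(trial, lo, hi):
    return [
        {"dur": d} for d in trial.dur if lo <= d <= hi
    ]


def random_trial(rng, n_max=10):
    n = int(rng.integers(1, n_max + 1))
    return Trial(
        x=rng.uniform(80, 800, n),
        y=rng.uniform(280, 320, n),
        dur=rng.uniform(25, 900, n),
        ia=np.where(rng.random(n) < 0.1, np.nan, rng.integers(1, 6, n).astype(float)),
    )


# ---------------------------------------------------------------------------
# stages 1-2


class TestMergePass:
    def test_hand_example_merge(self):
        # 70 ms fixation 12 px from a 200 ms host; 0.5 deg = 20 px
        t = make_trial([200, 70], xs=[100, 112], ys=[300, 300])
        out, k = merge_pass(t, 80.0, 0.5, GEOM)
        assert k == 1
        assert len(out) == 1
        assert out.dur[0] == 270.0
        assert out.x[0] == 100.0  # host keeps its position

    def test_hand_example_too_far(self):
        t = make_trial([200, 70], xs=[100, 160], ys=[300, 300])
        out, k = merge_pass(t, 80.0, 0.5, GEOM)
        assert k == 0
        assert len(out) == 2

    def test_no_candidates_identity(self):
        t = make_trial([100, 200, 300])
        out, k = merge_pass(t, 80.0, 0.5, GEOM)
        assert k == 0
        assert np.array_equal(out.dur, t.dur)

    def test_host_keeps_ia(self):
        t = make_trial([200, 70], xs=[100, 112], ias=[4, 5])
        out, _ = merge_pass(t, 80.0, 0.5, GEOM)
        assert out.ia[0] == 4

    def test_tiebreak_nearer_neighbor_wins(self):
        t = make_trial([200, 70, 300], xs=[100, 112, 130], ys=[300, 300, 300])
        # both neighbors longer & in range; right one is nearer (18 vs 12? no:
        # left dist 12, right dist 18) -> left wins
        out, _ = merge_pass(t, 80.0, 0.5, GEOM)
        assert len(out) == 2
        assert out.dur.tolist() == [270.0, 300.0]

    def test_tiebreak_equidistant_longer_wins(self):
        t = make_trial([200, 70, 300], xs=[100, 110, 120], ys=[300, 300, 300])
        out, _ = merge_pass(t, 80.0, 0.5, GEOM)
        assert out.dur.tolist() == [200.0, 370.0]

    def test_unmergeable_short_left_in_place(self):
        t = make_trial([70], xs=[100])
        out, k = merge_pass(t, 80.0, 0.5, GEOM)
        assert k == 0 and len(out) == 1

    def test_empty_trial_unchanged(self):
        t = Trial(np.array([]), np.array([]), np.array([]), np.array([]))
        out, k = merge_pass(t, 80.0, 0.5, GEOM)
        assert len(out) == 0 and k == 0

    def test_cascading_merges_run_to_fixpoint(self):
        # after the short merges into its neighbor, the neighbor grows and
        # absorbs the next short on a later pass
        t = make_trial([50, 60, 45], xs=[100, 105, 110])
        out, k = merge_pass(t, 80.0, 0.5, GEOM)
        assert out.dur.sum() == t.dur.sum()
        assert len(out) == 1

    def test_matches_oracle_on_random_trials(self):
        rng = np.random.default_rng(17)
        for _ in range(400):
            t = random_trial(rng)
            got, _ = merge_pass(t, 80.0, 0.5, GEOM)
            want = oracle_merge(t, 80.0, GEOM.deg_to_px(0.5))
            assert got.dur.tolist() == pytest.approx([f["dur"] for f in want])
            assert got.x.tolist() == pytest.approx([f["x"] for f in want])


# ---------------------------------------------------------------------------
# stage 3


class TestMergeIaRuns:
    def test_three_short_same_ia_merged(self):
        t = make_trial([100, 100, 100], ias=[5, 5, 5])
        out, k = merge_ia_runs(t, 140.0)
        assert k == 1
        assert len(out) == 1
        assert out.dur[0] == 300.0
        assert out.ia[0] == 5

    def test_two_short_same_ia_unchanged(self):
        t = make_trial([100, 100], ias=[5, 5])
        out, k = merge_ia_runs(t, 140.0)
        assert k == 0 and len(out) == 2

    def test_split_ias_unchanged(self):
        t = make_trial([100, 100, 100], ias=[5, 5, 6])
        out, k = merge_ia_runs(t, 140.0)
        assert k == 0 and len(out) == 3

    def test_weighted_centroid_position(self):
        t = make_trial([100, 200, 100], xs=[0, 30, 60], ias=[5, 5, 5])
        out, _ = merge_ia_runs(t, 250.0)
        assert out.x[0] == pytest.approx((0 * 100 + 30 * 200 + 60 * 100) / 400)

    def test_missing_ia_breaks_run(self):
        t = make_trial([100, 100, 100], ias=[5, np.nan, 5])
        out, k = merge_ia_runs(t, 140.0)
        assert k == 0 and len(out) == 3

    def test_runs_longer_than_three_merged_whole(self):
        t = make_trial([100] * 5, ias=[5] * 5)
        out, k = merge_ia_runs(t, 140.0)
        assert k == 1 and len(out) == 1 and out.dur[0] == 500.0

    def test_matches_oracle_on_random_trials(self):
        rng = np.random.default_rng(19)
        for _ in range(400):
            t = random_trial(rng)
            got, _ = merge_ia_runs(t, 140.0)
            want = oracle_ia_runs(t, 140.0)
            assert got.dur.tolist() == pytest.approx([f["dur"] for f in want])


# ---------------------------------------------------------------------------
# stage 4 and outside-IA deletion


class TestTemporalFilter:
    def test_direct_filter(self):
        t = make_trial([100, 200, 900])
        out, k = temporal_filter(t, 140.0, 800.0)
        assert out.dur.tolist() == [200.0]
        assert k == 2

    def test_boundaries_kept(self):
        # removal uses strict inequalities: shorter than min, longer than max
        t = make_trial([140, 800])
        out, k = temporal_filter(t, 140.0, 800.0)
        assert out.dur.tolist() == [140.0, 800.0]
        assert k == 0

    def test_unbounded_is_identity(self):
        t = make_trial([1, 500, 5000])
        out, k = temporal_filter(t, 0.0, math.inf)
        assert len(out) == 3 and k == 0


class TestDeleteOutsideIa:
    def test_all_inside_identity(self):
        t = make_trial([100, 200], ias=[1, 2])
        out, k = delete_outside_ia(t)
        assert len(out) == 2 and k == 0

    def test_one_outside_removed(self):
        t = make_trial([100, 200, 300], ias=[1, np.nan, 2])
        out, k = delete_outside_ia(t)
        assert len(out) == 2 and k == 1

    def test_equals_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            t = random_trial(rng)
            out, _ = delete_outside_ia(t)
            want = [d for d, i in zip(t.dur, t.ia) if not math.isnan(i)]
            assert out.dur.tolist() == want


# ---------------------------------------------------------------------------
# config-level behavior


class TestApplyCleaning:
    def test_no_cleaning_is_identity(self, artifact_dataset, catalog_map):
        cleaned, stats = apply_cleaning(artifact_dataset, catalog_map["no_cleaning"])
        assert datasets_identical(cleaned, artifact_dataset)
        assert stats.merges_stage1 == 0
        assert stats.removed_stage4 == 0
        assert stats.n_fixations_before == stats.n_fixations_after

    def test_standard_cleaning_removes_fixations(self, artifact_dataset, catalog_map):
        _, stats = apply_cleaning(artifact_dataset, catalog_map["standard"])
        assert stats.n_fixations_after < stats.n_fixations_before

    def test_catalog_has_14_configurations(self):
        catalog = build_catalog()
        assert len(catalog) == 14
        assert len({c.config_id for c in catalog}) == 14

    def test_mass_conserved_by_merge_stages(self, artifact_dataset, catalog_map):
        config = CleaningConfig(
            config_id="merge_only",
            stage4=TemporalStage(enabled=False),
        )
        cleaned, _ = apply_cleaning(artifact_dataset, config)
        orig = artifact_dataset.fixations.groupby(["subject_id", "trial_id"])[
            "duration_ms"
        ].sum()
        new = cleaned.fixations.groupby(["subject_id", "trial_id"])["duration_ms"].sum()
        pd.testing.assert_series_equal(orig, new)

    def test_stages_never_increase_count_vs_no_cleaning(
        self, artifact_dataset, catalog_map
    ):
        base = len(artifact_dataset.fixations)
        for config in build_catalog():
            cleaned, _ = apply_cleaning(artifact_dataset, config)
            assert len(cleaned.fixations) <= base

    def test_idempotent_on_catalog_configs(self, artifact_dataset):
        for config in build_catalog():
            once, _ = apply_cleaning(artifact_dataset, config)
            twice, _ = apply_cleaning(once, config)
            assert datasets_identical(once, twice), config.config_id

    def test_merge_tallies_match_count_change(self, artifact_dataset, catalog_map):
        _, stats = apply_cleaning(artifact_dataset, catalog_map["standard"])
        net = stats.n_fixations_before - stats.n_fixations_after
        assert net == (
            stats.merges_stage1
            + stats.merges_stage2
            + stats.removed_stage4
            + stats.removed_outside_ia
            + _stage3_net(artifact_dataset, catalog_map["standard"])
        )

    def test_invalid_stage4_bounds_rejected(self):
        with pytest.raises(ValueError):
            TemporalStage(min_dur_ms=800.0, max_dur_ms=140.0)


def _stage3_net(ts, config):
    """Fixations absorbed by stage-3 runs, recomputed independently."""
    from fixverse.cleaning import _iter_trials

    net = 0
    geom = ts.geometry
    for _, trial in _iter_trials(ts.fixations):
        t = trial
        if config.stage1.enabled:
            t, _ = merge_pass(t, config.stage1.max_dur_ms,
                              config.stage1.max_dist_deg, geom)
        if config.stage2.enabled:
            t, _ = merge_pass(t, config.stage2.max_dur_ms,
                              config.stage2.max_dist_deg, geom)
        before = len(t)
        t, _ = merge_ia_runs(t, config.stage3.max_dur_ms)
        net += before - len(t)
    return net


class TestDatasetsIdentical:
    def test_self_identity(self, artifact_dataset):
        assert datasets_identical(artifact_dataset, artifact_dataset)

    def test_stage4_only_noop_on_in_range_data(self, catalog_map):
        # floored, artifact-free data whose durations all fall inside
        # [min, max]: stage 4 removes nothing
        from fixverse.synthetic import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_subjects=4, n_items=6, seed=31,
            exgauss_mu_ms=300.0, exgauss_sigma_ms=20.0, exgauss_tau_ms=0.001,
            sd_subject_ms=5.0, sd_item_ms=5.0,
            min_duration_floor_ms=140.0,
        )
        ts = generate_dataset(cfg)
        assert ts.fixations["duration_ms"].between(140, 800).all()
        stage4_only = CleaningConfig(
            config_id="s4only",
            stage1=MergeStage(enabled=False),
            stage2=MergeStage(enabled=False, max_dur_ms=40.0, max_dist_deg=1.25),
            stage3=RunMergeStage(enabled=False),
        )
        cleaned, _ = apply_cleaning(ts, stage4_only)
        no_cleaning, _ = apply_cleaning(ts, catalog_map["no_cleaning"])
        assert datasets_identical(no_cleaning, cleaned)

    def test_cleaning_differs_on_artifact_data(self, artifact_dataset, catalog_map):
        a, _ = apply_cleaning(artifact_dataset, catalog_map["no_cleaning"])
        b, _ = apply_cleaning(artifact_dataset, catalog_map["standard"])
        assert not datasets_identical(a, b)


# ---------------------------------------------------------------------------
# property tests


@settings(max_examples=150, deadline=None)
@given(
    durs=st.lists(st.floats(25, 900), min_size=1, max_size=10),
    seed=st.integers(0, 10_000),
)
def test_merge_mass_and_count_properties(durs, seed):
    rng = np.random.default_rng(seed)
    n = len(durs)
    t = Trial(
        x=rng.uniform(80, 800, n),
        y=rng.uniform(280, 320, n),
        dur=np.asarray(durs),
        ia=rng.integers(1, 6, n).astype(float),
    )
    for stage_fn in (
        lambda tr: merge_pass(tr, 80.0, 0.5, GEOM),
        lambda tr: merge_ia_runs(tr, 140.0),
    ):
        out, _ = stage_fn(t)
        assert out.dur.sum() == pytest.approx(t.dur.sum())  # mass conserved
        assert len(out) <= len(t)
        again, k = stage_fn(out)
        assert k == 0  # stage output is a fixpoint of itself
        assert again.dur.tolist() == out.dur.tolist()
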