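"""Synthetic-study generator: cohorts, inverse posing, rendering, studies."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lunarcom import keypoints as kpt
from lunarcom.anthropometry import default_segment_table
from lunarcom.com import body_com
from lunarcom.mocap import read_openpose_frames, triangulate_poses
from lunarcom.pipeline import analysis_rows, run_study
from lunarcom.mocap import Pose3D
from lunarcom.synthetic import (
    _ARM_STATIC,
    EffectParams,
    GeneratorConfig,
    PoseTargetError,
    _solve_pose,
    default_camera_rig,
    generate_cohort,
    generate_study,
    generate_trial,
    reachable_radius,
    render_views,
    seated_keypoints,
    simulate_measured_rows,
)


def small_config(**over):
    base = dict(fps=5.0, window_s=2.0, n_rows={"male": 6, "female": 6},
                n_male=2, n_female=2)
    base.update(over)
    return GeneratorConfig(**base)


class TestCohort:
    def test_large_sample_mean_height_matches(self):
        from scipy import stats as sps
        cfg = GeneratorConfig(n_male=2500, n_female=10)
        h = np.concatenate([
            [p.height_m for p in generate_cohort(cfg, np.random.default_rng(s))
             if p.sex == "male"]
            for s in (100, 101, 102, 103)
        ])
        mu, sd = 1.83, cfg.anthro["male"]["height_sd"]
        lo, hi = 1.54, 1.95
        a, b = (lo - mu) / sd, (hi - mu) / sd
        expected = sps.truncnorm.mean(a, b, loc=mu, scale=sd)
        se = sps.truncnorm.std(a, b, loc=mu, scale=sd) / np.sqrt(len(h))
        assert abs(h.mean() - expected) < 3 * se
        # the truncated mean stays close to the nominal cohort mean
        assert abs(h.mean() - mu) < 0.01

    def test_zero_sd_gives_exact_means(self):
        cfg = GeneratorConfig(n_male=3, n_female=3)
        cfg.anthro["male"]["height_sd"] = 0.0
        cfg.anthro["male"]["mass_sd"] = 0.0
        cohort = generate_cohort(cfg, np.random.default_rng(0))
        males = [p for p in cohort if p.sex == "male"]
        assert all(p.height_m == 1.83 and p.mass_kg == 82.92 for p in males)

    def test_same_seed_identical_cohorts(self):
        cfg = GeneratorConfig(n_male=5, n_female=5)
        a = generate_cohort(cfg, np.random.default_rng(7))
        b = generate_cohort(cfg, np.random.default_rng(7))
        assert a == b

    def test_impossible_truncation_bounds_error(self):
        cfg = GeneratorConfig(n_male=1, n_female=0)
        cfg.anthro["bounds"]["height_min"] = 2.5
        cfg.anthro["bounds"]["height_max"] = 2.6
        with pytest.raises(ValueError):
            generate_cohort(cfg, np.random.default_rng(0))

    def test_volumes_scale_with_mass(self):
        cfg = GeneratorConfig(n_male=4, n_female=0)
        cohort = generate_cohort(cfg, np.random.default_rng(11))
        for p in cohort:
            ratio = p.mass_kg / cfg.anthro["male"]["mass_mean"]
            assert p.volumes_dm3["forearm"] == pytest.approx(1.37 * ratio)


class TestInversePosing:
    def test_posed_skeleton_reproduces_target(self, male_participant, default_config):
        """Inverse-then-forward: solve pose, measure CoM, recover target."""
        rng = np.random.default_rng(5)
        cfg = default_config
        model = default_segment_table("male", total_mass=male_participant.mass_kg)
        r_lo, r_hi = reachable_radius(male_participant, "static", cfg)
        for _ in range(25):
            r = rng.uniform(r_lo + 0.5, r_hi - 0.5)
            ang = rng.uniform(-2.0, 2.0)
            target = (r * np.cos(ang), r * np.sin(ang))     # (com_y, com_z)
            s, pitch, realized, clipped = _solve_pose(
                target, male_participant, "static", cfg)
            assert not clipped
            assert realized == pytest.approx(target, abs=1e-6)
            kp = seated_keypoints(male_participant, pitch, s, _ARM_STATIC,
                                  hip_height_cm=cfg.hip_height_cm)
            pose = Pose3D(0, 0.0, kp, np.ones(25, bool), np.zeros(25))
            sample = body_com(pose, model)
            # dY = pelvis_y - com_y = -target_y
            assert sample.d_y == pytest.approx(-target[0], abs=1e-6)
            assert sample.d_z == pytest.approx(-target[1], abs=1e-6)

    def test_unreachable_target_error_reports_range(self, male_participant,
                                                    default_config):
        with pytest.raises(PoseTargetError) as exc:
            _solve_pose((80.0, 0.0), male_participant, "static", default_config)
        lo, hi = exc.value.reachable_radius_cm
        assert 0 < lo < hi < 80.0

    def test_clip_preserves_proximodistal_coordinate(self, male_participant,
                                                     default_config):
        s, pitch, realized, clipped = _solve_pose(
            (10.0, 60.0), male_participant, "static", default_config,
            on_unreachable="clip")
        assert clipped
        assert realized[0] == pytest.approx(10.0, abs=1e-6)   # y kept
        _, r_hi = reachable_radius(male_participant, "static", default_config)
        assert np.hypot(*realized) == pytest.approx(r_hi, rel=1e-6)


class TestTrials:
    def test_noiseless_gravity_effect_is_exact(self, female_participant):
        """residual_sd=0: the 1/6g -> 1g window difference equals beta_g."""
        cfg = GeneratorConfig(pitch_jitter_deg=0.0, et_cv=0.0, fps=5.0)
        effects = dict(cfg.effects)
        for key, ep in effects.items():
            effects[key] = dataclasses.replace(ep, residual_sd=0.0)
        cfg.effects = effects
        t_low = generate_trial(female_participant, "1/6g", "static", 1.0, cfg,
                               np.random.default_rng(1))
        t_high = generate_trial(female_participant, "1g", "static", 1.0, cfg,
                                np.random.default_rng(2))
        assert not any(w.clipped for w in t_low.windows + t_high.windows)
        for wl, wh in zip(t_low.windows, t_high.windows):
            assert wh.d_y_realized - wl.d_y_realized == pytest.approx(
                cfg.effects[("female", "dY")].beta_g, abs=1e-9)
            assert wh.d_z_realized - wl.d_z_realized == pytest.approx(
                cfg.effects[("female", "dZ")].beta_g, abs=1e-9)

    def test_window_pose_measures_back_exactly(self, female_participant,
                                               default_config):
        trial = generate_trial(female_participant, "1g", "dynamic", 3.0,
                               default_config, np.random.default_rng(3),
                               on_unreachable="clip")
        model = default_segment_table("female",
                                      total_mass=female_participant.mass_kg)
        for w in trial.windows:
            pose = trial.window_pose(w.label, default_config)
            s = body_com(pose, model)
            assert s.d_y == pytest.approx(w.d_y_realized, abs=1e-6)
            assert s.d_z == pytest.approx(w.d_z_realized, abs=1e-6)

    def test_dynamic_commanded_hand_speed_within_cap(self, male_participant):
        cfg = GeneratorConfig(pitch_jitter_deg=0.0, fps=30.0)
        trial = generate_trial(male_participant, "1/6g", "dynamic", 1.0, cfg,
                               np.random.default_rng(4), on_unreachable="clip")
        wrists = np.array([kp[kpt.R_WRIST] for _, _, kp in trial.frames])
        times = np.array([t for _, t, _ in trial.frames])
        dt = np.diff(times)
        within = dt < 1.5 / cfg.fps                  # skip window gaps
        speed = np.linalg.norm(np.diff(wrists, axis=0), axis=1) / dt
        assert speed[within].max() <= cfg.max_hand_speed_cm_s + 1e-6

    def test_invalid_factor_levels_rejected(self, male_participant,
                                            default_config):
        with pytest.raises(ValueError):
            generate_trial(male_participant, "0.5g", "static", 1.0,
                           default_config, np.random.default_rng(0))


class TestRendering:
    def test_noiseless_render_triangulates_back(self, male_participant,
                                                tmp_path):
        cfg = small_config()
        trial = generate_trial(male_participant, "1g", "static", 1.0, cfg,
                               np.random.default_rng(6), on_unreachable="clip")
        rig = default_camera_rig(cfg)
        render_views(trial, rig, tmp_path, np.random.default_rng(0),
                     pixel_noise_sd=0.0, dropout_p=0.0)
        names = sorted(rig)
        seqs = [read_openpose_frames(tmp_path / n) for n in names]
        poses = triangulate_poses([rig[n] for n in names], seqs, fps=cfg.fps)
        truth = {i: kp for i, _, kp in trial.frames}
        for pose in poses:
            assert pose.valid.all()
            assert np.allclose(pose.xyz, truth[pose.frame_index], atol=1e-5)

    def test_full_dropout_of_one_camera_still_triangulates(self,
                                                           male_participant,
                                                           tmp_path):
        cfg = small_config()
        trial = generate_trial(male_participant, "1g", "static", 1.0, cfg,
                               np.random.default_rng(6), on_unreachable="clip")
        rig = default_camera_rig(cfg)
        names = sorted(rig)
        keep = {n: rig[n] for n in names[:2]}
        dead = {names[2]: rig[names[2]]}
        render_views(trial, keep, tmp_path, np.random.default_rng(0),
                     pixel_noise_sd=0.0, dropout_p=0.0)
        render_views(trial, dead, tmp_path, np.random.default_rng(0),
                     pixel_noise_sd=0.0, dropout_p=1.0)
        seqs = [read_openpose_frames(tmp_path / n) for n in names]
        poses = triangulate_poses([rig[n] for n in names], seqs,
                                  min_views=2, fps=cfg.fps)
        assert all(p.valid.all() for p in poses)

    def test_written_files_reread_identically(self, male_participant, tmp_path):
        cfg = small_config()
        trial = generate_trial(male_participant, "1/6g", "dynamic", 3.0, cfg,
                               np.random.default_rng(8), on_unreachable="clip")
        rig = default_camera_rig(cfg)
        render_views(trial, rig, tmp_path, np.random.default_rng(1))
        cam = sorted(rig)[0]
        frames = read_openpose_frames(tmp_path / cam)
        # the writer rounds to 6 decimals; re-reading must be exact
        raw = (tmp_path / cam / f"frame_{frames[0].frame_index:06d}.json").read_text()
        import json
        vals = json.loads(raw)["people"][0]["pose_keypoints_2d"]
        assert np.array_equal(np.asarray(vals).reshape(25, 3),
                              frames[0].keypoints)


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(root.rglob("*")):
        if f.is_file():
            h.update(str(f.relative_to(root)).encode())
            h.update(f.read_bytes())
    return h.hexdigest()


class TestStudies:
    def test_fixed_seed_byte_identical_tree(self, tmp_path):
        cfg = small_config()
        generate_study(cfg, tmp_path / "a", seed=99)
        generate_study(cfg, tmp_path / "b", seed=99)
        assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")
        generate_study(cfg, tmp_path / "c", seed=100)
        assert _tree_digest(tmp_path / "a") != _tree_digest(tmp_path / "c")

    def test_row_counts_match_configuration(self, tmp_path):
        cfg = small_config(n_rows={"male": 9, "female": 8})
        generate_study(cfg, tmp_path / "s", seed=5)
        df = run_study(tmp_path / "s")
        rows = analysis_rows(df, cfg.n_rows)
        counts = rows.groupby("sex").size().to_dict()
        assert counts == {"male": 9, "female": 8}

    def test_pipeline_measures_realized_truth(self, tmp_path):
        """render -> triangulate -> CoM window means match the ground truth."""
        cfg = small_config()
        truth = generate_study(cfg, tmp_path / "s", seed=21)
        df = run_study(tmp_path / "s")
        merged = df.merge(truth, on=["trial_id", "window"])
        assert len(merged) == len(df)
        # sub-millimetre pixel noise propagation at these settings
        assert np.abs(merged["dY_cm"] - merged["dY_realized"]).max() < 0.35
        assert np.abs(merged["dZ_cm"] - merged["dZ_realized"]).max() < 0.35

    def test_relative_to_start_alternative_response(self, tmp_path):
        from lunarcom.pipeline import relative_to_start
        cfg = small_config()
        generate_study(cfg, tmp_path / "s", seed=13)
        df = run_study(tmp_path / "s")
        rel = relative_to_start(df)
        starts = rel[rel["window"] == "start"]
        assert np.allclose(starts["dY_cm"], 0.0)
        assert np.allclose(starts["dZ_cm"], 0.0)
        mid = rel[rel["window"] == "middle"].set_index("trial_id")
        raw = df.set_index(["trial_id", "window"])
        for tid in mid.index:
            expected = (raw.loc[(tid, "middle"), "dY_cm"]
                        - raw.loc[(tid, "start"), "dY_cm"])
            assert mid.loc[tid, "dY_cm"] == pytest.approx(expected)

    def test_simulate_measured_rows_counts_and_determinism(self):
        cfg = small_config(n_rows={"male": 7, "female": 5})
        a = simulate_measured_rows(cfg, "male", np.random.default_rng(3))
        b = simulate_measured_rows(cfg, "male", np.random.default_rng(3))
        assert len(a) == 7
        pd.testing.assert_frame_equal(a, b)

    def test_distributional_fidelity_of_window_draws(self):
        """Linear-model draws have the configured cell means and SD."""
        cfg = GeneratorConfig(n_rows={"male": 114, "female": 3000})
        df = simulate_measured_rows(cfg, "female", np.random.default_rng(77),
                                    geometry=False)
        ep = cfg.effects[("female", "dY")]
        for (g, t), sub in df.groupby(["g_level", "task"]):
            mu = ep.mean(g, t)
            assert sub["dY"].mean() == pytest.approx(
                mu, abs=4 * ep.residual_sd / np.sqrt(len(sub)))
        resid = df["dY"] - [ep.mean(g, t) for g, t in zip(df["g_level"], df["task"])]
        assert resid.std() == pytest.approx(ep.residual_sd, rel=0.1)
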