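"""Generator contracts: counterbalanced design, RT generative model,
epoch/source simulations, and determinism."""

import numpy as np
import pandas as pd
import pytest

from megprime.containers import WORD_CONDITIONS, validate_trial_table
from megprime.synth import (
    EffectWindow,
    SimulationSpec,
    evoked_template,
    generate_design,
    simulate_roi_timecourses,
    simulate_rts,
    simulate_source_grid,
)


class TestGenerateDesign:
    def test_full_study_counts(self):
        spec = SimulationSpec(seed=0)
        design = generate_design(spec)
        words = design[design.condition != "nonword"]
        assert len(words) == 16 * 4 * 50 == 3200
        assert (words.prime_type == "related").sum() == 1600
        # per subject: 100 related and 100 unrelated word primes
        per_subj = words.groupby("subject_id").prime_type.value_counts().unstack()
        assert (per_subj["related"] == 100).all()
        assert (per_subj["unrelated"] == 100).all()
        # nonword fillers: 75 related / 125 unrelated per subject
        nw = design[design.condition == "nonword"]
        per_subj_nw = nw.groupby("subject_id").prime_type.value_counts().unstack()
        assert (per_subj_nw["related"] == 75).all()
        assert (per_subj_nw["unrelated"] == 125).all()

    def test_minimal_counterbalancing(self):
        spec = SimulationSpec(n_subjects=2, trials_per_condition=2,
                              n_nonword_trials=0, seed=0)
        design = generate_design(spec)
        counts = design.groupby(["subject_id", "condition"]).prime_type.value_counts()
        assert (counts == 1).all()  # exactly 1 related + 1 unrelated each

    def test_odd_trials_per_condition_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_design(SimulationSpec(trials_per_condition=3, seed=0))

    def test_versions_swap_relatedness(self):
        spec = SimulationSpec(n_subjects=2, trials_per_condition=4,
                              n_nonword_trials=0, seed=0)
        design = generate_design(spec)
        wide = design.pivot_table(
            index="item_id", columns="version", values="prime_type",
            aggfunc="first",
        )
        assert (wide["A"] != wide["B"]).all()

    def test_table_invariants_and_determinism(self):
        spec = SimulationSpec(n_subjects=4, trials_per_condition=6, seed=9)
        d1 = generate_design(spec)
        d2 = generate_design(spec)
        pd.testing.assert_frame_equal(d1, d2)
        validate_trial_table(d1)
        # within a version, every target carries exactly one prime type
        per_version = d1.groupby(["version", "item_id"]).prime_type.nunique()
        assert (per_version == 1).all()

    def test_albright_scores_only_for_verbs(self):
        design = generate_design(SimulationSpec(n_subjects=2, seed=1))
        has = design.groupby("condition").albright_score.apply(lambda s: s.notna().all())
        lacks = design.groupby("condition").albright_score.apply(lambda s: s.isna().all())
        assert has["regular"] and has["irregular"]
        assert lacks["identity"] and lacks["pseudo_irregular"] and lacks["nonword"]

    def test_albright_distribution_and_frequency_correlation(self):
        # one item set is one draw from the item population; moments are
        # checked against the generative targets at sampling precision
        spec = SimulationSpec(n_subjects=2, trials_per_condition=400, seed=2)
        items = (
            generate_design(spec)
            .drop_duplicates("item_id")
            .query("condition == 'irregular'")
        )
        assert abs(items.albright_score.mean() - 0.514) < 0.04
        assert abs(items.albright_score.std() - 0.228) < 0.04
        r = np.corrcoef(items.albright_score, items.log_surface_freq)[0, 1]
        assert abs(r - 0.29) < 0.12


class TestSimulateRts:
    def test_noise_free_generative_identity(self):
        spec = SimulationSpec(
            n_subjects=2, trials_per_condition=4, n_nonword_trials=0,
            subject_sd=0.0, item_sd=0.0, residual_sd=0.0,
            priming_effects_ms={c: 20.0 for c in WORD_CONDITIONS}, seed=0,
        )
        trials = simulate_rts(generate_design(spec), spec)
        gap = (
            trials[trials.prime_type == "unrelated"].rt_ms.mean()
            - trials[trials.prime_type == "related"].rt_ms.mean()
        )
        assert gap == pytest.approx(20.0, abs=1e-12)

    def test_determinism_bitwise(self):
        spec = SimulationSpec(n_subjects=3, trials_per_condition=4, seed=7)
        t1 = simulate_rts(generate_design(spec), spec)
        t2 = simulate_rts(generate_design(spec), spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_subject_sd_moment_recovery(self):
        # ~10^4 trials: the SD of fitted subject means should recover the
        # generative subject SD within 10%
        spec = SimulationSpec(
            n_subjects=50, trials_per_condition=50, n_nonword_trials=0,
            subject_sd=40.0, item_sd=0.0, residual_sd=30.0, seed=11,
        )
        trials = simulate_rts(generate_design(spec), spec)
        subject_means = trials.groupby("subject_id").rt_ms.mean()
        assert abs(subject_means.std() - 40.0) / 40.0 < 0.10

    def test_variance_decomposition(self):
        spec = SimulationSpec(
            n_subjects=100, trials_per_condition=26, n_nonword_trials=0,
            subject_sd=40.0, item_sd=25.0, residual_sd=60.0,
            priming_effects_ms={}, seed=13,
        )
        trials = simulate_rts(generate_design(spec), spec)
        total = 40.0**2 + 25.0**2 + 60.0**2
        assert abs(trials.rt_ms.var() - total) / total < 0.10

    def test_refuses_to_overwrite_rts(self, small_spec, small_trials):
        with pytest.raises(ValueError, match="rt_ms"):
            simulate_rts(small_trials, small_spec)


class TestSimulateRoiTimecourses:
    def test_noise_free_injected_bump_exact(self):
        win = EffectWindow(158.0, 208.0, 1.0, shape="boxcar")
        spec = SimulationSpec(
            n_subjects=2, trials_per_condition=4, n_nonword_trials=0,
            noise_sd=0.0, epoch_subject_gain_sd=0.0, epoch_item_gain_sd=0.0,
            effect_windows={"irregular": [win]}, seed=0,
        )
        design = generate_design(spec)
        ep = simulate_roi_timecourses(design, spec)
        irr = design[design.condition == "irregular"]
        rel = ep.subset(irr.index[irr.prime_type == "related"]).data.mean(axis=0)
        unrel = ep.subset(irr.index[irr.prime_type == "unrelated"]).data.mean(axis=0)
        np.testing.assert_allclose(unrel - rel, win.profile(ep.time_ms), atol=1e-12)

    def test_albright_scaling_noise_free(self):
        win = EffectWindow(158.0, 208.0, 1.0, shape="boxcar")
        spec = SimulationSpec(
            n_subjects=2, trials_per_condition=4, n_nonword_trials=0,
            noise_sd=0.0, epoch_subject_gain_sd=0.0, epoch_item_gain_sd=0.0,
            effect_windows={"irregular": [win]}, scale_effect_by_albright=True,
            seed=0,
        )
        design = generate_design(spec)
        ep = simulate_roi_timecourses(design, spec)
        template = evoked_template(ep.time_ms)
        prof = win.profile(ep.time_ms)
        irr = design[design.condition == "irregular"]
        for idx, row in irr.iterrows():
            expected = template.copy()
            if row.prime_type == "related":
                expected = expected - row.albright_score * prof
            np.testing.assert_allclose(
                ep.subset([idx]).data[0], expected, atol=1e-12
            )

    def test_mean_difference_tracks_bump_at_unit_snr(self):
        win = EffectWindow(158.0, 208.0, 1.0)
        spec = SimulationSpec(
            n_subjects=2, trials_per_condition=100, n_nonword_trials=0,
            noise_sd=1.0, ar1_rho=0.0, epoch_subject_gain_sd=0.0,
            epoch_item_gain_sd=0.0, effect_windows={"identity": [win]}, seed=3,
        )
        design = generate_design(spec)
        ident = design[design.condition == "identity"]  # 200 trials
        ep = simulate_roi_timecourses(design, spec).subset(ident.index)
        rel = ident.prime_type.to_numpy() == "related"
        diff = ep.data[~rel].mean(axis=0) - ep.data[rel].mean(axis=0)
        se = np.sqrt(1.0 / rel.sum() + 1.0 / (~rel).sum())
        assert np.all(np.abs(diff - win.profile(ep.time_ms)) < 3.5 * se)

    def test_null_fidelity(self):
        spec = SimulationSpec(
            n_subjects=4, trials_per_condition=40, n_nonword_trials=0,
            effect_windows={}, epoch_subject_gain_sd=0.0,
            epoch_item_gain_sd=0.0, seed=21,
        )
        design = generate_design(spec)
        ep = simulate_roi_timecourses(design, spec)
        rel = design.prime_type.to_numpy() == "related"
        diff = ep.data[rel].mean(axis=0) - ep.data[~rel].mean(axis=0)
        se = spec.noise_sd * np.sqrt(1.0 / rel.sum() + 1.0 / (~rel).sum())
        assert np.all(np.abs(diff) < 3.5 * se)

    def test_effect_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="outside epoch"):
            SimulationSpec(
                epoch_window_ms=(-150.0, 300.0),
                effect_windows={"identity": [EffectWindow(250.0, 400.0, 1.0)]},
            )


class TestSimulateSourceGrid:
    def test_effect_confined_to_patch_noise_free(self):
        win = EffectWindow(158.0, 208.0, 1.0, shape="boxcar")
        spec = SimulationSpec(
            n_subjects=2, trials_per_condition=4, n_nonword_trials=0,
            noise_sd=0.0, epoch_subject_gain_sd=0.0, epoch_item_gain_sd=0.0,
            effect_windows={"identity": [win]}, seed=0,
        )
        design = generate_design(spec)
        src = simulate_source_grid(design, spec, patch=[17])
        ident = design[design.condition == "identity"]
        rel = ident.prime_type.to_numpy() == "related"
        sub = src.subset(ident.index)
        diff = sub.data[~rel].mean(axis=0) - sub.data[rel].mean(axis=0)  # (S, T)
        nonzero = np.abs(diff).max(axis=1) > 1e-12
        assert list(np.flatnonzero(nonzero)) == [17]
        assert src.source_labels[17] == "inferior_temporal"

    def test_mask_layout_and_signs(self):
        spec = SimulationSpec(n_subjects=2, trials_per_condition=2,
                              n_nonword_trials=0, noise_sd=0.0, seed=0)
        design = generate_design(spec)
        src = simulate_source_grid(design, spec, patch=[0])
        assert src.source_labels[:10] == ["fusiform"] * 10
        assert src.source_labels[10:20] == ["inferior_temporal"] * 10
        # per-mask response signs: fusiform positive, temporal negative
        evoked = src.data.mean(axis=0).mean(axis=1)
        assert (evoked[:10] > 0).all() and (evoked[10:] < 0).all()

    def test_empty_patch_rejected(self, small_spec):
        design = generate_design(small_spec)
        with pytest.raises(ValueError, match="empty patch"):
            simulate_source_grid(design, small_spec, patch=[])
        with pytest.raises(ValueError, match="outside the grid"):
            simulate_source_grid(design, small_spec, patch=[99])

    def test_top_difference_sources_recover_patch_at_snr_2(self):
        win = EffectWindow(158.0, 208.0, 2.0)  # amplitude = 2 x noise SD
        spec = SimulationSpec(
            n_subjects=4, trials_per_condition=20, n_nonword_trials=0,
            noise_sd=1.0, effect_windows={"identity": [win], "regular": [win]},
            seed=5,
        )
        design = generate_design(spec)
        patch = {3, 4, 5, 6, 7}
        src = simulate_source_grid(design, spec, patch=sorted(patch))
        sel = design[design.condition.isin(["identity", "regular"])]
        rel = sel.prime_type.to_numpy() == "related"
        sub = src.subset(sel.index)
        sl = src.window_slice((158.0, 208.0))
        diff = (
            sub.data[~rel][:, :, sl].mean(axis=(0, 2))
            - sub.data[rel][:, :, sl].mean(axis=(0, 2))
        )
        top = set(np.argsort(-np.abs(diff))[: len(patch)])
        jaccard = len(top & patch) / len(top | patch)
        assert jaccard >= 0.9


class TestSimulationSpec:
    def test_json_round_trip(self, tmp_path):
        spec = SimulationSpec(
            n_subjects=5, seed=42,
            effect_windows={"regular": [EffectWindow(100.0, 150.0, 0.4)]},
        )
        path = tmp_path / "spec.json"
        spec.to_json(path)
        assert SimulationSpec.from_json(path) == spec

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationSpec(residual_sd=-1.0)
        with pytest.raises(ValueError):
            SimulationSpec(sampling_rate_hz=0.0)
        with pytest.raises(ValueError):
            SimulationSpec.from_dict({"not_a_field": 1})
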