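"""Phantom and cohort generators: determinism, ground-truth closure, cohort structure."""

import numpy as np
import pandas as pd
import pytest

from qctlung import (
    AIRWAY_REGIONS,
    CohortConfig,
    DeformationSpec,
    PhantomConfig,
    air_fraction,
    emphysema_percent,
    generate_airway_table,
    generate_cohort_metrics,
    generate_phantom_pair,
    null_family_config,
    uniform_expansion,
)
from qctlung.airway import branch_metrics, fit_trachea_reference, summarize_regions
from qctlung.images import LOBE_LABELS


class TestPhantomPair:
    def test_same_seed_is_bit_identical(self):
        cfg = PhantomConfig(seed=42, target_emph_pct=5.0, target_fsad_pct=10.0)
        a = generate_phantom_pair(cfg)
        b = generate_phantom_pair(PhantomConfig(seed=42, target_emph_pct=5.0, target_fsad_pct=10.0))
        assert np.array_equal(a.tlc_volume.data, b.tlc_volume.data)
        assert np.array_equal(a.exp_volume.data, b.exp_volume.data)
        assert np.array_equal(a.true_field.data, b.true_field.data)

    def test_identity_deformation_zero_noise_gives_identical_volumes(self):
        cfg = PhantomConfig(deformation_spec=DeformationSpec(), noise_sd_hu=0.0, seed=3)
        b = generate_phantom_pair(cfg)
        assert np.array_equal(b.tlc_volume.data, b.exp_volume.data)

    def test_emphysema_target_recovered_by_direct_count(self, still_phantom):
        b = still_phantom
        refs = b.config.refs
        # independent oracle: raw voxel count on the true fraction map
        for lobe, label in b.lobe_mask.labels.items():
            sel = b.lobe_mask.data == label
            direct = 100.0 * np.count_nonzero(
                b.true_beta_air_tlc.data[sel] > refs.emph_threshold
            ) / np.count_nonzero(sel)
            assert direct == pytest.approx(15.0, abs=0.5)
        measured = emphysema_percent(air_fraction(b.tlc_volume, refs), b.lobe_mask, refs)
        assert measured["whole_lung"] == pytest.approx(15.0, abs=0.5)

    def test_fraction_maps_bounded_and_mask_covers_blocks(self, deforming_phantom):
        b = deforming_phantom
        for m in (b.true_beta_air_tlc, b.true_beta_air_exp):
            assert np.all((m.data >= 0.0) & (m.data <= 1.0))
        n_block = sum(
            np.prod([hi - lo for lo, hi in block]) for block in b.config.lobe_layout.values()
        )
        assert np.count_nonzero(b.lobe_mask.data) == n_block

    def test_noninvertible_deformation_rejected(self):
        bad = DeformationSpec(sin_amplitude_mm=(30.0, 0.0, 0.0), sin_period_mm=(40.0, 64.0, 64.0))
        with pytest.raises(ValueError, match="not invertible"):
            generate_phantom_pair(PhantomConfig(deformation_spec=bad))

    def test_overlapping_lobes_rejected(self):
        layout = {"LUL": ((4, 20), (4, 20), (4, 20)), "LLL": ((10, 26), (4, 20), (4, 20))}
        with pytest.raises(ValueError, match="overlap"):
            PhantomConfig(lobe_layout=layout).validate()

    def test_tissue_mass_conserved_under_rigid_translation(self):
        # one-voxel translation: pull-back is exact, J = 1, whole-grid tissue
        # volume must agree to well under 0.1%
        cfg = PhantomConfig(
            deformation_spec=DeformationSpec(translation_mm=(2.0, 0.0, 0.0)),
            noise_sd_hu=0.0,
            seed=5,
        )
        b = generate_phantom_pair(cfg)
        t_insp = float(np.sum(1.0 - b.true_beta_air_tlc.data))
        t_exp = float(np.sum(1.0 - b.true_beta_air_exp.data))
        assert abs(t_exp / t_insp - 1.0) < 1e-3

    def test_expansion_jacobian_matches_volume_ratio(self):
        cfg = PhantomConfig(
            deformation_spec=DeformationSpec(affine=uniform_expansion(1.3)),
            noise_sd_hu=0.0,
            seed=6,
        )
        b = generate_phantom_pair(cfg)
        assert b.true_jacobian == pytest.approx(np.full(b.true_jacobian.shape, 1.3), rel=1e-12)


class TestAirwayTable:
    def test_completeness_all_subjects_all_regions(self):
        table = generate_airway_table(CohortConfig(n_per_group=3, seed=1))
        assert table["subject_id"].nunique() == 9
        counts = table.groupby("subject_id")["region"].nunique()
        assert (counts == 10).all()
        assert set(table["region"]) == set(AIRWAY_REGIONS)

    def test_seed_fixed_identical_table(self):
        a = generate_airway_table(CohortConfig(n_per_group=4, seed=9))
        b = generate_airway_table(CohortConfig(n_per_group=4, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_copd_luminal_narrowing_shows_in_dh_star(self):
        table = generate_airway_table(CohortConfig(n_per_group=40, seed=2))
        demo = table.drop_duplicates("subject_id")[["subject_id", "group", "sex", "age", "height"]]
        trachea = branch_metrics(table[table["region"] == "trachea"])
        tr = trachea.groupby("subject_id")[["Dh"]].mean().reset_index().merge(demo, on="subject_id")
        ref = fit_trachea_reference(tr[tr["group"] == "healthy"], "Dh")
        summary = summarize_regions(table, demo, dh_reference=ref)
        sub = summary[summary["metric"] == "Dh_star"].merge(demo[["subject_id", "group"]], on="subject_id")
        means = sub.groupby("group")["value"].mean()
        assert means["COPD"] < means["healthy"]

    def test_isoperimetric_consistency_by_construction(self):
        table = generate_airway_table(CohortConfig(n_per_group=3, seed=4))
        # branch_metrics would raise on any isoperimetric violation
        out = branch_metrics(table)
        assert (out["Cr"] <= 1.0).all() and (out["Cr"] > 0.0).all()


class TestCohortMetrics:
    def test_configured_ordering_of_group_means(self):
        metrics = generate_cohort_metrics(CohortConfig(n_per_group=100, seed=7))
        m = metrics[metrics["metric"] == "fSAD_pct"].groupby("group")["value"].mean()
        assert m["healthy"] < m["asthma"] < m["COPD"]
        j = metrics[metrics["metric"] == "Jacobian"].groupby("group")["value"].mean()
        assert j["COPD"] < j["asthma"] < j["healthy"]

    def test_unknown_metric_in_effect_table_rejected(self):
        cfg = CohortConfig(effect_table={"not_a_metric": {"COPD": {"shift": 1.0}}})
        with pytest.raises(ValueError, match="unknown metric"):
            generate_cohort_metrics(cfg)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n_per_group"):
            generate_cohort_metrics(CohortConfig(n_per_group=0))

    def test_determinism_and_substream_independence(self):
        a = generate_cohort_metrics(CohortConfig(n_per_group=5, seed=3))
        b = generate_cohort_metrics(CohortConfig(n_per_group=5, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_null_family_has_requested_width(self):
        cfg = null_family_config(n_tests=87, n_per_group=5, seed=1)
        metrics = generate_cohort_metrics(cfg)
        assert metrics.groupby(["metric", "region"]).ngroups == 87

    def test_dvair_fractions_sum_to_one_per_subject(self):
        metrics = generate_cohort_metrics(CohortConfig(n_per_group=5, seed=8))
        dv = metrics[metrics["metric"] == "dVair_f"]
        sums = dv.groupby("subject_id")["value"].sum().to_numpy()
        assert sums == pytest.approx(np.ones(len(sums)))
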