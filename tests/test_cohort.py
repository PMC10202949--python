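"""Cohort generator: latent-burden links, calibrated preset, determinism."""

import math

import numpy as np
import pytest

from hpcsi.acquisition import AcquisitionParams
from hpcsi.cohort import (EAELink, GroupSpec, MarkerLink, StudySpec,
                          designed_fold_changes, generate_study,
                          cpz_eae_preset, sample_animal)
from hpcsi.kinetics import auc_ratio_theory
from hpcsi.phantom import default_phantom


def make_group(**kw) -> GroupSpec:
    defaults = dict(name="g", n_animals=4, burden_mean=0.0, burden_sd=0.25)
    defaults.update(kw)
    return GroupSpec(**defaults)


class TestSampleAnimal:
    def test_degenerate_spec_gives_identical_animals(self, phantom):
        spec = make_group(burden_sd=0.0, kpl_log_slope=0.0,
                          markers={"pdh": MarkerLink(5.0)},
                          lesion=MarkerLink(0.4))
        a = sample_animal(spec, phantom, seed=1)
        b = sample_animal(spec, phantom, seed=2)
        assert a.record.burden == b.record.burden
        assert a.record.kpl_brain == b.record.kpl_brain
        assert a.record.markers == b.record.markers
        assert a.record.eae_score == b.record.eae_score == 0

    def test_all_zero_category_law_gives_zero_scores(self, phantom):
        """A treatment arm designed to fully prevent impairment."""
        spec = make_group(burden_mean=2.0, eae=EAELink.all_zero())
        scores = [sample_animal(spec, phantom, seed=s).record.eae_score
                  for s in range(50)]
        assert scores == [0] * 50

    def test_latent_correlation_matches_closed_form(self, phantom):
        """corr(log kPL, marker) from the shared-latent construction.

        log kPL = log k0 + beta*b exactly; marker = a + gamma*b + noise.
        The bivariate-normal closed form gives
        corr = gamma*sd_b / sqrt(gamma^2 sd_b^2 + s^2).
        """
        beta, gamma, s, sd_b = 0.5, 2.0, 1.0, 0.5
        spec = make_group(burden_sd=sd_b, kpl_log_slope=beta,
                          markers={"iba1": MarkerLink(20.0, gamma, s)})
        log_kpl, iba1 = [], []
        for seed in range(500):
            rec = sample_animal(spec, phantom, seed=seed).record
            log_kpl.append(math.log(rec.kpl_brain))
            iba1.append(rec.markers["iba1"])
        expected = gamma * sd_b / math.sqrt((gamma * sd_b) ** 2 + s ** 2)
        observed = np.corrcoef(log_kpl, iba1)[0, 1]
        assert observed > 0
        assert abs(observed - expected) < 0.05

    def test_censoring_caps_scores_at_four(self, phantom):
        spec = make_group(eae=EAELink(probs=(0, 0, 0, 0, 0, 0.5, 0.5)))
        for seed in range(20):
            rec = sample_animal(spec, phantom, seed=seed).record
            assert rec.eae_score == 4
            assert rec.censored

    def test_censoring_flag_requires_high_score(self, phantom):
        spec = make_group(eae=EAELink(probs=(0, 1.0, 0, 0, 0, 0, 0)))
        rec = sample_animal(spec, phantom, seed=0).record
        assert rec.eae_score == 1 and not rec.censored

    def test_vascular_kpl_untouched(self, phantom):
        spec = make_group(burden_mean=2.0, kpl_log_slope=1.0)
        a = sample_animal(spec, phantom, seed=3)
        kpl = a.phantom.kpl_map()
        assert np.all(kpl[a.phantom.vascular_mask] == 0.0)
        assert kpl[a.phantom.brain_mask].max() > 0.029

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            make_group(n_animals=0)
        with pytest.raises(ValueError):
            make_group(markers={"nope": MarkerLink(1.0)})
        with pytest.raises(ValueError):
            EAELink(probs=(0.5, 0.5, 0.5, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            MarkerLink(1.0, noise_sd=-0.1)


class TestGenerateStudy:
    def test_group_sizes_match_designed_preset(self):
        spec = cpz_eae_preset(seed=0)
        study = generate_study(spec, simulate=False)
        counts = study.ground_truth_table().group.value_counts()
        assert counts["control"] == 14
        assert counts["cpz_eae"] == 12
        assert counts["cpz_eae_dmf"] == 11
        assert counts["cpz_eae_fty720"] == 14

    def test_master_seed_determinism(self):
        spec = cpz_eae_preset(seed=5)
        s1 = generate_study(spec, simulate=True)
        s2 = generate_study(spec, simulate=True)
        t1, t2 = s1.ground_truth_table(), s2.ground_truth_table()
        assert t1.equals(t2)
        assert np.array_equal(s1.animals[0].dataset.kspace,
                              s2.animals[0].dataset.kspace)

    def test_duplicate_group_names_rejected(self):
        g = make_group(name="dup")
        with pytest.raises(ValueError):
            StudySpec(groups=(g, g))

    def test_group_mean_kpl_within_three_se(self, phantom):
        """Law of large numbers: lognormal kPL mean recovered at n = 200."""
        beta, b_mean, sd_b = 0.74, 1.0, 0.25
        spec = StudySpec(
            groups=(make_group(name="g", n_animals=200, burden_mean=b_mean,
                               burden_sd=sd_b, kpl_log_slope=beta),),
            phantom_template=phantom, master_seed=12,
        )
        table = generate_study(spec, simulate=False).ground_truth_table()
        expected = 0.029 * math.exp(beta * b_mean + (beta * sd_b) ** 2 / 2)
        se = table.kpl_brain.std(ddof=1) / math.sqrt(len(table))
        assert abs(table.kpl_brain.mean() - expected) < 3 * se


class TestCalibratedPreset:
    def test_designed_contrasts(self):
        folds = designed_fold_changes(cpz_eae_preset())
        assert folds["lacpyr_disease_vs_control"] == pytest.approx(2.1, abs=1e-4)
        assert folds["lacpyr_decrease_cpz_eae_dmf"] == pytest.approx(1.31, abs=1e-3)
        assert folds["lacpyr_decrease_cpz_eae_fty720"] == pytest.approx(1.35, abs=1e-3)
        assert folds["lesion_disease_vs_control"] == pytest.approx(5.2, abs=1e-6)

    def test_control_ratio_equals_kinetic_closed_form(self, acq):
        """Designed control lac/pyr = kPL/(R1_lac + lambda_RF) at base kPL."""
        spec = cpz_eae_preset()
        kin = None
        ph = spec.phantom_template
        for row, mrow in zip(ph.kinetics, ph.brain_mask):
            for k, m in zip(row, mrow):
                if m:
                    kin = k
        lam = -math.log(math.cos(math.radians(10.0))) / 0.06
        expected = 0.029 / (1.0 / 30.0 + lam)
        assert auc_ratio_theory(kin, acq) == pytest.approx(expected, rel=1e-9)

    def test_marker_sign_constraints_disease_vs_control(self):
        """Immune/injury markers rise with burden; PDH and myelin fall."""
        spec = cpz_eae_preset()
        ctl, dis = spec.group("control"), spec.group("cpz_eae")
        up = ("iba1", "cd68", "cd3", "pdk1", "gfap", "fibrinogen")
        for m in up:
            assert dis.markers[m].mean(dis.burden_mean) > \
                ctl.markers[m].mean(ctl.burden_mean)
            assert dis.markers[m].slope > 0
        for m in ("pdh", "myelin"):
            assert dis.markers[m].mean(dis.burden_mean) < \
                ctl.markers[m].mean(ctl.burden_mean)
            assert dis.markers[m].slope < 0

    def test_expected_eae_means_hit_targets(self):
        spec = cpz_eae_preset()
        dis = spec.group("cpz_eae")
        dmf = spec.group("cpz_eae_dmf")
        assert dis.eae.expected_score(dis.burden_mean, dis.burden_sd) == \
            pytest.approx(2.6, abs=1e-6)
        assert dmf.eae.expected_score(dmf.burden_mean, dmf.burden_sd) == \
            pytest.approx(1.1, abs=1e-6)

    def test_large_simulation_recovers_designed_folds(self):
        """2000 animals per arm reproduce the designed contrasts within 2%.

        lac/pyr is linear in kPL, so the designed fold equals the ratio
        of group-mean kPL.
        """
        spec = cpz_eae_preset(
            seed=21, n_override={g: 2000 for g in
                                 ("control", "cpz_eae", "cpz_eae_dmf",
                                  "cpz_eae_fty720")})
        table = generate_study(spec, simulate=False).ground_truth_table()
        mean_kpl = table.groupby("group").kpl_brain.mean()
        assert mean_kpl["cpz_eae"] / mean_kpl["control"] == \
            pytest.approx(2.1, rel=0.02)
        assert mean_kpl["cpz_eae"] / mean_kpl["cpz_eae_dmf"] == \
            pytest.approx(1.31, rel=0.02)
        assert mean_kpl["cpz_eae"] / mean_kpl["cpz_eae_fty720"] == \
            pytest.approx(1.35, rel=0.02)
        mean_lesion = table.groupby("group").lesion_volume_mm3.mean()
        assert mean_lesion["cpz_eae"] / mean_lesion["control"] == \
            pytest.approx(5.2, rel=0.02)

    def test_shared_link_marker_means_monotone_in_burden(self, phantom):
        """Under a shared link, expected marker means follow group burden."""
        shared_up = MarkerLink(intercept=5.0, slope=3.0, noise_sd=0.5)
        shared_down = MarkerLink(intercept=8.0, slope=-2.0, noise_sd=0.5)
        means_up, means_down = [], []
        for b in (0.0, 0.5, 1.0):
            means_up.append(shared_up.mean(b))
            means_down.append(shared_down.mean(b))
        assert means_up[0] < means_up[1] < means_up[2]
        assert means_down[0] > means_down[1] > means_down[2]
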