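"""Synthetic-trial generator: design counts, distributions, titration."""

import numpy as np
import pytest

import nafamopk as nk
from nafamopk.dataset import ObsKind, ValidationError
from nafamopk.synth import StudyDesign, generate_covariates, generate_study, titrate


class TestTitrationPolicy:
    def test_inside_target_unchanged(self):
        assert titrate(15.0, 60.0, (40.0, 80.0)) == 15.0

    def test_below_target_steps_up(self):
        assert titrate(15.0, 30.0, (40.0, 80.0)) == 20.0

    def test_above_target_floors_at_five(self):
        assert titrate(10.0, 95.0, (40.0, 80.0)) == 5.0
        assert titrate(7.0, 95.0, (40.0, 80.0)) == 5.0

    def test_requires_positive_rate(self):
        with pytest.raises(ValidationError):
            titrate(0.0, 50.0)


class TestCovariates:
    def test_seeded_determinism(self):
        a = generate_covariates(10, rng_seed=5)
        b = generate_covariates(10, rng_seed=5)
        assert a == b

    def test_gas_flow_median_matches_population(self):
        covs = generate_covariates(10_000, rng_seed=1)
        med = np.median([c["gas_flow_rate"] for c in covs])
        assert med == pytest.approx(3.75, rel=0.10)

    def test_ecmo_type_proportions(self):
        covs = generate_covariates(10_000, rng_seed=2)
        va = np.mean([c["ecmo_type"] == "VA" for c in covs])
        assert va == pytest.approx(13 / 24, abs=0.02)

    def test_gas_flow_within_plausible_range(self):
        covs = generate_covariates(5000, rng_seed=3)
        g = np.array([c["gas_flow_rate"] for c in covs])
        assert g.min() >= 0.5 and g.max() <= 12.0


@pytest.fixture(scope="module")
def clean_design_study(patient_model, ecmo_model):
    design = StudyDesign(titration="none", dropout_prob=0.0)
    return generate_study(design, patient_model, ecmo_model, rng_seed=21)


class TestGenerateStudy:
    def test_planned_observation_counts(self, clean_design_study):
        ds_p, ds_e, _ = clean_design_study
        for ds in (ds_p, ds_e):
            assert ds.n_observations(ObsKind.CONCENTRATION) == 24 * 7
            assert ds.n_observations(ObsKind.APTT) == 24 * 3

    def test_predose_records_are_blq(self, clean_design_study):
        ds_p, _, _ = clean_design_study
        for s in ds_p.subjects:
            predose = [o for o in s.observations_of(ObsKind.CONCENTRATION)
                       if o.time == 0.0]
            assert len(predose) == 1 and predose[0].blq

    def test_post_filter_count(self, clean_design_study):
        ds_p, _, _ = clean_design_study
        res = nk.filter_blq(ds_p)
        assert res.dataset.n_observations(ObsKind.CONCENTRATION) == 168 - 24

    def test_datasets_pass_validation_by_construction(self, synthetic_study):
        ds_p, ds_e, _ = synthetic_study
        ds_p.validate()
        ds_e.validate()
        assert ds_p.site is nk.Site.PATIENT and ds_e.site is nk.Site.ECMO

    def test_ground_truth_replays_observations(self, patient_model, ecmo_model):
        """Noise-free profiles from the truth record plus the residual draws
        reproduce the stored observations (replayability at the profile
        level: regenerate with the same seed and compare)."""
        design = StudyDesign()
        a = generate_study(design, patient_model, ecmo_model, rng_seed=33)
        b = generate_study(design, patient_model, ecmo_model, rng_seed=33)
        for ds_a, ds_b in ((a[0], b[0]), (a[1], b[1])):
            for sa, sb in zip(ds_a.subjects, ds_b.subjects):
                assert [o.value for o in sa.observations] == [
                    o.value for o in sb.observations
                ]
        assert a[2].individual_params == b[2].individual_params

    def test_shared_dose_history_across_sites(self, synthetic_study):
        ds_p, ds_e, _ = synthetic_study
        for sp, se in zip(ds_p.subjects, ds_e.subjects):
            assert [(d.start_time, d.end_time, d.rate) for d in sp.doses] == [
                (d.start_time, d.end_time, d.rate) for d in se.doses
            ]

    def test_titration_raises_rate_for_below_target_subjects(
        self, patient_model, ecmo_model
    ):
        """Subjects whose interim circuit aPTT sits below 40 s get +5 mg/h."""
        design = StudyDesign(dropout_prob=0.0)
        _, ds_e, truth = generate_study(design, patient_model, ecmo_model,
                                        rng_seed=2)
        n_changed = 0
        for sid, segs in truth.dose_events.items():
            rates = [r for (_, _, r) in segs]
            assert all(r >= 5.0 for r in rates)
            assert abs(rates[0] - 15.0) < 1e-12
            if len(set(rates)) > 1:
                n_changed += 1
            for r0, r1 in zip(rates, rates[1:]):
                assert abs(r1 - r0) in (0.0, 5.0)
        # the published truth puts the typical circuit aPTT below target,
        # so a substantial share of subjects must have been up-titrated
        assert n_changed >= 8

    def test_dropout_thins_records(self, patient_model, ecmo_model):
        design = StudyDesign(titration="none", dropout_prob=0.3)
        ds_p, _, _ = generate_study(design, patient_model, ecmo_model, rng_seed=9)
        assert ds_p.n_observations(ObsKind.CONCENTRATION) < 24 * 7

    def test_design_validation(self):
        with pytest.raises(ValidationError):
            StudyDesign(dropout_prob=1.5)
        with pytest.raises(ValidationError):
            StudyDesign(titration="aggressive")


DENSE_PK_MINUTES = tuple(
    float(x)
    for x in (0, 2, 3, 4, 6, 8, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240,
              300, 360, 420, 480)
)

ECMO_TRUTH = {"cl": 85.2, "v1": 3.83, "q": 46.7, "v2": 36.8}


class TestRecoveryAtInflatedN:
    """100 subjects with dense sampling: structural parameters recover.

    Under the published fixture, V1 (62.8% IIV fixed at truth, informed
    only by the first minutes of the profile) shows a genuine upward
    shrinkage-related bias under conditional estimation, and Q (134% fixed
    IIV, 46.9% reported RSE) is too noisy for its 10-replicate median to
    sit reliably inside 10%; the median-bias check under the published
    truth therefore covers CL and V2.  A companion check without the
    extreme fixed IIVs shows the estimator itself is unbiased for all
    four parameters.
    """

    def _biases(self, truth_model, fit_model, seeds, fast_settings,
                patient_model):
        errs = {k: [] for k in ECMO_TRUTH}
        for seed in seeds:
            design = StudyDesign(n_subjects=100, titration="none",
                                 dropout_prob=0.0,
                                 pk_sample_times=DENSE_PK_MINUTES)
            _, ds_e, _ = generate_study(design, patient_model, truth_model,
                                        rng_seed=seed)
            fr = nk.fit(nk.filter_blq(ds_e).dataset, fit_model, "pk",
                        fast_settings)
            for k in errs:
                errs[k].append(fr.estimates[k] / ECMO_TRUTH[k] - 1.0)
        return {k: float(np.median(v)) for k, v in errs.items()}

    def test_identified_parameters_under_published_truth(self, ecmo_model,
                                                         patient_model,
                                                         fast_settings):
        med = self._biases(ecmo_model, ecmo_model, range(100, 110),
                           fast_settings, patient_model)
        for k in ("cl", "v2"):
            assert abs(med[k]) < 0.10, (k, med)

    def test_all_parameters_without_extreme_fixed_iiv(self, ecmo_model,
                                                      patient_model,
                                                      fast_settings):
        m = ecmo_model.copy()
        m.omega.omega2["v1"] = 0.0
        m.omega.omega2["q"] = 0.0
        med = self._biases(m, m, range(100, 105), fast_settings, patient_model)
        for k in ECMO_TRUTH:
            assert abs(med[k]) < 0.10, (k, med)
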