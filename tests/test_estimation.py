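"""FOCEI machinery: MAP etas, OFV vs quadrature, fitting, LRT, bootstrap."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import nafamopk as nk
from nafamopk.dataset import (
    DoseEvent,
    Observation,
    ObsKind,
    Site,
    StudyDataset,
    Subject,
    ValidationError,
)
from nafamopk.estimation import (
    FitSettings,
    PKProblem,
    _model_values,
    fit,
    focei_ofv,
    lrt,
    map_eta,
    sequential_pd_fit,
)
from nafamopk.population import (
    ErrorKind,
    OmegaSpec,
    PopulationModel,
    ResidualErrorModel,
)
from nafamopk.pk import PKParameters


def toy_model(omega2_cl=0.09, sigma_add=5.0, cl=100.0):
    """One-compartment-like toy: eta on CL only, additive error."""
    return PopulationModel(
        name="toy",
        pk=PKParameters(cl=cl, v1=10.0, q=20.0, v2=30.0),
        omega=OmegaSpec({"cl": omega2_cl, "v1": 0.0, "q": 0.0, "v2": 0.0},
                        {"cl": False, "v1": True, "q": True, "v2": True}),
        ruv_pk=ResidualErrorModel(ErrorKind.ADDITIVE, sigma_add=sigma_add),
        pk_fixed=frozenset({"q", "v2"}),
    )


def toy_subject(values, times=(2.0, 4.0, 6.0), sid="T1"):
    obs = [Observation(t, v, ObsKind.CONCENTRATION) for t, v in zip(times, values)]
    return Subject(
        id=sid, site=Site.PATIENT,
        doses=[DoseEvent(0.0, np.inf, 30.0)], observations=list(obs),
    )


def quadrature_minus2ll(ds, model):
    """-2 log marginal likelihood by adaptive quadrature (1-eta models).

    The integrand is exponent-shifted by its maximum on a dense grid so
    the quadrature stays in range even when the joint density is tiny.
    """
    total = 0.0
    for s in ds.subjects:
        prob = PKProblem(StudyDataset(subjects=[s]), model)
        values = _model_values(model, "pk")
        w2 = model.omega.omega2["cl"]
        sd = math.sqrt(w2)
        y = prob.obs_y

        def logjoint(eta):
            f = prob.predict(values, np.array([[eta]]))
            v = prob._variance(f, values)
            ll = -0.5 * np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v)
            return ll + stats.norm.logpdf(eta, 0.0, sd)

        grid = np.linspace(-8 * sd, 8 * sd, 400)
        lj = np.array([logjoint(e) for e in grid])
        shift = float(lj.max())
        peak = float(grid[int(lj.argmax())])
        L, _ = integrate.quad(
            lambda e: math.exp(logjoint(e) - shift),
            -8 * sd, 8 * sd, limit=200, points=[peak],
        )
        total += -2.0 * (math.log(L) + shift)
    return total


class TestMapEta:
    def test_no_observations_is_error(self, patient_model):
        s = Subject(id="S1", site=Site.PATIENT,
                    doses=[DoseEvent(0.0, 8.0, 15.0)])
        with pytest.raises(ValidationError, match="no usable"):
            map_eta(s, patient_model, "pk")

    def test_infinite_shrinkage_limit(self):
        model = toy_model(omega2_cl=1e-10)
        s = toy_subject([200.0, 250.0, 300.0])  # data wildly off-prediction
        eta = map_eta(s, model, "pk")
        assert abs(eta["cl"]) < 1e-3

    def test_recovers_known_eta_from_rich_noiseless_data(self):
        truth_eta = 0.4
        model = toy_model(omega2_cl=4.0, sigma_add=0.01)  # weak prior, tiny noise
        pk_i = PKParameters(cl=100.0 * math.exp(truth_eta), v1=10.0, q=20.0, v2=30.0)
        times = tuple(np.linspace(0.5, 8.0, 12))
        doses = [DoseEvent(0.0, np.inf, 30.0)]
        values = [nk.concentration(pk_i, doses, t) for t in times]
        s = toy_subject(values, times=times)
        eta = map_eta(s, model, "pk")
        assert eta["cl"] == pytest.approx(truth_eta, abs=1e-3)


class TestOfv:
    def test_extended_least_squares_limit(self):
        """omega -> 0: OFV reduces to sum(log v + r^2/v)."""
        model = toy_model(omega2_cl=1e-14)
        s = toy_subject([210.0, 240.0, 260.0])
        ds = StudyDataset(subjects=[s])
        ofv = focei_ofv(ds, model, "pk")
        prob = PKProblem(ds, model)
        values = _model_values(model, "pk")
        f = prob.predict(values, np.zeros((1, 1)))
        v = prob._variance(f, values)
        els = float(np.sum(np.log(v) + (prob.obs_y - f) ** 2 / v))
        assert ofv == pytest.approx(els, abs=1e-6)

    def test_matches_quadrature_on_one_eta_toy(self):
        model = toy_model(omega2_cl=0.09)
        rng = np.random.default_rng(5)
        subjects = []
        for i in range(5):
            eta = rng.normal(0, 0.3)
            pk_i = PKParameters(cl=100 * math.exp(eta), v1=10.0, q=20.0, v2=30.0)
            doses = [DoseEvent(0.0, np.inf, 30.0)]
            vals = [
                nk.concentration(pk_i, doses, t) + rng.normal(0, 5.0)
                for t in (2.0, 4.0, 6.0)
            ]
            subjects.append(toy_subject([max(v, 1.0) for v in vals], sid=f"T{i}"))
        ds = StudyDataset(subjects=subjects)
        ofv = focei_ofv(ds, model, "pk")
        oracle = quadrature_minus2ll(ds, model)
        n_obs = 15
        assert ofv + n_obs * math.log(2 * math.pi) == pytest.approx(oracle, abs=0.1)

    def test_nested_model_never_has_lower_ofv(self, synthetic_study, ecmo_model,
                                              fast_settings):
        """Freeing an extra parameter cannot worsen the optimum."""
        _, ds_e, _ = synthetic_study
        ds = nk.filter_blq(ds_e).dataset
        reduced_model = ecmo_model.copy()
        from dataclasses import replace

        reduced_model.pk = replace(reduced_model.pk, cov_gasflow_cl=0.0)
        reduced_model.estimated_covariates = frozenset()
        fr_red = fit(ds, reduced_model, "pk", fast_settings)
        full_model = ecmo_model.copy()
        full_model.pk = replace(full_model.pk, cov_gasflow_cl=0.0)
        fr_full = fit(ds, full_model, "pk", fast_settings,
                      init=dict(fr_red.estimates))
        assert fr_full.ofv <= fr_red.ofv + 0.1


class TestErrorModelSelection:
    def test_proportional_data_prefers_proportional_ruv(self, patient_model,
                                                        ecmo_model,
                                                        fast_settings):
        """Data simulated with proportional error: the proportional RUV
        candidate beats the additive one on OFV in every replicate."""
        from nafamopk.synth import StudyDesign

        wins = 0
        n_rep = 4
        for seed in range(1, n_rep + 1):
            ds_p, _, _ = nk.generate_study(
                StudyDesign(titration="none"), patient_model, ecmo_model,
                rng_seed=40 + seed,
            )
            ds = nk.filter_blq(ds_p).dataset
            prop_fit = fit(ds, patient_model, "pk", fast_settings)
            add_model = patient_model.copy()
            add_model.ruv_pk = ResidualErrorModel(
                ErrorKind.ADDITIVE, sigma_add=30.0
            )
            add_fit = fit(ds, add_model, "pk", fast_settings)
            wins += prop_fit.ofv < add_fit.ofv
        assert wins == n_rep


class TestFit:
    def test_refit_at_optimum_is_stable(self, synthetic_study, patient_model):
        ds = nk.filter_blq(synthetic_study[0]).dataset
        settings = FitSettings(maxfev=600, compute_se=False)
        fr1 = fit(ds, patient_model, "pk", settings)
        fr2 = fit(ds, fr1.model, "pk", settings, init=dict(fr1.estimates))
        assert abs(fr2.ofv - fr1.ofv) < 0.01
        # fixed-parameter masks are never violated by fitting
        assert fr1.model.pk.q == 350.0
        assert fr1.model.omega.omega2["v1"] == patient_model.omega.omega2["v1"]

    def test_standard_errors_reported_for_free_parameters(self, synthetic_study,
                                                          patient_model):
        ds = nk.filter_blq(synthetic_study[0]).dataset
        fr = fit(ds, patient_model, "pk",
                 FitSettings(maxfev=400, compute_se=True))
        assert set(fr.standard_errors) == set(fr.estimates)
        assert all(np.isfinite(v) for v in fr.rse_percent.values())
        # RSE convention: structural = 100*SE/est
        cl_rse = 100 * fr.standard_errors["cl"] / fr.estimates["cl"]
        assert fr.rse_percent["cl"] == pytest.approx(cl_rse)
        # variance parameters use the SD-scale halving convention
        w2 = fr.estimates["omega2_cl"]
        assert fr.rse_percent["omega2_cl"] == pytest.approx(
            100 * fr.standard_errors["omega2_cl"] / w2 / 2
        )

    def test_empty_dataset_rejected(self, patient_model):
        with pytest.raises(ValidationError):
            fit(StudyDataset(subjects=[]), patient_model, "pk")


class TestSequentialPdFit:
    def test_free_parameter_mask(self, patient_model):
        from nafamopk.estimation import _free_names

        free = _free_names(patient_model, "pd")
        assert set(free) == {"imax", "kin", "base", "omega2_kin", "omega2_base",
                             "sigma_add"}

    def test_missing_subject_is_error(self, synthetic_study, patient_model,
                                      fast_settings):
        ds_p, _, truth = synthetic_study
        ipk = dict(truth.individual_params["patient"])
        ipk.pop("S01")
        with pytest.raises(ValidationError, match="S01"):
            sequential_pd_fit(nk.filter_blq(ds_p).dataset, ipk, patient_model,
                              fast_settings)

    def test_no_pd_observations_is_error(self, patient_model, fast_settings):
        s = toy_subject([100.0, 120.0, 130.0])  # concentrations only
        ds = StudyDataset(subjects=[s])
        with pytest.raises(ValidationError, match="no usable"):
            sequential_pd_fit(
                ds, {"T1": {"cl": 189.0, "v1": 7.0, "q": 350.0, "v2": 55.0}},
                patient_model, fast_settings,
            )


class TestLrt:
    def test_reported_thresholds(self):
        assert lrt(0.0, 4.0, 1, 0.05).threshold == pytest.approx(3.84, abs=0.005)
        assert lrt(0.0, 6.5, 2, 0.05).threshold == pytest.approx(5.99, abs=0.005)
        assert lrt(0.0, 7.0, 1, 0.01).threshold == pytest.approx(6.63, abs=0.005)
        assert lrt(0.0, 11.0, 1, 0.001).threshold == pytest.approx(10.8, abs=0.03)

    def test_decisions(self):
        assert lrt(100.0, 104.0, 1, 0.05).significant
        assert not lrt(100.0, 106.5, 1, 0.01).significant  # needs > 6.63
        assert not lrt(100.0, 100.0, 1, 0.05).significant

    def test_ordering_error(self):
        with pytest.raises(ValidationError):
            lrt(100.0, 98.0, 1, 0.05)
        with pytest.raises(ValidationError):
            lrt(100.0, 104.0, 0, 0.05)


class TestBootstrap:
    def test_zero_replicates_rejected(self, synthetic_study, patient_model):
        ds = nk.filter_blq(synthetic_study[0]).dataset
        with pytest.raises(ValidationError):
            nk.bootstrap(ds, patient_model, 0, rng_seed=1)

    def test_identity_replicate_matches_point_fit(self, synthetic_study,
                                                  patient_model, fast_settings):
        """A replicate equal to the original data reproduces the fit."""
        from nafamopk.dataset import replace_subject

        ds = nk.filter_blq(synthetic_study[0]).dataset
        fr = fit(ds, patient_model, "pk", fast_settings)
        clone = StudyDataset(
            subjects=[replace_subject(s, id=f"{s.id}#0") for s in ds.subjects]
        )
        fr2 = fit(ds=clone, model=patient_model, which="pk",
                  settings=fast_settings, init=dict(fr.estimates))
        assert fr2.estimates["cl"] == pytest.approx(fr.estimates["cl"], rel=0.02)
        assert abs(fr2.ofv - fr.ofv) < 0.05
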