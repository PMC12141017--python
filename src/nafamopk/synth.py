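"""Virtual-trial generator emulating the study design.

The study enrolled 24 ECMO patients on a continuous nafamostat infusion
started at 15 mg/h and titrated to an aPTT target of 40-80 s, with PK
samples predose and at 3, 6, 30, 120, 300 and 480 min from two sites
(patient central vein and ECMO circuit) and aPTT at predose, 240 and
480 min.  This module simulates that design from ground-truth population
models so every pipeline stage is testable without the raw clinical data;
the per-subject ground truth (etas, individual parameters, dose history)
is returned for recovery experiments and exact replay.

Per-site individual parameters are drawn independently (the two sampling
sites were fitted as independent models); the *dose history* is shared
between sites and, under the simple titration policy, reacts to the
simulated ECMO-circuit aPTT — regional anticoagulation targets the
circuit.  The titration rule itself (±5 mg/h steps, 5 mg/h floor, applied
at the 240-min aPTT draw) is a synthetic stand-in: the study reports that
titration happened but not the rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import (
    LLOQ_UG_PER_L,
    DoseEvent,
    Observation,
    ObsKind,
    Site,
    StudyDataset,
    Subject,
    ValidationError,
)
from .pd import aptt_profile_fast
from .pk import PKParameters, concentration_profile
from .population import PopulationModel, draw_individual

__all__ = ["StudyDesign", "generate_covariates", "generate_study", "titrate", "GroundTruth"]

#: Planned sampling schedules, minutes after infusion start.
PK_SAMPLE_MINUTES = (0.0, 3.0, 6.0, 30.0, 120.0, 300.0, 480.0)
PD_SAMPLE_MINUTES = (0.0, 240.0, 480.0)


@dataclass
class StudyDesign:
    """Trial-design knobs; defaults emulate the study protocol."""

    n_subjects: int = 24
    pk_sample_times: tuple = PK_SAMPLE_MINUTES  # minutes
    pd_sample_times: tuple = PD_SAMPLE_MINUTES  # minutes
    start_rate: float = 15.0  # mg/h
    titration: str = "simple"  # "none" | "simple"
    target_aptt: tuple = (40.0, 80.0)  # s
    dropout_prob: float = 0.04
    lloq: float = LLOQ_UG_PER_L
    covariates: dict = field(default_factory=dict)  # overrides for the sampler

    def __post_init__(self) -> None:
        for times in (self.pk_sample_times, self.pd_sample_times):
            if list(times) != sorted(times) or times[0] < 0:
                raise ValidationError("sample times must be sorted and non-negative")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValidationError("dropout_prob must lie in [0, 1)")
        if self.titration not in ("none", "simple"):
            raise ValidationError(f"unknown titration policy {self.titration!r}")


def titrate(current_rate: float, observed_aptt: float, target=(40.0, 80.0)) -> float:
    """Simple titration policy: ±5 mg/h toward the target, floor 5 mg/h."""
    if not current_rate > 0:
        raise ValidationError("current_rate must be > 0")
    lo, hi = target
    if observed_aptt < lo:
        return current_rate + 5.0
    if observed_aptt > hi:
        return max(current_rate - 5.0, 5.0)
    return current_rate


# -- covariate distributions (matched to the study population summaries) ----
#
# Gas flow rate: lognormal matched to mean 4.31 / SD 2.39 L/min, truncated
# to [0.5, 12]; its implied median ~3.77 sits on the reported median 3.75.
# The remaining covariates are generated only as candidate covariates for
# the search machinery and carry no effect in the truth models.

_GASFLOW_MEAN, _GASFLOW_SD = 4.31, 2.39
_GASFLOW_RANGE = (0.5, 12.0)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def generate_covariates(n: int, spec: dict | None = None, rng_seed=0) -> list[dict]:
    """Draw ``n`` covariate maps from the study-population distributions."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    spec = spec or {}
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    mu, sigma = _lognormal_params(
        spec.get("gasflow_mean", _GASFLOW_MEAN), spec.get("gasflow_sd", _GASFLOW_SD)
    )
    out = []
    for _ in range(n):
        g = float(np.exp(rng.normal(mu, sigma)))
        while not (_GASFLOW_RANGE[0] <= g <= _GASFLOW_RANGE[1]):
            g = float(np.exp(rng.normal(mu, sigma)))
        out.append(
            {
                "gas_flow_rate": g,
                "sex": "M" if rng.random() < 17 / 24 else "F",
                "age": float(np.clip(rng.normal(60.3, 12.1), 18.0, 95.0)),
                "weight": float(np.clip(rng.normal(70.3, 15.7), 35.0, 140.0)),
                "height": float(np.clip(rng.normal(167.0, 8.77), 140.0, 200.0)),
                "ecmo_type": "VA" if rng.random() < 13 / 24 else "VV",
                "fio2": float(np.clip(rng.normal(0.683, 0.175), 0.21, 1.0)),
            }
        )
    return out


@dataclass
class GroundTruth:
    """Everything needed to replay a generated study exactly."""

    individual_params: dict[str, dict[str, dict[str, float]]]  # site -> sid -> params
    dose_events: dict[str, list[tuple[float, float, float]]]  # sid -> (t0, t1, rate)
    covariates: dict[str, dict]
    seed: int


def _simulate_site(
    params: dict[str, float],
    doses: list[DoseEvent],
    t_pk_h: np.ndarray,
    t_pd_h: np.ndarray,
):
    """Noise-free profiles at the sampling times for one subject/site."""
    pk_i = PKParameters(cl=params["cl"], v1=params["v1"], q=params["q"], v2=params["v2"])
    conc = concentration_profile(pk_i, doses, t_pk_h)
    grid = np.unique(np.concatenate([np.arange(0.0, t_pd_h[-1] + 1e-9, 1.0 / 60.0), t_pd_h]))
    cp = concentration_profile(pk_i, doses, grid)
    aptt_grid = aptt_profile_fast(
        params["kin"],
        params["kin"] / params["base"],
        min(params["imax"], 1.0),
        params["ic50"],
        params["base"],
        cp[None, :],
        grid,
    )[0]
    idx = np.searchsorted(grid, t_pd_h)
    return conc, aptt_grid[idx]


def generate_study(
    design: StudyDesign,
    truth_patient: PopulationModel,
    truth_ecmo: PopulationModel,
    rng_seed: int = 0,
) -> tuple[StudyDataset, StudyDataset, GroundTruth]:
    """Generate one virtual trial: paired patient / ECMO-site datasets.

    Returns ``(patient_ds, ecmo_ds, truth)``.  Observations include
    residual error; concentrations below the LLOQ are kept with their
    ``blq`` flag set (filtering is the caller's decision).  Predose
    concentrations are zero and therefore BLQ by construction.
    """
    rng = np.random.default_rng(rng_seed)
    covs = generate_covariates(design.n_subjects, design.covariates, rng)
    t_pk = np.asarray(design.pk_sample_times, float) / 60.0
    t_pd = np.asarray(design.pd_sample_times, float) / 60.0
    end_h = max(t_pk[-1], t_pd[-1])

    site_models = {"patient": truth_patient, "ecmo": truth_ecmo}
    indiv: dict[str, dict[str, dict[str, float]]] = {"patient": {}, "ecmo": {}}
    dose_log: dict[str, list[tuple[float, float, float]]] = {}
    cov_log: dict[str, dict] = {}
    subjects: dict[str, list[Subject]] = {"patient": [], "ecmo": []}

    for i in range(design.n_subjects):
        sid = f"S{i + 1:02d}"
        cov_log[sid] = covs[i]
        params = {
            site: draw_individual(m, covs[i], rng) for site, m in site_models.items()
        }
        for site in params:
            indiv[site][sid] = params[site]

        # dose history: shared between sites; titration keys on the
        # simulated (noisy) ECMO-circuit aPTT at interim PD draws
        if design.titration == "none":
            doses = [DoseEvent(0.0, end_h, design.start_rate)]
        else:
            doses = []
            rate = design.start_rate
            seg_start = 0.0
            for t_adj in t_pd[(t_pd > 0) & (t_pd < end_h)]:
                doses.append(DoseEvent(seg_start, float(t_adj), rate))
                _, aptt_interim = _simulate_site(
                    params["ecmo"],
                    doses + [DoseEvent(float(t_adj), end_h, rate)],
                    t_pk[:1],
                    np.asarray([t_adj]),
                )
                observed = float(
                    aptt_interim[0]
                    + rng.normal(0.0, truth_ecmo.ruv_pd.sigma_add)
                )
                rate = titrate(rate, observed, design.target_aptt)
                seg_start = float(t_adj)
            doses.append(DoseEvent(seg_start, end_h, rate))
        dose_log[sid] = [(d.start_time, d.end_time, d.rate) for d in doses]

        for site, model in site_models.items():
            conc, aptt = _simulate_site(params[site], doses, t_pk, t_pd)
            obs: list[Observation] = []
            for t, f in zip(t_pk, conc):
                if rng.random() < design.dropout_prob:
                    continue
                y = f * (1.0 + rng.normal(0.0, model.ruv_pk.sigma_prop))
                y = max(y, 0.0)
                obs.append(
                    Observation(
                        time=float(t),
                        value=float(y),
                        kind=ObsKind.CONCENTRATION,
                        blq=bool(y < design.lloq),
                    )
                )
            for t, f in zip(t_pd, aptt):
                if rng.random() < design.dropout_prob:
                    continue
                y = max(f + rng.normal(0.0, model.ruv_pd.sigma_add), 0.0)
                obs.append(Observation(time=float(t), value=float(y), kind=ObsKind.APTT))
            obs.sort(key=lambda o: o.time)
            subjects[site].append(
                Subject(
                    id=sid,
                    site=Site(site),
                    covariates=dict(covs[i]),
                    doses=list(doses),
                    observations=obs,
                )
            )

    truth = GroundTruth(
        individual_params=indiv,
        dose_events=dose_log,
        covariates=cov_log,
        seed=int(rng_seed),
    )
    return (
        StudyDataset(subjects=subjects["patient"]),
        StudyDataset(subjects=subjects["ecmo"]),
        truth,
    )
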