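"""Random-effects layer: lognormal IIV, residual error, model containers.

Inter-individual variability follows the multiplicative convention
``theta_i = theta * exp(eta_i)`` with ``eta ~ N(0, omega^2)`` drawn
independently per parameter (diagonal Omega).  Omega magnitudes are
reported as percent = 100*sqrt(omega^2), the usual approximate CV on the
log scale; the conversion is exact and bijective.

Residual unexplained variability supports additive, proportional and
combined error models with variance sigma_add^2 + f^2 * sigma_prop^2.
"""

from __future__ import annotations

import importlib.resources
import math
import tomllib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .dataset import ValidationError
from .pd import PDParameters
from .pk import PKParameters, apply_pk_covariates

__all__ = [
    "OmegaSpec",
    "ErrorKind",
    "ResidualErrorModel",
    "PopulationModel",
    "percent_to_variance",
    "variance_to_percent",
    "draw_individual",
    "apply_ruv",
    "load_model",
    "available_models",
]

PK_PARAM_NAMES = ("cl", "v1", "q", "v2")
PD_PARAM_NAMES = ("imax", "ic50", "kin", "base")


def percent_to_variance(percent: float) -> float:
    """omega% -> omega^2 on the log scale (61.3 -> 0.613^2)."""
    return (percent / 100.0) ** 2


def variance_to_percent(omega2: float) -> float:
    return 100.0 * math.sqrt(omega2)


@dataclass
class OmegaSpec:
    """Diagonal IIV specification: parameter -> (omega^2, fixed flag).

    ``omega2 == 0`` means no IIV on that parameter (no eta is drawn or
    estimated for it); a fixed nonzero omega2 contributes IIV but is held
    constant during fitting.
    """

    omega2: dict[str, float] = field(default_factory=dict)
    fixed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.omega2.items():
            if v < 0:
                raise ValidationError(f"omega^2 for {k} must be >= 0")
            self.fixed.setdefault(k, False)

    def active(self, names=None) -> list[str]:
        """Parameters that carry an eta (omega^2 > 0), in ``names`` order."""
        names = names if names is not None else list(self.omega2)
        return [n for n in names if self.omega2.get(n, 0.0) > 0.0]

    def percent(self, name: str) -> float:
        return variance_to_percent(self.omega2.get(name, 0.0))

    def copy(self) -> "OmegaSpec":
        return OmegaSpec(dict(self.omega2), dict(self.fixed))


class ErrorKind(str, Enum):
    ADDITIVE = "additive"
    PROPORTIONAL = "proportional"
    COMBINED = "combined"


@dataclass
class ResidualErrorModel:
    kind: ErrorKind
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    fixed: bool = False

    def __post_init__(self) -> None:
        self.kind = ErrorKind(self.kind)
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValidationError("sigmas must be >= 0")
        # sigma = 0 is permitted (simulation degenerates to the prediction);
        # a zero sigma is never offered as a free parameter during fitting

    def variance(self, f):
        """Residual variance at prediction(s) ``f``."""
        f = np.asarray(f, dtype=float)
        if self.kind is ErrorKind.ADDITIVE:
            return np.full_like(f, self.sigma_add**2)
        if self.kind is ErrorKind.PROPORTIONAL:
            return f**2 * self.sigma_prop**2
        return self.sigma_add**2 + f**2 * self.sigma_prop**2

    def copy(self) -> "ResidualErrorModel":
        return ResidualErrorModel(self.kind, self.sigma_add, self.sigma_prop, self.fixed)


@dataclass
class PopulationModel:
    """Structural parameters + IIV + residual error + estimation mask.

    ``pk_fixed`` / ``pd_fixed`` name structural parameters held constant
    during fitting (e.g. Q in the patient model, IC50 in both PD models).
    Covariate coefficients live on :class:`~nafamopk.pk.PKParameters`; the
    set of *active* coefficients is given by nonzero values or by entries
    in ``estimated_covariates`` (coefficients being estimated may pass
    through zero).
    """

    name: str
    pk: PKParameters
    omega: OmegaSpec
    ruv_pk: ResidualErrorModel
    pd: PDParameters | None = None
    ruv_pd: ResidualErrorModel | None = None
    pk_fixed: frozenset = frozenset()
    pd_fixed: frozenset = frozenset()
    estimated_covariates: frozenset = frozenset()  # e.g. {"cov_gasflow_cl"}

    def __post_init__(self) -> None:
        self.pk_fixed = frozenset(self.pk_fixed)
        self.pd_fixed = frozenset(self.pd_fixed)
        self.estimated_covariates = frozenset(self.estimated_covariates)
        for p in self.pk_fixed:
            if p not in PK_PARAM_NAMES:
                raise ValidationError(f"unknown fixed PK parameter {p!r}")
        for p in self.pd_fixed:
            if p not in PD_PARAM_NAMES:
                raise ValidationError(f"unknown fixed PD parameter {p!r}")

    def copy(self) -> "PopulationModel":
        return PopulationModel(
            name=self.name,
            pk=self.pk,
            omega=self.omega.copy(),
            ruv_pk=self.ruv_pk.copy(),
            pd=self.pd,
            ruv_pd=self.ruv_pd.copy() if self.ruv_pd else None,
            pk_fixed=self.pk_fixed,
            pd_fixed=self.pd_fixed,
            estimated_covariates=self.estimated_covariates,
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_individual(
    model: PopulationModel,
    covariates: dict | None,
    rng_seed,
    include_pd: bool = True,
) -> dict[str, float]:
    """Realize one individual's parameter set.

    Covariate equations are applied to the typical values first, then each
    parameter with omega^2 > 0 is multiplied by exp(eta).  Imax draws that
    would exceed 1 are rejected and redrawn (the lognormal convention is
    kept for all parameters; imax is a fraction so the rare tail draw is
    resampled).  Deterministic given the seed.
    """
    rng = _as_rng(rng_seed)
    covariates = covariates or {}
    gfr = covariates.get("gas_flow_rate")
    pk = model.pk
    if gfr is not None:
        pk = apply_pk_covariates(pk, float(gfr))
    out: dict[str, float] = {n: getattr(pk, n) for n in PK_PARAM_NAMES}
    if include_pd and model.pd is not None:
        out.update({n: getattr(model.pd, n) for n in PD_PARAM_NAMES})
    for name in list(out):
        w2 = model.omega.omega2.get(name, 0.0)
        if w2 > 0.0:
            eta = rng.normal(0.0, math.sqrt(w2))
            if name == "imax":
                for _ in range(100):
                    if out[name] * math.exp(eta) <= 1.0:
                        break
                    eta = rng.normal(0.0, math.sqrt(w2))
                else:
                    eta = 0.0
            out[name] = out[name] * math.exp(eta)
    return out


def apply_ruv(prediction, ruv: ResidualErrorModel, rng_seed):
    """Simulate observation(s) from prediction(s) under the error model.

    Proportional: f*(1+eps); additive: f+eps; combined: f*(1+eps1)+eps2.
    A negative simulated value is redrawn once, then floored at 0 (values
    such as concentrations and aPTT are physically non-negative).
    """
    rng = _as_rng(rng_seed)
    f = np.asarray(prediction, dtype=float)
    if np.any(f < 0):
        raise ValidationError("prediction must be >= 0")

    def one_draw():
        y = f.astype(float).copy()
        if ruv.kind in (ErrorKind.PROPORTIONAL, ErrorKind.COMBINED):
            y = y * (1.0 + rng.normal(0.0, ruv.sigma_prop, size=f.shape))
        if ruv.kind in (ErrorKind.ADDITIVE, ErrorKind.COMBINED):
            y = y + rng.normal(0.0, ruv.sigma_add, size=f.shape)
        return y

    y = one_draw()
    neg = y < 0
    if np.any(neg):
        y2 = one_draw()
        y = np.where(neg, y2, y)
        y = np.maximum(y, 0.0)
    if np.ndim(prediction) == 0:
        return float(y)
    return y


# ---------------------------------------------------------------------------
# Packaged model fixtures (final fitted parameter sets per sampling site)


def available_models() -> list[str]:
    files = importlib.resources.files("nafamopk") / "models"
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".toml"))


def load_model(name: str) -> PopulationModel:
    """Load a packaged model fixture (``"patient"`` or ``"ecmo"``)."""
    res = importlib.resources.files("nafamopk") / "models" / f"{name}.toml"
    try:
        raw = res.read_bytes()
    except FileNotFoundError:
        raise FileNotFoundError(
            f"no packaged model {name!r}; available: {available_models()}"
        ) from None
    return model_from_dict(tomllib.loads(raw.decode()), name=name)


def model_from_dict(cfg: dict, name: str = "model") -> PopulationModel:
    """Build a :class:`PopulationModel` from a declarative config mapping."""
    pk_cfg = cfg["pk"]
    cov_kwargs = {}
    for cov in pk_cfg.get("covariate", []):
        par = cov["parameter"]
        key = f"cov_gasflow_{par}"
        if cov.get("covariate", "gas_flow_rate") != "gas_flow_rate":
            raise ValidationError("only the gas_flow_rate covariate is supported")
        cov_kwargs[key] = float(cov["coefficient"])
        cov_kwargs["gasflow_ref"] = float(cov.get("reference", 3.75))
    pk = PKParameters(
        cl=float(pk_cfg["cl"]),
        v1=float(pk_cfg["v1"]),
        q=float(pk_cfg["q"]),
        v2=float(pk_cfg["v2"]),
        **cov_kwargs,
    )
    omega2: dict[str, float] = {}
    fixed: dict[str, bool] = {}

    def read_iiv(section: dict) -> None:
        for pname, spec in section.items():
            if "percent" in spec:
                omega2[pname] = percent_to_variance(float(spec["percent"]))
            else:
                omega2[pname] = float(spec["omega2"])
            fixed[pname] = bool(spec.get("fixed", False))

    read_iiv(pk_cfg.get("iiv", {}))
    err = pk_cfg["error"]
    ruv_pk = ResidualErrorModel(
        kind=err["kind"],
        sigma_add=float(err.get("sigma_add", 0.0)),
        sigma_prop=float(err.get("sigma_prop", 0.0)),
    )
    pd_obj = None
    ruv_pd = None
    pd_fixed: frozenset = frozenset()
    if "pd" in cfg:
        pd_cfg = cfg["pd"]
        pd_obj = PDParameters(
            imax=float(pd_cfg["imax"]),
            ic50=float(pd_cfg["ic50"]),
            kin=float(pd_cfg["kin"]),
            base=float(pd_cfg["base"]),
        )
        read_iiv(pd_cfg.get("iiv", {}))
        perr = pd_cfg["error"]
        ruv_pd = ResidualErrorModel(
            kind=perr["kind"],
            sigma_add=float(perr.get("sigma_add", 0.0)),
            sigma_prop=float(perr.get("sigma_prop", 0.0)),
        )
        pd_fixed = frozenset(pd_cfg.get("fixed", []))
    return PopulationModel(
        name=cfg.get("name", name),
        pk=pk,
        omega=OmegaSpec(omega2, fixed),
        ruv_pk=ruv_pk,
        pd=pd_obj,
        ruv_pd=ruv_pd,
        pk_fixed=frozenset(pk_cfg.get("fixed", [])),
        pd_fixed=pd_fixed,
        estimated_covariates=frozenset(
            f"cov_gasflow_{c['parameter']}"
            for c in pk_cfg.get("covariate", [])
            if not c.get("fixed", False)
        ),
    )
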