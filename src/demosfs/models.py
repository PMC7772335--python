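"""Two-population demographic scenarios and their parameterizations.

The history is an isolation-with-migration design for an ancestral-range
(African) and a derived (European) population: the ancestral population
undergoes a stepwise expansion at ``T_exp``; forward in time the European
population splits off at ``T_split`` with an instantaneous bottleneck to
``nu_bot`` followed by exponential recovery to ``nu_eu``.  Four scenarios
differ only in gene flow after the split:

====== =========================================================
NOMIG   no migration
SYMIG   symmetric migration since the split
ASYMIG  asymmetric migration since the split
RASYMIG asymmetric migration starting only at ``T_mig`` (< split)
====== =========================================================

All quantities are in coalescent (diffusion) units: population sizes
relative to the ancestral size ``N_ANC``, times in units of ``2 N_ANC``
generations before present, migration rates as ``2 N_ANC m`` where ``m``
is the per-generation fraction of the *receiving* (forward-in-time)
population made of migrants.  Backwards in time a lineage currently in
the receiving population jumps to the source population at per-lineage
rate ``M`` on this time scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "AUTOSOME_L",
    "X_L",
    "ModelSpec",
    "ScaledParams",
    "ScalingConfig",
    "PhysicalParams",
    "make_model_spec",
    "validate_params",
    "size_trajectory",
    "migration_matrix",
    "to_physical",
    "from_physical",
]

MODEL_NAMES = ("NOMIG", "SYMIG", "ASYMIG", "RASYMIG")

#: effective sequence lengths used in the study design (bp)
AUTOSOME_L = 4_020_733
X_L = 5_859_268

_FREE_PARAMS = {
    "NOMIG": ("nu_af", "nu_bot", "nu_eu", "T_exp", "T_split"),
    "SYMIG": ("nu_af", "nu_bot", "nu_eu", "T_exp", "T_split", "M_AtoE"),
    "ASYMIG": ("nu_af", "nu_bot", "nu_eu", "T_exp", "T_split", "M_AtoE", "M_EtoA"),
    "RASYMIG": (
        "nu_af",
        "nu_bot",
        "nu_eu",
        "T_exp",
        "T_split",
        "M_AtoE",
        "M_EtoA",
        "T_mig",
    ),
}


@dataclass(frozen=True)
class ModelSpec:
    """Identity of a demographic scenario and its free-parameter space."""

    name: str
    free_param_names: tuple[str, ...]

    @property
    def k(self) -> int:
        """Number of free demographic parameters (for AIC); theta is profiled
        analytically and not counted."""
        return len(self.free_param_names)

    @property
    def has_migration(self) -> bool:
        return self.name != "NOMIG"


def make_model_spec(name: str) -> ModelSpec:
    """Return the :class:`ModelSpec` for a scenario name (case-insensitive)."""
    key = str(name).upper()
    if key not in _FREE_PARAMS:
        raise ValueError(
            f"unknown demographic model {name!r}; valid choices: {', '.join(MODEL_NAMES)}"
        )
    return ModelSpec(name=key, free_param_names=_FREE_PARAMS[key])


@dataclass
class ScaledParams:
    """Demographic parameters in coalescent units (see module docstring).

    ``T_mig`` is only meaningful under RASYMIG; it is ignored (and may be
    ``None``) for the other scenarios.
    """

    nu_af: float = 1.0  # post-expansion African size / N_ANC
    nu_bot: float = 0.1  # European size right after the split bottleneck
    nu_eu: float = 1.0  # current European size / N_ANC
    T_exp: float = 0.5  # time of African stepwise expansion (2 N_ANC gens)
    T_split: float = 0.1  # population split time (2 N_ANC gens)
    M_AtoE: float = 0.0  # scaled migration into Europe (2 N_ANC m)
    M_EtoA: float = 0.0  # scaled migration into Africa
    T_mig: float | None = None  # RASYMIG: migration active on [0, T_mig]

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kw) -> "ScaledParams":
        return replace(self, **kw)


def validate_params(spec: ModelSpec, params: ScaledParams) -> list[str]:
    """Check parameter invariants; returns a list of violations (empty = pass)."""
    v: list[str] = []
    for name in ("nu_af", "nu_bot", "nu_eu"):
        x = getattr(params, name)
        if not (x > 0):
            v.append(f"{name}: size must be > 0 (got {x})")
    for name in ("T_exp", "T_split"):
        x = getattr(params, name)
        if not (x > 0):
            v.append(f"{name}: time must be > 0 (got {x})")
    for name in ("M_AtoE", "M_EtoA"):
        x = getattr(params, name)
        if x < 0:
            v.append(f"{name}: migration rate must be >= 0 (got {x})")
    if params.T_exp <= params.T_split:
        v.append(
            f"T_exp ({params.T_exp}) must exceed T_split ({params.T_split}): "
            "the ancestral expansion is older than the split"
        )
    if spec.name == "NOMIG":
        if params.M_AtoE != 0 or params.M_EtoA != 0:
            v.append("NOMIG: migration rates must be fixed at 0")
    elif spec.name == "SYMIG":
        if params.M_AtoE != params.M_EtoA:
            v.append("SYMIG: migration must be symmetric (M_AtoE == M_EtoA)")
    if spec.name == "RASYMIG":
        if params.T_mig is None or not (params.T_mig > 0):
            v.append("RASYMIG: T_mig must be set and > 0")
        elif params.T_mig > params.T_split:
            v.append(
                f"RASYMIG: T_mig ({params.T_mig}) must not exceed "
                f"T_split ({params.T_split})"
            )
    return v


def _require_valid(spec: ModelSpec, params: ScaledParams) -> None:
    v = validate_params(spec, params)
    if v:
        raise ValueError("invalid demographic parameters: " + "; ".join(v))


def eu_growth_rate(params: ScaledParams) -> float:
    """Exponential rate beta with nu_EU(t) = nu_eu * exp(-beta t) backwards in
    time, so that nu(0)=nu_eu and nu(T_split)=nu_bot."""
    return math.log(params.nu_eu / params.nu_bot) / params.T_split


def size_trajectory(
    spec: ModelSpec, params: ScaledParams, pop: str, t: float
) -> float:
    """Relative population size nu(t) at scaled time ``t`` before present.

    ``pop`` is ``"AF"`` or ``"EU"``.  The African population sits at
    ``nu_af`` from the present back to ``T_exp`` and at 1 earlier; the
    European population interpolates exponentially between ``nu_eu`` now
    and ``nu_bot`` at the split and does not exist for ``t >= T_split``.
    """
    _require_valid(spec, params)
    if t < 0:
        raise ValueError("t must be >= 0")
    pop = pop.upper()
    if pop == "AF":
        return params.nu_af if t < params.T_exp else 1.0
    if pop == "EU":
        if t >= params.T_split:
            raise ValueError(
                "the European population does not exist at t >= T_split"
            )
        return params.nu_eu * math.exp(-eu_growth_rate(params) * t)
    raise ValueError(f"unknown population {pop!r}; expected AF or EU")


def migration_matrix(
    spec: ModelSpec, params: ScaledParams, t: float
) -> np.ndarray:
    """2x2 matrix of scaled backward per-lineage migration rates at time t.

    Entry ``[i, j]`` is the rate at which a lineage in population i
    (0 = AF, 1 = EU) jumps to population j, on the 2 N_ANC-generation time
    scale.  Only defined for ``t < T_split``.
    """
    _require_valid(spec, params)
    if t >= params.T_split:
        raise ValueError("migration is undefined at t >= T_split (single population)")
    m = np.zeros((2, 2))
    if spec.name == "NOMIG":
        return m
    active = True
    if spec.name == "RASYMIG":
        active = t <= params.T_mig
    if active:
        # forward A->E migrants are received in Europe: EU lineages jump to AF
        m[1, 0] = params.M_AtoE
        m[0, 1] = params.M_EtoA
    return m


@dataclass(frozen=True)
class ScalingConfig:
    """Constants converting coalescent units to individuals and years."""

    mu: float = 5.21e-9  # per-bp per-generation mutation rate
    gens_per_year: float = 15.0
    L: float = AUTOSOME_L  # effective sequence length (bp)

    def __post_init__(self):
        if not (self.mu > 0 and self.gens_per_year > 0 and self.L > 0):
            raise ValueError("all scaling constants must be strictly positive")


@dataclass(frozen=True)
class PhysicalParams:
    """Demographic estimates in individuals / years (Table-style units).

    Migration rates stay in scaled ``2 N_ANC m`` units by convention.
    """

    N_ANC: float
    N_AF: float
    N_BOT: float
    N_EU: float
    T_split_years: float
    T_exp_years: float
    T_mig_years: float | None
    M_AtoE: float
    M_EtoA: float

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["T_mig_years"] is None:
            d.pop("T_mig_years")
        return d


def to_physical(
    params: ScaledParams, theta_hat: float, scaling: ScalingConfig
) -> PhysicalParams:
    """Convert scaled parameters to individuals and years.

    ``N_ANC = theta_hat / (4 mu L)``; sizes scale by nu; times convert via
    ``T_years = T_scaled * 2 N_ANC / gens_per_year``; scaled migration
    rates pass through unchanged.
    """
    if not theta_hat > 0:
        raise ValueError("theta_hat must be > 0")
    n_anc = theta_hat / (4.0 * scaling.mu * scaling.L)
    t_factor = 2.0 * n_anc / scaling.gens_per_year
    return PhysicalParams(
        N_ANC=n_anc,
        N_AF=params.nu_af * n_anc,
        N_BOT=params.nu_bot * n_anc,
        N_EU=params.nu_eu * n_anc,
        T_split_years=params.T_split * t_factor,
        T_exp_years=params.T_exp * t_factor,
        T_mig_years=None if params.T_mig is None else params.T_mig * t_factor,
        M_AtoE=params.M_AtoE,
        M_EtoA=params.M_EtoA,
    )


def from_physical(phys: PhysicalParams, scaling: ScalingConfig) -> tuple[ScaledParams, float]:
    """Inverse of :func:`to_physical`; returns ``(ScaledParams, theta_hat)``."""
    if not phys.N_ANC > 0:
        raise ValueError("N_ANC must be > 0")
    theta_hat = phys.N_ANC * 4.0 * scaling.mu * scaling.L
    t_factor = 2.0 * phys.N_ANC / scaling.gens_per_year
    return (
        ScaledParams(
            nu_af=phys.N_AF / phys.N_ANC,
            nu_bot=phys.N_BOT / phys.N_ANC,
            nu_eu=phys.N_EU / phys.N_ANC,
            T_exp=phys.T_exp_years / t_factor,
            T_split=phys.T_split_years / t_factor,
            M_AtoE=phys.M_AtoE,
            M_EtoA=phys.M_EtoA,
            T_mig=None
            if phys.T_mig_years is None
            else phys.T_mig_years / t_factor,
        ),
        theta_hat,
    )


def params_to_config(spec: ModelSpec, params: ScaledParams) -> str:
    """Serialize a scenario + parameters as a flat ``key = value`` text block."""
    lines = [f"model = {spec.name}", "units = coalescent(2*N_ANC)"]
    for k, v in params.as_dict().items():
        if v is None:
            continue
        lines.append(f"{k} = {v!r}")
    return "\n".join(lines) + "\n"


def params_from_config(text: str) -> tuple[ModelSpec, ScaledParams]:
    """Parse the flat config produced by :func:`params_to_config`."""
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        k, _, v = line.partition("=")
        kv[k.strip()] = v.strip()
    if "model" not in kv:
        raise ValueError("config is missing the 'model' key")
    spec = make_model_spec(kv.pop("model"))
    kv.pop("units", None)
    valid = {f.name for f in fields(ScaledParams)}
    unknown = set(kv) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return spec, ScaledParams(**{k: float(v) for k, v in kv.items()})
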