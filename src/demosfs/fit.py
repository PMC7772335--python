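"""Poisson composite-likelihood fitting of demographic models to a joint SFS.

The model object follows the statsmodels convention: build an
:class:`SFSDemographyModel` from an observed :class:`~demosfs.sfs.JointSFS`
and a scenario name, call :meth:`~SFSDemographyModel.fit`, and work with
the returned :class:`SFSDemographyResults` (parameter estimates, profiled
theta, log-likelihood, AIC, ``summary()``, physical-unit conversion, and
parametric-bootstrap confidence intervals).

The likelihood is the Poisson random-field composite likelihood: each
unmasked SFS cell is an independent Poisson count with mean
``theta * E[branch length]/2``, where the expectation comes from the
Monte-Carlo engine.  theta is profiled analytically
(``theta_hat = sum(obs) / sum(expected per theta)``) and is therefore
not counted among the k free parameters in the AIC.  Within one fit the
Monte-Carlo expectation reuses a fixed genealogy seed (common random
numbers), which makes the objective deterministic and smooth enough for
derivative-free optimization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from .models import (
    ModelSpec,
    PhysicalParams,
    ScaledParams,
    ScalingConfig,
    make_model_spec,
    to_physical,
    validate_params,
)
from .sfs import JointSFS
from .simulate import expected_jsfs

logger = logging.getLogger(__name__)

__all__ = [
    "SFSDemographyModel",
    "SFSDemographyResults",
    "ConfidenceIntervals",
    "poisson_loglik",
    "fit_model",
    "model_choice",
    "parametric_bootstrap",
]

_EXPECTED_FLOOR = 1e-12
# broad sanity box (log10) keeping the simulator in a numerically sane regime
_BOUNDS = {
    "nu": (1e-4, 1e4),
    "T_split": (1e-4, 30.0),
    "gap": (1e-6, 30.0),
    "M": (1e-8, 60.0),
}


def poisson_loglik(observed, expected_per_theta, mask=None):
    """Profile-theta Poisson composite log-likelihood.

    Returns ``(loglik, theta_hat)`` with
    ``theta_hat = sum(obs) / sum(expected_per_theta)`` over unmasked
    cells and ``loglik = sum S ln M - M - ln S!`` at
    ``M = theta_hat * expected_per_theta``.  Cells with zero Monte-Carlo
    expectation but positive observed count are floored at a tiny
    expectation (finite, heavily penalized) rather than returning -inf.
    """
    if isinstance(observed, JointSFS):
        if mask is None:
            mask = observed.mask
        obs = observed.counts
    else:
        obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected_per_theta, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected shapes differ")
    if np.any(exp < 0):
        raise ValueError("expected entries must be >= 0")
    if mask is None:
        mask = np.zeros_like(obs, dtype=bool)
    use = ~np.asarray(mask, dtype=bool)
    s = obs[use]
    m_unit = exp[use]
    s_tot = s.sum()
    e_tot = m_unit.sum()
    if s_tot == 0:
        return 0.0, 0.0
    if e_tot == 0:
        raise ValueError("expected SFS is identically zero but data are not")
    theta_hat = s_tot / e_tot
    m = theta_hat * m_unit
    m_safe = np.where(m > 0, m, _EXPECTED_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(s > 0, s * np.log(m_safe), 0.0) - m - gammaln(s + 1)
    return float(terms.sum()), float(theta_hat)


def _transform(spec: ModelSpec, params: ScaledParams) -> np.ndarray:
    """Free parameters -> unconstrained optimizer vector."""
    x = []
    for name in spec.free_param_names:
        if name == "T_exp":
            x.append(math.log(params.T_exp - params.T_split))
        elif name == "T_mig":
            frac = params.T_mig / params.T_split
            frac = min(max(frac, 1e-9), 1 - 1e-9)
            x.append(math.log(frac / (1 - frac)))
        else:
            x.append(math.log(getattr(params, name)))
    return np.array(x)


def _untransform(
    spec: ModelSpec, x: np.ndarray, template: ScaledParams
) -> tuple[ScaledParams, float]:
    """Optimizer vector -> valid ScaledParams + soft-bound penalty.

    Positivity and the orderings T_exp > T_split, 0 < T_mig <= T_split
    hold by construction; values escaping the sanity box are clipped
    with a quadratic penalty so the search is steered back.
    """
    vals = dict(zip(spec.free_param_names, x))
    penalty = 0.0

    def boxed(v, lo, hi):
        nonlocal penalty
        if v < math.log(lo):
            penalty += (v - math.log(lo)) ** 2
            v = math.log(lo)
        elif v > math.log(hi):
            penalty += (v - math.log(hi)) ** 2
            v = math.log(hi)
        return math.exp(v)

    kw = template.as_dict()
    for name in ("nu_af", "nu_bot", "nu_eu"):
        if name in vals:
            kw[name] = boxed(vals[name], *_BOUNDS["nu"])
    if "T_split" in vals:
        kw["T_split"] = boxed(vals["T_split"], *_BOUNDS["T_split"])
    if "T_exp" in vals:
        gap = boxed(vals["T_exp"], *_BOUNDS["gap"])
        kw["T_exp"] = kw["T_split"] + gap
    for name in ("M_AtoE", "M_EtoA"):
        if name in vals:
            kw[name] = boxed(vals[name], *_BOUNDS["M"])
    if spec.name == "NOMIG":
        kw["M_AtoE"] = kw["M_EtoA"] = 0.0
    elif spec.name == "SYMIG":
        kw["M_EtoA"] = kw["M_AtoE"]
    if "T_mig" in vals:
        z = min(max(vals["T_mig"], -30.0), 30.0)
        frac = 1.0 / (1.0 + math.exp(-z))
        kw["T_mig"] = frac * kw["T_split"]
    elif spec.name != "RASYMIG":
        kw["T_mig"] = None
    return ScaledParams(**kw), penalty


_DEFAULT_INIT = ScaledParams(
    nu_af=2.0, nu_bot=0.1, nu_eu=1.0, T_exp=0.4, T_split=0.1,
    M_AtoE=1.0, M_EtoA=1.0, T_mig=0.05,
)


class SFSDemographyModel:
    """Demographic model for an observed joint SFS (Poisson random field).

    Parameters
    ----------
    observed : JointSFS
        Observed unfolded joint spectrum (corners masked).
    model : str or ModelSpec
        One of NOMIG, SYMIG, ASYMIG, RASYMIG.
    n_mc : int
        Monte-Carlo genealogies per likelihood evaluation.
    seed : int
        Master seed; fixes the common-random-numbers genealogy seed and
        the start perturbations, making :meth:`fit` fully reproducible.
    """

    def __init__(self, observed: JointSFS, model="ASYMIG", n_mc: int = 20_000,
                 seed: int = 0):
        if not isinstance(observed, JointSFS):
            raise TypeError("observed must be a JointSFS")
        if observed.folded:
            raise ValueError("fitting requires an unfolded (polarized) SFS")
        if observed.total <= 0:
            raise ValueError("observed SFS has no segregating sites")
        self.observed = observed
        self.spec = model if isinstance(model, ModelSpec) else make_model_spec(model)
        self.n_mc = int(n_mc)
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        self.mc_seed = int(self._rng.integers(2**31 - 1))
        self.n1 = observed.n1
        self.n2 = observed.n2

    def expected_sfs(self, params: ScaledParams) -> np.ndarray:
        """Expected joint SFS per unit theta under the common-random-numbers
        genealogy set of this model instance."""
        return expected_jsfs(
            self.spec, params, self.n1, self.n2, self.n_mc, self.mc_seed
        ).per_theta

    def loglike(self, params: ScaledParams) -> tuple[float, float]:
        """(log-likelihood, profiled theta_hat) at the given parameters."""
        v = validate_params(self.spec, params)
        if v:
            raise ValueError("invalid parameters: " + "; ".join(v))
        return poisson_loglik(self.observed, self.expected_sfs(params))

    def _objective(self, x: np.ndarray) -> float:
        params, penalty = _untransform(self.spec, x, _DEFAULT_INIT)
        exp = self.expected_sfs(params)
        ll, _ = poisson_loglik(self.observed, exp)
        return -ll + 1e5 * penalty

    def fit(
        self,
        start_params: ScaledParams | None = None,
        n_starts: int = 10,
        extra_starts: list[ScaledParams] | None = None,
        perturb_sigma: float = 0.5,
        maxiter: int | None = None,
        maxfev: int | None = None,
        xatol: float = 1e-3,
        fatol: float = 1e-2,
    ) -> "SFSDemographyResults":
        """Multi-start Nelder-Mead maximization in transformed space.

        ``n_starts`` runs begin at ``start_params`` (first start
        unperturbed, the rest multiplied by lognormal factors of spread
        ``perturb_sigma``); any ``extra_starts`` are run unperturbed in
        addition.  The best converged run is kept; all runs are recorded.
        """
        init = start_params or _DEFAULT_INIT
        if self.spec.name == "RASYMIG" and init.T_mig is None:
            init = init.replace(T_mig=init.T_split / 2)
        if self.spec.name == "NOMIG":
            init = init.replace(M_AtoE=0.0, M_EtoA=0.0)
        if self.spec.name == "SYMIG":
            init = init.replace(M_EtoA=init.M_AtoE)
        bad = validate_params(self.spec, init)
        if bad:
            raise ValueError("invalid start parameters: " + "; ".join(bad))
        x0 = _transform(self.spec, init)
        dim = len(x0)
        if maxiter is None:
            maxiter = 300 * dim
        if maxfev is None:
            maxfev = 3 * maxiter

        starts = [x0]
        for _ in range(n_starts - 1):
            starts.append(x0 + self._rng.normal(0.0, perturb_sigma, size=dim))
        for p in extra_starts or []:
            q = p
            if self.spec.name == "RASYMIG" and q.T_mig is None:
                q = q.replace(T_mig=q.T_split / 2)
            starts.append(_transform(self.spec, q))

        records = []
        best = None
        for s_idx, xs in enumerate(starts):
            # explicit initial simplex: scipy's default step is ~0 for
            # coordinates near 0 (log-parameters equal to 1 would freeze)
            simplex = np.vstack([xs] + [xs + 0.3 * np.eye(dim)[i]
                                        for i in range(dim)])
            res = optimize.minimize(
                self._objective,
                xs,
                method="Nelder-Mead",
                options=dict(maxiter=maxiter, xatol=xatol, fatol=fatol,
                             maxfev=maxfev, adaptive=True,
                             initial_simplex=simplex),
            )
            p_init, _ = _untransform(self.spec, xs, _DEFAULT_INIT)
            p_fin, _ = _untransform(self.spec, res.x, _DEFAULT_INIT)
            rec = dict(
                start=s_idx,
                init=p_init.as_dict(),
                final=p_fin.as_dict(),
                loglik=-float(res.fun),
                converged=bool(res.success),
                nfev=int(res.nfev),
            )
            records.append(rec)
            if best is None or res.fun < best[0].fun:
                best = (res, p_fin)
        if best is None or not any(r["converged"] for r in records):
            raise RuntimeError(
                "no optimizer start converged; records: " + repr(records)
            )
        res, p_best = best
        ll, theta_hat = poisson_loglik(self.observed, self.expected_sfs(p_best))
        return SFSDemographyResults(
            model=self,
            spec=self.spec,
            params=p_best,
            theta_hat=theta_hat,
            llf=ll,
            starts=records,
            converged=bool(res.success),
        )


@dataclass
class SFSDemographyResults:
    """Fit output: best parameters, profiled theta, log-likelihood, AIC."""

    model: SFSDemographyModel
    spec: ModelSpec
    params: ScaledParams
    theta_hat: float
    llf: float
    starts: list = field(default_factory=list)
    converged: bool = True

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    @property
    def n_mc(self) -> int:
        return self.model.n_mc

    def to_physical(self, scaling: ScalingConfig | None = None) -> PhysicalParams:
        return to_physical(self.params, self.theta_hat, scaling or ScalingConfig())

    def expected_counts(self) -> np.ndarray:
        """Fitted Poisson means per SFS cell (theta_hat x expectation)."""
        return self.theta_hat * self.model.expected_sfs(self.params)

    def summary(self, scaling: ScalingConfig | None = None) -> str:
        phys = self.to_physical(scaling)
        lines = [
            f"SFS demographic fit: model {self.spec.name} "
            f"(k={self.k} free parameters)",
            f"  log-likelihood {self.llf:.3f}   AIC {self.aic:.3f}   "
            f"theta_hat {self.theta_hat:.4g}",
            f"  n_mc {self.n_mc}   seed {self.model.seed}   "
            f"starts {len(self.starts)} "
            f"({sum(r['converged'] for r in self.starts)} converged)",
            "  scaled parameters:",
        ]
        for k, v in self.params.as_dict().items():
            if v is None:
                continue
            lines.append(f"    {k:>8s} = {v:.5g}")
        lines.append("  physical units (mu={:.3g}, {:g} gens/yr, L={:g} bp):".format(
            (scaling or ScalingConfig()).mu,
            (scaling or ScalingConfig()).gens_per_year,
            (scaling or ScalingConfig()).L,
        ))
        for k, v in phys.as_dict().items():
            lines.append(f"    {k:>14s} = {v:,.6g}")
        return "\n".join(lines)

    def parametric_bootstrap(self, n_boot: int = 150, seed: int | None = None,
                             **kw) -> "ConfidenceIntervals":
        return parametric_bootstrap(self, n_boot=n_boot, seed=seed, **kw)


def fit_model(
    spec,
    observed: JointSFS,
    start_params: ScaledParams | None = None,
    n_starts: int = 10,
    n_mc: int = 20_000,
    seed: int = 0,
    **fit_kw,
) -> SFSDemographyResults:
    """One-call fit: build :class:`SFSDemographyModel` and run :meth:`fit`."""
    model = SFSDemographyModel(observed, model=spec, n_mc=n_mc, seed=seed)
    return model.fit(start_params=start_params, n_starts=n_starts, **fit_kw)


def model_choice(fits: list[SFSDemographyResults]):
    """Rank fitted scenarios by AIC (ties broken by smaller k).

    Returns ``(table, best_fit)`` where ``table`` is a DataFrame with
    loglik, k, AIC and delta-AIC rows sorted ascending by AIC.  All fits
    must refer to the same observed spectrum.
    """
    if len(fits) < 2:
        raise ValueError("model choice needs at least two fits")
    ref = fits[0].model.observed
    for f in fits[1:]:
        o = f.model.observed
        if o.counts.shape != ref.counts.shape or not np.array_equal(
            o.counts, ref.counts
        ):
            raise ValueError("fits were computed on different observed spectra")
    rows = [
        dict(model=f.spec.name, k=f.k, loglik=f.llf, AIC=f.aic) for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(["AIC", "k"]).reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].iloc[0]
    best_name = table["model"].iloc[0]
    best = next(f for f in fits if f.spec.name == best_name)
    return table, best


@dataclass
class ConfidenceIntervals:
    """Percentile parametric-bootstrap confidence intervals (physical units)."""

    table: pd.DataFrame  # index: parameter; columns: point, lower, upper
    replicates: pd.DataFrame  # per-replicate physical estimates
    n_boot: int
    n_failed: int

    @property
    def point_outside(self) -> list[str]:
        """Parameters whose point estimate escapes its own percentile CI
        (possible with percentile CIs from re-fits; flagged, not an error)."""
        t = self.table
        return list(t.index[(t["point"] < t["lower"]) | (t["point"] > t["upper"])])

    def summary(self) -> str:
        lines = [
            f"parametric bootstrap: {self.n_boot} replicates "
            f"({self.n_failed} failed), 2.5-97.5% percentile CIs"
        ]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:,.6g}"))
        out = self.point_outside
        if out:
            lines.append(f"note: point estimate outside CI for: {', '.join(out)}")
        return "\n".join(lines)


def parametric_bootstrap(
    best: SFSDemographyResults,
    n_boot: int = 150,
    seed: int | None = None,
    scaling: ScalingConfig | None = None,
    n_starts: int = 1,
    n_mc: int | None = None,
    max_failure_frac: float = 0.2,
    method: str = "poisson",
    resim_n_loci: int = 500,
    **fit_kw,
) -> ConfidenceIntervals:
    """Percentile CIs by simulating pseudo-observed spectra from the fit.

    Each replicate draws pseudo-data, re-fits the same scenario starting
    from the point estimate, and converts to physical units; the 2.5 and
    97.5 percentiles of the replicate estimates form the interval for
    each parameter.  With ``method="poisson"`` (default) pseudo-spectra
    are Poisson draws around the fitted expected SFS — exactly the data
    model the composite likelihood assumes; ``method="resimulate"``
    instead re-runs the genealogy simulator (``resim_n_loci`` unlinked
    loci carrying the fitted total theta), which preserves the
    genealogy-level overdispersion the composite likelihood ignores.
    """
    if not best.converged:
        raise ValueError("cannot bootstrap an unconverged fit")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 20:
        warnings.warn(
            f"n_boot={n_boot} gives degenerate 2.5-97.5 percentiles",
            stacklevel=2,
        )
    if method not in ("poisson", "resimulate"):
        raise ValueError("method must be 'poisson' or 'resimulate'")
    scaling = scaling or ScalingConfig()
    rng = np.random.default_rng(best.model.seed + 1 if seed is None else seed)
    fitted_m = best.expected_counts()
    mask = best.model.observed.mask
    rows = []
    n_failed = 0
    for rep in range(n_boot):
        if method == "poisson":
            counts = rng.poisson(np.where(mask, 0.0, fitted_m))
        else:
            from .simulate import simulate_sfs_counts

            counts = simulate_sfs_counts(
                best.spec, best.params, best.model.n1, best.model.n2,
                resim_n_loci, best.theta_hat / resim_n_loci,
                int(rng.integers(2**31 - 1)),
            )
        pseudo = JointSFS(counts.astype(float),
                          pop_names=best.model.observed.pop_names)
        try:
            res = fit_model(
                best.spec,
                pseudo,
                start_params=best.params,
                n_starts=n_starts,
                n_mc=n_mc or best.model.n_mc,
                seed=int(rng.integers(2**31 - 1)),
                **fit_kw,
            )
        except (RuntimeError, ValueError) as exc:
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            n_failed += 1
            continue
        rows.append(res.to_physical(scaling).as_dict())
    reps = pd.DataFrame(rows)
    if n_failed > max_failure_frac * n_boot:
        err = RuntimeError(
            f"{n_failed}/{n_boot} bootstrap replicate fits failed"
        )
        err.partial_replicates = reps
        raise err
    point = best.to_physical(scaling).as_dict()
    table = pd.DataFrame(
        {
            "point": pd.Series(point),
            "lower": reps.quantile(0.025),
            "upper": reps.quantile(0.975),
        }
    ).loc[[k for k in point]]
    return ConfidenceIntervals(
        table=table, replicates=reps, n_boot=n_boot, n_failed=n_failed
    )
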