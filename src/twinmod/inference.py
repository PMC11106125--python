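"""Shared maximum-likelihood machinery: fitting, LRTs, AIC, profile CIs.

Every fitted model in this package minimizes a pairwise full-information
-2 log-likelihood and reports a :class:`FitResult`.  Degrees of freedom follow
the observed-statistics convention (number of non-missing data entries minus
free parameters) and AIC is deviance-based, ``AIC = -2LL - 2*df`` — the
convention under which a smaller (more negative) value is better and which
matches standard twin-modeling software output.

Confidence intervals are profile-likelihood bounds: the points where the
deviance rises by the chi-square(1) critical value above its minimum while all
nuisance parameters are re-optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "LRTResult",
    "MLModel",
    "aic",
    "lrt",
    "profile_ci",
]

def aic(minus2ll: float, df: int) -> float:
    """Deviance-based information criterion ``-2LL - 2*df``."""
    if df < 0:
        raise ValueError("degrees of freedom must be nonnegative")
    return minus2ll - 2.0 * df


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    estimates: dict[str, float]
    minus2ll: float
    df: int
    aic: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    status: str = "converged"
    n_pairs_used: int = 0
    fixed: dict[str, float] = field(default_factory=dict)
    n_free: int = 0
    model: str = ""

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = {k: list(v) for k, v in self.ci95.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        d = dict(d)
        d["ci95"] = {k: (float(v[0]), float(v[1])) for k, v in d.get("ci95", {}).items()}
        return cls(**d)


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of nested fits."""

    chi2: float
    df: int
    p: float


def lrt(full: FitResult, nested: FitResult) -> LRTResult:
    """Likelihood-ratio test of ``nested`` (fewer free parameters) against ``full``.

    Both fits must be on the same data; the statistic is the deviance
    difference referred to a central chi-square with df equal to the
    difference in free-parameter counts.
    """
    if full.n_pairs_used != nested.n_pairs_used:
        raise ValueError("fits compare different data (n_pairs_used differ)")
    ddf = nested.df - full.df if nested.df != full.df else full.n_free - nested.n_free
    if ddf < 1:
        ddf = max(full.n_free - nested.n_free, 0)
    chi2 = nested.minus2ll - full.minus2ll
    if chi2 < -1e-6:
        raise RuntimeError(
            f"negative LRT statistic ({chi2:.3g}): the full model fit worse; "
            "optimization likely failed"
        )
    chi2 = max(chi2, 0.0)
    if ddf == 0:
        return LRTResult(chi2=chi2, df=0, p=1.0)
    return LRTResult(chi2=chi2, df=ddf, p=float(stats.chi2.sf(chi2, ddf)))


class MLModel:
    """Base class for models fitted by minimizing a pairwise -2 log-likelihood.

    Subclasses define ``param_names``, ``minus2ll(theta)``,
    ``start_values()``, ``n_observed_statistics`` and ``n_pairs_used``.
    """

    param_names: Sequence[str] = ()

    # -- subclass contract -------------------------------------------------
    def minus2ll(self, theta: np.ndarray) -> float:
        raise NotImplementedError

    def start_values(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_observed_statistics(self) -> int:
        raise NotImplementedError

    @property
    def n_pairs_used(self) -> int:
        raise NotImplementedError

    # -- fitting -----------------------------------------------------------
    def _theta_full(self, theta_free, free_idx, fixed_full):
        full = fixed_full.copy()
        full[free_idx] = theta_free
        return full

    def fit(
        self,
        start: np.ndarray | Mapping[str, float] | None = None,
        fixed: Mapping[str, float] | None = None,
        n_starts: int = 5,
        jitter: float = 0.10,
        gtol: float = 1e-5,
        ci_params: Sequence[str] = (),
        seed: int = 0,
        maxiter: int = 2000,
        starts: Sequence[Mapping[str, float]] | None = None,
    ) -> FitResult:
        """Minimize -2LL; returns a :class:`FitResult`.

        ``fixed`` pins named parameters; ``start`` may be a vector over all
        parameters or a name->value mapping layered over the defaults.  Up to
        ``n_starts`` starts are tried (the first unjittered, later ones
        jittered by ``jitter`` relative), stopping at the first convergence.

        ``starts`` instead supplies an explicit ladder of start overrides
        (each a name->value mapping layered over ``start``); every rung is
        run to convergence and the best deviance wins.  Moderated liability
        models can be multimodal in the slope parameters, so slope ladders
        are the robust way to fit them.
        """
        if starts is not None:
            best = None
            for extra in starts:
                merged = dict(start) if isinstance(start, Mapping) else {}
                merged.update(extra)
                res = self.fit(start=merged if merged else start, fixed=fixed,
                               n_starts=n_starts, jitter=jitter, gtol=gtol,
                               seed=seed, maxiter=maxiter)
                if best is None or (res.converged and not best.converged) or (
                        res.converged == best.converged
                        and res.minus2ll < best.minus2ll - 1e-9):
                    best = res
            for p in ci_params:
                best.ci95[p] = profile_ci(self, best, p)
            return best

        names = list(self.param_names)
        fixed = dict(fixed or {})
        unknown = set(fixed) - set(names)
        if unknown:
            raise KeyError(f"unknown fixed parameters: {sorted(unknown)}")

        base = np.array(self.start_values(), dtype=float)
        if start is not None:
            if isinstance(start, Mapping):
                for k, v in start.items():
                    base[names.index(k)] = v
            else:
                base = np.array(start, dtype=float)
        fixed_full = base.copy()
        for k, v in fixed.items():
            fixed_full[names.index(k)] = v
        free_idx = np.array([i for i, n in enumerate(names) if n not in fixed], dtype=int)
        if free_idx.size == 0:
            m2ll = float(self.minus2ll(fixed_full))
            df = self.n_observed_statistics
            return FitResult(
                estimates={n: float(fixed_full[i]) for i, n in enumerate(names)},
                minus2ll=m2ll, df=df, aic=aic(m2ll, df), status="converged",
                n_pairs_used=self.n_pairs_used, fixed=dict(fixed), n_free=0,
                model=type(self).__name__,
            )

        def objective(theta_free):
            val = self.minus2ll(self._theta_full(theta_free, free_idx, fixed_full))
            if not np.isfinite(val):
                return 1e12
            return val

        rng = np.random.default_rng(seed)
        best = None
        status = "max_iter"
        x0 = fixed_full[free_idx]
        for attempt in range(max(n_starts, 1)):
            xs = x0 if attempt == 0 else x0 * (1 + jitter * rng.standard_normal(x0.size)) + (
                jitter * rng.standard_normal(x0.size) * (np.abs(x0) < 1e-8)
            )
            res = optimize.minimize(
                objective, xs, method="L-BFGS-B",
                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if res.success and np.isfinite(res.fun):
                best = res if res.fun <= best.fun + 1e-9 else best
                status = "converged"
                break
        if best is None:
            raise RuntimeError("optimization produced no result")
        if status != "converged" and best.success:
            status = "converged"

        theta_hat = self._theta_full(best.x, free_idx, fixed_full)
        m2ll = float(self.minus2ll(theta_hat))
        df = self.n_observed_statistics - free_idx.size
        result = FitResult(
            estimates={n: float(theta_hat[i]) for i, n in enumerate(names)},
            minus2ll=m2ll,
            df=df,
            aic=aic(m2ll, df),
            status=status,
            n_pairs_used=self.n_pairs_used,
            fixed=dict(fixed),
            n_free=int(free_idx.size),
            model=type(self).__name__,
        )
        for p in ci_params:
            result.ci95[p] = profile_ci(self, result, p)
        return result


def _profile_minus2ll(model: MLModel, fit: FitResult, param: str, value: float,
                      warm: Mapping[str, float]) -> tuple[float, dict]:
    fixed = dict(fit.fixed)
    fixed[param] = value
    sub = model.fit(start=dict(warm), fixed=fixed, n_starts=1)
    return sub.minus2ll, sub.estimates


def profile_ci(
    model: MLModel,
    fit: FitResult,
    param: str,
    level: float = 0.95,
    max_sd_multiple: float = 10.0,
    xtol: float = 1e-4,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one parameter.

    Each bound is the value where the profiled deviance rises by the
    chi-square(1) quantile above the minimum, found by stepping outward and
    bisecting; nuisance parameters are re-optimized at every probe point,
    warm-started from the neighbouring solution.  A bound that fails to cross
    the cutoff within ``max_sd_multiple`` curvature-based SDs is returned as
    ``+/-inf`` (open-ended).
    """
    if not fit.converged:
        raise RuntimeError("profile CI requires a converged fit")
    crit = float(stats.chi2.ppf(level, 1))
    target = fit.minus2ll + crit
    est = fit.estimates[param]

    # curvature-based scale guess for the initial step
    h = max(abs(est) * 0.05, 0.05)
    f0 = fit.minus2ll
    fp, _ = _profile_minus2ll(model, fit, param, est + h, fit.estimates)
    fm, _ = _profile_minus2ll(model, fit, param, est - h, fit.estimates)
    curv = max((fp + fm - 2 * f0) / h**2, 1e-8)
    se = np.sqrt(2.0 / curv)  # deviance curvature ~ 2/Var

    bounds = []
    for sign in (-1.0, +1.0):
        lo_v, lo_f = est, f0
        warm = dict(fit.estimates)
        step = se
        crossed = False
        v = est
        while abs(v - est) < max_sd_multiple * se:
            v = v + sign * step
            fv, warm_est = _profile_minus2ll(model, fit, param, v, warm)
            warm = warm_est
            if fv >= target:
                crossed = True
                break
            lo_v, lo_f = v, fv
            step *= 1.6
        if not crossed:
            bounds.append(sign * np.inf)
            continue
        hi_v = v
        # bisection between lo_v (below target) and hi_v (above target)
        while abs(hi_v - lo_v) > xtol:
            mid = 0.5 * (lo_v + hi_v)
            fv, warm_est = _profile_minus2ll(model, fit, param, mid, warm)
            warm = warm_est
            if fv >= target:
                hi_v = mid
            else:
                lo_v = mid
        bounds.append(0.5 * (lo_v + hi_v))
    lo, hi = sorted(bounds)
    return float(lo), float(hi)
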