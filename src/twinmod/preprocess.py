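"""Scale scoring, reliability, covariate adjustment and EM imputation.

Covers the steps between raw questionnaire items and analysis-ready scores:

* scale scoring (mean, mean-times-k, or sum rules, with not-applicable codes
  and excluded items, plus optional dichotomization of a skewed composite);
* Cronbach's alpha as the internal-consistency check;
* age/sex adjustment — continuous scores are log-transformed then residualized
  on age and sex by pooled-individual OLS (ordinal variables are left alone:
  their covariates enter the liability threshold model instead), optionally
  also removing a moderator's main effect from the dependent variables so
  moderation fits are not confounded by mean effects;
* multivariate-normal EM imputation of missing continuous scores, after
  excluding individuals who exceed a missingness threshold.  Binary liability
  variables are never imputed.

The log-then-residualize order is deliberate: residuals can be negative, so
the reverse order would be undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TwinDataset

__all__ = [
    "ScoringRule",
    "score_scales",
    "cronbach_alpha",
    "adjust_covariates",
    "em_impute",
    "em_mvnorm",
]


@dataclass
class ScoringRule:
    """How item responses aggregate into one scale score."""

    items: list
    method: str = "mean"                    # mean | mean_times_k | sum
    excluded_items: list = field(default_factory=list)
    not_applicable_code: float | None = None
    dichotomize_at: float | None = None
    response_range: tuple | None = None

    def __post_init__(self):
        if self.method not in ("mean", "mean_times_k", "sum"):
            raise ValueError(f"unknown scoring method {self.method!r}")
        if not set(self.excluded_items) <= set(self.items):
            raise ValueError("excluded_items must be a subset of items")


def score_scales(item_table: pd.DataFrame, rule: ScoringRule) -> pd.Series:
    """Score one scale for every respondent.

    Not-applicable codes are treated as missing for averaging; ``sum`` scores
    require all contributing items (a partially missing sum is missing).  A
    respondent with no usable item gets a missing score.  With
    ``dichotomize_at`` set, scores at or below the cut become category 0 and
    scores above it category 1.
    """
    use = [c for c in rule.items if c not in rule.excluded_items]
    X = item_table[use].astype(float).copy()
    if rule.not_applicable_code is not None:
        X = X.mask(X == rule.not_applicable_code)
    if rule.response_range is not None:
        lo, hi = rule.response_range
        bad = (X < lo) | (X > hi)
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"out-of-range response at row {item_table.index[r]}, item {use[c]!r}"
            )
    if rule.method == "sum":
        score = X.sum(axis=1, min_count=len(use)).where(X.notna().all(axis=1))
    else:
        score = X.mean(axis=1)
        if rule.method == "mean_times_k":
            score = score * len(rule.items)
    if rule.dichotomize_at is not None:
        score = (score > rule.dichotomize_at).astype(float).where(score.notna())
    return score


def cronbach_alpha(item_table) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum of item variances / total variance)``.

    Complete rows only; requires at least 2 items and 3 complete respondents.
    """
    X = np.asarray(pd.DataFrame(item_table).dropna(), dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 3:
        raise ValueError("need at least 3 complete respondents")
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise ValueError("zero variance of the item sum; alpha undefined")
    item_var = np.var(X, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y on design X (rows with any NaN propagate NaN)."""
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    if ok.sum() <= X.shape[1]:
        raise ValueError("too few complete observations for regression")
    Xo = X[ok]
    rank = np.linalg.matrix_rank(Xo)
    if rank < Xo.shape[1]:
        # constant columns are benign (intercept absorbs them); true
        # collinearity among non-constant covariates is an error
        keep = [0] + [j for j in range(1, Xo.shape[1]) if np.std(Xo[:, j]) > 0]
        Xo = Xo[:, keep]
        X = X[:, keep]
        if np.linalg.matrix_rank(Xo) < Xo.shape[1]:
            raise ValueError("singular covariate design")
    beta, *_ = np.linalg.lstsq(Xo, y[ok], rcond=None)
    out = np.full_like(y, np.nan, dtype=float)
    out[ok] = y[ok] - Xo @ beta
    partial = np.isfinite(y) & ~ok
    if partial.any():
        out[partial] = np.nan
    return out


def adjust_covariates(
    dataset: TwinDataset,
    continuous_vars=None,
    covariates=("age", "sex"),
    regress_out_moderator_mains: str | None = None,
    log_transform: bool = True,
) -> TwinDataset:
    """Residualize continuous scores on age and sex (pooled individuals).

    Scores are log-transformed first (they must be strictly positive), then
    regressed on centered age and sex; the residuals replace the scores.
    Ordinal variables are untouched — their covariate effects belong in the
    threshold model.  When ``regress_out_moderator_mains`` names a moderator,
    its (adjusted) linear main effect is additionally removed from every other
    adjusted continuous variable.
    """
    ds = dataset.copy()
    if continuous_vars is None:
        continuous_vars = [s.name for s in ds.specs if not s.is_ordinal]
    n = ds.n_pairs
    cov_cols = []
    for cname in covariates:
        v = ds.person_table([cname])[:, 0]
        if cname == "age":
            v = v - np.nanmean(v)
        cov_cols.append(v)
    X = np.column_stack([np.ones(2 * n)] + cov_cols)

    adjusted = {}
    for name in continuous_vars:
        y = ds.person_table([name])[:, 0]
        if log_transform:
            nonpos = np.isfinite(y) & (y <= 0)
            if nonpos.any():
                idx = int(np.argmax(nonpos))
                pair = idx % n
                raise ValueError(
                    f"nonpositive value of {name!r} at pair row {pair} "
                    "cannot be log-transformed"
                )
            y = np.where(np.isfinite(y), np.log(np.where(np.isfinite(y), y, 1.0)), np.nan)
        adjusted[name] = _ols_residuals(y, X)

    if regress_out_moderator_mains is not None:
        mod = regress_out_moderator_mains
        if mod not in adjusted:
            raise KeyError(f"moderator {mod!r} is not among the adjusted variables")
        m = adjusted[mod]
        Xm = np.column_stack([np.ones(2 * n), m])
        for name in continuous_vars:
            if name != mod:
                adjusted[name] = _ols_residuals(adjusted[name], Xm)

    for name, vals in adjusted.items():
        ds.set_person_table([name], vals[:, None])
    return ds


def em_mvnorm(X: np.ndarray, tol: float = 1e-6, max_iter: int = 500):
    """EM for a multivariate normal with missing entries.

    Returns ``(X_imputed, mean, cov, n_iter)``.  The E-step replaces missing
    entries by their conditional means given the observed block (adding the
    conditional covariance to the second-moment statistics); the M-step
    updates the mean vector and covariance.  Observed cells are untouched.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = np.isfinite(X)
    if not np.all(obs.any(axis=0)):
        raise ValueError("a variable is entirely missing")
    if (obs.all(axis=1)).sum() < 2:
        raise ValueError("need at least 2 complete rows")

    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0, ddof=1)
    Sigma = np.diag(np.maximum(var, 1e-8))

    patterns = {}
    for i in range(n):
        patterns.setdefault(obs[i].tobytes(), []).append(i)

    change = np.inf
    for it in range(1, max_iter + 1):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        for patt, rows in patterns.items():
            mask = np.frombuffer(patt, dtype=bool)
            rows = np.asarray(rows)
            o = np.where(mask)[0]
            m = np.where(~mask)[0]
            Xr = X[rows]
            Ex = Xr.copy()
            if m.size:
                if o.size:
                    Soo = Sigma[np.ix_(o, o)]
                    Smo = Sigma[np.ix_(m, o)]
                    K = Smo @ np.linalg.inv(Soo)
                    cond_mean = mu[m] + (Xr[:, o] - mu[o]) @ K.T
                    cond_cov = Sigma[np.ix_(m, m)] - K @ Smo.T
                else:
                    cond_mean = np.broadcast_to(mu[m], (rows.size, m.size))
                    cond_cov = Sigma[np.ix_(m, m)]
                Ex[:, m] = cond_mean
                S2[np.ix_(m, m)] += rows.size * cond_cov
            S1 += Ex.sum(axis=0)
            S2 += Ex.T @ Ex
        mu_new = S1 / n
        Sigma_new = S2 / n - np.outer(mu_new, mu_new)
        change = max(np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max())
        mu, Sigma = mu_new, Sigma_new
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(last parameter change {change:.3g})"
        )

    X_imp = X.copy()
    for patt, rows in patterns.items():
        mask = np.frombuffer(patt, dtype=bool)
        rows = np.asarray(rows)
        o = np.where(mask)[0]
        m = np.where(~mask)[0]
        if not m.size:
            continue
        if o.size:
            K = Sigma[np.ix_(m, o)] @ np.linalg.inv(Sigma[np.ix_(o, o)])
            X_imp[np.ix_(rows, m)] = mu[m] + (X[np.ix_(rows, o)] - mu[o]) @ K.T
        else:
            X_imp[np.ix_(rows, m)] = mu[m]
    return X_imp, mu, Sigma, it


def em_impute(dataset: TwinDataset, max_missing_fraction: float = 0.75,
              tol: float = 1e-6, max_iter: int = 500) -> TwinDataset:
    """Exclude high-missingness individuals, then EM-impute continuous scores.

    An individual missing more than ``max_missing_fraction`` of the model
    variables has all their phenotype scores dropped (the pair is retained as
    an incomplete pair).  Remaining missing continuous values are imputed at
    the score level by :func:`em_mvnorm`; ordinal (liability) variables are
    never imputed.
    """
    ds = dataset.copy()
    all_vars = ds.var_names
    cont_vars = [s.name for s in ds.specs if not s.is_ordinal]
    P = ds.person_table(all_vars)
    frac_missing = (~np.isfinite(P)).mean(axis=1)
    excluded = frac_missing > max_missing_fraction
    if excluded.any():
        P[excluded] = np.nan
        ds.set_person_table(all_vars, P)

    if not cont_vars:
        return ds
    Xc = ds.person_table(cont_vars)
    rows_ok = ~np.all(~np.isfinite(Xc), axis=1) & ~excluded
    if np.isfinite(Xc[rows_ok]).all():
        return ds
    X_imp, *_ = em_mvnorm(Xc[rows_ok], tol=tol, max_iter=max_iter)
    Xc[rows_ok] = X_imp
    ds.set_person_table(cont_vars, Xc)
    return ds
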