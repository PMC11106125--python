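"""Moderated variance-covariance models and moderation curves.

Two layers of moderation analysis over a (moderator, outcome) pair such as
childhood gender nonconformity (CGN) and sexual orientation (SO):

* *Phenotypic* moderation: a per-individual 2x2 Cholesky over (CGN, SO) whose
  paths are linear in the moderator, with saturated per-zygosity cross-twin
  latent correlation blocks — it asks whether observed variances and the
  covariance change with the moderator before any biometric decomposition.
* *Biometric* moderation: the full definition-variable ACE model in which the
  moderator is itself a dependent variable (bivariate with CGN as moderator,
  trivariate with early-life adversity as moderator), asking which latent
  components (A, C, E) carry the moderation.

Moderation curves evaluate the fitted unstandardized component variances and
covariances over a moderator grid (mean +/- 3 SD by default); this is exact
algebra on the estimates, no refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ace import ACEModel, ACEModelSpec
from .inference import FitResult, MLModel
from .io import TwinDataset
from .likelihood import ObsLayout, assemble_mu_bounds, loglik_pairs

__all__ = [
    "PhenotypicModerationModel",
    "fit_phenotypic_moderation",
    "fit_biometric_moderation",
    "biometric_model",
    "ModerationCurve",
    "moderation_curve",
    "moderation_table",
    "plot_moderation_curve",
]

_SPECTRAL_FLOOR = 1e-8


# -- phenotypic moderation -------------------------------------------------

def _project_cross(R):
    """Floor the spectrum of [[I, R], [R', I]] and return the adjusted R."""
    k = R.shape[0]
    J = np.empty((2 * k, 2 * k))
    J[:k, :k] = J[k:, k:] = np.eye(k)
    J[:k, k:] = R
    J[k:, :k] = R.T
    w, Q = np.linalg.eigh(J)
    if w.min() >= _SPECTRAL_FLOOR:
        return R
    w = np.maximum(w, _SPECTRAL_FLOOR)
    J2 = (Q * w) @ Q.T
    d = 1.0 / np.sqrt(np.diag(J2))
    J2 = J2 * np.outer(d, d)
    return J2[:k, k:]


class PhenotypicModerationModel(MLModel):
    """Moderated phenotypic Cholesky over (moderator-linked) variable pair.

    ``model1``: the first variable (e.g. CGN) moderates the covariance path
    and the second variable's specific path.  ``model2``: an external
    moderator (e.g. ELA, with main effects already regressed out upstream)
    additionally moderates the first variable's own path.

    The second variable may be a liability trait; its row is identified by
    rescaling to unit variance at the moderator mean, and its threshold is a
    free parameter.  Cross-twin structure is a free symmetric latent
    correlation matrix per zygosity.
    """

    def __init__(self, dataset: TwinDataset, variables, moderator: str,
                 threshold_covariates=()):
        self.dataset = dataset
        self.names = list(variables)
        if len(self.names) != 2:
            raise ValueError("phenotypic moderation is defined for a variable pair")
        self.k = 2
        self.specs = [dataset.spec(n) for n in self.names]
        self.moderator = moderator
        self.external_moderator = moderator not in self.names
        self.threshold_covariates = tuple(threshold_covariates)
        self._prepare(dataset)
        self._build_params()

    def _prepare(self, ds):
        k = self.k
        vals = {n: ds.values(n) for n in self.names}
        mv = ds.values(self.moderator)
        keep = np.isfinite(mv).all(axis=1)
        any_obs = np.zeros(ds.n_pairs, dtype=bool)
        for n in self.names:
            any_obs |= np.isfinite(vals[n]).any(axis=1)
        keep &= any_obs
        n_pairs = int(keep.sum())
        y = np.empty((n_pairs, 2 * k))
        for i, name in enumerate(self.names):
            v = vals[name][keep]
            y[:, i], y[:, k + i] = v[:, 0], v[:, 1]
        ord_slots = [s for i, vs in enumerate(self.specs) if vs.is_ordinal
                     for s in (i, k + i)]
        self.layout = ObsLayout.from_values(y, ord_slots)
        self._codes = {
            slot: np.where(np.isfinite(y[:, slot]), y[:, slot], 0).astype(int)
            for slot in ord_slots
        }
        self.is_mz = ds.is_mz[keep]
        m = mv[keep]
        self.m_center = float(np.mean(m))
        self.m_sd = float(np.std(m, ddof=1))
        self.M1 = m[:, 0] - self.m_center
        self.M2 = m[:, 1] - self.m_center
        self._thr_cov = {}
        for cname in self.threshold_covariates:
            cv = ds.values(cname)[keep]
            if cname == "age":
                cv = cv - np.nanmean(cv)
            self._thr_cov[cname] = np.nan_to_num(cv)

    def _build_params(self):
        names = ["p_11", "p_21"]
        if not self.specs[1].is_ordinal:
            names.append("p_22")
        if self.external_moderator:
            names.append("b_11")
        names.extend(["b_21", "b_22"])
        for i, vs in enumerate(self.specs):
            if vs.is_ordinal:
                names.append(f"tau_{vs.name}")
                names.extend(f"g_{c}_{vs.name}" for c in self.threshold_covariates)
            else:
                names.append(f"mu_{vs.name}")
        for zyg in ("mz", "dz"):
            names.extend([f"zr{zyg}_11", f"zr{zyg}_21", f"zr{zyg}_22"])
        self.param_names = names
        self._index = {n: i for i, n in enumerate(names)}

    def start_values(self):
        theta = np.zeros(len(self.param_names))
        k = self.k
        g = lambda name: self._index[name]
        col0 = self.layout.y[:, [0, k]].ravel()
        col0 = col0[np.isfinite(col0)]
        theta[g("p_11")] = np.std(col0, ddof=1) if col0.size > 1 else 1.0
        theta[g("p_21")] = 0.1
        if "p_22" in self._index:
            col1 = self.layout.y[:, [1, k + 1]].ravel()
            col1 = col1[np.isfinite(col1)]
            theta[g("p_22")] = np.std(col1, ddof=1) if col1.size > 1 else 1.0
        for i, vs in enumerate(self.specs):
            col = self.layout.y[:, [i, k + i]].ravel()
            col = col[np.isfinite(col)]
            if vs.is_ordinal:
                phat = np.clip(col.mean() if col.size else 0.1, 0.02, 0.98)
                theta[g(f"tau_{vs.name}")] = float(norm.ppf(1 - phat))
            else:
                theta[g(f"mu_{vs.name}")] = float(col.mean()) if col.size else 0.0
        for zyg, r0 in (("mz", 0.4), ("dz", 0.2)):
            theta[g(f"zr{zyg}_11")] = np.arctanh(r0)
            theta[g(f"zr{zyg}_22")] = np.arctanh(r0)
        return theta

    def _decode(self, theta):
        gt = lambda name, d=0.0: theta[self._index[name]] if name in self._index else d
        p11 = gt("p_11")
        p21 = gt("p_21")
        p22 = gt("p_22", 1.0)
        if self.specs[1].is_ordinal:
            s = 1.0 / np.sqrt(p21 * p21 + p22 * p22)
            p21, p22 = p21 * s, p22 * s
        b11 = gt("b_11")
        b21 = gt("b_21")
        b22 = gt("b_22")
        R = {}
        for zyg in ("mz", "dz"):
            r11 = np.tanh(gt(f"zr{zyg}_11"))
            r21 = np.tanh(gt(f"zr{zyg}_21"))
            r22 = np.tanh(gt(f"zr{zyg}_22"))
            R[zyg] = _project_cross(np.array([[r11, r21], [r21, r22]]))
        means = np.zeros(2)
        taus = {}
        gammas = {}
        for i, vs in enumerate(self.specs):
            if vs.is_ordinal:
                taus[vs.name] = np.array([gt(f"tau_{vs.name}")])
                gammas[vs.name] = {c: gt(f"g_{c}_{vs.name}")
                                   for c in self.threshold_covariates}
            else:
                means[i] = gt(f"mu_{vs.name}")
        L = np.array([[p11, 0.0], [p21, p22]])
        B = np.array([[b11, 0.0], [b21, b22]])
        return L, B, R, means, taus, gammas

    def _sigma(self, L, B, R):
        n = self.M1.size
        out = np.empty((n, 4, 4))
        l1 = {(i, j): L[i, j] + B[i, j] * self.M1 if B[i, j] != 0 else L[i, j]
              for i in range(2) for j in range(i + 1)}
        l2 = {(i, j): L[i, j] + B[i, j] * self.M2 if B[i, j] != 0 else L[i, j]
              for i in range(2) for j in range(i + 1)}
        Rz = np.where(self.is_mz[:, None, None], R["mz"][None], R["dz"][None])

        def within(l):
            return {(0, 0): l[(0, 0)] * l[(0, 0)],
                    (1, 0): l[(1, 0)] * l[(0, 0)],
                    (1, 1): l[(1, 0)] * l[(1, 0)] + l[(1, 1)] * l[(1, 1)]}

        w1, w2 = within(l1), within(l2)
        for (i, j), v in w1.items():
            out[:, i, j] = out[:, j, i] = v
        for (i, j), v in w2.items():
            out[:, 2 + i, 2 + j] = out[:, 2 + j, 2 + i] = v
        # cross block: L(M1) Rz L(M2)'
        for i in range(2):
            for j in range(2):
                s = 0.0
                for (li, ll) in [(0, (0, 0))] if i == 0 else [(0, (1, 0)), (1, (1, 1))]:
                    for (mj, mm) in [(0, (0, 0))] if j == 0 else [(0, (1, 0)), (1, (1, 1))]:
                        s = s + l1[ll] * Rz[:, li, mj] * l2[mm]
                out[:, i, 2 + j] = s
                out[:, 2 + j, i] = s
        return out

    def minus2ll(self, theta):
        L, B, R, means, taus, gammas = self._decode(np.asarray(theta, float))
        Sigma = self._sigma(L, B, R)
        n = self.layout.n
        mu, lo, hi = assemble_mu_bounds(self.specs, means, taus, gammas,
                                        self._thr_cov, self._codes, n, self.k)
        ll = loglik_pairs(Sigma, mu, lo, hi, self.layout)
        if not np.all(np.isfinite(ll)):
            return np.inf
        return float(-2.0 * ll.sum())

    @property
    def n_observed_statistics(self):
        return self.layout.n_observed_statistics

    @property
    def n_pairs_used(self):
        return self.layout.n


def fit_phenotypic_moderation(dataset: TwinDataset, model: str,
                              variables=("CGN", "SO"), ci_params=(),
                              threshold_covariates=(), **fit_kw) -> FitResult:
    """Fit phenotypic moderation model 1 (first variable as moderator) or
    model 2 (external moderator, default ELA, main effects pre-regressed).

    ``model`` is ``"model1_CGN"``-style: everything after the first underscore
    names the moderator.  Moderation masks follow the design: model 1 frees
    the covariance and outcome-specific slopes; model 2 additionally frees the
    first variable's own slope.
    """
    kind, _, mod = model.partition("_")
    if kind not in ("model1", "model2") or not mod:
        raise ValueError("model must be like 'model1_CGN' or 'model2_ELA'")
    if kind == "model1" and mod != variables[0]:
        raise ValueError("model1 uses the first modeled variable as moderator")
    if kind == "model2" and mod in variables:
        raise ValueError("model2 uses an external moderator")
    m = PhenotypicModerationModel(dataset, variables, moderator=mod,
                                  threshold_covariates=threshold_covariates)
    return m.fit(ci_params=ci_params, **fit_kw)


# -- biometric moderation --------------------------------------------------

_DESIGNS = {
    "bivariate_CGN": {
        "variables": ("CGN", "SO"),
        "moderator": "CGN",
        "paths": ((2, 1), (2, 2)),
    },
    "trivariate_ELA": {
        "variables": ("ELA", "CGN", "SO"),
        "moderator": "ELA",
        "paths": ((2, 1), (2, 2), (3, 1), (3, 2), (3, 3)),
    },
}
# Table rows reported by default: the moderator-outcome sub-results
_REPORTED = {
    "bivariate_CGN": {("A", 2, 1): "CGN-SO covariance", ("E", 2, 1): "CGN-SO covariance",
                      ("A", 2, 2): "SO variance", ("E", 2, 2): "SO variance",
                      ("C", 2, 1): "CGN-SO covariance", ("C", 2, 2): "SO variance"},
    "trivariate_ELA": {("A", 2, 2): "CGN variance", ("E", 2, 2): "CGN variance",
                       ("C", 2, 2): "CGN variance",
                       ("A", 3, 2): "CGN-SO covariance", ("E", 3, 2): "CGN-SO covariance",
                       ("C", 3, 2): "CGN-SO covariance",
                       ("A", 3, 3): "SO variance", ("E", 3, 3): "SO variance",
                       ("C", 3, 3): "SO variance"},
}


def biometric_model(dataset: TwinDataset, design: str, include_C: bool = False,
                    threshold_covariates=()) -> ACEModel:
    """Construct the moderated Cholesky ACE model for a named design."""
    try:
        d = _DESIGNS[design]
    except KeyError:
        raise ValueError(f"unknown design {design!r}; "
                         f"one of {sorted(_DESIGNS)}") from None
    comps = ("A", "C", "E") if include_C else ("A", "E")
    free_mods = [(c, i, j) for c in comps for i, j in d["paths"]]
    model = ACEModel(dataset, variables=list(d["variables"]), include_C=include_C,
                     moderator=d["moderator"], free_mods=free_mods,
                     threshold_covariates=threshold_covariates)
    if len(model.param_names) > model.n_observed_statistics:
        raise ValueError("model is not identified: more free parameters than "
                         "observed statistics")
    return model


def slope_ladder(design: str, values=(-0.6, 0.0, 0.6)) -> list:
    """Start overrides spanning the outcome-specific E-slope basins.

    The deviance of moderated liability models can be bimodal in the
    specific-variance slope (the moderated path may cross zero inside the
    observed moderator range), so fits are launched from a ladder of slope
    starts and the best deviance wins.
    """
    k = len(_DESIGNS[design]["variables"])
    name = f"bE_{k}{k}"
    return [{name: v} for v in values]


def fit_biometric_moderation(dataset: TwinDataset, design: str,
                             include_C: bool = False, ci_params=(),
                             threshold_covariates=(), starts=None,
                             **fit_kw) -> FitResult:
    """Fit the bivariate or trivariate biometric moderation model.

    C paths (and their moderation) are dropped by default, mirroring the
    simplification justified by a null drop-C likelihood-ratio test; pass
    ``include_C=True`` to keep them.  Fits run from a ladder of
    outcome-specific slope starts (see :func:`slope_ladder`) unless an
    explicit ``starts`` list is given.
    """
    model = biometric_model(dataset, design, include_C=include_C,
                            threshold_covariates=threshold_covariates)
    if starts is None:
        starts = slope_ladder(design)
    return model.fit(ci_params=ci_params, starts=starts, **fit_kw)


def moderation_table(fit: FitResult, design: str, full: bool = False) -> pd.DataFrame:
    """Moderator x component x target table of moderation estimates.

    By default only the moderator-outcome sub-results are reported (the
    trivariate model estimates more slopes than it reports); ``full=True``
    lists every freed term.
    """
    d = _DESIGNS[design]
    reported = _REPORTED[design]
    rows = []
    for name, est in fit.estimates.items():
        if not name.startswith("b"):
            continue
        comp, ij = name[1:].split("_")
        i, j = int(ij[0]), int(ij[1])
        key = (comp, i, j)
        if not full and key not in reported:
            continue
        target = reported.get(key, f"path {i}{j}")
        lo, hi = fit.ci95.get(name, (np.nan, np.nan))
        rows.append({"moderator": d["moderator"], "component": comp,
                     "target": target, "path": f"{i}{j}", "estimate": est,
                     "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


# -- moderation curves -----------------------------------------------------

@dataclass
class ModerationCurve:
    """Component (co)variances as exact functions of the moderator."""

    variable: str
    with_variable: str | None
    grid: np.ndarray              # centered moderator values
    varA: np.ndarray
    varC: np.ndarray
    varE: np.ndarray
    total_var: np.ndarray
    mean: np.ndarray
    covA: np.ndarray | None = None
    covC: np.ndarray | None = None
    covE: np.ndarray | None = None
    total_cov: np.ndarray | None = None
    r: np.ndarray | None = None
    moderator_sd: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        d = {"M": self.grid, "varA": self.varA, "varC": self.varC,
             "varE": self.varE, "total_var": self.total_var, "mean": self.mean}
        if self.covA is not None:
            d.update({"covA": self.covA, "covC": self.covC, "covE": self.covE,
                      "total_cov": self.total_cov, "r": self.r})
        return pd.DataFrame(d)


def _row_at(P, Bm, i, M):
    return P[i, : i + 1][None, :] + Bm[i, : i + 1][None, :] * M[:, None]


def moderation_curve(model, fit: FitResult, variable: str,
                     with_variable: str | None = None,
                     grid_sd: float = 3.0, n_grid: int = 61) -> ModerationCurve:
    """Evaluate fitted component variances/covariances over a moderator grid.

    The grid spans the moderator mean +/- ``grid_sd`` sample SDs (centered
    scale).  Pure algebra on the estimates — no refitting.  ``with_variable``
    adds the covariance decomposition and the model-implied correlation.
    """
    spec: ACEModelSpec = model.spec_from(fit) if hasattr(model, "spec_from") else model
    names = spec.var_names
    if variable not in names:
        raise KeyError(f"unknown variable {variable!r}")
    if with_variable is not None and with_variable not in names:
        raise KeyError(f"unknown variable {with_variable!r}")
    sd = getattr(model, "m_sd", 1.0)
    grid = np.linspace(-grid_sd * sd, grid_sd * sd, n_grid)
    i = names.index(variable)

    def comps_for(idx):
        va = (_row_at(spec.paths.a, spec.mods.beta_a, idx, grid) ** 2).sum(axis=1)
        vc = (_row_at(spec.paths.c, spec.mods.beta_c, idx, grid) ** 2).sum(axis=1)
        ve = (_row_at(spec.paths.e, spec.mods.beta_e, idx, grid) ** 2).sum(axis=1)
        return va, vc, ve

    varA, varC, varE = comps_for(i)
    total = varA + varC + varE
    mean = np.full(grid.size, spec.means[i])
    curve = ModerationCurve(variable=variable, with_variable=with_variable,
                            grid=grid, varA=varA, varC=varC, varE=varE,
                            total_var=total, mean=mean, moderator_sd=sd)
    if with_variable is not None:
        j = names.index(with_variable)
        lo_, hi_ = (j, i) if i > j else (i, j)
        width = lo_ + 1

        def cov_for(P, Bm):
            ri = _row_at(P, Bm, hi_, grid)[:, :width]
            rj = _row_at(P, Bm, lo_, grid)[:, :width]
            return (ri * rj).sum(axis=1)

        curve.covA = cov_for(spec.paths.a, spec.mods.beta_a)
        curve.covC = cov_for(spec.paths.c, spec.mods.beta_c)
        curve.covE = cov_for(spec.paths.e, spec.mods.beta_e)
        curve.total_cov = curve.covA + curve.covC + curve.covE
        vja, vjc, vje = comps_for(j)
        other_total = vja + vjc + vje
        curve.r = curve.total_cov / np.sqrt(total * other_total)
    return curve


def plot_moderation_curve(curve: ModerationCurve, path=None, ax=None):
    """Fig-3 style plot of component variances (and covariance) versus M."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    ax.plot(curve.grid, curve.varA, label="A", color="tab:blue")
    if np.any(curve.varC):
        ax.plot(curve.grid, curve.varC, label="C", color="tab:green")
    ax.plot(curve.grid, curve.varE, label="E", color="tab:orange")
    ax.plot(curve.grid, curve.total_var, label="total", color="black", ls="--")
    if curve.total_cov is not None:
        ax.plot(curve.grid, curve.total_cov, label=f"cov w/ {curve.with_variable}",
                color="tab:red", ls=":")
    ax.set_xlabel("moderator (centered)")
    ax.set_ylabel(f"unstandardized components: {curve.variable}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return ax
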