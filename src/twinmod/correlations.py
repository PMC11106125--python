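"""Constrained ML twin correlations: Pearson, polyserial and polychoric.

The saturated twin correlation model estimates, by joint maximum likelihood
over all pairs, a within-person correlation matrix (constrained equal across
birth order and zygosity), plus symmetric cross-twin correlation matrices
estimated separately for MZ and DZ pairs.  Variable scales dictate the
correlation type automatically: latent-normal (polychoric/polyserial)
correlations for ordinal variables through the liability likelihood, Pearson
for continuous pairs.  Incomplete pairs contribute their observed margins.

Correlations are parameterized through hyperbolic tangents of unbounded
parameters; if a proposed joint pair matrix leaves the positive semi-definite
cone it is projected back by flooring its spectrum at 1e-8 and renormalizing
the diagonal, so the optimizer cannot escape the valid region.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .bvn import bvn_cdf
from .inference import FitResult, MLModel, profile_ci
from .io import TwinDataset
from .likelihood import ObsLayout, assemble_mu_bounds, loglik_pairs

__all__ = [
    "CorrelationTable",
    "polychoric_from_table",
    "SaturatedCorrelationModel",
    "fit_saturated_correlations",
]

_SPECTRAL_FLOOR = 1e-8
_RHO_BOUND = 1.0 - 1e-6


@dataclass
class CorrelationTable:
    """Within-person and cross-twin (MZ/DZ) correlation matrices with CIs."""

    variables: list
    within_person: np.ndarray
    cross_twin_mz: np.ndarray
    cross_twin_dz: np.ndarray
    ci_within: dict = field(default_factory=dict)     # (i, j) -> (lo, hi)
    ci_mz: dict = field(default_factory=dict)
    ci_dz: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    fit: FitResult | None = None

    def to_csv(self, path) -> None:
        """Three stacked panels: within-person, cross-twin MZ, cross-twin DZ."""
        k = len(self.variables)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["panel", "row", "col", "r", "ci_lo", "ci_hi"])
            panels = [("within_person", self.within_person, self.ci_within),
                      ("cross_twin_MZ", self.cross_twin_mz, self.ci_mz),
                      ("cross_twin_DZ", self.cross_twin_dz, self.ci_dz)]
            for name, mat, cis in panels:
                for i in range(k):
                    jmax = i if name == "within_person" else i + 1
                    for j in range(jmax):
                        lo, hi = cis.get((i, j), ("", ""))
                        w.writerow([name, self.variables[i], self.variables[j],
                                    repr(float(mat[i, j])), lo, hi])


# -- polychoric from a contingency table -----------------------------------

def _cell_probs(rho, tau_r, tau_c):
    """Rectangle probabilities for every cell of an r x c table."""
    er = np.concatenate([[-np.inf], tau_r, [np.inf]])
    ec = np.concatenate([[-np.inf], tau_c, [np.inf]])
    H = bvn_cdf(er[:, None], ec[None, :], rho)
    return np.diff(np.diff(H, axis=0), axis=1)


def polychoric_from_table(counts):
    """ML polychoric correlation and thresholds from a 2-way table.

    The likelihood is multinomial over bivariate-normal rectangle
    probabilities.  Empty margins are collapsed (with a warning); a perfectly
    associated table yields a correlation at the boundary ``+/-(1 - 1e-6)``.

    Returns ``(rho, (row_thresholds, col_thresholds))``.
    """
    import warnings

    C = np.asarray(counts, dtype=float)
    if C.ndim != 2 or np.any(C < 0):
        raise ValueError("counts must be a nonnegative 2-way table")
    rm = C.sum(axis=1) > 0
    cm = C.sum(axis=0) > 0
    if not rm.all() or not cm.all():
        warnings.warn("collapsing empty margins of the contingency table")
        C = C[rm][:, cm]
    if C.shape[0] < 2 or C.shape[1] < 2:
        raise ValueError("need at least 2 categories per margin")
    n = C.sum()
    if n < 10:
        raise ValueError("need total count >= 10")

    # start: thresholds from cumulative margins, rho from normal scores
    pr = np.cumsum(C.sum(axis=1))[:-1] / n
    pc = np.cumsum(C.sum(axis=0))[:-1] / n
    t_r0 = norm.ppf(pr)
    t_c0 = norm.ppf(pc)

    def pack(z, tr, tc):
        return np.concatenate([[z], tr, tc])

    def unpack(theta):
        z = theta[0]
        tr = np.sort(theta[1:C.shape[0]])
        tc = np.sort(theta[C.shape[0]:])
        return np.tanh(z) * _RHO_BOUND, tr, tc

    def nll(theta):
        rho, tr, tc = unpack(theta)
        P = np.clip(_cell_probs(rho, tr, tc), 1e-300, 1.0)
        return -float((C * np.log(P)).sum())

    res = optimize.minimize(nll, pack(0.0, t_r0, t_c0), method="L-BFGS-B",
                            options={"maxiter": 500})
    rho, tr, tc = unpack(res.x)
    return float(rho), (tr, tc)


# -- saturated pairwise correlation model ----------------------------------

def _project_corr(R):
    """Spectral floor + diagonal renormalization; keeps R a correlation matrix."""
    w, Q = np.linalg.eigh(R)
    if w.min() >= _SPECTRAL_FLOOR:
        return R
    w = np.maximum(w, _SPECTRAL_FLOOR)
    R2 = (Q * w) @ Q.T
    d = 1.0 / np.sqrt(np.diag(R2))
    return R2 * np.outer(d, d)


class SaturatedCorrelationModel(MLModel):
    """Joint ML for the constrained twin correlation structure.

    Parameters: unbounded ``z`` (atanh) values for each within-person
    correlation (equal across twins and zygosity) and for each entry of the
    symmetric cross-twin matrices (per zygosity, including the diagonal twin
    correlations); means and log-SDs per continuous variable; thresholds per
    ordinal variable.
    """

    def __init__(self, dataset: TwinDataset, threshold_covariates=()):
        self.dataset = dataset
        self.specs = list(dataset.specs)
        self.names = dataset.var_names
        self.k = len(self.names)
        self.threshold_covariates = tuple(threshold_covariates)

        k = self.k
        vals = {n: dataset.values(n) for n in self.names}
        keep = np.zeros(dataset.n_pairs, dtype=bool)
        for n in self.names:
            keep |= np.isfinite(vals[n]).any(axis=1)
        self._keep = keep
        nk = int(keep.sum())
        y = np.empty((nk, 2 * k))
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
        self.is_mz = dataset.is_mz[keep]
        self._thr_cov = {}
        for cname in self.threshold_covariates:
            cv = dataset.values(cname)[keep]
            if cname == "age":
                cv = cv - np.nanmean(cv)
            self._thr_cov[cname] = np.nan_to_num(cv)

        names = []
        for i in range(k):
            for j in range(i):
                names.append(f"zw_{i + 1}{j + 1}")
        for zyg in ("mz", "dz"):
            for i in range(k):
                for j in range(i + 1):
                    names.append(f"z{zyg}_{i + 1}{j + 1}")
        for vs in self.specs:
            if vs.is_ordinal:
                ncut = vs.n_categories - 1
                if ncut == 1:
                    names.append(f"tau_{vs.name}")
                else:
                    names.extend(f"tau_{vs.name}_{c}" for c in range(1, ncut + 1))
                for cname in self.threshold_covariates:
                    names.append(f"g_{cname}_{vs.name}")
            else:
                names.append(f"mu_{vs.name}")
                names.append(f"lsd_{vs.name}")
        self.param_names = names
        self._index = {n: i for i, n in enumerate(names)}

    def start_values(self):
        theta = np.zeros(len(self.param_names))
        k = self.k
        for i, vs in enumerate(self.specs):
            col = np.concatenate([self.layout.y[:, i], self.layout.y[:, k + i]])
            col = col[np.isfinite(col)]
            if vs.is_ordinal:
                if vs.n_categories == 2:
                    phat = np.clip(col.mean() if col.size else 0.1, 0.02, 0.98)
                    theta[self._index[f"tau_{vs.name}"]] = float(norm.ppf(1 - phat))
                else:
                    for c in range(1, vs.n_categories):
                        q = np.clip(np.mean(col < c), 0.01, 0.99)
                        theta[self._index[f"tau_{vs.name}_{c}"]] = float(norm.ppf(q))
            else:
                theta[self._index[f"mu_{vs.name}"]] = float(np.mean(col)) if col.size else 0.0
                sd = float(np.std(col, ddof=1)) if col.size > 1 else 1.0
                theta[self._index[f"lsd_{vs.name}"]] = np.log(max(sd, 1e-6))
        # modest positive twin correlations as starting guesses
        for i in range(k):
            theta[self._index[f"zmz_{i + 1}{i + 1}"]] = np.arctanh(0.4)
            theta[self._index[f"zdz_{i + 1}{i + 1}"]] = np.arctanh(0.2)
        return theta

    def _decode(self, theta):
        k = self.k
        Rw = np.eye(k)
        for i in range(k):
            for j in range(i):
                Rw[i, j] = Rw[j, i] = np.tanh(theta[self._index[f"zw_{i + 1}{j + 1}"]])
        B = {}
        for zyg in ("mz", "dz"):
            M = np.empty((k, k))
            for i in range(k):
                for j in range(i + 1):
                    M[i, j] = M[j, i] = np.tanh(theta[self._index[f"z{zyg}_{i + 1}{j + 1}"]])
            B[zyg] = M
        sds = np.ones(k)
        means = np.zeros(k)
        taus = {}
        gammas = {}
        for i, vs in enumerate(self.specs):
            if vs.is_ordinal:
                ncut = vs.n_categories - 1
                if ncut == 1:
                    taus[vs.name] = np.array([theta[self._index[f"tau_{vs.name}"]]])
                else:
                    tau = np.array([theta[self._index[f"tau_{vs.name}_{c}"]]
                                    for c in range(1, ncut + 1)])
                    if np.any(np.diff(tau) <= 0):
                        raise FloatingPointError("non-monotone thresholds")
                    taus[vs.name] = tau
                gammas[vs.name] = {c: theta[self._index[f"g_{c}_{vs.name}"]]
                                   for c in self.threshold_covariates}
            else:
                means[i] = theta[self._index[f"mu_{vs.name}"]]
                # clamp so an excursion of the optimizer cannot overflow exp
                sds[i] = np.exp(np.clip(theta[self._index[f"lsd_{vs.name}"]], -20, 20))
        return Rw, B, sds, means, taus, gammas

    def _sigma_for(self, Rw, Bz, sds):
        k = self.k
        R = np.empty((2 * k, 2 * k))
        R[:k, :k] = R[k:, k:] = Rw
        R[:k, k:] = R[k:, :k] = Bz
        R = _project_corr(R)
        d = np.concatenate([sds, sds])
        return R * np.outer(d, d)

    def minus2ll(self, theta):
        try:
            Rw, B, sds, means, taus, gammas = self._decode(np.asarray(theta, float))
        except FloatingPointError:
            return np.inf
        S_mz = self._sigma_for(Rw, B["mz"], sds)
        S_dz = self._sigma_for(Rw, B["dz"], sds)
        n = self.layout.n
        Sigma = np.where(self.is_mz[:, None, None], S_mz[None], S_dz[None])
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

    def table_from(self, result: FitResult, ci: bool = False) -> CorrelationTable:
        theta = np.array([result.estimates[n] for n in self.param_names])
        Rw, B, sds, means, taus, gammas = self._decode(theta)
        table = CorrelationTable(
            variables=list(self.names),
            within_person=Rw,
            cross_twin_mz=B["mz"],
            cross_twin_dz=B["dz"],
            thresholds=dict(taus),
            fit=result,
        )
        if ci:
            k = self.k
            def _ci(pname):
                lo, hi = profile_ci(self, result, pname)
                return (float(np.tanh(lo)), float(np.tanh(hi)))
            for i in range(k):
                for j in range(i):
                    table.ci_within[(i, j)] = _ci(f"zw_{i + 1}{j + 1}")
            for zyg, store in (("mz", table.ci_mz), ("dz", table.ci_dz)):
                for i in range(k):
                    for j in range(i + 1):
                        store[(i, j)] = _ci(f"z{zyg}_{i + 1}{j + 1}")
        return table


def fit_saturated_correlations(dataset: TwinDataset, ci: bool = False,
                               threshold_covariates=(), **fit_kw) -> CorrelationTable:
    """Fit the constrained saturated twin correlation model.

    Requires at least 30 complete pairs per zygosity group.  Returns a
    :class:`CorrelationTable`; profile-likelihood CIs are computed on the
    atanh scale when ``ci=True`` (they respect the [-1, 1] range).
    """
    complete = np.ones(dataset.n_pairs, dtype=bool)
    for name in dataset.var_names:
        complete &= np.isfinite(dataset.values(name)).all(axis=1)
    for zyg, mask in (("MZ", dataset.is_mz), ("DZ", ~dataset.is_mz)):
        if (complete & mask).sum() < 30:
            raise ValueError(f"need >= 30 complete {zyg} pairs")
    model = SaturatedCorrelationModel(dataset, threshold_covariates=threshold_covariates)
    result = model.fit(**fit_kw)
    return model.table_from(result, ci=ci)
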