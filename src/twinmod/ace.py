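"""Cholesky ACE twin models with definition-variable path moderation.

The classical twin design decomposes phenotypic (co)variance into additive
genetic (A), shared environmental (C) and unique environmental (E) components
from the differing genetic resemblance of MZ and DZ pairs: cross-twin
component correlations are fixed at 1/0.5 (A, by zygosity), 1 (C) and 0 (E).
Multivariate structure is parameterized through lower-triangular path matrices
``a``, ``c``, ``e`` (a Cholesky factorization per component), so the implied
within-person covariance ``a a' + c c' + e e'`` is positive semi-definite by
construction.

Moderation follows the definition-variable construction: every path may be a
linear function of an observed per-twin moderator value, ``a_ij + bA_ij * M``
(and likewise for C and E), with each twin's block using that twin's own M
and cross-twin A/C terms using ``a(M1) a(M2)'``.  The moderator's own paths
are structurally unmoderated.

Binary traits enter as liability-threshold variables: a latent standard-normal
liability dichotomized at a threshold that may shift with covariates.  The
liability scale is identified by rescaling the unmoderated paths of an ordinal
variable so its total variance equals 1 at the moderator's centering point
(M = 0); moderated variance then varies freely with M.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import norm

from .inference import FitResult, MLModel
from .io import TwinDataset, VariableSpec
from .likelihood import ObsLayout, assemble_mu_bounds, loglik_pairs

__all__ = [
    "PathMatrices",
    "ModerationCoefficients",
    "ThresholdModel",
    "ACEModelSpec",
    "StandardizedComponents",
    "FalconerEstimates",
    "ACEModel",
    "expected_pair_covariance",
    "pair_loglik",
    "fit_ace",
    "standardize_components",
    "falconer_estimates",
    "liability_threshold",
    "spec_to_yaml",
    "spec_from_yaml",
]

R_A = {"MZ": 1.0, "DZ": 0.5}   # additive-genetic cross-twin correlation
R_C = 1.0                      # shared environment is fully shared
R_E = 0.0                      # unique environment is uncorrelated across twins


def _lower(mat, name):
    m = np.asarray(mat, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, np.tril(m)):
        raise ValueError(f"{name} must be lower-triangular")
    return m


@dataclass
class PathMatrices:
    """Lower-triangular a/c/e path coefficient matrices (k x k)."""

    a: np.ndarray
    c: np.ndarray
    e: np.ndarray

    def __post_init__(self):
        self.a = _lower(self.a, "a")
        self.c = _lower(self.c, "c")
        self.e = _lower(self.e, "e")
        if not (self.a.shape == self.c.shape == self.e.shape):
            raise ValueError("a, c, e must share one shape")

    @property
    def k(self) -> int:
        return self.a.shape[0]


@dataclass
class ModerationCoefficients:
    """Per-path moderation slopes; moderated path = path + beta * M."""

    beta_a: np.ndarray
    beta_c: np.ndarray
    beta_e: np.ndarray

    def __post_init__(self):
        self.beta_a = _lower(self.beta_a, "beta_a")
        self.beta_c = _lower(self.beta_c, "beta_c")
        self.beta_e = _lower(self.beta_e, "beta_e")

    @classmethod
    def zeros(cls, k: int) -> "ModerationCoefficients":
        z = np.zeros((k, k))
        return cls(z.copy(), z.copy(), z.copy())

    @property
    def any_nonzero(self) -> bool:
        return bool(np.any(self.beta_a) or np.any(self.beta_c) or np.any(self.beta_e))


@dataclass
class ThresholdModel:
    """Liability thresholds, shifted linearly by covariates.

    ``tau`` holds the baseline cutpoints (strictly increasing, in liability SD
    units); ``gammas`` maps covariate names ("age", "sex", "moderator") to
    per-unit threshold shifts.
    """

    tau: np.ndarray
    gammas: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if self.tau.size > 1 and np.any(np.diff(self.tau) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def shifted(self, covariates: dict) -> np.ndarray:
        shift = 0.0
        for name, g in self.gammas.items():
            shift = shift + g * covariates.get(name, 0.0)
        return self.tau[None, :] + np.atleast_1d(shift)[:, None]


@dataclass
class ACEModelSpec:
    """A complete moderated ACE model: paths, moderation, thresholds, means."""

    variables: list
    paths: PathMatrices
    mods: ModerationCoefficients | None = None
    thresholds: dict = field(default_factory=dict)
    means: np.ndarray | None = None
    include_C: bool = True
    moderator: str | None = None

    def __post_init__(self):
        k = self.paths.k
        if len(self.variables) != k:
            raise ValueError("variables and path matrices disagree on k")
        if self.mods is None:
            self.mods = ModerationCoefficients.zeros(k)
        if self.means is None:
            self.means = np.zeros(k)
        self.means = np.asarray(self.means, dtype=float)
        if not self.include_C and np.any(self.paths.c):
            raise ValueError("include_C=False but c paths are nonzero")
        if self.moderator is not None:
            i = self.var_index(self.moderator)
            for B in (self.mods.beta_a, self.mods.beta_c, self.mods.beta_e):
                if np.any(B[i, :]):
                    raise ValueError(
                        "the moderator's own paths must be unmoderated "
                        f"(row {i} of a beta matrix is nonzero)"
                    )
        elif self.mods.any_nonzero:
            raise ValueError("moderation coefficients set but no moderator named")
        for name in self.thresholds:
            if self.var_spec(name).scale != "ordinal":
                raise ValueError(f"threshold model given for non-ordinal {name!r}")

    @property
    def k(self) -> int:
        return self.paths.k

    @property
    def var_names(self) -> list:
        return [v.name if isinstance(v, VariableSpec) else str(v) for v in self.variables]

    def var_index(self, name: str) -> int:
        return self.var_names.index(name)

    def var_spec(self, name: str) -> VariableSpec:
        v = self.variables[self.var_index(name)]
        if isinstance(v, VariableSpec):
            return v
        raise TypeError("variables must be VariableSpec instances")

    @property
    def ordinal_names(self) -> list:
        return [v.name for v in self.variables
                if isinstance(v, VariableSpec) and v.is_ordinal]


# -- expected covariance ---------------------------------------------------

def _pair_sigma(a, c, e, ba, bc, be, rA, M1, M2) -> np.ndarray:
    """Implied (n, 2k, 2k) pair covariances from raw path/moderation arrays.

    Entry-level assembly: unmoderated path entries stay python scalars, so the
    per-pair work is a handful of length-n fused multiply-adds — this sits in
    the innermost loop of every fit.
    """
    M1 = np.atleast_1d(np.asarray(M1, dtype=float))
    M2 = np.atleast_1d(np.asarray(M2, dtype=float))
    rA = np.atleast_1d(np.asarray(rA, dtype=float))
    n = max(M1.size, M2.size, rA.size)
    M1, M2, rA = (np.broadcast_to(x, (n,)) for x in (M1, M2, rA))
    k = a.shape[0]

    comps = ((a.tolist(), ba.tolist()),
             (c.tolist(), bc.tolist()),
             (e.tolist(), be.tolist()))

    def entry(P, B, i, l, M):
        # path + beta*M; scalar when unmoderated
        return P[i][l] + B[i][l] * M if B[i][l] != 0.0 else P[i][l]

    out = np.empty((n, 2 * k, 2 * k))
    cross_w = (rA, R_C, R_E)
    for i in range(k):
        for j in range(i + 1):
            s11 = 0.0
            s22 = 0.0
            s12 = 0.0
            s21 = 0.0
            for (P, B), w in zip(comps, cross_w):
                skip_cross = isinstance(w, float) and w == 0.0
                for l in range(min(i, j) + 1):
                    p1i, p2i = entry(P, B, i, l, M1), entry(P, B, i, l, M2)
                    p1j, p2j = entry(P, B, j, l, M1), entry(P, B, j, l, M2)
                    s11 = s11 + p1i * p1j
                    s22 = s22 + p2i * p2j
                    if not skip_cross:
                        s12 = s12 + w * (p1i * p2j)
                        s21 = s21 + w * (p2i * p1j)
            out[:, i, j] = out[:, j, i] = s11
            out[:, k + i, k + j] = out[:, k + j, k + i] = s22
            out[:, i, k + j] = out[:, k + j, i] = s12
            out[:, k + i, j] = out[:, j, k + i] = s21
    return out


def batched_pair_sigma(paths: PathMatrices, mods: ModerationCoefficients,
                       rA, M1, M2) -> np.ndarray:
    """Implied (n, 2k, 2k) pair covariances for per-pair moderator values."""
    return _pair_sigma(paths.a, paths.c, paths.e,
                       mods.beta_a, mods.beta_c, mods.beta_e, rA, M1, M2)


def expected_pair_covariance(spec: ACEModelSpec, zygosity: str,
                             M1: float = 0.0, M2: float = 0.0) -> np.ndarray:
    """Model-implied 2k x 2k covariance of a twin pair.

    Within-twin blocks use paths evaluated at that twin's moderator value;
    the cross-twin block is ``rA * a(M1) a(M2)' + c(M1) c(M2)'`` with
    ``rA = 1`` (MZ) or ``0.5`` (DZ).
    """
    rA = R_A[zygosity]
    return batched_pair_sigma(spec.paths, spec.mods, np.array([rA]),
                              np.array([float(M1)]), np.array([float(M2)]))[0]


# -- single-pair likelihood (spec-level convenience / oracle hook) ---------

def pair_loglik(spec: ACEModelSpec, values: dict, zygosity: str,
                covariates: dict | None = None) -> float:
    """Log-likelihood contribution of one twin pair.

    ``values`` maps variable name -> (twin1, twin2); NaN marks missing
    entries, which are marginalized (incomplete pairs contribute singleton
    blocks).  Ordinal entries are integer category codes.  ``covariates`` may
    supply per-twin arrays for threshold shifts, e.g. ``{"age": (a1, a2)}``;
    moderator values are taken from ``values`` (already centered).
    """
    k = spec.k
    names = spec.var_names
    y = np.full((1, 2 * k), np.nan)
    for i, name in enumerate(names):
        v1, v2 = values.get(name, (np.nan, np.nan))
        y[0, i], y[0, k + i] = v1, v2

    if spec.moderator is not None:
        mi = spec.var_index(spec.moderator)
        M1, M2 = y[0, mi], y[0, k + mi]
        if not (np.isfinite(M1) and np.isfinite(M2)):
            raise ValueError("definition-variable moderator values cannot be missing")
    else:
        M1 = M2 = 0.0
    Sigma = batched_pair_sigma(spec.paths, spec.mods,
                               np.array([R_A[zygosity]]),
                               np.array([M1]), np.array([M2]))

    ord_slots = []
    lo = np.full((1, 2 * k), -np.inf)
    hi = np.full((1, 2 * k), np.inf)
    mu = np.zeros((1, 2 * k))
    covariates = covariates or {}
    for i, name in enumerate(names):
        vs = spec.variables[i]
        if isinstance(vs, VariableSpec) and vs.is_ordinal:
            tm = spec.thresholds.get(name, ThresholdModel(np.zeros(1)))
            for twin, slot in ((0, i), (1, k + i)):
                code = y[0, slot]
                if not np.isfinite(code):
                    continue
                cov_t = {c: np.atleast_1d(v)[twin] for c, v in covariates.items()}
                if spec.moderator is not None:
                    cov_t.setdefault("moderator", (M1, M2)[twin])
                cut = tm.shifted(cov_t)[0]
                ext = np.concatenate([[-np.inf], cut, [np.inf]])
                code_i = int(code)
                lo[0, slot], hi[0, slot] = ext[code_i], ext[code_i + 1]
                ord_slots.append(slot)
        else:
            mu[0, i] = mu[0, k + i] = spec.means[i]

    layout = ObsLayout.from_values(y, ord_slots)
    return float(loglik_pairs(Sigma, mu, lo, hi, layout)[0])


# -- fitted model ----------------------------------------------------------

_MOD_RE = re.compile(r"^b([ACE])_?(\d)(\d)$")


def _norm_mods(free_mods):
    out = []
    for m in free_mods:
        if isinstance(m, str):
            g = _MOD_RE.match(m)
            if not g:
                raise ValueError(f"bad moderation term {m!r}; use e.g. 'bE_22'")
            out.append((g.group(1), int(g.group(2)) - 1, int(g.group(3)) - 1))
        else:
            comp, i, j = m
            out.append((comp.upper(), int(i) - 1, int(j) - 1))
    for comp, i, j in out:
        if j > i:
            raise ValueError("moderation terms must sit on lower-triangular paths")
    return out


class ACEModel(MLModel):
    """Maximum-likelihood Cholesky ACE model over a :class:`TwinDataset`.

    Parameters
    ----------
    dataset : TwinDataset (already preprocessed: adjusted scores, imputation).
    variables : Cholesky ordering of the modeled variables (default: all).
    include_C : fit shared-environment paths (dropping C = masking them).
    moderator : variable whose observed, mean-centered value moderates paths.
    free_mods : moderation terms to free, e.g. ``["bA_21", "bE_22"]``.
    threshold_covariates : covariates entering ordinal threshold models.
    """

    def __init__(self, dataset: TwinDataset, variables=None, include_C: bool = True,
                 moderator: str | None = None, free_mods=(),
                 threshold_covariates=(), center_moderator: bool = True):
        self.dataset = dataset
        self.names = list(variables) if variables is not None else dataset.var_names
        self.k = len(self.names)
        self.specs = [dataset.spec(n) for n in self.names]
        self.include_C = include_C
        self.moderator = moderator
        self.free_mods = _norm_mods(free_mods)
        self.threshold_covariates = tuple(threshold_covariates)
        if moderator is not None and moderator not in self.names:
            raise ValueError("moderator must be one of the modeled variables")
        if self.free_mods and moderator is None:
            raise ValueError("free_mods given but no moderator named")
        if moderator is not None:
            mi = self.names.index(moderator)
            for comp, i, j in self.free_mods:
                if i == mi:
                    raise ValueError("the moderator's own paths cannot be moderated")

        self._prepare_data(center_moderator)
        self._build_params()

    # -- data --------------------------------------------------------------
    def _prepare_data(self, center_moderator):
        ds = self.dataset
        k = self.k
        vals = {n: ds.values(n) for n in self.names}
        n_all = ds.n_pairs
        any_obs = np.zeros(n_all, dtype=bool)
        for n in self.names:
            any_obs |= np.isfinite(vals[n]).any(axis=1)
        keep = any_obs
        if self.moderator is not None:
            mv = vals[self.moderator]
            keep = keep & np.isfinite(mv).all(axis=1)
        self._keep = keep
        n = int(keep.sum())
        if n == 0:
            raise ValueError("no usable pairs")

        y = np.empty((n, 2 * k))
        for i, name in enumerate(self.names):
            v = vals[name][keep]
            y[:, i], y[:, k + i] = v[:, 0], v[:, 1]
        ord_slots = [s for i, vs in enumerate(self.specs) if vs.is_ordinal
                     for s in (i, k + i)]
        self.layout = ObsLayout.from_values(y, ord_slots)
        self.rA = np.where(ds.is_mz[keep], R_A["MZ"], R_A["DZ"])
        self._codes = {
            slot: np.where(np.isfinite(y[:, slot]), y[:, slot], 0).astype(int)
            for slot in ord_slots
        }

        if self.moderator is not None:
            mv = vals[self.moderator][keep]
            self.m_center = float(np.nanmean(np.concatenate([mv[:, 0], mv[:, 1]]))) \
                if center_moderator else 0.0
            self.m_sd = float(np.nanstd(np.concatenate([mv[:, 0], mv[:, 1]]), ddof=1))
            self.M1 = mv[:, 0] - self.m_center
            self.M2 = mv[:, 1] - self.m_center
        else:
            self.m_center, self.m_sd = 0.0, 1.0
            self.M1 = np.zeros(n)
            self.M2 = np.zeros(n)

        # threshold covariates per twin (age centered; sex 0/1 as coded)
        self._thr_cov = {}
        for cname in self.threshold_covariates:
            if cname == "moderator":
                self._thr_cov[cname] = np.column_stack([self.M1, self.M2])
            else:
                cv = ds.values(cname)[keep]
                if cname == "age":
                    cv = cv - np.nanmean(cv)
                self._thr_cov[cname] = np.nan_to_num(cv)

    # -- parameters --------------------------------------------------------
    def _build_params(self):
        names = []
        comps = ["a", "c", "e"] if self.include_C else ["a", "e"]
        self._fixed_raw = {}      # (comp, i, j) -> value, for identification
        for i, vs in enumerate(self.specs):
            for comp in comps:
                for j in range(i + 1):
                    if vs.is_ordinal and comp == "e" and j == i:
                        self._fixed_raw[("e", i, i)] = 1.0
                        continue
                    names.append(f"{comp}_{i + 1}{j + 1}")
        for comp, i, j in self.free_mods:
            names.append(f"b{comp}_{i + 1}{j + 1}")
        for i, vs in enumerate(self.specs):
            if not vs.is_ordinal:
                names.append(f"mu_{vs.name}")
        for vs in self.specs:
            if vs.is_ordinal:
                ncut = vs.n_categories - 1
                if ncut == 1:
                    names.append(f"tau_{vs.name}")
                else:
                    names.extend(f"tau_{vs.name}_{c}" for c in range(1, ncut + 1))
                for cname in self.threshold_covariates:
                    names.append(f"g_{cname}_{vs.name}")
        self.param_names = names
        self._index = {n: i for i, n in enumerate(names)}

    def start_values(self) -> np.ndarray:
        theta = np.zeros(len(self.param_names))
        k = self.k
        ncomp = 3 if self.include_C else 2
        for i, vs in enumerate(self.specs):
            col = np.concatenate([self.layout.y[:, i], self.layout.y[:, k + i]])
            col = col[np.isfinite(col)]
            if vs.is_ordinal:
                diag = 1.0   # raw scale; rescaled to unit liability variance
                phat = np.clip(col.mean() if col.size else 0.1, 0.02, 0.98) \
                    if vs.n_categories == 2 else None
                if vs.n_categories == 2:
                    self._set(theta, f"tau_{vs.name}", float(norm.ppf(1 - phat)))
                else:
                    qs = [np.mean(col < c) for c in range(1, vs.n_categories)]
                    for c, q in enumerate(qs, start=1):
                        self._set(theta, f"tau_{vs.name}_{c}",
                                  float(norm.ppf(np.clip(q, 0.01, 0.99))))
            else:
                sd = float(np.std(col, ddof=1)) if col.size > 1 else 1.0
                diag = sd / np.sqrt(ncomp)
                self._set(theta, f"mu_{vs.name}", float(np.mean(col)) if col.size else 0.0)
            for comp in ("a", "c", "e") if self.include_C else ("a", "e"):
                for j in range(i + 1):
                    name = f"{comp}_{i + 1}{j + 1}"
                    if name not in self._index:
                        continue
                    self._set(theta, name, diag if j == i else 0.05 * diag)
        return theta

    def _set(self, theta, name, value):
        theta[self._index[name]] = value

    def _get(self, theta, name, default=0.0):
        idx = self._index.get(name)
        return theta[idx] if idx is not None else default

    # -- decoding ----------------------------------------------------------
    def _decode_raw(self, theta):
        """Parameter vector -> identified raw arrays (hot path, no validation).

        Applies the liability-scale identification: each ordinal variable's
        unmoderated path row (with its raw specific-E entry fixed at 1) is
        rescaled to unit total variance at M = 0; moderation slopes are left
        untouched.
        """
        k = self.k
        a = np.zeros((k, k))
        c = np.zeros((k, k))
        e = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1):
                a[i, j] = self._get(theta, f"a_{i + 1}{j + 1}")
                if self.include_C:
                    c[i, j] = self._get(theta, f"c_{i + 1}{j + 1}")
                e[i, j] = self._get(theta, f"e_{i + 1}{j + 1}")
        for (comp, i, j), v in self._fixed_raw.items():
            {"a": a, "c": c, "e": e}[comp][i, j] = v
        for i, vs in enumerate(self.specs):
            if vs.is_ordinal:
                tot = a[i, : i + 1] @ a[i, : i + 1] + c[i, : i + 1] @ c[i, : i + 1] \
                    + e[i, : i + 1] @ e[i, : i + 1]
                s = 1.0 / np.sqrt(tot)
                a[i, : i + 1] *= s
                c[i, : i + 1] *= s
                e[i, : i + 1] *= s

        ba = np.zeros((k, k))
        bc = np.zeros((k, k))
        be = np.zeros((k, k))
        for comp, i, j in self.free_mods:
            v = self._get(theta, f"b{comp}_{i + 1}{j + 1}")
            {"A": ba, "C": bc, "E": be}[comp][i, j] = v

        means = np.zeros(k)
        taus = {}
        gammas = {}
        for i, vs in enumerate(self.specs):
            if vs.is_ordinal:
                ncut = vs.n_categories - 1
                if ncut == 1:
                    tau = np.array([self._get(theta, f"tau_{vs.name}")])
                else:
                    tau = np.array([self._get(theta, f"tau_{vs.name}_{cc}")
                                    for cc in range(1, ncut + 1)])
                    if np.any(np.diff(tau) <= 0):
                        raise FloatingPointError("non-monotone thresholds")
                taus[vs.name] = tau
                gammas[vs.name] = {cname: self._get(theta, f"g_{cname}_{vs.name}")
                                   for cname in self.threshold_covariates}
            else:
                means[i] = self._get(theta, f"mu_{vs.name}")
        return a, c, e, ba, bc, be, means, taus, gammas

    def decode(self, theta) -> ACEModelSpec:
        """Parameter vector -> identified, validated :class:`ACEModelSpec`."""
        a, c, e, ba, bc, be, means, taus, gammas = self._decode_raw(np.asarray(theta, float))
        return ACEModelSpec(
            variables=list(self.specs),
            paths=PathMatrices(a, c, e),
            mods=ModerationCoefficients(ba, bc, be),
            thresholds={name: ThresholdModel(tau, gammas[name])
                        for name, tau in taus.items()},
            means=means,
            include_C=self.include_C,
            moderator=self.moderator,
        )

    # -- likelihood --------------------------------------------------------
    def minus2ll(self, theta) -> float:
        try:
            a, c, e, ba, bc, be, means, taus, gammas = self._decode_raw(
                np.asarray(theta, dtype=float)
            )
        except FloatingPointError:
            return np.inf
        k = self.k
        Sigma = _pair_sigma(a, c, e, ba, bc, be, self.rA, self.M1, self.M2)
        n = self.layout.n
        mu, lo, hi = assemble_mu_bounds(self.specs, means, taus, gammas,
                                        self._thr_cov, self._codes, n, k)
        ll = loglik_pairs(Sigma, mu, lo, hi, self.layout)
        if not np.all(np.isfinite(ll)):
            return np.inf
        return float(-2.0 * ll.sum())

    @property
    def n_observed_statistics(self) -> int:
        return self.layout.n_observed_statistics

    @property
    def n_pairs_used(self) -> int:
        return self.layout.n

    def spec_from(self, result: FitResult) -> ACEModelSpec:
        theta = np.array([result.estimates[n] for n in self.param_names])
        return self.decode(theta)


def fit_ace(dataset: TwinDataset, variables=None, include_C: bool = True,
            moderator: str | None = None, free_mods=(), threshold_covariates=(),
            start=None, fixed=None, ci_params=(), **fit_kw) -> FitResult:
    """Fit a (possibly moderated) Cholesky ACE model; returns a FitResult.

    Thin wrapper over :class:`ACEModel`; ``fixed`` masks parameters (e.g. all
    moderation terms to zero to recover the unmoderated fit).
    """
    model = ACEModel(dataset, variables=variables, include_C=include_C,
                     moderator=moderator, free_mods=free_mods,
                     threshold_covariates=threshold_covariates)
    return model.fit(start=start, fixed=fixed, ci_params=ci_params, **fit_kw)


# -- standardization and closed forms --------------------------------------

@dataclass
class StandardizedComponents:
    """Variance (diagonal) and covariance (off-diagonal) proportions."""

    h2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    undefined: np.ndarray | None = None   # off-diagonals with zero total covariance


def standardize_components(paths: PathMatrices) -> StandardizedComponents:
    """Standardize A/C/E (co)variance components from path matrices.

    Diagonals are variance proportions in [0, 1] summing to 1; off-diagonals
    are proportions of covariance (component covariance over total covariance)
    and may fall outside [0, 1].  Off-diagonals with zero total covariance are
    flagged undefined (NaN).
    """
    A = paths.a @ paths.a.T
    C = paths.c @ paths.c.T
    E = paths.e @ paths.e.T
    T = A + C + E
    if np.any(np.diag(T) <= 0):
        raise ValueError("total variance must be positive for every variable")
    undef = T == 0
    Tsafe = np.where(undef, np.nan, T)
    return StandardizedComponents(h2=A / Tsafe, c2=C / Tsafe, e2=E / Tsafe,
                                  undefined=undef)


@dataclass
class FalconerEstimates:
    a2: float
    c2: float
    e2: float
    negative_component: bool


def falconer_estimates(rMZ: float, rDZ: float) -> FalconerEstimates:
    """Closed-form variance components from twin correlations.

    ``a2 = 2(rMZ - rDZ)``, ``c2 = 2 rDZ - rMZ``, ``e2 = 1 - rMZ`` — the
    just-identified solution of the univariate decomposition under the
    unit-total-variance constraint.  Negative components are returned as-is
    with a flag; the caller decides any bounding.
    """
    if not (-1 <= rMZ <= 1 and -1 <= rDZ <= 1):
        raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (rMZ - rDZ)
    c2 = 2.0 * rDZ - rMZ
    e2 = 1.0 - rMZ
    return FalconerEstimates(a2, c2, e2, negative_component=(a2 < 0 or c2 < 0 or e2 < 0))


def liability_threshold(prevalence: float) -> float:
    """Threshold on a standard-normal liability giving the target prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    return float(norm.ppf(1.0 - prevalence))


# -- YAML round-trip -------------------------------------------------------

def spec_to_yaml(spec: ACEModelSpec, path=None) -> str:
    d = {
        "variables": [
            {"name": v.name, "scale": v.scale, "roles": sorted(v.roles),
             "n_categories": v.n_categories}
            for v in spec.variables
        ],
        "paths": {m: getattr(spec.paths, m).tolist() for m in ("a", "c", "e")},
        "mods": {m: getattr(spec.mods, m).tolist()
                 for m in ("beta_a", "beta_c", "beta_e")},
        "thresholds": {
            name: {"tau": tm.tau.tolist(), "gammas": dict(tm.gammas)}
            for name, tm in spec.thresholds.items()
        },
        "means": spec.means.tolist(),
        "include_C": spec.include_C,
        "moderator": spec.moderator,
    }
    text = yaml.safe_dump(d, sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def spec_from_yaml(source) -> ACEModelSpec:
    if isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml")):
        with open(source, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
    else:
        d = yaml.safe_load(source)
    variables = [
        VariableSpec(v["name"], v["scale"], frozenset(v["roles"]), v["n_categories"])
        for v in d["variables"]
    ]
    return ACEModelSpec(
        variables=variables,
        paths=PathMatrices(**{k: np.array(v) for k, v in d["paths"].items()}),
        mods=ModerationCoefficients(**{k: np.array(v) for k, v in d["mods"].items()}),
        thresholds={name: ThresholdModel(np.array(t["tau"]), dict(t["gammas"]))
                    for name, t in d["thresholds"].items()},
        means=np.array(d["means"]),
        include_C=d["include_C"],
        moderator=d["moderator"],
    )
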