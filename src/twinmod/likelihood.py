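"""Full-information pairwise likelihood for mixed continuous/ordinal twin data.

Each twin pair contributes the likelihood of its *observed* entries under a
2k-variate normal (k variables per twin): the continuous part is an ordinary
multivariate-normal density over the observed continuous entries, and each
observed ordinal entry contributes the probability of its category rectangle
under the conditional (given the continuous entries) normal for the latent
liabilities.  Missing entries are marginalized by dropping their rows and
columns, so incomplete pairs contribute their observed margins.

Up to two ordinal entries per pair are supported (one liability variable
measured on both twins), which covers the binary-orientation design; the
rectangle probabilities are then univariate or bivariate normal and computed
deterministically via Owen's T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bvn import interval_prob, rect_prob

__all__ = ["ObsLayout", "loglik_pairs"]

_LOG2PI = float(np.log(2.0 * np.pi))
_TINY = 1e-300


@dataclass
class ObsLayout:
    """Precomputed observation layout for a fixed variable list.

    Slot order is twin-major: slots ``0..k-1`` are twin 1's variables, slots
    ``k..2k-1`` twin 2's.  Rows are grouped by missingness pattern once so
    the per-evaluation work is pure batched linear algebra.
    """

    y: np.ndarray          # (n, 2k) observed values; NaN where missing
    ordinal: np.ndarray    # (2k,) bool — slot holds an ordinal variable
    groups: list           # [(rows, cont_idx, ord_idx), ...]
    n: int
    k: int

    @classmethod
    def from_values(cls, y: np.ndarray, ordinal_slots) -> "ObsLayout":
        y = np.asarray(y, dtype=float)
        n, two_k = y.shape
        k = two_k // 2
        ordinal = np.zeros(two_k, dtype=bool)
        ordinal[list(ordinal_slots)] = True
        obs = np.isfinite(y)
        groups = []
        patterns = {}
        for i in range(n):
            patterns.setdefault(obs[i].tobytes(), []).append(i)
        for patt, rows in patterns.items():
            mask = np.frombuffer(patt, dtype=bool)
            if not mask.any():
                continue
            cont_idx = np.where(mask & ~ordinal)[0]
            ord_idx = np.where(mask & ordinal)[0]
            if ord_idx.size > 2:
                raise NotImplementedError(
                    "more than two observed ordinal entries per pair is not supported"
                )
            groups.append((np.array(rows, dtype=int), cont_idx, ord_idx))
        return cls(y=y, ordinal=ordinal, groups=groups, n=n, k=k)

    @property
    def n_observed_statistics(self) -> int:
        return int(np.isfinite(self.y).sum())


def assemble_mu_bounds(specs, means, taus, gammas, thr_cov, codes, n, k):
    """Per-pair mean vector and liability rectangle bounds.

    ``specs`` is the ordered list of VariableSpec; ``taus``/``gammas`` map
    ordinal names to cutpoint arrays and covariate->slope dicts; ``thr_cov``
    maps covariate names to (n, 2) per-twin values; ``codes`` maps slot index
    to integer category codes.
    """
    mu = np.zeros((n, 2 * k))
    lo = np.full((n, 2 * k), -np.inf)
    hi = np.full((n, 2 * k), np.inf)
    for i, vs in enumerate(specs):
        if not vs.is_ordinal:
            mu[:, i] = mu[:, k + i] = means[i]
            continue
        tau = taus[vs.name]
        gam = gammas.get(vs.name, {})
        for twin, slot in ((0, i), (1, k + i)):
            shift = 0.0
            for cname, g in gam.items():
                if g != 0.0:
                    shift = shift + g * thr_cov[cname][:, twin]
            cd = codes[slot]
            if tau.size == 1:
                t = tau[0] + shift
                lo[:, slot] = np.where(cd >= 1, t, -np.inf)
                hi[:, slot] = np.where(cd <= 0, t, np.inf)
            else:
                cuts = tau[None, :] + (shift[:, None] if np.ndim(shift) else shift)
                cuts = np.broadcast_to(cuts, (n, tau.size))
                ext = np.concatenate(
                    [np.full((n, 1), -np.inf), cuts, np.full((n, 1), np.inf)], axis=1
                )
                idx = np.arange(n)
                lo[:, slot] = ext[idx, cd]
                hi[:, slot] = ext[idx, cd + 1]
    return mu, lo, hi


def _chol_batch(S):
    """Batched Cholesky; returns (L, ok) with rows flagged on failure."""
    try:
        return np.linalg.cholesky(S), np.ones(S.shape[0], dtype=bool)
    except np.linalg.LinAlgError:
        n = S.shape[0]
        L = np.zeros_like(S)
        ok = np.zeros(n, dtype=bool)
        for i in range(n):
            try:
                L[i] = np.linalg.cholesky(S[i])
                ok[i] = True
            except np.linalg.LinAlgError:
                pass
        return L, ok


def _quiet(fn):
    """Silence FP warnings: invalid trial points yield -inf, not noise."""
    import functools

    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            return fn(*args, **kwargs)
    return wrapper


@_quiet
def loglik_pairs(Sigma, mu, lo, hi, layout: ObsLayout) -> np.ndarray:
    """Per-pair log-likelihood contributions.

    Parameters
    ----------
    Sigma : (n, 2k, 2k) implied pair covariance (may vary per pair through
        definition variables).
    mu : (n, 2k) implied means (zero for liability slots).
    lo, hi : (n, 2k) liability-rectangle bounds; consulted only at observed
        ordinal slots (thresholds, shifted by any covariate effects).

    Non-positive-definite covariance at an evaluation point yields ``-inf``
    for the affected pairs, which the optimizer treats as a rejected step.
    """
    n = layout.n
    ll = np.zeros(n, dtype=float)
    for rows, ci, oi in layout.groups:
        m, q = ci.size, oi.size
        mu_g = mu[rows]
        z = None
        L = None
        okc = np.ones(rows.size, dtype=bool)
        if m:
            Scc = Sigma[np.ix_(rows, ci, ci)]
            dev = layout.y[np.ix_(rows, ci)] - mu_g[:, ci]
            if m == 1:
                v = Scc[:, 0, 0]
                okc = v > 0
                vs = np.where(okc, v, 1.0)
                part = -0.5 * (_LOG2PI + np.log(vs) + dev[:, 0] ** 2 / vs)
                part = np.where(okc, part, -np.inf)
            elif m == 2:
                v1, v2, cv = Scc[:, 0, 0], Scc[:, 1, 1], Scc[:, 0, 1]
                det = v1 * v2 - cv * cv
                okc = (v1 > 0) & (det > 0)
                dets = np.where(okc, det, 1.0)
                maha = (v2 * dev[:, 0] ** 2 - 2 * cv * dev[:, 0] * dev[:, 1]
                        + v1 * dev[:, 1] ** 2) / dets
                part = -0.5 * (2 * _LOG2PI + np.log(dets) + maha)
                part = np.where(okc, part, -np.inf)
            else:
                L, okc = _chol_batch(Scc)
                Lsafe = np.where(okc[:, None, None], L, np.eye(m))
                z = np.linalg.solve(Lsafe, dev[..., None])[..., 0]
                logdet = 2.0 * np.log(
                    np.maximum(np.diagonal(Lsafe, axis1=1, axis2=2), _TINY)
                ).sum(axis=1)
                part = -0.5 * (m * _LOG2PI + logdet + (z ** 2).sum(axis=1))
                part = np.where(okc, part, -np.inf)
        else:
            part = np.zeros(rows.size)

        if q:
            So = Sigma[np.ix_(rows, oi, oi)]
            mo = mu_g[:, oi]
            if m == 1:
                Sco = Sigma[np.ix_(rows, ci, oi)]          # (r, 1, q)
                v = np.where(okc, Scc[:, 0, 0], 1.0)
                w = Sco[:, 0, :] / v[:, None]              # (r, q)
                cov = So - Sco[:, 0, :, None] * w[:, None, :]
                mean = mo + w * dev[:, :1]
            elif m == 2:
                Sco = Sigma[np.ix_(rows, ci, oi)]          # (r, 2, q)
                v1, v2, cv = Scc[:, 0, 0], Scc[:, 1, 1], Scc[:, 0, 1]
                det = np.where(okc, v1 * v2 - cv * cv, 1.0)
                # inv(Scc) @ Sco, closed form
                i11, i22, i12 = v2 / det, v1 / det, -cv / det
                W0 = i11[:, None] * Sco[:, 0, :] + i12[:, None] * Sco[:, 1, :]
                W1 = i12[:, None] * Sco[:, 0, :] + i22[:, None] * Sco[:, 1, :]
                cov = So - (Sco[:, 0, :, None] * W0[:, None, :]
                            + Sco[:, 1, :, None] * W1[:, None, :])
                mean = mo + W0 * dev[:, :1] + W1 * dev[:, 1:2]
            elif m:
                Sco = Sigma[np.ix_(rows, ci, oi)]
                Lsafe = np.where(okc[:, None, None], L, np.eye(m))
                W = np.linalg.solve(Lsafe, Sco)          # (r, m, q)
                cov = So - np.einsum("rmp,rmq->rpq", W, W)
                mean = mo + np.einsum("rmp,rm->rp", W, z)
            else:
                cov, mean = So, mo
            lo_g = lo[np.ix_(rows, oi)]
            hi_g = hi[np.ix_(rows, oi)]
            var = np.diagonal(cov, axis1=1, axis2=2)
            bad = (var <= 0).any(axis=1)
            sd = np.sqrt(np.where(var <= 0, 1.0, var))
            a = (lo_g - mean) / sd
            b = (hi_g - mean) / sd
            if q == 1:
                p = interval_prob(a[:, 0], b[:, 0])
            else:
                rho = cov[:, 0, 1] / (sd[:, 0] * sd[:, 1])
                bad |= np.abs(rho) > 1 + 1e-12
                rho = np.clip(rho, -1.0, 1.0)
                p = rect_prob(a[:, 0], b[:, 0], a[:, 1], b[:, 1], rho)
            p = np.clip(p, _TINY, 1.0)
            part = part + np.where(bad, -np.inf, np.log(p))
        ll[rows] = part
    return ll
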