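"""REML variance-component estimation for the family-proportion model.

The analysis model is the Gaussian linear mixed model

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),  e ~ N(0, s2_e W^-1)

with crossed random factors (dam, sire, block, plant in the resistance
analysis) and, by default, an intercept-only fixed part fitted separately
per treatment arm.  Estimation is EM-REML: conditional-expectation updates
of each variance, which are non-negative by construction and never
decrease the restricted log-likelihood.  A SQUAREM-style extrapolation
(with a monotone fallback to the plain double EM step) is layered on top
because boundary components make plain EM arbitrarily slow.

Two algebraically equivalent computational routes are implemented and
cross-checked in the test-suite: a direct n x n covariance ("dense")
route, and Henderson's mixed-model-equations route whose cost scales
with the number of random-effect levels.

The restricted log-likelihood convention includes the +1/2 log|X'X| term
(Harville's error-contrast form), so for the intercept-only model with
V = I it reduces to -(n-1)/2 log(2 pi) - 1/2 * sum((y - ybar)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "VarianceComponents",
    "fit_reml",
    "restricted_loglik",
    "variance_shares",
    "DEFAULT_FACTORS",
]

DEFAULT_FACTORS = ("dam", "sire", "block", "plant")

_TOL = 1e-8
_MAX_ITER = 10_000


# ----------------------------------------------------------------------
# result container


@dataclass
class VarianceComponents:
    """Estimated variances on the analysed response scale."""

    var_dam: float = 0.0
    var_sire: float = 0.0
    var_block: float = 0.0
    var_plant: float = 0.0
    var_resid: float = 0.0
    n_obs: int = 0
    converged: bool = False
    loglik_restricted: float = float("nan")
    n_iter: int = 0
    degenerate: bool = False
    boundary: tuple[str, ...] = ()
    factors: tuple[str, ...] = DEFAULT_FACTORS
    loglik_path: tuple[float, ...] = field(default=(), repr=False)

    def component_dict(self) -> dict[str, float]:
        out = {name: getattr(self, f"var_{name}") for name in self.factors}
        out["resid"] = self.var_resid
        return out

    def to_dict(self) -> dict[str, object]:
        return {
            "var_dam": self.var_dam,
            "var_sire": self.var_sire,
            "var_block": self.var_block,
            "var_plant": self.var_plant,
            "var_resid": self.var_resid,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "loglik_restricted": self.loglik_restricted,
            "n_iter": self.n_iter,
            "degenerate": self.degenerate,
            "boundary": list(self.boundary),
            "factors": list(self.factors),
        }


def variance_shares(vc: VarianceComponents | Mapping[str, float]) -> dict[str, float]:
    """Percent of total estimated variance per component (sums to 100)."""
    if isinstance(vc, VarianceComponents):
        comps = vc.component_dict()
    else:
        comps = dict(vc)
    total = float(sum(comps.values()))
    if any(v < 0 for v in comps.values()):
        raise ValueError("variance components must be non-negative")
    if total <= 0:
        raise ValueError("all variance components are zero; shares undefined")
    return {name: 100.0 * v / total for name, v in comps.items()}


# ----------------------------------------------------------------------
# model engine


def _indicator(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    _, idx = np.unique(codes, return_inverse=True)
    q = idx.max() + 1
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), idx] = 1.0
    return Z


class MixedREML:
    """EM-REML engine for one response vector.

    ``z_blocks`` is an ordered list of ``(name, Z)`` indicator matrices.
    ``weights`` gives residual variance ``s2_e / w_i`` per row (PQL
    working weights); default all ones.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        z_blocks: Sequence[tuple[str, np.ndarray]],
        weights: np.ndarray | None = None,
    ) -> None:
        self.y = np.asarray(y, float).ravel()
        n = len(self.y)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response contains non-finite values")
        self.X = np.asarray(X, float).reshape(n, -1)
        self.p = self.X.shape[1]
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("rank-deficient fixed-effect design")
        self.names = [name for name, _ in z_blocks]
        self.Z = [np.asarray(Z, float) for _, Z in z_blocks]
        self.q = [Z.shape[1] for Z in self.Z]
        self.n = n
        self.w = np.ones(n) if weights is None else np.asarray(weights, float)
        if np.any(self.w <= 0):
            raise ValueError("weights must be positive")
        self.K = len(self.Z)

        # dense-route precomputations
        self._G = [Z @ Z.T for Z in self.Z]
        sign, self._logdet_xtx = np.linalg.slogdet(self.X.T @ self.X)

        # MME-route precomputations (W-weighted cross-products)
        Zall = np.hstack(self.Z) if self.Z else np.zeros((n, 0))
        Xw = self.X * self.w[:, None]
        self._A11 = Xw.T @ self.X
        self._A12 = Xw.T @ Zall
        self._A22 = (Zall * self.w[:, None]).T @ Zall
        self._b1 = Xw.T @ self.y
        self._b2 = (Zall * self.w[:, None]).T @ self.y
        self._yWy = float(self.y @ (self.w * self.y))
        self._offsets = np.concatenate([[0], np.cumsum(self.q)]).astype(int)
        self._m = int(self._offsets[-1])
        # MME wins when levels are fewer than observations
        self.use_mme = (self._m + self.p) < n

    # -- likelihood -----------------------------------------------------

    def loglik(self, theta: np.ndarray) -> float:
        """Restricted log-likelihood at variances ``theta`` = (components..., resid)."""
        theta = np.asarray(theta, float)
        if np.any(theta < 0):
            raise ValueError("variances must be non-negative")
        if self.use_mme and theta[-1] > 0:
            return self._loglik_mme(theta)
        return self._loglik_dense(theta)

    def _build_v(self, theta: np.ndarray) -> np.ndarray:
        V = np.diag(theta[-1] / self.w)
        for s2, G in zip(theta[:-1], self._G):
            if s2 > 0:
                V = V + s2 * G
        return V

    def _loglik_dense(self, theta: np.ndarray) -> float:
        V = self._build_v(theta)
        try:
            cf = linalg.cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError("singular total covariance") from exc
        except linalg.LinAlgError as exc:
            raise ValueError("singular total covariance") from exc
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vinv_X = linalg.cho_solve(cf, self.X)
        Vinv_y = linalg.cho_solve(cf, self.y)
        xtvx = self.X.T @ Vinv_X
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise ValueError("singular X'V^-1X")
        xtvy = self.X.T @ Vinv_y
        beta = np.linalg.solve(xtvx, xtvy)
        ypy = float(self.y @ Vinv_y - xtvy @ beta)
        return -0.5 * (
            (self.n - self.p) * np.log(2 * np.pi)
            + logdet_v
            + logdet_xtvx
            - self._logdet_xtx
            + ypy
        )

    def _mme_core(self, theta: np.ndarray, need_inv: bool):
        """One factorization of Henderson's equations.

        Returns ``(loglik, active, beta, u, Cinv)`` with ``Cinv`` None
        unless ``need_inv``.  Uses |C| = |Cuu| |X'V^-1X| s2e^p to get the
        restricted log-likelihood from a single Cholesky of C.
        """
        s2e = float(theta[-1])
        active = [k for k in range(self.K) if theta[k] > 0]
        idx = (
            np.concatenate(
                [np.arange(self._offsets[k], self._offsets[k + 1]) for k in active]
            ).astype(int)
            if active
            else np.array([], int)
        )
        A12 = self._A12[:, idx]
        Cuu = self._A22[np.ix_(idx, idx)].copy()
        if active:
            alpha = np.concatenate(
                [np.full(self.q[k], s2e / theta[k]) for k in active]
            )
            Cuu[np.diag_indices_from(Cuu)] += alpha
        C = np.block([[self._A11, A12], [A12.T, Cuu]])
        rhs = np.concatenate([self._b1, self._b2[idx]])
        try:
            cf = linalg.cho_factor(C, lower=True)
        except (np.linalg.LinAlgError, linalg.LinAlgError) as exc:
            raise ValueError("singular total covariance") from exc
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        sol = linalg.cho_solve(cf, rhs)
        beta, u = sol[: self.p], sol[self.p:]
        m = len(idx)
        # log|V| + log|X'V^-1X| = sum log(s2e/w) + sum q_k log s2_k
        #                         + log|C| - (m + p) log s2e
        logdets = (
            float(np.sum(np.log(s2e / self.w)))
            + float(sum(self.q[k] * np.log(theta[k]) for k in active))
            + logdet_c
            - (m + self.p) * np.log(s2e)
        )
        ypy = (self._yWy - self._b1 @ beta - self._b2[idx] @ u) / s2e
        ll = -0.5 * (
            (self.n - self.p) * np.log(2 * np.pi)
            + logdets
            - self._logdet_xtx
            + float(ypy)
        )
        Cinv = linalg.cho_solve(cf, np.eye(C.shape[0])) if need_inv else None
        return ll, active, beta, u, Cinv

    def _loglik_mme(self, theta: np.ndarray) -> float:
        return self._mme_core(theta, need_inv=False)[0]

    # -- EM -------------------------------------------------------------

    def em_step(self, theta: np.ndarray) -> np.ndarray:
        """One EM-REML update.  Components at exactly 0 stay at 0."""
        return self.em_step_ll(theta)[0]

    def em_step_ll(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        """One EM-REML update plus the log-likelihood at the input point."""
        theta = np.asarray(theta, float)
        if self.use_mme and theta[-1] > 0:
            return self._em_step_mme(theta)
        return self._em_step_dense(theta)

    def _em_step_dense(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        V = self._build_v(theta)
        cf = linalg.cho_factor(V, lower=True)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vinv = linalg.cho_solve(cf, np.eye(self.n))
        Vinv_X = Vinv @ self.X
        xtvx = self.X.T @ Vinv_X
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        xtvx_inv = np.linalg.inv(xtvx)
        P = Vinv - Vinv_X @ xtvx_inv @ Vinv_X.T
        Py = P @ self.y
        ll = -0.5 * (
            (self.n - self.p) * np.log(2 * np.pi)
            + logdet_v
            + logdet_xtvx
            - self._logdet_xtx
            + float(self.y @ Py)
        )
        new = theta.copy()
        for k in range(self.K):
            s2 = theta[k]
            if s2 <= 0:
                continue
            G = self._G[k]
            quad = float(Py @ G @ Py)
            tr = float(np.sum(P * G))
            new[k] = s2 + s2 * s2 * (quad - tr) / self.q[k]
        s2e = theta[-1]
        quad_e = float(Py @ (Py / self.w))
        tr_e = float(np.sum(np.diag(P) / self.w))
        new[-1] = (s2e * s2e * (quad_e - tr_e) + self.n * s2e) / self.n
        return np.maximum(new, 0.0), ll

    def _em_step_mme(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        ll, active, beta, u, Cinv = self._mme_core(theta, need_inv=True)
        s2e = float(theta[-1])
        new = theta.copy()
        Cinv_uu = Cinv[self.p:, self.p:]
        pos = 0
        tr_sum = 0.0  # sum_k (q_k - (s2e/s2_k) tr(Cinv_kk)) = sum_k s2_k tr(Z_k' P Z_k)
        for k in active:
            qk = self.q[k]
            uk = u[pos : pos + qk]
            tr_kk = float(np.trace(Cinv_uu[pos : pos + qk, pos : pos + qk]))
            new[k] = (float(uk @ uk) + s2e * tr_kk) / qk
            tr_sum += qk - (s2e / theta[k]) * tr_kk
            pos += qk
        resid = self.y - self.X @ beta
        if active:
            Zall = np.hstack([self.Z[k] for k in active])
            resid = resid - Zall @ u
        ewe = float(resid @ (self.w * resid))
        new[-1] = (ewe + s2e * (self.p + tr_sum)) / self.n
        return np.maximum(new, 0.0), ll

    def blup(self, theta: np.ndarray):
        """GLS fixed effects, random-effect BLUPs and fixed-effect covariance.

        Returns ``(beta, u_by_block, cov_beta)`` with ``cov_beta`` =
        (X'V^-1 X)^-1 at the supplied variances.
        """
        theta = np.asarray(theta, float)
        V = self._build_v(theta)
        cf = linalg.cho_factor(V, lower=True)
        Vinv_X = linalg.cho_solve(cf, self.X)
        Vinv_y = linalg.cho_solve(cf, self.y)
        xtvx = self.X.T @ Vinv_X
        cov_beta = np.linalg.inv(xtvx)
        beta = cov_beta @ (self.X.T @ Vinv_y)
        resid_v = Vinv_y - Vinv_X @ beta  # = P y
        u_blocks = []
        for k in range(self.K):
            if theta[k] > 0:
                u_blocks.append(theta[k] * (self.Z[k].T @ resid_v))
            else:
                u_blocks.append(np.zeros(self.q[k]))
        return beta, u_blocks, cov_beta

    # -- driver ----------------------------------------------------------

    def fit(
        self,
        start: np.ndarray | None = None,
        tol: float = _TOL,
        max_iter: int = _MAX_ITER,
        accelerate: bool = True,
    ) -> dict:
        """Run (accelerated) EM-REML to convergence.

        Convergence: maximum parameter change relative to the total
        variance falls below ``tol``.  Returns a dict with ``theta``,
        ``loglik``, ``converged``, ``n_iter`` and the non-decreasing
        ``loglik_path``.
        """
        s_y = float(np.var(self.y, ddof=1)) if self.n > 1 else 0.0
        if start is None:
            start = np.full(self.K + 1, 0.5 * s_y / max(self.K, 1))
            start[-1] = 0.5 * s_y if s_y > 0 else 1.0
        theta = np.asarray(start, float).copy()
        path: list[float] = []
        converged = False
        it = 0
        revivals = 0
        cycle = 0
        while it < max_iter:
            if not accelerate:
                theta1, ll0 = self.em_step_ll(theta)
                it += 1
                path.append(ll0)
                step = float(np.max(np.abs(theta1 - theta))) / max(
                    float(theta1.sum()), 1e-300
                )
                theta = theta1
            else:
                cycle += 1
                theta1, ll0 = self.em_step_ll(theta)
                theta2, ll1 = self.em_step_ll(theta1)
                it += 2
                path.extend((ll0, ll1))
                step = float(np.max(np.abs(theta1 - theta))) / max(
                    float(theta1.sum()), 1e-300
                )
                r = theta1 - theta
                v = (theta2 - theta1) - r
                vnorm = float(v @ v)
                theta_next = theta2
                if vnorm > 1e-300:
                    # SQUAREM-style extrapolation with a monotone
                    # safeguard; a second candidate parks near-boundary
                    # components exactly at 0
                    a = -np.sqrt(float(r @ r) / vnorm)
                    raw = np.maximum(theta - 2 * a * r + a * a * v, 0.0)
                    parked = raw.copy()
                    parked[:-1][parked[:-1] < 2e-4 * float(parked.sum())] = 0.0
                    cands = [parked, raw] if parked.sum() < raw.sum() else [raw]
                    for cand in cands:
                        try:
                            ll_c = self.loglik(cand)
                        except ValueError:
                            continue
                        if ll_c >= ll1 - 1e-12:
                            theta_next = cand
                            path.append(ll_c)
                            break
                # boundary probe: plain EM approaches a zero variance only
                # harmonically slowly, so periodically evaluate the
                # boundary point itself; the likelihood test keeps the
                # path monotone and rejects probes that zero a genuinely
                # positive component
                small = (
                    (r[:-1] < 0)
                    & (theta_next[:-1] > 0)
                    & (theta_next[:-1] < 0.05 * float(theta_next.sum()))
                )
                if small.any() and cycle % 3 == 0:
                    probe = theta_next.copy()
                    probe[:-1][small] = 0.0
                    try:
                        probe2, ll_p = self.em_step_ll(probe)
                        it += 1
                        if ll_p >= path[-1] - 1e-12:
                            theta_next = probe2
                            path.append(ll_p)
                    except ValueError:
                        pass
                theta = theta_next
            if step < tol:
                # boundary components: re-activate if the gradient at 0
                # is positive (an accelerated jump may have parked a
                # genuinely positive component at the boundary)
                if revivals < 3 and self._revive(theta):
                    revivals += 1
                    continue
                converged = True
                break
        ll = self.loglik(theta)
        path.append(ll)
        return {
            "theta": theta,
            "loglik": ll,
            "converged": converged,
            "n_iter": it,
            "loglik_path": tuple(path),
        }

    def _revive(self, theta: np.ndarray) -> bool:
        """Restart zeroed components whose score at 0 is positive."""
        zeroed = [k for k in range(self.K) if theta[k] == 0.0]
        if not zeroed or theta[-1] == 0.0:
            return False
        V = self._build_v(theta)
        try:
            cf = linalg.cho_factor(V, lower=True)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return False
        Vinv = linalg.cho_solve(cf, np.eye(self.n))
        Vinv_X = Vinv @ self.X
        P = Vinv - Vinv_X @ np.linalg.inv(self.X.T @ Vinv_X) @ Vinv_X.T
        Py = P @ self.y
        revived = False
        scale = max(float(theta.sum()), 1e-300)
        ll_now = self.loglik(theta)
        for k in zeroed:
            score = 0.5 * (float(Py @ self._G[k] @ Py) - float(np.sum(P * self._G[k])))
            if score > 1e-8:
                # restart small enough that the likelihood cannot dip
                for mag in (1e-4, 1e-6, 1e-8):
                    theta[k] = mag * scale
                    if self.loglik(theta) >= ll_now - 1e-12:
                        revived = True
                        break
                    theta[k] = 0.0
        return revived


# ----------------------------------------------------------------------
# public API on factor tables


def factor_column(design: pd.DataFrame, name: str) -> pd.Series:
    """Factor column lookup accepting either ``name`` or ``name_id``."""
    col = name if name in design.columns else f"{name}_id"
    if col not in design.columns:
        raise ValueError(f"design is missing factor column {name!r}")
    return design[col]


def _build_blocks(
    design: pd.DataFrame, factors: Sequence[str]
) -> list[tuple[str, np.ndarray]]:
    blocks = []
    for name in factors:
        col = name if name in design.columns else f"{name}_id"
        if col not in design.columns:
            raise ValueError(f"design is missing factor column {name!r}")
        Z = _indicator(design[col].to_numpy())
        blocks.append((name, Z))
    return blocks


def restricted_loglik(
    params: Mapping[str, float],
    response: np.ndarray,
    design: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    X: np.ndarray | None = None,
) -> float:
    """Exact restricted log-likelihood of the Gaussian model.

    ``params`` maps each factor name (and ``"resid"``) to its variance.
    Shared by the EM updates and by the brute-force test oracle.
    """
    y = np.asarray(response, float)
    factors = tuple(factors)
    theta = np.array([params[name] for name in factors] + [params["resid"]])
    if np.any(theta < 0):
        raise ValueError("variances must be non-negative")
    if X is None:
        X = np.ones((len(y), 1))
    model = MixedREML(y, X, _build_blocks(design, factors))
    return model.loglik(theta)


def fit_reml(
    response: np.ndarray,
    design: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    X: np.ndarray | None = None,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
    accelerate: bool = True,
    boundary_tol: float = 1e-6,
) -> VarianceComponents:
    """EM-REML fit of the family-proportion mixed model.

    ``response`` is the per-row proportion (or any Gaussian response);
    ``design`` supplies the factor columns.  Factors with a single level
    are reported as zero-variance with a boundary flag (their variance is
    confounded with the intercept).  A constant response returns an
    all-zero degenerate fit.
    """
    y = np.asarray(response, float)
    factors = tuple(factors)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    levels = {name: factor_column(design, name).nunique() for name in factors}
    if all(q < 2 for q in levels.values()):
        raise ValueError("need >= 2 levels in at least one factor")
    usable = tuple(name for name in factors if levels[name] >= 2)
    dropped = tuple(name for name in factors if levels[name] < 2)

    result = VarianceComponents(n_obs=len(y), factors=factors)
    if float(np.ptp(y)) == 0.0:
        result.converged = True
        result.degenerate = True
        result.boundary = factors
        return result

    model = MixedREML(
        y, np.ones((len(y), 1)) if X is None else X, _build_blocks(design, usable)
    )
    fit = model.fit(tol=tol, max_iter=max_iter, accelerate=accelerate)
    theta = fit["theta"]
    total = float(theta.sum())
    boundary = list(dropped)
    for i, name in enumerate(usable):
        value = float(theta[i])
        if value < boundary_tol * total:
            value = 0.0
            boundary.append(name)
        setattr(result, f"var_{name}", value)
    result.var_resid = float(theta[-1])
    result.converged = bool(fit["converged"])
    result.loglik_restricted = float(fit["loglik"])
    result.n_iter = int(fit["n_iter"])
    result.boundary = tuple(boundary)
    result.loglik_path = fit["loglik_path"]
    return result
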