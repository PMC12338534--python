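"""Tobit (censored-normal) regression in a statsmodels-like Model/Results shape.

The response y is modelled as y* = X b + e, e ~ N(0, sigma^2), observed as

    y = lower  if y* <= lower   (left-censored)
    y = upper  if y* >= upper   (right-censored)
    y = y*     otherwise

Uncensored points contribute the normal density, left-censored points the
lower tail Phi((lower - mu)/sigma), right-censored points the upper tail
1 - Phi((upper - mu)/sigma).  The MLE is found by direct numerical
maximization with sigma parameterized as exp(log sigma) and multiple starts
around the OLS initialization.

For Barnes-maze primary latencies the working scale is y = -log(latency s),
with lower = -log(240) (trials aborted at the 240 s cap) and upper =
-log(1) = 0 (the 1 s floor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["TobitModel", "TobitResults"]


@dataclass
class TobitResults:
    """MLE of a censored-normal regression."""

    params: np.ndarray          # regression coefficients b
    sigma: float
    llf: float
    converged: bool
    n_obs: int
    n_censored_low: int
    n_censored_high: int
    bse: np.ndarray | None = None
    exog_names: tuple[str, ...] = ()

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    def summary(self) -> str:
        lines = ["Tobit regression results", "-" * 40]
        lines.append(f"n_obs          {self.n_obs}")
        lines.append(
            f"censored       low={self.n_censored_low} high={self.n_censored_high}"
        )
        names = self.exog_names or tuple(f"x{i}" for i in range(len(self.params)))
        for name, b, se in zip(
            names, self.params,
            self.bse if self.bse is not None else [np.nan] * len(self.params),
        ):
            lines.append(f"{name:<12} {b:>12.6f}  (se {se:.4g})")
        lines.append(f"{'sigma':<12} {self.sigma:>12.6f}")
        lines.append(f"loglik         {self.llf:.6f}")
        lines.append(f"converged      {self.converged}")
        return "\n".join(lines)


class TobitModel:
    """Censored-normal linear regression.

    Parameters
    ----------
    endog : observed response (already clipped to [lower, upper]).
    exog : design matrix, shape (n, k); pass an explicit constant column.
    lower, upper : censoring limits; +-inf disables a side.
    left_censored, right_censored : optional boolean masks.  When omitted,
        censoring is inferred from equality (within 1e-12) with the limits.
    """

    def __init__(
        self,
        endog,
        exog,
        lower: float = -np.inf,
        upper: float = np.inf,
        left_censored=None,
        right_censored=None,
        exog_names: tuple[str, ...] = (),
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            self.exog = self.exog.T
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        self.lower = float(lower)
        self.upper = float(upper)
        if left_censored is None:
            left_censored = self.endog <= self.lower + 1e-12
        if right_censored is None:
            right_censored = self.endog >= self.upper - 1e-12
        self.left = np.asarray(left_censored, dtype=bool)
        self.right = np.asarray(right_censored, dtype=bool) & ~self.left
        self.free = ~self.left & ~self.right
        self.exog_names = exog_names or tuple(
            f"x{i}" for i in range(self.exog.shape[1])
        )

    # -- likelihood ---------------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at (b..., log sigma)."""
        b, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        mu = self.exog @ b
        ll = 0.0
        if self.free.any():
            z = (self.endog[self.free] - mu[self.free]) / sigma
            ll += np.sum(stats.norm.logpdf(z) - log_sigma)
        if self.left.any():
            ll += np.sum(stats.norm.logcdf((self.lower - mu[self.left]) / sigma))
        if self.right.any():
            ll += np.sum(stats.norm.logsf((self.upper - mu[self.right]) / sigma))
        return float(ll)

    # -- fitting ------------------------------------------------------------

    def _start_params(self) -> np.ndarray:
        X, y = self.exog, self.endog
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma0 = float(np.std(resid, ddof=min(X.shape[1], len(y) - 1)))
        sigma0 = max(sigma0, 1e-2)
        return np.concatenate([beta, [np.log(sigma0)]])

    def fit(self, maxiter: int = 500) -> TobitResults:
        n_left = int(self.left.sum())
        n_right = int(self.right.sum())
        # degenerate: every observation censored at one limit -> flat ridge
        if not self.free.any() and (n_left == 0 or n_right == 0):
            k = self.exog.shape[1]
            return TobitResults(
                params=np.full(k, np.nan),
                sigma=np.nan,
                llf=np.nan,
                converged=False,
                n_obs=len(self.endog),
                n_censored_low=n_left,
                n_censored_high=n_right,
                exog_names=self.exog_names,
            )

        start = self._start_params()
        starts = [start]
        for scale in (3.0, 1.0 / 3.0):
            alt = start.copy()
            alt[-1] = start[-1] + np.log(scale)
            starts.append(alt)

        best = None
        for s0 in starts:
            res = optimize.minimize(
                lambda p: -self.loglike(p),
                s0,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        params = best.x
        sigma = float(np.exp(params[-1]))
        llf = -float(best.fun)
        converged = bool(best.success) and np.isfinite(llf) and sigma > 0

        bse = None
        if converged:
            try:
                hess = _numerical_hessian(self.loglike, params)
                cov = np.linalg.inv(-hess)
                se = np.sqrt(np.diag(cov))
                bse = se[:-1]
            except np.linalg.LinAlgError:
                bse = None
        return TobitResults(
            params=params[:-1],
            sigma=sigma,
            llf=llf,
            converged=converged,
            n_obs=len(self.endog),
            n_censored_low=n_left,
            n_censored_high=n_right,
            bse=bse,
            exog_names=self.exog_names,
        )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps * eps)
    return H
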