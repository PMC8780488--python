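"""Poisson mixed model linking plant-bug density to square retention.

The retained-square count per quadrant (out of 25 inspected first-position
squares) is modelled as Poisson with log-mean
``beta0 + beta1 * density + b_field + b_quadrant``, with independent
Gaussian random intercepts for fields and for quadrants nested in fields.
The random effects are integrated out by a Laplace approximation to the
marginal likelihood; the slope is tested by a likelihood-ratio chi-square
against the ``beta1 = 0`` submodel. Percent retention predictions divide
the conditional mean (random effects at zero) by the number of positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .records import retention_to_frame

_SD_FLOOR = 1e-4  # random-effect SDs below this are reported as 0


@dataclass(frozen=True)
class InjuryFit:
    beta0: float
    beta1: float
    re_sd_field: float
    re_sd_quadrant: float
    se_beta1: float
    chi2_slope: float
    p_value: float
    loglik: float
    n_obs: int

    def __post_init__(self) -> None:
        if min(self.re_sd_field, self.re_sd_quadrant) < 0:
            raise ValueError("random-effect SDs must be non-negative")


class _LaplacePoisson:
    """Laplace-approximated marginal likelihood for the nested model."""

    def __init__(self, y, density, field_idx, quad_idx):
        self.y = np.asarray(y, float)
        self.d = np.asarray(density, float)
        self.fi = np.asarray(field_idx)
        self.qi = np.asarray(quad_idx)
        self.nf = self.fi.max() + 1
        self.nq = self.qi.max() + 1
        n = len(self.y)
        zf = np.zeros((n, self.nf))
        zf[np.arange(n), self.fi] = 1.0
        zq = np.zeros((n, self.nq))
        zq[np.arange(n), self.qi] = 1.0
        self.z = np.hstack([zf, zq])
        self._u = np.zeros(self.nf + self.nq)

    def _eta(self, beta0, beta1, u):
        return beta0 + beta1 * self.d + self.z @ u

    def marginal_nll(self, params, fix_beta1=None):
        if fix_beta1 is None:
            beta0, beta1, ls_f, ls_q = params
        else:
            beta0, ls_f, ls_q = params
            beta1 = fix_beta1
        prec = np.concatenate([
            np.full(self.nf, math.exp(-2.0 * ls_f)),
            np.full(self.nq, math.exp(-2.0 * ls_q)),
        ])
        u = self._u.copy()
        for _ in range(50):  # Newton on the concave penalized log-likelihood
            eta = np.clip(self._eta(beta0, beta1, u), -30, 30)
            mu = np.exp(eta)
            grad = self.z.T @ (mu - self.y) + prec * u
            h = (self.z.T * mu) @ self.z
            h[np.diag_indices_from(h)] += prec
            try:
                step = cho_solve(cho_factor(h), grad)
            except np.linalg.LinAlgError:
                return 1e10
            u_new = u - step
            if np.max(np.abs(step)) < 1e-9:
                u = u_new
                break
            u = u_new
        self._u = u  # warm start for the next outer evaluation
        eta = np.clip(self._eta(beta0, beta1, u), -30, 30)
        mu = np.exp(eta)
        pen_ll = float(self.y @ eta - mu.sum()
                       - 0.5 * (prec * u * u).sum())
        h = (self.z.T * mu) @ self.z
        h[np.diag_indices_from(h)] += prec
        sign, logdet_h = np.linalg.slogdet(h)
        if sign <= 0:
            return 1e10
        logdet_prec = float(np.log(prec).sum())
        ll = pen_ll + 0.5 * logdet_prec - 0.5 * logdet_h
        return -ll


def fit_injury(retention, density_col: str = "density") -> InjuryFit:
    """Fit the Poisson random-intercept injury model by Laplace ML.

    ``retention`` holds one row per quadrant inspection with the retained
    count and the paired insect density. Requires >= 10 records spanning
    >= 2 fields; retained counts must be integers.
    """
    frame = retention_to_frame(retention) if density_col == "density" \
        else pd.DataFrame(retention)
    y = frame["retained"].to_numpy()
    if not np.allclose(y, np.round(y)):
        raise ValueError("retained counts must be integers")
    if len(frame) < 10 or frame["field_id"].nunique() < 2:
        raise ValueError("need >= 10 records across >= 2 fields")
    d = frame[density_col].to_numpy(float)
    field_idx = pd.factorize(frame["field_id"])[0]
    quad_idx = pd.factorize(frame["field_id"].astype(str) + ":"
                            + frame["quadrant"].astype(str))[0]
    lap = _LaplacePoisson(y, d, field_idx, quad_idx)

    beta0_init = math.log(max(y.mean(), 0.5))
    bounds_sd = (math.log(_SD_FLOOR) - 1.0, 2.0)
    res = optimize.minimize(
        lap.marginal_nll, x0=[beta0_init, 0.0, math.log(0.1), math.log(0.1)],
        method="L-BFGS-B",
        bounds=[(None, None), (None, None), bounds_sd, bounds_sd])
    beta0, beta1, ls_f, ls_q = res.x
    ll_full = -res.fun

    lap0 = _LaplacePoisson(y, d, field_idx, quad_idx)
    res0 = optimize.minimize(
        lambda p: lap0.marginal_nll(p, fix_beta1=0.0),
        x0=[beta0_init, math.log(0.1), math.log(0.1)],
        method="L-BFGS-B", bounds=[(None, None), bounds_sd, bounds_sd])
    ll_null = -res0.fun
    chi2 = max(0.0, 2.0 * (ll_full - ll_null))
    p_val = float(stats.chi2.sf(chi2, df=1))

    # observed-information standard error for the slope from the full
    # 4-parameter numeric Hessian of the Laplace marginal deviance
    x_hat = np.array([beta0, beta1, ls_f, ls_q])
    steps = np.maximum(1e-4, 1e-4 * np.abs(x_hat))
    k = len(x_hat)
    hess = np.zeros((k, k))
    f0 = lap.marginal_nll(x_hat)
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * steps[i]
            ej = np.eye(k)[j] * steps[j]
            if i == j:
                val = (lap.marginal_nll(x_hat + ei) - 2 * f0
                       + lap.marginal_nll(x_hat - ei)) / steps[i] ** 2
            else:
                val = (lap.marginal_nll(x_hat + ei + ej)
                       - lap.marginal_nll(x_hat + ei - ej)
                       - lap.marginal_nll(x_hat - ei + ej)
                       + lap.marginal_nll(x_hat - ei - ej)) / (4 * steps[i] * steps[j])
            hess[i, j] = hess[j, i] = val
    try:
        cov = np.linalg.inv(hess)
        se_beta1 = float(math.sqrt(cov[1, 1])) if cov[1, 1] > 0 else float("nan")
    except np.linalg.LinAlgError:
        se_beta1 = float("nan")

    sd_f = math.exp(ls_f)
    sd_q = math.exp(ls_q)
    return InjuryFit(
        beta0=float(beta0), beta1=float(beta1),
        re_sd_field=0.0 if sd_f < _SD_FLOOR else sd_f,
        re_sd_quadrant=0.0 if sd_q < _SD_FLOOR else sd_q,
        se_beta1=se_beta1,
        chi2_slope=float(chi2), p_value=p_val,
        loglik=float(ll_full), n_obs=len(frame),
    )


def predict_retention(fit: InjuryFit, density: float, positions: int = 25) -> float:
    """Percent square retention at a density, random effects at zero."""
    if density < 0:
        raise ValueError("density must be non-negative")
    return 100.0 * math.exp(fit.beta0 + fit.beta1 * density) / positions
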