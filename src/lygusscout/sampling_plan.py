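"""Fixed-precision sampling plans from Taylor's power law.

Taylor's power law relates the variance of repeated counts to their mean,
``variance = a * mean**b``; ``b > 1`` indicates spatial aggregation. Under
the law, Green's fixed-precision sample size for estimating a mean ``m``
with relative precision ``D`` (SE/mean) is ``N = a * m**(b-2) / D**2``, and
its sequential form is a stop line in cumulative count versus number of
units sampled. Plans are validated empirically by resampling observed units
with replacement and recording the terminal sample size distribution
(the RVSP procedure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import units_to_frame


@dataclass(frozen=True)
class TaylorFit:
    """Power-law parameters from a log10-log10 mean-variance regression."""

    a: float
    b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    r2: float
    n_groups: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.ci_a[0] > self.ci_a[1] or self.ci_b[0] > self.ci_b[1]:
            raise ValueError("confidence bounds must be ordered")


def group_moments(records, grouping: str = "field") -> pd.DataFrame:
    """Per-group (mean, variance) pairs of unit counts.

    ``grouping`` is ``"field"`` (one pair per field x growth stage, the
    study's field-centric unit) or ``"field_quadrant"``.
    """
    units = units_to_frame(records)
    keys = {"field": ["field_id", "growth_stage"],
            "field_quadrant": ["field_id", "growth_stage", "quadrant"]}[grouping]
    g = units.groupby(keys)["total"].agg(mean="mean", var="var", n="count")
    return g.reset_index()


def fit_taylor(records, grouping: str = "field") -> TaylorFit:
    """OLS fit of log10(variance) on log10(mean) over group moments.

    Groups with fewer than two units, zero mean or zero variance carry no
    information about the mean-variance scaling on the log scale and are
    excluded; the count of exclusions is reported on the fit.
    """
    moments = group_moments(records, grouping)
    usable = moments[(moments["n"] >= 2) & (moments["mean"] > 0)
                     & (moments["var"] > 0)]
    n_excluded = len(moments) - len(usable)
    if len(usable) < 3:
        raise ValueError("need at least 3 usable groups with positive mean "
                         "and variance")
    x = np.log10(usable["mean"].to_numpy())
    y = np.log10(usable["var"].to_numpy())
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return TaylorFit(
        a=float(10.0 ** res.params[0]),
        b=float(res.params[1]),
        ci_a=(float(10.0 ** ci[0, 0]), float(10.0 ** ci[0, 1])),
        ci_b=(float(ci[1, 0]), float(ci[1, 1])),
        r2=float(res.rsquared),
        n_groups=len(usable),
        n_excluded=n_excluded,
    )


def green_sample_size(a: float, b: float, m: float, D: float) -> float:
    """Green's fixed-precision sample size ``N = a * m**(b-2) / D**2``.

    Returns the real-valued N; callers ceil when an integer number of
    sampling units is needed.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if m <= 0:
        raise ValueError("m must be positive")
    if not 0 < D <= 1:
        raise ValueError("D must lie in (0, 1]")
    return a * m ** (b - 2.0) / D**2


def stop_line(a: float, b: float, D: float, n_max: int) -> pd.DataFrame:
    """Cumulative-count stop boundary ``T_n = (D^2 n^(b-1) / a)^(1/(b-2))``.

    Sampling stops after ``n`` units once the cumulative count reaches
    ``T_n``; solving ``T_n / n = m`` recovers Green's sample size at mean
    ``m``. Degenerate at ``b = 2``, where the plan is mean-free
    (use ``N = a / D**2`` directly).
    """
    if b == 2.0:
        raise ValueError("b = 2 is degenerate: the required N is a/D**2 "
                         "independent of the mean; no stop line exists")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if not 0 < D <= 1:
        raise ValueError("D must lie in (0, 1]")
    n = np.arange(1, n_max + 1)
    t = (D**2 * n ** (b - 1.0) / a) ** (1.0 / (b - 2.0))
    return pd.DataFrame({"n": n, "T_n": t})


@dataclass(frozen=True)
class ResamplingValidationResult:
    """Terminal-sample-size distribution from sequential resampling."""

    n_sim: int
    navg: float
    nsd: float
    nmin: int
    nmax: int
    per_sim: list  # (terminal_n, terminal_mean) pairs

    def __post_init__(self) -> None:
        if len(self.per_sim) != self.n_sim:
            raise ValueError("per_sim length must equal n_sim")
        if not self.nmin <= self.navg <= self.nmax:
            raise ValueError("nmin <= navg <= nmax violated")


def resample_validation(
    units,
    a: float,
    b: float,
    D: float = 0.25,
    n_sim: int = 500,
    n_min_start: int = 3,
    seed: int = 0,
    n_cap: int = 1000,
) -> ResamplingValidationResult:
    """Sequential resampling validation of a fixed-precision plan (RVSP).

    Each simulation draws observed units with replacement, accumulating the
    cumulative count ``T`` and units sampled ``n``, and stops at the first
    ``n >= n_min_start`` where ``T`` reaches the Green stop line
    (equivalently ``n >= a * (T/n)**(b-2) / D**2``). The floor
    ``n_min_start`` prevents stopping on a single lucky draw. Returns the
    mean, SD, minimum and maximum terminal sample size over ``n_sim``
    seeded simulations.
    """
    pool = np.asarray(units)
    if pool.size == 0 or pool.mean() <= 0:
        raise ValueError("units must be non-empty with positive pooled mean")
    if (pool < 0).any():
        raise ValueError("units must be non-negative counts")
    rng = np.random.default_rng(seed)
    terminal = np.empty(n_sim, int)
    term_mean = np.empty(n_sim, float)
    capped = 0
    for s in range(n_sim):
        draws = rng.choice(pool, n_cap, replace=True)
        cum = np.cumsum(draws)
        n_arr = np.arange(1, n_cap + 1)
        m_hat = cum / n_arr
        with np.errstate(divide="ignore"):
            need = np.where(m_hat > 0, a * m_hat ** (b - 2.0) / D**2, np.inf)
        ok = (n_arr >= n_min_start) & (n_arr >= need)
        idx = np.argmax(ok) if ok.any() else n_cap - 1
        if not ok.any():
            capped += 1
        terminal[s] = n_arr[idx]
        term_mean[s] = m_hat[idx]
    if capped:
        warnings.warn(f"{capped} of {n_sim} simulations never met the stop "
                      f"rule and were capped at n = {n_cap}")
    return ResamplingValidationResult(
        n_sim=n_sim,
        navg=float(terminal.mean()),
        nsd=float(terminal.std(ddof=1)) if n_sim > 1 else 0.0,
        nmin=int(terminal.min()),
        nmax=int(terminal.max()),
        per_sim=list(zip(terminal.tolist(), term_mean.tolist())),
    )


@dataclass(frozen=True)
class SamplingPlan:
    """A fixed-precision plan: the fitted power law plus its stop line."""

    taylor: TaylorFit
    precision_D: float
    stop_table: pd.DataFrame

    @classmethod
    def from_fit(cls, taylor: TaylorFit, precision_D: float = 0.25,
                 n_max: int = 100) -> "SamplingPlan":
        return cls(taylor=taylor, precision_D=precision_D,
                   stop_table=stop_line(taylor.a, taylor.b, precision_D, n_max))

    def sample_size(self, m: float) -> float:
        return green_sample_size(self.taylor.a, self.taylor.b, m, self.precision_D)
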