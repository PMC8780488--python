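"""ANOVA-type variance component analysis for the nested scouting design.

Counts are decomposed over the random sources year, state, district, field
and quadrant-within-field plus residual error, using Henderson's Method I:
sequential (nesting-order) sums of squares are equated to their expected
values, which are linear in the variance components. On balanced designs
this reduces to the classical expected-mean-squares solution; negative
estimates are truncated to zero before percent-variation is computed, and
the per-source coefficient of variation is sqrt(vc) / overall mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import units_to_frame

VCA_SOURCES = ("year", "state", "district", "field", "field:quadrant", "error")


def _dummies(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(float)


def _orth_increment(basis: np.ndarray | None, block: np.ndarray,
                    tol: float = 1e-8) -> np.ndarray:
    """Orthonormal basis for the part of ``block`` outside ``basis``."""
    resid = block - basis @ (basis.T @ block) if basis is not None else block
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    scale = max(s[0], 1.0) if s.size else 1.0
    return u[:, s > tol * scale]


@dataclass
class VarianceComponentTable:
    """Per-source variance components, percent variation and CVs."""

    table: pd.DataFrame  # columns: source, df, vc, pct_variation, cv
    mean: float

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def fit_nested_vca(records, response: str = "total") -> VarianceComponentTable:
    """Henderson Method-I variance components for the nested count design.

    The sequential strata are year, state, district-within-state,
    field-within-district and quadrant-within-field; state is crossed with
    year (states repeat across years) but precedes district in the nesting
    order. Sources whose dummy columns add no rank beyond earlier strata
    (for example a single sampled year, or one unit per quadrant leaving no
    residual replication) get zero degrees of freedom and a zero component.
    """
    units = units_to_frame(records)
    if len(units) < 2:
        raise ValueError("need at least 2 observations")
    y = units[response].to_numpy(float)
    n = len(y)
    mean = float(y.mean())

    blocks = {
        "year": _dummies(units["year"]),
        "state": _dummies(units["state"]),
        "district": _dummies(units["state"].astype(str) + ":" + units["district"].astype(str)),
        "field": _dummies(units["field_id"]),
        "field:quadrant": _dummies(units["field_id"].astype(str) + ":"
                                   + units["quadrant"].astype(str)),
    }
    random_sources = list(blocks)

    # sequential orthonormal bases: intercept first, then each stratum
    basis = np.full((n, 1), 1.0 / np.sqrt(n))
    stratum_bases, dfs = {}, {}
    for src in random_sources:
        u = _orth_increment(basis, blocks[src])
        stratum_bases[src] = u
        dfs[src] = u.shape[1]
        if u.shape[1]:
            basis = np.hstack([basis, u])
    dfs["error"] = n - basis.shape[1]

    # observed sequential sums of squares
    ss = {src: float(((stratum_bases[src].T @ y) ** 2).sum())
          for src in random_sources}
    ss["error"] = float((y**2).sum() - ((basis.T @ y) ** 2).sum())

    # expected-SS coefficients: E[SS_k] = sum_l sigma2_l ||U_k' Z_l||_F^2
    #                                     + sigma2_e df_k
    rows, rhs = [], []
    # accumulated projection norms per random source (intercept included)
    acc = {l: float(((basis[:, :1].T @ blocks[l]) ** 2).sum())
           for l in random_sources}
    for src in random_sources:
        if dfs[src] == 0:
            continue
        u = stratum_bases[src]
        coef = []
        for l in random_sources:
            c = float(((u.T @ blocks[l]) ** 2).sum())
            acc[l] += c
            coef.append(c)
        coef.append(float(dfs[src]))
        rows.append(coef)
        rhs.append(ss[src])
    if dfs["error"] > 0:
        coef = [float((blocks[l] ** 2).sum() - acc[l]) for l in random_sources]
        coef.append(float(dfs["error"]))
        rows.append(coef)
        rhs.append(ss["error"])

    estimable = [l for l in random_sources if dfs[l] > 0]
    full = np.array(rows)
    keep = [i for i, l in enumerate(random_sources) if l in estimable]
    a_mat = full[:, keep + [len(random_sources)]]
    sol, *_ = np.linalg.lstsq(a_mat, np.array(rhs), rcond=None)
    vcs = dict.fromkeys(random_sources, 0.0)
    for l, v in zip(estimable, sol[:-1]):
        vcs[l] = float(v)
    vcs["error"] = float(sol[-1]) if dfs["error"] > 0 else 0.0

    zero_tol = 1e-10 * max(float(np.var(y)), 1e-12)
    truncated = {s: 0.0 if v < zero_tol else v for s, v in vcs.items()}
    total = sum(truncated.values())
    table = pd.DataFrame({
        "source": list(VCA_SOURCES),
        "df": [dfs[s] for s in VCA_SOURCES],
        "vc": [truncated[s] for s in VCA_SOURCES],
        "pct_variation": [100.0 * truncated[s] / total if total > 0 else 0.0
                          for s in VCA_SOURCES],
        "cv": [np.sqrt(truncated[s]) / mean if mean > 0 else np.nan
               for s in VCA_SOURCES],
    })
    return VarianceComponentTable(table=table, mean=mean)


def cv_asymptotic_test(sample_a, sample_b) -> dict:
    """Feltz-Miller asymptotic chi-square test of CV equality.

    The statistic pools the sample CVs weighted by degrees of freedom and is
    asymptotically chi-square with k-1 = 1 degrees of freedom under equal
    population CVs.
    """
    stats_out = []
    for s in (sample_a, sample_b):
        x = np.asarray(s, float)
        if x.size < 2:
            raise ValueError("both samples need n >= 2")
        if x.mean() <= 0:
            raise ValueError("CV undefined for non-positive sample mean")
        stats_out.append((x.size - 1.0, x.std(ddof=1) / x.mean()))
    nu = np.array([d for d, _ in stats_out])
    cv = np.array([c for _, c in stats_out])
    c_pool = float((nu * cv).sum() / nu.sum())
    if c_pool == 0.0:
        return {"statistic": 0.0, "p_value": 1.0}
    stat = float((nu * (cv - c_pool) ** 2).sum()
                 / (c_pool**2 * (0.5 + c_pool**2)))
    return {"statistic": stat, "p_value": float(stats.chi2.sf(stat, df=1))}
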