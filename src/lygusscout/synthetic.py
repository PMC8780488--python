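"""Seeded generators for every input the analysis pipeline consumes.

The study's raw scouting data are not deposited anywhere, so this module is
the canonical input source. It emulates

* per-sampling-unit tarnished plant bug counts (100-sweep sweep-net units at
  squaring, 1.5 row-m drop-cloth units at bloom) nested in
  quadrant -> field -> district -> state -> year, with multiplicative
  lognormal random effects sized to requested variance shares and a local
  variance-mean relationship following Taylor's power law
  (variance = a * mean**b);
* square-retention inspections (retained squares out of 25 positions per
  quadrant) driven by insect density through a log-linear Poisson model;
* field-level landscape covariate tables (land-cover proportions in a
  0.5 km buffer) together with the spatial count dataset generated from the
  hierarchical Poisson model with a Matern(nu=1) random field.

Everything is reproducible from an explicit integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from .records import (
    CULTIVATED_CLASSES,
    LANDSCAPE_CLASSES,
    RETENTION_COLUMNS,
    SpatialDataset,
    units_to_frame,
)

HIERARCHY_LEVELS = ("year", "state", "district", "field", "quadrant")
VARIANCE_SOURCES = HIERARCHY_LEVELS + ("error",)

STATE_NAMES = ("AL", "GA", "NC", "SC", "VA")


# ---------------------------------------------------------------------------
# hierarchical count generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HierarchySpec:
    """Design and dispersion parameters for the nested count generator.

    ``variance_shares`` apportions the raw-scale count variance among the
    nested sources; ``grand_mean`` is the expected count per sampling unit;
    ``taylor_a``/``taylor_b`` set the conditional unit-level variance
    ``a * m**b`` given the local mean ``m``. When ``total_sd`` is given the
    total count variance is anchored at ``total_sd**2`` and the hierarchy
    levels receive their shares of it; otherwise the total is inferred from
    the error share and the Taylor relation (the error stratum *is* the
    conditional count noise, so its share pins the overall scale).
    """

    n_states: int = 5
    districts_per_state: int = 2
    fields_per_district: int = 10
    variance_shares: dict = field(default_factory=lambda: {
        # magnitude pattern of the study's sweep-net decomposition
        "year": 0.09, "state": 0.0, "district": 0.11,
        "field": 0.45, "quadrant": 0.32, "error": 0.03,
    })
    grand_mean: float = 2.9
    taylor_a: float = 0.95
    taylor_b: float = 1.11
    seed: int = 0
    n_years: int = 2
    total_sd: float | None = 4.4

    def __post_init__(self) -> None:
        shares = dict(self.variance_shares)
        unknown = set(shares) - set(VARIANCE_SOURCES)
        if unknown:
            raise ValueError(f"unknown variance sources: {sorted(unknown)}")
        vals = np.array([shares.get(s, 0.0) for s in VARIANCE_SOURCES], float)
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("variance shares must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("variance shares must sum to 1")
        if self.grand_mean <= 0 or self.taylor_a <= 0:
            raise ValueError("grand_mean and taylor_a must be positive")
        if min(self.n_states, self.districts_per_state,
               self.fields_per_district, self.n_years) < 1:
            raise ValueError("design counts must be positive integers")

    @property
    def n_fields(self) -> int:
        return self.n_states * self.districts_per_state * self.fields_per_district

    def share(self, source: str) -> float:
        return float(self.variance_shares.get(source, 0.0))


def _lognormal_mult(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal effects."""
    if sigma == 0.0:
        return np.ones(size)
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size))


def calibrate_level_sds(spec: HierarchySpec) -> tuple[dict, float]:
    """Solve for per-level lognormal SDs matching the requested shares.

    With independent unit-mean multiplicative effects ``e_l`` of relative
    variance ``v_l``, the sequential (top-down) variance component of level
    ``l`` on the raw count scale is ``mu**2 * v_l * prod_{k above l}(1+v_k)``
    and the error stratum contributes ``E[a m**b]``. Levels are solved top
    down; when no ``total_sd`` anchor is given the overall variance is found
    by fixed-point iteration so the error stratum receives its share.

    Returns ``(sigmas, total_variance)`` where ``sigmas`` maps hierarchy
    levels to lognormal SDs.
    """
    mu, a, b = spec.grand_mean, spec.taylor_a, spec.taylor_b
    c = b * (b - 1.0) / 2.0

    def solve_levels(v_tot: float) -> tuple[dict, float]:
        v, cum = {}, 1.0
        for lvl in HIERARCHY_LEVELS:
            vc = spec.share(lvl) * v_tot
            v[lvl] = vc / (mu * mu * cum)
            cum *= 1.0 + v[lvl]
        return v, cum

    if spec.total_sd is not None:
        v_tot = float(spec.total_sd) ** 2
        v, _ = solve_levels(v_tot)
    else:
        s_err = spec.share("error")
        if s_err <= 0:
            raise ValueError(
                "an error share > 0 (or a total_sd anchor) is required to set "
                "the overall variance scale")
        v_tot = a * mu**b / s_err
        for _ in range(200):
            v, _ = solve_levels(v_tot)
            e_term = float(np.prod([(1.0 + v[l]) ** c for l in HIERARCHY_LEVELS]))
            v_new = a * mu**b * e_term / s_err
            if abs(v_new - v_tot) < 1e-12 * max(1.0, v_tot):
                v_tot = v_new
                break
            v_tot = v_new
        v, _ = solve_levels(v_tot)
    sigmas = {lvl: math.sqrt(math.log1p(v[lvl])) for lvl in HIERARCHY_LEVELS}
    return sigmas, v_tot


def _taylor_counts(rng: np.random.Generator, m: np.ndarray, a: float, b: float,
                   poisson_fallback: bool = True) -> np.ndarray:
    """Counts with mean ``m`` and variance ``a*m**b`` (elementwise).

    Overdispersed cells are drawn negative-binomial via its gamma-Poisson
    mixture; cells where the Taylor variance does not exceed the mean fall
    back to Poisson (a negative binomial cannot be underdispersed, and for
    b > 1 with a < 1 the power law crosses the Poisson line at small means).
    """
    m = np.asarray(m, float)
    var = a * np.power(m, b)
    over = var > m
    if not poisson_fallback and (~over).any():
        raise ValueError("Taylor variance <= mean and Poisson fallback disabled")
    lam = m.copy()
    if over.any():
        excess = var[over] - m[over]
        lam[over] = rng.gamma(m[over] ** 2 / excess, excess / m[over])
    return rng.poisson(lam)


def generate_hierarchical_counts(
    spec: HierarchySpec,
    method: str = "sweep",
    units_per_quadrant: int | None = None,
    poisson_fallback: bool = True,
) -> pd.DataFrame:
    """Simulate nested sampling-unit counts for one sampling technique.

    Sweep-net sampling yields one 100-sweep unit per quadrant (the sum of
    four 25-sweep transects); drop-cloth sampling yields two 1.5 row-m units
    per quadrant. Both defaults can be overridden via
    ``units_per_quadrant``. Each field is visited in a single year; states
    repeat across years (year and state effects are crossed).
    """
    if method not in ("sweep", "drop"):
        raise ValueError("method must be 'sweep' or 'drop'")
    if units_per_quadrant is None:
        units_per_quadrant = 1 if method == "sweep" else 2
    stage = "squaring" if method == "sweep" else "bloom"
    unit_size = 100.0 if method == "sweep" else 1.5

    sigmas, _ = calibrate_level_sds(spec)
    rng = np.random.default_rng(spec.seed)

    n_states = spec.n_states
    n_districts = n_states * spec.districts_per_state
    n_fields = spec.n_fields
    upq = units_per_quadrant

    e_year = _lognormal_mult(rng, sigmas["year"], spec.n_years)
    e_state = _lognormal_mult(rng, sigmas["state"], n_states)
    e_district = _lognormal_mult(rng, sigmas["district"], n_districts)
    e_field = _lognormal_mult(rng, sigmas["field"], n_fields)
    e_quad = _lognormal_mult(rng, sigmas["quadrant"], (n_fields, 4))

    f_idx = np.arange(n_fields)
    f_district = f_idx // spec.fields_per_district
    f_state = f_district // spec.districts_per_state
    f_year = f_idx % spec.n_years

    m_field = (spec.grand_mean * e_year[f_year] * e_state[f_state]
               * e_district[f_district] * e_field)
    m_unit = np.repeat(m_field[:, None] * e_quad, upq, axis=1)  # (n_fields, 4*upq)
    total = _taylor_counts(rng, m_unit.ravel(), spec.taylor_a, spec.taylor_b,
                           poisson_fallback)

    p_adult = rng.beta(2.0, 2.0, n_fields)
    adults = rng.binomial(total, np.repeat(p_adult, 4 * upq))

    states = [STATE_NAMES[i % len(STATE_NAMES)] if n_states <= len(STATE_NAMES)
              else f"S{i + 1}" for i in range(n_states)]
    rows_per_field = 4 * upq
    frame = pd.DataFrame({
        "year": np.repeat(2019 + f_year, rows_per_field),
        "state": np.repeat([states[s] for s in f_state], rows_per_field),
        "district": np.repeat(
            [f"{states[f_state[i]]}-D{f_district[i] % spec.districts_per_state + 1}"
             for i in f_idx], rows_per_field),
        "field_id": np.repeat([f"F{i + 1:03d}" for i in f_idx], rows_per_field),
        "quadrant": np.tile(np.repeat(np.arange(1, 5), upq), n_fields),
        "unit": np.tile(np.arange(1, upq + 1), 4 * n_fields),
        "method": method,
        "growth_stage": stage,
        "unit_size": unit_size,
        "adults": adults,
        "nymphs": total - adults,
        "total": total,
    })
    return frame


# ---------------------------------------------------------------------------
# Taylor-law pool specifications and refit-bias calibration
# ---------------------------------------------------------------------------

def _solve_field_dispersion(mean: float, sd: float, a: float, b: float) -> float:
    """Relative field-mean variance v such that the pooled unit variance is
    ``sd**2`` when units are conditionally Taylor-dispersed around lognormal
    field means: mu^2 v + a mu^b E[(m/mu)^b] = sd^2."""
    c = b * (b - 1.0) / 2.0
    f = lambda v: mean * mean * v + a * mean**b * (1.0 + v) ** c - sd * sd
    if f(0.0) >= 0.0:
        return 0.0
    return brentq(f, 1e-12, 1e4)


def taylor_pool_spec(
    grand_mean: float,
    unit_sd: float,
    taylor_a: float,
    taylor_b: float,
    n_fields: int,
    seed: int = 0,
) -> HierarchySpec:
    """A field-heterogeneity-only spec matched to printed pool moments.

    All between-unit structure above the field is dropped: units within a
    field are i.i.d. with conditional variance ``a*m**b``, so per-field
    (mean, variance) pairs follow the power law exactly, and the marginal
    unit mean and SD match ``grand_mean`` and ``unit_sd``.
    """
    v_f = _solve_field_dispersion(grand_mean, unit_sd, taylor_a, taylor_b)
    v_tot = unit_sd**2
    share_field = grand_mean**2 * v_f / v_tot
    return HierarchySpec(
        n_states=1, districts_per_state=1, fields_per_district=n_fields,
        variance_shares={"field": share_field, "error": 1.0 - share_field},
        grand_mean=grand_mean, taylor_a=taylor_a, taylor_b=taylor_b,
        seed=seed, n_years=1, total_sd=unit_sd,
    )


def _taylor_refit_batch(mean, sd, a_gen, b_gen, n_groups, units, reps, rng):
    """Vectorized replicate refits of the power law from simulated groups.

    Returns arrays (a_hat, b_hat) of length ``reps``; groups with zero mean
    or zero variance are excluded from each log10-log10 OLS, mirroring
    :func:`lygusscout.sampling_plan.fit_taylor`.
    """
    v_f = _solve_field_dispersion(mean, sd, a_gen, b_gen)
    s2 = math.log1p(v_f)
    mf = mean * np.exp(rng.normal(-s2 / 2.0, math.sqrt(s2), (reps, n_groups)))
    var = a_gen * mf**b_gen
    over = var > mf
    excess = np.where(over, var - mf, 1.0)
    shape = np.where(over, mf**2 / excess, 1.0)
    scale = np.where(over, excess / mf, 1.0)
    # one gamma-Poisson mixture draw per unit so units are i.i.d. within groups
    lam_units = rng.gamma(shape[..., None], scale[..., None],
                          (reps, n_groups, units))
    lam_units = np.where(over[..., None], lam_units,
                         np.broadcast_to(mf[..., None], lam_units.shape))
    counts = rng.poisson(lam_units)
    mm = counts.mean(axis=2)
    vv = counts.var(axis=2, ddof=1)
    mask = (mm > 0) & (vv > 0)
    x = np.where(mask, np.log10(np.where(mask, mm, 1.0)), 0.0)
    y = np.where(mask, np.log10(np.where(mask, vv, 1.0)), 0.0)
    n = mask.sum(axis=1)
    sx, sy = x.sum(1), y.sum(1)
    sxx, sxy = (x * x).sum(1), (x * y).sum(1)
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    inter = (sy - slope * sx) / n
    return 10.0**inter, slope


@dataclass(frozen=True)
class CalibratedTaylor:
    """Generating power-law parameters whose refit is centred on a nominal pair.

    Group variances estimated from a handful of counts are noisy, and the
    log10-log10 regression of those estimates is biased low relative to the
    generating relation (Jensen's inequality on the log of a small-sample
    variance, plus exclusion of zero-variance groups at low means). The
    calibration inverts that map by Monte Carlo so that simulated datasets,
    refit with the study's estimator at the study's design, are centred on
    the nominal parameters.
    """

    a_nominal: float
    b_nominal: float
    a_gen: float
    b_gen: float
    refit_median_a: float
    refit_median_b: float


def calibrate_taylor_generator(
    grand_mean: float,
    unit_sd: float,
    taylor_a: float,
    taylor_b: float,
    n_groups: int,
    units_per_group: int,
    reps: int = 200,
    seed: int = 0,
) -> CalibratedTaylor:
    """Find generating (a, b) whose median refit equals the nominal pair.

    A damped fixed-point iteration updates the generating pair by the ratio
    of nominal to refitted medians (common random numbers across
    iterations), keeping b below 1.85 where the map saturates for
    low-density designs; the best point visited is returned.
    """
    def medians(a_g, b_g):
        rng = np.random.default_rng(seed)
        a_hat, b_hat = _taylor_refit_batch(
            grand_mean, unit_sd, a_g, b_g, n_groups, units_per_group, reps, rng)
        return float(np.median(a_hat)), float(np.median(b_hat))

    damp = 0.7
    a_g, b_g = taylor_a, max(taylor_b, 1.01)
    best = None
    for _ in range(15):
        ma, mb = medians(a_g, b_g)
        loss = (((ma - taylor_a) / taylor_a) ** 2
                + ((mb - taylor_b) / taylor_b) ** 2)
        if best is None or loss < best[0]:
            best = (loss, a_g, b_g, ma, mb)
        if loss < 1e-5:
            break
        fac_a = np.clip(taylor_a / ma, 0.5, 2.0) ** damp
        fac_b = np.clip((taylor_b - 1.0) / max(mb - 1.0, 1e-3), 0.25, 4.0) ** damp
        a_g = float(np.clip(a_g * fac_a, 1e-3, 1e3))
        b_g = float(np.clip(1.0 + (b_g - 1.0) * fac_b, 1.01, 1.85))
    _, a_g, b_g, ma, mb = best
    return CalibratedTaylor(taylor_a, taylor_b, a_g, b_g, ma, mb)


def negative_binomial_pool(mean: float, sd: float, n: int,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """A pool of i.i.d. counts with the requested mean and SD.

    Negative binomial (gamma-Poisson) when sd**2 > mean, else Poisson. Used
    to rebuild the validation pools behind the resampling analysis from
    their printed moments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    var = sd * sd
    if var <= mean:
        return rng.poisson(mean, n)
    excess = var - mean
    lam = rng.gamma(mean * mean / excess, excess / mean, n)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# square retention
# ---------------------------------------------------------------------------

def generate_retention(
    records,
    beta0: float,
    beta1: float,
    re_sd_field: float = 0.0,
    re_sd_quadrant: float = 0.0,
    positions_checked: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate retained-square counts paired to quadrant insect densities.

    One retention record per (field, quadrant, growth stage) present in
    ``records``; the paired density is the mean count per sampling unit in
    that quadrant. Retained counts are Poisson with log-mean
    ``beta0 + beta1 * density`` plus nested random intercepts (quadrant
    within field), truncated at ``positions_checked``.
    """
    units = units_to_frame(records)
    if units.empty:
        raise ValueError("records must be non-empty")
    grouped = (units.groupby(["field_id", "quadrant", "growth_stage"], sort=True)
               ["total"].mean().reset_index(name="density"))
    rng = np.random.default_rng(seed)
    fields = grouped["field_id"].unique()
    b_field = dict(zip(fields, rng.normal(0.0, re_sd_field, len(fields))
                       if re_sd_field > 0 else np.zeros(len(fields))))
    b_quad = rng.normal(0.0, re_sd_quadrant, len(grouped)) \
        if re_sd_quadrant > 0 else np.zeros(len(grouped))
    eta = (beta0 + beta1 * grouped["density"].to_numpy()
           + grouped["field_id"].map(b_field).to_numpy() + b_quad)
    retained = np.minimum(rng.poisson(np.exp(eta)), positions_checked)
    out = grouped.assign(positions_checked=positions_checked, retained=retained)
    return out[list(RETENTION_COLUMNS)]


# ---------------------------------------------------------------------------
# landscape covariates and the spatial dataset
# ---------------------------------------------------------------------------

#: Mean composition of the 0.5 km buffers (southeastern USA row-crop mosaic).
#: ``other_agriculture`` collects cultivated cover outside the named classes
#: (pasture, small grains other than wheat, vegetables); ``other`` is
#: non-agricultural, non-forest cover (water, developed land).
BUFFER_COMPOSITION = {
    "corn": 0.08, "cotton": 0.20, "peanuts": 0.04, "soybeans": 0.12,
    "doublecrop_wheat_soy": 0.03, "wheat": 0.02, "other_agriculture": 0.12,
    "forest": 0.30, "other": 0.09,
}

#: Landscape coefficients used as generating truth (log-count per unit
#: proportion), matching the study region's fitted landscape model; wheat is
#: excluded from fitting by default and carries no generating effect.
DEFAULT_LANDSCAPE_EFFECTS = {
    "agriculture": 5.32, "corn": -2.12, "cotton": -2.28, "forest": 0.74,
    "soybeans": -1.47, "doublecrop_wheat_soy": 10.9,
}

DEFAULT_ALPHA0 = -1.08


def generate_landscape_dataset(
    n_fields: int,
    effects: dict | None = None,
    spatial_params: dict | None = None,
    stage_sd: float = 0.3,
    offset_range: tuple[int, int] = (2, 4),
    seed: int = 0,
    alpha0: float = DEFAULT_ALPHA0,
    window_km: float = 100.0,
    dirichlet_concentration: float = 8.0,
    visits_per_field: int = 2,
) -> tuple[pd.DataFrame, SpatialDataset]:
    """Simulate field locations, buffer compositions and adult counts.

    Buffer compositions are Dirichlet draws over a 9-class land-cover split
    (``agriculture`` is the sum of the cultivated classes plus an unnamed
    residual cultivated class, so it is never perfectly collinear with the
    named subclasses). Counts follow the hierarchical spatial Poisson model:
    ``log mu = alpha0 + log q + X beta + W(s) + u_stage`` with W a
    Matern(nu=1) Gaussian random field over planar km coordinates. The
    generating truth is stored on the returned dataset for recovery tests.
    """
    if n_fields < 10:
        raise ValueError("n_fields must be >= 10")
    effects = DEFAULT_LANDSCAPE_EFFECTS if effects is None else effects
    spatial_params = {"sigma2": 0.5, "range_km": 30.0} if spatial_params is None \
        else spatial_params
    sigma2 = float(spatial_params["sigma2"])
    range_km = float(spatial_params["range_km"])
    if sigma2 < 0 or range_km <= 0:
        raise ValueError("sigma2 must be >= 0 and range_km > 0")
    unknown = set(effects) - set(LANDSCAPE_CLASSES)
    if unknown:
        raise ValueError(f"unknown effect classes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, window_km, (n_fields, 2))

    names = list(BUFFER_COMPOSITION)
    alpha = dirichlet_concentration * np.array([BUFFER_COMPOSITION[k] for k in names])
    comp = rng.dirichlet(alpha, n_fields)
    comp_df = pd.DataFrame(comp, columns=names)
    landscape = pd.DataFrame({
        "field_id": [f"F{i + 1:03d}" for i in range(n_fields)],
        "x_km": coords[:, 0], "y_km": coords[:, 1],
    })
    landscape["agriculture"] = comp_df[
        list(CULTIVATED_CLASSES) + ["other_agriculture"]].sum(axis=1).clip(0, 1)
    for cls in LANDSCAPE_CLASSES:
        if cls != "agriculture":
            landscape[cls] = comp_df[cls].clip(0, 1)

    from .spatial import matern_cov  # local import: spatial does not import us

    if sigma2 > 0:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        cov = matern_cov(d, sigma2, range_km) + 1e-10 * sigma2 * np.eye(n_fields)
        w = np.linalg.cholesky(cov) @ rng.standard_normal(n_fields)
    else:
        w = np.zeros(n_fields)

    stages = ("squaring", "bloom")[:visits_per_field]
    u = rng.normal(0.0, stage_sd, len(stages)) if stage_sd > 0 else np.zeros(len(stages))

    n_rows = n_fields * len(stages)
    row_field = np.repeat(np.arange(n_fields), len(stages))
    row_stage = np.tile(np.arange(len(stages)), n_fields)
    q = rng.integers(offset_range[0], offset_range[1] + 1, n_rows)

    x_cols = [c for c in LANDSCAPE_CLASSES]
    x = landscape[x_cols].to_numpy(float)[row_field]
    beta = np.array([effects.get(c, 0.0) for c in x_cols])
    eta = alpha0 + np.log(q) + x @ beta + w[row_field] + u[row_stage]
    y = rng.poisson(np.exp(eta))

    dataset = SpatialDataset(
        field_id=landscape["field_id"].to_numpy()[row_field],
        coords_km=coords[row_field],
        covariates=pd.DataFrame(x, columns=x_cols),
        q=q,
        growth_stage=np.array(stages)[row_stage],
        y=y,
        truth={
            "alpha0": alpha0, "beta": dict(zip(x_cols, beta)),
            "W": w, "u": dict(zip(stages, u)), "sigma2": sigma2,
            "range_km": range_km, "stage_sd": stage_sd,
        },
    )
    return landscape, dataset


def raster_buffer_proportions(
    raster: np.ndarray,
    cell_size_m: float,
    center: tuple[float, float],
    buffer_m: float,
    class_names: dict | None = None,
) -> dict:
    """Class proportions inside a circular buffer on a categorical raster.

    A toy stand-in for GIS buffer extraction on crop land-cover rasters:
    cells whose centres fall within Euclidean distance ``buffer_m`` of
    ``center`` (coordinates in metres from the raster's lower-left corner)
    are tallied by class. If the buffer is narrower than half a cell, the
    cell containing the centre is used. Proportions sum to 1 over the
    classes observed in the buffer.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError("raster must be a 2-D integer grid")
    n_rows, n_cols = raster.shape
    cx, cy = center
    extent_x, extent_y = n_cols * cell_size_m, n_rows * cell_size_m
    if (cx - buffer_m < 0 or cy - buffer_m < 0
            or cx + buffer_m > extent_x or cy + buffer_m > extent_y):
        raise ValueError("buffer extends outside the raster extent")
    xs = (np.arange(n_cols) + 0.5) * cell_size_m
    ys = (np.arange(n_rows) + 0.5) * cell_size_m
    dist2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    mask = dist2 <= buffer_m**2
    if not mask.any():
        row = min(int(cy // cell_size_m), n_rows - 1)
        col = min(int(cx // cell_size_m), n_cols - 1)
        mask = np.zeros_like(raster, bool)
        mask[row, col] = True
    values, counts = np.unique(raster[mask], return_counts=True)
    total = counts.sum()
    out = {}
    for val, cnt in zip(values, counts):
        key = class_names[val] if class_names else int(val)
        out[key] = cnt / total
    return out
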