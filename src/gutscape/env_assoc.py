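"""Environmental screening and association.

Covers the six-covariate workflow (latitude, elevation, annual mean
temperature, annual precipitation, population density, human footprint):
VIF collinearity screening (threshold 10), marginal adonis-style screens of
each covariate against a community distance matrix, GLM fits of alpha
diversity on single covariates, great-circle distance–decay regression with
Mantel-style permutation inference, classical CCA with a permutation ANOVA,
and envfit-style vector fitting onto ordination scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .data_model import ENV_COLUMNS, FeatureTable

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
VIF_THRESHOLD = 10.0


def env_table(metadata: pd.DataFrame,
              columns: tuple[str, ...] = ENV_COLUMNS) -> pd.DataFrame:
    """Extract the environmental covariates; errors on missing values."""
    missing = [c for c in columns if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks covariates: {missing}")
    env = metadata.loc[:, list(columns)].astype(float)
    if env.isna().any().any():
        raise ValueError("missing values in environmental covariates")
    return env


def standardize(env: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (reversible given the original mean/sd)."""
    sd = env.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant covariates: {list(sd.index[sd == 0])}")
    return (env - env.mean()) / sd


def vif_screen(env: pd.DataFrame, threshold: float = VIF_THRESHOLD) -> pd.DataFrame:
    """Variance inflation factor per covariate: VIF_j = 1/(1 − R²_j).

    Perfectly collinear covariates report VIF = +inf (flagged, not an error).
    """
    n, p = env.shape
    if n <= p:
        raise ValueError("need more samples than covariates for VIF")
    x = env.to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(env.columns):
        others = sm.add_constant(np.delete(x, j, axis=1))
        r2 = sm.OLS(x[:, j], others).fit().rsquared
        vif = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"variable": name, "vif": float(vif),
                     "pass": bool(vif < threshold)})
    return pd.DataFrame(rows).set_index("variable")


def _gower_center(dm: DistanceMatrix) -> np.ndarray:
    a = -0.5 * dm.data**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _permutation_matrix(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def marginal_adonis_screen(dm: DistanceMatrix, env: pd.DataFrame,
                           n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Single-covariate PERMANOVA-style screen of each covariate.

    Uses the distance-based linear-model decomposition: for a centred
    covariate x, SS_model = xᵀGx / xᵀx with G the Gower-centred matrix;
    p-values come from permuting the covariate, with the +1 correction.
    Raw and Benjamini–Hochberg-adjusted p are both reported.
    """
    env = env.loc[list(dm.ids)]
    g = _gower_center(dm)
    ss_total = float(np.trace(g))
    n = g.shape[0]
    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(rng, n, n_perm)
    rows = []
    for name in env.columns:
        x = env[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant covariate {name!r}")
        x = x - x.mean()
        ss_model = float(x @ g @ x) / float(x @ x)
        r2 = ss_model / ss_total
        f_obs = ss_model / ((ss_total - ss_model) / (n - 2))
        xp = x[perms]  # (n_perm, n)
        ss_p = np.einsum("pi,ij,pj->p", xp, g, xp) / float(x @ x)
        f_p = ss_p / ((ss_total - ss_p) / (n - 2))
        p = (1 + int((f_p >= f_obs).sum())) / (1 + n_perm)
        rows.append({"variable": name, "R2": r2, "pseudo_F": f_obs, "p": p})
    out = pd.DataFrame(rows).set_index("variable")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class GlmFit:
    """Single-covariate GLM of an alpha-diversity index."""

    family: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    deviance: float
    fitted_x: np.ndarray
    fitted_y: np.ndarray

    @property
    def slope(self) -> float:
        return float(self.params.iloc[1])

    @property
    def slope_p(self) -> float:
        return float(self.pvalues.iloc[1])


def glm_alpha(alpha, covariate, family: str = "poisson") -> GlmFit:
    """Fit alpha ~ covariate by GLM.

    Poisson with log link (alpha values rounded to integers for the
    likelihood) suits count-like indices such as chao1; Gaussian with
    identity link suits continuous indices such as Faith's PD.
    """
    y = np.asarray(alpha, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    if family == "poisson":
        y = np.round(y)
        fam = sm.families.Poisson()
    elif family == "gaussian":
        fam = sm.families.Gaussian()
    else:
        raise ValueError(f"unsupported family {family!r}")
    exog = sm.add_constant(x)
    res = sm.GLM(y, exog, family=fam).fit()
    if not res.converged:
        raise RuntimeError("GLM did not converge")
    grid = np.linspace(x.min(), x.max(), 100)
    curve = res.predict(sm.add_constant(grid))
    names = ["intercept", "slope"]
    return GlmFit(family,
                  pd.Series(res.params, index=names),
                  pd.Series(res.bse, index=names),
                  pd.Series(res.pvalues, index=names),
                  float(res.deviance), grid, np.asarray(curve))


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in kilometres (Earth radius 6,371 km)."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(metadata: pd.DataFrame) -> DistanceMatrix:
    lat = metadata["latitude"].to_numpy(dtype=float)
    lon = metadata["longitude"].to_numpy(dtype=float)
    n = len(lat)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(out, ids=[str(i) for i in metadata.index])


def ddr_fit(dm: DistanceMatrix, metadata: pd.DataFrame, n_perm: int = 999,
            seed: int = 0) -> dict:
    """Distance–decay regression of community similarity on geography.

    OLS of pairwise Bray–Curtis similarity (1 − dissimilarity) on pairwise
    great-circle distance supplies slope/intercept/r; significance comes from
    a Mantel-style permutation of sample identities because pairwise points
    are not independent.
    """
    meta = metadata.loc[list(dm.ids)]
    if meta[["latitude", "longitude"]].drop_duplicates().shape[0] < 3:
        raise ValueError("need at least three distinct locations")
    geo = geographic_distance_matrix(meta)
    iu = np.triu_indices(len(dm.ids), k=1)
    sim = 1.0 - dm.data[iu]
    dist = geo.data[iu]
    if np.ptp(dist) == 0:
        raise ValueError("all samples co-located")
    slope, intercept = np.polyfit(dist, sim, 1)
    r_obs = float(np.corrcoef(dist, sim)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    n = len(dm.ids)
    simmat = 1.0 - dm.data
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = np.corrcoef(dist, simmat[np.ix_(perm, perm)][iu])[0, 1]
        if abs(r_p) >= abs(r_obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"slope": float(slope), "intercept": float(intercept),
            "r": r_obs, "p": float(p), "n_pairs": len(sim)}


@dataclass
class CCAResult:
    """Classical (chi-square) canonical correspondence analysis."""

    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame  # covariate arrows on the constrained axes
    constrained_inertia: float
    total_inertia: float
    # internals reused by the permutation test
    _qbar: np.ndarray
    _xw: np.ndarray
    _row_weights: np.ndarray


def cca(table: FeatureTable, env: pd.DataFrame) -> CCAResult:
    """Constrained correspondence analysis of counts on standardized env.

    The abundance matrix is chi-square standardized
    (q̄_ij = (p_ij − r_i c_j)/√(r_i c_j)); the weighted multivariate
    regression of q̄ on the covariates is eigen-decomposed. Total inertia
    equals the chi-square statistic of the table divided by its grand total;
    constrained inertia is the part captured by the covariates.
    """
    y = table.counts.T.astype(float)  # samples × taxa
    if (y.sum(axis=1) == 0).any() or (y.sum(axis=0) == 0).any():
        raise ValueError("zero-sum rows/columns not allowed in CCA")
    n, t = y.shape
    x = standardize(env.loc[table.sample_ids]).to_numpy(dtype=float)
    q = x.shape[1]
    if q >= n:
        raise ValueError("more constraints than samples")
    tot = y.sum()
    p = y / tot
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    qbar = (p - expected) / np.sqrt(expected)
    total_inertia = float((qbar**2).sum())
    # weighted regression: rows weighted by sqrt(r)
    xw = np.sqrt(r)[:, None] * (x - r @ x)  # center with row weights
    beta, *_ = np.linalg.lstsq(xw, qbar, rcond=None)
    fitted = xw @ beta
    u_svd, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int((s > 1e-10).sum())
    u_svd, s, vt = u_svd[:, :rank], s[:rank], vt[:rank]
    eig = s**2
    constrained = float(eig.sum())
    axes = [f"CCA{i + 1}" for i in range(rank)]
    # site scores (weighted averages convention, scaled by singular values)
    site = (u_svd / np.sqrt(r)[:, None]) * s
    species = vt.T / np.sqrt(c)[:, None]
    biplot = np.corrcoef(xw.T, u_svd.T)[:q, q:]
    return CCAResult(
        eigenvalues=eig,
        site_scores=pd.DataFrame(site, index=table.sample_ids, columns=axes),
        species_scores=pd.DataFrame(species, index=table.taxon_ids, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=list(env.columns), columns=axes),
        constrained_inertia=constrained,
        total_inertia=total_inertia,
        _qbar=qbar,
        _xw=xw,
        _row_weights=r,
    )


def cca_permutation_test(result: CCAResult, n_perm: int = 999,
                         seed: int = 0) -> dict:
    """Permutation ANOVA of the CCA: permute sample rows of the covariates,
    recompute the constrained-inertia pseudo-F, p with the +1 correction."""
    qbar = result._qbar
    xw = result._xw
    n, q = xw.shape
    resid_df = n - q - 1
    f_obs = (result.constrained_inertia / q) / (
        (result.total_inertia - result.constrained_inertia) / resid_df)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = xw[rng.permutation(n)]
        beta, *_ = np.linalg.lstsq(xp, qbar, rcond=None)
        ci = float(((xp @ beta) ** 2).sum())
        f_p = (ci / q) / ((result.total_inertia - ci) / resid_df)
        if f_p >= f_obs:
            count += 1
    return {"pseudo_F": float(f_obs), "p": (1 + count) / (1 + n_perm),
            "n_perm": n_perm}


def envfit(scores: pd.DataFrame, env: pd.DataFrame, n_perm: int = 999,
           seed: int = 0) -> pd.DataFrame:
    """Fit each covariate onto ordination axes (vegan envfit convention).

    r² is the fraction of the covariate's variance explained by a linear
    fit on the axis scores; the arrow is the unit direction of the fit;
    p comes from permuting the covariate values.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least two ordination axes")
    env = env.loc[scores.index]
    a = scores.to_numpy(dtype=float)
    a = a - a.mean(axis=0)
    # hat matrix of the axes (fixed across covariates and permutations)
    hat = a @ np.linalg.pinv(a.T @ a) @ a.T
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    perms = _permutation_matrix(rng, n, n_perm)
    rows = []
    for name in env.columns:
        v = env[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"constant covariate {name!r}")
        v = v - v.mean()
        ss_tot = float(v @ v)
        r2 = float(v @ hat @ v) / ss_tot
        coef, *_ = np.linalg.lstsq(a, v, rcond=None)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        vp = v[perms]
        r2_p = np.einsum("pi,ij,pj->p", vp, hat, vp) / ss_tot
        p = (1 + int((r2_p >= r2).sum())) / (1 + n_perm)
        row = {"variable": name, "r2": r2, "p": p}
        for k, ax in enumerate(scores.columns):
            row[f"dir_{ax}"] = float(direction[k])
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
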