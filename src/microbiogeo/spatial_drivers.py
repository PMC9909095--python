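"""Environmental-vs-spatial driver analyses.

Great-circle geographic distances, distance-decay of community similarity,
Mantel tests, one-factor PERMANOVA, PCNM spatial eigenfunctions, RDA on
Hellinger-transformed abundances, Spearman order-environment correlations,
and variation partitioning into pure environmental [a], shared [b], pure
spatial [c] and unexplained [d] adjusted-R2 fractions.

Permutation tests use seeded generators and enumerate all row/column
permutations exhaustively when the sample count is small enough, so small
cases are exact rather than Monte-Carlo.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .core_io import AbundanceTable, ParameterError, SampleFrame

logger = logging.getLogger("microbiogeo")

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str
    exhaustive: bool


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    ss_among: float
    ss_within: float
    ss_total: float


@dataclass(frozen=True)
class VpaResult:
    """Adjusted-R2 variation-partitioning fractions.

    [a] pure environment, [b] shared, [c] pure space, [d] unexplained;
    small negative adjusted fractions are reported as computed (flagged),
    never clipped.
    """

    a: float
    b: float
    c: float
    d: float
    env_total: float
    spat_total: float
    joint_total: float

    @property
    def has_negative(self) -> bool:
        return min(self.a, self.b, self.c) < 0

    def as_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two WGS-84 points, spherical Earth."""
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = phi2 - phi1
    dlmb = np.deg2rad(lon2) - np.deg2rad(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def haversine_matrix(frame: SampleFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between the samples' coordinates."""
    coords = frame.coordinates().to_numpy()
    lat = np.deg2rad(coords[:, 0])[:, None]
    lon = np.deg2rad(coords[:, 1])[:, None]
    dphi = lat - lat.T
    dlmb = lon - lon.T
    h = np.sin(dphi / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=frame.samples)


# ---------------------------------------------------------------------------
# Mantel and distance-decay
# ---------------------------------------------------------------------------


def _aligned_square(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(d1.ids) != set(d2.ids):
        raise ParameterError("distance matrices have different sample sets")
    order = list(d1.ids)
    m2 = pd.DataFrame(d2.data, index=d2.ids, columns=d2.ids).loc[order, order].to_numpy()
    return np.asarray(d1.data, dtype=float), m2


def _mantel_stat(x: np.ndarray, y_tri: np.ndarray, method: str, iu) -> float:
    xt = x[iu]
    if method == "spearman":
        xt = scipy.stats.rankdata(xt)
    r = np.corrcoef(xt, y_tri)[0, 1]
    return float(r)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    nperm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two distance matrices.

    The statistic is the Pearson or Spearman correlation of the lower
    triangles; significance comes from simultaneous row/column permutations
    of the first matrix. When n! <= nperm all n! permutations are enumerated
    and the p-value is exact (#{perm stat >= observed} / n!, the identity
    included); otherwise ``nperm`` random permutations are drawn and
    p = (1 + #{perm >= obs}) / (1 + nperm). One-sided "greater" by default.
    """
    if method not in ("spearman", "pearson"):
        raise ParameterError("method must be spearman or pearson")
    x, y = _aligned_square(d1, d2)
    n = x.shape[0]
    if n < 4:
        raise ParameterError("Mantel needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    y_tri = y[iu]
    if method == "spearman":
        y_tri = scipy.stats.rankdata(y_tri)
    if np.std(x[iu]) == 0 or np.std(y_tri) == 0:
        raise ParameterError("constant distance matrix; Mantel undefined")

    obs = _mantel_stat(x, y_tri, method, iu)

    def _one_sided(stat: float) -> bool:
        if alternative == "greater":
            return stat >= obs - 1e-12
        if alternative == "less":
            return stat <= obs + 1e-12
        return abs(stat) >= abs(obs) - 1e-12

    exhaustive = math.factorial(n) <= nperm
    if exhaustive:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            stat = _mantel_stat(x[np.ix_(p, p)], y_tri, method, iu)
            total += 1
            if _one_sided(stat):
                hits += 1
        return MantelResult(obs, hits / total, total, method, True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        p = rng.permutation(n)
        stat = _mantel_stat(x[np.ix_(p, p)], y_tri, method, iu)
        if _one_sided(stat):
            hits += 1
    p_value = (1 + hits) / (1 + nperm)
    return MantelResult(obs, p_value, nperm, method, False)


def distance_decay(
    community_d: DistanceMatrix,
    geo_d: DistanceMatrix,
    nperm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Distance-decay: Spearman correlation of community dissimilarity with
    geographic distance, Mantel-permutation p (pairs are non-independent)."""
    return mantel(community_d, geo_d, method="spearman", nperm=nperm, seed=seed)


# ---------------------------------------------------------------------------
# PERMANOVA (one factor)
# ---------------------------------------------------------------------------


def permanova(
    d: DistanceMatrix,
    groups: pd.Series,
    nperm: int = 999,
    seed: int = 0,
    strata: pd.Series | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = sum of squared distances over all pairs / N; SS_within sums
    the per-group squared distances divided by group size; pseudo-F =
    (SS_among/(k-1)) / (SS_within/(N-k)). p-value by permutation of the
    group labels, p = (1 + #{F_perm >= F}) / (1 + nperm).

    ``strata`` optionally restricts permutations to shuffle labels only
    within each stratum block — the appropriate null when a second,
    crossed factor structures the distances (free permutation is badly
    conservative for the orthogonal factor of a balanced design).
    """
    labels = groups.reindex(list(d.ids))
    if labels.isna().any():
        raise ParameterError("groups must cover all samples in the matrix")
    codes, uniques = pd.factorize(labels.to_numpy())
    k = len(uniques)
    n = len(codes)
    blocks: list[np.ndarray] | None = None
    if strata is not None:
        strata_labels = strata.reindex(list(d.ids))
        if strata_labels.isna().any():
            raise ParameterError("strata must cover all samples in the matrix")
        blocks = [
            np.flatnonzero(strata_labels.to_numpy() == s)
            for s in pd.unique(strata_labels.to_numpy())
        ]
    if k < 2:
        raise ParameterError("PERMANOVA needs at least 2 groups")
    d2 = np.asarray(d.data, dtype=float) ** 2

    def ss_within(c: np.ndarray) -> float:
        total = 0.0
        for g in range(k):
            members = np.flatnonzero(c == g)
            if members.size > 1:
                sub = d2[np.ix_(members, members)]
                total += sub.sum() / (2.0 * members.size)
        return total

    ss_total = d2.sum() / (2.0 * n)
    sw = ss_within(codes)
    sa = ss_total - sw
    df_among, df_within = k - 1, n - k
    if df_within <= 0:
        raise ParameterError("no within-group degrees of freedom")
    f_obs = (sa / df_among) / (sw / df_within) if sw > 0 else np.inf
    r2 = sa / ss_total if ss_total > 0 else np.nan

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        if blocks is None:
            perm_codes = codes[rng.permutation(n)]
        else:
            perm_codes = codes.copy()
            for block in blocks:
                perm_codes[block] = codes[rng.permutation(block)]
        sw_p = ss_within(perm_codes)
        sa_p = ss_total - sw_p
        f_p = (sa_p / df_among) / (sw_p / df_within) if sw_p > 0 else np.inf
        if f_p >= f_obs - 1e-12:
            hits += 1
    p_value = (1 + hits) / (1 + nperm)
    return PermanovaResult(float(f_obs), float(r2), p_value, nperm, float(sa), float(sw), float(ss_total))


# ---------------------------------------------------------------------------
# PCNM spatial eigenfunctions
# ---------------------------------------------------------------------------


def pcnm(geo_d: DistanceMatrix, n_keep: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """PCNM (dbMEM) spatial eigenfunctions from a geographic distance matrix.

    Distances above the truncation threshold t — the longest edge of the
    minimum spanning tree — are replaced by 4t; the truncated matrix is
    double-centred (-D^2/2) and eigendecomposed. Eigenvectors with positive
    eigenvalues, ordered by decreasing eigenvalue, are returned as unit
    vectors (optionally only the first ``n_keep``), along with the positive
    eigenvalues.
    """
    D = np.asarray(geo_d.data, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ParameterError("PCNM needs at least 3 samples")
    off = D[np.triu_indices(n, k=1)]
    if np.all(off == 0):
        raise ParameterError("all points coincident; PCNM undefined")
    mst = minimum_spanning_tree(D).toarray()
    t = mst[mst > 0].max()
    Dt = np.where(D > t, 4.0 * t, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    B = A - row - col + A.mean()
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(np.abs(eigval)) * 1e-10
    positive = eigval > tol
    eigval, eigvec = eigval[positive], eigvec[:, positive]
    if n_keep is not None:
        eigval, eigvec = eigval[:n_keep], eigvec[:, :n_keep]
    cols = [f"PCNM{i + 1}" for i in range(eigvec.shape[1])]
    return pd.DataFrame(eigvec, index=list(geo_d.ids), columns=cols), eigval


# ---------------------------------------------------------------------------
# RDA and variation partitioning
# ---------------------------------------------------------------------------


def _standardise(X: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance columns; constant columns dropped with warning."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping constant predictor(s): %s", list(X.columns[constant]))
        X = X.loc[:, ~constant]
        mu, sd = mu[~constant], sd[~constant]
    return (X - mu) / sd


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that do not increase matrix rank."""
    kept_idx: list[int] = []
    for j in range(X.shape[1]):
        candidate = X[:, kept_idx + [j]]
        if np.linalg.matrix_rank(candidate) > len(kept_idx):
            kept_idx.append(j)
        else:
            logger.warning("dropping collinear predictor %r", names[j])
    return X[:, kept_idx], [names[j] for j in kept_idx]


def rda(response: AbundanceTable | pd.DataFrame, predictors: pd.DataFrame) -> dict:
    """Redundancy analysis of a (Hellinger-transformed) community table.

    Least-squares projection of the centred response (samples x taxa) onto
    the standardised predictors. Returns raw R2, Ezekiel-adjusted R2
    (NaN-flagged when n <= p + 1), and each predictor's marginal adjusted R2
    from its single-variable model.
    """
    Y = response.data.T if isinstance(response, AbundanceTable) else response
    Y = Y.astype(float)
    X = predictors.reindex(Y.index)
    if X.isna().any().any():
        raise ParameterError("predictors do not cover all samples")
    Xs = _standardise(X)
    Xm, names = _drop_collinear(Xs.to_numpy(), list(Xs.columns))
    Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0, keepdims=True)
    ss_total = (Yc**2).sum()
    if ss_total == 0:
        raise ParameterError("response has no variance")

    def fit_r2(Xcols: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(Xcols, Yc, rcond=None)
        fitted = Xcols @ beta
        return float((fitted**2).sum() / ss_total)

    n, p = Yc.shape[0], Xm.shape[1]
    r2 = fit_r2(Xm)
    if n > p + 1:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        logger.warning("n <= p + 1: adjusted R2 undefined")
        adj = float("nan")
    marginal = {}
    for j, name in enumerate(names):
        r2_j = fit_r2(Xm[:, [j]])
        marginal[name] = (
            1.0 - (1.0 - r2_j) * (n - 1) / (n - 2) if n > 2 else float("nan")
        )
    return {
        "r2": r2,
        "adj_r2": adj,
        "marginal_adj_r2": marginal,
        "predictors": names,
        "n": n,
        "p": p,
    }


def variation_partitioning(
    response: AbundanceTable | pd.DataFrame,
    env: pd.DataFrame,
    spat: pd.DataFrame,
) -> VpaResult:
    """Partition community variation between environment and space.

    [a+b] = adjR2(Y ~ env), [b+c] = adjR2(Y ~ spat), [a+b+c] = adjR2(Y ~ both);
    [a] = [a+b+c] - [b+c], [c] = [a+b+c] - [a+b], [b] by inclusion-exclusion,
    [d] = 1 - [a+b+c]. Fractions sum to 1 by construction.
    """
    env = env.copy()
    spat = spat.copy()
    ab = rda(response, env)["adj_r2"]
    bc = rda(response, spat)["adj_r2"]
    joint_X = pd.concat([env, spat], axis=1)
    abc = rda(response, joint_X)["adj_r2"]
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    d = 1.0 - abc
    result = VpaResult(a=a, b=b, c=c, d=d, env_total=ab, spat_total=bc, joint_total=abc)
    if result.has_negative:
        logger.warning("negative adjusted fraction(s) in variation partitioning: %s", result.as_dict())
    return result


# ---------------------------------------------------------------------------
# Order-environment correlations
# ---------------------------------------------------------------------------


def env_taxon_correlations(
    orders: AbundanceTable,
    frame: SampleFrame,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman rho/p between each order's abundance and each factor.

    Factors default to the seven environmental variables plus longitude and
    latitude. Constant factors are flagged with NaN. Significance stars:
    * p<0.05, ** p<0.01, *** p<0.001.
    """
    factors = factors or list(frame.environment().columns) + ["longitude", "latitude"]
    samples = orders.samples
    meta = frame.data.loc[samples, factors].astype(float)
    rho, p = _spearman_cross(orders.data, meta.T)
    rows = []
    for order in orders.data.index:
        for factor in factors:
            r_val, p_val = rho.loc[order, factor], p.loc[order, factor]
            stars = ""
            if np.isfinite(p_val):
                for cut, sym in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
                    if p_val < cut:
                        stars = sym
                        break
            rows.append(
                {"order": order, "factor": factor, "rho": r_val, "p": p_val, "significance": stars}
            )
    return pd.DataFrame(rows)


def _spearman_cross(block_a: pd.DataFrame, block_b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-block Spearman via the shared all-pairs routine.

    Rows are shifted to be nonnegative (rank-invariant) so environmental
    variables can share the abundance-table code path.
    """
    from .cooccurrence import spearman_matrix

    stacked = pd.concat([block_a, block_b], axis=0)
    shifted = stacked.sub(stacked.min(axis=1).clip(upper=0.0), axis=0)
    rho, p = spearman_matrix(AbundanceTable(shifted, kind="raw"))
    return (
        rho.loc[block_a.index, block_b.index],
        p.loc[block_a.index, block_b.index],
    )
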