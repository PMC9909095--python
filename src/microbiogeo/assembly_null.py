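"""Three-step community-assembly framework: betaMNTD, betaNTI, RC-bray.

For each sample pair the observed between-community mean nearest taxon
distance (betaMNTD) is standardised against a null built by shuffling taxon
labels across the tips of the regional phylogeny, giving the beta nearest
taxon index betaNTI = (obs - mean_null) / sd_null. |betaNTI| > 2 indicates
selection (positive: heterogeneous, negative: homogeneous). Pairs inside the
+/-2 band are passed to the Bray-Curtis Raup-Crick metric, whose null
assembles both communities probabilistically from the regional pool (taxa by
occupancy frequency, reads by regional relative abundance, at the observed
richness and depth); RC > +0.95 indicates dispersal limitation, RC < -0.95
homogenizing dispersal, and the middle band drift. Per-stratum fractions of
the five processes summarise their relative importance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import CountTable, ParameterError, cophenetic_matrix, require_tip_coverage

logger = logging.getLogger("microbiogeo")

PROCESSES: tuple[str, ...] = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------


def _directional_mean(dist: np.ndarray, weights: np.ndarray) -> float:
    """Mean of per-taxon nearest-neighbour distances, abundance weighted."""
    return float(weights @ dist)


def bmntd(
    a: pd.Series, b: pd.Series, tree: TreeNode, weighted: bool = True
) -> float:
    """Between-community mean nearest taxon distance for one sample pair.

    ``a`` and ``b`` are abundance vectors indexed by taxon. For every taxon
    present in one community the minimum cophenetic distance to any taxon of
    the other community is taken (zero if shared); the two directional means
    — abundance-weighted within the source community by default — are
    averaged with weight 1/2.
    """
    ia = a[a > 0]
    ib = b[b > 0]
    if ia.empty or ib.empty:
        raise ParameterError("betaMNTD requires both samples non-empty")
    taxa = sorted(set(ia.index) | set(ib.index))
    D = cophenetic_matrix(tree, taxa).to_numpy()
    pos = {t: i for i, t in enumerate(taxa)}
    idx_a = np.array([pos[t] for t in ia.index])
    idx_b = np.array([pos[t] for t in ib.index])
    min_ab = D[np.ix_(idx_a, idx_b)].min(axis=1)
    min_ba = D[np.ix_(idx_b, idx_a)].min(axis=1)
    if weighted:
        wa = ia.to_numpy(dtype=float)
        wb = ib.to_numpy(dtype=float)
        wa, wb = wa / wa.sum(), wb / wb.sum()
    else:
        wa = np.full(idx_a.size, 1.0 / idx_a.size)
        wb = np.full(idx_b.size, 1.0 / idx_b.size)
    return 0.5 * (_directional_mean(min_ab, wa) + _directional_mean(min_ba, wb))


def _presence_and_weights(
    table: CountTable, weighted: bool
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    counts = table.data.to_numpy(dtype=float)
    idx, wts = [], []
    for j in range(counts.shape[1]):
        present = np.flatnonzero(counts[:, j] > 0)
        if present.size == 0:
            raise ParameterError(f"sample {table.samples[j]} has no taxa")
        if weighted:
            w = counts[present, j]
            w = w / w.sum()
        else:
            w = np.full(present.size, 1.0 / present.size)
        idx.append(present)
        wts.append(w)
    return idx, wts


def _bmntd_square(
    D: np.ndarray, idx: list[np.ndarray], wts: list[np.ndarray]
) -> np.ndarray:
    """All-pairs betaMNTD given a (possibly label-permuted) distance matrix.

    For each sample the vector of nearest-member distances from every taxon
    to that sample's members is precomputed once, making the null loop
    O(nulls * samples * taxa * richness) instead of per-pair submatrix work.
    """
    n = len(idx)
    minvec = [D[:, j_idx].min(axis=1) for j_idx in idx]
    out = np.zeros((n, n))
    for a in range(n):
        ia, wa = idx[a], wts[a]
        for b in range(a + 1, n):
            ib, wb = idx[b], wts[b]
            val = 0.5 * (wa @ minvec[b][ia] + wb @ minvec[a][ib])
            out[a, b] = out[b, a] = val
    return out


def bmntd_matrix(
    table: CountTable, tree: TreeNode, weighted: bool = True
) -> pd.DataFrame:
    """Observed betaMNTD for every sample pair (square symmetric frame)."""
    require_tip_coverage(tree, table.taxa)
    D = cophenetic_matrix(tree, table.taxa).to_numpy()
    idx, wts = _presence_and_weights(table, weighted)
    M = _bmntd_square(D, idx, wts)
    return pd.DataFrame(M, index=table.samples, columns=table.samples)


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------


def bnti_all_pairs(
    table: CountTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI for every sample pair against a tip-shuffle null.

    Each null randomization permutes taxon labels across the tips of the
    regional tree (all taxa of the metacommunity) and recomputes betaMNTD
    for every pair. Pairs whose null standard deviation is zero (e.g. a star
    phylogeny) get NaN betaNTI and are flagged, never silently dropped.
    Returns a long frame: sample_a, sample_b, bmntd_obs, null_mean, null_sd,
    bnti.
    """
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    require_tip_coverage(tree, table.taxa)
    D = cophenetic_matrix(tree, table.taxa).to_numpy()
    idx, wts = _presence_and_weights(table, weighted)
    obs = _bmntd_square(D, idx, wts)
    rng = np.random.default_rng(seed)
    n_taxa = D.shape[0]
    nulls = np.empty((n_null,) + obs.shape)
    for k in range(n_null):
        perm = rng.permutation(n_taxa)
        nulls[k] = _bmntd_square(D[np.ix_(perm, perm)], idx, wts)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)
    samples = table.samples
    iu = np.triu_indices(len(samples), k=1)
    df = pd.DataFrame(
        {
            "sample_a": np.asarray(samples)[iu[0]],
            "sample_b": np.asarray(samples)[iu[1]],
            "bmntd_obs": obs[iu],
            "null_mean": null_mean[iu],
            "null_sd": null_sd[iu],
            "bnti": bnti[iu],
        }
    )
    n_undef = int(df["bnti"].isna().sum())
    if n_undef:
        logger.warning("betaNTI undefined (zero null sd) for %d pair(s)", n_undef)
    return df


def bnti(
    a: pd.Series,
    b: pd.Series,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> float:
    """betaNTI for a single sample pair (convenience wrapper)."""
    data = pd.DataFrame({"a": a, "b": b}).fillna(0.0)
    if not np.allclose(data.to_numpy(), np.round(data.to_numpy())):
        table = CountTable((data * 10**6).round().astype(np.int64))
    else:
        table = CountTable(data.round().astype(np.int64))
    out = bnti_all_pairs(table, tree, n_null=n_null, seed=seed, weighted=weighted)
    return float(out["bnti"].iloc[0])


# ---------------------------------------------------------------------------
# RC-bray
# ---------------------------------------------------------------------------


def _bray(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom) if denom > 0 else np.nan


def rc_bray_pairs(
    table: CountTable,
    pairs: list[tuple[str, str]],
    n_null: int = 999,
    seed: int = 0,
) -> pd.Series:
    """Raup-Crick (Bray-Curtis) for the given sample pairs.

    The regional pool is the whole table: taxa are drawn for each null
    community without replacement with probability proportional to occupancy
    frequency, at the community's observed richness; the community's observed
    read total is then allocated among the drawn taxa with probability
    proportional to regional relative abundance. RC = 2 * [ (#null < obs)
    + 0.5 * (#null = obs) ] / n_null - 1, bounded in [-1, 1]; ties with the
    observed distance count half.
    """
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    counts = table.data.to_numpy(dtype=np.int64)
    samples = {s: j for j, s in enumerate(table.samples)}
    occupancy = (counts > 0).sum(axis=1).astype(float)
    regional = counts.sum(axis=1).astype(float)
    if (occupancy == 0).all():
        raise ParameterError("empty regional pool")
    p_occ = occupancy / occupancy.sum()
    n_taxa = counts.shape[0]
    rng = np.random.default_rng(seed)

    def null_community(richness: int, reads: int) -> np.ndarray:
        drawn = rng.choice(n_taxa, size=richness, replace=False, p=p_occ)
        p_ab = regional[drawn]
        if p_ab.sum() <= 0:
            p_ab = np.ones(richness)
        p_ab = p_ab / p_ab.sum()
        comm = np.zeros(n_taxa)
        comm[drawn] = rng.multinomial(reads, p_ab)
        return comm

    out = {}
    for name_a, name_b in pairs:
        for name in (name_a, name_b):
            if name not in samples:
                raise ParameterError(f"unknown sample {name!r}")
        xa = counts[:, samples[name_a]]
        xb = counts[:, samples[name_b]]
        if (xa > 0).sum() == 0 or (xb > 0).sum() == 0:
            raise ParameterError("RC-bray requires non-empty samples")
        obs = _bray(xa.astype(float), xb.astype(float))
        rich_a, rich_b = int((xa > 0).sum()), int((xb > 0).sum())
        reads_a, reads_b = int(xa.sum()), int(xb.sum())
        below = ties = 0
        for _ in range(n_null):
            d = _bray(null_community(rich_a, reads_a), null_community(rich_b, reads_b))
            if d < obs - 1e-12:
                below += 1
            elif abs(d - obs) <= 1e-12:
                ties += 1
        out[(name_a, name_b)] = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    return pd.Series(out, name="rc_bray")


def rc_bray(
    a_name: str,
    b_name: str,
    table: CountTable,
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """RC-bray for one pair against the table-wide regional pool."""
    return float(rc_bray_pairs(table, [(a_name, b_name)], n_null=n_null, seed=seed).iloc[0])


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------


def classify_pair(bnti_value: float, rc_value: float | None = None) -> str:
    """Map (betaNTI, RC-bray) to one of the five ecological processes.

    Strict inequalities throughout: betaNTI > +2 heterogeneous selection,
    betaNTI < -2 homogeneous selection; otherwise RC > +0.95 dispersal
    limitation, RC < -0.95 homogenizing dispersal, else drift. Boundary
    values (betaNTI exactly +/-2, RC exactly +/-0.95) fall to the
    less-deterministic side.
    """
    if np.isnan(bnti_value):
        raise ParameterError("betaNTI is undefined for this pair")
    if bnti_value > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value is None or (isinstance(rc_value, float) and np.isnan(rc_value)):
        raise ParameterError("RC-bray required when |betaNTI| <= 2")
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def process_fractions(
    results: pd.DataFrame, strata: pd.Series | None = None
) -> pd.DataFrame:
    """Fractions of classified pairs per process, overall and per stratum.

    A pair belongs to a stratum when both samples do; the "all" row covers
    every classified pair. Pairs with undefined betaNTI are excluded from
    the denominators and reported in the ``n_flagged`` column.
    """
    df = results.copy()
    flagged = df["process"].isna()
    strata_rows: dict[str, pd.Series] = {"all": pd.Series(True, index=df.index)}
    if strata is not None:
        for name in pd.unique(strata.dropna()):
            members = set(strata[strata == name].index)
            mask = df["sample_a"].isin(members) & df["sample_b"].isin(members)
            if mask.any():
                strata_rows[str(name)] = mask
            else:
                logger.warning("stratum %r has no within-stratum pairs; omitted", name)
    rows = {}
    for name, mask in strata_rows.items():
        sub = df.loc[mask & ~flagged, "process"]
        total = len(sub)
        row = {proc: (sub == proc).sum() / total if total else np.nan for proc in PROCESSES}
        row["n_pairs"] = total
        row["n_flagged"] = int((mask & flagged).sum())
        rows[name] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "stratum"
    return out


def assembly_analysis(
    table: CountTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    strata: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full framework on one table.

    Returns (pairwise results, process fractions). RC-bray is only computed
    for pairs with |betaNTI| <= 2, with a seed derived from ``seed``.
    """
    results = bnti_all_pairs(table, tree, n_null=n_null, seed=seed, weighted=weighted)
    need_rc = results["bnti"].abs() <= BNTI_THRESHOLD
    results["rc_bray"] = np.nan
    if need_rc.any():
        pairs = list(
            results.loc[need_rc, ["sample_a", "sample_b"]].itertuples(index=False, name=None)
        )
        rc = rc_bray_pairs(table, pairs, n_null=n_null, seed=seed + 1)
        results.loc[need_rc, "rc_bray"] = rc.to_numpy()
    labels = []
    for row in results.itertuples(index=False):
        if np.isnan(row.bnti):
            labels.append(None)
        else:
            labels.append(
                classify_pair(row.bnti, None if np.isnan(row.rc_bray) else row.rc_bray)
            )
    results["process"] = labels
    fractions = process_fractions(results, strata=strata)
    return results, fractions
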