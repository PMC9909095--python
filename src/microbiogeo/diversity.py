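"""Rarefaction, alpha-diversity, transforms, Bray-Curtis/PCoA and group comparisons.

Conventions: Shannon uses the natural log (so Pielou's J = H / ln S exactly),
Simpson is the Gini-Simpson form 1 - sum(p^2), Faith's PD is rooted (the
minimal subtree connecting the present tips always includes the path to the
root), and rarefaction is a single without-replacement draw per sample.
Beta-diversity follows the order rarefy -> Hellinger -> Bray-Curtis.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from .core_io import (
    AbundanceTable,
    CountTable,
    FormatError,
    ParameterError,
    require_tip_coverage,
)

logger = logging.getLogger("microbiogeo")


class EmptyResultError(ValueError):
    """Raised when an operation would return an empty result set."""


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning; taxa that end up with zero counts everywhere are retained (rows
    are never pruned, keeping axes comparable across rarefactions).
    """
    if depth < 1:
        raise ParameterError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept = {}
    dropped = []
    for sample in table.samples:
        counts = table.data[sample].to_numpy()
        total = int(counts.sum())
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            kept[sample] = counts
        else:
            kept[sample] = rng.multivariate_hypergeometric(counts, depth)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not kept:
        raise EmptyResultError(f"all samples have fewer than {depth} reads")
    data = pd.DataFrame(kept, index=table.taxa).astype(np.int64)
    return CountTable(data)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def _clean_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ParameterError("sample has no nonzero counts")
    return c[c > 0]


def shannon(counts) -> float:
    """Shannon-Wiener H' with natural log."""
    c = _clean_counts(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum(p^2), bounded in [0, 1]."""
    c = _clean_counts(counts)
    p = c / c.sum()
    return float(1.0 - (p**2).sum())


def richness(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def pielou(counts) -> float:
    """Pielou's evenness J = H / ln S; NaN (flagged missing) when S == 1."""
    s = richness(counts)
    if s <= 1:
        _clean_counts(counts)  # still error on all-zero input
        return float("nan")
    return shannon(counts) / math.log(s)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N, the estimated fraction of reads from seen taxa."""
    c = np.asarray(counts)
    n = c.sum()
    if n < 1:
        raise ParameterError("sample has no reads")
    f1 = int((c == 1).sum())
    return float(1.0 - f1 / n)


def faith_pd(present_taxa, tree: TreeNode) -> float:
    """Rooted Faith's phylogenetic diversity.

    Sum of branch lengths of the minimal subtree connecting the present tips
    to the root (the stem branches are included). Empty set -> 0.
    """
    present = list(present_taxa)
    if not present:
        return 0.0
    tips = {t.name: t for t in tree.tips()}
    unknown = [t for t in present if t not in tips]
    if unknown:
        raise FormatError(f"taxa not in tree: {unknown[:5]}")
    seen: set[int] = set()
    total = 0.0
    for name in present:
        node = tips[name]
        while node.parent is not None and id(node) not in seen:
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return float(total)


def alpha_diversity(
    table: CountTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Per-sample alpha-diversity table.

    Columns: shannon, simpson, pielou, faith_pd (NaN without a tree),
    goods_coverage, richness.
    """
    if tree is not None:
        require_tip_coverage(tree, table.taxa)
    rows = {}
    taxa = np.asarray(table.taxa)
    for sample in table.samples:
        counts = table.data[sample].to_numpy()
        pd_value = (
            faith_pd(taxa[counts > 0], tree) if tree is not None else float("nan")
        )
        rows[sample] = {
            "shannon": shannon(counts),
            "simpson": simpson(counts),
            "pielou": pielou(counts),
            "faith_pd": pd_value,
            "goods_coverage": goods_coverage(counts),
            "richness": richness(counts),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return df


# ---------------------------------------------------------------------------
# Transforms and beta diversity
# ---------------------------------------------------------------------------


def relative_abundance(table: CountTable | AbundanceTable) -> AbundanceTable:
    df = table.data.astype(float)
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        raise ParameterError("zero-total sample in abundance normalisation")
    return AbundanceTable(df / totals, kind="relative")


def hellinger(table: CountTable) -> AbundanceTable:
    """Hellinger transform: sqrt of relative abundance per taxon per sample."""
    rel = relative_abundance(table)
    return AbundanceTable(np.sqrt(rel.data), kind="hellinger")


def bray_curtis(table: CountTable | AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    df = table.data
    if df.shape[1] < 2:
        raise ParameterError("Bray-Curtis needs at least 2 samples")
    X = df.to_numpy(dtype=float).T
    if (X.sum(axis=1) <= 0).any():
        raise ParameterError("all-zero sample; Bray-Curtis undefined")
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(df.columns))


def pcoa(dm: DistanceMatrix) -> OrdinationResults:
    """Classical metric scaling (PCoA) of a distance matrix.

    Eigendecomposition of the double-centred -D^2/2 matrix; all eigenvalues
    are reported (negative ones included, sorted non-increasing) but
    coordinates span only the positive-eigenvalue axes.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)
    positive = res.eigvals[res.eigvals > 1e-12].index
    coords = res.samples.loc[:, positive]
    return OrdinationResults(
        short_method_name="PCoA",
        long_method_name="Principal Coordinate Analysis",
        eigvals=res.eigvals,
        samples=coords,
        proportion_explained=res.proportion_explained,
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration of all rank splits (average ranks on ties) when
    nA + nB <= 12; otherwise the normal approximation with tie correction.
    Returns (U statistic of group A, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    rank_sum_a = ranks[:n_a].sum()
    u_a = rank_sum_a - n_a * (n_a + 1) / 2.0

    if n_a + n_b <= 12:
        # enumerate all C(n, nA) assignments of the pooled ranks to group A
        mean_w = n_a * (n_a + n_b + 1) / 2.0
        obs_dev = abs(rank_sum_a - mean_w)
        hits = total = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mean_w) >= obs_dev - 1e-12:
                hits += 1
        return float(u_a), hits / total

    _, p = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic"
    )
    return float(u_a), float(p)


def alpha_group_tests(
    alpha: pd.DataFrame, grouping: pd.Series, metrics: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of alpha metrics between groups.

    One row per (metric, group pair) with the U statistic and two-sided p.
    """
    metrics = metrics or [c for c in alpha.columns if c != "richness"]
    groups = sorted(grouping.dropna().unique(), key=str)
    rows = []
    for metric in metrics:
        for g1, g2 in itertools.combinations(groups, 2):
            va = alpha.loc[grouping[grouping == g1].index, metric].dropna()
            vb = alpha.loc[grouping[grouping == g2].index, metric].dropna()
            if va.empty or vb.empty:
                continue
            u, p = wilcoxon_rank_sum(va, vb)
            rows.append(
                {"metric": metric, "group_a": g1, "group_b": g2, "U": u, "p": p}
            )
    return pd.DataFrame(rows)


def shared_taxon_counts(table: CountTable, grouping: pd.Series) -> dict:
    """Venn-style presence summary across groups (e.g. depth layers).

    A taxon is present in a group when its summed count there is > 0.
    Returns ``{"shared_all": int, "unique": {group: int}, "present": {group: int}}``.
    """
    unknown = [s for s in grouping.index if s not in table.samples]
    if unknown:
        raise ParameterError(f"grouping references unknown samples: {unknown[:5]}")
    missing = [s for s in table.samples if s not in grouping.index]
    if missing:
        raise ParameterError(f"grouping does not cover samples: {missing[:5]}")
    presence: dict[str, set[str]] = {}
    taxa = np.asarray(table.taxa)
    for group in pd.unique(grouping):
        samples = grouping[grouping == group].index
        sums = table.data.loc[:, list(samples)].sum(axis=1).to_numpy()
        presence[group] = set(taxa[sums > 0])
    shared = set.intersection(*presence.values()) if presence else set()
    unique = {
        g: len(s - set.union(*(o for k, o in presence.items() if k != g)))
        if len(presence) > 1
        else len(s)
        for g, s in presence.items()
    }
    return {
        "shared_all": len(shared),
        "unique": unique,
        "present": {g: len(s) for g, s in presence.items()},
    }
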