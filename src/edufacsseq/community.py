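"""Diversity, ordination, permutation tests and fraction enrichment.

Alpha diversity per sample: Shannon index (bits), Simpson evenness (inverse
Simpson over observed richness, 1 at perfect evenness) and observed features.
Beta diversity: unnormalized weighted UniFrac, ordinated by classical PCoA.
Group structure is tested with pairwise PERMANOVA (seeded permutations,
Benjamini-Hochberg q-values across the pairwise family) and Kruskal-Wallis
with Dunn's post-hoc. Differential abundance across sorted fractions uses an
ANCOM-style W statistic: per feature, the number of pairwise log-ratio tests
rejected after BH correction; an optional blocking covariate (e.g. the
experiment) is handled by within-block rank alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson_e as _skbio_simpson_e
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

from .filtering import FeatureTable

__all__ = [
    "PermanovaResult",
    "GroupTestResult",
    "AncomResult",
    "shannon",
    "simpson_evenness",
    "observed_features",
    "alpha_diversity",
    "rarefaction_curve",
    "weighted_unifrac",
    "pcoa",
    "permanova_pairwise",
    "kruskal_wallis_pairwise",
    "ancom_w",
    "fraction_enrichment_report",
]


# ---------------------------------------------------------------------------
# alpha diversity

def shannon(counts, base: float = 2.0) -> float:
    """Shannon index H = -sum p_i log p_i over nonzero features (bits by
    default)."""
    counts = np.asarray(counts, float)
    if counts.sum() <= 0:
        raise ValueError("empty sample: Shannon index undefined")
    return float(_skbio_shannon(counts, base=base))


def simpson_evenness(counts) -> float:
    """Inverse-Simpson diversity divided by observed richness, in (0, 1]."""
    counts = np.asarray(counts, float)
    if counts.sum() <= 0:
        raise ValueError("empty sample: Simpson evenness undefined")
    return float(_skbio_simpson_e(counts))


def observed_features(counts) -> int:
    return int(np.count_nonzero(np.asarray(counts)))


def alpha_diversity(tbl: FeatureTable) -> pd.DataFrame:
    """Per-sample Shannon (bits), Simpson evenness and observed features."""
    rows = {
        sid: {
            "shannon": shannon(row),
            "simpson_evenness": simpson_evenness(row),
            "observed_features": observed_features(row),
        }
        for sid, row in tbl.counts.iterrows()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(
    tbl: FeatureTable, depths, reps: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Mean observed richness per (sample, depth) over seeded subsamples.

    Samples shallower than a depth get NaN at that depth.
    """
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=tbl.counts.index, columns=list(depths), dtype=float)
    for sid in tbl.sample_ids:
        row = tbl.counts.loc[sid].to_numpy(np.int64)
        total = int(row.sum())
        for depth in depths:
            if depth > total:
                continue
            rich = [
                observed_features(rng.multivariate_hypergeometric(row, int(depth)))
                for _ in range(reps)
            ]
            out.loc[sid, depth] = float(np.mean(rich))
    return out


# ---------------------------------------------------------------------------
# beta diversity

def weighted_unifrac(tbl: FeatureTable, tree: TreeNode, normalized: bool = False) -> DistanceMatrix:
    """Pairwise weighted UniFrac: sum over branches of b * |A - B| where A, B
    are the fractions of each sample's reads descending from the branch.

    Every feature with a nonzero count must be a tip of ``tree``.
    """
    tips = {t.name for t in tree.tips()}
    present = tbl.counts.columns[(tbl.counts > 0).any(axis=0)]
    missing = sorted(set(present) - tips)
    if missing:
        raise ValueError(f"features absent from the tree: {missing}")
    in_tree = [f for f in tbl.feature_ids if f in tips]
    return beta_diversity(
        "weighted_unifrac",
        tbl.counts[in_tree].to_numpy(np.int64),
        ids=tbl.sample_ids,
        taxa=in_tree,
        tree=tree,
        normalized=normalized,
    )


def pcoa(dm: DistanceMatrix) -> OrdinationResults:
    """Classical scaling (PCoA) of a distance matrix; axes ordered by
    eigenvalue, negative eigenvalues reported as such."""
    if dm.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    return _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    group_a: str
    group_b: str
    pseudo_f: float
    p_value: float
    q_value: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    n = len(labels)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in uniq:
        idx = labels == g
        ng = int(idx.sum())
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * ng)
    k = len(uniq)
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def _permanova_two_group(d2: np.ndarray, labels: np.ndarray, n_perm: int, rng) -> tuple[float, float]:
    uniq = np.unique(labels)
    f_obs = _pseudo_f(d2, labels, uniq)
    n = len(labels)
    perms = rng.permuted(np.tile(labels, (n_perm, 1)), axis=1)
    ss_total = d2.sum() / (2 * n)
    f_perm = np.empty(n_perm)
    ind_a = (perms == uniq[0])
    ind_b = ~ind_a
    n_a = ind_a[0].sum()
    n_b = n - n_a
    within_a = np.einsum("pi,ij,pj->p", ind_a, d2, ind_a) / (2 * n_a)
    within_b = np.einsum("pi,ij,pj->p", ind_b, d2, ind_b) / (2 * n_b)
    ss_within = within_a + within_b
    f_perm = (ss_total - ss_within) / (ss_within / (n - 2))
    p = (1 + int(np.sum(f_perm >= f_obs))) / (1 + n_perm)
    return f_obs, p


def permanova_pairwise(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[PermanovaResult]:
    """Pairwise PERMANOVA over all group pairs with BH-adjusted q-values.

    ``groups`` is aligned to ``dm.ids``. Pairs where a group has a single
    sample are skipped with a warning. Permutation p-values use the +1
    convention, so p >= 1/(n_permutations + 1).
    """
    groups = pd.Series(list(groups), index=list(dm.ids))
    uniq = sorted(groups.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    results = []
    for a, b in combinations(uniq, 2):
        ids = [i for i in dm.ids if groups[i] in (a, b)]
        labels = groups[ids].to_numpy()
        if min(np.sum(labels == a), np.sum(labels == b)) < 2:
            import warnings

            warnings.warn(f"pair ({a}, {b}) skipped: a group has < 2 samples")
            continue
        sub = dm.filter(ids)
        d2 = sub.data ** 2
        f_obs, p = _permanova_two_group(d2, labels, n_permutations, rng)
        results.append((a, b, f_obs, p))
    if not results:
        return []
    pvals = [r[3] for r in results]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        PermanovaResult(a, b, f, p, float(q), n_permutations)
        for (a, b, f, p), q in zip(results, qvals)
    ]


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn

@dataclass(frozen=True)
class GroupTestResult:
    comparison: str      # "overall" or "A vs B"
    statistic: float     # KW H, or Dunn z
    p: float
    q: float


def kruskal_wallis_pairwise(values, groups) -> list[GroupTestResult]:
    """Kruskal-Wallis overall test plus Dunn's pairwise z tests with BH.

    Returns the overall result first (its q equals its p; it is its own
    family), then one result per group pair with BH-adjusted q across the
    pairwise family. All-identical values give p = 1.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    uniq = sorted(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    by_group = [values[groups == g] for g in uniq]
    if any(len(v) < 2 for v in by_group):
        raise ValueError("each group needs >= 2 observations")
    if np.ptp(values) == 0:
        overall = GroupTestResult("overall", 0.0, 1.0, 1.0)
        pairs = [GroupTestResult(f"{a} vs {b}", 0.0, 1.0, 1.0) for a, b in combinations(uniq, 2)]
        return [overall] + pairs
    h, p = stats.kruskal(*by_group)
    out = [GroupTestResult("overall", float(h), float(p), float(p))]

    # Dunn's test: z from mean-rank differences with tie correction
    n = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {g: ranks[groups == g].mean() for g in uniq}
    sizes = {g: int(np.sum(groups == g)) for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(uniq, 2):
        se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pz = 2 * stats.norm.sf(abs(z))
        rows.append((f"{a} vs {b}", float(z), float(pz)))
    qvals = multipletests([r[2] for r in rows], method="fdr_bh")[1]
    out.extend(
        GroupTestResult(name, z, p_, float(q)) for (name, z, p_), q in zip(rows, qvals)
    )
    return out


# ---------------------------------------------------------------------------
# ANCOM-style W

@dataclass
class AncomResult:
    """Per-feature W (rejected pairwise log-ratio tests) and detection flags."""

    table: pd.DataFrame  # columns: W, detected, structural_zero
    w_cutoff: float
    alpha: float


def _grouped_rank_test(x: np.ndarray, groups: np.ndarray, by_group_idx, block: np.ndarray | None) -> float:
    """p-value of a Kruskal-Wallis test of ``x`` across groups, rank-aligned
    within blocks when a blocking covariate is given."""
    if block is not None:
        aligned = np.empty_like(x)
        for b in pd.unique(block):
            idx = block == b
            aligned[idx] = stats.rankdata(x[idx])
        x = aligned
    samples = [x[idx] for idx in by_group_idx]
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(np.concatenate(samples)) == 0:
        return 1.0
    try:
        return float(stats.kruskal(*samples).pvalue)
    except ValueError:  # all values identical
        return 1.0


def ancom_w(
    tbl: FeatureTable,
    groups,
    block=None,
    alpha: float = 0.05,
    w_cutoff_quantile: float = 0.7,
) -> AncomResult:
    """ANCOM-style differential abundance across groups.

    Counts are pseudocounted (+1) and log-transformed. For each feature i,
    W_i is the number of features j != i for which the test of
    log(x_i / x_j) across groups rejects at BH-adjusted ``alpha``; the test
    is Kruskal-Wallis, rank-aligned within levels of ``block`` when given
    (the blocking covariate stands in for a random effect such as the
    experiment or the treatment). A feature is detected when
    W >= w_cutoff_quantile * (n_features - 1), or by the structural-zero
    shortcut: entirely absent in one group while present in >= 50% of the
    samples of another.
    """
    counts = tbl.counts
    n_feat = counts.shape[1]
    if n_feat < 3:
        raise ValueError("ANCOM needs at least 3 features")
    groups = np.asarray(list(groups))
    if len(groups) != counts.shape[0]:
        raise ValueError("groups must align with samples")
    uniq = sorted(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    block_arr = np.asarray(list(block)) if block is not None else None

    logx = np.log(counts.to_numpy(float) + 1.0)
    by_group_idx = [groups == g for g in uniq]

    # structural zeros: absent in one group, >= 50% prevalent in another
    raw = counts.to_numpy(float)
    absent = np.stack([raw[idx].sum(axis=0) == 0 for idx in by_group_idx])
    prevalent = np.stack([(raw[idx] > 0).mean(axis=0) >= 0.5 for idx in by_group_idx])
    structural = np.zeros(n_feat, bool)
    for i in range(len(uniq)):
        for j in range(len(uniq)):
            if i != j:
                structural |= absent[i] & prevalent[j]

    pmat = np.ones((n_feat, n_feat))
    for i, j in combinations(range(n_feat), 2):
        p = _grouped_rank_test(logx[:, i] - logx[:, j], groups, by_group_idx, block_arr)
        pmat[i, j] = pmat[j, i] = p
    w = np.zeros(n_feat, int)
    for i in range(n_feat):
        ps = np.delete(pmat[i], i)
        rej = multipletests(ps, alpha=alpha, method="fdr_bh")[0]
        w[i] = int(rej.sum())

    cutoff = w_cutoff_quantile * (n_feat - 1)
    detected = (w >= cutoff) | structural
    table = pd.DataFrame(
        {"W": w, "detected": detected, "structural_zero": structural},
        index=counts.columns,
    )
    return AncomResult(table=table, w_cutoff=float(cutoff), alpha=alpha)


def fraction_enrichment_report(
    tbl: FeatureTable,
    block_on: str = "experiment",
    alpha: float = 0.05,
    w_cutoff_quantile: float = 0.7,
) -> pd.DataFrame:
    """Mean +/- SD relative abundance per fraction per feature, joined with
    ANCOM detections (groups = sorted fraction, block = ``block_on``).

    Sheath samples are excluded: the comparison is among community fractions.
    Expects a filtered, rarefied table.
    """
    keep = tbl.meta.index[tbl.meta["fraction"] != "sheath"]
    sub = tbl.subset(keep)
    rel = sub.counts.div(sub.counts.sum(axis=1), axis=0)
    fractions = sub.meta["fraction"]
    mean = rel.groupby(fractions).mean().T
    sd = rel.groupby(fractions).std(ddof=1).T
    mean.columns = [f"mean_{c}" for c in mean.columns]
    sd.columns = [f"sd_{c}" for c in sd.columns]
    block = sub.meta[block_on] if block_on is not None and sub.meta[block_on].nunique() > 1 else None
    res = ancom_w(
        sub, fractions, block=block, alpha=alpha, w_cutoff_quantile=w_cutoff_quantile
    )
    return pd.concat([mean, sd, res.table], axis=1)
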