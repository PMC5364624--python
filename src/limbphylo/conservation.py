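"""Cross-species expression conservation statistics.

Profiles are columns of a genes x conditions matrix.  Conservation at one
stage is the mean of all species-pairwise Spearman coefficients,

    c = (1 / C(k, 2)) * sum_{i < j} r_ij,

whose robustness to gene selection is probed by repeatedly subsampling gene
sets without replacement at a range of intensities and reading 95% CIs off
the subsampled c distributions; stages differ significantly when their CIs
do not overlap.  Cluster significance reimplements the multiscale bootstrap:
gene resampling with replacement at several scales gives per-node bootstrap
probabilities BP_s, and the approximately-unbiased p-value AU comes from a
weighted least-squares fit of Phi^-1(1 - BP_s) against (sqrt(s), 1/sqrt(s)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))
AU_SIGNIFICANT = 0.95


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Average ranks per column (ties share their mean rank)."""
    return stats.rankdata(values, axis=0)


def _corr_from_ranks(ranks: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    return np.atleast_2d(corr)


def spearman_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman correlation matrix over profile columns.

    Constant profiles have undefined correlations; those entries are NaN
    and a warning is issued.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 profiles")
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    corr = _corr_from_ranks(_rank_columns(profiles.values))
    out = pd.DataFrame(corr, index=profiles.columns, columns=profiles.columns)
    np.fill_diagonal(out.values, 1.0)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        warnings.warn(
            f"constant profiles, correlations undefined: {bad}", stacklevel=2
        )
    return out


def mean_pairwise_spearman(profiles: pd.DataFrame) -> float:
    """Mean of the C(k,2) pairwise Spearman coefficients."""
    k = profiles.shape[1]
    if k < 2:
        raise ValueError("need at least 2 profiles")
    corr = _corr_from_ranks(_rank_columns(profiles.values))
    iu = np.triu_indices(k, k=1)
    return float(np.nanmean(corr[iu]))


def _c_from_ranked_subset(values: np.ndarray, idx: np.ndarray) -> float:
    ranks = _rank_columns(values[idx])
    corr = _corr_from_ranks(ranks)
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(np.nanmean(corr[iu]))


@dataclass
class ConservationResult:
    """Mean pairwise Spearman plus its subsampling distributions."""

    c: float
    k: int
    pair_r: pd.DataFrame
    distributions: dict[float, np.ndarray] = field(default_factory=dict)
    ci: dict[float, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "c": self.c,
            "k": self.k,
            "ci": {str(f): list(v) for f, v in self.ci.items()},
            "mean_subsampled_c": {
                str(f): float(np.mean(v)) for f, v in self.distributions.items()
            },
        }


def subsample_conservation(
    profiles: pd.DataFrame,
    intensities: list[float],
    n_draws: int = 500,
    seed: int | None = None,
) -> ConservationResult:
    """Subsampled conservation distributions and 95% CIs per intensity.

    At each intensity f, draws ``n_draws`` gene subsets of size round(f * n)
    without replacement and recomputes c; the CI is the 2.5th/97.5th
    percentile of the draws.  At f = 1.0 every draw is the full gene set and
    the CI has zero width.
    """
    n = profiles.shape[0]
    if not all(0 < f <= 1 for f in intensities):
        raise ValueError("intensities must lie in (0, 1]")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    values = profiles.values
    pair_r = spearman_matrix(profiles)
    result = ConservationResult(
        c=mean_pairwise_spearman(profiles), k=profiles.shape[1], pair_r=pair_r
    )
    for f in intensities:
        size = int(round(f * n))
        if size < 3:
            raise ValueError(f"intensity {f} gives subset size {size} < 3")
        draws = np.empty(n_draws)
        for d in range(n_draws):
            idx = rng.choice(n, size=size, replace=False)
            draws[d] = _c_from_ranked_subset(values, idx)
        result.distributions[f] = draws
        result.ci[f] = (
            float(np.percentile(draws, 2.5)),
            float(np.percentile(draws, 97.5)),
        )
    return result


def cis_disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Non-overlap criterion for two 95% CIs."""
    return a[1] < b[0] or b[1] < a[0]


def compare_stages(
    results: dict[str, ConservationResult], intensity: float
) -> dict[tuple[str, str], bool]:
    """Flag stage pairs whose subsampling CIs do not overlap."""
    stages = list(results)
    out = {}
    for i, s1 in enumerate(stages):
        for s2 in stages[i + 1 :]:
            out[(s1, s2)] = cis_disjoint(
                results[s1].ci[intensity], results[s2].ci[intensity]
            )
    return out


def stage_ttest(
    a: ConservationResult, b: ConservationResult, intensity: float = 1.0
) -> tuple[float, float]:
    """Welch t-test between two subsampled-c distributions.

    Interpretation note: the compared units are subsample-level c values,
    one distribution per stage.
    """
    t, p = stats.ttest_ind(
        a.distributions[intensity], b.distributions[intensity], equal_var=False
    )
    return float(t), float(p)


# ---------------------------------------------------------------------------
# multiscale bootstrap clustering significance
# ---------------------------------------------------------------------------


def spearman_distance(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Spearman distance over columns; NaN correlation -> 1."""
    corr = _corr_from_ranks(_rank_columns(values))
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices(dist.shape[0], k=1)
    return np.maximum(dist[iu], 0.0)


def linkage_clusters(linkage: np.ndarray, labels: list[str]) -> list[frozenset[str]]:
    """Leaf-label set of every internal node, in merge order."""
    n = len(labels)
    sets: list[frozenset[str]] = [frozenset([lab]) for lab in labels]
    out = []
    for left, right, _, _ in linkage:
        merged = sets[int(left)] | sets[int(right)]
        sets.append(merged)
        out.append(merged)
    return out


@dataclass
class ClusterNode:
    members: frozenset[str]
    bp: float  # bootstrap probability at scale 1.0 (or nearest)
    au: float
    degenerate: bool

    @property
    def significant(self) -> bool:
        return self.au >= AU_SIGNIFICANT


@dataclass
class ClusterSignificance:
    linkage: np.ndarray
    labels: list[str]
    nodes: list[ClusterNode]
    scales: tuple[float, ...]
    bp_by_scale: pd.DataFrame  # nodes x scales

    def node(self, members: set[str]) -> ClusterNode:
        target = frozenset(members)
        for nd in self.nodes:
            if nd.members == target:
                return nd
        raise KeyError(f"no cluster with members {sorted(target)}")

    def to_newick(self) -> str:
        n = len(self.labels)
        ann = {nd.members: nd for nd in self.nodes}

        def render(i: int) -> str:
            if i < n:
                return self.labels[i]
            left = int(self.linkage[i - n, 0])
            right = int(self.linkage[i - n, 1])
            members = frozenset()
            stack = [i]
            while stack:
                j = stack.pop()
                if j < n:
                    members |= {self.labels[j]}
                else:
                    stack.extend(
                        (int(self.linkage[j - n, 0]), int(self.linkage[j - n, 1]))
                    )
            nd = ann[members]
            label = f"au{nd.au:.3f}_bp{nd.bp:.3f}"
            return f"({render(left)},{render(right)}){label}"

        return render(n + len(self.linkage) - 1) + ";"


def fit_au(
    scales: np.ndarray, bps: np.ndarray, n_boot: int
) -> tuple[float, bool]:
    """AU p-value from per-scale bootstrap probabilities.

    Weighted least squares of z_s = Phi^-1(1 - BP_s) on (sqrt(s), 1/sqrt(s))
    with the usual binomial delta-method weights; AU = 1 - Phi(v - c).
    Degenerate nodes (BP stuck at 0 or 1 on fewer than two informative
    scales) return that limit with a flag.
    """
    scales = np.asarray(scales, dtype=float)
    bps = np.asarray(bps, dtype=float)
    usable = (bps > 0.0) & (bps < 1.0)
    if usable.sum() < 2:
        mean_bp = float(bps.mean())
        return (1.0 if mean_bp >= 0.5 else 0.0), True
    s = scales[usable]
    bp = bps[usable]
    z = stats.norm.ppf(1.0 - bp)
    dens = stats.norm.pdf(z)
    w = n_boot * dens**2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(s), 1.0 / np.sqrt(s)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    v, c = coef
    return float(1.0 - stats.norm.cdf(v - c)), False


def significant_clustering(
    profiles: pd.DataFrame,
    n_boot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int | None = None,
) -> ClusterSignificance:
    """Average-linkage clustering with multiscale-bootstrap AU/BP values.

    Distance is 1 - Spearman over the gene axis; each bootstrap resamples
    round(scale * n) genes with replacement and records which observed
    clusters reappear.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 profiles")
    if not (min(scales) < 1.0 < max(scales)):
        raise ValueError("scales must span values below and above 1")
    labels = list(profiles.columns)
    values = profiles.values
    if profiles.shape[1] == 2:
        # single trivial join: no testable internal node, no p-values
        return ClusterSignificance(
            linkage=hierarchy.average(spearman_distance(values)),
            labels=labels,
            nodes=[],
            scales=tuple(scales),
            bp_by_scale=pd.DataFrame(columns=list(scales)),
        )
    n = values.shape[0]
    rng = np.random.default_rng(seed)

    observed_linkage = hierarchy.average(spearman_distance(values))
    clusters = linkage_clusters(observed_linkage, labels)
    cluster_index = {cl: i for i, cl in enumerate(clusters)}

    counts = np.zeros((len(clusters), len(scales)))
    for si, scale in enumerate(scales):
        m = max(3, int(round(scale * n)))
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=m)
            boot_linkage = hierarchy.average(spearman_distance(values[idx]))
            for cl in linkage_clusters(boot_linkage, labels):
                pos = cluster_index.get(cl)
                if pos is not None:
                    counts[pos, si] += 1
    bp = counts / n_boot

    scale_arr = np.asarray(scales, dtype=float)
    near_one = int(np.argmin(np.abs(scale_arr - 1.0)))
    nodes = []
    for i, cl in enumerate(clusters):
        au, degenerate = fit_au(scale_arr, bp[i], n_boot)
        nodes.append(
            ClusterNode(
                members=cl,
                bp=float(bp[i, near_one]),
                au=au,
                degenerate=degenerate,
            )
        )
    bp_df = pd.DataFrame(
        bp,
        index=[",".join(sorted(cl)) for cl in clusters],
        columns=list(scales),
    )
    return ClusterSignificance(
        linkage=observed_linkage,
        labels=labels,
        nodes=nodes,
        scales=tuple(scales),
        bp_by_scale=bp_df,
    )
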