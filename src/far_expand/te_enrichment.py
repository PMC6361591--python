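"""Flank TE densities, the permutation null and the group comparison.

The core quantity is the *TE density* of a gene: the fraction of bases in the
10 kb windows immediately upstream and downstream of the gene body that are
covered by TE annotations.  Enrichment of a focal gene set (e.g. the expanded
FAR-A ortholog group) is assessed against a null distribution of mean
densities over randomly sampled gene sets of matched size, and the focal and
non-focal groups are compared directly with a Mann-Whitney U test.

Windows are strand-agnostic (upstream/downstream are symmetric for a density)
and exclude the gene body; the density denominator is the clipped flank
length, not 2*w, so genes near scaffold ends are not deflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from far_expand.io_annotations import (
    CLASS_OF_FAMILY,
    GeneRecord,
    GenomicInterval,
    ScaffoldIndex,
    TERecord,
)

CATEGORY_ALL = "all"


class UndefinedDensityError(ValueError):
    """Raised when a gene has no flank bases (flanks entirely clipped away).

    Callers should exclude such genes from the analysis.
    """


@dataclass(frozen=True)
class FlankWindows:
    """The clipped upstream/downstream windows of one gene."""

    gene_id: str
    windows: tuple[GenomicInterval, ...]
    total_len: int


@dataclass(frozen=True)
class DensityRecord:
    """Flank TE coverage of one gene for one TE category."""

    gene_id: str
    group: str
    category: str
    covered_bp: int
    total_bp: int

    @property
    def density(self) -> float:
        return self.covered_bp / self.total_bp


@dataclass(frozen=True)
class PermutationResult:
    """Observed mean flank density against the resampled null."""

    observed_mean: float
    n_perm: int
    n_ge: int
    p_empirical: float
    null_mean: float
    null_sd: float
    null_quantiles: Mapping[str, float]
    seed: int
    n_focal: int
    n_pool: int
    category: str = CATEGORY_ALL

    def to_dict(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "n_perm": self.n_perm,
            "n_ge": self.n_ge,
            "p_empirical": self.p_empirical,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_quantiles": dict(self.null_quantiles),
            "seed": self.seed,
            "n_focal": self.n_focal,
            "n_pool": self.n_pool,
            "category": self.category,
        }


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney comparison; U is reported for the first sample."""

    u_statistic: float
    n1: int
    n2: int
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {
            "u_statistic": self.u_statistic,
            "n1": self.n1,
            "n2": self.n2,
            "p_value": self.p_value,
            "method": self.method,
        }


def flank_windows(gene: GeneRecord, w: int, index: ScaffoldIndex) -> FlankWindows:
    """Clipped ``w``-bp windows on either side of the gene body.

    The upstream window is ``[max(0, start-w), start)`` and the downstream
    window ``[end, min(L, end+w))``; zero-length windows are dropped.
    """
    if w <= 0:
        raise ValueError("window size w must be > 0")
    iv = gene.interval
    length = index[iv.scaffold]
    index.validate(iv)
    windows = []
    up_start = max(0, iv.start - w)
    if up_start < iv.start:
        windows.append(GenomicInterval(iv.scaffold, up_start, iv.start))
    down_end = min(length, iv.end + w)
    if iv.end < down_end:
        windows.append(GenomicInterval(iv.scaffold, iv.end, down_end))
    total = sum(len(x) for x in windows)
    return FlankWindows(gene.gene_id, tuple(windows), total)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals on one scaffold into a disjoint set."""
    if not intervals:
        return []
    scaffolds = {iv.scaffold for iv in intervals}
    if len(scaffolds) > 1:
        raise ValueError(f"merge_intervals needs a single scaffold, got {sorted(scaffolds)}")
    merged: list[list[int]] = []
    for iv in sorted(intervals, key=lambda x: (x.start, x.end)):
        if merged and iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    scaffold = intervals[0].scaffold
    return [GenomicInterval(scaffold, s, e) for s, e in merged]


def _matches_category(te: TERecord, category: str) -> bool:
    if category == CATEGORY_ALL:
        return True
    if category in ("I", "II", "unknown"):
        return te.te_class == category
    return te.te_family == category


def build_te_trees(tes: Iterable[TERecord], category: str = CATEGORY_ALL) -> dict[str, IntervalTree]:
    """Per-scaffold interval trees of TE records matching *category*."""
    trees: dict[str, IntervalTree] = {}
    for te in tes:
        if not _matches_category(te, category):
            continue
        trees.setdefault(te.interval.scaffold, IntervalTree()).addi(
            te.interval.start, te.interval.end
        )
    return trees


def _covered_bp(windows: FlankWindows, trees: Mapping[str, IntervalTree]) -> int:
    covered = 0
    for window in windows.windows:
        tree = trees.get(window.scaffold)
        if tree is None:
            continue
        clipped = [
            GenomicInterval(window.scaffold, max(hit.begin, window.start), min(hit.end, window.end))
            for hit in tree.overlap(window.start, window.end)
        ]
        covered += sum(len(iv) for iv in merge_intervals(clipped))
    return covered


def te_density(
    gene: GeneRecord,
    tes: Iterable[TERecord] | Mapping[str, IntervalTree],
    w: int,
    index: ScaffoldIndex,
    category: str = CATEGORY_ALL,
) -> DensityRecord:
    """Fraction of the gene's flank bases covered by TEs of *category*.

    Overlapping TE records are unioned, so a base counts at most once per
    category (but once in each category it belongs to).
    """
    windows = flank_windows(gene, w, index)
    if windows.total_len == 0:
        raise UndefinedDensityError(
            f"gene {gene.gene_id} has no flank bases on {gene.interval.scaffold}; "
            "exclude it from the density analysis"
        )
    trees = tes if isinstance(tes, Mapping) else build_te_trees(tes, category)
    covered = _covered_bp(windows, trees)
    return DensityRecord(gene.gene_id, gene.group, category, covered, windows.total_len)


def compute_densities(
    genes: Sequence[GeneRecord],
    tes: Iterable[TERecord],
    w: int,
    index: ScaffoldIndex,
    category: str = CATEGORY_ALL,
) -> list[DensityRecord]:
    """Per-gene flank densities for one category, with the TE tree built once."""
    trees = build_te_trees(tes, category)
    records = []
    for gene in genes:
        try:
            records.append(te_density(gene, trees, w, index, category))
        except UndefinedDensityError:
            continue
    return records


def group_mean_density(records: Iterable[DensityRecord], group: str) -> float:
    """Unweighted arithmetic mean of per-gene densities in *group*."""
    densities = [rec.density for rec in records if rec.group == group]
    if not densities:
        raise ValueError(f"no density records with group {group!r}")
    return float(np.mean(densities))


def permutation_test(
    focal: Sequence[GeneRecord],
    pool: Sequence[GeneRecord],
    tes: Iterable[TERecord],
    w: int,
    index: ScaffoldIndex,
    n_perm: int = 10_000,
    seed: int = 0,
    category: str = CATEGORY_ALL,
    exclude_focal: bool = False,
) -> PermutationResult:
    """One-sided (upper-tail) permutation test of mean flank-density enrichment.

    Each replicate draws ``len(focal)`` genes from *pool* uniformly without
    replacement (replicates independent) and records the mean density; the
    empirical p-value uses the add-one estimator ``(n_ge + 1) / (n_perm + 1)``
    so it is never reported as zero.  Per-gene densities are computed once and
    cached, so the replicates only resample cached values.

    By default the pool is used as given (typically the full gene set
    including the focal genes); ``exclude_focal=True`` removes the focal
    gene ids from the pool first.
    """
    if len(focal) < 1:
        raise ValueError("focal gene set is empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if exclude_focal:
        focal_ids = {g.gene_id for g in focal}
        pool = [g for g in pool if g.gene_id not in focal_ids]
    if len(pool) < len(focal):
        raise ValueError(
            f"pool ({len(pool)} genes) smaller than focal set ({len(focal)} genes)"
        )
    trees = build_te_trees(tes, category)

    cache: dict[str, float] = {}

    def density_of(gene: GeneRecord) -> float | None:
        if gene.gene_id not in cache:
            try:
                cache[gene.gene_id] = te_density(gene, trees, w, index, category).density
            except UndefinedDensityError:
                cache[gene.gene_id] = float("nan")
        d = cache[gene.gene_id]
        return None if np.isnan(d) else d

    focal_densities = [d for d in (density_of(g) for g in focal) if d is not None]
    pool_densities = np.array(
        [d for d in (density_of(g) for g in pool) if d is not None], dtype=float
    )
    if not focal_densities:
        raise UndefinedDensityError("no focal gene has a defined flank density")
    if len(pool_densities) < len(focal_densities):
        raise ValueError("pool has fewer genes with defined density than the focal set")

    # means are taken over sorted values so that identical multisets of
    # densities give bit-identical means (the focal == pool identity), and
    # p is invariant to the labelling order of pool genes
    observed = float(np.sort(focal_densities).mean())
    k = len(focal_densities)
    pool_densities.sort()
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        sample = pool_densities[rng.choice(len(pool_densities), size=k, replace=False)]
        sample.sort()
        null_means[i] = sample.mean()
    n_ge = int(np.sum(null_means >= observed))
    p = (n_ge + 1) / (n_perm + 1)
    q = np.quantile(null_means, [0.025, 0.5, 0.975])
    return PermutationResult(
        observed_mean=observed,
        n_perm=n_perm,
        n_ge=n_ge,
        p_empirical=p,
        null_mean=float(null_means.mean()),
        null_sd=float(null_means.std(ddof=1)) if n_perm > 1 else 0.0,
        null_quantiles={"q025": float(q[0]), "q500": float(q[1]), "q975": float(q[2])},
        seed=seed,
        n_focal=k,
        n_pool=int(len(pool_densities)),
        category=category,
    )


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> GroupComparison:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    ``U = sum over pairs [x_i > y_j] + 1/2 [x_i == y_j]``, computed from
    midranks.  The exact null distribution is used when ``n1 * n2 <= 400``
    and there are no ties; otherwise the tie-corrected normal approximation
    without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size

    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    has_ties = np.unique(combined).size < combined.size
    if method == "auto":
        use_exact = n1 * n2 <= 400 and not has_ties
    elif method == "exact":
        if has_ties:
            raise ValueError("exact method is not defined in the presence of ties")
        use_exact = True
    elif method == "normal":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=False,
    )
    return GroupComparison(
        u_statistic=u1,
        n1=n1,
        n2=n2,
        p_value=float(res.pvalue),
        method="exact" if use_exact else "normal_tie_corrected",
    )


def categories_for(tes: Iterable[TERecord]) -> list[str]:
    """The analysis categories present in a TE set: all, classes, families."""
    classes = sorted({te.te_class for te in tes if te.te_class in ("I", "II")})
    families = sorted(
        {te.te_family for te in tes if te.te_family in CLASS_OF_FAMILY},
        key=list(CLASS_OF_FAMILY).index,
    )
    return [CATEGORY_ALL, *classes, *families]
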