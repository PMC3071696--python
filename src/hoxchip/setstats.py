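"""Monte-Carlo and enrichment statistics on gene and region sets.

All resampling p-values follow the add-one convention
p = (n_as_extreme + 1) / (n_iter + 1), which keeps p strictly positive and
gives a floor of 1/10001 ~ 1e-4 at the conventional 10,000 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hoxchip._rng import substream
from hoxchip.intervals import region_set_overlap
from hoxchip.peaks import BoundRegion


@dataclass(frozen=True)
class ResamplingResult:
    observed: float
    n_iter: int
    n_as_extreme: int
    p_value: float
    null_mean: float
    null_sd: float
    seed: int

    def __post_init__(self) -> None:
        expected = (self.n_as_extreme + 1) / (self.n_iter + 1)
        if abs(self.p_value - expected) > 1e-12:
            raise ValueError("p_value must equal (n_as_extreme + 1)/(n_iter + 1)")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value outside (0, 1]")


def _result(observed: float, null: np.ndarray, seed: int) -> ResamplingResult:
    b = int((null >= observed).sum())
    n = null.size
    return ResamplingResult(
        observed=float(observed),
        n_iter=n,
        n_as_extreme=b,
        p_value=(b + 1) / (n + 1),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n > 1 else 0.0,
        seed=seed,
    )


def mc_overlap_test(
    size_a: int,
    size_b: int,
    observed_overlap: int,
    universe,
    n_iter: int = 10_000,
    seed: int = 0,
) -> ResamplingResult:
    """Monte-Carlo significance of the overlap between two gene sets.

    Each iteration draws two fresh sets of ``size_a`` and ``size_b`` genes
    without replacement from the universe and counts their intersection;
    the one-sided p-value is for an intersection at least as large as
    observed.  ``universe`` may be a collection of gene ids or an integer
    universe size.
    """
    n_universe = universe if isinstance(universe, int) else len(set(universe))
    if not (0 < size_a <= n_universe and 0 < size_b <= n_universe):
        raise ValueError("set sizes must be in 1..|universe|")
    if not 0 <= observed_overlap <= min(size_a, size_b):
        raise ValueError("observed overlap incompatible with set sizes")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = substream(seed, "mc-overlap")
    null = np.empty(n_iter, dtype=np.int64)
    mask = np.zeros(n_universe, dtype=bool)
    for i in range(n_iter):
        a = rng.choice(n_universe, size=size_a, replace=False)
        b = rng.choice(n_universe, size=size_b, replace=False)
        mask[a] = True
        null[i] = int(mask[b].sum())
        mask[a] = False
    return _result(observed_overlap, null, seed)


def label_bias_test(
    pool_size: int,
    n_label_in_pool: int,
    subset_size: int,
    n_label_in_subset: int,
    n_iter: int = 10_000,
    seed: int = 0,
) -> ResamplingResult:
    """Monte-Carlo test for label over-representation in a subset.

    Each iteration samples ``subset_size`` items without replacement from a
    pool containing ``n_label_in_pool`` labelled items and counts the
    labelled draws (a hypergeometric draw); the one-sided p-value is for a
    labelled count at least the observed one.  Used for the repression-bias
    question: is the fraction of down-regulated genes among bound genes
    higher than in the expression dataset as a whole?
    """
    if not 0 < subset_size <= pool_size:
        raise ValueError("need 0 < subset_size <= pool_size")
    if not 0 <= n_label_in_pool <= pool_size:
        raise ValueError("label count exceeds pool")
    if not 0 <= n_label_in_subset <= subset_size:
        raise ValueError("observed label count exceeds subset")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = substream(seed, "label-bias")
    null = rng.hypergeometric(n_label_in_pool, pool_size - n_label_in_pool,
                              subset_size, size=n_iter)
    return _result(n_label_in_subset, null, seed)


def term_enrichment(
    study_set,
    universe,
    term_map: dict[str, set[str] | list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial over/under-representation of annotation terms in a study set.

    For each term with universe frequency f and k hits among the n study
    genes, the over-representation p is the upper binomial tail P(X >= k)
    and the under-representation p the lower tail P(X <= k); the reported
    direction is the smaller tail.  p-values are Bonferroni-corrected by
    the number of tested terms and capped at 1; a corrected p below
    ``alpha`` is flagged significant.
    """
    study = set(study_set)
    univ = set(universe)
    if not study <= univ:
        missing = sorted(study - univ)[:5]
        raise ValueError(f"study genes absent from universe, e.g. {missing}")
    n = len(study)
    n_univ = len(univ)
    gene_terms: dict[str, set[str]] = {g: set(ts) for g, ts in term_map.items()}
    terms = sorted({t for g, ts in gene_terms.items() if g in univ for t in ts})
    rows = []
    for term in terms:
        members = {g for g, ts in gene_terms.items() if term in ts} & univ
        f = len(members) / n_univ
        k = len(study & members)
        p_over = float(stats.binom.sf(k - 1, n, f))
        p_under = float(stats.binom.cdf(k, n, f))
        if p_over <= p_under:
            direction, p = "over", p_over
        else:
            direction, p = "under", p_under
        rows.append((term, k, n * f, direction, p))
    df = pd.DataFrame(rows, columns=["term", "observed", "expected", "direction", "p_value"])
    df["p_bonferroni"] = np.minimum(df["p_value"] * len(terms), 1.0)
    df["significant"] = df["p_bonferroni"] < alpha
    return df


def cooccurrence_permutation_test(
    regions_a: list[BoundRegion],
    regions_b: list[BoundRegion],
    chrom_sizes: dict[str, int],
    min_overlap_bp: int = 100,
    n_iter: int = 1000,
    seed: int = 0,
) -> ResamplingResult:
    """Permutation test for co-occurrence of two bound-region sets.

    The observed statistic is the number of A regions overlapped by at
    least ``min_overlap_bp`` with some B region.  Each iteration relocates
    every B region uniformly within its own chromosome (length preserved,
    A fixed) and recounts; the one-sided p-value is for an overlap count at
    least the observed one.
    """
    for r in regions_b:
        size = chrom_sizes.get(r.chrom)
        if size is None:
            raise ValueError(f"no chromosome size for {r.chrom!r}")
        if r.length > size:
            raise ValueError(f"region longer than chromosome {r.chrom!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = substream(seed, "cooccurrence")
    observed, _, _ = region_set_overlap(regions_a, regions_b, min_overlap_bp)
    null = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        shuffled = []
        for r in regions_b:
            start = int(rng.integers(0, chrom_sizes[r.chrom] - r.length + 1))
            shuffled.append(BoundRegion(r.chrom, start, start + r.length,
                                        start, r.height, r.fdr_tier))
        cnt, _, _ = region_set_overlap(regions_a, shuffled, min_overlap_bp)
        null[i] = cnt
    return _result(observed, null, seed)
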