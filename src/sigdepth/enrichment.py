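"""Length-bias-aware category enrichment of DE gene sets.

Long transcripts accumulate more reads, so at fixed expression change a
long gene is more likely to be called DE; a plain hypergeometric test
then over-states the enrichment of categories full of long genes.  The
correction is the usual two-step device: fit a monotone
probability-weighting function P(DE | length), then test each category
with the Wallenius noncentral hypergeometric distribution whose odds
parameter is the ratio of mean weights inside vs outside the category.
At odds 1 the test reduces exactly to the one-sided Fisher /
hypergeometric test.

The weighting function here is a local-linear (kernel) smooth of the DE
indicator on length rank projected onto the monotone cone by isotonic
regression, rather than a constrained spline.  The smoothing step
matters: raw isotonic regression of 0/1 flags interpolates noise at the
extremes (its boundary blocks can hit 0 or 1 on pure-null data), while
the local-linear pre-fit is unbiased for sloped trends at the
boundaries and leaves the isotonic projection to enforce monotonicity
only.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy.stats import nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression

from .datamodel import DegenerateInputError, DomainError
from .diffexp import bh_adjust

__all__ = ["EnrichmentResult", "fit_pwf", "wallenius_enrichment"]

logger = logging.getLogger("sigdepth")

WEIGHT_CLIP = (1e-6, 1.0 - 1e-6)

#: Kernel sd of the local-linear pre-smoother, as a fraction of the
#: number of genes (rank scale).
PWF_BANDWIDTH = 0.1


@dataclass
class EnrichmentResult:
    """Per-category enrichment table: size, DE members, Wallenius odds,
    raw and BH-adjusted p-values."""

    categories: list[str]
    size: np.ndarray
    n_de_in: np.ndarray
    odds: np.ndarray
    p_value: np.ndarray
    padj: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.size,
                "n_de_in": self.n_de_in,
                "odds": self.odds,
                "p_value": self.p_value,
                "padj": self.padj,
            },
            index=pd.Index(self.categories, name="category"),
        )

    def n_significant(self, alpha: float = 0.05) -> int:
        return int((self.padj <= alpha).sum())


def _local_linear_rate(y: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-kernel local-linear fit of ``y`` on its index.

    Evaluated at every index via moment convolutions; degree-1 fitting
    removes the boundary bias a running mean has on sloped trends.
    """
    n = y.size
    radius = int(np.ceil(3 * sigma))
    u = np.arange(-radius, radius + 1, dtype=float)
    kern = np.exp(-0.5 * (u / sigma) ** 2)
    ones = np.ones(n)
    s0 = np.correlate(ones, kern, "same")
    s1 = np.correlate(ones, kern * u, "same")
    s2 = np.correlate(ones, kern * u * u, "same")
    t0 = np.correlate(y, kern, "same")
    t1 = np.correlate(y, kern * u, "same")
    det = s0 * s2 - s1 * s1
    return (s2 * t0 - s1 * t1) / det


def fit_pwf(de_flags: np.ndarray, gene_lengths: np.ndarray) -> np.ndarray:
    """Fit the probability-weighting function P(DE | length).

    The 0/1 DE flags, ordered by gene length, are smoothed by a
    local-linear kernel fit (bandwidth ``PWF_BANDWIDTH`` of the gene
    count, rank scale) and projected onto the monotone nondecreasing
    cone by isotonic regression; weights are clipped to (0, 1) and
    renormalized so their mean equals the observed DE fraction to
    within 1e-6.  Requires at least 10 DE and 10 non-DE genes.
    """
    flags = np.asarray(de_flags, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if flags.shape != lengths.shape or flags.ndim != 1:
        raise DomainError("de_flags and gene_lengths must be aligned 1-D arrays")
    if not np.all(np.isin(flags, (0.0, 1.0))):
        raise DomainError("de_flags must be 0/1")
    n_de = int(flags.sum())
    if n_de == 0 or n_de == flags.size:
        raise DegenerateInputError("all DE flags identical; no PWF can be fit")
    if n_de < 10 or flags.size - n_de < 10:
        raise DegenerateInputError("need >= 10 DE and >= 10 non-DE genes")

    order = np.argsort(lengths, kind="mergesort")
    sigma = max(2.0, PWF_BANDWIDTH * flags.size)
    smooth = _local_linear_rate(flags[order], sigma)
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(flags.size, dtype=float), smooth)
    w = np.empty(flags.size)
    w[order] = fitted

    target = flags.mean()
    lo, hi = WEIGHT_CLIP
    w = np.clip(w, lo, hi)
    for _ in range(100):
        if abs(w.mean() - target) <= 1e-6:
            break
        w = np.clip(w * (target / w.mean()), lo, hi)
    return w


def wallenius_enrichment(
    categories: dict[str, set[str]],
    de_flags: np.ndarray,
    weights: np.ndarray,
    gene_ids: list[str],
) -> EnrichmentResult:
    """Wallenius noncentral hypergeometric over-representation test.

    For each category, the odds ``w`` is (mean weight inside) / (mean
    weight outside); the p-value is the upper tail
    P(X >= n_de_in) of Wallenius(N, size, n_DE, w).  Size-0 categories
    (no member in the universe) are skipped with a warning; p-values
    are BH-adjusted across the tested categories.
    """
    flags = np.asarray(de_flags, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    pos = {g: i for i, g in enumerate(gene_ids)}
    n_total = flags.size
    n_de = int(flags.sum())

    names: list[str] = []
    sizes: list[int] = []
    de_in: list[int] = []
    odds_list: list[float] = []
    pvals: list[float] = []
    for cat in sorted(categories):
        idx = np.array([pos[g] for g in categories[cat] if g in pos], dtype=np.intp)
        if idx.size == 0:
            logger.warning("category %s has no genes in the universe; skipped", cat)
            continue
        inside = np.zeros(n_total, dtype=bool)
        inside[idx] = True
        size = int(inside.sum())
        x = int((flags & inside).sum())
        mean_in = weights[inside].mean()
        mean_out = weights[~inside].mean() if size < n_total else mean_in
        odds = mean_in / mean_out if mean_out > 0 else 1.0
        if n_de == 0:
            p = 1.0
        else:
            # upper tail P(X >= x); X = DE genes landing inside the category
            p = float(nchypergeom_wallenius.sf(x - 1, n_total, size, n_de, odds))
            p = min(max(p, np.finfo(float).tiny), 1.0)
        names.append(cat)
        sizes.append(size)
        de_in.append(x)
        odds_list.append(float(odds))
        pvals.append(p)

    p_arr = np.asarray(pvals)
    return EnrichmentResult(
        categories=names,
        size=np.asarray(sizes),
        n_de_in=np.asarray(de_in),
        odds=np.asarray(odds_list),
        p_value=p_arr,
        padj=bh_adjust(p_arr) if p_arr.size else p_arr,
    )
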