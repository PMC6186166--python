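"""Normalization, negative-binomial differential expression, and
signature construction.

The stage follows the standard bulk RNA-seq recipe: relative log
expression (median-of-ratios) size factors, per-gene NB dispersion
estimates shrunk toward a fitted mean–dispersion trend, and a Wald test
on the log2 fold change between the two groups.  It is a deliberately
transparent approximation of that recipe — method-of-moments dispersion,
delta-method standard errors, no independent filtering or fold-change
shrinkage — validated by null-calibration and power tests rather than
by equivalence to any particular external engine, and pluggable behind
the :class:`DEResult` interface.

Model: counts ``n_gj ~ NB(mu_gj, alpha_g)`` with
``mu_gj = s_j * q_g * 2**(x_j * beta_g)``; the Wald statistic is
``lfc / se`` with

``lfc  = log2((mB + c0) / (mA + c0))``, c0 = 0.5,
``se^2 = [ (1/nA) (1/(mA+c0) + alpha) + (1/nB) (1/(mB+c0) + alpha) ] / ln(2)^2``,

where mA, mB are group means of normalized counts — the delta-method
variance of a log mean of NB counts.  Genes with both group means zero
get p = 1 and lfc = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import norm

from .datamodel import (
    ConfigError,
    ContrastError,
    CountMatrix,
    DomainError,
    GeneSignature,
    NormalizationError,
)

__all__ = [
    "DEResult",
    "SignatureFilter",
    "rle_size_factors",
    "estimate_dispersions",
    "fit_dispersion_trend",
    "shrink_dispersions",
    "wald_de_test",
    "bh_adjust",
    "build_signature",
    "run_de",
]

ALPHA_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """Per-gene differential-expression table plus the fit's nuisance
    parameters (per-sample size factors, per-gene dispersions)."""

    gene_ids: list[str]
    base_mean: np.ndarray
    lfc: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    padj: np.ndarray
    size_factors: np.ndarray
    dispersions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "base_mean": self.base_mean,
                "lfc": self.lfc,
                "se": self.se,
                "p_value": self.p_value,
                "padj": self.padj,
                "dispersion": self.dispersions,
            },
            index=pd.Index(self.gene_ids, name="gene"),
        )


@dataclass(frozen=True)
class SignatureFilter:
    """Thresholds turning a DE table into a gene signature: adjusted-p
    cutoff, minimum |log2 FC|, and a per-direction size cap."""

    alpha: float = 0.05
    lfc_min: float = 1.0
    max_per_direction: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.lfc_min < 0:
            raise ConfigError("lfc_min must be >= 0")
        if self.max_per_direction < 1:
            raise ConfigError("max_per_direction must be >= 1")


def rle_size_factors(counts: CountMatrix) -> np.ndarray:
    """Relative log expression (median-of-ratios) size factors.

    For each sample, the median over reference genes (genes positive in
    every sample) of count / geometric-mean-across-samples, then
    rescaled to geometric mean 1.
    """
    mat = counts.counts.astype(float)
    ref = np.all(mat > 0, axis=1)
    if not ref.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; cannot compute "
            "median-of-ratios size factors (try removing empty samples or "
            "filtering to expressed genes)"
        )
    log_geo = np.log(mat[ref]).mean(axis=1)
    s = np.exp(np.median(np.log(mat[ref]) - log_geo[:, None], axis=0))
    s /= np.exp(np.mean(np.log(s)))
    return s


def _group_stats(counts: CountMatrix, size_factors: np.ndarray):
    mask_a, mask_b = counts.group_masks()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ContrastError("each group needs >= 2 samples for DE")
    norm_counts = counts.counts / size_factors[None, :]
    a, b = norm_counts[:, mask_a], norm_counts[:, mask_b]
    return a, b


def _mom_dispersion_raw(
    counts: CountMatrix, size_factors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unfloored method-of-moments dispersion plus per-gene base mean.

    The raw value ``(pooled within-group variance - pooled mean) /
    pooled mean^2`` may be negative by sampling noise; keeping the sign
    matters for an unbiased trend fit.
    """
    a, b = _group_stats(counts, size_factors)
    pooled_mean = (a.mean(axis=1) + b.mean(axis=1)) / 2.0
    na, nb = a.shape[1], b.shape[1]
    pooled_var = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - pooled_mean) / pooled_mean**2
    raw = np.where(pooled_mean > 0, raw, 0.0)
    return raw, pooled_mean


def estimate_dispersions(counts: CountMatrix, size_factors: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion per gene.

    Using within-group deviations of normalized counts:
    ``alpha = max(floor, (pooled within-group variance - pooled mean)
    / pooled mean^2)`` with floor 1e-8; zero-mean genes get the floor.
    """
    raw, pooled_mean = _mom_dispersion_raw(counts, size_factors)
    raw = np.where(pooled_mean > 0, raw, ALPHA_FLOOR)
    return np.maximum(raw, ALPHA_FLOOR)


def fit_dispersion_trend(dispersions: np.ndarray, base_means: np.ndarray) -> np.ndarray:
    """Fit the mean–dispersion trend ``alpha(mu) = a0 + a1/mu`` by
    nonnegative least squares over genes with base mean > 1 and evaluate
    it at every gene's mean.

    Pass *unfloored* moment estimates (negatives kept) for an unbiased
    fit; restricting to positive estimates selects high-noise genes and
    biases the trend upward.
    """
    keep = base_means > 1.0
    if keep.sum() < 10:  # too few informative genes: flat fallback
        positive = dispersions[dispersions > ALPHA_FLOOR]
        level = float(np.median(positive)) if positive.size else ALPHA_FLOOR
        return np.full_like(dispersions, max(level, ALPHA_FLOOR))
    design = np.column_stack([np.ones(int(keep.sum())), 1.0 / base_means[keep]])
    coef, _ = nnls(design, dispersions[keep])
    trend = coef[0] + coef[1] / np.maximum(base_means, 1e-8)
    return np.maximum(trend, ALPHA_FLOOR)


#: A gene keeps its own dispersion estimate only when it exceeds the
#: trend by this factor (a genuine overdispersion outlier).
TREND_OUTLIER_FACTOR = 3.0


def shrink_dispersions(dispersions: np.ndarray, base_means: np.ndarray) -> np.ndarray:
    """Trend-shrunk dispersions used by the default pipeline.

    With a handful of replicates the per-gene moment estimator is far
    too noisy to plug into a Wald test directly.  Each gene therefore
    uses the fitted mean–dispersion trend unless its own estimate
    exceeds ``TREND_OUTLIER_FACTOR`` times the trend, in which case the
    (higher) per-gene value is kept — genuinely over-dispersed genes
    stay conservative while the bulk follows the trend.
    """
    trend = fit_dispersion_trend(dispersions, base_means)
    out = np.where(dispersions > TREND_OUTLIER_FACTOR * trend, dispersions, trend)
    return np.maximum(out, ALPHA_FLOOR)


def wald_de_test(
    counts: CountMatrix, size_factors: np.ndarray, dispersions: np.ndarray
) -> DEResult:
    """NB Wald test of the B-vs-A log2 fold change (see module docstring)."""
    a, b = _group_stats(counts, size_factors)
    na, nb = a.shape[1], b.shape[1]
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    c0 = PSEUDOCOUNT
    lfc = np.log2((m_b + c0) / (m_a + c0))
    se2 = (
        (1.0 / na) * (1.0 / (m_a + c0) + dispersions)
        + (1.0 / nb) * (1.0 / (m_b + c0) + dispersions)
    ) / np.log(2.0) ** 2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2.0 * norm.sf(np.abs(z))
    both_zero = (m_a == 0) & (m_b == 0)
    lfc = np.where(both_zero, 0.0, lfc)
    p = np.where(both_zero, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return DEResult(
        gene_ids=list(counts.gene_ids),
        base_mean=(m_a + m_b) / 2.0,
        lfc=lfc,
        se=se,
        p_value=p,
        padj=bh_adjust(p),
        size_factors=size_factors,
        dispersions=dispersions,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``padj_(i) = min_{j >= i} min(1, m * p_(j) / j)`` over the sorted
    p-values (cumulative-minimum enforcement of monotonicity).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DomainError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def build_signature(
    de: DEResult,
    filt: SignatureFilter | None = None,
    name: str = "signature",
    provenance: dict | None = None,
) -> GeneSignature:
    """Filter a DE table into up/down gene lists.

    Up = {padj <= alpha, lfc >= lfc_min}; down = {padj <= alpha,
    lfc <= -lfc_min}.  Each direction is truncated to the
    ``max_per_direction`` smallest p-values, ties broken by larger
    |lfc| then lexicographic gene id.  An empty signature is returned
    (not an error) and flagged by ``GeneSignature.is_empty``; the
    connectivity stage refuses empty signatures.
    """
    filt = filt or SignatureFilter()
    prov = dict(provenance or {})
    prov.setdefault("f", 1.0)
    prov.update(alpha=filt.alpha, lfc_min=filt.lfc_min, cap=filt.max_per_direction)

    genes = np.asarray(de.gene_ids)
    sig_sets: dict[str, frozenset[str]] = {}
    scores: dict[str, float] = {}
    for direction, mask in (
        ("up", (de.padj <= filt.alpha) & (de.lfc >= filt.lfc_min)),
        ("down", (de.padj <= filt.alpha) & (de.lfc <= -filt.lfc_min)),
    ):
        idx = np.flatnonzero(mask)
        keyed = sorted(
            idx, key=lambda i: (de.p_value[i], -abs(de.lfc[i]), genes[i])
        )[: filt.max_per_direction]
        sig_sets[direction] = frozenset(genes[i] for i in keyed)
        scores.update({str(genes[i]): float(de.lfc[i]) for i in keyed})
    return GeneSignature(
        name=name,
        up=sig_sets["up"],
        down=sig_sets["down"],
        scores=scores,
        provenance=prov,
    )


def run_de(counts: CountMatrix, shrink: bool = True) -> DEResult:
    """Full DE stage: RLE size factors, MoM dispersions (trend-shrunk by
    default), Wald test, BH adjustment."""
    s = rle_size_factors(counts)
    if shrink:
        raw, base_mean = _mom_dispersion_raw(counts, s)
        alpha = shrink_dispersions(raw, base_mean)
    else:
        alpha = estimate_dispersions(counts, s)
    return wald_de_test(counts, s, alpha)
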