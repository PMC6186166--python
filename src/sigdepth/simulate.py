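"""Synthetic data with planted ground truth.

Real depth-robustness studies start from tumour RNA-seq counts and a
large compendium of compound-induced expression profiles; neither fits
on a desk, so this module generates both with known truth:

* two-group negative-binomial counts with a stated fraction of
  differentially expressed genes, a mean–dispersion trend and
  log-normal library-size variation;
* a reference library with planted *reversers* (profiles opposing the
  disease contrast), planted *progressors* (mimicking it) and null
  perturbagens, replicated across cell lines with independent noise;
* GO-term-like gene categories with optional gene-length bias so the
  length-corrected enrichment stage has signal.

Every generator is a pure function of its seed.  One master seed
expands into per-component child seeds via :func:`child_seed`, which
hashes a label path into a ``numpy`` ``SeedSequence`` spawn key, so any
stage of a large grid can be reproduced in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .datamodel import ConfigError, CountMatrix, ReferenceLibrary

__all__ = [
    "SimConfig",
    "SimTruth",
    "child_seed",
    "generate_counts",
    "generate_reference_library",
    "generate_annotation",
]


def child_seed(master: int, *labels: object) -> int:
    """Derive a reproducible child seed from a master seed and a label path.

    Labels are stringified, CRC32-hashed and used as the spawn key of a
    ``SeedSequence`` rooted at ``master``; the result is folded into
    [0, 2^31) so it is usable anywhere an integer seed is accepted.
    """
    key = tuple(zlib.crc32(str(label).encode("utf-8")) for label in labels)
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=key)
    return int(ss.generate_state(1, np.uint64)[0] % (2**31))


@dataclass(frozen=True)
class SimConfig:
    """Scale and effect sizes of the synthetic study.

    Defaults are a desk-scale analogue of a whole-transcriptome cohort:
    2,000 genes, 6 vs 6 samples, 10% DE genes at |log2 FC| = 2, and a
    40-perturbagen x 3-cell-line library with 8 planted reversers and
    8 planted progressors at planted effect size kappa = 3.  The default
    expected depth (150,000 gene-assigned reads per sample, ~75 reads
    per gene, CV 0.3) places the full data comfortably above the
    detection limit and the lowest standard fraction (f = 0.01, ~0.75
    reads per gene) below it, so a thinning grid spans the whole
    detection transition rather than staying saturated.
    """

    n_genes: int = 2000
    n_per_group: int = 6
    pi_de: float = 0.1
    lfc_magnitude: float = 2.0
    #: (a0, a1) of the dispersion trend alpha(mu) = a0 + a1 / mu
    dispersion_params: tuple[float, float] = (0.05, 5.0)
    depth_mean: float = 150_000.0
    depth_cv: float = 0.3
    n_perturbagens: int = 40
    n_cell_lines: int = 3
    planted_effect: float = 3.0
    n_reversers: int = 8
    n_progressors: int = 8
    n_neuronal_cell_lines: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_per_group", "n_perturbagens", "n_cell_lines"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 < self.pi_de < 1.0:
            raise ConfigError("pi_de must lie in (0, 1)")
        if round(self.pi_de * self.n_genes) < 1:
            raise ConfigError("pi_de * n_genes must plant at least one DE gene")
        if self.lfc_magnitude < 0:
            raise ConfigError("lfc_magnitude must be >= 0")
        a0, a1 = self.dispersion_params
        if a0 < 0 or a1 < 0:
            raise ConfigError("dispersion_params must be nonnegative")
        if self.depth_mean <= 0 or self.depth_cv < 0:
            raise ConfigError("depth_mean must be positive, depth_cv nonnegative")
        if self.planted_effect < 0:
            raise ConfigError("planted_effect (kappa) must be >= 0")
        if self.n_reversers + self.n_progressors > self.n_perturbagens:
            raise ConfigError(
                "n_reversers + n_progressors exceeds n_perturbagens"
            )
        if not 0 <= self.n_neuronal_cell_lines <= self.n_cell_lines:
            raise ConfigError("n_neuronal_cell_lines outside [0, n_cell_lines]")


@dataclass
class SimTruth:
    """Planted ground truth of one synthetic study.

    ``de_genes`` maps gene id -> true log2 fold change (nonzero only for
    planted DE genes).  Reverser / progressor / null ids partition the
    perturbagen set.  ``category_truth`` is filled by
    :func:`generate_annotation` when categories are planted.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    reverser_ids: set[str] = field(default_factory=set)
    progressor_ids: set[str] = field(default_factory=set)
    null_ids: set[str] = field(default_factory=set)
    category_truth: dict[str, bool] | None = None


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _pert_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"pert{i:0{width}d}" for i in range(1, n + 1)]


def generate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a two-group NB count matrix with planted DE genes.

    Counts for gene g in sample j are NB with mean
    ``s_j * q_g * 2**(x_j * beta_g)`` and dispersion
    ``alpha(q_g) = a0 + a1/q_g``; x_j is the group indicator (0 for A,
    1 for B), beta_g = +-lfc_magnitude for planted genes (random sign,
    recorded in the returned truth) and 0 otherwise.  Baselines q_g are
    log-normal, rescaled so the expected library size is ``depth_mean``;
    per-sample factors s_j are log-normal with mean 1 and CV
    ``depth_cv``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(child_seed(config.seed, "counts"))
    n_genes, n = config.n_genes, config.n_per_group
    genes = _gene_ids(n_genes)

    q = np.exp(rng.normal(0.0, 1.0, n_genes))
    q *= config.depth_mean / q.sum()

    n_de = int(round(config.pi_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    beta = np.zeros(n_genes)
    beta[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * config.lfc_magnitude

    if config.depth_cv > 0:
        sigma2 = np.log1p(config.depth_cv**2)
        s = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), 2 * n))
    else:
        s = np.ones(2 * n)

    x = np.r_[np.zeros(n), np.ones(n)]  # group indicator per sample
    mu = s[None, :] * q[:, None] * np.power(2.0, np.outer(beta, x))
    a0, a1 = config.dispersion_params
    alpha = a0 + a1 / q
    counts = np.empty((n_genes, 2 * n), dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        counts[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        r = 1.0 / alpha[~poisson]
        p = r[:, None] / (r[:, None] + mu[~poisson])
        counts[~poisson] = rng.negative_binomial(r[:, None], p)

    cm = CountMatrix(
        gene_ids=genes,
        sample_ids=[f"A{j + 1:02d}" for j in range(n)] + [f"B{j + 1:02d}" for j in range(n)],
        counts=counts,
        groups=["A"] * n + ["B"] * n,
    )
    truth = SimTruth(
        de_genes={genes[i]: float(beta[i]) for i in np.sort(de_idx)}
    )
    return cm, truth


def generate_reference_library(
    truth: SimTruth, config: SimConfig
) -> tuple[ReferenceLibrary, SimTruth]:
    """Build a perturbagen x cell-line profile library around the truth.

    Reverser profiles score ``-kappa * sign(beta_g) + eps`` on planted
    DE genes (so they oppose the disease contrast), progressors
    ``+kappa * sign(beta_g) + eps``, null perturbagens pure standard
    normal noise; eps is drawn independently for every profile.  The
    first ``n_neuronal_cell_lines`` cell lines are tagged "neuronal".
    The returned truth is the input with the perturbagen partition
    recorded.
    """
    if not truth.de_genes:
        raise ConfigError("truth must contain at least one planted DE gene")
    rng = np.random.default_rng(child_seed(config.seed, "library"))
    genes = _gene_ids(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    perts = _pert_ids(config.n_perturbagens)

    order = rng.permutation(config.n_perturbagens)
    rev = {perts[i] for i in order[: config.n_reversers]}
    prog = {perts[i] for i in order[config.n_reversers: config.n_reversers + config.n_progressors]}
    null = set(perts) - rev - prog

    signal = np.zeros(config.n_genes)
    for g, beta in truth.de_genes.items():
        signal[gene_pos[g]] = np.sign(beta)

    cell_lines = [f"CL{c + 1}" for c in range(config.n_cell_lines)]
    n_profiles = config.n_perturbagens * config.n_cell_lines
    scores = rng.standard_normal((config.n_genes, n_profiles))
    col_perts: list[str] = []
    col_cells: list[str] = []
    j = 0
    for p in perts:
        for cl in cell_lines:
            if p in rev:
                scores[:, j] -= config.planted_effect * signal
            elif p in prog:
                scores[:, j] += config.planted_effect * signal
            col_perts.append(p)
            col_cells.append(cl)
            j += 1

    tags = {
        cl: ({"neuronal"} if c < config.n_neuronal_cell_lines else set())
        for c, cl in enumerate(cell_lines)
    }
    lib = ReferenceLibrary(
        gene_universe=genes,
        scores=scores,
        perturbagens=col_perts,
        cell_lines=col_cells,
        cell_line_tags=tags,
    )
    truth.reverser_ids = rev
    truth.progressor_ids = prog
    truth.null_ids = null
    return lib, truth


def generate_annotation(
    gene_ids: list[str],
    n_categories: int,
    size_range: tuple[int, int],
    length_bias: bool,
    seed: int,
    de_genes: Mapping[str, float] | None = None,
) -> tuple[dict[str, set[str]], np.ndarray]:
    """Sample gene categories and log-normal gene lengths.

    Returns ``(categories, gene_lengths)`` where ``categories`` maps
    category id to a gene set sampled without replacement and
    ``gene_lengths`` aligns with ``gene_ids`` (bases).  With
    ``length_bias`` set, planted DE genes (``de_genes`` keys, required)
    receive systematically longer transcripts, so P(DE | length)
    increases with length and the probability-weighting stage has
    signal to detect.  Deterministic given ``seed``.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ConfigError(f"invalid size_range {size_range}")
    if hi > len(gene_ids):
        raise ConfigError("max category size exceeds number of genes")
    if length_bias and not de_genes:
        raise ConfigError("length_bias requires the planted de_genes map")
    rng = np.random.default_rng(child_seed(seed, "annotation"))

    n_genes = len(gene_ids)
    lengths = np.exp(rng.normal(np.log(1500.0), 0.6, n_genes))
    if length_bias:
        de_mask = np.array([g in de_genes for g in gene_ids])
        # shift DE transcripts ~2.2x longer on the log scale
        lengths[de_mask] *= np.exp(0.8)
    lengths = np.maximum(np.round(lengths).astype(np.int64), 1)

    width = max(3, len(str(n_categories)))
    categories: dict[str, set[str]] = {}
    arr = np.asarray(gene_ids)
    for c in range(1, n_categories + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        categories[f"cat{c:0{width}d}"] = set(arr[members])
    return categories, lengths
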