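"""Connectivity mapping: score a gene signature against a reference
profile library and assign permutation significance.

The score is the simplest member of the sscMap family.  For a profile
with per-gene DE scores z over the universe U and a signature with up
set *u* and down set *d* (unit gene weights),

    raw     = sum_{g in u∩U} z(g) - sum_{g in d∩U} z(g)
    max_raw = sum of the k largest |z| in the profile, k = |(u∪d)∩U|
    score   = raw / max_raw  in [-1, 1].

A negative score means the profile opposes the signature (a *rev*
connection, the therapeutic direction); positive means it mimics it
(*prog*).  Significance comes from a permutation null of random
signatures with the same up/down sizes drawn uniformly from U; the same
null signatures are reused across every profile of a query (common
random numbers), which stabilises cross-perturbagen comparisons.  When
the signed-subset space is small enough the null is enumerated
exhaustively and p-values are exact.

Perturbagen-level results average profile scores and test the mean
against the mean of the same null draws, then BH across perturbagens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import sparse

from .datamodel import (
    ConfigError,
    ConnectionResult,
    CoverageError,
    GeneSignature,
    ReferenceLibrary,
)
from .diffexp import bh_adjust

__all__ = [
    "ConnectivityConfig",
    "connection_score",
    "score_profiles",
    "signature_coverage",
    "permutation_pvalues",
    "aggregate_and_classify",
    "connectivity_query",
]

logger = logging.getLogger("sigdepth")

#: Exhaustive-null feasibility bound on C(|U|, k) * 2**k.
EXHAUSTIVE_LIMIT = 1_000_000


@dataclass(frozen=True)
class ConnectivityConfig:
    """Permutation count, significance level, aggregation level
    (``"perturbagen"`` or ``"profile"``), optional cell-line tag filter,
    and the RNG seed for the permutation null."""

    M: int = 10_000
    alpha_conn: float = 0.05
    aggregation_level: str = "perturbagen"
    cell_line_filter: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 100:
            raise ConfigError("permutation count M must be >= 100")
        if not 0.0 < self.alpha_conn < 1.0:
            raise ConfigError("alpha_conn must lie in (0, 1)")
        if self.aggregation_level not in ("perturbagen", "profile"):
            raise ConfigError("aggregation_level must be 'perturbagen' or 'profile'")


def _signature_indices(
    signature: GeneSignature, library: ReferenceLibrary
) -> tuple[np.ndarray, np.ndarray]:
    if signature.is_empty:
        raise CoverageError(
            f"signature {signature.name!r} is empty; nothing to score"
        )
    up_idx = library.gene_index(signature.up)
    dn_idx = library.gene_index(signature.down)
    if up_idx.size + dn_idx.size == 0:
        raise CoverageError(
            f"signature {signature.name!r} shares no genes with the library universe"
        )
    return up_idx, dn_idx


def signature_coverage(
    signature: GeneSignature, library: ReferenceLibrary
) -> tuple[int, int]:
    """(genes used, genes dropped) when matching a signature to the
    library universe."""
    up_idx, dn_idx = _signature_indices(signature, library)
    used = int(up_idx.size + dn_idx.size)
    return used, len(signature.genes) - used


def _max_raw(z_abs_sorted: np.ndarray, k: int) -> float:
    # z_abs_sorted: |z| sorted descending for one profile
    return float(z_abs_sorted[:k].sum())


def connection_score(
    signature: GeneSignature, profile: np.ndarray, gene_universe: Sequence[str]
) -> float:
    """Score one signature against one profile vector (see module
    docstring).  Genes outside the universe are dropped."""
    z = np.asarray(profile, dtype=float)
    pos = {g: i for i, g in enumerate(gene_universe)}
    up_idx = np.array([pos[g] for g in signature.up if g in pos], dtype=np.intp)
    dn_idx = np.array([pos[g] for g in signature.down if g in pos], dtype=np.intp)
    k = up_idx.size + dn_idx.size
    if k == 0:
        raise CoverageError(
            f"signature {signature.name!r} shares no genes with the universe"
        )
    raw = z[up_idx].sum() - z[dn_idx].sum()
    max_raw = _max_raw(np.sort(np.abs(z))[::-1], k)
    return float(raw / max_raw) if max_raw > 0 else 0.0


def score_profiles(
    signature: GeneSignature, library: ReferenceLibrary
) -> np.ndarray:
    """Vector of connection scores against every library profile."""
    up_idx, dn_idx = _signature_indices(signature, library)
    dropped = len(signature.genes) - (up_idx.size + dn_idx.size)
    if dropped:
        logger.warning(
            "signature %s: %d gene(s) outside the library universe dropped",
            signature.name, dropped,
        )
    z = library.scores
    raw = z[up_idx].sum(axis=0) - z[dn_idx].sum(axis=0)
    k = up_idx.size + dn_idx.size
    z_abs = np.sort(np.abs(z), axis=0)[::-1]
    max_raw = z_abs[:k].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(max_raw > 0, raw / max_raw, 0.0)
    return scores


def _exhaustive_feasible(u: int, k: int) -> bool:
    return comb(u, k) * (2**k) <= EXHAUSTIVE_LIMIT


def _null_scores(
    signature: GeneSignature, library: ReferenceLibrary, config: ConnectivityConfig
) -> tuple[np.ndarray, bool]:
    """Null connection-score matrix (draws x profiles) plus an
    exhaustive-mode flag.

    Monte-Carlo mode draws ``config.M`` random signatures with the
    observed up/down sizes, uniformly without replacement from the
    universe.  Exhaustive mode enumerates every (up-set, down-set) pair
    with those sizes when the signed-subset space is small enough, so
    the resulting p-values are exact.
    """
    up_idx, dn_idx = _signature_indices(signature, library)
    k_up, k_dn = int(up_idx.size), int(dn_idx.size)
    k = k_up + k_dn
    u = len(library.gene_universe)
    z = library.scores
    z_abs = np.sort(np.abs(z), axis=0)[::-1]
    max_raw = z_abs[:k].sum(axis=0)
    max_raw = np.where(max_raw > 0, max_raw, 1.0)

    if _exhaustive_feasible(u, k):
        rows_idx: list[np.ndarray] = []
        rows_dat: list[np.ndarray] = []
        for subset in combinations(range(u), k):
            subset = np.asarray(subset, dtype=np.intp)
            for up_positions in combinations(range(k), k_up):
                signs = -np.ones(k)
                signs[list(up_positions)] = 1.0
                rows_idx.append(subset)
                rows_dat.append(signs)
        n_rows = len(rows_idx)
        indptr = np.arange(0, (n_rows + 1) * k, k)
        s_mat = sparse.csr_matrix(
            (np.concatenate(rows_dat), np.concatenate(rows_idx), indptr),
            shape=(n_rows, u),
        )
        null = (s_mat @ z) / max_raw[None, :]
        return null, True

    rng = np.random.default_rng(config.seed)
    m = config.M
    null = np.empty((m, z.shape[1]))
    chunk = max(1, 4_000_000 // max(u, 1))
    base = np.arange(u, dtype=np.intp)
    signs = np.r_[np.ones(k_up), -np.ones(k_dn)]
    done = 0
    while done < m:
        rows = min(chunk, m - done)
        perm = rng.permuted(np.tile(base, (rows, 1)), axis=1)[:, :k]
        indptr = np.arange(0, (rows + 1) * k, k)
        s_mat = sparse.csr_matrix(
            (np.tile(signs, rows), perm.ravel(), indptr), shape=(rows, u)
        )
        null[done: done + rows] = (s_mat @ z) / max_raw[None, :]
        done += rows
    return null, False


def _tail_p(null_abs: np.ndarray, obs_abs: np.ndarray, exact: bool) -> np.ndarray:
    """Two-sided tail probability of |score| under the null draws.

    Exhaustive mode returns the exact proportion (the observed
    configuration is one of the enumerated ones); Monte-Carlo mode uses
    the add-one estimator (1 + #exceed) / (M + 1), so p >= 1/(M+1).
    """
    count = (null_abs >= obs_abs[None, :] - 1e-12).sum(axis=0)
    n = null_abs.shape[0]
    if exact:
        return np.maximum(count, 1) / n
    return (1.0 + count) / (n + 1.0)


def permutation_pvalues(
    signature: GeneSignature,
    library: ReferenceLibrary,
    config: ConnectivityConfig | None = None,
) -> np.ndarray:
    """Per-profile permutation p-values for |score| (see
    :func:`_null_scores` for the null construction)."""
    config = config or ConnectivityConfig()
    obs = score_profiles(signature, library)
    null, exact = _null_scores(signature, library, config)
    return _tail_p(np.abs(null), np.abs(obs), exact)


def aggregate_and_classify(
    scores: np.ndarray,
    null_scores: np.ndarray,
    exact: bool,
    library: ReferenceLibrary,
    config: ConnectivityConfig,
) -> list[ConnectionResult]:
    """Aggregate per-profile scores to the configured level, BH-adjust,
    flag significance and classify direction.

    Perturbagen level: the observed statistic is the mean profile score
    and its null is the mean of the same null draws across that
    perturbagen's profiles.  Output is ranked by signed score (most
    negative — strongest rev — first).
    """
    results: list[ConnectionResult] = []
    if config.aggregation_level == "profile":
        p = _tail_p(np.abs(null_scores), np.abs(scores), exact)
        q = bh_adjust(p)
        for j in range(library.n_profiles):
            s = float(scores[j])
            results.append(
                ConnectionResult(
                    perturbagen=library.perturbagens[j],
                    cell_line=library.cell_lines[j],
                    score=s,
                    p_value=float(p[j]),
                    q_value=float(q[j]),
                    significant=bool(q[j] <= config.alpha_conn and s != 0.0),
                )
            )
    else:
        perts = library.perturbagen_ids
        obs_mean = np.empty(len(perts))
        null_mean = np.empty((null_scores.shape[0], len(perts)))
        for i, pert in enumerate(perts):
            cols = library.profile_columns(pert)
            obs_mean[i] = scores[cols].mean()
            null_mean[:, i] = null_scores[:, cols].mean(axis=1)
        p = _tail_p(np.abs(null_mean), np.abs(obs_mean), exact)
        q = bh_adjust(p)
        for i, pert in enumerate(perts):
            s = float(obs_mean[i])
            results.append(
                ConnectionResult(
                    perturbagen=pert,
                    cell_line=None,
                    score=s,
                    p_value=float(p[i]),
                    q_value=float(q[i]),
                    significant=bool(q[i] <= config.alpha_conn and s != 0.0),
                )
            )
    results.sort(key=lambda r: (r.score, r.perturbagen))
    return results


def connectivity_query(
    signature: GeneSignature,
    library: ReferenceLibrary,
    config: ConnectivityConfig | None = None,
) -> list[ConnectionResult]:
    """Full query: optional cell-line filter, scoring, shared
    permutation null, aggregation and rev/prog classification."""
    config = config or ConnectivityConfig()
    lib = library
    if config.cell_line_filter is not None:
        lib = library.filter_cell_lines(config.cell_line_filter)
        dropped = set(library.perturbagen_ids) - set(lib.perturbagen_ids)
        if dropped:
            logger.warning(
                "%d perturbagen(s) dropped by cell-line filter %r",
                len(dropped), config.cell_line_filter,
            )
    scores = score_profiles(signature, lib)
    null, exact = _null_scores(signature, lib, config)
    return aggregate_and_classify(scores, null, exact, lib, config)
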