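"""Fraction x iteration robustness grid and its stability statistics.

For every retention fraction f in the grid and every iteration the
pipeline is rerun end to end on a fresh thinning of the full count
matrix: thin -> normalize -> DE test -> signature -> connectivity
query.  The full-data run (f = 1) is executed once and serves as the
reference.  Stability of the drug-repurposing output is then summarised
by:

* per-fraction means and percentile confidence intervals of the DEG
  count and of the significant rev / prog connection counts;
* the *relative FDR*: the fraction of connections significant at
  (f, iteration) that are absent from the full-data reference set —
  treated as false positives because the complete data did not support
  them;
* per-connection *frequency*: the share of the K iterations at a
  fraction in which a connection is significant;
* a Venn partition of per-fraction consensus connection sets (a
  connection belongs to a fraction's set when its frequency reaches the
  consensus threshold), with lost / gained / consistent views relative
  to the reference;
* top-k compound stability: per-fraction rankings of the strongest
  reversers and their pairwise overlap / Jaccard.

Everything is a pure function of (inputs, config, master seed): child
seeds for each grid cell derive from the master seed and the cell's
(f, iteration) labels, and summaries serialize to byte-identical JSON
across reruns.  When an output directory is given, per-cell results are
persisted and already-computed cells are skipped on resume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .connectivity import ConnectivityConfig, connectivity_query
from .datamodel import (
    ConfigError,
    CountMatrix,
    DomainError,
    NormalizationError,
    ReferenceLibrary,
    SigdepthError,
    write_manifest,
)
from .diffexp import SignatureFilter, build_signature, run_de
from .simulate import child_seed
from .subsample import FractionGrid, thin_counts

__all__ = [
    "RobustnessSummary",
    "run_grid",
    "relative_fdr",
    "connection_frequency",
    "venn_partition",
    "topk_stability",
    "summarize_ci",
]

logger = logging.getLogger("sigdepth")


# ---------------------------------------------------------------------------
# Elementary statistics

def summarize_ci(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Mean with a percentile confidence interval (linear-interpolation
    percentiles; 2.5/97.5 at the default level).  A single value yields
    the degenerate interval (v, v, v)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("summarize_ci needs at least one value")
    if not 0.0 < level < 1.0:
        raise DomainError("level must lie in (0, 1)")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [tail, 100.0 - tail])
    return float(arr.mean()), float(lo), float(hi)


def relative_fdr(s_f: set, s_1: set) -> float:
    """|S_f \\ S_1| / |S_f| — the share of connections at fraction f not
    supported by the full-data reference set; 0 when S_f is empty."""
    if not s_f:
        logger.debug("relative_fdr: empty significant set at fraction; returning 0")
        return 0.0
    return len(s_f - s_1) / len(s_f)


def connection_frequency(iteration_sets: Sequence[set]) -> dict:
    """Per-connection detection frequency over K iteration sets.

    Connections never significant are absent from the returned map.
    """
    if len(iteration_sets) < 1:
        raise DomainError("need at least one iteration")
    k = len(iteration_sets)
    counts: dict = {}
    for s in iteration_sets:
        for item in s:
            counts[item] = counts.get(item, 0) + 1
    return {item: n / k for item, n in counts.items()}


def venn_partition(
    sets_by_fraction: Mapping[float, set], fraction_subset: Sequence[float]
) -> dict[tuple[float, ...], set]:
    """Exhaustive Venn regions over the chosen fractions.

    The region keyed by a tuple of fractions holds the connections in
    *all* of those fractions' sets and *none* of the others; regions are
    pairwise disjoint and their union is the union of the input sets.
    """
    subset = tuple(fraction_subset)
    missing = [f for f in subset if f not in sets_by_fraction]
    if missing:
        raise ConfigError(f"fractions {missing} not present in sets_by_fraction")
    if len(set(subset)) != len(subset) or not subset:
        raise ConfigError("fraction_subset must be nonempty and distinct")
    regions: dict[tuple[float, ...], set] = {}
    for r in range(1, len(subset) + 1):
        for included in combinations(subset, r):
            excluded = [f for f in subset if f not in included]
            region = set.intersection(*(set(sets_by_fraction[f]) for f in included))
            for f in excluded:
                region -= set(sets_by_fraction[f])
            regions[included] = region
    return regions


def topk_stability(
    scores_by_fraction: Mapping[float, Mapping[str, tuple[float, float]]],
    k: int = 50,
) -> dict:
    """Per-fraction top-k reverser rankings and their pairwise overlap.

    ``scores_by_fraction[f][perturbagen] = (score, q)``.  Ranking is by
    most-negative score (strongest rev first), ties broken by smaller q
    then lexicographic id; lists are truncated at k (the full list, with
    a warning, when fewer perturbagens are available).  Returns ranked
    lists plus overlap counts and Jaccard indices for every fraction
    pair.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    ranked: dict[float, list[str]] = {}
    for f, table in scores_by_fraction.items():
        if len(table) < k:
            logger.warning(
                "fraction %g has only %d perturbagens (< k=%d); using all",
                f, len(table), k,
            )
        order = sorted(table, key=lambda p: (table[p][0], table[p][1], p))
        ranked[f] = order[:k]
    overlap: dict[tuple[float, float], int] = {}
    jaccard: dict[tuple[float, float], float] = {}
    for f1, f2 in combinations(sorted(ranked), 2):
        a, b = set(ranked[f1]), set(ranked[f2])
        overlap[(f1, f2)] = len(a & b)
        union = a | b
        jaccard[(f1, f2)] = len(a & b) / len(union) if union else 1.0
    return {"k": k, "ranked": ranked, "overlap": overlap, "jaccard": jaccard}


# ---------------------------------------------------------------------------
# Grid orchestration

_DIRECTIONS = ("rev", "prog")
_PREFERRED_VENN = (0.01, 0.1, 0.5, 1.0)


@dataclass
class RobustnessSummary:
    """Aggregated stability statistics of one robustness grid run."""

    fractions: list[float]
    iterations: int
    master_seed: int
    #: per fraction: statistic -> (mean, ci_lo, ci_hi)
    per_fraction: dict[float, dict[str, tuple[float, float, float]]]
    #: per fraction: (perturbagen, direction) -> frequency in [0, 1]
    frequencies: dict[float, dict[tuple[str, str], float]]
    #: per fraction: direction -> consensus perturbagen set
    consensus: dict[float, dict[str, set[str]]]
    consensus_threshold: float
    #: reference (f = 1) significant sets, per direction
    reference: dict[str, set[str]]
    #: Venn over rev consensus sets: fractions used + region memberships
    venn: dict
    #: per fraction (rev direction): consensus-set differences vs reference
    gained: dict[float, set[str]]
    lost: dict[float, set[str]]
    consistent: set[str]
    topk: dict

    def to_dict(self) -> dict:
        fkey = lambda f: f"{f:g}"  # noqa: E731
        return {
            "fractions": [fkey(f) for f in self.fractions],
            "iterations": self.iterations,
            "master_seed": self.master_seed,
            "consensus_threshold": self.consensus_threshold,
            "per_fraction": {
                fkey(f): {k: list(v) for k, v in stats.items()}
                for f, stats in self.per_fraction.items()
            },
            "frequencies": {
                fkey(f): {f"{p}|{d}": fr for (p, d), fr in sorted(freqs.items())}
                for f, freqs in self.frequencies.items()
            },
            "consensus": {
                fkey(f): {d: sorted(s) for d, s in by_dir.items()}
                for f, by_dir in self.consensus.items()
            },
            "reference": {d: sorted(s) for d, s in self.reference.items()},
            "venn": {
                "fractions": [fkey(f) for f in self.venn["fractions"]],
                "regions": {
                    "&".join(fkey(f) for f in key): sorted(val)
                    for key, val in self.venn["regions"].items()
                },
            },
            "gained": {fkey(f): sorted(s) for f, s in self.gained.items()},
            "lost": {fkey(f): sorted(s) for f, s in self.lost.items()},
            "consistent": sorted(self.consistent),
            "topk": {
                "k": self.topk["k"],
                "ranked": {fkey(f): lst for f, lst in self.topk["ranked"].items()},
                "overlap": {
                    f"{fkey(a)}|{fkey(b)}": v
                    for (a, b), v in sorted(self.topk["overlap"].items())
                },
                "jaccard": {
                    f"{fkey(a)}|{fkey(b)}": v
                    for (a, b), v in sorted(self.topk["jaccard"].items())
                },
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"


def _run_cell(
    counts: CountMatrix,
    library: ReferenceLibrary,
    f: float,
    iteration: int,
    de_filter: SignatureFilter,
    conn_config: ConnectivityConfig,
    master_seed: int,
) -> dict:
    seed_thin = child_seed(master_seed, "thin", f"{f:g}", iteration)
    seed_conn = child_seed(master_seed, "conn", f"{f:g}", iteration)
    thinned = thin_counts(counts, f, seed_thin)
    sig = None
    n_deg = 0
    try:
        de = run_de(thinned)
    except NormalizationError:
        # thinned too sparse to normalize: the cell yields nothing
        logger.warning(
            "f=%g iteration %d: matrix too sparse to normalize; empty cell",
            f, iteration,
        )
    else:
        n_deg = int(
            ((de.padj <= de_filter.alpha) & (np.abs(de.lfc) >= de_filter.lfc_min)).sum()
        )
        sig = build_signature(
            de, de_filter, name=f"f{f:g}_i{iteration}",
            provenance={"f": f, "iteration": iteration},
        )
    cell: dict = {
        "f": f,
        "iteration": iteration,
        "seed_thin": seed_thin,
        "seed_conn": seed_conn,
        "n_deg": n_deg,
        "empty_signature": sig is None or sig.is_empty,
        "rev": [],
        "prog": [],
        "scores": {},
        "q": {},
    }
    if sig is None or sig.is_empty:
        if sig is not None:
            logger.warning("empty signature at f=%g iteration %d", f, iteration)
        return cell
    results = connectivity_query(
        sig, library, replace(conn_config, seed=seed_conn)
    )
    cell["rev"] = sorted(
        r.perturbagen for r in results if r.significant and r.direction == "rev"
    )
    cell["prog"] = sorted(
        r.perturbagen for r in results if r.significant and r.direction == "prog"
    )
    cell["scores"] = {r.perturbagen: r.score for r in results}
    cell["q"] = {r.perturbagen: r.q_value for r in results}
    return cell


def _default_venn_fractions(fractions: Sequence[float]) -> tuple[float, ...]:
    preferred = tuple(f for f in _PREFERRED_VENN if f in fractions)
    if len(preferred) >= 2:
        return preferred
    return tuple(fractions[: min(3, len(fractions) - 1)]) + (1.0,)


def run_grid(
    counts: CountMatrix,
    library: ReferenceLibrary,
    grid: FractionGrid,
    de_filter: SignatureFilter | None = None,
    conn_config: ConnectivityConfig | None = None,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    consensus_threshold: float = 0.5,
    venn_fractions: Sequence[float] | None = None,
    top_k: int = 50,
) -> RobustnessSummary:
    """Execute the fraction x iteration grid and assemble the summary.

    The f = 1 cell runs once and defines the reference connection sets;
    it must yield a nonempty signature (otherwise there is nothing to
    compare against and the run aborts).  With ``out_dir`` set, per-cell
    JSON results, the summary and a run manifest are written there and
    completed cells are skipped on re-invocation.
    """
    de_filter = de_filter or SignatureFilter()
    conn_config = conn_config or ConnectivityConfig()
    if not 0.0 < consensus_threshold <= 1.0:
        raise ConfigError("consensus_threshold must lie in (0, 1]")
    venn_fr = (
        tuple(venn_fractions)
        if venn_fractions is not None
        else _default_venn_fractions(grid.fractions)
    )
    if any(f not in grid.fractions for f in venn_fr):
        raise ConfigError(f"venn fractions {venn_fr} must be a subset of the grid")

    cells_dir: Path | None = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        cells_dir = out_dir / "cells"
        cells_dir.mkdir(parents=True, exist_ok=True)

    cells: dict[float, list[dict]] = {}
    for f in grid.fractions:
        cells[f] = []
        for i in range(grid.iterations_at(f)):
            cell_path = (
                cells_dir / f"f{f:g}_i{i}.json" if cells_dir is not None else None
            )
            if cell_path is not None and cell_path.exists():
                cell = json.loads(cell_path.read_text())
            else:
                cell = _run_cell(
                    counts, library, f, i, de_filter, conn_config, master_seed
                )
                if cell_path is not None:
                    cell_path.write_text(json.dumps(cell, sort_keys=True))
            cells[f].append(cell)

    ref_cell = cells[1.0][0]
    if ref_cell["empty_signature"]:
        raise SigdepthError(
            "the full-data (f = 1) run produced an empty signature; there is "
            "no reference connection set to compare against"
        )
    reference = {d: set(ref_cell[d]) for d in _DIRECTIONS}

    per_fraction: dict[float, dict[str, tuple[float, float, float]]] = {}
    frequencies: dict[float, dict[tuple[str, str], float]] = {}
    consensus: dict[float, dict[str, set[str]]] = {}
    for f in grid.fractions:
        stats: dict[str, tuple[float, float, float]] = {}
        stats["n_deg"] = summarize_ci([c["n_deg"] for c in cells[f]])
        stats["n_sig_rev"] = summarize_ci([len(c["rev"]) for c in cells[f]])
        stats["n_sig_prog"] = summarize_ci([len(c["prog"]) for c in cells[f]])
        stats["fdr_rev"] = summarize_ci(
            [relative_fdr(set(c["rev"]), reference["rev"]) for c in cells[f]]
        )
        stats["fdr_prog"] = summarize_ci(
            [relative_fdr(set(c["prog"]), reference["prog"]) for c in cells[f]]
        )
        per_fraction[f] = stats
        iter_sets = [
            {(p, d) for d in _DIRECTIONS for p in c[d]} for c in cells[f]
        ]
        frequencies[f] = connection_frequency(iter_sets)
        consensus[f] = {
            d: {
                p
                for (p, dd), fr in frequencies[f].items()
                if dd == d and fr >= consensus_threshold
            }
            for d in _DIRECTIONS
        }

    rev_sets = {f: consensus[f]["rev"] for f in grid.fractions}
    venn = {
        "fractions": list(venn_fr),
        "regions": venn_partition(rev_sets, venn_fr),
    }
    gained = {f: rev_sets[f] - reference["rev"] for f in grid.fractions}
    lost = {f: reference["rev"] - rev_sets[f] for f in grid.fractions}
    consistent = set.intersection(*(rev_sets[f] for f in grid.fractions))

    scores_by_fraction = {
        f: _mean_scores(cells[f]) for f in grid.fractions
    }
    topk = topk_stability(scores_by_fraction, k=top_k)

    summary = RobustnessSummary(
        fractions=list(grid.fractions),
        iterations=grid.iterations,
        master_seed=master_seed,
        per_fraction=per_fraction,
        frequencies=frequencies,
        consensus=consensus,
        consensus_threshold=consensus_threshold,
        reference=reference,
        venn=venn,
        gained=gained,
        lost=lost,
        consistent=consistent,
        topk=topk,
    )
    if out_dir is not None:
        (out_dir / "summary.json").write_text(summary.to_json())
        write_manifest(
            out_dir / "manifest.json",
            seed=master_seed,
            config={
                "fractions": [f"{f:g}" for f in grid.fractions],
                "iterations": grid.iterations,
                "filter": {
                    "alpha": de_filter.alpha,
                    "lfc_min": de_filter.lfc_min,
                    "cap": de_filter.max_per_direction,
                },
                "connectivity": {
                    "M": conn_config.M,
                    "alpha_conn": conn_config.alpha_conn,
                    "aggregation_level": conn_config.aggregation_level,
                    "cell_line_filter": conn_config.cell_line_filter,
                },
                "consensus_threshold": consensus_threshold,
                "top_k": top_k,
            },
            extra={
                "cells": {
                    f"{f:g}": [
                        {
                            "iteration": c["iteration"],
                            "seed_thin": c["seed_thin"],
                            "seed_conn": c["seed_conn"],
                            "empty_signature": c["empty_signature"],
                        }
                        for c in cells[f]
                    ]
                    for f in grid.fractions
                }
            },
        )
    return summary


def _mean_scores(cells: list[dict]) -> dict[str, tuple[float, float]]:
    """Perturbagen -> (mean score, mean q) across a fraction's iterations."""
    acc: dict[str, list[tuple[float, float]]] = {}
    for c in cells:
        for p, s in c["scores"].items():
            acc.setdefault(p, []).append((s, c["q"][p]))
    return {
        p: (
            float(np.mean([s for s, _ in vals])),
            float(np.mean([q for _, q in vals])),
        )
        for p, vals in acc.items()
    }
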