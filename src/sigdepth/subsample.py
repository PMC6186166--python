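"""Sequencing-depth reduction by binomial thinning.

Reduced cDNA library depth is simulated by keeping each gene-assigned
read independently with probability ``f``: entry ``n`` of the count
matrix is replaced by a ``Binomial(n, f)`` draw.  When read-to-gene
assignment does not depend on depth this is distributionally equivalent
to subsampling the mapped reads themselves, which lets the whole
alignment stack stay out of scope.

Each (fraction, iteration) cell of a robustness grid is an independent
fresh thinning of the *full* matrix — fractions are not nested inside
one another — matching a design where every fraction is its own
simulated experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ConfigError, CountMatrix, DomainError

__all__ = ["FractionGrid", "thin_counts", "DEFAULT_FRACTIONS"]

#: Default fraction grid; covers two orders of magnitude of depth loss.
DEFAULT_FRACTIONS: tuple[float, ...] = (0.01, 0.1, 0.25, 0.5, 0.7, 0.8, 0.9, 0.99, 1.0)


@dataclass(frozen=True)
class FractionGrid:
    """Ordered retention fractions plus the iteration count per fraction.

    ``fractions`` must be distinct values in (0, 1] sorted ascending and
    include 1.0 (the full-data reference).  ``iterations`` applies to
    every fraction below 1; the reference run is executed exactly once.
    """

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    iterations: int = 25

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if len(set(fr)) != len(fr):
            raise ConfigError("fractions must be distinct")
        if any(not 0.0 < f <= 1.0 for f in fr):
            raise ConfigError("fractions must lie in (0, 1]")
        if list(fr) != sorted(fr):
            raise ConfigError("fractions must be sorted ascending")
        if 1.0 not in fr:
            raise ConfigError("the grid must include the full-data fraction 1.0")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")

    def iterations_at(self, f: float) -> int:
        return 1 if f == 1.0 else self.iterations

    @property
    def n_cells(self) -> int:
        return sum(self.iterations_at(f) for f in self.fractions)


def thin_counts(counts: CountMatrix, f: float, seed: int) -> CountMatrix:
    """Binomially thin every count at retention fraction ``f``.

    Gene/sample order, group labels and gene lengths are preserved.
    ``f = 1`` returns an identical copy without consuming randomness;
    zero counts stay zero at every fraction.  Deterministic given
    ``seed``.
    """
    if not 0.0 < f <= 1.0:
        raise DomainError(f"retention fraction must lie in (0, 1], got {f}")
    out = counts.copy()
    if f == 1.0:
        return out
    rng = np.random.default_rng(seed)
    out.counts = rng.binomial(counts.counts, f).astype(np.int64)
    return out
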