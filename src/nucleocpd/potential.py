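"""Mutagenic-potential scoring per rotational position.

UV-induced C->T mutation at a methylated CpG requires two sequential
events that are both modulated by where the site faces on the histone
surface: formation of the cyclobutane pyrimidine dimer, and deamination
of its 5-methylcytosine.  Ignoring repair and replication, a site's
mutagenic potential relative to free DNA is the product of its relative
photoproduct yield and its relative deamination rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["SiteComparison", "relative_potential", "average_potential"]


@dataclass(frozen=True)
class SiteComparison:
    """Relative yield, relative rate and their product for one position."""

    position: int | str
    yield_fold: float
    rate_fold: float

    @property
    def potential(self) -> float:
        return self.yield_fold * self.rate_fold

    @property
    def reciprocal(self) -> float:
        """Fold *decrease*; reported when potential < 1 ("x-fold lower")."""
        return 1.0 / self.potential


def relative_potential(
    yield_ncp: float,
    yield_free: float,
    k_ncp: float,
    k_free: float,
    position: int | str = 0,
) -> SiteComparison:
    """Score one position: (yield_ncp/yield_free) * (k_ncp/k_free)."""
    for name, v in (
        ("yield_ncp", yield_ncp),
        ("yield_free", yield_free),
        ("k_ncp", k_ncp),
        ("k_free", k_free),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return SiteComparison(
        position=position,
        yield_fold=yield_ncp / yield_free,
        rate_fold=k_ncp / k_free,
    )


def average_potential(comparisons: Sequence[SiteComparison]) -> float:
    """Unweighted arithmetic mean of the per-position potentials.

    This is the expected relative mutagenic potential of a site in a
    rotationally unphased (weakly positioned) nucleosome, where the site
    samples all rotational settings with equal probability.
    """
    if len(comparisons) == 0:
        raise ValueError("empty comparison list")
    return sum(c.potential for c in comparisons) / len(comparisons)
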