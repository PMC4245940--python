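"""Packaged reference measurements for the dyad-axis T^mC site series.

The study this package reproduces measured CPD photoproduct yields and
deamination half-lives for a 5-methylated T^mCG site stepped through the
ten consecutive rotational positions at the nucleosome dyad axis
(sites ds1..ds10), plus two T^mCA variants (ds1A, ds6A) probing the
3'-flanking-base effect, each in free DNA and in the nucleosome core
particle (NCP).  The printed table values are packaged here so every
downstream quantity (rate constants, fold changes, free-energy
differences, mutagenic potentials) can be recomputed from them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SiteRecord", "site_table", "published_summary"]


@dataclass(frozen=True)
class SiteRecord:
    """One row of the published site table.

    ``yield_percent`` is the CPD photoproduct yield in percent;
    ``half_life_h`` the deamination half-life in hours with its printed
    ``half_life_pm_h`` uncertainty (1 SE).  ``yield_fold`` and
    ``half_life_fold`` are the fold-change columns as printed (NCP
    relative to the matching free-DNA substrate); ``None`` for free DNA.
    ``position`` is the rotational index 1-10 for the T^mCG series,
    ``None`` for the pooled free-DNA reference and the T^mCA variants.
    """

    site_id: str
    context: str  # "TmCG" or "TmCA"
    in_nucleosome: bool
    position: int | None
    yield_percent: float
    half_life_h: float
    half_life_pm_h: float
    yield_fold: float | None = None
    half_life_fold: float | None = None


_TABLE = (
    SiteRecord("Free ds1-10", "TmCG", False, None, 12.0, 13.0, 1.0),
    SiteRecord("NCP ds1", "TmCG", True, 1, 6.9, 41.0, 2.0, 0.6, 3.1),
    SiteRecord("NCP ds2", "TmCG", True, 2, 7.6, 39.0, 3.0, 0.6, 3.0),
    SiteRecord("NCP ds3", "TmCG", True, 3, 13.0, 15.0, 2.0, 1.1, 1.2),
    SiteRecord("NCP ds4", "TmCG", True, 4, 14.0, 9.0, 1.0, 1.2, 0.7),
    SiteRecord("NCP ds5", "TmCG", True, 5, 19.0, 5.0, 1.0, 1.6, 0.4),
    SiteRecord("NCP ds6", "TmCG", True, 6, 22.0, 3.5, 0.3, 1.9, 0.3),
    SiteRecord("NCP ds7", "TmCG", True, 7, 20.0, 3.6, 0.3, 1.7, 0.3),
    SiteRecord("NCP ds8", "TmCG", True, 8, 14.0, 10.0, 0.5, 1.2, 0.8),
    SiteRecord("NCP ds9", "TmCG", True, 9, 12.0, 12.0, 0.5, 1.0, 0.9),
    SiteRecord("NCP ds10", "TmCG", True, 10, 8.4, 36.0, 2.0, 0.7, 2.8),
    SiteRecord("Free ds1A", "TmCA", False, None, 14.0, 85.0, 6.0),
    SiteRecord("NCP ds1A", "TmCA", True, 1, 12.0, 117.0, 7.0, 0.8, 1.3),
    SiteRecord("Free ds6A", "TmCA", False, None, 14.0, 90.0, 3.0),
    SiteRecord("NCP ds6A", "TmCA", True, 6, 24.0, 28.0, 0.6, 1.7, 0.32),
)


def site_table() -> dict[str, SiteRecord]:
    """The published site table keyed by site id (15 entries)."""
    return {rec.site_id: rec for rec in _TABLE}


def published_summary() -> dict[str, float]:
    """Derived quantities as printed in the source study's text.

    These are comparison values only; the pipeline recomputes each of
    them from :func:`site_table` at run time.
    """
    return {
        "free_k_per_h": 0.053,
        "mean_ncp_k_per_h": 0.083,
        "ncp_vs_free_rate_ratio": 1.6,
        "deamination_range_fold": 12.0,
        "tmca_range_fold": 4.0,
        "outermost_acceleration_tmcg": 3.7,
        "outermost_acceleration_tmca": 3.2,
        "innermost_retardation_tmcg": 3.1,
        "innermost_retardation_tmca": 1.3,
        "potential_position6": 7.0,
        "potential_position1_fold_lower": 5.3,
        "average_potential": 2.3,
        "ddg_deamination_extremes_kcal_mol": 1.5,
        "inside_positions": 3.0,
        "outside_positions": 7.0,
    }
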