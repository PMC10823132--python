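"""Vertebrate carcass tallies, fish biomass conversion and extrapolation.

Carcasses found on 10-m bank transects across all habitat types (stony,
gravel, reed, sandy) are tallied at species level.  Fish counts are
converted to mass with the allometric length–weight relationship
W = a·Lᵇ using species-specific coefficients and measured lengths, then
extrapolated to river scale with the same two-bank transect arithmetic
used for shore mussels.  Habitat and along-river location effects are
screened with a Kruskal–Wallis test and the penalized-spline abundance
smooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UnknownTaxonError
from . import shore

HABITATS = ("stony", "gravel", "reed", "sandy")


@dataclass(frozen=True)
class VertebrateRecord:
    """Carcasses of one taxon on one 10-m transect, with any lengths."""

    transect_id: str
    river_km: float
    habitat: str
    taxon: str
    count: int
    lengths: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        object.__setattr__(self, "lengths", tuple(float(l) for l in self.lengths))
        if len(self.lengths) > self.count:
            raise ValueError("more length measurements than counted individuals")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("lengths must be positive (cm)")


@dataclass(frozen=True)
class LengthWeightCoeff:
    """Allometric coefficients of W = a·Lᵇ (W in g, L in cm)."""

    taxon: str
    a: float
    b: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("coefficient a must be positive")
        if not (2.5 <= self.b <= 3.5):
            warnings.warn(
                f"exponent b={self.b} for {self.taxon!r} outside the typical "
                "[2.5, 3.5] range",
                UserWarning,
            )


def mean_individual_mass(
    lengths: Sequence[float], coeff: LengthWeightCoeff
) -> float:
    """Mean per-individual mass in g: average of a·Lᵇ over measured fish.

    The mean of per-individual masses, not the mass of the mean length —
    the two differ for b ≠ 1 (Jensen's inequality) and only the former
    aggregates measured fish without bias.
    """
    if len(lengths) == 0:
        raise InsufficientDataError("at least one length measurement required")
    L = np.asarray(lengths, dtype=float)
    return float(np.mean(coeff.a * L ** coeff.b))


def transect_biomass(
    records: Sequence[VertebrateRecord],
    coeffs: dict[str, LengthWeightCoeff],
    fallback_mean_mass_g: Optional[dict[str, float]] = None,
) -> dict[str, float]:
    """Per-taxon biomass in kg summed over transects.

    Each taxon's mean individual mass is estimated from all its length
    measurements pooled across the dataset, then multiplied by the
    per-record counts.  A fish taxon with no lengths anywhere falls back
    to a config-supplied mean mass, or raises.
    """
    lengths_by_taxon: dict[str, list[float]] = {}
    counts_by_taxon: dict[str, int] = {}
    for rec in records:
        lengths_by_taxon.setdefault(rec.taxon, []).extend(rec.lengths)
        counts_by_taxon[rec.taxon] = counts_by_taxon.get(rec.taxon, 0) + rec.count

    biomass: dict[str, float] = {}
    for taxon, total_count in counts_by_taxon.items():
        if taxon not in coeffs:
            raise UnknownTaxonError(
                f"no length-weight coefficients for taxon {taxon!r}"
            )
        lengths = lengths_by_taxon.get(taxon, [])
        if lengths:
            mean_mass = mean_individual_mass(lengths, coeffs[taxon])
        elif fallback_mean_mass_g and taxon in fallback_mean_mass_g:
            mean_mass = fallback_mean_mass_g[taxon]
        else:
            raise InsufficientDataError(
                f"taxon {taxon!r} has no length measurements and no "
                "fallback mean mass"
            )
        biomass[taxon] = total_count * mean_mass / 1000.0
    return biomass


def extrapolate_vertebrates(
    per_transect_mean: float,
    river_length_km: float,
    transect_length_m: float = 10.0,
    n_banks: int = 2,
) -> float:
    """Extrapolate a per-transect mean (count or kg) to the whole reach.

    Delegates to the same transect-unit arithmetic used for shore
    mussels; typically reported for both a lower-river length and the
    full affected length.
    """
    return shore.extrapolate_total(
        per_transect_mean, river_length_km, transect_length_m, n_banks
    )


@dataclass
class HabitatEffectReport:
    """Habitat and location screening of per-transect fish counts."""

    kruskal_statistic: float
    kruskal_p: float
    habitat_groups: dict[str, list[int]]
    abundance_smooth: Optional[shore.AbundanceSmooth] = None


def habitat_effect(
    records: Sequence[VertebrateRecord],
    taxon: str,
    basis_dim: int = 6,
    fit_smooth: bool = True,
) -> HabitatEffectReport:
    """Kruskal–Wallis across habitat classes plus a km abundance smooth.

    Per-transect counts of the taxon are compared across habitat classes
    with the Kruskal–Wallis rank test (tie-corrected); the along-river
    trend is fit with the shared penalized-spline Poisson smooth when
    the design allows it.
    """
    per_transect: dict[str, tuple[float, str, int]] = {}
    for rec in records:
        if rec.taxon != taxon:
            continue
        km, hab, c = per_transect.get(rec.transect_id, (rec.river_km, rec.habitat, 0))
        per_transect[rec.transect_id] = (km, hab, c + rec.count)
    groups: dict[str, list[int]] = {}
    for km, hab, c in per_transect.values():
        groups.setdefault(hab, []).append(c)
    usable = {h: v for h, v in groups.items() if len(v) >= 3}
    if len(usable) < 2:
        raise InsufficientDataError(
            "need at least 2 habitat classes with 3+ transects each"
        )
    pooled = np.concatenate([np.asarray(v, float) for v in usable.values()])
    if np.ptp(pooled) == 0:
        # every transect identical: no rank variation, trivially null
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*usable.values())

    smooth = None
    if not fit_smooth:
        return HabitatEffectReport(
            kruskal_statistic=float(stat),
            kruskal_p=float(p),
            habitat_groups=usable,
        )
    pseudo = [
        shore.ShoreTransect(site_id=tid, river_km=km, bank="na", counts={taxon: c})
        for tid, (km, hab, c) in per_transect.items()
    ]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            smooth = shore.fit_abundance_smooth(pseudo, taxon, basis_dim=basis_dim)
    except InsufficientDataError:
        pass
    return HabitatEffectReport(
        kruskal_statistic=float(stat),
        kruskal_p=float(p),
        habitat_groups=usable,
        abundance_smooth=smooth,
    )
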