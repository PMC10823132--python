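"""Synthetic disaster scenarios with known ground truth.

Every input the pipeline consumes can be generated here with the
statistical structure of the Odra surveys: overdispersed shore counts
with a smooth spatial trend along river-km, binomially thinned flux
counts at a fixed detection rate, multi-taxon photo composition with
per-photo intensity variation, a lognormal before/after density shift,
and habitat-structured vertebrate tallies with Gaussian length
measurements.  Each generator is a pure function of (config, seed): the
scenario seed expands into fixed per-generator substreams so adding a
generator never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .river_frame import RiverFrame
from .flux import FluxSession
from .shore import ShoreTransect
from .population import DensitySample
from .photos import PhotoGrid
from .vertebrates import VertebrateRecord, HABITATS

# Fixed substream indices; append-only so draws stay stable.
_STREAMS = {
    "shore": 0,
    "flux": 1,
    "photos": 2,
    "density": 3,
    "vertebrates": 4,
}


def _default_frame() -> RiverFrame:
    # Lower Odra reach: Warta mouth (km 617.6) to Regalica mouth (km 741.6),
    # plus the 26-km Western Odra arm; 20-m strip on both banks.
    return RiverFrame(
        km_start=617.6,
        km_end=741.6,
        extra_branches=(("Western Odra", 26.0),),
        strip_width_w=20.0,
        n_banks=2,
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a synthetic mass-mortality scenario.

    Defaults reproduce the design of the 2022 Odra surveys: ω = 0.6
    detectability, a per-minute flux giving 5-minute counts of around
    thirty carcasses, a 12.6 ind/m² pre-event density declining by the
    fraction implied by the printed before/after densities, a snail to
    mussel composition matching the 147 M : 65 M headline proportion,
    and three dominant fish species on habitat-structured transects.
    """

    seed: int = 0
    frame: RiverFrame = field(default_factory=_default_frame)
    true_shore_total: float = 500_000.0
    trend_control_points: tuple[tuple[float, float], ...] = (
        (617.6, 0.0), (660.0, 1.0), (700.0, 0.4), (741.6, -0.5),
    )
    overdispersion_k: float = 2.0
    omega: float = 0.6
    flux_lambda: float = 10.0  # true carcasses per minute
    composition: tuple[tuple[str, float], ...] = (
        ("snail", 2.26), ("mussel", 1.0),
    )
    photo_mean_objects: float = 60.0
    before_density: float = 12.6  # ind/m²
    decline_fraction: float = 0.873
    density_sigma: float = 0.4  # lognormal log-sd of per-sample density
    sampled_area_range: tuple[float, float] = (3.0, 4.0)  # m², near 46/13
    fish_species: tuple[tuple[str, float, float, float], ...] = (
        # (taxon, mean count per transect, length mean cm, length sd cm)
        ("ruffe", 20.0, 10.0, 2.0),
        ("bream", 6.0, 30.0, 6.0),
        ("perch", 10.0, 15.0, 3.0),
    )
    habitat_multipliers: tuple[tuple[str, float], ...] = (
        ("stony", 1.0), ("gravel", 1.0), ("reed", 1.0), ("sandy", 1.0),
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.decline_fraction <= 1.0):
            raise ValueError("decline_fraction must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Seeded substream for one generator."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)


def _trend_density(config: ScenarioConfig, km: np.ndarray) -> np.ndarray:
    """Normalized spatial density p(km) of shore deposition (per km).

    The axis runs over the whole assessed length: branch segments
    continue past km_end with the trend clamped at its last control
    point, so the deposited total is spread over every extrapolated km.
    """
    from .river_frame import total_length

    pts = np.asarray(config.trend_control_points, dtype=float)
    intensity = np.exp(np.interp(km, pts[:, 0], pts[:, 1]))
    start = config.frame.km_start
    grid = np.linspace(start, start + total_length(config.frame), 2001)
    gi = np.exp(np.interp(grid, pts[:, 0], pts[:, 1]))
    integral = np.trapezoid(gi, grid)
    return intensity / integral


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, k: float
) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and dispersion k."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if pos.any():
        p = k / (k + mean[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def simulate_shore(
    config: ScenarioConfig,
    n_transects: int = 12,
    n_points: int = 56,
    taxon: str = "mussel",
) -> tuple[list[ShoreTransect], dict]:
    """Randomly placed 10-m bank transects with a known deposited total.

    The configured total is spread along the full assessed axis by the
    smooth trend and across both banks evenly; each sampling unit (survey
    transect or random point, both treated as 10-m segments) draws a
    negative-binomial count around the local expected deposition.
    Returns the transect list and a truth record with the exact total.
    """
    from .river_frame import total_length

    rng = config.rng("shore")
    frame = config.frame
    n_units = n_transects + n_points
    km = rng.uniform(
        frame.km_start, frame.km_start + total_length(frame), size=n_units
    )
    banks = rng.choice(["left", "right"], size=n_units)
    p = _trend_density(config, km)
    # expected count on a 10-m one-bank segment at position km
    mean = config.true_shore_total * p * 0.01 / frame.n_banks
    counts = _nb_draw(rng, mean, config.overdispersion_k)
    transects = []
    for i in range(n_units):
        prefix = "T" if i < n_transects else "P"
        transects.append(
            ShoreTransect(
                site_id=f"{prefix}{i + 1:02d}",
                river_km=float(km[i]),
                bank=str(banks[i]),
                counts={taxon: int(counts[i])},
            )
        )
    truth = {"true_shore_total": config.true_shore_total, "taxon": taxon}
    return transects, truth


def simulate_flux(
    config: ScenarioConfig,
    n_sessions: int = 12,
    session_minutes: float = 5.0,
) -> list[FluxSession]:
    """Timed flux sessions: Binomial(Poisson(λ·minutes), ω) counts."""
    rng = config.rng("flux")
    lam = config.flux_lambda * session_minutes
    true_counts = rng.poisson(lam, size=n_sessions)
    seen = rng.binomial(true_counts, config.omega)
    return [
        FluxSession(count_x=int(c), session_minutes=session_minutes)
        for c in seen
    ]


def simulate_photos(
    config: ScenarioConfig,
    n_photos: int = 13,
    grid_dims: tuple[int, int] = (8, 8),
) -> list[PhotoGrid]:
    """Grid-annotated photos with multinomial taxon composition.

    Photo-level intensity varies by a gamma multiplier; a random block
    of rows at the top of each photo is excluded (the demarcation line),
    and objects scatter uniformly over the remaining cells.
    """
    rng = config.rng("photos")
    n_rows, n_cols = grid_dims
    taxa = [t for t, _ in config.composition]
    props = np.array([w for _, w in config.composition], dtype=float)
    props = props / props.sum()
    photos = []
    for i in range(n_photos):
        n_excl_rows = int(rng.integers(0, max(1, n_rows // 3) + 1))
        excluded = frozenset(
            (r, c) for r in range(n_excl_rows) for c in range(n_cols)
        )
        included = [
            (r, c)
            for r in range(n_rows)
            for c in range(n_cols)
            if (r, c) not in excluded
        ]
        intensity = rng.gamma(shape=2.0, scale=config.photo_mean_objects / 2.0)
        total = int(rng.poisson(intensity))
        per_taxon = rng.multinomial(total, props)
        cells: dict[tuple[int, int], list[str]] = {}
        for taxon, n_obj in zip(taxa, per_taxon):
            if n_obj == 0:
                continue
            spots = rng.integers(0, len(included), size=n_obj)
            for s in spots:
                cells.setdefault(included[s], []).append(taxon)
        photos.append(
            PhotoGrid(
                photo_id=f"photo_{i + 1:02d}",
                n_rows=n_rows,
                n_cols=n_cols,
                cells=cells,
                excluded=excluded,
            )
        )
    return photos


def simulate_density_samples(
    config: ScenarioConfig,
    n_per_period: int = 13,
    taxon: str = "mussel",
) -> list[DensitySample]:
    """Benthic samples before and after the event.

    Per-sample densities are lognormal with means at the configured
    pre-event density and its post-decline value; sampled areas are
    uniform in the configured range and counts are the rounded
    density × area products.
    """
    rng = config.rng("density")
    out = []
    lo, hi = config.sampled_area_range
    for period, mean_density in (
        ("before", config.before_density),
        ("after", config.before_density * (1.0 - config.decline_fraction)),
    ):
        areas = rng.uniform(lo, hi, size=n_per_period)
        if mean_density > 0:
            mu = np.log(mean_density) - config.density_sigma**2 / 2.0
            dens = rng.lognormal(mu, config.density_sigma, size=n_per_period)
        else:
            dens = np.zeros(n_per_period)
        counts = np.rint(dens * areas).astype(int)
        for j in range(n_per_period):
            out.append(
                DensitySample(
                    site_id=f"S{j + 1:02d}",
                    period=period,
                    sampled_area=float(areas[j]),
                    counts={taxon: int(counts[j])},
                    method="diving" if j % 2 == 0 else "net",
                )
            )
    return out


def simulate_vertebrates(
    config: ScenarioConfig,
    n_transects: int = 43,
    reach_km: float = 20.0,
    max_measured: int = 10,
) -> list[VertebrateRecord]:
    """Habitat-structured vertebrate tallies on 10-m transects.

    Per-species counts are Poisson with habitat-specific multipliers;
    lengths are Gaussian per species, truncated at a small positive
    floor, measured for up to ``max_measured`` individuals per record.
    """
    rng = config.rng("vertebrates")
    frame = config.frame
    multipliers = dict(config.habitat_multipliers)
    km = rng.uniform(frame.km_start, frame.km_start + reach_km, size=n_transects)
    habitats = rng.choice(HABITATS, size=n_transects)
    records = []
    for i in range(n_transects):
        for taxon, intensity, l_mean, l_sd in config.fish_species:
            lam = intensity * multipliers.get(str(habitats[i]), 1.0)
            count = int(rng.poisson(lam)) if lam > 0 else 0
            n_meas = min(count, max_measured)
            lengths = tuple(
                float(max(0.1, l))
                for l in rng.normal(l_mean, l_sd, size=n_meas)
            )
            records.append(
                VertebrateRecord(
                    transect_id=f"V{i + 1:02d}",
                    river_km=float(km[i]),
                    habitat=str(habitats[i]),
                    taxon=taxon,
                    count=count,
                    lengths=lengths,
                )
            )
    return records


def scenario_truth(config: ScenarioConfig) -> dict:
    """Ground-truth record for a scenario, consumed by recovery tests."""
    comp = dict(config.composition)
    ref = comp.get("mussel", 1.0)
    return {
        "seed": config.seed,
        "true_shore_total": config.true_shore_total,
        "true_daily_flux": config.flux_lambda * 1440.0,
        "omega": config.omega,
        "before_density": config.before_density,
        "after_density": config.before_density * (1.0 - config.decline_fraction),
        "decline_fraction": config.decline_fraction,
        "snail_mussel_ratio": comp.get("snail", 0.0) / ref if ref else None,
        "fish_mean_counts": {t: i for t, i, _, _ in config.fish_species},
    }


def simulate_scenario(
    config: ScenarioConfig,
    outdir,
    n_transects: int = 12,
    n_points: int = 56,
    n_sessions: int = 12,
    n_photos: int = 13,
    n_density: int = 13,
    n_vert_transects: int = 43,
) -> dict:
    """Generate every pipeline input into ``outdir``, plus truth.json.

    Writes flux_sessions.csv, shore_transects.csv, density_samples.csv,
    vertebrate_records.csv, coeffs.csv, river.yaml and one annotation
    JSON per photo under photos/.  Returns the truth record.
    """
    from . import io as rio

    outdir = rio.ensure_dir(outdir)
    shore_t, _ = simulate_shore(config, n_transects, n_points)
    rio.write_shore_transects(outdir / "shore_transects.csv", shore_t)
    rio.write_flux_sessions(
        outdir / "flux_sessions.csv", simulate_flux(config, n_sessions)
    )
    rio.write_density_samples(
        outdir / "density_samples.csv",
        simulate_density_samples(config, n_density),
    )
    rio.write_vertebrate_records(
        outdir / "vertebrate_records.csv",
        simulate_vertebrates(config, n_vert_transects),
    )
    photo_dir = rio.ensure_dir(outdir / "photos")
    for photo in simulate_photos(config, n_photos):
        rio.write_photo_annotation(photo_dir / f"{photo.photo_id}.json", photo)
    rio.write_coeffs(outdir / "coeffs.csv", rio.demo_coefficients())
    rio.write_river_config(outdir / "river.yaml", config.frame)
    truth = scenario_truth(config)
    rio.write_json(outdir / "truth.json", truth)
    return truth
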