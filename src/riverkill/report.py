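"""Combined mortality report orchestrating every estimator.

``run_report`` reads whatever survey inputs an input directory provides
(flux sessions, shore transects, density samples, photo annotations,
vertebrate records, coefficients, river geometry), runs the matching
estimators with one configured seed, and assembles a
:class:`MortalityReport` whose JSON serialization is byte-identical
across runs with the same inputs and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as rio
from .errors import RiverkillError, SchemaError
from .flux import DetectionModel, estimate_flux
from .population import (
    compare_periods,
    mortality,
    population_abundance,
    standardize_density,
)
from .photos import taxon_ratio, proportional_estimate
from .river_frame import habitat_area, total_length
from .shore import estimate_shore_total
from .vertebrates import transect_biomass, extrapolate_vertebrates


@dataclass
class MortalityReport:
    """Headline quantities of one assessed mortality event."""

    river_length_km: Optional[float] = None
    habitat_area_m2: Optional[float] = None
    flux_per_day: Optional[float] = None
    flux_ci95: Optional[tuple[float, float]] = None
    shore_total: Optional[float] = None
    shore_ci95: Optional[tuple[float, float]] = None
    density_before: Optional[float] = None
    density_after: Optional[float] = None
    abundance_before: Optional[float] = None
    abundance_after: Optional[float] = None
    n_dead: Optional[float] = None
    percent_decline: Optional[float] = None
    comparison_test: Optional[str] = None
    comparison_p: Optional[float] = None
    snail_mussel_ratio: Optional[float] = None
    snail_total: Optional[float] = None
    fish_total_count: Optional[float] = None
    fish_biomass_tons: Optional[float] = None
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        """Human-readable summary rounded to 2 significant figures."""

        def fmt(x):
            if x is None:
                return "n/a"
            if isinstance(x, (tuple, list)):
                return "(" + ", ".join(fmt(v) for v in x) + ")"
            return f"{float(x):.2g}"

        lines = [
            "Mass mortality report",
            "=====================",
            f"river length assessed      : {fmt(self.river_length_km)} km",
            f"habitat strip area         : {fmt(self.habitat_area_m2)} m^2",
            f"carcass flux               : {fmt(self.flux_per_day)} ind/day "
            f"CI {fmt(self.flux_ci95)}",
            f"shore-deposited total      : {fmt(self.shore_total)} "
            f"CI {fmt(self.shore_ci95)}",
            f"density before / after     : {fmt(self.density_before)} / "
            f"{fmt(self.density_after)} ind/m^2",
            f"abundance before / after   : {fmt(self.abundance_before)} / "
            f"{fmt(self.abundance_after)}",
            f"estimated dead             : {fmt(self.n_dead)} "
            f"({fmt(self.percent_decline)}% decline)",
            f"before/after test          : {self.comparison_test or 'n/a'} "
            f"(p = {fmt(self.comparison_p)})",
            f"snail:mussel ratio         : {fmt(self.snail_mussel_ratio)}",
            f"snail total                : {fmt(self.snail_total)}",
            f"fish count / biomass       : {fmt(self.fish_total_count)} / "
            f"{fmt(self.fish_biomass_tons)} t",
        ]
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)


def run_report(
    input_dir,
    seed: int = 0,
    reference_taxon: str = "mussel",
    target_taxon: str = "snail",
    omega: float = 0.6,
    n_boot: int = 10_000,
    fish_extrapolation_km: Optional[float] = None,
) -> MortalityReport:
    """Run every estimator the input directory has data for.

    Expects the file layout written by :func:`riverkill.simulate_scenario`
    (river.yaml plus any of flux_sessions.csv, shore_transects.csv,
    density_samples.csv, photos/, vertebrate_records.csv + coeffs.csv).
    Raises a structured error when no usable input is present.
    """
    input_dir = Path(input_dir)
    report = MortalityReport()
    report.provenance = {
        "input_files": sorted(
            str(p.relative_to(input_dir))
            for p in input_dir.rglob("*")
            if p.is_file()
        ),
        "seed": seed,
        "omega": omega,
        "reference_taxon": reference_taxon,
        "target_taxon": target_taxon,
    }

    def note(msg: str) -> None:
        report.warnings.append(msg)

    river_path = input_dir / "river.yaml"
    if not river_path.exists():
        raise SchemaError(f"no river.yaml in {input_dir}; cannot extrapolate")
    frame = rio.read_river_config(river_path)
    report.river_length_km = total_length(frame)
    report.habitat_area_m2 = habitat_area(frame)

    any_data = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", UserWarning)

        flux_path = input_dir / "flux_sessions.csv"
        if flux_path.exists():
            any_data = True
            est = estimate_flux(
                rio.read_flux_sessions(flux_path),
                DetectionModel(omega),
                n_boot=n_boot,
                seed=seed,
            )
            report.flux_per_day = est.per_day
            report.flux_ci95 = est.ci95

        shore_path = input_dir / "shore_transects.csv"
        if shore_path.exists():
            any_data = True
            total, ci, _ = estimate_shore_total(
                rio.read_shore_transects(shore_path),
                reference_taxon,
                frame,
                n_boot=max(1000, n_boot // 10),
                seed=seed,
            )
            report.shore_total = total
            report.shore_ci95 = ci

        dens_path = input_dir / "density_samples.csv"
        if dens_path.exists():
            any_data = True
            samples = rio.read_density_samples(dens_path)
            d_before = standardize_density(samples, reference_taxon, "before")
            d_after = standardize_density(samples, reference_taxon, "after")
            report.density_before = d_before
            report.density_after = d_after
            report.abundance_before = population_abundance(d_before, frame)
            report.abundance_after = population_abundance(d_after, frame)
            res = mortality(report.abundance_before, report.abundance_after)
            report.n_dead = res.n_dead
            report.percent_decline = res.percent_decline
            before = [
                s.density(reference_taxon) for s in samples if s.period == "before"
            ]
            after = [
                s.density(reference_taxon) for s in samples if s.period == "after"
            ]
            if len(before) >= 3 and len(after) >= 3:
                cmp = compare_periods(before, after)
                report.comparison_test = cmp.test_used
                report.comparison_p = cmp.p_value

        photo_dir = input_dir / "photos"
        if photo_dir.is_dir():
            any_data = True
            photos = rio.read_photo_dir(photo_dir)
            try:
                ratio = taxon_ratio(photos, target_taxon, reference_taxon)
                report.snail_mussel_ratio = ratio
                if report.shore_total is not None:
                    report.snail_total = proportional_estimate(
                        ratio, report.shore_total
                    )
                else:
                    note("no shore total; snail total not scaled")
            except RiverkillError as exc:
                note(f"photo ratio unavailable: {exc}")

        vert_path = input_dir / "vertebrate_records.csv"
        coeff_path = input_dir / "coeffs.csv"
        if vert_path.exists():
            any_data = True
            records = rio.read_vertebrate_records(vert_path)
            fish_km = fish_extrapolation_km or total_length(frame)
            transect_ids = {r.transect_id for r in records}
            n_tr = max(1, len(transect_ids))
            total_count = sum(r.count for r in records)
            report.fish_total_count = extrapolate_vertebrates(
                total_count / n_tr, fish_km, n_banks=frame.n_banks
            )
            if coeff_path.exists():
                coeffs = rio.read_coeffs(coeff_path)
                try:
                    biomass = transect_biomass(records, coeffs)
                    per_transect_kg = sum(biomass.values()) / n_tr
                    report.fish_biomass_tons = (
                        extrapolate_vertebrates(
                            per_transect_kg, fish_km, n_banks=frame.n_banks
                        )
                        / 1000.0
                    )
                except RiverkillError as exc:
                    note(f"biomass unavailable: {exc}")
            else:
                note("no coeffs.csv; fish biomass not computed")

        for w in caught:
            note(str(w.message))

    if not any_data:
        raise SchemaError(f"no survey inputs found in {input_dir}")
    return report


def write_report(report: MortalityReport, outdir) -> tuple[Path, Path]:
    """Serialize the report as JSON and human-readable text."""
    outdir = rio.ensure_dir(outdir)
    json_path = outdir / "report.json"
    text_path = outdir / "report.txt"
    rio.write_json(json_path, report.to_dict())
    text_path.write_text(report.to_text() + "\n")
    return json_path, text_path
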