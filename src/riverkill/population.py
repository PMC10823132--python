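"""Before/after benthic density comparison and river-scale mortality.

Benthic samples (diving or hydrobiological net) are standardized to
individuals per m², averaged within period, scaled by the habitat-strip
area to river-scale abundance, and differenced to a mortality count and
percent decline.  The before/after comparison follows a normality-gated
test choice: Shapiro–Wilk on each group, then one-way ANOVA when both
groups look normal and Kruskal–Wallis otherwise, with histogram and Q-Q
diagnostic data recorded alongside the gate decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .river_frame import RiverFrame, habitat_area


@dataclass(frozen=True)
class DensitySample:
    """One benthic sample with its sampled area and per-taxon counts."""

    site_id: str
    period: str  # "before" | "after"
    sampled_area: float  # m²
    counts: dict[str, int]
    method: str = "net"  # "diving" | "net"

    def __post_init__(self) -> None:
        if self.sampled_area <= 0:
            raise ValueError("sampled_area must be positive")
        if self.period not in ("before", "after"):
            raise ValueError("period must be 'before' or 'after'")
        for taxon, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {taxon!r}")

    def density(self, taxon: str) -> float:
        """Individuals per m² of this sample, standardized to 1 m²."""
        return self.counts.get(taxon, 0) / self.sampled_area


@dataclass(frozen=True)
class MortalityResult:
    """Before/after abundance difference at river scale."""

    n_before: float
    n_after: float
    n_dead: float
    percent_decline: Optional[float]


def standardize_density(
    samples: Sequence[DensitySample],
    taxon: str,
    period: str,
    pooled: bool = False,
) -> float:
    """Mean density (ind/m²) of a taxon over samples of one period.

    Default is the mean of per-sample densities (each sample first
    standardized to 1 m², then averaged).  ``pooled=True`` instead
    divides the pooled count by the pooled area, which weights samples
    by their area.
    """
    sel = [s for s in samples if s.period == period]
    if not sel:
        raise InsufficientDataError(f"no samples for period {period!r}")
    if pooled:
        total = sum(s.counts.get(taxon, 0) for s in sel)
        area = sum(s.sampled_area for s in sel)
        return total / area
    return float(np.mean([s.density(taxon) for s in sel]))


def population_abundance(density: float, frame: RiverFrame) -> float:
    """River-scale abundance: density (ind/m²) × habitat-strip area (m²)."""
    if density < 0:
        raise ValueError("density must be non-negative")
    return density * habitat_area(frame)


def mortality(before: float, after: float) -> MortalityResult:
    """Difference pre- and post-event abundance into a mortality count.

    ``percent_decline`` is 100·(before − after)/before; it is reported
    as missing when ``before`` is zero, and a negative dead count (a
    population increase) is allowed but flagged with a warning.
    """
    if before < 0 or after < 0:
        raise ValueError("abundances must be non-negative")
    n_dead = before - after
    if n_dead < 0:
        warnings.warn(
            "after-abundance exceeds before-abundance (population increase)",
            UserWarning,
        )
    if before == 0:
        percent = None
        if after > 0:
            warnings.warn(
                "percent decline undefined: before-abundance is zero", UserWarning
            )
    else:
        percent = 100.0 * n_dead / before
    return MortalityResult(
        n_before=before, n_after=after, n_dead=n_dead, percent_decline=percent
    )


@dataclass
class ComparisonReport:
    """Outcome of the normality-gated before/after test."""

    test_used: Optional[str]  # "anova" | "kruskal-wallis" | None
    statistic: Optional[float]
    p_value: Optional[float]
    shapiro_p: dict[str, float] = field(default_factory=dict)
    normal_gate_passed: bool = False
    alpha: float = 0.05
    diagnostics: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _diagnostic_data(values: np.ndarray, bins: int = 10) -> dict:
    """Histogram bin counts and Q-Q point coordinates for one group."""
    hist, edges = np.histogram(values, bins=bins)
    (theoretical, ordered), (slope, intercept, _) = stats.probplot(values)
    return {
        "hist_counts": hist.tolist(),
        "hist_edges": edges.tolist(),
        "qq_theoretical": theoretical.tolist(),
        "qq_ordered": ordered.tolist(),
        "qq_line": {"slope": float(slope), "intercept": float(intercept)},
    }


def compare_periods(
    samples_before: Sequence[float],
    samples_after: Sequence[float],
    alpha: float = 0.05,
) -> ComparisonReport:
    """Normality-gated before/after comparison of per-sample densities.

    Each group is checked with the Shapiro–Wilk test at ``alpha``; when
    both pass, a one-way ANOVA compares the groups, otherwise a
    Kruskal–Wallis test is used.  The report records the gate decision,
    the statistic and p-value, and histogram/Q-Q diagnostic data.
    """
    before = np.asarray(samples_before, dtype=float)
    after = np.asarray(samples_after, dtype=float)
    if before.size < 3 or after.size < 3:
        raise InsufficientDataError("need at least 3 samples per group")

    report = ComparisonReport(
        test_used=None, statistic=None, p_value=None, alpha=alpha
    )
    report.diagnostics = {
        "before": _diagnostic_data(before),
        "after": _diagnostic_data(after),
    }

    if np.ptp(before) == 0 and np.ptp(after) == 0:
        msg = "both groups are constant; no test statistic can be computed"
        warnings.warn(msg, UserWarning)
        report.warnings.append(msg)
        return report

    for name, grp in (("before", before), ("after", after)):
        if np.ptp(grp) == 0:
            # Shapiro-Wilk is undefined for a constant group: fail the gate
            report.shapiro_p[name] = 0.0
        else:
            report.shapiro_p[name] = float(stats.shapiro(grp).pvalue)
    report.normal_gate_passed = all(p > alpha for p in report.shapiro_p.values())

    if report.normal_gate_passed:
        stat, p = stats.f_oneway(before, after)
        report.test_used = "anova"
    else:
        stat, p = stats.kruskal(before, after)
        report.test_used = "kruskal-wallis"
    report.statistic = float(stat)
    report.p_value = float(p)
    return report
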