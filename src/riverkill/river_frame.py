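"""River geometry and habitat-strip area arithmetic.

Positions along the river are expressed in official kilometer posts
increasing downstream; every transect position in the package is a km
float on this axis.  Side branches are additive one-dimensional segments
with their own km axes and are treated identically to the main stem by
all extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidGeometryError

M_PER_KM = 1000.0


@dataclass(frozen=True)
class RiverFrame:
    """Geometry of the assessed river reach.

    Parameters
    ----------
    km_start, km_end
        Kilometer posts bounding the main-stem reach (downstream-increasing).
    extra_branches
        Additional 1-D segments as ``(name, length_km)`` tuples, e.g. a
        side arm included in the assessment.
    strip_width_w
        Width in metres of the habitat strip occupied by mussels along
        each bank (live mussels concentrate in a ~20 m band of slow
        current along the coastal zone and between spur dikes).
    n_banks
        Number of banks carrying the strip; 2 for a river.
    """

    km_start: float
    km_end: float
    extra_branches: tuple[tuple[str, float], ...] = field(default_factory=tuple)
    strip_width_w: float = 20.0
    n_banks: int = 2

    def __post_init__(self) -> None:
        if not self.km_end > self.km_start:
            raise InvalidGeometryError(
                f"km_end ({self.km_end}) must exceed km_start ({self.km_start})"
            )
        if not self.strip_width_w > 0:
            raise InvalidGeometryError("strip_width_w must be positive")
        if self.n_banks not in (1, 2):
            raise InvalidGeometryError("n_banks must be 1 or 2")
        for name, length in self.extra_branches:
            if length <= 0:
                raise InvalidGeometryError(f"branch {name!r} has non-positive length")
        # normalise list input to a tuple so the dataclass stays hashable
        object.__setattr__(self, "extra_branches", tuple(
            (str(n), float(l)) for n, l in self.extra_branches
        ))

    @property
    def main_span_km(self) -> float:
        return self.km_end - self.km_start

    @classmethod
    def from_dict(cls, cfg: dict) -> "RiverFrame":
        """Build a frame from a YAML/JSON config block.

        Expected keys: km_start, km_end, optional branches (list of
        {name, length_km}), strip_width_m, n_banks.
        """
        branches = tuple(
            (b["name"], float(b["length_km"])) for b in cfg.get("branches", [])
        )
        return cls(
            km_start=float(cfg["km_start"]),
            km_end=float(cfg["km_end"]),
            extra_branches=branches,
            strip_width_w=float(cfg.get("strip_width_m", 20.0)),
            n_banks=int(cfg.get("n_banks", 2)),
        )


def total_length(frame: RiverFrame) -> float:
    """Total assessed river length in km: main-stem span plus branches."""
    return frame.main_span_km + sum(length for _, length in frame.extra_branches)


def habitat_area(frame: RiverFrame) -> float:
    """Total habitat-strip area in m²: length × strip width × bank count."""
    return total_length(frame) * M_PER_KM * frame.strip_width_w * frame.n_banks
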