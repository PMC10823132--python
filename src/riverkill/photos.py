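"""Proportional co-mortality from grid-annotated shoreline photographs.

Carcasses in each photograph are counted cell by cell on a superimposed
square grid; cells beyond a demarcation line (drawn where perspective
makes recognition unreliable) are excluded.  The target taxon's total is
then estimated proportionally: the ratio of mean target count to mean
reference count across photos, scaled by an independent estimate of the
reference taxon's total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UndefinedRatioError


@dataclass
class PhotoGrid:
    """A gridded photo annotation with an exclusion mask.

    ``cells`` maps (row, col) to the list of taxon labels counted in
    that cell; ``excluded`` holds the cells beyond the demarcation line,
    which must carry no counts.
    """

    photo_id: str
    n_rows: int
    n_cols: int
    cells: dict[tuple[int, int], list[str]] = field(default_factory=dict)
    excluded: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.excluded = frozenset(tuple(c) for c in self.excluded)
        self.cells = {tuple(k): list(v) for k, v in self.cells.items()}
        for (r, c) in self.excluded:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"excluded cell ({r}, {c}) outside the grid")
        for (r, c) in self.cells:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"annotated cell ({r}, {c}) outside the grid")
        # labels may sit in excluded cells (annotators label everything);
        # the exclusion rule is applied at count time, never here

    def known_taxa(self) -> set[str]:
        return {label for labels in self.cells.values() for label in labels}


def grid_count(photo: PhotoGrid, taxon: str) -> int:
    """Occurrences of a taxon over the photo's non-excluded cells."""
    if taxon not in photo.known_taxa():
        warnings.warn(
            f"taxon {taxon!r} not annotated in photo {photo.photo_id!r}",
            UserWarning,
        )
        return 0
    return sum(
        labels.count(taxon)
        for cell, labels in photo.cells.items()
        if cell not in photo.excluded
    )


def taxon_ratio(
    photos: Sequence[PhotoGrid],
    target_taxon: str,
    reference_taxon: str,
    drop_zero_reference: bool = False,
) -> float:
    """Ratio of mean target count to mean reference count across photos.

    A ratio of means, not a mean of ratios: photos with zero reference
    counts still contribute to both means by default (dropping them,
    available via ``drop_zero_reference``, biases the ratio upward and
    leaves the mean-of-ratios undefined).
    """
    if not photos:
        raise UndefinedRatioError("no photos supplied")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pairs = [
            (grid_count(p, target_taxon), grid_count(p, reference_taxon))
            for p in photos
        ]
    if drop_zero_reference:
        pairs = [pair for pair in pairs if pair[1] > 0]
        if not pairs:
            raise UndefinedRatioError("all photos have zero reference counts")
    targets = np.array([t for t, _ in pairs], dtype=float)
    refs = np.array([r for _, r in pairs], dtype=float)
    if refs.mean() == 0:
        raise UndefinedRatioError(
            f"mean {reference_taxon!r} count is zero; ratio undefined"
        )
    return float(targets.mean() / refs.mean())


def proportional_estimate(ratio: float, reference_total: float) -> float:
    """Scale the photo-derived ratio by the reference taxon's total."""
    if ratio < 0 or reference_total < 0:
        raise ValueError("ratio and reference total must be non-negative")
    return ratio * reference_total
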