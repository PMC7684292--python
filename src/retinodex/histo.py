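"""Photoreceptor-row histomorphometry.

Surviving photoreceptors are quantified by counting rows of nuclei in the
outer nuclear layer of a binary nuclei mask at fixed distances from the
optic nerve head (signed: positive = superior pole), and assembling the
superior-to-inferior "spider" profile.

A row is operationalized as a maximal run of consecutive image rows whose
nuclei occupancy within the lateral window is at least 50% of the window
width — a deterministic rule under which the phantom generator's row count
is exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from . import cli_io

#: default sampling locations (um from the ONH) on each pole
DEFAULT_LOCATIONS_UM = (100.0, 200.0, 300.0)
OCCUPANCY_FRACTION = 0.5


@dataclass
class OnlRowCount:
    """Row count at one signed location (um from the ONH)."""

    location_um: float
    n_rows: int
    mean_rows: float | None = None   # across replicates, if any
    se_rows: float | None = None


@dataclass
class SpiderProfile:
    """Row counts ordered from the superior to the inferior edge."""

    entries: list[OnlRowCount]
    group: str = ""

    def locations(self) -> list[float]:
        return [e.location_um for e in self.entries]

    def counts(self) -> list[int]:
        return [e.n_rows for e in self.entries]


def count_rows(mask: np.ndarray, column_window: tuple[int, int] | None = None
               ) -> int:
    """Number of nuclei rows within a lateral window of a binary mask.

    The window's vertical occupancy profile (fraction of positive pixels
    per image row) is thresholded at 50%; the count is the number of
    maximal runs of above-threshold rows.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise InputError("nuclei mask must be 2D")
    if column_window is None:
        column_window = (0, mask.shape[1])
    c0, c1 = column_window
    if not (0 <= c0 < c1 <= mask.shape[1]) or mask.shape[0] == 0:
        raise InputError(f"empty or out-of-bounds window {column_window} "
                         f"for mask of shape {mask.shape}")
    occupancy = mask[:, c0:c1].mean(axis=1)
    occupied = occupancy >= OCCUPANCY_FRACTION
    starts = np.diff(np.concatenate(([0], occupied.astype(int)))) == 1
    return int(starts.sum())


def build_spider(
    masks_by_location: Mapping[float, np.ndarray | Sequence[np.ndarray]]
    | Sequence[tuple[float, np.ndarray | Sequence[np.ndarray]]],
    group: str = "",
) -> SpiderProfile:
    """Assemble the spider profile from per-location masks.

    ``masks_by_location`` maps signed location (um, positive = superior) to
    one mask or a sequence of replicate masks — either a mapping or a
    sequence of ``(location, mask)`` pairs; duplicate locations are
    refused.  Replicates contribute a mean ± SE alongside the first
    replicate's count.  Entries are ordered from the superior edge (most
    positive) to the inferior edge.
    """
    if not isinstance(masks_by_location, Mapping):
        pairs = [(float(loc), m) for loc, m in masks_by_location]
        locations = [loc for loc, _ in pairs]
        if len(set(locations)) != len(locations):
            raise InputError("duplicate locations")
        masks_by_location = dict(pairs)
    if len(masks_by_location) == 0:
        raise InputError("need at least one location")
    by_loc = {float(k): v for k, v in masks_by_location.items()}
    entries: list[OnlRowCount] = []
    for loc in sorted(by_loc, reverse=True):
        masks = by_loc[loc]
        if isinstance(masks, np.ndarray):
            masks = [masks]
        counts = [count_rows(m) for m in masks]
        mean = se = None
        if len(counts) > 1:
            res = cli_io.group_summary({"replicates": counts})[0]
            mean, se = res.mean, res.se
        entries.append(OnlRowCount(location_um=loc, n_rows=counts[0],
                                   mean_rows=mean, se_rows=se))
    return SpiderProfile(entries=entries, group=group)
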