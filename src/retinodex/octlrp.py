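"""SD-OCT longitudinal-reflectivity-profile (LRP) analysis.

A B-scan is a 2D image of axial rows by lateral A-scan columns.  Averaging
a 100-pixel-wide lateral window at each axial row yields the LRP, whose
alternating high/low reflectivity bands correspond to synaptic and nuclear
retinal layers.  Four interfaces are called from the profile — ILM,
OPL/ONL, ONL/IS-OS and Bruch's membrane — from which total retinal
thickness (BM - ILM) and outer-nuclear-layer thickness (ONL/IS-OS -
OPL/ONL) follow.  Thickness is sampled at the standard scheme: 5 locations
50 pixels apart on either side of the optic nerve head for total thickness,
and at 88/176/264/352/440 um on either side for the ONL profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import AnalysisError, InputError
from . import cli_io

log = logging.getLogger("retinodex.octlrp")

#: lateral sampling of the total-thickness protocol: 5 windows 50 px apart
TOTAL_THICKNESS_OFFSETS_PX = tuple(50 * k for k in range(1, 6))
#: ONL sampling locations in um on either side of the ONH
ONL_OFFSETS_UM = (88.0, 176.0, 264.0, 352.0, 440.0)
DEFAULT_LRP_WIDTH_PX = 100


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BScan:
    """One OCT B-scan; rows are axial pixels (row 0 = vitreous side)."""

    image: np.ndarray
    axial_scale_um: float
    lateral_scale_um: float
    onh_column: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise InputError("B-scan must be a 2D array (axial x lateral)")
        if self.axial_scale_um <= 0 or self.lateral_scale_um <= 0:
            raise InputError("pixel scales must be positive")
        if np.any(self.image < 0):
            raise InputError("B-scan intensities must be nonnegative")

    @property
    def n_rows(self) -> int:
        return self.image.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.image.shape[1]


@dataclass
class LRProfile:
    """Lateral-averaged axial reflectivity profile."""

    depth_um: np.ndarray
    reflectivity: np.ndarray
    center_column: int
    width_px: int


@dataclass
class LayerBoundaries:
    """Called interface depths in um from the vitreous side."""

    ilm_um: float
    opl_onl_um: float
    onl_isos_um: float
    bm_um: float

    def __post_init__(self) -> None:
        if not (self.ilm_um < self.opl_onl_um < self.onl_isos_um < self.bm_um):
            raise AnalysisError(
                "boundary ordering violated: expected "
                "ILM < OPL/ONL < ONL/IS-OS < BM, got "
                f"{self.ilm_um:.2f}, {self.opl_onl_um:.2f}, "
                f"{self.onl_isos_um:.2f}, {self.bm_um:.2f}")

    @property
    def total_um(self) -> float:
        return self.bm_um - self.ilm_um

    @property
    def onl_um(self) -> float:
        return self.onl_isos_um - self.opl_onl_um


@dataclass
class ThicknessProfile:
    """Thickness summary of one averaged B-scan."""

    total_thickness_um: float
    onl_by_offset_um: dict[float, float]   # signed offset um -> ONL um
    age_days: int | None = None

    def __post_init__(self) -> None:
        for off, onl in self.onl_by_offset_um.items():
            if onl <= 0 or onl >= self.total_thickness_um:
                raise AnalysisError(
                    f"ONL thickness {onl:.1f} um at offset {off:+.0f} um "
                    "outside (0, total)")


class LongitudinalSummary(NamedTuple):
    table: "object"           # pandas DataFrame, one row per (age, group)
    monotone_decrease: bool   # per-age means strictly decrease with age
    comparisons: "object"     # DataFrame of per-age group differences (or None)


# ---------------------------------------------------------------------------
# registration and averaging
# ---------------------------------------------------------------------------

def estimate_shift(ref: np.ndarray, mov: np.ndarray) -> tuple[int, int]:
    """Integer (rows, cols) shift s such that ``np.roll(mov, s)`` best
    matches ``ref`` under circular cross-correlation."""
    if ref.shape != mov.shape:
        raise InputError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    a = ref - ref.mean()
    b = mov - mov.mean()
    corr = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real
    dy, dx = np.unravel_index(int(np.argmax(corr)), corr.shape)
    if dy > ref.shape[0] // 2:
        dy -= ref.shape[0]
    if dx > ref.shape[1] // 2:
        dx -= ref.shape[1]
    return int(dy), int(dx)


def register_and_average(bscans: Sequence[BScan]) -> BScan:
    """Align every scan to the first by the integer shift maximizing the
    cross-correlation, then average pixelwise.

    A single input is returned unchanged.  Averaging n independent speckle
    realizations reduces the per-pixel noise SD by ~sqrt(n).
    """
    if len(bscans) == 0:
        raise InputError("need at least one B-scan")
    ref = bscans[0]
    if len(bscans) == 1:
        return ref
    acc = ref.image.astype(float).copy()
    for scan in bscans[1:]:
        if scan.image.shape != ref.image.shape:
            raise InputError("all B-scans must share one shape")
        dy, dx = estimate_shift(ref.image, scan.image)
        acc += np.roll(scan.image, (dy, dx), axis=(0, 1))
    return BScan(image=acc / len(bscans), axial_scale_um=ref.axial_scale_um,
                 lateral_scale_um=ref.lateral_scale_um,
                 onh_column=ref.onh_column)


# ---------------------------------------------------------------------------
# LRP and boundary detection
# ---------------------------------------------------------------------------

def compute_lrp(b: BScan, center_column: int,
                width_px: int = DEFAULT_LRP_WIDTH_PX) -> LRProfile:
    """Mean reflectivity over a lateral window at every axial row."""
    if width_px < 1:
        raise InputError("width must be >= 1 pixel")
    c0 = center_column - width_px // 2
    c1 = c0 + width_px
    if c0 < 0 or c1 > b.n_ascans:
        raise InputError(
            f"LRP window [{c0}, {c1}) outside image of {b.n_ascans} A-scans")
    refl = b.image[:, c0:c1].mean(axis=1)
    depth = np.arange(b.n_rows, dtype=float) * b.axial_scale_um
    return LRProfile(depth_um=depth, reflectivity=refl,
                     center_column=int(center_column), width_px=int(width_px))


def _crossing(depth: np.ndarray, p: np.ndarray, thr: float, k0: int, k1: int,
              rising: bool, first: bool) -> float | None:
    """Sub-pixel depth of a threshold crossing in samples [k0, k1)."""
    seg = p[k0:k1 + 1]
    if rising:
        hits = np.nonzero((seg[:-1] < thr) & (seg[1:] >= thr))[0]
    else:
        hits = np.nonzero((seg[:-1] >= thr) & (seg[1:] < thr))[0]
    if hits.size == 0:
        return None
    k = k0 + (hits[0] if first else hits[-1])
    frac = (thr - p[k]) / (p[k + 1] - p[k])
    return float(depth[k] + frac * (depth[k + 1] - depth[k]))


def detect_boundaries(lrp: LRProfile) -> LayerBoundaries:
    """Call the four layer interfaces from one reflectivity profile.

    The profile is expected to show two hyper-reflective bands (inner
    retina and the IS/OS..BM complex) separated by the hypo-reflective ONL
    trough.  Edges are located at half-height between adjacent extremum
    plateaus and linearly interpolated to sub-pixel depth: the ILM is the
    first rising half-max edge, BM the last falling one, and the ONL
    interfaces the falling/rising half-height edges into and out of the
    deepest trough between them.  All landmarks are relative (half-height),
    so calls are invariant under global intensity scaling.
    """
    p = np.asarray(lrp.reflectivity, dtype=float)
    depth = np.asarray(lrp.depth_um, dtype=float)
    if p.size < 8:
        raise InputError("profile too short")
    top = float(p.max())
    vitreous = float(p[:3].mean())
    if top <= vitreous or np.ptp(p) == 0:
        raise AnalysisError("no extrema: profile is flat")
    half = (vitreous + top) / 2.0

    bright = p > half
    n_bands = int(np.count_nonzero(np.diff(bright.astype(int)) == 1)
                  + bright[0])
    if n_bands < 2:
        raise AnalysisError(
            f"expected >= 2 hyper-reflective bands, found {n_bands}")

    ilm = _crossing(depth, p, half, 0, p.size - 1, rising=True, first=True)
    bm = _crossing(depth, p, half, 0, p.size - 1, rising=False, first=False)
    if ilm is None:
        raise AnalysisError("missing landmark: ILM (no rising half-max edge)")
    if bm is None:
        raise AnalysisError("missing landmark: BM (no falling half-max edge)")

    k_ilm = int(np.searchsorted(depth, ilm))
    k_bm = int(np.searchsorted(depth, bm))
    if k_bm - k_ilm < 3:
        raise AnalysisError("retina too thin to contain a nuclear trough")
    inner = slice(k_ilm, k_bm)
    k_tr = k_ilm + int(np.argmin(p[inner]))
    v_tr = float(p[k_tr])
    if v_tr >= half:
        raise AnalysisError("missing landmark: ONL trough "
                            "(no hypo-reflective band between ILM and BM)")
    v_p1 = float(p[k_ilm:k_tr + 1].max())
    v_p2 = float(p[k_tr:k_bm + 1].max())
    opl_onl = _crossing(depth, p, (v_p1 + v_tr) / 2, k_ilm, k_tr,
                        rising=False, first=False)
    onl_isos = _crossing(depth, p, (v_p2 + v_tr) / 2, k_tr, k_bm,
                         rising=True, first=True)
    if opl_onl is None:
        raise AnalysisError("missing landmark: OPL/ONL edge")
    if onl_isos is None:
        raise AnalysisError("missing landmark: ONL/IS-OS edge")
    return LayerBoundaries(ilm_um=ilm, opl_onl_um=opl_onl,
                           onl_isos_um=onl_isos, bm_um=bm)


# ---------------------------------------------------------------------------
# thickness protocols
# ---------------------------------------------------------------------------

def _boundaries_at(b: BScan, columns: Iterable[tuple[str, int]],
                   width_px: int) -> dict[str, LayerBoundaries]:
    out: dict[str, LayerBoundaries] = {}
    failures: list[str] = []
    for label, col in columns:
        try:
            out[label] = detect_boundaries(compute_lrp(b, col, width_px))
        except (InputError, AnalysisError) as exc:
            failures.append(f"{label}: {exc}")
    if failures:
        raise AnalysisError(
            "boundary detection failed at " + "; ".join(failures))
    return out


def total_retinal_thickness(
    b: BScan,
    onh_column: int | None = None,
    *,
    width_px: int = DEFAULT_LRP_WIDTH_PX,
) -> float:
    """Mean ILM-to-BM thickness over the 10-location protocol.

    LRPs of ``width_px`` are taken at columns ``onh +/- 50*k`` (k = 1..5)
    and the 10 per-location thicknesses averaged.
    """
    onh = _resolve_onh(b, onh_column)
    cols = [(f"{s:+d}px", onh + s)
            for k in TOTAL_THICKNESS_OFFSETS_PX for s in (+k, -k)]
    bounds = _boundaries_at(b, cols, width_px)
    return float(np.mean([bd.total_um for bd in bounds.values()]))


def onl_thickness_profile(
    b: BScan,
    onh_column: int | None = None,
    *,
    width_px: int = DEFAULT_LRP_WIDTH_PX,
    age_days: int | None = None,
) -> ThicknessProfile:
    """ONL thickness at the fixed um offsets on either side of the ONH.

    Offsets are converted to columns by rounding ``offset / lateral_scale``
    to the nearest column (positive = superior).  The profile's total
    thickness is the mean ILM-to-BM span over the same 10 windows.
    """
    onh = _resolve_onh(b, onh_column)
    cols = []
    for off in ONL_OFFSETS_UM:
        for sign in (+1, -1):
            col = onh + sign * int(round(off / b.lateral_scale_um))
            cols.append((f"{sign * off:+.0f}um", col))
    bounds = _boundaries_at(b, cols, width_px)
    onl = {float(label[:-2]): bd.onl_um for label, bd in bounds.items()}
    total = float(np.mean([bd.total_um for bd in bounds.values()]))
    return ThicknessProfile(total_thickness_um=total, onl_by_offset_um=onl,
                            age_days=age_days)


def _resolve_onh(b: BScan, onh_column: int | None) -> int:
    if onh_column is not None:
        return int(onh_column)
    if b.onh_column is not None:
        return int(b.onh_column)
    return find_onh_column(b)


def find_onh_column(b: BScan, *, width_px: int = 20) -> int:
    """Convenience auto-detector: the column whose lateral window has the
    smallest integrated above-half-max reflectivity (the ONH excavation
    carries no retinal bands)."""
    img = b.image
    half = (img.max() + img.min()) / 2.0
    occupancy = (img > half).sum(axis=0).astype(float)
    kernel = np.ones(width_px) / width_px
    smooth = np.convolve(occupancy, kernel, mode="same")
    lo = width_px
    hi = img.shape[1] - width_px
    return int(lo + np.argmin(smooth[lo:hi]))


# ---------------------------------------------------------------------------
# longitudinal summaries
# ---------------------------------------------------------------------------

def longitudinal_summary(
    profiles: Sequence[ThicknessProfile],
    groups: Sequence[str] | None = None,
) -> LongitudinalSummary:
    """Per-age mean ± SE of total thickness, with the strict-decrease flag
    and (when exactly two groups are labelled) a per-age Welch comparison."""
    import pandas as pd

    if any(p.age_days is None for p in profiles):
        raise InputError("every profile needs an age_days label")
    ages = sorted({p.age_days for p in profiles})
    if len(ages) < 2:
        raise InputError("longitudinal summary needs >= 2 ages")
    if groups is None:
        groups = ["all"] * len(profiles)
    if len(groups) != len(profiles):
        raise InputError("one group label per profile required")

    rows = []
    for age in ages:
        for g in sorted(set(groups)):
            vals = [p.total_thickness_um for p, gg in zip(profiles, groups)
                    if p.age_days == age and gg == g]
            if not vals:
                continue
            res = cli_io.group_summary({g: vals})[0]
            rows.append({"age_days": age, "group": g, "n": res.n,
                         "mean_total_um": res.mean, "se_um": res.se})
    table = pd.DataFrame(rows)

    per_age_means = table.groupby("age_days")["mean_total_um"].mean()
    monotone = bool(np.all(np.diff(per_age_means.to_numpy()) < 0))

    comparisons = None
    names = sorted(set(groups))
    if len(names) == 2:
        comp_rows = []
        for age in ages:
            by_group = {
                g: [p.total_thickness_um for p, gg in zip(profiles, groups)
                    if p.age_days == age and gg == g]
                for g in names}
            if all(by_group.values()):
                res = cli_io.group_summary(by_group, compare=(names[0], names[1]))
                diff, t, pval = next(r for r in res
                                     if r.group == names[0]).comparison
                comp_rows.append({"age_days": age, "difference_um": diff,
                                  "t": t, "p": pval})
        comparisons = pd.DataFrame(comp_rows)
    return LongitudinalSummary(table=table, monotone_decrease=monotone,
                               comparisons=comparisons)
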