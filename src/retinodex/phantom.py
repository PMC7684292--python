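"""Seeded synthetic phantoms with known ground truth.

Four generators emulate the statistical structure the analysis pipelines
assume, each returning the data object together with a :class:`PhantomTruth`
used as the recovery oracle in tests:

* a spherical-eye cryo-fluorescence phantom (NADH and FAD channel volumes
  with a fluorescent retinal shell),
* a layered OCT B-scan with alternating hypo/hyper-reflective bands,
  multiplicative speckle and an optic-nerve-head excavation,
* a biphasic flash-ERG waveform whose a/b amplitudes follow a saturating
  (Naka-Rushton-type) intensity-response function, and
* a binary outer-nuclear-layer nuclei mask with a known number of rows.

All randomness flows from one explicit integer seed per call; identical
config + seed is bit-identical.  No global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .redox3d import FluorescenceVolume
from .octlrp import BScan
from .erg import ERGTrace

__all__ = [
    "EyePhantomConfig",
    "OctPhantomConfig",
    "ErgPhantomConfig",
    "PhantomTruth",
    "make_cryo_phantom",
    "make_oct_bscan",
    "make_erg_trace",
    "make_onl_mask",
    "CRYO_PROFILES",
    "OCT_PROFILES",
]


# ---------------------------------------------------------------------------
# configurations and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyePhantomConfig:
    """Geometry and photometry of the spherical cryo-imaging eye phantom.

    The default globe is a 2 mm sphere sampled at 10 um isotropic voxels
    (a 1:3.2 scale model of a rat eye); the fluorescent retinal shell is
    50 um thick, the p30 retinal thickness at that scale.  Intensities are
    arbitrary fluorescence units; ``noise_cv`` is the per-voxel coefficient
    of variation of both channels.
    """

    eye_diameter_um: float = 2000.0
    shell_outer_radius_um: float = 950.0
    shell_thickness_um: float = 50.0
    voxel_size_um: float = 10.0
    nadh_mean: float = 92.0
    fad_mean: float = 100.0
    noise_cv: float = 0.02
    background_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.shell_thickness_um < self.shell_outer_radius_um
                <= self.eye_diameter_um / 2):
            raise ConfigurationError(
                "need shell_thickness < shell_outer_radius <= eye_diameter/2")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.fad_mean <= 0 or self.nadh_mean < 0:
            raise ConfigurationError("channel means must be positive")
        if self.voxel_size_um <= 0:
            raise ConfigurationError("voxel size must be positive")

    @property
    def n_slices(self) -> int:
        """Number of z-slices (and of y/x pixels: the volume is cubic)."""
        return int(np.ceil(self.eye_diameter_um / self.voxel_size_um))

    @property
    def true_ratio(self) -> float:
        return self.nadh_mean / self.fad_mean


@dataclass(frozen=True)
class OctPhantomConfig:
    """Layered B-scan phantom: piecewise-constant axial bands + speckle.

    ``layer_depths_um`` are the interface depths from the vitreous side,
    strictly increasing: ILM first, Bruch's membrane last; any interfaces in
    between partition the retina into bands.  ``layer_reflectivities`` has
    one value per band, i.e. ``len(layer_depths_um) + 1`` entries counting
    the vitreous above the ILM and the background below BM.  Within
    ``onh_halfwidth_px`` of ``onh_center`` all retinal bands collapse to the
    vitreous level (optic-nerve-head excavation).  Speckle is multiplicative
    Normal(1, speckle_cv) — a variance-controllable simplification of
    Rayleigh OCT speckle.
    """

    n_ascans: int = 1000
    axial_pixels: int = 250
    axial_scale_um: float = 1.0
    lateral_scale_um: float = 2.0
    layer_depths_um: tuple[float, ...] = (30.5, 105.6, 160.6, 208.6)
    layer_reflectivities: tuple[float, ...] = (4.0, 180.0, 60.0, 200.0, 8.0)
    onh_center: int = 500
    onh_halfwidth_px: int = 10
    speckle_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.layer_depths_um, dtype=float)
        if d.size < 2 or np.any(np.diff(d) <= 0):
            raise ConfigurationError("layer depths must be strictly increasing")
        if d[-1] >= self.axial_pixels * self.axial_scale_um:
            raise ConfigurationError("deepest interface exceeds the image")
        if len(self.layer_reflectivities) != d.size + 1:
            raise ConfigurationError(
                "need one reflectivity per band (n_interfaces + 1)")
        if self.speckle_cv < 0:
            raise ConfigurationError("speckle_cv must be >= 0")

    # -- derived truth -----------------------------------------------------
    @property
    def ilm_um(self) -> float:
        return float(self.layer_depths_um[0])

    @property
    def bm_um(self) -> float:
        return float(self.layer_depths_um[-1])

    def onl_interfaces_um(self) -> tuple[float, float]:
        """(OPL/ONL, ONL/IS-OS): interfaces bounding the least-reflective
        retinal band, the outer-nuclear-layer trough of the profile."""
        inner = np.asarray(self.layer_reflectivities[1:-1], dtype=float)
        k = int(np.argmin(inner))
        return float(self.layer_depths_um[k]), float(self.layer_depths_um[k + 1])


@dataclass(frozen=True)
class ErgPhantomConfig:
    """Biphasic flash-ERG waveform generator parameters.

    The saturated a-wave (baseline to trough) and b-wave (trough to peak)
    amplitudes scale with flash intensity I through the Naka-Rushton form
    S(I) = I^n / (I^n + K^n); the two lobes are Gaussians peaking at the
    configured implicit times.  Amplitudes in uV, times in ms, intensities
    in mcd.s/m^2.
    """

    a_amp_max: float = 150.0
    b_amp_max: float = 300.0
    a_time_ms: float = 15.0
    b_time_ms: float = 60.0
    semi_saturation_K: float = 500.0
    hill_n: float = 1.0
    noise_sd: float = 5.0
    sampling_rate_hz: float = 2000.0
    flash_intensities: tuple[float, ...] = (
        100.0, 250.0, 500.0, 1000.0, 2500.0, 5000.0, 10000.0, 25000.0)
    seed: int = 0
    pre_ms: float = 20.0
    post_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.a_time_ms >= self.b_time_ms:
            raise ConfigurationError("a_time must precede b_time")
        if any(i <= 0 for i in self.flash_intensities):
            raise ConfigurationError("flash intensities must be positive")
        if self.noise_sd < 0 or self.sampling_rate_hz <= 0:
            raise ConfigurationError("noise_sd >= 0 and sampling rate > 0 required")

    def saturation(self, intensity: float) -> float:
        i_n = intensity ** self.hill_n
        return i_n / (i_n + self.semi_saturation_K ** self.hill_n)

    def a_amp(self, intensity: float) -> float:
        """Closed-form baseline-to-trough a-wave amplitude at intensity I."""
        return self.a_amp_max * self.saturation(intensity)

    def b_amp(self, intensity: float) -> float:
        """Closed-form trough-to-peak b-wave amplitude at intensity I."""
        return self.b_amp_max * self.saturation(intensity)


@dataclass
class PhantomTruth:
    """Generator ground truth used as the recovery oracle in tests."""

    shell_mask: np.ndarray | None = None
    true_ratio: float | None = None
    layer_depths_um: tuple[float, ...] | None = None
    true_total_thickness_um: float | None = None
    true_onl_thickness_um: float | None = None
    onh_column: int | None = None
    waveform_params: ErgPhantomConfig | None = None
    n_nuclei_rows: int | None = None
    config: object | None = None


# ---------------------------------------------------------------------------
# cryo-fluorescence eye phantom
# ---------------------------------------------------------------------------

def make_cryo_phantom(
    cfg: EyePhantomConfig,
) -> tuple[FluorescenceVolume, FluorescenceVolume, PhantomTruth]:
    """Generate the two-channel spherical-shell fluorescence volume.

    Voxels whose centres fall inside the shell
    ``outer_radius - thickness < r <= outer_radius`` draw
    Normal(channel_mean, noise_cv * channel_mean) truncated at 0; all other
    voxels draw around ``background_mean`` with the same CV.  The volume is
    cubic with ``ceil(eye_diameter / voxel_size)`` voxels per axis and the
    globe centred in it.
    """
    n = cfg.n_slices
    c = (n - 1) / 2.0
    ax = (np.arange(n, dtype=np.float32) - c) * cfg.voxel_size_um
    r2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
          + ax[None, None, :] ** 2)
    outer2 = cfg.shell_outer_radius_um ** 2
    inner2 = (cfg.shell_outer_radius_um - cfg.shell_thickness_um) ** 2
    shell = (r2 <= outer2) & (r2 > inner2)
    del r2

    rng = np.random.default_rng(cfg.seed)
    channels = {}
    for name, mean in (("NADH", cfg.nadh_mean), ("FAD", cfg.fad_mean)):
        vol = rng.normal(cfg.background_mean,
                         cfg.noise_cv * cfg.background_mean,
                         size=(n, n, n)).astype(np.float32)
        fore = rng.normal(mean, cfg.noise_cv * mean,
                          size=int(shell.sum())).astype(np.float32)
        vol[shell] = fore
        np.clip(vol, 0, None, out=vol)
        channels[name] = FluorescenceVolume(
            voxels=vol, voxel_size_um=(cfg.voxel_size_um,) * 3, channel=name)
    truth = PhantomTruth(shell_mask=shell, true_ratio=cfg.true_ratio, config=cfg)
    return channels["NADH"], channels["FAD"], truth


#: packaged cryo profiles, ratios calibrated to the reported group means
CRYO_PROFILES: dict[str, EyePhantomConfig] = {
    "SD": EyePhantomConfig(nadh_mean=92.0, fad_mean=100.0, seed=1),
    "P23H": EyePhantomConfig(nadh_mean=66.0, fad_mean=100.0, seed=1),
    "P23H-PBM": EyePhantomConfig(nadh_mean=97.0, fad_mean=100.0, seed=1),
}


def cryo_profile(name: str, *, seed: int | None = None,
                 noise_cv: float | None = None) -> EyePhantomConfig:
    """A packaged cryo profile, optionally reseeded or renoised."""
    try:
        cfg = CRYO_PROFILES[name]
    except KeyError:
        raise InputError(f"unknown cryo profile {name!r}; "
                         f"available: {sorted(CRYO_PROFILES)}") from None
    kw = {}
    if seed is not None:
        kw["seed"] = seed
    if noise_cv is not None:
        kw["noise_cv"] = noise_cv
    return replace(cfg, **kw) if kw else cfg


# ---------------------------------------------------------------------------
# OCT B-scan phantom
# ---------------------------------------------------------------------------

def make_oct_bscan(cfg: OctPhantomConfig) -> tuple[BScan, PhantomTruth]:
    """Generate one speckled, layered B-scan with its ground truth.

    Row ``r`` of every A-scan takes the reflectivity of the band containing
    depth ``r * axial_scale`` (so the noiseless column changes value exactly
    at the configured interface rows), then the whole image is multiplied by
    ``Normal(1, speckle_cv)`` speckle.  Columns within the ONH halfwidth are
    set to the vitreous band level at all rows before speckling.
    """
    depths_px = np.asarray(cfg.layer_depths_um) / cfg.axial_scale_um
    rows = np.arange(cfg.axial_pixels)
    band = np.searchsorted(depths_px, rows, side="right")
    column = np.asarray(cfg.layer_reflectivities, dtype=float)[band]
    image = np.tile(column[:, None], (1, cfg.n_ascans))

    lo = max(cfg.onh_center - cfg.onh_halfwidth_px, 0)
    hi = min(cfg.onh_center + cfg.onh_halfwidth_px + 1, cfg.n_ascans)
    image[:, lo:hi] = cfg.layer_reflectivities[0]

    if cfg.speckle_cv > 0:
        rng = np.random.default_rng(cfg.seed)
        image = image * rng.normal(1.0, cfg.speckle_cv, size=image.shape)
        np.clip(image, 0, None, out=image)

    opl_onl, onl_isos = cfg.onl_interfaces_um()
    truth = PhantomTruth(
        layer_depths_um=tuple(cfg.layer_depths_um),
        true_total_thickness_um=cfg.bm_um - cfg.ilm_um,
        true_onl_thickness_um=onl_isos - opl_onl,
        onh_column=cfg.onh_center,
        config=cfg,
    )
    scan = BScan(image=image, axial_scale_um=cfg.axial_scale_um,
                 lateral_scale_um=cfg.lateral_scale_um,
                 onh_column=cfg.onh_center)
    return scan, truth


def _oct_profile(total_um: float, onl_um: float, **kw) -> OctPhantomConfig:
    # half-pixel ILM placement: interfaces land inside sampling intervals,
    # where the half-height edge estimator is near-unbiased
    ilm = 30.5
    bm = ilm + total_um
    opl_onl = bm - onl_um - 48.0  # 48 um outer IS/OS..BM complex
    return OctPhantomConfig(
        layer_depths_um=(ilm, opl_onl, opl_onl + onl_um, bm), **kw)


#: packaged OCT profiles; totals match the reported p30 group means
OCT_PROFILES: dict[str, OctPhantomConfig] = {
    "PBM-p30": _oct_profile(178.1, 55.0, seed=1),
    "sham-p30": _oct_profile(169.2, 47.0, seed=1),
}


def oct_profile(name: str, *, seed: int | None = None) -> OctPhantomConfig:
    try:
        cfg = OCT_PROFILES[name]
    except KeyError:
        raise InputError(f"unknown OCT profile {name!r}; "
                         f"available: {sorted(OCT_PROFILES)}") from None
    return replace(cfg, seed=seed) if seed is not None else cfg


def make_oct_replicates(
    cfg: OctPhantomConfig,
    n_scans: int,
    *,
    jitter_px: int = 0,
) -> tuple[list[BScan], PhantomTruth]:
    """``n_scans`` speckle replicates of one phantom, optionally with random
    integer (axial, lateral) acquisition jitter applied as a circular shift.

    Replicate ``i`` uses seed ``cfg.seed + i`` so the set is reproducible.
    """
    if n_scans < 1:
        raise InputError("need at least one scan")
    scans: list[BScan] = []
    truth: PhantomTruth | None = None
    rng = np.random.default_rng(cfg.seed)
    for i in range(n_scans):
        scan, t = make_oct_bscan(replace(cfg, seed=cfg.seed + i))
        if jitter_px > 0 and i > 0:
            dy, dx = rng.integers(-jitter_px, jitter_px + 1, size=2)
            scan.image = np.roll(scan.image, (int(dy), int(dx)), axis=(0, 1))
        scans.append(scan)
        truth = truth or t
    return scans, truth


# ---------------------------------------------------------------------------
# ERG waveform phantom
# ---------------------------------------------------------------------------

def make_erg_trace(cfg: ErgPhantomConfig, intensity: float) -> ERGTrace:
    """Deterministic biphasic waveform plus Gaussian noise at one intensity.

    The trace is ``-A(I) g_a(t) + (B(I) - A(I)) g_b(t)`` with Gaussian lobes
    ``g`` peaking at the configured implicit times (widths a_time/3 and
    (b_time - a_time)/4, narrow enough that the lobes are separable), so the
    ISCEV-convention measurements recover A as baseline-to-trough and B as
    trough-to-peak.  Noise is Normal(0, noise_sd) per sample.
    """
    if intensity <= 0:
        raise InputError("flash intensity must be positive")
    dt = 1000.0 / cfg.sampling_rate_hz
    t = np.arange(-cfg.pre_ms, cfg.post_ms + dt / 2, dt)
    a = cfg.a_amp(intensity)
    b = cfg.b_amp(intensity)
    sig_a = cfg.a_time_ms / 3.0
    sig_b = (cfg.b_time_ms - cfg.a_time_ms) / 4.0
    v = (-a * np.exp(-0.5 * ((t - cfg.a_time_ms) / sig_a) ** 2)
         + (b - a) * np.exp(-0.5 * ((t - cfg.b_time_ms) / sig_b) ** 2))
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, int(round(intensity * 1000))]))
        v = v + rng.normal(0.0, cfg.noise_sd, size=t.size)
    return ERGTrace(time_ms=t, voltage_uv=v, flash_intensity=float(intensity),
                    protocol="scotopic_series")


# ---------------------------------------------------------------------------
# ONL nuclei-row mask
# ---------------------------------------------------------------------------

def make_onl_mask(
    n_rows: int,
    nucleus_diameter_um: float = 5.0,
    width_um: float = 100.0,
    *,
    pixel_size_um: float = 1.0,
) -> tuple[np.ndarray, PhantomTruth]:
    """Binary mask with exactly ``n_rows`` horizontal rows of disjoint
    ellipses (circular nuclei), one row per nucleus diameter of height.

    The mask is ``n_rows * diameter`` pixels tall, so the band height in um
    equals ``n_rows * nucleus_diameter_um``.
    """
    if n_rows < 0:
        raise InputError("n_rows must be >= 0")
    d = int(round(nucleus_diameter_um / pixel_size_um))
    if d < 3 and n_rows > 0:
        raise InputError("nucleus diameter must span at least 3 pixels")
    w = int(round(width_um / pixel_size_um))
    mask = np.zeros((n_rows * d, w), dtype=bool)
    if n_rows:
        period = int(np.ceil(1.6 * d))  # lateral centre spacing, gap >= 0.6 d
        y = np.arange(n_rows * d)[:, None]
        x = np.arange(w)[None, :]
        r = d / 2.0
        for row in range(n_rows):
            cy = row * d + (d - 1) / 2.0
            for cx in range(period // 2, w, period):
                mask |= (((y - cy) / r) ** 2 + ((x - cx) / r) ** 2) <= 1.0
    return mask, PhantomTruth(n_nuclei_rows=int(n_rows))
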