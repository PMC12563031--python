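"""Seed-deterministic synthetic data with known ground truth.

Three generators mirror the three measurement stages so the whole analysis
pipeline can be exercised and validated without instrument data:

* :func:`simulate_indentation` — ramp-and-hold indentation curves from a
  known SLS truth via the Lee–Radok forward model, with multiplicative
  Gaussian force noise (instrument-like) and an optional pre-contact
  approach segment.  Defaults follow the bench protocol: 500 um spherical
  tip, 30 um/s ramp to 300 um, 30 s hold.
* :func:`simulate_volume` — porous grayscale volumes at 6 um voxels with a
  controllable void fraction: overlapping spherical pores are carved out of
  a solid block until the target is met to +/-0.5 percentage points, then
  rendered as two intensity classes with additive Gaussian noise.
* :func:`simulate_cam_table` — paired 0 h/72 h vessel observations with
  per-group log-normal fold-change effects, default group sizes 9/7/6/6.

Every generator returns its ground truth beside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indentfit import IndentationCurve
from .mechanics import DepthProtocol, ProbeSpec, SampleGeometry, SLSParams, lee_radok_force
from .microct import VolumeImage

__all__ = [
    "CurveSimSpec",
    "VolumeSimSpec",
    "DEFAULT_CAM_GROUP_SIZES",
    "simulate_indentation",
    "simulate_volume",
    "simulate_cam_table",
]

#: CAM assay design: embryos per implantation group
DEFAULT_CAM_GROUP_SIZES = {
    "Control": 9,
    "Fibro-Gide": 7,
    "Mucoderm": 6,
    "Fibro-Matrix": 6,
}

# Mean vessel-count fold changes per group used by default.  The control CAM
# roughly doubles its vessel count over 72 h of normal development; the
# stiff/dense and slowly degrading scaffolds blunt the response.
_DEFAULT_CAM_EFFECTS = {
    "Control": 2.0,
    "Fibro-Gide": 1.3,
    "Mucoderm": 1.7,
    "Fibro-Matrix": 1.9,
}


@dataclass(frozen=True)
class CurveSimSpec:
    """Configuration of one synthetic indentation experiment.

    Units at this boundary are bench units: um, um/s, s, Hz.  ``truth`` is
    in Pa/s (SI) as everywhere in the mechanics core.  ``noise_fraction``
    is the SD of the multiplicative Gaussian force noise;
    ``approach_depth_um`` > 0 prepends a pre-contact travel segment with
    zero force so contact detection has something to find.
    """

    truth: SLSParams = SLSParams(e0=30e3, einf=10e3, tau=5.0)
    probe: ProbeSpec = ProbeSpec(tip_radius=500e-6, cantilever_stiffness=12.0)
    geometry: SampleGeometry = SampleGeometry()
    speed_um_s: float = 30.0
    max_depth_um: float = 300.0
    hold_s: float = 30.0
    sample_rate_hz: float = 100.0
    noise_fraction: float = 0.0
    approach_depth_um: float = 0.0
    force_noise_floor_n: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.speed_um_s, self.max_depth_um, self.hold_s, self.sample_rate_hz) <= 0:
            raise ValueError("speed, max_depth, hold and sample_rate must be > 0")
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.approach_depth_um < 0 or self.force_noise_floor_n < 0:
            raise ValueError("approach depth and noise floor must be >= 0")


def simulate_indentation(spec: CurveSimSpec) -> tuple[IndentationCurve, dict]:
    """Generate one ramp-and-hold curve plus its ground-truth record."""
    protocol = DepthProtocol.ramp_hold(
        speed=spec.speed_um_s * 1e-6,
        max_depth=spec.max_depth_um * 1e-6,
        hold=spec.hold_s,
        sample_rate=spec.sample_rate_hz,
    )
    force = lee_radok_force(protocol, spec.truth, spec.probe, spec.geometry)
    rng = np.random.default_rng(spec.seed)

    n_pre = int(round(spec.approach_depth_um / spec.speed_um_s * spec.sample_rate_hz))
    dt = 1.0 / spec.sample_rate_hz
    speed = spec.speed_um_s * 1e-6
    if n_pre > 0:
        t = np.arange(n_pre + protocol.time.size) * dt
        depth = np.concatenate([np.arange(n_pre) * dt * speed, n_pre * dt * speed + protocol.depth])
        f = np.concatenate([np.zeros(n_pre), force])
    else:
        t, depth, f = protocol.time, protocol.depth, force
    if spec.noise_fraction > 0:
        f = f * (1.0 + spec.noise_fraction * rng.standard_normal(f.size))
    if spec.force_noise_floor_n > 0:
        f = f + spec.force_noise_floor_n * rng.standard_normal(f.size)
    curve = IndentationCurve(
        time=t, depth=depth, force=f,
        probe=spec.probe, geometry=spec.geometry, label=spec.label,
    )
    truth = {
        "e0_pa": spec.truth.e0,
        "einf_pa": spec.truth.einf,
        "tau_s": spec.truth.tau,
        "contact_index": n_pre,
        "speed_um_s": spec.speed_um_s,
        "max_depth_um": spec.max_depth_um,
        "hold_s": spec.hold_s,
        "sample_rate_hz": spec.sample_rate_hz,
        "noise_fraction": spec.noise_fraction,
        "seed": spec.seed,
    }
    return curve, truth


@dataclass(frozen=True)
class VolumeSimSpec:
    """Configuration of one synthetic porous volume.

    Spherical pores (radii uniform in ``pore_radius_range_vox``, overlap
    allowed) are carved from a solid block that fills the volume up to
    ``air_margin_vox`` on every side; carving stops when the void fraction
    of the block is within +/-0.5 percentage points of
    ``target_void_fraction``.  Pore centres keep ``shell_clearance_vox``
    + radius away from the block surface so the internal pore network stays
    enclosed by solid (pores do not breach the surface).  ``dense_shell_vox``
    additionally reserves fully solid top/bottom slabs, emulating a dense
    collagen layer above the porous core.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 6.0
    target_void_fraction: float = 0.5
    pore_radius_range_vox: tuple[int, int] = (4, 12)
    solid_intensity: float = 180.0
    pore_intensity: float = 60.0
    intensity_sd: float = 15.0
    air_margin_vox: int = 4
    shell_clearance_vox: int = 2
    dense_shell_vox: int = 0
    tolerance: float = 0.005
    max_attempts: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_void_fraction < 1.0):
            raise ValueError("target_void_fraction must be in (0, 1)")
        if not (0 < self.pore_radius_range_vox[0] <= self.pore_radius_range_vox[1]):
            raise ValueError("pore_radius_range_vox must be increasing and positive")
        for v in (self.solid_intensity, self.pore_intensity):
            if not (0 <= v <= 255):
                raise ValueError("intensities must lie within 8-bit range")
        if min(self.shape) < 16:
            raise ValueError("shape must be at least 16 voxels per axis")


def _carve_sphere(void: np.ndarray, center: np.ndarray, r: int) -> tuple[slice, ...]:
    lo = np.maximum(center - r, 0)
    hi = np.minimum(center + r + 1, void.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    zz, yy, xx = np.ogrid[sl]
    ball = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= r * r
    return sl, ball


def simulate_volume(spec: VolumeSimSpec) -> tuple[VolumeImage, dict]:
    """Generate a noisy grayscale porous volume plus ground-truth masks.

    Returns ``(volume, truth)`` where ``truth`` holds the boolean
    ``solid_mask`` and ``block_mask`` (the scaffold extent, which a tight
    shrink-wrap ROI should recover) and the achieved ``void_fraction`` of
    the block.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape)
    m = spec.air_margin_vox
    block = np.zeros(spec.shape, dtype=bool)
    block[m : shape[0] - m, m : shape[1] - m, m : shape[2] - m] = True
    n_block = int(block.sum())

    void = np.zeros(spec.shape, dtype=bool)
    r_lo, r_hi = spec.pore_radius_range_vox
    shell = spec.shell_clearance_vox + spec.dense_shell_vox
    # largest radius whose centre region is nonempty on every axis
    r_feasible = (int(min(shape)) - 1) // 2 - m - shell - 1
    if r_feasible < r_lo:
        raise RuntimeError(
            f"pore radius range {spec.pore_radius_range_vox} too large for shape {spec.shape}"
        )
    r_hi = min(r_hi, r_feasible)
    n_void = 0
    target = spec.target_void_fraction
    attempts = 0
    while n_void / n_block < target:
        attempts += 1
        if attempts > spec.max_attempts:
            raise RuntimeError(
                f"could not reach void fraction {target} within {spec.max_attempts} "
                "attempts (pore radii too large for the volume?)"
            )
        r = int(rng.integers(r_lo, r_hi + 1))
        lo_c = m + shell + r
        hi_c = shape - (m + shell + r)  # exclusive
        if np.any(hi_c <= lo_c):
            raise RuntimeError("pore radius too large for the block interior")
        center = np.array([int(rng.integers(lo_c, hi_c[i])) for i in range(3)])
        sl, ball = _carve_sphere(void, center, r)
        region = void[sl]
        gained = int(np.count_nonzero(ball & ~region))
        if (n_void + gained) / n_block > target + spec.tolerance:
            continue  # would overshoot the band: reject this sphere, try again
        region |= ball
        n_void += gained

    solid = block & ~void
    if spec.dense_shell_vox > 0:
        ds = spec.dense_shell_vox
        solid[m : m + ds] = block[m : m + ds]
        solid[shape[0] - m - ds : shape[0] - m] = block[shape[0] - m - ds : shape[0] - m]

    intensities = np.where(solid, spec.solid_intensity, spec.pore_intensity)
    if spec.intensity_sd > 0:
        intensities = intensities + spec.intensity_sd * rng.standard_normal(spec.shape)
    data = np.clip(np.rint(intensities), 0, 255).astype(np.uint8)
    volume = VolumeImage(data=data, voxel_size_um=spec.voxel_size_um)
    truth = {
        "solid_mask": solid,
        "block_mask": block,
        "void_fraction": n_void / n_block,
        "target_void_fraction": target,
        "seed": spec.seed,
    }
    return volume, truth


def simulate_cam_table(
    n_per_group: dict[str, int] | None = None,
    group_effects: dict[str, float] | None = None,
    dispersion: float = 0.25,
    seed: int = 0,
    baseline_count_mean: float = 30.0,
    baseline_length_mm: float = 20.0,
    baseline_area_mm2: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Paired 0 h / 72 h CAM vessel observations per group.

    Fold changes are log-normal with mean equal to the group effect
    (mu = ln(effect) - sigma^2/2) and log-SD ``dispersion``; baselines are
    Poisson counts and log-normal lengths/areas.  Returns the table (one row
    per embryo, columns :data:`~scaffoldkit.angiometrics.VESSEL_COLUMNS`)
    and the ground-truth effect record.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    sizes = dict(DEFAULT_CAM_GROUP_SIZES if n_per_group is None else n_per_group)
    if any(n < 1 for n in sizes.values()):
        raise ValueError("need n >= 1 per group")
    effects = dict(_DEFAULT_CAM_EFFECTS if group_effects is None else group_effects)
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in sizes.items():
        effect = effects.get(group, 1.0)
        mu = math.log(effect) - 0.5 * dispersion**2
        for _ in range(n):
            c0 = int(rng.poisson(baseline_count_mean)) + 1
            l0 = float(baseline_length_mm * rng.lognormal(0.0, 0.2))
            a0 = float(baseline_area_mm2 * rng.lognormal(0.0, 0.2))
            folds = rng.lognormal(mu, dispersion, size=3)
            rows.append(
                {
                    "group": group,
                    "vessel_count_0h": c0,
                    "vessel_count_72h": int(round(c0 * folds[0])),
                    "total_length_0h": l0,
                    "total_length_72h": l0 * folds[1],
                    "network_area_0h": a0,
                    "network_area_72h": a0 * folds[2],
                }
            )
    table = pd.DataFrame(rows)
    truth = {"effects": effects, "dispersion": dispersion, "sizes": sizes, "seed": seed}
    return table, truth
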