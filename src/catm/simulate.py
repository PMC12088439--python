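"""Synthetic tomograms with known ground truth.

The forward model emulates the degradations that make particle assignment
in cryo-ET hard: a condensate-like packing of randomly oriented discs and
rods, modulated by the microscope contrast transfer function (CTF),
overlaid with white Gaussian noise at a stated SNR, and band-limited by the
missing wedge of a +/-60 degree tilt series.  The wedge is imposed directly
in Fourier space (no tilt-series projection/reconstruction), and is applied
to the final noisy volume so that data and wedge-filtered templates share
the same band limit.

Conventions: particles are positive density; the tilt axis is y and the
beam axis z; SNR is signal variance / noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.spatial.transform import Rotation
from scipy import ndimage

from .occupancy import OccupancyGrid, mask_voxel_indices
from .orientation import random_rotations, rotation_from_axis
from .particles import ParticleSet
from .templates import (DNA_ROD, NUCLEOSOME, ParticleShape, build_dna_template,
                        build_nucleosome_template, build_steric_mask,
                        rotate_volume)
from .volume import Volume

__all__ = [
    "ImagingModel",
    "GroundTruth",
    "SimulationConfig",
    "sample_particle_configuration",
    "render_volume",
    "apply_missing_wedge",
    "apply_ctf",
    "add_noise",
    "degrade",
    "generate_benchmark",
    "planted_condensate",
]


@dataclass(frozen=True)
class ImagingModel:
    """Forward-degradation parameters.

    tilt_min, tilt_max : degrees, stage tilt range (wedge axis = y)
    ctf_defocus : um (positive = underfocus)
    ctf_voltage : kV
    ctf_cs : mm, spherical aberration
    ctf_amplitude_contrast : fraction in [0, 1]
    snr : signal variance / noise variance; ``np.inf`` disables noise
    """

    tilt_min: float = -60.0
    tilt_max: float = 60.0
    ctf_defocus: float = 4.0
    ctf_voltage: float = 300.0
    ctf_cs: float = 2.7
    ctf_amplitude_contrast: float = 0.07
    snr: float = 0.078
    noise_correlation_nm: float = 1.0
    random_seed: int = 0

    def __post_init__(self):
        if not (-90.0 < self.tilt_min < self.tilt_max < 90.0 or
                (self.tilt_min, self.tilt_max) == (-90.0, 90.0)):
            raise ValueError("require -90 < tilt_min < tilt_max < 90")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass
class GroundTruth:
    """Known particle configuration of a simulated tomogram."""

    particles: ParticleSet
    box_size: np.ndarray = field(default_factory=lambda: np.zeros(3))


# ---------------------------------------------------------------------------
# particle configuration sampling


def default_templates(voxel_size: float = 1.0) -> dict[str, Volume]:
    return {
        "nucleosome_disc": build_nucleosome_template(NUCLEOSOME, voxel_size),
        "dna_rod": build_dna_template(DNA_ROD, voxel_size),
    }


def default_masks(templates: dict[str, Volume]) -> dict[str, Volume]:
    return {k: build_steric_mask(v, 0.5) for k, v in templates.items()}


def sample_particle_configuration(box_size, n_nucleosomes: int, n_dna: int,
                                  mask_set: dict[str, Volume] | None = None,
                                  seed: int | np.random.Generator = 0,
                                  voxel_size: float = 1.0,
                                  max_attempts: int = 20000) -> GroundTruth:
    """Uniformly random, sterically non-overlapping particle configuration.

    Positions are uniform inside the box (with a margin keeping each
    particle's mask cube in bounds), orientations uniform on SO(3).
    Rejection sampling against a shared occupancy grid enforces pairwise
    mask non-overlap; after ``max_attempts`` consecutive rejections a
    "density infeasible" error reports the density achieved so far.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    box_size = np.asarray(box_size, dtype=float).reshape(3)
    if mask_set is None:
        mask_set = default_masks(default_templates(voxel_size))
    shape_zyx = tuple(int(round(s / voxel_size)) for s in box_size[::-1])
    frame = Volume(np.zeros(shape_zyx, dtype=np.float32), voxel_size)
    occ = OccupancyGrid(frame)

    kinds = (["nucleosome_disc"] * n_nucleosomes) + (["dna_rod"] * n_dna)
    records = []
    for i, kind in enumerate(kinds):
        mask = mask_set[kind]
        margin = (mask.data.shape[0] / 2.0) * voxel_size
        lo, hi = margin, box_size - margin
        if np.any(hi <= lo):
            raise ValueError("density infeasible: box smaller than one particle")
        rejections = 0
        while True:
            pos = rng.uniform(lo, hi)
            rot = random_rotations(1, rng)[0]
            idx = mask_voxel_indices(mask, rot, pos, frame)
            if occ.overlap(idx) == 0:
                occ.insert(i, idx)
                eul = rot.as_euler("ZYZ", degrees=True)
                records.append((*pos, *eul, kind))
                break
            rejections += 1
            if rejections > max_attempts:
                achieved = len(records) / np.prod(box_size)
                raise RuntimeError(
                    f"density infeasible: {max_attempts} consecutive rejections "
                    f"after placing {len(records)} particles "
                    f"(achieved density {achieved:.2e} per nm^3)")
    import pandas as pd
    df = pd.DataFrame(records, columns=["x", "y", "z", "rot", "tilt", "psi", "kind"])
    return GroundTruth(ParticleSet(df), box_size)


# ---------------------------------------------------------------------------
# rendering


def render_volume(gt: GroundTruth, templates: dict[str, Volume] | None = None,
                  box: Volume | None = None, voxel_size: float = 1.0) -> Volume:
    """Sum of rotated, translated templates on a voxel grid.

    Each particle's template is resampled by a single trilinear affine
    transform combining the rotation and the sub-voxel part of the
    translation, then accumulated at the nearest-voxel window.  Linear in
    template amplitude by construction.
    """
    if templates is None:
        templates = default_templates(voxel_size)
    if box is None:
        shape_zyx = tuple(int(round(s / voxel_size)) for s in gt.box_size[::-1])
        box = Volume(np.zeros(shape_zyx, dtype=np.float32), voxel_size)
    out = np.zeros(box.data.shape, dtype=np.float64)
    p = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    parts = gt.particles
    rots = parts.rotations if len(parts) else None
    for i in range(len(parts)):
        kind = parts.kinds[i]
        tmpl = templates[kind]
        f_xyz = box.nm_to_voxel(parts.positions[i])
        g_xyz = np.rint(f_xyz).astype(int)
        frac_zyx = (f_xyz - g_xyz)[::-1]
        side = tmpl.data.shape[0]
        c = (side - 1) / 2.0
        g_zyx = g_xyz[::-1]
        lo = g_zyx - int(c)
        hi = lo + side
        if np.any(lo < 0) or np.any(hi > np.array(out.shape)):
            raise ValueError(f"particle {i} out of bounds at {parts.positions[i]}")
        m_xyz = rots[i].as_matrix()
        inv_zyx = (p @ m_xyz @ p).T
        cvec = np.full(3, c)
        offset = cvec - inv_zyx @ (cvec + frac_zyx)
        cube = ndimage.affine_transform(tmpl.data, inv_zyx, offset=offset,
                                        order=1, mode="constant", cval=0.0,
                                        prefilter=False)
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += cube
    return Volume(out.astype(np.float32), box.voxel_size, box.origin)


# ---------------------------------------------------------------------------
# degradations (all linear operators in Fourier space, plus additive noise)


def _wedge_mask(shape_zyx, tilt_min: float, tilt_max: float) -> np.ndarray:
    """Boolean rfft-layout mask of sampled Fourier coefficients.

    A coefficient with in-plane direction (kx, kz) is measured by the tilt
    t (about y) whose central section contains it: kx*sin(t) + kz*cos(t) = 0.
    Wrapping t into [-90, 90) gives a unique stage angle; the coefficient is
    sampled iff that angle lies in [tilt_min, tilt_max].  DC is retained.
    """
    nz, ny, nx = shape_zyx
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.rfftfreq(nx)[None, None, :]
    t = np.degrees(np.arctan2(-kz, kx))
    t = ((t + 90.0) % 180.0) - 90.0
    sampled = (t >= tilt_min) & (t <= tilt_max)
    sampled = np.broadcast_to(sampled, (nz, ny, nx // 2 + 1)).copy()
    sampled[0, :, 0] = True  # kx=kz=0 line (incl. DC) always measured
    return sampled


def apply_missing_wedge(v: Volume, tilt_min: float = -60.0,
                        tilt_max: float = 60.0) -> Volume:
    """Zero Fourier coefficients outside the sampled tilt fan (tilt axis y)."""
    f = sp_fft.rfftn(v.data)
    f *= _wedge_mask(v.data.shape, tilt_min, tilt_max)
    out = sp_fft.irfftn(f, s=v.data.shape)
    return v.with_data(out.astype(np.float32))


def electron_wavelength_nm(voltage_kv: float) -> float:
    """Relativistic electron wavelength in nm."""
    volts = voltage_kv * 1e3
    return 1.226426 / np.sqrt(volts * (1.0 + 0.97845e-6 * volts))


def ctf_1d(k_nm: np.ndarray, model: ImagingModel) -> np.ndarray:
    """Phase-contrast transfer function at spatial frequency k (cycles/nm).

    CTF(k) = -( sqrt(1 - A^2) sin(chi) + A cos(chi) ),
    chi = pi lambda df k^2 - (pi/2) Cs lambda^3 k^4  (underfocus positive),
    so CTF(0) = -A: pure amplitude contrast at DC, negative by the cryo-EM
    sign convention (weak-phase objects appear dark at underfocus).
    """
    lam = electron_wavelength_nm(model.ctf_voltage)
    df_nm = model.ctf_defocus * 1e3
    cs_nm = model.ctf_cs * 1e6
    k2 = np.asarray(k_nm, dtype=float) ** 2
    chi = np.pi * lam * df_nm * k2 - 0.5 * np.pi * cs_nm * lam**3 * k2**2
    a = model.ctf_amplitude_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def apply_ctf(v: Volume, model: ImagingModel) -> Volume:
    """Multiply the volume's Fourier transform by the radial CTF."""
    nz, ny, nx = v.data.shape
    kz = np.fft.fftfreq(nz, d=v.voxel_size)[:, None, None]
    ky = np.fft.fftfreq(ny, d=v.voxel_size)[None, :, None]
    kx = np.fft.rfftfreq(nx, d=v.voxel_size)[None, None, :]
    k = np.sqrt(kz * kz + ky * ky + kx * kx)
    f = sp_fft.rfftn(v.data)
    f *= ctf_1d(k, model)
    out = sp_fft.irfftn(f, s=v.data.shape)
    return v.with_data(out.astype(np.float32))


def add_noise(v: Volume, snr: float, seed: int | np.random.Generator = 0,
              correlation_nm: float = 0.0) -> Volume:
    """Add zero-mean Gaussian noise with variance var(v)/snr.

    With ``correlation_nm > 0`` the noise field is white noise smoothed by
    a Gaussian of that sigma and rescaled to the target variance — the
    band-limited noise characteristic of dose-limited tomographic
    reconstructions (detector MTF, exposure filtering).  ``correlation_nm
    = 0`` gives white noise.  Either way the added field has variance
    var(v)/snr, so the realized SNR matches the requested one.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return v.copy()
    var = float(np.var(v.data))
    if var == 0.0:
        raise ValueError("zero signal variance: cannot set noise level")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=v.data.shape)
    if correlation_nm > 0:
        noise = ndimage.gaussian_filter(noise, correlation_nm / v.voxel_size)
    noise *= np.sqrt(var / snr) / noise.std()
    return v.with_data(v.data + noise.astype(np.float32))


def degrade(v: Volume, model: ImagingModel, with_ctf: bool = True) -> Volume:
    """Wedge (+ optional CTF) filter as applied to templates during matching."""
    out = v
    if with_ctf:
        out = apply_ctf(out, model)
    return apply_missing_wedge(out, model.tilt_min, model.tilt_max)


# ---------------------------------------------------------------------------
# benchmark generation


@dataclass(frozen=True)
class SimulationConfig:
    """One synthetic condensate tomogram.

    Defaults give a 128 nm cube at 1 nm/voxel holding 150 nucleosomes and
    50 free-DNA rods — the same number density as ~500 nucleosomes in a
    ~192 nm cube, i.e. condensate-like packing (~4% nucleosome volume
    fraction).
    """

    box_size: tuple[float, float, float] = (128.0, 128.0, 128.0)
    voxel_size: float = 1.0
    n_nucleosomes: int = 150
    n_dna: int = 50
    imaging: ImagingModel = field(default_factory=ImagingModel)
    seed: int = 0


def generate_benchmark(config: SimulationConfig) -> tuple[Volume, GroundTruth, Volume]:
    """Simulate one tomogram: sample, render, CTF, noise, wedge.

    Returns (tomogram, ground_truth, clean_render).  Deterministic given
    ``config.seed``; the wedge is applied after the noise so the final
    volume — like a real reconstruction — carries no information in the
    missing wedge.
    """
    ss = np.random.SeedSequence(config.seed)
    s_conf, s_noise = ss.spawn(2)
    templates = default_templates(config.voxel_size)
    masks = default_masks(templates)
    gt = sample_particle_configuration(
        config.box_size, config.n_nucleosomes, config.n_dna,
        mask_set=masks, seed=np.random.default_rng(s_conf),
        voxel_size=config.voxel_size)
    clean = render_volume(gt, templates, voxel_size=config.voxel_size)
    m = config.imaging
    vol = apply_ctf(clean, m)
    if np.isfinite(m.snr):
        vol = add_noise(vol, m.snr, np.random.default_rng(s_noise),
                        correlation_nm=m.noise_correlation_nm)
    vol = apply_missing_wedge(vol, m.tilt_min, m.tilt_max)
    return vol, gt, clean


# ---------------------------------------------------------------------------
# planted condensates for the spatial-statistics pipeline


def planted_condensate(stack_lengths=(4, 4, 4, 4, 3, 5, 4, 4, 3, 4),
                       n_singletons: int = 12,
                       sphere_radius: float = 180.0,
                       shell_width: float = 20.0,
                       stack_spacing: float = 5.7,
                       seed: int = 0,
                       label_mode: str = "random"):
    """Synthetic condensate with known contact structure.

    Particles are arranged in face-to-face disc stacks (center spacing just
    above one disc height, so consecutive discs touch sterically) placed in
    the interior of a sphere, plus isolated singleton discs confined to the
    near-surface shell.  By construction the contact graph, valence
    distribution, DBSCAN clusters (= stacks of length >= 3 at the default
    parameters) and cluster-depth profile are all known exactly.

    Returns (particles, sphere_center, sphere_radius, planted) where
    ``planted`` records the expected valence counts and cluster sizes.
    ``label_mode``: "random" = iid 50/50 class labels (expected mixing
    assortativity ~0); "by_motif" = one class per stack (assortative).
    """
    rng = np.random.default_rng(seed)
    center = np.zeros(3)
    positions, kinds_motif = [], []
    bound = []  # bounding radius per motif
    motifs = [int(k) for k in stack_lengths] + [1] * n_singletons
    placed_centers, placed_radii = [], []
    for mi, length in enumerate(motifs):
        span = (length - 1) * stack_spacing
        r_bound = span / 2.0 + 8.0
        if length > 1:
            r_lo, r_hi = 0.0, max(sphere_radius - shell_width - r_bound, 1.0)
        else:
            r_lo = max(sphere_radius - shell_width + 6.0, 0.0)
            r_hi = sphere_radius - 6.0
        for _ in range(20000):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = (rng.uniform(r_lo**3, r_hi**3)) ** (1.0 / 3.0)
            c = center + u * rad
            ok = all(np.linalg.norm(c - pc) > r_bound + pr + 14.0
                     for pc, pr in zip(placed_centers, placed_radii))
            if ok:
                break
        else:
            raise RuntimeError("could not place planted motif; reduce counts")
        placed_centers.append(c)
        placed_radii.append(r_bound)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        offsets = (np.arange(length) - (length - 1) / 2.0) * stack_spacing
        for o in offsets:
            positions.append(c + axis * o)
            kinds_motif.append(mi)
        bound.append(r_bound)
    positions = np.asarray(positions)
    # orientations: disc normal along the stack axis (so stacked faces touch)
    rots = []
    k = 0
    for mi, length in enumerate(motifs):
        axis = positions[k + length - 1] - positions[k] if length > 1 else rng.normal(size=3)
        rots.extend([rotation_from_axis(axis)] * length)
        k += length
    parts = ParticleSet.from_arrays(positions, Rotation.concatenate(rots))
    motif_ids = np.array(kinds_motif)
    if label_mode == "random":
        labels = rng.integers(0, 2, size=len(parts))
    elif label_mode == "by_motif":
        motif_label = rng.integers(0, 2, size=len(motifs))
        labels = motif_label[motif_ids]
    else:
        raise ValueError(f"unknown label_mode {label_mode!r}")
    parts.table["class"] = labels
    parts.table["motif"] = motif_ids

    valence_counts = {}
    for length in motifs:
        if length == 1:
            valence_counts[0] = valence_counts.get(0, 0) + 1
        else:
            valence_counts[1] = valence_counts.get(1, 0) + 2
            if length > 2:
                valence_counts[2] = valence_counts.get(2, 0) + (length - 2)
    planted = {
        "valence_counts": valence_counts,
        "cluster_sizes": [l for l in motifs if l >= 3],
        "n_noise": sum(1 for l in motifs if l < 3),
    }
    return parts, center, sphere_radius, planted
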