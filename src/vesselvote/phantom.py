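"""Synthetic multi-modal vascular phantoms with ground truth.

Generates co-registered volumes of bright tubular structures (straight,
helical or bifurcating centerlines; Gaussian radial intensity profile) as
seen by two or more modalities that share the geometry but differ in point
spread, gain, additive noise and signal dropouts along the vessel.  Each
phantom carries a binary truth mask (voxels within the tube radius of the
centerline), a centerline voxel mask, and the true tangent direction per
in-tube voxel — enough to test every pipeline stage without clinical data.

The Gaussian radial falloff (default sd = radius/2, so the truth radius
sits at two profile sigmas) emulates partial-volume boundaries; the two
default modalities mimic the asymmetry of CT angiography (sharper, less
noisy) versus phase-contrast MR (blurrier, noisier).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import ScalarVolume

__all__ = [
    "Tube",
    "ModalityParams",
    "PhantomSpec",
    "PhantomBundle",
    "generate",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class Tube:
    """One tubular structure: a polyline centerline (mm) with radius and brightness."""

    points: tuple          # ((x, y, z) mm, ...) polyline vertices
    radius: float          # mm, constant along the tube
    intensity: float = 1.0

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("a tube centerline needs at least 2 points")
        if self.radius <= 0:
            raise ValueError("tube radius must be positive")


def straight_tube(start, end, radius, intensity=1.0) -> Tube:
    return Tube(points=(tuple(start), tuple(end)), radius=radius, intensity=intensity)


def helix_tube(center, axis_len, helix_radius, pitch, radius, intensity=1.0,
               n=200) -> Tube:
    """Helical centerline around a z-aligned axis through ``center`` (mm)."""
    cx, cy, cz = center
    t = np.linspace(0.0, axis_len, n)
    ang = 2 * math.pi * t / pitch
    pts = np.stack(
        [cx + helix_radius * np.cos(ang), cy + helix_radius * np.sin(ang),
         cz - axis_len / 2 + t], axis=1,
    )
    return Tube(points=tuple(map(tuple, pts)), radius=radius, intensity=intensity)


def bifurcation_tubes(root, junction, tip_a, tip_b, radius,
                      child_radius=None, intensity=1.0) -> tuple:
    """A parent tube splitting into two children at ``junction`` (all mm)."""
    child_radius = child_radius if child_radius is not None else 0.75 * radius
    return (
        Tube(points=(tuple(root), tuple(junction)), radius=radius, intensity=intensity),
        Tube(points=(tuple(junction), tuple(tip_a)), radius=child_radius, intensity=intensity),
        Tube(points=(tuple(junction), tuple(tip_b)), radius=child_radius, intensity=intensity),
    )


@dataclass(frozen=True)
class ModalityParams:
    """How one modality images the shared geometry."""

    name: str = "mod"
    gain: float = 1.0
    noise_sd: float = 0.05          # additive Gaussian, in intensity units
    psf_sd: float = 0.2             # Gaussian point-spread, mm
    dropouts: tuple = ()            # ((start_frac, end_frac), ...) per tube arclength
    dropout_atten: float = 0.15     # residual signal factor inside dropouts

    def __post_init__(self):
        for a, b in self.dropouts:
            if not (0 <= a < b <= 1):
                raise ValueError(f"bad dropout segment ({a}, {b})")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic multi-modal phantom."""

    shape: tuple = (48, 48, 48)
    spacing: tuple = (1.0, 1.0, 1.0)
    tubes: tuple = ()
    modalities: tuple = (
        ModalityParams(name="cta_like", noise_sd=0.05, psf_sd=0.2),
        ModalityParams(name="pcmr_like", noise_sd=0.12, psf_sd=0.5),
    )
    seed: int = 0
    profile_sd_factor: float = 0.5  # intensity profile sd = factor * radius

    def __post_init__(self):
        mn = min(self.spacing)
        for t in self.tubes:
            if t.radius < mn:
                raise ValueError(
                    f"tube radius {t.radius} mm is below one voxel ({mn} mm)"
                )


@dataclass
class PhantomBundle:
    """Generated phantom: modality volumes plus ground truth."""

    volumes: list                 # [ScalarVolume]
    truth: np.ndarray             # bool, voxels within radius of a centerline
    centerline: np.ndarray        # bool, voxels on the centerline itself
    axis: np.ndarray              # (..., 3) unit tangent inside truth, else 0
    spec: PhantomSpec = None
    clean: list = None            # noise/dropout-free signal per modality


def _sample_tubes(tubes, step):
    """Densely sample all centerlines; return points, tangents, metadata arrays."""
    pts, tans, rad, inten, tube_id, frac = [], [], [], [], [], []
    for ti, tube in enumerate(tubes):
        verts = np.asarray(tube.points, dtype=float)
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        total = seg.sum()
        n = max(2, int(np.ceil(total / step)) + 1)
        # arclength-uniform resampling of the polyline
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.linspace(0.0, total, n)
        p = np.empty((n, 3))
        for ax in range(3):
            p[:, ax] = np.interp(s, cum, verts[:, ax])
        t = np.gradient(p, s, axis=0)
        t /= np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
        pts.append(p)
        tans.append(t)
        rad.append(np.full(n, tube.radius))
        inten.append(np.full(n, tube.intensity))
        tube_id.append(np.full(n, ti))
        frac.append(s / total if total > 0 else np.zeros(n))
    cat = lambda xs: np.concatenate(xs) if xs else np.zeros((0,))
    return (
        np.concatenate(pts) if pts else np.zeros((0, 3)),
        np.concatenate(tans) if tans else np.zeros((0, 3)),
        cat(rad), cat(inten), cat(tube_id), cat(frac),
    )


def generate(spec: PhantomSpec) -> PhantomBundle:
    """Render the phantom described by ``spec``; deterministic under its seed."""
    shape = tuple(spec.shape)
    sp = np.asarray(spec.spacing, dtype=float)
    extent = (np.asarray(shape) - 1) * sp

    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij")
    vox_mm = np.stack([g.ravel() for g in grids], axis=1)

    if not spec.tubes:
        rng = np.random.default_rng(spec.seed)
        vols = []
        clean = [np.zeros(shape) for _ in spec.modalities]
        for mod in spec.modalities:
            noise = rng.normal(0.0, mod.noise_sd, size=shape)
            vols.append(ScalarVolume(data=noise, spacing=tuple(sp)))
        return PhantomBundle(
            volumes=vols,
            truth=np.zeros(shape, dtype=bool),
            centerline=np.zeros(shape, dtype=bool),
            axis=np.zeros(shape + (3,)),
            spec=spec,
            clean=clean,
        )

    step = sp.min() / 4.0
    pts, tans, rad, inten, tube_id, frac = _sample_tubes(spec.tubes, step)
    if np.any(pts < -1e-9) or np.any(pts > extent + 1e-9):
        raise ValueError("tube centerline exits the grid")

    tree = cKDTree(pts)
    maxdist = rad.max() * 3.0 + sp.max()
    dist, idx = tree.query(vox_mm, k=1, distance_upper_bound=maxdist)
    hit = np.isfinite(dist)
    idx = np.where(hit, idx, 0)

    r_near = rad[idx]
    sd = spec.profile_sd_factor * r_near
    signal = np.where(hit, inten[idx] * np.exp(-(dist**2) / (2 * sd**2)), 0.0)
    truth = (hit & (dist <= r_near)).reshape(shape)
    # 0.75 * spacing covers the worst in-plane voxel-centre offset (sqrt(2)/2)
    centerline = (hit & (dist <= 0.75 * sp.max())).reshape(shape)
    axis = np.zeros((len(vox_mm), 3))
    in_t = hit & (dist <= r_near)
    axis[in_t] = tans[idx[in_t]]
    axis = axis.reshape(shape + (3,))

    rng = np.random.default_rng(spec.seed)
    vols, clean = [], []
    for mod in spec.modalities:
        atten = np.ones(len(pts))
        for a, b in mod.dropouts:
            atten[(frac >= a) & (frac <= b)] = mod.dropout_atten
        msig = np.where(hit, signal * atten[idx], 0.0).reshape(shape)
        msig = mod.gain * msig
        if mod.psf_sd > 0:
            msig = ndimage.gaussian_filter(msig, mod.psf_sd / sp, mode="reflect")
        clean.append(msig)
        data = msig + rng.normal(0.0, mod.noise_sd, size=shape)
        vols.append(ScalarVolume(data=data, spacing=tuple(sp)))
    return PhantomBundle(
        volumes=vols, truth=truth, centerline=centerline, axis=axis,
        spec=spec, clean=clean,
    )


def _default_mods(dropouts_a=(), dropouts_b=()):
    return (
        ModalityParams(name="cta_like", noise_sd=0.05, psf_sd=0.2, dropouts=tuple(dropouts_a)),
        ModalityParams(name="pcmr_like", noise_sd=0.12, psf_sd=0.5, dropouts=tuple(dropouts_b)),
    )


def preset(name: str, seed: int = 0) -> PhantomSpec:
    """Named fixture phantoms: straight, helix, bifurcation, dropout-pair."""
    if name == "straight":
        return PhantomSpec(
            tubes=(straight_tube((23.5, 23.5, 2.0), (23.5, 23.5, 45.0), radius=2.0),),
            seed=seed,
        )
    if name == "helix":
        return PhantomSpec(
            tubes=(helix_tube((23.5, 23.5, 23.5), axis_len=40.0, helix_radius=10.0,
                              pitch=40.0, radius=2.0),),
            seed=seed,
        )
    if name == "bifurcation":
        return PhantomSpec(
            tubes=bifurcation_tubes(
                root=(23.5, 23.5, 3.0), junction=(23.5, 23.5, 24.0),
                tip_a=(10.0, 23.5, 44.0), tip_b=(37.0, 23.5, 44.0), radius=2.2,
            ),
            seed=seed,
        )
    if name == "dropout_pair":
        return PhantomSpec(
            tubes=(straight_tube((23.5, 23.5, 2.0), (23.5, 23.5, 45.0), radius=2.0),),
            modalities=_default_mods(
                dropouts_a=((0.15, 0.35),), dropouts_b=((0.55, 0.75),)
            ),
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("straight", "helix", "bifurcation", "dropout_pair")
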