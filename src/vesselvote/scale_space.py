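"""Multi-scale Hessian analysis: vesselness, optimal-scale image, token selection.

For a volume ``I`` and a log-spaced ladder of Gaussian scales ``sigma`` (mm),
this module computes gamma-normalised second derivatives, the eigensystem of
the Hessian ordered by absolute eigenvalue ``|k3| >= |k2| >= |k1|``, a smooth
tube-likeness (vesselness) response ``nu(x, sigma)`` in [0, 1], and the
optimal-scale image

    M(x) = argmax_sigma nu(x, sigma),

with ties broken toward the smallest scale.  Voxels whose Hessian satisfies
the bright-tube sign condition ``k2 < 0 and k3 < 0`` at at least one scale
are admitted as *tokens* and carry the eigensystem at their optimal scale
into the tensor-voting stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ScalarVolume

__all__ = [
    "ScaleLadder",
    "HessianEigen",
    "ScaleSpace",
    "TokenSet",
    "VesselnessParams",
    "make_scale_ladder",
    "hessian_at_scale",
    "eigendecompose",
    "eigendecompose_field",
    "vesselness",
    "build_scale_space",
    "select_tokens",
]


@dataclass(frozen=True)
class ScaleLadder:
    """Strictly increasing, log-equispaced list of analysis scales in mm."""

    sigmas: tuple

    def __post_init__(self):
        s = np.asarray(self.sigmas, dtype=float)
        if s.size < 2:
            raise ValueError("a scale ladder needs at least 2 scales")
        if np.any(np.diff(s) <= 0):
            raise ValueError("scales must be strictly increasing")
        logs = np.log(s)
        step = np.diff(logs)
        if not np.allclose(step, step[0], rtol=1e-6, atol=1e-9):
            raise ValueError("scales must be equally spaced in log-space")

    def __len__(self):
        return len(self.sigmas)

    def __iter__(self):
        return iter(self.sigmas)

    def __getitem__(self, i):
        return self.sigmas[i]

    @property
    def log_step(self) -> float:
        return float(np.log(self.sigmas[1]) - np.log(self.sigmas[0]))


def make_scale_ladder(sigma_min: float, sigma_max: float, n: int) -> ScaleLadder:
    """Log-uniform ladder of ``n`` scales from ``sigma_min`` to ``sigma_max`` (mm).

    Endpoints are exact; the interior points interpolate in log-space,
    ``sigmas[i] = exp(log s_min + i (log s_max - log s_min)/(n-1))``.
    """
    if sigma_min <= 0 or sigma_max <= sigma_min:
        raise ValueError(
            f"need 0 < sigma_min < sigma_max, got ({sigma_min}, {sigma_max})"
        )
    if n < 2:
        raise ValueError(f"need n >= 2 scales, got {n}")
    sig = np.exp(np.linspace(np.log(sigma_min), np.log(sigma_max), int(n)))
    sig[0], sig[-1] = sigma_min, sigma_max  # endpoints exact
    return ScaleLadder(sigmas=tuple(float(x) for x in sig))


def hessian_at_scale(volume: ScalarVolume, sigma: float, gamma: float = 1.0) -> np.ndarray:
    """Per-voxel 3x3 Hessian of Gaussian-smoothed intensity at physical scale sigma.

    Derivatives are taken in mm (spacing-aware, per-axis voxel sigma =
    sigma/spacing) with reflect boundary handling, and multiplied by
    ``sigma**(2*gamma)`` so responses are comparable across scales.
    Returns an array of shape ``volume.shape + (3, 3)``, exactly symmetric.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    sp = np.asarray(volume.spacing)
    if sigma < sp.max() / 2:
        warnings.warn(
            f"sigma={sigma} mm is below half the coarsest voxel size "
            f"({sp.max()} mm); derivatives will be under-resolved",
            stacklevel=2,
        )
    sigma_vox = sigma / sp
    kernels = [_gauss_kernels(sv) for sv in sigma_vox]
    norm = sigma ** (2.0 * gamma)
    H = np.empty(volume.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        for j in range(i, 3):
            d = volume.data
            for ax in range(3):
                order = (ax == i) + (ax == j)
                d = ndimage.correlate1d(d, kernels[ax][order], axis=ax, mode="reflect")
            d = d * (norm / (sp[i] * sp[j]))
            H[..., i, j] = d
            if i != j:
                H[..., j, i] = d
    return H


def _gauss_kernels(sigma_vox: float, truncate: float = 4.0):
    """Sampled Gaussian and its first two derivative kernels (voxel units).

    Discrete moments are corrected so a constant input yields exactly zero
    first and second derivatives and quadratics differentiate exactly
    (the raw sampled kernels violate these at the truncation-tail level,
    ~1e-4, which would break intensity-offset invariance).
    """
    r = max(1, int(truncate * sigma_vox + 0.5))
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2 * sigma_vox**2))
    g /= g.sum()
    g1 = -x / sigma_vox**2 * g
    g1 /= np.sum(-x * g1)                       # unit response to I = x
    g2 = (x**2 - sigma_vox**2) / sigma_vox**4 * g
    g2 -= g * g2.sum()                          # zero response to constants
    g2 /= np.sum(0.5 * x**2 * g2)               # unit response to I = x^2/2... times 2
    # correlate1d correlates (no kernel flip); flip so odd kernel acts as
    # a derivative with the conventional sign
    return g, g1[::-1], g2


@dataclass(frozen=True)
class HessianEigen:
    """Eigensystem of a 3x3 symmetric Hessian, ordered |k3| >= |k2| >= |k1|.

    ``kappas[i]`` pairs with the row eigenvector ``vecs[i]``; rows are
    orthonormal with a deterministic sign (largest-magnitude component
    positive).
    """

    kappas: np.ndarray  # (3,) ordered by ascending |.| -> (k1, k2, k3)
    vecs: np.ndarray    # (3, 3), vecs[i] is the eigenvector of kappas[i]


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvectors so the largest-|component| entry is positive."""
    idx = np.argmax(np.abs(vecs), axis=-1)
    lead = np.take_along_axis(vecs, idx[..., None], axis=-1)[..., 0]
    return np.where((lead < 0)[..., None], -vecs, vecs)


def eigendecompose_field(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised |.|-ordered eigendecomposition of symmetric 3x3 fields.

    Returns ``(kappas, vecs)`` with shapes ``(..., 3)`` and ``(..., 3, 3)``;
    ``vecs[..., i, :]`` is the unit eigenvector paired with ``kappas[..., i]``.
    """
    w, v = np.linalg.eigh(H)                 # ascending by value, column vectors
    order = np.argsort(np.abs(w), axis=-1, kind="stable")
    kappas = np.take_along_axis(w, order, axis=-1)
    vecs = np.take_along_axis(
        np.swapaxes(v, -1, -2), order[..., None], axis=-2
    )  # rows now match kappas
    return kappas, _fix_signs(vecs)


def eigendecompose(H: np.ndarray, tol: float = 1e-8) -> HessianEigen:
    """Eigendecompose one 3x3 symmetric matrix with |.|-ordering.

    Raises ValueError if ``H`` is non-symmetric beyond ``tol`` (relative to
    its magnitude).
    """
    H = np.asarray(H, dtype=np.float64)
    if H.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {H.shape}")
    scale = max(1.0, np.abs(H).max())
    if np.abs(H - H.T).max() > tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    kappas, vecs = eigendecompose_field(0.5 * (H + H.T))
    if np.all(H == 0):
        vecs = np.eye(3)
    return HessianEigen(kappas=kappas, vecs=vecs)


@dataclass
class VesselnessParams:
    """Parameters of the smooth tube-likeness response.

    variant
        ``"manniesing"`` (default): Frangi's three geometric factors times a
        smoothness factor ``exp(-2 c_s^2 / (|k2| k3^2))`` that suppresses
        weak responses continuously; ``"frangi"``: the plain three-factor
        form.
    alpha, beta
        Sensitivities of the plate/line ratio ``|k2|/|k3|`` and the blob
        ratio ``|k1|/sqrt(|k2 k3|)``.  Defaults 0.5 each, the values
        recommended in the vesselness literature.
    c
        Structureness sensitivity; ``None`` (default) sets it to half the
        maximum Frobenius norm of the (normalised) Hessian over the whole
        scale range of the volume at hand.
    smooth_rel
        Sets the smoothness constant ``c_s = smooth_rel * max|k3|^(3/2)``
        (manniesing variant only).  Small values make the factor ~1 except
        near-zero eigenvalues.
    """

    variant: str = "manniesing"
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None
    smooth_rel: float = 1e-3

    def __post_init__(self):
        if self.variant not in ("manniesing", "frangi"):
            raise ValueError(f"unknown vesselness variant {self.variant!r}")


def vesselness(kappas: np.ndarray, params: VesselnessParams | None = None,
               c: float | None = None, smooth_c: float | None = None) -> np.ndarray:
    """Tube-likeness in [0, 1] from |.|-ordered Hessian eigenvalues.

    ``kappas`` has shape ``(..., 3)`` ordered ``(k1, k2, k3)`` by absolute
    value.  The response is 0 wherever ``k2 >= 0`` or ``k3 >= 0``
    (bright-vessel convention), and smooth in the eigenvalues elsewhere.
    ``c``/``smooth_c`` override the corresponding derived constants (used by
    :func:`build_scale_space` to keep them global across scales).
    """
    params = params or VesselnessParams()
    kappas = np.asarray(kappas, dtype=np.float64)
    k1, k2, k3 = kappas[..., 0], kappas[..., 1], kappas[..., 2]
    cond = (k2 < 0) & (k3 < 0)
    S2 = k1 * k1 + k2 * k2 + k3 * k3
    if c is None:
        c = params.c
    if c is None:
        smax = np.sqrt(S2.max()) if S2.size else 0.0
        c = 0.5 * smax if smax > 0 else 1.0
    a2, b2 = k2 * k2, k3 * k3
    with np.errstate(divide="ignore", invalid="ignore"):
        RA2 = np.where(b2 > 0, a2 / b2, 0.0)
        RB2 = np.where(a2 * b2 > 0, (k1 * k1) / np.sqrt(a2 * b2), 0.0)
        nu = (
            (1.0 - np.exp(-RA2 / (2 * params.alpha**2)))
            * np.exp(-RB2 / (2 * params.beta**2))
            * (1.0 - np.exp(-S2 / (2 * c * c)))
        )
        if params.variant == "manniesing":
            if smooth_c is None:
                kmax = np.abs(k3).max() if k3.size else 0.0
                smooth_c = params.smooth_rel * kmax ** 1.5 if kmax > 0 else 0.0
            if smooth_c > 0:
                denom = np.abs(k2) * b2
                nu = nu * np.where(denom > 0, np.exp(-2 * smooth_c**2 / denom), 0.0)
    return np.where(cond, nu, 0.0)


@dataclass
class ScaleSpace:
    """Per-scale vesselness, the optimal-scale image and token condition.

    nu
        ``(n_scales,) + shape`` vesselness grids, values in [0, 1].
    sigma_idx
        per-voxel index into the ladder of the scale maximising nu
        (first/smallest scale on ties).
    M
        optimal-scale image in mm, ``M = sigmas[sigma_idx]``.
    nu_max
        ``nu[sigma_idx]`` per voxel.
    condition_any
        True where ``k2 < 0 and k3 < 0`` held at at least one scale.
    """

    ladder: ScaleLadder
    nu: np.ndarray
    sigma_idx: np.ndarray
    M: np.ndarray
    nu_max: np.ndarray
    condition_any: np.ndarray
    params: VesselnessParams = field(default_factory=VesselnessParams)
    gamma: float = 1.0
    c: float = 1.0
    smooth_c: float = 0.0

    @property
    def shape(self):
        return self.M.shape


def build_scale_space(
    volume: ScalarVolume,
    ladder: ScaleLadder,
    params: VesselnessParams | None = None,
    gamma: float = 1.0,
) -> ScaleSpace:
    """Compute nu(x, sigma) over the ladder and the optimal-scale image M(x).

    Two passes over the ladder: the first collects the global maximum
    Hessian Frobenius norm (and |k3|) so the structureness and smoothness
    constants of the vesselness are shared across scales; the second
    evaluates nu per scale.  The argmax tie-break keeps the smallest scale.
    """
    params = params or VesselnessParams()
    n = len(ladder)
    shape = volume.shape
    kappas_per_scale = np.empty((n,) + shape + (3,), dtype=np.float32)
    for i, sig in enumerate(ladder):
        H = hessian_at_scale(volume, sig, gamma=gamma)
        w = np.linalg.eigvalsh(H)
        order = np.argsort(np.abs(w), axis=-1, kind="stable")
        kappas_per_scale[i] = np.take_along_axis(w, order, axis=-1)

    kf = kappas_per_scale.astype(np.float64)
    S2max = float((kf**2).sum(axis=-1).max())
    c = params.c if params.c is not None else (0.5 * np.sqrt(S2max) if S2max > 0 else 1.0)
    kmax = float(np.abs(kf[..., 2]).max())
    smooth_c = params.smooth_rel * kmax**1.5 if (params.variant == "manniesing" and kmax > 0) else 0.0

    # curvatures below ~1e-11 of the data magnitude are floating-point noise
    # (gamma-normalised |kappa| is bounded by the intensity range); without
    # this guard a constant volume "detects" structure in rounding error
    mag = max(np.abs(volume.data).max(), np.ptp(volume.data))
    eps_k = 1e-11 * mag

    nu = np.empty((n,) + shape, dtype=np.float64)
    cond_any = np.zeros(shape, dtype=bool)
    for i in range(n):
        k = kf[i]
        cond = (k[..., 1] < -eps_k) & (k[..., 2] < -eps_k)
        nu[i] = np.where(cond, vesselness(k, params, c=c, smooth_c=smooth_c), 0.0)
        cond_any |= cond

    sigma_idx = np.argmax(nu, axis=0)  # first max -> smallest scale on ties
    nu_max = np.take_along_axis(nu, sigma_idx[None], axis=0)[0]
    M = np.asarray(ladder.sigmas)[sigma_idx]
    return ScaleSpace(
        ladder=ladder,
        nu=nu,
        sigma_idx=sigma_idx,
        M=M,
        nu_max=nu_max,
        condition_any=cond_any,
        params=params,
        gamma=gamma,
        c=c,
        smooth_c=smooth_c,
    )


@dataclass
class TokenSet:
    """Voxels admitted to voting, with their optimal-scale eigensystems.

    Arrays are aligned: row ``i`` describes the token at voxel ``sites[i]``
    with Hessian eigenvalues ``kappas[i]`` (|.|-ordered) and row
    eigenvectors ``vecs[i]`` computed at scale ``M[i] = sigmas[sigma_idx[i]]``.
    """

    sites: np.ndarray       # (N, 3) int voxel indices
    kappas: np.ndarray      # (N, 3)
    vecs: np.ndarray        # (N, 3, 3) rows
    nu: np.ndarray          # (N,)
    M: np.ndarray           # (N,) mm
    sigma_idx: np.ndarray   # (N,) int
    intensity: np.ndarray   # (N,)
    shape: tuple
    spacing: tuple

    def __len__(self):
        return len(self.sites)

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.sites.T)] = True
        return m


def select_tokens(
    scale_space: ScaleSpace,
    volume: ScalarVolume,
    mask: np.ndarray | None = None,
    min_nu_rel: float = 0.0,
) -> TokenSet:
    """Admit voxels with ``k2 < 0 and k3 < 0`` at >= 1 scale as tokens.

    Each admitted voxel carries the Hessian eigensystem recomputed at its
    optimal scale M(x).  ``mask`` (e.g. an intracranial mask) restricts
    candidates before selection.  ``min_nu_rel`` optionally drops tokens
    whose peak vesselness is below that fraction of the volume maximum —
    voxels with near-zero eigenvalues carry essentially no structural
    evidence and behave as noise.
    """
    admit = scale_space.condition_any.copy()
    if mask is not None:
        admit &= np.asarray(mask, dtype=bool)
    if min_nu_rel > 0:
        peak = scale_space.nu_max.max()
        if peak > 0:
            admit &= scale_space.nu_max >= min_nu_rel * peak
    sites = np.argwhere(admit)
    n = len(sites)
    kappas = np.zeros((n, 3))
    vecs = np.tile(np.eye(3), (n, 1, 1))
    idx_at = scale_space.sigma_idx[tuple(sites.T)]
    for si in np.unique(idx_at):
        sel = idx_at == si
        pts = sites[sel]
        H = hessian_at_scale(volume, scale_space.ladder[int(si)], gamma=scale_space.gamma)
        k, v = eigendecompose_field(H[tuple(pts.T)])
        kappas[sel] = k
        vecs[sel] = v
    return TokenSet(
        sites=sites,
        kappas=kappas,
        vecs=vecs,
        nu=scale_space.nu_max[tuple(sites.T)],
        M=scale_space.M[tuple(sites.T)],
        sigma_idx=idx_at,
        intensity=volume.data[tuple(sites.T)],
        shape=volume.shape,
        spacing=volume.spacing,
    )
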