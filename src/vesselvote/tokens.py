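"""Token initialisation: encode admitted voxels as symmetric PSD tensors.

A token tensor ``T`` decomposes (spectrum theorem) into stick, plate and
ball components

    T = (l1 - l2) e1 e1^T  +  (l2 - l3) (e1 e1^T + e2 e2^T)  +  l3 I,

with eigenvalues ``l1 >= l2 >= l3 >= 0``.  Three families of initialisation
are provided, six configurations in total:

====================  =========================================  ==================
family                eigenvalues                                eigenvectors
====================  =========================================  ==================
ball (no orientation) l1 = l2 = l3 = K | I(p) | nu(p)            canonical basis
Hessian stick         [|k1|^-1, |k2|^-1, |k3|^-1]  or            (v1, v2, v3)
                      [nu(p), 0, 0]
structure tensor      l1 - l2 = ||grad I||^2, l3 = 0             e1 ~ grad I
====================  =========================================  ==================

The Hessian stick orientation ``v1`` (eigenvector of the smallest-|.|
eigenvalue) points along the vessel; the structure-tensor stick points
along the local intensity gradient (the surface normal on tube walls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scale_space import ScaleSpace, TokenSet, eigendecompose_field
from .volume import ScalarVolume

__all__ = [
    "TokenField",
    "BALL_MODES",
    "HESSIAN_MODES",
    "stick_plate_ball",
    "decompose_field",
    "init_ball",
    "init_stick_hessian",
    "init_structure_tensor",
    "init_tokens",
]

BALL_MODES = ("constant", "intensity", "vesselness")
HESSIAN_MODES = ("inverse_kappa", "vesselness")

# config names for the six configurations
STRATEGIES = (
    "ball_k",
    "ball_intensity",
    "ball_vesselness",
    "hessian_kappa",
    "hessian_vesselness",
    "structure_tensor",
)


@dataclass
class TokenField:
    """A set of initialised token tensors on a voxel grid."""

    sites: np.ndarray    # (N, 3) int
    tensors: np.ndarray  # (N, 3, 3) symmetric PSD
    M: np.ndarray        # (N,) optimal scale in mm (sets each voting window)
    shape: tuple
    spacing: tuple

    def __len__(self):
        return len(self.sites)

    def __post_init__(self):
        assert self.tensors.shape == (len(self.sites), 3, 3)


def stick_plate_ball(T: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split one symmetric PSD 3x3 tensor into stick, plate and ball parts.

    Returns ``(S, P, B)`` with ``S + P + B == T`` (to rounding).
    """
    S, P, B = decompose_field(np.asarray(T, dtype=np.float64)[None])
    return S[0], P[0], B[0]


def decompose_field(T: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised stick/plate/ball decomposition of ``(..., 3, 3)`` tensors."""
    w, v = np.linalg.eigh(T)  # ascending: w[...,0]=l3 <= w[...,1]=l2 <= w[...,2]=l1
    l3, l2, l1 = w[..., 0], w[..., 1], w[..., 2]
    e1 = v[..., :, 2]
    e2 = v[..., :, 1]
    o1 = e1[..., :, None] * e1[..., None, :]
    o2 = e2[..., :, None] * e2[..., None, :]
    eye = np.eye(3)
    S = (l1 - l2)[..., None, None] * o1
    P = (l2 - l3)[..., None, None] * (o1 + o2)
    B = l3[..., None, None] * eye
    return S, P, B


def _saliency_ball(tokens: TokenSet, mode: str, K: float, volume: ScalarVolume | None):
    if mode == "constant":
        return np.full(len(tokens), float(K))
    if mode == "vesselness":
        return tokens.nu.copy()
    if mode == "intensity":
        s = tokens.intensity.copy()
        if np.any(s < 0):
            import warnings

            warnings.warn("negative intensities clamped to 0 for ball saliency")
            s = np.clip(s, 0.0, None)
        # rescale to [0,1] so cross-modality fusion magnitudes are comparable
        hi = np.percentile(s, 99.9) if len(s) else 0.0
        if hi > 0:
            s = np.clip(s / hi, 0.0, 1.0)
        return s
    raise ValueError(f"unknown ball saliency mode {mode!r}; choose from {BALL_MODES}")


def init_ball(
    tokens: TokenSet,
    saliency_mode: str = "vesselness",
    volume: ScalarVolume | None = None,
    K: float = 1.0,
) -> TokenField:
    """Isotropic (no preferred orientation) initialisation.

    Every token gets ``T = s * Identity`` with saliency ``s`` a constant
    ``K``, the token's (rescaled, clamped-nonnegative) image intensity, or
    its peak vesselness ``nu(p)``.
    """
    s = _saliency_ball(tokens, saliency_mode, K, volume)
    tensors = s[:, None, None] * np.eye(3)[None]
    return TokenField(
        sites=tokens.sites.copy(),
        tensors=tensors,
        M=tokens.M.copy(),
        shape=tokens.shape,
        spacing=tokens.spacing,
    )


def init_stick_hessian(
    tokens: TokenSet,
    mode: str = "vesselness",
    kappa_cap_factor: float = 1e3,
) -> TokenField:
    """Hessian-oriented initialisation: stick along the vessel direction v1.

    mode ``"vesselness"``: rank-1 stick ``nu(p) * v1 v1^T`` (eigenvalues
    ``[nu(p), 0, 0]``).  mode ``"inverse_kappa"``: eigenvalues
    ``[|k1|^-1, |k2|^-1, |k3|^-1]`` paired with ``(v1, v2, v3)``; the
    ordering ``l1 >= l2 >= l3`` follows automatically from
    ``|k3| >= |k2| >= |k1|``.  Zero kappas would make ``|k|^-1`` blow up,
    so each eigenvalue is capped at ``kappa_cap_factor`` times the median
    nonzero ``|k|^-1`` over the token set.
    """
    if mode not in HESSIAN_MODES:
        raise ValueError(f"unknown Hessian mode {mode!r}; choose from {HESSIAN_MODES}")
    n = len(tokens)
    if mode == "vesselness":
        e1 = tokens.vecs[:, 0, :]
        tensors = tokens.nu[:, None, None] * (e1[:, :, None] * e1[:, None, :])
    else:
        absk = np.abs(tokens.kappas)
        with np.errstate(divide="ignore"):
            lam = np.where(absk > 0, 1.0 / absk, np.inf)
        finite = lam[np.isfinite(lam)]
        cap = kappa_cap_factor * np.median(finite) if finite.size else 1.0
        lam = np.minimum(lam, cap)
        # lam[:, i] pairs with eigenvector v_{i+1}; ordering is asserted, not re-sorted
        assert np.all(np.diff(lam, axis=1) <= 1e-9 * np.maximum(1.0, lam[:, :1])), (
            "inverse-kappa eigenvalues lost their ordering"
        )
        v = tokens.vecs  # rows v1, v2, v3
        tensors = np.einsum("ni,nij,nik->njk", lam, v, v)
    return TokenField(
        sites=tokens.sites.copy(),
        tensors=tensors,
        M=tokens.M.copy(),
        shape=tokens.shape,
        spacing=tokens.spacing,
    )


def init_structure_tensor(
    volume: ScalarVolume,
    tokens: TokenSet,
    scale_space: ScaleSpace | None = None,
) -> TokenField:
    """Structure-tensor initialisation: stick along the intensity gradient.

    The gradient is computed with a Gaussian kernel at each token's optimal
    scale M(p) (sigma-normalised, i.e. multiplied by M(p), matching the
    gamma=1 Hessian convention), in mm.  ``T = grad I grad I^T`` gives a
    rank-1 stick with saliency ``l1 - l2 = ||grad I||^2``; zero gradient
    gives the zero tensor.
    """
    sp = np.asarray(volume.spacing)
    n = len(tokens)
    grads = np.zeros((n, 3))
    for si in np.unique(tokens.sigma_idx):
        sel = tokens.sigma_idx == si
        pts = tokens.sites[sel]
        sig = float(tokens.M[sel][0])
        for ax in range(3):
            order = [0, 0, 0]
            order[ax] = 1
            d = ndimage.gaussian_filter(volume.data, sig / sp, order=order, mode="reflect")
            grads[sel, ax] = d[tuple(pts.T)] * sig / sp[ax]
    tensors = grads[:, :, None] * grads[:, None, :]
    return TokenField(
        sites=tokens.sites.copy(),
        tensors=tensors,
        M=tokens.M.copy(),
        shape=tokens.shape,
        spacing=tokens.spacing,
    )


def init_tokens(
    strategy: str,
    tokens: TokenSet,
    volume: ScalarVolume,
    scale_space: ScaleSpace | None = None,
    K: float = 1.0,
) -> TokenField:
    """Dispatch one of the six named initialisation configurations."""
    if strategy == "ball_k":
        return init_ball(tokens, "constant", volume, K=K)
    if strategy == "ball_intensity":
        return init_ball(tokens, "intensity", volume)
    if strategy == "ball_vesselness":
        return init_ball(tokens, "vesselness", volume)
    if strategy == "hessian_kappa":
        return init_stick_hessian(tokens, "inverse_kappa")
    if strategy == "hessian_vesselness":
        return init_stick_hessian(tokens, "vesselness")
    if strategy == "structure_tensor":
        return init_structure_tensor(volume, tokens, scale_space)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
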