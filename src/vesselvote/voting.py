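"""Tensor voting: stick/plate/ball vote kernels and field accumulation.

Each token ``q`` propagates its structural evidence to the voxels ``p`` of a
scale-adaptive neighbourhood, and votes are summed per voxel:

    TV(p) = sum_q [ SV(v, S_q) + PV(v, P_q) + BV(v, B_q) ],   v = p - q,

with the neighbourhood reach set by the voter's optimal scale,
``N = 2 M(q)`` mm.  The stick vote follows the classic arc model: voter and
receiver are joined by the circular arc tangent to the stick direction at
the voter; the vote is the arc-rotated stick direction, attenuated by

    exp(-(s^2 + c * k^2) / sigma_d^2)

where ``s`` is the arc length, ``k`` its curvature, and ``sigma_d`` the
decay width (a fixed fraction of the window).  Votes vanish beyond an
angular cutoff (default 45 deg) between the displacement and the stick
direction.  Plate and ball votes are orientation averages of stick votes
over the plate's circle of line orientations (exact trigonometric
quadrature) and over a deterministic Fibonacci set of line orientations on
the hemisphere; the self-vote (v = 0) returns the component unchanged.

Two accumulation paths are provided: :func:`cast_all_votes` (production,
grouped by scale with vectorised window stencils and token batching) and
:func:`cast_all_votes_bruteforce` (a naive token-by-voxel double loop used
as a correctness oracle on small volumes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .tokens import TokenField, stick_plate_ball

__all__ = [
    "VoteParams",
    "voting_window",
    "window_offsets",
    "stick_vote",
    "plate_vote",
    "ball_vote",
    "cast_all_votes",
    "cast_all_votes_bruteforce",
]

_EPS = 1e-12
# component saliencies below this fraction of the token's trace are treated
# as exact zeros (eigh noise on rank-deficient tensors), token-locally so
# vote accumulation stays linear over token sets
_SAL_TOL = 1e-12


def _clip_saliency(sal: np.ndarray, trace: np.ndarray) -> np.ndarray:
    return np.where(sal > _SAL_TOL * np.maximum(trace, 0.0), sal, 0.0)


@dataclass
class VoteParams:
    """Tunable constants of the vote kernels.

    angular_cutoff_deg
        Maximum angle (degrees) between the displacement and the stick
        direction for a nonzero stick vote; in (0, 90].
    curvature_weight
        Weight ``c`` of the squared arc curvature in the decay; ``None``
        derives it from the decay width as ``c = -16 log(0.1) (sigma_d - 1)
        / pi^2`` (clamped at 0), the conventional coupling.
    decay_fraction
        ``sigma_d = decay_fraction * N`` with ``N = 2 M(q)`` the window
        reach; the default 1/3 makes votes negligible at the window edge.
    n_ball_dirs, n_plate_angles
        Sizes of the deterministic orientation sets for the ball and plate
        integrals.
    """

    angular_cutoff_deg: float = 45.0
    curvature_weight: float | None = None
    decay_fraction: float = 1.0 / 3.0
    n_ball_dirs: int = 1024
    n_plate_angles: int = 32

    def __post_init__(self):
        if not (0 < self.angular_cutoff_deg <= 90):
            raise ValueError("angular_cutoff_deg must be in (0, 90]")
        if self.decay_fraction <= 0:
            raise ValueError("decay_fraction must be positive")

    @property
    def angular_cutoff(self) -> float:
        return math.radians(self.angular_cutoff_deg)

    def sigma_d(self, reach_mm: float) -> float:
        return self.decay_fraction * reach_mm

    def curvature_c(self, sigma_d: float) -> float:
        if self.curvature_weight is not None:
            return self.curvature_weight
        return max(0.0, -16.0 * math.log(0.1) * (sigma_d - 1.0)) / math.pi**2


def voting_window(M_p: float, spacing) -> np.ndarray:
    """Per-axis half-width in voxels of the voting window of a token.

    The physical half-width is ``N = 2 M(p)`` mm, converted per axis with a
    ceiling, clamped to at least 1 voxel.
    """
    sp = np.asarray(spacing, dtype=float)
    return np.maximum(1, np.ceil(2.0 * float(M_p) / sp).astype(int))


def window_offsets(M_p: float, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Integer offsets and mm displacements of the voting neighbourhood.

    Offsets lie in the box of :func:`voting_window` half-widths and within
    the spherical reach ``||v||_mm <= 2 M(p)``; the 3x3x3 core is always
    kept so the minimum 1-voxel window is honoured on coarse grids.
    """
    sp = np.asarray(spacing, dtype=float)
    hw = voting_window(M_p, sp)
    ax = [np.arange(-h, h + 1) for h in hw]
    off = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    v = off * sp
    reach = 2.0 * float(M_p)
    keep = (np.linalg.norm(v, axis=1) <= reach + 1e-9) | (np.abs(off).max(axis=1) <= 1)
    return off[keep], v[keep]


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, roughly uniform line orientations (unit, z >= 0)."""
    i = np.arange(n)
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane with the given normal."""
    n = np.asarray(normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    a = np.zeros(3)
    a[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    w = np.cross(n, u)
    return u, w


def _stick_votes(V: np.ndarray, D: np.ndarray, sigma_d: float, c: float,
                 cutoff: float) -> np.ndarray:
    """Unit-saliency stick votes at displacements ``V`` (mm).

    ``V`` is ``(K, 3)``; ``D`` is one direction ``(3,)`` (returns
    ``(K, 3, 3)``) or a batch ``(T, 3)`` (returns ``(T, K, 3, 3)``).  The
    zero displacement returns the self-vote ``d d^T``; displacements at
    angle > cutoff from the stick line return zero.
    """
    V = np.atleast_2d(np.asarray(V, dtype=np.float64))
    D = np.asarray(D, dtype=np.float64)
    single = D.ndim == 1
    D2 = np.atleast_2d(D)
    D2 = D2 / np.linalg.norm(D2, axis=1, keepdims=True)

    l = np.linalg.norm(V, axis=1)                      # (K,)
    zero = l < _EPS
    lsafe = np.where(zero, 1.0, l)
    vhat = V / lsafe[:, None]

    ct = D2 @ vhat.T                                   # (T, K)
    sign = np.where(ct >= 0, 1.0, -1.0)
    cta = np.clip(np.abs(ct), 0.0, 1.0)
    theta = np.arccos(cta)
    st = np.sin(theta)
    straight = st < 1e-9
    stsafe = np.where(straight, 1.0, st)

    s_arc = np.where(straight, l[None, :], theta * l[None, :] / stsafe)
    kappa = 2.0 * st / lsafe[None, :]
    decay = np.exp(-(s_arc**2 + c * kappa**2) / sigma_d**2)

    d_eff = sign[:, :, None] * D2[:, None, :]          # (T, K, 3)
    u = (vhat[None, :, :] - cta[:, :, None] * d_eff) / stsafe[:, :, None]
    t = np.where(
        straight[:, :, None],
        d_eff,
        np.cos(2 * theta)[:, :, None] * d_eff + np.sin(2 * theta)[:, :, None] * u,
    )
    w = np.where(theta <= cutoff + 1e-12, decay, 0.0)
    w = np.where(zero[None, :], 1.0, w)                # self-vote: full weight,
    t = np.where(zero[None, :, None], D2[:, None, :], t)  # direction = stick
    out = w[:, :, None, None] * (t[:, :, :, None] * t[:, :, None, :])
    return out[0] if single else out


def _plate_kernel(V: np.ndarray, normal: np.ndarray, sigma_d: float, c: float,
                  cutoff: float, n_angles: int) -> np.ndarray:
    """Unit-saliency plate votes: average of sticks over the plate's circle.

    The plate with normal ``e3`` contains the line orientations
    ``d(phi) = cos(phi) u + sin(phi) w``; ``PV = 2 * mean_phi SV(v, d(phi))``
    so that the self-vote reproduces ``u u^T + w w^T`` exactly (equispaced
    line orientations over [0, pi) integrate quadratics exactly).
    """
    u, w = _plane_basis(normal)
    phis = (np.arange(n_angles) + 0.5) * math.pi / n_angles
    dirs = np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * w
    return 2.0 * _stick_votes(V, dirs, sigma_d, c, cutoff).mean(axis=0)


def _ball_kernel(V: np.ndarray, sigma_d: float, c: float, cutoff: float,
                 n_dirs: int) -> np.ndarray:
    """Unit-saliency ball votes: average of sticks over the hemisphere.

    ``BV = 3 * mean_d SV(v, d)`` over a deterministic Fibonacci set of line
    orientations; the zero displacement is pinned to the identity so the
    self-vote returns the ball component exactly.
    """
    V = np.atleast_2d(V)
    dirs = _fibonacci_hemisphere(n_dirs)
    acc = np.zeros((len(V), 3, 3))
    for lo in range(0, n_dirs, 64):  # chunked to bound memory
        acc += _stick_votes(V, dirs[lo:lo + 64], sigma_d, c, cutoff).sum(axis=0)
    acc *= 3.0 / n_dirs
    acc[np.linalg.norm(V, axis=1) < _EPS] = np.eye(3)
    return acc


def stick_vote(v, S_q: np.ndarray, sigma_d: float,
               params: VoteParams | None = None) -> np.ndarray:
    """Vote cast by a stick component ``S_q`` at displacement ``v`` (mm)."""
    params = params or VoteParams()
    c = params.curvature_c(sigma_d)
    w, vec = np.linalg.eigh(np.asarray(S_q, dtype=np.float64))
    sal, d = w[2], vec[:, 2]
    if sal <= 0:
        return np.zeros((3, 3))
    return sal * _stick_votes(np.asarray(v, float)[None], d, sigma_d, c,
                              params.angular_cutoff)[0]


def plate_vote(v, P_q: np.ndarray, sigma_d: float,
               params: VoteParams | None = None) -> np.ndarray:
    """Vote cast by a plate component ``P_q`` at displacement ``v`` (mm)."""
    params = params or VoteParams()
    c = params.curvature_c(sigma_d)
    w, vec = np.linalg.eigh(np.asarray(P_q, dtype=np.float64))
    sal, normal = w[2], vec[:, 0]
    if sal <= 0:
        return np.zeros((3, 3))
    return sal * _plate_kernel(np.asarray(v, float)[None], normal, sigma_d, c,
                               params.angular_cutoff, params.n_plate_angles)[0]


def ball_vote(v, B_q: np.ndarray, sigma_d: float,
              params: VoteParams | None = None) -> np.ndarray:
    """Vote cast by a ball component ``B_q`` at displacement ``v`` (mm)."""
    params = params or VoteParams()
    c = params.curvature_c(sigma_d)
    sal = float(np.trace(np.asarray(B_q, dtype=np.float64))) / 3.0
    if sal <= 0:
        return np.zeros((3, 3))
    return sal * _ball_kernel(np.asarray(v, float)[None], sigma_d, c,
                              params.angular_cutoff, params.n_ball_dirs)[0]


def cast_all_votes(field: TokenField, params: VoteParams | None = None) -> np.ndarray:
    """Accumulate all votes into a dense per-voxel tensor field.

    Tokens are grouped by optimal scale; per scale the ball kernel is
    precomputed on the window stencil once and splatted, stick kernels are
    evaluated in token batches vectorised over the stencil, and plate
    kernels (orientation integrals, rare outside the inverse-kappa
    initialisation) per token.  Returns ``field.shape + (3, 3)``; voxels
    receiving no votes are zero.
    """
    params = params or VoteParams()
    shape = field.shape
    out = np.zeros(shape + (3, 3))
    if len(field) == 0:
        warnings.warn("empty token set: accumulated field is all zero")
        return out
    sp = np.asarray(field.spacing, dtype=float)
    w, vv = np.linalg.eigh(field.tensors)
    tr = w.sum(axis=1)
    s_sal = _clip_saliency(w[:, 2] - w[:, 1], tr)
    s_dir = vv[:, :, 2]
    p_sal = _clip_saliency(w[:, 1] - w[:, 0], tr)
    p_nrm = vv[:, :, 0]
    b_sal = _clip_saliency(w[:, 0], tr)

    flat = out.reshape(-1, 9)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    cutoff = params.angular_cutoff

    def _splat(i, contrib, off, off_lin):
        site = field.sites[i]
        pos = site + off
        valid = np.all((pos >= 0) & (pos < shape), axis=1)
        lin = int(site @ strides) + off_lin[valid]
        flat[lin] += contrib[valid]

    for sigma in np.unique(field.M):
        sel = np.flatnonzero(field.M == sigma)
        off, vmm = window_offsets(sigma, sp)
        K = len(off)
        sigma_d = params.sigma_d(2.0 * float(sigma))
        c = params.curvature_c(sigma_d)
        off_lin = off @ strides

        ball_sel = sel[b_sal[sel] > 0]
        if len(ball_sel):
            kb9 = _ball_kernel(vmm, sigma_d, c, cutoff, params.n_ball_dirs).reshape(K, 9)
            for i in ball_sel:
                _splat(i, b_sal[i] * kb9, off, off_lin)

        stick_sel = sel[s_sal[sel] > 0]
        chunk = max(1, 2_000_000 // max(K, 1))
        for lo in range(0, len(stick_sel), chunk):
            ids = stick_sel[lo:lo + chunk]
            ks = _stick_votes(vmm, s_dir[ids], sigma_d, c, cutoff).reshape(len(ids), K, 9)
            for j, i in enumerate(ids):
                _splat(i, s_sal[i] * ks[j], off, off_lin)

        for i in sel[p_sal[sel] > 0]:
            kp = _plate_kernel(vmm, p_nrm[i], sigma_d, c, cutoff,
                               params.n_plate_angles).reshape(K, 9)
            _splat(i, p_sal[i] * kp, off, off_lin)
    return out


def cast_all_votes_bruteforce(field: TokenField,
                              params: VoteParams | None = None) -> np.ndarray:
    """Reference accumulation: explicit double loop over tokens and voxels.

    Intended for small volumes/token counts in tests; computes each vote
    through the public per-pair kernel functions.
    """
    params = params or VoteParams()
    shape = field.shape
    out = np.zeros(shape + (3, 3))
    if len(field) == 0:
        warnings.warn("empty token set: accumulated field is all zero")
        return out
    sp = np.asarray(field.spacing, dtype=float)
    for site, T, sigma in zip(field.sites, field.tensors, field.M):
        S, P, B = stick_plate_ball(T)
        thr = _SAL_TOL * max(np.trace(T), 0.0)
        off, vmm = window_offsets(float(sigma), sp)
        sigma_d = params.sigma_d(2.0 * float(sigma))
        for o, v in zip(off, vmm):
            p = site + o
            if np.any(p < 0) or np.any(p >= shape):
                continue
            tot = np.zeros((3, 3))
            if np.trace(S) > thr:
                tot += stick_vote(v, S, sigma_d, params)
            if np.trace(P) > 2 * thr:
                tot += plate_vote(v, P, sigma_d, params)
            if np.trace(B) > 3 * thr:
                tot += ball_vote(v, B, sigma_d, params)
            out[tuple(p)] += tot
    return out
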