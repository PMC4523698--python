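"""End-to-end extraction pipeline: volumes in, fused probability map out.

Per modality: scale-space vesselness -> token selection -> tensor encoding
-> tensor voting -> S-map extraction.  The per-modality S-maps are
percentile-normalised, resampled onto the grid of the first-listed
modality if needed, and fused (cosine by default).  The pipeline itself is
deterministic; the only randomness in the package lives in the phantom
generator.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .analysis import SaliencyMap, extract_maps
from .fusion import FUSION_OPS, FusedMap, fuse, normalize_saliency
from .scale_space import (
    VesselnessParams,
    build_scale_space,
    make_scale_ladder,
    select_tokens,
)
from .tokens import STRATEGIES, init_tokens
from .volume import ScalarVolume
from .voting import VoteParams, cast_all_votes

log = logging.getLogger("vesselvote")

__all__ = ["PipelineConfig", "run_modality", "extract_vessels"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of the whole extraction pipeline."""

    # scale ladder (mm); defaults: ten log-spaced scales from 1.0 to 4.5
    sigma_min: float = 1.0
    sigma_max: float = 4.5
    n_scales: int = 10
    gamma: float = 1.0
    # vesselness
    vesselness_variant: str = "manniesing"
    vesselness_alpha: float = 0.5
    vesselness_beta: float = 0.5
    vesselness_c: float | None = None
    vesselness_smooth_rel: float = 1e-3
    invert: bool = False            # set True for dark vessels on bright background
    # token selection / initialisation
    token_min_nu_rel: float = 0.05
    init_strategy: str = "hessian_vesselness"
    ball_k: float = 1.0
    # voting
    angular_cutoff_deg: float = 45.0
    curvature_weight: float | None = None
    decay_fraction: float = 1.0 / 3.0
    n_ball_dirs: int = 1024
    n_plate_angles: int = 32
    # fusion
    fusion_op: str = "cosine"
    normalize_percentile: float = 99.9
    # phantoms only; the pipeline itself is deterministic
    seed: int = 0

    def __post_init__(self):
        if self.init_strategy not in STRATEGIES:
            raise ValueError(
                f"init_strategy {self.init_strategy!r} not in {STRATEGIES}"
            )
        if self.fusion_op not in FUSION_OPS:
            raise ValueError(f"fusion_op {self.fusion_op!r} not in {FUSION_OPS}")
        make_scale_ladder(self.sigma_min, self.sigma_max, self.n_scales)

    def vesselness_params(self) -> VesselnessParams:
        return VesselnessParams(
            variant=self.vesselness_variant,
            alpha=self.vesselness_alpha,
            beta=self.vesselness_beta,
            c=self.vesselness_c,
            smooth_rel=self.vesselness_smooth_rel,
        )

    def vote_params(self) -> VoteParams:
        return VoteParams(
            angular_cutoff_deg=self.angular_cutoff_deg,
            curvature_weight=self.curvature_weight,
            decay_fraction=self.decay_fraction,
            n_ball_dirs=self.n_ball_dirs,
            n_plate_angles=self.n_plate_angles,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def run_modality(
    volume: ScalarVolume,
    config: PipelineConfig | None = None,
    mask: np.ndarray | None = None,
) -> tuple[SaliencyMap, dict]:
    """Run one modality through voting; return its S-map and stage artefacts."""
    config = config or PipelineConfig()
    vol = volume
    if config.invert:
        vol = volume.like(volume.data.max() - volume.data)
    ladder = make_scale_ladder(config.sigma_min, config.sigma_max, config.n_scales)
    timings = {}
    t0 = time.perf_counter()
    ss = build_scale_space(vol, ladder, config.vesselness_params(), gamma=config.gamma)
    timings["scale_space"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    tokens = select_tokens(ss, vol, mask=mask, min_nu_rel=config.token_min_nu_rel)
    tf = init_tokens(config.init_strategy, tokens, vol, ss, K=config.ball_k)
    timings["tokens"] = time.perf_counter() - t0
    log.info("%d tokens selected (%s init)", len(tokens), config.init_strategy)
    t0 = time.perf_counter()
    field_tv = cast_all_votes(tf, config.vote_params())
    timings["voting"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    smap, cmap, jmap = extract_maps(field_tv, spacing=vol.spacing)
    timings["analysis"] = time.perf_counter() - t0
    log.info(
        "stage timings: %s",
        ", ".join(f"{k}={v:.2f}s" for k, v in timings.items()),
    )
    return smap, {
        "scale_space": ss,
        "tokens": tokens,
        "token_field": tf,
        "voted": field_tv,
        "maps": (smap, cmap, jmap),
        "timings": timings,
    }


def _resample_smap(smap: SaliencyMap, affine, ref_shape, ref_affine) -> SaliencyMap:
    """Linear resampling of an S-map onto a reference grid.

    Saliencies are interpolated linearly; directions component-wise and
    renormalised (sentinel where the interpolated norm vanishes).
    """
    import nibabel as nib
    from nibabel.processing import resample_from_to

    def _res(arr, order=1):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine)
        out = resample_from_to(img, (ref_shape, ref_affine), order=order)
        return np.asanyarray(out.dataobj, dtype=np.float64)

    s = np.clip(_res(smap.s), 0.0, None)
    w = np.stack([_res(smap.w[..., k]) for k in range(3)], axis=-1)
    n = np.linalg.norm(w, axis=-1)
    ok = n > 1e-6
    w = np.where(ok[..., None], w / np.where(ok, n, 1.0)[..., None], 0.0)
    s = np.where(ok, s, 0.0)
    return SaliencyMap(s=s, w=w, map_kind=smap.map_kind, spacing=smap.spacing)


def extract_vessels(
    volumes,
    mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> tuple[FusedMap, list]:
    """Full multi-modal extraction; returns the fused map and per-modality S-maps.

    With a single volume the fusion stage is skipped (identity) with a
    warning.  Maps from modalities on other grids are resampled onto the
    grid of the first-listed volume before fusion.
    """
    config = config or PipelineConfig()
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    ref = volumes[0]
    smaps = []
    for i, vol in enumerate(volumes):
        m = mask
        if m is not None and m.shape != vol.shape:
            raise ValueError(
                f"mask shape {m.shape} does not match volume {i} shape {vol.shape}"
            )
        smap, _ = run_modality(vol, config, mask=m)
        if vol.shape != ref.shape or not np.allclose(vol.affine, ref.affine):
            smap = _resample_smap(smap, vol.affine, ref.shape, ref.affine)
        smaps.append(smap)
    norm = [normalize_saliency(m, config.normalize_percentile) for m in smaps]
    if len(norm) == 1:
        import warnings

        warnings.warn(
            f"single modality: {config.fusion_op} fusion skipped, "
            "S-map passed through"
        )
        fused = FusedMap(
            phi=norm[0].s.copy(), operator="identity", modalities=["mod1"],
            spacing=ref.spacing,
        )
    else:
        fused = fuse(norm, operator=config.fusion_op)
        fused.spacing = ref.spacing
    return fused, norm
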