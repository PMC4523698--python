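"""Fuse per-modality saliency maps into one vessel-probability map.

The cosine operator rewards direction consensus between modalities and
punishes discord: for two maps,

    phi(p) = 0.5 |w1 . w2| (s1 + s2),

the average of the saliencies when the directions agree, zero when they are
perpendicular (lines are unsigned, hence the absolute value).  For L
modalities,

    phi(p) = (1/L) sum_i s_i sum_{j != i} |w_i . w_j|,

which reduces to the pairwise form at L = 2.  Voxel-wise min and max are
provided as baselines (probabilistic AND / OR).  Sentinel (zero)
directions contribute zero alignment, so the cosine map vanishes where
either modality found nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import SaliencyMap

__all__ = [
    "FusedMap",
    "fuse_pair",
    "fuse_multi",
    "fuse_min",
    "fuse_max",
    "fuse",
    "normalize_saliency",
    "FUSION_OPS",
]

FUSION_OPS = ("cosine", "min", "max")


@dataclass
class FusedMap:
    """A fused scalar vessel-probability volume with its provenance."""

    phi: np.ndarray
    operator: str
    modalities: list = field(default_factory=list)
    spacing: tuple = (1.0, 1.0, 1.0)

    @property
    def shape(self):
        return self.phi.shape


def _check_grids(maps):
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(
            f"saliency maps live on different grids {sorted(shapes)}; "
            "resample them onto a common grid first"
        )


def normalize_saliency(m: SaliencyMap, percentile: float = 99.9) -> SaliencyMap:
    """Rescale saliencies to [0, 1] by the given percentile (robust to spikes).

    Applied per modality before fusion so no modality dominates through its
    intensity units; values above the percentile clip to 1.
    """
    hi = np.percentile(m.s, percentile)
    if hi <= 0:
        return m.with_s(np.zeros_like(m.s))
    return m.with_s(np.clip(m.s / hi, 0.0, 1.0))


def fuse_pair(map1: SaliencyMap, map2: SaliencyMap,
              names=("mod1", "mod2")) -> FusedMap:
    """Cosine fusion of two saliency maps: phi = 0.5 |w1.w2| (s1 + s2)."""
    _check_grids([map1, map2])
    align = np.abs(np.einsum("...i,...i->...", map1.w, map2.w))
    phi = 0.5 * align * (map1.s + map2.s)
    return FusedMap(phi=phi, operator="cosine", modalities=list(names),
                    spacing=map1.spacing)


def fuse_multi(maps, names=None) -> FusedMap:
    """Cosine fusion of L >= 2 maps; reduces to :func:`fuse_pair` at L = 2."""
    maps = list(maps)
    L = len(maps)
    if L < 2:
        raise ValueError(f"need at least 2 modalities to fuse, got {L}")
    _check_grids(maps)
    s = np.stack([m.s for m in maps])            # (L, ...)
    w = np.stack([m.w for m in maps])            # (L, ..., 3)
    align = np.abs(np.einsum("i...k,j...k->ij...", w, w))
    for i in range(L):
        align[i, i] = 0.0
    phi = np.einsum("i...,i...->...", s, align.sum(axis=1)) / L
    return FusedMap(phi=phi, operator="cosine",
                    modalities=list(names) if names else [f"mod{i+1}" for i in range(L)],
                    spacing=maps[0].spacing)


def fuse_min(maps, names=None) -> FusedMap:
    """Voxel-wise minimum of saliencies (probabilistic AND); directions ignored."""
    maps = list(maps)
    _check_grids(maps)
    phi = np.min(np.stack([m.s for m in maps]), axis=0)
    return FusedMap(phi=phi, operator="min",
                    modalities=list(names) if names else [f"mod{i+1}" for i in range(len(maps))],
                    spacing=maps[0].spacing)


def fuse_max(maps, names=None) -> FusedMap:
    """Voxel-wise maximum of saliencies (probabilistic OR); directions ignored."""
    maps = list(maps)
    _check_grids(maps)
    phi = np.max(np.stack([m.s for m in maps]), axis=0)
    return FusedMap(phi=phi, operator="max",
                    modalities=list(names) if names else [f"mod{i+1}" for i in range(len(maps))],
                    spacing=maps[0].spacing)


def fuse(maps, operator: str = "cosine", names=None) -> FusedMap:
    """Dispatch a named fusion operator over a list of saliency maps."""
    if operator == "cosine":
        return fuse_multi(maps, names=names)
    if operator == "min":
        return fuse_min(maps, names=names)
    if operator == "max":
        return fuse_max(maps, names=names)
    raise ValueError(f"unknown fusion operator {operator!r}; choose from {FUSION_OPS}")
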