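"""Decompose the accumulated tensor field into S/C/J saliency maps.

Per voxel the voted tensor is eigendecomposed (``l1 >= l2 >= l3 >= 0``) and
split into three (saliency, direction) maps:

=====  ===========  =========  =============================
map    saliency s   direction  interpretation
=====  ===========  =========  =============================
S      l1 - l2      e1         surfaceness; for vessels, a consensus
                               vesselness with e1 along the vessel
C      l2 - l3      e3         curveness
J      l3           (none)     junctionness / orientation-free
=====  ===========  =========  =============================

Voxels with a zero tensor get s = 0 and the sentinel direction (0, 0, 0);
fusion treats sentinel directions as zero alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SaliencyMap", "extract_maps"]


@dataclass
class SaliencyMap:
    """Per-voxel 2-tuple (s, w): scalar saliency + unit direction."""

    s: np.ndarray          # (...,) >= 0
    w: np.ndarray          # (..., 3) unit where s > 0 (sentinel 0 allowed)
    map_kind: str = "S"    # one of S, C, J
    spacing: tuple = (1.0, 1.0, 1.0)

    @property
    def shape(self):
        return self.s.shape

    def with_s(self, s: np.ndarray) -> "SaliencyMap":
        return SaliencyMap(s=s, w=self.w, map_kind=self.map_kind, spacing=self.spacing)


def extract_maps(field: np.ndarray, spacing=(1.0, 1.0, 1.0),
                 psd_tol: float = 1e-8) -> tuple[SaliencyMap, SaliencyMap, SaliencyMap]:
    """Extract the (S, C, J) maps from an accumulated tensor field.

    ``field`` has shape ``(...) + (3, 3)`` and must be PSD within
    ``psd_tol`` relative to each voxel's trace (tiny negative eigenvalues
    from rounding are clamped; larger ones raise, naming the voxel).
    The saliency identity ``l1 = s_S + s_C + s_J`` holds per voxel.
    """
    field = np.asarray(field, dtype=np.float64)
    w, v = np.linalg.eigh(field)  # ascending
    tr = np.trace(field, axis1=-2, axis2=-1)
    bad = w[..., 0] < -psd_tol * np.maximum(1e-30, np.abs(tr))
    if np.any(bad):
        vox = tuple(np.argwhere(bad)[0])
        raise RuntimeError(
            f"accumulated tensor at voxel {vox} is not PSD "
            f"(min eigenvalue {w[..., 0][vox]:.3e})"
        )
    w = np.clip(w, 0.0, None)
    l3, l2, l1 = w[..., 0], w[..., 1], w[..., 2]
    e1 = v[..., :, 2]
    e3 = v[..., :, 0]

    def _map(s, e, kind):
        wdir = np.where((s > 0)[..., None], e, 0.0)
        return SaliencyMap(s=s, w=wdir, map_kind=kind, spacing=tuple(spacing))

    return (
        _map(l1 - l2, e1, "S"),
        _map(l2 - l3, e3, "C"),
        _map(l3, np.zeros(field.shape[:-2] + (3,)), "J"),
    )
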