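"""Fuzzy Dice overlap, multi-rater consensus, and the comparison harness.

The fuzzy Dice similarity coefficient generalises binary Dice to
probabilistic maps by taking the voxel-wise minimum as the intersection:

    DSC = 2 sum min(S, M) / sum (S + M),

with both inputs in [0, 1] (probabilistic maps are percentile-normalised
first).  On binary inputs it equals the classic Dice coefficient; when both
inputs are identically zero it is 1 by convention.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = ["fuzzy_dice", "consensus", "otsu_binarize", "run_comparison"]


def fuzzy_dice(S: np.ndarray, M: np.ndarray) -> float:
    """Fuzzy Dice overlap of two same-grid maps with values in [0, 1]."""
    S = np.asarray(S, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    if S.shape != M.shape:
        raise ValueError(f"grid mismatch: {S.shape} vs {M.shape}")
    for name, a in (("S", S), ("M", M)):
        if a.min() < -1e-9 or a.max() > 1 + 1e-9:
            raise ValueError(f"{name} has values outside [0, 1]; normalise first")
    denom = float(S.sum() + M.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.minimum(S, M).sum()) / denom


def consensus(masks, threshold: int | None = None) -> np.ndarray:
    """Voxel-wise vote over binary rater masks.

    A voxel is set in the consensus iff at least ``threshold`` masks set it
    (default: majority, ceil(n/2)).
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) < 2:
        raise ValueError("consensus needs at least 2 masks")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError("masks live on different grids")
    n = len(masks)
    if threshold is None:
        threshold = math.ceil(n / 2)
    if not (1 <= threshold <= n):
        raise ValueError(f"threshold must be in [1, {n}], got {threshold}")
    return np.sum(np.stack(masks), axis=0) >= threshold


def otsu_binarize(phi: np.ndarray, percentile: float = 99.9) -> np.ndarray:
    """Percentile-normalise a probability map, then Otsu-threshold it."""
    phi = np.asarray(phi, dtype=np.float64)
    hi = np.percentile(phi, percentile)
    if hi <= 0:
        return np.zeros(phi.shape, dtype=bool)
    p = np.clip(phi / hi, 0.0, 1.0)
    return p > threshold_otsu(p)


def run_comparison(
    spec,
    strategies,
    fusion_ops=("cosine",),
    seeds=(0,),
    config=None,
) -> pd.DataFrame:
    """Fuzzy-DSC comparison of initialisation strategies and fusion operators.

    Regenerates the phantom described by ``spec`` for each seed, runs the
    full pipeline per (strategy, fusion operator), and scores the
    percentile-normalised probability map against the binary truth with
    fuzzy Dice (probabilistic path) and after Otsu thresholding (binary
    path).  Returns one row per combination with mean +/- sd over seeds.
    """
    from dataclasses import replace

    from .fusion import normalize_saliency
    from .phantom import generate
    from .pipeline import PipelineConfig, extract_vessels

    config = config or PipelineConfig()
    rows = []
    for strat in strategies:
        for op in fusion_ops:
            dscs, bdscs = [], []
            for seed in seeds:
                sp = replace(spec, seed=int(seed))
                bundle = generate(sp)
                cfg = replace(config, init_strategy=strat, fusion_op=op)
                fused, _ = extract_vessels(bundle.volumes, config=cfg)
                truth = bundle.truth.astype(float)
                hi = np.percentile(fused.phi, cfg.normalize_percentile)
                prob = np.clip(fused.phi / hi, 0.0, 1.0) if hi > 0 else np.zeros_like(fused.phi)
                dscs.append(fuzzy_dice(prob, truth))
                bdscs.append(fuzzy_dice(otsu_binarize(fused.phi).astype(float), truth))
            rows.append(
                {
                    "strategy": strat,
                    "fusion": op,
                    "n_seeds": len(seeds),
                    "dsc_mean": float(np.mean(dscs)),
                    "dsc_sd": float(np.std(dscs)),
                    "dsc_binary_mean": float(np.mean(bdscs)),
                    "dsc_binary_sd": float(np.std(bdscs)),
                }
            )
    return pd.DataFrame(rows)
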