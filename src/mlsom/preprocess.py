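"""Preprocessing chain producing the joint SOM training matrix.

The fixed order is: per-layer quantile normalization -> global per-gene
centering over all samples of all layers -> layer harmonization (one scalar
per layer) -> re-centering. The output is the delta-e matrix: for each gene,
its log2 expression deviation from its grand mean, on a scale where no layer
dominates Euclidean distances during SOM training.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import (
    ExpressionLayer,
    JointMatrix,
    MultiLayerDataset,
    ValidationError,
)

logger = logging.getLogger(__name__)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a genes x samples table.

    After normalization every column carries the same multiset of values: the
    per-rank means of the sorted columns. Ties within a column receive the
    mean of the tied ranks' reference values (average-rank convention), so
    the result is independent of input column or row order.
    """
    if values.shape[1] < 2:
        raise ValidationError(
            "quantile normalization needs >=2 samples, got "
            f"{values.shape[1]}"
        )
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks - 1.0, np.arange(n), reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize_layer(layer: ExpressionLayer) -> ExpressionLayer:
    """Quantile-normalize one layer's samples against each other."""
    return dataclasses.replace(layer, values=quantile_normalize(layer.values))


def center_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean over all samples (global centralization)."""
    return values.sub(values.mean(axis=1), axis=0)


def layer_mean_sd(values: pd.DataFrame, ddof: int = 1) -> float:
    """Mean over genes of the per-gene SD across this layer's samples."""
    return float(values.std(axis=1, ddof=ddof).mean())


def harmonize_layers(joint: JointMatrix) -> JointMatrix:
    """Rescale each layer's block by one scalar so every layer contributes
    equally to SOM training distances, then re-center.

    The per-layer statistic is the mean per-gene standard deviation across the
    layer's samples; each block is scaled so this statistic equals the
    across-layer median. Per-gene re-centering afterwards restores the
    zero-mean invariant without changing within-layer SDs, so the operation
    is idempotent.
    """
    values = joint.values.copy()
    layer_ids = list(dict.fromkeys(joint.samples["layer"]))
    stats = {}
    for lid in layer_ids:
        cols = joint.layer_samples(lid)
        sd = layer_mean_sd(values[cols])
        if sd <= 0 or not np.isfinite(sd):
            raise ValidationError(f"layer {lid!r} has zero total variance")
        stats[lid] = sd
    target = float(np.median(list(stats.values())))
    for lid in layer_ids:
        scale = target / stats[lid]
        cols = joint.layer_samples(lid)
        values[cols] = values[cols] * scale
        logger.debug("harmonization: layer %s scaled by %.4f", lid, scale)
    values = center_genes(values)
    return JointMatrix(values=values, samples=joint.samples)


def build_joint_matrix(dataset: MultiLayerDataset,
                       quantile_normalize_layers: bool = True,
                       harmonize: bool = True) -> JointMatrix:
    """Run the full preprocessing chain on a multi-layer dataset."""
    ds = dataset.restricted()
    blocks = []
    for layer in ds.layers:
        block = layer.values
        if quantile_normalize_layers:
            block = quantile_normalize(block)
        blocks.append(block)
    values = center_genes(pd.concat(blocks, axis=1))
    joint = JointMatrix(values=values, samples=ds.sample_table())
    if harmonize:
        joint = harmonize_layers(joint)
    assert joint.is_centered(), "joint matrix lost the zero-mean invariant"
    return joint
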