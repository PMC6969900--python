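"""Joint batch self-organizing-map training of genes into a metagene grid.

Genes are the objects, their delta-e profiles across all samples of all
layers are the features. Training is batch Kohonen: each epoch assigns every
gene to its best-matching unit (Euclidean distance) and replaces each unit's
prototype by the neighborhood-weighted mean of the assigned gene profiles.
Prototypes are initialized on the plane spanned by the first two principal
components of the gene cloud, which together with batch updates makes a run
fully deterministic. The Gaussian neighborhood is truncated beyond the
current radius, so the late fine-phase epochs (radius < 1) reduce exactly to
Lloyd/k-means iterations on the grid prototypes.

Because all layers are trained jointly, every unit ("metagene") holds the
same genes in every layer, and per-sample grid images ("portraits") are
directly comparable across layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import JointMatrix, PipelineConfig, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SOMModel:
    """A trained metagene grid shared by all layers.

    ``prototypes`` is units x samples (row-major unit order, delta-e scale);
    ``assignment`` maps every gene to its unit index; ``training_log`` has one
    row per epoch with the neighborhood radius and quantization error.
    """

    grid_shape: tuple[int, int]
    prototypes: np.ndarray  # (n_units, n_samples)
    samples: list[str]
    assignment: pd.Series  # gene -> unit index (row-major)
    training_log: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n_units = self.grid_shape[0] * self.grid_shape[1]
        if self.prototypes.shape != (n_units, len(self.samples)):
            raise ValidationError("prototype array shape mismatch")
        if not np.isfinite(self.prototypes).all():
            raise ValidationError("non-finite prototypes")
        if (self.assignment < 0).any() or (self.assignment >= n_units).any():
            raise ValidationError("assignment refers to units off the grid")

    @property
    def n_units(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def unit_index(self, row: int, col: int) -> int:
        return row * self.grid_shape[1] + col

    def unit_coords(self, unit: int) -> tuple[int, int]:
        return divmod(unit, self.grid_shape[1])

    def unit_genes(self, unit: int) -> list[str]:
        return list(self.assignment.index[self.assignment == unit])

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def portrait(self, samples: str | list[str]) -> np.ndarray:
        """Grid image of metagene expression for one sample, or the
        element-wise mean image for a group of samples."""
        if isinstance(samples, str):
            samples = [samples]
        if not samples:
            raise ValidationError("portrait of an empty sample group")
        idx = [self.sample_index(s) for s in samples]
        return self.prototypes[:, idx].mean(axis=1).reshape(self.grid_shape)

    def population_map(self) -> np.ndarray:
        """Genes per unit; sums to the number of assigned genes."""
        counts = np.bincount(self.assignment.to_numpy(), minlength=self.n_units)
        return counts.reshape(self.grid_shape)

    def variance_map(self, ddof: int = 0) -> np.ndarray:
        """Per-unit variance of the prototype across all samples."""
        return self.prototypes.var(axis=1, ddof=ddof).reshape(self.grid_shape)


@dataclass
class SupportMaps:
    """Per-grid summaries characterizing the trained map: how many genes each
    unit holds, how variable each metagene is across samples, and in how many
    portraits each unit falls inside an overexpression spot."""

    population: np.ndarray
    variance: np.ndarray
    overexpression_frequency: np.ndarray


def _radius_schedule(config: PipelineConfig, grid_shape: tuple[int, int]
                     ) -> list[tuple[str, float]]:
    start = max(grid_shape) / 2.0
    rough_end = min(config.rough_radius_end, start)
    fine_start = rough_end
    fine_end = min(config.fine_radius_end, fine_start)
    sched = [("rough", r) for r in
             np.linspace(start, rough_end, config.rough_epochs)]
    sched += [("fine", r) for r in
              np.linspace(fine_start, fine_end, config.fine_epochs)]
    return sched


def _pca_plane_init(X: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Prototypes spread on the first-two-principal-component plane of the
    gene cloud, spanning +/-2 SD along each component."""
    n_rows, n_cols = grid_shape
    mean = X.mean(axis=0)
    Xc = X - mean
    # genes are points in sample space; Vt rows are the principal directions
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    sd = s / np.sqrt(max(X.shape[0] - 1, 1))
    a_col = np.linspace(-1.0, 1.0, n_cols) if n_cols > 1 else np.zeros(1)
    a_row = np.linspace(-1.0, 1.0, n_rows) if n_rows > 1 else np.zeros(1)
    proto = np.tile(mean, (n_rows * n_cols, 1))
    if len(s) >= 1 and sd[0] > 0:
        proto += 2.0 * sd[0] * np.outer(np.tile(a_col, n_rows), Vt[0])
    if len(s) >= 2 and sd[1] > 0:
        proto += 2.0 * sd[1] * np.outer(np.repeat(a_row, n_cols), Vt[1])
    return proto


def _bmu_and_qe(X: np.ndarray, proto: np.ndarray) -> tuple[np.ndarray, float]:
    """Best-matching unit per gene and mean squared distance to it."""
    # ||x||^2 - 2 x.p + ||p||^2, computed blockwise-free (sizes are modest)
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ proto.T
        + np.sum(proto * proto, axis=1)[None, :]
    )
    bmu = np.argmin(d2, axis=1)
    qe = float(np.maximum(d2[np.arange(len(bmu)), bmu], 0.0).mean())
    return bmu, qe


def train_som(joint: JointMatrix, config: PipelineConfig) -> SOMModel:
    """Train the joint metagene grid on the preprocessed delta-e matrix.

    Two phases with a linearly shrinking neighborhood radius (rough:
    max(grid)/2 -> 3 over ``rough_epochs``; fine: 3 -> 0.5 over
    ``fine_epochs``). Empty units keep their previous prototype — they still
    carry interpolated expression and may later join spots; the population
    map exposes them.
    """
    X = joint.values.to_numpy(dtype=float)
    if X.size == 0:
        raise ValidationError("cannot train on an empty matrix")
    if not np.isfinite(X).all():
        raise ValidationError("joint matrix contains non-finite values")
    grid_shape = config.grid_shape
    n_units = grid_shape[0] * grid_shape[1]
    if X.shape[0] < n_units / 10:
        logger.warning("only %d genes for %d units; map will be sparse",
                       X.shape[0], n_units)

    proto = _pca_plane_init(X, grid_shape)
    rows, cols = np.divmod(np.arange(n_units), grid_shape[1])
    grid_d2 = (rows[:, None] - rows[None, :]) ** 2 \
        + (cols[:, None] - cols[None, :]) ** 2

    log_rows = []
    bmu = np.zeros(X.shape[0], dtype=int)
    for epoch, (phase, radius) in enumerate(_radius_schedule(config, grid_shape)):
        bmu, qe = _bmu_and_qe(X, proto)
        sigma2 = max(radius, 1e-12) ** 2
        H = np.exp(-grid_d2 / (2.0 * sigma2))
        H[grid_d2 > radius ** 2] = 0.0
        counts = np.bincount(bmu, minlength=n_units).astype(float)
        sums = np.zeros((n_units, X.shape[1]))
        np.add.at(sums, bmu, X)
        num = H @ sums
        den = H @ counts
        nonempty = den > 0
        proto[nonempty] = num[nonempty] / den[nonempty, None]
        log_rows.append((epoch, phase, float(radius), qe))

    bmu, qe = _bmu_and_qe(X, proto)
    log_rows.append((len(log_rows), "final", 0.0, qe))
    log = pd.DataFrame(log_rows, columns=["epoch", "phase", "radius",
                                          "quantization_error"])
    assignment = pd.Series(bmu, index=joint.values.index, name="unit")
    return SOMModel(grid_shape=grid_shape, prototypes=proto,
                    samples=list(joint.values.columns),
                    assignment=assignment, training_log=log)


def group_portraits(model: SOMModel, samples: pd.DataFrame,
                    by: tuple[str, ...] = ("layer", "group", "subgroup"),
                    ) -> dict[tuple, np.ndarray]:
    """Mean portraits for every (layer, group[, subgroup]) sample stratum.

    Keys are tuples of the ``by`` column values; strata with no samples do
    not occur. Subgroup '' (unset) forms its own stratum.
    """
    out: dict[tuple, np.ndarray] = {}
    for key, members in samples.groupby(list(by), sort=True):
        out[key] = model.portrait(list(members.index))
    return out


def support_maps(model: SOMModel, spot_masks: list[np.ndarray] | None = None
                 ) -> SupportMaps:
    """Population, variance, and overexpression-frequency maps."""
    masks = spot_masks or []
    if masks:
        freq = np.sum([m.astype(int) for m in masks], axis=0)
    else:
        freq = np.zeros(model.grid_shape, dtype=int)
    return SupportMaps(
        population=model.population_map(),
        variance=model.variance_map(),
        overexpression_frequency=np.asarray(freq, dtype=int),
    )
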