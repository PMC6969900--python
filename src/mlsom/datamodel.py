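"""Domain types shared across the pipeline.

The central objects mirror the study design the method expects: several
case/control expression datasets ("layers"), each tagged with its role in a
repositioning experiment (the drug/treatment dataset, the drug's approved
target disease, and one or more candidate repositioning diseases), all joined
on a common gene set and trained into one self-organizing map.
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

ROLE_TAGS = ("treatment", "target_disease", "repositioning_disease")
SAMPLE_GROUPS = ("target", "reference")


class ValidationError(ValueError):
    """Raised when an input object violates a pipeline invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed into a domain object."""


@dataclass
class ExpressionLayer:
    """One case/control dataset: a log2 gene x sample matrix plus sample roles.

    Parameters
    ----------
    layer_id
        Short unique name of the dataset (e.g. ``"UC"`` or a GEO accession).
    role_tag
        Role of the dataset in the repositioning design: ``"treatment"``
        (drug action vs baseline/placebo), ``"target_disease"`` (the drug's
        approved indication vs healthy) or ``"repositioning_disease"``
        (candidate indication vs healthy).
    values
        Genes x samples DataFrame of log2 expression (RMA-like scale).
    sample_group
        Maps every sample to ``"target"`` or ``"reference"``.
    sample_subgroup
        Optional finer labels (responder / non-responder / placebo / baseline
        / week8 ...) used to enumerate treatment-layer contrasts.
    """

    layer_id: str
    role_tag: str
    values: pd.DataFrame
    sample_group: dict[str, str]
    sample_subgroup: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str, subgroup: str | None = None) -> list[str]:
        """Samples in a target/reference group, optionally within a subgroup."""
        out = [s for s in self.samples if self.sample_group[s] == group]
        if subgroup is not None:
            sub = self.sample_subgroup or {}
            out = [s for s in out if sub.get(s) == subgroup]
        return out

    def validate(self) -> None:
        if self.role_tag not in ROLE_TAGS:
            raise ValidationError(
                f"layer {self.layer_id!r}: role_tag {self.role_tag!r} "
                f"not in {ROLE_TAGS}"
            )
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(
                f"layer {self.layer_id!r}: duplicate gene ids {dups[:5]}"
            )
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"layer {self.layer_id!r}: non-finite value at gene "
                f"{idx[g]!r}, sample {self.values.columns[s]!r}"
            )
        missing = [s for s in self.samples if s not in self.sample_group]
        if missing:
            raise ValidationError(
                f"layer {self.layer_id!r}: samples without a group: {missing[:5]}"
            )
        bad = {s: g for s, g in self.sample_group.items() if g not in SAMPLE_GROUPS}
        if bad:
            raise ValidationError(
                f"layer {self.layer_id!r}: invalid group values {bad}; "
                f"allowed: {SAMPLE_GROUPS}"
            )
        for grp in SAMPLE_GROUPS:
            if not self.group_samples(grp):
                raise ValidationError(
                    f"layer {self.layer_id!r}: no {grp!r} samples"
                )


@dataclass
class MultiLayerDataset:
    """Several expression layers restricted to their common gene set."""

    layers: list[ExpressionLayer]
    shared_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError("dataset has no layers")
        ids = [l.layer_id for l in self.layers]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate layer ids: {ids}")
        if not self.shared_genes:
            shared = set(self.layers[0].genes)
            for layer in self.layers[1:]:
                shared &= set(layer.genes)
            # keep the first layer's row order
            self.shared_genes = [g for g in self.layers[0].genes if g in shared]
        if not self.shared_genes:
            raise ValidationError("layers share no genes")
        all_samples = [s for l in self.layers for s in l.samples]
        if len(set(all_samples)) != len(all_samples):
            raise ValidationError("sample ids are not unique across layers")

    @property
    def layer_ids(self) -> list[str]:
        return [l.layer_id for l in self.layers]

    def layer(self, layer_id: str) -> ExpressionLayer:
        for l in self.layers:
            if l.layer_id == layer_id:
                return l
        raise KeyError(layer_id)

    def sample_table(self) -> pd.DataFrame:
        """Per-sample metadata: layer, role, group, subgroup."""
        rows = []
        for l in self.layers:
            sub = l.sample_subgroup or {}
            for s in l.samples:
                rows.append(
                    (s, l.layer_id, l.role_tag, l.sample_group[s], sub.get(s, ""))
                )
        return pd.DataFrame(
            rows, columns=["sample", "layer", "role", "group", "subgroup"]
        ).set_index("sample")

    def restricted(self) -> "MultiLayerDataset":
        """Return a copy whose layers carry exactly ``shared_genes`` rows."""
        layers = [
            dataclasses.replace(l, values=l.values.loc[self.shared_genes])
            for l in self.layers
        ]
        return MultiLayerDataset(layers=layers, shared_genes=list(self.shared_genes))


@dataclass
class JointMatrix:
    """The joint training matrix: centered log2 expression (delta-e) over all
    samples of all layers, plus the per-sample metadata table."""

    values: pd.DataFrame  # genes x all samples
    samples: pd.DataFrame  # index sample; columns layer, role, group, subgroup

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("joint matrix columns do not match sample table")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("joint matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def layer_samples(self, layer_id: str) -> list[str]:
        sel = self.samples.index[self.samples["layer"] == layer_id]
        if sel.empty:
            raise KeyError(f"unknown layer {layer_id!r}")
        return list(sel)

    def is_centered(self, tol: float = 1e-9) -> bool:
        return bool(np.abs(self.values.to_numpy().mean(axis=1)).max() <= tol)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), each with a free-text source tag."""

    sets: dict[str, list[str]]
    source_tag: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


EDGE_SIGNS = ("activation", "inhibition")


@dataclass
class PathwayGraph:
    """A signed directed pathway topology with linear fold changes on nodes.

    ``graph`` is a :class:`networkx.DiGraph` whose edges carry a ``sign``
    attribute (``"activation"`` or ``"inhibition"``) and whose nodes carry a
    positive linear-scale fold change ``fc``. Nodes with no incoming edge are
    the pathway inputs, nodes with no outgoing edge its sinks; an isolated
    node is both.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            fc = data.get("fc", 1.0)
            if not np.isfinite(fc) or fc <= 0:
                raise ValidationError(
                    f"node {node!r}: fold change must be positive, got {fc}"
                )
            data["fc"] = float(fc)
        for u, v, data in self.graph.edges(data=True):
            if data.get("sign") not in EDGE_SIGNS:
                raise ValidationError(
                    f"edge {u}->{v}: sign {data.get('sign')!r} not in {EDGE_SIGNS}"
                )
        if self.graph.number_of_nodes() == 0:
            raise ValidationError("pathway graph is empty")
        if not self.input_nodes or not self.sink_nodes:
            raise ValidationError("pathway graph needs >=1 input and >=1 sink")

    @property
    def input_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    @property
    def sink_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def node_fc(self, node: str) -> float:
        return float(self.graph.nodes[node]["fc"])


@dataclass
class PipelineConfig:
    """All tunable parameters of the portrayal / calling pipeline.

    Defaults mirror the published analysis settings: a 45x45 metagene grid,
    the 95th-percentile overexpression criterion, a +/-1 SD presence/absence
    threshold and the combined p < 0.05, fold change > 1.5 t-test criterion.
    """

    grid_size: int | tuple[int, int] = 45
    overexpression_quantile: float = 0.95
    sd_multiplier: float = 1.0
    ttest_alpha: float = 0.05
    fc_threshold: float | None = 1.5
    fdr_method: str = "fdr_bh"
    random_seed: int = 0
    connectivity: int = 8
    vote: str = "both"  # "both" = conservative AND; "any" = either caller
    welch: bool = True
    profile_source: str = "genes"  # spot profiles: member genes | prototypes
    underexpression: bool = False  # also segment the low-tail mirror spots
    # SOM schedule (batch Kohonen; see docs/methods.md)
    rough_epochs: int = 20
    fine_epochs: int = 30
    rough_radius_end: float = 3.0
    fine_radius_end: float = 0.5

    def __post_init__(self) -> None:
        r, c = self.grid_shape
        if r < 1 or c < 1:
            raise ValidationError("grid_size must be positive")
        if not 0.0 < self.overexpression_quantile < 1.0:
            raise ValidationError("overexpression_quantile must be in (0, 1)")
        if self.sd_multiplier <= 0:
            raise ValidationError("sd_multiplier must be positive")
        if not 0.0 < self.ttest_alpha < 1.0:
            raise ValidationError("ttest_alpha must be in (0, 1)")
        if self.fc_threshold is not None and self.fc_threshold <= 1.0:
            raise ValidationError("fc_threshold must exceed 1 (or be None)")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        if self.vote not in ("both", "any"):
            raise ValidationError("vote must be 'both' or 'any'")
        if self.profile_source not in ("genes", "prototypes"):
            raise ValidationError("profile_source must be 'genes' or 'prototypes'")

    @property
    def grid_shape(self) -> tuple[int, int]:
        if isinstance(self.grid_size, int):
            return (self.grid_size, self.grid_size)
        r, c = self.grid_size
        return (int(r), int(c))


@dataclass
class Contrast:
    """A target-vs-reference comparison within one layer."""

    name: str
    layer_id: str
    target_samples: list[str]
    reference_samples: list[str]

    def __post_init__(self) -> None:
        if not self.target_samples or not self.reference_samples:
            raise ValidationError(f"contrast {self.name!r}: empty sample set")
        if set(self.target_samples) & set(self.reference_samples):
            raise ValidationError(
                f"contrast {self.name!r}: target and reference overlap"
            )


def spot_labels(n: int) -> list[str]:
    """Spot labels A..Z, then A1..Z1, A2.. — row-major order of discovery."""
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        cycle, pos = divmod(i, 26)
        out.append(letters[pos] + (str(cycle) if cycle else ""))
    return out


@dataclass
class Spot:
    """A connected cluster of overexpressed metagenes on the summary map."""

    label: str
    units: list[tuple[int, int]]  # grid coordinates (row, col)
    genes: list[str]  # member genes (union of unit gene lists)
    profile: pd.Series  # sample -> mean delta-e over the spot's units

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class SpotCall:
    """Directional call for one spot under one contrast."""

    spot: str
    layer_id: str
    contrast: str
    pa_vote: str  # presence/absence vote: up / down / none
    t_vote: str  # t-test vote: up / down / none
    direction: str  # joint vote
    p_value: float
    linear_fc: float

    VOTES = ("up", "down", "none")


@dataclass
class PerturbationMatrix:
    """Spots x contrasts table of directional calls."""

    calls: dict[tuple[str, str], SpotCall]  # (spot label, contrast name) -> call
    spots: list[str]
    contrasts: list[Contrast]

    def call(self, spot: str, contrast: str) -> SpotCall:
        return self.calls[(spot, contrast)]

    def contrast(self, name: str) -> Contrast:
        for c in self.contrasts:
            if c.name == name:
                return c
        raise KeyError(f"unknown contrast {name!r}")

    def direction_frame(self) -> pd.DataFrame:
        """Spots x contrasts grid of joint directions (the heatmap content)."""
        names = [c.name for c in self.contrasts]
        data = {
            c: [self.calls[(s, c)].direction for s in self.spots] for c in names
        }
        return pd.DataFrame(data, index=self.spots, columns=names)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (spot, contrast) call."""
        rows = []
        for c in self.contrasts:
            for s in self.spots:
                call = self.calls[(s, c.name)]
                rows.append(
                    (s, c.layer_id, c.name, call.direction, call.pa_vote,
                     call.t_vote, call.p_value, call.linear_fc)
                )
        return pd.DataFrame(
            rows,
            columns=["spot", "layer", "contrast", "direction", "pa_vote",
                     "t_vote", "p_value", "linear_fc"],
        )


@dataclass
class RepositioningVerdict:
    """Outcome of the antagonistic-spot test for one drug/disease pair.

    The drug is a repositioning candidate iff at least one spot is regulated
    in opposite directions by the disease and the treatment contrast.
    Disease-dysregulated spots the drug leaves untouched are reported too:
    they flag pathology the drug would not address (or could worsen).
    """

    drug_layer: str
    disease_layer: str
    drug_contrast: str
    disease_contrast: str
    antagonistic_spots: list[tuple[str, str, str]]  # (spot, disease dir, drug dir)
    unopposed_disease_spots: list[str]
    verdict: str  # "candidate" | "not_supported"

    def __post_init__(self) -> None:
        expected = "candidate" if self.antagonistic_spots else "not_supported"
        if self.verdict != expected:
            raise ValidationError("verdict inconsistent with antagonistic spots")
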