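"""Readers and writers for the pipeline's external text formats.

Expression matrices and sample sheets are plain TSV, gene sets are standard
GMT, pathway topologies are signed edge lists with a separate node
fold-change table, and configuration is YAML. Matrices are taken as already
log2-scale (RMA-like); no re-logging is performed, and gene identifiers are
used verbatim — mapping between namespaces is the caller's responsibility.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    EDGE_SIGNS,
    ExpressionLayer,
    GeneSetCollection,
    MultiLayerDataset,
    ParseError,
    PathwayGraph,
    PipelineConfig,
    SAMPLE_GROUPS,
    ValidationError,
)

logger = logging.getLogger(__name__)


def read_expression_matrix(path: str | Path, layer_id: str,
                           role_tag: str = "target_disease",
                           sample_group: Mapping[str, str] | None = None,
                           sample_subgroup: Mapping[str, str] | None = None,
                           ) -> ExpressionLayer:
    """Parse a genes x samples TSV (first column gene id, header sample ids).

    When ``sample_group`` is omitted every sample is provisionally tagged
    ``"target"`` except one ``"reference"`` placeholder is NOT invented: the
    caller must supply groups (usually via :func:`read_sample_sheet` and
    :func:`assemble_dataset`) before validation can pass, so this function
    defers layer construction errors to that step by accepting a mapping.
    """
    path = Path(path)
    # round_trip parsing keeps write->read cycles bit-identical
    raw = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                      float_precision="round_trip")
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValidationError(
            f"{path.name}: duplicate gene id(s) {dups[:5]}"
        )
    values = raw
    if any(dtype == object for dtype in raw.dtypes):
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(coerced.isna().to_numpy())
        if bad.size:
            g, s = bad[0]
            raise ParseError(
                f"{path.name}: non-numeric cell {raw.iat[g, s]!r} at gene "
                f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
            )
        values = coerced
    if sample_group is None:
        # neutral provisional grouping; replaced by the sample sheet on join
        cols = list(values.columns)
        sample_group = {c: ("reference" if i == 0 else "target")
                        for i, c in enumerate(cols)}
    return ExpressionLayer(
        layer_id=layer_id,
        role_tag=role_tag,
        values=values.astype(float),
        sample_group=dict(sample_group),
        sample_subgroup=dict(sample_subgroup) if sample_subgroup else None,
    )


def write_expression_matrix(layer: ExpressionLayer, path: str | Path) -> None:
    """Write the layer's matrix as TSV; re-reading reproduces values exactly
    (floats are serialized with round-trip repr)."""
    df = layer.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Parse the sample sheet TSV: columns sample, layer, group[, subgroup].

    Returns a DataFrame indexed by sample with columns layer, group, subgroup.
    """
    path = Path(path)
    sheet = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "layer", "group"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {sorted(missing)}")
    if "subgroup" not in sheet.columns:
        sheet["subgroup"] = ""
    bad = sheet.loc[~sheet["group"].isin(SAMPLE_GROUPS)]
    if not bad.empty:
        raise ValidationError(
            f"{path.name}: invalid group value(s) "
            f"{sorted(bad['group'].unique())}; allowed: {list(SAMPLE_GROUPS)}"
        )
    if sheet["sample"].duplicated().any():
        dups = sorted(sheet.loc[sheet["sample"].duplicated(), "sample"])
        raise ValidationError(f"{path.name}: duplicate sample id(s) {dups[:5]}")
    return sheet[["sample", "layer", "group", "subgroup"]].set_index("sample")


def assemble_dataset(matrices: Mapping[str, ExpressionLayer] | Iterable[ExpressionLayer],
                     sheet: pd.DataFrame,
                     roles: Mapping[str, str] | None = None,
                     ) -> MultiLayerDataset:
    """Join parsed matrices with the sample sheet into a MultiLayerDataset.

    Keeps exactly the intersection of sheet samples and matrix columns;
    discarded samples (present on one side only) are logged. Layers named in
    the sheet but missing a matrix raise an error.
    """
    if not isinstance(matrices, Mapping):
        matrices = {l.layer_id: l for l in matrices}
    unknown = sorted(set(sheet["layer"]) - set(matrices))
    if unknown:
        raise ValidationError(
            f"sample sheet references unknown layer(s): {unknown}"
        )
    layers = []
    for layer_id, layer in matrices.items():
        rows = sheet.loc[sheet["layer"] == layer_id]
        keep = [s for s in layer.samples if s in rows.index]
        dropped_cols = sorted(set(layer.samples) - set(keep))
        dropped_sheet = sorted(set(rows.index) - set(keep))
        if dropped_cols:
            logger.info("layer %s: %d matrix column(s) not in sheet dropped: %s",
                        layer_id, len(dropped_cols), dropped_cols[:5])
        if dropped_sheet:
            logger.info("layer %s: %d sheet sample(s) not in matrix ignored: %s",
                        layer_id, len(dropped_sheet), dropped_sheet[:5])
        sub = rows.loc[keep, "subgroup"]
        layers.append(ExpressionLayer(
            layer_id=layer_id,
            role_tag=(roles or {}).get(layer_id, layer.role_tag),
            values=layer.values[keep],
            sample_group=rows.loc[keep, "group"].to_dict(),
            sample_subgroup=sub[sub != ""].to_dict() or None,
        ))
    ds = MultiLayerDataset(layers=layers)
    n_union = len(set().union(*(l.genes for l in layers)))
    if n_union > len(ds.shared_genes):
        logger.info("restricted to %d shared genes (%d dropped)",
                    len(ds.shared_genes), n_union - len(ds.shared_genes))
    return ds.restricted()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    tags: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name} line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path.name} line {lineno}: set {name!r} "
                                 "has no genes")
            sets[name] = genes
            tags[name] = desc
    return GeneSetCollection(sets=sets, source_tag=tags)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            tag = collection.source_tag.get(name, "")
            fh.write("\t".join([name, tag, *genes]) + "\n")


def read_pathway_graph(edges_path: str | Path,
                       node_fc_path: str | Path | None = None) -> PathwayGraph:
    """Parse a signed edge list (source, sign, sink) and an optional two-column
    node fold-change table (node, linear fc). Nodes without a fold change
    default to 1.0 with a logged warning."""
    edges_path = Path(edges_path)
    g = nx.DiGraph()
    with open(edges_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1 and len(line.split()) == 3:
                fields = line.split()
            if len(fields) == 2:
                # isolated node declaration: "node<TAB>."
                g.add_node(fields[0])
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"{edges_path.name} line {lineno}: expected "
                    "'source<TAB>sign<TAB>sink'"
                )
            src, sign, dst = fields
            if sign not in EDGE_SIGNS:
                raise ParseError(
                    f"{edges_path.name} line {lineno}: unknown sign {sign!r}; "
                    f"allowed: {list(EDGE_SIGNS)}"
                )
            g.add_edge(src, dst, sign=sign)
    fc: dict[str, float] = {}
    if node_fc_path is not None:
        tbl = pd.read_csv(node_fc_path, sep="\t", header=None,
                          names=["node", "fc"], dtype={"node": str})
        for node, value in zip(tbl["node"], tbl["fc"]):
            value = float(value)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"node {node!r}: fold change must be positive, got {value}"
                )
            fc[node] = value
            if node not in g:
                g.add_node(node)
    missing = [n for n in g.nodes if n not in fc]
    if node_fc_path is not None and missing:
        logger.warning("%d node(s) without fold change default to 1.0: %s",
                       len(missing), sorted(missing)[:5])
    nx.set_node_attributes(g, {n: fc.get(n, 1.0) for n in g.nodes}, "fc")
    return PathwayGraph(graph=g)


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration (see pipeline.run for the schema)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{Path(path).name}: config must be a YAML mapping")
    return cfg


def pipeline_config_from_dict(d: Mapping) -> PipelineConfig:
    """Build a PipelineConfig from the ``analysis:`` section of a run config."""
    allowed = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown analysis option(s): {sorted(unknown)}")
    kwargs = dict(d)
    if isinstance(kwargs.get("grid_size"), list):
        kwargs["grid_size"] = tuple(kwargs["grid_size"])
    return PipelineConfig(**kwargs)
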