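"""Synthetic multi-layer case/control expression data with planted modules.

The generator emulates the study design the pipeline expects: several
RMA-like log2 expression datasets (disease vs healthy, drug vs baseline),
each with a planted set of co-regulated gene modules. A module's genes share
a latent factor (loading 0.8) so they genuinely co-cluster on the SOM —
differential means alone would not make them a spot — plus a per-layer
directional mean shift: "up" adds the module's effect to the layer's target
samples, "down" to its reference samples (a treatment layer's diseased
baseline is elevated and treatment returns it toward normal). Per-gene
baselines are drawn once from Normal(7, 1.5) on the log2 scale, mimicking
RMA-normalized intensity ranges.

The factor model is standardized so the stated noise level is the *total*
per-gene noise SD: for a module gene the residual is
``noise_sd * (loading * f_s + sqrt(1 - loading^2) * eps)`` with ``f_s`` the
module's shared per-sample factor, giving within-module residual correlation
``loading**2`` (0.64 by default) without inflating the marginal noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionLayer,
    MultiLayerDataset,
    ValidationError,
)

BASELINE_MEAN = 7.0
BASELINE_SD = 1.5
LATENT_LOADING = 0.8


@dataclass
class PlantedModule:
    """One co-regulated gene module and its per-layer regulation."""

    genes: list[str]
    direction: dict[str, str]  # layer_id -> up / down / none
    effect: float = 1.0  # log2 mean shift

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValidationError("effect size must be >= 0")
        bad = {k: v for k, v in self.direction.items()
               if v not in ("up", "down", "none")}
        if bad:
            raise ValidationError(f"invalid direction(s): {bad}")


@dataclass
class LayerSpec:
    """Shape of one synthetic layer: its role and group sizes/subgroups."""

    layer_id: str
    role_tag: str = "target_disease"
    n_target: int = 10
    n_reference: int = 10
    target_subgroup: str | None = None
    reference_subgroup: str | None = None


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic study."""

    modules: list[PlantedModule]
    noise_sd: float = 0.5
    n_genes: int = 2000

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            overlap = seen & set(m.genes)
            if overlap:
                raise ValidationError(
                    f"module gene lists overlap: {sorted(overlap)[:5]}")
            seen |= set(m.genes)

    def to_json(self) -> str:
        return json.dumps({
            "n_genes": self.n_genes,
            "noise_sd": self.noise_sd,
            "modules": [
                {"genes": m.genes, "direction": m.direction, "effect": m.effect}
                for m in self.modules
            ],
        }, indent=2)


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate(truth: SyntheticTruth, layout: list[LayerSpec],
             seed: int) -> MultiLayerDataset:
    """Draw a multi-layer dataset under the given truth; deterministic in
    ``seed``. Needs >=2 layers, each with target and reference samples."""
    if len(layout) < 2:
        raise ValidationError("layout must name >= 2 layers")
    rng = np.random.default_rng(seed)
    genes = gene_names(truth.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=truth.n_genes)

    layers = []
    for spec in layout:
        t_names = [f"{spec.layer_id}_t{i:02d}" for i in range(spec.n_target)]
        r_names = [f"{spec.layer_id}_r{i:02d}" for i in range(spec.n_reference)]
        samples = t_names + r_names
        n = len(samples)
        X = baseline[:, None] + rng.normal(0.0, truth.noise_sd,
                                           size=(truth.n_genes, n))
        resid_scale = np.sqrt(1.0 - LATENT_LOADING ** 2)
        for module in truth.modules:
            idx = [gene_pos[g] for g in module.genes if g in gene_pos]
            if not idx:
                continue
            factor = rng.normal(0.0, 1.0, size=n)
            if truth.noise_sd > 0:  # noiseless mode is fully deterministic
                # replace the independent residual by a correlated one of the
                # same marginal SD (shared factor + shrunk residual)
                X[idx, :] = (baseline[idx, None]
                             + truth.noise_sd * (
                                 LATENT_LOADING * factor[None, :]
                                 + resid_scale * rng.standard_normal(
                                     (len(idx), n))))
            direction = module.direction.get(spec.layer_id, "none")
            if direction == "up":
                X[np.ix_(idx, range(len(t_names)))] += module.effect
            elif direction == "down":
                X[np.ix_(idx, range(len(t_names), n))] += module.effect
        group = {s: "target" for s in t_names}
        group.update({s: "reference" for s in r_names})
        subgroup = {}
        if spec.target_subgroup:
            subgroup.update({s: spec.target_subgroup for s in t_names})
        if spec.reference_subgroup:
            subgroup.update({s: spec.reference_subgroup for s in r_names})
        layers.append(ExpressionLayer(
            layer_id=spec.layer_id, role_tag=spec.role_tag,
            values=pd.DataFrame(X, index=genes, columns=samples),
            sample_group=group, sample_subgroup=subgroup or None))
    return MultiLayerDataset(layers=layers)


def repositioning_scenario(seed: int, n_genes: int = 2000,
                           module_size: int = 100, effect: float = 1.0,
                           noise_sd: float = 0.5, n_per_group: int = 10,
                           ) -> tuple[MultiLayerDataset, SyntheticTruth]:
    """The canonical end-to-end fixture: one drug layer whose treatment
    reverses a module that is up in two disease layers and untouched in a
    third (the null disease). The expected verdicts are candidate, candidate,
    not_supported."""
    genes = gene_names(n_genes)
    module = PlantedModule(
        genes=genes[:module_size],
        direction={"drug": "down", "dis1": "up", "dis2": "up", "dis3": "none"},
        effect=effect,
    )
    truth = SyntheticTruth(modules=[module], noise_sd=noise_sd,
                           n_genes=n_genes)
    layout = [
        LayerSpec("drug", "treatment", n_per_group, n_per_group,
                  target_subgroup="treated", reference_subgroup="baseline"),
        LayerSpec("dis1", "target_disease", n_per_group, n_per_group),
        LayerSpec("dis2", "repositioning_disease", n_per_group, n_per_group),
        LayerSpec("dis3", "repositioning_disease", n_per_group, n_per_group),
    ]
    return generate(truth, layout, seed), truth


def write_study(dataset: MultiLayerDataset, truth: SyntheticTruth,
                outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic study as standard pipeline inputs: one expression
    TSV per layer, a sample sheet, and the truth as JSON."""
    from .io import write_expression_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    sheet_rows = []
    for layer in dataset.layers:
        p = outdir / f"{layer.layer_id}.tsv"
        write_expression_matrix(layer, p)
        paths[layer.layer_id] = p
        sub = layer.sample_subgroup or {}
        for s in layer.samples:
            sheet_rows.append((s, layer.layer_id, layer.sample_group[s],
                               sub.get(s, "")))
    sheet = pd.DataFrame(sheet_rows,
                         columns=["sample", "layer", "group", "subgroup"])
    sheet_path = outdir / "samples.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    paths["sample_sheet"] = sheet_path
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    config_path = outdir / "config.yaml"
    lines = ["sample_sheet: samples.tsv", "layers:"]
    lines += [f"  - {{id: {l.layer_id}, role: {l.role_tag}, "
              f"expression: {l.layer_id}.tsv}}" for l in dataset.layers]
    lines += ["analysis: {grid_size: 20, random_seed: 0}", ""]
    config_path.write_text("\n".join(lines))
    paths["config"] = config_path
    return paths
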