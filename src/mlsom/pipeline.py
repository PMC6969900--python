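"""Workflow orchestration: config -> preprocessing -> SOM -> spots -> calls
-> enrichment / GSZ / PSF -> repositioning verdicts, with a run manifest.

Every stage is also usable on its own (and exposed as a CLI subcommand);
``run`` simply chains them. All intermediate artifacts are plain text, so a
run with identical config, inputs and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .datamodel import (
    Contrast,
    JointMatrix,
    MultiLayerDataset,
    PerturbationMatrix,
    PipelineConfig,
    RepositioningVerdict,
    Spot,
    ValidationError,
)
from .enrichment import annotate_spots, gsz_table
from .preprocess import build_joint_matrix
from .psf import propagate
from .som import SOMModel, group_portraits, support_maps, train_som
from .spots import (
    build_perturbation_matrix,
    enumerate_contrasts,
    overexpression_mask,
    repositioning_call,
    summary_map_and_segment,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything the pipeline computes for one study."""

    joint: JointMatrix
    model: SOMModel
    portraits: dict
    summary_mask: np.ndarray
    spots: list[Spot]
    contrasts: list[Contrast]
    perturbation: PerturbationMatrix
    verdicts: list[RepositioningVerdict] = field(default_factory=list)
    enrichment: pd.DataFrame | None = None
    gsz: pd.DataFrame | None = None


def analyze(dataset: MultiLayerDataset, config: PipelineConfig,
            contrasts: list[Contrast] | None = None,
            gene_sets=None,
            repositioning: list[tuple[str, str]] | None = None,
            ) -> StudyResult:
    """Run the analysis chain on an in-memory dataset.

    ``repositioning`` lists (drug_contrast, disease_contrast) name pairs; by
    default the first treatment-layer contrast is paired with every disease
    contrast.
    """
    joint = build_joint_matrix(dataset)
    model = train_som(joint, config)
    portraits = group_portraits(model, joint.samples)
    summary_mask, spots = summary_map_and_segment(portraits, model, config, joint)
    if contrasts is None:
        contrasts = enumerate_contrasts(joint.samples)
    pm = build_perturbation_matrix(spots, model, joint, contrasts, config)

    if repositioning is None:
        roles = joint.samples[["layer", "role"]].drop_duplicates().set_index("layer")
        drug_names = [c.name for c in contrasts
                      if roles.loc[c.layer_id, "role"] == "treatment"]
        disease_names = [c.name for c in contrasts
                         if roles.loc[c.layer_id, "role"] != "treatment"]
        repositioning = [(d, s) for d in drug_names[:1] for s in disease_names]
    verdicts = [repositioning_call(pm, drug, disease)
                for drug, disease in repositioning]

    enrich = None
    gsz = None
    if gene_sets is not None and spots:
        enrich = annotate_spots(spots, gene_sets, joint.genes)
        gsz = gsz_table(joint, gene_sets)
    return StudyResult(joint=joint, model=model, portraits=portraits,
                       summary_mask=summary_mask, spots=spots,
                       contrasts=contrasts, perturbation=pm,
                       verdicts=verdicts, enrichment=enrich, gsz=gsz)


# ---------------------------------------------------------------------------
# file-level stages (shared by the CLI subcommands and `run`)

def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_dataset(cfg: dict, base: Path) -> MultiLayerDataset:
    """Read layers + sample sheet named in a run config."""
    if "layers" not in cfg or "sample_sheet" not in cfg:
        raise ValidationError("config must name 'layers' and 'sample_sheet'")
    sheet = mio.read_sample_sheet(base / cfg["sample_sheet"])
    matrices = {}
    roles = {}
    for entry in cfg["layers"]:
        lid = entry["id"]
        role = entry.get("role", "target_disease")
        layer = mio.read_expression_matrix(base / entry["expression"], lid, role)
        matrices[lid] = layer
        roles[lid] = role
    return mio.assemble_dataset(matrices, sheet, roles=roles)


def contrasts_from_config(cfg: dict, dataset: MultiLayerDataset
                          ) -> list[Contrast] | None:
    """Explicit contrasts from config, or None to enumerate defaults.

    Each entry selects target/reference samples by group and optional
    subgroup within one layer::

        contrasts:
          - name: drug_response
            layer: drug
            target:    {group: target, subgroup: responder}
            reference: {group: reference, subgroup: baseline}
    """
    if "contrasts" not in cfg:
        return None
    out = []
    for entry in cfg["contrasts"]:
        layer = dataset.layer(entry["layer"])

        def pick(sel: dict) -> list[str]:
            return layer.group_samples(sel["group"], sel.get("subgroup"))

        out.append(Contrast(entry["name"], entry["layer"],
                            pick(entry["target"]), pick(entry["reference"])))
    return out


def write_joint(joint: JointMatrix, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    df = joint.values.copy()
    df.index.name = "gene"
    df.to_csv(outdir / "joint_matrix.tsv", sep="\t")
    joint.samples.to_csv(outdir / "joint_samples.tsv", sep="\t")


def read_joint(outdir: Path) -> JointMatrix:
    values = pd.read_csv(outdir / "joint_matrix.tsv", sep="\t", index_col=0,
                         float_precision="round_trip")
    samples = pd.read_csv(outdir / "joint_samples.tsv", sep="\t", index_col=0,
                          keep_default_na=False, dtype=str)
    return JointMatrix(values=values, samples=samples)


def write_model(model: SOMModel, outdir: Path) -> None:
    mdir = Path(outdir) / "model"
    mdir.mkdir(parents=True, exist_ok=True)
    proto = pd.DataFrame(model.prototypes, columns=model.samples)
    proto.index.name = "unit"
    proto.to_csv(mdir / "prototypes.tsv", sep="\t")
    rows, cols = np.divmod(model.assignment.to_numpy(), model.grid_shape[1])
    pd.DataFrame({"gene": model.assignment.index, "row": rows, "col": cols}
                 ).to_csv(mdir / "assignment.tsv", sep="\t", index=False)
    model.training_log.to_csv(mdir / "training_log.tsv", sep="\t", index=False)
    (mdir / "grid.json").write_text(json.dumps(
        {"rows": model.grid_shape[0], "cols": model.grid_shape[1]}))


def read_model(outdir: Path) -> SOMModel:
    mdir = Path(outdir) / "model"
    grid = json.loads((mdir / "grid.json").read_text())
    shape = (grid["rows"], grid["cols"])
    proto = pd.read_csv(mdir / "prototypes.tsv", sep="\t", index_col=0,
                        float_precision="round_trip")
    asg = pd.read_csv(mdir / "assignment.tsv", sep="\t", index_col=0)
    log = pd.read_csv(mdir / "training_log.tsv", sep="\t")
    assignment = pd.Series(
        (asg["row"] * shape[1] + asg["col"]).to_numpy(), index=asg.index,
        name="unit")
    return SOMModel(grid_shape=shape, prototypes=proto.to_numpy(),
                    samples=list(proto.columns), assignment=assignment,
                    training_log=log)


def write_spots(summary_mask: np.ndarray, spots: list[Spot],
                outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "summary_mask.tsv", summary_mask.astype(int),
               fmt="%d", delimiter="\t")
    rows = [
        {"spot": s.label, "n_units": s.n_units, "n_genes": s.n_genes,
         "units": ";".join(f"{r},{c}" for r, c in s.units),
         "genes": ";".join(s.genes)}
        for s in spots
    ]
    pd.DataFrame(rows, columns=["spot", "n_units", "n_genes", "units",
                                "genes"]).to_csv(
        outdir / "spots.tsv", sep="\t", index=False)
    profiles = pd.DataFrame({s.label: s.profile for s in spots}).T
    profiles.index.name = "spot"
    profiles.to_csv(outdir / "spot_profiles.tsv", sep="\t")


def read_spots(outdir: Path) -> tuple[np.ndarray, list[Spot]]:
    mask = np.loadtxt(outdir / "summary_mask.tsv", dtype=int,
                      delimiter="\t", ndmin=2).astype(bool)
    tbl = pd.read_csv(outdir / "spots.tsv", sep="\t", dtype={"spot": str},
                      keep_default_na=False)
    profiles = pd.read_csv(outdir / "spot_profiles.tsv", sep="\t", index_col=0,
                           float_precision="round_trip")
    spots = []
    for _, row in tbl.iterrows():
        units = [tuple(map(int, u.split(","))) for u in
                 str(row["units"]).split(";") if u]
        genes = [g for g in str(row["genes"]).split(";") if g]
        spots.append(Spot(label=row["spot"], units=units, genes=genes,
                          profile=profiles.loc[row["spot"]]))
    return mask, spots


def write_calls(pm: PerturbationMatrix, verdicts: list[RepositioningVerdict],
                outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pm.to_frame().to_csv(outdir / "perturbation.tsv", sep="\t", index=False)
    payload = [dataclasses.asdict(v) for v in verdicts]
    (outdir / "verdicts.json").write_text(json.dumps(payload, indent=2))
    lines = []
    for v in verdicts:
        lines.append(f"{v.drug_contrast} vs {v.disease_contrast}: {v.verdict}")
        for spot, d_dir, t_dir in v.antagonistic_spots:
            lines.append(f"  antagonistic spot {spot}: disease {d_dir}, "
                         f"drug {t_dir}")
        if v.unopposed_disease_spots:
            lines.append("  unopposed disease spots: "
                         + ", ".join(v.unopposed_disease_spots))
    (outdir / "verdicts.txt").write_text("\n".join(lines) + "\n" if lines else "")


def run(config_path: str | Path, outdir: str | Path,
        seed: int | None = None, overrides: dict | None = None,
        make_plots: bool = True) -> StudyResult:
    """Execute the full workflow from a YAML config; writes all artifacts
    plus a run manifest (written on both success and handled failure)."""
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = mio.read_config(config_path)
    base = config_path.parent
    analysis = dict(cfg.get("analysis", {}))
    analysis.update(overrides or {})
    if seed is not None:
        analysis["random_seed"] = seed
    config = mio.pipeline_config_from_dict(analysis)

    manifest: dict = {
        "config_file": str(config_path),
        "config": {**cfg, "analysis": analysis},
        "seed": config.random_seed,
        "stages": {},
        "status": "running",
    }

    def finish(status: str, failed_stage: str | None = None) -> None:
        manifest["status"] = status
        if failed_stage:
            manifest["failed_stage"] = failed_stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "io"
    try:
        t0 = time.perf_counter()
        dataset = load_dataset(cfg, base)
        manifest["inputs"] = {
            entry["id"]: _checksum(base / entry["expression"])
            for entry in cfg["layers"]
        }
        manifest["inputs"]["sample_sheet"] = _checksum(base / cfg["sample_sheet"])
        manifest["stages"]["io"] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        joint = build_joint_matrix(dataset)
        write_joint(joint, outdir)
        manifest["stages"]["preprocess"] = time.perf_counter() - t0

        stage = "som"
        t0 = time.perf_counter()
        model = train_som(joint, config)
        write_model(model, outdir)
        manifest["stages"]["som"] = time.perf_counter() - t0

        stage = "spots"
        t0 = time.perf_counter()
        portraits = group_portraits(model, joint.samples)
        summary_mask, spot_list = summary_map_and_segment(portraits, model,
                                                          config, joint)
        write_spots(summary_mask, spot_list, outdir)
        masks = [overexpression_mask(p, config.overexpression_quantile)
                 for p in portraits.values()]
        maps = support_maps(model, masks)
        np.savetxt(outdir / "population_map.tsv", maps.population, fmt="%d",
                   delimiter="\t")
        manifest["stages"]["spots"] = time.perf_counter() - t0

        stage = "calls"
        t0 = time.perf_counter()
        contrasts = contrasts_from_config(cfg, dataset)
        if contrasts is None:
            contrasts = enumerate_contrasts(joint.samples)
        pm = build_perturbation_matrix(spot_list, model, joint, contrasts,
                                       config)
        repositioning = None
        if "repositioning" in cfg:
            rp = cfg["repositioning"]
            repositioning = [(rp["drug_contrast"], d)
                             for d in rp["disease_contrasts"]]
        result = StudyResult(joint=joint, model=model, portraits=portraits,
                             summary_mask=summary_mask, spots=spot_list,
                             contrasts=contrasts, perturbation=pm)
        if repositioning is None:
            roles = joint.samples[["layer", "role"]].drop_duplicates(
            ).set_index("layer")
            drug_names = [c.name for c in contrasts
                          if roles.loc[c.layer_id, "role"] == "treatment"]
            disease_names = [c.name for c in contrasts
                             if roles.loc[c.layer_id, "role"] != "treatment"]
            repositioning = [(d, s) for d in drug_names[:1]
                             for s in disease_names]
        result.verdicts = [repositioning_call(pm, drug, disease)
                           for drug, disease in repositioning]
        write_calls(pm, result.verdicts, outdir)
        manifest["stages"]["calls"] = time.perf_counter() - t0

        if "gene_sets" in cfg:
            stage = "enrichment"
            t0 = time.perf_counter()
            sets = mio.read_gmt(base / cfg["gene_sets"])
            if spot_list:
                result.enrichment = annotate_spots(spot_list, sets,
                                                   joint.genes)
                result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t",
                                         index=False)
            result.gsz = gsz_table(joint, sets)
            result.gsz.to_csv(outdir / "gsz.tsv", sep="\t")
            manifest["stages"]["enrichment"] = time.perf_counter() - t0

        if "pathway" in cfg:
            stage = "psf"
            t0 = time.perf_counter()
            pw = cfg["pathway"]
            graph = mio.read_pathway_graph(
                base / pw["edges"],
                base / pw["node_fc"] if "node_fc" in pw else None)
            psf_result = propagate(graph)
            pd.Series(psf_result.node_signal, name="signal").rename_axis(
                "node").to_csv(outdir / "psf_nodes.tsv", sep="\t")
            pd.Series(psf_result.sink_values, name="signal").rename_axis(
                "sink").to_csv(outdir / "psf_sinks.tsv", sep="\t")
            manifest["stages"]["psf"] = time.perf_counter() - t0

        if make_plots:
            stage = "plots"
            from .plotting import (plot_perturbation_heatmap, plot_portrait,
                                   plot_summary_map)
            pdir = outdir / "portraits"
            pdir.mkdir(exist_ok=True)
            for key, portrait in portraits.items():
                name = "_".join(str(k) for k in key if k != "")
                plot_portrait(portrait, pdir / f"{name}.png", title=name)
            plot_summary_map(summary_mask, spot_list,
                             outdir / "summary_map.png")
            if spot_list:
                plot_perturbation_heatmap(pm, outdir / "perturbation.png")
    except Exception:
        finish("failed", stage)
        raise
    finish("ok")
    return result
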