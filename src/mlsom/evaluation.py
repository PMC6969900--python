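"""Self-evaluation studies on synthetic data.

These routines quantify the pipeline's operating characteristics under the
generator's standard study conditions: false-positive calibration of the
spot callers on null data, recovery of a planted module in a single layer,
and the full end-to-end repositioning pattern (a drug reversing a module
shared by two diseases and absent in a third). They are used by the test
suite and the reproduction script; all randomness is derived from explicit
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import PipelineConfig, Spot
from .pipeline import analyze
from .preprocess import build_joint_matrix
from .simulate import (
    LayerSpec,
    PlantedModule,
    SyntheticTruth,
    gene_names,
    generate,
    repositioning_scenario,
)
from .som import SOMModel
from .spots import joint_vote, presence_absence_call, ttest_call


@dataclass
class CalibrationResult:
    n_contrasts: int
    t_fired: int
    pa_fired: int
    joint_fired: int

    @property
    def t_rate(self) -> float:
        return self.t_fired / self.n_contrasts


def null_calling_calibration(n_contrasts: int = 500, seed: int = 0,
                             n_per_group: int = 10, module_size: int = 20,
                             n_genes: int = 200, noise_sd: float = 0.5,
                             ) -> CalibrationResult:
    """Fire rates of the spot callers on null contrasts (no planted effect).

    Each replicate draws a fresh two-layer null dataset, treats the
    (latent-factor-correlated but mean-null) module as the spot, and applies
    the t-test caller with the fold-change gate disabled, the
    presence/absence caller, and their conservative AND combination. Each
    layer contributes one contrast, so all contrasts carry independent noise.
    """
    genes = gene_names(n_genes)
    module = genes[:module_size]
    t_fired = pa_fired = joint_fired = done = 0
    rep = 0
    while done < n_contrasts:
        truth = SyntheticTruth(
            modules=[PlantedModule(genes=module, direction={}, effect=0.0)],
            noise_sd=noise_sd, n_genes=n_genes)
        layout = [LayerSpec("A", "target_disease", n_per_group, n_per_group),
                  LayerSpec("B", "target_disease", n_per_group, n_per_group)]
        dataset = generate(truth, layout, seed=seed + rep)
        joint = build_joint_matrix(dataset)
        rep += 1
        for lid in ("A", "B"):
            layer_samples = joint.layer_samples(lid)
            meta = joint.samples.loc[layer_samples]
            groups = (list(meta.index[meta["group"] == "target"]),
                      list(meta.index[meta["group"] == "reference"]))
            profile = pd.Series(
                joint.values.loc[module, layer_samples].mean(axis=0),
                index=layer_samples)
            spot = Spot(label="S", units=[(i, 0) for i in range(module_size)],
                        genes=module, profile=profile)
            # metagene-entry surrogate: one unit per module gene
            model = SOMModel(
                grid_shape=(module_size, 1),
                prototypes=joint.values.loc[module, layer_samples].to_numpy(),
                samples=layer_samples,
                assignment=pd.Series(range(module_size), index=module),
                training_log=pd.DataFrame())
            if done >= n_contrasts:
                break
            target, reference = groups
            t, _, _ = ttest_call(spot, target, reference,
                                 alpha=0.05, fc_threshold=None)
            pa = presence_absence_call(spot, model, layer_samples,
                                       target, reference, 1.0)
            joint_dir = joint_vote(pa, t, "both")
            t_fired += t != "none"
            pa_fired += pa != "none"
            joint_fired += joint_dir != "none"
            done += 1
    return CalibrationResult(n_contrasts=done, t_fired=t_fired,
                             pa_fired=pa_fired, joint_fired=joint_fired)


def planted_module_recovery(n_seeds: int = 100, seed0: int = 0,
                            n_genes: int = 2000, module_size: int = 100,
                            effect: float = 1.0, noise_sd: float = 0.5,
                            n_per_group: int = 10, grid: int = 20,
                            containment: float = 0.9) -> dict:
    """Fraction of replicates in which the planted module lands in one
    connected spot (>= ``containment`` of its genes) and that spot is called
    in the planted direction by the default joint vote."""
    genes = gene_names(n_genes)
    module = set(genes[:module_size])
    n_spot_ok = n_dir_ok = n_both = 0
    for i in range(n_seeds):
        truth = SyntheticTruth(
            modules=[PlantedModule(genes=list(genes[:module_size]),
                                   direction={"L": "up", "M": "none"},
                                   effect=effect)],
            noise_sd=noise_sd, n_genes=n_genes)
        layout = [LayerSpec("L", "target_disease", n_per_group, n_per_group),
                  LayerSpec("M", "repositioning_disease", n_per_group,
                            n_per_group)]
        dataset = generate(truth, layout, seed=seed0 + i)
        config = PipelineConfig(grid_size=grid, random_seed=seed0 + i)
        result = analyze(dataset, config)
        best = max(result.spots,
                   key=lambda s: len(module & set(s.genes)), default=None)
        spot_ok = (best is not None
                   and len(module & set(best.genes)) >= containment
                   * module_size)
        dir_ok = False
        if best is not None:
            call = result.perturbation.call(best.label,
                                            "L:target_vs_reference")
            dir_ok = call.direction == "up"
        n_spot_ok += spot_ok
        n_dir_ok += dir_ok
        n_both += spot_ok and dir_ok
    return {"n_seeds": n_seeds, "spot_ok": n_spot_ok, "direction_ok": n_dir_ok,
            "both_ok": n_both}


def repositioning_pattern_rate(n_seeds: int = 100, seed0: int = 0,
                               **scenario_kwargs) -> dict:
    """Fraction of replicates reproducing the qualitative verdict pattern
    (candidate, candidate, not_supported) for a drug that reverses a module
    shared by two disease layers and absent in a third."""
    grid = scenario_kwargs.pop("grid", 20)
    n_ok = 0
    for i in range(n_seeds):
        dataset, _ = repositioning_scenario(seed=seed0 + i, **scenario_kwargs)
        config = PipelineConfig(grid_size=grid, random_seed=seed0 + i)
        result = analyze(dataset, config)
        verdicts = {v.disease_contrast.split(":")[0]: v.verdict
                    for v in result.verdicts}
        n_ok += (verdicts.get("dis1") == "candidate"
                 and verdicts.get("dis2") == "candidate"
                 and verdicts.get("dis3") == "not_supported")
    return {"n_seeds": n_seeds, "pattern_ok": n_ok}
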