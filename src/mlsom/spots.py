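"""Overexpression spot segmentation and differential spot calling.

A spot is a connected cluster of metagenes that exceeds the overexpression
threshold (by default the 95th percentile of the portrait's own values) in at
least one group portrait. Spots are the unit of differential analysis: per
layer and contrast each spot receives a presence/absence vote (+/-1 SD of
spot-metagene expression) and a t-test vote (p < alpha and linear fold change
> threshold), combined into a joint direction. A drug is a repositioning
candidate for a disease when at least one spot is regulated antagonistically
between the disease and the treatment contrast.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .datamodel import (
    Contrast,
    JointMatrix,
    PerturbationMatrix,
    PipelineConfig,
    RepositioningVerdict,
    Spot,
    SpotCall,
    ValidationError,
    spot_labels,
)
from .som import SOMModel, group_portraits

logger = logging.getLogger(__name__)

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def overexpression_mask(portrait: np.ndarray, quantile: float = 0.95
                        ) -> np.ndarray:
    """Units whose value strictly exceeds the given quantile (linear
    interpolation between order statistics) of the portrait's own values."""
    if not 0.0 < quantile < 1.0:
        raise ValidationError("quantile must be in (0, 1)")
    threshold = float(np.quantile(portrait, quantile))
    return portrait > threshold


def underexpression_mask(portrait: np.ndarray, quantile: float = 0.05
                         ) -> np.ndarray:
    """Mirror criterion: units strictly below the given low quantile."""
    if not 0.0 < quantile < 1.0:
        raise ValidationError("quantile must be in (0, 1)")
    threshold = float(np.quantile(portrait, quantile))
    return portrait < threshold


def segment_mask(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected components of a boolean grid (0 = background);
    component ids are re-ordered row-major by component centroid."""
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return labeled
    centroids = ndimage.center_of_mass(mask, labeled, range(1, n + 1))
    order = sorted(range(n), key=lambda i: centroids[i])
    relabel = np.zeros(n + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        relabel[old + 1] = new
    return relabel[labeled]


def spot_profile(genes: list[str], unit_idx: list[int], model: SOMModel,
                 joint: JointMatrix | None, source: str) -> np.ndarray:
    """Per-sample spot expression: mean delta-e of the member genes (default)
    or mean of the spot units' prototype entries.

    Gene-based profiles weight each metagene by the genes it actually holds
    and ignore empty units, so a spot's fold change is not shrunk toward zero
    by sparsely populated border units.
    """
    if source == "genes" and genes:
        if joint is None:
            raise ValidationError("gene-based profiles need the joint matrix")
        return joint.values.loc[genes].to_numpy().mean(axis=0)
    if source not in ("genes", "prototypes"):
        raise ValidationError(f"unknown profile source {source!r}")
    # prototype fallback also covers spots made entirely of empty units
    return model.prototypes[unit_idx].mean(axis=0)


def summary_map_and_segment(portraits: dict, model: SOMModel,
                            config: PipelineConfig,
                            joint: JointMatrix | None = None,
                            ) -> tuple[np.ndarray, list[Spot]]:
    """Union all group overexpression masks into the summary map and segment
    it into labeled spots with member genes and per-sample profiles.

    ``portraits`` maps group keys to K x K portraits (see
    :func:`mlsom.som.group_portraits`). Returns (summary mask, spots); an
    empty union yields zero spots.
    """
    masks = [overexpression_mask(p, config.overexpression_quantile)
             for p in portraits.values()]
    if config.underexpression:
        # low-tail mirror: units strictly below the (1-q) quantile
        masks += [underexpression_mask(p, 1.0 - config.overexpression_quantile)
                  for p in portraits.values()]
    if not masks:
        raise ValidationError("no group portraits supplied")
    union = np.logical_or.reduce(masks)
    labeled = segment_mask(union, config.connectivity)
    n = labeled.max()
    if n == 0:
        logger.info("no unit exceeds the overexpression threshold; 0 spots")
        return union, []
    labels = spot_labels(n)
    assignment = model.assignment.to_numpy()
    spots = []
    for i, label in enumerate(labels, start=1):
        units = [tuple(uc) for uc in np.argwhere(labeled == i)]
        unit_idx = [model.unit_index(r, c) for r, c in units]
        genes = sorted(
            g for u in unit_idx
            for g in model.assignment.index[assignment == u]
        )
        values = spot_profile(genes, unit_idx, model, joint,
                              config.profile_source)
        profile = pd.Series(values, index=model.samples, name=label)
        spots.append(Spot(label=label, units=units, genes=genes,
                          profile=profile))
    return union, spots


def spot_prototype_block(spot: Spot, model: SOMModel,
                         sample_ids: list[str]) -> np.ndarray:
    """Spot-units x samples block of prototype entries."""
    unit_idx = [model.unit_index(r, c) for r, c in spot.units]
    col_idx = [model.sample_index(s) for s in sample_ids]
    return model.prototypes[np.ix_(unit_idx, col_idx)]


def presence_absence_call(spot: Spot, model: SOMModel,
                          layer_samples: list[str],
                          target: list[str], reference: list[str],
                          sd_multiplier: float = 1.0) -> str:
    """Presence/absence vote for one spot in one contrast.

    The criterion evaluates the difference in spot presence between the
    target and reference states: with sigma the SD of all spot-unit
    prototype entries across the layer's samples, the vote is up when
    (target mean - reference mean) spot expression exceeds
    +sd_multiplier*sigma, down below -sd_multiplier*sigma, else none.
    """
    block = spot_prototype_block(spot, model, layer_samples)
    sigma = float(block.std(ddof=1)) if block.size > 1 else 0.0
    if sigma == 0.0 or not np.isfinite(sigma):
        logger.warning("spot %s: zero spot-metagene SD in layer; vote none",
                       spot.label)
        return "none"
    threshold = sd_multiplier * sigma
    delta = float(spot.profile[target].mean() - spot.profile[reference].mean())
    if delta > threshold:
        return "up"
    if delta < -threshold:
        return "down"
    return "none"


def ttest_call(spot: Spot, target: list[str], reference: list[str],
               alpha: float = 0.05, fc_threshold: float | None = 1.5,
               welch: bool = True) -> tuple[str, float, float]:
    """t-test vote on per-sample spot means.

    Returns (vote, p_value, linear_fc) with linear_fc = 2^(mean_t - mean_r);
    the fold-change gate is two-sided (> fc or < 1/fc) and disabled when
    ``fc_threshold`` is None. Fewer than 2 samples per side yields vote none.
    """
    t_vals = spot.profile[target].to_numpy(dtype=float)
    r_vals = spot.profile[reference].to_numpy(dtype=float)
    linear_fc = float(2.0 ** (t_vals.mean() - r_vals.mean()))
    if len(t_vals) < 2 or len(r_vals) < 2:
        logger.warning("spot %s: <2 samples per side; t vote none", spot.label)
        return "none", float("nan"), linear_fc
    res = stats.ttest_ind(t_vals, r_vals, equal_var=not welch)
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance on both sides with equal means
        p = 1.0
    if p < alpha:
        if fc_threshold is None:
            return ("up" if linear_fc > 1.0 else
                    "down" if linear_fc < 1.0 else "none"), p, linear_fc
        if linear_fc > fc_threshold:
            return "up", p, linear_fc
        if linear_fc < 1.0 / fc_threshold:
            return "down", p, linear_fc
    return "none", p, linear_fc


def joint_vote(pa: str, t: str, mode: str = "both") -> str:
    """Combine the two votes into one direction.

    ``both`` (default): the common value when the votes agree, else none.
    ``any``: fire when at least one caller fires and they do not contradict.
    """
    if mode == "both":
        return pa if pa == t else "none"
    if mode == "any":
        fired = {v for v in (pa, t) if v != "none"}
        return fired.pop() if len(fired) == 1 else "none"
    raise ValidationError(f"unknown vote mode {mode!r}")


def enumerate_contrasts(samples: pd.DataFrame) -> list[Contrast]:
    """Derive the standard contrast set from the sample table.

    Disease layers contribute target-vs-reference. Treatment layers with
    subgroups contribute each target subgroup vs each reference subgroup plus
    all target-subgroup pairs (e.g. responder vs baseline, responder vs
    placebo, responder vs non-responder); without subgroups they reduce to
    target-vs-reference as well.
    """
    contrasts: list[Contrast] = []
    for lid, tbl in samples.groupby("layer", sort=False):
        role = tbl["role"].iloc[0]
        tgt = tbl[tbl["group"] == "target"]
        ref = tbl[tbl["group"] == "reference"]
        t_subs = [s for s in dict.fromkeys(tgt["subgroup"]) if s]
        r_subs = [s for s in dict.fromkeys(ref["subgroup"]) if s]
        if role == "treatment" and (t_subs or r_subs):
            for ts in (t_subs or [""]):
                t_samples = list(tgt.index if not ts
                                 else tgt.index[tgt["subgroup"] == ts])
                for rs in (r_subs or [""]):
                    r_samples = list(ref.index if not rs
                                     else ref.index[ref["subgroup"] == rs])
                    name = f"{lid}:{ts or 'target'}_vs_{rs or 'reference'}"
                    contrasts.append(Contrast(name, lid, t_samples, r_samples))
            for i, ts in enumerate(t_subs):
                for ts2 in t_subs[i + 1:]:
                    contrasts.append(Contrast(
                        f"{lid}:{ts}_vs_{ts2}", lid,
                        list(tgt.index[tgt["subgroup"] == ts]),
                        list(tgt.index[tgt["subgroup"] == ts2])))
        else:
            contrasts.append(Contrast(f"{lid}:target_vs_reference", lid,
                                      list(tgt.index), list(ref.index)))
    return contrasts


def call_spot(spot: Spot, model: SOMModel, joint: JointMatrix,
              contrast: Contrast, config: PipelineConfig) -> SpotCall:
    layer_samples = joint.layer_samples(contrast.layer_id)
    pa = presence_absence_call(spot, model, layer_samples,
                               contrast.target_samples,
                               contrast.reference_samples,
                               config.sd_multiplier)
    t, p, fc = ttest_call(spot, contrast.target_samples,
                          contrast.reference_samples,
                          config.ttest_alpha, config.fc_threshold,
                          config.welch)
    return SpotCall(spot=spot.label, layer_id=contrast.layer_id,
                    contrast=contrast.name, pa_vote=pa, t_vote=t,
                    direction=joint_vote(pa, t, config.vote),
                    p_value=p, linear_fc=fc)


def build_perturbation_matrix(spots: list[Spot], model: SOMModel,
                              joint: JointMatrix, contrasts: list[Contrast],
                              config: PipelineConfig) -> PerturbationMatrix:
    """One SpotCall per spot x contrast — the spot perturbation heatmap."""
    calls = {}
    for contrast in contrasts:
        for spot in spots:
            calls[(spot.label, contrast.name)] = call_spot(
                spot, model, joint, contrast, config)
    return PerturbationMatrix(calls=calls, spots=[s.label for s in spots],
                              contrasts=contrasts)


def repositioning_call(pm: PerturbationMatrix, drug_contrast: str,
                       disease_contrast: str) -> RepositioningVerdict:
    """Antagonistic-spot test: the drug is a candidate for the disease iff
    some spot is up in the disease contrast and down in the drug contrast,
    or vice versa."""
    drug = pm.contrast(drug_contrast)
    disease = pm.contrast(disease_contrast)
    antagonistic = []
    unopposed = []
    for spot in pm.spots:
        d_dir = pm.call(spot, disease_contrast).direction
        t_dir = pm.call(spot, drug_contrast).direction
        if {d_dir, t_dir} == {"up", "down"}:
            antagonistic.append((spot, d_dir, t_dir))
        elif d_dir != "none" and t_dir == "none":
            unopposed.append(spot)
    verdict = "candidate" if antagonistic else "not_supported"
    return RepositioningVerdict(
        drug_layer=drug.layer_id, disease_layer=disease.layer_id,
        drug_contrast=drug_contrast, disease_contrast=disease_contrast,
        antagonistic_spots=antagonistic, unopposed_disease_spots=unopposed,
        verdict=verdict)
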