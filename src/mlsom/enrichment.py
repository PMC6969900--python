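"""Functional annotation of spots and sample-wise gene-set scoring.

Spot annotation is the right-tailed Fisher exact test (hypergeometric tail)
on the 2x2 in-spot/out-spot x in-set/out-set table, with Benjamini-Hochberg
FDR across the queried sets within each spot. The gene-set Z score (GSZ) is
a simplified standardized set mean per sample,

    z = sqrt(n_S) * (mean delta-e over set genes - mean over all genes) / SD over all genes,

which is approximately standard normal for random sets under exchangeability.
Output metadata labels it "gsz-simplified" to distinguish it from variants
with hypergeometric variance corrections.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneSetCollection, JointMatrix, Spot, ValidationError

logger = logging.getLogger(__name__)

GSZ_VARIANT = "gsz-simplified"


def fisher_spot_annotation(spot_genes: set[str], gene_set: set[str],
                           universe: set[str]) -> float:
    """Right-tailed Fisher exact p for spot/set overlap within a universe:
    P(X >= overlap) for X ~ Hypergeometric(N=|universe|, K=|set|, n=|spot|)."""
    if not universe:
        raise ValidationError("empty gene universe")
    spot_genes = set(spot_genes) & universe
    gene_set = set(gene_set) & universe
    overlap = len(spot_genes & gene_set)
    n_universe, n_set, n_spot = len(universe), len(gene_set), len(spot_genes)
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_set, n_spot))


def annotate_spots(spots: list[Spot], collection: GeneSetCollection,
                   universe: list[str]) -> pd.DataFrame:
    """Fisher annotation of every spot against every set, BH-corrected within
    each spot. Returns a long-format table sorted by (spot, p)."""
    uni = set(universe)
    rows = []
    for spot in spots:
        spot_genes = set(spot.genes) & uni
        pvals = []
        for name, genes in collection:
            in_uni = set(genes) & uni
            dropped = len(genes) - len(in_uni)
            if dropped:
                logger.debug("set %s: %d gene(s) outside universe dropped",
                             name, dropped)
            p = fisher_spot_annotation(spot_genes, in_uni, uni)
            pvals.append(p)
            rows.append({
                "spot": spot.label, "gene_set": name,
                "overlap": len(spot_genes & in_uni),
                "set_size": len(in_uni), "spot_size": len(spot_genes),
                "p_value": p,
                "source_tag": collection.source_tag.get(name, ""),
            })
        if pvals:
            fdr = multipletests(pvals, method="fdr_bh")[1]
            for row, q in zip(rows[-len(pvals):], fdr):
                row["fdr"] = float(q)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["spot", "p_value"],
                              kind="stable").reset_index(drop=True)
    return out


def gsz_profile(joint: JointMatrix, gene_set: list[str] | set[str],
                samples: list[str] | None = None) -> pd.Series:
    """Sample-wise GSZ of one gene set on the delta-e matrix.

    Genes of the set absent from the matrix are dropped (counts logged);
    the score uses the remaining n_S genes.
    """
    genes = [g for g in joint.genes if g in set(gene_set)]
    dropped = len(set(gene_set)) - len(genes)
    if dropped:
        logger.debug("gsz: %d set gene(s) not in matrix dropped", dropped)
    if not genes:
        raise ValidationError("no gene of the set is present in the matrix")
    cols = samples if samples is not None else list(joint.values.columns)
    values = joint.values[cols]
    all_mean = values.mean(axis=0)
    all_sd = values.std(axis=0, ddof=1)
    if (all_sd <= 0).any():
        raise ValidationError("zero across-gene SD in some sample")
    set_mean = values.loc[genes].mean(axis=0)
    z = np.sqrt(len(genes)) * (set_mean - all_mean) / all_sd
    z.name = GSZ_VARIANT
    return z


def gsz_table(joint: JointMatrix, collection: GeneSetCollection
              ) -> pd.DataFrame:
    """GSZ of every set in every sample (sets x samples)."""
    rows = {name: gsz_profile(joint, genes) for name, genes in collection}
    out = pd.DataFrame(rows).T
    out.index.name = "gene_set"
    out.attrs["variant"] = GSZ_VARIANT
    return out
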