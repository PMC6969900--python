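import math

import numpy as np
import pandas as pd
import pytest

from mlsom import (
    GeneSetCollection,
    Spot,
    ValidationError,
    annotate_spots,
    fisher_spot_annotation,
    gsz_profile,
)
from mlsom.enrichment import gsz_table

from conftest import make_joint


def hypergeom_tail_oracle(overlap, n_universe, n_set, n_spot):
    """P(X >= overlap) by explicit pmf summation with exact binomials."""
    total = 0.0
    denom = math.comb(n_universe, n_spot)
    for k in range(overlap, min(n_set, n_spot) + 1):
        total += math.comb(n_set, k) * math.comb(n_universe - n_set,
                                                 n_spot - k) / denom
    return total


def named(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestFisher:
    def test_worked_example(self):
        universe = set(named("u", 100))
        spot = set(named("u", 10))
        gene_set = set(named("u", 8)) | {"u90", "u91", "u92", "u93", "u94",
                                         "u95", "u96", "u97", "u98", "u99",
                                         "u80", "u81"}
        assert len(gene_set) == 20 and len(spot & gene_set) == 8
        p = fisher_spot_annotation(spot, gene_set, universe)
        assert p == pytest.approx(hypergeom_tail_oracle(8, 100, 20, 10),
                                  abs=1e-12)
        # exact tail sum = 2.378e-5
        assert p == pytest.approx(2.378e-5, rel=1e-3)

    def test_zero_overlap_is_one(self):
        universe = set(named("u", 50))
        p = fisher_spot_annotation(set(named("u", 10)),
                                   set(named("u", 50)[40:]), universe)
        assert p == pytest.approx(1.0)

    def test_spot_equals_universe_is_one(self):
        universe = set(named("u", 30))
        p = fisher_spot_annotation(universe, set(named("u", 7)), universe)
        assert p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            fisher_spot_annotation(set(), set(), set())

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n_universe = int(rng.integers(2, 61))
            n_set = int(rng.integers(1, n_universe + 1))
            n_spot = int(rng.integers(1, n_universe + 1))
            universe = named("u", n_universe)
            gene_set = set(rng.choice(universe, n_set, replace=False))
            spot = set(rng.choice(universe, n_spot, replace=False))
            p = fisher_spot_annotation(spot, gene_set, set(universe))
            oracle = hypergeom_tail_oracle(len(spot & gene_set),
                                           n_universe, n_set, n_spot)
            assert abs(p - oracle) < 1e-10


class TestAnnotateSpots:
    def test_fdr_within_spot(self):
        universe = named("u", 60)
        spot = Spot(label="A", units=[(0, 0)], genes=universe[:10],
                    profile=pd.Series(dtype=float))
        coll = GeneSetCollection(sets={
            "hit": universe[:8], "miss": universe[50:], "half": universe[5:25],
        })
        table = annotate_spots([spot], coll, universe)
        assert set(table["gene_set"]) == {"hit", "miss", "half"}
        assert ((table["fdr"] >= 0) & (table["fdr"] <= 1)).all()
        assert table.sort_values("p_value").iloc[0]["gene_set"] == "hit"


class TestGSZ:
    def test_worked_example_z_of_two(self):
        # one sample where all genes have mean 0, SD 1 and a 4-gene set has
        # mean delta-e 1 -> z = sqrt(4) * (1 - 0) / 1 = 2
        rng = np.random.default_rng(4)
        n = 4000
        vals = rng.normal(0, 1, n)
        vals = (vals - vals.mean()) / vals.std(ddof=1)
        set_genes = [f"g{i:05d}" for i in range(4)]
        vals[:4] = vals[:4] - vals[:4].mean() + 1.0  # set mean exactly 1
        # re-standardization shifts the global moments only marginally
        joint = make_joint(np.c_[vals, -vals],
                           genes=[f"g{i:05d}" for i in range(n)])
        z = gsz_profile(joint, set_genes)
        expected = 2.0 * np.sqrt(1) * (1 - vals.mean()) / vals.std(ddof=1)
        assert z.iloc[0] == pytest.approx(expected, rel=1e-9)
        assert z.iloc[0] == pytest.approx(2.0, abs=0.1)

    def test_set_of_all_genes_scores_zero(self):
        rng = np.random.default_rng(5)
        joint = make_joint(rng.normal(size=(50, 4)))
        z = gsz_profile(joint, list(joint.genes))
        assert np.abs(z.to_numpy()).max() < 1e-12

    def test_sign_follows_set_mean(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 0.1, (10, 2))
        X[:3, 0] -= 2.0  # set genes dip in the first sample only
        joint = make_joint(X)
        z = gsz_profile(joint, joint.genes[:3])
        assert z.iloc[0] < 0 < z.iloc[1]

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(80, 3))
        z1 = gsz_profile(make_joint(base), [f"g{i:03d}" for i in range(8)])
        # adding a constant to a whole sample is removed by centering and
        # cancels inside the score
        shifted = base + np.array([5.0, -2.0, 0.0])[None, :]
        z2 = gsz_profile(make_joint(shifted), [f"g{i:03d}" for i in range(8)])
        assert np.abs(z1.to_numpy() - z2.to_numpy()).max() < 1e-9

    def test_null_scores_approximately_standard_normal(self):
        rng = np.random.default_rng(7)
        n_genes, n_draws, set_size = 1000, 1000, 25
        X = rng.normal(0, 1, (n_genes, 2))
        joint = make_joint(X)
        genes = np.array(joint.genes)
        zs = np.empty(n_draws)
        for i in range(n_draws):
            chosen = rng.choice(genes, set_size, replace=False)
            zs[i] = gsz_profile(joint, list(chosen)).iloc[0]
        assert abs(zs.mean()) < 0.1
        assert abs(zs.std(ddof=1) - 1.0) < 0.15

    def test_table_shape_and_metadata(self):
        rng = np.random.default_rng(8)
        joint = make_joint(rng.normal(size=(40, 5)))
        coll = GeneSetCollection(sets={"a": joint.genes[:5],
                                       "b": joint.genes[5:15]})
        table = gsz_table(joint, coll)
        assert table.shape == (2, 5)
        assert table.attrs["variant"] == "gsz-simplified"

    def test_absent_set_rejected(self):
        joint = make_joint(np.zeros((5, 3)) + np.arange(3)[None, :])
        with pytest.raises(ValidationError):
            gsz_profile(joint, ["nope1", "nope2"])
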