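import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlsom import (
    Contrast,
    PerturbationMatrix,
    PipelineConfig,
    Spot,
    SpotCall,
    joint_vote,
    overexpression_mask,
    presence_absence_call,
    repositioning_call,
    segment_mask,
    ttest_call,
)
from mlsom.datamodel import spot_labels
from mlsom.som import SOMModel


def flood_fill_oracle(mask, connectivity):
    """Independent component labeling by breadth-first flood fill."""
    from collections import deque

    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp, queue = [], deque([(r, c)])
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    comp.append((rr, cc))
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                                and mask[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                components.append(frozenset(comp))
    return set(components)


def make_spot(profile, label="A"):
    return Spot(label=label, units=[(0, 0)], genes=["g1"],
                profile=pd.Series(profile))


def make_model_for_pa(entries, samples):
    """1-unit-per-row model whose prototypes are the given spot entries."""
    n_units = entries.shape[0]
    return SOMModel(
        grid_shape=(n_units, 1), prototypes=np.asarray(entries, dtype=float),
        samples=list(samples),
        assignment=pd.Series(range(n_units),
                             index=[f"g{i}" for i in range(n_units)]),
        training_log=pd.DataFrame())


class TestOverexpressionMask:
    def test_type7_threshold_worked_example(self):
        portrait = np.array([[1.0, 2.0], [3.0, 10.0]])
        mask = overexpression_mask(portrait, 0.95)
        # type-7 quantile of {1,2,3,10} at 0.95 = 3 + 0.85*7 = 8.95
        assert mask.tolist() == [[False, False], [False, True]]

    def test_constant_portrait_empty_mask(self):
        assert not overexpression_mask(np.ones((3, 3)), 0.95).any()

    def test_quantile_zero_flags_all_but_minimum_ties(self):
        portrait = np.array([[0.0, 0.0], [1.0, 2.0]])
        mask = overexpression_mask(portrait, 1e-12)
        assert mask.tolist() == [[False, False], [True, True]]

    def test_matches_manual_type7_quantile_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            values = rng.normal(size=(6, 6))
            q = rng.uniform(0.05, 0.95)
            sorted_v = np.sort(values.ravel())
            pos = (sorted_v.size - 1) * q
            lo = int(np.floor(pos))
            frac = pos - lo
            manual = sorted_v[lo] + frac * (
                sorted_v[min(lo + 1, sorted_v.size - 1)] - sorted_v[lo])
            got = overexpression_mask(values, q)
            assert np.array_equal(got, values > manual)


class TestSegmentation:
    def test_diagonal_cells_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert segment_mask(mask, 8).max() == 1
        assert segment_mask(mask, 4).max() == 2

    def test_labels_row_major_by_centroid(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[4, 4] = True  # lower right
        mask[0, 0] = True  # upper left
        labeled = segment_mask(mask, 8)
        assert labeled[0, 0] == 1 and labeled[4, 4] == 2

    def test_empty_mask_no_components(self):
        assert segment_mask(np.zeros((3, 3), dtype=bool), 8).max() == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_on_random_masks(self, connectivity):
        rng = np.random.default_rng(13)
        for _ in range(15):
            mask = rng.random((20, 20)) < 0.3
            labeled = segment_mask(mask, connectivity)
            got = {frozenset(map(tuple, np.argwhere(labeled == i)))
                   for i in range(1, labeled.max() + 1)}
            assert got == flood_fill_oracle(mask, connectivity)

    def test_spot_labels_sequence(self):
        labels = spot_labels(30)
        assert labels[:3] == ["A", "B", "C"]
        assert labels[25] == "Z" and labels[26] == "A1"


class TestPresenceAbsence:
    def sigma_half_model(self):
        # one spot unit; entries chosen so SD over the layer's samples = 0.5
        samples = [f"s{i}" for i in range(9)]
        entries = np.array([[0.5, 0.5, 0.5, 0.5, -0.5, -0.5, -0.5, -0.5, 0.0]])
        model = make_model_for_pa(entries, samples)
        return model, samples

    def test_up_when_difference_exceeds_sigma(self):
        model, samples = self.sigma_half_model()
        sigma = model.prototypes.std(ddof=1)
        assert sigma == pytest.approx(0.5, abs=1e-12)
        spot = Spot(label="A", units=[(0, 0)], genes=["g0"],
                    profile=pd.Series([0.8] * 4 + [0.0] * 5, index=samples))
        vote = presence_absence_call(spot, model, samples, samples[:4],
                                     samples[4:], 1.0)
        assert vote == "up"

    def test_none_when_means_equal(self):
        model, samples = self.sigma_half_model()
        spot = Spot(label="A", units=[(0, 0)], genes=["g0"],
                    profile=pd.Series([0.4] * 9, index=samples))
        assert presence_absence_call(spot, model, samples, samples[:4],
                                     samples[4:], 1.0) == "none"

    def test_down_for_reversed_difference(self):
        model, samples = self.sigma_half_model()
        spot = Spot(label="A", units=[(0, 0)], genes=["g0"],
                    profile=pd.Series([-0.8] * 4 + [0.9] * 5, index=samples))
        assert presence_absence_call(spot, model, samples, samples[:4],
                                     samples[4:], 1.0) == "down"

    def test_zero_sigma_votes_none(self):
        samples = ["a", "b", "c", "d"]
        model = make_model_for_pa(np.zeros((1, 4)), samples)
        spot = Spot(label="A", units=[(0, 0)], genes=["g0"],
                    profile=pd.Series([9.0, 9.0, 0.0, 0.0], index=samples))
        assert presence_absence_call(spot, model, samples, samples[:2],
                                     samples[2:], 1.0) == "none"

    def test_swap_flips_direction(self):
        model, samples = self.sigma_half_model()
        spot = Spot(label="A", units=[(0, 0)], genes=["g0"],
                    profile=pd.Series([0.9] * 4 + [-0.2] * 5, index=samples))
        up = presence_absence_call(spot, model, samples, samples[:4],
                                   samples[4:], 1.0)
        down = presence_absence_call(spot, model, samples, samples[4:],
                                     samples[:4], 1.0)
        assert (up, down) == ("up", "down")


def welch_oracle(x, y):
    """Textbook Welch t statistic and two-sided p from the t distribution."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x), np.asarray(y)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    tstat = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    dof = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    return tstat, 2.0 * tdist.sf(abs(tstat), dof)


class TestTTestCall:
    def test_clear_shift_fires_up(self):
        profile = pd.Series([2.0, 2.1, 1.9, 1.0, 1.1, 0.9],
                            index=list("abcdef"))
        spot = make_spot(profile)
        vote, p, fc = ttest_call(spot, ["a", "b", "c"], ["d", "e", "f"])
        tstat, p_oracle = welch_oracle([2.0, 2.1, 1.9], [1.0, 1.1, 0.9])
        assert vote == "up"
        assert tstat == pytest.approx(12.247, abs=0.01)
        assert p == pytest.approx(p_oracle, abs=1e-12)
        assert fc == pytest.approx(2.0)

    def test_identical_groups_vote_none(self):
        profile = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        vote, p, fc = ttest_call(make_spot(profile), ["a", "b"], ["c", "d"])
        assert vote == "none" and fc == pytest.approx(1.0)

    def test_small_fold_change_gated_despite_tiny_p(self):
        rng = np.random.default_rng(0)
        t = 0.3 + rng.normal(0, 0.01, 10)
        r = rng.normal(0, 0.01, 10)
        profile = pd.Series(np.r_[t, r],
                            index=[f"s{i}" for i in range(20)])
        spot = make_spot(profile)
        vote, p, fc = ttest_call(spot, [f"s{i}" for i in range(10)],
                                 [f"s{i}" for i in range(10, 20)])
        assert p < 1e-6 and 1.0 < fc < 1.5
        assert vote == "none"

    def test_fc_gate_disabled_votes_on_sign(self):
        rng = np.random.default_rng(0)
        profile = pd.Series(np.r_[0.3 + rng.normal(0, 0.01, 10),
                                  rng.normal(0, 0.01, 10)],
                            index=[f"s{i}" for i in range(20)])
        spot = make_spot(profile)
        vote, _, _ = ttest_call(spot, [f"s{i}" for i in range(10)],
                                [f"s{i}" for i in range(10, 20)],
                                fc_threshold=None)
        assert vote == "up"

    def test_single_sample_side_votes_none(self):
        profile = pd.Series([5.0, 0.0, 0.1, 0.2], index=list("abcd"))
        vote, _, _ = ttest_call(make_spot(profile), ["a"], ["b", "c", "d"])
        assert vote == "none"

    def test_matches_welch_oracle_on_random_data(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.5, 2, rng.integers(3, 12))
            names = [f"s{i}" for i in range(len(x) + len(y))]
            spot = make_spot(pd.Series(np.r_[x, y], index=names))
            _, p, _ = ttest_call(spot, names[:len(x)], names[len(x):])
            assert p == pytest.approx(welch_oracle(x, y)[1], abs=1e-8)

    def test_swap_flips_direction(self):
        profile = pd.Series([2.0, 2.1, 1.9, 1.0, 1.1, 0.9],
                            index=list("abcdef"))
        spot = make_spot(profile)
        up, _, _ = ttest_call(spot, list("abc"), list("def"))
        down, _, _ = ttest_call(spot, list("def"), list("abc"))
        assert (up, down) == ("up", "down")


class TestJointVote:
    @pytest.mark.parametrize("pa,t,expected", [
        ("up", "up", "up"), ("down", "down", "down"),
        ("up", "none", "none"), ("none", "up", "none"),
        ("up", "down", "none"), ("none", "none", "none"),
    ])
    def test_conservative_and(self, pa, t, expected):
        assert joint_vote(pa, t, "both") == expected

    @pytest.mark.parametrize("pa,t,expected", [
        ("up", "up", "up"), ("up", "none", "up"), ("none", "down", "down"),
        ("up", "down", "none"), ("none", "none", "none"),
    ])
    def test_any_mode(self, pa, t, expected):
        assert joint_vote(pa, t, "any") == expected

    @given(pa=st.sampled_from(["up", "down", "none"]),
           t=st.sampled_from(["up", "down", "none"]))
    @settings(deadline=None)
    def test_and_never_fires_when_any_is_silent(self, pa, t):
        if joint_vote(pa, t, "any") == "none":
            assert joint_vote(pa, t, "both") == "none"


def toy_perturbation(directions):
    """Build a PerturbationMatrix from {contrast: {spot: direction}}."""
    contrast_names = list(directions)
    spots = sorted({s for d in directions.values() for s in d})
    contrasts = [Contrast(name, name.split(":")[0], ["t1", "t2"], ["r1", "r2"])
                 for name in contrast_names]
    calls = {}
    for cname, dirmap in directions.items():
        lid = cname.split(":")[0]
        for s in spots:
            d = dirmap.get(s, "none")
            calls[(s, cname)] = SpotCall(
                spot=s, layer_id=lid, contrast=cname, pa_vote=d, t_vote=d,
                direction=d, p_value=0.01 if d != "none" else 0.5,
                linear_fc=2.0 if d == "up" else 0.5 if d == "down" else 1.0)
    return PerturbationMatrix(calls=calls, spots=spots, contrasts=contrasts)


class TestRepositioning:
    def test_infliximab_like_pattern(self):
        # spot U up in the UC/CD/sarcoidosis-like disease contrasts and down
        # under the drug; a COPD-like layer carries no dysregulated spot
        pm = toy_perturbation({
            "drug:responder_vs_baseline": {"U": "down"},
            "UC:target_vs_reference": {"U": "up", "F": "up", "A": "down"},
            "CD:target_vs_reference": {"U": "up", "A": "down"},
            "sarcoidosis:target_vs_reference": {"U": "up", "T": "up"},
            "COPD:target_vs_reference": {},
        })
        drug = "drug:responder_vs_baseline"
        verdicts = {d: repositioning_call(pm, drug, f"{d}:target_vs_reference")
                    for d in ("UC", "CD", "sarcoidosis", "COPD")}
        assert verdicts["UC"].verdict == "candidate"
        assert verdicts["CD"].verdict == "candidate"
        assert verdicts["sarcoidosis"].verdict == "candidate"
        assert verdicts["COPD"].verdict == "not_supported"
        assert ("U", "up", "down") in verdicts["UC"].antagonistic_spots
        # disease spots the drug leaves untouched are reported
        assert "F" in verdicts["UC"].unopposed_disease_spots

    def test_same_direction_is_not_antagonistic(self):
        pm = toy_perturbation({
            "drug:target_vs_reference": {"A": "up"},
            "dis:target_vs_reference": {"A": "up"},
        })
        v = repositioning_call(pm, "drug:target_vs_reference",
                               "dis:target_vs_reference")
        assert v.verdict == "not_supported"

    def test_empty_matrix_not_supported(self):
        pm = toy_perturbation({
            "drug:target_vs_reference": {},
            "dis:target_vs_reference": {},
        })
        v = repositioning_call(pm, "drug:target_vs_reference",
                               "dis:target_vs_reference")
        assert v.verdict == "not_supported" and not v.antagonistic_spots

    def test_unknown_contrast_rejected(self):
        pm = toy_perturbation({"drug:target_vs_reference": {}})
        with pytest.raises(KeyError):
            repositioning_call(pm, "drug:target_vs_reference", "nope")


class TestSpotPartition:
    def test_spots_partition_flagged_units(self, small_trained):
        from mlsom import build_joint_matrix, group_portraits, \
            summary_map_and_segment
        _, _, joint, config, model = small_trained
        portraits = group_portraits(model, joint.samples)
        mask, spots = summary_map_and_segment(portraits, model, config, joint)
        covered = [u for s in spots for u in s.units]
        assert len(covered) == len(set(covered)) == int(mask.sum())


class TestUnderexpression:
    def test_mirror_mask_flags_low_tail(self):
        from mlsom.spots import underexpression_mask
        portrait = np.array([[-10.0, 2.0], [3.0, 1.0]])
        mask = underexpression_mask(portrait, 0.05)
        assert mask.tolist() == [[True, False], [False, False]]

    def test_flag_adds_spots_but_keeps_overexpression_ones(self, small_trained):
        import dataclasses
        from mlsom import build_joint_matrix, group_portraits, \
            summary_map_and_segment
        _, _, joint, config, model = small_trained
        portraits = group_portraits(model, joint.samples)
        mask_over, _ = summary_map_and_segment(portraits, model, config, joint)
        both_cfg = dataclasses.replace(config, underexpression=True)
        mask_both, _ = summary_map_and_segment(portraits, model, both_cfg,
                                               joint)
        assert mask_both[mask_over].all()
        assert mask_both.sum() > mask_over.sum()
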