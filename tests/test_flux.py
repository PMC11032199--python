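"""Wagner-parsimony reconstruction: worked examples, oracle checks, properties."""

import itertools

import numpy as np
import pytest

import helpers_wagner as hw
from stkflux.flux import FluxConfig, PhyleticProfile, summarize_flux, wagner_reconstruct
from stkflux.io import SpeciesTree
from stkflux.synthetic_data import SimConfig, gen_phyletic_profiles, gen_species_tree


def profile_of(taxa, rows, families=None):
    families = families or tuple(f"f{i}" for i in range(len(rows)))
    return PhyleticProfile(tuple(families), tuple(taxa), np.array(rows))


def realized_costs(result, tree, gain, loss):
    """Cost implied by the reconstruction itself, per family."""
    costs = np.zeros(len(result.families))
    for parent, child in tree.branches:
        diff = result.ancestral_counts[child] - result.ancestral_counts[parent]
        costs += np.where(diff > 0, gain * diff, -loss * diff)
    return costs


class TestWorkedExamples:
    def test_family_present_in_both_leaves_costs_nothing(self):
        tree = SpeciesTree.from_string("(A,B);")
        res = wagner_reconstruct(profile_of(["A", "B"], [[1, 1]]), tree)
        assert res.total_cost == 0
        assert res.ancestral_counts[tree.root_id][0] == 1
        assert all(not b.families_gained and not b.families_lost
                   for b in res.per_branch.values())

    def test_root_presence_with_single_loss_is_cheapest(self, tree_abc):
        # A=1, B=1, C=0 with penalties (2,1): ancestral presence with one
        # loss on the branch to C (cost 1) beats a gain on the (A,B)
        # ancestor branch (cost 2) and two parallel leaf gains (cost 4);
        # exhaustive enumeration over root/N1 in {0,1} confirms.
        res = wagner_reconstruct(profile_of(["A", "B", "C"], [[1, 1, 0]]),
                                 tree_abc, FluxConfig(2, 1))
        assert res.total_cost == 1
        assert res.ancestral_counts["N0"][0] == 1
        assert res.ancestral_counts["N1"][0] == 1
        assert res.per_branch[("N0", "C")].families_lost == {"f0"}

    def test_single_leaf_presence_is_terminal_gain(self, tree_abc):
        res = wagner_reconstruct(profile_of(["A", "B", "C"], [[1, 0, 0]]),
                                 tree_abc, FluxConfig(2, 1))
        assert res.total_cost == 2
        assert res.per_branch[("N1", "A")].families_gained == {"f0"}
        assert res.ancestral_counts["N1"][0] == 0

    def test_star_tree_single_loss_beats_double_gain(self):
        # (A,B,C) with counts (1,1,0), penalties (1,1): root 1 with one loss
        # (cost 1) is the unique optimum; root 0 would need two gains.
        tree = SpeciesTree.from_string("(A,B,C);")
        res = wagner_reconstruct(profile_of(["A", "B", "C"], [[1, 1, 0]]),
                                 tree, FluxConfig(1, 1))
        assert res.total_cost == 1
        assert res.ancestral_counts[tree.root_id][0] == 1
        assert res.per_branch[(tree.root_id, "C")].families_lost == {"f0"}

    def test_multicopy_units_counted(self, tree_abc):
        res = wagner_reconstruct(profile_of(["A", "B", "C"], [[3, 3, 0]]),
                                 tree_abc, FluxConfig(2, 1))
        # root 3, three unit losses on the branch to C (cost 3)
        assert res.per_branch[("N0", "C")].units_lost == 3
        assert res.per_branch[("N0", "C")].families_lost == {"f0"}
        assert res.total_cost == 3


class TestValidation:
    def test_profile_taxon_missing_from_tree(self, tree_abc):
        with pytest.raises(ValueError, match="absent from tree"):
            wagner_reconstruct(profile_of(["A", "B", "X"], [[1, 1, 1]]), tree_abc)

    def test_all_absent_families_dropped_with_warning(self, tree_abc):
        prof = profile_of(["A", "B", "C"], [[0, 0, 0], [1, 1, 1]])
        with pytest.warns(UserWarning, match="dropped 1 families"):
            res = wagner_reconstruct(prof, tree_abc)
        assert res.dropped_families == ("f0",)
        assert res.families == ("f1",)

    def test_nonpositive_penalties_rejected(self):
        with pytest.raises(ValueError):
            FluxConfig(gain_penalty=0)

    def test_count_cap_applied(self, tree_abc):
        prof = profile_of(["A", "B", "C"], [[5, 5, 5]])
        res = wagner_reconstruct(prof, tree_abc, FluxConfig(2, 1, max_count_cap=2))
        assert res.ancestral_counts["N0"][0] == 2


class TestOracle:
    @pytest.mark.parametrize("penalties", [(2, 1), (1, 1), (1, 2)])
    def test_dp_matches_brute_force_on_random_small_instances(self, rng, penalties):
        gain, loss = penalties
        cap = 2
        for _ in range(20):
            n_leaves = int(rng.integers(2, 6))
            shapes = hw.enumerate_shapes(n_leaves)
            shape = shapes[int(rng.integers(len(shapes)))]
            tree = SpeciesTree.from_string(hw.shape_to_newick(shape))
            profiles = rng.integers(0, cap + 1, size=(30, n_leaves))
            profiles = profiles[profiles.sum(axis=1) > 0]
            prof = PhyleticProfile(
                tuple(f"f{i}" for i in range(len(profiles))),
                tuple(tree.leaves), profiles,
            )
            res = wagner_reconstruct(prof, tree, FluxConfig(gain, loss))
            brute = hw.brute_min_costs(tree, profiles, gain, loss, cap)
            realized = realized_costs(res, tree, gain, loss)
            np.testing.assert_allclose(realized, brute)
            assert res.total_cost == pytest.approx(brute.sum())

    def test_fitch_equivalence_for_equal_penalties(self, rng):
        # binary profiles + equal penalties: total unit changes equal the
        # Fitch parsimony change count (binary trees).
        tree = SpeciesTree.from_string("(((A,B),(C,D)),(E,F));")
        profiles = rng.integers(0, 2, size=(50, 6))
        profiles = profiles[profiles.sum(axis=1) > 0]
        prof = PhyleticProfile(tuple(f"f{i}" for i in range(len(profiles))),
                               tuple(tree.leaves), profiles)
        res = wagner_reconstruct(prof, tree, FluxConfig(1, 1))
        total_units = sum(b.units_gained + b.units_lost
                          for b in res.per_branch.values())
        fitch_total = sum(
            hw.fitch_changes(tree, dict(zip(tree.leaves, row)))
            for row in profiles
        )
        assert total_units == fitch_total

    def test_gain_events_monotone_in_gain_penalty(self):
        # over all 4-leaf shapes and binary profiles, raising the gain
        # penalty never increases the number of inferred unit gains
        for shape in hw.enumerate_shapes(4):
            tree = SpeciesTree.from_string(hw.shape_to_newick(shape))
            profiles = np.array(
                [p for p in itertools.product([0, 1], repeat=4) if any(p)]
            )
            prof = PhyleticProfile(tuple(f"f{i}" for i in range(len(profiles))),
                                   tuple(tree.leaves), profiles)
            gains = []
            for gp in (1.0, 2.0, 3.0):
                res = wagner_reconstruct(prof, tree, FluxConfig(gp, 1.0))
                gains.append(sum(b.units_gained for b in res.per_branch.values()))
            assert gains[0] >= gains[1] >= gains[2]


class TestConservation:
    def test_root_to_leaf_identity(self, small_config):
        tree = gen_species_tree(small_config)
        profile, _ = gen_phyletic_profiles(small_config, tree)
        with pytest.warns(UserWarning):
            res = wagner_reconstruct(profile, tree, FluxConfig(2, 1))
        root_counts = res.ancestral_counts[tree.root_id]
        for leaf in tree.leaves:
            # accumulate signed units along the root -> leaf path
            path = [leaf]
            while path[-1] != tree.root_id:
                path.append(tree.parent[path[-1]])
            path.reverse()
            signed = np.zeros(len(res.families))
            for parent, child in zip(path, path[1:]):
                signed += (res.ancestral_counts[child]
                           - res.ancestral_counts[parent])
            np.testing.assert_array_equal(
                signed, res.ancestral_counts[leaf] - root_counts
            )


class TestSummary:
    def test_single_event_tally(self, tree_abc):
        res = wagner_reconstruct(profile_of(["A", "B", "C"], [[1, 1, 0]]),
                                 tree_abc, FluxConfig(2, 1))
        summ = summarize_flux(res, tree_abc)
        lost = dict(zip(zip(summ.per_branch.parent, summ.per_branch.child),
                        summ.per_branch.lost))
        assert lost[("N0", "C")] == 1
        assert sum(lost.values()) == 1
        assert summ.per_branch.gained.sum() == 0

    def test_all_ones_profile_counts_every_node(self, tree_abc):
        prof = profile_of(["A", "B", "C"], [[1, 1, 1], [1, 1, 1]])
        res = wagner_reconstruct(prof, tree_abc)
        summ = summarize_flux(res, tree_abc)
        assert set(summ.per_node.families_present) == {2}
        assert summ.per_branch.gained.sum() == 0
        assert summ.per_branch.lost.sum() == 0

    def test_category_crosstab(self, tree_abc):
        # f0 (category T): lost on the branch to C; f1 (K): gained on B
        prof = profile_of(["A", "B", "C"], [[1, 1, 0], [0, 1, 0]])
        res = wagner_reconstruct(prof, tree_abc, FluxConfig(2, 1))
        summ = summarize_flux(res, tree_abc, {"f0": "T", "f1": "K"})
        assert summ.category_crosstab is not None
        assert summ.category_crosstab.xs("loss", level="event").loc["C", "T"] == 1
        assert summ.category_crosstab.xs("gain", level="event").loc["B", "K"] == 1
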