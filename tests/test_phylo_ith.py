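"""Binary matrices, Fitch scoring, the ratchet, classes and ITH scores."""

import numpy as np
import pandas as pd
import pytest

from ithpipe import phylo_ith, simdata
from ithpipe.phylo_ith import (
    BinaryMutationMatrix,
    build_matrix,
    classify_mutations,
    enumerate_topologies,
    exhaustive_search,
    fitch_score,
    ith_score,
    parsimony_ratchet,
)


def matrix_from(presence, patient="P", silent=None):
    presence = np.asarray(presence, dtype=bool)
    return BinaryMutationMatrix(
        patient_id=patient,
        sample_ids=[f"S{i}" for i in range(presence.shape[0])],
        mutation_ids=[f"m{j}" for j in range(presence.shape[1])],
        presence=presence,
        silent=silent,
    )


def fitch_oracle(tree, presence):
    """Independent set-based Fitch implementation (per character)."""

    def score_char(states):  # states: per-leaf {0}/{1}
        total = 0

        def rec(node):
            nonlocal total
            if isinstance(node, int):
                return states[node]
            a, b = rec(node[0]), rec(node[1])
            if a & b:
                return a & b
            total += 1
            return a | b

        root = rec(tree)
        if 0 not in root:  # germline outgroup is all-absent
            total += 1
        return total

    return sum(
        score_char([{int(presence[i, j])} for i in range(presence.shape[0])])
        for j in range(presence.shape[1])
    )


class TestBuildMatrix:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["patient", "sample", "chrom", "pos", "ref", "alt", "exonic_func"]
        )

    def test_presence_column_for_partial_mutation(self):
        rows = [("P", s, "1", 100, "C", "T", "nonsynonymous SNV") for s in ("S1", "S2")]
        m = build_matrix(self._records(rows), sample_ids=["S1", "S2", "S3"])
        assert m.to_frame()["1:100:C>T"].tolist() == [1, 1, 0]

    def test_duplicate_calls_collapse(self):
        rows = [("P", "S1", "1", 100, "C", "T", "nonsynonymous SNV")] * 2 + [
            ("P", "S2", "1", 100, "C", "T", "nonsynonymous SNV")
        ]
        m = build_matrix(self._records(rows))
        assert m.n_mutations == 1 and m.presence.sum() == 2

    def test_single_sample_patient_rejected(self):
        rows = [("P", "S1", "1", 100, "C", "T", "nonsynonymous SNV")]
        with pytest.raises(ValueError, match=">=2"):
            build_matrix(self._records(rows))

    def test_silent_flag_and_exclusion_switch(self):
        rows = [
            ("P", "S1", "1", 100, "C", "T", "synonymous SNV"),
            ("P", "S2", "1", 100, "C", "T", "synonymous SNV"),
            ("P", "S1", "1", 200, "G", "A", "nonsynonymous SNV"),
            ("P", "S2", "1", 200, "G", "A", "nonsynonymous SNV"),
        ]
        m = build_matrix(self._records(rows))
        assert m.silent.tolist() == [True, False]
        m2 = build_matrix(self._records(rows), include_silent=False)
        assert m2.mutation_ids == ["1:200:G>A"]

    def test_simulated_matrix_matches_ground_truth(self, sim_patient):
        variants, _, _, truth = sim_patient
        m = build_matrix(variants, sample_ids=truth.sample_ids)
        for j, mid in enumerate(m.mutation_ids):
            carriers = [m.sample_ids[i] for i in np.flatnonzero(m.presence[:, j])]
            assert carriers == truth.presence[mid]


class TestClassification:
    def test_published_definitions(self):
        presence = np.zeros((9, 3), dtype=bool)
        presence[:, 0] = True  # 9/9
        presence[:5, 1] = True  # 5/9
        presence[0, 2] = True  # 1/9
        labels = classify_mutations(matrix_from(presence))
        assert labels.tolist() == ["trunk", "shared", "private"]

    def test_two_sample_patient_has_no_shared(self, rng):
        presence = rng.random((2, 40)) < 0.6
        presence = presence[:, presence.any(axis=0)]
        labels = classify_mutations(matrix_from(presence))
        assert set(labels) <= {"trunk", "private"}

    def test_noiseless_simulation_recovered_exactly(self, sim_patient):
        variants, _, _, truth = sim_patient
        m = build_matrix(variants, sample_ids=truth.sample_ids)
        labels = classify_mutations(m)
        assert [truth.labels[mid] for mid in m.mutation_ids] == labels.tolist()


class TestIthScore:
    def test_methods_definition(self):
        labels = ["trunk"] * 50 + ["shared"] * 60 + ["private"] * 40
        assert ith_score(labels, "methods") == pytest.approx(50.0)

    def test_undefined_ratio_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(ith_score(["trunk"] * 10, "methods"))

    def test_nontrunk_fraction_definition(self):
        labels = ["trunk"] * 617 + ["shared"] * 200 + ["private"] * 183
        assert ith_score(labels, "nontrunk_fraction") == pytest.approx(38.3)

    def test_invariant_to_reordering(self, rng):
        labels = ["trunk"] * 30 + ["shared"] * 20 + ["private"] * 10
        shuffled = list(rng.permutation(labels))
        for d in ("methods", "nontrunk_fraction"):
            assert ith_score(labels, d) == ith_score(shuffled, d)


class TestFitch:
    def test_perfect_character_single_change(self):
        m = matrix_from(np.array([[1], [1], [0], [0]]))
        assert fitch_score(((0, 1), (2, 3)), m) == 1

    def test_maximal_conflict_two_changes(self):
        m = matrix_from(np.array([[1], [0], [1], [0]]))
        assert fitch_score(((0, 1), (2, 3)), m) == 2

    def test_matches_independent_oracle_on_random_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 8))
            presence = rng.random((n, 15)) < 0.5
            presence = presence[:, presence.any(axis=0)]
            if presence.shape[1] == 0:
                continue
            m = matrix_from(presence)
            trees = list(enumerate_topologies(n))
            t = trees[int(rng.integers(len(trees)))]
            assert fitch_score(t, m) == fitch_oracle(t, presence)

    def test_column_duplication_adds_exactly_its_changes(self, rng):
        presence = rng.random((5, 10)) < 0.5
        presence = presence[:, presence.any(axis=0)]
        m = matrix_from(presence)
        tree = next(enumerate_topologies(5))
        base = fitch_score(tree, m)
        doubled = matrix_from(np.hstack([presence, presence]))
        assert fitch_score(tree, doubled) == 2 * base


class TestTopologyEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_unrooted_topology_counts(self, n, count):
        # (2n-3)!! unrooted trees over n samples + outgroup
        assert len(list(enumerate_topologies(n))) == count


class TestRatchet:
    def test_perfect_phylogeny_score_and_unique_edges(self, sim_patient):
        variants, _, _, truth = sim_patient
        m = build_matrix(variants, sample_ids=truth.sample_ids)
        res = parsimony_ratchet(m, iterations=20, seed=1)
        # tree-compatible data: one change per mutation
        assert res.parsimony_score == m.n_mutations
        assert all(len(e) == 1 for e in res.mutation_edges)
        assert not res.homoplastic.any()

    def test_trunk_mutations_on_outgroup_adjacent_edge(self, sim_patient):
        variants, _, _, truth = sim_patient
        m = build_matrix(variants, sample_ids=truth.sample_ids)
        res = parsimony_ratchet(m, iterations=20, seed=1)
        full = tuple(sorted(m.sample_ids))
        for j, lab in enumerate(res.labels):
            if lab == "trunk":
                assert res.mutation_edges[j] == [full]
            elif lab == "private":
                assert len(res.mutation_edges[j][0]) == 1

    def test_branch_lengths_sum_to_score(self, rng):
        presence = rng.random((6, 40)) < 0.4
        presence = presence[:, presence.any(axis=0)]
        m = matrix_from(presence)
        res = parsimony_ratchet(m, iterations=30, seed=2)
        assert sum(res.branch_lengths.values()) == res.parsimony_score

    def test_matches_exhaustive_on_small_random_matrices(self, rng):
        hits = 0
        for trial in range(10):
            n = int(rng.integers(5, 8))
            presence = rng.random((n, 30)) < 0.5
            presence = presence[:, presence.any(axis=0)]
            m = matrix_from(presence)
            _, exact = exhaustive_search(m)
            res = parsimony_ratchet(m, iterations=50, seed=trial)
            assert res.parsimony_score >= exact
            hits += res.parsimony_score == exact
        assert hits >= 9

    def test_deterministic_under_fixed_seed(self, rng):
        presence = rng.random((7, 50)) < 0.5
        presence = presence[:, presence.any(axis=0)]
        m = matrix_from(presence)
        a = parsimony_ratchet(m, iterations=25, seed=9)
        b = parsimony_ratchet(m, iterations=25, seed=9)
        assert a.newick == b.newick and a.parsimony_score == b.parsimony_score

    def test_iteration_count_validated(self):
        m = matrix_from(np.ones((3, 2), dtype=bool))
        with pytest.raises(ValueError):
            parsimony_ratchet(m, iterations=0)

    def test_newick_is_well_formed(self, sim_patient):
        import dendropy

        variants, _, _, truth = sim_patient
        m = build_matrix(variants, sample_ids=truth.sample_ids)
        res = parsimony_ratchet(m, iterations=10, seed=4)
        tree = dendropy.Tree.get(data=res.newick, schema="newick", preserve_underscores=True)
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(m.sample_ids) | {"germline"}
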