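import itertools

import pytest

from cervikit.phylo import (
    CharacterizedTree,
    count_origins,
    enumerate_mprs,
    fitch_counts,
    format_report,
    parse_newick,
    run_scenarios,
)
from cervikit.synth import FIXTURE_SCENARIOS, fixture_characterized_tree, fixture_phylo


# ---------------------------------------------------------------------------
# Independent oracle: plain exhaustive minimum over all labelings, written
# directly against the dendropy node structure.
# ---------------------------------------------------------------------------

def oracle_min_changes(ctree: CharacterizedTree) -> int:
    nodes = list(ctree.tree.preorder_node_iter())
    root = ctree.tree.seed_node
    fixed, free = {}, []
    for node in nodes:
        if node.is_leaf() and ctree.tip_states[node.taxon.label] != "?":
            fixed[node] = int(ctree.tip_states[node.taxon.label])
        elif node is root and ctree.root_constraint is not None:
            fixed[node] = ctree.root_constraint
        else:
            free.append(node)
    best = None
    for states in itertools.product((0, 1), repeat=len(free)):
        lab = dict(fixed)
        lab.update(zip(free, states))
        changes = sum(lab[n] != lab[c] for n in nodes for c in n.child_nodes())
        best = changes if best is None else min(best, changes)
    return best


def random_ctree(rng, n_tips, allow_unknown=True):
    """Random topology (polytomies allowed), random states, random root rule."""
    parts = [f"t{i}" for i in range(n_tips)]
    while len(parts) > 1:
        k = min(len(parts), int(rng.integers(2, 4)))
        idx = rng.choice(len(parts), size=k, replace=False)
        group = "(" + ",".join(parts[i] for i in sorted(idx)) + ")"
        parts = [p for i, p in enumerate(parts) if i not in idx] + [group]
    tree = parse_newick(parts[0] + ";")
    states = {}
    for i in range(n_tips):
        r = rng.random()
        if allow_unknown and r < 0.15:
            states[f"t{i}"] = "?"
        else:
            states[f"t{i}"] = int(r < 0.5)
    if sum(1 for s in states.values() if s != "?") < 2:
        states["t0"], states["t1"] = 0, 1
    constraint = [None, 0, 1][int(rng.integers(0, 3))]
    return CharacterizedTree(tree, states, root_constraint=constraint)


class TestParseNewick:
    def test_basic_bifurcating(self):
        tree = parse_newick("(A,(B,C));")
        assert len(tree.leaf_nodes()) == 3
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 2

    def test_polytomy_preserved(self):
        tree = parse_newick("(A,B,C);")
        assert len(tree.seed_node.child_nodes()) == 3

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((A,B);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("(A,(A,B));")


class TestFitchCounts:
    def test_uniform_states_need_no_changes(self):
        ctree = CharacterizedTree(parse_newick("(A,(B,(C,D)));"),
                                  {t: 0 for t in "ABCD"})
        assert fitch_counts(ctree)[0] == 0

    def test_two_tip_free_root_has_two_mprs(self):
        ctree = CharacterizedTree(parse_newick("(A,B);"), {"A": 0, "B": 1})
        recon = enumerate_mprs(ctree)
        assert recon.min_changes == 1
        assert len(recon.mprs) == 2

    def test_oracle_equivalence_on_random_trees(self):
        """DP minimum equals exhaustive enumeration on 200 random trees."""
        import numpy as np
        rng = np.random.default_rng(2024)
        for _ in range(200):
            ctree = random_ctree(rng, int(rng.integers(3, 11)))
            expected = oracle_min_changes(ctree)
            assert fitch_counts(ctree)[0] == expected
            assert enumerate_mprs(ctree).min_changes == expected

    def test_unknown_tip_never_increases_changes(self):
        import numpy as np
        rng = np.random.default_rng(7)
        for _ in range(30):
            ctree = random_ctree(rng, 6, allow_unknown=False)
            base = fitch_counts(ctree)[0]
            # graft an unknown tip onto the root
            import dendropy
            taxon = dendropy.Taxon(label="extra")
            ctree.tree.taxon_namespace.add_taxon(taxon)
            node = ctree.tree.seed_node.new_child()
            node.taxon = taxon
            states = dict(ctree.tip_states, extra="?")
            grown = CharacterizedTree(ctree.tree, states, ctree.root_constraint)
            assert fitch_counts(grown)[0] == base

    def test_state_relabeling_symmetry(self):
        import numpy as np
        rng = np.random.default_rng(13)
        for _ in range(30):
            ctree = random_ctree(rng, 7)
            flipped_states = {t: (s if s == "?" else 1 - s)
                              for t, s in ctree.tip_states.items()}
            flipped_constraint = (None if ctree.root_constraint is None
                                  else 1 - ctree.root_constraint)
            flipped = CharacterizedTree(ctree.tree, flipped_states,
                                        flipped_constraint)
            assert fitch_counts(ctree)[0] == fitch_counts(flipped)[0]
            a = enumerate_mprs(ctree)
            b = enumerate_mprs(flipped)
            assert sorted(a.origins_of(1)) == sorted(b.origins_of(0))


class TestOrigins:
    def test_all_ancestral_has_no_origins(self):
        ctree = CharacterizedTree(parse_newick("(A,(B,C));"),
                                  {t: 0 for t in "ABC"}, root_constraint=0)
        lo, hi, _ = count_origins(enumerate_mprs(ctree))
        assert (lo, hi) == (0, 0)

    def test_single_derived_tip_on_chain(self):
        ctree = CharacterizedTree(parse_newick("(A,(B,(C,D)));"),
                                  {"A": 0, "B": 0, "C": 0, "D": 1},
                                  root_constraint=0)
        lo, hi, _ = count_origins(enumerate_mprs(ctree))
        assert (lo, hi) == (1, 1)

    def test_derived_root_counts_as_origin(self):
        ctree = CharacterizedTree(parse_newick("(A,B);"), {"A": 1, "B": 1},
                                  root_constraint=1)
        recon = enumerate_mprs(ctree)
        assert recon.origins_of(1) == [1]


@pytest.fixture(scope="module")
def reports():
    ctree = fixture_characterized_tree()
    return run_scenarios(ctree, FIXTURE_SCENARIOS)


class TestEuarchontogliresFixture:
    """The shipped progesterone-withdrawal character under both mouse-lemur
    assumptions (state 1 = no systemic withdrawal / FPW)."""

    def test_fixture_shape(self):
        newick, chars, scenarios = fixture_phylo()
        tree = parse_newick(newick)
        assert len(tree.leaf_nodes()) == 16
        assert chars.loc[chars["taxon"] == "MouseLemur", "state"].iloc[0] == "?"
        assert set(scenarios) == {"lemur=0", "lemur=1"}

    def test_min_changes_per_scenario(self, reports):
        assert reports["lemur=1"]["min_changes"] == 3
        assert reports["lemur=0"]["min_changes"] == 4

    def test_fpw_arises_twice_in_both_scenarios(self, reports):
        for rep in reports.values():
            assert rep["origins"]["min"] == 2

    def test_lemur_fpw_makes_euarchonta_ancestrally_fpw(self, reports):
        assert reports["lemur=1"]["ancestors"]["Euarchonta"] == [1]
        # marmoset is then a reversal: its parent is derived in every MPR
        recon = reports["lemur=1"]["reconstruction"]
        marmoset = [l for l in recon.ctree.tree.leaf_node_iter()
                    if l.taxon.label == "Marmoset"][0]
        assert all(mpr[marmoset.parent_node] == 1 and mpr[marmoset] == 0
                   for mpr in recon.mprs)

    def test_lemur_withdrawal_leaves_primate_stem_ambiguous(self, reports):
        assert reports["lemur=0"]["ancestors"]["Primates"] == [0, 1]

    def test_glires_ancestor_is_withdrawal_in_both(self, reports):
        for rep in reports.values():
            assert rep["ancestors"]["Glires"] == [0]

    def test_guinea_pig_origin_lies_within_glires(self, reports):
        for rep in reports.values():
            recon = rep["reconstruction"]
            gp = [l for l in recon.ctree.tree.leaf_node_iter()
                  if l.taxon.label == "GuineaPig"][0]
            glires = recon.ctree.mrca(["Rabbit", "Rat"])
            glires_nodes = set(glires.preorder_iter())
            for mpr in recon.mprs:
                derived = [n for n in glires_nodes if mpr[n] == 1]
                assert derived == [gp]

    def test_report_formatting_mentions_ambiguity(self, reports):
        text = format_report(reports)
        assert "scenario lemur=0" in text and "ambiguous" in text


class TestGuards:
    def test_scenario_with_unknown_taxon_rejected(self):
        ctree = fixture_characterized_tree()
        with pytest.raises(ValueError, match="unknown taxa"):
            run_scenarios(ctree, {"bad": {"Dodo": 1}})

    def test_enumeration_guard(self):
        tips = {f"t{i}": i % 2 for i in range(30)}
        # caterpillar tree with 29 internal nodes exceeds the guard
        cat = "t0"
        for i in range(1, 30):
            cat = f"({cat},t{i})"
        ctree = CharacterizedTree(parse_newick(cat + ";"), tips)
        with pytest.raises(ValueError, match="guard"):
            enumerate_mprs(ctree)
        # the DP path still works
        assert fitch_counts(ctree)[0] >= 1
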