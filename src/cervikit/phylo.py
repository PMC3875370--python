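"""Parsimony reconstruction of a binary character on a rooted tree.

Built for one question: how often did functional progesterone withdrawal
(FPW, state 1 = no pre-partum drop in systemic progesterone) arise on the
Euarchontoglires phylogeny, given the ancestral condition of systemic
withdrawal (state 0)? The machinery is generic, though: any rooted tree
(polytomies allowed), binary tip states with ``?`` for unknown taxa, and an
optional fixed root state.

Two routes to the same answer are provided on purpose:

* :func:`fitch_counts` — a linear-time dynamic program (Sankoff-style
  integer costs, which on binary unordered characters reduces to the
  Fitch/Hartigan count, generalized to polytomies) giving the minimum
  number of state changes and the per-node downpass state sets;
* :func:`enumerate_mprs` — exact enumeration of every most-parsimonious
  reconstruction (MPR), the authoritative path at the scales used here
  (the guard refuses trees with more than 25 free nodes).

Origins of the derived state are counted per MPR as edges whose parent is
not in the derived state while the child is; a root labeled with the
derived state counts as one origin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

UNKNOWN = "?"

#: Refuse exact MPR enumeration beyond this many free (unfixed) nodes.
ENUMERATION_GUARD = 25


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted newick string; polytomies are preserved.

    Raises ``ValueError`` on malformed newick or duplicate tip names.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip name(s): {dup}")
    tree.is_rooted = True
    return tree


@dataclass
class CharacterizedTree:
    """A rooted tree plus binary tip states and an optional root constraint.

    ``tip_states`` maps every tip label to 0, 1 or ``'?'`` (unknown);
    ``root_constraint`` fixes the root's state (or ``None`` for a free root).
    """

    tree: dendropy.Tree
    tip_states: Mapping[str, int | str]
    root_constraint: int | None = None

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = tips - set(self.tip_states)
        if missing:
            raise ValueError(f"tips without a state: {sorted(missing)}")
        extra = set(self.tip_states) - tips
        if extra:
            raise ValueError(f"states for unknown taxa: {sorted(extra)}")
        clean: dict[str, int | str] = {}
        for taxon, state in self.tip_states.items():
            if state in (0, 1):
                clean[taxon] = int(state)
            elif str(state) in ("0", "1"):
                clean[taxon] = int(str(state))
            elif str(state) == UNKNOWN:
                clean[taxon] = UNKNOWN
            else:
                raise ValueError(f"invalid state {state!r} for taxon {taxon!r}")
        self.tip_states = clean
        if self.root_constraint not in (None, 0, 1):
            raise ValueError("root_constraint must be 0, 1 or None")
        known = [s for s in clean.values() if s != UNKNOWN]
        if len(known) < 2:
            raise ValueError("need at least 2 tips with known states")

    def with_states(self, overrides: Mapping[str, int | str]) -> "CharacterizedTree":
        """New characterized tree with some tip states replaced."""
        unknown = set(overrides) - set(self.tip_states)
        if unknown:
            raise ValueError(f"scenario names unknown taxa: {sorted(unknown)}")
        states = dict(self.tip_states)
        states.update(overrides)
        return CharacterizedTree(self.tree, states, self.root_constraint)

    def mrca(self, tip_labels: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of the named tips."""
        labels = list(tip_labels)
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:
            raise ValueError(f"no MRCA found for {labels}")
        return node


def _node_costs(ctree: CharacterizedTree) -> dict[dendropy.Node, tuple[float, float]]:
    """Postorder minimum-change costs (cost if node = 0, cost if node = 1).

    Unknown tips cost 0 in either state, so they can never force a change.
    """
    costs: dict[dendropy.Node, tuple[float, float]] = {}
    for node in ctree.tree.postorder_node_iter():
        if node.is_leaf():
            state = ctree.tip_states[node.taxon.label]
            if state == UNKNOWN:
                costs[node] = (0.0, 0.0)
            else:
                costs[node] = (0.0, float("inf")) if state == 0 else (float("inf"), 0.0)
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = costs[child]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            costs[node] = (c0, c1)
    return costs


def fitch_counts(ctree: CharacterizedTree) -> tuple[int, dict[dendropy.Node, frozenset[int]]]:
    """Minimum number of state changes and per-node downpass state sets.

    The downpass set of a node is the set of states achieving its minimum
    subtree cost. The root constraint restricts which root state counts;
    if the constrained state is costlier than the free optimum, the extra
    changes are included in the returned minimum.
    """
    costs = _node_costs(ctree)
    root = ctree.tree.seed_node
    r0, r1 = costs[root]
    if ctree.root_constraint is None:
        min_changes = min(r0, r1)
    else:
        min_changes = (r0, r1)[ctree.root_constraint]
    if min_changes == float("inf"):
        raise ValueError("root constraint is incompatible with the tip states")
    sets = {}
    for node, (c0, c1) in costs.items():
        best = min(c0, c1)
        sets[node] = frozenset(s for s, c in ((0, c0), (1, c1)) if c == best)
    return int(min_changes), sets


@dataclass
class Reconstruction:
    """All most-parsimonious reconstructions of a characterized tree.

    ``mprs`` is the full list of optimal labelings (node -> state, tips
    included); ``node_state_sets`` is, per node, the union of its states
    over all MPRs — a set of size 2 marks an ambiguous ancestor.
    """

    ctree: CharacterizedTree
    min_changes: int
    mprs: list[dict[dendropy.Node, int]]
    node_state_sets: dict[dendropy.Node, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_state_sets:
            self.node_state_sets = {
                node: frozenset(mpr[node] for mpr in self.mprs)
                for node in self.ctree.tree.preorder_node_iter()
            }

    def states_at(self, node: dendropy.Node) -> frozenset[int]:
        return self.node_state_sets[node]

    def states_at_mrca(self, tip_labels: Iterable[str]) -> frozenset[int]:
        return self.states_at(self.ctree.mrca(tip_labels))

    def origins_of(self, derived_state: int = 1) -> list[int]:
        """Per-MPR count of independent origins of ``derived_state``."""
        out = []
        for mpr in self.mprs:
            n = 0
            root = self.ctree.tree.seed_node
            if mpr[root] == derived_state:
                n += 1
            for node in self.ctree.tree.preorder_node_iter():
                for child in node.child_nodes():
                    if mpr[node] != derived_state and mpr[child] == derived_state:
                        n += 1
            out.append(n)
        return out


def enumerate_mprs(ctree: CharacterizedTree) -> Reconstruction:
    """Exhaustively enumerate every most-parsimonious reconstruction.

    Free nodes (internal nodes plus unknown tips, minus a constrained root)
    are assigned all 2^n binary labelings; labelings achieving the minimum
    change count are kept. Exponential by construction — guarded at
    ``ENUMERATION_GUARD`` free nodes.
    """
    nodes = list(ctree.tree.preorder_node_iter())
    fixed: dict[dendropy.Node, int] = {}
    free: list[dendropy.Node] = []
    root = ctree.tree.seed_node
    for node in nodes:
        if node.is_leaf():
            state = ctree.tip_states[node.taxon.label]
            if state == UNKNOWN:
                free.append(node)
            else:
                fixed[node] = int(state)
        elif node is root and ctree.root_constraint is not None:
            fixed[node] = ctree.root_constraint
        else:
            free.append(node)
    if len(free) > ENUMERATION_GUARD:
        raise ValueError(
            f"{len(free)} free nodes exceeds the exact-enumeration guard "
            f"({ENUMERATION_GUARD}); use fitch_counts for the change count")

    edges = [(node, child) for node in nodes for child in node.child_nodes()]
    best = None
    best_labelings: list[dict[dendropy.Node, int]] = []
    for assignment in itertools.product((0, 1), repeat=len(free)):
        labeling = dict(fixed)
        labeling.update(zip(free, assignment))
        changes = sum(1 for parent, child in edges
                      if labeling[parent] != labeling[child])
        if best is None or changes < best:
            best = changes
            best_labelings = [labeling]
        elif changes == best:
            best_labelings.append(labeling)
    assert best is not None
    return Reconstruction(ctree=ctree, min_changes=int(best), mprs=best_labelings)


def count_origins(reconstruction: Reconstruction, derived_state: int = 1
                  ) -> tuple[int, int, list[int]]:
    """(min, max, per-MPR) independent origins of ``derived_state``.

    An origin is an edge from a non-derived parent to a derived child; a
    root labeled derived counts as one origin (impossible when the root is
    fixed to the ancestral state).
    """
    detail = reconstruction.origins_of(derived_state)
    return min(detail), max(detail), detail


#: Named ancestors of interest on the Euarchontoglires fixture, defined by
#: tip pairs whose MRCA they are.
FIXTURE_ANCESTORS = {
    "Euarchonta": ("Tupaia", "Human"),
    "Primates": ("MouseLemur", "Human"),
    "Glires": ("Rabbit", "Rat"),
    "Euarchontoglires": ("Tupaia", "Rat"),
}


def run_scenarios(ctree: CharacterizedTree,
                  scenarios: Mapping[str, Mapping[str, int | str]] | None = None,
                  ancestors: Mapping[str, Sequence[str]] | None = None,
                  derived_state: int = 1) -> dict[str, dict]:
    """Run MPR enumeration under alternative tip-state assumptions.

    ``scenarios`` maps a scenario name to tip-state overrides (e.g.
    ``{"lemur=1": {"MouseLemur": 1}}``); an empty/None mapping runs the raw
    matrix once under the name ``"base"``. Each report gives the minimum
    change count, the origin range of the derived state, and the MPR state
    sets of the named ancestors (defaulting to the Euarchontoglires clades
    when their tips are present).
    """
    if not scenarios:
        scenarios = {"base": {}}
    if ancestors is None:
        tips = {leaf.taxon.label for leaf in ctree.tree.leaf_node_iter()}
        ancestors = {name: pair for name, pair in FIXTURE_ANCESTORS.items()
                     if set(pair) <= tips}
    reports: dict[str, dict] = {}
    for name, overrides in scenarios.items():
        scen_tree = ctree.with_states(overrides)
        recon = enumerate_mprs(scen_tree)
        lo, hi, detail = count_origins(recon, derived_state)
        reports[name] = {
            "min_changes": recon.min_changes,
            "n_mprs": len(recon.mprs),
            "origins": {"min": lo, "max": hi, "per_mpr": detail},
            "ancestors": {anc: sorted(recon.states_at_mrca(tips))
                          for anc, tips in ancestors.items()},
            "reconstruction": recon,
        }
    return reports


def format_report(reports: dict[str, dict], derived_state: int = 1) -> str:
    """Plain-text rendering of :func:`run_scenarios` output."""
    lines = []
    for name, rep in reports.items():
        lines.append(f"scenario {name}:")
        lines.append(f"  minimum changes: {rep['min_changes']}  "
                     f"(over {rep['n_mprs']} MPRs)")
        o = rep["origins"]
        lines.append(f"  origins of state {derived_state}: "
                     f"{o['min']}" + ("" if o["min"] == o["max"] else f"-{o['max']}"))
        for anc, states in rep["ancestors"].items():
            txt = "/".join(str(s) for s in states)
            tag = " (ambiguous)" if len(states) > 1 else ""
            lines.append(f"  {anc} ancestor: {txt}{tag}")
    return "\n".join(lines)
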