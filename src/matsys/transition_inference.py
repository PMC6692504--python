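"""Ancestral-state reconstruction of mating-compatibility systems by parsimony.

Given a rooted species tree and a map of tip species to one of the seven
mating-system categories (HET, 3LOC, FF1, FF2, PHC, PHN, NOMAT), this module
reconstructs ancestral states with minimum-change (Fitch/Sankoff) parsimony,
resolves ambiguity by explicit, logged policies, and counts evolutionary
transitions between systems, including the number of independent origins of
mating-type switching (entries into the {FF1, FF2, 3LOC} set of states).

Branch lengths are parsed but ignored: the reconstruction is cladistic.
Trees are used as rooted, exactly as supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import dendropy

STATES: Tuple[str, ...] = ("HET", "3LOC", "FF1", "FF2", "PHC", "PHN", "NOMAT")

#: Secondary-homothallic (mating-type switching) categories.
SWITCHING_STATES: FrozenSet[str] = frozenset({"FF1", "FF2", "3LOC"})

#: Homothallic categories (primary and secondary).
HOMOTHALLIC_STATES: FrozenSet[str] = frozenset({"PHC", "PHN", "FF1", "FF2", "3LOC"})

#: Fixed priority used to break remaining ties after parent-state preference.
#: Heterothallism first: derived systems are repeatedly observed to arise from
#: heterothallic ancestors, so ambiguous deep nodes resolve toward HET, then
#: toward primary homothallism, then toward the switching systems.
DEFAULT_PRIORITY: Tuple[str, ...] = ("HET", "PHC", "PHN", "FF1", "FF2", "3LOC", "NOMAT")

_PRIORITY_RANK = {s: i for i, s in enumerate(DEFAULT_PRIORITY)}

_INF = float("inf")


class TreeError(ValueError):
    """Raised for malformed Newick input or tree/state-map mismatches."""


@dataclass(frozen=True)
class PhyloTree:
    """A rooted phylogeny with uniquely named tips.

    Thin wrapper over a :class:`dendropy.Tree`; nodes are addressed by a
    stable integer index assigned in postorder, with tips carrying species
    names and internal nodes optionally named.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        names = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(names) < 2:
            raise TreeError("tree must have at least 2 tips")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate tip names: {dup}")
        # stable postorder indexing
        for i, node in enumerate(self.tree.postorder_node_iter()):
            node.index = i

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def tip_names(self) -> List[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def postorder(self) -> List["dendropy.Node"]:
        return list(self.tree.postorder_node_iter())

    def preorder(self) -> List["dendropy.Node"]:
        return list(self.tree.preorder_node_iter())

    @property
    def root(self) -> "dendropy.Node":
        return self.tree.seed_node

    @staticmethod
    def node_label(node: "dendropy.Node") -> str:
        if node.taxon is not None:
            return node.taxon.label
        if node.label:
            return node.label
        return f"n{node.index}"


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Branch lengths and quoted labels are accepted; lengths are ignored by all
    downstream operations. Raises :class:`TreeError` on unbalanced
    parentheses, a missing semicolon, or duplicate tip names.
    """
    if not text.strip():
        raise TreeError("empty Newick string")
    if not text.strip().endswith(";"):
        raise TreeError("Newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return PhyloTree(tree)


def read_newick(path: str) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# State maps
# ---------------------------------------------------------------------------


def validate_state_map(states: Mapping[str, str]) -> Dict[str, str]:
    out = {}
    for sp, st in states.items():
        if st not in STATES:
            raise ValueError(f"unknown state {st!r} for species {sp!r}; "
                             f"valid states: {STATES}")
        out[sp] = st
    return out


def read_state_map(path: str) -> Dict[str, str]:
    """Read a two-column TSV (species, category) into a state map."""
    states: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "species":  # header
                continue
            states[parts[0]] = parts[1]
    return validate_state_map(states)


# ---------------------------------------------------------------------------
# Reconstruction containers
# ---------------------------------------------------------------------------


@dataclass
class Reconstruction:
    """Result of an ancestral-state reconstruction.

    ``candidate_states`` holds, per node, the set of states that occur in at
    least one most-parsimonious reconstruction; ``resolved`` holds the single
    state chosen for each node by the tie-break policy. The resolved labeling
    always attains the parsimony minimum ``n_changes``.
    """

    tree: PhyloTree
    candidate_states: Dict[int, FrozenSet[str]]
    resolved: Dict[int, str]
    policy: str
    n_changes: int

    def resolved_by_label(self) -> Dict[str, str]:
        return {
            PhyloTree.node_label(node): self.resolved[node.index]
            for node in self.tree.postorder()
        }

    def to_newick(self) -> str:
        """Serialize the tree with every node labelled by its resolved state."""

        def fmt(node) -> str:
            state = self.resolved[node.index]
            if node.is_leaf():
                return f"{node.taxon.label}[&state={state}]"
            inner = ",".join(fmt(c) for c in node.child_nodes())
            return f"({inner}){state}"

        return fmt(self.tree.root) + ";"


@dataclass
class TransitionSummary:
    """Branch-level state-change events and their aggregate counts."""

    events: List[Tuple[str, str, str, str]] = field(default_factory=list)
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def to_homothallism(self) -> int:
        return sum(
            n for (a, b), n in self.counts.items()
            if a == "HET" and b in HOMOTHALLIC_STATES
        )

    @property
    def to_heterothallism(self) -> int:
        return sum(
            n for (a, b), n in self.counts.items()
            if a in HOMOTHALLIC_STATES and b == "HET"
        )

    @property
    def switching_origins(self) -> int:
        return sum(
            n for (a, b), n in self.counts.items()
            if a not in SWITCHING_STATES and b in SWITCHING_STATES
        )

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "counts": {f"{a}->{b}": n for (a, b), n in sorted(self.counts.items())},
            "to_homothallism": self.to_homothallism,
            "to_heterothallism": self.to_heterothallism,
            "switching_origins": self.switching_origins,
            "events": [
                {"parent": p, "child": c, "from": a, "to": b}
                for p, c, a, b in self.events
            ],
        }


# ---------------------------------------------------------------------------
# Sankoff dynamic programme (Fitch == Sankoff with uniform 0/1 costs)
# ---------------------------------------------------------------------------


def _uniform_costs() -> Dict[Tuple[str, str], float]:
    return {(a, b): (0.0 if a == b else 1.0) for a in STATES for b in STATES}


def _tip_costs(node, states: Mapping[str, str], missing: str) -> Dict[str, float]:
    name = node.taxon.label
    if name not in states:
        if missing == "uninformative":
            return {s: 0.0 for s in STATES}
        raise TreeError(f"tip {name!r} has no state in the state map")
    return {s: (0.0 if s == states[name] else _INF) for s in STATES}


def _sankoff_down(
    tree: PhyloTree,
    states: Mapping[str, str],
    costs: Mapping[Tuple[str, str], float],
    missing: str,
) -> Dict[int, Dict[str, float]]:
    """Bottom-up pass: dp[node][s] = min cost of node's subtree given state s."""
    dp: Dict[int, Dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            dp[node.index] = _tip_costs(node, states, missing)
        else:
            row = {}
            for s in STATES:
                total = 0.0
                for child in node.child_nodes():
                    total += min(
                        dp[child.index][t] + costs[(s, t)] for t in STATES
                    )
                row[s] = total
            dp[node.index] = row
    return dp


def _sankoff_up(
    tree: PhyloTree,
    dp: Dict[int, Dict[str, float]],
    costs: Mapping[Tuple[str, str], float],
) -> Dict[int, Dict[str, float]]:
    """Top-down pass: up[node][s] = min cost of the rest of the tree given
    that ``node`` has state s. Used to compute MPR-membership state sets."""
    up: Dict[int, Dict[str, float]] = {tree.root.index: {s: 0.0 for s in STATES}}
    for node in tree.preorder():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        # For each child, cost contributed by the other children given node
        # state t, plus the cost above the node.
        for child in children:
            row = {}
            for s in STATES:
                best = _INF
                for t in STATES:
                    above = up[node.index][t]
                    if above == _INF:
                        continue
                    sib_cost = 0.0
                    for other in children:
                        if other is child:
                            continue
                        sib_cost += min(
                            dp[other.index][u] + costs[(t, u)] for u in STATES
                        )
                    cand = above + sib_cost + costs[(t, s)]
                    if cand < best:
                        best = cand
                row[s] = best
            up[child.index] = row
    return up


def _resolve_top_down(
    tree: PhyloTree,
    dp: Dict[int, Dict[str, float]],
    costs: Mapping[Tuple[str, str], float],
    root_choice: Optional[str] = None,
) -> Dict[int, str]:
    """Resolve one state per node: root by minimum cost (ties by the fixed
    priority), children by parent-state preference among locally optimal
    states. The result always attains the parsimony minimum."""
    resolved: Dict[int, str] = {}
    root = tree.root
    if root_choice is None:
        best = min(dp[root.index].values())
        candidates = [s for s in DEFAULT_PRIORITY if dp[root.index][s] == best]
        root_choice = candidates[0]
    resolved[root.index] = root_choice
    for node in tree.preorder():
        if node.is_leaf():
            continue
        p_state = resolved[node.index]
        for child in node.child_nodes():
            row = dp[child.index]
            best = min(row[t] + costs[(p_state, t)] for t in STATES)
            opts = [t for t in STATES if row[t] + costs[(p_state, t)] == best]
            if p_state in opts:
                choice = p_state
            else:
                choice = min(opts, key=lambda t: _PRIORITY_RANK[t])
            resolved[child.index] = choice
    return resolved


def _count_changes(tree: PhyloTree, resolved: Mapping[int, str]) -> int:
    n = 0
    for node in tree.preorder():
        for child in node.child_nodes():
            if resolved[node.index] != resolved[child.index]:
                n += 1
    return n


# Lexicographic branch weights for the prefer_gains policy: minimize changes
# first, then maximize gains (HET -> non-HET), then minimize losses
# (non-HET -> HET). Lexicographic tuples are compatible with addition, so the
# Sankoff recursion remains exact.
def _gain_weight(a: str, b: str) -> Tuple[float, float, float]:
    change = 0.0 if a == b else 1.0
    gain = 1.0 if (a == "HET" and b != "HET") else 0.0
    loss = 1.0 if (a != "HET" and b == "HET") else 0.0
    return (change, -gain, loss)


def _resolve_prefer_gains(
    tree: PhyloTree, states: Mapping[str, str], missing: str
) -> Dict[int, str]:
    zero = (0.0, 0.0, 0.0)
    inf3 = (_INF, 0.0, 0.0)

    def add(x, y):
        return (x[0] + y[0], x[1] + y[1], x[2] + y[2])

    dp: Dict[int, Dict[str, Tuple[float, float, float]]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            base = _tip_costs(node, states, missing)
            dp[node.index] = {
                s: (zero if base[s] == 0.0 else inf3) for s in STATES
            }
        else:
            row = {}
            for s in STATES:
                total = zero
                for child in node.child_nodes():
                    best = min(
                        add(dp[child.index][t], _gain_weight(s, t))
                        for t in STATES
                    )
                    total = add(total, best)
                row[s] = total
            dp[node.index] = row

    resolved: Dict[int, str] = {}
    root = tree.root
    best = min(dp[root.index].values())
    resolved[root.index] = min(
        (s for s in STATES if dp[root.index][s] == best),
        key=lambda s: _PRIORITY_RANK[s],
    )
    for node in tree.preorder():
        if node.is_leaf():
            continue
        p = resolved[node.index]
        for child in node.child_nodes():
            row = dp[child.index]
            best = min(add(row[t], _gain_weight(p, t)) for t in STATES)
            opts = [t for t in STATES if add(row[t], _gain_weight(p, t)) == best]
            if p in opts:
                choice = p
            else:
                choice = min(opts, key=lambda t: _PRIORITY_RANK[t])
            resolved[child.index] = choice
    return resolved


def reconstruct_states(
    tree: PhyloTree,
    states: Mapping[str, str],
    policy: str = "default",
    costs: Optional[Mapping[Tuple[str, str], float]] = None,
    missing: str = "strict",
) -> Reconstruction:
    """Reconstruct ancestral mating-system states by parsimony.

    Parameters
    ----------
    tree
        Rooted species tree.
    states
        Map from tip species name to category. Under ``missing='strict'``
        every tip must be mapped; ``missing='uninformative'`` treats unmapped
        tips as missing data (all states equally cheap).
    policy
        ``'default'``: Sankoff/Fitch bottom-up followed by a top-down pass
        that keeps the parent's resolved state when it is locally optimal and
        otherwise falls back to the fixed HET-first priority.
        ``'prefer_gains'``: among all most-parsimonious reconstructions,
        select one maximizing the number of gain events (HET to non-HET),
        breaking remaining ties by fewest loss events and then by the fixed
        priority in preorder.
    costs
        Optional asymmetric cost matrix keyed by ``(from, to)`` state pairs;
        defaults to uniform 0/1 costs (Fitch parsimony).

    Returns
    -------
    Reconstruction
        Candidate (MPR-membership) state sets, one resolved state per node,
        and the minimum implied change count.
    """
    states = validate_state_map(states)
    tip_names = set(tree.tip_names())
    # extra species in the map are harmless; only tree tips are checked
    if missing == "strict":
        unmapped = tip_names - set(states)
        if unmapped:
            raise TreeError(
                f"tips without a state: {sorted(unmapped)}; "
                "use missing='uninformative' to treat them as missing data"
            )
    cost = dict(costs) if costs is not None else _uniform_costs()
    dp = _sankoff_down(tree, states, cost, missing)
    up = _sankoff_up(tree, dp, cost)
    best_total = min(dp[tree.root.index].values())
    candidate: Dict[int, FrozenSet[str]] = {}
    for node in tree.postorder():
        totals = {
            s: dp[node.index][s] + up[node.index][s] for s in STATES
        }
        candidate[node.index] = frozenset(
            s for s in STATES if totals[s] == best_total
        )
    if policy == "default":
        resolved = _resolve_top_down(tree, dp, cost)
    elif policy == "prefer_gains":
        if costs is not None:
            raise ValueError("prefer_gains is defined for uniform costs only")
        resolved = _resolve_prefer_gains(tree, states, missing)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    n_changes = _count_changes(tree, resolved)
    return Reconstruction(
        tree=tree,
        candidate_states=candidate,
        resolved=resolved,
        policy=policy,
        n_changes=n_changes,
    )


def parsimony_minimum(
    tree: PhyloTree,
    states: Mapping[str, str],
    costs: Optional[Mapping[Tuple[str, str], float]] = None,
    missing: str = "strict",
) -> float:
    """Minimum total change count (or cost) over all labelings."""
    cost = dict(costs) if costs is not None else _uniform_costs()
    dp = _sankoff_down(tree, validate_state_map(states), cost, missing)
    return min(dp[tree.root.index].values())


# ---------------------------------------------------------------------------
# MPR enumeration
# ---------------------------------------------------------------------------


def enumerate_mprs(
    tree: PhyloTree,
    states: Mapping[str, str],
    max_tips: int = 16,
    max_mprs: int = 100_000,
    missing: str = "strict",
) -> List[Dict[int, str]]:
    """Enumerate every most-parsimonious labeling of the tree.

    Each returned labeling maps node index to state and attains the Fitch
    minimum change count; the set is complete. ``max_tips`` guards against
    enumeration on large trees (raise it explicitly for condensed clade
    trees); ``max_mprs`` caps the size of the returned set.
    """
    if tree.n_tips > max_tips:
        raise TreeError(
            f"tree has {tree.n_tips} tips > max_tips={max_tips}; use a "
            "resolution policy (reconstruct_states) or raise max_tips"
        )
    states = validate_state_map(states)
    cost = _uniform_costs()
    dp = _sankoff_down(tree, states, cost, missing)
    root = tree.root
    best = min(dp[root.index].values())

    results: List[Dict[int, str]] = []

    def _expand(node, labeling: Dict[int, str]) -> List[Dict[int, str]]:
        children = node.child_nodes()
        if not children:
            return [labeling]
        s = labeling[node.index]
        options = []
        for child in children:
            row = dp[child.index]
            loc = min(row[t] + cost[(s, t)] for t in STATES)
            options.append([t for t in STATES if row[t] + cost[(s, t)] == loc])
        out = [labeling]
        for child, opts in zip(children, options):
            nxt: List[Dict[int, str]] = []
            for partial in out:
                for t in opts:
                    lab = dict(partial)
                    lab[child.index] = t
                    nxt.extend(_expand(child, lab))
                    if len(nxt) > max_mprs:
                        raise TreeError(
                            f"more than {max_mprs} MPRs; raise max_mprs"
                        )
            out = nxt
        return out

    for s in STATES:
        if dp[root.index][s] == best:
            for lab in _expand(root, {root.index: s}):
                results.append(lab)
    return results


def labeling_changes(tree: PhyloTree, labeling: Mapping[int, str]) -> int:
    return _count_changes(tree, labeling)


def labeling_gains_losses(
    tree: PhyloTree, labeling: Mapping[int, str]
) -> Tuple[int, int]:
    """Count (HET->non-HET, non-HET->HET) events of a labeling."""
    gains = losses = 0
    for node in tree.preorder():
        a = labeling[node.index]
        for child in node.child_nodes():
            b = labeling[child.index]
            if a == "HET" and b != "HET":
                gains += 1
            elif a != "HET" and b == "HET":
                losses += 1
    return gains, losses


# ---------------------------------------------------------------------------
# Transition counting
# ---------------------------------------------------------------------------


def count_transitions(rec: Reconstruction) -> TransitionSummary:
    """One event per branch whose resolved endpoint states differ."""
    summary = TransitionSummary()
    for node in rec.tree.preorder():
        a = rec.resolved[node.index]
        for child in node.child_nodes():
            b = rec.resolved[child.index]
            if a != b:
                summary.events.append(
                    (
                        PhyloTree.node_label(node),
                        PhyloTree.node_label(child),
                        a,
                        b,
                    )
                )
                summary.counts[(a, b)] = summary.counts.get((a, b), 0) + 1
    return summary


def count_switching_origins(summary: TransitionSummary) -> int:
    """Events entering the switching set {FF1, FF2, 3LOC} from outside it."""
    return summary.switching_origins
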