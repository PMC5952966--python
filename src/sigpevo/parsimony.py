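"""Fitch parsimony and branch-level event calling.

Ancestral secretion states (binary: 0 = no signal peptide, 1 = signal
peptide) and lifestyle states (0 = free-living, 1 = endosymbiont,
2 = commensal) are reconstructed on rooted cluster trees with the Fitch
dynamic program: bottom-up, a node's state set is the intersection of its
children's sets when nonempty, otherwise the union (each union costs one
change); top-down, a node's final set is its bottom-up set intersected with
the parent's final set when nonempty, otherwise its bottom-up set.

Every branch is then classified into exactly one of five types: gain
({0}->{1}), loss ({1}->{0}), uncertain (an ambiguous endpoint), keep_sp, or
stay_no_sp.  The root has no parent branch and generates no event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import dendropy
import pandas as pd

from .types import RANKS, Event

EVENT_TYPES = ("gain", "loss", "uncertain", "keep_sp", "stay_no_sp")
TRANSITION_CLASSES = ("to_free_living", "to_endosymbiont", "to_commensal",
                      "uncertain_transition")


@dataclass
class StateReconstruction:
    """Per-node Fitch state sets for one discrete character."""

    character: str
    bottom_up: dict[str, frozenset]
    final: dict[str, frozenset]
    changes: int


@dataclass
class LifestyleReconstruction:
    """3-state lifestyle reconstruction with per-branch transition classes."""

    reconstruction: StateReconstruction
    transitions: dict[tuple[str, str], str] = field(default_factory=dict)


def node_key(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return node.label


def ensure_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign deterministic labels to unlabeled internal nodes (preorder)."""
    taken = {node_key(n) for n in tree if node_key(n) is not None}
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            while f"N{k}" in taken:
                k += 1
            node.label = f"N{k}"
            taken.add(node.label)
    return tree


def _min_leaf_label(node: dendropy.Node) -> str:
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def binarize(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve polytomies deterministically (children ordered by their
    smallest descendant leaf label) with zero-length branches."""
    for node in list(tree.preorder_node_iter()):
        children = sorted(node.child_nodes(), key=_min_leaf_label)
        while len(children) > 2:
            a, b = children[0], children[1]
            node.remove_child(a)
            node.remove_child(b)
            merged = dendropy.Node(edge_length=0.0)
            merged.add_child(a)
            merged.add_child(b)
            node.add_child(merged)
            children = [merged] + children[2:]
    return ensure_labels(tree)


def fitch(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, int],
    n_states: int = 2,
    character: str = "sp",
) -> StateReconstruction:
    """Fitch parsimony reconstruction of a discrete character on a rooted tree.

    ``leaf_states`` maps leaf (taxon) labels to observed states in
    ``range(n_states)``.  Returns bottom-up and final state sets per node key
    and the minimal number of state changes.
    """
    ensure_labels(tree)
    valid = frozenset(range(n_states))
    bottom_up: dict[str, frozenset] = {}
    changes = 0
    for node in tree.postorder_node_iter():
        key = node_key(node)
        if node.is_leaf():
            label = node.taxon.label
            if label not in leaf_states:
                raise KeyError(f"no observed state for leaf {label!r}")
            state = leaf_states[label]
            if state not in valid:
                raise ValueError(f"leaf {label!r} has state {state} "
                                 f"outside range({n_states})")
            bottom_up[key] = frozenset({state})
        else:
            sets = [bottom_up[node_key(c)] for c in node.child_nodes()]
            acc = sets[0]
            for s in sets[1:]:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    changes += 1
            bottom_up[key] = acc
    final: dict[str, frozenset] = {}
    for node in tree.preorder_node_iter():
        key = node_key(node)
        if node.parent_node is None:
            final[key] = bottom_up[key]
        else:
            parent_final = final[node_key(node.parent_node)]
            inter = bottom_up[key] & parent_final
            final[key] = inter if inter else bottom_up[key]
    return StateReconstruction(character, bottom_up, final, changes)


def classify_branch(parent_final: frozenset, child_final: frozenset) -> str:
    if len(parent_final) > 1 or len(child_final) > 1:
        return "uncertain"
    p, c = next(iter(parent_final)), next(iter(child_final))
    if p == 0 and c == 1:
        return "gain"
    if p == 1 and c == 0:
        return "loss"
    return "keep_sp" if c == 1 else "stay_no_sp"


def call_events(
    reconstruction: StateReconstruction,
    tree: dendropy.Tree,
    cluster_id: str = "",
) -> list[Event]:
    """Classify every non-root branch into one of the five event types."""
    events = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_final = reconstruction.final[node_key(node.parent_node)]
        child_final = reconstruction.final[node_key(node)]
        events.append(Event(cluster_id, node_key(node.parent_node),
                            node_key(node), classify_branch(parent_final, child_final)))
    return events


def assign_event_rank(
    event: Event,
    tree: dendropy.Tree,
    taxonomy: Mapping[str, Mapping[str, str]],
    species_of: Optional[Callable[[str], str]] = None,
) -> str:
    """Minimal common taxonomic rank of the event's descendant genomes.

    ``taxonomy`` maps species ids to {rank: name} over species/genus/family/
    order; ``species_of`` maps a leaf label to its species id (identity by
    default).  Returns the lowest rank at which all descendants of the
    event's child node agree (``order`` if they disagree everywhere above).
    """
    species_of = species_of or (lambda label: label)
    child = next((n for n in tree.preorder_node_iter()
                  if node_key(n) == event.child), None)
    if child is None:
        raise KeyError(f"node {event.child!r} not in tree")
    species = {species_of(leaf.taxon.label) for leaf in child.leaf_iter()}
    paths = [taxonomy[s] for s in species]
    for rank in RANKS:
        if len({p[rank] for p in paths}) == 1:
            return rank
    return RANKS[-1]


def lifestyle_transitions(
    tree: dendropy.Tree,
    lifestyles: Mapping[str, int],
) -> LifestyleReconstruction:
    """3-state Fitch on lifestyles plus per-branch transition classes.

    A branch's class is determined by the child's final set: a singleton maps
    to the corresponding ``to_*`` class, anything else is
    ``uncertain_transition``.
    """
    recon = fitch(tree, lifestyles, n_states=3, character="lifestyle")
    singleton_class = {0: "to_free_living", 1: "to_endosymbiont", 2: "to_commensal"}
    transitions: dict[tuple[str, str], str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child_final = recon.final[node_key(node)]
        cls = (singleton_class[next(iter(child_final))]
               if len(child_final) == 1 else "uncertain_transition")
        transitions[(node_key(node.parent_node), node_key(node))] = cls
    return LifestyleReconstruction(recon, transitions)


def crosstab_events_lifestyle(
    events: Mapping[str, list[Event]],
    lifestyle_reconstructions: Mapping[str, LifestyleReconstruction],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """5x4 contingency table of branch event types against lifestyle
    transition classes, with within-column percentages.

    ``events`` maps cluster ids to the full per-branch event lists of that
    cluster; every branch contributes exactly one cell.
    """
    counts = pd.DataFrame(0, index=list(EVENT_TYPES),
                          columns=list(TRANSITION_CLASSES), dtype=int)
    for cluster_id, ev_list in events.items():
        trans = lifestyle_reconstructions[cluster_id].transitions
        for ev in ev_list:
            counts.loc[ev.etype, trans[(ev.parent, ev.child)]] += 1
    col_sums = counts.sum(axis=0).astype(float)
    safe = col_sums.where(col_sums > 0, other=float("nan"))
    percents = (counts.div(safe, axis=1) * 100.0).fillna(0.0)
    return counts, percents
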