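"""Molecular mechanism of gain/loss events: indel vs. substitution.

For each latest (leaf-nearest) gain or loss event, alignments of extant
descendants of the node above the event are compared: for every pair of an
SP-bearing leaf s (with predicted cleavage position) and an SP-less leaf t,
the length ratio lr = L_nt / L_sp is computed, where L_sp is the length of
s's signal peptide and L_nt the number of residues t retains in the MSA
columns spanned by that signal peptide.  lr near 0 indicates wholesale
insertion/deletion of the segment (indel mechanism); lr near 1 indicates a
segment of conserved length reshaped by substitutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .parsimony import node_key
from .phylo import GAP, Msa
from .types import Event

log = logging.getLogger(__name__)

#: lr at or below this -> indel; within SUBSTITUTION_BAND -> substitution
INDEL_THRESHOLD = 0.1
SUBSTITUTION_BAND = (0.9, 1.1)


@dataclass
class EventMechanism:
    event: Event
    lr: float
    category: str
    pair_lrs: list[float] = field(default_factory=list)
    nterm_identity: float = float("nan")
    cleavage_site_identity: float = float("nan")
    remainder_identity: float = float("nan")


def categorize_lr(lr: float, indel_threshold: float = INDEL_THRESHOLD) -> str:
    if lr <= indel_threshold:
        return "indel"
    if SUBSTITUTION_BAND[0] <= lr <= SUBSTITUTION_BAND[1]:
        return "substitution"
    return "intermediate"


def _node_index(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {node_key(n): n for n in tree.preorder_node_iter()}


def _leaf_labels(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def latest_events(
    events: Sequence[Event],
    tree: dendropy.Tree,
) -> tuple[list[Event], dict]:
    """Keep only leaf-nearest gain/loss events; report reversals.

    An event is dropped when another gain/loss event lies strictly below it
    (within its child's subtree).  Ancestor-descendant pairs of opposite type
    are reported as reversals; alternating nested triples as double
    reversals.  The retained set is an antichain in the ancestor order.
    """
    index = _node_index(tree)
    gl = [e for e in events if e.etype in ("gain", "loss")]
    below: dict[Event, set[str]] = {e: _leaf_labels(index[e.child]) for e in gl}
    # e2 descends from e1 iff e2's child-subtree leaves are a strict subset
    descendants = {
        e1: [e2 for e2 in gl if e2 is not e1 and below[e2] < below[e1]]
        for e1 in gl
    }
    retained = [e for e in gl if not descendants[e]]
    reversals = []
    for e1 in gl:
        for e2 in descendants[e1]:
            if e2.etype != e1.etype:
                reversals.append((e1, e2))
    doubles = []
    for e1, e2 in reversals:
        for e3 in descendants[e2]:
            if e3.etype == e1.etype:
                doubles.append((e1, e2, e3))
    return retained, {"reversals": reversals, "double_reversals": doubles}


def _sp_columns(row: str, cleavage_pos: int) -> list[int]:
    """MSA columns of the first ``cleavage_pos`` residues of a row."""
    cols = []
    for i, ch in enumerate(row):
        if ch != GAP:
            cols.append(i)
            if len(cols) == cleavage_pos:
                break
    return cols


def _event_pairs(
    event: Event,
    tree: dendropy.Tree,
    states: Mapping[str, int],
) -> tuple[list[str], list[str]]:
    """SP-bearing and SP-less extant leaves descending from the node above
    the event, with the new-state side taken from the child subtree."""
    index = _node_index(tree)
    child_leaves = _leaf_labels(index[event.child])
    parent_leaves = _leaf_labels(index[event.parent])
    outside = parent_leaves - child_leaves
    if event.etype == "loss":
        nosp = sorted(l for l in child_leaves if states.get(l) == 0)
        sp = sorted(l for l in outside if states.get(l) == 1)
    else:
        sp = sorted(l for l in child_leaves if states.get(l) == 1)
        nosp = sorted(l for l in outside if states.get(l) == 0)
    return sp, nosp


def length_ratio(
    event: Event,
    msa: Msa,
    cleavage_positions: Mapping[str, int],
    tree: dendropy.Tree,
    states: Mapping[str, int],
) -> Optional[tuple[float, list[float]]]:
    """Mean lr over all (SP leaf, non-SP leaf) pairs of the event.

    Returns None (logged) when no SP descendant has a cleavage position or a
    pair side is empty.
    """
    sp_leaves, nosp_leaves = _event_pairs(event, tree, states)
    sp_leaves = [s for s in sp_leaves if cleavage_positions.get(s)]
    if not sp_leaves or not nosp_leaves:
        log.debug("event %s->%s skipped: no usable SP/non-SP pair",
                  event.parent, event.child)
        return None
    pair_lrs = []
    for s in sp_leaves:
        cols = _sp_columns(msa.row(s), cleavage_positions[s])
        l_sp = len(cols)
        for t in nosp_leaves:
            row_t = msa.row(t)
            l_nt = sum(1 for c in cols if row_t[c] != GAP)
            pair_lrs.append(l_nt / l_sp)
    return float(sum(pair_lrs) / len(pair_lrs)), pair_lrs


def _identity_over_columns(row_a: str, row_b: str, cols: Sequence[int]) -> float:
    ident = sum(1 for c in cols if row_a[c] == row_b[c] and row_a[c] != GAP)
    len_a = sum(1 for c in cols if row_a[c] != GAP)
    len_b = sum(1 for c in cols if row_b[c] != GAP)
    shorter = min(len_a, len_b)
    return ident / shorter if shorter else 0.0


def nterm_identity_profile(
    event: Event,
    msa: Msa,
    cleavage_positions: Mapping[str, int],
    tree: dendropy.Tree,
    states: Mapping[str, int],
    lr_band: tuple[float, float] = SUBSTITUTION_BAND,
) -> list[dict]:
    """Per-pair identities over the signal-peptide region, restricted to
    pairs of comparable N-terminal length (lr within ``lr_band``).

    For each admissible pair: identity over the three cleavage-site columns
    (-3..-1 before the cleavage point), over the remaining SP columns, and
    over the whole SP span, all with shorter-length normalization.
    """
    sp_leaves, nosp_leaves = _event_pairs(event, tree, states)
    out = []
    for s in sp_leaves:
        cpos = cleavage_positions.get(s)
        if not cpos:
            continue
        cols = _sp_columns(msa.row(s), cpos)
        cleave_cols, remainder_cols = cols[-3:], cols[:-3]
        for t in nosp_leaves:
            row_t = msa.row(t)
            l_nt = sum(1 for c in cols if row_t[c] != GAP)
            lr = l_nt / len(cols)
            if not (lr_band[0] <= lr <= lr_band[1]):
                continue
            out.append({
                "sp_leaf": s, "nosp_leaf": t, "lr": lr,
                "nterm_identity": _identity_over_columns(msa.row(s), row_t, cols),
                "cleavage_site_identity": _identity_over_columns(
                    msa.row(s), row_t, cleave_cols),
                "remainder_identity": _identity_over_columns(
                    msa.row(s), row_t, remainder_cols),
            })
    return out


def classify_event_mechanism(
    event: Event,
    msa: Msa,
    cleavage_positions: Mapping[str, int],
    tree: dendropy.Tree,
    states: Mapping[str, int],
    indel_threshold: float = INDEL_THRESHOLD,
) -> Optional[EventMechanism]:
    res = length_ratio(event, msa, cleavage_positions, tree, states)
    if res is None:
        return None
    lr, pair_lrs = res
    mech = EventMechanism(event, lr, categorize_lr(lr, indel_threshold), pair_lrs)
    profile = nterm_identity_profile(event, msa, cleavage_positions, tree, states)
    if profile:
        mech.nterm_identity = sum(p["nterm_identity"] for p in profile) / len(profile)
        mech.cleavage_site_identity = (
            sum(p["cleavage_site_identity"] for p in profile) / len(profile))
        mech.remainder_identity = (
            sum(p["remainder_identity"] for p in profile) / len(profile))
    return mech


def mechanism_summary(mechanisms: Sequence[EventMechanism]) -> pd.DataFrame:
    """Counts per (event type x category); empty input yields an empty table."""
    rows = [(m.event.etype, m.category) for m in mechanisms]
    if not rows:
        return pd.DataFrame(columns=["etype", "category", "count"])
    df = pd.DataFrame(rows, columns=["etype", "category"])
    return (df.value_counts().rename("count").reset_index()
            .sort_values(["etype", "category"]).reset_index(drop=True))
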