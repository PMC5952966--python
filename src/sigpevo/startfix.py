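"""Gene-start correction: rescue signal peptides lost to mis-annotated starts.

Prokaryotic annotations mis-place gene starts often enough to create
spurious signal-peptide loss calls: a start annotated downstream of the true
one truncates the SP-encoding region, so predictors report the protein as
non-secreted.  For each consensus-NEGATIVE member of a mixed cluster, a
search window is derived from the cluster MSA (maximal signed offset of the
SP-bearing members' first residues in each direction, plus 30 residues);
every in-frame ATG/GTG/TTG within the window yields a candidate N-terminus,
which is re-predicted.  Decision priority: a TatP-positive candidate rejects
the whole cluster; a reliably positive candidate (best SignalP-like score)
re-annotates the start; with no reliable candidate at any start the protein
is deleted as discordant; otherwise the start is left unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .phylo import GAP, Msa
from .secretome import classify_clusters, consensus_state, detect_tat_motif, \
    heuristic_sp_score
from .types import ConsensusState, OrthologCluster, PredictionTriple, ProteinRecord

log = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")

#: residues added to the maximal MSA offset in each direction
WINDOW_PAD = 30


@dataclass
class StartCandidate:
    """One alternative start: positive shift = truncation (downstream),
    negative = extension (upstream); shift 0 is the annotated start."""

    protein_id: str
    shift: int
    codon: str
    sequence: str
    triple: PredictionTriple
    cds_start: int  # genomic coordinate of the candidate start


@dataclass
class CorrectionDecision:
    protein_id: str
    outcome: str  # cluster_rejected_tat | accepted_positive |
    #               accepted_negative_unchanged | protein_deleted_discordant
    candidate: Optional[StartCandidate] = None


@dataclass
class Round2Result:
    clusters: list[OrthologCluster]
    events: dict[str, list]
    reconstructions: dict[str, object]
    decisions: list[CorrectionDecision] = field(default_factory=list)
    corrected: int = 0


def zero_noise_predictor(sequence: str) -> PredictionTriple:
    """Deterministic triple straight from the heuristic scorer."""
    score, cpos = heuristic_sp_score(sequence)
    call = score > 0.5
    return PredictionTriple(round(score, 4), call, call,
                            detect_tat_motif(sequence),
                            cpos if call else None)


def correction_window(
    msa: Msa,
    target_id: str,
    sp_member_ids: Sequence[str],
) -> tuple[int, int]:
    """(upstream_limit, downstream_limit) in residues for one target.

    For each SP-bearing member, the signed start offset is measured in
    ungapped residues: members starting before the target contribute their
    own residue count over the intervening columns (upstream), members
    starting after contribute the target's residue count (downstream).  The
    maxima plus 30 give the window; both limits are at least 30.
    """
    if target_id not in msa:
        raise KeyError(f"target {target_id!r} not in alignment")
    t_row = msa.row(target_id)
    t_first = _first_residue_col(t_row)
    up = down = 0
    for sid in sp_member_ids:
        s_row = msa.row(sid)
        s_first = _first_residue_col(s_row)
        if s_first < t_first:
            offset = sum(1 for c in range(s_first, t_first) if s_row[c] != GAP)
            up = max(up, offset)
        elif s_first > t_first:
            offset = sum(1 for c in range(t_first, s_first) if t_row[c] != GAP)
            down = max(down, offset)
    return up + WINDOW_PAD, down + WINDOW_PAD


def _first_residue_col(row: str) -> int:
    for c, ch in enumerate(row):
        if ch != GAP:
            return c
    raise ValueError("all-gap alignment row")


def enumerate_alt_starts(
    record: ProteinRecord,
    window: tuple[int, int],
    predictor: Callable[[str], PredictionTriple] = zero_noise_predictor,
    min_length: int = 10,
) -> list[StartCandidate]:
    """All in-frame ATG/GTG/TTG starts within the window, re-predicted.

    The shift-0 candidate (the annotated start) is always present and
    reproduces the input record.  Extension candidates with an in-frame stop
    between the new start and the original body are excluded.  A window
    reaching beyond the available genomic context is truncated (logged).
    """
    up_limit, down_limit = window
    genomic, start0 = record.genomic_seq, record.cds_start
    if 3 * up_limit > start0:
        log.debug("%s: upstream window truncated to available context",
                  record.protein_id)
        up_limit = start0 // 3
    max_down = (len(record.sequence) - min_length)
    down_limit = min(down_limit, max_down)
    candidates = []
    for shift in range(-up_limit, down_limit + 1):
        pos = start0 + 3 * shift
        codon = genomic[pos:pos + 3]
        if shift != 0 and codon not in START_CODONS:
            continue
        if shift > 0:
            seq = "M" + record.sequence[shift + 1:]
        elif shift < 0:
            prefix = str(Seq(genomic[pos + 3:start0]).translate(table=11))
            if "*" in prefix:
                continue
            seq = "M" + prefix + record.sequence[1:]
        else:
            seq = record.sequence
        candidates.append(StartCandidate(
            record.protein_id, shift, codon if codon in START_CODONS else "ATG",
            seq, predictor(seq), pos))
    return candidates


def decide_correction(candidates: Sequence[StartCandidate]) -> CorrectionDecision:
    """Apply the priority rules to one protein's candidate set.

    1. any TatP-positive candidate rejects the whole cluster;
    2. positive consensus candidates win over keeping the negative start —
       the highest SignalP-like score is chosen (ties: smallest |shift|,
       then codon lexicographically);
    3. if no candidate is reliable (positive or negative) at any start, the
       protein is deleted as discordant;
    4. otherwise the start is left unchanged.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    protein_id = candidates[0].protein_id
    tat = [c for c in candidates if c.triple.tatp_call]
    if tat:
        return CorrectionDecision(protein_id, "cluster_rejected_tat", tat[0])
    by_state = {}
    for c in candidates:
        by_state.setdefault(consensus_state(c.triple), []).append(c)
    positives = by_state.get(ConsensusState.POSITIVE, [])
    if positives:
        best = min(positives, key=lambda c: (-c.triple.signalp_score,
                                             abs(c.shift), c.codon))
        return CorrectionDecision(protein_id, "accepted_positive", best)
    if ConsensusState.NEGATIVE in by_state:
        unchanged = next((c for c in candidates if c.shift == 0), candidates[0])
        return CorrectionDecision(protein_id, "accepted_negative_unchanged",
                                  unchanged)
    return CorrectionDecision(protein_id, "protein_deleted_discordant")


def apply_shift_to_row(row: str, new_seq: str, shift: int) -> str:
    """Update an alignment row for a corrected start.

    Truncation gaps out the removed prefix; extension fills the gap columns
    immediately left of the current first residue (the columns the residues
    occupied before mis-annotation).  Residue content at the boundary is
    taken from the new sequence.
    """
    cells = list(row)
    res_cols = [c for c, ch in enumerate(cells) if ch != GAP]
    if shift > 0:
        for c in res_cols[:shift]:
            cells[c] = GAP
        if len(res_cols) > shift:
            cells[res_cols[shift]] = new_seq[0]
    elif shift < 0:
        ext = -shift
        first = res_cols[0]
        gap_cols = [c for c in range(first - 1, -1, -1) if cells[c] == GAP]
        usable = list(reversed(gap_cols[:ext]))
        if len(usable) < ext:
            log.debug("extension exceeds alignment columns; filling %d of %d",
                      len(usable), ext)
        offset = ext - len(usable)
        for k, c in enumerate(usable):
            cells[c] = new_seq[offset + k]
        cells[first] = new_seq[ext]
    return "".join(cells)


def correct_cluster(
    cluster: OrthologCluster,
    predictor: Callable[[str], PredictionTriple] = zero_noise_predictor,
) -> tuple[OrthologCluster, list[CorrectionDecision]]:
    """Run the correction procedure on one mixed cluster (in place).

    Only consensus-NEGATIVE members are scanned; POSITIVE members are never
    modified.  Returns the (possibly rejected) cluster and the decisions.
    """
    decisions: list[CorrectionDecision] = []
    sp_ids = [pid for pid, s in cluster.states.items()
              if s is ConsensusState.POSITIVE]
    targets = [m for m in cluster.members
               if cluster.states[m.protein_id] is ConsensusState.NEGATIVE]
    deleted: list[str] = []
    for record in targets:
        window = correction_window(cluster.msa, record.protein_id, sp_ids)
        candidates = enumerate_alt_starts(record, window, predictor)
        decision = decide_correction(candidates)
        decisions.append(decision)
        if decision.outcome == "cluster_rejected_tat":
            cluster.class_label = "rejected"
            cluster.rejection_reason = "tat"
            return cluster, decisions
        if decision.outcome == "accepted_positive":
            cand = decision.candidate
            cluster.msa = cluster.msa.replace_row(
                record.protein_id,
                apply_shift_to_row(cluster.msa.row(record.protein_id),
                                   cand.sequence, cand.shift))
            record.sequence = cand.sequence
            record.cds_start = cand.cds_start
            cluster.states[record.protein_id] = ConsensusState.POSITIVE
        elif decision.outcome == "protein_deleted_discordant":
            deleted.append(record.protein_id)
    if deleted:
        cluster.members = [m for m in cluster.members
                           if m.protein_id not in deleted]
        for pid in deleted:
            cluster.states.pop(pid, None)
        cluster.msa = cluster.msa.drop(deleted)
        if cluster.tree is not None and len(cluster.members) >= 2:
            pruned = cluster.tree.clone(depth=1)
            pruned.retain_taxa_with_labels([m.protein_id for m in cluster.members])
            cluster.tree = pruned
    return cluster, decisions


def run_round2(
    clusters: Sequence[OrthologCluster],
    predictions: Mapping[str, PredictionTriple],
    predictor: Callable[[str], PredictionTriple] = zero_noise_predictor,
    min_size: int = 3,
) -> tuple[list[OrthologCluster], list[CorrectionDecision]]:
    """Correct every mixed cluster and re-filter for the second parsimony round.

    Sequences and alignment rows are updated in place; clusters are then
    re-classified (TAT rejection, size filter, positive/negative/mixed).
    """
    decisions: list[CorrectionDecision] = []
    for cluster in clusters:
        if cluster.class_label != "mixed":
            continue
        _, dec = correct_cluster(cluster, predictor)
        decisions.extend(dec)
    out = []
    for cluster in clusters:
        if cluster.class_label == "rejected":
            out.append(cluster)
        else:
            out.extend(classify_clusters([cluster], predictions,
                                         min_size=min_size))
    return out, decisions
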