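"""Consensus secretion-state calling and cluster classification.

Signal peptides of the Sec pathway have a tripartite architecture: a short,
positively charged n-region, a hydrophobic h-region of 8-14 residues, and a
polar c-region terminating in a signal-peptidase-I motif (canonically A-x-A)
immediately before the cleavage site.  ``heuristic_sp_score`` scores that
architecture directly; it is a documented stand-in for a trained predictor
and is used both to emulate predictor calls on synthetic sequences and to
re-predict alternative gene starts during start correction.

Per-protein predictor calls (a SignalP-like score+call, a Phobius-like call,
a TatP-like twin-arginine call) are combined into a four-way consensus:
TAT (rejects the whole cluster), POSITIVE, NEGATIVE, or DISCORDANT (protein
discarded).  Clusters are then labelled positive/negative/mixed.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import ConsensusState, OrthologCluster, PredictionTriple

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

STANDARD_AA = frozenset(KYTE_DOOLITTLE)

#: score/call decision threshold of the SignalP-like heuristic
SP_SCORE_THRESHOLD = 0.5
#: mean Kyte-Doolittle hydropathy required of the h-region window
H_REGION_MIN_HYDROPATHY = 2.0
#: minimal h-region window length
H_REGION_MIN_LEN = 7
#: admissible cleavage positions (1-based index of the last SP residue)
CLEAVAGE_RANGE = (15, 40)

#: residues tolerated at the -3 and -1 positions of the cleavage motif
MOTIF_MINUS3 = frozenset("AGSTVCIL")
MOTIF_MINUS1 = frozenset("AGSC")

#: twin-arginine consensus (S/T)-R-R-x-F-L-K with degenerate flanks;
#: one allowed set per position, None = any residue.
TAT_PATTERN = (frozenset("ST"), frozenset("R"), frozenset("R"), None,
               frozenset("FGAVML"), frozenset("LIVMF"), frozenset("KR"))
#: twin-arginine motif must start within this N-terminal window
TAT_WINDOW = 35


def heuristic_sp_score(sequence: str) -> tuple[float, Optional[int]]:
    """Score the tripartite signal-peptide architecture of an N-terminus.

    Scans candidate cleavage points within ``CLEAVAGE_RANGE``; a candidate is
    admissible when (i) the -3/-1 motif residues are small and uncharged,
    (ii) a window of >=7 residues ending shortly before the motif has mean
    Kyte-Doolittle hydropathy >= ``H_REGION_MIN_HYDROPATHY``, and (iii) the
    first five residues contain at least one K/R and no D/E.  Returns a score
    in [0, 1] (> 0.5 iff some candidate is admissible) and the best-scoring
    cleavage position (ties broken toward the most N-terminal candidate).
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = [i + 1 for i, aa in enumerate(sequence) if aa not in STANDARD_AA]
    if bad:
        raise ValueError(f"non-standard residues at positions {bad}")

    head = sequence[:CLEAVAGE_RANGE[1] + 1]
    # prefix sums of hydropathy over the N-terminal head
    acc = [0.0]
    for aa in head:
        acc.append(acc[-1] + KYTE_DOOLITTLE[aa])
    n_region = sequence[:5]
    n_pos = sum(aa in "KR" for aa in n_region)
    n_neg = sum(aa in "DE" for aa in n_region)
    charge_ok = n_pos >= 1 and n_neg == 0

    best_score, best_pos, best_partial = 0.0, None, 0
    lo, hi = CLEAVAGE_RANGE
    for c in range(lo, min(hi, len(sequence) - 1) + 1):
        motif_ok = sequence[c - 3] in MOTIF_MINUS3 and sequence[c - 1] in MOTIF_MINUS1
        # best hydrophobic window ending 3..9 residues before the cleavage point
        max_mean = -1e30
        for end in range(max(H_REGION_MIN_LEN - 1, c - 9), c - 2):
            for length in range(H_REGION_MIN_LEN, 15):
                start = end - length + 1
                if start < 0:
                    break
                mean = (acc[end + 1] - acc[start]) / length
                if mean > max_mean:
                    max_mean = mean
        h_ok = max_mean >= H_REGION_MIN_HYDROPATHY
        n_ok_components = int(motif_ok) + int(h_ok) + int(charge_ok)
        best_partial = max(best_partial, n_ok_components)
        if not (motif_ok and h_ok and charge_ok):
            continue
        motif_bonus = 1.0 if (sequence[c - 3] == "A" and sequence[c - 1] == "A") else 0.6
        h_bonus = min(1.0, max(0.0, (max_mean - H_REGION_MIN_HYDROPATHY) / 1.4))
        charge_bonus = min(1.0, n_pos / 2.0)
        score = 0.5 + 0.2 * motif_bonus + 0.2 * h_bonus + 0.1 * charge_bonus
        if score > best_score + 1e-12:
            best_score, best_pos = score, c

    if best_pos is not None:
        return best_score, best_pos
    return 0.15 * best_partial, None


def detect_tat_motif(sequence: str) -> bool:
    """True iff the twin-arginine consensus matches within the first 35 residues."""
    window = sequence[:TAT_WINDOW + len(TAT_PATTERN)]
    for i in range(min(TAT_WINDOW, len(window) - len(TAT_PATTERN) + 1)):
        if all(allowed is None or window[i + j] in allowed
               for j, allowed in enumerate(TAT_PATTERN)):
            return True
    return False


def consensus_state(triple: PredictionTriple) -> ConsensusState:
    """Four-way consensus: TAT dominates; then agreement/disagreement of
    the SignalP-like and Phobius-like calls."""
    if triple.tatp_call:
        return ConsensusState.TAT
    if triple.signalp_call and triple.phobius_call:
        return ConsensusState.POSITIVE
    if not triple.signalp_call and not triple.phobius_call:
        return ConsensusState.NEGATIVE
    return ConsensusState.DISCORDANT


def classify_clusters(
    clusters: Iterable[OrthologCluster],
    predictions: Mapping[str, PredictionTriple],
    min_size: int = 3,
) -> list[OrthologCluster]:
    """Apply the consensus filters and label clusters positive/negative/mixed.

    Any TAT member rejects the whole cluster; DISCORDANT members are removed
    from the cluster; clusters left with fewer than ``min_size`` members are
    rejected as too small.  Idempotent: re-running on the output is a no-op.
    """
    out = []
    for cluster in clusters:
        states = {
            m.protein_id: cluster.states.get(m.protein_id)
            or consensus_state(predictions[m.protein_id])
            for m in cluster.members
        }
        if any(s is ConsensusState.TAT for s in states.values()):
            cluster.states = states
            cluster.class_label = "rejected"
            cluster.rejection_reason = "tat"
            out.append(cluster)
            continue
        keep = [m for m in cluster.members
                if states[m.protein_id] is not ConsensusState.DISCORDANT]
        dropped = [m.protein_id for m in cluster.members
                   if states[m.protein_id] is ConsensusState.DISCORDANT]
        cluster.members = keep
        cluster.states = {m.protein_id: states[m.protein_id] for m in keep}
        if dropped:
            if cluster.msa is not None:
                cluster.msa = cluster.msa.drop(dropped)
            if cluster.tree is not None and len(keep) >= 2:
                cluster.tree = _prune_leaves(cluster.tree, [m.protein_id for m in keep])
        if len(keep) < min_size:
            cluster.class_label = "rejected"
            cluster.rejection_reason = "too_small"
            out.append(cluster)
            continue
        has_pos = any(s is ConsensusState.POSITIVE for s in cluster.states.values())
        has_neg = any(s is ConsensusState.NEGATIVE for s in cluster.states.values())
        cluster.class_label = ("mixed" if has_pos and has_neg
                               else "positive" if has_pos else "negative")
        cluster.rejection_reason = "none"
        out.append(cluster)
    return out


def _prune_leaves(tree, keep_labels):
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(keep_labels)
    return pruned


def secretome_summary(
    records: pd.DataFrame,
    include_discordant: bool = True,
) -> tuple[pd.DataFrame, dict[int, tuple[float, float]]]:
    """Per-genome secretome table plus a linear fit per lifestyle stratum.

    ``records`` needs columns protein_id, species_id, lifestyle, state
    (ConsensusState values as strings).  Returns one row per genome
    (n_proteins, n_sp, fraction_sp) and ``{lifestyle: (slope, intercept)}``
    of fraction_sp against n_proteins.  With ``include_discordant=False``
    discordant proteins are dropped from the denominator.
    """
    df = records.copy()
    if not include_discordant:
        df = df[df["state"] != ConsensusState.DISCORDANT.value]
    rows = []
    for (species, lifestyle), grp in df.groupby(["species_id", "lifestyle"], sort=True):
        n = len(grp)
        n_sp = int((grp["state"] == ConsensusState.POSITIVE.value).sum())
        rows.append((species, int(lifestyle), n, n_sp, n_sp / n if n else 0.0))
    table = pd.DataFrame(
        rows, columns=["species_id", "lifestyle", "n_proteins", "n_sp", "fraction_sp"])
    fits: dict[int, tuple[float, float]] = {}
    for lifestyle, grp in table.groupby("lifestyle"):
        if len(grp) >= 2 and grp["n_proteins"].nunique() > 1:
            slope, intercept = np.polyfit(grp["n_proteins"], grp["fraction_sp"], 1)
        else:
            slope, intercept = 0.0, float(grp["fraction_sp"].mean())
        fits[int(lifestyle)] = (float(slope), float(intercept))
    return table, fits
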