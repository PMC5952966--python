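"""Shared domain containers for the signal-peptide evolution pipeline.

The analysis operates on orthologous protein clusters (COGs) from a set of
bacterial genomes.  Each protein carries a consensus secretion state derived
from signal-peptide predictor calls; each cluster carries an alignment and a
rooted tree on which ancestral states are reconstructed by parsimony.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class ConsensusState(enum.Enum):
    """Four-way consensus of SignalP-like, Phobius-like and TatP-like calls."""

    TAT = "tat"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    DISCORDANT = "discordant"


class Lifestyle(enum.IntEnum):
    """Bacterial lifestyle, encoded as the parsimony character states."""

    FREE_LIVING = 0
    ENDOSYMBIONT = 1
    COMMENSAL = 2


#: taxonomy ranks from most to least specific
RANKS = ("species", "genus", "family", "order")


@dataclass
class PredictionTriple:
    """One protein's predictor calls.

    ``signalp_score`` lives in [0, 1] and is consistent with ``signalp_call``
    at the 0.5 threshold; ``cleavage_pos`` is the 1-based index of the last
    signal-peptide residue, present only for positive SignalP-like calls.
    """

    signalp_score: float
    signalp_call: bool
    phobius_call: bool
    tatp_call: bool
    cleavage_pos: Optional[int] = None


@dataclass
class ProteinRecord:
    """One gene product with its genomic context.

    ``genomic_seq`` is the coding strand covering the annotated CDS plus
    flanking context; ``cds_start``/``cds_end`` are 0-based half-open
    coordinates of the annotated CDS within ``genomic_seq``.
    """

    protein_id: str
    species_id: str
    sequence: str
    genomic_seq: str = ""
    cds_start: int = 0
    cds_end: int = 0
    go_terms: tuple[str, ...] = ()
    true_state: Optional[int] = None

    @property
    def cds(self) -> str:
        return self.genomic_seq[self.cds_start:self.cds_end]


@dataclass
class OrthologCluster:
    """A cluster of orthologous proteins with alignment and tree.

    ``class_label`` is one of ``positive``/``negative``/``mixed`` after
    filtering, or ``rejected`` with a ``rejection_reason`` of ``tat`` or
    ``too_small``.
    """

    cluster_id: str
    members: list[ProteinRecord] = field(default_factory=list)
    states: dict[str, ConsensusState] = field(default_factory=dict)
    msa: Optional["object"] = None  # phylo.Msa
    tree: Optional["object"] = None  # dendropy.Tree
    class_label: str = "unclassified"
    rejection_reason: str = "none"

    def member_ids(self) -> list[str]:
        return [m.protein_id for m in self.members]


@dataclass(frozen=True)
class Event:
    """A branch-level secretion-state transition.

    ``etype`` partitions every branch into one of five classes: ``gain``
    ({0}->{1}), ``loss`` ({1}->{0}), ``uncertain`` (an endpoint left
    ambiguous by parsimony), ``keep_sp`` and ``stay_no_sp``.
    """

    cluster_id: str
    parent: str
    child: str
    etype: str
    taxonomic_rank: Optional[str] = None


@dataclass
class DiscriminationResult:
    """Per-cluster lifestyle-vs-secretion 2x2 counts with d score and p."""

    cluster_id: str
    lifestyle_a: Lifestyle
    lifestyle_b: Lifestyle
    a_sp: int
    a_nosp: int
    b_sp: int
    b_nosp: int
    d: float
    fisher_p: float


@dataclass
class EnrichmentResult:
    term: str
    group: str
    k_in_group: int
    n_group: int
    K_background: int
    N_background: int
    p_one_sided: float
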