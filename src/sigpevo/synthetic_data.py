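"""Ground-truth-labelled synthetic datasets for the signal-peptide analysis.

The generator emulates the inputs of the real study: a set of bacterial
species with taxonomy, lifestyle and genome size; orthologous protein
families evolved along the species tree with known signal-peptide state at
every node; planted gain/loss events of two mechanisms (whole-segment indel
vs. in-place substitution); coding sequences with genomic context and
planted gene-start annotation errors; noisy predictor calls; and a small GO
DAG with annotations biased by secretion state.

Sequence model.  Every protein is a concatenation of zero or more
N-terminal "blocks" followed by a mature body.  A block is either a
functional signal peptide (tripartite: positively charged n-region,
hydrophobic h-region, polar c-region ending in A-x-A) or a polar remnant of
comparable length.  Indel events add or delete whole blocks (creating or
emptying alignment columns); substitution events rewrite the leftmost block
in place, conserving its length.  Because indel history is fully known, the
true MSA is emitted exactly; the body evolves by substitutions only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from . import parsimony
from .phylo import GAP, Msa
from .secretome import detect_tat_motif, heuristic_sp_score
from .types import OrthologCluster, PredictionTriple, ProteinRecord

log = logging.getLogger(__name__)

AA = "ACDEFGHIKLMNPQRSTVWY"
H_REGION_AA = list("LVIFAMW")
H_REGION_P = np.array([0.25, 0.2, 0.2, 0.15, 0.1, 0.07, 0.03])
POLAR_AA = list("STNQGDEKHP")
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: standard-code codons per amino acid (back-translation)
CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "M": ("ATG",),
    "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate the study conditions.

    Lifestyle fractions follow the real cohort (120 free-living, 21
    endosymbionts, 12 commensals of 153 genomes); genome-size means mirror
    the reported per-lifestyle protein counts; the loss rate is four times
    the gain rate, with losses further elevated on endosymbiont lineages.
    """

    seed: int = 0
    n_species: int = 153
    lifestyle_fractions: tuple[float, float, float] = (120 / 153, 21 / 153, 12 / 153)
    n_families: int = 500
    family_size_range: tuple[int, int] = (3, 25)
    sp_gain_rate: float = 0.01
    sp_loss_rate: float = 0.04
    mechanism_mix: float = 0.7  # probability an event uses the indel mechanism
    start_error_rate: float = 0.1
    start_shift_range: tuple[int, int] = (0, 10)  # residues past the cleavage site
    predictor_noise: tuple[float, float, float] = (0.04, 0.04, 0.001)
    substitution_rate: float = 0.02  # per site per branch (body only)
    root_sp_prob: float = 0.12
    tat_fraction: float = 0.01
    endo_loss_multiplier: float = 4.0
    body_length_range: tuple[int, int] = (80, 200)
    context_len: int = 300  # nt of genomic context on each side of the CDS
    genome_size_mean: dict = field(
        default_factory=lambda: {0: 3600.0, 1: 1066.0, 2: 3730.0})
    genome_size_sd: dict = field(
        default_factory=lambda: {0: 600.0, 1: 250.0, 2: 600.0})

    def __post_init__(self):
        probs = [*self.lifestyle_fractions, self.mechanism_mix,
                 self.start_error_rate, *self.predictor_noise,
                 self.root_sp_prob, self.tat_fraction]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.lifestyle_fractions) - 1.0) > 1e-9:
            raise ValueError("lifestyle_fractions must sum to 1")
        if self.sp_gain_rate < 0 or self.sp_loss_rate < 0 or self.substitution_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.family_size_range[0] < 3:
            raise ValueError("family_size_range minimum must be >= 3")


@dataclass
class Species:
    species_id: str
    taxonomy: dict[str, str]
    lifestyle: int
    genome_size: int


@dataclass
class SpeciesSet:
    species: list[Species]
    tree: dendropy.Tree

    def by_id(self) -> dict[str, Species]:
        return {s.species_id: s for s in self.species}


@dataclass
class FamilyTruth:
    """Planted history of one family."""

    node_states: dict[str, int]
    events: list[dict]  # parent, child, type (gain/loss), mechanism
    true_rows: dict[str, str]  # protein -> uncorrupted MSA row
    true_starts: dict[str, int]  # protein -> true cds_start in genomic coords
    start_errors: dict[str, int] = field(default_factory=dict)  # protein -> shift
    cleavage: dict[str, int] = field(default_factory=dict)
    is_tat: bool = False


@dataclass
class GroundTruth:
    families: dict[str, FamilyTruth] = field(default_factory=dict)
    lifestyle_transitions: dict = field(default_factory=dict)

    def planted_event_set(self) -> set[tuple[str, str, str, str]]:
        return {(cid, e["parent"], e["child"], e["type"])
                for cid, fam in self.families.items() for e in fam.events}


@dataclass
class Dataset:
    config: SimulationConfig
    species_set: SpeciesSet
    clusters: list[OrthologCluster]
    predictions: dict[str, PredictionTriple]
    truth: Optional[GroundTruth]
    go_dag: "object" = None  # networkx MultiDiGraph
    annotations: dict[str, tuple[str, ...]] = field(default_factory=dict)
    go_obo_text: str = ""


# ---------------------------------------------------------------------------
# taxonomy and species tree

def _join_random_subtrees(nodes: list, rng: np.random.Generator) -> dendropy.Node:
    """Random sequential joins into a rooted binary tree over given subtrees."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(0.25) + 0.02)
        b.edge.length = float(rng.exponential(0.25) + 0.02)
        nodes.append(parent)
    return nodes[0]


def simulate_taxonomy(config: SimulationConfig) -> SpeciesSet:
    """Species with a four-rank taxonomy, lifestyles, genome sizes, and a
    rooted bifurcating species tree whose clades respect the taxonomy."""
    if config.n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    n = config.n_species
    ids = [f"S{i:03d}" for i in range(n)]
    n_genera = max(1, round(n / 4))
    n_families = max(1, round(n_genera / 3))
    genus_of = np.concatenate([np.arange(n_genera),
                               rng.integers(0, n_genera, size=n - n_genera)])
    rng.shuffle(genus_of)
    family_of_genus = np.concatenate([
        np.arange(n_families),
        rng.integers(0, n_families, size=n_genera - n_families)])
    rng.shuffle(family_of_genus)

    lifestyles = rng.choice(3, size=n, p=np.asarray(config.lifestyle_fractions))
    species = []
    for i, sid in enumerate(ids):
        g = int(genus_of[i])
        f = int(family_of_genus[g])
        mean = config.genome_size_mean[int(lifestyles[i])]
        sd = config.genome_size_sd[int(lifestyles[i])]
        size = int(max(150, rng.normal(mean, sd)))
        species.append(Species(
            sid,
            {"species": sid, "genus": f"G{g:03d}", "family": f"F{f:02d}",
             "order": "O1"},
            int(lifestyles[i]), size))

    taxon_ns = dendropy.TaxonNamespace(ids)
    leaf_nodes = {}
    for sid in ids:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(sid)
        leaf_nodes[sid] = node
    genus_roots = {}
    for g in range(n_genera):
        members = [leaf_nodes[ids[i]] for i in range(n) if genus_of[i] == g]
        genus_roots[g] = _join_random_subtrees(members, rng)
    family_roots = {}
    for f in range(n_families):
        members = [genus_roots[g] for g in range(n_genera)
                   if int(family_of_genus[g]) == f]
        family_roots[f] = _join_random_subtrees(members, rng)
    root = _join_random_subtrees(list(family_roots.values()), rng)
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    tree.is_rooted = True
    parsimony.ensure_labels(tree)
    return SpeciesSet(species, tree)


# ---------------------------------------------------------------------------
# sequence building blocks

def sample_signal_peptide(rng: np.random.Generator, tat: bool = False,
                          length: Optional[int] = None) -> str:
    """One tripartite signal peptide; verified against the heuristic scorer."""
    for _ in range(100):
        if tat:
            n_region = "MSRRQFLK"
        else:
            n_len = int(rng.integers(3, 7))  # incl. initiator M
            body = []
            n_kr = 0
            for _ in range(n_len - 1):
                aa = str(rng.choice(list("KRNQSTA")))
                if body and body[-1] in "KR" and aa in "KR":
                    aa = "N"
                if aa in "KR":
                    n_kr += 1
                body.append(aa)
            if n_kr == 0:
                body[0] = "K"
            n_region = "M" + "".join(body)
        if length is None:
            h_len = int(rng.integers(8, 15))
            c_pad = int(rng.integers(0, 4))
        else:
            c_pad = int(rng.integers(0, 2))
            h_len = length - len(n_region) - c_pad - 3
            if h_len < 8 or h_len > 14:
                continue
        h_region = "".join(rng.choice(H_REGION_AA, size=h_len, p=H_REGION_P))
        c_region = ("".join(rng.choice(list("STNQG"), size=c_pad))
                    + "A" + str(rng.choice(list("STNQ"))) + "A")
        sp = n_region + h_region + c_region
        if length is not None and len(sp) != length:
            continue
        if len(sp) < 15 or len(sp) > 40:
            continue
        probe = sp + "TDNSQEGKTDNSQEG"
        score, cpos = heuristic_sp_score(probe)
        if score > 0.5 and cpos == len(sp) and detect_tat_motif(probe) == tat:
            return sp
    raise RuntimeError("could not sample a consistent signal peptide")


def sample_remnant(rng: np.random.Generator, length: Optional[int] = None) -> str:
    """Polar N-terminal segment that the scorer rejects."""
    if length is None:
        length = int(rng.integers(15, 25))
    return "M" + "".join(rng.choice(POLAR_AA, size=length - 1))


def destroy_sp(segment: str, rng: np.random.Generator) -> str:
    """Substitution-mechanism loss: rewrite ~half of the residues with polar
    ones, conserving length (initiator M kept)."""
    out = list(segment)
    for i in range(1, len(out)):
        if rng.random() < 0.55:
            out[i] = str(rng.choice(list("STNQDEG")))
    return "".join(out)


def build_sp_from_remnant(segment: str, rng: np.random.Generator) -> Optional[str]:
    """Substitution-mechanism gain: rewrite the segment into a signal peptide
    of identical length; None when the length cannot host one."""
    if not 15 <= len(segment) <= 40:
        return None
    try:
        return sample_signal_peptide(rng, length=len(segment))
    except RuntimeError:
        return None


def _random_body(rng: np.random.Generator, length: int) -> str:
    body = ["M"] + [str(a) for a in rng.choice(list(AA), size=length - 1)]
    # guarantee an in-frame alternative start early in the mature chain
    if not any(a in "MVL" for a in body[2:7]):
        body[3] = str(rng.choice(list("MVL")))
    return "".join(body)


# ---------------------------------------------------------------------------
# family simulation

@dataclass
class _NodeSeq:
    blocks: list[tuple[str, str]]  # (block_id, seq), leftmost first
    sp: bool  # leftmost block is a functional signal peptide
    body: str


def _mutate_body(body: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return body
    out = list(body)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        if i == 0:
            continue
        out[i] = str(rng.choice(list(AA)))
    return "".join(out)


def _all_endo(node: dendropy.Node, lifestyles: dict[str, str]) -> bool:
    return all(lifestyles[leaf.taxon.label] == 1 for leaf in node.leaf_iter())


def simulate_family(
    config: SimulationConfig,
    species_set: SpeciesSet,
    species_subset: Sequence[str],
    cluster_id: str,
    seed: int,
) -> tuple[OrthologCluster, FamilyTruth]:
    """Evolve one ortholog family along the induced species subtree.

    Returns the cluster (members with coding sequences and genomic context,
    the true MSA, the rooted true tree) and the planted ground truth.
    Resamples internally (new derived seed) if the heuristic readout of any
    leaf disagrees with its planted state.
    """
    if len(species_subset) < 3:
        raise ValueError("family needs at least 3 species")
    for attempt in range(30):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        result = _try_simulate_family(config, species_set, species_subset,
                                      cluster_id, rng)
        if result is not None:
            return result
    raise RuntimeError(f"family {cluster_id}: no consistent sample in 30 attempts")


def _induced_tree(species_tree: dendropy.Tree, subset, cluster_id) -> dendropy.Tree:
    tree = species_tree.extract_tree_with_taxa_labels(labels=list(subset))
    ns = dendropy.TaxonNamespace()
    tree.migrate_taxon_namespace(ns)
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = f"{cluster_id}|{leaf.taxon.label}"
    for node in tree.preorder_node_iter():
        node.label = None  # relabel deterministically per family
    tree.is_rooted = True
    parsimony.ensure_labels(tree)
    return tree


def _try_simulate_family(config, species_set, subset, cluster_id, rng):
    tree = _induced_tree(species_set.tree, subset, cluster_id)
    lifestyles = {f"{cluster_id}|{s.species_id}": s.lifestyle
                  for s in species_set.species}
    is_tat = bool(rng.random() < config.tat_fraction)
    body_len = int(rng.integers(*config.body_length_range))
    body = _random_body(rng, body_len)

    block_order: list[tuple[str, int]] = []  # (block_id, width), leftmost first
    block_counter = 0

    def new_block(seq: str) -> str:
        nonlocal block_counter
        bid = f"b{block_counter}"
        block_counter += 1
        block_order.insert(0, (bid, len(seq)))
        return bid

    root_state = int(rng.random() < config.root_sp_prob)
    if root_state:
        seg = sample_signal_peptide(rng, tat=is_tat)
    else:
        seg = sample_remnant(rng)
    root_bid = f"b{block_counter}"
    block_counter += 1
    block_order.append((root_bid, len(seg)))
    root_seq = _NodeSeq([(root_bid, seg)], bool(root_state), body)

    node_states: dict[str, int] = {}
    events: list[dict] = []
    node_seqs: dict[str, _NodeSeq] = {}

    for node in tree.preorder_node_iter():
        key = parsimony.node_key(node)
        if node.parent_node is None:
            node_seqs[key] = root_seq
            node_states[key] = root_state
            continue
        parent = node_seqs[parsimony.node_key(node.parent_node)]
        body_child = _mutate_body(parent.body, config.substitution_rate, rng)
        blocks = list(parent.blocks)
        sp = parent.sp
        loss_rate = config.sp_loss_rate
        if _all_endo(node, lifestyles):
            loss_rate = min(1.0, loss_rate * config.endo_loss_multiplier)
        if sp and rng.random() < loss_rate:
            if rng.random() < config.mechanism_mix:
                blocks = blocks[1:]  # indel: drop the whole segment
                mech = "indel"
            else:
                bid, seq = blocks[0]
                blocks[0] = (bid, destroy_sp(seq, rng))
                mech = "substitution"
            sp = False
            events.append({"parent": parsimony.node_key(node.parent_node),
                           "child": key, "type": "loss", "mechanism": mech})
        elif not sp and rng.random() < config.sp_gain_rate:
            mech = "indel" if rng.random() < config.mechanism_mix else "substitution"
            if mech == "substitution":
                # needs an existing N-terminal segment of hostable length
                rebuilt = build_sp_from_remnant(blocks[0][1], rng) if blocks else None
                if rebuilt is None:
                    mech = "indel"
                else:
                    blocks[0] = (blocks[0][0], rebuilt)
            if mech == "indel":
                seq = sample_signal_peptide(rng, tat=is_tat)
                blocks = [(new_block(seq), seq)] + blocks
            sp = True
            events.append({"parent": parsimony.node_key(node.parent_node),
                           "child": key, "type": "gain", "mechanism": mech})
        node_seqs[key] = _NodeSeq(blocks, sp, body_child)
        node_states[key] = int(sp)

    # --- assemble leaves: sequences, MSA rows, CDS with genomic context
    leaf_keys = sorted(l.taxon.label for l in tree.leaf_node_iter())
    widths = dict(block_order)
    col_blocks = [bid for bid, _ in block_order]
    members, rows, cleavage = [], {}, {}
    truth = FamilyTruth(node_states, events, {}, {}, is_tat=is_tat)
    for label in leaf_keys:
        ns = node_seqs[label]
        have = dict(ns.blocks)
        row_parts = [have.get(bid, GAP * widths[bid]) for bid in col_blocks]
        row = "".join(row_parts) + ns.body
        seq = "".join(have.get(bid, "") for bid in col_blocks) + ns.body
        state = int(ns.sp)
        # ensure a downstream in-frame start exists past the signal peptide
        if state:
            sp_len = len(ns.blocks[0][1])
            lo = sp_len
            hi = min(len(seq) - 2, sp_len + config.start_shift_range[1])
            if not any(seq[j] in "MVL" for j in range(lo, hi + 1)):
                delta = int(rng.integers(config.start_shift_range[0],
                                         config.start_shift_range[1] + 1))
                j = min(len(seq) - 2, sp_len + delta)
                aa = str(rng.choice(list("MVL")))
                seq = seq[:j] + aa + seq[j + 1:]
                # mirror in the alignment row
                res_idx = -1
                row_list = list(row)
                for c, ch in enumerate(row_list):
                    if ch != GAP:
                        res_idx += 1
                        if res_idx == j:
                            row_list[c] = aa
                            break
                row = "".join(row_list)
        # ground-truth consistency of the zero-noise heuristic readout
        score, cpos = heuristic_sp_score(seq)
        if (score > 0.5) != bool(state):
            return None
        if state:
            if cpos != sp_len:
                return None
            cleavage[label] = sp_len
        if detect_tat_motif(seq) != (is_tat and state):
            return None
        # a non-secreted label is only well defined if no alternative
        # in-frame start exposes a signal-peptide-like window
        if not state and _has_truncation_decoy(seq):
            return None
        rows[label] = row
        cds = _back_translate(seq, rng)
        upstream = _random_context(rng, config.context_len)
        downstream = "TAA" + _random_context(rng, config.context_len - 3)
        # an in-frame stop sits shortly upstream of essentially every real
        # prokaryotic gene start; plant one, plus an alternative start below it
        u_stop = int(rng.integers(10, 15))
        s0 = config.context_len - 3 * u_stop
        upstream = upstream[:s0] + "TAA" + upstream[s0 + 3:]
        u_res = int(rng.integers(2, u_stop))
        u0 = config.context_len - 3 * u_res
        codon = str(rng.choice(START_CODONS))
        upstream = upstream[:u0] + codon + upstream[u0 + 3:]
        genomic = upstream + cds + downstream
        species_id = label.split("|", 1)[1]
        members.append(ProteinRecord(
            protein_id=label, species_id=species_id, sequence=seq,
            genomic_seq=genomic, cds_start=config.context_len,
            cds_end=config.context_len + len(cds), true_state=state))
        truth.true_starts[label] = config.context_len
    truth.true_rows = dict(rows)
    truth.cleavage = cleavage
    msa = Msa(leaf_keys, rows)
    cluster = OrthologCluster(cluster_id, members, {}, msa, tree)
    return cluster, truth


def _has_truncation_decoy(seq: str, scan: int = 45) -> bool:
    """True if truncating at some in-frame-startable residue (M/V/L) within
    the N-terminal scan range yields a positive heuristic call."""
    for j in range(1, min(scan, len(seq) - 15)):
        if seq[j] in "MVL":
            score, _ = heuristic_sp_score("M" + seq[j + 1:])
            if score > 0.5:
                return True
    return False


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    picks = rng.integers(0, 6, size=len(protein))
    codons = ["ATG"]
    for aa, pick in zip(protein[1:], picks[1:]):
        options = CODONS[aa]
        codons.append(options[pick % len(options)])
    return "".join(codons)


_NT = "ACGT"


def _random_context(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# start-error planting and predictor emulation

def plant_start_errors(
    cluster: OrthologCluster,
    truth: FamilyTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> OrthologCluster:
    """Corrupt the annotated start of a random fraction of SP-bearing members.

    The start is moved downstream to the next in-frame ATG/GTG/TTG past the
    signal-peptide-encoding region; the amino-acid sequence and alignment row
    are re-derived and the true start stays recorded in the ground truth.
    Members whose truncated form would still score as secreted are skipped.
    """
    if config.start_error_rate <= 0:
        return cluster
    for record in cluster.members:
        label = record.protein_id
        if truth.node_states.get(label) != 1:
            continue
        if rng.random() >= config.start_error_rate:
            continue
        sp_len = truth.cleavage[label]
        cds = record.cds
        shift = None
        for j in range(sp_len, min(len(record.sequence) - 15,
                                   sp_len + config.start_shift_range[1] + 1)):
            if cds[3 * j:3 * j + 3] in START_CODONS:
                shift = j
                break
        if shift is None:
            log.debug("no in-frame alternative start for %s; member skipped", label)
            continue
        new_seq = "M" + record.sequence[shift + 1:]
        score, _ = heuristic_sp_score(new_seq)
        if score > 0.5 or detect_tat_motif(new_seq):
            log.debug("truncation of %s keeps a positive call; skipped", label)
            continue
        record.sequence = new_seq
        record.cds_start += 3 * shift
        # gap out the removed prefix in the alignment row; initiator becomes M
        row = list(cluster.msa.row(label))
        res_idx = -1
        for c, ch in enumerate(row):
            if ch != GAP:
                res_idx += 1
                if res_idx < shift:
                    row[c] = GAP
                elif res_idx == shift:
                    row[c] = "M"
                    break
        cluster.msa = cluster.msa.replace_row(label, "".join(row))
        truth.start_errors[label] = shift
    return cluster


def emulate_predictors(
    record: ProteinRecord,
    predictor_noise: tuple[float, float, float],
    seed: int,
) -> PredictionTriple:
    """SignalP/Phobius/TatP-like calls for one protein.

    With zero noise the calls equal the heuristic scorer's decision (and the
    twin-arginine detector for the Tat call); each call is independently
    flipped with its per-tool noise probability, the score staying consistent
    with the call at the 0.5 threshold.
    """
    if not record.sequence:
        raise ValueError(f"empty sequence for {record.protein_id}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    score, cpos = heuristic_sp_score(record.sequence)
    base_call = score > 0.5
    flip_sp, flip_phob, flip_tat = (rng.random(3) < np.asarray(predictor_noise))
    signalp_call = bool(base_call ^ flip_sp)
    if signalp_call == base_call:
        jitter = float(rng.uniform(-0.04, 0.04))
        score = min(1.0, max(0.0, score + jitter))
        score = max(score, 0.51) if signalp_call else min(score, 0.49)
    else:
        score = float(rng.uniform(0.55, 0.8)) if signalp_call \
            else float(rng.uniform(0.2, 0.45))
    phobius_call = bool(base_call ^ flip_phob)
    tat_call = bool(detect_tat_motif(record.sequence) ^ flip_tat)
    cleavage = cpos if (signalp_call and cpos is not None) else None
    return PredictionTriple(round(score, 4), signalp_call, phobius_call,
                            tat_call, cleavage)


# ---------------------------------------------------------------------------
# GO emulation

GO_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


def build_go_dag() -> tuple[str, list[tuple[str, str, str, list[str]]]]:
    """A small fixed GO-like DAG (synthetic stand-in for the real ontology).

    Returns the OBO text and the term table (id, name, namespace, is_a
    parents).  Includes a diamond (GO:1000113 has two parents).
    """
    terms = []
    idx = 100
    for ns_i, ns in enumerate(GO_NAMESPACES):
        root = f"GO:{idx * 10 + ns_i:07d}"
        terms.append((root, f"{ns} root", ns, []))
        mids = []
        for m in range(2):
            mid = f"GO:{1000000 + ns_i * 100 + m:07d}"
            mids.append(mid)
            terms.append((mid, f"{ns} mid {m}", ns, [root]))
        for k in range(4):
            leaf = f"GO:{1000010 + ns_i * 100 + k:07d}"
            parents = [mids[k % 2]]
            if ns_i == 1 and k == 3:
                parents = mids[:]  # diamond
            terms.append((leaf, f"{ns} leaf {k}", ns, parents))
    lines = ["format-version: 1.2", "ontology: go-synthetic", ""]
    for tid, name, ns, parents in terms:
        lines += ["[Term]", f"id: {tid}", f"name: {name}", f"namespace: {ns}"]
        lines += [f"is_a: {p} ! parent" for p in parents]
        lines.append("")
    return "\n".join(lines), terms


#: leaf terms biased toward secreted proteins (membrane/transport-like)
SECRETION_TERMS = ("GO:1000210", "GO:1000211", "GO:1000010")
#: leaf terms biased toward cytoplasmic proteins
INTRACELLULAR_TERMS = ("GO:1000212", "GO:1000213", "GO:1000011", "GO:1000110")
OTHER_TERMS = ("GO:1000012", "GO:1000013", "GO:1000111", "GO:1000112",
               "GO:1000113")


def annotate_proteins(
    clusters: Sequence[OrthologCluster],
    rng: np.random.Generator,
) -> dict[str, tuple[str, ...]]:
    annotations = {}
    for cluster in clusters:
        for record in cluster.members:
            secreted = record.true_state == 1
            pool = SECRETION_TERMS if (secreted and rng.random() < 0.7) else (
                INTRACELLULAR_TERMS if (not secreted and rng.random() < 0.7)
                else OTHER_TERMS)
            k = int(rng.integers(1, 3))
            annotations[record.protein_id] = tuple(
                sorted(str(t) for t in rng.choice(list(pool), size=k, replace=False)))
    return annotations


# ---------------------------------------------------------------------------
# whole-dataset simulation

def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Full synthetic dataset: taxonomy, families with planted events and
    start errors, noisy predictor calls, and GO annotations."""
    species_set = simulate_taxonomy(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    sizes = np.array([s.genome_size for s in species_set.species], dtype=float)
    weights = sizes / sizes.sum()
    ids = [s.species_id for s in species_set.species]
    clusters, truth = [], GroundTruth()
    predictions: dict[str, PredictionTriple] = {}
    for f in range(config.n_families):
        k = int(rng.integers(config.family_size_range[0],
                             config.family_size_range[1] + 1))
        k = min(k, len(ids))
        subset = sorted(rng.choice(ids, size=k, replace=False, p=weights))
        cluster_id = f"C{f:04d}"
        cluster, fam_truth = simulate_family(
            config, species_set, subset, cluster_id,
            seed=int((config.seed * 1_000_003 + f) % (2**31)))
        plant_start_errors(cluster, fam_truth, config,
                           np.random.default_rng(
                               np.random.SeedSequence((config.seed, 3, f))))
        for m_i, record in enumerate(cluster.members):
            predictions[record.protein_id] = emulate_predictors(
                record, config.predictor_noise,
                seed=int((config.seed * 11 + f * 1009 + m_i) % (2**31)))
        clusters.append(cluster)
        truth.families[cluster_id] = fam_truth
    lifestyles = {s.species_id: s.lifestyle for s in species_set.species}
    ls_recon = parsimony.lifestyle_transitions(species_set.tree, lifestyles)
    truth.lifestyle_transitions = {
        f"{p}->{c}": cls for (p, c), cls in ls_recon.transitions.items()
        if cls != "uncertain_transition"}
    obo_text, _ = build_go_dag()
    annotations = annotate_proteins(
        clusters, np.random.default_rng(np.random.SeedSequence((config.seed, 4))))
    import io as _io

    import obonet
    go_dag = obonet.read_obo(_io.StringIO(obo_text))
    return Dataset(config, species_set, clusters, predictions, truth,
                   go_dag, annotations, obo_text)
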