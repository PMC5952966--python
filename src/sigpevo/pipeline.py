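"""End-to-end two-round analysis on a dataset (synthetic or loaded).

Stage order: consensus classification -> trees/rooting -> first parsimony
round on mixed clusters -> gene-start correction -> re-filtering and second
parsimony round -> taxonomic placement, lifestyle crosstab, mechanism
classification -> secretome, identity, discrimination, GO-enrichment and
distribution statistics.  All results are collected in a ``RunReport`` and
optionally persisted as TSV/JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import mechanism as mech
from . import parsimony, phylo, startfix, stats
from .secretome import classify_clusters, secretome_summary
from .synthetic_data import Dataset, SimulationConfig, emulate_predictors, \
    simulate_dataset
from .types import ConsensusState, Event, Lifestyle, ProteinRecord

log = logging.getLogger(__name__)

LIFESTYLE_PAIRS = ((Lifestyle.FREE_LIVING, Lifestyle.ENDOSYMBIONT),
                   (Lifestyle.COMMENSAL, Lifestyle.ENDOSYMBIONT),
                   (Lifestyle.FREE_LIVING, Lifestyle.COMMENSAL))


@dataclass
class RoundSummary:
    clusters: dict[str, int]
    events: dict[str, int]

    @classmethod
    def empty(cls) -> "RoundSummary":
        return cls({"negative": 0, "positive": 0, "mixed": 0, "total": 0},
                   {"gain": 0, "loss": 0, "uncertain": 0, "total": 0})


@dataclass
class RunReport:
    round1: RoundSummary
    round2: RoundSummary
    kept_event_fraction: float
    kept_mixed_fraction: float
    secretome: pd.DataFrame
    secretome_fits: dict
    crosstab_counts: pd.DataFrame
    crosstab_percent: pd.DataFrame
    mechanism_table: pd.DataFrame
    mechanisms: list
    identity: dict
    identity_filtered: dict
    discrimination: dict
    spearman_d: Optional[tuple]
    enrichment: list
    ks_tests: dict
    cvm_test: Optional[tuple]
    corrections: list
    events_round1: dict[str, list[Event]]
    events_round2: dict[str, list[Event]]
    event_ranks: list
    reversals: dict

    def to_dict(self) -> dict:
        """JSON-serializable summary (used for determinism checks and CLI)."""
        return {
            "round1": {"clusters": self.round1.clusters,
                       "events": self.round1.events},
            "round2": {"clusters": self.round2.clusters,
                       "events": self.round2.events},
            "kept_event_fraction": self.kept_event_fraction,
            "kept_mixed_cluster_fraction": self.kept_mixed_fraction,
            "crosstab": self.crosstab_counts.to_dict(),
            "mechanism_counts": self.mechanism_table.to_dict("records"),
            "n_corrections": len([c for c in self.corrections
                                  if c.outcome == "accepted_positive"]),
            "identity_means": {k: v["mean"] for k, v in self.identity.items()},
            "secretome_mean_fraction": float(self.secretome["fraction_sp"].mean())
            if len(self.secretome) else float("nan"),
            "event_ranks": [(e.cluster_id, e.parent, e.child, e.etype, r)
                            for e, r in self.event_ranks],
        }


def summarize_round(clusters, events_by_cluster) -> RoundSummary:
    """Cluster and event counts for one parsimony round.

    Events are counted over mixed clusters only; gains, losses and uncertain
    branches are events, keep/stay branches are not.
    """
    counts = {"negative": 0, "positive": 0, "mixed": 0}
    for c in clusters:
        if c.class_label in counts:
            counts[c.class_label] += 1
    counts["total"] = sum(counts.values())
    ev = {"gain": 0, "loss": 0, "uncertain": 0}
    for events in events_by_cluster.values():
        for e in events:
            if e.etype in ev:
                ev[e.etype] += 1
    ev["total"] = sum(ev.values())
    return RoundSummary(counts, ev)


def tabulate_rounds(round1: RoundSummary, round2: RoundSummary) -> pd.DataFrame:
    """Two-round summary with within-round percentages and kept fractions."""
    rows = []
    for name, rnd in (("1", round1), ("2", round2)):
        row = {"round": name}
        for k in ("negative", "positive", "mixed"):
            row[f"clusters_{k}"] = rnd.clusters[k]
            row[f"clusters_{k}_pct"] = _pct(rnd.clusters[k], rnd.clusters["total"])
        row["clusters_total"] = rnd.clusters["total"]
        for k in ("gain", "loss", "uncertain"):
            row[f"events_{k}"] = rnd.events[k]
            row[f"events_{k}_pct"] = _pct(rnd.events[k], rnd.events["total"])
        row["events_total"] = rnd.events["total"]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["kept_event_fraction_pct"] = _pct(
        round2.events["total"], round1.events["total"])
    df.attrs["kept_mixed_cluster_fraction_pct"] = _pct(
        round2.clusters["mixed"], round1.clusters["mixed"])
    return df


def _pct(part: int, total: int) -> float:
    return 100.0 * part / total if total else 0.0


def _leaf_states(cluster) -> dict[str, int]:
    return {pid: 1 if s is ConsensusState.POSITIVE else 0
            for pid, s in cluster.states.items()}


def _prepare_tree(cluster):
    """Ensure a rooted, binary, labelled tree (NJ + midpoint when absent)."""
    if cluster.tree is None:
        if cluster.msa is None or len(cluster.msa) < 3:
            raise ValueError(f"cluster {cluster.cluster_id}: no tree and no "
                             f"alignment to build one from")
        cluster.tree = phylo.midpoint_root(phylo.build_nj_tree(cluster.msa))
    elif not cluster.tree.is_rooted:
        cluster.tree = phylo.midpoint_root(cluster.tree)
    parsimony.binarize(cluster.tree)
    return cluster.tree


def _parsimony_round(clusters):
    """Fitch + event calling on every mixed cluster."""
    events, recons = {}, {}
    for cluster in clusters:
        if cluster.class_label != "mixed":
            continue
        tree = _prepare_tree(cluster)
        recon = parsimony.fitch(tree, _leaf_states(cluster), n_states=2)
        recons[cluster.cluster_id] = recon
        events[cluster.cluster_id] = parsimony.call_events(
            recon, tree, cluster.cluster_id)
    return events, recons


def make_noisy_predictor(config: SimulationConfig, seed: int):
    """Sequence-level predictor with the configured per-tool noise; draws are
    taken from one seeded stream, so results depend only on call order."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))

    def predict(sequence: str):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        stub = ProteinRecord(protein_id="candidate", species_id="",
                             sequence=sequence)
        return emulate_predictors(stub, config.predictor_noise, sub_seed)

    if all(p == 0 for p in config.predictor_noise):
        return startfix.zero_noise_predictor
    return predict


def run_all(
    config: Optional[SimulationConfig] = None,
    dataset: Optional[Dataset] = None,
    out_dir: Optional[str] = None,
) -> RunReport:
    """Execute the full two-round analysis; returns the ``RunReport``.

    Exactly one of ``config`` (simulate first) or ``dataset`` (pre-loaded or
    pre-simulated; consumed/mutated) must be given.
    """
    if (config is None) == (dataset is None):
        raise ValueError("pass exactly one of config or dataset")
    if dataset is None:
        dataset = simulate_dataset(config)
    cfg = dataset.config
    species = dataset.species_set.by_id()

    # --- round 1
    clusters = classify_clusters(dataset.clusters, dataset.predictions)
    log.info("round 1: %d clusters classified", len(clusters))
    events1, _ = _parsimony_round(clusters)
    round1 = summarize_round(clusters, events1)

    # --- gene start correction + round 2
    predictor = make_noisy_predictor(cfg, cfg.seed)
    clusters, decisions = startfix.run_round2(
        clusters, dataset.predictions, predictor)
    for dec in decisions:
        if dec.outcome == "accepted_positive":
            dataset.predictions[dec.protein_id] = dec.candidate.triple
    events2, recons2 = _parsimony_round(clusters)
    round2 = summarize_round(clusters, events2)
    kept_events = _pct(round2.events["total"], round1.events["total"])
    kept_mixed = _pct(round2.clusters["mixed"], round1.clusters["mixed"])
    log.info("round 2: %d/%d events kept (%.1f%%)",
             round2.events["total"], round1.events["total"], kept_events)

    mixed = [c for c in clusters if c.class_label == "mixed"]
    taxonomy = {sid: sp.taxonomy for sid, sp in species.items()}
    species_of = lambda label: label.split("|", 1)[1] \
        if "|" in label else label  # noqa: E731

    # --- taxonomic placement of round-2 gain/loss events
    event_ranks = []
    for cluster in mixed:
        for e in events2[cluster.cluster_id]:
            if e.etype in ("gain", "loss", "uncertain"):
                rank = parsimony.assign_event_rank(
                    e, cluster.tree, taxonomy, species_of)
                event_ranks.append((e, rank))

    # --- lifestyle reconstruction and crosstab (mixed clusters)
    lifestyle_recons = {}
    for cluster in mixed:
        leaf_ls = {m.protein_id: species[m.species_id].lifestyle
                   for m in cluster.members}
        lifestyle_recons[cluster.cluster_id] = parsimony.lifestyle_transitions(
            cluster.tree, leaf_ls)
    xt_counts, xt_pct = parsimony.crosstab_events_lifestyle(
        {cid: evs for cid, evs in events2.items()}, lifestyle_recons)

    # --- mechanisms on latest events
    mechanisms, reversals = [], {"reversals": [], "double_reversals": []}
    for cluster in mixed:
        gl = [e for e in events2[cluster.cluster_id]
              if e.etype in ("gain", "loss")]
        latest, rep = mech.latest_events(gl, cluster.tree)
        reversals["reversals"].extend(rep["reversals"])
        reversals["double_reversals"].extend(rep["double_reversals"])
        cleavage = {m.protein_id:
                    dataset.predictions[m.protein_id].cleavage_pos
                    for m in cluster.members}
        states = _leaf_states(cluster)
        for e in latest:
            m_res = mech.classify_event_mechanism(
                e, cluster.msa, cleavage, cluster.tree, states)
            if m_res is not None:
                mechanisms.append(m_res)
    mech_table = mech.mechanism_summary(mechanisms)

    # --- sequence identity distributions
    identity = phylo.identity_distributions(mixed)
    identity_filtered = phylo.identity_distributions(mixed, max_identity=0.95)

    # --- per-genome secretome
    rows = []
    for cluster in clusters:
        if cluster.class_label == "rejected":
            continue
        for m in cluster.members:
            rows.append((m.protein_id, m.species_id,
                         species[m.species_id].lifestyle,
                         cluster.states[m.protein_id].value))
    records = pd.DataFrame(
        rows, columns=["protein_id", "species_id", "lifestyle", "state"])
    secretome, fits = (secretome_summary(records) if len(rows)
                       else (pd.DataFrame(columns=["species_id", "lifestyle",
                                                   "n_proteins", "n_sp",
                                                   "fraction_sp"]), {}))

    # --- discrimination scores per mixed cluster and lifestyle pair
    discrimination = {pair: [] for pair in LIFESTYLE_PAIRS}
    for cluster in mixed:
        by_ls: dict[int, list[int]] = {}
        for m in cluster.members:
            st = cluster.states[m.protein_id]
            by_ls.setdefault(species[m.species_id].lifestyle, []).append(
                1 if st is ConsensusState.POSITIVE else 0)
        counts = {ls: (sum(v), len(v) - sum(v)) for ls, v in by_ls.items()}
        for pair in LIFESTYLE_PAIRS:
            res = stats.cluster_discrimination(
                cluster.cluster_id, pair[0], pair[1], counts)
            if res is not None:
                discrimination[pair].append(res)
    spearman_d = _spearman_between_scores(
        discrimination[LIFESTYLE_PAIRS[0]], discrimination[LIFESTYLE_PAIRS[1]])

    # --- GO enrichment
    enrichment = []
    if dataset.go_dag is not None and dataset.annotations:
        closed = stats.go_propagate(dataset.annotations, dataset.go_dag)
        groups: dict[str, list[str]] = {"positive": [], "negative": [],
                                        "mixed": []}
        sp_groups: dict[str, list[str]] = {"with_sp": [], "without_sp": []}
        for cluster in clusters:
            if cluster.class_label in groups:
                groups[cluster.class_label].extend(cluster.member_ids())
            if cluster.class_label == "mixed":
                for m in cluster.members:
                    key = ("with_sp" if cluster.states[m.protein_id]
                           is ConsensusState.POSITIVE else "without_sp")
                    sp_groups[key].append(m.protein_id)
        enrichment = (stats.go_enrichment(groups, closed)
                      + stats.go_enrichment(sp_groups, closed))

    # --- lifestyle distribution tests on the per-genome table
    ks_tests, cvm = {}, None
    if len(secretome):
        by_ls = {ls: g for ls, g in secretome.groupby("lifestyle")}
        for a, b in LIFESTYLE_PAIRS:
            if int(a) in by_ls and int(b) in by_ls and \
                    min(len(by_ls[int(a)]), len(by_ls[int(b)])) >= 2:
                ks_tests[f"n_proteins_{a.name}_vs_{b.name}"] = stats.ks_two_sample(
                    by_ls[int(a)]["n_proteins"], by_ls[int(b)]["n_proteins"])
                ks_tests[f"fraction_sp_{a.name}_vs_{b.name}"] = stats.ks_two_sample(
                    by_ls[int(a)]["fraction_sp"], by_ls[int(b)]["fraction_sp"])
        fl, en = int(Lifestyle.FREE_LIVING), int(Lifestyle.ENDOSYMBIONT)
        if fl in by_ls and en in by_ls and \
                min(len(by_ls[fl]), len(by_ls[en])) >= 3:
            X = by_ls[fl][["n_proteins", "fraction_sp"]].to_numpy(float)
            Y = by_ls[en][["n_proteins", "fraction_sp"]].to_numpy(float)
            pooled = np.vstack([X, Y])
            mu, sd = pooled.mean(0), pooled.std(0)
            sd[sd == 0] = 1.0
            cvm = stats.cvm_two_sample_multivariate(
                (X - mu) / sd, (Y - mu) / sd, n_permutations=499,
                seed=cfg.seed + 13)

    report = RunReport(
        round1=round1, round2=round2, kept_event_fraction=kept_events,
        kept_mixed_fraction=kept_mixed, secretome=secretome,
        secretome_fits=fits, crosstab_counts=xt_counts, crosstab_percent=xt_pct,
        mechanism_table=mech_table, mechanisms=mechanisms, identity=identity,
        identity_filtered=identity_filtered, discrimination=discrimination,
        spearman_d=spearman_d, enrichment=enrichment, ks_tests=ks_tests,
        cvm_test=cvm, corrections=decisions, events_round1=events1,
        events_round2=events2, event_ranks=event_ranks, reversals=reversals)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _spearman_between_scores(res_a, res_b) -> Optional[tuple]:
    """Spearman rho between two per-cluster d-score sets (matched clusters)."""
    a = {r.cluster_id: r.d for r in res_a}
    b = {r.cluster_id: r.d for r in res_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        return None
    return stats.spearman([a[c] for c in shared], [b[c] for c in shared])


def write_report(report: RunReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab = tabulate_rounds(report.round1, report.round2)
    tab.to_csv(out / "rounds.tsv", sep="\t", index=False)
    report.secretome.to_csv(out / "secretome_summary.tsv", sep="\t", index=False)
    report.crosstab_counts.to_csv(out / "crosstab.tsv", sep="\t")
    report.mechanism_table.to_csv(out / "mechanisms_summary.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(
        [(m.event.cluster_id, m.event.parent, m.event.child, m.event.etype,
          m.lr, m.category, m.nterm_identity, m.cleavage_site_identity,
          m.remainder_identity) for m in report.mechanisms],
        columns=["cluster", "parent", "child", "etype", "lr", "category",
                 "nterm_identity", "cleavage_site_identity",
                 "remainder_identity"]).to_csv(
        out / "mechanisms.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c.protein_id, c.outcome,
          c.candidate.shift if c.candidate else "",
          c.candidate.codon if c.candidate else "")
         for c in report.corrections],
        columns=["protein_id", "outcome", "shift", "codon"]).to_csv(
        out / "corrections.tsv", sep="\t", index=False)
    ranks = {(e.cluster_id, e.parent, e.child): r
             for e, r in report.event_ranks}
    for name, events in (("events_round1.tsv", report.events_round1),
                         ("events_round2.tsv", report.events_round2)):
        pd.DataFrame(
            [(e.cluster_id, e.parent, e.child, e.etype,
              ranks.get((e.cluster_id, e.parent, e.child), ""))
             for evs in events.values() for e in evs],
            columns=["cluster", "parent", "child", "type", "rank"]).to_csv(
            out / name, sep="\t", index=False)
    disc_rows = []
    for pair, results in report.discrimination.items():
        for r in results:
            disc_rows.append((r.cluster_id, pair[0].name, pair[1].name,
                              r.a_sp, r.a_nosp, r.b_sp, r.b_nosp, r.d,
                              r.fisher_p))
    pd.DataFrame(disc_rows, columns=[
        "cluster", "lifestyle_a", "lifestyle_b", "a_sp", "a_nosp", "b_sp",
        "b_nosp", "d", "fisher_p"]).to_csv(
        out / "discrimination.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(r.term, r.group, r.k_in_group, r.n_group, r.K_background,
          r.N_background, r.p_one_sided) for r in report.enrichment],
        columns=["term", "group", "k", "n", "K", "N", "p"]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, default=str)
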