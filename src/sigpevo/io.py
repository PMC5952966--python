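"""Dataset persistence: FASTA/TSV/Newick/OBO/JSON round trip.

A dataset directory holds proteins.faa, cds.fna (CDS coordinates in the
headers), clusters.tsv, predictions.tsv, taxonomy.tsv, lifestyles.tsv,
msa/<cluster>.afa, trees/<cluster>.nwk, go.obo, annotations.tsv and, for
synthetic data, truth.json.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import phylo
from .synthetic_data import Dataset, FamilyTruth, GroundTruth, SimulationConfig, \
    Species, SpeciesSet
from .types import OrthologCluster, PredictionTriple, ProteinRecord


def write_dataset(dataset: Dataset, out_dir) -> None:
    out = Path(out_dir)
    (out / "msa").mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)

    with open(out / "proteins.faa", "w") as faa, \
            open(out / "cds.fna", "w") as fna:
        for cluster in dataset.clusters:
            for m in cluster.members:
                faa.write(f">{m.protein_id}\n{m.sequence}\n")
                fna.write(f">{m.protein_id} cds_start={m.cds_start} "
                          f"cds_end={m.cds_end}\n{m.genomic_seq}\n")

    pd.DataFrame(
        [(c.cluster_id, m.protein_id, m.species_id)
         for c in dataset.clusters for m in c.members],
        columns=["cluster_id", "protein_id", "species_id"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(pid, t.signalp_score, int(t.signalp_call), int(t.phobius_call),
          int(t.tatp_call), t.cleavage_pos if t.cleavage_pos else "")
         for pid, t in sorted(dataset.predictions.items())],
        columns=["protein_id", "signalp_score", "signalp_call",
                 "phobius_call", "tatp_call", "cleavage_pos"]).to_csv(
        out / "predictions.tsv", sep="\t", index=False)

    sp = dataset.species_set
    pd.DataFrame(
        [(s.species_id, s.taxonomy["order"], s.taxonomy["family"],
          s.taxonomy["genus"], s.taxonomy["species"], s.genome_size)
         for s in sp.species],
        columns=["species_id", "order", "family", "genus", "species",
                 "genome_size"]).to_csv(out / "taxonomy.tsv", sep="\t",
                                        index=False)
    pd.DataFrame(
        [(s.species_id, s.lifestyle) for s in sp.species],
        columns=["species_id", "lifestyle"]).to_csv(
        out / "lifestyles.tsv", sep="\t", index=False)
    with open(out / "species_tree.nwk", "w") as fh:
        fh.write(phylo.tree_to_newick(sp.tree) + "\n")

    for cluster in dataset.clusters:
        if cluster.msa is not None:
            cluster.msa.to_fasta(out / "msa" / f"{cluster.cluster_id}.afa")
        if cluster.tree is not None:
            with open(out / "trees" / f"{cluster.cluster_id}.nwk", "w") as fh:
                fh.write(phylo.tree_to_newick(cluster.tree) + "\n")

    if dataset.go_obo_text:
        (out / "go.obo").write_text(dataset.go_obo_text)
    if dataset.annotations:
        pd.DataFrame(
            [(pid, ",".join(terms))
             for pid, terms in sorted(dataset.annotations.items())],
            columns=["protein_id", "go_terms"]).to_csv(
            out / "annotations.tsv", sep="\t", index=False)

    if dataset.truth is not None:
        payload = {
            "config": dataclasses.asdict(dataset.config),
            "families": {cid: dataclasses.asdict(fam)
                         for cid, fam in dataset.truth.families.items()},
            "lifestyle_transitions": dataset.truth.lifestyle_transitions,
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=0, sort_keys=True)


def load_dataset(in_dir) -> Dataset:
    src = Path(in_dir)
    for required in ("proteins.faa", "clusters.tsv", "predictions.tsv",
                     "taxonomy.tsv", "lifestyles.tsv"):
        if not (src / required).exists():
            raise FileNotFoundError(f"missing input file: {src / required}")

    from Bio import SeqIO
    proteins = {rec.id: str(rec.seq)
                for rec in SeqIO.parse(str(src / "proteins.faa"), "fasta")}
    genomic, coords = {}, {}
    if (src / "cds.fna").exists():
        for rec in SeqIO.parse(str(src / "cds.fna"), "fasta"):
            genomic[rec.id] = str(rec.seq)
            fields = dict(kv.split("=") for kv in rec.description.split()[1:]
                          if "=" in kv)
            coords[rec.id] = (int(fields.get("cds_start", 0)),
                              int(fields.get("cds_end", 0)))

    tax = pd.read_csv(src / "taxonomy.tsv", sep="\t")
    ls = pd.read_csv(src / "lifestyles.tsv", sep="\t").set_index("species_id")
    species = [Species(r.species_id,
                       {"order": r.order, "family": r.family,
                        "genus": r.genus, "species": r.species},
                       int(ls.loc[r.species_id, "lifestyle"]),
                       int(getattr(r, "genome_size", 0)))
               for r in tax.itertuples()]
    sp_tree = None
    if (src / "species_tree.nwk").exists():
        sp_tree = phylo.tree_from_newick((src / "species_tree.nwk").read_text())
    species_set = SpeciesSet(species, sp_tree)

    preds = {}
    for r in pd.read_csv(src / "predictions.tsv", sep="\t").itertuples():
        cp = None if pd.isna(r.cleavage_pos) or r.cleavage_pos == "" \
            else int(r.cleavage_pos)
        preds[r.protein_id] = PredictionTriple(
            float(r.signalp_score), bool(r.signalp_call),
            bool(r.phobius_call), bool(r.tatp_call), cp)

    memb = pd.read_csv(src / "clusters.tsv", sep="\t")
    clusters = []
    for cid, grp in memb.groupby("cluster_id", sort=True):
        members = []
        for r in grp.itertuples():
            g = genomic.get(r.protein_id, "")
            c0, c1 = coords.get(r.protein_id, (0, 0))
            members.append(ProteinRecord(r.protein_id, r.species_id,
                                         proteins[r.protein_id], g, c0, c1))
        msa_path = src / "msa" / f"{cid}.afa"
        tree_path = src / "trees" / f"{cid}.nwk"
        msa = phylo.Msa.from_fasta(msa_path) if msa_path.exists() else None
        tree = (phylo.tree_from_newick(tree_path.read_text())
                if tree_path.exists() else None)
        clusters.append(OrthologCluster(str(cid), members, {}, msa, tree))

    truth, config = None, SimulationConfig()
    if (src / "truth.json").exists():
        payload = json.loads((src / "truth.json").read_text())
        cfg_dict = payload["config"]
        for key in ("lifestyle_fractions", "family_size_range",
                    "start_shift_range", "predictor_noise",
                    "body_length_range"):
            cfg_dict[key] = tuple(cfg_dict[key])
        for key in ("genome_size_mean", "genome_size_sd"):
            cfg_dict[key] = {int(k): v for k, v in cfg_dict[key].items()}
        config = SimulationConfig(**cfg_dict)
        truth = GroundTruth(
            {cid: FamilyTruth(**{**fam, "node_states": {
                k: int(v) for k, v in fam["node_states"].items()}})
             for cid, fam in payload["families"].items()},
            payload.get("lifestyle_transitions", {}))

    go_dag, annotations, obo_text = None, {}, ""
    if (src / "go.obo").exists():
        import io as _io

        import obonet
        obo_text = (src / "go.obo").read_text()
        go_dag = obonet.read_obo(_io.StringIO(obo_text))
    if (src / "annotations.tsv").exists():
        ann = pd.read_csv(src / "annotations.tsv", sep="\t")
        annotations = {r.protein_id: tuple(str(r.go_terms).split(","))
                       for r in ann.itertuples()}

    return Dataset(config, species_set, clusters, preds, truth, go_dag,
                   annotations, obo_text)
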