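# sigpevo

Evolutionary dynamics of bacterial signal peptides across orthologous
protein families: which orthologs changed their ability to be secreted,
where on the species tree, by what molecular mechanism, and how those
changes track bacterial lifestyle.

Most secreted bacterial proteins reach the Sec translocon via a cleavable
N-terminal **signal peptide** (SP) — a 20–30 residue segment with a
positively charged n-region, a hydrophobic h-region, and a polar c-region
ending in a signal-peptidase motif (canonically A-x-A). Orthologs of the
same protein can differ in SP possession, so secretion is itself an evolving
character. `sigpevo` implements the full analysis chain for studying it:

1. **Consensus secretion states** from SignalP/Phobius/TatP-style calls
   (Tat substrates reject the cluster; discordant proteins are discarded)
   and positive/negative/mixed cluster classification.
2. **Fitch parsimony** on rooted cluster trees for the binary SP character:
   each branch becomes a gain (0→1), loss (1→0), uncertain, or unchanged.
3. **Gene-start correction**: mis-annotated starts truncate SP-encoding
   regions and fake loss events. Alternative in-frame ATG/GTG/TTG starts in
   an MSA-derived window are re-predicted; rescued proteins flip to
   positive, and a second parsimony round measures how many round-1 events
   survive.
4. **Mechanisms**: for each leaf-nearest event, the length ratio
   lr = L(non-SP N-terminus) / L(signal peptide) over aligned descendant
   pairs separates whole-segment indels (lr ≈ 0) from substitution-driven
   changes (lr ≈ 1); reversals are reported.
5. **Lifestyle statistics**: 3-state lifestyle parsimony
   (free-living/endosymbiont/commensal) crossed with SP events; per-cluster
   discrimination scores d(a,b,g) = (a⁺−a⁻)/(a⁺+a⁻) − (b⁺−b⁻)/(b⁺+b⁻) with
   Fisher tests; GO-term enrichment after is_a closure; KS and multivariate
   energy-distance permutation tests of secretome size against lifestyle.

Because the real inputs (proteomes, ortholog databases, trained predictors)
are external services, the package ships a first-class **synthetic data
generator**: ortholog families evolved along a species tree with known SP
state at every node, planted gain/loss events of both mechanisms, planted
gene-start errors, lifestyle-correlated genome sizes, noisy predictor calls,
and a GO DAG — so every stage is testable against ground truth.
See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
from sigpevo import SimulationConfig, run_all

cfg = SimulationConfig(seed=7, n_species=30, n_families=60)
report = run_all(config=cfg)
r1, r2 = report.round1, report.round2
print(f"round 1: {r1.clusters['mixed']} mixed clusters, "
      f"{r1.events['gain']} gains / {r1.events['loss']} losses / "
      f"{r1.events['uncertain']} uncertain")
print(f"round 2: {r2.clusters['mixed']} mixed clusters, "
      f"{r2.events['gain']} gains / {r2.events['loss']} losses / "
      f"{r2.events['uncertain']} uncertain")
print(f"kept events: {report.kept_event_fraction:.1f}%  "
      f"kept mixed clusters: {report.kept_mixed_fraction:.1f}%")
```

prints

```
round 1: 17 mixed clusters, 8 gains / 14 losses / 4 uncertain
round 2: 14 mixed clusters, 8 gains / 7 losses / 4 uncertain
kept events: 73.1%  kept mixed clusters: 82.4%
```

Half of the round-1 losses disappear after gene-start correction — they were
planted annotation errors, not evolution. The per-genome secretome table
shows the lifestyle signal (mean SP fraction 0.159 for free-living genomes
vs. 0.097 for endosymbionts in this run), and the mechanism table splits the
remaining events into indel vs. substitution categories:

```
etype     category  count
 gain        indel      7
 gain substitution      1
 loss        indel      5
 loss substitution      2
```

The same pipeline runs from the shell:

```bash
sigpevo simulate --config sim.toml --out data/      # synthetic dataset
sigpevo run --in data/ --out results/               # full two-round analysis
sigpevo report --out results/                       # JSON summary
sigpevo tree --msa data/msa/C0000.afa               # NJ + midpoint rooting
```

`sigpevo run` writes every stage's output (`rounds.tsv`, `events_round*.tsv`,
`corrections.tsv`, `crosstab.tsv`, `mechanisms.tsv`, `discrimination.tsv`,
`enrichment.tsv`, `secretome_summary.tsv`, `report.json`) so each step can
be audited independently.

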