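# oxascreen

Tools for the computational redesign of bacterial **biotin carboxylase (BC)
inhibitors** built on the amino-oxazole scaffold. BC catalyzes the first
half-reaction of acetyl-CoA carboxylase, the committed step of bacterial
fatty-acid synthesis, and its ATP binding site is a validated antibacterial
target. Known amino-oxazole inhibitors are potent against Gram-negative but
not Gram-positive species; the route to broad-spectrum analogs is to vary
the two substituents (R1, R2) attached to the scaffold's amide nitrogen and
ask which chemotypes rank well against BC isoforms from *both* Gram groups.

The package implements the computational side of that campaign for anyone
running structure-based virtual screens of combinatorial libraries:

- **Library construction** — couple pairs of small building blocks
  (6–12 heavy atoms, ≤ 18 combined) to the 2-amino-oxazole-5-carboxamide
  scaffold, with Tanimoto-0.95 redundancy removal and seeded reservoir
  subsampling.
- **Binding-site conservation** — Shannon entropy H = −Σ p·log₂ p of
  per-position amino-acid frequencies, and classification of the 21
  binding-site residues across seven BC isoforms (four Gram-negative,
  three Gram-positive) as conserved, Gram-specific or variable.
- **Docking post-processing** — anchor-consistency filtering (the docked
  amino-oxazole substructure must sit within 2 Å of its reference pose in
  *every* isoform), the joint-probability accuracy estimate p = f^(1/k),
  and SUM-rule rank fusion of four docking scores per isoform followed by
  cross-isoform group consensus.
- **Chemotype enrichment** — leader clustering of building blocks at
  Tanimoto 0.7 and BEDROC early-enrichment scores per cluster, position and
  Gram group; ΔBEDROC = BEDROC(Gram−) − BEDROC(Gram+) flags group-specific
  chemotypes at |Δ| > 0.05.
- **Interaction profiling** — distance-based classification of
  protein–ligand contacts (hydrogen bond, halogen bond, aromatic,
  hydrophobic, destabilizing) and per-residue interaction profiles.
- **Synthetic data** — seeded generators standing in for the docking
  engine, vendor catalogues and sequence profiles, with planted structure
  (pass probabilities, inter-group correlations, boosted chemotypes) so
  every stage is testable end to end.

## Worked example

`examples/consensus_ranking.py` simulates a 2,000-compound screen against
the seven BC isoforms with a planted per-isoform anchor pass probability of
0.755 and an inter-group rank correlation of 0.8, then post-processes it:

```text
anchor-consistent compounds: 259 / 2000 (f = 0.130)
estimated per-docking accuracy p = f^(1/7) = 0.747
Gram-negative vs Gram-positive rank correlation: 0.780
top consensus compound (all species): ao-10000002-10000016-0004
```

The joint filter keeps f ≈ 0.755⁷ ≈ 0.14 of the library, the seventh root
recovers the planted single-docking accuracy, and the correlation between
the two group-consensus rankings recovers the planted coupling. Compound
identifiers encode the scaffold code and the R1/R2 block ids plus an
attachment-isomer combination number. The other scripts in `examples/`
demonstrate library enumeration, conservation profiling, ΔBEDROC chemotype
flagging and contact profiling, one capability each.

A full pipeline run (`oxa run --out OUT` or
`oxascreen.pipeline.run_pipeline`) chains library → post-processing →
enrichment → interaction profiling, writes per-stage TSVs and a JSON
report, and is byte-reproducible for a fixed seed.

## Layout

- `src/oxascreen/` — library modules (`chem_core`, `library_builder`,
  `conservation_profiler`, `screening_postprocess`, `enrichment_analysis`,
  `interaction_profiler`, `synthetic_data`, `pipeline`, `cli`)
- `src/oxascreen/data/` — bundled fixtures: the binding-site residue table,
  a protein-like amino-acid background composition, cross-docking benchmark
  RMSDs, reference compound scores, and the curated fragment pool
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, conventions and design choices
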