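# Methods

This note records the models, conventions and numerical choices behind
`oxascreen`, in the spirit of a methods supplement: what is computed, under
which assumptions, and where the design was genuinely open.

## Molecular representation and similarity

Molecules are RDKit structures keyed by canonical SMILES; two objects are
equal iff their canonical strings are. Elements are restricted to the
SMILES organic subset plus halogens, which covers drug-like building
blocks and assembled products.

Fingerprints are hashed **linear-path (topological) fingerprints**, paths
of 1–7 bonds folded into 2048 bits. The Tanimoto coefficient
Tc = |A∩B| / |A∪B| over set bits drives every similarity decision. Two
conventions are fixed here: two all-zero fingerprints compare as identical
(Tc = 1), and an all-zero against a non-empty fingerprint gives 0. A known
property of path fingerprints is that saturated chain homologs beyond the
maximum path length are indistinguishable (octane vs nonane, Tc = 1); the
synthetic redundancy families exploit exactly this, and it is one reason
redundancy removal uses the stringent 0.95 threshold.

Descriptors: molecular weight, Crippen atom-contribution logP (profiling
only, never in ranked comparisons), topological polar surface area,
donors = N/O bearing ≥ 1 H, acceptors = every N and O **except**
pyrrole-type NH (lone pair in the ring) and amide nitrogen. Acceptor
conventions differ between packages; this one is simple, documented, and
used only for profiling and the rule-of-five gate (inclusive bounds:
MW ≤ 500, logP ≤ 5, donors ≤ 5, acceptors ≤ 10).

## Library construction

The scaffold is 2-amino-1,3-oxazole-5-carboxamide (`NC(=O)c1cnc(N)o1`, 9
heavy atoms); both R-groups bond to its primary **amide nitrogen**, located
by SMARTS rather than a hard-coded index. A building block may attach
through any C, N, O or S atom bearing at least one hydrogen. Because both
substituents land on the same nitrogen, (b₁, b₂) and (b₂, b₁) are the same
molecule; enumeration therefore runs over **unordered pairs of
(block, attachment-point) sites**, self-pairing included (the dibenzylamide
prototype uses two identical benzyl groups). Blocks are admitted at 6–12
heavy atoms and a pair must not exceed 18 heavy atoms.

Attachment-isomer variants of the same block pair get sequential
combination numbers (zero-based, enumeration order of attachment-point
pairs, zero-padded to four digits; the parser accepts three-digit forms).
Deduplication — of blocks and of assembled products — is a **greedy leader
pass in input order**: an item is kept iff its Tanimoto to every previously
kept item is below the threshold (default 0.95). This is deterministic,
idempotent, and leaves the kept set pairwise sub-threshold. Subsampling
uses reservoir sampling, so the full library never needs to be held in
memory; a fixed seed reproduces the sample bit for bit.

## Binding-site conservation

Per-position variability is Shannon entropy H = −Σ p·log₂ p in bits
(0·log₂ 0 := 0), computed from 20-component amino-acid frequency vectors.
The bundled background composition is a Swiss-Prot-style table whose
entropy (≈ 4.17 bits) serves as the "maximally variable" reference;
published protein compositions put this value near 4.19, drifting slightly
between database releases, which is why a ±0.05-bit tolerance is attached
wherever it is compared.

The 21-position binding-site table carries, per residue (E. coli
numbering), the profile entropy, a ligand-binding probability/confidence
pair, and the residue identity in the seven isoforms (Ec, Hi, Pa, Mc
Gram-negative; Ef, Sp, Sa Gram-positive). Positions classify as
`conserved_all` (one residue everywhere), `gram_specific` (uniform within
each Gram group, different between: 169, 204, 287, 437), or `variable`.
Entropy summaries report the mean and the **sample (n−1)** standard
deviation; for the binding-site entropies the two sd conventions differ by
~0.02 bits (0.766 vs 0.747), so only the mean (1.41 bits) is treated as a
pinned value. Isoform models are described as substitution lists relative
to E. coli (e.g. Ec→Sp includes Y203V and I437T).

## Docking post-processing

One record per compound × isoform carries the anchor RMSD and four scores.
Score directions were an open choice (the score sources do not state
them): affinity is a predicted ln Ki, so **lower is better**; fitness and
binding are probability-like in [0, 1], **higher is better**; the
refinement interaction energy is reported with large positive values for
top compounds, so **higher is better**. All four are configurable per
call.

The anchor-consistency filter keeps a compound iff its anchor RMSD is
≤ 2 Å (inclusive) in *every* isoform; compounds missing any isoform fail.
Treating the k dockings as independent Bernoulli trials, the joint pass
fraction f estimates the single-docking accuracy as **p = f^(1/k)**; with
the reference counts (1,246,716 / 8,898,942, k = 7) this gives 0.755,
reported as 76%.

Ranking is two-level SUM-rule data fusion, nesting fixed as
scores → isoform, then isoforms → group: each score yields ranks (ties
averaged), the four ranks are summed and re-ranked per isoform, and the
per-isoform consensus ranks are summed again over the isoforms of a group
(Gram-negative, Gram-positive, or all). Final orderings break ties by
compound id, making every output deterministic. Rank-based fusion is
invariant under strictly monotone transformations of the underlying
scores — asserted as a test. Agreement between group consensuses is the
Pearson correlation of relative ranks (rank/N), i.e. a Spearman-type
statistic. Benchmark pose counting uses a strict `< cutoff` comparison; on
the bundled 14-ligand benchmark no value lies in [2.0, 2.208), so strict
vs inclusive is observationally equivalent there.

## Chemotype enrichment

Building blocks are clustered by the same greedy leader rule at Tanimoto
0.7 against the cluster **leader**; the representative of a cluster is the
member maximizing mean similarity to its co-members (lowest id on ties).

Enrichment of a cluster at a position (R1 or R2) treats the compounds
carrying a member block *at that exact position* as actives inside the
group-consensus ranking and scores them with **BEDROC**:

RIE = (Σᵢ e^(−α·rᵢ/N)) / ((n/N)·(1−e^(−α)) / (e^(α/N)−1)),
BEDROC = RIE · Ra·sinh(α/2) / (cosh(α/2) − cosh(α/2 − α·Ra)) + 1/(1 − e^(α(1−Ra))),

with Ra = n/N and α = 20 by default — the standard early-recognition
weighting, under which the top ~1/α of the list dominates. The degenerate
cases n = 0 and n = N are rejected (the formula is singular) rather than
assigned limit values. ΔBEDROC = BEDROC(Gram−) − BEDROC(Gram+) per cluster
and position; |Δ| > 0.05 is flagged as group-specific. Per-group consensus
lists (not the all-species list) feed the enrichment, matching the
group-contrast question being asked.

## Interaction profiling

Contacts are classified from heavy-atom distances only — no angle terms,
because hydrogens are often absent from PDB inputs. Default cutoffs
(declared substitutes for surface-based contact analysis, not
reconstructions of it): hydrogen bond, donor–acceptor ≤ 3.5 Å; halogen
bond, ligand halogen to protein N/O/S ≤ 3.6 Å; aromatic, both atoms
aromatic ≤ 5.0 Å; hydrophobic, apolar–apolar ≤ 4.5 Å; destabilizing
(hydrophilic–hydrophobic) ≤ 4.0 Å. Overlaps resolve by precedence
hbond > halogen bond > aromatic > hydrophobic > destabilizing, so each
qualifying pair yields exactly one contact. Halogens form their own
first-class category — folding them into the hydrophilic–hydrophobic class
obscures their weak-hydrogen-bond character, and halogenated substituents
are central to this inhibitor series.

Atom roles derive from element and connectivity: donor = N/O with ≥ 1 H;
acceptor = N/O not positively charged; hydrophobic = C/S bonded only to
C/S/H; hydrophilic = N/O; halogen exclusive. On PDB input, bonds are
inferred from covalent distances and rings of 5–6 atoms are treated as
aromatic — adequate for the planar rings encountered here, an approximation
for exotic saturated rings.

Per-residue profiles report the fraction of compounds forming ≥ 1 contact
with the residue and the class composition over all its contacts; halogen
shares are each residue's fraction of all halogen bonds.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical situation* of the screening
campaign, not docking physics:

- **Blocks** come from a bundled pool of 448 curated fragments containing
  tagged similarity families: chemotype families (bicyclic cores with short
  alkyl homologs, within-family Tc ≥ 0.7 to the leader, cross-family
  < 0.7 — margins verified when the pool was built) and redundancy series
  (saturated chain homologs, pairwise Tc ≥ 0.95, padded where needed with
  id-aliased duplicates emulating multi-vendor listings).
- **Docking records** follow a latent-quality model: each compound draws a
  bivariate normal (Gram-negative, Gram-positive) quality whose Pearson
  parameter is set to 2·sin(π·ρ/6) so that the *rank* correlation equals
  the requested ρ (Gaussian copula). The four scores are monotone maps of
  the group quality plus independent noise (default sd 0.25 against a
  unit-variance quality — small enough that consensus fusion recovers the
  planted correlation, large enough that individual scores disagree).
  Anchor pass events are independent Bernoulli(p) per isoform; passing
  RMSDs are uniform on [0, 2), failing ones on [2.05, 8). Planted
  chemotypes add their effect (latent-quality units) to one group for
  compounds carrying a member block at the stated position.
- **Profiles** are Dirichlet(c·background) draws with 0.995-point-mass
  conserved positions; as c → ∞ the entropy approaches the background
  value.
- **Complexes** realize a prescribed list of (residue, contact class)
  pairs exactly, by placing probe-atom groups 15 Å apart (beyond every
  cutoff) and rigidly translating the whole complex by a seeded offset.
  Geometric conflicts cannot arise because each prescription owns its own
  site; only unknown contact classes are rejected.

Default study conditions — 2,000 compounds × 7 isoforms, anchor pass
probability 0.755, inter-group rank correlation 0.8, planted effect 1.0 —
mirror the reference campaign's scale-reduced equivalents. Passing tests
on these synthetics demonstrates that the *post-processing machinery* is
correct and sensitive at realistic effect sizes; it says nothing about any
particular docking engine's accuracy on real complexes, and the toy
geometries say nothing about real binding-site shapes.

In the planted-chemotype detection check, a replicate counts as a success
when the planted cluster's ΔBEDROC exceeds the 0.05 flag while the
*median* unplanted |ΔBEDROC| stays below it: individual unplanted clusters
occasionally fluctuate past 0.05 (they hold ~100 actives each), so the
median is the statistically honest "typical background" summary.

## Problem sizes and determinism

Test and pipeline problem sizes are chosen so the full suite runs in a few
minutes on one core: parameter-recovery checks use n = 100,000 (anchor
pass probability, ±0.01), n = 5,000 (rank correlation, ±0.03) and
20 × 2,000 (chemotype detection, ≥ 90% over seeds); the end-to-end run
uses 2,000 compounds × 7 isoforms. All randomness flows through explicit
integer seeds (NumPy `default_rng`, Python `Random` for the reservoir);
there is no global random state, and repeated runs with the same
configuration produce byte-identical TSV outputs.

## Known limitations

- Fingerprint blindness to long-chain homologation (above) means Tc-based
  dedup can merge genuinely different saturated chains; for drug-like
  decorated fragments this is rarely limiting.
- The acceptor convention and the Crippen logP are coarse; neither feeds
  any ranked decision.
- Aromaticity-from-ring-membership on PDB input misclassifies saturated
  5/6-rings read from coordinates alone.
- The independence assumption behind p = f^(1/k) ignores correlation
  between dockings of the same compound to homologous pockets; the
  estimate is therefore conservative in the same way as the original.
- Leader clustering depends on input order (documented and deterministic),
  unlike centroid methods.
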