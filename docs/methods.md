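# Methods

## Problem

Estimating the accuracy of a protein–RNA complex structural model without
knowing the native structure (single-model quality assessment). The package
predicts, from one model in one pass, three global fold estimates
(backbone lDDT, GDT-TS, GDT-HA), three global interface estimates (iLDDT,
IPS, ICS) and two estimates (IPS, ICS) for each protein–RNA interface, and
also computes the corresponding ground-truth metrics when a reference is
available.

## Residue graph

Each residue (amino acid or ribonucleotide) is a node. An undirected edge
joins two residues when their anchor atoms (Cβ, Cα for glycine or when the
side chain is absent; C3′ for RNA) are within 14 Å, or when any heavy-atom
pair is within 6 Å. A residue is an interface residue when any heavy atom
lies within 6 Å of a chain of the opposite polymer type; a (protein chain,
RNA chain) pair with at least one such contact is an interface. Hydrogens
are excluded from every distance rule: structural models usually lack
them, and including them when present would make scores depend on
protonation conventions.

## Features

Node vectors have 66 channels, edge vectors 12, organized in named blocks
(`FeatureLayout`, versioned so alternative compositions can be swapped
in). The default node layout: residue identity one-hots (20 amino acid + 4
nucleotide + 1 unknown), polymer and interface indicators, distance and
orientation-angle to the complex and own-chain centers of mass, annotated
protein secondary structure (8-state) + RSA + φ/ψ (sin/cos), predicted
protein 3-state secondary structure + RSA + torsions (provider-supplied),
RNA pseudo-torsions η/θ (sin/cos), base-pairing flags (canonical,
non-canonical, any), secondary-structure element one-hot (stem, hairpin,
interior, multiloop, exterior) and two torsion-validity flags. The edge
layout: minimum heavy-atom distance, anchor–anchor distance, two
orientation-vector angles, three provider channels for predicted
intra-protein distance/angles, annotated RNA pair flag, two predicted RNA
pairing probabilities (one channel per pairing predictor), inter-chain and
protein–RNA indicators.

Distances are scaled by `min(d, D)/D` (D = 50 Å for center-of-mass
distances, 20 Å for inter-residue distances), angles by 180°, and torsions
enter as (sin, cos) pairs with undefined values encoded (0, 0) plus a
validity mask. The residue orientation vector is Cα→Cβ (Cα→C fallback) for
amino acids and C3′→C1′ for nucleotides; the "angle to center of mass" is
measured between this vector and the anchor→COM direction. The two angle
channels of an edge are ordered by node index so both directed arcs of an
undirected edge carry identical features.

### Internal annotators

All annotated channels are computed in-package from coordinates:

- **Torsions**: standard dihedrals; protein φ/ψ from C(i−1)–N–Cα–C and
  N–Cα–C–N(i+1); RNA pseudo-torsions η = C4′(i−1)–P(i)–C4′(i)–P(i+1) and
  θ = P(i)–C4′(i)–P(i+1)–C4′(i+1). Termini and residues with missing
  backbone atoms are flagged undefined.
- **Secondary structure**: hydrogen-bond based 8-state assignment. The
  amide H is placed on the bisector of the previous residue's C=O
  directions; the bond energy is the classic electrostatic model
  E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol with a bond
  below −0.5 kcal/mol. Helices (H/G/I) come from consecutive 4/3/5-turns,
  strands (E/B) from parallel/antiparallel bridge patterns, plus turns (T)
  and bends (S, Cα pseudo-angle > 70°). Chains under 4 residues are coil.
- **Solvent accessibility**: Shrake–Rupley with a 1.4 Å probe and a
  100-point Fibonacci sphere per heavy atom; RSA divides by the Tien et
  al. theoretical maxima for amino acids and, for nucleotides, by the
  central-residue SASA of an extended synthetic trinucleotide (computed
  once at 200 points and cached). The quadrature uses a fixed sphere
  orientation, so RSA is rotation-invariant only to within its
  discretization error (≲0.04 at 100 points; halving with point count).
- **RNA base pairs**: geometric detector. Canonical: complementary bases
  (A-U, G-C, G-U) with the Watson–Crick edge nitrogens (purine N1 /
  pyrimidine N3) within 3.5 Å and base-plane normals within 30°;
  non-canonical: any other base–base heavy-atom contact within 3.5 Å.
  Sequence neighbors are excluded (they stack, they do not pair).
- **RNA elements**: intra-chain pairs are reduced to their maximum
  non-crossing subset (interval dynamic program; pseudoknots are thus
  projected onto their best nested approximation), then unpaired residues
  are labeled by the loop that encloses them (0 inner branches → hairpin,
  1 → interior/bulge, ≥2 → multiloop), paired residues are stems,
  unenclosed residues exterior.

Predicted channels come from provider plug-ins (callables or TSV tables
keyed by chain/residue); without providers they are zero-filled, which the
network treats as "no prediction available".

## Network

Implemented in float64 numpy on a small in-package reverse-mode autodiff
engine (`rnpqa.autodiff`) — dense linear algebra, row gather / segment
scatter for message passing, masked and segment softmax. Gradients are
verified against finite differences in the test suite.

Three components, each followed by learned top-k pooling (ratio 0.8 per
component by default; keep ⌈ratio·N⌉ nodes by a learned projection score,
gate survivors by sigmoid(score), ties broken by node index):

1. **Global + local mixing**: multi-head self-attention over all node
   pairs, in parallel with a GINE-style aggregation
   (Σ_j ReLU(h_j + W_e e_ij) transformed with the center node), joined by
   a residual sum. This is the only stage that sees every node at once.
2. **Edge attention**: TransformerConv-style attention-weighted message
   passing along surviving edges, with edge features entering both keys
   and values.
3. The same edge-attention block run after deleting every arc that does
   not join a protein node to an RNA node — an explicit inductive bias
   toward the interface.

GraphNorm (per-graph feature standardization with learned scale/shift) and
ReLU follow every component. Three independent global-attention-pooling
heads read the final node embeddings concatenated with the raw interface
and polymer indicator channels: fold (3 outputs), interface (3 outputs)
and per-interface (2 outputs, attention masked to the interface's
surviving chain-pair nodes). All outputs pass through a sigmoid.

If pooling removes every node of some interface, the per-interface head
falls back to the same component's pre-pooling embeddings, and — should
whole chains vanish earlier — to the first component's embeddings over the
full node set. This keeps the per-interface output list always aligned
with the enumerated interfaces.

Default bare configuration (CPU desk scale): hidden 64, 4 attention
heads, pooling ratios 0.8, dropout 0.1, head hidden width 32 (~82k
parameters). All sizes are config keys. The training default
(`TrainConfig.model`) uses pooling ratios of 1.0 — on the ~20-node
synthetic graphs, dropping nodes discards interface residues the heads
need, and the non-dropping ratio validated best while keeping the
learned gating active; larger graphs warrant ratios below 1.

## Ground-truth metrics

- **bb-lDDT / iLDDT**: superposition-free; fraction of reference
  backbone-atom pair distances (within 15 Å, different residues — for
  iLDDT, different chains) preserved within {0.5, 1, 2, 4} Å, averaged
  over thresholds. Backbone = N, Cα, C, O (protein); P, C3′, C4′, O3′, O5′
  (RNA).
- **ICS**: F1 between inter-chain residue contact sets (heavy-atom
  minimum distance ≤ 5 Å), optionally restricted to one protein–RNA chain
  pair.
- **IPS**: Jaccard index between interface residue sets (6 Å
  opposite-polymer rule evaluated on each structure).
- **iRMSD**: interface residues taken from the *reference* (heavy atom
  within 10 Å of an opposite-polymer chain); shared backbone atoms
  superposed by Kabsch SVD and the RMSD reported.
- **GDT-TS/HA (approximate)**: a single global Kabsch superposition of all
  anchors, then the mean fraction within {1,2,4,8} / {0.5,1,2,4} Å. The
  full iterative multi-superposition GDT search is deliberately omitted;
  the approximation is a lower bound and is labeled approximate in every
  output.

The 5 Å contact and 10 Å interface cutoffs follow common docking-assessment
conventions and are config keys. Model/reference correspondence is by
(chain_id, seq_index) with identical chain labeling assumed; undefined
metrics (no reference contacts) are NaN and masked from the loss, never
imputed.

## Training

Multi-task L1 loss: per score type the mean absolute error over valid
entries (per-interface types average over interfaces first), averaged over
the score types with at least one valid entry. iRMSD is unbounded and is
evaluation-only. Optimization is Adam (lr 2·10⁻³ default) with per-example
updates, plateau lr decay (×0.5 after 5 stagnant epochs), checkpointing at
minimum validation loss and early stopping (patience 12); 40 epochs
default. These sizes — like the pooling ratio above — were selected by
validation loss on pilot runs of the synthetic ensembles and are ordinary
config keys.

On held-out decoys of training-fold complexes the trained toy models
order quality well (Spearman against true iLDDT around 0.6–0.7) but
resolve the very top of the quality range imperfectly: the native
typically ranks within the first handful of a 21-model ensemble rather
than always first, because separating it from the mildest decoys requires
resolving label differences of a few hundredths. Generalization to
entirely novel synthetic complexes is weaker still (each complex has its
own perturbation mode), which is the expected behaviour of a regression
QA model trained on 20 complexes.

Stratified 5-fold construction deals complexes to folds stratum by stratum
(RNA clans first, then protein-sequence clusters of clanless complexes),
shuffling each stratum and assigning to the currently smallest fold. This
*spreads* cluster members across folds — representative validation rather
than group-disjoint cross-validation — so validation scores are optimistic
for truly novel complexes; the dealing strategy is implemented as stated
and the leakage implication documented here.

## Synthetic data

`make_toy_complex` builds an ideal α-helical protein (φ = −57°, ψ = −47°,
standard backbone geometry, Cβ except glycine) docked against an
A-form-like single-stranded RNA (planar idealized bases, fixed sugar
template, 32.7° twist / 2.81 Å rise) so that at least three residue pairs
make close (≤ 3.8 Å) atomic contacts without steric clash. `decoy_set`
draws one dominant perturbation mode per complex — a screw axis, a
translation direction and a torsion-noise pattern — and scales it by a
control magnitude m ∈ (0, 1] (defaults at m = 1: 15° rotation, 5 Å
translation, 8° torsion jitter with downstream-atom propagation);
individual decoys scatter their directions within a 30° cone of the mode.
Quality therefore degrades monotonically with m in expectation while
same-magnitude decoys still differ, emulating how docking-funnel decoys
order by distance from the native pose. Internal jitter is applied by
exact rotations about backbone bonds, so covalent geometry is preserved to
machine precision.

What the generator does *not* emulate: side chains beyond Cβ, realistic
RNA sugar puckers and loop structure, base-specific hydrogen-bond
geometry, packing energetics, sequence-structure correlation, and decoys
from genuinely different docking basins. Passing tests on these fixtures
demonstrate that the pipeline's plumbing, metrics and learning dynamics
behave correctly — not that the network reaches practical accuracy on
experimental complexes, which requires training on real docking decoys.

## Numerical choices

- Float64 throughout the network; permutation invariance of outputs holds
  to ~1e-12 in practice, asserted at 1e-5.
- Top-k and argmax ties break by node/model index (stable, deterministic).
- Zero-variance Z-scores are defined as all-zero.
- Spearman uses average ranks for ties (scipy).
- Altloc resolution keeps the highest occupancy, ties by file order.
- Missing Cβ on non-glycine falls back to Cα (models frequently lack side
  chains); DNA and hybrid chains are rejected; common modified residues
  map to parents via a configurable alias table (MSE→MET, PSU→U, …).
- Every random path (generator, fold dealing, training shuffles, dropout)
  flows from explicit integer seeds; repeated runs are bit-identical.

## Known limitations

- Untrained (random-init) scoring is only a smoke surface; ranking power
  requires training.
- The GDT approximation under-reports quality for models whose best
  superposition differs from the global least-squares one.
- Chain mapping between model and reference must agree by chain id; no
  automatic chain-mapping search.
- The secondary-structure annotator is a faithful but simplified
  hydrogen-bond assignment; edge cases (bifurcated bonds, π-helix
  boundaries) may differ from reference implementations.
- Per-interface evaluation weighting follows the equal-target-representation
  reading (each target's entries share unit weight); the direct
  interface-count weighting is available behind a flag.
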