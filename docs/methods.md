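# Methods

## Scope and data model

The package analyses hydration networks in two input regimes that share one
in-memory model (`Structure`: an ordered list of atoms with water flags):

* **static structures** — PDB files with crystallographic waters, read with
  Bio.PDB; the first MODEL is used, and alternate locations are collapsed to
  the highest-occupancy conformer (ties keep the first encountered). Waters
  are recognised by residue name against a configurable set
  (HOH/WAT/TIP3/SPC/T3P/SOL by default);
* **trajectory frames** — any topology/trajectory pair MDAnalysis can read,
  snapshotted per frame with copied coordinates. Frames are assumed to be
  already unwrapped and aligned; the package does no PBC processing.

## Common indexing and superposition

Cross-structure comparisons require residues with comparable indices and
coordinates in one frame.

* **Sequence alignment.** Structure-derived sequences (nonstandard residues
  → X) are aligned with a center-star progressive scheme: all pairwise global
  Needleman–Wunsch alignments (BLOSUM62, gap open 10, extend 0.5 — common
  defaults), center = sequence with the highest summed pairwise identity,
  remaining sequences merged against the center column-wise. For the
  closely-related families this tool targets, center-star and tree-guided
  progressive alignment coincide in practice, and downstream analyses consume
  only the residue→column mapping; an externally computed MSA (PIR or aligned
  FASTA) can be imported instead and is reconciled residue-by-residue against
  each structure, naming the first discrepancy on mismatch. Gap runs longer
  than `max_gap` (default 20) raise a warning rather than being forbidden
  outright — affine penalties already discourage them, and a hard cap is not
  expressible in the pairwise scorer.
* **Superposition.** Kabsch least-squares fitting on Cα atoms of residues
  sharing an alignment column (≥ 3 pairs required); the fitted proper
  rotation is applied to all atoms including waters. Cα-only fitting keeps
  the fit insensitive to side-chain rearrangement. The reference structure is
  the lexicographically first unless configured.

## Hydrogen-bond networks

Candidate pairs come from a k-d tree query of each water oxygen against the
combined pool of water oxygens and protein donor/acceptor heavy atoms
(N and O of any residue, S of Cys/Met; carbon never participates). The
`neighbor_k` = 10 nearest candidates per water are distance-tested, making
construction linear in water count and exact whenever no water exceeds k
in-cutoff partners (the regime the default was chosen for). Edges require
donor–acceptor distance ≤ 3.8 Å; with hydrogens present, additionally a
D–H···A angle ≥ 150° from at least one hydrogen of either partner — the
passing donor orients the edge, and when both directions pass the
lower-serial atom donates (a pure tie-break). Networks are water-centric:
protein–protein pairs are never tested. Modes restrict edges to
water–water, water–protein, or both; an active region (closed ball around a
selection's center of mass or an atom) keeps all in-region water oxygens as
nodes and retains out-of-region partners of in-region waters so boundary
bonds are not lost. Per-structure tasks are independent, so joblib
parallelism cannot change results, only wall time.

## Graph metrics

Density uses 2E/N(N−1) (undirected) or E/N(N−1) (directed); all other
metrics are computed on the undirected projection. Degree entropy is the
Shannon entropy of the empirical degree histogram in nats (the log base only
rescales; regular graphs score 0). The characteristic path length is
computed per connected component (mean hop count over distinct vertex pairs);
the component average is unweighted over components with ≥ 2 nodes, and the
largest component is chosen by node count, then edge count, then smallest
node key — a deterministic tie-break. Graphs with no 2-node component yield
an absent value rather than 0, so empty networks are never mistaken for
tight ones.

## Conserved-water analysis

Pooled water-oxygen positions (no deduplication; one row per observation
with structure/frame/serial provenance) are clustered with DBSCAN
(eps 1.0 Å, min_samples 5 by default), HDBSCAN, or OPTICS as implemented in
scikit-learn; noise points are excluded and centroids are arithmetic means of
members. Defaults were chosen so that hydration sites resolved to typical
crystallographic precision (≲ 0.5 Å spread) form one cluster each while
transient positions fall out as noise; they are fully configurable.

* **Per-cluster conservation**: fraction of structures/frames with ≥ 1 water
  within the match tolerance (1 Å) of the centroid.
* **Pairwise conservation**: for centroid pairs closer than 2 Å, the fraction
  of units occupying both sites simultaneously.
* **Per-structure score**: S = (1/N_s) Σ_i a_i/(1 + w_i), where a_i flags a
  water within 1 Å of summary site i and w_i counts the structure's other
  waters within the 6 Å local sphere of that site, the nearest matched water
  excluded. The +1 keeps the matched water in the denominator, so an exact,
  uncrowded match of every site gives exactly 1 and crowded solvation cannot
  inflate the score. Matching is independent per summary site (not a
  bipartite assignment): when two sites could claim the same water, both
  count — the simplest reading of the definition, adequate when sites are
  farther apart than the match tolerance, which clustering guarantees unless
  eps is set below 2×match_distance.
* **Interaction scores**: per residue (keyed by alignment column where a map
  exists, else by chain/resnum/icode), total water–protein interaction count
  divided by the number of units, split into backbone (N, O, OXT) and
  side-chain contributions, plus the mean number of distinct simultaneously
  bound waters over units with at least one.
* **Two-angle descriptor**: each water–protein contact is reduced to the two
  angles at the water oxygen toward fixed reference points — (0, 10, 0) and
  (10, 0, 10) Å by default, or any chosen coordinates such as conserved Cα
  positions. With all structures superposed, the pair of angles separates
  distinct hydration positions in two dimensions, independent of residue
  identity. Fixed-point references are *not* invariant under rigid motion of
  the family; Cα-derived references are, and the invariance test uses them.
* **Density grids**: water-oxygen occupancy counts on an axis-aligned grid
  (0.5 Å default spacing) covering a spherical region, normalisable by frame
  count, exported in OpenDX format.

## Synthetic data generator

The generator emulates the study inputs at desk scale: a serine-like
pseudo-helix (rise 1.5 Å, radius 2.3 Å, 100°/residue — non-collinear Cα so
superposition is fully determined) carrying backbone N/CA/C/O and a
side-chain OG per residue; planted water sites with per-unit presence
probabilities or explicit per-frame schedules, isotropic Gaussian jitter, and
optional hydrogens placed at 0.96 Å with an exactly planted D–H···A angle
toward a chosen acceptor (solved by 1-D root finding). Rigid per-structure
perturbations exercise the alignment stage. All randomness derives from one
seed via `default_rng([seed, unit])`, making sub-generators order-independent.
What it does **not** emulate: real side-chain chemistry and rotamers,
correlated water dynamics, resolution-dependent water placement, altloc/
occupancy noise, or crystal contacts — so passing tests demonstrate the
correctness of the graph/score machinery on controlled geometry, not
biological conclusions about any real protein family.

## Numerical choices and degenerate inputs

Distances use closed cutoffs (≤), making threshold semantics exact for
planted geometry. Angle arccosines are clamped to [−1, 1]. Empty structures,
empty selections, all-noise clusterings, and empty summary networks are
signalled (error or warning + empty result) rather than silently zeroed;
conservation against an empty summary is undefined and raises. CSV output
columns have fixed order and rounded values so repeated runs are
byte-identical.

## Problem sizes

Tests and the acceptance script run on synthetic inputs of 5–20 structures
or 10 frames with ≤ 200 atoms each, and 100-fixture randomized sweeps for
oracle equivalence — sizes at which exhaustive O(n²) reference
implementations are tractable for comparison. The library itself has no such
limits; the k-d tree search and per-structure parallelism are the scaling
path for real inputs.

## Known limitations

* Protein hydrogens are used when present but protonation states are never
  assigned; structures without hydrogens fall back to distance-only criteria.
* The center-star MSA is not a full guide-tree progressive alignment and may
  be suboptimal for deeply diverged families; import an external MSA there.
* Interaction counting treats each H-bond as one interaction; a single water
  bridging backbone and side chain of the same residue counts twice (the
  backbone/side-chain split preserves the distinction).
* Summary-network edges use the plain H-bond distance cutoff between
  centroids; no angle criterion is possible for centroids.
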