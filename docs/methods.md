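# Methods

This note documents the models and procedures the package implements, the
choices that were genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## The spreading model

All prediction methods in this package are variants of two-round resource
diffusion on a layered graph.

**De novo spreading core** (`simspread.network`). The graph has a feature
layer F, a drug layer D and a target layer T, encoded as two biadjacency
blocks: FD (non-negative weights) and DT (binary annotations). A query
starts with a non-negative resource vector on F. In round one, every
feature node divides its resource by its degree towards D and hands one
share down each edge. In round two, every drug node divides what it
received by its *joint* degree over F and T — the drug sends resources both
back to the feature layer and forward to the targets — and distributes it
the same way. The final resources on T are the scores. Two propagation
modes are exposed:

* **binary** — shares are equal over the edge count (each neighbour gets
  `r/deg`), regardless of edge weight;
* **weighted** — shares are proportional to edge weight and normalised by
  the node's summed edge weight (target edges count weight 1).

Both modes conserve the total resource exactly: each node passes on
everything it holds, so after each round the system total equals the
initial query mass whenever no resource sits on a degree-zero node. The
test suite pins this to 1e-12 (in practice the residual is at machine
epsilon), and pins the vectorised matrix-product implementation to an
independent per-node traversal implementation (`simspread.reference`) on
hundreds of random instances.

**SimSpread** instantiates F as a copy of the training drugs, with FD the
thresholded drug–drug similarity matrix S′ and the query's S′ row (query
vs. training drugs) as initial resources. The drug–drug block keeps its
diagonal: self-similarity is 1, so every drug stays connected to its own
targets even when it resembles no other training drug; without the
diagonal, conservation and behaviour on sparse-similarity data would
degrade. Weighted propagation is the default for the similarity-weighted
variant, binary propagation for the binary variant; the choice is recorded
in every run manifest because the degree normalisation of the
similarity-weighted variant (weighted vs. unweighted degree) is a genuine
modelling choice — weighted normalisation is used here because it preserves
conservation for arbitrary non-negative weights and reduces to the binary
rule on 0/1 matrices.

**SDTNBI** is the same core with F = fingerprint bit positions, FD = the
transposed training fingerprint matrix, and binary propagation; the package
implements it literally as a call into the shared spreading core (a test
asserts bit-for-bit equality).

**NBI** is the transductive bipartite ancestor: one unit of resource per
annotated target of the query drug, targets split equally over their
ligands, ligands split equally over their targets. The total final resource
equals the query's annotated-target count, which the tests pin as the
convention check. NBI cannot score drugs outside the network, which is why
the interaction-holdout protocol exists (below).

**k-NN** scores each target by the maximum similarity between the query and
the target's annotated ligands (k = 1, the benchmark setting). For k > 1
the top-k similarities are averaged; the mean reduces to the max at k = 1.

## Feature matrix and descriptors

S′ applies an inclusive threshold (Sᵢⱼ ≥ α) and one of two weightings:
binary (surviving entries become 1) or similarity (surviving entries keep
Sᵢⱼ). Defaults follow the optimised operating point: ECFP4 fingerprints
folded to 4096 bits, α = 0.2, similarity weighting. The fold length is
applied uniformly; α should be re-optimised per descriptor (a sweep utility
over 0…1 in steps of 0.05 is provided) because the similarity distribution,
not the method, dictates the useful range.

Descriptors: ECFP4/FCFP4 (Morgan radius 2, the FCFP variant with
pharmacophoric atom invariants), MACCS keys, and `fp2`, a Daylight-style
path fingerprint (paths up to length 7, 4096 bits) provided as the RDKit
analog of OpenBabel's FP2. The Klekota–Roth fingerprint has no installed
backend and is rejected with a clear error; any precomputed binary matrix
can be imported from TSV instead, which also covers externally computed
descriptors. Continuous descriptor matrices are supported through the
continuous Tanimoto form Σab/(Σa²+Σb²−Σab) after column-wise min–max
normalisation to [0,1]; constant columns normalise to 0 rather than NaN so
similarities stay finite. The 0/0 similarity case (two empty vectors) is
defined as 0: an empty fingerprint should not link compounds. The Tversky
index (default asymmetric setting α=0.0/β=1.0) is available as an
alternative for binary fingerprints.

## Validation protocols and metrics

Splitting is drug-wise: a held-out drug loses *all* its edges before the
network is rebuilt. Targets disconnected by a split can never be predicted
and are masked from that unit's metrics. Leave-one-out and repeated k-fold
(default 10×10) report per-drug and per-fold values respectively; the
per-fold value is the mean over the fold's evaluable drugs (pooling the
fold's rankings instead would weight drugs by panel size; averaging was
chosen and is recorded here because either convention is defensible). The
interaction-holdout variant partitions edges instead of drugs for
transductive methods; a drug's retained training edges are masked during
evaluation since they are known annotations, not prediction tasks. The
time-split harness consumes a train/test pair produced by
`datasets.time_split`, which restricts both snapshots to shared targets and
removes already-known edges from the test set. One integer seed drives all
shuffles (per-repeat seeds are `seed + repeat`), and reports are bitwise
reproducible.

Out-of-domain queries (no similarity above α) are evaluated with their
all-zero scores — the worst-case ranking — *and* flagged in the report, so
summaries can include or exclude them.

Eight metrics per unit: AuROC (average-rank Mann–Whitney form, ties count
one half), AuPRC as average precision (step-wise interpolation — trapezoids
over PR points would over-credit the gaps), BEDROC with decay 20, P@20 and
R@20, and the maxima of MCC, F1 and balanced accuracy over every observed
score threshold (inclusive cut). Undefined values (no positive, or no
negative, among evaluable targets) are NaN and counted, never dropped
silently.

Two top-k conventions deserve emphasis because they are silent
discrepancy sources:

* **P@k keeps denominator k** even when the target panel is smaller, so a
  one-positive query caps at P@20 = 0.05.
* **A zero score is "no prediction".** Resource scores are zero exactly
  when the diffusion cannot reach a target; such targets are never counted
  as retrieved in top-k cuts even if they would fall inside the first k
  slots of a full ordering. Without this rule, top-20 recall on a panel of
  ≤ 20 targets would be identically 1 for any ranking, including random
  ones, and the metric would measure nothing.

Ranking ties are broken deterministically by (score descending, target ID
ascending) everywhere.

## Filtering and dataset statistics

The bioactivity filter keeps records with Ki/Kd/IC50/EC50 strictly below
10 µM, heavy atoms strictly between 5 and 80, clinical phase ≥ 1 and a
matching organism (human by default); unknown activity types are skipped
with a warning, and surviving duplicates collapse to one unweighted edge.
The strict inequalities are deliberate and tested — "<" vs. "≤" at a
printed cutoff silently changes datasets. Dataset statistics (density as a
percentage of all possible pairs, mean ± SD degrees) are computed over the
declared ID lists, including zero-degree nodes.

## Exploration analysis

For scaffold/target hopping analysis, predictions are pooled globally over
all (query, target) pairs and sorted by score with deterministic
(score, query, target) tie-breaking — the top-L cut is global, not
per-query. Ligands are reduced to canonical Bemis–Murcko frameworks
(acyclic molecules yield an empty scaffold and a warning); a scaffold is
"known" if it occurs among training-set scaffolds, else "novel". Targets
are described by binary GO-term presence vectors over the union vocabulary
of the supplied annotation table. The 2D UMAP embedding is a plotting
utility only; no metric or test depends on its geometry beyond sanity
checks.

## Synthetic benchmarks: what they show

The generators in `simspread.fixtures` plant the structure the method is
supposed to exploit. `generate_clustered_library` reserves a disjoint block
of fingerprint bits per cluster and draws a prototype (density 0.6 within
its block); members flip every bit independently with probability 0.05.
Between-cluster similarity therefore comes from flip noise alone (~0.05 on
average) while within-cluster similarity is ~0.6 — a clean separation on
either side of the default α = 0.2. The block design is deliberate: with
uniform random prototypes the upper tail of the between-cluster similarity
distribution crosses any fixed cutoff often enough to create spurious
cross-cluster edges, making the planted structure leaky in a way real
chemical series are not. `generate_planted_dti` gives each cluster a
disjoint target block and annotates members to block targets with a fixed
probability (0.8 by default, each compound guaranteed ≥ 1 edge) — the
similarity-property principle made literal.

On this data, leave-one-out SimSpread recovers held-out compounds' targets
nearly perfectly, while the y-scrambling control (the same rankings
evaluated against a target-permuted edge set) collapses to the chance level
set by the block size (~0.25 top-20 recall with 4 clusters). Passing these
tests shows the implementation finds planted similarity-bioactivity
structure; it does *not* show real-world performance. Real datasets have
overlapping chemical series, promiscuous targets, heavy-tailed degree
distributions and annotation noise, none of which the generator emulates.
The published benchmark protocols can be rerun on real data with
`scripts/external_benchmarks.py`.

Problem sizes in the shipped tests and the acceptance script are chosen at
desk scale: spreading-oracle and metric-oracle agreement on 100 random
instances of ≤ 10 nodes per layer, conservation on 50 networks, planted
recovery on the 60-compound / 20-target library, and dataset statistics on
count-matched random bipartite graphs up to the largest published panel
(1844 × 1032, 10185 edges). These finish in seconds on one CPU.

## Known limitations

* Two spreading rounds only; deeper diffusion (heat-spreading hybrids,
  edge-weighted NBI variants) is out of scope.
* The drug–target layer is binary; bioactivity values are carried through
  I/O but do not weight edges.
* Protein-side similarity is not modelled; targets interact only through
  shared ligands.
* Scores are relative ranks, not calibrated probabilities; comparing raw
  scores across methods or across queries with different feature-vector
  norms is not meaningful.
* A query outside the application domain (no similarity ≥ α to any
  training drug) receives no prediction by construction; this is reported,
  not worked around.
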