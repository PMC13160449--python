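# Methods

`hypermatch` integrates two unpaired single-cell modalities — a query
matrix **X** (n<sub>x</sub> × p<sub>x</sub>) and a reference matrix **Y**
(n<sub>y</sub> × p<sub>y</sub>), n<sub>x</sub> ≤ n<sub>y</sub> — into
explicit cell–cell matchings and a shared embedding, using only a set of
*linked features* as cross-modal anchors. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Feature linkage

Linked features are obtained by (i) exact name intersection, (ii) a
user-supplied gene↔protein map, or (iii) collapsing chromatin-accessibility
regions into gene-activity columns: a region is assigned to a gene when it
overlaps the gene body or the strand-aware 2000-bp window upstream of the
transcription start (+ strand: `[start−2000, start)`; − strand:
`[end, end+2000)`; coordinates are 0-based half-open internally, GTF starts
shifted by −1 on read). Multiple regions per gene are **summed** by default
(a `mean` mode is available); summing preserves total accessibility signal
and yields the one-to-one linked-column structure the matching stage needs.
Name matching is case-sensitive by default with an opt-in
case-insensitive flag, and we deliberately require an explicit
gene↔protein map rather than bundling an alias database.

The linkage ratio ρ = min(p<sub>link</sub>/p<sub>x</sub>,
p<sub>link</sub>/p<sub>y</sub>) classifies a dataset pair as *weakly
linked* when ρ < 0.10.

## Adaptive kNN graphs

Each modality's cells are reduced by PCA (default 100 components, capped
at min(n, p) − 1; deterministic sign convention: each component's
largest-|loading| entry is positive) and connected to their top-k
candidates under a bounded weight, by default `cosine01`
w = (1 + cos)/2 ∈ [0, 1] (alternative: `inv_dist` 1/(1+d)). Per cell i
with candidate weights w<sub>i1</sub> ≥ … ≥ w<sub>ik</sub>, neighbors with

  w<sub>ij</sub> > t<sub>i</sub> = 1 − (mean<sub>l≤k</sub> w<sub>il</sub> − 1 − δ)²

are retained. The rule is self-normalizing: tight, dense neighborhoods
(mean weight near 1) get low thresholds and keep many neighbors, loose
ones keep few. When no candidate clears the strict inequality (e.g. all
weights equal), the single best candidate is kept so every cell has degree
≥ 1. Note the threshold is *not* monotone in δ globally — it peaks at
δ = mean − 1 — so the intuition "raising δ prunes harder" holds only while
δ ≤ mean − 1, which covers the practical regime (mean weights near 1,
δ ∈ [−2, 0]).

Defaults: k = 30 and δ = −0.5; integration quality is flat for
k ∈ [15, 25] on the synthetic fixtures. Directed retained edges are
symmetrized by elementwise max (strongest evidence of proximity wins) and
normalized as Ā = D<sup>−1/2</sup>(A + I)D<sup>−1/2</sup> with
D<sub>ii</sub> = Σ<sub>j</sub>(A + I)<sub>ij</sub> — the standard
symmetric GCN operator. A `literal_exponent` flag switches the right
factor to D<sup>+1/2</sup> for users who want the asymmetric variant.

## Hypergraph contrastive encoder

The encoder H(E, Ā) refines an n × d embedding with two parallel branches
per layer l = 1…L, both fed by E<sup>(l−1)</sup> (E<sup>(0)</sup> = E):

* local: Ē<sup>(l)</sup> = Ā E<sup>(l−1)</sup> (parameter-free GCN step);
* global: Ẽ<sup>(l)</sup> = H(H<sup>T</sup>E<sup>(l−1)</sup>) with
  H = E<sup>(0)</sup>W, where W (d × K) is the only learnable parameter —
  a soft incidence map from cells to K virtual hyperedges. The product is
  always evaluated right-to-left through the K-dimensional bottleneck, so
  no n × n matrix is materialized.

The branches are aligned by an InfoNCE loss with cosine similarity and
temperature τ: anchors are local rows, candidates global rows of the same
layer, the positive is the same cell, and negatives are all other cells
(exact loss by default; for n > 20 000 a seeded per-anchor negative
subsample keeps the epoch cost linear). Cosine similarity of a zero-norm
row is defined as 0. The training objective is ℒ = ℒ<sub>c</sub> + λ‖W‖²;
‖Θ‖² reduces to ‖W‖² because W is the only parameter. Layer outputs fuse
without extra weights — E<sup>(l)</sup> = Ē<sup>(l)</sup> + Ẽ<sup>(l)</sup>,
Ê = Σ<sub>l</sub>E<sup>(l)</sup> — keeping the head parameter-free.

Training is implemented directly in numpy: the forward pass and its
reverse-mode gradient are written out by hand over this fixed computation
graph (verified against finite differences to ~5 × 10<sup>−9</sup>) and
optimized with Adam (β₁ = 0.9, β₂ = 0.999, ε = 10<sup>−8</sup>). W is
initialized from a seeded normal scaled by 1/√(nd), which keeps the
hyperedge operator HH<sup>T</sup> near unit spectral scale at the start;
every run is bitwise-reproducible given its seed. Negatives including the
anchor's own local/global cross terms are not added; the loss is exactly
the local-anchor/global-candidate form. W is re-initialized at every
encoder call — each invocation inside the outer loop is self-contained.

Defaults: L = 2, K = 128, τ = 0.5, λ = 10<sup>−2</sup>, learning rate
10<sup>−3</sup>, 200 epochs standalone. Inside the pipeline, which makes
2 + 2T encoder calls per run, the per-call budget defaults to 50 epochs;
on the reference fixtures the loss has essentially plateaued by then and
final matchings are unchanged, so the larger standalone default buys
nothing within the loop.

## Matching

Embedding rows are compared by Pearson correlation; the matching degree is
d<sub>ij</sub> = (1 − PCC)/2, mapping [−1, 1] onto [0, 1] (a `literal`
flag gives clip(1 − PCC, 0, 1) instead; the affine map is the default
because it is injective on the whole correlation range). Constant rows get
PCC ≡ 0, hence d = 0.5.

The assignment min ⟨Π, D⟩ s.t. Π1 = 1, Π<sup>T</sup>1 ≤ 1 is solved
exactly with the rectangular Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`); a monotone column perturbation
of order 10<sup>−9</sup> breaks ties toward the lowest column index so
outputs are solver-independent. The *p-best* initial matching solves the
assignment p times, forbidding previously selected (i, j) cells between
rounds; this guarantees exactly p distinct partners per query cell
(p·n<sub>x</sub> triples) with non-decreasing round costs. We chose
sequential solve-and-forbid over Murty-style k-best enumeration because
the target object is a many-to-many matching with disjoint partner sets,
which enumeration of next-best *full* assignments does not provide. The
degree filter keeps triples with d ≤ α (default 0.6) but always retains a
query cell's best triple, so coverage never drops below 1 per cell;
degrees are frozen from the distance matrix at matching time, not
recomputed after filtering. The final 1-to-N matching stacks N copies of
D vertically and solves once; the column constraint forces N distinct
partners per query cell. Defaults: p = 3, α = 0.6, N = 1.

## CCA joint embedding

C(X, Y, M): each modality is PCA-reduced (r<sub>x</sub> = r<sub>y</sub> =
40 by default, capped at min(n − 1, p)); the *matched triples* of M are
the paired samples (a query cell with several partners contributes several
samples — the alternative reading that enumerates all n<sub>x</sub>·n<sub>y</sub>
pairs is statistically incoherent and is not used). Canonical loadings
come from the SVD of the whitened cross-covariance, with a 10<sup>−4</sup>
ridge on the within-set covariances so the fit remains well-posed when
|M| approaches r, and an optional (1 − d) per-sample weighting (off by
default). Correlations are clipped to [0, 1] and sorted non-increasing; a
joint sign convention (largest-|entry| of each X-loading positive, Y
flipped with it) removes the sign ambiguity. All cells — matched or not —
are projected: X<sub>r</sub> = X<sub>rx</sub>C<sub>x</sub>,
Y<sub>r</sub> = Y<sub>ry</sub>C<sub>y</sub>. Default joint dimensions
r = r* = 20.

## Pipeline

After the initial linked-feature matching M<sup>(0)</sup>, the loop for
t = 1…T (default T = 3; T = 0 returns the initial matching and its CCA
embedding untouched) alternates CCA conditioned on the current matching,
hypergraph re-encoding of both joint embeddings on the *fixed* stage-1
graphs, and re-matching (skipped at t = T). The final 1-to-N assignment is
solved on the last distance matrix and a final CCA at dimension r* gives
X*, Y*. One master seed is fanned out per stage via `SeedSequence`, and
per-iteration diagnostics (matching sizes, mean degree, encoder losses)
are returned. Downstream: `predict_features` projects reference profiles
onto query cells as the unweighted mean over the N matched partners
(1 − d weighting optional), and `smooth_by_neighbors` averages expression
over each cell's k nearest joint-embedding neighbors.

## Evaluation

ACC is the label-agreement fraction over all matched triples (1-to-N
matchings average over all N·n<sub>x</sub> triples). FOSCTTM counts
other-modality cells *strictly* closer than the true match, normalized by
n<sub>other</sub> − 1 (worst case exactly 1) and averaged over both
directions; it requires ground-truth pairing. NMI/ARI follow the scIB
protocol: Leiden clustering on a 15-NN graph over resolutions 0.1–2.0
(step 0.1), reporting the resolution that maximizes NMI.
ASW<sub>label</sub> = (silhouette + 1)/2; ASW<sub>batch</sub> averages
1 − |batch silhouette| within each cell-type group containing both
modalities. Graph connectivity is the mean largest-connected-component
fraction of each type's 15-NN subgraph (singleton classes count as
connected). The nested scores are

  S_bio = [ACC + (1 − FOSCTTM)·𝟙_paired + NMI + max(0, ARI) + ASW_label] / (4 + 𝟙_paired)
  S_batch = (GC + ASW_batch)/2,  S_overall = 0.6·S_bio + 0.4·S_batch,

all bounded in [0, 1]; the normalizer 4 + 𝟙_paired keeps S_bio bounded
whether or not a true pairing exists.

## Synthetic data

The generator draws type means as random directions at a fixed radius
(2√latent_dim, within-type sd 1), so every type has the same
separation-to-spread ratio; cells observe their latent state through
modality-specific Gaussian loadings plus noise, and linked columns share
loading vectors blended by `linkage_strength` (cross-modal correlation of
a linked column ≈ the strength). The first n<sub>x</sub> reference cells
reuse the query latent states, giving a known true pairing. An optional
`tightness_gamma` makes rare types looser (sd = (prop_max/prop)^γ),
emulating the empirical pattern that abundant populations are denser in
embedding space; without some abundance–density coupling the adaptive-k
rule saturates at k for every sufficiently dense class and the
size-versus-k relationship is undefined.

Reference fixtures: `easy_strong` (3 types, 600 + 600 cells, ρ = 0.30,
strength 0.9, noise 0.3), `hard_weak` (5 imbalanced types, 800 + 1000
cells, p<sub>x</sub> = 2000 vs p<sub>y</sub> = 120, ρ = 0.02, strength
0.4, noise 0.8), `imbalanced_aknn` (6 types spanning proportions 30.3% to
2.34%, 1200 cells, γ = 0.5, noise 0.3).

**What passing these benchmarks shows — and does not.** The fixtures are
Gaussian linear-loading models of *preprocessed* data: they exercise the
adaptive graph, the encoder, exact matching, CCA conditioning and the
score framework under weak/strong linkage, imbalance and unequal cell
counts. They do not model count sparsity or overdispersion, batch effects
beyond the modality gap, nonlinear feature responses, or annotation noise,
so results here demonstrate correctness of the machinery, not expected
accuracy on real assays.

## Problem sizes and determinism

Acceptance-scale runs use the fixture sizes above with T = 3 and the
50-epoch in-pipeline encoder budget; unit tests use miniature datasets
(~80–300 cells) with few-epoch encoders. Every stochastic component —
generator, encoder initialization, negative subsampling, Leiden — is
seeded, and identical seeds reproduce results bitwise on a given platform.

## Known limitations

No inductive mapping onto a pre-trained reference; exactly two
modalities; no approximate-nearest-neighbor backend for >10⁶ cells; the
exact InfoNCE loss is O(n²) per epoch (mitigated but not removed by
negative subsampling); matching requires full query coverage — there is
no partial-assignment mode for query cells genuinely absent from the
reference.
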