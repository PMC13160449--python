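# hypermatch

Diagonal (unpaired) integration of two single-cell modalities with weakly
correlated shared features.

Emerging single-cell assays — antibody panels, spatial proteomics,
chromatin accessibility — measure different cells with different features
than scRNA-seq. Integrating such *unpaired* datasets must rely on a
handful of *linked features* (a protein and its encoding gene, a peak and
its target gene), and when those anchors are few or weakly correlated
(linkage ratio ρ = min(p_link/p_x, p_link/p_y) < 10%), naive correlation
matching breaks down. `hypermatch` is for computational biologists who
need explicit cell–cell correspondences and a joint embedding in exactly
that regime: cross-modal label transfer, regression-free feature
prediction, and joint-space downstream analysis.

## Method

For query **X** (n_x × p_x) and reference **Y** (n_y × p_y), n_x ≤ n_y:

1. **Adaptive kNN graphs.** Per modality, PCA scores are connected to
   their top-k candidates with bounded weights w ∈ [0, 1]; cell *i* keeps
   neighbors with w_ij > 1 − (mean_l w_il − 1 − δ)², so dense populations
   keep large neighborhoods and rare ones small. The max-symmetrized
   adjacency is normalized as Ā = D^(−1/2)(A + I)D^(−1/2).
2. **Hypergraph contrastive encoder** H(E, Ā): per layer, a local GCN
   branch Ē = ĀE and a global branch Ẽ = H(Hᵀ E) with H = E⁽⁰⁾W, a learned
   soft incidence onto K virtual hyperedges; the branches are aligned by
   an InfoNCE loss with temperature τ (plus λ‖W‖²) and fused by
   unweighted summation Ê = Σ_l (Ē⁽ˡ⁾ + Ẽ⁽ˡ⁾).
3. **p-best assignment matching.** With D_ij = (1 − PCC(x̂_i, ŷ_j))/2,
   p successive exact linear assignments (previously chosen cells
   forbidden) give p·n_x matching triples, filtered by a degree threshold
   α while always keeping each query cell's best pair.
4. **Iterative CCA refinement.** For t = 1…T: CCA on the matched samples
   produces joint embeddings, the encoder refines them on the fixed
   graphs, and the matching is re-solved. The final 1-to-N matching
   stacks N copies of the last distance matrix, and a final CCA yields
   X*, Y*.

Quality is summarized by seven scIB-style metrics nested into
S_bio, S_batch and S_overall = 0.6·S_bio + 0.4·S_batch. See
[docs/methods.md](docs/methods.md) for assumptions, defaults and
limitations.

## Worked example

`examples/03_full_pipeline.py` generates the strong-linkage synthetic
fixture (600 + 600 cells, 3 cell types, 60 of 200 features linked,
known true pairing) and runs the full pipeline:

```
$ python examples/03_full_pipeline.py
linkage: p_link=60, rho=0.30 (strong)
mean matching degree per stage: [0.1797, 0.0952, 0.0916, 0.0734]
ACC       = 1.0000   (label agreement of matched pairs)
FOSCTTM   = 0.1729   (0 = perfect cross-modal alignment)
NMI/ARI   = 0.9718/0.9871
S_bio     = 0.8638
S_batch   = 0.9980
S_overall = 0.9175  (0.6*S_bio + 0.4*S_batch)
```

The mean matching degree (a correlation distance; smaller is better)
shrinks across the refinement iterations; every matched pair joins cells
of the same ground-truth type (ACC = 1); and the near-1 S_batch shows the
two modalities are thoroughly mixed in the joint embedding. The other
examples cover feature linking (`01`), the adaptive graph's response to
class imbalance (`02`), and cross-modality feature prediction plus kNN
smoothing (`04`). A thin CLI mirrors the library:
`hypermatch run|match|predict|evaluate|simulate --help`.

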