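# Methods

## Model

Two multilayer perceptrons encode the two modalities into a common space:
`f_str` maps a 2048-bit ECFP presence vector to R^256 through widths
2048–512–256–256; `f_sig` maps a 978-dimensional landmark-gene signature
through 978–512–512–256–256. ReLU sits between layers; the final layer has no
activation, so embeddings can point anywhere on the sphere and cosine
similarity spans its full [-1, 1] range. Embeddings are *not* L2-normalized:
cosine similarity is scale-invariant, so normalization would be a no-op for
the objective and is omitted.

Training minimizes the mean cosine triplet hinge
`max(sim(z_sig, z_str^neg) − sim(z_sig, z_str^pos) + α, 0)`. Minimizing this
hinge is identical, up to sign and an additive constant, to maximizing the
saturating objective `min(sim_pos − sim_neg − α, 0)`: both vanish exactly when
the positive beats the negative by the margin and grow linearly in the
violation. Each replicate signature of a compound is its own anchor, so
heavily profiled compounds are seen proportionally often; signatures from
different conditions are kept as separate anchors rather than averaged.
Negatives are drawn uniformly among in-batch structures of other compounds
(`random_in_batch`); `hardest_in_batch` is available but was not better in our
experiments (it collapses early on small corpora). A minibatch containing a
single distinct compound has no valid negative and is skipped with a warning.

The encoders, Adam optimizer and backpropagation through the cosine hinge are
implemented directly on numpy arrays; the gradient is verified against finite
differences in the test suite. Weights use fan-in uniform initialization from
a seeded generator; data order, negative draws and validation triplets all
derive from the configured seed, so training is bit-reproducible.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `margin_alpha` | 0.2 (reference); 1.0 for synthetic experiments | required cosine gap between positive and negative pairs (dimensionless, range [0, 2]) |
| `learning_rate` | 1e-4 (reference); 3e-4 synthetic | Adam step size |
| `batch_size` | 512 (reference); 256 synthetic | anchors per minibatch |
| `max_epochs` / `patience` | 100 / 10 (reference); 200 / 20 synthetic | early-stopping on validation triplet loss, best weights restored |
| `weight_p` | 1 | GSEA running-sum weight exponent; 0 gives the classic unweighted Kolmogorov–Smirnov statistic |
| `n_perm` | 1000 | gene-label permutations per ranked list |
| `min_size` / `max_size` | 5 / 500 | pathway size bounds after intersection with the ranked list |
| FDR threshold | 0.1 | significance call for MoA candidates |
| ECFP radius / bits | 2 / 2048 | Morgan fingerprint settings (ECFP4 convention), recorded in the model archive |

The margin deserves a note. With cosine similarities confined to [-1, 1], a
margin of 0.2 saturates quickly on a small, cleanly separable corpus: most
triplets reach zero loss while the embedding geometry is still coarse. We
selected the synthetic-experiment margin by the model-assessment criterion the
method itself uses — the correlation between embedding-based and
raw-signature-based connectivity profiles on *validation* compounds — which
rose from ≈0.45 (α=0.2) to ≈0.74 (α=1.0) across corpus seeds. The reference
defaults are kept in `TrainConfig` for full-scale use;
`moable.pipeline.default_synthetic_train_config` carries the desk-scale
settings.

## Connectivity

The connectivity of compound c to GP gene g is the maximum cosine similarity
between the query embedding and any GP embedding targeting g. Replicates from
all three perturbation types (knock-down, knock-out, over-expression) are
pooled before the max; over-expression vectors are not sign-flipped, because a
single max over the pooled set is how multiple GP signatures per gene are
aggregated, and the max is inert to ties (the contributing sample id is
reported with first-occurrence tie-breaking). The max is taken globally, not
within cell line. Genes that appear in pathways but have no GP column are
simply absent from the ranking. The identical aggregation runs on raw
signature vectors for the connectivity baseline, so the two routes differ only
in what the query and bank vectors are.

Gene identity across GP metadata, signature rows and GMT symbols is exact,
case-sensitive string match; `PathwayCollection.uppercased()` provides an
explicit normalization switch.

## Enrichment statistics

The enrichment score walks the ranked gene list: an in-set gene at score s
adds `|s|^p / N_R` (N_R = sum of `|s|^p` over all in-set genes in the list; if
all hit scores are zero, hits get equal weight), an out-of-set gene subtracts
`1/(n − n_hits)`. ES is the signed maximum deviation from zero. When the set
covers the whole list the miss step is zero and ES = 1. Exact peak/trough ties
(|max| = |min| within 1e-12) resolve to the earlier list position; the
vectorized permutation path evaluates the running sum only at its candidate
extremes (just after each hit, just before each hit) and implements the same
tie rule, and the test suite asserts equality of the two paths to 1e-9
including tie-provoking integer-valued scores.

The null reassigns set membership uniformly at random to list positions with
scores fixed — the only coherent permutation scheme for a connectivity
ranking, which has no sample classes to permute. p-values are one-sided within
the same-sign null and add-one smoothed, `p = (1 + #extreme)/(1 + #same-sign
nulls)`, so p is never 0 and is at least `1/(n_perm + 1)`; under the null it
is approximately uniform (asserted by a KS test over 500 simulations). NES
divides ES by the mean |null ES| of the matching sign. FDR follows the
sign-stratified ratio-of-tails procedure over null NES pooled across
pathways, monotonized within each sign (a more extreme NES never receives a
larger FDR) and capped at 1; Benjamini–Hochberg over the permutation p-values
is available via `fdr_method="bh"`. Nulls are seeded per (seed, overlap size),
which makes the result table invariant to pathway input order. Ranking ties
break by gene id ascending. Only positive-ES pathways are reported as MoA
candidates by `predict-moa` (MoAs are enriched, not depleted, pathways); the
full signed table is available with `--all-signs`, and the recovery metric
follows the same candidate definition.

## Synthetic data generator

The generator emulates the statistical skeleton of a compound/GP signature
corpus: gene g has a latent template t_g (i.i.d. standard normal over
`sig_dim` = 978 coordinates) and a private motif of `motif_bits_per_target` =
32 reserved fingerprint bits. A non-decoy compound picks a target gene; its
fingerprint sets the motif bits on top of sparse background bits
(`background_bit_rate` = 0.02) and every bit then flips independently with
probability `structure_noise_rate` = 0.05; its 3 replicate signatures are t_g
plus N(0, 0.5²) noise. GP columns are independent noisy template copies, 3
replicates per perturbation type per gene. Pathways partition the 30 genes
into 6 disjoint sets of 5; the truth table maps each compound to the pathways
containing its target. Decoy compounds (10%) receive background-only
fingerprints, pure-noise signatures and no truth entry — they calibrate the
chance level of every downstream metric. The template's own-gene coordinate is
elevated by `target_effect` = 2.0, giving the direct-signature baseline
genuine but weaker signal than the connectivity routes — without it that
baseline would be structurally blind and comparisons against it vacuous.
`compound_signature_noise_sd` overrides the noise of compound columns only,
for degraded-signature experiments.

What the generator does *not* model: real chemistry (fingerprints are abstract
bit patterns, not hashed substructures of valid molecules), L1000's z-score
moderation and 978→12,328 gene inference, correlated off-target
transcriptional programs, cell-line and dose structure, and polypharmacology
(one target per compound). Passing tests therefore demonstrate that the
pipeline recovers a planted structure→signature→pathway linkage under noise —
not that it attains any particular accuracy on real LINCS data, where
signature structure is far richer and the reference magnitude for
embedding-vs-signature connectivity correlation is a moderate positive mean
rather than the ≈0.8 reached here.

## Problem sizes and numerical choices

The reported experiments run at 200 compounds × 3 replicate signatures,
30 GP genes × 9 columns each, 6 pathways, 1000 permutations — sized so the
complete train-to-evaluate cycle finishes in about a minute on one CPU while
every stage still operates above the degenerate regime (≥5 genes per pathway,
≥2 batches per epoch, p-value resolution 1/1001). The compound-disjoint
70/15/15 split uses largest-remainder rounding with ties to the earlier split.
With only 30 rankable genes, a random 5-gene pathway contains the single
strongly connected gene with probability 1/6, so true-pathway p-values floor
near 0.17 even for a perfect ranking; recovery (the true pathway attaining the
minimal candidate p) is the sharper readout at this scale. Text formats
round-trip floats at 10 significant digits; the GCT reader accepts 1.2 (with a
`.meta.tsv` sidecar for column metadata) and 1.3 (embedded metadata), and the
writer emits 1.2 — the binary GCTX carrier is out of scope. Seeds fan out from
one global seed by fixed offsets (`pipeline.SEED_OFFSETS`), keeping every
stage independently reproducible.

## Known limitations

- The retrieval geometry is only as good as the planted linkage; compounds
  sharing a target are interchangeable to the model by construction.
- The sign-stratified FDR depends on the candidate pathway set; with very few
  pathways it is coarse (multiples of tail fractions) and best read alongside
  the permutation p.
- `hardest_in_batch` negative mining is exposed but untuned.
- Depleted (negative-ES) pathways are excluded from MoA calling by design;
  applications expecting inhibition-as-depletion semantics should use
  `--all-signs` and interpret signs themselves.
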