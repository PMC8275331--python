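# moable

Mechanism-of-action (MoA) pathway prediction for compounds **without measured
transcriptomic signatures**, via coembedding of chemical structure and
perturbation signatures.

Identifying which signaling pathways a compound modulates usually requires its
transcriptomic signature (a differential expression profile over the 978 L1000
landmark genes). For novel or merely virtual compounds no such signature
exists. `moable` trains a deep metric-learning model that maps a compound's
2048-bit extended-connectivity fingerprint (ECFP) and its induced signature
into one shared embedding space, so that the *structure* embedding of a new
compound stands in for the signature it would induce. MoA pathways are then
read off from the compound's connectivity to genetic-perturbation (GP)
signatures — knock-down, knock-out and over-expression experiments — followed
by pathway enrichment. The package is aimed at computational chemists and
systems pharmacologists who want pathway-level MoA hypotheses from structures
alone.

## Method

Two MLP encoders share one output space:

- structure encoder `f_str : {0,1}^2048 → R^256` (widths 2048–512–256–256),
- signature encoder `f_sig : R^978 → R^256` (widths 978–512–512–256–256),

with ReLU between layers and none after the last. Training minimizes a cosine
triplet hinge over anchors: for each compound signature (anchor `z_sig`), its
own compound's structure embedding is the positive `z_str+` and another
in-batch compound's structure embedding the negative `z_str−`:

```
L = mean_i max( sim(z_sig_i, z_str−_i) − sim(z_sig_i, z_str+_i) + α, 0 ),
sim(u, v) = u·v / (‖u‖‖v‖)
```

optimized with Adam. After training, every GP signature is embedded through
`f_sig`, and the connectivity of compound *c* to gene *g* pools replicates and
perturbation types by a max:

```
S_{c,g} = max_{i=1..N_g} sim(z_c, z_g^i)
```

Genes ranked by `S_{c,g}` feed a preranked gene set enrichment analysis
(weighted running-sum statistic, gene-label permutation null, add-one smoothed
one-sided p within the same-sign null, sign-stratified NES/FDR). Enriched
pathways with FDR below threshold (default 0.1) are the MoA candidates.
Baselines that *do* use measured signatures — raw-signature connectivity and
direct-signature enrichment — run through the same machinery for comparison.

Because the real corpora behind this kind of model (LINCS L1000 level-5
signatures, clue.io MoA labels, KEGG pathway/drug annotations) need large
external downloads, the package ships a first-class synthetic-data generator
(`moable.synthetic_data`) that plants a compound → target gene → pathway
linkage in both modalities, so the whole pipeline is testable end to end
offline. See `docs/methods.md` for the generative model and its limits.

## Worked example

```
$ moable demo --seed 7 --out demo/
INFO moable: evaluation summary: {'n_compounds': 72, 'median_pvalue': 0.276, 'median_auroc': 0.75}
demo complete; MoA table at demo/moa.tsv
```

The demo simulates a small corpus (80 compounds, 20 GP genes, 4 pathways),
trains the coembedding model, embeds the GP signatures, computes connectivity
profiles for every compound from its fingerprint alone, and runs pathway
enrichment. `demo/moa.tsv` holds one row per compound × enriched pathway:

```
compound_id  pathway_id  ES            NES           p_value       FDR           n_overlap  significant
CPD0000      PW000       0.3746867223  0.6211975923  0.905362776   0.9050632911  5          0
CPD0000      PW001       0.8789301223  1.457188748   0.02208201893 0.05696202532 5          1
```

`ES` is the running-sum enrichment score of the pathway's genes in the
compound's connectivity ranking, `NES` its null-normalized value, and
`significant` flags FDR < 0.1 — here PW001, the pathway containing CPD0000's
planted target gene, is called as the MoA. The report under `demo/report/`
aggregates the true-pathway p-values and per-compound AUROC (median 0.75
above; 0.5 is chance) against the generator's truth table.

Each stage is also exposed separately (`moable simulate | train | embed |
connect | predict-moa | evaluate | run`); every output directory carries a
`manifest.json` with the config snapshot, seeds and input digests, and reruns
with the same manifest reproduce result tables byte for byte.

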