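"""Stage composition: simulate -> split -> train -> embed -> connect -> GSEA.

The CLI and the reproduction script both drive the pipeline through these
functions, so a run is fully scripted from one global seed. The seed fans out
to per-stage seeds by fixed offsets, keeping every stage independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coembedding import (
    CoembeddingModel,
    EmbeddingBank,
    EncoderSpec,
    TrainConfig,
    TrainPair,
    embed_gp_signatures,
    embed_structures,
    train,
)
from .connectivity import (
    ConnectivityProfile,
    connectivity_profile,
    raw_signature_connectivity,
)
from .enrichment import (
    EnrichmentResult,
    direct_signature_enrichment,
    gsea_preranked,
    rank_from_profile,
)
from .io_formats import CompoundRecord, PathwayCollection, SignatureMatrix, SplitSpec, split_compounds
from .synthetic_data import SimCorpus

_SEED_MOD = 2**31 - 1
SEED_OFFSETS = {
    "simulate": 0,
    "split": 101,
    "train": 202,
    "gsea": 303,
    "decoy_labels": 404,
}


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Fan one global seed out to per-stage seeds by fixed offsets."""
    return {k: (int(global_seed) + off) % _SEED_MOD for k, off in SEED_OFFSETS.items()}


def default_synthetic_train_config(seed: int) -> TrainConfig:
    """Training settings for desk-scale synthetic corpora.

    Selected by embedding fidelity (correlation between embedding-based and
    raw-signature-based connectivity) on validation compounds across corpus
    seeds: with cosine similarities confined to [-1, 1], a margin of 1.0 (half
    the attainable range) keeps pulling positives apart from negatives long
    after a small margin has saturated, and a slightly larger learning rate
    suits the small-corpus regime.
    """
    return TrainConfig(margin_alpha=1.0, learning_rate=3e-4, batch_size=256,
                       max_epochs=200, patience=20, seed=seed)


def build_train_pairs(records: list[CompoundRecord],
                      signatures: SignatureMatrix) -> list[TrainPair]:
    """Each replicate signature of each compound becomes one anchor pair."""
    pairs = []
    col_index = {s: i for i, s in enumerate(signatures.sample_ids)}
    for rec in records:
        for sid in rec.signature_ids:
            pairs.append(TrainPair(rec.compound_id, rec.fingerprint,
                                   signatures.values[:, col_index[sid]]))
    return pairs


@dataclass
class PipelineResult:
    model: CoembeddingModel
    train_log: list[dict]
    splits: dict[str, list[str]]
    gp_bank: EmbeddingBank
    structure_bank: EmbeddingBank
    embedding_profiles: dict[str, ConnectivityProfile] = field(default_factory=dict)
    raw_profiles: dict[str, ConnectivityProfile] = field(default_factory=dict)
    moa_results: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    raw_moa_results: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    direct_moa_results: dict[str, list[EnrichmentResult]] = field(default_factory=dict)


def run_pipeline(corpus: SimCorpus, global_seed: int,
                 train_config: TrainConfig | None = None,
                 str_spec: EncoderSpec | None = None,
                 sig_spec: EncoderSpec | None = None,
                 split_spec: SplitSpec | None = None,
                 n_perm: int = 1000, weight_p: float = 1.0,
                 min_size: int = 5, max_size: int = 500,
                 with_baselines: bool = False) -> PipelineResult:
    """Train the coembedding model on the corpus and predict MoA pathways for
    every compound from its structure embedding.

    ``with_baselines`` additionally runs the raw-signature connectivity route
    and the direct-signature enrichment baseline (both consume each compound's
    mean replicate signature as the query).
    """
    seeds = derive_seeds(global_seed)
    split_spec = split_spec or SplitSpec(seed=seeds["split"])
    train_recs, val_recs, test_recs = split_compounds(corpus.compounds, split_spec)
    splits = {
        "train": [r.compound_id for r in train_recs],
        "validation": [r.compound_id for r in val_recs],
        "test": [r.compound_id for r in test_recs],
    }

    cfg = train_config or TrainConfig(seed=seeds["train"])
    pairs = build_train_pairs(train_recs, corpus.compound_signatures)
    val_pairs = build_train_pairs(val_recs, corpus.compound_signatures)
    model, log = train(pairs, cfg, validation_pairs=val_pairs,
                       str_spec=str_spec, sig_spec=sig_spec)

    gp_bank = embed_gp_signatures(model, corpus.gp_signatures)
    fps = {c.compound_id: c.fingerprint for c in corpus.compounds}
    structure_bank = embed_structures(model, fps)

    result = PipelineResult(model, log, splits, gp_bank, structure_bank)

    gsea_kwargs = dict(n_perm=n_perm, weight_p=weight_p, seed=seeds["gsea"],
                       min_size=min_size, max_size=max_size)
    mean_sigs = mean_compound_signatures(corpus)
    for cid in fps:
        prof = connectivity_profile(structure_bank.get(cid), gp_bank, cid)
        result.embedding_profiles[cid] = prof
        result.moa_results[cid] = gsea_preranked(
            rank_from_profile(prof), corpus.pathways, **gsea_kwargs
        )
        if with_baselines:
            raw = raw_signature_connectivity(mean_sigs[cid], corpus.gp_signatures, cid)
            result.raw_profiles[cid] = raw
            result.raw_moa_results[cid] = gsea_preranked(
                rank_from_profile(raw), corpus.pathways, **gsea_kwargs
            )
            result.direct_moa_results[cid] = direct_signature_enrichment(
                mean_sigs[cid], corpus.compound_signatures.gene_ids,
                corpus.pathways, **gsea_kwargs
            )
    return result


def mean_compound_signatures(corpus: SimCorpus) -> dict[str, np.ndarray]:
    """Replicate-averaged signature per compound (the query for raw-signature
    baselines)."""
    col_index = {s: i for i, s in enumerate(corpus.compound_signatures.sample_ids)}
    out = {}
    for rec in corpus.compounds:
        idx = [col_index[s] for s in rec.signature_ids]
        out[rec.compound_id] = corpus.compound_signatures.values[:, idx].mean(axis=1)
    return out


def raw_connectivity_profiles(corpus: SimCorpus) -> dict[str, ConnectivityProfile]:
    """Raw-signature connectivity profile for every compound."""
    mean_sigs = mean_compound_signatures(corpus)
    return {
        cid: raw_signature_connectivity(sig, corpus.gp_signatures, cid)
        for cid, sig in mean_sigs.items()
    }
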