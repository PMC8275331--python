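"""Per-gene connectivity between a query and the genetic-perturbation bank.

The connectivity score of compound c with gene g is the maximum cosine
similarity between the compound's query vector and any GP vector targeting g,
S_{c,g} = max_i sim(z_c, z_g^i), with replicates pooled across perturbation
types (knock-down, knock-out, over-expression) before the max. The same
aggregation runs either on embedding vectors (the coembedding route) or on raw
978-dimensional signatures (the direct-connectivity baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coembedding import EmbeddingBank, cosine_similarity_matrix
from .errors import DimensionError, MissingGeneError, ValidationError
from .io_formats import SignatureMatrix

MODES = ("embedding", "raw_signature")


@dataclass
class ConnectivityProfile:
    """One compound's per-gene connectivity scores S_{c,g}."""

    compound_id: str
    scores: dict[str, float]
    mode: str = "embedding"
    best_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        arr = np.array(list(self.scores.values()), dtype=float)
        if arr.size and (not np.isfinite(arr).all() or (np.abs(arr) > 1 + 1e-9).any()):
            raise ValidationError("connectivity scores must be finite and in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.scores)


def gene_connectivity(query: np.ndarray, gp_vectors_for_gene) -> float:
    """Max cosine similarity between the query and one gene's GP vectors."""
    vectors = list(gp_vectors_for_gene)
    if not vectors:
        raise MissingGeneError("gene has no GP vectors")
    V = np.stack([np.asarray(v, dtype=float) for v in vectors])
    q = np.asarray(query, dtype=float)
    if V.shape[1] != q.shape[0]:
        raise DimensionError(q.shape[0], V.shape[1], "GP vector")
    sims = cosine_similarity_matrix(q[None, :], V)[0]
    return float(sims.max())


def _profile(query: np.ndarray, sample_ids: list[str], vectors: np.ndarray,
             target_genes: list[str], compound_id: str, mode: str) -> ConnectivityProfile:
    q = np.asarray(query, dtype=float)
    if vectors.shape[1] != q.shape[0]:
        raise DimensionError(q.shape[0], vectors.shape[1], "GP vector")
    sims = cosine_similarity_matrix(q[None, :], vectors)[0]
    scores: dict[str, float] = {}
    best: dict[str, str] = {}
    for sid, gene, s in zip(sample_ids, target_genes, sims):
        # max over replicates, pooled across pert_types; first occurrence wins ties
        if gene not in scores or s > scores[gene]:
            scores[gene] = float(s)
            best[gene] = sid
    return ConnectivityProfile(compound_id, scores, mode=mode, best_sample=best)


def connectivity_profile(query: np.ndarray, bank: EmbeddingBank,
                         compound_id: str = "") -> ConnectivityProfile:
    """One S_{c,g} per distinct target gene in the GP embedding bank."""
    gp = bank.subset("gp_signature")
    if not len(gp):
        raise ValidationError("embedding bank has no gp_signature entries")
    genes = [m["target_gene"] for m in gp.meta]
    return _profile(query, gp.ids, gp.vectors, genes, compound_id, "embedding")


def raw_signature_connectivity(compound_signature: np.ndarray, gp: SignatureMatrix,
                               compound_id: str = "") -> ConnectivityProfile:
    """Direct-signature connectivity: same max-aggregation on raw columns."""
    cols = gp.gp_columns()
    if not cols:
        raise ValidationError("signature matrix has no genetic-perturbation columns")
    idx = [gp.sample_ids.index(c) for c in cols]
    genes = [gp.column_meta[c]["target_gene"] for c in cols]
    return _profile(compound_signature, cols, gp.values[:, idx].T, genes,
                    compound_id, "raw_signature")
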