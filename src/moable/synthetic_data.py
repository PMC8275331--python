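"""Self-contained synthetic corpora with a planted compound -> target gene ->
pathway linkage expressed in both modalities.

Generative model: every gene carries a latent signature template (standard
normal, with its own signature coordinate elevated by ``target_effect`` so a
direct-signature baseline has genuine, weaker signal) and a private motif of
reserved fingerprint bits. A compound picks a target gene; its fingerprint is
the gene's motif plus background bits, corrupted by independent bit flips; its
replicate signatures are the template plus Gaussian noise. Genetic-perturbation
columns for a gene are independent noisy copies of the same template per
replicate and perturbation type. Pathways partition the genes; the truth table
maps each compound to every pathway containing its target. Decoy compounds get
random fingerprints, pure-noise signatures and an empty truth entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .evaluation import MoATruth
from .io_formats import (
    CompoundRecord,
    PathwayCollection,
    SignatureMatrix,
    read_fingerprint_tsv,
    read_gmt,
    read_signature_gct,
    read_truth_tsv,
    write_fingerprint_tsv,
    write_gmt,
    write_signature_gct,
    write_truth_tsv,
)

GP_TYPES = ("knock-down", "knock-out", "over-expression")


@dataclass
class SimConfig:
    """Study conditions for one synthetic corpus.

    Defaults give a desk-scale corpus: 200 compounds over 30 GP genes grouped
    into 6 disjoint pathways of 5 genes, 3 replicate signatures per compound,
    3 GP replicates per gene and perturbation type, moderate structure noise
    (5% bit flips) and signature noise (sd 0.5 against unit-variance
    templates). ``compound_signature_noise_sd`` overrides the signature noise
    for compound columns only, for degraded-compound-signature experiments.
    """

    n_compounds: int = 200
    n_genes: int = 30
    n_pathways: int = 6
    genes_per_pathway: int = 5
    n_bits: int = 2048
    sig_dim: int = 978
    replicates_per_gene: int = 3
    signatures_per_compound: int = 3
    motif_bits_per_target: int = 32
    structure_noise_rate: float = 0.05
    signature_noise_sd: float = 0.5
    compound_signature_noise_sd: float | None = None
    background_bit_rate: float = 0.02
    target_effect: float = 2.0
    decoy_compound_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < self.n_pathways:
            raise ValidationError("need n_genes >= n_pathways")
        if self.genes_per_pathway * self.n_pathways > self.n_genes:
            raise ValidationError("disjoint pathways need gpp * n_pathways <= n_genes")
        if self.n_genes * self.motif_bits_per_target > self.n_bits:
            raise ValidationError("motif bit demand exceeds n_bits")
        for r in (self.structure_noise_rate, self.decoy_compound_fraction,
                  self.background_bit_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if self.signature_noise_sd < 0:
            raise ValidationError("signature_noise_sd must be >= 0")
        if self.sig_dim < self.n_genes:
            raise ValidationError("sig_dim must be >= n_genes (genes index rows)")


@dataclass
class SimCorpus:
    compounds: list[CompoundRecord]
    compound_signatures: SignatureMatrix
    gp_signatures: SignatureMatrix
    pathways: PathwayCollection
    truth: MoATruth
    target_map: dict[str, str]
    config: SimConfig | None = None
    decoys: list[str] = field(default_factory=list)

    def validate(self):
        gp_genes = {m["target_gene"] for m in self.gp_signatures.column_meta.values()
                    if m.get("target_gene")}
        for cid, gene in self.target_map.items():
            in_pathway = any(gene in gs for gs in self.pathways.pathways.values())
            if not in_pathway:
                raise ValidationError(f"target {gene} of {cid} in no pathway")
            if gene not in gp_genes:
                raise ValidationError(f"target {gene} of {cid} has no GP column")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate(config: SimConfig) -> SimCorpus:
    """Draw one corpus from the generative model; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    sig_rows = genes + [f"DIM{i:04d}" for i in range(config.n_genes, config.sig_dim)]

    # (1) latent signature template per gene, own coordinate elevated
    templates = rng.standard_normal((config.n_genes, config.sig_dim))
    templates[np.arange(config.n_genes), np.arange(config.n_genes)] += config.target_effect

    # (2) private fingerprint motif per gene
    motif_positions = rng.permutation(config.n_bits)[
        : config.n_genes * config.motif_bits_per_target
    ].reshape(config.n_genes, config.motif_bits_per_target)

    # pathways partition the leading genes
    pw: dict[str, set[str]] = {}
    for p in range(config.n_pathways):
        members = genes[p * config.genes_per_pathway:(p + 1) * config.genes_per_pathway]
        pw[f"PW{p:03d}"] = set(members)
    pathways = PathwayCollection(pw, "synthetic")
    pathway_genes = sorted(set().union(*pw.values()))
    gene_to_pw = {g: [pid for pid, gs in pw.items() if g in gs] for g in genes}

    n_decoys = math.floor(config.n_compounds * config.decoy_compound_fraction)
    n_real = config.n_compounds - n_decoys

    comp_sd = (config.compound_signature_noise_sd
               if config.compound_signature_noise_sd is not None
               else config.signature_noise_sd)

    compounds: list[CompoundRecord] = []
    target_map: dict[str, str] = {}
    truth_labels: dict[str, set[str]] = {}
    decoys: list[str] = []
    sig_cols, sig_ids, col_meta = [], [], {}

    gene_index = {g: i for i, g in enumerate(genes)}
    for i in range(config.n_compounds):
        cid = f"CPD{i:04d}"
        is_decoy = i >= n_real
        fp = (rng.random(config.n_bits) < config.background_bit_rate).astype(np.uint8)
        if is_decoy:
            decoys.append(cid)
        else:
            # (3) planted target: motif bits on top of background, then flips
            gene = pathway_genes[int(rng.integers(len(pathway_genes)))]
            target_map[cid] = gene
            truth_labels[cid] = set(gene_to_pw[gene])
            fp[motif_positions[gene_index[gene]]] = 1
        flips = rng.random(config.n_bits) < config.structure_noise_rate
        fp = np.where(flips, 1 - fp, fp).astype(np.uint8)

        ids = []
        for r in range(config.signatures_per_compound):
            sid = f"{cid}_r{r}"
            ids.append(sid)
            sig_ids.append(sid)
            if is_decoy:
                col = rng.standard_normal(config.sig_dim)
            else:
                col = (templates[gene_index[target_map[cid]]]
                       + rng.standard_normal(config.sig_dim) * comp_sd)
            sig_cols.append(col)
            col_meta[sid] = {"perturbagen_id": cid, "pert_type": "compound"}
        compounds.append(CompoundRecord(cid, fingerprint=fp, signature_ids=ids))

    compound_signatures = SignatureMatrix(
        sig_rows, sig_ids, np.column_stack(sig_cols), col_meta
    )

    # (4) GP columns: noisy template copies per replicate and pert_type
    gp_cols, gp_ids, gp_meta = [], [], {}
    for gi, gene in enumerate(genes):
        for pt in GP_TYPES:
            for r in range(config.replicates_per_gene):
                sid = f"{gene}_{pt}_r{r}"
                gp_ids.append(sid)
                gp_cols.append(templates[gi]
                               + rng.standard_normal(config.sig_dim)
                               * config.signature_noise_sd)
                gp_meta[sid] = {"perturbagen_id": gene, "pert_type": pt,
                                "target_gene": gene}
    gp_signatures = SignatureMatrix(sig_rows, gp_ids, np.column_stack(gp_cols), gp_meta)

    corpus = SimCorpus(
        compounds, compound_signatures, gp_signatures, pathways,
        MoATruth(truth_labels, "target_pathway"), target_map,
        config=config, decoys=decoys,
    )
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# file round trip
# ---------------------------------------------------------------------------

def corpus_to_files(corpus: SimCorpus, directory) -> dict[str, Path]:
    """Write the corpus in the exact io_formats dialects; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "compound_signatures": d / "compound_signatures.gct",
        "gp_signatures": d / "gp_signatures.gct",
        "pathways": d / "pathways.gmt",
        "fingerprints": d / "fingerprints.tsv",
        "truth": d / "truth.tsv",
        "target_map": d / "target_map.tsv",
        "decoys": d / "decoys.tsv",
    }
    write_signature_gct(corpus.compound_signatures, paths["compound_signatures"])
    write_signature_gct(corpus.gp_signatures, paths["gp_signatures"])
    write_gmt(corpus.pathways, paths["pathways"])
    write_fingerprint_tsv(
        {c.compound_id: c.fingerprint for c in corpus.compounds},
        paths["fingerprints"],
    )
    write_truth_tsv(corpus.truth.labels, paths["truth"])
    with open(paths["target_map"], "w") as fh:
        for cid in sorted(corpus.target_map):
            fh.write(f"{cid}\t{corpus.target_map[cid]}\n")
    with open(paths["decoys"], "w") as fh:
        for cid in corpus.decoys:
            fh.write(cid + "\n")
    return paths


def corpus_from_files(directory) -> SimCorpus:
    """Read back a corpus written by :func:`corpus_to_files`."""
    d = Path(directory)
    compound_signatures = read_signature_gct(d / "compound_signatures.gct")
    gp_signatures = read_signature_gct(d / "gp_signatures.gct")
    pathways = read_gmt(d / "pathways.gmt", source_name="synthetic")
    fps = read_fingerprint_tsv(d / "fingerprints.tsv")
    truth = MoATruth(read_truth_tsv(d / "truth.tsv"), "target_pathway")
    target_map = {}
    with open(d / "target_map.tsv") as fh:
        for line in fh:
            cid, gene = line.rstrip("\n").split("\t")
            target_map[cid] = gene
    decoys = [
        line.strip() for line in open(d / "decoys.tsv") if line.strip()
    ] if (d / "decoys.tsv").exists() else []
    by_compound: dict[str, list[str]] = {}
    for sid, meta in compound_signatures.column_meta.items():
        by_compound.setdefault(meta.get("perturbagen_id", ""), []).append(sid)
    compounds = [
        CompoundRecord(cid, fingerprint=fp, signature_ids=sorted(by_compound.get(cid, [])))
        for cid, fp in fps.items()
    ]
    return SimCorpus(compounds, compound_signatures, gp_signatures, pathways,
                     truth, target_map, decoys=decoys)
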