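"""Two-encoder metric-learning model mapping compound structures (ECFP bit
vectors) and perturbation transcriptomic signatures into one cosine-metric
embedding space.

The structure encoder f_str (default 2048-512-256-256) and the signature
encoder f_sig (default 978-512-512-256-256 collapsed to 512-512-256-256 hidden
widths) are plain MLPs with ReLU between layers and no activation after the
last layer, so embeddings can point anywhere on the sphere. Training minimizes
a cosine triplet hinge: the anchor is a compound signature embedding, the
positive is the same compound's structure embedding, and the negative is the
structure embedding of another compound in the minibatch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import DimensionError, ValidationError, ZeroVectorError
from .io_formats import SignatureMatrix, FLOAT_FMT, GP_PERT_TYPES

logger = logging.getLogger(__name__)

ARCHIVE_WEIGHTS = "weights.npz"
ARCHIVE_META = "metadata.json"


# ---------------------------------------------------------------------------
# similarity and loss primitives
# ---------------------------------------------------------------------------

def cosine_similarity(u, v) -> float:
    """u.v / (|u||v|); raises on zero vectors rather than silently returning 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionError(u.shape, v.shape, "vector")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def cosine_similarity_rows(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity between two (n, d) arrays."""
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    if (nu == 0).any() or (nv == 0).any():
        raise ZeroVectorError("cosine similarity undefined for a zero vector")
    return np.einsum("ij,ij->i", U, V) / (nu * nv)


def cosine_similarity_matrix(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """All-pairs cosine similarity, (n, m) for inputs (n, d) and (m, d)."""
    nu = np.linalg.norm(U, axis=1, keepdims=True)
    nv = np.linalg.norm(V, axis=1, keepdims=True)
    if (nu == 0).any() or (nv == 0).any():
        raise ZeroVectorError("cosine similarity undefined for a zero vector")
    return (U / nu) @ (V / nv).T


def triplet_loss(sim_pos: float, sim_neg: float, margin_alpha: float) -> float:
    """Hinge loss max(sim_neg - sim_pos + alpha, 0) for one triplet.

    Minimizing sum_i max(sim_neg_i - sim_pos_i + alpha, 0) is identical (up to
    sign and an additive constant) to maximizing the saturating objective
    sum_i min(sim_pos_i - sim_neg_i - alpha, 0): both are zero exactly when the
    positive beats the negative by at least the margin, and otherwise grow
    linearly in the margin violation.
    """
    return float(max(sim_neg - sim_pos + margin_alpha, 0.0))


def batch_triplet_loss(sims_pos: np.ndarray, sims_neg: np.ndarray,
                       margin_alpha: float) -> float:
    """Mean hinge over a batch of triplets; equals the mean of per-triplet
    :func:`triplet_loss` values."""
    return float(np.mean(np.maximum(sims_neg - sims_pos + margin_alpha, 0.0)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EncoderSpec:
    """Layer widths of one MLP encoder (ReLU between layers, none after last)."""

    input_dim: int
    hidden_dims: list[int] = field(default_factory=lambda: [512, 256])
    output_dim: int = 256
    activation: str = "relu"

    def __post_init__(self):
        dims = [self.input_dim, *self.hidden_dims, self.output_dim]
        if any(d <= 0 for d in dims):
            raise ValidationError("all encoder dims must be positive")
        if self.activation != "relu":
            raise ValidationError("only 'relu' activation is supported")

    @property
    def dims(self) -> list[int]:
        return [self.input_dim, *self.hidden_dims, self.output_dim]


def default_structure_spec(n_bits: int = 2048, output_dim: int = 256) -> EncoderSpec:
    return EncoderSpec(input_dim=n_bits, hidden_dims=[512, 256], output_dim=output_dim)


def default_signature_spec(sig_dim: int = 978, output_dim: int = 256) -> EncoderSpec:
    return EncoderSpec(input_dim=sig_dim, hidden_dims=[512, 512, 256], output_dim=output_dim)


@dataclass
class TrainConfig:
    margin_alpha: float = 0.2
    learning_rate: float = 1e-4
    batch_size: int = 512
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    negative_strategy: str = "random_in_batch"

    def __post_init__(self):
        if not np.isfinite(self.margin_alpha) or self.margin_alpha < 0:
            raise ValidationError("margin_alpha must be finite and >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.batch_size < 2:
            raise ValidationError("batch_size must be >= 2 (a negative must exist)")
        if self.negative_strategy not in ("random_in_batch", "hardest_in_batch"):
            raise ValidationError(
                f"unknown negative_strategy {self.negative_strategy!r}"
            )


# ---------------------------------------------------------------------------
# numpy MLP with explicit backprop
# ---------------------------------------------------------------------------

class _MLP:
    """Minimal MLP: y = W_L(...relu(W_1 x + b_1)...) + b_L, with backprop."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        dims = spec.dims
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(fan_in)  # fan-in uniform init
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-bound, bound, size=fan_out))

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]

    def forward(self, X: np.ndarray, want_cache: bool = False):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise DimensionError(self.spec.input_dim,
                                 X.shape[1] if X.ndim == 2 else X.shape, "encoder input")
        acts = [X]
        h = X
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        if want_cache:
            return h, acts
        return h

    def backward(self, acts: list[np.ndarray], dout: np.ndarray):
        """Gradients of a scalar loss wrt params, given d(loss)/d(output)."""
        n_layers = len(self.W)
        dW = [None] * n_layers
        db = [None] * n_layers
        grad = dout
        for i in range(n_layers - 1, -1, -1):
            if i < n_layers - 1:
                grad = grad * (acts[i + 1] > 0)  # ReLU mask of this layer's output
            dW[i] = acts[i].T @ grad
            db[i] = grad.sum(axis=0)
            if i > 0:
                grad = grad @ self.W[i].T
        return dW + db


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _d_cosine(A: np.ndarray, B: np.ndarray):
    """Row-wise d cos(a,b)/da and /db: ((v - cos*u)/|a|, (u - cos*v)/|b|)
    with u, v the unit rows."""
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    U, V = A / na, B / nb
    cos = np.einsum("ij,ij->i", U, V)[:, None]
    return (V - cos * U) / na, (U - cos * V) / nb


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class CoembeddingModel:
    """Trained pair of encoders sharing one embedding space."""

    def __init__(self, str_spec: EncoderSpec, sig_spec: EncoderSpec,
                 seed: int = 0, metadata: dict | None = None):
        if str_spec.output_dim != sig_spec.output_dim:
            raise ValidationError("both encoders must share output_dim")
        rng = np.random.default_rng(seed)
        self.str_spec = str_spec
        self.sig_spec = sig_spec
        self.f_str = _MLP(str_spec, rng)
        self.f_sig = _MLP(sig_spec, rng)
        self.metadata = dict(metadata or {})
        self.metadata.setdefault("init_seed", seed)

    @property
    def output_dim(self) -> int:
        return self.str_spec.output_dim

    def forward_structure(self, fingerprints: np.ndarray) -> np.ndarray:
        """Embed a batch of binary fingerprint vectors, (n, n_bits) -> (n, d)."""
        X = np.atleast_2d(np.asarray(fingerprints, dtype=float))
        return self.f_str.forward(X)

    def forward_signature(self, signatures: np.ndarray) -> np.ndarray:
        """Embed a batch of transcriptomic signature vectors, (n, G) -> (n, d)."""
        X = np.atleast_2d(np.asarray(signatures, dtype=float))
        return self.f_sig.forward(X)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name, mlp in (("str", self.f_str), ("sig", self.f_sig)):
            for i, (W, b) in enumerate(zip(mlp.W, mlp.b)):
                arrays[f"{name}_W{i}"] = W
                arrays[f"{name}_b{i}"] = b
        np.savez(directory / ARCHIVE_WEIGHTS, **arrays)
        meta = {
            "str_spec": asdict(self.str_spec),
            "sig_spec": asdict(self.sig_spec),
            "metadata": self.metadata,
        }
        (directory / ARCHIVE_META).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "CoembeddingModel":
        directory = Path(directory)
        meta = json.loads((directory / ARCHIVE_META).read_text())
        model = cls(EncoderSpec(**meta["str_spec"]), EncoderSpec(**meta["sig_spec"]),
                    seed=meta["metadata"].get("init_seed", 0),
                    metadata=meta["metadata"])
        with np.load(directory / ARCHIVE_WEIGHTS) as npz:
            for name, mlp in (("str", model.f_str), ("sig", model.f_sig)):
                for i in range(len(mlp.W)):
                    mlp.W[i] = npz[f"{name}_W{i}"]
                    mlp.b[i] = npz[f"{name}_b{i}"]
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainPair:
    """One anchor instance: a compound's signature with its fingerprint.

    A compound with k replicate signatures contributes k pairs, so frequently
    profiled compounds are seen proportionally often.
    """

    compound_id: str
    fingerprint: np.ndarray
    signature: np.ndarray


def _negatives(rng: np.random.Generator, compound_ids: np.ndarray,
               strategy: str, Zs=None, Zp_all=None) -> np.ndarray:
    """Pick, for each anchor, the index of an in-batch negative (a different
    compound)."""
    n = len(compound_ids)
    neg = np.empty(n, dtype=int)
    if strategy == "hardest_in_batch" and Zs is not None:
        sims = cosine_similarity_matrix(Zs, Zp_all)
        for i in range(n):
            mask = compound_ids != compound_ids[i]
            cand = np.where(mask)[0]
            neg[i] = cand[np.argmax(sims[i, cand])]
    else:
        for i in range(n):
            cand = np.where(compound_ids != compound_ids[i])[0]
            neg[i] = rng.choice(cand)
    return neg


def _fixed_validation_triplets(pairs: list[TrainPair], seed: int):
    """Validation triplets are drawn once so the early-stopping signal is a
    fixed function of the parameters."""
    rng = np.random.default_rng(seed)
    cids = np.array([p.compound_id for p in pairs])
    if len(set(cids)) < 2:
        return None
    neg = _negatives(rng, cids, "random_in_batch")
    Xs = np.stack([p.signature for p in pairs])
    Xp = np.stack([p.fingerprint.astype(float) for p in pairs])
    Xn = Xp[neg]
    return Xs, Xp, Xn


def _triplet_batch_loss_and_grads(model: CoembeddingModel, Xs, Xp, Xn, margin):
    """Forward + backward for one batch of (anchor, positive, negative).

    Positives and negatives run through f_str separately; their parameter
    gradients are summed, which handles a compound appearing in both roles.
    """
    Zs, cache_s = model.f_sig.forward(Xs, want_cache=True)
    Zp, cache_p = model.f_str.forward(Xp, want_cache=True)
    Zn, cache_n = model.f_str.forward(Xn, want_cache=True)

    sim_pos = cosine_similarity_rows(Zs, Zp)
    sim_neg = cosine_similarity_rows(Zs, Zn)
    hinge = np.maximum(sim_neg - sim_pos + margin, 0.0)
    loss = float(hinge.mean())

    n = len(hinge)
    active = (hinge > 0).astype(float)[:, None] / n
    d_pos_a, d_pos_p = _d_cosine(Zs, Zp)   # grads of sim_pos
    d_neg_a, d_neg_n = _d_cosine(Zs, Zn)   # grads of sim_neg
    dZs = active * (d_neg_a - d_pos_a)
    dZp = -active * d_pos_p
    dZn = active * d_neg_n

    g_sig = model.f_sig.backward(cache_s, dZs)
    g_str_p = model.f_str.backward(cache_p, dZp)
    g_str_n = model.f_str.backward(cache_n, dZn)
    g_str = [a + b for a, b in zip(g_str_p, g_str_n)]
    return loss, g_sig, g_str


def evaluate_triplet_loss(model: CoembeddingModel, Xs, Xp, Xn, margin) -> float:
    Zs = model.forward_signature(Xs)
    Zp = model.forward_structure(Xp)
    Zn = model.forward_structure(Xn)
    return batch_triplet_loss(
        cosine_similarity_rows(Zs, Zp), cosine_similarity_rows(Zs, Zn), margin
    )


def train(pairs: list[TrainPair], config: TrainConfig,
          validation_pairs: list[TrainPair] | None = None,
          str_spec: EncoderSpec | None = None,
          sig_spec: EncoderSpec | None = None):
    """Train the coembedding model with Adam on the cosine triplet hinge.

    Returns ``(model, log)`` where log is a list of
    ``{"epoch", "train_loss", "val_loss"}`` records. Early stopping watches the
    validation loss with the configured patience and restores the best
    parameters. Fully deterministic given ``config.seed``.
    """
    if len({p.compound_id for p in pairs}) < 2:
        raise ValidationError("training needs >=2 distinct compounds")
    n_bits = len(pairs[0].fingerprint)
    sig_dim = len(pairs[0].signature)
    str_spec = str_spec or default_structure_spec(n_bits)
    sig_spec = sig_spec or default_signature_spec(sig_dim)
    if str_spec.input_dim != n_bits:
        raise DimensionError(str_spec.input_dim, n_bits, "fingerprint")
    if sig_spec.input_dim != sig_dim:
        raise DimensionError(sig_spec.input_dim, sig_dim, "signature")

    model = CoembeddingModel(str_spec, sig_spec, seed=config.seed,
                             metadata={"train_config": asdict(config)})
    params = model.f_sig.params() + model.f_str.params()
    opt = _Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    Xs_all = np.stack([p.signature for p in pairs])
    Xp_all = np.stack([p.fingerprint.astype(float) for p in pairs])
    cids_all = np.array([p.compound_id for p in pairs])

    val = _fixed_validation_triplets(validation_pairs, config.seed + 2) \
        if validation_pairs else None

    best_val = np.inf
    best_params = None
    bad_epochs = 0
    log: list[dict] = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for start in range(0, len(pairs), config.batch_size):
            idx = order[start:start + config.batch_size]
            cids = cids_all[idx]
            if len(set(cids)) < 2:
                logger.warning("skipping batch with a single distinct compound")
                continue
            Zp_all = None
            if config.negative_strategy == "hardest_in_batch":
                Zp_all = model.forward_structure(Xp_all[idx])
                Zs_tmp = model.forward_signature(Xs_all[idx])
                neg = _negatives(rng, cids, "hardest_in_batch", Zs_tmp, Zp_all)
            else:
                neg = _negatives(rng, cids, "random_in_batch")
            Xs, Xp, Xn = Xs_all[idx], Xp_all[idx], Xp_all[idx][neg]
            loss, g_sig, g_str = _triplet_batch_loss_and_grads(
                model, Xs, Xp, Xn, config.margin_alpha
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training aborted: non-finite loss at epoch {epoch}"
                )
            opt.step(params, g_sig + g_str)
            epoch_losses.append(loss)

        train_loss = float(np.mean(epoch_losses)) if epoch_losses else np.nan
        val_loss = (
            evaluate_triplet_loss(model, *val, config.margin_alpha)
            if val is not None else np.nan
        )
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})

        monitor = val_loss if val is not None else train_loss
        if monitor < best_val - 1e-9:
            best_val = monitor
            best_params = [p.copy() for p in params]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                logger.info("early stopping at epoch %d", epoch)
                break

    if best_params is not None:
        k = len(model.f_sig.params())
        model.f_sig.set_params(best_params[:k])
        model.f_str.set_params(best_params[k:])
    return model, log


# ---------------------------------------------------------------------------
# embedding bank
# ---------------------------------------------------------------------------

PROVENANCES = ("structure", "compound_signature", "gp_signature")


@dataclass
class EmbeddingBank:
    """id -> embedding vector store with provenance and GP metadata."""

    ids: list[str]
    vectors: np.ndarray
    provenance: list[str]
    meta: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or len(self.ids) != self.vectors.shape[0]:
            raise ValidationError("vectors must be (n_entries, dim)")
        if not np.isfinite(self.vectors).all():
            raise ValidationError("embedding vectors must be finite")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate entry ids in bank")
        if any(p not in PROVENANCES for p in self.provenance):
            raise ValidationError("unknown provenance")
        if not self.meta:
            self.meta = [{} for _ in self.ids]
        for p, m in zip(self.provenance, self.meta):
            if p == "gp_signature" and not m.get("target_gene"):
                raise ValidationError("gp_signature entries need target_gene")

    def __len__(self):
        return len(self.ids)

    def subset(self, provenance: str) -> "EmbeddingBank":
        keep = [i for i, p in enumerate(self.provenance) if p == provenance]
        return EmbeddingBank(
            [self.ids[i] for i in keep], self.vectors[keep],
            [self.provenance[i] for i in keep], [self.meta[i] for i in keep],
        )

    def get(self, entry_id: str) -> np.ndarray:
        return self.vectors[self.ids.index(entry_id)]

    def save_tsv(self, path) -> None:
        dim = self.vectors.shape[1]
        with open(path, "w") as fh:
            fh.write("entry_id\tprovenance\ttarget_gene\tpert_type\t"
                     + "\t".join(f"v{i}" for i in range(dim)) + "\n")
            for eid, prov, m, vec in zip(self.ids, self.provenance,
                                         self.meta, self.vectors):
                fh.write("\t".join([
                    eid, prov, m.get("target_gene", ""), m.get("pert_type", ""),
                    *(FLOAT_FMT % v for v in vec),
                ]) + "\n")

    @classmethod
    def load_tsv(cls, path) -> "EmbeddingBank":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", dtype={
            "entry_id": str, "provenance": str,
            "target_gene": str, "pert_type": str,
        }).fillna("")
        vcols = [c for c in df.columns if c.startswith("v")]
        meta = [
            {k: r[k] for k in ("target_gene", "pert_type") if r[k]}
            for _, r in df[["target_gene", "pert_type"]].iterrows()
        ]
        return cls(df["entry_id"].tolist(), df[vcols].to_numpy(float),
                   df["provenance"].tolist(), meta)


def embed_gp_signatures(model: CoembeddingModel, gp: SignatureMatrix) -> EmbeddingBank:
    """Embed every genetic-perturbation column of ``gp`` through the signature
    encoder, carrying target_gene and pert_type into the bank."""
    cols = gp.gp_columns()
    if not cols:
        raise ValidationError("signature matrix has no genetic-perturbation columns")
    if gp.n_genes != model.sig_spec.input_dim:
        raise DimensionError(model.sig_spec.input_dim, gp.n_genes, "GP signature")
    idx = [gp.sample_ids.index(c) for c in cols]
    Z = model.forward_signature(gp.values[:, idx].T)
    meta = [
        {
            "target_gene": gp.column_meta[c]["target_gene"],
            "pert_type": gp.column_meta[c]["pert_type"],
        }
        for c in cols
    ]
    return EmbeddingBank(cols, Z, ["gp_signature"] * len(cols), meta)


def embed_structures(model: CoembeddingModel,
                     fingerprints: dict[str, np.ndarray]) -> EmbeddingBank:
    ids = list(fingerprints)
    Z = model.forward_structure(np.stack([fingerprints[i].astype(float) for i in ids]))
    return EmbeddingBank(ids, Z, ["structure"] * len(ids))


def embed_compound_signatures(model: CoembeddingModel,
                              sm: SignatureMatrix) -> EmbeddingBank:
    cols = [
        s for s in sm.sample_ids
        if sm.column_meta.get(s, {}).get("pert_type") not in GP_PERT_TYPES
    ]
    idx = [sm.sample_ids.index(c) for c in cols]
    Z = model.forward_signature(sm.values[:, idx].T)
    meta = [
        {"perturbagen_id": sm.column_meta.get(c, {}).get("perturbagen_id", "")}
        for c in cols
    ]
    return EmbeddingBank(cols, Z, ["compound_signature"] * len(cols), meta)
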