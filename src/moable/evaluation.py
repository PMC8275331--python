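"""Quantitative evaluation of MoA pathway predictions.

Two protocols: (1) the distribution of true-MoA-pathway p-values across
compounds, and (2) a per-compound AUROC where the permutation FDR acts as the
decision score (lower FDR = more confidently called) and pathways are labeled
true/false by the truth table. Also the embedding-fidelity check (per-compound
Pearson correlation between embedding-based and raw-signature-based
connectivity profiles) and Tanimoto-based stratification of evaluation
compounds into unseen / unseen-hard sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, rankdata

from .connectivity import ConnectivityProfile
from .enrichment import EnrichmentResult
from .errors import ValidationError

logger = logging.getLogger(__name__)

LABEL_MODES = ("target_pathway", "expanded")
STRATA = ("all", "unseen", "unseen_hard", "anticancer", "custom")


@dataclass
class MoATruth:
    """compound_id -> set of true MoA pathway ids."""

    labels: dict[str, set[str]]
    label_mode: str = "target_pathway"

    def __post_init__(self):
        if self.label_mode not in LABEL_MODES:
            raise ValidationError(f"unknown label_mode {self.label_mode!r}")
        for cid, pids in self.labels.items():
            if not pids:
                raise ValidationError(f"compound {cid!r} has an empty truth set")


@dataclass
class EvalReport:
    """Per-compound records plus recomputable aggregate medians."""

    records: list[dict]
    stratum: str = "all"
    aggregates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stratum not in STRATA:
            raise ValidationError(f"unknown stratum {self.stratum!r}")
        pooled = [p for r in self.records for p in r.get("true_pvalues", [])]
        aurocs = [r["auroc"] for r in self.records if r.get("auroc") is not None]
        self.aggregates = {
            "n_compounds": len(self.records),
            "median_pvalue": float(np.median(pooled)) if pooled else None,
            "median_auroc": float(np.median(aurocs)) if aurocs else None,
        }


ResultsByCompound = dict[str, list[EnrichmentResult]]


def true_pathway_pvalues(results: ResultsByCompound, truth: MoATruth):
    """p-values of each compound's true pathways.

    Returns ``{compound_id: {"pvalues": [...], "not_evaluable": [...]}}``.
    Truth pathways absent from a compound's result table are reported under
    ``not_evaluable`` rather than silently dropped.
    """
    missing = [c for c in truth.labels if c not in results]
    if missing:
        raise ValidationError(f"compounds missing from results: {missing}")
    out = {}
    for cid, true_pids in truth.labels.items():
        by_pid = {r.pathway_id: r for r in results[cid]}
        pvals, not_eval = [], []
        for pid in sorted(true_pids):
            if pid in by_pid:
                pvals.append(by_pid[pid].p_value)
            else:
                not_eval.append(pid)
        out[cid] = {"pvalues": pvals, "not_evaluable": not_eval}
    return out


def _midrank_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUROC with midrank tie handling; equals the fraction of
    correctly ordered (true, false) pairs with ties counted one half."""
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def fdr_threshold_auroc(results: ResultsByCompound, truth: MoATruth) -> dict[str, float]:
    """Per-compound AUROC sweeping the FDR as decision score.

    Lower FDR means a more confident positive call, so the score is -FDR.
    Compounds whose evaluated pathways are all true or all false are excluded
    with a logged reason.
    """
    out: dict[str, float] = {}
    for cid, true_pids in truth.labels.items():
        if cid not in results:
            raise ValidationError(f"compound {cid!r} missing from results")
        res = results[cid]
        labels = np.array([r.pathway_id in true_pids for r in res])
        if not res or labels.all() or not labels.any():
            logger.info("compound %s: one-class pathway labels, excluded", cid)
            continue
        scores = -np.array([r.fdr for r in res])
        out[cid] = _midrank_auroc(scores, labels)
    return out


def embedding_fidelity_correlation(signature_profiles: list[ConnectivityProfile],
                                   embedding_profiles: list[ConnectivityProfile]):
    """Pearson r, per compound, between the two connectivity profiles over the
    shared gene set. Returns ``(per_compound, summary)``; on real L1000-scale
    data the reference magnitude for the mean is a moderate positive
    correlation, documented rather than asserted."""
    emb = {p.compound_id: p for p in embedding_profiles}
    per_compound: dict[str, float] = {}
    skipped: list[str] = []
    for sp in signature_profiles:
        ep = emb.get(sp.compound_id)
        if ep is None:
            raise ValidationError(f"no embedding profile for {sp.compound_id!r}")
        shared = sorted(set(sp.scores) & set(ep.scores))
        if len(shared) < 3:
            skipped.append(sp.compound_id)
            continue
        x = np.array([sp.scores[g] for g in shared])
        y = np.array([ep.scores[g] for g in shared])
        if np.std(x) == 0 or np.std(y) == 0:
            skipped.append(sp.compound_id)
            continue
        per_compound[sp.compound_id] = float(pearsonr(x, y).statistic)
    vals = np.array(list(per_compound.values()))
    summary = {
        "mean": float(vals.mean()) if vals.size else None,
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
        "n": int(vals.size),
        "skipped": skipped,
    }
    return per_compound, summary


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto |a&b|/|a|b| for binary fingerprint matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        t = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return t


def tanimoto_stratify(train_fps: dict[str, np.ndarray],
                      eval_fps: dict[str, np.ndarray],
                      threshold: float = 0.3):
    """Max Tanimoto similarity of each evaluation compound to the training set;
    a compound is 'unseen_hard' when that max falls below the threshold."""
    if not train_fps:
        raise ValidationError("empty training fingerprint set")
    T = np.stack([train_fps[i] for i in train_fps])
    eval_ids = list(eval_fps)
    E = np.stack([eval_fps[i] for i in eval_ids])
    max_sim = tanimoto_matrix(E, T).max(axis=1)
    return {
        cid: {"max_tanimoto": float(s),
              "stratum": "unseen_hard" if s < threshold else "unseen"}
        for cid, s in zip(eval_ids, max_sim)
    }


def lowest_pvalue_recovery(results: ResultsByCompound, truth: MoATruth,
                           candidates: str = "enriched") -> float:
    """Fraction of compounds whose true pathway reaches the minimum p-value
    among MoA candidates (ties with the minimum count as recovered).

    ``candidates="enriched"`` (default) restricts to positive-ES pathways —
    the ones the pipeline reports as MoA candidates; ``"all"`` scores over the
    full signed table. Compounds with several true pathways count when any of
    them attains the minimum."""
    if candidates not in ("enriched", "all"):
        raise ValidationError(f"unknown candidates mode {candidates!r}")
    hits, total = 0, 0
    for cid, true_pids in truth.labels.items():
        res = results.get(cid)
        if res and candidates == "enriched":
            res = [r for r in res if r.es >= 0]
        if not res:
            continue
        total += 1
        pmin = min(r.p_value for r in res)
        if any(r.pathway_id in true_pids and r.p_value <= pmin for r in res):
            hits += 1
    if total == 0:
        raise ValidationError("no compounds with results to score")
    return hits / total


def build_report(results: ResultsByCompound, truth: MoATruth,
                 stratum: str = "all") -> EvalReport:
    """Combine both protocols into one per-compound report."""
    pvals = true_pathway_pvalues(results, truth)
    aurocs = fdr_threshold_auroc(results, truth)
    records = []
    for cid in sorted(truth.labels):
        records.append({
            "compound_id": cid,
            "true_pvalues": pvals[cid]["pvalues"],
            "not_evaluable": pvals[cid]["not_evaluable"],
            "auroc": aurocs.get(cid),
        })
    return EvalReport(records, stratum=stratum)
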