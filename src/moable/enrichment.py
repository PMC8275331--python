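"""Preranked gene set enrichment over connectivity-ranked GP genes.

Weighted running-sum enrichment score (Kolmogorov-Smirnov style): walking down
the ranked list, in-set genes push the sum up by |score|^p normalized over all
in-set hits, out-of-set genes pull it down by 1/(n - n_hits); the enrichment
score (ES) is the signed maximum deviation from zero. Significance comes from a
gene-label permutation null (set membership reassigned uniformly at random to
list positions, scores fixed), with add-one smoothed one-sided p-values,
null-normalized enrichment scores (NES) and a sign-stratified ratio-of-tails
false discovery rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityProfile
from .errors import ValidationError
from .io_formats import PathwayCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ranked list
# ---------------------------------------------------------------------------

@dataclass
class RankedGeneList:
    """Genes sorted by score descending; ties broken by gene id ascending."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        order = sorted(range(len(self.genes)),
                       key=lambda i: (-self.scores[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.scores = self.scores[order]

    def __len__(self):
        return len(self.genes)

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "RankedGeneList":
        genes = list(scores)
        return cls(genes, np.array([scores[g] for g in genes]))


def rank_from_profile(profile: ConnectivityProfile) -> RankedGeneList:
    return RankedGeneList.from_scores(profile.scores)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(ranked: RankedGeneList, gene_set: set[str],
                     weight_p: float = 1.0):
    """Weighted running-sum ES of ``gene_set`` on ``ranked``.

    Returns ``(ES, running_sum)`` where running_sum[i] is the value after
    scanning position i. Raises ``ValidationError`` when the set does not
    intersect the list.
    """
    if len(ranked) == 0:
        raise ValidationError("ranked list is empty")
    if weight_p < 0:
        raise ValidationError("weight_p must be >= 0")
    n = len(ranked)
    hits = np.fromiter((g in gene_set for g in ranked.genes), bool, count=n)
    k = int(hits.sum())
    if k == 0:
        raise ValidationError("gene set does not overlap the ranked list")
    w = np.abs(ranked.scores) ** weight_p
    wh = np.where(hits, w, 0.0)
    nr = wh.sum()
    if nr == 0.0:  # all hit scores zero: fall back to equal hit weights
        wh = hits / k
        nr = 1.0
    miss_step = 1.0 / (n - k) if n > k else 0.0
    steps = wh / nr - np.where(hits, 0.0, miss_step)
    running = np.cumsum(steps)
    # earliest position attaining the max (resp. min) within tolerance, so
    # cumsum rounding cannot reorder exact ties
    pos_pk = int(np.argmax(running >= running.max() - _TIE_TOL))
    pos_tr = int(np.argmax(running <= running.min() + _TIE_TOL))
    es = float(_signed_extreme(running[pos_pk], pos_pk, running[pos_tr], pos_tr))
    return es, running


_TIE_TOL = 1e-12


def _signed_extreme(peak, pos_pk, trough, pos_tr):
    """Signed maximum deviation from zero; near-exact |peak| == |trough| ties
    go to the earlier list position, so the full running-sum scan and the
    candidate-based permutation path agree."""
    if abs(peak) > abs(trough) + _TIE_TOL:
        return peak
    if abs(trough) > abs(peak) + _TIE_TOL:
        return trough
    return peak if pos_pk <= pos_tr else trough


def _es_from_positions(scores: np.ndarray, positions: np.ndarray,
                       weight_p: float) -> np.ndarray:
    """ES for many permutations at once.

    ``positions`` is (m, k): hit positions per permutation (any order). The
    running sum's extreme is attained right after a hit (peaks) or right
    before one (troughs); evaluating only those candidates matches the full
    running-sum ES, including the first-occurrence tie rule.
    """
    n = len(scores)
    m, k = positions.shape
    q = np.sort(positions, axis=1)
    w_all = np.abs(scores) ** weight_p
    wh = w_all[q]
    nr = wh.sum(axis=1, keepdims=True)
    uniform = nr == 0.0
    if uniform.any():
        wh = np.where(uniform, 1.0 / k, wh)
        nr = np.where(uniform, 1.0, nr)
    cumw = np.cumsum(wh, axis=1) / nr
    miss_step = 1.0 / (n - k) if n > k else 0.0
    j = np.arange(k)
    miss_before = (q - j) * miss_step
    after = cumw - miss_before                       # running[q_j]
    before = np.concatenate(
        [np.zeros((m, 1)), cumw[:, :-1]], axis=1
    ) - miss_before                                  # running[q_j - 1]
    rows = np.arange(m)
    # earliest candidate within tolerance of the extreme, matching the
    # full-scan tie rule of enrichment_score
    pk_ok = after >= after.max(axis=1, keepdims=True) - _TIE_TOL
    tr_ok = before <= before.min(axis=1, keepdims=True) + _TIE_TOL
    i_pk = np.argmax(pk_ok, axis=1)
    i_tr = np.argmax(tr_ok, axis=1)
    peak, trough = after[rows, i_pk], before[rows, i_tr]
    pos_pk = q[rows, i_pk]            # index of the peak in the full list
    pos_tr = q[rows, i_tr] - 1        # index of the trough
    take_peak = np.abs(peak) > np.abs(trough) + _TIE_TOL
    tie = np.abs(np.abs(peak) - np.abs(trough)) <= _TIE_TOL
    take_peak = take_peak | (tie & (pos_pk <= pos_tr))
    return np.where(take_peak, peak, trough)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    pathway_id: str
    es: float
    nes: float
    p_value: float
    fdr: float
    n_overlap: int


def _null_bank(n: int, sizes: set[int], scores: np.ndarray, n_perm: int,
               weight_p: float, seed: int) -> dict[int, np.ndarray]:
    """Null ES arrays per overlap size k. Seeded per (seed, k) so results do
    not depend on pathway input order."""
    out = {}
    for k in sorted(sizes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        positions = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        out[k] = _es_from_positions(scores, positions, weight_p)
    return out


def _signed_mean(null: np.ndarray, sign: float) -> float:
    same = null[null >= 0] if sign >= 0 else null[null < 0]
    if same.size:
        return float(np.abs(same).mean())
    overall = np.abs(null).mean()
    return float(overall) if overall > 0 else 1.0


def gsea_preranked(ranked: RankedGeneList, pathways: PathwayCollection,
                   n_perm: int = 1000, weight_p: float = 1.0, seed: int = 0,
                   min_size: int = 5, max_size: int = 500,
                   fdr_method: str = "sign_stratified") -> list[EnrichmentResult]:
    """Preranked GSEA of every retained pathway against ``ranked``.

    p-values use add-one smoothing (1 + #extreme)/(1 + n_perm) on the matching
    sign, so p >= 1/(n_perm + 1) always. NES divides ES by the mean |null ES|
    of the same sign. FDR follows the sign-stratified ratio-of-tails procedure
    over pooled null NES, monotonized within each sign and capped at 1;
    ``fdr_method="bh"`` applies Benjamini-Hochberg to the permutation p-values
    instead. Deterministic given ``seed`` and invariant to pathway order.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    genes_in_list = set(ranked.genes)
    n = len(ranked)

    retained: list[tuple[str, set[str]]] = []
    for pid in sorted(pathways.pathways):
        overlap = pathways[pid] & genes_in_list
        if not overlap:
            logger.info("pathway %s: no overlap with ranked list, skipped", pid)
            continue
        if not (min_size <= len(overlap) <= max_size):
            logger.info("pathway %s: overlap %d outside [%d, %d], excluded",
                        pid, len(overlap), min_size, max_size)
            continue
        retained.append((pid, overlap))
    if not retained:
        return []

    nulls = _null_bank(n, {len(o) for _, o in retained}, ranked.scores,
                       n_perm, weight_p, seed)

    rows = []
    for pid, overlap in retained:
        es, _ = enrichment_score(ranked, overlap, weight_p)
        null = nulls[len(overlap)]
        # one-sided p within the same-sign null (the conventional preranked
        # GSEA convention), add-one smoothed so p >= 1/(n_perm + 1) > 0
        if es >= 0:
            extreme = int(np.sum(null >= es))
            n_side = int(np.sum(null >= 0))
        else:
            extreme = int(np.sum(null <= es))
            n_side = int(np.sum(null < 0))
        p = (1 + extreme) / (1 + n_side)
        nes = es / _signed_mean(null, es)
        # normalize this pathway's nulls the same way for the pooled FDR null
        pos_mean = _signed_mean(null, 1.0)
        neg_mean = _signed_mean(null, -1.0)
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        rows.append({"pathway_id": pid, "es": es, "nes": nes, "p": p,
                     "n_overlap": len(overlap), "null_nes": null_nes})

    obs_nes = np.array([r["nes"] for r in rows])
    if fdr_method == "bh":
        from scipy.stats import false_discovery_control
        fdrs = false_discovery_control([r["p"] for r in rows])
    elif fdr_method == "sign_stratified":
        pooled = np.concatenate([r["null_nes"] for r in rows])
        fdrs = np.empty(len(rows))
        for i, r in enumerate(rows):
            nes = r["nes"]
            if nes >= 0:
                num_den = np.sum(pooled >= 0)
                num = np.sum(pooled >= nes) / num_den if num_den else 0.0
                den = np.sum(obs_nes >= nes) / max(np.sum(obs_nes >= 0), 1)
            else:
                num_den = np.sum(pooled < 0)
                num = np.sum(pooled <= nes) / num_den if num_den else 0.0
                den = np.sum(obs_nes <= nes) / max(np.sum(obs_nes < 0), 1)
            fdrs[i] = min(num / den, 1.0) if den > 0 else 1.0
        # monotonize within each sign: a more extreme NES never has larger FDR
        for sign in (1, -1):
            idx = [i for i, r in enumerate(rows)
                   if (r["nes"] >= 0) == (sign == 1)]
            idx.sort(key=lambda i: -abs(rows[i]["nes"]))  # extreme -> mild
            # q_i = min of FDRs over pathways at most as extreme
            for j in range(len(idx) - 2, -1, -1):
                fdrs[idx[j]] = min(fdrs[idx[j]], fdrs[idx[j + 1]])
    else:
        raise ValidationError(f"unknown fdr_method {fdr_method!r}")

    results = [
        EnrichmentResult(r["pathway_id"], r["es"], r["nes"], r["p"],
                         float(f), r["n_overlap"])
        for r, f in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: r.pathway_id)
    return results


def direct_signature_enrichment(values: np.ndarray, gene_ids: list[str],
                                pathways: PathwayCollection,
                                **kwargs) -> list[EnrichmentResult]:
    """Direct-signature baseline: rank genes by their signature value
    descending and run the identical preranked GSEA."""
    ranked = RankedGeneList(list(gene_ids), np.asarray(values, dtype=float))
    return gsea_preranked(ranked, pathways, **kwargs)
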