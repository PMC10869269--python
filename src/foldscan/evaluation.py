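"""Benchmark metrics: ROC1 sensitivity, weighted precision-recall,
per-residue coverage and alignment quality.

Labels follow the usual domain-classification hierarchy: each entry has a
(family, superfamily, fold) triple with consistent nesting.  At family
level a true positive is a hit within the same family; at superfamily
level, same superfamily but not same family; at fold level, same fold but
not same superfamily.  Hits across folds are false positives at every
level; everything else is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: entry id -> (family, superfamily, fold)
Labels = dict[str, tuple[str, str, str]]

LEVELS = ("family", "superfamily", "fold")


@dataclass(frozen=True)
class QualityScores:
    sensitivity: float
    precision: float

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.precision
        return 2.0 * s * p / (s + p) if (s + p) > 0 else 0.0


def check_label_nesting(labels: Labels) -> None:
    """Families must not straddle superfamilies, nor superfamilies folds."""
    fam_to_sf: dict[str, str] = {}
    sf_to_fold: dict[str, str] = {}
    for fam, sf, fold in labels.values():
        if fam_to_sf.setdefault(fam, sf) != sf:
            raise ValueError(f"family {fam} spans multiple superfamilies")
        if sf_to_fold.setdefault(sf, fold) != fold:
            raise ValueError(f"superfamily {sf} spans multiple folds")


def classify_hit(labels: Labels, query_id: str, target_id: str,
                 level: str) -> str:
    """'TP', 'FP' or 'ignore' for one query-target pair at one level."""
    qf, qs, qd = labels[query_id]
    tf, ts, td = labels[target_id]
    if qd != td:
        return "FP"
    if level == "family":
        return "TP" if qf == tf else "ignore"
    if level == "superfamily":
        if qf == tf:
            return "ignore"
        return "TP" if qs == ts else "ignore"
    if level == "fold":
        if qs == ts:
            return "ignore"
        return "TP"
    raise ValueError(f"unknown level {level!r}")


def _possible_tps(labels: Labels, query_id: str, level: str) -> int:
    return sum(1 for other in labels
               if other != query_id and classify_hit(labels, query_id, other, level) == "TP")


def roc1_sensitivity(ranked_hits: dict[str, list[str]], labels: Labels,
                     level: str) -> tuple[dict[str, float], float]:
    """Fraction of possible TPs ranked before the first FP, per query.

    ``ranked_hits`` maps each query id to its target ids sorted by the
    tool's ranking; self-hits are removed here.  Queries with no possible
    TP at the level are excluded from the mean; a query id absent from the
    labels raises.
    """
    per_query: dict[str, float] = {}
    for query_id, targets in ranked_hits.items():
        if query_id not in labels:
            raise KeyError(f"query {query_id!r} not in labels")
        possible = _possible_tps(labels, query_id, level)
        if possible == 0:
            continue
        n_tp = 0
        for target_id in targets:
            if target_id == query_id:
                continue
            cls = classify_hit(labels, query_id, target_id, level)
            if cls == "FP":
                break
            if cls == "TP":
                n_tp += 1
        per_query[query_id] = n_tp / possible
    mean = float(np.mean(list(per_query.values()))) if per_query else 0.0
    return per_query, mean


def _group_sizes(labels: Labels, level: str) -> dict[str, int]:
    pos = LEVELS.index(level)
    sizes: dict[str, int] = {}
    for triple in labels.values():
        sizes[triple[pos]] = sizes.get(triple[pos], 0) + 1
    return sizes


def weighted_precision_recall(pooled_hits: list[tuple[str, str, float]],
                              labels: Labels, level: str
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Size-weighted precision-recall curve over pooled, scored hits.

    Every TP/FP/FN count is weighted by the reciprocal of the query's
    group size at the level, so large families contribute linearly rather
    than quadratically.  Returns (precision, recall, thresholds) sampled
    after each pooled hit (sorted by descending score, self-hits dropped).
    """
    pos = LEVELS.index(level)
    sizes = _group_sizes(labels, level)

    def weight(query_id: str) -> float:
        return 1.0 / sizes[labels[query_id][pos]]

    total_tp = sum(_possible_tps(labels, q, level) * weight(q) for q in labels)
    hits = sorted((h for h in pooled_hits if h[0] != h[1]),
                  key=lambda h: (-h[2], h[0], h[1]))
    w_tp = w_fp = 0.0
    precision, recall, thresholds = [], [], []
    for query_id, target_id, score in hits:
        cls = classify_hit(labels, query_id, target_id, level)
        if cls == "TP":
            w_tp += weight(query_id)
        elif cls == "FP":
            w_fp += weight(query_id)
        else:
            continue
        precision.append(w_tp / (w_tp + w_fp))
        recall.append(w_tp / total_tp if total_tp > 0 else 0.0)
        thresholds.append(score)
    return np.array(precision), np.array(recall), np.array(thresholds)


TP_LDDT = 0.6
FP_LDDT = 0.25


def per_residue_coverage(query_lengths: dict[str, int],
                         ranked_matches: dict[str, list[tuple[float, int, int]]],
                         max_x: int = 5) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Fraction of query residues covered by at least x true matches.

    ``ranked_matches`` maps each query to its matches in rank order as
    ``(alignment_lddt, q_start, q_end)`` half-open query intervals.
    Matches with LDDT >= 0.6 are true, < 0.25 false (truncating the list),
    the band in between is ignored.  Returns the mean curve over queries
    for x = 1..max_x and the per-query curves.
    """
    per_query: dict[str, np.ndarray] = {}
    for query_id, L in query_lengths.items():
        depth = np.zeros(L, dtype=np.int64)
        for lddt, q_start, q_end in ranked_matches.get(query_id, []):
            if lddt < FP_LDDT:
                break
            if lddt >= TP_LDDT:
                depth[q_start:q_end] += 1
        per_query[query_id] = np.array([(depth >= x).mean() for x in range(1, max_x + 1)])
    if not per_query:
        return np.zeros(max_x), per_query
    return np.mean(list(per_query.values()), axis=0), per_query


def alignment_quality(predicted_pairs, mode: str,
                      reference_pairs=None,
                      residue_lddt=None,
                      query_length: int | None = None) -> QualityScores:
    """Alignment quality against a reference or by residue-wise LDDT.

    reference_based: sensitivity is the fraction of reference residue
    pairs recovered, precision the fraction of predicted pairs that are in
    the reference; an empty prediction scores sensitivity 0.

    reference_free: each aligned residue is classified by its residue-wise
    LDDT (true >= 0.6, false < 0.25, mid-band ignored); sensitivity is
    true residues / query length, precision true residues over the
    classified residues of the alignment.
    """
    if mode == "reference_based":
        if not reference_pairs:
            raise ValueError("reference_based mode requires a non-empty reference")
        pred = set(map(tuple, predicted_pairs or []))
        ref = set(map(tuple, reference_pairs))
        correct = len(pred & ref)
        sensitivity = correct / len(ref)
        precision = correct / len(pred) if pred else 0.0
        return QualityScores(sensitivity, precision)
    if mode == "reference_free":
        if residue_lddt is None or query_length is None:
            raise ValueError("reference_free mode requires residue_lddt and query_length")
        lddt = np.asarray(residue_lddt, dtype=np.float64)
        lddt = lddt[~np.isnan(lddt)]
        n_tp = int((lddt >= TP_LDDT).sum())
        n_fp = int((lddt < FP_LDDT).sum())
        sensitivity = n_tp / query_length if query_length else 0.0
        precision = n_tp / (n_tp + n_fp) if (n_tp + n_fp) else 0.0
        return QualityScores(sensitivity, precision)
    raise ValueError(f"unknown mode {mode!r}")
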