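"""Alignment quality scores: LDDT, TM-score and the structural bit score.

LDDT is superposition-free: for each aligned query residue the distances
to its spatial neighbors are compared with the distances between the
corresponding target residues, and differences are scored through four
thresholds (0.5/1/2/4 A).  The implementation hashes query CA atoms into
a 15 A grid so neighbor search touches only the 27 adjacent cells; an
O(L^2) oracle in the tests checks the grid path exactly.

TM-score is computed on a *fixed* alignment by searching for the best
superposition: Kabsch fits seeded from aligned fragments, refined by
iterating inclusion of residue pairs within a shrinking distance cutoff.

The ranking statistic is the structural bit score: the alignment bit
score times the geometric mean of alignment TM-score and mean LDDT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_LDDT_RADIUS = 15.0
DEFAULT_LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class LddtParams:
    radius: float = DEFAULT_LDDT_RADIUS
    thresholds: tuple[float, ...] = DEFAULT_LDDT_THRESHOLDS
    #: 'aligned_neighbors' divides by the neighbors that are themselves
    #: aligned; 'all_neighbors' divides by every neighbor within the radius,
    #: so unaligned neighbors count as zero-scoring.
    denominator_mode: str = "aligned_neighbors"

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be strictly increasing")
        if self.denominator_mode not in ("aligned_neighbors", "all_neighbors"):
            raise ValueError(f"unknown denominator mode {self.denominator_mode!r}")


def lddt_pair_score(d: float, thresholds=DEFAULT_LDDT_THRESHOLDS) -> float:
    """Per-pair score of a distance difference: the fraction of thresholds
    the difference stays under (0.25 each with the four defaults)."""
    return sum(d < t for t in thresholds) / len(thresholds)


def _grid_cells(coords: np.ndarray, cell: float) -> dict[tuple[int, int, int], list[int]]:
    cells: dict[tuple[int, int, int], list[int]] = {}
    keys = np.floor(coords / cell).astype(np.int64)
    for i, key in enumerate(map(tuple, keys)):
        cells.setdefault(key, []).append(i)
    return cells


def _neighbors_within(i: int, coords: np.ndarray, cells: dict, cell: float,
                      radius: float) -> np.ndarray:
    key = tuple(np.floor(coords[i] / cell).astype(np.int64))
    cand: list[int] = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                cand.extend(cells.get((key[0] + dx, key[1] + dy, key[2] + dz), ()))
    cand_arr = np.array([c for c in cand if c != i], dtype=np.int64)
    if cand_arr.size == 0:
        return cand_arr
    dist = np.linalg.norm(coords[cand_arr] - coords[i], axis=1)
    return cand_arr[dist <= radius]


def alignment_lddt(q_coords: np.ndarray, t_coords: np.ndarray,
                   alignment: list[tuple[int, int]],
                   params: LddtParams = LddtParams()
                   ) -> tuple[np.ndarray, float]:
    """Per-residue LDDT scores for the aligned query residues and their mean.

    ``alignment`` maps query residue indices to target residue indices.
    Returns one score per alignment pair (NaN when a residue has no
    neighbors to judge it by) and the mean of the defined scores.
    """
    if len(alignment) == 0:
        raise ValueError("undefined LDDT: empty alignment")
    q_coords = np.asarray(q_coords, float)
    t_coords = np.asarray(t_coords, float)
    q_idx = np.array([a for a, _ in alignment], dtype=np.int64)
    t_of_q = {a: b for a, b in alignment}
    cell = params.radius
    cells = _grid_cells(q_coords, cell)
    thr = np.array(params.thresholds)
    per_residue = np.full(len(alignment), np.nan)
    for row, i in enumerate(q_idx):
        neigh = _neighbors_within(int(i), q_coords, cells, cell, params.radius)
        if neigh.size == 0:
            continue
        aligned_mask = np.array([j in t_of_q for j in neigh])
        aligned = neigh[aligned_mask]
        score_sum = 0.0
        if aligned.size:
            dq = np.linalg.norm(q_coords[aligned] - q_coords[i], axis=1)
            tj = np.array([t_of_q[int(j)] for j in aligned])
            dt = np.linalg.norm(t_coords[tj] - t_coords[t_of_q[int(i)]], axis=1)
            d = np.abs(dq - dt)
            score_sum = float((d[:, None] < thr[None, :]).mean(axis=1).sum())
        if params.denominator_mode == "aligned_neighbors":
            if aligned.size == 0:
                continue
            per_residue[row] = score_sum / aligned.size
        else:
            per_residue[row] = score_sum / neigh.size
    defined = ~np.isnan(per_residue)
    if not defined.any():
        raise ValueError("undefined LDDT: no residue has scoreable neighbors")
    return per_residue, float(per_residue[defined].mean())


# ---------------------------------------------------------------------------
# TM-score on a fixed alignment
# ---------------------------------------------------------------------------

def tm_d0(L: int) -> float:
    """Length-dependent distance scale, clamped below at 0.5 A."""
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with ``R P + t ~ Q``."""
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


_REFINE_CUTOFFS = (8.0, 6.0, 4.5, 3.5)


def _tm_sum(dist: np.ndarray, L_norm: int) -> float:
    d0 = tm_d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (dist / d0) ** 2)) / L_norm)


def tm_score(q_coords: np.ndarray, t_coords: np.ndarray,
             alignment: list[tuple[int, int]],
             normalize_by: str = "both") -> tuple[float, float, float]:
    """TM-score of a fixed alignment via fragment-seeded superposition.

    Seeds Kabsch fits from aligned fragments of length n, n/2 and n/4,
    refines each by iterating inclusion of pairs within a shrinking
    distance cutoff to a fixed point, and keeps the best score.  Returns
    ``(tm_query, tm_target, tm_avg)`` — normalized by query length, target
    length and their average respectively.
    """
    if len(alignment) < 3:
        raise ValueError("TM-score needs at least 3 aligned pairs")
    if normalize_by not in ("query", "target", "both"):
        raise ValueError(f"unknown normalization {normalize_by!r}")
    q_coords = np.asarray(q_coords, float)
    t_coords = np.asarray(t_coords, float)
    qi = np.array([a for a, _ in alignment])
    ti = np.array([b for _, b in alignment])
    P = q_coords[qi]
    Q = t_coords[ti]
    n = len(P)
    Lq, Lt = len(q_coords), len(t_coords)
    best_q, best_t = 0.0, 0.0
    frag_lengths = sorted({n, max(3, n // 2), max(3, n // 4)}, reverse=True)
    for frag in frag_lengths:
        step = max(1, frag // 2)
        for start in range(0, n - frag + 1, step):
            sel = np.arange(start, start + frag)
            for _ in range(40):  # refine to a fixed point
                R, t = kabsch(P[sel], Q[sel])
                dist = np.linalg.norm((P @ R.T + t) - Q, axis=1)
                # every intermediate superposition competes; the best one
                # is kept even if later refinement drifts (outliers can
                # re-enter through the inclusion cutoff)
                best_q = max(best_q, _tm_sum(dist, Lq))
                best_t = max(best_t, _tm_sum(dist, Lt))
                new_sel = sel
                for cutoff in _REFINE_CUTOFFS:
                    inc = np.nonzero(dist < cutoff)[0]
                    if inc.size >= 3:
                        new_sel = inc
                        break
                if np.array_equal(new_sel, sel):
                    break
                sel = new_sel
    return best_q, best_t, (best_q + best_t) / 2.0


def structural_bit_score(corrected_bits: float, tm_avg: float,
                         lddt_mean: float) -> float:
    """Bit score scaled by the geometric mean of TM-score and mean LDDT."""
    if tm_avg < 0 or lddt_mean < 0:
        raise ValueError("TM-score and LDDT must be non-negative")
    return corrected_bits * float(np.sqrt(tm_avg * lddt_mean))
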