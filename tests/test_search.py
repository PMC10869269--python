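"""Prefilter, similar k-mers, bias correction and local alignment."""

import itertools

import numpy as np
import pytest

import foldscan as fs
from foldscan.structure_io import DatabaseEntry
from foldscan.search import (AlignmentParams, PrefilterParams, _self_score,
                             build_kmer_index, combined_score_matrix,
                             composition_bias_correction, make_search_index,
                             prefilter, similar_kmers, smith_waterman)
from foldscan.substitution import SubstitutionCounts, estimate_matrix

LETTERS = "ABCDEFGHIJKLMNOPQRST"


def _random_matrix(seed, n=20):
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.5, 30, size=(n, n))
    counts = raw + raw.T + np.diag(rng.uniform(50, 200, size=n))
    return estimate_matrix(SubstitutionCounts(counts, 1.0, LETTERS[:n]))


def _entry(eid, tdi, aa=None):
    L = len(tdi)
    ca = np.stack([np.arange(L) * 3.8, np.zeros(L), np.zeros(L)], axis=1)
    return DatabaseEntry(eid, aa or ("A" * L), tdi, ca)


class TestKmerIndex:
    def test_window_count(self):
        idx = build_kmer_index([_entry("t", "AAAAAAA")], PrefilterParams(k=6))
        assert idx == {"AAAAAA": [("t", 0), ("t", 1)]}

    def test_short_target_yields_nothing(self):
        assert build_kmer_index([_entry("t", "ABC")], PrefilterParams(k=6)) == {}

    def test_window_with_unknown_skipped(self):
        idx = build_kmer_index([_entry("t", "AAAXAAAAAA")], PrefilterParams(k=6))
        assert list(idx) == ["AAAAAA"]  # only the final clean window


class TestSimilarKmers:
    def test_self_threshold_includes_self(self, default_matrix):
        kmer = "ACF"
        out = similar_kmers(kmer, default_matrix, _self_score(kmer, default_matrix))
        assert kmer in out
        for w in out:
            s = sum(default_matrix.scores_int[default_matrix.index_of(a),
                                              default_matrix.index_of(b)]
                    for a, b in zip(kmer, w))
            assert s >= _self_score(kmer, default_matrix)

    def test_unbounded_threshold_enumerates_everything(self, default_matrix):
        out = similar_kmers("AB", default_matrix, -np.inf)
        assert len(out) == 400

    def test_matches_exhaustive_search_at_k3(self):
        matrix = _random_matrix(5)
        kmer = "DGA"
        self_s = _self_score(kmer, matrix)
        for threshold in (self_s - 2, self_s - 6, self_s - 10):
            got = similar_kmers(kmer, matrix, threshold)
            expect = set()
            for w in itertools.product(LETTERS, repeat=3):
                s = sum(matrix.scores_int[matrix.index_of(a), matrix.index_of(b)]
                        for a, b in zip(kmer, w))
                if s >= threshold:
                    expect.add("".join(w))
            assert got == expect

    def test_raising_threshold_shrinks_the_set(self, default_matrix):
        kmer = "AFC"
        self_s = _self_score(kmer, default_matrix)
        prev = None
        for threshold in (self_s - 12, self_s - 6, self_s - 2, self_s):
            cur = similar_kmers(kmer, default_matrix, threshold)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestCompositionBias:
    def test_uniform_sequence_correction_is_self_score(self, default_matrix):
        seq = "E" * 10
        offsets = composition_bias_correction(seq, default_matrix, window=40)
        e = default_matrix.index_of("E")
        np.testing.assert_allclose(offsets, -default_matrix.scores_int[e, e])

    def test_alternating_sequence_matches_windowed_mean_oracle(self, default_matrix):
        seq = ("AB" * 15)[:30]
        window = 8
        offsets = composition_bias_correction(seq, default_matrix, window=window)
        ext = default_matrix.extended_int().astype(float)
        for p in range(len(seq)):
            lo, hi = max(0, p - window // 2), min(len(seq), p + window // 2 + 1)
            neigh = [default_matrix.index_of(seq[q]) for q in range(lo, hi) if q != p]
            expect = -np.mean([ext[default_matrix.index_of(seq[p]), j] for j in neigh])
            assert offsets[p] == pytest.approx(expect)

    def test_window_larger_than_sequence_is_finite(self, default_matrix):
        offsets = composition_bias_correction("ABC", default_matrix, window=100)
        assert np.isfinite(offsets).all()


# ---------------------------------------------------------------------------
# textbook affine-gap Smith-Waterman oracle (quadratic space, pure python)
# ---------------------------------------------------------------------------

def _oracle_sw(S, gap_open, gap_extend):
    Lq, Lt = S.shape
    NEG = -1e30
    H = np.zeros((Lq + 1, Lt + 1))
    E = np.full((Lq + 1, Lt + 1), NEG)
    F = np.full((Lq + 1, Lt + 1), NEG)
    best = 0.0
    for i in range(1, Lq + 1):
        for j in range(1, Lt + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + S[i - 1, j - 1], E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _cigar_score(S, result, gap_open, gap_extend):
    """Re-score a reported alignment path directly from its cigar."""
    score = 0.0
    qi, ti = result[1], result[3]
    count = 0
    for ch in result[5]:
        if ch.isdigit():
            count = count * 10 + int(ch)
            continue
        if ch == "M":
            for s in range(count):
                score += S[qi + s, ti + s]
            qi += count
            ti += count
        else:
            score -= gap_open + (count - 1) * gap_extend
            if ch == "I":
                qi += count
            else:
                ti += count
        count = 0
    return score


class TestSmithWaterman:
    def test_matches_textbook_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            Lq, Lt = rng.integers(5, 35, size=2)
            S = rng.normal(loc=-1.0, scale=4.0, size=(Lq, Lt))
            go, ge = 11.0, 1.0
            result = smith_waterman(S, go, ge)
            assert result[0] == pytest.approx(_oracle_sw(S, go, ge), abs=1e-9)
            # the reported path achieves the reported score
            if result[5]:
                assert _cigar_score(S, result, go, ge) == pytest.approx(result[0])

    def test_all_negative_matrix_gives_empty_alignment(self):
        score, q0, q1, t0, t1, cigar = smith_waterman(np.full((4, 4), -5.0), 11, 1)
        assert score == 0.0 and cigar == ""


class TestAlignLocal:
    def test_self_alignment_score_equals_direct_sum(self, small_entries,
                                                    default_matrix):
        entry = small_entries[0]
        params = AlignmentParams(use_reverse_correction=False)
        aln = fs.align_local(entry, entry, default_matrix, params=params)
        S = combined_score_matrix(entry, entry, default_matrix, params=params)
        diag = np.diag(S)
        # identity path over the full positive-scoring stretch
        assert aln.raw_score == pytest.approx(_oracle_sw(S, 11, 1), abs=1e-9)
        assert aln.raw_score >= diag.sum() - 2 * np.abs(diag).max()
        assert aln.bit_score == pytest.approx(aln.raw_score / 2)

    def test_palindromic_query_has_zero_corrected_bits(self, default_matrix):
        tdi = "ABCDEFGFEDCBA"
        aa = "GALVWVLAGWVLG"[:len(tdi)]
        aa = aa[:6] + aa[6] + aa[:6][::-1]  # palindromic amino acids too
        query = _entry("pal", tdi, aa)
        target = _entry("t", "ABCDEFGHIJKLMNOPQRST")
        aln = fs.align_local(query, target, default_matrix)
        assert aln.corrected_bits == pytest.approx(0.0, abs=1e-9)

    def test_corrected_bits_bounded_by_forward_bits(self, small_entries,
                                                    default_matrix):
        q, t = small_entries[0], small_entries[1]
        aln = fs.align_local(q, t, default_matrix)
        assert aln.corrected_bits <= aln.bit_score + 1e-12

    def test_empty_sequence_raises(self, default_matrix):
        good = _entry("g", "ABCDEF")
        with pytest.raises(ValueError):
            fs.align_local(good, DatabaseEntry("e", "", "", np.zeros((0, 3))),
                           default_matrix)


# ---------------------------------------------------------------------------
# brute-force prefilter oracle
# ---------------------------------------------------------------------------

def _oracle_prefilter(query, targets, matrix, params, aln_params):
    """Explicit enumeration: all similar k-mers, all occurrences, all
    diagonals; ungapped best-segment score per double-match diagonal."""
    k = params.k
    hits = []
    for target in targets:
        diag_positions = {}
        for qpos in range(len(query.tdi_seq) - k + 1):
            word = query.tdi_seq[qpos:qpos + k]
            if "X" in word:
                continue
            thr = (params.kmer_sim_threshold if params.kmer_sim_threshold is not None
                   else _self_score(word, matrix) - params.kmer_sim_delta)
            sims = similar_kmers(word, matrix, thr)
            for tpos in range(len(target.tdi_seq) - k + 1):
                if target.tdi_seq[tpos:tpos + k] in sims:
                    diag_positions.setdefault(qpos - tpos, set()).add(qpos)
        doubles = [d for d, qs in diag_positions.items() if len(qs) >= 2]
        if not doubles:
            continue
        S = combined_score_matrix(query, target, matrix, params=aln_params)
        best_bits, best_diag = -np.inf, None
        for d in doubles:
            qs, ts = max(0, d), max(0, -d)
            n = min(S.shape[0] - qs, S.shape[1] - ts)
            run = best = 0.0
            for s in range(n):
                run = max(0.0, run + S[qs + s, ts + s])
                best = max(best, run)
            bits = best / 2.0
            if bits > best_bits:
                best_bits, best_diag = bits, d
        if best_bits >= params.ungapped_min_bits:
            hits.append((target.entry_id, best_diag, best_bits))
    hits.sort(key=lambda h: (-h[2], h[0]))
    return hits


class TestPrefilter:
    def test_self_match_reported_on_diagonal_zero(self, small_entries,
                                                  default_matrix):
        query = small_entries[0]
        index = make_search_index(small_entries)
        hits = prefilter(query, index, default_matrix)
        me = [h for h in hits if h.target_id == query.entry_id]
        assert me and me[0].diagonal == 0

    def test_single_isolated_kmer_match_not_reported(self, default_matrix):
        rng = np.random.default_rng(0)
        shared = "ACDEFG"
        query = _entry("q", shared + "".join(rng.choice(list(LETTERS), size=20)))
        # target shares exactly one k-mer at a different position
        target = _entry("t", "".join(rng.choice(list("MNOPQR"), size=15)) + shared)
        params = PrefilterParams(kmer_sim_threshold=_self_score(shared, default_matrix))
        index = make_search_index([target], params)
        hits = prefilter(query, index, default_matrix, params)
        assert hits == []

    def test_equals_brute_force_on_fixture_database(self, default_matrix):
        """Hit set, diagonals and ungapped bits all match the explicit
        enumeration oracle on a 50-entry database."""
        fam = fs.make_family(fs.SyntheticFamilySpec(n_families=8,
                                                    members_per_family=5,
                                                    n_decoys=10, seed=23))
        entries = fs.make_entries(fam.chains, fs.default_alphabet())
        assert len(entries) == 50
        params = PrefilterParams()
        aln_params = AlignmentParams()
        index = make_search_index(entries, params)
        queries = entries[::10]  # five queries across families
        for query in queries:
            got = [(h.target_id, h.diagonal, h.ungapped_bits)
                   for h in prefilter(query, index, default_matrix, params, aln_params)]
            expect = _oracle_prefilter(query, entries, default_matrix, params, aln_params)
            assert [(t, d) for t, d, _ in got] == [(t, d) for t, d, _ in expect]
            np.testing.assert_allclose([b for _, _, b in got],
                                       [b for _, _, b in expect], atol=1e-9)

    def test_query_shorter_than_k_warns_and_returns_empty(self, small_entries,
                                                          default_matrix):
        short = _entry("s", "ABC")
        index = make_search_index(small_entries)
        with pytest.warns(UserWarning):
            assert prefilter(short, index, default_matrix) == []


def test_prefilter_recall_on_families(small_family_set, small_entries, default_matrix):
    """Targets whose corrected alignment scores >= 30 bits are recovered by
    the prefilter at default thresholds (>= 90%)."""
    index = make_search_index(small_entries)
    recovered = total = 0
    for query in small_entries:
        hits = {h.target_id for h in prefilter(query, index, default_matrix)}
        for target in small_entries:
            if target.entry_id == query.entry_id:
                continue
            if fs.align_local(query, target, default_matrix).corrected_bits >= 30:
                total += 1
                recovered += target.entry_id in hits
    assert total > 0
    assert recovered / total >= 0.9
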