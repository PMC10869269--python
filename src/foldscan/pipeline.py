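"""End-to-end drivers: encode structures, train an alphabet from aligned
families, and run the full prefilter -> align -> score -> calibrate search.

These are thin orchestration layers over the per-stage modules; every
stage can also be driven directly (see examples/).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import calibration, evaluation, scoring
from .alphabet import (Alphabet3Di, PairFilterParams, ValidationBenchmark, VqvaeConfig,
                       build_training_pairs, encode_structure, select_best_alphabet,
                       train_vqvae)
from .chain import Chain
from .fixtures import FamilySet
from .geometry import VirtualCenterParams
from .scoring import LddtParams
from .search import (AlignmentParams, AlignmentResult, PrefilterParams, align_local,
                     make_search_index, prefilter)
from .structure_io import DatabaseEntry, reconstruct_cbeta
from .substitution import SubstitutionMatrix, matrix_from_encoded_alignments

_DATA_DIR = Path(__file__).parent / "data"


def default_alphabet() -> Alphabet3Di:
    """The alphabet shipped with the package (trained on synthetic families)."""
    return Alphabet3Di.load(_DATA_DIR / "default_alphabet.json")


def default_substitution_matrix() -> SubstitutionMatrix:
    """Substitution matrix matching :func:`default_alphabet`."""
    return SubstitutionMatrix.load(_DATA_DIR / "default_substitution.mat")


@dataclass
class MatchRecord:
    """One query-target hit with all similarity statistics."""

    alignment: AlignmentResult
    lddt_mean: float
    lddt_per_residue: np.ndarray
    tm_query: float
    tm_target: float
    tm_avg: float
    structural_bits: float
    evalue: float = np.nan
    prob_tp: float = np.nan

    @property
    def query_id(self) -> str:
        return self.alignment.query_id

    @property
    def target_id(self) -> str:
        return self.alignment.target_id


def make_entry(chain: Chain, alphabet: Alphabet3Di,
               vc_params: VirtualCenterParams = VirtualCenterParams(),
               entry_id: str | None = None) -> DatabaseEntry:
    """Chain -> database entry: CB reconstruction + state encoding."""
    chain = reconstruct_cbeta(chain)
    tdi = encode_structure(chain, alphabet, vc_params)
    return DatabaseEntry(entry_id or chain.chain_id, chain.aa, tdi, chain.ca,
                         source=chain.source)


def make_entries(chains: dict[str, Chain] | list[Chain], alphabet: Alphabet3Di,
                 vc_params: VirtualCenterParams = VirtualCenterParams()
                 ) -> list[DatabaseEntry]:
    items = chains.items() if isinstance(chains, dict) else [(c.chain_id, c) for c in chains]
    return [make_entry(chain, alphabet, vc_params, entry_id=eid) for eid, chain in items]


@dataclass
class SearchConfig:
    prefilter: PrefilterParams = field(default_factory=PrefilterParams)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    lddt: LddtParams = field(default_factory=LddtParams)
    max_evalue: float | None = None
    min_corrected_bits: float = 0.0


def score_match(query: DatabaseEntry, target: DatabaseEntry,
                aln: AlignmentResult, lddt_params: LddtParams = LddtParams()
                ) -> MatchRecord:
    """Attach LDDT, TM-score and the structural bit score to an alignment."""
    pairs = aln.aligned_pairs()
    per_res, lddt_mean = scoring.alignment_lddt(query.ca_coords, target.ca_coords,
                                                pairs, lddt_params)
    if len(pairs) >= 3:
        tm_q, tm_t, tm_avg = scoring.tm_score(query.ca_coords, target.ca_coords, pairs)
    else:
        tm_q = tm_t = tm_avg = 0.0
    bits = max(aln.corrected_bits, 0.0)
    sbits = scoring.structural_bit_score(bits, tm_avg, lddt_mean)
    return MatchRecord(alignment=aln, lddt_mean=lddt_mean, lddt_per_residue=per_res,
                       tm_query=tm_q, tm_target=tm_t, tm_avg=tm_avg,
                       structural_bits=sbits)


def search_database(queries: list[DatabaseEntry], targets: list[DatabaseEntry],
                    tdi_matrix: SubstitutionMatrix,
                    config: SearchConfig | None = None,
                    evalue_model: calibration.EvalueModel | None = None,
                    mixtures: calibration.GammaMixturePair | None = None,
                    skip_prefilter: bool = False,
                    ) -> dict[str, list[MatchRecord]]:
    """Full search of every query against the target set.

    Hits per query are sorted by structural bit score (descending), then
    E-value (ascending), then target id.  With ``skip_prefilter`` every
    target is aligned (forced-alignment mode for quality benchmarks).
    """
    config = config or SearchConfig()
    index = None if skip_prefilter else make_search_index(targets, config.prefilter)
    target_by_id = {t.entry_id: t for t in targets}
    results: dict[str, list[MatchRecord]] = {}
    for query in queries:
        if skip_prefilter:
            candidate_ids = [t.entry_id for t in targets]
        else:
            hits = prefilter(query, index, tdi_matrix, config.prefilter,
                             config.alignment)
            candidate_ids = [h.target_id for h in hits]
        records = []
        for target_id in candidate_ids:
            target = target_by_id[target_id]
            aln = align_local(query, target, tdi_matrix, params=config.alignment)
            if not aln.cigar or aln.corrected_bits <= config.min_corrected_bits:
                continue
            try:
                rec = score_match(query, target, aln, config.lddt)
            except ValueError:  # no scoreable residue pair
                continue
            if evalue_model is not None:
                # E-values are calibrated on forward (uncorrected) bit scores,
                # so they are applied to the forward score as well; the
                # reverse-corrected score feeds the ranking statistic instead
                feats = calibration.query_features(query, tdi_matrix.letters)
                rec.evalue = calibration.evalue(evalue_model, feats,
                                                aln.bit_score, len(targets))
                if config.max_evalue is not None and rec.evalue > config.max_evalue:
                    continue
            if mixtures is not None:
                rec.prob_tp = calibration.p_tp(rec.structural_bits, mixtures)
            records.append(rec)
        records.sort(key=lambda r: (-r.structural_bits,
                                    r.evalue if np.isfinite(r.evalue) else 0.0,
                                    r.target_id))
        results[query.entry_id] = records
    return results


def calibration_query_set(alphabet: Alphabet3Di, n_queries: int = 110,
                          seed: int = 5,
                          vc_params: VirtualCenterParams = VirtualCenterParams()
                          ) -> list[DatabaseEntry]:
    """Variable-length synthetic queries for E-value calibration.

    The (mu, lambda) regression needs length and composition variation, so
    chains are drawn with random element plans between roughly 10 and 90
    residues.
    """
    from .fixtures import make_chain

    rng = np.random.default_rng(seed)
    kinds = ("helix", "strand", "coil")
    chains = []
    for i in range(n_queries):
        n_elements = int(rng.integers(2, 7))
        plan = tuple((kinds[rng.integers(0, 3)], int(rng.integers(5, 16)))
                     for _ in range(n_elements))
        chains.append(make_chain(plan, seed=int(rng.integers(0, 2 ** 31 - 1)),
                                 chain_id=f"cal{i:03d}"))
    return make_entries(chains, alphabet, vc_params)


def scrambled_raw_evalues(model: calibration.EvalueModel,
                          targets: list[DatabaseEntry],
                          tdi_matrix: SubstitutionMatrix,
                          n_scrambled: int = 20, seed: int = 0,
                          aln_params: AlignmentParams | None = None
                          ) -> list[np.ndarray]:
    """Raw (uncorrected) E-values of scrambled queries against the targets.

    Each scrambled query is a permuted copy of a target entry; every target
    is aligned (forward score, no prefilter) and converted to a raw E-value
    with the model's predicted Gumbel parameters.
    """
    rng = np.random.default_rng(seed)
    params = replace(aln_params or AlignmentParams(), use_reverse_correction=False)
    picks = rng.choice(len(targets), size=min(n_scrambled, len(targets)), replace=False)
    out = []
    for p in picks:
        query = calibration.shuffle_entry(targets[p], rng)
        mu, lam = model.predict(calibration.query_features(query, tdi_matrix.letters))
        es = [calibration.evalue_from_params(
                  mu, lam, align_local(query, t, tdi_matrix, params=params).bit_score,
                  len(targets))
              for t in targets]
        out.append(np.array(es))
    return out


def calibrate_search_correction(model: calibration.EvalueModel,
                                targets: list[DatabaseEntry],
                                tdi_matrix: SubstitutionMatrix,
                                n_scrambled: int = 20, seed: int = 0
                                ) -> calibration.EvalueModel:
    """Re-estimate the E-value correction on a scrambled search against the
    actual target set and return an updated model."""
    raw = scrambled_raw_evalues(model, targets, tdi_matrix, n_scrambled, seed)
    exponent, scale = calibration.fit_evalue_correction(raw)
    return replace(model, correction_exponent=exponent, correction_scale=scale)


# ---------------------------------------------------------------------------
# alphabet training from a labeled family set
# ---------------------------------------------------------------------------

def family_training_alignments(families: FamilySet,
                               ) -> list[tuple[Chain, Chain, list[tuple[int, int]], float]]:
    """Reference alignments of a family set with their TM-scores attached."""
    out = []
    for id_a, id_b, pairs in families.ref_alignments:
        chain_a, chain_b = families.chains[id_a], families.chains[id_b]
        tm = scoring.tm_score(chain_a.ca, chain_b.ca, pairs)[2]
        out.append((chain_a, chain_b, pairs, tm))
    return out


def matrix_for_alphabet(alphabet: Alphabet3Di, families: FamilySet,
                        vc_params: VirtualCenterParams = VirtualCenterParams(),
                        pseudocount: float = 1.0) -> SubstitutionMatrix:
    """Estimate a substitution matrix from the family reference alignments
    encoded with the given alphabet."""
    encoded = {eid: encode_structure(reconstruct_cbeta(chain), alphabet, vc_params)
               for eid, chain in families.chains.items()}
    letter_pairs = []
    for id_a, id_b, pairs in families.ref_alignments:
        sa, sb = encoded[id_a], encoded[id_b]
        letter_pairs.append(("".join(sa[i] for i, _ in pairs),
                             "".join(sb[j] for _, j in pairs)))
    return matrix_from_encoded_alignments(letter_pairs, pseudocount=pseudocount,
                                          letters=alphabet.letters)


def make_validation_benchmark(families: FamilySet,
                              vc_params: VirtualCenterParams = VirtualCenterParams(),
                              reference_auc: dict[str, float] | None = None
                              ) -> ValidationBenchmark:
    """Alignment-only all-vs-all benchmark for alphabet selection.

    Each candidate encodes the validation chains, a matrix is estimated
    from its encodings, every pair is aligned (no prefilter) and hits are
    ranked by corrected bits; the score per level is the mean ROC1
    sensitivity.  The reference AUC defaults to 1.0 per level, i.e. the
    selection criterion reduces to the summed AUCs.
    """
    reference_auc = reference_auc or {level: 1.0 for level in evaluation.LEVELS}

    def evaluate(alphabet: Alphabet3Di) -> dict[str, float]:
        matrix = matrix_for_alphabet(alphabet, families, vc_params)
        entries = make_entries(families.chains, alphabet, vc_params)
        ranked: dict[str, list[str]] = {}
        for query in entries:
            recs = []
            for target in entries:
                if target.entry_id == query.entry_id:
                    continue
                aln = align_local(query, target, matrix)
                recs.append((-aln.corrected_bits, target.entry_id))
            recs.sort()
            ranked[query.entry_id] = [tid for _, tid in recs]
        return {level: evaluation.roc1_sensitivity(ranked, families.labels, level)[1]
                for level in evaluation.LEVELS}

    return ValidationBenchmark(evaluate=evaluate, reference_auc=reference_auc)


def split_family_set(families: FamilySet, keep: set[str]) -> FamilySet:
    """Restrict a family set to the entries whose fold label is in ``keep``."""
    chains = {eid: ch for eid, ch in families.chains.items()
              if families.labels[eid][2] in keep}
    labels = {eid: families.labels[eid] for eid in chains}
    refs = [(a, b, pairs) for a, b, pairs in families.ref_alignments
            if a in chains and b in chains]
    return FamilySet(chains=chains, labels=labels, ref_alignments=refs)


def cross_validate_alphabet(families: FamilySet,
                            config: VqvaeConfig = VqvaeConfig(),
                            n_folds: int = 4,
                            vc_params: VirtualCenterParams = VirtualCenterParams()
                            ) -> list[dict]:
    """Fold-stratified cross-validation of alphabet training.

    The structural fold labels are split into ``n_folds`` parts (all
    domains of one fold stay together, so train and test never share a
    fold); an alphabet + matrix is trained on the training parts and
    scored on the held-out part by mean ROC1 sensitivity per level.
    Returns one result dict per part.
    """
    fold_labels = sorted({triple[2] for triple in families.labels.values()})
    if len(fold_labels) < n_folds:
        raise ValueError(f"{len(fold_labels)} folds cannot fill {n_folds} parts")
    parts = [set(fold_labels[p::n_folds]) for p in range(n_folds)]
    results = []
    for p, held_out in enumerate(parts):
        train_set = split_family_set(families, set(fold_labels) - held_out)
        test_set = split_family_set(families, held_out)
        alphabet, matrix = train_alphabet(train_set, config, vc_params=vc_params)
        # score held-out entries with the trained alphabet AND matrix (the
        # test set contributes nothing to either)
        entries = make_entries(test_set.chains, alphabet, vc_params)
        ranked: dict[str, list[str]] = {}
        for query in entries:
            scored = sorted(
                (-align_local(query, target, matrix).corrected_bits,
                 target.entry_id)
                for target in entries if target.entry_id != query.entry_id)
            ranked[query.entry_id] = [tid for _, tid in scored]
        aucs = {level: evaluation.roc1_sensitivity(ranked, test_set.labels, level)[1]
                for level in evaluation.LEVELS}
        results.append({"part": p, "held_out_folds": sorted(held_out), **aucs})
    return results


def train_alphabet(families: FamilySet,
                   config: VqvaeConfig = VqvaeConfig(),
                   filters: PairFilterParams = PairFilterParams(),
                   vc_params: VirtualCenterParams = VirtualCenterParams(),
                   benchmark: ValidationBenchmark | None = None
                   ) -> tuple[Alphabet3Di, SubstitutionMatrix]:
    """Train alphabet candidates on the family reference alignments and
    return the benchmark-selected alphabet with its substitution matrix."""
    aligned = family_training_alignments(families)
    pairs = build_training_pairs(aligned, filters, vc_params)
    candidates = [train_vqvae(pairs, replace(config, seed=config.seed + r))[0]
                  for r in range(config.n_restarts)]
    if len(candidates) == 1:
        best = candidates[0]
    else:
        benchmark = benchmark or make_validation_benchmark(families, vc_params)
        best = select_best_alphabet(candidates, benchmark)
    return best, matrix_for_alphabet(best, families, vc_params)
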