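"""Log-odds substitution matrix over structural states.

Estimated BLOSUM-style from counts of structurally aligned state pairs:
``S(x, y) = 2 log2 p(x, y) / (p(x) p(y))``, so the scores are in half-bit
units (bit score = raw score / 2).  An integer-rounded copy is used for
k-mer similarity generation and alignment scoring; the 'X' state scores 0
against everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import STATE_LETTERS, UNKNOWN


@dataclass
class SubstitutionCounts:
    counts: np.ndarray  # symmetric (A, A)
    pseudocount: float
    letters: str = STATE_LETTERS


@dataclass
class SubstitutionMatrix:
    """Symmetric scores with background frequencies and an 'X' extension."""

    scores: np.ndarray      # (A, A) real, half-bit units
    scores_int: np.ndarray  # nearest-integer rounding (ties to even)
    background: np.ndarray  # (A,) marginal state frequencies
    letters: str = STATE_LETTERS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.scores_int = np.asarray(self.scores_int)
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("substitution scores must be symmetric")

    @property
    def n_states(self) -> int:
        return len(self.letters)

    def index_of(self, letter: str) -> int:
        """Letter -> state index; 'X' maps to the extension index A."""
        if letter == UNKNOWN:
            return self.n_states
        idx = self.letters.find(letter)
        if idx < 0:
            raise KeyError(f"letter {letter!r} not in alphabet")
        return idx

    def encode(self, seq: str) -> np.ndarray:
        return np.array([self.index_of(ch) for ch in seq], dtype=np.int64)

    def extended_int(self) -> np.ndarray:
        """(A+1, A+1) integer matrix with the 'X' row/column set to 0."""
        A = self.n_states
        ext = np.zeros((A + 1, A + 1), dtype=np.int64)
        ext[:A, :A] = self.scores_int
        return ext

    def free_entries(self) -> int:
        """Independent entries of the symmetric core (upper triangle incl.
        diagonal)."""
        A = self.n_states
        return A * (A + 1) // 2

    # -- serialization (BLOSUM-style text) ---------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# structural-state substitution matrix, half-bit units\n")
            fh.write("# background " + " ".join(f"{p:.6g}" for p in self.background) + "\n")
            fh.write("  " + " ".join(self.letters) + "\n")
            for i, letter in enumerate(self.letters):
                row = " ".join(f"{int(v):3d}" for v in self.scores_int[i])
                fh.write(f"{letter} {row}\n")

    @classmethod
    def load(cls, path) -> "SubstitutionMatrix":
        background = None
        rows = []
        letters = ""
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# background"):
                    background = np.array([float(x) for x in line.split()[2:]])
                elif line.startswith("#") or not line.strip():
                    continue
                elif not letters:
                    letters = "".join(line.split())
                else:
                    parts = line.split()
                    rows.append([float(x) for x in parts[1:]])
        scores_int = np.array(rows, dtype=np.int64)
        if background is None:
            background = np.full(len(letters), 1.0 / len(letters))
        return cls(scores=scores_int.astype(float), scores_int=scores_int,
                   background=background, letters=letters)


def count_substitutions(encoded_pairs, pseudocount: float = 1.0,
                        letters: str = STATE_LETTERS) -> SubstitutionCounts:
    """Tally aligned state pairs into a symmetric count matrix.

    Each observation increments both (x, y) and (y, x) — the diagonal twice
    — so the marginals stay consistent.  Pairs containing 'X' are skipped;
    letters outside the alphabet raise.
    """
    A = len(letters)
    index = {ch: i for i, ch in enumerate(letters)}
    counts = np.full((A, A), float(pseudocount))
    for a, b in encoded_pairs:
        if a == UNKNOWN or b == UNKNOWN:
            continue
        try:
            i, j = index[a], index[b]
        except KeyError as exc:
            raise ValueError(f"unknown state letter in pair ({a!r}, {b!r})") from exc
        counts[i, j] += 1.0
        counts[j, i] += 1.0
    return SubstitutionCounts(counts=counts, pseudocount=pseudocount, letters=letters)


def estimate_matrix(counts: SubstitutionCounts) -> SubstitutionMatrix:
    """Normalize counts into joint/marginal frequencies and take log-odds."""
    c = np.asarray(counts.counts, float)
    total = c.sum()
    if total <= 0:
        raise ValueError("no counts to estimate from")
    if (c <= 0).any():
        raise ValueError("zero cells present; use a positive pseudocount")
    joint = c / total
    marginal = joint.sum(axis=1)
    scores = 2.0 * np.log2(joint / np.outer(marginal, marginal))
    scores = 0.5 * (scores + scores.T)  # exact symmetry despite fp rounding
    scores_int = np.rint(scores).astype(np.int64)  # numpy rint: ties to even
    return SubstitutionMatrix(scores=scores, scores_int=scores_int,
                              background=marginal, letters=counts.letters)


def matrix_from_encoded_alignments(pairs_of_strings, pseudocount: float = 1.0,
                                   letters: str = STATE_LETTERS) -> SubstitutionMatrix:
    """Convenience: aligned state-string pairs -> substitution matrix."""
    encoded = []
    for s1, s2 in pairs_of_strings:
        encoded.extend(zip(s1, s2))
    return estimate_matrix(count_substitutions(encoded, pseudocount, letters))


# ---------------------------------------------------------------------------
# amino-acid scoring companion (standard BLOSUM62, doubled to the half-bit
# raw scale shared with the structural matrix)
# ---------------------------------------------------------------------------

_AA_MATRIX_CACHE: SubstitutionMatrix | None = None


def amino_acid_matrix() -> SubstitutionMatrix:
    """BLOSUM62 over the 20 amino acids, doubled into half-bit raw units,
    with 'X' neutral (score 0)."""
    global _AA_MATRIX_CACHE
    if _AA_MATRIX_CACHE is None:
        from biotite.sequence.align import SubstitutionMatrix as BiotiteMatrix

        from .chain import AA_ALPHABET

        blosum = BiotiteMatrix.std_protein_matrix()
        alph = blosum.get_alphabet1()
        order = [alph.encode(ch) for ch in AA_ALPHABET]
        raw = np.asarray(blosum.score_matrix())[np.ix_(order, order)]
        doubled = 2 * raw.astype(np.int64)
        _AA_MATRIX_CACHE = SubstitutionMatrix(
            scores=doubled.astype(float), scores_int=doubled,
            background=np.full(len(AA_ALPHABET), 1.0 / len(AA_ALPHABET)),
            letters=AA_ALPHABET)
    return _AA_MATRIX_CACHE
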