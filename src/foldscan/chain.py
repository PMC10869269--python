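"""Per-chain backbone container.

A :class:`Chain` stores, for one polymer chain, the one-letter amino-acid
sequence and the backbone coordinates (N, CA, C, CB) as ``(L, 3)`` float
arrays in Angstrom.  Missing atoms are NaN rows; every residue is guaranteed
to have a CA.  Residues are renumbered consecutively 1..L after parsing, and
all sequence-distance features downstream use this renumbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical one-letter amino-acid alphabet; 'X' = unknown
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CA_CB_BOND = 1.53  # Angstrom, the CA-CB bond length


@dataclass
class Chain:
    """Backbone record for one polymer chain.

    Parameters
    ----------
    chain_id:
        Author chain identifier.
    aa:
        One-letter sequence of length L over the 20 amino acids plus 'X'.
    n, ca, c, cb:
        ``(L, 3)`` coordinate arrays in Angstrom; NaN rows mark absent atoms.
        ``ca`` must be fully populated.
    """

    chain_id: str
    aa: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    cb: np.ndarray
    source: str = field(default="")

    def __post_init__(self) -> None:
        L = len(self.aa)
        for name in ("n", "ca", "c", "cb"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (L, 3):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({L}, 3)")
            setattr(self, name, arr)
        if L < 1:
            raise ValueError("chain must contain at least one residue")
        if np.isnan(self.ca).any():
            raise ValueError("every residue must have a CA coordinate")

    def __len__(self) -> int:
        return len(self.aa)

    def has_atom(self, which: str) -> np.ndarray:
        """Boolean mask of residues possessing the given backbone atom."""
        return ~np.isnan(getattr(self, which)).any(axis=1)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Chain":
        """Return a rigidly moved copy (``x -> R x + t``); NaNs stay NaN."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def mv(a: np.ndarray) -> np.ndarray:
            return a @ R.T + t

        return Chain(self.chain_id, self.aa, mv(self.n), mv(self.ca), mv(self.c),
                     mv(self.cb), source=self.source)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, self.aa, self.n.copy(), self.ca.copy(),
                     self.c.copy(), self.cb.copy(), source=self.source)
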