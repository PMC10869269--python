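"""Regenerate the packaged default alphabet and substitution matrix.

Trains the structural alphabet on the default synthetic family set
(seed 42, 8 families x 5 members, 10 decoys, three restarts with
benchmark selection) and writes the result into src/foldscan/data/ so
that searches work out of the box.

Run from the repository root:  python scripts/train_default_alphabet.py
"""

from pathlib import Path

from foldscan.alphabet import VqvaeConfig
from foldscan.fixtures import SyntheticFamilySpec, make_family
from foldscan.pipeline import train_alphabet

DATA_DIR = Path(__file__).resolve().parent.parent / "src" / "foldscan" / "data"
SEED = 42


def main() -> None:
    families = make_family(SyntheticFamilySpec(seed=SEED, n_decoys=10))
    alphabet, matrix = train_alphabet(families, VqvaeConfig(n_restarts=3, seed=SEED))
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    alphabet.save(DATA_DIR / "default_alphabet.json")
    matrix.save(DATA_DIR / "default_substitution.mat")
    print(f"wrote {DATA_DIR / 'default_alphabet.json'}")
    print(f"wrote {DATA_DIR / 'default_substitution.mat'}")
    print("matrix diagonal:", matrix.scores_int.diagonal().tolist())


if __name__ == "__main__":
    main()
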