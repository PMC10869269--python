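"""Structure parsing, CB reconstruction and the on-disk entry database.

Parsing is delegated to gemmi (PDB and mmCIF).  Each polymer chain becomes
one :class:`~foldscan.chain.Chain`; residues without a CA atom are dropped
with a warning and the survivors are renumbered consecutively.

The database stores, per entry, the amino-acid sequence, the structural
(3Di-style) state sequence and the CA trace.  CA coordinates are optionally
delta-compressed: the first coordinate is kept as three 4-byte floats and
every subsequent coordinate as 2-byte signed integer differences in
fixed-point units of 0.01 Angstrom.  If any step overflows the 2-byte range
the whole entry falls back to plain 4-byte floats, so the roundtrip is
lossless up to the declared fixed-point resolution.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .chain import AA_ALPHABET, CA_CB_BOND, Chain

#: fixed-point unit for 2-byte CA deltas (Angstrom per integer step)
DELTA_RESOLUTION = 0.01

_TETRA_COS = np.sqrt(1.0 / 3.0)  # cos of the half-angle of a regular tetrahedron
_TETRA_SIN = np.sqrt(2.0 / 3.0)


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when no chain contributes a single CA atom."""


class DatabaseIOError(IOError):
    """Raised on corrupt or truncated database files."""


@dataclass
class DatabaseEntry:
    """One searchable entry: sequences plus the CA trace."""

    entry_id: str
    aa_seq: str
    tdi_seq: str
    ca_coords: np.ndarray
    compressed: bool = False
    source: str = field(default="")

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=np.float64).reshape(-1, 3)
        if not (len(self.aa_seq) == len(self.tdi_seq) == len(self.ca_coords)):
            raise ValueError(
                f"entry {self.entry_id}: sequence/coordinate lengths differ "
                f"({len(self.aa_seq)}/{len(self.tdi_seq)}/{len(self.ca_coords)})"
            )

    def __len__(self) -> int:
        return len(self.aa_seq)


def _residue_one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        letter = info.one_letter_code.upper()
        if letter in AA_ALPHABET:
            return letter
    return "X"


def _pick_altloc(atoms) -> "gemmi.Atom | None":
    """Highest occupancy wins; first in file order on ties."""
    best = None
    for atom in atoms:
        if best is None or atom.occ > best.occ + 1e-9:
            best = atom
    return best


def _load_gemmi_structure(source, fmt: str) -> gemmi.Structure:
    text: str | None = None
    if isinstance(source, Path):
        path = str(source)
    elif isinstance(source, str) and "\n" in source:
        text = source
        path = None
    else:
        path = str(source)
    try:
        if fmt == "pdb":
            if text is not None:
                return gemmi.read_pdb_string(text)
            return gemmi.read_pdb(path)
        elif fmt == "mmcif":
            if text is not None:
                doc = gemmi.cif.read_string(text)
            else:
                doc = gemmi.cif.read(path)
            return gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise StructureFormatError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse structure: {exc}") from exc


def parse_structure(source, format: str = "pdb") -> list[Chain]:
    """Parse a PDB or mmCIF file (path or text) into per-chain records.

    Only the first model of multi-model files is used.  Alternate locations
    are resolved to the highest-occupancy atom (first on ties), residues
    lacking a CA are dropped with a warning, and the remaining residues are
    renumbered 1..L in file order (insertion codes respected through gemmi's
    ordering).
    """
    st = _load_gemmi_structure(source, format)
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError("structure contains no models")
    model = st[0]
    src = st.name or ""
    chains: list[Chain] = []
    for gchain in model:
        aa: list[str] = []
        coords = {k: [] for k in ("n", "ca", "c", "cb")}
        n_dropped = 0
        for res in gchain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and not info.is_amino_acid():
                continue  # waters, ligands, nucleic acids
            atom_map = {}
            for name in ("N", "CA", "C", "CB"):
                group = [a for a in res if a.name == name]
                atom = _pick_altloc(group)
                if atom is not None:
                    atom_map[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if "CA" not in atom_map:
                n_dropped += 1
                continue
            aa.append(_residue_one_letter(res.name))
            for key, name in (("n", "N"), ("ca", "CA"), ("c", "C"), ("cb", "CB")):
                coords[key].append(atom_map.get(name, np.full(3, np.nan)))
        if n_dropped:
            warnings.warn(
                f"chain {gchain.name}: dropped {n_dropped} residue(s) without CA",
                stacklevel=2,
            )
        if not aa:
            continue
        chains.append(
            Chain(
                chain_id=gchain.name,
                aa="".join(aa),
                n=np.array(coords["n"]),
                ca=np.array(coords["ca"]),
                c=np.array(coords["c"]),
                cb=np.array(coords["cb"]),
                source=src,
            )
        )
    if not chains:
        raise EmptyStructureError("no chain with at least one CA atom")
    return chains


def tetrahedral_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                      bond_length: float = CA_CB_BOND) -> np.ndarray:
    """Place CB at the fourth vertex of a regular tetrahedron around CA.

    The N and C directions fix two vertices; of the two remaining vertex
    directions the one matching L-amino-acid chirality is returned, at the
    canonical CA-CB bond length.
    """
    u_n = n - ca
    u_c = c - ca
    u_n = u_n / np.linalg.norm(u_n)
    u_c = u_c / np.linalg.norm(u_c)
    bisector = u_n + u_c
    norm = np.linalg.norm(bisector)
    perp = np.cross(u_n, u_c)
    perp_norm = np.linalg.norm(perp)
    if norm < 1e-8 or perp_norm < 1e-8:
        raise ValueError("degenerate N/CA/C geometry for CB placement")
    direction = -_TETRA_COS * (bisector / norm) + _TETRA_SIN * (perp / perp_norm)
    return ca + bond_length * direction


def reconstruct_cbeta(chain: Chain) -> Chain:
    """Fill in missing CB atoms by ideal tetrahedral placement.

    Residues with an existing CB are untouched (the operation is idempotent).
    Residues missing N or C as well stay CB-less; downstream encoding assigns
    them the unknown state.
    """
    out = chain.copy()
    missing = ~chain.has_atom("cb")
    can_fix = missing & chain.has_atom("n") & chain.has_atom("c")
    for i in np.nonzero(can_fix)[0]:
        out.cb[i] = tetrahedral_cbeta(chain.n[i], chain.ca[i], chain.c[i])
    return out


_AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_pdb(chain: Chain, path, chain_id: str | None = None) -> None:
    """Write a chain's backbone as a minimal PDB file."""
    cid = (chain_id or chain.chain_id or "A")[:1]
    serial = 1
    lines = []
    for i in range(len(chain)):
        resname = _AA_THREE.get(chain.aa[i], "UNK")
        for name, key, elem in (("N", "n", "N"), ("CA", "ca", "C"),
                                ("C", "c", "C"), ("CB", "cb", "C")):
            xyz = getattr(chain, key)[i]
            if np.isnan(xyz).any():
                continue
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {cid}{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           {elem}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# on-disk database: <path>.dat (records) + <path>.index (TSV) + <path>.lookup
# ---------------------------------------------------------------------------

_MAGIC = b"FSDB"
_INT16_MAX = 32767


def _encode_entry(entry: DatabaseEntry, compress: bool) -> bytes:
    L = len(entry)
    ca = entry.ca_coords
    payload_compressed = False
    coord_blob = b""
    if compress and L >= 1:
        deltas = np.diff(ca, axis=0) / DELTA_RESOLUTION
        quant = np.rint(deltas).astype(np.int64)
        if L == 1 or np.abs(quant).max(initial=0) <= _INT16_MAX:
            payload_compressed = True
            coord_blob = ca[0].astype("<f4").tobytes()
            coord_blob += quant.astype("<i2").tobytes()
    if not payload_compressed:
        coord_blob = ca.astype("<f4").tobytes()
    head = struct.pack("<BI", int(payload_compressed), L)
    return head + entry.aa_seq.encode() + entry.tdi_seq.encode() + coord_blob


def _decode_entry(entry_id: str, blob: bytes, source: str = "") -> DatabaseEntry:
    try:
        compressed, L = struct.unpack_from("<BI", blob, 0)
        off = struct.calcsize("<BI")
        aa_seq = blob[off:off + L].decode()
        off += L
        tdi_seq = blob[off:off + L].decode()
        off += L
        if compressed:
            first = np.frombuffer(blob, dtype="<f4", count=3, offset=off).astype(np.float64)
            off += 12
            deltas = np.frombuffer(blob, dtype="<i2", count=3 * (L - 1), offset=off)
            steps = deltas.reshape(L - 1, 3).astype(np.float64) * DELTA_RESOLUTION
            ca = np.vstack([first, first + np.cumsum(steps, axis=0)]) if L > 1 else first[None]
        else:
            ca = np.frombuffer(blob, dtype="<f4", count=3 * L, offset=off)
            ca = ca.reshape(L, 3).astype(np.float64)
        if len(aa_seq) != L or len(tdi_seq) != L:
            raise ValueError("truncated sequence payload")
    except (struct.error, ValueError, UnicodeDecodeError) as exc:
        raise DatabaseIOError(f"corrupt database record for entry {entry_id!r}: {exc}") from exc
    return DatabaseEntry(entry_id, aa_seq, tdi_seq, ca, compressed=bool(compressed),
                         source=source)


def write_database(entries: list[DatabaseEntry], path, compress: bool = True) -> None:
    """Write entries to ``<path>.dat`` / ``<path>.index`` / ``<path>.lookup``.

    The index is a TSV of (entry id, offset, length); the lookup TSV maps
    entry ids back to their source file/chain.  The data file header records
    the fixed-point resolution of the delta compression.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = _MAGIC + json.dumps({"delta_resolution": DELTA_RESOLUTION}).encode() + b"\n"
    index_rows = []
    lookup_rows = []
    with open(path.with_suffix(".dat"), "wb") as fh:
        fh.write(header)
        offset = fh.tell()
        for entry in entries:
            blob = _encode_entry(entry, compress)
            fh.write(blob)
            index_rows.append((entry.entry_id, offset, len(blob)))
            lookup_rows.append((entry.entry_id, entry.source))
            offset += len(blob)
    with open(path.with_suffix(".index"), "w") as fh:
        for entry_id, off, length in index_rows:
            fh.write(f"{entry_id}\t{off}\t{length}\n")
    with open(path.with_suffix(".lookup"), "w") as fh:
        for entry_id, src in lookup_rows:
            fh.write(f"{entry_id}\t{src}\n")


def read_database(path) -> list[DatabaseEntry]:
    """Read back a database written by :func:`write_database`."""
    path = Path(path)
    dat_path = path.with_suffix(".dat")
    try:
        data = dat_path.read_bytes()
    except OSError as exc:
        raise DatabaseIOError(f"cannot read {dat_path}: {exc}") from exc
    if not data.startswith(_MAGIC):
        raise DatabaseIOError(f"{dat_path} is not a foldscan database")
    lookup: dict[str, str] = {}
    lookup_path = path.with_suffix(".lookup")
    if lookup_path.exists():
        for line in lookup_path.read_text().splitlines():
            if line:
                entry_id, _, src = line.partition("\t")
                lookup[entry_id] = src
    entries = []
    for line in path.with_suffix(".index").read_text().splitlines():
        if not line:
            continue
        entry_id, off_s, len_s = line.split("\t")
        off, length = int(off_s), int(len_s)
        blob = data[off:off + length]
        if len(blob) != length:
            raise DatabaseIOError(f"truncated record for entry {entry_id!r}")
        entries.append(_decode_entry(entry_id, blob, source=lookup.get(entry_id, "")))
    return entries
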