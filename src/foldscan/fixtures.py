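"""Synthetic protein structures and labeled homolog families.

Chains are assembled from ideal secondary-structure elements — alpha
helices (1.5 A rise, 100 deg twist per residue), extended strands
(~3.4 A translation per residue with an alternating pleat) and seeded
random coils — connected without steric clashes.  A full N/CA/C/CB
backbone is derived from the CA trace with standard bond geometry, so
every downstream stage (virtual centers, descriptors, encoding, search)
runs on these fixtures exactly as it would on parsed structures.

Families are noise-perturbed copies of a founder chain; the identity
alignment between members is retained as the reference alignment, and a
family/superfamily/fold label hierarchy is derived from the element-plan
topology.  Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import Chain
from .structure_io import tetrahedral_cbeta

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
STRAND_STEP = 3.4
STRAND_PLEAT = 0.85  # gives ~3.8 A CA-CA along the pleated strand
CA_STEP = 3.8
CLASH_DISTANCE = 2.5
N_CA_BOND = 1.46
CA_C_BOND = 1.52

Element = tuple[str, int]  # ("helix" | "strand" | "coil", length)

#: default topology: an 88-residue three-layer alpha/beta arrangement,
#: desk-scale for a single protein domain
DEFAULT_ELEMENT_PLAN: tuple[Element, ...] = (
    ("helix", 15), ("coil", 4), ("strand", 10), ("coil", 4), ("helix", 12),
    ("coil", 4), ("strand", 9), ("coil", 4), ("helix", 14), ("coil", 4),
    ("strand", 8),
)


class GenerationError(RuntimeError):
    """Raised when clash-free assembly fails after the retry budget."""


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Conditions for a synthetic homolog benchmark set."""

    n_families: int = 8
    members_per_family: int = 5
    element_plan: tuple[Element, ...] = DEFAULT_ELEMENT_PLAN
    noise_sigma: float = 0.5
    reorient_domains: bool = False
    seed: int = 0
    n_decoys: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for kind, length in self.element_plan:
            if length < 4:
                raise ValueError(f"element length {length} < 4")
            if kind not in ("helix", "strand", "coil"):
                raise ValueError(f"unknown element kind {kind!r}")


@dataclass
class FamilySet:
    """Chains plus benchmark labels and reference alignments."""

    chains: dict[str, Chain]
    #: entry id -> (family, superfamily, fold)
    labels: dict[str, tuple[str, str, str]]
    #: (id_a, id_b, [(i, j)]) identity alignments between family members
    ref_alignments: list[tuple[str, str, list[tuple[int, int]]]] = field(default_factory=list)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _helix_trace(n: int) -> np.ndarray:
    t = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST_DEG) * t
    return np.stack([HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang),
                     HELIX_RISE * t], axis=1)


def _strand_trace(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.stack([STRAND_STEP * t, STRAND_PLEAT * (-1.0) ** t,
                     np.zeros(n)], axis=1)


def _coil_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    pts = [np.zeros(3)]
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for _ in range(n - 1):
        direction = direction + 0.8 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + CA_STEP * direction)
    return np.array(pts)


def _segment_trace(kind: str, length: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "helix":
        return _helix_trace(length)
    if kind == "strand":
        return _strand_trace(length)
    return _coil_trace(length, rng)


def _has_clash(existing: np.ndarray, new: np.ndarray) -> bool:
    if existing.size == 0:
        return False
    d2 = np.sum((existing[:, None, :] - new[None, :, :]) ** 2, axis=2)
    return bool((d2 < CLASH_DISTANCE ** 2).any())


def _assemble_ca_trace(element_plan, rng: np.random.Generator,
                       max_tries: int = 1000) -> tuple[np.ndarray, list[slice]]:
    """Place segments one after another, rejecting clashing orientations."""
    ca = np.empty((0, 3))
    segments: list[slice] = []
    for kind, length in element_plan:
        placed = False
        for _ in range(max_tries):
            local = _segment_trace(kind, length, rng)
            local = local @ _random_rotation(rng).T
            if ca.size == 0:
                candidate = local - local[0]
            else:
                step = rng.normal(size=3)
                step /= np.linalg.norm(step)
                start = ca[-1] + CA_STEP * step
                candidate = local - local[0] + start
                # ignore the two junction residues when testing for clashes
                if _has_clash(ca[:-1], candidate) or \
                        np.linalg.norm(candidate[0] - ca[-1]) < CLASH_DISTANCE:
                    continue
            segments.append(slice(len(ca), len(ca) + length))
            ca = np.vstack([ca, candidate])
            placed = True
            break
        if not placed:
            raise GenerationError(f"could not place {kind}({length}) without clashes")
    return ca, segments


def backbone_from_ca(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive plausible N, C and CB positions from a CA trace.

    N and C are placed off the local chain axis with standard bond lengths;
    CB completes the tetrahedron.  This is idealized geometry, not a
    rotamer-aware reconstruction — sufficient for frame-based features.
    """
    L = len(ca)
    n_atoms = np.zeros((L, 3))
    c_atoms = np.zeros((L, 3))
    cb = np.zeros((L, 3))
    for i in range(L):
        d_prev = ca[i - 1] - ca[i] if i > 0 else ca[i] - ca[i + 1]
        d_next = ca[i + 1] - ca[i] if i < L - 1 else ca[i] - ca[i - 1]
        d_prev = d_prev / np.linalg.norm(d_prev)
        d_next = d_next / np.linalg.norm(d_next)
        perp = np.cross(d_next, d_prev)
        if np.linalg.norm(perp) < 1e-6:  # collinear stretch: pick any normal
            helper = np.array([1.0, 0.0, 0.0])
            if abs(d_next @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            perp = np.cross(d_next, helper)
        perp = perp / np.linalg.norm(perp)
        dir_n = 0.6 * d_prev + 0.8 * perp
        dir_c = 0.6 * d_next + 0.8 * perp
        n_atoms[i] = ca[i] + N_CA_BOND * dir_n / np.linalg.norm(dir_n)
        c_atoms[i] = ca[i] + CA_C_BOND * dir_c / np.linalg.norm(dir_c)
        cb[i] = tetrahedral_cbeta(n_atoms[i], ca[i], c_atoms[i])
    return n_atoms, c_atoms, cb


_AA_POOL = "ADEFGHIKLMNPQRSTVWY"  # C excluded to avoid fake disulfide pairs


def make_chain(element_plan, seed: int, chain_id: str = "A") -> Chain:
    """Build one synthetic chain from an element plan, deterministically."""
    if not element_plan:
        raise ValueError("element plan must be non-empty")
    rng = np.random.default_rng(seed)
    ca, _ = _assemble_ca_trace(element_plan, rng)
    n_atoms, c_atoms, cb = backbone_from_ca(ca)
    aa = "".join(rng.choice(list(_AA_POOL), size=len(ca)))
    return Chain(chain_id, aa, n_atoms, ca, c_atoms, cb)


_NOISE_KERNEL_SIGMA = 2.0  # residues; correlation length of the deformation


def _smooth_noise(L: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Sequence-correlated Gaussian displacement field, per-residue std sigma.

    Homologous structures differ by smooth, low-frequency deformations, not
    independent per-residue jitter (which would model coordinate error and
    scramble local backbone directions).  White noise is convolved with a
    Gaussian kernel along the chain and rescaled so the marginal
    displacement of each residue keeps the requested standard deviation.
    """
    half = int(np.ceil(3 * _NOISE_KERNEL_SIGMA))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (t / _NOISE_KERNEL_SIGMA) ** 2)
    kernel /= np.sqrt(np.sum(kernel ** 2))  # unit output variance
    white = rng.normal(size=(L + 2 * half, 3))
    smooth = np.stack([np.convolve(white[:, c], kernel, mode="valid")
                       for c in range(3)], axis=1)
    return sigma * smooth


def perturb_chain(chain: Chain, sigma: float, rng: np.random.Generator,
                  reorient_tail: bool = False) -> Chain:
    """Smooth Gaussian coordinate noise, applied jointly per residue.

    The same displacement moves all backbone atoms of a residue, preserving
    local bond geometry; displacements are correlated along the sequence
    (see :func:`_smooth_noise`).  With ``reorient_tail`` the final third of
    the chain is additionally rotated rigidly about its junction, emulating
    inter-domain flexibility.
    """
    out = chain.copy()
    if sigma > 0:
        shift = _smooth_noise(len(chain), sigma, rng)
        for name in ("n", "ca", "c", "cb"):
            arr = getattr(out, name)
            arr += shift
    if reorient_tail and len(chain) >= 9:
        pivot_idx = 2 * len(chain) // 3
        pivot = out.ca[pivot_idx].copy()
        angle = rng.uniform(0.2, 0.6) * rng.choice([-1.0, 1.0])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        for name in ("n", "ca", "c", "cb"):
            arr = getattr(out, name)
            arr[pivot_idx:] = (arr[pivot_idx:] - pivot) @ R.T + pivot
    return out


def _jitter_plan(plan, rng: np.random.Generator) -> tuple[Element, ...]:
    out = []
    for kind, length in plan:
        out.append((kind, max(4, length + int(rng.integers(-2, 3)))))
    return tuple(out)


def _family_plan(spec: SyntheticFamilySpec, k: int,
                 rng: np.random.Generator) -> tuple[Element, ...]:
    """Element plan for family k: half the families keep the base topology,
    the rest get a reversed or strand/helix-swapped topology so several
    superfamilies and folds exist in one benchmark set."""
    plan = _jitter_plan(spec.element_plan, rng)
    variant = k % 4
    if variant == 1:
        plan = tuple(reversed(plan))
    elif variant == 2:
        swap = {"helix": "strand", "strand": "helix", "coil": "coil"}
        plan = tuple((swap[kind], length) for kind, length in plan)
    elif variant == 3:
        plan = tuple(reversed([(("strand" if kind == "helix" else
                                 "helix" if kind == "strand" else "coil"), length)
                               for kind, length in plan]))
    return plan


def _topology_labels(plan) -> tuple[str, str]:
    kinds = [kind for kind, _ in plan if kind != "coil"]
    superfamily = "sf_" + "-".join(kinds)
    counts = {"helix": 0, "strand": 0}
    for kind in kinds:
        counts[kind] += 1
    if counts["strand"] == 0:
        fold = "fold_all_helix"
    elif counts["helix"] == 0:
        fold = "fold_all_strand"
    elif counts["helix"] > counts["strand"]:
        fold = "fold_mostly_helix"
    elif counts["strand"] > counts["helix"]:
        fold = "fold_mostly_strand"
    else:  # balanced alpha/beta: distinguish by the leading element
        fold = f"fold_alternating_{kinds[0]}"
    return superfamily, fold


def make_family(spec: SyntheticFamilySpec) -> FamilySet:
    """Generate the full labeled set: families, members, decoys, references."""
    rng = np.random.default_rng(spec.seed)
    chains: dict[str, Chain] = {}
    labels: dict[str, tuple[str, str, str]] = {}
    ref_alignments: list[tuple[str, str, list[tuple[int, int]]]] = []
    for k in range(spec.n_families):
        plan = _family_plan(spec, k, rng)
        founder_seed = int(rng.integers(0, 2 ** 31 - 1))
        founder = make_chain(plan, founder_seed)
        superfamily, fold = _topology_labels(plan)
        family = f"F{k:02d}"
        member_ids = []
        for m in range(spec.members_per_family):
            if m == 0:
                member = founder.copy()
            else:
                member = perturb_chain(founder, spec.noise_sigma, rng,
                                       reorient_tail=spec.reorient_domains)
            entry_id = f"{family}_m{m}"
            member.chain_id = entry_id
            chains[entry_id] = member
            labels[entry_id] = (family, superfamily, fold)
            member_ids.append(entry_id)
        identity = list(zip(range(len(founder)), range(len(founder))))
        for a in range(len(member_ids)):
            for b in range(a + 1, len(member_ids)):
                ref_alignments.append((member_ids[a], member_ids[b], identity))
    for d in range(spec.n_decoys):
        plan = _jitter_plan(spec.element_plan, rng)
        rng.shuffle(plan := list(plan))
        plan = tuple(plan)
        decoy = make_chain(plan, int(rng.integers(0, 2 ** 31 - 1)))
        entry_id = f"decoy_{d:02d}"
        decoy.chain_id = entry_id
        chains[entry_id] = decoy
        superfamily, fold = _topology_labels(plan)
        labels[entry_id] = (f"Fdecoy{d:02d}", f"{superfamily}_decoy{d:02d}",
                            f"{fold}_decoy{d:02d}")
    return FamilySet(chains=chains, labels=labels, ref_alignments=ref_alignments)
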