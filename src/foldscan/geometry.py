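"""Virtual centers, nearest-neighbor selection and interaction descriptors.

Each residue is paired with the residue whose *virtual center* — a
pseudo-atom placed at a fixed angle/dihedral/distance from the CA/CB/N
frame — is closest in space.  The geometry of residue ``i`` together with
its partner ``j`` is then summarized in a 10-feature descriptor: seven
cosines of angles between backbone direction vectors, the CA-CA distance,
and two sequence-separation features.  These descriptors are what the
structural alphabet discretizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import CA_CB_BOND, Chain

N_FEATURES = 10

#: descriptor component order
FEATURE_NAMES = (
    "cos_phi_12", "cos_phi_34", "cos_phi_15", "cos_phi_35",
    "cos_phi_14", "cos_phi_23", "cos_phi_13",
    "ca_dist", "seq_clip", "seq_log",
)


class DegenerateGeometryError(ValueError):
    """Raised when coordinates collapse (zero-length direction vectors)."""


@dataclass(frozen=True)
class VirtualCenterParams:
    """Placement of the virtual center V relative to the CA/CB/N frame.

    ``theta_deg`` is the angle V-CA-CB, ``tau_deg`` the dihedral
    V-CA-CB-N and ``l_factor`` scales the canonical 1.53 A CA-CB bond to
    give |V - CA|.  The defaults (270, 0, 2) favor long-range tertiary
    contacts over backbone neighbors.
    """

    theta_deg: float = 270.0
    tau_deg: float = 0.0
    l_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.l_factor <= 0:
            raise ValueError("l_factor must be positive")


def virtual_center(n_xyz, ca_xyz, cb_xyz,
                   params: VirtualCenterParams = VirtualCenterParams()) -> np.ndarray:
    """Place the virtual center from the three frame atoms.

    Uses the standard internal-coordinate construction: bond length
    ``l_factor * 1.53`` from CA, bond angle ``theta`` at CA against the
    CA->CB direction, and torsion ``tau`` measured against N about the
    CB->CA axis.
    """
    n = np.asarray(n_xyz, float)
    ca = np.asarray(ca_xyz, float)
    cb = np.asarray(cb_xyz, float)
    # NeRF frame with A=N, B=CB, C=CA, placing D=V
    bc = ca - cb
    bc_len = np.linalg.norm(bc)
    ab = cb - n
    if bc_len < 1e-9:
        raise DegenerateGeometryError("CA and CB coincide")
    bc = bc / bc_len
    normal = np.cross(ab, bc)
    normal_len = np.linalg.norm(normal)
    if normal_len < 1e-9:
        raise DegenerateGeometryError("N, CA, CB are collinear: dihedral undefined")
    normal = normal / normal_len
    m = np.stack([bc, np.cross(normal, bc), normal], axis=1)
    d = params.l_factor * CA_CB_BOND
    theta = np.deg2rad(params.theta_deg)
    tau = np.deg2rad(params.tau_deg)
    local = d * np.array([-np.cos(theta), np.sin(theta) * np.cos(tau),
                          np.sin(theta) * np.sin(tau)])
    return ca + m @ local


def _window_valid(L: int) -> np.ndarray:
    """Interior residues: i-1, i, i+1 all exist (CA is guaranteed)."""
    valid = np.zeros(L, dtype=bool)
    if L >= 3:
        valid[1:L - 1] = True
    return valid


def chain_virtual_centers(chain: Chain,
                          params: VirtualCenterParams = VirtualCenterParams()
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Virtual centers for every residue with a complete N/CA/CB frame.

    Returns ``(centers, valid)`` where centers is (L, 3) with NaN rows for
    residues lacking frame atoms.
    """
    L = len(chain)
    centers = np.full((L, 3), np.nan)
    frame_ok = chain.has_atom("n") & chain.has_atom("cb")
    for i in np.nonzero(frame_ok)[0]:
        try:
            centers[i] = virtual_center(chain.n[i], chain.ca[i], chain.cb[i], params)
        except DegenerateGeometryError:
            frame_ok[i] = False
    return centers, frame_ok


def select_partners(chain: Chain,
                    params: VirtualCenterParams = VirtualCenterParams()) -> np.ndarray:
    """Nearest neighbor of each residue by virtual-center distance.

    Returns an int array of length L; ``partner[i]`` is the 0-based index of
    the residue whose virtual center is closest to that of ``i``, or -1 when
    ``i`` has no valid center or no candidate exists.  Candidates are
    restricted to residues with a valid center *and* a full descriptor
    window (both sequence neighbors present).  Exact all-pairs search.
    """
    L = len(chain)
    centers, has_center = chain_virtual_centers(chain, params)
    candidate = has_center & _window_valid(L)
    partner = np.full(L, -1, dtype=np.int64)
    cand_idx = np.nonzero(candidate)[0]
    if cand_idx.size == 0:
        return partner
    cand_centers = centers[cand_idx]
    for i in np.nonzero(has_center)[0]:
        d2 = np.sum((cand_centers - centers[i]) ** 2, axis=1)
        d2[cand_idx == i] = np.inf
        best = d2.min()
        if not np.isfinite(best):
            continue
        # tolerance-based tie-break (lowest index) keeps the choice stable
        # under floating-point jitter from rigid-body motion
        near = np.nonzero(d2 <= best + 1e-9)[0]
        partner[i] = cand_idx[near[0]]
    return partner


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateGeometryError("zero-length direction vector (duplicate CA)")
    return v / norm


def compute_descriptor(chain: Chain, i: int, j: int) -> np.ndarray:
    """10-feature interaction descriptor for the residue pair (i, j).

    ``i`` and ``j`` are 0-based; both must be interior residues.  Features
    (in order): cos phi_12, _34, _15, _35, _14, _23, _13 from the five unit
    vectors u1: CA(i-1)->CA(i), u2: CA(i)->CA(i+1), u3: CA(j-1)->CA(j),
    u4: CA(j)->CA(j+1), u5: CA(i)->CA(j); then |CA_i - CA_j|; then
    sign(i-j)*min(|i-j|, 4) and sign(i-j)*log(|i-j| + 1).
    """
    L = len(chain)
    if not (0 < i < L - 1 and 0 < j < L - 1):
        raise ValueError(f"residues {i}, {j} lack full descriptor windows (L={L})")
    ca = chain.ca
    u1 = _unit(ca[i] - ca[i - 1])
    u2 = _unit(ca[i + 1] - ca[i])
    u3 = _unit(ca[j] - ca[j - 1])
    u4 = _unit(ca[j + 1] - ca[j])
    u5 = _unit(ca[j] - ca[i])
    sep = i - j
    sign = np.sign(sep)
    return np.array([
        u1 @ u2, u3 @ u4, u1 @ u5, u3 @ u5, u1 @ u4, u2 @ u3, u1 @ u3,
        np.linalg.norm(ca[j] - ca[i]),
        sign * min(abs(sep), 4),
        sign * np.log(abs(sep) + 1),
    ])


def chain_descriptors(chain: Chain,
                      params: VirtualCenterParams = VirtualCenterParams()
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Descriptors for every residue with a partner and valid windows.

    Returns ``(features, valid, partner)``: features is (L, 10) with NaN
    rows where invalid, valid a boolean mask, partner the 0-based partner
    indices (-1 where absent).
    """
    L = len(chain)
    partner = select_partners(chain, params)
    window = _window_valid(L)
    features = np.full((L, N_FEATURES), np.nan)
    valid = np.zeros(L, dtype=bool)
    for i in range(L):
        j = partner[i]
        if j < 0 or not window[i]:
            continue
        try:
            features[i] = compute_descriptor(chain, i, int(j))
        except DegenerateGeometryError:
            continue
        valid[i] = True
    return features, valid, partner


def dump_descriptors_tsv(chain: Chain, path,
                         params: VirtualCenterParams = VirtualCenterParams()) -> None:
    """Debug dump: one row per residue with a valid descriptor."""
    features, valid, partner = chain_descriptors(chain, params)
    with open(path, "w") as fh:
        fh.write("entry\ti\tj\t" + "\t".join(FEATURE_NAMES) + "\n")
        for i in np.nonzero(valid)[0]:
            row = "\t".join(f"{x:.6f}" for x in features[i])
            fh.write(f"{chain.chain_id}\t{i + 1}\t{partner[i] + 1}\t{row}\n")
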