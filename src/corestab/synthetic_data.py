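"""Synthetic structures, complexes and ensembles with exact ground truth.

Every generator returns ``(object, GroundTruth)`` and, before returning,
verifies its own ground-truth claims with independent brute-force checks
(direct double loops, closed-form counts), so a generator bug surfaces at
generation time rather than as a silent test-oracle error.

Backbone geometry uses canonical bond lengths and angles (N-CA 1.458 Å,
CA-C 1.525 Å, C-N 1.329 Å, ω = 180°), so canonical φ/ψ values give canonical
hydrogen-bond energies.  Side chains are minimal: alanine-like residues carry
a single CB; *decorations* append bare pseudo-carbons at caller-chosen offsets
to make hydrophobic wrapping fully controllable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize

from .structure_io import AtomRecord, Ensemble, Structure
from . import hbond_wrapping as hw

__all__ = [
    "GroundTruth",
    "make_helix",
    "make_hairpin",
    "make_extended",
    "decorate_hydrophobics",
    "make_dimer",
    "make_ensemble",
]

# canonical backbone geometry
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O = 121.7, 111.2, 116.2, 120.8
OMEGA = 180.0


@dataclass
class GroundTruth:
    """Designed quantities emitted next to generated coordinates."""

    kind: str
    designed_hbonds: list[tuple[int, int]] = field(default_factory=list)  # (donor_seq, acceptor_seq)
    designed_ss: dict[int, str] = field(default_factory=dict)             # seq -> helix|sheet|turn|other
    designed_interface: list[tuple] = field(default_factory=list)         # residue keys
    designed_wrapping: dict[tuple[int, int], int] = field(default_factory=dict)
    designed_rmsf: np.ndarray | None = None                               # per residue, Å
    designed_mode_variances: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = asdict(self)
        if d["designed_rmsf"] is not None:
            d["designed_rmsf"] = list(map(float, d["designed_rmsf"]))
        d["designed_wrapping"] = {f"{k[0]}-{k[1]}": v
                                  for k, v in self.designed_wrapping.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# internal-coordinate chain building (NeRF)
# ---------------------------------------------------------------------------

def place_atom(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position a fourth atom bonded to p3 with given bond length, bond angle
    (p2-p3-new) and torsion (p1-p2-p3-new)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-length * math.cos(ang),
                  length * math.sin(ang) * math.cos(tor),
                  length * math.sin(ang) * math.sin(tor)])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(phi_psi: list[tuple[float, float]],
                    residue_name: str = "ALA", chain_id: str = "A",
                    first_seq: int = 1, with_cb: bool = True):
    """Backbone (+CB) coordinates for a chain with given per-residue (φ, ψ)."""
    n_res = len(phi_psi)
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    O = [None] * n_res
    N[0] = np.zeros(3)
    CA[0] = np.array([B_N_CA, 0.0, 0.0])
    # first C placed in the xy-plane (the absolute frame is arbitrary)
    ang = math.radians(A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n_res):
        phi_i, psi_i = phi_psi[i]
        if i + 1 < n_res:
            N[i + 1] = place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi_i)
            O[i] = place_atom(N[i + 1], CA[i], C[i], B_C_O, A_CA_C_O, 180.0)
            CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], B_N_CA, A_C_N_CA, OMEGA)
            C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], B_CA_C, A_N_CA_C,
                                  phi_psi[i + 1][0])
        else:
            O[i] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi_i + 180.0)
    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(n_res):
        seq = first_seq + i
        per_res = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i]), ("O", "O", O[i])]
        if with_cb and residue_name != "GLY":
            cb = place_atom(N[i], C[i], CA[i], B_CA_CB, 110.1, -122.6)
            per_res.insert(2, ("CB", "C", cb))
        for name, el, xyz in per_res:
            atoms.append(AtomRecord(serial=serial, name=name, element=el,
                                    residue_name=residue_name, residue_seq=seq,
                                    insertion_code="", chain_id=chain_id,
                                    coords=xyz))
            serial += 1
    return atoms


def _structure(atoms: list[AtomRecord], source_id: str) -> Structure:
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return Structure(atoms, source_id=source_id)


def _bond_seq_set(bonds) -> set[tuple[int, int]]:
    return {(b.donor.seq, b.acceptor.seq) for b in bonds}


# ---------------------------------------------------------------------------
# helix
# ---------------------------------------------------------------------------

def make_helix(n: int, phi: float = -57.0, psi: float = -47.0,
               residue_name: str = "ALA", chain_id: str = "A",
               first_seq: int = 1) -> tuple[Structure, GroundTruth]:
    """Ideal α-helix of ``n`` residues; ground truth lists the i+4→i backbone
    H-bonds (donor seq, acceptor seq) for i = 1..n-4 and helix class for the
    interior residues."""
    if n < 1:
        raise ValueError("helix needs n >= 1")
    atoms = _build_backbone([(phi, psi)] * n, residue_name, chain_id, first_seq)
    s = _structure(atoms, f"helix{n}")
    designed = [(first_seq + i + 4, first_seq + i) for i in range(max(0, n - 4))]
    ss = {first_seq + i: ("helix" if 1 <= i <= n - 2 and n >= 6 else "other")
          for i in range(n)}
    gt = GroundTruth(kind="helix", designed_hbonds=designed, designed_ss=ss,
                     params={"n": n, "phi": phi, "psi": psi})
    found = _bond_seq_set(hw.extract_bhb(s))
    if found != set(designed):
        raise RuntimeError(
            f"helix generator self-check failed: designed {sorted(designed)} "
            f"vs extracted {sorted(found)}")
    return s, gt


# ---------------------------------------------------------------------------
# extended chain / hairpin
# ---------------------------------------------------------------------------

def make_extended(n: int, phi: float = -139.0, psi: float = 135.0,
                  residue_name: str = "ALA", chain_id: str = "A",
                  first_seq: int = 1) -> Structure:
    """A single extended (β-conformation) chain with no designed H-bonds."""
    atoms = _build_backbone([(phi, psi)] * n, residue_name, chain_id, first_seq)
    return _structure(atoms, f"ext{n}")


def _rigid(params: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Apply a 6-dof rigid transform (rotation vector + translation)."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_rotvec(params[:3])
    return rot.apply(coords) + params[3:]


def make_hairpin(len_per_strand: int, register: int = 0, turn_len: int = 2,
                 residue_name: str = "ALA") -> tuple[Structure, GroundTruth]:
    """Two antiparallel strands joined by a short turn, with a canonical
    H-bond ladder at the designed register.

    Residues 1..L form strand A, the next ``turn_len`` the turn, and the rest
    strand B.  Narrow pairs (two H-bonds each) sit at residues
    ``L-2k`` / ``L+turn_len+1+2k+register``; ``register`` shifts the partner
    by whole residues, so a shift of 2 gives a disjoint designed bond list.

    Strand B is placed rigidly by minimising a distance-geometry objective
    (N···O = 2.9 Å, H···O = 1.9 Å for every designed bond, with a clash
    penalty) from a set of deterministic antiparallel starting placements; the
    extracted bond set is verified against the design before returning.
    """
    L, T = len_per_strand, turn_len
    if L < 2:
        raise ValueError("strands need >= 2 residues")
    if T < 1:
        raise ValueError("the turn needs at least one residue")
    strand_pp = (-139.0, 135.0)
    a_atoms = _build_backbone([strand_pp] * L, residue_name, "A", 1)
    b_atoms = _build_backbone([strand_pp] * L, residue_name, "A", L + T + 1)
    b_first = L + T + 1

    pairs: list[tuple[int, int]] = []
    k = 0
    while True:
        i = L - 2 * k
        j = b_first + 2 * k + register
        if i < 1 or not (b_first <= j <= b_first + L - 1):
            break
        pairs.append((i, j))
        k += 1
    if not pairs:
        raise ValueError("no feasible narrow pairs for this register")
    # chain-initial residue 1 has no amide H and cannot donate
    designed = [b for i, j in pairs for b in ((j, i), (i, j)) if b[0] != 1]

    # per-strand atom lookups
    def res_atoms(atoms):
        out: dict[int, dict[str, np.ndarray]] = {}
        for a in atoms:
            out.setdefault(a.residue_seq, {})[a.name] = a.coords
        return out

    a_map = res_atoms(a_atoms)
    b_map0 = res_atoms(b_atoms)
    a_xyz = np.array([a.coords for a in a_atoms])
    b_xyz0 = np.array([a.coords for a in b_atoms])
    b_index = {(a.residue_seq, a.name): i for i, a in enumerate(b_atoms)}

    def a_amide_h(seq: int) -> np.ndarray | None:
        if seq - 1 not in a_map:
            return None
        co = a_map[seq - 1]["C"] - a_map[seq - 1]["O"]
        return a_map[seq]["N"] + co / np.linalg.norm(co)

    def objective(params: np.ndarray) -> float:
        xyz = _rigid(params, b_xyz0)
        cost = 0.0
        for d_seq, a_seq in designed:
            if d_seq >= b_first:          # donor on strand B
                n = xyz[b_index[(d_seq, "N")]]
                o = a_map[a_seq]["O"]
                cost += (np.linalg.norm(n - o) - 2.9) ** 2
                if d_seq - 1 >= b_first:  # H derivable from B itself
                    co = xyz[b_index[(d_seq - 1, "C")]] - xyz[b_index[(d_seq - 1, "O")]]
                    h = n + co / np.linalg.norm(co)
                    cost += (np.linalg.norm(h - o) - 1.9) ** 2
            else:                          # donor on strand A
                n = a_map[d_seq]["N"]
                o = xyz[b_index[(a_seq, "O")]]
                cost += (np.linalg.norm(n - o) - 2.9) ** 2
                h = a_amide_h(d_seq)
                if h is not None:
                    cost += (np.linalg.norm(h - o) - 1.9) ** 2
        dmat = np.linalg.norm(a_xyz[:, None, :] - xyz[None, :, :], axis=2)
        clash = np.clip(3.2 - dmat, 0.0, None)
        return cost + 0.5 * float((clash ** 2).sum())

    # deterministic starting placements: B antiparallel, offset to either side
    starts = []
    for rotvec in ((0.0, 0.0, math.pi), (math.pi, 0.0, 0.0),
                   (0.0, math.pi, 0.0)):
        for dy in (4.8, -4.8):
            p = np.zeros(6)
            p[:3] = rotvec
            p[3:] = (a_xyz.mean(axis=0)
                     - _rigid(np.array([*rotvec, 0, 0, 0]), b_xyz0).mean(axis=0)
                     + np.array([0.0, dy, 0.0]))
            starts.append(p)

    last_err = "no placement attempted"
    for start in starts:
        opt = minimize(objective, start, method="L-BFGS-B",
                       options={"maxiter": 2000})
        b_xyz = _rigid(opt.x, b_xyz0)
        structure, gt, err = _assemble_hairpin(
            a_atoms, b_atoms, b_xyz, designed, pairs, L, T,
            residue_name, register)
        if err is None:
            return structure, gt
        last_err = err
    raise RuntimeError(f"hairpin generator self-check failed: {last_err}")


def _assemble_hairpin(a_atoms, b_atoms, b_xyz, designed, pairs, L, T,
                      residue_name, register):
    """Attach the turn, assemble the chain, and verify the designed ladder."""
    b_atoms = [AtomRecord(0, a.name, a.element, a.residue_name, a.residue_seq,
                          "", "A", xyz.copy())
               for a, xyz in zip(b_atoms, b_xyz)]
    b_first = L + T + 1
    b_map = {}
    for a in b_atoms:
        b_map.setdefault(a.residue_seq, {})[a.name] = a.coords
    a_map = {}
    for a in a_atoms:
        a_map.setdefault(a.residue_seq, {})[a.name] = a.coords

    ca_a, ca_b = a_map[L]["CA"], b_map[b_first]["CA"]
    sheet_normal = np.cross(a_map[L]["CA"] - a_map[1]["CA"], ca_b - ca_a)
    nrm = np.linalg.norm(sheet_normal)
    sheet_normal = sheet_normal / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])

    turn_atoms: list[AtomRecord] = []
    for t in range(T):
        seq = L + 1 + t
        f = (t + 1) / (T + 1)
        centre = (1 - f) * ca_a + f * ca_b + 4.5 * math.sin(math.pi * f) * sheet_normal
        local = {"N": np.array([-0.8, 0.2, 0.3]), "CA": np.zeros(3),
                 "C": np.array([0.9, 0.5, -0.2]), "O": np.array([1.1, 1.6, 0.1])}
        for name in ("N", "CA", "C", "O"):
            turn_atoms.append(AtomRecord(0, name, name[0], residue_name, seq,
                                         "", "A", centre + local[name]))
    # engineer the last turn carbonyl so the first B-strand donor gets an
    # ideal amide H (anti to C->O of the preceding residue)
    if (b_first, 1) not in [(d, 0) for d in ()]:  # always
        n_b = b_map[b_first]["N"]
        acceptors = [a for d, a in designed if d == b_first]
        if acceptors:
            o_target = a_map[acceptors[0]]["O"]
            h_dir = (o_target - n_b) / np.linalg.norm(o_target - n_b)
        else:
            h_dir = sheet_normal
        # C of the last turn residue sits on the peptide bond to N(b_first)
        side = np.cross(h_dir, sheet_normal)
        if np.linalg.norm(side) < 1e-6:
            side = np.array([1.0, 0.0, 0.0])
        side /= np.linalg.norm(side)
        c_pos = n_b + 1.329 * (0.37 * h_dir + 0.93 * side)
        o_pos = c_pos - 1.231 * h_dir
        for a in turn_atoms:
            if a.residue_seq == L + T:
                if a.name == "C":
                    a.coords = c_pos
                elif a.name == "O":
                    a.coords = o_pos

    all_atoms = a_atoms + turn_atoms + b_atoms
    all_atoms = [AtomRecord(0, a.name, a.element, a.residue_name, a.residue_seq,
                            "", "A", a.coords.copy()) for a in all_atoms]
    all_atoms.sort(key=lambda a: a.residue_seq)
    s = _structure(all_atoms, f"hairpin{L}")

    def on_strand(seq: int) -> int:
        if seq <= L:
            return 0
        if seq >= b_first:
            return 1
        return -1

    found = {b for b in _bond_seq_set(hw.extract_bhb(s))
             if on_strand(b[0]) >= 0 and on_strand(b[1]) >= 0
             and on_strand(b[0]) != on_strand(b[1])}
    if found != set(designed):
        return None, None, (f"designed {sorted(set(designed))} vs extracted "
                            f"inter-strand {sorted(found)}")
    ss = {seq: ("sheet" if on_strand(seq) >= 0 else "turn")
          for seq in range(1, 2 * L + T + 1)}
    gt = GroundTruth(kind="hairpin", designed_hbonds=designed, designed_ss=ss,
                     params={"len_per_strand": L, "register": register,
                             "turn_len": T, "narrow_pairs": pairs})
    return s, gt, None


# ---------------------------------------------------------------------------
# hydrophobic decorations
# ---------------------------------------------------------------------------

def _brute_force_nonpolar(structure: Structure) -> list[bool]:
    """Independent O(n²) nonpolar-carbon classification (generation oracle)."""
    heavy = structure.heavy_atoms
    flags = []
    for a in structure.atoms:
        if a.is_hydrogen or a.element != "C":
            flags.append(False)
            continue
        polar = False
        for b in heavy:
            if b is a:
                continue
            if b.element in ("N", "O", "S") and np.linalg.norm(a.coords - b.coords) < 1.9:
                polar = True
                break
        flags.append(not polar)
    return flags


def brute_force_wrapping(structure: Structure, donor_ca: np.ndarray,
                         acceptor_ca: np.ndarray, radius: float = 6.5) -> int:
    """Independent O(atoms) wrapping count for one bond (generation oracle)."""
    flags = _brute_force_nonpolar(structure)
    count = 0
    for a, np_flag in zip(structure.atoms, flags):
        if not np_flag:
            continue
        if (np.linalg.norm(a.coords - donor_ca) <= radius
                or np.linalg.norm(a.coords - acceptor_ca) <= radius):
            count += 1
    return count


def decorate_hydrophobics(structure: Structure,
                          decorations: list[tuple[int, str, np.ndarray]],
                          radius: float = 6.5) -> tuple[Structure, GroundTruth]:
    """Append pseudo side-chain carbons and record exact per-bond wrapping.

    ``decorations`` is a list of ``(residue_seq, element, offset)`` with the
    offset in Å relative to that residue's Cα.  Offsets clashing (< 1.5 Å)
    with existing atoms raise a generation error.  The ground truth stores,
    for every backbone H-bond of the decorated structure, the wrapping count
    obtained by an independent brute-force scan.
    """
    res_by_seq = {}
    for r in structure.residues():
        res_by_seq.setdefault(r.seq, r)
    new_atoms = [AtomRecord(a.serial, a.name, a.element, a.residue_name,
                            a.residue_seq, a.insertion_code, a.chain_id,
                            a.coords.copy(), a.occupancy, a.altloc, a.is_hetatm)
                 for a in structure.atoms]
    existing = np.array([a.coords for a in structure.atoms])
    # continue numbering past any decorations already present
    counter: dict[int, int] = {}
    for a in structure.atoms:
        if a.name.startswith("CX"):
            try:
                counter[a.residue_seq] = max(counter.get(a.residue_seq, 0),
                                             int(a.name[2:]))
            except ValueError:
                pass
    appended = []
    for seq, element, offset in decorations:
        r = res_by_seq.get(seq)
        if r is None:
            raise ValueError(f"no residue with seq {seq}")
        ca = r.coord("CA")
        xyz = ca + np.asarray(offset, dtype=float)
        if existing.size and np.min(np.linalg.norm(existing - xyz, axis=1)) < 1.5:
            raise RuntimeError(f"decoration at residue {seq} clashes with an existing atom")
        k = counter.get(seq, 0) + 1
        counter[seq] = k
        appended.append(AtomRecord(0, f"CX{k}", element.upper(), r.name, seq,
                                   r.insertion_code, r.chain_id, xyz))
        existing = np.vstack([existing, xyz[None, :]])
    # keep residue atom blocks contiguous
    all_atoms = new_atoms + appended
    all_atoms.sort(key=lambda a: (a.chain_id, a.residue_seq, a.insertion_code))
    s = _structure(all_atoms, structure.source_id + "+dec")

    bonds = hw.extract_bhb(s)
    wrapping = {}
    for b in bonds:
        wrapping[(b.donor.seq, b.acceptor.seq)] = brute_force_wrapping(
            s, b.donor.coord("CA"), b.acceptor.coord("CA"), radius)
    gt = GroundTruth(kind="decorated", designed_wrapping=wrapping,
                     designed_hbonds=[(b.donor.seq, b.acceptor.seq) for b in bonds],
                     params={"n_decorations": len(decorations), "radius": radius})
    return s, gt


# ---------------------------------------------------------------------------
# dimer with designed contact patch
# ---------------------------------------------------------------------------

def make_dimer(n_residues: int, contact_patch: tuple[int, int],
               separation: float | None = None,
               partner_residue_name: str = "GLY",
               n_points: int = 240) -> tuple[Structure, GroundTruth]:
    """Two-chain complex whose chain-A interface is a designed residue range.

    Chain A is an extended alanine chain.  Chain B sandwiches the inclusive
    residue range ``contact_patch`` with two extended partner segments, one
    above and one below the strand plane, so that every patch residue loses
    solvent exposure regardless of which face its side chain points to.  With
    ``separation`` unset, a bounded deterministic search over the approach
    distance (and, as a fallback, segment length and lateral shift) finds a
    placement where exactly the patch residues of chain A lose >= 10% SASA —
    verified with the surface module at ``n_points`` sphere points; failure
    raises a generation error.  An explicit large ``separation`` yields an
    empty designed interface.
    """
    from scipy.spatial.transform import Rotation
    from .surface_interface import interface_residues

    lo, hi = contact_patch
    if not (1 <= lo <= hi <= n_residues):
        raise ValueError("contact patch outside the chain")
    chain_a = make_extended(n_residues, chain_id="A")
    patch_len = hi - lo + 1
    patch_atoms = np.array([a.coords for a in chain_a.atoms
                            if lo <= a.residue_seq <= hi])
    centre = patch_atoms.mean(axis=0)
    flip = Rotation.from_euler("x", 180, degrees=True)

    def placed(z: float, extra: int, dx: float) -> Structure:
        plen = patch_len + extra
        seg = _build_backbone([(-139.0, 135.0)] * plen, partner_residue_name,
                              "B", 1, with_cb=(partner_residue_name != "GLY"))
        seg_xyz = np.array([a.coords for a in seg])
        atoms = []
        for sign, seq_off in ((+1, 0), (-1, plen)):
            xyz = flip.apply(seg_xyz) if sign > 0 else seg_xyz
            shift = centre - xyz.mean(axis=0) + np.array([dx, 0.0, sign * z])
            for a, x in zip(seg, xyz):
                atoms.append(AtomRecord(0, a.name, a.element, a.residue_name,
                                        a.residue_seq + seq_off, "", "B",
                                        x + shift))
        return _structure(
            [AtomRecord(0, a.name, a.element, a.residue_name, a.residue_seq,
                        "", "A", a.coords.copy()) for a in chain_a.atoms]
            + atoms, f"dimer{n_residues}")

    patch_keys = {("A", s, "") for s in range(lo, hi + 1)}

    def a_interface(s: Structure):
        calls = interface_residues(s, ({"A"}, {"B"}), n_points=n_points)
        return {c.residue_key for c in calls if c.is_interface}

    if separation is not None:
        s = placed(separation, 0, 0.0)
        iface = a_interface(s)
        gt = GroundTruth(kind="dimer", designed_interface=sorted(iface),
                         params={"n_residues": n_residues, "patch": contact_patch,
                                 "separation": separation})
        return s, gt

    for extra in (0, 1, 2):
        for dx in (0.0, -1.7, 1.7):
            for z in np.arange(4.0, 9.01, 0.25):
                s = placed(float(z), extra, dx)
                iface = a_interface(s)
                if {k for k in iface if k[0] == "A"} == patch_keys:
                    gt = GroundTruth(
                        kind="dimer", designed_interface=sorted(iface),
                        params={"n_residues": n_residues, "patch": contact_patch,
                                "separation": float(z), "extra": extra,
                                "lateral_shift": dx})
                    return s, gt
    raise RuntimeError(
        f"could not place a partner burying exactly residues {lo}-{hi}")


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def make_ensemble(base: Structure, amplitude_profile: np.ndarray | None = None,
                  mode_spec: list[tuple[np.ndarray, float]] | None = None,
                  n_frames: int = 100, seed: int = 0,
                  rigid_motion: bool = False) -> tuple[Ensemble, GroundTruth]:
    """Gaussian coordinate ensemble around ``base`` with known ground truth.

    ``amplitude_profile`` gives each residue's isotropic per-coordinate noise
    s.d. in Å (expected RMSF contribution ``a_i * sqrt(3)``);  ``mode_spec`` is
    a list of ``(direction_field, variance)`` collective modes, each direction
    field a unit-norm (n_atoms, 3) array whose amplitude is drawn from
    N(0, variance) per frame.  ``rigid_motion`` additionally applies a random
    rotation/translation per frame to exercise superposition.  The ground
    truth stores the exact expected per-residue (Cα) RMSF and the mode
    variances.
    """
    rng = np.random.default_rng(seed)
    residues = base.residues()
    n_res = len(residues)
    n_atoms = len(base.atoms)
    amp = np.zeros(n_res) if amplitude_profile is None else np.asarray(amplitude_profile, float)
    if amp.shape != (n_res,):
        raise ValueError("amplitude profile must have one entry per residue")
    res_index = {}
    for i, r in enumerate(residues):
        res_index[r.key] = i
    atom_res = np.array([res_index[a.residue_key] for a in base.atoms])
    atom_amp = amp[atom_res]

    # rigid-body displacement fields at the base structure; collective modes
    # are projected off this subspace (superposition removes it, so a mode
    # with a rigid component would lose variance in any fitted observable)
    base_xyz0 = base.coords()
    centred = base_xyz0 - base_xyz0.mean(axis=0)
    rigid_fields = []
    for k in range(3):
        t = np.zeros((n_atoms, 3))
        t[:, k] = 1.0
        rigid_fields.append(t.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        rigid_fields.append(np.cross(axis, centred).ravel())
    q, _ = np.linalg.qr(np.stack(rigid_fields, axis=1))

    modes = []
    variances = []
    if mode_spec:
        for direction, var in mode_spec:
            d = np.asarray(direction, float)
            if d.shape != (n_atoms, 3):
                raise ValueError("mode direction field must be (n_atoms, 3)")
            v = d.ravel()
            v = v - q @ (q.T @ v)
            nrm = np.linalg.norm(v)
            if nrm < 1e-9:
                raise ValueError("mode direction lies in the rigid-body subspace")
            modes.append((v / nrm).reshape(n_atoms, 3))
            variances.append(float(var))

    base_xyz = base_xyz0
    frames = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        x = base_xyz.copy()
        for d, var in zip(modes, variances):
            x = x + d * rng.normal(0.0, math.sqrt(var))
        x = x + rng.normal(0.0, 1.0, size=(n_atoms, 3)) * atom_amp[:, None]
        if rigid_motion:
            from scipy.spatial.transform import Rotation
            rot = Rotation.random(random_state=rng)
            x = rot.apply(x) + rng.normal(0.0, 5.0, size=3)
        frames[f] = x

    # expected Cα RMSF per residue
    ca_atom = np.full(n_res, -1)
    for i, a in enumerate(base.atoms):
        if a.name == "CA" and ca_atom[atom_res[i]] < 0:
            ca_atom[atom_res[i]] = i
    expected = np.zeros(n_res)
    for r in range(n_res):
        i = ca_atom[r]
        if i < 0:
            continue
        var = 3.0 * amp[r] ** 2
        for d, v in zip(modes, variances):
            var += v * float(np.sum(d[i] ** 2))
        expected[r] = math.sqrt(var)

    gt = GroundTruth(kind="ensemble", designed_rmsf=expected,
                     designed_mode_variances=variances,
                     params={"n_frames": n_frames, "seed": seed,
                             "rigid_motion": rigid_motion})

    # generation self-checks
    if not modes and np.all(amp == 0) and not rigid_motion:
        if not np.allclose(frames, frames[0]):
            raise RuntimeError("zero-amplitude ensemble is not rigid")
    if n_frames >= 200 and not rigid_motion:
        emp = np.sqrt(np.mean(np.sum(
            (frames - frames.mean(axis=0)) ** 2, axis=2), axis=0))
        ca_ok = ca_atom >= 0
        design = expected[ca_ok]
        meas = emp[ca_atom[ca_ok]]
        scale = max(design.max(), 1e-9)
        if np.max(np.abs(meas - design)) > 0.2 * scale + 1e-9:
            raise RuntimeError("ensemble self-check failed: empirical RMSF "
                               "deviates from the designed profile")
    return Ensemble(base, frames), gt
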