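"""Ensemble observables: superposition, RMSD/RMSF, H-bond series, salt
bridges and Cα principal component analysis (essential dynamics).

All fits use the Kabsch least-squares superposition (proper rotation
enforced).  RMSF is computed about the iterated mean structure (two passes of
fit-to-mean), and PCA is the eigendecomposition of the 3N×3N positional
covariance of the superposed frames; a mode's *contribution* is its
eigenvalue's percentage of the total variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Ensemble, Structure
from .hbond_wrapping import extract_bhb, DEFAULT_ENERGY_CUTOFF

__all__ = [
    "SuperpositionResult",
    "FlexibilityProfile",
    "SaltBridgeRecord",
    "PCAResult",
    "superpose",
    "rmsd_series",
    "rmsf",
    "hbond_series",
    "salt_bridges",
    "pca",
]

#: charged side-chain atoms considered for salt bridges
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2")}
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # 3-vector, Å
    rmsd: float               # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class FlexibilityProfile:
    rmsd_series: np.ndarray         # per frame, Å
    rmsf_per_residue: np.ndarray    # per selected atom/residue, Å
    selection: str


@dataclass
class SaltBridgeRecord:
    acidic_residue: tuple          # residue key
    basic_residue: tuple
    acidic_name: str
    basic_name: str
    min_atom_pair: tuple[str, str]
    distance: float                # Å (min over frames for ensembles)
    occupancy: float               # fraction of frames formed


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # Å², descending
    eigenvectors: np.ndarray       # (n_modes, 3N), orthonormal rows
    contribution_pct: np.ndarray   # per mode, sums to 100
    mean: np.ndarray               # (N, 3) mean structure of the fit


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def superpose(reference: np.ndarray, mobile: np.ndarray,
              weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted Kabsch fit of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimising the weighted
    RMSD of ``mobile @ R.T + t`` to ``reference``.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    ref_c = ref - (w[:, None] * ref).sum(axis=0)
    mob_c = mob - (w[:, None] * mob).sum(axis=0)
    # collinearity guard: rank of the weighted covariance
    cov = (w[:, None] * mob_c).T @ ref_c
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    fitted = mob_c @ rot.T
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - ref_c) ** 2, axis=1))))
    translation = (w[:, None] * ref).sum(axis=0) - (w[:, None] * mob).sum(axis=0) @ rot.T
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def _selection_mask(topology: Structure, selection) -> np.ndarray:
    """Selection: None (all atoms), "CA", an iterable of atom indices, or a
    boolean mask."""
    n = len(topology.atoms)
    if selection is None:
        return np.ones(n, dtype=bool)
    if isinstance(selection, str):
        name = selection.upper()
        if name in ("CA", "CALPHA"):
            return np.array([a.name == "CA" and not a.is_hetatm for a in topology.atoms])
        raise ValueError(f"unknown selection string {selection!r}")
    sel = np.asarray(selection)
    if sel.dtype == bool:
        if sel.shape != (n,):
            raise ValueError("boolean selection mask has wrong length")
        return sel
    mask = np.zeros(n, dtype=bool)
    mask[sel.astype(int)] = True
    return mask


def rmsd_series(ensemble: Ensemble, reference_frame: int = 0,
                selection="CA") -> np.ndarray:
    """Per-frame RMSD to a reference frame after per-frame Kabsch fit,
    both fit and measurement over the selection."""
    mask = _selection_mask(ensemble.topology, selection)
    if mask.sum() == 0:
        raise ValueError("empty selection")
    ref = ensemble.frames[reference_frame][mask]
    out = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        out[i] = superpose(ref, ensemble.frames[i][mask]).rmsd
    return out


def _fit_frames_to_mean(frames: np.ndarray, passes: int = 2) -> np.ndarray:
    fitted = frames.copy()
    mean = fitted[0]
    for _ in range(passes):
        for i in range(fitted.shape[0]):
            sp = superpose(mean, fitted[i])
            fitted[i] = sp.apply(fitted[i])
        mean = fitted.mean(axis=0)
    return fitted


def rmsf(ensemble: Ensemble, selection="CA", fit_selection=None) -> np.ndarray:
    """Per-selected-atom RMSF about the iterated mean structure (2 passes).

    ``fit_selection`` (default: the measurement selection) chooses the atoms
    used for the superposition.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mask = _selection_mask(ensemble.topology, selection)
    fit_mask = mask if fit_selection is None else _selection_mask(ensemble.topology, fit_selection)
    if mask.sum() == 0 or fit_mask.sum() == 0:
        raise ValueError("empty selection")
    # fit on fit_mask, carry the per-frame transform to the measured selection
    frames = np.empty((ensemble.n_frames, int(mask.sum()), 3))
    mean_fit = ensemble.frames[:, fit_mask, :].copy()
    mean = mean_fit[0]
    for _ in range(2):
        for i in range(ensemble.n_frames):
            sp = superpose(mean, ensemble.frames[i][fit_mask])
            mean_fit[i] = sp.apply(ensemble.frames[i][fit_mask])
            frames[i] = sp.apply(ensemble.frames[i][mask])
        mean = mean_fit.mean(axis=0)
    mean_pos = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean_pos) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# hydrogen-bond time series
# ---------------------------------------------------------------------------

_DONOR_SIDE = {"SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "LYS": ("NZ",),
               "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",), "GLN": ("NE2",),
               "HIS": ("ND1", "NE2"), "TRP": ("NE1",)}
_ACCEPTOR_SIDE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
                  "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
                  "HIS": ("ND1", "NE2")}


def _geometric_hbond_count(structure: Structure, dist_cutoff: float = 3.5,
                           angle_cutoff: float = 120.0) -> int:
    """Donor-acceptor pairs < 3.5 Å with antecedent-donor-acceptor angle
    > 120° (side-chain-inclusive geometric criterion)."""
    donors = []    # (donor atom, antecedent atom)
    acceptors = []
    residues = structure.residues()
    for idx, r in enumerate(residues):
        if r.coord("N") is not None and r.name != "PRO":
            ante = r.coord("CA")
            if ante is not None:
                donors.append((r, "N", ante))
        for name in _DONOR_SIDE.get(r.name, ()):
            if r.coord(name) is not None:
                heavy = [a for a in r.atoms.values()
                         if not a.is_hydrogen and a.name != name]
                if heavy:
                    nearest = min(heavy, key=lambda a: np.linalg.norm(a.coords - r.coord(name)))
                    donors.append((r, name, nearest.coords))
        if r.coord("O") is not None:
            acceptors.append((r, "O"))
        for name in _ACCEPTOR_SIDE.get(r.name, ()):
            if r.coord(name) is not None:
                acceptors.append((r, name))
    if not donors or not acceptors:
        return 0
    acc_xyz = np.array([r.coord(nm) for r, nm in acceptors])
    tree = cKDTree(acc_xyz)
    count = 0
    for r, dname, ante in donors:
        d = r.coord(dname)
        for j in tree.query_ball_point(d, dist_cutoff):
            ra, aname = acceptors[j]
            if ra.key == r.key:
                continue
            v1 = ante - d
            v2 = acc_xyz[j] - d
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle > angle_cutoff:
                count += 1
    return count


def hbond_series(ensemble: Ensemble, energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
                 mode: str = "backbone") -> np.ndarray:
    """Per-frame intramolecular H-bond count.

    ``mode="backbone"`` counts Kabsch–Sander backbone bonds (consistent with
    the wrapping stage); ``mode="all"`` uses a geometric criterion
    (donor-acceptor < 3.5 Å, angle > 120°) including side chains.
    """
    out = np.empty(ensemble.n_frames, dtype=int)
    for i in range(ensemble.n_frames):
        frame = ensemble.frame_structure(i)
        if mode == "backbone":
            out[i] = len(extract_bhb(frame, energy_cutoff=energy_cutoff))
        elif mode == "all":
            out[i] = _geometric_hbond_count(frame)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------

def salt_bridges(obj: Structure | Ensemble,
                 cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF) -> list[SaltBridgeRecord]:
    """Acidic/basic side-chain pairs whose charged heavy atoms come within
    ``cutoff`` Å; for ensembles, occupancy is the fraction of frames formed."""
    if isinstance(obj, Structure):
        ensemble = Ensemble(obj, obj.coords()[None, :, :])
    else:
        ensemble = obj
    topo = ensemble.topology
    residues = topo.residues()
    acidic = [(r, nm) for r in residues for nm in ACIDIC_ATOMS.get(r.name, ())
              if nm in r.atoms]
    basic = [(r, nm) for r in residues for nm in BASIC_ATOMS.get(r.name, ())
             if nm in r.atoms]
    if not acidic or not basic:
        return []
    atom_index = {id(a): i for i, a in enumerate(topo.atoms)}
    a_idx = np.array([atom_index[id(r.atoms[nm])] for r, nm in acidic])
    b_idx = np.array([atom_index[id(r.atoms[nm])] for r, nm in basic])

    pair_stats: dict[tuple, dict] = {}
    n_frames = ensemble.n_frames
    for f in range(n_frames):
        xyz = ensemble.frames[f]
        d = np.linalg.norm(xyz[a_idx][:, None, :] - xyz[b_idx][None, :, :], axis=2)
        # minimum distance per residue pair in this frame
        frame_min: dict[tuple, tuple[float, tuple[str, str]]] = {}
        for i, (ra, na) in enumerate(acidic):
            for j, (rb, nb) in enumerate(basic):
                if ra.key == rb.key:
                    continue
                key = (ra.key, rb.key)
                if key not in frame_min or d[i, j] < frame_min[key][0]:
                    frame_min[key] = (float(d[i, j]), (na, nb))
        for key, (dist, pair) in frame_min.items():
            rec = pair_stats.setdefault(key, {"formed": 0, "best": (np.inf, pair)})
            if dist <= cutoff:
                rec["formed"] += 1
            if dist < rec["best"][0]:
                rec["best"] = (dist, pair)

    res_by_key = {r.key: r for r in residues}
    out = []
    for (ka, kb), rec in pair_stats.items():
        if rec["formed"] == 0:
            continue
        out.append(SaltBridgeRecord(
            acidic_residue=ka, basic_residue=kb,
            acidic_name=res_by_key[ka].name, basic_name=res_by_key[kb].name,
            min_atom_pair=rec["best"][1], distance=rec["best"][0],
            occupancy=rec["formed"] / n_frames))
    out.sort(key=lambda r: (r.acidic_residue, r.basic_residue))
    return out


# ---------------------------------------------------------------------------
# PCA / essential dynamics
# ---------------------------------------------------------------------------

def pca(ensemble: Ensemble, selection="CA", n_modes: int | None = None) -> PCAResult:
    """PCA of the positional covariance of the superposed selection.

    Frames are fitted to the iterated mean structure, the 3N-dimensional
    covariance is diagonalised (via SVD of the centred frame matrix), and each
    mode's contribution is its eigenvalue's share of the total variance.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    mask = _selection_mask(ensemble.topology, selection)
    if mask.sum() == 0:
        raise ValueError("empty selection")
    fitted = _fit_frames_to_mean(ensemble.frames[:, mask, :])
    mean = fitted.mean(axis=0)
    x = (fitted - mean).reshape(ensemble.n_frames, -1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2 / ensemble.n_frames
    if n_modes is not None:
        eigvals, vt = eigvals[:n_modes], vt[:n_modes]
    total = float((x ** 2).sum() / ensemble.n_frames)
    contrib = 100.0 * eigvals / total
    return PCAResult(eigenvalues=eigvals, eigenvectors=vt,
                     contribution_pct=contrib, mean=mean)
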