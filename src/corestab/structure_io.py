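"""Reading, writing and selecting protein structures and coordinate ensembles.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`AtomRecord` plus residue bookkeeping, and an :class:`Ensemble`
is one topology with a stack of coordinate frames.  PDB parsing and writing is
delegated to :mod:`gemmi`; this module only adapts between gemmi's hierarchy
and the flat records the analysis stages consume.

Conventions
-----------
* Coordinates are in Ångström; residue numbers are the author numbers from the
  file; all residue ranges are inclusive.
* Water and monoatomic ions are dropped on reading, except zinc, which is kept
  (p53-family domains coordinate a structural Zn2+) and listed in
  ``Structure.zinc_atoms``.
* Hydrogens present in a file are kept but ignored by heavy-atom analyses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "Ensemble",
    "StructureError",
    "read_structure",
    "read_ensemble",
    "write_pdb",
    "select",
    "classify_nonpolar_carbons",
]

#: Residue names treated as solvent/ions and excluded on reading (zinc is kept).
_EXCLUDED_HET = {"HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "CA", "SO4", "PO4", "GOL", "EDO"}

#: Maximum heavy-atom distance regarded as a covalent bond (upper bound for C-S).
COVALENT_CUTOFF = 1.9


class StructureError(ValueError):
    """Raised for unreadable, inconsistent or empty structural input."""


@dataclass
class AtomRecord:
    """One atom of a structure (PDB ATOM/HETATM record)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetatm: bool = False
    is_nonpolar_carbon: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """A view of one residue: its atoms indexed by atom name."""

    chain_id: str
    seq: int
    insertion_code: str
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    #: linear index of the residue within its chain (gap-free, used for
    #: sequence-separation rules; author numbering may have gaps)
    chain_index: int = 0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.insertion_code)

    def coord(self, atom_name: str) -> np.ndarray | None:
        a = self.atoms.get(atom_name)
        return None if a is None else a.coords

    @property
    def has_backbone(self) -> bool:
        return all(n in self.atoms for n in ("N", "CA", "C", "O"))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}{self.seq}{self.insertion_code}:{self.chain_id}"


class Structure:
    """An ordered collection of atoms with residue/chain bookkeeping."""

    def __init__(self, atoms: list[AtomRecord], source_id: str = "",
                 resolution_note: str | None = None):
        self.atoms = list(atoms)
        self.source_id = source_id
        self.resolution_note = resolution_note
        self.zinc_atoms: list[AtomRecord] = [a for a in self.atoms if a.element == "ZN"]
        self._check_unique()

    def _check_unique(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            k = (a.chain_id, a.residue_seq, a.insertion_code, a.name, a.altloc)
            if k in seen:
                raise StructureError(f"duplicate atom {k}")
            seen.add(k)

    # -- basic views ------------------------------------------------------
    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms])

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def residues(self) -> list[Residue]:
        """Residues in file order, with per-chain linear indices."""
        out: list[Residue] = []
        current: Residue | None = None
        chain_counter: dict[str, int] = {}
        for a in self.atoms:
            if current is None or a.residue_key != current.key:
                idx = chain_counter.get(a.chain_id, 0)
                chain_counter[a.chain_id] = idx + 1
                current = Residue(a.chain_id, a.residue_seq, a.insertion_code,
                                  a.residue_name, {}, chain_index=idx)
                out.append(current)
            current.atoms.setdefault(a.name, a)
        return out

    def residue(self, chain_id: str, seq: int, insertion_code: str = "") -> Residue:
        for r in self.residues():
            if r.key == (chain_id, seq, insertion_code):
                return r
        raise StructureError(f"residue {chain_id}/{seq}{insertion_code} not found")

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure carrying new coordinates (same atom set)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape does not match atom count")
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        s = Structure.__new__(Structure)
        s.atoms = atoms
        s.source_id = self.source_id
        s.resolution_note = self.resolution_note
        s.zinc_atoms = [a for a in atoms if a.element == "ZN"]
        return s

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Structure {self.source_id or '?'}: {len(self.atoms)} atoms, chains {self.chains}>"


@dataclass
class Ensemble:
    """An ordered set of coordinate frames over a fixed atom set."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_labels: list | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise StructureError("ensemble needs >= 1 frame of shape (n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise StructureError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _element_of(atom: gemmi.Atom, residue_name: str) -> str:
    el = atom.element.name.upper()
    if el and el not in ("X",):
        return el
    # infer from the atom name: strip digits/primes, first letter is element
    # (protein context: two-letter metals are given in full in the name)
    name = atom.name.strip().lstrip("0123456789")
    if residue_name.strip() in ("ZN",):
        return "ZN"
    return name[:1].upper() if name else "X"


def _resolve_altlocs(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy == "all":
        return atoms
    if policy != "best":
        raise ValueError(f"unknown altloc policy {policy!r}")
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        k = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            # keep the highest occupancy; ties resolved by altloc order ('A' first)
            if (a.occupancy, -ord(a.altloc or "~")) > (b.occupancy, -ord(b.altloc or "~")):
                best[k] = a
    out = []
    for k in order:
        a = best[k]
        out.append(replace(a, altloc=""))
    return out


def _model_atoms(model: gemmi.Model, include_hetatm_zinc: bool = True) -> list[AtomRecord]:
    records: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            resname = res.name.strip()
            is_het = res.het_flag == "H"
            if is_het and resname in _EXCLUDED_HET:
                continue
            if is_het and resname == "ZN" and not include_hetatm_zinc:
                continue
            for atom in res:
                el = _element_of(atom, resname)
                records.append(AtomRecord(
                    serial=atom.serial,
                    name=atom.name.strip(),
                    element=el,
                    residue_name=resname,
                    residue_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    chain_id=chain.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=float(np.clip(atom.occ, 0.0, 1.0)),
                    altloc=(atom.altloc or "").strip("\x00 ").strip(),
                    is_hetatm=is_het,
                ))
    return records


def read_structure(path: str | os.PathLike, model_index: int = 0,
                   altloc_policy: str = "best") -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    model_index : 0-based index into the file's MODEL records (0 = first).
    altloc_policy : ``"best"`` keeps the highest-occupancy conformer per atom
        (ties resolved toward altloc ``A``); ``"all"`` keeps every conformer.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")
    if not 0 <= model_index < len(st):
        raise IndexError(f"{path}: model index {model_index} out of range (file has {len(st)})")
    atoms = _resolve_altlocs(_model_atoms(st[model_index]), altloc_policy)
    if not any(not a.is_hetatm for a in atoms):
        raise StructureError(f"{path}: no protein atoms")
    note = None
    if st.resolution:
        note = f"resolution {st.resolution:.2f} A"
    return Structure(atoms, source_id=st.name or os.path.basename(str(path)),
                     resolution_note=note)


def read_ensemble(paths: list[str | os.PathLike] | str | os.PathLike) -> Ensemble:
    """Read one or more (multi-)MODEL PDB files as a coordinate ensemble.

    Frames are concatenated in argument order; every frame must carry the same
    atom set in the same order as the first one.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    topology: Structure | None = None
    key: list[tuple] | None = None
    frames: list[np.ndarray] = []
    for p in paths:
        st = gemmi.read_pdb(str(p))
        if len(st) == 0:
            raise StructureError(f"{p}: no models found")
        for model in st:
            atoms = _resolve_altlocs(_model_atoms(model), "best")
            k = [(a.chain_id, a.residue_seq, a.insertion_code, a.name) for a in atoms]
            if topology is None:
                topology = Structure(atoms, source_id=os.path.basename(str(p)))
                key = k
            elif k != key:
                raise StructureError(f"{p}: atom set differs from the first frame")
            frames.append(np.array([a.coords for a in atoms]))
    assert topology is not None
    return Ensemble(topology, np.stack(frames))


def _to_gemmi(structure: Structure, frames: np.ndarray | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.source_id or "CORESTAB"
    frame_list = [structure.coords()] if frames is None else list(frames)
    for m_i, coords in enumerate(frame_list, start=1):
        # gemmi's add_* methods copy, so build each level bottom-up
        model = gemmi.Model(m_i)
        groups: list[tuple[str, list[tuple[AtomRecord, np.ndarray]]]] = []
        for a, xyz in zip(structure.atoms, coords):
            if not groups or groups[-1][0] != a.chain_id:
                groups.append((a.chain_id, []))
            groups[-1][1].append((a, xyz))
        for chain_id, members in groups:
            chain = gemmi.Chain(chain_id)
            res = None
            last_key = None
            for a, xyz in members:
                if a.residue_key != last_key:
                    if res is not None:
                        chain.add_residue(res)
                    res = gemmi.Residue()
                    res.name = a.residue_name
                    res.seqid = gemmi.SeqId(a.residue_seq, a.insertion_code or " ")
                    res.het_flag = "H" if a.is_hetatm else "A"
                    last_key = a.residue_key
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element.capitalize())
                at.pos = gemmi.Position(*map(float, xyz))
                at.occ = a.occupancy
                at.altloc = a.altloc or "\x00"
                res.add_atom(at)
            if res is not None:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(obj: Structure | Ensemble, path: str | os.PathLike) -> None:
    """Write a structure (single MODEL) or ensemble (one MODEL per frame)."""
    if isinstance(obj, Ensemble):
        st = _to_gemmi(obj.topology, obj.frames)
    else:
        st = _to_gemmi(obj)
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _match(a: AtomRecord, chain, residue_range, atom_names) -> bool:
    if chain is not None and a.chain_id != chain:
        return False
    if residue_range is not None:
        lo, hi = residue_range
        if not (lo <= a.residue_seq <= hi):
            return False
    if atom_names is not None and a.name not in atom_names:
        return False
    return True


def select(obj: Structure | Ensemble, chain: str | None = None,
           residue_range: tuple[int, int] | None = None,
           atom_names=None) -> Structure | Ensemble:
    """Subset a structure or ensemble by chain, inclusive residue range
    and/or atom names. Returns the same kind of object."""
    if residue_range is not None and residue_range[0] > residue_range[1]:
        raise ValueError(f"malformed residue range {residue_range}")
    if atom_names is not None:
        atom_names = set(atom_names)
    structure = obj.topology if isinstance(obj, Ensemble) else obj
    if chain is not None and chain not in structure.chains:
        raise StructureError(f"chain {chain!r} not present (have {structure.chains})")
    mask = [_match(a, chain, residue_range, atom_names) for a in structure.atoms]
    atoms = [a for a, m in zip(structure.atoms, mask) if m]
    sub = Structure(atoms, source_id=structure.source_id,
                    resolution_note=structure.resolution_note)
    if isinstance(obj, Ensemble):
        return Ensemble(sub, obj.frames[:, np.array(mask, dtype=bool), :],
                        frame_labels=obj.frame_labels)
    return sub


# ---------------------------------------------------------------------------
# chemistry flags
# ---------------------------------------------------------------------------

def classify_nonpolar_carbons(structure: Structure) -> Structure:
    """Flag nonpolar ("carbonaceous CH") carbons in place and return the structure.

    A carbon is nonpolar iff none of its covalently bonded heavy neighbours
    (heavy-heavy distance < 1.9 Å) is N, O or S.  Isolated carbons are
    nonpolar; non-carbons are always False.  Order-independent.
    """
    heavy = structure.heavy_atoms
    if heavy:
        xyz = np.array([a.coords for a in heavy])
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(COVALENT_CUTOFF)
        polar_neighbour = [False] * len(heavy)
        for i, j in pairs:
            if heavy[j].element in ("N", "O", "S"):
                polar_neighbour[i] = True
            if heavy[i].element in ("N", "O", "S"):
                polar_neighbour[j] = True
        flags = {id(a): (a.element == "C" and not polar_neighbour[i])
                 for i, a in enumerate(heavy)}
    else:
        flags = {}
    for a in structure.atoms:
        a.is_nonpolar_carbon = flags.get(id(a), False)
    return structure
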