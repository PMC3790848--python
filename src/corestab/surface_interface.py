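"""Solvent-accessible surface areas, interface residues, interface propensity.

SASA is computed with the Shrake–Rupley method: each heavy atom carries a
deterministic quasi-uniform point set on its solvent-expanded sphere of radius
``r_vdw + probe``; the accessible area is the unoccluded point fraction times
the sphere area.  The point set is a generalised (golden-section) spiral so
results are bit-reproducible without a random seed.

Interface residues of a two-component complex are those losing at least 10%
of the SASA they have in their isolated component (same coordinates, partner
atoms deleted — the POPSCOMP-style operation).  Interface propensity of an
amino-acid type is the fraction of its occurrences, pooled over a dataset of
complexes, that are interface residues; an optional exposure filter restricts
both numerator and denominator to residues whose isolated-component SASA
reaches a minimum area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, Structure, StructureError

__all__ = [
    "SasaTable",
    "InterfaceCall",
    "PropensityTable",
    "VDW_RADII",
    "sasa",
    "residue_exposure",
    "interface_residues",
    "interface_propensity",
    "exposure_statistics",
]

#: Chothia-type van der Waals radii (Å) used for SASA.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "ZN": 1.39, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
#: inclusive relative SASA reduction that makes a residue an interface residue
INTERFACE_REDUCTION = 0.10


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (generalised spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaTable:
    """Per-atom and per-residue solvent-accessible areas of one structure."""

    per_atom: dict[int, float]              # heavy-atom index (into structure.atoms) -> Å²
    per_residue: dict[tuple, float]         # residue key (chain, seq, icode) -> Å²
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_atom.values()))

    def residue_area(self, chain_id: str, seq: int, insertion_code: str = "") -> float:
        key = (chain_id, seq, insertion_code)
        if key not in self.per_residue:
            raise StructureError(f"residue {key} not in SASA table")
        return self.per_residue[key]


@dataclass
class InterfaceCall:
    """Interface decision for one residue of a two-component complex."""

    complex_id: str
    residue_key: tuple
    residue_name: str
    sasa_isolated: float
    sasa_in_complex: float
    relative_reduction: float
    is_interface: bool


@dataclass
class PropensityTable:
    """Interface-propensity counts per amino-acid type."""

    per_aa: dict[str, dict]                 # 3-letter code -> {n_total, n_interface, p}
    exposure_filter: float | None = None

    def p(self, aa: str) -> float | None:
        rec = self.per_aa.get(aa.upper())
        return None if rec is None else rec["p"]


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _radii_for(structure: Structure) -> tuple[list[int], np.ndarray, np.ndarray]:
    idx, xyz, rad = [], [], []
    for i, a in enumerate(structure.atoms):
        if a.is_hydrogen:
            continue
        r = VDW_RADII.get(a.element.upper())
        if r is None:
            raise StructureError(f"no van der Waals radius for element {a.element!r}")
        idx.append(i)
        xyz.append(a.coords)
        rad.append(r)
    return idx, np.asarray(xyz, dtype=float), np.asarray(rad, dtype=float)


def sasa(structure: Structure, probe_radius: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS) -> SasaTable:
    """Shrake–Rupley SASA over heavy atoms.

    Per-atom area is ``(unoccluded points / n_points) * 4π (r_vdw + probe)²``;
    per-residue areas sum the residue's atoms (whole-residue convention,
    backbone plus side chain).
    """
    idx, xyz, rad = _radii_for(structure)
    if len(idx) == 0:
        raise StructureError("no heavy atoms to compute SASA for")
    ext = rad + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(xyz)
    per_atom: dict[int, float] = {}
    max_ext = ext.max()
    for k in range(len(idx)):
        pts = xyz[k] + ext[k] * unit
        neighbours = tree.query_ball_point(xyz[k], ext[k] + max_ext)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            if j == k:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
            if not accessible.any():
                break
        area = accessible.sum() / n_points * 4.0 * math.pi * ext[k] ** 2
        per_atom[idx[k]] = float(area)
    per_residue: dict[tuple, float] = {}
    for i, area in per_atom.items():
        key = structure.atoms[i].residue_key
        per_residue[key] = per_residue.get(key, 0.0) + area
    return SasaTable(per_atom=per_atom, per_residue=per_residue,
                     probe_radius=probe_radius, n_sphere_points=n_points)


def residue_exposure(structure: Structure, chain_id: str, seq: int,
                     insertion_code: str = "", table: SasaTable | None = None,
                     **sasa_kwargs) -> float:
    """Whole-residue (backbone + side-chain) SASA of one residue, Å²."""
    if table is None:
        table = sasa(structure, **sasa_kwargs)
    return table.residue_area(chain_id, seq, insertion_code)


# ---------------------------------------------------------------------------
# interfaces
# ---------------------------------------------------------------------------

def _component(structure: Structure, chains: set[str]) -> Structure:
    atoms = [a for a in structure.atoms if a.chain_id in chains]
    return Structure(atoms, source_id=structure.source_id)


def interface_residues(complex_structure: Structure,
                       partition: tuple[set[str] | list[str], set[str] | list[str]],
                       probe_radius: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS,
                       reduction: float = INTERFACE_REDUCTION) -> list[InterfaceCall]:
    """Interface residues of a complex by the 10%-SASA-reduction rule.

    ``partition`` assigns every chain of the complex to one of two components.
    Each residue's SASA is compared between the whole complex and its isolated
    component at the same coordinates; a relative reduction of at least
    ``reduction`` (inclusive) makes it an interface residue.  Residues with
    zero isolated SASA are never interface residues.
    """
    side_a, side_b = (set(partition[0]), set(partition[1]))
    chains = set(complex_structure.chains)
    if not side_a or not side_b or (side_a | side_b) != chains or (side_a & side_b):
        raise ValueError(
            f"partition {partition} must split the complex chains {sorted(chains)} "
            "into two non-empty disjoint components")
    table_complex = sasa(complex_structure, probe_radius, n_points)
    calls: list[InterfaceCall] = []
    for comp in (side_a, side_b):
        iso = _component(complex_structure, comp)
        table_iso = sasa(iso, probe_radius, n_points)
        for res in iso.residues():
            a_iso = table_iso.per_residue.get(res.key, 0.0)
            a_cpx = table_complex.per_residue.get(res.key, 0.0)
            if a_iso > 0:
                red = (a_iso - a_cpx) / a_iso
            else:
                red = 0.0
            calls.append(InterfaceCall(
                complex_id=complex_structure.source_id,
                residue_key=res.key,
                residue_name=res.name,
                sasa_isolated=a_iso,
                sasa_in_complex=a_cpx,
                relative_reduction=red,
                is_interface=bool(a_iso > 0 and red >= reduction),
            ))
    return calls


def interface_propensity(dataset, exposure_min: float | None = None,
                         **kwargs) -> PropensityTable:
    """Interface propensity per amino-acid type over a dataset of complexes.

    ``dataset`` is a list of ``(complex_structure, partition)`` pairs or,
    directly, of precomputed ``list[InterfaceCall]``.  With ``exposure_min``
    set, only residues whose isolated-component SASA is at least that many Å²
    enter the counts (numerator and denominator alike).  Types whose
    denominator is empty are reported with ``p = None``.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("interface propensity requires a non-empty dataset")
    counts: dict[str, dict] = {}
    for item in dataset:
        if isinstance(item, tuple) and isinstance(item[0], Structure):
            calls = interface_residues(item[0], item[1], **kwargs)
        else:
            calls = item
        for c in calls:
            if exposure_min is not None and c.sasa_isolated < exposure_min:
                continue
            rec = counts.setdefault(c.residue_name, {"n_total": 0, "n_interface": 0})
            rec["n_total"] += 1
            rec["n_interface"] += int(c.is_interface)
    for rec in counts.values():
        rec["p"] = rec["n_interface"] / rec["n_total"] if rec["n_total"] else None
    return PropensityTable(per_aa=counts, exposure_filter=exposure_min)


def exposure_statistics(dataset: list[Structure], residue_type: str,
                        **sasa_kwargs) -> tuple[float, float]:
    """Mean and population SD of whole-residue SASA over all instances of a type."""
    residue_type = residue_type.upper()
    areas: list[float] = []
    for s in dataset:
        table = sasa(s, **sasa_kwargs)
        for res in s.residues():
            if res.name == residue_type and res.key in table.per_residue:
                areas.append(table.per_residue[res.key])
    if not areas:
        raise ValueError(f"no {residue_type} residues in the dataset")
    arr = np.asarray(areas)
    return float(arr.mean()), float(arr.std())
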