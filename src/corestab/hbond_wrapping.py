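"""Backbone hydrogen bonds, their hydrophobic wrapping, and vulnerable bonds.

Backbone hydrogen bonds (BHBs) are called with the Kabsch–Sander electrostatic
model used by DSSP:

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond whenever ``E <= -0.5`` kcal/mol.  Crystal structures carry no
hydrogens, so the amide H is reconstructed on the donor nitrogen, 1.00 Å along
the direction opposite the preceding residue's C→O bond (the DSSP convention).

The *wrapping* of a BHB is the number of nonpolar carbons ("hydrophobic CH
groups") inside its desolvation domain — the union of two 6.5 Å spheres
centred on the donor and acceptor Cα atoms.  Poorly wrapped bonds sit in the
low tail of the wrapping distribution of a background set of complexes and are
called *vulnerable* (dehydrons); the default tail threshold is a wrapping of
16 or fewer carbons, inclusive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, Structure, classify_nonpolar_carbons

__all__ = [
    "BackboneHBond",
    "WrappingProfile",
    "WrappingBackground",
    "place_amide_hydrogen",
    "kabsch_sander_energy",
    "extract_bhb",
    "wrapping_count",
    "wrapping_profile",
    "threshold_from_counts",
    "calibrate_threshold",
]

log = logging.getLogger(__name__)

#: Kabsch–Sander coupling constant q1*q2*332 (kcal/mol * Å)
KS_CONSTANT = 0.084 * 332  # = 27.888
#: DSSP floor on the bond energy (guards against near-contact singularities)
KS_ENERGY_FLOOR = -9.9
#: default bond-energy cutoff, kcal/mol
DEFAULT_ENERGY_CUTOFF = -0.5
#: default desolvation-sphere radius, Å
DEFAULT_SPHERE_RADIUS = 6.5
#: default vulnerability threshold (wrapping <= threshold -> vulnerable)
DEFAULT_VULNERABILITY_THRESHOLD = 16
#: minimum intra-chain donor/acceptor separation in chain positions
MIN_SEQ_SEPARATION = 2
#: donors whose Cα is farther than this from the acceptor Cα are not evaluated
CA_PRESCREEN = 9.0


class GeometryError(ValueError):
    """Raised when atoms are unphysically close for the energy model."""


@dataclass
class BackboneHBond:
    """One backbone N-H···O=C hydrogen bond."""

    donor: Residue
    acceptor: Residue
    energy: float  # kcal/mol
    wrapping: int | None = None
    vulnerable: bool | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"BHB({self.donor!r} -> {self.acceptor!r}, "
                f"E={self.energy:.2f}, w={self.wrapping})")


@dataclass
class WrappingProfile:
    """Per-structure wrapping summary: mean wrapping ρ and vulnerable bonds."""

    structure_id: str
    bonds: list[BackboneHBond]
    rho: float
    n_vulnerable: int
    threshold: int
    sphere_radius: float
    energy_cutoff: float


@dataclass
class WrappingBackground:
    """Pooled background wrapping distribution and its derived tail threshold."""

    source_ids: list[str]
    pooled_counts: list[int]
    derived_threshold: int
    tail_fraction: float

    @property
    def histogram(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in sorted(self.pooled_counts):
            out[c] = out.get(c, 0) + 1
        return out


# ---------------------------------------------------------------------------
# geometry / energy
# ---------------------------------------------------------------------------

def place_amide_hydrogen(residue: Residue, previous_residue: Residue | None) -> np.ndarray | None:
    """DSSP-style amide hydrogen: 1.00 Å from N, anti to the previous C→O.

    Returns ``None`` for prolines, chain-initial residues, and residues whose
    own N or the previous residue's C/O are missing (such donors are skipped).
    """
    if residue.name == "PRO" or previous_residue is None:
        return None
    n = residue.coord("N")
    c_prev = previous_residue.coord("C")
    o_prev = previous_residue.coord("O")
    if n is None or c_prev is None or o_prev is None:
        log.warning("cannot place amide H on %r: missing backbone atoms", residue)
        return None
    co = c_prev - o_prev
    norm = np.linalg.norm(co)
    if norm < 1e-6:
        return None
    return n + co / norm


def kabsch_sander_energy(donor: Residue, acceptor: Residue,
                         h_coord: np.ndarray | None = None) -> float:
    """Kabsch–Sander electrostatic H-bond energy, kcal/mol, floored at -9.9.

    ``h_coord`` is the donor amide-H position; if omitted the donor residue
    must carry an ``H`` atom.
    """
    n = donor.coord("N")
    h = h_coord if h_coord is not None else donor.coord("H")
    c = acceptor.coord("C")
    o = acceptor.coord("O")
    if n is None or h is None or c is None or o is None:
        raise GeometryError(f"incomplete donor/acceptor atoms for {donor!r}->{acceptor!r}")
    r_on = float(np.linalg.norm(o - n))
    r_ch = float(np.linalg.norm(c - h))
    r_oh = float(np.linalg.norm(o - h))
    r_cn = float(np.linalg.norm(c - n))
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        raise GeometryError(
            f"inter-atom distance < 0.5 A between {donor!r} and {acceptor!r}")
    e = KS_CONSTANT * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, KS_ENERGY_FLOOR)


# ---------------------------------------------------------------------------
# bond extraction
# ---------------------------------------------------------------------------

def _residue_tables(structure: Structure):
    residues = [r for r in structure.residues()
                if not r.atoms or not all(a.is_hetatm for a in r.atoms.values())]
    residues = [r for r in residues if r.name != "HOH"]
    by_chain: dict[str, list[Residue]] = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    prev: dict[tuple, Residue | None] = {}
    for chain_res in by_chain.values():
        for i, r in enumerate(chain_res):
            prev[r.key] = chain_res[i - 1] if i > 0 else None
    return residues, prev


def extract_bhb(structure: Structure,
                energy_cutoff: float = DEFAULT_ENERGY_CUTOFF) -> list[BackboneHBond]:
    """All backbone H-bonds with Kabsch–Sander energy ``<= energy_cutoff``.

    Donor/acceptor pairs are evaluated for |chain-position separation| >= 2
    within a chain and for every pair across chains; per DSSP convention at
    most the two lowest-energy acceptors are kept per donor.
    """
    residues, prev = _residue_tables(structure)
    donors = []
    for r in residues:
        h = place_amide_hydrogen(r, prev.get(r.key))
        if h is not None:
            donors.append((r, h))
    acceptors = [r for r in residues
                 if r.coord("C") is not None and r.coord("O") is not None]
    if not donors or not acceptors:
        return []

    acc_ca = np.array([(r.coord("CA") if r.coord("CA") is not None else r.coord("C"))
                       for r in acceptors])
    tree = cKDTree(acc_ca)

    per_donor: dict[tuple, list[BackboneHBond]] = {}
    for r, h in donors:
        d_ca = r.coord("CA") if r.coord("CA") is not None else r.coord("N")
        for j in tree.query_ball_point(d_ca, CA_PRESCREEN):
            a = acceptors[j]
            if a.key == r.key:
                continue
            if a.chain_id == r.chain_id and abs(a.chain_index - r.chain_index) < MIN_SEQ_SEPARATION:
                continue
            try:
                e = kabsch_sander_energy(r, a, h_coord=h)
            except GeometryError:
                log.warning("skipping clashing pair %r -> %r", r, a)
                continue
            if e <= energy_cutoff:
                per_donor.setdefault(r.key, []).append(BackboneHBond(r, a, e))

    bonds: list[BackboneHBond] = []
    for r, _h in donors:
        cand = sorted(per_donor.get(r.key, []), key=lambda b: b.energy)
        bonds.extend(cand[:2])
    return bonds


# ---------------------------------------------------------------------------
# wrapping
# ---------------------------------------------------------------------------

def wrapping_count(structure: Structure, bond: BackboneHBond,
                   radius: float = DEFAULT_SPHERE_RADIUS) -> int:
    """Nonpolar carbons inside the bond's desolvation domain.

    The domain is the union of two ``radius``-Å spheres centred on the donor
    and acceptor Cα; each qualifying atom is counted once, and the donor's and
    acceptor's own carbons participate.  Requires
    :func:`~corestab.structure_io.classify_nonpolar_carbons` to have run.
    """
    d_ca = bond.donor.coord("CA")
    a_ca = bond.acceptor.coord("CA")
    if d_ca is None or a_ca is None:
        raise GeometryError(f"missing CA for bond {bond!r}")
    count = 0
    for atom in structure.atoms:
        if not atom.is_nonpolar_carbon:
            continue
        x = atom.coords
        if (np.linalg.norm(x - d_ca) <= radius) or (np.linalg.norm(x - a_ca) <= radius):
            count += 1
    return count


def _wrapping_counts_fast(structure: Structure, bonds: list[BackboneHBond],
                          radius: float) -> list[int]:
    np_atoms = [a for a in structure.atoms if a.is_nonpolar_carbon]
    if not np_atoms:
        return [0] * len(bonds)
    tree = cKDTree(np.array([a.coords for a in np_atoms]))
    out = []
    for b in bonds:
        d_ca, a_ca = b.donor.coord("CA"), b.acceptor.coord("CA")
        if d_ca is None or a_ca is None:
            out.append(None)
            continue
        idx = set(tree.query_ball_point(d_ca, radius)) | set(tree.query_ball_point(a_ca, radius))
        out.append(len(idx))
    return out


def wrapping_profile(structure: Structure,
                     threshold: int = DEFAULT_VULNERABILITY_THRESHOLD,
                     radius: float = DEFAULT_SPHERE_RADIUS,
                     cutoff: float = DEFAULT_ENERGY_CUTOFF) -> WrappingProfile:
    """Full wrapping analysis of one structure (mean ρ, vulnerable bonds)."""
    classify_nonpolar_carbons(structure)
    bonds = extract_bhb(structure, energy_cutoff=cutoff)
    counts = _wrapping_counts_fast(structure, bonds, radius)
    kept: list[BackboneHBond] = []
    for b, w in zip(bonds, counts):
        if w is None:
            log.warning("bond %r has no CA; excluded from profile", b)
            continue
        b.wrapping = int(w)
        b.vulnerable = w <= threshold
        kept.append(b)
    rho = float(np.mean([b.wrapping for b in kept])) if kept else math.nan
    return WrappingProfile(
        structure_id=structure.source_id,
        bonds=kept,
        rho=rho,
        n_vulnerable=sum(1 for b in kept if b.vulnerable),
        threshold=threshold,
        sphere_radius=radius,
        energy_cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# background calibration
# ---------------------------------------------------------------------------

def threshold_from_counts(pooled_counts, tail_fraction: float) -> int:
    """Largest observed wrapping ``t`` with ``P(wrapping <= t) <= tail_fraction``.

    With ``tail_fraction = 0`` (or when even the smallest count exceeds the
    tail) the result falls one below the minimum observed count, so no bond is
    vulnerable at that threshold.
    """
    counts = np.array(sorted(int(c) for c in pooled_counts))
    if counts.size == 0:
        raise ValueError("empty wrapping distribution")
    if not 0.0 <= tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in [0, 1]")
    n = counts.size
    threshold = int(counts.min()) - 1
    for t in np.unique(counts):
        if np.sum(counts <= t) / n <= tail_fraction:
            threshold = int(t)
    return threshold


def calibrate_threshold(background, tail_fraction: float,
                        radius: float = DEFAULT_SPHERE_RADIUS,
                        cutoff: float = DEFAULT_ENERGY_CUTOFF) -> WrappingBackground:
    """Derive the vulnerability threshold from a background set of structures.

    ``background`` is a list of :class:`Structure` (their per-bond wrapping
    counts are pooled) or, directly, an iterable of pooled per-bond wrapping
    integers.  The threshold is the largest observed wrapping ``t`` such that
    the fraction of bonds with wrapping ``<= t`` does not exceed
    ``tail_fraction`` (see :func:`threshold_from_counts`).  Pooling is
    duplication-invariant: two copies of one structure give the same threshold
    as one.
    """
    background = list(background)
    if not background:
        raise ValueError("calibration requires a non-empty background")
    pooled: list[int] = []
    ids: list[str] = []
    if isinstance(background[0], Structure):
        for s in background:
            prof = wrapping_profile(s, radius=radius, cutoff=cutoff)
            pooled.extend(b.wrapping for b in prof.bonds)
            ids.append(s.source_id)
    else:
        pooled = [int(c) for c in background]
        ids = ["<counts>"]
    if not pooled:
        raise ValueError("background structures yielded no backbone H-bonds")
    threshold = threshold_from_counts(pooled, tail_fraction)
    return WrappingBackground(source_ids=ids, pooled_counts=pooled,
                              derived_threshold=threshold, tail_fraction=tail_fraction)
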