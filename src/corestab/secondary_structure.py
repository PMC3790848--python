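"""Secondary-structure assignment from backbone H-bond patterns.

The assigner applies the Kabsch–Sander pattern rules to the backbone H-bonds
called by :mod:`corestab.hbond_wrapping`: an *n-turn* at residue i is a bond
from the C=O of i to the N-H of i+n (n = 3, 4, 5); two consecutive n-turns
make a minimal 3₁₀/α/π helix (G/H/I); parallel and antiparallel bridge
patterns give bridges (B), and consecutive bridges form ladders (E); residues
inside an unassigned turn get T, the remainder coil (C).

Simplified classes: helix = {H, G, I}, sheet = {E, B}, other = {T, C}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure_io import Residue, Structure
from .hbond_wrapping import BackboneHBond, extract_bhb, DEFAULT_ENERGY_CUTOFF

__all__ = [
    "SSAssignment",
    "SSContent",
    "SSSegment",
    "assign_ss",
    "ss_content",
    "segments",
    "interstrand_hbonds",
]

HELIX_CLASSES = frozenset("HGI")
SHEET_CLASSES = frozenset("EB")


@dataclass
class SSContent:
    pct_helix: float
    pct_sheet: float
    pct_other: float


@dataclass
class SSSegment:
    """A maximal helix or strand run (label such as S1/H1, inclusive range)."""

    label: str
    ss_class: str                  # "helix" | "sheet"
    chain_id: str
    start_seq: int
    end_seq: int
    residue_keys: list[tuple]

    def contains(self, key: tuple) -> bool:
        return key in set(self.residue_keys)


@dataclass
class SSAssignment:
    """Per-residue secondary-structure classes for one structure."""

    residues: list[Residue]
    per_residue: dict[tuple, str]          # residue key -> class in HGIEBTC
    bonds: list[BackboneHBond] = field(default_factory=list)

    def simplified(self, key: tuple) -> str:
        c = self.per_residue[key]
        if c in HELIX_CLASSES:
            return "helix"
        if c in SHEET_CLASSES:
            return "sheet"
        return "other"


def _linear_tables(structure: Structure):
    residues = [r for r in structure.residues()
                if not all(a.is_hetatm for a in r.atoms.values())]
    index = {r.key: i for i, r in enumerate(residues)}
    contiguous = [False] * len(residues)  # contiguous[i]: residue i follows i-1 in chain
    for i in range(1, len(residues)):
        contiguous[i] = (residues[i].chain_id == residues[i - 1].chain_id
                         and residues[i].chain_index == residues[i - 1].chain_index + 1)
    return residues, index, contiguous


def assign_ss(structure: Structure,
              energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
              bonds: list[BackboneHBond] | None = None) -> SSAssignment:
    """Assign H/G/I/E/B/T/C classes from the backbone H-bond pattern."""
    residues, index, contiguous = _linear_tables(structure)
    n = len(residues)
    if bonds is None:
        bonds = extract_bhb(structure, energy_cutoff=energy_cutoff)
    # HB(i, j): C=O of residue i accepts the N-H of residue j
    hb: set[tuple[int, int]] = set()
    for b in bonds:
        ai, di = index.get(b.acceptor.key), index.get(b.donor.key)
        if ai is not None and di is not None:
            hb.add((ai, di))

    def run_ok(i: int, j: int) -> bool:
        """residues i..j are consecutive within one chain"""
        return 0 <= i and j < n and all(contiguous[k] for k in range(i + 1, j + 1))

    turn = {m: [False] * n for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(n - m):
            if (i, i + m) in hb and run_ok(i, i + m):
                turn[m][i] = True

    cls = ["C"] * n

    # α-helices first (two consecutive 4-turns -> residues i..i+3)
    for i in range(1, n):
        if turn[4][i - 1] and turn[4][i]:
            for k in range(i, i + 4):
                cls[k] = "H"
    # bridges and ladders
    bridges: list[tuple[int, int, str]] = []
    for i in range(n):
        for j in range(i + 3, n):
            par = (((i - 1, j) in hb and (j, i + 1) in hb and run_ok(i - 1, i + 1)) or
                   ((j - 1, i) in hb and (i, j + 1) in hb and run_ok(j - 1, j + 1)))
            anti = (((i, j) in hb and (j, i) in hb) or
                    ((i - 1, j + 1) in hb and (j - 1, i + 1) in hb
                     and run_ok(i - 1, i + 1) and run_ok(j - 1, j + 1)))
            if par:
                bridges.append((i, j, "P"))
            if anti:
                bridges.append((i, j, "A"))
    bridge_set = {(i, j, t) for i, j, t in bridges}
    for i, j, t in bridges:
        if t == "P":
            ladder = ((i + 1, j + 1, t) in bridge_set or (i - 1, j - 1, t) in bridge_set)
        else:
            ladder = ((i + 1, j - 1, t) in bridge_set or (i - 1, j + 1, t) in bridge_set)
        code = "E" if ladder else "B"
        for k in (i, j):
            if cls[k] == "C" or (code == "E" and cls[k] == "B"):
                cls[k] = code
    # shorter/longer helices (3-10 and pi)
    for m, code in ((3, "G"), (5, "I")):
        for i in range(1, n):
            if turn[m][i - 1] and turn[m][i]:
                for k in range(i, i + m):
                    if cls[k] == "C":
                        cls[k] = code
    # turns
    for m in (3, 4, 5):
        for i in range(n - m):
            if turn[m][i]:
                for k in range(i + 1, i + m):
                    if cls[k] == "C":
                        cls[k] = "T"

    per_residue = {r.key: c for r, c in zip(residues, cls)}
    return SSAssignment(residues=residues, per_residue=per_residue, bonds=bonds)


def ss_content(assignment: SSAssignment) -> SSContent:
    """Percentages of helix / sheet / other over all assigned residues."""
    if not assignment.residues:
        raise ValueError("empty assignment")
    total = len(assignment.residues)
    n_h = sum(1 for r in assignment.residues
              if assignment.per_residue[r.key] in HELIX_CLASSES)
    n_s = sum(1 for r in assignment.residues
              if assignment.per_residue[r.key] in SHEET_CLASSES)
    return SSContent(pct_helix=100.0 * n_h / total,
                     pct_sheet=100.0 * n_s / total,
                     pct_other=100.0 * (total - n_h - n_s) / total)


def segments(assignment: SSAssignment, min_strand: int = 2,
             min_helix: int = 4) -> list[SSSegment]:
    """Maximal helix/strand runs in sequence order, labelled S1.. / H1..

    Runs shorter than ``min_strand`` (sheet) or ``min_helix`` (helix) are
    dropped.
    """
    residues = assignment.residues
    runs: list[tuple[str, list[Residue]]] = []
    current_kind: str | None = None
    current: list[Residue] = []
    prev: Residue | None = None
    for r in residues:
        kind = assignment.simplified(r.key)
        broken = (prev is None or r.chain_id != prev.chain_id
                  or r.chain_index != prev.chain_index + 1)
        if kind in ("helix", "sheet") and kind == current_kind and not broken:
            current.append(r)
        else:
            if current_kind in ("helix", "sheet") and current:
                runs.append((current_kind, current))
            current_kind, current = kind, [r]
        prev = r
    if current_kind in ("helix", "sheet") and current:
        runs.append((current_kind, current))

    out: list[SSSegment] = []
    n_s = n_h = 0
    for kind, members in runs:
        if kind == "sheet" and len(members) < min_strand:
            continue
        if kind == "helix" and len(members) < min_helix:
            continue
        if kind == "sheet":
            n_s += 1
            label = f"S{n_s}"
        else:
            n_h += 1
            label = f"H{n_h}"
        out.append(SSSegment(label=label, ss_class=kind,
                             chain_id=members[0].chain_id,
                             start_seq=members[0].seq, end_seq=members[-1].seq,
                             residue_keys=[m.key for m in members]))
    return out


def interstrand_hbonds(structure: Structure, segment_a: SSSegment,
                       segment_b: SSSegment,
                       bonds: list[BackboneHBond] | None = None) -> int:
    """Backbone H-bonds (either direction) linking two disjoint segments."""
    keys_a, keys_b = set(segment_a.residue_keys), set(segment_b.residue_keys)
    if keys_a & keys_b:
        raise ValueError("segments overlap")
    if bonds is None:
        bonds = extract_bhb(structure)
    count = 0
    for b in bonds:
        d, a = b.donor.key, b.acceptor.key
        if (d in keys_a and a in keys_b) or (d in keys_b and a in keys_a):
            count += 1
    return count
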