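"""One-call stability profile of a structure: wrapping, secondary structure,
notable exposures and salt bridges, with a full parameter echo."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd

from .structure_io import Structure, read_structure, select
from .hbond_wrapping import (wrapping_profile, WrappingProfile,
                             DEFAULT_ENERGY_CUTOFF, DEFAULT_SPHERE_RADIUS,
                             DEFAULT_VULNERABILITY_THRESHOLD)
from .surface_interface import sasa, DEFAULT_PROBE, DEFAULT_N_POINTS
from .secondary_structure import assign_ss, ss_content, segments, SSContent
from .conformation_analysis import salt_bridges, SaltBridgeRecord, DEFAULT_SALT_BRIDGE_CUTOFF

log = logging.getLogger(__name__)

#: defaults and whether each comes from the published protocol or is a
#: package design decision
DEFAULT_CONFIG: dict[str, tuple] = {
    "radius": (DEFAULT_SPHERE_RADIUS, "paper"),
    "cutoff": (DEFAULT_ENERGY_CUTOFF, "paper"),
    "threshold": (DEFAULT_VULNERABILITY_THRESHOLD, "paper"),
    "probe": (DEFAULT_PROBE, "decision"),
    "n_points": (DEFAULT_N_POINTS, "decision"),
    "salt_bridge_cutoff": (DEFAULT_SALT_BRIDGE_CUTOFF, "decision"),
    "exposure_top_n": (5, "decision"),
}


@dataclass
class StabilityProfile:
    structure_id: str
    chain: str | None
    wrapping: WrappingProfile
    ss: SSContent
    notable_exposures: list[tuple]         # (chain, seq, name, Å²), largest first
    salt_bridges: list[SaltBridgeRecord]
    parameters: dict

    def summary(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "chain": self.chain,
            "rho": None if math.isnan(self.wrapping.rho) else round(self.wrapping.rho, 2),
            "n_bhb": len(self.wrapping.bonds),
            "n_vulnerable": self.wrapping.n_vulnerable,
            "threshold": self.wrapping.threshold,
            "pct_helix": round(self.ss.pct_helix, 1),
            "pct_sheet": round(self.ss.pct_sheet, 1),
            "pct_other": round(self.ss.pct_other, 1),
            "n_salt_bridges": len(self.salt_bridges),
            "notable_exposures": [
                {"chain": c, "seq": s, "name": n, "area_A2": round(a, 1)}
                for c, s, n, a in self.notable_exposures],
            "parameters": self.parameters,
        }


def _resolve_config(config: dict | None) -> dict:
    cfg = {k: v for k, (v, _src) in DEFAULT_CONFIG.items()}
    tags = {k: src for k, (_v, src) in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if k not in cfg:
            raise KeyError(f"unknown config key {k!r}")
        cfg[k] = v
        tags[k] = "override"
    cfg["_sources"] = tags
    return cfg


def profile(structure: Structure | str | os.PathLike, chain: str | None = "A",
            config: dict | None = None) -> StabilityProfile:
    """Run the full per-structure pipeline: ingest → classify → wrap →
    secondary structure → SASA → salt bridges.  Deterministic."""
    cfg = _resolve_config(config)
    if not isinstance(structure, Structure):
        structure = read_structure(structure)
    if chain is not None:
        if chain not in structure.chains:
            chain = structure.chains[0]
            log.warning("requested chain absent; falling back to %s", chain)
        structure = select(structure, chain=chain)
    try:
        wrap = wrapping_profile(structure, threshold=cfg["threshold"],
                                radius=cfg["radius"], cutoff=cfg["cutoff"])
    except Exception as exc:
        raise RuntimeError(f"stage 'wrapping' failed: {exc}") from exc
    try:
        assignment = assign_ss(structure, energy_cutoff=cfg["cutoff"],
                               bonds=wrap.bonds)
        content = ss_content(assignment)
    except Exception as exc:
        raise RuntimeError(f"stage 'secondary_structure' failed: {exc}") from exc
    try:
        table = sasa(structure, probe_radius=cfg["probe"], n_points=cfg["n_points"])
    except Exception as exc:
        raise RuntimeError(f"stage 'sasa' failed: {exc}") from exc
    try:
        bridges = salt_bridges(structure, cutoff=cfg["salt_bridge_cutoff"])
    except Exception as exc:
        raise RuntimeError(f"stage 'salt_bridges' failed: {exc}") from exc

    res_names = {r.key: r.name for r in structure.residues()}
    exposures = sorted(((k[0], k[1], res_names.get(k, "?"), a)
                        for k, a in table.per_residue.items()),
                       key=lambda t: -t[3])[:cfg["exposure_top_n"]]
    return StabilityProfile(
        structure_id=structure.source_id, chain=chain, wrapping=wrap,
        ss=content, notable_exposures=exposures, salt_bridges=bridges,
        parameters=cfg)


def write_report(p: StabilityProfile, out_dir: str | os.PathLike) -> None:
    """Write report.json plus wrap.tsv / saltbridges.tsv under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(p.summary(), fh, indent=1, default=str)
    pd.DataFrame([{
        "donor": f"{b.donor.chain_id}/{b.donor.seq}",
        "acceptor": f"{b.acceptor.chain_id}/{b.acceptor.seq}",
        "energy_kcal_mol": round(b.energy, 3),
        "wrapping": b.wrapping,
        "vulnerable": b.vulnerable,
    } for b in p.wrapping.bonds]).to_csv(
        os.path.join(out_dir, "wrap.tsv"), sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(b) for b in p.salt_bridges]).to_csv(
        os.path.join(out_dir, "saltbridges.tsv"), sep="\t", index=False)
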