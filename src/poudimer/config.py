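"""YAML/JSON system definitions for the equilibrium solver.

A system file has three blocks::

    proteins:
      - {name: Oct4, total_conc: 50.0, label: GFP}
    motifs:
      - {name: MORE, element_class: MORE, total_conc: 5.0, label: Cy5}
    reactions:
      - complex_id: Oct4_homodimer_MORE
        dna: MORE
        stoichiometry: {Oct4: 2}
        kd_steps: [20.0, 20.0]
        cooperativity: 10.0

Concentrations are nM; cooperativity defaults to 1.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .equilibrium import (
    BindingReaction,
    DnaMotifSpecies,
    EquilibriumSystem,
    ProteinSpecies,
)

__all__ = ["load_system", "dump_system"]


def load_system(path) -> EquilibriumSystem:
    """Read an equilibrium system from a YAML (or JSON) file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return system_from_dict(data)


def system_from_dict(data: dict) -> EquilibriumSystem:
    proteins = tuple(
        ProteinSpecies(p["name"], float(p["total_conc"]), p.get("label"))
        for p in data.get("proteins", [])
    )
    motifs = tuple(
        DnaMotifSpecies(
            d["name"], d["element_class"], float(d["total_conc"]), d.get("label")
        )
        for d in data.get("motifs", [])
    )
    reactions = tuple(
        BindingReaction(
            r["complex_id"],
            r["dna"],
            {k: int(v) for k, v in r["stoichiometry"].items()},
            tuple(float(k) for k in r["kd_steps"]),
            float(r.get("cooperativity", 1.0)),
        )
        for r in data.get("reactions", [])
    )
    return EquilibriumSystem(proteins, motifs, reactions)


def dump_system(system: EquilibriumSystem, path) -> None:
    """Write a system back out as YAML."""
    data = {
        "proteins": [
            {"name": p.name, "total_conc": p.total_conc, "label": p.label}
            for p in system.proteins
        ],
        "motifs": [
            {
                "name": d.name,
                "element_class": d.element_class,
                "total_conc": d.total_conc,
                "label": d.label,
            }
            for d in system.motifs
        ],
        "reactions": [
            {
                "complex_id": r.complex_id,
                "dna": r.dna,
                "stoichiometry": dict(r.protein_stoichiometry),
                "kd_steps": list(r.kd_steps),
                "cooperativity": r.cooperativity,
            }
            for r in system.reactions
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
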