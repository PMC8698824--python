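"""Serialization: FASTA strand libraries, tidy trace CSV, design and run
reports, reaction tables and an SBML-shaped network export."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .kinetics_sim import TraceSet
from .reaction_network import ReactionNetwork
from .sequence_designer import StrandLibrary

__all__ = [
    "library_to_fasta",
    "load_matrix_text",
    "network_to_sbml_dict",
    "sha256_of",
    "traces_to_dataframe",
    "write_design_report",
]


def library_to_fasta(lib: StrandLibrary, path: Path,
                     include_fragments: bool = False) -> None:
    """Write the library as FASTA (record id = strand name; the rA site is
    encoded as lowercase ``a``; positions are listed in the design report
    sidecar)."""
    records = []
    for name in sorted(lib.strands):
        strand = lib.strands[name]
        if not include_fragments and name.endswith(("_5p", "_3p")):
            continue
        desc = strand.kind.value
        if strand.fluorophore:
            desc += f" 5'-{strand.fluorophore}"
        if strand.quencher:
            desc += f" 3'-{strand.quencher}"
        records.append(SeqRecord(Seq(strand.seq), id=name, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_design_report(lib: StrandLibrary, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(lib.design_report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def traces_to_dataframe(traces: Sequence[TraceSet]) -> pd.DataFrame:
    """Tidy long-format table: run, channel, time_min, value, normalized."""
    rows = []
    for t in traces:
        run = t.metadata.get("label", "run")
        for channel, values in sorted(t.channels.items()):
            norm = t.normalized[channel] if t.normalized is not None else None
            for idx, tm in enumerate(t.times_min):
                rows.append({
                    "run": run,
                    "channel": channel,
                    "time_min": float(tm),
                    "value": float(values[idx]),
                    "normalized": float(norm[idx]) if norm is not None
                    else float("nan"),
                })
    return pd.DataFrame(rows)


def network_to_sbml_dict(net: ReactionNetwork) -> Dict[str, object]:
    """SBML-shaped plain-data structure (listOfSpecies / listOfReactions
    with mass-action kinetic laws) for interoperability."""
    species = [
        {"id": _sbml_id(name), "name": name,
         "initialConcentration": conc, "compartment": "well"}
        for name, conc in net.species.items()
    ]
    reactions = []
    for i, r in enumerate(net.reactions):
        reactions.append({
            "id": f"r{i}",
            "reversible": False,
            "listOfReactants": [{"species": _sbml_id(s)}
                                for s in r.reactants],
            "listOfProducts": [{"species": _sbml_id(s)}
                               for s in r.products],
            "kineticLaw": {
                "type": "mass-action",
                "rateConstant": r.rate,
                "kind": r.kind,
            },
        })
    return {
        "sbml": {
            "model": {
                "listOfCompartments": [{"id": "well", "size": 1.0}],
                "listOfSpecies": species,
                "listOfReactions": reactions,
            }
        }
    }


def _sbml_id(name: str) -> str:
    out = name.replace(".", "_").replace("+", "_")
    return out if out[0].isalpha() else "s_" + out


def load_matrix_text(path: Path) -> List[List[int]]:
    """Read a matrix from minimal text: one row per line, 0/1 entries
    separated by whitespace or commas; JSON arrays also accepted."""
    text = Path(path).read_text().strip()
    if text.startswith("["):
        return json.loads(text)
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([int(tok) for tok in line.replace(",", " ").split()])
    return rows


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
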