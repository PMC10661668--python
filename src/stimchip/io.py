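"""Config and trace file loading.

Chamber configs are YAML/JSON mappings with ``edges`` (each carrying either
a plain ``resistance`` in ohms or a rectangular channel ``geometry`` in
metres), a current ``source``, an ``electrolyte`` and optionally an
``electrode``.  Sampled traces (voltage excursions, cyclic voltammograms)
are two-column CSV files with a header, SI units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .dosimetry import (
    ChannelGeometry,
    Edge,
    ElectrodeSpec,
    Electrolyte,
    ResistorNetwork,
    SampledTrace,
)
from .errors import DomainError

__all__ = ["ChamberConfig", "load_chamber_config", "load_trace_csv"]


@dataclass(frozen=True)
class ChamberConfig:
    network: ResistorNetwork
    electrolyte: Electrolyte
    electrode: ElectrodeSpec | None = None


def _parse_edge(spec: dict) -> Edge:
    kwargs = {"node_a": str(spec["from"]), "node_b": str(spec["to"])}
    if "resistance" in spec:
        kwargs["resistance"] = float(spec["resistance"])
    if "geometry" in spec:
        g = spec["geometry"]
        kwargs["geometry"] = ChannelGeometry(
            length=float(g["length"]),
            width=float(g["width"]),
            height=float(g["height"]),
            label=str(g.get("label", "")),
        )
    return Edge(**kwargs)


def load_chamber_config(path: str | Path) -> ChamberConfig:
    """Load a chamber description from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise DomainError(f"{path}: expected a mapping at top level")
    for key in ("edges", "source", "electrolyte"):
        if key not in data:
            raise DomainError(f"{path}: missing required key {key!r}")

    electrolyte = Electrolyte(conductivity=float(data["electrolyte"]["sigma"]))
    src = data["source"]
    network = ResistorNetwork(
        edges=tuple(_parse_edge(e) for e in data["edges"]),
        source=(str(src["from"]), str(src["to"]), float(src["i_in"])),
        electrolyte=electrolyte,
    )
    electrode = None
    if "electrode" in data:
        e = data["electrode"]
        electrode = ElectrodeSpec(
            diameter=float(e["diameter"]),
            capacitance=float(e["capacitance"]) if "capacitance" in e else None,
            voltage_window=float(e["voltage_window"]) if "voltage_window" in e else None,
        )
    return ChamberConfig(network=network, electrolyte=electrolyte, electrode=electrode)


def load_trace_csv(path: str | Path) -> SampledTrace:
    """Read a two-column CSV (header required) into a :class:`SampledTrace`."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DomainError(f"{path}: expected two columns, got {df.shape[1]}")
    return SampledTrace(x=df.iloc[:, 0].to_numpy(float), y=df.iloc[:, 1].to_numpy(float))
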