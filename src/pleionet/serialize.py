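"""Genotype serialization.

Hosts are written as an edge-list CSV (``source_id, target_id, coefficient``)
plus a JSON sidecar holding the architecture tag and the protein roster;
parasites are single JSON records.  Loading validates genotype legality, so a
file containing e.g. a detector-effector edge is rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import model_core as mc

_EDGE_COLUMNS = ["source_id", "target_id", "coefficient"]


def _paths(base: str | Path) -> tuple[Path, Path]:
    base = Path(base)
    return base.with_suffix(".json"), base.with_suffix(".edges.csv")


def save_host(host: mc.Host, base: str | Path) -> Path:
    meta_path, edges_path = _paths(base)
    meta = {
        "kind": "host",
        "architecture": host.architecture,
        "proteins": [
            {"id": p.id, "role": p.role, "network": p.network} for p in host.proteins
        ],
        "edges_file": edges_path.name,
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    frame = pd.DataFrame(
        [(e.source, e.target, e.coefficient) for e in host.edges],
        columns=_EDGE_COLUMNS,
    )
    frame.to_csv(edges_path, index=False, float_format="%.17g")  # lossless round-trip
    return meta_path


def load_host(base: str | Path) -> mc.Host:
    meta_path, edges_path = _paths(base)
    meta = json.loads(meta_path.read_text())
    if meta.get("kind") != "host":
        raise ValueError(f"{meta_path} does not describe a host genotype")
    proteins = tuple(
        mc.Protein(int(p["id"]), p["role"], p["network"]) for p in meta["proteins"]
    )
    frame = pd.read_csv(edges_path, float_precision="round_trip")
    if list(frame.columns) != _EDGE_COLUMNS:
        raise ValueError(f"{edges_path} must have columns {_EDGE_COLUMNS}")
    edges = tuple(
        mc.RegulatoryEdge(int(r.source_id), int(r.target_id), float(r.coefficient))
        for r in frame.itertuples()
    )
    return mc.validate_host(mc.Host(meta["architecture"], proteins, edges))


def save_parasite(parasite: mc.Parasite, base: str | Path) -> Path:
    path = Path(base).with_suffix(".json")
    record = {
        "kind": "parasite",
        "target_index": parasite.target_index,
        "target_coefficient": parasite.target_coefficient,
        "self_coefficient": parasite.self_coefficient,
        "detector_coefficient": parasite.detector_coefficient,
    }
    path.write_text(json.dumps(record, indent=2) + "\n")
    return path


def load_parasite(base: str | Path) -> mc.Parasite:
    path = Path(base).with_suffix(".json")
    record = json.loads(path.read_text())
    if record.get("kind") != "parasite":
        raise ValueError(f"{path} does not describe a parasite genotype")
    if not -1.0 <= record["target_coefficient"] <= 1.0:
        raise ValueError("parasite target coefficient outside [-1, 1]")
    return mc.Parasite(
        target_index=int(record["target_index"]),
        target_coefficient=float(record["target_coefficient"]),
        self_coefficient=float(record["self_coefficient"]),
        detector_coefficient=float(record["detector_coefficient"]),
    )


def save_genotype(genotype, base: str | Path) -> Path:
    """Dispatch on genotype kind; returns the JSON path written."""
    if isinstance(genotype, mc.Host):
        return save_host(genotype, base)
    if isinstance(genotype, mc.Parasite):
        return save_parasite(genotype, base)
    raise TypeError(f"cannot serialize {type(genotype).__name__}")


def load_genotype(base: str | Path):
    meta_path = Path(base).with_suffix(".json")
    kind = json.loads(meta_path.read_text()).get("kind")
    if kind == "host":
        return load_host(base)
    if kind == "parasite":
        return load_parasite(base)
    raise ValueError(f"{meta_path} has unknown genotype kind {kind!r}")


def save_life_record(record, base: str | Path) -> Path:
    """Export a life trajectory as tidy CSV plus a JSON scalar summary.

    The CSV has one row per (step, node) with the active fraction; the
    parasite node is labelled ``parasite``.  Steps count from the start of
    the equilibrium phase.  The JSON carries the derived areas, costs and
    fitness.
    """
    from . import lifecycle as lc

    base = Path(base)
    csv_path = base.with_suffix(".life.csv")
    json_path = base.with_suffix(".life.json")
    rows = []
    for pid, series in sorted(record.active.items()):
        rows.extend(
            {"step": t, "node": str(pid), "active_fraction": float(v)}
            for t, v in enumerate(series)
        )
    if record.parasite_series is not None:
        rows.extend(
            {"step": t, "node": "parasite", "active_fraction": float(v)}
            for t, v in enumerate(record.parasite_series)
        )
    pd.DataFrame(rows, columns=["step", "node", "active_fraction"]).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    summary = {
        "architecture": record.host.architecture,
        "infection_step": record.infection_step,
        "equilibrium_steps": record.equilibrium_steps,
        "life_steps": record.life_steps,
        "immune_effector_area": lc.immune_effector_area(record),
        "parasite_area": lc.parasite_area(record),
        "developmental_cost": lc.record_developmental_cost(record),
        "host_fitness": lc.host_fitness(record),
    }
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
    return csv_path


def genotype_hash(host: mc.Host) -> str:
    """Stable digest of the canonicalized roster and edge list."""
    payload = json.dumps(
        {
            "architecture": host.architecture,
            "proteins": [(p.id, p.role, p.network) for p in host.proteins],
            "edges": [(e.source, e.target, e.coefficient) for e in host.edges],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
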