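"""CSV / JSON readers and writers for the external data formats.

All files use actor-id strings, never positional indices:

* edge lists: ``wave,source_id,target_id[,layer]``
* monadic attributes: one row per actor, keyed by ``actor_id``
* dyadic attributes: long format ``id_a,id_b,variable,value``
* composition schedule: ``actor_id,entry,exit``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ActorRoster,
    CompositionChangeSchedule,
    DyadicAttributeSet,
    MonadicAttributeTable,
    NetworkWave,
    SupportLayerSet,
    SUPPORT_LAYERS,
)

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_layers",
    "read_layers",
    "write_monadic",
    "read_monadic",
    "write_dyadic",
    "read_dyadic",
    "write_schedule",
    "read_schedule",
    "write_roster",
    "read_roster",
    "wave_to_json",
    "wave_from_json",
]


def _edges_frame(wave: NetworkWave, roster: ActorRoster) -> pd.DataFrame:
    src, dst = np.nonzero(wave.adjacency)
    return pd.DataFrame(
        {
            "wave": wave.label,
            "source_id": [roster.ids[i] for i in src],
            "target_id": [roster.ids[j] for j in dst],
        }
    )


def write_edge_list(path: str | Path, wave: NetworkWave, roster: ActorRoster) -> None:
    _edges_frame(wave, roster).to_csv(path, index=False)


def read_edge_list(
    path: str | Path, roster: ActorRoster, label: str | None = None
) -> NetworkWave:
    df = pd.read_csv(path, dtype={"source_id": str, "target_id": str})
    if label is not None:
        df = df[df["wave"].astype(str) == label]
    elif df["wave"].nunique() > 1:
        raise ValueError("file holds several waves; pass label=")
    pos = {a: i for i, a in enumerate(roster.ids)}
    adj = np.zeros((roster.n, roster.n), dtype=np.int8)
    for s, t in zip(df["source_id"], df["target_id"]):
        adj[pos[s], pos[t]] = 1
    lbl = label if label is not None else (str(df["wave"].iloc[0]) if len(df) else "")
    return NetworkWave(lbl, adj, roster)


def write_layers(path: str | Path, layers: SupportLayerSet, roster: ActorRoster) -> None:
    frames = []
    for name in SUPPORT_LAYERS:
        f = _edges_frame(NetworkWave(layers.label, layers.layers[name]), roster)
        f["layer"] = name
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_layers(path: str | Path, roster: ActorRoster, label: str) -> SupportLayerSet:
    df = pd.read_csv(path, dtype={"source_id": str, "target_id": str})
    df = df[df["wave"].astype(str) == label]
    pos = {a: i for i, a in enumerate(roster.ids)}
    mats = {name: np.zeros((roster.n, roster.n), dtype=np.int8) for name in SUPPORT_LAYERS}
    for s, t, layer in zip(df["source_id"], df["target_id"], df["layer"]):
        mats[layer][pos[s], pos[t]] = 1
    return SupportLayerSet(label, mats, roster)


def write_monadic(path: str | Path, table: MonadicAttributeTable, roster: ActorRoster) -> None:
    out = table.frame.copy()
    out.insert(0, "actor_id", roster.ids)
    out.to_csv(path, index=False)


def read_monadic(path: str | Path, roster: ActorRoster) -> MonadicAttributeTable:
    df = pd.read_csv(path, dtype={"actor_id": str})
    df = df.set_index("actor_id").loc[roster.ids].reset_index(drop=True)
    return MonadicAttributeTable(df)


def write_dyadic(path: str | Path, dyads: DyadicAttributeSet, roster: ActorRoster) -> None:
    rows = []
    for name, m in dyads.matrices.items():
        a, b = np.nonzero(m)
        for i, j in zip(a, b):
            rows.append((roster.ids[i], roster.ids[j], name, m[i, j]))
    pd.DataFrame(rows, columns=["id_a", "id_b", "variable", "value"]).to_csv(
        path, index=False
    )


def read_dyadic(path: str | Path, roster: ActorRoster) -> DyadicAttributeSet:
    df = pd.read_csv(path, dtype={"id_a": str, "id_b": str})
    pos = {a: i for i, a in enumerate(roster.ids)}
    mats: dict[str, np.ndarray] = {}
    for name, grp in df.groupby("variable"):
        m = np.zeros((roster.n, roster.n))
        for a, b, v in zip(grp["id_a"], grp["id_b"], grp["value"]):
            m[pos[a], pos[b]] = v
        mats[name] = m
    return DyadicAttributeSet(mats)


def write_schedule(
    path: str | Path, schedule: CompositionChangeSchedule, roster: ActorRoster
) -> None:
    pd.DataFrame(
        {"actor_id": roster.ids, "entry": schedule.entry, "exit": schedule.exit}
    ).to_csv(path, index=False)


def read_schedule(path: str | Path, roster: ActorRoster) -> CompositionChangeSchedule:
    df = pd.read_csv(path, dtype={"actor_id": str}).set_index("actor_id").loc[roster.ids]
    return CompositionChangeSchedule(df["entry"].to_numpy(), df["exit"].to_numpy())


def write_roster(path: str | Path, roster: ActorRoster) -> None:
    pd.DataFrame(
        {
            "actor_id": roster.ids,
            "village": roster.village,
            "present_w1": roster.present[:, 0].astype(int),
            "present_w2": roster.present[:, 1].astype(int),
        }
    ).to_csv(path, index=False)


def read_roster(path: str | Path) -> ActorRoster:
    df = pd.read_csv(path, dtype={"actor_id": str})
    present = df[["present_w1", "present_w2"]].to_numpy(dtype=bool)
    return ActorRoster(list(df["actor_id"]), df["village"].to_numpy(), present)


def wave_to_json(wave: NetworkWave, roster: ActorRoster) -> str:
    src, dst = np.nonzero(wave.adjacency)
    return json.dumps(
        {
            "label": wave.label,
            "actors": roster.ids,
            "edges": [[roster.ids[i], roster.ids[j]] for i, j in zip(src, dst)],
        }
    )


def wave_from_json(payload: str) -> tuple[NetworkWave, list[str]]:
    data = json.loads(payload)
    ids = data["actors"]
    pos = {a: i for i, a in enumerate(ids)}
    adj = np.zeros((len(ids), len(ids)), dtype=np.int8)
    for s, t in data["edges"]:
        adj[pos[s], pos[t]] = 1
    return NetworkWave(data["label"], adj), ids
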