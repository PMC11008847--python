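"""Configuration parsing and trajectory/metrics serialization.

Configs are YAML key-value files; unspecified fields fall back to the
standard non-dimensional parameter set.  Trajectories can be written as a
CSV-dialect text table (portable, lossless via 17-significant-digit
floats) or as an .npz binary container (bit-exact round trip).  Every
trajectory carries a header with the fully resolved config, which alone
suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .engine import Frame, ScenarioConfig, SimResult
from .mechanics import BondSet
from .params import ModelParams

FORMAT_NAME = "epilayer-trajectory"
FORMAT_VERSION = 1

_CONFIG_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def config_to_dict(config: ScenarioConfig) -> dict:
    d = {f.name: getattr(config, f.name)
         for f in dataclasses.fields(ScenarioConfig)}
    d["params"] = config.params.to_dict()
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    unknown = set(d) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    d = dict(d)
    if "params" in d and not isinstance(d["params"], ModelParams):
        d["params"] = ModelParams.from_dict(d["params"] or {})
    return ScenarioConfig(**d)


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a YAML scenario config; unspecified fields use the standard
    defaults.  Unknown keys and non-numeric values raise with context."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    try:
        return config_from_dict(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# trajectory containers

def _header_dict(config: ScenarioConfig) -> dict:
    return {"format": FORMAT_NAME, "version": FORMAT_VERSION,
            "config": config_to_dict(config)}


def write_trajectory(result_or_frames, path: str | Path,
                     config: ScenarioConfig | None = None) -> None:
    """Write a trajectory; the format follows the file suffix
    (.npz binary, anything else CSV text)."""
    if isinstance(result_or_frames, SimResult):
        frames = result_or_frames.frames
        config = result_or_frames.config
    else:
        frames = result_or_frames
        if config is None:
            raise ValueError("config required when passing bare frames")
    path = Path(path)
    if path.suffix == ".npz":
        _write_npz(frames, config, path)
    else:
        _write_csv(frames, config, path)


def read_trajectory(path: str | Path) -> tuple[list[Frame], ScenarioConfig]:
    path = Path(path)
    if path.suffix == ".npz":
        return _read_npz(path)
    return _read_csv(path)


def _bondset_arrays(b: BondSet) -> dict[str, np.ndarray]:
    return {"sub": np.column_stack([b.sub_cell, b.sub_node, b.sub_k])
            if b.n_substrate_bonds else np.empty((0, 3), dtype=np.intp),
            "cc": np.column_stack([b.cc_ci, b.cc_ni, b.cc_cj, b.cc_nj,
                                   b.cc_attractive.astype(np.intp)])
            if b.n_cell_bonds else np.empty((0, 5), dtype=np.intp)}


def _bondset_from_arrays(sub: np.ndarray, cc: np.ndarray,
                         n_cells: int) -> BondSet:
    sub = sub.astype(np.intp).reshape(-1, 3)
    cc = cc.astype(np.intp).reshape(-1, 5)
    from .mechanics import BondSet as BS
    N_sub = np.bincount(sub[:, 0], minlength=n_cells).astype(np.intp)
    return BS(sub_cell=sub[:, 0], sub_node=sub[:, 1], sub_k=sub[:, 2],
              cc_ci=cc[:, 0], cc_ni=cc[:, 1], cc_cj=cc[:, 2], cc_nj=cc[:, 3],
              cc_attractive=cc[:, 4].astype(bool), N_sub=N_sub,
              left_contact=np.zeros(n_cells, dtype=bool),
              right_contact=np.zeros(n_cells, dtype=bool))


def _write_npz(frames: list[Frame], config: ScenarioConfig,
               path: Path) -> None:
    arrays: dict[str, np.ndarray] = {
        "header": np.frombuffer(
            json.dumps(_header_dict(config)).encode(), dtype=np.uint8)}
    for i, f in enumerate(frames):
        b = _bondset_arrays(f.bonds)
        arrays[f"f{i}_step"] = np.array([f.step])
        arrays[f"f{i}_nodes"] = (np.concatenate(f.cells)
                                 if f.cells else np.empty((0, 2)))
        arrays[f"f{i}_counts"] = np.array([len(c) for c in f.cells],
                                          dtype=np.intp)
        arrays[f"f{i}_sub"] = b["sub"]
        arrays[f"f{i}_cc"] = b["cc"]
    np.savez(path, **arrays)


def _read_npz(path: Path) -> tuple[list[Frame], ScenarioConfig]:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header.get("format") != FORMAT_NAME:
            raise ValueError(f"{path}: not an epilayer trajectory")
        config = config_from_dict(header["config"])
        frames: list[Frame] = []
        i = 0
        while f"f{i}_step" in data:
            counts = data[f"f{i}_counts"]
            nodes = data[f"f{i}_nodes"]
            cells, off = [], 0
            for c in counts:
                cells.append(nodes[off:off + int(c)].copy())
                off += int(c)
            bonds = _bondset_from_arrays(data[f"f{i}_sub"], data[f"f{i}_cc"],
                                         len(counts))
            step = int(data[f"f{i}_step"][0])
            frames.append(Frame(
                step=step,
                time_h=step * config.params.dt / config.params.steps_per_hour,
                cells=cells, bonds=bonds))
            i += 1
    return frames, config


_CSV_COLUMNS = "step,kind,cell,node,x,z,cell2,node2,attractive"


def _write_csv(frames: list[Frame], config: ScenarioConfig,
               path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(_header_dict(config)) + "\n")
        fh.write(_CSV_COLUMNS + "\n")
        for f in frames:
            for ci, nodes in enumerate(f.cells):
                for ni, (x, z) in enumerate(nodes):
                    fh.write(f"{f.step},node,{ci},{ni},"
                             f"{float(x)!r},{float(z)!r},,,\n")
            b = f.bonds
            for ci, ni, k in zip(b.sub_cell, b.sub_node, b.sub_k):
                fh.write(f"{f.step},sub_bond,{ci},{ni},,,,{k},\n")
            for ci, ni, cj, nj, a in zip(b.cc_ci, b.cc_ni, b.cc_cj, b.cc_nj,
                                         b.cc_attractive):
                fh.write(f"{f.step},cc_bond,{ci},{ni},,,{cj},{nj},"
                         f"{int(a)}\n")


def _read_csv(path: Path) -> tuple[list[Frame], ScenarioConfig]:
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.startswith("# "):
            raise ValueError(f"{path}: missing trajectory header")
        header = json.loads(header_line[2:])
        if header.get("format") != FORMAT_NAME:
            raise ValueError(f"{path}: not an epilayer trajectory")
        config = config_from_dict(header["config"])
        columns = fh.readline().strip()
        if columns != _CSV_COLUMNS:
            raise ValueError(f"{path}: unexpected column header")
        per_step: dict[int, dict] = {}
        order: list[int] = []
        last_complete = None
        try:
            for line in fh:
                parts = line.rstrip("\n").split(",")
                if len(parts) != 9:
                    raise ValueError(f"short row: {line!r}")
                s = int(parts[0])
                if s not in per_step:
                    per_step[s] = {"nodes": {}, "sub": [], "cc": []}
                    order.append(s)
                    if len(order) > 1:
                        last_complete = order[-2]
                rec = per_step[s]
                kind = parts[1]
                if kind == "node":
                    ci, ni = int(parts[2]), int(parts[3])
                    rec["nodes"].setdefault(ci, []).append(
                        (ni, float(parts[4]), float(parts[5])))
                elif kind == "sub_bond":
                    rec["sub"].append((int(parts[2]), int(parts[3]),
                                       int(parts[7])))
                elif kind == "cc_bond":
                    rec["cc"].append((int(parts[2]), int(parts[3]),
                                      int(parts[6]), int(parts[7]),
                                      int(parts[8])))
                else:
                    raise ValueError(f"unknown record kind {kind!r}")
        except ValueError as exc:
            at = (f"after complete frame step={last_complete}"
                  if last_complete is not None else "before any complete frame")
            raise IOError(f"{path}: truncated or corrupt {at}: {exc}") from exc
    frames = []
    for s in order:
        rec = per_step[s]
        cells = []
        for ci in sorted(rec["nodes"]):
            rows = sorted(rec["nodes"][ci])
            cells.append(np.array([[x, z] for _, x, z in rows]))
        sub = np.array(rec["sub"], dtype=np.intp).reshape(-1, 3)
        cc = np.array(rec["cc"], dtype=np.intp).reshape(-1, 5)
        bonds = _bondset_from_arrays(sub, cc, len(cells))
        frames.append(Frame(
            step=s, time_h=s * config.params.dt / config.params.steps_per_hour,
            cells=cells, bonds=bonds))
    return frames, config


# ---------------------------------------------------------------------------
# metrics

def metrics_from_frames(frames: list[Frame],
                        config: ScenarioConfig):
    """Recompute per-frame metrics from a stored trajectory.

    Uses the bond tables saved with each frame, so the result matches the
    metrics computed online during the run."""
    import pandas as pd

    from .geometry import Cell
    from .metrics import frame_metrics
    rows = []
    for f in frames:
        cells = [Cell(nodes=n, preferred_area=config.params.A0,
                      node_ref_spacing=1.0) for n in f.cells]
        rows.extend(frame_metrics(cells, f.bonds, f.time_h,
                                  config.params.cc_threshold))
    return pd.DataFrame([vars(r) for r in rows])


def write_metrics(df, path: str | Path) -> None:
    df.to_csv(path, index=False)
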