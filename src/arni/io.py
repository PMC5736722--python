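"""Plain-text file round-trips: time series, edge lists, results, manifests.

All files are TSV or flat ``key = value`` text. Unit indices are 1-based in
files (0-based internally). A time-series file carries an explicit ``segment``
column — boundaries are never inferred from time gaps — and a sidecar
``<name>.meta`` file with the sampling interval and provenance; reading
without the sampling interval is a hard error (derivatives are undefined).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .netgen import NetworkSpec
from .simulate import TimeSeriesSet

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_network", "read_network",
    "write_results", "write_score_matrix", "read_score_matrix",
    "write_manifest", "read_manifest",
]

EDGE_HEADER = "# arni-edges v1"


def write_timeseries(ts: TimeSeriesSet, path: str) -> None:
    names = ts.component_names()
    frames = []
    for k, seg in enumerate(ts.segments):
        df = pd.DataFrame(seg, columns=names)
        df.insert(0, "time", np.arange(seg.shape[0]) * ts.dt)
        df.insert(0, "segment", k + 1)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.17g")
    meta = {"dt": ts.dt}
    for k in ("model", "seed", "eta", "m", "S"):
        if k in ts.meta:
            meta[k] = ts.meta[k]
    meta["layout"] = ";".join(",".join(str(c + 1) for c in cols)
                              for cols in ts.unit_layout)
    write_manifest(meta, path + ".meta")


def read_timeseries(path: str) -> TimeSeriesSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "segment" not in df.columns:
        raise ValueError(f"{path}: missing 'segment' column")
    meta_path = path + ".meta"
    if not os.path.exists(meta_path):
        raise FileNotFoundError(
            f"{meta_path} not found: the sampling interval dt is required"
        )
    meta = read_manifest(meta_path)
    if "dt" not in meta:
        raise ValueError(f"{meta_path}: missing dt (derivatives undefined)")
    dt = float(meta["dt"])
    value_cols = [c for c in df.columns if c not in ("segment", "time")]
    segments = [g[value_cols].to_numpy(dtype=float)
                for _, g in df.groupby("segment", sort=True)]
    if "layout" in meta:
        layout = [[int(c) - 1 for c in grp.split(",")]
                  for grp in str(meta["layout"]).split(";")]
    else:
        layout = [[i] for i in range(len(value_cols))]
    out_meta = {k: v for k, v in meta.items() if k not in ("dt", "layout")}
    return TimeSeriesSet(segments=segments, dt=dt, unit_layout=layout,
                         meta=out_meta)


def write_network(spec: NetworkSpec, path: str) -> None:
    """Edge list: ``i TAB j TAB weight`` (1-based, link j -> i); hypernetwork
    entries as ``i TAB j TAB k TAB weight``."""
    with open(path, "w") as fh:
        fh.write(EDGE_HEADER + "\n")
        fh.write(f"# N = {spec.N}\n")
        ii, jj = np.nonzero(spec.J)
        for i, j in zip(ii.tolist(), jj.tolist()):
            fh.write(f"{i + 1}\t{j + 1}\t{spec.J[i, j]:.17g}\n")
        if spec.E is not None:
            for i in sorted(spec.E):
                js, ks = np.nonzero(spec.E[i])
                for j, k in zip(js.tolist(), ks.tolist()):
                    fh.write(f"{i + 1}\t{j + 1}\t{k + 1}\t"
                             f"{spec.E[i][j, k]:.17g}\n")


def read_network(path: str) -> NetworkSpec:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(EDGE_HEADER):
        raise ValueError(f"{path}: not an edge-list file (missing header)")
    N = None
    for ln in lines:
        if ln.startswith("# N ="):
            N = int(ln.split("=")[1])
    if N is None:
        raise ValueError(f"{path}: missing '# N =' line")
    J = np.zeros((N, N))
    E: dict[int, np.ndarray] = {}
    for ln in lines:
        if ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) == 3:
            i, j, w = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])
            J[i, j] = w
        elif len(parts) == 4:
            i, j, k = (int(p) - 1 for p in parts[:3])
            E.setdefault(i, np.zeros((N, N)))[j, k] = float(parts[3])
        else:
            raise ValueError(f"{path}: malformed line {ln!r}")
    return NetworkSpec(N=N, J=J, E=E or None)


def write_results(results, path: str) -> None:
    """Ranked-interaction table: target, component, key, rank, costs."""
    rows = []
    for u in results.units:
        for key, step, tc, vc in u.ranked:
            ks = ",".join(str(k + 1) for k in key) if isinstance(key, tuple) \
                else str(key + 1)
            rows.append(dict(target=u.target + 1,
                             component=u.target_component + 1,
                             key=ks, rank=step, train_cost=tc, val_cost=vc))
    pd.DataFrame(rows, columns=["target", "component", "key", "rank",
                                "train_cost", "val_cost"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def write_score_matrix(S: np.ndarray, path: str) -> None:
    n = S.shape[0]
    pd.DataFrame(S, index=[f"u{i + 1}" for i in range(n)],
                 columns=[f"u{j + 1}" for j in range(n)]).to_csv(
        path, sep="\t", float_format="%.17g")


def read_score_matrix(path: str) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip").to_numpy(dtype=float)


def write_manifest(cfg: dict, path: str) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"arni_version = {__version__}\n")
        for k in sorted(cfg):
            v = cfg[k]
            if isinstance(v, np.ndarray):
                v = ",".join(f"{x:.17g}" for x in np.ravel(v))
            fh.write(f"{k} = {v}\n")


def read_manifest(path: str) -> dict:
    out = {}
    with open(path) as fh:
        for ln in fh:
            if "=" not in ln:
                continue
            k, v = ln.split("=", 1)
            out[k.strip()] = v.strip()
    return out
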