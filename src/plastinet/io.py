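"""On-disk formats: spike rasters, connectivity snapshots, traces, manifests.

* spike raster — two-column TSV ``neuron_id <TAB> spike_time_ms``, 0-based
  ids, excitatory ids before inhibitory ids;
* connectivity snapshots — Matrix Market files of the sparse E-E
  synapse-count matrix with a companion weight snapshot sharing the
  sparsity pattern, one pair per timestamp;
* trace tables — TSV of the recorded population traces;
* manifest — JSON with the full configuration, seeds and package version,
  linking every output of a run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_snapshot",
    "read_snapshot",
    "snapshot_series",
    "write_traces",
    "read_traces",
    "write_manifest",
]


def write_spikes(path, times_s: np.ndarray, ids: np.ndarray, append: bool = False) -> None:
    """Append-per-interval TSV raster (neuron_id, spike_time_ms)."""
    df = pd.DataFrame(
        {"neuron_id": np.asarray(ids, dtype=np.int64),
         "spike_time_ms": np.asarray(times_s, dtype=float) * 1e3}
    )
    mode = "a" if append else "w"
    df.to_csv(path, sep="\t", index=False, mode=mode, header=not append)


def read_spikes(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TSV raster; returns (times_s, neuron_ids)."""
    df = pd.read_csv(path, sep="\t")
    return df["spike_time_ms"].to_numpy() * 1e-3, df["neuron_id"].to_numpy(np.int64)


def _snapshot_paths(directory: Path, t: float) -> tuple[Path, Path]:
    tag = f"{t:012.3f}".replace(".", "_")
    return directory / f"counts_t{tag}.mtx", directory / f"weights_t{tag}.mtx"


def write_snapshot(directory, counts: np.ndarray, weights: np.ndarray, t: float) -> tuple[Path, Path]:
    """Write one (counts, weights) MTX snapshot pair; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cpath, wpath = _snapshot_paths(directory, t)
    csr = scipy.sparse.coo_matrix(np.asarray(counts, dtype=np.int64))
    scipy.io.mmwrite(str(cpath), csr, comment=f"t={t!r} s; synapse counts")
    wsp = scipy.sparse.coo_matrix(np.asarray(weights, dtype=float))
    scipy.io.mmwrite(
        str(wpath), wsp, comment=f"t={t!r} s; summed weights (mV)", precision=17
    )
    return cpath, wpath


def read_snapshot(counts_path, weights_path) -> tuple[np.ndarray, np.ndarray]:
    """Read a snapshot pair back as dense arrays (counts int64, weights float)."""
    counts = scipy.io.mmread(str(counts_path)).toarray().astype(np.int64)
    weights = scipy.io.mmread(str(weights_path)).toarray().astype(float)
    return counts, weights


def snapshot_series(directory) -> list[tuple[float, Path, Path]]:
    """All snapshot pairs in a directory, sorted by timestamp."""
    directory = Path(directory)
    out = []
    for cpath in sorted(directory.glob("counts_t*.mtx")):
        tag = cpath.stem.removeprefix("counts_t")
        t = float(tag.replace("_", "."))
        wpath = directory / cpath.name.replace("counts_", "weights_")
        if not wpath.exists():
            raise FileNotFoundError(f"missing weight snapshot for {cpath}")
        out.append((t, cpath, wpath))
    return out


def write_traces(path, traces: pd.DataFrame) -> None:
    traces.to_csv(path, sep="\t", index=False)


def read_traces(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path, config, extra: dict | None = None) -> None:
    """JSON manifest of a run: configuration, seed and package version."""
    from . import __version__

    payload = {
        "plastinet_version": __version__,
        "config": dataclasses.asdict(config),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")
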