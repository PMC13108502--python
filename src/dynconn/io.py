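"""Readers and writers for the pipeline's tabular artifacts.

Everything is plain text: TSV tables with ``#``-prefixed provenance header
lines plus a JSON sidecar/manifest where structured metadata is needed.
Time series are written as one column per parcel and one row per volume,
with the sampling interval and region labels in a ``<name>.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coherence import ConnectivityStack, ParcelTimeSeries, ValidationError
from .community import ModularityConfig, MultilayerPartition
from .consensus import ConsensusPartition

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_stack",
    "read_stack",
    "write_partitions",
    "read_partitions",
    "write_consensus",
    "read_consensus",
    "write_metric_table",
    "read_metric_table",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: ParcelTimeSeries, path: str | Path,
                     extra: dict | None = None) -> Path:
    """TSV (header = parcel ids) plus JSON sidecar with tr and regions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ts.values, columns=ts.parcel_ids).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
    meta = {
        "tr": ts.tr,
        "region_labels": dict(zip(ts.parcel_ids, map(str, ts.region_labels))),
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_timeseries(path: str | Path) -> ParcelTimeSeries:
    """Read a time-series TSV and its sidecar; errors name the offence."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such time-series file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"missing sidecar {sidecar} (needs key 'tr')")
    meta = json.loads(sidecar.read_text())
    if "tr" not in meta:
        raise ValidationError(f"sidecar {sidecar} missing required key 'tr'")
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # ragged rows, etc.
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    bad_cols = [c for c in frame.columns
                if not np.issubdtype(frame[c].dtype, np.number)]
    if bad_cols:
        raise ValidationError(
            f"non-numeric cells in {path}, columns {bad_cols}"
        )
    parcel_ids = list(frame.columns)
    regions = meta.get("region_labels", {})
    region_labels = np.asarray(
        [regions.get(p, "left") for p in parcel_ids], dtype=object
    )
    return ParcelTimeSeries(
        values=frame.to_numpy(dtype=float),
        tr=float(meta["tr"]),
        parcel_ids=parcel_ids,
        region_labels=region_labels,
    )


def write_stack(stack: ConnectivityStack, out_dir: str | Path) -> Path:
    """One TSV per layer plus a manifest carrying order/band/window."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, layer in enumerate(stack.layers):
        name = f"layer_{i:03d}.tsv"
        np.savetxt(out / name, layer, delimiter="\t", fmt="%.8g")
        names.append(name)
    manifest = {
        "layers": names,
        "band": list(stack.band),
        "window_len": stack.window_len,
        "parcel_ids": list(stack.parcel_ids),
        "region_labels": list(map(str, stack.region_labels)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_stack(in_dir: str | Path) -> ConnectivityStack:
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"missing stack manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    layers = np.stack(
        [np.loadtxt(in_dir / name, delimiter="\t", ndmin=2)
         for name in manifest["layers"]]
    )
    return ConnectivityStack(
        layers=layers,
        band=tuple(manifest["band"]),
        window_len=int(manifest["window_len"]),
        parcel_ids=list(manifest["parcel_ids"]),
        region_labels=np.asarray(manifest["region_labels"], dtype=object),
    )


def write_partitions(
    partitions: list[MultilayerPartition],
    out_dir: str | Path,
    config: ModularityConfig | None = None,
) -> Path:
    """Node x layer label TSV per run plus a run manifest (seed, q)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names, qs = [], []
    for i, p in enumerate(partitions):
        name = f"partition_{i:03d}.tsv"
        np.savetxt(out / name, p.labels, delimiter="\t", fmt="%d")
        names.append(name)
        qs.append(p.q_value)
    cfg = config or (partitions[0].config if partitions else None)
    manifest = {"runs": names, "q_values": qs}
    if cfg is not None:
        manifest.update(
            {"gamma": cfg.gamma, "omega": cfg.omega,
             "n_iter": cfg.n_iter, "seed": cfg.seed}
        )
    (out / "runs.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_partitions(in_dir: str | Path) -> list[MultilayerPartition]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "runs.json").read_text())
    out = []
    for name, q in zip(manifest["runs"], manifest["q_values"]):
        labels = np.loadtxt(in_dir / name, delimiter="\t", dtype=int, ndmin=2)
        out.append(MultilayerPartition(labels=labels, q_value=q))
    return out


def write_consensus(cons: ConsensusPartition, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# provenance: {json.dumps(cons.provenance)}\n")
        fh.write("node\tlabel\n")
        for i, lab in enumerate(cons.labels):
            fh.write(f"{i}\t{lab}\n")
    return path


def read_consensus(path: str | Path) -> ConsensusPartition:
    path = Path(path)
    provenance = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = json.loads(first.split(":", 1)[1])
    frame = pd.read_csv(path, sep="\t", comment="#")
    return ConsensusPartition(
        labels=frame["label"].to_numpy(dtype=int), provenance=provenance
    )


def write_metric_table(table: pd.DataFrame, path: str | Path,
                       provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# provenance: {json.dumps(provenance)}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    return path


def read_metric_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
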