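"""On-disk formats: expression TSV + JSON sidecar, HDF5 tensors and models.

Expression data travels as a genes x samples TSV (first column gene ID,
header row sample IDs) with a JSON sidecar holding the modulator vector,
gene roles and optional tissue labels. Network tensors and fitted subspace
models use HDF5 containers written with ``track_times=False`` so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, NetworkTensor
from .exceptions import ParseError
from .trip import LinearHead, MLPHead, SubspaceModel

_H5_OPTS = {"track_times": False}


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_expression(data: ExpressionDataset, path) -> None:
    """Write the TSV matrix and its JSON sidecar."""
    path = Path(path)
    out = data.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    sidecar = {
        "modulator": data.modulator.tolist(),
        "roles": data.roles.to_dict(),
    }
    if data.tissue is not None:
        sidecar["tissue"] = data.tissue.to_dict()
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_expression(path) -> ExpressionDataset:
    """Read and validate a TSV + JSON sidecar expression dataset."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"expression file {path} does not exist")
    sp = sidecar_path(path)
    if not sp.exists():
        raise ParseError(f"sidecar {sp} does not exist")
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = None
    if values.isna().any().any():
        na = values.isna()
        gene = na.any(axis=1).idxmax()
        sample = na.loc[gene].idxmax()
        raise ParseError(f"missing value at gene {gene!r}, sample {sample!r}")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ParseError(f"duplicate gene identifier {dup!r}")
    meta = json.loads(sp.read_text())
    modulator = np.asarray(meta["modulator"], dtype=float)
    if modulator.shape[0] != values.shape[1]:
        raise ParseError(
            f"sidecar modulator length {modulator.shape[0]} does not match "
            f"sample count {values.shape[1]}"
        )
    roles = pd.Series(meta["roles"]).reindex(values.index)
    if roles.isna().any():
        missing = roles.index[roles.isna()][0]
        raise ParseError(f"gene {missing!r} has no role in the sidecar")
    tissue = None
    if "tissue" in meta:
        tissue = pd.Series(meta["tissue"]).reindex(values.columns)
    return ExpressionDataset(values=values, roles=roles, modulator=modulator,
                             tissue=tissue)


def _write_strings(group, name, items):
    group.create_dataset(name, data=np.array(items, dtype=h5py.string_dtype()),
                         **_H5_OPTS)


def _read_strings(group, name):
    return [s.decode() if isinstance(s, bytes) else str(s) for s in group[name][()]]


def write_network_tensor(tensor: NetworkTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coefficients", data=tensor.coefficients, **_H5_OPTS)
        f.create_dataset("intercepts", data=tensor.intercepts, **_H5_OPTS)
        if tensor.modulator is not None:
            f.create_dataset("modulator", data=tensor.modulator, **_H5_OPTS)
        _write_strings(f, "target_ids", tensor.target_ids)
        _write_strings(f, "regulator_ids", tensor.regulator_ids)
        _write_strings(f, "sample_ids", tensor.sample_ids)


def load_network_tensor(path) -> NetworkTensor:
    with h5py.File(path, "r") as f:
        return NetworkTensor(
            coefficients=f["coefficients"][()],
            intercepts=f["intercepts"][()],
            target_ids=_read_strings(f, "target_ids"),
            regulator_ids=_read_strings(f, "regulator_ids"),
            sample_ids=_read_strings(f, "sample_ids"),
            modulator=f["modulator"][()] if "modulator" in f else None,
        )


def write_edge_lists(tensor: NetworkTensor, path) -> None:
    """Per-sample nonzero edges as TSV (sample, target, regulator, weight)."""
    rows = []
    for a, sid in enumerate(tensor.sample_ids):
        sl = tensor.coefficients[:, :, a]
        ls, js = np.nonzero(sl)
        for l, j in zip(ls, js):
            rows.append((sid, tensor.target_ids[l], tensor.regulator_ids[j],
                         sl[l, j]))
    pd.DataFrame(rows, columns=["sample", "target", "regulator", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_subspace_model(model: SubspaceModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["gamma"] = model.gamma
        f.attrs["loss_kind"] = model.loss_kind
        f.attrs["fitted"] = model.fitted
        for k, (C, Z) in enumerate(zip(model.projections, model.latents), start=1):
            f.create_dataset(f"C{k}", data=C, **_H5_OPTS)
            f.create_dataset(f"Z{k}", data=Z, **_H5_OPTS)
        f.create_dataset("history", data=np.asarray(model.history), **_H5_OPTS)
        head = model.head
        if isinstance(head, LinearHead):
            f.attrs["head"] = "linear"
            f.create_dataset("head/w", data=head.w, **_H5_OPTS)
            f.attrs["head_b"] = head.b
        elif isinstance(head, MLPHead):
            f.attrs["head"] = "mlp"
            f.create_dataset("head/W1", data=head.W1, **_H5_OPTS)
            f.create_dataset("head/b1", data=head.b1, **_H5_OPTS)
            f.create_dataset("head/w2", data=head.w2, **_H5_OPTS)
            f.attrs["head_b"] = head.b2
        else:
            raise ParseError(f"cannot serialize head of type {type(head).__name__}")


def load_subspace_model(path) -> SubspaceModel:
    with h5py.File(path, "r") as f:
        projections = [f["C1"][()], f["C2"][()]]
        latents = [f["Z1"][()], f["Z2"][()]]
        kind = f.attrs["head"]
        dim = projections[0].shape[1] * projections[1].shape[1]
        if kind == "linear":
            head = LinearHead(dim)
            head.w = f["head/w"][()]
            head.b = float(f.attrs["head_b"])
        else:
            W1 = f["head/W1"][()]
            head = MLPHead(dim, width=W1.shape[0])
            head.W1 = W1
            head.b1 = f["head/b1"][()]
            head.w2 = f["head/w2"][()]
            head.b2 = float(f.attrs["head_b"])
        return SubspaceModel(
            projections=projections,
            latents=latents,
            head=head,
            gamma=float(f.attrs["gamma"]),
            loss_kind=str(f.attrs["loss_kind"]),
            history=list(f["history"][()]),
            fitted=bool(f.attrs["fitted"]),
        )


def write_component_scores(scores, sample_ids, path) -> None:
    """ComponentScores to TSV: sample, component_1..J (normalized u), pc_1..r."""
    J = scores.matrix.shape[0]
    r = scores.pc_scores.shape[1]
    df = pd.DataFrame({"sample": sample_ids})
    for j in range(J):
        df[f"component_{j+1}"] = scores.matrix[j, :]
    for c in range(r):
        df[f"pc_{c+1}"] = scores.pc_scores[:, c]
    df.to_csv(path, sep="\t", index=False)


def load_component_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
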