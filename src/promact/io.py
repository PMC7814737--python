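"""File I/O for the standard input and artifact formats.

Methylation tables follow the Bismark coverage convention: tab-separated
``chrom, 1-based position, [percentage,] methylated reads, unmethylated
reads``; the optional percentage column is tolerated and ignored.
Feature tensors are persisted as ``.npz`` with a JSON sidecar recording
provenance (catalog, sample, ordering, scales, seed).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTensor


def read_methylation(path) -> pd.DataFrame:
    """Read a Bismark-coverage-like methylation table to 0-based positions."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", header=None)
    if df.shape[1] >= 6:
        # full Bismark coverage: chrom start end percentage meth unmeth
        df = df.iloc[:, [0, 1, 4, 5]]
    elif df.shape[1] == 5:
        # chrom pos percentage meth unmeth
        df = df.iloc[:, [0, 1, 3, 4]]
    elif df.shape[1] == 4:
        df = df.iloc[:, [0, 1, 2, 3]]
    else:
        raise ValueError(f"methylation table has {df.shape[1]} columns; expected 4-6")
    df.columns = ["chrom", "pos", "meth", "unmeth"]
    df["pos"] = df["pos"].astype(int) - 1
    return df


def save_tensor(tensor: FeatureTensor, path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        values=tensor.values,
        transcript_ids=np.asarray(tensor.transcript_ids).astype(str),
    )
    meta = {
        "sample_id": tensor.sample_id,
        "ordering": tensor.ordering,
        "scales": list(tensor.scales),
        "shape": list(tensor.values.shape),
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, default=str))


def load_tensor(path) -> FeatureTensor:
    path = Path(path)
    data = np.load(path, allow_pickle=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return FeatureTensor(
        values=data["values"],
        transcript_ids=data["transcript_ids"],
        sample_id=meta.get("sample_id", ""),
        ordering=meta.get("ordering", "transcriptional"),
        scales=tuple(meta.get("scales", (250, 2500))),
    )


def read_expression(path) -> pd.DataFrame:
    """Two-column table: gene id, FPKM (header optional)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0].lower() not in ("gene_id", "gene"):
        df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "fpkm"]
    return df


def write_sidecar(path, **meta) -> None:
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))
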