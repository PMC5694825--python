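"""Reading and writing the pipeline's tabular and matrix formats.

All on-disk formats are plain text: connectivity matrices are square,
labelled CSV (header row and index column of region labels); cohort tables
are headered CSV in long format; reports are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .metrics import WeightedConnectivityMatrix


def read_matrix(path: str | Path) -> WeightedConnectivityMatrix:
    """Read a labelled square CSV into a connectivity matrix.

    The first row and first column carry region labels; the diagonal is
    zeroed on load (self-connections are meaningless for these networks).
    """
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError(f"{path}: row and column labels differ")
    w = df.to_numpy(dtype=float)
    np.fill_diagonal(w, 0.0)
    return WeightedConnectivityMatrix(labels=labels, weights=w)


def write_matrix(path: str | Path, matrix: WeightedConnectivityMatrix) -> None:
    df = pd.DataFrame(matrix.weights, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, float_format="%.6f")


def matrix_paths(directory: str | Path, timepoint: str = "baseline") -> dict[str, Path]:
    """Map subject_id -> matrix file for one timepoint in a directory.

    Files follow the ``<subject_id>_<timepoint>.csv`` convention used by the
    simulator.
    """
    directory = Path(directory)
    out: dict[str, Path] = {}
    for p in sorted(directory.glob(f"*_{timepoint}.csv")):
        sid = p.name[: -(len(timepoint) + 5)]
        out[sid] = p
    return out


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_of(paths: Iterable[str | Path]) -> str:
    """Stable digest over a set of files (names + contents).

    Only basenames enter the digest so reports and staleness manifests are
    reproducible when the same outputs live under a different directory.
    """
    h = hashlib.sha256()
    for p in sorted(Path(p) for p in paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()
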