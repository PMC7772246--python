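"""Plain-text readers/writers for the exchange formats.

Netmats files follow the HCP dialect: one subject per line, the full
n_ics x n_ics connectivity matrix flattened row-major, whitespace
separated; n_ics is inferred from the line length on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BrainFeatureSet, conn_feature_name, upper_triangle_pairs

__all__ = ["write_netmats", "read_netmats", "write_kinship", "read_kinship"]


def write_netmats(fs: BrainFeatureSet, path: str | Path) -> None:
    """Write connectivity features as flattened full square matrices."""
    n_ics = fs.provenance["n_ics"]
    pairs = upper_triangle_pairs(n_ics)
    conn = fs.of_kind("connectivity")
    rows = np.zeros((fs.n_subjects, n_ics * n_ics))
    for col, (i, j) in enumerate(pairs):
        v = conn[conn_feature_name(i, j)].to_numpy()
        rows[:, i * n_ics + j] = v
        rows[:, j * n_ics + i] = v
    np.savetxt(path, rows, fmt="%.8g")


def read_netmats(
    path: str | Path, subjects: list[str] | None = None
) -> BrainFeatureSet:
    """Read an HCP-dialect netmats file; n_ics inferred from row length."""
    arr = np.loadtxt(path)
    if arr.ndim == 1:
        arr = arr[None, :]
    n_ics = int(round(np.sqrt(arr.shape[1])))
    if n_ics * n_ics != arr.shape[1]:
        raise ValueError(
            f"row length {arr.shape[1]} is not a perfect square; not a flattened "
            "square connectivity matrix"
        )
    pairs = upper_triangle_pairs(n_ics)
    names = [conn_feature_name(i, j) for i, j in pairs]
    data = np.column_stack([arr[:, i * n_ics + j] for i, j in pairs])
    index = pd.Index(
        subjects if subjects is not None else [f"S{i:06d}" for i in range(arr.shape[0])],
        name="subject",
    )
    features = pd.DataFrame(data, index=index, columns=names)
    meta = pd.DataFrame(
        {"kind": ["connectivity"] * len(names),
         "ic_pair": [f"{i}-{j}" for i, j in pairs]},
        index=pd.Index(names, name="feature"),
    )
    return BrainFeatureSet(features, meta, {"n_ics": n_ics, "netmat_variant": "partial"})


def write_kinship(kinship: pd.DataFrame, path: str | Path) -> None:
    kinship.to_csv(path, index=False)


def read_kinship(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_a", "subject_b", "relation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kinship table missing columns: {sorted(missing)}")
    if "same_gender" in df.columns:
        df["same_gender"] = df["same_gender"].astype(bool)
    return df
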