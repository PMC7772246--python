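"""Canonical-network annotation of independent components.

Each IC spatial map is correlated (Pearson, over voxels) with every
canonical network template; the largest correlation determines the label.
Thresholding at the 99th percentile of nonzero voxels is provided for
building template supports from continuous maps; matching itself uses the
full continuous map against the binary template.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["threshold_ic_map", "match_templates", "read_voxel_maps", "write_voxel_maps"]


def threshold_ic_map(ic_map: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Binary support: nonzero voxels above the percentile of nonzero voxels."""
    ic_map = np.asarray(ic_map, dtype=float)
    nonzero = ic_map != 0
    if not nonzero.any():
        raise ValueError("all-zero IC map has no support to threshold")
    vals = ic_map[nonzero]
    cut = np.percentile(vals, percentile)
    support = nonzero & (ic_map > cut)
    if not support.any():
        warnings.warn(
            "degenerate percentile threshold (constant nonzero map?); empty support"
        )
    return support


def match_templates(
    ic_maps: np.ndarray,
    templates: np.ndarray,
    template_labels: list[str] | None = None,
    weak_floor: float = 0.1,
) -> pd.DataFrame:
    """Label each IC with its best-correlated canonical template.

    Returns a table with the winning label, its correlation, and flags for
    weak matches (below ``weak_floor``), ties (resolved toward the earlier
    template) and zero-variance ICs (left unlabeled).
    """
    ic_maps = np.atleast_2d(np.asarray(ic_maps, dtype=float))
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    if ic_maps.shape[1] != templates.shape[1]:
        raise ValueError(
            f"voxel mismatch: ICs have {ic_maps.shape[1]}, templates {templates.shape[1]}"
        )
    if templates.shape[0] == 0:
        raise ValueError("template set is empty")
    labels = template_labels or [f"template_{t}" for t in range(templates.shape[0])]

    rows = []
    for k, m in enumerate(ic_maps):
        if np.std(m) == 0:
            rows.append(
                {"ic": k, "label": None, "correlation": np.nan,
                 "note": "zero-variance IC; unlabeled"}
            )
            continue
        corrs = np.array(
            [
                np.corrcoef(m, t)[0, 1] if np.std(t) > 0 else np.nan
                for t in templates
            ]
        )
        best = int(np.nanargmax(corrs))
        note = ""
        ties = np.flatnonzero(np.isclose(corrs, corrs[best], atol=1e-12))
        if len(ties) > 1:
            best = int(ties[0])
            note = f"tie among templates {ties.tolist()}; first kept"
        if corrs[best] < weak_floor:
            note = (note + "; " if note else "") + f"weak match (r < {weak_floor})"
        rows.append(
            {"ic": k, "label": labels[best], "correlation": float(corrs[best]),
             "note": note}
        )
    return pd.DataFrame(rows).set_index("ic")


def write_voxel_maps(maps: np.ndarray, path) -> None:
    """One map per column, one voxel per line (plain-text exchange format)."""
    np.savetxt(path, np.atleast_2d(maps).T, fmt="%.8g")


def read_voxel_maps(path) -> np.ndarray:
    arr = np.loadtxt(path)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr.T
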