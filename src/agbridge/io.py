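"""Delimited-text dataset exchange and result serialization.

Datasets travel as a delimited table with header columns ``Y``, ``U``,
``X_1..X_P`` plus a two-column sidecar group map (``column_name``,
``group_id``) assigning every covariate column to a group, in column
order.  This is the simplest unambiguous exchange format for a grouped
design.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "load_dataset",
    "write_dataset",
    "write_fit_result",
]


class DatasetError(ValueError):
    """A dataset or group-map file failed validation."""


def load_dataset(
    path,
    group_map_path,
    rescale_u: bool = False,
    response: str = "Y",
    index: str = "U",
    delimiter: str = ",",
):
    """Read a dataset table and its group-map sidecar.

    Returns ``(y, X, u, group_sizes, column_names, group_ids)`` where
    ``group_sizes`` follows first-appearance order of group ids in the
    map.  ``rescale_u`` min-max rescales the index column to [0, 1];
    without it an out-of-range index is an error.
    """
    path, group_map_path = Path(path), Path(group_map_path)
    try:
        # round_trip parsing keeps %.17g-written doubles bit-identical
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except FileNotFoundError:
        raise DatasetError(f"dataset file not found: {path}") from None
    try:
        gmap = pd.read_csv(group_map_path, sep=delimiter)
    except FileNotFoundError:
        raise DatasetError(f"group map file not found: {group_map_path}") from None

    for col in (response, index):
        if col not in df.columns:
            raise DatasetError(f"dataset is missing required column {col!r}")
    if not {"column_name", "group_id"} <= set(gmap.columns):
        raise DatasetError(
            "group map must have columns 'column_name' and 'group_id'"
        )

    x_cols = [c for c in df.columns if c not in (response, index)]
    mapped = list(gmap["column_name"].astype(str))
    if sorted(mapped) != sorted(x_cols) or len(set(mapped)) != len(mapped):
        raise DatasetError(
            "group map must cover every covariate column exactly once; "
            f"dataset has {x_cols}, map lists {mapped}"
        )

    # order columns as in the map so groups are contiguous
    sub = df[[response, index] + mapped]
    if not np.all([np.issubdtype(t, np.number) for t in sub.dtypes]):
        bad = [c for c, t in sub.dtypes.items() if not np.issubdtype(t, np.number)]
        raise DatasetError(f"non-numeric entries in columns {bad}")

    y = sub[response].to_numpy(dtype=float)
    u = sub[index].to_numpy(dtype=float)
    X = sub[mapped].to_numpy(dtype=float)

    if rescale_u:
        lo, hi = u.min(), u.max()
        if hi > lo:
            u = (u - lo) / (hi - lo)
        else:
            u = np.zeros_like(u)
    elif u.min() < 0.0 or u.max() > 1.0:
        raise DatasetError(
            "index column U must lie in [0, 1]; pass rescale_u to min-max "
            "rescale it"
        )

    gids = list(gmap["group_id"])
    order: list = []
    for g in gids:
        if g not in order:
            order.append(g)
    sizes = np.array([gids.count(g) for g in order], dtype=int)
    # map must be order-preserving: each group's columns contiguous
    seen_done = set()
    prev = None
    for g in gids:
        if g != prev and g in seen_done:
            raise DatasetError(
                f"group {g!r} appears in non-contiguous blocks in the map"
            )
        if prev is not None and g != prev:
            seen_done.add(prev)
        prev = g
    return y, X, u, sizes, mapped, order


def write_dataset(path, group_map_path, y, X, u, group_sizes, delimiter=","):
    """Write arrays as a dataset table + group map (inverse of load_dataset)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    u = np.asarray(u, dtype=float)
    names = [f"X_{k + 1}" for k in range(X.shape[1])]
    df = pd.DataFrame({"Y": y, "U": u})
    for k, nm in enumerate(names):
        df[nm] = X[:, k]
    # %.17g round-trips IEEE doubles exactly through text
    df.to_csv(path, index=False, sep=delimiter, float_format="%.17g")
    gids = np.repeat(np.arange(1, len(group_sizes) + 1), group_sizes)
    pd.DataFrame({"column_name": names, "group_id": gids}).to_csv(
        group_map_path, index=False, sep=delimiter
    )


def write_fit_result(results, out_prefix, f_grid_points: int = 101) -> dict:
    """Serialize a fitted model: coefficients by group (CSV), the smooth
    estimate sampled on a grid (CSV) and a JSON summary.

    Returns the dict written to ``<out_prefix>_summary.json``.
    """
    out_prefix = str(out_prefix)
    d = results.model.design
    rows = []
    for j, s in enumerate(d.slices):
        for col in range(s.start, s.stop):
            rows.append(
                {
                    "group": results.model.group_names[j],
                    "group_index": j + 1,
                    "column": col + 1,
                    "estimate": results.params[col],
                    "selected": int(j in set(results.selected_groups.tolist())),
                }
            )
    pd.DataFrame(rows).to_csv(out_prefix + "_coefficients.csv", index=False)

    grid = np.linspace(0.0, 1.0, f_grid_points)
    pd.DataFrame({"u": grid, "f_hat": results.f_hat(grid)}).to_csv(
        out_prefix + "_fhat.csv", index=False
    )

    summary = {
        "method": results.method,
        "lambda": results.lambda_,
        "gamma": results.gamma,
        "n_iter": results.n_iter,
        "converged": bool(results.converged),
        "selected_groups": [int(j) + 1 for j in results.selected_groups],
        "selected_group_names": results.selected_group_names,
        "sigma2_hat": results.scale,
        "n_obs": int(d.n),
        "n_groups": int(d.n_groups),
    }
    with open(out_prefix + "_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
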