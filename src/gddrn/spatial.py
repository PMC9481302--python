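"""Neighbourhood-based spatial adjustment for field trials.

Each plot observation loads on nine spatial effects: the 3x3 square of
grid cells centered on the plot itself and on its eight Chebyshev
neighbours.  Virtual plots are added over trial borders and into empty
grid cells so that every real plot has a full neighbourhood.  The
spatial relationship matrix is ``S = X X' / (tr(X X') / n)`` for the
n x q incidence ``X`` (n real plots, q real + virtual spatial ids);
with exactly nine ones per row this scales the diagonal to 1, and the
off-diagonal entries are the shared-square counts / 9, i.e. values in
{0, 1/9, ..., 6/9}.  No directional gradient is assumed: smoothing is
isotropic within a field, and plots in different environments are
unrelated (S is block-diagonal across year-locations).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["add_virtual_plots", "spatial_incidence", "build_spatial_matrix"]

_NEIGH = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]


def _check_coords(layout: pd.DataFrame) -> None:
    for col in ("x", "y"):
        vals = layout[col]
        if vals.isna().any():
            bad = layout.loc[vals.isna(), "obs_id"].tolist()[:5]
            raise ValueError(f"plots with missing {col} coordinate: {bad}")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"non-integer {col} coordinates in layout")


def add_virtual_plots(layout: pd.DataFrame) -> pd.DataFrame:
    """Complete the grid: every real plot gets all eight neighbours.

    Input columns: ``obs_id, env_id, x, y`` (plus any others, carried
    through).  Added rows have ``is_virtual = True``, no ``obs_id`` and
    no phenotype.  Idempotent on a completed layout.
    """
    real = layout[~layout.get("is_virtual", pd.Series(False, index=layout.index)).astype(bool)]
    _check_coords(real)
    dup = real.duplicated(subset=["env_id", "x", "y"])
    if dup.any():
        raise ValueError("duplicate (env_id, x, y) among real plots")
    out = layout.copy()
    if "is_virtual" not in out.columns:
        out["is_virtual"] = False
    new_rows = []
    for env, grp in real.groupby("env_id"):
        occupied = set(zip(grp["x"].astype(int), grp["y"].astype(int)))
        existing_virtual = out[(out["env_id"] == env) & out["is_virtual"]]
        occupied |= set(zip(existing_virtual["x"].astype(int), existing_virtual["y"].astype(int)))
        for x, y in sorted(set(zip(grp["x"].astype(int), grp["y"].astype(int)))):
            for dx, dy in _NEIGH:
                cell = (x + dx, y + dy)
                if cell not in occupied:
                    occupied.add(cell)
                    new_rows.append(
                        {"obs_id": None, "env_id": env, "x": cell[0], "y": cell[1],
                         "line_id": None, "is_virtual": True}
                    )
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
    return out


def spatial_incidence(layout: pd.DataFrame) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Indicator matrix relating real plots to spatial-effect ids.

    Returns ``(X, obs_ids, spatial_ids)`` where ``X`` is n x q sparse
    with exactly nine ones per row.  Requires a completed layout (run
    :func:`add_virtual_plots` first); a missing neighbour raises.
    """
    if "is_virtual" not in layout.columns:
        layout = add_virtual_plots(layout)
    cells = {
        (row.env_id, int(row.x), int(row.y))
        for row in layout.itertuples()
    }
    real = layout[~layout["is_virtual"].astype(bool)].sort_values("obs_id")
    spatial_ids = sorted(f"{e}|{x}|{y}" for (e, x, y) in cells)
    pos = {sid: i for i, sid in enumerate(spatial_ids)}
    rows, cols = [], []
    obs_ids = []
    for i, row in enumerate(real.itertuples()):
        obs_ids.append(row.obs_id)
        x, y = int(row.x), int(row.y)
        for dx, dy in _NEIGH:
            key = f"{row.env_id}|{x + dx}|{y + dy}"
            if key not in pos:
                raise ValueError(f"plot {row.obs_id}: neighbour cell {key} missing from layout")
            rows.append(i)
            cols.append(pos[key])
    X = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(obs_ids), len(spatial_ids))
    )
    return X, obs_ids, spatial_ids


def build_spatial_matrix(layout: pd.DataFrame) -> pd.DataFrame:
    """Spatial relationship matrix ``S = X X' / (tr(X X') / n)``.

    Trace equals n and the diagonal is exactly 1.  Returned dense and
    labeled by ``obs_id``.
    """
    completed = add_virtual_plots(layout)
    X, obs_ids, _ = spatial_incidence(completed)
    n = X.shape[0]
    if n < 1:
        raise ValueError("no real plots in layout")
    XXt = (X @ X.T).toarray()
    scale = np.trace(XXt) / n
    S = XXt / scale
    return pd.DataFrame(S, index=pd.Index(obs_ids, name="obs_id"), columns=obs_ids)
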