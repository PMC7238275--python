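"""Correspondence analysis of expression tables, plus the ddCt utility.

CA decomposes the standardized residuals of a nonnegative table: with
``P = X / grandtotal``, row masses ``r`` and column masses ``c``,
``S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` is factored by SVD.  Principal
inertias are the squared singular values and sum to the Pearson chi-square
statistic divided by the grand total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from podmat.datamodel_io import ValidationError


@dataclass
class CAResult:
    principal_inertias: np.ndarray
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    explained_fraction: np.ndarray
    total_inertia: float


def correspondence_analysis(table: pd.DataFrame) -> CAResult:
    """Correspondence analysis of a nonnegative rows x columns table.

    All-zero rows and columns are dropped with a warning.  Row and column
    coordinates are principal coordinates (scaled by singular values); axis
    signs are not identifiable.
    """
    x = table.to_numpy(dtype=float)
    if x.size == 0:
        raise ValidationError("empty table")
    if (x < 0).any():
        raise ValidationError("table contains negative entries")
    row_keep = x.sum(axis=1) > 0
    col_keep = x.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        warnings.warn(
            f"dropping {(~row_keep).sum()} all-zero rows and "
            f"{(~col_keep).sum()} all-zero columns"
        )
    x = x[np.ix_(row_keep, col_keep)]
    row_index = table.index[row_keep]
    col_index = table.columns[col_keep]
    grand = x.sum()
    if grand <= 0:
        raise ValidationError("zero grand total")
    p = x / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sigma, vt = np.linalg.svd(s, full_matrices=False)
    n_dims = max(0, min(x.shape) - 1)
    sigma = sigma[:n_dims]
    u = u[:, :n_dims]
    v = vt[:n_dims].T
    inertias = sigma ** 2
    total = float((s ** 2).sum())
    explained = inertias / total if total > 0 else np.zeros_like(inertias)
    row_coords = (u / np.sqrt(r)[:, None]) * sigma[None, :]
    col_coords = (v / np.sqrt(c)[:, None]) * sigma[None, :]
    dims = [f"dim{i + 1}" for i in range(n_dims)]
    return CAResult(
        principal_inertias=inertias,
        row_coords=pd.DataFrame(row_coords, index=row_index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=col_index, columns=dims),
        explained_fraction=explained,
        total_inertia=total,
    )


def ddct_relative_expression(ct_target_test: float, ct_hk_test: float,
                             ct_target_ctrl: float, ct_hk_ctrl: float) -> float:
    """Relative expression 2^(-ddCt) from four qPCR cycle thresholds.

    ddCt = (Ct_target,test - Ct_housekeeping,test)
         - (Ct_target,control - Ct_housekeeping,control).
    """
    for v in (ct_target_test, ct_hk_test, ct_target_ctrl, ct_hk_ctrl):
        if not np.isfinite(v):
            raise ValidationError("Ct values must be finite")
    ddct = (ct_target_test - ct_hk_test) - (ct_target_ctrl - ct_hk_ctrl)
    return float(2.0 ** (-ddct))
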