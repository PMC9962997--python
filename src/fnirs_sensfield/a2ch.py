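"""Area-to-channel (A2Ch) coupling analysis.

The sensitivity matrix is reduced over cortical parcellations: summing a
channel's coefficients over the vertices of an area gives the reduced
matrix B; dividing by the channel's total sensitivity over all vertices
gives the normalized coupling A2Ch% in [0, 1] — the fraction of what a
channel senses that comes from that area. Group statistics (median and
IQR across subjects) are compared against reference anatomies with a
0.2 reporting threshold and a 0.2 difference flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mc import SensitivityMatrix
from .montage import Parcellation


@dataclass
class A2chTable:
    median: pd.DataFrame  # channels x areas, group median A2Ch%
    iqr: pd.DataFrame  # channels x areas, Q3 - Q1 across subjects
    references: dict[str, pd.DataFrame]  # named reference A2Ch% tables
    flags: pd.DataFrame  # bool, |median - any reference| > diff threshold
    kept_channels: list  # channels surviving the reporting threshold


def _as_matrix(A) -> np.ndarray:
    return A.A if isinstance(A, SensitivityMatrix) else np.asarray(A)


def reduce_by_area(A, parc: Parcellation) -> np.ndarray:
    """B[i, a] = sum of A[i, j] over vertices j of area a.

    Unlabelled vertices belong to no area. Empty areas produce zero
    columns (with a warning from the caller's perspective via zeros).
    """
    mat = _as_matrix(A)
    areas = parc.area_ids
    B = np.zeros((mat.shape[0], len(areas)))
    for k, a in enumerate(areas):
        j = parc.vertex_indices(a)
        if j.size:
            B[:, k] = mat[:, j].sum(axis=1)
    return B


def a2ch_percent(B: np.ndarray, A) -> np.ndarray:
    """Normalize the reduced matrix by channel total sensitivity.

    Channels with zero total sensitivity get NaN rows (flagged
    undefined rather than silently zero).
    """
    mat = _as_matrix(A)
    totals = mat.sum(axis=1)
    out = np.full(B.shape, np.nan)
    ok = totals > 0
    out[ok] = B[ok] / totals[ok, None]
    return out


def group_stats_and_flags(tables: list[pd.DataFrame],
                          references: dict[str, pd.DataFrame] | None = None,
                          report_threshold: float = 0.2,
                          diff_threshold: float = 0.2) -> A2chTable:
    """Median/IQR across subjects, reporting cutoff, reference flags.

    All per-subject tables (channels x areas) must share indexing. A
    channel row is kept when any cell — group median or any reference —
    is strictly above ``report_threshold``. A cell is flagged when the
    group median differs from any reference by strictly more than
    ``diff_threshold``. IQR is Q3 - Q1 with linear interpolation.
    """
    references = references or {}
    idx, cols = tables[0].index, tables[0].columns
    for t in list(tables) + list(references.values()):
        if not (t.index.equals(idx) and t.columns.equals(cols)):
            raise ValueError("all tables must share channel/area indexing")
    stack = np.stack([t.values for t in tables])
    median = pd.DataFrame(np.median(stack, axis=0), index=idx, columns=cols)
    q1 = np.percentile(stack, 25.0, axis=0)
    q3 = np.percentile(stack, 75.0, axis=0)
    iqr = pd.DataFrame(q3 - q1, index=idx, columns=cols)

    keep = (median > report_threshold).any(axis=1)
    for ref in references.values():
        keep |= (ref > report_threshold).any(axis=1)
    kept = list(idx[keep])

    flags = pd.DataFrame(False, index=idx, columns=cols)
    for ref in references.values():
        flags |= (median - ref).abs() > diff_threshold
    return A2chTable(median=median, iqr=iqr, references=references,
                     flags=flags, kept_channels=kept)


def a2ch_table(A, parc: Parcellation, channel_names: list | None = None
               ) -> pd.DataFrame:
    """One subject's A2Ch% as a channels x areas DataFrame."""
    B = reduce_by_area(A, parc)
    pct = a2ch_percent(B, A)
    names = [parc.area_names.get(a, f"area_{a}") for a in parc.area_ids]
    if channel_names is None:
        ids = A.channel_ids if isinstance(A, SensitivityMatrix) else range(pct.shape[0])
        channel_names = [f"ch{c}" for c in ids]
    return pd.DataFrame(pct, index=channel_names, columns=names)
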