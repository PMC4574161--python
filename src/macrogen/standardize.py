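"""Within-study standardisation of diversity values.

The "standardised" (Z) model family works on diversity z-scored within each
dataID (study x marker group): subtract the group mean, divide by the group
sample standard deviation (n-1 denominator).  Groups where the z-score is
undefined — a single member, or zero variance — are excluded and reported,
never zero-filled.
"""

from __future__ import annotations

from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .records import DiversityDataset


def zscore_by_group(
    values: Sequence[float],
    groups: Sequence[Hashable],
) -> tuple[np.ndarray, list[Hashable]]:
    """Z-score ``values`` within each group label.

    Returns ``(z, skipped)`` where ``z`` matches the input order and
    ``skipped`` lists group labels with fewer than two members or zero
    variance; entries of skipped groups are NaN in ``z``.

    Within every retained group, the output has mean 0 and sample standard
    deviation 1 (to numerical tolerance).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    ser = pd.Series(values)
    key = pd.Series(list(groups))
    z = np.full(len(values), np.nan)
    skipped: list[Hashable] = []
    for g, idx in ser.groupby(key).groups.items():
        vals = values[np.asarray(idx)]
        if len(vals) < 2 or np.std(vals, ddof=1) == 0.0:
            skipped.append(g)
            continue
        z[np.asarray(idx)] = (vals - vals.mean()) / np.std(vals, ddof=1)
    return z, skipped


def add_zscores(ds: DiversityDataset) -> tuple[DiversityDataset, list[str]]:
    """Attach a ``z`` column (per-dataID z-scored H) to the dataset.

    Records belonging to degenerate dataIDs (fewer than two populations or
    zero variance in H) are dropped from the returned dataset; their dataIDs
    are returned as the skip list.
    """
    z, skipped = zscore_by_group(ds.df["H"].to_numpy(), ds.df["dataID"].to_numpy())
    df = ds.df.copy()
    df["z"] = z
    df = df[~df["z"].isna()]
    if len(df) == 0:
        raise ValueError("no records remain after excluding degenerate dataIDs")
    return DiversityDataset(df), [str(s) for s in skipped]
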