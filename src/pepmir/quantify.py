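"""Count normalization (median-of-ratios size factors) and composition profiles.

The size factor of library j is the median, over rows with a positive
geometric mean, of count_ij divided by the row geometric mean -- the
median-of-ratios estimator used by count-based differential expression
packages. Only normalization is performed here; no dispersion estimation or
testing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import Tag


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, one per library (column).

    Rows containing any zero are excluded from the reference (classic
    estimator). With ``pseudo_reference=True`` the geometric mean is instead
    taken over non-zero entries only, a fallback for sparse matrices where no
    all-positive row exists.
    """
    m = counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logm = np.where(m > 0, np.log(m), np.nan)
        gm = np.exp(np.nanmean(logm, axis=1))
        rows = ~np.isnan(gm) & (gm > 0)
    else:
        rows = (m > 0).all(axis=1)
        if not rows.any():
            raise ValueError(
                "no row with all counts > 0; rerun with pseudo_reference=True"
            )
        gm = np.exp(np.log(m, where=m > 0, out=np.zeros_like(m)).mean(axis=1))
    ratios = m[rows] / gm[rows, None]
    s = np.median(ratios, axis=0)
    if not (s > 0).all():
        raise ValueError("non-positive size factor; matrix too sparse")
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Divide each library column by its size factor."""
    return counts / s


def normalized_int(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Normalized counts rounded to integers, as printed in catalog tables."""
    return normalize(counts, s).round().astype(int)


def length_5p_profile(tags: Sequence[Tag]) -> pd.DataFrame:
    """Count-weighted (length, 5' nucleotide) composition per library.

    Rows are a MultiIndex (length, nt); columns are libraries; each column
    sums to that library's total read count over the given tags.
    """
    if not tags:
        return pd.DataFrame()
    libraries = tags[0].libraries
    cells: dict[tuple[int, str], np.ndarray] = {}
    for tag in tags:
        key = (len(tag.seq), tag.seq[0])
        if key not in cells:
            cells[key] = np.zeros(len(libraries), dtype=np.int64)
        cells[key] += np.asarray(tag.counts, dtype=np.int64)
    idx = pd.MultiIndex.from_tuples(sorted(cells), names=["length", "nt5"])
    data = np.vstack([cells[k] for k in sorted(cells)])
    return pd.DataFrame(data, index=idx, columns=libraries)


def plot_profile(profile: pd.DataFrame, path: str) -> None:
    """Bar chart of the length/5'-nt composition, one panel per library."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    libs = list(profile.columns)
    fig, axes = plt.subplots(
        len(libs), 1, figsize=(8, 2.2 * len(libs)), squeeze=False
    )
    labels = [f"{l}{n}" for l, n in profile.index]
    for ax, lib in zip(axes.ravel(), libs):
        ax.bar(range(len(profile)), profile[lib].to_numpy())
        ax.set_xticks(range(len(profile)))
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_ylabel(lib)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
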