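"""Developmental trajectory standardization, regulation classes, time-point clustering.

Genes are classified by comparing the developmental trajectory to the
hypothetical linearly increasing trajectory y = x: Pearson r > 0.5 is
up-regulated, r < -0.5 down-regulated. Genes whose abundance never changes
two-fold between any two time points are invariant; invariance is tested
first so a flat-but-noisy gene is never called up or down. Everything else is
"other" (e.g. transient regulation).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datatypes import parse_sample_name

__all__ = [
    "replicate_mean_profiles",
    "standardize_profiles",
    "classify_regulation",
    "cluster_timepoints",
    "heatmap_order",
    "HeatmapLayout",
]


def replicate_mean_profiles(
    logged: pd.DataFrame,
) -> pd.DataFrame:
    """Average log-scale replicate values into one trajectory per gene.

    Input columns follow the ``SPECIES_Thh_Rn`` convention; output columns are
    time points in hours, ascending.
    """
    groups: dict[int, list[str]] = {}
    for col in logged.columns:
        _sp, hours, _rep = parse_sample_name(col)
        groups.setdefault(hours, []).append(col)
    out = {hours: logged[cols].mean(axis=1) for hours, cols in sorted(groups.items())}
    return pd.DataFrame(out)


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene's trajectory across time points (population sd).

    Constant trajectories map to all zeros.
    """
    values = profiles.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population (divide-by-T) convention
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def classify_regulation(
    log_profiles: pd.DataFrame,
    fold_threshold: float = 2.0,
    cor_threshold: float = 0.5,
) -> pd.DataFrame:
    """Call up / down / invariant / other for every gene.

    ``log_profiles`` holds replicate-mean log2 abundances (gene x time).
    The fold change between the extreme time points is 2**(max - min); a gene
    below ``fold_threshold`` is invariant before any correlation is computed.
    Returns a frame with columns reg_class, correlation, max_fold.
    """
    if log_profiles.shape[1] < 3:
        raise ValueError("classification requires at least 3 time points")
    values = log_profiles.to_numpy(dtype=float)
    t = np.arange(1, values.shape[1] + 1, dtype=float)
    span = values.max(axis=1) - values.min(axis=1)
    max_fold = np.exp2(span)

    tz = (t - t.mean()) / t.std()
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ((values - values.mean(axis=1, keepdims=True)) / sd[:, None] * tz).mean(axis=1)
    r[sd == 0] = 0.0

    classes = np.where(
        max_fold < fold_threshold,
        "invariant",
        np.where(r > cor_threshold, "up", np.where(r < -cor_threshold, "down", "other")),
    )
    return pd.DataFrame(
        {"reg_class": classes, "correlation": r, "max_fold": max_fold},
        index=log_profiles.index,
    )


def cluster_timepoints(matrix: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Average-linkage hierarchical clustering of time-point columns.

    Distance is 1 - Pearson correlation between columns over all genes.
    Returns (scipy linkage matrix, column labels in input order).
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 time points and 2 genes")
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=0)
    if (sds == 0).any():
        bad = [str(c) for c, s in zip(matrix.columns, sds) if s == 0]
        raise ValueError(f"constant columns have undefined correlation: {bad}")
    corr = np.corrcoef(values, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0, None), checks=False)
    return linkage(condensed, method="average"), list(matrix.columns)


@dataclass
class HeatmapLayout:
    order: list          # gene ids, top to bottom
    boundaries: list     # cumulative section boundaries incl. 0 and n
    sections: list       # section names in display order


def heatmap_order(calls: pd.DataFrame, z_profiles: pd.DataFrame) -> HeatmapLayout:
    """Display order: down-regulated, intermediate (other + invariant), up.

    Within a section genes sort by the time index of their trajectory maximum,
    ties broken by gene id.
    """
    if set(calls.index) != set(z_profiles.index):
        raise ValueError("calls and profiles must cover the same genes")
    peak = pd.Series(
        np.argmax(z_profiles.to_numpy(dtype=float), axis=1), index=z_profiles.index
    )
    section_of = {"down": 0, "other": 1, "invariant": 1, "up": 2}
    df = pd.DataFrame(
        {
            "section": calls["reg_class"].map(section_of),
            "peak": peak.reindex(calls.index),
            "gene": calls.index,
        }
    )
    df = df.sort_values(["section", "peak", "gene"], kind="mergesort")
    counts = [int((df["section"] == s).sum()) for s in (0, 1, 2)]
    boundaries = [0, counts[0], counts[0] + counts[1], len(df)]
    return HeatmapLayout(
        order=list(df["gene"]),
        boundaries=boundaries,
        sections=["down", "intermediate", "up"],
    )
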