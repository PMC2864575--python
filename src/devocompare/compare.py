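"""Cross-species conservation of ortholog expression profiles and abundance.

Profile conservation is the Pearson correlation between the two species'
replicate-mean log trajectories of each ortholog pair, summarized into four
similarity sections and a 2-D (abundance x similarity) kernel density.
Temporal shifts are detected on the poorly correlated pairs (r < 0.75) by
cross-correlation at whole time-step lags, following the R ``ccf`` convention:
the lagged covariance over the overlapping time points is normalized by the
full-series standard deviations and length, so lagged correlations of
unrelated profiles shrink with the overlap and rarely clear the threshold by
chance. A pair is assigned the shift class whose lag first exceeds the
threshold correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import parse_sample_name

logger = logging.getLogger(__name__)

__all__ = [
    "ortholog_similarity",
    "timepoint_correspondence",
    "shift_classification",
    "abundance_conservation",
    "category_rank_percentile",
    "nonortholog_abundance_test",
    "SIMILARITY_SECTIONS",
]

#: Section labels, most to least conserved, with their (lo, hi] correlation bounds.
SIMILARITY_SECTIONS = (
    ("r>0.5", 0.5, np.inf),
    ("0<r<=0.5", 0.0, 0.5),
    ("-0.5<r<=0", -0.5, 0.0),
    ("r<=-0.5", -np.inf, -0.5),
)


def _pair_arrays(
    profiles_a: pd.DataFrame, profiles_b: pd.DataFrame, orthologs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    a = profiles_a.loc[orthologs["gene_a"]].to_numpy(dtype=float)
    b = profiles_b.loc[orthologs["gene_b"]].to_numpy(dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("both species must have the same number of time points")
    return a, b


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    sa = a.std(axis=1)
    sb = b.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (
            (a - a.mean(axis=1, keepdims=True)) * (b - b.mean(axis=1, keepdims=True))
        ).mean(axis=1) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan
    return r


def _nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference bandwidth (per dimension)."""
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sd = x.std(ddof=1)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 1.06 * spread * len(x) ** (-1 / 5) if spread > 0 else 1.0


def _kde2d(x: np.ndarray, y: np.ndarray, gridsize: int = 50) -> dict:
    hx, hy = _nrd_bandwidth(x), _nrd_bandwidth(y)
    gx = np.linspace(x.min(), x.max(), gridsize)
    gy = np.linspace(y.min(), y.max(), gridsize)
    zx = stats.norm.pdf((gx[:, None] - x[None, :]) / hx) / hx
    zy = stats.norm.pdf((gy[:, None] - y[None, :]) / hy) / hy
    density = zx @ zy.T / len(x)
    return {"x": gx.tolist(), "y": gy.tolist(), "density": density.tolist()}


def ortholog_similarity(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    orthologs: pd.DataFrame,
    gridsize: int = 50,
) -> tuple[pd.DataFrame, dict[str, int], dict]:
    """Per-pair profile correlation, similarity sections, and 2-D density.

    Profiles are replicate-mean log2 trajectories. Pairs with a constant
    profile in either species have undefined correlation; they are reported
    with NaN, excluded from the sections, and counted under ``undefined``.
    The density grid spans (log10 mean abundance, correlation).
    """
    a, b = _pair_arrays(profiles_a, profiles_b, orthologs)
    r = _rowwise_pearson(a, b)
    mean_abundance = (np.exp2(np.concatenate([a, b], axis=1)) - 1).mean(axis=1)
    section = np.full(len(r), "undefined", dtype=object)
    for name, lo, hi in SIMILARITY_SECTIONS:
        section[(r > lo) & (r <= hi)] = name
    pairs = pd.DataFrame(
        {
            "gene_a": orthologs["gene_a"].to_numpy(),
            "gene_b": orthologs["gene_b"].to_numpy(),
            "correlation": r,
            "mean_abundance": mean_abundance,
            "section": section,
        }
    )
    counts = {name: int((section == name).sum()) for name, *_ in SIMILARITY_SECTIONS}
    counts["undefined"] = int(np.isnan(r).sum())
    ok = ~np.isnan(r)
    density = (
        _kde2d(np.log10(mean_abundance[ok] + 1), r[ok], gridsize)
        if ok.sum() >= 2
        else {"x": [], "y": [], "density": []}
    )
    return pairs, counts, density


def timepoint_correspondence(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> pd.DataFrame:
    """Best-matching species-A time point for every species-B time point.

    Both matrices are (ortholog gene x time) in matched gene order; the
    correlation is computed across genes. Ties go to the earliest A column.
    """
    if matrix_a.shape[0] != matrix_b.shape[0]:
        raise ValueError("matrices must be restricted to the same ortholog pairs")
    a = matrix_a.to_numpy(dtype=float)
    b = matrix_b.to_numpy(dtype=float)
    rows = []
    for j, col_b in enumerate(matrix_b.columns):
        rs = np.array(
            [stats.pearsonr(a[:, i], b[:, j]).statistic for i in range(a.shape[1])]
        )
        best = int(np.argmax(rs))  # argmax returns the earliest maximal index
        rows.append({"timepoint_b": col_b, "best_a": matrix_a.columns[best], "r": rs[best]})
    return pd.DataFrame(rows).set_index("timepoint_b")


def _ccf_lag(a: np.ndarray, b: np.ndarray, lag: int) -> tuple[float, int]:
    """Lagged cross-correlation, full-series normalization (R ccf convention).

    Positive lag means species B is delayed: b[t + lag] is aligned with a[t].
    Returns (correlation, number of overlapping points).
    """
    T = len(a)
    da = a - a.mean()
    db = b - b.mean()
    denom = T * a.std() * b.std()
    if lag >= 0:
        prod = (da[: T - lag] * db[lag:]).sum()
        n_overlap = T - lag
    else:
        prod = (da[-lag:] * db[: T + lag]).sum()
        n_overlap = T + lag
    return float(prod / denom) if denom > 0 else np.nan, n_overlap


def shift_classification(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    orthologs: pd.DataFrame,
    threshold: float = 0.75,
    step_hours: float = 4.0,
    max_shift_steps: int = 2,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Temporal-shift classes for ortholog pairs.

    Pairs already correlated above ``threshold`` are class ``none``; the rest
    are tested at lags of +-1..max_shift_steps whole time steps (B delayed and
    A delayed), keeping lags with at least ``min_overlap`` overlapping points.
    The best lag whose ccf-normalized correlation exceeds the threshold gives
    the class: one step is the "+4h" class, two or more is ">4h", for the
    delayed species; pairs that never clear the threshold are unclassified.
    """
    if profiles_a.shape[1] < 4:
        raise ValueError("shift detection requires at least 4 time points")
    a, b = _pair_arrays(profiles_a, profiles_b, orthologs)
    step_label = f"{step_hours:g}h"
    records = []
    lags = [l for l in range(-max_shift_steps, max_shift_steps + 1) if l != 0]
    for i in range(len(a)):
        base = _rowwise_pearson(a[i : i + 1], b[i : i + 1])[0]
        if np.isnan(base):
            records.append(("unclassified", base, np.nan, 0))
            continue
        if base >= threshold:
            records.append(("none", base, base, 0))
            continue
        best_r, best_lag = -np.inf, 0
        for lag in lags:
            r, n_overlap = _ccf_lag(a[i], b[i], lag)
            if n_overlap < min_overlap or np.isnan(r):
                continue
            if r > best_r or (r == best_r and abs(lag) < abs(best_lag)):
                best_r, best_lag = r, lag
        if best_r > threshold:
            species = "B" if best_lag > 0 else "A"
            rel = "+" if abs(best_lag) == 1 else ">"
            cls = f"{species}{rel}{step_label}"
            records.append((cls, base, best_r, best_lag))
        else:
            records.append(("unclassified", base, best_r if np.isfinite(best_r) else np.nan, 0))
    out = pd.DataFrame(
        records,
        columns=["shift_class", "base_correlation", "achieved_correlation", "lag_steps"],
    )
    out.insert(0, "gene_b", orthologs["gene_b"].to_numpy())
    out.insert(0, "gene_a", orthologs["gene_a"].to_numpy())
    return out


ABUNDANCE_TIERS = (("low", -np.inf, 1000.0), ("intermediate", 1000.0, 10000.0), ("high", 10000.0, np.inf))


def developmental_sums(scaled_values: pd.DataFrame) -> pd.Series:
    """Sum of replicate-mean scaled abundance over all developmental stages."""
    by_time: dict[int, list[str]] = {}
    for col in scaled_values.columns:
        _sp, hours, _rep = parse_sample_name(col)
        by_time.setdefault(hours, []).append(col)
    means = pd.DataFrame(
        {hours: scaled_values[cols].mean(axis=1) for hours, cols in sorted(by_time.items())}
    )
    return means.sum(axis=1)


def abundance_tier(sums: pd.Series) -> pd.Series:
    """low (<1,000), intermediate (1,000-10,000 inclusive), high (>10,000)."""
    tier = pd.Series("intermediate", index=sums.index, dtype=object)
    tier[sums < 1000.0] = "low"
    tier[sums > 10000.0] = "high"
    return tier


@dataclass
class AbundanceConservation:
    sums_a: pd.Series
    sums_b: pd.Series
    correlation: float  # Pearson on log10 sums; NaN when undefined
    tiers_a: pd.Series
    tiers_b: pd.Series


def abundance_conservation(
    scaled_a: pd.DataFrame, scaled_b: pd.DataFrame, orthologs: pd.DataFrame
) -> AbundanceConservation:
    """Conservation of summed developmental abundance between ortholog pairs."""
    sums_a = developmental_sums(scaled_a).loc[orthologs["gene_a"]]
    sums_b = developmental_sums(scaled_b).loc[orthologs["gene_b"]]
    la = np.log10(sums_a.to_numpy(dtype=float) + 1)
    lb = np.log10(sums_b.to_numpy(dtype=float) + 1)
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        logger.warning("one species' abundance sums are constant; correlation undefined")
        r = np.nan
    else:
        r = float(np.corrcoef(la, lb)[0, 1])
    return AbundanceConservation(
        sums_a=sums_a,
        sums_b=sums_b,
        correlation=r,
        tiers_a=abundance_tier(sums_a),
        tiers_b=abundance_tier(sums_b),
    )


def category_rank_percentile(
    abundances: pd.Series, category_map: dict[str, set[str] | list[str]]
) -> pd.DataFrame:
    """Median abundance-rank percentile of each functional category.

    Genes are ranked ascending (average ranks for ties) over all N genes of
    the species; a gene's percentile is 100*rank/N, and a category's summary
    P is the median percentile of its members. Categories may overlap; empty
    categories are skipped with a warning.
    """
    ranks = pd.Series(
        stats.rankdata(abundances.to_numpy(dtype=float), method="average"),
        index=abundances.index,
    )
    percentile = 100.0 * ranks / len(abundances)
    rows = {}
    for term, members in category_map.items():
        members = [m for m in members if m in percentile.index]
        if not members:
            logger.warning("category %r has no genes with abundance; skipped", term)
            continue
        rows[term] = {
            "median_percentile": float(percentile.loc[members].median()),
            "n_genes": len(members),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class TwoSampleResult:
    statistic: float
    pvalue: float
    mean_ortholog: float
    mean_nonortholog: float
    direction: str  # "orthologs_higher" / "nonorthologs_higher" / "equal"


def nonortholog_abundance_test(
    sums: pd.Series, is_ortholog: pd.Series
) -> TwoSampleResult:
    """Welch t-test of log10 developmental abundance sums, orthologs vs not."""
    flags = is_ortholog.reindex(sums.index).astype(bool)
    x = np.log10(sums[flags].to_numpy(dtype=float) + 1)
    y = np.log10(sums[~flags].to_numpy(dtype=float) + 1)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 genes")
    mx, my = float(x.mean()), float(y.mean())
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and mx == my:
        return TwoSampleResult(0.0, 1.0, mx, my, "equal")
    res = stats.ttest_ind(x, y, equal_var=False)
    direction = (
        "orthologs_higher" if mx > my else "nonorthologs_higher" if my > mx else "equal"
    )
    return TwoSampleResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_ortholog=mx,
        mean_nonortholog=my,
        direction=direction,
    )
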