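"""Differential-abundance statistics for label-free protein quantification.

The pipeline order is fixed: arcsinh-transform the normalized abundances,
average the technical replicates of each biological sample on the
transformed scale, test group differences with a pooled-variance two-sample
t-test on the transformed sample means, compute fold changes on the
untransformed normalized-abundance scale, apply the significance filter
(>=2 unique peptides, |fold change| >= 2, p <= 0.05), and rank by the
Euclidean distance from the origin of the volcano plane

    d_eucl = sqrt( (log10 p)^2 + (log10 FC)^2 ),

which combines effect size and significance into one score (FC is the
unsigned >= 1 fold change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ValidationError
from .hyperspec_io import ProteinAbundanceTable

__all__ = [
    "SignificanceThresholds",
    "DERecord",
    "arcsinh_transform",
    "sinh_inverse",
    "average_replicates",
    "differential_test",
    "fold_change",
    "euclidean_rank",
    "significance_filter",
    "differential_analysis",
    "volcano_export",
]

VOLCANO_CONTOURS = (1.0, 1.5, 2.0)


@dataclass(frozen=True)
class SignificanceThresholds:
    """Filter for differential expression: peptide support, effect, p-value."""

    min_unique_peptides: int = 2
    min_fold_change: float = 2.0
    max_p_value: float = 0.05


@dataclass
class DERecord:
    """Per-protein differential-abundance result."""

    accession: str
    gene: str
    unique_peptides: int
    p_value: float
    fold_change: float  # unsigned, >= 1
    direction: str  # 'A-higher' / 'B-higher'
    signed_fc: float  # +fc or -fc
    significant: bool
    d_eucl: float
    degenerate: bool = False


def arcsinh_transform(values: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Variance-stabilizing y = ln(x + sqrt(x^2 + 1)) for abundances >= 0."""
    arr = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if np.any(arr < 0):
        raise ValidationError("abundances must be nonnegative for arcsinh transform")
    out = np.arcsinh(arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def sinh_inverse(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`arcsinh_transform`."""
    return np.sinh(np.asarray(values, float))


def average_replicates(
    abundances: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Average technical-replicate columns into one column per sample.

    Works on whatever scale the input is on; call it on the arcsinh scale
    for testing and on the raw normalized scale for fold changes.
    Replicate order is irrelevant (plain mean).
    """
    out = {}
    for sample, sub in design.groupby("sample", sort=True):
        runs = sub["run"].tolist()
        missing = [r for r in runs if r not in abundances.columns]
        if missing:
            raise ValidationError(f"sample '{sample}': runs {missing} absent from table")
        if not runs:
            raise ValidationError(f"sample '{sample}' has no replicates")
        out[str(sample)] = abundances[runs].mean(axis=1)
    return pd.DataFrame(out)


def differential_test(
    per_sample: pd.DataFrame, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Pooled-variance two-sided t-test per protein across two groups.

    Returns a frame with ``t``, ``p_value`` and a ``degenerate`` flag.
    Zero pooled variance yields p = 1 for equal means and p -> 0 (flagged
    degenerate) for unequal means.
    """
    if len(groups) != 2:
        raise ParameterError("differential test requires exactly two groups")
    (name_a, samples_a), (name_b, samples_b) = groups.items()
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("each group needs >=2 biological samples")
    a = per_sample[samples_a].to_numpy(dtype=float)
    b = per_sample[samples_b].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled_var = ss / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    zero_var = pooled_var == 0
    equal_means = mean_a == mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = zero_var & ~equal_means
    p = np.where(zero_var & equal_means, 1.0, p)
    p = np.where(degenerate, np.nextafter(0.0, 1.0), p)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(mean_a - mean_b) * np.inf, t)
    return pd.DataFrame(
        {"t": t, "p_value": p, "degenerate": degenerate}, index=per_sample.index
    )


def fold_change(
    per_sample_raw: pd.DataFrame, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Group-mean ratio on the normalized-abundance (untransformed) scale.

    ``fold_change`` is the unsigned max(r, 1/r) >= 1; ``signed_fc`` carries
    the sign (negative when group B is higher).  Proteins with a zero group
    mean are flagged ``fc_degenerate`` and excluded from ranking.
    """
    (name_a, samples_a), (name_b, samples_b) = groups.items()
    mean_a = per_sample_raw[samples_a].mean(axis=1).to_numpy()
    mean_b = per_sample_raw[samples_b].mean(axis=1).to_numpy()
    degenerate = (mean_a <= 0) | (mean_b <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(degenerate, np.nan, mean_a / np.where(mean_b > 0, mean_b, 1.0))
    fc = np.where(ratio >= 1, ratio, 1.0 / ratio)
    direction = np.where(ratio >= 1, f"{name_a}-higher", f"{name_b}-higher")
    signed = np.where(ratio >= 1, fc, -fc)
    return pd.DataFrame(
        {
            "fold_change": fc,
            "direction": direction,
            "signed_fc": signed,
            "fc_degenerate": degenerate,
        },
        index=per_sample_raw.index,
    )


def euclidean_rank(
    p_value: float | np.ndarray, fold_change: float | np.ndarray
) -> float | np.ndarray:
    """Euclidean distance from the volcano-plane origin.

    ``d = sqrt((log10 p)^2 + (log10 FC)^2)`` with p in (0, 1] and the
    unsigned fold change >= 1.  Monotonic: smaller p or larger FC never
    decreases d.
    """
    p = np.asarray(p_value, dtype=float)
    fc = np.asarray(fold_change, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    if np.any(fc < 1):
        raise ParameterError("fold change must be the unsigned ratio >= 1")
    d = np.sqrt(np.log10(p) ** 2 + np.log10(fc) ** 2)
    return float(d) if d.ndim == 0 else d


def significance_filter(
    records: pd.DataFrame, thresholds: SignificanceThresholds | None = None
) -> pd.DataFrame:
    """Mark records significant iff all three thresholds hold.

    Expects columns ``unique_peptides``, ``fold_change``, ``p_value`` and a
    ``direction`` column for the per-direction counts.
    """
    thresholds = thresholds or SignificanceThresholds()
    records = records.copy()
    records["significant"] = (
        (records["unique_peptides"] >= thresholds.min_unique_peptides)
        & (records["fold_change"] >= thresholds.min_fold_change)
        & (records["p_value"] <= thresholds.max_p_value)
    )
    if "fc_degenerate" in records.columns:
        records.loc[records["fc_degenerate"].astype(bool), "significant"] = False
    records.attrs["significant_counts_by_direction"] = (
        records.loc[records["significant"], "direction"].value_counts().to_dict()
    )
    return records


def differential_analysis(
    table: ProteinAbundanceTable,
    thresholds: SignificanceThresholds | None = None,
    fold_change_scale: str = "normalized",
) -> pd.DataFrame:
    """Full analysis: transform -> average -> test + fold change -> filter -> rank.

    ``fold_change_scale='normalized'`` (default) takes group-mean ratios of
    the replicate-averaged raw normalized abundances;
    ``'back-transformed'`` instead back-transforms the arcsinh sample means.
    Output is sorted by d_eucl descending, ties broken by smaller p then
    accession.  Adds an information-only Benjamini-Hochberg column
    ``p_adj_bh`` (no correction enters the significance filter).
    """
    groups = table.groups
    if len(groups) != 2:
        raise ValidationError("differential analysis requires exactly two groups")
    transformed = arcsinh_transform(table.abundances)
    per_sample_t = average_replicates(transformed, table.design)
    test = differential_test(per_sample_t, groups)
    if fold_change_scale == "normalized":
        per_sample_raw = average_replicates(table.abundances, table.design)
    elif fold_change_scale == "back-transformed":
        per_sample_raw = per_sample_t.apply(sinh_inverse)
    else:
        raise ParameterError(f"unknown fold_change_scale '{fold_change_scale}'")
    fc = fold_change(per_sample_raw, groups)

    records = pd.concat(
        [table.proteins.reset_index(drop=True), test.reset_index(drop=True),
         fc.reset_index(drop=True)],
        axis=1,
    )
    records = significance_filter(records, thresholds)
    ok = ~records["fc_degenerate"].astype(bool)
    records["d_eucl"] = np.nan
    records.loc[ok, "d_eucl"] = euclidean_rank(
        records.loc[ok, "p_value"].to_numpy(), records.loc[ok, "fold_change"].to_numpy()
    )
    from statsmodels.stats.multitest import multipletests

    records["p_adj_bh"] = multipletests(records["p_value"].to_numpy(), method="fdr_bh")[1]
    records = records.sort_values(
        ["d_eucl", "p_value", "accession"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return records


def volcano_export(
    records: pd.DataFrame, contour_levels: tuple[float, ...] = VOLCANO_CONTOURS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volcano-plot table plus the contour-circle geometry.

    Per record: signed log10 fold change, -log10 p, d_eucl and the highest
    contour level <= d_eucl (closed boundary: a record exactly on a circle
    belongs to that tier).  Contours are origin-centered circles in the
    (log10 FC, -log10 p) plane.
    """
    if len(records) == 0:
        empty = pd.DataFrame(
            columns=["accession", "log10_fc_signed", "neg_log10_p", "d_eucl", "tier"]
        )
        return empty, _contour_frame(contour_levels)
    out = pd.DataFrame(
        {
            "accession": records["accession"],
            "log10_fc_signed": np.sign(records["signed_fc"])
            * np.log10(records["fold_change"]),
            "neg_log10_p": -np.log10(records["p_value"]),
            "d_eucl": records["d_eucl"],
        }
    )
    levels = sorted(contour_levels)
    tier = np.zeros(len(out))
    for level in levels:
        tier = np.where(out["d_eucl"].to_numpy() >= level, level, tier)
    out["tier"] = tier
    return out.reset_index(drop=True), _contour_frame(contour_levels)


def _contour_frame(levels: tuple[float, ...], n_points: int = 181) -> pd.DataFrame:
    theta = np.linspace(0, 2 * np.pi, n_points)
    rows = []
    for level in sorted(levels):
        rows.append(
            pd.DataFrame(
                {
                    "level": level,
                    "log10_fc": level * np.cos(theta),
                    "neg_log10_p": level * np.sin(theta),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
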