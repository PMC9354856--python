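"""Feature engineering: replicate signals -> reliability-adjusted fold changes,
sample weights, gene filtering, and descriptor curation/normalization.

The reliability adjustment shrinks the fold-change *increment* (distance from
1) of unreliable cells toward no-change. Severity order, strongest wins and no
compounding:

1. every detection call Absent (both groups, both data sources) -> set to 1;
2. Welch p > 0.1 -> increment times 1/4 (1.4 becomes 1.1);
3. treated-group Absent calls at/above the source threshold (2 of 3 in vivo,
   1 of 2 in vitro) or 0.05 <= p <= 0.1 -> increment times 1/2 (1.5 becomes 1.25);
4. otherwise unchanged.

Down-regulated cells (F < 1) are shrunk in reciprocal space, so the rule is
symmetric in the sign of log2 F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DescriptorTable,
    FoldChangeMatrix,
    ReplicateExpressionTable,
    ValidationError,
)

__all__ = [
    "AdjustmentContext",
    "WeightRule",
    "compute_fold_change",
    "adjust_fold_change",
    "adjust_matrix",
    "assign_weight",
    "weight_matrix",
    "filter_genes",
    "curate_descriptors",
    "normalize_descriptors",
    "apply_descriptor_transforms",
    "pearson_normality_statistic",
]


@dataclass(frozen=True)
class AdjustmentContext:
    """Thresholds of the reliability-shrinkage rules for one data source."""

    source: str
    flagA_threshold: int
    p_half_band: tuple[float, float] = (0.05, 0.1)
    p_quarter_threshold: float = 0.1
    shrink_half: float = 0.5
    shrink_quarter: float = 0.25

    def __post_init__(self) -> None:
        if self.flagA_threshold <= 0:
            raise ValidationError("flagA_threshold must be positive")
        for k in (self.shrink_half, self.shrink_quarter):
            if not 0 < k < 1:
                raise ValidationError("shrink factors must lie in (0, 1)")

    @classmethod
    def for_source(cls, source: str) -> "AdjustmentContext":
        # >=2 of 3 treated replicates Absent in vivo; >=1 of 2 in vitro.
        return cls(source=source, flagA_threshold={"in_vivo": 2, "in_vitro": 1}[source])


@dataclass(frozen=True)
class WeightRule:
    """Training-sample weights by fold-change magnitude: >=1.5x -> 1.5, >=4x -> 2.

    Magnitude is max(F, 1/F) so down-regulation is weighted symmetrically.
    """

    thresholds: tuple[tuple[float, float], ...] = ((4.0, 2.0), (1.5, 1.5))
    default: float = 1.0


def compute_fold_change(table: ReplicateExpressionTable) -> FoldChangeMatrix:
    """Fold change, Welch p-value and Absent-call summaries per (substance, gene).

    F = mean(treated signals) / mean(control signals); the p-value comes from an
    unequal-variance two-sample t-test on the log2 signals. Cells where both
    groups have zero variance and equal means get an undefined p (NaN), which
    the adjustment rules treat as no evidence against the change.
    """
    treated = table.signal_array("treated")
    control = table.signal_array("control")
    ctrl_mean = control.mean(axis=2)
    if not (ctrl_mean > 0).all():
        s, g = np.argwhere(~(ctrl_mean > 0))[0]
        raise ValidationError(
            f"non-positive control mean at (substance={table.substances[s]}, "
            f"gene={table.genes[g]})"
        )
    values = treated.mean(axis=2) / ctrl_mean
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # near-identical replicates give a degenerate t-test; the undefined
        # (NaN) p that results is handled explicitly by the adjustment rules
        _warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(
            np.log2(treated), np.log2(control), axis=2, equal_var=False
        )
        pvals = np.asarray(res.pvalue, dtype=float)
    flag_a = (table.call_array("treated") == "A").sum(axis=2)
    idx, cols = table.substances, table.genes
    return FoldChangeMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        source=table.source,
        pvalues=pd.DataFrame(pvals, index=idx, columns=cols),
        flag_summary=pd.DataFrame(flag_a, index=idx, columns=cols),
        all_absent=table.all_absent(),
    )


def _shrink(F: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Shrink the fold-change increment by factor k, reciprocal space for F < 1."""
    up = 1.0 + (F - 1.0) * k
    down = 1.0 / (1.0 + (1.0 / F - 1.0) * k)
    return np.where(F >= 1.0, up, down)


def adjust_fold_change(
    F: float,
    flagA_count: int,
    all_absent: bool,
    p: float,
    ctx: AdjustmentContext,
) -> float:
    """Apply the single most severe reliability rule to one fold change."""
    if not F > 0:
        raise ValidationError(f"fold change must be positive, got {F}")
    if all_absent:
        return 1.0
    lo, hi = ctx.p_half_band
    p_defined = p is not None and not np.isnan(p)
    if p_defined and p > ctx.p_quarter_threshold:
        k = ctx.shrink_quarter
    elif flagA_count >= ctx.flagA_threshold or (p_defined and lo <= p <= hi):
        k = ctx.shrink_half
    else:
        return float(F)
    return float(_shrink(np.asarray(F, dtype=float), k))


def adjust_matrix(
    fc: FoldChangeMatrix,
    ctx: AdjustmentContext,
    cross_source_all_absent: pd.DataFrame | None = None,
) -> FoldChangeMatrix:
    """Vectorized reliability adjustment of a whole fold-change matrix.

    The set-to-1 rule fires only where the calls are all Absent in *both*
    data sources; pass the other source's all-Absent frame (aligned or
    alignable on shared substances/genes) to enable it. With no cross-source
    frame the matrix's own all-Absent indicator is used alone.
    """
    F = fc.values.to_numpy(dtype=float)
    p = (
        fc.pvalues.to_numpy(dtype=float)
        if fc.pvalues is not None
        else np.full(F.shape, np.nan)
    )
    flags = (
        fc.flag_summary.to_numpy()
        if fc.flag_summary is not None
        else np.zeros(F.shape, dtype=int)
    )
    own_absent = (
        fc.all_absent.to_numpy(dtype=bool)
        if fc.all_absent is not None
        else np.zeros(F.shape, dtype=bool)
    )
    if cross_source_all_absent is not None:
        other = (
            cross_source_all_absent.reindex(
                index=fc.substances, columns=fc.genes
            )
            .fillna(False)
            .to_numpy(dtype=bool)
        )
        absent = own_absent & other
    else:
        absent = own_absent

    lo, hi = ctx.p_half_band
    with np.errstate(invalid="ignore"):
        quarter = p > ctx.p_quarter_threshold  # NaN compares False
        half = (flags >= ctx.flagA_threshold) | ((p >= lo) & (p <= hi))
    k = np.ones_like(F)
    k = np.where(half, ctx.shrink_half, k)
    k = np.where(quarter, ctx.shrink_quarter, k)  # quarter outranks half
    adjusted = _shrink(F, k)
    adjusted = np.where(absent, 1.0, adjusted)  # strongest rule wins
    return FoldChangeMatrix(
        values=pd.DataFrame(adjusted, index=fc.substances, columns=fc.genes),
        source=fc.source,
        pvalues=fc.pvalues,
        flag_summary=fc.flag_summary,
        all_absent=fc.all_absent,
    )


def assign_weight(F_adjusted: float, rule: WeightRule = WeightRule()) -> float:
    if not F_adjusted > 0:
        raise ValidationError(f"fold change must be positive, got {F_adjusted}")
    magnitude = max(F_adjusted, 1.0 / F_adjusted)
    for threshold, weight in rule.thresholds:
        if magnitude >= threshold:
            return weight
    return rule.default


def weight_matrix(fc: FoldChangeMatrix, rule: WeightRule = WeightRule()) -> pd.DataFrame:
    F = fc.values.to_numpy(dtype=float)
    magnitude = np.maximum(F, 1.0 / F)
    w = np.full(F.shape, rule.default)
    for threshold, weight in sorted(rule.thresholds):  # ascending: larger overwrites
        w = np.where(magnitude >= threshold, weight, w)
    return pd.DataFrame(w, index=fc.substances, columns=fc.genes)


def filter_genes(
    in_vivo: FoldChangeMatrix,
    min_substances: int = 10,
    fold_threshold: float = 1.5,
) -> list[str]:
    """Retain genes differentially expressed (>= fold_threshold either way)
    in at least ``min_substances`` substances; genes with rarer responses give
    the per-gene models too little signal to learn from."""
    F = in_vivo.values.to_numpy(dtype=float)
    magnitude = np.maximum(F, 1.0 / F)
    counts = (magnitude >= fold_threshold).sum(axis=0)
    return [g for g, c in zip(in_vivo.genes, counts) if c >= min_substances]


# ---------------------------------------------------------------------------
# Descriptor curation
# ---------------------------------------------------------------------------


def curate_descriptors(
    table: DescriptorTable, corr_threshold: float = 0.95
) -> DescriptorTable:
    """Drop descriptors with missing values, constants, then high pair correlation.

    Correlation pruning is a greedy left-to-right scan: a column is dropped if
    its |Pearson r| with any already-retained column exceeds the threshold, so
    the earlier column of a correlated pair survives. Idempotent.
    """
    df = table.values
    if len(df) < 3:
        raise ValidationError("descriptor curation needs at least 3 substances")
    log = list(table.curation_log)

    with_missing = [c for c in df.columns if df[c].isna().any()]
    log += [{"descriptor": c, "reason": "missing"} for c in with_missing]
    df = df.drop(columns=with_missing)

    constant = [c for c in df.columns if df[c].nunique() <= 1]
    log += [{"descriptor": c, "reason": "constant"} for c in constant]
    df = df.drop(columns=constant)

    corr = df.corr().abs().to_numpy()
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(df.shape[1]):
        if keep and (corr[j, keep] > corr_threshold).any():
            dropped.append(df.columns[j])
        else:
            keep.append(j)
    log += [{"descriptor": c, "reason": "pair_correlation"} for c in dropped]
    return DescriptorTable(
        values=df.iloc[:, keep].copy(),
        curation_log=log,
        transform_log=list(table.transform_log),
    )


# ---------------------------------------------------------------------------
# Normalizing-transform selection (bestNormalize-style)
# ---------------------------------------------------------------------------

_EPS = np.finfo(float).eps


def pearson_normality_statistic(x: np.ndarray) -> float:
    """Pearson chi-squared goodness of fit of standardized values vs N(0, 1).

    Uses ceil(2 * n^(2/5)) classes with equal probability under the standard
    normal; lower is closer to normal. This is the deterministic ranking
    statistic used to pick the per-descriptor normalizing transform.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.inf
    z = (x - x.mean()) / sd
    k = int(np.ceil(2 * n ** 0.4))
    edges = stats.norm.ppf(np.linspace(0, 1, k + 1))
    observed, _ = np.histogram(z, bins=edges)
    expected = n / k
    return float(((observed - expected) ** 2 / expected).sum())


def _fit_transform_candidates(x: np.ndarray) -> list[dict]:
    """All applicable normalizing transforms for one column, with fitted params."""
    candidates: list[dict] = []
    lmbda = stats.yeojohnson_normmax(x)
    candidates.append(
        {"transform": "yeo_johnson", "params": {"lmbda": float(lmbda)},
         "values": stats.yeojohnson(x, lmbda=lmbda)}
    )
    if (x > 0).all():
        lmbda = stats.boxcox_normmax(x, method="mle")
        candidates.append(
            {"transform": "box_cox", "params": {"lmbda": float(lmbda)},
             "values": stats.boxcox(x, lmbda=lmbda)}
        )
        candidates.append({"transform": "log10", "params": {}, "values": np.log10(x)})
    if (x >= 0).all():
        candidates.append({"transform": "sqrt", "params": {}, "values": np.sqrt(x)})
    if ((x >= 0) & (x <= 1)).all():
        candidates.append(
            {"transform": "arcsine", "params": {}, "values": np.arcsin(np.sqrt(x))}
        )
    candidates.append({"transform": "identity", "params": {}, "values": x.copy()})
    return candidates


def _apply_transform(x: np.ndarray, name: str, params: dict) -> np.ndarray:
    if name == "yeo_johnson":
        return stats.yeojohnson(x, lmbda=params["lmbda"])
    if name == "box_cox":
        return stats.boxcox(x, lmbda=params["lmbda"])
    if name == "log10":
        return np.log10(x)
    if name == "sqrt":
        return np.sqrt(x)
    if name == "arcsine":
        return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))
    if name == "identity":
        return np.asarray(x, dtype=float)
    raise ValidationError(f"unknown transform {name!r}")


def normalize_descriptors(table: DescriptorTable) -> DescriptorTable:
    """Pick the best normalizing transform per column, then center/scale.

    Candidates: Yeo-Johnson (always), Box-Cox and log10 (strictly positive
    columns), square root (nonnegative), arcsine of the square root (values in
    [0, 1]) and identity. The transform minimizing the Pearson chi-squared
    normality statistic wins; ties go to the earlier candidate in that order.
    The fitted pipeline (transform + centering constants) is recorded in
    ``transform_log`` and replayable on new substances via
    :func:`apply_descriptor_transforms`.
    """
    df = table.values
    if df.isna().any().any():
        raise ValidationError("normalize_descriptors requires a curated table")
    out = {}
    log: list[dict] = []
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        candidates = _fit_transform_candidates(x)
        stats_ = [pearson_normality_statistic(c["values"]) for c in candidates]
        best = candidates[int(np.argmin(stats_))]
        values = best["values"]
        mean, sd = float(values.mean()), float(values.std(ddof=1))
        if sd == 0:
            raise ValidationError(f"descriptor {col!r} constant after transform")
        out[col] = (values - mean) / sd
        log.append(
            {
                "descriptor": col,
                "transform": best["transform"],
                "params": best["params"],
                "center": mean,
                "scale": sd,
            }
        )
    return DescriptorTable(
        values=pd.DataFrame(out, index=df.index),
        curation_log=list(table.curation_log),
        transform_log=log,
    )


def apply_descriptor_transforms(
    raw: pd.DataFrame, transform_log: list[dict]
) -> pd.DataFrame:
    """Replay a fitted normalization pipeline on new substances.

    ``raw`` must contain every descriptor named in the log; extra columns are
    ignored (they were curated away during training).
    """
    missing = [rec["descriptor"] for rec in transform_log if rec["descriptor"] not in raw.columns]
    if missing:
        raise ValidationError(f"descriptors missing from input: {missing[:10]}")
    out = {}
    for rec in transform_log:
        x = raw[rec["descriptor"]].to_numpy(dtype=float)
        values = _apply_transform(x, rec["transform"], rec["params"])
        out[rec["descriptor"]] = (values - rec["center"]) / rec["scale"]
    return pd.DataFrame(out, index=raw.index)
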