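"""PCA-based read-across analytics and quantitative IVIVE evaluation.

Score/loading analysis of expression matrices, quadrant gene rankings by
loading length, principal-component-related gene sets and their Venn
partition across data sources, normalized per-gene RMSE comparison of
predicted vs in vitro profiles (Welch's t-test), projection of external
substances into the training PCA space, nearest-neighbor retrieval in the
(PC1, PC2) plane, and a minimal 2-component PLS-DA on toxicity labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import train_test_split

from .data_model import (
    FoldChangeMatrix,
    ModelBank,
    PCAResult,
    ToxicityLabels,
    ValidationError,
)

__all__ = [
    "fit_pca",
    "project",
    "loading_length",
    "quadrant_top_genes",
    "QuadrantGeneRanking",
    "pc_related_gene_set",
    "venn_partition",
    "qivive_rmse",
    "RmseComparison",
    "biosimilar_neighbors",
    "plsda",
    "PlsdaResult",
    "class_ellipses",
]

_SEED_MOD = 2**31 - 1


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def fit_pca(
    matrix: pd.DataFrame, scale: bool = False, n_components: int | None = None
) -> PCAResult:
    """Column-centered SVD principal components (prcomp-style).

    Expression matrices are centered but not scaled; descriptor matrices
    arrive pre-normalized so centering alone suffices there too. Sign
    convention: each loading column's largest-magnitude element is positive,
    making quadrant assignments reproducible across linear-algebra backends.
    """
    if len(matrix) < 3:
        raise ValidationError("PCA needs at least 3 substances")
    X = matrix.to_numpy(dtype=float)
    center = X.mean(axis=0)
    Xc = X - center
    scale_s = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValidationError("cannot scale constant columns")
        Xc = Xc / sd
        scale_s = pd.Series(sd, index=matrix.columns)
    if not Xc.any():
        raise ValidationError("constant matrix has no principal components")

    U, D, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = min(len(matrix) - 1, matrix.shape[1])
    if n_components is not None:
        rank = min(rank, n_components)
    U, D, Vt = U[:, :rank], D[:rank], Vt[:rank]

    # deterministic signs: largest |loading| per component made positive
    flip = np.sign(Vt[np.arange(rank), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T

    comp_names = [f"PC{i + 1}" for i in range(rank)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=comp_names),
        explained_variance=D**2 / (len(matrix) - 1),
        center=pd.Series(center, index=matrix.columns),
        scale=scale_s,
    )


def project(pca: PCAResult, new_matrix: pd.DataFrame) -> pd.DataFrame:
    """Scores of new substances in the training PCA space.

    The training geometry is left untouched: new rows are centered with the
    training means (and training scales, if any) and rotated by the training
    loadings.
    """
    missing = [f for f in pca.loadings.index if f not in new_matrix.columns]
    if missing:
        raise ValidationError(f"features missing from new matrix: {missing[:10]}")
    X = new_matrix[pca.loadings.index].to_numpy(dtype=float)
    Xc = X - pca.center.to_numpy(dtype=float)
    if pca.scale is not None:
        Xc = Xc / pca.scale.to_numpy(dtype=float)
    return pd.DataFrame(
        Xc @ pca.loadings.to_numpy(dtype=float),
        index=new_matrix.index,
        columns=pca.loadings.columns,
    )


def loading_length(loadings: np.ndarray | pd.Series) -> float:
    """Euclidean length of a feature's (PC1, PC2) loadings (Pythagorean)."""
    v = np.asarray(loadings, dtype=float)[:2]
    return float(np.sqrt((v**2).sum()))


_QUADRANT_SIGNS = {1: (1, 1), 2: (-1, 1), 3: (-1, -1), 4: (1, -1)}


@dataclass
class QuadrantGeneRanking:
    """Genes of one (PC1, PC2) loading quadrant ranked by loading length."""

    quadrant: int
    entries: pd.DataFrame  # columns: gene, loading_PC1, loading_PC2, loading_length


def quadrant_top_genes(
    pca: PCAResult, quadrant: int, k: int = 30
) -> QuadrantGeneRanking:
    """Top-k genes of a loading-plane quadrant, by descending loading length.

    Quadrants use strict sign matching (a zero loading belongs to no
    quadrant); ties in length break by gene id for determinism.
    """
    if quadrant not in _QUADRANT_SIGNS:
        raise ValidationError(f"quadrant must be 1-4, got {quadrant}")
    s1, s2 = _QUADRANT_SIGNS[quadrant]
    l1 = pca.loadings["PC1"]
    l2 = pca.loadings["PC2"]
    mask = (np.sign(l1) == s1) & (np.sign(l2) == s2)
    df = pd.DataFrame(
        {
            "gene": pca.loadings.index[mask],
            "loading_PC1": l1[mask].to_numpy(),
            "loading_PC2": l2[mask].to_numpy(),
        }
    )
    df["loading_length"] = np.hypot(df["loading_PC1"], df["loading_PC2"])
    df = df.sort_values(
        ["loading_length", "gene"], ascending=[False, True], kind="mergesort"
    ).head(k)
    return QuadrantGeneRanking(quadrant=quadrant, entries=df.reset_index(drop=True))


def pc_related_gene_set(pca: PCAResult, k: int = 30) -> set[str]:
    """Union of top-k and bottom-k genes by signed loading on PC1 and on PC2."""
    out: set[str] = set()
    for pc in ("PC1", "PC2"):
        ranked = pca.loadings[pc].sort_values(kind="mergesort")
        out.update(ranked.index[:k])
        out.update(ranked.index[-k:])
    return out


def venn_partition(sets: dict[str, set[str]]) -> dict[frozenset[str], int]:
    """Exclusive-region counts of a Venn diagram over named sets.

    Keys are frozensets of set names (every nonempty combination); values are
    the number of elements belonging to exactly those sets. Counts sum to the
    size of the union.
    """
    if len(sets) < 2:
        raise ValidationError("venn_partition needs at least 2 sets")
    names = list(sets)
    regions = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    for element in set().union(*sets.values()):
        membership = frozenset(n for n in names if element in sets[n])
        regions[membership] += 1
    return regions


# ---------------------------------------------------------------------------
# Quantitative IVIVE evaluation
# ---------------------------------------------------------------------------


@dataclass
class RmseComparison:
    """Per-gene RMSE of predicted and in vitro profiles against in vivo data,
    on source-wise z-normalized log2 fold changes, with a Welch t-test
    comparing the two RMSE distributions."""

    per_gene_rmse_raid: pd.Series
    per_gene_rmse_invitro: pd.Series
    gene_scope: str
    welch_t: float
    welch_p: float

    @property
    def mean_rmse_raid(self) -> float:
        return float(self.per_gene_rmse_raid.mean())

    @property
    def mean_rmse_invitro(self) -> float:
        return float(self.per_gene_rmse_invitro.mean())


def _znorm(frame: pd.DataFrame) -> pd.DataFrame:
    """Z-normalize over all entries pooled (source-wise distribution match)."""
    arr = frame.to_numpy(dtype=float)
    sd = arr.std()
    if sd == 0:
        raise ValidationError("cannot normalize a constant matrix")
    return (frame - arr.mean()) / sd


def qivive_rmse(
    pred: FoldChangeMatrix,
    invivo: FoldChangeMatrix,
    invitro: FoldChangeMatrix,
    scope: str = "all",
    bank: ModelBank | None = None,
) -> RmseComparison:
    """Compare predicted and in vitro profiles against in vivo ground truth.

    Each source's log2 matrix is z-normalized over all its entries to remove
    distributional differences between sources, then RMSE is computed per gene
    across substances. ``scope="invitro_important"`` restricts to genes whose
    model places nonzero coefficient mass on the in vitro block (requires the
    trained bank).
    """
    genes = [g for g in invivo.genes if g in pred.genes and g in invitro.genes]
    subs = [s for s in invivo.substances if s in pred.substances and s in invitro.substances]
    if scope == "invitro_important":
        if bank is None:
            raise ValidationError("scope 'invitro_important' requires a trained bank")
        genes = [
            g for g in genes
            if g in bank.models and bank.models[g].invitro_importance > 0
        ]
    elif scope != "all":
        raise ValidationError(f"unknown scope {scope!r}")
    if not genes:
        raise ValidationError(f"no genes in scope {scope!r}")

    z = {
        name: _znorm(m.log2_values.loc[subs, genes])
        for name, m in (("pred", pred), ("invivo", invivo), ("invitro", invitro))
    }
    rmse_raid = np.sqrt(((z["pred"] - z["invivo"]) ** 2).mean(axis=0))
    rmse_invitro = np.sqrt(((z["invitro"] - z["invivo"]) ** 2).mean(axis=0))
    if rmse_raid.equals(rmse_invitro):
        t, p = 0.0, 1.0  # identical samples: no difference by construction
    else:
        t, p = stats.ttest_ind(rmse_raid, rmse_invitro, equal_var=False)
    return RmseComparison(
        per_gene_rmse_raid=rmse_raid,
        per_gene_rmse_invitro=rmse_invitro,
        gene_scope=scope,
        welch_t=float(t),
        welch_p=float(p),
    )


# ---------------------------------------------------------------------------
# Neighbor retrieval
# ---------------------------------------------------------------------------


def biosimilar_neighbors(
    scores: pd.DataFrame, query: str, k: int = 5
) -> pd.DataFrame:
    """Nearest substances to ``query`` in the (PC1, PC2) score plane.

    ``scores`` may mix training scores and projected external substances.
    Euclidean distance, ascending; ties break by substance id; the query is
    excluded from its own list.
    """
    if query not in scores.index:
        raise ValidationError(f"unknown query substance {query!r}")
    plane = scores[["PC1", "PC2"]]
    q = plane.loc[query].to_numpy(dtype=float)
    others = plane.drop(index=query)
    dist = np.sqrt(((others.to_numpy(dtype=float) - q) ** 2).sum(axis=1))
    out = pd.DataFrame({"substance": others.index, "distance": dist})
    out = out.sort_values(
        ["distance", "substance"], kind="mergesort"
    ).head(k)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PlsdaResult:
    scores: pd.DataFrame  # substances x components (training + test)
    x_weights: pd.DataFrame
    holdout_accuracy: float
    test_substances: list[str]


def plsda(
    matrix: pd.DataFrame,
    labels: ToxicityLabels,
    n_components: int = 2,
    split_seed: int = 0,
) -> PlsdaResult:
    """Minimal NIPALS PLS discriminant analysis on a 0/1 toxicity response.

    Stratified 70/30 split from ``split_seed``; a substance is called toxic
    when its predicted response exceeds 0.5; accuracy is reported on the
    held-out 30%.
    """
    subs = list(matrix.index)
    y = labels.binary(subs)
    if len(np.unique(y)) < 2:
        raise ValidationError("PLS-DA needs both toxicity classes present")
    train_idx, test_idx = train_test_split(
        np.arange(len(subs)),
        test_size=0.3,
        stratify=y,
        random_state=split_seed % _SEED_MOD,
    )
    X = matrix.to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X[train_idx], y[train_idx].astype(float))
    pred = (pls.predict(X[test_idx]).ravel() > 0.5).astype(int)
    accuracy = float((pred == y[test_idx]).mean())
    comp_names = [f"PLS{i + 1}" for i in range(n_components)]
    return PlsdaResult(
        scores=pd.DataFrame(
            pls.transform(X), index=subs, columns=comp_names
        ),
        x_weights=pd.DataFrame(
            pls.x_weights_, index=matrix.columns, columns=comp_names
        ),
        holdout_accuracy=accuracy,
        test_substances=[subs[i] for i in test_idx],
    )


def class_ellipses(
    scores: pd.DataFrame, labels: ToxicityLabels, level: float = 0.95
) -> dict[str, dict]:
    """Per-class covariance-ellipse parameters in the (PC1, PC2) plane.

    Returns, per class, the centroid, semi-axis lengths (sqrt of scaled
    eigenvalues) and orientation angle in radians — the numeric content of the
    probability ellipses usually drawn on score plots.
    """
    chi2_q = stats.chi2.ppf(level, df=2)
    out: dict[str, dict] = {}
    for cls in ToxicityLabels.LABELS:
        members = [s for s in scores.index if labels.labels.get(s) == cls]
        if len(members) < 3:
            continue
        pts = scores.loc[members, ["PC1", "PC2"]].to_numpy(dtype=float)
        mean = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        out[cls] = {
            "center": mean.tolist(),
            "semi_axes": np.sqrt(np.maximum(evals, 0) * chi2_q).tolist(),
            "angle": float(np.arctan2(evecs[1, -1], evecs[0, -1])),
            "n": len(members),
        }
    return out
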