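"""Training and application of the per-gene weighted elastic-net model bank.

Each retained gene gets one linear model predicting its in vivo log2 fold
change from two feature blocks: curated/normalized chemical descriptors and
the in vitro log2 fold changes of the retained genes. The fitted objective,
with per-substance weights w_i, is

    (1 / (2 * sum(w))) * sum_i w_i * (y_i - b0 - x_i . b)^2
        + lambda * (alpha * ||b||_1 + (1 - alpha) / 2 * ||b||_2^2)

minimized over an (alpha, lambda) grid by 5-fold cross-validation with folds
drawn once per gene and shared across the grid. Features are standardized
internally; coefficients are stored on the standardized scale together with
the means/sds needed to apply the model to raw inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

from .data_model import (
    INVITRO_FEATURE_PREFIX,
    DescriptorTable,
    FoldChangeMatrix,
    GeneModel,
    ModelBank,
    ValidationError,
)
from .preprocess import WeightRule, apply_descriptor_transforms, weight_matrix

__all__ = [
    "TrainingDesign",
    "BankConfig",
    "fit_gene_model",
    "train_bank",
    "predict",
    "invitro_importance",
    "top_importance_genes",
]

_SEED_MOD = 2**31 - 1


@dataclass
class TrainingDesign:
    """Everything needed to fit one gene's model.

    ``X`` holds raw (unstandardized) feature columns: the descriptor block plus
    the in vitro block (columns named ``invitro:<gene>``); row order matches
    ``y`` and ``sample_weights``.
    """

    gene_id: str
    X: pd.DataFrame
    y: np.ndarray
    sample_weights: np.ndarray
    invitro_features: tuple[str, ...] = ()
    cv_folds: int = 5
    alpha_grid: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 11), 2))
    lambda_path_length: int = 100
    lambda_min_ratio: float = 1e-4
    selection_rule: str = "1se"
    #: explicit penalty grid; overrides the automatic lambda path when set
    lambda_grid: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_rule not in ("1se", "min"):
            raise ValidationError(
                f"selection_rule must be '1se' or 'min', got {self.selection_rule!r}"
            )
        n = len(self.X)
        if len(self.y) != n or len(self.sample_weights) != n:
            raise ValidationError("X, y and sample_weights must share row order/length")
        if n < self.cv_folds:
            raise ValidationError(
                f"need at least {self.cv_folds} substances, got {n}"
            )
        if np.isnan(self.X.to_numpy(dtype=float)).any() or np.isnan(self.y).any():
            raise ValidationError("missing values in training design")


@dataclass
class BankConfig:
    """Bank-level training configuration.

    ``invitro_feature_mode``: "all" feeds every retained gene's in vitro signal
    to every model (the penalty does the selection); "same_gene" restricts each
    model to its own gene's in vitro signal.
    """

    cv_folds: int = 5
    alpha_grid: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 11), 2))
    lambda_path_length: int = 100
    lambda_min_ratio: float = 1e-4
    selection_rule: str = "1se"
    seed: int = 0
    invitro_feature_mode: str = "all"
    weight_rule: WeightRule = field(default_factory=WeightRule)


def _weighted_mean(v: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * v) / np.sum(w))


def _lambda_max(Z: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float) -> float:
    """Smallest penalty zeroing every coefficient (glmnet convention).

    For alpha -> 0 the elastic net never fully zeroes out, so the mixing is
    floored at 0.001 purely to anchor the path.
    """
    wn = w / w.sum()
    r = y - np.sum(wn * y)
    grad = np.abs(Z.T @ (wn * r))
    lam = grad.max() / max(alpha, 1e-3)
    if not np.isfinite(lam) or lam <= 0:
        lam = 1e-3
    return float(lam)


def _ridge_path(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, lambdas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form weighted ridge solutions for a whole penalty path via SVD.

    Minimizes sum w r^2 + lam * sum(w) * ||b||^2 after weighted centering,
    which is the alpha = 0 elastic-net objective up to the constant 2*sum(w).
    Returns (coefs: len(lambdas) x p, intercepts).
    """
    sw = w.sum()
    xbar = (w @ Z) / sw
    ybar = _weighted_mean(y, w)
    s = np.sqrt(w)
    A = s[:, None] * (Z - xbar)
    b = s * (y - ybar)
    U, D, Vt = np.linalg.svd(A, full_matrices=False)
    Utb = U.T @ b
    coefs = np.empty((len(lambdas), Z.shape[1]))
    for i, lam in enumerate(lambdas):
        shrink = D / (D**2 + lam * sw)
        coefs[i] = Vt.T @ (shrink * Utb)
    intercepts = ybar - coefs @ xbar
    return coefs, intercepts


def _enet_path_weighted(
    Z: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-descent solutions along a descending lambda path.

    Sample weights are folded into the data: after weighted-mean centering,
    rows are rescaled by sqrt(w * n / sum(w)), under which the unweighted
    elastic-net objective (1/(2n)) ||y - Zb||^2 + penalty equals the weighted
    objective (1/(2 sum w)) sum w r^2 + penalty. One Cython path call per fold
    keeps the grid search cheap.
    """
    n = len(y)
    sw = w.sum()
    xbar = (w @ Z) / sw
    ybar = _weighted_mean(y, w)
    s = np.sqrt(w * n / sw)
    Zw = s[:, None] * (Z - xbar)
    yw = s * (y - ybar)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            Zw, yw, l1_ratio=alpha, alphas=lambdas, max_iter=5000, tol=1e-6
        )
    coefs = coefs.T  # n_lambda x p
    intercepts = ybar - coefs @ xbar
    return coefs, intercepts


def _solve_path(Z, y, w, alpha, lambdas):
    if alpha == 0:
        return _ridge_path(Z, y, w, lambdas)
    return _enet_path_weighted(Z, y, w, alpha, lambdas)


def fit_gene_model(design: TrainingDesign) -> GeneModel:
    """Fit one gene's weighted elastic net, selecting (alpha, lambda) by CV.

    Folds are substance-level, drawn once from the design seed and shared
    across the whole grid. The mixing alpha is chosen at the global weighted
    CV-MSE minimum; within that alpha the default ``"1se"`` rule then takes
    the largest lambda whose CV-MSE lies within one standard error of the
    minimum (the glmnet ``lambda.1se`` convention), trading a negligible
    amount of CV error for a markedly sparser, better-identified support.
    ``selection_rule="min"`` keeps the exact CV minimizer instead. A
    zero-variance target short-circuits to an intercept-only model flagged
    ``degenerate``.
    """
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(design.y, dtype=float)
    w = np.asarray(design.sample_weights, dtype=float)
    features = list(design.X.columns)

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    sds_safe = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds_safe

    def _model(coef, intercept, alpha, lam, cv_mse, degenerate=False):
        return GeneModel(
            gene_id=design.gene_id,
            intercept=float(intercept),
            coef=pd.Series(coef, index=features, dtype=float),
            alpha=float(alpha),
            lambda_=float(lam),
            cv_mse=float(cv_mse),
            feature_means=pd.Series(means, index=features),
            feature_sds=pd.Series(sds_safe, index=features),
            invitro_features=tuple(design.invitro_features),
            degenerate=degenerate,
        )

    if np.allclose(y, y[0]):
        return _model(
            np.zeros(len(features)), _weighted_mean(y, w),
            alpha=0.0, lam=np.inf, cv_mse=0.0, degenerate=True,
        )

    folds = list(
        KFold(
            n_splits=design.cv_folds, shuffle=True,
            random_state=design.seed % _SEED_MOD,
        ).split(Z)
    )

    best = None  # (cv_mse, se_at_min, alpha, lambda_index)
    curves: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for alpha in design.alpha_grid:
        if design.lambda_grid is not None:
            lambdas = np.sort(np.asarray(design.lambda_grid, dtype=float))[::-1]
        else:
            lam_max = _lambda_max(Z, y, w, alpha)
            lambdas = np.geomspace(
                lam_max, lam_max * design.lambda_min_ratio, design.lambda_path_length
            )
        fold_mse = np.empty((design.cv_folds, len(lambdas)))
        for fi, (train_idx, val_idx) in enumerate(folds):
            coefs, intercepts = _solve_path(
                Z[train_idx], y[train_idx], w[train_idx], alpha, lambdas
            )
            pred = Z[val_idx] @ coefs.T + intercepts  # n_val x n_lambda
            resid2 = (y[val_idx, None] - pred) ** 2
            fold_mse[fi] = (w[val_idx] @ resid2) / w[val_idx].sum()
        cv_mse = fold_mse.mean(axis=0)
        cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(design.cv_folds)
        curves[alpha] = (lambdas, cv_mse, cv_se)
        i = int(cv_mse.argmin())  # descending lambda: argmin ties keep larger
        if best is None or cv_mse[i] < best[0]:
            best = (cv_mse[i], cv_se[i], alpha, i)

    mse_min, se_min, alpha, i_sel = best
    lambdas, cv_mse, _ = curves[alpha]
    if design.selection_rule == "1se":
        # largest lambda within one SE of the minimum, along the chosen alpha
        i_sel = int(np.flatnonzero(cv_mse <= mse_min + se_min).min())
    lam = float(lambdas[i_sel])
    coefs, intercepts = _solve_path(Z, y, w, alpha, np.array([lam]))
    return _model(coefs[0], intercepts[0], alpha, lam, float(cv_mse[i_sel]))


def _build_feature_frame(
    descriptors: pd.DataFrame, invitro_log2: pd.DataFrame
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    invitro_block = invitro_log2.add_prefix(INVITRO_FEATURE_PREFIX)
    X = pd.concat([descriptors, invitro_block], axis=1)
    return X, tuple(invitro_block.columns)


def train_bank(
    invivo: FoldChangeMatrix,
    invitro: FoldChangeMatrix,
    descriptors: DescriptorTable,
    retained_genes: list[str],
    config: BankConfig = BankConfig(),
    progress: bool = False,
) -> ModelBank:
    """Fit one model per retained gene; deterministic given ``config.seed``.

    ``invivo`` and ``invitro`` must be reliability-adjusted fold-change
    matrices; ``descriptors`` must already be curated and normalized (its
    curation/transform logs travel into the bank so the pipeline can be
    replayed on new substances at prediction time).
    """
    subs = invivo.substances
    if invitro.substances != subs or descriptors.substances != subs:
        raise ValidationError("substance order mismatch across inputs")
    unknown = [g for g in retained_genes if g not in invivo.genes or g not in invitro.genes]
    if unknown:
        raise ValidationError(f"retained genes absent from matrices: {unknown[:5]}")

    invitro_log2 = invitro.log2_values[retained_genes]
    invivo_log2 = invivo.log2_values[retained_genes]
    weights = weight_matrix(invivo, config.weight_rule)[retained_genes]
    medians = invitro_log2.median(axis=0)

    models: dict[str, GeneModel] = {}
    for gi, gene in enumerate(retained_genes):
        if config.invitro_feature_mode == "same_gene":
            block = invitro_log2[[gene]]
        elif config.invitro_feature_mode == "all":
            block = invitro_log2
        else:
            raise ValidationError(
                f"unknown invitro_feature_mode {config.invitro_feature_mode!r}"
            )
        X, invitro_features = _build_feature_frame(descriptors.values, block)
        design = TrainingDesign(
            gene_id=gene,
            X=X,
            y=invivo_log2[gene].to_numpy(dtype=float),
            sample_weights=weights[gene].to_numpy(dtype=float),
            invitro_features=invitro_features,
            cv_folds=config.cv_folds,
            alpha_grid=config.alpha_grid,
            lambda_path_length=config.lambda_path_length,
            lambda_min_ratio=config.lambda_min_ratio,
            selection_rule=config.selection_rule,
            seed=(config.seed + gi) % _SEED_MOD,
        )
        models[gene] = fit_gene_model(design)
        if progress:
            print(f"fitted {gi + 1}/{len(retained_genes)}: {gene}", flush=True)

    return ModelBank(
        models=models,
        training_gene_set=list(retained_genes),
        invitro_feature_medians=medians,
        descriptor_curation_log=list(descriptors.curation_log),
        descriptor_transform_log=list(descriptors.transform_log),
        random_seed=config.seed,
    )


def predict(
    bank: ModelBank,
    descriptors: DescriptorTable,
    invitro: FoldChangeMatrix | None = None,
) -> FoldChangeMatrix:
    """Predict in vivo fold changes for new substances.

    Raw descriptors are passed through the bank's stored curation/normalization
    pipeline. In vitro profiles are optional per substance and per gene; any
    missing in vitro value is imputed with the training median of that gene's
    in vitro log2 fold change before the models are applied.
    """
    desc_norm = apply_descriptor_transforms(
        descriptors.values, bank.descriptor_transform_log
    )
    subs = list(desc_norm.index)

    medians = bank.invitro_feature_medians
    if invitro is not None:
        invitro_log2 = invitro.log2_values.reindex(
            index=subs, columns=medians.index
        )
        invitro_log2 = invitro_log2.fillna(
            {g: medians[g] for g in medians.index}
        )
    else:
        invitro_log2 = pd.DataFrame(
            np.tile(medians.to_numpy(dtype=float), (len(subs), 1)),
            index=subs,
            columns=medians.index,
        )
    X, _ = _build_feature_frame(desc_norm, invitro_log2)

    log2_pred = pd.DataFrame(
        {g: bank.models[g].predict(X) for g in bank.training_gene_set},
        index=subs,
    )
    return FoldChangeMatrix.from_log2(log2_pred, source="predicted")


def invitro_importance(model: GeneModel) -> float:
    """Fraction of standardized coefficient magnitude on the in vitro block."""
    return model.invitro_importance


def top_importance_genes(
    bank: ModelBank, k: int = 20
) -> list[tuple[str, float]]:
    """Genes ranked by in vitro importance, descending; ties break by gene id."""
    if k > len(bank):
        warnings.warn(
            f"k={k} exceeds bank size {len(bank)}; returning all genes",
            stacklevel=2,
        )
        k = len(bank)
    ranked = sorted(
        ((g, bank.models[g].invitro_importance) for g in bank.training_gene_set),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]
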