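"""Typed containers and TSV readers/writers for the virtual-microarray pipeline.

Axes convention: every matrix is substances-as-rows, features-as-columns,
serialized as UTF-8 TSV with a leading ``substance_id`` column and "." as
the decimal separator. Fold changes live on the ratio scale (treated mean /
control mean) with a derived base-2 logarithmic view, because the modelling
target throughout is the log2 fold change.

Gene identifiers are opaque strings; Affymetrix probe IDs such as
``1398250_at`` are valid but nothing here assumes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SchemaVersionError",
    "GROUPS",
    "DETECTION_CALLS",
    "REPLICATES_PER_GROUP",
    "ReplicateExpressionTable",
    "FoldChangeMatrix",
    "DescriptorTable",
    "ToxicityLabels",
    "GeneModel",
    "ModelBank",
    "PCAResult",
    "read_replicate_table",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_descriptor_table",
    "read_toxicity_labels",
    "bundled_hepatotoxicity_labels",
    "write_model_bank",
    "read_model_bank",
    "INVITRO_FEATURE_PREFIX",
    "MODEL_BANK_SCHEMA_VERSION",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


class SchemaVersionError(ValueError):
    """Raised when a serialized model bank declares an unknown schema."""


GROUPS = ("treated", "control")
DETECTION_CALLS = ("A", "M", "P")  # MAS5 Absent / Marginal / Present

#: Replicate design of the source study: n = 3 in vivo, n = 2 in vitro.
REPLICATES_PER_GROUP = {"in_vivo": 3, "in_vitro": 2}

EXPRESSION_SOURCES = ("in_vivo", "in_vitro")
MATRIX_SOURCES = ("in_vivo", "in_vitro", "predicted")

#: Column-name prefix marking the in vitro expression block in model features.
INVITRO_FEATURE_PREFIX = "invitro:"

MODEL_BANK_SCHEMA_VERSION = "1"

_REPLICATE_COLUMNS = ["substance", "gene", "group", "replicate", "signal", "call"]


def _ordered_unique(values: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


# ---------------------------------------------------------------------------
# Replicate-level expression
# ---------------------------------------------------------------------------


@dataclass
class ReplicateExpressionTable:
    """Per-substance, per-gene replicate signals with MAS5 detection calls.

    ``records`` holds one row per (substance, gene, group, replicate) with a
    strictly positive MAS5-scale ``signal`` and a ``call`` in ``A``/``M``/``P``.
    """

    records: pd.DataFrame
    source: str
    replicates_per_group: int

    def __post_init__(self) -> None:
        if self.source not in EXPRESSION_SOURCES:
            raise ValidationError(f"unknown expression source {self.source!r}")
        self.validate()

    def validate(self) -> None:
        df = self.records
        missing = [c for c in _REPLICATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"replicate table missing columns: {missing}")
        bad_group = df.loc[~df["group"].isin(GROUPS)]
        if len(bad_group):
            raise ValidationError(
                f"unknown group {bad_group['group'].iloc[0]!r} at row "
                f"{bad_group.index[0]}"
            )
        bad_call = df.loc[~df["call"].isin(DETECTION_CALLS)]
        if len(bad_call):
            raise ValidationError(
                f"unknown detection call {bad_call['call'].iloc[0]!r} at row "
                f"{bad_call.index[0]}"
            )
        if not np.issubdtype(df["signal"].dtype, np.number):
            raise ValidationError("signal column is not numeric")
        nonpos = df.loc[~(df["signal"] > 0)]
        if len(nonpos):
            raise ValidationError(
                f"non-positive signal {nonpos['signal'].iloc[0]!r} at row "
                f"{nonpos.index[0]} "
                f"(substance={nonpos['substance'].iloc[0]}, gene={nonpos['gene'].iloc[0]})"
            )
        counts = df.groupby(["substance", "gene", "group"], sort=False).size()
        wrong = counts[counts != self.replicates_per_group]
        if len(wrong):
            key = wrong.index[0]
            raise ValidationError(
                f"expected {self.replicates_per_group} replicates for "
                f"(substance={key[0]}, gene={key[1]}, group={key[2]}), found {wrong.iloc[0]}"
            )

    @property
    def substances(self) -> list[str]:
        return _ordered_unique(self.records["substance"])

    @property
    def genes(self) -> list[str]:
        return _ordered_unique(self.records["gene"])

    def signal_array(self, group: str) -> np.ndarray:
        """Signals as a (substances, genes, replicates) array in table order."""
        return self._cube(group, "signal").astype(float)

    def call_array(self, group: str) -> np.ndarray:
        return self._cube(group, "call")

    def _cube(self, group: str, value: str) -> np.ndarray:
        df = self.records[self.records["group"] == group]
        subs, genes = self.substances, self.genes
        piv = df.pivot_table(
            index="substance",
            columns=["gene", "replicate"],
            values=value,
            aggfunc="first",
            sort=False,
        )
        cols = pd.MultiIndex.from_product(
            [genes, sorted(df["replicate"].unique())]
        )
        piv = piv.reindex(index=subs, columns=cols)
        if piv.isna().any().any():
            raise ValidationError("incomplete replicate design")
        return piv.to_numpy().reshape(len(subs), len(genes), self.replicates_per_group)

    def all_absent(self) -> pd.DataFrame:
        """Boolean substances x genes frame: every call (both groups) is Absent."""
        df = self.records
        absent = (
            df.assign(is_a=df["call"].eq("A"))
            .groupby(["substance", "gene"], sort=False)["is_a"]
            .all()
            .unstack()
        )
        return absent.reindex(index=self.substances, columns=self.genes)


def read_replicate_table(path: str | Path, source: str) -> ReplicateExpressionTable:
    """Read a replicate-level expression TSV and validate its design.

    Expected header: substance, gene, group, replicate, signal, call.
    Any malformed row raises :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    for col, kind in (("replicate", int), ("signal", float)):
        try:
            df[col] = df[col].astype(kind)
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] + 2 if len(bad) else "?"
            raise ValidationError(
                f"{path}: non-numeric {col} value at file line {row}"
            ) from exc
    if source not in REPLICATES_PER_GROUP:
        raise ValidationError(f"unknown source {source!r}")
    return ReplicateExpressionTable(
        records=df.reset_index(drop=True),
        source=source,
        replicates_per_group=REPLICATES_PER_GROUP[source],
    )


# ---------------------------------------------------------------------------
# Fold-change matrices
# ---------------------------------------------------------------------------


@dataclass
class FoldChangeMatrix:
    """Substances x genes fold changes on the ratio scale.

    ``values`` are strictly positive ratios (treated/control); ``log2_values``
    is the derived base-2 logarithmic view used for modelling. Optional
    companions, aligned cell-by-cell: Welch p-values, treated-group Absent-call
    counts (``flag_summary``) and an all-calls-Absent indicator.
    """

    values: pd.DataFrame
    source: str
    pvalues: pd.DataFrame | None = None
    flag_summary: pd.DataFrame | None = None
    all_absent: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.source not in MATRIX_SOURCES:
            raise ValidationError(f"unknown matrix source {self.source!r}")
        if not (self.values.to_numpy(dtype=float) > 0).all():
            bad = self.values.stack()
            bad = bad[~(bad > 0)]
            raise ValidationError(
                f"non-positive fold change at (substance={bad.index[0][0]}, "
                f"gene={bad.index[0][1]})"
            )
        for name in ("pvalues", "flag_summary", "all_absent"):
            companion = getattr(self, name)
            if companion is not None and companion.shape != self.values.shape:
                raise ValidationError(f"{name} shape does not match values")

    @property
    def log2_values(self) -> pd.DataFrame:
        return np.log2(self.values)

    @property
    def substances(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_log2(cls, log2_values: pd.DataFrame, source: str, **kw) -> "FoldChangeMatrix":
        return cls(values=np.exp2(log2_values), source=source, **kw)

    def subset(self, substances: list[str]) -> "FoldChangeMatrix":
        """Row subset (e.g. a train/test split), carrying companions along."""
        pick = lambda df: None if df is None else df.loc[substances]
        return FoldChangeMatrix(
            values=self.values.loc[substances],
            source=self.source,
            pvalues=pick(self.pvalues),
            flag_summary=pick(self.flag_summary),
            all_absent=pick(self.all_absent),
        )

    def to_tsv(self, path: str | Path, scale: str = "ratio") -> None:
        frame = self.values if scale == "ratio" else self.log2_values
        write_matrix_tsv(frame, path)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str, scale: str = "ratio") -> "FoldChangeMatrix":
        frame = read_matrix_tsv(path)
        if scale == "log2":
            return cls.from_log2(frame, source=source)
        return cls(values=frame, source=source)


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="substance_id", float_format="%.17g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col="substance_id", float_precision="round_trip"
    )
    nonnum = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if nonnum:
        raise ValidationError(f"{path}: non-numeric cells in columns {nonnum}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValidationError(f"{path}: missing value in column {col!r}")
    return df


# ---------------------------------------------------------------------------
# Chemical descriptors
# ---------------------------------------------------------------------------


@dataclass
class DescriptorTable:
    """Substances x numeric chemical descriptors with curation provenance.

    ``curation_log`` records dropped columns as (descriptor, reason) with
    reason in {"missing", "constant", "pair_correlation"}; ``transform_log``
    records, per retained column, the chosen normalizing transform, its fitted
    parameters and the post-transform centering/scaling constants, so the
    fitted pipeline can be replayed on new substances.
    """

    values: pd.DataFrame
    curation_log: list[dict] = field(default_factory=list)
    transform_log: list[dict] = field(default_factory=list)

    @property
    def substances(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptors(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        write_matrix_tsv(self.values, path)

    def subset(self, substances: list[str]) -> "DescriptorTable":
        return DescriptorTable(
            values=self.values.loc[substances],
            curation_log=list(self.curation_log),
            transform_log=list(self.transform_log),
        )


def read_descriptor_table(path: str | Path, allow_missing: bool = True) -> DescriptorTable:
    """Read a raw descriptor TSV; missing cells are permitted (curation drops them)."""
    df = pd.read_csv(path, sep="\t", index_col="substance_id")
    for c in df.columns:
        if not np.issubdtype(df[c].dtype, np.number):
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = df[c].notna() & coerced.isna()
            if bad.any():
                raise ValidationError(
                    f"{path}: non-numeric cell in column {c!r}, substance "
                    f"{df.index[bad.argmax()]!r}"
                )
            df[c] = coerced
    if not allow_missing and df.isna().any().any():
        raise ValidationError(f"{path}: missing values not allowed here")
    return DescriptorTable(values=df)


# ---------------------------------------------------------------------------
# Toxicity labels
# ---------------------------------------------------------------------------


@dataclass
class ToxicityLabels:
    """Map substance -> {"toxic", "non_toxic"}."""

    labels: dict[str, str]

    LABELS = ("toxic", "non_toxic")

    def __post_init__(self) -> None:
        bad = {s: l for s, l in self.labels.items() if l not in self.LABELS}
        if bad:
            s, l = next(iter(bad.items()))
            raise ValidationError(f"unknown toxicity label {l!r} for substance {s!r}")

    def __getitem__(self, substance: str) -> str:
        return self.labels[substance]

    def __len__(self) -> int:
        return len(self.labels)

    def binary(self, substances: Iterable[str]) -> np.ndarray:
        """0/1 vector (toxic = 1) over the given substances."""
        return np.array([1 if self.labels[s] == "toxic" else 0 for s in substances])

    def validate_against(self, substances: Iterable[str]) -> None:
        known = set(substances)
        orphans = [s for s in self.labels if s not in known]
        if orphans:
            raise ValidationError(
                f"labeled substances absent from expression data: {orphans[:5]}"
            )


def read_toxicity_labels(path: str | Path) -> ToxicityLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "substance_id" not in df.columns or "label" not in df.columns:
        raise ValidationError(f"{path}: need columns substance_id and label")
    return ToxicityLabels(dict(zip(df["substance_id"], df["label"])))


def bundled_hepatotoxicity_labels() -> pd.DataFrame:
    """The bundled TG-GATEs hepatotoxicity class table (115 rat-study substances).

    Columns: substance_id, abbreviation, label. Classes follow the
    histopathology/serum-chemistry-based assignment used by the source study.
    """
    with resources.files("raidkit.data").joinpath(
        "tggates_hepatotoxicity_labels.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# Gene models and the model bank
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One fitted weighted elastic-net model predicting a gene's in vivo log2 FC.

    Coefficients are stored on the standardized-feature scale together with the
    per-feature training mean/sd, so predictions are
    ``intercept + sum_j beta_j * (x_j - mean_j) / sd_j``.
    """

    gene_id: str
    intercept: float
    coef: pd.Series  # standardized scale, indexed by feature name
    alpha: float  # L1/L2 mixing in [0, 1]
    lambda_: float  # penalty strength
    cv_mse: float
    feature_means: pd.Series
    feature_sds: pd.Series
    invitro_features: tuple[str, ...]
    degenerate: bool = False  # zero-variance target: beta = 0, intercept only

    @property
    def features(self) -> list[str]:
        return list(self.coef.index)

    @property
    def coef_original(self) -> pd.Series:
        """Coefficients on the original (unstandardized) feature scale."""
        return self.coef / self.feature_sds

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValidationError(
                f"gene {self.gene_id}: features missing from input: {missing[:5]}"
            )
        Z = (X[self.features] - self.feature_means) / self.feature_sds
        return self.intercept + Z.to_numpy(dtype=float) @ self.coef.to_numpy(dtype=float)

    @property
    def invitro_importance(self) -> float:
        """Share of total standardized |coefficient| mass on in vitro features.

        0 by convention when every coefficient is zero.
        """
        mags = self.coef.abs()
        total = float(mags.sum())
        if total == 0.0:
            return 0.0
        invitro = float(mags.loc[list(self.invitro_features)].sum()) if self.invitro_features else 0.0
        return invitro / total


@dataclass
class ModelBank:
    """The virtual microarray: one elastic-net model per retained gene,
    plus everything needed to apply it to new substances (descriptor pipeline,
    training medians of the in vitro features for imputation)."""

    models: dict[str, GeneModel]
    training_gene_set: list[str]
    invitro_feature_medians: pd.Series  # indexed by gene id, log2 scale
    descriptor_curation_log: list[dict]
    descriptor_transform_log: list[dict]
    schema_version: str = MODEL_BANK_SCHEMA_VERSION
    random_seed: int = 0

    def __post_init__(self) -> None:
        extra = set(self.models) - set(self.training_gene_set)
        if extra:
            raise ValidationError(f"models for genes outside the training set: {extra}")
        used = {
            g[len(INVITRO_FEATURE_PREFIX):]
            for m in self.models.values()
            for g in m.invitro_features
        }
        undeclared = used - set(self.invitro_feature_medians.index)
        if undeclared:
            raise ValidationError(f"no training median for in vitro features: {undeclared}")

    def __len__(self) -> int:
        return len(self.models)


def _series_to_doc(s: pd.Series) -> dict:
    return {"index": [str(i) for i in s.index], "values": [float(v) for v in s.to_numpy()]}


def _series_from_doc(doc: Mapping) -> pd.Series:
    return pd.Series(doc["values"], index=doc["index"], dtype=float)


def write_model_bank(bank: ModelBank, path: str | Path) -> None:
    """Serialize a bank to a schema-versioned, human-diffable JSON document.

    Floats are written with ``repr`` precision (17 significant digits), so a
    read/write round trip is bit-exact.
    """
    doc = {
        "format": "raidkit-model-bank",
        "schema_version": bank.schema_version,
        "random_seed": bank.random_seed,
        "training_gene_set": bank.training_gene_set,
        "invitro_feature_medians": _series_to_doc(bank.invitro_feature_medians),
        "descriptor_curation_log": bank.descriptor_curation_log,
        "descriptor_transform_log": bank.descriptor_transform_log,
        "models": {
            g: {
                "intercept": m.intercept,
                "coef": _series_to_doc(m.coef),
                "alpha": m.alpha,
                "lambda": m.lambda_,
                "cv_mse": m.cv_mse,
                "feature_means": _series_to_doc(m.feature_means),
                "feature_sds": _series_to_doc(m.feature_sds),
                "invitro_features": list(m.invitro_features),
                "degenerate": m.degenerate,
            }
            for g, m in bank.models.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model_bank(path: str | Path) -> ModelBank:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != MODEL_BANK_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: unknown model-bank schema_version {version!r} "
            f"(this build reads {MODEL_BANK_SCHEMA_VERSION!r})"
        )
    models = {
        g: GeneModel(
            gene_id=g,
            intercept=d["intercept"],
            coef=_series_from_doc(d["coef"]),
            alpha=d["alpha"],
            lambda_=d["lambda"],
            cv_mse=d["cv_mse"],
            feature_means=_series_from_doc(d["feature_means"]),
            feature_sds=_series_from_doc(d["feature_sds"]),
            invitro_features=tuple(d["invitro_features"]),
            degenerate=d["degenerate"],
        )
        for g, d in doc["models"].items()
    }
    return ModelBank(
        models=models,
        training_gene_set=list(doc["training_gene_set"]),
        invitro_feature_medians=_series_from_doc(doc["invitro_feature_medians"]),
        descriptor_curation_log=list(doc["descriptor_curation_log"]),
        descriptor_transform_log=list(doc["descriptor_transform_log"]),
        schema_version=version,
        random_seed=int(doc["random_seed"]),
    )


# ---------------------------------------------------------------------------
# PCA container
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Centered (optionally scaled) principal-component decomposition.

    ``scores = (X - center) @ loadings`` on the training data; loading columns
    are orthonormal; components are ordered by decreasing explained variance
    with a deterministic sign convention (largest-magnitude loading positive).
    """

    scores: pd.DataFrame  # substances x components
    loadings: pd.DataFrame  # features x components
    explained_variance: np.ndarray
    center: pd.Series
    scale: pd.Series | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.explained_variance.sum()
        return self.explained_variance / total if total > 0 else self.explained_variance
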