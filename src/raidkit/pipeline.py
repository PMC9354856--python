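"""End-to-end orchestration: preprocess -> filter -> train -> predict ->
PCA/read-across -> RMSE evaluation, with a machine-readable report bundle.

Every stage is an independently importable function elsewhere in the package;
this module only wires them together, stamps a manifest, and keeps stage
failures attributable (:class:`StageError` names the stage that died).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data_model import (
    DescriptorTable,
    FoldChangeMatrix,
    ModelBank,
    ToxicityLabels,
    read_descriptor_table,
    read_replicate_table,
    read_toxicity_labels,
    write_matrix_tsv,
    write_model_bank,
)
from .model_bank import BankConfig, predict, train_bank
from .preprocess import (
    AdjustmentContext,
    adjust_matrix,
    compute_fold_change,
    curate_descriptors,
    filter_genes,
    normalize_descriptors,
)
from .read_across import (
    biosimilar_neighbors,
    fit_pca,
    pc_related_gene_set,
    qivive_rmse,
    quadrant_top_genes,
    venn_partition,
)
from .synthetic_data import SimulationConfig, generate

__all__ = ["PipelineConfig", "PipelineReport", "StageError", "run_end_to_end"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs either come from TSV files or from the synthetic generator."""

    invivo_path: str | None = None
    invitro_path: str | None = None
    descriptors_path: str | None = None
    labels_path: str | None = None
    simulate: SimulationConfig | None = None
    seed: int = 0
    filter_min_substances: int = 10
    filter_fold_threshold: float = 1.5
    corr_threshold: float = 0.95
    bank: BankConfig = field(default_factory=BankConfig)
    neighbors_k: int = 5
    quadrant_k: int = 30
    pc_gene_k: int = 30


@dataclass
class PipelineReport:
    """In-memory results of one end-to-end run."""

    retained_genes: list[str]
    invivo_adjusted: FoldChangeMatrix
    invitro_adjusted: FoldChangeMatrix
    descriptors_normalized: DescriptorTable
    bank: ModelBank
    predicted: FoldChangeMatrix
    pca: dict[str, object]
    quadrant_rankings: dict[int, object]
    venn_counts: dict[frozenset[str], int]
    rmse_all: object
    rmse_important: object
    neighbors: pd.DataFrame
    labels: ToxicityLabels | None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kw):
            try:
                return fn(*args, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    quiet: bool = True,
) -> PipelineReport:
    """Run the whole workflow; optionally write the report bundle to disk."""

    @_stage("load")
    def load():
        if config.simulate is not None:
            sim = generate(config.simulate)
            return sim.invivo, sim.invitro, sim.descriptors, sim.labels
        if not (config.invivo_path and config.invitro_path and config.descriptors_path):
            raise ValueError("need invivo, invitro and descriptors paths (or simulate)")
        invivo = read_replicate_table(config.invivo_path, "in_vivo")
        invitro = read_replicate_table(config.invitro_path, "in_vitro")
        desc = read_descriptor_table(config.descriptors_path)
        labels = (
            read_toxicity_labels(config.labels_path) if config.labels_path else None
        )
        return invivo, invitro, desc, labels

    invivo_table, invitro_table, descriptors_raw, labels = load()

    @_stage("preprocess")
    def preprocess():
        fc_vivo = compute_fold_change(invivo_table)
        fc_vitro = compute_fold_change(invitro_table)
        adj_vivo = adjust_matrix(
            fc_vivo, AdjustmentContext.for_source("in_vivo"),
            cross_source_all_absent=fc_vitro.all_absent,
        )
        adj_vitro = adjust_matrix(
            fc_vitro, AdjustmentContext.for_source("in_vitro"),
            cross_source_all_absent=fc_vivo.all_absent,
        )
        return adj_vivo, adj_vitro

    adj_vivo, adj_vitro = preprocess()

    @_stage("filter")
    def gene_filter():
        return filter_genes(
            adj_vivo, config.filter_min_substances, config.filter_fold_threshold
        )

    retained = gene_filter()

    @_stage("descriptors")
    def descriptors():
        curated = curate_descriptors(descriptors_raw, config.corr_threshold)
        return normalize_descriptors(curated)

    desc_norm = descriptors()

    @_stage("train")
    def train():
        return train_bank(
            adj_vivo, adj_vitro, desc_norm, retained,
            config.bank, progress=not quiet,
        )

    bank = train()

    @_stage("predict")
    def predict_stage():
        return predict(bank, descriptors_raw, adj_vitro)

    predicted = predict_stage()

    @_stage("readacross")
    def readacross():
        matrices = {
            "in_vivo": adj_vivo.log2_values[retained],
            "raid": predicted.log2_values[retained],
            "in_vitro": adj_vitro.log2_values[retained],
        }
        pca = {name: fit_pca(m) for name, m in matrices.items()}
        k = min(config.pc_gene_k, len(retained))
        gene_sets = {
            name: pc_related_gene_set(p, k=k) for name, p in pca.items()
        }
        quadrants = {
            q: quadrant_top_genes(pca["in_vivo"], q, k=config.quadrant_k)
            for q in (1, 4)
        }
        venn = venn_partition(gene_sets)
        neighbor_frames = []
        scores = pca["raid"].scores
        for s in scores.index:
            nb = biosimilar_neighbors(scores, s, k=config.neighbors_k)
            nb.insert(0, "query", s)
            neighbor_frames.append(nb)
        return pca, quadrants, venn, pd.concat(neighbor_frames, ignore_index=True)

    pca, quadrants, venn, neighbors = readacross()

    @_stage("evaluate")
    def evaluate():
        from .data_model import ValidationError

        rmse_all = qivive_rmse(predicted, adj_vivo, adj_vitro, scope="all")
        try:
            rmse_imp = qivive_rmse(
                predicted, adj_vivo, adj_vitro, scope="invitro_important", bank=bank
            )
        except ValidationError:
            rmse_imp = None  # no model uses the in vitro block
        return rmse_all, rmse_imp

    rmse_all, rmse_important = evaluate()

    report = PipelineReport(
        retained_genes=retained,
        invivo_adjusted=adj_vivo,
        invitro_adjusted=adj_vitro,
        descriptors_normalized=desc_norm,
        bank=bank,
        predicted=predicted,
        pca=pca,
        quadrant_rankings=quadrants,
        venn_counts=venn,
        rmse_all=rmse_all,
        rmse_important=rmse_important,
        neighbors=neighbors,
        labels=labels,
    )
    if out_dir is not None:
        _write_bundle(report, config, Path(out_dir))
    return report


@_stage("write")
def _write_bundle(report: PipelineReport, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.invivo_adjusted.to_tsv(out / "fc_invivo_adjusted.tsv")
    report.invitro_adjusted.to_tsv(out / "fc_invitro_adjusted.tsv")
    report.predicted.to_tsv(out / "fc_predicted.tsv")
    report.descriptors_normalized.to_tsv(out / "descriptors_normalized.tsv")
    write_model_bank(report.bank, out / "bank.raid")
    for name, pca in report.pca.items():
        write_matrix_tsv(pca.scores, out / f"pca_scores_{name}.tsv")
        pca.loadings.to_csv(out / f"pca_loadings_{name}.tsv", sep="\t",
                            index_label="feature", float_format="%.17g")
    for q, ranking in report.quadrant_rankings.items():
        ranking.entries.to_csv(
            out / f"quadrant{q}_top_genes.tsv", sep="\t", index=False,
            float_format="%.17g",
        )
    venn_doc = {
        "+".join(sorted(region)): count
        for region, count in report.venn_counts.items()
    }
    (out / "venn_counts.json").write_text(json.dumps(venn_doc, indent=1, sort_keys=True))
    rmse_doc = {}
    for scope, cmp in (("all", report.rmse_all), ("invitro_important", report.rmse_important)):
        if cmp is None:
            rmse_doc[scope] = {"n_genes": 0}
            continue
        rmse_doc[scope] = {
            "mean_rmse_raid": cmp.mean_rmse_raid,
            "mean_rmse_invitro": cmp.mean_rmse_invitro,
            "welch_t": cmp.welch_t,
            "welch_p": cmp.welch_p,
        }
        pd.DataFrame(
            {
                "gene": cmp.per_gene_rmse_raid.index,
                "rmse_raid": cmp.per_gene_rmse_raid.to_numpy(),
                "rmse_invitro": cmp.per_gene_rmse_invitro.to_numpy(),
            }
        ).to_csv(out / f"rmse_{scope}.tsv", sep="\t", index=False, float_format="%.17g")
    (out / "rmse_summary.json").write_text(json.dumps(rmse_doc, indent=1))
    report.neighbors.to_csv(
        out / "neighbors.tsv", sep="\t", index=False, float_format="%.17g"
    )
    manifest = {
        "tool": "raidkit",
        "version": __version__,
        "command": "run_end_to_end",
        "seed": config.seed,
        "config": _config_doc(config),
        "input_digests": {
            name: _sha256(Path(p))
            for name, p in (
                ("invivo", config.invivo_path),
                ("invitro", config.invitro_path),
                ("descriptors", config.descriptors_path),
                ("labels", config.labels_path),
            )
            if p
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _config_doc(config: PipelineConfig) -> dict:
    doc = asdict(config)
    doc["bank"]["alpha_grid"] = list(doc["bank"]["alpha_grid"])
    doc["bank"]["weight_rule"] = {
        "thresholds": [list(t) for t in config.bank.weight_rule.thresholds],
        "default": config.bank.weight_rule.default,
    }
    return doc
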