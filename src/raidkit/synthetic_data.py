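"""Self-contained synthetic datasets with the statistical structure the
virtual-microarray pipeline assumes.

The generative model lives on the log2 scale. Chemical descriptors D are
standard normal; a sparse map A sends descriptors to in vitro log2 fold
changes; the in vivo response of each gene combines a sparse descriptor
effect (B) with, for a designated "in vitro-driven" subset of genes, a
per-gene coefficient (c) on that gene's *realized* in vitro signal — so for
driven genes the in vitro measurement genuinely carries information the
descriptors alone do not. Replicate-level MAS5-style signals are derived from
a per-gene baseline with multiplicative (log2) replicate noise; Absent calls
are drawn at a configurable rate, enriched at low absolute signal. Toxicity
labels come from thresholding a latent linear score of the true in vivo
profile, so supervised analyses have a planted structure to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import (
    DescriptorTable,
    ReplicateExpressionTable,
    ToxicityLabels,
    ValidationError,
    write_matrix_tsv,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate",
    "worked_example_fixture",
    "WorkedExample",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; generation is a pure function of this.

    Defaults emulate a modest toxicogenomics panel: 80 training substances
    (plus 40 held-out test substances drawn from the same ground-truth maps),
    20 genes of which 8 are in vitro-driven, 30 informative descriptors with
    planted correlated/constant columns, log2-scale effect sd 1.0 against
    residual noise sd 0.1, and the source study's replicate design
    (n = 3 in vivo, n = 2 in vitro).
    """

    n_substances: int = 80
    n_test_substances: int = 40
    n_genes: int = 20
    n_descriptors: int = 30
    n_invitro_driven_genes: int = 8
    descriptor_sparsity: float = 0.1
    effect_size_sd: float = 1.0
    noise_sd_invitro: float = 0.1
    noise_sd_invivo: float = 0.1
    replicate_noise_sd: float = 0.1
    absent_call_rate: float = 0.05
    toxic_fraction: float = 0.4
    correlated_descriptor_pairs: int = 2
    constant_descriptor_count: int = 1
    seed: int = 7

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in {
                "descriptor_sparsity", "absent_call_rate", "toxic_fraction",
            }:
                if not 0 <= v <= 1:
                    raise ValidationError(f"{f.name} must be in [0, 1], got {v}")
            elif f.name.startswith(("n_",)) and f.name != "n_test_substances":
                if v <= 0:
                    raise ValidationError(f"{f.name} must be positive, got {v}")
        if self.n_invitro_driven_genes > self.n_genes:
            raise ValidationError("more in vitro-driven genes than genes")
        if self.n_test_substances < 0:
            raise ValidationError("n_test_substances must be nonnegative")


@dataclass
class GroundTruth:
    """The planted maps and noiseless quantities behind a simulated dataset."""

    descriptor_to_invitro: pd.DataFrame  # A: descriptors x genes
    descriptor_to_invivo: pd.DataFrame  # B: descriptors x genes
    invitro_to_invivo: pd.Series  # c: per-gene coefficient, 0 off the driven set
    driven_genes: list[str]
    invitro_log2: pd.DataFrame  # realized (pre-replicate-noise) in vitro log2 FC
    invivo_log2: pd.DataFrame  # realized in vivo log2 FC (with biological noise)
    invivo_log2_noiseless: pd.DataFrame  # linear predictor without invivo noise
    latent_toxicity: pd.Series

    def support(self, gene: str) -> set[str]:
        """Truth feature support of one gene's in vivo model (named features)."""
        out = set(
            self.descriptor_to_invivo.index[
                self.descriptor_to_invivo[gene] != 0
            ]
        )
        if self.invitro_to_invivo[gene] != 0:
            out.add(f"invitro:{gene}")
        return out


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    invivo: ReplicateExpressionTable
    invitro: ReplicateExpressionTable
    descriptors: DescriptorTable
    labels: ToxicityLabels
    truth: GroundTruth

    @property
    def substances(self) -> list[str]:
        return list(self.descriptors.values.index)

    @property
    def train_substances(self) -> list[str]:
        return self.substances[: self.config.n_substances]

    @property
    def test_substances(self) -> list[str]:
        return self.substances[self.config.n_substances :]

    def write_tsvs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in (("invivo", self.invivo), ("invitro", self.invitro)):
            table.records.to_csv(out / f"replicates_{name}.tsv", sep="\t", index=False)
        self.descriptors.to_tsv(out / "descriptors.tsv")
        pd.DataFrame(
            {"substance_id": list(self.labels.labels), "label": list(self.labels.labels.values())}
        ).to_csv(out / "labels.tsv", sep="\t", index=False)
        write_matrix_tsv(self.truth.invivo_log2, out / "truth_invivo_log2.tsv")
        write_matrix_tsv(self.truth.invitro_log2, out / "truth_invitro_log2.tsv")


def _sparse_map(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    sparsity: float,
    effect_sd: float,
) -> np.ndarray:
    mask = rng.random((n_rows, n_cols)) < sparsity
    # every column needs at least one effect or the gene would be pure noise
    for j in range(n_cols):
        if not mask[:, j].any():
            mask[rng.integers(n_rows), j] = True
    return np.where(mask, rng.normal(0.0, effect_sd, (n_rows, n_cols)), 0.0)


def _replicate_table(
    rng: np.random.Generator,
    log2_fc: pd.DataFrame,
    source: str,
    n_reps: int,
    replicate_noise_sd: float,
    absent_call_rate: float,
) -> ReplicateExpressionTable:
    substances, genes = list(log2_fc.index), list(log2_fc.columns)
    baseline = 2.0 ** rng.normal(7.0, 1.0, size=len(genes))  # MAS5-ish scale
    rows = []
    log_q25 = np.log2(np.quantile(baseline, 0.25))
    for si, s in enumerate(substances):
        for gi, g in enumerate(genes):
            for group, shift in (("treated", log2_fc.iloc[si, gi]), ("control", 0.0)):
                noise = rng.normal(0.0, replicate_noise_sd, n_reps)
                signals = baseline[gi] * 2.0 ** (shift + noise)
                for r in range(n_reps):
                    p_absent = min(
                        1.0,
                        absent_call_rate
                        * 2.0
                        * expit(log_q25 - np.log2(signals[r])),
                    ) if absent_call_rate > 0 else 0.0
                    u = rng.random()
                    call = "A" if u < p_absent else ("M" if u < p_absent + 0.03 else "P")
                    rows.append((s, g, group, r + 1, signals[r], call))
    records = pd.DataFrame(
        rows, columns=["substance", "gene", "group", "replicate", "signal", "call"]
    )
    return ReplicateExpressionTable(
        records=records, source=source, replicates_per_group=n_reps
    )


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Draw a complete paired in vitro / in vivo study from the config.

    Randomness is split into purpose-keyed streams so the planted ground
    truth (effect maps, driven-gene set, label direction) depends only on the
    seed and the structural sizes, and the first ``n_substances`` training
    rows are unchanged when ``n_test_substances`` varies.
    """
    rng_maps = np.random.default_rng([config.seed, 0])
    rng_subs = np.random.default_rng([config.seed, 1])
    rng_noise_vitro = np.random.default_rng([config.seed, 2])
    rng_extra = np.random.default_rng([config.seed, 3])
    rng_reps_vivo = np.random.default_rng([config.seed, 4])
    rng_noise_vivo = np.random.default_rng([config.seed, 5])
    rng_reps_vitro = np.random.default_rng([config.seed, 6])

    n_total = config.n_substances + config.n_test_substances
    substances = [f"S{i + 1:03d}" for i in range(n_total)]
    genes = [f"g{i + 1:03d}" for i in range(config.n_genes)]
    base_desc = [f"d{i + 1:03d}" for i in range(config.n_descriptors)]

    D = rng_subs.normal(0.0, 1.0, (n_total, config.n_descriptors))

    A = _sparse_map(
        rng_maps, config.n_descriptors, config.n_genes,
        config.descriptor_sparsity, config.effect_size_sd,
    )
    B = _sparse_map(
        rng_maps, config.n_descriptors, config.n_genes,
        config.descriptor_sparsity, config.effect_size_sd,
    )
    driven_idx = rng_maps.choice(
        config.n_genes, size=config.n_invitro_driven_genes, replace=False
    )
    driven_idx.sort()
    c = np.zeros(config.n_genes)
    c[driven_idx] = rng_maps.choice([-1.0, 1.0], len(driven_idx)) * (
        config.effect_size_sd * rng_maps.uniform(0.8, 1.2, len(driven_idx))
    )
    toxic_direction = _unit_vector(rng_maps, config.n_genes)

    invitro_log2 = D @ A + rng_noise_vitro.normal(
        0.0, config.noise_sd_invitro, (n_total, config.n_genes)
    )
    predictor = D @ B + invitro_log2 * c  # noiseless linear predictor
    invivo_log2 = predictor + rng_noise_vivo.normal(
        0.0, config.noise_sd_invivo, (n_total, config.n_genes)
    )

    # planted curation hazards: near-duplicate and constant descriptor columns
    desc_cols = {name: D[:, j] for j, name in enumerate(base_desc)}
    corr_noise = rng_extra.normal(
        0.0, 0.15, (n_total, config.correlated_descriptor_pairs)
    ) if config.correlated_descriptor_pairs else None
    for i in range(config.correlated_descriptor_pairs):
        src = base_desc[i % config.n_descriptors]
        desc_cols[f"{src}_corr"] = desc_cols[src] + corr_noise[:, i]
    for i in range(config.constant_descriptor_count):
        desc_cols[f"const{i + 1}"] = np.full(n_total, 1.0)
    descriptors = DescriptorTable(
        values=pd.DataFrame(desc_cols, index=substances)
    )

    latent = invivo_log2 @ toxic_direction
    threshold = np.quantile(latent, 1.0 - config.toxic_fraction)
    labels = ToxicityLabels(
        {
            s: ("toxic" if latent[i] > threshold else "non_toxic")
            for i, s in enumerate(substances)
        }
    )

    invitro_frame = pd.DataFrame(invitro_log2, index=substances, columns=genes)
    invivo_frame = pd.DataFrame(invivo_log2, index=substances, columns=genes)
    truth = GroundTruth(
        descriptor_to_invitro=pd.DataFrame(A, index=base_desc, columns=genes),
        descriptor_to_invivo=pd.DataFrame(B, index=base_desc, columns=genes),
        invitro_to_invivo=pd.Series(c, index=genes),
        driven_genes=[genes[i] for i in driven_idx],
        invitro_log2=invitro_frame,
        invivo_log2=invivo_frame,
        invivo_log2_noiseless=pd.DataFrame(predictor, index=substances, columns=genes),
        latent_toxicity=pd.Series(latent, index=substances),
    )

    invivo_table = _replicate_table(
        rng_reps_vivo, invivo_frame, "in_vivo", 3,
        config.replicate_noise_sd, config.absent_call_rate,
    )
    invitro_table = _replicate_table(
        rng_reps_vitro, invitro_frame, "in_vitro", 2,
        config.replicate_noise_sd, config.absent_call_rate,
    )
    return SimulatedDataset(
        config=config,
        invivo=invivo_table,
        invitro=invitro_table,
        descriptors=descriptors,
        labels=labels,
        truth=truth,
    )


def _unit_vector(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=n)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Hand-built worked example
# ---------------------------------------------------------------------------

_TIGHT_BASE = (100.0, 101.0, 99.0)  # replicate shape giving tiny log2 variance
_SPREAD_BASE = (50.0, 100.0, 150.0)  # wide shape pushing Welch p above 0.1
_TIGHT_BASE_2 = (100.0, 102.0)


@dataclass
class WorkedExample:
    """A tiny hand-built dataset exercising every preprocessing branch."""

    invivo: ReplicateExpressionTable
    invitro: ReplicateExpressionTable
    descriptors: DescriptorTable
    labels: ToxicityLabels
    #: planted (substance, gene) -> expected adjusted in vivo fold change
    expected_adjusted: dict[tuple[str, str], float]
    #: expected weights at the planted cells
    expected_weights: dict[tuple[str, str], float]
    #: gene-filter settings that straddle the retention boundary
    filter_min_substances: int
    expected_retained_genes: list[str]


def worked_example_fixture() -> WorkedExample:
    """6 substances x 4 genes x 5 descriptors, all values chosen by hand.

    Planted behavior (in vivo matrix):

    * (S1, g1): F = 1.5 with 2 of 3 treated replicates Absent -> half rule -> 1.25
    * (S2, g2): F = 1.4 with widely spread replicates (Welch p > 0.1) -> 1.1
    * (S3, g3): every call Absent in both sources -> forced to 1 (raw F = 2)
    * (S4, g4): F = 3 with clean flags and tiny p -> unchanged; weight 1.5
    * (S5, g4): F = 4 -> weight 2;  (S5, g2): F = 0.25 -> magnitude 4, weight 2
    * gene filter at min_substances = 3: per-gene counts of adjusted
      |FC| >= 1.5 are {g1: 1, g2: 2, g3: 3, g4: 4} -> retained {g3, g4}
    * descriptor d5 = 2 * d1 (pair correlation 1) and d4 constant
    """
    substances = [f"S{i}" for i in range(1, 7)]
    genes = ["g1", "g2", "g3", "g4"]

    # fold change and replicate shape per in vivo cell: (F, base, treated_calls)
    default = (1.0, _TIGHT_BASE, "PPP")
    cells: dict[tuple[str, str], tuple[float, tuple, str]] = {
        ("S1", "g1"): (1.5, _TIGHT_BASE, "AAP"),  # half via flag count
        ("S2", "g2"): (1.4, _SPREAD_BASE, "PPP"),  # quarter via p > 0.1
        ("S3", "g3"): (2.0, _TIGHT_BASE, "AAA"),  # all-Absent -> 1
        ("S4", "g4"): (3.0, _TIGHT_BASE, "PPP"),  # unchanged, weight 1.5
        ("S5", "g4"): (4.0, _TIGHT_BASE, "PPP"),  # weight 2
        ("S5", "g2"): (0.25, _TIGHT_BASE, "PPP"),  # down-regulated, weight 2
        ("S6", "g1"): (2.0, _TIGHT_BASE, "PPP"),
        ("S6", "g2"): (1.6, _TIGHT_BASE, "PPP"),
        ("S1", "g3"): (2.0, _TIGHT_BASE, "PPP"),
        ("S2", "g3"): (2.0, _TIGHT_BASE, "PPP"),
        ("S4", "g3"): (1.5, _TIGHT_BASE, "PPP"),
        ("S2", "g4"): (2.0, _TIGHT_BASE, "PPP"),
        ("S6", "g4"): (2.0, _TIGHT_BASE, "PPP"),
    }

    rows = []
    for s in substances:
        for g in genes:
            F, base, treated_calls = cells.get((s, g), default)
            control_calls = "AAA" if treated_calls == "AAA" else "PPP"
            for group, factor, calls in (
                ("treated", F, treated_calls),
                ("control", 1.0, control_calls),
            ):
                for r, b in enumerate(base, start=1):
                    rows.append((s, g, group, r, factor * b, calls[r - 1]))
    invivo = ReplicateExpressionTable(
        records=pd.DataFrame(
            rows, columns=["substance", "gene", "group", "replicate", "signal", "call"]
        ),
        source="in_vivo",
        replicates_per_group=3,
    )

    rows = []
    for s in substances:
        for g in genes:
            F, _, treated_calls = cells.get((s, g), default)
            all_absent = treated_calls == "AAA"
            calls = "AA" if all_absent else "PP"
            for group, factor in (("treated", F), ("control", 1.0)):
                for r, b in enumerate(_TIGHT_BASE_2, start=1):
                    rows.append((s, g, group, r, factor * b, calls[r - 1]))
    invitro = ReplicateExpressionTable(
        records=pd.DataFrame(
            rows, columns=["substance", "gene", "group", "replicate", "signal", "call"]
        ),
        source="in_vitro",
        replicates_per_group=2,
    )

    d1 = np.array([0.5, 1.2, -0.3, 2.2, 1.0, 0.1])
    descriptors = DescriptorTable(
        values=pd.DataFrame(
            {
                "d1": d1,
                "d2": [3.1, 0.2, 1.5, -0.7, 0.9, 2.0],
                "d3": [10.0, 12.0, 9.5, 11.0, 10.5, 13.0],
                "d4": [1.0] * 6,  # constant
                "d5": 2.0 * d1,  # exact duplicate up to scale, r = 1
            },
            index=substances,
        )
    )
    labels = ToxicityLabels(
        {s: ("toxic" if s in {"S1", "S2", "S3"} else "non_toxic") for s in substances}
    )
    return WorkedExample(
        invivo=invivo,
        invitro=invitro,
        descriptors=descriptors,
        labels=labels,
        expected_adjusted={
            ("S1", "g1"): 1.25,
            ("S2", "g2"): 1.1,
            ("S3", "g3"): 1.0,
            ("S4", "g4"): 3.0,
        },
        expected_weights={
            ("S4", "g4"): 1.5,
            ("S5", "g4"): 2.0,
            ("S5", "g2"): 2.0,
            ("S1", "g1"): 1.0,
        },
        filter_min_substances=3,
        expected_retained_genes=["g3", "g4"],
    )
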