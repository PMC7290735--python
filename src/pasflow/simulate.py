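"""Synthetic hepatectomy-style studies with planted pathway effects.

The generator emulates the three-arm design of the reference experiment:
sham, normal hepatectomy (nHx) and extended hepatectomy (eHx), each at five
post-surgery time points with replicate animals.  Expression is drawn per
gene around a log-normal baseline; a planted effect on a pathway multiplies
the expected expression of that pathway's activators by the fold change and
divides its repressors by it (reversed for a "down" effect) in the chosen
arm and time point, so the planted pathway has a coherent expected PAS sign.

Two expression regimes are available: multiplicative log-normal noise
(the default; PAS operates on expression ratios) and a negative-binomial
count mode for the paths that need integer reads (CPM normalization, the
miRNA read-count filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ARMS, TIME_POINTS, ExpressionStudy
from .knowledgebase import GeneRole, Pathway, PathwayDB
from .mirna import MirnaTargetTable

__all__ = ["PlantedEffect", "SimulationConfig", "generate_study", "null_study"]


@dataclass(frozen=True)
class PlantedEffect:
    """A pathway-coherent expression shift in one arm at one time point."""

    pathway_id: str
    arm: str
    time_h: int
    direction: str  # "up" or "down"
    fold_change: float

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"planted effect arm {self.arm!r} not one of {ARMS}")
        if self.time_h not in TIME_POINTS:
            raise ValueError(f"planted effect time_h {self.time_h} not one of {TIME_POINTS}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"planted effect direction must be 'up' or 'down', got {self.direction!r}")
        if not self.fold_change > 1:
            raise ValueError(f"planted effect fold_change must exceed 1, got {self.fold_change}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the reference design (3 arms x 5 time points x 3
    replicates) at a desk-testable scale of 200 genes in 20 pathways, with
    log2 baseline spread 1.5 and multiplicative log2 noise 0.25.
    """

    n_genes: int = 200
    n_pathways: int = 20
    genes_per_pathway: tuple[int, int] = (5, 15)
    activator_fraction: float = 0.7
    time_points: tuple[int, ...] = TIME_POINTS
    replicates: int = 3
    expression_model: str = "lognormal"  # or "negative_binomial"
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.25
    nb_dispersion: float = 0.1
    planted_effects: tuple[PlantedEffect, ...] = ()
    n_mirnas: int = 10
    targets_per_mirna: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be positive")
        lo, hi = self.genes_per_pathway
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid genes_per_pathway range {self.genes_per_pathway}")
        if hi > self.n_genes:
            raise ValueError("genes_per_pathway upper bound exceeds n_genes")
        if not 0 <= self.activator_fraction <= 1:
            raise ValueError("activator_fraction must be in [0, 1]")
        if self.expression_model not in ("lognormal", "negative_binomial"):
            raise ValueError(f"unknown expression_model {self.expression_model!r}")
        if self.replicates < 2:
            raise ValueError("replicates must be at least 2")
        if self.noise_log2_sd <= 0:
            raise ValueError("noise_log2_sd must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        known = {f"PW{k + 1:03d}" for k in range(self.n_pathways)}
        for eff in self.planted_effects:
            if eff.pathway_id not in known:
                raise ValueError(
                    f"planted pathway {eff.pathway_id!r} not among the "
                    f"{self.n_pathways} generated pathways"
                )


def _generate_db(cfg: SimulationConfig, rng: np.random.Generator) -> PathwayDB:
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    lo, hi = cfg.genes_per_pathway
    pathways = []
    for k in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        member_idx = rng.choice(cfg.n_genes, size=size, replace=False)
        members = tuple(
            GeneRole(genes[i], 1.0 if rng.random() < cfg.activator_fraction else -1.0)
            for i in member_idx
        )
        pathways.append(Pathway(f"PW{k + 1:03d}", f"Synthetic pathway {k + 1}", members))
    return PathwayDB(tuple(pathways))


def generate_study(
    config: SimulationConfig,
) -> tuple[PathwayDB, ExpressionStudy, MirnaTargetTable, pd.DataFrame]:
    """Generate a complete synthetic study, fully determined by the seed.

    Returns the pathway knowledge base, the expression study (raw counts in
    negative-binomial mode), a miRNA target table, and the truth table of
    planted effects (columns pathway_id, arm, time_h, direction, fold_change).
    """
    rng = np.random.default_rng(config.seed)
    db = _generate_db(config, rng)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                                 size=config.n_genes)

    # per-(arm, time) multiplicative effect vector from the planted effects
    effect_by_group: dict[tuple[str, int], np.ndarray] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for eff in config.planted_effects:
        key = (eff.arm, eff.time_h)
        mult = effect_by_group.setdefault(key, np.ones(config.n_genes))
        pw = db[eff.pathway_id]
        for g, arr in pw.roles.items():
            up = (arr > 0) == (eff.direction == "up")
            mult[gene_pos[g]] *= eff.fold_change if up else 1.0 / eff.fold_change

    columns, meta_rows = [], []
    data = np.empty((config.n_genes, 0))
    blocks = []
    for arm in ARMS:
        for t in config.time_points:
            mult = effect_by_group.get((arm, t), 1.0)
            mean = baseline * mult
            for rep in range(1, config.replicates + 1):
                sid = f"{arm}_t{t:02d}_r{rep}"
                columns.append(sid)
                meta_rows.append({"sample_id": sid, "arm": arm, "time_h": t, "replicate": rep})
                if config.expression_model == "lognormal":
                    vals = mean * 2.0 ** rng.normal(0.0, config.noise_log2_sd, config.n_genes)
                else:
                    mu = mean * 2.0 ** rng.normal(0.0, config.noise_log2_sd, config.n_genes)
                    n = 1.0 / config.nb_dispersion
                    vals = rng.negative_binomial(n, n / (n + mu)).astype(float)
                blocks.append(vals)
    data = np.column_stack(blocks)
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=columns)
    study = ExpressionStudy(matrix, pd.DataFrame(meta_rows), normalized=False)

    lo, hi = config.targets_per_mirna
    rows = []
    for m in range(config.n_mirnas):
        size = int(rng.integers(lo, hi + 1))
        for i in rng.choice(config.n_genes, size=size, replace=False):
            rows.append({"mirna_id": f"miR-{m + 1:03d}", "target_gene": genes[i],
                         "evidence": "validated"})
    targets = MirnaTargetTable(pd.DataFrame(rows, columns=["mirna_id", "target_gene", "evidence"]))

    truth = pd.DataFrame(
        [
            {"pathway_id": e.pathway_id, "arm": e.arm, "time_h": e.time_h,
             "direction": e.direction, "fold_change": e.fold_change}
            for e in config.planted_effects
        ],
        columns=["pathway_id", "arm", "time_h", "direction", "fold_change"],
    )
    return db, study, targets, truth


def null_study(
    config: SimulationConfig,
) -> tuple[PathwayDB, ExpressionStudy, MirnaTargetTable, pd.DataFrame]:
    """A study with no planted effects (empty truth table)."""
    return generate_study(replace(config, planted_effects=()))


def write_study(outdir: str | Path, db: PathwayDB, study: ExpressionStudy,
                targets: MirnaTargetTable, truth: pd.DataFrame, seed: int) -> dict[str, Path]:
    """Write all study components as the TSV formats the loaders read."""
    from .knowledgebase import write_pathway_db

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression.tsv",
        "meta": outdir / "samples.tsv",
        "pathways": outdir / "pathways.tsv",
        "targets": outdir / "mirna_targets.tsv",
        "truth": outdir / "truth.tsv",
    }
    header = f"# seed={seed}\n"
    for key, frame in (("matrix", study.matrix), ("meta", study.meta),
                       ("targets", targets.table), ("truth", truth)):
        with open(paths[key], "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=key == "matrix")
    write_pathway_db(db, paths["pathways"])
    return paths
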