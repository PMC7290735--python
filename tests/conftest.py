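import numpy as np
import pandas as pd
import pytest

from pasflow import (
    ExpressionStudy,
    GeneRole,
    Pathway,
    PathwayDB,
    PlantedEffect,
    SimulationConfig,
    generate_study,
)


@pytest.fixture(scope="session")
def small_db() -> PathwayDB:
    return PathwayDB((
        Pathway("P1", "Alpha", (GeneRole("g1", 1), GeneRole("g2", 1), GeneRole("g3", -1))),
        Pathway("P2", "Beta", (GeneRole("g2", 1), GeneRole("g3", 1), GeneRole("g4", -1))),
    ))


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    return SimulationConfig(
        planted_effects=(PlantedEffect("PW001", "eHx", 32, "up", 4.0),),
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_study(planted_config):
    """(db, study, targets, truth) with one 4-fold up effect on PW001/eHx/32h."""
    return generate_study(planted_config)


def make_study(values: dict[str, list[float]], genes: list[str],
               meta_rows: list[tuple[str, str, int, int]],
               normalized: bool = False) -> ExpressionStudy:
    """Small hand-built study; meta_rows are (sample_id, arm, time_h, replicate)."""
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "arm", "time_h", "replicate"])
    return ExpressionStudy(matrix, meta, normalized=normalized)


@pytest.fixture()
def six_sample_study() -> ExpressionStudy:
    """3 sham + 3 eHx samples at 8 h, 4 genes, with a planted 4x gene g1."""
    rng = np.random.default_rng(5)
    base = np.array([100.0, 50.0, 200.0, 10.0])
    cols = {}
    meta = []
    for i in range(3):
        cols[f"s{i}"] = base * rng.lognormal(0, 0.05, 4)
        meta.append((f"s{i}", "sham", 8, i + 1))
    for i in range(3):
        v = base * rng.lognormal(0, 0.05, 4)
        v[0] *= 4.0
        cols[f"c{i}"] = v
        meta.append((f"c{i}", "eHx", 8, i + 1))
    return make_study(cols, ["g1", "g2", "g3", "g4"], meta)
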