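"""miRNA target filtering and projection of miRNA action onto pathway scores.

The module consumes a pre-built miRNA -> target-mRNA table (e.g. exported
from a curated interaction database) — it never queries a database itself.
Targets are trusted only when the target gene shows minimal expression
support in the study (total raw read count >= 10 by default, summed across
all samples).

The projection answers "how would this miRNA set tilt each pathway's
activation?": the PAS sum is evaluated over only the pathway members that
are targets of the miRNA, with every targeted member's contribution entered
as repression (its CNR inverted).  This is an explicit modelling convention
of this package, reflecting the canonically repressive action of miRNAs on
their target transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .expression import ExpressionStudy
from .knowledgebase import PathwayDB
from .pas import GeneEvidence

EVIDENCE_LEVELS = ("validated", "novel-no-targets")

__all__ = [
    "MirnaTargetTable",
    "load_target_table",
    "filter_targets",
    "mirna_pas_projection",
]


@dataclass(frozen=True)
class MirnaTargetTable:
    """Rows of (mirna_id, target_gene, evidence) with unique pairs."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mirna_id", "target_gene", "evidence"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"target table missing columns {sorted(missing)}")
        bad = set(self.table["evidence"]) - set(EVIDENCE_LEVELS)
        if bad:
            raise ValueError(f"unknown evidence level(s) {sorted(bad)}")
        dup = self.table.duplicated(subset=["mirna_id", "target_gene"])
        if dup.any():
            pairs = self.table.loc[dup, ["mirna_id", "target_gene"]].apply(tuple, axis=1)
            raise ValueError(f"duplicate (mirna_id, target_gene) pairs: {list(pairs)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mirna_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["mirna_id"]))

    def targets_of(self, mirna_id: str) -> frozenset[str]:
        rows = self.table[self.table["mirna_id"] == mirna_id]
        return frozenset(rows["target_gene"])


def load_target_table(path: str | Path) -> MirnaTargetTable:
    """Read a miRNA target table TSV (columns mirna_id, target_gene, evidence)."""
    return MirnaTargetTable(pd.read_csv(path, sep="\t", dtype=str, comment="#"))


def filter_targets(
    table: MirnaTargetTable, study: ExpressionStudy, min_reads: int = 10
) -> MirnaTargetTable:
    """Keep targets with expression support: total raw reads >= min_reads.

    Read support is the sum of raw counts across all study samples, so the
    filter requires a study of raw counts (``normalized`` False).  The
    comparison is inclusive; ``min_reads=0`` is the identity.  Target genes
    absent from the matrix have zero support.
    """
    if study.normalized:
        raise ValueError("read-count filtering requires raw counts, not normalized values")
    support = study.matrix.sum(axis=1)
    reads = table.table["target_gene"].map(support).fillna(0)
    return MirnaTargetTable(table.table[reads >= min_reads].reset_index(drop=True))


def mirna_pas_projection(
    table: MirnaTargetTable,
    db: PathwayDB,
    evidence: Mapping[str, GeneEvidence],
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Projected PAS contribution of each miRNA's target set on each pathway.

    For pathway p and miRNA m, sums ARR · BTIF · log(1/CNR) over the members
    of p targeted by m — each targeted gene contributes with its CNR
    inverted, encoding miRNA repression of the target.  Returns a pathway x
    miRNA frame; a miRNA targeting no member of a pathway projects 0 there.
    """
    mirnas = table.mirna_ids
    out = pd.DataFrame(0.0, index=db.pathway_ids, columns=mirnas)
    out.index.name = "pathway_id"
    for m in mirnas:
        targets = table.targets_of(m)
        for pw in db.pathways:
            total = 0.0
            for gene, arr in pw.roles.items():
                if gene not in targets:
                    continue
                ev = evidence.get(gene)
                if ev is None:
                    continue
                total += arr * ev.btif * math.log(1.0 / ev.cnr, log_base)
            out.loc[pw.pathway_id, m] = total
    return out
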