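"""Pathway activation strength (PAS) scoring.

For a pathway *p* and a case sample, the activation strength is

    PAS_p = Σ_n  ARR_{n,p} · BTIF_n · log10(CNR_n)

summed over member genes *n*, where

* ``CNR`` (case-to-normal ratio) is the gene's expression in the case sample
  divided by its mean expression in the control group (with a pseudocount);
* ``BTIF`` (beyond-tolerance-interval flag) is 1 only when the gene is both
  statistically outside the control tolerance interval (p < 0.05, strict)
  and its CNR falls below 0.66 or above 1.5 (strict bounds);
* ``ARR`` is the signed activator/repressor role weight from the knowledge
  base.

A positive PAS marks an activated pathway, a negative PAS a silenced one.
Significance machinery: per-sample Gaussian p-values from the control-derived
PAS distribution, group-level Wilcoxon rank-sum p-values (case vs control
per-sample PAS) and Benjamini–Hochberg FDR across the pathways of a profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionStudy
from .knowledgebase import Pathway, PathwayDB

__all__ = [
    "PASConfig",
    "GeneEvidence",
    "PASProfile",
    "compute_cnr",
    "compute_btif",
    "gene_tolerance_p",
    "compute_pas",
    "compute_evidence",
    "pas_profile",
    "group_pas_profile",
]


@dataclass(frozen=True)
class PASConfig:
    """Tunable thresholds of the PAS engine.

    ``cnr_low``/``cnr_high`` bound the tolerance band of unremarkable
    fold-change (defaults 0.66 / 1.5, strict comparisons); ``alpha`` is the
    strict gene-level significance gate of the BTIF; ``log_base`` fixes the
    base of the CNR logarithm (10, so one significant activator at 10-fold
    induction contributes exactly +1); ``aggregator`` maps per-sample PAS to
    a single group value.
    """

    cnr_low: float = 0.66
    cnr_high: float = 1.5
    alpha: float = 0.05
    pseudocount: float | None = None  # None -> study's default convention
    log_base: float = 10.0
    aggregator: str = "mean"  # or "median"
    group_test_reference: str = "loo"  # or "whole"

    def __post_init__(self) -> None:
        if not (0 < self.cnr_low < 1 < self.cnr_high):
            raise ValueError("need 0 < cnr_low < 1 < cnr_high")
        if self.aggregator not in ("mean", "median"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.group_test_reference not in ("loo", "whole"):
            raise ValueError(f"unknown group_test_reference {self.group_test_reference!r}")


@dataclass(frozen=True)
class GeneEvidence:
    """Per-gene inputs to the PAS sum for one case sample."""

    gene_id: str
    cnr: float
    btif: int
    p_gene: float

    def __post_init__(self) -> None:
        if self.cnr <= 0:
            raise ValueError(f"CNR must be positive for {self.gene_id!r}")


def compute_cnr(case_value: float, control_values: Sequence[float],
                pseudocount: float = 0.0) -> float:
    """Case-to-normal ratio: (case + c) / (mean(controls) + c)."""
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 1:
        raise ValueError("need at least one control value")
    denom = controls.mean() + pseudocount
    if denom == 0:
        raise ValueError("control mean plus pseudocount is zero")
    return (case_value + pseudocount) / denom


def compute_btif(cnr: float, p_gene: float, low: float = 0.66,
                 high: float = 1.5, alpha: float = 0.05) -> int:
    """Beyond-tolerance-interval flag.

    1 iff the gene is significantly outside the control tolerance interval
    (p_gene < alpha, strict) *and* its CNR lies outside (low, high) — i.e.
    strictly below ``low`` or strictly above ``high``.
    """
    if not (0 < low < 1 < high):
        raise ValueError("need 0 < low < 1 < high")
    return int(p_gene < alpha and (cnr < low or cnr > high))


def gene_tolerance_p(case_value: float, control_values: Sequence[float],
                     pseudocount: float = 0.0) -> float:
    """Two-sided Gaussian tail probability of a case value under the controls.

    A normal distribution is fitted to log(control + c); the returned value
    is P(|Z| >= |z|) for the case value's z-score.  A degenerate control
    group (zero spread) yields 1.0 when the case equals the constant and 0.0
    otherwise.
    """
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least two control values")
    logc = np.log(controls + pseudocount)
    mu, sd = logc.mean(), logc.std(ddof=1)
    x = math.log(case_value + pseudocount)
    if sd == 0:
        return 1.0 if x == mu else 0.0
    return 2.0 * stats.norm.sf(abs(x - mu) / sd)


def compute_pas(pathway: Pathway, evidence: Mapping[str, GeneEvidence],
                log_base: float = 10.0) -> float:
    """Evaluate the PAS sum for one pathway.

    Members absent from ``evidence`` contribute 0 (they are counted by the
    coverage diagnostics of :func:`pas_profile`, not here).
    """
    total = 0.0
    for gene, arr in pathway.roles.items():
        ev = evidence.get(gene)
        if ev is None:
            continue
        if ev.cnr <= 0:
            raise ValueError(f"CNR must be positive for gene {gene!r}")
        total += arr * ev.btif * math.log(ev.cnr, log_base)
    return total


def compute_evidence(
    study: ExpressionStudy,
    case_id: str,
    control_ids: Sequence[str],
    config: PASConfig = PASConfig(),
) -> dict[str, GeneEvidence]:
    """Per-gene CNR/BTIF evidence for one case sample against a control group."""
    c = study.default_pseudocount() if config.pseudocount is None else config.pseudocount
    case = study.matrix[case_id].to_numpy(dtype=float)
    ctrl = study.matrix[list(control_ids)].to_numpy(dtype=float)
    cnr, p, btif = _evidence_arrays(case[:, None], ctrl, c, config)
    return {
        g: GeneEvidence(g, float(cnr[i, 0]), int(btif[i, 0]), float(p[i, 0]))
        for i, g in enumerate(study.genes)
    }


def _evidence_arrays(case: np.ndarray, ctrl: np.ndarray, pseudocount: float,
                     config: PASConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized CNR / tolerance-p / BTIF for genes x case-samples arrays."""
    if ctrl.shape[1] < 2:
        raise ValueError("need at least two control samples")
    denom = ctrl.mean(axis=1, keepdims=True) + pseudocount
    if (denom <= 0).any():
        raise ValueError("control mean plus pseudocount must be positive")
    cnr = (case + pseudocount) / denom
    logc = np.log(ctrl + pseudocount)
    mu = logc.mean(axis=1, keepdims=True)
    sd = logc.std(axis=1, ddof=1, keepdims=True)
    x = np.log(case + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(x - mu) / sd
    p = 2.0 * stats.norm.sf(z)
    degenerate = np.broadcast_to(sd == 0, p.shape)
    p = np.where(degenerate, np.where(x == mu, 1.0, 0.0), p)
    btif = (p < config.alpha) & ((cnr < config.cnr_low) | (cnr > config.cnr_high))
    return cnr, p, btif.astype(int)


@dataclass(frozen=True)
class PASProfile:
    """Pathway activation profile of a case group against a control group.

    ``sample_pas`` holds per-case-sample PAS (pathway x sample); the control
    samples' own PAS values (each scored against the whole control set,
    itself included) back the Gaussian per-sample p-values and the rank-sum
    group test.  ``coverage`` is the fraction of each pathway's members
    present in the expression matrix.
    """

    sample_pas: pd.DataFrame
    control_pas: pd.DataFrame
    group_pas: pd.Series
    p_sample: pd.DataFrame
    p_group: pd.Series
    fdr: pd.Series
    coverage: pd.Series
    config: PASConfig = field(default_factory=PASConfig)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sample_pas.index)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: group PAS, per-sample PAS columns, p, FDR, coverage."""
        out = pd.DataFrame({"pas_group": self.group_pas})
        for s in self.sample_pas.columns:
            out[f"pas:{s}"] = self.sample_pas[s]
        for s in self.p_sample.columns:
            out[f"p_sample:{s}"] = self.p_sample[s]
        out["p_group"] = self.p_group
        out["fdr"] = self.fdr
        out["coverage"] = self.coverage
        out.index.name = "pathway_id"
        return out


def _rank_sum_p(case: np.ndarray, ctrl: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p; 1.0 for all-tied input."""
    if np.all(case == case[0]) and np.all(ctrl == case[0]):
        return 1.0
    return float(stats.mannwhitneyu(case, ctrl, alternative="two-sided").pvalue)


def pas_profile(
    study: ExpressionStudy,
    db: PathwayDB,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    config: PASConfig = PASConfig(),
) -> PASProfile:
    """Score every pathway in ``db`` for each case sample against the controls.

    The case and control selections must be disjoint and non-empty, with at
    least two control samples.  Control samples are additionally scored
    against their own group (the whole control set as reference) to provide
    the null PAS distribution used by the per-sample Gaussian test and the
    group rank-sum test.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise ValueError("case and control selections must be non-empty")
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise ValueError(f"case and control selections overlap: {sorted(overlap)}")
    c = study.default_pseudocount() if config.pseudocount is None else config.pseudocount
    ctrl = study.matrix[control_ids].to_numpy(dtype=float)
    case = study.matrix[case_ids].to_numpy(dtype=float)

    # signed membership weights: pathways x genes
    gene_index = {g: i for i, g in enumerate(study.genes)}
    n_path, n_genes = len(db), len(study.genes)
    weights = np.zeros((n_path, n_genes))
    coverage = np.zeros(n_path)
    for k, pw in enumerate(db.pathways):
        hits = 0
        for g, arr in pw.roles.items():
            i = gene_index.get(g)
            if i is not None:
                weights[k, i] = arr
                hits += 1
        coverage[k] = hits / len(pw)

    log_scale = math.log(config.log_base)

    def score(block: np.ndarray) -> np.ndarray:
        cnr, _, btif = _evidence_arrays(block, ctrl, c, config)
        contrib = btif * (np.log(cnr) / log_scale)
        return weights @ contrib

    pas_case = score(case)
    pas_ctrl = score(ctrl)

    # Control PAS entering the rank-sum: scored leave-one-out by default so
    # case and control values are exchangeable under the null.  A control
    # sample inside its own reference shrinks both its CNR and its tolerance
    # z toward null, deflating control PAS spread and making the rank-sum
    # anti-conservative.  The reported control_pas keeps the whole-set
    # reference convention.
    if config.group_test_reference == "loo" and ctrl.shape[1] >= 3:
        cols = []
        for j in range(ctrl.shape[1]):
            ref = np.delete(ctrl, j, axis=1)
            cnr_j, _, btif_j = _evidence_arrays(ctrl[:, j:j + 1], ref, c, config)
            cols.append((weights @ (btif_j * (np.log(cnr_j) / log_scale)))[:, 0])
        pas_ctrl_test = np.column_stack(cols)
    else:
        pas_ctrl_test = pas_ctrl

    ids = db.pathway_ids
    sample_pas = pd.DataFrame(pas_case, index=ids, columns=case_ids)
    control_pas = pd.DataFrame(pas_ctrl, index=ids, columns=control_ids)

    # Gaussian per-sample p from the control PAS distribution
    mu = pas_ctrl.mean(axis=1, keepdims=True)
    sd = pas_ctrl.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(pas_case - mu) / sd
    p_sample = 2.0 * stats.norm.sf(z)
    degenerate = np.broadcast_to(sd == 0, p_sample.shape)
    p_sample = np.where(degenerate, np.where(pas_case == mu, 1.0, 0.0), p_sample)

    p_group = np.array([_rank_sum_p(pas_case[k], pas_ctrl_test[k]) for k in range(n_path)])
    fdr = multipletests(p_group, method="fdr_bh")[1]

    agg = np.mean if config.aggregator == "mean" else np.median
    group_pas = pd.Series(agg(pas_case, axis=1), index=ids)

    return PASProfile(
        sample_pas=sample_pas,
        control_pas=control_pas,
        group_pas=group_pas,
        p_sample=pd.DataFrame(p_sample, index=ids, columns=case_ids),
        p_group=pd.Series(p_group, index=ids),
        fdr=pd.Series(fdr, index=ids),
        coverage=pd.Series(coverage, index=ids),
        config=config,
    )


def group_pas_profile(
    study: ExpressionStudy,
    db: PathwayDB,
    arm: str,
    time_h: int,
    config: PASConfig = PASConfig(),
    reference: str = "matched",
) -> PASProfile:
    """Convenience wrapper: one arm/time-point case group against sham.

    ``reference='matched'`` uses sham samples at the same time point (the
    default baseline); ``'pooled'`` uses all sham samples.
    """
    case_ids = study.select(arm=arm, time_h=time_h)
    if reference == "matched":
        control_ids = study.select(arm="sham", time_h=time_h)
    elif reference == "pooled":
        control_ids = study.select(arm="sham")
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    if not control_ids:
        raise ValueError(f"no sham reference samples for {arm} at {time_h} h")
    return pas_profile(study, db, case_ids, control_ids, config)
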