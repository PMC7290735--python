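"""Expression matrices, normalization, differential expression and phase overlap.

The study design is a three-arm murine hepatectomy time course: sham
(laparotomy only), normal 68% hepatectomy (``nHx``) and extended 86%
hepatectomy (``eHx``), each sampled at 1, 8, 16, 32 and 48 h post surgery
with replicate animals.  Differential expression is always called per time
point against sham at the same time point, which serves as the baseline arm.

Candidate genes are those with ``|log2FC| >= 1`` and ``p <= 0.05`` (both
boundaries inclusive).  The two-group test is a Welch t-test on log2(x + c)
values; the pseudocount ``c`` is 1 for raw counts and half the smallest
nonzero value for pre-normalized input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ARMS = ("sham", "nHx", "eHx")
TIME_POINTS = (1, 8, 16, 32, 48)
PHASES = {"early": (1, 8), "late": (16, 32, 48)}

__all__ = [
    "ARMS",
    "TIME_POINTS",
    "PHASES",
    "ExpressionStudy",
    "DEResult",
    "load_expression",
    "normalize",
    "differential_expression",
    "phase_overlap",
]


@dataclass(frozen=True)
class ExpressionStudy:
    """A gene-by-sample expression matrix with aligned sample metadata.

    ``matrix`` holds non-negative finite values (raw counts or pre-normalized
    expression); ``meta`` has one row per matrix column with columns
    ``sample_id``, ``arm``, ``time_h``, ``replicate``.
    """

    matrix: pd.DataFrame
    meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        m, meta = self.matrix, self.meta
        if list(m.columns) != list(meta["sample_id"]):
            raise ValueError(
                "matrix columns and metadata sample_id must match in order; "
                f"matrix-only: {sorted(set(m.columns) - set(meta['sample_id']))}, "
                f"meta-only: {sorted(set(meta['sample_id']) - set(m.columns))}"
            )
        if m.index.duplicated().any():
            dup = m.index[m.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        values = m.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains NaN or infinite values")
        if (values < 0).any():
            raise ValueError("expression matrix contains negative values")
        bad_arm = set(meta["arm"]) - set(ARMS)
        if bad_arm:
            raise ValueError(f"unknown arm(s) {sorted(bad_arm)}; expected one of {ARMS}")
        key = meta[["arm", "time_h", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError(f"duplicate (arm, time_h, replicate): {key[key.duplicated()].tolist()}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def select(self, arm: str | None = None, time_h: int | None = None) -> list[str]:
        """Sample ids matching the given arm and/or time point."""
        mask = pd.Series(True, index=self.meta.index)
        if arm is not None:
            mask &= self.meta["arm"] == arm
        if time_h is not None:
            mask &= self.meta["time_h"] == time_h
        return list(self.meta.loc[mask, "sample_id"])

    def default_pseudocount(self) -> float:
        """Pseudocount convention: 1 for counts, half the smallest nonzero value otherwise."""
        if not self.normalized:
            return 1.0
        vals = self.matrix.to_numpy()
        nz = vals[vals > 0]
        return 0.5 * float(nz.min()) if nz.size else 1.0


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential expression for one (arm, time) vs sham contrast."""

    arm: str
    time_h: int
    table: pd.DataFrame  # index gene_id; columns log2fc, p_value, candidate
    lfc_threshold: float = 1.0
    alpha: float = 0.05

    @property
    def candidates(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["candidate"]])


def load_expression(matrix_path: str | Path, meta_path: str | Path,
                    normalized: bool = False) -> ExpressionStudy:
    """Load an expression study from a matrix TSV and a metadata TSV.

    Matrix: first column ``gene_id``, remaining columns one per sample.
    Metadata: columns ``sample_id``, ``arm``, ``time_h``, ``replicate``.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    required = {"sample_id", "arm", "time_h", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{meta_path}: missing metadata columns {sorted(missing)}")
    meta = meta.astype({"sample_id": str, "arm": str, "time_h": int, "replicate": int})
    # align column order to metadata order after verifying the same id sets
    if set(matrix.columns) != set(meta["sample_id"]):
        raise ValueError(
            "sample ids disagree between matrix and metadata; "
            f"matrix-only: {sorted(set(matrix.columns) - set(meta['sample_id']))}, "
            f"meta-only: {sorted(set(meta['sample_id']) - set(matrix.columns))}"
        )
    matrix = matrix[list(meta["sample_id"])]
    return ExpressionStudy(matrix, meta.reset_index(drop=True), normalized=normalized)


def normalize(study: ExpressionStudy, method: str = "cpm") -> ExpressionStudy:
    """Library-size normalization.

    ``cpm`` rescales every column to sum to 1e6 (counts per million);
    ``none`` returns the study unchanged apart from the ``normalized`` flag.
    """
    if study.normalized:
        raise ValueError("study is already normalized")
    if method == "none":
        return replace(study, normalized=True)
    if method != "cpm":
        raise ValueError(f"unknown normalization method {method!r}")
    sums = study.matrix.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero column(s): {zero}")
    return replace(study, matrix=study.matrix / sums * 1e6, normalized=True)


def _welch_log_test(case: np.ndarray, control: np.ndarray, pseudocount: float) -> np.ndarray:
    """Two-sided Welch t-test per gene on log2(x + c); returns p-values."""
    lc = np.log2(case + pseudocount)
    lk = np.log2(control + pseudocount)
    res = stats.ttest_ind(lc, lk, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance-in-both-groups genes: identical -> p 1, else Welch is fine
    both_const = (lc.std(axis=1) == 0) & (lk.std(axis=1) == 0)
    equal_means = np.isclose(lc.mean(axis=1), lk.mean(axis=1))
    p[both_const & equal_means] = 1.0
    p[both_const & ~equal_means] = 0.0
    return p


def differential_expression(
    study: ExpressionStudy,
    arm: str,
    time_h: int,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float | None = None,
    test: Callable[[np.ndarray, np.ndarray, float], np.ndarray] | None = None,
) -> DEResult:
    """Differential expression of ``arm`` vs sham at the same time point.

    log2FC = log2((mean_case + c) / (mean_sham + c)); candidates satisfy
    |log2FC| >= lfc_threshold and p <= alpha (inclusive thresholds).  The
    two-group test is pluggable via ``test`` (defaults to Welch on log2).
    """
    if arm == "sham":
        raise ValueError("contrast arm must differ from the sham baseline")
    case_ids = study.select(arm=arm, time_h=time_h)
    ctrl_ids = study.select(arm="sham", time_h=time_h)
    if not ctrl_ids:
        raise ValueError(f"no sham samples at {time_h} h")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"need >= 2 replicates per side at {time_h} h; "
            f"got {len(case_ids)} {arm} and {len(ctrl_ids)} sham"
        )
    c = study.default_pseudocount() if pseudocount is None else pseudocount
    case = study.matrix[case_ids].to_numpy(dtype=float)
    ctrl = study.matrix[ctrl_ids].to_numpy(dtype=float)
    log2fc = np.log2(case.mean(axis=1) + c) - np.log2(ctrl.mean(axis=1) + c)
    p = (test or _welch_log_test)(case, ctrl, c)
    candidate = (np.abs(log2fc) >= lfc_threshold) & (p <= alpha)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "candidate": candidate}, index=study.genes
    )
    return DEResult(arm=arm, time_h=time_h, table=table,
                    lfc_threshold=lfc_threshold, alpha=alpha)


def phase_overlap(results: Iterable[DEResult], phase: str | Sequence[int]) -> frozenset[str]:
    """Genes called candidate at *every* time point of a regeneration phase.

    ``phase`` is ``"early"`` (1, 8 h), ``"late"`` (16, 32, 48 h) or an
    explicit sequence of time points.  All requested time points must be
    present among ``results``.
    """
    times = PHASES[phase] if isinstance(phase, str) else tuple(phase)
    by_time = {r.time_h: r for r in results}
    missing = [t for t in times if t not in by_time]
    if missing:
        raise ValueError(f"missing DE results for time point(s) {missing}")
    sets = [by_time[t].candidates for t in times]
    return frozenset(frozenset.intersection(*sets))
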