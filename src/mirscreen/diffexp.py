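"""Per-miRNA two-group inference.

Normality screening (Shapiro-Wilk per probe per group, advisory only),
unpaired two-tailed t-tests (Welch by default, pooled-variance Student
selectable), Benjamini-Hochberg FDR adjustment and a ranked top-k table.

Sign convention: positive t means the case mean exceeds the control mean;
``direction`` ("up"/"down") is derived from that sign.  Effect sizes are
differences of glog-scale group means, not raw-scale ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, UndefinedValueError
from .preprocess import STAGE_NORMALIZED, ExpressionMatrix
from .simulate import CASE_LABEL, CONTROL_LABEL

__all__ = [
    "welch_ttest",
    "ttest_per_feature",
    "bh_adjust",
    "normality_screen",
    "build_de_table",
    "DEResult",
]


def _split_groups(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    case = matrix.values[:, matrix.labels == CASE_LABEL]
    control = matrix.values[:, matrix.labels == CONTROL_LABEL]
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise InsufficientDataError(
            f"need >=2 samples per group, got {case.shape[1]} cases / "
            f"{control.shape[1]} controls"
        )
    return case, control


def welch_ttest(
    case: np.ndarray, control: np.ndarray, method: str = "welch"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised row-wise two-sample t-test: (t, two-tailed p).

    Rows are features; columns samples.  Degenerate rows (zero variance in
    both groups, equal means) get t = 0, p = 1 by convention.
    """
    if method not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance rows handled below
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=(method == "pooled"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return t, p


def ttest_per_feature(
    matrix: ExpressionMatrix, method: str = "welch"
) -> pd.DataFrame:
    """Per-probe two-group t-test table (p_adjusted left unfilled).

    Columns: probe_id, mean_case, mean_control, delta (case - control on
    the normalized scale), direction, t_stat, p_value, degenerate.
    """
    case, control = _split_groups(matrix)
    t, p = welch_ttest(case, control, method=method)
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    delta = mean_case - mean_control
    return pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "delta": delta,
            "direction": np.where(delta >= 0, "up", "down"),
            "t_stat": t,
            "p_value": p,
            "degenerate": (t == 0.0) & (p == 1.0) & (delta == 0.0),
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity by a
    cumulative minimum from the largest rank, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise UndefinedValueError("bh_adjust expects a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise UndefinedValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normality_screen(
    matrix: ExpressionMatrix, alpha: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Shapiro-Wilk normality check per probe per group (advisory only).

    A probe passes if both groups pass at ``alpha``; constant (zero
    variance) probes fail as degenerate.  Returns the per-probe flag table
    and the overall passing fraction; nothing downstream is gated on it.
    """
    case = matrix.values[:, matrix.labels == CASE_LABEL]
    control = matrix.values[:, matrix.labels == CONTROL_LABEL]
    if case.shape[1] < 3 or control.shape[1] < 3:
        raise InsufficientDataError("Shapiro-Wilk needs >=3 samples per group")

    def group_pass(block: np.ndarray) -> np.ndarray:
        out = np.zeros(block.shape[0], dtype=bool)
        for i, row in enumerate(block):
            if np.ptp(row) == 0.0:
                continue  # degenerate: fail
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pval = stats.shapiro(row).pvalue
            out[i] = bool(np.isfinite(pval) and pval > alpha)
        return out

    pass_case = group_pass(case)
    pass_control = group_pass(control)
    table = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "pass_case": pass_case,
            "pass_control": pass_control,
            "passes": pass_case & pass_control,
        }
    )
    return table, float(table["passes"].mean())


@dataclass
class DEResult:
    """Ranked differential-expression table plus significance counts."""

    table: pd.DataFrame
    n_probes: int
    n_significant_unadjusted: int
    n_significant_adjusted: int
    alpha: float
    method: str

    def summary(self) -> str:
        lines = [
            f"Differential expression ({self.method} t-test, "
            f"Benjamini-Hochberg adjustment)",
            f"  probes tested:              {self.n_probes}",
            f"  p < {self.alpha:g} unadjusted:      {self.n_significant_unadjusted}",
            f"  adjusted p < {self.alpha:g}:        {self.n_significant_adjusted}",
            "",
            self.table.head(10).to_string(index=False),
        ]
        return "\n".join(lines)


def build_de_table(
    matrix: ExpressionMatrix,
    top_k: int = 30,
    method: str = "welch",
    alpha: float = 0.05,
) -> DEResult:
    """Full DE analysis, ranked by ascending p and truncated to ``top_k``.

    Ties broken by larger |t| first, then probe_id lexicographically, so
    tables are deterministic.  The returned counts cover all probes, not
    just the reported rows.
    """
    if matrix.stage != STAGE_NORMALIZED:
        raise UndefinedValueError("build_de_table expects a normalized matrix")
    table = ttest_per_feature(matrix, method=method)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    n_unadj = int((table["p_value"] < alpha).sum())
    n_adj = int((table["p_adjusted"] < alpha).sum())

    table["abs_t"] = table["t_stat"].abs()
    table = table.sort_values(
        ["p_value", "abs_t", "probe_id"], ascending=[True, False, True]
    ).drop(columns=["abs_t", "degenerate"])
    table["rank"] = np.arange(1, len(table) + 1)

    if top_k > len(table):
        warnings.warn(
            f"top_k={top_k} exceeds the number of probes ({len(table)}); clipping",
            stacklevel=2,
        )
        top_k = len(table)
    return DEResult(
        table=table.head(top_k).reset_index(drop=True),
        n_probes=len(matrix.probe_ids),
        n_significant_unadjusted=n_unadj,
        n_significant_adjusted=n_adj,
        alpha=alpha,
        method=method,
    )
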