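"""Relative expression from qRT-PCR Ct tables, and its link to barrier strength.

Expression of the silk barrier gene (*Tcb1-f/PME38*) is measured against a
tubulin reference by the comparative-Ct method with amplification efficiency
assumed exactly 2: relative expression = 2^(Ct_reference - Ct_target).
Measurements follow the 3 biological x 3 technical replicate design;
technical replicates are averaged within each biological replicate first,
and the mean and standard error are taken over biological replicates.

The association analysis pairs per-line expression summaries with measured
barrier strengths and reports a Spearman rank correlation, plus which
below-threshold lines behave as barrier-less (BS ~ 1) — the
expression-threshold picture of epigenetically silenced lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "ExpressionSummary",
    "relative_expression",
    "summarize",
    "summarize_table",
    "expression_barrier_association",
    "read_ct_table",
]

CT_COLUMNS = ["sample_id", "line_name", "gene", "biological_rep",
              "technical_rep", "ct"]


@dataclass(frozen=True)
class ExpressionSummary:
    """Per-line relative expression (target vs reference) with its SEM."""

    line_name: str
    relative_expression: float
    sem: float
    n_biological: int


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Comparative-Ct relative expression, 2^(Ct_ref - Ct_target).

    Equal Cts give 1.0; each cycle the target leads the reference halves
    expression, each cycle it lags doubles it.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_reference - ct_target)


def summarize(measurements: pd.DataFrame, reference: str = "reference") -> ExpressionSummary:
    """Summarize one line's Ct measurements into relative expression +/- SEM.

    ``measurements`` holds CtMeasurement rows for a single line (columns
    ``gene``, ``biological_rep``, ``ct`` at minimum; ``gene`` is ``"target"``
    or the reference gene name).  Undetermined Cts (NaN) are dropped as
    missing.  Technical replicates are averaged within biological replicate;
    the per-biological-replicate delta-Ct gives a relative expression, and
    mean and SEM are taken over biological replicates (ddof=1).
    """
    lines = measurements["line_name"].unique()
    if len(lines) != 1:
        raise ValueError(f"expected one line, got {list(lines)}")
    clean = measurements.dropna(subset=["ct"])
    mean_ct = (
        clean.groupby(["gene", "biological_rep"])["ct"].mean().unstack("gene")
    )
    target_col = "target"
    ref_cols = [c for c in mean_ct.columns if c != target_col]
    if target_col not in mean_ct.columns or not ref_cols:
        raise ValueError("need Ct rows for both the target and a reference gene")
    if len(ref_cols) > 1:
        raise ValueError(f"multiple reference genes found: {ref_cols}")
    paired = mean_ct.dropna(subset=[target_col, ref_cols[0]])
    if len(paired) < 2:
        raise ValueError("need >= 2 complete biological replicates")
    rel = 2.0 ** (paired[ref_cols[0]] - paired[target_col])
    return ExpressionSummary(
        line_name=str(lines[0]),
        relative_expression=float(rel.mean()),
        sem=float(rel.std(ddof=1) / math.sqrt(len(rel))),
        n_biological=int(len(rel)),
    )


def summarize_table(ct_table: pd.DataFrame) -> list[ExpressionSummary]:
    """Summarize every line in a Ct table (grouped by ``line_name``)."""
    return [
        summarize(group) for _, group in ct_table.groupby("line_name", sort=True)
    ]


def expression_barrier_association(
    summaries: list[ExpressionSummary],
    strengths: dict[str, float],
    threshold: float | None = None,
    no_barrier_band: float = 0.25,
) -> dict:
    """Rank correlation between expression level and barrier strength.

    ``strengths`` maps line name to measured barrier strength; every summary
    must be paired.  Returns the Spearman coefficient, its p-value, and —
    when an expression ``threshold`` is given — which below-threshold lines
    have barrier strength within ``no_barrier_band`` of 1.0 (the expected
    no-barrier value) and which violate that expectation.
    """
    unpaired = [s.line_name for s in summaries if s.line_name not in strengths]
    if unpaired:
        raise ValueError(f"lines without a barrier strength: {unpaired}")
    expr = np.array([s.relative_expression for s in summaries])
    bs = np.array([strengths[s.line_name] for s in summaries])
    rho, pval = stats.spearmanr(expr, bs)
    report: dict = {
        "spearman_rho": float(rho),
        "p_value": float(pval),
        "n_lines": len(summaries),
    }
    if threshold is not None:
        below = [s for s in summaries if s.relative_expression < threshold]
        report["below_threshold"] = {
            s.line_name: {
                "barrier_strength": strengths[s.line_name],
                "no_barrier": abs(strengths[s.line_name] - 1.0) <= no_barrier_band,
            }
            for s in below
        }
    return report


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with the CtMeasurement columns; validates structure."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"].dropna() <= 0).any():
        raise ValueError("Ct values must be positive")
    return df
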