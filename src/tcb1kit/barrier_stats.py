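"""Ear-scoring statistics for crossing-barrier experiments.

A mixed-pollination experiment yields, per female, a pair of ears scored for
the two donor classes: the test ear (the female whose barrier is in
question) and a control ``tcb1`` ear pollinated by the same mix.  The pair
forms a 2x2 table — donor class x ear — on which a two-tailed Fisher exact
test asks whether the test ear accepted ``tcb1``-donor pollen at the same
rate as the control.  Ears are classified into tiers at the p < 0.0001
(strong) and 0.0001 <= p < 0.01 (partial) thresholds, counting significance
only in the barrier direction (fewer ``tcb1``-sired kernels on the test
ear).

Barrier strength is the odds ratio of compatible:incompatible kernels
between the two ears: 1.0 means no barrier, larger values a stronger one.

Two further statistics serve mapping and screening: exact cosegregation of a
presence/absence marker with the barrier phenotype across recombinants, and
exact-binomial outlier flagging of ears in the open-pollinated screen whose
sugary fraction exceeds the r/2 null (Bonferroni-corrected over ears).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pollination_sim import EarCount

__all__ = [
    "TwoByTwoTable",
    "EarClassification",
    "exact_test_2x2",
    "barrier_strength",
    "classify_ear",
    "cosegregation",
    "flag_screen_outliers",
]

STRONG_P = 1e-4
PARTIAL_P = 1e-2


@dataclass(frozen=True)
class TwoByTwoTable:
    """Test-vs-control kernel classification table.

    ``a``/``b``: yellow (compatible-donor) / purple (tcb1-donor) kernels on
    the test ear; ``c``/``d``: the same on the control ear.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if any(x < 0 for x in (self.a, self.b, self.c, self.d)):
            raise ValueError("table counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_ears(cls, test: EarCount, control: EarCount) -> "TwoByTwoTable":
        return cls(test.n_yellow, test.n_purple, control.n_yellow, control.n_purple)


@dataclass(frozen=True)
class EarClassification:
    """Outcome of the two-tier significance classification of one ear pair."""

    p_value: float
    tier: str  # "strong" | "partial" | "none"
    barrier_strength: float


def exact_test_2x2(table: TwoByTwoTable) -> float:
    """Two-tailed Fisher exact test on a 2x2 table.

    With all margins fixed, the p-value sums the hypergeometric point
    probabilities of every table at least as extreme as (point probability
    no larger than) the observed one.
    """
    if table.total == 0:
        raise ValueError("cannot test an empty table")
    res = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(min(res.pvalue, 1.0))


def barrier_strength(
    test: EarCount, control: EarCount, correction: float = 0.5
) -> float:
    """Barrier strength: odds ratio of compatible:tcb1 kernels, test vs control.

    BS = (yellow_test/purple_test) / (yellow_ctrl/purple_ctrl); 1.0 means the
    test ear accepted the two pollen classes in the same proportion as the
    control — no barrier.  When any cell is zero the Haldane-Anscombe
    ``correction`` (default 0.5) is added to all four cells.
    """
    if correction < 0:
        raise ValueError("correction must be nonnegative")
    if test.n_total == 0 and control.n_total == 0:
        raise ValueError("both ears are empty")
    cells = [test.n_yellow, test.n_purple, control.n_yellow, control.n_purple]
    if any(c == 0 for c in cells):
        cells = [c + correction for c in cells]
    a, b, c, d = cells
    return (a / b) / (c / d)


def classify_ear(test: EarCount, control: EarCount) -> EarClassification:
    """Two-tier classification of a test/control ear pair.

    Significance counts only in the barrier direction: the ``tcb1``-sired
    (purple) fraction must be lower on the test ear than on the control.
    Tiers: strong at p < 1e-4, partial at 1e-4 <= p < 0.01, else none.
    """
    table = TwoByTwoTable.from_ears(test, control)
    p = exact_test_2x2(table)
    test_frac = test.n_purple / test.n_total if test.n_total else np.nan
    ctrl_frac = control.n_purple / control.n_total if control.n_total else np.nan
    barrier_direction = test_frac < ctrl_frac
    if barrier_direction and p < STRONG_P:
        tier = "strong"
    elif barrier_direction and p < PARTIAL_P:
        tier = "partial"
    else:
        tier = "none"
    return EarClassification(p, tier, barrier_strength(test, control))


def cosegregation(
    marker_present: Sequence[bool], barrier_phenotype: Sequence[bool]
) -> tuple[int, int, float]:
    """Concordance of a presence/absence marker with the barrier phenotype.

    For recombinant plants scored for both a candidate-gene marker (e.g. a
    dCAPS assay) and the female barrier, returns (n_concordant,
    n_discordant, p) where p is the two-tailed Fisher exact test on the
    marker x phenotype 2x2 table.  Perfect cosegregation of 6 barrier
    carriers and 9 non-carriers gives p = 1/5005.
    """
    if len(marker_present) != len(barrier_phenotype):
        raise ValueError("marker and phenotype lists differ in length")
    marker = np.asarray(marker_present, dtype=bool)
    pheno = np.asarray(barrier_phenotype, dtype=bool)
    n_concordant = int(np.sum(marker == pheno))
    n_discordant = int(np.sum(marker != pheno))
    table = TwoByTwoTable(
        int(np.sum(marker & pheno)),
        int(np.sum(marker & ~pheno)),
        int(np.sum(~marker & pheno)),
        int(np.sum(~marker & ~pheno)),
    )
    return n_concordant, n_discordant, exact_test_2x2(table)


def flag_screen_outliers(
    ears: pd.DataFrame,
    null_fraction: float = 0.03,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag screen ears whose sugary fraction exceeds the barrier null.

    Under an intact barrier the sugary fraction is r/2 (``null_fraction``).
    Each ear gets a one-sided exact binomial tail p = P(X >= observed) under
    Binomial(n_kernels, null_fraction); an ear is flagged when p is below
    the Bonferroni-corrected threshold alpha / n_ears.

    ``ears`` needs columns ``ear_id``, ``n_kernels``, ``n_sugary``; returns
    a copy with ``p_value`` and ``flagged`` columns appended.
    """
    if not 0.0 < null_fraction < 1.0:
        raise ValueError("null_fraction must lie in (0, 1)")
    n_ears = len(ears)
    out = ears.copy()
    pvals = [
        stats.binomtest(int(k), int(n), null_fraction, alternative="greater").pvalue
        for k, n in zip(ears["n_sugary"], ears["n_kernels"])
    ]
    out["p_value"] = pvals
    out["flagged"] = out["p_value"] < (alpha / n_ears if n_ears else np.nan)
    return out
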