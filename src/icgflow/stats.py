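"""Agreement statistics between two raters or methods over categorical labels.

Used to compare the optical-flow direction verdicts with a reference reading
(in the clinical setting, the microscope's commercial software): Cohen's
kappa with the conventional interpretation bands, raw percent agreement, and
the paired t-test / normal Q-Q check applied to delay-time differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "PairedTResult",
    "QQSummary",
    "cohen_kappa",
    "percent_agreement",
    "paired_t_test",
    "normality_check",
]

#: Interpretation bands for kappa, lower-edge inclusive on the named range.
KAPPA_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (float("inf"), "almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value onto the slight/fair/moderate/substantial/almost-perfect bands."""
    for upper, name in KAPPA_BANDS:
        if kappa <= upper:
            return name
    return "almost perfect"  # pragma: no cover


@dataclass
class ContingencyTable:
    """k x k count matrix; rows = method A labels, columns = method B labels."""

    counts: np.ndarray
    row_labels: Sequence[str] | None = None
    col_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contingency table must be square")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be nonnegative numbers")
        if self.counts.sum() <= 0:
            raise ValueError("contingency table total must be positive")
        k = self.counts.shape[0]
        if self.row_labels is None:
            self.row_labels = [f"cat{i}" for i in range(k)]
        if self.col_labels is None:
            self.col_labels = list(self.row_labels)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_labels(cls, a: Sequence, b: Sequence) -> "ContingencyTable":
        """Build the table from two aligned label sequences."""
        if len(a) != len(b):
            raise ValueError("label sequences must have equal length")
        cats = sorted(set(a) | set(b), key=str)
        idx = {c: i for i, c in enumerate(cats)}
        counts = np.zeros((len(cats), len(cats)), dtype=int)
        for x, y in zip(a, b):
            counts[idx[x], idx[y]] += 1
        return cls(counts, [str(c) for c in cats])

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        """Read a table written as CSV with a header row and label column."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels).to_csv(path)


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    interpretation: str
    se: float | None = None  # Fleiss-style asymptotic standard error under H0

    def as_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "p_observed": self.p_observed,
            "p_expected": self.p_expected,
            "interpretation": self.interpretation,
            "se": self.se,
        }


def cohen_kappa(table: ContingencyTable | np.ndarray) -> KappaResult:
    """Chance-corrected agreement kappa = (Po - Pe) / (1 - Pe).

    Po is the observed proportion of concordant pairs (diagonal mass) and Pe
    the agreement expected from the marginals alone. Degenerate marginals
    with Pe = 1 leave kappa undefined and raise ``ValueError``.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(table)
    c = table.counts.astype(float)
    n = c.sum()
    po = float(np.trace(c) / n)
    row = c.sum(axis=1) / n
    col = c.sum(axis=0) / n
    pe = float(np.dot(row, col))
    if pe >= 1.0 - 1e-15:
        raise ValueError("expected agreement is 1 (degenerate marginals); kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    # asymptotic SE under independence (reported, not used as a gate)
    se0 = math.sqrt(max(pe + pe**2 - float(np.sum(row * col * (row + col))), 0.0)) / (
        (1.0 - pe) * math.sqrt(n)
    )
    return KappaResult(kappa, po, pe, interpret_kappa(kappa), se0)


def percent_agreement(table: ContingencyTable | np.ndarray) -> float:
    """Fraction of concordant cases: sum of the diagonal over the total."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(table)
    return float(np.trace(table.counts) / table.n)


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p, "mean": self.mean,
            "sd": self.sd, "ci95": [self.ci_low, self.ci_high],
        }


def paired_t_test(differences: Sequence[float]) -> PairedTResult:
    """Two-sided one-sample t-test of mean(differences) = 0.

    Implements the textbook formula directly: t = mean / (sd / sqrt(n)),
    df = n - 1, CI = mean +- t_{0.975,df} * se. A zero-variance sample has
    an undefined statistic and raises ``ValueError``.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise ValueError("zero standard deviation: t statistic undefined")
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2.0 * _sps.t.sf(abs(t), df))
    tcrit = float(_sps.t.ppf(0.975, df))
    return PairedTResult(t, df, p, mean, sd, mean - tcrit * se, mean + tcrit * se)


@dataclass
class QQSummary:
    theoretical: np.ndarray
    sample: np.ndarray
    correlation: float
    flagged: bool = False


def normality_check(differences: Sequence[float]) -> QQSummary:
    """Normal Q-Q summary: ordered sample vs standard-normal plotting positions.

    Plotting positions follow Blom's rule (i - 3/8) / (n + 1/4); the returned
    correlation is the usual Q-Q plot straightness measure. Constant input
    leaves the correlation undefined and is returned flagged with NaN.
    """
    d = np.sort(np.asarray(differences, dtype=float))
    n = d.size
    if n < 3:
        raise ValueError("normality check needs at least 3 values")
    pos = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = _sps.norm.ppf(pos)
    if np.ptp(d) == 0:
        return QQSummary(theo, d, float("nan"), flagged=True)
    r = float(np.corrcoef(theo, d)[0, 1])
    return QQSummary(theo, d, r)
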