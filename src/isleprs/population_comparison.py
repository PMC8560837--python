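"""Between-cohort comparisons of control score distributions and allele frequencies."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortTable, DosageMatrix
from .errors import DegenerateInputError
from .prs_engine import control_raf

__all__ = ["FreqComparison", "welch_t_test", "raf_chi2", "snp_comparison_report", "score_comparison_report"]


@dataclass
class FreqComparison:
    """Risk-allele frequency contrast for one SNP between two control samples."""

    rsid: str
    cohort_a: str
    cohort_b: str
    raf_a: float
    raf_b: float
    allele_counts: np.ndarray  # 2x2: rows risk/other, cols cohort a/b
    chi2: float
    p: float

    def __post_init__(self):
        self.allele_counts = np.asarray(self.allele_counts, dtype=int)
        if self.allele_counts.shape != (2, 2):
            raise ValueError("allele_counts must be 2x2")
        if self.chi2 < 0.0:
            raise ValueError("chi2 must be non-negative")


def welch_t_test(z_a: np.ndarray, z_b: np.ndarray) -> tuple[float, float, float]:
    """Two-sample unequal-variance t test.

    Returns ``(t, df, p)`` with the Welch statistic, Welch-Satterthwaite
    degrees of freedom and the two-sided p-value.
    """
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateInputError("both samples have zero variance")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def raf_chi2(
    dosages_a: DosageMatrix,
    table_a: CohortTable,
    dosages_b: DosageMatrix,
    table_b: CohortTable,
    rsid: str,
) -> FreqComparison:
    """Pearson chi-squared contrast of control risk-allele frequencies for one SNP.

    Allele "counts" are the rounded expected counts ``2n * RAF`` (dosages may
    be fractional post-imputation); the test is the df=1 Pearson chi-squared
    on the 2x2 risk/other x cohort table, without continuity correction.
    """
    raf_a = control_raf(dosages_a, table_a, rsid)
    raf_b = control_raf(dosages_b, table_b, rsid)
    na = 2 * table_a.n_controls
    nb = 2 * table_b.n_controls
    table = np.array(
        [
            [round(na * raf_a), round(nb * raf_b)],
            [na - round(na * raf_a), nb - round(nb * raf_b)],
        ],
        dtype=int,
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateInputError(f"{rsid}: zero margin in the 2x2 allele table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return FreqComparison(
        rsid=rsid,
        cohort_a=table_a.name,
        cohort_b=table_b.name,
        raf_a=raf_a,
        raf_b=raf_b,
        allele_counts=table,
        chi2=float(chi2),
        p=float(p),
    )


def snp_comparison_report(comparisons: list[FreqComparison]) -> pd.DataFrame:
    """Per-SNP TSV-shaped report with a convenience Bonferroni column."""
    df = pd.DataFrame(
        [
            {
                "rsid": c.rsid,
                "cohort_a": c.cohort_a,
                "cohort_b": c.cohort_b,
                "raf_a": c.raf_a,
                "raf_b": c.raf_b,
                "chi2": c.chi2,
                "p": c.p,
            }
            for c in comparisons
        ]
    )
    if not df.empty:
        df["p_bonferroni"] = np.minimum(df["p"] * len(df["rsid"].unique()), 1.0)
    return df


def score_comparison_report(rows: list[dict]) -> pd.DataFrame:
    cols = ["subset", "cohort_a", "n_a", "mean_a", "cohort_b", "n_b", "mean_b", "t", "df", "p"]
    return pd.DataFrame(rows, columns=cols)
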