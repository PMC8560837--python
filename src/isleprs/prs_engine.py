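"""Polygenic score computation and cross-cohort standardisation."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import CohortTable, DosageMatrix
from .errors import DegenerateInputError
from .snp_panel import Panel

__all__ = ["ScoreVector", "score", "pooled_zscore", "control_raf", "write_scores"]


@dataclass
class ScoreVector:
    """Per-individual risk scores for one cohort and one panel subset."""

    individual_ids: np.ndarray
    raw: np.ndarray
    cohort: str
    subset_name: str
    z: np.ndarray | None = None

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.individual_ids) != len(self.raw):
            raise ValueError("ids and raw scores length mismatch")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if len(self.z) != len(self.raw):
                raise ValueError("z length mismatch")

    def __len__(self) -> int:
        return len(self.raw)


def score(dosages: DosageMatrix, panel: Panel, subset_name: str = "full") -> ScoreVector:
    """Weighted dosage sum: ``raw_i = sum_j ln(OR_j) * d_ij`` over the subset.

    Weights are natural-log odds ratios; the score is an unnormalised sum.
    When the panel designates an HLA tag, the "full" score is computed as
    the sum of the "no_hla" and "hla_only" scores so the decomposition
    ``full = no_hla + hla_only`` holds bit-exactly, not merely to rounding.
    Every subset SNP must be present in the dosage matrix (hard failure, no
    silent imputation).
    """
    if subset_name == "full" and panel.hla_tag is not None:
        parts = score(dosages, panel, "no_hla").raw + score(dosages, panel, "hla_only").raw
        return ScoreVector(dosages.individual_ids, parts, dosages.cohort, "full")
    idx = panel.subsets[subset_name] if subset_name in panel.subsets else None
    if idx is None:
        raise KeyError(f"unknown subset {subset_name!r}")
    rsids = [panel.snps[i].rsid for i in idx]
    cols = dosages.snp_indices(rsids)
    weights = panel.log_ors[idx]
    raw = dosages.dosages[:, cols] @ weights
    return ScoreVector(dosages.individual_ids, raw, dosages.cohort, subset_name)


def pooled_zscore(scores: list[ScoreVector]) -> list[ScoreVector]:
    """Standardise raw scores against the pooled mean/SD of all supplied cohorts.

    The pool is the union of every individual in every supplied ScoreVector;
    per-cohort z means may therefore differ from 0. Population SD (ddof=0).
    """
    if not scores:
        raise ValueError("no score vectors supplied")
    subsets = {s.subset_name for s in scores}
    if len(subsets) != 1:
        raise ValueError(f"cannot pool different subsets: {sorted(subsets)}")
    raws = np.concatenate([s.raw for s in scores])
    if len(raws) < 2:
        raise DegenerateInputError("pooled standardisation needs at least 2 individuals")
    mu = raws.mean()
    sd = raws.std(ddof=0)
    if sd == 0.0:
        raise DegenerateInputError("zero pooled standard deviation")
    return [replace(s, z=(s.raw - mu) / sd) for s in scores]


def control_raf(dosages: DosageMatrix, cohort_table: CohortTable, rsid: str) -> float:
    """Risk-allele frequency among controls: sum of control dosages / (2 * n_controls)."""
    if not np.array_equal(dosages.individual_ids, cohort_table.ids):
        raise ValueError("dosage matrix and cohort table are not row-aligned")
    mask = cohort_table.control_mask
    n = int(mask.sum())
    if n == 0:
        raise DegenerateInputError(f"cohort {cohort_table.name!r} has no controls")
    return float(dosages.snp_column(rsid)[mask].sum() / (2.0 * n))


def write_scores(scores: list[ScoreVector], path) -> None:
    """Write one or more score vectors as TSV ``id cohort subset raw z``."""
    frames = [
        pd.DataFrame(
            {
                "id": s.individual_ids,
                "cohort": s.cohort,
                "subset": s.subset_name,
                "raw": s.raw,
                "z": s.z if s.z is not None else np.nan,
            }
        )
        for s in scores
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
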