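"""Shared data containers: per-cohort dosage matrices and phenotype tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingSnpError

_DOSAGE_TOL = 1e-9

PHENOTYPE_COLUMNS = ["id", "status", "age", "sex", "pc1", "pc2"]


@dataclass
class DosageMatrix:
    """Individuals x SNPs expected risk-allele counts for one cohort.

    ``dosages[i, j]`` is the expected count (in [0, 2]) of the panel's risk
    allele for individual ``individual_ids[i]`` at SNP ``snp_ids[j]``.
    Fractional values are allowed (post-imputation dosages).
    """

    individual_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    cohort: str = ""
    _snp_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match id vectors")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids in dosage matrix")
        if len(set(self.individual_ids)) != n:
            raise ValueError(f"duplicate individual ids in cohort {self.cohort!r}")
        lo, hi = self.dosages.min(initial=0.0), self.dosages.max(initial=0.0)
        if lo < -_DOSAGE_TOL or hi > 2.0 + _DOSAGE_TOL:
            raise ValueError(f"dosages outside [0, 2]: min={lo}, max={hi}")
        self._snp_index = {rsid: j for j, rsid in enumerate(self.snp_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_column(self, rsid: str) -> np.ndarray:
        try:
            return self.dosages[:, self._snp_index[rsid]]
        except KeyError:
            raise MissingSnpError(f"SNP {rsid!r} not present in cohort {self.cohort!r}") from None

    def snp_indices(self, rsids) -> np.ndarray:
        missing = [r for r in rsids if r not in self._snp_index]
        if missing:
            raise MissingSnpError(
                f"SNP(s) {', '.join(map(repr, missing))} not present in cohort {self.cohort!r}"
            )
        return np.array([self._snp_index[r] for r in rsids], dtype=int)


@dataclass
class CohortTable:
    """Per-individual phenotype and covariates, row-aligned with a DosageMatrix."""

    ids: np.ndarray
    status: np.ndarray  # 0 control / 1 case
    age: np.ndarray
    sex: np.ndarray  # 'F' / 'M'
    pc1: np.ndarray
    pc2: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.status = np.asarray(self.status, dtype=int)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.pc2 = np.asarray(self.pc2, dtype=float)
        n = len(self.ids)
        for name in ("status", "age", "sex", "pc1", "pc2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if not set(np.unique(self.status)) <= {0, 1}:
            raise ValueError("status must be 0/1")
        bad = set(np.unique(self.sex)) - {"F", "M"}
        if bad:
            raise ValueError(f"sex must be 'F'/'M', got {bad}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    @property
    def control_mask(self) -> np.ndarray:
        return self.status == 0

    @property
    def sex_male(self) -> np.ndarray:
        return (self.sex == "M").astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "status": self.status,
                "age": self.age,
                "sex": self.sex,
                "pc1": self.pc1,
                "pc2": self.pc2,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "") -> "CohortTable":
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing column(s) {missing}")
        return cls(
            ids=df["id"].to_numpy(dtype=object),
            status=df["status"].to_numpy(),
            age=df["age"].to_numpy(),
            sex=df["sex"].to_numpy(dtype=object),
            pc1=df["pc1"].to_numpy(),
            pc2=df["pc2"].to_numpy(),
            name=name,
        )

    def subset(self, mask_or_ids) -> "CohortTable":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            m = mask_or_ids
        else:
            wanted = set(mask_or_ids)
            m = np.array([i in wanted for i in self.ids])
        if not m.any():
            raise DegenerateInputError("subset selects no individuals")
        return CohortTable(
            self.ids[m], self.status[m], self.age[m], self.sex[m], self.pc1[m], self.pc2[m], self.name
        )
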