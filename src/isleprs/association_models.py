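"""Case/control models and their evaluation statistics.

Implements the per-cohort modelling stages: the Gaussian-error group
comparison of z-scores, genomic-kinship estimation and unrelated-subset
filtering, covariate-adjusted logistic regression, Nagelkerke pseudo-R2,
ROC/AUC, inverse-variance meta-analysis across cohorts, and genotype PCA
for ancestry covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._pooling import pool_fixed_effect
from .core import CohortTable, DosageMatrix
from .errors import (
    CollinearityError,
    ConvergenceFailure,
    DegenerateInputError,
    SeparationError,
)
from .prs_engine import ScoreVector

logger = logging.getLogger(__name__)

COVARIATE_NAMES = ["age", "sex", "pc1", "pc2"]

#: kinship above which a pair counts as related
KINSHIP_THRESHOLD = 0.05

#: divergence guard for the logistic slope (separation heuristic)
_SEPARATION_BOUND = 50.0


@dataclass
class ModelFit:
    """One fitted case/control model; ``coefficient`` is the z-PRS effect."""

    coefficient: float
    se: float
    stat: float
    wald_p: float
    aic: float
    n_used: int
    model_kind: str  # "gaussian_identity" | "logistic"
    covariate_names: tuple[str, ...]
    loglik: float = float("nan")

    def __post_init__(self):
        if np.isfinite(self.se) and self.se <= 0.0:
            raise ValueError("standard error must be positive")

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * self.se
        return (self.coefficient - half, self.coefficient + half)


@dataclass
class EvalStats:
    nagelkerke_r2: float
    auc: float
    auc_se: float


@dataclass
class KinshipMatrix:
    individual_ids: np.ndarray
    kinship: np.ndarray
    method: str = "grm"

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.kinship = np.asarray(self.kinship, dtype=float)
        n = len(self.individual_ids)
        if self.kinship.shape != (n, n):
            raise ValueError("kinship matrix shape mismatch")
        if not np.allclose(self.kinship, self.kinship.T, atol=0.0):
            raise ValueError("kinship matrix must be exactly symmetric")


# ---------------------------------------------------------------------------
# Design-matrix plumbing


def _align(scores: ScoreVector, cohort: CohortTable) -> np.ndarray:
    if scores.z is None:
        raise ValueError("scores must be standardised (z is None)")
    if np.array_equal(scores.individual_ids, cohort.ids):
        return scores.z
    pos = {i: k for k, i in enumerate(scores.individual_ids)}
    try:
        idx = np.array([pos[i] for i in cohort.ids])
    except KeyError as e:
        raise ValueError(f"individual {e.args[0]!r} has no score") from None
    return scores.z[idx]


def _covariate_matrix(cohort: CohortTable) -> np.ndarray:
    return np.column_stack([cohort.age, cohort.sex_male, cohort.pc1, cohort.pc2])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # name columns implicated in the rank deficiency via near-zero R diagonal
    _, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    bad = [names[j] for j in np.where(d < 1e-8 * max(d.max(), 1.0))[0]]
    raise CollinearityError(f"singular design matrix; collinear column(s): {bad or names}")


# ---------------------------------------------------------------------------
# Gaussian group comparison


def gaussian_group_model(scores: ScoreVector, cohort: CohortTable) -> ModelFit:
    """Linear model ``z ~ status + age + sex + pc1 + pc2`` by least squares.

    The status coefficient is the covariate-adjusted case-control difference
    in mean z-score; its two-sided p comes from the t statistic.
    """
    if cohort.n_cases == 0 or cohort.n_controls == 0:
        raise DegenerateInputError(
            f"cohort {cohort.name!r}: need both cases and controls (no contrast)"
        )
    z = _align(scores, cohort)
    names = ["const", "status", *COVARIATE_NAMES]
    X = np.column_stack([np.ones(cohort.n), cohort.status.astype(float), _covariate_matrix(cohort)])
    _check_rank(X, names)
    res = sm.OLS(z, X).fit()
    return ModelFit(
        coefficient=float(res.params[1]),
        se=float(res.bse[1]),
        stat=float(res.tvalues[1]),
        wald_p=float(res.pvalues[1]),
        aic=float(res.aic),
        n_used=cohort.n,
        model_kind="gaussian_identity",
        covariate_names=tuple(COVARIATE_NAMES),
        loglik=float(res.llf),
    )


# ---------------------------------------------------------------------------
# Kinship and relatedness filtering


def kinship_estimate(dosages: DosageMatrix) -> KinshipMatrix:
    """Genomic-relationship kinship: phi_ij = (1/2m) sum_k (d_ik-2p_k)(d_jk-2p_k)/(2p_k(1-p_k)).

    ``p_k`` is the sample allele frequency. Self-kinship is ~0.5 and full
    siblings ~0.25. Monomorphic SNPs are dropped from the sum with a warning.
    """
    if dosages.n_individuals < 2:
        raise DegenerateInputError("kinship needs at least 2 individuals")
    d = dosages.dosages
    p = d.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0) & (d.var(axis=0) > 0.0)
    if not poly.all():
        logger.warning("kinship: dropping %d monomorphic SNP(s)", int((~poly).sum()))
    if not poly.any():
        raise DegenerateInputError("no polymorphic SNP for kinship estimation")
    dp = d[:, poly]
    pp = p[poly]
    zc = (dp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    m = zc.shape[1]
    phi = (zc @ zc.T) / (2.0 * m)
    phi = (phi + phi.T) / 2.0  # enforce exact symmetry against FP noise
    return KinshipMatrix(dosages.individual_ids, phi, method="grm")


def filter_unrelated(
    kinship: KinshipMatrix,
    threshold: float = KINSHIP_THRESHOLD,
    case_ids=None,
) -> list:
    """Greedy unrelated-subset selection with case protection.

    Iteratively removes the individual with the most pairwise kinships above
    ``threshold`` (ties: larger summed kinship to relatives, then lexicographic
    id) until no pair exceeds the threshold. Individuals in ``case_ids`` are
    protected: a case can only be removed on account of case-case pairs.
    Returns the retained ids in input order.
    """
    if threshold <= 0.0:
        raise ValueError("threshold must be > 0")
    ids = list(kinship.individual_ids)
    n = len(ids)
    cases = set(case_ids) if case_ids is not None else set()
    is_case = np.array([i in cases for i in ids])
    phi = kinship.kinship.copy()
    np.fill_diagonal(phi, 0.0)
    adj = phi > threshold

    alive = np.ones(n, dtype=bool)
    while True:
        deg_all = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg_all[~alive] = 0
        # controls count every related pair; cases only case-case pairs
        case_adj = adj & is_case[None, :]
        deg_case = (case_adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg = np.where(is_case, deg_case, deg_all)
        if deg.max() == 0:
            break
        cand = np.where(deg == deg.max())[0]
        if len(cand) > 1:
            ksum = np.array([(phi[i] * (adj[i] & alive)).sum() for i in cand])
            cand = cand[ksum == ksum.max()]
        victim = min(cand, key=lambda i: str(ids[i]))
        alive[victim] = False
    return [i for i, a in zip(ids, alive) if a]


# ---------------------------------------------------------------------------
# Logistic regression


def _fit_logit(y: np.ndarray, X: np.ndarray, names: list[str]) -> sm.Logit:
    _check_rank(X, names)
    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, disp=False)
    except PerfectSeparationError as e:
        raise SeparationError(f"perfect separation: {e}") from e
    except np.linalg.LinAlgError:
        # Newton can hit a singular Hessian on near-saturated fits; retry with
        # a gradient method before declaring failure.
        try:
            res = sm.Logit(y, X).fit(method="bfgs", maxiter=500, disp=False, gtol=1e-8)
        except (PerfectSeparationError, np.linalg.LinAlgError) as e:
            raise SeparationError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceFailure("logistic fit did not converge in 100 iterations")
    if np.abs(res.params).max() > _SEPARATION_BOUND:
        raise SeparationError(
            f"coefficient diverged beyond |{_SEPARATION_BOUND}|: likely separation"
        )
    return res


def logistic_fit(
    scores: ScoreVector,
    cohort: CohortTable,
    retained_ids=None,
) -> tuple[ModelFit, ModelFit]:
    """Fit ``status ~ z + age + sex + pc1 + pc2`` and the covariate-only null model.

    Maximum likelihood by Newton IRLS; SEs from the observed information.
    ``retained_ids`` restricts the fit (e.g. to the unrelated subset).
    Returns ``(fit, null_fit)``; the null fit's coefficient fields are NaN.
    """
    if retained_ids is not None:
        cohort = cohort.subset(retained_ids)
    if cohort.n_cases == 0 or cohort.n_controls == 0:
        raise DegenerateInputError(
            f"cohort {cohort.name!r}: both cases and controls required among retained ids"
        )
    z = _align(scores, cohort)
    y = cohort.status.astype(float)
    cov = _covariate_matrix(cohort)
    X_full = np.column_stack([np.ones(cohort.n), z, cov])
    X_null = np.column_stack([np.ones(cohort.n), cov])
    res = _fit_logit(y, X_full, ["const", "z", *COVARIATE_NAMES])
    res0 = _fit_logit(y, X_null, ["const", *COVARIATE_NAMES])
    fit = ModelFit(
        coefficient=float(res.params[1]),
        se=float(res.bse[1]),
        stat=float(res.tvalues[1]),
        wald_p=float(res.pvalues[1]),
        aic=float(res.aic),
        n_used=cohort.n,
        model_kind="logistic",
        covariate_names=tuple(COVARIATE_NAMES),
        loglik=float(res.llf),
    )
    null = ModelFit(
        coefficient=float("nan"),
        se=float("nan"),
        stat=float("nan"),
        wald_p=float("nan"),
        aic=float(res0.aic),
        n_used=cohort.n,
        model_kind="logistic",
        covariate_names=tuple(COVARIATE_NAMES),
        loglik=float(res0.llf),
    )
    return fit, null


# ---------------------------------------------------------------------------
# Evaluation statistics


def nagelkerke_r2(fit: ModelFit, null_fit: ModelFit, n: int) -> float:
    """Nagelkerke pseudo-R2 from full and nested-null log-likelihoods.

    R2_CS = 1 - exp((2/n)(l0 - l1)); R2_N = R2_CS / (1 - exp((2/n) l0)).
    """
    l1, l0 = fit.loglik, null_fit.loglik
    if not (np.isfinite(l1) and np.isfinite(l0)):
        raise ValueError("fits must carry log-likelihoods")
    if l0 > l1 + 1e-8:
        raise DegenerateInputError(
            f"null log-likelihood ({l0}) exceeds full ({l1}): models not nested on the same data"
        )
    r2_cs = 1.0 - np.exp((2.0 / n) * (l0 - l1))
    denom = 1.0 - np.exp((2.0 / n) * l0)
    if denom <= 0.0:
        raise DegenerateInputError("degenerate null likelihood; Nagelkerke undefined")
    return float(r2_cs / denom)


def roc_auc(predicted: np.ndarray, status: np.ndarray) -> tuple[float, float]:
    """AUC as the Mann-Whitney case-outranks-control probability, ties counted 1/2.

    SE by the Hanley-McNeil approximation.
    """
    predicted = np.asarray(predicted, dtype=float)
    status = np.asarray(status, dtype=int)
    n1 = int((status == 1).sum())
    n0 = int((status == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("ROC needs at least one case and one control")
    ranks = stats.rankdata(predicted)
    auc = (ranks[status == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(auc), float(np.sqrt(max(var, 0.0)))


def fixed_effect_meta(fits: list[ModelFit]) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect pooling of per-cohort coefficients."""
    if not fits:
        raise ValueError("no fits to pool")
    kinds = {f.model_kind for f in fits}
    if len(kinds) != 1:
        raise ValueError(f"cannot pool fits on different scales: {sorted(kinds)}")
    return pool_fixed_effect([f.coefficient for f in fits], [f.se for f in fits])


# ---------------------------------------------------------------------------
# Genotype PCA


def genotype_pca(dosages: DosageMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Top-k PCA of frequency-standardised dosages.

    Columns are centred at 2p and scaled by sqrt(2p(1-p)); the returned
    per-individual scores are U*S for the leading k singular triplets, with
    each component's sign fixed so its largest-magnitude loading is positive.
    Returns ``(scores, loadings)`` with shapes (n, k) and (m_poly, k).
    """
    d = dosages.dosages
    p = d.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if poly.sum() < k:
        raise DegenerateInputError(f"need >= {k} polymorphic SNPs, have {int(poly.sum())}")
    x = (d[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if rank < k:
        raise DegenerateInputError(f"requested {k} components but matrix rank is {rank}")
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return scores, loadings


def combine_dosages(matrices: list[DosageMatrix]) -> DosageMatrix:
    """Stack cohorts row-wise on the shared SNP set (order of the first matrix)."""
    first = matrices[0]
    rsids = list(first.snp_ids)
    blocks, ids = [], []
    for m in matrices:
        cols = m.snp_indices(rsids)
        blocks.append(m.dosages[:, cols])
        ids.extend(f"{m.cohort}:{i}" if m.cohort else str(i) for i in m.individual_ids)
    return DosageMatrix(np.array(ids, dtype=object), np.array(rsids, dtype=object), np.vstack(blocks), cohort="combined")


# ---------------------------------------------------------------------------
# Reporting


def model_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble the model-results table (one row per cohort x subset, plus nulls)."""
    cols = ["model", "estimate", "se", "stat", "p", "aic", "r2_nagelkerke", "auc", "auc_se"]
    return pd.DataFrame(rows, columns=cols)
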