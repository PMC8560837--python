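"""Synthetic three-cohort generator.

Produces a mainland cohort and two isolate cohorts whose statistical
structure matches what the downstream analysis assumes: dosages as sums of
two Bernoulli(RAF) alleles (optionally correlated within LD blocks through a
latent Gaussian copula), disease status from a logistic model on centred
dosages, sib-pair families with expected kinship 0.25 embedded among
controls, and covariates with configurable population-specific locations.

Everything is driven by a single integer seed fanned out to per-stage
substreams, so identical calls are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .core import CohortTable, DosageMatrix
from .errors import CaseCountUnreachable
from .snp_panel import Panel, SnpEffect

logger = logging.getLogger(__name__)

_ITERATION_CAP_FACTOR = 1000

HLA_TAG_RSID = "rs9271069"


@dataclass
class PopulationSpec:
    """Target composition of one synthetic cohort."""

    name: str
    n_cases: int
    n_controls: int
    raf: np.ndarray
    prevalence_per_1e5: float
    n_families: int = 0
    age_mean: float = 50.0
    age_sd: float = 15.0
    female_frac: float = 0.5
    pc_mu: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.raf = np.asarray(self.raf, dtype=float)
        if np.any(self.raf <= 0.0) or np.any(self.raf >= 1.0):
            raise ValueError(f"{self.name}: RAFs must lie strictly in (0,1); monomorphic SNPs rejected")
        if self.n_cases + self.n_controls <= 0:
            raise ValueError(f"{self.name}: n_cases + n_controls must be > 0")
        if self.n_controls < 2 * self.n_families:
            raise ValueError(f"{self.name}: {self.n_families} sib-pair families exceed the control quota")
        if not (0.0 < self.prevalence_per_1e5 < 100_000.0):
            raise ValueError(f"{self.name}: prevalence out of range")


@dataclass
class EffectModel:
    """Generative disease model shared by the cohorts of one scenario.

    ``log_or`` acts on centred dosages: logit(p_i) = intercept
    + sum_j log_or_j (d_ij - 2 raf_j) + covariate terms, so ``intercept``
    is the baseline log-odds calibrated to the cohort's target prevalence.
    ``ld_blocks`` is a list of ``(snp_indices, rho)`` pairs; rho is the
    latent-Gaussian equicorrelation within the block, in [0, 1).
    """

    snp_ids: np.ndarray
    log_or: np.ndarray
    covariate_effects: np.ndarray = field(default_factory=lambda: np.zeros(4))
    ld_blocks: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.log_or = np.asarray(self.log_or, dtype=float)
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        if len(self.snp_ids) != len(self.log_or):
            raise ValueError("snp_ids and log_or length mismatch")
        if self.covariate_effects.shape != (4,):
            raise ValueError("covariate_effects must have length 4 (age, sex, pc1, pc2)")
        for idx, rho in self.ld_blocks:
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"LD correlation parameter must be in [0,1), got {rho}")

    @classmethod
    def from_panel(cls, panel: Panel, **kwargs) -> "EffectModel":
        return cls(
            snp_ids=np.array(panel.rsids, dtype=object),
            log_or=panel.log_ors,
            **kwargs,
        )


@dataclass
class SyntheticScenario:
    """A generated multi-cohort data set plus its generative ground truth."""

    panel: Panel
    cohorts: dict[str, tuple[DosageMatrix, CohortTable]]
    specs: dict[str, PopulationSpec]
    model: EffectModel

    def designed_control_delta_raw(self, target: str, baseline: str) -> float:
        """Designed difference in population-mean raw score (target - baseline).

        E[raw] = sum_j log_or_j * 2 raf_j, so the designed control-mean gap is
        ``2 (raf_t - raf_b) . log_or`` (controls ~ population at low prevalence).
        """
        rt = self.specs[target].raf
        rb = self.specs[baseline].raf
        return float(2.0 * (rt - rb) @ self.model.log_or)


# ---------------------------------------------------------------------------
# Sampling primitives


def _draw_dosages(rng: np.random.Generator, n: int, raf: np.ndarray, ld_blocks) -> np.ndarray:
    """Sum of two Bernoulli(raf) allele draws, correlated within LD blocks."""
    m = len(raf)
    thresh = stats.norm.ppf(raf)
    d = np.zeros((n, m))
    for _ in range(2):
        z = rng.standard_normal((n, m))
        for idx, rho in ld_blocks:
            shared = rng.standard_normal((n, 1))
            z[:, idx] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z[:, idx]
        d += z < thresh
    return d


def _draw_sib_pair_dosages(rng: np.random.Generator, n_fam: int, raf: np.ndarray):
    """Mendelian transmission from simulated parents; sibs share each transmitted
    allele with probability 1/2, giving expected kinship 0.25."""
    m = len(raf)
    mother = [(rng.random((n_fam, m)) < raf).astype(float) for _ in range(2)]
    father = [(rng.random((n_fam, m)) < raf).astype(float) for _ in range(2)]
    children = []
    for _ in range(2):
        pick_m = rng.random((n_fam, m)) < 0.5
        pick_f = rng.random((n_fam, m)) < 0.5
        mat = np.where(pick_m, mother[0], mother[1])
        pat = np.where(pick_f, father[0], father[1])
        children.append(mat + pat)
    return children


def _draw_covariates(rng: np.random.Generator, n: int, spec: PopulationSpec):
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    sex = np.where(rng.random(n) < spec.female_frac, "F", "M").astype(object)
    pc1 = rng.normal(spec.pc_mu[0], 1.0, n)
    pc2 = rng.normal(spec.pc_mu[1], 1.0, n)
    return age, sex, pc1, pc2


def _case_probability(
    dosages: np.ndarray,
    spec: PopulationSpec,
    model: EffectModel,
    intercept: float,
    age,
    sex,
    pc1,
    pc2,
) -> np.ndarray:
    centred = dosages - 2.0 * spec.raf
    eta = intercept + centred @ model.log_or
    cov = np.column_stack([age, (sex == "M").astype(float), pc1, pc2])
    eta = eta + cov @ model.covariate_effects
    return expit(eta)


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(
    spec: PopulationSpec, model: EffectModel, seed: int
) -> tuple[DosageMatrix, CohortTable]:
    """Generate one cohort with exactly the requested case/control composition.

    Individuals are drawn from the generative model and retained by rejection
    until the case and control quotas are filled; sampling stops with
    :class:`CaseCountUnreachable` once 1000x the requested cohort size has
    been drawn. ``n_families`` sib pairs (both conditioned to be controls)
    are embedded among the controls.
    """
    if len(spec.raf) != len(model.snp_ids):
        raise ValueError("spec and model do not reference the same SNP panel")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    intercept = float(logit(spec.prevalence_per_1e5 / 100_000.0))

    rows, table_rows = [], []

    # sib-pair families first, conditioned to be control/control
    fam_needed = spec.n_families
    fam_drawn = 0
    fam_cap = max(_ITERATION_CAP_FACTOR * max(spec.n_families, 1), 1)
    fam_count = 0
    while fam_needed > 0:
        batch = min(max(2 * fam_needed, 64), 10_000)
        fam_drawn += batch
        if fam_drawn > fam_cap:
            raise CaseCountUnreachable(
                f"{spec.name}: could not realise {spec.n_families} control sib-pair "
                f"families within the {_ITERATION_CAP_FACTOR}x iteration cap"
            )
        c1, c2 = _draw_sib_pair_dosages(rng, batch, spec.raf)
        covs = [_draw_covariates(rng, batch, spec) for _ in range(2)]
        p1 = _case_probability(c1, spec, model, intercept, *covs[0])
        p2 = _case_probability(c2, spec, model, intercept, *covs[1])
        ok = (rng.random(batch) >= p1) & (rng.random(batch) >= p2)
        for k in np.where(ok)[0][:fam_needed]:
            fam_count += 1
            for sib, (d, cv) in enumerate(((c1[k], covs[0]), (c2[k], covs[1])), start=1):
                rows.append(d)
                table_rows.append(
                    (
                        f"{spec.name}_f{fam_count:05d}_{sib}",
                        0,
                        cv[0][k],
                        cv[1][k],
                        cv[2][k],
                        cv[3][k],
                    )
                )
        fam_needed = spec.n_families - fam_count

    # singletons by rejection until both quotas are met
    need_cases = spec.n_cases
    need_controls = spec.n_controls - 2 * spec.n_families
    cap = _ITERATION_CAP_FACTOR * (spec.n_cases + spec.n_controls)
    drawn = 0
    idx = 0
    while need_cases > 0 or need_controls > 0:
        if drawn >= cap:
            raise CaseCountUnreachable(
                f"{spec.name}: case quota ({spec.n_cases}) unreachable within the "
                f"{_ITERATION_CAP_FACTOR}x iteration cap ({cap} draws at prevalence "
                f"{spec.prevalence_per_1e5}/100000)"
            )
        approx_rate = max(spec.prevalence_per_1e5 / 100_000.0, 1e-6)
        batch = int(min(max(need_controls + need_cases / approx_rate, 1024), 200_000, cap - drawn))
        drawn += batch
        d = _draw_dosages(rng, batch, spec.raf, model.ld_blocks)
        age, sex, pc1, pc2 = _draw_covariates(rng, batch, spec)
        p = _case_probability(d, spec, model, intercept, age, sex, pc1, pc2)
        is_case = rng.random(batch) < p
        case_keep = np.where(is_case)[0][: need_cases]
        ctrl_keep = np.where(~is_case)[0][: need_controls]
        need_cases -= len(case_keep)
        need_controls -= len(ctrl_keep)
        for k in np.concatenate([case_keep, ctrl_keep]):
            idx += 1
            rows.append(d[k])
            table_rows.append(
                (f"{spec.name}_{idx:06d}", int(is_case[k]), age[k], sex[k], pc1[k], pc2[k])
            )

    # shuffle so that row order carries no case/control or family structure
    order = rng.permutation(len(rows))
    dosage = np.vstack(rows)[order]
    ids = np.array([table_rows[i][0] for i in order], dtype=object)
    dm = DosageMatrix(ids, model.snp_ids.copy(), dosage, cohort=spec.name)
    ct = CohortTable(
        ids=ids,
        status=np.array([table_rows[i][1] for i in order]),
        age=np.array([table_rows[i][2] for i in order], dtype=float),
        sex=np.array([table_rows[i][3] for i in order], dtype=object),
        pc1=np.array([table_rows[i][4] for i in order], dtype=float),
        pc2=np.array([table_rows[i][5] for i in order], dtype=float),
        name=spec.name,
    )
    return dm, ct


# ---------------------------------------------------------------------------
# Default scenario


def default_panel(seed: int = 0, n_background: int = 126) -> Panel:
    """127-SNP synthetic panel: one large-effect HLA-like tag plus background SNPs.

    The tag SNP has OR 2.77; background ORs are uniform in [1.05, 1.20].
    Positions are spaced 1 Mb apart so default-window clumping has no pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    snps = [
        SnpEffect(
            rsid=HLA_TAG_RSID,
            chrom="6",
            pos=32_600_000,
            risk_allele="G",
            other_allele="A",
            or_value=2.77,
            p_value=1e-12,
            source="synthetic",
        )
    ]
    ors = rng.uniform(1.05, 1.20, n_background)
    pvals = 10.0 ** rng.uniform(-10.0, -4.0, n_background)
    for i in range(n_background):
        chrom = str((i % 22) + 1)
        pos = 10_000_000 + (i // 22 + 1) * 1_000_000
        snps.append(
            SnpEffect(
                rsid=f"rs{9_000_001 + i}",
                chrom=chrom,
                pos=pos,
                risk_allele="G",
                other_allele="A",
                or_value=float(ors[i]),
                p_value=float(pvals[i]),
                source="synthetic",
            )
        )
    return Panel(snps, hla_tag=HLA_TAG_RSID)


#: Table-1-style defaults: (n_cases, n_controls, prevalence, age_mean, age_sd, female_frac, pc_mu)
DEFAULT_COHORT_PARAMS = {
    "mainland": (30, 8708, 145.0, 46.25, 14.97, 0.590, (0.0, 0.0)),
    "isle_a": (97, 2118, 402.0, 54.09, 15.28, 0.607, (3.0, 0.0)),
    "isle_b": (15, 2090, 295.0, 49.93, 15.26, 0.600, (0.0, 3.0)),
}

#: HLA tag control risk-allele frequency per cohort
DEFAULT_HLA_RAF = {"mainland": 0.17, "isle_a": 0.23, "isle_b": 0.21}


def default_scenario(
    seed: int,
    n_scale: float = 1.0,
    n_families: int = 0,
) -> SyntheticScenario:
    """The default three-cohort scenario.

    Cohort sizes 30/8708, 97/2118, 15/2090 (scaled by ``n_scale``), a
    large-effect HLA-like SNP at control frequency 0.17/0.23/0.21, and 126
    background SNPs at frequencies shared across the populations.
    """
    panel = default_panel(seed=0)
    model = EffectModel.from_panel(panel)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7002]))
    background_raf = rng.uniform(0.10, 0.90, len(panel) - 1)
    ss = np.random.SeedSequence(seed).spawn(len(DEFAULT_COHORT_PARAMS))

    specs, cohorts = {}, {}
    for (name, (nca, nco, prev, amu, asd, ff, pcmu)), sub in zip(
        DEFAULT_COHORT_PARAMS.items(), ss
    ):
        raf = np.concatenate([[DEFAULT_HLA_RAF[name]], background_raf])
        spec = PopulationSpec(
            name=name,
            n_cases=max(1, round(nca * n_scale)),
            n_controls=max(2, round(nco * n_scale)),
            raf=raf,
            prevalence_per_1e5=prev,
            n_families=n_families,
            age_mean=amu,
            age_sd=asd,
            female_frac=ff,
            pc_mu=pcmu,
        )
        specs[name] = spec
        cohorts[name] = generate_cohort(spec, model, seed=int(sub.generate_state(1)[0]))
    return SyntheticScenario(panel=panel, cohorts=cohorts, specs=specs, model=model)
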