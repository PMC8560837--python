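"""End-to-end orchestration: simulate/load -> panel QC -> score -> fit -> compare -> attribute.

A single :class:`RunConfig` (usually from a YAML file) drives every stage;
the same config and seed always produce byte-identical outputs, and a run
manifest records the seed, config hash and a checksum of every report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association_models as am
from . import attribution as attr
from . import io as isio
from . import population_comparison as pc
from . import prs_engine as prs
from . import snp_panel as sp
from . import synthetic_cohorts as syn
from .core import CohortTable, DosageMatrix
from .errors import IslePrsError

logger = logging.getLogger(__name__)

SUBSETS = ("full", "no_hla", "hla_only")

#: default observed-prevalence records for the synthetic scenario's populations
DEFAULT_PREVALENCE = {
    "mainland": attr.PrevalenceRecord("mainland", 145.0, 5_400_000),
    "isle_a": attr.PrevalenceRecord("isle_a", 402.0, 22_000),
    "isle_b": attr.PrevalenceRecord("isle_b", 295.0, 23_000),
}


class StageError(IslePrsError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class CohortInput:
    name: str
    dosage_path: str
    phenotype_path: str
    format: str = "tsv"  # "tsv" | "vcf"


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "out"
    # synthetic scenario (used when no cohort files are given)
    synthetic_n_scale: float = 1.0
    synthetic_n_families: int = 0
    cohorts: list[CohortInput] = field(default_factory=list)
    panel_path: str | None = None
    hla_tag: str = syn.HLA_TAG_RSID
    clump_r2_max: float = 0.25
    clump_window_bp: int = 200_000
    clump_cohort: str | None = None  # which cohort's dosages supply the r2
    kinship_threshold: float = 0.05
    # Kinship needs genome-wide dosages: estimated from a ~100-SNP scoring
    # panel its sampling SD (~0.04) swamps the 0.05 threshold. Enable only
    # when the dosage input is much wider than the panel.
    kinship_enabled: bool = False
    baseline: str = "mainland"
    prevalence_path: str | None = None
    write_vcf: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohorts = [CohortInput(**c) for c in raw.pop("cohorts", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(cohorts=cohorts, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohorts(config: RunConfig):
    """Return (panel, {name: (DosageMatrix, CohortTable)}, synthetic?)."""
    if config.cohorts:
        if config.panel_path is None:
            raise ValueError("panel_path is required when cohort files are supplied")
        panel = sp.load_panel(config.panel_path, hla_tag=config.hla_tag)
        cohorts = {}
        for c in config.cohorts:
            reader = isio.read_vcf if c.format == "vcf" else isio.read_dosage_tsv
            dm = reader(c.dosage_path, cohort=c.name)
            ct = isio.read_phenotypes(c.phenotype_path, name=c.name)
            if not np.array_equal(dm.individual_ids, ct.ids):
                raise ValueError(f"cohort {c.name!r}: dosage and phenotype ids differ")
            cohorts[c.name] = (dm, ct)
        return panel, cohorts, False
    scenario = syn.default_scenario(
        config.seed,
        n_scale=config.synthetic_n_scale,
        n_families=config.synthetic_n_families,
    )
    return scenario.panel, scenario.cohorts, True


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs.append(p)
        return p

    # --- inputs / simulation -------------------------------------------------
    try:
        panel, cohorts, synthetic = _load_cohorts(config)
    except Exception as e:  # noqa: BLE001 - surface with stage name
        raise StageError("inputs", e) from e

    if synthetic:
        try:
            for name, (dm, ct) in cohorts.items():
                p1 = out / f"{name}.dosages.tsv"
                isio.write_dosage_tsv(dm, p1)
                p2 = out / f"{name}.phenotypes.tsv"
                isio.write_phenotypes(ct, p2)
                outputs += [p1, p2]
                if config.write_vcf:
                    pv = out / f"{name}.vcf"
                    isio.write_vcf(dm, panel, pv)
                    outputs.append(pv)
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", e) from e

    # --- panel QC ------------------------------------------------------------
    try:
        clump_name = config.clump_cohort or next(iter(cohorts))
        if clump_name not in cohorts:
            raise ValueError(f"clump_cohort {clump_name!r} is not a cohort")
        panel, clump_report = sp.build_panel(
            list(panel.snps),
            dosages=cohorts[clump_name][0],
            hla_tag=config.hla_tag,
            r2_max=config.clump_r2_max,
            window_bp=config.clump_window_bp,
        )
        emit(panel.to_frame(), "panel.tsv")
        emit(clump_report, "clump_report.tsv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("build-panel", e) from e

    # --- scoring -------------------------------------------------------------
    try:
        scores: dict[str, dict[str, prs.ScoreVector]] = {n: {} for n in cohorts}
        for subset in SUBSETS:
            raw = [prs.score(dm, panel, subset) for dm, _ in cohorts.values()]
            for sv in prs.pooled_zscore(raw):
                scores[sv.cohort][subset] = sv
        flat = [scores[n][s] for n in cohorts for s in SUBSETS]
        p = out / "scores.tsv"
        prs.write_scores(flat, p)
        outputs.append(p)
    except Exception as e:  # noqa: BLE001
        raise StageError("score", e) from e

    # --- association models --------------------------------------------------
    try:
        retained: dict[str, list] = {}
        for name, (dm, ct) in cohorts.items():
            if config.kinship_enabled:
                kin = am.kinship_estimate(dm)
                case_ids = set(ct.ids[ct.status == 1])
                retained[name] = am.filter_unrelated(kin, config.kinship_threshold, case_ids)
            else:
                retained[name] = list(ct.ids)

        rows = []
        gaussian_fits: dict[tuple[str, str], am.ModelFit] = {}
        logistic_fits: dict[tuple[str, str], am.ModelFit] = {}
        for name, (dm, ct) in cohorts.items():
            for subset in SUBSETS:
                sv = scores[name][subset]
                gaussian_fits[(name, subset)] = am.gaussian_group_model(sv, ct)
                fit, null = am.logistic_fit(sv, ct, retained[name])
                logistic_fits[(name, subset)] = fit
                ct_r = ct.subset(retained[name])
                # rank by fitted full-model probabilities for the ROC
                auc, auc_se = am.roc_auc(_linear_predictor(sv, ct_r), ct_r.status)
                rows.append(
                    {
                        "model": f"{name}: {subset}",
                        "estimate": fit.coefficient,
                        "se": fit.se,
                        "stat": fit.stat,
                        "p": fit.wald_p,
                        "aic": fit.aic,
                        "r2_nagelkerke": am.nagelkerke_r2(fit, null, fit.n_used),
                        "auc": auc,
                        "auc_se": auc_se,
                    }
                )
            rows.append(
                {
                    "model": f"{name}: null",
                    "estimate": np.nan,
                    "se": np.nan,
                    "stat": np.nan,
                    "p": np.nan,
                    "aic": null.aic,
                    "r2_nagelkerke": np.nan,
                    "auc": np.nan,
                    "auc_se": np.nan,
                }
            )
        emit(am.model_report(rows), "model_report.tsv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", e) from e

    # --- population comparisons ---------------------------------------------
    try:
        names = list(cohorts)
        trows = []
        for subset in SUBSETS:
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    za = scores[a][subset].z[cohorts[a][1].control_mask]
                    zb = scores[b][subset].z[cohorts[b][1].control_mask]
                    t, df, pval = pc.welch_t_test(za, zb)
                    trows.append(
                        {
                            "subset": subset,
                            "cohort_a": a,
                            "n_a": len(za),
                            "mean_a": za.mean(),
                            "cohort_b": b,
                            "n_b": len(zb),
                            "mean_b": zb.mean(),
                            "t": t,
                            "df": df,
                            "p": pval,
                        }
                    )
        emit(pc.score_comparison_report(trows), "score_comparison.tsv")

        comparisons = []
        for rsid in panel.rsids:
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    comparisons.append(
                        pc.raf_chi2(cohorts[a][0], cohorts[a][1], cohorts[b][0], cohorts[b][1], rsid)
                    )
        emit(pc.snp_comparison_report(comparisons), "snp_comparison.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("compare", e) from e

    # --- attribution ---------------------------------------------------------
    try:
        if config.prevalence_path is not None:
            prevalence = attr.load_prevalence_table(config.prevalence_path)
        elif synthetic:
            prevalence = DEFAULT_PREVALENCE
        else:
            raise ValueError("prevalence_path is required for file-based cohorts")
        baseline = config.baseline
        if baseline not in cohorts:
            raise ValueError(f"baseline {baseline!r} is not a cohort")
        metas = {}
        for subset in SUBSETS:
            beta, se, _ = am.fixed_effect_meta([logistic_fits[(n, subset)] for n in cohorts])
            metas[subset] = (beta, se)
        delta_means = {}
        for name in cohorts:
            if name == baseline:
                continue
            for subset in SUBSETS:
                zb = scores[baseline][subset].z[cohorts[baseline][1].control_mask]
                zt = scores[name][subset].z[cohorts[name][1].control_mask]
                delta_means[(name, subset)] = float(zt.mean() - zb.mean())
        results = attr.attribution_report(delta_means, metas, prevalence, baseline)
        emit(attr.report_frame(results), "attribution.tsv")
        ptxt = out / "attribution.txt"
        ptxt.write_text(attr.render_text_table(results))
        outputs.append(ptxt)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("attribute", e) from e

    # --- manifest ------------------------------------------------------------
    cfg = config.to_dict()
    manifest = {
        "seed": config.seed,
        "package_version": _pkg_version("isleprs"),
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _linear_predictor(sv: prs.ScoreVector, ct: CohortTable) -> np.ndarray:
    """Refit the logistic model on this table and return fitted probabilities."""
    import statsmodels.api as sm

    pos = {i: k for k, i in enumerate(sv.individual_ids)}
    z = sv.z[[pos[i] for i in ct.ids]]
    X = np.column_stack([np.ones(ct.n), z, ct.age, ct.sex_male, ct.pc1, ct.pc2])
    res = sm.Logit(ct.status.astype(float), X).fit(method="newton", maxiter=100, disp=False)
    return np.asarray(res.predict(X))
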