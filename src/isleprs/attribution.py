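"""Attribution calculus: from score-frequency differences to excess cases.

Converts control-mean score differences into expected log odds-ratios,
prevalence pairs into observed log odds-ratios, and log odds-ratios into the
equivalent number of excess cases per 100,000 against a baseline prevalence.
The odds conversion and the prevalence-derived odds are exact inverses of one
another, so the two directions round-trip to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateInputError

PER_1E5 = 100_000.0

SUBSET_LABELS = {
    "full": "all common risk variants",
    "no_hla": "common risk variants without the HLA tag SNP",
    "hla_only": "HLA tag SNP only",
}


@dataclass(frozen=True)
class PrevalenceRecord:
    population: str
    prevalence_per_1e5: float
    population_size: int | None = None

    def __post_init__(self):
        if not (0.0 < self.prevalence_per_1e5 < PER_1E5):
            raise ValueError(
                f"{self.population}: prevalence must be in (0, 100000), got {self.prevalence_per_1e5}"
            )

    @property
    def odds(self) -> float:
        return self.prevalence_per_1e5 / (PER_1E5 - self.prevalence_per_1e5)


@dataclass
class AttributionResult:
    comparison: tuple[str, str]  # (baseline, target)
    subset_name: str
    log_or: float
    ci: tuple[float, float]
    excess_cases_per_1e5: float
    excess_cases_absolute: float | None
    kind: str  # "expected" | "observed"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (reporting convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def expected_log_or(
    delta_mean_z: float, beta_meta: float, beta_se: float = 0.0
) -> tuple[float, tuple[float, float]]:
    """Expected log odds-ratio: control-mean z difference (target - baseline) x pooled beta.

    The CI propagates the beta uncertainty only (the mean difference is
    treated as fixed): ``delta * (beta +/- 1.96 se)``, returned ordered.
    """
    if not math.isfinite(beta_meta):
        raise ValueError("beta_meta must be finite")
    log_or = delta_mean_z * beta_meta
    lo = delta_mean_z * (beta_meta - 1.96 * beta_se)
    hi = delta_mean_z * (beta_meta + 1.96 * beta_se)
    return log_or, (min(lo, hi), max(lo, hi))


def observed_log_or(baseline: PrevalenceRecord | float, target: PrevalenceRecord | float) -> float:
    """Observed log odds-ratio between two prevalences (per 100,000), via contingency odds."""
    b = baseline if isinstance(baseline, PrevalenceRecord) else PrevalenceRecord("baseline", float(baseline))
    t = target if isinstance(target, PrevalenceRecord) else PrevalenceRecord("target", float(target))
    return math.log(t.odds / b.odds)


def log_or_to_excess_cases(log_or: float, baseline_prev_per_1e5: float) -> float:
    """Equivalent excess cases per 100,000 implied by a log odds-ratio.

    Applies the odds-ratio to the baseline odds and converts back to a
    prevalence: odds1 = odds0 * exp(log_or); P1 = 1e5 * odds1/(1+odds1);
    returns P1 - P0 unrounded (round only at reporting).
    """
    p0 = PrevalenceRecord("baseline", baseline_prev_per_1e5)
    odds1 = p0.odds * math.exp(log_or)
    p1 = PER_1E5 * odds1 / (1.0 + odds1)
    return p1 - p0.prevalence_per_1e5


def absolute_excess(excess_per_1e5: float, population_size: int) -> float:
    """Scale a per-100,000 excess to a population headcount (unrounded)."""
    if population_size <= 0:
        raise ValueError("population_size must be > 0")
    return excess_per_1e5 * population_size / PER_1E5


def load_prevalence_table(path) -> dict[str, PrevalenceRecord]:
    df = pd.read_csv(path, sep="\t")
    required = ["population", "prevalence_per_1e5", "population_size"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"prevalence table missing column(s) {missing}")
    return {
        str(r.population): PrevalenceRecord(
            str(r.population), float(r.prevalence_per_1e5), int(r.population_size)
        )
        for r in df.itertuples(index=False)
    }


def attribution_report(
    delta_means: dict[tuple[str, str], float],
    metas: dict[str, tuple[float, float]],
    prevalence: dict[str, PrevalenceRecord],
    baseline: str,
    subsets: tuple[str, ...] = ("full", "no_hla", "hla_only"),
) -> list[AttributionResult]:
    """Assemble expected + observed attribution rows for every target population.

    Parameters
    ----------
    delta_means
        ``(target_population, subset) -> control-mean z difference`` relative
        to the baseline population.
    metas
        ``subset -> (pooled beta, pooled se)`` from the cross-cohort
        meta-analysis of the per-z logistic coefficients.
    prevalence
        Per-population observed prevalence records; must cover the baseline
        and every target.
    baseline
        Population used as the reference for both expected and observed rows.
    """
    if baseline not in prevalence:
        raise DegenerateInputError(f"baseline {baseline!r} missing from the prevalence table")
    targets = sorted({pop for pop, _ in delta_means})
    base = prevalence[baseline]
    results: list[AttributionResult] = []
    for pop in targets:
        if pop not in prevalence:
            raise DegenerateInputError(f"population {pop!r} missing from the prevalence table")
        rec = prevalence[pop]
        for subset in subsets:
            if (pop, subset) not in delta_means:
                raise DegenerateInputError(f"missing delta mean for ({pop!r}, {subset!r})")
            if subset not in metas:
                raise DegenerateInputError(f"missing meta beta for subset {subset!r}")
            beta, se = metas[subset]
            lo_or, ci = expected_log_or(delta_means[(pop, subset)], beta, se)
            excess = log_or_to_excess_cases(lo_or, base.prevalence_per_1e5)
            absolute = (
                absolute_excess(excess, rec.population_size)
                if rec.population_size
                else None
            )
            results.append(
                AttributionResult(
                    comparison=(baseline, pop),
                    subset_name=subset,
                    log_or=lo_or,
                    ci=ci,
                    excess_cases_per_1e5=excess,
                    excess_cases_absolute=absolute,
                    kind="expected",
                )
            )
        obs = observed_log_or(base, rec)
        obs_excess = rec.prevalence_per_1e5 - base.prevalence_per_1e5
        results.append(
            AttributionResult(
                comparison=(baseline, pop),
                subset_name="observed",
                log_or=obs,
                ci=(obs, obs),
                excess_cases_per_1e5=obs_excess,
                excess_cases_absolute=(
                    absolute_excess(obs_excess, rec.population_size)
                    if rec.population_size
                    else None
                ),
                kind="observed",
            )
        )
    return results


def report_frame(results: list[AttributionResult]) -> pd.DataFrame:
    """Flatten attribution rows into the report table, with rounded reporting columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "baseline": r.comparison[0],
                "target": r.comparison[1],
                "subset": r.subset_name,
                "kind": r.kind,
                "log_or": r.log_or,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "excess_per_1e5": r.excess_cases_per_1e5,
                "excess_per_1e5_rounded": round_half_away(r.excess_cases_per_1e5),
                "excess_absolute": r.excess_cases_absolute,
                "excess_absolute_rounded": (
                    round_half_away(r.excess_cases_absolute)
                    if r.excess_cases_absolute is not None
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)


def render_text_table(results: list[AttributionResult]) -> str:
    """Human-readable attribution table, one block per target population."""
    lines = []
    by_target: dict[str, list[AttributionResult]] = {}
    for r in results:
        by_target.setdefault(r.comparison[1], []).append(r)
    for target, rows in by_target.items():
        base = rows[0].comparison[0]
        lines.append(f"Excess disease risk: {target} vs {base}")
        for r in rows:
            label = SUBSET_LABELS.get(r.subset_name, r.subset_name)
            if r.kind == "observed":
                lines.append(
                    f"  observed                 log(OR) {r.log_or:6.2f}"
                    f"   excess/1e5 {round_half_away(r.excess_cases_per_1e5):5d}"
                )
            else:
                lines.append(
                    f"  expected: {label:<45s} log(OR) {r.log_or:6.2f}"
                    f" ({r.ci[0]:.2f}, {r.ci[1]:.2f})"
                    f"   excess/1e5 {round_half_away(r.excess_cases_per_1e5):5d}"
                )
        lines.append("")
    return "\n".join(lines)
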