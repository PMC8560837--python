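"""Scoring-panel construction.

Builds the risk-variant panel used for scoring: loads effect tables,
deduplicates entries for the same variant by inverse-variance meta-analysis,
filters on p-value, harmonises risk alleles to the dosage-counted allele, and
greedily prunes variants in linkage disequilibrium.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._pooling import pool_fixed_effect, se_from_p
from .core import DosageMatrix
from .errors import AlleleMismatchError, DegenerateInputError, MissingSnpError, PalindromicSnpError

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["rsid", "chrom", "pos", "risk_allele", "other_allele", "or", "p", "source"]

#: default panel-inclusion p-value cut-off
P_VALUE_MAX = 1e-3

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class SnpEffect:
    """One risk variant with its published effect: the unit of the panel."""

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    or_value: float
    p_value: float
    source: str = ""

    def __post_init__(self):
        if self.or_value <= 0.0:
            raise ValueError(f"{self.rsid}: odds ratio must be > 0, got {self.or_value}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.rsid}: p-value must be in (0, 1], got {self.p_value}")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: risk and other allele identical")

    @property
    def log_or(self) -> float:
        return math.log(self.or_value)

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.risk_allele, self.other_allele}) in _PALINDROMIC


@dataclass
class Panel:
    """Ordered panel of scoring SNPs plus its named scoring subsets.

    ``subsets`` always contains "full" (every SNP), "no_hla" (every SNP except
    the designated HLA tag) and "hla_only" (the tag alone) when ``hla_tag``
    is set.
    """

    snps: list[SnpEffect]
    hla_tag: str | None = None
    _rsid_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            dups = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValueError(f"duplicate rsid(s) in panel: {dups}")
        if self.hla_tag is not None and self.hla_tag not in rsids:
            raise ValueError(f"hla_tag {self.hla_tag!r} not in panel")
        self._rsid_index = {r: i for i, r in enumerate(rsids)}

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def log_ors(self) -> np.ndarray:
        return np.array([s.log_or for s in self.snps])

    @property
    def subsets(self) -> dict[str, np.ndarray]:
        full = np.arange(len(self.snps))
        out = {"full": full}
        if self.hla_tag is not None:
            tag = self._rsid_index[self.hla_tag]
            out["no_hla"] = full[full != tag]
            out["hla_only"] = np.array([tag])
        return out

    def subset_rsids(self, subset_name: str) -> list[str]:
        idx = self.subsets.get(subset_name)
        if idx is None:
            raise KeyError(f"unknown subset {subset_name!r}")
        return [self.snps[i].rsid for i in idx]

    def get(self, rsid: str) -> SnpEffect:
        return self.snps[self._rsid_index[rsid]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": s.rsid,
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "risk_allele": s.risk_allele,
                    "other_allele": s.other_allele,
                    "or": s.or_value,
                    "p": s.p_value,
                    "source": s.source,
                }
                for s in self.snps
            ],
            columns=PANEL_COLUMNS,
        )


# ---------------------------------------------------------------------------
# IO


def write_panel(panel: Panel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def load_effects(path) -> list[SnpEffect]:
    """Read an effect table TSV with the panel header into SnpEffect records."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str, "source": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"effect table {path} missing column(s) {missing}")
    df = df.rename(columns={"or": "or_value", "p": "p_value"})
    return [
        SnpEffect(
            rsid=r.rsid,
            chrom=str(r.chrom),
            pos=int(r.pos),
            risk_allele=str(r.risk_allele),
            other_allele=str(r.other_allele),
            or_value=float(r.or_value),
            p_value=float(r.p_value),
            source="" if pd.isna(r.source) else str(r.source),
        )
        for r in df.itertuples(index=False)
    ]


def load_panel(path, hla_tag: str | None = None) -> Panel:
    return Panel(load_effects(path), hla_tag=hla_tag)


# ---------------------------------------------------------------------------
# Harmonisation


def harmonise_alleles(
    effect: SnpEffect, counted_allele: str, other_allele: str
) -> tuple[SnpEffect, bool]:
    """Express an effect on the scale of the dosage-counted allele.

    Parameters
    ----------
    effect
        The published effect (risk allele + OR).
    counted_allele, other_allele
        The allele whose copies the dosage counts (ALT in a VCF with ``DS``)
        and its companion allele.

    Returns
    -------
    (effect, flip_dosage)
        ``flip_dosage`` is True when the risk allele is the *non*-counted
        allele, i.e. scoring must use ``2 - d``. The returned effect always
        keeps the published risk allele and OR; callers never see an OR < 1
        introduced by strand bookkeeping.

    Raises
    ------
    PalindromicSnpError
        For strand-ambiguous A/T and C/G SNPs, which are excluded outright.
    AlleleMismatchError
        When the effect's alleles are not the dosage's allele pair.
    """
    if effect.is_palindromic:
        raise PalindromicSnpError(
            f"{effect.rsid}: palindromic {effect.risk_allele}/{effect.other_allele} SNP excluded"
        )
    if {effect.risk_allele, effect.other_allele} != {counted_allele, other_allele}:
        raise AlleleMismatchError(
            f"{effect.rsid}: effect alleles {effect.risk_allele}/{effect.other_allele} "
            f"do not match dosage alleles {counted_allele}/{other_allele}"
        )
    return effect, effect.risk_allele != counted_allele


# ---------------------------------------------------------------------------
# Meta-analysis deduplication


def meta_dedupe(effects: list[SnpEffect]) -> SnpEffect:
    """Collapse several effect entries for one variant into a single pooled entry.

    Entries are first harmonised to the risk allele of the first entry
    (flipping OR -> 1/OR when risk/other are reversed), then pooled on the
    log-OR scale by inverse-variance weighting with per-entry SEs recovered
    from the reported p-values. Entries whose SE is undefined (p = 1 or
    OR = 1) are excluded with a warning.
    """
    if not effects:
        raise ValueError("meta_dedupe needs at least one entry")
    rsids = {e.rsid for e in effects}
    if len(rsids) != 1:
        raise ValueError(f"meta_dedupe expects one rsid, got {sorted(rsids)}")
    first = effects[0]
    if len(effects) == 1:
        return first

    harmonised = []
    for e in effects:
        if (e.risk_allele, e.other_allele) == (first.risk_allele, first.other_allele):
            harmonised.append(e)
        elif (e.risk_allele, e.other_allele) == (first.other_allele, first.risk_allele):
            harmonised.append(
                replace(
                    e,
                    risk_allele=first.risk_allele,
                    other_allele=first.other_allele,
                    or_value=1.0 / e.or_value,
                )
            )
        else:
            raise AlleleMismatchError(
                f"{e.rsid}: alleles {e.risk_allele}/{e.other_allele} irreconcilable "
                f"with {first.risk_allele}/{first.other_allele}"
            )

    betas, ses = [], []
    for e in harmonised:
        se = se_from_p(e.log_or, e.p_value)
        if not np.isfinite(se):
            logger.warning("%s: entry from %r has undefined SE; excluded from meta", e.rsid, e.source)
            continue
        betas.append(e.log_or)
        ses.append(se)
    if not betas:
        raise DegenerateInputError(f"{first.rsid}: no entry with a defined SE to pool")
    beta, se, p = pool_fixed_effect(betas, ses)
    # pooled p of exactly 0 is impossible; clip to keep SnpEffect valid
    p = max(p, 5e-324)
    sources = ";".join(dict.fromkeys(e.source for e in effects))
    return replace(
        first, or_value=math.exp(beta), p_value=p, source=f"meta({sources})"
    )


def dedupe_effects(effects: list[SnpEffect]) -> list[SnpEffect]:
    """Group an effect list by rsid and meta-pool duplicates, keeping first-seen order."""
    by_rsid: dict[str, list[SnpEffect]] = {}
    for e in effects:
        by_rsid.setdefault(e.rsid, []).append(e)
    return [es[0] if len(es) == 1 else meta_dedupe(es) for es in by_rsid.values()]


def filter_by_p(effects: list[SnpEffect], p_max: float = P_VALUE_MAX) -> list[SnpEffect]:
    kept = [e for e in effects if e.p_value < p_max]
    if len(kept) < len(effects):
        logger.info("p-value filter (< %g) dropped %d of %d SNPs", p_max, len(effects) - len(kept), len(effects))
    return kept


# ---------------------------------------------------------------------------
# LD clumping


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0  # zero-variance column: uninformative, treated as unlinked
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_clump(
    panel: Panel,
    dosages: DosageMatrix,
    r2_max: float = 0.25,
    window_bp: int = 200_000,
) -> tuple[Panel, pd.DataFrame]:
    """Greedy LD pruning: keep the most significant SNP of each correlated neighbourhood.

    Repeatedly takes the remaining SNP with the smallest p-value (ties broken
    by larger \\|log OR\\|, then rsid) and drops every other remaining SNP on the
    same chromosome within ``window_bp`` of it whose squared Pearson
    correlation of dosages exceeds ``r2_max`` (strictly). Survivors keep their
    input order.

    Returns the pruned panel and a report with one row per dropped SNP
    (``kept_rsid dropped_rsid r2 distance_bp``).
    """
    for s in panel.snps:
        if s.rsid not in dosages._snp_index:
            raise MissingSnpError(f"clumping requires dosages for {s.rsid!r}")

    order = sorted(
        range(len(panel.snps)),
        key=lambda i: (panel.snps[i].p_value, -abs(panel.snps[i].log_or), panel.snps[i].rsid),
    )
    remaining = set(range(len(panel.snps)))
    kept: set[int] = set()
    records = []
    for i in order:
        if i not in remaining:
            continue
        remaining.discard(i)
        kept.add(i)
        si = panel.snps[i]
        xi = dosages.snp_column(si.rsid)
        if xi.std() == 0.0:
            logger.warning("%s: zero-variance dosage column; r2 treated as 0", si.rsid)
        for j in sorted(remaining):
            sj = panel.snps[j]
            if sj.chrom != si.chrom or abs(sj.pos - si.pos) > window_bp:
                continue
            r2 = _pairwise_r2(xi, dosages.snp_column(sj.rsid))
            if r2 > r2_max:
                remaining.discard(j)
                records.append(
                    {
                        "kept_rsid": si.rsid,
                        "dropped_rsid": sj.rsid,
                        "r2": r2,
                        "distance_bp": abs(sj.pos - si.pos),
                    }
                )
    survivors = [s for i, s in enumerate(panel.snps) if i in kept]
    hla = panel.hla_tag if panel.hla_tag in {s.rsid for s in survivors} else None
    report = pd.DataFrame(records, columns=["kept_rsid", "dropped_rsid", "r2", "distance_bp"])
    return Panel(survivors, hla_tag=hla), report


def build_panel(
    effects: list[SnpEffect],
    dosages: DosageMatrix | None = None,
    hla_tag: str | None = None,
    p_max: float = P_VALUE_MAX,
    r2_max: float = 0.25,
    window_bp: int = 200_000,
) -> tuple[Panel, pd.DataFrame]:
    """Full panel QC: p-filter, meta-dedupe, then (if dosages given) LD-clump."""
    effects = filter_by_p(dedupe_effects(effects), p_max=p_max)
    if not effects:
        raise DegenerateInputError("no SNP survives the p-value filter")
    panel = Panel(effects, hla_tag=hla_tag if hla_tag in {e.rsid for e in effects} else None)
    if dosages is None:
        return panel, pd.DataFrame(columns=["kept_rsid", "dropped_rsid", "r2", "distance_bp"])
    return ld_clump(panel, dosages, r2_max=r2_max, window_bp=window_bp)
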