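"""Autosomal-recessive segregation checking and carrier-frequency estimation.

Under the AR model an affected individual must be homozygous for the
alternate (disease) allele; an unaffected parent of an affected is an
obligate carrier and must be heterozygous; a declared carrier likewise; any
other unaffected individual may be anything except homozygous alternate.
Concordance is the percentage of typed individuals whose genotype is
compatible with their expectation class. Carrier frequency in a healthy
panel is the heterozygote fraction with an exact (Clopper–Pearson) 95%
binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import beta

from .model import Pedigree, PedmapError, VariantGenotypeTable
from .homozygosity import round_half_up

EXPECTATION_CLASSES = (
    "affected->hom-alt",
    "obligate-carrier->het",
    "declared-carrier->het",
    "unaffected->not-hom-alt",
    "untyped",
)


@dataclass(frozen=True)
class ARCompatibilityVerdict:
    individual_id: str
    genotype: str                  # hom_ref | het | hom_alt | missing
    expectation: str               # one of EXPECTATION_CLASSES
    compatible: bool
    reason: str = ""


def _expectation_class(pedigree: Pedigree, iid: str, obligate: set[str]) -> str:
    ind = pedigree[iid]
    if ind.phenotype == "affected":
        return "affected->hom-alt"
    if iid in obligate or ind.declared_status == "obligate_carrier":
        return "obligate-carrier->het"
    if ind.declared_status == "declared_carrier":
        return "declared-carrier->het"
    return "unaffected->not-hom-alt"


def _compatible(genotype: str, expectation: str) -> tuple[bool, str]:
    if expectation == "affected->hom-alt":
        return (genotype == "hom_alt",
                "" if genotype == "hom_alt" else "affected not hom-alt")
    if expectation in ("obligate-carrier->het", "declared-carrier->het"):
        return (genotype == "het", "" if genotype == "het" else "carrier not het")
    return (genotype != "hom_alt", "" if genotype != "hom_alt" else "unaffected hom-alt")


def obligate_carriers(pedigree: Pedigree) -> set[str]:
    """Unaffected parents of affected individuals (AR obligate carriers)."""
    out: set[str] = set()
    for ind in pedigree:
        if ind.phenotype == "affected" and ind.sire is not None:
            for pid in (ind.sire, ind.dam):
                if pedigree[pid].phenotype != "affected":
                    out.add(pid)
    return out


def classify_compatibility(
    pedigree: Pedigree, variant_table: VariantGenotypeTable
) -> list[ARCompatibilityVerdict]:
    """AR-model compatibility verdict for every individual in the table.

    Parents of affecteds are auto-promoted to obligate carriers. Individuals
    with a missing genotype get an 'untyped' verdict and never enter the
    concordance denominator.
    """
    for iid in variant_table.table["individual"]:
        if iid not in pedigree:
            raise PedmapError(f"individual {iid!r} in variant table but not in pedigree")
    promoted = obligate_carriers(pedigree)
    verdicts = []
    for rec in variant_table.table.itertuples(index=False):
        if rec.genotype == "missing":
            verdicts.append(
                ARCompatibilityVerdict(rec.individual, "missing", "untyped", True, "untyped")
            )
            continue
        expectation = _expectation_class(pedigree, rec.individual, promoted)
        ok, reason = _compatible(rec.genotype, expectation)
        verdicts.append(
            ARCompatibilityVerdict(rec.individual, rec.genotype, expectation, ok, reason)
        )
    return verdicts


def concordance(verdicts: list[ARCompatibilityVerdict]) -> tuple[float, list[ARCompatibilityVerdict]]:
    """Percentage of typed verdicts that are compatible, with the
    incompatible ones listed; rounded half-up to one decimal."""
    typed = [v for v in verdicts if v.expectation != "untyped"]
    if not typed:
        raise PedmapError("no typed individuals: concordance undefined")
    incompatible = [v for v in typed if not v.compatible]
    pct = round_half_up(100.0 * (len(typed) - len(incompatible)) / len(typed), 1)
    return pct, incompatible


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not 0 <= k <= n or n <= 0:
        raise PedmapError("need 0 <= k <= n, n > 0")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class CarrierStats:
    label: str
    n_total: int
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int
    carrier_pct: float
    ci95: tuple[float, float]      # fractions in [0, 1]
    excluded_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_hom_ref + self.n_het + self.n_hom_alt != self.n_total:
            raise PedmapError("genotype counts do not sum to n_total")


def carrier_frequency(
    variant_table: VariantGenotypeTable,
    exclude_ids: list[str] | tuple[str, ...] = (),
    label: str = "",
    level: float = 0.95,
) -> CarrierStats:
    """Heterozygote percentage in a panel after caller-supplied exclusions.

    The percentage is over genotyped individuals; missing genotypes are
    reported separately. Homozygous-alternate individuals are counted (and
    unexpected in a healthy control panel — callers should treat a nonzero
    count as a red flag).
    """
    df = variant_table.table
    df = df[~df["individual"].isin(set(exclude_ids))]
    counts = df["genotype"].value_counts()
    n_missing = int(counts.get("missing", 0))
    n_het = int(counts.get("het", 0))
    n_hom_ref = int(counts.get("hom_ref", 0))
    n_hom_alt = int(counts.get("hom_alt", 0))
    n_total = n_het + n_hom_ref + n_hom_alt
    if n_total == 0:
        raise PedmapError("panel empty after exclusions")
    return CarrierStats(
        label=label or variant_table.variant_id,
        n_total=n_total,
        n_hom_ref=n_hom_ref,
        n_het=n_het,
        n_hom_alt=n_hom_alt,
        n_missing=n_missing,
        carrier_pct=round_half_up(100.0 * n_het / n_total, 1),
        ci95=clopper_pearson(n_het, n_total, level),
        excluded_ids=tuple(exclude_ids),
    )


def panel_summary(
    variant_table: VariantGenotypeTable, level: float = 0.95
) -> pd.DataFrame:
    """Per-breed carrier statistics plus a total row (counts are sums)."""
    df = variant_table.table
    if df["breed"].eq("").all():
        raise PedmapError("panel summary requires breed labels")
    rows = []
    for breed, sub in df.groupby("breed", sort=False):
        stats = carrier_frequency(
            VariantGenotypeTable(variant_table.variant_id, variant_table.ref,
                                 variant_table.alt, sub),
            label=str(breed), level=level,
        )
        rows.append(stats)
    total = carrier_frequency(variant_table, label="Total", level=level)
    rows.append(total)
    return pd.DataFrame(
        [
            {
                "breed": s.label,
                "n_hom_ref": s.n_hom_ref,
                "n_het": s.n_het,
                "n_hom_alt": s.n_hom_alt,
                "n_total": s.n_total,
                "carrier_pct": s.carrier_pct,
                "ci95_low_pct": round_half_up(100 * s.ci95[0], 2),
                "ci95_high_pct": round_half_up(100 * s.ci95[1], 2),
            }
            for s in rows
        ]
    )
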