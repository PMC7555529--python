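"""Cohort-level aggregation: karyotype table, origin counts, GTN incidence
stratified by maternal contribution, and Fisher's exact test.

A case belongs to the "maternal contribution" stratum when any of its
chromosomes carries a maternal homolog — an extra maternal chromosome or a
biparental disomy.  GTN (gestational trophoblastic neoplasia) incidence is
compared between strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, DataError
from .karyotype import KaryotypeEstimate

OUTCOMES = ("SR", "GTN")


@dataclass(frozen=True)
class CaseCall:
    """Per-case results feeding the cohort report.

    ``extra_origins`` lists (chromosome, origin) for chromosomes beyond the
    disomic baseline (including a supernumerary sex chromosome, whose
    origin is paternal in an androgenetic mole); ``biparental_disomies``
    lists disomic autosomes with one maternal homolog.
    """

    case_id: str
    karyotype: str
    euploid: bool
    extra_origins: tuple[tuple[str, str], ...] = ()
    biparental_disomies: tuple[str, ...] = ()
    outcome: str = "SR"
    confident: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ConfigError(f"unknown outcome {self.outcome!r}")

    @property
    def maternal_contribution(self) -> bool:
        return bool(self.biparental_disomies
                    or any(o == "maternal" for _, o in self.extra_origins))


def case_call_from_estimate(case_id: str, estimate: KaryotypeEstimate,
                            origins, outcome: str = "SR") -> CaseCall:
    """Assemble a :class:`CaseCall` from a karyotype estimate and per-
    chromosome origin calls (mapping chromosome → OriginCall)."""
    extras: list[tuple[str, str]] = []
    disomies: list[str] = []
    for chrom in estimate.gains:
        call = origins.get(chrom)
        extras.append((chrom, call.extra_origin if call is not None else "undetermined"))
    for chrom, call in origins.items():
        if call.copy_number == 2 and call.biparental_disomy:
            disomies.append(chrom)
    for extra_sex in estimate.sex[2:] if estimate.sex != "ambiguous" else "":
        extras.append((extra_sex, "paternal"))
    return CaseCall(case_id=case_id, karyotype=estimate.string,
                    euploid=estimate.euploid, extra_origins=tuple(extras),
                    biparental_disomies=tuple(sorted(disomies, key=int)),
                    outcome=outcome, confident=estimate.confident)


@dataclass
class CohortReport:
    cases: pd.DataFrame
    n_cases: int
    n_euploid: int
    n_aneuploid: int
    n_maternal_extras: int
    n_paternal_extras: int
    n_biparental_disomies: int
    gtn_overall: tuple[int, int]  # (GTN cases, cases)
    gtn_by_stratum: dict[str, tuple[int, int]] = field(default_factory=dict)
    fisher_gtn_p: float = float("nan")

    @property
    def aneuploidy_percent(self) -> float:
        return 100.0 * self.n_aneuploid / self.n_cases if self.n_cases else 0.0


def summarize_cohort(calls: list[CaseCall]) -> CohortReport:
    """Aggregate per-case calls into the cohort report.

    Pure function of its input: order-invariant, duplicate case ids
    rejected.  The GTN × maternal-contribution association is tested with
    Fisher's exact test when both strata are populated.
    """
    ids = [c.case_id for c in calls]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate case ids in cohort")
    calls = sorted(calls, key=lambda c: c.case_id)

    rows = []
    for c in calls:
        rows.append({
            "case_id": c.case_id,
            "karyotype": c.karyotype,
            "euploid": c.euploid,
            "extra_origins": ";".join(f"{ch}:{o}" for ch, o in c.extra_origins),
            "biparental_disomies": ";".join(c.biparental_disomies),
            "maternal_contribution": c.maternal_contribution,
            "outcome": c.outcome,
            "confident": c.confident,
        })
    df = pd.DataFrame(rows, columns=["case_id", "karyotype", "euploid",
                                     "extra_origins", "biparental_disomies",
                                     "maternal_contribution", "outcome",
                                     "confident"])

    n = len(calls)
    n_euploid = sum(c.euploid for c in calls)
    extras = [o for c in calls for _, o in c.extra_origins]
    strata = _strata(calls)
    report = CohortReport(
        cases=df,
        n_cases=n,
        n_euploid=n_euploid,
        n_aneuploid=n - n_euploid,
        n_maternal_extras=sum(o == "maternal" for o in extras),
        n_paternal_extras=sum(o == "paternal" for o in extras),
        n_biparental_disomies=sum(len(c.biparental_disomies) for c in calls),
        gtn_overall=(sum(c.outcome == "GTN" for c in calls), n),
        gtn_by_stratum=strata,
    )
    (g1, n1), (g0, n0) = strata["maternal_contribution"], strata["no_maternal_contribution"]
    if n1 and n0:
        report.fisher_gtn_p = fisher_exact(((g1, n1 - g1), (g0, n0 - g0))).p_value
    return report


def _strata(calls: list[CaseCall]) -> dict[str, tuple[int, int]]:
    out = {}
    for name, keep in (("maternal_contribution", True),
                       ("no_maternal_contribution", False)):
        group = [c for c in calls if c.maternal_contribution is keep]
        out[name] = (sum(c.outcome == "GTN" for c in group), len(group))
    return out


def gtn_stratification(report: CohortReport) -> dict[str, dict]:
    """GTN incidence per maternal-contribution stratum and overall."""
    def entry(g, n):
        return {"gtn": g, "n": n, "proportion": (g / n if n else float("nan"))}

    out = {name: entry(*gn) for name, gn in report.gtn_by_stratum.items()}
    out["overall"] = entry(*report.gtn_overall)
    return out


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    zero_margin: bool = False


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2×2 table of counts.

    Uses the probability-ordering convention: the p-value sums the
    hypergeometric probabilities of every table with the same margins whose
    probability does not exceed the observed one.  Computed in exact
    integer arithmetic (ratios of binomial coefficients), so ties are
    resolved exactly rather than through floating-point tolerances.  A
    table with an empty margin carries no information: p = 1, flagged.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise DataError("contingency table cells must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        odds = float("nan")
        return FisherResult(1.0, odds, zero_margin=True)

    observed = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(n, c1)
    numerator = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        weight = math.comb(r1, x) * math.comb(r2, c1 - x)
        if weight <= observed:
            numerator += weight
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return FisherResult(numerator / total, odds)


def report_to_dict(report: CohortReport) -> dict:
    return {
        "n_cases": report.n_cases,
        "n_euploid": report.n_euploid,
        "n_aneuploid": report.n_aneuploid,
        "aneuploidy_percent": report.aneuploidy_percent,
        "n_maternal_extras": report.n_maternal_extras,
        "n_paternal_extras": report.n_paternal_extras,
        "n_biparental_disomies": report.n_biparental_disomies,
        "gtn": gtn_stratification(report),
        "fisher_gtn_p": report.fisher_gtn_p,
        "cases": report.cases.to_dict(orient="records"),
    }
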