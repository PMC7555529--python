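"""Conceptus classification from mole + maternal STR profiles.

The zygosity rules are the forensic-style ones used in molar diagnostics:
a villous sample that fails to share any allele with the mother at one or
more loci is androgenetic; an androgenetic mole with at least one
two-allele locus is dispermic, and one with a single allele at every locus
is monospermic.  Any locus showing three or more distinct alleles raises a
triploidy suspicion.  Peak heights are not modelled — only allele sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError
from .sample import StrProfile

CATEGORIES = (
    "androgenetic_monospermic",
    "androgenetic_dispermic",
    "biparental_diploid",
    "triploid_suspect",
    "indeterminate",
)

#: Minimum loci typed in both profiles for a classification attempt.
MIN_SHARED_LOCI = 8


@dataclass(frozen=True)
class LocusEvidence:
    locus: str
    mole_alleles: tuple[str, ...]
    maternal_alleles: tuple[str, ...]
    shares_maternal: bool
    n_alleles: int


@dataclass(frozen=True)
class ConceptusClass:
    category: str
    evidence: tuple[LocusEvidence, ...] = ()
    reason: str = ""

    #: Loci that decided the call (no maternal allele shared, or >= 3 alleles).
    deciding_loci: tuple[str, ...] = field(default=())


def _shared_evidence(mole: StrProfile, mother: StrProfile) -> list[LocusEvidence]:
    shared = sorted(set(mole.alleles) & set(mother.alleles))
    out = []
    for locus in shared:
        ma, pa = mole.alleles[locus], mother.alleles[locus]
        out.append(LocusEvidence(
            locus=locus, mole_alleles=ma, maternal_alleles=pa,
            shares_maternal=bool(set(ma) & set(pa)), n_alleles=len(ma),
        ))
    return out


def classify_conceptus(mole: StrProfile, mother: StrProfile) -> ConceptusClass:
    """Apply the allele-sharing rules to a mole/mother duo.

    Returns ``indeterminate`` (with a reason) when fewer than
    ``MIN_SHARED_LOCI`` loci are typed in both profiles.
    """
    evidence = _shared_evidence(mole, mother)
    if len(evidence) < MIN_SHARED_LOCI:
        return ConceptusClass(
            "indeterminate", tuple(evidence),
            reason=f"only {len(evidence)} shared loci (need {MIN_SHARED_LOCI})",
        )

    multi = [e.locus for e in evidence if e.n_alleles >= 3]
    if multi:
        return ConceptusClass("triploid_suspect", tuple(evidence),
                              reason="locus with three or more alleles",
                              deciding_loci=tuple(multi))

    unshared = [e.locus for e in evidence if not e.shares_maternal]
    if unshared:
        biallelic = [e.locus for e in evidence if e.n_alleles == 2]
        category = "androgenetic_dispermic" if biallelic else "androgenetic_monospermic"
        return ConceptusClass(category, tuple(evidence),
                              deciding_loci=tuple(unshared))

    # every locus shares a maternal allele: consistent with a biparental
    # conception (an androgenetic mole would need a very unusual duo)
    return ConceptusClass("biparental_diploid", tuple(evidence),
                          reason="all loci share a maternal allele")


def count_biallelic_loci(profile: StrProfile) -> int:
    """Number of loci showing exactly two distinct alleles."""
    return sum(1 for alleles in profile.alleles.values() if len(alleles) == 2)


def classification_to_dict(result: ConceptusClass) -> dict:
    return {
        "category": result.category,
        "reason": result.reason,
        "deciding_loci": list(result.deciding_loci),
        "evidence": [
            {
                "locus": e.locus,
                "mole_alleles": list(e.mole_alleles),
                "maternal_alleles": list(e.maternal_alleles),
                "shares_maternal": e.shares_maternal,
                "n_alleles": e.n_alleles,
            }
            for e in result.evidence
        ],
    }
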