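"""Parent-of-origin inference from a mole/mother duo: the selected-BAF test.

Restrict the mole's BAF to loci where the mother's genotype is AA.  On
those loci the mother can only have transmitted an A allele, so any
chromosome that carries a maternal homolog cannot reach BAF 1 — its true
BAF is capped at (n−1)/n.  An entirely paternal chromosome, by contrast,
retains a BAF≈1 band (the mole can be BB/BBB there regardless of the
mother).  Loss of the top band on a trisomic chromosome therefore marks a
maternal extra homolog; loss on a disomic chromosome marks a biparental
disomy inside an otherwise androgenetic genome.

The retention statistic is the observed fraction of selected loci with
BAF above ``top_band_cut``, divided by the fraction expected if every
homolog were paternal.  The expectation is computed analytically from
panel allele frequencies (probability that all n homologs carry B),
or empirically as the median observed fraction over confidently
all-paternal chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .karyotype import ChromosomeCall
from .panel import AUTOSOMES, LocusPanel
from .sample import SnpArraySample


@dataclass(frozen=True)
class OriginConfig:
    """Numeric surrogates for the visual "loss of plots near 1.0" read-out.

    ``top_band_cut`` = 0.85 separates the BB band from the ABB band at 2/3
    given BAF noise around 0.03; ``loss_threshold`` calls a loss when the
    retention statistic falls below a quarter of its all-paternal
    expectation; ``min_selected`` guards sparse chromosomes."""

    top_band_cut: float = 0.85
    loss_threshold: float = 0.25
    min_selected: int = 30
    min_shared_fraction: float = 0.90


DEFAULT_ORIGIN_CONFIG = OriginConfig()


@dataclass
class SelectedBafSet:
    """Mole BAF restricted to maternal-AA loci, keyed by chromosome.

    Each per-chromosome frame has columns ``snp_name``, ``position``,
    ``baf``."""

    by_chrom: dict[str, pd.DataFrame]

    _EMPTY = pd.DataFrame(columns=["snp_name", "position", "baf"])

    def loci(self, chromosome: str) -> pd.DataFrame:
        return self.by_chrom.get(chromosome, self._EMPTY)

    def selected_ids(self) -> set[str]:
        out: set[str] = set()
        for df in self.by_chrom.values():
            out |= set(df["snp_name"])
        return out

    def n_selected(self, chromosome: str) -> int:
        return len(self.loci(chromosome))


def select_loci_maternal_AA(
    mole: SnpArraySample,
    mother: SnpArraySample,
    config: OriginConfig = DEFAULT_ORIGIN_CONFIG,
    genotype: str = "AA",
) -> SelectedBafSet:
    """Keep exactly the loci where the maternal genotype call is AA.

    Maternal no-calls are excluded.  The two samples must share at least
    ``min_shared_fraction`` of their loci, otherwise the duo is rejected
    as mismatched.  ``genotype="BB"`` gives the mirrored selection used as
    a cross-check (the maternal-BB loci, where a maternal homolog forces
    BAF > 0 and the diagnostic band is the one at BAF ≈ 0).
    """
    if genotype not in ("AA", "BB"):
        raise DataError("selection genotype must be AA or BB")
    mole_df = mole.data
    mother_df = mother.data
    aligned = (len(mole_df) == len(mother_df)
               and np.array_equal(mole_df["snp_name"].to_numpy(),
                                  mother_df["snp_name"].to_numpy()))
    if aligned:
        keep = mole_df[(mother_df["gtype"].to_numpy() == genotype)]
    else:
        shared = set(mole_df["snp_name"]) & set(mother_df["snp_name"])
        need = config.min_shared_fraction * max(len(mole_df), len(mother_df))
        if len(shared) < need:
            raise DataError(
                f"duo shares only {len(shared)} loci "
                f"(need >= {need:.0f}); sample mismatch?")
        aa = mother_df.loc[mother_df["gtype"] == genotype, "snp_name"]
        keep = mole_df[mole_df["snp_name"].isin(set(aa) & shared)]
    keep = keep[np.isfinite(keep["baf"])]
    by_chrom = {
        chrom: sub[["snp_name", "position", "baf"]].reset_index(drop=True)
        for chrom, sub in keep.groupby("chrom", sort=False)
    }
    return SelectedBafSet(by_chrom)


@dataclass(frozen=True)
class RetentionResult:
    chromosome: str
    observed_fraction: float
    expected_fraction: float
    statistic: float
    n_selected: int
    determined: bool
    reason: str = ""


def expected_top_fraction(panel: LocusPanel, selected: SelectedBafSet,
                          chromosome: str, copy_number: int) -> float:
    """Analytic all-paternal expectation: mean over the selected loci of the
    probability that all ``copy_number`` homologs carry the B allele.

    Homologs are treated as independent draws from the population
    frequency; shared paternal haplotypes in a dispermic mole make the
    true retention larger, never smaller, so the analytic expectation is a
    conservative denominator for loss detection.
    """
    sel = selected.loci(chromosome)
    freqs = panel.freq_by_id.reindex(sel["snp_name"].to_numpy()).dropna()
    if len(freqs) == 0:
        return float("nan")
    return float(np.mean(freqs.to_numpy() ** copy_number))


def expected_bottom_fraction(panel: LocusPanel, selected: SelectedBafSet,
                             chromosome: str, copy_number: int) -> float:
    """Mirrored expectation: probability all homologs carry A."""
    sel = selected.loci(chromosome)
    freqs = panel.freq_by_id.reindex(sel["snp_name"].to_numpy()).dropna()
    if len(freqs) == 0:
        return float("nan")
    return float(np.mean((1.0 - freqs.to_numpy()) ** copy_number))


def top_band_retention(
    selected: SelectedBafSet,
    chromosome: str,
    copy_number: int,
    panel: LocusPanel | None = None,
    expected_fraction: float | None = None,
    config: OriginConfig = DEFAULT_ORIGIN_CONFIG,
    mirrored: bool = False,
) -> RetentionResult:
    """Measure retention of the BAF≈1 band among selected loci.

    ``expected_fraction`` may be supplied directly (empirical mode);
    otherwise ``panel`` must be given for the analytic expectation.
    With ``mirrored=True`` the set must come from maternal-BB selection and
    the band tested is the one at BAF ≈ 0 (diagnostic cross-check only).
    """
    sel = selected.loci(chromosome)
    n = len(sel)
    if n < config.min_selected:
        return RetentionResult(chromosome, float("nan"), float("nan"),
                               float("nan"), n, determined=False,
                               reason=f"only {n} selected loci (need {config.min_selected})")
    baf = sel["baf"].to_numpy()
    observed = float(np.mean(baf <= 1.0 - config.top_band_cut) if mirrored
                     else np.mean(baf >= config.top_band_cut))
    if expected_fraction is None:
        if panel is None:
            raise DataError("need a panel or an explicit expected_fraction")
        expect = expected_bottom_fraction if mirrored else expected_top_fraction
        expected_fraction = expect(panel, selected, chromosome, copy_number)
    if not np.isfinite(expected_fraction) or expected_fraction <= 0:
        return RetentionResult(chromosome, observed, float(expected_fraction),
                               float("nan"), n, determined=False,
                               reason="no usable all-paternal expectation")
    return RetentionResult(chromosome, observed, float(expected_fraction),
                           observed / expected_fraction, n, determined=True)


@dataclass(frozen=True)
class OriginCall:
    chromosome: str
    copy_number: int
    maternal_contribution: bool
    extra_origin: str  # "maternal" | "paternal" | "n/a"
    biparental_disomy: bool
    retention: RetentionResult
    threshold: float

    @property
    def determined(self) -> bool:
        return self.retention.determined


def call_origin(
    mole: SnpArraySample,
    mother: SnpArraySample,
    chromosome_call: ChromosomeCall,
    panel: LocusPanel | None = None,
    selected: SelectedBafSet | None = None,
    config: OriginConfig = DEFAULT_ORIGIN_CONFIG,
) -> OriginCall:
    """Decide maternal vs paternal contribution for one called chromosome.

    For a trisomic chromosome, a lost top band means the extra homolog is
    maternal; a retained band means it is paternal.  For a disomic
    chromosome a lost band flags a biparental disomy.  Requires an
    unambiguous copy-number call.
    """
    cn = chromosome_call.copy_number
    if cn == "ambiguous":
        raise DataError(
            f"chromosome {chromosome_call.chromosome}: copy number ambiguous; "
            "origin not callable")
    if selected is None:
        selected = select_loci_maternal_AA(mole, mother, config)
    retention = top_band_retention(selected, chromosome_call.chromosome,
                                   int(cn), panel=panel, config=config)
    maternal = bool(retention.determined
                    and retention.statistic < config.loss_threshold)
    return OriginCall(
        chromosome=chromosome_call.chromosome,
        copy_number=int(cn),
        maternal_contribution=maternal,
        extra_origin=("n/a" if cn < 3 or not retention.determined
                      else ("maternal" if maternal else "paternal")),
        biparental_disomy=bool(cn == 2 and maternal),
        retention=retention,
        threshold=config.loss_threshold,
    )


@dataclass
class MitoIdentityReport:
    """Cohort-wide mitochondrial genotype comparison.

    ``informative_loci`` are the MT loci with at least two distinct called
    genotypes across the samples; ``mismatches`` counts, for each sample
    pair, informative loci with differing called genotypes (no-calls
    ignored)."""

    informative_loci: list[str]
    mismatches: pd.DataFrame

    def identical(self, a: str, b: str) -> bool:
        return int(self.mismatches.loc[a, b]) == 0


def mito_identity(samples: list[SnpArraySample]) -> MitoIdentityReport:
    """Compare mitochondrial genotypes across samples.

    A mole and its mother must be identical at every informative MT locus
    (the mitochondrial genome is maternally inherited); a mismatch flags a
    sample swap or an unrelated duo.  A single-sample cohort trivially has
    no informative loci.
    """
    if not samples:
        raise DataError("mitochondrial identity needs at least one sample")
    genotypes = {}
    for s in samples:
        g = s.mt_genotypes()
        if g.empty:
            raise DataError(f"sample {s.sample_id} has no MT loci")
        genotypes[s.sample_id] = g
    table = pd.DataFrame(genotypes)

    called = table.where(table != "NC")
    n_distinct = called.nunique(axis=1, dropna=True)
    informative = list(n_distinct.index[n_distinct >= 2])

    ids = list(genotypes)
    mism = pd.DataFrame(0, index=ids, columns=ids)
    sub = called.loc[informative]
    for i, a in enumerate(ids):
        va = sub[a]
        for b in ids[i + 1:]:
            vb = sub[b]
            diff = int(((va != vb) & va.notna() & vb.notna()).sum())
            mism.loc[a, b] = mism.loc[b, a] = diff
    return MitoIdentityReport(informative, mism)


def origin_calls_for_sample(
    mole: SnpArraySample,
    mother: SnpArraySample,
    calls: dict[str, ChromosomeCall],
    panel: LocusPanel | None = None,
    config: OriginConfig = DEFAULT_ORIGIN_CONFIG,
) -> dict[str, OriginCall]:
    """Run the origin caller over every unambiguous autosomal call, sharing
    one locus selection."""
    selected = select_loci_maternal_AA(mole, mother, config)
    out = {}
    for chrom in AUTOSOMES:
        call = calls.get(chrom)
        if call is None or call.copy_number == "ambiguous":
            continue
        out[chrom] = call_origin(mole, mother, call, panel=panel,
                                 selected=selected, config=config)
    return out


def origin_to_dict(call: OriginCall) -> dict:
    r = call.retention
    return {
        "chromosome": call.chromosome,
        "copy_number": call.copy_number,
        "maternal_contribution": call.maternal_contribution,
        "extra_origin": call.extra_origin,
        "biparental_disomy": call.biparental_disomy,
        "retention": {
            "observed_fraction": r.observed_fraction,
            "expected_fraction": r.expected_fraction,
            "statistic": r.statistic,
            "n_selected": r.n_selected,
            "determined": r.determined,
            "reason": r.reason,
        },
        "threshold": call.threshold,
    }
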