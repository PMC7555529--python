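"""Per-chromosome copy-number calling from BAF band structure and LRR shift.

At copy number n the BAF of a locus with k B alleles clusters at k/n, so a
heterozygous disomic chromosome shows bands {0, 0.5, 1}, a trisomic one
{0, 1/3, 2/3, 1}, and a fully homozygous chromosome only {0, 1} whatever
its copy number.  Band occupancy disambiguates copy number where
intermediate bands exist; the median LRR (ideally attenuation × log2(n/2))
decides the homozygous cases and must agree with the band pattern,
otherwise the chromosome is flagged ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .panel import AUTOSOMES
from .sample import SnpArraySample

#: Band levels that distinguish copy hypotheses when occupied.
_THIRD = (1.0 / 3.0, 2.0 / 3.0)
_QUARTER = (0.25, 0.75)
_HALF = 0.5


@dataclass(frozen=True)
class BandModel:
    """Theoretical BAF bands for one copy hypothesis.

    ``tolerance`` is the half-width of the window around each level;
    a band is "present" when at least ``min_occupancy`` of the chromosome's
    called loci (and at least ``min_band_loci`` of them) fall in its window.
    """

    copy_n: int
    tolerance: float = 0.08
    min_occupancy: float = 0.02
    min_band_loci: int = 10

    def __post_init__(self) -> None:
        if self.copy_n not in (1, 2, 3, 4):
            raise ConfigError("copy hypothesis must be 1..4")
        gap = 1.0 / self.copy_n
        if self.tolerance >= gap / 2:
            raise ConfigError(
                f"tolerance {self.tolerance} does not separate bands at copy {self.copy_n}")

    @property
    def levels(self) -> tuple[float, ...]:
        n = self.copy_n
        return tuple(k / n for k in range(n + 1))


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the copy-number and sex caller.

    ``lrr_gain_threshold`` defaults to half the ideal trisomy shift
    (0.5 × attenuation × log2(1.5) ≈ 0.29 at attenuation 1);
    ``lrr_ambiguity_margin`` flags chromosomes whose median LRR does not
    clearly prefer one copy hypothesis.
    """

    band_tolerance: float = 0.08
    min_band_occupancy: float = 0.02
    min_band_loci: int = 10
    min_loci: int = 50
    lrr_attenuation: float = 1.0
    lrr_gain_threshold: float | None = None
    lrr_ambiguity_margin: float = 0.05
    y_presence_call_rate: float = 0.5

    @property
    def gain_threshold(self) -> float:
        if self.lrr_gain_threshold is not None:
            return self.lrr_gain_threshold
        return 0.5 * self.lrr_attenuation * math.log2(1.5)

    def expected_lrr(self, copy_n: int) -> float:
        return self.lrr_attenuation * math.log2(copy_n / 2)

    def band_model(self, copy_n: int) -> BandModel:
        return BandModel(copy_n, self.band_tolerance,
                         self.min_band_occupancy, self.min_band_loci)


DEFAULT_CONFIG = CallerConfig()


@dataclass(frozen=True)
class ChromosomeCall:
    chromosome: str
    copy_number: int | str  # 1..4 or "ambiguous"
    band_occupancy: dict[float, float]
    lrr_median: float
    lrr_mean: float
    n_loci: int
    confident: bool
    reason: str = ""


def baf_band_profile(sample: SnpArraySample, chromosome: str,
                     model: BandModel) -> dict[float, float]:
    """Fraction of called loci within ``model.tolerance`` of each band level.

    Raises :class:`DataError` when the chromosome has fewer than 50 called
    loci — too sparse for band statistics.
    """
    called = sample.called(chromosome)
    if len(called) < 50:
        raise DataError(
            f"chromosome {chromosome}: only {len(called)} called loci for band profile")
    baf = called["baf"].to_numpy()
    return {level: float(np.mean(np.abs(baf - level) <= model.tolerance))
            for level in model.levels}


def _bands_present(sample: SnpArraySample, chromosome: str,
                   config: CallerConfig) -> tuple[dict[float, float], set[float], int]:
    """Occupancy and presence over the union of all hypothesis levels."""
    called = sample.called(chromosome)
    n = len(called)
    if n < config.min_loci:
        raise DataError(f"chromosome {chromosome}: only {n} called loci")
    baf = called["baf"].to_numpy()
    levels = sorted({0.0, 1.0, _HALF, *_THIRD, *_QUARTER})
    occupancy = {lv: float(np.mean(np.abs(baf - lv) <= config.band_tolerance))
                 for lv in levels}
    present = {lv for lv, occ in occupancy.items()
               if occ >= config.min_band_occupancy and occ * n >= config.min_band_loci}
    return occupancy, present, n


def call_copy_number(sample: SnpArraySample, chromosome: str,
                     config: CallerConfig = DEFAULT_CONFIG) -> ChromosomeCall:
    """Call the copy number of one chromosome.

    Intermediate-band logic: occupied bands at 1/3 and 2/3 demand copy 3,
    at 1/4 and 3/4 copy 4, and at 1/2 copy 2 — each confirmed by the median
    LRR.  A chromosome showing only the homozygous bands {0, 1} is decided
    by whichever copy hypothesis its median LRR is closest to; when two
    hypotheses are nearly equally close the call is ambiguous, as it is
    whenever bands and LRR disagree.
    """
    try:
        occupancy, present, n = _bands_present(sample, chromosome, config)
    except DataError as exc:
        return ChromosomeCall(chromosome, "ambiguous", {}, float("nan"),
                              float("nan"), 0, False, reason=str(exc))
    sub = sample.chrom_data(chromosome)
    lrr = sub["lrr"].to_numpy()
    lrr = lrr[np.isfinite(lrr)]
    med, mean = float(np.median(lrr)), float(np.mean(lrr))

    has_third = all(lv in present for lv in _THIRD)
    has_quarter = all(lv in present for lv in _QUARTER)
    has_half = _HALF in present
    thr = config.gain_threshold

    def call(copy_n, confident=True, reason=""):
        return ChromosomeCall(chromosome, copy_n, occupancy, med, mean, n,
                              confident, reason)

    if has_quarter and not has_third:
        midpoint = (config.expected_lrr(3) + config.expected_lrr(4)) / 2
        if med > midpoint:
            return call(4)
        return call("ambiguous", False, "quarter bands without tetrasomic LRR shift")
    if has_third:
        if med > thr:
            return call(3)
        return call("ambiguous", False, "trisomic bands without LRR shift")
    if has_half:
        if abs(med) <= thr:
            return call(2)
        return call("ambiguous", False, "heterozygous disomic bands with shifted LRR")

    # only homozygous bands: copy number from LRR proximity alone
    dists = {cn: abs(med - config.expected_lrr(cn)) for cn in (1, 2, 3, 4)}
    ranked = sorted(dists, key=dists.get)
    best, second = ranked[0], ranked[1]
    if dists[second] - dists[best] < config.lrr_ambiguity_margin:
        return call("ambiguous", False, "LRR between copy-number expectations")
    return call(best)


def call_sex(sample: SnpArraySample,
             config: CallerConfig = DEFAULT_CONFIG) -> str:
    """Call the sex-chromosome constitution (XX/XY/XYY/XXYY/ambiguous).

    Y presence is decided by the Y-locus call rate (absent Y renders as
    no-calls); Y copy number then comes from the Y median LRR, X copy
    number from the X band/LRR logic.
    """
    x_data = sample.chrom_data("X")
    y_data = sample.chrom_data("Y")
    if len(x_data) == 0 or len(y_data) == 0:
        raise DataError("panel has no sex-chromosome loci")

    y_called = float(np.mean(y_data["gtype"].to_numpy() != "NC"))
    n_y = 0
    if y_called >= config.y_presence_call_rate:
        y_lrr = y_data["lrr"].to_numpy()
        med = float(np.median(y_lrr[np.isfinite(y_lrr)]))
        n_y = 1 if med < -0.5 * config.lrr_attenuation else 2

    x_call = call_copy_number(sample, "X", config)
    if x_call.copy_number == "ambiguous":
        return "ambiguous"
    constitution = "X" * int(x_call.copy_number) + "Y" * n_y
    return constitution if constitution in ("XX", "XY", "XYY", "XXYY") else "ambiguous"


@dataclass(frozen=True)
class KaryotypeEstimate:
    """Assembled molecular karyotype, e.g. ``47,XY,+13``."""

    total: int
    sex: str
    gains: tuple[str, ...]
    losses: tuple[str, ...]
    confident: bool
    calls: dict[str, ChromosomeCall] = field(default_factory=dict)

    @property
    def string(self) -> str:
        parts = [str(self.total), self.sex]
        parts += [f"+{c}" for c in self.gains]
        parts += [f"-{c}" for c in self.losses]
        return ",".join(parts)

    @property
    def euploid(self) -> bool:
        return not self.gains and not self.losses and self.sex in ("XX", "XY")


def estimate_karyotype(sample: SnpArraySample,
                       config: CallerConfig = DEFAULT_CONFIG) -> KaryotypeEstimate:
    """Call every autosome plus the sex constitution and assemble the
    karyotype string.  Any ambiguous autosome or sex call makes the
    estimate non-confident."""
    calls = {c: call_copy_number(sample, c, config) for c in AUTOSOMES}
    sex = call_sex(sample, config)

    gains: list[str] = []
    losses: list[str] = []
    confident = sex != "ambiguous"
    for chrom in AUTOSOMES:
        cn = calls[chrom].copy_number
        if cn == "ambiguous":
            confident = False
        elif cn == 3:
            gains.append(chrom)
        elif cn == 4:
            gains += [chrom, chrom]
        elif cn == 1:
            losses.append(chrom)

    n_sex = len(sex) if sex != "ambiguous" else 2
    total = 44 + n_sex + len(gains) - len(losses)
    return KaryotypeEstimate(total=total, sex=sex, gains=tuple(gains),
                             losses=tuple(losses), confident=confident, calls=calls)


def lrr_shift_summary(sample: SnpArraySample) -> pd.DataFrame:
    """Median and mean LRR per chromosome, the diagnostic that shifts to the
    right (larger) on trisomic chromosomes."""
    rows = []
    for chrom in sample.chromosomes:
        if chrom == "MT":
            continue
        lrr = sample.chrom_data(chrom)["lrr"].to_numpy()
        lrr = lrr[np.isfinite(lrr)]
        if lrr.size == 0:
            continue
        rows.append((chrom, float(np.median(lrr)), float(np.mean(lrr)), lrr.size))
    return pd.DataFrame(rows, columns=["chrom", "lrr_median", "lrr_mean", "n_loci"])


def karyotype_to_dict(estimate: KaryotypeEstimate) -> dict:
    return {
        "karyotype": estimate.string,
        "total": estimate.total,
        "sex": estimate.sex,
        "gains": list(estimate.gains),
        "losses": list(estimate.losses),
        "confident": estimate.confident,
        "calls": {
            chrom: {
                "copy_number": call.copy_number,
                "lrr_median": call.lrr_median,
                "lrr_mean": call.lrr_mean,
                "n_loci": call.n_loci,
                "confident": call.confident,
                "reason": call.reason,
            }
            for chrom, call in estimate.calls.items()
        },
    }
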