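"""SNP locus panels, genetic maps and the STR marker panel.

A :class:`LocusPanel` is the universe of array loci the simulator and the
callers operate on: for every locus it stores the chromosome, the physical
position and the population frequency of the B allele.  The default panel is
exome-array-like: ~20k autosomal loci, 800 on X, 100 on Y and 208
mitochondrial loci, with B-allele population frequencies drawn once from
Uniform(0.05, 0.95).

A :class:`GeneticMap` gives each chromosome a genetic length in Morgans and
maps physical position to genetic position linearly.  The Y chromosome and
the mitochondrial genome do not recombine (length 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y", "MT")

#: Approximate physical chromosome lengths in bp (human reference scale).
CHROM_LENGTH_BP: dict[str, int] = {
    "1": 249_250_000, "2": 243_200_000, "3": 198_000_000, "4": 191_150_000,
    "5": 180_900_000, "6": 171_100_000, "7": 159_100_000, "8": 146_360_000,
    "9": 141_200_000, "10": 135_530_000, "11": 135_000_000, "12": 133_850_000,
    "13": 115_170_000, "14": 107_350_000, "15": 102_530_000, "16": 90_350_000,
    "17": 81_190_000, "18": 78_080_000, "19": 59_130_000, "20": 63_030_000,
    "21": 48_130_000, "22": 51_300_000, "X": 155_270_000, "Y": 59_370_000,
    "MT": 16_569,
}

CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}


@dataclass(frozen=True)
class LocusPanel:
    """Ordered table of array loci.

    ``table`` has columns ``locus_id``, ``chrom``, ``position``,
    ``pop_b_freq`` and is sorted by (chromosome, position).  Positions are
    1-based and strictly increasing within a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"locus_id", "chrom", "position", "pop_b_freq"}
        missing = required - set(t.columns)
        if missing:
            raise ConfigError(f"panel table missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise ConfigError("empty locus panel")
        if t["locus_id"].duplicated().any():
            raise ConfigError("duplicate locus ids in panel")
        by_chrom = {}
        for chrom, sub in t.groupby("chrom", sort=False):
            if chrom != "MT" and not sub["position"].is_monotonic_increasing:
                raise ConfigError(f"positions not increasing on chromosome {chrom}")
            if sub["position"].duplicated().any():
                raise ConfigError(f"duplicate positions on chromosome {chrom}")
            by_chrom[chrom] = sub
        # per-chromosome views are cached: the panel is immutable by contract
        object.__setattr__(self, "_by_chrom", by_chrom)
        object.__setattr__(self, "_arrays", {})
        object.__setattr__(self, "_chromosomes",
                           [c for c in CHROMOSOMES if c in by_chrom])
        object.__setattr__(self, "_freq_by_id",
                           pd.Series(t["pop_b_freq"].to_numpy(),
                                     index=t["locus_id"].to_numpy()))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chromosomes)

    @property
    def freq_by_id(self) -> pd.Series:
        """Population B-allele frequency indexed by locus id."""
        return self._freq_by_id

    def loci(self, chrom: str) -> pd.DataFrame:
        try:
            return self._by_chrom[chrom]
        except KeyError:
            return self.table.iloc[0:0]

    def n_loci(self, chrom: str) -> int:
        return len(self.loci(chrom))

    def _array(self, chrom: str, column: str) -> np.ndarray:
        key = (chrom, column)
        if key not in self._arrays:
            self._arrays[key] = self.loci(chrom)[column].to_numpy()
        return self._arrays[key]

    def positions(self, chrom: str) -> np.ndarray:
        return self._array(chrom, "position")

    def freqs(self, chrom: str) -> np.ndarray:
        return self._array(chrom, "pop_b_freq")

    def ids(self, chrom: str) -> np.ndarray:
        return self._array(chrom, "locus_id")


def default_panel(
    n_autosomal: int = 20_000,
    n_x: int = 800,
    n_y: int = 100,
    n_mt: int = 208,
    seed: int | np.random.SeedSequence = 20_000,
) -> LocusPanel:
    """Build the default exome-array-like panel.

    Autosomal loci are apportioned to chromosomes 1..22 in proportion to
    physical length (largest-remainder rounding), positions are sorted
    uniform draws, and population B-allele frequencies are Uniform(0.05,
    0.95).  Deterministic for a given ``seed``.
    """
    if n_autosomal < 22 or n_x < 1 or n_y < 1 or n_mt < 1:
        raise ConfigError("panel needs at least one locus per chromosome")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    lengths = np.array([CHROM_LENGTH_BP[c] for c in AUTOSOMES], dtype=float)
    quota = n_autosomal * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    # largest remainder keeps the total exact
    rem = quota - counts
    for i in np.argsort(rem)[::-1][: n_autosomal - counts.sum()]:
        counts[i] += 1

    rows = []
    plan = list(zip(AUTOSOMES, counts)) + [("X", n_x), ("Y", n_y), ("MT", n_mt)]
    for chrom, n in plan:
        n = int(n)
        length = CHROM_LENGTH_BP[chrom]
        if length <= 4 * n:
            pos = np.arange(1, n + 1, dtype=np.int64)
        else:
            pos = np.unique(rng.integers(1, length + 1, size=n, dtype=np.int64))
            while pos.size < n:  # top up the rare collisions
                extra = rng.integers(1, length + 1, size=n - pos.size, dtype=np.int64)
                pos = np.unique(np.concatenate([pos, extra]))
            pos = np.sort(pos)
        freq = rng.uniform(0.05, 0.95, size=n)
        prefix = "mt" if chrom == "MT" else "snp"
        for i in range(n):
            rows.append((f"{prefix}_{chrom}_{i:05d}", chrom, int(pos[i]), float(freq[i])))
    table = pd.DataFrame(rows, columns=["locus_id", "chrom", "position", "pop_b_freq"])
    return LocusPanel(table)


@dataclass(frozen=True)
class GeneticMap:
    """Per-chromosome genetic lengths (Morgans) with a linear bp→Morgan map."""

    morgans: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, m in self.morgans.items():
            if chrom in AUTOSOMES + ("X",) and m <= 0:
                raise ConfigError(f"genetic length must be > 0 for {chrom}")
            if chrom in ("Y", "MT") and m != 0:
                raise ConfigError(f"{chrom} does not recombine; length must be 0")

    def length(self, chrom: str) -> float:
        return self.morgans[chrom]

    def genetic_position(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """Linear interpolation of physical position onto the genetic scale."""
        return np.asarray(bp, dtype=float) / CHROM_LENGTH_BP[chrom] * self.morgans[chrom]


def default_genetic_map() -> GeneticMap:
    """Autosome/X lengths 1.0–2.8 Morgans scaled linearly by physical size."""
    recombining = AUTOSOMES + ("X",)
    lengths = np.array([CHROM_LENGTH_BP[c] for c in recombining], dtype=float)
    lo, hi = lengths.min(), lengths.max()
    morgans = {c: 1.0 + 1.8 * (CHROM_LENGTH_BP[c] - lo) / (hi - lo) for c in recombining}
    morgans["Y"] = 0.0
    morgans["MT"] = 0.0
    return GeneticMap(morgans)


@dataclass(frozen=True)
class StrLocus:
    name: str
    chrom: str
    position: int
    alleles: tuple[str, ...]
    freqs: tuple[float, ...]


@dataclass(frozen=True)
class StrPanel:
    """Forensic-style STR panel: 15 polymorphic autosomal loci + a sex marker.

    Locus names follow the common 16-plex kits; allele designations are
    repeat numbers with uniform population frequencies (real kit frequency
    tables are not redistributed here).  The sex marker ("AMEL") is handled
    by chromosome content, not by frequency draws.
    """

    loci: tuple[StrLocus, ...]
    sex_marker: str = "AMEL"

    def autosomal(self) -> tuple[StrLocus, ...]:
        return self.loci

    def names(self) -> list[str]:
        return [l.name for l in self.loci] + [self.sex_marker]


_STR_LAYOUT = [
    # (name, chrom, position Mb, n alleles, first repeat number)
    ("D3S1358", "3", 45_580_000, 8, 12),
    ("TH01", "11", 2_190_000, 7, 5),
    ("D21S11", "21", 20_550_000, 10, 26),
    ("D18S51", "18", 60_950_000, 10, 10),
    ("PentaE", "15", 97_370_000, 10, 7),
    ("D5S818", "5", 123_110_000, 7, 7),
    ("D13S317", "13", 82_720_000, 8, 8),
    ("D7S820", "7", 83_790_000, 8, 6),
    ("D16S539", "16", 86_380_000, 8, 5),
    ("CSF1PO", "5", 149_450_000, 7, 7),
    ("PentaD", "21", 45_060_000, 9, 8),
    ("vWA", "12", 6_090_000, 8, 13),
    ("D8S1179", "8", 125_900_000, 9, 8),
    ("TPOX", "2", 1_490_000, 6, 6),
    ("FGA", "4", 155_510_000, 10, 18),
]


def default_str_panel() -> StrPanel:
    loci = []
    for name, chrom, pos, n_alleles, first in _STR_LAYOUT:
        alleles = tuple(str(first + i) for i in range(n_alleles))
        freqs = tuple([1.0 / n_alleles] * n_alleles)
        loci.append(StrLocus(name, chrom, pos, alleles, freqs))
    return StrPanel(tuple(loci))
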