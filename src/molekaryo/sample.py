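"""In-memory containers for rendered data: SNP-array samples and STR profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .panel import CHROM_ORDER

GTYPES = ("AA", "AB", "BB", "NC")

#: Column layout of the per-locus table backing :class:`SnpArraySample`.
ARRAY_COLUMNS = ("snp_name", "chrom", "position", "gtype", "baf", "lrr")


@dataclass
class SnpArraySample:
    """Per-locus array records for one individual.

    ``data`` holds one row per locus with columns ``snp_name``, ``chrom``,
    ``position``, ``gtype`` (AA/AB/BB/NC), ``baf`` and ``lrr``; rows are
    sorted by (chromosome, position).  ``NC`` marks a no-call; its BAF/LRR
    values are retained as the array software reports them.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ARRAY_COLUMNS) - set(self.data.columns)
        if missing:
            raise DataError(f"sample table missing columns: {sorted(missing)}")
        bad = set(self.data["gtype"].unique()) - set(GTYPES)
        if bad:
            raise DataError(f"invalid genotype calls: {sorted(bad)}")
        # rows never change after construction; cache per-chromosome views
        self._by_chrom = dict(tuple(self.data.groupby("chrom", sort=False)))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def chromosomes(self) -> list[str]:
        present = set(self.data["chrom"])
        return [c for c in CHROM_ORDER if c in present]

    def chrom_data(self, chrom: str) -> pd.DataFrame:
        try:
            return self._by_chrom[chrom]
        except KeyError:
            return self.data.iloc[0:0]

    def called(self, chrom: str) -> pd.DataFrame:
        """Loci on ``chrom`` with a genotype call and a finite BAF."""
        sub = self.chrom_data(chrom)
        return sub[(sub["gtype"] != "NC") & np.isfinite(sub["baf"])]

    def mt_genotypes(self) -> pd.Series:
        sub = self.chrom_data("MT")
        return pd.Series(sub["gtype"].to_numpy(), index=sub["snp_name"].to_numpy())

    @staticmethod
    def sort_table(data: pd.DataFrame) -> pd.DataFrame:
        key = data["chrom"].map(CHROM_ORDER)
        return (data.assign(_k=key)
                    .sort_values(["_k", "position"], kind="mergesort")
                    .drop(columns="_k")
                    .reset_index(drop=True))


def allele_sort_key(allele: str):
    """Numeric designations sort numerically; X/Y and variants after."""
    try:
        return (0, float(allele), allele)
    except ValueError:
        return (1, 0.0, allele)


@dataclass(frozen=True)
class StrProfile:
    """Allele-set genotypes over a forensic STR panel for one individual.

    ``alleles`` maps locus name to the sorted tuple of distinct allele
    designations observed (1–4 per locus).  Peak heights are not modelled;
    a locus shows the *set* of alleles its homologs carry.
    """

    sample_id: str
    alleles: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for locus, obs in self.alleles.items():
            if not 1 <= len(obs) <= 4:
                raise DataError(f"locus {locus}: {len(obs)} alleles (expected 1-4)")
            if len(set(obs)) != len(obs):
                raise DataError(f"locus {locus}: duplicate alleles in set")

    def loci(self) -> list[str]:
        return list(self.alleles)

    def n_alleles(self, locus: str) -> int:
        return len(self.alleles[locus])
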