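"""Readers/writers for the tabular formats the pipeline touches.

Final-report TSV: the tab-delimited export dialect of array genotyping
software, with a ``[Header]`` key/value block followed by a ``[Data]``
section whose columns are Sample ID, SNP Name, Chr, Position, GType,
B Allele Freq, Log R Ratio.  STR tables are plain CSV with one row per
(sample, locus) and semicolon-separated allele designations.
"""

from __future__ import annotations

import csv
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .panel import CHROM_ORDER, StrPanel
from .sample import GTYPES, SnpArraySample, StrProfile, allele_sort_key

FINAL_REPORT_COLUMNS = (
    "Sample ID", "SNP Name", "Chr", "Position", "GType",
    "B Allele Freq", "Log R Ratio",
)

_INTERNAL = ("sample_id", "snp_name", "chrom", "position", "gtype", "baf", "lrr")


def read_final_report(path) -> dict[str, SnpArraySample]:
    """Parse a final-report TSV into one :class:`SnpArraySample` per sample.

    ``NC`` genotype rows are kept as missing calls; an empty BAF/LRR field
    becomes NaN; a non-numeric BAF/LRR or Position raises :class:`DataError`,
    as do missing mandatory columns and duplicate (sample, locus) rows.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    try:
        data_start = next(i for i, l in enumerate(lines) if l.strip() == "[Data]")
    except StopIteration:
        raise DataError(f"{path}: no [Data] section")
    if data_start + 1 >= len(lines):
        raise DataError(f"{path}: [Data] section has no column header")

    header = lines[data_start + 1].split("\t")
    for col in FINAL_REPORT_COLUMNS:
        if col not in header:
            raise DataError(f"{path}: missing mandatory column {col!r}")
    idx = {col: header.index(col) for col in FINAL_REPORT_COLUMNS}

    records: dict[str, list] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines[data_start + 2:], start=data_start + 3):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise DataError(f"{path}:{lineno}: expected {len(header)} fields")
        sid = fields[idx["Sample ID"]]
        snp = fields[idx["SNP Name"]]
        if (sid, snp) in seen:
            raise DataError(f"{path}:{lineno}: duplicate record for ({sid}, {snp})")
        seen.add((sid, snp))
        gtype = fields[idx["GType"]]
        if gtype not in GTYPES:
            raise DataError(f"{path}:{lineno}: invalid GType {gtype!r}")
        records.setdefault(sid, []).append((
            snp,
            fields[idx["Chr"]],
            _parse_int(fields[idx["Position"]], path, lineno, "Position"),
            gtype,
            _parse_float(fields[idx["B Allele Freq"]], path, lineno, "B Allele Freq"),
            _parse_float(fields[idx["Log R Ratio"]], path, lineno, "Log R Ratio"),
        ))

    out = {}
    for sid, rows in records.items():
        df = pd.DataFrame(rows, columns=["snp_name", "chrom", "position",
                                         "gtype", "baf", "lrr"])
        bad_baf = df["baf"].dropna()
        if ((bad_baf < 0) | (bad_baf > 1)).any():
            raise DataError(f"{path}: BAF outside [0, 1] for sample {sid}")
        out[sid] = SnpArraySample(sid, SnpArraySample.sort_table(df))
    return out


def _parse_int(text: str, path, lineno: int, col: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise DataError(f"{path}:{lineno}: malformed {col} value {text!r}")


def _parse_float(text: str, path, lineno: int, col: str) -> float:
    if text.strip() == "":
        return float("nan")
    try:
        return float(text)
    except ValueError:
        raise DataError(f"{path}:{lineno}: malformed {col} value {text!r}")


def write_final_report(samples: list[SnpArraySample], path,
                       header_fields: dict[str, str] | None = None) -> None:
    """Write samples as a final-report TSV.

    Rows are emitted in deterministic (sample, chromosome, position) order;
    a missing BAF/LRR value becomes an empty field.  An empty sample list
    produces a header-only file.
    """
    path = Path(path)
    n_snps = len(samples[0].data) if samples else 0
    meta = {"Content": "molekaryo final report", "Num SNPs": str(n_snps),
            "Num Samples": str(len(samples))}
    meta.update(header_fields or {})
    lines = ["[Header]"]
    lines += [f"{k}\t{v}" for k, v in meta.items()]
    lines.append("[Data]")
    lines.append("\t".join(FINAL_REPORT_COLUMNS))
    for sample in sorted(samples, key=lambda s: s.sample_id):
        df = SnpArraySample.sort_table(sample.data)
        for row in df.itertuples(index=False):
            lines.append("\t".join((
                sample.sample_id, row.snp_name, row.chrom, str(row.position),
                row.gtype, _fmt(row.baf), _fmt(row.lrr),
            )))
    _atomic_write(path, "\n".join(lines) + "\n")


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.4f}"


def read_str_table(path, panel: StrPanel | None = None) -> dict[str, StrProfile]:
    """Read an STR CSV (columns sample_id, locus, alleles) into profiles.

    Allele fields are semicolon-separated designations; repeats collapse to
    a set ("9;9" becomes {9}).  More than four distinct alleles at a locus
    is rejected.  Loci absent from ``panel`` (when given) are retained with
    a warning, so partial or extended kits still parse.
    """
    path = Path(path)
    known = set(panel.names()) if panel is not None else None
    profiles: dict[str, dict[str, tuple[str, ...]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"sample_id", "locus", "alleles"} <= set(reader.fieldnames):
            raise DataError(f"{path}: expected columns sample_id, locus, alleles")
        for row in reader:
            alleles = tuple(sorted({a.strip() for a in row["alleles"].split(";") if a.strip()},
                                   key=allele_sort_key))
            if not alleles:
                raise DataError(f"{path}: empty allele list for {row['sample_id']}/{row['locus']}")
            if len(alleles) > 4:
                raise DataError(f"{path}: >4 alleles at locus {row['locus']} "
                                f"for sample {row['sample_id']}")
            locus = row["locus"]
            if known is not None and locus not in known:
                warnings.warn(f"unknown STR locus {locus!r} retained", stacklevel=2)
            profiles.setdefault(row["sample_id"], {})[locus] = alleles
    return {sid: StrProfile(sid, alleles) for sid, alleles in profiles.items()}


def write_str_table(profiles: list[StrProfile], path) -> None:
    """Write STR profiles as CSV, sorted by (sample, locus)."""
    rows = []
    for profile in sorted(profiles, key=lambda p: p.sample_id):
        for locus in sorted(profile.alleles):
            rows.append((profile.sample_id, locus, ";".join(profile.alleles[locus])))
    lines = ["sample_id,locus,alleles"]
    lines += [",".join(r) for r in rows]
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_plot_data(sample: SnpArraySample, path, column: str = "baf",
                    loci: pd.DataFrame | None = None) -> None:
    """Export per-locus values as a BED-like TSV (chrom, start, end, value)
    for external plotting.  ``loci`` optionally restricts the export (e.g.
    to a selected-BAF subset with columns snp_name)."""
    df = sample.data
    if loci is not None:
        df = df[df["snp_name"].isin(set(loci["snp_name"]))]
    lines = []
    for row in df.itertuples(index=False):
        value = getattr(row, column)
        if isinstance(value, float) and np.isnan(value):
            continue
        lines.append(f"{row.chrom}\t{row.position - 1}\t{row.position}\t{value}")
    _atomic_write(Path(path), "\n".join(lines) + ("\n" if lines else ""))


def _atomic_write(path: Path, text: str) -> None:
    """Write via a temp file + rename so a crash never leaves a torn file."""
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)
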