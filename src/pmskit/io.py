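"""Genotype-table I/O, report serialization and convenience importers.

The genotype table dialect is a header-first TSV/CSV:

    sample_id  sex  Marker1  Marker2 ...
    S1         M    120/124  A/C
    D1         F    120/120  NA

Sex tokens are M/F/U; genotypes are two '/'-separated allele tokens;
missing cells are "NA", "-" or empty.  Two-column-per-marker vendor
layouts must be converted to this dialect as a pre-step.

Reports serialize to JSON (lossless round trip) and to a flat TSV for
spreadsheets, and embed every decision needed to reproduce the run
(algorithm, indicator, PE mode, tie rule, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import (
    GenotypeMatrix,
    InvalidInputError,
    ParentPool,
    format_genotype,
    parse_genotype,
)
from .exhaustive import PMS
from . import metrics as _metrics

__all__ = [
    "MISSING_TOKENS",
    "read_genotype_table",
    "write_genotype_table",
    "ScreenReport",
    "summarize_pms",
    "filter_by_maf",
    "vcf_to_table",
]

MISSING_TOKENS = {"NA", "", "-"}
_SEX_TOKENS = {"M", "F", "U"}


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        if delimiter not in ("\t", ","):
            raise InvalidInputError("delimiter must be tab or comma")
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_genotype_table(path, delimiter: Optional[str] = None):
    """Read a parent genotype table.

    Returns ``(ParentPool, panel, GenotypeMatrix)``.  Missing cells are
    recorded as ``None`` in the matrix (screening entry points reject
    them; the assigner tolerates them).  Malformed genotypes, unknown
    sex tokens and duplicate ids raise with row/column coordinates.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "sex":
        raise InvalidInputError(
            "header must start with 'sample_id', 'sex', then at least one marker id"
        )
    markers = cols[2:]
    if len(set(markers)) != len(markers):
        raise InvalidInputError("duplicate marker ids in header")
    ids = list(df["sample_id"])
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInputError(f"duplicate sample id(s): {', '.join(dup)}")
    sex = {}
    entries = {}
    for row_idx, row in df.iterrows():
        pid = row["sample_id"]
        if row["sex"] not in _SEX_TOKENS:
            raise InvalidInputError(
                f"row {row_idx + 2}: unknown sex token {row['sex']!r} for {pid!r}"
            )
        sex[pid] = row["sex"]
        for m in markers:
            cell = row[m].strip()
            if cell in MISSING_TOKENS:
                entries[(pid, m)] = None
                continue
            try:
                entries[(pid, m)] = parse_genotype(cell)
            except InvalidInputError as err:
                raise InvalidInputError(
                    f"row {row_idx + 2}, marker {m!r}, sample {pid!r}: {err}"
                ) from None
    pool = ParentPool(tuple(ids), sex)
    matrix = GenotypeMatrix(ids, markers, entries)
    return pool, markers, matrix


def write_genotype_table(
    pool: ParentPool,
    panel: Sequence[str],
    matrix: GenotypeMatrix,
    path,
    delimiter: Optional[str] = None,
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    rows = []
    for pid in pool.parent_ids:
        row = {"sample_id": pid, "sex": pool.sex[pid]}
        for m in panel:
            g = matrix.get(pid, m)
            row[m] = format_genotype(g) if g is not None else "NA"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass
class ScreenReport:
    """Serializable record of one screening run."""

    n_parents: int
    n_markers: int
    sex_mode: str
    n_pairs: int
    algorithm: str
    indicator: str = "pdi"
    pe_mode: str = "pair"
    tie_break: str = "panel"
    seed: Optional[int] = None
    unsolvable: bool = False
    pms: list = field(default_factory=list)  # [{markers, source, size, avg_pic, cpe}]
    redundancy_set: list = field(default_factory=list)
    indistinguishable_pairs: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ScreenReport":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        return cls(**json.loads(text))

    def to_tsv(self, path=None) -> str:
        """Flat one-PMS-per-row view for spreadsheets."""
        rows = []
        for entry in self.pms:
            rows.append(
                {
                    "markers": ";".join(entry["markers"]),
                    "source": entry["source"],
                    "size": entry["size"],
                    "avg_pic": entry.get("avg_pic"),
                    "cpe": entry.get("cpe"),
                }
            )
        if not rows and self.unsolvable:
            rows = [
                {"markers": "UNSOLVABLE", "source": f"{a[0]}x{a[1]}|{b[0]}x{b[1]}",
                 "size": 0, "avg_pic": None, "cpe": None}
                for a, b in self.indistinguishable_pairs
            ]
        text = pd.DataFrame(rows).to_csv(sep="\t", index=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_pms(pms: PMS, matrix: GenotypeMatrix, pe_mode: str = "pair") -> dict:
    """Size, average PIC and CPE of one PMS (report row)."""
    markers = list(pms.marker_ids)
    entry = {"markers": markers, "source": pms.source, "size": len(markers)}
    if markers:
        freqs = _metrics.allele_frequencies(matrix, markers)
        pics = [_metrics.pic(freqs[m]) for m in markers]
        pes = [_metrics.pe(freqs[m], mode=pe_mode) for m in markers]
        entry["avg_pic"] = sum(pics) / len(pics)
        entry["cpe"] = _metrics.cpe(pes)
    else:
        entry["avg_pic"] = 0.0
        entry["cpe"] = 0.0
    return entry


def filter_by_maf(matrix: GenotypeMatrix, panel: Sequence[str], min_maf: float) -> list:
    """Markers whose minor-allele frequency (in the pool) is >= min_maf.

    A simple pre-filter for SNP panels where low-MAF calls are more
    likely to be genotyping artifacts.
    """
    if not (0.0 <= min_maf <= 0.5):
        raise InvalidInputError("min_maf must lie in [0, 0.5]")
    freqs = _metrics.allele_frequencies(matrix, panel)
    return [m for m in panel if min(freqs[m].values()) >= min_maf]


def vcf_to_table(vcf_path, out_path, sex: Optional[dict] = None) -> None:
    """Convert biallelic GT records of a VCF into the genotype-table dialect.

    A convenience importer only: sample sexes default to U (override
    with ``sex``), non-biallelic records are skipped, and missing GT
    calls become NA cells.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    sex = sex or {}
    markers = []
    columns: dict = {s: {} for s in samples}
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        mid = var.ID or f"{var.CHROM}_{var.POS}"
        alleles = [var.REF, var.ALT[0]]
        markers.append(mid)
        for s, gt in zip(samples, var.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                columns[s][mid] = "NA"
            else:
                g = sorted([alleles[a1], alleles[a2]])
                columns[s][mid] = f"{g[0]}/{g[1]}"
    rows = []
    for s in samples:
        row = {"sample_id": s, "sex": sex.get(s, "U")}
        row.update({m: columns[s].get(m, "NA") for m in markers})
        rows.append(row)
    sep = "," if Path(str(out_path)).suffix.lower() == ".csv" else "\t"
    pd.DataFrame(rows).to_csv(out_path, sep=sep, index=False)
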