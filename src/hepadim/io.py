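"""Readers, writers, and validated in-memory containers.

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention). GFF3 input (1-based closed) is converted at the boundary.
Tabular files are tab-separated UTF-8; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hepadim")

VALID_SEXES = ("male", "female")


class FormatError(ValueError):
    """Raised when an input file violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionAtlas:
    """Genes x tissues nonnegative signal matrix (fluorescence units)."""

    gene_ids: list[str]
    tissue_ids: list[str]
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.tissue_ids, "tissue")
        if self.signal.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise FormatError(
                f"signal shape {self.signal.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.tissue_ids)} tissues"
            )
        if not np.isfinite(self.signal).all():
            raise FormatError("atlas signal contains non-finite values")
        if (self.signal < 0).any():
            bad = np.argwhere(self.signal < 0)[0]
            raise FormatError(
                f"negative signal for gene {self.gene_ids[bad[0]]!r}, "
                f"tissue {self.tissue_ids[bad[1]]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signal, index=self.gene_ids, columns=self.tissue_ids)


@dataclass
class CountMatrix:
    """Genes x samples integer count matrix with per-sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``sex`` (male/female),
    ``dose`` (ug/kg, >= 0) and ``duration`` (days).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("count matrix shape mismatch")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.allclose(as_int, np.round(as_int)):
                raise FormatError("counts must be integers")
            self.counts = np.round(as_int).astype(np.int64)
        if (self.counts < 0).any():
            raise FormatError("counts must be nonnegative")
        missing = set(self.sample_ids) - set(self.sample_meta.index)
        if missing:
            raise FormatError(f"samples missing metadata: {sorted(missing)}")
        for col in ("sex", "dose", "duration"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample metadata missing column {col!r}")
        bad_sex = set(self.sample_meta["sex"]) - set(VALID_SEXES)
        if bad_sex:
            raise FormatError(f"invalid sex labels: {sorted(bad_sex)}")
        if (self.sample_meta["dose"] < 0).any():
            raise FormatError("dose must be >= 0")

    def sex_of(self, sample_id: str) -> str:
        return str(self.sample_meta.loc[sample_id, "sex"])


FC_COLUMNS = ["gene_id", "contrast_id", "log2fc", "p1t", "max_reads"]


@dataclass
class FoldChangeTable:
    """Per (gene, contrast): log2 fold-change, posterior P1(t), read ceiling."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FC_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"fold-change table missing columns: {missing}")
        self.data = self.data[FC_COLUMNS].reset_index(drop=True)
        if self.data.duplicated(["gene_id", "contrast_id"]).any():
            dup = self.data[self.data.duplicated(["gene_id", "contrast_id"])].iloc[0]
            raise FormatError(
                f"duplicate row for gene {dup.gene_id!r}, contrast {dup.contrast_id!r}"
            )
        p = self.data["p1t"].to_numpy(float)
        if ((p < 0) | (p > 1)).any():
            bad = self.data.loc[(p < 0) | (p > 1), "gene_id"].iloc[0]
            raise FormatError(f"p1t outside [0,1] for gene {bad!r}")
        if not np.isfinite(self.data["log2fc"].to_numpy(float)).all():
            raise FormatError("log2fc must be finite")
        if (self.data["max_reads"].to_numpy(float) < 0).any():
            raise FormatError("max_reads must be >= 0")

    def contrast(self, contrast_id: str) -> pd.DataFrame:
        sub = self.data[self.data["contrast_id"] == contrast_id]
        if sub.empty:
            raise FormatError(f"contrast {contrast_id!r} not present")
        return sub.reset_index(drop=True)

    def contrasts(self) -> list[str]:
        return list(dict.fromkeys(self.data["contrast_id"]))

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True, order=True)
class GeneModel:
    """Gene with chromosome, body interval (0-based half-open) and strand."""

    chrom: str = field(compare=True)
    tss: int = field(compare=True)
    gene_id: str = field(compare=True)
    start: int = field(compare=False)
    end: int = field(compare=False)
    strand: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r} for {self.gene_id!r}")
        if self.end <= self.start:
            raise FormatError(
                f"empty interval for {self.gene_id!r}: [{self.start},{self.end})"
            )
        expected = self.start if self.strand == "+" else self.end - 1
        if self.tss != expected:
            raise FormatError(f"tss inconsistent with strand for {self.gene_id!r}")


def make_gene_model(gene_id: str, chrom: str, start: int, end: int, strand: str) -> GeneModel:
    """Build a GeneModel, deriving the TSS from the strand convention."""
    tss = start if strand == "+" else end - 1
    return GeneModel(chrom=chrom, tss=tss, gene_id=gene_id, start=start, end=end, strand=strand)


PEAK_COLUMNS = ["chrom", "start", "end", "fdr", "sex"]


@dataclass
class PeakSet:
    """ChIP enrichment intervals (0-based half-open) with FDR and sex label."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"peak table missing columns: {missing}")
        self.data = self.data[PEAK_COLUMNS].reset_index(drop=True)
        if (self.data["end"] <= self.data["start"]).any():
            raise FormatError("peak intervals must satisfy end > start")
        f = self.data["fdr"].to_numpy(float)
        if ((f < 0) | (f > 1)).any():
            raise FormatError("peak fdr outside [0,1]")
        bad = set(self.data["sex"]) - set(VALID_SEXES)
        if bad:
            raise FormatError(f"invalid peak sex labels: {sorted(bad)}")

    def for_sex(self, sex: str) -> "PeakSet":
        return PeakSet(self.data[self.data["sex"] == sex].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_expression_atlas(path: str | Path) -> ExpressionAtlas:
    """Read a genes x tissues signal TSV (first column: gene id)."""
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need a gene column plus >= 2 tissue columns")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str).tolist()
    tissues = [str(c) for c in df.columns[1:]]
    try:
        signal = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric signal cell ({exc})") from exc
    atlas = ExpressionAtlas(genes, tissues, signal)
    logger.info("read atlas %s: %d genes x %d tissues", path, len(genes), len(tissues))
    return atlas


def write_expression_atlas(atlas: ExpressionAtlas, path: str | Path) -> None:
    atlas.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a genes x samples count TSV plus a sample metadata TSV."""
    df = _read_tsv(counts_path, index_col=0)
    meta = _read_tsv(meta_path, index_col=0)
    cm = CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(),
        sample_meta=meta,
    )
    logger.info(
        "read counts %s: %d genes x %d samples", counts_path, len(cm.gene_ids), len(cm.sample_ids)
    )
    return cm


def write_counts(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids).rename_axis(
        "gene_id"
    ).to_csv(counts_path, sep="\t")
    cm.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def read_fold_change_table(path: str | Path) -> FoldChangeTable:
    df = _read_tsv(path)
    missing = [c for c in FC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("fold-change table %s is empty", path)
    table = FoldChangeTable(df)
    logger.info("read fold-change table %s: %d rows", path, len(table))
    return table


def write_fold_change_table(table: FoldChangeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_peaks(path: str | Path) -> PeakSet:
    df = _read_tsv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("peak table %s is empty", path)
    peaks = PeakSet(df)
    logger.info("read peaks %s: %d intervals", path, len(peaks))
    return peaks


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    peaks.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (BED6 / GFF3)
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (.bed) or GFF3 (.gff/.gff3).

    BED is taken as 0-based half-open; GFF as 1-based closed and converted.
    The returned list is sorted by (chrom, tss, gene_id).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        models = _read_bed6(path)
    elif suffix in (".gff", ".gff3"):
        models = _read_gff3(path)
    else:
        raise FormatError(f"unrecognized gene-model extension: {path.name}")
    models.sort()
    logger.info("read gene models %s: %d genes", path, len(models))
    return models


def _read_bed6(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: BED6 line with {len(fields)} fields")
            chrom, start, end, name, _score, strand = fields[:6]
            models.append(make_gene_model(name, chrom, int(start), int(end), strand))
    return models


def _read_gff3(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: GFF3 line with {len(fields)} fields")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
            if ftype != "gene":
                continue
            gene_id = None
            for item in attrs.split(";"):
                key, _, val = item.strip().partition("=")
                if key in ("ID", "gene_id", "Name"):
                    gene_id = val
                    break
            if gene_id is None:
                raise FormatError(f"{path}: gene record without ID attribute")
            # GFF 1-based closed -> 0-based half-open
            models.append(make_gene_model(gene_id, chrom, int(start) - 1, int(end), strand))
    return models


def write_gene_models_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: uppercase sequence} dict."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_set(path: str | Path) -> list[str]:
    """One-gene-id-per-line text file."""
    with open(path) as fh:
        ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    _check_unique(ids, "gene")
    return ids


def write_gene_set(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
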