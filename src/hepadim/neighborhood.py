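"""Genome-order cumulative fold-change tracks and co-regulated segments.

Genes are walked in transcription start site (TSS) order within each
chromosome. Starting from the first differentially expressed (DE) gene, each
DE gene adds its log2 fold-change to a running score; a gene without a
change in expression leaves the score unchanged (and carries it). Dramatic
sustained decreases (or increases) of the track mark neighborhoods of
closely located genes under putative shared regulation, such as the
chromosome-4 major urinary protein (Mup) cluster coordinately repressed by
TCDD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hepadim.io import FormatError, GeneModel

logger = logging.getLogger("hepadim")


@dataclass
class Segment:
    chrom: str
    first: int  # track index of first retained DE gene (inclusive)
    last: int   # track index of last retained DE gene (inclusive)
    direction: str  # induced / repressed
    magnitude: float  # |sum of member DE log2fc|
    n_de_genes: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.last < self.first:
            raise FormatError("segment last < first")
        if self.magnitude <= 0:
            raise FormatError("segment magnitude must be > 0")


def running_fold_change(
    models: list[GeneModel],
    de: pd.DataFrame,
) -> pd.DataFrame:
    """Per-chromosome cumulative sum of DE log2 fold-changes in TSS order.

    ``de`` must carry columns gene_id, log2fc, de (bool); genes in ``de``
    absent from ``models`` are logged and skipped, genes without an
    expression record contribute 0. The score resets at each chromosome.
    Returns the track frame: gene_id, chrom, tss, de_flag, log2fc,
    cumulative_score.
    """
    for col in ("gene_id", "log2fc", "de"):
        if col not in de.columns:
            raise FormatError(f"de frame missing column {col!r}")
    fc = dict(zip(de["gene_id"], de["log2fc"]))
    flag = dict(zip(de["gene_id"], de["de"]))
    model_ids = {m.gene_id for m in models}
    orphans = set(de["gene_id"]) - model_ids
    if orphans:
        logger.info("%d genes in expression table lack gene models; skipped",
                    len(orphans))
    rows = []
    for m in sorted(models):  # (chrom, tss, gene_id)
        is_de = bool(flag.get(m.gene_id, False))
        contrib = float(fc.get(m.gene_id, 0.0)) if is_de else 0.0
        rows.append((m.gene_id, m.chrom, m.tss, is_de, contrib))
    track = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "de_flag", "log2fc"])
    track["cumulative_score"] = track.groupby("chrom", sort=False)["log2fc"].cumsum()
    return track


def detect_segments(
    track: pd.DataFrame,
    min_genes: int = 3,
    min_magnitude: float = 4.0,
    max_gap: int = 2,
    trim_frac: float = 0.5,
) -> list[Segment]:
    """Maximal same-sign DE runs with gap tolerance, count and magnitude floors.

    A run collects consecutive DE genes of one fold-change sign, tolerating
    up to ``max_gap`` intervening non-DE genes; a DE gene of the opposite
    sign or a longer gap terminates it. To keep gap-bridged weak flanking
    genes from dilating a strong block, terminal run members whose |log2fc|
    falls below ``trim_frac`` times the median |log2fc| of the run are
    trimmed before reporting. Surviving runs need >= ``min_genes`` DE genes
    and a total |delta cumulative score| >= ``min_magnitude``; the returned
    list is non-overlapping, sorted by magnitude descending.
    """
    segments: list[Segment] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        de_flag = sub["de_flag"].to_numpy(bool)
        fc = sub["log2fc"].to_numpy(float)
        gid = sub["gene_id"].to_numpy()
        run: list[int] = []  # local positions of DE members in current run
        sign = 0

        def flush() -> None:
            nonlocal run, sign
            if run:
                seg = _finalize_run(run, idx, fc, gid, str(chrom),
                                    min_genes, min_magnitude, trim_frac)
                if seg is not None:
                    segments.append(seg)
            run, sign = [], 0

        gap = 0
        for i in range(len(idx)):
            if not de_flag[i] or fc[i] == 0.0:
                if run:
                    gap += 1
                    if gap > max_gap:
                        flush()
                        gap = 0
                continue
            s = 1 if fc[i] > 0 else -1
            if run and s != sign:
                flush()
            if not run:
                sign = s
            run.append(i)
            gap = 0
        flush()
    segments.sort(key=lambda s: -s.magnitude)
    logger.info("detected %d segments", len(segments))
    return segments


def _finalize_run(
    run: list[int],
    idx: np.ndarray,
    fc: np.ndarray,
    gid: np.ndarray,
    chrom: str,
    min_genes: int,
    min_magnitude: float,
    trim_frac: float,
) -> Segment | None:
    members = list(run)
    med = float(np.median(np.abs(fc[members])))
    floor = trim_frac * med
    while members and abs(fc[members[0]]) < floor:
        members.pop(0)
    while members and abs(fc[members[-1]]) < floor:
        members.pop()
    if len(members) < min_genes:
        return None
    total = float(fc[members].sum())
    if abs(total) < min_magnitude:
        return None
    return Segment(
        chrom=chrom,
        first=int(idx[members[0]]),
        last=int(idx[members[-1]]),
        direction="induced" if total > 0 else "repressed",
        magnitude=abs(total),
        n_de_genes=len(members),
        gene_ids=[str(g) for g in gid[members]],
    )


def segments_to_bed(segments: list[Segment], track: pd.DataFrame) -> pd.DataFrame:
    """BED-like frame with the segment magnitude in the score column."""
    rows = []
    for s in segments:
        start = int(track.loc[s.first, "tss"])
        end = int(track.loc[s.last, "tss"]) + 1
        rows.append((s.chrom, start, end, s.direction, s.magnitude, s.n_de_genes))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "magnitude", "n_de_genes"]
    )
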