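"""Putative dioxin response element (pDRE) scanning and AhR peak integration.

The AhR:ARNT dimer binds dioxin response elements built on the invariant
5'-GCGTG-3' core. Candidate sites are scored against a position weight
matrix with the conservation-weighted matrix similarity score (MSS): each
position contributes its conservation weight times the frequency of the
observed base, and the sum is min-max normalized so the consensus scores
exactly 1 and the anti-consensus exactly 0. Sites with MSS >= 0.85 are
considered functional pDREs.

Significant ChIP peaks (FDR <= 0.05) are assigned to genes whose body plus a
TSS-side flank they intersect; gene-level male/female enrichment partitions
and pDRE-in-peak co-occurrence counts summarize direct AhR-DRE regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from hepadim.io import FormatError, GeneModel, PeakSet
from hepadim.specificity import GeneSet

logger = logging.getLogger("hepadim")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")

MSS_CUTOFF = 0.85
PEAK_FDR_MAX = 0.05
UPSTREAM_FLANK = 10_000
DRE_CORE = "GCGTG"


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# PWM and MSS scanning
# ---------------------------------------------------------------------------


@dataclass
class PWM:
    """Position frequency matrix with per-position conservation weights.

    ``freq`` is L x 4 (A,C,G,T), each row summing to 1 after pseudocount.
    The conservation weight of position i is
    c_i = (100/ln 4) * sum_b f(i,b) * ln(4 f(i,b)), clipped at 0: it is 0
    for a uniform position and approaches 100 for a deterministic one.
    """

    freq: np.ndarray
    conservation: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise FormatError("PWM frequency matrix must be L x 4")
        if (self.freq <= 0).any() or (self.freq > 1).any():
            raise FormatError("PWM frequencies must lie in (0,1]")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-6):
            raise FormatError("PWM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    @property
    def min_score(self) -> float:
        return float((self.conservation * self.freq.min(axis=1)).sum())

    @property
    def max_score(self) -> float:
        return float((self.conservation * self.freq.max(axis=1)).sum())


def conservation_weights(freq: np.ndarray) -> np.ndarray:
    """c_i = (100/ln4) * sum_b f(i,b) ln(4 f(i,b)), clipped at 0."""
    freq = np.asarray(freq, dtype=float)
    c = (100.0 / np.log(4.0)) * (freq * np.log(4.0 * freq)).sum(axis=1)
    return np.clip(c, 0.0, None)


def build_pwm(freq_matrix: "np.ndarray | pd.DataFrame", pseudocount: float = 0.01) -> PWM:
    """Build a PWM from an L x 4 frequency (or count) matrix.

    Rows are renormalized after adding ``pseudocount``; matrices shorter than
    the 5-bp GCGTG core are rejected.
    """
    if isinstance(freq_matrix, pd.DataFrame):
        freq_matrix = freq_matrix[list(BASES)].to_numpy(dtype=float)
    m = np.asarray(freq_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise FormatError("PWM input must have 4 columns (A,C,G,T)")
    if m.shape[0] < 5:
        raise FormatError("PWM shorter than the 5-bp DRE core")
    if (m < 0).any():
        raise FormatError("PWM entries must be nonnegative")
    rowsum = m.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise FormatError("PWM row with zero total")
    m = m / rowsum  # counts -> frequencies
    m = (m + pseudocount) / (1.0 + 4.0 * pseudocount)
    return PWM(freq=m, conservation=conservation_weights(m))


def read_pwm(path: str, pseudocount: float = 0.01) -> PWM:
    """PWM TSV: L rows x 4 columns, header A, C, G, T."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [b for b in BASES if b not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing base columns {missing}")
    return build_pwm(df, pseudocount=pseudocount)


def write_pwm(pwm: PWM, path: str) -> None:
    pd.DataFrame(pwm.freq, columns=list(BASES)).to_csv(path, sep="\t", index=False)


def default_test_pwm(flank: int = 2, pseudocount: float = 0.01) -> PWM:
    """Synthetic testing matrix: uniform flanks around a fixed GCGTG core.

    Shipped only so the scanner can be exercised without a real matrix; real
    analyses must supply their own PWM file.
    """
    rows = []
    for _ in range(flank):
        rows.append([0.25, 0.25, 0.25, 0.25])
    for b in DRE_CORE:
        row = [0.0, 0.0, 0.0, 0.0]
        row[BASE_INDEX[b]] = 1.0
        rows.append(row)
    for _ in range(flank):
        rows.append([0.25, 0.25, 0.25, 0.25])
    return build_pwm(np.asarray(rows), pseudocount=pseudocount)


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int  # forward-strand 0-based half-open window
    end: int
    strand: str
    mss: float
    matched: str


def window_mss(window: str, pwm: PWM) -> float:
    """MSS of one window on the given strand's orientation."""
    if len(window) != pwm.length:
        raise FormatError("window length does not match PWM length")
    score = 0.0
    for i, b in enumerate(window):
        score += pwm.conservation[i] * pwm.freq[i, BASE_INDEX[b]]
    lo, hi = pwm.min_score, pwm.max_score
    if hi == lo:
        return 1.0
    return (score - lo) / (hi - lo)


def mss_scan(
    chrom: str,
    sequence: str,
    pwm: PWM,
    cutoff: float = MSS_CUTOFF,
) -> list[MotifHit]:
    """Scan both strands; return hits with MSS >= cutoff in coordinate order.

    Windows containing N (or any non-ACGT symbol) are skipped. Reverse-strand
    hits are reported at the forward-strand coordinates of their window.
    """
    seq = sequence.upper()
    L = pwm.length
    n = len(seq)
    if n < L:
        return []
    # integer-encode; anything non-ACGT -> 4 (invalid)
    code = np.full(n, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        code[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    nwin = n - L + 1
    # per-position score lookup, padded with NaN for invalid bases
    fwd_tab = np.concatenate(
        [pwm.conservation[:, None] * pwm.freq, np.full((L, 1), np.nan)], axis=1
    )
    # reverse strand: position i of the motif reads the complement of the
    # base at window offset L-1-i
    comp = np.array([3, 2, 1, 0, 4])
    rev_scores = np.zeros(nwin)
    fwd_scores = np.zeros(nwin)
    for i in range(L):
        fwd_scores += fwd_tab[i, code[i : i + nwin]]
        rev_scores += fwd_tab[i, comp[code[L - 1 - i : L - 1 - i + nwin]]]
    lo, hi = pwm.min_score, pwm.max_score
    span = (hi - lo) if hi > lo else 1.0
    hits: list[MotifHit] = []
    with np.errstate(invalid="ignore"):
        mss_fwd = np.where(np.isnan(fwd_scores), -1.0, (fwd_scores - lo) / span)
        mss_rev = np.where(np.isnan(rev_scores), -1.0, (rev_scores - lo) / span)
        if hi == lo:
            mss_fwd = np.where(mss_fwd < 0, -1.0, 1.0)
            mss_rev = np.where(mss_rev < 0, -1.0, 1.0)
    for start in np.nonzero((mss_fwd >= cutoff) | (mss_rev >= cutoff))[0]:
        for strand, mss in (("+", mss_fwd[start]), ("-", mss_rev[start])):
            if mss >= cutoff:
                hits.append(
                    MotifHit(chrom, int(start), int(start) + L, strand,
                             float(mss), seq[start : start + L])
                )
    logger.info("scanned %s (%d bp): %d hits at MSS >= %g", chrom, n, len(hits), cutoff)
    return hits


def hits_to_bed(hits: list[MotifHit]) -> pd.DataFrame:
    """BED6-style frame with mss*1000 in the score column."""
    return pd.DataFrame(
        [
            (h.chrom, h.start, h.end, h.matched, int(round(h.mss * 1000)), h.strand)
            for h in hits
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


# ---------------------------------------------------------------------------
# Peak-to-gene assignment and partitions
# ---------------------------------------------------------------------------


@dataclass
class GenePeakAssignment:
    gene_id: str
    peak_indices: list[int]
    has_pdre: dict[int, bool] = field(default_factory=dict)


def assignment_window(model: GeneModel, upstream_flank: int = UPSTREAM_FLANK) -> tuple[int, int]:
    """Gene body extended by ``upstream_flank`` on the TSS side (>= 0 clipped)."""
    if model.strand == "+":
        return max(0, model.start - upstream_flank), model.end
    return model.start, model.end + upstream_flank


def assign_peaks_to_genes(
    peaks: PeakSet,
    models: list[GeneModel],
    upstream_flank: int = UPSTREAM_FLANK,
    fdr_max: float = PEAK_FDR_MAX,
) -> list[GenePeakAssignment]:
    """Assign significant peaks (fdr <= fdr_max) to genes they intersect.

    The assignment window is the gene body plus the upstream flank on the
    TSS side; a peak may be assigned to several genes. Returns one entry per
    gene with >= 1 assigned peak.
    """
    trees: dict[str, IntervalTree] = {}
    df = peaks.data
    for i, row in df.iterrows():
        if row.fdr <= fdr_max:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, int(i))
    out = []
    for m in sorted(models):
        tree = trees.get(m.chrom)
        if tree is None:
            continue
        lo, hi = assignment_window(m, upstream_flank)
        found = sorted(iv.data for iv in tree.overlap(lo, hi))
        if found:
            out.append(GenePeakAssignment(gene_id=m.gene_id, peak_indices=found))
    logger.info("assigned peaks to %d genes (flank %d, fdr <= %g)",
                len(out), upstream_flank, fdr_max)
    return out


def partition_by_sex(
    assignments_male: list[GenePeakAssignment],
    assignments_female: list[GenePeakAssignment],
    universe: GeneSet,
) -> dict[str, list[str]]:
    """Disjoint both / male_only / female_only / neither classes over a universe."""
    uni = list(universe.members)
    male = {a.gene_id for a in assignments_male} & set(uni)
    female = {a.gene_id for a in assignments_female} & set(uni)
    part = {
        "both": [g for g in uni if g in male and g in female],
        "male_only": [g for g in uni if g in male and g not in female],
        "female_only": [g for g in uni if g in female and g not in male],
        "neither": [g for g in uni if g not in male and g not in female],
    }
    assert sum(len(v) for v in part.values()) == len(uni)
    logger.info(
        "sex partition of %d genes: both=%d male_only=%d female_only=%d neither=%d",
        len(uni), len(part["both"]), len(part["male_only"]),
        len(part["female_only"]), len(part["neither"]),
    )
    return part


def peak_contains_pdre(peak_start: int, peak_end: int, hits: list[MotifHit],
                       chrom: str) -> bool:
    """Full containment: the hit window must lie entirely within the peak."""
    return any(
        h.chrom == chrom and h.start >= peak_start and h.end <= peak_end
        for h in hits
    )


def annotate_peaks_with_pdres(
    assignments: list[GenePeakAssignment],
    peaks: PeakSet,
    hits: list[MotifHit],
) -> tuple[list[GenePeakAssignment], dict[str, int]]:
    """Flag assigned peaks containing >= 1 fully-enclosed pDRE hit.

    Returns the annotated assignments and summary counts over the distinct
    assigned peaks: total and with-pDRE.
    """
    hit_by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        hit_by_chrom.setdefault(h.chrom, []).append(h)
    df = peaks.data
    flagged: dict[int, bool] = {}
    for a in assignments:
        for pi in a.peak_indices:
            if pi not in flagged:
                row = df.loc[pi]
                flagged[pi] = peak_contains_pdre(
                    int(row.start), int(row.end),
                    hit_by_chrom.get(row.chrom, []), str(row.chrom),
                )
            a.has_pdre[pi] = flagged[pi]
    counts = {
        "assigned_peaks": len(flagged),
        "peaks_with_pdre": int(sum(flagged.values())),
    }
    logger.info("pDRE co-occurrence: %d/%d assigned peaks contain a pDRE",
                counts["peaks_with_pdre"], counts["assigned_peaks"])
    return assignments, counts
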