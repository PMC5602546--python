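"""Synthetic inputs with planted ground truth.

Every file format the pipeline reads can be generated here with a known
answer key: a multi-tissue expression atlas with planted liver-specific
genes, male/female negative-binomial count matrices with planted sex-biased
genes, and a synthetic genome (gene models, per-gene fold-change table, ChIP
peak intervals, FASTA sequence) carrying a planted co-repressed gene block,
consensus DRE instances and peak-gene links.

Defaults mirror the study conditions the pipeline emulates: a 96-tissue
atlas with 181 planted liver-specific genes (DeltaSignal plant 6,000 units
against the 5,000-unit call threshold), vehicle-arm count data with n = 5
per sex, NB dispersion 0.05 and planted 2^1.5-fold sex effects, and a
chromosome carrying an 8-gene block at log2FC -4 against a 10% background
DE rate.

A single global seed fans out to per-component generators through
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with fixed component
keys, so each component is individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hepadim.io import (
    CountMatrix,
    ExpressionAtlas,
    FoldChangeTable,
    FormatError,
    GeneModel,
    PeakSet,
    make_gene_model,
    write_counts,
    write_expression_atlas,
    write_fasta,
    write_fold_change_table,
    write_gene_models_bed,
    write_peaks,
)
from hepadim.regulatory import DRE_CORE, PWM, default_test_pwm, revcomp

# component keys for seed fan-out
_ATLAS, _COUNTS, _GENOME = 11, 23, 37

# background DE effect sizes consistent with the 1.5-fold DE gate
BACKGROUND_DE_LOG2FC = (np.log2(1.5), 2.0)


def component_rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class TruthBundle:
    """Planted ground truth for one simulated data set."""

    liver_specific_ids: list[str] = field(default_factory=list)
    male_biased_ids: list[str] = field(default_factory=list)
    female_biased_ids: list[str] = field(default_factory=list)
    cluster_chrom: str | None = None
    cluster_members: list[str] = field(default_factory=list)
    cluster_log2fc: float | None = None
    planted_dre_positions: list[dict] = field(default_factory=list)
    planted_peak_gene_links: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Expression atlas
# ---------------------------------------------------------------------------


def simulate_atlas(
    n_genes: int = 2000,
    n_tissues: int = 96,
    n_specific: int = 181,
    delta_planted: float = 6000.0,
    noise_sd: float = 200.0,
    seed: int = 0,
    target_tissue: str = "liver",
    background_low: float = 50.0,
    background_high: float = 3000.0,
) -> tuple[ExpressionAtlas, TruthBundle]:
    """Atlas with ``n_specific`` planted target-tissue-specific genes.

    Background signal for every gene/tissue is uniform on
    [background_low, background_high] (ceiling below the 5,000-unit call
    threshold); planted genes get a target-tissue signal equal to their own
    maximum over other tissues plus ``delta_planted`` before Gaussian noise.
    """
    if n_genes <= 0 or n_tissues < 2:
        raise FormatError("need n_genes > 0 and n_tissues >= 2")
    if n_specific > n_genes:
        raise FormatError("n_specific must be <= n_genes")
    if delta_planted <= 0:
        raise FormatError("delta_planted must be > 0")
    rng = component_rng(seed, _ATLAS)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    tissues = [target_tissue] + [f"tissue{j:02d}" for j in range(1, n_tissues)]
    signal = rng.uniform(background_low, background_high, size=(n_genes, n_tissues))
    specific = sorted(rng.choice(n_genes, size=n_specific, replace=False).tolist())
    other_max = np.delete(signal, 0, axis=1).max(axis=1)
    signal[specific, 0] = other_max[specific] + delta_planted
    if noise_sd > 0:
        signal = np.clip(signal + rng.normal(0, noise_sd, size=signal.shape), 0, None)
    truth = TruthBundle(liver_specific_ids=[genes[i] for i in specific])
    return ExpressionAtlas(genes, tissues, signal), truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def simulate_counts(
    n_genes: int = 2000,
    n_per_sex: int = 5,
    frac_male_biased: float = 0.05,
    frac_female_biased: float = 0.05,
    effect_log2fc: float = 1.5,
    dispersion: float = 0.05,
    lib_size_range: tuple[float, float] = (0.7, 1.3),
    seed: int = 0,
    base_mean_median: float = 500.0,
    base_mean_sigma: float = 0.8,
) -> tuple[CountMatrix, TruthBundle]:
    """Male/female NB counts with planted sex-biased genes.

    Planted genes carry a total male/female mean ratio of 2**(+-effect_log2fc),
    split symmetrically between the sexes; library-size factors are uniform
    on ``lib_size_range``. Counts are NB with gene-wise lognormal base means
    and common ``dispersion`` (var = mu + dispersion * mu^2).
    """
    if dispersion <= 0:
        raise FormatError("dispersion must be > 0")
    if frac_male_biased + frac_female_biased >= 1:
        raise FormatError("biased fractions must sum to < 1")
    rng = component_rng(seed, _COUNTS)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    n_m = int(round(frac_male_biased * n_genes))
    n_f = int(round(frac_female_biased * n_genes))
    picks = rng.choice(n_genes, size=n_m + n_f, replace=False)
    male_idx = np.sort(picks[:n_m])
    female_idx = np.sort(picks[n_m:])

    base = rng.lognormal(mean=np.log(base_mean_median), sigma=base_mean_sigma,
                         size=n_genes)
    log2_effect = np.zeros(n_genes)
    log2_effect[male_idx] = effect_log2fc
    log2_effect[female_idx] = -effect_log2fc

    samples = [f"male_{i+1}" for i in range(n_per_sex)] + [
        f"female_{i+1}" for i in range(n_per_sex)
    ]
    sexes = ["male"] * n_per_sex + ["female"] * n_per_sex
    lib = rng.uniform(lib_size_range[0], lib_size_range[1], size=2 * n_per_sex)

    mult = np.where(
        np.array(sexes) == "male",
        2.0 ** (+log2_effect[:, None] / 2.0),
        2.0 ** (-log2_effect[:, None] / 2.0),
    )
    mu = base[:, None] * mult * lib[None, :]
    r = 1.0 / dispersion  # NB size parameter
    counts = rng.negative_binomial(r, r / (r + mu))

    meta = pd.DataFrame(
        {"sex": sexes, "dose": 0.0, "duration": 28}, index=pd.Index(samples, name="sample_id")
    )
    cm = CountMatrix(genes, samples, counts, meta)
    truth = TruthBundle(
        male_biased_ids=[genes[i] for i in male_idx],
        female_biased_ids=[genes[i] for i in female_idx],
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Genome, response table, peaks, sequence
# ---------------------------------------------------------------------------


def _scrub_cores(seq: np.ndarray, start: int, end: int, rng: np.random.Generator) -> None:
    """Remove every GCGTG / CACGC occurrence from seq[start:end] in place."""
    cores = (DRE_CORE, revcomp(DRE_CORE))
    for _ in range(50):
        segment = "".join(seq[max(0, start - 4) : end + 4])
        found = False
        for core in cores:
            pos = segment.find(core)
            while pos != -1:
                found = True
                # break the core by rewriting its middle base
                mid = max(0, start - 4) + pos + 2
                current = seq[mid]
                seq[mid] = {"A": "T", "C": "A", "G": "A", "T": "C"}[current]
                pos = segment.find(core, pos + 1)
        if not found:
            return
    raise RuntimeError("core scrubbing did not converge")


def simulate_genome_and_response(
    n_chrom: int = 2,
    genes_per_chrom: int = 500,
    cluster_size: int = 8,
    cluster_log2fc: float = -4.0,
    background_de_rate: float = 0.1,
    dre_density: float = 0.5,
    peak_fdr: float = 0.01,
    seed: int = 0,
    gene_spacing: int = 20_000,
    gene_length: int = 1_500,
    peak_halfwidth: int = 250,
    peak_gene_rate: float = 0.3,
    contrast_id: str = "tcdd_30ug",
    pwm: PWM | None = None,
    with_sequence: bool = True,
) -> tuple[list[GeneModel], FoldChangeTable, PeakSet, dict[str, str], TruthBundle]:
    """Synthetic genome with a planted co-regulated block, DREs and peaks.

    One chromosome carries ``cluster_size`` consecutive genes all at
    ``cluster_log2fc`` (differentially expressed); every other gene is DE
    with probability ``background_de_rate`` with |log2FC| uniform on
    [log2(1.5), 2] and random sign. A fraction ``peak_gene_rate`` of genes
    get a ChIP peak spanning their TSS (fdr = ``peak_fdr``; sex male,
    female, or both); with probability ``dre_density`` a gene's peak region
    carries a planted consensus DRE (random strand). Peak intervals are
    scrubbed of accidental GCGTG cores before planting, so pDRE-in-peak
    truth counts are exact; elsewhere the background core rate stays at the
    4^-5 per-strand-position null of the i.i.d. uniform sequence.

    With ``with_sequence=False`` the FASTA dict is empty and no DREs are
    planted (fast mode for neighborhood-scale simulations).
    """
    if cluster_size >= genes_per_chrom:
        raise FormatError("cluster_size must be < genes_per_chrom")
    if cluster_log2fc == 0:
        raise FormatError("cluster_log2fc must be nonzero (undetectable plant)")
    rng = component_rng(seed, _GENOME)
    if pwm is None:
        pwm = default_test_pwm()
    consensus = pwm.consensus

    models: list[GeneModel] = []
    rows = []
    truth = TruthBundle()
    chrom_len = gene_spacing * genes_per_chrom + gene_spacing

    cluster_chrom = "chr1"
    cstart = int(rng.integers(2, genes_per_chrom - cluster_size - 2))
    truth.cluster_chrom = cluster_chrom
    truth.cluster_log2fc = float(cluster_log2fc)

    peak_rows = []
    planted_links: list[dict] = []
    dre_plants: list[dict] = []  # staged; positions recorded after planting

    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        for i in range(genes_per_chrom):
            gid = f"{chrom}_g{i:04d}"
            tss_anchor = gene_spacing // 2 + i * gene_spacing
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = tss_anchor, tss_anchor + gene_length
            else:
                start, end = tss_anchor - gene_length + 1, tss_anchor + 1
            models.append(make_gene_model(gid, chrom, start, end, strand))

            in_cluster = chrom == cluster_chrom and cstart <= i < cstart + cluster_size
            if in_cluster:
                log2fc, p1t, de = float(cluster_log2fc), 0.99, True
                max_reads = int(rng.integers(10_000, 30_000))
                truth.cluster_members.append(gid)
            elif rng.random() < background_de_rate:
                mag = rng.uniform(*BACKGROUND_DE_LOG2FC)
                log2fc = float(mag if rng.random() < 0.5 else -mag)
                p1t = float(rng.uniform(0.85, 1.0))
                de = True
                max_reads = int(rng.integers(100, 10_000))
            else:
                log2fc = float(rng.normal(0, 0.15))
                p1t = float(rng.uniform(0.0, 0.5))
                de = False
                max_reads = int(rng.integers(100, 10_000))
            rows.append((gid, contrast_id, log2fc, p1t, max_reads))

            # peaks over the TSS; cluster genes always get a male peak
            wants_peak = in_cluster or rng.random() < peak_gene_rate
            if wants_peak:
                pstart = max(0, tss_anchor - peak_halfwidth)
                pend = min(chrom_len, tss_anchor + peak_halfwidth)
                sexes = (
                    ("male",)
                    if in_cluster
                    else {0: ("male",), 1: ("female",), 2: ("male", "female")}[
                        int(rng.integers(0, 3))
                    ]
                )
                has_dre = with_sequence and rng.random() < min(dre_density, 1.0)
                for sex in sexes:
                    peak_index = len(peak_rows)
                    peak_rows.append((chrom, pstart, pend, float(peak_fdr), sex))
                    planted_links.append(
                        {"gene_id": gid, "peak_index": peak_index,
                         "sex": sex, "has_dre": bool(has_dre)}
                    )
                if has_dre:
                    strand_dre = "+" if rng.random() < 0.5 else "-"
                    offset = tss_anchor - len(consensus) // 2
                    dre_plants.append(
                        {"chrom": chrom, "offset": int(offset),
                         "strand": strand_dre, "peak": (pstart, pend)}
                    )

    table = FoldChangeTable(
        pd.DataFrame(rows, columns=["gene_id", "contrast_id", "log2fc", "p1t", "max_reads"])
    )
    peaks = PeakSet(pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "fdr", "sex"]))
    truth.planted_peak_gene_links = planted_links

    sequences: dict[str, str] = {}
    if with_sequence:
        bases = np.array(list("ACGT"))
        for c in range(1, n_chrom + 1):
            chrom = f"chr{c}"
            seq = bases[rng.integers(0, 4, size=chrom_len)]
            for _chrom, pstart, pend, _fdr, _sex in peak_rows:
                if _chrom == chrom:
                    _scrub_cores(seq, int(pstart), int(pend), rng)
            for plant in dre_plants:
                if plant["chrom"] != chrom:
                    continue
                word = consensus if plant["strand"] == "+" else revcomp(consensus)
                off = plant["offset"]
                seq[off : off + len(word)] = list(word)
                truth.planted_dre_positions.append(
                    {"chrom": chrom, "offset": off, "strand": plant["strand"]}
                )
            sequences[chrom] = seq.astype("S1").tobytes().decode("ascii")

    return models, table, peaks, sequences, truth


# ---------------------------------------------------------------------------
# Bundle emission (exactly the formats io_core reads)
# ---------------------------------------------------------------------------


def emit_bundle(
    outdir: str | Path,
    seed: int = 0,
    atlas_kwargs: dict | None = None,
    counts_kwargs: dict | None = None,
    genome_kwargs: dict | None = None,
) -> dict[str, Path]:
    """Write a full synthetic input set (TSV/BED/FASTA + truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    atlas, atlas_truth = simulate_atlas(seed=seed, **(atlas_kwargs or {}))
    paths["atlas"] = outdir / "atlas.tsv"
    write_expression_atlas(atlas, paths["atlas"])

    cm, count_truth = simulate_counts(seed=seed, **(counts_kwargs or {}))
    paths["counts"] = outdir / "counts.tsv"
    paths["samples"] = outdir / "samples.tsv"
    write_counts(cm, paths["counts"], paths["samples"])

    models, table, peaks, seqs, genome_truth = simulate_genome_and_response(
        seed=seed, **(genome_kwargs or {})
    )
    paths["genes"] = outdir / "genes.bed"
    write_gene_models_bed(models, paths["genes"])
    paths["fold_changes"] = outdir / "fold_changes.tsv"
    write_fold_change_table(table, paths["fold_changes"])
    paths["peaks"] = outdir / "peaks.tsv"
    write_peaks(peaks, paths["peaks"])
    if seqs:
        paths["genome"] = outdir / "genome.fa"
        write_fasta(seqs, paths["genome"])

    truth = TruthBundle(
        liver_specific_ids=atlas_truth.liver_specific_ids,
        male_biased_ids=count_truth.male_biased_ids,
        female_biased_ids=count_truth.female_biased_ids,
        cluster_chrom=genome_truth.cluster_chrom,
        cluster_members=genome_truth.cluster_members,
        cluster_log2fc=genome_truth.cluster_log2fc,
        planted_dre_positions=genome_truth.planted_dre_positions,
        planted_peak_gene_links=genome_truth.planted_peak_gene_links,
    )
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
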