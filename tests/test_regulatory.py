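import numpy as np
import pandas as pd
import pytest

from hepadim import regulatory as reg
from hepadim.io import FormatError, PeakSet, make_gene_model
from hepadim.specificity import GeneSet


def random_pwm(rng, length=19):
    counts = rng.uniform(0.1, 10, size=(length, 4))
    return reg.build_pwm(counts)


# ---------------------------------------------------------------------------
# PWM construction and conservation weights
# ---------------------------------------------------------------------------


def test_uniform_position_has_zero_conservation():
    pwm = reg.build_pwm(np.full((5, 4), 0.25))
    np.testing.assert_allclose(pwm.conservation, 0.0, atol=1e-12)


def test_deterministic_position_is_near_maximally_conserved():
    rows = np.tile([1.0, 0.0, 0.0, 0.0], (5, 1))
    pwm = reg.build_pwm(rows, pseudocount=0.001)
    assert (pwm.conservation > 95).all()
    assert pwm.conservation.max() <= 100.0


def test_conservation_matches_direct_formula(rng):
    pwm = random_pwm(rng)
    expected = np.clip(
        (100.0 / np.log(4.0))
        * np.array(
            [sum(f * np.log(4 * f) for f in row) for row in pwm.freq]
        ),
        0.0,
        None,
    )
    np.testing.assert_allclose(pwm.conservation, expected, rtol=1e-12)


def test_pwm_shorter_than_dre_core_is_fatal():
    with pytest.raises(FormatError, match="core"):
        reg.build_pwm(np.full((4, 4), 0.25))


def test_pwm_tsv_round_trip(tmp_path, rng):
    pwm = random_pwm(rng, length=8)
    path = tmp_path / "pwm.tsv"
    reg.write_pwm(pwm, str(path))
    back = reg.read_pwm(str(path), pseudocount=0.0)
    np.testing.assert_allclose(back.freq, pwm.freq, rtol=1e-12)


# ---------------------------------------------------------------------------
# MSS scanning
# ---------------------------------------------------------------------------


def brute_force_scan(chrom, seq, pwm, cutoff):
    """Score every window on both strands with explicit python loops."""
    hits = []
    L = pwm.length
    lo, hi = pwm.min_score, pwm.max_score
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if any(b not in "ACGT" for b in window):
            continue
        for strand, w in (("+", window), ("-", reg.revcomp(window))):
            score = sum(
                pwm.conservation[i] * pwm.freq[i, reg.BASE_INDEX[b]]
                for i, b in enumerate(w)
            )
            mss = (score - lo) / (hi - lo)
            if mss >= cutoff:
                hits.append((chrom, start, strand, mss))
    return hits


def test_consensus_and_anticonsensus_hit_the_normalization_anchors(rng):
    pwm = random_pwm(rng, length=10)
    assert reg.window_mss(pwm.consensus, pwm) == pytest.approx(1.0, abs=1e-12)
    worst = "".join("ACGT"[i] for i in pwm.freq.argmin(axis=1))
    assert reg.window_mss(worst, pwm) == pytest.approx(0.0, abs=1e-12)


def test_scan_matches_brute_force_on_random_sequence(rng):
    pwm = random_pwm(rng, length=19)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    cutoff = 0.80
    got = [(h.chrom, h.start, h.strand, h.mss)
           for h in reg.mss_scan("chr1", seq, pwm, cutoff=cutoff)]
    expected = brute_force_scan("chr1", seq, pwm, cutoff)
    assert len(got) == len(expected)
    for g, e in zip(sorted(got), sorted(expected)):
        assert g[:3] == e[:3]
        assert g[3] == pytest.approx(e[3], abs=1e-9)


def test_windows_containing_n_are_skipped():
    pwm = reg.default_test_pwm()
    seq = "AA" + "GCGTG" + "AA"
    assert len(reg.mss_scan("c", seq, pwm)) >= 1
    assert reg.mss_scan("c", seq[:4] + "N" + seq[5:], pwm) == []
    assert reg.mss_scan("c", "", pwm) == []


def test_scan_is_reverse_complement_symmetric(rng):
    pwm = random_pwm(rng, length=9)
    seq = "".join(rng.choice(list("ACGT"), size=800))
    fwd = reg.mss_scan("c", seq, pwm, cutoff=0.75)
    rev = reg.mss_scan("c", reg.revcomp(seq), pwm, cutoff=0.75)
    n = len(seq)
    mirrored = sorted(
        (n - h.end, n - h.start, {"+": "-", "-": "+"}[h.strand], round(h.mss, 9))
        for h in rev
    )
    assert mirrored == sorted(
        (h.start, h.end, h.strand, round(h.mss, 9)) for h in fwd
    )


def test_raising_cutoff_never_adds_hits(rng):
    pwm = random_pwm(rng, length=9)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    loose = {(h.start, h.strand) for h in reg.mss_scan("c", seq, pwm, cutoff=0.7)}
    tight = {(h.start, h.strand) for h in reg.mss_scan("c", seq, pwm, cutoff=0.9)}
    assert tight <= loose


# ---------------------------------------------------------------------------
# Peak assignment, partitions, co-occurrence
# ---------------------------------------------------------------------------


def peaks_of(rows):
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "fdr", "sex"]))


def test_peak_assignment_window_and_fdr_gate():
    gene = make_gene_model("g1", "chr1", 10_000, 20_000, "+")
    inside = peaks_of([("chr1", 5000, 5200, 0.04, "male")])
    assert [a.gene_id for a in reg.assign_peaks_to_genes(inside, [gene])] == ["g1"]
    not_significant = peaks_of([("chr1", 5000, 5200, 0.06, "male")])
    assert reg.assign_peaks_to_genes(not_significant, [gene]) == []
    too_far = peaks_of([("chr1", 20_500, 20_700, 0.01, "male")])
    assert reg.assign_peaks_to_genes(too_far, [gene]) == []
    # minus-strand gene: flank extends from the TSS (right) side
    minus = make_gene_model("g2", "chr1", 10_000, 20_000, "-")
    downstream = peaks_of([("chr1", 25_000, 25_100, 0.01, "male")])
    assert [a.gene_id for a in reg.assign_peaks_to_genes(downstream, [minus])] == ["g2"]
    assert reg.assign_peaks_to_genes(downstream, [gene]) == []


def test_relaxing_fdr_never_removes_assignments(small_genome):
    peaks = small_genome["peaks"].for_sex("male")
    models = small_genome["models"]
    strict = {a.gene_id for a in reg.assign_peaks_to_genes(peaks, models, fdr_max=0.01)}
    loose = {a.gene_id for a in reg.assign_peaks_to_genes(peaks, models, fdr_max=0.5)}
    assert strict <= loose


def test_planted_peak_links_recovered_exactly(small_genome):
    truth = small_genome["truth"]
    models = small_genome["models"]
    for sex in ("male", "female"):
        assignments = reg.assign_peaks_to_genes(
            small_genome["peaks"].for_sex(sex), models
        )
        got = {a.gene_id for a in assignments}
        expected = {l["gene_id"] for l in truth.planted_peak_gene_links
                    if l["sex"] == sex}
        assert got == expected


def test_sex_partition_is_disjoint_and_exhaustive():
    universe = GeneSet("u", [f"g{i}" for i in range(181)])
    male = [reg.GenePeakAssignment(f"g{i}", [0]) for i in range(135)]       # 79+56
    female = [reg.GenePeakAssignment(f"g{i}", [1]) for i in range(79)] + [
        reg.GenePeakAssignment("g135", [2])
    ]
    part = reg.partition_by_sex(male, female, universe)
    sizes = {k: len(v) for k, v in part.items()}
    assert sizes == {"both": 79, "male_only": 56, "female_only": 1, "neither": 45}
    assert sum(sizes.values()) == 181

    same = reg.partition_by_sex(male, male, universe)
    assert len(same["male_only"]) == len(same["female_only"]) == 0
    empty = reg.partition_by_sex([], [], universe)
    assert len(empty["neither"]) == 181


def test_pdre_counting_requires_full_containment():
    peaks = peaks_of([("chr1", 100, 200, 0.01, "male")])
    assignment = [reg.GenePeakAssignment("g", [0])]
    inside = [reg.MotifHit("chr1", 150, 159, "+", 0.9, "GCGTGAAAA")]
    straddle = [reg.MotifHit("chr1", 195, 204, "+", 0.9, "GCGTGAAAA")]
    _, counts = reg.annotate_peaks_with_pdres(assignment, peaks, inside)
    assert counts["peaks_with_pdre"] == 1
    assignment = [reg.GenePeakAssignment("g", [0])]
    _, counts = reg.annotate_peaks_with_pdres(assignment, peaks, straddle)
    assert counts["peaks_with_pdre"] == 0


def test_planted_dres_under_peaks_counted_exactly(small_genome):
    truth = small_genome["truth"]
    pwm = reg.default_test_pwm()
    hits = []
    for chrom, seq in small_genome["seqs"].items():
        hits.extend(reg.mss_scan(chrom, seq, pwm))
    for sex in ("male", "female"):
        sub = small_genome["peaks"].for_sex(sex)
        assignments = reg.assign_peaks_to_genes(sub, small_genome["models"])
        _, counts = reg.annotate_peaks_with_pdres(assignments, sub, hits)
        expected = sum(
            l["has_dre"] for l in truth.planted_peak_gene_links if l["sex"] == sex
        )
        assert counts["peaks_with_pdre"] == expected
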