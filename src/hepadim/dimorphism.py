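"""Normalized expression, fold-changes, empirical-Bayes posteriors, DE calls.

Counts are variance-stabilized with an arcsinh transform on size-factor
normalized counts (median-of-ratios size factors), location-aligned across
samples by median-centering to a pseudo-reference, and compared between two
groups (e.g. male vs female vehicle livers, or treated vs vehicle within a
sex). Per gene, the moderated t statistic feeds a two-component scale-mixture
model fitted by EM; the posterior probability of membership in the wider
(differential) component is reported as P1(t).

Calling conventions follow the study design this pipeline emulates:
differential expression requires |fold-change| >= 1.5 and P1(t) >= 0.8;
sexual dimorphism requires |fold-change| >= 2.0 and P1(t) >= 0.8 (both
inclusive). Fold-changes are reported as signed log2 ratios; the linear fold
is 2**|log2fc| with the sign carried separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hepadim.io import CountMatrix, FoldChangeTable, FormatError

logger = logging.getLogger("hepadim")

LN2 = float(np.log(2.0))

DE_FC_THRESHOLD = 1.5
DIMORPHIC_FC_THRESHOLD = 2.0
P1T_THRESHOLD = 0.8


# ---------------------------------------------------------------------------
# Normalization / transformation
# ---------------------------------------------------------------------------


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (ratio to per-gene geometric mean).

    Genes with a zero in any sample are excluded from the reference, as usual
    for this estimator; if no gene is everywhere-positive, falls back to
    library-size ratios.
    """
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=1)
    if allpos.sum() >= 1:
        logc = np.log(counts[allpos])
        ref = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        logger.warning("no everywhere-positive gene; using library-size factors")
        lib = counts.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    return sf


def vst(cm: CountMatrix) -> pd.DataFrame:
    """Variance-stabilizing transform: arcsinh(count / size_factor).

    A zero count maps to exactly 0; for large counts the transform behaves
    like ln(2x), so between-group differences divided by ln(2) read as log2
    fold-changes.
    """
    counts = np.asarray(cm.counts, dtype=float)
    if counts.shape[1] < 2:
        raise FormatError("vst requires >= 2 samples")
    if not counts.any():
        raise FormatError("vst on an all-zero count matrix")
    sf = size_factors(counts)
    mat = np.arcsinh(counts / sf)
    return pd.DataFrame(mat, index=cm.gene_ids, columns=cm.sample_ids)


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Align per-sample location to a per-gene median pseudo-reference.

    For each sample the median (over genes) of its difference to the
    pseudo-reference is subtracted, so a constant per-sample shift is removed
    exactly.
    """
    if matrix.shape[1] == 1:
        logger.warning("single sample: normalization is the identity")
        return matrix.copy()
    ref = matrix.median(axis=1)
    shifts = matrix.sub(ref, axis=0).median(axis=0)
    return matrix.sub(shifts, axis=1)


# ---------------------------------------------------------------------------
# Empirical-Bayes two-component posterior
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Two-component zero-mean Gaussian scale mixture over moderated t."""

    pi0: float
    pi1: float
    sigma0: float
    sigma1: float
    converged: bool
    n_iter: int
    loglik_path: np.ndarray

    def posterior_alt(self, t: np.ndarray) -> np.ndarray:
        from scipy.stats import norm

        f0 = self.pi0 * norm.pdf(t, 0.0, self.sigma0)
        f1 = self.pi1 * norm.pdf(t, 0.0, self.sigma1)
        total = f0 + f1
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        return f1 / total


def fit_scale_mixture(
    t: np.ndarray,
    min_ratio: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MixtureFit:
    """EM fit of pi1, sigma0, sigma1 (sigma1 >= min_ratio * sigma0).

    Both components have mean zero, so the fit depends on t only through t**2
    and posteriors are exactly invariant to a global sign flip of t. The
    constrained M-step alternates closed-form updates of sigma0 and the scale
    ratio (clipped at min_ratio), each of which cannot decrease the EM lower
    bound, so the log-likelihood path is non-decreasing.
    """
    from scipy.stats import norm

    t = np.asarray(t, dtype=float)
    n = t.size
    t2 = t**2
    # robust init: null scale from the central mass, wide alternative
    sigma0 = float(np.median(np.abs(t))) / 0.6745
    sigma0 = max(sigma0, 1e-6)
    ratio = 4.0
    pi1 = 0.1
    loglik_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sigma1 = ratio * sigma0
        f0 = (1 - pi1) * norm.pdf(t, 0.0, sigma0)
        f1 = pi1 * norm.pdf(t, 0.0, sigma1)
        total = np.maximum(f0 + f1, np.finfo(float).tiny)
        ll = float(np.log(total).sum())
        loglik_path.append(ll)
        if len(loglik_path) > 1 and abs(ll - loglik_path[-2]) < tol * (1 + abs(ll)):
            converged = True
            break
        w = f1 / total  # responsibility of the wide component
        sw = float(w.sum())
        pi1 = sw / n
        pi1 = min(max(pi1, 1e-12), 1 - 1e-12)
        # constrained M-step: sigma0 and ratio given responsibilities
        for _ in range(5):
            s0sq = float(((1 - w) * t2).sum() + (w * t2).sum() / ratio**2) / n
            sigma0 = max(np.sqrt(s0sq), 1e-9)
            if sw > 0:
                rsq = float((w * t2).sum()) / (sw * sigma0**2)
                ratio = max(np.sqrt(max(rsq, 0.0)), min_ratio)
            else:
                ratio = min_ratio
    if not converged:
        logger.warning("mixture EM did not converge in %d iterations", max_iter)
    return MixtureFit(
        pi0=1 - pi1,
        pi1=pi1,
        sigma0=sigma0,
        sigma1=ratio * sigma0,
        converged=converged,
        n_iter=it,
        loglik_path=np.asarray(loglik_path),
    )


def empirical_bayes_posteriors(
    matrix: pd.DataFrame,
    group_labels: "pd.Series | np.ndarray | list[str]",
    groups: tuple[str, str] | None = None,
    contrast_id: str = "contrast",
    nu0: float = 4.0,
    max_reads: "np.ndarray | None" = None,
) -> tuple[FoldChangeTable, MixtureFit]:
    """Per-gene log2 fold-changes and empirical-Bayes posteriors P1(t).

    ``matrix`` is the transformed/normalized genes x samples frame;
    ``group_labels`` assigns each sample (column) to one of two groups.
    log2fc is (mean of first group - mean of second group) / ln 2, i.e.
    positive values mean higher in the first group. Gene variances are
    shrunk toward their global mean with ``nu0`` prior pseudo-samples before
    forming moderated t statistics.
    """
    labels = np.asarray(group_labels)
    if labels.size != matrix.shape[1]:
        raise FormatError("group_labels length must equal number of samples")
    if groups is None:
        uniq = list(dict.fromkeys(labels.tolist()))
        if len(uniq) != 2:
            raise FormatError(f"need exactly 2 groups, got {uniq}")
        groups = (uniq[0], uniq[1])
    g1 = labels == groups[0]
    g2 = labels == groups[1]
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise FormatError("each group needs >= 2 samples")

    x = matrix.to_numpy(dtype=float)
    m1 = x[:, g1].mean(axis=1)
    m2 = x[:, g2].mean(axis=1)
    delta = m1 - m2
    log2fc = delta / LN2

    v1 = x[:, g1].var(axis=1, ddof=1)
    v2 = x[:, g2].var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    s2_prior = float(s2.mean())
    s2_mod = (nu0 * s2_prior + df * s2) / (nu0 + df)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    tstat = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)

    fit = fit_scale_mixture(tstat)
    p1t = fit.posterior_alt(tstat)

    if max_reads is None:
        max_reads = np.zeros(matrix.shape[0], dtype=int)
    table = FoldChangeTable(
        pd.DataFrame(
            {
                "gene_id": list(matrix.index),
                "contrast_id": contrast_id,
                "log2fc": log2fc,
                "p1t": p1t,
                "max_reads": np.asarray(max_reads, dtype=int),
            }
        )
    )
    logger.info(
        "empirical Bayes fit (%s vs %s): pi1=%.3f sigma0=%.2f sigma1=%.2f (%d iter)",
        groups[0], groups[1], fit.pi1, fit.sigma0, fit.sigma1, fit.n_iter,
    )
    return table, fit


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimorphismCall:
    gene_id: str
    log2fc_mf: float
    p1t: float
    bias: str  # male / female / none


def call_dimorphic(
    table: FoldChangeTable,
    fc_threshold: float = DIMORPHIC_FC_THRESHOLD,
    p_threshold: float = P1T_THRESHOLD,
) -> list[DimorphismCall]:
    """Sex-bias calls: |fold| >= fc_threshold and P1(t) >= p_threshold.

    log2fc is taken as the male-over-female log2 ratio, so positive passing
    genes are male-biased and negative ones female-biased.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise FormatError("thresholds must be positive")
    calls = []
    for row in table.data.itertuples(index=False):
        fold = 2.0 ** abs(row.log2fc)
        if fold >= fc_threshold and row.p1t >= p_threshold:
            bias = "male" if row.log2fc > 0 else "female"
        else:
            bias = "none"
        calls.append(DimorphismCall(row.gene_id, float(row.log2fc), float(row.p1t), bias))
    n_m = sum(c.bias == "male" for c in calls)
    n_f = sum(c.bias == "female" for c in calls)
    logger.info("dimorphic calls: %d male-biased, %d female-biased", n_m, n_f)
    return calls


def call_differential(
    table: FoldChangeTable,
    fc_threshold: float = DE_FC_THRESHOLD,
    p_threshold: float = P1T_THRESHOLD,
) -> pd.DataFrame:
    """Differential-expression flags: |fold| >= fc_threshold, P1(t) >= p_threshold.

    Returns a frame with gene_id, log2fc, p1t, de (bool) and direction
    (induced / repressed / none).
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise FormatError("thresholds must be positive")
    df = table.data.copy()
    fold = 2.0 ** np.abs(df["log2fc"].to_numpy(float))
    de = (fold >= fc_threshold) & (df["p1t"].to_numpy(float) >= p_threshold)
    direction = np.where(~de, "none", np.where(df["log2fc"] > 0, "induced", "repressed"))
    out = df[["gene_id", "contrast_id", "log2fc", "p1t", "max_reads"]].copy()
    out["de"] = de
    out["direction"] = direction
    logger.info("differential calls: %d/%d DE", int(de.sum()), len(out))
    return out


def dimorphism_analysis(
    cm: CountMatrix,
    groups: tuple[str, str] = ("male", "female"),
    contrast_id: str = "male_vs_female",
    fc_threshold: float = DIMORPHIC_FC_THRESHOLD,
    p_threshold: float = P1T_THRESHOLD,
) -> tuple[FoldChangeTable, list[DimorphismCall], list[str]]:
    """End-to-end: VST -> normalize -> empirical Bayes -> dimorphic calls.

    Genes with zero counts in every sample are dropped before fitting and
    returned as the third element ("not assessed").
    """
    counts = np.asarray(cm.counts)
    assessed = counts.sum(axis=1) > 0
    dropped = [g for g, keep in zip(cm.gene_ids, assessed) if not keep]
    if dropped:
        logger.info("dropping %d all-zero genes (not assessed)", len(dropped))
    sub = CountMatrix(
        gene_ids=[g for g, keep in zip(cm.gene_ids, assessed) if keep],
        sample_ids=cm.sample_ids,
        counts=counts[assessed],
        sample_meta=cm.sample_meta,
    )
    mat = normalize(vst(sub))
    labels = [sub.sex_of(s) for s in sub.sample_ids]
    table, _fit = empirical_bayes_posteriors(
        mat,
        labels,
        groups=groups,
        contrast_id=contrast_id,
        max_reads=np.asarray(sub.counts).max(axis=1),
    )
    calls = call_dimorphic(table, fc_threshold=fc_threshold, p_threshold=p_threshold)
    return table, calls, dropped
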