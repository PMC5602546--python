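"""Tissue-specificity scoring from a multi-tissue expression atlas.

A gene's specificity for a target tissue is the difference (DeltaSignal)
between its signal in that tissue and its maximum signal over every other
tissue. Genes with DeltaSignal at or above an absolute threshold (default
5,000 signal units) are called tissue-specific. The absolute difference is
used rather than a fold change so only highly expressed genes qualify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hepadim.io import ExpressionAtlas, FormatError

logger = logging.getLogger("hepadim")

DELTA_SIGNAL_THRESHOLD = 5000.0


@dataclass(frozen=True)
class SpecificityScore:
    gene_id: str
    delta_signal: float
    target_tissue: str


@dataclass
class GeneSet:
    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set name must be nonempty")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.name!r} has duplicate members")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


def delta_signal(atlas: ExpressionAtlas, target_tissue: str) -> list[SpecificityScore]:
    """DeltaSignal = target-tissue signal minus max signal over other tissues.

    One score per gene, in atlas row order; invariant to tissue column order.
    """
    if target_tissue not in atlas.tissue_ids:
        raise FormatError(f"tissue {target_tissue!r} not in atlas")
    if len(atlas.tissue_ids) < 2:
        raise FormatError("atlas must contain >= 2 tissues")
    t = atlas.tissue_ids.index(target_tissue)
    target = atlas.signal[:, t]
    others = np.delete(atlas.signal, t, axis=1)
    delta = target - others.max(axis=1)
    return [
        SpecificityScore(g, float(d), target_tissue)
        for g, d in zip(atlas.gene_ids, delta)
    ]


def call_specific_genes(
    scores: list[SpecificityScore], threshold: float = DELTA_SIGNAL_THRESHOLD
) -> GeneSet:
    """Genes with delta_signal >= threshold (inclusive)."""
    if not np.isfinite(threshold):
        raise FormatError("threshold must be finite")
    target = scores[0].target_tissue if scores else "tissue"
    members = [s.gene_id for s in scores if s.delta_signal >= threshold]
    logger.info(
        "called %d/%d %s-specific genes at DeltaSignal >= %g",
        len(members), len(scores), target, threshold,
    )
    return GeneSet(name=f"{target}_specific", members=members)


def scores_to_frame(scores: list[SpecificityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "delta_signal": [s.delta_signal for s in scores],
            "target_tissue": [s.target_tissue for s in scores],
        }
    )
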