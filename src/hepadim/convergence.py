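"""Classification of treatment-induced loss of sexually dimorphic expression.

For a gene with a baseline sex bias, the dimorphism index is the log2
male/female expression ratio. With per-sex treatment responses (log2
fold-changes of treated over vehicle), the treated index is obtained
additively: di_treated = di_baseline + log2fc_male - log2fc_female. The
classifier compares the two indices under differential-expression gates:

- ``unchanged``: neither sex responds (no DE in either response).
- ``lost_dimorphism``: both sexes respond and the net change opposes the
  baseline bias — the indices converge toward (possibly across) zero, as
  when a male-biased gene is repressed in males while induced in females.
- ``feminized_male`` / ``masculinized_female``: only the male (resp. female)
  response is DE and it moves the index toward the other sex's profile.
- ``reinforced``: the net change widens the divergence in the direction of
  the baseline bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from hepadim.dimorphism import (
    DE_FC_THRESHOLD,
    P1T_THRESHOLD,
    DimorphismCall,
)
from hepadim.io import FoldChangeTable, FormatError

logger = logging.getLogger("hepadim")

CLASSES = (
    "lost_dimorphism",
    "reinforced",
    "feminized_male",
    "masculinized_female",
    "unchanged",
)

# Gene panels named in the study this pipeline emulates; dose context varies
# per gene ("up to" folds at 30 ug/kg), but panels are evaluated one
# contrast at a time.
DEFAULT_PANELS: dict[str, list[str]] = {
    "hepatokines": ["Lect2", "Igf1", "Ahsg", "Angptl6", "Sepp1", "Fgf21", "Serpina6"],
    "albuminoids": ["Alb", "Afp", "Afm", "Gc"],
    "fetal_markers": ["Afp", "H19", "Gpc3"],
    "mups": ["Mup1", "Mup3", "Mup7", "Mup10", "Mup11", "Mup14", "Mup17", "Mup20", "Mup21"],
    "hemoglobins": ["Hba-a1", "Hba-a2", "Hbb-bs", "Hbb-bt"],
    "regulators": [
        "Ghr", "Stat5a", "Stat5b", "Bcl6", "Hnf4a", "Onecut1",
        "Foxa1", "Foxa2", "Foxa3", "Zhx2", "Cux2",
    ],
}


@dataclass(frozen=True)
class ConvergenceCall:
    gene_id: str
    baseline_bias: str  # male / female
    male_log2fc: float
    male_de: bool
    female_log2fc: float
    female_de: bool
    di_baseline: float
    di_treated: float
    klass: str


def _de_gate(log2fc: float, p1t: float, fc_threshold: float, p_threshold: float) -> bool:
    return 2.0 ** abs(log2fc) >= fc_threshold and p1t >= p_threshold


def classify_convergence(
    baseline: list[DimorphismCall],
    male_fc: FoldChangeTable,
    female_fc: FoldChangeTable,
    fc_threshold: float = DE_FC_THRESHOLD,
    p_threshold: float = P1T_THRESHOLD,
) -> list[ConvergenceCall]:
    """Classify every baseline-dimorphic gene by its per-sex responses.

    Genes missing from a response table get a zero / not-DE response for
    that sex (logged). The baseline dimorphism index is the call's
    male-over-female log2 ratio.
    """
    male_rows = {r.gene_id: r for r in male_fc.data.itertuples(index=False)}
    female_rows = {r.gene_id: r for r in female_fc.data.itertuples(index=False)}
    calls: list[ConvergenceCall] = []
    missing = 0
    for b in baseline:
        if b.bias == "none":
            continue
        mr = male_rows.get(b.gene_id)
        fr = female_rows.get(b.gene_id)
        if mr is None or fr is None:
            missing += 1
        l2m = float(mr.log2fc) if mr is not None else 0.0
        l2f = float(fr.log2fc) if fr is not None else 0.0
        de_m = (
            _de_gate(l2m, float(mr.p1t), fc_threshold, p_threshold)
            if mr is not None else False
        )
        de_f = (
            _de_gate(l2f, float(fr.p1t), fc_threshold, p_threshold)
            if fr is not None else False
        )
        di_b = b.log2fc_mf
        di_t = di_b + l2m - l2f
        klass = _classify(di_b, di_t, de_m, de_f)
        calls.append(
            ConvergenceCall(
                gene_id=b.gene_id,
                baseline_bias=b.bias,
                male_log2fc=l2m,
                male_de=de_m,
                female_log2fc=l2f,
                female_de=de_f,
                di_baseline=di_b,
                di_treated=di_t,
                klass=klass,
            )
        )
    if missing:
        logger.warning("%d genes missing from a response table (response set to 0)",
                       missing)
    return calls


def _classify(di_b: float, di_t: float, de_m: bool, de_f: bool) -> str:
    if not de_m and not de_f:
        return "unchanged"
    delta = di_t - di_b
    converging = delta * np.sign(di_b) < 0
    if not converging:
        return "reinforced"
    if de_m and de_f:
        return "lost_dimorphism"
    if de_m:
        return "feminized_male"
    return "masculinized_female"


def calls_to_frame(calls: list[ConvergenceCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


# ---------------------------------------------------------------------------
# Fixed gene panels
# ---------------------------------------------------------------------------


@dataclass
class PanelSummary:
    panel: str
    table: pd.DataFrame  # gene_id, per-sex log2fc/fold/de
    consensus: str  # induced / repressed / mixed / none
    n_de: int
    missing: list[str]


def load_panels(path: str | None = None) -> dict[str, list[str]]:
    if path is None:
        return {k: list(v) for k, v in DEFAULT_PANELS.items()}
    with open(path) as fh:
        panels = yaml.safe_load(fh)
    if not isinstance(panels, dict):
        raise FormatError("panel config must map panel name -> gene list")
    return {str(k): [str(g) for g in v] for k, v in panels.items()}


def summarize_panels(
    tables: dict[str, FoldChangeTable],
    panels: dict[str, list[str]] | None = None,
    fc_threshold: float = DE_FC_THRESHOLD,
    p_threshold: float = P1T_THRESHOLD,
) -> list[PanelSummary]:
    """Signed linear folds per sex for each fixed gene panel.

    ``tables`` maps a label (e.g. sex) to its response table. The consensus
    direction is the majority sign among DE members across all tables
    ("mixed" on a tie, "none" when no member is DE); panels whose genes are
    all absent are skipped with a warning.
    """
    panels = panels if panels is not None else load_panels()
    out: list[PanelSummary] = []
    for name, genes in panels.items():
        rows = []
        missing = []
        n_up = n_down = 0
        for g in genes:
            row: dict[str, object] = {"gene_id": g}
            seen = False
            for label, table in tables.items():
                sub = table.data[table.data["gene_id"] == g]
                if sub.empty:
                    row[f"{label}_log2fc"] = np.nan
                    row[f"{label}_fold"] = np.nan
                    row[f"{label}_de"] = False
                    continue
                seen = True
                l2 = float(sub["log2fc"].iloc[0])
                p = float(sub["p1t"].iloc[0])
                de = _de_gate(l2, p, fc_threshold, p_threshold)
                # signed linear fold: magnitude 2^|log2fc|, sign of log2fc
                row[f"{label}_log2fc"] = l2
                row[f"{label}_fold"] = float(np.sign(l2) * 2.0 ** abs(l2))
                row[f"{label}_de"] = de
                if de:
                    if l2 > 0:
                        n_up += 1
                    else:
                        n_down += 1
            if not seen:
                missing.append(g)
            rows.append(row)
        if len(missing) == len(genes):
            logger.warning("panel %s: no member present in any table; skipped", name)
            continue
        if n_up == n_down == 0:
            consensus = "none"
        elif n_up == n_down:
            consensus = "mixed"
        else:
            consensus = "induced" if n_up > n_down else "repressed"
        out.append(
            PanelSummary(
                panel=name,
                table=pd.DataFrame(rows),
                consensus=consensus,
                n_de=n_up + n_down,
                missing=missing,
            )
        )
    return out
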