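"""Cross-fraction inference of direct miRNA targets and developmental concordance.

A transcript is called a direct target when its abundance rises in the
Ago2-immunoprecipitated (RISC) fraction at the chosen FDR.  The paired
global-fraction outcome assigns the mode of regulation:

* significant global decrease  -> ``degradation`` (RISC-mediated decay)
* no significant global change -> ``translational_suppression``
* significant global increase  -> excluded (neither admissible outcome;
  reported with a reason code, not called)

The concordance analysis asks whether perturbation-responsive mRNAs move in
the opposite direction during postnatal development (adult vs P10), the
expectation when the perturbed miRNA itself falls with maturation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .counts_io import CONCORDANCE_COLUMNS, DIRECT_TARGET_COLUMNS

MODE_DEGRADATION = "degradation"
MODE_SUPPRESSION = "translational_suppression"
EXCLUDED_GLOBAL_UP = "excluded_global_increase"

OPPOSITE_SIGNIFICANT = "opposite_significant"
OPPOSITE_NONSIGNIFICANT = "opposite_nonsignificant"
CONCORDANT = "concordant"


class UniverseMismatchError(ValueError):
    pass


@dataclass
class ConcordanceSummary:
    n_responsive: int
    n_opposite_significant: int
    n_opposite_nonsignificant: int
    n_concordant: int

    def percentages(self) -> dict[str, Optional[int]]:
        if self.n_responsive == 0:
            return {OPPOSITE_SIGNIFICANT: None, OPPOSITE_NONSIGNIFICANT: None,
                    CONCORDANT: None}
        return {
            OPPOSITE_SIGNIFICANT: round(100 * self.n_opposite_significant / self.n_responsive),
            OPPOSITE_NONSIGNIFICANT: round(100 * self.n_opposite_nonsignificant / self.n_responsive),
            CONCORDANT: round(100 * self.n_concordant / self.n_responsive),
        }


def _aligned(risc_de: pd.DataFrame, global_de: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    r = risc_de.set_index("gene_id")
    g = global_de.set_index("gene_id")
    only_r = r.index.difference(g.index)
    only_g = g.index.difference(r.index)
    if len(only_r) or len(only_g):
        raise UniverseMismatchError(
            f"gene universes differ: {len(only_r)} genes only in RISC, "
            f"{len(only_g)} only in global (e.g. "
            f"{list(only_r[:3]) + list(only_g[:3])})"
        )
    return r, g.loc[r.index]


def classify_direct_targets(
    risc_de: pd.DataFrame,
    global_de: pd.DataFrame,
    fdr: float = 0.1,
    min_risc_lfc: float = 0.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Call direct targets from paired RISC / global DE results.

    Both inputs are DEResult frames over the same gene universe (genes that
    passed detection filters in both fractions).  A gene is called when
    ``risc_q <= fdr`` and ``risc_log2fc > min_risc_lfc`` (default: any
    positive enrichment); the mode comes from the global outcome as
    described in the module docstring.  Returns ``(calls, excluded)``:
    calls sorted by RISC q ascending with DirectTargetCall columns, and the
    RISC-enriched genes excluded for a significant global increase.
    """
    r, g = _aligned(risc_de, global_de)
    enriched = (r["qvalue"] <= fdr) & (r["log2fc"] > min_risc_lfc)
    global_sig = g["qvalue"] <= fdr
    degraded = enriched & global_sig & (g["log2fc"] < 0)
    suppressed = enriched & ~global_sig
    excluded_up = enriched & global_sig & (g["log2fc"] >= 0)

    def _frame(mask: pd.Series, mode: str) -> pd.DataFrame:
        idx = r.index[mask]
        return pd.DataFrame(
            {
                "gene_id": idx,
                "mode": mode,
                "risc_log2fc": r.loc[idx, "log2fc"].to_numpy(),
                "risc_q": r.loc[idx, "qvalue"].to_numpy(),
                "global_log2fc": g.loc[idx, "log2fc"].to_numpy(),
                "global_q": g.loc[idx, "qvalue"].to_numpy(),
            },
            columns=DIRECT_TARGET_COLUMNS,
        )

    calls = pd.concat(
        [_frame(degraded, MODE_DEGRADATION), _frame(suppressed, MODE_SUPPRESSION)],
        ignore_index=True,
    )
    calls = calls.sort_values("risc_q", kind="mergesort").reset_index(drop=True)
    excluded = _frame(excluded_up, EXCLUDED_GLOBAL_UP).reset_index(drop=True)
    return calls, excluded


def concordance_with_development(
    responsive: pd.DataFrame,
    developmental: pd.DataFrame,
    fdr: float = 0.1,
) -> Tuple[pd.DataFrame, ConcordanceSummary]:
    """Classify perturbation-responsive mRNAs against the developmental contrast.

    ``responsive`` holds the perturbation DE rows already selected as
    significant (its log2fc sign gives the perturbation direction);
    ``developmental`` is the adult-vs-P10 DEResult frame and must cover
    every responsive gene (the universes are intersected upstream).  A gene
    is ``opposite_significant`` when the developmental sign differs and
    developmental q <= fdr, ``opposite_nonsignificant`` when the sign
    differs without significance, else ``concordant``.
    """
    dev = developmental.set_index("gene_id")
    missing = [g for g in responsive["gene_id"] if g not in dev.index]
    if missing:
        raise UniverseMismatchError(
            f"{len(missing)} responsive genes absent from the developmental "
            f"results (e.g. {missing[:5]})"
        )
    if responsive.empty:
        empty = pd.DataFrame(columns=CONCORDANCE_COLUMNS)
        return empty, ConcordanceSummary(0, 0, 0, 0)

    pert_dir = np.where(responsive["log2fc"].to_numpy() > 0, "up", "down")
    dev_rows = dev.loc[responsive["gene_id"]]
    dev_dir = np.where(dev_rows["log2fc"].to_numpy() > 0, "up", "down")
    dev_q = dev_rows["qvalue"].to_numpy()
    opposite = pert_dir != dev_dir
    cls = np.where(
        opposite & (dev_q <= fdr),
        OPPOSITE_SIGNIFICANT,
        np.where(opposite, OPPOSITE_NONSIGNIFICANT, CONCORDANT),
    )
    records = pd.DataFrame(
        {
            "gene_id": responsive["gene_id"].to_numpy(),
            "perturbation_direction": pert_dir,
            "developmental_direction": dev_dir,
            "developmental_q": dev_q,
            "class": cls,
        },
        columns=CONCORDANCE_COLUMNS,
    )
    summary = ConcordanceSummary(
        n_responsive=len(records),
        n_opposite_significant=int((cls == OPPOSITE_SIGNIFICANT).sum()),
        n_opposite_nonsignificant=int((cls == OPPOSITE_NONSIGNIFICANT).sum()),
        n_concordant=int((cls == CONCORDANT).sum()),
    )
    return records, summary
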