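"""Signed fold-change arithmetic for microarray-style group means.

The sign convention is the one used in islet expression tables: a linear
ratio r = 2^(alt - ref) is reported as +r when r >= 1 and as -1/r when
r < 1, so "-4.2" reads as "4.2-fold lower".  |signed fold| is therefore
always >= 1 and equal group means give exactly +1.0.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

TABLE1_FIXTURE = "table1_mirnas.tsv"


def as_signed_fold(ratio: float) -> float:
    """Convert a positive linear ratio to the signed-fold convention."""
    if ratio <= 0 or not np.isfinite(ratio):
        raise ValueError(f"ratio must be positive and finite, got {ratio}")
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def signed_fold_change(mean_log2_ref: float, mean_log2_alt: float) -> float:
    """Signed linear fold of `alt` relative to `ref` from log2 group means."""
    return as_signed_fold(2.0 ** (float(mean_log2_alt) - float(mean_log2_ref)))


def round_fold(fold: float, decimals: int = 1) -> float:
    """Display rounding: half away from zero (numpy.round is half-even)."""
    scale = 10 ** decimals
    return float(np.sign(fold) * np.floor(abs(fold) * scale + 0.5) / scale)


def select_changed(
    records: pd.DataFrame, fc_threshold: float = 2.0, q_threshold: float = 0.05
) -> Tuple[pd.DataFrame, int, int]:
    """Two-fold selection rule on a (feature_id, signed_fc, qvalue) frame.

    Selected iff |signed_fc| >= fc_threshold and q <= q_threshold, both
    boundaries inclusive.  Returns (selected frame, n up, n down).
    """
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be positive")
    required = {"feature_id", "signed_fc", "qvalue"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if records["qvalue"].isna().any():
        bad = records.loc[records["qvalue"].isna(), "feature_id"].tolist()
        raise ValueError(f"records without q-values: {bad}")
    sel = records[
        (records["signed_fc"].abs() >= fc_threshold)
        & (records["qvalue"] <= q_threshold)
    ]
    n_up = int((sel["signed_fc"] > 0).sum())
    n_down = int((sel["signed_fc"] < 0).sum())
    return sel, n_up, n_down


def load_table1_fixture() -> pd.DataFrame:
    """Packaged microarray table: 17 maturation-regulated miRNAs.

    Columns: mirna, fold_change_adult_vs_p10 (printed signed fold),
    adjusted_p, mean_p10_log2, mean_adult_log2.
    """
    with resources.files("isletmir.data").joinpath(TABLE1_FIXTURE).open() as fh:
        return pd.read_csv(fh, sep="\t")


def check_table1_fixture(tolerance: float = 0.1) -> pd.DataFrame:
    """Recompute every fixture row's signed fold from its log2 means.

    Returns a frame with the recomputed fold, whether it matches the printed
    fold exactly at one decimal, and whether it is within ``tolerance``
    (residuals at the third digit trace back to the one-decimal rounding of
    the printed log2 means).
    """
    tab = load_table1_fixture()
    recomputed = [
        signed_fold_change(r.mean_p10_log2, r.mean_adult_log2)
        for r in tab.itertuples()
    ]
    tab = tab.assign(recomputed_fold=recomputed)
    tab["exact_one_decimal"] = [
        round_fold(rc, 1) == printed
        for rc, printed in zip(tab["recomputed_fold"], tab["fold_change_adult_vs_p10"])
    ]
    tab["within_tolerance"] = (
        (tab["recomputed_fold"] - tab["fold_change_adult_vs_p10"]).abs() <= tolerance
    )
    return tab
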