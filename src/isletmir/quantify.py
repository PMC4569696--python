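"""Abundance units (RpM, FPKM), low-abundance filters, and qPCR relative expression.

Two filters operate on different scales and with different boundary
conventions, both honoured strictly:

* miRNAs are *flagged* ``below_read_cutoff`` when strictly more than a given
  fraction of samples (default 50%) fall strictly below an RpM threshold
  (default 10 RpM); flagged genes are reported, not deleted.
* mRNAs are *removed* when their total reads over all samples amount to less
  than a given fraction (default 1/100,000) of the grand total; a gene sitting
  exactly on the threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, GeneLengths

KEPT = "kept"
BELOW_READ_CUTOFF = "below_read_cutoff"
REMOVED_LOW_FRACTION = "removed_low_fraction"


class DegenerateLibraryError(ValueError):
    pass


@dataclass
class AbundanceMatrix:
    """Non-negative real abundances in a declared unit (``RpM`` or ``FPKM``)."""

    values: pd.DataFrame  # genes x samples
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("RpM", "FPKM"):
            raise ValueError(f"unknown abundance unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")


def compute_rpm(counts: CountMatrix) -> AbundanceMatrix:
    """Reads per million reads mapped: count / column-total x 1e6.

    Each column of the result sums to 1e6 whenever the library has reads;
    an all-zero library is a degenerate input.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise DegenerateLibraryError(f"zero total reads in sample(s) {zero}")
    return AbundanceMatrix(counts.counts / totals * 1e6, "RpM")


def compute_fpkm(counts: CountMatrix, lengths: GeneLengths) -> AbundanceMatrix:
    """Fragments per kilobase of exon per million mapped reads.

    value[g, s] = count[g, s] / (length_kb(g) * total(s) / 1e6).
    """
    missing = [g for g in counts.gene_ids if g not in lengths.lengths.index]
    if missing:
        raise KeyError(f"genes without exonic length: {missing[:10]}")
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise DegenerateLibraryError(f"zero total reads in sample(s) {zero}")
    kb = lengths.lengths.loc[counts.gene_ids].astype(float) / 1e3
    vals = counts.counts.div(totals / 1e6, axis=1).div(kb, axis=0)
    return AbundanceMatrix(vals, "FPKM")


def flag_low_mirnas(
    abund: AbundanceMatrix,
    threshold: float = 10.0,
    sample_fraction: float = 0.5,
) -> pd.DataFrame:
    """Flag miRNAs below the read cutoff (report-only, nothing deleted).

    A miRNA is ``below_read_cutoff`` iff strictly more than
    ``sample_fraction`` of the samples show RpM strictly below ``threshold``.
    Returns a FilterReport frame (gene_id, flag, statistic = fraction of
    samples below threshold).
    """
    if abund.unit != "RpM":
        raise ValueError(f"flag_low_mirnas needs RpM input, got {abund.unit}")
    frac_below = (abund.values < threshold).mean(axis=1)
    flag = np.where(frac_below > sample_fraction, BELOW_READ_CUTOFF, KEPT)
    return pd.DataFrame(
        {"gene_id": abund.values.index, "flag": flag, "statistic": frac_below.to_numpy()}
    )


def filter_low_mrnas(
    counts: CountMatrix, fraction_threshold: float = 1e-5
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Remove mRNAs holding < ``fraction_threshold`` of the grand total reads.

    The denominator is the grand total over all samples of the matrix; a
    gene at exactly the threshold is kept.  Returns the reduced matrix
    (row order preserved) and a FilterReport covering every input gene.
    """
    grand = int(counts.counts.to_numpy().sum())
    if grand == 0:
        raise DegenerateLibraryError("grand total of counts is zero")
    gene_frac = counts.counts.sum(axis=1) / grand
    removed = gene_frac < fraction_threshold
    report = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "flag": np.where(removed, REMOVED_LOW_FRACTION, KEPT),
            "statistic": gene_frac.to_numpy(),
        }
    )
    kept = counts.counts.loc[~removed.to_numpy()]
    return CountMatrix(kept, counts.sample_meta), report


def qpcr_relative_expression(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    baseline_condition: str,
) -> pd.Series:
    """Delta-delta-Ct relative expression per condition, as signed fold.

    ``ct`` is long-format (sample_id, gene_id, Ct, condition).  Per
    condition, dCt = mean Ct(target) - mean Ct(reference); expression
    relative to baseline is 2^-(dCt - dCt_baseline), reported with the
    negative-reciprocal sign convention (0.25 -> -4.0, 1.0 -> +1.0).
    """
    from .foldchange import as_signed_fold

    required = {"sample_id", "gene_id", "Ct", "condition"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ref_samples = set(ct.loc[ct["gene_id"] == reference_gene, "sample_id"])
    all_samples = set(ct["sample_id"])
    if ref_samples != all_samples:
        raise ValueError(
            f"reference gene {reference_gene!r} missing in samples "
            f"{sorted(all_samples - ref_samples)}"
        )
    dct = {}
    for cond, sub in ct.groupby("condition"):
        t = sub.loc[sub["gene_id"] == target_gene, "Ct"]
        r = sub.loc[sub["gene_id"] == reference_gene, "Ct"]
        if t.empty:
            raise ValueError(f"target {target_gene!r} unmeasured in condition {cond!r}")
        dct[cond] = t.mean() - r.mean()
    if baseline_condition not in dct:
        raise ValueError(f"baseline condition {baseline_condition!r} not present")
    base = dct[baseline_condition]
    rel = {cond: 2.0 ** -(d - base) for cond, d in dct.items()}
    return pd.Series({cond: as_signed_fold(r) for cond, r in rel.items()})
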