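"""Shared fixtures: small hand-built matrices and the default synthetic run.

The expensive end-to-end run on the default synthetic dataset (5,000 mRNAs,
100+100 planted direct targets, n=4 per group) is session-scoped so the
recovery, concordance and acceptance tests share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from isletmir.counts_io import CountMatrix
from isletmir.diffexpr import run_de
from isletmir.quantify import filter_low_mrnas
from isletmir.risc import classify_direct_targets, concordance_with_development
from isletmir.simulate import (
    SimulationConfig,
    generate_developmental_counts,
    generate_paired_fraction_counts,
)

SEED = 1


def make_count_matrix(array, conditions, fraction="global", gene_ids=None):
    arr = np.asarray(array)
    genes = gene_ids or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = [f"s{j + 1}" for j in range(arr.shape[1])]
    counts = pd.DataFrame(arr, index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "fraction": [fraction] * arr.shape[1],
            "condition": list(conditions),
            "timepoint": [""] * arr.shape[1],
        },
        index=samples,
    )
    return CountMatrix(counts, meta)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(rng_seed=SEED)


@pytest.fixture(scope="session")
def recovery_run(default_config):
    """Default-conditions end-to-end run: generate, filter, DE both fractions, call."""
    g, r, truth = generate_paired_fraction_counts(default_config)
    g_f, _ = filter_low_mrnas(g)
    r_f, _ = filter_low_mrnas(r)
    universe = [x for x in g_f.gene_ids if x in set(r_f.gene_ids)]
    g_f, r_f = g_f.subset_genes(universe), r_f.subset_genes(universe)
    global_de = run_de(g_f, ("control", "perturbed"), fdr=0.1)
    risc_de = run_de(r_f, ("control", "perturbed"), fdr=0.1)
    calls, excluded = classify_direct_targets(risc_de, global_de, fdr=0.1)
    return {
        "config": default_config,
        "truth": truth.set_index("feature_id"),
        "universe": universe,
        "global_de": global_de,
        "risc_de": risc_de,
        "calls": calls,
        "excluded": excluded,
        "global_counts": g,
        "risc_counts": r,
    }


@pytest.fixture(scope="session")
def concordance_run(default_config, recovery_run):
    dev = generate_developmental_counts(default_config, recovery_run["truth"].reset_index())
    dev_f, _ = filter_low_mrnas(dev)
    dev_universe = [x for x in recovery_run["universe"] if x in set(dev_f.gene_ids)]
    dev_de = run_de(dev_f.subset_genes(dev_universe), ("P10", "adult"), fdr=0.1)
    gde = recovery_run["global_de"]
    responsive = gde[(gde["qvalue"] <= 0.1) & gde["gene_id"].isin(dev_universe)]
    records, summary = concordance_with_development(responsive, dev_de, fdr=0.1)
    return {"records": records, "summary": summary, "dev_de": dev_de,
            "responsive": responsive}
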