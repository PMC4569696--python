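"""Seeded synthetic datasets emulating the paired RISC/global islet sequencing design.

The generator produces the statistical structure the analysis assumes, with
truth tables, so that every pipeline stage is testable without external
downloads:

* paired global / Ago2-RISC mRNA count matrices for a control-vs-miRNA-
  overexpression contrast (negative binomial, Var = mu + alpha*mu^2,
  log-normal library sizes so size factors are non-trivial), with planted
  direct targets in two modes — *degradation* (RISC up, global down) and
  *translational suppression* (RISC up, global untouched);
* a developmental (adult vs P10) global mRNA matrix in which degradation
  plants move opposite to the perturbation (development lowers the miRNA,
  its targets rise) with variable magnitude, plus independent developmental
  DE genes;
* miRNA annotations organised into genomic clusters and seed families,
  including a family spanning two clusters (the miR-17/92 vs miR-106b/25
  situation), with 3'UTRs for planted targets that are guaranteed to carry
  a reverse-complement seed site of the perturbed miRNA;
* a miRNA developmental count matrix and postnatal time courses with a
  planted step change and anticorrelated targets.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .counts_io import (
    CountMatrix,
    GeneLengths,
    MiRNAAnnotation,
    write_count_table,
    write_gene_lengths,
    write_mirna_fasta,
    write_mirna_gff3,
    write_sample_sheet,
)
from .organization import reverse_complement, seed_sequence
from .timecourse import DEFAULT_TIMEPOINTS, TimeCourse

ROLE_NULL = "null"
ROLE_DEGRADATION = "direct_degradation"
ROLE_SUPPRESSION = "direct_suppression"
ROLE_DEV_UP = "developmental_up"
ROLE_DEV_DOWN = "developmental_down"

_NT = np.array(list("ACGU"))


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic datasets.

    The defaults mirror the emulated study: thousands of post-filter mRNAs,
    ~300 miRNAs, 3-4 animals per group, modest NB dispersion, ~2e6 mapped
    reads per library, 100 planted targets per regulation mode with planted
    |log2 fold| in [1, 2], 600 developmental DE mRNAs, and a six-timepoint
    postnatal series.
    """

    rng_seed: int
    n_mrnas: int = 5000
    n_mirnas: int = 300
    n_per_group: int = 4
    nb_dispersion: float = 0.05
    library_size_log_mean: float = float(np.log(2e6))
    library_size_log_sd: float = 0.25
    n_planted_degradation: int = 100
    n_planted_suppression: int = 100
    planted_lfc_low: float = 1.0
    planted_lfc_high: float = 2.0
    n_developmental_de: int = 600
    timepoints: Tuple[str, ...] = DEFAULT_TIMEPOINTS

    # baseline abundance model (documented generator choices)
    base_log_mean: float = float(np.log(150.0))
    base_log_sd: float = 1.2
    base_floor: float = 30.0
    low_tail_fraction: float = 0.03

    # miRNA annotation structure
    n_clusters: int = 40
    cluster_size_low: int = 2
    cluster_size_high: int = 6
    n_shared_seed_families: int = 5
    cluster_max_gap_bp: int = 10000
    utr_length: int = 200

    # miRNA developmental counts
    n_mirna_changed_up: int = 30
    n_mirna_changed_down: int = 38
    mirna_low_fraction: float = 0.1

    # time course
    n_timecourse_pairs: int = 20
    change_timepoint: str = "P23"
    step_log2fc: float = -2.0
    r_true: float = -0.9
    n_replicates_per_timepoint: int = 4
    replicate_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ConfigError("rng_seed is mandatory")
        n_planted = (
            self.n_planted_degradation
            + self.n_planted_suppression
            + self.n_developmental_de
        )
        n_eligible = self.n_mrnas - int(round(self.low_tail_fraction * self.n_mrnas))
        if n_planted > n_eligible:
            raise ConfigError(
                f"{n_planted} planted genes exceed the {n_eligible} mRNAs above "
                f"the low-abundance tail (n_mrnas={self.n_mrnas})"
            )
        if self.change_timepoint not in self.timepoints:
            raise ConfigError(
                f"change timepoint {self.change_timepoint!r} not in grid "
                f"{self.timepoints}"
            )
        if len(self.timepoints) < 3:
            raise ConfigError("need >= 3 timepoints")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson NB sample with Var = mu + alpha*mu^2."""
    mu = np.maximum(mu, 1e-12)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# miRNA annotations


def build_mirna_annotations(
    config: SimulationConfig,
) -> Tuple[list[MiRNAAnnotation], pd.DataFrame]:
    """In-memory miRNA annotations plus the planted partition truth.

    Clusters are laid out far apart (>= 1 Mb) on 20 chromosomes so the
    planted cluster partition is unambiguous at any reasonable gap
    threshold; within a cluster, consecutive loci sit 200-5000 bp apart
    (within ``cluster_max_gap_bp``).  ``n_shared_seed_families`` seed pairs
    are planted, the first spanning clusters 0 and 1.
    """
    rng = np.random.default_rng((config.rng_seed, 11))
    n = config.n_mirnas
    ids = [f"mir-{i + 1:04d}" for i in range(n)]

    # cluster membership: n_clusters multi-miRNA clusters, rest singletons
    sizes = rng.integers(
        config.cluster_size_low, config.cluster_size_high + 1, size=config.n_clusters
    )
    while len(sizes) and sizes.sum() > n:  # never exceed the miRNA count
        sizes = sizes[:-1]
    members_per_cluster: list[list[int]] = []
    i = 0
    for sz in sizes:
        members_per_cluster.append(list(range(i, i + int(sz))))
        i += int(sz)
    for j in range(i, n):
        members_per_cluster.append([j])

    chroms = [f"chr{c + 1}" for c in range(20)]
    cluster_idx = np.empty(n, dtype=int)
    loci: list[tuple[str, int, int, str]] = [None] * n  # type: ignore[list-item]
    for k, members in enumerate(members_per_cluster):
        chrom = chroms[k % 20]
        base = 1_000_000 * (k // 20 + 1) + int(rng.integers(0, 100_000))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = base
        for m in members:
            start = pos
            end = start + 80
            loci[m] = (chrom, start, end, strand)
            cluster_idx[m] = k
            pos = end + int(rng.integers(200, 5001))

    # seed assignment: unique seeds, then overwrite planted shared pairs
    seeds: list[str] = []
    seen: set[str] = set()
    while len(seeds) < n:
        s = _random_seq(rng, 7)
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    family_idx = np.arange(n)
    shared = 0
    # first planted family spans clusters 0 and 1 (if both exist)
    if config.n_shared_seed_families > 0 and len(members_per_cluster) >= 2:
        a = members_per_cluster[0][0]
        b = members_per_cluster[1][0]
        seeds[b] = seeds[a]
        family_idx[b] = family_idx[a]
        shared += 1
    free = [j for j in range(n) if family_idx[j] == j and j not in
            {members_per_cluster[0][0], members_per_cluster[1][0] if len(members_per_cluster) > 1 else -1}]
    while shared < config.n_shared_seed_families and len(free) >= 2:
        pick = rng.choice(len(free), size=2, replace=False)
        a, b = free[pick[0]], free[pick[1]]
        seeds[b] = seeds[a]
        family_idx[b] = family_idx[a]
        free = [j for j in free if j not in (a, b)]
        shared += 1

    annotations = []
    for j in range(n):
        mature = _random_seq(rng, 1) + seeds[j] + _random_seq(rng, 14)
        chrom, start, end, strand = loci[j]
        annotations.append(
            MiRNAAnnotation(
                mirna_id=ids[j],
                mature_sequence=mature,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
            )
        )
    truth = pd.DataFrame(
        {
            "mirna_id": ids,
            "seed": seeds,
            "cluster_index": cluster_idx,
            "family_index": family_idx,
        }
    )
    return annotations, truth


def generate_mirna_annotations(
    config: SimulationConfig, out_dir: Optional[str] = None
) -> Tuple[list[MiRNAAnnotation], pd.DataFrame]:
    """Annotations plus truth; optionally writes ``mirnas.gff3``/``mirnas.fa``."""
    annotations, truth = build_mirna_annotations(config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mirna_gff3(annotations, out / "mirnas.gff3")
        write_mirna_fasta(annotations, out / "mirnas.fa")
        truth.to_csv(out / "mirna_truth.tsv", sep="\t", index=False)
    return annotations, truth


# ---------------------------------------------------------------------------
# paired-fraction mRNA counts


def _plan_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline means, roles and planted fold changes for every mRNA."""
    n = config.n_mrnas
    gene_ids = [f"gene-{i + 1:05d}" for i in range(n)]
    base = config.base_floor + rng.lognormal(
        config.base_log_mean, config.base_log_sd, size=n
    )
    n_tail = int(round(config.low_tail_fraction * n))
    tail = rng.choice(n, size=n_tail, replace=False)
    base[tail] = rng.uniform(0.2, 3.0, size=n_tail)

    roles = np.full(n, ROLE_NULL, dtype=object)
    pert_global = np.zeros(n)
    pert_risc = np.zeros(n)
    dev = np.zeros(n)

    eligible = np.setdiff1d(np.arange(n), tail)
    n_deg, n_sup = config.n_planted_degradation, config.n_planted_suppression
    n_dev = config.n_developmental_de
    picks = rng.choice(eligible, size=n_deg + n_sup + n_dev, replace=False)
    deg, sup, dev_genes = (
        picks[:n_deg],
        picks[n_deg : n_deg + n_sup],
        picks[n_deg + n_sup :],
    )

    lfc_deg = rng.uniform(config.planted_lfc_low, config.planted_lfc_high, size=n_deg)
    roles[deg] = ROLE_DEGRADATION
    pert_risc[deg] = lfc_deg
    pert_global[deg] = -lfc_deg
    # development reverses the perturbation for true targets, with variable
    # magnitude so some land short of significance (the emulated 60%/21% split)
    dev[deg] = lfc_deg * rng.uniform(0.3, 1.0, size=n_deg)

    lfc_sup = rng.uniform(config.planted_lfc_low, config.planted_lfc_high, size=n_sup)
    roles[sup] = ROLE_SUPPRESSION
    pert_risc[sup] = lfc_sup  # global untouched: translational suppression

    half = n_dev // 2
    lfc_dev = rng.uniform(config.planted_lfc_low, config.planted_lfc_high, size=n_dev)
    dev[dev_genes[:half]] = lfc_dev[:half]
    dev[dev_genes[half:]] = -lfc_dev[half:]
    roles[dev_genes[:half]] = ROLE_DEV_UP
    roles[dev_genes[half:]] = ROLE_DEV_DOWN

    return pd.DataFrame(
        {
            "feature_id": gene_ids,
            "role": roles,
            "base_mean": base,
            "perturb_risc_log2fc": pert_risc,
            "perturb_global_log2fc": pert_global,
            "dev_log2fc": dev,
        }
    )


def _counts_for_design(
    rng: np.random.Generator,
    config: SimulationConfig,
    base: np.ndarray,
    lfc: np.ndarray,
    sample_prefix: str,
    conditions: Tuple[str, str],
    fraction: str,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts for a two-group design; second condition carries the lfc."""
    rel = base / base.sum()
    cols, metas = {}, []
    for cond_i, cond in enumerate(conditions):
        effect = 2.0 ** (lfc * cond_i)
        for r in range(config.n_per_group):
            lib = rng.lognormal(config.library_size_log_mean, config.library_size_log_sd)
            mu = rel * effect
            mu = mu / mu.sum() * lib
            sid = f"{sample_prefix}_{cond}_{r + 1}"
            cols[sid] = _nb_draw(rng, mu, config.nb_dispersion)
            metas.append((sid, fraction, cond, ""))
    counts = pd.DataFrame(cols)
    meta = pd.DataFrame(
        metas, columns=["sample_id", "fraction", "condition", "timepoint"]
    ).set_index("sample_id")
    return counts, meta


def generate_paired_fraction_counts(
    config: SimulationConfig,
) -> Tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Global and RISC count matrices for control vs miRNA overexpression.

    Returns ``(global_counts, risc_counts, truth)``.  The truth frame
    carries one row per mRNA: role, baseline mean, planted log2 fold changes
    per contrast, the assigned (perturbed) miRNA for direct targets, and a
    3'UTR containing at least one reverse-complement seed site of that
    miRNA.
    """
    rng = np.random.default_rng((config.rng_seed, 7))
    plan = _plan_genes(config, rng)
    base = plan["base_mean"].to_numpy()

    g_counts, g_meta = _counts_for_design(
        rng, config, base, plan["perturb_global_log2fc"].to_numpy(),
        "global", ("control", "perturbed"), "global",
    )
    r_counts, r_meta = _counts_for_design(
        rng, config, base, plan["perturb_risc_log2fc"].to_numpy(),
        "risc", ("control", "perturbed"), "RISC",
    )
    g_counts.index = plan["feature_id"]
    r_counts.index = plan["feature_id"]

    # assign the perturbed miRNA and a seed-site-bearing UTR to direct targets
    annotations, _ = build_mirna_annotations(config)
    perturbed = annotations[0]
    site = reverse_complement(seed_sequence(perturbed.mature_sequence))
    utr_rng = np.random.default_rng((config.rng_seed, 13))
    utrs = np.full(len(plan), "", dtype=object)
    mirnas = np.full(len(plan), "", dtype=object)
    direct = plan["role"].isin([ROLE_DEGRADATION, ROLE_SUPPRESSION]).to_numpy()
    for i in np.flatnonzero(direct):
        u = list(_random_seq(utr_rng, config.utr_length))
        pos = int(utr_rng.integers(0, config.utr_length - 7 + 1))
        u[pos : pos + 7] = site
        utrs[i] = "".join(u)
        mirnas[i] = perturbed.mirna_id
    truth = plan.assign(assigned_mirna=mirnas, utr=utrs)

    return (
        CountMatrix(g_counts, g_meta),
        CountMatrix(r_counts, r_meta),
        truth,
    )


def generate_developmental_counts(
    config: SimulationConfig, truth: pd.DataFrame
) -> CountMatrix:
    """Global mRNA counts for the adult-vs-P10 developmental contrast.

    Uses the baseline means and ``dev_log2fc`` planted by
    :func:`generate_paired_fraction_counts` so the two contrasts share a
    gene universe and planted direct targets move opposite to the
    perturbation.
    """
    rng = np.random.default_rng((config.rng_seed, 17))
    counts, meta = _counts_for_design(
        rng, config, truth["base_mean"].to_numpy(),
        truth["dev_log2fc"].to_numpy(), "dev", ("P10", "adult"), "global",
    )
    counts.index = truth["feature_id"]
    meta["timepoint"] = np.where(meta["condition"] == "P10", "P10", "adult")
    return CountMatrix(counts, meta)


def generate_gene_lengths(config: SimulationConfig, truth: pd.DataFrame) -> GeneLengths:
    rng = np.random.default_rng((config.rng_seed, 19))
    lengths = rng.integers(500, 5001, size=len(truth))
    return GeneLengths(pd.Series(lengths, index=truth["feature_id"], name="exonic_length_bp"))


def generate_mirna_counts(
    config: SimulationConfig,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """miRNA developmental (P10 vs adult) counts with planted two-fold changes.

    ``n_mirna_changed_up``/``down`` miRNAs get planted |log2fc| in [1.5, 3]
    (comfortably past the two-fold selection rule); a ``mirna_low_fraction``
    tail sits below the 10 RpM read cutoff.  Returns the matrix and a truth
    frame (mirna_id, planted_log2fc, low_abundance).
    """
    rng = np.random.default_rng((config.rng_seed, 23))
    annotations, _ = build_mirna_annotations(config)
    ids = [a.mirna_id for a in annotations]
    n = len(ids)
    base = rng.lognormal(np.log(2000.0), 1.0, size=n)
    n_low = int(round(config.mirna_low_fraction * n))
    low = rng.choice(n, size=n_low, replace=False)
    base[low] = rng.uniform(0.2, 4.0, size=n_low)

    lfc = np.zeros(n)
    eligible = np.setdiff1d(np.arange(n), low)
    n_up, n_down = config.n_mirna_changed_up, config.n_mirna_changed_down
    picks = rng.choice(eligible, size=n_up + n_down, replace=False)
    lfc[picks[:n_up]] = rng.uniform(1.5, 3.0, size=n_up)
    lfc[picks[n_up:]] = -rng.uniform(1.5, 3.0, size=n_down)

    rel = base / base.sum()
    cols, metas = {}, []
    for cond_i, cond in enumerate(("P10", "adult")):
        effect = 2.0 ** (lfc * cond_i)
        for r in range(config.n_per_group):
            lib = rng.lognormal(np.log(1e6), config.library_size_log_sd)
            mu = rel * effect
            mu = mu / mu.sum() * lib
            sid = f"mir_{cond}_{r + 1}"
            cols[sid] = _nb_draw(rng, mu, config.nb_dispersion)
            metas.append((sid, "global", cond, cond))
    counts = pd.DataFrame(cols, index=ids)
    meta = pd.DataFrame(
        metas, columns=["sample_id", "fraction", "condition", "timepoint"]
    ).set_index("sample_id")
    truth = pd.DataFrame(
        {"mirna_id": ids, "planted_log2fc": lfc, "low_abundance": np.isin(np.arange(n), low)}
    )
    return CountMatrix(counts, meta), truth


# ---------------------------------------------------------------------------
# time courses


def generate_timecourse(
    config: SimulationConfig,
) -> Tuple[list[TimeCourse], list[TimeCourse], pd.DataFrame]:
    """Anticorrelated miRNA / target time courses with a planted step change.

    Each planted miRNA steps from 1.0 to ``2**step_log2fc`` at
    ``change_timepoint``; its paired target follows the mirrored trajectory
    with per-timepoint Gaussian noise sized so the planted correlation of
    the mean trajectories equals ``r_true`` (``r_true = 0`` yields pure
    noise of matched variance).  Gaussian replicate noise
    (``replicate_noise_sd``) is added around every per-timepoint mean.
    Returns ``(mirna_tcs, mrna_tcs, truth)``.
    """
    tps = config.timepoints
    rng = np.random.default_rng((config.rng_seed, 29))
    change_i = tps.index(config.change_timepoint)
    x = np.where(np.arange(len(tps)) >= change_i, 2.0 ** config.step_log2fc, 1.0)
    vx = float(np.var(x))
    r = float(config.r_true)
    noise_var = vx * (1.0 - r ** 2) if abs(r) > 0 else vx

    mirna_tcs, mrna_tcs, rows = [], [], []
    n_rep = config.n_replicates_per_timepoint
    for i in range(config.n_timecourse_pairs):
        mid, gid = f"mir-tc-{i + 1:03d}", f"gene-tc-{i + 1:03d}"
        y_mean = 2.0 + r * (x - x.mean()) + rng.normal(0.0, np.sqrt(noise_var), len(tps))
        m_vals = {
            tp: x[j] + rng.normal(0.0, config.replicate_noise_sd, n_rep)
            for j, tp in enumerate(tps)
        }
        g_vals = {
            tp: y_mean[j] + rng.normal(0.0, config.replicate_noise_sd, n_rep)
            for j, tp in enumerate(tps)
        }
        mirna_tcs.append(TimeCourse(mid, tps, m_vals))
        mrna_tcs.append(TimeCourse(gid, tps, g_vals))
        rows.append((mid, gid, config.change_timepoint, r))
    truth = pd.DataFrame(
        rows, columns=["mirna_id", "mrna_id", "change_timepoint", "r_true"]
    )
    return mirna_tcs, mrna_tcs, truth


# ---------------------------------------------------------------------------
# fixture tree


def emit_fixture_tree(config: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Write the full synthetic fixture tree (TSVs, GFF3, FASTA, truth tables)."""
    from .timecourse import timecourses_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    g, r, truth = generate_paired_fraction_counts(config)
    dev = generate_developmental_counts(config, truth)
    lengths = generate_gene_lengths(config, truth)
    mirna_counts, mirna_de_truth = generate_mirna_counts(config)
    annotations, mirna_truth = build_mirna_annotations(config)
    mirna_tcs, mrna_tcs, tc_truth = generate_timecourse(config)

    def _save(name: str, writer, *args) -> None:
        p = out / name
        writer(*args, p)
        paths[name] = str(p)

    _save("global_counts.tsv", write_count_table, g)
    _save("risc_counts.tsv", write_count_table, r)
    _save("developmental_counts.tsv", write_count_table, dev)
    _save("mirna_counts.tsv", write_count_table, mirna_counts)
    _save("gene_lengths.tsv", write_gene_lengths, lengths)
    _save("mirnas.gff3", write_mirna_gff3, annotations)
    _save("mirnas.fa", write_mirna_fasta, annotations)
    meta = pd.concat(
        [g.sample_meta, r.sample_meta, dev.sample_meta, mirna_counts.sample_meta]
    )
    _save("sample_sheet.tsv", write_sample_sheet, meta)
    for name, frame in [
        ("truth_mrna.tsv", truth),
        ("truth_mirna_partition.tsv", mirna_truth),
        ("truth_mirna_de.tsv", mirna_de_truth),
        ("truth_timecourse.tsv", tc_truth),
        ("timecourse_mirna.tsv", timecourses_to_frame(mirna_tcs)),
        ("timecourse_mrna.tsv", timecourses_to_frame(mrna_tcs)),
    ]:
        p = out / name
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    return paths
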