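"""Generator contracts: determinism, planted structure, downstream preconditions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from isletmir.organization import (
    group_clusters,
    group_families,
    scan_seed_matches,
    seed_sequence,
)
from isletmir.quantify import filter_low_mrnas
from isletmir.simulate import (
    ConfigError,
    SimulationConfig,
    build_mirna_annotations,
    generate_mirna_counts,
    generate_paired_fraction_counts,
    generate_timecourse,
)


def _partition(labels: dict) -> set:
    groups: dict = {}
    for k, v in labels.items():
        groups.setdefault(v, set()).add(k)
    return {frozenset(s) for s in groups.values()}


class TestConfig:
    def test_infeasible_plant_count(self):
        with pytest.raises(ConfigError, match="planted"):
            SimulationConfig(rng_seed=1, n_mrnas=500)

    def test_bad_change_timepoint(self):
        with pytest.raises(ConfigError, match="timepoint"):
            SimulationConfig(rng_seed=1, change_timepoint="P99")


class TestDeterminism:
    def test_paired_counts_identical_across_calls(self, default_config):
        g1, r1, t1 = generate_paired_fraction_counts(default_config)
        g2, r2, t2 = generate_paired_fraction_counts(default_config)
        assert g1.counts.equals(g2.counts)
        assert r1.counts.equals(r2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_timecourse_identical_across_calls(self, default_config):
        m1, g1, t1 = generate_timecourse(default_config)
        m2, g2, t2 = generate_timecourse(default_config)
        for a, b in zip(m1 + g1, m2 + g2):
            for tp in a.timepoints:
                np.testing.assert_array_equal(a.values[tp], b.values[tp])
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self, default_config):
        other = dataclasses.replace(default_config, rng_seed=default_config.rng_seed + 1)
        g1, _, _ = generate_paired_fraction_counts(default_config)
        g2, _, _ = generate_paired_fraction_counts(other)
        assert not g1.counts.equals(g2.counts)


class TestPlantedCountStructure:
    def test_truth_roles_are_disjoint_and_sized(self, recovery_run):
        truth = recovery_run["truth"]
        counts = truth["role"].value_counts()
        assert counts["direct_degradation"] == 100
        assert counts["direct_suppression"] == 100
        assert counts["developmental_up"] == 300
        assert counts["developmental_down"] == 300

    def test_post_filter_scale(self, recovery_run):
        # filters trim only the planted low-abundance tail
        filtered, _ = filter_low_mrnas(recovery_run["global_counts"])
        assert 4800 <= len(filtered.gene_ids) <= 5200

    def test_suppression_plants_leave_global_untouched(self, recovery_run):
        truth = recovery_run["truth"]
        sup = truth[truth["role"] == "direct_suppression"]
        assert (sup["perturb_global_log2fc"] == 0).all()
        assert (sup["perturb_risc_log2fc"] >= 1).all()

    def test_degradation_plants_mirror_fractions(self, recovery_run):
        truth = recovery_run["truth"]
        deg = truth[truth["role"] == "direct_degradation"]
        np.testing.assert_allclose(
            deg["perturb_risc_log2fc"], -deg["perturb_global_log2fc"]
        )
        assert (deg["dev_log2fc"] > 0).all()  # development reverses the effect

    def test_null_config_gives_nominal_type_one_error(self, default_config):
        from isletmir.diffexpr import run_de

        cfg = dataclasses.replace(
            default_config, n_mrnas=2000, n_planted_degradation=0,
            n_planted_suppression=0, n_developmental_de=0, rng_seed=99,
        )
        g, _, _ = generate_paired_fraction_counts(cfg)
        de = run_de(g, ("control", "perturbed"))
        frac = (de["pvalue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_planted_utrs_carry_seed_sites(self, recovery_run):
        truth = recovery_run["truth"].reset_index()
        cfg = recovery_run["config"]
        annotations, _ = build_mirna_annotations(cfg)
        seeds = {a.mirna_id: seed_sequence(a.mature_sequence) for a in annotations}
        direct = truth[truth["role"].isin(["direct_degradation", "direct_suppression"])]
        assert len(direct) == 200
        for row in direct.itertuples():
            assert len(scan_seed_matches(row.utr, seeds[row.assigned_mirna])) >= 1


class TestAnnotationStructure:
    def test_planted_partitions_recovered_exactly(self, default_config):
        annotations, truth = build_mirna_annotations(default_config)
        group_families(annotations)
        group_clusters(annotations, max_gap_bp=default_config.cluster_max_gap_bp)
        fam = _partition({a.mirna_id: a.family_id for a in annotations})
        clu = _partition({a.mirna_id: a.cluster_id for a in annotations})
        t = truth.set_index("mirna_id")
        assert fam == _partition(t["seed"].to_dict())
        assert clu == _partition(t["cluster_index"].to_dict())

    def test_cross_cluster_family_planted(self, default_config):
        annotations, truth = build_mirna_annotations(default_config)
        group_families(annotations)
        group_clusters(annotations)
        by_id = {a.mirna_id: a for a in annotations}
        multi = truth.groupby("family_index")["mirna_id"].apply(list)
        spanning = [
            ids for ids in multi if len(ids) > 1
            and len({by_id[i].cluster_id for i in ids}) > 1
        ]
        assert spanning, "expected at least one seed family spanning two clusters"
        # a shared family strictly coarsens the partition: fewer families than
        # the member count would suggest
        assert len({a.family_id for a in annotations}) < len(annotations)

    def test_single_mirna_config(self):
        cfg = SimulationConfig(
            rng_seed=5, n_mirnas=1, n_mrnas=2000, n_planted_degradation=10,
            n_planted_suppression=10, n_developmental_de=10,
            n_shared_seed_families=0,
        )
        annotations, _ = build_mirna_annotations(cfg)
        group_families(annotations)
        group_clusters(annotations)
        assert len(annotations) == 1
        assert annotations[0].family_id == annotations[0].mirna_id
        assert annotations[0].cluster_id == annotations[0].mirna_id


class TestMirnaCounts:
    def test_planted_mirna_changes_scaled(self, default_config):
        cm, truth = generate_mirna_counts(default_config)
        assert len(cm.gene_ids) == default_config.n_mirnas
        assert (truth["planted_log2fc"] > 0).sum() == 30
        assert (truth["planted_log2fc"] < 0).sum() == 38
        assert cm.counts.shape == (300, 8)
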