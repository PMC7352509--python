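"""Generator correctness: planted structure, determinism, limiting laws."""

import numpy as np
import pandas as pd
import pytest

from astropair.params import HMMParams
from astropair.synthetic_data import (
    CNAEvent,
    CohortSpec,
    build_gene_map,
    simulate_cohort,
    simulate_pair_profiles,
    simulate_variant_tables,
)

from conftest import small_spec


class TestGeneMap:
    def test_even_split_and_total_order(self):
        gm = build_gene_map(small_spec(n_genes=10, n_chromosomes=2))
        assert gm["chrom"].value_counts().tolist() == [5, 5]
        assert gm["order"].tolist() == list(range(10))

    def test_single_gene(self):
        gm = build_gene_map(
            CohortSpec(n_genes=1, n_chromosomes=1, n_patients=1,
                       progression_groups={"A2->A3": 1})
        )
        assert len(gm) == 1
        assert 0 <= gm["start"].iloc[0] < gm["end"].iloc[0]

    def test_sortedness_invariant(self):
        gm = build_gene_map(small_spec())
        # natural chromosome order is already (chrom, start)-sorted per chrom
        for _, grp in gm.groupby("chrom"):
            assert grp["start"].is_monotonic_increasing
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_more_chromosomes_than_genes_rejected(self):
        with pytest.raises(ValueError):
            build_gene_map(small_spec(n_genes=3, n_chromosomes=6))


class TestCohort:
    def test_seed_determinism_bit_identical(self):
        a = simulate_cohort(small_spec(seed=7))
        b = simulate_cohort(small_spec(seed=7))
        pd.testing.assert_frame_equal(a.logexpr, b.logexpr)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.segments, b.segments)

    def test_planted_cna_shift_exact_in_mean(self):
        # one +1 event, attenuation 1: noiseless means of affected genes in
        # carrier samples exceed the normal baseline by exactly 1 log2 unit
        spec = small_spec(
            cna_truth=[CNAEvent("chr4", 0, 10_000_000, 1.0, subgroup=None)],
            cna_attenuation=1.0,
            within_pair_sd=1e-12,
        )
        c = simulate_cohort(spec)
        gm = c.gene_map
        genes = gm.loc[gm["chrom"] == "chr4", "gene"]
        sig_genes = set().union(*(s.centroid.index for s in c.signatures))
        genes = [g for g in genes if g not in sig_genes]
        normals = c.sample_sheet.loc[c.sample_sheet["role"] == "normal", "sample"]
        tumor = c.sample_sheet.loc[c.sample_sheet["role"] == "initial", "sample"].iloc[0]
        delta = (
            c.truth.expr_mean.loc[genes, tumor]
            - c.truth.expr_mean.loc[genes, normals].mean(axis=1)
        )
        assert np.allclose(delta, 1.0, atol=1e-9)

    def test_zero_attenuation_removes_cna_effect(self):
        spec = small_spec(
            cna_truth=[CNAEvent("chr4", 0, 10_000_000, 1.0)],
            cna_attenuation=0.0,
            within_pair_sd=1e-12,
        )
        c = simulate_cohort(spec)
        genes = c.gene_map.loc[c.gene_map["chrom"] == "chr4", "gene"]
        normals = c.sample_sheet.loc[c.sample_sheet["role"] == "normal", "sample"]
        tumor = c.sample_sheet.loc[c.sample_sheet["role"] == "initial", "sample"].iloc[0]
        sig_genes = set().union(*(s.centroid.index for s in c.signatures))
        genes = [g for g in genes if g not in sig_genes]
        delta = (
            c.truth.expr_mean.loc[genes, tumor]
            - c.truth.expr_mean.loc[genes, normals].mean(axis=1)
        )
        assert np.allclose(delta, 0.0, atol=1e-9)

    def test_attenuated_shift_is_half(self):
        spec = small_spec(
            cna_truth=[CNAEvent("chr4", 0, 10_000_000, 1.0)],
            cna_attenuation=0.5,
            within_pair_sd=1e-12,
        )
        c = simulate_cohort(spec)
        genes = c.gene_map.loc[c.gene_map["chrom"] == "chr4", "gene"]
        sig_genes = set().union(*(s.centroid.index for s in c.signatures))
        genes = [g for g in genes if g not in sig_genes]
        normals = c.sample_sheet.loc[c.sample_sheet["role"] == "normal", "sample"]
        tumor = c.sample_sheet.loc[c.sample_sheet["role"] == "initial", "sample"].iloc[0]
        delta = (
            c.truth.expr_mean.loc[genes, tumor]
            - c.truth.expr_mean.loc[genes, normals].mean(axis=1)
        )
        assert np.allclose(delta, 0.5, atol=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            small_spec(noise_sd=0.0).validate()
        with pytest.raises(ValueError):
            small_spec(
                cna_truth=[CNAEvent("chr1", 0, 99_000_000, 1.0)]
            ).validate()
        with pytest.raises(ValueError):
            small_spec(progression_groups={"A2->A3": 1}).validate()


class TestPairProfiles:
    def test_tiny_emission_sd_reproduces_state_means(self):
        spec = small_spec(
            hmm_truth=HMMParams(variances=np.full(3, 1e-18))
        )
        profiles, truth = simulate_pair_profiles(spec)
        means = np.array([-3.0, 0.0, 3.0])
        expected = means[truth.hmm_states.to_numpy() + 1]
        assert np.allclose(profiles.to_numpy(), expected, atol=1e-6)

    def test_run_length_geometric(self):
        # self-transition 0.99 -> run lengths geometric(p=0.01), mean 100
        p_leave = 0.01
        spec = CohortSpec(
            n_patients=1,
            progression_groups={"A3->G4": 1},
            n_genes=100_000,
            n_chromosomes=1,
            n_subgroup_genes=1,
            n_signature_genes=1,
            hmm_truth=HMMParams(
                transmat=np.full((3, 3), p_leave / 2) + np.eye(3) * (0.99 - p_leave / 2)
            ),
            seed=1,
        )
        _, truth = simulate_pair_profiles(spec)
        states = truth.hmm_states.iloc[:, 0].to_numpy()
        runs = np.diff(np.flatnonzero(np.diff(states) != 0))
        mean_run = runs.mean()
        # geometric mean 1/p with MC standard error sd/sqrt(n)
        se = (np.sqrt(1 - p_leave) / p_leave) / np.sqrt(runs.size)
        assert abs(mean_run - 1 / p_leave) < 3 * se

    def test_first_state_frequencies_uniform(self):
        # many short chromosomes -> many independent draws of the first state
        spec = CohortSpec(
            n_patients=1,
            progression_groups={"A3->G4": 1},
            n_genes=40_000,
            n_chromosomes=20_000,
            n_subgroup_genes=1,
            n_signature_genes=1,
            seed=1,
        )
        _, truth = simulate_pair_profiles(spec)
        states = truth.hmm_states.iloc[:, 0].to_numpy()
        first = states[::2]  # chromosomes have 2 genes each
        n = first.size
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for s in (-1, 0, 1):
            assert abs(np.mean(first == s) - 1 / 3) < 3 * se

    def test_state_marginals_approach_stationary(self):
        spec = CohortSpec(
            n_patients=1,
            progression_groups={"A3->G4": 1},
            n_genes=60_000,
            n_chromosomes=2,
            n_subgroup_genes=1,
            n_signature_genes=1,
            hmm_truth=HMMParams(
                startprob=np.array([0.8, 0.1, 0.1]),
                transmat=np.array(
                    [[0.90, 0.05, 0.05], [0.10, 0.80, 0.10], [0.02, 0.08, 0.90]]
                ),
            ),
            seed=1,
        )
        pi = spec.hmm_truth.stationary()  # eigen-decomposition oracle
        _, truth = simulate_pair_profiles(spec)
        states = truth.hmm_states.iloc[:, 0].to_numpy() + 1
        freq = np.bincount(states, minlength=3) / states.size
        assert np.allclose(freq, pi, atol=0.02)

    def test_non_stochastic_transitions_rejected(self):
        bad = HMMParams(transmat=np.eye(3) * 0.5)
        with pytest.raises(ValueError):
            simulate_pair_profiles(small_spec(hmm_truth=bad))


class TestVariantTables:
    def test_forced_identical_sets(self):
        spec = small_spec(
            variant_truth={"P01": (8, 0, 0)}, mutated_gene_truth={}
        )
        tables, _ = simulate_variant_tables(spec)
        ini, rec = tables["P01"]
        assert len(ini) == len(rec) == 8
        key = ["chrom", "pos", "ref", "alt"]
        assert set(map(tuple, ini[key].itertuples(index=False))) == set(
            map(tuple, rec[key].itertuples(index=False))
        )

    def test_no_cross_pair_key_collisions_needed_for_uniqueness(self):
        tables, truth = simulate_variant_tables(small_spec())
        for pat, (ini, rec) in tables.items():
            key = ["chrom", "pos", "ref", "alt"]
            assert ini[key].duplicated().sum() == 0
            assert rec[key].duplicated().sum() == 0

    def test_counts_recorded_in_truth(self):
        spec = small_spec(variant_truth={"P01": (60, 26, 77), "P02": (5, 1, 2)},
                          mutated_gene_truth={})
        tables, truth = simulate_variant_tables(spec)
        assert truth.variant_counts["P01"] == (60, 26, 77)
        ini, rec = tables["P01"]
        assert len(ini) == 86 and len(rec) == 137
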