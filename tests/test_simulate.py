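import numpy as np
import pandas as pd
import pytest

import syncomstats as scs
from syncomstats.stats import aggregate_by_origin, relative_abundance


def lj_design(panel, **kw):
    return scs.DesignSpec(
        treatment="sequential",
        resident_set=frozenset(panel.native_ids("Lj")),
        invader_set=frozenset(panel.native_ids("At")),
        **kw,
    )


class TestCompetition:
    def test_depth_conservation(self, panel4):
        design = scs.DesignSpec(replicates_per_cell=2)
        effects = scs.EffectSpec(depth=1000)
        counts, meta, _ = scs.simulate_competition(panel4, design, effects, seed=0)
        assert (counts.sample_sums() == 1000).all()

    def test_metadata_covers_every_sample(self, panel4):
        design = scs.DesignSpec(replicates_per_cell=3)
        counts, meta, _ = scs.simulate_competition(
            panel4, design, scs.EffectSpec(depth=100), seed=0
        )
        assert list(meta.index) == counts.sample_ids
        assert set(meta["compartment"]) == {"root", "rhizosphere", "soil"}
        assert len(meta) == 2 * 3 * 3  # hosts x compartments x replicates

    def test_no_preference_gives_symmetric_expectation(self, panel32):
        """phi = 1 everywhere: paired bases make the expected aggregated RA
        of Lj-derived strains exactly 0.5 in every sample."""
        design = scs.DesignSpec(replicates_per_cell=2)
        effects = scs.EffectSpec(phi_root=1.0, depth=1000)
        _, meta, truth = scs.simulate_competition(panel32, design, effects, seed=5)
        lj = panel32.native_ids("Lj")
        agg = truth.expected_ra[lj].sum(axis=1)
        assert np.allclose(agg, 0.5, atol=1e-12)

    def test_preference_ratio_matches_closed_form(self, panel32):
        """phi_root = 4: for every native strain the expected RA ratio
        cognate/other root is exactly 4 (paired bases cancel), and the
        empirical mean ratio agrees within 3 Monte-Carlo standard errors."""
        reps = 100
        design = scs.DesignSpec(replicates_per_cell=reps, compartments=("root",))
        effects = scs.EffectSpec(phi_root=4.0, depth=100_000,
                                 overdispersion=200.0)
        counts, meta, truth = scs.simulate_competition(panel32, design, effects,
                                                       seed=11)
        # closed form on the realized truth
        for strain in panel32.ids:
            host = panel32.host_of_origin[strain]
            other = "At" if host == "Lj" else "Lj"
            on_c = truth.expected_ra.loc[meta["host_species"] == host, strain]
            on_o = truth.expected_ra.loc[meta["host_species"] == other, strain]
            assert np.isclose(on_c.iloc[0] / on_o.iloc[0], 4.0, rtol=1e-12)
        # Monte-Carlo agreement of empirical means
        ab = relative_abundance(counts).values
        for strain in panel32.ids[:8]:
            host = panel32.host_of_origin[strain]
            other = "At" if host == "Lj" else "Lj"
            x = ab.loc[(meta["host_species"] == host).to_numpy(), strain]
            y = ab.loc[(meta["host_species"] == other).to_numpy(), strain]
            ratio = x.mean() / y.mean()
            # delta-method MC standard error of the ratio
            se = ratio * np.sqrt(x.var() / (len(x) * x.mean() ** 2)
                                 + y.var() / (len(y) * y.mean() ** 2))
            assert abs(ratio - 4.0) <= 3 * se + 1e-9

    def test_soil_is_neutral(self, panel32):
        design = scs.DesignSpec(replicates_per_cell=1, compartments=("soil",))
        effects = scs.EffectSpec(phi_root=10.0, depth=1000)
        _, meta, truth = scs.simulate_competition(panel32, design, effects, seed=2)
        lj = panel32.native_ids("Lj")
        assert np.allclose(truth.expected_ra[lj].sum(axis=1), 0.5, atol=1e-12)

    def test_mutant_attenuation_interpolates(self, panel32):
        hosts = (scs.Host("Lj", "wt"), scs.Host("Lj", "nfr5"), scs.Host("At", "wt"))
        design = scs.DesignSpec(hosts=hosts, replicates_per_cell=1,
                                compartments=("root",))
        effects = scs.EffectSpec(phi_root=4.0, nfr5_attenuation=0.5, depth=100)
        _, meta, truth = scs.simulate_competition(panel32, design, effects, seed=3)
        lj = panel32.native_ids("Lj")
        agg = truth.expected_ra[lj].sum(axis=1)
        wt = agg[meta["host_genotype"] == "wt"][meta["host_species"] == "Lj"].iloc[0]
        mut = agg[meta["host_genotype"] == "nfr5"].iloc[0]
        # preference reduced but still present in the symbiosis mutant
        assert 0.5 < mut < wt

    def test_determinism(self, panel4):
        design = scs.DesignSpec(replicates_per_cell=2)
        effects = scs.EffectSpec(depth=500)
        a = scs.simulate_competition(panel4, design, effects, seed=9)
        b = scs.simulate_competition(panel4, design, effects, seed=9)
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_label_swap_symmetry(self, panel32):
        """Swapping all host-of-origin labels and all sample host labels
        leaves the generative expectations invariant when phi is shared."""
        design = scs.DesignSpec(replicates_per_cell=1, compartments=("root",))
        effects = scs.EffectSpec(phi_root=3.0, depth=100)
        _, meta, truth = scs.simulate_competition(panel32, design, effects, seed=4)
        swapped = panel32.strains.assign(
            host_of_origin=panel32.host_of_origin.map({"Lj": "At", "At": "Lj"})
        )
        swapped_panel = scs.StrainPanel(swapped.reset_index(drop=True))
        _, meta2, truth2 = scs.simulate_competition(swapped_panel, design,
                                                    effects, seed=4)
        lj_row = truth.expected_ra[meta["host_species"] == "Lj"].iloc[0]
        at_row2 = truth2.expected_ra[meta2["host_species"] == "At"].iloc[0]
        assert np.allclose(lj_row, at_row2, atol=1e-12)


class TestInvasion:
    def test_no_effects_balanced(self, panel32):
        design = lj_design(panel32, replicates_per_cell=1, compartments=("root",))
        effects = scs.EffectSpec(phi_root=1.0, pi_priority=1.0, depth=100)
        _, meta, truth = scs.simulate_invasion(panel32, design, effects, seed=0)
        lj = panel32.native_ids("Lj")
        assert np.allclose(truth.expected_ra[lj].sum(axis=1), 0.5, atol=1e-12)

    def test_priority_three_gives_expected_075(self, panel32):
        """pi = 3, phi = 1, paired bases: expected resident aggregated RA is
        exactly 3/(3+1) on both hosts."""
        design = lj_design(panel32, replicates_per_cell=1, compartments=("root",))
        effects = scs.EffectSpec(phi_root=1.0, pi_priority=3.0, depth=100)
        _, meta, truth = scs.simulate_invasion(panel32, design, effects, seed=0)
        lj = panel32.native_ids("Lj")
        lj_first = meta["first_syncom"] == "Lj"
        assert np.allclose(truth.expected_ra.loc[lj_first.to_numpy(), lj].sum(axis=1),
                           0.75, atol=1e-12)
        at_first = meta["first_syncom"] == "At"
        assert np.allclose(truth.expected_ra.loc[at_first.to_numpy(), lj].sum(axis=1),
                           0.25, atol=1e-12)

    def test_metadata_labels_inoculation_order(self, panel32):
        design = lj_design(panel32, replicates_per_cell=1)
        _, meta, _ = scs.simulate_invasion(
            panel32, design, scs.EffectSpec(depth=100), seed=0
        )
        assert set(meta["first_syncom"]) == {"Lj", "At", "mixed"}
        seq = meta.loc[meta["treatment"] == "sequential"]
        assert ((seq["first_syncom"] == "Lj") == (seq["second_syncom"] == "At")).all()
        mixed = meta.loc[meta["first_syncom"] == "mixed"]
        assert (mixed["second_syncom"] == "mock").all()
        assert (mixed["treatment"] == "competition").all()

    def test_overlapping_sets_rejected(self, panel32):
        ids = panel32.ids
        with pytest.raises(ValueError, match="disjoint"):
            scs.DesignSpec(treatment="sequential",
                           resident_set=frozenset(ids[:17]),
                           invader_set=frozenset(ids[16:]))

    def test_partition_required(self, panel32):
        design = scs.DesignSpec(treatment="sequential",
                                resident_set=frozenset(panel32.ids[:4]),
                                invader_set=frozenset(panel32.ids[4:8]))
        with pytest.raises(ValueError, match="partition"):
            scs.simulate_invasion(panel32, design, scs.EffectSpec(depth=10), seed=0)


class TestReads:
    def test_error_free_reads_equal_reference(self, panel4):
        design = scs.DesignSpec(replicates_per_cell=1, compartments=("root",))
        counts, _, _ = scs.simulate_competition(panel4, design,
                                                scs.EffectSpec(depth=50), seed=1)
        reads = scs.simulate_reads(counts, panel4, sub_error_rate=0.0, seed=1)
        refs = set(panel4.ref_seqs)
        for sample, recs in reads.items():
            assert len(recs) == counts.counts.loc[sample].sum()
            assert all(seq in refs for _, seq in recs)

    def test_round_trip_recovers_count_table(self, panel4):
        design = scs.DesignSpec(replicates_per_cell=2)
        counts, _, _ = scs.simulate_competition(panel4, design,
                                                scs.EffectSpec(depth=200), seed=2)
        reads = scs.simulate_reads(counts, panel4, 0.0, seed=2)
        result = scs.map_reads_exact(reads, panel4)
        assert result.counts.counts.loc[counts.sample_ids].equals(counts.counts)
        assert (result.unmapped == 0).all()
        assert (result.ambiguous == 0).all()

    def test_substitution_rate_scales_mismatches(self, panel4):
        design = scs.DesignSpec(replicates_per_cell=1, compartments=("root",))
        counts, _, _ = scs.simulate_competition(panel4, design,
                                                scs.EffectSpec(depth=500), seed=3)
        reads = scs.simulate_reads(counts, panel4, sub_error_rate=0.01, seed=3)
        refs = set(panel4.ref_seqs)
        sample = counts.sample_ids[0]
        n_perfect = sum(seq in refs for _, seq in reads[sample])
        n = len(reads[sample])
        seq_len = len(panel4.ref_seqs.iloc[0])
        expected = n * (1 - 0.01) ** seq_len
        assert abs(n_perfect - expected) < 4 * np.sqrt(expected)

    def test_unknown_feature_rejected(self, panel4):
        df = pd.DataFrame([[5]], index=["s"], columns=["nope"])
        with pytest.raises(KeyError, match="reference"):
            scs.simulate_reads(scs.CountTable(df), panel4, 0.0, seed=0)

    def test_fastq_round_trip(self, panel4, tmp_path):
        from syncomstats.io import read_fastq_dir

        design = scs.DesignSpec(replicates_per_cell=1, compartments=("root",))
        counts, _, _ = scs.simulate_competition(panel4, design,
                                                scs.EffectSpec(depth=20), seed=4)
        reads = scs.simulate_reads(counts, panel4, 0.0, seed=4)
        scs.write_fastq_dir(reads, tmp_path / "fq")
        back = read_fastq_dir(tmp_path / "fq")
        assert set(back) == set(reads)
        for sid in reads:
            assert back[sid] == reads[sid]


class TestIrlPlates:
    def test_low_density_wells_are_pure(self):
        """At 0.1 cells/well, P(singleton | non-empty) = (lam e^-lam)/(1-e^-lam)
        ~= 0.949; multi-founder wells can still be single-OTU, so >= 95% of
        non-empty wells contain one OTU."""
        ra = pd.Series(np.full(10, 0.1), index=[f"otu{i}" for i in range(10)])
        wells = scs.simulate_irl_plates(ra, n_wells=4000, cells_per_well_mean=0.1,
                                        reads_per_well=200, seed=0)
        nonempty = wells[wells.sum(axis=1) > 0]
        single = ((nonempty > 0).sum(axis=1) == 1).mean()
        assert single >= 0.95

    def test_zero_wells(self):
        ra = pd.Series([1.0], index=["otu1"])
        wells = scs.simulate_irl_plates(ra, 0, 1.0, 100, seed=0)
        assert wells.shape[0] == 0

    def test_deterministic(self):
        ra = pd.Series([0.6, 0.4], index=["a", "b"])
        w1 = scs.simulate_irl_plates(ra, 50, 2.0, 100, seed=5)
        w2 = scs.simulate_irl_plates(ra, 50, 2.0, 100, seed=5)
        assert w1.equals(w2)

    def test_profile_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            scs.simulate_irl_plates(pd.Series([0.5, 0.4]), 10, 1.0, 100, seed=0)


class TestTruthRecord:
    def test_parameter_round_trip(self, panel4, tmp_path):
        design = scs.DesignSpec(replicates_per_cell=1)
        effects = scs.EffectSpec(phi_root=2.5, depth=100)
        _, _, truth = scs.simulate_competition(panel4, design, effects, seed=6)
        prefix = str(tmp_path / "truth")
        truth.to_files(prefix)
        back = scs.TruthRecord.from_files(prefix)
        assert back.params == truth.params
        assert np.allclose(back.base_abundance, truth.base_abundance)
        assert np.allclose(back.expected_ra, truth.expected_ra)
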