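import numpy as np
import pytest

from mescore import conservation, mes, synthetic, variant_map
from mescore import struct_features as sf
from mescore.msa_io import occupancies


class TestMakeAlignment:
    def test_deterministic_under_seed(self):
        a1, t1 = synthetic.make_alignment(seed=9)
        a2, t2 = synthetic.make_alignment(seed=9)
        assert [s.gapped_sequence for s in a1.sequences] == [
            s.gapped_sequence for s in a2.sequences
        ]
        assert t1 == t2

    def test_different_seed_differs(self):
        a1, _ = synthetic.make_alignment(seed=1)
        a2, _ = synthetic.make_alignment(seed=2)
        assert [s.gapped_sequence for s in a1.sequences] != [
            s.gapped_sequence for s in a2.sequences
        ]

    def test_all_single_type_profile_forces_shenkin_six(self):
        aln, _ = synthetic.make_alignment(
            n_sequences=10, n_human=3, n_columns=5,
            conservation_profile=[1] * 5, gap_fraction=0.0, seed=0,
        )
        profile = conservation.profile_alignment(aln)
        assert all(c.shenkin == pytest.approx(6.0) for c in profile)

    def test_conserved_truth_columns_have_lower_mean_shenkin(self):
        aln, truth = synthetic.make_alignment(n_columns=60, seed=3)
        profile = conservation.profile_alignment(aln)
        cons = [c.shenkin for c, t in zip(profile, truth.true_conservation)
                if t == "conserved"]
        div = [c.shenkin for c, t in zip(profile, truth.true_conservation)
               if t == "unconserved"]
        assert np.mean(cons) < np.mean(div)

    def test_infeasible_profile_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_alignment(n_columns=3, conservation_profile=[1, 25, 2])
        with pytest.raises(ValueError):
            synthetic.make_alignment(n_sequences=5, n_human=6)

    def test_human_sequences_are_gapless(self):
        aln, _ = synthetic.make_alignment(seed=4)
        occ = occupancies(aln)
        n_human = len(aln.human_sequences)
        assert all(o.occupancy_human == n_human for o in occ)


class TestMakeVariants:
    def test_zero_rate_gives_no_missense(self):
        aln, truth = synthetic.make_alignment(
            n_columns=10, baseline_rate=0.0, depleted_rate_ratio=0.0, seed=5
        )
        variants = synthetic.make_variants(aln, truth, seed=6, synonymous_rate=0.0)
        assert variants == []

    def test_total_missense_near_expectation(self):
        aln, truth = synthetic.make_alignment(
            n_sequences=40, n_human=30, n_columns=50,
            frac_depleted=0.0, baseline_rate=1.0, seed=7,
        )
        variants = synthetic.make_variants(aln, truth, seed=8, synonymous_rate=0.0)
        tallies, _ = variant_map.tally_columns(variants, aln)
        total = sum(t.n_missense for t in tallies)
        expected = 30 * 50 * 1.0
        assert abs(total - expected) < 4 * np.sqrt(expected)

    def test_synonymous_rate_independent_of_divergence(self):
        """The synonymous control: no divergence effect in the regression."""
        from mescore.regression import RegressionInput, adjust_fdr, fit_domain

        rng_seeds = range(30)
        pvals = []
        for s in rng_seeds:
            aln, truth = synthetic.make_alignment(
                n_sequences=40, n_human=20, n_columns=40, frac_depleted=0.0, seed=s
            )
            variants = synthetic.make_variants(aln, truth, seed=s + 500,
                                               synonymous_rate=0.8)
            tallies, _ = variant_map.tally_columns(variants, aln)
            profile = conservation.profile_alignment(aln)
            res = fit_domain(
                RegressionInput(
                    tuple(float(t.n_synonymous) for t in tallies),
                    tuple(t.n_human_residues for t in tallies),
                    tuple(c.shenkin for c in profile),
                )
            )
            pvals.append(res.p_beta12)
        discoveries = (np.asarray(adjust_fdr(pvals)) < 0.05).mean()
        assert discoveries <= 0.1

    def test_pathogenic_planted_at_depleted_columns(self):
        aln, truth = synthetic.make_alignment(n_columns=30, seed=9)
        variants = synthetic.make_variants(aln, truth, seed=10, pathogenic_prob=0.5)
        tallies, _ = variant_map.tally_columns(variants, aln)
        depleted = {j + 1 for j, c in enumerate(truth.true_class) if c == "depleted"}
        for t in tallies:
            if t.n_pathogenic > 0:
                assert t.column in depleted


class TestMakeStructuralFeatures:
    def test_zero_noise_consensus_equals_truth(self):
        aln, truth = synthetic.make_alignment(n_columns=20, gap_fraction=0.0, seed=11)
        recs = synthetic.make_structural_features(aln, truth, seed=12,
                                                  exposure_noise=0.0)
        cols = sf.summarise_columns(aln, sf.summarise_sequences(recs))
        for c, exp in zip(cols, truth.true_exposure):
            assert c.consensus_exposure == exp

    def test_chain_count_does_not_change_column_summaries(self):
        aln, truth = synthetic.make_alignment(n_columns=15, seed=13)
        one = synthetic.make_structural_features(aln, truth, seed=14, n_chains=1)
        many = synthetic.make_structural_features(aln, truth, seed=14, n_chains=50)
        c_one = sf.summarise_columns(aln, sf.summarise_sequences(one))
        c_many = sf.summarise_columns(aln, sf.summarise_sequences(many))
        for x, y in zip(c_one, c_many):
            assert x.consensus_exposure == y.consensus_exposure
            assert x.n_ligand_sequences == y.n_ligand_sequences
            assert x.n_domain_sequences == y.n_domain_sequences
            assert x.pdb_sequence_coverage == y.pdb_sequence_coverage

    def test_determinism(self):
        aln, truth = synthetic.make_alignment(n_columns=10, seed=15)
        r1 = synthetic.make_structural_features(aln, truth, seed=16)
        r2 = synthetic.make_structural_features(aln, truth, seed=16)
        assert r1 == r2


class TestEndToEndPower:
    def test_depleted_columns_recovered_in_deep_families(self):
        """Strong depletion + many human paralogs -> most truth columns called."""
        hits = total = 0
        for seed in range(10):
            aln, truth = synthetic.make_alignment(
                n_sequences=60, n_human=50, n_columns=40,
                baseline_rate=1.0, depleted_rate_ratio=0.05, seed=seed,
            )
            variants = synthetic.make_variants(aln, truth, seed=seed + 1000)
            tallies, _ = variant_map.tally_columns(variants, aln)
            results, _ = mes.score_domain(tallies)
            calls = {r.column: r.call for r in results}
            for j, cls in enumerate(truth.true_class):
                if cls == "depleted":
                    total += 1
                    hits += calls.get(j + 1) == "depleted"
        assert hits / total >= 0.8
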