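import numpy as np
import pytest

from ervography.io_core import PipelineConfig, SpeciesTree, ValidationError
from ervography.synthetic_data import (ERVModel, apply_ltr_recombination,
                                       default_branch_rates, mutate, simulate)

PURINES = set("AG")


class TestMutate:
    def test_zero_rate_identity(self, rng):
        s = "ACGTN" * 200
        assert mutate(s, 0.0, 2.0, rng) == s

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValidationError):
            mutate("ACGT", -0.1, 2.0, rng)

    def test_length_preserved_and_n_untouched(self, rng):
        s = "ACGTN" * 2000
        m = mutate(s, 0.3, 2.0, rng)
        assert len(m) == len(s)
        assert all(b == "N" for a, b in zip(s, m) if a == "N")

    def test_realized_p_distance_tracks_expectation(self):
        """Monte-Carlo: p-distance within 3 sigma of the 1-exp curve at mu=0.05."""
        mu, n, reps = 0.05, 10_000, 30
        master = "ACGT" * (n // 4)
        # expected p: fraction of sites whose final state differs; a site hit
        # k>=1 times differs unless the substitution chain returns home.
        # For small mu the return probability is second order; use the
        # empirical tolerance band stated for the generator: [0.04, 0.055].
        rng = np.random.default_rng(123)
        for _ in range(reps):
            m = mutate(master, mu, 2.0, rng)
            p = sum(a != b for a, b in zip(master, m)) / n
            assert 0.04 <= p <= 0.055

    def test_infinite_kappa_suppresses_transversions(self, rng):
        s = "ACGT" * 2500
        m = mutate(s, 0.2, 1e12, rng)
        assert all((a in PURINES) == (b in PURINES) for a, b in zip(s, m))


class TestERVModel:
    def test_segment_partition_enforced(self, rng):
        model = ERVModel.random(rng, ltr_len=300, internal_len=1500)
        assert model.u3_len + model.r_len + model.u5_len == model.ltr_len
        assert (model.pre_gag_len + model.gag_len + model.pol_len
                + model.env_len) == len(model.internal_seq)
        with pytest.raises(ValidationError):
            ERVModel(ltr_seq="ACGT" * 100, internal_seq="ACGT" * 200,
                     u3_len=100, r_len=100, u5_len=100,  # does not sum to 400
                     pre_gag_len=200, gag_len=200, pol_len=200, env_len=200)

    def test_pseudogene_lacks_u3_and_u5(self, rng):
        model = ERVModel.random(rng, ltr_len=300, internal_len=1500)
        ps = model.pseudogene_seq
        assert ps.startswith(model.ltr_seq[model.u3_len:])          # R+U5 start
        assert ps.endswith("A" * model.polya_len)
        core = ps[:-model.polya_len]
        assert core.endswith(model.ltr_seq[:model.u3_len + model.r_len])  # U3+R end

    def test_gene_orfs_are_translatable(self, rng):
        from Bio.Seq import Seq

        model = ERVModel.random(rng, ltr_len=300, internal_len=1500)
        for gene, (lo, hi) in model.gene_intervals().items():
            nt = model.provirus_seq[lo:hi]
            aa = str(Seq(nt).translate())
            assert aa.startswith("M") and aa.endswith("*")
            assert "*" not in aa[:-1]


class TestLTRRecombination:
    def test_identical_ltrs_give_identical_ltr(self, rng, small_model):
        pv = small_model.provirus_seq
        out = apply_ltr_recombination(pv, small_model.ltr_len, rng)
        assert out == small_model.ltr_seq

    def test_midpoint_crossover_makes_chimera(self, small_model):
        ltr = small_model.ltr_seq
        L = len(ltr)
        # two diagnostic substitutions: one near each end of the LTR
        def sub(s, i):
            repl = "A" if s[i] != "A" else "C"
            return s[:i] + repl + s[i + 1:]
        ltr5 = sub(ltr, 10)
        ltr3 = sub(ltr, L - 10)
        pv = ltr5 + small_model.internal_seq + ltr3
        out = apply_ltr_recombination(pv, L, crossover=L // 2)
        assert out == ltr5[:L // 2] + ltr3[L // 2:]
        assert out[10] == ltr5[10] and out[L - 10] == ltr3[L - 10]

    def test_pseudogene_rejected(self, rng, small_model):
        with pytest.raises(ValidationError, match="provirus"):
            apply_ltr_recombination(small_model.pseudogene_seq,
                                    small_model.ltr_len, rng,
                                    mechanism="processed_pseudogene")

    def test_diverged_ltrs_rejected(self, rng, small_model):
        pv = small_model.ltr_seq + small_model.internal_seq + \
            mutate(small_model.ltr_seq, 0.5, 2.0, rng)
        with pytest.raises(ValidationError, match="80%"):
            apply_ltr_recombination(pv, small_model.ltr_len, rng)


class TestSimulate:
    def test_zero_rate_truth_empty(self, tree, small_model, config):
        rng = np.random.default_rng(5)
        rates = {bid: 0.0 for bid, _ in tree.branches()}
        sim = simulate(tree, small_model, rates, config, rng,
                       background_len=100_000)
        assert len(sim.truth) == 0
        assert len(sim.genomes) == 6
        lengths = {len(g.seq) for g in sim.genomes}
        assert lengths == {100_000}

    def test_single_event_forward_dollo(self, tree, small_model, config):
        """An event on one internal branch is present in exactly that clade."""
        rng = np.random.default_rng(5)
        rates = {bid: 0.0 for bid, _ in tree.branches()}
        rates["chimp+gorilla+human"] = 5.0
        sim = simulate(tree, small_model, rates, config, rng,
                       background_len=400_000, n_events=1)
        ev = sim.events[0]
        assert ev.branch_id == "chimp+gorilla+human"
        assert set(sim.truth.presence_species(ev.locus_id)) == \
            {"chimp", "gorilla", "human"}
        states = sim.truth.state_matrix().loc[ev.locus_id]
        assert states["rhesus"] == "empty" and states["human"] == "full"

    def test_mechanism_mix_near_two_thirds(self, tree, config):
        """Pseudogene fraction ~2/3 within binomial error at n=200."""
        rng = np.random.default_rng(5)
        model = ERVModel.random(rng, ltr_len=250, internal_len=900)
        sim = simulate(tree, model, default_branch_rates(tree), config, rng,
                       background_len=6_000_000, n_events=200)
        frac = np.mean([e.mechanism == "processed_pseudogene" for e in sim.events])
        se = np.sqrt((2 / 3) * (1 / 3) / 200)
        assert abs(frac - 2 / 3) < 3 * se

    def test_truth_matches_genome_slice(self, small_sim):
        by_sp = {g.species_id: g for g in small_sim.genomes}
        df = small_sim.truth.df
        present = df[df.state.isin(["full", "solitary_ltr"])]
        assert len(present) > 0
        for _, r in present.iterrows():
            assert by_sp[r.species_id].seq[int(r.start):int(r.end)] == r.seq

    def test_forward_dollo_presence_sets(self, small_sim):
        for ev in small_sim.events:
            pres = set(small_sim.truth.presence_species(ev.locus_id))
            assert pres == set(small_sim.tree.leaves_below(ev.branch_id))

    def test_recombination_yields_solitary_clades(self, small_sim):
        recombined = [e for e in small_sim.events if e.recombination_branch]
        assert len(recombined) == 3
        sm = small_sim.truth.state_matrix()
        for ev in recombined:
            below = set(small_sim.tree.leaves_below(ev.recombination_branch))
            for sp in small_sim.tree.species:
                st = sm.loc[ev.locus_id, sp]
                if sp in below:
                    assert st == "solitary_ltr"
                else:
                    assert st != "solitary_ltr"

    def test_capacity_error_before_simulation(self, tree, small_model, config):
        rng = np.random.default_rng(5)
        with pytest.raises(ValidationError, match="infeasible"):
            simulate(tree, small_model, default_branch_rates(tree), config, rng,
                     background_len=50_000, n_events=100)

    def test_divergence_grows_linearly_with_path_length(self, tree, config):
        """Mean pairwise divergence of shared loci regresses on patristic
        distance with slope within 10% of the substitution rate."""
        rng = np.random.default_rng(77)
        model = ERVModel.random(rng, ltr_len=300, internal_len=1200)
        rates = {bid: 0.0 for bid, _ in tree.branches()}
        rates[tree.root.branch_id] = 1.0
        sim = simulate(tree, model, rates, config, rng,
                       background_len=2_500_000, n_events=100)
        from ervography.comparative import k2p_distance

        xs, ys = [], []
        sp = tree.species
        seqs = {}
        for _, r in sim.truth.df.iterrows():
            if r.state == "full":
                seqs[(r.locus_id, r.species_id)] = r.seq
        for lid in {e.locus_id for e in sim.events}:
            for i in range(len(sp)):
                for j in range(i + 1, len(sp)):
                    a = seqs.get((lid, sp[i]))
                    b = seqs.get((lid, sp[j]))
                    if a is None or b is None or len(a) != len(b):
                        continue
                    # the mutation process is the K2P jump chain, so the K2P
                    # correction is an unbiased estimate of rate x path length
                    xs.append(tree.path_length(sp[i], sp[j]))
                    ys.append(k2p_distance(a, b))
        slope = np.polyfit(xs, ys, 1)[0]
        assert abs(slope - config.subst_rate) < 0.10 * config.subst_rate
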