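"""Generator determinism and agreement with its own generative model."""

import numpy as np
import pandas as pd
import pytest

from conftest import yule_tree
from dietcnv import dupmode, ingest, simulate, trees, trophic


class TestSimulateTree:
    def test_deterministic_under_seed(self):
        p = simulate.SimParams(n_species=4, seed=1)
        assert (simulate.simulate_tree(p).newick()
                == simulate.simulate_tree(p).newick())

    def test_tip_count_and_ultrametric(self):
        t = yule_tree(50, 2)
        assert t.n_tips == 50
        assert trees.is_ultrametric(t)

    def test_depth_matches_pure_birth_expectation(self):
        # depth = waiting times from the first split (2 lineages) through
        # n lineages: E[depth] = (1/rate) * (sum_{k=2}^{n-1} 1/k + 1/n)
        n, rate, reps = 8, 1.0, 200
        expect = (sum(1.0 / k for k in range(2, n)) + 1.0 / n) / rate
        depths = []
        for s in range(reps):
            t = yule_tree(n, 1000 + s, birth_rate=rate)
            depths.append(max(t.tip_depths().values()))
        se = np.std(depths, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(depths) - expect) < 3 * se

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimParams(n_species=3)


class TestTrophicStates:
    def test_zero_rates_inherit_root(self):
        t = yule_tree(10, 3)
        st = simulate.simulate_trophic_states(
            t, np.zeros((3, 3)), "herbivore", seed=1)
        assert set(st["category"]) == {"herbivore"}

    def test_fast_chain_reaches_stationarity(self):
        t = yule_tree(500, 4)
        st = simulate.simulate_trophic_states(
            t, simulate.default_rate_matrix(10.0), "carnivore", seed=5)
        freq = st["category"].value_counts(normalize=True)
        se = np.sqrt((1 / 3) * (2 / 3) / 500)
        for cat in simulate.CATEGORIES:
            assert abs(freq[cat] - 1 / 3) < 3 * se

    def test_seed_reproducibility(self):
        t = yule_tree(20, 6)
        Q = simulate.default_rate_matrix(0.5)
        a = simulate.simulate_trophic_states(t, Q, seed=7)
        b = simulate.simulate_trophic_states(t, Q, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_q_rejected(self):
        t = yule_tree(5, 1)
        with pytest.raises(ValueError):
            simulate.simulate_trophic_states(t, np.ones((3, 3)), seed=0)


class TestCopyNumbers:
    def test_iid_poisson_moment(self):
        # sigma2 = 0, beta = 0: counts are iid Poisson(e^mu)
        mu = np.log(3.0)
        p = simulate.SimParams(n_species=50, n_families=40, mu=mu,
                               sigma2_phylo=0.0, sigma2_resid=0.0, seed=8)
        t = simulate.simulate_tree(p)
        st = simulate.simulate_trophic_states(t, p.Q, seed=9)
        m = simulate.simulate_copy_numbers(t, st, p)
        draws = m.to_numpy().ravel()  # 2,000 draws
        se = np.sqrt(3.0 / draws.size)
        assert abs(draws.mean() - 3.0) < 3 * se

    def test_category_effect_on_link_scale(self):
        p = simulate.SimParams(n_species=400, n_families=10, mu=np.log(2.0),
                               beta=np.log(4.0), sigma2_phylo=0.0,
                               sigma2_resid=0.0, seed=10,
                               focal_category="herbivore")
        t = simulate.simulate_tree(p)
        st = simulate.simulate_trophic_states(
            t, simulate.default_rate_matrix(5.0), seed=11)
        m = simulate.simulate_copy_numbers(t, st, p)
        herb = st.loc[st["category"] == "herbivore", "species"]
        rest = st.loc[st["category"] != "herbivore", "species"]
        ratio = m.loc[herb].to_numpy().mean() / m.loc[rest].to_numpy().mean()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_counts_nonnegative_integers(self):
        p = simulate.SimParams(n_species=10, n_families=5, seed=12)
        t = simulate.simulate_tree(p)
        st = simulate.simulate_trophic_states(t, p.Q, seed=13)
        m = simulate.simulate_copy_numbers(t, st, p)
        assert (m.to_numpy() >= 0).all()
        assert np.issubdtype(m.to_numpy().dtype, np.integer)

    def test_phylogenetic_variance_injects_signal(self):
        # with sigma2_phylo > 0 the average fitted signal is positive
        ks, lams = [], []
        from dietcnv import comparative
        for s in range(20):
            p = simulate.SimParams(n_species=40, n_families=1, mu=2.0,
                                   sigma2_phylo=0.5, sigma2_resid=0.05,
                                   seed=100 + s)
            t = simulate.simulate_tree(p)
            cov = trees.vcv_matrix(t)
            st = simulate.simulate_trophic_states(t, p.Q, seed=200 + s)
            y = simulate.simulate_copy_numbers(t, st, p).iloc[:, 0]
            y = y.loc[cov.species].to_numpy(dtype=float)
            if np.allclose(y, y[0]):
                continue
            K, _ = comparative.blombergs_k(y, cov, n_perm=0)
            lam, _, _ = comparative.pagels_lambda(y, cov)
            ks.append(K)
            lams.append(lam)
        assert np.mean(ks) > 0.2
        assert np.mean(lams) > 0.4


class TestLocusTable:
    def _calls(self, frac, seed=1, n_fam=30):
        p = simulate.SimParams(n_species=10, n_families=n_fam, mu=1.0,
                               seed=seed)
        t = simulate.simulate_tree(p)
        st = simulate.simulate_trophic_states(t, p.Q, seed=seed + 1)
        m = simulate.simulate_copy_numbers(t, st, p)
        loci = simulate.simulate_locus_table(m, tandem_fraction=frac,
                                             seed=seed + 2)
        return dupmode.classify_all(loci)

    def test_all_tandem_when_fraction_one(self):
        calls = [c for c in self._calls(1.0) if c.call != "ND"]
        assert calls and all(c.call == "tandem" for c in calls)

    def test_all_interchromosomal_when_fraction_zero(self):
        calls = [c for c in self._calls(0.0) if c.call != "ND"]
        assert calls and all(c.call == "interchromosomal" for c in calls)

    def test_mixed_fraction_within_binomial_interval(self):
        calls = [c for c in self._calls(0.5, seed=3, n_fam=200)
                 if c.call != "ND"]
        n = len(calls)
        tandem = sum(c.call == "tandem" for c in calls)
        half_width = 2.576 * np.sqrt(0.25 / n)
        assert abs(tandem / n - 0.5) < half_width


class TestDietComposition:
    def test_herbivores_eat_primary_producers_only(self):
        st = pd.DataFrame({"species": ["a"], "category": ["herbivore"]})
        dc = simulate.simulate_diet_composition(st, seed=1)
        assert len(dc) == 1
        assert dc.iloc[0]["prey_class"] == "primary_producer"
        assert dc.iloc[0]["proportion"] == 1.0

    def test_rows_sum_to_one(self):
        st = pd.DataFrame({
            "species": list("abcdef"),
            "category": ["herbivore", "carnivore", "omnivore"] * 2})
        dc = simulate.simulate_diet_composition(st, seed=2)
        sums = dc.groupby("species")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_pure_herbivorous_prey_gives_tl_three(self):
        tl = trophic.trophic_level({"herbivorous_prey": 1.0})
        assert tl == pytest.approx(3.0)


class TestOrthologRoundTrip:
    def test_roundtrip_identity(self, tmp_path):
        p = simulate.SimParams(n_species=12, n_families=25, mu=0.5, seed=14)
        t = simulate.simulate_tree(p)
        st = simulate.simulate_trophic_states(t, p.Q, seed=15)
        m = simulate.simulate_copy_numbers(t, st, p)
        path = tmp_path / "orth.tsv"
        simulate.write_ortholog_groups(m, path)
        back = ingest.read_ortholog_groups(path)
        pd.testing.assert_frame_equal(back, m)

    def test_zero_entry_written_as_star(self, tmp_path):
        m = pd.DataFrame([[0, 3]], index=pd.Index(["spA"], name="species"),
                         columns=["f1", "f2"])
        path = tmp_path / "o.tsv"
        simulate.write_ortholog_groups(m, path)
        lines = path.read_text().splitlines()
        assert lines[1].split("\t")[1] == "*"
        assert lines[2].split("\t")[1].count(",") == 2
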