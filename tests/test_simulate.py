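"""Demographic simulator: Hardy-Weinberg founders, Mendelian transmission,
mortality, philopatry, sampling degradation, and reproducibility."""

import networkx as nx
import numpy as np
import pytest

from pedpop import (
    MarkerPanel,
    SimConfig,
    advance_year,
    collect_samples,
    default_panel,
    init_population,
    mendelian_offspring_genotype,
    simulate_population,
)
from pedpop.panel import MISSING


class TestPanelAndConfig:
    def test_boundary_allele_frequency_rejected(self):
        freqs = np.full(85, 0.5)
        freqs[3] = 1.0
        with pytest.raises(ValueError):
            MarkerPanel(autosomal_freqs=freqs)

    def test_panel_composition(self, panel):
        assert panel.n_autosomal == 85
        assert panel.n_assays == 96
        assert len(panel.mt_ids) == 4 and len(panel.y_ids) == 4 and len(panel.x_ids) == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"adult_mortality_f": 1.2},
            {"cub_mortality": -0.1},
            {"philopatry_sd_f": 30.0, "dispersal_sd_m": 5.0},
            {"n_founders": 1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestFounders:
    def test_hardy_weinberg_heterozygosity(self):
        panel = default_panel(freqs=np.full(85, 0.5))
        pop = init_population(SimConfig(seed=3, n_founders=100), panel)
        genos = np.stack([ind.genotype for ind in pop.individuals.values()])
        het = float(np.mean(genos == 1))
        assert abs(het - 0.5) < 0.05

    def test_seed_reproducibility(self, panel):
        cfg = SimConfig(seed=42, n_founders=40, n_years=6)
        a = simulate_population(cfg, panel)
        b = simulate_population(cfg, panel)
        assert list(a.individuals) == list(b.individuals)
        for iid in a.individuals:
            assert np.array_equal(a.individuals[iid].genotype, b.individuals[iid].genotype)
            assert a.individuals[iid].center == b.individuals[iid].center
        sa = collect_samples(a, cfg)
        sb = collect_samples(b, cfg)
        assert sa.to_frame().equals(sb.to_frame())

    def test_both_sexes_present(self, panel):
        pop = init_population(SimConfig(seed=0, n_founders=10), panel)
        sexes = {ind.sex for ind in pop.individuals.values()}
        assert sexes == {"F", "M"}


class TestAdvanceYear:
    def test_no_breeding_no_mortality_only_ages(self, panel):
        cfg = SimConfig(
            seed=1,
            n_founders=20,
            breeding_age=100,  # nobody reaches breeding age
            adult_mortality_f=0.0,
            adult_mortality_m=0.0,
            cub_mortality=0.0,
        )
        pop = init_population(cfg, panel)
        before = {i: (ind.birth_year, ind.center) for i, ind in pop.individuals.items()}
        advance_year(pop, cfg)
        assert pop.year == 1
        assert {i: (ind.birth_year, ind.center) for i, ind in pop.individuals.items()} == before
        assert all(ind.alive for ind in pop.individuals.values())

    def test_total_female_mortality(self, panel):
        cfg = SimConfig(
            seed=2, n_founders=30, adult_mortality_f=1.0, cub_mortality=0.0
        )
        pop = init_population(cfg, panel)
        advance_year(pop, cfg)
        for iid in pop.alive_ids:
            ind = pop.individuals[iid]
            if ind.sex == "F":
                assert pop.age(ind) < cfg.breeding_age

    def test_offspring_allele_frequency_preserved(self, rng):
        p = 0.4
        n = 10_000
        dams = (rng.binomial(1, p, (n, 1)) + rng.binomial(1, p, (n, 1))).astype(np.int8)
        sires = (rng.binomial(1, p, (n, 1)) + rng.binomial(1, p, (n, 1))).astype(np.int8)
        kids = np.array(
            [mendelian_offspring_genotype(dams[i], sires[i], rng)[0] for i in range(n)]
        )
        freq = kids.mean() / 2.0
        sd = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(freq - p) < 3 * sd


class TestMendelianTransmission:
    def test_homozygous_parents_forced(self, rng):
        out = mendelian_offspring_genotype(np.full(10, 2), np.full(10, 2), rng)
        assert np.all(out == 2)

    def test_het_cross_segregates_1_2_1(self, rng):
        n = 4000
        draws = np.array(
            [mendelian_offspring_genotype([1], [1], rng)[0] for _ in range(n)]
        )
        props = [(draws == g).mean() for g in (0, 1, 2)]
        assert abs(props[0] - 0.25) < 0.03
        assert abs(props[1] - 0.50) < 0.03
        assert abs(props[2] - 0.25) < 0.03

    def test_incomplete_parent_rejected(self, rng):
        with pytest.raises(ValueError):
            mendelian_offspring_genotype([MISSING], [2], rng)


class TestPedigreeInvariants:
    def test_acyclic_and_sex_consistent(self, population):
        g = nx.DiGraph()
        for ind in population.individuals.values():
            if ind.dam_id:
                assert population.individuals[ind.dam_id].sex == "F"
                g.add_edge(ind.dam_id, ind.id)
            if ind.sire_id:
                assert population.individuals[ind.sire_id].sex == "M"
                g.add_edge(ind.sire_id, ind.id)
        assert nx.is_directed_acyclic_graph(g)

    def test_parents_born_before_offspring(self, population):
        for ind in population.individuals.values():
            for pid in (ind.dam_id, ind.sire_id):
                if pid:
                    assert population.individuals[pid].birth_year < ind.birth_year

    def test_matrilineal_mt_lineage(self, population):
        for ind in population.individuals.values():
            if ind.dam_id:
                assert ind.mt_lineage == population.individuals[ind.dam_id].mt_lineage

    def test_female_philopatry_in_settlement(self, population):
        dd, ss = [], []
        for ind in population.individuals.values():
            if not ind.dam_id:
                continue
            dam = population.individuals[ind.dam_id]
            sire = population.individuals[ind.sire_id]
            d = np.hypot(
                ind.center[0] - dam.center[0], ind.center[1] - dam.center[1]
            )
            s = np.hypot(
                ind.center[0] - sire.center[0], ind.center[1] - sire.center[1]
            )
            (dd if ind.sex == "F" else ss).append(d if ind.sex == "F" else s)
        assert np.mean(dd) < np.mean(ss)


class TestSampling:
    def test_perfect_calls_without_noise(self, panel):
        cfg = SimConfig(seed=5, n_founders=30, n_years=4, dropout_prob=0.0,
                        typing_error=0.0, sampling_zero_prob=0.0)
        pop = simulate_population(cfg, panel)
        samples = collect_samples(pop, cfg)
        assert len(samples) > 0
        for s in samples.samples:
            truth = pop.individuals[s.individual_id]
            assert np.array_equal(s.auto_calls, truth.genotype)
            assert s.mt_called.all() and s.x_called.all()
            assert s.y_called.all() == (truth.sex == "M")

    def test_total_dropout(self, panel):
        cfg = SimConfig(seed=5, n_founders=20, n_years=2, dropout_prob=1.0)
        pop = simulate_population(cfg, panel)
        samples = collect_samples(pop, cfg)
        for s in samples.samples:
            assert np.all(s.auto_calls == MISSING)
            assert not s.mt_called.any() and not s.y_called.any() and not s.x_called.any()

    def test_typing_error_rate(self, panel):
        cfg = SimConfig(seed=6, n_founders=60, n_years=2, dropout_prob=0.0,
                        typing_error=0.01, sampling_zero_prob=0.0,
                        samples_per_individual_mean=4.0)
        pop = simulate_population(cfg, panel)
        samples = collect_samples(pop, cfg)
        errors = [
            int(np.sum(s.auto_calls != pop.individuals[s.individual_id].genotype))
            for s in samples.samples
        ]
        # binomial mean: 85 loci * 0.01 = 0.85 erroneous calls per sample
        assert abs(np.mean(errors) - 0.85) < 0.25

    def test_females_never_show_y_calls(self, population):
        samples = collect_samples(population)
        assert len(samples) > 0
        for s in samples.samples:
            if population.individuals[s.individual_id].sex == "F":
                assert not s.y_called.any()

    def test_sample_location_within_scatter_radius(self, panel):
        cfg = SimConfig(seed=7, n_founders=30, n_years=2)
        pop = simulate_population(cfg, panel)
        for s in collect_samples(pop, cfg).samples:
            center = pop.individuals[s.individual_id].center
            d = np.hypot(s.location[0] - center[0], s.location[1] - center[1])
            assert d <= cfg.sample_scatter_radius + 1e-9


class TestIO:
    def test_sample_csv_roundtrip(self, panel, tmp_path):
        cfg = SimConfig(seed=8, n_founders=20, n_years=3)
        pop = simulate_population(cfg, panel)
        samples = collect_samples(pop, cfg)
        path = tmp_path / "samples.csv"
        samples.to_csv(path)
        back = type(samples).from_csv(path, panel)
        assert len(back) == len(samples)
        for a, b in zip(samples.samples, back.samples):
            assert a.sample_id == b.sample_id
            assert a.individual_id == b.individual_id
            assert np.array_equal(a.auto_calls, b.auto_calls)
            assert np.array_equal(a.y_called, b.y_called)

    def test_pedigree_csv_columns(self, population, tmp_path):
        path = tmp_path / "pedigree.csv"
        population.pedigree_to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == [
            "id", "sex", "birth_year", "death_year", "dam_id", "sire_id", "x", "y",
        ]
        assert len(df) == len(population.individuals)
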