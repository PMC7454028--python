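"""Unit and property tests for the two-deme biennial simulator."""

import numpy as np
import pytest

from temporal_demes import (
    EmigrantCohort,
    SimulationConfig,
    advance_generation,
    draw_emigrants,
    emigrant_count,
    init_deme,
    recruit_count,
    reproductive_year,
    run_simulation,
    sample_offspring_genotypes,
)
from temporal_demes.biennial_model import gene_diversity


@pytest.mark.parametrize(
    "t, deme, expected",
    [(1, "d1", 1), (1, "d2", 2), (50, "d2", 100), (7, "d1", 13)],
)
def test_reproductive_years_alternate(t, deme, expected):
    assert reproductive_year(t, deme) == expected


def test_reproductive_year_rejects_nonpositive_generation():
    with pytest.raises(ValueError):
        reproductive_year(0, "d1")


@pytest.mark.parametrize(
    "n_prev, lam, expected",
    [(1000, 1.0, 1000), (0, 1.3, 0), (1000, 1.013, 1013), (3, 0.4, 1)],
)
def test_recruit_count_rounds_to_nearest(n_prev, lam, expected):
    assert recruit_count(n_prev, lam) == expected


def test_recruit_count_rejects_negative():
    with pytest.raises(ValueError):
        recruit_count(-1, 1.0)
    with pytest.raises(ValueError):
        recruit_count(10, -0.1)


@pytest.mark.parametrize(
    "n_r, m, event, expected",
    [(1000, 0.5, True, 500), (1000, 0.5, False, 0), (1000, 0.0, True, 0),
     (3, 0.9, True, 3)],
)
def test_emigrant_count(n_r, m, event, expected):
    assert emigrant_count(n_r, m, event) == expected


def test_emigrant_count_rejects_bad_rate():
    with pytest.raises(ValueError):
        emigrant_count(10, 1.5, True)


class TestInitDeme:
    def test_fixed_allele(self, rng):
        cfg = SimulationConfig(n0=20, n_loci=5, p0=1.0)
        st = init_deme(cfg, "d1", rng)
        assert (st.genotypes == 2).all()
        assert np.allclose(st.allele_freqs, 1.0)

    def test_binomial_sampling_frequency(self, rng):
        cfg = SimulationConfig(n0=1000, n_loci=200, p0=0.5)
        st = init_deme(cfg, "d1", rng)
        se = np.sqrt(0.25 / 2000)
        assert abs(st.allele_freqs.mean() - 0.5) < 3 * se / np.sqrt(200)
        assert (np.abs(st.allele_freqs - 0.5) < 5 * se).all()

    def test_empty_deme_is_extinct(self, rng):
        cfg = SimulationConfig(n0=0, n_loci=3)
        st = init_deme(cfg, "d2", rng)
        assert st.extinct and st.genotypes.shape == (0, 3)


class TestOffspringSampling:
    def test_fixed_frequencies(self, rng):
        assert (sample_offspring_genotypes(np.ones(4), 5, rng) == 2).all()
        assert (sample_offspring_genotypes(np.zeros(4), 5, rng) == 0).all()

    def test_frequency_recovery(self, rng):
        g = sample_offspring_genotypes(np.full(50, 0.5), 10000, rng)
        freqs = g.mean(axis=0) / 2
        # per-locus binomial bound wide enough for 50 simultaneous checks
        assert (np.abs(freqs - 0.5) < 0.015).all()
        assert abs(freqs.mean() - 0.5) < 3 * np.sqrt(0.25 / 20000) / np.sqrt(50)

    def test_rejects_bad_frequency(self, rng):
        with pytest.raises(ValueError):
            sample_offspring_genotypes(np.array([1.2]), 3, rng)


class TestDrawEmigrants:
    def test_extremes(self, rng):
        mat = rng.integers(0, 3, size=(10, 4))
        emig, rest = draw_emigrants(mat, 0, rng)
        assert emig.shape[0] == 0 and rest.shape[0] == 10
        emig, rest = draw_emigrants(mat, 10, rng)
        assert emig.shape[0] == 10 and rest.shape[0] == 0

    def test_conservation_of_rows(self, rng):
        mat = rng.integers(0, 3, size=(10, 4))
        emig, rest = draw_emigrants(mat, 4, rng)
        combined = sorted(map(tuple, np.vstack([emig, rest])))
        assert combined == sorted(map(tuple, mat))

    def test_overdraw_clips_with_warning(self, rng, caplog):
        mat = rng.integers(0, 3, size=(5, 2))
        with caplog.at_level("WARNING"):
            emig, rest = draw_emigrants(mat, 9, rng)
        assert emig.shape[0] == 5 and rest.shape[0] == 0
        assert "clipping" in caplog.text


class TestAdvanceGeneration:
    def test_spec_startup_example(self):
        """First d1 year at m=0.5 with the event on: 1000 recruits, 500
        leave, nobody arrives; d2 then receives those 500."""
        cfg = SimulationConfig(
            n_generations=1, n0=1000, n_loci=4, lambda_sd=0.0,
            m12=0.5, m21=0.5, p_event=1.0, seed=42,
        )
        traj = run_simulation(cfg)
        d1 = traj.deme_series("d1").iloc[0]
        d2 = traj.deme_series("d2").iloc[0]
        assert (d1.N_R, d1.N_E, d1.N_M, d1.N_T) == (1000, 500, 0, 500)
        assert (d2.N_R, d2.N_E, d2.N_M, d2.N_T) == (1000, 500, 500, 1000)

    def test_extinct_deme_absorbing_without_immigrants(self, rng):
        cfg = SimulationConfig(n0=0, n_loci=3, lambda_sd=0.0)
        st = init_deme(cfg, "d1", rng)
        nxt, out = advance_generation(st, None, cfg, rng)
        assert nxt.extinct and nxt.N_T == 0 and out.size == 0

    def test_recolonization_by_immigrants(self, rng):
        cfg = SimulationConfig(n0=0, n_loci=3, lambda_sd=0.0)
        st = init_deme(cfg, "d1", rng)
        cohort = EmigrantCohort("d2", 2, np.ones((7, 3), dtype=np.int8))
        nxt, _ = advance_generation(st, cohort, cfg, rng)
        assert nxt.N_T == 7 and nxt.recolonized and not nxt.extinct


class TestRunSimulation:
    def test_flat_without_migration_or_noise(self):
        cfg = SimulationConfig(
            n_generations=10, n0=300, n_loci=5, lambda_sd=0.0, seed=3
        )
        traj = run_simulation(cfg)
        assert (traj.series["N_T"] == 300).all()
        assert not traj.series["extinct"].any()

    def test_same_seed_identical(self):
        cfg = SimulationConfig(
            n_generations=8, n0=100, n_loci=10, m12=0.3, m21=0.3,
            p_event=0.5, seed=11,
        )
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert a.series.equals(b.series)
        for d in ("d1", "d2"):
            assert np.array_equal(a.final_genotypes[d], b.final_genotypes[d])

    def test_accounting_identity_every_generation(self):
        cfg = SimulationConfig(
            n_generations=20, n0=80, n_loci=6, m12=0.6, m21=0.4,
            p_event=0.7, seed=5,
        )
        s = run_simulation(cfg).series
        assert (s["N_T"] == s["N_R"] + s["N_M"] - s["N_E"]).all()
        assert (s["N_T"] >= 0).all()
        assert (s["extinct"] == (s["N_T"] == 0)).all()

    def test_zero_rate_event_probability_equivalence(self):
        """With m = 0 the event draw changes nothing, so p_event = 0 and 1
        give bitwise-identical runs from the same seed."""
        base = dict(n_generations=12, n0=150, n_loci=8, seed=9)
        a = run_simulation(SimulationConfig(p_event=0.0, **base))
        b = run_simulation(SimulationConfig(p_event=1.0, **base))
        assert a.series.equals(b.series)

    def test_config_file_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_generations: 5\nn0: 40\nn_loci: 3\nm12: 0.2\nseed: 1\n")
        cfg = SimulationConfig.from_file(p)
        assert cfg.n0 == 40 and cfg.m12 == 0.2
        with pytest.raises(ValueError):
            (tmp_path / "bad.yaml").write_text("nope: 3\n")
            SimulationConfig.from_file(tmp_path / "bad.yaml")


class TestNeutralDriftExpectations:
    """Small-population drift checks against Wright-Fisher closed forms.

    The founding sample is itself one binomial draw, so after t simulated
    generations the allele-frequency variance corresponds to t + 1
    Wright-Fisher steps.
    """

    def test_frequency_variance_growth(self):
        n0, t, reps = 50, 10, 25
        msds = []
        for i in range(reps):
            cfg = SimulationConfig(
                n_generations=t, n0=n0, n_loci=100, lambda_sd=0.0, seed=1000 + i
            )
            traj = run_simulation(cfg)
            g = traj.final_genotypes["d1"]
            p = g.mean(axis=0) / 2
            msds.append(((p - 0.5) ** 2).mean())
        expected = 0.25 * (1 - (1 - 1 / (2 * n0)) ** (t + 1))
        mean, se = np.mean(msds), np.std(msds, ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) < 3 * se

    def test_gene_diversity_decay(self):
        n0, t, reps = 50, 10, 25
        vals = []
        for i in range(reps):
            cfg = SimulationConfig(
                n_generations=t, n0=n0, n_loci=100, lambda_sd=0.0, seed=2000 + i
            )
            traj = run_simulation(cfg)
            vals.append(gene_diversity(traj.final_genotypes["d2"]))
        # the unbiased estimator at generation t is unbiased for the parental
        # pool's heterozygosity, i.e. t drift steps including the founding draw
        expected = 0.5 * (1 - 1 / (2 * n0)) ** t
        mean, se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) < 3 * se
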