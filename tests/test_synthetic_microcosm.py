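import numpy as np
import pytest

from conftest import consortium
from microstab.errors import DomainError
from microstab.niche_profiles import (
    AffinityMatrix,
    community_metabolic_diversity,
    niche_breadth,
    pairwise_overlap,
)
from microstab.synthetic_microcosm import (
    GeneratorConfig,
    generate_affinity_matrix,
    generate_experiment,
    simulate_abundances,
    simulate_eh,
    simulate_endpoints,
    species_setpoints,
    write_experiment,
)
from microstab.wavelet_stability import default_scale_grid, treatment_stability

DAY = 86400.0
FAST = dict(duration=1 * DAY)  # 96 samples: enough for every structural check


def identical_profile_matrix(k=2, breadth=10, n_substrates=95):
    cells = np.zeros((k, n_substrates), dtype=np.int8)
    cells[:, :breadth] = 1
    return AffinityMatrix(
        tuple(f"sp{i + 1:02d}" for i in range(k)),
        tuple(f"sub{j}" for j in range(n_substrates)),
        cells,
    )


def disjoint_profile_matrix(k=2, breadth=10, n_substrates=95):
    cells = np.zeros((k, n_substrates), dtype=np.int8)
    for i in range(k):
        cells[i, i * breadth:(i + 1) * breadth] = 1
    return AffinityMatrix(
        tuple(f"sp{i + 1:02d}" for i in range(k)),
        tuple(f"sub{j}" for j in range(n_substrates)),
        cells,
    )


class TestGeneratorConfig:
    def test_defaults_shape(self):
        cfg = GeneratorConfig()
        assert cfg.n_samples == 1248
        assert cfg.n_probes == 8

    def test_breadth_exceeding_substrates(self):
        with pytest.raises(DomainError):
            GeneratorConfig(breadth_range=(10, 100), n_substrates=95)

    def test_bad_compensation(self):
        with pytest.raises(DomainError):
            GeneratorConfig(compensation_strength=1.5)

    def test_json_round_trip(self):
        cfg = GeneratorConfig(seed=7, fluctuation_sd=0.2)
        cfg2 = GeneratorConfig.from_json(cfg.to_json())
        assert cfg2 == cfg


class TestGenerateAffinityMatrix:
    def test_deterministic(self):
        cfg = GeneratorConfig(seed=5)
        m1 = generate_affinity_matrix(cfg)
        m2 = generate_affinity_matrix(cfg)
        np.testing.assert_array_equal(m1.cells, m2.cells)

    def test_breadths_within_range(self):
        cfg = GeneratorConfig(seed=3, breadth_range=(10, 20))
        m = generate_affinity_matrix(cfg)
        for s in m.species_ids:
            assert 10 <= niche_breadth(m, s) <= 20

    def test_forced_saturation(self):
        cfg = GeneratorConfig(seed=1, breadth_range=(95, 95))
        m = generate_affinity_matrix(cfg)
        assert np.all(m.cells == 1)
        c = consortium(*m.species_ids)
        assert community_metabolic_diversity(m, c) == 95

    def test_uniform_limit_matches_hypergeometric_oracle(self):
        # conc -> infinity: substrates uniform; mean Jaccard of many pairs
        # should match an independent uniform-subset sampler
        cfg = GeneratorConfig(seed=11, substrate_popularity_concentration=None,
                              breadth_range=(20, 30), n_species=12)
        vals = []
        for s in range(90):
            m = generate_affinity_matrix(cfg.replace(seed=s))
            ids = m.species_ids
            for i in range(0, 12, 2):
                vals.append(pairwise_overlap(m, ids[i], ids[i + 1]))
        oracle_rng = np.random.default_rng(999)
        oracle = []
        for _ in range(1000):
            b1, b2 = oracle_rng.integers(20, 31, size=2)
            s1 = set(oracle_rng.choice(95, size=b1, replace=False).tolist())
            s2 = set(oracle_rng.choice(95, size=b2, replace=False).tolist())
            oracle.append(len(s1 & s2) / len(s1 | s2))
        assert np.mean(vals) == pytest.approx(np.mean(oracle), abs=0.02)

    def test_lower_concentration_means_higher_overlap(self):
        def mean_overlap(conc):
            vals = []
            for s in range(20):
                m = generate_affinity_matrix(
                    GeneratorConfig(seed=s, substrate_popularity_concentration=conc,
                                    breadth_range=(20, 30))
                )
                ids = m.species_ids
                vals.extend(
                    pairwise_overlap(m, ids[i], ids[j])
                    for i in range(12) for j in range(i + 1, 12)
                )
            return np.mean(vals)

        assert mean_overlap(0.1) > mean_overlap(50.0) + 0.05


class TestSimulateAbundances:
    def test_no_noise_constant_shares(self):
        m = identical_profile_matrix(k=3)
        cfg = GeneratorConfig(fluctuation_sd=0.0, **FAST)
        paths = simulate_abundances(consortium(*m.species_ids), m, cfg)
        np.testing.assert_allclose(paths.shares, 1 / 3)

    def test_conservation_and_nonnegativity(self):
        m = disjoint_profile_matrix(k=4, breadth=8)
        cfg = GeneratorConfig(seed=2, fluctuation_sd=0.4, **FAST)
        paths = simulate_abundances(consortium(*m.species_ids), m, cfg)
        assert np.all(paths.shares >= 0)
        np.testing.assert_allclose(paths.shares.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_compensation_correlations_at_compositional_null(self):
        # exact share conservation forces mean pairwise r of -1/(k-1);
        # with compensation off there is no structure beyond that
        k = 12
        cells = np.eye(k, 95, dtype=np.int8)  # disjoint
        m = AffinityMatrix(tuple(f"sp{i:02d}" for i in range(k)),
                           tuple(f"sub{j}" for j in range(95)), cells)
        c = consortium(*m.species_ids)
        rs = []
        for s in range(8):
            cfg = GeneratorConfig(seed=s, compensation_strength=0.0, **FAST)
            shares = simulate_abundances(c, m, cfg).shares
            corr = np.corrcoef(shares.T)
            iu = np.triu_indices(k, 1)
            rs.extend(corr[iu])
        assert abs(np.mean(rs) - (-1 / (k - 1))) < 0.05

    def test_strong_compensation_identical_pair_anticorrelated(self):
        # at c = 1 an identical pair is perfectly buffered (constant shares,
        # checked below), so the anti-correlation is probed just inside
        m = identical_profile_matrix(k=2)
        c = consortium(*m.species_ids)
        rs = []
        for s in range(50):
            cfg = GeneratorConfig(seed=s, compensation_strength=0.95, **FAST)
            shares = simulate_abundances(c, m, cfg).shares
            rs.append(np.corrcoef(shares[:, 0], shares[:, 1])[0, 1])
        assert np.mean(rs) < -0.3

    def test_full_compensation_identical_pair_fully_buffered(self):
        m = identical_profile_matrix(k=2)
        c = consortium(*m.species_ids)
        cfg = GeneratorConfig(seed=1, compensation_strength=1.0, **FAST)
        shares = simulate_abundances(c, m, cfg).shares
        np.testing.assert_allclose(shares, 0.5, atol=1e-12)


class TestSimulateEh:
    def quiet(self, **kw):
        return GeneratorConfig(observation_noise_sd=0.0, probe_noise_sd=0.0,
                               drift_amplitude_mV=0.0, **FAST, **kw)

    def test_single_species_constant_at_setpoint(self):
        m = identical_profile_matrix(k=1)
        cfg = self.quiet(fluctuation_sd=0.0)
        c = consortium("sp01")
        paths = simulate_abundances(c, m, cfg)
        sps = species_setpoints(m, cfg)
        series = simulate_eh(c, paths, cfg, setpoints=sps)
        for s in series:
            np.testing.assert_allclose(s.values, sps["sp01"])

    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(seed=9, **FAST)
        m = generate_affinity_matrix(cfg)
        c = consortium(*m.species_ids[:3])
        out = []
        for _ in range(2):
            paths = simulate_abundances(c, m, cfg)
            out.append(simulate_eh(c, paths, cfg, matrix=m))
        for a, b in zip(*out):
            np.testing.assert_array_equal(a.values, b.values)

    def test_compensation_reduces_composite_variance_for_redundant_pair(self):
        m = identical_profile_matrix(k=2)
        c = consortium(*m.species_ids)
        ratios = []
        for s in range(20):
            out = {}
            for comp in (0.0, 1.0):
                cfg = self.quiet(fluctuation_sd=0.3).replace(
                    seed=s, compensation_strength=comp
                )
                paths = simulate_abundances(c, m, cfg)
                # force distinct setpoints so redistribution is visible
                series = simulate_eh(c, paths, cfg,
                                     setpoints={"sp01": -200.0, "sp02": 100.0})
                out[comp] = np.var(series[0].values)
            ratios.append(out[1.0] / out[0.0])
        assert np.median(ratios) < 1.0

    def test_probe_count_and_grid(self):
        cfg = GeneratorConfig(seed=4, n_probes=5, **FAST)
        m = generate_affinity_matrix(cfg)
        c = consortium(*m.species_ids[:2])
        series = simulate_eh(c, simulate_abundances(c, m, cfg), cfg, matrix=m)
        assert len(series) == 5
        assert {s.probe_depth for s in series} == set(range(5))
        assert all(s.n == cfg.n_samples for s in series)


class TestSimulateEndpoints:
    def test_noiseless_linear_in_cmd(self):
        cfg = GeneratorConfig(seed=6, endpoint_noise_sd=0.0, **FAST)
        m = generate_affinity_matrix(cfg)
        from microstab.niche_profiles import build_design

        design = build_design(m.species_ids)
        df = simulate_endpoints(design, m, cfg)
        np.testing.assert_allclose(df["doc"], cfg.doc_slope * df["cmd"])
        np.testing.assert_allclose(df["etsa"], cfg.etsa_slope * df["cmd"])

    def test_zero_slope_null_correlation(self):
        from microstab.association_stats import pearson
        from microstab.niche_profiles import build_design

        rs = []
        for s in range(60):
            cfg = GeneratorConfig(seed=s, doc_slope=0.0, **FAST)
            m = generate_affinity_matrix(cfg)
            df = simulate_endpoints(build_design(m.species_ids), m, cfg)
            rs.append(pearson(df["cmd"], df["doc"]).r)
        assert abs(np.mean(rs)) < 0.05

    def test_nonnegative_outputs(self):
        for s in range(10):
            cfg = GeneratorConfig(seed=s, endpoint_noise_sd=80.0, **FAST)
            m = generate_affinity_matrix(cfg)
            from microstab.niche_profiles import build_design

            df = simulate_endpoints(build_design(m.species_ids), m, cfg)
            assert (df["etsa"] >= 0).all() and (df["doc"] >= 0).all()


class TestGenerateExperiment:
    def test_structure_small(self):
        cfg = GeneratorConfig(seed=1, **FAST)
        exp = generate_experiment(cfg)
        assert len(exp.eh) == 51
        assert sum(len(v) for v in exp.eh.values()) == 51 * 8
        assert all(s.n == 96 for v in exp.eh.values() for s in v)
        assert len(exp.endpoints) == 51

    def test_truth_cmd_consistent(self):
        cfg = GeneratorConfig(seed=2, **FAST)
        exp = generate_experiment(cfg)
        by_label = {c.label: c for c in exp.design.consortia}
        for mc_id, rec in exp.truth["microcosms"].items():
            c = by_label[rec["consortium_label"]]
            assert rec["cmd"] == community_metabolic_diversity(exp.matrix, c)

    def test_seed_changes_data_not_shapes(self):
        e1 = generate_experiment(GeneratorConfig(seed=1, **FAST))
        e2 = generate_experiment(GeneratorConfig(seed=2, **FAST))
        assert set(e1.eh) == set(e2.eh)
        assert not np.array_equal(e1.eh["SR2-A-r1"][0].values, e2.eh["SR2-A-r1"][0].values)

    def test_byte_identical_reruns(self, tmp_path):
        cfg = GeneratorConfig(seed=3, **FAST)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_experiment(generate_experiment(cfg), d1)
        write_experiment(generate_experiment(cfg), d2)
        for name in ("affinity.tsv", "design.json", "eh.csv", "endpoints.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestEffectDirection:
    def test_overlap_plus_compensation_stabilizes(self):
        """High-overlap consortia beat disjoint ones of equal richness."""
        k = 4
        m_over = identical_profile_matrix(k=k, breadth=12)
        m_dis = disjoint_profile_matrix(k=k, breadth=12)
        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            stabs = {}
            for name, m in (("over", m_over), ("dis", m_dis)):
                cfg = GeneratorConfig(seed=s, compensation_strength=0.7,
                                      n_species=k, **FAST)
                c = consortium(*m.species_ids)
                paths = simulate_abundances(c, m, cfg)
                series = simulate_eh(c, paths, cfg, matrix=m)
                grid = default_scale_grid(series[0].n, series[0].dt, 4)
                stabs[name] = treatment_stability(series, grid).stability
            wins += stabs["over"] > stabs["dis"]
        assert wins > n_seeds / 2
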