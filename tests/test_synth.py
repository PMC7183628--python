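"""Synthetic cohort generator: graphs, VAR embedding, recordings, metadata."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from somnonet.errors import InvalidParameterError
from somnonet.mvgc import companion_spectral_radius
from somnonet.netmetrics import adjacency_to_graph, small_world
from somnonet.recording import MONTAGE_10_20
from somnonet.synth import (
    DEFAULT_PROFILES,
    CohortConfig,
    CouplingGraph,
    StageProfile,
    bdi_severity,
    draw_subjects,
    graph_to_mvar,
    make_cohort,
    make_coupling_graph,
    score_bdi,
    simulate_recording,
)


class TestCouplingGraph:
    def test_ring_lattice_at_zero_rewiring(self):
        g = make_coupling_graph(19, 4, 0.0, seed=1)
        assert len(g.edges) == 19 * 4
        out_deg = np.zeros(19, int)
        for s, t in g.edges:
            out_deg[s] += 1
            # lattice targets are the two nearest neighbours on each side
            ring_dist = min(abs(s - t), 19 - abs(s - t))
            assert ring_dist <= 2
        assert np.all(out_deg == 4)

    def test_full_rewiring_conserves_edge_count(self):
        lattice = set(make_coupling_graph(19, 4, 0.0, seed=3).edges)
        g = make_coupling_graph(19, 4, 1.0, seed=3)
        assert len(g.edges) == 76
        assert len(set(g.edges)) == 76
        assert set(g.edges) != lattice
        out_deg = np.zeros(19, int)
        for s, _ in g.edges:
            out_deg[s] += 1
        assert np.all(out_deg == 4)  # out-degree-preserving rewiring

    def test_seeded_determinism(self):
        a = make_coupling_graph(19, 4, 0.1, seed=7)
        b = make_coupling_graph(19, 4, 0.1, seed=7)
        assert a.edges == b.edges

    def test_mean_degree_too_large_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_coupling_graph(5, 6, 0.1, seed=0)

    def test_no_self_loops_invariant(self):
        with pytest.raises(InvalidParameterError):
            CouplingGraph(n_nodes=3, edges=((0, 0),), weights=np.ones(1),
                          rewiring_prob=0.0)


class TestGraphToMvar:
    def test_no_edges_gives_independent_channels(self):
        g = CouplingGraph(n_nodes=4, edges=(), weights=np.zeros(0), rewiring_prob=0.0)
        m = graph_to_mvar(g, DEFAULT_PROFILES["W"], order=2, fs=200.0, seed=0)
        for k in range(m.order):
            off = m.coeffs[k] - np.diag(np.diag(m.coeffs[k]))
            assert np.all(off == 0)
        assert np.all(m.resid_cov == np.diag(np.diag(m.resid_cov)))

    def test_coupling_coefficient_read_back(self):
        # one edge 0 -> 1 of weight 0.4 at unit coupling strength lands on
        # the lag-1 cross coefficient (target row, source column)
        g = CouplingGraph(n_nodes=2, edges=((0, 1),), weights=np.array([0.4]),
                          rewiring_prob=0.0)
        prof = StageProfile("W", ((10.0, 1.0),), rewiring_prob=0.0,
                            coupling_strength=1.0, pole_radius=0.5)
        m = graph_to_mvar(g, prof, order=2, fs=200.0, stability_margin=0.95, seed=1)
        assert m.coeffs[0][1, 0] == pytest.approx(0.4)

    def test_stationarity_over_random_configs(self):
        # enforced invariant: companion spectral radius <= stability margin
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(3, 20))
            k = int(2 * rng.integers(1, (n - 1) // 2 + 1))
            g = make_coupling_graph(n, k, float(rng.uniform(0, 1)), seed=trial)
            prof = list(DEFAULT_PROFILES.values())[trial % 4]
            m = graph_to_mvar(g, prof, order=int(rng.integers(2, 6)), fs=200.0,
                              stability_margin=0.9, seed=trial)
            assert companion_spectral_radius(m.coeffs) <= 0.9 + 1e-9

    def test_order_below_two_rejected(self):
        g = make_coupling_graph(5, 2, 0.0, seed=0)
        with pytest.raises(InvalidParameterError):
            graph_to_mvar(g, DEFAULT_PROFILES["W"], order=1, fs=200.0)

    def test_band_center_above_nyquist_rejected(self):
        g = make_coupling_graph(5, 2, 0.0, seed=0)
        prof = StageProfile("W", ((40.0, 1.0),), rewiring_prob=0.0)
        with pytest.raises(InvalidParameterError):
            graph_to_mvar(g, prof, order=2, fs=70.0)


class TestSimulateRecording:
    def test_duration_and_hypnogram(self, rem_models):
        rec, hyp, mask = simulate_recording(
            {"REM": rem_models["REM"]}, ("REM",) * 9, fs=200.0, seed=5
        )
        assert rec.duration_s == pytest.approx(180.0)
        assert len(hyp) == 9 and set(hyp.stages) == {"REM"}
        assert len(mask) == 9

    def test_seeded_determinism_bit_identical(self, rem_models):
        a = simulate_recording({"REM": rem_models["REM"]}, ("REM",) * 3, seed=11)
        b = simulate_recording({"REM": rem_models["REM"]}, ("REM",) * 3, seed=11)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert np.array_equal(a[2].clean, b[2].clean)

    def test_zero_artifact_fraction_all_clean(self, rem_models):
        _, _, mask = simulate_recording({"REM": rem_models["REM"]}, ("REM",) * 6,
                                        seed=2, artifact_fraction=0.0)
        assert mask.clean.all()

    def test_missing_stage_model_rejected(self, rem_models):
        with pytest.raises(InvalidParameterError):
            simulate_recording({"REM": rem_models["REM"]}, ("W", "REM"), seed=0)


class TestCohort:
    def test_cohort_size_and_composition(self):
        cfg = CohortConfig(n_men=28, n_women=16, epochs_per_stage=2,
                           stages=("REM",), seed=0)
        bundles = make_cohort(cfg)
        assert len(bundles) == 44
        sexes = [s.sex for s, *_ in bundles]
        assert sexes.count("M") == 28 and sexes.count("F") == 16
        rec = bundles[0][1]
        assert rec.channel_labels == MONTAGE_10_20

    def test_cohort_determinism(self):
        cfg = CohortConfig(n_men=1, n_women=1, epochs_per_stage=2,
                           stages=("REM",), seed=4)
        a = make_cohort(cfg)
        b = make_cohort(cfg)
        for (sa, ra, *_), (sb, rb, *_) in zip(a, b):
            assert sa == sb
            assert np.array_equal(ra.samples, rb.samples)

    def test_sex_effect_lives_in_rem_rewiring(self):
        subs = draw_subjects(CohortConfig(seed=1))
        men = [s.extras["rewiring"] for s in subs if s.sex == "M"]
        women = [s.extras["rewiring"] for s in subs if s.sex == "F"]
        assert np.mean([r["REM"] for r in women]) > np.mean([r["REM"] for r in men])
        for stage in ("3", "4"):
            assert {r[stage] for r in men} == {r[stage] for r in women}

    def test_rank_coupling_calibration_window(self):
        # with rho=0.6 and n_women=16 the realized Spearman correlation
        # between BDI and REM rewiring lies in (0.2, 0.9) in >= 90% of seeds
        hits = 0
        for seed in range(50):
            subs = draw_subjects(CohortConfig(seed=seed))
            w = [s for s in subs if s.sex == "F"]
            rho, _ = spearmanr([s.bdi for s in w],
                               [s.extras["rewiring"]["REM"] for s in w])
            hits += 0.2 < rho < 0.9
        assert hits >= 45

    def test_null_coupling_shows_no_association(self):
        # rho=0: the women's BDI-topology Spearman test is non-significant
        # at alpha=0.05 in >= 90% of 20 seeds
        nonsig = 0
        for seed in range(20):
            subs = draw_subjects(CohortConfig(seed=seed, bdi_omega_rho_women=0.0))
            w = [s for s in subs if s.sex == "F"]
            _, p = spearmanr([s.bdi for s in w],
                             [s.extras["rewiring"]["REM"] for s in w])
            nonsig += p > 0.05
        assert nonsig >= 18

    def test_perfect_coupling_is_monotone(self):
        subs = draw_subjects(CohortConfig(seed=3, bdi_omega_rho_women=1.0))
        w = [s for s in subs if s.sex == "F"]
        order = np.argsort([s.extras["rewiring"]["REM"] for s in w])
        bdi_sorted = np.array([s.bdi for s in w])[order]
        assert np.all(np.diff(bdi_sorted) >= 0)

    def test_ground_truth_omega_increases_with_rewiring(self):
        # ensemble-mean small-worldness of the coupling graphs rises as the
        # rewiring probability goes 0 -> 0.3
        means = []
        for p in (0.0, 0.1, 0.3):
            vals = []
            for seed in range(12):
                g = make_coupling_graph(19, 4, p, seed=seed)
                bg = adjacency_to_graph(g.adjacency())
                vals.append(small_world(bg, n_surrogates=10, seed=seed).swc)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestBdi:
    @pytest.mark.parametrize("items,expected", [
        ([3] * 13, 39),
        ([0] * 13, 0),
        ([1, 1, 1] + [0] * 10, 3),
    ])
    def test_scores(self, items, expected):
        assert score_bdi(items) == expected

    @pytest.mark.parametrize("score,label", [
        (0, "absence of depression"),
        (4, "absence of depression"),
        (5, "subclinical depression"),
        (8, "moderate depression"),
        (15, "moderate depression"),
        (16, "severe depression"),
        (39, "severe depression"),
    ])
    def test_severity_cutoffs(self, score, label):
        assert bdi_severity(score) == label

    @pytest.mark.parametrize("bad", [[1] * 12, [1] * 14, [4] + [0] * 12, [-1] + [0] * 12])
    def test_validation(self, bad):
        with pytest.raises(InvalidParameterError):
            score_bdi(bad)
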