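import itertools

import numpy as np
import pandas as pd
import pytest

from hairpinxb.namfis import (NamfisDeconvolution, PoolObservables,
                              fit_populations, jackknife_stability,
                              pool_observables, predict_averages)
from hairpinxb.restraints import DistanceRestraint, JRestraint, karplus_j
from hairpinxb.synthetic import default_distance_pairs


@pytest.fixture(scope="module")
def mixed_pool_obs(small_pool, default_cfg):
    """Observables for 5 folded + 5 unfolded conformers."""
    pool, truth = small_pool
    subset = pool[:5] + pool[10:15]
    pairs, _ = default_distance_pairs(default_cfg)
    return pool_observables(subset, pairs, phi_residues=range(2, 10))


def exact_restraints(pool_obs, p):
    """Noise-free restraints generated from known populations."""
    dists, js = predict_averages(p, pool_obs)
    dr = [DistanceRestraint(tuple(c.split("/")), v, max(0.1 * v, 0.2))
          for c, v in dists.items()]
    jr = [JRestraint(c, v, 0.5) for c, v in js.items()]
    return dr, jr


def simplex_grid(n, step=0.02):
    """All population vectors on the n-simplex with the given resolution."""
    m = int(round(1.0 / step))
    out = []
    for comp in itertools.combinations(range(m + n - 1), n - 1):
        prev = -1
        parts = []
        for c in comp:
            parts.append(c - prev - 1)
            prev = c
        parts.append(m + n - 2 - prev)
        out.append(np.array(parts) / m)
    return np.array(out)


class TestPredictAverages:
    def test_single_conformer_identity(self, mixed_pool_obs):
        p = np.zeros(len(mixed_pool_obs))
        p[0] = 1.0
        dists, js = predict_averages(p, mixed_pool_obs)
        assert np.allclose(dists, mixed_pool_obs.distances.iloc[0], atol=1e-12)
        assert np.allclose(
            js, karplus_j(mixed_pool_obs.dihedrals.iloc[0].to_numpy()),
            atol=1e-12)

    def test_r6_average_hand_checked(self):
        dist = pd.DataFrame({"a/b": [2.0, 4.0]}, index=[1, 2])
        dih = pd.DataFrame({"phi2": [0.0, 0.0]}, index=[1, 2])
        po = PoolObservables(dist, dih)
        dists, _ = predict_averages([0.5, 0.5], po)
        assert dists["a/b"] == pytest.approx(
            (0.5 * 2.0**-6 + 0.5 * 4.0**-6) ** (-1 / 6), rel=1e-12)
        assert dists["a/b"] == pytest.approx(2.24, abs=0.01)

    def test_degenerate_pool(self):
        dist = pd.DataFrame({"a/b": [3.0, 3.0, 3.0]}, index=[1, 2, 3])
        dih = pd.DataFrame({"phi2": [-60.0, -60.0, -60.0]}, index=[1, 2, 3])
        po = PoolObservables(dist, dih)
        for p in ([1, 0, 0], [0.2, 0.5, 0.3]):
            dists, js = predict_averages(p, po)
            assert dists["a/b"] == pytest.approx(3.0, rel=1e-12)
            assert js["phi2"] == pytest.approx(karplus_j(-60.0), rel=1e-12)

    def test_off_simplex_rejected(self, mixed_pool_obs):
        p = np.full(len(mixed_pool_obs), 0.2)
        with pytest.raises(ValueError, match="simplex"):
            predict_averages(p, mixed_pool_obs)


class TestFitPopulations:
    def test_recovery_oracle(self, mixed_pool_obs):
        """Noise-free two-conformer mixture recovered to 1e-3 (max abs)."""
        p_true = np.zeros(len(mixed_pool_obs))
        p_true[0], p_true[5] = 0.7, 0.3
        dr, jr = exact_restraints(mixed_pool_obs, p_true)
        assert len(dr) + len(jr) >= 8
        sol = fit_populations(dr, jr, mixed_pool_obs, seed=1234)
        assert np.abs(sol.populations.to_numpy() - p_true).max() <= 1e-3
        assert sol.sse <= 1e-8

    def test_single_conformer_pool(self, mixed_pool_obs):
        dist = mixed_pool_obs.distances.iloc[[0]]
        dih = mixed_pool_obs.dihedrals.iloc[[0]]
        po = PoolObservables(dist, dih)
        dr = [DistanceRestraint(tuple(c.split("/")), v + 0.3,
                                max(0.1 * v, 0.2))
              for c, v in dist.iloc[0].items()]
        sol = fit_populations(dr, [], po)
        assert sol.populations.iloc[0] == pytest.approx(1.0, abs=1e-12)
        direct = sum(((r.r - dist.iloc[0][f"{r.proton_pair[0]}/"
                                          f"{r.proton_pair[1]}"]) /
                      r.tolerance) ** 2 for r in dr)
        assert sol.sse == pytest.approx(direct, rel=1e-9)

    def test_beats_grid_oracle_on_3_subpools(self, mixed_pool_obs):
        """Optimiser SSE <= brute-force 0.02-resolution simplex grid over
        every 3-conformer sub-pool of a 6-conformer pool."""
        po = PoolObservables(mixed_pool_obs.distances.iloc[[0, 1, 2, 5, 6, 7]],
                             mixed_pool_obs.dihedrals.iloc[[0, 1, 2, 5, 6, 7]])
        p_true = np.array([0.5, 0.0, 0.0, 0.3, 0.2, 0.0])
        dr, jr = exact_restraints(po, p_true)
        sol = fit_populations(dr, jr, po, seed=1234)

        r_pow = po.distances.to_numpy() ** -6.0
        jmat = karplus_j(po.dihedrals.to_numpy())
        dobs = np.array([r.r for r in dr])
        dtol = np.array([r.tolerance for r in dr])
        jobs = np.array([r.j for r in jr])
        jtol = np.array([r.tolerance for r in jr])
        grid = simplex_grid(3, 0.02)
        best = np.inf
        for subset in itertools.combinations(range(6), 3):
            pred_r = (grid @ r_pow[list(subset)]) ** (-1 / 6)
            pred_j = grid @ jmat[list(subset)]
            sse = (((dobs - pred_r) / dtol) ** 2).sum(axis=1) + \
                  (((jobs - pred_j) / jtol) ** 2).sum(axis=1)
            best = min(best, float(sse.min()))
        assert sol.sse <= best + 1e-12

    def test_no_restraints_rejected(self, mixed_pool_obs):
        with pytest.raises(ValueError, match="restraint"):
            fit_populations([], [], mixed_pool_obs)


class TestInvariants:
    def test_simplex_and_reorder_invariance(self, mixed_pool_obs):
        p_true = np.zeros(len(mixed_pool_obs))
        p_true[1], p_true[6] = 0.6, 0.4
        dr, jr = exact_restraints(mixed_pool_obs, p_true)
        sol = fit_populations(dr, jr, mixed_pool_obs, seed=7)
        assert sol.populations.sum() == pytest.approx(1.0, abs=1e-8)
        assert (sol.populations >= -1e-12).all()
        # reorder the pool: SSE invariant, populations permute
        perm = np.arange(len(mixed_pool_obs))[::-1]
        po2 = PoolObservables(mixed_pool_obs.distances.iloc[perm],
                              mixed_pool_obs.dihedrals.iloc[perm])
        sol2 = fit_populations(dr, jr, po2, seed=7)
        assert sol2.sse == pytest.approx(sol.sse, abs=1e-6)
        for cid in sol.populations.index:
            assert sol2.populations[cid] == pytest.approx(
                sol.populations[cid], abs=1e-3)

    def test_duplicate_conformer_never_hurts(self, mixed_pool_obs):
        p_true = np.zeros(len(mixed_pool_obs))
        p_true[0], p_true[5] = 0.7, 0.3
        dr, jr = exact_restraints(mixed_pool_obs, p_true)
        sol = fit_populations(dr, jr, mixed_pool_obs, seed=3)
        dup_d = pd.concat([mixed_pool_obs.distances,
                           mixed_pool_obs.distances.iloc[[0]]
                           .set_axis([999])])
        dup_h = pd.concat([mixed_pool_obs.dihedrals,
                           mixed_pool_obs.dihedrals.iloc[[0]]
                           .set_axis([999])])
        sol_dup = fit_populations(dr, jr, PoolObservables(dup_d, dup_h),
                                  seed=3)
        assert sol_dup.sse <= sol.sse + 1e-9

    def test_folded_share_recovery(self, small_pool, default_cfg):
        """Recovered folded share within 0.05 of the generating share."""
        pool, truth = small_pool
        pairs, _ = default_distance_pairs(default_cfg)
        po = pool_observables(pool, pairs, phi_residues=range(2, 10))
        from hairpinxb.synthetic import pool_truth_populations
        p_true = pool_truth_populations(truth, folded_share=0.5,
                                        n_active=3).to_numpy()
        dr, jr = exact_restraints(po, p_true)
        sol = fit_populations(dr, jr, po, seed=1234)
        share = sol.folded_share(truth["folded"])
        assert abs(share - 0.5) <= 0.05


class TestJackknife:
    def test_consistent_data_is_stable_and_deterministic(self, mixed_pool_obs):
        p_true = np.zeros(len(mixed_pool_obs))
        p_true[0], p_true[5] = 0.7, 0.3
        dr, jr = exact_restraints(mixed_pool_obs, p_true)
        out1 = jackknife_stability(dr, jr, mixed_pool_obs, fraction=0.2,
                                   n_reps=8, seed=11)
        out2 = jackknife_stability(dr, jr, mixed_pool_obs, fraction=0.2,
                                   n_reps=8, seed=11)
        pd.testing.assert_frame_equal(out1, out2)
        assert (out1["iqr"] < 0.02).all()

    def test_zero_fraction_matches_full_fit(self, mixed_pool_obs):
        p_true = np.zeros(len(mixed_pool_obs))
        p_true[2], p_true[7] = 0.5, 0.5
        dr, jr = exact_restraints(mixed_pool_obs, p_true)
        full = fit_populations(dr, jr, mixed_pool_obs, seed=11)
        out = jackknife_stability(dr, jr, mixed_pool_obs, fraction=0.0,
                                  n_reps=3, seed=11)
        assert np.allclose(out["median"], full.populations, atol=1e-9)
        assert np.allclose(out["iqr"], 0.0, atol=1e-12)

    def test_nreps_validation(self, mixed_pool_obs):
        dr = [DistanceRestraint(("HA1", "H2"), 3.0, 0.3)]
        with pytest.raises(ValueError, match="n_reps"):
            jackknife_stability(dr, [], mixed_pool_obs, n_reps=1)
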