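"""Ordination and permutational inference against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from phyllotraj import (
    DistanceMatrix,
    dispersion_homogeneity,
    mantel,
    nmds,
    pcoa,
    permanova,
    shepard,
)
from phyllotraj.table import TableError


def euclid_dm(points):
    points = np.asarray(points, dtype=float)
    d = squareform(pdist(points))
    return DistanceMatrix(d, [f"s{i}" for i in range(len(points))], "euclidean")


class TestPcoa:
    def test_points_on_a_line_recovered(self):
        pts = np.array([[0.0], [1.0], [2.5], [4.0]])
        d = euclid_dm(pts)
        ord_ = pcoa(d, k=2)
        x = ord_.coordinates.to_numpy()[:, 0]
        # axis 1 is the line up to sign/shift
        gaps = np.diff(np.sort(x))
        np.testing.assert_allclose(sorted(gaps), sorted(np.diff(pts[:, 0])),
                                   atol=1e-8)
        assert abs(ord_.eigenvalues[1]) < 1e-8 * ord_.eigenvalues[0]

    def test_square_has_two_equal_eigenvalues(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1]]
        ord_ = pcoa(euclid_dm(pts), k=2)
        w = ord_.eigenvalues
        # centered squared distances of the unit square give twin eigenvalue 1
        assert w[0] == pytest.approx(w[1], rel=1e-10)
        assert w[0] == pytest.approx(1.0, rel=1e-10)

    def test_duplicate_samples_coincide(self):
        pts = [[0, 0], [0, 0], [3, 4]]
        ord_ = pcoa(euclid_dm(pts), k=1)
        c = ord_.coordinates.to_numpy()
        np.testing.assert_allclose(c[0], c[1], atol=1e-10)

    def test_matches_skbio(self, clean_table):
        import skbio

        from phyllotraj import bray_curtis, hellinger_transform

        d = bray_curtis(hellinger_transform(clean_table))
        mine = pcoa(d, k=3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, d.ids))
        np.testing.assert_allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-6)


class TestNmds:
    def test_exact_two_dimensional_input(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        ord_ = nmds(euclid_dm(pts), k=2, seed=1, n_restarts=2)
        assert ord_.stress < 0.01

    def test_full_dimensional_embedding_is_stressless(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 5))
        ord_ = nmds(euclid_dm(pts), k=5, seed=1, n_restarts=2)
        assert ord_.stress < 1e-3

    def test_monotone_distortion_preserves_rank_order(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts)) ** (1 / 3)  # cube root: monotone distortion
        dm = DistanceMatrix(d, [f"s{i}" for i in range(6)])
        ord_ = nmds(dm, k=2, seed=3, n_restarts=10, max_iter=1000)
        rec = pdist(ord_.coordinates.to_numpy())
        orig = squareform(d)
        # rank order preserved: recovered distances nondecreasing in the
        # input-dissimilarity order (weak monotone fit allows exact ties)
        ordered = rec[np.argsort(orig)]
        assert (np.diff(ordered) > -1e-6 * ordered.max()).all()
        assert ord_.stress < 0.01

    def test_reported_stress_matches_recomputation(self, clean_table):
        from phyllotraj import bray_curtis, hellinger_transform
        from phyllotraj.ordination import _config_dist, _monotone_fit, _stress1, _tri

        d = bray_curtis(hellinger_transform(clean_table))
        ord_ = nmds(d, k=2, seed=5, n_restarts=2)
        conf = _config_dist(ord_.coordinates.to_numpy())
        recomputed = _stress1(conf, _monotone_fit(_tri(d.values), conf))
        assert ord_.stress == pytest.approx(recomputed, abs=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(TableError):
            nmds(euclid_dm([[0, 0], [1, 1]]), k=2)


class TestShepard:
    def test_perfect_fit(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 2], [3, 1]])
        d = euclid_dm(pts)
        ord_ = nmds(d, k=2, seed=1, n_restarts=2)
        tab = shepard(d, ord_)
        np.testing.assert_allclose(tab["fitted"], tab["distance"], atol=1e-4)

    def test_stress_from_triples(self, clean_table):
        from phyllotraj import bray_curtis, hellinger_transform

        d = bray_curtis(hellinger_transform(clean_table))
        ord_ = nmds(d, k=2, seed=5, n_restarts=2)
        tab = shepard(d, ord_)
        stress = np.sqrt(((tab["distance"] - tab["fitted"]) ** 2).sum()
                         / (tab["distance"] ** 2).sum())
        assert stress == pytest.approx(ord_.stress, abs=1e-8)

    def test_matches_isotonic_oracle(self):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3))
        d = euclid_dm(pts)
        noisy = d.values + squareform(
            np.abs(rng.normal(0, 0.05, size=45)))
        np.fill_diagonal(noisy, 0)
        dm = DistanceMatrix((noisy + noisy.T) / 2, d.ids)
        ord_ = nmds(dm, k=2, seed=1, n_restarts=4)
        tab = shepard(dm, ord_)
        iso = IsotonicRegression(increasing=True)
        expected = iso.fit_transform(tab["dissimilarity"], tab["distance"])
        np.testing.assert_allclose(tab["fitted"], expected, atol=1e-10)


def brute_force_permanova(d, meta, terms):
    """Independent sequential-SS oracle building hat matrices explicitly."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j

    def design(term):
        cols = []
        for part in term.split(":"):
            v = meta[part]
            if np.issubdtype(np.asarray(v).dtype, np.number):
                cols.append([np.asarray(v, float)])
            else:
                levels = sorted(set(v))[1:]
                cols.append([np.asarray([x == lv for x in v], float)
                             for lv in levels])
        out = cols[0]
        for block in cols[1:]:
            out = [a_ * b_ for a_ in out for b_ in block]
        return np.column_stack(out)

    def hat(m):
        return m @ np.linalg.pinv(m.T @ m) @ m.T

    m = np.ones((n, 1))
    prev_hat, prev_rank = hat(m), 1
    rows = []
    for t in terms:
        m = np.hstack([m, design(t)])
        h = hat(m)
        rank = np.linalg.matrix_rank(m)
        ss = np.trace((h - prev_hat) @ g)
        rows.append((t, rank - prev_rank, ss))
        prev_hat, prev_rank = h, rank
    ss_res = np.trace((np.eye(n) - prev_hat) @ g)
    df_res = n - prev_rank
    out = []
    for t, df, ss in rows:
        out.append((t, df, ss, ss / np.trace(g),
                    (ss / df) / (ss_res / df_res)))
    return out, ss_res, df_res


class TestPermanova:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        pts[3:] += [1.5, 0, 0]
        d = euclid_dm(pts)
        meta = pd.DataFrame({
            "grp": ["a", "a", "a", "b", "b", "b"],
            "x": [0.1, 0.9, 0.4, 0.2, 0.8, 0.3],
        }, index=d.ids)
        return d, meta

    def test_matches_brute_force_oracle(self, toy):
        d, meta = toy
        res = permanova(d, meta, ["grp", "x"], n_perm=9, seed=0)
        oracle, ss_res, df_res = brute_force_permanova(d.values, meta,
                                                       ["grp", "x"])
        for i, (t, df, ss, r2, f) in enumerate(oracle):
            row = res.table.iloc[i]
            assert row["Df"] == df
            assert row["SumOfSqs"] == pytest.approx(ss, abs=1e-10)
            assert row["R2"] == pytest.approx(r2, abs=1e-10)
            assert row["F"] == pytest.approx(f, abs=1e-10)
        assert res.table.iloc[-2]["SumOfSqs"] == pytest.approx(ss_res, abs=1e-10)

    def test_r2_sums_to_one(self, clean_table):
        from phyllotraj import bray_curtis, hellinger_transform

        d = bray_curtis(hellinger_transform(clean_table))
        res = permanova(d, clean_table.sample_meta,
                        ["doy", "subpopulation", "doy:subpopulation"],
                        n_perm=29, seed=1)
        terms = res.table[res.table["term"] != "Total"]
        assert terms["R2"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_skbio_one_way(self, toy):
        from skbio.stats.distance import permanova as sk_permanova
        import skbio

        d, meta = toy
        res = permanova(d, meta, ["grp"], n_perm=99, seed=0)
        ref = sk_permanova(skbio.DistanceMatrix(d.values, d.ids),
                           meta["grp"].to_numpy(), permutations=99)
        assert res.table.loc[0, "F"] == pytest.approx(ref["test statistic"],
                                                      abs=1e-10)

    def test_degenerate_grouping_errors(self, toy):
        d, meta = toy
        meta = meta.assign(ident=[f"u{i}" for i in range(6)])
        with pytest.raises(TableError):
            permanova(d, meta, ["ident"], n_perm=9)
        with pytest.raises(TableError):
            permanova(d, meta.assign(const="z"), ["const"], n_perm=9)

    def test_strata_never_cross_blocks(self):
        from phyllotraj.ordination import _strata_permutation

        rng = np.random.default_rng(0)
        codes = np.repeat(np.arange(10), 2)
        for _ in range(10_000):
            perm = _strata_permutation(rng, codes)
            assert (codes[perm] == codes).all()

    def test_strata_singleton_error(self, toy):
        d, meta = toy
        meta = meta.assign(plant=["p1", "p1", "p2", "p2", "p3", "p4"])
        with pytest.raises(TableError, match="singleton"):
            permanova(d, meta, ["grp"], strata="plant", n_perm=9)

    def test_planted_shift_increases_timepoint_r2(self):
        from phyllotraj import (SimulationConfig, bray_curtis,
                                hellinger_transform, simulate)

        r2 = []
        for shift in (0.0, 0.5, 1.5):
            cfg = SimulationConfig(n_genotypes=10, n_otus=25, n_snps=30,
                                   time_shift=shift, subpop_effect=0.0,
                                   infected_fraction=0.0, seed=13)
            table, _, _ = simulate(cfg)
            real = table.real_samples()
            d = bray_curtis(hellinger_transform(real))
            res = permanova(d, real.sample_meta, ["timepoint"], n_perm=9,
                            seed=0)
            r2.append(res.table.loc[0, "R2"])
        assert r2[0] < r2[1] < r2[2]


class TestDispersion:
    def test_mirror_groups_equal_dispersion(self):
        pts = np.array([[1, 0], [2, 1], [3, -1], [-1, 0], [-2, 1], [-3, -1]],
                       dtype=float)
        d = euclid_dm(pts)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=d.ids)
        res = dispersion_homogeneity(d, groups, n_perm=199, seed=0)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"])
        assert res.p_value > 0.5

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 2))
        b = rng.normal(size=(15, 2)) * 3.0
        d = euclid_dm(np.vstack([a, b]))
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=d.ids)
        res = dispersion_homogeneity(d, groups, n_perm=199, seed=1)
        assert res.p_value < 0.05

    def test_duplicated_point_zero_distance(self):
        pts = np.array([[0, 0], [0, 0], [5, 5], [6, 5]], dtype=float)
        d = euclid_dm(pts)
        groups = pd.Series(["a", "a", "b", "b"], index=d.ids)
        res = dispersion_homogeneity(d, groups, n_perm=19, seed=0)
        assert res.dispersions.iloc[0] == pytest.approx(0.0, abs=1e-10)


class TestMantel:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        d = euclid_dm(pts)
        res = mantel(d, d, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        d1 = euclid_dm(pts)
        v = 2 * d1.values + 1
        np.fill_diagonal(v, 0)
        d2 = DistanceMatrix(v, d1.ids)
        assert mantel(d1, d2, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        v = np.ones((4, 4)) - np.eye(4)
        d = DistanceMatrix(v, list("abcd"))
        with pytest.raises(TableError):
            mantel(d, d, n_perm=9)

    def test_matches_skbio_r(self):
        from skbio.stats.distance import mantel as sk_mantel
        import skbio

        rng = np.random.default_rng(5)
        d1 = euclid_dm(rng.normal(size=(12, 3)))
        d2 = euclid_dm(rng.normal(size=(12, 3)))
        mine = mantel(d1, d2, n_perm=99, seed=0)
        r_ref = sk_mantel(skbio.DistanceMatrix(d1.values, d1.ids),
                          skbio.DistanceMatrix(d2.values, d2.ids),
                          permutations=0)[0]
        assert mine.r == pytest.approx(r_ref, abs=1e-10)
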