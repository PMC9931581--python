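"""Hex regionalization, border field, Ripley's L, diffusion, crowding."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

from eelkit import spatial_stats as st
from eelkit.spatial_stats import _axial_to_xy


def hex_pure_two_domain(k_per_hex=40, n_q=14, n_r=10, spacing=50.0):
    """Molecules exactly at hex centers; gene usage disjoint left vs right.

    Every occupied hex is 100% one domain, so the two domains are exact at
    hex granularity (left genes L0..L4, right genes R0..R4).
    """
    rng = np.random.default_rng(0)
    qs, rs = np.meshgrid(np.arange(n_q), np.arange(n_r))
    q, r = qs.ravel(), rs.ravel()
    x, y = _axial_to_xy(q, r, spacing)
    split = np.median(x)
    rows = []
    for xi, yi in zip(x, y):
        pool = [f"L{i}" for i in range(5)] if xi < split else [f"R{i}" for i in range(5)]
        for g in rng.choice(pool, size=k_per_hex):
            rows.append((g, xi, yi))
    mol = pd.DataFrame(rows, columns=["gene", "x_um", "y_um"])
    return mol, split, spacing


class TestHexbin:
    def test_single_molecule(self):
        mol = pd.DataFrame({"gene": ["g"], "x_um": [10.0], "y_um": [20.0]})
        grid = st.hexbin(mol, 100.0)
        assert grid.n_hexes == 1
        assert grid.counts.to_numpy().sum() == 1

    def test_count_conservation(self, uniform_molecules):
        grid = st.hexbin(uniform_molecules, 50.0)
        assert int(grid.counts.to_numpy().sum()) == len(uniform_molecules)

    def test_uniform_density_matches_hex_area(self, uniform_molecules):
        spacing = 50.0
        grid = st.hexbin(uniform_molecules, spacing)
        lam = len(uniform_molecules) / 1e6  # molecules per um^2
        expected = lam * grid.hex_area_um2()
        # interior hexes only (border hexes are clipped by the window)
        c = grid.centers
        interior = (
            (c["x_um"] > spacing) & (c["x_um"] < 1000 - spacing)
            & (c["y_um"] > spacing) & (c["y_um"] < 1000 - spacing)
        )
        per_hex = grid.counts.loc[interior.to_numpy()].to_numpy().sum(axis=1)
        se = np.sqrt(expected / len(per_hex))
        assert abs(per_hex.mean() - expected) < 2 * se

    def test_adjacency_symmetric_max_six(self, uniform_molecules):
        grid = st.hexbin(uniform_molecules, 50.0)
        adj = grid.adjacency
        assert (adj != adj.T).nnz == 0
        assert adj.sum(axis=1).max() <= 6

    def test_bad_spacing(self, uniform_molecules):
        with pytest.raises(ValueError):
            st.hexbin(uniform_molecules, 0.0)


class TestRegionalize:
    def test_two_disjoint_domains_recovered_exactly(self):
        mol, split, spacing = hex_pure_two_domain()
        grid = st.hexbin(mol, spacing)
        out = st.regionalize(grid, n_regions=2, n_components=5)
        truth = (grid.centers["x_um"] < split).astype(int)
        assert adjusted_rand_score(truth, out.region_labels) == 1.0

    def test_lda_reduction_also_separates(self):
        mol, split, spacing = hex_pure_two_domain()
        grid = st.hexbin(mol, spacing)
        out = st.regionalize(grid, n_regions=2, n_components=4, reduction="lda")
        truth = (grid.centers["x_um"] < split).astype(int)
        assert adjusted_rand_score(truth, out.region_labels) == 1.0

    def test_single_region(self, uniform_molecules):
        grid = st.hexbin(uniform_molecules, 100.0)
        out = st.regionalize(grid, n_regions=1)
        assert set(out.region_labels) == {0}

    def test_regions_are_connected_subgraphs(self, uniform_molecules):
        grid = st.hexbin(uniform_molecules, 50.0)
        out = st.regionalize(grid, n_regions=6)
        for lab in np.unique(out.region_labels):
            mask = out.region_labels == lab
            sub = grid.adjacency[mask][:, mask]
            n_comp = sparse.csgraph.connected_components(sub, directed=False)[0]
            assert n_comp == 1

    def test_too_many_regions(self, uniform_molecules):
        grid = st.hexbin(uniform_molecules, 200.0)
        with pytest.raises(ValueError):
            st.regionalize(grid, n_regions=grid.n_hexes + 1)


class TestMixColors:
    def test_pure_hexes_get_their_region_color(self):
        mol, _, spacing = hex_pure_two_domain()
        grid = st.regionalize(st.hexbin(mol, spacing), 2, n_components=5)
        mixed = st.mix_region_colors(grid, seed=0)
        colors = np.array([grid.region_colors[lab] for lab in grid.region_labels])
        # perfectly separable domains: the classifier is certain everywhere
        assert np.abs(mixed - colors).max() < 0.05

    def test_gradient_mixes_monotonically(self):
        # two pure domains joined by a linear transition ramp: the binned
        # mixed color must interpolate monotonically from one region color
        # to the other along the gradient axis
        rng = np.random.default_rng(1)
        n = 60000
        x = rng.uniform(0, 1200, n)
        y = rng.uniform(0, 300, n)
        p_b = np.clip((x - 400) / 400, 0, 1)
        gene = np.where(rng.uniform(size=n) < p_b, "B", "A")
        grid = st.hexbin(pd.DataFrame({"gene": gene, "x_um": x, "y_um": y}), 60.0)
        grid = st.regionalize(grid, 2, n_components=2)
        mixed = st.mix_region_colors(grid, seed=0)
        # orient along the channel that differs most between the two regions
        ca, cb = (np.array(grid.region_colors[k]) for k in (0, 1))
        ch = int(np.argmax(np.abs(ca - cb)))
        df = pd.DataFrame({"x": grid.centers["x_um"].to_numpy(), "m": mixed[:, ch]})
        binned = df.groupby(pd.cut(df["x"], 12), observed=True)["m"].mean().to_numpy()
        if binned[0] > binned[-1]:
            binned = binned[::-1]
        assert (np.diff(binned) >= -0.02).all()
        lo, hi = sorted([ca[ch], cb[ch]])
        assert binned[0] == pytest.approx(lo, abs=0.05)
        assert binned[-1] == pytest.approx(hi, abs=0.05)

    def test_single_class_warns_flat(self):
        mol = pd.DataFrame(
            {"gene": ["g1", "g2"] * 50,
             "x_um": np.linspace(0, 50, 100), "y_um": 0.0}
        )
        grid = st.hexbin(mol, 100.0)
        grid = st.regionalize(grid, 1)
        with pytest.warns(UserWarning):
            mixed = st.mix_region_colors(grid)
        assert np.ptp(mixed, axis=0).max() == 0.0


class TestBorderField:
    @staticmethod
    def two_domain_molecules(seed=0, n=30000, boundary=500.0, rot_deg=0.0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1000, n)
        y = rng.uniform(0, 1000, n)
        gene = np.where(
            x < boundary,
            rng.choice([f"L{i}" for i in range(5)], n),
            rng.choice([f"R{i}" for i in range(5)], n),
        )
        mol = pd.DataFrame({"gene": gene, "x_um": x, "y_um": y})
        if rot_deg:
            th = np.radians(rot_deg)
            cx, cy = 500.0, 500.0
            dx, dy = mol["x_um"] - cx, mol["y_um"] - cy
            mol["x_um"] = cx + np.cos(th) * dx - np.sin(th) * dy
            mol["y_um"] = cy + np.sin(th) * dx + np.cos(th) * dy
        return mol

    @staticmethod
    def interior(bf, radius=200.0, extent=1000.0):
        # clipped disks at the window edge imbalance the halves by area
        # alone, so edge comparisons are made on interior grid points only
        keep = (
            (bf["x_um"] >= radius) & (bf["x_um"] <= extent - radius)
            & (bf["y_um"] >= radius) & (bf["y_um"] <= extent - radius)
        )
        return bf[keep]

    def test_boundary_maximum_and_vertical_angle(self):
        mol = self.two_domain_molecules()
        bf = self.interior(st.border_field(mol, 100.0, radius_um=200.0, n_angles=12))
        peak = bf.loc[bf["strength"].idxmax()]
        assert abs(peak["x_um"] - 500.0) <= 100.0
        assert peak["angle_deg"] == pytest.approx(90.0)
        # boundary column is much stronger than deep-domain points
        far = bf[(bf["x_um"] < 250) | (bf["x_um"] > 750)]["strength"].max()
        assert peak["strength"] > 3 * far

    def test_translation_invariance(self):
        mol = self.two_domain_molecules()
        bf0 = st.border_field(mol, 200.0, radius_um=150.0)
        shifted = mol.assign(x_um=mol["x_um"] + 37.0, y_um=mol["y_um"] - 11.0)
        bf1 = st.border_field(shifted, 200.0, radius_um=150.0)
        np.testing.assert_allclose(
            bf0["strength"].to_numpy(), bf1["strength"].to_numpy()
        )
        np.testing.assert_allclose(
            bf0["angle_deg"].to_numpy(), bf1["angle_deg"].to_numpy()
        )

    def test_rotation_shifts_reported_angle(self):
        # rotating the field by one angular step (180/12 = 15 deg) shifts the
        # peak's split-line orientation by the same step
        bf0 = st.border_field(self.two_domain_molecules(), 100.0, radius_um=200.0)
        bf15 = st.border_field(
            self.two_domain_molecules(rot_deg=15.0), 100.0, radius_um=200.0
        )
        a0 = bf0.loc[bf0["strength"].idxmax(), "angle_deg"]
        a15 = bf15.loc[bf15["strength"].idxmax(), "angle_deg"]
        assert (a15 - a0) % 180 == pytest.approx(15.0)

    def test_uniform_field_is_noise_floor(self):
        rng = np.random.default_rng(2)
        n = 30000
        mol = pd.DataFrame(
            {
                "gene": rng.choice(["A", "B"], n),
                "x_um": rng.uniform(0, 1000, n),
                "y_um": rng.uniform(0, 1000, n),
            }
        )
        bf = self.interior(st.border_field(mol, 100.0, radius_um=200.0))
        # permutation baseline: shuffling gene labels of the two-domain data
        # destroys the border and leaves only count noise
        two = self.two_domain_molecules()
        two_dom = self.interior(st.border_field(two, 100.0, radius_um=200.0))
        shuffled = two.assign(gene=rng.permutation(two["gene"].to_numpy()))
        baseline = self.interior(st.border_field(shuffled, 100.0, radius_um=200.0))
        assert bf["strength"].max() < 2 * baseline["strength"].max()
        assert two_dom["strength"].max() > 5 * baseline["strength"].max()

    def test_empty_disk_flagged(self):
        mol = pd.DataFrame(
            {
                "gene": ["A"] * 30 + ["B"] * 30,
                "x_um": np.r_[np.zeros(30), np.full(30, 2000.0)],
                "y_um": np.r_[np.zeros(30), np.full(30, 2000.0)],
            }
        )
        bf = st.border_field(mol, 500.0, radius_um=100.0, min_molecules=10)
        mid = bf[(bf["x_um"] == 1000.0) & (bf["y_um"] == 1000.0)]
        assert bool(mid["low_support"].iloc[0]) and mid["strength"].iloc[0] == 0.0

    def test_needs_two_genes(self):
        mol = pd.DataFrame({"gene": ["A"] * 10, "x_um": np.arange(10.0), "y_um": 0.0})
        with pytest.raises(ValueError):
            st.border_field(mol, 10.0)


class TestRipley:
    def test_two_point_exact_step(self):
        # two interior points at distance d, circles fully inside the window:
        # weights are 1, so K jumps from 0 to area * 2 / n^2 = area/2 at r = d
        extent = (200.0, 200.0)
        pts = np.array([[100.0, 100.0], [110.0, 100.0]])
        radii = np.array([5.0, 9.9, 10.0, 20.0])
        out = st.ripley_l(pts, radii, extent)
        area = 200.0 * 200.0
        np.testing.assert_allclose(out["K"], [0.0, 0.0, area / 2, area / 2])

    def test_csr_within_monte_carlo_envelope(self):
        extent = (500.0, 500.0)
        radii = np.linspace(2, 50, 15)
        n = 1500
        rng = np.random.default_rng(3)
        obs = st.ripley_l(rng.uniform(0, 500, (n, 2)), radii, extent)
        sims = np.array(
            [
                st.ripley_l(rng.uniform(0, 500, (n, 2)), radii, extent)["L_minus_r"]
                for _ in range(39)
            ]
        )
        lo, hi = sims.min(axis=0), sims.max(axis=0)
        assert ((obs["L_minus_r"] >= lo) & (obs["L_minus_r"] <= hi)).all()

    def test_cell_scale_clustering_peaks_near_cluster_size(self):
        # molecules grouped in 5-um-radius disks: L(r)-r peaks near the
        # ~10-um cluster diameter, the typical cell size
        rng = np.random.default_rng(4)
        centers = rng.uniform(50, 450, size=(60, 2))
        pts = np.vstack(
            [
                c
                + np.column_stack(
                    [
                        5.0 * np.sqrt(rng.uniform(size=40)) * np.cos(t := rng.uniform(0, 2 * np.pi, 40)),
                        5.0 * np.sqrt(rng.uniform(size=40)) * np.sin(t),
                    ]
                )
                for c in centers
            ]
        )
        radii = np.linspace(1, 60, 60)
        out = st.ripley_l(pts, radii, (500.0, 500.0))
        peak_r = out.loc[out["L_minus_r"].idxmax(), "r"]
        assert 5.0 <= peak_r <= 20.0

    def test_toroidal_csr(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 300, (2000, 2))
        radii = np.linspace(5, 40, 8)
        out = st.ripley_l(pts, radii, (300.0, 300.0), correction="toroidal")
        assert np.abs(out["L_minus_r"]).max() < 1.5

    def test_radius_bound_enforced(self):
        with pytest.raises(ValueError):
            st.ripley_l(np.zeros((3, 2)), np.array([200.0]), (300.0, 300.0))


class TestDiffusionProfile:
    def test_rayleigh_median_recovered(self):
        rng = np.random.default_rng(6)
        sigma = 3.0
        # cells on a grid so DBSCAN cannot merge neighbors
        gx, gy = np.meshgrid(np.arange(8), np.arange(5))
        centers = np.column_stack([100.0 + 120.0 * gx.ravel(), 100.0 + 120.0 * gy.ravel()])
        pts = np.vstack([c + rng.normal(0, sigma, (120, 2)) for c in centers])
        mol = pd.DataFrame({"gene": "Vip", "x_um": pts[:, 0], "y_um": pts[:, 1]})
        prof = st.diffusion_profile(mol, "Vip", dbscan_eps=5.0, dbscan_min_samples=10)
        assert prof["n_cells"] == 40
        expected = sigma * np.sqrt(2 * np.log(2))
        assert prof["median_radius_um"] == pytest.approx(expected, rel=0.05)

    def test_two_separated_cells(self):
        mol = pd.DataFrame(
            {
                "gene": "Vip",
                "x_um": np.r_[np.random.default_rng(0).normal(10, 0.5, 20),
                              np.random.default_rng(1).normal(500, 0.5, 20)],
                "y_um": 0.0,
            }
        )
        prof = st.diffusion_profile(mol, "Vip", dbscan_eps=5.0, dbscan_min_samples=5)
        assert prof["n_cells"] == 2

    def test_single_point_cluster_zero_distance(self):
        mol = pd.DataFrame({"gene": "Vip", "x_um": [5.0], "y_um": [5.0]})
        prof = st.diffusion_profile(mol, "Vip", dbscan_eps=1.0, dbscan_min_samples=1)
        assert prof["median_radius_um"] == 0.0

    def test_missing_marker(self):
        mol = pd.DataFrame({"gene": ["A"], "x_um": [0.0], "y_um": [0.0]})
        with pytest.raises(ValueError):
            st.diffusion_profile(mol, "Vip")


class TestOpticalCrowding:
    def test_single_point_always_resolvable(self):
        out = st.optical_crowding(np.array([1]), n_rep=5, seed=0)
        assert out["fraction_resolvable"].iloc[0] == 1.0

    def test_monotone_non_increasing(self):
        out = st.optical_crowding(np.array([1, 50, 150, 400]), n_rep=60, seed=1)
        f = out["fraction_resolvable"].to_numpy()
        assert (np.diff(f) <= 1e-9).all()

    def test_matches_poisson_void_probability(self):
        # sparse limit: P(resolvable) ~ exp(-n pi d^2 / A), d = lambda/(2 NA)
        n = 100
        out = st.optical_crowding(np.array([n]), 660.0, 1.4, n_rep=400, seed=2)
        d = 660.0 / (2 * 1.4) / 1000.0
        analytic = np.exp(-n * np.pi * d**2 / 100.0)
        assert out["fraction_resolvable"].iloc[0] == pytest.approx(analytic, rel=0.02)


class TestLinkRegions:
    def make_grid(self, profiles, seed=0):
        """Tiny grid with one region per profile row."""
        rng = np.random.default_rng(seed)
        genes = list(profiles.columns)
        rows = []
        for k, (_, prof) in enumerate(profiles.iterrows()):
            for g, lam in prof.items():
                for _ in range(rng.poisson(lam * 30)):
                    rows.append((g, 200.0 * k + rng.uniform(0, 50), rng.uniform(0, 50)))
        mol = pd.DataFrame(rows, columns=["gene", "x_um", "y_um"])
        grid = st.hexbin(mol, 60.0)
        # label hexes by x position band
        grid.region_labels = (grid.centers["x_um"] // 200.0).astype(int).to_numpy()
        return grid

    def test_identical_profiles_match_perfectly(self):
        profiles = pd.DataFrame(
            [[10, 1, 1], [1, 10, 1], [1, 1, 10]], columns=["a", "b", "c"]
        )
        ga = self.make_grid(profiles, seed=0)
        gb = self.make_grid(profiles, seed=1)
        out = st.link_regions(ga, gb, threshold=0.7)
        assert len(out) == 3
        assert (out["region_a"] == out["region_b"]).all()
        assert (out["r"] > 0.9).all()

    def test_anticorrelated_profiles_unmatched(self):
        pa = pd.DataFrame([[20, 1, 1]], columns=["a", "b", "c"])
        pb = pd.DataFrame([[1, 20, 1]], columns=["a", "b", "c"])
        out = st.link_regions(self.make_grid(pa), self.make_grid(pb), threshold=0.7)
        assert len(out) == 0

    def test_gene_name_keyed_join(self):
        profiles = pd.DataFrame([[10, 1, 1], [1, 10, 1]], columns=["a", "b", "c"])
        ga = self.make_grid(profiles, seed=0)
        gb = self.make_grid(profiles[["c", "a", "b"]], seed=1)
        out = st.link_regions(ga, gb, threshold=0.7)
        assert len(out) == 2
        assert (out["region_a"] == out["region_b"]).all()

    def test_no_shared_genes(self):
        pa = pd.DataFrame([[10]], columns=["a"])
        pb = pd.DataFrame([[10]], columns=["z"])
        with pytest.raises(ValueError):
            st.link_regions(self.make_grid(pa), self.make_grid(pb))
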