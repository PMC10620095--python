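import numpy as np
import pandas as pd
import pytest

import loopmap as lm
from loopmap import connectome as con
from loopmap.atlas import AtlasError

from conftest import make_points


def _uniform_points(rng, n, mouse_ids):
    return pd.DataFrame({
        "x_um": rng.uniform(-4000, 4000, n),
        "y_um": rng.uniform(0, 7000, n),
        "z_um": rng.uniform(0, 2500, n),
        "hemisphere": np.where(rng.random(n) < 0.5, "L", "R"),
        "lobule": "A",
        "mouse_id": rng.choice(mouse_ids, n),
    })


class TestNormalizedDensity:
    def test_single_lobule_identity(self, tiny_atlas):
        pts = make_points([(500, 500, 500, "R", "A", 0)] * 7)
        prof = con.normalized_density(pts, tiny_atlas)
        row = prof.per_mouse.set_index("region").loc["A"]
        assert row.fraction == 1.0
        assert row.density == pytest.approx(1.0 / 2000)

    def test_hand_arithmetic_three_lobules(self, tiny_atlas):
        # counts (10, 30, 60) over voxel volumes (2000, 4000, 4000)
        rows = ([(1, 1, 1, "R", "A", 0)] * 10 + [(1, 1500, 1, "R", "B", 0)] * 30
                + [(1, 2500, 1, "R", "C", 0)] * 60)
        prof = con.normalized_density(make_points(rows), tiny_atlas)
        got = prof.per_mouse.set_index("region")
        assert got.loc["A"].fraction == pytest.approx(0.1)
        assert got.loc["B"].fraction == pytest.approx(0.3)
        assert got.loc["C"].fraction == pytest.approx(0.6)
        assert got.loc["A"].density == pytest.approx(5.0e-5)
        assert got.loc["B"].density == pytest.approx(7.5e-5)
        assert got.loc["C"].density == pytest.approx(1.5e-4)

    def test_zero_count_lobule_has_zero_density(self, tiny_atlas):
        prof = con.normalized_density(
            make_points([(1, 1, 1, "R", "A", 0)] * 5), tiny_atlas)
        assert prof.per_mouse.set_index("region").loc["B"].density == 0.0

    def test_fractions_sum_to_one_per_mouse(self, atlas):
        cfg = lm.GenerationConfig(seed=21)
        inputs, _ = lm.gen_anatomy(cfg, atlas, n_mice=5)
        prof = con.normalized_density(inputs, atlas)
        sums = prof.per_mouse.groupby("mouse_id").fraction.sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_unknown_lobule_errors(self, tiny_atlas):
        with pytest.raises(AtlasError):
            con.normalized_density(
                make_points([(1, 1, 1, "R", "Z", 0)]), tiny_atlas)

    def test_single_hemisphere_halves_volume(self, tiny_atlas):
        pts = make_points([(500, 500, 500, "R", "A", 0)] * 4
                          + [(-500, 500, 500, "L", "A", 0)] * 4)
        both = con.normalized_density(pts, tiny_atlas)
        single = con.normalized_density(pts, tiny_atlas,
                                        combine_hemispheres=False)
        assert both.per_mouse.set_index("region").loc["A"].density \
            == pytest.approx(1.0 / 2000)
        assert single.per_mouse.set_index("region").loc["A"].density \
            == pytest.approx(1.0 / 1000)


class TestKDE:
    def test_matches_brute_force_kernel_sum(self, rng):
        pts = _uniform_points(rng, 50, [0])
        w = np.array([20.0, 20.0, 20.0])
        dens = con.kde_map(pts, tuple(w))
        xyz = pts[["x_um", "y_um", "z_um"]].to_numpy()
        norm = (2 * np.pi) ** 1.5 * np.prod(w)
        brute = np.array([
            np.mean(np.exp(-0.5 * np.sum(((xyz - p) / w) ** 2, axis=1)))
            / norm for p in xyz])
        np.testing.assert_allclose(dens, brute, rtol=1e-10)

    def test_symmetric_pair_equal_density(self):
        pts = make_points([(-100, 0, 0, "L", "A", 0), (100, 0, 0, "R", "A", 0)])
        dens = con.kde_map(pts)
        assert dens[0] == pytest.approx(dens[1], rel=1e-12)

    def test_mode_at_single_point(self, rng):
        pts = _uniform_points(rng, 30, [0])
        dens = con.kde_map(pts, (50.0, 50.0, 50.0))
        assert np.all(dens > 0)

    def test_nonpositive_width_rejected(self):
        pts = make_points([(0, 0, 0, "R", "A", 0)])
        with pytest.raises(ValueError):
            con.kde_map(pts, (0.0, 20.0, 20.0))


class TestSublobuleSplit:
    @pytest.mark.parametrize("x_um,lobule,expected", [
        (3500.0, "Crus 1", "lat-Crus 1"),   # 3.5 mm lateral vs 3.2 threshold
        (2000.0, "SIM", "med-SIM"),         # 2.0 mm vs 2.5 threshold
        (-3500.0, "Crus 1", "lat-Crus 1"),  # mediolateral distance is |x|
        (2700.0, "Crus 2", "lat-Crus 2"),   # tie: >= threshold → lateral
        (500.0, "Lob VII", "Lob VII"),      # non-splittable untouched
    ])
    def test_threshold_relabeling(self, atlas, x_um, lobule, expected):
        pts = make_points([(x_um, 1, 1, "R" if x_um >= 0 else "L", lobule, 0)])
        out = con.split_sublobules(pts, atlas)
        assert out.lobule.iloc[0] == expected

    def test_split_partitions_lobule(self, atlas):
        cfg = lm.GenerationConfig(seed=30)
        inputs, _ = lm.gen_anatomy(cfg, atlas, n_mice=3)
        out = con.split_sublobules(inputs, atlas)
        for name in ("SIM", "Crus 1", "Crus 2"):
            n_parent = (inputs.lobule == name).sum()
            n_med = (out.lobule == "med-" + name).sum()
            n_lat = (out.lobule == "lat-" + name).sum()
            assert n_med + n_lat == n_parent


class TestClassification:
    def _profile(self, densities, atlas, regions):
        per_mouse = pd.DataFrame([
            {"mouse_id": 0, "region": r, "count": 1, "fraction": 1,
             "volume_voxels": 1, "density": d}
            for r, d in zip(regions, densities)])
        summary = per_mouse.rename(columns={"density": "mean_density"})[
            ["region", "mean_density"]].assign(sem_density=0.0, n_mice=1)
        return con.ConnectivityProfile(per_mouse, summary, regions, True)

    def test_four_outcomes(self, tiny_atlas):
        regions = ["A", "B", "C"]
        pin = self._profile([5e-11, 5e-11, 0.0], tiny_atlas, regions)
        pout = self._profile([3e-11, 0.0, 0.0], tiny_atlas, regions)
        cls = con.classify_regions(pin, pout, 1e-11)
        assert cls.groups == {"A": "conjunction", "B": "input-dominant",
                              "C": "excluded"}

    def test_monotone_in_input_density(self, tiny_atlas):
        regions = ["A"]
        pout = self._profile([5e-11], tiny_atlas, regions)
        order = []
        for din in (0.0, 2e-11, 5e-11):
            cls = con.classify_regions(
                self._profile([din], tiny_atlas, regions), pout, 1e-11)
            order.append(cls.groups["A"])
        assert order == ["output-dominant", "conjunction", "conjunction"]

    def test_mismatched_region_sets_error(self, tiny_atlas):
        pin = self._profile([1e-10], tiny_atlas, ["A"])
        pout = self._profile([1e-10], tiny_atlas, ["B"])
        with pytest.raises(AtlasError):
            con.classify_regions(pin, pout)


class TestVoxelize:
    def test_empty_cloud(self):
        grid = con.voxelize(pd.DataFrame(columns=["x_um", "y_um", "z_um"]),
                            pd.DataFrame(columns=["x_um", "y_um", "z_um"]))
        assert len(grid.table) == 0

    def test_binning_convention(self):
        pts = make_points([(50, 50, 50, "R", "A", 0)])
        grid = con.voxelize(pts, pts.iloc[:0], edge_um=100.0)
        assert tuple(grid.table.iloc[0][["ix", "iy", "iz"]]) == (0, 0, 0)

    def test_counts_match_brute_force(self, rng):
        pts = _uniform_points(rng, 1000, [0])
        grid = con.voxelize(pts, pts.iloc[:0], edge_um=100.0)
        # brute force: floor-div every point individually
        brute = {}
        for _, p in pts.iterrows():
            key = tuple(int(np.floor(p[c] / 100.0))
                        for c in ("x_um", "y_um", "z_um"))
            brute[key] = brute.get(key, 0) + 1
        got = {tuple(r[["ix", "iy", "iz"]]): r.input_count
               for _, r in grid.table.iterrows()}
        assert got == brute
        assert grid.table.input_count.sum() == 1000  # conservation
        assert grid.table.input_norm.sum() == pytest.approx(1.0)


class TestConnectivityActivityModel:
    def _grid(self, seed, mode, n=200, noise=0.05):
        rng = np.random.default_rng(seed)
        i = rng.lognormal(0, 1, n)
        o = rng.lognormal(0, 1, n)
        i, o = i / i.sum(), o / o.sum()
        act = {"product": i * o, "input": i,
               "null": np.zeros(n)}[mode]
        act = act / (act.std() or 1.0)
        tab = pd.DataFrame({
            "ix": range(n), "iy": 0, "iz": 0,
            "input_count": 1, "output_count": 1,
            "input_norm": i, "output_norm": o, "n_units": 5,
            "frac_selective": act + rng.normal(0, noise, n),
            "mean_amplitude_hz": act + rng.normal(0, noise, n)})
        return con.VoxelGrid(100.0, tab)

    def test_product_structure_recovered(self):
        mc = con.connectivity_activity_model(self._grid(0, "product"), seed=0)
        assert mc.winner["frac_selective"] == "product"
        assert mc.winner["mean_amplitude_hz"] == "product"

    def test_null_activity_near_zero_r2(self):
        mc = con.connectivity_activity_model(
            self._grid(1, "null", n=500, noise=1.0), seed=1)
        for d in mc.r2.values():
            for v in d.values():
                assert v <= 0.05

    def test_input_beats_output_when_input_generates(self):
        mc = con.connectivity_activity_model(self._grid(2, "input"), seed=2)
        r = mc.r2["frac_selective"]
        assert r["input"] > r["output"]

    def test_degenerate_predictor_reported_nan(self):
        grid = self._grid(3, "null")
        grid.table["output_norm"] = 0.5
        mc = con.connectivity_activity_model(grid, seed=3)
        assert np.isnan(mc.r2["frac_selective"]["output"])

    def test_too_few_voxels_errors(self):
        grid = self._grid(4, "null", n=200)
        grid.table["n_units"] = 0
        with pytest.raises(ValueError):
            con.connectivity_activity_model(grid)
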