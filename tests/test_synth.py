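"""Array geometry, planted-model sampling, and 10x-style export round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from stniche.io import load_tenx
from stniche.synth import (
    ArraySpec,
    CellTypeProfile,
    GradientGene,
    GroundTruth,
    HotspotRegion,
    banded_proportions,
    constant_proportions,
    demo_tissue,
    disc_region,
    export_tenx,
    load_ground_truth,
    make_array,
    simulate_tissue,
)


def nearest_neighbor_distances(df):
    D = squareform(pdist(df[["x_um", "y_um"]].to_numpy()))
    np.fill_diagonal(D, np.inf)
    return D.min(axis=1)


class TestMakeArray:
    def test_default_array_matches_published_figures(self, default_array):
        assert len(default_array) == 5000
        nn = nearest_neighbor_distances(default_array)
        assert np.allclose(nn, 100.0, rtol=0, atol=1e-9)
        assert ArraySpec().spot_diameter_um == 55.0

    def test_single_spot_sits_at_area_center(self):
        df = make_array(ArraySpec(n_spots=1))
        assert len(df) == 1
        assert df.loc[0, "x_um"] == pytest.approx(3250.0)
        assert df.loc[0, "y_um"] == pytest.approx(3250.0)

    def test_square_3x3_all_neighbor_distances_exact(self):
        # oracle: brute-force all-pairs distances
        df = make_array(ArraySpec(n_spots=9), layout="square")
        d = pdist(df[["x_um", "y_um"]].to_numpy())
        assert sorted(set(np.round(d, 9))) == sorted(
            {100.0, 200.0, np.round(np.hypot(100, 100), 9),
             np.round(np.hypot(100, 200), 9), np.round(np.hypot(200, 200), 9)}
        )
        assert np.all(nearest_neighbor_distances(df) == 100.0)

    @pytest.mark.parametrize("layout", ["hex", "square"])
    def test_deterministic_and_within_tolerated_frame(self, layout):
        spec = ArraySpec(width_um=1000, height_um=1000, n_spots=80)
        a, b = make_array(spec, layout), make_array(spec, layout)
        pd.testing.assert_frame_equal(a, b)
        pitch = spec.center_spacing_um
        assert a["x_um"].between(0, spec.width_um + pitch).all()
        assert a["y_um"].between(0, spec.height_um + pitch).all()

    def test_infeasible_request_names_maximum(self):
        with pytest.raises(ValueError, match="maximum feasible count"):
            make_array(ArraySpec(width_um=300, height_um=300, n_spots=500))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ArraySpec(n_spots=0).validate()
        with pytest.raises(ValueError):
            ArraySpec(spot_diameter_um=120.0).validate()


class TestSimulateTissue:
    def setup_method(self):
        self.coords = make_array(
            ArraySpec(width_um=1500, height_um=1500, n_spots=200)
        )
        self.gene_ids = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        self.profile = CellTypeProfile("tissue", rng.gamma(4.0, 1.0, 30))

    def test_full_dropout_gives_all_zero_counts(self):
        truth = GroundTruth(
            constant_proportions(200, [1.0]), ("tissue",), dropout_rate=1.0
        )
        ds, _ = simulate_tissue(self.coords, truth, [self.profile], self.gene_ids, 1)
        assert ds.counts.nnz == 0

    def test_law_of_large_numbers_recovers_profile_means(self):
        # oracle: per-gene mean count converges to the profile mean
        coords = make_array(ArraySpec(n_spots=5000))
        truth = GroundTruth(constant_proportions(5000, [1.0]), ("tissue",))
        ds, _ = simulate_tissue(coords, truth, [self.profile], self.gene_ids, 2)
        observed = np.asarray(ds.counts.mean(axis=1)).ravel()
        mc_se = np.sqrt(self.profile.gene_means / 5000)
        assert np.all(np.abs(observed - self.profile.gene_means) < 3 * mc_se)

    def test_planted_hotspot_elevates_in_region_means(self):
        region = disc_region(self.coords, (750.0, 750.0), 20)
        genes = tuple(self.gene_ids[:5])
        truth = GroundTruth(
            constant_proportions(200, [1.0]),
            ("tissue",),
            hotspot_regions=[HotspotRegion("hs", genes, tuple(map(int, region)), 10.0)],
        )
        ds, _ = simulate_tissue(self.coords, truth, [self.profile], self.gene_ids, 3)
        sub = np.asarray(ds.counts[:5].todense())
        inside = sub[:, region].mean()
        outside = np.delete(sub, region, axis=1).mean()
        assert inside > outside

    def test_gradient_gene_decays_with_distance_from_niche(self):
        ref = np.flatnonzero(self.coords["x_um"] <= 300)
        truth = GroundTruth(
            constant_proportions(200, [1.0]),
            ("tissue",),
            gradient_genes=[GradientGene("g0", "left", 2e-3, 20.0)],
            niche_spots={"left": ref},
        )
        ds, _ = simulate_tissue(self.coords, truth, [self.profile], self.gene_ids, 4)
        x = ds.gene_row("g0")
        near = x[self.coords["x_um"] < 600].mean()
        far = x[self.coords["x_um"] > 1000].mean()
        assert near > far

    def test_seed_determinism_and_validation(self):
        truth = GroundTruth(constant_proportions(200, [1.0]), ("tissue",))
        a, _ = simulate_tissue(self.coords, truth, [self.profile], self.gene_ids, 7)
        b, _ = simulate_tissue(self.coords, truth, [self.profile], self.gene_ids, 7)
        assert (a.counts != b.counts).nnz == 0
        with pytest.raises(ValueError, match="at least one"):
            simulate_tissue(self.coords, truth, [], self.gene_ids, 7)
        bad = GroundTruth(
            constant_proportions(200, [1.0]), ("tissue",), dropout_rate=1.5
        )
        with pytest.raises(ValueError, match="dropout"):
            simulate_tissue(self.coords, bad, [self.profile], self.gene_ids, 7)

    def test_proportion_rows_must_sum_to_one(self):
        props = constant_proportions(200, [1.0]) * 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            GroundTruth(props, ("tissue",)).validate()


class TestExportRoundTrip:
    def make_toy(self, n_spots=3, seed=5):
        coords = make_array(ArraySpec(width_um=400, height_um=400, n_spots=n_spots))
        gene_ids = ["gA", "gB", "gC", "gZero"]
        profile = CellTypeProfile("t", np.array([5.0, 2.0, 1.0, 0.0]))
        truth = GroundTruth(constant_proportions(n_spots, [1.0]), ("t",))
        ds, _ = simulate_tissue(coords, truth, [profile], gene_ids, seed)
        return ds, truth

    def test_round_trip_counts_ids_coords_exact(self, tmp_path):
        ds, truth = self.make_toy(n_spots=12)
        export_tenx(ds, truth, tmp_path)
        back = load_tenx(tmp_path)
        assert (back.counts != ds.counts).nnz == 0
        assert back.gene_ids == ds.gene_ids
        assert back.spot_ids == ds.spot_ids
        assert np.array_equal(
            back.coords[["x_um", "y_um"]].to_numpy(),
            ds.coords[["x_um", "y_um"]].to_numpy(),
        )
        rt = load_ground_truth(tmp_path / "ground_truth.json")
        assert np.allclose(rt.spot_cell_proportions, truth.spot_cell_proportions)

    def test_zero_count_gene_survives_round_trip(self, tmp_path):
        ds, truth = self.make_toy()
        export_tenx(ds, truth, tmp_path)
        back = load_tenx(tmp_path)
        assert "gZero" in back.gene_ids
        assert back.gene_row("gZero").sum() == 0

    def test_positions_csv_has_one_row_per_spot(self, tmp_path):
        ds, truth = self.make_toy(n_spots=3)
        export_tenx(ds, truth, tmp_path)
        lines = (tmp_path / "tissue_positions.csv").read_text().splitlines()
        data = [ln for ln in lines if not ln.startswith("#")]
        assert len(data) == 1 + 3  # header + rows

    def test_same_seed_byte_identical_exports(self, tmp_path):
        for sub in ("a", "b"):
            ds, truth = self.make_toy(seed=9)
            export_tenx(ds, truth, tmp_path / sub)
        for name in (
            "matrix.mtx",
            "barcodes.tsv.gz",
            "features.tsv.gz",
            "tissue_positions.csv",
            "ground_truth.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name


class TestBuilders:
    def test_banded_proportions_partition_and_purity(self, default_array):
        props, band = banded_proportions(default_array, 3, purity=0.9)
        assert np.allclose(props.sum(axis=1), 1.0)
        assert np.all(props[np.arange(len(band)), band] == 0.9)
        assert set(band) == {0, 1, 2}

    def test_demo_tissue_is_seed_deterministic(self):
        a, ta, _, _ = demo_tissue(seed=3)
        b, tb, _, _ = demo_tissue(seed=3)
        assert (a.counts != b.counts).nnz == 0
        assert [h.spots for h in ta.hotspot_regions] == [
            h.spots for h in tb.hotspot_regions
        ]
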