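"""Generator contracts: determinism, planted structure, placement rules."""

import numpy as np
import pandas as pd
import pytest

from frcscape.exceptions import ParameterError, PlacementError
from frcscape.synthetic import (
    CohortConfig,
    NetworkParams,
    PHENOTYPE_NAMES,
    TFEArchetype,
    default_tfe_archetypes,
    draw_survival,
    generate_cohort,
    generate_frc_network,
    generate_sample_image,
    place_cells,
)


class TestNetworkGeneration:
    def test_zero_density_yields_empty_field(self):
        raster, truth = generate_frc_network(
            NetworkParams(field_size_px=(64, 64), fiber_density=0.0, seed=1)
        )
        assert not raster.any()
        assert truth.n_branches == 0
        assert truth.total_length_um == 0.0

    def test_same_seed_bit_identical(self):
        p = NetworkParams(field_size_px=(128, 128), seed=42)
        r1, t1 = generate_frc_network(p)
        r2, t2 = generate_frc_network(p)
        assert np.array_equal(r1, r2)
        assert t1.n_branches == t2.n_branches

    def test_different_seeds_differ(self):
        r1, _ = generate_frc_network(NetworkParams(field_size_px=(128, 128), seed=1))
        r2, _ = generate_frc_network(NetworkParams(field_size_px=(128, 128), seed=2))
        assert not np.array_equal(r1, r2)

    def test_small_field_rejected(self):
        with pytest.raises(ParameterError):
            NetworkParams(field_size_px=(16, 64))

    def test_negative_density_rejected(self):
        with pytest.raises(ParameterError):
            NetworkParams(fiber_density=-1.0)

    def test_truth_totals_consistent(self, network_fixture):
        _, _, truth = network_fixture
        assert truth.n_branches == len(truth.branch_lengths_um)
        assert truth.total_length_um == pytest.approx(sum(truth.branch_lengths_um))


class TestSampleImage:
    def test_no_cells_gives_empty_table(self, archetypes):
        net = NetworkParams(field_size_px=(64, 64), seed=0)
        s = generate_sample_image(net, archetypes["TFE4"], 0, seed=0)
        assert len(s["cell_table"]) == 0
        assert s["label_mask"].max() == 0
        # stroma truth untouched by (absent) cell layer
        assert (s["stroma_truth"] > 0).any()

    def test_channels_match_panel(self, coupled_sample, panel):
        assert coupled_sample["image"].channels.shape[0] == len(panel)

    def test_pdpn_bright_on_network(self, coupled_sample):
        img = coupled_sample["image"]
        frc = coupled_sample["frc_mask"]
        pdpn = img.channel("PDPN")
        assert np.median(pdpn[frc]) > 10 * np.median(pdpn[~frc])

    def test_uncoupled_clearance_enforced_exactly(self, uncoupled_sample):
        """Every CD8 centroid sits >= 12 um from the nearest network pixel
        (brute force over all network pixels)."""
        cells = uncoupled_sample["cell_table"]
        net_px = np.argwhere(uncoupled_sample["frc_mask"])
        cent = cells[["centroid_row", "centroid_col"]].to_numpy()
        d2 = ((cent[:, None, :] - net_px[None, :, :]) ** 2).sum(axis=2)
        assert np.sqrt(d2.min(axis=1)).min() >= 12.0

    def test_coupled_cells_near_network(self, coupled_sample):
        """>= 60% of coupled CD8 centroids fall within 5 um of the network
        (brute-force nearest-pixel distances)."""
        cells = coupled_sample["cell_table"]
        net_px = np.argwhere(coupled_sample["frc_mask"])
        cent = cells[["centroid_row", "centroid_col"]].to_numpy()
        d = np.sqrt(((cent[:, None, :] - net_px[None, :, :]) ** 2).sum(axis=2).min(axis=1))
        assert (d <= 5.0).mean() >= 0.60

    def test_placement_error_when_infeasible(self):
        rng = np.random.default_rng(0)
        dense = np.ones((64, 64), dtype=bool)  # no pixel can clear 12 um
        with pytest.raises(PlacementError):
            place_cells(rng, dense, 5, "uncoupled", 12.0, 1.0, max_retries_factor=10)

    def test_archetype_frequencies_match_weights(self, archetypes):
        """Planted phenotype frequencies at n=2000 stay within 3 binomial sd
        of the archetype weights."""
        net = NetworkParams(field_size_px=(512, 512), seed=7)
        s = generate_sample_image(net, archetypes["TFE3"], 2000, seed=7)
        counts = s["cell_table"]["archetype"].value_counts()
        n = 2000
        for name in PHENOTYPE_NAMES:
            p = archetypes["TFE3"].cd8_cluster_weights[name]
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(name, 0) / n - p) <= 3 * sd

    def test_determinism(self, archetypes):
        net = NetworkParams(field_size_px=(64, 64), seed=3)
        a = generate_sample_image(net, archetypes["TFE2"], 20, seed=9)
        b = generate_sample_image(net, archetypes["TFE2"], 20, seed=9)
        assert np.array_equal(a["image"].channels, b["image"].channels)
        pd.testing.assert_frame_equal(a["cell_table"], b["cell_table"])


class TestArchetypes:
    def test_weights_simplex_enforced(self):
        bad = dict(zip(PHENOTYPE_NAMES, (0.5, 0.5, 0.5, 0.5)))
        with pytest.raises(ParameterError):
            TFEArchetype("TFE1", bad, 0.5, "elongated", "coupled", 0.0, 0.1)

    def test_uncoupled_requires_clearance(self):
        w = dict(zip(PHENOTYPE_NAMES, (0.25, 0.25, 0.25, 0.25)))
        with pytest.raises(ParameterError):
            TFEArchetype("TFE1", w, 0.5, "elongated", "uncoupled", 0.0, 0.1)

    def test_default_library_hazard_ordering(self):
        lib = {a.name: a for a in default_tfe_archetypes()}
        assert lib["TFE1"].hazard_rate / lib["TFE4"].hazard_rate >= 3
        assert (
            lib["TFE1"].hazard_rate
            > max(lib["TFE2"].hazard_rate, lib["TFE3"].hazard_rate)
            > min(lib["TFE2"].hazard_rate, lib["TFE3"].hazard_rate)
            > lib["TFE4"].hazard_rate
        )


class TestCohort:
    def test_round_robin_assignment(self):
        cfg = CohortConfig(n_samples=8, cores_per_sample=1, n_cd8_per_core=30,
                           core_field_px=(64, 64), seed=1)
        bundle = generate_cohort(cfg)
        counts = bundle.truth_archetypes.value_counts()
        assert (counts == 2).all() and len(counts) == 4

    def test_full_censoring_zeroes_events(self):
        cfg = CohortConfig(n_samples=8, cores_per_sample=1, n_cd8_per_core=20,
                           core_field_px=(64, 64), censor_fraction=1.0, seed=1)
        bundle = generate_cohort(cfg)
        assert (bundle.clinical["event"] == 0).all()

    def test_exponential_mean_closed_form(self):
        """10,000 exponential draws at hazard 0.1/month have mean ~10 months
        (within 3%)."""
        rng = np.random.default_rng(5)
        t, e = draw_survival(rng, 0.1, 10_000, censor_fraction=0.0)
        assert t.mean() == pytest.approx(10.0, rel=0.03)
        assert (e == 1).all()

    def test_empty_archetype_library_rejected(self):
        with pytest.raises(ParameterError):
            CohortConfig(archetype_library=())

    def test_cohort_determinism(self):
        cfg = CohortConfig(n_samples=4, cores_per_sample=2, n_cd8_per_core=25,
                           core_field_px=(64, 64), seed=9)
        b1, b2 = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(b1.clinical, b2.clinical)
        pd.testing.assert_frame_equal(b1.pooled_cd8(), b2.pooled_cd8())
        for s1, s2 in zip(b1.samples, b2.samples):
            for c1, c2 in zip(s1.cores, s2.cores):
                assert np.array_equal(c1.network_raster, c2.network_raster)

    def test_survival_median_ordering_across_seeds(self):
        """KM medians order TFE1 < {TFE2, TFE3} < TFE4 in >= 90% of seeds at
        n=50/group with the default hazards and 20% censoring."""
        from frcscape.stats import km_median

        lib = {a.name: a for a in default_tfe_archetypes()}
        ok = 0
        trials = 60
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            med = {}
            for name in ("TFE1", "TFE2", "TFE3", "TFE4"):
                t, e = draw_survival(rng, lib[name].hazard_rate, 50, 0.2)
                med[name] = km_median(t, e)
            if (
                med["TFE1"] < min(med["TFE2"], med["TFE3"])
                and max(med["TFE2"], med["TFE3"]) < med["TFE4"]
            ):
                ok += 1
        assert ok / trials >= 0.90
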