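"""Lifetime-threshold aggregate detection and aggregation metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import flimaggr as fa

from conftest import BIN, REP


def _image(tau_field, photons=1000.0):
    tau = np.asarray(tau_field, dtype=float)
    return fa.LifetimeImage(tau, np.full(tau.shape, photons), 100, REP, pixel_size=0.1)


class TestDetect:
    def test_uniform_native_field_no_particles(self):
        img = _image(np.full((20, 20), 3.3))
        report = fa.detect_aggregates(img, np.ones((20, 20), int))
        assert len(report.particles) == 0
        assert (report.per_cell["aggregate_area_px2"] == 0).all()

    def test_min_area_boundary(self):
        tau = np.full((10, 10), 3.3)
        tau[4, 4:7] = 6.0   # one 3-px component
        img = _image(tau)
        cells = np.ones((10, 10), int)
        rej = fa.detect_aggregates(img, cells, fa.AggregateConfig(min_particle_area=4))
        kept = fa.detect_aggregates(img, cells, fa.AggregateConfig(min_particle_area=1))
        assert len(rej.particles) == 0
        assert len(kept.particles) == 1
        assert kept.particles["area_px2"].iloc[0] == 3

    def test_invalid_pixels_never_aggregate(self):
        tau = np.full((8, 8), 6.0)
        tau[:4] = np.nan
        img = _image(tau)
        report = fa.detect_aggregates(img, np.ones((8, 8), int))
        assert report.aggregate_mask[:4].sum() == 0
        # invalid pixels are excluded from the cell area as well
        assert report.per_cell["cell_area_px2"].iloc[0] == 32

    def test_particle_spanning_two_cells_is_split(self):
        tau = np.full((8, 8), 3.3)
        tau[3:5, 2:6] = 6.0
        cells = np.ones((8, 8), int)
        cells[:, 4:] = 2
        img = _image(tau)
        report = fa.detect_aggregates(img, cells, fa.AggregateConfig(min_particle_area=1))
        assert len(report.particles) == 2
        assert sorted(report.particles["cell_label"]) == [1, 2]
        assert report.particles["area_px2"].sum() == 8

    def test_empty_mask_warns_not_raises(self):
        img = _image(np.full((6, 6), 3.3))
        with pytest.warns(RuntimeWarning):
            report = fa.detect_aggregates(img, np.zeros((6, 6), int))
        assert report.n_cells == 0

    def test_recovery_iou_against_ground_truth(self, high_snr_scene, gaussian_irf):
        spec, stack, truth = high_snr_scene
        img = fa.lifetime_image(stack, gaussian_irf, min_photons=100)
        report = fa.detect_aggregates(img, truth.cell_labels)
        inter = (report.aggregate_mask & truth.aggregate_mask).sum()
        union = (report.aggregate_mask | truth.aggregate_mask).sum()
        assert inter / union > 0.95
        assert len(report.particles) == len(truth.puncta) == 6


class TestProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_precision_and_recall_one_high_snr(self, seed, gaussian_irf):
        """On bright 6 ns puncta over a 3.3 ns background every ground-truth
        punctum is found and nothing else is (20 seeds)."""
        spec = fa.SceneSpec(
            image_size=(96, 96),
            cells=fa.default_cells((96, 96), 3),
            puncta_per_cell=2,
            puncta_tau_range=(6.0, 7.6),
            puncta_radius_range=(3.0, 4.0),
            photons_per_pixel=500.0,
            seed=seed,
        )
        stack, truth = fa.simulate_flim_scene(spec, REP, BIN)
        img = fa.lifetime_image(stack, gaussian_irf, min_photons=100)
        report = fa.detect_aggregates(img, truth.cell_labels)
        from skimage.measure import label as cc_label

        gt = cc_label(truth.aggregate_mask, connectivity=2)
        n_gt = gt.max()
        # recall: every GT punctum overlaps a detection
        hit = {gt[r, c] for r, c in np.argwhere(report.aggregate_mask) if gt[r, c]}
        assert len(hit) == n_gt
        # precision: every detected particle overlaps the GT mask
        det = cc_label(report.aggregate_mask, connectivity=2)
        for pid in range(1, det.max() + 1):
            assert truth.aggregate_mask[det == pid].any()

    def test_particle_area_conservation(self, high_snr_scene, gaussian_irf):
        spec, stack, truth = high_snr_scene
        img = fa.lifetime_image(stack, gaussian_irf)
        report = fa.detect_aggregates(img, truth.cell_labels)
        per_cell_sum = report.particles.groupby("cell_label")["area_px2"].sum()
        for _, row in report.per_cell.iterrows():
            assert per_cell_sum.get(row["label"], 0) == row["aggregate_area_px2"]

    def test_threshold_monotonicity(self, high_snr_scene, gaussian_irf):
        spec, stack, truth = high_snr_scene
        img = fa.lifetime_image(stack, gaussian_irf)
        areas = []
        for thr in (6.5, 5.5, 5.0, 4.5, 4.0):
            rep = fa.detect_aggregates(
                img, truth.cell_labels,
                fa.AggregateConfig(lifetime_threshold=thr, min_particle_area=1),
            )
            areas.append(rep.per_cell["aggregate_area_px2"].sum())
        assert np.all(np.diff(areas) >= 0)

    def test_percent_cells_monotone_in_puncta_per_cell(self, gaussian_irf):
        """Percent of cells with aggregates increases with the seeded puncta
        load (Spearman over 5 levels x 10 seeds)."""
        levels, percents = [], []
        for ppc in range(5):
            for seed in range(10):
                spec = fa.SceneSpec(
                    image_size=(64, 64),
                    cells=fa.default_cells((64, 64), 4),
                    puncta_per_cell=ppc,
                    puncta_tau_range=(6.0, 7.6),
                    puncta_radius_range=(2.0, 3.0),
                    photons_per_pixel=300.0,
                    seed=100 * ppc + seed,
                )
                stack, truth = fa.simulate_flim_scene(spec, REP, BIN)
                img = fa.lifetime_image(stack, gaussian_irf)
                report = fa.detect_aggregates(img, truth.cell_labels)
                summary = fa.summarize_aggregation(report)
                levels.append(ppc)
                percents.append(summary.percent_cells)
        rho, _ = spearmanr(levels, percents)
        assert rho > 0


class TestSummary:
    def _report(self, flags, fractions):
        per_cell = pd.DataFrame(
            {
                "label": np.arange(1, len(flags) + 1),
                "cell_area_px2": np.full(len(flags), 100),
                "aggregate_area_px2": (np.asarray(fractions) * 100).astype(int),
                "particle_count": np.asarray(flags, int),
                "has_aggregate": flags,
            }
        )
        return fa.AggregateReport(
            per_cell=per_cell,
            particles=pd.DataFrame(columns=["cell_label", "particle_id", "area_px2"]),
            aggregate_mask=np.zeros((2, 2), bool),
            config=fa.AggregateConfig(),
            pixel_size=0.1,
        )

    def test_percent_cells(self):
        flags = [True] * 3 + [False] * 7
        s = fa.summarize_aggregation(self._report(flags, [0.0] * 10))
        assert s.percent_cells == pytest.approx(30.0)

    def test_mean_area_fraction(self):
        s = fa.summarize_aggregation(self._report([True] * 5, [0.02] * 5))
        assert s.mean_area_fraction == pytest.approx(0.02)

    def test_adding_clean_cell_lowers_metrics(self):
        base = fa.summarize_aggregation(self._report([True, True], [0.1, 0.1]))
        more = fa.summarize_aggregation(self._report([True, True, False], [0.1, 0.1, 0.0]))
        assert more.percent_cells < base.percent_cells
        assert more.mean_area_fraction < base.mean_area_fraction

    def test_zero_cells_flagged(self):
        with pytest.warns(RuntimeWarning):
            s = fa.summarize_aggregation(self._report([], []))
        assert s.undefined and np.isnan(s.percent_cells)


class TestSizeDistribution:
    def _report_with_areas(self, areas, image_id=""):
        particles = pd.DataFrame(
            {"cell_label": 1, "particle_id": np.arange(1, len(areas) + 1),
             "area_px2": areas}
        )
        return fa.AggregateReport(
            per_cell=pd.DataFrame(columns=["label", "cell_area_px2",
                                           "aggregate_area_px2", "particle_count",
                                           "has_aggregate"]),
            particles=particles,
            aggregate_mask=np.zeros((2, 2), bool),
            config=fa.AggregateConfig(),
            pixel_size=0.1,
            image_id=image_id,
        )

    def test_unit_conversion(self):
        rep = self._report_with_areas([25])
        dist = fa.size_distribution([rep], 0.1, np.array([0.0, 0.2, 0.3, 1.0]))
        # 25 px^2 at 0.1 µm/px = 0.25 µm^2 -> middle bin
        assert dist.iloc[0, 1] == pytest.approx(1.0)

    def test_rows_normalised(self):
        reps = [self._report_with_areas([10, 20, 40]), self._report_with_areas([])]
        dist = fa.size_distribution(reps, 0.1, np.linspace(0, 1, 6))
        assert dist.iloc[0].sum() == pytest.approx(1.0)
        assert dist.iloc[1].sum() == 0.0

    def test_mean_shifts_with_generator_radius(self, gaussian_irf):
        """Scenes seeded with larger puncta give a larger mean particle size."""
        def mean_size(radius_range, seed):
            spec = fa.SceneSpec(
                image_size=(96, 96),
                cells=fa.default_cells((96, 96), 3),
                puncta_per_cell=2,
                puncta_tau_range=(6.0, 7.0),
                puncta_radius_range=radius_range,
                seed=seed,
            )
            stack, truth = fa.simulate_flim_scene(spec, REP, BIN)
            img = fa.lifetime_image(stack, gaussian_irf)
            rep = fa.detect_aggregates(img, truth.cell_labels)
            return rep.particles["area_px2"].mean() * 0.1**2

        small = np.mean([mean_size((2.0, 3.0), s) for s in range(3)])
        large = np.mean([mean_size((4.0, 5.0), s) for s in range(3)])
        assert large > small
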