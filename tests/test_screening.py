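"""Aggregation, ranking, extremes and the bundled reference survey."""

import math
import random

import numpy as np
import pytest

from fabriscope.coverage import FabricMeasurement, porosity
from fabriscope.reference import reference_summaries, reference_table
from fabriscope.screening import (
    FabricSummary,
    MaskRecord,
    extremes,
    rank_fabrics,
    summaries_to_frame,
    summarize_fabric,
)
from fabriscope.pipeline import analyze_image
from fabriscope.synthetic import WeaveParams, generate_weave_image


def _measurement(cover, sizes, region=0, mask_id="MX", layer="L1"):
    return FabricMeasurement(
        cover_factor_pct=cover,
        porosity_pct=porosity(cover),
        n_yarn=int(cover * 100),
        n_total=10000,
        pore_sizes_um=tuple(sizes),
        mask_id=mask_id,
        layer=layer,
        region_index=region,
    )


def _summary(mask_id, pore_mean, cover_mean, layer="L1", mask_type="I"):
    return FabricSummary(
        mask_id=mask_id, layer=layer, pore_size_mean_um=pore_mean,
        pore_size_sd_um=1.0, cover_factor_mean_pct=cover_mean,
        cover_factor_sd_pct=1.0, porosity_mean_pct=100 - cover_mean,
        n_pore=10, n_regions=5, mask_type=mask_type,
    )


class TestMaskRecord:
    def test_type_constraints(self):
        MaskRecord("M1", "I", (("L1", "cotton"), ("L2", "cotton")))
        MaskRecord("M13", "II", (("L1", "cotton"), ("L2", "polyester")))
        with pytest.raises(ValueError):
            MaskRecord("M1", "I", (("L1", "cotton"), ("L2", "polyester")))
        with pytest.raises(ValueError):
            MaskRecord("M13", "II", (("L1", "cotton"), ("L2", "cotton")))


class TestSummarizeFabric:
    def test_identical_pores_have_zero_sd(self):
        s = summarize_fabric([_measurement(85, [100, 100, 100])])
        assert s.pore_size_mean_um == 100.0 and s.pore_size_sd_um == 0.0

    def test_sample_sd_of_two_cover_factors(self):
        ms = [_measurement(80, [50], region=0), _measurement(90, [60], region=1)]
        s = summarize_fabric(ms)
        assert s.cover_factor_mean_pct == pytest.approx(85.0)
        assert s.cover_factor_sd_pct == pytest.approx(math.sqrt(50.0))

    def test_pools_k_largest_across_regions(self):
        ms = [
            _measurement(80, range(100, 110), region=0),  # 100..109
            _measurement(82, range(200, 210), region=1),  # 200..209
        ]
        s = summarize_fabric(ms, k_pores=10)
        assert s.pore_size_mean_um == pytest.approx(np.mean(range(200, 210)))

    def test_cover_uses_first_five_regions(self):
        ms = [_measurement(70 + i, [100], region=i) for i in range(8)]
        s = summarize_fabric(ms, n_regions_for_cover=5)
        assert s.cover_factor_mean_pct == pytest.approx(np.mean([70, 71, 72, 73, 74]))
        assert s.n_regions == 5

    def test_porosity_complements_cover(self):
        s = summarize_fabric([_measurement(83, [120])])
        assert s.porosity_mean_pct == pytest.approx(100 - s.cover_factor_mean_pct)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_fabric([])

    def test_synthetic_regions_recover_true_cover(self):
        # five noisy renderings of one geometry; the 0.6 crop of the
        # 800 px frame spans exactly 8 pitch periods, so no window bias
        params = dict(
            warp_pitch=60, weft_pitch=60, warp_width=30, weft_width=30,
            image_size=(800, 800), noise_sd=5.0, blur_sigma_px=0.8,
        )
        ms = []
        for i in range(5):
            image, truth = generate_weave_image(WeaveParams(**params, seed=i))
            image.mask_id, image.layer, image.region_index = "S1", "L1", i
            ms.append(analyze_image(image))
        s = summarize_fabric(ms)
        assert s.cover_factor_mean_pct == pytest.approx(
            truth.true_cover_factor, abs=2.0
        )


class TestRankFabrics:
    def test_reference_type1_best_and_worst(self):
        report = rank_fabrics(reference_summaries(mask_type="I"))
        assert report.ranked[0].mask_id == "M6"
        assert report.ranked[-1].mask_id == "M10"
        assert report.recommendation == ("M6", "L1")

    def test_single_summary(self):
        report = rank_fabrics([_summary("M3", 200, 80)])
        assert len(report.ranked) == 1
        assert report.recommendation == ("M3", "L1")

    def test_tie_broken_by_cover_factor(self):
        report = rank_fabrics([_summary("A", 150, 80), _summary("B", 150, 90)])
        assert [s.mask_id for s in report.ranked] == ["B", "A"]

    def test_ranking_independent_of_input_order(self):
        summaries = reference_summaries()
        shuffled = summaries.copy()
        random.Random(7).shuffle(shuffled)
        assert rank_fabrics(summaries).ranked == rank_fabrics(shuffled).ranked

    def test_droplet_flags_ten_of_twelve_type1(self):
        report = rank_fabrics(reference_summaries(mask_type="I"))
        flagged = [k for k, v in report.exceeds_droplet_range.items() if v]
        assert len(flagged) == 10
        unflagged = {k[0] for k, v in report.exceeds_droplet_range.items() if not v}
        assert unflagged == {"M6", "M12"}

    def test_every_reference_fabric_exceeds_aerosol_size(self):
        report = rank_fabrics(reference_summaries())
        assert all(report.exceeds_aerosol_size.values())


class TestExtremes:
    def test_type1_cover_factor_range(self):
        lo, hi = extremes(reference_summaries(), "cover_factor", "type_i")
        assert (lo.mask_id, lo.cover_factor_mean_pct) == ("M10", 66.0)
        assert (hi.mask_id, hi.cover_factor_mean_pct) == ("M12", 96.0)

    def test_type1_minimum_pore_size(self):
        lo, _ = extremes(reference_summaries(), "pore_size", "type_i")
        assert (lo.mask_id, lo.pore_size_mean_um) == ("M6", 77.0)

    def test_overall_pore_and_cover_extremes(self):
        _, hi = extremes(reference_summaries(), "pore_size", "all")
        assert (hi.mask_id, hi.layer, hi.pore_size_mean_um) == ("M15", "L2", 723.0)
        lo, _ = extremes(reference_summaries(), "cover_factor", "all")
        assert (lo.mask_id, lo.layer, lo.cover_factor_mean_pct) == ("M15", "L2", 42.0)

    def test_single_summary_is_both_extremes(self):
        s = _summary("M1", 100, 80)
        lo, hi = extremes([s], "pore_size")
        assert lo is s and hi is s


class TestReferenceData:
    def test_twenty_fabric_entries(self):
        table = reference_table()
        assert len(table) == 20
        assert table["mask_id"].nunique() == 16
        assert (table.query("mask_type == 'II'").groupby("mask_id").size() == 2).all()

    def test_summary_frame_round_trip(self):
        frame = summaries_to_frame(reference_summaries())
        assert frame["porosity_mean_pct"].equals(100 - frame["cover_factor_mean_pct"])
        assert set(frame.columns) >= {
            "mask_id", "layer", "pore_size_mean_um", "pore_size_sd_um",
            "cover_factor_mean_pct", "cover_factor_sd_pct", "porosity_mean_pct",
        }
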