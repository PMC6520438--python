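"""SRB partitioning, the ratiometric index and control normalisation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from srbindex import (
    AnalysisConfig,
    FluorescenceField,
    ImageInputError,
    MissingControlError,
    SyntheticSpec,
    UndefinedIndexError,
    analyze_field,
    normalize_to_control,
    partition_srb,
    ratiometric_index,
)
from srbindex.cytometry import CellCensus
from srbindex.ratiometry import SRBPartition
from srbindex.segmentation import build_nuclear_mask
from srbindex.synthsim import generate_field_images, spec_for_density


def square_mask(shape=(20, 20), size=10):
    """Mask with one square particle covering size^2 of the field."""
    hoechst = np.zeros(shape)
    hoechst[:size, :size] = 200.0
    return build_nuclear_mask(hoechst, pixel_size=1.0, background=0.0)


class TestPartitionSRB:
    def test_uniform_image_split(self):
        mask = square_mask()  # 100 of 400 px nuclear
        srb = np.full((20, 20), 7.0)
        part = partition_srb(srb, mask, background=0.0)
        assert part.esrb_total == pytest.approx(7.0 * 300)
        assert part.nsrb_mean == pytest.approx(7.0)

    def test_signal_conservation_identity(self, small_field):
        field, _ = small_field
        mask = build_nuclear_mask(field.hoechst, field.pixel_size)
        part = partition_srb(field.srb, mask)
        corrected_sum = np.clip(field.srb - part.background, 0, None).sum()
        assert part.esrb_total + part.nuclear_total == pytest.approx(
            corrected_sum, rel=1e-12
        )

    def test_linearity_in_gain(self):
        mask = square_mask()
        srb = np.random.default_rng(0).uniform(1, 50, (20, 20))
        p1 = partition_srb(srb, mask, background=0.0)
        p5 = partition_srb(5 * srb, mask, background=0.0)
        assert p5.esrb_total == pytest.approx(5 * p1.esrb_total)
        assert p5.nsrb_mean == pytest.approx(5 * p1.nsrb_mean)

    def test_shape_mismatch_rejected(self):
        mask = square_mask()
        with pytest.raises(ImageInputError):
            partition_srb(np.zeros((10, 10)), mask)

    def test_no_nuclear_pixels_flagged(self):
        mask = build_nuclear_mask(np.zeros((20, 20)), pixel_size=1.0)
        part = partition_srb(np.full((20, 20), 3.0), mask, background=0.0)
        assert part.flagged
        assert np.isnan(part.nsrb_mean)


def make_partition(esrb, nsrb):
    return SRBPartition(
        esrb_total=esrb,
        nsrb_mean=nsrb,
        nsrb_per_particle=np.array([nsrb]),
        background=0.0,
        n_nuclear_pixels=1,
        nuclear_total=nsrb,
    )


class TestRatiometricIndex:
    def test_arithmetic(self):
        census = CellCensus(n_mono=8, n_binucleate=1, n_fibroblast=1)
        result = ratiometric_index(make_partition(6.0e5, 200.0), census)
        assert result.index == pytest.approx(300.0)  # the ~0.3e3 control scale

    def test_zero_cells_undefined(self):
        with pytest.raises(UndefinedIndexError):
            ratiometric_index(make_partition(100.0, 10.0), CellCensus(0, 0, 0))

    def test_zero_nuclear_signal_undefined(self):
        with pytest.raises(UndefinedIndexError):
            ratiometric_index(make_partition(100.0, 0.0), CellCensus(5, 0, 0))

    def test_common_gain_cancels(self):
        census = CellCensus(n_mono=10, n_binucleate=0, n_fibroblast=0)
        r1 = ratiometric_index(make_partition(5.0e4, 150.0), census)
        r2 = ratiometric_index(make_partition(10 * 5.0e4, 10 * 150.0), census)
        assert r1.index == pytest.approx(r2.index)


class TestAnalyzeField:
    def test_matches_generator_ground_truth(self, small_field):
        field, gt = small_field
        result = analyze_field(field)
        assert result.index == pytest.approx(gt.analytic_index, rel=0.10)
        assert result.n_cells == pytest.approx(gt.n_cells, rel=0.05)

    def test_blank_field_undefined(self):
        blank = FluorescenceField(
            hoechst=np.full((64, 64), 5.0), srb=np.full((64, 64), 5.0), pixel_size=1.0
        )
        with pytest.raises(UndefinedIndexError):
            analyze_field(blank)

    def test_deterministic(self, small_field):
        field, _ = small_field
        r1 = analyze_field(field)
        r2 = analyze_field(field)
        assert r1.index == r2.index
        assert r1.n_cells == r2.n_cells

    def test_gain_invariance_below_saturation(self, clean_field, zero_background_config):
        """10x gain on both channels moves the index by far less than 0.1%."""
        field, _ = clean_field
        r1 = analyze_field(field, zero_background_config)
        scaled = FluorescenceField(
            hoechst=field.hoechst * 10.0,
            srb=field.srb * 10.0,
            pixel_size=field.pixel_size,
            well_id="gain10",
        )
        r10 = analyze_field(scaled, zero_background_config)
        assert abs(r10.index - r1.index) / r1.index < 1e-3

    def test_index_linear_in_biomass(self, small_spec):
        """Index tracks the per-cell biomass factor over a 2-fold range."""
        factors = [1.0, 1.25, 1.5, 1.75, 2.0]
        indices = []
        for f in factors:
            spec = dataclasses.replace(small_spec, hypertrophy_factor=f)
            field, _ = generate_field_images(spec)
            indices.append(analyze_field(field).index)
        r = np.corrcoef(factors, indices)[0, 1]
        assert r**2 > 0.95
        assert np.all(np.diff(indices) > 0)

    def test_index_decreases_with_density(self, small_spec):
        """Fig 4C direction: higher seeding density, lower per-cell growth."""
        counts = [116, 252, 388, 524]
        fields = [generate_field_images(spec_for_density(small_spec, n))[0] for n in counts]
        # classification models shared plate-wide, fitted on the densest field
        probe = analyze_field(fields[-1])
        from srbindex.cytometry import determine_area_cutoff, fit_circularity_mixture

        cut = determine_area_cutoff(probe.particles)
        mix = fit_circularity_mixture([p for p in probe.particles if p.area > cut.cutoff])
        shared = AnalysisConfig(cutoff=cut, mixture=mix)
        indices = [analyze_field(f, shared).index for f in fields]
        assert np.all(np.diff(indices) < 0)
        assert indices[0] / indices[-1] > 2.0


class TestNormalizeToControl:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(
            rows,
            columns=["well_id", "index", "condition", "dose", "duration", "isolation", "is_control"],
        )

    def test_percent_of_control(self):
        df = self.frame(
            [
                ("A1", 0.30, "control", 0.0, 24.0, "iso1", True),
                ("A2", 0.45, "PE", 10.0, 24.0, "iso1", False),
            ]
        )
        out = normalize_to_control(df)
        pe = out[out["condition"] == "PE"]
        assert pe["response_percent"].item() == pytest.approx(150.0)

    def test_control_is_100_percent(self):
        df = self.frame(
            [
                ("A1", 0.30, "control", 0.0, 24.0, "iso1", True),
                ("A2", 0.30, "control", 0.0, 24.0, "iso1", True),
            ]
        )
        out = normalize_to_control(df)
        assert out["response_percent"].item() == pytest.approx(100.0)

    def test_summary_across_isolations(self):
        df = self.frame(
            [
                ("A1", 0.30, "control", 0.0, 24.0, "iso1", True),
                ("A2", 0.42, "PE", 10.0, 24.0, "iso1", False),
                ("B1", 0.30, "control", 0.0, 24.0, "iso2", True),
                ("B2", 0.48, "PE", 10.0, 24.0, "iso2", False),
            ]
        )
        out = normalize_to_control(df)
        pe = out[out["condition"] == "PE"]
        assert sorted(pe["response_percent"]) == pytest.approx([140.0, 160.0])
        assert pe["response_percent"].mean() == pytest.approx(150.0)

    def test_missing_control_names_stratum(self):
        df = self.frame(
            [
                ("A1", 0.30, "control", 0.0, 24.0, "iso1", True),
                ("B2", 0.48, "PE", 10.0, 48.0, "iso2", False),
            ]
        )
        with pytest.raises(MissingControlError, match="iso2"):
            normalize_to_control(df)
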