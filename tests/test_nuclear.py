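import numpy as np
import pytest

from dnuptake import nuclear, synthetic, uptake
from dnuptake.exceptions import InvalidInputError
from dnuptake.image import FluorescenceImage
from dnuptake.nuclear import (
    NuclearROISet,
    estimate_cell_mask,
    intranuclear_efficiency,
    intranuclear_intensity,
    segment_nuclei,
)


def _nuclear_img(pixels):
    return FluorescenceImage(np.asarray(pixels, dtype=float), "nuclear")


def _dn_img(pixels):
    return FluorescenceImage(np.asarray(pixels, dtype=float), "internal")


@pytest.fixture(scope="module")
def one_cell_field():
    spec = synthetic.CellImageSpec(
        n_cells=1, seed=3, noise_model="none", background_offset=0.0
    )
    return spec, *synthetic.make_cell_image(spec)


class TestSegmentNuclei:
    def test_blank_image_yields_no_nuclei(self):
        with pytest.warns(UserWarning):
            rois = segment_nuclei(_nuclear_img(np.zeros((64, 64))))
        assert rois.n_nuclei == 0

    def test_single_ellipse_area_recovered_without_erosion(self, one_cell_field):
        spec, _, _, nuclear_img, _ = one_cell_field
        drawn_area = int((nuclear_img.pixels > 0).sum())
        rois = segment_nuclei(nuclear_img, erosion_radius=0, min_area=0)
        assert rois.n_nuclei == 1
        assert rois.areas[0] == pytest.approx(drawn_area, rel=0.02)

    def test_erosion_strictly_shrinks_every_nucleus(self, default_field):
        _, _, _, nuclear_img, _ = default_field
        full = segment_nuclei(nuclear_img, erosion_radius=0)
        eroded = segment_nuclei(nuclear_img, erosion_radius=2)
        assert full.n_nuclei == eroded.n_nuclei > 0
        assert (eroded.areas < full.areas).all()

    def test_default_conditions_find_all_cells(self, default_field):
        spec, _, _, nuclear_img, _ = default_field
        rois = segment_nuclei(nuclear_img)
        assert rois.n_nuclei == spec.n_cells


class TestIntranuclearIntensity:
    def test_uniform_field_reports_the_field_value(self, one_cell_field):
        _, _, _, nuclear_img, _ = one_cell_field
        rois = segment_nuclei(nuclear_img)
        dn = _dn_img(np.full(nuclear_img.shape, 3.5))
        values = intranuclear_intensity(dn, rois)
        assert values == pytest.approx(np.full(rois.n_nuclei, 3.5))

    def test_zero_channel_reports_zero(self, one_cell_field):
        _, _, _, nuclear_img, _ = one_cell_field
        rois = segment_nuclei(nuclear_img)
        assert not intranuclear_intensity(
            _dn_img(np.zeros(nuclear_img.shape)), rois
        ).any()

    def test_dimension_mismatch_rejected(self, one_cell_field):
        _, _, _, nuclear_img, _ = one_cell_field
        rois = segment_nuclei(nuclear_img)
        with pytest.raises(InvalidInputError):
            intranuclear_intensity(_dn_img(np.zeros((10, 10))), rois)

    def test_invariant_to_padding_with_empty_frame(self, one_cell_field):
        _, _, internal_img, nuclear_img, _ = one_cell_field
        rois = segment_nuclei(nuclear_img)
        base = intranuclear_intensity(_dn_img(internal_img.pixels), rois)
        pad = 24
        padded_labels = np.pad(rois.label_grid, pad)
        padded_rois = NuclearROISet(padded_labels, rois.areas)
        padded = intranuclear_intensity(
            _dn_img(np.pad(internal_img.pixels, pad)), padded_rois
        )
        assert padded == pytest.approx(base)

    def test_uniform_field_value_invariant_to_erosion_radius(self, one_cell_field):
        _, _, _, nuclear_img, _ = one_cell_field
        dn = _dn_img(np.full(nuclear_img.shape, 2.0))
        for radius in (0, 2, 4):
            rois = segment_nuclei(nuclear_img, erosion_radius=radius)
            assert intranuclear_intensity(dn, rois) == pytest.approx([2.0])


class TestIntranuclearEfficiency:
    def test_all_signal_inside_nuclei_gives_unity(self, one_cell_field):
        _, surface_img, _, nuclear_img, _ = one_cell_field
        rois = segment_nuclei(nuclear_img, erosion_radius=0)
        dn = _dn_img((rois.label_grid > 0) * 5.0)
        eff, mean = intranuclear_efficiency(
            dn, rois, estimate_cell_mask(surface_img)
        )
        assert mean == pytest.approx(1.0)

    def test_no_signal_inside_nuclei_gives_zero(self, one_cell_field):
        _, surface_img, _, nuclear_img, _ = one_cell_field
        rois = segment_nuclei(nuclear_img, erosion_radius=0)
        mask = estimate_cell_mask(surface_img)
        dn = _dn_img(mask * (rois.label_grid == 0) * 5.0)
        eff, mean = intranuclear_efficiency(dn, rois, mask)
        assert mean == pytest.approx(0.0)

    def test_efficiency_always_within_unit_interval(self, default_field):
        spec, surface_img, internal_img, nuclear_img, _ = default_field
        dn = uptake.subtract_background(internal_img, spec.background_offset)
        rois = segment_nuclei(nuclear_img)
        eff, mean = intranuclear_efficiency(
            dn, rois, estimate_cell_mask(surface_img)
        )
        assert np.all((eff >= 0) & (eff <= 1))
        assert 0.0 <= mean <= 1.0

    def test_cells_without_signal_flagged_missing(self, one_cell_field):
        _, surface_img, _, nuclear_img, _ = one_cell_field
        rois = segment_nuclei(nuclear_img)
        with pytest.warns(UserWarning):
            eff, mean = intranuclear_efficiency(
                _dn_img(np.zeros(nuclear_img.shape)), rois,
                estimate_cell_mask(surface_img),
            )
        assert np.isnan(eff).all() and np.isnan(mean)


def _measured_fraction(nuclear_fraction, seed):
    spec = synthetic.CellImageSpec(nuclear_fraction=nuclear_fraction, seed=seed)
    surface_img, internal_img, nuclear_img, truth = synthetic.make_cell_image(spec)
    dn = uptake.subtract_background(internal_img, spec.background_offset)
    rois = segment_nuclei(nuclear_img)
    _, mean = intranuclear_efficiency(dn, rois,
                                      estimate_cell_mask(surface_img))
    return mean


def test_programmed_nuclear_fraction_recovered(default_field):
    assert _measured_fraction(0.3, seed=21) == pytest.approx(0.3, abs=0.03)


def test_efficiency_monotone_in_programmed_fraction():
    estimates = [_measured_fraction(f, seed=31) for f in (0.0, 0.3, 0.6, 1.0)]
    assert estimates == sorted(estimates)
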