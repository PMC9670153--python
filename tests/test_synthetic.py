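"""Tests of the parametric face renderer and the synthetic database builder."""

import numpy as np
import pytest

from aufaces.au import AU_IDS, EXPRESSIONS, AUVector
from aufaces.faces import (
    CultureMap,
    DatabaseSpec,
    FaceIdentity,
    face_bbox,
    generate_database,
    generate_probe_set,
    render_face,
    sample_expression_aus,
)


class TestAUVector:
    def test_defaults_to_all_zero(self):
        v = AUVector.zeros()
        assert len(v) == 20
        assert all(v[a] == 0.0 for a in AU_IDS)

    def test_unknown_au_rejected_by_name(self):
        with pytest.raises(KeyError, match="AU#3"):
            AUVector({3: 0.5})

    @pytest.mark.parametrize("bad", [-0.1, 1.0001, 2.0])
    def test_out_of_range_intensity_rejected(self, bad):
        with pytest.raises(ValueError, match="outside"):
            AUVector({12: bad})

    def test_array_round_trip_in_table_order(self):
        v = AUVector({12: 0.5, 27: 1.0})
        arr = v.as_array()
        assert arr[AU_IDS.index(12)] == 0.5
        assert arr[AU_IDS.index(27)] == 1.0
        assert arr.sum() == pytest.approx(1.5)


class TestRenderFace:
    def test_zero_aus_reproduces_neutral_template(self, average_face, neutral_render):
        again = render_face(average_face, AUVector.zeros(), 64)
        assert np.array_equal(again, neutral_render)

    def test_deterministic_for_identical_arguments(self, average_face):
        a = render_face(average_face, AUVector.single(12, 0.7), 64)
        b = render_face(average_face, AUVector.single(12, 0.7), 64)
        assert np.array_equal(a, b)

    def test_au12_difference_confined_to_lower_face(self, average_face):
        neutral = render_face(average_face, AUVector.zeros(), 128).astype(int)
        smile = render_face(average_face, AUVector.single(12, 1.0), 128).astype(int)
        diff = np.abs(smile - neutral)
        assert diff[:64].sum() == 0       # upper half untouched
        assert diff[64:].sum() > 0        # lower half deformed

    def test_output_range_and_dtype(self, neutral_render):
        assert neutral_render.dtype == np.uint8
        assert neutral_render.shape == (64, 64)

    def test_size_below_minimum_rejected(self, average_face):
        with pytest.raises(ValueError, match="size"):
            render_face(average_face, AUVector.zeros(), 16)

    @pytest.mark.parametrize("au", AU_IDS)
    def test_deformation_monotone_in_intensity(self, au, average_face, neutral_render):
        """L1 distance to the neutral render never decreases with intensity."""
        n = neutral_render.astype(int)
        d = [
            np.abs(render_face(average_face, AUVector.single(au, t), 64).astype(int) - n).sum()
            for t in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(d) >= 0), f"AU#{au} not monotone: {d}"

    def test_deformation_monotone_for_sampled_identities(self):
        rng = np.random.default_rng(2024)
        for k in range(3):
            ident = FaceIdentity.sample(f"id{k}", rng)
            n = render_face(ident, AUVector.zeros(), 64).astype(int)
            for au in (4, 12, 26, 27):
                d = [
                    np.abs(render_face(ident, AUVector.single(au, t), 64).astype(int) - n).sum()
                    for t in np.linspace(0, 1, 11)
                ]
                assert np.all(np.diff(d) >= 0), f"AU#{au}, identity {k}: {d}"

    def test_identity_reproducible_from_seed(self):
        a = FaceIdentity.sample("x", np.random.default_rng(5))
        b = FaceIdentity.sample("x", np.random.default_rng(5))
        assert a == b

    def test_bbox_contains_face_oval(self, average_face):
        x0, y0, w, h = face_bbox(average_face, 64)
        assert 0 <= x0 and x0 + w <= 64 and 0 <= y0 and y0 + h <= 64
        # the oval's extreme points are inside the box
        assert x0 <= (0.5 - 0.34) * 64 and x0 + w >= (0.5 + 0.34) * 64
        assert y0 <= (0.52 - 0.45) * 64 and y0 + h >= (0.52 + 0.45) * 64


def _culture(sd=0.0):
    means = {
        "neutral": {}, "happy": {12: 0.8}, "fearful": {20: 0.5}, "sad": {15: 0.7},
        "angry": {4: 0.8}, "surprised": {26: 0.7}, "disgusted": {9: 0.7},
    }
    return CultureMap.from_means(means, sd=sd)


class TestSampleExpressionAUs:
    def test_neutral_is_all_zero(self):
        v = sample_expression_aus(_culture(), "neutral", 0)
        assert all(v[a] == 0.0 for a in AU_IDS)

    def test_zero_sd_returns_means_exactly(self):
        v = sample_expression_aus(_culture(sd=0.0), "happy", 123)
        assert v[12] == 0.8
        assert sum(v[a] for a in AU_IDS) == pytest.approx(0.8)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="bored"):
            sample_expression_aus(_culture(), "bored", 0)

    def test_truncated_normal_mean_unbiased_at_center(self):
        """10,000 draws at mean 0.5, sd 0.1: symmetric truncation is unbiased."""
        culture = CultureMap.from_means({"happy": {12: 0.5}}, sd=0.1)
        rng = np.random.default_rng(77)
        draws = [sample_expression_aus(culture, "happy", rng)[12] for _ in range(10_000)]
        assert abs(np.mean(draws) - 0.5) < 0.02
        assert 0.0 <= min(draws) and max(draws) <= 1.0

    def test_neutral_mean_must_be_zero(self):
        with pytest.raises(ValueError, match="neutral"):
            CultureMap.from_means({"neutral": {12: 0.3}})


class TestGenerateDatabase:
    def test_counts_one_image_per_identity_and_label(self):
        spec = DatabaseSpec("t", _culture(), n_identities=12, seed=3, image_size=64)
        images = generate_database(spec)
        assert len(images) == 12 * 7
        for label in EXPRESSIONS:
            assert sum(im.label == label for im in images) == 12

    def test_deterministic_given_seed(self):
        spec = DatabaseSpec("t", _culture(sd=0.1), n_identities=12, seed=3, image_size=64)
        a, b = generate_database(spec), generate_database(spec)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_too_few_identities_rejected(self):
        with pytest.raises(ValueError, match="n_identities"):
            DatabaseSpec("t", _culture(), n_identities=7)

    def test_culture_separability(self):
        """Cultures differing only in 'angry' agree image-for-image elsewhere."""
        means_a = {
            "neutral": {}, "happy": {12: 0.8}, "fearful": {20: 0.5},
            "sad": {15: 0.7}, "angry": {4: 0.4, 22: 0.8},
            "surprised": {26: 0.7}, "disgusted": {9: 0.7},
        }
        means_b = {**means_a, "angry": {4: 0.4, 23: 0.8}}
        spec_a = DatabaseSpec("t", CultureMap.from_means(means_a, sd=0.1),
                              n_identities=12, seed=5, image_size=64)
        spec_b = DatabaseSpec("t", CultureMap.from_means(means_b, sd=0.1),
                              n_identities=12, seed=5, image_size=64)
        for ia, ib in zip(generate_database(spec_a), generate_database(spec_b)):
            assert ia.label == ib.label and ia.identity == ib.identity
            if ia.label == "angry":
                assert not np.array_equal(ia.pixels, ib.pixels)
            else:
                assert np.array_equal(ia.pixels, ib.pixels)


@pytest.fixture(scope="module")
def probe():
    return generate_probe_set(size=64)


class TestProbeSet:
    def test_has_20_series_of_11_images(self, probe):
        assert len(probe.series) == 20
        assert all(len(s) == 11 for s in probe.series.values())

    def test_intensity_grid_is_uniform(self, probe):
        assert np.allclose(probe.intensities, np.arange(11) / 10)

    def test_null_image_identical_across_series(self, probe):
        for au in AU_IDS:
            assert np.array_equal(probe.series[au][0], probe.null_image)

    def test_full_intensity_differs_from_null(self, probe):
        for au in AU_IDS:
            assert not np.array_equal(probe.series[au][10], probe.null_image)
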