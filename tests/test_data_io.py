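"""Palette codec, preprocessing, augmentation and the synthetic scene
generator: round trips, determinism, label safety and leakage guards."""

import numpy as np
import pytest
from skimage.measure import label as cc_label

from weedseg.data_io import (
    PALETTE,
    SceneSpec,
    augment,
    compute_channel_stats,
    decode_color_mask,
    elastic_distort,
    encode_color_mask,
    generate_synthetic_dataset,
    generate_synthetic_scene,
    miscut_transform,
    preprocess,
    read_dataset,
    write_dataset,
)


# ---------------------------------------------------------------------------
# codec
# ---------------------------------------------------------------------------

def test_palette_convention():
    img = np.array([[[0, 0, 0], [0, 255, 0], [255, 0, 0]]], dtype=np.uint8)
    assert decode_color_mask(img).tolist() == [[0, 1, 2]]
    assert np.array_equal(encode_color_mask(np.array([[2]])),
                          np.array([[[255, 0, 0]]], dtype=np.uint8))
    assert np.all(encode_color_mask(np.zeros((3, 3), dtype=int)) == 0)


def test_codec_round_trips_exactly(rng):
    mask = rng.integers(0, 3, size=(17, 13))
    assert np.array_equal(decode_color_mask(encode_color_mask(mask)), mask)
    rgb = PALETTE[rng.integers(0, 3, size=(9, 9))]
    assert np.array_equal(encode_color_mask(decode_color_mask(rgb)), rgb)


def test_off_palette_pixels_snap_to_nearest_colour():
    antialiased = np.array([[[10, 200, 30]]], dtype=np.uint8)  # nearly green
    assert decode_color_mask(antialiased)[0, 0] == 1
    dark_red = np.array([[[160, 40, 40]]], dtype=np.uint8)
    assert decode_color_mask(dark_red)[0, 0] == 2


def test_codec_input_validation():
    with pytest.raises(ValueError):
        decode_color_mask(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        encode_color_mask(np.array([[3]]))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_resizes_and_standardises(rng):
    image = rng.random((97, 123, 3))
    mask = rng.integers(0, 3, size=(97, 123))
    chw, small = preprocess(image, mask, size=(64, 64))
    assert chw.shape == (3, 64, 64) and small.shape == (64, 64)
    assert set(np.unique(small)) <= set(np.unique(mask))  # nearest: no new labels
    # with dataset statistics and no resampling, channels standardise to
    # mean ~0, sd ~1
    big = rng.random((64, 64, 3))
    mean, std = big.reshape(-1, 3).mean(0), big.reshape(-1, 3).std(0)
    chw2, _ = preprocess(big, None, size=(64, 64), mean=mean, std=std)
    assert abs(chw2.mean()) < 0.05 and abs(chw2.std() - 1.0) < 0.05


def test_preprocess_rejects_misaligned_pairs(rng):
    with pytest.raises(ValueError):
        preprocess(rng.random((10, 10, 3)), np.zeros((9, 10), dtype=int))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_augment_deterministic_and_label_safe(rng):
    image = rng.random((32, 32, 3))
    mask = rng.integers(0, 3, size=(32, 32))
    a_img, a_mask = augment(image, mask, seed=5)
    b_img, b_mask = augment(image, mask, seed=5)
    assert np.array_equal(a_img, b_img) and np.array_equal(a_mask, b_mask)
    assert set(np.unique(a_mask)) <= {0, 1, 2}


def test_flips_are_joint_and_involutive(rng):
    image = rng.random((16, 16, 3))
    mask = rng.integers(0, 3, size=(16, 16))
    hv_img = image[::-1, ::-1]
    hv_mask = mask[::-1, ::-1]
    assert np.array_equal(hv_img[::-1, ::-1], image)
    assert np.array_equal(hv_mask[::-1, ::-1], mask)
    # blur must leave the mask bit-identical: force the blur branch
    a_img, a_mask = augment(image, mask, seed=11, blur_prob=1.0)
    assert np.array_equal(np.sort(a_mask.ravel()), np.sort(mask.ravel()))


def test_geometric_ops_move_image_and_mask_together(rng):
    # a mask-coloured image must stay aligned with its mask under every
    # geometric op (flips, elastic, shear)
    mask = rng.integers(0, 3, size=(24, 24))
    image = encode_color_mask(mask).astype(float) / 255.0
    for seed in range(4):
        a_img, a_mask = augment(image, mask, seed=seed, blur_prob=0.0)
        assert np.array_equal(decode_color_mask((a_img * 255).astype(np.uint8)),
                              a_mask)
    e_img, e_mask = elastic_distort(image, mask, seed=1, alpha=4.0)
    assert (decode_color_mask((e_img * 255).astype(np.uint8)) == e_mask).mean() > 0.95
    m_img, m_mask = miscut_transform(image, mask, seed=1)
    assert (decode_color_mask((m_img * 255).astype(np.uint8)) == m_mask).mean() > 0.95


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

def test_scene_is_seed_deterministic():
    spec = SceneSpec.for_size((96, 96), seed=3)
    img1, mask1 = generate_synthetic_scene(spec)
    img2, mask2 = generate_synthetic_scene(spec)
    assert np.array_equal(img1, img2) and np.array_equal(mask1, mask2)


def test_scene_without_weeds_has_no_weed_label():
    spec = SceneSpec.for_size((96, 96), n_weeds=0, seed=1)
    _, mask = generate_synthetic_scene(spec)
    assert 2 not in np.unique(mask)
    assert 1 in np.unique(mask)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_nonoverlapping_crops_form_three_components(seed):
    spec = SceneSpec(size=(128, 128), n_crops=3, overlap_prob=0.0,
                     crop_radius_range=(12.0, 18.0), seed=seed)
    _, mask = generate_synthetic_scene(spec)
    n_components = cc_label(mask == 1).max()
    assert n_components == 3


def test_oversized_objects_raise():
    with pytest.raises(ValueError):
        generate_synthetic_scene(SceneSpec(size=(32, 32),
                                           crop_radius_range=(30.0, 40.0)))


def test_weed_radii_must_be_smaller_than_crop_radii():
    with pytest.raises(ValueError):
        SceneSpec(crop_radius_range=(5.0, 8.0), weed_radius_range=(6.0, 9.0))


def test_paddy_background_with_reflections_keeps_background_label():
    spec = SceneSpec.for_size((96, 96), background="paddy", reflection=True, seed=2)
    img, mask = generate_synthetic_scene(spec)
    assert set(np.unique(mask)) <= {0, 1, 2}
    assert img.shape == (96, 96, 3) and img.min() >= 0 and img.max() <= 1


def test_weed_pixel_fraction_grows_with_n_weeds():
    def frac(n_weeds):
        fracs = []
        for seed in range(5):
            spec = SceneSpec.for_size((96, 96), n_weeds=n_weeds, seed=seed)
            _, mask = generate_synthetic_scene(spec)
            fracs.append((mask == 2).mean())
        return np.mean(fracs)

    f0, f8, f24 = frac(0), frac(8), frac(24)
    assert f0 == 0.0 and f0 < f8 < f24


# ---------------------------------------------------------------------------
# dataset generation and layout
# ---------------------------------------------------------------------------

def test_dataset_split_sizes_and_leakage_guard():
    spec = SceneSpec.for_size((64, 64))
    tr, va, te = generate_synthetic_dataset(spec, 10, 2, 2, seed=9)
    assert (len(tr), len(va), len(te)) == (10, 2, 2)
    digests = [img.tobytes() for split in (tr, va, te) for img, _ in split]
    assert len(set(digests)) == len(digests)  # no image repeats across splits


def test_split_streams_reproduce_independently():
    spec = SceneSpec.for_size((64, 64))
    _, va1, _ = generate_synthetic_dataset(spec, 3, 2, 1, seed=4)
    _, va2, _ = generate_synthetic_dataset(spec, 3, 2, 1, seed=4)
    for (i1, m1), (i2, m2) in zip(va1, va2):
        assert np.array_equal(i1, i2) and np.array_equal(m1, m2)


def test_augmented_copies_stay_within_split():
    spec = SceneSpec.for_size((64, 64))
    tr, va, te = generate_synthetic_dataset(spec, 2, 1, 1, seed=0,
                                            augment_per_scene=2)
    assert len(tr) == 6 and len(va) == 3 and len(te) == 3


def test_dataset_directory_round_trip(rng, tmp_path):
    spec = SceneSpec(size=(48, 48)).scaled_to((48, 48))
    pairs = [generate_synthetic_scene(SceneSpec.for_size((48, 48), seed=s))
             for s in range(2)]
    write_dataset(str(tmp_path), pairs)
    loaded = read_dataset(str(tmp_path))
    assert len(loaded) == 2
    for (img, mask), (limg, lmask) in zip(pairs, loaded):
        assert np.array_equal(mask, lmask)            # palette PNGs are lossless
        assert np.abs(img - limg).max() <= 1 / 255 + 1e-9  # 8-bit quantisation

    mean, std = compute_channel_stats(loaded)
    assert mean.shape == (3,) and np.all(std > 0)
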