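import re
import string

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecotree.preprocessing import (
    AugmentationParams,
    SynonymDictionary,
    augment,
    background_perturb,
    clean_text,
    local_affine,
    normalize_entities,
    occlude,
)


def checkerboard(h=20, w=20, seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


class TestBackgroundPerturb:
    def test_identity_parameters(self, rng):
        img = checkerboard()
        mask = rng.random((20, 20)) < 0.5
        out = background_perturb(img, mask, alpha=1.0, beta=0.0)
        assert np.array_equal(out, img)

    def test_direct_evaluation(self):
        img = np.full((4, 4, 3), 100, dtype=np.uint8)
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        out = background_perturb(img, mask, alpha=1.2, beta=10.0)
        assert tuple(out[0, 0]) == (130, 130, 130)
        assert np.array_equal(out[1:], img[1:])

    def test_clipping_bound(self):
        img = np.full((2, 2, 3), 250, dtype=np.uint8)
        mask = np.ones((2, 2), dtype=bool)
        out = background_perturb(img, mask, alpha=1.3, beta=20.0)
        assert out.max() == out.min() == 255

    def test_foreground_untouched_random(self, rng):
        for _ in range(20):
            img = checkerboard(seed=int(rng.integers(1e6)))
            mask = rng.random((20, 20)) < 0.3
            out = background_perturb(img, mask, alpha=rng.uniform(0.7, 1.3), beta=rng.uniform(-20, 20))
            assert np.array_equal(out[~mask], img[~mask])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mask"):
            background_perturb(checkerboard(), np.zeros((5, 5), dtype=bool), 1.0, 0.0)


class TestOcclude:
    def test_empty_region_identity(self):
        img = checkerboard()
        out = occlude(img, np.zeros((0, 2), dtype=int), (0, 0, 0))
        assert np.array_equal(out, img)

    def test_full_occlusion(self):
        img = checkerboard()
        out = occlude(img, np.ones((20, 20), dtype=bool), (0, 0, 0))
        assert out.sum() == 0

    def test_rectangle_changes_exactly_its_pixels(self):
        img = np.full((30, 30, 3), 7, dtype=np.uint8)
        region = np.array([(r, c) for r in range(5, 15) for c in range(8, 18)])
        out = occlude(img, region, (200, 100, 50))
        diff = np.any(out != img, axis=2)
        assert diff.sum() == 100  # pixel-diff count oracle
        assert np.all(out[5:15, 8:18] == (200, 100, 50))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            occlude(checkerboard(), np.array([[25, 3]]), (0, 0, 0))


class TestLocalAffine:
    def test_identity_transform_bit_exact(self):
        img = checkerboard()
        out = local_affine(img, (2, 3, 12, 13), np.eye(2), np.zeros(2))
        assert np.array_equal(out, img)

    def test_translation_displaces_bright_pixel(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        img[10, 5] = 255
        # forward map x' = x + (5, 0): bright pixel moves 5 columns right
        out = local_affine(img, (0, 0, 20, 20), np.eye(2), np.array([5.0, 0.0]))
        assert tuple(out[10, 10]) == (255, 255, 255)
        assert tuple(out[10, 5]) == (0, 0, 0)

    def test_quarter_turn_equals_index_permutation(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(11, 11, 3), dtype=np.uint8)
        # rotation by 90 degrees about the region center
        c = 5.0
        A = np.array([[0.0, -1.0], [1.0, 0.0]])
        t = np.array([c - (A[0, 0] * c + A[0, 1] * c), c - (A[1, 0] * c + A[1, 1] * c)])
        out = local_affine(img, (0, 0, 11, 11), A, t)
        expected = np.rot90(img, k=-1)  # (x,y)->(-y,x) is a CCW quarter turn in xy
        assert np.array_equal(out, expected)

    def test_outside_region_untouched(self):
        img = checkerboard()
        out = local_affine(img, (5, 5, 15, 15), 2 * np.eye(2), np.array([1.0, -2.0]))
        untouched = np.ones((20, 20), dtype=bool)
        untouched[5:15, 5:15] = False
        assert np.array_equal(out[untouched], img[untouched])

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            local_affine(checkerboard(), (0, 0, 10, 10), np.zeros((2, 2)), np.zeros(2))

    def test_brute_force_warp_oracle(self):
        """Inverse warp with clamped bilinear sampling, pixel by pixel."""
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        A = np.array([[1.1, 0.2], [-0.1, 0.9]])
        t = np.array([1.5, -0.5])
        out = local_affine(img, (0, 0, 16, 16), A, t)
        Ainv = np.linalg.inv(A)
        for ry in range(16):
            for rx in range(16):
                sx, sy = Ainv @ (np.array([rx, ry]) - t)
                sx = min(max(sx, 0.0), 15.0)
                sy = min(max(sy, 0.0), 15.0)
                x0, y0 = int(np.floor(sx)), int(np.floor(sy))
                x1, y1 = min(x0 + 1, 15), min(y0 + 1, 15)
                fx, fy = sx - x0, sy - y0
                val = (
                    img[y0, x0] * (1 - fx) * (1 - fy)
                    + img[y0, x1] * fx * (1 - fy)
                    + img[y1, x0] * (1 - fx) * fy
                    + img[y1, x1] * fx * fy
                )
                expected = np.round(np.clip(val, 0, 255)).astype(np.uint8)
                assert np.array_equal(out[ry, rx], expected), (ry, rx)


class TestAugment:
    def test_all_gates_closed_identity(self, rng):
        img = checkerboard(40, 40)
        mask = rng.random((40, 40)) < 0.5
        params = AugmentationParams(p_bg=0.0, p_occ=0.0, p_affine=0.0, seed=5)
        assert np.array_equal(augment(img, mask, params), img)

    def test_fixed_seed_reproducible(self, rng):
        img = checkerboard(64, 64)
        mask = rng.random((64, 64)) < 0.5
        params = AugmentationParams(seed=11)
        a = augment(img, mask, params)
        b = augment(img, mask, params)
        assert np.array_equal(a, b)
        assert a.tobytes() == b.tobytes()

    def test_occlusion_always_produces_constant_region(self):
        img = checkerboard(64, 64, seed=9)  # random noise: no natural constant patch
        mask = np.ones((64, 64), dtype=bool)
        params = AugmentationParams(p_bg=0.0, p_occ=1.0, p_affine=0.0, seed=21)
        out = augment(img, mask, params)
        changed = np.any(out != img, axis=2)
        assert changed.any()
        colors = out[changed]
        assert (colors == colors[0]).all()  # one constant occluder color


class TestCleanText:
    def test_worked_example(self):
        assert clean_text("Aphids!!!   feed  on sap..") == "Aphids! feed on sap."

    def test_already_clean_unchanged(self):
        s = "Coccinella septempunctata preys on Aphis gossypii."
        assert clean_text(s) == s

    def test_empty_string(self):
        assert clean_text("") == ""

    def test_strips_control_and_emoji(self):
        assert clean_text("ladybird\x07 \U0001F41E eats") == "ladybird eats"

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet=string.printable + "\U0001F41E☀", max_size=80))
    def test_idempotent_and_non_increasing(self, text):
        once = clean_text(text)
        assert clean_text(once) == once
        assert len(once) <= len(text)

    def test_reference_regex_oracle(self):
        """Rule-by-rule reference: punctuation collapse then whitespace collapse."""
        cases = ["a!!b", "x  ,,  y", "..a..b..", "tabs\t\tand\nnewlines"]
        for raw in cases:
            ref = re.sub(r"([!-/:-@\[-`{-~])\1+", r"\1", raw)
            ref = re.sub(r"\s+", " ", ref).strip()
            assert clean_text(raw) == ref


class TestNormalizeEntities:
    DICT = SynonymDictionary(
        {
            "seven-spot lady beetle": "Coccinella septempunctata",
            "aphids": "Aphidoidea",
            "lady beetle": "Coccinellidae",
        }
    )

    def test_two_dictionary_hits(self):
        _txt, ents = normalize_entities("seven-spot lady beetle eats aphids", self.DICT)
        assert ents == {"Coccinella septempunctata", "Aphidoidea"}

    def test_no_hits(self):
        _txt, ents = normalize_entities("wheat field at dawn", self.DICT)
        assert ents == set()

    def test_longest_match_wins(self):
        _txt, ents = normalize_entities("a seven-spot lady beetle rests", self.DICT)
        assert ents == {"Coccinella septempunctata"}  # not the shorter alias

    def test_shorter_alias_matches_alone(self):
        _txt, ents = normalize_entities("a lady beetle rests", self.DICT)
        assert ents == {"Coccinellidae"}

    def test_standard_names_are_fixed_points(self):
        for std in ("Coccinella septempunctata", "Aphidoidea"):
            _txt, ents = normalize_entities(f"observed {std} today", self.DICT)
            assert ents == {std}

    def test_case_insensitive(self):
        _txt, ents = normalize_entities("APHIDS everywhere", self.DICT)
        assert ents == {"Aphidoidea"}

    def test_brute_force_tiling_oracle(self):
        """Greedy longest-match equals the best over all match tilings here."""
        text = "lady beetle near seven-spot lady beetle and aphids"
        _txt, ents = normalize_entities(text, self.DICT)
        assert ents == {"Coccinellidae", "Coccinella septempunctata", "Aphidoidea"}
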