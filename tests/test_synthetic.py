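"""Phantom generators, paired effects, and planted-rule cohorts."""

import numpy as np
import pytest

from fractolung import (
    CohortSpec,
    PairedEffectSpec,
    PhantomSpec,
    PlantedRule,
    apply_planted_rules,
    box_counting_dimension,
    cohort_to_csv,
    generate_cohort,
    generate_paired_volumes,
    generate_phantom,
    lacunarity,
)
from fractolung.errors import ConfigurationError, GenerationError


class TestPhantomSpec:
    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec("blob", 16)

    def test_menger_size_must_be_power_of_three(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec("menger_sponge", 32, level=3)
        PhantomSpec("menger_sponge", 27, level=3)  # valid

    def test_occupancy_bounds(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec("random_dust", 16, occupancy=0.0)
        with pytest.raises(ConfigurationError):
            PhantomSpec("random_dust", 16, occupancy=1.5)


class TestPhantoms:
    def test_menger_recursion_oracle(self):
        # level-L sponge = 20 copies of the level-(L-1) sponge
        for level in (1, 2, 3):
            occ = generate_phantom(
                PhantomSpec("menger_sponge", 3**level, level=level)
            ).occupancy
            assert occ.sum() == 20**level
            if level > 1:
                sub = generate_phantom(
                    PhantomSpec("menger_sponge", 3**(level - 1), level=level - 1)
                ).occupancy
                s = 3**(level - 1)
                # corner child block equals the lower-level sponge
                np.testing.assert_array_equal(occ[:s, :s, :s], sub)
                # center child block is empty
                assert not occ[s:2 * s, s:2 * s, s:2 * s].any()

    def test_exact_occupied_counts(self):
        for kind in ("random_dust", "uniform_points", "thresholded_field"):
            m = generate_phantom(PhantomSpec(kind, 24, occupancy=0.25, seed=3))
            assert m.n_occupied == round(0.25 * 24**3)

    def test_determinism_byte_identical(self):
        a = generate_phantom(PhantomSpec("thresholded_field", 24, seed=11))
        b = generate_phantom(PhantomSpec("thresholded_field", 24, seed=11))
        assert a.occupancy.tobytes() == b.occupancy.tobytes()
        c = generate_phantom(PhantomSpec("thresholded_field", 24, seed=12))
        assert a.occupancy.tobytes() != c.occupancy.tobytes()

    def test_plane_and_line(self):
        plane = generate_phantom(PhantomSpec("plane", 16))
        assert plane.n_occupied == 16 * 16
        line = generate_phantom(PhantomSpec("line_points", 16))
        assert line.n_occupied == 16


class TestPairedVolumes:
    DUST = PhantomSpec("random_dust", 32, occupancy=0.875, seed=0)

    def test_zero_shift_identity(self):
        spec = PairedEffectSpec(base=self.DUST, lacunarity_shift=0.0, seed=1)
        pre, post = generate_paired_volumes(spec)
        assert np.array_equal(pre.occupancy, post.occupancy)
        assert pre.occupancy is not post.occupancy

    def test_positive_shift_on_thresholded_field(self):
        base = PhantomSpec("thresholded_field", 48, occupancy=0.15,
                           correlation_length=0.75, seed=0)
        spec = PairedEffectSpec(base=base, lacunarity_shift=0.01, seed=2)
        pre, post = generate_paired_volumes(spec)
        d_lac = lacunarity(post)[0] - lacunarity(pre)[0]
        assert d_lac > 0.01
        d_box = box_counting_dimension(post)[0] - box_counting_dimension(pre)[0]
        assert abs(d_box) <= spec.preserve_boxfd_tol

    def test_negative_shift(self):
        spec = PairedEffectSpec(base=self.DUST, lacunarity_shift=-2e-4, seed=3)
        pre, post = generate_paired_volumes(spec)
        assert lacunarity(post)[0] - lacunarity(pre)[0] <= -2e-4

    def test_occupancy_count_preserved(self):
        spec = PairedEffectSpec(base=self.DUST, lacunarity_shift=2e-4, seed=4)
        pre, post = generate_paired_volumes(spec)
        assert pre.n_occupied == post.n_occupied

    def test_determinism(self):
        spec = PairedEffectSpec(base=self.DUST, lacunarity_shift=2e-4, seed=5)
        a = generate_paired_volumes(spec)
        b = generate_paired_volumes(spec)
        for m1, m2 in zip(a, b):
            assert m1.occupancy.tobytes() == m2.occupancy.tobytes()

    def test_unreachable_shift_raises(self):
        spec = PairedEffectSpec(base=self.DUST, lacunarity_shift=50.0,
                                seed=6, max_retries=2)
        with pytest.raises(GenerationError, match="not achievable"):
            generate_paired_volumes(spec)

    def test_deterministic_base_rejected(self):
        with pytest.raises(ConfigurationError):
            PairedEffectSpec(base=PhantomSpec("filled_cube", 16),
                             lacunarity_shift=0.01)


class TestCohorts:
    RULES = (
        PlantedRule("v20_pct", 17.5, p_above=1.0),
        PlantedRule("d_lacunarity", 0.03, p_above=1.0, p_below=0.0),
    )
    FEATURES = ("age", "v20_pct", "d_lacunarity")

    def _spec(self, **kw):
        defaults = dict(n_patients=60, feature_names=self.FEATURES,
                        tree_rules=self.RULES, seed=0)
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_labels_follow_planted_rules_exactly(self):
        df = generate_cohort(self._spec())
        expected = (df["v20_pct"] > 17.5) | (df["d_lacunarity"] > 0.03)
        assert (df["label"] == expected).all()

    def test_grades_consistent_with_labels(self):
        df = generate_cohort(self._spec())
        assert ((df["rp_grade"] >= 2) == df["label"]).all()
        assert df["rp_grade"].between(0, 3).all()

    def test_determinism_byte_identical(self):
        a = cohort_to_csv(generate_cohort(self._spec(seed=9)))
        b = cohort_to_csv(generate_cohort(self._spec(seed=9)))
        assert a == b
        assert a != cohort_to_csv(generate_cohort(self._spec(seed=10)))

    def test_label_noise_flips_labels(self):
        clean = generate_cohort(self._spec(seed=4))
        noisy = generate_cohort(self._spec(seed=4, label_noise=0.3))
        flips = (clean["label"] != noisy["label"]).sum()
        assert 0 < flips < len(clean)

    def test_noise_features_added(self):
        df = generate_cohort(self._spec(noise_features=2))
        assert {"noise_0", "noise_1"} <= set(df.columns)

    def test_apply_planted_rules_probabilities(self):
        df = generate_cohort(self._spec())
        p = apply_planted_rules(df, self.RULES)
        assert set(np.unique(p)) <= {0.0, 1.0}

    def test_validation(self):
        with pytest.raises(ConfigurationError, match="p_below"):
            self._spec(tree_rules=(PlantedRule("age", 50.0, p_above=1.0),))
        with pytest.raises(ConfigurationError, match="outside"):
            self._spec(tree_rules=(
                PlantedRule("v20_pct", 99.0, p_above=1.0, p_below=0.0),))
        with pytest.raises(ConfigurationError):
            self._spec(n_patients=1)
        with pytest.raises(ConfigurationError):
            self._spec(label_noise=0.6)
        with pytest.raises(ConfigurationError):
            PlantedRule("age", 50.0, p_above=1.5)

    def test_binary_features_are_binary(self):
        spec = CohortSpec(
            n_patients=40, feature_names=("sex", "smoking", "age"),
            tree_rules=(PlantedRule("age", 60.0, p_above=1.0, p_below=0.0),),
            seed=1,
        )
        df = generate_cohort(spec)
        assert set(df["sex"].unique()) <= {0.0, 1.0}
        assert set(df["smoking"].unique()) <= {0.0, 1.0}
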