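"""Tolerance score: merging, the raw/squashed profiles, kernels, smoothing."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfipred.variants import AlleleTable, CodingSequence, ProteinVariant
from vfipred.vfi import (
    compute_vfi,
    default_alpha,
    gaussian_kernel,
    merge_frequency_sources,
    position_tolerance,
    sliding_window_score,
    squash,
)


def _table(rows):
    return AlleleTable(
        pd.DataFrame(rows, columns=["variant", "allele_count", "total_alleles", "source"])
    )


class TestMerge:
    def test_larger_panel_wins(self):
        v = ProteinVariant("G", 2, "E")
        merged = merge_frequency_sources(
            _table(
                [
                    {"variant": v, "allele_count": 3, "total_alleles": 150_000, "source": "v2"},
                    {"variant": v, "allele_count": 5, "total_alleles": 280_000, "source": "v3"},
                ]
            )
        )
        assert len(merged) == 1
        row = merged.frame.iloc[0]
        assert row["source"] == "v3" and row["allele_count"] == 5

    def test_disjoint_sources_concatenate(self):
        rows = [
            {"variant": ProteinVariant("G", 2, "E"), "allele_count": 1, "total_alleles": 10, "source": "v2"},
            {"variant": ProteinVariant("A", 3, "T"), "allele_count": 1, "total_alleles": 20, "source": "v3"},
        ]
        assert len(merge_frequency_sources(_table(rows))) == 2

    def test_single_source_identity(self):
        rows = [
            {"variant": ProteinVariant("G", 2, "E"), "allele_count": 1, "total_alleles": 10, "source": "v2"},
        ]
        merged = merge_frequency_sources(_table(rows))
        pd.testing.assert_frame_equal(merged.frame, _table(rows).frame)

    def test_empty_input(self):
        empty = AlleleTable(
            pd.DataFrame(columns=["variant", "allele_count", "total_alleles", "source"])
        )
        assert len(merge_frequency_sources(empty)) == 0


class TestPositionTolerance:
    def test_direct_formula(self):
        # Trp codon TGG reaches 5 distinct missense residues; with summed
        # allele count 50 and N=1000: f = 50 / (1000 * 5) = 0.01
        cds = CodingSequence("TGG")
        rows = [
            {"variant": ProteinVariant("W", 1, "R"), "allele_count": 30, "total_alleles": 1000, "source": "v3"},
            {"variant": ProteinVariant("W", 1, "C"), "allele_count": 20, "total_alleles": 1000, "source": "v3"},
        ]
        f = position_tolerance(merge_frequency_sources(_table(rows)), cds, n_total=1000)
        assert f[0] == pytest.approx(0.01)

    def test_no_observations_zero(self):
        cds = CodingSequence("TGGAAA")
        rows = [
            {"variant": ProteinVariant("W", 1, "R"), "allele_count": 1, "total_alleles": 10, "source": "v3"},
        ]
        f = position_tolerance(merge_frequency_sources(_table(rows)), cds, n_total=10)
        assert f[1] == 0.0

    def test_saturation_identity(self):
        # every possible variant observed once each with N = 1 gives f = 1
        cds = CodingSequence("TGG")
        alts = ["R", "G", "S", "L", "C"]
        rows = [
            {"variant": ProteinVariant("W", 1, a), "allele_count": 1, "total_alleles": 1, "source": "v3"}
            for a in alts
        ]
        f = position_tolerance(merge_frequency_sources(_table(rows)), cds, n_total=1)
        assert f[0] == pytest.approx(1.0)

    def test_monotone_in_allele_count(self, gene):
        """Increasing one allele count never decreases f, F or VFI anywhere."""
        merged = merge_frequency_sources(gene.allele_table)
        f0 = position_tolerance(merged, gene.cds)
        bumped = merged.frame.copy()
        bumped.loc[bumped.index[0], "allele_count"] += 7
        f1 = position_tolerance(AlleleTable(bumped), gene.cds)
        assert (f1 >= f0 - 1e-15).all()
        alpha = default_alpha(f0)
        F0, F1 = squash(f0, alpha), squash(f1, alpha)
        assert (F1 >= F0 - 1e-15).all()
        v0 = compute_vfi(F0, sigma=2.0).values
        v1 = compute_vfi(F1, sigma=2.0).values
        assert (v1 >= v0 - 1e-12).all()


class TestSquash:
    def test_fixed_point_half(self):
        for alpha in (0.001, 0.1, 1.0, 37.5):
            assert squash(alpha, alpha) == pytest.approx(0.5)

    def test_zero_and_three_alpha(self):
        assert squash(0.0, 0.3) == 0.0
        assert squash(3 * 0.2, 0.2) == pytest.approx(0.75)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            squash(1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        f1=st.floats(0, 1e6, allow_nan=False),
        f2=st.floats(0, 1e6, allow_nan=False),
        alpha=st.floats(1e-6, 1e3, allow_nan=False),
    )
    def test_strictly_monotone_order_preserving(self, f1, f2, alpha):
        """The squash is a monotone bijection of [0, inf) onto [0, 1):
        rankings by f and by F agree."""
        F1, F2 = squash(f1, alpha), squash(f2, alpha)
        assert 0 <= F1 < 1 and 0 <= F2 < 1
        if f1 < f2:
            assert F1 < F2
        elif f1 == f2:
            assert F1 == F2


class TestKernel:
    def test_symmetry_and_normalization(self):
        for sigma in (0.5, 2.0, 5.0):
            k = gaussian_kernel(sigma, radius=8)
            assert np.allclose(k, k[::-1])
            assert abs(k.sum() - 1.0) < 1e-12

    def test_shape_ratio(self):
        # unnormalized K(2)/K(0) = exp(-0.5) for sigma = 2
        k = gaussian_kernel(2.0, radius=8)
        center = len(k) // 2
        assert k[center + 2] / k[center] == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.0, 4)


def _naive_smooth(F, kernel):
    """Double-loop truncated-and-renormalized convolution oracle."""
    radius = len(kernel) // 2
    out = np.zeros(len(F))
    for n in range(len(F)):
        num = den = 0.0
        for j in range(-radius, radius + 1):
            idx = n - j
            if 0 <= idx < len(F):
                w = kernel[j + radius]
                num += w * F[idx]
                den += w
        out[n] = num / den
    return out


class TestComputeVfi:
    def test_constant_preserved(self):
        out = compute_vfi(np.full(40, 0.3), sigma=3.0)
        assert np.allclose(out.values, 0.3)

    def test_impulse_reproduces_kernel(self):
        F = np.zeros(101)
        F[50] = 1.0
        out = compute_vfi(F, sigma=2.0, radius=8)
        k = gaussian_kernel(2.0, 8)
        assert np.allclose(out.values[42:59], k, atol=1e-12)

    def test_oracle_equivalence_random_profiles(self, rng):
        """<= 1e-12 agreement with the naive double-loop oracle on 100
        random profiles."""
        for _ in range(100):
            L = int(rng.integers(5, 60))
            F = rng.random(L)
            sigma = float(rng.uniform(0.5, 4.0))
            radius = int(rng.integers(1, 10))
            out = compute_vfi(F, sigma=sigma, radius=radius)
            oracle = _naive_smooth(F, gaussian_kernel(sigma, radius))
            assert np.max(np.abs(out.values - oracle)) <= 1e-12

    def test_values_within_input_range(self, rng):
        F = rng.random(200)
        out = compute_vfi(F, sigma=2.0)
        assert out.values.min() >= F.min() - 1e-12
        assert out.values.max() <= F.max() + 1e-12

    def test_narrow_kernel_limit(self, rng):
        """As sigma -> 0 the smoothed profile converges to F element-wise."""
        F = rng.random(50)
        out = compute_vfi(F, sigma=1e-3, radius=1)
        assert np.allclose(out.values, F, atol=1e-9)


class TestSlidingWindow:
    def test_constant_input(self):
        assert np.allclose(sliding_window_score(np.full(50, 0.4), 31), 0.4)

    def test_window3_hand_convolution(self):
        F = np.zeros(6)
        F[0] = 1.0
        out = sliding_window_score(F, 3)
        assert out[0] == pytest.approx(1 / 2)
        assert out[1] == pytest.approx(1 / 3)
        assert out[2] == pytest.approx(0.0)

    def test_equals_uniform_kernel_substitution(self, rng):
        """The window baseline is smoothing with a flat kernel of equal support."""
        F = rng.random(80)
        out = sliding_window_score(F, 7)
        oracle = _naive_smooth(F, np.full(7, 1 / 7))
        assert np.allclose(out, oracle, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_score(np.ones(10), 4)
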