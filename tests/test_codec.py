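"""Codec contract: widths, losslessness, random access, offsets, sizes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import random_image
from ctpcodec import (
    CompressedImage,
    CorruptionError,
    DynamicImage,
    compress,
    compression_stats,
    compute_offsets,
    decompress,
    read_timeseries,
    read_voxel,
    required_bits,
    uncompressed_size_bits,
)

class TestRequiredBits:
    @pytest.mark.parametrize(
        "vmin,vmax,expected",
        [
            (46, 191, 8),     # vessel-like voxel spanning 145 HU
            (22, 72, 6),      # tissue voxel spanning 50 HU
            (0, 65535, 16),   # full 16-bit range
            (10, 10, 0),      # temporally constant
            (-32768, -32768, 0),
            (0, 1, 1),
            (0, 2, 2),
        ],
    )
    def test_worked_examples(self, vmin, vmax, expected):
        assert required_bits(vmin, vmax) == expected

    def test_rejects_inverted_range(self):
        with pytest.raises(ValueError):
            required_bits(5, 4)

    @settings(max_examples=200, derandomize=True)
    @given(
        vmin=st.integers(min_value=-32768, max_value=32767),
        span=st.integers(min_value=0, max_value=65535),
    )
    def test_matches_integer_ceil_log2(self, vmin, span):
        vmax = min(vmin + span, 65535)
        got = required_bits(vmin, vmax)
        r = vmax - vmin
        # independent ceil(log2(r+1)) by counting: smallest k with 2^k > r
        k = 0
        while (1 << k) <= r:
            k += 1
        assert got == k


class TestCompressDecompress:
    def test_single_voxel_worked_example(self):
        img = DynamicImage(np.array([10, 12, 11, 10], np.int16).reshape(4, 1, 1, 1))
        c = compress(img)
        assert list(c.C) == [10]
        assert list(c.B) == [2]
        assert c.D.bit_length == 8
        # deltas 0,2,1,0 packed 2 bits each, LSB-first
        assert [(int(c.D.words[0]) >> (2 * t)) & 3 for t in range(4)] == [0, 2, 1, 0]
        assert np.array_equal(decompress(c).data.reshape(-1), [10, 12, 11, 10])

    def test_constant_image_uses_zero_widths(self):
        img = DynamicImage(np.full((24, 2, 3, 4), -7, dtype=np.int16))
        c = compress(img)
        assert not c.B.any()
        assert c.D.bit_length == 0
        assert np.array_equal(decompress(c).data, img.data)

    def test_24_step_vessel_voxel_occupies_192_bits(self, rng):
        series = rng.integers(46, 192, size=24, dtype=np.int16)
        series[0], series[1] = 46, 191
        img = DynamicImage(series.reshape(24, 1, 1, 1))
        c = compress(img)
        assert list(c.B) == [8]
        assert c.D.bit_length == 24 * 8 == 192

    def test_roundtrip_on_extreme_random_image(self, rng):
        img = random_image(rng, 24, (3, 6, 5))
        out = decompress(compress(img))
        assert out.data.dtype == np.int16
        assert np.array_equal(out.data, img.data)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.sampled_from([1, 2, 24]),
        shape=st.tuples(
            st.integers(1, 3), st.integers(1, 6), st.integers(1, 6)
        ),
        data=st.data(),
    )
    def test_losslessness_property(self, n, shape, data):
        arr = data.draw(
            hnp.arrays(
                np.int16,
                (n, *shape),
                elements=st.integers(min_value=-32768, max_value=32767),
            )
        )
        img = DynamicImage(arr)
        assert np.array_equal(decompress(compress(img)).data, arr)

    def test_chunked_compression_is_bit_identical(self, rng):
        img = random_image(rng, 5, (2, 7, 9))
        ref = compress(img)
        for chunk in (1, 3, 17, 1000):
            alt = compress(img, chunk_voxels=chunk)
            assert alt.D == ref.D
            assert np.array_equal(alt.C, ref.C)
            assert np.array_equal(alt.B, ref.B)
            assert np.array_equal(alt.O, ref.O)

    def test_metadata_survives_roundtrip(self):
        img = DynamicImage(
            np.zeros((3, 1, 2, 2), np.int16),
            acquisition_times=[0.0, 2.5, 5.0],
            voxel_spacing=(5.0, 0.5, 0.5),
        )
        out = decompress(compress(img))
        assert np.allclose(out.acquisition_times, [0.0, 2.5, 5.0])
        assert out.voxel_spacing == (5.0, 0.5, 0.5)

    def test_widening_range_never_shrinks_width(self, rng):
        base = rng.integers(-100, 100, size=(8, 1, 2, 2), dtype=np.int16)
        img = DynamicImage(base)
        widened = base.copy()
        widened[0] = widened[0] + np.int16(400)  # push max up everywhere
        c0, c1 = compress(img), compress(DynamicImage(widened))
        assert (c1.B >= c0.B).all()

    def test_decompress_detects_inconsistent_structure(self):
        img = DynamicImage(np.array([1, 3, 0, 9], np.int16).reshape(2, 1, 1, 2))
        c = compress(img)
        # widths inconsistent with the stored stream length
        broken = CompressedImage(
            C=c.C, B=c.B + 1, O=compute_offsets(c.B + 1, c.n),
            D=c.D, n=c.n, shape=c.shape,
        )
        with pytest.raises(CorruptionError):
            decompress(broken)
        # offsets that are not the prefix sum of n*B
        shifted = CompressedImage(
            C=c.C, B=c.B, O=c.O + np.uint64(1), D=c.D, n=c.n, shape=c.shape,
        )
        with pytest.raises(CorruptionError):
            decompress(shifted)

    def test_bad_input_validation(self):
        with pytest.raises(ValueError):
            DynamicImage(np.zeros((2, 2, 2), np.int16))  # 3D
        with pytest.raises(ValueError):
            DynamicImage(np.full((2, 1, 1, 1), 70000, np.int64))  # overflow
        with pytest.raises(ValueError):
            DynamicImage(
                np.zeros((2, 1, 1, 1), np.int16), acquisition_times=[3.0, 1.0]
            )


class TestRandomAccess:
    def test_constant_voxel_reads_base_at_every_t(self):
        img = DynamicImage(np.full((6, 1, 2, 2), 42, dtype=np.int16))
        c = compress(img)
        assert all(read_voxel(c, 0, 1, 1, t) == 42 for t in range(6))

    def test_single_voxel_example_time_1(self):
        img = DynamicImage(np.array([10, 12, 11, 10], np.int16).reshape(4, 1, 1, 1))
        c = compress(img)
        assert read_voxel(c, 0, 0, 0, 1) == 12

    def test_exhaustive_agreement_with_decompression(self, rng):
        img = random_image(rng, 4, (8, 8, 8))
        c = compress(img)
        full = decompress(c).data
        for t in range(4):
            for z in range(8):
                for y in range(8):
                    for x in range(8):
                        assert read_voxel(c, z, y, x, t) == full[t, z, y, x]

    def test_sampled_agreement_on_phantom(self, small_phantom, small_phantom_compressed):
        img, _ = small_phantom
        c = small_phantom_compressed
        full = img.data
        rng = np.random.default_rng(99)
        Z, Y, X = c.shape
        for _ in range(1000):
            t, z, y, x = (int(rng.integers(d)) for d in (c.n, Z, Y, X))
            assert read_voxel(c, z, y, x, t) == full[t, z, y, x]

    def test_timeseries_matches_decompressed_column(self, small_phantom, small_phantom_compressed):
        img, _ = small_phantom
        c = small_phantom_compressed
        for z, y, x in [(0, 0, 0), (1, 16, 16), (0, 10, 22), (1, 31, 31)]:
            assert np.array_equal(
                read_timeseries(c, z, y, x), img.data[:, z, y, x]
            )

    def test_out_of_range_indices_raise(self, small_phantom_compressed):
        c = small_phantom_compressed
        with pytest.raises(IndexError):
            read_voxel(c, 0, 0, 0, c.n)
        with pytest.raises(IndexError):
            read_voxel(c, 0, 0, c.shape[2], 0)
        with pytest.raises(IndexError):
            read_timeseries(c, c.shape[0], 0, 0)


class TestOffsets:
    def test_worked_example(self):
        assert list(compute_offsets(np.array([6, 8]), 24)) == [0, 144]

    def test_empty_and_first_element(self):
        assert compute_offsets(np.array([], dtype=np.uint8), 24).size == 0
        assert compute_offsets(np.array([9]), 24)[0] == 0

    def test_matches_loop_oracle(self, rng):
        B = rng.integers(0, 17, size=200).astype(np.uint8)
        n = 24
        acc, expected = 0, []
        for b in B:
            expected.append(acc)
            acc += n * int(b)
        assert list(compute_offsets(B, n)) == expected

    def test_stored_offsets_equal_prefix_sum(self, small_phantom_compressed):
        c = small_phantom_compressed
        assert np.array_equal(c.O, compute_offsets(c.B, c.n))
        assert c.D.bit_length == int(c.n) * int(c.B.astype(np.int64).sum())


class TestStats:
    def test_constant_image_overhead_is_56_bits_per_voxel(self):
        img = DynamicImage(np.zeros((24, 2, 4, 4), np.int16))
        stats = compression_stats(compress(img), offset_bits=32)
        m = 2 * 4 * 4
        assert stats.compressed_bits == 56 * m  # 16 + 32 + 8 + 0
        assert stats.uncompressed_bits == 384 * m
        assert stats.ratio == pytest.approx(384 / 56)

    def test_incompressible_image_ratio_below_one(self, rng):
        data = rng.integers(-32768, 32768, size=(2, 2, 4, 4), dtype=np.int16)
        data[0], data[1] = -32768, 32767  # force full-range voxels
        stats = compression_stats(compress(DynamicImage(data)))
        assert stats.ratio < 1

    def test_clinical_volume_geometry(self):
        mb = 2 ** 20
        one_volume = uncompressed_size_bits((320, 512, 512), 1) // 8
        assert one_volume == 160 * mb
        assert uncompressed_size_bits((320, 512, 512), 24) // 8 == 3840 * mb

    def test_histogram_counts_all_voxels(self, small_phantom_compressed):
        stats = compression_stats(small_phantom_compressed)
        assert stats.width_histogram.sum() == small_phantom_compressed.num_voxels
        expected = np.bincount(small_phantom_compressed.B, minlength=17)
        assert np.array_equal(stats.width_histogram, expected)

    def test_offset_convention_changes_only_offset_term(self, small_phantom_compressed):
        s32 = compression_stats(small_phantom_compressed, offset_bits=32)
        s64 = compression_stats(small_phantom_compressed, offset_bits=64)
        m = small_phantom_compressed.num_voxels
        assert s64.compressed_bits - s32.compressed_bits == 32 * m
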