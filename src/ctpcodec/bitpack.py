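"""Variable-width bit packing into 32-bit words.

Delta values of a compressed voxel time series are stored back to back in a
flat stream of 32-bit words, LSB-first: stream bit ``b`` lives in word
``b // 32`` at bit position ``b % 32``.  Because record widths never exceed
32 bits, any single read or write touches at most two adjacent words and
costs a fixed number of shift/mask operations, independent of stream size.

Values are packed little-endian-in-bits: bit ``k`` of a value maps to stream
bit ``offset + k``.  The stream is zero-padded to the next word boundary at
its end only; there is never padding between records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BitStream",
    "write_bits",
    "read_bits",
    "pack_sequence",
    "bits_to_stream",
    "stream_to_bits",
]

_WORD_BITS = 32


@dataclass
class BitStream:
    """A packed sequence of bits stored in 32-bit words, LSB-first.

    Attributes
    ----------
    words:
        Backing storage, dtype ``uint32``.
    bit_length:
        Number of valid bits.  Bits at positions >= ``bit_length`` are zero
        (canonical padding), which makes equal streams byte-identical.
    access_log:
        When set to a list, every :func:`read_bits` call appends the word
        indices it touched.  Used to verify the two-word access bound; left
        ``None`` in normal operation.
    """

    words: np.ndarray
    bit_length: int
    access_log: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.words = np.ascontiguousarray(self.words, dtype=np.uint32)
        if self.bit_length < 0:
            raise ValueError("bit_length must be non-negative")
        if self.bit_length > _WORD_BITS * self.words.size:
            raise ValueError(
                f"bit_length {self.bit_length} exceeds capacity "
                f"{_WORD_BITS * self.words.size}"
            )

    @classmethod
    def zeros(cls, bit_length: int) -> "BitStream":
        """An all-zero stream with capacity for `bit_length` bits."""
        nwords = (bit_length + _WORD_BITS - 1) // _WORD_BITS
        return cls(np.zeros(nwords, dtype=np.uint32), bit_length)

    @property
    def nbytes(self) -> int:
        return self.words.size * 4

    def copy(self) -> "BitStream":
        return BitStream(self.words.copy(), self.bit_length)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BitStream):
            return NotImplemented
        return self.bit_length == other.bit_length and np.array_equal(
            self.words, other.words
        )


def _check_width(width: int) -> None:
    if not 0 <= width <= _WORD_BITS:
        raise ValueError(f"width must be in 0..32, got {width}")


def write_bits(stream: BitStream, bit_offset: int, width: int, value: int) -> BitStream:
    """Write `value` into `stream` at `bit_offset` using `width` bits.

    Bits outside ``[bit_offset, bit_offset + width)`` are untouched; a width
    of 0 is a no-op.  The stream is modified in place and returned.
    """
    _check_width(width)
    if bit_offset < 0:
        raise IndexError("bit_offset must be non-negative")
    if width == 0:
        return stream
    value = int(value)
    if not 0 <= value < (1 << width):
        raise ValueError(f"value {value} does not fit in {width} bits")
    if bit_offset + width > _WORD_BITS * stream.words.size:
        raise IndexError(
            f"write of {width} bits at offset {bit_offset} exceeds capacity"
        )
    w, s = divmod(bit_offset, _WORD_BITS)
    mask = (1 << width) - 1
    lo = int(stream.words[w])
    lo &= ~((mask << s) & 0xFFFFFFFF)
    lo |= (value << s) & 0xFFFFFFFF
    stream.words[w] = lo
    spill = s + width - _WORD_BITS
    if spill > 0:
        hi = int(stream.words[w + 1])
        hi &= ~(mask >> (_WORD_BITS - s))
        hi |= value >> (_WORD_BITS - s)
        stream.words[w + 1] = hi
    return stream


def read_bits(stream: BitStream, bit_offset: int, width: int) -> int:
    """Read the `width`-bit unsigned value at `bit_offset`.

    Touches at most two words; constant number of operations regardless of
    stream size.  Width 0 returns 0.
    """
    _check_width(width)
    if bit_offset < 0:
        raise IndexError("bit_offset must be non-negative")
    if width == 0:
        return 0
    if bit_offset + width > stream.bit_length:
        raise IndexError(
            f"read of {width} bits at offset {bit_offset} exceeds "
            f"bit_length {stream.bit_length}"
        )
    w, s = divmod(bit_offset, _WORD_BITS)
    if stream.access_log is not None:
        stream.access_log.append(w)
    value = int(stream.words[w]) >> s
    if s + width > _WORD_BITS:
        if stream.access_log is not None:
            stream.access_log.append(w + 1)
        value |= int(stream.words[w + 1]) << (_WORD_BITS - s)
    return value & ((1 << width) - 1)


def pack_sequence(values, width: int) -> BitStream:
    """Pack a sequence of unsigned integers at a fixed width.

    Value ``i`` occupies stream bits ``[i*width, (i+1)*width)``; the result
    has ``bit_length == width * len(values)``.  A 24-step voxel whose deltas
    need 6 bits therefore packs to 144 bits, and one needing 8 bits to 192.
    """
    _check_width(width)
    values = np.asarray(values, dtype=np.uint64)
    if width == 0:
        return BitStream.zeros(0)
    if values.size and int(values.max()) >= (1 << width):
        raise ValueError(f"values do not fit in {width} bits")
    bits = (
        (values[:, None] >> np.arange(width, dtype=np.uint64)) & np.uint64(1)
    ).astype(np.uint8)
    return bits_to_stream(bits.reshape(-1))


def bits_to_stream(bits: np.ndarray) -> BitStream:
    """Pack a flat 0/1 array (bit ``b`` of the stream at index ``b``)."""
    bits = np.asarray(bits, dtype=np.uint8)
    packed = np.packbits(bits, bitorder="little")
    pad = (-packed.size) % 4
    if pad:
        packed = np.concatenate([packed, np.zeros(pad, dtype=np.uint8)])
    words = packed.view("<u4")
    return BitStream(words, int(bits.size))


def stream_to_bits(stream: BitStream) -> np.ndarray:
    """Unpack a stream into a flat uint8 array of its valid bits."""
    raw = np.ascontiguousarray(stream.words).view(np.uint8)
    if stream.words.dtype.byteorder == ">":  # pragma: no cover - LE hosts
        raw = stream.words.byteswap().view(np.uint8)
    return np.unpackbits(raw, count=stream.bit_length, bitorder="little")
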