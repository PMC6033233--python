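"""Two-bit nucleotide packing and bit-parallel mismatch counting.

Every target site in the database is held in a single 64-bit word:

    [ suffix bases | PAM bases | 16-bit occurrence count ]

with two bits per base (A=00, C=01, G=10, T=11), the first base of the
suffix in the most significant slot.  The *suffix* is the protospacer with
its bin prefix removed; the prefix itself is implicit in the bin the word
is stored in, which is what lets a site of up to 24 bases (plus the prefix)
fit next to a 16-bit count.  Genomic positions are packed into a second
64-bit word: 24 bits of contig index, 39 bits of offset, 1 strand bit.

Mismatch counting XORs two sequence words, folds each 2-bit slot to a
single indicator bit, masks out the PAM and count slots, and population
counts — a handful of register operations instead of a character loop.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_TO_BASE = dict(enumerate(BASES))

#: occurrence counts saturate here instead of wrapping
COUNT_MAX = 0xFFFF
COUNT_BITS = 16

#: alternating 01 bits, used to fold 2-bit slots to single indicators
_LOW_BITS = 0x5555555555555555

MAX_ENCODED_BASES = 24

# position word layout: contig 24 bits | offset 39 bits | strand 1 bit
_OFFSET_BITS = 39
_CONTIG_BITS = 24
_MAX_OFFSET = (1 << _OFFSET_BITS) - 1
_MAX_CONTIG = (1 << _CONTIG_BITS) - 1


class EncodingError(ValueError):
    """Raised when a sequence cannot be packed into two bits per base."""


def encode_bases(seq: str) -> int:
    """Pack ``seq`` (A/C/G/T only, <= 24 bases) into an integer, first base
    in the most significant 2-bit slot.
    """
    if len(seq) > MAX_ENCODED_BASES:
        raise EncodingError(
            f"cannot encode {len(seq)} bases; limit is {MAX_ENCODED_BASES}"
        )
    word = 0
    for i, base in enumerate(seq):
        code = BASE_TO_CODE.get(base)
        if code is None:
            raise EncodingError(
                f"non-ACGT base {base!r} at offset {i} of {seq!r}"
            )
        word = (word << 2) | code
    return word


def decode_bases(word: int, length: int) -> str:
    """Inverse of :func:`encode_bases`; ``length`` bases are recovered."""
    out = []
    for slot in range(length - 1, -1, -1):
        out.append(CODE_TO_BASE[(word >> (2 * slot)) & 0b11])
    return "".join(out)


def comparison_mask(suffix_len: int, pam_len: int) -> int:
    """Mask with ``11`` in every protospacer-suffix slot of a target word.

    PAM slots and the count field are zero so that PAM degeneracy and
    occurrence tallies never contribute to a mismatch count.
    """
    seq_mask = (1 << (2 * suffix_len)) - 1
    return seq_mask << (2 * pam_len + COUNT_BITS)


def count_mismatches(a: int, b: int, mask: int) -> int:
    """Hamming distance between two packed words over the masked base slots."""
    x = (a ^ b) & mask
    folded = (x | (x >> 1)) & _LOW_BITS
    return folded.bit_count()


def count_mismatches_array(a, b, mask: int) -> np.ndarray:
    """Vectorised :func:`count_mismatches` over numpy uint64 arrays."""
    a = np.asarray(a, dtype=np.uint64)
    b = np.asarray(b, dtype=np.uint64)
    m = np.uint64(mask)
    x = (a ^ b) & m
    folded = (x | (x >> np.uint64(1))) & np.uint64(_LOW_BITS)
    return np.bitwise_count(folded).astype(np.int64)


def pack_target(suffix: str, pam: str, count: int = 0) -> int:
    """Pack a (suffix, PAM, count) triple into one 64-bit target word."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if 2 * (len(suffix) + len(pam)) + COUNT_BITS > 64:
        raise EncodingError(
            f"suffix ({len(suffix)}) + PAM ({len(pam)}) bases do not fit a "
            f"64-bit word beside a {COUNT_BITS}-bit count"
        )
    seq_word = encode_bases(suffix + pam)
    return (seq_word << COUNT_BITS) | min(count, COUNT_MAX)


def unpack_target(word: int, suffix_len: int, pam_len: int) -> tuple[str, str, int]:
    """Recover the (suffix, PAM, count) triple from a target word."""
    count = word & COUNT_MAX
    seq = decode_bases(word >> COUNT_BITS, suffix_len + pam_len)
    return seq[:suffix_len], seq[suffix_len:], count


def target_count(word: int) -> int:
    return word & COUNT_MAX


def set_target_count(word: int, count: int) -> int:
    """Return ``word`` with its count field replaced (saturating at 65535)."""
    return (word & ~COUNT_MAX) | min(count, COUNT_MAX)


def saturating_add(count: int, delta: int = 1) -> int:
    return min(count + delta, COUNT_MAX)


def split_prefix(
    site: str, prefix_len: int, pam_len: int, pam_side: str = "three_prime"
) -> tuple[str, int]:
    """Split a full site string into its bin prefix and an encoded target word.

    The prefix is the first ``prefix_len`` bases of the *protospacer* (not of
    the raw site string: for a 5'-PAM enzyme the PAM precedes the protospacer).
    The returned word carries suffix + PAM with a zero count; together with
    the prefix and the enzyme geometry it reconstructs the full site exactly.
    """
    if pam_side == "three_prime":
        protospacer, pam = site[: len(site) - pam_len], site[len(site) - pam_len:]
    elif pam_side == "five_prime":
        pam, protospacer = site[:pam_len], site[pam_len:]
    else:
        raise ValueError(f"unknown pam_side {pam_side!r}")
    if prefix_len >= len(protospacer):
        raise ValueError(
            f"prefix_len {prefix_len} must be shorter than the protospacer "
            f"({len(protospacer)} bases)"
        )
    prefix = protospacer[:prefix_len]
    suffix = protospacer[prefix_len:]
    return prefix, pack_target(suffix, pam, 0)


def join_prefix(
    prefix: str, word: int, suffix_len: int, pam_len: int,
    pam_side: str = "three_prime",
) -> str:
    """Inverse of :func:`split_prefix`: rebuild the full site string."""
    suffix, pam, _ = unpack_target(word, suffix_len, pam_len)
    if pam_side == "three_prime":
        return prefix + suffix + pam
    return pam + prefix + suffix


def encode_position(contig_index: int, offset: int, strand: str) -> int:
    """Pack a genomic location (0-based forward-strand start of the full
    site) into one 64-bit word."""
    if not 0 <= contig_index <= _MAX_CONTIG:
        raise ValueError(f"contig index {contig_index} exceeds 24 bits")
    if not 0 <= offset <= _MAX_OFFSET:
        raise ValueError(f"offset {offset} exceeds 39 bits")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return (contig_index << (_OFFSET_BITS + 1)) | (offset << 1) | (strand == "-")


def decode_position(word: int) -> tuple[int, int, str]:
    """Inverse of :func:`encode_position`: (contig index, offset, strand)."""
    strand = "-" if word & 1 else "+"
    offset = (word >> 1) & _MAX_OFFSET
    contig = word >> (_OFFSET_BITS + 1)
    return contig, offset, strand
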