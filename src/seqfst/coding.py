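"""String-level helpers and rate calculators for the DNA storage codes.

The machines in :mod:`seqfst.presets` define the codes; this module wraps
them for everyday use (encode a bit string to DNA, decode DNA back to
bits, Hamming-protect a message through a noisy channel) and provides the
small information-theoretic calculators for their efficiency: expansion
factors of radix converters, the Shannon content of repeat-free DNA, and
the best bit-batching ratios.
"""

from __future__ import annotations

import math

from . import algebra, decode, presets


# ------------------------------------------------------------ rate calculators

def expansion_factor(n_in: int, radix_in: int, n_out: int, radix_out: int) -> float:
    """Inefficiency of a batched radix converter mapping ``n_in`` digits of
    base ``radix_in`` to ``n_out`` digits of base ``radix_out``: the ratio
    of the information capacity consumed on the output side to the
    information carried by the input batch,

        (n_out * log radix_out) / (n_in * log radix_in).

    1.0 is a perfect converter; the 3-bit-to-2-trit stage gives
    log 9 / log 8 ~ 1.06 and the trit-to-repeat-free-base stage
    log 4 / log 3 ~ 1.26.
    """
    return (n_out * math.log(radix_out)) / (n_in * math.log(radix_in))


def binary_to_ternary_inefficiency() -> float:
    """log 9 / log 8: the batched 3-bit -> 2-trit stage's overhead."""
    return expansion_factor(3, 2, 2, 3)


def ternary_to_dna_inefficiency() -> float:
    """log 4 / log 3: repeat-free DNA versus unconstrained DNA."""
    return expansion_factor(1, 3, 1, 4)


def storage_code_inefficiency() -> float:
    """Total overhead of the composed binary -> repeat-free-DNA code
    relative to the 2-bits-per-nucleotide Shannon limit: the product of
    the stage inefficiencies, which works out to exactly 4/3."""
    return binary_to_ternary_inefficiency() * ternary_to_dna_inefficiency()


def repeat_free_bits_per_symbol(alphabet_size: int = 4) -> float:
    """Shannon information content of a repeat-free sequence: with k
    symbols and no adjacent repeats, k-1 choices per position, hence
    log2(k-1) bits/symbol (log2 3 ~ 1.58 for DNA)."""
    return math.log2(alphabet_size - 1)


def best_batch_ratio(bits: int) -> tuple[int, float]:
    """Smallest trit count whose 3^t values cover 2^bits batch values, and
    the resulting bits-per-trit ratio.  Batching 3 bits gives 3/2; no
    batch size improves on that until 11 bits, where 2^11 = 2048 fits in
    3^7 = 2187 and the ratio reaches 11/7 ~ 1.57."""
    trits = 1
    while 3 ** trits < 2 ** bits:
        trits += 1
    return trits, bits / trits


# ------------------------------------------------------------- storage code

def _check_bits(bits: str) -> None:
    if not set(bits) <= {"0", "1"}:
        raise ValueError(f"message must be a bit string, got {bits!r}")


def encode_bits(bits: str, with_eof: bool = True) -> str:
    """Encode a binary message as repeat-free DNA.

    With the end-of-message marker, messages are zero-padded up to a
    multiple of 3 bits, and the padded batches are followed by the marker
    pair of trits (two nucleotides); keep the original bit length around
    to strip the padding after decoding.  Without the marker, the length
    must already be a multiple of 3.
    """
    _check_bits(bits)
    if with_eof:
        pad = (-len(bits)) % 3
        bits = bits + "0" * pad
    elif len(bits) % 3:
        raise ValueError("without the end-of-message marker the bit length "
                         "must be a multiple of 3")
    code = presets.storage_code(with_eof)
    dna, lw = decode.viterbi_output(code, bits)
    if dna is None:
        raise ValueError(f"message {bits!r} is not encodable")
    return dna


def decode_dna(dna: str, n_bits: int | None = None, with_eof: bool = True) -> str:
    """Decode repeat-free DNA back to bits (the transpose machine's best
    output).  ``n_bits`` strips the encoder's zero padding."""
    code = algebra.transpose(presets.storage_code(with_eof))
    bits, lw = decode.viterbi_output(code, dna)
    if bits is None:
        raise ValueError(f"{dna!r} is not in the code's image")
    if n_bits is not None:
        if n_bits > len(bits):
            raise ValueError(f"decoded only {len(bits)} bits, cannot take {n_bits}")
        bits = bits[:n_bits]
    return bits


# -------------------------------------------------------------- parity code

def hamming_encode(bits: str) -> str:
    """Hamming(7,4)-encode a message whose length is a multiple of 4."""
    _check_bits(bits)
    if len(bits) % 4:
        raise ValueError("Hamming(7,4) input length must be a multiple of 4")
    out, lw = decode.viterbi_output(presets.hamming74(), bits)
    if out is None:
        raise ValueError(f"message {bits!r} is not encodable")
    return out


def hamming_decode(received: str, q: float = 0.05) -> str:
    """Maximum-likelihood decode of a (possibly corrupted) Hamming(7,4)
    stream through a bit-flip channel with flip probability q: the best
    path through the transposed encoder-plus-channel machine.  Corrects
    any single flipped bit per 7-bit block when q < 0.5."""
    _check_bits(received)
    if len(received) % 7:
        raise ValueError("received length must be a multiple of 7")
    noisy = algebra.compose(presets.hamming74(), presets.bitflip_channel(q))
    bits, lw = decode.viterbi_output(algebra.transpose(noisy), received)
    if bits is None:
        raise ValueError(f"{received!r} cannot be decoded")
    return bits
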