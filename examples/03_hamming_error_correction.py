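"""Protect a message with a Hamming(7,4) parity machine and decode through
a noisy bit-flip channel.

The encoder and channel are both machines, so the decoder is simply the
best path through the transpose of their composition.
"""

from seqfst import coding

data = "1011" * 4
codeword = coding.hamming_encode(data)
print(f"data {data} -> codeword {codeword}")

# flip one bit in each 7-bit block
corrupted = "".join(
    block[:3] + ("1" if block[3] == "0" else "0") + block[4:]
    for block in (codeword[i:i + 7] for i in range(0, len(codeword), 7)))
decoded = coding.hamming_decode(corrupted, q=0.05)
print(f"corrupted {corrupted}")
print(f"decoded   {decoded} (matches original: {decoded == data})")
# every single-bit error per block is corrected by maximum-likelihood
# decoding as long as the flip probability is below one half
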