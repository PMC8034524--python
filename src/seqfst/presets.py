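"""Preset machine constructors.

Ready-made machines for common sequence-analysis and coding tasks:
sequence generators/recognizers, restricted regular expressions, DNA-to-
RNA conversion, the repeat-free DNA storage code (binary-to-ternary and
ternary-to-DNA factors, with an end-of-message marker), Hamming(7,4)
parity coding and a bit-flip channel, symmetric context-independent and
asymmetric context-dependent sequencing-error models, protein-to-codon
translation, CTC merge-repeats recognizers for neural-network output
matrices, the Jukes-Cantor substitution model, and a k-mer-avoiding
recognizer built from a de Bruijn graph.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Machine, ParamModel, machine, transition
from .expr import Param, as_expr
from . import algebra
from .normalize import tidy

DNA = ("A", "C", "G", "T")
BITS = ("0", "1")
TRITS = ("0", "1", "2")


# ---------------------------------------------------------------- sequences

def generator(seq: str, alphabet: Iterable[str] | None = None) -> Machine:
    """A generator emitting exactly ``seq`` with weight 1 (empty input
    alphabet).  The output alphabet defaults to the distinct symbols of
    the sequence."""
    if alphabet is None:
        alphabet = sorted(set(seq))
    alphabet = tuple(alphabet)
    if not set(seq) <= set(alphabet):
        raise ValueError(f"sequence {seq!r} uses symbols outside {alphabet!r}")
    n = len(seq)
    states = [f"s{i}" for i in range(n + 1)]
    trans = [transition(f"s{i}", None, seq[i], f"s{i+1}", 1.0) for i in range(n)]
    return machine((), alphabet, states, trans)


def recognizer(seq: str, alphabet: Iterable[str] | None = None) -> Machine:
    """A recognizer accepting exactly ``seq`` with weight 1: the transpose
    of :func:`generator`."""
    return algebra.transpose(generator(seq, alphabet))


def epsilon_machine(input_alphabet: Iterable[str] = (),
                    output_alphabet: Iterable[str] = ()) -> Machine:
    """The single-state machine: weight 1 on the empty pair, 0 elsewhere."""
    return machine(tuple(input_alphabet), tuple(output_alphabet), ["s0"], [])


# ----------------------------------------------------------- regular expressions

def regex_machine(pattern: str, alphabet: Iterable[str] = DNA) -> Machine:
    """Recognizer for a restricted regular expression.

    Supported syntax: literals, character classes ``[..]``, wildcard
    ``.``, postfix ``*``, ``+``, ``?``, alternation ``|`` and grouping
    ``(..)``.  Accepted strings get weight 1 provided the pattern is
    unambiguous (each string matches one way).
    """
    alphabet = tuple(alphabet)
    pos = 0

    def error(msg: str):
        raise ValueError(f"malformed pattern at position {pos}: {msg} in {pattern!r}")

    def parse_alt() -> Machine:
        nonlocal pos
        branches = [parse_seq()]
        while pos < len(pattern) and pattern[pos] == "|":
            pos += 1
            branches.append(parse_seq())
        out = branches[0]
        for b in branches[1:]:
            out = algebra.add(out, b)
        return out

    def parse_seq() -> Machine:
        nonlocal pos
        out = epsilon_machine(alphabet, ())
        while pos < len(pattern) and pattern[pos] not in "|)":
            out = algebra.concat(out, parse_rep())
        return out

    def parse_rep() -> Machine:
        nonlocal pos
        atom = parse_atom()
        while pos < len(pattern) and pattern[pos] in "*+?":
            op = pattern[pos]
            pos += 1
            if op == "*":
                atom = algebra.kleene_star(atom)
            elif op == "+":
                atom = algebra.concat(atom, algebra.kleene_star(atom))
            else:
                atom = algebra.add(atom, epsilon_machine(alphabet, ()))
        return atom

    def class_machine(chars: Sequence[str]) -> Machine:
        out = recognizer(chars[0], alphabet)
        for c in chars[1:]:
            out = algebra.add(out, recognizer(c, alphabet))
        return out

    def parse_atom() -> Machine:
        nonlocal pos
        if pos >= len(pattern):
            error("unexpected end of pattern")
        c = pattern[pos]
        if c == "(":
            pos += 1
            inner = parse_alt()
            if pos >= len(pattern) or pattern[pos] != ")":
                error("unbalanced parenthesis")
            pos += 1
            return inner
        if c == "[":
            close = pattern.find("]", pos + 1)
            if close < 0:
                error("unterminated character class")
            chars = pattern[pos + 1:close]
            if not chars:
                error("empty character class")
            for ch in chars:
                if ch not in alphabet:
                    error(f"symbol {ch!r} not in alphabet")
            pos = close + 1
            return class_machine(list(dict.fromkeys(chars)))
        if c == ".":
            pos += 1
            return class_machine(list(alphabet))
        if c in "*+?|)":
            error(f"unexpected operator {c!r}")
        if c not in alphabet:
            error(f"symbol {c!r} not in alphabet")
        pos += 1
        return recognizer(c, alphabet)

    out = parse_alt()
    if pos != len(pattern):
        error("trailing input")
    return tidy(out)


# ------------------------------------------------------------------ DNA/RNA

def dna_to_rna() -> Machine:
    """Single-state transducer copying DNA to RNA: A->A, C->C, G->G, T->U."""
    pairs = {"A": "A", "C": "C", "G": "G", "T": "U"}
    trans = [transition("s", d, r, "s", 1.0) for d, r in pairs.items()]
    return machine(DNA, ("A", "C", "G", "U"), ["s"], trans)


# ------------------------------------------------------------- storage code

def binary_to_ternary(with_eof: bool = True) -> Machine:
    """Binary-to-ternary converter batching three bits into two trits.

    A 3-bit batch with value v (most-significant bit first) emits the
    two-trit base-3 representation (v div 3, v mod 3); since v <= 7 the
    aligned trit pair "22" never arises from data, and with ``with_eof``
    it is emitted once at end of input as the end-of-message marker.
    Without the marker, inputs whose length is not a multiple of 3 have
    weight 0.
    """
    states = ["r"]
    trans = []
    for a in BITS:
        states.append(f"b{a}")
        trans.append(transition("r", a, None, f"b{a}", 1.0))
        for b in BITS:
            states.append(f"b{a}{b}")
            trans.append(transition(f"b{a}", b, None, f"b{a}{b}", 1.0))
    for e in TRITS:
        states.append(f"e{e}")
        trans.append(transition(f"e{e}", None, e, "r", 1.0))
    for a, b, c in itertools.product(BITS, repeat=3):
        v = int(a + b + c, 2)
        hi, lo = divmod(v, 3)
        trans.append(transition(f"b{a}{b}", c, str(hi), f"e{lo}", 1.0))
    if with_eof:
        states.append("f")
        trans.append(transition("r", None, "2", "f", 1.0))
        trans.append(transition("f", None, "2", "end", 1.0))
    else:
        trans.append(transition("r", None, None, "end", 1.0))
    states.append("end")
    return tidy(machine(BITS, TRITS, states, trans))


def ternary_to_dna() -> Machine:
    """Ternary-to-DNA converter whose output never repeats a base.

    From previous base b (the start state stands for previous base T),
    trit t emits the t-th base, in alphabetical order, of the three bases
    other than b.  Five states: the start/previous-T state, one state per
    other previous base, and the end state.
    """
    prev_of = {"r": "T", "sA": "A", "sC": "C", "sG": "G"}
    states = ["r", "sA", "sC", "sG", "end"]
    trans = []
    for st, prev in prev_of.items():
        allowed = sorted(set(DNA) - {prev})
        for t_idx, base in enumerate(allowed):
            dst = "r" if base == "T" else f"s{base}"
            trans.append(transition(st, str(t_idx), base, dst, 1.0))
        trans.append(transition(st, None, None, "end", 1.0))
    return machine(TRITS, DNA, states, trans)


def storage_code(with_eof: bool = True) -> Machine:
    """The repeat-free DNA storage code: the matrix product of
    :func:`binary_to_ternary` and :func:`ternary_to_dna`.  Encoding maps a
    binary message to non-repeating DNA; decoding runs the transpose.
    See :mod:`seqfst.coding` for string-level encode/decode helpers."""
    return algebra.compose(binary_to_ternary(with_eof), ternary_to_dna())


# ------------------------------------------------------------- parity code

def _hamming_codeword(d: str) -> str:
    # codeword layout p1 p2 d1 p3 d2 d3 d4, even parity

    d1, d2, d3, d4 = (int(c) for c in d)
    p1 = d1 ^ d2 ^ d4
    p2 = d1 ^ d3 ^ d4
    p3 = d2 ^ d3 ^ d4
    return "".join(str(b) for b in (p1, p2, d1, p3, d2, d3, d4))


def hamming74() -> Machine:
    """Hamming(7,4) encoder: each 4-bit batch d1..d4 maps to the 7-bit
    codeword p1 p2 d1 p3 d2 d3 d4 with even parity (p1 covers positions
    1,3,5,7; p2 covers 2,3,6,7; p3 covers 4,5,6,7).  Input length must be
    a multiple of 4 (otherwise weight 0)."""
    states = ["r"]
    trans = []
    for k in range(1, 4):
        for bits in itertools.product(BITS, repeat=k):
            states.append("b" + "".join(bits))
    for a in BITS:
        trans.append(transition("r", a, None, f"b{a}", 1.0))
    for k in (1, 2):
        for bits in itertools.product(BITS, repeat=k):
            prefix = "".join(bits)
            for a in BITS:
                trans.append(transition(f"b{prefix}", a, None, f"b{prefix}{a}", 1.0))
    for bits in itertools.product(BITS, repeat=4):
        d = "".join(bits)
        cw = _hamming_codeword(d)
        chain = [f"c{d}.{i}" for i in range(1, 7)]
        states.extend(chain)
        trans.append(transition(f"b{d[:3]}", d[3], cw[0], chain[0], 1.0))
        for i in range(1, 6):
            trans.append(transition(chain[i - 1], None, cw[i], chain[i], 1.0))
        trans.append(transition(chain[5], None, cw[6], "r", 1.0))
    trans.append(transition("r", None, None, "end", 1.0))
    states.append("end")
    return tidy(machine(BITS, BITS, states, trans))


def bitflip_channel(q: float) -> Machine:
    """Memoryless binary symmetric channel: each bit passes with weight
    1-q and flips with weight q."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"flip probability must lie in [0, 1], got {q}")
    trans = [transition("s", a, b, "s", (1.0 - q) if a == b else q)
             for a in BITS for b in BITS]
    return machine(BITS, BITS, ["s"], trans)


# ------------------------------------------------------------ error models

def _default_sub(match: float = 0.91, mismatch: float = 0.03) -> dict[str, float]:
    return {f"sub_{a}{b}": (match if a == b else mismatch)
            for a in DNA for b in DNA}


def error_model_sci(params: Mapping[str, float] | None = None) -> Machine:
    """Symmetric context-independent sequencing-error model.

    A DNA-to-DNA transducer with one match, one insert and one delete
    state (plus start and end): matches weighted by a 4x4 substitution
    table ``sub_xy``, insertions and deletions sharing a single gap-open /
    gap-extend parameter pair (``gap_open``, ``gap_ext``).  Weights are
    symbolic over these named parameters, with numeric defaults that can
    be overridden via ``params``.
    """
    values = {"gap_open": 0.02, "gap_ext": 0.4, **_default_sub()}
    if params:
        values.update(params)
    states = ["start", "I", "D", "M", "end"]
    trans = [transition("start", None, None, "M", 1.0),
             transition("M", None, None, "end", 1.0),
             transition("I", None, None, "M", 1.0),
             transition("D", None, None, "M", 1.0)]
    for a in DNA:
        for b in DNA:
            trans.append(transition("M", a, b, "M", Param(f"sub_{a}{b}")))
    for b in DNA:
        trans.append(transition("M", None, b, "I", as_expr("gap_open") * 0.25))
        trans.append(transition("I", None, b, "I", as_expr("gap_ext") * 0.25))
    for a in DNA:
        trans.append(transition("M", a, None, "D", Param("gap_open")))
        trans.append(transition("D", a, None, "D", Param("gap_ext")))
    return machine(DNA, DNA, states, trans, ParamModel(values))


def error_model_acd(params: Mapping[str, float] | None = None) -> Machine:
    """Asymmetric context-dependent sequencing-error model.

    Match, insert and delete states are replicated once per dinucleotide
    flanking context (previous reference base x current reference base =
    16 contexts), giving 48 context states plus dedicated start and end
    states: 50 in total.  Each context carries its own substitution
    weights ``am_<prev><cur><obs>``, insertion weight ``ai_<prev><cur>``
    and deletion weight ``ad_<prev><cur>`` — insertions and deletions are
    parameterized separately (asymmetric) and every weight may depend on
    the flanking bases (context-dependent).  The reference is treated as
    left-padded with 'A' for the first position's context.
    """
    values: dict[str, float] = {}
    for p, c in itertools.product(DNA, repeat=2):
        for b in DNA:
            values[f"am_{p}{c}{b}"] = 0.85 if b == c else 0.03
        values[f"ai_{p}{c}"] = 0.03
        values[f"ad_{p}{c}"] = 0.03
    if params:
        values.update(params)

    contexts = list(itertools.product(DNA, repeat=2))
    states = ["start"]
    for p, c in contexts:
        states.extend([f"M{p}{c}", f"I{p}{c}", f"D{p}{c}"])
    states.append("end")

    def last_ref(state: str) -> str:
        return "A" if state == "start" else state[2]

    def ins_ctx(state: str) -> tuple[str, str]:
        return ("A", "A") if state == "start" else (state[1], state[2])

    trans = []
    sources = ["start"] + [s for s in states if s[0] in "MID"]
    for src in sources:
        L = last_ref(src)
        for c in DNA:
            for b in DNA:
                trans.append(transition(src, c, b, f"M{L}{c}", Param(f"am_{L}{c}{b}")))
            trans.append(transition(src, c, None, f"D{L}{c}", Param(f"ad_{L}{c}")))
        ip, ic = ins_ctx(src)
        for b in DNA:
            trans.append(transition(src, None, b, f"I{ip}{ic}",
                                    as_expr(f"ai_{ip}{ic}") * 0.25))
        trans.append(transition(src, None, None, "end", 1.0))
    return machine(DNA, DNA, states, trans, ParamModel(values))


# --------------------------------------------------------------- translation

def _standard_codon_map() -> dict[str, list[str]]:
    from Bio.Data import CodonTable
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out


def protein_to_codon(codon_weights: Mapping[str, Mapping[str, float]] | None = None,
                     ) -> Machine:
    """Transducer reading one amino acid and emitting one codon.

    ``codon_weights`` maps each amino acid to a distribution over its
    synonymous codons under the standard genetic code (default: uniform).
    Each codon is emitted through two intermediate states (one transition
    per nucleotide); composing with an error model yields a protein-to-
    noisy-DNA aligner.
    """
    aa_codons = _standard_codon_map()
    if codon_weights is None:
        codon_weights = {aa: {c: 1.0 / len(cs) for c in cs}
                         for aa, cs in aa_codons.items()}
    trans = []
    states = ["p"]
    for aa in sorted(codon_weights):
        if aa not in aa_codons:
            raise ValueError(f"unknown amino acid {aa!r}")
        dist = codon_weights[aa]
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"codon weights for {aa!r} sum to {total!r}, not 1")
        for codon, w in sorted(dist.items()):
            if codon not in aa_codons[aa]:
                raise ValueError(f"{codon!r} does not encode {aa!r}")
            s1, s2 = f"{aa}.{codon}.1", f"{aa}.{codon}.2"
            states.extend([s1, s2])
            trans.append(transition("p", aa, codon[0], s1, w))
            trans.append(transition(s1, None, codon[1], s2, 1.0))
            trans.append(transition(s2, None, codon[2], "p", 1.0))
    missing = sorted(set(aa_codons) - set(codon_weights))
    if missing:
        raise ValueError(f"codon weights missing for amino acids {missing}")
    trans.append(transition("p", None, None, "end", 1.0))
    states.append("end")
    aas = tuple(sorted(aa_codons))
    return machine(aas, DNA, states, trans)


# ----------------------------------------------------------------- CTC

def ctc_recognizer(prob_matrix, alphabet: Sequence[str] | None = None) -> Machine:
    """Recognizer over label sequences from per-frame symbol weights.

    ``prob_matrix`` is a (T, K+1) array of non-negative per-frame weights
    over ``alphabet`` plus a final blank column (or a DataFrame whose
    columns name the symbols and a ``blank`` column).  The weight of a
    label sequence y is the total weight of all length-T framewise paths
    that collapse to y under the CTC rule: merge adjacent repeats, then
    delete blanks.  States track (frame, previous frame symbol).
    """
    try:  # pandas DataFrame with named columns
        cols = list(prob_matrix.columns)
        if alphabet is None:
            alphabet = [c for c in cols if c.lower() != "blank"]
        order = list(alphabet) + [c for c in cols if c.lower() == "blank"]
        P = prob_matrix[order].to_numpy(dtype=float)
    except AttributeError:
        if alphabet is None:
            raise ValueError("alphabet is required for a plain array")
        P = np.asarray(prob_matrix, dtype=float)
    alphabet = tuple(alphabet)
    if P.ndim != 2 or P.shape[0] == 0 or P.shape[1] != len(alphabet) + 1:
        raise ValueError(f"probability matrix must be (T, {len(alphabet) + 1}) "
                         f"with the blank column last; got shape {P.shape}")
    if (P < 0).any():
        raise ValueError("probability matrix entries must be non-negative")
    T = P.shape[0]
    symbols = list(alphabet) + ["-"]  # '-' marks the blank in state names
    states = [f"t{t}.{s}" for t in range(T + 1) for s in symbols]
    trans = []
    for t in range(T):
        for last in symbols:
            src = f"t{t}.{last}"
            for k, c in enumerate(alphabet):
                w = float(P[t, k])
                if c == last:  # adjacent repeat: merged, consumes no label
                    trans.append(transition(src, None, None, f"t{t+1}.{c}", w))
                else:
                    trans.append(transition(src, c, None, f"t{t+1}.{c}", w))
            trans.append(transition(src, None, None, f"t{t+1}.-", float(P[t, -1])))
    for s in symbols:
        trans.append(transition(f"t{T}.{s}", None, None, "end", 1.0))
    states.append("end")
    m = machine(alphabet, (), states, trans)
    # start must be t0.-: reorder so the blank start state comes first
    start = "t0.-"
    ordered = [start] + [s for s in states if s != start]
    m = m.with_(states=tuple(ordered))
    return tidy(m)


# ------------------------------------------------------------- substitution

def jukes_cantor(t: float, rate: float = 1.0) -> Machine:
    """One-state DNA transducer with Jukes-Cantor substitution weights at
    divergence time t: same base 1/4 + 3/4 exp(-4 rate t / 3), different
    base 1/4 - 1/4 exp(-4 rate t / 3).  Rows sum to 1."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    e = np.exp(-4.0 * rate * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    trans = [transition("s", a, b, "s", same if a == b else diff)
             for a in DNA for b in DNA]
    return machine(DNA, DNA, ["s"], trans)


# ---------------------------------------------------------- de Bruijn codes

def kmer_avoiding_recognizer(k: int, prohibited: Iterable[str],
                             alphabet: Sequence[str] = DNA) -> Machine:
    """Recognizer accepting (weight 1) exactly the strings containing no
    prohibited k-mer.

    Built from the de Bruijn graph over (k-1)-mers with the transitions
    spelling prohibited k-mers deleted.  Useful via intersection for
    constraining storage codes to avoid restriction sites and similar
    motifs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alphabet = tuple(alphabet)
    prohibited = set(prohibited)
    for kmer in prohibited:
        if len(kmer) != k or not set(kmer) <= set(alphabet):
            raise ValueError(f"prohibited k-mer {kmer!r} is not a length-{k} "
                             f"word over {alphabet!r}")
    states: list[str] = []
    trans = []
    seen = set()
    stack = [""]
    seen.add("")
    while stack:
        ctx = stack.pop()
        states.append(f"[{ctx}]")
        for c in alphabet:
            word = ctx + c
            if len(word) >= k and word[-k:] in prohibited:
                continue
            nxt = word[-(k - 1):] if k > 1 else ""
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
            trans.append(transition(f"[{ctx}]", c, None, f"[{nxt}]", 1.0))
    states.sort(key=lambda s: (len(s), s))  # start "[]" first, deterministic
    for s in states:
        trans.append(transition(s, None, None, "end", 1.0))
    states.append("end")
    return tidy(machine(alphabet, (), states, trans))
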