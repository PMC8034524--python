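"""Serialization and standard-format readers.

Machines have a canonical JSON document format (validated structurally,
with JSON-pointer paths in error messages), and can be exported as
GraphViz dot text.  Sequence and matrix inputs come from FASTA (via
Biopython) and headed CSV (via pandas); profile HMMs are imported from
HMMER3 text files (parsed by pyhmmer) and turned into generator machines.

JSON machine document, version 1::

    {
      "schema_version": "1",
      "input_alphabet": ["A", ...],
      "output_alphabet": ["A", ...],
      "states": [
        {"id": "s0",
         "transitions": [{"to": "s1", "in": "A", "out": "C", "weight": 0.5}]},
        ...
      ],
      "params": {"values": {...}, "prob_groups": [[...]], "rates": [...]}
    }

An absent "in"/"out" field denotes epsilon.  A weight is a number, a
parameter-name string, or an operator object with exactly one of the keys
"+", "*", "-", "/", "pow" (lists of operands) or "exp", "log" (single
operand).
"""

from __future__ import annotations

import json
import warnings
from typing import Sequence, TextIO

import pandas as pd

from .core import Machine, ParamModel, Transition, machine
from .expr import Const, OPERATOR_KEYS, expr_from_json

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A machine document violates the schema; ``pointer`` locates the fault."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


# ------------------------------------------------------------- machine JSON

def machine_to_document(m: Machine) -> dict:
    by_src: dict[str, list[Transition]] = {s: [] for s in m.states}
    for t in m.transitions:
        by_src[t.src].append(t)
    states = []
    for s in m.states:
        trans = []
        for t in by_src[s]:
            rec: dict = {"to": t.dst}
            if t.inp is not None:
                rec["in"] = t.inp
            if t.out is not None:
                rec["out"] = t.out
            rec["weight"] = t.weight.to_json()
            trans.append(rec)
        states.append({"id": s, "transitions": trans})
    return {
        "schema_version": SCHEMA_VERSION,
        "input_alphabet": list(m.input_alphabet),
        "output_alphabet": list(m.output_alphabet),
        "states": states,
        "params": {
            "values": dict(sorted(m.params.values.items())),
            "prob_groups": [list(g) for g in m.params.prob_groups],
            "rates": list(m.params.rates),
        },
    }


def _check_weight(doc, pointer: str) -> None:
    if isinstance(doc, bool):
        raise SchemaError(pointer, "weight must not be a boolean")
    if isinstance(doc, (int, float)):
        if doc < 0:
            raise SchemaError(pointer, f"numeric weight {doc!r} is negative")
        return
    if isinstance(doc, str):
        if not doc:
            raise SchemaError(pointer, "parameter-name weight must be non-empty")
        return
    if isinstance(doc, dict):
        if len(doc) != 1:
            raise SchemaError(pointer, "weight operator object must have exactly one key")
        (op, arg), = doc.items()
        if op not in OPERATOR_KEYS:
            raise SchemaError(f"{pointer}/{op}", f"unknown weight operator {op!r}")
        if op in ("exp", "log"):
            _check_weight(arg, f"{pointer}/{op}")
        else:
            if not isinstance(arg, list) or len(arg) < 2:
                raise SchemaError(f"{pointer}/{op}",
                                  f"operator {op!r} requires a list of >= 2 operands")
            for i, a in enumerate(arg):
                _check_weight(a, f"{pointer}/{op}/{i}")
        return
    raise SchemaError(pointer, f"invalid weight {doc!r}")


def validate_document(doc) -> None:
    """Structural validation; raises :class:`SchemaError` with a JSON
    pointer to the first fault."""
    if not isinstance(doc, dict):
        raise SchemaError("", "machine document must be a JSON object")
    for key in ("schema_version", "input_alphabet", "output_alphabet", "states"):
        if key not in doc:
            raise SchemaError(f"/{key}", "required field is missing")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise SchemaError("/schema_version",
                          f"unsupported version {doc['schema_version']!r}")
    for key in ("input_alphabet", "output_alphabet"):
        alpha = doc[key]
        if not isinstance(alpha, list) or not all(
                isinstance(c, str) and len(c) == 1 for c in alpha):
            raise SchemaError(f"/{key}", "must be a list of single-character symbols")
    states = doc["states"]
    if not isinstance(states, list) or not states:
        raise SchemaError("/states", "must be a non-empty list")
    ids = set()
    for si, st in enumerate(states):
        if not isinstance(st, dict) or "id" not in st:
            raise SchemaError(f"/states/{si}", "state must be an object with an 'id'")
        if not isinstance(st["id"], str) or not st["id"]:
            raise SchemaError(f"/states/{si}/id", "must be a non-empty string")
        ids.add(st["id"])
        for ti, tr in enumerate(st.get("transitions", [])):
            ptr = f"/states/{si}/transitions/{ti}"
            if not isinstance(tr, dict) or "to" not in tr or "weight" not in tr:
                raise SchemaError(ptr, "transition must have 'to' and 'weight'")
            for lab in ("in", "out"):
                if lab in tr and not (isinstance(tr[lab], str) and len(tr[lab]) == 1):
                    raise SchemaError(f"{ptr}/{lab}", "label must be a single character")
            _check_weight(tr["weight"], f"{ptr}/weight")
    for si, st in enumerate(states):
        for ti, tr in enumerate(st.get("transitions", [])):
            if tr["to"] not in ids:
                raise SchemaError(f"/states/{si}/transitions/{ti}/to",
                                  f"undeclared state {tr['to']!r}")
    params = doc.get("params", {})
    if not isinstance(params, dict):
        raise SchemaError("/params", "must be an object")
    if not isinstance(params.get("values", {}), dict):
        raise SchemaError("/params/values", "must be an object")
    for gi, g in enumerate(params.get("prob_groups", [])):
        if not isinstance(g, list) or not all(isinstance(n, str) for n in g):
            raise SchemaError(f"/params/prob_groups/{gi}", "must be a list of names")
    if not isinstance(params.get("rates", []), list):
        raise SchemaError("/params/rates", "must be a list of names")


def machine_from_document(doc) -> Machine:
    validate_document(doc)
    params = doc.get("params", {})
    pm = ParamModel(params.get("values", {}),
                    tuple(tuple(g) for g in params.get("prob_groups", [])),
                    tuple(params.get("rates", [])))
    states = [st["id"] for st in doc["states"]]
    transitions = []
    for st in doc["states"]:
        for tr in st.get("transitions", []):
            transitions.append(Transition(st["id"], tr.get("in"), tr.get("out"),
                                          tr["to"], expr_from_json(tr["weight"])))
    return machine(doc["input_alphabet"], doc["output_alphabet"],
                   states, transitions, pm)


def dumps_machine(m: Machine) -> str:
    """Canonical serialization: sorted keys, 1-space indent, shortest
    round-trip decimals, trailing newline.  Stable byte-for-byte."""
    return json.dumps(machine_to_document(m), sort_keys=True, indent=1) + "\n"


def write_machine(m: Machine, path_or_file: str | TextIO) -> None:
    if hasattr(path_or_file, "write"):
        path_or_file.write(dumps_machine(m))
    else:
        with open(path_or_file, "w") as fh:
            fh.write(dumps_machine(m))


def read_machine(path_or_file: str | TextIO) -> Machine:
    if hasattr(path_or_file, "read"):
        doc = json.load(path_or_file)
    else:
        with open(path_or_file) as fh:
            doc = json.load(fh)
    return machine_from_document(doc)


def loads_machine(text: str) -> Machine:
    return machine_from_document(json.loads(text))


# ---------------------------------------------------------------- GraphViz

def export_graphviz(m: Machine) -> str:
    """Dot-format rendering: one node per state, one edge per transition
    labelled in/out with the epsilon glyph for an empty label."""
    def q(s: str) -> str:
        return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'

    lines = ["digraph machine {", "  rankdir=LR;"]
    for i, s in enumerate(m.states):
        shape = "doublecircle" if s == m.end else "circle"
        style = ' style=bold' if s == m.start else ""
        lines.append(f"  {q(s)} [shape={shape}{style}];")
    for t in m.transitions:
        label = f"{t.inp if t.inp is not None else 'ε'}/{t.out if t.out is not None else 'ε'}"
        w = t.weight.to_json()
        if w != 1.0:
            label += f" {json.dumps(w) if not isinstance(w, str) else w}"
        lines.append(f"  {q(t.src)} -> {q(t.dst)} [label={q(label)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------- sequences

def read_fasta(path_or_file: str | TextIO) -> list[tuple[str, str]]:
    """Read FASTA records as (name, uppercased sequence) pairs, in file
    order.  Duplicate names trigger a warning."""
    from Bio import SeqIO
    if hasattr(path_or_file, "read"):
        handle = path_or_file
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        with open(path_or_file) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    return out


def read_csv_matrix(path_or_file: str | TextIO) -> pd.DataFrame:
    """Read a per-position weight matrix from headed CSV.

    The header row names the alphabet symbols and the blank column (for
    CTC recognizers: e.g. ``A,C,G,T,blank``); rows are returned in file
    order.  A non-numeric cell is an error naming its row and column.
    """
    df = pd.read_csv(path_or_file, dtype=str, skipinitialspace=True)
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"non-numeric value {df[col][row]!r} at row {row}, "
                             f"column {col!r}")
        out[col] = converted.astype(float)
    return pd.DataFrame(out)


# ------------------------------------------------------------ HMMER import

_PLAN7 = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


def read_hmmer_profile(path: str) -> Machine:
    """Import a HMMER3 text profile as a generator machine.

    Parsing is delegated to pyhmmer; the stored negative-log emission and
    transition values become probabilities (exp(-v), with '*' meaning
    zero).  The machine has a begin state, a match/insert/delete block per
    profile column, and an end state; emissions ride on the transitions
    entering each match or insert state.
    """
    import pyhmmer

    with pyhmmer.plan7.HMMFile(path) as fh:
        hmm = fh.read()
    K = hmm.alphabet.K
    symbols = hmm.alphabet.symbols[:K]
    M = hmm.M
    me = [[float(hmm.match_emissions[k][a]) for a in range(K)] for k in range(M + 1)]
    ie = [[float(hmm.insert_emissions[k][a]) for a in range(K)] for k in range(M + 1)]
    tp = {name: [float(hmm.transition_probabilities[k][ci])
                 for k in range(M + 1)]
          for ci, name in enumerate(_PLAN7)}

    states = ["B", "I0"]
    for k in range(1, M + 1):
        states.extend([f"M{k}", f"I{k}", f"D{k}"])
    states.append("E")
    trans: list[Transition] = []

    def t_(src, inp, out, dst, w):
        if w > 0.0:
            trans.append(Transition(src, inp, out, dst, Const(w)))

    def emit_edge(src, dst, base_w, emissions):
        for a, sym in enumerate(symbols):
            t_(src, None, sym, dst, base_w * emissions[a])

    # begin block: node 0 owns B->M1 / B->I0 / B->D1 and the I0 loop
    emit_edge("B", "M1", tp["MM"][0], me[1])
    emit_edge("B", "I0", tp["MI"][0], ie[0])
    emit_edge("I0", "I0", tp["II"][0], ie[0])
    emit_edge("I0", "M1", tp["IM"][0], me[1])
    t_("B", None, None, "D1", tp["MD"][0])
    for k in range(1, M):
        emit_edge(f"M{k}", f"M{k+1}", tp["MM"][k], me[k + 1])
        emit_edge(f"M{k}", f"I{k}", tp["MI"][k], ie[k])
        emit_edge(f"I{k}", f"I{k}", tp["II"][k], ie[k])
        emit_edge(f"I{k}", f"M{k+1}", tp["IM"][k], me[k + 1])
        t_(f"M{k}", None, None, f"D{k+1}", tp["MD"][k])
        emit_edge(f"D{k}", f"M{k+1}", tp["DM"][k], me[k + 1])
        t_(f"D{k}", None, None, f"D{k+1}", tp["DD"][k])
    t_(f"M{M}", None, None, "E", tp["MM"][M])
    emit_edge(f"M{M}", f"I{M}", tp["MI"][M], ie[M])
    emit_edge(f"I{M}", f"I{M}", tp["II"][M], ie[M])
    t_(f"I{M}", None, None, "E", tp["IM"][M])
    t_(f"D{M}", None, None, "E", tp["DM"][M])

    from .normalize import tidy
    return tidy(machine((), tuple(symbols), states, trans))
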