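"""Synthetic probe sequences used to validate the selective demethylation.

The dually modified probe carries a cap-adjacent m6Am as its first
transcribed nucleotide and one internal m6A; the selective in vitro FTO
reaction must erase the former and spare the latter.  Modified bases are
written in bracket notation, e.g. ``(m6Am)GG...GG(m6A)CAUC...``.
"""

from __future__ import annotations

import re
from typing import Dict, Tuple

# Dually modified m6Am & m6A probe (cap omitted): the first A is the
# cap-adjacent m6Am, the internal modified A sits in a GGACU context.
DUAL_PROBE = (
    "(m6Am)GGAUAGCAGGCAUGGAAUCCUUCAAGACUAU"
    "CUACCUGUCCAGUAGCCUUCAGGAUCAUGCUGUCUGACUUGCUGG"
    "(m6A)CAUCAUUCUAGUGCCAUAACUUCAGC"
)

_MOD_RE = re.compile(r"\(([^)]+)\)")
_MOD_BASE = {"m6Am": "A", "m6A": "A", "Am": "A", "m7G": "G"}


def parse_modified_rna(seq: str) -> Tuple[str, Dict[int, str]]:
    """Split a bracket-annotated RNA string into sequence + modifications.

    Returns the plain RNA sequence and a dict mapping 0-based position
    to modification name.  Each ``(mod)`` token contributes one base.
    """
    plain = []
    mods: Dict[int, str] = {}
    i = 0
    while i < len(seq):
        m = _MOD_RE.match(seq, i)
        if m:
            name = m.group(1)
            if name not in _MOD_BASE:
                raise ValueError(f"unknown modification {name!r}")
            mods[len(plain)] = name
            plain.append(_MOD_BASE[name])
            i = m.end()
        else:
            c = seq[i].upper()
            if c not in "ACGUT":
                raise ValueError(f"unexpected character {seq[i]!r} at {i}")
            plain.append("U" if c == "T" else c)
            i += 1
    return "".join(plain), mods


def modification_separation(seq: str = DUAL_PROBE) -> int:
    """Number of nucleotides strictly between the first two modified bases."""
    _, mods = parse_modified_rna(seq)
    if len(mods) < 2:
        raise ValueError("need at least two modified positions")
    pos = sorted(mods)
    return pos[1] - pos[0] - 1
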