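"""Physicochemical label vocabulary shared by all pipeline stages.

Atoms carry subsets of six role labels: acceptor (ACP), aromatic (ARM),
donor (DON), hydrophobic (HPB), negative (NEG) and positive (POS).
Everywhere inside the package labels are the two-letter short codes; the
long names appear only in the shipped typing table for readability.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable

#: long -> short code map (short codes are used in serialized labels)
LONG_TO_SHORT = {
    "ACP": "AC",
    "ARM": "AR",
    "DON": "DN",
    "HPB": "HB",
    "NEG": "NG",
    "POS": "PS",
}
SHORT_TO_LONG = {s: l for l, s in LONG_TO_SHORT.items()}
SHORT_CODES = frozenset(LONG_TO_SHORT.values())

#: charge labels, used by the salt-bridge / repulsive conditions
CHARGES = ("NG", "PS")
OPPOSITE_CHARGE = {"NG": "PS", "PS": "NG"}

LabelSet = FrozenSet[str]


def as_label_set(labels: Iterable[str]) -> LabelSet:
    """Normalize an iterable of long or short codes into a short-code frozenset."""
    out = set()
    for lab in labels:
        lab = lab.strip().upper()
        if lab in SHORT_CODES:
            out.add(lab)
        elif lab in LONG_TO_SHORT:
            out.add(LONG_TO_SHORT[lab])
        else:
            raise ValueError(f"unknown physicochemical label: {lab!r}")
    return frozenset(out)


def canonical_label(labels: Iterable[str]) -> str:
    """Serialize a label set as sorted short codes joined by '/' (e.g. 'AC/NG')."""
    ls = as_label_set(labels)
    if not ls:
        raise ValueError("cannot serialize an empty label set")
    return "/".join(sorted(ls))


def parse_label(text: str) -> LabelSet:
    """Inverse of :func:`canonical_label`."""
    return as_label_set(text.split("/"))


def labels_compatible(a: Iterable[str], b: Iterable[str]) -> bool:
    """Subset-compatibility used during pattern-to-graph matching.

    Two label sets match when one is a subset of the other, in either
    direction; this lets a pattern node carrying only the roles exercised
    by its pattern edges match a graph node with a richer label.
    """
    sa, sb = frozenset(a), frozenset(b)
    return sa <= sb or sb <= sa
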