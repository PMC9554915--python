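"""Composition/Transition/Distribution (CTD) sequence descriptors.

A residue attribute (hydrophobicity by default) partitions the 20 amino
acids into three classes; the protein sequence becomes a string over
{1,2,3} and is summarised by 21 numbers:

* composition — the 3 class fractions;
* transition — for each unordered class pair, the fraction of adjacent
  positions switching between the two classes (out of L−1 pairs);
* distribution — for each class, the sequence positions (as % of length)
  of its 1st, 25%-th, 50%-th, 75%-th and last occurrence.

The three-class partitions follow the standard Dubchak scheme for
hydrophobicity, secondary-structure propensity and solvent accessibility.
Exactly one attribute (configurable) contributes its 21-value block to the
feature vector.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from math import ceil

logger = logging.getLogger(__name__)

#: Three-class residue partitions per attribute (one-letter codes).
ATTRIBUTE_PARTITIONS: dict[str, tuple[str, str, str]] = {
    # class 1 = polar, 2 = neutral, 3 = hydrophobic
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    # class 1 = helix, 2 = strand, 3 = coil
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    # class 1 = buried, 2 = exposed, 3 = intermediate
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

DEFAULT_ATTRIBUTE = "hydrophobicity"

_CLASS_PAIRS = (("1", "2"), ("1", "3"), ("2", "3"))
_PERCENTILE_LABELS = ("first", "p25", "p50", "p75", "last")


def ctd_feature_names() -> list[str]:
    """The 21 CTD feature names, fixed order (C block, T block, D block)."""
    names = [f"CTD.C.{c}" for c in "123"]
    names += [f"CTD.T.{a}{b}" for a, b in _CLASS_PAIRS]
    for c in "123":
        names += [f"CTD.D.{c}.{p}" for p in _PERCENTILE_LABELS]
    return names


def encode_sequence(sequence: str, attribute: str = DEFAULT_ATTRIBUTE) -> str:
    """Encode a one-letter sequence as a class string over {1,2,3}.

    Non-canonical letters are skipped with a warning; an empty usable
    sequence is an error.
    """
    try:
        partition = ATTRIBUTE_PARTITIONS[attribute]
    except KeyError:
        raise ValueError(f"unknown CTD attribute: {attribute!r}") from None
    lookup = {
        letter: str(i + 1) for i, group in enumerate(partition) for letter in group
    }
    encoded, skipped = [], 0
    for letter in sequence.upper():
        cls = lookup.get(letter)
        if cls is None:
            skipped += 1
        else:
            encoded.append(cls)
    if skipped:
        logger.warning("CTD encoding skipped %d non-canonical letter(s)", skipped)
    if not encoded:
        raise ValueError("no usable residues in sequence")
    return "".join(encoded)


def ctd_features(
    sequence: str, attribute: str = DEFAULT_ATTRIBUTE, *, encoded: bool = False
) -> OrderedDict[str, float]:
    """The 21 CTD values of a sequence under one attribute partition.

    With ``encoded=True`` the input is taken to be a {1,2,3} class string
    directly (useful for testing).  Sequences of length 1 yield zero
    transitions with a warning.
    """
    enc = sequence if encoded else encode_sequence(sequence, attribute)
    if encoded and (not enc or set(enc) - set("123")):
        raise ValueError("encoded sequence must be a non-empty string over {1,2,3}")
    length = len(enc)
    out: OrderedDict[str, float] = OrderedDict()
    for c in "123":
        out[f"CTD.C.{c}"] = enc.count(c) / length
    if length < 2:
        logger.warning("CTD: sequence of length %d has no transitions", length)
        for a, b in _CLASS_PAIRS:
            out[f"CTD.T.{a}{b}"] = 0.0
    else:
        pairs = list(zip(enc, enc[1:]))
        for a, b in _CLASS_PAIRS:
            n = sum(1 for p in pairs if p in ((a, b), (b, a)))
            out[f"CTD.T.{a}{b}"] = n / (length - 1)
    for c in "123":
        positions = [i + 1 for i, x in enumerate(enc) if x == c]  # 1-based
        if not positions:
            for p in _PERCENTILE_LABELS:
                out[f"CTD.D.{c}.{p}"] = 0.0
            continue
        n = len(positions)
        picks = (
            positions[0],
            positions[ceil(0.25 * n) - 1],
            positions[ceil(0.50 * n) - 1],
            positions[ceil(0.75 * n) - 1],
            positions[-1],
        )
        for label, pos in zip(_PERCENTILE_LABELS, picks):
            out[f"CTD.D.{c}.{label}"] = pos / length * 100.0
    return out
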