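"""Canonical 96-channel trinucleotide substitution encoding.

Single-base substitutions are reduced to the pyrimidine-reference
representation: a mutation whose reference base is a purine (A or G) is
reverse-complemented, together with its flanking bases, before encoding.
The resulting channel index follows the canonical COSMIC ordering:

* six substitution classes, in the fixed order
  ``C>A, C>G, C>T, T>A, T>C, T>G``;
* within each class, the 16 flank pairs ordered by the 5' base and then
  the 3' base, each in alphabetical order ``A, C, G, T``.

Channel 0 is therefore ``A[C>A]A`` and channel 95 is ``T[T>G]T``.  Any
consistent ordering is statistically equivalent; this one is fixed so
that channel indices are stable across files and runs.
"""

from __future__ import annotations

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: substitution classes in canonical order, as (ref, alt) pairs
SUBSTITUTION_CLASSES: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

_CLASS_INDEX = {rc_alt: i for i, rc_alt in enumerate(SUBSTITUTION_CLASSES)}


class ContextError(ValueError):
    """Raised when a trinucleotide context cannot be encoded."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_context(trinucleotide: str, ref: str, alt: str) -> int:
    """Map a trinucleotide context and substitution to its channel index.

    Parameters
    ----------
    trinucleotide :
        Three reference bases centered on the mutated position
        (5' flank, ref, 3' flank), on the + strand.
    ref, alt :
        Reference and alternate base of the substitution.

    Returns
    -------
    int
        Channel index in ``0..95`` under the canonical COSMIC ordering.

    Raises
    ------
    ContextError
        If any base is outside ``{A, C, G, T}`` (ambiguity codes such as
        ``N`` cannot be encoded) or the middle base disagrees with *ref*.
    ValueError
        If ``ref == alt`` (not a substitution).
    """
    tri = trinucleotide.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(tri) != 3:
        raise ContextError(f"trinucleotide must have length 3, got {tri!r}")
    if any(b not in _BASES for b in tri) or ref not in _BASES or alt not in _BASES:
        raise ContextError(f"non-ACGT base in context {tri!r} {ref}>{alt}")
    if tri[1] != ref:
        raise ContextError(
            f"middle base of context {tri!r} does not match ref {ref!r}"
        )
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref}); not a substitution")
    if ref in "AG":  # purine reference: collapse to the pyrimidine strand
        tri = reverse_complement(tri)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    sub = _CLASS_INDEX[(ref, alt)]
    return sub * 16 + _BASES.index(tri[0]) * 4 + _BASES.index(tri[2])


def channel_label(channel: int) -> str:
    """Human-readable label ``5'[ref>alt]3'`` for a channel index."""
    if not 0 <= channel < 96:
        raise ValueError(f"channel must be in 0..95, got {channel}")
    sub, rest = divmod(channel, 16)
    five, three = divmod(rest, 4)
    ref, alt = SUBSTITUTION_CLASSES[sub]
    return f"{_BASES[five]}[{ref}>{alt}]{_BASES[three]}"


def parse_channel_label(label: str) -> int:
    """Inverse of :func:`channel_label`; accepts e.g. ``A[C>A]A``."""
    label = label.strip().upper()
    if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
        raise ValueError(f"malformed channel label {label!r}")
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    return encode_context(five + ref + three, ref, alt)


#: all 96 labels in canonical order
CHANNEL_LABELS: tuple[str, ...] = tuple(channel_label(i) for i in range(96))

#: the four NpCpG C>T channels (A/C/G/T 5' flank, G 3' flank)
CPG_TRANSITION_CHANNELS: tuple[int, ...] = tuple(
    encode_context(f + "CG", "C", "T") for f in _BASES
)
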