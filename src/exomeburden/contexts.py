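"""Trinucleotide mutation-context machinery shared across the package.

Single-base substitutions are classified into 96 categories by the
pyrimidine-normalized substitution type (C>A, C>G, C>T, T>A, T>C, T>G) and
the reference bases immediately 5' and 3' of the mutated base.  When the
reference base is a purine, the substitution and both flanking bases are
reverse-complemented before binning, so that every SNV maps to exactly one
category regardless of which strand it was reported on.

Category order is fixed lexicographically by (substitution type, 5' base,
3' base), giving labels "A[C>A]A", "A[C>A]C", ..., "T[T>G]T".
"""

from __future__ import annotations

import itertools

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _make_labels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTION_TYPES:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: The 96 category labels, in canonical order.
CONTEXT_LABELS: tuple[str, ...] = _make_labels()

#: Label -> index in canonical order.
CONTEXT_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}

#: The 32 pyrimidine-centred reference trinucleotides ("ACA", "ACC", ...).
REF_TRINUCLEOTIDES: tuple[str, ...] = tuple(
    f"{five}{mid}{three}"
    for mid in PYRIMIDINES
    for five, three in itertools.product(BASES, BASES)
)


def canonical_trinucleotide(tri: str) -> str:
    """Pyrimidine-normalize a reference trinucleotide (central base C or T)."""
    if len(tri) != 3:
        raise ValueError(f"trinucleotide must have length 3, got {tri!r}")
    if tri[1] in PYRIMIDINES:
        return tri
    return revcomp(tri)


def context_label(ref: str, alt: str, five_prime: str, three_prime: str) -> str:
    """Classify one SNV into its 96-category label.

    ``five_prime`` and ``three_prime`` are the reference bases flanking the
    mutated position on the same strand as ``ref``/``alt``.
    """
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    for b in (ref, alt, five_prime, three_prime):
        if b not in BASES:
            raise ValueError(f"invalid base {b!r}")
    if ref not in PYRIMIDINES:
        ref, alt = complement(ref), complement(alt)
        five_prime, three_prime = complement(three_prime), complement(five_prime)
    return f"{five_prime}[{ref}>{alt}]{three_prime}"


def context_index(ref: str, alt: str, five_prime: str, three_prime: str) -> int:
    """Index (0..95) of one SNV in the canonical category order."""
    return CONTEXT_INDEX[context_label(ref, alt, five_prime, three_prime)]


def parse_label(label: str) -> tuple[str, str, str, str]:
    """Split "A[C>T]G" into (ref, alt, five_prime, three_prime)."""
    if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
        raise ValueError(f"malformed context label {label!r}")
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    return ref, alt, five, three
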