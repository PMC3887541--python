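"""Motif algebra: canonical rotations, primitive units, reverse complements, GC content.

A repeat motif is a string over {A, C, G, T} of length 1-50.  Motif classes
are identified by the lexicographically least cyclic rotation of the
primitive unit (ASCII order, A < C < G < T).  A motif and its reverse
complement are distinct classes; :func:`pair_label` renders the joint
"AAG/CTT"-style display form used in summary tables.
"""

from __future__ import annotations

from .errors import MotifError, UndefinedContentError

MAX_UNIT = 50

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")


def _check(unit: str) -> str:
    if not unit:
        raise MotifError("motif must be a nonempty string")
    if len(unit) > MAX_UNIT:
        raise MotifError(f"motif longer than {MAX_UNIT} nt: {len(unit)}")
    if not _VALID_BASES.issuperset(unit):
        bad = sorted(set(unit) - _VALID_BASES)
        raise MotifError(f"motif contains non-ACGT characters: {bad}")
    return unit


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest cyclic rotation of ``unit``.

    The representative of a motif class: canonical_rotation("AGA") ==
    canonical_rotation("GAA") == "AAG".  Idempotent.
    """
    _check(unit)
    doubled = unit + unit
    n = len(unit)
    return min(doubled[i : i + n] for i in range(n))


def primitive_unit(unit: str) -> str:
    """Shortest string whose repetition yields ``unit``.

    Computed from the classic border (failure) function: the smallest
    period p divides len(unit) iff unit is a whole number of copies of
    its length-p prefix; otherwise the unit is already primitive.
    """
    _check(unit)
    n = len(unit)
    border = [0] * n
    k = 0
    for i in range(1, n):
        while k > 0 and unit[i] != unit[k]:
            k = border[k - 1]
        if unit[i] == unit[k]:
            k += 1
        border[i] = k
    period = n - border[-1]
    if period < n and n % period == 0:
        return unit[:period]
    return unit


def is_primitive(unit: str) -> bool:
    return primitive_unit(unit) == unit


def reverse_complement(unit: str) -> str:
    """Watson-Crick reverse complement; an involution on ACGT strings."""
    _check(unit)
    return unit.translate(_COMPLEMENT)[::-1]


def canonical_class(unit: str) -> str:
    """Canonical representative of the observed unit: least rotation of its
    primitive reduction."""
    return canonical_rotation(primitive_unit(unit))


def pair_label(unit: str) -> str:
    """Joint display form of a motif and its reverse-complement class.

    The queried motif's canonical form comes first ("AAG/CTT"); a
    palindromic class ("AT") is shown alone.  Counting stays separate —
    this is presentation only.
    """
    c = canonical_class(unit)
    rc = canonical_rotation(reverse_complement(c))
    if rc == c:
        return c
    return f"{c}/{rc}"


def gc_content(seq: str) -> float:
    """Percent G+C among valid nucleotides (A/C/G/T) of ``seq``.

    N and other ambiguity codes are excluded from the denominator;
    raises :class:`UndefinedContentError` when no valid nucleotide exists.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedContentError("no valid nucleotides in sequence")
    return 100.0 * gc / (gc + at)
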