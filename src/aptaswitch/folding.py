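"""Thin, cached wrapper around the ViennaRNA folding engine.

All secondary-structure thermodynamics in this package go through the two
functions here: :func:`fold_mfe` (constrained MFE folding) and
:func:`duplex_fold` (bimolecular duplex energy, used for SD:anti-SD
hybridization). Folding uses the Turner 2004 nearest-neighbour parameters
(the ViennaRNA 2.x default) with dangling-end contributions disabled.

Constraint strings use the dot-bracket constraint alphabet:
``.`` unconstrained, ``x`` forced unpaired, ``(`` / ``)`` forced pair.
Forced pairs are enforced (they appear in the returned structure), and the
wrapper rejects forced pairs that are not Watson-Crick or GU wobble, which
the engine would otherwise silently accept.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import RNA

VALID_BASES = frozenset("ACGU")
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
_CONSTRAINT_CHARS = frozenset(".x()")

#: energy (kcal/mol) above which a constrained fold is considered infeasible
_INF_ENERGY = 1e5


class SequenceError(ValueError):
    """Invalid nucleotide sequence."""


class ConstraintError(ValueError):
    """Malformed or contradictory folding constraint."""


def normalize_rna(sequence: str) -> str:
    """Uppercase, strip whitespace, map T->U, and validate the alphabet."""
    seq = "".join(sequence.split()).upper().replace("T", "U")
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceError(
            f"invalid characters {sorted(bad)} in sequence {sequence[:30]!r}..."
        )
    return seq


def pair_table(structure: str) -> dict[int, int]:
    """Map 1-based position -> 1-based partner for a dot-bracket string."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ConstraintError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            pairs[i] = pos
            pairs[pos] = i
    if stack:
        raise ConstraintError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def validate_constraint(sequence: str, constraint: str) -> None:
    """Check length, alphabet, balance and canonicity of forced pairs."""
    if len(constraint) != len(sequence):
        raise ConstraintError(
            f"constraint length {len(constraint)} != sequence length {len(sequence)}"
        )
    bad = set(constraint) - _CONSTRAINT_CHARS
    if bad:
        raise ConstraintError(f"invalid constraint characters {sorted(bad)}")
    for i, j in pair_table(constraint).items():
        if i < j and (sequence[i - 1], sequence[j - 1]) not in CANONICAL_PAIRS:
            raise ConstraintError(
                f"forced pair {i}-{j} ({sequence[i-1]}-{sequence[j-1]}) "
                "is not a canonical base pair"
            )


@dataclass(frozen=True)
class FoldState:
    """An MFE secondary structure and its folding free energy.

    ``dg_fold`` is in kcal/mol; ``constraint`` records the constraint
    string the fold was computed under (None for unconstrained).
    """

    structure: str
    dg_fold: float
    constraint: str | None = None


@lru_cache(maxsize=200_000)
def _fold_cached(seq: str, constraint: str | None, temp_c: float) -> tuple[str, float]:
    md = RNA.md()
    md.dangles = 0
    md.temperature = temp_c
    fc = RNA.fold_compound(seq, md)
    if constraint is not None:
        fc.hc_add_from_db(
            constraint, RNA.CONSTRAINT_DB_DEFAULT | RNA.CONSTRAINT_DB_ENFORCE_BP
        )
    structure, energy = fc.mfe()
    return structure, float(energy)


def fold_mfe(
    sequence: str, constraint: str | None = None, temperature_c: float = 37.0
) -> FoldState:
    """Constrained minimum-free-energy fold of an RNA sequence.

    Raises :class:`SequenceError` for bad alphabets and
    :class:`ConstraintError` for malformed or contradictory constraints.
    """
    seq = normalize_rna(sequence)
    if constraint is not None:
        validate_constraint(seq, constraint)
        if set(constraint) <= {"."}:
            constraint = None  # no-op constraint; share the cache entry
    structure, energy = _fold_cached(seq, constraint, float(temperature_c))
    if energy > _INF_ENERGY:
        raise ConstraintError("contradictory constraint: no feasible structure")
    return FoldState(structure=structure, dg_fold=energy, constraint=constraint)


@dataclass(frozen=True)
class DuplexSite:
    """Best intermolecular duplex between two strands.

    ``span1``/``span2`` are 1-based inclusive intervals of the *paired*
    region on each strand; ``dg`` is the duplex free energy (kcal/mol).
    """

    dg: float
    span1: tuple[int, int]
    span2: tuple[int, int]
    structure: str


@lru_cache(maxsize=200_000)
def _duplex_cached(seq1: str, seq2: str, temp_c: float):
    # duplexfold reads the legacy global model settings
    old_d, old_t = RNA.cvar.dangles, RNA.cvar.temperature
    try:
        RNA.cvar.dangles = 0
        RNA.cvar.temperature = temp_c
        dup = RNA.duplexfold(seq1, seq2)
    finally:
        RNA.cvar.dangles, RNA.cvar.temperature = old_d, old_t
    return dup.structure, dup.i, dup.j, float(dup.energy)


def duplex_fold(
    seq1: str, seq2: str, temperature_c: float = 37.0
) -> DuplexSite | None:
    """Most favourable duplex between ``seq1`` and ``seq2``.

    Returns None when no stabilizing duplex exists (no base pairs, or a
    non-negative duplex energy).
    """
    s1 = normalize_rna(seq1)
    s2 = normalize_rna(seq2)
    if not s1 or not s2:
        raise SequenceError("duplex strands must be non-empty")
    structure, i, j, energy = _duplex_cached(s1, s2, float(temperature_c))
    seg1, seg2 = structure.split("&")
    if "(" not in seg1 or energy >= 0.0:
        return None
    # seg1 covers seq1 positions i-len(seg1)+1 .. i; seg2 covers j .. j+len(seg2)-1
    start1 = i - len(seg1) + 1
    p1 = [start1 + k for k, ch in enumerate(seg1) if ch == "("]
    p2 = [j + k for k, ch in enumerate(seg2) if ch == ")"]
    return DuplexSite(
        dg=energy,
        span1=(p1[0], p1[-1]),
        span2=(p2[0], p2[-1]),
        structure=structure,
    )


def clear_fold_cache() -> None:
    _fold_cached.cache_clear()
    _duplex_cached.cache_clear()
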