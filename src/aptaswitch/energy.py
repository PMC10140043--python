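"""Ribosome-mRNA binding free energy: the five-term model and the rate law.

The translation initiation rate of a bacterial mRNA is controlled by the
free-energy difference between two states:

* the *initial* state -- the mRNA folded on its own (dG_initial);
* the *final* state -- the 30S pre-initiation complex, in which the 16S
  rRNA 3' tail is hybridized to the Shine-Dalgarno (SD) sequence, the
  initiator tRNA is paired with the start codon, and every mRNA structure
  overlapping the ribosome footprint has been unfolded (dG_final).

dG_final decomposes into five terms::

    dG_final = dG_mRNA:rRNA + dG_start + dG_spacing + dG_standby + dG_refold

where dG_refold is the folding energy of the mRNA *outside* the footprint.
The total binding energy is dG_total = dG_final - dG_initial, and the
translation initiation rate follows the Boltzmann relationship
``TIR = k_tir * exp(-beta * dG_total)``.

The SD placement is not given a priori: :func:`ribosome_final_state`
enumerates every placement whose spacing to the start codon lies within
the calibrated range and returns the placement minimizing dG_final.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .calibration import CalibrationParams
from .folding import (
    ConstraintError,
    FoldState,
    SequenceError,
    duplex_fold,
    fold_mfe,
    normalize_rna,
    validate_constraint,
)

START_CODONS = ("AUG", "GUG", "UUG")


@dataclass(frozen=True)
class MrnaRecord:
    """An mRNA with a known start codon position.

    ``cds_start`` is the 1-based index of the first nucleotide of the
    start codon. The sequence must extend at least 12 nt past it so the
    ribosome footprint fits.
    """

    name: str
    sequence: str
    cds_start: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        n = len(self.sequence)
        if not 1 <= self.cds_start <= n - 2:
            raise SequenceError(
                f"{self.name}: cds_start {self.cds_start} outside sequence (len {n})"
            )
        codon = self.start_codon
        if codon not in START_CODONS:
            raise SequenceError(
                f"{self.name}: codon {codon!r} at cds_start is not a start codon"
            )
        if n < self.cds_start + 12:
            raise SequenceError(
                f"{self.name}: sequence must extend >= 12 nt past the start codon"
            )

    @property
    def start_codon(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_start + 2]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Five-term decomposition of the ribosome binding free energy.

    All energies are kcal/mol. ``sd_span`` is the 1-based inclusive
    interval of the mRNA paired with the anti-SD; ``spacing_nt`` the
    distance from the SD span's 3' end to the start codon. When no SD
    placement pairs at all, ``no_sd`` is set and the ribosome terms are
    zero (weakest-binding sentinel) so that dead designs can still be
    scored.
    """

    dg_mrna_rrna: float
    dg_start: float
    dg_spacing: float
    dg_standby: float
    dg_initial: float
    dg_final: float
    dg_total: float
    sd_span: tuple[int, int] | None
    spacing_nt: int | None
    initial_state: FoldState
    final_state: FoldState
    no_sd: bool = False

    @property
    def dg_refold(self) -> float:
        """Folding energy of the mRNA outside the ribosome footprint."""
        return self.final_state.dg_fold


def sd_hybridization(
    mrna_window: str, anti_sd: str, temperature_c: float = 37.0
) -> tuple[float, tuple[int, int]] | None:
    """Best SD:anti-SD duplex within an mRNA window.

    Returns ``(dg_mrna_rrna, sd_span)`` with the span 1-based on the
    window, or None when no stabilizing duplex can form.
    """
    site = duplex_fold(mrna_window, anti_sd, temperature_c)
    if site is None:
        return None
    return site.dg, site.span1


def _constraint_feasible(constraint: str | None, lo: int, hi: int) -> bool:
    """True when no position in [lo, hi] (1-based) is forced paired."""
    if constraint is None:
        return True
    return not any(ch in "()" for ch in constraint[lo - 1 : hi])


def _footprint_constraint(
    constraint: str | None, n: int, lo: int, hi: int
) -> str:
    """Constraint string forcing [lo, hi] unpaired, keeping the rest."""
    base = list(constraint) if constraint is not None else ["."] * n
    for k in range(lo - 1, hi):
        base[k] = "x"
    return "".join(base)


def _standby_penalty(
    seq: str,
    constraint: str | None,
    footprint_fold: FoldState,
    footprint_cons: str,
    sd_start: int,
    calib: CalibrationParams,
) -> float:
    """Unfolding cost of structure occluding the standby site.

    Simplified standby model: the docking penalty is the free-energy cost
    of additionally forcing the standby window (``standby_window`` nt
    immediately 5' of the SD span) unpaired, given the state's fold with
    the footprint already open. Aptamer-constraint pairs touching the
    window are dropped in the opened fold (the comparison asks what the
    window costs to clear), and the penalty is clamped at >= 0.
    """
    lo = max(1, sd_start - calib.standby_window)
    hi = sd_start - 1
    if hi < lo:
        return 0.0
    opened = list(footprint_cons)
    if constraint is not None:
        from .folding import pair_table

        for i, j in pair_table(constraint).items():
            if i < j and (lo <= i <= hi or lo <= j <= hi):
                opened[i - 1] = "."
                opened[j - 1] = "."
    for k in range(lo - 1, hi):
        opened[k] = "x"
    opened_fold = fold_mfe(seq, "".join(opened), calib.fold_temperature_c)
    return max(0.0, opened_fold.dg_fold - footprint_fold.dg_fold)


def ribosome_final_state(
    m: MrnaRecord,
    constraint: str | None = None,
    calib: CalibrationParams | None = None,
) -> EnergyBreakdown:
    """Minimum-dG_final ribosome placement on an mRNA.

    Enumerates candidate SD placements with spacing (3' end of the paired
    SD span to the base before the start codon) from 0 to
    ``calib.spacing_max``. For each placement,

    * the footprint (5' end of the SD span through
      ``cds_start + footprint_past_start - 1``) is forced unpaired and the
      rest of the mRNA refolded, honouring any aptamer constraint outside
      the footprint;
    * placements whose footprint overlaps a position the constraint forces
      *paired* are infeasible -- the ribosome cannot displace a
      protein-locked helix;
    * dG_final sums the duplex, start-codon, spacing, standby and
      outside-footprint terms.

    Returns the placement minimizing dG_final (ties: smallest spacing,
    then 5'-most SD). If no placement pairs, returns a flagged sentinel
    breakdown with all ribosome terms zero. The ``dg_initial``/``dg_total``
    slots of the returned breakdown are NaN; :func:`total_binding_energy`
    completes them.
    """
    calib = calib or CalibrationParams()
    seq = m.sequence
    n = len(seq)
    if constraint is not None:
        validate_constraint(seq, constraint)
    temp_c = calib.fold_temperature_c
    anti_len = len(calib.anti_sd)

    best: tuple[tuple[float, int, int], EnergyBreakdown] | None = None
    for spacing in range(calib.spacing_max + 1):
        end = m.cds_start - 1 - spacing
        if end < 1:
            break
        start = max(1, end - anti_len + 1)
        hit = sd_hybridization(seq[start - 1 : end], calib.anti_sd, temp_c)
        if hit is None:
            continue
        dg_duplex, (w_lo, w_hi) = hit
        sd_span = (start + w_lo - 1, start + w_hi - 1)
        realized = m.cds_start - 1 - sd_span[1]
        if realized > calib.spacing_max:
            continue
        foot_lo = sd_span[0]
        foot_hi = min(n, m.cds_start + calib.footprint_past_start - 1)
        if not _constraint_feasible(constraint, foot_lo, foot_hi):
            continue
        final_cons = _footprint_constraint(constraint, n, foot_lo, foot_hi)
        final = fold_mfe(seq, final_cons, temp_c)
        dg_spacing = calib.spacing_penalty(realized)
        dg_start = calib.start_codon_energies[m.start_codon]
        dg_standby = _standby_penalty(
            seq, constraint, final, final_cons, sd_span[0], calib
        )
        dg_final = dg_duplex + dg_start + dg_spacing + dg_standby + final.dg_fold
        bd = EnergyBreakdown(
            dg_mrna_rrna=dg_duplex,
            dg_start=dg_start,
            dg_spacing=dg_spacing,
            dg_standby=dg_standby,
            dg_initial=math.nan,
            dg_final=dg_final,
            dg_total=math.nan,
            sd_span=sd_span,
            spacing_nt=realized,
            initial_state=FoldState("", math.nan),
            final_state=final,
        )
        key = (dg_final, realized, sd_span[0])
        if best is None or key < best[0]:
            best = (key, bd)

    if best is not None:
        return best[1]

    # no SD anywhere in range: weakest-binding sentinel, flagged
    final = fold_mfe(seq, constraint, temp_c)
    return EnergyBreakdown(
        dg_mrna_rrna=0.0,
        dg_start=0.0,
        dg_spacing=0.0,
        dg_standby=0.0,
        dg_initial=math.nan,
        dg_final=final.dg_fold,
        dg_total=math.nan,
        sd_span=None,
        spacing_nt=None,
        initial_state=FoldState("", math.nan),
        final_state=final,
        no_sd=True,
    )


def total_binding_energy(
    m: MrnaRecord,
    constraint: str | None = None,
    calib: CalibrationParams | None = None,
) -> EnergyBreakdown:
    """Full ribosome binding energy: dG_total = dG_final - dG_initial."""
    calib = calib or CalibrationParams()
    initial = fold_mfe(m.sequence, constraint, calib.fold_temperature_c)
    partial = ribosome_final_state(m, constraint, calib)
    return replace(
        partial,
        dg_initial=initial.dg_fold,
        dg_total=partial.dg_final - initial.dg_fold,
        initial_state=initial,
    )


def tir(dg_total: float, calib: CalibrationParams | None = None) -> float:
    """Translation initiation rate, ``k_tir * exp(-beta * dG_total)`` (au)."""
    calib = calib or CalibrationParams()
    return calib.k_tir * math.exp(-calib.beta * dg_total)
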