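"""Four-state riboswitch thermodynamics and regulation-ratio predictions.

A translational riboswitch is modeled through its four predominant
states: {protein-unbound, protein-bound} x {mRNA free, ribosome-bound}.
In the unbound state the aptamer folds freely with the rest of the mRNA;
in the protein-bound state the aptamer is locked into its protein-bound
structure, applied as a hard folding constraint to both the initial and
final states. Three regulation ratios are predicted:

* ``r_max``   -- fold-change at saturating protein (100% occupancy);
* ``r_conc``  -- fold-change at a specified protein concentration,
  using single-site equilibrium occupancy at the aptamer's Kd;
* ``r_actual``-- like r_conc but with the Kd penalized by the refolding
  energy needed to reach the protein-bound mRNA conformation
  (``kd_eff = kd * exp(dG_refold / RT)``), the complete model.

All ratios are reported >= 1, with ``as_designed`` recording whether the
protein moves translation in the direction the declared ON/OFF mode
intends.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .calibration import CalibrationParams
from .folding import ConstraintError, fold_mfe, normalize_rna, pair_table
from .energy import EnergyBreakdown, MrnaRecord, tir, total_binding_energy


class Mode(str, enum.Enum):
    """Design intent: ON activates translation on binding, OFF represses."""

    ON = "ON"
    OFF = "OFF"


@dataclass(frozen=True)
class AptamerSpec:
    """A protein-binding RNA aptamer: sequence, bound structure, affinity.

    ``bound_structure`` is the dot-bracket conformation the aptamer adopts
    in the protein complex; dots are *unconstrained* positions (free to
    refold with flanking mRNA), brackets are protein-locked pairs.
    ``kd`` is the dissociation constant in molar.
    """

    name: str
    sequence: str
    bound_structure: str
    kd: float
    ligand_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.bound_structure) != len(self.sequence):
            raise ValueError(
                f"{self.name}: bound_structure length != sequence length"
            )
        pair_table(self.bound_structure)  # raises if unbalanced
        if not self.kd > 0:
            raise ValueError(f"{self.name}: kd must be > 0 M, got {self.kd}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RiboswitchConstruct:
    """A riboswitch mRNA: pre-aptamer | aptamer | post-aptamer | CDS.

    The post-aptamer region carries the SD and spacer. ``cds`` must begin
    with a start codon and extend far enough for the ribosome footprint.
    """

    name: str
    pre_aptamer: str
    aptamer: AptamerSpec
    post_aptamer: str
    cds: str
    mode: Mode = Mode.ON

    def __post_init__(self) -> None:
        object.__setattr__(self, "pre_aptamer", normalize_rna(self.pre_aptamer))
        object.__setattr__(self, "post_aptamer", normalize_rna(self.post_aptamer))
        object.__setattr__(self, "cds", normalize_rna(self.cds))
        object.__setattr__(self, "mode", Mode(self.mode))
        # full validation (start codon, footprint room) happens in mrna()

    @property
    def sequence(self) -> str:
        return (
            self.pre_aptamer + self.aptamer.sequence + self.post_aptamer + self.cds
        )

    @property
    def cds_start(self) -> int:
        return (
            len(self.pre_aptamer) + len(self.aptamer) + len(self.post_aptamer) + 1
        )

    @property
    def aptamer_span(self) -> tuple[int, int]:
        """1-based inclusive interval of the aptamer on the assembled mRNA."""
        lo = len(self.pre_aptamer) + 1
        return lo, lo + len(self.aptamer) - 1

    def mrna(self) -> MrnaRecord:
        return MrnaRecord(self.name, self.sequence, self.cds_start)

    def bound_constraint(self) -> str:
        """Full-length constraint locking the aptamer's bound structure."""
        return (
            "." * len(self.pre_aptamer)
            + self.aptamer.bound_structure
            + "." * len(self.post_aptamer)
            + "." * len(self.cds)
        )


@dataclass(frozen=True)
class SwitchPrediction:
    """Model output for one riboswitch at one protein concentration."""

    name: str
    mode: Mode
    unbound: EnergyBreakdown
    bound: EnergyBreakdown
    dg_ligand: float
    dg_refold: float
    kd: float
    kd_eff: float
    protein_conc: float
    tir_unbound: float
    tir_bound: float
    r_max: float
    r_conc: float
    r_actual: float
    as_designed: bool

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mode": self.mode.value,
            "dg_total_unbound": self.unbound.dg_total,
            "dg_total_bound": self.bound.dg_total,
            "dg_ligand": self.dg_ligand,
            "dg_refold": self.dg_refold,
            "kd": self.kd,
            "kd_eff": self.kd_eff,
            "protein_conc": self.protein_conc,
            "tir_unbound": self.tir_unbound,
            "tir_bound": self.tir_bound,
            "r_max": self.r_max,
            "r_conc": self.r_conc,
            "r_actual": self.r_actual,
            "as_designed": self.as_designed,
        }


def dg_ligand_from_kd(kd: float, temperature: float = 310.15) -> float:
    """Protein-aptamer binding free energy, RT*ln(Kd), 1 M reference state."""
    if not kd > 0:
        raise ValueError(f"kd must be > 0 M, got {kd}")
    from .calibration import R_KCAL

    return R_KCAL * temperature * math.log(kd)


def fraction_bound(protein_conc: float, kd_eff: float) -> float:
    """Single-site equilibrium occupancy, f = P / (P + Kd)."""
    if protein_conc < 0:
        raise ValueError("protein concentration must be >= 0")
    if not kd_eff > 0:
        raise ValueError("kd_eff must be > 0")
    if math.isinf(protein_conc):
        return 1.0
    return protein_conc / (protein_conc + kd_eff)


def ensemble_tir(tir_bound: float, tir_unbound: float, f: float) -> float:
    """Mean translation rate of an mRNA ensemble at occupancy f.

    Rates, not free energies, average over the ensemble:
    ``f * tir_bound + (1 - f) * tir_unbound``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("occupancy f must be in [0, 1]")
    return f * tir_bound + (1.0 - f) * tir_unbound


def max_fold_change(dg_bound: float, dg_unbound: float, beta: float) -> float:
    """Maximum TIR fold-change, exp(-beta * (dG_bound - dG_unbound)).

    Equals r_max for an ON switch and 1/r_max for an OFF switch.
    """
    return math.exp(-beta * (dg_bound - dg_unbound))


def refolding_penalty(
    c: RiboswitchConstruct, calib: CalibrationParams | None = None
) -> float:
    """Energy needed to reach the protein-bound mRNA conformation.

    dG_refold = dG_initial(aptamer locked) - dG_initial(unconstrained),
    clamped at >= 0 (a hard constraint can never lower the MFE).
    """
    calib = calib or CalibrationParams()
    t = calib.fold_temperature_c
    seq = c.sequence
    unconstrained = fold_mfe(seq, None, t)
    constrained = fold_mfe(seq, c.bound_constraint(), t)
    return max(0.0, constrained.dg_fold - unconstrained.dg_fold)


def _oriented(raw: float, as_designed: bool) -> float:
    return raw if as_designed else 1.0 / raw


def evaluate_switch(
    c: RiboswitchConstruct,
    protein_conc: float = math.inf,
    calib: CalibrationParams | None = None,
) -> SwitchPrediction:
    """Evaluate the four states of a riboswitch and its regulation ratios.

    The unbound state is evaluated unconstrained; the bound state with the
    aptamer locked into its protein-bound structure (initial and final
    states alike). The ensemble rate at occupancy f mixes rates, not
    energies: ``tir(P) = f*tir_bound + (1-f)*tir_unbound``; r_conc uses
    f at the aptamer Kd, r_actual at the stability-corrected kd_eff.
    """
    calib = calib or CalibrationParams()
    m = c.mrna()
    unbound = total_binding_energy(m, None, calib)
    bound = total_binding_energy(m, c.bound_constraint(), calib)

    tir_u = tir(unbound.dg_total, calib)
    tir_b = tir(bound.dg_total, calib)

    dg_refold = refolding_penalty(c, calib)
    kd_eff = c.aptamer.kd * math.exp(dg_refold / calib.rt)
    dg_ligand = dg_ligand_from_kd(c.aptamer.kd, calib.temperature)

    raw = tir_b / tir_u if c.mode is Mode.ON else tir_u / tir_b
    as_designed = raw >= 1.0
    r_max = _oriented(raw, as_designed)

    def ratio_at(kd_val: float) -> float:
        # algebraically equal to ensemble_tir(tir_b, tir_u, f) / tir_u
        # (or its reciprocal for OFF) but exact at tir_b == tir_u
        f = fraction_bound(protein_conc, kd_val)
        g = 1.0 + f * (tir_b - tir_u) / tir_u
        r = g if c.mode is Mode.ON else 1.0 / g
        return _oriented(r, as_designed)

    return SwitchPrediction(
        name=c.name,
        mode=c.mode,
        unbound=unbound,
        bound=bound,
        dg_ligand=dg_ligand,
        dg_refold=dg_refold,
        kd=c.aptamer.kd,
        kd_eff=kd_eff,
        protein_conc=protein_conc,
        tir_unbound=tir_u,
        tir_bound=tir_b,
        r_max=r_max,
        r_conc=ratio_at(c.aptamer.kd),
        r_actual=ratio_at(kd_eff),
        as_designed=as_designed,
    )
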