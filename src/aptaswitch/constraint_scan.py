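"""Aptamer subconstraint scanning and constraint selection.

The protein-bound aptamer structure entering the model is an assumption:
often only part of the published aptamer is truly locked by the protein.
This module enumerates every contiguous aptamer subregion [i, j],
refolds it in isolation, treats its MFE structure as the bound-state
constraint (flanking aptamer nucleotides migrate into the pre-/post-
aptamer regions, leaving the assembled mRNA unchanged), recomputes the
predicted r_actual per subconstraint, and selects the subconstraint that
best explains measured regulation ratios across a set of riboswitches
sharing the aptamer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .calibration import CalibrationParams
from .folding import fold_mfe
from .switch import AptamerSpec, RiboswitchConstruct, evaluate_switch


@dataclass(frozen=True)
class SubConstraint:
    """Aptamer subregion [i, j] (1-based inclusive) and its refolded MFE.

    Unpaired positions in the refolded substructure stay dots, i.e.
    unconstrained -- free to refold with adjacent mRNA in the bound state.
    """

    i: int
    j: int
    substructure: str


@dataclass(frozen=True)
class ConstraintScanResult:
    """Grid of predicted r_actual over all subconstraints of one switch."""

    name: str
    grid: dict[tuple[int, int], float]
    baseline: float
    protein_conc: float

    @property
    def fold_span(self) -> float:
        """max/min predicted r_actual across the grid (>= 1)."""
        vals = list(self.grid.values())
        return max(vals) / min(vals)


@dataclass(frozen=True)
class SelectedConstraint:
    """Best subconstraint for an aptamer plus its accuracy report."""

    i: int
    j: int
    r_squared: float
    within_twofold: float
    n: int


def enumerate_subconstraints(
    aptamer: AptamerSpec, calib: CalibrationParams | None = None
) -> list[SubConstraint]:
    """All L(L+1)/2 contiguous subconstraints, each refolded by MFE."""
    calib = calib or CalibrationParams()
    t = calib.fold_temperature_c
    seq = aptamer.sequence
    out = []
    for i in range(1, len(seq) + 1):
        for j in range(i, len(seq) + 1):
            sub = seq[i - 1 : j]
            if len(sub) == 1:
                structure = "."
            else:
                structure = fold_mfe(sub, None, t).structure
            out.append(SubConstraint(i=i, j=j, substructure=structure))
    return out


def rebuild_construct(
    c: RiboswitchConstruct, s: SubConstraint
) -> RiboswitchConstruct:
    """Move the constraint partition: aptamer flanks join pre/post.

    The assembled mRNA sequence is unchanged; only which positions carry
    the bound-structure constraint moves.
    """
    apt = c.aptamer
    L = len(apt)
    if not 1 <= s.i <= s.j <= L:
        raise ValueError(f"subconstraint ({s.i},{s.j}) outside aptamer 1..{L}")
    new_apt = AptamerSpec(
        name=f"{apt.name}[{s.i}-{s.j}]",
        sequence=apt.sequence[s.i - 1 : s.j],
        bound_structure=s.substructure,
        kd=apt.kd,
        ligand_name=apt.ligand_name,
    )
    return replace(
        c,
        pre_aptamer=c.pre_aptamer + apt.sequence[: s.i - 1],
        aptamer=new_apt,
        post_aptamer=apt.sequence[s.j :] + c.post_aptamer,
    )


def scan_r_actual(
    c: RiboswitchConstruct,
    protein_conc: float,
    calib: CalibrationParams | None = None,
) -> ConstraintScanResult:
    """Predicted r_actual for every aptamer subconstraint of one switch.

    All other sequences and model parameters are held fixed; only the
    bound-state structural constraint varies. ``protein_conc`` should be
    the assay's maximum-induction concentration (molar).
    """
    calib = calib or CalibrationParams()
    baseline = evaluate_switch(c, protein_conc, calib).r_actual
    grid: dict[tuple[int, int], float] = {}
    for s in enumerate_subconstraints(c.aptamer, calib):
        pred = evaluate_switch(rebuild_construct(c, s), protein_conc, calib)
        grid[(s.i, s.j)] = pred.r_actual
    return ConstraintScanResult(
        name=c.name, grid=grid, baseline=baseline, protein_conc=protein_conc
    )


def select_constraint(
    scans: dict[str, ConstraintScanResult],
    measured: dict[str, float],
) -> SelectedConstraint:
    """Subconstraint maximizing log-log prediction accuracy.

    For each candidate (i, j) the accuracy score is the squared Pearson
    correlation between ln(predicted r_actual) and ln(measured ratio)
    across all riboswitches sharing the aptamer. Ties (including grids
    with zero predictive variance) break to the smallest region j-i, then
    the 5'-most i. Also reports the fraction of riboswitches whose
    prediction is within 2-fold of the measurement at the selected
    constraint.
    """
    names = sorted(set(scans) & set(measured))
    if len(names) < 2:
        raise ValueError(
            "select_constraint needs >= 2 riboswitches with measured ratios"
        )
    for nm in names:
        if not measured[nm] > 0:
            raise ValueError(f"measured ratio for {nm!r} must be > 0")
    cells = sorted(next(iter(scans.values())).grid)
    y = np.log([measured[nm] for nm in names])

    best_key: tuple[float, int, int] | None = None
    best: tuple[int, int, float] | None = None
    for (i, j) in cells:
        x = np.log([scans[nm].grid[(i, j)] for nm in names])
        if np.ptp(x) <= 1e-12 or np.ptp(y) <= 1e-12:
            r2 = -math.inf  # no predictive variance; only wins by tie rule
        else:
            r2 = stats.pearsonr(x, y).statistic ** 2
        key = (-r2, j - i, i)
        if best_key is None or key < best_key:
            best_key = key
            best = (i, j, r2)

    i, j, r2 = best
    preds = np.array([scans[nm].grid[(i, j)] for nm in names])
    meas = np.array([measured[nm] for nm in names])
    within = float(np.mean(np.maximum(preds / meas, meas / preds) <= 2.0))
    return SelectedConstraint(
        i=i, j=j, r_squared=(r2 if math.isfinite(r2) else float("nan")),
        within_twofold=within, n=len(names),
    )
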