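"""Synthetic fixtures with known ground truth.

Real riboswitch assays come from plate readers and aptamers from SELEX
papers; everything here emulates those inputs at desk scale so every
downstream stage (endpoint analysis, beta regression, constraint
selection) can be exercised against a recoverable truth without any
external data. Traces follow a logistic accumulation curve -- expression
rises after an onset lag and plateaus once the reaction exhausts -- on
top of a baseline, a slow linear drift, and Gaussian reader noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay import KineticTrace, TraceRole
from .calibration import CalibrationParams, txtl_calibration
from .constraint_scan import SubConstraint, rebuild_construct
from .energy import tir, total_binding_energy
from .folding import fold_mfe
from .switch import AptamerSpec, Mode, RiboswitchConstruct, evaluate_switch


@dataclass(frozen=True)
class TraceGeneratorParams:
    """Parameters of one synthetic kinetic trace.

    fluorescence(t) = baseline + drift_slope*t
                      + plateau / (1 + exp(-rise_rate*(t - onset_time)))
                      + N(0, noise_sd)
    """

    plateau: float
    onset_time: float = 295.0
    rise_rate: float = 1.0
    baseline: float = 50.0
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    n_points: int = 60
    interval: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau < 0 or self.noise_sd < 0:
            raise ValueError("plateau and noise_sd must be >= 0")
        if self.n_points < 30:
            raise ValueError("n_points must be >= 30 for endpoint analysis")


def generate_trace(
    p: TraceGeneratorParams,
    well: str = "A1",
    construct: str = "",
    ligand_conc: float = 0.0,
    replicate: int = 0,
    role: TraceRole = TraceRole.RIBOSWITCH,
) -> KineticTrace:
    """Seeded logistic accumulation trace."""
    rng = np.random.default_rng(p.seed)
    t = np.arange(p.n_points) * p.interval
    f = (
        p.baseline
        + p.drift_slope * t
        + p.plateau / (1.0 + np.exp(-p.rise_rate * (t - p.onset_time)))
    )
    if p.noise_sd > 0:
        f = f + rng.normal(0.0, p.noise_sd, size=p.n_points)
    return KineticTrace(
        well=well,
        times=tuple(t),
        fluorescence=tuple(f),
        construct=construct,
        ligand_conc=ligand_conc,
        replicate=replicate,
        role=role,
    )


def toy_aptamer(
    kind: str = "hairpin",
    stem_len: int = 4,
    loop_len: int = 4,
    kd: float = 1e-7,
    name: str | None = None,
    ligand_name: str = "toy-protein",
) -> AptamerSpec:
    """A designed aptamer whose MFE structure *is* its bound structure.

    ``hairpin`` gives a G:C stem with an A loop; ``bulged_hairpin`` adds a
    single-A bulge in the 3' strand; ``double_hairpin`` stacks two
    hairpins (stems ``stem_len`` and ``stem_len - 1``) joined by a short
    linker, giving structurally distinct subregions. The declared bound
    structure is verified by folding; degenerate parameter choices are
    retried across alternative stems and otherwise rejected with a
    diagnostic.
    """
    if stem_len < 3 or loop_len < 3:
        raise ValueError("stem_len and loop_len must both be >= 3")
    candidates = []
    if kind == "hairpin":
        for five, three in (("G", "C"), ("C", "G")):
            candidates.append(five * stem_len + "A" * loop_len + three * stem_len)
    elif kind == "bulged_hairpin":
        k = stem_len // 2
        for five, three in (("G", "C"), ("C", "G")):
            candidates.append(
                five * stem_len
                + "A" * loop_len
                + three * (stem_len - k)
                + "A"
                + three * k
            )
    elif kind == "double_hairpin":
        for five, three in (("G", "C"), ("C", "G")):
            candidates.append(
                five * stem_len
                + "A" * loop_len
                + three * stem_len
                + "AAA"
                + five * (stem_len - 1)
                + "A" * loop_len
                + three * (stem_len - 1)
            )
    else:
        raise ValueError(f"unknown aptamer kind {kind!r}")

    for seq in candidates:
        state = fold_mfe(seq)
        n_pairs = state.structure.count("(")
        if n_pairs >= stem_len - 1 and state.dg_fold < 0:
            return AptamerSpec(
                name=name or f"toy-{kind}-s{stem_len}l{loop_len}",
                sequence=seq,
                bound_structure=state.structure,
                kd=kd,
                ligand_name=ligand_name,
            )
    raise ValueError(
        f"toy_aptamer({kind}, stem={stem_len}, loop={loop_len}): all candidate "
        "sequences fold degenerately; choose a longer stem"
    )


def steric_switch(
    aptamer: AptamerSpec,
    gap: int = 0,
    cds: str | None = None,
    name: str | None = None,
) -> RiboswitchConstruct:
    """An OFF switch repressing purely by steric hindrance.

    The aptamer is placed ``gap`` nt (unstructured A spacer) upstream of
    a consensus SD at optimal spacing, with structure-invariant flanks:
    the mRNA structure is the same in the free and protein-bound states,
    so any repression must come from the bound protein physically
    blocking ribosome docking -- a mechanism outside the free-energy
    model, which accordingly predicts r_max = 1 for such designs.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    return RiboswitchConstruct(
        name=name or f"steric+{gap}",
        pre_aptamer="AAA",
        aptamer=aptamer,
        post_aptamer="A" * gap + "AAGGAGGU" + "AACAA",
        cds=cds or REPORTER_CDS,
        mode=Mode.OFF,
    )


# -- whole-study generation ---------------------------------------------

_SD_VARIANTS = (
    "AAGGAGG",
    "AGGAGG",
    "AGGAG",
    "GGAGG",
    "AGGA",
    "GGAG",
    "GAGG",
    "AAGGA",
)

#: reporter CDS stub: start codon + enough codons for the footprint
REPORTER_CDS = "AUGGCUUCCUCCGAAGACGUUAUCAAA"


@dataclass
class StudyConfig:
    """Knobs of the synthetic study generator (defaults = study conditions)."""

    n_constructs: int = 34
    n_replicates: int = 6
    mode: Mode = Mode.OFF
    dose: float = 1.25e-6  # molar, maximum induction
    aptamer_kind: str = "hairpin"
    stem_len: int = 4
    loop_len: int = 4
    kd: float = 187.7e-9
    true_subconstraint: tuple[int, int] | None = None  # default: full aptamer
    trace_noise_sd: float = 0.0
    ratio_noise_sd: float = 0.0  # lognormal sigma on measured ratios
    calib: CalibrationParams = field(default_factory=txtl_calibration)


@dataclass
class SyntheticStudy:
    """A generated study: constructs, traces, and the generating truth."""

    config: StudyConfig
    seed: int
    aptamer: AptamerSpec
    constructs: list[RiboswitchConstruct]
    subconstraint: SubConstraint
    dg_total_unbound: dict[str, float]
    true_endpoints: dict[str, dict[float, float]]  # name -> dose -> plateau
    measured_ratios: dict[str, float]
    true_ratios: dict[str, float]
    traces: list[KineticTrace]

    @property
    def calib(self) -> CalibrationParams:
        return self.config.calib


def _random_construct(
    rng: np.random.Generator, aptamer: AptamerSpec, mode: Mode, idx: int
) -> RiboswitchConstruct:
    bases = "ACGU"
    pre = "".join(rng.choice(list(bases), size=rng.integers(6, 14)))
    sd = _SD_VARIANTS[rng.integers(0, len(_SD_VARIANTS))]
    spacer = "".join(rng.choice(list("ACU"), size=rng.integers(4, 9)))
    lead = "".join(rng.choice(list(bases), size=rng.integers(0, 5)))
    return RiboswitchConstruct(
        name=f"RS{idx:02d}",
        pre_aptamer=pre,
        aptamer=aptamer,
        post_aptamer=lead + sd + spacer,
        cds=REPORTER_CDS,
        mode=mode,
    )


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Build a seeded synthetic riboswitch study with full ground truth.

    Constructs are random UTR designs around one toy aptamer; their
    model-true expression endpoints at each dose follow the riboswitch
    model itself, evaluated under the configured "true" calibration and
    the configured true aptamer subconstraint. Kinetic traces and noisy
    measured ratios are derived from those endpoints, so every downstream
    estimate (corrected endpoints, beta, the selected subconstraint) has
    a closed-form generating value.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    calib = config.calib
    aptamer = toy_aptamer(
        config.aptamer_kind, config.stem_len, config.loop_len, config.kd
    )
    L = len(aptamer)
    i_star, j_star = config.true_subconstraint or (1, L)
    sub_seq = aptamer.sequence[i_star - 1 : j_star]
    sub_structure = (
        "." if len(sub_seq) == 1 else fold_mfe(sub_seq, None, calib.fold_temperature_c).structure
    )
    sub = SubConstraint(i=i_star, j=j_star, substructure=sub_structure)

    constructs = [
        _random_construct(rng, aptamer, config.mode, k)
        for k in range(config.n_constructs)
    ]

    dg_unbound: dict[str, float] = {}
    true_endpoints: dict[str, dict[float, float]] = {}
    true_ratios: dict[str, float] = {}
    measured: dict[str, float] = {}
    traces: list[KineticTrace] = []

    well_idx = 0
    for c in constructs:
        bd = total_binding_energy(c.mrna(), None, calib)
        dg_unbound[c.name] = bd.dg_total
        truth = evaluate_switch(rebuild_construct(c, sub), config.dose, calib)
        e0 = tir(bd.dg_total, calib)
        # oriented r_actual back to a raw +dose/-dose expression factor
        factor = truth.r_actual if truth.mode is Mode.ON else 1.0 / truth.r_actual
        if not truth.as_designed:
            factor = 1.0 / factor
        e_dose = e0 * factor
        true_endpoints[c.name] = {0.0: e0, config.dose: e_dose}
        true_ratios[c.name] = truth.r_actual
        noise = (
            math.exp(rng.normal(0.0, config.ratio_noise_sd))
            if config.ratio_noise_sd > 0
            else 1.0
        )
        measured[c.name] = truth.r_actual * noise

        for dose, plateau in true_endpoints[c.name].items():
            for rep in range(config.n_replicates):
                well_idx += 1
                p = TraceGeneratorParams(
                    plateau=plateau,
                    noise_sd=config.trace_noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                traces.append(
                    generate_trace(
                        p,
                        well=f"W{well_idx:03d}",
                        construct=c.name,
                        ligand_conc=dose,
                        replicate=rep,
                        role=TraceRole.RIBOSWITCH,
                    )
                )

    # one no-DNA control per replicate (shared across constructs)
    for rep in range(config.n_replicates):
        well_idx += 1
        p = TraceGeneratorParams(
            plateau=0.0,
            noise_sd=config.trace_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        traces.append(
            generate_trace(
                p,
                well=f"W{well_idx:03d}",
                construct="no_dna",
                ligand_conc=0.0,
                replicate=rep,
                role=TraceRole.NO_DNA_CONTROL,
            )
        )

    return SyntheticStudy(
        config=config,
        seed=seed,
        aptamer=aptamer,
        constructs=constructs,
        subconstraint=sub,
        dg_total_unbound=dg_unbound,
        true_endpoints=true_endpoints,
        measured_ratios=measured,
        true_ratios=true_ratios,
        traces=traces,
    )
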