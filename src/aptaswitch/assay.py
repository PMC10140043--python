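"""Cell-free (TX-TL) plate-reader analysis.

Turns kinetic mRFP1 fluorescence traces into corrected endpoints,
activation/repression ratios with no-aptamer-control correction,
dose-response (Hill) fits, and the apparent-Boltzmann-factor regression
relating predicted ribosome binding energies to measured expression.

Endpoint convention: the endpoint of a reaction is the mean of its last
~15 samples (expression has plateaued), the background the mean of its
first ~15 samples (before mature reporter accumulates), and the slow
non-specific fluorescence rise is removed by subtracting the same
endpoint-minus-background quantity measured on a no-DNA reaction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .switch import Mode


class TraceRole(str, enum.Enum):
    RIBOSWITCH = "riboswitch"
    NO_APTAMER_CONTROL = "no_aptamer_control"
    NO_MRFP1_CONTROL = "no_mrfp1_control"
    NO_DNA_CONTROL = "no_dna_control"


class DegenerateRatioError(ValueError):
    """A regulation ratio could not be formed from non-positive endpoints."""


@dataclass(frozen=True)
class KineticTrace:
    """One well's fluorescence time series (times in minutes, au)."""

    well: str
    times: tuple[float, ...]
    fluorescence: tuple[float, ...]
    construct: str = ""
    ligand_conc: float = 0.0
    replicate: int = 0
    role: TraceRole = TraceRole.RIBOSWITCH

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape:
            raise ValueError(f"{self.well}: times and fluorescence differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.well}: times must be strictly increasing")
        if np.any(~np.isfinite(f)):
            raise ValueError(f"{self.well}: NaN/inf fluorescence values")
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "fluorescence", tuple(f))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class AssayResult:
    """Corrected endpoint of one reaction."""

    well: str
    endpoint: float
    background: float
    drift_correction: float
    corrected_endpoint: float
    n_replicates: int = 1
    mean: float = math.nan
    sd: float = math.nan
    ci95: tuple[float, float] = (math.nan, math.nan)


def endpoint(
    trace: KineticTrace, no_dna: KineticTrace, window: int = 15
) -> AssayResult:
    """Background- and drift-corrected expression endpoint of one well.

    corrected = (mean(last window) - mean(first window))
                - (same quantity on the no-DNA trace)
    The two windows must not overlap on either trace.
    """
    for t in (trace, no_dna):
        if len(t) < 2 * window:
            raise ValueError(
                f"trace {t.well!r} has {len(t)} points; needs >= {2 * window} "
                f"for two non-overlapping {window}-point windows"
            )

    def rise(t: KineticTrace) -> tuple[float, float]:
        f = np.asarray(t.fluorescence)
        return float(f[-window:].mean()), float(f[:window].mean())

    end, back = rise(trace)
    drift = rise(no_dna)[0] - rise(no_dna)[1]
    corrected = (end - back) - drift
    return AssayResult(
        well=trace.well,
        endpoint=end,
        background=back,
        drift_correction=drift,
        corrected_endpoint=corrected,
    )


def summarize_replicates(results: list[AssayResult]) -> AssayResult:
    """Pool replicate corrected endpoints: mean, sd, 95% t-interval."""
    if not results:
        raise ValueError("no replicates to summarize")
    vals = np.array([r.corrected_endpoint for r in results])
    n = len(vals)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    else:
        half = 0.0
    return AssayResult(
        well=results[0].well,
        endpoint=mean,
        background=math.nan,
        drift_correction=math.nan,
        corrected_endpoint=mean,
        n_replicates=n,
        mean=mean,
        sd=sd,
        ci95=(mean - half, mean + half),
    )


def regulation_ratio(
    with_ligand: AssayResult, without_ligand: AssayResult, mode: Mode
) -> float:
    """Mode-oriented expression ratio between +ligand and -ligand wells.

    ON: endpoint(+ligand)/endpoint(-ligand); OFF: the reciprocal. A value
    below 1 means the construct moved opposite to its declared mode.
    """
    a = with_ligand.corrected_endpoint
    b = without_ligand.corrected_endpoint
    if a <= 0 or b <= 0:
        raise DegenerateRatioError(
            f"non-positive corrected endpoint (with={a:.3g}, without={b:.3g})"
        )
    return a / b if Mode(mode) is Mode.ON else b / a


def correct_nonspecific(
    riboswitch_ratio: float, control_ratio: float, mode: Mode
) -> float:
    """Divide out the no-aptamer control's non-specific response.

    Both ratios must be expressed in the same mode orientation (use
    :func:`regulation_ratio` with the same mode for both constructs; a
    control that *rises* 2.37-fold under an OFF-mode assay has repression
    ratio 1/2.37, so dividing by it multiplies the switch's ratio).
    """
    Mode(mode)
    if riboswitch_ratio <= 0 or control_ratio <= 0:
        raise ValueError("ratios must be > 0")
    return riboswitch_ratio / control_ratio


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter Hill fit of corrected endpoints vs concentration."""

    baseline: float
    amplitude: float
    half_max_conc: float
    hill_n: float
    direction: str  # "activation" | "repression"
    rss: float
    converged: bool
    degenerate: bool = False

    def predict(self, conc):
        p = np.asarray(conc, dtype=float)
        occ = np.zeros_like(p)
        pos = p > 0
        occ[pos] = p[pos] ** self.hill_n / (
            p[pos] ** self.hill_n + self.half_max_conc**self.hill_n
        )
        return self.baseline + self.amplitude * occ


def fit_dose_response(
    concs: list[float], corrected_endpoints: list[float]
) -> DoseResponseFit:
    """Least-squares Hill fit: E(P) = baseline + A * P^n / (P^n + K^n).

    The amplitude is signed; its sign determines activation vs
    repression. Flat data returns a degenerate flagged fit instead of a
    spurious curve; non-convergence is flagged, never silent.
    """
    p = np.asarray(concs, dtype=float)
    y = np.asarray(corrected_endpoints, dtype=float)
    if p.shape != y.shape or len(p) < 4:
        raise ValueError("need >= 4 (conc, endpoint) pairs")
    if len(np.unique(p)) < 4 or 0.0 not in p:
        raise ValueError("need >= 4 distinct concentrations including 0")

    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1.0)
    if span <= 1e-9 * scale:
        return DoseResponseFit(
            baseline=float(y.mean()), amplitude=0.0, half_max_conc=float("nan"),
            hill_n=1.0, direction="activation", rss=float(np.sum((y - y.mean()) ** 2)),
            converged=True, degenerate=True,
        )

    baseline0 = float(y[p == 0].mean())
    amp0 = float(y[p == p.max()].mean() - baseline0)
    pos = np.sort(p[p > 0])
    k0 = float(np.median(pos))

    def model(pp, base, amp, k, n):
        occ = np.where(pp > 0, pp**n / (pp**n + k**n), 0.0)
        return base + amp * occ

    try:
        popt, _ = optimize.curve_fit(
            model,
            p,
            y,
            p0=[baseline0, amp0, k0, 1.0],
            bounds=(
                [-np.inf, -np.inf, pos.min() / 100.0, 0.1],
                [np.inf, np.inf, pos.max() * 100.0, 10.0],
            ),
            maxfev=20_000,
        )
        converged = True
    except RuntimeError:
        popt = [baseline0, amp0, k0, 1.0]
        converged = False
    base, amp, k, n = (float(v) for v in popt)
    rss = float(np.sum((model(p, base, amp, k, n) - y) ** 2))
    return DoseResponseFit(
        baseline=base,
        amplitude=amp,
        half_max_conc=k,
        hill_n=n,
        direction="activation" if amp >= 0 else "repression",
        rss=rss,
        converged=converged,
    )


@dataclass(frozen=True)
class BetaFit:
    """Apparent Boltzmann factor from ln(expression) vs -dG_total OLS."""

    beta_hat: float
    ln_k_hat: float
    r_squared: float
    p_value: float
    n: int
    beta_se: float
    ci95: tuple[float, float]


def fit_beta(dg_totals: list[float], corrected_endpoints: list[float]) -> BetaFit:
    """OLS of ln(endpoint) on -dG_total.

    The slope is the apparent Boltzmann factor beta, the intercept
    ln(k). Reports Pearson R^2 and the two-sided slope p-value.
    """
    dg = np.asarray(dg_totals, dtype=float)
    y = np.asarray(corrected_endpoints, dtype=float)
    if dg.shape != y.shape or len(dg) < 3:
        raise ValueError("need >= 3 (dG_total, endpoint) pairs")
    if np.any(y <= 0):
        raise ValueError("endpoints must be > 0 for log-linear regression")
    x = -dg
    if np.ptp(x) <= 0:
        raise ValueError("dG_total values are all identical; slope undefined")
    res = stats.linregress(x, np.log(y))
    n = len(x)
    half = stats.t.ppf(0.975, n - 2) * res.stderr if n > 2 else math.inf
    return BetaFit(
        beta_hat=float(res.slope),
        ln_k_hat=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        beta_se=float(res.stderr),
        ci95=(float(res.slope - half), float(res.slope + half)),
    )


def welch_ttest(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-tailed two-sample t-test with unequal variances (Welch)."""
    res = stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False)
    return float(res.statistic), float(res.pvalue)
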