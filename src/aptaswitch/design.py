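"""Multi-objective genetic design of pre-/post-aptamer sequences.

The designer searches the space of pre- and post-aptamer sequences
flanking a fixed aptamer for riboswitches maximizing the predicted
regulation ratio. The search is a seeded NSGA-II-style genetic
algorithm (non-dominated sorting, crowding distance, tournament
selection, per-region one-point crossover, per-base mutation, and
bounded insertion/deletion so the designed length itself evolves).
Objectives, per the design mode:

* maximize the mode-oriented log fold-change log(r_max);
* ON: additionally maximize TIR_bound and minimize TIR_unbound;
* OFF: the reverse.

The returned set is the Pareto-optimal (mutually non-dominated) front.
:func:`brute_force_design` exhaustively enumerates tiny design spaces and
serves as the test oracle for the GA.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

from .calibration import CalibrationParams
from .switch import (
    AptamerSpec,
    Mode,
    RiboswitchConstruct,
    SwitchPrediction,
    evaluate_switch,
)

_BASES = "ACGU"


class DesignError(ValueError):
    """Infeasible design specification."""


def search_space_log10(length: int) -> int:
    """floor(log10(4^L)): order of magnitude of an L-nt design space."""
    if length < 0:
        raise ValueError("length must be >= 0")
    return math.floor(length * math.log10(4))


@dataclass
class DesignSpec:
    """Inputs and knobs of a design run.

    ``length_range`` bounds the *combined* designed pre+post length.
    ``post_scaffold`` is an optional constant 3' tail of the post-aptamer
    region (e.g. a fixed SD cassette), excluded from the evolvable length
    and from motif screening. ``forbidden_motifs`` are screened out of the
    designed regions (default: no spurious AUG start in the 5' UTR).
    """

    aptamer: AptamerSpec
    cds: str
    mode: Mode = Mode.ON
    length_range: tuple[int, int] = (44, 55)
    post_scaffold: str = ""
    forbidden_motifs: tuple[str, ...] = ("AUG",)
    population: int = 100
    generations: int = 50
    mutation_rate: float = 0.05
    crossover_rate: float = 0.8
    indel_rate: float = 0.1
    seed: int = 0
    calib: CalibrationParams = field(default_factory=CalibrationParams)

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        lo, hi = self.length_range
        if not 0 <= lo <= hi <= 200:
            raise DesignError(f"length_range {self.length_range} outside [0, 200]")
        if hi + len(self.post_scaffold) < 12:
            raise DesignError(
                "designed region too short to host an SD and spacer; "
                f"max designed length {hi} + scaffold {len(self.post_scaffold)} < 12"
            )
        if self.population < 4:
            raise DesignError("population must be >= 4")


@dataclass(frozen=True)
class DesignCandidate:
    """One designed riboswitch and its objective values."""

    pre_aptamer: str
    post_aptamer: str
    prediction: SwitchPrediction
    objectives: tuple[float, float, float]  # (r_max oriented raw, tir_bound, tir_unbound)

    @property
    def sequence_key(self) -> str:
        return self.pre_aptamer + "&" + self.post_aptamer


def _motif_ok(spec: DesignSpec, pre: str, post: str) -> bool:
    return not any(m in pre or m in post for m in spec.forbidden_motifs)


def _assemble(spec: DesignSpec, pre: str, post: str) -> RiboswitchConstruct:
    return RiboswitchConstruct(
        name=f"design:{pre}|{post}",
        pre_aptamer=pre,
        aptamer=spec.aptamer,
        post_aptamer=post + spec.post_scaffold,
        cds=spec.cds,
        mode=spec.mode,
    )


def _evaluate(spec: DesignSpec, pre: str, post: str) -> DesignCandidate:
    pred = evaluate_switch(_assemble(spec, pre, post), math.inf, spec.calib)
    # raw mode-oriented ratio (may be < 1 for dead designs)
    if spec.mode is Mode.ON:
        raw = pred.tir_bound / pred.tir_unbound
    else:
        raw = pred.tir_unbound / pred.tir_bound
    return DesignCandidate(
        pre_aptamer=pre,
        post_aptamer=post,
        prediction=pred,
        objectives=(raw, pred.tir_bound, pred.tir_unbound),
    )


def _maximized_objectives(c: DesignCandidate, mode: Mode) -> tuple[float, ...]:
    """All-maximized objective vector used for dominance checks."""
    raw, tir_b, tir_u = c.objectives
    if mode is Mode.ON:
        return (raw, tir_b, -tir_u)
    return (raw, tir_u, -tir_b)


def _dominates(a: tuple[float, ...], b: tuple[float, ...]) -> bool:
    return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))


def pareto_filter(
    candidates: list[DesignCandidate], mode: Mode | None = None
) -> list[DesignCandidate]:
    """Exact non-dominated subset, deduplicated by sequence.

    Ordered by descending oriented r_max, ties broken lexicographically on
    the designed sequences for determinism.
    """
    if not candidates:
        raise ValueError("pareto_filter requires at least one candidate")
    mode = mode or candidates[0].prediction.mode
    unique: dict[str, DesignCandidate] = {}
    for c in candidates:
        unique.setdefault(c.sequence_key, c)
    pool = list(unique.values())
    vecs = [_maximized_objectives(c, mode) for c in pool]
    front = [
        c
        for i, c in enumerate(pool)
        if not any(_dominates(vecs[j], vecs[i]) for j in range(len(pool)) if j != i)
    ]
    front.sort(key=lambda c: (-c.objectives[0], c.sequence_key))
    return front


# -- NSGA-II machinery ---------------------------------------------------


def _fast_nondominated_sort(vecs: list[tuple[float, ...]]) -> list[int]:
    n = len(vecs)
    ranks = [0] * n
    dominated: list[list[int]] = [[] for _ in range(n)]
    counts = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(vecs[i], vecs[j]):
                dominated[i].append(j)
                counts[j] += 1
            elif _dominates(vecs[j], vecs[i]):
                dominated[j].append(i)
                counts[i] += 1
    front = [i for i in range(n) if counts[i] == 0]
    rank = 0
    while front:
        nxt = []
        for i in front:
            ranks[i] = rank
            for j in dominated[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        front = nxt
        rank += 1
    return ranks


def _crowding(vecs: list[tuple[float, ...]], idx: list[int]) -> dict[int, float]:
    dist = {i: 0.0 for i in idx}
    if len(idx) <= 2:
        return {i: math.inf for i in idx}
    n_obj = len(vecs[idx[0]])
    for k in range(n_obj):
        order = sorted(idx, key=lambda i: vecs[i][k])
        span = vecs[order[-1]][k] - vecs[order[0]][k]
        dist[order[0]] = dist[order[-1]] = math.inf
        if span <= 0:
            continue
        for a in range(1, len(order) - 1):
            dist[order[a]] += (vecs[order[a + 1]][k] - vecs[order[a - 1]][k]) / span
    return dist


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _random_individual(spec: DesignSpec, rng: random.Random) -> tuple[str, str]:
    lo, hi = spec.length_range
    total = rng.randint(lo, hi)
    n_pre = rng.randint(0, total)
    for _ in range(200):
        pre = _random_seq(rng, n_pre)
        post = _random_seq(rng, total - n_pre)
        if _motif_ok(spec, pre, post):
            return pre, post
    raise DesignError("could not sample a motif-free individual")


def _mutate_region(seq: str, spec: DesignSpec, rng: random.Random) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < spec.mutation_rate:
            out[i] = rng.choice(_BASES.replace(out[i], ""))
    return "".join(out)


def _indel(pre: str, post: str, spec: DesignSpec, rng: random.Random) -> tuple[str, str]:
    lo, hi = spec.length_range
    total = len(pre) + len(post)
    grow = rng.random() < 0.5
    if grow and total < hi:
        if rng.random() < 0.5 and True:
            region, other, is_pre = pre, post, True
        else:
            region, other, is_pre = post, pre, False
        pos = rng.randint(0, len(region))
        region = region[:pos] + rng.choice(_BASES) + region[pos:]
        return (region, other) if is_pre else (other, region)
    if not grow and total > lo and total > 0:
        pick_pre = len(pre) > 0 and (len(post) == 0 or rng.random() < 0.5)
        region = pre if pick_pre else post
        pos = rng.randrange(len(region))
        region = region[:pos] + region[pos + 1 :]
        return (region, post) if pick_pre else (pre, region)
    return pre, post


def _crossover(
    a: tuple[str, str], b: tuple[str, str], rng: random.Random
) -> tuple[str, str]:
    def cross(x: str, y: str) -> str:
        if not x or not y:
            return x
        cut_x = rng.randint(0, len(x))
        cut_y = rng.randint(0, len(y))
        return x[:cut_x] + y[cut_y:]

    return cross(a[0], b[0]), cross(a[1], b[1])


def _repair(spec: DesignSpec, pre: str, post: str, rng: random.Random) -> tuple[str, str]:
    lo, hi = spec.length_range
    total = len(pre) + len(post)
    while total > hi:
        pick_pre = len(pre) > 0 and (len(post) == 0 or rng.random() < 0.5)
        if pick_pre:
            pos = rng.randrange(len(pre))
            pre = pre[:pos] + pre[pos + 1 :]
        else:
            pos = rng.randrange(len(post))
            post = post[:pos] + post[pos + 1 :]
        total -= 1
    while total < lo:
        if rng.random() < 0.5:
            pos = rng.randint(0, len(pre))
            pre = pre[:pos] + rng.choice(_BASES) + pre[pos:]
        else:
            pos = rng.randint(0, len(post))
            post = post[:pos] + rng.choice(_BASES) + post[pos:]
        total += 1
    for _ in range(500):
        hit = None
        for m in spec.forbidden_motifs:
            k = pre.find(m)
            if k >= 0:
                hit = ("pre", k, m)
                break
            k = post.find(m)
            if k >= 0:
                hit = ("post", k, m)
                break
        if hit is None:
            return pre, post
        which, k, m = hit
        j = k + rng.randrange(len(m))
        if which == "pre":
            pre = pre[:j] + rng.choice(_BASES.replace(pre[j], "")) + pre[j + 1 :]
        else:
            post = post[:j] + rng.choice(_BASES.replace(post[j], "")) + post[j + 1 :]
    raise DesignError("motif repair did not converge")


def design_switches(
    spec: DesignSpec, on_generation=None
) -> list[DesignCandidate]:
    """Run the seeded genetic design and return the Pareto-optimal set.

    Deterministic for a given spec + seed. Every returned candidate
    satisfies the length and forbidden-motif constraints, and the set is
    mutually non-dominated. ``on_generation(gen, best_raw_ratio)`` is
    invoked after each environmental selection when given.
    """
    rng = random.Random(spec.seed)
    cache: dict[str, DesignCandidate] = {}

    def evaluated(pre: str, post: str) -> DesignCandidate:
        key = pre + "&" + post
        if key not in cache:
            cache[key] = _evaluate(spec, pre, post)
        return cache[key]

    pop = [evaluated(*_random_individual(spec, rng)) for _ in range(spec.population)]

    for gen in range(spec.generations):
        vecs = [_maximized_objectives(c, spec.mode) for c in pop]
        ranks = _fast_nondominated_sort(vecs)
        by_rank: dict[int, list[int]] = {}
        for i, r in enumerate(ranks):
            by_rank.setdefault(r, []).append(i)
        crowd: dict[int, float] = {}
        for idx in by_rank.values():
            crowd.update(_crowding(vecs, idx))

        def tourney() -> DesignCandidate:
            i, j = rng.randrange(len(pop)), rng.randrange(len(pop))
            if (ranks[i], -crowd[i]) <= (ranks[j], -crowd[j]):
                return pop[i]
            return pop[j]

        offspring: list[DesignCandidate] = []
        while len(offspring) < spec.population:
            p1, p2 = tourney(), tourney()
            pre, post = p1.pre_aptamer, p1.post_aptamer
            if rng.random() < spec.crossover_rate:
                pre, post = _crossover(
                    (pre, post), (p2.pre_aptamer, p2.post_aptamer), rng
                )
            pre = _mutate_region(pre, spec, rng)
            post = _mutate_region(post, spec, rng)
            if rng.random() < spec.indel_rate:
                pre, post = _indel(pre, post, spec, rng)
            pre, post = _repair(spec, pre, post, rng)
            offspring.append(evaluated(pre, post))

        # elitist environmental selection on the combined pool
        combined = pop + offspring
        vecs = [_maximized_objectives(c, spec.mode) for c in combined]
        ranks_c = _fast_nondominated_sort(vecs)
        by_rank = {}
        for i, r in enumerate(ranks_c):
            by_rank.setdefault(r, []).append(i)
        crowd = {}
        for idx in by_rank.values():
            crowd.update(_crowding(vecs, idx))
        order = sorted(
            range(len(combined)),
            key=lambda i: (ranks_c[i], -crowd[i], combined[i].sequence_key),
        )
        pop = [combined[i] for i in order[: spec.population]]
        if on_generation is not None:
            on_generation(gen, max(c.objectives[0] for c in pop))

    return pareto_filter(pop, spec.mode)


def brute_force_design(spec: DesignSpec, max_space: int = 100_000) -> DesignCandidate:
    """Exhaustively enumerate a tiny design space; oracle for the GA.

    Returns the global optimum by oriented r_max (ties broken
    lexicographically on the designed sequences). Refuses spaces larger
    than ``max_space`` with a size estimate.
    """
    lo, hi = spec.length_range
    size = sum((total + 1) * 4**total for total in range(lo, hi + 1))
    if size > max_space:
        raise DesignError(
            f"design space has ~{size:.3g} candidates (> {max_space}); "
            "brute force refused"
        )
    best: DesignCandidate | None = None
    for total in range(lo, hi + 1):
        for n_pre in range(total + 1):
            for combo in _all_seqs(total):
                pre, post = combo[:n_pre], combo[n_pre:]
                if not _motif_ok(spec, pre, post):
                    continue
                cand = _evaluate(spec, pre, post)
                if best is None or (-cand.objectives[0], cand.sequence_key) < (
                    -best.objectives[0],
                    best.sequence_key,
                ):
                    best = cand
    if best is None:
        raise DesignError("no feasible candidate in the design space")
    return best


def _all_seqs(length: int):
    if length == 0:
        yield ""
        return
    for head in _all_seqs(length - 1):
        for b in _BASES:
            yield head + b
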