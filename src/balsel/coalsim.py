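"""Coalescent simulator for null distributions and synthetic data.

The simulator runs the standard neutral coalescent with recombination
(Hudson's ancestral-recombination-graph algorithm) under piecewise
demographic models: per-population sizes with exponential growth phases,
population splits, instantaneous bottlenecks of given intensity, and
symmetric or asymmetric migration.  Mutations follow the infinite-sites
model, placed as a Poisson process of rate theta/2 per unit of scaled
branch length (the simulation is conditioned on the mutation rate, not on
the number of segregating sites).

A second mode models an ancient balanced polymorphism: lineages are
partitioned into two allelic classes at a focal site, coalescence is
restricted to within-class, lineages switch class at a low rate, and the
classes are forced to merge at the age of the balanced allele.  Sampling
both classes therefore forces the root of the genealogy to predate the
allele age, producing the two deep haplotype clades characteristic of
long-term balancing selection.

Internal time is measured in generations; conversion to years (via the
generation time) happens only in reporting code.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Sequence

import numpy as np

from balsel.haplotypes import (
    HaplotypeAlignment,
    ReferencePanel,
    _fractions_to_positions,
)

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


# ----------------------------------------------------------------------
# Demography
# ----------------------------------------------------------------------

@dataclass
class Population:
    name: str
    size: float           # diploid effective size at time 0
    growth_rate: float = 0.0   # forward per-generation exponential rate

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise SimulationError(f"population {self.name}: size must be > 0")


@dataclass
class Event:
    """Demographic event at a (backwards) time in generations.

    kinds
    -----
    size_change : population ``pop`` takes ``size`` and ``growth`` further
        back in time.
    split : all lineages of ``pop`` move into ``dest`` (backwards merge of
        a derived population into its ancestor).
    bottleneck : instantaneous coalescence burst in ``pop`` such that a
        pair of lineages finds a common ancestor with probability
        ``strength``.
    migration_off : all migration rates become zero.
    set_migration : migration matrix replaced by ``rates``.
    """

    time: float
    kind: str
    pop: int | None = None
    dest: int | None = None
    size: float | None = None
    growth: float | None = None
    strength: float | None = None
    rates: list | None = None


@dataclass
class DemographicModel:
    populations: list[Population]
    migration: np.ndarray | None = None   # per-lineage per-generation, row=source (backwards)
    events: list[Event] = field(default_factory=list)
    name: str = "custom"

    def __post_init__(self) -> None:
        r = len(self.populations)
        if self.migration is None:
            self.migration = np.zeros((r, r))
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (r, r):
            raise SimulationError("migration matrix shape mismatch")
        if np.any(self.migration < 0):
            raise SimulationError("migration rates must be >= 0")
        np.fill_diagonal(self.migration, 0.0)
        self.events = sorted(self.events, key=lambda e: e.time)
        if any(e.time < 0 for e in self.events):
            raise SimulationError("event times must be >= 0")

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def reference_size(self) -> float:
        """N0 used to scale theta and rho (first population, present day)."""
        return self.populations[0].size

    @classmethod
    def constant(cls, N: float, name: str = "constant") -> "DemographicModel":
        return cls(populations=[Population("pop1", N)], name=name)

    @classmethod
    def island(
        cls, n_pops: int, N: float, migration_rate: float, name: str = "island"
    ) -> "DemographicModel":
        """Symmetric island model; ``migration_rate`` per lineage per gen."""
        M = np.full((n_pops, n_pops), migration_rate / max(n_pops - 1, 1))
        np.fill_diagonal(M, 0.0)
        pops = [Population(f"pop{i + 1}", N) for i in range(n_pops)]
        return cls(populations=pops, migration=M, name=name)


def calibrated_human_3pop() -> DemographicModel:
    """Calibrated three-population human model (African/European/Asian).

    Parameter constants (sizes, event times in generations, bottleneck
    intensities, migration rates) are program data stored in
    ``data/calibrated_human_3pop.json``; they reproduce the best-fit
    demographic model commonly used to calibrate human coalescent
    simulations, with out-of-Africa and population-specific bottlenecks,
    recent expansions, and low inter-continental migration.
    """
    ref = resources.files("balsel") / "data" / "calibrated_human_3pop.json"
    spec = json.loads(ref.read_text())
    pops = [Population(p["name"], p["size"]) for p in spec["populations"]]
    idx = {p.name: i for i, p in enumerate(pops)}
    r = len(pops)
    M = np.zeros((r, r))
    for m in spec.get("migration", []):
        M[idx[m["from"]], idx[m["to"]]] = m["rate"]
    events = []
    for e in spec["events"]:
        kw = dict(time=e["time"], kind=e["kind"])
        if "pop" in e:
            kw["pop"] = idx[e["pop"]]
        if "dest" in e:
            kw["dest"] = idx[e["dest"]]
        for k in ("size", "growth", "strength"):
            if k in e:
                kw[k] = e[k]
        events.append(Event(**kw))
    return DemographicModel(
        populations=pops, migration=M, events=events, name=spec["name"]
    )


# ----------------------------------------------------------------------
# Simulation configuration
# ----------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of one simulation run.

    theta and rho are per-locus population-scaled parameters
    (``4 * N_ref * rate_per_locus_per_generation``).  In balanced mode the
    sample of each population is split between the two allelic classes at
    the equilibrium frequency, the focal allele column is appended to the
    output, and ``balanced_age`` (generations) bounds the class structure.
    """

    n: Sequence[int]
    L: int
    theta: float
    rho: float = 0.0
    seed: int = 1
    iterations: int = 1
    mode: str = "neutral"          # "neutral" | "balanced"
    balanced_age: float | None = None      # generations
    balanced_freq: float = 0.5
    balanced_switch_rate: float = 0.0      # per lineage per generation
    focal_frac: float = 0.5
    pop_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.n = [int(x) for x in np.atleast_1d(self.n)]
        if sum(self.n) < 2:
            raise SimulationError("need at least 2 sampled chromosomes")
        if self.theta < 0 or self.rho < 0:
            raise SimulationError("theta and rho must be >= 0")
        if self.iterations < 1:
            raise SimulationError("iterations must be >= 1")
        if self.mode not in ("neutral", "balanced"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.mode == "balanced":
            if not self.balanced_age or self.balanced_age <= 0:
                raise SimulationError("balanced mode requires balanced_age > 0")
            if not (0 < self.balanced_freq < 1):
                raise SimulationError("balanced_freq must be in (0, 1)")
            if self.rho > 0:
                raise SimulationError(
                    "balanced mode models a non-recombining LD block (rho=0)"
                )


@dataclass
class SimReplicate:
    alignment: HaplotypeAlignment
    tmrca_gens: float
    focal_index: int | None = None    # column of the balanced focal site


# ----------------------------------------------------------------------
# ARG engine
# ----------------------------------------------------------------------

class _Lineage:
    __slots__ = ("pop", "cls", "segments")

    def __init__(self, pop: int, cls: int, segments: list):
        self.pop = pop
        self.cls = cls
        # segments: sorted list of [left, right, node, n_subtended]
        self.segments = segments

    @property
    def span(self) -> tuple[float, float]:
        return self.segments[0][0], self.segments[-1][1]


class _Engine:
    """One coalescent replicate (classes are sub-demes of populations)."""

    def __init__(self, config: SimConfig, model: DemographicModel, rng):
        self.cfg = config
        self.model = model
        self.rng = rng
        self.n_total = sum(config.n)
        n_ref = model.reference_size
        self.mu_locus = config.theta / (4.0 * n_ref)
        self.r_locus = config.rho / (4.0 * n_ref)

        self.node_time: list[float] = []
        self.edges: list[tuple[float, float, int, int]] = []
        self.roots: list[tuple[float, float, int, float]] = []

        self.sizes = [p.size for p in model.populations]
        self.growth = [p.growth_rate for p in model.populations]
        self.epoch_start = [0.0] * model.n_pops
        self.migration = model.migration.copy()

        self.balanced = config.mode == "balanced"
        self.cls_freq = [1.0 - config.balanced_freq, config.balanced_freq]
        self.classes_active = self.balanced
        self.focal_classes: list[int] = []

        self.lineages: list[_Lineage] = []
        if len(config.n) != model.n_pops:
            raise SimulationError(
                "sample-size list length does not match population count"
            )
        for pop, k in enumerate(config.n):
            for _ in range(k):
                cls = 0
                if self.balanced:
                    # deterministic split at the equilibrium frequency:
                    # conditioning on the polymorphism being observed
                    n_der = max(1, min(k - 1, round(config.balanced_freq * k)))
                    cls = 1 if sum(
                        1 for l in self.lineages if l.pop == pop and l.cls == 1
                    ) < n_der else 0
                node = len(self.node_time)
                self.node_time.append(0.0)
                self.lineages.append(
                    _Lineage(pop, cls, [[0.0, 1.0, node, 1]])
                )
                self.focal_classes.append(cls)

        self.event_queue = list(model.events)
        if self.balanced:
            self.event_queue.append(
                Event(time=config.balanced_age, kind="merge_classes")
            )
        self.event_queue.sort(key=lambda e: e.time)

    # -- demography helpers --------------------------------------------
    def _size_at(self, pop: int, t: float) -> float:
        g = self.growth[pop]
        if g == 0.0:
            return self.sizes[pop]
        return self.sizes[pop] * math.exp(-g * (t - self.epoch_start[pop]))

    def _coal_wait(self, pop: int, cls: int, k: int, t: float, f: float) -> float:
        """Waiting time to next coalescence in deme (pop, cls)."""
        if k < 2:
            return math.inf
        pairs = k * (k - 1) / 2.0
        e = self.rng.exponential()
        N = self._size_at(pop, t) * f
        g = self.growth[pop]
        if g == 0.0:
            return 2.0 * N * e / pairs
        # backward in time N(t+w) = N(t) * exp(-g w); hazard inversion
        arg = 1.0 + g * 2.0 * N * e / pairs
        if arg <= 0.0:
            return math.inf
        return math.log(arg) / g

    # -- event mechanics -------------------------------------------------
    def _new_node(self, t: float) -> int:
        self.node_time.append(t)
        return len(self.node_time) - 1

    def _coalesce_pair(self, i: int, j: int, t: float) -> None:
        a, b = self.lineages[i], self.lineages[j]
        node = self._new_node(t)
        bounds = sorted(
            {s[0] for s in a.segments}
            | {s[1] for s in a.segments}
            | {s[0] for s in b.segments}
            | {s[1] for s in b.segments}
        )

        def seg_at(lin: _Lineage, x: float):
            for s in lin.segments:
                if s[0] <= x < s[1]:
                    return s
            return None

        new_segments: list[list] = []

        def push(left, right, nd, nsub):
            if new_segments and new_segments[-1][2] == nd and \
                    new_segments[-1][1] == left and new_segments[-1][3] == nsub:
                new_segments[-1][1] = right
            else:
                new_segments.append([left, right, nd, nsub])

        for x0, x1 in zip(bounds[:-1], bounds[1:]):
            sa, sb = seg_at(a, x0), seg_at(b, x0)
            if sa is None and sb is None:
                continue
            if sa is not None and sb is not None:
                self.edges.append((x0, x1, node, sa[2]))
                self.edges.append((x0, x1, node, sb[2]))
                nsub = sa[3] + sb[3]
                if nsub == self.n_total:
                    self.roots.append((x0, x1, node, t))
                else:
                    push(x0, x1, node, nsub)
            else:
                s = sa if sa is not None else sb
                push(x0, x1, s[2], s[3])

        keep = _Lineage(a.pop, a.cls, new_segments)
        lin = self.lineages
        for idx in sorted((i, j), reverse=True):
            lin.pop(idx)
        if new_segments:
            lin.append(keep)

    def _recombine(self, i: int, u: float) -> None:
        lin = self.lineages[i]
        left_segs: list[list] = []
        right_segs: list[list] = []
        for s in lin.segments:
            if s[1] <= u:
                left_segs.append(s)
            elif s[0] >= u:
                right_segs.append(s)
            else:
                left_segs.append([s[0], u, s[2], s[3]])
                right_segs.append([u, s[1], s[2], s[3]])
        if not left_segs or not right_segs:
            return  # breakpoint outside ancestral material: no-op
        self.lineages[i] = _Lineage(lin.pop, lin.cls, left_segs)
        self.lineages.append(_Lineage(lin.pop, lin.cls, right_segs))

    def _bottleneck(self, pop: int, strength: float, t: float) -> None:
        tau = -math.log(1.0 - strength)
        classes = (0, 1) if self.classes_active else (0,)
        for cls in classes:
            # a class holding a fraction f of the population feels tau / f
            f = self.cls_freq[cls] if self.classes_active else 1.0
            remaining = tau / f
            while remaining > 0:
                idx = [
                    k for k, l in enumerate(self.lineages)
                    if l.pop == pop and l.cls == cls
                ]
                k = len(idx)
                if k < 2:
                    break
                w = self.rng.exponential() / (k * (k - 1) / 2.0)
                if w > remaining:
                    break
                remaining -= w
                i, j = self.rng.choice(k, size=2, replace=False)
                self._coalesce_pair(idx[i], idx[j], t)

    def _apply_event(self, ev: Event, t: float) -> None:
        if ev.kind == "size_change":
            self.sizes[ev.pop] = ev.size
            self.growth[ev.pop] = ev.growth or 0.0
            self.epoch_start[ev.pop] = t
        elif ev.kind == "split":
            for l in self.lineages:
                if l.pop == ev.pop:
                    l.pop = ev.dest
        elif ev.kind == "bottleneck":
            self._bottleneck(ev.pop, ev.strength, t)
        elif ev.kind == "migration_off":
            self.migration[:] = 0.0
        elif ev.kind == "set_migration":
            self.migration = np.asarray(ev.rates, dtype=float)
        elif ev.kind == "merge_classes":
            for l in self.lineages:
                l.cls = 0
            self.classes_active = False
        else:  # pragma: no cover - guarded by Event construction
            raise SimulationError(f"unknown event kind {ev.kind!r}")

    # -- main loop -------------------------------------------------------
    def run(self) -> None:
        t = 0.0
        ev_i = 0
        rng = self.rng
        guard = 0
        while self.lineages:
            guard += 1
            if guard > 2_000_000:
                raise SimulationError("event-loop guard tripped")
            next_ev = (
                self.event_queue[ev_i].time
                if ev_i < len(self.event_queue)
                else math.inf
            )
            # deme occupancy
            demes: dict[tuple[int, int], list[int]] = {}
            for k, l in enumerate(self.lineages):
                demes.setdefault((l.pop, l.cls), []).append(k)

            best_t = math.inf
            best_action: tuple | None = None

            for (pop, cls), members in demes.items():
                f = self.cls_freq[cls] if self.classes_active else 1.0
                w = self._coal_wait(pop, cls, len(members), t, f)
                if t + w < best_t:
                    best_t = t + w
                    best_action = ("coal", pop, cls)

            mig_rates = [
                float(self.migration[l.pop].sum()) for l in self.lineages
            ]
            R_mig = sum(mig_rates)
            if R_mig > 0:
                w = rng.exponential() / R_mig
                if t + w < best_t:
                    best_t = t + w
                    best_action = ("mig",)

            if self.classes_active and self.cfg.balanced_switch_rate > 0:
                sw_rates = [
                    self.cfg.balanced_switch_rate * self.cls_freq[1 - l.cls]
                    for l in self.lineages
                ]
                R_sw = sum(sw_rates)
                if R_sw > 0:
                    w = rng.exponential() / R_sw
                    if t + w < best_t:
                        best_t = t + w
                        best_action = ("switch", sw_rates, R_sw)

            if self.r_locus > 0:
                spans = [l.span[1] - l.span[0] for l in self.lineages]
                R_rec = self.r_locus * sum(spans)
                if R_rec > 0:
                    w = rng.exponential() / R_rec
                    if t + w < best_t:
                        best_t = t + w
                        best_action = ("rec", spans)

            if best_t >= next_ev:
                if math.isinf(next_ev):
                    raise SimulationError(
                        "lineages cannot coalesce: isolated populations with "
                        "no merging event"
                    )
                t = next_ev
                self._apply_event(self.event_queue[ev_i], t)
                ev_i += 1
                continue

            t = best_t
            kind = best_action[0]
            if kind == "coal":
                _, pop, cls = best_action
                members = [
                    k for k, l in enumerate(self.lineages)
                    if l.pop == pop and l.cls == cls
                ]
                i, j = rng.choice(len(members), size=2, replace=False)
                self._coalesce_pair(members[i], members[j], t)
            elif kind == "mig":
                probs = np.asarray(mig_rates) / R_mig
                k = int(rng.choice(len(self.lineages), p=probs))
                row = self.migration[self.lineages[k].pop]
                dest = int(rng.choice(len(row), p=row / row.sum()))
                self.lineages[k].pop = dest
            elif kind == "switch":
                _, sw_rates, R_sw = best_action
                probs = np.asarray(sw_rates) / R_sw
                k = int(rng.choice(len(self.lineages), p=probs))
                self.lineages[k].cls = 1 - self.lineages[k].cls
            elif kind == "rec":
                _, spans = best_action
                probs = np.asarray(spans) / sum(spans)
                k = int(rng.choice(len(self.lineages), p=probs))
                lo, hi = self.lineages[k].span
                self._recombine(k, rng.uniform(lo, hi))

    # -- mutation dropping ------------------------------------------------
    def drop_mutations(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Poisson mutations on the marginal trees.

        Returns (position fractions, haplotype matrix, tmrca in gens).
        """
        rng = self.rng
        n = self.n_total
        bounds = sorted(
            {0.0, 1.0}
            | {e[0] for e in self.edges}
            | {e[1] for e in self.edges}
        )
        tmrca = max(r[3] for r in self.roots)
        positions: list[float] = []
        cols: list[np.ndarray] = []
        for x0, x1 in zip(bounds[:-1], bounds[1:]):
            tree_edges = [
                e for e in self.edges if e[0] <= x0 and e[1] >= x1
            ]
            if not tree_edges:
                continue
            blens = np.asarray(
                [self.node_time[p] - self.node_time[c] for _, _, p, c in tree_edges]
            )
            total = float(blens.sum())
            lam = self.mu_locus * (x1 - x0) * total
            m = rng.poisson(lam)
            if m == 0:
                continue
            children: dict[int, list[int]] = {}
            for _, _, p, c in tree_edges:
                children.setdefault(p, []).append(c)
            leafsets: dict[int, np.ndarray] = {}

            def leaves(nd: int) -> np.ndarray:
                got = leafsets.get(nd)
                if got is not None:
                    return got
                if nd < n:
                    v = np.zeros(n, dtype=np.int8)
                    v[nd] = 1
                else:
                    v = np.zeros(n, dtype=np.int8)
                    for c in children.get(nd, []):
                        v |= leaves(c)
                leafsets[nd] = v
                return v

            picks = rng.choice(len(tree_edges), size=m, p=blens / total)
            for e_idx in picks:
                child = tree_edges[e_idx][3]
                positions.append(rng.uniform(x0, x1))
                cols.append(leaves(child).copy())
        if not positions:
            return np.zeros(0), np.zeros((n, 0), dtype=np.int8), tmrca
        order = np.argsort(positions)
        pos = np.asarray(positions)[order]
        H = np.stack([cols[i] for i in order], axis=1)
        return pos, H, tmrca


# ----------------------------------------------------------------------
# Public API
# ----------------------------------------------------------------------

def _pop_names(config: SimConfig, model: DemographicModel) -> list[str]:
    if config.pop_names is not None:
        return list(config.pop_names)
    return [p.name for p in model.populations]


def _one_replicate(
    config: SimConfig, model: DemographicModel, rep: int
) -> SimReplicate:
    rng = np.random.default_rng([config.seed, rep])
    eng = _Engine(config, model, rng)
    eng.run()
    frac, H, tmrca = eng.drop_mutations()
    focal_index = None
    if config.mode == "balanced":
        col = np.asarray(eng.focal_classes, dtype=np.int8)
        insert = int(np.searchsorted(frac, config.focal_frac))
        frac = np.insert(frac, insert, config.focal_frac)
        H = np.insert(H, insert, col, axis=1)
        focal_index = insert
    pos = _fractions_to_positions(frac, config.L)
    names = _pop_names(config, model)
    labels: list[str] = []
    for name, k in zip(names, config.n):
        labels.extend([name] * k)
    aln = HaplotypeAlignment(
        chrom="sim",
        start=1,
        end=config.L,
        positions=pos,
        H=H,
        sample_ids=[f"hap{i}" for i in range(sum(config.n))],
        pop_labels=labels,
        polarized=np.ones(H.shape[1], dtype=bool),
        outgroup=np.zeros(H.shape[1], dtype=np.int8),
    )
    return SimReplicate(alignment=aln, tmrca_gens=tmrca, focal_index=focal_index)


def simulate(config: SimConfig, model: DemographicModel) -> list[SimReplicate]:
    """Run ``config.iterations`` coalescent replicates.

    Deterministic given ``config.seed``; each replicate uses an
    independent derived substream, so replicate ``k`` is reproducible in
    isolation.
    """
    return [_one_replicate(config, model, rep) for rep in range(config.iterations)]


def simulate_balanced(config: SimConfig, model: DemographicModel) -> list[SimReplicate]:
    """Balanced-polymorphism simulation (requires ``mode='balanced'``)."""
    if config.mode != "balanced":
        config = replace(config, mode="balanced")
    if config.balanced_age is None or config.balanced_age <= 0:
        raise SimulationError("balanced mode requires balanced_age > 0")
    last_split = max(
        (e.time for e in model.events if e.kind == "split"), default=0.0
    )
    if config.balanced_age <= last_split:
        raise SimulationError(
            "balanced allele age must predate the oldest population split "
            f"({last_split:g} generations) so that all populations share "
            "the polymorphism"
        )
    return simulate(config, model)


def null_distribution(
    stat: str | Callable[[HaplotypeAlignment], float],
    config: SimConfig,
    model: DemographicModel,
    iterations: int | None = None,
) -> ReferencePanel:
    """Simulated null distribution of a per-region statistic.

    Replicates on which the statistic is undefined (for example Tajima's D
    when a replicate has no segregating sites) are redrawn from fresh
    substreams; the redraw count is logged.
    """
    from balsel import sumstats

    if config.theta == 0:
        raise SimulationError("theta=0 never yields segregating sites")
    iterations = iterations if iterations is not None else config.iterations
    if isinstance(stat, str):
        fn = sumstats.STATISTIC_REGISTRY.get(stat)
        if fn is None:
            raise SimulationError(f"unknown statistic {stat!r}")
        name = stat
    else:
        fn, name = stat, getattr(stat, "__name__", "statistic")

    values: list[float] = []
    rep = 0
    redrawn = 0
    while len(values) < iterations:
        r = _one_replicate(config, model, rep)
        rep += 1
        try:
            v = fn(r.alignment)
        except sumstats.UndefinedStatistic:
            redrawn += 1
            if redrawn > 100 * iterations:
                raise SimulationError(
                    f"statistic {name!r} undefined on nearly every replicate"
                )
            continue
        values.append(float(v))
    if redrawn:
        logger.info("redrew %d replicates with undefined %s", redrawn, name)
    return ReferencePanel(
        statistic=name,
        values=np.asarray(values),
        window_length=config.L,
        sample_size=sum(config.n),
        provenance="simulated",
    )
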