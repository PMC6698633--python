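"""Native multi-deme, multi-locus structured-coalescent simulator.

Time runs backwards in generations.  The model is the haploid coalescent:
within a deme holding ``k`` lineages and ``N`` gene copies the pair
coalescence rate is ``k(k-1)/(2N)`` per generation, so for a locus of
length ``L`` with per-site mutation rate ``mu`` the scaled diversity is
``theta = 2*N*mu*L`` (E[pairwise differences] for two samples from one
deme of constant size).

Demes may grow exponentially forward in time (size shrinks backwards),
exchange migrants at constant per-lineage rates, and be reorganized by
time-ordered demographic events: lineage merges (population splits viewed
backwards), instantaneous size changes, growth-rate changes, and migration
matrix changes.  Ghost (unsampled) demes are ordinary demes with zero
samples.  Within an epoch, waiting times are exact: exponential for
migration, and closed-form inverse-hazard sampling for coalescence under
exponential growth.

Mutations follow the infinite-sites model: Poisson(mu*L*total branch
length) mutations are placed on branches proportionally to length, each at
a distinct site.  Rendered sequences use an all-'A' reference with the
derived state drawn uniformly from the three alternatives; statistics never
depend on the rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .mlst_io import LocusAlignment, MLSTDataset

__all__ = [
    "Deme",
    "Event",
    "Locus",
    "DemographicScenario",
    "SimulatedDataset",
    "simulate_dataset",
    "validate_scenario",
    "scenario_from_yaml",
]


# ---------------------------------------------------------------------------
# scenario declaration
# ---------------------------------------------------------------------------

@dataclass
class Deme:
    name: str
    size: float              # present-day gene copies
    growth: float = 0.0      # forward exponential rate per generation


@dataclass
class Event:
    """Demographic event at a backward time (generations before present).

    kinds:
      - ``merge``: all lineages of ``deme`` move into ``dest``; ``deme``
        becomes inactive (a forward-time population split).
      - ``size``: ``deme`` size set to ``value`` (for older times), growth
        reset to 0 unless ``growth`` given.
      - ``growth``: ``deme`` growth rate set to ``value``.
      - ``migration``: whole migration matrix replaced by ``matrix``.
    """

    time: float
    kind: str
    deme: str | None = None
    dest: str | None = None
    value: float | None = None
    growth: float | None = None
    matrix: np.ndarray | None = None


@dataclass
class Locus:
    name: str
    length: int
    mu: float  # per-site per-generation


@dataclass
class DemographicScenario:
    demes: list[Deme]
    samples: dict[str, int]
    loci: list[Locus]
    events: list[Event] = field(default_factory=list)
    migration: np.ndarray | None = None  # [i, j] = per-lineage rate i -> j
    label: str = "scenario"

    def deme_index(self) -> dict[str, int]:
        return {d.name: i for i, d in enumerate(self.demes)}

    def bind(self, **params) -> "DemographicScenario":
        """Convenience for templates: returns self (subclasses override)."""
        return self


def validate_scenario(sc: DemographicScenario) -> list[str]:
    """Diagnostics: invariant violations and unreachable-coalescence traps."""
    diags: list[str] = []
    names = [d.name for d in sc.demes]
    if len(set(names)) != len(names):
        diags.append("duplicate deme names")
    for d in sc.demes:
        if d.size <= 0:
            diags.append(f"deme {d.name}: non-positive size")
    for nm in sc.samples:
        if nm not in names:
            diags.append(f"samples refer to unknown deme {nm!r}")
    if sum(sc.samples.values()) < 2:
        diags.append("total sample size must be >= 2")
    times = [e.time for e in sc.events]
    if any(t <= 0 for t in times):
        diags.append("event times must be strictly positive")
    if times != sorted(times):
        diags.append("events not sorted by time")
    # follow merges: all demes must collapse into one connected unit unless
    # migration connects them
    alive = set(names)
    merged_into: dict[str, str] = {}
    for e in sc.events:
        if e.kind == "merge":
            if e.deme not in alive:
                diags.append(f"merge of inactive/unknown deme {e.deme!r}")
            else:
                alive.discard(e.deme)
                merged_into[e.deme] = e.dest
            if e.dest not in alive and e.dest not in names:
                diags.append(f"merge destination unknown {e.dest!r}")
    if len(alive) > 1:
        mig = sc.migration
        has_mig = mig is not None and np.any(np.asarray(mig) > 0)
        has_mig = has_mig or any(e.kind == "migration" and e.matrix is not None
                                 and np.any(e.matrix > 0) for e in sc.events)
        if not has_mig:
            diags.append(
                f"demes {sorted(alive)} never merge and no migration: "
                "lineages can never fully coalesce"
            )
    return diags


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class _Genealogy:
    """Coalescent tree: node 0..n-1 are leaves; internal nodes appended.
    parent[i] = -1 for the root; branch[i] = length in generations."""

    parent: np.ndarray
    branch: np.ndarray
    n_leaves: int

    def leaf_sets(self) -> list[np.ndarray]:
        """Boolean leaf membership per node."""
        n_nodes = len(self.parent)
        sets = np.zeros((n_nodes, self.n_leaves), dtype=bool)
        sets[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        for node in range(n_nodes):  # children always precede parents
            p = self.parent[node]
            if p >= 0:
                sets[p] |= sets[node]
        return sets


try:
    from numba import njit

    @njit(cache=True)
    def _kingman_piecewise_kernel(n, boundaries, sizes, seed):  # pragma: no cover
        """Single-deme coalescent with piecewise-constant size.

        boundaries[i] is the end time of epoch i (last = inf); sizes[i] the
        gene-copy count within it.  Returns (parent, birth) arrays over
        2n-1 nodes (children precede parents).
        """
        np.random.seed(seed)
        total = 2 * n - 1
        parent = np.full(total, -1, dtype=np.int64)
        birth = np.zeros(total)
        lineages = np.arange(n)
        k = n
        t = 0.0
        epoch = 0
        nxt = n
        while k > 1:
            rate = k * (k - 1) / (2.0 * sizes[epoch])
            dt = np.random.exponential(1.0 / rate)
            if t + dt >= boundaries[epoch]:
                t = boundaries[epoch]
                epoch += 1
                continue
            t += dt
            i = np.random.randint(k)
            j = np.random.randint(k - 1)
            if j >= i:
                j += 1
            a, b = lineages[i], lineages[j]
            parent[a] = nxt
            parent[b] = nxt
            birth[nxt] = t
            lo, hi = (i, j) if i < j else (j, i)
            lineages[hi] = lineages[k - 1]
            lineages[lo] = nxt
            k -= 1
            nxt += 1
        return parent, birth

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _single_deme_schedule(sc: DemographicScenario):
    """(boundaries, sizes) when the scenario is a single-deme, zero-growth,
    zero-migration, size-change-only model; None otherwise."""
    sampled = [nm for nm, c in sc.samples.items() if c > 0]
    if len(sc.demes) != 1 or len(sampled) != 1:
        return None
    d = sc.demes[0]
    if d.growth != 0.0:
        return None
    if sc.migration is not None and np.any(np.asarray(sc.migration) != 0):
        return None
    boundaries, sizes = [], [d.size]
    for e in sc.events:
        if e.kind != "size" or e.deme != d.name or e.growth:
            return None
        boundaries.append(e.time)
        sizes.append(float(e.value))
    boundaries.append(np.inf)
    return np.asarray(boundaries), np.asarray(sizes)


def _simulate_genealogy(sc: DemographicScenario, rng: np.random.Generator) -> _Genealogy:
    if _HAVE_NUMBA:
        sched = _single_deme_schedule(sc)
        if sched is not None:
            n = sum(sc.samples.values())
            seed = int(rng.integers(2 ** 31))
            parent, birth = _kingman_piecewise_kernel(n, sched[0], sched[1], seed)
            branch = np.zeros(len(parent))
            has_parent = parent >= 0
            branch[has_parent] = birth[parent[has_parent]] - birth[np.where(has_parent)[0]]
            return _Genealogy(parent, branch, n)
    return _simulate_genealogy_generic(sc, rng)


def _simulate_genealogy_generic(sc: DemographicScenario, rng: np.random.Generator) -> _Genealogy:
    idx = sc.deme_index()
    nd = len(sc.demes)
    sizes = np.array([d.size for d in sc.demes], dtype=float)
    growth = np.array([d.growth for d in sc.demes], dtype=float)
    epoch_start = np.zeros(nd)  # reference time for each deme's size
    mig = (np.asarray(sc.migration, dtype=float).copy()
           if sc.migration is not None else np.zeros((nd, nd)))
    np.fill_diagonal(mig, 0.0)
    active = np.ones(nd, dtype=bool)

    # lineages per deme: lists of node ids
    n_total = sum(sc.samples.values())
    lineages: list[list[int]] = [[] for _ in range(nd)]
    node = 0
    for nm, cnt in sc.samples.items():
        for _ in range(cnt):
            lineages[idx[nm]].append(node)
            node += 1
    parent = list(np.full(n_total, -1, dtype=np.int64))
    birth = list(np.zeros(n_total))  # time the lineage (node) starts, backwards

    t = 0.0
    events = list(sc.events)
    ev_i = 0
    n_live = n_total
    mig_rowsum = mig.sum(axis=1)

    def deme_size_at(d: int, time: float) -> float:
        return sizes[d] * math.exp(-growth[d] * (time - epoch_start[d]))

    exp = rng.exponential
    log = math.log
    while n_live > 1:
        t_next_event = events[ev_i].time if ev_i < len(events) else math.inf
        # candidate coalescence waiting time per deme (inverse hazard under
        # exponential growth), candidate migration time (exponential)
        best_dt = math.inf
        best_action = None  # ("coal", d) or ("mig", d)
        for d in range(nd):
            k = len(lineages[d])
            if k == 0 or not active[d]:
                continue
            if k >= 2:
                g = growth[d]
                e = exp()
                if g == 0.0:
                    dt = e * 2.0 * sizes[d] / (k * (k - 1))
                else:
                    base = k * (k - 1) / (2.0 * deme_size_at(d, t))
                    # hazard to dt: base*(exp(g*dt)-1)/g  (size shrinks back)
                    arg = 1.0 + g * e / base
                    dt = log(arg) / g if arg > 0 else math.inf
                if dt < best_dt:
                    best_dt, best_action = dt, ("coal", d)
            if mig_rowsum[d] > 0:
                dt = exp(1.0 / (k * mig_rowsum[d]))
                if dt < best_dt:
                    best_dt, best_action = dt, ("mig", d)
        if best_dt == math.inf and t_next_event == math.inf:
            raise RuntimeError(
                f"scenario {sc.label!r}: lineages can never coalesce "
                "(disconnected demes?)"
            )
        if t + best_dt >= t_next_event:
            # advance to the event and apply it
            ev = events[ev_i]
            ev_i += 1
            # update growth reference points
            for d in range(nd):
                sizes[d] = deme_size_at(d, ev.time)
                epoch_start[d] = ev.time
            t = ev.time
            if ev.kind == "merge":
                src, dst = idx[ev.deme], idx[ev.dest]
                lineages[dst].extend(lineages[src])
                lineages[src] = []
                active[src] = False
                mig[src, :] = 0.0
                mig[:, src] = 0.0
                mig_rowsum = mig.sum(axis=1)
            elif ev.kind == "size":
                d = idx[ev.deme]
                sizes[d] = float(ev.value)
                growth[d] = float(ev.growth or 0.0)
            elif ev.kind == "growth":
                d = idx[ev.deme]
                growth[d] = float(ev.value)
            elif ev.kind == "migration":
                mig = np.asarray(ev.matrix, dtype=float).copy()
                np.fill_diagonal(mig, 0.0)
                mig_rowsum = mig.sum(axis=1)
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
            continue
        t += best_dt
        kind, d = best_action
        if kind == "coal":
            k = len(lineages[d])
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            a, b = lineages[d][i], lineages[d][j]
            new = len(parent)
            parent.append(-1)
            birth.append(t)
            parent[a] = new
            parent[b] = new
            lineages[d] = [x for x in lineages[d] if x not in (a, b)] + [new]
            n_live -= 1
        else:
            k = len(lineages[d])
            li = int(rng.integers(k))
            dests = mig[d]
            probs = dests / dests.sum()
            dd = int(rng.choice(nd, p=probs))
            moved = lineages[d].pop(li)
            lineages[dd].append(moved)

    parent_arr = np.asarray(parent, dtype=np.int64)
    birth_arr = np.asarray(birth)
    branch = np.zeros(len(parent))
    for i in range(len(parent)):
        p = parent_arr[i]
        if p >= 0:
            branch[i] = birth_arr[p] - birth_arr[i]
    return _Genealogy(parent_arr, branch, n_total)


@dataclass
class SimulatedDataset:
    """Per-locus 0/1 haplotype matrices under infinite sites.

    ``matrices[l]`` has shape (n_samples, S_l); ``positions[l]`` gives the
    0-based site of each column within the locus.  Row order follows the
    scenario's sample declaration; ``deme_of`` labels each row.
    """

    matrices: list[np.ndarray]
    positions: list[np.ndarray]
    loci: list[Locus]
    deme_of: list[str]
    scenario_label: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.matrices[0].shape[0]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.matrices, axis=1) if self.matrices else np.empty((self.n, 0))

    def render_sequences(self, rng: np.random.Generator | None = None,
                         strain_ids: list[str] | None = None) -> MLSTDataset:
        """Render as ACGT alignments: 'A' reference, random derived state."""
        rng = rng if rng is not None else np.random.default_rng(0)
        ids = strain_ids or [f"S{i + 1:04d}" for i in range(self.n)]
        alns = []
        for mat, pos, loc in zip(self.matrices, self.positions, self.loci):
            ref = np.full(loc.length, b"A", dtype="S1")
            rows = np.tile(ref, (self.n, 1))
            alts = rng.choice(np.array([b"C", b"G", b"T"], dtype="S1"),
                              size=len(pos))
            for c, (p, alt) in enumerate(zip(pos, alts)):
                rows[mat[:, c] == 1, p] = alt
            seqs = {sid: rows[i].tobytes().decode() for i, sid in enumerate(ids)}
            alns.append(LocusAlignment(loc.name, seqs))
        return MLSTDataset(alns)


def simulate_dataset(sc: DemographicScenario, seed: int | None = None) -> SimulatedDataset:
    """Simulate independent genealogies per locus and drop infinite-sites
    mutations; deterministic given ``seed``."""
    diags = validate_scenario(sc)
    fatal = [d for d in diags if "never" in d or "unknown" in d or "non-positive" in d
             or "must" in d or "not sorted" in d]
    if fatal:
        raise ValueError(f"invalid scenario {sc.label!r}: {fatal}")
    rng = np.random.default_rng(seed)
    deme_of = []
    for nm, cnt in sc.samples.items():
        deme_of.extend([nm] * cnt)
    matrices, positions = [], []
    for loc in sc.loci:
        gen = _simulate_genealogy(sc, rng)
        total_len = gen.branch.sum()
        n_mut = rng.poisson(loc.mu * loc.length * total_len)
        n_mut = min(n_mut, loc.length)  # finite rendering capacity
        if n_mut == 0:
            matrices.append(np.zeros((gen.n_leaves, 0), dtype=np.int8))
            positions.append(np.empty(0, dtype=np.int64))
            continue
        probs = gen.branch / total_len
        branch_pick = rng.choice(len(gen.branch), size=n_mut, p=probs)
        pos = np.sort(rng.choice(loc.length, size=n_mut, replace=False))
        sets = gen.leaf_sets()
        mat = sets[branch_pick].T.astype(np.int8)
        matrices.append(mat)
        positions.append(pos)
    return SimulatedDataset(matrices, positions, list(sc.loci), deme_of,
                            sc.label, seed=seed)


def simulate_infinite_island_dataset(n: int, theta: float, M: float,
                                     tau: float, loci: list[Locus],
                                     seed: int | None = None) -> SimulatedDataset:
    """Exact infinite-island spatial-expansion simulation.

    All ``n`` samples come from one deme of ``theta`` gene copies (time in
    units where mutational time equals generations, i.e. total per-genome
    mutation rate 1/2).  Before ``tau`` (backwards) lineages in the home
    deme coalesce at the haploid rate and emigrate at per-lineage rate
    ``M/(2*theta)``; an emigrant lands in a fresh unoccupied deme and, with
    infinitely many demes, never meets another lineage again.  At ``tau``
    everyone enters the ancestral deme (also ``theta``) and coalesces as a
    standard Kingman process.  This is the exact model behind the spatial
    closed form, with at most O(n) events (no migration random walk).
    """
    if min(theta, tau) <= 0 or M < 0:
        raise ValueError("theta and tau must be > 0, M >= 0")
    rng = np.random.default_rng(seed)
    m = M / (2.0 * theta)
    matrices, positions = [], []
    for loc in loci:
        parent = list(np.full(n, -1, dtype=np.int64))
        birth = [0.0] * n
        home = list(range(n))
        away: list[int] = []
        t = 0.0

        def coalesce(pool, time):
            i = int(rng.integers(len(pool)))
            j = int(rng.integers(len(pool) - 1))
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            new = len(parent)
            parent.append(-1)
            birth.append(time)
            parent[a] = new
            parent[b] = new
            lo, hi = (i, j) if i < j else (j, i)
            pool[hi] = pool[-1]
            pool.pop()
            pool[lo] = new

        while t < tau and len(home) >= 1 and (len(home) + len(away)) > 1:
            k = len(home)
            coal_rate = k * (k - 1) / (2.0 * theta)
            mig_rate = k * m
            total = coal_rate + mig_rate
            if total == 0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= tau:
                break
            t += dt
            if rng.random() < coal_rate / total:
                coalesce(home, t)
            else:
                i = int(rng.integers(k))
                away.append(home[i])
                home[i] = home[-1]
                home.pop()
        # ancestral panmictic phase
        pool = home + away
        t = max(t, tau)
        while len(pool) > 1:
            k = len(pool)
            t += rng.exponential(2.0 * theta / (k * (k - 1)))
            coalesce(pool, t)

        parent_arr = np.asarray(parent, dtype=np.int64)
        birth_arr = np.asarray(birth)
        branch = np.zeros(len(parent))
        has_p = parent_arr >= 0
        branch[has_p] = birth_arr[parent_arr[has_p]] - birth_arr[np.where(has_p)[0]]
        gen = _Genealogy(parent_arr, branch, n)
        total_len = branch.sum()
        n_mut = min(int(rng.poisson(loc.mu * loc.length * total_len)), loc.length)
        if n_mut == 0:
            matrices.append(np.zeros((n, 0), dtype=np.int8))
            positions.append(np.empty(0, dtype=np.int64))
            continue
        probs = branch / total_len
        picks = rng.choice(len(branch), size=n_mut, p=probs)
        pos = np.sort(rng.choice(loc.length, size=n_mut, replace=False))
        sets = gen.leaf_sets()
        matrices.append(sets[picks].T.astype(np.int8))
        positions.append(pos)
    return SimulatedDataset(matrices, positions, list(loci), ["D0"] * n,
                            "infinite_island", seed=seed)


# ---------------------------------------------------------------------------
# YAML scenario files
# ---------------------------------------------------------------------------

def scenario_from_yaml(path_or_stream) -> DemographicScenario:
    """Load a scenario from YAML.

    Layout::

        label: model_10
        demes: [{name: CI, size: 1e5, growth: 0.0}, ...]
        samples: {CI: 82, CII: 97, CIII: 87}
        loci: [{name: nodA, length: 535, mu: 1e-8}, ...]
        migration: [[0, 0], [0, 0]]        # optional
        events:
          - {time: 204300, kind: merge, deme: CI, dest: CIII}
    """
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    demes = [Deme(d["name"], float(d["size"]), float(d.get("growth", 0.0)))
             for d in doc["demes"]]
    loci = [Locus(l["name"], int(l["length"]), float(l["mu"])) for l in doc["loci"]]
    events = []
    for e in doc.get("events", []):
        events.append(Event(
            time=float(e["time"]), kind=e["kind"], deme=e.get("deme"),
            dest=e.get("dest"),
            value=float(e["value"]) if "value" in e else None,
            growth=float(e["growth"]) if "growth" in e else None,
            matrix=np.asarray(e["matrix"], dtype=float) if "matrix" in e else None,
        ))
    events.sort(key=lambda e: e.time)
    mig = np.asarray(doc["migration"], dtype=float) if "migration" in doc else None
    return DemographicScenario(
        demes=demes, samples={k: int(v) for k, v in doc["samples"].items()},
        loci=loci, events=events, migration=mig,
        label=doc.get("label", "scenario"),
    )
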