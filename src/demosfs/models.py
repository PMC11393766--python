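"""Demographic model types: populations, events, migration, free parameters.

A :class:`DemographicModel` describes a multi-deme divergence history the way
coalescent samplers see it: time runs *backward* from the present (t = 0) in
generations, a divergence event moves all lineages of its ``source`` deme into
its ``sink`` deme, and a size-change event sets the effective size a deme has
for times older than the event.  Years appear only at I/O boundaries, through
:class:`TimeScale`.

Migration is configured forward in time — ``m[i -> j]`` is the fraction of deme
``j`` that is replaced by migrants from deme ``i`` each generation — because
that is how gene-flow arrows are drawn on demographic-model figures.  Backward
in time this same number is the probability that a lineage currently in ``j``
had its parent in ``i``, which is what the simulator uses (see
:meth:`MigrationEpoch.backward_matrix`).  Migration is legal only between demes
of the same island group and only during the recent epoch ``[0, t_end)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ModelError",
    "TimeScale",
    "Population",
    "DemographicEvent",
    "MigrationEpoch",
    "FreeParameter",
    "DemographicModel",
    "generations_to_years",
    "years_to_generations",
    "build_model",
    "load_model",
    "model_to_spec",
    "save_model",
    "Topology",
    "enumerate_topologies",
    "enumerate_candidates",
    "DEFAULT_TIME_BOUNDS",
    "DEFAULT_SIZE_BOUNDS",
    "DEFAULT_MIGRATION_BOUNDS",
]


class ModelError(ValueError):
    """A model specification violates a structural invariant."""


# Default log-uniform search bounds; they bracket every estimate the method is
# expected to produce for Late-Pleistocene island radiations.
DEFAULT_TIME_BOUNDS = (1e2, 1e5)  # generations
DEFAULT_SIZE_BOUNDS = (1e2, 1e6)  # diploid individuals
DEFAULT_MIGRATION_BOUNDS = (1e-8, 1e-1)  # forward fraction per generation


@dataclass(frozen=True)
class TimeScale:
    """Conversion between coalescent generations and calendar years."""

    generation_time_years: float = 5.0

    def __post_init__(self) -> None:
        if not self.generation_time_years > 0:
            raise ModelError("generation_time_years must be > 0")


def generations_to_years(t_gen, ts: TimeScale = TimeScale()) -> float:
    """Convert a time in generations before present to years before present."""
    t = np.asarray(t_gen, dtype=float)
    if np.any(t < 0):
        raise ModelError("time in generations must be non-negative")
    out = t * ts.generation_time_years
    return float(out) if out.ndim == 0 else out


def years_to_generations(t_years, ts: TimeScale = TimeScale()) -> float:
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ModelError("time in years must be non-negative")
    out = t / ts.generation_time_years
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Population:
    """A sampled deme: an ecotype/species group on one island group."""

    name: str
    island_group: str
    n_diploid: int
    N_current: float

    def __post_init__(self) -> None:
        if self.n_diploid < 1:
            raise ModelError(f"population {self.name}: n_diploid must be >= 1")
        if not self.N_current > 0:
            raise ModelError(f"population {self.name}: N_current must be > 0")
        if not self.island_group:
            raise ModelError(f"population {self.name}: island_group is required")


@dataclass(frozen=True)
class DemographicEvent:
    """A divergence (source merges into sink, backward in time) or size change.

    ``label`` lets several events share a free parameter (e.g. one reduction
    time applied to three demes) and lets parameter bindings refer to events
    without relying on list positions.
    """

    time: float
    kind: str  # "divergence" | "size_change"
    source: str
    sink: str | None = None
    new_size: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ModelError("event time must be >= 0")
        if self.kind == "divergence":
            if self.sink is None or self.sink == self.source:
                raise ModelError(
                    f"divergence at t={self.time}: needs two distinct demes"
                )
        elif self.kind == "size_change":
            if self.new_size is None or not self.new_size > 0:
                raise ModelError(
                    f"size_change at t={self.time}: new_size must be > 0"
                )
        else:
            raise ModelError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class MigrationEpoch:
    """Recent gene flow, forward-parameterised, active for 0 <= t < t_end.

    ``rates`` maps ordered pairs ``(i, j)`` to the forward per-generation
    fraction of deme ``j`` founded by migrants from deme ``i``.
    """

    t_end: float
    rates: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.t_end < 0:
            raise ModelError("migration t_end must be >= 0")
        for (i, j), m in self.rates.items():
            if i == j:
                raise ModelError(f"self-migration {i}->{j} is meaningless")
            if not (0.0 <= m <= 1.0):
                raise ModelError(f"migration fraction {i}->{j} = {m} outside [0, 1]")

    def backward_matrix(self, names: Sequence[str]) -> np.ndarray:
        """D x D backward lineage-movement probabilities.

        Entry ``[j, i]`` is the per-generation probability that a lineage
        currently in deme ``j`` traces back to deme ``i`` — numerically equal
        to the forward fraction ``m[i -> j]`` of ``j`` made of ``i`` migrants.
        """
        idx = {n: k for k, n in enumerate(names)}
        out = np.zeros((len(names), len(names)))
        for (i, j), m in self.rates.items():
            out[idx[j], idx[i]] = m
        return out


@dataclass(frozen=True)
class FreeParameter:
    """A named scalar bound to one or more model slots.

    Slot forms (dicts): ``{"kind": "event_time", "label": L}``,
    ``{"kind": "event_size", "label": L}``, ``{"kind": "pop_size", "pop": P}``,
    ``{"kind": "migration", "from": A, "to": B}`` (symmetric pairs list both
    directions as two slots).
    """

    name: str
    bounds: tuple[float, float]
    log_scale: bool = True
    slots: tuple[Mapping[str, str], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ModelError(f"parameter {self.name}: bad bounds {self.bounds}")
        if not self.slots:
            raise ModelError(f"parameter {self.name}: bound to no model slot")


@dataclass(frozen=True)
class DemographicModel:
    populations: tuple[Population, ...]
    events: tuple[DemographicEvent, ...]
    migration: MigrationEpoch | None = None
    mu: float = 1.74e-8
    free_params: tuple[FreeParameter, ...] = ()
    name: str = "model"
    # explicit event-time nesting: pairs of event labels (younger, older);
    # needed when the merge structure alone does not force an order (e.g.
    # two clades joining the same sink deme in a candidate topology)
    time_order: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.populations:
            raise ModelError("model needs at least one population")
        if not self.mu > 0:
            raise ModelError("mu must be > 0")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ModelError("duplicate population names")
        object.__setattr__(
            self,
            "events",
            tuple(sorted(self.events, key=lambda e: e.time)),
        )
        self._check_topology()
        self._check_migration()
        self._check_bindings()
        self._check_time_order()

    # -- validation -------------------------------------------------------

    def _check_topology(self) -> None:
        names = {p.name for p in self.populations}
        extant = set(names)
        for ev in self.events:  # sorted young -> old
            if ev.source not in names or (ev.sink is not None and ev.sink not in names):
                raise ModelError(f"event references unknown deme: {ev}")
            if ev.kind == "divergence":
                if ev.source not in extant:
                    raise ModelError(
                        f"divergence at t={ev.time}: source {ev.source} already merged"
                    )
                if ev.sink not in extant:
                    raise ModelError(
                        f"divergence at t={ev.time}: sink {ev.sink} already merged"
                    )
                extant.discard(ev.source)
            else:
                if ev.source not in extant:
                    raise ModelError(
                        f"size_change at t={ev.time}: deme {ev.source} already merged"
                    )
        n_div = sum(1 for e in self.events if e.kind == "divergence")
        if n_div != len(self.populations) - 1:
            raise ModelError(
                f"{n_div} divergence events leave {len(extant)} ancestral lineages; "
                "exactly one must remain"
            )

    def _check_migration(self) -> None:
        if self.migration is None:
            return
        group = {p.name: p.island_group for p in self.populations}
        for (i, j) in self.migration.rates:
            if i not in group or j not in group:
                raise ModelError(f"migration references unknown deme {i} or {j}")
            if group[i] != group[j]:
                raise ModelError(
                    f"illegal cross-island-group migration {i} ({group[i]}) -> "
                    f"{j} ({group[j]})"
                )

    def _check_bindings(self) -> None:
        labels = {e.label for e in self.events if e.label}
        pops = {p.name for p in self.populations}
        for par in self.free_params:
            for slot in par.slots:
                kind = slot["kind"]
                if kind in ("event_time", "event_size"):
                    if slot["label"] not in labels:
                        raise ModelError(
                            f"parameter {par.name}: no event labelled {slot['label']!r}"
                        )
                elif kind == "pop_size":
                    if slot["pop"] not in pops:
                        raise ModelError(
                            f"parameter {par.name}: unknown population {slot['pop']!r}"
                        )
                elif kind == "migration":
                    if self.migration is None or (
                        (slot["from"], slot["to"]) not in self.migration.rates
                    ):
                        raise ModelError(
                            f"parameter {par.name}: no migration slot "
                            f"{slot['from']}->{slot['to']}"
                        )
                else:
                    raise ModelError(f"parameter {par.name}: unknown slot kind {kind!r}")

    def _check_time_order(self) -> None:
        if not self.time_order:
            return
        times = {e.label: e.time for e in self.events if e.label}
        for younger, older in self.time_order:
            if younger not in times or older not in times:
                raise ModelError(
                    f"time_order references unknown event label "
                    f"({younger!r}, {older!r})"
                )
            if times[younger] > times[older]:
                raise ModelError(
                    f"event {younger!r} (t={times[younger]}) must not be older "
                    f"than {older!r} (t={times[older]})"
                )

    # -- convenience ------------------------------------------------------

    @property
    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise ModelError(f"unknown population {name!r}")

    def param_values(self) -> dict[str, float]:
        """Current values of the free parameters, read off the model slots."""
        out: dict[str, float] = {}
        for par in self.free_params:
            slot = par.slots[0]
            if slot["kind"] == "event_time":
                out[par.name] = next(
                    e.time for e in self.events if e.label == slot["label"]
                )
            elif slot["kind"] == "event_size":
                out[par.name] = next(
                    e.new_size for e in self.events if e.label == slot["label"]
                )
            elif slot["kind"] == "pop_size":
                out[par.name] = self.population(slot["pop"]).N_current
            else:
                out[par.name] = self.migration.rates[(slot["from"], slot["to"])]
        return out

    def with_params(self, values: Mapping[str, float]) -> "DemographicModel":
        """Return a copy with named free parameters set to new values."""
        unknown = set(values) - {p.name for p in self.free_params}
        if unknown:
            raise ModelError(f"unknown free parameters: {sorted(unknown)}")
        events = list(self.events)
        pops = list(self.populations)
        mig_rates = dict(self.migration.rates) if self.migration else None
        for par in self.free_params:
            if par.name not in values:
                continue
            v = float(values[par.name])
            for slot in par.slots:
                kind = slot["kind"]
                if kind == "event_time":
                    events = [
                        replace(e, time=v) if e.label == slot["label"] else e
                        for e in events
                    ]
                elif kind == "event_size":
                    events = [
                        replace(e, new_size=v) if e.label == slot["label"] else e
                        for e in events
                    ]
                elif kind == "pop_size":
                    pops = [
                        replace(p, N_current=v) if p.name == slot["pop"] else p
                        for p in pops
                    ]
                else:
                    mig_rates[(slot["from"], slot["to"])] = v
        migration = (
            MigrationEpoch(self.migration.t_end, mig_rates) if mig_rates is not None else None
        )
        return replace(
            self,
            populations=tuple(pops),
            events=tuple(events),
            migration=migration,
        )

    def restrict(self, names: Iterable[str]) -> "DemographicModel":
        """Copy keeping only the named free parameters (others stay fixed at
        their current slot values)."""
        names = set(names)
        unknown = names - {p.name for p in self.free_params}
        if unknown:
            raise ModelError(f"unknown free parameters: {sorted(unknown)}")
        return replace(
            self,
            free_params=tuple(p for p in self.free_params if p.name in names),
        )

    def is_feasible(self, values: Mapping[str, float]) -> bool:
        """Whether setting the given parameter values yields a valid history."""
        try:
            self.with_params(values)
            return True
        except ModelError:
            return False

    def time_bracket(self, name: str) -> tuple[float, float]:
        """Feasible interval for a free event-time parameter, conditional on
        the current values of all other events (used by coordinate ascent)."""
        par = next(p for p in self.free_params if p.name == name)
        lo, hi = par.bounds
        labels = {s["label"] for s in par.slots if s["kind"] == "event_time"}
        if not labels:
            return lo, hi
        own = [e for e in self.events if e.label in labels]
        kill = {
            e.source: (e.time, e.label)
            for e in self.events
            if e.kind == "divergence"
        }
        for ev in own:
            # this event must fire while its participants are still extant
            parts = [ev.source] + ([ev.sink] if ev.sink else [])
            for d in parts:
                t_kill, kill_label = kill.get(d, (np.inf, None))
                if d == ev.source and ev.kind == "divergence":
                    continue  # its own kill time
                if kill_label is not None and kill_label in labels:
                    continue  # shared-label polytomy moves together
                hi = min(hi, t_kill)
            # other events that need this event's participants extant must
            # stay younger: they lower-bound this time only when this event
            # is the divergence that removes a deme
            if ev.kind == "divergence":
                for other in self.events:
                    if other.label in labels:
                        continue
                    parts_o = [other.source] + ([other.sink] if other.sink else [])
                    if ev.source in parts_o:
                        lo = max(lo, other.time)
        # explicit nesting constraints
        times = {e.label: e.time for e in self.events if e.label}
        for younger, older in self.time_order:
            if younger in labels and older not in labels:
                hi = min(hi, times[older])
            if older in labels and younger not in labels:
                lo = max(lo, times[younger])
        return lo, min(hi, par.bounds[1])


# ---------------------------------------------------------------------------
# structured-config construction


def _as_tuple_slots(slots: Iterable[Mapping[str, str]]) -> tuple:
    return tuple(dict(s) for s in slots)


def build_model(spec: Mapping) -> DemographicModel:
    """Materialise a :class:`DemographicModel` from a structured description.

    The description is the parsed form of the YAML model configs shipped with
    the package; see ``data/e1.yaml`` for the full dialect.
    """
    pops = tuple(
        Population(
            name=str(p["name"]),
            island_group=str(p["island_group"]),
            n_diploid=int(p.get("n_diploid", 1)),
            N_current=float(p["N_current"]),
        )
        for p in spec["populations"]
    )
    events = tuple(
        DemographicEvent(
            time=float(e["time"]),
            kind=str(e["kind"]),
            source=str(e["source"]),
            sink=str(e["sink"]) if e.get("sink") is not None else None,
            new_size=float(e["new_size"]) if e.get("new_size") is not None else None,
            label=str(e["label"]) if e.get("label") is not None else None,
        )
        for e in spec.get("events", ())
    )
    migration = None
    mig_spec = spec.get("migration")
    if mig_spec:
        rates: dict[tuple[str, str], float] = {}
        for r in mig_spec.get("rates", ()):
            a, b, m = str(r["from"]), str(r["to"]), float(r["m"])
            rates[(a, b)] = m
            if mig_spec.get("symmetric", False):
                rates[(b, a)] = m
        migration = MigrationEpoch(t_end=float(mig_spec["t_end"]), rates=rates)
    free = tuple(
        FreeParameter(
            name=str(f["name"]),
            bounds=tuple(float(b) for b in f.get("bounds", DEFAULT_TIME_BOUNDS)),
            log_scale=bool(f.get("log", True)),
            slots=_as_tuple_slots(f["slots"]),
        )
        for f in spec.get("free_params", ())
    )
    return DemographicModel(
        populations=pops,
        events=events,
        migration=migration,
        mu=float(spec.get("mu", 1.74e-8)),
        free_params=free,
        name=str(spec.get("name", "model")),
        time_order=tuple(
            (str(a), str(b)) for a, b in spec.get("time_order", ())
        ),
    )


def load_model(path) -> DemographicModel:
    """Load a model from a YAML config file (round-trips with the bundled
    ``e1.yaml`` / ``g2.yaml`` fixtures)."""
    with open(path) as fh:
        return build_model(yaml.safe_load(fh))


def model_to_spec(model: DemographicModel) -> dict:
    """Structured description that :func:`build_model` reconstructs exactly.

    Migration is emitted directionally (one entry per ordered pair), which is
    the most general form; symmetric configs re-load equivalently.
    """
    spec: dict = {
        "name": model.name,
        "mu": model.mu,
        "populations": [
            {
                "name": p.name,
                "island_group": p.island_group,
                "n_diploid": p.n_diploid,
                "N_current": p.N_current,
            }
            for p in model.populations
        ],
        "events": [
            {
                "time": e.time,
                "kind": e.kind,
                "source": e.source,
                **({"sink": e.sink} if e.sink is not None else {}),
                **({"new_size": e.new_size} if e.new_size is not None else {}),
                **({"label": e.label} if e.label is not None else {}),
            }
            for e in model.events
        ],
    }
    if model.migration is not None:
        spec["migration"] = {
            "t_end": model.migration.t_end,
            "rates": [
                {"from": i, "to": j, "m": m}
                for (i, j), m in sorted(model.migration.rates.items())
            ],
        }
    if model.free_params:
        spec["free_params"] = [
            {
                "name": p.name,
                "bounds": list(p.bounds),
                "log": p.log_scale,
                "slots": [dict(s) for s in p.slots],
            }
            for p in model.free_params
        ]
    if model.time_order:
        spec["time_order"] = [list(pair) for pair in model.time_order]
    return spec


def save_model(model: DemographicModel, path) -> None:
    """Write the YAML form of :func:`model_to_spec`."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_spec(model), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# candidate enumeration


@dataclass(frozen=True)
class Topology:
    """A rooted (possibly multifurcating) divergence ordering over taxa.

    Stored as a nested structure of frozensets; ``id`` is a canonical
    newick-like string, stable under taxon reordering.
    """

    tree: tuple  # nested: leaf = str, internal = tuple of children

    @property
    def id(self) -> str:
        return _canon(self.tree)

    def clades(self) -> set[frozenset]:
        out: set[frozenset] = set()

        def walk(node) -> frozenset:
            if isinstance(node, str):
                return frozenset([node])
            leaves = frozenset().union(*(walk(c) for c in node))
            out.add(leaves)
            return leaves

        walk(self.tree)
        return out

    def leaves(self) -> frozenset:
        def walk(node):
            if isinstance(node, str):
                return frozenset([node])
            return frozenset().union(*(walk(c) for c in node))

        return walk(self.tree)


def _canon(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(sorted(_canon(c) for c in node)) + ")"


def _set_partitions(items: list) -> Iterable[list[list]]:
    """All partitions of ``items`` into non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


def _rooted_trees(leaves: tuple) -> Iterable[tuple]:
    """All rooted multifurcating topologies over the given leaves."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    for part in _set_partitions(list(leaves)):
        if len(part) < 2:
            continue
        blocks = [tuple(sorted(b)) for b in part]
        subtrees = [list(_rooted_trees(b)) for b in blocks]
        for combo in itertools.product(*subtrees):
            yield tuple(combo)


def enumerate_topologies(
    taxa: Sequence[str],
    required_clades: Iterable[Iterable[str]] = (),
) -> list[Topology]:
    """Every rooted divergence ordering of ``taxa`` (polytomies = tied times),
    deduplicated under the canonical form, filtered by required clades."""
    taxa = tuple(sorted(taxa))
    req = [frozenset(c) for c in required_clades]
    for c in req:
        if not c <= set(taxa):
            raise ModelError(f"constraint clade {sorted(c)} references unknown taxa")
    seen: dict[str, Topology] = {}
    for tree in _rooted_trees(taxa):
        topo = Topology(tree)
        if topo.id in seen:
            continue
        clades = topo.clades()
        if all(c in clades or len(c) <= 1 for c in req):
            seen[topo.id] = topo
    return [seen[k] for k in sorted(seen)]


def topology_to_model(
    topo: Topology,
    populations: Sequence[Population],
    *,
    mu: float = 1.74e-8,
    migration: MigrationEpoch | None = None,
    time_bounds: tuple[float, float] = DEFAULT_TIME_BOUNDS,
    initial_spread: tuple[float, float] = (1e3, 3e4),
) -> DemographicModel:
    """Fill a bare topology into a fittable model.

    Each internal node becomes one free divergence-time parameter shared by
    its (possibly multi-way) merge; deme sizes come from ``populations``.
    Initial node times are spaced log-evenly, younger nodes nested inside
    older ones so the starting history is valid.
    """
    pops = {p.name: p for p in populations}
    missing = topo.leaves() - set(pops)
    if missing:
        raise ModelError(f"topology references unsampled taxa {sorted(missing)}")

    events: list[DemographicEvent] = []
    free: list[FreeParameter] = []
    # assign times by node height (leaves = 0); deeper nesting = younger
    heights: dict[int, int] = {}

    def height(node) -> int:
        if isinstance(node, str):
            return 0
        h = 1 + max(height(c) for c in node)
        heights[id(node)] = h
        return h

    max_h = height(topo.tree)
    lo, hi = initial_spread
    counter = itertools.count(1)

    time_order: list[tuple[str, str]] = []

    def walk(node) -> tuple[str, str | None]:
        """Returns (representative deme, event label) of the subtree."""
        if isinstance(node, str):
            return node, None
        results = [walk(c) for c in node]
        children = [r[0] for r in results]
        sink = min(children)
        h = heights[id(node)]
        t0 = lo * (hi / lo) ** ((h - 1) / max(max_h - 1, 1)) if max_h > 1 else lo
        label = f"T{next(counter)}"
        for c in children:
            if c != sink:
                events.append(
                    DemographicEvent(
                        time=t0, kind="divergence", source=c, sink=sink, label=label
                    )
                )
        # child internal nodes must stay younger than this node
        for _, child_label in results:
            if child_label is not None:
                time_order.append((child_label, label))
        free.append(
            FreeParameter(
                name=label,
                bounds=time_bounds,
                slots=({"kind": "event_time", "label": label},),
            )
        )
        return sink, label

    walk(topo.tree)
    used = sorted(topo.leaves())
    return DemographicModel(
        populations=tuple(pops[n] for n in used),
        events=tuple(events),
        migration=migration,
        mu=mu,
        free_params=tuple(free),
        name=topo.id,
        time_order=tuple(time_order),
    )


def enumerate_candidates(
    taxa: Sequence[str],
    populations: Sequence[Population],
    constraints: Iterable[Iterable[str]] = (),
    *,
    mu: float = 1.74e-8,
    migration: MigrationEpoch | None = None,
) -> list[DemographicModel]:
    """Candidate divergence models for a step of the stepwise model search:
    every rooted ordering of ``taxa`` consistent with clades won at previous
    steps, each carrying free time parameters and a stable identifier."""
    if not (2 <= len(taxa) <= 6):
        raise ModelError("candidate enumeration supports 2-6 taxa")
    topos = enumerate_topologies(taxa, constraints)
    return [
        topology_to_model(t, populations, mu=mu, migration=migration) for t in topos
    ]
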