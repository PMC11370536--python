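"""Declarative cohesin reaction-network topologies.

Cohesin is modelled as a molecule that is either free in the nucleoplasm
(``FREE``) or chromatin-loaded in one of several biochemical states defined by
which regulatory protein (NIPBL, PDS5 or WAPL) is bound to the loaded core
complex.  Under the mutual-exclusivity assumption each loaded state carries at
most one regulator: ``R`` (bare), ``RN`` (NIPBL-bound, the actively-extruding
state), ``RP`` (PDS5-bound) and ``RW`` (WAPL-bound).  A topology is a directed
graph of mass-action transitions between these states; the chemistry of every
edge (which regulator is consumed from or released to the free pool, and
whether the step is first- or second-order) is inferred from the regulator
sets of its endpoints.

The module provides systematic enumeration of all reaction *cycles*
``FREE -> s1 <-> s2 <-> s3 <-> s4 -> FREE`` with irreversible loading and
unloading, plus a catalogue of named alternative topologies (regulator
excursions, strict PDS5+WAPL co-binding, fully reversible acyclic families).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import yaml

REGULATORS = ("NIPBL", "PDS5", "WAPL")

#: Canonical single-regulator state labels.
STATE_REGULATORS = {
    "FREE": frozenset(),
    "R": frozenset(),
    "RN": frozenset({"NIPBL"}),
    "RP": frozenset({"PDS5"}),
    "RW": frozenset({"WAPL"}),
    "RPW": frozenset({"PDS5", "WAPL"}),
}


@dataclass(frozen=True)
class SpeciesId:
    """A molecular species with its total nuclear copy number."""

    name: str
    total_abundance: float

    def __post_init__(self):
        if self.total_abundance <= 0:
            raise ValueError(f"total abundance of {self.name} must be > 0")


@dataclass(frozen=True)
class CohesinState:
    """A cohesin biochemical state, defined by its bound regulators."""

    label: str
    bound_regulators: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_label(cls, label: str) -> "CohesinState":
        try:
            return cls(label, STATE_REGULATORS[label])
        except KeyError:
            raise ValueError(f"unknown state label {label!r}") from None

    @property
    def is_free(self) -> bool:
        return self.label == "FREE"


FREE = CohesinState.from_label("FREE")


@dataclass(frozen=True)
class Transition:
    """A single mass-action transition between two cohesin states.

    ``order`` is 1 for unimolecular steps and 2 for steps whose rate is
    proportional to the free nucleoplasmic pool of ``consumed_species``.
    Exchange steps (e.g. RP -> RW) are composite: the incoming regulator is
    consumed from its free pool and the outgoing one released instantaneously.
    """

    from_state: str
    to_state: str
    kind: str  # load | unload | bind | unbind | exchange
    consumed_species: str | None = None
    released_species: str | None = None
    order: int = 1

    @property
    def key(self) -> tuple:
        return (self.from_state, self.to_state)

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.from_state}->{self.to_state}"


def infer_transition(from_state: CohesinState, to_state: CohesinState) -> Transition:
    """Infer the chemistry of an edge from the regulator sets of its endpoints."""
    gained = to_state.bound_regulators - from_state.bound_regulators
    lost = from_state.bound_regulators - to_state.bound_regulators
    if gained and to_state.is_free:
        raise ValueError("unloading cannot consume a regulator")
    if len(gained) > 1 or (len(lost) > 1 and not to_state.is_free):
        raise ValueError(
            f"{from_state.label}->{to_state.label}: at most one regulator may "
            "be exchanged per elementary step"
        )
    consumed = next(iter(gained), None)
    released = next(iter(lost), None)
    if from_state.is_free:
        # Loading may co-bind the regulator of the entry state.
        kind, order = "load", (2 if consumed else 1)
    elif to_state.is_free:
        # Unloading releases everything the exiting state carried (possibly
        # more than one regulator in the strict co-binding variant).
        released = "+".join(sorted(lost)) if lost else None
        kind, order = "unload", 1
    elif consumed and released:
        kind, order = "exchange", 2
    elif consumed:
        kind, order = "bind", 2
    elif released:
        kind, order = "unbind", 1
    else:
        raise ValueError(
            f"{from_state.label}->{to_state.label}: endpoints carry identical "
            "regulators; no elementary chemistry"
        )
    return Transition(from_state.label, to_state.label, kind, consumed, released, order)


@dataclass
class ReactionTopology:
    """A candidate cohesin reaction network.

    Parameters
    ----------
    name : str
        Identifier (e.g. ``"five_state"`` or ``"cycle_RN-R-RP-RW"``).
    states : list of CohesinState
        Must contain ``FREE`` exactly once.
    transitions : list of Transition
    family : str
        One of ``cycle``, ``acyclic_linear``, ``acyclic_branched``,
        ``acyclic_star``, ``excursion_NIPBL``, ``excursion_PDS5``,
        ``cobinding_strict``.
    """

    name: str
    states: list
    transitions: list
    family: str = "cycle"

    # -- convenience accessors -------------------------------------------------
    @property
    def state_labels(self) -> list:
        return [s.label for s in self.states]

    @property
    def loaded_states(self) -> list:
        return [s for s in self.states if not s.is_free]

    def state(self, label: str) -> CohesinState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    def transitions_from(self, label: str) -> list:
        return [t for t in self.transitions if t.from_state == label]

    def transitions_into(self, label: str) -> list:
        return [t for t in self.transitions if t.to_state == label]

    @property
    def load_transitions(self) -> list:
        return [t for t in self.transitions if t.kind == "load"]

    @property
    def unload_transitions(self) -> list:
        return [t for t in self.transitions if t.kind == "unload"]

    def regulators_of(self, label: str) -> frozenset:
        return self.state(label).bound_regulators

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "family": self.family,
            "states": [
                {"label": s.label, "bound_regulators": sorted(s.bound_regulators)}
                for s in self.states
            ],
            "transitions": [
                {
                    "from": t.from_state,
                    "to": t.to_state,
                    "kind": t.kind,
                    "consumed": t.consumed_species,
                    "released": t.released_species,
                    "order": t.order,
                }
                for t in self.transitions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionTopology":
        states = [
            CohesinState(s["label"], frozenset(s.get("bound_regulators", ())))
            for s in d["states"]
        ]
        transitions = [
            Transition(t["from"], t["to"], t["kind"], t.get("consumed"),
                       t.get("released"), t.get("order", 1))
            for t in d["transitions"]
        ]
        return cls(d["name"], states, transitions, d.get("family", "cycle"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReactionTopology":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Construction helpers


def _edges_to_topology(name, labels, edges, family) -> ReactionTopology:
    states = [CohesinState.from_label(lbl) for lbl in labels]
    by_label = {s.label: s for s in states}
    transitions = [infer_transition(by_label[a], by_label[b]) for a, b in edges]
    return ReactionTopology(name, states, transitions, family)


def make_cycle(loaded_order, name=None) -> ReactionTopology:
    """Build the cycle FREE -> s1 <-> s2 <-> s3 <-> s4 -> FREE.

    Loading into the first loaded state and unloading from the last are
    irreversible; the intermediate regulator-exchange steps are reversible.
    """
    order = list(loaded_order)
    edges = [("FREE", order[0])]
    for a, b in zip(order, order[1:]):
        edges += [(a, b), (b, a)]
    edges.append((order[-1], "FREE"))
    name = name or "cycle_" + "-".join(order)
    return _edges_to_topology(name, ["FREE"] + order, edges, "cycle")


def enumerate_cycles(loaded_states) -> list:
    """All reaction cycles over the given loaded states (one per ordering).

    Parameters
    ----------
    loaded_states : sequence of str or CohesinState
        Distinct loaded states; n states yield n! candidate cycles.
    """
    labels = [s.label if isinstance(s, CohesinState) else s for s in loaded_states]
    if len(set(labels)) != len(labels):
        raise ValueError("loaded states must be distinct")
    if "FREE" in labels:
        raise ValueError("FREE is not a loaded state")
    return [make_cycle(perm) for perm in itertools.permutations(labels)]


def builtin_topologies() -> dict:
    """Catalogue of named topologies examined as alternatives to the cycle.

    Returns a dict mapping topology id to :class:`ReactionTopology`:

    - ``five_state``: the surviving cycle FREE -> RN <-> R <-> RP <-> RW -> FREE.
    - ``nipbl_excursion``: NIPBL binding is a reversible excursion off the bare
      loaded state instead of mediating loading.
    - ``pds5_excursion``: PDS5 reversibly binds the core complex but does not
      recruit WAPL (no RP <-> RW edge).
    - ``cobinding_strict``: WAPL and PDS5 strictly co-bind; unloading proceeds
      only from the co-bound RPW state.
    - ``acyclic_linear`` / ``acyclic_branched`` / ``acyclic_star``:
      representative members of the fully reversible acyclic families.
    """
    cat = {}
    cat["five_state"] = make_cycle(["RN", "R", "RP", "RW"], name="five_state")

    # NIPBL excursion: main cycle FREE -> R <-> RP <-> RW -> FREE, RN off R.
    cat["nipbl_excursion"] = _edges_to_topology(
        "nipbl_excursion", ["FREE", "R", "RN", "RP", "RW"],
        [("FREE", "R"), ("R", "RP"), ("RP", "R"), ("RP", "RW"), ("RW", "RP"),
         ("RW", "FREE"), ("R", "RN"), ("RN", "R")],
        "excursion_NIPBL")

    # PDS5 excursion: main cycle FREE -> RN <-> R <-> RW -> FREE, RP off R.
    cat["pds5_excursion"] = _edges_to_topology(
        "pds5_excursion", ["FREE", "RN", "R", "RP", "RW"],
        [("FREE", "RN"), ("RN", "R"), ("R", "RN"), ("R", "RW"), ("RW", "R"),
         ("RW", "FREE"), ("R", "RP"), ("RP", "R")],
        "excursion_PDS5")

    # Strict co-binding: WAPL joins only on top of PDS5; unload from RPW.
    cat["cobinding_strict"] = _edges_to_topology(
        "cobinding_strict", ["FREE", "RN", "R", "RP", "RPW"],
        [("FREE", "RN"), ("RN", "R"), ("R", "RN"), ("R", "RP"), ("RP", "R"),
         ("RP", "RPW"), ("RPW", "RP"), ("RPW", "FREE")],
        "cobinding_strict")

    # Fully reversible acyclic families (every edge reversible; loading and
    # unloading share the single FREE edge).
    cat["acyclic_linear"] = _edges_to_topology(
        "acyclic_linear", ["FREE", "RN", "R", "RP", "RW"],
        [("FREE", "RN"), ("RN", "FREE"), ("RN", "R"), ("R", "RN"),
         ("R", "RP"), ("RP", "R"), ("RP", "RW"), ("RW", "RP")],
        "acyclic_linear")
    cat["acyclic_star"] = _edges_to_topology(
        "acyclic_star", ["FREE", "R", "RN", "RP", "RW"],
        [("FREE", "R"), ("R", "FREE"), ("R", "RN"), ("RN", "R"),
         ("R", "RP"), ("RP", "R"), ("R", "RW"), ("RW", "R")],
        "acyclic_star")
    cat["acyclic_branched"] = _edges_to_topology(
        "acyclic_branched", ["FREE", "RN", "R", "RP", "RW"],
        [("FREE", "RN"), ("RN", "FREE"), ("RN", "R"), ("R", "RN"),
         ("R", "RP"), ("RP", "R"), ("R", "RW"), ("RW", "R")],
        "acyclic_branched")
    return cat


# ---------------------------------------------------------------------------
# Validation


def _reachable(topology, sources, forward=True):
    adj = {}
    for t in topology.transitions:
        a, b = (t.from_state, t.to_state) if forward else (t.to_state, t.from_state)
        adj.setdefault(a, set()).add(b)
    seen = set(sources)
    stack = list(sources)
    while stack:
        for nxt in adj.get(stack.pop(), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def validate_topology(topology: ReactionTopology) -> list:
    """Check structural invariants; returns a list of violation strings.

    An empty list means the topology is well formed: FREE occurs exactly once,
    every loaded state is reachable from FREE and co-reachable back to it,
    transition chemistry is consistent with the regulator bookkeeping of its
    endpoint states, loading originates at FREE and unloading terminates there,
    and cycle-family topologies carry exactly 8 transitions with irreversible
    loading and unloading.
    """
    v = []
    labels = topology.state_labels
    if labels.count("FREE") != 1:
        v.append("FREE must appear exactly once")
        return v
    if len(set(labels)) != len(labels):
        v.append("duplicate states")

    by_label = {s.label: s for s in topology.states}
    for t in topology.transitions:
        if t.from_state not in by_label or t.to_state not in by_label:
            v.append(f"{t}: endpoint not in state list")
            continue
        try:
            ref = infer_transition(by_label[t.from_state], by_label[t.to_state])
        except ValueError as err:
            v.append(f"{t}: {err}")
            continue
        if (t.kind, t.consumed_species, t.order) != (ref.kind, ref.consumed_species, ref.order):
            v.append(f"{t}: chemistry ({t.kind}, consumes {t.consumed_species}, "
                     f"order {t.order}) inconsistent with regulator sets "
                     f"(expected {ref.kind}, consumes {ref.consumed_species}, "
                     f"order {ref.order})")
        if t.released_species != ref.released_species:
            v.append(f"{t}: released species {t.released_species!r} inconsistent "
                     f"with regulator sets (expected {ref.released_species!r})")
        if t.kind == "load" and t.from_state != "FREE":
            v.append(f"{t}: load transitions must originate at FREE")
        if t.kind == "unload" and t.to_state != "FREE":
            v.append(f"{t}: unload transitions must terminate at FREE")

    loaded = {s.label for s in topology.loaded_states}
    fwd = _reachable(topology, {"FREE"}, forward=True)
    missing = loaded - fwd
    if missing:
        v.append(f"states unreachable from FREE: {sorted(missing)}")
    back = _reachable(topology, {"FREE"}, forward=False)
    stuck = loaded - back
    if stuck:
        v.append(f"states that cannot return to FREE: {sorted(stuck)}")

    if topology.family == "cycle":
        n_loaded = len(topology.loaded_states)
        expected = 2 * n_loaded  # irreversible load + unload + reversible pairs
        if len(topology.transitions) != expected:
            v.append(f"cycle family over {n_loaded} loaded states requires "
                     f"exactly {expected} transitions, "
                     f"found {len(topology.transitions)}")
        # a reversed load or unload edge would show up as an extra
        # unload/load transition, so uniqueness enforces irreversibility
        if len(topology.load_transitions) != 1:
            v.append("cycle family requires exactly one (irreversible) load")
        if len(topology.unload_transitions) != 1:
            v.append("cycle family requires exactly one (irreversible) unload")
    return v
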