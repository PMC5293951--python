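"""Event-driven lineage diversification under the T_I / T_S / T_R framework.

A single ancestral population experiences isolating events (expected
waiting time ``t_i`` per extant lineage).  Each split creates a pair of
sister populations that schedules two competing clocks: secondary contact
(expected waiting time ``t_s``) and completion of reproductive isolation
(``t_r``, either a fixed/exponential parameter or drawn as ``k / u`` with
``k`` geometric in the hole probability epsilon and ``u`` the neutral
substitution rate).  Contact after RI is inconsequential — the populations
are distinct species.  Contact before RI resolves to one of: fusion (the
pair merges back into one population and the period of isolation becomes
invisible to later phylogenetic reconstruction), reinforcement (selection
against unfit hybrids completes RI), or extinction of one or both
populations.

Trees are reconstructed from the true history under the assumption that
reconstruction is exact: a bifurcation survives if both sides leave
populations alive at the reading time; fused and extinct branches are
pruned and pass-through nodes are collapsed.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ContactOutcomes",
    "RICoupling",
    "RegimeParameters",
    "Lineage",
    "Event",
    "LineageHistory",
    "EmptyTreeError",
    "classify_regime",
    "simulate_history",
    "reconstruct_tree",
    "tree_to_newick",
    "internode_summary",
    "InternodeSummary",
    "DiversificationEstimate",
    "diversification_estimate",
    "branching_intervals",
    "sweep_mutation_rate",
]


class EmptyTreeError(ValueError):
    """Raised when reconstruction is asked for a time with no living lineage."""


@dataclass(frozen=True)
class ContactOutcomes:
    """Outcome probabilities when contact occurs with only partial RI.

    The remainder ``1 - p_reinforce - p_extinct_one - p_extinct_both`` is
    the fusion probability.
    """

    p_reinforce: float = 0.5
    p_extinct_one: float = 0.25
    p_extinct_both: float = 0.05

    def __post_init__(self) -> None:
        probs = (self.p_reinforce, self.p_extinct_one, self.p_extinct_both)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("outcome probabilities must lie in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("outcome probabilities must sum to <= 1")

    @property
    def p_fuse(self) -> float:
        return max(0.0, 1.0 - self.p_reinforce - self.p_extinct_one - self.p_extinct_both)


@dataclass(frozen=True)
class RICoupling:
    """Draw T_R as k/u: k geometric(epsilon) substitutions at neutral rate u."""

    epsilon: float
    u: float

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must be in (0, 1)")
        if self.u <= 0:
            raise ValueError("mutation rate u must be > 0")


@dataclass(frozen=True)
class RegimeParameters:
    """Waiting-time scales and bookkeeping for a diversification run.

    ``timing_mode="exponential"`` draws every waiting time from an
    exponential law with the stated mean; ``"fixed"`` uses the mean itself.
    ``t_r`` may be replaced by a :class:`RICoupling`, in which case each
    pair's RI time is an independent draw ``k / u``.
    """

    t_i: float
    t_s: float
    t_r: float | None = None
    coupling: RICoupling | None = None
    timing_mode: str = "exponential"
    contact_outcomes: ContactOutcomes = field(default_factory=ContactOutcomes)
    total_time: float = 1000.0
    max_lineages: int = 200

    def __post_init__(self) -> None:
        if self.t_i <= 0 or self.t_s <= 0:
            raise ValueError("t_i and t_s must be > 0")
        if (self.t_r is None) == (self.coupling is None):
            raise ValueError("exactly one of t_r and coupling must be given")
        if self.t_r is not None and self.t_r <= 0:
            raise ValueError("t_r must be > 0")
        if self.timing_mode not in ("fixed", "exponential"):
            raise ValueError(f"unknown timing_mode {self.timing_mode!r}")
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")
        if self.max_lineages < 2:
            raise ValueError("max_lineages must be >= 2")

    @property
    def expected_t_r(self) -> float:
        if self.t_r is not None:
            return self.t_r
        return (1.0 / self.coupling.epsilon) / self.coupling.u


@dataclass
class Lineage:
    """One population line; dies only by fusion or extinction."""

    id: int
    parent: int | None
    birth: float
    death: float | None = None
    fate: str | None = None  # None (extant) | "fused" | "extinct"
    epoch: int = 0

    @property
    def extant(self) -> bool:
        return self.death is None


@dataclass(frozen=True)
class Event:
    time: float
    type: str  # isolation | contact | fuse | reinforce | extinction | ri_complete
    lineages: tuple[int, ...]


@dataclass
class LineageHistory:
    """Timed record of a diversification run."""

    params: RegimeParameters
    lineages: dict[int, Lineage]
    events: list[Event]
    truncated: bool
    end_time: float

    def alive_at(self, t: float) -> list[Lineage]:
        return [
            l
            for l in self.lineages.values()
            if l.birth <= t and (l.death is None or l.death > t)
        ]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": [e.time for e in self.events],
                "type": [e.type for e in self.events],
                "lineages": [";".join(map(str, e.lineages)) for e in self.events],
            }
        )


def classify_regime(t_i: float, t_s: float, t_r: float, far_factor: float = 10.0) -> str:
    """Label the expected diversification pattern from the three timescales.

    * ``isolation_completes_ri``: t_s >= t_r — RI wins before contact, every
      isolating event yields a species.
    * ``fusion_latest_split_only``: t_r >> t_s (ratio >= far_factor) and
      t_i > t_s — populations merge back before the next split, so only the
      latest split is visible.
    * ``chained_isolation``: t_r >> t_s and t_i <= t_s — new splits outpace
      contact.
    * ``partial_ri_contact``: t_s < t_r < far_factor * t_s — contact with
      partial RI; reinforcement/extinction outcomes apply.
    """
    if t_i <= 0 or t_s <= 0 or t_r <= 0:
        raise ValueError("all waiting times must be > 0")
    if t_s >= t_r:
        return "isolation_completes_ri"
    if t_r / t_s >= far_factor:
        return "fusion_latest_split_only" if t_i > t_s else "chained_isolation"
    return "partial_ri_contact"


def _draw(mean: float, mode: str, rng: np.random.Generator) -> float:
    return mean if mode == "fixed" else rng.exponential(mean)


def simulate_history(params: RegimeParameters, seed=None) -> LineageHistory:
    """Run the event-driven simulation from one lineage to ``total_time``.

    Pending secondary-contact events are cancelled when either member of
    the pair undergoes a population-changing event (a later split of its
    own, a fusion, or an extinction) before contact fires; RI completion
    and reinforcement leave clocks untouched.  Reaching ``max_lineages``
    halts the run and sets the ``truncated`` flag.
    """
    rng = np.random.default_rng(seed)
    lineages: dict[int, Lineage] = {0: Lineage(0, None, 0.0)}
    events: list[Event] = []
    pair_ri: dict[int, bool] = {}
    pair_members: dict[int, tuple[int, int]] = {}
    next_id = itertools.count(1)
    next_pair = itertools.count(0)
    seq = itertools.count(0)
    heap: list[tuple[float, int, str, tuple]] = []
    truncated = False
    end_time = params.total_time

    def draw_tr() -> float:
        if params.coupling is not None:
            k = int(rng.geometric(params.coupling.epsilon))
            return k / params.coupling.u
        return _draw(params.t_r, params.timing_mode, rng)

    def schedule(t: float, kind: str, data: tuple) -> None:
        heapq.heappush(heap, (t, next(seq), kind, data))

    def schedule_isolation(lid: int, now: float) -> None:
        schedule(now + _draw(params.t_i, params.timing_mode, rng), "isolation", (lid, lineages[lid].epoch))

    schedule_isolation(0, 0.0)

    while heap:
        t, _, kind, data = heapq.heappop(heap)
        if t > params.total_time:
            break

        if kind == "isolation":
            lid, epoch = data
            lin = lineages[lid]
            if not lin.extant or lin.epoch != epoch:
                continue
            n_alive = sum(1 for l in lineages.values() if l.extant)
            if n_alive + 1 > params.max_lineages:
                truncated = True
                end_time = t
                break
            child = Lineage(next(next_id), lid, t)
            lineages[child.id] = child
            lin.epoch += 1
            events.append(Event(t, "isolation", (lid, child.id)))
            pid = next(next_pair)
            pair_ri[pid] = False
            pair_members[pid] = (lid, child.id)
            schedule(t + _draw(params.t_s, params.timing_mode, rng), "contact",
                     (pid, lid, lin.epoch, child.id, child.epoch))
            schedule(t + draw_tr(), "ri", (pid,))
            schedule_isolation(lid, t)
            schedule_isolation(child.id, t)

        elif kind == "ri":
            (pid,) = data
            a, b = pair_members[pid]
            if pair_ri[pid] or not lineages[a].extant or not lineages[b].extant:
                continue
            pair_ri[pid] = True
            events.append(Event(t, "ri_complete", (a, b)))

        elif kind == "contact":
            pid, a, ea, b, eb = data
            la, lb = lineages[a], lineages[b]
            if not (la.extant and lb.extant and la.epoch == ea and lb.epoch == eb):
                continue
            if pair_ri[pid]:
                continue  # distinct species; contact has no consequence
            oc = params.contact_outcomes
            r = rng.random()
            if r < oc.p_reinforce:
                pair_ri[pid] = True
                events.append(Event(t, "reinforce", (a, b)))
            elif r < oc.p_reinforce + oc.p_extinct_one:
                victim = a if rng.random() < 0.5 else b
                v = lineages[victim]
                v.death, v.fate = t, "extinct"
                events.append(Event(t, "extinction", (victim,)))
            elif r < oc.p_reinforce + oc.p_extinct_one + oc.p_extinct_both:
                for lid in (a, b):
                    l = lineages[lid]
                    l.death, l.fate = t, "extinct"
                events.append(Event(t, "extinction", (a, b)))
            else:
                # fusion: the spawned record dies; the parent line continues
                lb.death, lb.fate = t, "fused"
                la.epoch += 1
                events.append(Event(t, "fuse", (a, b)))
                schedule_isolation(a, t)

    return LineageHistory(params, lineages, events, truncated, end_time)


class _Node:
    __slots__ = ("time", "children", "label")

    def __init__(self, time: float, children=(), label: str | None = None):
        self.time = time
        self.children = list(children)
        self.label = label


def _build_node(
    lid: int,
    t0: float,
    at_time: float,
    lineages: dict[int, Lineage],
    children_of: dict[int, list[tuple[float, int]]],
) -> _Node | None:
    kids = [(b, c) for (b, c) in children_of.get(lid, ()) if t0 < b <= at_time]
    if kids:
        b, cid = kids[0]
        right = _build_node(cid, b, at_time, lineages, children_of)
        left = _build_node(lid, b, at_time, lineages, children_of)
        if right is not None and left is not None:
            return _Node(b, (left, right))
        return left if left is not None else right
    lin = lineages[lid]
    if lin.birth <= at_time and (lin.death is None or lin.death > at_time):
        return _Node(at_time, label=f"L{lid}")
    return None


def reconstruct_tree(history: LineageHistory, at_time: float | None = None) -> dendropy.Tree:
    """Exact phylogeny of the populations alive at ``at_time``.

    Bifurcations are isolation events with surviving descendants on both
    sides; fused/extinct branches are pruned, pass-through nodes collapsed,
    and branch lengths are elapsed generations.  Ultrametric by
    construction.  Raises :class:`EmptyTreeError` when nothing is alive.
    """
    if at_time is None:
        at_time = history.end_time
    if at_time > history.params.total_time:
        raise ValueError("at_time exceeds total_time")
    children_of: dict[int, list[tuple[float, int]]] = {}
    for lin in history.lineages.values():
        if lin.parent is not None:
            children_of.setdefault(lin.parent, []).append((lin.birth, lin.id))
    for v in children_of.values():
        v.sort()
    root = _build_node(0, 0.0, at_time, history.lineages, children_of)
    if root is None:
        raise EmptyTreeError(f"no extant lineages at time {at_time}")

    tree = dendropy.Tree()
    tns = tree.taxon_namespace

    def convert(node: _Node, parent_time: float) -> dendropy.Node:
        dnode = dendropy.Node()
        dnode.edge.length = node.time - parent_time
        if node.children:
            for ch in node.children:
                dnode.add_child(convert(ch, node.time))
        else:
            taxon = tns.new_taxon(label=node.label)
            dnode.taxon = taxon
        return dnode

    tree.seed_node = convert(root, 0.0)
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths, no internal labels."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class InternodeSummary:
    mean: float
    variance: float
    count: int


def internode_summary(tree: dendropy.Tree) -> InternodeSummary:
    """Mean/variance of internal-edge lengths (waiting times between splits).

    The root's subtending edge (origin to first split) is included; tip
    edges are not.
    """
    tips = len(tree.leaf_nodes())
    if tips < 2:
        raise ValueError("internode summary undefined for trees with < 2 tips")
    lengths = [
        node.edge.length
        for node in tree.preorder_node_iter()
        if not node.is_leaf() and node.edge.length is not None
    ]
    arr = np.asarray(lengths, dtype=float)
    return InternodeSummary(float(arr.mean()), float(arr.var()), len(arr))


@dataclass(frozen=True)
class DiversificationEstimate:
    lambda_hat: float
    n_tips: int
    crown_age: float


def diversification_estimate(tree: dendropy.Tree) -> DiversificationEstimate:
    """Pure-birth speciation-rate estimator ln(n_tips) / crown_age."""
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("diversification estimate undefined for < 2 tips")
    # distance_from_root includes the seed edge; crown age is the depth
    # below the first split.
    crown_age = max(leaf.distance_from_root() for leaf in leaves) - tree.seed_node.edge.length
    if crown_age <= 0:
        raise ValueError("crown age must be > 0")
    lam = float(np.log(len(leaves)) / crown_age)
    return DiversificationEstimate(lam, len(leaves), crown_age)


def branching_intervals(history: LineageHistory) -> list[tuple[int, float]]:
    """(k, waiting time) pairs between successive isolation events.

    ``k`` is the number of lineages present during the wait.  Under a pure
    Yule regime (every split permanent) the wait with ``k`` lineages is
    exponential with mean ``t_i / k``.  Only completed (uncensored)
    intervals are returned.
    """
    times = [e.time for e in history.events if e.type == "isolation"]
    out = []
    prev = 0.0
    for j, t in enumerate(times):
        out.append((j + 1, t - prev))
        prev = t
    return out


def sweep_mutation_rate(
    u_values,
    epsilon: float,
    base_params: RegimeParameters,
    n_histories: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean diversification-rate estimate as a function of mutation rate.

    For each ``u``, T_R is coupled as ``k / u`` with ``k`` geometric in
    ``epsilon`` (each pair draws independently), ``n_histories`` runs are
    simulated, and the mean stem-age estimate ``ln(n_tips) / total_time``
    is reported (a history ending with a single lineage contributes 0: no
    detectable branching).  The stem-age form is used here rather than the
    crown-age form of :func:`diversification_estimate` because fusion
    prunes the earliest splits from the reconstructed tree, which makes the
    crown age itself shrink with the fusion rate and would mask the
    tip-count signal the sweep is meant to expose.
    """
    rows = []
    for ui, u in enumerate(u_values):
        params = replace(base_params, t_r=None, coupling=RICoupling(epsilon, u))
        lams = []
        for h in range(n_histories):
            ss = np.random.SeedSequence(seed, spawn_key=(ui, h))
            hist = simulate_history(params, ss)
            try:
                tree = reconstruct_tree(hist)
                n_tips = len(tree.leaf_nodes())
                lams.append(np.log(n_tips) / hist.end_time)
            except EmptyTreeError:
                lams.append(0.0)
        rows.append(
            {
                "u": u,
                "mean_lambda": float(np.mean(lams)),
                "expected_t_r": (1.0 / epsilon) / u,
                "n_histories": n_histories,
            }
        )
    return pd.DataFrame(rows)
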