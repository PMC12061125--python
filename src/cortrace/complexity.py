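"""Connectivity- and representation-complexity calculators for incremental
binding architectures.

The framework counts, per hierarchical level ``l`` with ``L_l`` retinotopic
positions, ``N_F,l`` features per position and neighbourhood sizes
``K_{l-1}, K_l, K_{l+1}`` toward the lower/same/higher level:

* base-evidence channels      ``N_BE,l = K_{l-1} N_F,l-1 N_F,l``
* naive binding channels      ``N_BS,l = N_F,l P_l``
* decomposed binding channels ``N_B,l  = N_F,l + P_l``
* context channels            ``N_C,l  = N_F,l (K_{l+1} N_F,l+1)``

with the neighbour pool ``P_l = K_{l-1} N_F,l-1 + K_l N_F,l + K_{l+1}
N_F,l+1`` (missing terms at hierarchy boundaries contribute 0).  The
asymptotic expressions are evaluated literally with coefficient 1; the
results are formula counts, not wiring diagrams.  Neighbourhoods are taken
to include the node's own position.

A toy Boolean propagation model demonstrates how the availability of a
coarser level changes the number of steps to bind a contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ArchitectureSpec",
    "LevelCounts",
    "ComplexityReport",
    "InterfaceCounts",
    "encoding_bits",
    "channel_counts",
    "interface_counts",
    "toy_propagation",
]


def encoding_bits(variant: str) -> tuple[float, float]:
    """Output bits (and memory bits) a local neural processor needs.

    ``two_node_static`` encodes the base-evidence and binding-state bits
    independently (2 bits); ``single_node_static`` exploits that binding
    implies base evidence, leaving 3 states (log2 3 bits); a
    ``single_node_phasic`` processor codes 1 bit per phase but must remember
    its base-evidence state across phases (1 bit of memory).
    """
    table = {
        "two_node_static": (2.0, 0.0),
        "single_node_static": (math.log2(3.0), 0.0),
        "single_node_phasic": (1.0, 1.0),
    }
    if variant not in table:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(table)}")
    return table[variant]


@dataclass(frozen=True)
class ArchitectureSpec:
    """A hierarchical incremental-binding architecture.

    ``positions[l]`` and ``features[l]`` give ``L_l`` and ``N_F,l`` per level
    (level 0 is the lowest).  ``k_lower/k_same/k_higher`` are neighbourhood
    sizes toward the adjacent levels; boundary entries are ignored.  Proxy
    parameters describe the featureless binding-state map: ``proxy_positions``
    (``L_p``) and the neighbourhood sizes ``k_proxy_to_level`` /
    ``k_level_to_proxy``.
    """

    positions: tuple
    features: tuple
    k_lower: int = 9
    k_same: int = 9
    k_higher: int = 9
    interface: str = "full"  # top | bottom | full
    proxy_positions: int | None = None
    k_proxy_to_level: int = 9
    k_level_to_proxy: int = 9

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.features):
            raise ValueError("positions and features must have the same length")
        if any(int(x) <= 0 for x in self.positions + self.features):
            raise ValueError("all counts must be positive integers")
        for k in (self.k_lower, self.k_same, self.k_higher):
            if k <= 0:
                raise ValueError("neighbourhood sizes must be positive")
        if self.interface not in ("top", "bottom", "full"):
            raise ValueError("interface must be 'top', 'bottom' or 'full'")

    @property
    def n_levels(self) -> int:
        return len(self.positions)

    @property
    def lp(self) -> int:
        """Proxy map size; defaults to the largest level."""
        return self.proxy_positions if self.proxy_positions is not None else max(self.positions)

    def targeted_levels(self) -> list[int]:
        if self.interface == "top":
            return [self.n_levels - 1]
        if self.interface == "bottom":
            return [0]
        return list(range(self.n_levels))


@dataclass(frozen=True)
class LevelCounts:
    level: int
    pool: int  # P_l
    n_be: int  # base-evidence channels
    n_bs_naive: int  # naive binding channels
    n_b_decomposed: int  # decomposed binding channels
    n_context: int  # context (compatibility) channels


@dataclass
class ComplexityReport:
    levels: list = field(default_factory=list)
    total_naive: int = 0
    total_decomposed: int = 0
    meta: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        return [
            {
                "level": lc.level,
                "pool": lc.pool,
                "n_be": lc.n_be,
                "n_bs_naive": lc.n_bs_naive,
                "n_b_decomposed": lc.n_b_decomposed,
                "n_context": lc.n_context,
            }
            for lc in self.levels
        ]


def channel_counts(spec: ArchitectureSpec) -> ComplexityReport:
    """Per-level and total channel counts, naive vs decomposed binding."""
    report = ComplexityReport(
        meta={"neighbourhoods_include_self": True, "coefficients": 1}
    )
    nf = spec.features
    for l in range(spec.n_levels):
        lower = spec.k_lower * nf[l - 1] if l > 0 else 0
        same = spec.k_same * nf[l]
        higher = spec.k_higher * nf[l + 1] if l < spec.n_levels - 1 else 0
        pool = lower + same + higher
        n_be = (spec.k_lower * nf[l - 1] * nf[l]) if l > 0 else 0
        n_bs = nf[l] * pool
        n_b = nf[l] + pool
        n_c = nf[l] * higher
        report.levels.append(LevelCounts(l, pool, n_be, n_bs, n_b, n_c))
    report.total_naive = sum(lc.n_be + lc.n_bs_naive for lc in report.levels)
    report.total_decomposed = sum(
        lc.n_be + lc.n_b_decomposed + lc.n_context for lc in report.levels
    )
    return report


@dataclass(frozen=True)
class InterfaceCounts:
    """Connection/node counts for a task-interface realisation.

    ``injection_connections`` is ``N_Inj``, the wiring that injects the seed
    (and reads the binding state back); ``total_connections`` additionally
    counts the model-internal binding-state transmission the interface
    variant implies, which is what the shared proxy absorbs.
    """

    variant: str  # top | bottom | full
    proxy: str  # none | separate | shared
    controller_connections: int  # wires the task controller itself needs
    injection_connections: int  # N_Inj
    total_connections: int  # N_Inj + binding-state channels
    extra_nodes: int


def interface_counts(spec: ArchitectureSpec, proxy: str = "separate") -> InterfaceCounts:
    """Connections needed to inject the attentional seed and transmit the
    binding state.

    Without a proxy the controller wires into every space-feature node of
    the targeted levels (``M = sum L_l N_F,l``), and each level carries its
    decomposed binding-state channels ``L_l (N_F,l + P_l)``.  A separate
    proxy map reduces the controller side to ``L_p`` (``N_Inj = L_p + M``)
    at the cost of one proxy node per interface position plus per-level
    binding-proxy nodes.  Sharing a single proxy map between interfacing and
    binding-state transmission keeps only ``L_p`` extra nodes and replaces
    the per-level binding channels by local couplings to the common map,
    ``sum L_l P*_l`` with ``P*_l = N_F,l K_p,l + N_F,l K_l,p``.
    """
    if proxy not in ("none", "separate", "shared"):
        raise ValueError("proxy must be 'none', 'separate' or 'shared'")
    targeted = spec.targeted_levels()
    m = sum(spec.positions[l] * spec.features[l] for l in targeted)
    lp = spec.lp
    binding = sum(
        spec.positions[l] * (spec.features[l] + channel_counts(spec).levels[l].pool)
        for l in targeted
    )
    if proxy == "none":
        return InterfaceCounts(spec.interface, proxy, m, m, m + binding, 0)
    if proxy == "separate":
        return InterfaceCounts(
            spec.interface, proxy, lp, lp + m, lp + m + binding,
            lp + sum(spec.positions[l] for l in targeted),
        )
    # shared proxy: the interfacing map doubles as the binding-state channel
    p_star = sum(
        spec.positions[l]
        * (spec.features[l] * spec.k_proxy_to_level + spec.features[l] * spec.k_level_to_proxy)
        for l in targeted
    )
    return InterfaceCounts(spec.interface, proxy, lp, lp + m, lp + p_star, lp)


# ---------------------------------------------------------------------------
# toy Boolean propagation


def _level_neighbours(spec: ArchitectureSpec, level: int, pos: int) -> list[tuple[int, int]]:
    """Neighbours of node (level, pos) under the K neighbourhoods.

    Levels are 1D chains; adjacent levels are coupled through the positional
    mapping ``pos_l ~ pos_m * L_l / L_m``.
    """
    out = []
    half_same = spec.k_same // 2
    ll = spec.positions[level]
    for d in range(-half_same, half_same + 1):
        q = pos + d
        if 0 <= q < ll and d != 0:
            out.append((level, q))
    for other, k in ((level - 1, spec.k_lower), (level + 1, spec.k_higher)):
        if not 0 <= other < spec.n_levels:
            continue
        lo = spec.positions[other]
        centre = int(round(pos * (lo - 1) / max(ll - 1, 1))) if ll > 1 else 0
        half = k // 2
        for d in range(-half, half + 1):
            q = centre + d
            if 0 <= q < lo:
                out.append((other, q))
    return out


def toy_propagation(
    spec: ArchitectureSpec,
    base_evidence: dict,
    seed: tuple[int, int],
    max_steps: int = 10_000,
) -> dict:
    """Synchronous Boolean spread of the binding state over an NProc graph.

    ``base_evidence`` maps (level, pos) to True where base evidence exists;
    nodes missing from the map have none (e.g. an interference-blocked
    level).  A node binds once it has base evidence and a bound neighbour
    (the seed binds at step 0).  Returns the binding step per node; binding
    is monotone, so the result is the closure of the seed's component.
    """
    if not base_evidence.get(seed, False):
        raise ValueError("seed node must carry base evidence")
    bound = {seed: 0}
    frontier = [seed]
    step = 0
    while frontier and step < max_steps:
        step += 1
        new = []
        for node in frontier:
            for nb in _level_neighbours(spec, *node):
                if nb in bound or not base_evidence.get(nb, False):
                    continue
                bound[nb] = step
                new.append(nb)
        frontier = new
    return bound
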