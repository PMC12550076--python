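"""Shared test helpers: valid mutations against the packaged reference."""

from __future__ import annotations

from mtfounder.haplotype_io import TRANSITION, MitoHaplotype, Mutation, PositionConfig
from mtfounder.reference import reference_base, transition_partner


def tsub(pos: int) -> Mutation:
    """The transition at *pos* (always valid against the reference)."""
    return Mutation(pos, transition_partner(reference_base(pos)), TRANSITION)


def hap(sample_id: str, positions, region: str = "", island: str = "",
        lat: float = 0.0, lon: float = 0.0) -> MitoHaplotype:
    return MitoHaplotype(
        sample_id=sample_id,
        variants=frozenset(tsub(p) for p in positions),
        region=region,
        island=island or region,
        lat=lat,
        lon=lon,
    )


def uniform_cfg() -> PositionConfig:
    """Position config with uniform character weights (no hotspots)."""
    return PositionConfig(downweighted=frozenset(), default_weight=10.0,
                          reduced_weight=7.0)


def tree_length(tree) -> int:
    return sum(len(d["mutations"]) for _, _, d in tree.graph.edges(data=True))


def oracle_mp_length(rows) -> int:
    """Independent exhaustive minimum Steiner length in the binary
    hypercube (Dreyfus-Wagner over all 2^s nodes; pure-python, kept
    deliberately separate from the package's implementation)."""
    s = len(rows[0])
    n_nodes = 1 << s
    terms = sorted({int("".join(map(str, r)), 2) for r in rows})
    t = len(terms)
    if t == 1:
        return 0

    def d(u, v):
        return bin(u ^ v).count("1")

    INF = float("inf")
    dp = [[INF] * n_nodes for _ in range(1 << t)]
    for i, ti in enumerate(terms):
        for v in range(n_nodes):
            dp[1 << i][v] = d(ti, v)
    for S in range(1, 1 << t):
        if bin(S).count("1") <= 1:
            continue
        merged = [INF] * n_nodes
        T = (S - 1) & S
        while T:
            U = S ^ T
            if T < U:
                row_t, row_u = dp[T], dp[U]
                for v in range(n_nodes):
                    c = row_t[v] + row_u[v]
                    if c < merged[v]:
                        merged[v] = c
            T = (T - 1) & S
        row = dp[S]
        for v in range(n_nodes):
            row[v] = min(merged[u] + d(u, v) for u in range(n_nodes))
    return int(min(dp[(1 << t) - 1]))
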