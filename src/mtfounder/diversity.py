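"""Diversity statistics: the rho founder statistic and nucleotide diversity.

rho is the mean number of mutations separating each sampled haplotype
from a designated root, averaged over samples; under a molecular clock
it converts directly to an age.  Its standard error treats per-branch
mutation counts as independent Poisson draws, giving

    sigma^2 = sum_e m_e * (n_e / n)^2

over tree edges, where ``m_e`` is the number of mutations on edge *e*
and ``n_e`` the number of samples subtended by it.  Both the root-to-tip
path-sum form and the edge-weighted form of rho are implemented and
asserted equal.

Nucleotide diversity pi is the average pairwise difference per site,
computed on masked substitution profiles over the full molecule length
by default (matching the way whole-mitogenome tables are usually
reported); a frequency-weighted (uncorrected) variant is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .haplotype_io import MitoHaplotype
from .network import RootedHaploTree
from .reference import MT_LENGTH

logger = logging.getLogger(__name__)


class MembershipError(KeyError):
    """A requested sample is not a tip of the tree."""


class UndefinedEstimateError(ValueError):
    """The estimator is undefined for the given sample size."""


@dataclass(frozen=True)
class RhoEstimate:
    rho: float
    sigma: float
    n: int
    region: str = ""
    root_id: str = ""

    def __post_init__(self):
        if self.rho < 0 or self.sigma < 0 or self.n < 1:
            raise ValueError("invalid rho estimate")


@dataclass(frozen=True)
class PiEstimate:
    pi: float
    n: int
    seq_length: int

    def __post_init__(self):
        if not 0 <= self.pi <= 1 or self.n < 2:
            raise ValueError("invalid pi estimate")


def _sample_counts(tree: RootedHaploTree, samples: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for sid in samples:
        node = tree.sample_node.get(sid)
        if node is None:
            raise MembershipError(f"sample {sid!r} is not in the tree")
        counts[node] = counts.get(node, 0) + 1
    return counts


def rho(
    tree: RootedHaploTree,
    samples: Iterable[str] | None = None,
    region: str = "",
) -> RhoEstimate:
    """rho and its Poisson standard error for *samples* against the root.

    *samples* defaults to every sample in the tree.  Both formulations
    of rho (mean root-to-tip path length, and edge mutations weighted by
    the fraction of samples subtended) are computed and cross-checked.
    """
    if samples is None:
        samples = list(tree.sample_node)
    else:
        samples = list(samples)
    if not samples:
        raise UndefinedEstimateError("rho requires at least one sample")
    counts = _sample_counts(tree, samples)
    n = sum(counts.values())

    # path-sum form
    path_sum = sum(tree.depth(node) * c for node, c in counts.items())
    rho_path = path_sum / n

    # edge-weighted form
    below = tree.subtended_counts(counts)
    rho_edge = 0.0
    var = 0.0
    for u, v, d in tree.graph.edges(data=True):
        m_e = len(d["mutations"])
        n_e = below[v]
        rho_edge += m_e * n_e / n
        var += m_e * (n_e / n) ** 2
    assert abs(rho_path - rho_edge) < 1e-9, "rho formulations disagree"

    return RhoEstimate(
        rho=rho_path, sigma=float(np.sqrt(var)), n=n, region=region, root_id=tree.root
    )


def rho_sigma(tree: RootedHaploTree, samples: Iterable[str] | None = None) -> float:
    """Standard error of rho (convenience wrapper)."""
    return rho(tree, samples).sigma


def nucleotide_diversity(
    haps: Sequence[MitoHaplotype],
    seq_length: int = MT_LENGTH,
    corrected: bool = True,
) -> PiEstimate:
    """Average pairwise difference per site over *seq_length*.

    With ``corrected=True`` (default) pairs are counted as
    ``sum_{i<j} d_ij / C(n, 2)`` — the usual sample estimator.  With
    ``corrected=False`` the frequency-weighted form
    ``sum_ij x_i x_j d_ij`` is used, which is invariant under
    duplicating every sample.
    """
    n = len(haps)
    if n < 2:
        raise UndefinedEstimateError("pi requires at least two samples")
    profiles: dict[frozenset, int] = {}
    for h in haps:
        profiles[h.substitutions] = profiles.get(h.substitutions, 0) + 1
    uniq = list(profiles)
    counts = np.array([profiles[p] for p in uniq], dtype=float)

    total = 0.0
    for (i, a), (j, b) in itertools.combinations(enumerate(uniq), 2):
        d = len(a ^ b)
        total += d * counts[i] * counts[j]
    if corrected:
        mean_d = total / (n * (n - 1) / 2)
    else:
        mean_d = 2 * total / (n * n)
    return PiEstimate(pi=mean_d / seq_length, n=n, seq_length=seq_length)


def filter_min_n(
    groups: Mapping[str, Sequence],
    threshold: int = 15,
) -> dict[str, Sequence]:
    """Drop groups with fewer than *threshold* members (default 15)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    kept = {k: v for k, v in groups.items() if len(v) >= threshold}
    dropped = sorted(set(groups) - set(kept))
    if dropped:
        logger.info(
            "filter_min_n: dropped %s (n < %d)",
            ", ".join(f"{k} (n={len(groups[k])})" for k in dropped),
            threshold,
        )
    return kept


def regional_diversity_table(
    tree: RootedHaploTree,
    haps: Sequence[MitoHaplotype],
    min_n: int = 15,
    seq_length: int = MT_LENGTH,
):
    """Per-region n / pi / rho / sigma table (as a pandas DataFrame)."""
    import pandas as pd

    by_region: dict[str, list[MitoHaplotype]] = {}
    for h in haps:
        by_region.setdefault(h.region, []).append(h)
    kept = filter_min_n(by_region, threshold=min_n)
    rows = []
    for region in sorted(kept):
        group = kept[region]
        est = rho(tree, [h.sample_id for h in group], region=region)
        pi = nucleotide_diversity(group, seq_length=seq_length)
        rows.append(
            {
                "region": region,
                "n": est.n,
                "pi": round(pi.pi, 6),
                "rho": round(est.rho, 3),
                "sigma": round(est.sigma, 3),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n", "pi", "rho", "sigma"])
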