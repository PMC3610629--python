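"""Binary contact maps, contiguous spatial-macrodomain segmentation, and
partition comparison.

Segmentation minimizes total intra-domain dissimilarity
``V(a, b) = min_m sum_{j=a..b} (1 - C[j, m])`` over contiguous partitions,
with the centromere (when present) pre-fixed as its own domain.  Because
domains are contiguous the optimum is found exactly by dynamic programming
over boundary placements — no iterative medoid heuristic is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ContactMap",
    "Partition",
    "map_from_conformations",
    "map_from_enrichment",
    "segment",
    "partition_overlap",
    "overlap_pvalue",
    "random_partition",
]


@dataclass
class ContactMap:
    """Symmetric binary segment-contact matrix with an optional masked
    centromere interval (half-open segment indices)."""

    matrix: np.ndarray
    segment_width: int = 60_000  # bp
    centromere: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact map must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("contact map must be symmetric")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("contact map must be binary")
        m = m.astype(np.int8).copy()
        np.fill_diagonal(m, 0)
        if self.centromere is not None:
            c0, c1 = self.centromere
            if not 0 <= c0 <= c1 <= m.shape[0]:
                raise ValueError("centromere interval out of range")
            m[c0:c1, :] = 0
            m[:, c0:c1] = 0
        self.matrix = m

    @property
    def n_segments(self) -> int:
        return self.matrix.shape[0]

    def n_contacts(self) -> int:
        """Number of non-zero upper-triangle entries."""
        return int(np.triu(self.matrix, k=1).sum())


@dataclass
class Partition:
    """Contiguous subdivision of segments into domains.

    ``boundaries`` are the interior cut positions (a cut at ``b`` separates
    segment ``b-1`` from ``b``); ``centromere_domain`` is the id of the
    domain coinciding with the centromere, or None.
    """

    n_segments: int
    boundaries: list[int]
    centromere_domain: int | None = None
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        b = list(self.boundaries)
        if sorted(set(b)) != b or (b and (b[0] <= 0 or b[-1] >= self.n_segments)):
            raise ValueError("boundaries must be strictly increasing interior cuts")
        cuts = [0] + b + [self.n_segments]
        lab = np.empty(self.n_segments, dtype=np.int64)
        for d, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
            lab[s:e] = d
        self.labels = lab
        if self.centromere_domain is not None:
            if not 0 <= self.centromere_domain < self.n_domains:
                raise ValueError("centromere_domain out of range")

    @property
    def n_domains(self) -> int:
        return len(self.boundaries) + 1

    def domain_intervals(self) -> list[tuple[int, int]]:
        cuts = [0] + list(self.boundaries) + [self.n_segments]
        return list(zip(cuts[:-1], cuts[1:]))


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

def segment_mean_distances(
    chain_list: list[np.ndarray],
    beads_per_segment: int,
    box_side: float | None = None,
) -> np.ndarray:
    """Mean inter-segment bead-pair distance, averaged over chain copies.

    Each chain is split into consecutive ``beads_per_segment``-bead segments;
    the distance between segments i and j is the mean over all bead pairs
    (minimum-image if ``box_side`` given), then averaged over the chains.
    """
    n_beads = len(chain_list[0])
    for ch in chain_list:
        if len(ch) != n_beads:
            raise ValueError("all chain copies must have equal length")
    n_seg = n_beads // beads_per_segment
    acc = np.zeros((n_seg, n_seg))
    for ch in chain_list:
        pos = np.asarray(ch, dtype=float)[: n_seg * beads_per_segment]
        d = pos[:, None, :] - pos[None, :, :]
        if box_side is not None:
            d -= box_side * np.round(d / box_side)
        dist = np.sqrt((d ** 2).sum(-1))
        # average bead-pair distance per segment block
        blocks = dist.reshape(n_seg, beads_per_segment, n_seg, beads_per_segment)
        acc += blocks.mean(axis=(1, 3))
    return acc / len(chain_list)


def map_from_conformations(
    chain_list: list[np.ndarray],
    beads_per_segment: int,
    n_contacts: int,
    centromere: tuple[int, int] | None = None,
    box_side: float | None = None,
    segment_width: int = 60_000,
) -> ContactMap:
    """Binary map marking the ``n_contacts`` closest segment pairs.

    Distances are mean bead-pair distances averaged over the chain copies;
    the smallest ``n_contacts`` off-mask pairs become contacts, mirroring a
    density-matched comparison against a reference map.
    """
    dist = segment_mean_distances(chain_list, beads_per_segment, box_side)
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    if centromere is not None:
        c0, c1 = centromere
        masked = ((iu >= c0) & (iu < c1)) | ((ju >= c0) & (ju < c1))
        iu, ju = iu[~masked], ju[~masked]
    vals = dist[iu, ju]
    if n_contacts > len(vals):
        n_contacts = len(vals)
    order = np.argsort(vals, kind="stable")[:n_contacts]
    m = np.zeros((n, n), dtype=np.int8)
    m[iu[order], ju[order]] = 1
    m = np.maximum(m, m.T)
    return ContactMap(matrix=m, segment_width=segment_width, centromere=centromere)


def map_from_enrichment(
    triplets: pd.DataFrame | np.ndarray,
    threshold: float,
    n_segments: int,
    centromere: tuple[int, int] | None = None,
    segment_width: int = 60_000,
) -> ContactMap:
    """Binarize an (i, j, value) enrichment list at ``threshold``.

    Entries with value >= threshold are set; the map is symmetrized and the
    centromere masked.
    """
    arr = np.asarray(triplets)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("triplets must have columns (i, j, value)")
    m = np.zeros((n_segments, n_segments), dtype=np.int8)
    for i, j, v in arr:
        ii, jj = int(i), int(j)
        if not (0 <= ii < n_segments and 0 <= jj < n_segments):
            raise ValueError(f"segment index ({ii},{jj}) out of range")
        if ii != jj and v >= threshold:
            m[ii, jj] = 1
            m[jj, ii] = 1
    return ContactMap(matrix=m, segment_width=segment_width, centromere=centromere)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _interval_costs(c: np.ndarray) -> np.ndarray:
    """cost[a, b] = min over medoid m in [a, b] of sum_{j=a..b} (1 - C[j, m]),
    for inclusive interval [a, b]."""
    n = c.shape[0]
    dis = 1.0 - c.astype(float)
    np.fill_diagonal(dis, 0.0)
    # prefix sums of columns: colsum[a, b, m] = sum_{j=a..b} dis[j, m]
    cs = np.vstack([np.zeros(n), np.cumsum(dis, axis=0)])  # (n+1, n) rows j, cols m
    cost = np.full((n, n), np.inf)
    for a in range(n):
        for b in range(a, n):
            seg = cs[b + 1, a:b + 1] - cs[a, a:b + 1]  # candidate medoids in [a,b]
            cost[a, b] = seg.min()
    return cost


def _dp_arm(cost: np.ndarray, lo: int, hi: int, k: int) -> tuple[float, list[int]]:
    """Optimal partition of segments [lo, hi) into exactly k contiguous
    domains; returns (total cost, interior cut positions).  Ties break
    toward earlier boundaries."""
    n = hi - lo
    if k == 0:
        return (0.0, []) if n == 0 else (np.inf, [])
    if n < k:
        return np.inf, []
    # f[d][e] = best cost covering [lo, lo+e) with d domains
    NEG = np.inf
    f = np.full((k + 1, n + 1), NEG)
    arg = np.zeros((k + 1, n + 1), dtype=np.int64)
    f[0, 0] = 0.0
    for d in range(1, k + 1):
        for e in range(d, n + 1):
            best, bs = np.inf, -1
            for s in range(d - 1, e):  # previous cut at lo+s
                if f[d - 1, s] == np.inf:
                    continue
                v = f[d - 1, s] + cost[lo + s, lo + e - 1]
                if v < best - 1e-12:
                    best, bs = v, s
            f[d, e] = best
            arg[d, e] = bs
    if not np.isfinite(f[k, n]):
        return np.inf, []
    cuts = []
    e, d = n, k
    while d > 1:
        s = int(arg[d, e])
        cuts.append(lo + s)
        e, d = s, d - 1
    return float(f[k, n]), sorted(cuts)


def segment(cmap: ContactMap, n_domains: int) -> Partition:
    """Exact optimal contiguous partition into ``n_domains`` domains.

    If the map has a centromere, that interval is fixed as one domain and
    the remaining ``n_domains - 1`` domains are distributed over the two
    arms so as to minimize the total off-centromere interval cost.
    """
    n = cmap.n_segments
    if not 2 <= n_domains <= min(10, n):
        raise ValueError("n_domains must be in [2, min(10, n_segments)]")
    cost = _interval_costs(cmap.matrix)
    cen = cmap.centromere
    if cen is None:
        total, cuts = _dp_arm(cost, 0, n, n_domains)
        if not np.isfinite(total):
            raise ValueError("infeasible segmentation")
        return Partition(n, cuts)
    c0, c1 = cen
    if c0 <= 0 or c1 >= n:
        # centromere at an end: single arm
        k = n_domains - 1
        if c0 <= 0:
            total, cuts = _dp_arm(cost, c1, n, k)
            cuts = [c1] + cuts if c1 > 0 else cuts
            cen_dom = 0
        else:
            total, cuts = _dp_arm(cost, 0, c0, k)
            cuts = cuts + [c0]
            cen_dom = n_domains - 1
        if not np.isfinite(total):
            raise ValueError("infeasible segmentation")
        return Partition(n, cuts, centromere_domain=cen_dom)
    best = (np.inf, None, None, None)
    for k_left in range(0, n_domains):
        k_right = n_domains - 1 - k_left
        cl, cuts_l = _dp_arm(cost, 0, c0, k_left)
        cr, cuts_r = _dp_arm(cost, c1, n, k_right)
        tot = cl + cr
        if tot < best[0] - 1e-12:
            best = (tot, k_left, cuts_l, cuts_r)
    if not np.isfinite(best[0]):
        raise ValueError("infeasible segmentation with centromere fixed")
    _, k_left, cuts_l, cuts_r = best
    cuts = sorted(set(cuts_l) | {c0, c1} | set(cuts_r))
    cuts = [c for c in cuts if 0 < c < n]
    part = Partition(n, cuts)
    cen_dom = int(part.labels[c0])
    part.centromere_domain = cen_dom
    return part


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------

def partition_overlap(p1: Partition, p2: Partition) -> float:
    """Max fraction of (non-centromere) segments with identical assignment
    under the best one-to-one domain correspondence."""
    if p1.n_segments != p2.n_segments:
        raise ValueError("partitions cover different segment counts")
    if p1.n_domains != p2.n_domains:
        raise ValueError("partitions must have equal domain counts")
    keep = np.ones(p1.n_segments, dtype=bool)
    cen_pair = (p1.centromere_domain, p2.centromere_domain)
    if (cen_pair[0] is None) != (cen_pair[1] is None):
        raise ValueError("centromere fixed in only one partition")
    if cen_pair[0] is not None:
        keep &= p1.labels != cen_pair[0]
        keep &= p2.labels != cen_pair[1]
    l1, l2 = p1.labels[keep], p2.labels[keep]
    if l1.size == 0:
        return 1.0
    k = p1.n_domains
    cont = np.zeros((k, k))
    np.add.at(cont, (l1, l2), 1.0)
    if cen_pair[0] is not None:
        # force centromere domains to map to each other, exclude from search
        big = l1.size + 1.0
        cont[cen_pair[0], :] = -big
        cont[:, cen_pair[1]] = -big
        cont[cen_pair[0], cen_pair[1]] = 0.0
    rows, cols = linear_sum_assignment(-cont)
    matched = cont[rows, cols]
    return float(matched[matched > -0.5].sum() / l1.size)


def random_partition(
    n_segments: int,
    n_domains: int,
    centromere: tuple[int, int] | None,
    rng: np.random.Generator,
) -> Partition:
    """Uniform random contiguous partition with the centromere fixed.

    The non-centromere domain count is split between the two arms uniformly
    over feasible splits; each arm's interior boundaries are then a uniform
    sample of cut positions without replacement.
    """
    if centromere is None:
        cuts = sorted(rng.choice(np.arange(1, n_segments), size=n_domains - 1,
                                 replace=False).tolist())
        return Partition(n_segments, cuts)
    c0, c1 = centromere
    n_left, n_right = c0, n_segments - c1
    k_tot = n_domains - 1
    feas = [
        kl for kl in range(0, k_tot + 1)
        if kl <= n_left and (k_tot - kl) <= n_right
        and (kl > 0 or n_left == 0) and ((k_tot - kl) > 0 or n_right == 0)
    ]
    if not feas:
        raise ValueError("no feasible arm split for the requested domain count")
    k_left = int(rng.choice(feas))
    k_right = k_tot - k_left
    cuts = []
    if k_left > 1:
        cuts += sorted(rng.choice(np.arange(1, c0), size=k_left - 1,
                                  replace=False).tolist())
    if c0 > 0:
        cuts.append(c0)
    if c1 < n_segments:
        cuts.append(c1)
    if k_right > 1:
        cuts += sorted(rng.choice(np.arange(c1 + 1, n_segments),
                                  size=k_right - 1, replace=False).tolist())
    part = Partition(n_segments, sorted(cuts))
    part.centromere_domain = int(part.labels[c0]) if c0 < n_segments else None
    return part


def overlap_pvalue(
    p_obs: Partition,
    p_ref: Partition,
    n_samples: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value of the observed overlap against random
    contiguous partitions compared to the reference; add-one corrected."""
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    cen = None
    if p_ref.centromere_domain is not None:
        cen = p_ref.domain_intervals()[p_ref.centromere_domain]
    observed = partition_overlap(p_obs, p_ref)
    k = 0
    for _ in range(n_samples):
        rp = random_partition(p_ref.n_segments, p_ref.n_domains, cen, rng)
        if partition_overlap(rp, p_ref) >= observed:
            k += 1
    return (k + 1) / (n_samples + 1)
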