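"""Coregulation network inference from discretized expression profiles.

The workflow is: tertile-discretize each gene's expression profile, compute
plug-in mutual information (MI, in bits) for all gene pairs, fit a
two-parameter gamma null to the MI histogram within genomic-distance bins,
keep pairs exceeding the per-bin E-value threshold (expected false positives
= 1), and collapse near-degenerate pairs keeping the highest-MI
representative.  Degree-preserving and position-randomizing null models of
the resulting network are provided for comparison experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LOG2_3 = float(np.log2(3.0))

__all__ = [
    "ExpressionMatrix",
    "MIEstimate",
    "NullFit",
    "CoregNetwork",
    "NetworkStats",
    "discretize",
    "mutual_information",
    "mutual_information_matrix",
    "fit_null_and_threshold",
    "select_significant_pairs",
    "deduplicate_pairs",
    "clustering_coefficient",
    "reshuffle_pairings",
    "randomize_positions",
    "infer_network",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x experiments intensities with optional 3-level discretization.

    ``levels`` uses 0/1/2 for low/medium/high; ``-1`` marks genes excluded
    from MI analysis (e.g. constant profiles).
    """

    gene_ids: list[str]
    intensities: np.ndarray
    levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (genes x experiments)")
        if len(self.gene_ids) != self.intensities.shape[0]:
            raise ValueError("gene_ids length must match intensity rows")
        if self.levels is not None:
            self.levels = np.asarray(self.levels, dtype=np.int64)
            if self.levels.shape != self.intensities.shape:
                raise ValueError("levels shape must match intensities")

    @property
    def n_genes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.intensities.shape[1]

    def ensure_levels(self) -> np.ndarray:
        if self.levels is None:
            self.levels = discretize(self.intensities)
        return self.levels


@dataclass(frozen=True)
class MIEstimate:
    i: int
    j: int
    mi: float  # bits
    genomic_separation: float | None = None  # bp between interval midpoints


@dataclass
class NullFit:
    """Gamma null fitted to one genomic-distance bin of MI values."""

    bin_index: int
    bin_range: tuple[float, float]
    n_pairs_in_bin: int
    shape: float
    scale: float
    mi_threshold: float
    ok: bool = True


@dataclass
class CoregNetwork:
    """Genes with genomic intervals plus MI-weighted selected pair edges."""

    gene_ids: list[str]
    starts: np.ndarray  # bp, 0-based half-open
    ends: np.ndarray
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        seen: set[tuple[int, int]] = set()
        canon: list[tuple[int, int, float]] = []
        for i, j, w in self.edges:
            if i == j:
                raise ValueError(f"self-edge on gene index {i}")
            a, b = (i, j) if i < j else (j, i)
            if not (0 <= a < len(self.gene_ids) and b < len(self.gene_ids)):
                raise ValueError(f"edge ({i},{j}) references unknown gene")
            if (a, b) in seen:
                raise ValueError(f"duplicate edge ({a},{b})")
            seen.add((a, b))
            canon.append((a, b, float(w)))
        self.edges = canon

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_sequence(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=np.int64)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.gene_ids[i], self.gene_ids[j], w) for i, j, w in self.edges],
            columns=["gene_i", "gene_j", "mi"],
        )


@dataclass
class NetworkStats:
    node_ids: list[str]
    clustering: np.ndarray  # NaN where undefined (degree < 2)
    n_neighbours: np.ndarray
    n_neighbour_links: np.ndarray
    mean_clustering: float


# ---------------------------------------------------------------------------
# discretization and MI
# ---------------------------------------------------------------------------

def discretize(intensities: np.ndarray, n_levels: int = 3) -> np.ndarray:
    """Per-gene tertile discretization to levels 0/1/2.

    Ties are broken by stable rank order (original column order), so the
    assignment is deterministic and per-level counts differ by at most one.
    Constant profiles (or profiles with fewer distinct values than levels)
    are flagged with all-(-1) rows and a warning.
    """
    if n_levels != 3:
        raise ValueError("only 3-level discretization is supported")
    x = np.asarray(intensities, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    n_genes, n_exp = x.shape
    levels = np.empty((n_genes, n_exp), dtype=np.int64)
    bad = []
    for g in range(n_genes):
        row = x[g]
        if not np.all(np.isfinite(row)) or len(np.unique(row)) < n_levels:
            levels[g] = -1
            bad.append(g)
            continue
        order = np.argsort(row, kind="stable")
        rank = np.empty(n_exp, dtype=np.int64)
        rank[order] = np.arange(n_exp)
        levels[g] = (rank * n_levels) // n_exp
    if bad:
        warnings.warn(
            f"{len(bad)} profile(s) excluded from discretization "
            f"(constant or too few distinct values): indices {bad[:10]}",
            stacklevel=2,
        )
    return levels[0] if squeeze else levels


def _mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in MI (bits) from a 3x3 contingency table."""
    n = counts.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p = counts / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (pi * pj), 1.0)
        terms = np.where(p > 0, p * np.log2(ratio), 0.0)
    return max(float(terms.sum()), 0.0)


def mutual_information(levels_i: np.ndarray, levels_j: np.ndarray) -> float:
    """Plug-in mutual information in bits between two 3-level profiles."""
    a = np.asarray(levels_i, dtype=np.int64)
    b = np.asarray(levels_j, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("profiles must be equal-length 1-D arrays")
    if np.any(a < 0) or np.any(b < 0) or np.any(a > 2) or np.any(b > 2):
        raise ValueError("levels must be in {0,1,2}")
    counts = np.bincount(3 * a + b, minlength=9).reshape(3, 3).astype(float)
    return _mi_from_counts(counts)


def mutual_information_matrix(levels: np.ndarray) -> np.ndarray:
    """All-pairs plug-in MI (bits) for a genes x experiments level matrix.

    Rows containing -1 (excluded genes) yield NaN rows/columns.
    Vectorized via one indicator matrix product per (a, b) level pair.
    """
    L = np.asarray(levels, dtype=np.int64)
    n_genes, n_exp = L.shape
    valid = np.all(L >= 0, axis=1)
    ind = [(L == a).astype(np.float64) for a in range(3)]
    joint = np.empty((3, 3, n_genes, n_genes))
    for a in range(3):
        for b in range(3):
            joint[a, b] = ind[a] @ ind[b].T
    p = joint / n_exp
    pi = p.sum(axis=1)  # (3, G, G) marginal of gene i
    pj = p.sum(axis=0)  # (3, G, G) marginal of gene j
    mi = np.zeros((n_genes, n_genes))
    with np.errstate(divide="ignore", invalid="ignore"):
        for a in range(3):
            for b in range(3):
                pab = p[a, b]
                term = np.where(
                    pab > 0, pab * np.log2(pab / (pi[a] * pj[b])), 0.0
                )
                mi += np.nan_to_num(term)
    np.fill_diagonal(mi, LOG2_3)
    mi = np.clip(mi, 0.0, LOG2_3)
    mi[~valid, :] = np.nan
    mi[:, ~valid] = np.nan
    return mi


# ---------------------------------------------------------------------------
# null fit and selection
# ---------------------------------------------------------------------------

def fit_null_and_threshold(
    mi_values: np.ndarray,
    separations: np.ndarray,
    bin_width: float = 4e6,
    min_pairs_per_bin: int = 50,
    bulk_quantile: float = 0.99,
) -> list[NullFit]:
    """Fit a gamma null per genomic-distance bin and derive E-value cutoffs.

    Pairs are binned by midpoint separation into [0, w), [w, 2w), ...
    Bins with fewer than ``min_pairs_per_bin`` pairs are merged with the
    next bin (the trailing remainder merges backwards).  The gamma is fit
    by maximum likelihood on MI values below the ``bulk_quantile`` within
    each bin, which keeps genuine coregulation signal in the tail from
    inflating the null.  The threshold t* solves
    ``n_pairs_in_bin * SF(t*) = 1`` (at most one expected false positive).
    """
    mi_values = np.asarray(mi_values, dtype=float)
    separations = np.asarray(separations, dtype=float)
    if mi_values.shape != separations.shape:
        raise ValueError("mi_values and separations must align")
    if mi_values.size == 0:
        return []
    n_bins = int(np.floor(separations.max() / bin_width)) + 1
    raw_idx = np.minimum((separations // bin_width).astype(int), n_bins - 1)

    # merge sparse bins with their right neighbour
    edges: list[tuple[int, int]] = []
    start = 0
    while start < n_bins:
        stop = start + 1
        while (
            stop < n_bins
            and np.sum((raw_idx >= start) & (raw_idx < stop)) < min_pairs_per_bin
        ):
            stop += 1
        edges.append((start, stop))
        start = stop
    if len(edges) > 1:
        s, e = edges[-1]
        if np.sum((raw_idx >= s) & (raw_idx < e)) < min_pairs_per_bin:
            ps, _ = edges.pop()
            s0, _ = edges.pop()
            edges.append((s0, e))

    fits: list[NullFit] = []
    for b, (s, e) in enumerate(edges):
        sel = (raw_idx >= s) & (raw_idx < e)
        vals = mi_values[sel]
        vals = vals[np.isfinite(vals)]
        n_pairs = int(vals.size)
        rng_bin = (s * bin_width, e * bin_width)
        if n_pairs < 3 or np.ptp(vals) <= 0:
            fits.append(NullFit(b, rng_bin, n_pairs, np.nan, np.nan, np.inf, ok=False))
            continue
        cutoff = float(np.quantile(vals, bulk_quantile))
        bulk = vals[vals <= cutoff]
        bulk = np.maximum(bulk, 1e-12)  # gamma logpdf needs positive support
        try:
            shape, scale = _fit_truncated_gamma(bulk, cutoff)
        except Exception:
            fits.append(NullFit(b, rng_bin, n_pairs, np.nan, np.nan, np.inf, ok=False))
            continue
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            fits.append(NullFit(b, rng_bin, n_pairs, np.nan, np.nan, np.inf, ok=False))
            continue
        t_star = float(stats.gamma.isf(1.0 / n_pairs, shape, scale=scale))
        fits.append(NullFit(b, rng_bin, n_pairs, float(shape), float(scale), t_star))
    return fits


def _fit_truncated_gamma(bulk: np.ndarray, cutoff: float) -> tuple[float, float]:
    """ML fit of a gamma to samples observed below ``cutoff``.

    Maximizes sum log pdf(x) - n log CDF(cutoff), so discarding the top
    quantile (possible true positives) does not bias the null downward.
    """
    from scipy.optimize import minimize

    s0, _, sc0 = stats.gamma.fit(bulk, floc=0.0)

    def nll(theta):
        shape, scale = np.exp(theta)
        logcdf = stats.gamma.logcdf(cutoff, shape, scale=scale)
        return -(stats.gamma.logpdf(bulk, shape, scale=scale).sum()
                 - len(bulk) * logcdf)

    res = minimize(nll, np.log([s0, sc0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500})
    shape, scale = np.exp(res.x)
    return float(shape), float(scale)


def select_significant_pairs(
    estimates: list[MIEstimate],
    fits: list[NullFit],
) -> list[MIEstimate]:
    """Keep pairs whose MI exceeds the threshold of their distance bin."""
    if not fits:
        return []
    lo = np.array([f.bin_range[0] for f in fits])
    hi = np.array([f.bin_range[1] for f in fits])
    out = []
    for est in estimates:
        d = est.genomic_separation
        if d is None or not np.isfinite(est.mi):
            continue
        k = np.searchsorted(lo, d, side="right") - 1
        k = int(np.clip(k, 0, len(fits) - 1))
        if d >= hi[k] and k < len(fits) - 1:
            k += 1
        f = fits[k]
        if f.ok and est.mi > f.mi_threshold:
            out.append(est)
    return out


# ---------------------------------------------------------------------------
# redundancy filter
# ---------------------------------------------------------------------------

def deduplicate_pairs(
    selected: list[MIEstimate],
    midpoints: np.ndarray,
    merge_distance: float,
    gene_ids: list[str] | None = None,
    starts: np.ndarray | None = None,
    ends: np.ndarray | None = None,
) -> CoregNetwork:
    """Collapse near-degenerate pairs, keeping the max-MI representative.

    Two pairs are grouped when their endpoints can be matched so that both
    matched midpoints are within ``merge_distance`` (bp).  Grouping is
    transitive (connected components of that relation).
    """
    midpoints = np.asarray(midpoints, dtype=float)
    n = len(selected)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    def near(a: int, b: int) -> bool:
        return abs(midpoints[a] - midpoints[b]) < merge_distance

    for p in range(n):
        ip, jp = selected[p].i, selected[p].j
        for q in range(p + 1, n):
            iq, jq = selected[q].i, selected[q].j
            if (near(ip, iq) and near(jp, jq)) or (near(ip, jq) and near(jp, iq)):
                union(p, q)

    best: dict[int, MIEstimate] = {}
    for p in range(n):
        r = find(p)
        if r not in best or selected[p].mi > best[r].mi:
            best[r] = selected[p]

    if gene_ids is None:
        gene_ids = [f"g{k}" for k in range(len(midpoints))]
    if starts is None:
        starts = midpoints.astype(np.int64)
    if ends is None:
        ends = starts + 1
    edges = [(e.i, e.j, e.mi) for e in best.values()]
    return CoregNetwork(list(gene_ids), starts, ends, edges)


# ---------------------------------------------------------------------------
# graph statistics
# ---------------------------------------------------------------------------

def clustering_coefficient(network: CoregNetwork) -> NetworkStats:
    """Watts-Strogatz per-node clustering; mean over nodes with >= 2 links."""
    n = network.n_genes
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j, _ in network.edges:
        adj[i].add(j)
        adj[j].add(i)
    c = np.full(n, np.nan)
    n_nb = np.zeros(n, dtype=np.int64)
    e_nb = np.zeros(n, dtype=np.int64)
    for v in range(n):
        nb = adj[v]
        n_nb[v] = len(nb)
        if len(nb) < 2:
            continue
        links = 0
        nbl = sorted(nb)
        for a_idx, a in enumerate(nbl):
            for b in nbl[a_idx + 1:]:
                if b in adj[a]:
                    links += 1
        e_nb[v] = links
        c[v] = 2.0 * links / (len(nb) * (len(nb) - 1))
    defined = ~np.isnan(c)
    mean_c = float(np.mean(c[defined])) if defined.any() else float("nan")
    return NetworkStats(list(network.gene_ids), c, n_nb, e_nb, mean_c)


# ---------------------------------------------------------------------------
# randomized variants
# ---------------------------------------------------------------------------

def reshuffle_pairings(
    network: CoregNetwork,
    fraction: float = 1.0,
    seed: int | None = None,
    max_tries_factor: int = 200,
) -> CoregNetwork:
    """Degree-preserving partial/full rewiring via double-edge swaps.

    Swaps (a-b, c-d) -> (a-d, c-b) are attempted (rejecting self loops and
    duplicates) until at least ``fraction`` of the edges differ from the
    native edge set, or the attempt budget is exhausted (then a warning is
    emitted and the best-effort network returned).  MI weights follow the
    surviving endpoint ``a``/``c`` arbitrarily; node positions untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if network.n_edges < 2:
        raise ValueError("need at least 2 edges to reshuffle")
    if fraction == 0.0:
        return CoregNetwork(
            list(network.gene_ids), network.starts.copy(), network.ends.copy(),
            list(network.edges),
        )
    rng = np.random.default_rng(seed)
    native = network.edge_set()
    edges = [(i, j) for i, j, _ in network.edges]
    weights = {(i, j): w for i, j, w in network.edges}
    target = int(np.ceil(fraction * len(edges)))
    edge_set = set(edges)
    max_tries = max_tries_factor * len(edges)
    tries = 0
    while tries < max_tries:
        tries += 1
        changed = sum(1 for e in edge_set if e not in native)
        if changed >= target:
            break
        p, q = rng.integers(0, len(edges), size=2)
        if p == q:
            continue
        a, b = edges[p]
        c, d = edges[q]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[p])
        edge_set.discard(edges[q])
        w1 = weights.pop(edges[p])
        w2 = weights.pop(edges[q])
        edges[p], edges[q] = e1, e2
        edge_set.add(e1)
        edge_set.add(e2)
        weights[e1] = w1
        weights[e2] = w2
    else:
        warnings.warn(
            "reshuffle_pairings: attempt budget exhausted before reaching "
            f"the requested rewired fraction ({fraction:.2f})",
            stacklevel=2,
        )
    new_edges = [(i, j, weights[(i, j)]) for i, j in edges]
    return CoregNetwork(
        list(network.gene_ids), network.starts.copy(), network.ends.copy(), new_edges
    )


def randomize_positions(
    network: CoregNetwork,
    chromosome_length: int,
    centromere: tuple[int, int] | None = None,
    seed: int | None = None,
) -> CoregNetwork:
    """Randomly reposition gene intervals, keeping pairings verbatim.

    Interval lengths are preserved, placements are non-overlapping and
    outside the centromere.
    """
    rng = np.random.default_rng(seed)
    lengths = (network.ends - network.starts).astype(np.int64)
    starts = _pack_intervals(
        lengths, chromosome_length, centromere, rng
    )
    return CoregNetwork(
        list(network.gene_ids), starts, starts + lengths, list(network.edges)
    )


def _pack_intervals(
    lengths: np.ndarray,
    chromosome_length: int,
    centromere: tuple[int, int] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place intervals of given lengths non-overlapping, avoiding the
    centromere; order along the chromosome is randomized."""
    if centromere is not None:
        c0, c1 = centromere
        if not 0 <= c0 <= c1 <= chromosome_length:
            raise ValueError("centromere must lie within the chromosome")
        segs = [(0, c0), (c1, chromosome_length)]
    else:
        segs = [(0, chromosome_length)]
    avail = sum(e - s for s, e in segs)
    total = int(lengths.sum())
    slack = avail - total
    if slack < 0:
        raise ValueError("intervals do not fit outside the centromere")
    order = rng.permutation(len(lengths))
    gaps = np.floor(rng.dirichlet(np.ones(len(lengths) + 1)) * slack).astype(np.int64)
    # lay out genes on the concatenated available space, then map back
    concat_pos = np.empty(len(lengths), dtype=np.int64)
    cursor = 0
    for k, g in enumerate(order):
        cursor += gaps[k]
        concat_pos[g] = cursor
        cursor += lengths[g]
    starts = np.empty(len(lengths), dtype=np.int64)
    for g in range(len(lengths)):
        pos = concat_pos[g]
        for s, e in segs:
            if pos + lengths[g] <= e - s:
                starts[g] = s + pos
                break
            pos -= e - s
        else:
            raise AssertionError("interval packing overflow")
    return starts


# ---------------------------------------------------------------------------
# end-to-end inference
# ---------------------------------------------------------------------------

def infer_network(
    matrix: ExpressionMatrix,
    starts: np.ndarray,
    ends: np.ndarray,
    bin_width: float = 4e6,
    min_pairs_per_bin: int = 50,
    merge_distance: float = 300.0,
    gene_ids: list[str] | None = None,
) -> tuple[CoregNetwork, list[NullFit]]:
    """Full MI -> null fit -> E-value selection -> dedup pipeline.

    ``merge_distance`` is in bp.  For the default chromatin calibration
    (30 nm beads, 10 kb/bead, 150 nm persistence length) the Kuhn length of
    300 nm corresponds to 10 beads, i.e. 100 kb; pass that explicitly when
    working at chromosomal scale.  The small default only suits compact
    synthetic annotations.
    """
    levels = matrix.ensure_levels()
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    mid = 0.5 * (starts + ends)
    mi = mutual_information_matrix(levels)
    n = matrix.n_genes
    iu, ju = np.triu_indices(n, k=1)
    vals = mi[iu, ju]
    seps = np.abs(mid[iu] - mid[ju])
    finite = np.isfinite(vals)
    ests = [
        MIEstimate(int(a), int(b), float(v), float(d))
        for a, b, v, d in zip(iu[finite], ju[finite], vals[finite], seps[finite])
    ]
    fits = fit_null_and_threshold(
        vals[finite], seps[finite], bin_width=bin_width,
        min_pairs_per_bin=min_pairs_per_bin,
    )
    chosen = select_significant_pairs(ests, fits)
    ids = gene_ids if gene_ids is not None else list(matrix.gene_ids)
    net = deduplicate_pairs(
        chosen, mid, merge_distance, gene_ids=ids, starts=starts, ends=ends
    )
    return net, fits
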