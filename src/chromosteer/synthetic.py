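"""Synthetic expression compendia, gene annotations and reference contact
maps with planted structure, for end-to-end testing without external data.

Expression model: each planted module (clique) shares, per experiment, a
latent 3-state value; member genes copy it with probability ``1 - noise_eta``
and otherwise draw uniformly from the three states.  Background genes are
i.i.d. uniform.  Ground truth is the set of all within-module pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domains import ContactMap
from .network import ExpressionMatrix


@dataclass
class SyntheticDesign:
    n_genes: int
    n_experiments: int
    chromosome_length: int  # bp
    centromere: tuple[int, int] | None = None  # bp, half-open
    modules: list[frozenset[int]] = field(default_factory=list)
    noise_eta: float = 0.1
    seed: int = 0
    gene_length: int = 5_000  # bp span of each synthetic gene

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_eta <= 1.0:
            raise ValueError("noise_eta must lie in [0, 1]")
        self.modules = [frozenset(m) for m in self.modules]
        seen: set[int] = set()
        for m in self.modules:
            for g in m:
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"module references nonexistent gene {g}")
                if g in seen:
                    raise ValueError(f"gene {g} appears in two modules")
                seen.add(g)
        if self.centromere is not None:
            c0, c1 = self.centromere
            if not 0 <= c0 <= c1 <= self.chromosome_length:
                raise ValueError("centromere outside chromosome")


@dataclass
class ReferenceMapDesign:
    n_segments: int
    domain_boundaries: list[int]  # interior boundaries, strictly increasing
    centromere_segments: tuple[int, int] | None = None  # half-open
    p_in: float = 0.8
    p_out: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        b = list(self.domain_boundaries)
        if any(b[k] >= b[k + 1] for k in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")
        if b and (b[0] <= 0 or b[-1] >= self.n_segments):
            raise ValueError("boundaries must be interior segment indices")
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.centromere_segments is not None:
            c0, c1 = self.centromere_segments
            cuts = [0] + b + [self.n_segments]
            if (c0, c1) not in zip(cuts[:-1], cuts[1:]):
                raise ValueError("centromere must coincide with one domain")


def generate_expression(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, set[tuple[int, int]]]:
    """Draw a compendium from the latent-state model; return matrix + truth.

    Intensities are ``level + U(0, 1)`` jitter so that downstream tertile
    discretization of the continuous values is well defined; the exact
    planted levels are attached as ``matrix.levels``.
    """
    rng = np.random.default_rng(design.seed)
    G, E = design.n_genes, design.n_experiments
    levels = rng.integers(0, 3, size=(G, E))
    for module in design.modules:
        latent = rng.integers(0, 3, size=E)
        for g in sorted(module):
            noise = rng.random(E) < design.noise_eta
            row = np.where(noise, rng.integers(0, 3, size=E), latent)
            levels[g] = row
    intensities = levels + rng.random((G, E)) * 0.999
    gene_ids = [f"gene{g:05d}" for g in range(G)]
    matrix = ExpressionMatrix(gene_ids, intensities, levels=levels)
    truth: set[tuple[int, int]] = set()
    for module in design.modules:
        mem = sorted(module)
        for a_idx, a in enumerate(mem):
            for b in mem[a_idx + 1:]:
                truth.add((a, b))
    return matrix, truth


def planted_pair_mi(noise_eta: float) -> float:
    """Closed-form MI (bits) of two genes sharing one latent 3-state factor.

    q(a|s) = (1-eta) + eta/3 on the diagonal, eta/3 off; the pair joint is
    p(a,b) = sum_s (1/3) q(a|s) q(b|s).
    """
    q = np.full((3, 3), noise_eta / 3.0)
    np.fill_diagonal(q, 1.0 - noise_eta + noise_eta / 3.0)
    p = (q.T @ q) / 3.0
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p / (pi * pj)), 0.0)
    return float(t.sum())


def generate_annotation(design: SyntheticDesign) -> np.ndarray:
    """Non-overlapping gene intervals outside the centromere.

    Returns an (n_genes, 2) array of 0-based half-open [start, end) bp
    intervals, in gene-index order.  Deterministic under the design seed.
    """
    from .network import _pack_intervals

    rng = np.random.default_rng(design.seed + 1)
    lengths = np.full(design.n_genes, design.gene_length, dtype=np.int64)
    starts = _pack_intervals(
        lengths, design.chromosome_length, design.centromere, rng
    )
    return np.stack([starts, starts + lengths], axis=1)


def generate_reference_map(design: ReferenceMapDesign) -> ContactMap:
    """Block-structured binary map with planted domains and masked centromere."""
    rng = np.random.default_rng(design.seed)
    n = design.n_segments
    cuts = [0] + list(design.domain_boundaries) + [n]
    label = np.empty(n, dtype=np.int64)
    for d, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
        label[s:e] = d
    same = label[:, None] == label[None, :]
    u = rng.random((n, n))
    u = np.triu(u, k=1)
    u = u + u.T  # symmetric uniforms
    m = np.where(same, u < design.p_in, u < design.p_out).astype(np.int8)
    np.fill_diagonal(m, 0)
    cen = design.centromere_segments
    if cen is not None:
        c0, c1 = cen
        m[c0:c1, :] = 0
        m[:, c0:c1] = 0
    return ContactMap(matrix=m, centromere=cen)


def clique_design(
    n_cliques: int = 20,
    clique_size: int = 4,
    n_background: int = 120,
    n_experiments: int = 500,
    chromosome_length: int = 20_000_000,
    centromere: tuple[int, int] | None = None,
    noise_eta: float = 0.1,
    seed: int = 0,
) -> SyntheticDesign:
    """Convenience factory: planted cliques scattered among background genes.

    Module gene indices are interleaved with the background uniformly so the
    planted pairs span the full range of genomic separations.
    """
    n_genes = n_cliques * clique_size + n_background
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_genes)
    modules = [
        frozenset(int(perm[k]) for k in range(c * clique_size, (c + 1) * clique_size))
        for c in range(n_cliques)
    ]
    return SyntheticDesign(
        n_genes=n_genes,
        n_experiments=n_experiments,
        chromosome_length=chromosome_length,
        centromere=centromere,
        modules=modules,
        noise_eta=noise_eta,
        seed=seed,
    )
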