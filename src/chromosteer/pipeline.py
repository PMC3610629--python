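"""End-to-end reproducible pipeline driver.

Stages: synthetic compendium -> network inference -> system construction ->
push-off relaxation -> steering -> contact map -> segmentation ->
partition comparison.  All randomness flows from one seed via named
substreams; a JSON manifest echoes the resolved configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .domains import map_from_conformations, overlap_pvalue, partition_overlap, segment
from .engine import RunParams, pushoff_relax
from .network import infer_network
from .polymer import (
    ForceFieldParams,
    box_side_for_volume_fraction,
    build_mitotic,
    maxwell_boltzmann_velocities,
    place_chains,
)
from .steering import run_steered, schedule_from_network
from .synthetic import (
    ReferenceMapDesign,
    clique_design,
    generate_annotation,
    generate_expression,
    generate_reference_map,
)


def stream_seed(seed: int, name: str) -> int:
    """Deterministic integer sub-seed for a named pipeline substream."""
    tag = int.from_bytes(name.encode(), "little") % 2 ** 31
    ss = np.random.SeedSequence([seed, tag])
    return int(ss.generate_state(1)[0])


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, decorrelated child generator of the global seed."""
    return np.random.default_rng(stream_seed(seed, name))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    # synthetic compendium
    n_cliques: int = 6
    clique_size: int = 3
    n_background: int = 30
    n_experiments: int = 400
    chromosome_length: int = 1_200_000
    noise_eta: float = 0.1
    # polymer system
    n_chains: int = 2
    bp_per_bead: int = 10_000
    volume_fraction: float = 0.10
    loop_length_beads: int = 12
    # runs
    relax_steps: int = 2000
    steer_steps: int = 6000
    dt: float = 0.01
    friction: float = 0.5
    k0: float = 0.05
    k1: float = 5.0
    contact_cutoff: float = 4.0
    # segmentation
    beads_per_segment: int = 6
    n_domains: int = 4
    merge_distance_bp: int = 20_000
    force_field: ForceFieldParams = field(default_factory=ForceFieldParams)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write artifacts under ``config.out_dir``.

    Returns a summary dict (also written as JSON manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = config.force_field

    # --- stage 1: synthetic expression + annotation ----------------------
    design = clique_design(
        n_cliques=config.n_cliques,
        clique_size=config.clique_size,
        n_background=config.n_background,
        n_experiments=config.n_experiments,
        chromosome_length=config.chromosome_length,
        noise_eta=config.noise_eta,
        seed=stream_seed(config.seed, "expression"),
    )
    matrix, truth = generate_expression(design)
    ann = generate_annotation(design)
    cio.write_expression_tsv(out / "expression.tsv", matrix)
    cio.write_bed(out / "genes.bed", ann[:, 0], ann[:, 1], matrix.gene_ids)

    # --- stage 2: network inference --------------------------------------
    network, fits = infer_network(
        matrix, ann[:, 0], ann[:, 1],
        merge_distance=config.merge_distance_bp,
    )
    cio.write_edges_tsv(out / "network.tsv", network)

    # --- stage 3: system construction + relaxation ------------------------
    n_beads = config.chromosome_length // config.bp_per_bead
    box = box_side_for_volume_fraction(
        n_beads * config.n_chains, phi=config.volume_fraction
    )
    confs = [
        build_mitotic(n_beads, loop_length_beads=config.loop_length_beads)
        for _ in range(config.n_chains)
    ]
    state = place_chains(confs, box, seed=stream_seed(config.seed, "placement"))
    rng = np.random.default_rng(stream_seed(config.seed, "velocities"))
    state.vel = maxwell_boltzmann_velocities(state.n_beads, 1.0, rng)
    pushoff_relax(
        state, ff, n_steps=config.relax_steps,
        run=RunParams(dt=0.005, friction=1.0,
                      seed=stream_seed(config.seed, "relax")),
    )
    cio.write_xyz(out / "relaxed.xyz", state)

    # --- stage 4: steering ------------------------------------------------
    run = RunParams(
        dt=config.dt, n_steps=config.steer_steps, friction=config.friction,
        seed=stream_seed(config.seed, "steer"),
    )
    schedule = schedule_from_network(
        network, state, config.bp_per_bead,
        k0=config.k0, k1=config.k1,
        t_steer=config.steer_steps * config.dt,
    )
    _, report = run_steered(state, ff, schedule, run, r_c=config.contact_cutoff)
    report.to_frame().to_csv(out / "steering.tsv", sep="\t", index=False)
    cio.write_xyz(out / "steered.xyz", state)

    # --- stage 5: contact map + segmentation ------------------------------
    n_seg = n_beads // config.beads_per_segment
    n_contacts = max(config.n_domains * 3, int(0.08 * n_seg * (n_seg - 1) / 2))
    cmap = map_from_conformations(
        state.chains, config.beads_per_segment, n_contacts,
        box_side=state.box_side,
        segment_width=config.beads_per_segment * config.bp_per_bead,
    )
    cio.write_map_dense(out / "contact_map.txt", cmap)
    cio.write_map_triplets(out / "contact_map_triplets.tsv", cmap)
    part = segment(cmap, config.n_domains)
    cio.write_partition_bed(
        out / "domains.bed", part, config.beads_per_segment * config.bp_per_bead
    )

    # --- stage 6: reference comparison ------------------------------------
    ref_design = ReferenceMapDesign(
        n_segments=n_seg,
        domain_boundaries=list(
            np.linspace(0, n_seg, config.n_domains + 1, dtype=int)[1:-1]
        ),
        p_in=0.8, p_out=0.05,
        seed=stream_seed(config.seed, "reference"),
    )
    ref_map = generate_reference_map(ref_design)
    ref_part = segment(ref_map, config.n_domains)
    overlap = partition_overlap(part, ref_part)
    pval = overlap_pvalue(
        part, ref_part, n_samples=200,
        seed=stream_seed(config.seed, "pvalue"),
    )

    summary = {
        "config": {k: v for k, v in asdict(config).items()
                   if k != "force_field"},
        "force_field": asdict(ff),
        "n_genes": network.n_genes,
        "n_edges": network.n_edges,
        "n_planted_pairs": len(truth),
        "final_Q_percent": report.q[-1] if report.q else None,
        "n_domains": part.n_domains,
        "overlap_vs_reference": overlap,
        "overlap_pvalue": pval,
    }
    cio.write_manifest(out / "manifest.json", summary)
    return summary
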