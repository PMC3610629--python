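"""Plain-text readers/writers: expression TSV, BED annotations, edge lists,
contact maps (dense and triplet), extended-XYZ conformations, and run
manifests.  Readers validate strictly and report the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import ContactMap, Partition
from .network import CoregNetwork, ExpressionMatrix
from .polymer import SystemState


class FormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def write_expression_tsv(path: str | Path, matrix: ExpressionMatrix) -> None:
    df = pd.DataFrame(
        matrix.intensities,
        index=matrix.gene_ids,
        columns=[f"exp{k}" for k in range(matrix.n_experiments)],
    )
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expression table has no experiment columns")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    vals = coerced.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise FormatError(
            f"{path}: non-numeric entry at data row {bad[0] + 1}, "
            f"column {bad[1] + 1}"
        )
    return ExpressionMatrix([str(g) for g in df.index], vals)


# ---------------------------------------------------------------------------
# BED annotation (0-based half-open)
# ---------------------------------------------------------------------------

def write_bed(
    path: str | Path,
    starts: np.ndarray,
    ends: np.ndarray,
    names: list[str],
    chrom: str = "chrS",
) -> None:
    with open(path, "w") as fh:
        for s, e, n in zip(starts, ends, names):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{n}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            if not 0 <= start < end:
                raise FormatError(
                    f"{path}:{lineno}: require 0 <= start < end "
                    f"(got {start}, {end})"
                )
            name = parts[3] if len(parts) > 3 else f"feature{lineno}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------

def write_edges_tsv(path: str | Path, network: CoregNetwork) -> None:
    network.to_frame().to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_i", "gene_j"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: edge table needs columns gene_i, gene_j")
    if "mi" not in df.columns:
        df["mi"] = np.nan
    return df[["gene_i", "gene_j", "mi"]]


def network_from_files(edges_path: str | Path, bed_path: str | Path) -> CoregNetwork:
    bed = read_bed(bed_path)
    edges = read_edges_tsv(edges_path)
    idx = {name: k for k, name in enumerate(bed["name"])}
    edge_list = []
    for lineno, row in enumerate(edges.itertuples(index=False), start=2):
        if row.gene_i not in idx or row.gene_j not in idx:
            raise FormatError(
                f"{edges_path}:{lineno}: edge references gene absent from BED"
            )
        edge_list.append((idx[row.gene_i], idx[row.gene_j], float(row.mi)))
    return CoregNetwork(
        list(bed["name"]),
        bed["start"].to_numpy(),
        bed["end"].to_numpy(),
        edge_list,
    )


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def write_map_dense(path: str | Path, cmap: ContactMap) -> None:
    np.savetxt(path, cmap.matrix, fmt="%d")


def write_map_triplets(path: str | Path, cmap: ContactMap) -> None:
    iu, ju = np.nonzero(np.triu(cmap.matrix, k=1))
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i, j in zip(iu, ju):
            fh.write(f"{i}\t{j}\t1\n")


def read_map_dense(
    path: str | Path, centromere: tuple[int, int] | None = None
) -> ContactMap:
    m = np.loadtxt(path)
    return ContactMap(matrix=m.astype(np.int8), centromere=centromere)


def read_map_triplets(
    path: str | Path,
    n_segments: int,
    centromere: tuple[int, int] | None = None,
) -> ContactMap:
    df = pd.read_csv(path, sep="\t")
    m = np.zeros((n_segments, n_segments), dtype=np.int8)
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        i, j = int(row.i), int(row.j)
        if not (0 <= i < n_segments and 0 <= j < n_segments):
            raise FormatError(f"{path}:{lineno}: segment index out of range")
        if row.value:
            m[i, j] = m[j, i] = 1
    return ContactMap(matrix=m, centromere=centromere)


def read_triplets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"i", "j", "value"} <= set(df.columns):
        raise FormatError(f"{path}: triplet file needs columns i, j, value")
    return df


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def write_partition_bed(
    path: str | Path, part: Partition, segment_width: int, chrom: str = "chrS"
) -> None:
    with open(path, "w") as fh:
        for d, (s, e) in enumerate(part.domain_intervals()):
            tag = "centromere" if d == part.centromere_domain else f"domain{d}"
            fh.write(
                f"{chrom}\t{s * segment_width}\t{e * segment_width}\t{tag}\n"
            )


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz(
    path: str | Path,
    state: SystemState,
    append: bool = False,
    comment: str | None = None,
) -> None:
    """One extended-XYZ frame: element column is the chain id."""
    mode = "a" if append else "w"
    cid = state.chain_id
    with open(path, mode) as fh:
        fh.write(f"{state.n_beads}\n")
        fh.write(
            comment
            or f"box={state.box_side:.6f} time={state.time:.6f} "
               f"chains={state.n_chains}"
        )
        fh.write("\n")
        for c, (x, y, z) in zip(cid, state.pos):
            fh.write(f"C{c}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_xyz(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """All frames as (positions, chain_id) tuples."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    k = 0
    while k < len(lines):
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise FormatError(f"{path}:{k + 1}: expected atom count") from exc
        body = lines[k + 2:k + 2 + n]
        if len(body) < n:
            raise FormatError(f"{path}:{k + 1}: truncated frame")
        pos = np.empty((n, 3))
        cid = np.empty(n, dtype=np.int64)
        for a, line in enumerate(body):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{k + 3 + a}: expected 4 columns")
            cid[a] = int(parts[0].lstrip("C"))
            pos[a] = [float(v) for v in parts[1:]]
        frames.append((pos, cid))
        k += 2 + n
    return frames


def state_from_xyz_frame(
    pos: np.ndarray, cid: np.ndarray, box_side: float
) -> SystemState:
    change = np.nonzero(np.diff(cid))[0] + 1
    starts = np.concatenate([[0], change, [len(cid)]])
    return SystemState(pos, starts, box_side)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
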