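"""Depth-based gene copy-number estimation and cytogenetic correction terms.

Copy number per haploid genome follows the normalised-depth identity

    copies_per_haploid = mean_depth * genome_size / library_bases

where ``library_bases`` is the total sequenced (mapped) bases of the library
and ``genome_size`` the haploid genome that library samples. For soma the
genome size is the assembly size; for germline the content of ``f`` GRCs is
added (``f`` = GRCs per haploid A-genome set), so that a single-copy gene
estimates ~1 in both tissues and a GRC-amplified gene estimates ~1 + f*c in
germline.

The cytogenetic quantities: ``f = 2G / (4G + 2S)`` from counts of tetraploid
germline cells (two GRCs each) and diploid somatic cells in a testis
preparation, and GRC physical size as the synaptonemal-complex length ratio
against chromosome 2 times the chromosome 2 assembly size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "estimate_copy_number",
    "grc_per_haploid",
    "grc_size",
    "germline_genome_size",
    "split_high_variance",
    "gene_copy_numbers",
]


def estimate_copy_number(mean_depth, library_bases: float, genome_size: float):
    """copies_per_haploid = depth * genome_size / library_bases (exact)."""
    if library_bases <= 0:
        raise ValueError("library size must be positive")
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return np.asarray(mean_depth, dtype=float) * genome_size / library_bases if np.ndim(mean_depth) else float(mean_depth) * genome_size / library_bases


def grc_per_haploid(n_germ_cells: int, n_soma_cells: int) -> float:
    """GRCs per haploid A-genome set from FISH-positive (germline, tetraploid
    with two GRCs) and FISH-negative (somatic, diploid) cell counts:
    f = 2G / (4G + 2S); bounded by 0.5 in the all-germline limit."""
    if n_germ_cells < 0 or n_soma_cells < 0:
        raise ValueError("cell counts must be non-negative")
    if n_germ_cells == 0 and n_soma_cells == 0:
        raise ValueError("at least one cell must be counted")
    return 2.0 * n_germ_cells / (4.0 * n_germ_cells + 2.0 * n_soma_cells)


def grc_size(sc_length_ratio: float, chr2_size_mb: float) -> float:
    """GRC size in Mb: synaptonemal GRC/chromosome-2 length ratio times the
    chromosome 2 assembly size (1.07 * 156.41 Mb = 167.4 Mb in zebra finch)."""
    return sc_length_ratio * chr2_size_mb


def germline_genome_size(assembly_size: float, f: float, grc_size_bp: float) -> float:
    """Effective germline genome size: assembly plus the content of f GRCs."""
    return assembly_size + f * grc_size_bp


def _best_split_threshold(depths: np.ndarray) -> float:
    """Exact 1-D 2-means: the depth threshold minimising within-class SSE."""
    x = np.sort(depths.astype(float))
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    best_sse, best_t = np.inf, x[0]
    for i in range(1, n):
        n1, n2 = i, n - i
        s1, s2 = csum[i - 1], csum[-1] - csum[i - 1]
        q1, q2 = csq[i - 1], csq[-1] - csq[i - 1]
        sse = (q1 - s1**2 / n1) + (q2 - s2**2 / n2)
        if sse < best_sse:
            best_sse = sse
            best_t = (x[i - 1] + x[i]) / 2.0
    return float(best_t)


def split_high_variance(
    depths: np.ndarray,
    cv_threshold: float = 0.5,
    min_run: int = 50,
) -> list[tuple[int, int, float]]:
    """Partition a transcript's per-position depth into contiguous segments.

    When the coefficient of variation exceeds ``cv_threshold``, positions are
    classified high/low by exact 1-D 2-means on depth and contiguous runs of
    the same class become segments (runs shorter than ``min_run`` bp are
    absorbed into their neighbour, suppressing single-position noise).
    Otherwise the transcript is a single segment. Returns
    ``[(start, end, mean_depth), ...]`` in transcript coordinates.
    """
    depths = np.asarray(depths, dtype=float)
    n = depths.size
    if n < 200:
        raise ValueError("transcript must be at least 200 bp")
    mean = depths.mean()
    if mean <= 0 or depths.std() / mean <= cv_threshold:
        return [(0, n, float(mean))]
    thr = _best_split_threshold(depths)
    labels = depths >= thr
    # contiguous runs, absorbing short ones
    bounds = [0] + list(np.nonzero(np.diff(labels))[0] + 1) + [n]
    runs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (e - s < min_run or labels[s] == labels[merged[-1][0]]):
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # a leading short run may still need absorbing into its successor
    if len(merged) > 1 and merged[0][1] - merged[0][0] < min_run:
        merged[1][0] = merged[0][0]
        merged.pop(0)
    return [(s, e, float(depths[s:e].mean())) for s, e in merged]


def gene_copy_numbers(
    pileup: dict[str, np.ndarray],
    annotation: pd.DataFrame,
    library_bases: float,
    genome_size: float,
    cv_threshold: float = 0.5,
    split: bool = False,
) -> pd.DataFrame:
    """Per-gene copy-number estimates from a pileup restricted to annotated
    gene intervals; optionally split high-variance genes into segments."""
    rows = []
    for _, g in annotation.iterrows():
        depths = pileup[g["chrom"]][int(g["start"]) : int(g["end"])].sum(axis=1)
        if split:
            segments = split_high_variance(depths, cv_threshold=cv_threshold)
        else:
            segments = [(0, len(depths), float(depths.mean()))]
        for s, e, mean_depth in segments:
            rows.append(
                (
                    g["gene_id"],
                    int(g["start"]) + s,
                    int(g["start"]) + e,
                    mean_depth,
                    estimate_copy_number(mean_depth, library_bases, genome_size),
                )
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "mean_depth", "copies_per_haploid"]
    )
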