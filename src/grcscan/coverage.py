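"""Coverage-ratio calling of GRC-amplified regions.

Germline reads from a germline-restricted chromosome (GRC) map onto the
single-copy A-chromosomal paralogs of the somatic reference, so GRC-amplified
regions show strongly germline-increased read depth. This module reproduces
the correction-and-filter cascade used to call such regions from windowed
depth of a germline and a soma library over the same reference:

1. mean depth per window (1 kb for plotting, 5 kb for calling);
2. library-depth normalisation — germline windows multiplied by the
   soma/germline total-coverage ratio;
3. removal of germline windows above mean + 2 SD from a linear fit of
   germline on soma depth; the fitted slope then corrects *all* germline
   windows down (removed windows stay callable — they are exactly the
   amplified ones);
4. log2(germline/soma) ratios, low-coverage (<5th percentile germline) and
   GC (outside 30–60%) filters, centring of the ratio distribution on 0, and
   an inclusive log2 >= 2 cut-off (>=4-fold germline excess);
5. merging adjacent called windows into blocks (>=10 kb blocks vs
   singletons) and a soma-excess negative control with tissue roles swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import seq_to_index

__all__ = [
    "window_depths",
    "depth_normalise",
    "remove_outliers_and_fit",
    "call_amplified",
    "intersect_genes",
    "scan_coverage",
    "CoverageResult",
]

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "gc",
    "depth_germ",
    "depth_soma",
    "outlier_removed",
    "low_coverage",
    "gc_fail",
    "log2_ratio",
    "amplified",
]


def window_depths(
    germ_pileup: dict[str, np.ndarray],
    soma_pileup: dict[str, np.ndarray],
    reference: dict[str, str],
    window_size: int = 5000,
) -> pd.DataFrame:
    """Tile each chromosome into fixed windows (terminal window truncated) and
    compute mean per-position depth per tissue plus reference GC content."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    frames = []
    for chrom, seq in reference.items():
        L = len(seq)
        if L == 0:
            continue
        starts = np.arange(0, L, window_size)
        ends = np.minimum(starts + window_size, L)
        lengths = (ends - starts).astype(float)
        dg = germ_pileup[chrom].sum(axis=1).astype(float)
        ds = soma_pileup[chrom].sum(axis=1).astype(float)
        idx = seq_to_index(seq)
        is_gc = ((idx == 1) | (idx == 2)).astype(float)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "gc": np.add.reduceat(is_gc, starts) / lengths,
                    "depth_germ": np.add.reduceat(dg, starts) / lengths,
                    "depth_soma": np.add.reduceat(ds, starts) / lengths,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    w = pd.concat(frames, ignore_index=True)
    for flag in ("outlier_removed", "low_coverage", "gc_fail", "amplified"):
        w[flag] = False
    w["log2_ratio"] = np.nan
    return w


def depth_normalise(windows: pd.DataFrame) -> pd.DataFrame:
    """Rescale germline window depths by the soma/germline total-depth ratio,
    removing the effect of unequal library sizes."""
    total_g = float(windows["depth_germ"].sum())
    total_s = float(windows["depth_soma"].sum())
    if total_g <= 0 or total_s <= 0:
        raise ValueError("both tissues must have nonzero total depth")
    out = windows.copy()
    out["depth_germ"] = out["depth_germ"] * (total_s / total_g)
    return out


def remove_outliers_and_fit(windows: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Exclude germline-depth outliers (> mean + 2 SD) from a zero-intercept
    OLS fit of germline on soma depth, then divide every germline window by
    the fitted slope.

    The excluded windows are flagged ``outlier_removed`` but remain eligible
    for calling: amplified windows are by construction the extreme ones.
    """
    if len(windows) < 100:
        raise ValueError("need at least 100 windows for a stable slope fit")
    out = windows.copy()
    g = out["depth_germ"].to_numpy()
    s = out["depth_soma"].to_numpy()
    cut = g.mean() + 2.0 * g.std()
    keep = g <= cut
    out["outlier_removed"] = ~keep
    denom = float((s[keep] ** 2).sum())
    if denom <= 0 or np.isclose(s[keep].std(), 0.0):
        raise ValueError("soma depth degenerate; slope undefined")
    slope = float((g[keep] * s[keep]).sum() / denom)
    if slope <= 0:
        raise ValueError("non-positive fitted slope; inputs degenerate")
    out["depth_germ"] = out["depth_germ"] / slope
    return out, slope


def _histogram_mode(values: np.ndarray, bin_width: float = 0.05) -> float:
    """Mode of a histogram with fixed bin width — the centring statistic.

    The mode of the log2-ratio distribution pins the 1:1 peak even when many
    windows are amplified, which would drag a mean or median upward.
    """
    v = values[np.isfinite(values)]
    if v.size == 0:
        return 0.0
    lo, hi = v.min(), v.max()
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(v, bins=nbins, range=(lo, lo + nbins * bin_width))
    best = int(np.argmax(counts))
    return float((edges[best] + edges[best + 1]) / 2.0)


@dataclass
class CoverageResult:
    """Windows with call states, merged amplified blocks, the negative-control
    count, and (when an annotation is supplied) the amplified gene list."""

    windows: pd.DataFrame
    blocks: pd.DataFrame
    n_soma_excess: int
    slope: float | None = None
    genes: list[str] = field(default_factory=list)


def _merge_blocks(called: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent called windows into blocks; >=10 kb spans are blocks,
    shorter runs singletons."""
    rows = []
    for chrom, grp in called.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        n = 0
        for _, r in grp.iterrows():
            if cur_end is not None and r["start"] == cur_end:
                cur_end = r["end"]
                n += 1
            else:
                if cur_start is not None:
                    rows.append((chrom, cur_start, cur_end, n))
                cur_start, cur_end, n = r["start"], r["end"], 1
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, n))
    blocks = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])
    blocks["is_block"] = (blocks["end"] - blocks["start"]) >= 10_000
    return blocks


def _directional_calls(
    w: pd.DataFrame,
    num: str,
    den: str,
    cutoff_log2: float,
    gc_bounds: tuple[float, float],
    low_pct: float,
) -> tuple[pd.Series, pd.Series, pd.Series, np.ndarray]:
    """One direction of the calling rule (numerator-tissue excess over
    denominator tissue). Returns (low_coverage, gc_fail, amplified, ratios)."""
    num_d = w[num].to_numpy(float)
    den_d = w[den].to_numpy(float)
    low_cut = np.percentile(num_d, low_pct)
    low = (num_d < low_cut) | (den_d <= 0)
    gc_fail = (w["gc"] < gc_bounds[0]) | (w["gc"] > gc_bounds[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(num_d / den_d)
    ratio[~np.isfinite(ratio)] = np.nan
    centre = _histogram_mode(ratio[~low])
    ratio = ratio - centre
    amplified = pd.Series(
        (ratio >= cutoff_log2) & ~low & ~gc_fail.to_numpy() & np.isfinite(ratio),
        index=w.index,
    )
    return pd.Series(low, index=w.index), gc_fail, amplified, ratio


def call_amplified(
    windows: pd.DataFrame,
    cutoff_log2: float = 2.0,
    gc_bounds: tuple[float, float] = (0.30, 0.60),
    low_pct: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Call germline-amplified windows from normalised, slope-corrected depths.

    Windows below the ``low_pct`` germline-depth percentile (or with zero soma
    depth) and windows with GC outside ``gc_bounds`` are never called. The
    log2 ratio distribution is centred on its histogram mode (bin width 0.05)
    before the inclusive ``log2 >= cutoff_log2`` threshold. Adjacent calls are
    merged into blocks. The returned ``n_soma_excess`` is the symmetric
    negative control: the same rule applied with tissue roles swapped.
    """
    w = windows.copy()
    low, gc_fail, amplified, ratio = _directional_calls(
        w, "depth_germ", "depth_soma", cutoff_log2, gc_bounds, low_pct
    )
    w["low_coverage"] = low
    w["gc_fail"] = gc_fail
    w["log2_ratio"] = ratio
    w["amplified"] = amplified
    _, _, soma_amp, _ = _directional_calls(
        w, "depth_soma", "depth_germ", cutoff_log2, gc_bounds, low_pct
    )
    blocks = _merge_blocks(w[w["amplified"]])
    return w, blocks, int(soma_amp.sum())


def intersect_genes(called: pd.DataFrame, annotation: pd.DataFrame) -> list[str]:
    """Genes whose annotated interval overlaps any called window/block
    (half-open intervals; abutting does not overlap). Each gene once, in
    annotation order."""
    hits: list[str] = []
    if called.empty or annotation.empty:
        return hits
    for _, gene in annotation.iterrows():
        sub = called[called["chrom"] == gene["chrom"]]
        if ((sub["start"] < gene["end"]) & (sub["end"] > gene["start"])).any():
            hits.append(gene["gene_id"])
    return hits


def scan_coverage(
    germ_pileup: dict[str, np.ndarray],
    soma_pileup: dict[str, np.ndarray],
    reference: dict[str, str],
    annotation: pd.DataFrame | None = None,
    window_size: int = 5000,
    cutoff_log2: float = 2.0,
    gc_bounds: tuple[float, float] = (0.30, 0.60),
    low_pct: float = 5.0,
) -> CoverageResult:
    """End-to-end coverage scan: window, normalise, outlier-correct, call,
    merge blocks, intersect with the gene annotation."""
    w = window_depths(germ_pileup, soma_pileup, reference, window_size)
    w = depth_normalise(w)
    w, slope = remove_outliers_and_fit(w)
    w, blocks, n_soma_excess = call_amplified(w, cutoff_log2, gc_bounds, low_pct)
    genes: list[str] = []
    if annotation is not None:
        genes = intersect_genes(w[w["amplified"]], annotation)
    return CoverageResult(
        windows=w, blocks=blocks, n_soma_excess=n_soma_excess, slope=slope, genes=genes
    )
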