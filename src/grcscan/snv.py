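"""Germline-specific SNV calling against paired soma pileups.

A GRC-linked paralog diverges from its single-copy A-chromosomal locus, so
germline reads carry substitution alleles that are entirely absent from soma
reads of the same individual. A site is called germline-specific when an
alternate base has at least ``min_germ`` supporting germline reads, zero
supporting soma reads, and the soma is adequately covered there (absence of
evidence is not evidence of absence). Swapping the tissue roles yields the
negative control, which on real data returned zero soma-specific SNVs.

Per-gene tallies feed the high-confidence rule: a gene is high-confidence if
it carries at least five germline-specific SNVs (intersected across all
germline samples) or lies in a coverage-amplified region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import BASES, BASE_INDEX, seq_to_index

__all__ = [
    "call_specific_snvs",
    "negative_control",
    "intersect_samples",
    "summarise_genes",
    "build_consensus",
    "verify_transcription",
]

CALL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "germ_alt_reads",
    "germ_depth",
    "soma_alt_reads",
    "soma_depth",
]


def call_specific_snvs(
    germ_pileup: dict[str, np.ndarray],
    soma_pileup: dict[str, np.ndarray],
    reference: dict[str, str],
    min_germ: int = 10,
    min_soma_depth: int = 10,
    count_mode: str = "allele",
) -> pd.DataFrame:
    """Call single-base substitutions private to the germline.

    ``count_mode`` selects how the >=``min_germ`` germline threshold is read:
    ``"allele"`` (default) requires that many reads supporting the alternate
    base; ``"site"`` requires that much total germline depth plus at least one
    alternate read. Multi-allelic sites yield one call per (locus, alt).
    Soma sites with depth below ``min_soma_depth`` are skipped.
    """
    if count_mode not in ("allele", "site"):
        raise ValueError("count_mode must be 'allele' or 'site'")
    rows = []
    for chrom, seq in reference.items():
        germ = germ_pileup[chrom]
        soma = soma_pileup[chrom]
        ridx = seq_to_index(seq)
        germ_depth = germ.sum(axis=1)
        soma_depth = soma.sum(axis=1)
        for b in range(4):
            if count_mode == "allele":
                enough = germ[:, b] >= min_germ
            else:
                enough = (germ_depth >= min_germ) & (germ[:, b] > 0)
            mask = enough & (soma[:, b] == 0) & (soma_depth >= min_soma_depth) & (ridx != b)
            for p in np.nonzero(mask)[0]:
                rows.append(
                    (
                        chrom,
                        int(p),
                        BASES[ridx[p]],
                        BASES[b],
                        int(germ[p, b]),
                        int(germ_depth[p]),
                        int(soma[p, b]),
                        int(soma_depth[p]),
                    )
                )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom", "pos", "alt"]).reset_index(drop=True)


def negative_control(
    germ_pileup: dict[str, np.ndarray],
    soma_pileup: dict[str, np.ndarray],
    reference: dict[str, str],
    **kwargs,
) -> int:
    """Count soma-specific SNVs: the identical rule with tissues swapped."""
    swapped = call_specific_snvs(soma_pileup, germ_pileup, reference, **kwargs)
    return len(swapped)


def intersect_samples(per_sample_calls: list[pd.DataFrame]) -> pd.DataFrame:
    """Keep calls whose (chrom, pos, alt) is called in every germline sample.

    Read counts reported for the surviving calls come from the first sample.
    A single-sample input is returned unchanged.
    """
    if not per_sample_calls:
        raise ValueError("need at least one sample")
    first = per_sample_calls[0]
    if len(per_sample_calls) == 1:
        return first.reset_index(drop=True)
    key = ["chrom", "pos", "alt"]
    shared = set(map(tuple, first[key].itertuples(index=False)))
    for other in per_sample_calls[1:]:
        shared &= set(map(tuple, other[key].itertuples(index=False)))
    mask = first[key].apply(tuple, axis=1).isin(shared)
    return first[mask].reset_index(drop=True)


def _assign_genes(calls: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Gene id per call (NaN when the site is intergenic)."""
    gene = pd.Series(pd.NA, index=calls.index, dtype="object")
    for _, g in annotation.iterrows():
        mask = (
            (calls["chrom"] == g["chrom"])
            & (calls["pos"] >= g["start"])
            & (calls["pos"] < g["end"])
        )
        gene[mask] = g["gene_id"]
    return gene


def summarise_genes(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    amplified_genes: set[str] | list[str] = (),
    min_snvs: int = 5,
) -> pd.DataFrame:
    """Per-gene germline-specific SNV counts and the high-confidence flag.

    ``high_confidence`` is the union rule: at least ``min_snvs`` intersected
    germline-specific SNVs, or membership in the coverage-amplified gene set.
    """
    amplified = set(amplified_genes)
    if calls.empty:
        n = pd.Series(0, index=annotation["gene_id"])
    else:
        gene = _assign_genes(calls, annotation)
        n = gene.dropna().value_counts().reindex(annotation["gene_id"], fill_value=0)
    out = pd.DataFrame(
        {
            "gene_id": annotation["gene_id"].to_numpy(),
            "n_specific_snvs": n.to_numpy(),
        }
    )
    out["amplified"] = out["gene_id"].isin(amplified)
    out["high_confidence"] = (out["n_specific_snvs"] >= min_snvs) | out["amplified"]
    return out


def build_consensus(
    calls: pd.DataFrame,
    reference: dict[str, str],
    annotation: pd.DataFrame,
) -> dict[str, tuple[str, str]]:
    """Per-gene somatic ('ref') and germline-specific ('alt') consensus pair.

    The alt consensus is the reference gene sequence with every called
    alternate base substituted; lengths are always equal (substitutions only).
    """
    gene = _assign_genes(calls, annotation) if not calls.empty else pd.Series(dtype="object")
    out: dict[str, tuple[str, str]] = {}
    for _, g in annotation.iterrows():
        ref_seq = reference[g["chrom"]][g["start"] : g["end"]]
        alt = list(ref_seq)
        if not calls.empty:
            for _, call in calls[gene == g["gene_id"]].iterrows():
                alt[int(call["pos"]) - int(g["start"])] = call["alt"]
        out[g["gene_id"]] = (ref_seq, "".join(alt))
    return out


def verify_transcription(
    calls: pd.DataFrame,
    rna_pileup: dict[str, np.ndarray],
    annotation: pd.DataFrame,
    min_reads: int = 100,
    min_ratio: float = 0.01,
) -> pd.DataFrame:
    """Check which germline-specific SNVs are supported by RNA reads.

    A call is transcription-supported when RNA depth at the site is at least
    ``min_reads`` and the alt/ref read ratio strictly exceeds ``min_ratio``
    (the >1% rule). Sites below ``min_reads`` are not evaluated. A gene is
    flagged expressed when any of its specific SNVs is supported.
    """
    supported = []
    for _, call in calls.iterrows():
        col = rna_pileup[call["chrom"]][int(call["pos"])]
        depth = int(col.sum())
        if depth < min_reads:
            supported.append(False)
            continue
        ref_n = int(col[BASE_INDEX[call["ref"]]])
        alt_n = int(col[BASE_INDEX[call["alt"]]])
        supported.append(ref_n > 0 and alt_n / ref_n > min_ratio)
    calls = calls.copy()
    calls["rna_supported"] = supported if len(calls) else pd.Series(dtype=bool)
    gene = _assign_genes(calls, annotation) if not calls.empty else pd.Series(dtype="object")
    rows = []
    for _, g in annotation.iterrows():
        mask = gene == g["gene_id"] if not calls.empty else pd.Series(dtype=bool)
        any_sup = bool(calls.loc[mask, "rna_supported"].any()) if not calls.empty else False
        rows.append((g["gene_id"], any_sup))
    return pd.DataFrame(rows, columns=["gene_id", "expressed"])
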