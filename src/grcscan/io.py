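"""Readers and writers for the on-disk formats of the pipeline.

Dialects are strict and documented: BED is 0-based half-open; pileups are
TSV with columns (chrom, pos0, ref, A, C, G, T) — one file per tissue; SNV
calls round-trip through minimal VCF 4.2 with per-tissue allele depths in
INFO; trees are Newick with internal support labels; truth and reports are
JSON. Malformed records raise line-numbered parse errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import BASES, BASE_INDEX

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_pileup",
    "write_pileup",
    "read_vcf",
    "write_vcf",
    "write_consensus_fasta",
    "read_expression_table",
    "write_truth",
    "ParseError",
]


class ParseError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    """BED4 (or BED5 with score): chrom, start, end, name[, score]."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, i, "BED needs at least 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, i, "non-integer BED coordinates") from None
            name = parts[3] if len(parts) > 3 else f"feature{i}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def write_bed(df: pd.DataFrame, path, score: str | None = None) -> None:
    """Write chrom/start/end(/name/score) columns as BED; ``score`` names an
    optional numeric column (e.g. the log2 ratio of a window)."""
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fields = [str(r["chrom"]), str(int(r["start"])), str(int(r["end"]))]
            if "gene_id" in df.columns:
                fields.append(str(r["gene_id"]))
            elif score is not None:
                fields.append(".")
            if score is not None:
                fields.append(f"{r[score]:.4f}" if np.isfinite(r[score]) else ".")
            fh.write("\t".join(fields) + "\n")


PILEUP_HEADER = ["chrom", "pos", "ref", "A", "C", "G", "T"]


def write_pileup(pileup: dict[str, np.ndarray], reference: dict[str, str], path) -> None:
    """Pileup TSV: one row per position with per-base read counts."""
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_HEADER) + "\n")
        for chrom, counts in pileup.items():
            seq = reference[chrom]
            for p in range(counts.shape[0]):
                fh.write(
                    f"{chrom}\t{p}\t{seq[p]}\t"
                    + "\t".join(str(int(x)) for x in counts[p])
                    + "\n"
                )


def read_pileup(path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Read a pileup TSV back into count matrices plus the reference bases."""
    counts: dict[str, list] = {}
    refs: dict[str, list] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PILEUP_HEADER:
            raise ParseError(path, 1, f"unexpected pileup header {header}")
        for i, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ParseError(path, i, "pileup rows need 7 columns")
            chrom, pos, ref = parts[0], int(parts[1]), parts[2]
            counts.setdefault(chrom, []).append([int(x) for x in parts[3:]])
            refs.setdefault(chrom, []).append(ref)
            if pos != len(counts[chrom]) - 1:
                raise ParseError(path, i, f"non-contiguous position {pos}")
    return (
        {c: np.array(v, dtype=np.int32) for c, v in counts.items()},
        {c: "".join(v) for c, v in refs.items()},
    )


VCF_HEADER = """##fileformat=VCFv4.2
##source=grcscan
##INFO=<ID=GAD,Number=1,Type=Integer,Description="Germline alt-supporting read depth">
##INFO=<ID=GDP,Number=1,Type=Integer,Description="Germline total depth">
##INFO=<ID=SAD,Number=1,Type=Integer,Description="Soma alt-supporting read depth">
##INFO=<ID=SDP,Number=1,Type=Integer,Description="Soma total depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: pd.DataFrame, path, contigs: dict[str, int] | None = None) -> None:
    """One VCF record per germline-specific SNV call (positions become
    1-based on disk)."""
    with open(path, "w") as fh:
        if contigs:
            fh.write("##fileformat=VCFv4.2\n##source=grcscan\n")
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write(VCF_HEADER.split("\n", 2)[2])
        else:
            fh.write(VCF_HEADER)
        for _, c in calls.iterrows():
            info = (
                f"GAD={int(c['germ_alt_reads'])};GDP={int(c['germ_depth'])};"
                f"SAD={int(c['soma_alt_reads'])};SDP={int(c['soma_depth'])}"
            )
            fh.write(
                f"{c['chrom']}\t{int(c['pos']) + 1}\t.\t{c['ref']}\t{c['alt']}\t.\tPASS\t{info}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read grcscan VCF output back to the internal 0-based call table."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ParseError(path, i, "VCF records need 8 columns")
            info = dict(kv.split("=") for kv in parts[7].split(";") if "=" in kv)
            try:
                rows.append(
                    (
                        parts[0],
                        int(parts[1]) - 1,
                        parts[3],
                        parts[4],
                        int(info["GAD"]),
                        int(info["GDP"]),
                        int(info["SAD"]),
                        int(info["SDP"]),
                    )
                )
            except (KeyError, ValueError):
                raise ParseError(path, i, "missing or malformed GAD/GDP/SAD/SDP INFO") from None
    from .snv import CALL_COLUMNS

    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_consensus_fasta(consensus: dict[str, tuple[str, str]], path) -> None:
    """Paired '>gene_ref' / '>gene_alt' records per gene."""
    records = []
    for gene_id, (ref_seq, alt_seq) in consensus.items():
        records.append(SeqRecord(Seq(ref_seq), id=f"{gene_id}_ref", description=""))
        records.append(SeqRecord(Seq(alt_seq), id=f"{gene_id}_alt", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_expression_table(path) -> pd.DataFrame:
    """Gene-by-tissue TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth(dataset, outdir) -> None:
    """Serialise the simulator's ground truth as TSV + JSON next to the data."""
    outdir = Path(outdir)
    dataset.truth_snvs.to_csv(outdir / "truth_snvs.tsv", sep="\t", index=False)
    truth = {
        "grc_fraction": dataset.grc.grc_fraction,
        "grc_size_mb": dataset.grc.grc_size_mb,
        "genes": [
            {"gene_id": g.gene_id, "copies": g.copies, "divergence_rate": g.divergence_rate}
            for g in dataset.grc.genes
        ],
        "depth_soma": dataset.depth_soma,
        "error_rate": dataset.error_rate,
        "seed": dataset.seed,
        "library_bases": dataset.library_bases,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
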