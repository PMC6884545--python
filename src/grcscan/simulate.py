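"""Synthetic paired germline/soma datasets emulating a germline-restricted chromosome.

A germline-restricted chromosome (GRC) carries paralogs of single-copy
A-chromosomal genes, present only in germline cells. When germline reads are
mapped onto the somatic reference, a GRC paralog with ``c`` copies per GRC and
``f`` GRCs per haploid A-genome set piles onto its single-copy A locus, so the
expected germline/soma depth ratio over that gene is ``1 + f*c`` and GRC-private
divergence alleles appear at fraction ``f*c / (1 + f*c)`` of germline depth
while being entirely absent from soma.

The generator emits alignments directly as per-position pileup columns (one
A/C/G/T count matrix per tissue), bypassing a read aligner: GRC-derived reads
map to their A-paralog locus by construction. Per-position depths are Poisson;
divergence sites are uniform within gene bodies; sequencing errors are uniform
over the three non-reference bases. Everything is deterministic for a fixed
seed, and a machine-readable truth table accompanies every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "GrcGene",
    "GrcModel",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_pileups",
    "simulate_rna_pileups",
    "simulate_expression_table",
    "simulate_gene_tree",
    "seq_to_index",
    "DEFAULT_TISSUES",
]

DEFAULT_TISSUES = ("brain", "heart", "kidney", "liver", "testis", "ovary")


def seq_to_index(seq: str) -> np.ndarray:
    """Map an ACGT string to an int8 array of base indices (A=0..T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return out


@dataclass(frozen=True)
class GrcGene:
    """One GRC-amplified gene: ``copies`` paralogs per GRC, each diverged at
    ``divergence_rate`` substitutions/site from the A-chromosomal locus."""

    gene_id: str
    copies: int
    divergence_rate: float

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"{self.gene_id}: copies must be >= 1")
        if not 0.0 <= self.divergence_rate < 0.2:
            raise ValueError(f"{self.gene_id}: divergence_rate must be in [0, 0.2)")


@dataclass(frozen=True)
class GrcModel:
    """Parameterisation of a germline-restricted chromosome.

    Parameters
    ----------
    grc_fraction
        GRCs per haploid A-genome set (``f``); 0.364 in the zebra finch,
        derived from tetraploid germline cells carrying two GRCs mixed with
        diploid somatic cells in testis preparations.
    genes
        GRC-linked genes with per-gene copy number (up to several hundred
        copies of a single gene are observed in nature) and divergence rate.
    grc_size_mb
        Physical GRC size in Mb (167.3 Mb in the zebra finch); used only for
        genome-size corrections, not by the pileup generator.
    """

    grc_fraction: float
    genes: tuple[GrcGene, ...] = ()
    grc_size_mb: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.grc_fraction <= 0.5:
            raise ValueError("grc_fraction must lie in [0, 0.5]")
        object.__setattr__(self, "genes", tuple(self.genes))

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}

    def gene(self, gene_id: str) -> GrcGene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def validate_against(self, annotation: pd.DataFrame) -> None:
        """Every GRC gene must reference an annotated gene."""
        known = set(annotation["gene_id"])
        missing = self.gene_ids - known
        if missing:
            raise ValueError(f"GRC genes absent from annotation: {sorted(missing)}")


@dataclass
class SimulatedDataset:
    """A paired germline/soma pileup dataset with full ground truth.

    ``soma_pileup`` / ``germline_pileup`` map chromosome name to an (L, 4)
    count matrix in A,C,G,T order. ``truth_snvs`` lists every GRC divergence
    site (chrom, pos, ref, alt, gene_id, copies). The soma pileup carries no
    GRC-derived alleles; germline depth over a GRC gene has expectation
    ``depth_soma * (1 + f*c)`` before any normalisation.
    """

    reference: dict[str, str]
    annotation: pd.DataFrame
    soma_pileup: dict[str, np.ndarray]
    germline_pileup: dict[str, np.ndarray]
    library_bases: dict[str, int]
    grc: GrcModel
    truth_snvs: pd.DataFrame
    depth_soma: float
    error_rate: float
    seed: int

    @property
    def assembly_size(self) -> int:
        return sum(len(s) for s in self.reference.values())

    def grc_content_bp(self) -> float:
        """Per-GRC base content of the simulated GRC: sum of c * gene length.

        ``assembly_size + f * grc_content_bp()`` is the effective germline
        genome size that makes the depth-based copy-number formula exact on
        simulated data.
        """
        lengths = self.annotation.set_index("gene_id")
        total = 0.0
        for g in self.grc.genes:
            row = lengths.loc[g.gene_id]
            total += g.copies * (int(row["end"]) - int(row["start"]))
        return total

    def germline_genome_size(self) -> float:
        return self.assembly_size + self.grc.grc_fraction * self.grc_content_bp()


def _gc_at(gc_profile, length: int) -> np.ndarray:
    """Per-position target GC fraction: constant, or linear gradient (lo, hi)."""
    if np.isscalar(gc_profile):
        gc = np.full(length, float(gc_profile))
    else:
        lo, hi = gc_profile
        gc = np.linspace(float(lo), float(hi), length)
    if gc.min() < 0 or gc.max() > 1:
        raise ValueError("GC profile must lie in [0, 1]")
    return gc


def simulate_genome(
    n_chrom: int,
    chrom_len: int,
    n_genes: int,
    gc_profile=0.45,
    seed: int = 0,
    gene_length: int = 6000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a reference genome and a non-overlapping gene annotation.

    Genes are spread evenly over chromosomes with random jitter inside their
    allotted slots, so they never overlap. ``gc_profile`` is either a constant
    GC fraction or a ``(lo, hi)`` gradient along each chromosome, letting the
    downstream GC window filter be exercised.

    Returns ``(reference, annotation)`` with BED-style 0-based half-open gene
    intervals. Byte-identical across runs for a fixed seed.
    """
    if chrom_len < 50_000:
        raise ValueError("chrom_len must be >= 50 kb")
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    records = []
    # distribute genes round-robin across chromosomes
    genes_per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    gene_no = 0
    base_arr = np.array(list(BASES))
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        gc = _gc_at(gc_profile, chrom_len)
        is_gc = rng.random(chrom_len) < gc
        strong = rng.integers(0, 2, chrom_len)  # G vs C, A vs T
        idx = np.where(is_gc, np.where(strong == 0, 1, 2), np.where(strong == 0, 0, 3))
        reference[chrom] = "".join(base_arr[idx])
        ng = genes_per_chrom[ci]
        if ng == 0:
            continue
        slot = chrom_len // ng
        if slot <= gene_length:
            raise ValueError(
                f"{ng} genes of {gene_length} bp do not fit on a {chrom_len} bp chromosome"
            )
        # jitter within half the slot slack so consecutive genes always keep
        # an inter-gene gap of at least (slot - gene_length) / 2
        for gi in range(ng):
            jitter = int(rng.integers(0, max(1, (slot - gene_length) // 2)))
            start = gi * slot + jitter
            gene_no += 1
            records.append((chrom, start, start + gene_length, f"gene{gene_no:04d}"))
    annotation = pd.DataFrame(records, columns=["chrom", "start", "end", "gene_id"])
    return reference, annotation


def _apply_errors(counts: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """Mutate ``counts`` in place: each read base errs with ``error_rate``,
    landing uniformly on one of the three other bases."""
    if error_rate <= 0:
        return
    for src in range(4):
        n_err = rng.binomial(counts[:, src], error_rate)
        if n_err.sum() == 0:
            continue
        counts[:, src] -= n_err
        targets = [b for b in range(4) if b != src]
        split = rng.multinomial(n_err, [1 / 3] * 3)
        for j, tgt in enumerate(targets):
            counts[:, tgt] += split[:, j]


def simulate_pileups(
    reference: dict[str, str],
    annotation: pd.DataFrame,
    grc: GrcModel,
    depth_soma: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
    germ_depth_factor: float = 1.0,
    depth_variation_cv: float = 0.1,
    depth_variation_segment: int = 200,
) -> SimulatedDataset:
    """Simulate paired germline and soma pileups over a shared reference.

    Soma depth is Poisson(``depth_soma``) everywhere. Germline depth is
    Poisson(``depth_soma * germ_depth_factor``) outside GRC genes and
    Poisson(``depth_soma * germ_depth_factor * (1 + f*c)``) inside a GRC gene
    with copy number ``c`` — the extra mass being GRC-derived reads, a
    binomial fraction ``f*c/(1+f*c)`` of each germline column. Divergence
    sites (binomially many at the gene's divergence rate, uniform within the
    gene body) carry the GRC reads on a single alternate base.

    ``germ_depth_factor`` models unequal library depth between tissues, which
    the coverage module's normalisation must absorb. A smooth positional
    depth modulation shared by both tissues (lognormal with coefficient of
    variation ``depth_variation_cv`` per ``depth_variation_segment`` bp,
    unit mean) emulates the GC/mappability structure of real libraries: it
    makes germline and soma window depths tightly correlated while cancelling
    out of the germline/soma ratio.
    """
    if depth_soma <= 0:
        raise ValueError("depth_soma must be positive")
    if not 0 <= error_rate < 0.01:
        raise ValueError("error_rate must be in [0, 0.01)")
    grc.validate_against(annotation)
    rng = np.random.default_rng(seed)
    f = grc.grc_fraction
    ann_by_gene = annotation.set_index("gene_id")

    soma_pileup: dict[str, np.ndarray] = {}
    germ_pileup: dict[str, np.ndarray] = {}
    truth_rows = []

    ref_idx = {chrom: seq_to_index(seq) for chrom, seq in reference.items()}
    for chrom, seq in reference.items():
        L = len(seq)
        ridx = ref_idx[chrom]
        pos = np.arange(L)

        if depth_variation_cv > 0:
            sigma = np.sqrt(np.log1p(depth_variation_cv**2))
            n_seg = -(-L // depth_variation_segment)
            modulation = rng.lognormal(-(sigma**2) / 2.0, sigma, n_seg)
            modulation = np.repeat(modulation, depth_variation_segment)[:L]
        else:
            modulation = np.ones(L)

        sdepth = rng.poisson(depth_soma * modulation).astype(np.int32)
        soma = np.zeros((L, 4), dtype=np.int32)
        soma[pos, ridx] = sdepth

        germ_mean = depth_soma * germ_depth_factor * modulation
        gene_spans: list[tuple[GrcGene, int, int]] = []
        for g in grc.genes:
            row = ann_by_gene.loc[g.gene_id]
            if row["chrom"] != chrom:
                continue
            s, e = int(row["start"]), int(row["end"])
            germ_mean[s:e] *= 1.0 + f * g.copies
            gene_spans.append((g, s, e))

        gdepth = rng.poisson(germ_mean).astype(np.int32)
        germ = np.zeros((L, 4), dtype=np.int32)
        germ[pos, ridx] = gdepth

        for g, s, e in gene_spans:
            q = f * g.copies / (1.0 + f * g.copies)
            n_div = rng.binomial(e - s, g.divergence_rate)
            if n_div == 0:
                continue
            div_pos = np.sort(rng.choice(np.arange(s, e), size=n_div, replace=False))
            grc_reads = rng.binomial(gdepth[div_pos], q)
            alt_off = rng.integers(1, 4, size=n_div)  # 1..3 away from ref, mod 4
            alt_idx = (ridx[div_pos] + alt_off) % 4
            germ[div_pos, ridx[div_pos]] -= grc_reads
            germ[div_pos, alt_idx] += grc_reads
            for p, a, n in zip(div_pos, alt_idx, grc_reads):
                truth_rows.append(
                    (chrom, int(p), BASES[ridx[p]], BASES[a], g.gene_id, g.copies, int(n))
                )

        _apply_errors(soma, error_rate, rng)
        _apply_errors(germ, error_rate, rng)
        soma_pileup[chrom] = soma
        germ_pileup[chrom] = germ

    truth_snvs = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "gene_id", "copies", "grc_reads"],
    )
    library_bases = {
        "soma": int(sum(m.sum() for m in soma_pileup.values())),
        "germline": int(sum(m.sum() for m in germ_pileup.values())),
    }
    return SimulatedDataset(
        reference=reference,
        annotation=annotation,
        soma_pileup=soma_pileup,
        germline_pileup=germ_pileup,
        library_bases=library_bases,
        grc=grc,
        truth_snvs=truth_snvs,
        depth_soma=depth_soma,
        error_rate=error_rate,
        seed=seed,
    )


def simulate_rna_pileups(
    dataset: SimulatedDataset,
    expressed_genes: set[str] | None = None,
    depth: float = 200.0,
    alt_fraction: float | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """RNA pileups over gene bodies of expressed genes.

    Transcript depth is Poisson(``depth``) inside expressed genes and zero
    elsewhere. At truth divergence sites of expressed GRC genes, the GRC
    ('alt') transcript contributes ``alt_fraction`` of the reads (default:
    the DNA dosage fraction ``f*c/(1+f*c)`` of that gene).
    """
    rng = np.random.default_rng(seed)
    if expressed_genes is None:
        expressed_genes = set(dataset.annotation["gene_id"])
    f = dataset.grc.grc_fraction
    rna: dict[str, np.ndarray] = {}
    ref_idx = {c: seq_to_index(s) for c, s in dataset.reference.items()}
    for chrom, seq in dataset.reference.items():
        L = len(seq)
        counts = np.zeros((L, 4), dtype=np.int32)
        rna[chrom] = counts
    for _, row in dataset.annotation.iterrows():
        if row["gene_id"] not in expressed_genes:
            continue
        chrom, s, e = row["chrom"], int(row["start"]), int(row["end"])
        d = rng.poisson(depth, e - s).astype(np.int32)
        counts = rna[chrom]
        counts[np.arange(s, e), ref_idx[chrom][s:e]] = d
    for _, snv in dataset.truth_snvs.iterrows():
        if snv["gene_id"] not in expressed_genes:
            continue
        chrom, p = snv["chrom"], int(snv["pos"])
        if alt_fraction is None:
            c = dataset.grc.gene(snv["gene_id"]).copies
            q = f * c / (1.0 + f * c)
        else:
            q = alt_fraction
        counts = rna[chrom]
        ri, ai = BASE_INDEX[snv["ref"]], BASE_INDEX[snv["alt"]]
        n_alt = rng.binomial(counts[p, ri], q)
        counts[p, ri] -= n_alt
        counts[p, ai] += n_alt
    return rna


def simulate_expression_table(
    n_genes: int,
    tissue_probs: dict[str, float] | None = None,
    seed: int = 0,
    frac_unexpressed: float = 0.0,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
) -> pd.DataFrame:
    """A gene-by-tissue expression table with a designated argmax tissue.

    Each expressed gene draws its tissue-of-max from ``tissue_probs`` (uniform
    by default) and receives a strictly highest value there; a stated fraction
    of genes is unexpressed (all-zero rows) to exercise the background
    exclusion rule of the enrichment test.
    """
    rng = np.random.default_rng(seed)
    tissues = tuple(tissues)
    if tissue_probs is None:
        probs = np.full(len(tissues), 1.0 / len(tissues))
    else:
        probs = np.array([tissue_probs.get(t, 0.0) for t in tissues], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("tissue probabilities must sum to 1")
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    if n_genes == 0:
        return pd.DataFrame(columns=list(tissues))
    values = rng.uniform(0.0, 8.0, size=(n_genes, len(tissues)))
    max_tissue = rng.choice(len(tissues), size=n_genes, p=probs)
    values[np.arange(n_genes), max_tissue] = rng.uniform(10.0, 20.0, size=n_genes)
    unexpressed = rng.random(n_genes) < frac_unexpressed
    values[unexpressed] = 0.0
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=list(tissues))


# ---------------------------------------------------------------------------
# Gene trees


class _AltClade:
    """Marks the node where the GRC ('alt') lineage attaches; carries its
    bootstrap support."""

    def __init__(self, children, support):
        self.children = children
        self.support = support


def _estrildid_subtree():
    return (
        "Uraeginthus_granatina",
        (
            ("Lonchura_striata", "Lonchura_castaneothorax"),
            (
                "Stizoptera_bichenovii",
                (
                    "Poephila_acuticauda",
                    ("Taeniopygia_guttata_guttata", "Taeniopygia_guttata_castanotis"),
                ),
            ),
        ),
    )


def _leafset(node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    if isinstance(node, _AltClade):
        return frozenset().union(*(_leafset(c) for c in node.children))
    return frozenset().union(*(_leafset(c) for c in node))


_INSERTION_TARGETS = {
    5: frozenset(["Taeniopygia_guttata_castanotis"]),
    4: frozenset(["Taeniopygia_guttata_guttata", "Taeniopygia_guttata_castanotis"]),
    3: frozenset(
        [
            "Stizoptera_bichenovii",
            "Poephila_acuticauda",
            "Taeniopygia_guttata_guttata",
            "Taeniopygia_guttata_castanotis",
        ]
    ),
    2: _leafset(_estrildid_subtree()),
}


def _species_tree():
    return (
        "Corvus_cornix",
        (
            "Zonotrichia_albicollis",
            ("Geospiza_fortis", ("Serinus_canaria", _estrildid_subtree())),
        ),
    )


def _insert_alt(node, target: frozenset, alt_label: str, support: int):
    if _leafset(node) == target:
        return _AltClade((alt_label, node), support)
    if isinstance(node, str):
        return node
    return tuple(_insert_alt(c, target, alt_label, support) for c in node)


def _to_newick(node, rng: np.random.Generator) -> str:
    bl = rng.uniform(0.01, 0.1)
    if isinstance(node, str):
        return f"{node}:{bl:.4f}"
    if isinstance(node, _AltClade):
        inner = ",".join(_to_newick(c, rng) for c in node.children)
        return f"({inner}){node.support}:{bl:.4f}"
    inner = ",".join(_to_newick(c, rng) for c in node)
    return f"({inner})100:{bl:.4f}"


def simulate_gene_tree(
    insertion_branch: int,
    seed: int = 0,
    alt_support: int = 100,
    alt_label: str = "alt",
) -> str:
    """A rooted gene tree with one GRC ('alt') tip attached at the species-tree
    branch corresponding to the requested evolutionary stratum.

    ``insertion_branch`` 1..5 maps oldest to youngest: 1 attaches the alt
    lineage at the songbird stem (sister to all refs but the corvid root),
    2 at the estrildid stem, 3 within estrildids, 4 at the zebra finch
    species stem, 5 inside the Australian subspecies. ``alt_support`` sets
    the bootstrap label of the alt-attachment node; every other internal node
    is labelled 100. Returns Newick.
    """
    if insertion_branch not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown stratum index {insertion_branch!r}")
    rng = np.random.default_rng(seed)
    tree = _species_tree()
    if insertion_branch == 1:
        # sister to everything except the corvid outgroup
        target = _leafset(tree[1])
    else:
        target = _INSERTION_TARGETS[insertion_branch]
    tree = _insert_alt(tree, target, alt_label, alt_support)
    return f"({_to_newick(tree[0], rng)},{_to_newick(tree[1], rng)});"
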