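"""Cytogenetic estimators and depth-based copy-number recovery.

f (GRCs per haploid A-genome set) comes from counting tetraploid germline
cells (two GRCs each) against diploid somatic cells; GRC size from the
synaptonemal-complex length ratio against chromosome 2. Gene copy number per
haploid genome is depth * genome_size / library_bases.
"""

from grcscan import copynum, simulate
from grcscan.simulate import GrcGene, GrcModel

f = copynum.grc_per_haploid(n_germ_cells=67, n_soma_cells=50)
size_mb = copynum.grc_size(sc_length_ratio=1.07, chr2_size_mb=156.41)
print(f"f = GRCs per haploid set:  {f:.3f}")
print(f"GRC size:                  {size_mb:.1f} Mb")
print(f"germline genome size:      {copynum.germline_genome_size(1223.0, f, size_mb):.1f} Mb"
      " (assembly 1223 Mb + f GRCs)")

reference, annotation = simulate.simulate_genome(1, 260_000, 4, seed=5, gene_length=12_000)
copies = (2, 8, 50, 308)
genes = tuple(GrcGene(g, c, 0.0) for g, c in zip(annotation["gene_id"], copies))
ds = simulate.simulate_pileups(reference, annotation, GrcModel(0.364, genes),
                               depth_soma=20.0, seed=6)
table = copynum.gene_copy_numbers(
    ds.germline_pileup, ds.annotation, ds.library_bases["germline"],
    ds.germline_genome_size(),
).set_index("gene_id")
for g in genes:
    est = table.loc[g.gene_id, "copies_per_haploid"]
    print(f"{g.gene_id}: c={g.copies:>3} -> estimated {est:7.2f} copies/haploid "
          f"(expected 1 + f*c = {1 + 0.364 * g.copies:.2f})")
# The estimate includes the single A-chromosomal copy, hence 1 + f*c.
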