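"""Evolutionary stratum assignment from gene trees.

Genes copied from A chromosomes onto the GRC on the same branch of the
species phylogeny form an evolutionary stratum: the GRC ('alt') consensus
diverges from its A-chromosomal ('ref') paralog at that branch, so the set of
species that fall *inside* the smallest clade containing both the alt lineage
and the focal species' ref tip dates the copy event. With the sampled
songbird ladder this yields five strata, oldest to youngest:

  S1  songbird stem (alt outside the non-estrildid oscines)
  S2  estrildid-finch stem (alt diverges before all sampled estrildids)
  S3  within estrildid finches (a proper subset of estrildids)
  S4  zebra finch species stem (both subspecies inside)
  S5  Australian zebra finch subspecies only

Assignment is purely topological (branch lengths never matter). Trees whose
alt lineage is non-monophyletic, or whose alt-attachment node has bootstrap
support below 50, are returned unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import yaml

__all__ = [
    "SpeciesLadder",
    "StratumAssignment",
    "DEFAULT_LADDER",
    "root_tree",
    "assign_stratum",
    "assign_strata",
]


@dataclass(frozen=True)
class SpeciesLadder:
    """Strictly nested species clades, innermost (youngest stratum) first.

    ``strata`` maps stratum index to the species *added* at that level going
    outward; cumulative unions give the candidate divergence sets. A level
    may add no species (the estrildid stem S2 shares its species set with S3:
    a complete estrildid divergence set means S2, a proper subset S3).
    """

    focal: str
    outgroup: str
    strata: tuple[tuple[int, tuple[str, ...]], ...]

    def cumulative(self) -> list[tuple[int, frozenset]]:
        """(stratum, cumulative species set) innermost-first."""
        acc: set[str] = set()
        out = []
        for stratum, adds in self.strata:
            acc |= set(adds)
            out.append((stratum, frozenset(acc)))
        return out

    @property
    def all_species(self) -> frozenset:
        return self.cumulative()[-1][1] | {self.outgroup}

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesLadder":
        strata = tuple(
            (int(level["stratum"]), tuple(level.get("adds", ()))) for level in d["strata"]
        )
        return cls(focal=d["focal"], outgroup=d["outgroup"], strata=strata)

    @classmethod
    def from_yaml(cls, path) -> "SpeciesLadder":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "outgroup": self.outgroup,
            "strata": [{"stratum": s, "adds": list(a)} for s, a in self.strata],
        }


DEFAULT_LADDER = SpeciesLadder(
    focal="Taeniopygia_guttata_castanotis",
    outgroup="Corvus_cornix",
    strata=(
        (5, ("Taeniopygia_guttata_castanotis",)),
        (4, ("Taeniopygia_guttata_guttata",)),
        (
            3,
            (
                "Poephila_acuticauda",
                "Stizoptera_bichenovii",
                "Lonchura_striata",
                "Lonchura_castaneothorax",
                "Uraeginthus_granatina",
            ),
        ),
        (2, ()),  # estrildid stem: same species set as S3, complete divergence set
        (1, ("Serinus_canaria", "Geospiza_fortis", "Zonotrichia_albicollis")),
    ),
)


@dataclass
class StratumAssignment:
    gene_id: str
    stratum: int | None
    divergence_set: frozenset = frozenset()
    bootstrap_ok: bool = True
    reason: str = ""


def _parse_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(
        data=tree, schema="newick", rooting="force-rooted", preserve_underscores=True
    )


def root_tree(tree, outgroup: str) -> dendropy.Tree:
    """Root (or re-root) a tree on the deepest sampled lineage, placing the
    named outgroup tip as sister to everything else."""
    t = _parse_tree(tree)
    node = t.find_node_with_taxon_label(outgroup) or t.find_node_with_taxon_label(
        outgroup.replace("_", " ")
    )
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    t.to_outgroup_position(node, update_bipartitions=True, suppress_unifurcations=True)
    return t


def _is_alt(label: str, alt_label: str) -> bool:
    return label == alt_label or label.endswith(f"_{alt_label}") or label.startswith(f"{alt_label}_")


def assign_stratum(
    tree,
    ladder: SpeciesLadder = DEFAULT_LADDER,
    gene_id: str = "",
    alt_label: str = "alt",
    min_support: float = 50.0,
) -> StratumAssignment:
    """Assign one rooted gene tree to an evolutionary stratum.

    The divergence set D is every ref species descended from the MRCA of the
    alt clade and the focal species' ref tip, alt tips excluded. The stratum
    is the innermost ladder level whose cumulative species set contains D,
    with the stem-vs-within rule: D equal to the complete estrildid set maps
    to the stem stratum (S2), a proper subset to the within stratum (S3).
    Non-monophyletic alt tips or alt-attachment bootstrap < ``min_support``
    give an unassigned result.
    """
    t = _parse_tree(tree)
    alt_nodes = [
        lf for lf in t.leaf_node_iter() if _is_alt(lf.taxon.label.replace(" ", "_"), alt_label)
    ]
    if not alt_nodes:
        raise ValueError("tree contains no alt tip")
    focal_node = t.find_node_with_taxon_label(ladder.focal) or t.find_node_with_taxon_label(
        ladder.focal.replace("_", " ")
    )
    if focal_node is None:
        raise ValueError(f"focal ref tip {ladder.focal!r} missing from tree")

    alt_taxa = [n.taxon for n in alt_nodes]
    if len(alt_nodes) == 1:
        alt_root = alt_nodes[0]
    else:
        alt_root = t.mrca(taxa=alt_taxa)
        under = [lf.taxon.label.replace(" ", "_") for lf in alt_root.leaf_iter()]
        if not all(_is_alt(l, alt_label) for l in under):
            return StratumAssignment(
                gene_id, None, reason="alt tips not monophyletic", bootstrap_ok=True
            )

    attach = alt_root.parent_node
    support = None
    if attach is not None and attach.label is not None:
        try:
            support = float(attach.label)
        except ValueError:
            support = None
    if support is not None and support < min_support:
        return StratumAssignment(
            gene_id, None, bootstrap_ok=False, reason=f"alt attachment support {support:g} < {min_support:g}"
        )

    mrca = t.mrca(taxa=alt_taxa + [focal_node.taxon])
    D = frozenset(
        lf.taxon.label.replace(" ", "_")
        for lf in mrca.leaf_iter()
        if not _is_alt(lf.taxon.label.replace(" ", "_"), alt_label)
    )
    levels = ladder.cumulative()
    stratum = None
    for s, cum in levels:
        if D <= cum:
            stratum = s
            if D == cum:
                # stem rule: a complete divergence set at this level belongs to
                # the deepest ladder level sharing the same species set
                for s2, cum2 in levels:
                    if cum2 == cum:
                        stratum = s2
            break
    if stratum is None:
        return StratumAssignment(gene_id, None, divergence_set=D, reason="divergence set exceeds ladder")
    return StratumAssignment(gene_id, stratum, divergence_set=D)


def assign_strata(
    trees: dict[str, str],
    ladder: SpeciesLadder = DEFAULT_LADDER,
    alt_label: str = "alt",
    min_support: float = 50.0,
) -> "pd.DataFrame":
    """Assign a collection of gene trees; returns a tidy table."""
    import pandas as pd

    rows = []
    for gene_id, newick in trees.items():
        a = assign_stratum(
            newick, ladder=ladder, gene_id=gene_id, alt_label=alt_label, min_support=min_support
        )
        rows.append(
            (
                gene_id,
                a.stratum if a.stratum is not None else pd.NA,
                a.bootstrap_ok,
                ";".join(sorted(a.divergence_set)),
                a.reason,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "stratum", "bootstrap_ok", "divergence_set", "reason"]
    )
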