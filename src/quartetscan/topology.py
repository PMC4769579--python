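"""Rule-based gene-tree classification of gene-flow timing and direction.

Compares per-locus gene trees against the species-tree expectation for a
clade structure of the form

    ((donor clade), (focal species + other species of its own clade)), outgroup

and classifies each tree into one of six categories by an ordered rule
set R0–R5. The focal species is the putative introgression partner from
the clade sister to the donor clade (in the motivating system, a
silvaniform butterfly exchanging alleles with the melpomene-cydno-
timareta clade). Every call records which rule fired and the bootstrap
support of the decisive branch, so classifications are auditable.

Rules, applied in order:

R0  All reference clades recovered → ``concordant`` (no rearrangement).
R1  The focal species is monophyletic but sits inside the donor clade
    (its sister group is a proper subset of donor-clade leaves) →
    gene flow between the donor clade and the focal species; timing
    "ancestral" when the sister group spans several donor taxa (the
    haplotype predates their diversification), "recent" when it is a
    single terminal taxon.
R2  One donor-clade taxon nests inside a single silvaniform species →
    gene flow from that silvaniform species into the donor taxon.
R3  The focal species is sister to the *entire* donor clade → exchange
    with the donor-clade ancestor; the direction cannot be polarized
    (no intervening clade before the outgroup).
R4  As R1/R2 but with a non-focal species of the focal's clade forming
    the introgression-defining clade → ``other_silvaniform_involved``,
    with the species named.
R5  Any residual discordance, or decisive-branch support below the
    threshold → ``uninterpretable``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy

from .genotype_io import ConfigError, FormatError

CATEGORIES = ("concordant", "focal_nested_in_donor",
              "donor_taxon_nested_in_focal_clade", "focal_sister_to_donor_clade",
              "other_silvaniform_involved", "uninterpretable")

_CLADES = ("focal_silvaniform", "other_silvaniform", "donor_clade", "outgroup")


@dataclass
class CladeMap:
    """sample id → (species, clade) assignment defining the reference tree."""

    assignments: dict  # sample -> (species, clade)

    def __post_init__(self):
        for s, (sp, clade) in self.assignments.items():
            if clade not in _CLADES:
                raise ConfigError(f"sample {s!r}: unknown clade {clade!r}")
        if not self.samples_in_clade("outgroup"):
            raise ConfigError("clade map lacks an outgroup sample")
        if not self.samples_in_clade("focal_silvaniform"):
            raise ConfigError("clade map lacks focal-species samples")

    @classmethod
    def from_tsv(cls, path: str) -> "CladeMap":
        out = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}:{ln}: expected sample<TAB>species<TAB>clade")
                out[parts[0]] = (parts[1], parts[2])
        return cls(out)

    def species_of(self, sample: str) -> str:
        return self.assignments[sample][0]

    def clade_of(self, sample: str) -> str:
        return self.assignments[sample][1]

    def samples_in_clade(self, clade: str) -> frozenset:
        return frozenset(s for s, (_, c) in self.assignments.items() if c == clade)

    def samples_of_species(self, species: str) -> frozenset:
        return frozenset(s for s, (sp, _) in self.assignments.items()
                         if sp == species)

    def species_in_clade(self, clade: str) -> frozenset:
        return frozenset(sp for _, (sp, c) in self.assignments.items()
                         if c == clade)


@dataclass
class TreeClassification:
    """Outcome of classifying one gene tree (or one locus)."""

    locus_id: str
    category: str
    direction: str = "unknown"          # "donor->recipient" style or "unknown"
    timing: str | None = None           # recent | ancestral | clade-ancestral
    rule: str | None = None
    support: float | None = None        # min support on the decisive branch
    donors: tuple = ()
    note: str = ""


# ---------------------------------------------------------------------------
# Newick parsing and rooted clade extraction
# ---------------------------------------------------------------------------

def parse_tree_with_support(newick: str, clade_map: CladeMap) -> dendropy.Tree:
    """Parse a newick string and root it on the outgroup leaf set.

    Internal node labels are read as bootstrap supports on the 0–100
    scale; a tree without any support labels is treated as fully
    supported (100) with a warning.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"unparseable newick: {exc}") from exc
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unmapped = leaves - set(clade_map.assignments)
    if unmapped:
        raise ConfigError(f"tree leaves absent from clade map: {sorted(unmapped)}")
    og = leaves & clade_map.samples_in_clade("outgroup")
    if not og:
        raise ConfigError("tree contains no outgroup leaf; cannot root")

    any_support = False
    for nd in tree.preorder_internal_node_iter():
        if nd.label is not None and nd.label.strip():
            try:
                nd.support = float(nd.label)
                any_support = True
                continue
            except ValueError:
                pass
        nd.support = None
    if not any_support:
        warnings.warn("tree carries no support values; treating all branches "
                      "as support 100")
    for nd in tree.preorder_internal_node_iter():
        if nd.support is None:
            nd.support = 100.0

    if len(og) == 1:
        og_node = next(lf for lf in tree.leaf_node_iter()
                       if lf.taxon.label in og)
        tree.reroot_at_edge(og_node.edge, update_bipartitions=False)
    else:
        mrca = tree.mrca(taxon_labels=sorted(og))
        if mrca is not tree.seed_node:
            tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    return tree


def _clades(tree: dendropy.Tree):
    """(leafset → support) for every internal node of the rooted tree."""
    out = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd._leafset = frozenset({nd.taxon.label})
        else:
            nd._leafset = frozenset().union(*(c._leafset for c in
                                              nd.child_nodes()))
            out[nd._leafset] = getattr(nd, "support", 100.0)
    return out


def _sister(tree: dendropy.Tree, leafset: frozenset):
    """Sister leaf set of the clade with exactly this leaf set, or None."""
    for nd in tree.postorder_internal_node_iter():
        for child in nd.child_nodes():
            if child._leafset == leafset:
                others = [c._leafset for c in nd.child_nodes() if c is not child]
                if others:
                    return frozenset().union(*others)
    for nd in tree.leaf_node_iter():
        if nd._leafset == leafset and nd.parent_node is not None:
            others = [c._leafset for c in nd.parent_node.child_nodes()
                      if c is not nd]
            return frozenset().union(*others) if others else None
    return None


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------

def classify_gene_tree(tree, clade_map: CladeMap,
                       support_threshold: float = 80.0,
                       locus_id: str = "locus") -> TreeClassification:
    """Classify one gene tree by the ordered rules R0–R5."""
    if isinstance(tree, str):
        tree = parse_tree_with_support(tree, clade_map)
    clades = _clades(tree)
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())

    present = lambda group: group & leaves
    focal = present(clade_map.samples_in_clade("focal_silvaniform"))
    donor = present(clade_map.samples_in_clade("donor_clade"))
    others = present(clade_map.samples_in_clade("other_silvaniform"))
    outgrp = present(clade_map.samples_in_clade("outgroup"))
    silva = focal | others
    ingroup = leaves - outgrp

    def mono(group):
        group = frozenset(group)
        if len(group) <= 1:
            return True
        if group == ingroup:  # the root child; trivially a clade after rooting
            return True
        return group in clades

    def support_of(group):
        group = frozenset(group)
        if len(group) <= 1 or group == ingroup:
            return 100.0
        return clades.get(group, 100.0)

    all_species = {clade_map.species_of(s) for s in ingroup}
    species_sets = {sp: present(clade_map.samples_of_species(sp))
                    for sp in all_species}

    def species_spanned(group):
        return {clade_map.species_of(s) for s in group}

    def finish(category, rule, direction, timing, decisive, donors=(), note=""):
        sup = support_of(decisive) if decisive is not None else 100.0
        if category != "uninterpretable" and sup < support_threshold:
            return TreeClassification(
                locus_id, "uninterpretable", "unknown", None, "R5", sup,
                note=f"decisive support {sup:g} below threshold "
                     f"{support_threshold:g} (would be {category})")
        return TreeClassification(locus_id, category, direction, timing,
                                  rule, sup, tuple(sorted(donors)), note)

    # R0: every reference clade recovered
    species_ok = all(mono(species_sets[sp]) for sp in all_species)
    if species_ok and mono(silva) and mono(donor):
        return finish("concordant", "R0", "unknown", None, silva)

    # R1 / R3: focal species displaced toward the donor clade
    if focal and mono(focal):
        sis = _sister(tree, focal)
        if sis is not None and sis and sis <= donor:
            rest_ok = all(mono(species_sets[sp]) for sp in
                          species_spanned(others))
            if not rest_ok:
                return finish("uninterpretable", "R5", "unknown", None, None,
                              note="discordance beyond the focal rearrangement")
            if sis == donor:
                return finish("focal_sister_to_donor_clade", "R3", "unknown",
                              "clade-ancestral", focal | sis,
                              donors=species_spanned(sis))
            spanned = species_spanned(sis)
            timing = "ancestral" if len(spanned) > 1 else "recent"
            return finish("focal_nested_in_donor", "R1",
                          "donor_clade->focal", timing, focal | sis,
                          donors=spanned)

    # R2 / R4: a donor taxon nested inside a silvaniform species
    for sp in sorted(species_spanned(donor)):
        dset = species_sets[sp]
        if not dset or not mono(dset):
            continue
        sis = _sister(tree, dset)
        if sis is None or not sis:
            continue
        host_species = species_spanned(sis)
        if len(host_species) == 1 and sis <= silva:
            host = next(iter(host_species))
            focal_species = species_spanned(focal)
            decisive = dset | sis
            if focal_species and host in focal_species:
                return finish("donor_taxon_nested_in_focal_clade", "R2",
                              f"{host}->{sp}", "recent", decisive,
                              donors={host})
            return finish("other_silvaniform_involved", "R4",
                          f"{host}->{sp}", "recent", decisive,
                          donors={host}, note=f"non-focal species {host}")

    # R4 (mirror): a non-focal silvaniform species displaced into the donor clade
    for sp in sorted(species_spanned(others)):
        oset = species_sets[sp]
        if not oset or not mono(oset):
            continue
        sis = _sister(tree, oset)
        if sis is not None and sis and sis <= donor:
            return finish("other_silvaniform_involved", "R4",
                          f"donor_clade->{sp}",
                          "ancestral" if len(species_spanned(sis)) > 1
                          else "recent",
                          oset | sis, donors=species_spanned(sis),
                          note=f"non-focal species {sp}")

    return finish("uninterpretable", "R5", "unknown", None, None,
                  note="no rule matched the observed rearrangement")


def classify_locus_set(trees: dict, clade_map: CladeMap,
                       support_threshold: float = 80.0,
                       locus_id: str = "locus") -> TreeClassification:
    """Consolidate classifications from original and extended windows.

    ``trees`` maps window labels (e.g. "original", "extended") to newick
    strings or parsed trees. The consolidated call is made only when all
    windows agree on the category; disagreement (an introgressed
    haplotype shorter than the extended window, say) yields
    ``uninterpretable`` with a note. A single tree is passed through,
    flagged single-window.
    """
    if not trees:
        raise ConfigError("need at least one tree per locus")
    calls = {label: classify_gene_tree(t, clade_map, support_threshold,
                                       f"{locus_id}:{label}")
             for label, t in trees.items()}
    items = list(calls.values())
    if len(items) == 1:
        only = items[0]
        return TreeClassification(locus_id, only.category, only.direction,
                                  only.timing, only.rule, only.support,
                                  only.donors, note="single-window")
    cats = {c.category for c in items}
    if len(cats) == 1:
        best = min(items, key=lambda c: (c.support is None, c.support))
        return TreeClassification(locus_id, best.category, best.direction,
                                  best.timing, best.rule, best.support,
                                  best.donors,
                                  note=f"windows agree ({len(items)})")
    detail = "; ".join(f"{lbl}={c.category}" for lbl, c in calls.items())
    return TreeClassification(locus_id, "uninterpretable", "unknown", None,
                              None, None, (),
                              note=f"window disagreement: {detail}")


def classify_tree_file(path: str, clade_map: CladeMap,
                       support_threshold: float = 80.0) -> list:
    """Classify every tree in a (multi-)newick file; one result per tree."""
    results = []
    with open(path) as fh:
        text = fh.read()
    chunks = [c.strip() + ";" for c in text.split(";") if c.strip()]
    for i, chunk in enumerate(chunks):
        results.append(classify_gene_tree(chunk, clade_map, support_threshold,
                                          locus_id=f"tree{i}"))
    return results
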