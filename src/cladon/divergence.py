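"""Clade divergence relative to a slow reference gene set, and tree clade
utilities.

The fold-divergence statistic asks how much faster a gene-family clade has
diverged than a conserved reference (here, a mitochondrial-like gene set on
the same species): mean within-clade pairwise Jukes–Cantor distance divided
by the mean pairwise JC distance among the reference sequences of the same
species.  Species matching keeps taxon-sampling differences from inflating
or deflating the denominator; when no two reference sequences match the
clade's species the full reference is used and the fallback is logged.

Distances default to all typed sites; ``sites="ff3"`` restricts to third
positions of fourfold-degenerate codons in both sequences, a proxy for
synonymous-site divergence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .codes import get_code
from .io import CodonAlignment, GeneRecord, PhyloTree, ValidationError
from .popgen import jukes_cantor

log = logging.getLogger(__name__)


@dataclass
class DivergenceReport:
    clade_label: str
    n_genes: int
    n_pairs: int
    n_pairs_dropped: int
    mean_pairwise_jc: float
    reference_mean_jc: float
    reference_n_pairs: int
    reference_matched_species: bool
    fold: float | None
    reason: str = ""


def pairwise_jc_distance(
    a: GeneRecord, b: GeneRecord, sites: str = "all", code_id: int = 1
) -> float | None:
    """Jukes–Cantor distance between two aligned sequences.

    Sites with a gap or ``N`` in either sequence are excluded pairwise.
    ``sites="ff3"`` uses only third positions of codons that are fourfold-
    degenerate in both sequences.  Returns ``None`` when saturated
    (p >= 3/4); raises if no sites remain to compare.
    """
    if len(a.sequence) != len(b.sequence):
        raise ValidationError("sequences differ in length")
    if sites == "all":
        pairs = [
            (x, y)
            for x, y in zip(a.sequence, b.sequence)
            if x in "ACGT" and y in "ACGT"
        ]
    elif sites == "ff3":
        code = get_code(code_id)
        pairs = [
            (ca[2], cb[2])
            for ca, cb in zip(a.codons(), b.codons())
            if ca in code.fourfold_codons and cb in code.fourfold_codons
        ]
    else:
        raise ValidationError(f"unknown sites mode: {sites!r}")
    if not pairs:
        raise ValidationError(
            f"no comparable sites between {a.gene_id!r} and {b.gene_id!r}"
        )
    p = sum(x != y for x, y in pairs) / len(pairs)
    return jukes_cantor(p)


def _mean_pairwise(records, sites: str, code_id: int) -> tuple[float, int, int]:
    """(mean JC over defined pairs, n defined, n dropped as saturated)."""
    dists, dropped = [], 0
    for a, b in itertools.combinations(records, 2):
        d = pairwise_jc_distance(a, b, sites=sites, code_id=code_id)
        if d is None:
            dropped += 1
        else:
            dists.append(d)
    if not dists:
        raise ValidationError("all pairwise distances saturated or undefined")
    return sum(dists) / len(dists), len(dists), dropped


def clade_fold_divergence(
    clade_alignments: dict[str, CodonAlignment],
    reference: CodonAlignment,
    sites: str = "all",
) -> list[DivergenceReport]:
    """Fold divergence of each clade relative to the reference gene set.

    Each clade alignment needs >= 2 genes and the reference >= 2 sequences.
    The reference mean is computed over reference-sequence pairs whose
    ``species`` labels both occur in the clade; if fewer than 2 such
    sequences exist the full reference is used (logged fallback).
    """
    if len(reference) < 2:
        raise ValidationError("reference needs >= 2 sequences")
    reports = []
    for clade_label in sorted(clade_alignments):
        aln = clade_alignments[clade_label]
        if len(aln) < 2:
            raise ValidationError(f"clade {clade_label!r} has < 2 genes")
        mean_jc, n_pairs, dropped = _mean_pairwise(
            list(aln), sites, aln.genetic_code_id
        )

        clade_species = {r.species for r in aln if r.species}
        ref_records = [r for r in reference if r.species in clade_species]
        matched = len(ref_records) >= 2
        if not matched:
            log.warning(
                "clade %r: < 2 reference sequences match its species; "
                "falling back to all reference pairs",
                clade_label,
            )
            ref_records = list(reference)
        ref_mean, ref_pairs, _ = _mean_pairwise(
            ref_records, sites, reference.genetic_code_id
        )

        fold, reason = None, ""
        if ref_mean > 0:
            fold = mean_jc / ref_mean
        else:
            reason = "reference mean distance is 0"
        reports.append(
            DivergenceReport(
                clade_label=clade_label,
                n_genes=len(aln),
                n_pairs=n_pairs,
                n_pairs_dropped=dropped,
                mean_pairwise_jc=mean_jc,
                reference_mean_jc=ref_mean,
                reference_n_pairs=ref_pairs,
                reference_matched_species=matched,
                fold=fold,
                reason=reason,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# tree clade utilities


def _descendant_tip_sets(tree: PhyloTree):
    """Yield (node, frozenset of descendant tip labels) for every node."""
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            yield node, frozenset([node.taxon.label])
        else:
            tips = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon
            )
            yield node, tips


def is_monophyletic(tree: PhyloTree, tips) -> bool:
    """Do ``tips`` form a clade (rooted) / an edge bipartition (unrooted)?"""
    tips = frozenset(tips)
    all_tips = frozenset(tree.tip_labels)
    unknown = tips - all_tips
    if unknown:
        raise ValidationError(f"unknown tips: {sorted(unknown)}")
    if not tips or tips == all_tips:
        raise ValidationError("tips must be a nonempty proper subset")
    complement = all_tips - tips
    for _, below in _descendant_tip_sets(tree):
        if below == tips:
            return True
        if not tree.is_rooted and below == complement:
            return True
    return False


def extract_clade(tree: PhyloTree, tips, outgroup: str | None = None) -> frozenset:
    """All tips descending from the MRCA of ``tips``.

    Rooted trees are used as-is; an unrooted tree must be given an
    ``outgroup`` tip to root on first.
    """
    tips = list(tips)
    if not tips:
        raise ValidationError("tips must be nonempty")
    all_tips = set(tree.tip_labels)
    unknown = set(tips) - all_tips
    if unknown:
        raise ValidationError(f"unknown tips: {sorted(unknown)}")

    work = tree
    if not tree.is_rooted:
        if outgroup is None:
            raise ValidationError("unrooted tree: an outgroup tip is required")
        if outgroup not in all_tips:
            raise ValidationError(f"unknown outgroup tip: {outgroup!r}")
        work = tree.clone()
        node = work.tree.find_node_with_taxon_label(outgroup)
        work.tree.reroot_at_edge(node.edge, update_bipartitions=False)

    # MRCA descendant set = smallest descendant tip set containing the query
    query = frozenset(tips)
    best = None
    for _, below in _descendant_tip_sets(work):
        if query <= below and (best is None or len(below) < len(best)):
            best = below
    assert best is not None  # the root always contains the query
    return best
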