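"""Family assignment of mined peptides from their phylogenetic placement.

The decision rule codifies visual tree inspection: a family "clade" is the
maximal well-supported edge whose leaf side contains every reference leaf of
that family and no reference leaf of any other family.  A query peptide is a
``member`` of the family whose clade contains it; a group of query-only
leaves forming a supported clade of its own is a ``novel_cluster``; a query
attached immediately outside one or more complete family clades is ``basal``
to that family set; everything else is ``unclassified``.  All of this is
evaluated on bipartitions of the unrooted tree, so verdicts do not depend on
rooting or leaf order.  The species-by-family occurrence matrix summarizes
the verdicts: ``+`` for membership, ``?`` for basal-only evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .phylo import PhyloTree
from .refpanel import FAMILY_VOCABULARY


@dataclass(frozen=True)
class ClassifyConfig:
    min_support: float = 0.70
    min_novel_cluster_size: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.min_support <= 1):
            raise ValueError("min_support must be in [0, 1]")
        if self.min_novel_cluster_size < 2:
            raise ValueError("min_novel_cluster_size must be >= 2")


@dataclass(frozen=True)
class FamilyClade:
    family: str
    leaves: frozenset
    support: float


@dataclass(frozen=True)
class FamilyAssignment:
    peptide_id: str
    verdict: str  # member | basal | novel_cluster | unclassified
    families: tuple[str, ...] = ()
    cluster_leaves: frozenset = frozenset()
    supporting_edge_support: float = 0.0


def _supported_sides(
    tree: PhyloTree, min_support: float
) -> list[tuple[frozenset, float]]:
    """Both orientations of every supported edge, leaf edges included."""
    all_leaves = frozenset(tree.leaf_names())
    sides: dict[frozenset, float] = {}
    for below, support, node in tree.edges(include_leaves=True):
        if support is None:
            raise ValueError("tree carries no support values")
        for side in (below, all_leaves - below):
            if 0 < len(side) < len(all_leaves) and support >= min_support:
                prev = sides.get(side)
                if prev is None or support > prev:
                    sides[side] = support
    return sorted(sides.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))


def family_clades(
    tree: PhyloTree,
    panel_labels: Mapping[str, str],
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[dict[str, FamilyClade], list[str]]:
    """Resolve each family to its core clade.

    The core is the smallest supported edge side that contains every
    reference leaf of the family and no reference leaf of any other family
    (query leaves nested among the references are included).  Returns
    ``(clades, unresolved)``; a family is unresolved when no such side
    exists (paraphyly, or the separating edge falls below ``min_support``).
    On an unrooted tree the complement of any other family's clade is also
    "pure", so a maximal pure side is not well defined; queries attaching
    just below the core are handled by the joining rule in :func:`assign`.
    """
    leaves = set(tree.leaf_names())
    ref_by_family: dict[str, set] = {}
    for pid, fam in panel_labels.items():
        if pid in leaves:
            ref_by_family.setdefault(fam, set()).add(pid)
    ref_all = set().union(*ref_by_family.values()) if ref_by_family else set()
    sides = _supported_sides(tree, config.min_support)  # smallest first
    clades: dict[str, FamilyClade] = {}
    unresolved: list[str] = []
    for fam in sorted(ref_by_family):
        fam_refs = ref_by_family[fam]
        best: Optional[tuple[frozenset, float]] = None
        for side, support in sides:
            if fam_refs.issubset(side) and not (side & ref_all) - fam_refs:
                best = (side, support)
                break
        if best is None:
            unresolved.append(fam)
        else:
            clades[fam] = FamilyClade(family=fam, leaves=best[0], support=best[1])
    return clades, unresolved


def assign(
    peptide_leaf: str,
    tree: PhyloTree,
    clades: Mapping[str, FamilyClade],
    config: ClassifyConfig = ClassifyConfig(),
    panel_labels: Optional[Mapping[str, str]] = None,
) -> FamilyAssignment:
    """Classify one query leaf relative to the resolved family clades.

    Decision order: (1) member, if the leaf lies inside exactly one family
    core; (2) novel cluster, if it belongs to a supported clade of at least
    ``min_novel_cluster_size`` query-only leaves; (3) member by joining, if
    a supported edge groups the leaf with exactly one complete family and
    nothing from any other family; (4) basal, if its nearest supported
    ref-containing side holds one or more complete families (several
    equally-near families are merged into one basal set); else
    (5) unclassified.
    """
    all_leaves = set(tree.leaf_names())
    if peptide_leaf not in all_leaves:
        raise ValueError(f"unknown leaf {peptide_leaf!r}")
    panel_labels = panel_labels or {}
    ref_leaves = {pid for pid in panel_labels if pid in all_leaves}
    ref_family = {pid: panel_labels[pid] for pid in ref_leaves}
    refs_of = {
        fam: {r for r, f in ref_family.items() if f == fam}
        for fam in set(ref_family.values())
    }

    # (1) member inside a family core
    inside = [f for f in sorted(clades) if peptide_leaf in clades[f].leaves]
    if len(inside) == 1:
        clade = clades[inside[0]]
        return FamilyAssignment(
            peptide_id=peptide_leaf,
            verdict="member",
            families=(inside[0],),
            supporting_edge_support=clade.support,
        )

    sides = _supported_sides(tree, config.min_support)  # smallest first

    # (2) novel cluster: maximal supported query-only clade of enough leaves
    best_novel: Optional[tuple[frozenset, float]] = None
    for side, support in sides:
        if peptide_leaf not in side or side & ref_leaves:
            continue
        if len(side) < config.min_novel_cluster_size:
            continue
        if best_novel is None or len(side) > len(best_novel[0]):
            best_novel = (side, support)
    if best_novel is not None:
        return FamilyAssignment(
            peptide_id=peptide_leaf,
            verdict="novel_cluster",
            cluster_leaves=best_novel[0],
            supporting_edge_support=best_novel[1],
        )

    # (3) member by joining: smallest pure supported side with one family
    joining: dict[str, tuple[frozenset, float]] = {}
    for fam in sorted(clades):
        fam_refs = refs_of.get(fam, set())
        for side, support in sides:
            if peptide_leaf not in side or not fam_refs.issubset(side):
                continue
            if (side & ref_leaves) - fam_refs:
                continue  # impure: touches another family
            joining[fam] = (side, support)
            break
    if joining:
        min_size = min(len(s) for s, _ in joining.values())
        nearest = [f for f, (s, _) in joining.items() if len(s) == min_size]
        if len(nearest) == 1:
            side, support = joining[nearest[0]]
            return FamilyAssignment(
                peptide_id=peptide_leaf,
                verdict="member",
                families=(nearest[0],),
                supporting_edge_support=support,
            )
        # equally near to several complete families: basal to their union
        return FamilyAssignment(
            peptide_id=peptide_leaf,
            verdict="basal",
            families=tuple(sorted(nearest)),
            supporting_edge_support=min(
                joining[f][1] for f in nearest
            ),
        )

    # (4) basal: smallest supported ref-containing side, complete families
    for side, support in sides:
        if peptide_leaf not in side:
            continue
        refs_in = side & ref_leaves
        if not refs_in:
            continue
        fams = {ref_family[r] for r in refs_in}
        if all(refs_of[fam] <= side for fam in fams):
            return FamilyAssignment(
                peptide_id=peptide_leaf,
                verdict="basal",
                families=tuple(sorted(fams)),
                supporting_edge_support=support,
            )
        break  # nearest ref-containing side splits a family: unclassified

    return FamilyAssignment(peptide_id=peptide_leaf, verdict="unclassified")


def classify_all(
    tree: PhyloTree,
    panel_labels: Mapping[str, str],
    query_ids: Sequence[str],
    config: ClassifyConfig = ClassifyConfig(),
) -> list[FamilyAssignment]:
    """Assign every query leaf; novel clusters get stable numbered ids."""
    clades, _ = family_clades(tree, panel_labels, config)
    out = []
    for qid in sorted(query_ids):
        out.append(
            assign(qid, tree, clades, config, panel_labels=panel_labels)
        )
    return out


def novel_cluster_ids(assignments: Sequence[FamilyAssignment]) -> dict[frozenset, str]:
    """Number distinct novel clusters in order of first appearance."""
    ids: dict[frozenset, str] = {}
    for a in sorted(assignments, key=lambda a: a.peptide_id):
        if a.verdict == "novel_cluster" and a.cluster_leaves not in ids:
            ids[a.cluster_leaves] = f"NC{len(ids) + 1}"
    return ids


def occurrence_matrix(
    assignments: Sequence[FamilyAssignment],
    species_of: Mapping[str, str],
    families: Sequence[str] = (),
) -> pd.DataFrame:
    """Species-by-family table: '+' member evidence, '?' basal-only, '' none."""
    fams = list(families) if families else [f for f in FAMILY_VOCABULARY if f != "GT2other"]
    species = sorted(set(species_of.values()))
    df = pd.DataFrame("", index=species, columns=fams)
    for a in assignments:
        sp = species_of.get(a.peptide_id)
        if sp is None:
            continue
        if a.verdict == "member":
            for fam in a.families:
                if fam in df.columns:
                    df.loc[sp, fam] = "+"
        elif a.verdict == "basal":
            for fam in a.families:
                if fam in df.columns and df.loc[sp, fam] != "+":
                    df.loc[sp, fam] = "?"
    return df


def write_assignments_tsv(
    assignments: Sequence[FamilyAssignment],
    species_of: Mapping[str, str],
    path,
) -> None:
    cluster_ids = novel_cluster_ids(assignments)
    with open(path, "w") as fh:
        fh.write("# peptide\tspecies\tverdict\tfamilies_or_cluster\tsupport\n")
        for a in sorted(assignments, key=lambda a: a.peptide_id):
            if a.verdict == "novel_cluster":
                detail = cluster_ids[a.cluster_leaves]
            else:
                detail = ",".join(a.families) or "-"
            fh.write(
                f"{a.peptide_id}\t{species_of.get(a.peptide_id, '-')}\t"
                f"{a.verdict}\t{detail}\t{a.supporting_edge_support:.3f}\n"
            )


def write_occurrence_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="species")
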