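"""Gene reuse: shared selection between species pairs versus divergence time.

For every pair of species with the same ecomorph, count the genes selected
on both terminal branches, normalize by the maximum observed shared count
(so the max-attaining pair scores 1.0 — normalizing by the full gene
universe would crush the dynamic range), and regress the proportion on the
pair's node age.  A negative slope means recently diverged pairs reuse the
same genes more, the classic expectation for gene reuse; restriction to a
GO term's annotated genes repeats the analysis on a functional subset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .phylo import TimeTree
from .regression import RegressionFit, fit_ols
from .screen import SelectionMatrix

__all__ = [
    "PairRecord",
    "same_ecomorph_pairs",
    "pair_shared_counts",
    "normalize_by_max",
    "build_pair_records",
    "reuse_regression",
    "restrict_to_go",
    "records_to_frame",
    "plot_reuse",
]


@dataclass(frozen=True)
class PairRecord:
    species_a: str
    species_b: str
    ecomorph: str
    node_age: float
    shared_count: int
    proportion: float | None = None


def same_ecomorph_pairs(
    matrix: SelectionMatrix,
    include_groups: Sequence[str] | None = None,
    exclude_groups: Sequence[str] = ("outgroup",),
) -> list:
    """(species_a, species_b, ecomorph) for all within-group pairs.

    By default all ecomorphs except the outgroup contribute; pass
    ``include_groups`` to restrict, or list "outgroup" there for the
    Myotis-versus-outgroup contrast.
    """
    meta = matrix.meta
    groups = sorted(
        set(meta.loc[meta["is_terminal"], "ecomorph"].dropna())
    )
    if include_groups is not None:
        groups = [g for g in groups if g in set(include_groups)]
    else:
        groups = [g for g in groups if g not in set(exclude_groups)]
    pairs = []
    for g in groups:
        species = matrix.species_of_ecomorph(g)
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                pairs.append((a, b, g))
    return pairs


def pair_shared_counts(
    matrix: SelectionMatrix, pairs: Iterable[tuple], genes: Iterable[str] | None = None
) -> list:
    """Shared-selected-gene count per species pair.

    A gene counts for a pair when it is selected on both terminal
    branches; genes absent (untested) on either branch cannot contribute.
    ``genes`` optionally restricts the countable universe (used for the
    GO-subset analyses).
    """
    gene_filter = set(genes) if genes is not None else None
    out = []
    for a, b, *rest in pairs:
        sel_a = matrix.selected_genes_on(matrix.species_branch_key(a))
        sel_b = matrix.selected_genes_on(matrix.species_branch_key(b))
        shared = sel_a & sel_b
        if gene_filter is not None:
            shared &= gene_filter
        out.append(((a, b, *rest), len(shared)))
    return out


def normalize_by_max(records: Sequence[PairRecord]) -> list:
    """Proportions = shared_count / max observed shared_count.

    The max-attaining pair(s) score exactly 1.0; all counts zero is an
    error (nothing to scale by).
    """
    if not records:
        raise ValueError("no pair records")
    peak = max(r.shared_count for r in records)
    if peak == 0:
        raise ValueError("all shared counts are zero")
    return [replace(r, proportion=r.shared_count / peak) for r in records]


def build_pair_records(
    matrix: SelectionMatrix,
    tree: TimeTree,
    pairs: Iterable[tuple] | None = None,
    genes: Iterable[str] | None = None,
) -> list:
    """Counts + node ages + max-normalized proportions in one pass.

    Node ages come from the full (unpruned) time tree.
    """
    if pairs is None:
        pairs = same_ecomorph_pairs(matrix)
    counts = pair_shared_counts(matrix, pairs, genes=genes)
    records = []
    for (a, b, *rest), n_shared in counts:
        eco = rest[0] if rest else "pair"
        records.append(
            PairRecord(a, b, eco, tree.node_age(a, b).age, n_shared)
        )
    return normalize_by_max(records)


def reuse_regression(
    records: Sequence[PairRecord], group: str | None = None, use_counts: bool = False
) -> RegressionFit:
    """OLS of reuse proportion (or raw count) on node age."""
    if group is not None:
        records = [r for r in records if r.ecomorph == group]
    if len(records) < 3:
        raise ValueError("need at least 3 pair records")
    x = [r.node_age for r in records]
    if use_counts:
        y = [float(r.shared_count) for r in records]
    else:
        if any(r.proportion is None for r in records):
            raise ValueError("records not normalized (run normalize_by_max)")
        y = [r.proportion for r in records]
    return fit_ols(x, y)


def _genes_of_term(
    go_term: str,
    annotations: Mapping[str, Iterable[str]],
    graph: "nx.DiGraph | None" = None,
) -> set:
    if go_term not in annotations and (graph is None or go_term not in graph):
        raise KeyError(f"term {go_term!r} not in annotations")
    genes = set(annotations.get(go_term, ()))
    if graph is not None and go_term in graph:
        # obonet convention: edges point child -> parent, so descendants of a
        # term are its ancestors in the graph.
        for child in nx.ancestors(graph, go_term):
            genes |= set(annotations.get(child, ()))
    return genes


def restrict_to_go(
    matrix: SelectionMatrix,
    tree: TimeTree,
    go_term: str,
    annotations: Mapping[str, Iterable[str]],
    graph: "nx.DiGraph | None" = None,
    pairs: Iterable[tuple] | None = None,
) -> list:
    """Reuse records recomputed over one GO term's annotated genes.

    Descendant terms are folded in when a term graph is supplied; counts
    are renormalized by the restricted maximum.
    """
    genes = _genes_of_term(go_term, annotations, graph)
    if not genes:
        raise ValueError(f"term {go_term!r} annotates no genes")
    return build_pair_records(matrix, tree, pairs=pairs, genes=genes)


def records_to_frame(records: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_a": r.species_a,
                "species_b": r.species_b,
                "ecomorph": r.ecomorph,
                "node_age": r.node_age,
                "shared_count": r.shared_count,
                "proportion": r.proportion,
            }
            for r in records
        ]
    )


def plot_reuse(records: Sequence[PairRecord], path, fit: RegressionFit | None = None):
    """Age-versus-proportion scatter with one marker style per ecomorph."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = {"trawler": "s", "aerial_hawker": "o", "gleaner": "^", "outgroup": "D"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for eco in sorted({r.ecomorph for r in records}):
        sub = [r for r in records if r.ecomorph == eco]
        ax.scatter(
            [r.node_age for r in sub],
            [r.proportion for r in sub],
            marker=markers.get(eco, "x"),
            label=eco,
            alpha=0.7,
        )
    if fit is not None:
        xs = sorted(r.node_age for r in records)
        ax.plot(xs, [fit.intercept + fit.slope * x for x in xs], "k--", lw=1)
        ax.set_title(f"R²={fit.r_squared:.3f}, P={fit.p:.3g}")
    ax.set_xlabel("node age (My)")
    ax.set_ylabel("proportion of shared selected genes")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
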