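"""Ingestion and aggregation of per-branch positive-selection screens.

Branch-site tests such as aBSREL report one p-value per tested branch per
gene.  The functions here read those results (plain TSV or the tool's JSON
result files), apply Benjamini–Hochberg correction *within each gene across
its tested branches*, and assemble a gene × branch selection matrix that
distinguishes three states per cell: selected, tested-but-not-selected,
and absent (the branch was not in that gene's alignment).  Keeping the
absent state separate matters downstream — a missing branch is not
evidence of no selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import BranchID, TimeTree, branch_key, parse_branch_key
from .regression import RegressionFit, fit_ols

__all__ = [
    "SelectionCall",
    "SelectionMatrix",
    "bh_adjust",
    "fdr_within_gene",
    "read_screen_results",
    "apply_fdr",
    "build_selection_matrix",
    "branch_metadata",
    "branch_bias_check",
]


@dataclass(frozen=True)
class SelectionCall:
    gene: str
    branch: BranchID
    p_raw: float
    q: float
    selected: bool


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fdr_within_gene(p_values: Sequence[float]) -> list:
    """BH correction across the tested branches of a single gene."""
    return bh_adjust(p_values).tolist()


# -- readers --------------------------------------------------------------


def _resolve_branch(name: str, tips: frozenset) -> BranchID | None:
    bid = parse_branch_key(name)
    return bid if bid <= tips else None


def read_screen_results(
    paths: Iterable[str | Path],
    tree: TimeTree,
    dialect: str = "tsv",
    use_corrected: bool = False,
):
    """Read selection-test results into (gene, branch, p) records.

    ``dialect='tsv'`` expects columns gene, branch, p (branch named by a
    tip label or sorted clade tips joined with ``|``).  ``dialect='native'``
    expects one JSON result file per gene in the branch-site tool's layout,
    reading the per-branch uncorrected p-value by default so the
    within-gene correction is applied explicitly (``use_corrected=True``
    trusts the file's corrected values instead).

    Returns ``(records, unresolved)`` where unresolved lists branch names
    that could not be matched to tips of the analysis tree.
    """
    records: list[tuple] = []
    unresolved: list[tuple] = []
    tips = tree.tips
    for path in paths:
        path = Path(path)
        if dialect == "tsv":
            df = pd.read_csv(path, sep="\t", comment="#")
            cols = {c.lower(): c for c in df.columns}
            for want in ("gene", "branch", "p"):
                if want not in cols:
                    raise ValueError(f"{path}: missing column {want!r}")
            for gene, branch, p in zip(
                df[cols["gene"]], df[cols["branch"]], df[cols["p"]]
            ):
                p = float(p)
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{path}: p outside [0,1] for {gene}/{branch}")
                bid = _resolve_branch(str(branch), tips)
                if bid is None:
                    unresolved.append((str(gene), str(branch)))
                else:
                    records.append((str(gene), bid, p))
        elif dialect == "native":
            payload = json.loads(path.read_text())
            gene = payload.get("input", {}).get("file name", path.stem)
            attrs = payload["branch attributes"]["0"]
            key = "Corrected P-value" if use_corrected else "Uncorrected P-value"
            for branch, info in attrs.items():
                if key not in info:
                    continue
                p = float(info[key])
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{path}: p outside [0,1] for {branch}")
                bid = _resolve_branch(branch, tips)
                if bid is None:
                    unresolved.append((gene, branch))
                else:
                    records.append((gene, bid, p))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    if not records:
        raise ValueError("no selection records parsed")
    return records, unresolved


def apply_fdr(records: Iterable[tuple], alpha: float = 0.05) -> list:
    """Turn (gene, branch, p) records into SelectionCalls via within-gene BH."""
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    by_gene: dict[str, list] = {}
    for gene, branch, p in records:
        by_gene.setdefault(gene, []).append((branch, p))
    calls = []
    for gene, items in by_gene.items():
        q = bh_adjust([p for _, p in items])
        for (branch, p), qi in zip(items, q):
            calls.append(SelectionCall(gene, branch, p, float(qi), bool(qi <= alpha)))
    return calls


# -- the matrix -----------------------------------------------------------


class SelectionMatrix:
    """Gene × branch selection calls plus per-branch metadata.

    ``data`` holds 1.0 (selected), 0.0 (tested, not selected) or NaN
    (branch absent from the gene's test).  ``meta`` is indexed by branch
    key with columns species, ecomorph, region, is_terminal.
    """

    def __init__(self, data: pd.DataFrame, meta: pd.DataFrame):
        missing = set(data.columns) - set(meta.index)
        if missing:
            raise ValueError(f"metadata missing for branches: {sorted(missing)[:5]}")
        term = meta.loc[list(data.columns)]
        bad = term[(term["is_terminal"]) & (term["species"].isna())]
        if len(bad):
            raise ValueError("terminal branches without species metadata")
        sp = term.loc[term["is_terminal"], ["species", "ecomorph"]].dropna()
        if sp["species"].duplicated().any():
            raise ValueError("a species appears on more than one terminal branch")
        self.data = data
        self.meta = meta

    # -- queries ----------------------------------------------------------

    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def branch_keys(self) -> list:
        return list(self.data.columns)

    def species_branch_key(self, species: str) -> str:
        hits = self.meta.index[
            (self.meta["is_terminal"]) & (self.meta["species"] == species)
        ]
        if len(hits) != 1:
            raise KeyError(f"species {species!r} has no terminal branch in matrix")
        return hits[0]

    def species_of_ecomorph(self, ecomorph: str) -> list:
        sub = self.meta[
            (self.meta["is_terminal"]) & (self.meta["ecomorph"] == ecomorph)
        ]
        return sorted(sub["species"].tolist())

    def selected_genes_on(self, branch_key_: str) -> set:
        col = self.data[branch_key_]
        return set(col.index[col == 1.0])

    # -- I/O --------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.replace({1.0: "1", 0.0: "0"}).fillna("NA")
        with open(path, "w") as fh:
            fh.write("# selection matrix: rows genes, columns branch keys; 1 selected / 0 tested / NA absent\n")
            out.to_csv(fh, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, meta: pd.DataFrame) -> "SelectionMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene", dtype=str)
        data = df.apply(pd.to_numeric, errors="coerce")  # "NA" -> NaN
        return cls(data, meta)


def branch_metadata(
    tree: TimeTree,
    ecomorph_map: Mapping[str, str],
    region_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Metadata table for every branch of the analysis tree."""
    unmapped = tree.tips - set(ecomorph_map)
    if unmapped:
        raise ValueError(f"species without ecomorph: {sorted(unmapped)}")
    rows = []
    for bid in tree.branch_ids():
        terminal = len(bid) == 1
        species = next(iter(bid)) if terminal else None
        rows.append(
            {
                "branch": branch_key(bid),
                "species": species,
                "ecomorph": ecomorph_map.get(species) if terminal else None,
                "region": (region_map or {}).get(species) if terminal else None,
                "is_terminal": terminal,
            }
        )
    return pd.DataFrame(rows).set_index("branch")


def build_selection_matrix(
    calls: Iterable[SelectionCall],
    meta: pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> SelectionMatrix:
    """Assemble the gene × branch matrix from per-branch calls.

    Cells without a call stay NaN (absent).  ``genes`` may extend the row
    index with genes that had no tested branch at all.
    """
    calls = list(calls)
    gene_order: list[str] = list(genes) if genes is not None else []
    seen = set(gene_order)
    for c in calls:
        if c.gene not in seen:
            gene_order.append(c.gene)
            seen.add(c.gene)
    cols = list(meta.index)
    data = pd.DataFrame(np.nan, index=gene_order, columns=cols)
    data.index.name = "gene"
    for c in calls:
        key = branch_key(c.branch)
        if key not in data.columns:
            raise KeyError(f"call references branch {key} absent from metadata")
        data.loc[c.gene, key] = 1.0 if c.selected else 0.0
    return SelectionMatrix(data, meta)


def branch_bias_check(matrix: SelectionMatrix) -> RegressionFit:
    """Regression of per-branch selected-gene counts on branch representation.

    Guards against genome-completeness heterogeneity: if patchy alignments
    drove the screen, branches present in more gene alignments would
    collect more selection calls.  Returns the OLS fit of
    (#genes selected on branch) on (#gene tests containing branch).
    """
    tested = matrix.data.notna().sum(axis=0).to_numpy(dtype=float)
    selected = (matrix.data == 1.0).sum(axis=0).to_numpy(dtype=float)
    if tested.size < 3:
        raise ValueError("need at least 3 branches")
    return fit_ols(tested, selected)
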