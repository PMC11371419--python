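"""Ecomorph-level aggregation of convergence evidence.

Builds per-ecomorph gene sets from the selection matrix ("selected in at
least one species of the group", terminal branches by default), partitions
them into Venn regions, filters branch-pair convergence records on the
error-corrected convergence rate (omega_c), and cross-references the three
evidence streams (selection screen, RER association, omega_c).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .phylo import BranchID, branch_key, parse_branch_key
from .screen import SelectionMatrix

__all__ = [
    "GeneSet",
    "OmegaCRecord",
    "VennPartition",
    "genes_selected_in_group",
    "venn_partition",
    "filter_omega_c",
    "overlap_evidence",
    "read_omega_c_tsv",
    "write_omega_c_tsv",
]

OMEGA_C_MODES = ("any2spe", "any2any", "spe2spe")


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset

    def __len__(self) -> int:
        return len(self.genes)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.genes)) + "\n")

    @classmethod
    def read(cls, path: str | Path, label: str | None = None) -> "GeneSet":
        genes = frozenset(
            line.strip() for line in Path(path).read_text().splitlines() if line.strip()
        )
        return cls(label or Path(path).stem, genes)


@dataclass(frozen=True)
class OmegaCRecord:
    gene: str
    branch_pair: frozenset  # two BranchIDs
    omega_c: float
    mode: str

    def __post_init__(self):
        if self.omega_c < 0:
            raise ValueError("omega_c must be >= 0")
        if len(self.branch_pair) != 2:
            raise ValueError("branch pair must contain two distinct branches")
        if self.mode not in OMEGA_C_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class VennPartition:
    """Counts for the 7 regions of three sets plus per-set exclusive shares."""

    labels: tuple
    regions: dict = field(default_factory=dict)  # key like '110' (in a, in b, not c)
    exclusive_fraction: dict = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def genes_selected_in_group(
    matrix: SelectionMatrix, ecomorph: str, terminal_only: bool = True
) -> GeneSet:
    """Genes selected on >= 1 branch of the ecomorph's species.

    Membership follows the at-least-one-species rule; with
    ``terminal_only`` (the default, matching screens restricted to extant
    phenotypes) only terminal branches count.
    """
    meta = matrix.meta.loc[list(matrix.data.columns)]
    sub = meta[meta["ecomorph"] == ecomorph]
    if terminal_only:
        sub = sub[sub["is_terminal"]]
    if len(sub) == 0:
        raise KeyError(f"no branch for ecomorph {ecomorph!r}")
    genes: set = set()
    for key in sub.index:
        genes |= matrix.selected_genes_on(key)
    return GeneSet(ecomorph, frozenset(genes))


def venn_partition(a: GeneSet, b: GeneSet, c: GeneSet) -> VennPartition:
    """Mutually exclusive region counts for three gene sets."""
    sets = (a.genes, b.genes, c.genes)
    regions = {}
    for mask in ("100", "010", "001", "110", "101", "011", "111"):
        inside = [s for s, m in zip(sets, mask) if m == "1"]
        outside = [s for s, m in zip(sets, mask) if m == "0"]
        members = set.intersection(*[set(s) for s in inside])
        for s in outside:
            members -= s
        regions[mask] = len(members)
    exclusive = {}
    for label, s, mask in zip(
        (a.label, b.label, c.label), sets, ("100", "010", "001")
    ):
        exclusive[label] = regions[mask] / len(s) if len(s) else 0.0
    return VennPartition((a.label, b.label, c.label), regions, exclusive)


def filter_omega_c(
    records: Iterable[OmegaCRecord],
    threshold: float = 3.0,
    mode: str = "any2spe",
    foreground: Iterable[BranchID] | None = None,
    require_both: bool = False,
) -> GeneSet:
    """Genes with >= 1 branch-pair record passing the convergence filter.

    A record passes when omega_c >= threshold (inclusive), its mode
    matches, and at least one branch of the pair is foreground
    (``require_both`` demands both).  With no foreground given, any pair
    qualifies.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    fg = {frozenset(b) for b in foreground} if foreground is not None else None
    genes = set()
    for rec in records:
        if rec.mode != mode or rec.omega_c < threshold:
            continue
        if fg is not None:
            n_fg = sum(1 for b in rec.branch_pair if frozenset(b) in fg)
            if n_fg < (2 if require_both else 1):
                continue
        genes.add(rec.gene)
    return GeneSet(f"omega_c>={threshold:g}", frozenset(genes))


def overlap_evidence(
    selected: GeneSet, rer_significant: GeneSet, omega_significant: GeneSet
) -> dict:
    """Three-way cross-reference of the evidence streams for one ecomorph.

    Returns the Venn partition plus the share of screen-selected genes
    also carrying each convergence signal (and the RER/omega_c overlap,
    which published screens tend to find empty).
    """
    venn = venn_partition(selected, rer_significant, omega_significant)
    n_sel = len(selected)

    def frac(other: GeneSet) -> float:
        return len(selected.genes & other.genes) / n_sel if n_sel else 0.0

    return {
        "venn": venn,
        "selected_and_rer": frac(rer_significant),
        "selected_and_omega": frac(omega_significant),
        "rer_and_omega": len(rer_significant.genes & omega_significant.genes),
        "all_three": venn.regions["111"],
    }


# -- omega_c table I/O ----------------------------------------------------


def write_omega_c_tsv(records: Iterable[OmegaCRecord], path: str | Path) -> None:
    rows = [
        {
            "gene": r.gene,
            "branch1": branch_key(sorted(r.branch_pair, key=branch_key)[0]),
            "branch2": branch_key(sorted(r.branch_pair, key=branch_key)[1]),
            "mode": r.mode,
            "omega_c": r.omega_c,
        }
        for r in records
    ]
    with open(path, "w") as fh:
        fh.write("# omega_c records: gene, branch1, branch2, mode, omega_c\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_omega_c_tsv(path: str | Path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        OmegaCRecord(
            str(row.gene),
            frozenset(
                [parse_branch_key(str(row.branch1)), parse_branch_key(str(row.branch2))]
            ),
            float(row.omega_c),
            str(row.mode),
        )
        for row in df.itertuples()
    ]
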