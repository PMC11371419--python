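"""Relative evolutionary rates (RER) and their binary-trait association.

This is a self-contained reimplementation of the RER core used in
convergence screens: per-gene branch lengths are regressed, after a
variance-stabilizing transform, on genome-average ("master") branch
lengths, optionally with inverse-variance weights estimated in master-
length bins to correct heteroscedasticity; the standardized residuals are
the RERs.  A gene whose branches evolve proportionally to the genome
average has RERs near zero everywhere; acceleration on a subset of
branches shows up as positive residuals there.

Association with a convergent phenotype is the Kendall rank correlation
between a gene's RERs and a 0/1 foreground-branch indicator (foreground =
terminal branches of the species in one ecomorph).

Phylogenetic covariance among residuals beyond the master-tree regression
is not modeled; see the package methods notes for the implications.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import BranchID, branch_key

__all__ = [
    "RateMatrix",
    "GeneTraitAssociation",
    "compute_master_lengths",
    "compute_rers",
    "kendall_tau",
    "trait_association",
]

EXACT_N_MAX = 9  # exact permutation p-value up to this many observations


class RateMatrix:
    """Gene × branch matrix of branch lengths (substitutions/site).

    NaN cells mark branches absent from a gene's alignment/tree.
    ``master`` (per-branch average over genes) is attached by
    :func:`compute_master_lengths`.
    """

    def __init__(self, data: pd.DataFrame, master: pd.Series | None = None):
        if (data.to_numpy(dtype=float) < -1e-12).any():
            raise ValueError("negative branch lengths in rate matrix")
        self.data = data
        self.master = master

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# rate matrix: rows genes, columns branch keys; substitutions/site\n")
            self.data.to_csv(fh, sep="\t", index_label="gene", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "RateMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene", na_values="NA")
        return cls(df.astype(float))


@dataclass(frozen=True)
class GeneTraitAssociation:
    gene: str
    tau: float
    p: float
    n_branches: int
    significant: bool


def compute_master_lengths(rates: RateMatrix, min_genes: int = 5) -> pd.Series:
    """Per-branch mean length over genes where the branch is present.

    Branches observed in fewer than ``min_genes`` genes are dropped — too
    few observations make the average (and residuals against it)
    unstable.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    present = rates.data.notna().sum(axis=0)
    keep = present[present >= min_genes].index
    if len(keep) == 0:
        raise ValueError("no branch present in enough genes")
    master = rates.data[keep].mean(axis=0, skipna=True)
    rates.master = master
    return master


_TRANSFORMS = {"sqrt": np.sqrt, "log1p": np.log1p}


def compute_rers(
    rates: RateMatrix,
    transform: str = "sqrt",
    weighting: str = "binned-variance",
    min_n: int = 10,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Residual rates for every gene × branch cell present.

    Two passes: an unweighted per-gene regression of transformed gene
    lengths on transformed master lengths, then (for
    ``weighting='binned-variance'``) a weighted refit with inverse
    residual variance estimated in ``n_bins`` master-length quantile bins
    pooled across genes.  Residuals are standardized per gene to unit
    scale; genes with fewer than ``min_n`` usable branches are skipped.
    """
    if rates.master is None:
        raise ValueError("master lengths not computed (call compute_master_lengths)")
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if weighting not in ("none", "binned-variance", "branch-variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    f = _TRANSFORMS[transform]
    master = rates.master
    cols = list(master.index)
    X = f(master.to_numpy(dtype=float))
    mat = rates.data[cols].to_numpy(dtype=float)
    n_genes = mat.shape[0]
    out = np.full_like(mat, np.nan)
    skipped = 0

    def _fit(x, y, w=None, studentize=False):
        if w is None:
            w = np.ones_like(x)
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx == 0:
            return y - ym
        b = (w * (x - xm) * (y - ym)).sum() / sxx
        r = y - (ym + b * (x - xm))
        if not studentize:
            return r
        # internally studentized residuals: scale by sqrt(w) to undo the
        # per-branch noise scale, and by sqrt(1-h) to undo the shrinkage
        # of high-leverage (heavily weighted or extreme-x) branches
        h = w * (1.0 / sw + (x - xm) ** 2 / sxx)
        return r * np.sqrt(w) / np.sqrt(np.clip(1.0 - h, 1e-8, None))

    resid1 = np.full_like(mat, np.nan)
    masks = []
    for g in range(n_genes):
        mask = np.isfinite(mat[g])
        masks.append(mask)
        if mask.sum() < min_n:
            skipped += 1
            continue
        resid1[g, mask] = _fit(X[mask], f(mat[g, mask]))
    if skipped:
        warnings.warn(f"{skipped} genes skipped (< {min_n} branches)")
    # residuals below float-noise scale mean exact proportionality; zero
    # them so variance estimates cannot turn rounding error into weights
    tol = 1e-9 * max(1.0, float(np.nanmax(np.abs(f(np.nan_to_num(mat))))))
    resid1[np.abs(resid1) < tol] = 0.0

    if weighting == "branch-variance":
        # each branch is observed across many genes, so its residual
        # variance is directly estimable; sharper than master-length bins
        # when per-branch noise scales differ within a bin
        global_var = np.nanvar(resid1)
        if not np.isfinite(global_var) or global_var == 0:
            global_var = 1.0
        branch_var = np.full(X.size, global_var)
        counts = np.isfinite(resid1).sum(axis=0)
        est = np.nanvar(resid1, axis=0)
        ok = (counts >= 10) & np.isfinite(est) & (est > tol**2)
        branch_var[ok] = est[ok]
        weights = 1.0 / branch_var
    elif weighting == "binned-variance":
        # variance of first-pass residuals as a step function of master length
        edges = np.quantile(X, np.linspace(0, 1, n_bins + 1))
        edges[-1] += 1e-9
        bin_of = np.clip(np.searchsorted(edges, X, side="right") - 1, 0, n_bins - 1)
        global_var = np.nanvar(resid1)
        if not np.isfinite(global_var) or global_var == 0:
            global_var = 1.0
        bin_var = np.full(n_bins, global_var)
        for b in range(n_bins):
            vals = resid1[:, bin_of == b]
            vals = vals[np.isfinite(vals)]
            if vals.size >= 10 and vals.var() > tol**2:
                bin_var[b] = vals.var()
        weights = 1.0 / bin_var[bin_of]
    else:
        weights = np.ones_like(X)

    resid2 = np.full_like(mat, np.nan)
    for g in range(n_genes):
        mask = masks[g]
        if mask.sum() < min_n:
            continue
        resid2[g, mask] = _fit(X[mask], f(mat[g, mask]), weights[mask], studentize=True)
    resid2[np.abs(resid2) < tol] = 0.0
    if n_genes >= 20:
        # empirical rescaling: force each branch's residuals to unit
        # across-gene scale so ranks are comparable between branches
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col_sd = np.nanstd(resid2, axis=0)
            col_sd[~np.isfinite(col_sd) | (col_sd < tol)] = 1.0
            resid2 /= col_sd
    for g in range(n_genes):
        mask = masks[g]
        if mask.sum() < min_n:
            continue
        r = resid2[g, mask]
        s = r.std()
        out[g, mask] = r / s if s > tol else np.zeros(r.size)
    return pd.DataFrame(out, index=rates.data.index, columns=cols)


# -- Kendall correlation --------------------------------------------------


def _tau_numerator(x: np.ndarray, y: np.ndarray) -> float:
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    return float((sx * sy)[np.triu_indices(x.size, k=1)].sum())


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Tie-corrected Kendall tau-b with a two-sided p-value.

    The p-value is exact where an exact null is tractable: by permutation
    enumeration of the y ranks for n <= 9, and through the Mann–Whitney
    correspondence when one variable is binary and the other untied (for
    a 0/1 grouping |tau_b| is monotone in |U - m(n-m)/2|, so the exact U
    null gives the exact tau null).  Otherwise the standard tie-corrected
    normal approximation is used.  All-tied input is an error: tau is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined for all-tied input")
    res = stats.kendalltau(x, y, method="asymptotic")
    tau = float(res.statistic)
    if n <= EXACT_N_MAX:
        p = _exact_perm_p(x, y)
    else:
        p = _binary_exact_p(x, y)
        if p is None:
            p = _binary_exact_p(y, x)
        if p is None:
            p = float(res.pvalue)
    return tau, min(max(p, np.nextafter(0, 1)), 1.0)


def _binary_exact_p(x: np.ndarray, y: np.ndarray) -> float | None:
    """Exact two-sided p via Mann–Whitney when y is binary and x untied."""
    groups = np.unique(y)
    if groups.size != 2 or np.unique(x).size != x.size:
        return None
    res = stats.mannwhitneyu(
        x[y == groups[1]], x[y == groups[0]], alternative="two-sided", method="exact"
    )
    return float(res.pvalue)


def _exact_perm_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p: share of y-permutations with |T| >= |T_obs|.

    Permuting y fixes both tie structures, so the tau-b denominator is
    constant and numerators can be compared directly.
    """
    n = x.size
    t_obs = abs(_tau_numerator(x, y))
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu, ju = np.triu_indices(n, k=1)
    sxu = sx[iu, ju]
    perms = np.array(list(permutations(range(n))), dtype=np.int8)
    t_all = (sxu[None, :] * sy[perms[:, iu], perms[:, ju]]).sum(axis=1)
    hits = int((np.abs(t_all) >= t_obs - 1e-9).sum())
    return hits / len(perms)


def trait_association(
    rers: pd.DataFrame,
    foreground: Iterable[BranchID | str],
    alpha: float = 0.01,
    min_n: int = 10,
) -> list:
    """Kendall association of each gene's RERs with a foreground indicator.

    ``foreground`` names the branches carrying the phenotype (BranchIDs or
    branch keys), typically the terminal branches of one ecomorph's
    species.  Genes whose present branches are all foreground or all
    background, or that cover fewer than ``min_n`` branches, are skipped.
    """
    fg_keys = {
        b if isinstance(b, str) else branch_key(b) for b in foreground
    }
    if not fg_keys:
        raise ValueError("empty foreground")
    indicator = np.array([1.0 if c in fg_keys else 0.0 for c in rers.columns])
    out = []
    values = rers.to_numpy(dtype=float)
    for g, gene in enumerate(rers.index):
        mask = np.isfinite(values[g])
        if mask.sum() < min_n:
            continue
        ind = indicator[mask]
        if ind.min() == ind.max():
            continue
        tau, p = kendall_tau(values[g, mask], ind)
        out.append(
            GeneTraitAssociation(str(gene), tau, p, int(mask.sum()), bool(p <= alpha))
        )
    return out


def associations_to_frame(assocs: Iterable[GeneTraitAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": a.gene,
                "tau": a.tau,
                "p": a.p,
                "n_branches": a.n_branches,
                "significant": a.significant,
            }
            for a in assocs
        ]
    )
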