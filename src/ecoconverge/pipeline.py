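"""End-to-end driver: screen -> groups -> RER -> omega_c -> overlap ->
reuse -> enrichment, with input validation and a machine-readable summary.

Inputs either come from files (tree, screen TSV, rate matrix, omega_c
table, group maps, GMT) or are simulated in place from a seed; every
stage writes its table under the output directory and contributes to
``summary.json``.  Stage failures abort with a stage-tagged error;
degenerate outcomes that have a defined meaning (e.g. an empty gene set
making a regression impossible) are reported in the summary instead of
raising.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import convergence, enrichment, phylo, rer, reuse, screen, synth

log = logging.getLogger("ecoconverge")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    outdir: str = "ecoconverge_out"
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    sim: synth.SimConfig | None = None
    # ... or read files
    tree_path: str | None = None
    screen_path: str | None = None
    rates_path: str | None = None
    omega_path: str | None = None
    ecomorph_path: str | None = None
    region_path: str | None = None
    gmt_path: str | None = None
    # thresholds
    alpha_fdr: float = 0.05
    alpha_kendall: float = 0.01
    omega_c_min: float = 3.0
    q_enrich: float = 0.05
    min_taxa: int = 20
    randomization_draws: int = 200
    rer_min_n: int = 10
    rer_min_genes: int = 5

    def __post_init__(self):
        if self.sim is None:
            self.sim = synth.SimConfig(seed=self.seed)
        for name, lo, hi in (
            ("alpha_fdr", 0, 1),
            ("alpha_kendall", 0, 1),
            ("q_enrich", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must be in [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim is not None:
            if "term_size_range" in sim:
                sim["term_size_range"] = tuple(sim["term_size_range"])
            cfg.sim = synth.SimConfig(**sim)
        return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim = config.sim
        if sim.seed != config.seed:
            sim = synth.SimConfig(**{**asdict(sim), "seed": config.seed})
            sim.term_size_range = tuple(sim.term_size_range)
        data = synth.simulate_dataset(sim)
        return data
    tree = phylo.read_tree(config.tree_path)
    eco = phylo.read_group_map(config.ecomorph_path)
    reg = phylo.read_group_map(config.region_path) if config.region_path else {}
    records, unresolved = screen.read_screen_results(
        [config.screen_path], tree, dialect="tsv"
    )
    if unresolved:
        log.warning("%d unresolved branch names in screen input", len(unresolved))
    meta = screen.branch_metadata(tree, eco, reg)
    calls = screen.apply_fdr(records, alpha=config.alpha_fdr)
    matrix = screen.build_selection_matrix(calls, meta)
    rates = rer.RateMatrix.from_tsv(config.rates_path) if config.rates_path else None
    omega = (
        convergence.read_omega_c_tsv(config.omega_path) if config.omega_path else []
    )
    annotations = enrichment.read_gmt(config.gmt_path) if config.gmt_path else {}
    return synth.SimulatedData(
        config.sim, tree, eco, reg, pd.DataFrame(), rates, matrix, records,
        annotations, [], omega,
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return str(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": {
            "alpha_fdr": config.alpha_fdr,
            "alpha_kendall": config.alpha_kendall,
            "omega_c_min": config.omega_c_min,
            "q_enrich": config.q_enrich,
        },
    }

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("inputs")
        data = _load_inputs(config)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("inputs", e)

    matrix, tree = data.matrix, data.tree
    ecomorphs = sorted(
        set(matrix.meta["ecomorph"].dropna()) - {"outgroup"}
    )

    try:
        stage("screen")
        if config.simulate and config.alpha_fdr != data.config.alpha:
            calls = screen.apply_fdr(data.screen_records, alpha=config.alpha_fdr)
            matrix = screen.build_selection_matrix(
                calls, matrix.meta, genes=matrix.genes
            )
        matrix.to_tsv(outdir / "selection_matrix.tsv")
        bias = screen.branch_bias_check(matrix)
        summary["branch_bias"] = {
            "slope": bias.slope, "r_squared": bias.r_squared,
            "f_stat": bias.f_stat, "df": list(bias.df), "p": bias.p,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("screen", e)

    try:
        stage("groups")
        group_sets = {
            eco: convergence.genes_selected_in_group(matrix, eco) for eco in ecomorphs
        }
        for eco, gs in group_sets.items():
            gs.write(outdir / f"selected_{eco}.txt")
        summary["group_sizes"] = {eco: len(gs) for eco, gs in group_sets.items()}
        if len(ecomorphs) == 3:
            venn = convergence.venn_partition(*[group_sets[e] for e in ecomorphs])
            summary["venn_regions"] = venn.regions
            summary["exclusive_fraction"] = venn.exclusive_fraction
    except Exception as e:  # noqa: BLE001
        raise PipelineError("groups", e)

    rer_sets = {eco: convergence.GeneSet(eco, frozenset()) for eco in ecomorphs}
    try:
        stage("rer")
        if data.rates is not None:
            rer.compute_master_lengths(data.rates, min_genes=config.rer_min_genes)
            rers = rer.compute_rers(data.rates, min_n=config.rer_min_n)
            summary["rer_significant"] = {}
            for eco in ecomorphs:
                fg = [
                    frozenset([sp]) for sp in matrix.species_of_ecomorph(eco)
                ]
                assoc = rer.trait_association(
                    rers, fg, alpha=config.alpha_kendall, min_n=config.rer_min_n
                )
                frame = rer.associations_to_frame(assoc)
                with open(outdir / f"rer_association_{eco}.tsv", "w") as fh:
                    fh.write("# columns: gene, tau, p, n_branches, significant\n")
                    frame.to_csv(fh, sep="\t", index=False)
                sig = frozenset(a.gene for a in assoc if a.significant)
                rer_sets[eco] = convergence.GeneSet(f"rer_{eco}", sig)
                summary["rer_significant"][eco] = len(sig)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("rer", e)

    omega_sets = {eco: convergence.GeneSet(eco, frozenset()) for eco in ecomorphs}
    try:
        stage("omega_c")
        if data.omega_records:
            summary["omega_significant"] = {}
            for eco in ecomorphs:
                fg = [frozenset([sp]) for sp in matrix.species_of_ecomorph(eco)]
                gs = convergence.filter_omega_c(
                    data.omega_records, threshold=config.omega_c_min,
                    mode="any2spe", foreground=fg,
                )
                omega_sets[eco] = convergence.GeneSet(f"omega_{eco}", gs.genes)
                summary["omega_significant"][eco] = len(gs)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("omega_c", e)

    try:
        stage("overlap")
        summary["overlap"] = {}
        for eco in ecomorphs:
            ov = convergence.overlap_evidence(
                group_sets[eco], rer_sets[eco], omega_sets[eco]
            )
            summary["overlap"][eco] = {
                "selected_and_rer": ov["selected_and_rer"],
                "selected_and_omega": ov["selected_and_omega"],
                "rer_and_omega": ov["rer_and_omega"],
                "all_three": ov["all_three"],
            }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("overlap", e)

    try:
        stage("reuse")
        summary["reuse"] = {}
        try:
            records = reuse.build_pair_records(matrix, tree)
            frame = reuse.records_to_frame(records)
            with open(outdir / "pair_records.tsv", "w") as fh:
                fh.write(
                    "# columns: species_a, species_b, ecomorph, node_age,"
                    " shared_count, proportion\n"
                )
                frame.to_csv(fh, sep="\t", index=False)
            fit = reuse.reuse_regression(records)
            summary["reuse"]["all_pairs"] = {
                "n_pairs": len(records), "slope": fit.slope,
                "r_squared": fit.r_squared, "p": fit.p,
            }
            reuse.plot_reuse(records, outdir / "reuse.svg", fit)
            for eco in ecomorphs:
                n_eco = sum(1 for r in records if r.ecomorph == eco)
                if n_eco >= 3:
                    f = reuse.reuse_regression(records, group=eco)
                    summary["reuse"][eco] = {
                        "n_pairs": n_eco, "slope": f.slope,
                        "r_squared": f.r_squared, "p": f.p,
                    }
        except ValueError as e:
            summary["reuse"]["error"] = str(e)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("reuse", e)

    try:
        stage("enrichment")
        if data.annotations:
            background = convergence.GeneSet("screened", frozenset(matrix.genes))
            summary["enrichment"] = {}
            for eco in ecomorphs:
                if not len(group_sets[eco]):
                    summary["enrichment"][eco] = {"error": "empty study set"}
                    continue
                recs = enrichment.hypergeom_enrich(
                    group_sets[eco], background, data.annotations,
                    alpha=config.q_enrich,
                )
                frame = enrichment.records_to_frame(recs)
                with open(outdir / f"enrichment_{eco}.tsv", "w") as fh:
                    fh.write("# columns: term, name, k, K, n, N, p, q, log_q, significant\n")
                    frame.to_csv(fh, sep="\t", index=False)
                sig = sorted(r.term for r in recs if r.significant)
                rand = enrichment.randomization_test(
                    group_sets[eco], background, data.annotations,
                    seed=config.seed, terms=sig or None,
                    draws=max(100, config.randomization_draws),
                )
                summary["enrichment"][eco] = {
                    "n_significant": len(sig),
                    "significant_terms": sig,
                    "randomization_empirical_p": {
                        r.term: r.empirical_p for r in rand if r.term in set(sig)
                    },
                }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("enrichment", e)

    payload = json.dumps(_jsonable(summary), indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(payload + "\n")
    log.info("wrote %s", outdir / "summary.json")
    return summary


def validate_inputs(config: RunConfig) -> list:
    """Cross-check tree, matrices and maps; returns (level, message) entries.

    Levels: ``fatal`` (inconsistent identifiers) and ``warning``.
    An empty report means the bundle is internally consistent.
    """
    report: list[tuple] = []
    if config.simulate:
        data = synth.simulate_dataset(config.sim)
        tree, eco, matrix = data.tree, data.ecomorph_map, data.matrix
        rates = data.rates
    else:
        try:
            tree = phylo.read_tree(config.tree_path)
        except Exception as e:  # noqa: BLE001
            return [("fatal", f"tree unreadable: {e}")]
        eco = phylo.read_group_map(config.ecomorph_path) if config.ecomorph_path else {}
        matrix = None
        rates = rer.RateMatrix.from_tsv(config.rates_path) if config.rates_path else None

    tips = tree.tips
    for sp in eco:
        if sp not in tips:
            report.append(("fatal", f"species {sp!r} in ecomorph map but not in tree"))
    for sp in tips:
        if sp not in eco:
            report.append(("fatal", f"tip {sp!r} missing from ecomorph map"))
    valid_keys = {phylo.branch_key(b) for b in tree.branch_ids()}
    for source, cols in (
        ("selection matrix", matrix.data.columns if matrix is not None else []),
        ("rate matrix", rates.data.columns if rates is not None else []),
    ):
        for col in cols:
            if col not in valid_keys and not set(col.split("|")) <= tips:
                report.append(("warning", f"{source} column {col!r} matches no tree branch"))
    if not config.simulate and config.screen_path:
        try:
            _, unresolved = screen.read_screen_results([config.screen_path], tree)
            for gene, name in unresolved[:50]:
                report.append(("warning", f"screen branch {name!r} (gene {gene}) unresolved"))
        except Exception as e:  # noqa: BLE001
            report.append(("fatal", f"screen results unreadable: {e}"))
    return report
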