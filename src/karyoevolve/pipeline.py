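"""End-to-end demo pipeline: simulate -> sex-linkage -> elements -> dosage -> enrichment.

Every stage writes provenance-stamped TSVs; a fixed seed makes the whole run
byte-identical.  Stage-local seeds are derived deterministically from the
global seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import covsex, dosagex, elements, io, simdata

__all__ = ["run_pipeline", "stage_seeds"]


def stage_seeds(seed: int, n: int = 6) -> list[int]:
    """Deterministic per-stage seeds derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _focal_tip(history: simdata.KaryotypeHistory) -> str:
    """Default focal species: the tip closest to the root (fewest expected events)."""
    best, best_dist = None, None
    for leaf in history.tree.leaf_node_iter():
        dist = 0.0
        node = leaf
        while node.parent_node is not None:
            dist += node.edge.length or 0.0
            node = node.parent_node
        name = leaf.taxon.label
        if best_dist is None or dist < best_dist or (dist == best_dist and name < best):
            best, best_dist = name, dist
    return best


def _coverage_tip(history: simdata.KaryotypeHistory, focal: str) -> str:
    """Default coverage tip: one with a fused (multi-element) X if any, else the focal."""
    for name in sorted(history.tips):
        tip = history.tips[name]
        for chrom in tip.chroms_with_element("X"):
            if len(tip.element_content(chrom)) > 1:
                return name
    non_focal = [t for t in sorted(history.tips) if t != focal]
    return non_focal[0] if non_focal else focal


def run_pipeline(config: io.PipelineConfig, outdir: Union[str, Path]) -> dict[str, object]:
    """Run every stage on synthetic data and write all result tables.

    Returns a dict with output paths and per-stage summary counts.  Any
    stage failure raises with the stage name attached.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    meta_base = {"seed": config.seed, "config_hash": config.config_hash()}
    paths: dict[str, Path] = {}
    log: dict[str, object] = {}
    stage = "simulate"
    try:
        history = simdata.simulate_karyotype_history(
            config.tree,
            n_elements=config.n_elements,
            genes_per_element=config.genes_per_element,
            fusion_rate=config.fusion_rate,
            fission_rate=config.fission_rate,
            seed=seeds[0],
        )
        table = simdata.simulate_ortholog_table(history, config.shuffle_rate, seed=seeds[1])
        paths["orthologs"] = out / "orthologs.tsv"
        io.write_ortholog_table(table, paths["orthologs"], meta=dict(meta_base, stage=stage))
        truth = history.truth_table()
        paths["truth"] = out / "truth_genes.tsv"
        io.write_table(truth, paths["truth"], meta=dict(meta_base, stage=stage))
        log["simulate"] = {
            "tips": len(history.tips),
            "genes": history.tips[next(iter(history.tips))].gene_count(),
            "events": sum(len(v) for v in history.events.values()),
        }

        stage = "sexlink"
        focal = config.focal or _focal_tip(history)
        cov_tip_name = config.coverage_tip or _coverage_tip(history, focal)
        cov_tip = history.tips[cov_tip_name]
        spec = simdata.coverage_spec_from_tip(cov_tip, genes_per_window=config.genes_per_window)
        for i in range(config.n_y_scaffolds):
            spec[f"scafY{i + 1}"] = [("Y", config.y_windows_each)]
        params = simdata.CoverageSimParams(
            window_size=config.window_size,
            mean_depth_f=config.depth_f,
            mean_depth_m=config.depth_m,
            dispersion=config.dispersion,
            theta=config.theta,
            seed=seeds[2],
        )
        sim = simdata.simulate_coverage(spec, params)
        paths["female_bedgraph"] = out / "female.bedgraph"
        paths["male_bedgraph"] = out / "male.bedgraph"
        io.write_bedgraph(sim.female, paths["female_bedgraph"])
        io.write_bedgraph(sim.male, paths["male_bedgraph"])
        # read back through the parser so the on-disk path is the one tested
        cov_f = io.read_bedgraph(paths["female_bedgraph"])
        cov_m = io.read_bedgraph(paths["male_bedgraph"])
        windows = covsex.make_windows(sim.chrom_sizes(), config.window_size)
        wf = covsex.window_medians(cov_f, windows)
        wm = covsex.window_medians(cov_m, windows)
        ratios = covsex.fm_ratio(wf, wm, normalization=config.normalization,
                                 min_m_depth=config.min_m_depth)
        calls = covsex.classify_scaffolds(
            ratios, x_threshold=config.x_threshold, y_threshold=config.y_threshold,
            min_windows=config.min_windows,
        )
        paths["windows"] = out / "windows.tsv"
        io.write_table(ratios.windows, paths["windows"], meta=dict(meta_base, stage=stage))
        paths["scaffold_calls"] = out / "scaffold_calls.tsv"
        io.write_table(calls, paths["scaffold_calls"], meta=dict(meta_base, stage=stage))
        x_chroms = cov_tip.chroms_with_element("X")
        bp_rows = []
        breakpoint_bp: int | None = None
        x_chrom = x_chroms[0] if x_chroms else None
        for chrom in x_chroms:
            n_ok = int(((ratios.windows["chrom"] == chrom)
                        & (ratios.windows["flag"] == "")).sum())
            if n_ok < 10:
                continue
            est = covsex.detect_breakpoint(ratios, chrom, x_threshold=config.x_threshold,
                                           y_threshold=config.y_threshold)
            bp_rows.append(
                (chrom, est.found, est.position, est.boundary_index, est.n_windows,
                 est.left_class, est.right_class,
                 round(est.left_mean_log2, 6), round(est.right_mean_log2, 6),
                 est.ci[0] if est.ci else "", est.ci[1] if est.ci else "",
                 round(est.gain, 6))
            )
            if est.found and chrom == x_chrom:
                breakpoint_bp = est.position
        bp_df = pd.DataFrame(
            bp_rows,
            columns=["chrom", "found", "position", "boundary_index", "n_windows",
                     "left_class", "right_class", "left_mean_log2", "right_mean_log2",
                     "ci_lo", "ci_hi", "gain"],
        )
        paths["breakpoints"] = out / "breakpoints.tsv"
        io.write_table(bp_df, paths["breakpoints"], meta=dict(meta_base, stage=stage))
        log["sexlink"] = {
            "windows": len(ratios.windows),
            "scaffolds": len(calls),
            "x_called": int((calls["call"] == "X_linked").sum()),
            "y_called": int((calls["call"] == "Y_linked").sum()),
            "breakpoints_found": int(bp_df["found"].sum()) if len(bp_df) else 0,
        }

        stage = "elements"
        targets = [t for t in sorted(history.tips) if t != focal]
        matrices = {t: elements.build_homology_matrix(table, focal, t) for t in targets}
        focal_tip = history.tips[focal]
        focal_x_chroms = focal_tip.chroms_with_element("X")
        focal_x = focal_x_chroms[0] if focal_x_chroms else None
        assignment = elements.assign_elements(
            matrices, min_orthologs=config.min_orthologs,
            majority_frac=config.majority_frac, focal_x=focal_x,
        )
        comp = elements.composition_table(assignment)
        paths["composition"] = out / "composition.tsv"
        io.write_table(comp, paths["composition"], meta=dict(meta_base, stage=stage), index=True)
        ev_rows = [
            (sp, ec.n_fusions, ec.n_fissions)
            for sp in targets
            for ec in [elements.count_events(assignment, sp)]
        ]
        ev_df = pd.DataFrame(ev_rows, columns=["species", "n_fusions", "n_fissions"])
        paths["events"] = out / "events.tsv"
        io.write_table(ev_df, paths["events"], meta=dict(meta_base, stage=stage))
        if cov_tip_name in matrices:
            neo = elements.detect_neo_sex_elements(assignment, calls, cov_tip_name)
        else:
            neo = pd.DataFrame(columns=["element", "focal_lg", "n_x_orthologs", "kind"])
        paths["sex_elements"] = out / "sex_elements.tsv"
        io.write_table(neo, paths["sex_elements"], meta=dict(meta_base, stage=stage))
        log["elements"] = {
            "assigned": len(assignment.assigned_lgs()),
            "unassigned": len(assignment.lgs) - len(assignment.assigned_lgs()),
            "sex_linked_elements": len(neo),
        }

        stage = "dosage"
        genes = simdata.expression_genes_from_tip(cov_tip)
        expr_params = simdata.ExpressionSimParams(dc_mode=config.dc_mode, seed=seeds[3])
        sim_expr = simdata.simulate_expression(genes, expr_params)
        paths["expression"] = out / "expression.tsv"
        io.write_table(sim_expr.matrix, paths["expression"], meta=dict(meta_base, stage=stage),
                       index=True)
        paths["samples"] = out / "samples.tsv"
        io.write_table(sim_expr.samples, paths["samples"], meta=dict(meta_base, stage=stage))
        bp_per_gene = config.window_size / config.genes_per_window
        gene_coords = genes.assign(position=(genes["position"] * bp_per_gene).astype(int))
        partition = dosagex.partition_genes(gene_coords, x_chrom=x_chroms,
                                            breakpoint_bp=breakpoint_bp)
        filtered, counts = dosagex.filter_expressed(
            sim_expr.matrix, sim_expr.samples,
            {"sex": "M", "compartment": "soma"}, {"sex": "F", "compartment": "soma"},
            min_value=config.min_fpkm,
        )
        result = dosagex.dosage_compare(filtered, sim_expr.samples, partition,
                                        compartment="soma", alpha=config.alpha)
        paths["dosage_summary"] = out / "dosage_summary.tsv"
        io.write_table(result.summary, paths["dosage_summary"],
                       meta=dict(meta_base, stage=stage, family_size=result.family_size,
                                 **counts))
        pw = result.pairwise.copy()
        pw["group1"] = ["/".join(g) for g in pw["group1"]]
        pw["group2"] = ["/".join(g) for g in pw["group2"]]
        paths["dosage_pairwise"] = out / "dosage_pairwise.tsv"
        io.write_table(pw, paths["dosage_pairwise"], meta=dict(meta_base, stage=stage))
        log["dosage"] = dict(counts, strata=len(result.summary))

        stage = "enrich"
        bias = dosagex.classify_gonad_bias(sim_expr.matrix, sim_expr.samples, fold=config.fold)
        paths["bias_calls"] = out / "bias_calls.tsv"
        io.write_table(bias.rename_axis("gene").reset_index(), paths["bias_calls"],
                       meta=dict(meta_base, stage=stage))
        enrich = dosagex.test_enrichment(bias, partition, alpha=config.alpha)
        paths["enrichment"] = out / "enrichment.tsv"
        io.write_table(enrich, paths["enrichment"],
                       meta=dict(meta_base, stage=stage, family_size=enrich.attrs["family_size"]))
        log["enrich"] = {
            "ovary_biased": int((bias == "ovary").sum()),
            "testis_biased": int((bias == "testis").sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_lines = [f"{st}: " + ", ".join(f"{k}={v}" for k, v in rec.items())
                 for st, rec in log.items()]
    paths["log"] = out / "pipeline_log.txt"
    with open(paths["log"], "w") as fh:
        fh.write(f"# seed={config.seed} config_hash={config.config_hash()}\n")
        fh.write("\n".join(log_lines) + "\n")
    return {"paths": {k: str(v) for k, v in paths.items()}, "log": log,
            "focal": focal, "coverage_tip": cov_tip_name}
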