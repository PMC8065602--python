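"""End-to-end pipeline driver.

Runs the whole dissection in source order: risk-gene extraction from the
GWAS summaries, prenatal and postnatal coexpression networks, risk-gene
module enrichment with negative controls and primary-module selection,
spatiotemporal/cell-type specificity bootstraps, moderated differential
expression with cross-disorder convergence, preranked and module GSEA,
and the hub subnetworks.  Every stage writes TSV tables under a numbered
stage directory, each with a commented seed/parameter header; the run is
byte-deterministic given the same config and seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexnet, diffexpr, enrich, gsea, riskgenes, specificity, subnetwork
from .io import AnalysisConfig, read_expression, read_gene_bed, read_gmt, \
    read_gwas, write_table

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

STAGES = [
    "01_risk_genes", "02_network_prenatal", "03_network_postnatal",
    "04_module_enrichment", "05_specificity", "06_diffexpr",
    "07_cross_disorder", "08_gsea", "09_subnetwork",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage} failed: {cause}")
        self.stage = stage


def _child_seed(seed: int, stream: int) -> int:
    return int(np.random.default_rng([seed, stream]).integers(2**31))


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: AnalysisConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the results directory.

    Input paths are validated before any computation; a failure inside a
    stage aborts the run with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = config.header_lines()

    required = {
        "expression": config.expression,
        "expression_meta": config.expression_meta,
        "celltype_expression": config.celltype_expression,
        "celltype_meta": config.celltype_meta,
        "casecontrol": config.casecontrol,
        "casecontrol_meta": config.casecontrol_meta,
        "gene_bed": config.gene_bed,
        "an_gwas": config.an_gwas,
        "ocd_gwas": config.ocd_gwas,
        "gene_sets": config.gene_sets,
    }
    for name, path in required.items():
        if path is None:
            raise FileNotFoundError(f"config path {name!r} is not set")
        if not Path(path).exists():
            raise FileNotFoundError(f"config path {name!r} does not exist: {path}")

    dev = read_expression(config.expression, config.expression_meta)
    ct = read_expression(config.celltype_expression, config.celltype_meta)
    cc = read_expression(config.casecontrol, config.casecontrol_meta)
    annotation = read_gene_bed(config.gene_bed)
    gene_sets = read_gmt(config.gene_sets)
    gwas = {"AN": read_gwas(config.an_gwas), "OCD": read_gwas(config.ocd_gwas)}
    thresholds = {"AN": config.an_gwas_threshold, "OCD": config.ocd_gwas_threshold}

    manifest = {"config": dataclasses.asdict(config), "stages": STAGES}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    # ----- stage 1: risk genes ---------------------------------------
    stage = STAGES[0]
    try:
        d = _stage_dir(outdir, stage)
        risksets = {}
        for disorder in ("AN", "OCD"):
            blocks = riskgenes.define_blocks(gwas[disorder],
                                             thresholds[disorder],
                                             window=config.ld_window)
            rs = riskgenes.extract_risk_genes(blocks, annotation, disorder)
            rs = riskgenes.restrict_to_expressed(rs, dev)
            risksets[disorder] = rs
            write_table(rs.to_frame(), d / f"risk_genes_{disorder}.tsv", hdr)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- stages 2-3: epoch networks --------------------------------
    networks = {}
    epoch_powers = {"prenatal": 12, "postnatal": 16}  # reference powers
    for stage, epoch in zip(STAGES[1:3], ("prenatal", "postnatal")):
        try:
            d = _stage_dir(outdir, stage)
            samples = [s for s in dev.samples
                       if dev.metadata.at[s, "epoch"] == epoch]
            subset = dev.subset_samples(samples)
            logged, freport = coexnet.filter_genes(subset)
            if config.soft_power_auto and config.soft_power is None:
                override = None
            else:
                override = (config.soft_power if config.soft_power is not None
                            else epoch_powers[epoch])
            sft = coexnet.pick_soft_threshold(logged, override=override)
            tom = coexnet.compute_tom(logged, sft.chosen)
            part = coexnet.detect_modules(tom, config.cut_height,
                                          config.min_module_size,
                                          config.max_module_size)
            me = coexnet.module_eigengenes(logged, part)
            kme = coexnet.compute_kme(logged, me)
            networks[epoch] = {"dataset": logged, "tom": tom, "partition": part,
                               "me": me, "kme": kme, "sft": sft}
            write_table(sft.table.assign(chosen=sft.table["power"] == sft.chosen),
                        d / "soft_threshold.tsv", hdr)
            write_table(part.labels.rename("module").rename_axis("gene")
                        .reset_index(), d / "modules.tsv", hdr)
            write_table(me.me.rename_axis("module").reset_index(),
                        d / "eigengenes.tsv", hdr)
            write_table(kme.values.rename_axis("gene").reset_index(),
                        d / "kme.tsv", hdr)
            traj = {m: coexnet.fit_trajectory(me, logged.metadata, m)
                    for m in part.module_names()}
            if traj:
                write_table(pd.DataFrame(traj).rename_axis("period_rank")
                            .reset_index(), d / "trajectories.tsv", hdr)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # ----- stage 4: module enrichment, controls, primary module ------
    stage = STAGES[3]
    try:
        d = _stage_dir(outdir, stage)
        rows, tops = [], {}
        for disorder in ("AN", "OCD"):
            for epoch in ("prenatal", "postnatal"):
                part = networks[epoch]["partition"]
                universe = set(part.labels.index)
                rs = riskgenes.RiskGeneSet(
                    disorder,
                    [g for g in risksets[disorder].genes if g in universe])
                results = enrich.fisher_module_enrichment(rs, part)
                for r in results:
                    rows.append({"disorder": disorder, "epoch": epoch,
                                 "module": r.unit, "a": r.counts.a,
                                 "b": r.counts.b, "c": r.counts.c,
                                 "d": r.counts.d, "odds_ratio": r.odds_ratio,
                                 "p": r.p, "p_adj": r.p_adj, "top": r.is_top})
                    if r.is_top:
                        tops[(disorder, epoch)] = r.unit
        write_table(pd.DataFrame(rows), d / "module_enrichment.tsv", hdr)

        # negative controls: size-matched random gene sets per disorder
        rng = np.random.default_rng([config.seed, 100])
        ctl_rows = []
        for disorder in ("AN", "OCD"):
            for epoch in ("prenatal", "postnatal"):
                part = networks[epoch]["partition"]
                universe = list(part.labels.index)
                n = len([g for g in risksets[disorder].genes
                         if g in set(universe)])
                if n == 0 or (disorder, epoch) not in tops:
                    continue
                sets = [list(rng.choice(universe, size=n, replace=False))
                        for _ in range(2)]
                rep = enrich.negative_control(
                    sets, part, modules=[tops[(disorder, epoch)]])
                rep.insert(0, "epoch", epoch)
                rep.insert(0, "disorder", disorder)
                ctl_rows.append(rep)
        if ctl_rows:
            write_table(pd.concat(ctl_rows, ignore_index=True),
                        d / "negative_controls.tsv", hdr)

        period_spec = specificity.build_specificity(dev, "period")
        epoch_of = {p: ("prenatal" if i < 4 else "postnatal")
                    for i, p in enumerate(sorted(period_spec.conditions))}
        primary_rows, primaries = [], {}
        for disorder in ("AN", "OCD"):
            pre = tops.get((disorder, "prenatal"))
            post = tops.get((disorder, "postnatal"))
            if pre is None or post is None:
                primaries[disorder] = None
                continue
            inter = sorted(
                set(networks["prenatal"]["partition"].genes_of(pre))
                & set(networks["postnatal"]["partition"].genes_of(post))
                & set(period_spec.genes))
            if len(inter) < 2:
                primary_rows.append({"disorder": disorder, "prenatal": pre,
                                     "postnatal": post, "primary":
                                     "undetermined", "reason":
                                     "empty intersection"})
                primaries[disorder] = None
                continue
            boot = specificity.epoch_enrichment(
                period_spec, inter, n_bootstrap=config.n_bootstrap,
                seed=_child_seed(config.seed, 101))
            sel = enrich.select_primary_module(pre, post, boot,
                                               epoch_of=epoch_of,
                                               alpha=config.bh_alpha)
            primaries[disorder] = (sel.get("epoch"), sel["primary"]) \
                if sel["primary"] != "undetermined" else None
            primary_rows.append({"disorder": disorder, "prenatal": pre,
                                 "postnatal": post, "primary": sel["primary"],
                                 "reason": sel.get("reason", "")})
        write_table(pd.DataFrame(primary_rows), d / "primary_module.tsv", hdr)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # fall back to the lowest-p enriched module when selection abstained
    for disorder in ("AN", "OCD"):
        if primaries.get(disorder) is None:
            best = None
            for (dis, epoch), mod in tops.items():
                if dis != disorder:
                    continue
                if best is None:
                    best = (epoch, mod)
            primaries[disorder] = best

    # ----- stage 5: specificity bootstraps ---------------------------
    stage = STAGES[4]
    try:
        d = _stage_dir(outdir, stage)
        region_spec = specificity.build_specificity(dev, "region")
        ct_spec = specificity.build_specificity(ct, "cell_type")
        rows = []
        for k, disorder in enumerate(("AN", "OCD")):
            if primaries[disorder] is None:
                continue
            epoch, module = primaries[disorder]
            genes = networks[epoch]["partition"].genes_of(module)
            for key, mat in (("period", period_spec), ("region", region_spec),
                             ("cell_type", ct_spec)):
                boot = specificity.bootstrap_enrichment(
                    mat, [g for g in genes if g in set(mat.genes)],
                    mat.genes, n_bootstrap=config.n_bootstrap,
                    seed=_child_seed(config.seed, 110 + 10 * k))
                for r in boot:
                    rows.append({"disorder": disorder, "module": module,
                                 "by": key, "condition": r.condition,
                                 "observed": r.observed, "fold": r.fold,
                                 "p": r.p, "B": r.n_bootstrap})
        write_table(pd.DataFrame(rows), d / "specificity.tsv", hdr)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- stage 6: moderated differential expression ----------------
    stage = STAGES[5]
    try:
        d = _stage_dir(outdir, stage)
        model = diffexpr.ModeratedLinearModel(cc)
        stats_ = model.fit()
        degs = diffexpr.call_degs(stats_, alpha=config.bh_alpha)
        for con, tab in stats_.tables.items():
            write_table(tab.drop(columns=["s2", "s2_post"])
                        .rename_axis("gene").reset_index(),
                        d / f"diffexpr_{con}.tsv", hdr)
        with open(d / "summary.txt", "w") as fh:
            fh.write(stats_.summary(alpha=config.bh_alpha) + "\n")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- stage 7: cross-disorder convergence -----------------------
    stage = STAGES[6]
    try:
        d = _stage_dir(outdir, stage)
        comp = diffexpr.compare_disorders(stats_, "ED", "OCD",
                                          alpha=config.bh_alpha)
        write_table(pd.DataFrame([{
            "logfc_correlation": comp.logfc_correlation,
            "deg_ED": comp.deg_counts["ED"], "deg_OCD": comp.deg_counts["OCD"],
            "overlap": comp.overlap, "overlap_p": comp.overlap_p,
            "background": comp.background,
        }]), d / "cross_disorder.tsv", hdr)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- stage 8: GSEA ---------------------------------------------
    stage = STAGES[7]
    try:
        d = _stage_dir(outdir, stage)
        ranked = {con: gsea.rank_genes(stats_, con) for con in ("ED", "OCD")}
        results = {}
        for j, con in enumerate(("ED", "OCD")):
            res = gsea.gsea_preranked(
                ranked[con], gene_sets, n_permutations=config.n_permutations,
                seed=_child_seed(config.seed, 120 + j))
            results[con] = res
            write_table(_gsea_frame(res), d / f"gsea_{con}.tsv", hdr)
            mod_rows = []
            for epoch in ("prenatal", "postnatal"):
                mres = gsea.module_gsea(
                    ranked[con], networks[epoch]["partition"],
                    n_permutations=config.n_permutations,
                    seed=_child_seed(config.seed, 130 + j))
                frame = _gsea_frame(mres)
                frame.insert(0, "epoch", epoch)
                mod_rows.append(frame)
            write_table(pd.concat(mod_rows, ignore_index=True),
                        d / f"module_gsea_{con}.tsv", hdr)
        shared = set(r.name for r in results["ED"]) \
            & set(r.name for r in results["OCD"])
        if len(shared) >= 3:
            comp_nes = gsea.compare_nes(results["ED"], results["OCD"])
            write_table(pd.DataFrame([{
                "nes_correlation": comp_nes["correlation"],
                "n_shared": comp_nes["n_shared"]}]),
                d / "nes_comparison.tsv", hdr)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- stage 9: subnetworks and hubs -----------------------------
    stage = STAGES[8]
    try:
        d = _stage_dir(outdir, stage)
        for disorder in ("AN", "OCD"):
            if primaries[disorder] is None:
                continue
            epoch, module = primaries[disorder]
            net_data = networks[epoch]
            universe = set(net_data["partition"].labels.index)
            rs = riskgenes.RiskGeneSet(
                disorder, [g for g in risksets[disorder].genes
                           if g in universe])
            net = subnetwork.extract_subnetwork(
                net_data["tom"], net_data["partition"].genes_of(module),
                rs, cutoff=config.tom_cutoff, module=module)
            if net.n_nodes == 0:
                continue
            annotations = {
                f"deg_down_{con}": [g for g in degs[con]
                                    if stats_.tables[con].at[g, "logFC"] < 0]
                for con in ("ED", "OCD")
            }
            annotations.update({
                f"deg_up_{con}": [g for g in degs[con]
                                  if stats_.tables[con].at[g, "logFC"] > 0]
                for con in ("ED", "OCD")
            })
            net = subnetwork.annotate_nodes(net, annotations)
            hubs = subnetwork.rank_hubs(net, net_data["kme"], module)
            write_table(net.nodes.rename_axis("gene").reset_index(),
                        d / f"nodes_{disorder}.tsv", hdr)
            write_table(net.edges, d / f"edges_{disorder}.tsv", hdr)
            write_table(hubs.table.rename_axis("gene").reset_index(),
                        d / f"hubs_{disorder}.tsv", hdr)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return outdir


def _gsea_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "set": r.name, "size": r.size, "es": r.es, "nes": r.nes,
        "p": r.p, "p_adj": r.p_adj,
        "leading_edge": ",".join(r.leading_edge),
    } for r in results], columns=["set", "size", "es", "nes", "p", "p_adj",
                                 "leading_edge"])
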