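"""End-to-end orchestration: simulate/load -> classify -> operons ->
discover -> scan -> refine -> report.

``run_all`` executes the whole regulon-inference analysis under a single
structured config and a single seed, writing per-stage outputs, a run
manifest sufficient to reproduce the run, and a regulon table in the
journal style (lead locus, gene name, box centre, promoter class,
description, operon span; "ND" where no TSS was mapped).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import assignments_to_frame, classify_all
from .io import (
    Category,
    Thresholds,
    load_config,
    read_annotation,
    read_expression_table,
    read_overrides,
    read_tss_table,
    write_motif,
    write_sites_bed,
)
from .motifs import consensus_string
from .operons import (
    DEFAULT_MAX_GAP,
    DEFAULT_UPSTREAM_LENGTH,
    annotate_site,
    build_operons,
    extract_gene_upstream,
    extract_upstream,
)
from .scanner import refine
from .simulate import SimConfig, simulate

CATEGORY_SET = {Category.CAT1.value, Category.CAT2.value, Category.CAT3.value,
                Category.CAT4.value, Category.CAT5.value}


@dataclass
class RunManifest:
    """Reproducibility record of a completed (or aborted) run."""

    version: str
    seed: int
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    timestamp: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, default=str)

    def comparable(self) -> dict:
        d = dict(self.__dict__)
        d.pop("timestamp", None)
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _ratio(x, num: str, den: Optional[str] = None):
    v = getattr(x, num)
    if v is None:
        return None
    if den is None:
        return v
    w = getattr(x, den)
    if w is None:
        return None
    return v / w


def run_all(config: dict | str | Path, out_dir: str | Path, seed: int = 0) -> RunManifest:
    """Run the full pipeline; returns the manifest (also written to disk).

    ``config`` keys (all optional):

    * ``inputs``: either ``{"synthetic": {... SimConfig overrides ...}}``
      (default) or paths ``{"genome", "annotation", "tss", "expression"}``;
    * ``thresholds``: t_ind/t_unaff/t_diff/t_up;
    * ``overrides``: path of a per-gene label override TSV;
    * ``operons``: ``max_gap``;
    * ``promoters``: ``length``;
    * ``discovery``: width/palindromic/restarts/n_motifs;
    * ``scan``: p_max/keep_distal/genome_wide;
    * ``stages``: ``{"motifs": false}`` stops after classification.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=seed, config=cfg,
                           timestamp=time.time())
    th = Thresholds(**cfg.get("thresholds", {}))
    stages_cfg = cfg.get("stages", {})

    # ---- stage: inputs ----------------------------------------------------
    inputs = cfg.get("inputs", {})
    if "expression" in inputs:
        genes = read_annotation(inputs["annotation"])
        tss = read_tss_table(inputs["tss"])
        expression = read_expression_table(inputs["expression"],
                                           cfg.get("expression_columns"))
        import pyfaidx

        genome = pyfaidx.Fasta(inputs["genome"])
        for key in ("genome", "annotation", "tss", "expression"):
            manifest.input_checksums[key] = _sha256(inputs[key])
        truth = None
    else:
        sim_overrides = dict(inputs.get("synthetic", {}))
        sim_overrides.setdefault("seed", seed)
        sim = simulate(SimConfig(**sim_overrides), out_dir=out / "inputs")
        genes, tss, expression, truth = sim.genes, sim.tss, sim.expression, sim.truth
        genome = {sim.config.contig: sim.genome}
        for key, path in sim.paths.items():
            manifest.input_checksums[key] = _sha256(path)
    manifest.stages.append({"stage": "inputs", "status": "done",
                            "n_genes": len(genes), "n_tss": len(tss)})

    # ---- stage: classification -------------------------------------------
    overrides = read_overrides(cfg["overrides"]) if cfg.get("overrides") else None
    assignments, summary = classify_all(expression, th, overrides=overrides)
    adf = assignments_to_frame(assignments)
    adf.to_csv(out / "assignments.tsv", sep="\t", index=False)
    (out / "classification_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.stages.append({"stage": "classify", "status": "done",
                            "summary": summary,
                            "outputs": ["assignments.tsv", "classification_summary.json"]})
    if stages_cfg.get("motifs", True) is False:
        manifest.stages.append({"stage": "motifs", "status": "skipped",
                                "reason": "disabled in config"})
        (out / "manifest.json").write_text(manifest.to_json())
        return manifest

    # ---- stage: operons & promoters --------------------------------------
    max_gap = cfg.get("operons", {}).get("max_gap", DEFAULT_MAX_GAP)
    operons = build_operons(genes, tss, max_gap=max_gap)
    genes_by_id = {g.gene_id: g for g in genes}
    odf = pd.DataFrame(
        [{"operon_id": op.operon_id, "span": op.span, "strand": op.strand,
          "lead_gene": op.lead_gene, "n_genes": len(op.gene_ids),
          "tss": op.tss.position if op.tss else "ND",
          "genes": ",".join(op.gene_ids)} for op in operons]
    )
    odf.to_csv(out / "operons.tsv", sep="\t", index=False)

    label_by_gene = {a.gene_id: a.label.value for a in assignments}
    expr_by_gene = {x.gene_id: x for x in expression}

    def operon_has(pred) -> list:
        sel = []
        for op in operons:
            for gid in op.gene_ids:
                x = expr_by_gene.get(gid)
                if x is not None and pred(gid, x):
                    sel.append(op)
                    break
        return sel

    nf_ge = lambda gid, x: (v := _ratio(x, "N", "F")) is not None and v >= th.t_diff
    seed_ops = operon_has(nf_ge)
    category_ops = [op for op in operons
                    if any(label_by_gene.get(g) in CATEGORY_SET for g in op.gene_ids)]
    fnr_down_ops = operon_has(
        lambda gid, x: x.F is not None and x.F <= 1 / th.t_ind)

    length = cfg.get("promoters", {}).get("length", DEFAULT_UPSTREAM_LENGTH)
    prom_of = {}
    for op in {o.operon_id: o for o in (seed_ops + category_ops + fnr_down_ops)}.values():
        prom_of[op.operon_id] = extract_upstream(op, genes_by_id, genome, length=length)
    with open(out / "promoters.fasta", "w") as fh:
        for pid in sorted(prom_of):
            fh.write(f">{pid}\n{prom_of[pid].sequence}\n")
    manifest.stages.append({"stage": "operons", "status": "done",
                            "n_operons": len(operons), "n_seed": len(seed_ops),
                            "outputs": ["operons.tsv", "promoters.fasta"]})

    # ---- stage: discovery + refinement -----------------------------------
    disc_cfg = cfg.get("discovery", {})
    scan_cfg = cfg.get("scan", {})
    p_max = scan_cfg.get("p_max", 1e-4)
    seed_proms = [prom_of[o.operon_id] for o in seed_ops]
    all_proms = [prom_of[o.operon_id] for o in category_ops]

    target_sets: dict[str, list] = {
        "nf_upregulated_operons": seed_proms,
        "fnr_downregulated_operons": [prom_of[o.operon_id] for o in fnr_down_ops],
    }
    up_genes = [gid for gid, x in expr_by_gene.items()
                if x.F is not None and x.F >= th.t_ind]
    tss_by_gene = {t.assigned_gene: t for t in tss if t.assigned_gene}
    target_sets["fnr_upregulated_genes"] = [
        extract_gene_upstream(genes_by_id[g], genome, length=length,
                              tss=tss_by_gene.get(g))
        for g in sorted(up_genes)
    ]
    if scan_cfg.get("genome_wide", True):
        target_sets["genome_wide_5prime"] = [
            extract_gene_upstream(g, genome, length=length,
                                  tss=tss_by_gene.get(g.gene_id))
            for g in genes
        ]

    report = refine(
        seed_proms,
        all_proms,
        width=disc_cfg.get("width", 14),
        palindromic=disc_cfg.get("palindromic", False),
        p_max=p_max,
        restarts=disc_cfg.get("restarts", 10),
        seed=seed,
        target_sets=target_sets,
    )
    write_motif(report.initial.pwm, out / "motif_initial.meme", name="box_initial")
    write_motif(report.refined.pwm, out / "motif_refined.meme", name="box_refined")
    per_col, total = report.refined.pwm.information_content()
    pd.DataFrame({"column": np.arange(1, len(per_col) + 1), "bits": per_col}).to_csv(
        out / "motif_ic.tsv", sep="\t", index=False)
    consensus = consensus_string(report.refined.pwm)
    (out / "consensus.txt").write_text(consensus + "\n")
    manifest.stages.append({"stage": "discover_refine", "status": "done",
                            "consensus": consensus, "ic_bits": total,
                            "n_hit_positive": len(report.hit_positive),
                            "outputs": ["motif_initial.meme", "motif_refined.meme",
                                        "motif_ic.tsv", "consensus.txt"]})

    # ---- stage: regulon table --------------------------------------------
    windows = cfg.get("class_windows")
    from .operons import DEFAULT_CLASS_WINDOWS

    windows = {k: tuple(v) for k, v in windows.items()} if windows else DEFAULT_CLASS_WINDOWS
    prom_lookup: dict[str, object] = {}
    for seqs in target_sets.values():
        for p in seqs:
            prom_lookup.setdefault(p.ref_id, p)
    op_by_id = {o.operon_id: o for o in operons}
    keep_distal = scan_cfg.get("keep_distal", True)
    width = report.refined.pwm.width

    rows = []
    all_sites = []
    for set_name in ("nf_upregulated_operons", "fnr_downregulated_operons"):
        seen = set()
        for h in report.target_hits.get(set_name, []):
            region = prom_lookup[h.ref_id]
            site = annotate_site(region, h.offset, width, h.matched, h.score,
                                 h.p_value, windows=windows)
            if not keep_distal and site.promoter_class.value in ("DISTAL", "NO_TSS"):
                continue
            all_sites.append(site)
            op = op_by_id.get(h.ref_id)
            lead = genes_by_id[op.lead_gene] if op else None
            first_for_operon = h.ref_id not in seen
            seen.add(h.ref_id)
            rows.append({
                "set": set_name,
                "operon_id": h.ref_id,
                "locus": lead.gene_id if lead else h.ref_id,
                "name": (lead.name or "") if lead else "",
                "centre": "ND" if site.center_offset is None else site.center_offset,
                "class": site.promoter_class.value,
                "score": round(site.score, 3),
                "p_value": site.p_value,
                "description": lead.product if lead else "",
                "operon": op.span if op else "",
                "primary": first_for_operon,
            })
    regulon = pd.DataFrame(rows, columns=["set", "operon_id", "locus", "name",
                                          "centre", "class", "score", "p_value",
                                          "description", "operon", "primary"])
    regulon.to_csv(out / "regulon_table.tsv", sep="\t", index=False)
    write_sites_bed(all_sites, out / "sites.bed")

    extra_rows = []
    regulon_ids = set(regulon["operon_id"])
    for set_name in ("fnr_upregulated_genes", "genome_wide_5prime"):
        for h in report.target_hits.get(set_name, []):
            gene = genes_by_id.get(h.ref_id)
            in_known = False
            if gene is not None:
                for op in category_ops:
                    if h.ref_id in op.gene_ids and op.operon_id in regulon_ids:
                        in_known = True
                        break
            region = prom_lookup[h.ref_id]
            site = annotate_site(region, h.offset, width, h.matched, h.score,
                                 h.p_value, windows=windows)
            extra_rows.append({"set": set_name, "gene_id": h.ref_id,
                               "centre": "ND" if site.center_offset is None
                               else site.center_offset,
                               "class": site.promoter_class.value,
                               "score": round(site.score, 3), "p_value": site.p_value,
                               "known_regulon": in_known})
    pd.DataFrame(extra_rows, columns=["set", "gene_id", "centre", "class", "score",
                                      "p_value", "known_regulon"]).to_csv(
        out / "extra_hits.tsv", sep="\t", index=False)
    manifest.stages.append({"stage": "report", "status": "done",
                            "n_regulon_rows": len(regulon),
                            "n_extra_hits": len(extra_rows),
                            "outputs": ["regulon_table.tsv", "sites.bed",
                                        "extra_hits.tsv"]})

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
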