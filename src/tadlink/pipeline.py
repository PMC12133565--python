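"""End-to-end orchestration: parse -> consensus/Venn -> normalize -> DE ->
annotate -> TAD-link -> summarize -> (optional) motif enrichment.

A single YAML config parameterizes every stage; every headline number in
the machine-readable report is recomputable from the stage output files
written next to it. Reruns with an identical config and seed produce
byte-identical outputs (timestamps are confined to the run log).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import counts_stats as cs
from . import motif as mf
from . import peaks as pk
from . import tad_linking as tl
from .genomic_model import (
    Interval,
    TadPartition,
    harmonize_chrom_name,
    parse_fasta,
    parse_gene_models,
    parse_intervals,
    write_intervals,
)

__all__ = ["PipelineError", "RunReport", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    config_hash: str
    seed: int
    counts: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "counts": self.counts,
            "warnings": self.warnings,
        }


_DEFAULT_ANALYSIS = {
    "alpha_de": 0.05,
    "lfc_min": 1.0,
    "alpha_corr": 0.05,
    "corr_adjust": False,
    "corr_p_threshold": 0.05,
    "min_samples": 2,
    "promoter_upstream": 1000,
    "promoter_downstream": 100,
    "tts_window": 100,
    "vst_method": "asinh_nb",
    "seed": 17,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with an 'inputs' section")
    cfg.setdefault("analysis", {})
    merged = dict(_DEFAULT_ANALYSIS)
    merged.update(cfg["analysis"] or {})
    cfg["analysis"] = merged
    cfg.setdefault("motif", {"enabled": False})
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _resolve(base: Path, p: str) -> Path:
    q = Path(p)
    return q if q.is_absolute() else base / q


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full analysis described by a YAML config.

    Stage order: parse inputs, per-group consensus peaks, Venn
    classification, normalization (size factors + VST) of both count
    matrices, NB differential test on RNA with BH adjustment and
    threshold calls, peak annotation, TAD assignment, within-TAD pair
    enumeration, correlation linking, link summary, differential genes
    with correlated accessibility, and optionally PWM motif enrichment of
    group-B-unique peak sequences against a GC-matched genomic
    background. All intermediate tables are written under the output
    directory; the report's counts are recomputable from them.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    base = config_path.parent
    inputs = cfg["inputs"]
    ana = cfg["analysis"]
    out = Path(out_dir or cfg.get("output_dir", "tadlink_out"))
    if not out.is_absolute():
        out = base / out
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] {stage}: {msg}")

    report = RunReport(config_hash=_config_hash(cfg), seed=int(ana["seed"]))
    acfg = cs.AnalysisConfig(
        alpha_de=float(ana["alpha_de"]),
        lfc_min=float(ana["lfc_min"]),
        alpha_corr=float(ana["alpha_corr"]),
        corr_adjust=bool(ana["corr_adjust"]),
        promoter_window=(int(ana["promoter_upstream"]), int(ana["promoter_downstream"])),
        tts_window=int(ana["tts_window"]),
        min_samples=int(ana["min_samples"]),
        vst_method=str(ana["vst_method"]),
        seed=int(ana["seed"]),
    )

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log(name, "start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(name, f"FAILED: {exc}")
                    _write_log(out, log_lines)
                    raise PipelineError(name, exc) from exc
                log(name, "done")

        return _Ctx()

    harmonize = bool(inputs.get("harmonize_chr_prefix", False))

    def _fix_ivs(ivs):
        if not harmonize:
            return ivs
        return [
            type(iv)(**{**iv.__dict__, "chrom": harmonize_chrom_name(iv.chrom)})
            for iv in ivs
        ]

    with stage("parse"):
        genes = parse_gene_models(_resolve(base, inputs["genes_gtf"]))
        if harmonize:
            genes = [
                type(g)(g.gene_id, harmonize_chrom_name(g.chrom), g.strand, g.start,
                        g.end, _fix_ivs(list(g.exons)))
                for g in genes
            ]
        tads = TadPartition(
            _fix_ivs(parse_intervals(_resolve(base, inputs["tads_bed"]), "bed6"))
        )
        for msg in tads.repairs:
            report.warnings.append(f"TAD repair: {msg}")
        master_peaks = _fix_ivs(
            parse_intervals(_resolve(base, inputs["master_peaks"]), "narrowpeak")
        )
        groups: dict[str, str] = {}
        with open(_resolve(base, inputs["groups"])) as fh:
            header = fh.readline()
            for line in fh:
                sid, grp = line.split()
                groups[sid] = grp
        sample_peaks = {
            sid: _fix_ivs(parse_intervals(_resolve(base, rel), "narrowpeak"))
            for sid, rel in inputs["sample_peaks"].items()
        }
        atac = cs.parse_counts_table(_resolve(base, inputs["atac_counts"]))
        rna = cs.parse_counts_table(_resolve(base, inputs["rna_counts"]))
        atac.group_labels = {s: groups[s] for s in atac.sample_ids}
        rna.group_labels = {s: groups[s] for s in rna.sample_ids}
        if atac.sample_ids != rna.sample_ids:
            raise ValueError("ATAC and RNA count tables list different samples")

    with stage("consensus"):
        group_ids = sorted(set(groups.values()))
        if len(group_ids) != 2:
            raise ValueError(f"need exactly 2 groups, got {group_ids}")
        consensus = {}
        for g in group_ids:
            members = {s: sample_peaks[s] for s in sample_peaks if groups[s] == g}
            consensus[g] = pk.build_group_consensus(
                members, min_samples=acfg.min_samples, group_label=g
            )
            write_intervals(out / f"consensus_{g}.bed", consensus[g].peaks, "bed6")
            report.counts[f"consensus_peaks_{g}"] = len(consensus[g])
            stats = pk.peak_size_summary(consensus[g].peaks)
            report.counts[f"peak_size_mean_{g}"] = round(stats["mean"], 3)
            report.counts[f"peak_size_median_{g}"] = stats["median"]

    with stage("venn"):
        ga, gb = group_ids
        venn = pk.venn_classify(consensus[ga], consensus[gb])
        for label, regions in (
            ("shared", venn.shared),
            (f"unique_{ga}", venn.unique_a),
            (f"unique_{gb}", venn.unique_b),
        ):
            write_intervals(out / f"venn_{label}.bed", regions, "bed3")
        report.counts["venn_shared"] = len(venn.shared)
        report.counts[f"venn_unique_{ga}"] = len(venn.unique_a)
        report.counts[f"venn_unique_{gb}"] = len(venn.unique_b)

    with stage("normalize"):
        sf_atac = cs.size_factors_median_of_ratios(atac)
        sf_rna = cs.size_factors_median_of_ratios(rna)
        norm_atac = cs.vst_normalize(atac, sf_atac, method=acfg.vst_method)
        norm_rna = cs.vst_normalize(rna, sf_rna, method=acfg.vst_method)
        norm_rna.to_frame().round(6).to_csv(out / "rna_vst.tsv", sep="\t", index_label="feature")
        norm_atac.to_frame().round(6).to_csv(out / "atac_vst.tsv", sep="\t", index_label="feature")
        scores, frac = cs.pca_embed(norm_atac)
        report.counts["atac_pc1_variance_fraction"] = round(float(frac[0]), 4)

    with stage("differential"):
        records = cs.nb_wald_test(rna)
        calls = cs.call_differential(records, acfg)
        cs.differential_frame(records).round(6).to_csv(
            out / "de_results.tsv", sep="\t", index=False
        )
        report.counts["genes_tested"] = len(records)
        report.counts["de_up"] = len(calls["up"])
        report.counts["de_down"] = len(calls["down"])

    with stage("annotate"):
        annotations = pk.annotate_peaks(
            master_peaks, genes,
            promoter_window=acfg.promoter_window, tts_window=acfg.tts_window,
        )
        with open(out / "peak_annotations.tsv", "w") as fh:
            fh.write("peak\tclass\tnearest_gene\ttss_distance\n")
            for a in annotations:
                fh.write(
                    f"{a.peak_id}\t{a.annotation_class}\t{a.nearest_gene_id}\t{a.tss_distance}\n"
                )

    with stage("tad_link"):
        peak_assign = tl.assign_to_tads(tad_partition=tads, peaks=master_peaks)
        gene_assign = tl.assign_to_tads(tad_partition=tads, genes=genes)
        n_unassigned = sum(1 for a in peak_assign + gene_assign if a.tad_id is None)
        if n_unassigned:
            report.warnings.append(f"{n_unassigned} elements outside every TAD")
        pairs = tl.enumerate_tad_pairs(peak_assign, gene_assign)
        links, dropped = tl.link_peaks_genes(pairs, norm_atac, norm_rna, annotations, acfg)
        for pid, gid, reason in dropped:
            report.warnings.append(f"pair ({pid}, {gid}) dropped: {reason}")
        tl.links_frame(links).round(6).to_csv(out / "links.tsv", sep="\t", index=False)
        summary = tl.summarize_links(links, n_dropped=len(dropped))
        report.counts["pairs_tested"] = summary.n_pairs_tested
        report.counts["pairs_dropped"] = summary.n_dropped
        report.counts["links_significant"] = summary.n_significant
        report.counts["links_positive"] = summary.n_positive
        report.counts["links_negative"] = summary.n_negative
        report.counts["link_class_proportions"] = summary.class_proportions
        correlated_up = tl.select_correlated_de_genes(
            links, calls["up"], float(ana["corr_p_threshold"])
        )
        (out / "correlated_up_genes.txt").write_text(
            "".join(g + "\n" for g in correlated_up)
        )
        report.counts["de_up_with_correlated_accessibility"] = len(correlated_up)

    if cfg["motif"].get("enabled"):
        with stage("motif"):
            genome = parse_fasta(_resolve(base, inputs["genome_fasta"]))
            if harmonize:
                genome = {harmonize_chrom_name(c): s for c, s in genome.items()}
            pwms = mf.parse_pwm(_resolve(base, inputs["motif_pwm"]))
            ga, gb = group_ids
            target_regions = [
                p for p in master_peaks
                if any(p.overlaps(u) for u in venn.unique_b)
            ]
            target_seqs = {
                p.id or f"peak_{i}": genome[p.chrom][p.start:p.end]
                for i, p in enumerate(target_regions)
            }
            rng_seed = int(ana["seed"])
            background = mf.sample_gc_matched_background(
                target_seqs,
                genome,
                n_background=int(cfg["motif"].get("n_background", 2 * len(target_seqs))),
                seed=rng_seed,
                target_regions=master_peaks,
            )
            results = []
            for pwm in pwms:
                res = mf.motif_enrichment(
                    target_seqs, background, pwm,
                    scan_p=float(cfg["motif"].get("scan_p", 1e-4)),
                )
                results.append(res.as_dict())
            with open(out / "motif_enrichment.json", "w") as fh:
                json.dump(results, fh, indent=1, sort_keys=True)
            report.counts["motif_results"] = results

    with stage("report"):
        with open(out / "report.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=1, sort_keys=True)
        _write_log(out, log_lines)
    return report


def _write_log(out: Path, lines: list[str]) -> None:
    (out / "run_log.txt").write_text("".join(l + "\n" for l in lines))
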