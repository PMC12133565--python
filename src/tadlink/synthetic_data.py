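"""Truth-annotated synthetic multi-omics datasets.

Generates a small genome (FASTA), gene models (GTF), a disjoint TAD
partition (BED), per-sample peak calls with replicate jitter, NB count
matrices for peaks and genes with planted group effects, planted
within-TAD peak-gene correlations of either sign, and motif instances
written preferentially into one group's unique peaks — so every pipeline
stage can be tested against a known ground truth without any download.

Study design mirrored by the defaults: two genotype groups with four
biological replicates each. Planted correlation is induced by a shared
log-normal latent factor added to the NB means of the peak and its
partner gene (negated exponent for negative links), which keeps counts
marginally NB-like; the factor scale is calibrated per entity so the
expected Pearson r on VST values is approximately ``link_r_target``.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .counts_stats import CountsMatrix, write_counts_table
from .genomic_model import (
    GeneModel,
    Interval,
    Peak,
    TadPartition,
    write_fasta,
    write_gene_models,
    write_intervals,
)

__all__ = [
    "SimConfig",
    "TruthLedger",
    "generate_genome",
    "generate_peaks_and_truth",
    "generate_counts",
    "generate_link_benchmark",
    "write_dataset",
]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults are sized for desk scale (full pipeline in seconds): two
    1-Mb chromosomes, 20 TADs, 300 genes, 1000 peaks, and 2 groups x 4
    replicates matching the profiled study design. ``nb_dispersion`` is
    the NB dispersion alpha (Var = mu + alpha*mu^2); 0.1 is a typical
    between-biological-replicate value for inbred-mouse tumor counts.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_tads: int = 20
    n_genes: int = 300
    n_peaks: int = 1000
    n_samples_per_group: int = 4
    gc_content: float = 0.42
    nb_mean_range: tuple[float, float] = (50.0, 500.0)
    nb_dispersion: float = 0.1
    frac_linked_pairs: float = 0.01
    link_r_target: float = 0.9
    frac_link_negative: float = 0.2
    frac_de_genes: float = 0.1
    de_lfc: float = 2.0
    frac_group_unique_peaks: float = 0.3
    frac_promoter_peaks: float = 0.4
    peak_jitter_bp: int = 10
    motif_plant_rate_target: float = 0.6
    motif_plant_rate_background: float = 0.05
    seed: int = 17

    def __post_init__(self) -> None:
        for name in (
            "frac_linked_pairs",
            "frac_link_negative",
            "frac_de_genes",
            "frac_group_unique_peaks",
            "frac_promoter_peaks",
            "motif_plant_rate_target",
            "motif_plant_rate_background",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TruthLedger:
    """Ground truth of everything the generator planted."""

    links: list[dict] = field(default_factory=list)  # peak, gene, tad, sign, r_target
    de_genes: list[dict] = field(default_factory=list)  # gene, lfc
    group_unique_peaks: dict[str, list[str]] = field(default_factory=dict)
    motif_placements: list[dict] = field(default_factory=list)  # peak, chrom, offset, strand

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenomeArtifacts:
    sequences: dict[str, str]
    genes: list[GeneModel]
    tads: TadPartition


@dataclass
class PeakArtifacts:
    master_peaks: list[Peak]
    sample_peaks: dict[str, list[Peak]]  # sample id -> peaks
    group_of_sample: dict[str, str]
    truth: TruthLedger


@dataclass
class DatasetBundle:
    config: SimConfig
    genome: GenomeArtifacts
    peaks: PeakArtifacts
    atac_counts: CountsMatrix
    rna_counts: CountsMatrix
    truth: TruthLedger


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs)
    return "".join("ACGT"[c] for c in codes)


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> GenomeArtifacts:
    """Random genome with disjointly tiled TADs and genes whose TSS lies
    inside a TAD. Deterministic for a fixed config/seed."""
    rng = rng or np.random.default_rng(config.seed)
    if config.n_tads % config.n_chromosomes != 0:
        raise ValueError("n_tads must be divisible by n_chromosomes")
    tads_per_chrom = config.n_tads // config.n_chromosomes
    min_tad = config.chrom_length // (tads_per_chrom * 4)
    if min_tad < 20_000:
        raise ValueError(
            "chromosomes too short for the requested TAD count; need length >= "
            f"{tads_per_chrom * 80_000}"
        )
    sequences: dict[str, str] = {}
    tad_list: list[Interval] = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        sequences[chrom] = _random_dna(rng, config.chrom_length, config.gc_content)
        # jittered equal tiling: boundaries at i*L/k +- up to 20%
        width = config.chrom_length / tads_per_chrom
        bounds = [0]
        for i in range(1, tads_per_chrom):
            jitter = rng.uniform(-0.2, 0.2) * width
            bounds.append(int(i * width + jitter))
        bounds.append(config.chrom_length)
        for i in range(tads_per_chrom):
            tad_list.append(
                Interval(chrom, bounds[i], bounds[i + 1], id=f"tad_{chrom}_{i}")
            )
    tads = TadPartition(tad_list)

    genes: list[GeneModel] = []
    all_tads = list(tads)
    for g in range(config.n_genes):
        tad = all_tads[int(rng.integers(len(all_tads)))]
        strand = "+" if rng.random() < 0.5 else "-"
        body_len = int(rng.integers(2_000, 10_000))
        margin = 100
        tss = int(rng.integers(tad.start + margin, tad.end - margin))
        if strand == "+":
            start, end = tss, min(tss + body_len, config.chrom_length)
        else:
            start, end = max(tss - body_len + 1, 0), tss + 1
        # exons: first exon at the TSS end, plus one internal
        exons: list[Interval] = []
        ex1_len = min(300, end - start)
        if strand == "+":
            exons.append(Interval(tad.chrom, start, start + ex1_len))
            if end - start > 1200:
                mid = start + (end - start) // 2
                exons.append(Interval(tad.chrom, mid, min(mid + 200, end)))
        else:
            exons.append(Interval(tad.chrom, end - ex1_len, end))
            if end - start > 1200:
                mid = start + (end - start) // 2
                exons.append(Interval(tad.chrom, max(mid - 200, start), mid))
        genes.append(
            GeneModel(f"gene_{g:04d}", tad.chrom, strand, start, end, tuple(exons))
        )
    return GenomeArtifacts(sequences, genes, tads)


# ---------------------------------------------------------------------------
# peaks + planted truth
# ---------------------------------------------------------------------------


def generate_peaks_and_truth(
    genome: GenomeArtifacts,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    motif_consensus: str | None = None,
) -> PeakArtifacts:
    """Master peak set (promoter-proximal + distal, non-overlapping, each
    inside a TAD), per-sample jittered peak calls, group-unique peaks,
    planted within-TAD peak-gene links, and motif instances written into
    group-B unique peak sequences at ``motif_plant_rate_target`` (and
    into group-A unique peaks at the background rate)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    chrom_len = {c: len(s) for c, s in genome.sequences.items()}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_len}

    def place(chrom: str, start: int, width: int) -> Peak | None:
        end = start + width
        if start < 0 or end > chrom_len[chrom]:
            return None
        # keep master peaks disjoint with a small gap
        for s, e in occupied[chrom]:
            if s - 50 < end and start < e + 50:
                return None
        occupied[chrom].append((start, end))
        return Peak(chrom, start, end)

    master: list[Peak] = []
    n_promoter = int(round(config.frac_promoter_peaks * config.n_peaks))
    attempts = 0
    while len(master) < n_promoter and attempts < config.n_peaks * 50:
        attempts += 1
        g = genome.genes[int(rng.integers(len(genome.genes)))]
        width = int(np.clip(rng.normal(400, 80), 150, 1000))
        # center the peak near the TSS so its midpoint falls in the promoter window
        offset = int(rng.integers(-300, 50))
        center = g.tss + (offset if g.strand == "+" else -offset)
        p = place(g.chrom, center - width // 2, width)
        if p is not None:
            master.append(p)
    all_tads = list(genome.tads)
    while len(master) < config.n_peaks and attempts < config.n_peaks * 100:
        attempts += 1
        tad = all_tads[int(rng.integers(len(all_tads)))]
        width = int(np.clip(rng.normal(400, 80), 150, 1000))
        start = int(rng.integers(tad.start, max(tad.start + 1, tad.end - width)))
        p = place(tad.chrom, start, width)
        if p is not None:
            master.append(p)
    if len(master) < config.n_peaks:
        raise RuntimeError(
            f"could not place {config.n_peaks} disjoint peaks; genome too small"
        )
    master.sort(key=lambda p: (p.chrom, p.start))
    master = [
        Peak(p.chrom, p.start, p.end, id=f"peak_{i:05d}", sample_of_origin="master")
        for i, p in enumerate(master)
    ]

    # group membership: shared / A-only / B-only
    n_unique = int(round(config.frac_group_unique_peaks * len(master)))
    n_unique_a = n_unique // 2
    perm = rng.permutation(len(master))
    unique_a = {master[i].id for i in perm[:n_unique_a]}
    unique_b = {master[i].id for i in perm[n_unique_a:n_unique]}
    truth = TruthLedger(
        group_unique_peaks={"A": sorted(unique_a), "B": sorted(unique_b)}
    )

    # per-sample peak calls with boundary jitter
    group_of_sample: dict[str, str] = {}
    sample_peaks: dict[str, list[Peak]] = {}
    j = config.peak_jitter_bp
    for group in ("A", "B"):
        skip = unique_b if group == "A" else unique_a
        for rep in range(1, config.n_samples_per_group + 1):
            sid = f"{group}{rep}"
            group_of_sample[sid] = group
            plist: list[Peak] = []
            for p in master:
                if p.id in skip:
                    continue
                ds = int(rng.integers(-j, j + 1)) if j > 0 else 0
                de = int(rng.integers(-j, j + 1)) if j > 0 else 0
                start = max(0, p.start + ds)
                end = min(chrom_len[p.chrom], p.end + de)
                if end <= start:
                    start, end = p.start, p.end
                plist.append(Peak(p.chrom, start, end, id=p.id, sample_of_origin=sid))
            sample_peaks[sid] = plist

    # planted links: shared peaks paired with genes in the same TAD,
    # each peak and gene used at most once
    peak_tad = {
        p.id: genome.tads.find(p.chrom, p.midpoint) for p in master
    }
    genes_by_tad: dict[str, list[GeneModel]] = {}
    for g in genome.genes:
        t = genome.tads.find(g.chrom, g.tss)
        if t is not None:
            genes_by_tad.setdefault(t.id, []).append(g)
    eligible: list[tuple[str, str, str]] = []
    for p in master:
        if p.id in unique_a or p.id in unique_b:
            continue
        t = peak_tad[p.id]
        if t is None or t.id not in genes_by_tad:
            continue
        for g in genes_by_tad[t.id]:
            eligible.append((p.id, g.gene_id, t.id))
    n_links = int(round(config.frac_linked_pairs * len(eligible)))
    order = rng.permutation(len(eligible))
    used_peaks: set[str] = set()
    used_genes: set[str] = set()
    for idx in order:
        if len(truth.links) >= n_links:
            break
        pid, gid, tid = eligible[idx]
        if pid in used_peaks or gid in used_genes:
            continue
        used_peaks.add(pid)
        used_genes.add(gid)
        sign = "negative" if rng.random() < config.frac_link_negative else "positive"
        truth.links.append(
            {"peak": pid, "gene": gid, "tad": tid, "sign": sign,
             "r_target": config.link_r_target}
        )
    if n_links > 0 and len(truth.links) < n_links:
        raise RuntimeError(
            f"frac_linked_pairs demands {n_links} links but only "
            f"{len(truth.links)} disjoint pairs exist"
        )

    # differential genes: drawn from genes not used by planted links
    free_genes = [g.gene_id for g in genome.genes if g.gene_id not in used_genes]
    n_de = int(round(config.frac_de_genes * len(genome.genes)))
    de_ids = sorted(
        free_genes[i] for i in rng.permutation(len(free_genes))[:n_de]
    )
    truth.de_genes = [{"gene": gid, "lfc": config.de_lfc} for gid in de_ids]

    # motif planting into group-unique peak sequences
    if motif_consensus:
        L = len(motif_consensus)
        seqs = genome.sequences
        for pid_set, rate in (
            (sorted(unique_b), config.motif_plant_rate_target),
            (sorted(unique_a), config.motif_plant_rate_background),
        ):
            by_id = {p.id: p for p in master}
            for pid in pid_set:
                if rng.random() >= rate:
                    continue
                p = by_id[pid]
                if p.length <= L + 2:
                    continue
                off = int(rng.integers(1, p.length - L - 1))
                strand = "+" if rng.random() < 0.5 else "-"
                inst = motif_consensus if strand == "+" else _revcomp(motif_consensus)
                s = seqs[p.chrom]
                pos = p.start + off
                seqs[p.chrom] = s[:pos] + inst + s[pos + L:]
                truth.motif_placements.append(
                    {"peak": pid, "chrom": p.chrom, "offset": pos, "strand": strand}
                )
    return PeakArtifacts(master, sample_peaks, group_of_sample, truth)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (Var = mu + alpha*mu^2)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _latent_scale(r_target: float, noise_var: float) -> float:
    """Latent log-sd b with b^2 = r/(1-r) * v_noise, so that two entities
    sharing the factor have expected log-scale correlation ~ r_target."""
    r = min(max(r_target, 0.0), 0.995)
    return float(np.sqrt(r / (1.0 - r) * noise_var))


def _log_noise_var(mean: float, alpha: float) -> float:
    """Approximate Var(log X) for X ~ NB(mean, alpha): 1/mean + alpha."""
    return 1.0 / mean + alpha


def generate_counts(
    genome: GenomeArtifacts,
    peaks: PeakArtifacts,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountsMatrix, CountsMatrix]:
    """NB count matrices for peaks (ATAC) and genes (RNA).

    Group effects: DE genes have their group-B mean multiplied by
    2**de_lfc; group-unique peaks are near-silent (mean x 0.02) in the
    other group. Linked pairs share a per-sample log-normal latent factor
    (negated exponent on the peak for negative links), calibrated so the
    expected VST-scale Pearson r is ~ link_r_target. Per-sample library
    depth factors are drawn log-uniform in [0.7, 1.4] to exercise size
    factor estimation.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    samples = sorted(peaks.group_of_sample)  # A1..An, B1..Bn
    groups = np.array([peaks.group_of_sample[s] for s in samples])
    n_samples = len(samples)
    alpha = config.nb_dispersion
    lo, hi = config.nb_mean_range

    depth = np.exp(rng.uniform(np.log(0.7), np.log(1.4), n_samples))

    link_by_peak = {lk["peak"]: lk for lk in peaks.truth.links}
    link_by_gene = {lk["gene"]: lk for lk in peaks.truth.links}
    de_lfc_by_gene = {d["gene"]: d["lfc"] for d in peaks.truth.de_genes}
    unique_a = set(peaks.truth.group_unique_peaks.get("A", []))
    unique_b = set(peaks.truth.group_unique_peaks.get("B", []))

    # one latent factor per planted link, shared by its peak and gene
    latent = {
        lk["peak"]: rng.normal(0.0, 1.0, n_samples) for lk in peaks.truth.links
    }

    def base_mean() -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    atac_rows = []
    for p in peaks.master_peaks:
        m = base_mean()
        mean = np.full(n_samples, m)
        if p.id in unique_a:
            mean[groups == "B"] *= 0.02
        elif p.id in unique_b:
            mean[groups == "A"] *= 0.02
        lk = link_by_peak.get(p.id)
        if lk is not None:
            b = _latent_scale(lk["r_target"], _log_noise_var(m, alpha))
            z = latent[lk["peak"]]
            sgn = 1.0 if lk["sign"] == "positive" else -1.0
            mean = mean * np.exp(sgn * b * z - 0.5 * b * b)
        atac_rows.append(_nb_sample(rng, mean * depth, alpha))
    atac = CountsMatrix(
        np.vstack(atac_rows),
        feature_ids=[p.id for p in peaks.master_peaks],
        sample_ids=samples,
        group_labels=peaks.group_of_sample,
    )

    rna_rows = []
    for g in genome.genes:
        m = base_mean()
        mean = np.full(n_samples, m)
        if g.gene_id in de_lfc_by_gene:
            mean[groups == "B"] *= 2.0 ** de_lfc_by_gene[g.gene_id]
        lk = link_by_gene.get(g.gene_id)
        if lk is not None:
            b = _latent_scale(lk["r_target"], _log_noise_var(m, alpha))
            z = latent[lk["peak"]]
            mean = mean * np.exp(b * z - 0.5 * b * b)
        rna_rows.append(_nb_sample(rng, mean * depth, alpha))
    rna = CountsMatrix(
        np.vstack(rna_rows),
        feature_ids=[g.gene_id for g in genome.genes],
        sample_ids=samples,
        group_labels=peaks.group_of_sample,
    )
    return atac, rna


# ---------------------------------------------------------------------------
# focused benchmark generator (correlation-recovery study)
# ---------------------------------------------------------------------------


def generate_link_benchmark(
    n_linked: int = 200,
    n_null: int = 2000,
    frac_negative: float = 0.2,
    r_target: float = 0.9,
    n_samples_per_group: int = 4,
    nb_dispersion: float = 0.1,
    nb_mean_range: tuple[float, float] = (50.0, 500.0),
    seed: int = 17,
) -> dict:
    """Paired peak/gene NB count matrices with ``n_linked`` planted
    correlated pairs (a fraction with negative sign) and ``n_null``
    independent pairs; no group effects, so null pairs are exactly null.

    Returns a dict with 'atac', 'rna' (CountsMatrix over pair features),
    'pairs' [(peak_id, gene_id, tad_id)] and 'truth' (sign or None per
    pair, aligned with 'pairs').
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_linked + n_null
    n_samples = 2 * n_samples_per_group
    samples = [f"A{i+1}" for i in range(n_samples_per_group)] + [
        f"B{i+1}" for i in range(n_samples_per_group)
    ]
    groups = {s: s[0] for s in samples}
    lo, hi = nb_mean_range
    alpha = nb_dispersion
    atac_rows, rna_rows, pairs, truth = [], [], [], []
    for k in range(n_pairs):
        pid, gid, tid = f"peak_{k:05d}", f"gene_{k:05d}", f"tad_{k:05d}"
        m_p = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        m_g = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        mean_p = np.full(n_samples, m_p)
        mean_g = np.full(n_samples, m_g)
        if k < n_linked:
            sign = "negative" if rng.random() < frac_negative else "positive"
            z = rng.normal(0.0, 1.0, n_samples)
            b_p = _latent_scale(r_target, _log_noise_var(m_p, alpha))
            b_g = _latent_scale(r_target, _log_noise_var(m_g, alpha))
            sgn = 1.0 if sign == "positive" else -1.0
            mean_p = mean_p * np.exp(sgn * b_p * z - 0.5 * b_p * b_p)
            mean_g = mean_g * np.exp(b_g * z - 0.5 * b_g * b_g)
            truth.append(sign)
        else:
            truth.append(None)
        atac_rows.append(_nb_sample(rng, mean_p, alpha))
        rna_rows.append(_nb_sample(rng, mean_g, alpha))
        pairs.append((pid, gid, tid))
    atac = CountsMatrix(
        np.vstack(atac_rows),
        feature_ids=[p for p, _, _ in pairs],
        sample_ids=samples,
        group_labels=groups,
    )
    rna = CountsMatrix(
        np.vstack(rna_rows),
        feature_ids=[g for _, g, _ in pairs],
        sample_ids=samples,
        group_labels=groups,
    )
    return {"atac": atac, "rna": rna, "pairs": pairs, "truth": truth}


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------


def generate_dataset(config: SimConfig, motif_consensus: str | None = None) -> DatasetBundle:
    """Run the three generation stages under one master seed."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    peaks = generate_peaks_and_truth(genome, config, rng, motif_consensus)
    atac, rna = generate_counts(genome, peaks, config, rng)
    return DatasetBundle(config, genome, peaks, atac, rna, peaks.truth)


def write_dataset(bundle: DatasetBundle, out_dir: str | Path) -> dict:
    """Write every artifact in the formats the readers understand and a
    manifest JSON listing paths, seed, config hash and the truth ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    paths = {
        "genome_fasta": "genome.fa",
        "genes_gtf": "genes.gtf",
        "tads_bed": "tads.bed",
        "master_peaks": "peaks/master.narrowPeak",
        "atac_counts": "atac_counts.tsv",
        "rna_counts": "rna_counts.tsv",
        "groups": "groups.tsv",
        "truth": "truth.json",
    }
    write_fasta(out / paths["genome_fasta"], bundle.genome.sequences)
    write_gene_models(out / paths["genes_gtf"], bundle.genome.genes)
    write_intervals(out / paths["tads_bed"], list(bundle.genome.tads), dialect="bed6")
    write_intervals(
        out / paths["master_peaks"], bundle.peaks.master_peaks, dialect="narrowpeak"
    )
    sample_paths = {}
    for sid in sorted(bundle.peaks.sample_peaks):
        rel = f"peaks/sample_{sid}.narrowPeak"
        write_intervals(out / rel, bundle.peaks.sample_peaks[sid], dialect="narrowpeak")
        sample_paths[sid] = rel
    paths["sample_peaks"] = sample_paths
    write_counts_table(out / paths["atac_counts"], bundle.atac_counts)
    write_counts_table(out / paths["rna_counts"], bundle.rna_counts)
    with open(out / paths["groups"], "w") as fh:
        fh.write("sample\tgroup\n")
        for sid in sorted(bundle.peaks.group_of_sample):
            fh.write(f"{sid}\t{bundle.peaks.group_of_sample[sid]}\n")
    with open(out / paths["truth"], "w") as fh:
        json.dump(bundle.truth.as_dict(), fh, indent=1, sort_keys=True)
    manifest = {
        "seed": bundle.config.seed,
        "config": asdict(bundle.config),
        "config_hash": bundle.config.config_hash(),
        "paths": paths,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
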