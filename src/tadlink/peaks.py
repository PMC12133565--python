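"""Peak set algebra: merging, replicate consensus, Venn classification,
size statistics and genomic-context annotation.

Conventions: intervals are 0-based half-open; merging requires at least
one shared base (half-open adjacency does NOT merge); the Venn counting
unit is a merged region of the A∪B union, so a shared region is counted
once regardless of how many input peaks cover it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_model import GeneModel, Interval, Peak

__all__ = [
    "ConsensusPeakSet",
    "VennClassification",
    "PeakAnnotation",
    "merge_intervals",
    "build_group_consensus",
    "venn_classify",
    "peak_size_summary",
    "annotate_peaks",
]


@dataclass
class ConsensusPeakSet:
    """Merged peaks supported by at least ``min_samples`` replicates."""

    group_label: str
    peaks: list[Peak]
    support: list[int]
    min_samples: int

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class VennClassification:
    """Partition of the merged A∪B union into shared / A-only / B-only regions."""

    shared: list[Interval]
    unique_a: list[Interval]
    unique_b: list[Interval]

    @property
    def counts(self) -> tuple[int, int, int]:
        """(shared, unique_a, unique_b) merged-region counts."""
        return (len(self.shared), len(self.unique_a), len(self.unique_b))


@dataclass
class PeakAnnotation:
    peak_id: str
    annotation_class: str  # promoter | tts | exon | intron | intergenic
    nearest_gene_id: str | None
    tss_distance: int | None  # signed, transcription-oriented; negative = upstream


def _sort_key(iv: Interval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


class _OverlapIndex:
    """Binary-search overlap test over a merged (disjoint, sorted) interval set."""

    def __init__(self, intervals: Sequence[Interval]):
        merged = merge_intervals(intervals)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for iv in merged:
            starts.setdefault(iv.chrom, []).append(iv.start)
            ends.setdefault(iv.chrom, []).append(iv.end)
        for chrom in starts:
            self._by_chrom[chrom] = (
                np.asarray(starts[chrom]),
                np.asarray(ends[chrom]),
            )

    def overlaps(self, region: Interval) -> bool:
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return False
        s_arr, e_arr = entry
        # first interval ending strictly after region.start
        i = int(np.searchsorted(e_arr, region.start, side="right"))
        return i < len(s_arr) and int(s_arr[i]) < region.end


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union-merge intervals; overlap of >= 1 bp is required to merge.

    Returns sorted disjoint intervals; empty input yields an empty list.
    """
    ivs = sorted(intervals, key=_sort_key)
    out: list[Interval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = Interval(prev.chrom, prev.start, iv.end)
        else:
            out.append(Interval(iv.chrom, iv.start, iv.end))
    return out


def build_group_consensus(
    sample_peak_sets: Mapping[str, Sequence[Interval]],
    min_samples: int = 2,
    group_label: str = "consensus",
) -> ConsensusPeakSet:
    """Merged union of all samples' peaks, keeping regions supported by
    peaks from at least ``min_samples`` distinct samples.

    Support is counted at the merged-region level: a sample supports a
    region if any of its peaks overlaps it.
    """
    if not sample_peak_sets:
        raise ValueError("need at least one sample peak set")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > len(sample_peak_sets):
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({len(sample_peak_sets)})"
        )
    merged = merge_intervals(
        iv for peaks in sample_peak_sets.values() for iv in peaks
    )
    peaks: list[Peak] = []
    support: list[int] = []
    # deterministic sample order for support counting
    sample_ids = sorted(sample_peak_sets)
    indexes = {s: _OverlapIndex(sample_peak_sets[s]) for s in sample_ids}
    for region in merged:
        n_support = sum(1 for s in sample_ids if indexes[s].overlaps(region))
        if n_support >= min_samples:
            peaks.append(
                Peak(
                    region.chrom,
                    region.start,
                    region.end,
                    id=f"{group_label}_{len(peaks)}",
                    sample_of_origin=group_label,
                )
            )
            support.append(n_support)
    return ConsensusPeakSet(group_label, peaks, support, min_samples)


def venn_classify(
    consensus_a: ConsensusPeakSet | Sequence[Interval],
    consensus_b: ConsensusPeakSet | Sequence[Interval],
) -> VennClassification:
    """Partition the merged A∪B union into shared and group-unique regions.

    Each merged region of the union is labelled by which input sets it
    overlaps: both -> shared, only A -> unique_a, only B -> unique_b.
    """
    peaks_a = consensus_a.peaks if isinstance(consensus_a, ConsensusPeakSet) else consensus_a
    peaks_b = consensus_b.peaks if isinstance(consensus_b, ConsensusPeakSet) else consensus_b
    a_sorted = merge_intervals(peaks_a)
    b_sorted = merge_intervals(peaks_b)
    union = merge_intervals(list(a_sorted) + list(b_sorted))
    idx_a, idx_b = _OverlapIndex(a_sorted), _OverlapIndex(b_sorted)
    shared: list[Interval] = []
    unique_a: list[Interval] = []
    unique_b: list[Interval] = []
    for region in union:
        in_a = idx_a.overlaps(region)
        in_b = idx_b.overlaps(region)
        if in_a and in_b:
            shared.append(region)
        elif in_a:
            unique_a.append(region)
        else:
            unique_b.append(region)
    return VennClassification(shared, unique_a, unique_b)


def peak_size_summary(peaks: Sequence[Interval]) -> dict[str, float]:
    """Summary statistics of peak lengths (bp): n, mean, median, quartiles."""
    if not peaks:
        raise ValueError("peak_size_summary requires at least one peak")
    lengths = np.array([p.length for p in peaks], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {
        "n": int(lengths.size),
        "mean": float(lengths.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def annotate_peaks(
    peaks: Sequence[Interval],
    gene_models: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (1000, 100),
    tts_window: int = 100,
    use_summit: bool = False,
) -> list[PeakAnnotation]:
    """Classify each peak by its anchor point with precedence
    promoter > tts > exon > intron > intergenic.

    The promoter window is transcription-oriented: ``promoter_window =
    (upstream, downstream)`` means positions with signed TSS distance in
    ``[-upstream, +downstream)``. The TTS window is symmetric
    ``±tts_window`` around the transcription end site. The anchor is the
    peak midpoint, or the summit when present and ``use_summit`` is set.
    Ties between equidistant genes break toward the lexicographically
    smaller gene_id.
    """
    up, down = promoter_window
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for lst in genes_by_chrom.values():
        lst.sort(key=lambda g: g.gene_id)

    out: list[PeakAnnotation] = []
    for k, peak in enumerate(peaks):
        anchor = peak.midpoint
        if use_summit and isinstance(peak, Peak) and peak.summit_offset is not None:
            anchor = peak.summit
        pid = peak.id if peak.id is not None else f"peak_{k}"
        genes = genes_by_chrom.get(peak.chrom, [])
        nearest: GeneModel | None = None
        nearest_dist: int | None = None
        is_promoter = is_tts = is_exon = is_intron = False
        for g in genes:
            d = g.signed_tss_distance(anchor)
            if nearest_dist is None or abs(d) < abs(nearest_dist):
                nearest, nearest_dist = g, d
            if -up <= d < down:
                is_promoter = True
            if abs(anchor - g.tes) <= tts_window:
                is_tts = True
            if g.start <= anchor < g.end:
                if any(ex.start <= anchor < ex.end for ex in g.exons):
                    is_exon = True
                else:
                    is_intron = True
        if is_promoter:
            cls = "promoter"
        elif is_tts:
            cls = "tts"
        elif is_exon:
            cls = "exon"
        elif is_intron:
            cls = "intron"
        else:
            cls = "intergenic"
        out.append(
            PeakAnnotation(
                peak_id=pid,
                annotation_class=cls,
                nearest_gene_id=nearest.gene_id if nearest else None,
                tss_distance=nearest_dist,
            )
        )
    return out
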