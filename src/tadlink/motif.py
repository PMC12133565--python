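"""PWM-based known-motif enrichment.

A position weight matrix is scored in log2-odds bits against a 0-order
background; the scan threshold is derived from an exact (discretized)
score distribution under the background model rather than a fraction of
the maximal score; both strands are scanned; enrichment of sequence-level
motif presence in targets vs a GC-matched background is tested with a
one-sided hypergeometric upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_model import FormatError, Interval

__all__ = [
    "Pwm",
    "MotifHit",
    "EnrichmentResult",
    "parse_pwm",
    "write_pwm",
    "score_threshold_for_pvalue",
    "scan_sequences",
    "sample_gc_matched_background",
    "motif_enrichment",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class Pwm:
    """A motif as a 4 x L column-stochastic probability matrix (rows A,C,G,T)
    with a 0-order background; log-odds scores are in bits."""

    id: str
    name: str
    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.shape[0] != 4:
            raise ValueError("probability matrix must have 4 rows (A,C,G,T)")
        if not np.allclose(self.probabilities.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(self.probabilities <= 0):
            raise ValueError(
                "PWM probabilities must be strictly positive (apply a pseudocount)"
            )

    @property
    def length(self) -> int:
        return self.probabilities.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L matrix of log2(prob / background) in bits."""
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probabilities, axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str  # '+' | '-'
    score: float  # bits


@dataclass
class EnrichmentResult:
    motif_id: str
    n_target: int
    k_target: int
    n_background: int
    k_background: int
    fold_enrichment: float
    p_hyper: float
    score_threshold: float

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        if math.isinf(d["fold_enrichment"]):
            d["fold_enrichment"] = None
        return d


def load_builtin_pwm(name: str = "nfat_ap1_synthetic", **kwargs) -> Pwm:
    """Load a PWM shipped with the package (a synthetic composite
    NFAT:AP1-like matrix is included as a scanning fixture)."""
    path = Path(__file__).parent / "data" / f"{name}.jaspar"
    return parse_pwm(path, **kwargs)[0]


def parse_pwm(
    path: str | Path,
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> list[Pwm]:
    """Parse JASPAR-format PFM text into Pwm objects.

    Accepts headers ``>ID name`` followed by four rows in A/C/G/T order,
    with or without the ``A [ ... ]`` row-label brackets. Counts become
    probabilities after adding a background-split pseudocount: cell_b +=
    4 * pseudocount * background_b per column (so a uniform background
    adds ``pseudocount`` to every cell), then column-normalizing.
    """
    bg = np.asarray(background, dtype=float) if background is not None else UNIFORM_BACKGROUND.copy()
    motifs: list[Pwm] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(
                f"motif {header[0]}: expected 4 base rows (A,C,G,T), got {len(rows)}"
            )
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"motif {header[0]}: rows of unequal length")
        counts = np.asarray(rows, dtype=float)
        if np.any(counts < 0):
            raise FormatError(f"motif {header[0]}: negative counts")
        if np.any(counts.sum(axis=0) == 0) and pseudocount == 0:
            raise FormatError(f"motif {header[0]}: all-zero column with zero pseudocount")
        adjusted = counts + 4.0 * pseudocount * bg[:, None]
        colsum = adjusted.sum(axis=0)
        if np.any(colsum == 0):
            raise FormatError(f"motif {header[0]}: all-zero column")
        motifs.append(Pwm(header[0], header[1], adjusted / colsum, bg.copy()))
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            else:
                if header is None:
                    raise FormatError(f"{path}: matrix row before any '>' header")
                cleaned = line
                if cleaned[0] in "ACGTacgt" and (
                    len(cleaned) == 1 or not cleaned[1].isdigit()
                ):
                    cleaned = cleaned[1:]
                cleaned = cleaned.replace("[", " ").replace("]", " ")
                try:
                    rows.append([float(tok) for tok in cleaned.split()])
                except ValueError as exc:
                    raise FormatError(f"{path}: bad matrix row {line!r}") from exc
    flush()
    if not motifs:
        raise FormatError(f"{path}: no motifs found")
    return motifs


def write_pwm(path: str | Path, counts_by_motif: Mapping[str, np.ndarray]) -> None:
    """Write count matrices in JASPAR PFM text (``>ID`` + bracketed rows)."""
    with open(path, "w") as fh:
        for mid, counts in counts_by_motif.items():
            counts = np.asarray(counts)
            fh.write(f">{mid} {mid}\n")
            for b, row in zip(_BASES, counts):
                cells = " ".join(
                    str(int(v)) if float(v).is_integer() else repr(float(v)) for v in row
                )
                fh.write(f"{b} [ {cells} ]\n")


def score_distribution(pwm: Pwm, bin_width: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Exact discretized distribution of the log-odds score of a random
    background L-mer, by dynamic programming over columns.

    Per-column scores are rounded to ``bin_width``-bit bins and the
    column distributions convolved. Returns (scores, probabilities) with
    scores ascending.
    """
    lo = pwm.log_odds
    bins = np.rint(lo / bin_width).astype(int)  # 4 x L integer bin indices
    # DP over an offset integer grid
    dist: dict[int, float] = {0: 1.0}
    for col in range(pwm.length):
        new: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + int(bins[b, col])
                new[key] = new.get(key, 0.0) + p * float(pwm.background[b])
        dist = new
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys])
    return keys * bin_width, probs


def score_threshold_for_pvalue(
    pwm: Pwm, target_p: float = 1e-4, bin_width: float = 0.01
) -> float:
    """Smallest discretized score t with P(score >= t | background) <= target_p.

    The DP rounds each column's score to the bin grid, so a window's
    exact score can drift from its binned sum by up to L*bin_width/2.
    The returned threshold is the qualifying bin value minus that drift,
    so scanning exact window scores against it keeps every window the DP
    tail counted (and at most a one-bin-per-column fringe beyond). If
    even the maximal score's bin exceeds target_p in probability, the
    maximal bin's adjusted value is returned (the scan then reports only
    perfect matches). Non-increasing as target_p grows.
    """
    if not 0 < target_p < 1:
        raise ValueError("target_p must be in (0, 1)")
    scores, probs = score_distribution(pwm, bin_width)
    tail = np.cumsum(probs[::-1])[::-1]
    ok = tail <= target_p
    idx = int(np.argmax(ok)) if np.any(ok) else len(scores) - 1
    return float(scores[idx] - pwm.length * bin_width / 2.0)


def _encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3, anything else -> 4 (treated as N)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scan_one_strand(codes: np.ndarray, lo_ext: np.ndarray, L: int) -> np.ndarray:
    """Score every window on one strand; windows containing N get -inf."""
    n = codes.size
    if n < L:
        return np.empty(0)
    idx = np.arange(n - L + 1)[:, None] + np.arange(L)[None, :]
    window_codes = codes[idx]
    scores = lo_ext[window_codes, np.arange(L)[None, :]].sum(axis=1)
    has_n = (window_codes == 4).any(axis=1)
    scores[has_n] = -np.inf
    return scores


def scan_sequences(
    sequences: Mapping[str, str], pwm: Pwm, threshold: float
) -> list[MotifHit]:
    """All two-strand PWM hits with score >= threshold (bits).

    The reverse strand is scored on the reverse complement of each
    window; windows containing N are skipped. Sequences shorter than the
    motif yield no hits.
    """
    L = pwm.length
    lo = pwm.log_odds
    lo_ext = np.vstack([lo, np.full((1, L), -np.inf)])  # row 4 = N sentinel
    hits: list[MotifHit] = []
    for sid in sequences:
        seq = sequences[sid].upper()
        codes = _encode(seq)
        fwd = _scan_one_strand(codes, lo_ext, L)
        for off in np.flatnonzero(fwd >= threshold):
            hits.append(MotifHit(sid, int(off), "+", float(fwd[off])))
        rc = seq.translate(_COMPLEMENT)[::-1]
        rev = _scan_one_strand(_encode(rc), lo_ext, L)
        n = len(seq)
        for off in np.flatnonzero(rev >= threshold):
            orig = n - int(off) - L  # window position on the forward strand
            hits.append(MotifHit(sid, orig, "-", float(rev[off])))
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.strand))
    return hits


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in _BASES)
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def sample_gc_matched_background(
    target_seqs: Mapping[str, str],
    genome: Mapping[str, str],
    n_background: int,
    seed: int,
    target_regions: Sequence[Interval] = (),
    gc_tolerance: float = 0.05,
    max_tries_per_window: int = 200,
) -> dict[str, str]:
    """Random genomic windows length-matched to the targets and accepted
    only if their GC fraction is within ``gc_tolerance`` of a sampled
    target's GC. Windows overlapping ``target_regions`` are rejected.
    Seeded and reproducible.
    """
    if not target_seqs:
        raise ValueError("no target sequences")
    if n_background < len(target_seqs):
        raise ValueError("n_background must be >= number of targets")
    rng = np.random.default_rng(seed)
    target_ids = sorted(target_seqs)
    lengths = [len(target_seqs[t]) for t in target_ids]
    gcs = [gc_fraction(target_seqs[t]) for t in target_ids]
    chroms = sorted(genome)
    blocked: dict[str, list[tuple[int, int]]] = {}
    for reg in target_regions:
        blocked.setdefault(reg.chrom, []).append((reg.start, reg.end))
    out: dict[str, str] = {}
    worst_gap = 0.0
    for k in range(n_background):
        i = int(rng.integers(len(target_ids)))
        length, want_gc = lengths[i], gcs[i]
        placed = False
        for _ in range(max_tries_per_window):
            chrom = chroms[int(rng.integers(len(chroms)))]
            limit = len(genome[chrom]) - length
            if limit <= 0:
                continue
            start = int(rng.integers(limit))
            end = start + length
            if any(s < end and start < e for s, e in blocked.get(chrom, [])):
                continue
            seq = genome[chrom][start:end].upper()
            if "N" in seq:
                continue
            gap = abs(gc_fraction(seq) - want_gc)
            if gap <= gc_tolerance:
                out[f"bg_{k}_{chrom}_{start}"] = seq
                placed = True
                break
            worst_gap = max(worst_gap, gap)
        if not placed:
            raise RuntimeError(
                f"could not GC-match background window {k} within "
                f"{max_tries_per_window} tries (best unmet tolerance ~{worst_gap:.3f})"
            )
    return out


def motif_enrichment(
    target_seqs: Mapping[str, str],
    background_seqs: Mapping[str, str],
    pwm: Pwm,
    scan_p: float = 1e-4,
    bin_width: float = 0.01,
) -> EnrichmentResult:
    """Hypergeometric over-representation of sequence-level motif presence.

    A sequence is a success if it carries >= 1 hit at the background-model
    score threshold for ``scan_p``. p = P(X >= k_target) for X
    hypergeometric(n_target draws from the pooled target+background
    universe with k_target + k_background successes). Fold enrichment is
    (k_t/n_t)/(k_b/n_b), infinite when the background has no hits.
    """
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must be non-empty")
    overlap = set(target_seqs) & set(background_seqs)
    if overlap:
        raise ValueError(f"target/background id spaces overlap: {sorted(overlap)[:3]}")
    threshold = score_threshold_for_pvalue(pwm, scan_p, bin_width)
    k_t = len({h.sequence_id for h in scan_sequences(target_seqs, pwm, threshold)})
    k_b = len({h.sequence_id for h in scan_sequences(background_seqs, pwm, threshold)})
    n_t, n_b = len(target_seqs), len(background_seqs)
    p = float(stats.hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t))
    if k_b > 0:
        fold = (k_t / n_t) / (k_b / n_b)
    else:
        fold = math.inf if k_t > 0 else 1.0
    return EnrichmentResult(
        motif_id=pwm.id,
        n_target=n_t,
        k_target=k_t,
        n_background=n_b,
        k_background=k_b,
        fold_enrichment=fold,
        p_hyper=min(max(p, 0.0), 1.0),
        score_threshold=threshold,
    )
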