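"""PWM parsing, exact score-distribution thresholds, scanning, enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tadlink.genomic_model import FormatError, Interval
from tadlink.motif import (
    Pwm,
    gc_fraction,
    load_builtin_pwm,
    motif_enrichment,
    parse_pwm,
    sample_gc_matched_background,
    scan_sequences,
    score_distribution,
    score_threshold_for_pvalue,
    write_pwm,
)

SEED = 1


def pwm_from_probs(cols, background=None):
    return Pwm("m", "m", np.array(cols).T, background if background is not None
               else np.full(4, 0.25))


def random_pwm(rng, length):
    counts = rng.integers(0, 20, size=(4, length)).astype(float)
    adjusted = counts + 0.8
    return Pwm("rnd", "rnd", adjusted / adjusted.sum(axis=0), np.full(4, 0.25))


class TestParsePwm:
    def test_uniform_column_zero_pseudocount(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M1 test\nA [ 1 ]\nC [ 1 ]\nG [ 1 ]\nT [ 1 ]\n")
        (pwm,) = parse_pwm(p, pseudocount=0.0)
        assert pwm.probabilities[:, 0] == pytest.approx([0.25] * 4)

    def test_background_split_pseudocount(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M1 test\nA [ 10 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n")
        (pwm,) = parse_pwm(p, pseudocount=1.0)
        assert pwm.probabilities[:, 0] == pytest.approx([11 / 14, 1 / 14, 1 / 14, 1 / 14])

    def test_missing_base_row_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M1 test\nA [ 1 2 ]\nC [ 1 2 ]\nG [ 1 2 ]\n")
        with pytest.raises(FormatError, match="4 base rows"):
            parse_pwm(p)

    def test_unequal_row_lengths_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M1 test\nA [ 1 2 ]\nC [ 1 ]\nG [ 1 2 ]\nT [ 1 2 ]\n")
        with pytest.raises(FormatError, match="unequal"):
            parse_pwm(p)

    def test_round_trip_through_writer(self, tmp_path):
        counts = {"M1": np.array([[3, 0], [1, 1], [0, 9], [2, 4]], dtype=float)}
        p = tmp_path / "m.jaspar"
        write_pwm(p, counts)
        (pwm,) = parse_pwm(p, pseudocount=0.5)
        expected = counts["M1"] + 0.5
        expected = expected / expected.sum(axis=0)
        assert pwm.probabilities == pytest.approx(expected)

    def test_builtin_fixture_loads(self):
        pwm = load_builtin_pwm()
        assert pwm.length == 15
        assert pwm.probabilities.sum(axis=0) == pytest.approx(np.ones(15))


class TestScoreThreshold:
    def test_uniform_single_column_degenerate(self):
        # every word scores 0 bits; the threshold sits at that single bin
        pwm = pwm_from_probs([[0.25, 0.25, 0.25, 0.25]])
        t = score_threshold_for_pvalue(pwm, 0.5, bin_width=0.01)
        assert abs(t) <= 0.01
        assert len(scan_sequences({"s": "ACGT"}, pwm, t)) > 0

    @pytest.mark.parametrize("length", [2, 3, 4, 5, 6])
    def test_dp_tail_matches_exhaustive_enumeration(self, length):
        rng = np.random.default_rng(SEED + length)
        pwm = random_pwm(rng, length)
        bin_width = 0.01
        scores, probs = score_distribution(pwm, bin_width)
        lo = pwm.log_odds
        # enumerate all 4^L words under the uniform background
        word_scores = {}
        for word in itertools.product(range(4), repeat=length):
            s = sum(lo[b, i] for i, b in enumerate(word))
            key = round(sum(round(lo[b, i] / bin_width) for i, b in enumerate(word)))
            word_scores[key] = word_scores.get(key, 0.0) + 0.25 ** length
        for t in np.linspace(scores.min(), scores.max(), 23):
            dp_tail = probs[scores >= t - 1e-12].sum()
            enum_tail = sum(
                pr for k, pr in word_scores.items() if k * bin_width >= t - 1e-12
            )
            assert dp_tail == pytest.approx(enum_tail, abs=1e-12)

    def test_threshold_non_increasing_in_target_p(self):
        rng = np.random.default_rng(SEED)
        pwm = random_pwm(rng, 6)
        thresholds = [
            score_threshold_for_pvalue(pwm, p) for p in (1e-4, 1e-3, 1e-2, 0.1, 0.5)
        ]
        assert thresholds == sorted(thresholds, reverse=True)


def revcomp(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class TestScan:
    def test_consensus_hits_at_offset_zero_with_max_score(self):
        pwm = load_builtin_pwm()
        hits = scan_sequences({"s": pwm.consensus}, pwm, threshold=0.0)
        fwd = [h for h in hits if h.strand == "+"]
        assert fwd[0].offset == 0
        assert fwd[0].score == pytest.approx(pwm.max_score)

    def test_reverse_complement_hits_on_minus_strand_same_score(self):
        pwm = load_builtin_pwm()
        hits = scan_sequences({"s": revcomp(pwm.consensus)}, pwm, threshold=5.0)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1 and minus[0].offset == 0
        assert minus[0].score == pytest.approx(pwm.max_score)

    def test_sequence_shorter_than_motif_yields_no_hits(self):
        pwm = load_builtin_pwm()
        assert scan_sequences({"s": "ACGT"}, pwm, threshold=-100) == []

    def test_windows_with_n_skipped(self):
        pwm = pwm_from_probs([[0.97, 0.01, 0.01, 0.01], [0.97, 0.01, 0.01, 0.01]])
        hits = scan_sequences({"s": "ANAAA"}, pwm, threshold=0.0)
        assert {h.offset for h in hits if h.strand == "+"} == {2, 3}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_window_rescoring(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, 5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        threshold = 2.0
        hits = scan_sequences({"s": seq}, pwm, threshold)
        lo = pwm.log_odds
        expected = set()
        for off in range(len(seq) - 5 + 1):
            window = seq[off : off + 5]
            s_fwd = sum(lo["ACGT".index(b), i] for i, b in enumerate(window))
            if s_fwd >= threshold:
                expected.add((off, "+", round(s_fwd, 9)))
            rc = revcomp(window)
            s_rev = sum(lo["ACGT".index(b), i] for i, b in enumerate(rc))
            if s_rev >= threshold:
                expected.add((off, "-", round(s_rev, 9)))
        got = {(h.offset, h.strand, round(h.score, 9)) for h in hits}
        assert got == expected

    def test_strand_symmetry_on_reverse_complemented_input(self):
        rng = np.random.default_rng(SEED)
        pwm = random_pwm(rng, 6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        fwd_hits = scan_sequences({"s": seq}, pwm, 1.0)
        rc_hits = scan_sequences({"s": revcomp(seq)}, pwm, 1.0)
        flip = {"+": "-", "-": "+"}
        mapped = sorted(
            (len(seq) - h.offset - pwm.length, flip[h.strand], round(h.score, 9))
            for h in rc_hits
        )
        assert mapped == sorted(
            (h.offset, h.strand, round(h.score, 9)) for h in fwd_hits
        )


class TestGcMatchedBackground:
    @staticmethod
    def toy_genome(rng, n=60_000, gc=0.45):
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return {"chr1": "".join("ACGT"[i] for i in rng.choice(4, n, p=probs))}

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(SEED)
        genome = self.toy_genome(rng)
        targets = {f"t{i}": genome["chr1"][i * 1000 : i * 1000 + 200] for i in range(10)}
        a = sample_gc_matched_background(targets, genome, 20, seed=7)
        b = sample_gc_matched_background(targets, genome, 20, seed=7)
        assert a == b

    def test_gc_distribution_matches_targets(self):
        rng = np.random.default_rng(SEED)
        genome = self.toy_genome(rng)
        targets = {f"t{i}": genome["chr1"][i * 2000 : i * 2000 + 300] for i in range(15)}
        bg = sample_gc_matched_background(targets, genome, 60, seed=3)
        t_mean = np.mean([gc_fraction(s) for s in targets.values()])
        b_mean = np.mean([gc_fraction(s) for s in bg.values()])
        assert abs(t_mean - b_mean) < 0.05

    def test_background_avoids_target_regions(self):
        rng = np.random.default_rng(SEED)
        genome = self.toy_genome(rng)
        regions = [Interval("chr1", i * 2000, i * 2000 + 300) for i in range(15)]
        targets = {f"t{i}": genome["chr1"][r.start : r.end] for i, r in enumerate(regions)}
        bg = sample_gc_matched_background(targets, genome, 40, seed=3, target_regions=regions)
        for name in bg:
            _, _, chrom, start = name.split("_")
            s = int(start)
            e = s + len(bg[name])
            assert not any(r.start < e and s < r.end for r in regions)


class TestEnrichment:
    def test_exact_two_by_two_hypergeometric(self):
        pwm = pwm_from_probs(
            [[0.97, 0.01, 0.01, 0.01]] * 4  # consensus AAAA
        )
        targets = {"t1": "CCAAAACC", "t2": "GGAAAAGG"}
        background = {"b1": "CCCCGGGG", "b2": "GGGGCCCC"}
        res = motif_enrichment(targets, background, pwm, scan_p=0.02)
        assert res.k_target == 2 and res.k_background == 0
        assert res.p_hyper == pytest.approx(1 / 6)

    def test_motif_absent_everywhere_gives_p_one(self):
        pwm = pwm_from_probs([[0.97, 0.01, 0.01, 0.01]] * 6)
        res = motif_enrichment(
            {"t": "CGCGCGCGCG"}, {"b": "GCGCGCGCGC"}, pwm, scan_p=0.01
        )
        assert res.k_target == 0 and res.p_hyper == 1.0

    def test_overlapping_id_spaces_rejected(self):
        pwm = pwm_from_probs([[0.97, 0.01, 0.01, 0.01]] * 4)
        with pytest.raises(ValueError, match="overlap"):
            motif_enrichment({"x": "AAAA"}, {"x": "CCCC"}, pwm)

    def test_planted_motif_strongly_enriched(self):
        rng = np.random.default_rng(SEED)
        pwm = load_builtin_pwm()
        cons = pwm.consensus

        def seqs(n, rate, prefix):
            out = {}
            for i in range(n):
                s = list("".join("ACGT"[c] for c in rng.integers(0, 4, 300)))
                if rng.random() < rate:
                    off = int(rng.integers(0, 300 - len(cons)))
                    s[off : off + len(cons)] = cons
                out[f"{prefix}{i}"] = "".join(s)
            return out

        res = motif_enrichment(seqs(200, 0.6, "t"), seqs(2000, 0.05, "b"), pwm)
        assert res.p_hyper < 1e-6
        assert res.fold_enrichment > 3

    def test_null_enrichment_p_calibrated(self):
        # identical generative process for targets and background:
        # repeated enrichment p should reject at ~alpha
        rng = np.random.default_rng(SEED)
        pwm = load_builtin_pwm()
        threshold_p = 0.05
        n_trials = 200
        rejections = 0
        for trial in range(n_trials):
            targets = {
                f"t{i}": "".join("ACGT"[c] for c in rng.integers(0, 4, 250))
                for i in range(40)
            }
            background = {
                f"b{i}": "".join("ACGT"[c] for c in rng.integers(0, 4, 250))
                for i in range(80)
            }
            res = motif_enrichment(targets, background, pwm, scan_p=5e-3)
            if res.p_hyper < threshold_p:
                rejections += 1
        frac = rejections / n_trials
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_trials)
        # hypergeometric p is discrete, hence conservative: at most alpha + CI
        assert frac <= 0.05 + ci
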