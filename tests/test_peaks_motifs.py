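"""PWM scanning, peak signal, differential calls and interval annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopscape import peaks_motifs as pm
from loopscape import synthgen
from loopscape.core import GenomicInterval, Loop, Peak, Track
from loopscape.synthgen import reverse_complement


def brute_force_scan(sequence, pwm, min_relative):
    """Independent oracle: score every window on both strands explicitly."""
    hits = []
    span = pwm.max_score - pwm.min_score
    for start in range(len(sequence) - pwm.width + 1):
        window = sequence[start: start + pwm.width]
        for strand in "+-":
            target = window if strand == "+" else reverse_complement(window)
            raw = 0.0
            for k, base in enumerate(target):
                if base == "N":
                    continue
                row = "ACGT".index(base)
                raw += np.log(pwm.probabilities[row, k] / pwm.background[row])
            rel = (raw - pwm.min_score) / span
            if rel >= min_relative:
                hits.append((start, strand, round(raw, 9)))
    return sorted(hits)


class TestPwmScan:
    def test_consensus_scores_one(self, sharp_pwm):
        hits = pm.pwm_scan(sharp_pwm.consensus, sharp_pwm)
        plus = [h for h in hits if h.strand == "+"]
        assert plus[0].position == 0
        assert plus[0].relative_score == pytest.approx(1.0)

    def test_reverse_complement_symmetry(self, sharp_pwm):
        rc = reverse_complement(sharp_pwm.consensus)
        hits = pm.pwm_scan(rc, sharp_pwm)
        minus = [h for h in hits if h.strand == "-"]
        assert minus[0].position == 0
        assert minus[0].relative_score == pytest.approx(1.0)

    @pytest.mark.parametrize("min_relative", [0.0, 0.5, 0.8])
    def test_matches_brute_force_oracle(self, toy_pwm, min_relative):
        rng = np.random.default_rng(3)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGTN"), size=12, p=[0.23] * 4 + [0.08]))
            got = sorted(
                (h.position, h.strand, round(h.raw_score, 9))
                for h in pm.pwm_scan(seq, toy_pwm, min_relative=min_relative)
            )
            assert got == brute_force_scan(seq, toy_pwm, min_relative)

    def test_sequence_shorter_than_motif(self, sharp_pwm):
        assert pm.pwm_scan("ACG", sharp_pwm) == []

    @given(st.text(alphabet="ACGT", min_size=4, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_strand_mirror_property(self, toy_pwm, seq):
        # scanning the reverse complement mirrors positions and swaps strands
        pwm = toy_pwm
        fwd = pm.pwm_scan(seq, pwm, min_relative=0.6)
        rev = pm.pwm_scan(reverse_complement(seq), pwm, min_relative=0.6)
        n = len(seq)
        mirrored = sorted(
            (n - pwm.width - h.position, {"+": "-", "-": "+"}[h.strand],
             round(h.raw_score, 9))
            for h in rev
        )
        assert mirrored == sorted(
            (h.position, h.strand, round(h.raw_score, 9)) for h in fwd
        )


class TestBestMotifAtPeak:
    def test_planted_orientation_recovered(self, sharp_pwm):
        genome, peaks, truth = synthgen.simulate_peaks_and_genome(
            60, 100_000, sharp_pwm, planted_fraction=1.0, seed=4
        )
        correct = sum(
            (h := pm.best_motif_at_peak(p, genome, sharp_pwm)) is not None
            and h.strand == s
            for p, s in zip(peaks, truth["strand"])
        )
        assert correct >= 0.95 * len(peaks)

    def test_random_sequence_no_hit(self, sharp_pwm):
        rng = np.random.default_rng(8)
        genome = {"chrS": "".join(rng.choice(list("ACGT"), size=2000))}
        peak = Peak(GenomicInterval("chrS", 900, 1100), summit=1000)
        assert pm.best_motif_at_peak(peak, genome, sharp_pwm) is None

    def test_window_clipped_at_chromosome_start(self, sharp_pwm):
        genome = {"chrS": sharp_pwm.consensus + "ACGTACGTACGT"}
        peak = Peak(GenomicInterval("chrS", 0, 30), summit=5)
        hit = pm.best_motif_at_peak(peak, genome, sharp_pwm)
        assert hit is not None and hit.position == 0


class TestPeakSignal:
    def _peak(self, summit=500):
        return Peak(GenomicInterval("chrS", summit - 200, summit + 200),
                    summit=summit)

    def test_constant_track_auc(self):
        track = Track(chrom="chrS", step=1, values=np.full(1000, 2.0))
        assert pm.peak_signal(track, self._peak(), "auc_200bp") == 400.0

    def test_constant_track_mean(self):
        track = Track(chrom="chrS", step=1, values=np.full(1000, 2.0))
        assert pm.peak_signal(track, self._peak(), "mean_100bp") == 2.0

    def test_triangular_pulse_matches_brute_force(self):
        values = np.zeros(1000)
        values[400:601] = np.concatenate(
            [np.arange(101), np.arange(99, -1, -1)]
        ).astype(float)
        track = Track(chrom="chrS", step=1, values=values)
        peak = self._peak(500)
        assert pm.peak_signal(track, peak, "auc_200bp") == values[400:600].sum()
        assert pm.peak_signal(track, peak, "mean_100bp") == pytest.approx(
            values[450:550].mean()
        )

    def test_off_chromosome_window_missing(self):
        track = Track(chrom="chrS", step=1, values=np.ones(100))
        peak = Peak(GenomicInterval("chrS", 0, 10_000), summit=5000)
        assert np.isnan(pm.peak_signal(track, peak, "mean_100bp"))


class TestCongruentChange:
    def _peaks(self, n=1):
        return [Peak(GenomicInterval("c", 0, 100), summit=50) for _ in range(n)]

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ((10, 10), (13, 12.5), "gain"),      # both >= 1.25x
            ((10, 10), (13, 11), "unchanged"),   # second pair only +10%
            ((10, 10), (7.5, 7.0), "loss"),      # both <= 0.75x
            ((10, 10), (12.5, 12.5), "gain"),    # exactly 25% counts
            ((0, 0), (5, 3), "gain"),            # zero reference, signal gained
            ((10, 10), (10, 10), "unchanged"),
        ],
    )
    def test_rule(self, ref, alt, expected):
        calls = pm.congruent_change_peaks(
            self._peaks(), np.array([ref]), np.array([alt])
        )
        assert calls[0].klass == expected

    def test_unequal_replicates_rejected(self):
        with pytest.raises(ValueError):
            pm.congruent_change_peaks(
                self._peaks(), np.array([[1.0, 2.0]]), np.array([[1.0]])
            )

    def test_noisy_sensitivity(self, sharp_pwm):
        _, peaks, truth = synthgen.simulate_peaks_and_genome(
            200, 400_000, sharp_pwm, planted_fraction=0.0,
            noise_sigma=0.1, seed=9,
        )
        ref = np.array([[p.signal_by_sample["ref_1"], p.signal_by_sample["ref_2"]]
                        for p in peaks])
        alt = np.array([[p.signal_by_sample["alt_1"], p.signal_by_sample["alt_2"]]
                        for p in peaks])
        calls = pm.congruent_change_peaks(list(peaks), ref, alt)
        truth_class = list(truth["class"])
        gains = [k for k, t in enumerate(truth_class) if t == "gain"]
        recovered = sum(calls[k].klass == "gain" for k in gains)
        assert recovered >= 0.9 * len(gains)


class TestCpG:
    @pytest.mark.parametrize("seq,n", [("CGCG", 2), ("GCGC", 1), ("AAAA", 0)])
    def test_counts(self, seq, n):
        assert pm.count_cpg(seq) == n


class TestPromotersEnhancers:
    def test_promoter_window(self):
        (p,) = pm.define_promoters([("chr1", 1000)], flank_bp=500)
        assert (p.start, p.end) == (500, 1500)

    def test_peak_promoter_annotation_3kb(self):
        peak = Peak(GenomicInterval("chr1", 3900, 4100), summit=4000)
        assert pm.annotate_peak_promoter(peak, [("chr1", 1000)], flank_bp=3000)
        assert not pm.annotate_peak_promoter(peak, [("chr1", 500)],
                                             flank_bp=3000)

    def test_empty_tss_list(self):
        assert pm.define_promoters([]) == []

    def _peak(self, chrom, start, end):
        return Peak(GenomicInterval(chrom, start, end), summit=(start + end) // 2)

    def test_enhancer_definition(self):
        open_peaks = [
            self._peak("c", 100, 200),    # overlaps acetyl, no promoter
            self._peak("c", 300, 400),    # open only
            self._peak("c", 500, 600),    # open + acetyl + promoter
        ]
        acetyl = [self._peak("c", 150, 250), self._peak("c", 550, 650)]
        promoters = [GenomicInterval("c", 590, 700)]
        enh = pm.define_enhancers(open_peaks, acetyl, promoters)
        assert enh == [open_peaks[0].interval]

    def test_enhancer_definition_order_independent_idempotent(self):
        rng = np.random.default_rng(5)
        open_peaks = [self._peak("c", s, s + 50)
                      for s in rng.integers(0, 10_000, 30)]
        acetyl = [self._peak("c", s, s + 80)
                  for s in rng.integers(0, 10_000, 20)]
        promoters = pm.define_promoters([("c", int(t))
                                         for t in rng.integers(0, 10_000, 5)])
        enh1 = pm.define_enhancers(open_peaks, acetyl, promoters)
        enh2 = pm.define_enhancers(open_peaks[::-1], acetyl[::-1],
                                   promoters[::-1])
        assert sorted((e.start, e.end) for e in enh1) == sorted(
            (e.start, e.end) for e in enh2
        )
        # idempotent: re-filtering the enhancer set changes nothing
        as_peaks = [Peak(e, summit=e.midpoint) for e in enh1]
        enh3 = pm.define_enhancers(as_peaks, acetyl, promoters)
        assert [e for e in enh3] == [e.interval for e in as_peaks]


def _loop(chrom, m5, m3):
    return Loop.from_anchors(
        GenomicInterval(chrom, m5 - 5000, m5 + 5000),
        GenomicInterval(chrom, m3 - 5000, m3 + 5000),
        10_000,
    )


class TestLoopDomains:
    def test_smallest_containing_domain(self):
        small = _loop("c", 1_000_000, 1_200_000)   # 200 kb span
        big = _loop("c", 900_000, 1_900_000)       # 1 Mb span
        assert pm.smallest_containing_domain(("c", 1_100_000),
                                             [big, small]) is small

    def test_point_outside_all_domains(self):
        assert pm.smallest_containing_domain(
            ("c", 10), [_loop("c", 1_000_000, 1_200_000)]
        ) is None

    def test_tie_breaks_to_leftmost(self):
        a = _loop("c", 1_000_000, 1_200_000)
        b = _loop("c", 1_050_000, 1_250_000)
        assert pm.smallest_containing_domain(("c", 1_100_000), [b, a]) is a

    def test_flank_enhancer_count(self):
        domain = _loop("c", 2_000_000, 3_000_000)
        left = [GenomicInterval("c", 1_600_000 + k * 10_000,
                                1_601_000 + k * 10_000) for k in range(3)]
        right = [GenomicInterval("c", 3_100_000 + k * 10_000,
                                 3_101_000 + k * 10_000) for k in range(2)]
        inside = [GenomicInterval("c", 2_500_000, 2_501_000)]
        assert pm.count_flank_enhancers(domain, left + right + inside) == 5
        assert pm.count_flank_enhancers(domain, inside) == 0
        assert pm.count_flank_enhancers(domain, []) == 0


class TestNearestDistance:
    def test_basic_and_self_exclusion(self):
        q = [GenomicInterval("c", 900, 1100)]   # midpoint 1000
        subjects = [
            GenomicInterval("c", 900, 1100),    # identical: excluded
            GenomicInterval("c", 2900, 3100),   # midpoint 3000
            GenomicInterval("c", 9900, 10100),
        ]
        (d,) = pm.nearest_distance(q, subjects)
        assert d == 2000

    def test_no_subject_on_chromosome(self):
        q = [GenomicInterval("c1", 0, 100)]
        assert np.isnan(pm.nearest_distance(q, [GenomicInterval("c2", 0, 100)]))

    def test_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(10)
        ivs = [
            GenomicInterval("c", int(s), int(s) + 100)
            for s in rng.integers(0, 1_000_000, 100)
        ]
        got = pm.nearest_distance(ivs, ivs)
        for k, q in enumerate(ivs):
            brute = min(
                abs(q.midpoint - s.midpoint)
                for s in ivs
                if not (s.start == q.start and s.end == q.end)
            )
            assert got[k] == brute
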