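"""PWM scanning: scoring oracles, strand symmetry, counting."""

import importlib.resources as ir
import math

import numpy as np
import pandas as pd
import pytest

import relascape
from relascape.motifs import (
    PWM,
    BackgroundModel,
    PeakSequence,
    estimate_background,
    motif_density_profile,
    motifs_per_peak,
    read_jaspar_pfm,
    read_peak_fasta,
    revcomp,
    scan_peaks,
    score_window,
    write_peak_fasta,
)
from relascape.stats import mann_whitney_two_sided

PWM_PATH = str(ir.files(relascape) / "data" / "rela_pwm_synthetic.jaspar")


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def random_pwm(rng, width):
    counts = rng.integers(0, 50, size=(width, 4)).astype(float)
    return PWM.from_counts(counts)


def oracle_score(window, pwm, bg):
    """Direct product-of-probabilities log ratio."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    lp_m = sum(math.log(pwm.probs[i, code[b]]) for i, b in enumerate(window))
    if bg.order == 0:
        lp_b = sum(math.log(bg.freqs[code[b]]) for b in window)
    else:
        lp_b = math.log(bg.freqs[code[window[0]]])
        for a, b in zip(window, window[1:]):
            lp_b += math.log(bg.transitions[code[a], code[b]])
    return lp_m - lp_b


class TestPWM:
    def test_rows_sum_to_one(self):
        pwm = read_jaspar_pfm(PWM_PATH)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        assert (pwm.probs > 0).all()
        assert pwm.consensus() == "GGGAATTTCC"

    def test_pseudocount_regularizes_zeros(self):
        pwm = PWM.from_counts([[100, 0, 0, 0]], pseudocount=1.0)
        assert pwm.probs[0, 0] == pytest.approx(100.25 / 101)
        assert pwm.probs[0, 1] == pytest.approx(0.25 / 101)


class TestBackground:
    def test_all_a_order0(self):
        bg = estimate_background(["A" * 1000], order=0)
        assert bg.freqs[0] > 0.99

    def test_repeat_transitions(self):
        bg = estimate_background(["AC" * 1000], order=1)
        assert bg.transitions[0, 1] > 0.99  # P(C | A)
        assert bg.transitions[1, 0] > 0.99  # P(A | C)

    def test_uniform_sequence(self, rng):
        bg = estimate_background([random_seq(rng, 10_000)], order=1)
        assert np.allclose(bg.freqs, 0.25, atol=0.02)
        assert np.allclose(bg.transitions, 0.25, atol=0.02)

    def test_empty_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_background([""], order=0)
        with pytest.raises(ValueError):
            estimate_background(["ACGT" * 10], order=1)


class TestScoreWindow:
    def test_consensus_vs_uniform_background(self):
        # near-deterministic PWM scored on its consensus under a uniform
        # order-0 background approaches W * ln 4
        W = 8
        counts = np.zeros((W, 4))
        counts[:, 2] = 10_000  # all G
        pwm = PWM.from_counts(counts)
        bg = BackgroundModel.uniform(0)
        w = score_window("G" * W, pwm, bg)
        assert w == pytest.approx(W * math.log(4), rel=1e-3)

    def test_identity_background_zero(self):
        probs = np.tile([0.1, 0.4, 0.3, 0.2], (5, 1))
        pwm = PWM(probs)
        bg = BackgroundModel(0, np.array([0.1, 0.4, 0.3, 0.2]))
        assert score_window("CGTAC", pwm, bg) == pytest.approx(0.0, abs=1e-12)

    def test_n_window_unscorable(self):
        pwm = random_pwm(np.random.default_rng(0), 4)
        assert math.isnan(score_window("ACNG", pwm, BackgroundModel.uniform(0)))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            W = int(rng.integers(4, 12))
            pwm = random_pwm(rng, W)
            seqs = [random_seq(rng, 300) for _ in range(3)]
            bg = estimate_background(seqs, order=int(rng.integers(0, 2)))
            window = random_seq(rng, W)
            assert score_window(window, pwm, bg) == pytest.approx(
                oracle_score(window, pwm, bg), abs=1e-9
            )


class TestScanPeaks:
    def _setup(self, rng):
        pwm = read_jaspar_pfm(PWM_PATH)
        consensus = pwm.consensus()
        seq = random_seq(rng, 401, gc=0.41)
        summit = 200
        planted = seq[:summit] + consensus + seq[summit + len(consensus):]
        return pwm, consensus, planted, summit

    def test_planted_consensus_at_summit(self, rng):
        pwm, consensus, seq, summit = self._setup(rng)
        bg = BackgroundModel.uniform(1)
        hits = scan_peaks([PeakSequence("pk", seq, summit)], pwm, bg)
        fwd = hits[(hits["strand"] == "+") & (hits["offset"] == 0)]
        assert len(fwd) == 1

    def test_reverse_complement_hit_mirrored(self, rng):
        pwm, consensus, _, _ = self._setup(rng)
        seq = random_seq(rng, 401, gc=0.41)
        summit = 200
        rc = revcomp(consensus)
        planted = seq[:summit] + rc + seq[summit + len(rc):]
        bg = BackgroundModel.uniform(1)
        hits = scan_peaks([PeakSequence("pk", planted, summit)], pwm, bg)
        rev = hits[(hits["strand"] == "-") & (hits["offset"] == 0)]
        assert len(rev) == 1

    def test_threshold_monotonicity(self, rng):
        pwm = read_jaspar_pfm(PWM_PATH)
        seqs = [PeakSequence(f"p{i}", random_seq(rng, 400), 200) for i in range(20)]
        bg = estimate_background([s.seq for s in seqs], order=1)
        prev = None
        for t in (0.0, 1.0, 2.0, 4.0):
            n = len(scan_peaks(seqs, pwm, bg, threshold=t))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_strand_symmetry(self, rng):
        # scanning the reverse-complemented sequences swaps strands and
        # mirrors offsets but leaves per-peak counts invariant
        pwm = read_jaspar_pfm(PWM_PATH)
        seqs = [PeakSequence(f"p{i}", random_seq(rng, 300), 150) for i in range(10)]
        bg = BackgroundModel.uniform(1)
        fwd = scan_peaks(seqs, pwm, bg, threshold=0.5)
        flipped = [
            PeakSequence(s.peak_id, revcomp(s.seq), len(s.seq) - 1 - s.summit_offset)
            for s in seqs
        ]
        rev = scan_peaks(flipped, pwm, bg, threshold=0.5)
        assert len(fwd) == len(rev)
        counts_f = fwd.groupby("peak_id").size().to_dict()
        counts_r = rev.groupby("peak_id").size().to_dict()
        assert counts_f == counts_r

    def test_uniform_pwm_uniform_background_no_hits(self, rng):
        pwm = PWM(np.full((8, 4), 0.25))
        bg = BackgroundModel.uniform(0)
        seqs = [PeakSequence("p", random_seq(rng, 500), 250)]
        assert len(scan_peaks(seqs, pwm, bg, threshold=1.0)) == 0


class TestCounting:
    def _hits(self, offsets):
        return pd.DataFrame({
            "peak_id": ["p0"] * len(offsets),
            "offset": offsets,
            "strand": ["+"] * len(offsets),
            "weight": [2.0] * len(offsets),
        })

    def test_window_boundary(self):
        counts = motifs_per_peak(self._hits([100, 101, -100, -101]), ["p0"], 100)
        assert counts["p0"] == 2

    def test_zero_hits(self):
        counts = motifs_per_peak(self._hits([]), ["p0", "p1"], 100)
        assert counts.tolist() == [0, 0]

    def test_density_profile_trivia(self):
        hits = pd.DataFrame({
            "peak_id": ["p0", "p1"], "offset": [0, 0],
            "strand": ["+", "+"], "weight": [2.0, 2.0],
        })
        prof = motif_density_profile(hits, ["p0", "p1"], flank=100, binsize=20)
        assert prof.loc[prof["bin_offset"] == 0, "fraction"].item() == 1.0
        empty = motif_density_profile(hits.iloc[:0], ["p0"], 100, 20)
        assert (empty["fraction"] == 0).all()

    def test_planted_summit_centered_mode(self, rng):
        pwm = read_jaspar_pfm(PWM_PATH)
        consensus = pwm.consensus()
        seqs = []
        for i in range(100):
            raw = random_seq(rng, 401, gc=0.41)
            off = int(np.clip(rng.normal(0, 15), -60, 60))
            pos = 200 + off
            planted = raw[:pos] + consensus + raw[pos + len(consensus):]
            seqs.append(PeakSequence(f"p{i}", planted, 200))
        bg = BackgroundModel.uniform(1)
        hits = scan_peaks(seqs, pwm, bg, threshold=3.0)
        prof = motif_density_profile(hits, [s.peak_id for s in seqs], 200, 40)
        best = prof.loc[prof["fraction"].idxmax(), "bin_offset"]
        assert best in (-40, 0)  # mode at the summit-centred bins

    def test_planted_group_difference_mann_whitney(self, rng):
        # 4 planted motifs vs 1: Mann-Whitney on per-peak counts p < 0.01
        pwm = read_jaspar_pfm(PWM_PATH)
        consensus = pwm.consensus()

        def group(n_motifs, n_seqs, prefix):
            out = []
            for i in range(n_seqs):
                raw = list(random_seq(rng, 401, gc=0.41))
                for k in range(n_motifs):
                    pos = 120 + 40 * k
                    raw[pos : pos + len(consensus)] = list(consensus)
                out.append(PeakSequence(f"{prefix}{i}", "".join(raw), 200))
            return out

        many, few = group(4, 200, "m"), group(1, 200, "f")
        bg = estimate_background([s.seq for s in many + few], order=1)
        hits = scan_peaks(many + few, pwm, bg, threshold=1.0)
        c_many = motifs_per_peak(hits, [s.peak_id for s in many], 100)
        c_few = motifs_per_peak(hits, [s.peak_id for s in few], 100)
        assert c_many.mean() > c_few.mean()
        assert mann_whitney_two_sided(c_many, c_few) < 0.01


class TestFastaIO:
    def test_roundtrip(self, tmp_path, rng):
        records = [
            ("p0", "chr1", 100, 200, 150, random_seq(rng, 100)),
            ("p1", "chr2", 500, 650, 600, random_seq(rng, 150)),
        ]
        path = tmp_path / "peaks.fasta"
        write_peak_fasta(records, path)
        seqs = read_peak_fasta(path)
        assert [(s.peak_id, s.summit_offset, len(s.seq)) for s in seqs] == [
            ("p0", 50, 100), ("p1", 100, 150)
        ]
        assert seqs[0].seq == records[0][5]
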