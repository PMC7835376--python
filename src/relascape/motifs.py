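"""PWM scanning of peak sequences against a Markov background.

The scanner follows the matrix-scan convention: a window of width W gets a
weight score ln P(window | motif) - ln P(window | background), with the
motif model a pseudocount-regularised position probability matrix and the
background a Markov model of order 0 or 1 estimated from the scanned
sequences themselves.  Hits are windows with weight >= 1 (natural-log
scale) on either strand; positions are reported as the signed offset of the
window start from the peak summit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "PWM",
    "BackgroundModel",
    "PeakSequence",
    "read_jaspar_pfm",
    "read_peak_fasta",
    "write_peak_fasta",
    "estimate_background",
    "score_window",
    "scan_peaks",
    "motifs_per_peak",
    "motif_density_profile",
]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix (W x 4, rows sum to 1, all entries > 0)."""

    probs: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be W x 4 (columns A, C, G, T)")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be > 0 after regularization")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, counts, pseudocount: float = 1.0) -> "PWM":
        """Regularise a count matrix: the pseudocount is distributed equally
        across the four bases at every position."""
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError("count matrix must be W x 4")
        probs = (c + pseudocount / 4.0) / (c.sum(axis=1, keepdims=True) + pseudocount)
        return cls(probs, pseudocount)

    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def read_jaspar_pfm(path, pseudocount: float = 1.0) -> PWM:
    """Read a JASPAR-format position frequency matrix into a PWM."""
    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in ALPHABET], dtype=float).T
    return PWM.from_counts(counts, pseudocount)


@dataclass
class BackgroundModel:
    """Order-0 or order-1 Markov sequence model.

    For order 1 the first base of a window is scored with the initial
    (stationary order-0) distribution and subsequent bases with the 4 x 4
    transition matrix.
    """

    order: int
    freqs: np.ndarray  # order-0 / initial distribution
    transitions: np.ndarray | None = None  # 4 x 4, rows sum to 1

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("background order must be 0 or 1")
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("base frequencies must sum to 1")
        if self.order == 1:
            if self.transitions is None:
                raise ValueError("order-1 background needs a transition matrix")
            self.transitions = np.asarray(self.transitions, dtype=float)
            if not np.allclose(self.transitions.sum(axis=1), 1.0):
                raise ValueError("transition rows must sum to 1")

    @classmethod
    def uniform(cls, order: int = 0) -> "BackgroundModel":
        if order == 0:
            return cls(0, np.full(4, 0.25))
        return cls(1, np.full(4, 0.25), np.full((4, 4), 0.25))


def estimate_background(seqs, order: int = 1, pseudocount: float = 1.0) -> BackgroundModel:
    """Maximum-likelihood background with +pseudocount per cell; bases other
    than ACGT are skipped (and break order-1 adjacency)."""
    base_counts = np.zeros(4)
    trans_counts = np.zeros((4, 4))
    total = 0
    for seq in seqs:
        codes = _encode(seq)
        valid = codes >= 0
        total += int(valid.sum())
        base_counts += np.bincount(codes[valid], minlength=4)
        if order == 1 and len(codes) > 1:
            a, b = codes[:-1], codes[1:]
            ok = (a >= 0) & (b >= 0)
            np.add.at(trans_counts, (a[ok], b[ok]), 1)
    if total == 0:
        raise ValueError("cannot estimate a background from empty input")
    if total < 100 * 4**order:
        raise ValueError(
            f"too little sequence ({total} bp) for an order-{order} background"
        )
    freqs = (base_counts + pseudocount) / (base_counts.sum() + 4 * pseudocount)
    if order == 0:
        return BackgroundModel(0, freqs)
    trans = (trans_counts + pseudocount) / (
        trans_counts.sum(axis=1, keepdims=True) + 4 * pseudocount
    )
    return BackgroundModel(1, freqs, trans)


def _bg_logprob_windows(windows: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    lf = np.log(bg.freqs)
    if bg.order == 0:
        return lf[windows].sum(axis=1)
    lt = np.log(bg.transitions)
    out = lf[windows[:, 0]]
    for j in range(1, windows.shape[1]):
        out = out + lt[windows[:, j - 1], windows[:, j]]
    return out


def score_window(window: str, pwm: PWM, bg: BackgroundModel) -> float:
    """Weight of a single window: ln P(w | motif) - ln P(w | background).

    Windows containing non-ACGT characters are unscorable and return NaN.
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    codes = _encode(window)
    if (codes < 0).any():
        return float("nan")
    w = codes[np.newaxis, :].astype(np.int64)
    lp_motif = pwm.log_probs()[np.arange(pwm.width), codes].sum()
    lp_bg = _bg_logprob_windows(w, bg)[0]
    return float(lp_motif - lp_bg)


@dataclass
class PeakSequence:
    """Sequence under one peak; ``summit_offset`` indexes into ``seq``."""

    peak_id: str
    seq: str
    summit_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < len(self.seq)):
            raise ValueError(
                f"{self.peak_id}: summit offset {self.summit_offset} outside sequence"
            )


def read_peak_fasta(path) -> list[PeakSequence]:
    """Read peak sequences keyed ``id|chrom|start|end|summit`` (summit is the
    absolute genomic position; the in-sequence offset is summit - start)."""
    from Bio import SeqIO

    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 5:
            raise ValueError(
                f"FASTA header {record.id!r}: expected id|chrom|start|end|summit"
            )
        pid, _, start, _, summit = parts
        out.append(PeakSequence(pid, str(record.seq), int(summit) - int(start)))
    return out


def write_peak_fasta(records, path) -> None:
    """``records`` as (peak_id, chrom, start, end, summit, seq) tuples."""
    with open(path, "w") as fh:
        for pid, chrom, start, end, summit, seq in records:
            fh.write(f">{pid}|{chrom}|{start}|{end}|{summit}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _scan_encoded(codes: np.ndarray, pwm: PWM, bg: BackgroundModel):
    """Weights of all windows of one encoded sequence; NaN where unscorable."""
    W = pwm.width
    n_win = len(codes) - W + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, W).astype(np.int64)
    valid = (windows >= 0).all(axis=1)
    weights = np.full(n_win, np.nan)
    if valid.any():
        wv = windows[valid]
        lp_motif = pwm.log_probs()[np.arange(W), wv].sum(axis=1)
        weights[valid] = lp_motif - _bg_logprob_windows(wv, bg)
    return weights


def scan_peaks(
    sequences: list[PeakSequence],
    pwm: PWM,
    bg: BackgroundModel,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Scan both strands of every peak sequence and emit hits with weight >=
    threshold.

    A minus-strand hit is a window whose reverse complement matches; its
    offset refers to the window's start in forward-strand coordinates, so
    counts are strand-symmetric.  Columns: peak_id, offset, strand, weight.
    """
    rows = []
    W = pwm.width
    for ps in sequences:
        codes = _encode(ps.seq)
        fwd = _scan_encoded(codes, pwm, bg)
        rc = _encode(revcomp(ps.seq))
        rev = _scan_encoded(rc, pwm, bg)
        L = len(ps.seq)
        for j in np.flatnonzero(~np.isnan(fwd) & (fwd >= threshold)):
            rows.append((ps.peak_id, int(j) - ps.summit_offset, "+", float(fwd[j])))
        for j in np.flatnonzero(~np.isnan(rev) & (rev >= threshold)):
            start_fwd = L - W - int(j)  # window start in forward coordinates
            rows.append((ps.peak_id, start_fwd - ps.summit_offset, "-", float(rev[j])))
    df = pd.DataFrame(rows, columns=["peak_id", "offset", "strand", "weight"])
    return df.sort_values(["peak_id", "offset", "strand"], ignore_index=True)


def motifs_per_peak(
    hits: pd.DataFrame, peak_ids, half_window: int = 100
) -> pd.Series:
    """Number of hits whose start lies within +/- half_window of the summit,
    for every peak id (zero included)."""
    counts = (
        hits.loc[hits["offset"].abs() <= half_window]
        .groupby("peak_id")
        .size()
    )
    return counts.reindex(list(peak_ids), fill_value=0).astype(int)


def motif_density_profile(
    hits: pd.DataFrame, peak_ids, flank: int, binsize: int
) -> pd.DataFrame:
    """Fraction of peaks with >= 1 hit per distance bin from the summit.

    Bins are [offset, offset + binsize) for offsets -flank .. +flank-binsize;
    a peak counts once per bin however many hits fall in it.
    """
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of binsize")
    peak_ids = list(peak_ids)
    offsets = np.arange(-flank, flank, binsize)
    sub = hits.loc[(hits["offset"] >= -flank) & (hits["offset"] < flank)].copy()
    sub["bin"] = ((sub["offset"] + flank) // binsize).astype(int)
    frac = np.zeros(len(offsets))
    if len(sub):
        per_bin = sub.drop_duplicates(["peak_id", "bin"]).groupby("bin").size()
        frac[per_bin.index] = per_bin.to_numpy() / len(peak_ids)
    return pd.DataFrame({"bin_offset": offsets, "fraction": frac})
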