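"""PWM motif scanning with exact p-value score thresholds, and Tn5
footprint scoring of candidate binding sites.

The score threshold for a motif at p-value ``p`` is the smallest achievable
log-odds score ``s`` with ``P(score >= s) <= p`` under an i.i.d. background
sequence model. The null score distribution is computed by dynamic
programming over positions: after position ``i`` the DP holds the exact
probability mass of every achievable partial score. Partial sums are
accumulated left-to-right, so they coincide bit-for-bit with naive
enumeration over all 4^L words; states are merged only when equal to within
1e-9. For long motifs whose state space would explode, scores fall back to
a fixed 1e-4-bit grid (still far finer than the spacing of realistic
log-odds values).

A footprint at a bound site is a local depletion of transposase insertions:
the mean normalized insertion signal over the site (S_center) drops below
the means over the two flanking windows (S_left, S_right), each flank being
triple the site width. A site passes when both S_left - S_center and
S_right - S_center strictly exceed the configured delta (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import PipelineError
from .genome import GenomicInterval, SignalTrack

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_STATE_KEY_DECIMALS = 9
_SCORE_SLACK = 1e-7  # absorbs per-step key rounding (<= L * 5e-10)
_MAX_DP_STATES = 2_000_000
_FALLBACK_BIN_BITS = 1e-4


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass
class PWM:
    motif_id: str
    tf_name: str
    matrix: np.ndarray        # L x 4 probabilities (A,C,G,T)
    background: np.ndarray    # 4 probabilities
    log_odds: np.ndarray = field(init=False)  # L x 4, bits

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise PipelineError("pwm-shape", "matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise PipelineError("pwm-rowsum", "probability rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise PipelineError("pwm-background", "background must sum to 1")
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.matrix / self.background)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())


def build_pwm(
    counts,
    pseudocount: float = 1.0,
    background=None,
    motif_id: str = "motif",
    tf_name: str | None = None,
) -> PWM:
    """Counts -> probability PWM: (count + pc) / (rowsum + 4 pc)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise PipelineError("pwm-shape", "counts must be L x 4")
    if counts.shape[0] < 1:
        raise PipelineError("pwm-shape", "empty motif")
    if np.any(counts < 0):
        raise PipelineError("pwm-negative", "negative counts")
    if pseudocount == 0 and np.any(counts.sum(axis=1) == 0):
        raise PipelineError("zero-column", "all-zero row with pseudocount 0")
    if background is None:
        background = np.full(4, 0.25)
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return PWM(motif_id, tf_name or motif_id, probs, np.asarray(background, dtype=float))


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    motif_id: str
    site: GenomicInterval
    strand: str
    score: float


def _score_distribution(pwm: PWM) -> dict[float, float]:
    """Exact null distribution {score: probability} under the background."""
    dist: dict[float, float] = {0.0: 1.0}
    for row in pwm.log_odds:
        nxt: dict[float, float] = {}
        for s, pr in dist.items():
            for b in range(4):
                key = round(s + row[b], _STATE_KEY_DECIMALS)
                nxt[key] = nxt.get(key, 0.0) + pr * pwm.background[b]
        if len(nxt) > _MAX_DP_STATES:
            coarse: dict[float, float] = {}
            for s, pr in nxt.items():
                key = round(s / _FALLBACK_BIN_BITS) * _FALLBACK_BIN_BITS
                coarse[key] = coarse.get(key, 0.0) + pr
            nxt = coarse
        dist = nxt
    return dist


def score_threshold(pwm: PWM, p: float) -> float:
    """Smallest achievable score s with P(score >= s) <= p under background.

    Returns max_score + epsilon with a ``p-unreachable`` warning when even
    the best possible word is more probable than ``p`` (motif too short).
    """
    if not (0.0 < p < 1.0):
        raise PipelineError("bad-p", "p must be in (0,1)")
    dist = _score_distribution(pwm)
    scores = sorted(dist, reverse=True)
    # scores within the comparison slack are one mathematical tie (their DP
    # keys may differ by ~1e-9 from float rounding); never split a tie group
    groups: list[tuple[float, float]] = []  # (lowest member, total mass)
    for s in scores:
        if groups and groups[-1][0] - s <= _SCORE_SLACK:
            low, mass = groups[-1]
            groups[-1] = (s, mass + dist[s])
        else:
            groups.append((s, dist[s]))
    tail = 0.0
    threshold = None
    for low, mass in groups:
        tail += mass
        if tail <= p + 1e-15:
            threshold = low
        else:
            break
    if threshold is None:
        warnings.warn(
            f"{pwm.motif_id}: p={p} unreachable (min tail {dist[scores[0]]:.3g})",
            stacklevel=2,
        )
        return pwm.max_score + 1e-6
    return float(threshold)


def score_tail_probability(pwm: PWM, score: float) -> float:
    """P(score of a random background word >= score), from the exact DP."""
    dist = _score_distribution(pwm)
    return float(sum(pr for s, pr in dist.items() if s >= score - _SCORE_SLACK))


def _encode(sequence: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (N) -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def _window_scores(log_odds: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Rounded window scores for every offset; NaN where the window has N."""
    L = log_odds.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = log_odds[np.arange(L), safe].sum(axis=1)
    scores = np.round(scores, _STATE_KEY_DECIMALS)
    scores[~valid] = np.nan
    return scores


def scan_peak(
    pwm: PWM,
    sequence: str,
    threshold: float,
    peak: GenomicInterval | None = None,
    peak_id: str = "peak",
) -> list[MotifHit]:
    """Scan both strands; emit hits with score >= threshold.

    Coordinates are half-open within the peak's genomic frame (or a frame
    starting at 0 when no peak interval is supplied). Windows containing N
    are skipped. A minus-strand hit at sequence offset ``i`` covers the same
    genomic bases as the plus-strand window at ``i``.
    """
    sequence = sequence.upper()
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return []
    if peak is None:
        peak = GenomicInterval("peak", 0, max(n, 1))
    idx = _encode(sequence)
    fwd = _window_scores(pwm.log_odds, idx)
    # reverse strand: score the reverse complement, then map offsets back so
    # a minus hit at offset i covers the same genomic bases as the plus window
    rc_idx = (3 - idx[::-1]) % 4
    rc_idx[idx[::-1] < 0] = -1
    rev = _window_scores(pwm.log_odds, rc_idx)[::-1]
    hits = []
    cut = threshold - _SCORE_SLACK
    for i in np.flatnonzero(~np.isnan(fwd) & (fwd >= cut)):
        site = GenomicInterval(peak.chrom, peak.start + int(i), peak.start + int(i) + L)
        hits.append(MotifHit(peak_id, pwm.motif_id, site, "+", float(fwd[i])))
    for i in np.flatnonzero(~np.isnan(rev) & (rev >= cut)):
        site = GenomicInterval(peak.chrom, peak.start + int(i), peak.start + int(i) + L)
        hits.append(MotifHit(peak_id, pwm.motif_id, site, "-", float(rev[i])))
    return sorted(hits, key=lambda h: (h.site.start, h.strand))


# ------------------------------------------------------------------ footprint


@dataclass(frozen=True)
class FootprintScore:
    s_left: float
    s_center: float
    s_right: float
    passes: bool


def footprint_score(
    insertion: SignalTrack,
    site: GenomicInterval,
    cfg: PipelineConfig | None = None,
    chrom_length: int | None = None,
) -> FootprintScore:
    """Mean insertion over the site vs its two flanks.

    Each flank abuts the site and is ``flank_multiple`` (default 3) times
    the site width; flanks running off the chromosome are truncated with a
    warning. Passing requires BOTH flank-minus-center differences to exceed
    ``footprint_delta`` strictly.
    """
    cfg = cfg or PipelineConfig()
    if len(site) < 1:
        raise PipelineError("bad-site", "zero-width site")
    w = len(site) * cfg.flank_multiple
    left_start = site.start - w
    right_end = site.end + w
    if left_start < 0:
        warnings.warn(f"left flank truncated at chromosome start for {site}", stacklevel=2)
        left_start = 0
    if chrom_length is not None and right_end > chrom_length:
        warnings.warn(f"right flank truncated at chromosome end for {site}", stacklevel=2)
        right_end = chrom_length
    if left_start >= site.start or right_end <= site.end:
        raise PipelineError("bad-site", "no flank room at chromosome edge")
    s_center = insertion.mean_over(site)
    s_left = insertion.mean_over(GenomicInterval(site.chrom, left_start, site.start))
    s_right = insertion.mean_over(GenomicInterval(site.chrom, site.end, right_end))
    # strict >, with a 1e-9 guard so averaging round-off cannot promote an
    # exact-boundary difference past the cutoff
    eps = 1e-9
    passes = (s_left - s_center > cfg.footprint_delta + eps) and (
        s_right - s_center > cfg.footprint_delta + eps
    )
    return FootprintScore(s_left, s_center, s_right, passes)


def predict_binding_sites(
    expression_by_celltype: dict[str, dict[str, float]],
    pwms: dict[str, PWM],
    tf_motifs: dict[str, str],
    peaks: dict[str, GenomicInterval],
    sequences: dict[str, str],
    insertion_by_celltype: dict[str, SignalTrack],
    cfg: PipelineConfig | None = None,
) -> dict[str, list[tuple[str, MotifHit, FootprintScore]]]:
    """Cell-type-specific TF-binding-site prediction.

    Per cell type: drop TFs whose mean normalized expression is below
    ``tf_expr_min`` (default 0.1); scan each expressed TF's motif over the
    peak sequences at the exact-p-value score threshold (``motif_p``,
    default 5e-5); keep hits whose footprint passes for that cell type's
    insertion track.

    ``expression_by_celltype``: cell_type -> {tf: mean normalized expr};
    ``tf_motifs``: tf -> motif_id (TFs without a motif are skipped with a
    warning).
    """
    cfg = cfg or PipelineConfig()
    thresholds = {mid: score_threshold(pwm, cfg.motif_p) for mid, pwm in pwms.items()}
    hit_cache: dict[str, list[MotifHit]] = {}

    def hits_for(motif_id: str) -> list[MotifHit]:
        if motif_id not in hit_cache:
            pwm = pwms[motif_id]
            all_hits = []
            for peak_id, seq in sequences.items():
                all_hits.extend(
                    scan_peak(pwm, seq, thresholds[motif_id], peaks[peak_id], peak_id)
                )
            hit_cache[motif_id] = all_hits
        return hit_cache[motif_id]

    out: dict[str, list[tuple[str, MotifHit, FootprintScore]]] = {}
    for cell_type, expr in expression_by_celltype.items():
        track = insertion_by_celltype[cell_type]
        kept: list[tuple[str, MotifHit, FootprintScore]] = []
        for tf, mean_expr in expr.items():
            if mean_expr < cfg.tf_expr_min:
                continue
            motif_id = tf_motifs.get(tf)
            if motif_id is None or motif_id not in pwms:
                warnings.warn(f"no-motif: TF {tf} has no PWM; skipped", stacklevel=2)
                continue
            for hit in hits_for(motif_id):
                fp = footprint_score(track, hit.site, cfg)
                if fp.passes:
                    kept.append((tf, hit, fp))
        out[cell_type] = kept
    return out
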