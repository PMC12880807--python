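"""Classification of accessible elements by histone-mark evidence.

An accessible element carries a histone mark when it overlaps a called
peak for that mark AND its mean signal within the element exceeds 2.5
(strict). Classes are assigned with precedence
H3K4me3+ -> TSS; else H3K27ac+ -> aEnhancer; else H3K4me1+ -> pEnhancer;
else unclassified. An optional bivalent-TSS flag (H3K4me3+ and H3K27me3+)
can be requested; it never changes the class.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .errors import PipelineError
from .genome import GenomicInterval, SignalTrack

REQUIRED_MARKS = ("H3K4me3", "H3K27ac", "H3K4me1")
CLASSES = ("TSS", "aEnhancer", "pEnhancer", "unclassified")


@dataclass(frozen=True)
class MarkCall:
    mark: str
    overlaps_peak: bool
    mean_signal: float
    positive: bool


@dataclass(frozen=True)
class ElementAnnotation:
    peak_id: str
    calls: dict
    cls: str
    bivalent: bool = False


def mean_signal_in(track: SignalTrack, region: GenomicInterval) -> float:
    """Length-weighted mean signal over region; uncovered bases count 0."""
    return track.mean_over(region)


def call_mark(
    peak: GenomicInterval,
    mark: str,
    mark_peaks: list[GenomicInterval],
    mark_track: SignalTrack,
    cfg: PipelineConfig | None = None,
) -> MarkCall:
    cfg = cfg or PipelineConfig()
    overlaps = any(peak.overlaps(mp) for mp in mark_peaks)
    mean = mean_signal_in(mark_track, peak)
    positive = overlaps and mean > cfg.histone_signal_min
    return MarkCall(mark, overlaps, mean, positive)


def classify_element(calls: dict) -> str:
    """Precedence rule over the three required marks (strictly one class)."""
    missing = [m for m in REQUIRED_MARKS if m not in calls]
    if missing:
        raise PipelineError("missing-mark", f"missing marks: {missing}")
    if calls["H3K4me3"].positive:
        return "TSS"
    if calls["H3K27ac"].positive:
        return "aEnhancer"
    if calls["H3K4me1"].positive:
        return "pEnhancer"
    return "unclassified"


def annotate_elements(
    peaks: dict[str, GenomicInterval],
    mark_peaks: dict[str, list[GenomicInterval]],
    mark_tracks: dict[str, SignalTrack],
    cfg: PipelineConfig | None = None,
    flag_bivalent: bool = False,
) -> dict[str, ElementAnnotation]:
    """Annotate every peak; marks beyond the required three are called but
    only H3K27me3 participates (and only in the optional bivalent flag)."""
    cfg = cfg or PipelineConfig()
    out = {}
    for peak_id, peak in peaks.items():
        calls = {
            mark: call_mark(peak, mark, mark_peaks.get(mark, []), mark_tracks[mark], cfg)
            for mark in mark_tracks
        }
        cls = classify_element(calls)
        bivalent = (
            flag_bivalent
            and "H3K27me3" in calls
            and calls["H3K4me3"].positive
            and calls["H3K27me3"].positive
        )
        out[peak_id] = ElementAnnotation(peak_id, calls, cls, bivalent)
    return out
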