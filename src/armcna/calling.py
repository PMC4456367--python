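"""Allele-specific copy-number calling from paired tumor/normal probe signals.

The caller works on the relative-ratio scale of genome-imbalance mapping:
per SNP and per allele, the tumor/normal intensity ratio is computed (with a
trimmed-median summary when replicate probes are present), smoothed by a
running median along the genome, and thresholded — ratio > 1.3 is a gain
(1.6 copies), ratio < 0.7 a loss (0.4 copies), both strict.  Maximal runs of
a constant per-allele state pair become segments, which are then categorised:

========================  =================================
(A-state, B-state)        category
========================  =================================
(loss, loss)              homozygous-deletion
(loss, gain) either way   cnn-loh (copy-number-neutral LOH)
one loss, other neutral   hemizygous-loss
any gain, no loss         gain
(neutral, neutral)        no segment
========================  =================================

Finally each segment is classified focal vs whole-arm: a segment whose probe
span covers more than 98% of the genomic span between its arm's first and
last probe is whole-arm.  Segments crossing the centromere are split at the
arm boundary before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation

__all__ = [
    "CallerConfig",
    "compute_allelic_ratios",
    "smooth_ratios",
    "call_segments",
    "classify_arm_span",
    "arm_events_from_segments",
    "write_seg",
    "read_segments",
]

_SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "state_a", "state_b",
                "category", "n_probes", "ratio_a", "ratio_b"]


@dataclass
class CallerConfig:
    """Thresholds and smoothing settings of the caller.

    gain_threshold / loss_threshold
        Strict ratio cut-offs: > 1.3 gain, < 0.7 loss (1.6 and 0.4 copies
        on the 0.5/1.0/1.5 ratio scale).
    gain_extend / loss_extend
        Hysteresis extension thresholds.  A run must contain at least one
        probe beyond the detection threshold, but extends over contiguous
        probes beyond the (weaker) extension threshold, so a long event
        whose smoothed track grazes the detection cut-off is not
        fragmented.  Setting them equal to the detection thresholds
        disables hysteresis.
    smoothing_window
        Running-median window in probes; odd, truncated at chromosome ends.
    min_probes
        Minimum probes for an emitted segment.
    max_gap
        A run of <= max_gap discordant probes inside an otherwise constant
        state run is absorbed into the run (noise tolerance).
    whole_arm_fraction
        A segment spanning more than this fraction of its arm's probe span
        is whole-arm (strictly greater; exactly 98% is focal).
    """

    gain_threshold: float = 1.3
    loss_threshold: float = 0.7
    gain_extend: float = 1.15
    loss_extend: float = 0.85
    smoothing_window: int = 15
    min_probes: int = 10
    max_gap: int = 2
    whole_arm_fraction: float = 0.98

    def __post_init__(self) -> None:
        if not self.loss_threshold < 1.0 < self.gain_threshold:
            raise ValueError("need loss_threshold < 1 < gain_threshold")
        if not self.loss_threshold <= self.loss_extend < 1.0 < self.gain_extend \
                <= self.gain_threshold:
            raise ValueError("extension thresholds must lie between the "
                             "detection thresholds and 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if not 0.0 < self.whole_arm_fraction < 1.0:
            raise ValueError("whole_arm_fraction must be in (0, 1)")


def trimmed_replicate_summary(values: np.ndarray) -> np.ndarray:
    """Median after dropping one maximum and one minimum, per row.

    Requires >= 3 replicates; the robust per-SNP summary used before ratio
    formation when replicate probe intensities are available.
    """
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] < 3:
        raise ValueError("trimmed summary needs >= 3 replicates")
    s = np.sort(values, axis=1)
    return np.median(s[:, 1:-1], axis=1)


def _replicate_columns(table: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in table.columns
            if c.startswith(prefix + "_") and c[len(prefix) + 1:].isdigit()]
    return sorted(cols, key=lambda c: int(c.rsplit("_", 1)[1]))


def compute_allelic_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP, per-allele tumor/normal relative ratios.

    *table* carries columns ``snp_id, chrom, pos, tumorA, tumorB, normalA,
    normalB``; alternatively replicate columns ``tumorA_1 .. tumorA_k`` (and
    likewise for the other three signals, k >= 3), which are collapsed with
    the trimmed-median summary before the ratio is formed.

    Returns the table extended with ``ratio_a`` and ``ratio_b``.
    """
    out = table.copy()
    signals = {}
    for name in ("tumorA", "tumorB", "normalA", "normalB"):
        reps = _replicate_columns(table, name)
        if reps:
            signals[name] = trimmed_replicate_summary(table[reps].to_numpy())
        elif name in table.columns:
            signals[name] = table[name].to_numpy(float)
        else:
            raise KeyError(f"missing signal column {name}")
    for which in ("A", "B"):
        normal = signals[f"normal{which}"]
        bad = ~(normal > 0)
        if bad.any():
            snp = table["snp_id"].to_numpy()[bad][0]
            raise ValueError(f"non-positive normal {which} signal at SNP {snp}")
        out[f"ratio_{which.lower()}"] = signals[f"tumor{which}"] / normal
    return out


def smooth_ratios(track: pd.DataFrame, config: CallerConfig | None = None) -> pd.DataFrame:
    """Running-median smoothing of both allelic ratios along each chromosome.

    The window is centred and truncated at chromosome ends, so the output
    has the same length and order as the input.  If a chromosome has fewer
    probes than the window, its whole-chromosome median is used (with a
    warning).
    """
    config = config or CallerConfig()
    w = config.smoothing_window
    out = track.copy()
    for col in ("ratio_a", "ratio_b"):
        smoothed = np.empty(len(track))
        for chrom, sub in track.groupby("chrom", sort=False):
            vals = sub[col]
            if len(vals) < w:
                warnings.warn(
                    f"smoothing window {w} exceeds {len(vals)} probes on "
                    f"chromosome {chrom}; using whole-chromosome median",
                    stacklevel=2)
                sm = pd.Series(np.full(len(vals), vals.median()), index=vals.index)
            else:
                sm = vals.rolling(w, center=True, min_periods=1).median()
            smoothed[track.index.get_indexer(sub.index)] = sm.to_numpy()
        out[col] = smoothed
    return out


def _probe_states(ratios: np.ndarray, config: CallerConfig) -> np.ndarray:
    """-1 loss / 0 neutral / +1 gain per probe, hysteresis thresholding.

    A probe is assigned a non-neutral state when it lies in a contiguous
    run beyond the extension threshold that contains at least one probe
    beyond the strict detection threshold (> gain_threshold or
    < loss_threshold).  With extension == detection this reduces to plain
    strict thresholding.
    """
    out = np.zeros(len(ratios), dtype=int)
    for sign, strong_mask, weak_mask in (
        (1, ratios > config.gain_threshold, ratios > config.gain_extend),
        (-1, ratios < config.loss_threshold, ratios < config.loss_extend),
    ):
        i, n = 0, len(ratios)
        while i < n:
            if not weak_mask[i]:
                i += 1
                continue
            j = i
            while j < n and weak_mask[j]:
                j += 1
            if strong_mask[i:j].any():
                out[i:j] = sign
            i = j
    return out


def _merge_gaps(pairs: np.ndarray, max_gap: int) -> list[tuple[int, int, tuple]]:
    """Run-length encode state pairs, absorbing short discordant gaps.

    A run of <= max_gap probes flanked on both sides by runs of one same
    state pair is absorbed into that pair, iterated to a fixed point.
    """
    runs = [(s, e, tuple(pairs[s])) for s, e in _runs_pairs(pairs)]
    changed = True
    while changed and len(runs) >= 3:
        changed = False
        out = [runs[0]]
        i = 1
        while i < len(runs):
            s, e, st = runs[i]
            prev = out[-1]
            if (i + 1 < len(runs) and (e - s) <= max_gap
                    and prev[2] == runs[i + 1][2] and prev[2] != st):
                nxt = runs[i + 1]
                out[-1] = (prev[0], nxt[1], prev[2])
                i += 2
                changed = True
            else:
                if st == prev[2]:
                    out[-1] = (prev[0], e, st)
                else:
                    out.append(runs[i])
                i += 1
        runs = out
    return runs


def _runs_pairs(pairs: np.ndarray) -> list[tuple[int, int]]:
    diff = np.any(pairs[1:] != pairs[:-1], axis=1)
    edges = np.flatnonzero(diff) + 1
    bounds = np.concatenate([[0], edges, [len(pairs)]])
    return list(zip(bounds[:-1], bounds[1:]))


def _category(sa: int, sb: int) -> str | None:
    if (sa, sb) == (0, 0):
        return None
    if sa == -1 and sb == -1:
        return "homozygous-deletion"
    if -1 in (sa, sb) and 1 in (sa, sb):
        return "cnn-loh"
    if -1 in (sa, sb):
        return "hemizygous-loss"
    return "gain"


_STATE_NAME = {-1: "loss", 0: "neutral", 1: "gain"}


def call_segments(track: pd.DataFrame, genome: GenomeAnnotation,
                  config: CallerConfig | None = None,
                  sample_id: str = "sample") -> pd.DataFrame:
    """Threshold the smoothed ratio track and emit CNA segments.

    Returns a DataFrame with one row per segment: coordinates (0-based
    half-open, from first probe position to last probe position + 1),
    per-allele states, category, probe count and mean smoothed ratios.
    """
    config = config or CallerConfig()
    if len(track) != len(genome.probes):
        raise ValueError("ratio track and genome probe map differ in length")
    if not np.array_equal(track["pos"].to_numpy(), genome.probes["pos"].to_numpy()):
        raise ValueError("ratio track and genome probe map differ in positions")
    segments = []
    for chrom, sub in track.groupby("chrom", sort=False):
        ra = sub["ratio_a"].to_numpy()
        rb = sub["ratio_b"].to_numpy()
        pos = sub["pos"].to_numpy()
        pairs = np.stack([_probe_states(ra, config), _probe_states(rb, config)], axis=1)
        for s, e, (sa, sb) in _merge_gaps(pairs, config.max_gap):
            cat = _category(sa, sb)
            if cat is None or (e - s) < config.min_probes:
                continue
            segments.append((
                sample_id, chrom, int(pos[s]), int(pos[e - 1]) + 1,
                _STATE_NAME[sa], _STATE_NAME[sb], cat, int(e - s),
                float(np.mean(ra[s:e])), float(np.mean(rb[s:e])),
            ))
    return pd.DataFrame(segments, columns=_SEG_COLUMNS)


def classify_arm_span(segments: pd.DataFrame, genome: GenomeAnnotation,
                      config: CallerConfig | None = None) -> pd.DataFrame:
    """Assign each segment to an arm and classify it focal vs whole-arm.

    Segments spanning the centromere are split at the arm boundary first.
    The span fraction is the genomic length of the segment's probe span
    divided by the span between the arm's first and last probe; strictly
    greater than ``whole_arm_fraction`` (default 0.98) means whole-arm.

    Returns the segments with added columns ``arm``, ``span_fraction`` and
    ``span_class``.
    """
    config = config or CallerConfig()
    rows = []
    for _, seg in segments.iterrows():
        for part in _split_at_centromere(seg, genome):
            # splitting can leave sub-minimal slivers (e.g. smoothing bleed
            # across the centromere); the probe-count floor still applies
            if part["n_probes"] < config.min_probes:
                continue
            first, last = genome.arm_probe_span(part["chrom"], part["arm"])
            arm_span = last - first
            lo = max(part["start"], first)
            hi = min(part["end"] - 1, last)
            frac = (hi - lo) / arm_span if arm_span > 0 else 1.0
            part["span_fraction"] = frac
            part["span_class"] = ("whole-arm" if frac > config.whole_arm_fraction
                                  else "focal")
            rows.append(part)
    return pd.DataFrame(rows, columns=_SEG_COLUMNS + ["arm", "span_fraction",
                                                      "span_class"])


def _split_at_centromere(seg: pd.Series, genome: GenomeAnnotation) -> list[dict]:
    arms = genome.arms[genome.arms["chrom"] == seg["chrom"]]
    parts = []
    for _, arm in arms.iterrows():
        lo = max(seg["start"], arm["start"])
        hi = min(seg["end"], arm["end"])
        if lo >= hi:
            continue
        sub = genome.probes[(genome.probes["chrom"] == seg["chrom"]) &
                            (genome.probes["arm"] == arm["arm"]) &
                            (genome.probes["pos"] >= lo) & (genome.probes["pos"] < hi)]
        if sub.empty:
            continue
        d = seg.to_dict()
        d.update(start=int(lo), end=int(hi), arm=str(arm["arm"]),
                 n_probes=int(len(sub)))
        parts.append(d)
    if not parts:
        raise ValueError(
            f"segment {seg['chrom']}:{seg['start']}-{seg['end']} overlaps no modeled arm")
    return parts


def arm_events_from_segments(classified: pd.DataFrame) -> pd.DataFrame:
    """One event per (sample, arm): whole-arm if any segment there is whole-arm.

    This is the counting unit for arm-level event tables — a tumor
    contributes each altered arm exactly once.
    """
    if classified.empty:
        return pd.DataFrame(columns=["sample_id", "chrom", "arm", "event_class"])
    grp = classified.groupby(["sample_id", "chrom", "arm"], sort=False)
    rows = []
    for (sid, chrom, arm), sub in grp:
        cls = "whole-arm" if (sub["span_class"] == "whole-arm").any() else "focal"
        rows.append((sid, chrom, arm, cls))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "arm", "event_class"])


def write_seg(classified: pd.DataFrame, seg_path, sidecar_path=None) -> None:
    """Write segments as IGV ``.seg`` plus an optional sidecar TSV.

    ``seg.mean`` is log2 of the total-copy ratio, estimated from the mean
    allelic ratios as ``log2(ratio_a + ratio_b - 1)`` (each allele ratio r
    maps to r*2 - 1 copies on the 0.5/1.0/1.5 scale; total relative copy
    number is their mean).
    """
    total = (classified["ratio_a"] + classified["ratio_b"] - 1.0).clip(lower=1e-3)
    seg = pd.DataFrame({
        "ID": classified["sample_id"],
        "chrom": classified["chrom"],
        "loc.start": classified["start"],
        "loc.end": classified["end"],
        "num.mark": classified["n_probes"],
        "seg.mean": np.round(np.log2(total), 4),
    })
    seg.to_csv(seg_path, sep="\t", index=False)
    if sidecar_path is not None:
        classified.to_csv(sidecar_path, sep="\t", index=False)


def read_segments(sidecar_path) -> pd.DataFrame:
    """Read the sidecar TSV written by :func:`write_seg`."""
    return pd.read_csv(sidecar_path, sep="\t",
                       dtype={"chrom": str, "arm": str, "sample_id": str})
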