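"""Recovery metrics against planted ground truth.

Used by the test-suite and the reproduction script to score the caller on
simulated cohorts: a planted event is *recovered* when a called segment of
the same sample and chromosome overlaps at least half of it; a called
segment is a *false discovery* when planted events cover less than half of
its own span.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["segment_recovery"]


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def segment_recovery(truth: pd.DataFrame, classified: pd.DataFrame,
                     min_overlap: float = 0.5) -> dict:
    """Score called segments against the planted truth table.

    Returns sensitivity, false-discovery rate, category accuracy among the
    recovered events, and the planted vs called whole-arm event fractions.
    """
    tp = 0
    cat_ok = 0
    for _, ev in truth.iterrows():
        sub = classified[(classified["sample_id"] == ev["sample_id"]) &
                         (classified["chrom"] == ev["chrom"])]
        best, best_ov = None, 0
        for j, c in sub.iterrows():
            ov = _overlap(ev["start"], ev["end"], c["start"], c["end"])
            if ov > best_ov:
                best_ov, best = ov, j
        if best is not None and best_ov >= min_overlap * (ev["end"] - ev["start"]):
            tp += 1
            if classified.loc[best, "category"] == ev["category"]:
                cat_ok += 1
    fp = 0
    for _, c in classified.iterrows():
        sub = truth[(truth["sample_id"] == c["sample_id"]) &
                    (truth["chrom"] == c["chrom"])]
        covered = sum(_overlap(c["start"], c["end"], ev["start"], ev["end"])
                      for _, ev in sub.iterrows())
        if covered < min_overlap * (c["end"] - c["start"]):
            fp += 1
    from .calling import arm_events_from_segments
    events = arm_events_from_segments(classified)
    return {
        "n_planted": int(len(truth)),
        "n_called": int(len(classified)),
        "sensitivity": tp / len(truth) if len(truth) else float("nan"),
        "fdr": fp / len(classified) if len(classified) else 0.0,
        "category_accuracy": cat_ok / tp if tp else float("nan"),
        "whole_arm_fraction_planted": float(truth["whole_arm"].mean())
        if len(truth) else float("nan"),
        "whole_arm_fraction_called": float((events["event_class"] == "whole-arm").mean())
        if len(events) else float("nan"),
    }
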