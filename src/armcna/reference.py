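"""Published reference inputs: arm-level event counts and contingency tables.

These are the printed summary data of a published ovarian-carcinoma cohort
(14 high-grade serous and 31 clear-cell tumors profiled on paired 250K SNP
arrays; 55 tumors on expression arrays).  They serve as fixed inputs for the
arm-level arithmetic and the exact contingency tests — no patient-level data
are included or required.

Notes
-----
The serous "arm change" column of the published per-arm table sums to 51
whole-arm events (232 total) while the accompanying text reports 50/231;
:func:`arm_count_summary` tallies the table as printed and leaves the choice
of totals to the caller.  The clear-cell columns reconcile exactly
(99 whole-arm / 112 focal).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_arm_event_counts",
    "arm_count_summary",
    "CONTINGENCY_TABLES",
    "REPORTED_TOTALS",
]

#: Printed cohort totals used for the whole-arm ratio comparison
#: (whole-arm events, all events, sample count) per histology.
REPORTED_TOTALS = {
    "CCC": {"whole_arm": 99, "all_events": 211, "n_samples": 31},
    "SC": {"whole_arm": 50, "all_events": 231, "n_samples": 13},
}

#: Published 2x2 contingency tables (rows x columns as printed), with the
#: comparison each encodes.
CONTINGENCY_TABLES = {
    # coexistent PIK3CA+ARID1A alteration: present/absent x CCC-1/3 vs CCC-2
    "pik3ca_arid1a_coalteration": [[7, 4], [0, 10]],
    # ARID1A decreased expression: present/absent x CCC-1/3 vs CCC-2
    "arid1a_loss": [[8, 2], [3, 8]],
    # stage I/II vs III/IV x CCC-1 vs CCC-3
    "stage_ccc1_vs_ccc3": [[9, 0], [3, 3]],
    # chemosensitive/resistant x expression cluster A vs B+C
    "chemosensitivity_cluster_a": [[1, 5], [10, 4]],
    # stage I/II vs III/IV x expression cluster A vs B+C
    "stage_cluster_a": [[19, 16], [2, 18]],
    # whole-arm vs focal events x CCC vs SC (reported totals)
    "whole_arm_ccc_vs_sc": [[99, 112], [50, 181]],
}


def load_arm_event_counts() -> pd.DataFrame:
    """Per-arm whole-arm / focal event counts for the serous and clear-cell
    groups, one row per modeled chromosome arm (41 arms, acrocentric short
    arms absent)."""
    with resources.files("armcna.data").joinpath(
            "reference_arm_event_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"arm": str})


def arm_count_summary() -> dict:
    """Column sums, whole-arm ratios and mean event counts from the table.

    Ratios are percentages; means are events per sample to one decimal,
    using the published sample counts (31 clear-cell, 13 serous with
    informative arrays).
    """
    tab = load_arm_event_counts()
    ccc_w = int(tab["ccc_whole_arm"].sum())
    ccc_f = int(tab["ccc_focal"].sum())
    sc_w = int(tab["sc_whole_arm"].sum())
    sc_f = int(tab["sc_focal"].sum())
    return {
        "ccc_whole_arm": ccc_w,
        "ccc_focal": ccc_f,
        "sc_whole_arm": sc_w,
        "sc_focal": sc_f,
        "ccc_whole_arm_ratio_pct": round(100.0 * ccc_w / (ccc_w + ccc_f), 1),
        "sc_whole_arm_ratio_pct": round(100.0 * sc_w / (sc_w + sc_f), 1),
        "ccc_mean_cna": round((ccc_w + ccc_f) / REPORTED_TOTALS["CCC"]["n_samples"], 1),
        "sc_mean_cna_reported": round(
            REPORTED_TOTALS["SC"]["all_events"] / REPORTED_TOTALS["SC"]["n_samples"], 1),
    }
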