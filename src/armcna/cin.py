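"""Arm-level CNA burden: CIN classes, event tables, clustering, TSG LOH.

A tumor's chromosomal-instability (CIN) class is driven by the number of
chromosome arms carrying at least one alteration of any category (gains,
losses, homozygous deletions and copy-number-neutral LOH all count):

* ``negative`` — 0 altered arms
* ``low`` — 1 to 8 altered arms
* ``high`` — 9 or more altered arms

Arm-level event tables count one event per (sample, arm), whole-arm taking
precedence over focal when an arm carries both.  The same per-arm encoding
(none=0, focal=1, whole-arm=2) is the feature matrix for hierarchical
clustering of CNA profiles (Euclidean distance, complete linkage).

Tumor-suppressor LOH status is read off segment overlap with a small
built-in locus table (TP53, NF1, BRCA1 on 17; RB1, BRCA2 on 13; GRCh37
coordinates), overridable with a BED file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genome import GenomeAnnotation
from .stats import fisher_exact_two_sided

__all__ = [
    "DEFAULT_TSG_LOCI",
    "cin_class",
    "build_cna_profiles",
    "arm_event_matrix",
    "arm_event_table",
    "whole_arm_ratio_test",
    "mean_cna_count",
    "cluster_cna_profiles",
    "tsg_loh_status",
    "loh_co_occurrence",
    "read_loci_bed",
]

_EVENT_CODE = {"none": 0, "focal": 1, "whole-arm": 2}

#: Built-in tumor-suppressor loci (GRCh37 bp), one row per gene.
DEFAULT_TSG_LOCI = pd.DataFrame(
    [
        ("TP53", "17", "17p13.1", 7_571_720, 7_590_868),
        ("NF1", "17", "17q11.2", 29_421_945, 29_708_905),
        ("BRCA1", "17", "17q21.2", 41_196_312, 41_277_500),
        ("RB1", "13", "13q14.2", 48_877_883, 49_056_122),
        ("BRCA2", "13", "13q13.2", 32_889_611, 32_973_805),
    ],
    columns=["gene", "chrom", "cytoband", "start", "end"],
)


def cin_class(arm_count: int) -> str:
    """CIN class from the number of arms with >= 1 CNA (boundaries 0/1, 8/9)."""
    if arm_count < 0:
        raise ValueError("arm count must be non-negative")
    if arm_count == 0:
        return "negative"
    return "high" if arm_count >= 9 else "low"


def build_cna_profiles(arm_events: pd.DataFrame, genome: GenomeAnnotation,
                       sample_ids=None, histology=None) -> pd.DataFrame:
    """Per-sample arm count and CIN class from the arm-event table.

    *arm_events* is the one-event-per-(sample, arm) table produced by
    :func:`armcna.calling.arm_events_from_segments`.  *sample_ids* may list
    samples with zero events so they appear as CIN-negative; *histology*
    optionally maps sample id to a group label.
    """
    counts = arm_events.groupby("sample_id").size() if len(arm_events) else pd.Series(dtype=int)
    ids = list(sample_ids) if sample_ids is not None else sorted(counts.index)
    rows = []
    for sid in ids:
        n = int(counts.get(sid, 0))
        if n > genome.n_arms:
            raise ValueError(f"sample {sid}: more altered arms than modeled arms")
        rows.append({
            "sample_id": sid,
            "histology": None if histology is None else histology[sid],
            "arm_count": n,
            "cin_class": cin_class(n),
        })
    return pd.DataFrame(rows)


def arm_event_matrix(arm_events: pd.DataFrame, genome: GenomeAnnotation,
                     sample_ids=None) -> pd.DataFrame:
    """Samples x arms matrix encoding per-arm event class as 0/1/2.

    none=0, focal=1, whole-arm=2 — the ordinal encoding used for CNA-profile
    clustering.
    """
    ids = list(sample_ids) if sample_ids is not None \
        else sorted(arm_events["sample_id"].unique())
    mat = pd.DataFrame(0, index=ids, columns=genome.arm_names, dtype=int)
    for _, ev in arm_events.iterrows():
        mat.loc[ev["sample_id"], f"{ev['chrom']}{ev['arm']}"] = _EVENT_CODE[ev["event_class"]]
    return mat


def arm_event_table(arm_events: pd.DataFrame, groups: pd.Series,
                    genome: GenomeAnnotation | None = None) -> pd.DataFrame:
    """Per (arm, group) whole-arm and focal event counts, with totals.

    *groups* maps sample id to group label; every sample in *arm_events*
    must be labeled.  Returns a long table (``arm``, ``group``,
    ``whole_arm``, ``focal``) whose grand totals equal the number of
    (sample, arm) pairs with at least one segment.
    """
    groups = pd.Series(groups)
    unknown = set(arm_events["sample_id"]) - set(groups.index)
    if unknown:
        raise KeyError(f"samples without group label: {sorted(unknown)[:5]}")
    ev = arm_events.copy()
    ev["group"] = ev["sample_id"].map(groups)
    ev["arm_name"] = ev["chrom"].astype(str) + ev["arm"].astype(str)
    arms = genome.arm_names if genome is not None else sorted(ev["arm_name"].unique())
    rows = []
    for arm in arms:
        for grp in sorted(groups.unique()):
            sub = ev[(ev["arm_name"] == arm) & (ev["group"] == grp)]
            rows.append({
                "arm": arm,
                "group": grp,
                "whole_arm": int((sub["event_class"] == "whole-arm").sum()),
                "focal": int((sub["event_class"] == "focal").sum()),
            })
    return pd.DataFrame(rows)


@dataclass
class WholeArmRatioResult:
    """Whole-arm fraction per group and the Fisher comparison between two."""

    ratios: dict
    counts: dict          # group -> (whole_arm, focal)
    p_value: float | None
    undefined_groups: list


def whole_arm_ratio_test(table: pd.DataFrame, group_a: str, group_b: str
                         ) -> WholeArmRatioResult:
    """Whole-arm / all-events ratio per group and a two-sided Fisher p.

    The 2x2 table is (whole-arm, focal) x (group_a, group_b).  A group with
    zero events has an undefined ratio and is flagged rather than tested.
    """
    counts, ratios, undefined = {}, {}, []
    for grp in (group_a, group_b):
        sub = table[table["group"] == grp]
        if sub.empty:
            raise KeyError(f"group {grp!r} absent from event table")
        w, f = int(sub["whole_arm"].sum()), int(sub["focal"].sum())
        counts[grp] = (w, f)
        if w + f == 0:
            undefined.append(grp)
            ratios[grp] = None
        else:
            ratios[grp] = w / (w + f)
    if undefined:
        return WholeArmRatioResult(ratios, counts, None, undefined)
    res = fisher_exact_two_sided([[counts[group_a][0], counts[group_a][1]],
                                  [counts[group_b][0], counts[group_b][1]]])
    return WholeArmRatioResult(ratios, counts, res.p_value, [])


def mean_cna_count(profiles: pd.DataFrame, group: str | None = None) -> float:
    """Mean arm-level events per sample in a group, to one decimal.

    Events follow the arm-event convention: each altered arm counts once.
    """
    sub = profiles if group is None else profiles[profiles["histology"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} has no samples")
    return float(np.round(sub["arm_count"].sum() / len(sub), 1))


def cluster_cna_profiles(matrix: pd.DataFrame, k: int):
    """Hierarchical clustering of per-arm CNA profiles.

    Euclidean distance, complete linkage, tree cut at *k*.  Returns
    ``(labels, linkage_matrix)`` with labels as a Series (values 1..k)
    indexed like the matrix rows.
    """
    if k > len(matrix):
        raise ValueError("k exceeds the number of samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    z = hierarchy.linkage(pdist(matrix.to_numpy(float), metric="euclidean"),
                          method="complete")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster"), z


def read_loci_bed(path) -> pd.DataFrame:
    """Gene loci from a BED file (chrom, start, end, name; 0-based half-open)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "gene"],
                      usecols=[0, 1, 2, 3], dtype={"chrom": str})
    bed["chrom"] = bed["chrom"].str.removeprefix("chr")
    bed["cytoband"] = ""
    return bed[["gene", "chrom", "cytoband", "start", "end"]]


def tsg_loh_status(classified: pd.DataFrame, loci: pd.DataFrame | None = None,
                   genome: GenomeAnnotation | None = None,
                   sample_ids=None) -> pd.DataFrame:
    """Per (sample, gene) LOH status from segment overlap.

    Any overlap counts.  A locus overlapped by a hemizygous-loss or
    homozygous-deletion segment is ``LOH``; one overlapped only by a
    cnn-loh segment is ``CNN LOH``; otherwise ``nl`` (physical loss takes
    precedence when both overlap).  Returns samples x genes DataFrame.
    """
    loci = DEFAULT_TSG_LOCI if loci is None else loci
    if genome is not None:
        bounds = genome.arms.groupby("chrom").agg(lo=("start", "min"),
                                                  hi=("end", "max"))
        for _, g in loci.iterrows():
            if g["chrom"] not in bounds.index or not (
                    bounds.loc[g["chrom"], "lo"] <= g["start"]
                    and g["end"] <= bounds.loc[g["chrom"], "hi"]):
                raise ValueError(f"locus {g['gene']} outside modeled genome")
    ids = list(sample_ids) if sample_ids is not None \
        else sorted(classified["sample_id"].unique())
    status = pd.DataFrame("nl", index=ids, columns=list(loci["gene"]))
    for _, g in loci.iterrows():
        over = classified[(classified["chrom"] == g["chrom"]) &
                          (classified["start"] < g["end"]) &
                          (classified["end"] > g["start"])]
        for sid, sub in over.groupby("sample_id"):
            if sid not in status.index:
                continue
            cats = set(sub["category"])
            if cats & {"hemizygous-loss", "homozygous-deletion"}:
                status.loc[sid, g["gene"]] = "LOH"
            elif "cnn-loh" in cats:
                status.loc[sid, g["gene"]] = "CNN LOH"
    return status


def loh_co_occurrence(status: pd.DataFrame, groups: pd.Series | None = None,
                      include_cnn: bool = True) -> pd.DataFrame:
    """Conditional LOH co-occurrence: P(LOH at Y | LOH at X) per group.

    Returns a long table (group, gene_x, gene_y, n_x, n_xy, fraction).
    ``include_cnn`` counts CNN LOH as LOH (both abolish heterozygosity).
    """
    hit_states = {"LOH", "CNN LOH"} if include_cnn else {"LOH"}
    hits = status.isin(hit_states)
    if groups is None:
        groups = pd.Series("all", index=status.index)
    else:
        groups = pd.Series(groups).reindex(status.index)
    rows = []
    for grp, idx in hits.groupby(groups).groups.items():
        sub = hits.loc[idx]
        for gx in status.columns:
            n_x = int(sub[gx].sum())
            for gy in status.columns:
                if gx == gy:
                    continue
                n_xy = int((sub[gx] & sub[gy]).sum())
                rows.append({
                    "group": grp, "gene_x": gx, "gene_y": gy,
                    "n_x": n_x, "n_xy": n_xy,
                    "fraction": n_xy / n_x if n_x else np.nan,
                })
    return pd.DataFrame(rows)
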