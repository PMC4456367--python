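"""Chromosome-arm annotation and SNP probe maps.

The unit of analysis throughout the package is the chromosome arm: copy-number
events are classified as whole-arm or focal relative to the span an arm's
probes cover, and per-sample instability is the number of arms carrying at
least one alteration.  This module holds the arm model (22 autosomes + X with
p/q arms; the five acrocentric chromosomes 13, 14, 15, 21 and 22 are modeled
q-only, giving 41 arms) and reads/writes the UCSC ``cytoBand.txt`` dialect.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeAnnotation", "default_genome", "read_cytoband", "ACROCENTRIC"]

#: Chromosomes modeled without a p arm (satellite-only short arms).
ACROCENTRIC = frozenset({"13", "14", "15", "21", "22"})

# Approximate chromosome sizes and centromere midpoints (bp), GRCh37 scale.
# Only the relative arm geometry matters for arm-level analysis.
_CHROM_TABLE = {
    #  chrom: (centromere, length)
    "1": (125_000_000, 249_250_000),
    "2": (93_300_000, 243_200_000),
    "3": (91_000_000, 198_000_000),
    "4": (50_400_000, 191_200_000),
    "5": (48_400_000, 180_900_000),
    "6": (61_000_000, 171_100_000),
    "7": (59_900_000, 159_100_000),
    "8": (45_600_000, 146_400_000),
    "9": (49_000_000, 141_200_000),
    "10": (40_200_000, 135_500_000),
    "11": (53_700_000, 135_000_000),
    "12": (35_800_000, 133_900_000),
    "13": (17_900_000, 115_200_000),
    "14": (17_600_000, 107_300_000),
    "15": (19_000_000, 102_500_000),
    "16": (36_600_000, 90_400_000),
    "17": (24_000_000, 81_200_000),
    "18": (17_200_000, 78_100_000),
    "19": (26_500_000, 59_100_000),
    "20": (27_500_000, 63_000_000),
    "21": (13_200_000, 48_100_000),
    "22": (14_700_000, 51_300_000),
    "X": (60_600_000, 155_300_000),
}


@dataclass
class GenomeAnnotation:
    """Arm extents plus an ordered SNP probe map.

    Attributes
    ----------
    arms : pandas.DataFrame
        Columns ``chrom``, ``arm`` ('p'/'q'), ``start``, ``end`` (bp,
        0-based half-open), one row per modeled arm, genome-ordered.
    probes : pandas.DataFrame
        Columns ``snp_id``, ``chrom``, ``pos``, ``arm``; positions strictly
        increasing within a chromosome, each inside exactly one arm.
    """

    arms: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        arms = self.arms
        if (arms["end"] <= arms["start"]).any():
            raise ValueError("arm with non-positive extent")
        for chrom, sub in arms.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ValueError(f"overlapping arms on chromosome {chrom}")
        for chrom, sub in self.probes.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError(f"probe positions not strictly increasing on {chrom}")
        counts = self.probes.groupby(["chrom", "arm"]).size()
        for _, row in arms.iterrows():
            if counts.get((row["chrom"], row["arm"]), 0) < 1:
                raise ValueError(f"arm {row['chrom']}{row['arm']} has no probes")

    # -- lookups -----------------------------------------------------------

    @property
    def arm_names(self) -> list[str]:
        return [f"{c}{a}" for c, a in zip(self.arms["chrom"], self.arms["arm"])]

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def arm_bounds(self, chrom: str, arm: str) -> tuple[int, int]:
        row = self.arms[(self.arms["chrom"] == chrom) & (self.arms["arm"] == arm)]
        if row.empty:
            raise KeyError(f"no arm {chrom}{arm}")
        r = row.iloc[0]
        return int(r["start"]), int(r["end"])

    def arm_probe_span(self, chrom: str, arm: str) -> tuple[int, int]:
        """Genomic positions of the first and last probe on an arm.

        Probe coverage defines what is observable at arm tips, so whole-arm
        classification is measured against this span, not band extents.
        """
        sub = self.probes[(self.probes["chrom"] == chrom) & (self.probes["arm"] == arm)]
        if sub.empty:
            raise KeyError(f"no probes on arm {chrom}{arm}")
        pos = sub["pos"].to_numpy()
        return int(pos[0]), int(pos[-1])

    def arm_of(self, chrom: str, pos: int) -> str:
        sub = self.arms[self.arms["chrom"] == chrom]
        hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
        if hit.empty:
            raise ValueError(f"position {chrom}:{pos} outside modeled arms")
        return str(hit.iloc[0]["arm"])

    # -- I/O ---------------------------------------------------------------

    def write_cytoband(self, path) -> None:
        """Write arm extents in the UCSC cytoBand.txt dialect (one band per arm)."""
        rows = [
            (f"chr{r['chrom']}", int(r["start"]), int(r["end"]), f"{r['arm']}11", "gneg")
            for _, r in self.arms.iterrows()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def write_probes(self, path) -> None:
        self.probes.to_csv(path, sep="\t", index=False)


def read_cytoband(path, probes: pd.DataFrame | None = None,
                  probes_per_arm: int = 200) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from a UCSC ``cytoBand.txt`` file.

    Bands are aggregated to arms by the leading 'p'/'q' of the band name.
    If *probes* is None, ``probes_per_arm`` evenly spaced probes are laid
    down on each arm.
    """
    bands = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str},
    )
    bands["chrom"] = bands["chrom"].str.removeprefix("chr")
    bands["arm"] = bands["band"].str[0]
    if not bands["arm"].isin(["p", "q"]).all():
        raise ValueError("band names must start with 'p' or 'q'")
    arms = (
        bands.groupby(["chrom", "arm"], sort=False)
        .agg(start=("start", "min"), end=("end", "max"))
        .reset_index()[["chrom", "arm", "start", "end"]]
    )
    arms = _genome_order(arms)
    if probes is None:
        probes = _even_probes(arms, probes_per_arm)
    else:
        probes = _assign_probe_arms(probes, arms)
    return GenomeAnnotation(arms=arms, probes=probes)


def default_genome(probes_per_arm: int = 200,
                   chromosomes: list[str] | None = None) -> GenomeAnnotation:
    """The built-in 41-arm human genome model with evenly spaced probes.

    Parameters
    ----------
    probes_per_arm : int
        SNP probes laid down per arm (> 0).
    chromosomes : list of str, optional
        Restrict to a subset (e.g. ``["17"]``); default is 1..22 plus X.
    """
    if probes_per_arm < 1:
        raise ValueError("probes_per_arm must be >= 1")
    chroms = list(_CHROM_TABLE) if chromosomes is None else [
        str(c).removeprefix("chr") for c in chromosomes
    ]
    rows = []
    for c in chroms:
        if c not in _CHROM_TABLE:
            raise KeyError(f"unknown chromosome {c!r}")
        cen, length = _CHROM_TABLE[c]
        if c not in ACROCENTRIC:
            rows.append((c, "p", 0, cen))
        rows.append((c, "q", cen, length))
    arms = pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])
    probes = _even_probes(arms, probes_per_arm)
    return GenomeAnnotation(arms=arms, probes=probes)


def _genome_order(arms: pd.DataFrame) -> pd.DataFrame:
    order = {c: i for i, c in enumerate(_CHROM_TABLE)}
    arms = arms.copy()
    arms["_k"] = arms["chrom"].map(lambda c: order.get(c, 99))
    arms = arms.sort_values(["_k", "start"]).drop(columns="_k").reset_index(drop=True)
    return arms


def _even_probes(arms: pd.DataFrame, per_arm: int) -> pd.DataFrame:
    frames = []
    for _, r in arms.iterrows():
        span = r["end"] - r["start"]
        pos = r["start"] + ((np.arange(per_arm) + 0.5) * span / per_arm).astype(int)
        frames.append(pd.DataFrame({
            "snp_id": [f"SNP_{r['chrom']}{r['arm']}_{i:05d}" for i in range(per_arm)],
            "chrom": r["chrom"],
            "pos": pos,
            "arm": r["arm"],
        }))
    return pd.concat(frames, ignore_index=True)


def _assign_probe_arms(probes: pd.DataFrame, arms: pd.DataFrame) -> pd.DataFrame:
    probes = probes.copy()
    labels = []
    for _, p in probes.iterrows():
        sub = arms[(arms["chrom"] == p["chrom"]) &
                   (arms["start"] <= p["pos"]) & (p["pos"] < arms["end"])]
        if sub.empty:
            raise ValueError(f"probe {p['snp_id']} outside modeled arms")
        labels.append(sub.iloc[0]["arm"])
    probes["arm"] = labels
    return probes
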