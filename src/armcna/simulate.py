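"""Synthetic cohort generator: planted CNAs, probe signals, expression, clinical.

Every downstream stage of the pipeline (allelic-ratio calling, arm-level
profiling, consensus subtyping, survival statistics) is exercised against
cohorts produced here, with known ground truth:

* **CNA truth** — per-sample allele-specific copy-number intervals planted on
  chromosome arms, drawn per histology archetype.  Archetypes differ in the
  expected number of altered arms and in the probability that an event spans
  the whole arm, emulating the contrast between clear-cell-like tumors (few
  CNAs, mostly whole-arm) and serous-like tumors (many CNAs, mostly focal).
* **Probe signals** — paired tumor/normal per-allele intensities on the SNP
  probe map.  An allele planted at ``c`` copies in a tumor of purity ``p``
  has expected tumor/normal ratio ``(1-p)*1 + p*(1+c)/2``: the pure-tumor
  ratio scale puts 0/1/2 copies at 0.5/1.0/1.5, and stromal admixture pulls
  ratios toward the diploid value 1.  Noise is multiplicative log-normal on
  both tumor and normal signals (ratios stay positive).
* **Expression** — linear-scale probe-by-sample matrices with planted cluster
  structure: each cluster owns a disjoint marker-gene set shifted by a
  configured log2 effect; all other genes are exchangeable noise.
* **Clinical covariates** — progression-free survival from an exponential
  proportional-hazards model with per-cluster hazard multipliers and
  administrative censoring, plus stage / chemoresponse / mutation-status
  flags drawn from per-cluster proportions.

All generators are deterministic given the seed recorded in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, default_genome

__all__ = [
    "ArchetypeConfig",
    "SimulationConfig",
    "ExpressionSim",
    "generate_genome",
    "simulate_cna_profiles",
    "simulate_probe_signals",
    "simulate_expression",
    "simulate_clinical",
    "truth_category",
]

#: allele-copy pairs per planted event category, and their default mix
_CATEGORY_COPIES = {
    "gain": (1, 2),
    "hemizygous-loss": (0, 1),
    "cnn-loh": (0, 2),
    "homozygous-deletion": (0, 0),
}
_CATEGORY_WEIGHTS = {"gain": 0.40, "hemizygous-loss": 0.35,
                     "cnn-loh": 0.18, "homozygous-deletion": 0.07}


@dataclass
class ArchetypeConfig:
    """One histology archetype of the simulated cohort.

    ``mean_cna`` is the expected number of altered arms per tumor and
    ``whole_arm_prob`` the probability that an individual event spans its
    whole arm.  ``tsg_co_loss_prob`` plants, with that probability, a
    co-occurring hemizygous loss of 17p, 17q and 13q — the pattern by which
    serous tumors lose TP53, NF1, BRCA1, RB1 and BRCA2 together.
    """

    name: str
    n_samples: int = 15
    mean_cna: float = 7.0
    whole_arm_prob: float = 0.47
    tsg_co_loss_prob: float = 0.0
    #: optional arm-name -> selection weight map; unlisted arms get weight 0
    #: when a map is given, uniform selection otherwise.  Lets archetypes
    #: carry recurrent arm signatures rather than scattering events.
    arm_weights: dict | None = None

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if self.mean_cna < 0:
            raise ValueError("mean_cna must be non-negative")
        if not 0.0 <= self.whole_arm_prob <= 1.0:
            raise ValueError("whole_arm_prob must be in [0, 1]")
        if not 0.0 <= self.tsg_co_loss_prob <= 1.0:
            raise ValueError("tsg_co_loss_prob must be in [0, 1]")


def _default_archetypes() -> list[ArchetypeConfig]:
    # Event counts / whole-arm rates mirror the printed cohort contrasts:
    # clear-cell-like ~7 CNAs with ~47% whole-arm, serous-like ~18 CNAs with
    # ~22% whole-arm, endometrioid-like intermediate.
    return [
        ArchetypeConfig("CCC-like", n_samples=15, mean_cna=7.0, whole_arm_prob=0.47),
        ArchetypeConfig("SC-like", n_samples=15, mean_cna=18.0, whole_arm_prob=0.22,
                        tsg_co_loss_prob=0.85),
        ArchetypeConfig("EC-like", n_samples=15, mean_cna=10.0, whole_arm_prob=0.30),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Parameters
    ----------
    archetypes : list of ArchetypeConfig
        Histology groups and their CNA regimes.
    purity : float in (0, 1]
        Tumor-cell fraction; observed ratios are purity-weighted mixtures of
        tumor and diploid stroma.  Default 0.8 (sections with a high
        carcinoma fraction, no downstream purity correction).
    noise_sd : float
        Standard deviation of the log-normal multiplicative noise applied to
        each tumor and normal signal independently (so the tumor/normal
        ratio carries log-noise sd ``sqrt(2) * noise_sd``).
    probes_per_arm : int
        SNP probe density of the simulated arrays (default 200/arm).
    min_event_probes : int
        Smallest planted focal event, in probes.
    category_weights : dict
        Mix of planted event categories.
    n_genes, markers_per_cluster, log2_effect, expr_noise_sd, n_clusters
        Expression-matrix conditions.
    baseline_hazard : float
        Events per month for the reference cluster.
    hazard_multipliers : tuple of float
        Per-cluster proportional-hazards multipliers (cluster 2 protective
        by default).
    followup_months : float
        Administrative censoring horizon.
    stage_advanced_prob, chemo_sensitive_prob, pik3ca_prob, arid1a_loss_prob
        Per-cluster clinical proportions.
    seed : int
        Master seed, recorded in all outputs.
    """

    archetypes: list[ArchetypeConfig] = field(default_factory=_default_archetypes)
    purity: float = 0.8
    noise_sd: float = 0.1
    probes_per_arm: int = 200
    chromosomes: list[str] | None = None
    min_event_probes: int = 20
    max_focal_fraction: float = 0.9
    category_weights: dict = field(default_factory=lambda: dict(_CATEGORY_WEIGHTS))
    # expression
    n_genes: int = 2000
    n_clusters: int = 3
    markers_per_cluster: int = 100
    log2_effect: float = 2.0
    expr_noise_sd: float = 0.5
    # clinical / survival
    baseline_hazard: float = 0.02
    hazard_multipliers: tuple = (1.0, 0.2, 1.0)
    followup_months: float = 60.0
    stage_advanced_prob: tuple = (0.0, 0.2, 0.5)
    chemo_sensitive_prob: tuple = (0.0, 1.0, 0.33)
    pik3ca_prob: tuple = (0.89, 0.40, 0.50)
    arid1a_loss_prob: tuple = (0.78, 0.20, 0.50)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.probes_per_arm < 1:
            raise ValueError("probes_per_arm must be positive")
        if self.min_event_probes < 1:
            raise ValueError("min_event_probes must be positive")
        if any(m <= 0 for m in self.hazard_multipliers):
            raise ValueError("hazard multipliers must be positive")
        if self.followup_months < 0:
            raise ValueError("follow-up horizon must be non-negative")
        if abs(sum(self.category_weights.values()) - 1.0) > 1e-9:
            raise ValueError("category weights must sum to 1")
        for a in self.archetypes:
            a.validate()

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def truth_category(copies_a: int, copies_b: int) -> str:
    """Event category implied by a planted allele-copy pair."""
    lo, hi = sorted((copies_a, copies_b))
    if (lo, hi) == (0, 0):
        return "homozygous-deletion"
    if lo == 0 and hi >= 2:
        return "cnn-loh"
    if lo == 0 and hi == 1:
        return "hemizygous-loss"
    if lo >= 1 and hi >= 2:
        return "gain"
    raise ValueError(f"allele copies ({copies_a}, {copies_b}) are the neutral state")


def generate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Build the probe-bearing arm model for a simulation run.

    Deterministic: the probe grid depends only on the arm geometry and
    probe density, so identical configs yield identical annotations.
    """
    config.validate()
    return default_genome(probes_per_arm=config.probes_per_arm,
                          chromosomes=config.chromosomes)


def simulate_cna_profiles(genome: GenomeAnnotation, config: SimulationConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Plant per-sample allele-specific CNA truth intervals.

    Each tumor draws a Poisson number of altered arms (capped at the number
    of modeled arms); arms are sampled without replacement, so one arm
    carries at most one event — the unit in which arm-level event tables are
    counted.  An event is whole-arm with the archetype's probability,
    otherwise focal with a uniformly drawn probe span.

    Returns a DataFrame with columns ``sample_id``, ``histology``, ``chrom``,
    ``arm``, ``start``, ``end``, ``copies_a``, ``copies_b``, ``category``,
    ``whole_arm``.  The diploid background (1, 1) is never stored.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1]) if seed is None \
        else np.random.default_rng(seed)
    cats = list(config.category_weights)
    cat_p = np.array([config.category_weights[c] for c in cats])
    arm_rows = list(genome.arms.itertuples(index=False))
    probes_by_arm = {
        (r.chrom, r.arm): genome.probes[(genome.probes["chrom"] == r.chrom) &
                                        (genome.probes["arm"] == r.arm)]["pos"].to_numpy()
        for r in arm_rows
    }
    out = []
    arm_names = [f"{r.chrom}{r.arm}" for r in arm_rows]
    for arch in config.archetypes:
        if arch.arm_weights is None:
            weights = None
            n_selectable = len(arm_rows)
        else:
            w = np.array([arch.arm_weights.get(a, 0.0) for a in arm_names], float)
            if w.sum() <= 0:
                raise ValueError(f"archetype {arch.name}: arm weights sum to 0")
            weights = w / w.sum()
            n_selectable = int((w > 0).sum())
        for i in range(arch.n_samples):
            sid = f"{arch.name}-{i + 1:03d}"
            n_ev = min(int(rng.poisson(arch.mean_cna)), n_selectable)
            arm_idx = rng.choice(len(arm_rows), size=n_ev, replace=False,
                                 p=weights)
            chosen = {(arm_rows[j].chrom, arm_rows[j].arm) for j in arm_idx}
            if arch.tsg_co_loss_prob > 0 and rng.random() < arch.tsg_co_loss_prob:
                # joint hemizygous loss of the TP53/NF1/BRCA1 and RB1/BRCA2 arms
                for key in (("17", "p"), ("17", "q"), ("13", "q")):
                    if key in probes_by_arm:
                        chosen.discard(key)
                        arm = genome.arms[(genome.arms["chrom"] == key[0]) &
                                          (genome.arms["arm"] == key[1])].iloc[0]
                        out.append((sid, arch.name, key[0], key[1],
                                    int(arm["start"]), int(arm["end"]), 0, 1,
                                    "hemizygous-loss", True))
            for key in sorted(chosen):
                chrom, arm_label = key
                arm = genome.arms[(genome.arms["chrom"] == chrom) &
                                  (genome.arms["arm"] == arm_label)].iloc[0]
                pos = probes_by_arm[key]
                cat = cats[rng.choice(len(cats), p=cat_p)]
                ca, cb = _CATEGORY_COPIES[cat]
                if rng.random() < 0.5:
                    ca, cb = cb, ca
                whole = bool(rng.random() < arch.whole_arm_prob)
                if whole or len(pos) <= config.min_event_probes:
                    start, end = int(arm["start"]), int(arm["end"])
                    whole = True
                else:
                    max_len = max(config.min_event_probes,
                                  int(config.max_focal_fraction * len(pos)))
                    n_probes = int(rng.integers(config.min_event_probes, max_len + 1))
                    first = int(rng.integers(0, len(pos) - n_probes + 1))
                    start = int(pos[first])
                    end = int(pos[first + n_probes - 1]) + 1
                out.append((sid, arch.name, chrom, arm_label, start, end,
                            ca, cb, cat, whole))
    return pd.DataFrame(out, columns=[
        "sample_id", "histology", "chrom", "arm", "start", "end",
        "copies_a", "copies_b", "category", "whole_arm",
    ])


def expected_ratio(copies: np.ndarray | float, purity: float):
    """Expected tumor/normal allele ratio for planted copy number *copies*.

    Pure-tumor scale: 0, 1, 2 copies map to ratios 0.5, 1.0, 1.5; stromal
    admixture mixes toward 1.
    """
    return (1.0 - purity) * 1.0 + purity * (1.0 + np.asarray(copies, float)) / 2.0


def simulate_probe_signals(truth: pd.DataFrame, genome: GenomeAnnotation,
                           purity: float, noise_sd: float,
                           seed: int = 0, base_intensity: float = 1000.0,
                           ) -> dict[str, pd.DataFrame]:
    """Paired tumor/normal per-allele probe intensities for each sample.

    Returns a dict mapping sample id to a probe table with columns
    ``snp_id, chrom, pos, tumorA, tumorB, normalA, normalB``, genome-ordered.
    Normal signals fluctuate around a constant diploid level; tumor signals
    around ``base * expected_ratio(c, purity)`` per allele.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    _check_truth_in_genome(truth, genome)
    rng = np.random.default_rng(seed)
    probes = genome.probes
    n = len(probes)
    pos = probes["pos"].to_numpy()
    chrom = probes["chrom"].to_numpy()
    tables: dict[str, pd.DataFrame] = {}
    for sid, sub in truth.groupby("sample_id", sort=False):
        copies_a = np.ones(n)
        copies_b = np.ones(n)
        for _, ev in sub.iterrows():
            mask = (chrom == ev["chrom"]) & (pos >= ev["start"]) & (pos < ev["end"])
            copies_a[mask] = ev["copies_a"]
            copies_b[mask] = ev["copies_b"]
        mu_a = base_intensity * expected_ratio(copies_a, purity)
        mu_b = base_intensity * expected_ratio(copies_b, purity)
        noise = rng.normal(0.0, noise_sd, size=(4, n)) if noise_sd > 0 else np.zeros((4, n))
        tables[sid] = pd.DataFrame({
            "snp_id": probes["snp_id"].to_numpy(),
            "chrom": chrom,
            "pos": pos,
            "tumorA": mu_a * np.exp(noise[0]),
            "tumorB": mu_b * np.exp(noise[1]),
            "normalA": base_intensity * np.exp(noise[2]),
            "normalB": base_intensity * np.exp(noise[3]),
        })
    return tables


def _check_truth_in_genome(truth: pd.DataFrame, genome: GenomeAnnotation) -> None:
    bounds = genome.arms.groupby("chrom").agg(lo=("start", "min"), hi=("end", "max"))
    for _, ev in truth.iterrows():
        if ev["chrom"] not in bounds.index:
            raise ValueError(f"truth interval on unmodeled chromosome {ev['chrom']}")
        b = bounds.loc[ev["chrom"]]
        if ev["start"] < b["lo"] or ev["end"] > b["hi"]:
            raise ValueError(
                f"truth interval {ev['chrom']}:{ev['start']}-{ev['end']} outside genome")
        if (ev["copies_a"], ev["copies_b"]) == (1, 1):
            raise ValueError("neutral state (1,1) must not be stored as truth")


def simulate_background_signals(sample_ids, genome: GenomeAnnotation,
                                noise_sd: float, seed: int = 0,
                                base_intensity: float = 1000.0,
                                ) -> dict[str, pd.DataFrame]:
    """Diploid-only signal tables for samples with an empty truth set."""
    rng = np.random.default_rng(seed)
    out = {}
    probes = genome.probes
    n = len(probes)
    for sid in sample_ids:
        noise = rng.normal(0.0, noise_sd, size=(4, n)) if noise_sd > 0 else np.zeros((4, n))
        out[sid] = pd.DataFrame({
            "snp_id": probes["snp_id"].to_numpy(),
            "chrom": probes["chrom"].to_numpy(),
            "pos": probes["pos"].to_numpy(),
            "tumorA": base_intensity * np.exp(noise[0]),
            "tumorB": base_intensity * np.exp(noise[1]),
            "normalA": base_intensity * np.exp(noise[2]),
            "normalB": base_intensity * np.exp(noise[3]),
        })
    return out


@dataclass
class ExpressionSim:
    """Planted expression matrix plus its marker-gene truth."""

    matrix: pd.DataFrame          # probes x samples, linear scale
    markers: dict[int, list[str]]  # cluster label -> marker probe ids


def simulate_expression(labels, config: SimulationConfig,
                        seed: int | None = None) -> ExpressionSim:
    """Linear-scale expression matrix with planted cluster structure.

    *labels* maps sample ids to integer cluster labels (1..K).  Each cluster
    receives ``markers_per_cluster`` disjoint marker genes whose log2 level
    is shifted by ``log2_effect`` in that cluster's samples; every other
    entry is i.i.d. log-normal noise around a per-gene baseline.
    """
    labels = pd.Series(labels)
    clusters = sorted(labels.unique())
    if len(clusters) < 2 and config.log2_effect != 0:
        raise ValueError("need >= 2 clusters unless the planted effect is 0")
    n_marked = len(clusters) * config.markers_per_cluster
    if config.log2_effect != 0 and n_marked > config.n_genes:
        raise ValueError("marker genes exceed total gene count")
    rng = np.random.default_rng([config.seed, 2]) if seed is None \
        else np.random.default_rng(seed)
    genes = [f"PROBE_{i:05d}" for i in range(config.n_genes)]
    baseline = rng.normal(6.0, 1.0, size=config.n_genes)
    marker_idx = rng.choice(config.n_genes, size=n_marked, replace=False) \
        if config.log2_effect != 0 else np.array([], dtype=int)
    markers: dict[int, list[str]] = {}
    shift = np.zeros((config.n_genes, len(labels)))
    for j, c in enumerate(clusters):
        if config.log2_effect == 0:
            markers[c] = []
            continue
        idx = marker_idx[j * config.markers_per_cluster:(j + 1) * config.markers_per_cluster]
        markers[c] = [genes[i] for i in idx]
        cols = (labels.to_numpy() == c)
        shift[np.ix_(idx, np.where(cols)[0])] = config.log2_effect
    log2 = baseline[:, None] + shift + rng.normal(0.0, config.expr_noise_sd,
                                                  size=(config.n_genes, len(labels)))
    mat = pd.DataFrame(np.exp2(log2), index=genes, columns=list(labels.index))
    return ExpressionSim(matrix=mat, markers=markers)


def simulate_clinical(labels, config: SimulationConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Clinical table with a planted cluster-dependent progression hazard.

    PFS times are exponential with hazard ``baseline_hazard *
    hazard_multipliers[cluster-1]`` and administratively censored at the
    follow-up horizon.  Stage, chemoresponse and mutation-status flags are
    Bernoulli draws from the per-cluster proportions in the config.
    """
    config.validate()
    labels = pd.Series(labels)
    rng = np.random.default_rng([config.seed, 3]) if seed is None \
        else np.random.default_rng(seed)
    rows = []
    for sid, c in labels.items():
        ci = (int(c) - 1) % len(config.hazard_multipliers)
        hazard = config.baseline_hazard * config.hazard_multipliers[ci]
        t = rng.exponential(1.0 / hazard)
        event = int(t <= config.followup_months)
        time = min(t, config.followup_months)
        adv = rng.random() < _cycle(config.stage_advanced_prob, ci)
        rows.append({
            "sample_id": sid,
            "cluster": int(c),
            "histology": "CCC",
            "age": float(np.round(rng.normal(55.0, 10.0), 1)),
            "stage": "III/IV" if adv else "I/II",
            "chemoresponse": "sensitive"
            if rng.random() < _cycle(config.chemo_sensitive_prob, ci) else "resistant",
            "pik3ca_altered": int(rng.random() < _cycle(config.pik3ca_prob, ci)),
            "arid1a_loss": int(rng.random() < _cycle(config.arid1a_loss_prob, ci)),
            "pfs_months": float(np.round(time, 3)),
            "pfs_event": event,
        })
    return pd.DataFrame(rows)


def _cycle(seq, i):
    return seq[i % len(seq)]
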