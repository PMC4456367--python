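import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from armcna.cin import (DEFAULT_TSG_LOCI, arm_event_matrix, arm_event_table,
                        build_cna_profiles, cin_class, cluster_cna_profiles,
                        loh_co_occurrence, mean_cna_count, read_loci_bed,
                        tsg_loh_status, whole_arm_ratio_test)
from armcna.genome import default_genome
from armcna.reference import REPORTED_TOTALS, arm_count_summary


@pytest.fixture(scope="module")
def genome():
    return default_genome(probes_per_arm=20)


def make_events(spec):
    """spec: list of (sample, chrom, arm, event_class)."""
    return pd.DataFrame(spec, columns=["sample_id", "chrom", "arm", "event_class"])


# -- CIN classes ----------------------------------------------------------

@pytest.mark.parametrize("count,expected", [
    (0, "negative"), (1, "low"), (8, "low"), (9, "high"), (41, "high"),
])
def test_cin_class_boundaries(count, expected):
    assert cin_class(count) == expected


def test_profiles_count_each_arm_once(genome):
    events = make_events([("s1", "1", "p", "focal")])
    prof = build_cna_profiles(events, genome, sample_ids=["s1", "s2"])
    assert prof.set_index("sample_id").loc["s2", "cin_class"] == "negative"
    assert prof.set_index("sample_id").loc["s1", "arm_count"] == 1
    # multiple segments on one arm were already collapsed to one event by
    # the event-table convention; a sample with 9 distinct arms is CIN-high
    nine = make_events([("s3", c, "q", "focal")
                        for c in ["1", "2", "3", "4", "5", "6", "7", "8", "9"]])
    prof = build_cna_profiles(nine, genome)
    assert prof["cin_class"].iloc[0] == "high"
    eight = make_events([("s4", c, "q", "focal")
                         for c in ["1", "2", "3", "4", "5", "6", "7", "8"]])
    assert build_cna_profiles(eight, genome)["cin_class"].iloc[0] == "low"


# -- arm event table ------------------------------------------------------

def test_arm_event_table_matches_brute_force(genome, rng):
    """Counts equal an independent per-cell recount of a random event map."""
    samples = [f"s{i}" for i in range(10)]
    groups = pd.Series({s: ("A" if i < 5 else "B") for i, s in enumerate(samples)})
    rows = []
    for s in samples:
        arms = rng.choice(len(genome.arms), size=rng.integers(0, 8), replace=False)
        for j in arms:
            arm = genome.arms.iloc[j]
            rows.append((s, arm["chrom"], arm["arm"],
                         "whole-arm" if rng.random() < 0.4 else "focal"))
    events = make_events(rows)
    table = arm_event_table(events, groups, genome)
    # independent recount
    for _, r in table.iterrows():
        n_w = n_f = 0
        for s, chrom, arm, cls in rows:
            if f"{chrom}{arm}" == r["arm"] and groups[s] == r["group"]:
                if cls == "whole-arm":
                    n_w += 1
                else:
                    n_f += 1
        assert (r["whole_arm"], r["focal"]) == (n_w, n_f)
    assert table["whole_arm"].sum() + table["focal"].sum() == len(rows)


def test_arm_event_table_requires_labels(genome):
    events = make_events([("s1", "1", "p", "focal")])
    with pytest.raises(KeyError, match="without group label"):
        arm_event_table(events, pd.Series({"other": "A"}), genome)


def test_sample_without_events_contributes_nothing(genome):
    events = make_events([("s1", "1", "p", "focal")])
    groups = pd.Series({"s1": "A", "s2": "A"})
    table = arm_event_table(events, groups, genome)
    assert table["whole_arm"].sum() + table["focal"].sum() == 1


# -- whole-arm ratio ------------------------------------------------------

def test_reference_table_whole_arm_ratio():
    """Summed reference counts reproduce the published 46.9% ratio."""
    summary = arm_count_summary()
    assert summary["ccc_whole_arm"] == 99
    assert summary["ccc_focal"] == 112
    assert summary["ccc_whole_arm_ratio_pct"] == 46.9


def test_whole_arm_ratio_fisher(genome):
    table = pd.DataFrame([
        {"arm": "1p", "group": "CCC", "whole_arm": 99, "focal": 112},
        {"arm": "1p", "group": "SC", "whole_arm": 50, "focal": 181},
    ])
    res = whole_arm_ratio_test(table, "CCC", "SC")
    assert res.ratios["CCC"] == pytest.approx(99 / 211)
    assert res.p_value < 0.0001


def test_identical_groups_fisher_p_one():
    table = pd.DataFrame([
        {"arm": "1p", "group": "A", "whole_arm": 10, "focal": 20},
        {"arm": "1p", "group": "B", "whole_arm": 10, "focal": 20},
    ])
    assert whole_arm_ratio_test(table, "A", "B").p_value == pytest.approx(1.0)


def test_zero_event_group_flagged():
    table = pd.DataFrame([
        {"arm": "1p", "group": "A", "whole_arm": 5, "focal": 5},
        {"arm": "1p", "group": "B", "whole_arm": 0, "focal": 0},
    ])
    res = whole_arm_ratio_test(table, "A", "B")
    assert res.p_value is None and res.undefined_groups == ["B"]


# -- mean CNA counts ------------------------------------------------------

def profiles_with_total(total, n, group):
    base = total // n
    rest = total - base * n
    counts = [base + (1 if i < rest else 0) for i in range(n)]
    return pd.DataFrame({"sample_id": [f"x{i}" for i in range(n)],
                         "histology": group, "arm_count": counts,
                         "cin_class": [cin_class(c) for c in counts]})


def test_mean_cna_count_reproduces_published_averages():
    ccc = REPORTED_TOTALS["CCC"]
    sc = REPORTED_TOTALS["SC"]
    assert mean_cna_count(profiles_with_total(ccc["all_events"],
                                              ccc["n_samples"], "CCC")) == 6.8
    assert mean_cna_count(profiles_with_total(sc["all_events"],
                                              sc["n_samples"], "SC")) == 17.8
    assert mean_cna_count(profiles_with_total(0, 5, "empty")) == 0.0


# -- CNA-profile clustering ----------------------------------------------

def test_archetype_profiles_cluster_apart(genome):
    """Archetypes planted with distinct recurrent-arm signatures separate."""
    from armcna.simulate import ArchetypeConfig, SimulationConfig, simulate_cna_profiles
    arms = genome.arm_names
    cfg = SimulationConfig(seed=13, archetypes=[
        ArchetypeConfig("sparse", n_samples=12, mean_cna=4, whole_arm_prob=0.9,
                        arm_weights={a: 1.0 for a in arms[:20]}),
        ArchetypeConfig("dense", n_samples=12, mean_cna=15, whole_arm_prob=0.05,
                        arm_weights={a: 1.0 for a in arms[20:]})])
    truth = simulate_cna_profiles(genome, cfg)
    events = truth.rename(columns={"whole_arm": "wa"})
    events["event_class"] = np.where(events["wa"], "whole-arm", "focal")
    mat = arm_event_matrix(events[["sample_id", "chrom", "arm", "event_class"]],
                           genome)
    labels, _ = cluster_cna_profiles(mat, 2)
    archetype = [s.rsplit("-", 1)[0] for s in mat.index]
    assert adjusted_rand_score(archetype, labels) >= 0.9


def test_duplicate_sample_merges_at_height_zero(genome):
    mat = pd.DataFrame([[1, 0, 2], [1, 0, 2], [0, 2, 0]],
                       index=["a", "b", "c"], columns=["1p", "1q", "2p"])
    labels, z = cluster_cna_profiles(mat, 2)
    assert z[0, 2] == 0.0  # first merge at zero distance
    assert labels["a"] == labels["b"] != labels["c"]


def test_k_equals_n_gives_singletons(genome):
    mat = pd.DataFrame(np.eye(4), index=list("abcd"), columns=["1p", "1q", "2p", "2q"])
    labels, _ = cluster_cna_profiles(mat, 4)
    assert labels.nunique() == 4
    with pytest.raises(ValueError):
        cluster_cna_profiles(mat, 5)


# -- TSG LOH --------------------------------------------------------------

def seg(sample, chrom, start, end, category):
    return {"sample_id": sample, "chrom": chrom, "start": start, "end": end,
            "state_a": "loss", "state_b": "neutral", "category": category,
            "n_probes": 50, "ratio_a": 0.6, "ratio_b": 1.0,
            "arm": "q", "span_fraction": 0.5, "span_class": "focal"}


def test_chr17_loss_hits_all_three_genes(genome):
    segs = pd.DataFrame([seg("SC-1", "17", 0, 81_200_000, "hemizygous-loss")])
    status = tsg_loh_status(segs, genome=genome)
    assert status.loc["SC-1", ["TP53", "NF1", "BRCA1"]].tolist() == ["LOH"] * 3
    assert status.loc["SC-1", ["RB1", "BRCA2"]].tolist() == ["nl", "nl"]


def test_13q_cnn_loh_pattern(genome):
    q_start, q_end = genome.arm_bounds("13", "q")
    segs = pd.DataFrame([seg("CCC-8", "13", q_start, q_end, "cnn-loh")])
    status = tsg_loh_status(segs, genome=genome)
    assert status.loc["CCC-8", ["RB1", "BRCA2"]].tolist() == ["CNN LOH"] * 2
    assert status.loc["CCC-8", ["TP53", "NF1", "BRCA1"]].tolist() == ["nl"] * 3


def test_no_segments_all_nl():
    segs = pd.DataFrame(columns=["sample_id", "chrom", "start", "end", "category"])
    status = tsg_loh_status(segs, sample_ids=["s1"])
    assert (status.loc["s1"] == "nl").all()


def test_locus_outside_genome_rejected():
    small = default_genome(probes_per_arm=5, chromosomes=["1"])
    segs = pd.DataFrame([seg("s", "1", 0, 100, "cnn-loh")])
    with pytest.raises(ValueError, match="outside modeled genome"):
        tsg_loh_status(segs, genome=small)


def test_co_occurrence_is_one_for_jointly_planted_loss(genome):
    segs = pd.DataFrame([
        seg("s1", "17", 0, 81_200_000, "hemizygous-loss"),
        seg("s2", "17", 0, 81_200_000, "hemizygous-loss"),
        seg("s3", "13", 17_900_000, 115_200_000, "hemizygous-loss"),
    ])
    status = tsg_loh_status(segs, genome=genome)
    co = loh_co_occurrence(status)
    brca1_tp53 = co[(co["gene_x"] == "BRCA1") & (co["gene_y"] == "TP53")]
    assert brca1_tp53["fraction"].iloc[0] == 1.0
    rb1_brca2 = co[(co["gene_x"] == "RB1") & (co["gene_y"] == "BRCA2")]
    assert rb1_brca2["fraction"].iloc[0] == 1.0


def test_loci_bed_round_trip(tmp_path):
    path = tmp_path / "loci.bed"
    DEFAULT_TSG_LOCI.assign(chrom=lambda d: "chr" + d["chrom"])[
        ["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", header=False,
                                                  index=False)
    loci = read_loci_bed(path)
    assert loci["gene"].tolist() == DEFAULT_TSG_LOCI["gene"].tolist()
    assert loci["start"].tolist() == DEFAULT_TSG_LOCI["start"].tolist()
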