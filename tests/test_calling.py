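import numpy as np
import pandas as pd
import pytest

from armcna.calling import (CallerConfig, arm_events_from_segments,
                            call_segments, classify_arm_span,
                            compute_allelic_ratios, read_segments,
                            smooth_ratios, trimmed_replicate_summary,
                            write_seg)
from armcna.genome import default_genome
from conftest import constant_track


@pytest.fixture(scope="module")
def genome():
    return default_genome(probes_per_arm=50, chromosomes=["1", "13"])


def signal_table(genome, tumor_a=1000.0, tumor_b=1000.0, normal=1000.0):
    p = genome.probes
    return pd.DataFrame({
        "snp_id": p["snp_id"].to_numpy(), "chrom": p["chrom"].to_numpy(),
        "pos": p["pos"].to_numpy(),
        "tumorA": tumor_a, "tumorB": tumor_b,
        "normalA": normal, "normalB": normal,
    })


# -- ratios ---------------------------------------------------------------

def test_identical_tumor_normal_gives_unit_ratios(genome):
    tab = compute_allelic_ratios(signal_table(genome))
    assert (tab["ratio_a"] == 1.0).all() and (tab["ratio_b"] == 1.0).all()


def test_trimmed_summary_drops_one_extreme_each_side():
    # median of {0.9, 1.0, 1.2} after dropping the 5.0 spike and the 0.8 low
    reps = np.array([[0.8, 1.0, 1.2, 5.0, 0.9]])
    assert trimmed_replicate_summary(reps)[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        trimmed_replicate_summary(np.array([[1.0, 2.0]]))


def test_replicate_columns_use_trimmed_summary(genome):
    tab = signal_table(genome).drop(columns=["tumorA"])
    for i, v in enumerate([800, 1000, 1200, 5000, 900], start=1):
        tab[f"tumorA_{i}"] = float(v)
    out = compute_allelic_ratios(tab)
    assert np.allclose(out["ratio_a"], 1.0)


def test_non_positive_normal_names_the_snp(genome):
    tab = signal_table(genome)
    tab.loc[3, "normalA"] = 0.0
    with pytest.raises(ValueError, match=str(tab.loc[3, "snp_id"])):
        compute_allelic_ratios(tab)


# -- smoothing ------------------------------------------------------------

def test_constant_track_unchanged(make_track):
    track = make_track(1.2, 0.9)
    out = smooth_ratios(track, CallerConfig(smoothing_window=15))
    pd.testing.assert_frame_equal(out, track)


def test_single_outlier_removed(genome):
    track = constant_track(genome)
    track.loc[25, "ratio_a"] = 5.0
    out = smooth_ratios(track, CallerConfig(smoothing_window=15))
    assert out.loc[25, "ratio_a"] == pytest.approx(1.0)


def test_window_one_is_identity(genome, rng):
    track = constant_track(genome)
    track["ratio_a"] = rng.lognormal(0, 0.3, len(track))
    out = smooth_ratios(track, CallerConfig(smoothing_window=1))
    pd.testing.assert_frame_equal(out, track)


def test_running_median_matches_brute_force(genome, rng):
    """Truncated-window running median against a direct per-probe oracle."""
    track = constant_track(genome)
    track["ratio_a"] = rng.lognormal(0, 0.3, len(track))
    w = 7
    out = smooth_ratios(track, CallerConfig(smoothing_window=w))
    for chrom, sub in track.groupby("chrom"):
        vals = sub["ratio_a"].to_numpy()
        sm = out.loc[sub.index, "ratio_a"].to_numpy()
        for i in range(len(vals)):
            lo, hi = max(0, i - w // 2), min(len(vals), i + w // 2 + 1)
            assert sm[i] == pytest.approx(np.median(vals[lo:hi]))


def test_oversized_window_falls_back_to_chromosome_median():
    genome = default_genome(probes_per_arm=3, chromosomes=["21"])
    track = constant_track(genome)
    track["ratio_a"] = [0.5, 1.0, 2.0]
    with pytest.warns(UserWarning, match="whole-chromosome median"):
        out = smooth_ratios(track, CallerConfig(smoothing_window=15))
    assert (out["ratio_a"] == 1.0).all()


# -- threshold calls and categories --------------------------------------

@pytest.mark.parametrize("ra,rb,category", [
    (0.5, 1.5, "cnn-loh"),           # hemizygous deletion + opposite gain
    (0.5, 0.5, "homozygous-deletion"),
    (1.0, 1.5, "gain"),              # 3 total copies, no LOH
    (1.5, 1.5, "gain"),
    (0.65, 1.0, "hemizygous-loss"),
])
def test_sustained_levels_map_to_category(genome, ra, rb, category):
    track = constant_track(genome)
    q13 = track["chrom"] == "13"
    track.loc[q13, "ratio_a"] = ra
    track.loc[q13, "ratio_b"] = rb
    segs = call_segments(smooth_ratios(track), genome)
    assert set(segs["chrom"]) == {"13"}
    assert (segs["category"] == category).all()


def test_threshold_is_strict(genome):
    track = constant_track(genome, ratio_a=1.29, ratio_b=1.0)
    assert call_segments(smooth_ratios(track), genome).empty
    track = constant_track(genome, ratio_a=1.0, ratio_b=0.7)
    assert call_segments(smooth_ratios(track), genome).empty


def test_identity_input_yields_zero_segments_any_config(genome):
    tab = compute_allelic_ratios(signal_table(genome))
    for cfg in (CallerConfig(), CallerConfig(gain_threshold=1.1,
                                             loss_threshold=0.9,
                                             gain_extend=1.05,
                                             loss_extend=0.95,
                                             smoothing_window=5,
                                             min_probes=1)):
        assert call_segments(smooth_ratios(tab, cfg), genome, cfg).empty


def test_min_probes_floor(genome):
    track = constant_track(genome)
    # a 4-probe spike on chromosome 1 p: below the 10-probe floor
    track.loc[10:13, "ratio_a"] = 1.5
    segs = call_segments(track, genome, CallerConfig(smoothing_window=1))
    assert segs.empty


def test_calls_are_monotone_in_thresholds(genome, rng):
    """Raising the gain cut-off never creates a gain call."""
    track = constant_track(genome)
    track["ratio_a"] = rng.lognormal(0.1, 0.25, len(track))
    track["ratio_b"] = rng.lognormal(0.0, 0.25, len(track))
    sm = smooth_ratios(track)

    def gain_probes(gain_thr):
        cfg = CallerConfig(gain_threshold=gain_thr,
                           gain_extend=min(1.15, gain_thr), min_probes=1)
        segs = call_segments(sm, genome, cfg)
        return int(segs[segs["category"] == "gain"]["n_probes"].sum())

    counts = [gain_probes(t) for t in (1.2, 1.3, 1.45, 1.6)]
    assert counts == sorted(counts, reverse=True)


def test_track_genome_mismatch_rejected(genome):
    track = constant_track(genome).iloc[:-5]
    with pytest.raises(ValueError, match="differ"):
        call_segments(track, genome)


# -- span classification --------------------------------------------------

def span_segment(genome, chrom, arm, frac):
    """A hemizygous-loss segment covering `frac` of the arm's probe span."""
    first, last = genome.arm_probe_span(chrom, arm)
    end = first + frac * (last - first)
    return pd.DataFrame([{
        "sample_id": "s", "chrom": chrom, "start": first, "end": int(end) + 1,
        "state_a": "loss", "state_b": "neutral", "category": "hemizygous-loss",
        "n_probes": 50, "ratio_a": 0.6, "ratio_b": 1.0,
    }])


@pytest.mark.parametrize("frac,expected", [
    (1.0, "whole-arm"),
    (0.97, "focal"),
    (0.98, "focal"),   # exactly 98% is not whole-arm (strictly greater rule)
    (0.985, "whole-arm"),
])
def test_span_fraction_rule(genome, frac, expected):
    out = classify_arm_span(span_segment(genome, "1", "q", frac), genome)
    assert list(out["span_class"]) == [expected]
    assert out["span_fraction"].iloc[0] == pytest.approx(frac, abs=0.01)


def test_centromere_spanning_segment_is_split(genome):
    pa_first, _ = genome.arm_probe_span("1", "p")
    _, q_last = genome.arm_probe_span("1", "q")
    seg = pd.DataFrame([{
        "sample_id": "s", "chrom": "1", "start": pa_first, "end": q_last + 1,
        "state_a": "loss", "state_b": "neutral", "category": "hemizygous-loss",
        "n_probes": 100, "ratio_a": 0.6, "ratio_b": 1.0,
    }])
    out = classify_arm_span(seg, genome)
    assert sorted(out["arm"]) == ["p", "q"]
    assert (out["span_class"] == "whole-arm").all()


def test_arm_events_unit(genome):
    classified = pd.DataFrame([
        {"sample_id": "s", "chrom": "1", "arm": "p", "span_class": "focal"},
        {"sample_id": "s", "chrom": "1", "arm": "p", "span_class": "whole-arm"},
        {"sample_id": "s", "chrom": "13", "arm": "q", "span_class": "focal"},
    ])
    events = arm_events_from_segments(classified)
    assert len(events) == 2  # one event per (sample, arm)
    assert set(events["event_class"]) == {"whole-arm", "focal"}


def test_seg_round_trip(genome, tmp_path):
    track = constant_track(genome)
    track.loc[track["chrom"] == "13", "ratio_a"] = 0.5
    segs = call_segments(smooth_ratios(track), genome, sample_id="T1")
    classified = classify_arm_span(segs, genome)
    write_seg(classified, tmp_path / "t.seg", tmp_path / "t.tsv")
    seg = pd.read_csv(tmp_path / "t.seg", sep="\t")
    assert list(seg.columns) == ["ID", "chrom", "loc.start", "loc.end",
                                 "num.mark", "seg.mean"]
    back = read_segments(tmp_path / "t.tsv")
    assert back["category"].tolist() == classified["category"].tolist()
    assert back["span_class"].tolist() == classified["span_class"].tolist()
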