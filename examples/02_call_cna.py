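"""Call allele-specific copy-number segments for one simulated tumor.

Per-SNP tumor/normal allele ratios sit on the 0.5/1.0/1.5 scale (0, 1 and 2
copies of an allele); after running-median smoothing, ratios > 1.3 are
gains and < 0.7 losses, and runs of a constant per-allele state pair become
segments categorised as gain, hemizygous loss, homozygous deletion or
copy-number-neutral LOH.
"""

from armcna.calling import (CallerConfig, call_segments, classify_arm_span,
                            compute_allelic_ratios, smooth_ratios)
from armcna.simulate import (SimulationConfig, generate_genome,
                             simulate_cna_profiles, simulate_probe_signals)

config = SimulationConfig(seed=1)
genome = generate_genome(config)
truth = simulate_cna_profiles(genome, config)
sample = truth["sample_id"].iloc[0]
planted = truth[truth["sample_id"] == sample]

signals = simulate_probe_signals(planted, genome, purity=config.purity,
                                 noise_sd=config.noise_sd, seed=2)[sample]
caller = CallerConfig()
track = smooth_ratios(compute_allelic_ratios(signals), caller)
segments = classify_arm_span(call_segments(track, genome, caller,
                                           sample_id=sample), genome, caller)

print(f"{sample}: {len(planted)} planted events, {len(segments)} called segments")
print(segments[["chrom", "arm", "start", "end", "category",
                "span_class", "n_probes"]].to_string(index=False))
print()
print("Each segment reports its per-allele category and whether it spans")
print(">98% of its arm's probe span (whole-arm) or less (focal).")
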