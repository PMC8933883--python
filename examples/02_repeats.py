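"""Repeat scanning: SSRs (MISA thresholds 10/5/4/3/3/3), tandem arrays and
dispersed/palindromic repeat pairs, summarised by genomic region."""
import plastokit as pk

ancestor, truth = pk.build_ancestor(pk.SynthConfig.small(seed=2))

ssrs = pk.find_ssrs(ancestor.seq)
print(f"{len(ssrs)} SSRs found ({len(truth.ssrs)} were planted):")
for s in ssrs[:6]:
    print(f"  {s.motif:>4s} x{s.copies:<3d} at {s.start:>6,}")

summary = pk.ssr_region_summary(ssrs, truth.partition, ancestor.genes)
print("motif classes (%):",
      {k: round(v, 1) for k, v in summary.class_percent.items() if v})
print("by region:", summary.region_counts.to_dict())
print("loci with >= 3 SSRs:", summary.flagged)

tandem = pk.find_tandem_repeats(ancestor.seq)
print(f"tandem arrays (unit >= 7 bp, score >= 50): {len(tandem)}")
pairs = pk.find_pair_repeats(ancestor.seq, "dispersed")
print(f"dispersed pairs (>= 30 bp, >= 90% identity): {len(pairs)}")

# The flagged loci are the spacers carrying >= 3 SSRs - the SSR half of the
# highly-variable-region (barcode candidate) rule.
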