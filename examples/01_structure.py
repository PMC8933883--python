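"""Quadripartite structure: detect the IR pair, partition a plastome and
type its IR/SC junctions.

Builds a small synthetic plastome family with a known layout, then recovers
the structure from sequence alone.
"""
import plastokit as pk

cfg = pk.SynthConfig.small(seed=1, junction_edit="typeII")
ancestor, family, truth = pk.make_family(cfg)

genome = family[0]
irp = pk.detect_inverted_repeats(genome.seq)
part = pk.partition_genome(genome, irp)
print(f"genome {genome.id}: {part.n:,} bp")
for region, length in part.region_lengths.items():
    print(f"  {region:4s} {length:>7,} bp")
print(f"  IR copies at identity {irp.identity:.4f}")

profile = pk.profile_junctions(genome, part)
label, why = pk.classify_junction_type(profile, with_trace=True)
print(f"junction type: {label} ({why}); planted: {truth.junction_type}")
for jname, slot in profile.slots.items():
    if slot.overlap:
        print(f"  {jname}: inside {slot.overlap.name} "
              f"(split {slot.split[0]}/{slot.split[1]} bp)")
    else:
        print(f"  {jname}: {slot.left.name} --{slot.left_dist} bp-- | "
              f"--{slot.right_dist} bp-- {slot.right.name}")

# The region lengths sum to the genome size; the junction label tells which
# genes flank (or span) each IR/single-copy boundary - here a type II
# architecture, i.e. IR expansion that fully duplicates ycf1.
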