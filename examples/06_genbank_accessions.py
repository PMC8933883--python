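"""Run the structural pipeline on real plastomes from GenBank.

Downloads the three Aroideae accessions (~160 kb each) and reports their
quadripartite structure, junction types and SSR counts. Requires network
access to NCBI; everything else in this package runs offline.
"""
import sys

import plastokit as pk

ACCESSIONS = ["MN972442", "MN972441", "MW628970"]

genomes = []
for acc in ACCESSIONS:
    try:
        path = pk.fetch_genbank(acc, "scratch/genbank")
    except Exception as e:  # noqa: BLE001
        sys.exit(f"could not reach NCBI ({e}); this example needs network access")
    genomes.append(pk.read_genbank(path))

partitions = []
for g in genomes:
    part = pk.partition_genome(g, pk.detect_inverted_repeats(g.seq))
    partitions.append(part)
    label = pk.classify_junction_type(pk.profile_junctions(g, part))
    n_ssrs = len(pk.find_ssrs(g.seq))
    print(f"{g.id}: {part.n:,} bp | LSC {part.lsc.length:,} | "
          f"SSC {part.ssc.length:,} | IR {part.irb.length:,} | "
          f"GC {100 * g.gc:.1f}% | junction type {label} | {n_ssrs} SSRs")

for c in pk.region_size_correlations(partitions):
    print(f"{c.pair[0]}~{c.pair[1]}: r={c.r:+.3f} R^2={c.r2:.3f} p={c.p:.3g}")
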