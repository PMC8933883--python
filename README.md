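# plastokit

Comparative analysis of chloroplast genomes (plastomes) for people working on
plant phylogenetics and marker development: detect the quadripartite
LSC–IRb–SSC–IRa architecture and type its IR/single-copy junctions, scan for
microsatellites and larger repeats, rank genes and intergenic spacers by
nucleotide diversity, nominate and score DNA barcodes against a reference
phylogeny, and screen protein-coding genes for selection with a pairwise
Ka/Ks. A synthetic plastome-family generator with exact ground truth backs
every stage, so the whole pipeline is testable end to end without downloading
anything.

## What it computes

* **Quadripartite structure.** The inverted repeat is the maximal pair of
  non-overlapping arcs of the circular genome where one arc matches the
  reverse complement of the other (ungapped, identity ≥ 0.99, length ≥ 1 kb),
  found by k-mer seeding and X-drop extension. The longer inter-IR arc is the
  LSC, the shorter the SSC; IRb is the copy upstream of the SSC. Junctions are
  typed I–IV from the genes that flank or span them (e.g. type II = IR
  expansion placing the IRb/SSC boundary inside *ndhF* and duplicating *ycf1*;
  type IV = reverse-complemented SSC).
* **Repeats.** SSRs are maximal perfect runs of primitive 1–6 bp units with
  class thresholds 10/5/4/3/3/3 (mono→hexa); tandem arrays with unit ≥ 7 bp
  are scored +2/−7 against the array consensus; dispersed and palindromic
  pairs need ≥ 30 bp at ≥ 90 % identity.
* **Nucleotide diversity.** Per shared gene or spacer,
  π = Σ_{i<j} d_ij / C(n,2) over columns surviving complete gap/N deletion.
* **Barcodes.** Highly variable regions are spacers/genes with π strictly
  above 0.17 that also carry ≥ 3 SSRs in at least one focal taxon. Each
  candidate (alone or concatenated) gets an NJ + bootstrap tree; its
  *discrimination success ratio* is 100 × the fraction of non-trivial
  reference-tree splits its own tree recovers, alongside variable /
  parsimony-informative site counts and the number of edges with bootstrap
  support > 75.
* **Selection.** Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3), plastid (bacterial) genetic code.

## Worked example

```python
import plastokit as pk

cfg = pk.SynthConfig.small(seed=1, junction_edit="typeII")
ancestor, family, truth = pk.make_family(cfg)

genome = family[0]
part = pk.partition_genome(genome, pk.detect_inverted_repeats(genome.seq))
print(part.region_lengths)
label, why = pk.classify_junction_type(
    pk.profile_junctions(genome, part), with_trace=True)
print(label, why)
```

prints

```
{'LSC': 14000, 'IRb': 6898, 'SSC': 4102, 'IRa': 6898}
II IR expansion duplicating ycf1
```

— the four region lengths sum to the 31,898 bp genome, the IR pair was
recovered at the exact planted coordinates, and the junction profile shows
the type II signature (IRb/SSC boundary splitting *ndhF* 450/450 bp, *ycf1*
fully duplicated into both IRs).

Running the diversity + barcode stages on a default family
(`examples/03_diversity_hotspots.py`, `examples/04_barcodes.py`) yields

```
mean pi per class: {'coding': 0.0248, 'noncoding': 0.0583}
top regions by pi:  psaC-ndhE 0.2369 | trnS-trnG 0.2233 | atpH-atpI 0.2231
HVR candidates: [('atpH-atpI', 0.225, 4), ('psaC-ndhE', 0.229, 3), ('trnS-trnG', 0.226, 3)]
atpH-atpI+psaC-ndhE+trnS-trnG   2400 bp   discrimination 100.0
```

i.e. spacers are more diverse than coding regions, the three planted hotspot
spacers are selected as barcode candidates by the π > 0.17 ∧ ≥ 3 SSR rule,
and the combined barcode recovers every reference-tree split.

The `examples/` directory has one short script per capability; `plastokit
--help` exposes the same stages as a thin CLI (`synth`, `structure`,
`repeats`, `diversity`, `tree`, `kaks`, `barcodes`, `convert`).
`examples/06_genbank_accessions.py` runs the structural pipeline on the three
Aroideae accessions MN972442 / MN972441 / MW628970 when network access to
NCBI is available.

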