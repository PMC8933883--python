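# Methods

## Scope and data model

plastokit treats a plastome as a circular DNA string over {A,C,G,T,N} with a
flat list of gene features. Coordinates are 0-based half-open on the forward
strand of one linearization; external GFF3-like tables are 1-based inclusive;
features that wrap the origin are split into sub-intervals so all interval
arithmetic stays linear. Ambiguity codes other than N degrade to N on load
(with a warning) rather than erroring, because archival records contain them.

## Inverted-repeat detection and partitioning

The IR pair is defined as the maximal-length pair of non-overlapping arcs
(i₁, i₂) with segment(i₂) = revcomp(segment(i₁)) ungapped at identity ≥
`min_identity` (default 0.99) and length ≥ `min_len` (default 1000 bp).
Detection seeds exact 31-mers of the (logically doubled, for circularity)
sequence against its reverse complement, merges seeds per anti-diagonal and
extends ungapped. Extension uses +1/−p scoring with p =
round(min_identity/(1−min_identity)) (99 at the default) and an X-drop stop,
trimming each end at its score maximum. The penalty makes sustained extension
require *local* identity ≥ min_identity; a global running-identity rule was
rejected because, with a ~25 kb exact match banked, it tolerates hundreds of
bases of random flank and smears the boundary. With X-drop the boundary of a
(near-)exact IR is recovered to the base. Ties are broken by longer length,
then smaller start. Indel-containing IRs are out of scope: the ungapped
definition is exact on the genomes this tool targets.

The two inter-IR arcs become LSC (longer) and SSC (shorter); equal arcs raise
an ambiguity error carrying both assignments. IRb is the IR copy whose
clockwise neighbour is the SSC — a convention, fixed here because the
clockwise region order is then always LSC–IRb–SSC–IRa and a rotation alone
canonicalises any input (`rotate_to_lsc_origin` is idempotent and
length-preserving).

## Junction profile and boundary types

For each of the four junctions the profile reports either the single
annotated gene overlapping the junction point (with the bp split across it)
or the nearest annotated gene on each side with distances (circular, capped
at 10 kb). "Junction between A and B" means the junction point lies in the
intergenic interval flanked by A and B, irrespective of strand. The
classifier is a pure decision table on marker genes
(trnN, ndhF, ycf1, rps15, trnR):

| type | IRb/SSC | SSC/IRa |
|------|---------|---------|
| I    | between trnN and ndhF | within ycf1, or between ycf1 and trnN (sub-case recorded) |
| II   | within ndhF | between rps15 and ycf1 (ycf1 fully inside the IR) |
| III  | between trnR and trnN | between ycf1 and trnN |
| IV   | between trnN and ycf1 | between ndhF and trnN |

anything else is `unclassified` with a reason. Both type-I sub-cases are
accepted because "within ycf1 and trnN" is genuinely ambiguous between the
spanning and the adjacent reading.

## Region-size correlations

Pearson r with the two-sided p from the t distribution (df = n−2) for the six
pairs among total size, LSC, SSC and IR length (scipy.stats.pearsonr behind
the interface). Signed r is reported alongside R², since an R² alone
conflates strength and direction. Zero-variance variables yield a
NaN result with an explanatory note for that pair instead of aborting the
table.

## Repeat scanning

**SSRs.** Maximal perfect runs of primitive units (1–6 bp) meeting class
thresholds {1:10, 2:5, 3:4, 4:3, 5:3, 6:3}. A run is reported once, at its
leftmost phase, under its shortest primitive unit; motifs are canonicalised
to the lexicographically smallest rotation; N breaks runs. Compound
(interruption-merged) SSRs are *not* merged — each simple run counts once —
and runs of different unit lengths may physically overlap by a few bases
(both are maximal; a brute-force scan agrees). Same-unit phase duplicates
never occur.

**Tandem arrays** (unit ≥ 7 bp) are a simplified Tandem Repeats Finder:
candidate periods from recurring exact 7-mers, lag-d extension with +2/−7
scoring and X-drop, then scoring of the whole array against its per-phase
majority consensus (+2 match / −7 mismatch, so a perfect 35 bp array scores
70); arrays scoring ≥ 50 are kept and overlaps reduce to the best scorer.
No probabilistic model, no indels in the array alignment, no period
refinement — counts from this stage are indicative, not calibrated to TRF.

**Dispersed/palindromic pairs** seed exact 20-mers of the sequence against
itself (or its reverse complement), exclude the trivial diagonal, extend with
the same X-drop rule at the 90 % identity penalty, keep hits ≥ 30 bp,
collapse symmetric duplicates and merge overlapping hits. Extension is
ungapped; hyper-repetitive seeds (> 60 occurrences) are skipped as
low-complexity. On a full plastome the IR itself surfaces as the largest
palindromic hit, which is the expected behaviour of this screen.

## Nucleotide diversity

π = Σ_{i<j} d_ij / C(n,2) with d_ij the proportion of differing sites over
retained columns. Complete deletion of gap/N columns is the default (matching
the common desktop tool's behaviour); pairwise deletion is a switch. Zero
retained columns is an error, not π = 0. Shared regions are every gene name
and every adjacent-gene spacer "A–B" (genome order, hyphen convention)
present in ≥ 2 taxa; gene sequences are strand-normalised. The built-in
aligner is progressive Needleman–Wunsch (match 1, mismatch −1, gap −2;
sequences joined to the most 6-mer-similar centre, "once a gap always a
gap") and is intended for toy/test scale; genome-scale work ingests external
alignments. The aligner never changes sequence content (degap round trip is
asserted at run time).

## Barcode selection and evaluation

A region is a highly-variable-region candidate iff π strictly exceeds
`pi_threshold` (default 0.17) **and** it carries ≥ `min_ssr` (default 3) SSRs
in at least one focal taxon; the spellings trnN–trnF and trnN–ndhF are
treated as aliases. Concatenation intersects taxa (dropped taxa recorded) and
records part boundaries. Variable sites are columns with ≥ 2 distinct
non-gap/non-N states; parsimony-informative sites additionally need ≥ 2
states each in ≥ 2 taxa. Discrimination success ratio ≝ 100 × |splits(marker
tree) ∩ splits(reference tree)| / |splits(reference tree)| over non-trivial
splits — no standard formula exists for this quantity, and this reading
reproduces the expected 100 %-on-self property. Support counting is strict
("> 75"), on internal edges of the point-estimate NJ tree.

## Trees

Distances: p, JC69 (−(3/4)ln(1−4p/3)) or K2P, with pairwise deletion;
out-of-domain logs raise a saturation error naming the pair. NJ is the
standard Saitou–Nei Q-matrix algorithm; Q ties break on the smallest index
pair; negative branch lengths clamp to 0 with a warning. Bootstrap resamples
columns with replacement (replicate r uses an RNG stream derived from
(seed, r), so runs are deterministic and order-independent); replicates whose
distances saturate are skipped and counted, and support is the percentage of
completed replicates containing each original-tree split. The engine is
deliberately distance-based: likelihood and Bayesian inference are external
analyses this package does not attempt to reproduce.

## Ka/Ks (NG86)

Synonymous site potential per codon position is the fraction of the three
alternative bases giving a synonymous change; changes *to* stop codons count
as nonsynonymous, so every counted codon contributes exactly 3 sites.
Differences average over all minimal substitution pathways per codon,
excluding pathways through a stop when a stop-free pathway exists. Codons
with a gap or N in either sequence are excluded pairwise; a terminal stop is
dropped; an internal stop raises naming the codon. Both proportions are
Jukes–Cantor corrected; ω = Ka/Ks is undefined (None) when Ks = 0 — a
consequence being that a gene with purely nonsynonymous changes has no ω
rather than a large one. The screen reports the mean of defined pairwise ω
per gene and flags mean ω > 1.

## The synthetic generator

The generator is the package's study system: circular genomes with the
canonical quadripartite layout, junction marker genes placed as in a type-I
plastome (ycf1 spanning the SSC/IRa junction with its reverse-complement
"ψycf1" tail at the IRb end; trnN and trnR inside the IR; ndhF and rps15 in
the SSC; rps19/rpl2/trnH around the LSC junctions), planted SSRs and
dispersed/palindromic/tandem repeats, and per-region GC. Defaults mirror a
large Aroideae-like plastome: LSC 91,710 bp, SSC 22,994 bp, IR 25,601 bp
(165,906 bp total) with GC 33.8/28.6/42.3 % in LSC/SSC/IR; a ~30 kb
`SynthConfig.small()` variant with the same architecture exists for
simulation-heavy work. Three LSC spacers (atpH–atpI, trnS–trnG, psaC–ndhE)
are designated mutation hotspots (rate ×6) and each carries three planted
SSRs, so the HVR rule has an exact expected answer.

Junction edits rewrite the type-I ancestor into the other architectures:
type II duplicates the SSC margins into both IRs (ycf1 fully duplicated,
boundary inside ndhF); type III contracts the IR past trnN, plants a trnN in
the expanded SSC and leaves the IRa-side trnN annotated (the degraded
IRb-side copy is unannotated — IR copies with asymmetric annotation are the
only geometry consistent with this boundary type); type IV
reverse-complements the SSC in place (an involution on the sequence; the
junction-spanning ycf1 is split and its stranded IR fragment dropped from the
annotation, as a pseudogene).

Evolution is Jukes–Cantor per site along a user tree (default: 8 taxa,
balanced, all branches 0.01 expected substitutions/site), with per-site rate
multipliers: CDS 0.8, tRNA/rRNA 0.3, intergenic 1.0, hotspots 6.0, and IR
sites ×0.15. There are no indels, so every tip stays positionally aligned
with the ancestor and π truth is exact. Three deliberate departures from
plain JC keep the ground truth exact and the sequences biologically sane:

1. **Concerted IR evolution** — one mutation stream is applied to the IR and
   mirrored into both copies, emulating plastid gene conversion; the IR pair
   therefore stays an exact reverse-complement match and boundary recovery
   can be asserted to the base.
2. **Fixed SSR loci** — planted SSR runs (plus one flanking base) do not
   accept substitutions. Real microsatellites evolve mainly by slippage,
   which this simulator does not model; substitution would simply erode them,
   whereas the biological observation the HVR rule relies on is that the loci
   persist across related taxa.
3. **Nonsense purging** — a mutation creating an internal stop in a fully
   single-copy CDS is reverted to the parent state (purifying selection
   against nonsense), keeping CDS regions usable by the Ka/Ks screen. The
   junction-spanning ycf1 is exempt (its IR portion is regenerated from the
   concerted IR copy) and is excluded from codon-level screens.

Additionally, the four single-copy bases flanking the IR boundaries are held
invariant and constrained not to extend the reverse-complement match — four
"junction anchor" sites out of ~10⁵, without which any seeded detector would
overrun a planted boundary whenever the flanking base happens to complement
its counterpart (25 % of genomes per boundary).

Per-taxon truth marks a planted SSR "intact" only if its run is unchanged and
still maximal in that tip. Determinism: every operation draws from an RNG
stream keyed by (config seed, operation tag), so results are independent of
call order and byte-identical across runs.

## Problem sizes used by the tests and the acceptance script

Simulation-heavy checks run on the ~30 kb small configuration: 20 families
for structure/junction/HVR recovery, 100 families for the coding-vs-noncoding
π comparison, 50 families for the combined-vs-single barcode comparison, and
200 bootstrap replicates at 8 taxa for the discrimination evaluations; the
full-scale 166 kb default is measured once for the structural quantities.
The combined-vs-single comparison deliberately uses a marginal-signal tree
(internal branches 0.0008, terminal 0.01) so that single markers do not
saturate at 100 % and the comparison is informative; it asserts combined ≥
best single, since discrimination is a recovered-split fraction and ties at
100 % are the expected end state. The SSR oracle comparison uses 100 random
2 kb sequences over a deliberately low-entropy alphabet mix so runs actually
occur.

## Limitations

* The generator has no indel or rearrangement process beyond the scripted
  junction edits, no codon model, and no slippage; passing recovery tests
  shows correctness of the analysis code under these conditions, not
  robustness to indel-rich real alignments (external aligners cover that
  path).
* The IR detector assumes ungapped, near-identical IR copies; plastomes with
  indel-divergent IRs would be reported at the matching core only.
* Tandem-repeat counts are not calibrated against Tandem Repeats Finder
  output; the detector shares its thresholds but not its probabilistic
  model.
* The Ka/Ks screen is a pairwise counting method; it is not a substitute for
  site-model likelihood analyses and is expected to flag noise near ω ≈ 1 on
  neutral data.
* Junction typing depends on the annotation: missing marker genes yield
  `unclassified`, and asymmetrically annotated IRs (as in the type III
  architecture) are typed from whatever copies are annotated.
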