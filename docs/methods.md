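# Methods

## Scope and model

`beadphase` analyses (and simulates) a two-emulsion bead-barcoding
experiment. The first emulsion loads degenerate barcode oligonucleotides
onto primer-coated beads; the second pairs one enriched bead per droplet
with genomic fragments and amplifies two target regions per fragment
with the bead barcode attached. Both loading steps are modelled as
Poisson: with rate λ (copies per bead, c.p.b.), the occupancy is
`1 − e^(−λ)` and the monoclonal fraction of occupied compartments is
`λe^(−λ)/(1 − e^(−λ))`. "Monoclonal" at the loading level means exactly
one molecule per compartment (K = 1); the read-based monoclonality
labels computed downstream are separate, observational classifications
that are *compared against* this prediction, not defined by it. No
droplet-size heterogeneity or non-Poisson loading is modelled.

## Synthetic data generator

The simulator is first-class, tested code and defines the conditions all
pipeline-level checks run under:

* **Reference panel** — four species per run by default. Each target
  region (150 nt by default) descends from one random ancestor with
  independent substitutions at 5% per base per species, so species pairs
  differ at an expected `2·0.05·0.95 ≈ 9.5%` of positions — the order of
  divergence seen between bacterial species in 16S variable regions. A
  constant 20-nt primer per target (shared by all species, mutually
  distinguishable) starts every read 2.
* **Loading** — barcode c.p.b. 0.1 and fragment c.p.b. 0.1, the design
  point of the assay; 15-nt degenerate barcodes (configurable 15–20, a
  population of 4^15 ≈ 10^9 so collisions are negligible at desk scale).
* **Mixture** — species abundances (0.4, 0.3, 0.2, 0.1): skewed, as
  observed in real mixtures, and giving a chance-collision level
  Σpᵢ² = 0.30 that clearly separates observed from corrected rates.
* **Depth** — Poisson-distributed reads per amplicon with mean 20:
  enough that the support filters pass nearly all true clusters while
  Poisson dropout still produces occasional missing targets.
* **Errors** — i.i.d. per-base substitutions at 0.5% (short-read scale),
  uniformly to one of the three other bases; no indels, chimeras, PCR
  recombination or quality-score profiles. Quality strings are constant.
  Polyclonal beads contribute each read's barcode uniformly at random
  from their barcode set.

Runs are fully deterministic: one seed drives independent per-stage
streams keyed by `(seed, crc32(stage))`, so identical configurations
give byte-identical FASTQ, truth tables and summaries. The truth record
maps every read to its droplet, fragment, species, target and true
barcode.

Because the generator is substitution-only with known primers and a tiny
reference panel, passing tests demonstrate correctness of the
*algorithms* under the stated noise model — not robustness to indels,
chimeric amplicons, contamination, or classification against large
reference databases.

## Pipeline stages and numerical choices

* **Barcode extraction** — handles located at fixed offsets on read 1;
  a read is kept if the mismatches summed over both handles are ≤ 4.
  Rejected reads are excluded from all counts, with reasons recorded.
* **Well demultiplexing** — observed tag assigned to the unique designed
  tag within 2 mismatches; tag sets are validated to be pairwise > 4
  apart so the assignment is unambiguous (generated tags are 12 nt at
  pairwise distance ≥ 5).
* **Barcode clustering** — "mismatch" means Hamming distance on
  equal-length strings (degenerate barcodes are fixed-length; no
  indels). Distinct barcodes are ranked by descending read count (ties:
  lexicographically smaller first); a sweep makes each unassigned
  barcode a seed and absorbs every later unassigned barcode within 2
  mismatches of it; clusters are re-ranked on aggregated counts and the
  sweep repeats until the number of clusters stops decreasing. A barcode
  within range of two seeds goes to the higher-ranked one. The reported
  seed is the cluster's most abundant member. Direct members lie within
  the seed's radius; merges in later passes can chain slightly beyond
  it, which is the intended fixed-point behaviour of the iterative
  procedure.
* **Well clonality** — a cluster "counts" if it holds ≥ 10% of the
  well's reads; 0/1/≥2 counting clusters give empty/monoclonal/
  polyclonal. The 10% floor is this package's automated surrogate for a
  manual read-distribution call, and is configurable.
* **Target assignment** — read 2 is assigned to the unique target whose
  primer matches its prefix within 2 mismatches, then primer-trimmed;
  primer pairs too similar to distinguish are a configuration error.
* **Filtering** — target groups with < 3 reads are dropped, then
  clusters with < 5 surviving reads. These defaults are deliberate,
  configurable stand-ins: depth-dependent filtering belongs in the
  pipeline, but the thresholds are parameters, not ground truth.
* **Variant sub-clustering** — same greedy procedure as barcode
  clustering with a per-base threshold of 2% of the compared length
  (comparisons truncate to the shorter read). 2% sits between the 0.5%
  error scale (errors collapse onto the template) and the ~9.5%
  between-species scale (species split).
* **Consensus** — positional majority over the dominant variant group;
  consensus length is the modal read length (ties → shorter), base ties
  break to the lexicographically smallest base. No multiple alignment:
  with a substitution-only error model reads are positionally
  comparable.
* **Amplification clonality** — monoclonal iff the largest variant group
  holds ≥ 90% of every present target's reads; 90% is a configurable
  default chosen to tolerate stray many-error reads at moderate depth.
* **Classification** — k-mer containment (k = 8, forward strand:
  amplicons are orientation-fixed by the primers):
  `score = |shared k-mers| / |query k-mers|`. The hit list is every
  species scoring within 0.05 of the top; the best call requires the top
  to clear the runner-up by > 0.05, otherwise the call is explicitly
  "ambiguous" (an ambiguous call is excluded from phasing-rate
  eligibility — a match cannot be adjudicated). This is a declared
  desk-scale surrogate for database alignment; its behaviour is
  validated on simulations, not against real-data hit counts.
* **Phasing statistics** — `P_obs` over clusters with both targets
  called unambiguously; `P_rand` as the mean over 100 shuffles of the
  second target's calls (first target fixed), reported with its
  Monte-Carlo SE; `P_corr = (P_obs − P_rand)/(1 − P_rand)`, clamped
  below at zero and undefined (signalled, not silently 0) when
  `P_rand = 1` or no cluster is eligible. Dominant-species removal drops
  every cluster whose calls include the most abundant best-call species
  and recomputes all three rates on the remainder.
* **Hit-list overlap** — per both-target cluster,
  `reduction = 1 − |A∩B| / mean(|A|, |B|)`. The mean-length denominator
  is one reasonable convention among several (min or max would also do);
  the metric is labelled and kept alongside the raw mean lengths and
  overlaps so alternatives can be derived.
* **Depth subsampling** — reads are subsampled without replacement at
  given fractions and the whole pipeline rerun, tabulating clusters
  passing filters and the both-targets fraction against depth.

## Problem sizes

The default simulated run uses 60,000 beads and 5,000 droplets, yielding
roughly 480 read-bearing clusters and ~20,000 read pairs — large enough
that binomial error bands around the Poisson predictions are a percentage
point or two wide, and small enough that the full test suite completes in
well under a minute. Clustering cost is quadratic in the number of
distinct barcodes per pass; at these scales (a few thousand distinct
barcodes) the vectorised implementation runs in seconds, and an
all-pairs naive transcription of the same procedure is kept as a test
oracle for instances up to 200 barcodes.

## Known limitations

* Substitution-only error model; the clustering tolerances are not meant
  for indel-rich platforms.
* The classifier is a containment score over a small panel; it is not a
  replacement for alignment against comprehensive 16S databases, and
  hit-list sizes on real data would differ.
* Chained absorption across clustering passes means the member-to-seed
  distance can slightly exceed the nominal radius after merges.
* The well-clonality and amplification-clonality thresholds (10%, 90%)
  and the support filters (3 reads/target, 5 reads/cluster) are
  surrogates for unpublished criteria; conclusions sensitive to them
  should be checked across settings.
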