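# beadphase

Simulation and analysis of two-stage emulsion bead barcoding for
single-molecule phasing of amplicons.

## The problem

Short-read sequencers lose *phase*: when two variable loci are sequenced
as separate amplicons, nothing in the reads says whether the two variants
sat on the same DNA molecule. One way to recover phase is to
compartmentalise single molecules with uniquely barcoded beads in
emulsion droplets, amplify several target regions of the molecule with
the bead's barcode attached, and trace reads back to their molecule of
origin through the barcode. `beadphase` implements the full data-analysis
side of such an experiment — plus a ground-truthed simulator of the
experiment itself, so the whole pipeline is testable on a desk with no
sequencing data.

The motivating application is bacterial 16S rRNA profiling: two variable
regions (called `16S.1` and `16S.2` throughout) are amplified per
genomic fragment, and a cluster whose two amplicons classify to the same
species is evidence that both regions were read from one molecule.

## The model

Loading of barcode oligonucleotides onto beads (and of genomic fragments
into droplets) is Poisson. With a mean of λ copies per bead (c.p.b.):

* occupancy (enriched-bead fraction): `P(K≥1) = 1 − e^(−λ)` — ~9.5% at
  the λ = 0.1 design point, i.e. "about 10% of beads";
* monoclonal fraction of occupied compartments:
  `P(K=1 | K≥1) = λe^(−λ) / (1 − e^(−λ))` — ~95.1% at λ = 0.1.

Downstream, reads are grouped into **barcode clusters** by an iterative,
abundance-ranked greedy procedure with a Hamming mismatch tolerance
(default 2). Each cluster's reads are assigned to targets by primer
prefix, filtered for support, sub-clustered into sequence variants, and
the dominant variant's positional-majority consensus is classified
against a small reference panel by k-mer containment. The headline
statistics are then

* the observed phasing rate `P_obs` — the fraction of both-target
  clusters whose two consensuses classify to the same species;
* the random match rate `P_rand` — the same fraction after shuffling one
  target's calls across clusters (chance baseline; analytically `Σ pᵢ²`
  for call frequencies `p`);
* the corrected phasing rate
  `P_corr = (P_obs − P_rand) / (1 − P_rand)` — the estimated fraction of
  clusters whose match is not explained by chance.

## Worked example

Simulate and analyse a small run (1,000 droplets, four species at
0.4/0.3/0.2/0.1 abundance, 0.1 c.p.b. loading, 0.5% sequencing error):

```sh
beadphase phase --outdir demo --seed 42 --n-beads 12000 --n-droplets 1000
```

prints (stage counts go to stderr):

```json
{
  "frac_both": 1.0,
  "monoclonal_rate": 0.9555555555555556,
  "n_clusters": 90,
  "p_corr": 0.9684443041969075,
  "p_obs": 0.9777777777777777,
  "p_rand": 0.2957777777777778,
  "p_rand_se": 0.004646850127961373,
  ...
}
```

Reading this: 90 barcode clusters passed the support filters (≈9.5% of
the 1,000 droplets received a fragment, as Poisson predicts); 95.6% of
them amplified monoclonally (Poisson predicts 95.1% single-fragment
droplets); 97.8% of both-target clusters matched species across targets,
of which an estimated 29.6% would match by chance (the skewed
four-species collision value Σpᵢ² = 0.30), giving a corrected phasing
rate of 96.8% — close to the true single-fragment fraction recorded in
the simulator's `truth.tsv`. The other subcommands (`simulate`,
`cluster`, `consensus`, `classify`, `stats`, `sort`, `model`) expose the
individual stages; `beadphase sort` runs the well-plate
bead-monoclonality experiment and `beadphase model` prints the Poisson
expectations.

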