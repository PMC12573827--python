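# Methods

## Background: negative restriction-site selection

Classical reduced-representation sequencing (RAD-seq, GBS) sequences the
DNA *adjacent to* restriction-enzyme cut sites. Inverse RAD-seq turns the
selection around: whole-genome Tn5 tagmentation libraries are prepared
first, pooled, and then digested with a panel of enzymes. A library
molecule that contains a complete recognition site is cleaved and loses one
of its sequencing adapters, so only molecules *free* of every panel motif
remain amplifiable. Together with a size-selection step this reproducibly
samples the site-free portion of the genome across samples.

`iradsim` models the computational side of this design: which genomic
intervals survive for a given panel, what a simulated library looks like,
how many residual-site reads incomplete digestion leaves, and how the
resulting genotypes resolve a backcross population into recombination bins.

## Digestion model

An enzyme is a name plus an IUPAC recognition motif (all six built-ins —
MseI TTAA, MspI CCGG, AluI AGCT, DpnII GATC, HindIII AAGCTT, HinP1I GCGC —
are palindromic 4- or 6-cutters). Site scanning matches the motif on the
forward strand and, for non-palindromic motifs, its reverse complement as
well, reporting forward-strand intervals. Matching is position-wise IUPAC
set membership with all overlapping occurrences reported; an assembly `N`
satisfies no motif symbol, because digestion needs real sequence. All
coordinates are 0-based half-open; sequences are upper-cased on ingest, so
soft-masking is ignored.

Site-free fragments are derived under two boundary conventions:

* **between_sites** (default): fragments run between consecutive merged
  site intervals, excluding the site bases. With chromosome-end fragments
  included (default), fragments plus merged site intervals partition the
  genome exactly — the conservation identity the test suite asserts.
* **maximal_site_free**: maximal intervals containing no complete motif
  occurrence. Real digestion leaves partial sites at molecule ends, so
  these intervals extend into the flanking sites (all but one base) and
  consecutive fragments can overlap by a few bases. `union_length()`
  accounts for the shared flanks. This convention defines the space a
  surviving (site-free) library insert can occupy, and is what the library
  simulator is validated against.

Only sites *minimal under containment* constrain maximal site-free
intervals (avoiding an inner motif occurrence necessarily avoids any outer
one), which gives a linear-time derivation after sorting.

## Panel-evaluation statistics

* Threshold summaries count fragments with length strictly greater than
  each threshold ("longer than T"; a flag switches to `>=` because the
  off-by-one changes printed counts) and report coverage as retained bases
  over the total assembly length (N included; a non-N denominator is
  available since assemblies differ widely in N content).
* Gap profiles follow the field's convention that a gap is the *distance*
  between consecutive retained fragments, so site bases inside a gap count
  toward its length; terminal genome segments count as gaps by default and
  a chromosome with no retained fragment is one whole-chromosome gap. The
  profile also reports a site-excluded gap total, with which retained
  coverage + gaps + merged site bases sum exactly to the genome length.
* Window density tiles each chromosome with fixed windows (default 10 kb;
  a step smaller than the window gives a true sliding track) and reports
  per-window overlapping-fragment counts and covered fraction, exportable
  as bedGraph.
* Panel comparisons report relative deltas against a baseline panel,
  (baseline − panel)/baseline.

A note on monotonicity: adding an enzyme to a panel can only remove
sequenceable bases, so retained *length* (and hence coverage) above any
threshold is non-increasing in panel size unconditionally. The retained
*count* above a threshold is not: splitting a long fragment can yield two
above-threshold pieces. Counts order the way published comparisons show
only in the site-dense regime where thresholds sit in the fragment-length
tail — which is where real plant genomes digested with 4-cutters live, and
where the corresponding acceptance check operates.

## Library simulation

Tagmentation is modelled as `n_inserts` independent inserts: chromosome
chosen proportional to length, start uniform, length from a configurable
model. The default is lognormal with median 450 bp and log-sd 0.35,
truncated to [50, 2000] bp — a plausible Tn5 profile; the protocol this
models does not pin down the distribution, so it is fully configurable
(`normal` and `constant` models are built in). Sequence composition bias
of Tn5 and fragmentation of individual molecules are deliberately out of
scope: the target quantities are locus-selection statistics.

Digestion marks an insert as site-containing when its reference sequence
contains at least one complete panel motif on either strand. Incomplete
digestion is a single per-insert escape probability `p_escape` (default 0):
a site-containing insert survives with that probability. Per-site escape
would multiply parameters without changing the read-level summary this
reproduces.

Size selection keeps pending inserts whose *total* molecule length —
insert plus 136 bp of adapters — lies in [430, 780] bp inclusive, i.e.
insert lengths 294–644 bp with the defaults. The published window is
stated as approximately 300–650 bp of insert; the implementation uses the
exact adapter arithmetic and exposes both bounds as flags.

Read emission writes paired 150 bp reads: R1 the first `read_len` bases of
the insert, R2 the reverse complement of the last `read_len`; shorter
inserts yield full-insert reads. Adapter bases are never emitted and no
sequencing-error model is applied (screening concerns genomic sequence
only). The truth table records per insert its coordinates, fate, escape
flag and whether its emitted reads contain a visible panel site — sites in
the unsequenced middle of a long insert are invisible to read-level
screening, so screened fractions are honest lower bounds on residual-site
molecules.

## Read screening

A read "contains" an enzyme's site when the motif occurs in the read or
its reverse complement (identical for palindromic motifs; `N` bases match
nothing). Paired input is scored per *pair* by default — the insert, not
the read, is the unit digestion acts on — with a per-read mode for
comparison with per-read published ratios. Optional filtering drops
containing reads/pairs while preserving order; the report's counts are
conserved between kept and dropped outputs.

## Bin genotyping

Informative markers are SNPs where both parents are homozygous for
different alleles. Progeny are coded A/B (parental homozygotes), H
(heterozygous) or U (missing or non-parental, which the consistency filter
treats as uninformative rather than an error).

Smoothing slides a window of `w = 15` informative markers (step one
marker) along each line and chromosome. A window is called A or B when the
majority fraction among its homozygous codes reaches `purity = 0.8`, H when
its heterozygous fraction does; otherwise the previous window's call
carries over (leading ambiguity backfills from the first decided window;
an all-ambiguous or shorter-than-`w` track falls back to a majority call).
Each marker takes the state of the window centred on it, and runs shorter
than `min_run = w` markers are absorbed into their larger neighbour,
shortest first. These three defaults are this package's choices — the
approach is standard but unparameterised in the literature it follows —
and all are exposed as flags. Raising purity can only move windows from
decided to carried, so the breakpoint count is non-increasing in purity (a
property test asserts this).

A breakpoint is one maximal state transition, reported as the interval
between the last marker of the left run and the first marker of the right
run — the honest uncertainty of marker data — with the midpoint used when
a point boundary is needed. Bin construction projects all lines'
breakpoint midpoints as boundaries per chromosome; bins are the intervals
between consecutive boundaries plus chromosome ends, each line's bin state
is its smoothed state over the markers inside (nearest marker when empty),
and adjacent bins with identical state vectors across all lines are
merged. Bins tile each chromosome exactly. No population-design prior
biases the calls; H is a first-class state throughout.

## Synthetic data

The genome generator plants motif occurrences with exponentially
distributed spacing (mean `target_site_spacing`) over i.i.d. background of
configurable GC content (default 0.46, a typical plant euchromatin value).
In `clean` mode (default) the background is iteratively repaired so no
accidental occurrence of any planted motif survives, making the truth
table exhaustive — that is what lets tests assert site scans *exactly*.
Optional N-runs (geometric lengths, mean 100 bp) emulate assembly gaps
without touching planted sites. What this generator does **not** emulate:
repeat structure, GC heterogeneity, motif clustering (e.g. CpG-island MspI
density), or chromosome-scale isochores — so passing tests demonstrate
algorithmic correctness and statistical behaviour, not genome realism.

The population generator produces advanced-backcross-like lines: per line
and chromosome a Poisson(1) number of crossovers placed uniformly, segment
states drawn from expected BC1F4 class proportions A:H:B = 0.72:0.06:0.22
(one backcross to the recurrent parent, then three selfings halving
heterozygosity) with consecutive segments forced to differ, observed on a
marker grid of one informative SNP per 20 kb with 1% genotype error and 2%
missing data. Defaults use 50 lines and ten 40-Mb chromosomes — a
rice-scale genome that keeps the suite fast while leaving segments long
enough to be identifiable at the default window width. It does not model
linked crossover interference, segregation distortion, or marker-density
heterogeneity.

## Verification design and problem sizes

* Digestion is verified exactly against per-offset brute-force oracles on
  100 random genome/panel draws per convention, plus hypothesis-driven
  property tests for the IUPAC matcher.
* The simulator/designer agreement check uses a 5-Mb genome with 30-kb
  mean site spacing and 10^5 inserts. The spacing follows a sampling-depth
  argument: union coverage converges to the predicted site-free space only
  where every eligible base has expected depth well above 1, and bases
  within an insert length of a site have structurally depressed coverage
  rates, so the near-site "shadow" must be a small fraction of the genome
  for a 1%-absolute comparison to be informative.
* Residual-site recovery runs at `p_escape = 0.03` and checks both that
  escapes are binomial in the site-containing, in-window inserts and that
  the screened read fraction equals the truth table's expectation.
* Crossover recovery runs the full default population (50 × 10 × 40 Mb,
  ~500 planted crossovers) and scores recovery within one window width
  (300 kb) and the false-call fraction.

## Known limitations

* Cut positions within the recognition site, sticky ends, methylation
  sensitivity and type IIB enzymes are not modelled; the toolkit reasons
  about site presence/absence only.
* Read screening cannot see motifs confined to the unsequenced middle of
  long inserts, nor sites destroyed by variants in the sequenced accession
  (that requires alignment and variant calling, outside this package).
* The published fragment counts for real assemblies may depend on whether
  the original tooling counted terminal fragments or site-inclusive
  lengths; both toggles exist (`include_terminal`, the boundary convention,
  `>` vs `>=`) so either accounting can be reproduced.
* Genetic-map distances (cM) and QTL scans are downstream of the bin
  matrix and intentionally left to dedicated mapping software.
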