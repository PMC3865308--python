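# Methods

`ampliconid` implements a universal species-identification assay for
mammals built around a single mitochondrial 16S rRNA mini-amplicon: a short
(~73–81 nt in the bundled panel) variable region enclosed by two highly
conserved primer sites. Because the primer sites are near-universal across
mammals, one PCR amplifies every species in a sample, and deep amplicon
sequencing then resolves mixtures — including minor components around 1% of
template copies. This note documents the models, defaults and numerical
choices; everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Amplicon model and primer matching

The target region is the sequence *between* the primer sites, primers
excluded; all coordinates are 0-based half-open. Primer matching is
ungapped with IUPAC-aware mismatch counting: a subject base matches a
primer position iff it is one of the bases the degenerate code represents.
`N` in the subject always counts as a mismatch, so N-runs in draft
references cannot create spurious sites. Indels inside an 18–21-nt primer
site are not modelled — at pyrosequencing error rates an indel inside the
primer loses the read, which the mismatch budget cannot and should not
rescue.

Defaults: `max_mismatches = 3` for reference-site discovery (most mammal
templates carry 0–1 differences; 3 leaves headroom for taxa outside the
bundled panel) and `2` for read trimming (sequencing errors inside primers
should not discard reads). Amplicon length bounds default to 40–160 nt,
deliberately wide around the mammalian ~75-nt mode so that unusual taxa are
not silently dropped. Extraction checks both strands and reports the target
on the strand where the forward primer precedes the reverse site; ties are
broken by fewest total primer mismatches, then shortest amplicon, then
leftmost position, and equally good *disjoint* candidates raise an
ambiguity error rather than picking one arbitrarily (two amplicons in one
record is a data problem the caller must see).

Reference FASTA headers are parsed for a `species=<binomial>` key, falling
back to the first two words after the record id; a custom regex can
override both. Lowercase reference letters are uppercased on ingest.

### Primer-site conservation

`primer_conservation_report` consumes primer-site sequences extracted from
an alignment (one per reference, '-' allowed) and reports per-position
A/C/G/T/gap percentages plus a *universality* statistic: the fraction of
references whose site has ≤ k mismatches to the primer (k = 1 by default).
A gap character counts as one mismatch — a site with a deletion is not a
perfect primer template, but a single gap should not exclude the reference
from the statistic entirely. Degenerate primer positions accept any of
their realizations as a match.

## Discriminability

Pairwise species differences are unit-cost global edit distances
(edlib, Needleman–Wunsch mode): substitutions and single-base indels each
count 1, and terminal gaps count because the region is delimited by primers
on both ends. An alignment-free per-pair distance was chosen over a single
multiple-alignment column count because it is deterministic, has an easily
stated cost model, and is checkable against an independent dynamic-
programming oracle; at the divergences involved (tens of differences over
~75 nt) the two counts coincide for practical purposes, though exact
replication of MSA-derived statistics may differ in the last digit.

The UPGMA tree uses arithmetic-average linkage with node heights equal to
half the merge distance, which makes the tree ultrametric by construction
(verified to 1e-9 in tests). Ties in the minimum inter-cluster distance are
broken toward the pair created earliest in label order, and children are
ordered by their earliest original leaf, so output is fully deterministic.
Newick is emitted with 6-decimal branch lengths and no internal labels.
On tie-free matrices the merge heights agree exactly with
`scipy.cluster.hierarchy.average`; with ties, either tie-break is a valid
UPGMA and results can differ legitimately.

Summary statistics use sample standard deviations (ddof = 1). The
identical-pair fraction counts species pairs with byte-identical targets —
the pairs the assay cannot resolve (e.g. closely related canids);
intraspecific variation is deliberately not modelled, one sequence
representing each species.

## Read pipeline

Stage order and defaults:

1. **Quality filter** — keep reads with mean Phred ≥ 20. Mean-based
   because downstream matching uses whole-read identity, not per-base
   calls.
2. **Demultiplex** — exact match of the 10-mer forward barcode at the 5'
   end; if absent, the reverse complement of the read is tried and matched
   reads are re-oriented. Barcode mismatches default to 0 (sample
   cross-talk is worse than read loss at these depths).
3. **Trim** — locate the forward primer (≤ 2 mismatches, ungapped), then
   the reverse-primer site downstream; keep the in-between sequence.
   An exact-string fast path handles error-free primer copies; the scan
   only runs for reads with primer errors. Results are memoized per unique
   read sequence.
4. **Collapse** — dereplicate identical targets, sorted by count then
   sequence.
5. **Minimum-count filter** — keep sequences supported by ≥ 20 identical
   reads (configurable). This is the error-suppression step: at per-base
   error rates of ~1e-3, error variants are overwhelmingly singletons or
   low-count, while any real template at ≥ ~1% of a deep run clears 20
   reads easily.
6. **Assign** — exact hit against the reference database first; otherwise
   nearest edit distance with `max_distance = 3` and `min_margin = 1`
   between best and second-best species. Several species tied at the
   minimum (identical or near-identical references) yield an *ambiguous*
   call reported under a group label — the shared genus where there is one,
   e.g. `Canis (2 spp.)`. The margin prevents a single-error read of
   species A being called as a species B one difference away.
7. **Report** — per-taxon read counts and fractions over assigned reads;
   unassigned reads reported separately. Matching is against the local
   reference database only: this removes any dependence on remote-database
   versions, and the discriminability analysis is exactly the evidence that
   the local targets suffice.

Per-stage read accounting is emitted and tested: low-quality + unmatched +
trim-failed + collapsed counts equals the input count.

## Simulator

The simulator emulates a pyrosequencing amplicon run on a known mixture;
it is the package's stand-in for instrument data and defines the conditions
under which the pipeline's claims are tested.

* **Composition**: one seeded multinomial draw over weight × bias products.
  Weights are relative template copy numbers (99:1 etc.); the per-species
  bias multiplier (default 1.0) emulates amplification-efficiency
  differences such as the strong (~10–20×) under-recovery of human
  template observed in emulsion-PCR mixtures — a phenomenological stressor,
  not a mechanistic claim.
* **Substitutions**: i.i.d. per base, default 1.0e-3, uniform over the
  three alternatives.
* **Homopolymer indels**: per maximal run of length L ≥ 2, one ±1-base
  event with probability min(1, r·(L−1)), r = 0.004 by default; shorten and
  lengthen are equally likely. Linear-in-L is the standard caricature of
  flow-value noise and reproduces the dominant real artifact — a 5-base
  adenosine stretch read with four bases. With these defaults a
  homopolymer-rich ~73-nt target (human, containing AAAAA) accrues several
  times the erroneous-read fraction of a run-poor target, matching the
  observed elk/human contrast in error rates (0.0014 vs 0.0047 per base).
* **Decoration**: barcode + forward primer + mutated target +
  reverse-complemented reverse primer; degenerate primer positions are
  realized to the majority variant (R → A). Qualities are a constant Q30
  string — the pipeline's filter is mean-based, so a richer quality model
  would add nothing the pipeline could see. Errors are applied to the
  target region only.

Output is byte-identical for identical (config, seed). The truth table
(read id → species, substitution and indel counts) matches the
composition draw exactly.

What the simulator does **not** model: flowgram-level noise, chimeras,
length-dependent quality decay, PCR-cycle error compounding. Pipeline
results on simulated data therefore demonstrate the *logic* of filtering,
collapsing and assignment under a realistic error magnitude, not the full
error structure of any particular instrument.

## Error statistics

`error_rate_simple(n_reads, n_identical, mean_length)` =
(erroneous reads)/(reads × mean length) — the quick run-QC arithmetic that
charges one error per erroneous read. On the package's reference worked
examples it gives 0.0014 errors/base (11,683 reads, 1,211 erroneous, mean
length 72) and 0.0047 errors/base (5,268 reads, 66% identical, 73-nt
target). `error_rate_edit` is the exact alternative — Σ(count × edit
distance) / Σ(count × length) — and is the rigorous default in reports;
the two agree exactly iff every erroneous read has edit distance 1.

Variant classification is template-relative: an inserted/deleted base is a
*homopolymer* indel iff it matches an adjacent reference base inside a run
of length ≥ 2 (the artifact is defined by the template's runs, not the
variant's). The homopolymer share is the fraction of erroneous reads whose
edits are exclusively homopolymer indels; it is undefined (None) when no
read is erroneous. Classification walks the optimal edlib global
alignment; where the optimum is degenerate (gap placement within a run) any
placement yields the same classification because the run membership is what
is tested.

## Problem sizes and determinism

The bundled 15-species panel drives all desk-scale analyses. Detection
experiments use 20,000-read runs (a realistic bench-top amplicon depth,
matching the deeper runs in the mixture study this assay derives from) with
100 seeded replicates per condition, and 1,500-read runs to demonstrate
loss of the 1% component below depth — at 1,500 reads the minor species
expects ~15 reads, under the 20-read filter, so detection requires an
upward fluctuation and usually fails. All stochastic tests are seeded;
`scripts/acceptance.py` derives every stream from its `--seed` argument via
`numpy.random.SeedSequence`.

## Known limitations

* Single primer pair per database; no primer thermodynamics.
* No chimera detection and no abundance-bias correction — bias exists only
  as a simulator stressor.
* Intraspecific variation and heteroplasmy are not adjudicated: a true
  low-count variant and an error variant below the read-count filter are
  indistinguishable by design.
* Species whose reference targets are identical are reported as a group,
  never resolved further.
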