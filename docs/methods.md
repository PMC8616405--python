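# Methods

This note documents the models, conventions and numerical choices behind the
package, the assumptions of the synthetic-data generator, and the known
limitations.

## ORF model and coordinates

All coordinates are 0-based half-open internally; genome-browser style
1-based inclusive coordinates appear only at I/O boundaries. An ORF is an
ATG-initiated run of sense codons ending in a stop codon, scanned in all six
frames. Per (strand, frame, stop-to-stop segment) exactly one ORF is
reported: the 5′-most ATG leaving ≥ `min_aa` codons before the stop
(`atg_policy="first"`; `"all"` reports every qualifying ATG). The reported
interval includes the terminal stop, so `len(interval) = 3·(aa_length + 1)`.
ORFs running off the locus edge are excluded by default (`require_stop`).
Codons containing N are neither start nor stop and invalidate any candidate
spanning them; the scanner then tries the next ATG in the segment. Antisense
ORF identifiers carry an `as` infix (ORF7 vs ORFas7), numbered by genomic
position per strand.

The scanner operates on genomic sequence only; spliced (transcript-aware)
ORFs and non-ATG starts are out of scope.

## Kozak model

Translation-initiation strength is scored from the 10-mer covering positions
−6…−1, the ATG and +4 (the base after the ATG), read 5′→3′ on the ORF strand
and N-padded at locus edges. The score is the sum of per-position weights,
min–max normalized so the consensus context scores exactly 1 and the
anti-consensus 0; N contributes the position minimum. The shipped PWM
(`data/kozak_pwm.tsv`) is a *Drosophila*-style consensus model
(C A A A A C | ATG | G) — a documented stand-in, since published strength
tables give relative ranks rather than a canonical PWM. Any TSV with columns
`position, A, C, G, T` can replace it.

## Homology, ortholog groups and age

Peptide pairs are aligned with exact local Smith–Waterman (Biopython
`PairwiseAligner`), BLOSUM62, BLAST-style affine gap cost 11 + k·1.
Significance uses the Karlin–Altschul form E = K·m·n·exp(−λS) with the
standard gapped constants (K = 0.041, λ = 0.267) and the two peptide lengths
as effective lengths. In all-by-all grouping, only cross-species pairs
sharing at least one 4-mer are aligned: at E ≤ 10⁻⁵ a hit needs a raw score
(~65+) that is unreachable without a shared exact 4-mer at these peptide
lengths, so the seed prefilter does not change the edge set, only the cost.
Groups are single-linkage connected components of the E ≤ 10⁻⁵ edge graph;
every ORF belongs to exactly one group. A group's minimal evolutionary age
is the largest pairwise divergence time among its member species; singletons
have age 0. The shipped divergence matrix (`data/divergence_my.tsv`) covers
the 11 *Drosophila* assemblies used for BX-C annotation; the exact values are
editable, chosen ultrametric-consistent such that multi-species group ages
fall in {10, 14, 27, 40} My, the values observed in the reference candidate
table.

## dN/dS (NG86)

Pairwise dN/dS uses Nei–Gojobori (1986) counting on a codon alignment
obtained by back-threading a global protein alignment onto the nucleotide
sequences (gaps in whole codons). Synonymous site fractions are enumerated
per codon position; changes creating a stop codon count as nonsynonymous.
For codons differing at k positions, differences are averaged over all k!
single-step pathways, excluding pathways through stop codons unless all are.
Proportions are Jukes–Cantor corrected, d = −¾·ln(1 − 4p/3). Results carry a
caution flag: `dS_too_small` below 0.01 (too little divergence for a stable
ratio), `dS_too_large` above 2 or when the correction diverges (p ≥ ¾).
ω is undefined when dS = 0. The operation requires ≥ 10 ungapped codon pairs
by default (`min_codons`, overridable for toy inputs). In the pipeline, a
surviving ORF's ω is the mean over reliable pairwise comparisons between the
reference ORF and each ortholog-group partner; this replaces maximum-
likelihood estimation over a phylogeny and is adequate for classifying
purifying selection (ω < 1), not for precise branch-wise rates.

## Feature annotations

- **Conservation**: the per-ORF statistic is the arithmetic mean of per-base
  track scores over the ORF interval, ignoring missing bases (NaN if all are
  missing). The mean was chosen because reference tables report continuous
  per-ORF values in (0, 1).
- **Promoter**: among same-strand promoter calls at or 5′ of the ATG, the
  nearest wins (ties broken by higher score). Distances are reported signed
  (negative = upstream) and compared on magnitude.
- **Read support**: `n_reads` counts alignments overlapping the ORF by ≥ 1 bp;
  `breadth_pct` is the percentage of ORF bases with ≥ 1× coverage. Positional
  overlap stands in for the original BLAST-based read assignment.
- **Context**: one category per ORF with priority CDS > UTR > lncRNA >
  intergenic; frame congruence against the host CDS is evaluated modulo 3
  from the phase-adjusted CDS start; orientation is sense/antisense by strand
  comparison. Ties at equal priority go to the larger overlap.
- **PolyA scan**: positions of AATAAA/ATTAAA on the ORF strand within 150 nt
  downstream of the stop. Descriptive only — the cascade deliberately does
  not filter on it, mirroring the original study design.

## ELM scanning and score

Motif classes are regular expressions over the amino-acid alphabet; the
pattern set is first restricted to classes matching at least one Hox protein.
Counts are distinct match start positions, overlapping matches included
(implemented with a lookahead wrapper). The ELM score of ORF *i* is
10⁶ · (Σ_j n_{j,i}/n_{j,all}) / L_i with the denominator population fixed to
the **initial** prediction set, before any filtering; reports round to
integer, computation keeps full precision. The shipped pattern TSV is a
small ELM-style demonstration set; per-ORF counts from a specific ELM
database release are not reproducible without that release, so packaged
reference counts are consumed as data, not recomputed.

## Calibration and cascade

Thresholds for conservation, promoter distance/score and Kozak strength are
the extreme values among reference-flagged rows (candidates matching
previously published altORF peptide sets). The conservation cutoff is
floored (not rounded) to 2 decimals: rounding up could exceed the flagged
minimum itself and silently drop the anchoring rows. Read-support cutoffs
(≥ 5 reads, ≥ 40 % breadth) and the species/age minima (≥ 2 species,
≥ 10 My) are configuration values, as their original calibration used data
outside a single locus. The nine steps run in fixed order; step 9 annotates
survivors with dN/dS and removes nothing. ELM-score bins are <100,
[100, 200] (inclusive bounds, which reproduces the packaged table's 8/19/21
split) and >200.

## Synthetic bundle generator

The generator emulates the data regime the pipeline consumes: a reference
locus with planted ORFs, orthologous loci in four further species, a
conservation track, promoter calls, read alignments, a gene-model stub and a
truth table. Design elements:

- **Neighborhoods**: each plant lives in an insulated cassette
  `[TTAATTAATTAA][pad][Kozak 6-mer][ATG][body][TAA][pad][TTAATTAATTAA]`
  (built in plant-strand orientation, reverse-complemented into the genome
  for − plants). The insulator holds stop codons in all six frames on both
  strands, so no reading frame crosses a cassette boundary. Pads are T-less
  ({A,C,G}), hence free of start/stop codons on both strands; bodies encode
  random peptides over an 18-residue alphabet (no Met/Trp) with codons chosen
  to avoid ATG — and CAT (a reverse-strand ATG) where residue chemistry
  allows — at every offset. Consequently every planted ATG is the 5′-most in
  its segment and the scanner recovers each plant exactly (the generator
  asserts this).
- **Evolution**: i.i.d. per-site substitution with probability
  p = rate·divergence (default 0.002/My over a 0–40 My ladder of five
  species). Inside planted coding regions, amino-acid-changing substitutions
  are accepted with probability ω (default 0.1), stop-creating ones never;
  planted start/stop codons and insulators are invariant. Species outside a
  plant's target set receive a scrambled cassette, making the plant absent
  there. No indels are simulated, so the codon aligner sees gap-free
  orthologs from the generator (gapped paths are exercised by dedicated
  tests).
- **Tracks**: conservation is `level + N(0, 0.02)` over planted ORFs against
  a 0.08 background; promoters are planted at the specified upstream
  distance/score plus low-scoring noise calls in the filler; reads tile
  expressed plants end-to-end (12 fixed-length reads).
- **The default bundle** (`default_config(seed)`): 20 pass-everything plants
  (6 reference-flagged, drawn from the low end of the passing range so they
  pin the calibrated cutoffs below every other passing plant) and 80
  single-fault decoys — 10 Hox fragments, 14 single-species, 14 too-young
  (5 My), 14 unconserved, 14 promoter-faulted (distance 600 nt or score
  0.30), 7 weak-Kozak, 7 unexpressed. Each decoy passes every step except
  its designated one.

What the generator does **not** emulate: realistic mutation spectra, indels
by default, splicing, overlapping genes, read-depth heterogeneity or mapping
noise. Passing the synthetic end-to-end test therefore demonstrates the
correctness of the bookkeeping (feature computation, calibration, step order
and predicates), not the field performance of the thresholds on real
genomes.

## Problem sizes

Default test and acceptance runs use a ~44 kb five-species locus (about 200
reference ORFs), 100 random 1-kb loci for scanner/oracle equivalence, 500
random peptide pairs for aligner/oracle equivalence and 50 replicates of
300-codon pairs for ω recovery — sizes chosen so the whole suite completes
in well under a minute of compute per component while keeping estimator
variance far below the asserted tolerances.

## Known limitations

- BLAST score parity is not promised: E-values use fixed Karlin–Altschul
  constants, adequate for the near-identity orthology regime the cascade
  needs, not for remote-homology search.
- The Hox FASTA and ELM pattern TSV shipped with the package are synthetic or
  demonstration stand-ins (labelled as such); real analyses should supply
  the corresponding curated inputs.
- The pairwise-mean ω is conservative relative to ML estimates on a tree and
  is reported with caution flags rather than confidence intervals.
- Full-scale reproduction of a real locus requires external inputs (genome
  assemblies, conservation tracks, promoter predictions, RNA-seq) supplied
  in the documented formats; the package ships only the calibration table.
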