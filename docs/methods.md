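# Methods

`okamut` analyses the mutational signature of budding-yeast strains
deficient in Okazaki-fragment maturation (loss of the flap endonuclease
Rad27/FEN1). Such strains accumulate short (<300 bp) structural changes
whose sequence context identifies the mechanism: slippage in simple
sequence repeats, duplications/deletions mediated by short direct
repeats, and — the most mechanistically informative class — fold-back
template switching at inverted repeats. This note describes the models,
the numerical choices, and what the synthetic data do and do not show.

## Sequence-context primitives

**Inverted repeats (IRs).** An IR is a pair of arms with the left arm
equal to the reverse complement of the right, separated by a spacer
(the loop of the hairpin the sequence can form). The scanner anchors at
every innermost complementary base pair and extends outward, reporting
one IR per maximal complementary run: a reported IR can be extended
neither outward (flanking bases do not pair) nor inward (the next inner
pair does not pair, or the spacer is minimal). This avoids enumerating
the nested sub-repeats inside every palindrome. Arms never contain N.
The implementation is vectorised per spacer; an exhaustive
triple-enumeration oracle in the test suite checks exact set equality
on random and adversarial sequences.

**Quasi-palindromes.** A quasi-palindrome is an IR whose arms differ by
a small number of mismatches and/or indels ("arm edits"). Arm
comparison uses a banded unit-cost edit distance (band width = the edit
budget) between the left arm and the reverse complement of the right
arm, anchored at the innermost complementary pair and required to end
on an exact match at the arm tips. For each anchor the scanner keeps
the Pareto frontier of (arm length, edits) — spending an edit must
strictly lengthen the arm. Public output drops degenerate reports
(fewer than `arm_len − 2·edits = 1` net matched positions) and
re-descriptions of perfect IRs; the model fitter consumes the full
candidate set because exact-match simulation is its own filter. Random
DNA is rich in weak quasi-palindromes; consumers should treat the
standalone quasi listing as candidate structures, not as evidence of
mechanism.

**Tandem repeats.** A deliberately simple tandem detector (exact
self-match seeding at lag *p*, purity-scored extension across mismatch
gaps, overlap deduplication by purity then span then smallest period)
supplies unit/period/purity to the classifier. It is not a full
probabilistic tandem-repeat finder and does not try to resolve nested
or fuzzy satellite structure beyond what classification needs. The
classifier additionally checks for a *perfect* tract through the event
site by direct pointer expansion, because greedy extension can absorb
adjacent near-repeats and under-report purity.

**Direct-repeat decomposition.** An INDEL of length L is explained as
ABA ↔ ABABA when the inserted/deleted unit matches the adjacent
reference L-mer (a tandem duplication) and a split A+B (len A + len B =
L, both ≥ 1) places a third A copy on the far side. All four
phase/side combinations are tried; the split maximising mean pairwise
identity of the A copies wins, ties preferring longer A, then the
leftmost anchor. Default minimum similarity 0.9. No caps are imposed
below the observed ranges (A up to 21 nt, B up to 91 nt).

## Fold-back template-switch models

Replication stalls; the nascent strand folds back at an IR stem (loop ≥
3 nt, a physical hairpin constraint), transiently copies itself
(appending the reverse complement of the sequence upstream of the
stem's left arm), and realigns to the true template. Four outcomes:

* **correction** — one arm of a quasi-palindrome is rewritten from the
  reverse complement of the other, yielding a perfect IR. With
  mismatch-only edits the length is preserved; indel edits change the
  length, and the delta is booked as palindrome growth (`expansion_len`)
  or shrinkage (`resected_len`) so that the exact identity below holds.
* **expansion** — synthesis resumes exactly at the stall: net insertion
  of the self-copied stretch, palindrome grows outward.
* **expansion_amplified** — the fork realigns *behind* the stall,
  additionally duplicating a reference segment in direct orientation.
* **expansion_resected** — an exonuclease removes nascent bases before
  fold-back; those bases are never re-synthesised.

Every model satisfies, exactly and by construction:

    len(alt) − len(ref) = expansion_len + amplification_len − resected_len

Fitting is exact: candidates are enumerated from the perfect IRs
(expansion family) and quasi-palindromes (correction) of the reference
window on both strands, forward-simulated, and kept only when the
simulated strand equals the observed alternate nucleotide for
nucleotide. Parsimony ranks survivors: fewest template switches, then
smallest self-copy, then smallest resection, then leftmost fold centre;
coordinates are always reported on the top strand and equivalent-output
alternatives are counted in the model notes. Two identifiability
caveats are inherent to exact fitting: (i) the self-copy/realignment
split of an amplified expansion is only defined up to sequence-identical
models, so the reported `self_len` is the smallest that reproduces the
observation; (ii) a length-neutral resected expansion can coincide with
an arm homogenisation, in which case the single-switch correction is
reported. Stems are perfect IRs by default; imperfect stems (which the
data occasionally suggest) are a recognised limitation of the fitter.
Fitting refuses windows above 600 nt — the method targets short events.

## Event handling

Events are extracted per focal strain from per-chromosome multi-strain
alignments as maximal runs of disagreeing columns; runs within 25 bp
(configurable) merge, giving `snp_cluster` (pure substitutions) or
`mixed` (substitutions plus gaps) events. Changes carried by *all*
focal strains, or shared with any control strain (the earlier
subculture samples), are removed as ancestry rather than new mutation.
INDELs are left-aligned maximally (VCF practice) so loci have a
deterministic identity; coordinates are 1-based inclusive, BED masks
0-based half-open. Filtering removes events within 20 kb of chromosome
ends (the paper-style telomere exclusion is a fixed distance because no
precise definition exists), events over Ns, masked intervals, and
events below a 0.9 support fraction when per-strain support is
attached. Recurrent loci are proximity-chained groups (25 bp default)
flagged when an alternate allele occurs in ≥2 strains or ≥2 distinct
alternates occur at one locus. Rates are events per colony per
generation per assayable base pair; one generation ≡ one subculture
(configurable multiplier for cell divisions per subculture).

## Mechanism classification

A deterministic cascade with one arbitration rule:

1. `ssr` if the INDEL is a whole-unit change of a tandem tract of
   period ≤ 6 spanning the site (micro-satellite scale; longer-unit
   events fall through to the direct-repeat test);
2. `direct_repeat` if the ABA ↔ ABABA decomposition succeeds;
3. `palindrome_expansion` / `quasi_palindrome_correction` if a
   fold-back model reproduces the alternate exactly;
4. `other` — the only fallback.

Arbitration: a **perfect** tract keeps the event in `ssr`; imperfect
tract evidence yields to a fitting direct-repeat decomposition (events
in non-perfect simple-repeat regions classify as direct-repeat
duplications). Isolated single SNPs are never tested for fold-back: a
one-edit correction is indistinguishable from a point mutation, and
chance quasi-palindromic contexts would otherwise absorb a large
fraction of unrelated substitutions; only clustered changes carry
usable signal. All thresholds live in `ClassifyParams`.

## Phylogenetic IR-form analysis

For an orthologous locus, each genome's degapped subsequence is
scanned; genomes with a perfect IR are binned by the exact (left arm,
spacer, right arm) string — the "form". The spacer content is part of
the form key, so spacer-only differences count as different forms when
they fall inside the IR footprint; per-genome status strings make such
cases visible. `n_forms` is the number of distinct bins. Multiple
perfect forms at one locus are the evolutionary signature of
quasi-palindrome ↔ palindrome interconversion: point substitutions
rarely walk a locus from one perfect palindrome to a different one.

The null evolves the locus root down the given phylogeny under HKY85
with empirical base frequencies and a transition/transversion ratio
estimated from the alignment (a crude ×2 pairwise count ratio; the
model choice is deliberately minimal and is a config knob), homogeneous
site rates, with **no** template-switching move. The root is the
majority-rule column consensus — cheap, reproducible, and applied
identically to observation and simulation. The empirical p-value is
one-sided with add-one correction, p = (1 + #{replicates ≥ observed}) /
(1 + n). Because the statistic is discrete, p-values are valid but
conservative; calibration tests confirm the type-I rate sits at or just
below nominal on matched synthetic data. Replicates are evolved in one
batched traversal and each distinct leaf sequence is scanned once (all
uniques joined with N-separators longer than the spacer bound, which no
IR can bridge).

Trees must carry branch lengths (the default seven-taxon tree does);
least-squares branch-length estimation for length-free topologies is
not implemented.

## Synthetic data

The generator emulates the structure of a haploid yeast
mutation-accumulation experiment, not its raw reads: a toy reference
(default 4 × 250 kb, GC 0.38) seeded with non-overlapping features —
pure SSR tracts (primitive units 1–4 nt, 6–14 copies), (AB)ᵏA
direct-repeat structures (A 4–12 nt, B 6–30 nt), perfect palindromes
(arms 8–16 nt, loops 3–8 nt) and quasi-palindromes (2–3 arm edits) —
all ≥ 300 bp apart and ≥ 20 kb from chromosome ends. Every planted
feature is verified by the scanners after stamping (collisions with
chance background structure are redrawn), so plant-and-detect identity
holds by construction.

The cohort mimics the two-line subculture design: per line one
subculture-0 sample (identical to the reference), one subculture-5
control carrying the line's shared-branch mutations, and five
subculture-25 strains carrying shared plus private mutations.
Mechanism-specific rates are per feature per generation
(1 − e^(−rate·g) per branch), proportioned so a default cohort echoes
the observed class mix (SSR : direct repeat : template switch ≈
183 : 177 : 21), with an insertion bias of 0.67 and a 10× hotspot
multiplier on a few features so recurrent loci arise across strains.
Alignments are emitted directly from the known events (left-justified
alternate blocks padded with gaps), which reproduces the column
structure a profile aligner would give these simple loci. Limitations:
no sequencing error, no read-level support, no controls' private drift,
no overlapping features, and background SNPs are kept clear of planted
features — so classifier recovery on this cohort measures the decision
logic, not robustness to alignment artefacts or feature interference in
real genomes.

The phylogenetic generator evolves one planted palindrome per gene down
the default seven-taxon tree under HKY (κ = 3); with a positive switch
rate, loci additionally undergo per-branch conversion moves (a
symmetric arm change plus arm re-homogenisation) that create new
perfect forms, with truth labels recording which loci switched.
Substitution-only evolution means per-gene alignments are trivially the
leaf sequences; indel evolution is not modelled.

## Problem sizes in the shipped checks

The test suite and the acceptance script use: 1000 random sequences
(≤ 200 nt) for the scanner/oracle equivalence; 500 planted fold-back
models per type for round-trip recovery; the default 1 Mb cohort
(~450 planted events, ~250 distinct loci) for classifier recovery; and
200 loci × 200 replicates for null calibration — sizes chosen so the
whole battery runs in minutes on one core while keeping Monte-Carlo
error well inside the asserted bands. All randomness flows from
explicit seeds; identical seeds give byte-identical outputs at every
stage.
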