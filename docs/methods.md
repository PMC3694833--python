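# Methods

`nhejseq` analyses deep-sequencing data from a single site-specific chromosomal
double-strand break (DSB) repaired by non-homologous end joining (NHEJ).  A
nuclease such as HO cuts a defined promoter position leaving 4-nucleotide 3′
overhangs; amplicon sequencing across the cut then samples the repair-product
population.  The package enumerates every repair product the two broken ends
can template, assigns each read to one of them, summarises joint frequencies,
and tests two strains for differential joint usage with a negative-binomial
exact test.  This note records the model, its assumptions, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Cut-locus model

A locus is the reference top strand (1-based, inclusive coordinates) plus a
cut geometry `(t, v)`: `t` is the position of the most distal base of the left
end's overhang and `v` the overhang length (HO: `v = 4`).  The left end is
`top[1..t]` with single-stranded `top[t−v+1..t]`; the right end templates
`top[t−v+1..N]` through its bottom-strand overhang, which is the reverse
complement of the left overhang — precise religation therefore restores the
reference exactly.  Because `t` is anchored on the most distal overhang base,
the product algebra below is identical for 3′ and 5′ overhangs and for blunt
cuts (`v = 0`); the polarity flag is descriptive.  The amplicon window and
read layout (6-base inline index, optional primer offset, 100 bp reads by
default) determine which part of each product a forward read observes; only
forward reads cross the cut in the assay this models, so reverse reads are
never consulted.

## Joint space and nomenclature

Each candidate product is a descriptor `(D, M, L, R, I)`: net base pairs
gained/lost (`D`), microhomologous bases at the junction (`M`), bases deleted
from the left and right ends measured from the most distal overhang base
(`L`, `R`), and 0–2 non-templated inserted bases read from the top strand
(`I`).  These obey `D = v − L − R − M + |I|`, and the repaired top strand is

    product = top[1 .. t−L] + I + top[t−v+R+M+1 .. N]

`M > 0` requires the left end's retained terminal `M` bases to equal the `M`
bases the right end would otherwise template (`top[t−L−M+1..t−L] ==
top[t−v+R+1..t−v+R+M]`): those bases anneal and appear once.  The same rule
covers partially annealed overhangs filled in by polymerase — the classic
"+CA"-type duplications, which require the overhang's terminal `M` bases to
equal its first `M` bases — and the fully blunt fill-in joint (`M = 0`,
`D = +v`).  Insertions are modelled only at `M = 0` junctions; allowing both
at once creates unresolvable redundancy without adding distinguishable
products.

Distinct descriptors can yield the same product string (a one-base
microhomology deletion is also a plain deletion shifted by one), so
enumeration deduplicates by product and keeps a canonical descriptor:
maximal `M`, then minimal `|I|`, then minimal `L` (then `R` and the insertion
string purely to fix exact ties).  Templated explanations thus beat
non-templated ones and identifiers are deterministic.  Identifiers render as
`D{±n|0}_M{m}_L{l}_R{r}[_I{seq}]`, with the religation product spelled
`precise`; the rendering is this package's convention, the field semantics are
the standard D/M/L/R/I nomenclature.  Simple joints also get the classical
short alias: `+<dup>` for pure fill-in duplications and `-<deleted>` for pure
deletions whose deleted string is unambiguous.

Default enumeration bounds are `L, R ≤ 25`, `M ≤ 10`, insertions over `ACGT`
up to 2 nt, additionally bounded by the requirement that the read cover the
junction plus three flanking bases; limits that push any junction outside the
read raise an error naming the offending joint.  The chemistry itself imposes
no deletion bound — these defaults simply cover everything a 100 bp read can
identify.  (Tests and simulations use `L, R ≤ 6`, `M ≤ 4`, which already give
~650 distinct products on a 200 bp locus.)

## Read classification

Reads are processed in three stages mirroring the experimental logic:

1. **Contaminant removal.**  Spiked control-library reads (PhiX-type) are
   removed first by a shared-k-mer filter: a read is contaminant when at least
   half of its 21-mers occur in the contaminant reference (both strands).
   This replaces an external aligner for a task where the contaminant is
   unrelated to the locus; the filter is pluggable should an aligner-based
   one be preferred.
2. **Demultiplexing.**  The leading 6 bases are matched exactly against the
   sample-index table; no mismatch tolerance is applied (6-mers are short, and
   a conservative drop beats a sample swap).  Tables whose indexes are closer
   than Hamming distance 2 trigger a warning.
3. **Joint assignment.**  Every joint, including every insertion and deletion
   variant, is a full-length read template, so classification is pure Hamming
   comparison over the non-index bases — no gapped alignment.  A read is
   assigned to the unique template with the lowest distance within the
   1-mismatch tolerance; a tie for best is `ambiguous`; no template within
   tolerance is `unmatched`.  Best-hit rather than any-hit resolution is
   essential: an exhaustive joint space always contains deletion-plus-
   insertion joints whose product is one substitution from the precise
   sequence, so an any-hit rule would call every single read ambiguous.
   Reads shorter than the nominal length are compared over their length but
   must still cover the junction ±3 bases.  Base qualities are ignored (an
   optional mean-quality filter exists but is off by default).

Read conservation is checked on every run: joint counts plus
ambiguous/unmatched/contaminant plus index-unassigned and truncated reads sum
exactly to the reads processed.

**Known cross-talk.**  Because some template pairs differ by one base, a
single sequencing error can convert a read of joint A into an exact match of
joint B.  For small-fraction joints this is negligible (per neighbour,
probability `e/3·(1−e)^(ℓ−1)` per read, ≈0.1% at `e = 0.002`), but the
precise joint has ~25 such neighbours, giving it a systematic recovery
deficit of roughly 1.5% (relative) at a 0.2% error rate and ~3% at 1%.  This
is a property of 1-mismatch-tolerant exhaustive-template classification, not
of this implementation; it is far below the resolution of any strain-level
conclusion but is why the synthetic benchmarks quote recovered-versus-planted
tolerances of ±2 points on the precise fraction.

## Quantification

Joint fractions divide each joint count by the sample's total over joint rows
only; ambiguous/unmatched/contaminant are reported as fractions of all reads
but never enter the joint denominator (a flag on the CLI level could fold
them in; excluded is the default and the recommended convention).  Joints are
categorised as `precise`, `major_imprecise` (fraction ≥ 0.1% in at least one
sample — inclusive threshold) or `other`.

Colony-based assays are summarised by exact integer arithmetic: the precise
fraction of survivors is `round_half_up(100·recleavable/tested)`, and
marker-loss colonies are split into imprecise-joining vs large-deletion
classes by extrapolating the junction-PCR rate from the tested subsample:
`imprecise% = round(100·(PCR⁺/PCRtested)·(marker-loss/total))`, large
deletions its PCR-negative complement, `other%` the colonies that kept the
marker.  Rounding is half-up throughout; the three percentages sum to 100
within 1 point for any input.

## Differential joint testing

Raw counts go in as-is.  Per-sample size factors use the median-of-ratios
rule over joints with positive counts in every sample.  Per-joint dispersion
is method-of-moments on normalised counts within each condition,
`α = (s² − μ)/μ²` averaged across conditions and clamped at zero; with only
two replicates per condition these estimates are very noisy, so by default
they are blended with a parametric mean-dispersion trend `α(μ) = a₁ + a₀/μ`
by taking the maximum of the fitted and per-joint values — the conservative
sharing rule of classic count-based differential testing.  The trend is fit
by least squares on the *unclamped* moment estimates of joints with
normalised mean ≥ 5: the moment estimator is unbiased around the true trend,
so keeping its negative excursions and excluding the pure-noise estimates of
near-zero-count joints keeps the fitted trend centred (fitting only the
clamped positive values would inflate it and, through the max rule, destroy
power at high counts).  `share_mode="per_joint"` (CLI `--per-joint-only`)
disables sharing.  A numerical floor of 1e−8 keeps the NB parameterisation
away from the Poisson singularity; at `α = 0` the margins are evaluated as
Poisson outright.

The test itself is the conditional exact NB test: given a joint's total
`k = k_A + k_B`, each condition's margin is NB with mean proportional to its
summed size factors and variance `μ + αμ²`; the p-value is the summed
probability of all splits at most as likely as the observed one, normalised
over all `k+1` splits (computed in log space with a 1e−9 tie tolerance, so
p ∈ (0, 1] and the balanced split yields exactly 1).  In the `α → 0` limit
this reduces to the exact binomial test (verified to 1e−6 in the suite).
Multiplicity is controlled by Bonferroni over the number of joints tested,
with significance declared at adjusted p < 0.005; joints are flagged
`is_major` at the 0.1% fraction threshold so the analysis can be restricted
to well-counted joints.  With only two replicates per condition the max-rule
leaves per-joint power at roughly 0.9 even for 8-fold changes at high counts,
which is why the power benchmark is defined on a fixed simulation design.

## Synthetic data

The generator emulates the statistical structure of the recleavage
experiment and nothing more: a fixed amplicon with a 4-nt 3′-overhang cut, a
6-base inline index, a dominant precise class plus a long-tailed imprecise
profile, i.i.d. per-base substitution error, and a contaminant spike-in drawn
as random windows of a contaminant reference (tests use a seeded 5 kb
synthetic stand-in, not the real PhiX genome).  Built-in spectra fix the
study conditions: ≥99.5% precise before induction, 60% precise / 40%
imprecise after 24 h of recleavage in repair-proficient strains, 97% precise
for the ligase-deletion strain.  The imprecise mass is spread by a symmetric
Dirichlet (concentration 0.3) over a seeded subset of 40 enumerated joints,
giving the few-major-joints, long-tail shape observed in real spectra; the
catalytic-mutant spectrum shares the wild-type base profile but multiplies
twelve mid-ranked joints alternately by 6 and 1/6 (mid-ranked so
renormalisation leaves realised ratios near the planted fold), giving the
differential stage a known answer key with changes in both directions.
Per-sample joint counts are exact multinomial draws returned as the ground
truth; the contaminant count is `round(fraction × reads)` exactly.  Count
tables for the differential benchmarks are drawn directly from NB
distributions with stated means and dispersion.  Everything is deterministic
given the seed (NumPy `default_rng` integer seeding).

What the passing benchmarks show: error-free spectra are recovered exactly;
at 1% error the planted imprecise fractions are recovered within 3 binomial
standard errors in ≥95% of seeded replicates; the NB test controls
family-wise error on null data and detects planted 8-fold changes with
correct sign.  What they do not show: robustness to indel sequencing errors
(substitution-only model — real indel errors would be misread as insertion
or deletion joints, a documented limitation shared with the mismatch-only
classifier), PCR amplification bias, chimeric reads, quality-score
pathologies, or any biology of repair kinetics (re-cleavage cycles,
resection) beyond the planted end-point fractions.

## Problem sizes used in the checks

The bundled benchmarks run on a 200 bp locus (~650 joints after
deduplication), 8 samples × 20 000 reads for the study emulation, 100 × 1 200
reads for the error-recovery property, and 100 seeded null datasets of 500
joints at 2+2 replicates for the type-I check — sizes chosen so the full
suite exercises every stage at meaningful depth while remaining quick to run
on a laptop.

## Known limitations

* Insertions are not modelled at microhomology junctions, and templated
  (locally copied) insertions are not distinguished from non-templated ones.
* Large resection-mediated deletions extending past the read window are out
  of scope — such events are invisible to junction-spanning amplicon reads.
* The contaminant filter is k-mer containment, not alignment; highly
  locus-similar contaminants would need the pluggable aligner-based filter.
* The dispersion model is the classic two-condition exact-test workflow; no
  GLM, shrunken fold changes, or multi-factor designs.
* Identifier rendering (`D+2_M2_L0_R0` etc.) is a package convention; the
  field semantics, not the exact strings, are the interchange contract.
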