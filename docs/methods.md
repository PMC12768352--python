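# Methods

## The measurement problem

A long dsRNA trigger against a known transcript (the "target", e.g. a
720-nt eGFP CDS) is injected into embryos; small RNA libraries are then
sequenced. The pipeline answers, per library and per replicate group:
how much target-derived siRNA is there (on a scale comparable across
libraries), where on the target do the reads fall and on which strand, what
is their length spectrum and positional nucleotide composition, are their
5′ ends periodically spaced (phased dicing), and is there evidence of
secondary-siRNA amplification.

## Assignment model

Reads are collapsed to unique sequences with multiplicities and filtered to
18–30 nt (both bounds inclusive; shorter fragments are dominated by
degradation, longer ones are outside the small-RNA size selection).
Matching is exact — zero mismatches, both strands for double-stranded
references — with a fixed precedence:

1. **spike-in** (forward strand; synthetic single-stranded oligos),
2. **mature miRNA** (forward strand; a read may extend up to 2 nt past the
   mature 3′ end, those overhang bases being unconstrained, a stand-in for
   quantifier-style windows around annotated matures),
3. **genome proxy** (both strands),
4. **target** (both strands; all loci recorded with strand and 0-based
   start),
5. unassigned.

A read is tested against a compartment only when every earlier compartment
rejected it. Placing the genome before the target implements genome
subtraction: endogenous reads can never inflate the target signal.
Spike-ins and miRNAs precede the genome so that synthetic oligos and
annotated guides are not absorbed by genomic matches; the order is a
function argument.

Exact matching instead of a short-read aligner is a deliberate choice: the
scientific claims rest on perfectly matching reads, desk-scale references
(a transcript, not a genome) need no index, and exactness lets every test
compare against a brute-force scan. Reads matching the target on both
strands (reverse-complement palindromes or two-locus sequences on opposite
strands) are counted once, flagged ambiguous, and excluded from
strand-resolved outputs; multi-locus reads contribute count/loci per locus
to coverage and are excluded from phasing.

## Normalization

* **Spike-in factor** = arithmetic mean of the four spike-in counts (the
  mean rather than the sum; the two differ by a constant ×4 and change no
  comparison). `spikein_normalized = raw / factor`. Valid whenever
  libraries share the same molar spike-in input. A spike-in with zero reads
  is an error, not a silent NaN.
* **RPM** = raw × 10⁶ / denominator. The denominator is a genuine free
  choice; default `mapped_total` (genome + target reads, spike-ins and
  unassigned excluded — a depth measure of the biological sample), with
  `filtered_total` selectable; the choice is echoed in all outputs.
* Replicate summaries emit mean, standard deviation and standard error;
  different figures conventionally use either spread measure.

## Phasing

Unique hits (distinct sequences, single target locus, 20–22 nt,
multiplicity collapsed to 1 — so each siRNA *species* counts once) are
reduced to registers: the 5′ position modulo m ∈ {20, 21}, measured on each
strand's own 5′→3′ axis (`start` for +, `target_length − start − length`
for −), because a processive Dicer steps along each strand from that
strand's 5′ end. Per strand and pooled, the register fractions, the maximal
register fraction, and a chi-square goodness-of-fit against uniformity over
the m registers are reported. The verdict "phased" requires both p < 10⁻³
and max fraction > 2/m (both thresholds are arguments): a tiny p-value
alone can reflect mild non-uniformity at a large species count, and a large
register fraction alone can be a small-sample artifact.

**Calibration caveat.** Because species are weighted equally, the register
counts of a *saturated* library (most possible species observed at least
once) are Bernoulli-underdispersed relative to the multinomial the
chi-square assumes, making the test conservative — in deep uniform
simulations the null rejection rate falls to zero. Null-calibration runs in
the test-suite therefore use sparse sampling (library depth 2 000, ~280
unique species out of ~4 200 equally likely ones), where inclusion is
near-independent and the nominal α is recovered. On real data the same
caveat applies: a non-significant chi-square in a deeply sequenced library
is expected even under mild periodicity, while the max-register fraction
remains interpretable.

## Secondary-siRNA screens

All screens return an effect size, a test with p-value, and a verdict;
any group with fewer than two replicates yields `underpowered`.

* **upstream**: per replicate, the fraction of target-mapped read mass
  whose match lies entirely within [0, interval_start), i.e. upstream of a
  partial dsRNA trigger. Being a within-library ratio, spike-in factors
  cancel. Verdict `signal` needs the mean fraction above τ = 0.01 *and* a
  one-sided one-sample t-test against τ to reject at 0.05. The τ absorbs
  chance multi-locus artifacts; visually absent upstream signal corresponds
  to a fraction of exactly zero in simulation.
* **rpph**: one-way ANOVA over treatment groups of spike-in-normalized
  target counts with Tukey HSD pairwise contrasts (Tukey–Kramer for
  unbalanced designs); effect = treated/mock ratio of group means; verdict
  `signal` needs treated > mock with the Tukey-adjusted contrast p < 0.05.
  Although treated and untreated aliquots come from the same RNA, the
  group-level ANOVA is the default analysis; a paired t-test is available
  by flag.
* **size_shift**: effect = treated − mock difference in the 22-nt fraction
  (22 nt being the expected secondary-siRNA mode), tested across replicates
  by a two-sample t-test, plus the Jensen–Shannon divergence of the pooled
  length spectra in natural log (disjoint supports give ln 2 ≈ 0.693);
  `signal` needs a positive significant difference and JSD > 0.01.
* **loading**: in RISC-enriched (AGO-IP/TraPR) libraries, per-replicate RPM
  of target reads versus RPM of the miRNA compartment after the ≥2-reads
  guide filter; effect = ratio of means, tested by a two-tailed paired
  t-test; `signal` needs ratio > 1 with p < 0.05.

## Companion statistics

* **ΔΔCt**: ΔCt = Ct_target − Ct_reference per sample; ΔΔCt against the
  *control-group mean* ΔCt (group-mean convention rather than per-pair
  matching — fold changes are reported at group level with n = 3);
  fold = 2^−ΔΔCt; percent knockdown = (1 − mean fold) × 100. Group tests
  are t-tests on ΔCt values; a one-tailed test requires the caller to
  declare the direction — it is never inferred from the data.
* **Bands**: per membrane, every intensity is divided by that membrane's
  darkest band (removing exposure differences), then each protein by the
  lane's normalized GAPDH; fold changes against the control-group mean.
  Both normalizations are scale-free, so per-membrane multiplicative
  exposure changes cancel exactly. When no test is forced, Shapiro–Wilk at
  α = 0.05 chooses t versus Mann–Whitney, and the choice is reported.
* **Fluorescence**: per embryo, background is subtracted (clamped at zero
  with a warning — negative net intensity indicates a segmentation
  problem); per image/replicate, the mean over its 20–30 embryos; groups
  compared by a two-tailed t-test on replicate means.
* **miRNA totals**: a guide is retained iff it reaches ≥ 2 reads in at
  least one replicate; totals per replicate are sums over retained guides,
  with a spike-in-normalized variant.
* BH-FDR is applied over the family of pairwise Wilcoxon tests following a
  Kruskal–Wallis omnibus.

## The simulator

What it emulates, and the defaults (all `SimConfig` fields):

| parameter | default | meaning |
|---|---|---|
| `target_sequence` | 720-nt synthetic | the transgene CDS |
| `injected_interval` | [0, 720) | dsRNA trigger span; [360, 720) for the half-trigger design |
| `length_distribution` | modes 0.30/0.30 at 20/21 nt | Dicer product lengths |
| `hotspot_concentration` | 0.3 | gamma shape of per-position initiation weights; small ⇒ strong hotspots |
| `strand_bias_concentration` | 0.5 | beta concentration of per-locus sense probability; < 1 ⇒ strand-committed loci |
| `secondary_fraction` | 0 | share of target molecules that are secondary siRNAs |
| `secondary_length_shift` | mode 0.5 at 22 nt | secondary (RdRp) product lengths |
| `secondary_upstream_only` | True | secondary 5′ ends upstream of the trigger, antisense |
| `ppp_fraction_secondary` | 1.0 | secondary molecules carrying 5′-triphosphate |
| `target_fraction` | 0.20 | target-derived share of the pool |
| `spikein_fraction` | 0.02 | equimolar share of the four spike-ins (fixed molar input) |
| `noise_fraction` | 0.05 | decoy degradation fragments, 15–30 nt |
| `depth` | 100 000 | reads per library |

Two seeds separate biology from sequencing: `biology_seed` draws the
hotspot weights and strand preferences *once*, so replicates sharing it
share coverage structure — the mechanism behind the recurring per-position
pattern across biological replicates — while `sampling_seed` drives only
the multinomial read draw. Protocol capture masks model library chemistry:
`standard` sees only 5′-monophosphate, `rpph` additionally 5′-triphosphate,
`pandora` additionally modified species. In processive mode, dicing starts
every `processive_step` (21) nt from the interval start with all products
of exactly that length, producing fully phased registers; with the
half-interval [360, 720) on a 720-nt target, sense and antisense registers
coincide (both ≡ 3 mod 21), so pooled phasing detects the signal cleanly.

Noise fragments are drawn from decoy contigs (which also serve as the
genome proxy) generated under a 15-mer disjointness guarantee against the
target (both strands), the miRNAs and the spike-ins — so a noise read can
*never* be assigned to the target, which isolates the pipeline's
specificity claims from chance matches. Default spike-ins are synthetic
seeded 22-mers carrying the conventional names of the wet-lab spike-in mix
(lin-4-5p, miR-125a-5p, miR-148a-3p, miR-659-5p).

What the simulator does **not** model: PCR duplication, adapter
read-through, sequencing error, quality-score realism, partial ("trimmed")
siRNA ends, and modification chemistry beyond the three capture classes.
Passing tests therefore demonstrate correctness of the quantification and
screening logic under idealized reads; they do not certify behaviour on
error-containing or bias-containing real libraries, where exact matching
will drop erroneous reads rather than rescue them.

## Problem sizes and numerical choices

Test-suite and acceptance-script runs use: assignment-fidelity checks at
depth 10⁵ × 3 replicates; upstream-screen power at depth 10⁵ over 50
simulated experiments and specificity at 5×10⁴ over 100; RppH-contrast
null calibration over 200 experiments at depth 2×10⁴; phasing null
calibration over 200 draws at depth 2×10³ (sparse regime, see above).
Monte-Carlo error rates are judged against the exact central 95% binomial
band at the nominal α. Operating-characteristic loops tally compartment
counts from the simulator truth tables, which the assignment-fidelity
tests prove identical to running the matcher.

Degenerate inputs: empty phasing input yields a flagged profile rather
than an exception; a zero-count spike-in, an empty post-capture pool, an
all-zero membrane, a missing loading-control lane and an upstream test
with no upstream region are errors; ties in modal-length reporting are
handled by the 90%-of-peak plateau rule (an exact tie between two equally
likely modal lengths has probability ~0 in any finite sample).

## Known limitations

* Exact matching discards reads with sequencing errors; on real data the
  absolute counts are therefore conservative, and comparisons remain valid
  only when error rates are comparable across libraries.
* The miRNA 3′-overhang window checks only bases within the mature
  sequence; true templated extensions beyond the annotated mature are
  indistinguishable from untemplated additions.
* The chi-square phasing test is conservative on saturated libraries (see
  calibration caveat); the max-register fraction should be read alongside
  it.
* Verdict thresholds (τ = 0.01 upstream, JSD > 0.01, p < 10⁻³ and > 2/m
  for phasing) are explicit knobs: the field has no agreed quantitative
  criterion separating "no secondary siRNAs" from trace production, so the
  defaults encode "visibly absent", and sensitivity to them should be
  reported when the calls are borderline.
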