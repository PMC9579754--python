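# Methods

This note documents the models, conventions and design choices behind
`duoscan`, in the spirit of a methods appendix: what is computed, under
what assumptions, and why the open choices were made the way they were.

## Marker catalogue and frequencies

A marker SNP is a site where one founder strain is homozygous reference
(`0/0`) and the other homozygous alternate (`1/1`), with the call
confirmed by the strain's alternate-allele frequency estimate (< 0.05 for
`0/0`, > 0.95 for `1/1`). The catalogue records, per marker, the
chromosome, arm, 1-based position, and which nucleotide each founder
carries. Sites with residual heterozygosity are whatever the upstream
genotyper called them; the catalogue builder takes genotypes as given.

Frequencies come from PoPoolation2 `sync` files (tab-separated
`A:T:C:G:N:del` counts per sample). Conventions:

* coverage = A+T+C+G; `N` and deletion counts are excluded;
* the focal-allele frequency uses only the two parental alleles,
  `focal/(focal+other)`; reads supporting a third allele are ignored
  (biallelic contract) and tallied per sample;
* zero informative coverage makes a marker *missing* (NaN) — never 0;
* positions are 1-based everywhere, matching the format;
* only markers measured in every sample of both temperature regimes are
  analysed (set intersection across all six samples).

Because mean coverage differs strongly between regimes (≈9–12× versus
≈107–133×), the high-coverage samples are down-sampled: per marker a new
coverage c\* ~ Poisson(12) is drawn and the focal count redrawn as
Binomial(c\*, f̂). This equalises the Pool-Seq sampling noise between
regimes; it is unbiased for the frequency. Per-sample random streams
derive from one master seed (`SeedSequence(seed).spawn`, column order).

## Windows

Windows contain exactly *w* consecutive markers (default 250). The arms
of a chromosome are concatenated (2L then 2R, 3L then 3R) before
windowing — the only scheme consistent with the published window totals —
so a window may span the centromere. Each chromosome contributes
⌊n/w⌋ complete windows; the trailing partial window is dropped (a flag
retains it, marked partial, for diagnostics). Chromosome 4 is excluded
by default (72 markers in the fly catalogue). With the published per-arm
retained counts this yields 8021/1603/801 windows on the autosomes and
1275/255/127 on the X for w = 50/250/500 — a bookkeeping identity the
test suite checks.

Per replicate, the window frequency is the unweighted mean over its
available markers (a window is discarded only if some sample has no
available marker at all). AFC = window frequency − p₀ with p₀ = 0.3; the
replicate-mean AFC is reported with s.e. = sd/√R and a 95% CI of
±1.96 s.e. Window centres are midpoints of the first and last member
marker on the concatenated-arm coordinate.

## Forward simulator

The neutral null and the synthetic experiments use the same
individual-based Wright–Fisher simulator:

* N diploids per generation (default 1500 — the census of 300 adults ×
  5 bottles; no bottle substructure is modelled);
* founders are fully homozygous; round(N·p_geno) focal individuals
  (p_geno = 0.3), sexes alternating within each founder class;
* each offspring draws a mother and father with probability proportional
  to fitness (uniform under neutrality), sex Bernoulli(1/2);
* female gametes recombine with Poisson(genetic length) crossovers placed
  by inverse-CDF on the cumulative genetic map (no interference); males
  are achiasmatic (whole-copy transmission), as in *Drosophila*;
* the X is explicitly sexed: two copies in females, one in males, sons
  inherit the maternal X; X frequencies count copies (2 per female,
  1 per male);
* genomes are founder-ancestry mosaics (breakpoint lists), so marker
  frequencies are read off segment ancestry exactly; there is no
  mutation or migration (markers are fixed founder differences).

Selection targets carry per-regime coefficients (s18, s29) and a
dominance h; genotype fitnesses are 1, 1+hs, 1+s (hemizygous X males:
1, 1+s), multiplicative across targets.

Single-marker drift matches the closed form
p₀q₀(1 − (1 − 1/2N)^t) — at N = 1500, t = 20 the acceptance suite
verifies the variance within 15% over 600 runs. Randomness is fully
deterministic: replicate streams come from
`SeedSequence(master, spawn_key=(1, temperature_index, replicate))` for
experiments and `(2, run, replicate)` for null runs.

The null distribution pools simulated replicate-mean window AFCs per
chromosome across all runs *and* windows. A per-window-only null (100
values, minimum p = 0.01) could not support BH correction at the FDR
levels used over hundreds of windows; pooling gives a resolution of
1/(100 × windows per chromosome). Null runs are frequency-level: no
Pool-Seq read sampling is added, since at windowed scale the sequencing
noise variance (<10⁻⁴) is an order of magnitude below drift variance
(~1.4 × 10⁻³).

## Tests and classification

The empirical p-value of a window is direction-conditional: for positive
observed AFC, the fraction of pooled null values strictly greater; for
negative, strictly smaller; an exact zero maps to p = 1. No pseudocount
is added, so p = 0 is legal. Note a structural property inherited from
this definition: under neutrality these p-values are approximately
uniform on (0, 0.5), so the subsequent BH correction (applied per
chromosome, per regime) is anti-conservative by roughly a factor two,
and chromosome-coherent drift (all windows of a chromosome share their
early-generation trajectories) can push many windows across the step-up
threshold together. This is a property of the method being implemented,
not a defect of the implementation; the calibration checks below
quantify its practical effect.

The per-window linear model AFC ~ temperature (18°C reference) is
computed directly as the pooled-variance two-sample t-test with
2(R−1) = 4 degrees of freedom, to which OLS with a two-level factor is
mathematically identical (the test suite cross-checks against
`statsmodels` OLS to 10⁻¹⁰). Zero pooled variance yields p = 1 when the
contrast is zero, p = 0 otherwise. Its p-values are BH-adjusted per
chromosome over the non-neutral windows only (significant at either
regime).

Classification at an FDR threshold q (default 10%, also run at 5%/15%):

| sig18 | sig29 | sigLM | direction | label |
|---|---|---|---|---|
| no | no | — | — | drift_only |
| yes | no | — | — | change_18C_only |
| no | yes | — | — | change_29C_only |
| yes | yes | no | — | no_temperature_effect |
| yes | yes | yes | same sign | different_magnitude |
| yes | yes | yes | opposite | different_direction |

Direction is taken from the signs of the two observed replicate-mean
AFCs, not from the sign pair of the model coefficients: the literal
coefficient-sign rule would label a same-direction-but-smaller response
(e.g. +0.2 at 18°C, +0.1 at 29°C, contrast −0.1) as "different
direction", which contradicts its own definition. Windows significant at
both regimes with opposite AFC signs but a non-significant contrast fall
into no_temperature_effect (the only remaining branch); such windows are
rare edge cases. Class fractions are summarised per chromosome, with the
genome-wide row the *unweighted* mean over chromosomes (a
window-weighted variant is available behind a flag), plus the share of
different-magnitude windows whose |AFC| is larger at 29°C.

Window-series autocorrelation (per chromosome and replicate, on
frequency series; a pooled-replicate variant behind a flag) uses the
standard biased sample ACF; the first lag below 1.96/√n is converted to
base pairs with the mean spacing of window centres on that chromosome.

## Synthetic experiments

The generator emulates the real experiment's structure: two homozygous
founders, 2,000 markers per arm placed uniformly at random, three
replicates per regime evolved 20 generations from a 0.3/0.7 founder mix
of 1500 flies, and Pool-Seq counts with the study's asymmetric
per-replicate coverages (12/11/9× and 123/107/133×). The karyotype is
five linkage groups (four two-armed autosomes A–D plus X) with fly-like
female map rates (2.4 cM/Mb autosomes, 2.9 cM/Mb X).

Two scale choices deserve explanation:

**Arm length (70 Mb default).** The real catalogue has a marker every
~0.3 kb and 250-SNP windows spanning ~0.1 cM, so neighbouring windows are
almost perfectly correlated — which is why, in the real data, almost no
window looks neutral once any chromosome drifts coherently. At desk
scale the marker density is ~100× lower; stretching each arm to ~170 cM
makes the ~40 windows per chromosome quasi-independent, so the FDR
machinery can actually be calibrated and planted signatures attributed
to their own windows. The dense-linkage regime (window-to-window
autocorrelation near 1) is still reproduced by the autocorrelation tests
with a compressed map.

**Balanced planting.** At generation 0 every locus is in complete LD
with every other, so any net fitness aggregate — per chromosome
(within-chromosome LD persists for many generations) or genome-wide
(inter-chromosome LD halves per generation; multiplicative fitness also
creates F1 heterosis whenever Σln(1+hs) ≠ 0) — drives a correlated
response that swamps planted signatures. The default layout therefore
keeps Σln(1+s) and Σln(1+hs) near zero per chromosome at both regimes:

* single-regime classes (chromosomes A and C) and no_temperature_effect
  (X) plant near-mirrored +/− targets at |s| = 0.3 (ln 1.3 ≈ −ln 0.7 ×
  3/4, four positive and three negative targets; h = 0.5663 on the
  negatives cancels the heterozygote sum);
* different_direction (D) plants mirrored orientations with h = 1, which
  self-balances each pair;
* different_magnitude (B) is necessarily all-positive — a negative
  variant saturates at the frequency floor, where doubling the
  coefficient changes nothing and the contrast vanishes — so its
  aggregate is absorbed by 25 weak "laboratory adaptation" background
  loci spread over B (ungraded, labelled `background` in the truth
  table). Their smooth negative field also keeps the magnitude windows
  away from the ceiling, preserving the contrast. The coefficients
  (−0.058 at 18°C, −0.111 at 29°C, h = 0.565) solve the homozygote and
  heterozygote balance; the 29°C magnitude coefficient is stretched to
  0.80 (rather than double 0.35) because pilot simulations showed the
  contrast detectable in too few windows at exactly 2×.

**Recovery is validated per class** (`recovery_study`): each class is
planted in its own otherwise-neutral genome, one experiment per seed,
and recovery is pooled over five seeds; an all-neutral genome per seed
provides the drift-only calibration and its simulated null is shared by
that seed's class experiments (marker placement and coverage draws
depend only on the seed, so the retained windows are identical). A
genome carrying all five signatures at once is deliberately *not* used
for calibration: pilot runs showed that the combined selection load
inflates drift variance ~1.5–2× beyond the neutral null — the situation
of the real experiment, where only ~1% of windows look neutral — making
calibrated recovery impossible by construction. The full five-class
genome remains the default configuration for demonstrations and
pipeline tests.

What passing these checks shows — and what it does not: the synthetic
data exercise the entire statistical pipeline under the study's census,
duration, replication and coverage, but they do not emulate read-mapping
artefacts (mapping or reference bias, indel noise), uneven marker
spacing along real chromosomes, natural map heterogeneity, or the
real experiment's genome-wide polygenic response.

## Numerical and engineering notes

* Meiosis, ancestry queries and frequency tallies are numba kernels over
  flat breakpoint arrays; buffers grow geometrically on overflow and the
  retry reuses identical randomness, so results do not depend on the
  initial capacity.
* Crossover positions are continuous (float bp); coincidences with
  existing breakpoints have probability zero and are not special-cased.
* BH adjustment is delegated to `statsmodels.stats.multitest`, the ACF
  to `statsmodels.tsa.stattools.acf`; both are cross-checked against
  hand-rolled oracles in the tests.
* `fit_window_lm` detects the zero-variance case by exact equality of
  replicates (ptp = 0) rather than a tolerance.
* The pipeline writes a manifest (parameters, seed, package version,
  input MD5 checksums) sufficient to reproduce any run bit-for-bit.
* Problem sizes in the routine checks (600 drift runs, five seeds × six
  experiments with 100-run shared nulls, 2,000 markers/arm) complete in
  a few minutes on one CPU.

## Known limitations

* The empirical p-value's (0, 0.5) null support makes the per-chromosome
  BH step anti-conservative (see above); drift-only fractions at FDR 10%
  on fully neutral genomes average ~0.90, not ~0.98.
* Selection in the experiment inflates drift variance relative to the
  neutral null; classifications on genomes with strong polygenic
  response should be read as descriptive, as in the original analysis.
* Crossover interference is not modelled; the recombination map is
  treated as a female map with achiasmatic males for all chromosomes.
* The catalogue builder trusts upstream genotype calls; no read-level
  evidence is re-examined.
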