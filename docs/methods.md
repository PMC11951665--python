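# Methods

## The imputation model

Imputation follows the Li & Stephens haplotype-copying model.  The
hidden state is the ordered pair (j, k) of reference haplotypes the
target's two chromosomes are currently copying; the diploid transition
kernel is the product of two independent per-haplotype processes, each
switching template with probability s = 1 − exp(−ρ·d) over a genetic
distance d cM and resampling uniformly over the K panel haplotypes.
Copying error is symmetric per allele with probability μ, giving the
3×3 kernel P(g | g*, μ) between the copied genotype g* = H[j,m] + H[k,m]
and the emitted genotype g.  A site's emission integrates its
genotype-likelihood triple over this kernel; a site with no likelihood
record emits uniformly, so its posterior rests entirely on LD with
flanking sites.  Genotype posteriors are marginalised through the same
kernel — p(g) ∝ L(g) · Σ_t w_t P(g | t, μ) with w_t the posterior state
mass at copied genotype t — rather than hard-assigning g = g*, keeping
the output consistent with the emission model.

The forward–backward pass is exact over all K² states with per-site
normalisation, O(M·K²) via the factorised transition.  This is
deliberate: at desk scale (K ≤ ~200) exactness buys oracle-checkability
— a path-enumeration oracle (`brute_force_posteriors`) reproduces the
posteriors to ~1e-15 on small instances — at the cost of the
PBWT/state-sampling accelerations production imputers use for K in the
tens of thousands.  Phasing is not emitted; only genotype posteriors
are evaluated.

Parameters: ρ (switch rate per cM per haplotype) defaults to 0.04, a
4Ne/K-flavoured magnitude appropriate for a ~100-haplotype panel; μ
(copying error) defaults to 1e-3.  Both are exposed in `HMMParams`.
The proxy genetic map is a constant 1 Mb = 1 cM.  Chromosomes are tiled
into 100 Mb core windows with 200 kb buffers; cores partition the
chromosome exactly and only core-interval sites are emitted, so merged
output never duplicates a site.  Enlarging the buffer 2.5x moves core
posteriors by < 1e-6 on the default data, which is what justifies the
chunked approximation.

## Strategies and merging

`ld_only` withholds SV likelihoods (uniform emission at SV sites) and
calls every panel SV; `gl_supplemented` feeds phred-scaled SV genotype
likelihoods (PL = round(−10·log10 L/L_max), half-away-from-zero
rounding) into the same HMM and excludes SVs lacking an evidence record,
as they would be absent from a genotype-likelihood input file.  Because
all sites share one joint HMM, adding SV evidence also perturbs
neighbouring SNV posteriors slightly; SNV records used downstream are
taken from the LD-only run, so merged SNV output is byte-identical to
the base run.

Merging operates per SV on unfiltered posteriors: "logical" keeps the
record with the higher PP (ties resolve to the evidence-bearing,
GL-supplemented record, a deterministic choice for a measure-zero
event), "non-logical" always keeps the GL-supplemented record, and SVs
covered only by the LD-only run are appended.  PP cut-offs (0.60, 0.75,
0.90) are applied after merging; this ordering makes the logical
merge's recall dominance over both base runs exact, since the merged
PP is the pairwise maximum wherever both runs call an SV.

## Metrics

"Correct" means exact diploid dosage match.  PPV = correct /
(correct + incorrect) among non-missing calls (undefined, not zero,
when nothing passes).  Recall = passing calls / all panel variants of
the stratum, so GL-supplemented runs pay their evidence dropout as
recall against the full panel denominator — the mechanism behind their
low recall at 1x.  SV strata are additionally binned by length:
100–500, 500–1000, 1000–2000, 2000–5000, 5000–10,000 and
10,000–2,000,000 bp, left-closed/right-open with the last bin closed.
Out-panel truth is restricted to panel variants before evaluation:
exact chromosome/position match for SNVs, same-class 90% reciprocal
overlap for SVs; private variants never enter a denominator.  A full
3×3 true-vs-imputed confusion matrix is available alongside the
aggregate PPVs.

The bespoke SNV hard filter (biallelic, no indels, QUAL ≥ 30, MAF ≥
0.01 and call rate ≥ 0.7 after masking genotypes with GQ < 10 or
DP < 4) reimplements the standard vcftools-style criteria with all
thresholds inclusive; genotype masks are applied before the site-level
MAF and call-rate tests, matching the tool it models.

## The synthetic-data generator

The generator defines the study conditions; it emulates a
population-scale WGS resource without sequence content:

* **Panel.** 100 haplotypes (50 diploid samples) on a 10 Mb chromosome
  with 2,000 SNVs and 100/20/10 DEL/DUP/INV, SV lengths log-uniform
  within class-specific ranges spanning the length bins (deletions up
  to 400 kb).  Haplotypes are mosaics of 8 founder sequences with an
  expected 1 template switch per Mb, so founder identity — hence allele
  state — is shared over ~Mb scales and SVs are in LD with flanking
  SNVs.  A founder-mosaic construction was chosen over a coalescent
  simulator because it is desk-scale, dependency-free and gives
  directly controllable LD; panels from real joint calling have
  site-frequency and missingness structure this does not attempt to
  match.  Monomorphic columns are re-polarised founder-wise so every
  emitted site is polymorphic.
* **SV panel noise.** SV columns receive per-haplotype allele flips
  (DEL 0.04, DUP 0.10, INV 0.08), emulating residual genotyping and
  phasing error of short-read SV calls in a real panel, ordered by the
  classes' known genotyping difficulty.  This is the feature that keeps
  LD-only SV imputation imperfect and gives SV read evidence its value;
  without it, founder mosaics tag SVs perfectly and the two strategies
  are indistinguishable.
* **Targets.** In-panel targets are panel samples re-imputed
  leave-one-out (both haplotypes removed, variant list unchanged).
  Out-panel targets are fresh two-haplotype mosaics of panel rows plus
  private variants at a configurable fraction (default 0.45, the
  approximate share of out-panel SVs absent from a reference panel in
  comparable call sets), injected at uniform positions since their true
  genomic placement is not modelled.
* **Read evidence.** Per SNV, depth ~ Poisson(coverage) and alternate
  reads ~ Binomial(depth, (g/2)(1−ε) + (1−g/2)ε) with ε = 0.001
  (Illumina-like); the likelihood triple is the product over reads.
  SVs use the same count model with class-specific effective depth
  (DEL 1.0, DUP/INV 0.7 of nominal) and noisier effective error
  (DEL 0.02, DUP 0.08, INV 0.06), and each SV independently lacks
  evidence with p_miss(c) = exp(−c/λ) (λ: DEL 1.0, DUP/INV 1.3) — at
  1x roughly 37–46% of SVs have no genotype-likelihood record, at 4x
  2–5%.  The dropout draw is keyed per site and seed only, so lower
  depths' evidence sets are nested within higher depths', as when
  down-sampling a single sequencing run.

What passing tests on this generator do and do not show: they validate
the pipeline's mechanics and the direction of every qualitative effect
(SV evidence raises SV PPV; dropout costs recall at low depth; merging
dominates both base runs; accuracy ordering SNV > DEL > DUP; recall
monotone in the PP cut-off), but absolute PPV/recall levels depend on
the synthetic LD structure and noise rates and are not calibrated to
any real panel.  Read-level artefacts (mapping bias, indel realignment,
multi-allelic sites, sex chromosomes) are out of scope.

## Numerical and design notes

* Coordinates are 1-based inclusive; SV length = END − POS + 1.  SVLEN
  is not written to VCF because htslib derives END from it under the
  END = POS + SVLEN convention, which differs by one.
* Likelihoods are linear internally, log10 in the VCF GL field, integer
  phred in PL; `gl_to_pl` then renormalising back reproduces input
  ratios within 0.5 phred.
* Forward-backward rejects a site where every emission vanishes (only
  possible with μ = 0 and contradictory evidence), naming the site.
* Chunk cores tile from position 1; window > 2·buffer is required.
* Degenerate inputs: zero coverage yields uniform triples (never a
  fabricated call); empty chunks are skipped with a warning; recall is
  rejected (not 0) for an empty denominator; PPV over zero calls is
  reported absent.
* Determinism: every stochastic operation draws from
  `numpy.random.SeedSequence([seed, tag, ...])` streams; one global
  seed fans out to per-stage seeds recorded in run manifests, and VCF
  headers carry the generating seed.
* Experiment sizes (10 leave-one-out targets, depths 1x and 4x) keep a
  full grid around a minute on one CPU while leaving every stratum
  populated; depths 2–3x interpolate the endpoints and can be enabled
  in `ExperimentConfig.depths`.

## Known limitations

Exact K² inference caps practical panel size well below production
imputers.  The generator's allele-frequency spectrum is uniform-ish
rather than neutral-coalescent.  Evidence dropout is independent per
SV, ignoring depth correlation along the genome.  Only biallelic sites
on a single autosome-like chromosome are modelled, and imputation
uncertainty is summarised by PP alone (no calibration curves).
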