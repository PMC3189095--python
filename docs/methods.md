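# Methods

## Sequence model and digestion

DNA is modeled as the canonical top strand of a duplex, linear or
circular, over a strict {A,C,G,T} alphabet (IUPAC ambiguity codes are
rejected so site scanning stays exact). Coordinates are 0-based,
half-open; GenBank serialization converts to the 1-based inclusive
convention, and circular topology is carried in the LOCUS line (FASTA,
which has no topology slot, uses a `[circular]` description token).
Circular sequences compare equal under rotation and reverse complement
(`circular_equal`), implemented by substring search in the doubled
string.

Each bundled enzyme is a palindromic hexamer with two cut offsets: the
top strand is cut before `recognition[cut_top]`, the bottom strand before
`recognition[cut_bottom]` in top-strand coordinates. The offsets are
standard enzymology rather than anything this package derives, so they
are pinned in a packaged table and tested against the overhang facts the
cloning chemistry requires (BglII/BamHI both leave 5′-GATC; AvrII/SpeI
both leave 5′-CTAG; AatII and SacI leave the 3′ overhangs ACGT and AGCT).
Digestion fragments tile the parent's top strand at the top-strand cut
positions, so re-ligation in order reconstructs the parent exactly — the
round-trip invariant all assembly tests lean on. Two ends ligate iff
their overhang kinds match and the protruding strands are mutual reverse
complements; since all eight bundled overhangs are self-complementary
this reduces to string equality, but the general rule is kept so
user-supplied non-palindromic geometries fail correctly. Ligation is
deterministic pairwise joining chosen by the caller: this is CAD
semantics, not reaction kinetics, and no attempt is made to model star
activity, partial digests or ligation efficiency.

## The assembly standard

A part is valid when the four standard sites occur exactly once each in
the flanks and never in the insert. Validation deliberately checks the
*flanked* sequence rather than the bare insert: a site can form across
the insert boundary (an insert starting `CGAG` forms `CTCGAG` against the
BglII half of the prefix), and such a part would fail in downstream
assembly even though its insert alone is clean. This choice has a useful
consequence: the 5-bp neighborhoods of an insert are identical inside a
part (prefix ends `GATCT`, suffix starts `GGATC`) and at an assembly
junction (the scar `GGATCT` provides both), so any two valid parts
compose into a valid part — idempotence is exact, not probabilistic.
The scar's in-frame translation Gly-Ser is exposed but follows from
standard chemistry, not from any claim about a particular construct.

The default flank spacers (`GAATTC aaa AGATCT` / `GGATCC aaa CTCGAG`)
reproduce the spacer geometry observable in the platform's construction
primer tails; the exact registry-standard prefix/suffix beyond the
enzyme sites is not fully pinned by that evidence, so flanks are a
configuration object rather than a constant.

## Domestication

Site removal considers only single-base substitutions, matching how the
original components were repaired. Inside an annotated ORF, candidates
are substitutions within the codons overlapping the hexamer that (a) are
synonymous under the standard code, (b) destroy the target site, and
(c) create no new site from the enzyme set; they are ranked by the
relative usage fraction of the replacement codon in the bundled E. coli
K-12 table (renormalized per amino acid at load; swappable via config).
Stop-to-stop swaps are admitted with usage rank 0. Outside ORFs all 18
hexamer edits are filtered by (b) and (c) and ranked by distance from
annotated features, with the explicit caveat that regulatory effects of
such edits are not modeled. Completeness against an exhaustive
single-edit oracle is a tested property, and iterating propose/apply
terminates in at most one application per initial site because the
site count strictly decreases.

The six QuikChange pairs bundled as the construction QC fixture encode
only the mutant strand (capitalized base = introduced mutation); the
wild-type base is recovered as the unique substitution at that position
that restores the named recognition site. For the pBBR1 copy-up mutation
the printed strands differ (A on the forward oligo, T on its
complement), so the package records mutations strand-explicitly and
makes no claim about which strand a "C to T" description references.

## Primers and PCR

Annealing is modeled as exact, unique string matching (≥ 15 nt), with no
mismatch tolerance or thermodynamics: the product of a simulated PCR is
`fwd.tail + template[fwd…rev] + revcomp(rev.tail)`, and amplicons may
span a circular origin. Mutagenic pairs are a template window with the
mutation at a configurable (possibly asymmetric) arm position, paired
with its reverse complement; whole-plasmid mutagenesis requires the
oligo to match the template with exactly one mismatch. SOE fusion gives
each junction a `half`-sized overlap arm on both sides (default 15 nt,
`max(overlap//2, 15)`), so the two inner primers of a junction are
mutual reverse complements carrying any junction mutation; the fused
product is pure sequence algebra and is checked against independent
concatenation. Tm uses the Wallace rule below 14 nt and the simple GC
formula 64.9 + 41·(GC − 16.4)/N otherwise — chosen for determinism, not
accuracy; the platform's construction reports no Tm criteria.

## Vector architecture and library generation

A pBb vector is `AatII + expression + AvrII + origin + SacI + marker`,
circular, with each boundary site unique and the expression payload
containing exactly one EcoRI/BglII/BamHI/XhoI cassette in order. The
real parent-plasmid sequences are not distributed with the package;
module payloads default to deterministic synthetic placeholders
(restriction-clean uniform random sequences of realistic length: origins
0.9–1.6 kb, markers 0.95 kb, expression modules ≈1.76 kb including a
real ribosome-binding-site sequence in the cassette), clearly labeled
synthetic, with GenBank import available for real payloads. Promoter
codes 2, 3/4, 5 and 8 are fixed by published usage (Ptet, the two PprpB
variants, PlacUV5, PBAD); the assignment of 1, 6, 7 among Ptrc,
PLlacO-1 and PT7 and the 3-vs-4 ordering are catalog defaults,
overridable in configuration, because the in-text evidence does not pin
them.

Module swapping digests the vector at the slot's two boundary enzymes
and religates the backbone — identified as the fragment still carrying
the third boundary site — with the new module's fragment; this keeps
swap semantics within the same digestion/ligation machinery the rest of
the package uses. The broad-host-range origin install is modeled
separately: an AvrII/SpeI-cut product ligated into the single AvrII site
regenerates one AvrII junction and leaves a hybrid scar cut by neither
enzyme at the other, mirroring the original construction.

## Datasheet analytics

Specific fluorescence is the pointwise ratio F/OD600, computed after
optional blank subtraction and masked (not divided) below an OD floor of
0.05. The dose-response summary takes the measured timepoint nearest
18 h with no interpolation — at a 570-s cadence the summary time is off
by at most 285 s — and normalizes by the mean control-well SF when
controls are present (absolute values are always reported too, since the
published bar charts do not state which convention they use). Replicates
are aggregated as mean ± sd with no outlier rejection. The control
induction level is configuration (default 12.5 µM IPTG, the assay-design
value; the results text elsewhere says 100 µM, and the discrepancy is
deliberately not resolved in code). The Hill fit is bounded least
squares with deterministic initialization (basal = min, span = max−min,
K = geometric median of nonzero doses, n = 1); non-convergence is
reported in diagnostics rather than raised.

Crosstalk and repression are percent changes of the treated condition
against its baseline at the same summary time, positive meaning
enhancement — chosen so that a 0.8 ratio prints −20% and a 1.4 ratio
+40%, the reporting convention of the platform's characterization.

qPCR quantification always goes through fitted standard curves (OLS of
Ct on log₁₀Q per target), never a ΔΔCt shortcut: efficiency is
10^(−1/slope) − 1, a non-negative slope raises (a four-fold dilution
series read in the wrong direction), and Cts outside a curve's
calibrated range attach an extrapolation warning to the result. Copy
number is the ratio of nptII/16S quantity ratios between sample and
single-copy reference strain, which makes the reference map to exactly 1
for any pair of curves.

## Synthetic data

The generators emulate the characterization design: logistic growth
OD(t) = K/(1 + ((K−OD₀)/OD₀)e^(−rt)); expression as a Hill dose factor
times a linear rise saturating at t_rise = 8 h, so the noiseless SF
plateau equals the Hill value exactly at the 18-h summary; raw
fluorescence as SF × OD with multiplicative log-normal noise (default
σ = 0.05, giving the few-percent triplicate CVs typical of plate
assays); per-target Ct as intercept − log₁₀Q/log₁₀(1+E) plus Gaussian
noise (default sd 0.1). Crosstalk coefficients and a glucose factor
multiply SF for non-cognate-inducer and 1%-glucose conditions. qPCR
unknowns are expressed in units of the standard stock and fall inside
the seven-point four-fold dilution range, as they do when standards are
prepared from the same kind of digested total-DNA preparation; this
matters because extrapolated reads amplify slope noise. All generators
are pure functions of (parameters, seed) and emit ground-truth sidecars.

What the generators do *not* emulate: growth-dependent expression
coupling, autofluorescence background, plate position effects, inhibited
or variable qPCR efficiency between replicates, and any mechanistic
transcription/translation kinetics. Passing recovery tests therefore
demonstrate that the analytics invert the stated statistical model at
realistic noise, not that they are robust to every artifact of real
plate or qPCR data.

## Problem sizes and statistical checks

Property suites run 1,000 random digest/ligate round trips, 1,000
random part-pair assemblies, 200 random CDS domestication instances
against the exhaustive oracle, and 100-seed recovery studies for copy
number and Hill K; these sizes give comfortable statistical power while
keeping the full suite in a few seconds. With Ct noise 0.1 and
triplicate unknowns a single run's copy-number estimate has ≈8% CV, so
recovery of the planted copy numbers {5, 10, 60} is assessed on the
simulation-study mean over 100 seeded runs (observed bias < 1%);
per-run scatter is reported by the same tests. Hill K at 5% noise stays
within 20% of truth per run and in mean. The noiseless perfect-efficiency
standard curve reproduces slope −log₂10 ≈ −3.3219 and efficiency 1.000
to machine precision, a closed-form identity used as an exactness check.

## Known limitations

- Only single-base domestication plans; multi-base or insertion/deletion
  repairs are out of scope.
- No mixed-standard (RFC 10) conversion, no two-antibiotic automated
  assembly strategy, and no promoter-less vector variants.
- Placeholder payloads make library-level tests structural: they verify
  architecture, uniqueness and surgery, not biology of the real parent
  sequences.
- Percent-change panels assume positive baselines; conditions with zero
  expression are reported as undefined rather than clamped.
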