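# Methods

This note records the models implemented in `glycosearch`, their
assumptions, the defaults that matter, and the places where the design was
genuinely open and a choice had to be made.

## Glycan compositions and the Y-ladder approximation

Glycans are handled as compositions (multisets of residues), never as
topologies. Residue masses are computed from elemental compositions
(Hex C6H10O5, HexNAc C8H13NO5, dHex C6H10O4, NeuAc C11H17NO8, NeuGc
C11H17NO9, Pent C5H8O4) via pyteomics; nothing is transcribed by hand. The
built-in table covers these six residues and is extensible at run time.

The peptide+Y ladder for an N-glycan is generated semi-structurally:

* *core fragments* — all rooted sub-structures of the canonical
  HexNAc₂Hex₃ core tree, merged by mass, each optionally carrying one
  reducing-end dHex (if the composition contains dHex) or Pent;
* *non-core fragments* — the full core motif plus every multiset
  combination of the remaining non-labile residues;
* NeuAc and NeuGc are labile and never ride on Y fragments;
* compositions that do not cover the core motif (small O-glycans,
  truncated N-glycans) fall back to pure combination enumeration.

Glycan coverage divides the number of distinct matched ladder masses by the
normalizer d(g) = max(n ln n, n) when dHex is present and
max(½ n ln n, n) otherwise, with n the approximate size (residues − sialic
acids − 1 if ≥2 dHex, floored at 0; d floored at max(n, 1) so 1–2-residue
O-glycan cores stay well-defined). The ½ factor reflects the single-child
root of the unfucosylated core; core fucosylation roughly doubles the
distinct-mass count by decorating every fragment.

An independent brute-force oracle (tests/oracle_trees.py) builds explicit
high-mannose, hybrid, and complex-type topologies of 5–14 residues and
counts distinct Y-fragment masses exactly. Two interpretation choices make
the envelope statement precise, and both are documented in the oracle:
fragments arise from at most **3 simultaneous glycosidic cleavages**
(unrestricted subtree enumeration over-counts improbable multi-cleavage
products and breaks the upper bound for fucosylated tetra-antennary trees),
and **Y0 is not counted** (the bare peptide carries no glycan information;
d(g) normalizes glycan evidence). Under these rules every fixture count
lies at or below ⌈n ln n⌉, complex-type fixtures lie at or above
½ n ln n, and the homogeneous high-mannose ladders fall below the lower
bound — the known exception.

Decoy glycans reuse the target ladder with every fragment of ≥2 residues
shifted by an independent Uniform(1, 30) Da draw; Y0 and Y1 keep exact
target masses so decoy matches always reach the baseline score of a glycan
that is almost entirely eliminated. Shifts are seeded per
(glycan, peptide) pair via CRC32 of their text forms, so results are
reproducible without a global ordering.

## Spectrum scores

All scores use log base 10, so the model-enhanced forms reduce exactly to
the base forms when the model terms vanish (asserted to 1e-9 in the test
suite). Defaults: α = 0.5, β = 0.4, γ = 1, w = 0.65, fragment tolerance
20 ppm, precursor tolerance 5 ppm, σ_pre = 5 ppm.

* Peptide: Σ log₁₀(intensity)·(1 − |ppm/tol|⁴) over matched b/y, times
  coverage_P^γ, where coverage_P counts cleavage bonds with ≥1 matched ion.
* Glycan: the same weighted sum over matched Y fragments, times
  coverage_G^α · coverage_core^β.
* Precursor accuracy bias: −10·log₁₀(max(1e-3, 1 − exp(−ppm²/2σ²))),
  capped at +30; the denominator is the Gaussian 2σ² convention and the
  floor keeps a perfect match finite.
* Signature ions: NeuAc/NeuGc oxonium masses are derived from residue
  compositions (protonated, with/without water loss; matched at residue
  and residue−water in neutral-mass spectra). An observed oxonium for an
  absent residue costs 10·log₁₀(1 − relative intensity) (capped at 0.999);
  an expected oxonium missing (≤1% of base peak) costs
  10·log₁₀(1 − min(count/2, 0.99)).
* Model-enhanced peptide score: each term gains ×(φ+1)+φ, plus
  Cor_P = (ρ+1)·log₁₀(m_p); the FDR layer additionally uses
  Cor′_P = (ρ+1)·m_p·coverage_P, which scales linearly with matches.
* Model-enhanced glycan score: the reliability and correlation terms
  (Rel_G = Σ pad(φ)·max(ρ_G, 0.25) with pad(x) = 0.5x+0.5, and
  Cor_G = (ρ_G+1)/2) are scaled by the number of non-trivial Y fragments
  (glycan size > 1) and by s(coverage_P) = min(exp(3·coverage_P − 1), 1),
  so the glycan model cannot rescue a wrong backbone.
* Pearson ρ on fewer than 3 points or zero-variance vectors is defined as
  0 (the neutral value after the +1 shift); with no matched peptide
  fragments all four correlation terms are 0.

## Fragmentation learning

Training data are annotated spectra (peptide, glycan, per-peak fragment
labels). The partition grid is peptide length {≤10, 11–15, 16–20, 21–27,
≥28} × glycan size {≤9, ≥10} × charge {1, 2, 3, 4, ≥5} × proton mobility
{mobile, partial, immobile} — 150 cells per glycosylation type. Mobility
compares K+R+H count to precursor charge.

**Reliability (φ).** Binary inter-peak features per peak under a series
hypothesis: b/y complement to the peptide mass, ±amino-acid residue
offsets, ±HexNAc for backbone ions; ±HexNAc/±Hex/±dHex for Y ions; all at
fragment tolerance. Likelihood ratios P(f | annotated)/P(f | unannotated)
with add-one smoothing combine naive-Bayes style with the partition's
annotation prior. Unannotated peaks below 0.1% of the base peak are
excluded from training (a noise floor); inference imposes no rank
restriction. Partitions with fewer than 50 spectra borrow adjacent charge
bins (reliability only).

**Intensity (θ).** Relative intensities within a series group (backbone,
or Y split by ladder direction) are modeled as a multinomial whose
probabilities are a softmax of fragment features: fragment amino-acid
composition, one-hot flanking residues at the cleavage, series, relative
position, and mobility interactions for b/y; glycan-size terms, basic
residue content, and mobility for Y. Fitting maximizes the weighted
multinomial log-likelihood (spectrum weight ∝ log of total matched signal,
peak weight ∝ φ, or 1 when the φ-weighted fit is unstable) by Newton steps
with step-halving, so the objective is non-decreasing; convergence at
|Δ log-likelihood| < 1e-6 or 100 iterations; a singular Hessian triggers a
1e-4 ridge retry and ultimately a uniform fallback. The ladder direction
(ascending/descending intensity with glycan size) is the sign of the
Spearman correlation; ties default to descending, the majority class under
stepped collision energy. Charge bins are never borrowed for intensity
fits. A missing partition resolves to the nearest fitted one by Manhattan
distance on bin indices, then to a global model — the fallback is total.

## Site-specific glycome smoothing

The glycome graph has glycan compositions as nodes and edges between
compositions at monosaccharide-count L1 distance 1. Nine rule-based
N-glycan neighborhoods (high-mannose, paucimannose, hybrid, bi/tri/tetra-
antennary, fucosylated, sialylated, poly-sialylated) define trapezoidal
membership weights A; users can supply their own rules in a text file. No
models are fit for O-glycosylation sites.

Per site, observed glycan scores y (the *base-scale* glycan score — u is
added inside the same bracket as the log-intensity sum, so the two must be
commensurate; the quadratic model-enhanced score would let u dominate) are
smoothed by minimizing over (u, τ):

    Σ_observed (y − u)²  +  Σ_unobserved u²  +  λ·uᵀLu  +  λ·μ·‖u − Aτ‖²

with μ = 1, solved by block-coordinate descent (linear solves, relative
tolerance 1e-8). The absence anchor on unobserved nodes is essential: the
objective without it admits a constant-u minimizer (exact data fit, zero
Laplacian penalty) and credit would propagate without bound; with it, the
credit an unobserved composition receives is proportional to λ times the
evidence flowing in from graph neighbors and neighborhood means, which is
what the λ cap exists to control. λ is selected from
{0, 0.025, …, 0.2} by leave-one-observation-out squared error and is
hard-capped at 0.2. At λ = 0 the model reproduces observed scores exactly
and assigns zero credit elsewhere. u is clipped at 0.

Decoy parity is structural: u lookups key on (site, composition) only, and
decoy peptides carry mirrored site coordinates mapping to the target
protein's site, so the smoothing path cannot distinguish targets from
decoys.

## Relative retention time and revision

For each peptide backbone with ≥2 distinct glycoforms, the reference time
is the abundance-weighted mean apex and the reference composition the
abundance-weighted mean counts. RT offsets from the reference are modeled
as linear in signed monosaccharide-count differences plus adduct counts,
fit per overlapping time bin (8 bins at 50% overlap over the run span) so
the column's behavior may drift along the gradient. Bin membership is
keyed on the backbone's *reference* time, not each apex: selecting on the
apex truncates on the response and attenuates the coefficients. Bin
residual scale is MAD × 1.4826; empty bins inherit the nearest populated
bin. Coverage extends iteratively to backbones whose compositions lie
within L1 distance 2 of covered ones (fixpoint or 10 rounds); the covered
fraction is reported.

The RT score is max(0, 1 − 2|residual|/span) — the complement of the
probability that a uniformly random time point lands within the observed
residual, so 0.75 corresponds to a 25% random-chance window.

Revision considers, for each identification the model covers, the identity
and every applicable mass-closed rule (default family:
NeuAc+NH₃ ↔ Hex+dHex, net 11.2 mDa, asserted at registration; candidate
compositions must exist in the search space). A revision must reduce the
absolute RT residual by more than 2× the residual scale, must not
contradict diagnostic ions (removing the last NeuAc is vetoed when its
oxonium exceeds 1% of the base peak; adding a first NeuAc is vetoed when
the oxonium is absent), and must pass the caller's FDR guard. Two
implementation details matter in practice and are this package's own
choices where the published description is a contract rather than an
equation: predictions during revision use **leave-one-out references**
(removing the identification's own abundance-weighted contribution, so an
abundant misassignment cannot anchor itself), and revision runs
**iteratively** — fit, revise, refit — because misassignments contaminate
the very coefficients that would expose them. Revision is idempotent once
the fixpoint is reached. Pure adduct addition/removal is handled upstream
by parsimony over shared MS1 features: a mass-shifted assignment with no
co-eluting unshifted version is replaced by a rule-mapped unshifted
alternative when one exists.

## FDR control

Peptide q-values: Percolator-style semi-supervised iteration (3 rounds,
linear SVM with C = 1, seeded) over [peptide score, coverage_P, Cor′_P],
initialized by the raw score; targets at q ≤ 0.01 versus decoys; a round
is kept only if it does not reduce the confident-target yield; fewer than
20 decoys falls back to score-only counting with a warning.

Glycan q-values: decoy counting on the glycan score against decoy-glycan
matches, with an optional Gamma tail fit to the decoy survival function.
Compositions of ≤3 residues produce too few Y ions for the estimate to be
meaningful; their glycan FDR is undefined and the joint FDR propagates the
peptide FDR with a flag.

Joint FDR: p + g − p·g. q-values use the classical counting estimate
(#decoys ≥ s / #targets ≥ s) with monotonization from the best score; the
conservative +1-pseudocount variant is available by argument.

## Search engine

Candidate generation is glycan-first: for each allowed mass shift
(ammonium ×0..2 by default), the sorted glycan mass index proposes
complement peptide masses looked up at the precursor tolerance. Candidates
are ranked by a cheap pre-score — matched core Y masses plus matched b/y
among the ten most intense peaks (the published method caps candidates
without stating its pre-ranking; this one is the package's choice) — and
truncated to k = 70 per shift. Targets, reversed-protein decoy peptides,
and shifted-ladder decoy glycans flow through byte-identical matching and
scoring code; per spectrum the best candidate in each target/decoy channel
feeds the corresponding FDR estimate, and the best target–target
assignment is reported once per spectrum.

## Synthetic data: what it emulates, what it does not

The generator emits deconvoluted, neutral-mass spectra: b/y intensities
drawn from a softmax over the same feature space the intensity model fits
(ground-truth θ defaults emulate enhanced cleavage at D/E and N-terminal
to proline, y-over-b preference, and mobility effects), an ascending or
descending peptide+Y ladder (30% ascending by default), NeuAc oxonium
peaks for sialylated compositions, multiplicative log-normal intensity
noise (σ = 0.3), ~2 ppm mass jitter, and Poisson-count uniform noise peaks
(mean 20). LC runs place backbones uniformly over a 90-minute span with
per-monosaccharide elution shifts (Hex +0.5, HexNAc +0.8, NeuAc +2.0,
dHex −0.3 min per residue; NH₃ adduct −0.5 min), Gaussian apex noise
(0.1 min), optional linear coefficient drift, and a configurable fraction
of identifications recorded under the NeuAc+NH₃ → Hex+dHex swap with truth
labels. Score-population fixtures draw genuine targets, null targets, and
decoys from known Gaussians so realized false-discovery proportions can be
measured against estimates.

What passing tests on these fixtures shows: the estimators recover the
parameters that generated the data, the FDR estimates are calibrated when
decoys are exchangeable with false targets, and the full pipeline is
internally consistent end-to-end. What they do not show: robustness to
chimeric/co-isolated precursors, deisotoping artifacts, real
chromatographic tailing, instrument-specific fragmentation quirks, or
search spaces of realistic size — the synthetic databases are hundreds of
peptides, not proteome-scale.

## Problem sizes used in the checked runs

Parameter-recovery checks use 500 simulated spectra (intensity θ), 60
backbones × 6 glycoforms (RT coefficients), and 250 backbones × 8
glycoforms with a 10% planted swap rate (revision). FDR calibration pools
20 simulations of 1,800 scores each. The end-to-end benchmark searches 200
glycopeptide spectra against a database built from 6 synthetic proteins ×
16 glycans with decoys, trains the fragmentation model on a disjoint
150-spectrum batch, fits site models from first-pass confident results,
and requires ≥95% recovery at 1% joint FDR.

## Known limitations

* b/y and Y ions only — no ETD/EThcD (c/z) support, no NH₃/H₂O neutral
  losses, no sulfate/phosphate signature ions.
* One glycan per peptide; multi-site peptides enumerate site choices as
  separate candidates without localization scoring.
* The annotated-MGF token grammar is this package's own (documented in
  `glycosearch.spectra`); other tools' annotated MGFs are not parsed.
* No cross-run pooling: each LC-MS/MS run is processed independently.
* The RT model presumes reverse-phase-like additive elution shifts; it is
  not appropriate for porous graphitic carbon or electrophoretic
  separations.
* The exact feature tables and supplementary equations of the published
  reliability/intensity and RT layers are not public; the feature sets and
  closed forms here are the package's documented reference configuration
  honoring the published grid sizes, caps, and contracts.
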