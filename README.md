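# glycosearch

Layered identification of intact N-glycopeptides from deconvoluted MS/MS
spectra.

## The problem

Stepped-collision-energy HCD spectra of glycopeptides mix three kinds of
evidence: peptide backbone b/y ions, glycan oxonium (B) ions, and intact
peptide+Y ions carrying residual parts of the glycan. Confident
identification requires scoring the peptide and the glycan *moieties
independently* and controlling a false discovery rate for each, because a
correct peptide with a wrong glycan (or vice versa) is still a wrong answer.
On top of that, some glycan assignments are quasi-isobaric — NeuAc plus an
ammonium adduct differs from Hex plus dHex by ~11 mDa — and cannot be
resolved from fragmentation alone.

`glycosearch` implements a layered engine for this problem:

1. **Composition-level glycan scoring.** Instead of enumerating glycan
   topologies, peptide+Y ladders are generated from *compositions*: the
   canonical HexNAc₂Hex₃ core (optionally dHex/Pent-decorated) plus every
   combination of the remaining non-labile residues, with NeuAc/NeuGc
   treated as labile. Glycan coverage is the number of distinct matched
   ladder masses over the normalizer

   d(g) = max(n ln n, n)  if dHex present,  max(½ n ln n, n)  otherwise,

   where n is the approximate glycan size (residues minus sialic acids,
   minus one if ≥2 dHex). For n ≤ 7 this reduces to d = n.
2. **A mixed spectrum score.** Per-moiety, mass-accuracy-weighted
   log₁₀-intensity sums scaled by coverage terms (exponents α = 0.5,
   β = 0.4 for glycan/core coverage, γ = 1 for peptide coverage), combined
   with weight w = 0.65, plus precursor mass-accuracy and sialic-acid
   signature-ion biases.
3. **A learned fragmentation layer.** A naive-Bayes *reliability* φ for each
   matched peak from inter-peak relationship features (b/y complements,
   amino-acid and monosaccharide mass offsets), and a multinomial (softmax)
   *intensity* model θ per data partition (peptide length × glycan size ×
   charge × proton mobility; 150 cells per glycosylation type), fit by
   iteratively re-weighted least squares. Both feed reliability- and
   correlation-enhanced scores.
4. **Site-specific glycome smoothing.** A graph over glycan compositions
   (edges = ±1 monosaccharide) with biosynthetic neighborhoods; observed
   glycans at a site propagate prior credit u(g) to related compositions
   through a Laplacian-regularized objective with smoothing parameter
   λ ≤ 0.2. Decoys receive exactly the same u(g) as their targets.
5. **Relative retention-time revision.** Glycoforms of a shared backbone are
   modeled as linear elution shifts per monosaccharide/adduct in
   overlapping time bins; quasi-isobaric assignments whose observed apex
   disagrees with the prediction are revised under diagnostic-ion vetoes.
6. **FDR control.** Percolator-style semi-supervised peptide q-values
   (linear SVM over score, coverage, and correlation features), decoy-
   counting glycan q-values (decoy ladders carry uniform 1–30 Da shifts
   beyond Y1; compositions of ≤3 residues are excluded), combined by
   inclusion–exclusion into a joint FDR.

All layers run identically for targets and decoys, and everything is
exercised end-to-end on seeded synthetic spectra and elution tables — no
external data downloads are required.

## Worked example

Glycan arithmetic:

```python
from glycosearch import parse_composition, approx_size, coverage_normalizer, generate_y_ladder

g = parse_composition("{Hex:5; HexNAc:4; dHex:1; NeuAc:2}")
print(g.mass)                  # 2350.8303 Da
print(approx_size(g))          # 10   (12 residues - 2 NeuAc)
print(coverage_normalizer(g))  # 23.026  (10 * ln 10, fucosylated branch)
print(len(generate_y_ladder(g)))  # 27 distinct peptide+Y masses (11 core)
```

A small synthetic search:

```python
import numpy as np
from glycosearch.engine import SearchConfig, build_database, search_run
from glycosearch.simulate import (SimulationConfig, example_glycans,
                                  example_proteins, simulate_spectra)

db = build_database(example_proteins(), example_glycans())
targets = [p for p in db.peptides if not p.is_decoy and 6 <= len(p.sequence) <= 30]
rng = np.random.default_rng(0)
pairs = [(targets[int(rng.integers(len(targets)))],
          db.glycans[int(rng.integers(len(db.glycans)))]) for _ in range(25)]
spectra, truth = simulate_spectra(pairs, SimulationConfig(seed=1))
df = search_run(spectra, db, SearchConfig())
print(df[["scan_id", "peptide", "glycan", "score_total", "fdr_joint"]].head())
```

prints (top rows):

```
scan_id                       peptide                     glycan  score_total  fdr_joint
  sim_0    YVQPAQICENQTMKMCAPNMTEDHVR  {Hex:6; HexNAc:4; dHex:1}   164.156627        0.0
  sim_7 PNMTVEAFFVWRSCINFTFKILMLNYTSR          {Hex:6; HexNAc:5}   153.803080        0.0
 sim_15    YVQPAQICENQTMKMCAPNMTEDHVR          {Hex:7; HexNAc:2}   147.581187        0.0
```

Each row is the best target–target assignment for one spectrum: the mixed
total score and the joint (peptide ∧ glycan) q-value; all 25 spectra here
are recovered at 1% joint FDR with the correct peptide and glycan.

A CLI wraps the same library for shell use:

```sh
glycosearch simulate --n 50 --seed 1 --out-mgf sim.mgf --out-truth truth.tsv
glycosearch train-frag sim.mgf -o frag_model.json
glycosearch search sim.mgf proteins.fasta glycans.txt -o results.tsv
glycosearch rt-revise ids.tsv -o revised.tsv
```

## Layout

| module | contents |
| --- | --- |
| `glycosearch.chem` | monosaccharide residues, adducts, oxonium masses |
| `glycosearch.glycans` | compositions, Y ladders, coverage normalizer, decoy ladders |
| `glycosearch.peptides` | digestion, sequons, reversed decoys, b/y fragments, proton mobility |
| `glycosearch.spectra` | deconvoluted-spectrum model, MGF dialect, results TSV |
| `glycosearch.scoring` | base / model-enhanced / smoothed GPSM scores |
| `glycosearch.fragmodel` | partitioning, reliability (φ), intensity (θ) learning |
| `glycosearch.siteglycome` | glycome graph, neighborhoods, u(g) smoothing |
| `glycosearch.rt` | relative RT model, RT score, quasi-isobaric revision |
| `glycosearch.fdr` | peptide/glycan/joint q-values |
| `glycosearch.engine` | database build, glycan-first search, orchestration |
| `glycosearch.simulate` | seeded synthetic spectra, LC runs, score populations |

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
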