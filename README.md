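# readpref

Models of sequence-dependent non-uniformity in RNA-seq read-start counts.

Read starts in short-read RNA-seq are far from uniform along a transcript:
the local sequence context around the first base of a read (random-priming
efficiency, linker interactions, local secondary structure) multiplies the
expected read-start rate by a *sequencing preference*. Treating counts as
draws from a single per-gene Poisson rate therefore badly misfits real
data — variance-to-mean ratios run in the tens to thousands where a
constant-rate Poisson predicts 1.

`readpref` is a library + CLI for transcriptomics practitioners who want
to model, quantify, and correct this bias. It implements:

* **A Poisson log-linear preference model.** The count at position *j* of
  gene *i* is n<sub>ij</sub> ~ Poisson(μ<sub>ij</sub>) with

  log μ<sub>ij</sub> = ν<sub>i</sub> + α + Σ<sub>k</sub> Σ<sub>h∈{A,C,G}</sub> β<sub>kh</sub> I(b<sub>ijk</sub> = h),

  where ν<sub>i</sub> is the gene's log expression level and
  b<sub>ij1</sub>…b<sub>ijK</sub> is the K-base window around the read
  start (base T is the reference level, so an 80-nt window has 3×80 = 240
  coefficients). The fit alternates two exact conditional maximizations —
  a Poisson offset regression for (α, β) and the closed-form update
  ν<sub>i</sub> = log(N<sub>i</sub>/W<sub>i</sub>), with W<sub>i</sub> the
  gene's sum of preferences — until the deviance decrease falls below 1%.
  Goodness of fit is the deviance R² = 1 − d/d₀ against the
  uniform-preference null model μ<sub>ij</sub> = N<sub>i</sub>/L<sub>i</sub>.

* **A boosted-trees preference model (MART)** for the nonlinear part of
  the signal: per-position empirical log preferences
  log(max(n<sub>ij</sub>, 0.5)/(N<sub>i</sub>/L<sub>i</sub>)) are
  regressed on the one-hot window features by weighted squared-error
  gradient tree boosting (11-leaf trees, shrinkage 0.06, 2000 trees,
  weights N<sub>i</sub>/L<sub>i</sub>), evaluated by gene-level 5-fold
  cross-validated deviance R² with the closed-form expression MLE
  ν̂ = log(Σn<sub>j</sub> / Σe<sup>a<sub>j</sub></sup>) on held-out genes.

* **Preference-corrected estimators.** The sum of sequencing preferences
  (SSP) of a region acts as its effective length: expression = N/SSP
  instead of N/L, the fold change max(p̄, 1/p̄) (p̄ = SSP/L) quantifies
  how much the correction matters, and a Poisson EM maximizes the
  isoform-abundance likelihood with exon means proportional to exon SSPs
  rather than exon lengths.

* **A synthetic-data generator** producing transcripts with flanks,
  planted preference functions, and independent Poisson counts, so the
  whole pipeline is testable end to end with known ground truth.

## Worked example

Simulate 20 genes with a planted log-linear preference over a (3, 3)
window, then run the full pipeline (filter → linear fit → cross-validated
boosting → preference prediction → corrected expression):

```sh
python -c "
import json, numpy as np
rng = np.random.default_rng(42)
spec = {'alpha': 0.0, 'w_up': 3, 'w_down': 3,
        'beta': rng.normal(0, 0.3, 18).tolist()}
json.dump(spec, open('spec.json', 'w'))"

readpref simulate --n-genes 20 --length-min 300 --length-max 600 \
    --flank 10 --seed 1 --pref-spec spec.json --out-dir sim
readpref run --counts sim/counts.tsv --fasta sim/transcripts.fasta \
    --w-up 3 --w-down 3 --trees 2000 --seed 1 --out-dir out
```

which prints

```
cv_r2 = 0.9698; manifest in out/manifest.json
```

and writes `out/expression.tsv` beginning

```
gene_id  N      L    ssp        est_uniform  est_ssp    fold_change  rpkm
g0000    53702  442  438.93691  121.49774    122.3456   1.0069784    86628
g0001    85921  456  451.39603  188.42325    190.34505  1.0101994    134346
```

Reading the numbers: the boosted model explains ~97% of the null-model
deviance on held-out genes (the planted signal is strong and fully
sequence-determined). Gene `g0000` received N = 53702 reads over
L = 442 positions; its SSP under the fitted model is 438.9, slightly
below its length, so the corrected estimate N/SSP = 122.3 exceeds the
uniform estimate N/L = 121.5 by a fold change of 1.007 — for whole genes
the local preference swings largely average out, exactly the smoothing
effect that makes the correction matter most for short regions (exons,
junctions) rather than full-length transcripts. The manifest records the
linear model's training R² (0.9727 here) alongside the CV result.

Other subcommands: `readpref count` (toy exact-match, unique-mapping
read-start counting), `fit-linear`, `fit-boost`, `predict`, `express`,
and `isoform` (exon-count EM given a structure TSV with per-isoform exon
SSPs, which the library computes via `express.region_ssp` over
`treepref.predict_pref` output). All commands are deterministic given
`--seed`.

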