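# magscan

Upstream-ORF annotation and a quantitative model of magnesium-dependent
translation initiation on the TRPM7 mRNA 5′-leader, with an analysis
pipeline for in vitro translation kinetics.

## The problem

TRPM7 is the vertebrate channel-kinase that lets Mg²⁺ into cells.  Its
mRNA is abundant but the protein is scarce: translation of the main
reading frame is throttled by the 5′-leader, which carries two
conserved upstream AUGs.  uORF1 (strong Kozak context, overlapping the
main coding sequence) removes most scanning ribosomes outright; uORF2
(weak context, U at −3) captures ribosomes *more efficiently at high
Mg²⁺*, so that lowering magnesium opens a leaky-scanning path to the
main start codon.  The leader is thus a magnesium sensor: reporter
mRNAs carrying it have a low, potassium-invariant magnesium optimum,
while a β-globin leader's optimum tracks the ionic balance of the
extract.

`magscan` is for people who want to analyse (or simulate) this kind of
experiment: uORF/Kozak annotation of leaders, a computable
leaky-scanning/reinitiation model, and the kinetic analysis that turns
plate-reader luminescence curves into maximal synthesis rates,
bell-shaped Mg-response curves and magnesium optima.

## The model in brief

Reporter flux is a branching process over the leader's AUGs:

    flux(Mg, K) = loading(Mg, K) × P(scanning complex reaches and
                                     initiates at the reporter AUG)

* `loading(Mg, K) = A·exp(−(Mg − c(K))²/2w²)`, a Gaussian bell in
  added Mg whose center `c(K) = c₀ + c₁K` rises with added K
  (cation competition for the 40S subunit);
* at each AUG the initiation probability is a logistic in Mg per Kozak
  class, `p(Mg) = floor + (ceil − floor)·σ((Mg − m)/s)` — flat for
  strong contexts, rising for the suboptimal uORF2 context (stringent
  selection at high Mg²⁺, leaky scanning at low Mg²⁺);
* initiation at a uORF overlapping the reporter ORF sequesters the
  ribosome; after a short upstream uORF, scanning resumes with a
  single reinitiation probability q.

An exact closed form and a Monte-Carlo twin are both provided, along
with mutation operators for the classical reporter series
(1AUC, 2AUC, 1AUC2AUC, 2stopCGA, 2ndLuc) and a fitted parameter preset
`paper2014`.  The kinetic statistic is the maximal synthesis rate
(max OLS slope over 5-min windows, ALU/min); the magnesium optimum is
the center of a Gaussian bell fitted to rate vs added Mg.
See `docs/methods.md` for assumptions, parameters and limitations —
including a structural infeasibility in the printed constraint set
that the fit reports rather than hides.

## Worked example

Simulate a calibration experiment (TRPM7-like and β-globin-like
reporters, 60 mM added K, Mg from 0.2 to 1.4 mM, 3 replicates, 3%
read noise) and analyse it:

```bash
magscan simulate --constructs M7-Luc-M7,beta-Luc-M7 --k-levels 60 \
    --replicates 3 --noise-sd 0.03 --seed 7 --out data
magscan analyze data/traces.csv --out out
```

which prints

```
M7-Luc-M7 @ K=60 mM: Mg optimum 0.802 mM added (amplitude 8.42 ALU/min)
beta-Luc-M7 @ K=60 mM: Mg optimum 0.974 mM added (amplitude 72 ALU/min)
```

The TRPM7-like leader peaks at 0.80 mM added Mg — the reference
optimum used to calibrate extracts — and suppresses the absolute rate
roughly an order of magnitude relative to the no-uORF leader, whose
optimum sits 0.17 mM higher at this potassium level.  `out/` contains
the per-well rate table (`rates.tsv`), fitted bell parameters per
construct (`curves.tsv`), pairwise optimum comparisons
(`comparisons.tsv`) and a provenance record.

The same flows are available as a library:

```python
from magscan import (annotate, make_leader_fixture, GEOMETRY_PRESETS,
                     load_params_preset, build_construct, closed_form_flux)

ann = annotate(make_leader_fixture(GEOMETRY_PRESETS["trpm7-mouse-like"], seed=1))
[(u.start, u.length_nt, u.overlap_nt, u.context.cls) for u in ann.uorfs]
# [(101, 390, 206, 'strong'), (217, 63, 0, 'adequate')]

params = load_params_preset("paper2014")
wt = build_construct("M7-Luc-M7")
closed_form_flux(wt, params, 0.6, 60.0).reporter_flux / \
    closed_form_flux(wt, params, 1.4, 60.0).reporter_flux
# ≈ 10.1 — the leader derepresses ten-fold as Mg drops from 1.4 to 0.6 mM
```

`magscan fit-model --seed 0 --out params.yaml` refits the scanning
model to the printed constraint set and prints the per-constraint
misfit report.

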