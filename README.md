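# probeval

Evaluation toolkit for transcriptome-scale RNA chemical-probing data
(DMS/SHAPE, RT-stop and mutational profiling).

Chemical probing reads out RNA structure in living cells: a reagent
modifies accessible (mostly unpaired) bases, and the modifications are
detected either as reverse-transcription stops (SEQ) or as mutations
introduced during reverse transcription (MaP). `probeval` takes the
per-position event counts such experiments produce and answers the
questions an analyst asks of them:

* **Reactivity** — raw per-base rates, `Mrate = Mnum / Mdepth` for
  mutational profiling and `STrate = STnum / STdepth` for RT-stop
  profiling (the denominator is reads informative at the position),
  with optional background adjustment
  `rate(probe+) − rate(probe−)`, a strict coverage filter (depth > 500),
  the DMS A/C base restriction, and the ≥ 50-well-covered-bases
  inclusion rule for mRNAs.
* **Structure concordance** — ROC/AUC against a reference dot-bracket
  structure with the *unpaired* base as the positive class
  (AUC = P(reactivity of a random dot > reactivity of a random bracket),
  ties at half credit), the top-*x*% unpaired fraction, rate histograms,
  and class-conditional summaries with an overlap coefficient.
* **Ensemble pairing probabilities** — marginals m\[i\] = Σ\_j p\[i\]\[j\]
  from imported base-pair probability matrices, plus an exhaustive toy
  ensemble (every nested structure, weighted w^#pairs) as a built-in
  oracle, and flagging of discordant bases (marginal ≥ 0.995 yet
  top-10% reactivity).
* **Solvent accessibility** — an in-repo Shrake–Rupley implementation
  with a 3 Å probe on RNA coordinates from PDB files, per-residue
  relative accessibility, and reactivity–accessibility Pearson
  correlations stratified by reactivity rank or pairing state.
* **Simulation** — a generative model of probing experiments from a
  known structure (single-hit kinetics, 3'-most-modification censoring
  of RT stops with its 5' detection bias, natural stops, sequencing
  errors, independent background channel), with closed-form expected
  rates for validation.

The package ingests count tables; read mapping and deduplication are
upstream of it.

## Worked example

Simulate a realistic "overlap" experiment (200-nt RNA, 45% unpaired,
partially overlapping class rate distributions, 100 000 molecules),
compute reactivity, and score it against the ground-truth structure:

```
$ printf 'scenario=overlap\nseed=7\n' > sim.cfg
$ probeval simulate --config sim.cfg --out-dir run
$ probeval react --plus run/plus.tsv --probe SHAPE --out run/reactivity.tsv
$ probeval evaluate --reactivity run/reactivity.tsv \
      --structure run/structure.db --out run/report.json
```

`run/report.json` then contains (abridged):

```
auc                  0.7821717171717171
n_pos                90        # valid unpaired bases
n_neg                110       # valid paired bases
fraction_rate_ge_0.1 0.065
top_x_curve          [[5, 1.0], [10, 1.0], [20, 1.0], [30, 0.883...], ...]
class_summary.overlap 0.4717...
```

Reading: reactivity ranks unpaired above paired bases far better than
chance (AUC 0.78) but imperfectly, because the class rate distributions
overlap (overlap coefficient 0.47); only 6.5% of bases exceed rate 0.1,
yet *every* base in the top 10–20% of reactivity is truly unpaired —
high reactivity is a reliable unpaired signal even when most of the
profile is silent. The same operations are available as library calls
(`probeval.roc_auc`, `probeval.top_fraction_unpaired`, …) on profiles
read from TSV via `probeval.read_counts_tsv` / `read_reactivity_tsv`.

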