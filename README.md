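# emapkit

Analysis of quantitative genetic-interaction screens (E-MAPs, epistatic
miniarray profiles) for systems biologists running systematic double-mutant
colony arrays: from replicate colony sizes of [query × array] crosses to
S scores, interaction-profile correlations, chemogenetic (drug vs control)
differential calls, and detection of chromosomally clustered artifact
interactions caused by undeclared suppressor mutations.

## The model

Under the multiplicative neutral model, a double mutant's expected colony
size is the product of the single-mutant effects; a genetic interaction is a
deviation from it. After plate-median normalization, each cross (query *q*,
array *a*) is scored with the modified t-statistic of the E-MAP tradition:

```
S_qa = (mean_obs − μ_a) / sqrt(σ_a²/n_ctrl + max(s²_qa, σ_floor²)/n_obs)
```

where μ_a and σ_a are robust (median / scaled-MAD) control statistics of
array gene *a* across all queries, s²_qa is the cross's own replicate
variance, and σ_floor is the screen-wide median spread (flooring keeps
accidentally tight replicates from reaching absurd significance). Negative S
= synthetic sick/lethal; positive S = alleviation/suppression. Scores from
reciprocal crosses [q × a] and [a × q] are averaged; P values come from an
empirical null (robust standardization of the S distribution, which is
dominated by non-interacting pairs) or optionally from a permutation null.

On top of the matrix sit: profile correlations (Pearson similarity of two
genes' interaction profiles, excluding their mutual entry), significance
classification at P ≤ 0.005 (S) / P ≤ 0.05 (correlation), hierarchical
clustering, windowed S-vs-correlation curves, aggravated/alleviated calls
between conditions, linkage masking of same-chromosome pairs < 100 kb apart,
and a genome-ordered scan for contiguous runs of genes uniformly interacting
with one distant gene — the signature of an undeclared suppressor lost
through linkage to the selected array marker.

A synthetic-screen generator with a fully recorded ground truth
(interactions, drug shifts, noisy strains, suppressors) backs all recovery
tests; see `docs/methods.md` for its assumptions.

## Worked example

```python
from emapkit import EMapScreen, SimConfig, simulate_screen

truth, grids = simulate_screen(SimConfig(), seed=1)   # 120 genes, control+drug
res = EMapScreen(grids, truth.loci).fit()
print(res.summary())
```

```
E-MAP screen fit
================
genes: 120   conditions: control, drug
thresholds: P(S) <= 0.005, P(corr) <= 0.05, linkage < 100 kb, region cut S < -3.0

condition    tested    neg    pos  masked  noisy  recip_r  bonferroni
control        6700     89     78     440      0    0.478   7.463e-06
drug           6700     98     80     440      0    0.466   7.463e-06

differential: 11 aggravated, 10 alleviated (|ΔS| >= 2.0, gated at P <= 0.005)
```

Of 7,140 gene pairs, 440 are linkage-masked, leaving 6,700 tested; the
~90/80 significant negative/positive counts recover the planted 2%
interaction rate, `recip_r` is the reciprocal-cross concordance of unaveraged
scores, and the 21 differential calls recover the 20 planted drug shifts.
The planted suppressor shows up as one region call:

```python
(call,) = res.detect_regions("control")
call.distant_gene, call.chromosome, call.run_length, round(call.median_S, 1)
# ('g078', 'chr1', 10, -7.6)
```

a 10-gene block whose members all score ≈ −8 with one strain on another
chromosome — colony sizes, not biology. `res.region_null_rate()` calibrates
how often positional chance alone produces such a call, and
`res.genome_heatmap("heatmap.png")` draws the genome-ordered matrix with
masked cells in grey.

The same pipeline is scriptable: `emapkit simulate|score|qc|correlate|diff|
regions|report`, each taking `--config` (TOML), `--seed` and `--out`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline on the reference synthetic screen — simulation,
fitting, differential comparison, region detection — printing the fit
summary and writing the results JSON. The statistical acceptance checks
(null calibration, reciprocal concordance, oracle equivalence of the core
numerics, suppressor-region and differential recovery) live in
`tests/test_acceptance.py`.
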