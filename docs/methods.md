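# Methods

## Scoring model

Colony sizes are strictly positive and right-skewed, and most gene pairs do
not interact. Both facts shape every numerical choice below.

**Normalization.** Each plate is rescaled so its median colony size equals
the screen's global median. In the simulated reference world a plate holds
one query's crosses, so plate scaling simultaneously removes the plate
effect and the query's single-mutant fitness. An optional row/column median
polish in log space (two sweeps) removes residual linear gradients; it is
off by default because the reference world plants none.

**Control statistics.** For each array gene, the expected size is the median
of all its replicate measurements across queries and the spread is the
scaled MAD (× 1.4826) of the same values. Medians and MADs are used instead
of means and SDs because true interactions contaminate the column; at the
default 2% interaction rate they never displace the central order
statistics. Spreads are floored at the screen-wide median spread; the floor
itself is floored at 1e−9 × the global median size so that a noise-free
screen still produces finite scores (and, because the epsilon scales with
colony size, S remains invariant under global rescaling). Array genes with
fewer than 4 usable crosses are flagged missing.

**S score.** The modified t-statistic

S = (mean_obs − expected) / sqrt(spread²/n_ctrl + max(var_obs, floor²)/n_obs)

with n_ctrl equal to the replicate count (4). Per-direction scores from the
reciprocal crosses are averaged; single-direction pairs are kept but flagged.
Under the null this statistic has standard deviation ≈ 0.5 (not 1): the
spread term in the denominator is conservative. Significance therefore never
reads S directly.

**Significance.** The default empirical null robust-standardizes the full
unflagged S distribution (median / scaled MAD) and evaluates two-sided tails
against the standard normal; this presumes the bulk of pairs are
non-interacting, which holds by design in the reference world and by biology
in real screens. A permutation null (shuffling which query each cross
belongs to within every array column; 2000 rounds, seeded) is available for
screens too small (< 50 scored pairs) to estimate an empirical null. On
pure-null simulations the empirical route is calibrated at the working
threshold: the fraction of pairs with P < 0.005 sits within 3 binomial
standard errors of 0.005 at 10⁴ pairs (asserted in the acceptance suite).

**Quality control.** A strain's reliability is measured by its reciprocal
discordance: the median over partners of |s_qa − s_aq|. Strains above
k_noisy (default 3) times the screen-wide median discordance are flagged;
statistics are recomputed once without them and the criterion applied a
second time, then the procedure stops — one iteration keeps it deterministic
and order-independent. Flagged strains' pairs are excluded downstream but
their S values are retained (flag, never impute), so removal cannot change
any other pair's score.

## Network layer

Profile correlations are pairwise-complete Pearson correlations of two
genes' S profiles, always excluding the mutual entries S[i,j] (a single
strong interaction must not certify its own profile similarity) and all
flagged cells; P values use the t transform with n_used − 2 degrees of
freedom, uncorrected except for a reported Bonferroni reference line.
Windowed curves along the correlation axis (mean significant S; ratio of
significant positives to negatives) use non-overlapping chunks of 10 pairs
by default; a rolling mode is provided because "a window of k values" is
ambiguous, and the choice only smooths, never moves, the knee. Ratio windows
without negative scores report missing, not infinity. Clustering is
average-linkage on distance 1 − r with missing correlations treated as r = 0
and genes presorted lexicographically so the tree is a deterministic
function of the values.

Hyper-interactors are genes whose significant-interaction count exceeds
mean + 2 SD of the per-gene counts **and** covers at least 25% of their
possible partners. The fraction condition is what distinguishes a strain
that interacts throughout the map (the phenomenon the flag names; ≥ 30% of
partners in the sensitivity fixture) from ordinary Poisson fluctuation of
counts and from a suppressor artifact block (at most one linkage window ≈
10 genes plus the base rate, ≈ 17% worst case in a 120-gene screen) — both
of which a pure mean + k·SD rule flags spuriously.

## Differential comparison

ΔS = S_drug − S_control per pair, over pairs unflagged in both conditions.
Calls require |ΔS| ≥ min_delta (default 2.0 — chosen so the published
example of a strong interaction deepening by 0.9 is correctly "unchanged"),
significance (P ≤ 0.005) in the anchoring condition (drug for AGGRAVATED,
control for ALLEVIATED), and a negative anchoring score: aggravation and
alleviation describe synthetic sickness created or relieved, so changes
among positive interactions are deliberately left out of this vocabulary
(without the sign condition, a strong positive interaction drifting between
conditions is mislabeled). With null S noise of sd ≈ 0.5 per condition the
gating has an intrinsic false-call probability of ≈ 5 × 10⁻⁴ per pair —
regression to the mean lets a barely significant anchor coincide with an
extreme delta. A differential-recovery experiment must therefore be sized so
planted shifts are not swamped: the acceptance experiment uses a 60-gene
screen (1,770 pairs, expected ≈ 1 false call) with 20 planted shifts of
|Δε| = 0.45, which at 15% noise and 4+4 replicates gives |ΔS| ≈ 4.2 = 2 ×
min_delta by the closed form ΔS ≈ Δε / (cv·sqrt(1/n_ctrl + 1/n_obs)). At
the 120-gene default world the same gating yields precision ≈ 0.87 — a
property of the fixed thresholds, not of the implementation.

The axis-artifact scan flags pairs significant in exactly one cross
direction (score beyond the empirical-null bound in one orientation, inside
it in the other) and reports the drug/control excess ratio.

## Genome-order layer

Pairs on the same chromosome with start coordinates closer than 100 kb
(strict inequality) are masked as linkage, excluded from significance
counts, correlations and region calls. Coordinates are 0-based half-open;
a gene's representative position is its start.

The suppressor-region scan walks each chromosome in genome order for every
candidate distant gene and collects maximal runs of consecutive genes with
S below region_s_cut (−3.0, the published edge-of-region magnitude; a
single cut with reported min/median S rather than a two-tier edge/center
rule). Runs of ≥ region_min_run (5) genes become calls; missing cells are
skipped without breaking a run by default (a failed cross should not split
a real region; `missing_breaks_run` inverts this), runs touching the
distant gene's own linkage window are discarded as linkage signal, and
hyper-interactors are excluded as distant genes only — region members may
be anything. region_min_run = 5 balances the planted 10-gene fixture
against the permutation null: published examples span roughly 4–12 genes.
The permutation null re-assigns genes to loci (re-deriving the linkage
mask each round) and reports the mean and 95th percentile of call counts,
so a real call can be judged against positional chance.

## The synthetic world

The generator emulates exactly the structure the analysis assumes:
multiplicative double-mutant fitness with interactions as (1 + ε);
lognormal replicate noise at CV 0.15; per-plate scale factors (lognormal,
sd 0.1, one plate per query row); single-mutant fitness uniform in
0.7–1.0; 120 genes on 4 chromosomes spaced 20 kb; 2% of pairs interacting
with |ε| in 0.3–0.6, signs balanced; 20 drug shifts (half new synthetic
sickness at Δε = −0.45 on neutral unlinked pairs, half full alleviations
Δε = −ε of planted sick pairs — an alleviation is only observable on an
interaction that exists without the drug); and one suppressor. The
suppressor locus sits midway between two genes so that exactly 10 genes lie
within the 100-kb linkage window; the carrier (on another chromosome) is
restored by the suppressor to its originally drawn fitness
(single_fitness = draw / rescue_factor, rescue_factor 6), and the rescue is
lost — deterministically, no recombination gradient — whenever the carrier
is crossed against a linked partner, in either orientation, collapsing the
cross by the full factor and producing the planted region at S ≈ −8.
Noisy strains carry a per-cross multiplicative bias (lognormal, CV =
10 × noise_cv, shared by the cross's replicates): iid replicate noise alone
is absorbed by the score's own variance term, so an unreliable strain is one
whose crosses are biased, not merely scattered.

What the generator does not emulate — and green tests therefore do not
establish robustness to: spatial plate gradients beyond a per-plate scale
(an optional linear column gradient exists for testing the polish),
batch effects across screen repetitions, non-lognormal outliers (pinned or
merged colonies), linkage decaying smoothly with distance, or biologically
structured interaction networks (planted interactions are uniform random
pairs, so clustering tests use constructed block fixtures instead).

The exact noise-free limits (all non-planted S exactly 0; reciprocal
correlation exactly 1) hold in the noise-free preset with uniform fitness
(noise_cv = 0, fitness_sd = 0, plate scales active). With drawn fitness they
hold only approximately: median normalization removes a multiplicative row
or column effect exactly only while planted outliers never displace the
central order statistics, and the ~0.3% residuals this leaves are invisible
under real noise but dominate a noise-free screen, whose significance floor
is the epsilon scale.

## Known limitations

- The empirical null assumes the S bulk is null; screens where most pairs
  interact need the permutation route.
- The region scan names regions, not suppressor genes; identifying the
  suppressor inside a called region is follow-up biology.
- compare_conditions reports only pairs measured in both conditions;
  one-condition pairs are counted and logged, not called.
- Correlation P values ignore the dependence between overlapping profiles;
  they are screening P values, as in the tradition this follows.
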