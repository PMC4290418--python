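# Methods

## Model and assumptions

The unit of value is expected surviving phylogenetic diversity (EPD) at a
future horizon. The model assumes:

* a rooted, time-scaled phylogeny (Myr) with no stem edge; strictly
  bifurcating trees have exactly 2n − 2 edges, and all calculations sum over
  those edges;
* independent tip extinctions, with per-tip probabilities given by a Red
  List category → probability transformation over a stated time window;
* an edge survives iff at least one descendant tip survives, giving the
  daughter-product recursion p(i) = p(j)·p(k) and
  EPD(T) = Σ L_i (1 − p(i)).

ADEPD(j) = EPD(DL(T, j)) − EPD(T) values one-category downlisting of
species j. Because downlisting changes probabilities only on j's root path,
the implementation updates that path (O(depth) per species, products
re-formed from children rather than divided, so zero probabilities are
safe); the test suite pins its equality with full recomputation at 1e-9
relative tolerance. ADEPD-cost divides by the downlisting cost c_j
(Myr/USD); 1e-6 Myr/$ = 1 year of PD per dollar.

## Risk transformations

Built-ins: IUCN50 (default; LC 0.00005, NT/DD/NE 0.004, VU 0.05, EN 0.42,
CR 0.97, EW 1, 50-year window), IUCN500, a pessimistic scenario, and the
ordinal GE weights used only inside EDGE = ln(1 + ED) + GE·ln 2. DD and NE
are treated as NT (the category they are most likely to be reassessed into);
EW is certain extinction. GE's EW entry is 6 as printed in the source table;
it never enters probability computations (GE is refused there) and EW
species cannot appear in a costed cohort. Custom transforms load from
`category=probability` files for sensitivity analysis; every probabilistic
transform must be monotone along LC ≤ NT ≤ VU ≤ EN ≤ CR ≤ EW. Downlisting
DD/NE/LC is an error rather than a silent no-op.

## Prioritization procedure

Per tree, the greedy complementarity pass repeatedly (1) computes the
instantaneous ADEPD-cost of every remaining cohort species on the current
partially-downlisted state, (2) downlists the argmax, (3) records that
species' score at selection time. Recorded scores are averaged across the
tree distribution and species ranked by the average; per-tree sequences can
be dumped. Argmax ties break lexicographically on species label —
deterministic and seed-free. The spending curve downlists in rank order,
recording cumulative cost and mean ± sample SD (over trees) of the EPD gain;
its derivative is the forward difference Δgain/Δcost between consecutive
events, the natural grid. The curve endpoint is order-independent (verified
against downlisting everything at once). The current-spending projection is
linear: per tree, species j contributes e_j · ADEPD_j / c_j for past
expenditure e_j; missing expenditures count as zero with a logged warning.
The linear model is deliberately uncapped — extrapolated gain can exceed the
full-downlisting gain when e_j > c_j — with an optional per-species cap at
ADEPD_j for users who find that implausible. Ranking comparisons use Pearson
correlation on rank vectors (two-sided p), optionally restricted to the
*first* ranking's top k; correlating raw scores instead is exposed as an
option. k < 3 is an error.

Budget interpolation (`gain_at_budget`) funds whole events and a linear
fraction of the first unaffordable one; only whole-event points are written
to the curve CSV.

## Polytomies and tree handling

Multifurcations are accepted with a warning — the survival product
generalizes to all children — and a strict mode rejects them; how best to
resolve polytomies for prioritization is an open question, so both
behaviours are available. A stem edge above the root is dropped (warning);
its length never enters PD or EPD. Tip labels are normalized
(whitespace → underscore) before matching species tables; a cohort species
absent from any tree is a hard load-time error. Branch lengths are assumed
Myr; a scale factor converts other units on load.

## Synthetic data

The generator emulates the structure of the real inputs the method targets —
a distribution of ultrametric avian phylogenies, Red List statuses, and an
expert-costed threatened cohort — without any download:

* **Trees**: pure-birth (Yule) at rate 0.05/Myr, stopped at n tips, stem
  discarded; expected total branch length ≈ (n − 2)/λ, verified in tests.
  Yule was chosen over birth–death for simplicity; real phylogenies are more
  unbalanced than Yule trees, so topological imbalance effects are
  under-represented.
* **Statuses**: i.i.d. by the global avian Red List tally (7656 LC / 877 NT /
  59 DD / 111 NE / 710 VU / 393 EN / 183 CR / 4 EW of 9993). Real threat is
  phylogenetically clustered; i.i.d. assignment understates complementarity
  effects, which is why dedicated sister-pair fixtures test those directly.
* **Cohort**: threatened (VU/EN/CR) tips, stratified toward a 102:65:39
  CR:EN:VU mix when subsampled; log-normal costs (median $1M, σ_ln 2.3,
  spanning ~4 orders of magnitude, mirroring the contrast between
  condor-scale and laughingthrush-scale programmes); expenditures are a
  log-normal fraction of cost (median 0.15, σ_ln 0.8) zeroed with
  probability 0.03 (matching the reported <3% of species with no funding).
* Everything is a pure function of (config, seed).

Passing tests on these data demonstrate the machinery's correctness, not
field performance: real trees are larger, unbalanced, and their statuses,
costs and expenditures are mutually correlated in ways the generator does
not model.

A six-tip worked fixture with every quantity (EPD, ADEPD, greedy order,
curve, projection, ED) derived by hand in decimal arithmetic is shipped in
`adepd.simulate` and exercised end-to-end through the CLI.

## Numerical choices

Probabilities are multiplied in linear space — at desk-to-study tree depths
the products stay far from underflow, and products are re-formed from
children on update rather than divided, avoiding 0/0. Oracle equalities are
asserted at 1e-9 relative; Monte-Carlo agreement at 3 standard errors of
100 000 draws. Sample SDs use ddof=1 and report 0 for a single tree.
Currency conversion uses a single configurable USD↔GBP rate (default
1.6667); a year of PD is 365 days for hours-per-dollar conversions.

## Problem sizes

Tests and the acceptance script run the full method on 10–96-tip trees and
distributions of up to 300 trees, the package's chosen desk-scale study
analogue; the implementation itself is O(trees × cohort² × depth) in the
greedy pass and handles larger inputs without modification.

## Known limitations

Single-step downlisting only (funds for one downlisting are not assumed to
buy two); no HEDGE/HED scoring; no exact knapsack/ILP solution of the
underlying allocation problem (greedy only); no cost sharing between
sympatric species; no modelling of status misclassification or of
uncertainty in cost estimates; independence of tip extinctions ignores
spatially or ecologically correlated threats.
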