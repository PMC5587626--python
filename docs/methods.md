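# Methods

`spingroup` implements three cooperating pieces: a peak-list registration
analysis (self and pairwise), a variance-informed DBSCAN that groups peaks
of one list into spin systems, and a peak-list simulator used to validate
both. This note records the models, the parameters that matter, and the
numerical choices made where the design was genuinely open.

## Registration analysis

Given an "input" and a "root" peak list (the same list twice in self mode),
registration seeks the peak mapping that makes the two lists' internal
geometry agree. A candidate mapping `(i, j)` is *supported* by another
mapping `(m, n)` when, in every comparable dimension `l`,

    |(input_i[l] − input_m[l]) − (root_j[l] − root_n[l])| ≤ t · std[l],

with `t = 4` standard-deviation units by default. The support set SS_{i,j}
collects all such `(m, n)`. Candidates are ranked by a robustness score

    robustness(i, j) = Σ_{(m,n) ∈ SS_{i,j}}
        |SS_{i,j} ∩ SS_{m,n}| / |SS_{i,j} ∪ SS_{m,n}| · p_χ²(i, j, m, n),

the Jaccard similarity between support sets weighted by the upper-tail
chi-square probability of the difference-of-differences statistic

    χ²(i,j,m,n) = Σ_l ( Δ_l / (std[l] · f) )²,   f = 2 by default,

at `df` = number of comparable dimensions. `f = 2` rather than the √2 of
independent error propagation reflects non-independent error propagation in
the difference-of-differences; `f = √2` is selectable
(`RegistrationConfig(std_factor=...)`). The support list of the most robust
candidate becomes the matched pairs; per-dimension offsets and stds are
computed from them, and the loop repeats with the refreshed stds until the
maximum relative std change falls below `convergence_tol` (1e-3) or
`max_iterations` (20) is hit.

Implementation: with `v_{i,j} = input_i − root_j` restricted to comparable
dimensions, `(m,n) ∈ SS_{i,j}` iff `|v_{i,j} − v_{m,n}| ≤ t·std` per
dimension, so support sets are Chebyshev-box neighborhoods among the
`n_input · n_root` difference vectors; a k-d tree provides the neighbor
graph. The robustness arg-max uses the exact bound `robustness(P) ≤ Σ
supporter probabilities` to evaluate candidates in descending bound order
and stop early; results equal direct evaluation (property-tested against an
O(n⁴) brute force). Ties are broken by larger support, then smallest
`(i, j)`.

### Conventions and numerical choices

* **Offsets** translate the input list onto the root list:
  `offset = mean(root − input)` over matched pairs. Self mode pins offsets
  at zero (no translation is modelled between a list and itself).
* **Per-peak std convention.** In self mode each matched pair is a
  difference of two equally noisy coordinates, so the scale of the raw
  differences is √2·σ. Matched pairs are canonicalized to `m < n` (each
  unordered pair would otherwise appear in both orders), pooled about zero,
  and the scale estimate is divided by √2; the reported stds therefore
  estimate the *per-peak* positional σ. All downstream consumers (support
  tolerance, chi-square scaling, grouping cutoff) use this convention.
* **Robust scale estimator.** The per-dimension std is estimated by the
  normal-consistent median absolute deviation (1.4826·MAD) rather than the
  sample standard deviation (selectable via `std_estimator="rms"`). The
  pipeline poses a peak list as a mixture of variance populations; tier-1
  registration must estimate the scale of the *smallest-variance*
  population, and a sample std over the matched pairs absorbs the heavy
  population (plus box-edge spurious matches), inflating the grouping
  tolerance of exactly the tier that should be tight. On single-population
  data the two estimators agree to sampling error.
* **Initial stds** (before any statistics exist): 0.02 ppm for H-labelled
  dimensions, 0.2 ppm for C/N dimensions — typical matching tolerances in
  assignment practice; overridable per run.
* **Std floor** of 1e-6 ppm keeps the statistics finite on duplicate-rich
  (e.g. zero-variance simulated) lists.
* **One-to-one mapping**: the best candidate's support list may reuse a
  peak; conflicts are resolved greedily by descending chi-square
  probability, then lexicographically (deterministic).
* Chi-square probabilities within an iteration use that iteration's current
  stds. Registration fails (a signal, not a crash) when no candidate has
  support or fewer than two matched pairs survive; fewer than three sets a
  low-confidence flag.

## Grouping

Peaks of one list are clustered by DBSCAN in which the Euclidean region
query is replaced by the variance-normalized distance

    d(i, j) = sqrt( Σ_k ((peak_i[k] − peak_j[k]) / std[k])² )   over comparable dims,

and the radius by the chi-square quantile `sqrt(F⁻¹(p, df))` with
`p = 1e-4` by default (`F⁻¹` = upper-tail/inverse-survival quantile, i.e.
membership is a statistical test at level `p` given the per-dimension
variances supplied by self-registration). `min_points = 2` (the query peak
counts itself, as in canonical DBSCAN) because HN(CO)CACB spin systems
carry two peaks; a glycine predecessor contributes a single CA peak that
legitimately stays unclustered. Peaks are visited in file order; a border
point reachable from two clusters joins the first discovered — the
deterministic source of the overlap-vs-split asymmetry in evaluation.

With `min_points = 2` every non-isolated point is core, so clusters are the
connected components of the cutoff graph; the implementation is plain
DBSCAN nonetheless so larger `min_points` behaves classically
(property-tested against a textbook oracle and cross-checked against
scikit-learn's DBSCAN).

## Combined pipeline

Tier loop: self-register the current peak set → group with the recovered
stds → move clustered peaks into the results → repeat on the unclustered
remainder. Termination: fewer than `2·min_points` peaks remain, a tier
forms no cluster, registration fails, or `max_outer = 5` tiers. Later tiers
warm-start registration at 3× the previous tier's stds (the remaining
population is expected to be wider); each cluster records its tier so
evaluation can attribute accuracy per variance population.
`single_iteration_mode` stops after one pass and exists for the
iterative-vs-single comparison.

## Simulator

`synth_assignments` draws a random sequence (approximate natural amino-acid
frequencies) and per-atom shifts from per-residue-type Gaussian priors
(amide H 8.3 ± 0.6 ppm; amide N 119.9 ± 4.2, glycine 109.8 ± 3.3; CA/CB
per residue type; CO ≈ 176.5 ± 1.9). Glycine carries no CB, proline no
amide H. These priors emulate the per-atom-class spread of assigned
protein shifts; they do **not** reproduce the sequence- and
structure-driven correlations of real proteins, nor artefact peaks, missing
assignments, or intensity information — so passing benchmarks demonstrate
algorithmic behaviour under controlled positional variance, not performance
on any particular experimental data set.

`ideal_peaklist` expands a declarative spectrum description (per-dimension
resonance-class alternatives at relative residue positions; the `CX`
pseudo-class covers CA/CB/CO — a documented simplification of full
side-chain coverage) into the 0-variance peak list, labelling every peak
with its true spin-system id (the anchor residue index). For HN(CO)CACB:
residue `i` with an amide and an existing predecessor yields
`(H_i, N_i, CA_{i−1})` and, unless residue `i−1` is glycine,
`(H_i, N_i, CB_{i−1})`.

Noise is `N(0, σ)` per dimension (Box–Muller via NumPy's generator,
seeded). The two-source mixture flags `round(0.2·N)` peaks — sampled per
peak, so the two peaks of one spin system can land in different
populations — and multiplies their σ by 5 in the selected dimensions.
Cohort filters mirror the simulation-set construction: reject proteins
whose ideal list contains exact duplicate peaks, or a missing CA/CB on a
contributing non-glycine residue. Grid defaults run σ_H 0.001–0.050 ppm
and σ_C/σ_N 0.01–0.50 ppm over 50 joint steps.

### Expected-count formulas

The closed forms for HN(CO)CACB —
peaks `= (L − nPro − nGly)·2 + nGly − 1`, spin systems
`= L − 1 − nGly − nPro` — assume no leading proline, no glycine–proline
dipeptide imbalance and no terminal glycine; `expected_counts(...,
exact=True)` enumerates the generation rule instead and holds exactly for
any sequence (the property the test suite asserts on random sequences).
Degenerate formula inputs are floored at 0 with a warning.

## Evaluation

Each groupable true system (≥2 observed peaks) is classified as identified
(cluster = exactly its peaks), partial (cluster ⊂ its peaks), overlapped
(all its clustered peaks in one mixed cluster), split (spread over ≥2
clusters) or missing (no peak clustered); categories are disjoint and
exhaustive. Singleton systems (glycine CA peaks) are expected-ungrouped and
reported separately. Percentages are reported with two denominators: all
truth-labelled peaks, and groupable peaks only; the benchmark numbers use
the groupable denominator, since singleton peaks can never satisfy
`min_points = 2`. Curve aggregation reports mean ± SEM (sample std/√n)
across peak lists per noise level; a single list yields SEM 0 with a flag.

## Benchmark problem sizes

The bundled benchmarks (acceptance script and heavy tests) use 50 synthetic
proteins of 60–120 residues (≈110–230 peaks per list) per noise condition —
the package's reduced-scale stand-in for a repository-wide cohort. On this
cohort the pipeline groups ≈99% of groupable peaks at the lowest
single-source noise, ≈81% at the high single-source level, and ≈63–66%
under the two-source mixture at base σ_H = 0.01 ppm (the acceptance script
and the heavy tests recompute these, with cohort-seed variation of a few
points on the mixture condition). The dominant loss mechanism at the
mixture's top level is spin-system overlap at the 5× noise scale, which is
bounded by how crowded 60–120-residue synthetic amide maps are rather than
by the variance-estimation loop.

## Known limitations

* Simulated positions only: no artefact peaks, intensities, lineshapes or
  missing-data patterns; evaluation on simulated data treats simulator
  output as the complete observed set.
* Registration cost grows with the square of the peak count (difference
  vectors) and with the support-graph density in the first iteration;
  lists of a few hundred peaks register in seconds, thousands would not.
* Translation equivariance of pairwise registration is exact in the
  mathematics but, on lists containing duplicate comparable coordinates
  (ideal spin-system pairs), floating-point perturbations can flip
  near-tied arg-max candidates and change the matched set slightly.
* The NMR-STAR route is a container-level adapter (`AssignedShiftTable`
  accepts externally parsed tables); no NMR-STAR parser is bundled.
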