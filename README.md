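# spingroup

Peak-list registration analysis and variance-informed spin-system grouping
for protein NMR, with a peak-list simulator for validation.

Grouping the peaks of a triple-resonance peak list (HN(CO)CACB, NCACX,
NCOCX, ...) into spin systems is the first step of automated resonance
assignment, and it normally forces the user to guess per-dimension match
tolerances. Worse, experimental peak lists usually mix *several* sources of
positional variance: a subset of peaks groups cleanly under tight
tolerances while another subset needs loose ones, and no single uniform
tolerance serves both. `spingroup` is for NMR spectroscopists and
assignment-pipeline developers who want those tolerances *measured from
the data* and the mixture handled explicitly.

## The method

**Registration analysis** estimates per-dimension offsets and standard
deviations by finding the most self-consistent peak mapping between an
input and a root peak list (the same list twice in self mode, where offsets
are fixed at zero and the statistics describe within-spin-system scatter).
A candidate mapping (i, j) is supported by (m, n) when, per comparable
dimension l,

    |(input_i[l] − input_m[l]) − (root_j[l] − root_n[l])| ≤ 4·std[l],

and candidates are ranked by the robustness score

    robustness(i,j) = Σ_{(m,n)∈SS_ij} |SS_ij ∩ SS_mn| / |SS_ij ∪ SS_mn| · p_χ²(i,j,m,n),

a Jaccard-weighted sum of chi-square probabilities of the
difference-of-differences statistic (scaled by `std·2`; √2 selectable).
The best mapping's matched pairs yield fresh stds and the analysis iterates
until they converge.

**Grouping** is DBSCAN with the region query replaced by the
variance-normalized distance and a chi-square cutoff: peaks i, j are
neighbors when

    sqrt( Σ_k ((peak_i[k] − peak_j[k]) / std[k])² ) ≤ sqrt(F⁻¹(p, df)),

with `p = 1e-4` and `min_points = 2` by default, std[k] supplied by
self-registration.

**The combined pipeline** peels variance populations off tier by tier:
self-register → group → re-register the unclustered remainder to find the
next, larger variance → group again — posing the peak list as a linear
mixture of normal-like populations.

**The simulator** builds ideal peak lists from assigned-shift tables
through declarative spectrum descriptions (resonance classes at relative
residue positions, JSON-configurable), adds per-dimension Gaussian noise —
optionally a two-source mixture with 20% of peaks at 5× σ — and ships a
synthetic assigned-shift generator, so everything runs without external
data. An evaluation module scores groupings against truth
(identified/missing/overlapped/split systems, grouped/overlapped peak
percentages with SEM across lists).

## Worked example

```python
from spingroup import *
from spingroup.simulator import sigmas_for

spec = builtin_description("HNcoCACB")
table = synth_assignments(80, seed=42)            # 80-residue synthetic protein
ideal = ideal_peaklist(table, spec)
noisy = add_noise(ideal, NoiseModel(sigmas_for(spec, 0.005, 0.05, 0.05),
                                    fraction_high=0.2, multiplier=5.0, seed=7))

reg = register(noisy, mode="self")
print(reg.stats.stds, reg.stats.n_matched)

result = run_pipeline(noisy)
rep = score_grouping(result, noisy)
```

prints (this exact run):

```
peaks: 139 expected: (139, 67)
self-registration stds: (0.0053, 0.0626) n_matched: 54 iterations: 3
tier 1: stds=(0.0053, 0.0626) clusters=54
tier 2: stds=(0.027, 0.2134) clusters=10
unclustered: 6
identified 60/67 spin systems; 89.6% of groupable peaks grouped, 9.0% overlapped
```

Reading it: the list carries base noise σ_H = 0.005, σ_N = 0.05 ppm on 80%
of peaks and 5× that on 20%. Tier-1 self-registration recovers stds close
to the base σ in H and N (the comparable dimensions), groups 54 clusters at
those tight tolerances; tier 2 re-registers the leftovers, finds the
~4–5× wider population and recovers 10 more clusters. 60 of 67 two-peak
spin systems come out exactly right; the unclustered remainder is mostly
glycine-predecessor singleton peaks, which can never form a two-peak
cluster.

The same flow is available from the shell:

```sh
spingroup simulate --n-proteins 2 --n-res 60:80 --steps 2 --format json --outdir sims/
spingroup pipeline --input sims/synth-..._step000.json --format json --out clusters.json
spingroup evaluate --clusters clusters.json --peaklist sims/synth-..._step000.json
spingroup register --input peaks.list --self --dims 0,1 --out stats.json
```

## File formats

* **sparky** — `Assignment  w1 w2 [w3 [w4]]` whitespace columns, one header
  line; unassigned peaks labelled `?-?-?`.
* **autoassign** — tab-separated `Index<TAB>w1..wN<TAB>Assignment` with a
  one-line header.
* **json** — full fidelity: dimensions, comparable dimensions, labels and
  (for simulated data) true spin-system ids.

Text formats round shifts to 4 decimals (ppm); all dialects round-trip
through `read_peaklist`/`write_peaklist`.

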