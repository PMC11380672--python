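# Methods

This note documents the models and procedures implemented in `commselect`,
the choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish about real experiments.

## The selection procedure

A *community* is a k-subset of an ordered species pool (default: the
11-species MWF-degrading system, k = 4). A *compatibility map* lists species
pairs that cannot be told apart on selective plates; legal communities
contain no such pair. The default map holds six pairs
(Ct–At2, Af–Ct, Ml–Sw, Ml–Ea, Ac–Pf, Ct–Kp).

Exhaustive enumeration of 4-subsets of 11 species under these six pairs
yields **156** legal communities (330 unconstrained), confirmed by an
independent inclusion–exclusion count. The experimental literature on this
system quotes 174 possible communities under the same six pairs; that number
is not reproducible from the stated constraints (nor is it consistent with
the winning community reported there, which contains the listed pair Af–Ct —
suggesting the published pair list and the figure quoting 174 reflect
slightly different constraint sets). The package always reports the number
it computes and never hard-codes either value.

Each round executes five steps:

1. **Measure** — every community's degradation percent
   `(1 − COD_sample/COD_control) × 100`. Negative values (sample above
   control) are preserved, never clipped at measurement time.
2. **Select and disassemble** — the `top_k` (10) communities with the
   highest *unpenalized* degradation percent are plated; ties break by
   ascending community id. The random control draws its 10 uniformly.
   Plating classifies each inoculated species as survivor or extinction
   (detected iff CFU/ml ≥ `detection_limit`); detected non-inoculated
   species are contaminants and never affect the penalty.
3. **Score** — penalized score = degradation × f, f = survivors/inoculated.
4. **Stock ledger** — each species detected in ≥ 1 plated community is
   re-stocked from the highest-penalized-score such community; species
   detected nowhere carry their previous stock (ultimately an "ancestor"
   sentinel).
5. **Generate** — 29 offspring compositions are drawn with replacement from
   the 10 plated parents in proportion to penalized score (uniformly in the
   random control); 21 of the 29 then receive an invader that replaces one
   resident.

**Two-stage scoring.** The plated set is chosen on unpenalized degradation
(the penalty is only observable *after* plating), while offspring sampling
uses the penalized score. This asymmetry is implemented literally; the
switch `penalty_at_selection` (default false) exposes the alternative, which
in simulation mode — where survival is observable for every community — is
honored exactly.

**Negative scores.** Scores are floored at `probability_floor` (default 0)
before normalization into sampling probabilities. If every floored score is
non-positive the engine falls back to uniform sampling and logs a warning;
how the original experiments handled this corner is not recorded anywhere,
so the floor is exposed as configuration.

**Invasions.** An invader must be absent from the receiving community and
compatible with the three residents remaining after a uniform-random
removal. Species missing from the entire offspring set are introduced first
(coverage), into random designated communities that can legally host them.
Coverage is re-checked after all invasions (a removal can orphan a species)
and repaired by re-drawing, with every repair audited. Two bounded fallbacks
keep the constraints satisfiable: if all legal hosts for a missing species
fall outside the drawn 21-community target set, the target set is redrawn
(cap 200); if *no* offspring admits the species by one legal substitution —
possible when the meta-community converges on compositions that each carry
two of the species' forbidden partners — one designated community is rebuilt
as the closest legal composition containing it. This "coverage override" is
the only event that can exceed one substitution per invaded community; it is
always logged and never occurred in the seeded test sweeps.

**Comparators.** *Propagule* propagates each selected parent's composition
unchanged (round-robin to fill the rack, no invasion); *migrant pool* gives
every offspring the union of the selected parents' members (size constraint
relaxed), which converges toward culturing the whole pool together.

**Determinism.** Every stochastic stage (initial draw, plated choice,
offspring sampling, invasion targets, invader identity, landscape noise)
draws from its own substream, seeded by
`BLAKE2b(master_seed : round : treatment/stage) mod 2³¹`. Identical
configurations replay byte-identically, and changing one stage cannot
perturb another. Audit records carry a logical sequence number rather than
wall-clock time for the same reason.

## The synthetic landscape

The landscape is a deliberately simple single-endpoint model — **it is not
taken from any experimental system's fitted dynamics**. It exists so the
engine can be exercised and benchmarked in silico, and it is the simplest
form able to express the four archetypes the real system displays: strong
degraders, weak degraders facilitated by partners, free-riders, and
competitors that drive partners extinct.

For a community M, each member i realizes a log₁₀ abundance

```
L_i = b_i + Σ_{j∈M, j≠i} A[i][j] + Normal(0, σ_growth)
```

and survives iff `L_i ≥ detection_threshold`. Degradation is additive over
survivors with pairwise epistasis, clipped to [−20, d_max]:

```
D_raw = clip( Σ_{i∈S} d_i + Σ_{i<j∈S} B[i][j] )
```

and the simulated assay reads
`COD_sample = COD_control × (1 − (D_raw + Normal(0, σ_measure))/100)`,
clipped at ≥ 0. Survivor counts are `10^{L_i}` CFU/ml; contaminants appear
independently with probability `contamination_rate` at the threshold
abundance. Only survivors contribute to degradation — a documented
simplification, since a species extinct by day 4 may in reality have
degraded earlier.

Measurement noise acts on the percent scale (not the concentration scale)
so `σ_measure` is directly comparable with the 4–8 percent-point score
standard deviations typical of the COD assay; the default is 5.
`COD_control` defaults to 12 g/l, inside the assay's 1–15 g/l working range
(degradation percent is scale-invariant, so the value is otherwise
arbitrary). `σ_growth` defaults to 0.3 log₁₀ units;
`detection_threshold` to 3.0 log₁₀ CFU/ml, matching the scoring module's
10³ CFU/ml plating floor (the real dilution series bottoms out near there,
though no explicit limit is published).

### Fixtures

- **paper11** — the 11-species benchmark. Monoculture degradation is
  anchored to the printed values of the real system where printed
  (Pf 66, Ct 58, At1 50, Ac 11, Af 2, Ea 2, At2 4); the remaining four
  (Sw 18, Ml 6, Kp 28, Pr 35) are invented mid/low values. Pair totals
  Ac+Pf = 50, Ac+Ct = 46, At1+Ac = 13 are anchored by back-deriving
  `B[i][j] = total − d_i − d_j`; At1+Af = 75 is invented as the
  best-performing pair. Unanchored epistasis follows
  `B[i][j] = −0.6·min(d_i,d_j) − 3` (functional redundancy), with the three
  strong degraders competing harder (At1–Pf −45, Ct–Pf −40, At1–Ct −35) so
  that the landscape peaks below the `d_max` = 95 ceiling, at a unique
  optimum (At1+Af+Ea+Pf, expected penalized score 81.2). Growth motifs:
  At1 boosts Af by +3.5 logs (Af's `b` = 3.2 sits just above the detection
  threshold, so facilitation is what lets it thrive); Pr collapses in the
  presence of At1 (an extinction-prone pair); and the free-rider Ac gains
  +1.5 logs from each of Pf, Ct and At1 while dragging their degradation
  down.
- **additive** — A = B = 0, monoculture effects uniform on [0, 60]: the
  null for exact linear-model recovery and monotonicity checks.
- **killer** — one strong degrader (Sw, d = 60 vs 20 for all others) drives
  every partner extinct (A[·][Sw] = −6): exercises the extinction penalty.
- **flat** — all species identical: pure drift.

### What the benchmarks do and do not show

Passing the simulation benchmarks shows that the *algorithm* behaves as
specified — score-proportional heredity, constraint-respecting mutation,
coverage maintenance, penalty-driven avoidance of aggressive species, and
reliable convergence toward a known optimum on a landscape of realistic
size and noise. It does **not** validate the landscape model itself against
real community dynamics: real systems have time-resolved, higher-order and
resource-mediated interactions, within-species evolution, day-to-day batch
effects and assay saturation, none of which are modelled. The anchored
fixture values are parameterization, not independent measurements, so tests
against them guard the fixture against drift rather than validate the
science.

## Default run configuration

| key | default | meaning |
|---|---|---|
| `n_communities` | 29 | communities per treatment per round (one 30-tube rack minus a control) |
| `top_k` | 10 | communities plated/disassembled per round |
| `n_invaded` | 21 | offspring receiving a one-species exchange |
| `community_size` | 4 | species per community |
| `n_rounds` | 18 | selection transitions (19 measured generations) |
| `master_seed` | 0 | root of all RNG substreams |
| `probability_floor` | 0 | floor applied to scores before normalization |
| `penalty_at_selection` | false | rank plated set by penalized rather than raw degradation |
| `detection_limit` | 10³ CFU/ml | plate-count detection floor |

## Analysis choices

- **Evenness** — ¹D = exp(−Σ pₖ ln pₖ) over *detected* species, normalized
  by the number of detected species S (not the 4 inoculated); a
  single-species community has evenness 1 by convention. The alternative
  denominator is available via the `counts` the caller passes.
- **Representation band** — the one-SD band around the chance expectation
  `window × plated × size / pool` uses the empirical SD of the observed
  per-species counts (the published ±11.8 band is not derivable from a
  stated null); `sd_mode="binomial"` switches to the per-slot occupancy
  null. Counts are reported as counts; mapping them onto a percent axis is
  a presentation choice left to the user.
- **Presence model** — ordinary least squares on 0/1 presence, intercept
  included by default (switchable). Goodness of fit is the Pearson
  correlation between predicted and observed on the regime's test set; both
  r and r² are reported with r² as the headline, since "R²" is used
  ambiguously in this literature. Rank-deficient designs are fitted by
  pseudo-inverse and flagged.
- **Interactions** — log₂ fold-change of the focal species' mean CFU/ml,
  co-culture vs monoculture; the two directions of a pair are estimated
  independently. Significance by Welch's t-test on log counts with
  Benjamini–Hochberg adjustment across all tested pairs; zero counts are
  substituted by the detection limit and flagged.

## Numerical conventions

- Initial-round generation: uniform rejection sampling from the enumerated
  legal set with a coverage repair pass (replace a duplicated slot with a
  community containing the rarest uncovered species); 10,000 attempts, then
  a configuration error.
- All ordering tie-breaks are deterministic: ascending community id for
  score ties, pool (lexicographic) order for composition ties.
- Hamming distance is returned in both conventions simultaneously — the
  fraction of mismatched presence coordinates over the pool, and the number
  of substitutions |a \ b| — because both are in routine use.
- CSV round-trips serialize floats at `repr` precision; plans, score
  sheets, ledgers and audit logs replay byte-identically from a manifest of
  SHA-256 checksums.
- Test problem sizes (20 replicate experiment pairs, 500 invasion rounds,
  10⁴-draw sampling checks) were chosen as the smallest sizes at which the
  corresponding statistical contrasts are decisive.

## Known limitations

- No time-resolved dynamics: the landscape maps composition directly to an
  endpoint; transient extinctions and regrowth cannot occur.
- No within-species evolution: a species is one fixed trait bundle for the
  whole run (the engine has a natural hook point — the stock ledger — but
  it ships disabled).
- The assay model ignores the COD instrument's saturation behavior beyond
  input validation.
- `count_allowed` prunes the inclusion–exclusion lattice by union size; for
  dense forbidden-pair graphs with k near the pool size it can still be
  exponential — enumeration is the right tool there, and the two are
  cross-checked against each other in the tests.
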