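# Methods

## Model and procedure

The pipeline estimates where an invasive, container-breeding mosquito
is most likely to arrive next if its spread is mediated by marine
cargo. It composes four steps:

1. **Connectivity (LSBCI).** Bilateral liner-shipping connectivity of a
   country pair is the mean of five min-max-normalized indicators
   (transshipment count, common direct connections, common
   one-transshipment connections, carrier competition, largest ship on
   the thinnest route). Normalization is per indicator across *all*
   pairs in the supplied table — the normalization population is the
   analysis table itself, and this is deliberate: the original index's
   global normalization population is not public. Consequences: adding
   or removing pairs can shift every value, but the *ordering* within a
   table is unaffected by affine rescalings of any indicator column
   (tested property).
2. **Introduction risk (LASIMTI).** `LSBCI / days at sea`, summed over
   source-population countries. Dividing by transit time encodes that
   long voyages give desiccation and mortality more time to act on
   stowaway stages. Pairs absent from either input table contribute
   zero to the sum and are logged: sparse tables reflect genuinely
   unrecorded liner service, not errors.
3. **Establishment weighting (HSI).** A per-country scalar in [0, 1].
   How a spatial suitability surface is reduced to one number per
   country is the caller's responsibility; the pipeline consumes the
   scalar. Two combination rules are implemented because the right one
   is genuinely open: lexicographic (rank by HSI, then LASIMTI sum) is
   the default as the more conservative reading — introduction risk
   only breaks ties among equally suitable habitats; the
   multiplicative composite `lasimti_sum × hsi` treats the two as
   independent probabilities. Countries with missing HSI cannot be
   scored for establishment and are ranked after every scored country
   under both rules (ordered among themselves by LASIMTI sum) rather
   than being dropped or imputed.
4. **Trade network and centrality.** Directed top-k graph (k = 3):
   each country links to all partners whose LSBCI ties into its k
   largest *eligible* values. Eligibility excludes zero-LSBCI pairs (a
   weight-0 edge carries no flow) and, when the days cutoff is active,
   pairs beyond it. The cutoff is applied **before** top-k selection,
   so a country whose three best partners are all beyond the window
   still links to its best reachable ones — the alternative
   (post-filtering the top three) silently disconnects nodes, which is
   the wrong default for a surveillance-prioritization tool. Weighted
   directed PageRank uses transition probabilities proportional to
   edge weight, uniform teleport with damping 0.85 (the common
   graph-library default, configurable), and uniform redistribution of
   dangling-node mass, so the result is always a probability
   distribution.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `k` | 3 | partners | top-k rule of the network model |
| `max_days` | off | days | egg-desiccation window; ~14 days when used |
| `damping` | 0.85 | — | standard PageRank teleport mix |
| `tol`, `max_iter` | 1e-10, 1000 | L1 / iterations | power-iteration stop |
| indicator orientation | transshipments inverted | — | connectivity should reward direct routes; fully configurable because the published convention is unstated |
| HSI strategy | `hsi_then_lasimti` | — | see step 3 |

Tie-breaks everywhere are alphabetical by alpha-3 code, so every output
file is a pure function of its inputs.

## Synthetic scenarios

The generator stands in for three external data sources (published
connectivity indices, AIS transit times, suitability rasters) and is
first-class, tested code:

* **Connectivity**: i.i.d. Beta(2, 6) per pair — bounded, right-skewed
  (most pairs weak, few strong), independent of geography by default
  since liner connectivity is a property of service topology, not
  distance. An optional `distance_decay` mixes in `exp(-days/14)` for
  realism experiments.
* **Transit times**: each country receives a port on the unit sphere;
  days = great-circle distance at a uniform 14-knot speed (so an
  antipodal voyage is ≈ 32.2 days). Source ports cluster in a basin
  (≤ 5° radius); target ports sit on an annulus 85°–95° away. The
  annulus makes every target–source route a long haul of comparable
  length (≈ 13–18 days). This is a deliberate departure from uniform
  port placement: with fully random ports, 1/days varies by two orders
  of magnitude across targets and port-placement luck, not the planted
  connectivity signal, decides recovery experiments. Target–target
  distances still span the full range, which is what the days-cutoff
  network variant exercises.
* **HSI**: uniform on [0, 1] with exactly `round(fraction × n)`
  missing entries.
* **Planted signal**: one target's connectivity to every source is
  multiplied by `boost` and capped at 1; the answer key records the
  ground truth.

What the generator does *not* emulate: real port geography or real
index magnitudes, country-level hub structure (connectivity draws are
independent across pairs), temporal correlation across years, and any
directionality of trade volumes. Passing tests therefore demonstrate
the pipeline's algorithmic correctness and its ability to recover a
planted connectivity signal — not predictive validity on real shipping
data.

## Numerical choices

* Min-max normalization with a degenerate column (max = min) maps to
  all zeros and emits an explicit warning — deterministic and bounded.
* Exact-value equality defines network ties (published index ties are
  exact); no tolerance is applied.
* PageRank is renormalized to sum exactly to 1 after convergence; the
  teleport floor (1 − d)/n then holds to ~1e-15 rounding.
* Transit times are floored at 0.01 days against the measure-zero
  event of coincident random ports.
* Rank tables round-trip bit-exactly through CSV (`round_trip` float
  parsing on read).
* The recovery experiment's scale (100 scenarios of 30 targets and 4
  sources; boost ×3 against a boost ×1 null) keeps the whole suite
  under a few seconds while the binomial noise on the recovery rate is
  ~±2 points. At these conditions the measured recovery rate is
  ~94–96% across seed sets: the planted target's own four connectivity
  draws (sum CV ≈ 0.29, further truncated by the cap at 1) lose to the
  maximum of 29 competitors a few percent of the time even with
  identical transit times, so rates in the low-to-mid 90s are the
  signal's intrinsic ceiling, not an implementation defect.

## Known limitations

* Country-level resolution only; no per-port detail, no specific
  goods, no vessel types.
* The LSBCI reconstruction cannot replicate published index values
  (inputs and full methodology are proprietary); it reproduces the
  documented construction on whatever indicator table is supplied.
* Years are analyzed independently; no temporal smoothing.
* The HSI reduction from raster to scalar is out of scope.
* PageRank centrality describes network position, not introduction
  probability; the two rankings answer different questions and are
  reported separately.
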