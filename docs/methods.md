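# Methods

## The analysis

`comorbnet` analyses event-level administrative health records — care
contacts, each carrying one primary and up to three secondary ICD-10
diagnoses — as a weighted co-occurrence network, and contrasts the
comorbidity structure of population cohorts.

### Co-occurrence network

Diagnoses are nodes. With `D` the event-by-diagnosis incidence matrix
(`D_ik = 1` if diagnosis *i* was recorded in event *k*), the edge weight
between diagnoses *i* and *j* is

    W_ij = Σ_k D_ik D_jk ,   i ≠ j ,

i.e. the number of events in which both codes appear. This is the
**complete** mode (every unordered pair of distinct codes in an event
co-occurs) and is the default. A **star** mode, in which only
(primary, secondary) pairs count, is retained behind a flag: the two
readings correspond to treating an event as a clique of its diagnoses
versus a star rooted at the main diagnosis. The diagonal of `D Dᵀ`
(self-pairs) is always discarded — self-loops have no co-occurrence
meaning and would corrupt clique semantics downstream. Weights count
event rows; multiple same-day events of one person each count.

A cohort's network equals the superposition (node union, weights added)
of its members' ego-networks; this exchange-of-summation identity is an
exact invariant and is tested as such.

Mortality networks are built identically over cause-of-death lists (main
cause first, up to three underlying causes). Because multi-cause death
records are what make cause cliques observable at all, the default
mortality mode is also `complete`; a degenerate `main_only` mode (main
cause frequencies, no edges) is available for settings where underlying
causes are unusable.

### Degree, strength, CCDF, and the strength cut

Degree `K_i` is the neighbour count, strength `F_i = Σ_j W_ij`. Both
distributions are summarised by the empirical complementary cumulative
distribution function `P(X ≥ x)`, evaluated on the distinct observed
values (the discrete analogue of the survival integral). Since
`F_i ≥ K_i` whenever all weights are ≥ 1, the strength CCDF dominates
the degree CCDF pointwise — a tested invariant.

The network is reduced by keeping nodes with strength **strictly**
greater than a threshold (default 10), centring the analysis on
recurrently co-occurring diagnoses. The cut is one-pass: strengths are
computed on the full network, the sub-threshold nodes are removed, and
strengths are *not* recomputed before selection. Consequently a second
pass may remove more nodes (a survivor can lose most of its strength
with its removed neighbours); an iterative variant that repeats the cut
to a fixed point is available behind a flag, but the single selection is
the default and the documented behaviour.

### Communities: k-clique percolation

Overlapping diagnosis communities are found by k-clique percolation:
maximal cliques are enumerated (pivoting Bron–Kerbosch, via networkx),
all k-node cliques are generated as k-subsets of maximal cliques of size
≥ k, and two k-cliques are *adjacent* when they share k−1 nodes — the
most two distinct k-cliques can share, so adjacency is discovered by
hashing each clique's (k−1)-subsets and union-finding the buckets, which
avoids the quadratic clique-pair loop. Communities are the connected
components of this adjacency relation, reported as the node union plus
the member cliques. Communities may overlap in nodes but never share a
k-clique, and every k-community's node set nests inside some
(k−1)-community (tested).

The default k is 4, the maximum number of diagnoses one event can carry
(one primary + three secondary), which is the natural clique scale of
the data; `k=None` derives it from the input's maximum observed
diagnoses per event. Percolation runs on topology only — any
positive-weight edge counts — because the weighted information is
handled by the motif metrics in the next stage.

Output ordering is deterministic everywhere (cliques lexicographic,
communities by size descending then smallest member node) so that
reports are byte-reproducible and diffable.

### Motif intensity and coherence

A candidate subgraph *g* (a maximal clique or a community) with edge set
`l_g` is scored by

    I(g) = ( Π_{(i,j)∈l_g} W_ij )^(1/|l_g|)        (intensity)
    Q(g) = I(g) · |l_g| / Σ_{(i,j)∈l_g} W_ij        (coherence)

— the geometric mean of the member weights, and the ratio of geometric
to arithmetic mean. By AM–GM, `Q ∈ (0, 1]` with equality exactly at
uniform weights: high coherence flags clusters whose couplings are
homogeneously strong rather than dominated by one heavy pair. `I` scales
linearly with a global weight rescaling while `Q` is scale-invariant
(both tested). Intensity is computed in log-space; it agrees with the
direct product to relative error < 1e-12 for weights up to 10⁶.

Cliques are scored on all their pairwise edges (each must exist with
positive weight — a missing or zero-weight edge is an error naming the
edge). Communities are scored on the induced edges of their node union
by default; a `community_edges="cliques"` flag restricts scoring to
member-clique edges. Ranking is by coherence descending, ties broken by
intensity descending, then lexicographic node labels. A histogram of
coherence values (bin width 0.05, configurable) accompanies every
ranking.

### Cohort pipeline and comparison

Per cohort: filter records → build network → degree/strength + CCDFs →
strength cut → maximal cliques → k-communities → motif ranking →
mortality network → morbidity–mortality overlap. Cohort comparison is
deliberately descriptive — set algebra on the top-coherence motifs
(shared nodes, cohort-exclusive nodes) plus per-node strength ratios —
since no statistical test between cohorts is part of the method.
Morbidity–mortality overlap is the Jaccard index on node sets between
top morbidity motifs and the maximal cliques (size ≥ 2) of the mortality
network; the convention is stated in every report header because
"overlap" admits several definitions.

Cohort semantics: the victim flag is the one label that persists over
time, so the `victim` cohort selects every flagged person regardless of
current classification, while `sisben` and `other` select by the primary
label *excluding* flagged persons. The three analysis cohorts therefore
partition the registry and the non-victim cohorts are clean controls;
crude-rate denominators use the primary label for the same reason.

## The synthetic-records generator

No comparable administrative dataset is publicly deposited, so the
package ships a generator whose defaults define the study conditions for
all tests:

| parameter | default | rationale |
|---|---|---|
| `n_persons` | 10,000 | large enough for stable plant recovery, small enough for seconds-scale runs |
| `cohort_fractions` | victim 0.2 / sisben 0.3 / other 0.5 | overlapping vulnerable minorities against a majority background |
| `victim_overlap_rate` | 0.05 | some sisben/other persons carry the persistent victim flag |
| `events_per_person` | Poisson(10) | ≈ 10 care contacts per affiliated person over a six-year window |
| `max_dx_per_event` | 4 | one primary + up to three secondary diagnoses |
| `background_codes` | 36 common primary-care codes, Zipf(1.1) probabilities | hub-dominated, fat-tailed degree/strength profile without tuning |
| `mortality_rate` | 0.024 | ≈ 2.4% cumulative mortality over the window |
| planted morbidity motifs | metabolic cluster {E119, I119, E781, E782} in victim+sisben (rate 0.08, draw 3); mental–metabolic coupling {F341, F412, E119, I119, E781, E782} in victims only (rate 0.08, draw 3) | a shared chronic-disease cluster plus a cohort-specific mental-health comorbidity signature |
| planted mortality motifs | {E119, I119, E107} for victims, {E119, E781, I10X} for sisben (rate 0.3) | cohort-specific fatal outcomes of the metabolic cluster |
| study window | 2011-01-01 – 2016-12-31 | dates are I/O realism only; network math ignores them |

Each person's events are, independently, drawn from a planted motif with
the motif's `event_rate` (when the person belongs to a targeted cohort)
or from the background pool. A motif event emits `within_event_draw`
motif codes uniformly without replacement — and *only* motif codes. This
keeps every planted clique identifiable as a maximal clique with
near-uniform weights (hence coherence near 1), while background cliques
inherit the Zipf skew of the pool and score low. Duplicate codes within
an event never occur (sampling is without replacement), matching the
distinct-pair counting of the network construction.

Three RNG streams (population / events / mortality) are spawned from the
master seed, so regenerating one table never reshuffles another, and
identical configurations are byte-identical. Generation fails loudly
(`GenerationError`) if any planted motif with positive rate produces no
qualifying event or death record in a target cohort — small populations
can legitimately trigger this, which is preferable to silently
unrecoverable plants. The truth manifest records realized event counts
and expected per-pair weights per motif and cohort.

### What the generator does and does not emulate

It reproduces the *structural* features the pipeline consumes:
event-level multi-diagnosis records, overlapping cohorts, heavy-tailed
background co-occurrence, planted high-coherence cliques, cohort-specific
couplings, and sparse multi-cause mortality. It does **not** model age-
or sex-specific disease gradients, longitudinal disease progression,
seasonality, or mixing between planted and background diagnoses within
one event — the planted component is disconnected from the background
subnetwork. Passing recovery tests therefore demonstrates that the
pipeline isolates homogeneous high-weight cliques against realistic
heavy-tailed noise; it does not demonstrate performance when signal and
noise share nodes, where motif coherence degrades gracefully but
top-1 recovery is not guaranteed.

## Numerical and degenerate-input choices

- Strict `>` in the strength cut (a node with strength exactly at the
  threshold is removed).
- Intensity/coherence in log-space; zero or missing member edges are
  errors, not zeros, because a "motif" with an absent coupling is not a
  motif of the network.
- Empty tables yield empty networks and empty results, never errors;
  an unknown person yields an empty ego-network with a warning.
- Rates with a zero denominator are emitted as missing, not zero.
- CSV ingestion rejects invalid rows with row-numbered reasons into a
  `.rejects.csv` sidecar and aborts when more than 5% of rows are bad
  (configurable); repeated codes within an event are deduplicated
  keep-first rather than rejected.
- Crude rates count a person once per cause group; groups map ICD-10
  chapter prefixes (I → cardiovascular, A/B → communicable, F → mental
  and behavioural, E → metabolic, G → nervous system, else "other") and
  are user-overridable.

## Known limitations

- Coherence compares geometric to arithmetic mean and is blind to the
  *level* of weights; ranking purely by coherence can prefer a small
  homogeneous clique over a heavier but skewed one. Intensity is
  reported alongside for this reason.
- The one-pass strength cut is order-dependent with respect to repeated
  application (documented above and tested).
- Maximal-clique enumeration is exponential in the worst case; on
  strength-filtered diagnosis networks (dozens to hundreds of nodes) it
  is fast, but the package makes no guarantee for adversarial dense
  graphs.
- Cohort comparison is descriptive; observed differences carry no
  significance statement.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at the
default study conditions (10,000 persons, ≈ 100,000 events) across 50
generator seeds, the network-construction oracle on 100 random event
tables of up to 1,000 events, and the percolation oracle on 100 random
graphs of up to 25 nodes — sizes at which the brute-force oracles remain
exact and the whole suite completes in a few minutes on one core.
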