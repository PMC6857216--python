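# Methods

## Data model

A study is an ordered collection of labelled ego networks sharing one
attribute codebook. Each network is one ego, her `n_alters` named alters
(default 10, so 11 actors), and a symmetric binary relation "talks about the
innovation with". Ties are stored once per unordered pair; every reported
tie count uses the directed-symmetric convention (2 × unordered count,
110 possible among 11 actors), which is how matrix-based SNA software prints
counts for symmetric data and how the source tables this package mirrors are
written. The relation is single and binary by design: the relationship type
(relative, co-worker, neighbour, ...) is an attribute of the alter relative
to her ego, not an edge type. Multiplex, weighted and longitudinal networks
are out of scope.

Actors carry categorical attributes validated against the codebook, with NA
allowed where the questionnaire logic makes a field inapplicable (marriage
type for single women; relationship-to-ego fields for the ego herself).
Actors also carry an optional numeric age: the categorical age group alone
cannot yield the per-network "alter age mean ± SD" table, so age in years
backs the age group (and the generator derives the group from the sampled
age).

### Education recoding

The roster codes education at three levels (none / primary-or-secondary /
tertiary) while the E-I analyses split at "less than secondary" vs "at least
secondary". Where the pooled middle level falls is genuinely ambiguous, so
both variants are provided (`pool-primary-up`, `pool-primary-down`; CLI flag
`--edu-recode`). The default is `pool-primary-down`: a pooled
"primary or secondary" category contains primary-only women, for whom
"at least secondary" would be the stronger unsupported claim. This default is
this package's assumption, not a documented choice of the original analysts.

## Statistics

All statistics are computed on the undirected binary graph, in full
precision, and rendered at two decimals with ties rounded away from zero.

- **Density**: directed tie count / n(n−1), identical to unordered
  count / (n(n−1)/2). Requires n ≥ 2.
- **Degree**: distinct neighbours per actor; the network average is
  directed tie count / n, so average degree × n = directed ties =
  110 × density for n = 11 (a useful internal identity).
- **Betweenness**: Brandes' single-source accumulation, each unordered
  endpoint pair counted once; pairs with no connecting path contribute 0
  (the standard convention for disconnected graphs). Normalized betweenness
  divides by the maximum (n−1)(n−2)/2 and is expressed in percent, so a star
  centre scores 100. The test suite keeps an exhaustive oracle that
  enumerates every simple path of every pair and counts geodesics directly;
  the two agree exactly on hundreds of random graphs with n ≤ 8, and
  networkx provides a second, independent cross-check.
- **Freeman degree centralization**: Σ_v (C_max − C_v) / ((n−1)(n−2)) × 100,
  defined for n ≥ 3 (the two-actor network renders NA).
- **E-I index** per attribute group: I = ties with both endpoints in the
  group, E = ties with exactly one. Ties touching an actor with a missing
  attribute value are excluded from both counts — counting them as external
  would push the index outside [−1, 1] under missingness. The index is NA
  (rendered "–") for an empty group or when E + I = 0. For symmetric data
  the ratio is identical under directed or undirected counting, so the
  convention choice is inconsequential.
- **Actor-level homophily**: the published homophily-source table comes with
  no formula, so the rule here is declared: an actor is *homophilic* on an
  attribute when a strict majority of its countable ties are to actors of
  its own category — equivalently its personal E-I index is < 0. The
  threshold is a parameter (`--homophily-rule`); 0 is the default and an
  exact half-half split is *not* homophilic. Attributes with more than two
  levels are compared on their binary recoded groups, matching the group
  E-I analyses. Isolated actors and actors with a missing value are NA and
  count toward the denominators (which cover every enrolled actor) but not
  the numerators.

## Sociogram encoding

Nodes carry drawing attributes; layout and rendering are left to GraphML/DOT
consumers. Shape: circle for injectable users, square for non-users. Colour:
red ego; alters pink (relatives and close friends), blue (close friends,
when coded separately), black (co-workers), green (neighbours/acquaintances)
— the mapping is configurable because some codebooks pool the first two.
Size is affine in degree (strictly monotone). The `boxed` flag marks the
actors with the top three betweenness values, with two refinements: when all
values are equal no node is boxed, and actors at the global minimum are never
boxed (otherwise every leaf of a star would "tie" into the top three; with
this rule only the star's centre is boxed). A tie at the third rank above the
minimum boxes all tied actors, deterministically.

## Synthetic generator

The generator emulates the questionnaire outputs, not the field process:
20 egos split over two sites, 10 alters each, attributes sampled
independently per actor from configurable marginals, and each unordered pair
tied with probability `logistic(logit(p0) + Σ_attr w_attr · 1[same
category])`. Assortativity on the log-odds scale composes additively across
attributes and never needs clipping; `p0 ∈ {0, 1}` short-circuits to
edgeless/complete networks.

Defaults: marginals equal to the observed all-actor margins (80.5% Hausa,
62.7% aged ≥ 30, 98.2% married, 84.1% injectable users, ...); egos forced
married and injectable users, as observed; `p0 = 0.60` with weights
ethnicity 1.0, age group 0.5, injectable use 0.5. These were fixed once to
land the realized density distribution in the reported dense regime (the
published mean density is ≈ 0.78; the defaults realize a mean ≈ 0.8 with all
networks above 0.5) while making majority-group E-I indices internal-leaning.
Randomness uses one root seed with per-network child streams keyed by a
stable hash of the network label, so regenerating with more networks leaves
existing ones' actors and ties bit-identical (the site tag is positional and
may move).

What the generator does **not** model — and hence what passing tests do not
show about real data: joint attribute structure (education × occupation
correlation, site differences in marginals), dependence between ties (no
triadic closure or other ERGM-style terms beyond what shared attributes
induce), elicitation effects of the fixed-choice name generator (which
likely inflates observed density), and any adoption dynamics. Tests
demonstrate that the pipeline's arithmetic and algorithms are correct and
that the generator's dials act as declared (density monotone in p0, group
E-I monotone in the homophily weight), not that the synthetic networks are
distributionally faithful to Gombe.

## Numerical and degenerate-input choices

- Rounding for rendering: two decimals, half away from zero; computation is
  never performed on rounded values.
- n < 3: normalized betweenness and centralization are undefined and render
  NA; n < 2: density is undefined (error).
- Matrix ingestion OR-symmetrizes one-sided entries with a logged warning;
  non-square matrices, non-binary cells, non-zero diagonals, undeclared
  actors, duplicate ids and self-ties are hard errors naming the file, line
  or record.
- Empty collections tabulate to header-only tables without error.

## Published-table consistency

Four cells of the published per-network summary disagree with their own
printed tie counts and are treated as errata (excluded from exact
reproduction, flagged by `analysis/06_reported_consistency.py`):

| network | printed | recomputed from its tie count |
|---------|---------|-------------------------------|
| SNA-C   | density 0.46 | 50/110 = 0.45 |
| SNA-D   | density 0.86 | 94/110 = 0.85 |
| SNA-F   | density 0.98 | 88/110 = 0.80 |
| SNA-H   | avg degree 8.37 | 92/11 = 8.36 (as row SNA-I prints for the same count) |

SNA-C and SNA-D look like double rounding (0.4545 → 0.455 → 0.46), SNA-F
like a typo. Separately, the published E-I row for the complete network
SNA-L cannot arise from any binary partition of a complete 11-actor graph
under the E-I formula; since the underlying grouping is unrecoverable, only
the analytic endpoints (+1, −1, NA) of the index are verified.

## Problem sizes

The exhaustive betweenness oracle runs on 200 random graphs with n ≤ 8 —
large enough to exercise multiple-geodesic and disconnected cases, small
enough for exact path enumeration. Generator-recovery checks use 200
replicate networks per parameter value (55 pair draws each); marginal
recovery uses 10,000 actor draws (±2 percentage points around P(Hausa) =
0.805 is ≈ 5 Monte-Carlo standard errors).
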