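# egonet

Egocentric (personal) social-network analysis for innovation-diffusion
surveys, built around the networks of early adopters of community health
worker-delivered injectable contraceptives (CHWDIC) in Gombe, Nigeria: each
respondent (*ego*) names ten women of reproductive age (*alters*) and reports,
for every actor pair, whether the two talk about the innovation. The package
computes the structural statistics such studies report, renders their table
shapes, exports attribute-encoded sociograms, and ships a seeded synthetic
questionnaire-data generator so the whole pipeline is testable without the
(undeposited) field data.

## What it computes

For an undirected binary network of n actors (n = 11 per ego network; tie
counts reported under the directed-symmetric convention, 110 possible):

- **density** D = ties / possible ties, the standard cohesion measure;
- **degree centrality** C_D(v) = number of distinct actors tied to v, plus
  the network mean (directed ties / n);
- **betweenness centrality** C_B(v) = Σ_{s<t} σ_st(v)/σ_st over geodesics
  (Brandes' algorithm), normalized to a percentage of its maximum
  (n−1)(n−2)/2 ("nBetweenness");
- **Freeman degree centralization** Σ_v (C_max − C_v) / ((n−1)(n−2)) × 100,
  0 for regular graphs, 100 for a star;
- **Krackhardt–Stern E-I index** (E − I)/(E + I) per attribute group, where
  I counts ties inside the group and E ties crossing its boundary: −1 is
  perfectly homophilic, +1 perfectly heterophilic, undefined cells are
  printed as "–";
- **homophily sources**: the share of egos/alters whose ties are mostly
  within their own category (actor-level E−I < 0), per attribute;
- descriptive tables (actor characteristics by role, alters' relation to
  ego by site, per-network age profiles) and GraphML/DOT sociograms whose
  node shape, colour, size and "boxed" flag encode injectable use,
  relationship to ego, degree, and top-three betweenness.

A generator produces study-shaped collections: attribute marginals and two
constraints (egos married, egos injectable users) match the observed margins,
and each pair is tied with probability
`logistic(logit(p0) + Σ_attr w_attr · 1[same category])`, so assortativity is
tunable per attribute on the log-odds scale.

## Worked example

```
python analysis/01_simulate.py          # synthetic study -> results/data/
python analysis/02_descriptives.py
python analysis/03_network_metrics.py
python analysis/04_homophily.py
python analysis/05_sociograms.py
python analysis/06_reported_consistency.py
```

`03_network_metrics.py` prints one row per network, e.g.

```
network site  ties  density  ego_degree  average_degree  ego_nbetweenness  average_nbetweenness  centralization_pct  cbdic_users
  SNA-A    A    94     0.85          10            8.55              2.83                  1.62               17.78            9
  SNA-B    A    92     0.84           8            8.36              0.91                  1.82               20.00           10

density range 0.75-0.96; 20/20 networks denser than 0.5; 0 at full density
centralization range 4.4-31.1%
```

SNA-A has 94 of 110 possible directed ties (density 0.85), its ego talks to
all 10 alters, and no actor dominates shortest paths (low nBetweenness,
centralization 17.8%) — the dense, weakly centralized profile typical of
these networks. `04_homophily.py` reports that 18 of 20 networks have a
negative (internal-leaning) E-I index for the majority ethnic group, the
signature of ethnic homophily.

The same pipeline runs on real roster/tie files through the CLI:

```
egonet simulate --seed 3 --out data/
egonet analyze  --roster data/roster.csv --ties data/ties.csv --out report/
egonet sociogram --roster data/roster.csv --ties data/ties.csv \
    --network SNA-B --out SNA-B.graphml
egonet report --seed 3 --out report/        # end-to-end
```

Ties may be an edge list or per-network 0/1 adjacency matrices; one-sided
matrix entries are kept as ties with a logged warning.

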