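# Methods

## The screening model

The package operationalises the rule-based screening cascade used in
network-pharmacology studies of multi-component agents. Each stage is
a deterministic function of its inputs and thresholds; there is no
model fitting anywhere except the dose-response stage. The implicit
assumptions are the field's usual ones: predicted compound-target
interactions and database disease associations are taken at face value
after score thresholding; gene identity is by symbol string (uppercased,
no alias or HGNC resolution); the PPI graph is treated as unweighted
and undirected once the confidence cut has been applied.

## Parameters that matter

| parameter | default | unit/range | why |
|---|---|---|---|
| `min_peak_area_pct` | 0.12 | % of total ion current | conventional GC-MS reporting cut; strict `>` ("more than") |
| ADMET rules | GI = High, P-gp = No, DL pass, ≤ 1 violation, BBB unconstrained | enums | see "ADMET defaults" below |
| `target_score_floor` | 0.8 | prediction score ∈ [0,1] | standard target-prediction cut; inclusive `≥` |
| `ppi_min_score` | 0.9 | STRING-style confidence | "highest confidence" interaction class; inclusive `≥` |
| `core_rounds` / `core_metrics` | 2 / dc, bc, cc, ec | — | two-stage topology screen over the four CytoNCA-style centralities |
| `enrich_alpha` | 0.05 | raw p | conventional reporting threshold (adjusted-p filtering available) |
| `top_go`, `top_pathway` | 10, 30 | terms | conventional figure sizes |
| 4PL bounds | lower ∈ [−50, 50] %, upper ∈ [10, 250] %, hill ∈ [0.05, 20] | — | generous envelopes that exclude only unphysical fits |

## ADMET defaults

The packaged lavender-oil component table itself contains entries that
the stated screening rule would exclude: two BBB-impermeant compounds
and one P-glycoprotein substrate, plus one entry with a single
drug-likeness violation. The default rule set is therefore calibrated
to what the table actually retains where that is coherent — BBB is
unconstrained and one DL violation is tolerated — but keeps the P-gp
exclusion active, because dropping it would disable the rejection
semantics the screen is defined by; under defaults the packaged table
passes 20 of 21. The fully strict rule set is available as
`STRICT_SWISSADME` (GI High, BBB Yes, P-gp No, DL pass). Molecular
weights use average (not monoisotopic) atomic masses, fixed in code to
four decimals, because printed MW columns in such tables are average
masses.

## Centralities and core extraction

Degree, betweenness (Brandes' dependency accumulation, unnormalised,
endpoints excluded, each unordered pair counted once — consistent with
the magnitudes such papers print), closeness in the component-wise form
`(|C|−1)/Σd` (values in [0,1], defined on disconnected graphs, isolated
nodes 0), and eigenvector centrality of the largest component,
max-normalised. The eigenvector is computed by power iteration on
`A + I` rather than `A`: the shift leaves eigenvectors unchanged but
makes the leading eigenvalue strictly dominant on bipartite components,
where raw power iteration oscillates between `±λ_max`. Convergence is
the max absolute difference of successive max-normalised iterates
< 1e-10, capped at 10,000 iterations, from a uniform start — all
deterministic.

Core extraction repeats an above-median screen with strict `>` (a
weak `≥` would keep whole tied blocks and can make the screen a no-op).
The default schedule is *progressive*: every round but the last keeps
nodes above the median on **any** selected metric, the final round
demands it on **every** metric. A uniformly conjunctive schedule was
tried first and systematically loses dense-core members: inside a
near-clique, shortest-path traffic splits across many equivalent
routes, so individual core members' betweenness dilutes below the
global median even though the core dominates degree, closeness and
eigenvector centrality (median planted-core recall 0.70 versus 0.90
for the progressive schedule under the default generator). The
progressive shape also matches the retention pattern two-stage
topology screens report in practice — a first cut keeping most of the
network (~90 %) and a sharp second cut (~25 %). Uniform `"all"` and
`"any"` modes remain available. Survivors are ranked by degree,
descending, ties broken alphabetically, so extraction is reproducible.
If a round would empty the graph (e.g. every node tied on every
metric), iteration stops beforehand and the result is flagged
`exhausted`; published screens sometimes hand-pick a final shortlist
from the core (a 46-to-19 style step) — that selection has no stated
criterion and is deliberately not modelled.

## Enrichment

The hypergeometric upper tail is evaluated with scipy's survival
function (log-space internally, exact to well below 1e-12 on
enumerable universes). Benjamini-Hochberg is the package's own step-up
implementation, adjusted within each category (BP/CC/MF/pathway
families are separate test families); tests compare it against
statsmodels. Terms with zero overlap are omitted rather than assigned
p = 1, matching common ORA tools. The default significance filter is
on the raw p-value — fidelity to how such screens report — with
`filter_on="adjusted"` available. When no universe is supplied, the
union of all collection members is used and logged; published screens
rarely state their background, and this is the common fallback. The
pipeline enriches the full common-target set by default (`enrich_on=
"core"` switches to the extracted core).

## Dose-response

The 4PL is fitted by least squares on the dose scale with
data-derived initial values (the IC50 guess is the dose nearest the
half-range response). The reported IC50 is the fitted inflection dose
(*relative* IC50); the dose where the curve crosses 50 % viability
(*absolute* IC50) is reported alongside when it exists. Replicate
wells are averaged before fitting. Viability values may exceed 100 %
or drop below 0 % under noise and are not clamped. A fitted IC50
outside [min dose/10, max dose·10] — e.g. from non-decreasing
viability — is flagged `in_range = False` rather than silently
reported. The fit is deterministic given the data.

## What the synthetic generators emulate

Each generator is a pure function of the configuration (one integer
seed, fixed named substream per generator, so adding one generator
never perturbs another; identical configs give byte-identical files):

* **Compound tables** — formulas, retention times, peak areas and ADMET
  flags built so that exactly `round(n · pass_fraction)` rows pass the
  default screen, failures cycling through the four rejection causes.
* **Target lists** — five disease sources (default sizes 250/60/40/
  50/80 from a 500-gene universe) sharing a planted 25-gene core, plus
  a per-compound drug-target map whose score-passing entries meet the
  disease union in exactly 40 planted common genes; sub-threshold decoy
  rows exercise the score filter.
* **PPI graphs** — 100 nodes: a 10-node quasi-clique at edge
  probability 0.9 over an Erdős–Rényi background at 0.03, scores
  uniform in [0.9, 1.0].
* **Gene sets** — 50 random terms of 10–50 genes plus one planted term
  sharing 15 genes with a 20-gene query.
* **Plates** — replicate ODs from a 4PL (true IC50 524 μg/mL, Hill 2)
  at the seven assay doses 50–1000 μg/mL, blank 0.05 / control 0.95,
  Gaussian noise of 3 % of the dynamic range on every well, three
  replicates.

These fixtures reproduce the *structure* of real inputs, not their
biology: gene symbols are synthetic tokens, the interactome is a
planted-core ER graph rather than a scale-free network, annotation
terms are random draws without a GO DAG, and compound identities are
arbitrary. Passing tests therefore demonstrate that the algorithms
recover planted truth under the stated noise — not that any particular
real dataset would yield the same counts. Real-study magnitudes that
depend on unversioned database snapshots (hundreds of drug targets,
~12,000 disease genes, specific network sizes, GO/KEGG entry counts)
are treated as non-reproducible context; the pipeline's internal count
arithmetic is instead verified against generator manifests.

## Numerical and degenerate-input choices

* All threshold comparisons are as documented per stage: strict `>` for
  peak area and median screens, inclusive `≥` for prediction-score and
  PPI-confidence cuts.
* Duplicate PPI edges collapse to the maximum score; self-loops are
  dropped; endpoints of sub-threshold edges are not added as isolated
  nodes.
* Empty inputs propagate as empty outputs with flags
  (`no_common_targets`, `exhausted`) rather than errors, except where a
  computation is undefined (empty universe, zero flow-cytometry events,
  control OD equal to blank).
* Plate files quantise ODs to four decimals; this limits noiseless
  IC50 recovery to ~0.04 % rather than machine precision.

## Problem sizes

The default test and acceptance workloads use 100-node PPI graphs
(20 seeds), 500-gene universes with 51-term collections (100 seeds),
50 seeded plates, the exhaustive connected-graph atlas to 6 nodes plus
200 random 8-node graphs for centrality oracles, and all hypergeometric
configurations with universes up to 12 for exact enumeration. These
desk-scale sizes exercise every code path; the algorithms are
polynomial (Brandes is O(nm)) and run comfortably on larger graphs.

## Known limitations

* No alias/HGNC symbol resolution; string-identical symbols only.
* No GO DAG propagation or gene-ID mapping in enrichment.
* Shortest paths ignore edge confidence beyond the initial cut.
* The 46→19-style manual shortlist step of published screens is not
  modelled (no stated criterion).
* SMILES strings are carried as opaque text; molecular weight comes
  from the formula column, not from structure.
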