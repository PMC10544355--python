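# Methods

## Scope and data flow

`p2t` consumes a pathway-enrichment result table (SPIA or enrichr
dialect), keeps the pathways with adjusted p strictly below `alpha`
(default 0.05), resolves each significant pathway to its member gene
products through a backend, scores every member with a weighted linear
combination of target attributes, and emits ranked target and therapeutic
tables plus an optional hypergeometric enrichment test of the top ranks
against a gold set. Upstream steps — differential expression, the
enrichment algorithms themselves, multiple-testing correction — are out
of scope: the input p-values arrive already adjusted, and the filter
applies a strict `<` comparison to whatever adjusted column the dialect
supplies (FWER-style column preferred over FDR over the uncorrected
global p, when several are present).

## The scoring model

Each target's score is the dot product of a ten-component weight vector
with (pathway count, tractability count, approved count, safety-liability
count, unique-drug count, disease-association count, phase-1..4 counts).
Assumptions worth making explicit:

* **The pathway count is per-run, not global.** It counts the distinct
  *significant input pathways* containing the target, recomputed from the
  enrichment table each run; it is deliberately not a stored target
  attribute.
* **Phase counts are exclusive, not cumulative**: a therapeutic is
  counted at its maximum phase only. The approved count and the phase-4
  count are both scored even though they typically coincide (an approved
  drug is a post-approval, phase-4 drug); with default weights 1 and 2
  this makes approval effectively worth 3 per therapeutic.
* **Attributes enter raw.** No log-scaling, capping or normalization is
  applied, so the disease-association count (hundreds to thousands)
  dominates default-preset scores. This is a deliberate property of the
  default preset, not an accident; users who dislike it can down-weight
  `w_diseases` (the novel preset sets it to 0.01).
* **Tractability flags are reported, not scored**; only the integer
  tractability count carries weight. The count is backend-supplied rather
  than derived from the 12 modality×stage flags, because the flags are a
  summary of a richer bucket list and their true-count can disagree with
  the published count.

Ties in the ranking are broken by approved count (desc), unique-drug
count (desc), then symbol (asc), making the ranked order a deterministic
function of the input set — permuting the input cannot change the output.
Duplicate target accessions are a usage error.

Each drug inherits the **maximum** score over its linked scored targets:
a therapeutic is as promising as its best target. Alternatives (sum,
mean) would reward promiscuity rather than the quality of the best
opportunity.

## Weight configuration

Weights are arbitrary finite reals; presets `default`
(1, 1, 1, −2, 1, 1, 0.5, 1, 1.5, 2 for pathways, tractability, approved,
safety, unique drugs, diseases, phase 1, 2, 3, 4) and `novel`
(0.5, 0.5, 0.5, −2, 0.5, 0.01, 10, 4, 0.5, 0.01). A YAML override file
may set any subset of the ten keys on top of a preset; unknown keys are
rejected rather than ignored. Output tables carry a short hash of the
weight vector in their header comment for provenance.

## Enrichment test

The top-k test draws its universe from the run's own scored-target list
(size N), counts the gold symbols present in that universe (K,
case-insensitive symbol match), and reports the upper-tail
P(X ≥ hits) for X ~ Hypergeom(N, K, k) via scipy's log-gamma-based
survival function. Only over-representation is tested. Using the run's
own list as the universe answers "does the *ranking* concentrate gold
targets at the top?", not "are gold targets enriched among pathway
members?" — the latter would need a genome-wide universe.

Degenerate cases: zero gold symbols in the universe returns p = 1;
k must satisfy 1 ≤ k ≤ N; zero observed hits returns p = 1 exactly.

## The snapshot backend

An offline JSON bundle (pathway membership, gene-identifier crosswalk,
target attributes, drug links) is the reference backend, validated on
load: schema via pydantic, plus referential-integrity checks (every drug
link must point at a stored target; gene-map Ensembl ids must be unique;
pathway members must be ENSG-patterned). Serialization is canonical
(sorted keys, fixed indentation), so load→save→load is byte-stable.
Pathway lookup tries the accession first, then exact name; fuzzy matching
was rejected to keep runs deterministic. Missing pathways and pathway
members absent from the target table are logged and skipped, not fatal —
public pathway membership routinely exceeds any annotation snapshot's
coverage. Missing numeric attributes default to 0 and missing subcellular
locations to "No data".

A live GraphQL client (stdlib `urllib`, exponential backoff) can populate
an equivalent snapshot from an Open Targets-style endpoint. Query
construction and response conversion are pure functions and are tested
offline; only the network call itself is untested, and nothing else in
the package depends on it.

## Synthetic-data generator

The generator emulates a mid-scale pathway pull — by default 50 targets,
10 Reactome-style pathways of 3–15 members, 0–4 drug links per target
(with ~20% of links reusing an existing drug so the drug table has real
duplicates), and a 5-target *gold* subset whose approved, phase-4 and
unique-drug counts are inflated 10× (`round(background_draw × 10)`),
playing the role of an indication's approved targets.

Attribute draws follow the shapes of real annotation data rather than
uniform noise: disease-association counts are heavy-tailed (lognormal,
median ≈ 6% of the 2,500 cap, σ = 1, clipped — only a handful of targets
per snapshot reach the thousands, as in real pulls where the famous
oncogenes dominate), safety-liability counts are exponential with most
targets near zero, and drug/phase/tractability counts are uniform over
Table-scale ranges (unique drugs ≤ 100, phases ≤ 15, tractability ≤ 12).
Two structural constraints hold by construction: a target's unique-drug
count is at least its approved count, and a gold target has at least one
approved therapeutic before inflation (an approved-indication target
cannot have zero). The phase-4 count equals the approved count, matching
the identity observed in real annotation rows.

What the generator does **not** emulate: correlation between disease
association and drug counts (in reality heavily-drugged targets are also
heavily studied), biological pathway overlap structure, identifier
messiness (every synthetic gene maps cleanly), and drug polypharmacology
beyond random link reuse. Passing the planted-signal tests therefore
shows that the scorer recovers a drug-side signal against realistic
annotation noise — it does not certify performance on real data, where
the confounding between study bias and approval status is stronger.

All draws come from one `numpy` generator seeded per call; identical
parameters give byte-identical canonical snapshots.

## Numerical and interface choices

* Scores are plain float arithmetic on integer attributes; the published
  half-unit scores are reproduced exactly, no tolerance needed.
* The hypergeometric tail is validated against exhaustive subset
  enumeration for every universe of size ≤ 12 at 1e-12.
* Problem sizes in the test suite (50-target snapshots, 20 seeds for the
  stochastic properties, enumeration up to N = 12) keep the full suite
  around two seconds while exercising every code path.
* TSV outputs start with a `# p2t <version> weights=<hash>` comment;
  reruns with identical config are byte-identical (no timestamps).
* Zero significant pathways is a prominent warning plus empty outputs,
  exit 0 — an empty result is an answer, not a crash.

## Known limitations

* The linear score has no uncertainty: two targets differing by 0.5 are
  ranked strictly. No attempt is made at multi-objective trade-offs.
* The raw disease-association term makes the default preset favor
  well-studied targets; this recapitulates, rather than corrects, the
  literature's study bias.
* Gold-set matching is by symbol, so aliased or outdated symbols silently
  miss; feed symbols from the same vocabulary as the snapshot.
* The enrichment p-value is not corrected across multiple gold sets or
  multiple k choices; treat repeated probing accordingly.
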