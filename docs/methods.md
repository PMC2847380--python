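# Methods

This note records the models, rules and design choices behind `mpdkit`,
including where the design was genuinely open and which way we went.

## Hub-and-spoke identifier mapping

All identifier translation routes through a single canonical hub namespace,
`UniProtKB_AC` by default (configurable, but single-valued). An
object→object mapping composes exactly two hops: source id → hub
accession(s) → target ids. An object→attribute mapping reads the hub
protein's attribute edges (GO term, pathway, taxon, ...). We deliberately do
not chain through arbitrary intermediate namespaces: multi-hop composition
across partially consistent cross-reference tables silently accumulates
wrong links, while two-hop composition keeps every result attributable to
two auditable edges.

Object edges may be many-to-one (several aliases for one protein — the
normal case when laboratories use different identifier systems) and
one-to-many (a genuinely ambiguous alias). Ambiguity is surfaced, never
resolved by the mapper: match lists carry every hub accession an alias
reaches, sorted lexicographically, and filtering is the caller's decision.
Identifier values are compared case-sensitively after trimming surrounding
whitespace, because accessions are case-significant in several source
databases. Provenance-verified mapping is reduced to a boolean `verified`
flag per object edge; `--strict` queries drop unverified edges. Full
sequence/taxonomy verification of an edge is out of scope for the mapper
and is exercised through the sequence store in tests.

## Peptide match

Matching is exact substring search, 1-based inclusive coordinates, all
overlapping occurrences reported. Ambiguity codes (B, X, Z, J) are matched
literally, never as wildcards, and I/L are distinct — the contract is exact
identity, not mass equivalence. The engine is an in-package Aho–Corasick
automaton (goto/fail/output links over a dict-based trie) giving one pass
per sequence regardless of the number of query peptides; below 4 distinct
peptides a naive `str.find` loop is used instead, since building the
automaton costs more than it saves there. Both paths implement the same
contract and the suite checks them against an independent per-position scan.

## Ungapped identity and homolog clustering

"High identity with no gaps" admits several formalizations; ours is
*ungapped sliding-window containment*:

    identity(a, b) = max over all ungapped alignments of the shorter
                     sequence within the longer of
                     (#identical positions) / length(shorter)

This tolerates terminal extensions (a fragment contained in a longer
protein scores 1.0) but admits no internal gaps. Note that production
reference-cluster systems use gapped alignment tools with coverage rules;
cluster ids and memberships here are not expected to match any public
resource — the definition is chosen for determinism and for exactness under
substitution-only synthetic data.

Clustering is greedy and incremental: records sorted by (length descending,
accession ascending); each record joins the first existing cluster whose
*representative* it matches at ≥ threshold (default 0.90), else founds a
new cluster. Consequences, asserted in tests: member sets partition the
input; every member reaches its representative at ≥ threshold;
representatives are mutually below threshold; raising the threshold never
decreases the cluster count. Complexity is O(n²·L); intended scale is
≤ 1,000 sequences, which clusters in about a second.

Bridging returns, for each query accession, all co-cluster members of the
target taxon (excluding the query itself), sorted. We do not force
one-to-one orthology: if a cluster holds several target-taxon members, all
are returned and downstream aggregation handles multiplicity.

## Structured assertions and aggregation

An assertion is the minimal analyzed result: (accession, experiment,
condition-keyword set, expression status), with status from the closed
vocabulary {increase, decrease, present} and experiments tagged by data
type from {mass_spectrometry, microarray, interaction, clone, structure}.
Condition keywords are free lowercase tokens matched case-insensitively as
whole tokens (a keyword filter requires every query token to be present),
not substrings — a deliberately minimal stand-in for a full experimental
ontology.

Loading enforces the vocabularies, referential integrity (experiment must
exist; accession must exist when a protein store is supplied), and
duplicate-key policy: identical duplicate rows collapse with a logged
warning, conflicting statuses for the same (accession, experiment,
keywords) are an error. Serialization is canonical (sorted), so
load → dump → load is byte-stable.

Cross-data-type queries use set-intersection semantics: a protein qualifies
when it has at least one qualifying assertion in *every* required data
type. An empty requirement set degenerates to "any assertion at all". For
presence-style status filters, increase and decrease imply present (a
protein asserted changed was necessarily detected).

Status aggregation collapses several assertions to a single call, needed
when a network node gets one color:

| inputs contain            | result   |
|---------------------------|----------|
| increase AND decrease     | conflict |
| increase (no decrease)    | increase |
| decrease (no increase)    | decrease |
| only present              | present  |
| nothing                   | none     |

`conflict` propagates (any conflicting input keeps the aggregate in
conflict). Surfacing conflict, rather than majority-voting or preferring
one platform, was an open choice; we surface it because a silently wrong
direction is worse than an honest "the data disagree".

## Functional profiling

A slim rollup of a term is its ancestor closure (child→parent edges, term
itself included) intersected with the slim set; a protein's effective
categories are the union of its terms' rollups. The ontology input contract
is a plain child/parent edge TSV plus a one-term-per-line slim list —
format-stable and trivially testable; OBO conversion is out of scope.
Pathway categorization uses a flat protein→pathway table with no rollup.

Counting is multi-membership: a protein with k categories adds 1 to each of
the k counts ("number of occurrences" semantics), and an uncategorized
protein counts once under `uncategorized`. Fractional weighting was
rejected because the target statistic is occurrences, not mass. This fixes
the conservation identity used as an invariant: each cross-comparison
column sums to Σ_p max(1, |categories(p)|). Both raw-term and slim-rolled
counting are exposed; the rollup is optional because either convention is
defensible and the choice belongs to the analyst.

## Network overlay and prioritization

Edges are directed pathogen → host in the SIF export, with the interaction
type taken from the edge's method string (lowercased; yeast two-hybrid
edges read `y2h`); roles and statuses live in the node-attribute file, not
the edge type. A pathogen node's status aggregates its own microarray and
mass-spectrometry assertions. A host node's status aggregates assertions on
itself plus every bridged assay-taxon homolog, with the same conflict-
surfacing rule across homologs. Hosts whose homologs carry no data keep
status `none` and stay in the network (dropping them is a caller-side
filter, not a default). Each non-`none` host status records the
contributing accessions, so every status is reproducible by re-querying the
assertion store with the recorded bridging.

Prioritization selects edges whose host status is `decrease` (deduplicated
by protein pair, sorted), flagging those whose pathogen status is
`increase`. Significance testing is deliberately absent: assertions are
taken to encode already-significant calls made upstream at data-analysis
time, and this module never re-tests them.

## Synthetic data generator

The generator emulates the *shapes* of multi-center pathogen/host holdings,
with every planted truth recorded in a YAML manifest:

* **Proteomes.** Random sequences over the 20 standard residues, lengths
  150–240 aa (typical bacterial protein lengths, and long enough that two
  random sequences sit far below any clustering threshold). Default taxa
  are labeled 1392-like (pathogen), 9606-like (interaction-screen host) and
  10090-like (expression-assay host).
* **Homolog families.** Each family has a founder sequence (the host
  member) and members mutated by substitutions only — never indels — at
  exactly round((1−identity)·L) positions, so the realized ungapped
  identity equals the planted band to within one position (asserted at
  generation time). Default intra-family identity 0.94 against a 0.90
  clustering threshold; inter-family identity is that of unrelated random
  sequences (≈0.1, far below threshold).
* **Assertions.** 300 pathogen proteins by default, 47 of them covered by
  all three of interaction/microarray/mass-spectrometry — the study-shaped
  scenario — with disjoint partial-coverage groups for the rest, so the
  triple query has a unique planted answer.
* **Network.** 60 interaction edges by default; 8 prioritized edges are
  planted by giving exactly 8 hosts' mouse homologs a decrease assertion,
  and 3 of their 8 distinct pathogen partners all-increase assertions (the
  other 5 get present). Non-prioritized hosts never receive decrease
  signals, so the planted sets are exact, not merely lower bounds.

One `random.Random(seed)` stream drives everything; the same seed yields a
byte-identical bundle. What the generator does **not** emulate: realistic
sequence composition, indel evolution, noisy/contradictory assertions
beyond the explicit conflict cases, scale-free interaction topology, or
raw spectra/intensities. Passing tests therefore demonstrate the
correctness of the mapping/query/clustering/overlay machinery under the
stated contracts — not robustness to the noise profiles of real
instruments.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
500-edge mapping tables; 200-record stores × 100 peptides × 20 seeds for
peptide match; 3–10 planted families per clustering seed (20 seeds); the
default 340-protein bundle for the end-to-end workflow. Identity
comparisons are exact rational arithmetic in effect (integer match counts
over integer lengths); the only floating-point tolerance in the suite is
pytest.approx on identity oracle comparisons. Ties everywhere break
lexicographically; all serializations are sorted; no step reads the clock
or environment.

## Known limitations

* Cluster memberships depend on greedy insertion order (longest first);
  a different order could produce a different, equally valid partition.
* Two-hop mapping cannot recover links that only exist via a chain of
  non-hub namespaces — by design.
* The assertion model has no effect sizes, p-values or time courses; an
  analysis needing them must go back to the primary data.
* `expression_status_of` treats every experiment equally; there is no
  platform weighting or recency preference.
* Peptide match is exact-only: no I/L equivalence, no mass tolerance.
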