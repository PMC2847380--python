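# mpdkit

Protein-centric integration of heterogeneous high-throughput results —
mass spectrometry, microarray, protein interaction, clone and structure
experiments — for pathogen/host systems, as a local, testable toolkit.

Results from different laboratories arrive keyed to different identifier
systems and different host species, and the conclusions ("protein V
increased under condition W") live in supplementary tables rather than in
queryable form. `mpdkit` makes that material jointly queryable:

* **Identifier mapping** (`mpdkit.identifier_map`): every source identifier
  (GI number, RefSeq accession, gene name, ...) resolves through a canonical
  *hub* accession (UniProtKB-style), supporting object↔object translation
  and object→attribute lookup (GO terms, pathways, taxa). Composition is
  restricted to exactly two hops through the hub.
* **Peptide match** (`mpdkit.sequence_store`): exact, overlap-inclusive
  multi-peptide search against a FASTA proteome (Aho–Corasick automaton with
  a naive-scan fallback), optionally restricted by taxon.
* **Homolog clustering** (`mpdkit.homolog_clusters`): greedy UniRef90-style
  clustering at an ungapped identity threshold (default 0.90), used to
  bridge proteins between species — e.g. from human interactors to the
  mouse homologs that carry the expression data.
* **Structured assertions** (`mpdkit.assertion_store`): minimal analyzed
  results — protein, experiment, condition keywords, expression status from
  the closed vocabulary {increase, decrease, present} — with cross-data-type
  intersection queries ("proteins with interaction AND microarray AND mass
  spectrometry data").
* **Functional profiling** (`mpdkit.functional_profiling`): GO-slim rollup
  by ancestor closure, per-category protein frequencies (multi-membership
  counting), and cross-comparison matrices across data sets.
* **Network overlay** (`mpdkit.network_integration`): pathogen–host
  interaction networks colored by aggregated expression status, with
  prioritization of edges whose host protein decreased on infection
  (highest tier: pathogen partner increased), exported as Cytoscape
  SIF + node-attribute files.
* **Synthetic data** (`mpdkit.fixtures`): a deterministic generator that
  emits every input format with planted ground truth (homolog families at
  exact identities, a known triple-covered protein set, known prioritized
  edges) so the whole workflow is testable offline.

## Worked example

Generate a synthetic study-shaped bundle and run the full workflow:

```
mpdkit fixtures --seed 42 --out bundle/
mpdkit cluster --fasta bundle/proteins.fasta --threshold 0.90 -o clusters.tsv
mpdkit query --experiments bundle/experiments.tsv --assertions bundle/assertions.tsv \
    --require-type interaction --require-type microarray \
    --require-type mass_spectrometry --taxon 1392 | head -4
mpdkit network --interactions bundle/interactions.tsv \
    --experiments bundle/experiments.tsv --assertions bundle/assertions.tsv \
    --clusters clusters.tsv --fasta bundle/proteins.fasta \
    --assay-taxon 10090 --out overlay
```

The query prints one row per (protein, data type) for the 47 pathogen
proteins covered by all three data types, e.g.:

```
accession	data_type	experiment_ids
PA0009	interaction	PRC_interaction_01
PA0009	mass_spectrometry	PRC_mass_spectrometry_01
PA0009	microarray	PRC_microarray_01
```

The network command writes `overlay.sif` and `overlay.node_attrs.tsv` for
Cytoscape and prints the prioritized interactions — the edges whose host
protein (via its bridged mouse homolog) decreased on infection, flagged
when the pathogen partner increased:

```
pathogen	host	pathogen_status	host_status	pathogen_increased
PA0013	HS0000	increase	decrease	yes
PA0032	HS0004	present	decrease	no
PA0089	HS0001	increase	decrease	yes
...
```

With the default bundle this yields 8 prioritized interactions, 3 of them
flagged — the planted ground truth recorded in `bundle/manifest.yaml`.

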