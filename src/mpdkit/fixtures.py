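"""Deterministic synthetic data with planted ground truth.

Real multi-center pathogen/host holdings cannot be redistributed, so every
input format the toolkit consumes is emulated here with known answers:

* a multi-organism FASTA — random pathogen proteins plus host/assay-species
  homolog *families* mutated (substitution only, never indels) to an exact
  planted identity, so the ungapped-identity clustering must recover the
  family partition;
* identifier tables with many-aliases-to-one-hub cases and one deliberately
  ambiguous alias pointing at two hub accessions;
* experiment and assertion tables over the closed expression vocabulary,
  planting a known set of pathogen proteins covered by all three of
  {interaction, microarray, mass_spectrometry};
* an ontology edge list with a slim subset and per-protein annotations with
  recorded category counts;
* a bipartite pathogen-host interaction set planting a known number of
  prioritized edges (host homolog decreased) of which a known subset has an
  increased pathogen partner.

The defaults mirror the motivating case study's shape: a ~300-protein
pathogen proteome with 47 triple-covered proteins, human interactors whose
expression signal lives on mouse homologs, and 8 prioritized interactions
with 3 increased pathogen partners.

A single integer seed drives one ``random.Random`` stream; the same seed
yields a byte-identical bundle.  Wall-clock entropy is never used.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ValidationError
from .homolog_clusters import ungapped_identity

AA20 = "ACDEFGHIKLMNPQRSTVWY"

KEYWORD_VOCAB = ("infection", "control", "log-phase", "stationary", "spore", "4h", "24h")

BUNDLE_FILES = (
    "proteins.fasta",
    "id_object_edges.tsv",
    "id_attribute_edges.tsv",
    "experiments.tsv",
    "assertions.tsv",
    "annotations.tsv",
    "ontology_edges.tsv",
    "slim_terms.txt",
    "interactions.tsv",
    "manifest.yaml",
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic bundle.  Defaults are the study-shaped
    conditions described in the module docstring."""

    seed: int = 42
    # taxa (pathogen / interaction-screen host / expression-assay host)
    pathogen_taxon: int = 1392
    host_taxon: int = 9606
    assay_taxon: int = 10090
    # proteome sizes
    n_pathogen: int = 300
    n_families: int = 20
    family_size: int = 2  # host member + assay member (+ alternating extras)
    seq_len_min: int = 150
    seq_len_max: int = 240
    # planted identity band (substitution-only mutations from the founder)
    intra_identity: float = 0.94
    inter_identity_max: float = 0.60
    threshold: float = 0.90
    # assertions
    n_triple: int = 47  # pathogen proteins covered by all three data types
    # interaction network
    n_interactions: int = 60
    n_prioritized: int = 8  # edges whose host homolog decreased
    n_flagged: int = 3  # of those, edges with an increased pathogen partner
    # identifier mapping
    n_multi_alias: int = 5  # proteins given two GI aliases

    def validate(self) -> None:
        counts = {
            "n_pathogen": self.n_pathogen,
            "n_families": self.n_families,
            "family_size": self.family_size,
            "n_triple": self.n_triple,
            "n_interactions": self.n_interactions,
            "n_prioritized": self.n_prioritized,
            "n_flagged": self.n_flagged,
            "n_multi_alias": self.n_multi_alias,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.family_size < 2:
            raise ValidationError("family_size must be >= 2 (host + assay member)")
        if not (self.inter_identity_max < self.threshold < self.intra_identity):
            raise ValidationError(
                "identity bands must satisfy intra > threshold > inter "
                f"(got {self.intra_identity} / {self.threshold} / {self.inter_identity_max})"
            )
        if self.n_triple > self.n_pathogen:
            raise ValidationError("n_triple cannot exceed n_pathogen")
        if self.n_flagged > self.n_prioritized:
            raise ValidationError("n_flagged cannot exceed n_prioritized")
        if self.n_prioritized > self.n_interactions:
            raise ValidationError("n_prioritized cannot exceed n_interactions")
        if self.n_prioritized > self.n_families:
            raise ValidationError(
                "n_prioritized distinct decreased hosts require n_prioritized <= n_families"
            )
        if self.n_prioritized > self.n_triple:
            raise ValidationError(
                "prioritized edges draw distinct pathogen partners from the "
                "triple-covered set; need n_prioritized <= n_triple"
            )
        if self.seq_len_min < 30 or self.seq_len_max < self.seq_len_min:
            raise ValidationError("sequence length band is invalid")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "FixtureSpec":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"fixture spec {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown fixture spec key(s): {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def _mutate(rng: random.Random, seq: str, identity: float) -> str:
    """Substitute exactly round((1-identity)*len) positions, each to a
    different residue, so the realized ungapped identity is exact."""
    n_subs = round((1.0 - identity) * len(seq))
    positions = rng.sample(range(len(seq)), n_subs)
    out = list(seq)
    for pos in positions:
        choices = [aa for aa in AA20 if aa != out[pos]]
        out[pos] = rng.choice(choices)
    return "".join(out)


def generate(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the full bundle into ``out_dir`` and return the manifest."""
    spec.validate()
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- proteomes --------------------------------------------------------
    pathogen_accs = [f"PA{i:04d}" for i in range(spec.n_pathogen)]
    fasta_records: list[tuple[str, int, str, str]] = []  # acc, taxon, organism, seq
    for acc in pathogen_accs:
        seq = _random_seq(rng, rng.randint(spec.seq_len_min, spec.seq_len_max))
        fasta_records.append((acc, spec.pathogen_taxon, "Synthetic pathogen", seq))

    families: list[list[str]] = []
    taxon_of: dict[str, int] = {acc: spec.pathogen_taxon for acc in pathogen_accs}
    host_of_family: list[str] = []
    assay_of_family: list[str] = []
    host_idx = 0
    assay_idx = 0
    for fam in range(spec.n_families):
        length = rng.randint(spec.seq_len_min, spec.seq_len_max)
        founder_seq = _random_seq(rng, length)
        members: list[str] = []
        # member roles alternate host/assay; the host member founds the
        # family (lowest accession at equal length -> greedy representative)
        for slot in range(spec.family_size):
            if slot % 2 == 0:
                acc = f"HS{host_idx:04d}"
                host_idx += 1
                taxon = spec.host_taxon
                organism = "Synthetic host"
            else:
                acc = f"MM{assay_idx:04d}"
                assay_idx += 1
                taxon = spec.assay_taxon
                organism = "Synthetic assay host"
            seq = founder_seq if slot == 0 else _mutate(rng, founder_seq, spec.intra_identity)
            if slot > 0:
                realized = ungapped_identity(seq, founder_seq)
                planted = 1.0 - round((1.0 - spec.intra_identity) * length) / length
                if abs(realized - planted) > 1.0 / length:
                    raise AssertionError(
                        f"mutation procedure missed the identity band: {realized} vs {planted}"
                    )
            members.append(acc)
            taxon_of[acc] = taxon
            fasta_records.append((acc, taxon, organism, seq))
        families.append(sorted(members))
        host_of_family.append(members[0])
        assay_of_family.append(members[1])

    fasta_path = out_dir / "proteins.fasta"
    with open(fasta_path, "w", encoding="utf-8") as out:
        for acc, taxon, organism, seq in fasta_records:
            out.write(f">{acc} taxon={taxon} {organism}\n")
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")

    all_accs = sorted(taxon_of)
    expected_partition = sorted(
        sorted(fam) for fam in families
    ) + [[acc] for acc in all_accs if not any(acc in fam for fam in families)]
    expected_partition = sorted(expected_partition)

    # ---- identifier mapping tables ---------------------------------------
    object_edges: list[tuple[str, str, str]] = []
    gi_counter = 1000
    for i, acc in enumerate(all_accs):
        object_edges.append(("GI_Number", str(gi_counter), acc))
        gi_counter += 1
        object_edges.append(("RefSeq_AC", f"NP_{i:06d}", acc))
    for acc in pathogen_accs[: spec.n_multi_alias]:
        object_edges.append(("GI_Number", str(gi_counter), acc))
        gi_counter += 1
    ambiguous = None
    if spec.n_pathogen >= 2:
        # one alias deliberately pointing at two hub accessions; surfaced,
        # not resolved, by the mapping layer
        ambiguous = {
            "namespace": "GI_Number",
            "value": str(gi_counter),
            "hubs": [pathogen_accs[0], pathogen_accs[1]],
        }
        object_edges.append(("GI_Number", str(gi_counter), pathogen_accs[0]))
        object_edges.append(("GI_Number", str(gi_counter), pathogen_accs[1]))
        gi_counter += 1

    with open(out_dir / "id_object_edges.tsv", "w", encoding="utf-8") as out:
        out.write("# namespace\tsource_id\thub_accession\n")
        for ns, src, hub in object_edges:
            out.write(f"{ns}\t{src}\t{hub}\n")

    # ---- ontology, slim, annotations -------------------------------------
    n_terms = 40
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    roots = terms[:3]
    dag_edges: list[tuple[str, str]] = []
    for i in range(3, n_terms):
        n_parents = 1 if rng.random() < 0.7 else 2
        parents = rng.sample(terms[:i], min(n_parents, i))
        for parent in parents:
            dag_edges.append((terms[i], parent))
    slim_terms = sorted(set(roots) | set(rng.sample(terms[3:16], 5)))

    annotations: dict[str, list[str]] = {}
    category_counts: dict[str, int] = {"uncategorized": 0}
    leafish = terms[3:]
    for acc in pathogen_accs:
        k = rng.choices([0, 1, 2, 3], weights=[15, 40, 30, 15])[0]
        cats = sorted(rng.sample(leafish, k)) if k else []
        annotations[acc] = cats
        if not cats:
            category_counts["uncategorized"] += 1
        for cat in cats:
            category_counts[cat] = category_counts.get(cat, 0) + 1

    with open(out_dir / "ontology_edges.tsv", "w", encoding="utf-8") as out:
        out.write("child\tparent\n")
        for child, parent in sorted(dag_edges):
            out.write(f"{child}\t{parent}\n")
    with open(out_dir / "slim_terms.txt", "w", encoding="utf-8") as out:
        for term in slim_terms:
            out.write(term + "\n")

    pathway_pool = [f"map{i:05d}" for i in (10, 20, 30, 40)]
    with open(out_dir / "annotations.tsv", "w", encoding="utf-8") as out:
        out.write("accession\tcategory_namespace\tcategory_id\n")
        for acc in pathogen_accs:
            for cat in annotations[acc]:
                out.write(f"{acc}\tGO_ID\t{cat}\n")
        for i, acc in enumerate(pathogen_accs):
            if i % 10 == 0:
                out.write(f"{acc}\tKEGG_Pathway_ID\t{pathway_pool[(i // 10) % len(pathway_pool)]}\n")

    with open(out_dir / "id_attribute_edges.tsv", "w", encoding="utf-8") as out:
        out.write("# hub_accession\tnamespace\tvalue\n")
        for acc in all_accs:
            out.write(f"{acc}\tTaxon_ID\t{taxon_of[acc]}\n")
        for acc in pathogen_accs:
            for cat in annotations[acc]:
                out.write(f"{acc}\tGO_ID\t{cat}\n")

    # ---- experiments ------------------------------------------------------
    experiments: list[tuple[str, str, int, str, str]] = []
    pathogen_exps: dict[str, list[str]] = {"mass_spectrometry": [], "microarray": [], "interaction": []}
    for dtype, count, center in (
        ("mass_spectrometry", 2, "PRC-MS Center"),
        ("microarray", 2, "PRC-Array Center"),
        ("interaction", 1, "PRC-Y2H Center"),
    ):
        for k in range(1, count + 1):
            eid = f"PRC_{dtype}_{k:02d}"
            pathogen_exps[dtype].append(eid)
            experiments.append(
                (eid, dtype, spec.pathogen_taxon, center, f"synthetic pathogen {dtype} study {k}")
            )
    assay_exps: dict[str, str] = {}
    for dtype in ("mass_spectrometry", "microarray"):
        eid = f"HOSTLAB_{dtype}_01"
        assay_exps[dtype] = eid
        experiments.append(
            (eid, dtype, spec.assay_taxon, "Host Lab", f"synthetic infected-macrophage {dtype} study")
        )
    interaction_exp = pathogen_exps["interaction"][0]

    with open(out_dir / "experiments.tsv", "w", encoding="utf-8") as out:
        out.write("experiment_id\tdata_type\ttaxon\tcenter\tdescription\n")
        for row in experiments:
            out.write("\t".join(str(x) for x in row) + "\n")

    # ---- data-type coverage groups ---------------------------------------
    shuffled = pathogen_accs[:]
    rng.shuffle(shuffled)
    triple = sorted(shuffled[: spec.n_triple])
    rest = shuffled[spec.n_triple :]
    q = len(rest) // 4
    group_mm = rest[:q]                      # microarray + MS (no interaction)
    group_im = rest[q : 2 * q]               # interaction + microarray
    group_ms = rest[2 * q : 3 * q]           # MS only
    group_ma = rest[3 * q : 3 * q + q // 2]  # microarray only
    type_sets: dict[str, set[str]] = {acc: set() for acc in pathogen_accs}
    for acc in triple:
        type_sets[acc] = {"interaction", "microarray", "mass_spectrometry"}
    for acc in group_mm:
        type_sets[acc] = {"microarray", "mass_spectrometry"}
    for acc in group_im:
        type_sets[acc] = {"interaction", "microarray"}
    for acc in group_ms:
        type_sets[acc] = {"mass_spectrometry"}
    for acc in group_ma:
        type_sets[acc] = {"microarray"}

    interaction_capable = sorted(
        acc for acc, types in type_sets.items() if "interaction" in types
    )

    # prioritized-edge cast: distinct pathogens from the triple set, distinct
    # decreased hosts (one per leading family)
    triple_shuffled = triple[:]
    rng.shuffle(triple_shuffled)
    prioritized_pathogens = triple_shuffled[: spec.n_prioritized]
    flagged_pathogens = sorted(prioritized_pathogens[: spec.n_flagged])
    present_pathogens = set(prioritized_pathogens[spec.n_flagged :])
    decrease_hosts = [host_of_family[i] for i in range(spec.n_prioritized)]
    decrease_assay = [assay_of_family[i] for i in range(spec.n_prioritized)]

    # ---- assertions -------------------------------------------------------
    assertion_rows: list[tuple[str, str, str, str]] = []

    def pathogen_status(acc: str) -> str:
        if acc in flagged_pathogens:
            return "increase"
        if acc in present_pathogens:
            return "present"
        return rng.choice(["increase", "decrease", "present"])

    for acc in pathogen_accs:
        keywords = ["infection"] if acc in triple else [rng.choice(KEYWORD_VOCAB)]
        if rng.random() < 0.5:
            extra = rng.choice(KEYWORD_VOCAB)
            if extra not in keywords:
                keywords.append(extra)
        kw = ";".join(sorted(keywords))
        for dtype in sorted(type_sets[acc]):
            eid = rng.choice(pathogen_exps[dtype])
            status = "present" if dtype == "interaction" else pathogen_status(acc)
            assertion_rows.append((acc, eid, kw, status))

    for i in range(spec.n_families):
        assay_acc = assay_of_family[i]
        if i < spec.n_prioritized:
            eid = assay_exps[rng.choice(["mass_spectrometry", "microarray"])]
            assertion_rows.append((assay_acc, eid, "infection", "decrease"))
        else:
            if rng.random() < 0.6:
                eid = assay_exps[rng.choice(["mass_spectrometry", "microarray"])]
                status = rng.choice(["increase", "present"])
                assertion_rows.append((assay_acc, eid, "infection", status))
            # else: no expression data for this homolog -> host status none

    with open(out_dir / "assertions.tsv", "w", encoding="utf-8") as out:
        out.write("accession\texperiment_id\tcondition_keywords\texpression_status\n")
        for row in assertion_rows:
            out.write("\t".join(row) + "\n")

    # ---- interaction network ---------------------------------------------
    edges: list[tuple[str, str]] = [
        (prioritized_pathogens[i], decrease_hosts[i]) for i in range(spec.n_prioritized)
    ]
    other_hosts = [host_of_family[i] for i in range(spec.n_prioritized, spec.n_families)]
    n_extra = spec.n_interactions - spec.n_prioritized
    if n_extra > 0:
        if not other_hosts:
            raise ValidationError(
                "need at least one non-prioritized family to place extra edges"
            )
        pool = [
            (p, h)
            for p in interaction_capable
            for h in other_hosts
            if (p, h) not in set(edges)
        ]
        if n_extra > len(pool):
            raise ValidationError(
                f"cannot place {n_extra} extra unique edges; only {len(pool)} pairs available"
            )
        edges.extend(rng.sample(pool, n_extra))

    with open(out_dir / "interactions.tsv", "w", encoding="utf-8") as out:
        out.write("pathogen_acc\thost_acc\texperiment_id\tmethod\n")
        for pathogen, host in edges:
            out.write(f"{pathogen}\t{host}\t{interaction_exp}\tY2H\n")

    prioritized_edges = sorted(
        [prioritized_pathogens[i], decrease_hosts[i]] for i in range(spec.n_prioritized)
    )
    flagged_edges = sorted(
        [prioritized_pathogens[i], decrease_hosts[i]]
        for i in range(spec.n_prioritized)
        if prioritized_pathogens[i] in flagged_pathogens
    )

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "spec": asdict(spec),
        "taxa": {
            "pathogen": spec.pathogen_taxon,
            "host": spec.host_taxon,
            "assay": spec.assay_taxon,
        },
        "families": [list(fam) for fam in sorted(families)],
        "expected_partition": [list(c) for c in expected_partition],
        "triple_type_proteins": triple,
        "prioritized_edges": [list(e) for e in prioritized_edges],
        "flagged_edges": [list(e) for e in flagged_edges],
        "decrease_hosts": sorted(decrease_hosts),
        "decrease_assay_homologs": sorted(decrease_assay),
        "flagged_pathogens": flagged_pathogens,
        "category_counts": category_counts,
        "ambiguous_alias": ambiguous,
        "interaction_experiment": interaction_exp,
    }
    with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as out:
        yaml.safe_dump(manifest, out, sort_keys=True)
    return manifest


def load_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as handle:
        return yaml.safe_load(handle)
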