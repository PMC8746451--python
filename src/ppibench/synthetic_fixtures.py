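"""Synthetic proteomes, interactomes and annotations for self-contained runs.

Real PPI corpora are hub-heavy: the positive network is scale-free while
random negative pairs are drawn near-uniformly, and it is precisely that
mismatch that membership-bias models exploit.  The generators here emulate
that structure — preferential-attachment interactomes over i.i.d. random
proteomes, toy ontologies, and domain assignments with an optional *planted*
interacting-domain-pair signal so that genuinely pairwise predictors have
something real to recover on protein-disjoint test data.

Everything is driven by one master seed; sub-seeds are derived by fixed
offsets so every artifact is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset_builder import (
    HeldOutConfig,
    PairDataset,
    RatioSpec,
    assign_heldout_bins,
    build_full_datasets,
    build_heldout_datasets,
    enumerate_heldout_configs,
    stratified_folds,
    write_pair_dataset,
)
from .io_formats import (
    STANDARD_AMINO_ACIDS,
    AnnotationMap,
    InteractionSet,
    OntologyDAG,
    ProteinRecord,
    Proteome,
    canonical_pair,
    write_domains,
    write_fasta,
    write_gaf,
    write_interactions,
    write_obo,
)

# Sub-seed offsets from the master seed (kept below 2**31 after addition).
_SEED_PROTEOME = 11
_SEED_INTERACTOME = 23
_SEED_ANNOTATIONS = 37
_SEED_DATASETS = 53


@dataclass
class SynthSpec:
    """Parameters of the synthetic study system.

    Defaults describe a desk-scale analogue of a hub-heavy interactome:
    2,000 proteins, 10,000 interactions grown by preferential attachment,
    a 30-domain vocabulary with about two domains per protein, five planted
    interacting domain pairs with a 10x enrichment, and a three-level toy
    ontology with 30% of proteins left unannotated.
    """

    n_proteins: int = 2000
    min_length: int = 31
    max_length: int = 120
    n_interactions: int = 10000
    attachment_bias: float = 1.0     # attachment probability ~ (degree + bias)
    n_domains: int = 30
    domains_per_protein: float = 2.0  # Poisson mean
    n_planted_pairs: int = 5
    effect_multiplier: float = 10.0
    ontology_depth: int = 3
    ontology_branching: int = 3
    terms_per_protein: float = 3.0    # Poisson mean
    missing_fraction: float = 0.3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 31:
            raise ValueError("min_length must be >= 31")
        for name in ("n_proteins", "n_interactions", "n_domains"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_proteome(spec: SynthSpec) -> Proteome:
    """I.i.d. uniform sequences over the 20 letters, lengths >= 31."""
    rng = np.random.default_rng(spec.master_seed + _SEED_PROTEOME)
    width = len(str(spec.n_proteins - 1))
    records = []
    letters = np.array(list(STANDARD_AMINO_ACIDS))
    for i in range(spec.n_proteins):
        L = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = "".join(letters[rng.integers(0, 20, size=L)])
        pid = f"P{i:0{width}d}"
        records.append(ProteinRecord(protein_id=pid, gene_id=f"G{i:0{width}d}",
                                     sequence=seq))
    return Proteome(records, min_length_applied=spec.min_length)


def _grow_interactome(ids: list[str], m: int, bias: float,
                      rng: np.random.Generator,
                      pair_weight=None) -> InteractionSet:
    """Preferential-attachment growth over a fixed protein set.

    Initialized with a uniform random matching, then edges are added with
    endpoint probability proportional to (degree + bias); ``pair_weight``
    (pair -> relative weight) thins candidate edges by rejection, enriching
    high-weight pairs.
    """
    n = len(ids)
    if m > n * (n - 1) // 2:
        raise ValueError(f"cannot place {m} edges among {n} proteins")
    edges: set[tuple[str, str]] = set()
    endpoints: list[int] = []   # node index repeated once per incident edge

    def try_edge(i: int, j: int) -> bool:
        if i == j:
            return False
        pair = canonical_pair(ids[i], ids[j])
        if pair in edges:
            return False
        if pair_weight is not None:
            w = pair_weight(pair)
            if w < 1.0 and rng.random() > w:
                return False
        edges.add(pair)
        endpoints.append(i)
        endpoints.append(j)
        return True

    # seed with a small uniform random matching; keeping it small lets
    # preferential attachment dominate, as in real hub-heavy interactomes
    perm = rng.permutation(n)
    seed_edges = max(1, min(n // 2, m // 100))
    k = 0
    while k + 1 < n and len(edges) < min(seed_edges, m):
        try_edge(int(perm[k]), int(perm[k + 1]))
        k += 2

    def draw() -> int:
        # P(node) ~ degree + bias, via a degree-proportional endpoint
        # multiset mixed with a uniform component
        total = len(endpoints) + n * bias
        if endpoints and rng.random() < len(endpoints) / total:
            return endpoints[int(rng.integers(0, len(endpoints)))]
        return int(rng.integers(0, n))

    max_tries = 500 * m + 10000
    tries = 0
    while len(edges) < m and tries < max_tries:
        tries += 1
        try_edge(draw(), draw())
    if len(edges) < m:
        raise RuntimeError(f"could not place {m} edges (got {len(edges)})")
    return InteractionSet(edges, provenance="synthetic scale-free")


def generate_scalefree_interactome(proteome: Proteome,
                                   spec: SynthSpec) -> InteractionSet:
    """Hub-heavy interaction network grown by preferential attachment."""
    rng = np.random.default_rng(spec.master_seed + _SEED_INTERACTOME)
    return _grow_interactome(proteome.ids(), spec.n_interactions,
                             spec.attachment_bias, rng)


def generate_toy_ontology(spec: SynthSpec,
                          rng: np.random.Generator,
                          namespace: str = "biological_process",
                          ) -> OntologyDAG:
    """A rooted random DAG with the requested depth and branching; most terms
    have one parent, a fraction get a second (it stays a DAG by construction)."""
    parents: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    prefix = namespace[:2].upper()
    root = f"{prefix}:0"
    parents[root] = set()
    namespaces[root] = namespace
    levels = [[root]]
    counter = 1
    for depth in range(1, spec.ontology_depth + 1):
        level = []
        for parent in levels[-1]:
            for _ in range(spec.ontology_branching):
                term = f"{prefix}:{counter}"
                counter += 1
                ps = {parent}
                if depth >= 2 and rng.random() < 0.2:
                    ps.add(levels[-1][int(rng.integers(0, len(levels[-1])))])
                parents[term] = ps
                namespaces[term] = namespace
                level.append(term)
        levels.append(level)
    return OntologyDAG(parents, namespaces)


@dataclass
class SyntheticAnnotations:
    """Bundle produced by :func:`generate_annotations`."""

    dag: OntologyDAG
    go_annotations: AnnotationMap
    domain_annotations: AnnotationMap
    planted_pairs: list[tuple]
    interactions: InteractionSet


def generate_annotations(proteome: Proteome,
                         interactions: InteractionSet | None,
                         spec: SynthSpec) -> SyntheticAnnotations:
    """Toy ontology + domain assignments with a planted interaction signal.

    Domains are assigned per protein (Poisson count over a fixed vocabulary);
    ``n_planted_pairs`` domain pairs are declared *interacting* and the
    interactome is regenerated with pairs carrying a planted domain pair
    accepted ``effect_multiplier`` times more readily, so positive pairs are
    enriched for the planted signal while random pairs are not.  A
    ``missing_fraction`` of proteins is left unannotated in GO and domains,
    emulating real annotation coverage.
    """
    rng = np.random.default_rng(spec.master_seed + _SEED_ANNOTATIONS)
    ids = proteome.ids()
    dag = generate_toy_ontology(spec, rng)
    terms = sorted(dag.terms - dag.roots())

    missing = set(ids[i] for i in
                  rng.choice(len(ids),
                             size=int(spec.missing_fraction * len(ids)),
                             replace=False))

    go = AnnotationMap()
    for pid in ids:
        if pid in missing:
            go.terms[pid] = set()
            continue
        k = max(1, int(rng.poisson(spec.terms_per_protein)))
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        go.terms[pid] = {terms[i] for i in chosen}

    databases = ("Pfam", "Prosite", "InterPro")
    domain_vocab = [(databases[d % 3], f"D{d:03d}")
                    for d in range(spec.n_domains)]
    domains = AnnotationMap()
    dom_sets: dict[str, set] = {}
    for pid in ids:
        if pid in missing:
            domains.terms[pid] = set()
            dom_sets[pid] = set()
            continue
        k = max(1, int(rng.poisson(spec.domains_per_protein)))
        chosen = rng.choice(len(domain_vocab), size=min(k, len(domain_vocab)),
                            replace=False)
        anns = {domain_vocab[i] for i in chosen}
        domains.terms[pid] = anns
        dom_sets[pid] = anns

    planted: list[tuple] = []
    if spec.n_planted_pairs:
        idx = rng.choice(len(domain_vocab),
                         size=min(2 * spec.n_planted_pairs, len(domain_vocab)),
                         replace=False)
        for i in range(0, len(idx) - 1, 2):
            planted.append((domain_vocab[idx[i]], domain_vocab[idx[i + 1]]))

    planted_set = {frozenset(p) for p in planted}

    def carries_planted(pair: tuple[str, str]) -> bool:
        da, db = dom_sets.get(pair[0], set()), dom_sets.get(pair[1], set())
        for d1, d2 in planted:
            if (d1 in da and d2 in db) or (d2 in da and d1 in db):
                return True
        return False

    mult = spec.effect_multiplier

    def pair_weight(pair: tuple[str, str]) -> float:
        # normalized so the maximum weight is 1 (rejection sampling)
        return 1.0 if carries_planted(pair) else 1.0 / max(mult, 1.0)

    n_edges = (len(interactions) if interactions is not None
               else spec.n_interactions)
    new_interactions = _grow_interactome(
        ids, n_edges, spec.attachment_bias, rng,
        pair_weight=pair_weight if mult != 1.0 else None)

    return SyntheticAnnotations(dag=dag, go_annotations=go,
                                domain_annotations=domains,
                                planted_pairs=planted,
                                interactions=new_interactions)


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

#: Reference dataset sizes at scale 1.0 (positives, negatives): the Full
#: regime grid the benchmark's tables are organized around.
FULL_GRID = {
    "cv_50": {"positive_fraction": 0.5, "n_pairs": 125000},
    "train_20": {"positive_fraction": 0.2, "n_positive": 20000},
    "test_10": {"positive_fraction": 0.1, "n_positive": 10000},
    "test_03": {"positive_fraction": 0.003, "n_positive": 1500,
                "total": 500000},
}


@dataclass
class BenchmarkSuite:
    """All Table-1-shaped datasets at a configurable scale."""

    proteome: Proteome
    interactions: InteractionSet
    full: dict[str, PairDataset]
    heldout_bins: HeldOutConfig
    heldout_configs: list[frozenset[int]]
    heldout: dict[str, dict[str, PairDataset]]
    manifest: dict


def make_benchmark_suite(spec: SynthSpec, scale: float = 0.01,
                         heldout_configs: list[frozenset[int]] | None = None,
                         n_bins: int = 6) -> BenchmarkSuite:
    """Build the {Full, Held-Out} x {train 50/20%, test 50/10/0.3%} grid.

    ``scale`` multiplies the reference dataset sizes (scale 0.01 gives a
    0.3%-positive test set of 15 positives and 4,985 negatives).  By default
    only the first held-out configuration is materialized; pass
    ``enumerate_heldout_configs()`` for all 21.
    """
    proteome = generate_proteome(spec)
    interactions = generate_scalefree_interactome(proteome, spec)
    seed = spec.master_seed + _SEED_DATASETS

    def s(x: float) -> int:
        return max(1, int(round(x * scale)))

    full: dict[str, PairDataset] = {}
    train50, test50 = build_full_datasets(
        proteome, interactions,
        RatioSpec(0.5, s(62500)),
        RatioSpec(0.5, s(62500)),
        rng_seed=seed)
    full["train_50"], full["test_50"] = train50, test50
    train20, test10 = build_full_datasets(
        proteome, interactions,
        RatioSpec(0.2, s(20000)),
        RatioSpec(0.1, s(10000)),
        rng_seed=seed + 1)
    full["train_20"], full["test_10"] = train20, test10
    # the 0.3% test set shares the 20% train set
    _, test03 = build_full_datasets(
        proteome, interactions,
        RatioSpec(0.2, s(20000)),
        RatioSpec(0.003, s(1500), total=s(1500) + int(round(s(1500) * 0.997 / 0.003))),
        rng_seed=seed + 1)
    full["test_03"] = test03

    bins = assign_heldout_bins(proteome, n_bins=n_bins, rng_seed=seed + 2)
    configs = heldout_configs or [enumerate_heldout_configs(n_bins)[0]]
    heldout: dict[str, dict[str, PairDataset]] = {}
    for held in configs:
        cfg = HeldOutConfig(n_bins=n_bins, held_bins=held,
                            bin_assignment=bins.bin_assignment)
        name = "h" + "_".join(str(b) for b in sorted(held))
        group: dict[str, PairDataset] = {}
        tr50, te50 = build_heldout_datasets(
            proteome, interactions, cfg,
            RatioSpec(0.5, s(50000)), RatioSpec(0.5, "all"),
            rng_seed=seed + 3)
        group["train_50"], group["test_50"] = tr50, te50
        tr20, te10 = build_heldout_datasets(
            proteome, interactions, cfg,
            RatioSpec(0.2, s(20000)), RatioSpec(0.1, "all"),
            rng_seed=seed + 4)
        group["train_20"], group["test_10"] = tr20, te10
        n_pos03 = max(1, te10.n_positive // 10)
        _, te03 = build_heldout_datasets(
            proteome, interactions, cfg,
            RatioSpec(0.2, s(20000)), RatioSpec(0.003, n_pos03),
            rng_seed=seed + 4)
        group["test_03"] = te03
        heldout[name] = group

    manifest = {"scale": scale, "master_seed": spec.master_seed,
                "n_bins": n_bins,
                "heldout_configs": [sorted(c) for c in configs]}
    return BenchmarkSuite(proteome=proteome, interactions=interactions,
                          full=full, heldout_bins=bins,
                          heldout_configs=configs, heldout=heldout,
                          manifest=manifest)


def write_fixture_files(spec: SynthSpec, out_dir: str | Path) -> dict:
    """Write FASTA/TSV/OBO/GAF fixture files plus a manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(spec)
    bundle = generate_annotations(proteome, None, spec)
    paths = {
        "fasta": out / "proteome.fasta",
        "interactions": out / "interactions.tsv",
        "obo": out / "ontology.obo",
        "gaf": out / "annotations.gaf",
        "domains": out / "domains.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(proteome, paths["fasta"])
    write_interactions(bundle.interactions, paths["interactions"])
    write_obo(bundle.dag, paths["obo"])
    write_gaf(bundle.go_annotations, bundle.dag, paths["gaf"])
    write_domains(bundle.domain_annotations, paths["domains"])
    manifest = {"master_seed": spec.master_seed,
                "n_proteins": spec.n_proteins,
                "n_interactions": spec.n_interactions,
                "effect_multiplier": spec.effect_multiplier,
                "planted_pairs": [list(map(list, p))
                                  for p in bundle.planted_pairs]}
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return {k: str(v) for k, v in paths.items()}
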