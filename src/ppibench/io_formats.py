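"""Readers, writers and identity conventions for the benchmark's input formats.

Handles FASTA proteomes, TSV interaction pair lists (optionally carrying PSI-MI
detection-method codes and labels), OBO ontologies, GAF 2.x annotation files and
TSV domain-assignment files.  All identifiers are treated case-sensitively and
proteins are represented at the gene level: one record per gene after isoform
collapse, with annotations of all of a gene's protein accessions unioned onto
the retained record.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ppibench")

#: The 20 standard amino acids, alphabetical.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Letters that may appear in real sequence data but are outside the standard
#: alphabet; they are retained on read and contribute zero counts in descriptors.
NONSTANDARD_LETTERS = frozenset("BJOUXZ")

#: Default minimum retained sequence length: sequences of 30 residues or fewer
#: are removed, matching the shortest length several descriptor lags require.
MIN_SEQUENCE_LENGTH = 31


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


class IntegrityError(ValueError):
    """Parsed data violate a structural invariant (duplicates, cycles...)."""


class CapacityError(ValueError):
    """A sampling request exceeds the available pair/protein space."""


class ConfigError(ValueError):
    """An operation was invoked with an inconsistent configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein: accession, owning gene identifier and amino-acid sequence."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise IntegrityError(f"empty sequence for {self.protein_id!r}")
        if any(c.isspace() for c in self.sequence):
            raise IntegrityError(f"whitespace in sequence of {self.protein_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def nonstandard_letters(self) -> set[str]:
        return set(self.sequence) - set(STANDARD_AMINO_ACIDS)


class Proteome:
    """A collection of :class:`ProteinRecord` keyed by unique ``protein_id``."""

    def __init__(self, records: Iterable[ProteinRecord] = (),
                 min_length_applied: int | None = None):
        self.records: dict[str, ProteinRecord] = {}
        self.min_length_applied = min_length_applied
        for rec in records:
            self.add(rec)

    def add(self, rec: ProteinRecord) -> None:
        if rec.protein_id in self.records:
            raise IntegrityError(f"duplicate protein_id {rec.protein_id!r}")
        self.records[rec.protein_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.records

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self.records[protein_id]

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records.values())

    def ids(self) -> list[str]:
        """Protein identifiers in sorted order (deterministic iteration)."""
        return sorted(self.records)

    def by_gene(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {}
        for rec in self:
            out.setdefault(rec.gene_id, []).append(rec)
        return out

    def sequence(self, protein_id: str) -> str:
        return self.records[protein_id].sequence


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-free canonical form of a protein pair (lexicographic)."""
    return (a, b) if a <= b else (b, a)


class InteractionSet:
    """Deduplicated, order-independent, self-pair-free positive pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = (),
                 provenance: str = ""):
        self.pairs: set[tuple[str, str]] = set()
        self.provenance = provenance
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            return
        self.pairs.add(canonical_pair(a, b))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    def proteins(self) -> set[str]:
        return {p for pair in self.pairs for p in pair}

    def validate(self, proteome: Proteome) -> None:
        missing = self.proteins() - set(proteome.records)
        if missing:
            raise IntegrityError(
                f"{len(missing)} interaction proteins absent from proteome, "
                f"e.g. {sorted(missing)[:5]}")

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.pairs:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg


class AnnotationMap:
    """Protein identifier -> set of annotation keys.

    Keys are GO term accessions (strings) for ontology annotations, or
    ``(database, accession)`` tuples for domain assignments.  Empty sets are
    permitted and represent missing data.
    """

    def __init__(self, mapping: Mapping[str, Iterable] | None = None):
        self.terms: dict[str, set] = {}
        if mapping:
            for pid, anns in mapping.items():
                self.terms[pid] = set(anns)

    def get(self, protein_id: str) -> set:
        return self.terms.get(protein_id, set())

    def add(self, protein_id: str, key) -> None:
        self.terms.setdefault(protein_id, set()).add(key)

    def __len__(self) -> int:
        return len(self.terms)

    def proteins(self) -> list[str]:
        return sorted(self.terms)

    def restrict_namespace(self, dag: "OntologyDAG", namespace: str) -> "AnnotationMap":
        """Keep only term annotations belonging to one ontology namespace."""
        out = AnnotationMap()
        for pid, anns in self.terms.items():
            kept = {t for t in anns
                    if t in dag.terms and dag.namespace.get(t) == namespace}
            out.terms[pid] = kept
        return out

    def by_database(self, database: str) -> "AnnotationMap":
        """Keep only ``(database, accession)`` domain keys for one database."""
        out = AnnotationMap()
        for pid, anns in self.terms.items():
            out.terms[pid] = {k for k in anns
                              if isinstance(k, tuple) and k[0] == database}
        return out

    def vocabulary(self) -> list:
        vocab = set()
        for anns in self.terms.values():
            vocab.update(anns)
        return sorted(vocab)


class OntologyDAG:
    """An is_a ontology: terms, child->parent edges and per-term namespace."""

    def __init__(self, parents: Mapping[str, Iterable[str]],
                 namespace: Mapping[str, str] | None = None):
        self.parents: dict[str, set[str]] = {t: set(ps) for t, ps in parents.items()}
        # terms referenced only as parents are still terms
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, set())
        self.terms: set[str] = set(self.parents)
        self.namespace: dict[str, str] = dict(namespace or {})
        self.children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise IntegrityError(f"parent {p!r} of {child!r} unknown")
                self.children[p].add(child)
        self._check_acyclic()
        self._depth_cache: dict[str, int] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise IntegrityError("ontology contains an is_a cycle")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """All terms reachable by ascending is_a edges."""
        if term not in self.terms:
            raise KeyError(term)
        seen: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents[t])
        if include_self:
            seen.add(term)
        return seen

    def descendants(self, term: str, include_self: bool = True) -> set[str]:
        if term not in self.terms:
            raise KeyError(term)
        seen: set[str] = set()
        stack = list(self.children[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.children[t])
        if include_self:
            seen.add(term)
        return seen

    def depth(self, term: str) -> int:
        """Shortest-path depth from the term's namespace root (root = 0)."""
        if term in self._depth_cache:
            return self._depth_cache[term]
        if term not in self.terms:
            raise KeyError(term)
        if not self.parents[term]:
            d = 0
        else:
            d = 1 + min(self.depth(p) for p in self.parents[term])
        self._depth_cache[term] = d
        return d

    def terms_at_depth(self, depth: int, namespace: str | None = None) -> set[str]:
        out = {t for t in self.terms if self.depth(t) == depth}
        if namespace is not None:
            out = {t for t in out if self.namespace.get(t) == namespace}
        return out

    def namespaces(self) -> set[str]:
        return set(self.namespace.values())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Proteome:
    """Read a FASTA file into a :class:`Proteome`.

    The first whitespace-separated token of each header is the protein
    identifier; an optional ``gene=<id>`` tag elsewhere in the header supplies
    the gene identifier (defaults to the protein identifier).  Sequences are
    uppercased.  Duplicate identifiers raise :class:`IntegrityError`.
    """
    path = Path(path)
    proteome = Proteome()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # biopython raises assorted ValueErrors
        raise ParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not parsed:
        # distinguish "empty file" from "garbage file"
        text = path.read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            raise ParseError(f"{path}: sequence data before first FASTA header")
    for rec in parsed:
        gene_id = rec.id
        for tok in rec.description.split():
            if tok.startswith("gene="):
                gene_id = tok[len("gene="):]
        proteome.add(ProteinRecord(protein_id=rec.id, gene_id=gene_id,
                                   sequence=str(rec.seq).upper()))
    return proteome


def write_fasta(proteome: Proteome, path: str | Path) -> None:
    records = [SeqRecord(Seq(rec.sequence), id=rec.protein_id,
                         description=f"gene={rec.gene_id}")
               for rec in sorted(proteome, key=lambda r: r.protein_id)]
    SeqIO.write(records, str(path), "fasta")


def filter_short_sequences(proteome: Proteome,
                           min_length: int = MIN_SEQUENCE_LENGTH) -> Proteome:
    """Remove sequences shorter than ``min_length`` residues.

    With the default of 31, sequences of length 30 or fewer are removed, the
    convention several descriptor algorithms require.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [rec for rec in proteome if rec.length >= min_length]
    return Proteome(kept, min_length_applied=min_length)


def collapse_gene_isoforms(proteome: Proteome) -> Proteome:
    """Keep one record per gene: the longest isoform.

    Ties at equal maximal length are broken by the lexicographically smallest
    protein identifier so that builds are deterministic.
    """
    for rec in proteome:
        if not rec.gene_id:
            raise IntegrityError(f"record {rec.protein_id!r} lacks gene_id")
    best: dict[str, ProteinRecord] = {}
    for rec in sorted(proteome, key=lambda r: r.protein_id):
        cur = best.get(rec.gene_id)
        if cur is None or rec.length > cur.length:
            best[rec.gene_id] = rec
        elif rec.length == cur.length and rec.protein_id < cur.protein_id:
            best[rec.gene_id] = rec
    return Proteome(best.values(),
                    min_length_applied=proteome.min_length_applied)


# ---------------------------------------------------------------------------
# Interaction pair lists
# ---------------------------------------------------------------------------

def read_interactions(path: str | Path,
                      accepted_mi_codes: set[str] | None = None,
                      proteome: Proteome | None = None,
                      provenance: str = "") -> InteractionSet:
    """Read a TSV pair file into an :class:`InteractionSet`.

    Expected header: ``protein_a\tprotein_b[\tmi_code][\tlabel]``.  Self-pairs
    are dropped, duplicates in either orientation collapse to one pair, rows
    whose detection-method code is outside ``accepted_mi_codes`` (when given)
    are dropped, and rows referencing proteins absent from ``proteome`` (when
    given) are dropped and counted in the skip log.
    """
    path = Path(path)
    out = InteractionSet(provenance=provenance or str(path))
    n_unknown = n_filtered = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "protein_a" or header[1] != "protein_b":
            raise ParseError(f"{path}:1: expected 'protein_a\\tprotein_b...' header")
        mi_col = header.index("mi_code") if "mi_code" in header else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns")
            a, b = cols[0], cols[1]
            if not a or not b:
                raise ParseError(f"{path}:{lineno}: empty protein identifier")
            if mi_col is not None and accepted_mi_codes is not None:
                if len(cols) <= mi_col or cols[mi_col] not in accepted_mi_codes:
                    n_filtered += 1
                    continue
            if proteome is not None and (a not in proteome or b not in proteome):
                n_unknown += 1
                continue
            out.add(a, b)
    if n_unknown or n_filtered:
        logger.info("read_interactions(%s): skipped %d rows with unknown "
                    "proteins, %d rows filtered by MI code",
                    path, n_unknown, n_filtered)
    out.n_skipped_unknown = n_unknown  # type: ignore[attr-defined]
    out.n_filtered_mi = n_filtered  # type: ignore[attr-defined]
    return out


def write_interactions(interactions: InteractionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in interactions.sorted_pairs():
            fh.write(f"{a}\t{b}\n")


def mi_descendant_closure(dag: OntologyDAG, root_code: str) -> set[str]:
    """The term plus every descendant, e.g. all direct-biophysical PSI-MI codes
    under the physical-association detection method MI:0407."""
    if root_code not in dag:
        raise KeyError(f"unknown ontology term {root_code!r}")
    return dag.descendants(root_code, include_self=True)


# ---------------------------------------------------------------------------
# OBO / GAF / domain files
# ---------------------------------------------------------------------------

def read_obo(path: str | Path) -> OntologyDAG:
    """Read an OBO 1.2 ontology into an :class:`OntologyDAG` (is_a edges only)."""
    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:
        raise ParseError(f"cannot parse OBO {path}: {exc}") from exc
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        parents.setdefault(term, set())
        if "namespace" in data:
            namespace[term] = data["namespace"]
    # obonet edges run child -> parent, keyed by relation type
    for child, parent, rel in graph.edges(keys=True):
        if rel == "is_a":
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
    return OntologyDAG(parents, namespace)


#: GAF 2.x columns (17 in total); the ones this reader uses.
_GAF_COLS = 17
_GAF_OBJECT_ID = 1
_GAF_QUALIFIER = 3
_GAF_GO_ID = 4


def read_gaf(path: str | Path, proteome: Proteome,
             accession_to_gene: Mapping[str, str] | None = None) -> AnnotationMap:
    """Read a GAF 2.x annotation file restricted to a proteome.

    Rows whose qualifier contains ``NOT`` are skipped; evidence codes are not
    filtered.  When ``accession_to_gene`` is supplied, rows keyed by a protein
    accession that is absent from the proteome but maps to a gene with a
    retained record have their annotations unioned onto that gene's record.
    """
    ann = AnnotationMap()
    gene_rep: dict[str, str] = {}
    for rec in proteome:
        gene_rep.setdefault(rec.gene_id, rec.protein_id)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != _GAF_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_GAF_COLS} GAF columns, "
                    f"got {len(cols)}")
            if "NOT" in cols[_GAF_QUALIFIER].split("|"):
                continue
            acc, term = cols[_GAF_OBJECT_ID], cols[_GAF_GO_ID]
            if acc in proteome:
                ann.add(acc, term)
            elif accession_to_gene is not None:
                gene = accession_to_gene.get(acc)
                if gene is not None and gene in gene_rep:
                    ann.add(gene_rep[gene], term)
    return ann


def read_domains(path: str | Path, proteome: Proteome) -> AnnotationMap:
    """Read a ``protein_id\tdatabase\taccession`` TSV of domain assignments."""
    ann = AnnotationMap()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_id", "database", "accession"]:
            raise ParseError(f"{path}:1: expected "
                             "'protein_id\\tdatabase\\taccession' header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            pid, db, acc = cols[0], cols[1], cols[2]
            if pid in proteome:
                ann.add(pid, (db, acc))
    return ann


def write_domains(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdatabase\taccession\n")
        for pid in ann.proteins():
            for db, acc in sorted(ann.get(pid)):
                fh.write(f"{pid}\t{db}\t{acc}\n")


def write_obo(dag: OntologyDAG, path: str | Path,
              ontology_name: str = "toy") -> None:
    """Write a minimal OBO 1.2 file readable by :func:`read_obo`."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            ns = dag.namespace.get(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent in sorted(dag.parents[term]):
                fh.write(f"is_a: {parent} ! {parent}\n")
            fh.write("\n")


def write_gaf(ann: AnnotationMap, dag: OntologyDAG, path: str | Path) -> None:
    """Write annotations as GAF 2.2 rows (one per protein-term assignment)."""
    aspect = {"biological_process": "P", "molecular_function": "F",
              "cellular_component": "C"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for pid in ann.proteins():
            for term in sorted(ann.get(pid)):
                asp = aspect.get(dag.namespace.get(term, ""), "P")
                cols = ["SYNTH", pid, pid, "enables", term, "SYNTH:0",
                        "IEA", "", asp, "", "", "protein", "taxon:0000",
                        "20210101", "SYNTH", "", ""]
                fh.write("\t".join(cols) + "\n")
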