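"""Readers and writers for every external format the toolkit touches.

Formats: multi-record FASTA for sequences; comma-separated annotation rows
(protein ID followed by its category numbers); tab-separated alignment hits
(standard 12-column tabular with the bit score in column 12, or a minimal
3-column query/subject/score dialect); tab-separated weighted interaction
edges (STRING-like combined scores); an optional 2-column ID map between the
annotation and network namespaces; and a plain YAML config.

Readers validate strictly and name the offending line; they never silently
repair malformed input.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import FunctionScheme

CONFIG_KEYS = {"lambda", "omega", "properties", "tie_rule", "seed", "folds", "repeats"}


@dataclass
class Dataset:
    """Everything one prediction/evaluation run consumes.

    ``annotations`` maps protein ID to its category-number set and preserves
    insertion order; ``similarity_hits`` are directed, HSP-aggregated
    (query, subject, score) triples; ``interaction_edges`` are undirected
    (a, b, weight) triples in the network ID space; ``id_map`` translates
    annotation-space IDs to network-space IDs (identity when absent —
    unmapped proteins simply lack interaction evidence).
    """

    sequences: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, frozenset[int]] = field(default_factory=dict)
    similarity_hits: list[tuple[str, str, float]] = field(default_factory=list)
    interaction_edges: list[tuple[str, str, float]] = field(default_factory=list)
    id_map: dict[str, str] | None = None

    def hits_by_query(self) -> dict[str, dict[str, float]]:
        """Similarity hits grouped per query, keeping the max score per pair."""
        out: dict[str, dict[str, float]] = {}
        for q, s, score in self.similarity_hits:
            row = out.setdefault(q, {})
            if score > row.get(s, -1.0):
                row[s] = score
        return out

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Undirected interaction neighbours in the *annotation* ID space.

        Edges are registered under both endpoints; parallel edges keep the
        maximum weight.  When an ``id_map`` is present, network IDs are
        translated back to every annotation ID that maps onto them.
        """
        if self.id_map is not None:
            reverse: dict[str, list[str]] = {}
            for ann_id, net_id in self.id_map.items():
                reverse.setdefault(net_id, []).append(ann_id)
        else:
            reverse = None
        adj: dict[str, dict[str, float]] = {}

        def names(net_id: str) -> list[str]:
            if reverse is None:
                return [net_id]
            return reverse.get(net_id, [])

        for a, b, w in self.interaction_edges:
            for pa in names(a):
                for pb in names(b):
                    if pa == pb:
                        continue
                    row = adj.setdefault(pa, {})
                    if w > row.get(pb, -1.0):
                        row[pb] = w
                    row = adj.setdefault(pb, {})
                    if w > row.get(pa, -1.0):
                        row[pa] = w
        return adj


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{id: upper-cased sequence}``.

    The record ID is the header token up to the first whitespace.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate record ID {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {record.id!r} has an empty sequence")
        sequences[record.id] = seq
    return sequences


def read_annotation_csv(path, scheme: FunctionScheme | None = None) -> list[tuple[str, frozenset[int]]]:
    """Read variable-width annotation rows: protein ID, then its categories."""
    scheme = scheme or FunctionScheme.funcat24()
    known = set(int(n) for n in scheme.numbers)
    out: list[tuple[str, frozenset[int]]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            row = [f.strip() for f in row if f.strip()]
            if not row:
                continue
            pid = row[0]
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: protein {pid!r} lists no categories")
            cats = []
            for f in row[1:]:
                try:
                    c = int(f)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: category {f!r} is not an integer"
                    ) from None
                if c not in known:
                    raise ValueError(
                        f"{path}:{lineno}: category {c} is not in the scheme"
                    )
                cats.append(c)
            if len(set(cats)) != len(cats):
                warnings.warn(
                    f"{path}:{lineno}: duplicate categories for {pid!r} collapsed",
                    stacklevel=2,
                )
            out.append((pid, frozenset(cats)))
    return out


def _parse_score(text: str, path, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: score {text!r} is not a number") from None
    if value < 0:
        raise ValueError(f"{path}:{lineno}: negative score {value}")
    return value


def read_similarity(path) -> list[tuple[str, str, float]]:
    """Read alignment hits, auto-detecting the 12-column or 3-column dialect.

    Multiple HSP lines for one (query, subject) pair are aggregated by
    keeping the maximum bit score.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 12:
                q, s, score = fields[0], fields[1], _parse_score(fields[11], path, lineno)
            elif len(fields) == 3:
                q, s, score = fields[0], fields[1], _parse_score(fields[2], path, lineno)
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            key = (q, s)
            if key not in best:
                order.append(key)
                best[key] = score
            elif score > best[key]:
                best[key] = score
    return [(q, s, best[(q, s)]) for q, s in order]


def read_interactions(path) -> list[tuple[str, str, float]]:
    """Read undirected weighted edges: protein1, protein2, combined score."""
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            edges.append((fields[0], fields[1], _parse_score(fields[2], path, lineno)))
    return edges


def read_id_map(path) -> dict[str, str]:
    """Read a 2-column annotation-ID to network-ID map."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            if fields[0] in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate mapping for {fields[0]!r}")
            mapping[fields[0]] = fields[1]
    return mapping


def read_config(path) -> dict:
    """Read a YAML config; only the documented keys are accepted."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


# ---------------------------------------------------------------------------
# writers


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_annotation_csv(annotations, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        items = annotations.items() if hasattr(annotations, "items") else annotations
        for pid, cats in items:
            writer.writerow([pid, *sorted(cats)])


def write_similarity(hits, path) -> None:
    with open(path, "w") as fh:
        for q, s, score in hits:
            fh.write(f"{q}\t{s}\t{score:g}\n")


def write_interactions(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:g}\n")


def write_id_map(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def write_dataset(dataset: Dataset, directory) -> None:
    """Write a dataset as a fixture directory of plain-text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.sequences, directory / "sequences.fasta")
    write_annotation_csv(dataset.annotations, directory / "annotations.csv")
    write_similarity(dataset.similarity_hits, directory / "similarity.tsv")
    write_interactions(dataset.interaction_edges, directory / "interactions.tsv")
    if dataset.id_map is not None:
        write_id_map(dataset.id_map, directory / "id_map.tsv")


def read_dataset(directory, scheme: FunctionScheme | None = None) -> Dataset:
    """Read back a fixture directory written by :func:`write_dataset`."""
    directory = Path(directory)
    id_map_path = directory / "id_map.tsv"
    return Dataset(
        sequences=read_fasta(directory / "sequences.fasta"),
        annotations=dict(read_annotation_csv(directory / "annotations.csv", scheme)),
        similarity_hits=read_similarity(directory / "similarity.tsv"),
        interaction_edges=read_interactions(directory / "interactions.tsv"),
        id_map=read_id_map(id_map_path) if id_map_path.exists() else None,
    )
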