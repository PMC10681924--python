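"""Gene-target set handling: loading, union, intersection and the
compound-target bipartite network.

Disease-associated genes arrive as one list per source database; drug
(compound-predicted) targets arrive either as a flat list or as a
per-compound map with optional prediction scores.  Symbols are
normalised to uppercase, whitespace-free tokens; no alias or HGNC
resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "TargetSet",
    "CompoundTargetMap",
    "BipartiteNetwork",
    "load_gene_list",
    "write_gene_list",
    "union_disease_targets",
    "intersect_drug_disease",
    "load_target_map",
    "build_bipartite",
    "venn_counts",
]


class ValidationError(ValueError):
    pass


def normalize_symbol(sym: str) -> str:
    s = "".join(str(sym).split()).upper()
    if not s:
        raise ValidationError(f"empty gene symbol from {sym!r}")
    return s


@dataclass
class TargetSet:
    """A named set of gene symbols from one source."""

    name: str
    genes: frozenset
    kind: str = "disease"  # "drug" | "disease"

    def __post_init__(self) -> None:
        if self.kind not in ("drug", "disease"):
            raise ValidationError(f"kind must be drug or disease, got {self.kind!r}")
        self.genes = frozenset(normalize_symbol(g) for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in self.genes


def load_gene_list(path: Union[str, Path], name: str, kind: str = "disease") -> tuple[TargetSet, dict]:
    """Read a one-symbol-per-line file into a TargetSet.

    Blank lines are ignored; symbols are case-folded to uppercase and
    deduplicated.  Returns ``(target_set, stats)`` where stats reports
    ``raw`` (non-blank lines) vs ``unique`` counts.
    """
    raw = 0
    genes = set()
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if not tok:
                continue
            raw += 1
            genes.add(normalize_symbol(tok))
    return TargetSet(name=name, genes=frozenset(genes), kind=kind), {"raw": raw, "unique": len(genes)}


def write_gene_list(ts: TargetSet, path: Union[str, Path]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(ts.genes)))


def union_disease_targets(sets: Sequence[TargetSet], name: str = "disease_union") -> tuple[TargetSet, dict]:
    """Union of all disease-source sets after deduplication.

    Returns the merged set plus per-source counts for a Venn/upset report.
    Mixing drug-kind sets in raises :class:`ValidationError`.
    """
    if any(s.kind != "disease" for s in sets):
        raise ValidationError("union_disease_targets requires disease-kind sets only")
    merged: frozenset = frozenset()
    for s in sets:
        merged = merged | s.genes
    counts = {s.name: len(s.genes) for s in sets}
    counts["union"] = len(merged)
    return TargetSet(name=name, genes=merged, kind="disease"), counts


def intersect_drug_disease(drug: TargetSet, disease: TargetSet, name: str = "common") -> TargetSet:
    """Venn intersection: the drug-disease common target set."""
    return TargetSet(name=name, genes=drug.genes & disease.genes, kind="drug")


def venn_counts(sets: Sequence[TargetSet]) -> list[dict]:
    """Per-source and pairwise-intersection counts (TSV-ready rows)."""
    rows = [{"set_a": s.name, "set_b": "", "count": len(s.genes)} for s in sets]
    for i, a in enumerate(sets):
        for b in sets[i + 1 :]:
            rows.append({"set_a": a.name, "set_b": b.name, "count": len(a.genes & b.genes)})
    return rows


@dataclass
class CompoundTargetMap:
    """Per-compound predicted target genes, optionally score-filtered.

    ``score_floor`` applies an inclusive >= cut when scores are present
    (prediction confidence in [0, 1]).
    """

    entries: dict
    score_floor: float = 0.8

    def __post_init__(self) -> None:
        self.entries = {str(c): frozenset(normalize_symbol(g) for g in gs) for c, gs in self.entries.items()}

    def all_targets(self) -> frozenset:
        out: frozenset = frozenset()
        for gs in self.entries.values():
            out = out | gs
        return out


def load_target_map(path: Union[str, Path], score_floor: float = 0.8) -> CompoundTargetMap:
    """Read a compound→gene TSV (2 columns, or 3 with a score).

    With a third column present, rows with score < ``score_floor`` are
    dropped (inclusive >= keeps the boundary).
    """
    entries: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"line {ln}: expected 'compound<TAB>gene[<TAB>score]'")
            comp, gene = parts[0].strip(), parts[1]
            if len(parts) >= 3 and parts[2].strip():
                if float(parts[2]) < score_floor:
                    continue
            entries.setdefault(comp, set()).add(normalize_symbol(gene))
    return CompoundTargetMap(entries={c: frozenset(g) for c, g in entries.items()}, score_floor=score_floor)


@dataclass
class BipartiteNetwork:
    """Compound-target bipartite graph (the drug-target network)."""

    compound_nodes: list
    target_nodes: list
    edges: set  # {(compound, gene)}

    def __post_init__(self) -> None:
        comp, tgt = set(self.compound_nodes), set(self.target_nodes)
        for c, g in self.edges:
            if c not in comp or g not in tgt:
                raise ValidationError(f"edge ({c}, {g}) has an endpoint outside the node lists")


def build_bipartite(cmap: CompoundTargetMap, keep: TargetSet) -> BipartiteNetwork:
    """Edges {(c, g) : g in targets(c) ∩ keep}; edgeless compounds dropped."""
    edges = set()
    compounds = []
    targets = set()
    for comp in sorted(cmap.entries):
        hits = cmap.entries[comp] & keep.genes
        if hits:
            compounds.append(comp)
            for g in hits:
                edges.add((comp, g))
                targets.add(g)
    return BipartiteNetwork(compound_nodes=compounds, target_nodes=sorted(targets), edges=edges)


def write_sif(net: BipartiteNetwork, path: Union[str, Path], interaction: str = "interacts") -> None:
    """Write the bipartite network in Cytoscape simple-interaction format."""
    with open(path, "w") as fh:
        for c, g in sorted(net.edges):
            fh.write(f"{c}\t{interaction}\t{g}\n")
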