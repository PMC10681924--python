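"""Hypergeometric over-representation analysis (ORA) of a gene set.

Given a query set (e.g. the drug-disease common targets), annotation
collections in GMT format (GO biological process / cellular component /
molecular function, or pathways), and a gene universe, each term is
tested with the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the term size within the universe,
n the query size and k the observed overlap.  P-values are adjusted by
Benjamini-Hochberg within each category.  The default significance
filter is on the raw p-value (<= 0.05), with adjusted-p filtering
available; terms with zero overlap are omitted rather than scored 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from scipy.stats import hypergeom

from .target_sets import TargetSet, normalize_symbol

__all__ = [
    "GeneSet",
    "EnrichmentRecord",
    "read_gmt",
    "write_gmt",
    "hypergeom_tail",
    "benjamini_hochberg",
    "run_ora",
    "select_top",
]

CATEGORIES = ("BP", "CC", "MF", "pathway")

DEFAULT_TOP_N = {"BP": 10, "CC": 10, "MF": 10, "pathway": 30}


class ValidationError(ValueError):
    pass


class GmtFormatError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    """One annotation term and its member genes."""

    term_id: str
    term_name: str
    category: str
    members: frozenset

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if not self.members:
            raise ValidationError(f"{self.term_id}: empty gene set")


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    category: str
    k: int  # overlap
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    p_value: float
    p_adjusted: float = float("nan")


def read_gmt(path: Union[str, Path], category: str = "pathway") -> list[GeneSet]:
    """Parse a GMT file: ``term<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are deduplicated.  A line with fewer
    than three fields raises :class:`GmtFormatError` with its number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtFormatError(f"line {ln}: GMT lines need term, description and >=1 gene")
            members = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
            sets.append(GeneSet(term_id=parts[0], term_name=parts[1], category=category, members=members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail p-value P(X >= k) for X ~ Hypergeom(N, K, n).

    Exact for any valid counts (scipy evaluates the pmf in log space).
    ``k = 0`` gives 1 by definition.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValidationError(f"impossible counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values (FDR), in the input order.

    adj_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j),
    capped at 1; preserves the ordering of the raw p-values.
    """
    m = len(p_values)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p_values[i] * m / rank_from_top)
        adj[i] = running
    return adj


def run_ora(
    query: TargetSet,
    collection: Sequence[GeneSet],
    universe: Optional[TargetSet] = None,
) -> list[EnrichmentRecord]:
    """Test every term against the query; BH-adjust within category.

    The universe defaults to the union of all collection members (the
    background is rarely stated in published screens; this default is the
    common ORA-tool fallback and is logged by the pipeline).  Query genes
    outside the universe are dropped; each term is intersected with the
    universe before testing.  Terms with zero overlap are omitted.
    Records are sorted by p-value ascending, ties by term_id.
    """
    if universe is None:
        members: frozenset = frozenset()
        for s in collection:
            members = members | s.members
        universe = TargetSet(name="collection_union", genes=members, kind="disease")
    if len(universe.genes) == 0:
        raise ValidationError("empty universe")
    q = query.genes & universe.genes
    records: list[EnrichmentRecord] = []
    N, n = len(universe.genes), len(q)
    for s in collection:
        term = s.members & universe.genes
        k = len(term & q)
        if k == 0:
            continue
        records.append(
            EnrichmentRecord(
                term_id=s.term_id,
                term_name=s.term_name,
                category=s.category,
                k=k,
                K=len(term),
                n=n,
                N=N,
                p_value=hypergeom_tail(k, len(term), n, N),
            )
        )
    # BH within each category, then global sort
    out: list[EnrichmentRecord] = []
    for cat in CATEGORIES:
        cat_recs = [r for r in records if r.category == cat]
        if not cat_recs:
            continue
        adj = benjamini_hochberg([r.p_value for r in cat_recs])
        for r, a in zip(cat_recs, adj):
            out.append(replace(r, p_adjusted=a))
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out


def select_top(
    records: Sequence[EnrichmentRecord],
    per_category: Optional[Mapping[str, int]] = None,
    alpha: float = 0.05,
    filter_on: str = "raw",
) -> list[EnrichmentRecord]:
    """Significance filter then per-category head.

    Keeps records with p <= ``alpha`` (raw p by default, matching the
    conventional reporting; ``filter_on="adjusted"`` uses BH-adjusted p),
    then the first N per category in the incoming order (defaults: 10 for
    each GO category, 30 for pathways).
    """
    if filter_on not in ("raw", "adjusted"):
        raise ValidationError("filter_on must be 'raw' or 'adjusted'")
    limits = dict(DEFAULT_TOP_N)
    if per_category:
        limits.update(per_category)
    taken = {c: 0 for c in CATEGORIES}
    out = []
    for r in records:
        p = r.p_value if filter_on == "raw" else r.p_adjusted
        if p > alpha:
            continue
        if taken[r.category] >= limits.get(r.category, 0):
            continue
        taken[r.category] += 1
        out.append(r)
    return out


def write_enrichment_table(records: Sequence[EnrichmentRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tterm_name\tcategory\tk\tK\tn\tN\tp_value\tp_adjusted\n")
        for r in records:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.category}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.p_adjusted:.6g}\n"
            )
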