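"""Seeded generators for every input the screening pipeline consumes.

Each generator plants a known answer (which compounds pass the ADMET
screen, which genes are common to drug and disease lists, which nodes
form the dense PPI core, which annotation term is enriched, what the
true IC50 is) and records it in a manifest, so every downstream stage
has recoverable ground truth.  One integer seed drives a named
substream per generator: adding a generator never perturbs the draws of
the others, and identical configurations produce byte-identical files.

Defaults mirror the published screen's structure — seven doses from 50
to 1000 ug/mL, five disease sources, a two-round core extraction — at
desk-size networks (hundreds of genes, 100-node PPI graphs).  Gene
symbols are synthesized "G000001"-style tokens, not real gene names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = ["SyntheticConfig", "gen_compounds", "gen_target_universe", "gen_ppi", "gen_gene_sets", "gen_plate", "generate_all"]

# fixed substream ids; never renumber (determinism contract)
_STREAMS = {"compounds": 1, "targets": 2, "ppi": 3, "gene_sets": 4, "plate": 5}

#: the seven assay concentrations, ug/mL
DEFAULT_DOSES = (50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0)


class ValidationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Knobs for all generators; the seed fixes every draw."""

    seed: int = 0
    # compound table
    n_compounds: int = 21
    admet_pass_fraction: float = 0.8
    # disease sources
    n_sources: int = 5
    source_sizes: Sequence[int] = (250, 60, 40, 50, 80)
    overlap_gene_count: int = 25
    disjoint_sources: bool = False
    universe_size: int = 500
    # drug targets
    drug_targets_per_compound: int = 12
    common_target_count: int = 40
    # PPI
    ppi_nodes: int = 100
    ppi_core_size: int = 10
    core_density: float = 0.9
    periphery_density: float = 0.03
    edge_score_range: tuple = (0.9, 1.0)
    # gene sets
    n_terms: int = 50
    term_size_range: tuple = (10, 50)
    planted_term_overlap: int = 15
    query_size: int = 20
    # plate
    ic50_true: float = 524.0
    hill_true: float = 2.0
    od_noise_sd: float = 0.03
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.core_density <= self.periphery_density:
            raise ValidationError("core_density must exceed periphery_density")
        if not (0.0 <= self.admet_pass_fraction <= 1.0):
            raise ValidationError("admet_pass_fraction outside [0, 1]")
        if self.ppi_core_size >= self.ppi_nodes:
            raise ValidationError("ppi_core_size must be smaller than ppi_nodes")
        if self.planted_term_overlap > self.query_size:
            raise ValidationError("planted_term_overlap cannot exceed query_size")
        for name, v in (("n_compounds", self.n_compounds), ("n_sources", self.n_sources),
                        ("universe_size", self.universe_size), ("n_terms", self.n_terms)):
            if v <= 0:
                raise ValidationError(f"{name} must be positive")


def _rng(cfg: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


def _gene_pool(n: int, prefix: str = "G") -> list:
    return [f"{prefix}{i:06d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------- compounds

_COMPOUND_HEADER = (
    "Name\tFormula\tCanonical SMILES\tCID No\tTime\tPeak area %\t"
    "Drug likeness (DL)\tGI absorption (OB)\tP-gp substrate\tBBB\n"
)


def gen_compounds(cfg: SyntheticConfig, out_path) -> dict:
    """Write a compound table where exactly round(n * pass_fraction) rows
    satisfy the default ADMET screen; the manifest names the passers.

    Failing rows cycle through the four rejection causes (low GI
    absorption, P-gp substrate, drug-likeness fail, too many
    violations).  All peak areas exceed the default 0.12 % cut so the
    ADMET rules alone decide the outcome.
    """
    rng = _rng(cfg, "compounds")
    n = cfg.n_compounds
    n_pass = int(round(n * cfg.admet_pass_fraction))
    pass_flags = np.zeros(n, dtype=bool)
    pass_flags[rng.choice(n, size=n_pass, replace=False)] = True

    fail_modes = ["gi", "pgp", "dl", "violations"]
    rows, passers = [], []
    fail_i = 0
    for i in range(n):
        name = f"Compound-{i + 1:03d}"
        c = int(rng.integers(5, 21))
        h = int(rng.integers(6, 2 * c + 3))
        o = int(rng.integers(0, 5))
        formula = f"C{c}H{h}" + ("" if o == 0 else ("O" if o == 1 else f"O{o}"))
        smiles = "C" * min(c, 9) + ("O" if o else "")
        rt = float(np.round(rng.uniform(5, 50), 2))
        area = float(np.round(rng.uniform(0.13, 12.0), 2))
        gi, pgp, dl, viol, bbb = "High", "No", "Yes", 0, ("Yes" if rng.random() < 0.8 else "No")
        if not pass_flags[i]:
            mode = fail_modes[fail_i % len(fail_modes)]
            fail_i += 1
            if mode == "gi":
                gi = "Low"
            elif mode == "pgp":
                pgp = "Yes"
            elif mode == "dl":
                dl, viol = "No", 3
            else:
                viol = 2
        else:
            viol = int(rng.integers(0, 2))  # 0 or 1, both pass defaults
            passers.append(name)
        rows.append(
            f"{name}\t{formula}\t{smiles}\t{900000 + i}\t{rt}\t{area}\t"
            f"{dl}; {viol} violation\t{gi}\t{pgp}\t{bbb}\n"
        )
    Path(out_path).write_text(_COMPOUND_HEADER + "".join(rows))
    return {"n_compounds": n, "n_pass": n_pass, "passing_compounds": passers}


# ------------------------------------------------------------------ targets

def gen_target_universe(cfg: SyntheticConfig, out_dir) -> dict:
    """Write per-source disease gene lists plus a per-compound drug-target
    map with a planted drug-disease common set.

    Every disease source contains the designated shared core of
    ``overlap_gene_count`` genes (unless ``disjoint_sources``); the drug
    map's retained entries (score >= 0.8) intersect the disease union in
    exactly ``common_target_count`` genes.  A handful of sub-threshold
    decoy rows exercises the score filter.  The manifest states exact
    union, pairwise-intersection and common-target memberships.
    """
    rng = _rng(cfg, "targets")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pool = _gene_pool(cfg.universe_size)

    sources: dict = {}
    if cfg.disjoint_sources:
        start = 0
        for i, size in enumerate(cfg.source_sizes[: cfg.n_sources]):
            sources[f"source_{i + 1}"] = set(pool[start : start + size])
            start += size
    else:
        core = list(rng.choice(pool, size=cfg.overlap_gene_count, replace=False))
        rest = [g for g in pool if g not in set(core)]
        for i, size in enumerate(cfg.source_sizes[: cfg.n_sources]):
            extra = max(size - len(core), 0)
            picked = list(rng.choice(rest, size=min(extra, len(rest)), replace=False))
            sources[f"source_{i + 1}"] = set(core) | set(picked)

    union: set = set()
    for genes in sources.values():
        union |= genes
    for name, genes in sources.items():
        (out / f"{name}.txt").write_text("".join(f"{g}\n" for g in sorted(genes)))

    # drug-target map: planted common genes from the union, plus genes
    # guaranteed outside it (D-prefixed) so the intersection is exact
    union_sorted = sorted(union)
    commons = list(rng.choice(union_sorted, size=min(cfg.common_target_count, len(union_sorted)), replace=False))
    decoy_pool = _gene_pool(cfg.universe_size, prefix="D")
    compounds = [f"Compound-{i + 1:03d}" for i in range(cfg.n_compounds)]
    lines, entries = [], {}
    ci = 0
    for comp in compounds:
        k_common = min(len(commons) - ci, max(1, cfg.drug_targets_per_compound // 3)) if ci < len(commons) else 0
        mine = commons[ci : ci + k_common]
        ci += k_common
        n_out = cfg.drug_targets_per_compound - len(mine)
        mine = mine + list(rng.choice(decoy_pool, size=max(n_out, 0), replace=False))
        entries[comp] = set(mine)
        for g in mine:
            lines.append(f"{comp}\t{g}\t{rng.uniform(0.8, 1.0):.3f}\n")
        # sub-threshold decoys the loader must drop
        for g in rng.choice(decoy_pool, size=2, replace=False):
            lines.append(f"{comp}\t{g}X\t{rng.uniform(0.1, 0.79):.3f}\n")
    # any planted commons not yet assigned go to the last compound
    if ci < len(commons):
        leftovers = commons[ci:]
        entries[compounds[-1]] |= set(leftovers)
        for g in leftovers:
            lines.append(f"{compounds[-1]}\t{g}\t{rng.uniform(0.8, 1.0):.3f}\n")
    (out / "drug_targets.tsv").write_text("".join(lines))

    names = sorted(sources)
    manifest = {
        "sources": {k: sorted(sources[k]) for k in names},
        "source_sizes": {k: len(sources[k]) for k in names},
        "union_size": len(union),
        "union": sorted(union),
        "pairwise_intersections": {
            f"{a}&{b}": len(sources[a] & sources[b]) for i, a in enumerate(names) for b in names[i + 1 :]
        },
        "common_targets": sorted(commons),
        "n_common": len(commons),
    }
    return manifest


# ---------------------------------------------------------------------- PPI

def gen_ppi(
    cfg: SyntheticConfig,
    out_path,
    node_names: Optional[Sequence[str]] = None,
    core_nodes: Optional[Sequence[str]] = None,
) -> dict:
    """Write a scored edge list: Erdos-Renyi periphery plus a planted
    dense quasi-clique core.

    Within-core pairs connect with probability ``core_density``; every
    other pair with ``periphery_density``.  Scores are uniform in
    ``edge_score_range``.  The manifest lists the planted core nodes.
    """
    rng = _rng(cfg, "ppi")
    nodes = list(node_names) if node_names is not None else _gene_pool(cfg.ppi_nodes, prefix="P")
    if len(nodes) != cfg.ppi_nodes:
        raise ValidationError("node_names length must equal cfg.ppi_nodes")
    if core_nodes is not None:
        core = set(core_nodes)
        if not core <= set(nodes) or len(core) != cfg.ppi_core_size:
            raise ValidationError("core_nodes must be ppi_core_size names drawn from node_names")
    else:
        core = set(rng.choice(nodes, size=cfg.ppi_core_size, replace=False))
    lo, hi = cfg.edge_score_range
    lines = []
    n_edges = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            p = cfg.core_density if (a in core and b in core) else cfg.periphery_density
            if rng.random() < p:
                lines.append(f"{a}\t{b}\t{rng.uniform(lo, hi):.4f}\n")
                n_edges += 1
    Path(out_path).write_text("".join(lines))
    return {"nodes": nodes, "core_nodes": sorted(core), "n_edges": n_edges}


# ---------------------------------------------------------------- gene sets

def gen_gene_sets(cfg: SyntheticConfig, gmt_path, query_path=None, category: str = "pathway",
                  query_genes: Optional[Sequence[str]] = None) -> dict:
    """Write a GMT collection with one planted enriched term.

    Random terms draw uniformly from the synthetic universe; the planted
    term shares ``planted_term_overlap`` genes with the emitted query.
    With overlap 0 the planted term contains no query gene at all.
    """
    rng = _rng(cfg, "gene_sets")
    pool = _gene_pool(cfg.universe_size)
    if query_genes is None:
        query = list(rng.choice(pool, size=cfg.query_size, replace=False))
    else:
        query = list(query_genes)
    lo, hi = cfg.term_size_range
    lines = []
    for t in range(1, cfg.n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(pool, size=size, replace=False))
        lines.append("\t".join([f"{category}_T{t:03d}", f"random term {t}", *members]) + "\n")
    # planted term
    size = max(int(rng.integers(lo, hi + 1)), cfg.planted_term_overlap)
    overlap = list(rng.choice(query, size=cfg.planted_term_overlap, replace=False)) if cfg.planted_term_overlap else []
    non_query = [g for g in pool if g not in set(query)]
    filler = list(rng.choice(non_query, size=size - len(overlap), replace=False))
    planted_id = f"{category}_PLANTED"
    lines.append("\t".join([planted_id, "planted enriched term", *(overlap + filler)]) + "\n")
    Path(gmt_path).write_text("".join(lines))
    if query_path is not None:
        Path(query_path).write_text("".join(f"{g}\n" for g in query))
    return {"planted_term": planted_id, "overlap": len(overlap), "query": sorted(query), "n_terms": cfg.n_terms + 1}


# -------------------------------------------------------------------- plate

def gen_plate(cfg: SyntheticConfig, out_path, doses: Sequence[float] = DEFAULT_DOSES) -> dict:
    """Write an MTT plate TSV: replicate ODs drawn from a 4PL at the
    seven assay doses, plus blank and control wells.

    OD = blank + viability/100 * (control - blank) + N(0, sd * range),
    clipped at 0.  The manifest records the true IC50 and Hill slope.
    """
    rng = _rng(cfg, "plate")
    blank_od, control_od = 0.05, 0.95
    span = control_od - blank_od
    reps = cfg.n_replicates
    lines = [f"dose\t" + "\t".join(f"od{r + 1}" for r in range(reps)) + "\n"]

    def wells(mean_od):
        vals = mean_od + rng.normal(0.0, cfg.od_noise_sd * span, size=reps)
        return "\t".join(f"{max(v, 0.0):.4f}" for v in vals)

    lines.append("blank\t" + wells(blank_od) + "\n")
    lines.append("control\t" + wells(control_od) + "\n")
    for d in doses:
        v = 100.0 / (1.0 + (d / cfg.ic50_true) ** cfg.hill_true)
        lines.append(f"{d:g}\t" + wells(blank_od + v / 100.0 * span) + "\n")
    Path(out_path).write_text("".join(lines))
    return {"ic50_true": cfg.ic50_true, "hill_true": cfg.hill_true, "doses": list(doses),
            "od_noise_sd": cfg.od_noise_sd, "n_replicates": reps}


# ---------------------------------------------------------------------- all

def generate_all(cfg: SyntheticConfig, out_dir) -> dict:
    """Emit every pipeline input into ``out_dir`` plus manifest.json.

    The PPI graph is laid over the planted common targets (padded with
    other disease-union genes up to ``ppi_nodes``), and the planted PPI
    core is drawn inside the common set so core extraction has in-common
    ground truth.  Annotation collections (BP/CC/MF/pathway) are planted
    against the common-target query.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(cfg)}
    manifest["compounds"] = gen_compounds(cfg, out / "compounds.tsv")
    tgt = gen_target_universe(cfg, out / "targets")
    manifest["targets"] = tgt

    commons = tgt["common_targets"]
    others = [g for g in tgt["union"] if g not in set(commons)]
    ppi_nodes = (commons + others)[: cfg.ppi_nodes]
    if len(ppi_nodes) < cfg.ppi_nodes:
        raise ValidationError("disease union too small for requested ppi_nodes")
    # plant the dense core inside the common-target block
    manifest["ppi"] = gen_ppi(cfg, out / "ppi_edges.tsv", node_names=ppi_nodes,
                              core_nodes=commons[: cfg.ppi_core_size])

    gs = {}
    for cat in ("BP", "CC", "MF", "pathway"):
        sub = SyntheticConfig(**{**asdict(cfg), "seed": cfg.seed + _category_offset(cat)})
        gs[cat] = gen_gene_sets(sub, out / f"genesets_{cat}.gmt", category=cat, query_genes=commons[: cfg.query_size])
    manifest["gene_sets"] = gs
    manifest["plate"] = gen_plate(cfg, out / "plate.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _category_offset(cat: str) -> int:
    return {"BP": 101, "CC": 102, "MF": 103, "pathway": 104}[cat]
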