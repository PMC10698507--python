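"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study design end to end: replicate peak sets
sharing a planted fraction of common regions, differential-expression
tables with planted up-regulated genes, multi-plate high-content screens
with a block of control wells per plate and planted pro-/anti-phenotype
effect genes, scale-free weighted interaction networks with a planted
dense module around designated seeds, and a toy term ontology for
similarity weighting. Every planted signal is reported in a ground-truth
manifest returned alongside the data (and written to a separate file by
the pipeline, never read by analysis stages). All generators are pure
functions of their spec, seed included.

Readout noise is log-normal on raw intensities — imaging intensities are
positive and right-skewed — with gene effects additive on the log scale
in units of the noise SD, and plate effects additive log-scale shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .regions import GeneModel, PeakSet

DEFAULT_READOUTS = ["ICAM1", "ROS", "VECAD", "NUCLEI"]
CONTROL_LABEL = "scramble"
# typical log median intensities / counts for the four channels
_BASELINE_LOG = {"ICAM1": 7.0, "ROS": 6.5, "VECAD": 7.2, "NUCLEI": 6.2}


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


# ---------------------------------------------------------------------------
# screen

@dataclass
class SyntheticScreenSpec:
    """Design of a simulated multi-plate knockdown screen.

    ``effect_genes`` maps gene -> {readout -> signed effect in SD units};
    positive effects raise the readout relative to controls.
    """

    n_genes: int = 81
    n_plates: int = 5
    controls_per_plate: int = 8
    readout_names: list[str] = field(default_factory=lambda: list(DEFAULT_READOUTS))
    effect_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.25
    plate_shift_sd: float = 0.25
    seed: int = 0

    def genes(self) -> list[str]:
        return [f"GENE{i + 1:03d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.n_plates >= 1, "n_plates", "must be >= 1")
        _check(self.controls_per_plate >= 2, "controls_per_plate", "must be >= 2")
        _check(len(self.readout_names) == 4, "readout_names", "exactly four readouts expected")
        _check(self.noise_sd > 0, "noise_sd", "must be > 0")
        _check(self.plate_shift_sd > 0, "plate_shift_sd", "must be > 0")
        unknown = set(self.effect_genes) - set(self.genes())
        _check(not unknown, "effect_genes", f"not a subset of genes: {sorted(unknown)}")
        for g, eff in self.effect_genes.items():
            bad = set(eff) - set(self.readout_names)
            _check(not bad, "effect_genes", f"{g} has unknown readouts {sorted(bad)}")


def gen_screen(spec: SyntheticScreenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a per-well screen table; returns (table, ground-truth manifest)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.genes()
    rows = []
    for p in range(1, spec.n_plates + 1):
        plate = f"P{p}"
        shifts = {r: rng.normal(0.0, spec.plate_shift_sd) for r in spec.readout_names}
        conditions = [CONTROL_LABEL] * spec.controls_per_plate + genes
        for w, cond in enumerate(conditions, start=1):
            row = {"plate": plate, "well": f"{plate}_W{w:03d}", "condition": cond}
            eff = spec.effect_genes.get(cond, {})
            for r in spec.readout_names:
                base = _BASELINE_LOG.get(r, 7.0)
                log_val = (
                    base
                    + shifts[r]
                    + eff.get(r, 0.0) * spec.noise_sd
                    + rng.normal(0.0, spec.noise_sd)
                )
                row[r] = float(np.exp(log_val))
            rows.append(row)
    table = pd.DataFrame(rows)
    manifest = pd.DataFrame(
        [
            {"gene": g, "readout": r, "effect_sd": e}
            for g, eff in spec.effect_genes.items()
            for r, e in eff.items()
        ],
        columns=["gene", "readout", "effect_sd"],
    )
    return table, manifest


def pro_effect(size_sd: float = 3.0) -> dict[str, float]:
    """Effect signature of a pro-dysfunction gene knockdown (exacerbates)."""
    return {"ICAM1": size_sd, "ROS": size_sd, "VECAD": -size_sd, "NUCLEI": -size_sd}


def anti_effect(size_sd: float = 3.0) -> dict[str, float]:
    """Effect signature of an anti-dysfunction gene knockdown (ameliorates)."""
    return {k: -v for k, v in pro_effect(size_sd).items()}


# ---------------------------------------------------------------------------
# network

@dataclass
class SyntheticNetworkSpec:
    """Scale-free interaction network with a planted dense module."""

    n_nodes: int = 400
    attachment_parameter: int = 3
    planted_module_nodes: list[str] = field(default_factory=list)
    planted_module_density: float = 0.5
    weight_range: tuple[float, float] = (0.1, 1.0)
    seed: int = 0

    def node_names(self) -> list[str]:
        return [f"GENE{i + 1:03d}" for i in range(self.n_nodes)]

    def validate(self) -> None:
        _check(self.n_nodes >= 2, "n_nodes", "must be >= 2")
        _check(
            1 <= self.attachment_parameter < self.n_nodes,
            "attachment_parameter",
            "must be in [1, n_nodes)",
        )
        _check(
            len(self.planted_module_nodes) <= self.n_nodes,
            "n_nodes",
            "smaller than the planted module",
        )
        unknown = set(self.planted_module_nodes) - set(self.node_names())
        _check(not unknown, "planted_module_nodes", f"not among node names: {sorted(unknown)}")
        _check(0 < self.planted_module_density <= 1, "planted_module_density", "must be in (0, 1]")
        lo, hi = self.weight_range
        _check(0 < lo <= hi <= 1, "weight_range", "must satisfy 0 < low <= high <= 1")


def gen_network(spec: SyntheticNetworkSpec) -> tuple[nx.Graph, dict]:
    """Preferential-attachment backbone plus planted module edges.

    Module-internal edges are added independently at the planted density;
    every edge weight is uniform in ``weight_range``. Returns
    (graph, manifest).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = nx.barabasi_albert_graph(
        spec.n_nodes, spec.attachment_parameter, seed=int(rng.integers(2**31))
    )
    names = spec.node_names()
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    module = list(spec.planted_module_nodes)
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            if spec.planted_module_density >= 1.0 or rng.random() < spec.planted_module_density:
                g.add_edge(module[i], module[j])
    lo, hi = spec.weight_range
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(lo, hi))
    manifest = {"module_nodes": sorted(module), "density": spec.planted_module_density}
    return g, manifest


# ---------------------------------------------------------------------------
# peaks

@dataclass
class SyntheticPeakSpec:
    """Replicate peak sets with a planted fraction of shared regions."""

    n_conditions: int = 4
    replicates_per_condition: int = 3
    genome_length: int = 2_000_000
    n_common_regions: int = 40
    n_private_regions_per_condition: int = 10
    peak_width_range: tuple[int, int] = (300, 800)
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_conditions >= 1, "n_conditions", "must be >= 1")
        _check(self.replicates_per_condition >= 1, "replicates_per_condition", "must be >= 1")
        lo, hi = self.peak_width_range
        _check(0 < lo <= hi, "peak_width_range", "widths must be positive")
        total = self.n_common_regions + self.n_conditions * self.n_private_regions_per_condition
        max_margin = _MARGIN_BASE + self.n_conditions * _MARGIN_STEP
        slot = hi + 2 * max_margin + 2 * _JITTER + hi  # peak + flanks + spacing
        _check(
            total * slot <= self.genome_length,
            "genome_length",
            f"cannot place {total} disjoint peak regions of width <= {hi}",
        )


# peak margins: each condition's peaks extend the planted region by a
# condition-specific flank; flank steps dominate the centre jitter so a
# peak of one condition nests inside the peak of any wider condition.
_MARGIN_BASE = 50
_MARGIN_STEP = 40
_JITTER = _MARGIN_STEP // 4


def gen_peak_replicates(
    spec: SyntheticPeakSpec,
) -> tuple[dict[str, list[PeakSet]], pd.DataFrame]:
    """Per-condition replicate peak sets; returns (map, region manifest).

    Each planted region is covered, in every replicate of its
    condition(s), by a peak spanning the region plus a condition-specific
    flank, with a small centre jitter (well under half the peak width).
    Because the flanks are spaced wider than the jitter, peaks over the
    same region nest across conditions, so the containment-based
    cross-condition intersection recovers every planted common region.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.peak_width_range
    max_margin = _MARGIN_BASE + spec.n_conditions * _MARGIN_STEP
    slot = hi + 2 * max_margin + 2 * _JITTER + hi  # peak + flanks + spacing
    n_slots = spec.genome_length // slot
    total = spec.n_common_regions + spec.n_conditions * spec.n_private_regions_per_condition
    if n_slots < total:
        raise ValueError("genome_length: planted regions would overlap")
    slots = rng.choice(n_slots, size=total, replace=False)

    regions = []
    for s in slots:
        width = int(rng.integers(lo, hi + 1))
        start = int(s) * slot + max_margin + _JITTER
        regions.append(("chr1", start, start + width))
    common = regions[: spec.n_common_regions]
    private = {
        f"cond{c + 1}": regions[
            spec.n_common_regions
            + c * spec.n_private_regions_per_condition : spec.n_common_regions
            + (c + 1) * spec.n_private_regions_per_condition
        ]
        for c in range(spec.n_conditions)
    }

    out: dict[str, list[PeakSet]] = {}
    for ci, (cond, priv) in enumerate(private.items()):
        margin = _MARGIN_BASE + ci * _MARGIN_STEP
        reps = []
        for r in range(spec.replicates_per_condition):
            rows = []
            for chrom, s, e in common + priv:
                jit = int(rng.integers(-_JITTER, _JITTER + 1))
                rows.append((chrom, max(0, s - margin + jit), e + margin + jit))
            reps.append(PeakSet.from_tuples(rows, label=f"{cond}_rep{r + 1}"))
        out[cond] = reps

    manifest_rows = [
        {"chrom": c, "start": s, "end": e, "kind": "common", "condition": ""}
        for c, s, e in common
    ]
    for cond, priv in private.items():
        manifest_rows += [
            {"chrom": c, "start": s, "end": e, "kind": "private", "condition": cond}
            for c, s, e in priv
        ]
    return out, pd.DataFrame(manifest_rows)


# ---------------------------------------------------------------------------
# DE tables, gene models, regulon, ontology

def gen_de_table(
    genes: list[str], planted_up: list[str], lfc_magnitude: float = 2.0, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE result table with planted up-regulated genes.

    Planted genes receive log2FC >= ``lfc_magnitude`` and adjusted
    p <= 0.01; background genes |log2FC| < 0.5 and adjusted p >= 0.2, so
    the standard cut (padj <= 0.05, |log2FC| >= 1.5) recovers exactly the
    planted set whenever ``lfc_magnitude >= 1.5``.
    """
    unknown = set(planted_up) - set(genes)
    _check(not unknown, "planted_up", f"not a subset of genes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    planted = set(planted_up)
    rows = []
    for g in genes:
        if g in planted:
            lfc = lfc_magnitude + abs(rng.normal(0.0, 0.3))
            padj = float(10 ** rng.uniform(-8, -2))
        else:
            lfc = float(rng.uniform(-0.45, 0.45))
            padj = float(rng.uniform(0.2, 1.0))
        rows.append({"gene": g, "log2fc": float(lfc), "pvalue": padj * rng.uniform(0.2, 1.0),
                     "padj": padj})
    table = pd.DataFrame(rows)
    manifest = pd.DataFrame({"gene": sorted(planted), "planted": "up"})
    return table, manifest


def gen_gene_models(
    regions: list[tuple[str, int, int]],
    genes_on_regions: list[str],
    background_genes: list[str] = (),
    seed: int = 0,
) -> list[GeneModel]:
    """One gene per region (TSS at the region midpoint) plus background genes.

    Background genes are placed on a separate chromosome so they never
    fall under the supplied regions.
    """
    _check(
        len(genes_on_regions) <= len(regions),
        "genes_on_regions",
        "more genes than regions to anchor them",
    )
    rng = np.random.default_rng(seed)
    models = []
    for (chrom, s, e), gene in zip(regions, genes_on_regions):
        tss = (s + e) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        span = (max(0, tss - 500), tss + 4500) if strand == "+" else (max(0, tss - 4500), tss + 500)
        exon1 = (tss, tss + 200) if strand == "+" else (tss - 200, tss)
        models.append(
            GeneModel(gene=gene, chrom=chrom, strand=strand, tss=tss, gene_span=span,
                      exons=[exon1])
        )
    pos = 10_000
    for gene in background_genes:
        models.append(
            GeneModel(gene=gene, chrom="chr_bg", strand="+", tss=pos,
                      gene_span=(pos - 500, pos + 4500), exons=[(pos, pos + 200)])
        )
        pos += 20_000
    return models


def gen_regulon(
    tfs: list[str], targets: list[str], decoy_pairs: list[tuple[str, str]] = (), seed: int = 0
) -> pd.DataFrame:
    """TRRUST-like TF->target table covering the given targets round-robin."""
    _check(len(tfs) >= 1, "tfs", "need at least one TF")
    rows = [
        {"tf": tfs[i % len(tfs)], "target": t, "evidence": "planted"}
        for i, t in enumerate(targets)
    ]
    rows += [{"tf": a, "target": b, "evidence": "decoy"} for a, b in decoy_pairs]
    return pd.DataFrame(rows, columns=["tf", "target", "evidence"]).drop_duplicates(
        subset=["tf", "target"]
    ).reset_index(drop=True)


def gen_ontology(n_branches: int = 3, depth: int = 3, fanout: int = 2):
    """Toy single-root term DAG; returns (edges child->parent, leaves per branch)."""
    _check(n_branches >= 1, "n_branches", "must be >= 1")
    _check(depth >= 1, "depth", "must be >= 1")
    edges = []
    leaves: dict[str, list[str]] = {}
    for b in range(n_branches):
        branch = f"B{b + 1}"
        level = [f"{branch}:d1"]
        edges.append((level[0], "root"))
        for d in range(2, depth + 1):
            nxt = []
            for parent in level:
                for f in range(fanout):
                    child = f"{parent.split(':')[0]}:d{d}_{len(nxt) + 1}"
                    edges.append((child, parent))
                    nxt.append(child)
            level = nxt
        leaves[branch] = level
    return edges, leaves


def gen_annotations(
    genes: list[str],
    leaves_by_branch: dict[str, list[str]],
    branch_of_gene: dict[str, str] | None = None,
    terms_per_gene: int = 2,
    seed: int = 0,
) -> dict[str, set]:
    """Annotate genes with leaf terms, clustered by branch or spread at random."""
    rng = np.random.default_rng(seed)
    branches = sorted(leaves_by_branch)
    out = {}
    for g in genes:
        branch = (branch_of_gene or {}).get(g) or branches[int(rng.integers(len(branches)))]
        pool = leaves_by_branch[branch]
        k = min(terms_per_gene, len(pool))
        out[g] = set(rng.choice(pool, size=k, replace=False))
    return out
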