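"""End-to-end orchestration of the prioritisation pipeline.

A run directory is populated stage by stage: synthetic input generation
(optional), peak integration and the DEG/TF funnel, screen statistics,
direction-aware rank aggregation, network propagation with the
degree-preserving null, and enrichment statistics. Every stochastic
stage derives its seed deterministically from the global seed and the
stage name, so a rerun with the same config reproduces every output file
byte for byte (checksums are recorded in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import io, propagation, rra, screen, synthetic
from . import regions as reg

logger = logging.getLogger("ednet")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Flat, stage-namespaced parameters for a full pipeline run."""

    seed: int = 0
    out_dir: str = "ednet_run"
    synthetic: bool = True

    # synthetic screen design (study conditions)
    screen_genes: int = 81
    n_plates: int = 5
    controls_per_plate: int = 8
    n_pro: int = 10
    n_anti: int = 10
    effect_sd: float = 3.0
    noise_sd: float = 0.25
    plate_shift_sd: float = 0.25

    # synthetic peaks / DE
    peak_conditions: int = 4
    peak_replicates: int = 3
    n_common_regions: int = 90
    n_private_regions: int = 10
    genome_length: int = 4_000_000
    n_background_genes: int = 40
    n_tfs: int = 10
    lfc_magnitude: float = 2.0

    # synthetic network
    network_nodes: int = 400
    attachment: int = 3
    module_extra_nodes: int = 15
    module_density: float = 0.5

    # regions funnel
    min_support: int | None = None  # default: majority of replicates
    promoter_window: int = 3000
    padj_max: float = 0.05
    lfc_min: float = 1.5

    # screen statistics
    n_boot: int = 1000
    resample_size: int = 8
    z_scope: str = "plate"
    outlier_cutoff: float = 3.0
    alpha_screen: float = 0.05

    # rank aggregation
    n_perm: int = 1000
    alpha_rra: float = 0.05

    # propagation
    n_random: int = 1000
    restart: float = 0.15
    gamma: float = 0.5
    alpha_network: float = 0.01
    swap_factor: int = 10

    # enrichment
    alpha_enrich: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Runner:
    """Executes pipeline stages against a run directory."""

    def __init__(self, config: RunConfig, run_dir: str | Path | None = None):
        self.cfg = config
        self.run_dir = Path(run_dir or config.out_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self._log_path = self.run_dir / "run_log.jsonl"

    # -- helpers ----------------------------------------------------------
    def _log(self, stage: str, message: str, **extra) -> None:
        logger.info("[%s] %s", stage, message)
        entry = {"stage": stage, "message": message, **extra}
        with self._log_path.open("a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    def _dir(self, name: str) -> Path:
        d = self.run_dir / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _stage(self, name: str, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - report failing stage by name
            self._log(name, f"FAILED: {e}")
            raise StageError(name, e) from e

    # -- stages -----------------------------------------------------------
    def stage_synth(self) -> None:
        """Generate every pipeline input with planted ground truth."""
        def _run():
            cfg = self.cfg
            inputs, truth = self._dir("inputs"), self._dir("truth")
            rng = np.random.default_rng(derive_seed(cfg.seed, "synth"))

            # planted effect genes among the screened panel
            screen_spec = synthetic.SyntheticScreenSpec(
                n_genes=cfg.screen_genes,
                n_plates=cfg.n_plates,
                controls_per_plate=cfg.controls_per_plate,
                noise_sd=cfg.noise_sd,
                plate_shift_sd=cfg.plate_shift_sd,
                seed=derive_seed(cfg.seed, "synth.screen"),
            )
            genes = screen_spec.genes()
            chosen = rng.choice(len(genes), size=cfg.n_pro + cfg.n_anti, replace=False)
            pro = sorted(genes[i] for i in chosen[: cfg.n_pro])
            anti = sorted(genes[i] for i in chosen[cfg.n_pro:])
            screen_spec.effect_genes = {
                **{g: synthetic.pro_effect(cfg.effect_sd) for g in pro},
                **{g: synthetic.anti_effect(cfg.effect_sd) for g in anti},
            }
            table, screen_manifest = synthetic.gen_screen(screen_spec)
            io.write_table(table, inputs / "screen.tsv")
            io.write_table(screen_manifest, truth / "screen_manifest.tsv")

            # peaks + gene models + DE + regulon (the funnel inputs)
            peak_spec = synthetic.SyntheticPeakSpec(
                n_conditions=cfg.peak_conditions,
                replicates_per_condition=cfg.peak_replicates,
                genome_length=cfg.genome_length,
                n_common_regions=cfg.n_common_regions,
                n_private_regions_per_condition=cfg.n_private_regions,
                seed=derive_seed(cfg.seed, "synth.peaks"),
            )
            peaksets, region_manifest = synthetic.gen_peak_replicates(peak_spec)
            peaks_dir = self._dir("inputs/peaks")
            for cond, reps in peaksets.items():
                for i, ps in enumerate(reps, start=1):
                    io.write_bed(ps.intervals, peaks_dir / f"{cond}_rep{i}.bed")
            io.write_table(region_manifest, truth / "region_manifest.tsv")

            common = [
                (r.chrom, r.start, r.end)
                for r in region_manifest.itertuples()
                if r.kind == "common"
            ]
            if len(genes) > len(common):
                raise ValueError("not enough common regions to anchor the screened genes")
            background = [f"BG{i + 1:03d}" for i in range(cfg.n_background_genes)]
            models = synthetic.gen_gene_models(
                common, genes, background, seed=derive_seed(cfg.seed, "synth.models")
            )
            io.write_gene_models(models, inputs / "gene_models.tsv")

            de_table, de_manifest = synthetic.gen_de_table(
                genes + background, genes, lfc_magnitude=cfg.lfc_magnitude,
                seed=derive_seed(cfg.seed, "synth.de"),
            )
            io.write_table(de_table, inputs / "de_table.tsv")
            io.write_table(de_manifest, truth / "de_manifest.tsv")

            tfs = genes[: cfg.n_tfs]
            regulon = synthetic.gen_regulon(
                tfs, genes, decoy_pairs=[(t, b) for t, b in zip(tfs, background)]
            )
            io.write_table(regulon, inputs / "regulon.tsv")
            (inputs / "tf_list.txt").write_text("\n".join(tfs) + "\n")

            # network with a planted module around the pro genes
            net_spec = synthetic.SyntheticNetworkSpec(
                n_nodes=cfg.network_nodes,
                attachment_parameter=cfg.attachment,
                planted_module_density=cfg.module_density,
                seed=derive_seed(cfg.seed, "synth.network"),
            )
            names = net_spec.node_names()
            extras = [n for n in names if n not in genes]
            extra_pick = rng.choice(len(extras), size=cfg.module_extra_nodes, replace=False)
            module = sorted(pro) + sorted(extras[i] for i in extra_pick)
            net_spec.planted_module_nodes = module
            graph, net_manifest = synthetic.gen_network(net_spec)
            io.write_edge_list(graph, inputs / "network_edges.tsv")

            # toy ontology: module genes cluster in one branch
            edges, leaves = synthetic.gen_ontology(n_branches=3, depth=3)
            pd.DataFrame(edges, columns=["child", "parent"]).to_csv(
                inputs / "ontology_edges.tsv", sep="\t", index=False
            )
            branch_of = {g: "B1" for g in module}
            annotations = synthetic.gen_annotations(
                names, leaves, branch_of, seed=derive_seed(cfg.seed, "synth.annotations")
            )
            pd.DataFrame(
                [{"gene": g, "terms": ";".join(sorted(t))} for g, t in sorted(annotations.items())]
            ).to_csv(inputs / "annotations.tsv", sep="\t", index=False)

            io.write_json(
                {"pro": pro, "anti": anti, "module_nodes": module,
                 "panel": sorted(genes), "density": net_manifest["density"]},
                truth / "planted.json",
            )
            self._log("synth", f"generated inputs for {len(genes)} screened genes",
                      n_pro=len(pro), n_anti=len(anti), module_size=len(module))

        self._stage("synth", _run)

    def stage_regions(self) -> dict:
        """Peak consensus, cross-condition containment, annotation, gene funnel."""
        def _run():
            cfg = self.cfg
            inputs, out = self.run_dir / "inputs", self._dir("regions")
            peaks_dir = inputs / "peaks"
            by_cond: dict[str, list[reg.PeakSet]] = {}
            for bed in sorted(peaks_dir.glob("*_rep*.bed")):
                cond = bed.stem.rsplit("_rep", 1)[0]
                by_cond.setdefault(cond, []).append(
                    reg.PeakSet(io.read_bed(bed), label=bed.stem)
                )
            if not by_cond:
                raise FileNotFoundError(f"no replicate BED files under {peaks_dir}")

            consensus = {}
            for cond, reps in sorted(by_cond.items()):
                support = cfg.min_support or math.ceil(len(reps) / 2)
                consensus[cond] = reg.consensus_peaks(reps, min_support=support)
                io.write_bed(consensus[cond].intervals, out / f"consensus_{cond}.bed")
            common = reg.common_regions(list(consensus.values()))
            io.write_bed(common.intervals, out / "common_regions.bed")

            models = io.read_gene_models(inputs / "gene_models.tsv")
            annotated = reg.annotate_peaks(common, models, promoter_window=cfg.promoter_window)
            io.write_table(annotated, out / "annotated_peaks.tsv")

            de = io.read_table(inputs / "de_table.tsv")
            degs = reg.filter_degs(de, padj_max=cfg.padj_max, lfc_min=cfg.lfc_min)
            under = reg.genes_under_peaks({"all": set(degs["gene"])}, annotated)
            tfs = (inputs / "tf_list.txt").read_text().split()
            regulon = io.read_table(inputs / "regulon.tsv")
            kept, panel, counts = reg.filter_by_regulon(under, tfs, regulon)
            io.write_table(kept, out / "regulon_support.tsv")
            pd.DataFrame({"gene": sorted(panel)}).to_csv(out / "panel.tsv", sep="\t", index=False)
            self._log("regions", f"panel of {len(panel)} genes", **counts,
                      common_regions=len(common), degs=len(degs))
            return {"panel": sorted(panel), "common_regions": len(common),
                    "degs": int(len(degs)), **counts}

        return self._stage("regions", _run)

    def stage_screen(self) -> dict:
        """Normalise and test the high-content screen."""
        def _run():
            cfg = self.cfg
            out = self._dir("screen")
            table = io.read_screen_table(self.run_dir / "inputs" / "screen.tsv")
            results = screen.screen_test(
                table,
                control_label=synthetic.CONTROL_LABEL,
                n_boot=cfg.n_boot,
                resample_size=cfg.resample_size,
                seed=derive_seed(cfg.seed, "screen"),
                z_scope=cfg.z_scope,
                outlier_cutoff=cfg.outlier_cutoff,
                alpha=cfg.alpha_screen,
            )
            io.write_table(results, out / "screen_results.tsv")
            z_summary = results.pivot(index="condition", columns="readout", values="median_z")
            z_summary.to_csv(out / "z_summary.tsv", sep="\t")
            n_sig = int(results["significant"].sum())
            self._log("screen", f"{n_sig} significant (condition, readout) pairs",
                      conditions=z_summary.shape[0])
            return {"significant_pairs": n_sig, "conditions": int(z_summary.shape[0])}

        return self._stage("screen", _run)

    def stage_aggregate(self) -> dict:
        """Direction-aware robust rank aggregation and gene classification."""
        def _run():
            cfg = self.cfg
            out = self._dir("aggregate")
            z_summary = pd.read_csv(self.run_dir / "screen" / "z_summary.tsv",
                                    sep="\t", index_col=0)
            res = {}
            for direction in ("pro", "anti"):
                res[direction] = rra.aggregate_direction(
                    z_summary, direction, n_perm=cfg.n_perm,
                    seed=derive_seed(cfg.seed, f"aggregate.{direction}"),
                )
                res[direction].rename_axis("gene").to_csv(
                    out / f"aggregation_{direction}.tsv", sep="\t"
                )
            classes = rra.classify_genes(res["pro"], res["anti"], alpha=cfg.alpha_rra)
            io.write_json(classes, out / "classification.json")
            self._log("aggregate", f"{len(classes['pro'])} pro / {len(classes['anti'])} anti",
                      inconsistent=len(classes["inconsistent"]))
            return {k: len(v) for k, v in classes.items()}

        return self._stage("aggregate", _run)

    def stage_propagate(self) -> dict:
        """RWR propagation of pro/anti seeds with the configuration-model null."""
        def _run():
            cfg = self.cfg
            out = self._dir("propagate")
            net = io.read_edge_list(self.run_dir / "inputs" / "network_edges.tsv")
            classes = json.loads((self.run_dir / "aggregate" / "classification.json").read_text())
            summary = {}
            for direction in ("pro", "anti"):
                genes = classes[direction]
                agg = pd.read_csv(self.run_dir / "aggregate" / f"aggregation_{direction}.tsv",
                                  sep="\t", index_col=0)
                seeds = rra.seed_importance(agg, genes)
                seeds = {g: w for g, w in seeds.items() if g in net and w > 0}
                if not seeds:
                    self._log("propagate", f"no usable {direction} seeds; skipping")
                    summary[direction] = {"nodes": 0, "edges": 0,
                                          "clustering_average_local": 0.0,
                                          "clustering_transitivity": 0.0}
                    continue
                result, sub = propagation.propagate_with_null(
                    net, seeds,
                    n_random=cfg.n_random,
                    seed=derive_seed(cfg.seed, f"propagate.{direction}"),
                    restart=cfg.restart, gamma=cfg.gamma,
                    alpha=cfg.alpha_network, swap_factor=cfg.swap_factor,
                )
                result.reset_index().to_csv(out / f"propagation_{direction}.tsv",
                                            sep="\t", index=False)
                io.write_edge_list(sub, out / f"subnetwork_{direction}.tsv")
                io.write_graphml(sub, out / f"subnetwork_{direction}.graphml")
                summary[direction] = {
                    "nodes": sub.number_of_nodes(),
                    "edges": sub.number_of_edges(),
                    "clustering_average_local": propagation.clustering_coefficient(
                        sub, "average_local"),
                    "clustering_transitivity": propagation.clustering_coefficient(
                        sub, "transitivity"),
                }
                self._log("propagate", f"{direction}: {sub.number_of_nodes()} nodes / "
                          f"{sub.number_of_edges()} edges", n_seeds=len(seeds))
            return summary

        return self._stage("propagate", _run)

    def stage_enrich(self) -> dict:
        """Overlap, over-representation and semantic-similarity statistics."""
        def _run():
            cfg = self.cfg
            out = self._dir("enrich")
            inputs = self.run_dir / "inputs"
            net = io.read_edge_list(inputs / "network_edges.tsv")
            background = set(net)
            planted = json.loads((self.run_dir / "truth" / "planted.json").read_text()) \
                if (self.run_dir / "truth" / "planted.json").exists() else None

            result: dict = {}
            sub_nodes = {}
            for direction in ("pro", "anti"):
                path = self.run_dir / "propagate" / f"subnetwork_{direction}.tsv"
                nodes = set()
                if path.exists():
                    sub = io.read_edge_list(path)
                    nodes = set(sub)
                sub_nodes[direction] = nodes

            # how strongly each subnetwork captures the planted module
            if planted:
                module = set(planted["module_nodes"]) & background
                for direction, nodes in sub_nodes.items():
                    if nodes:
                        ov = enr.hypergeom_overlap(module, nodes, background)
                        result[f"{direction}_module_overlap_p"] = ov["pvalue"]
                        result[f"{direction}_module_overlap_k"] = ov["overlap"]

            ann_df = pd.read_csv(inputs / "annotations.tsv", sep="\t")
            annotations = {r.gene: set(str(r.terms).split(";")) for r in ann_df.itertuples()}
            onto = pd.read_csv(inputs / "ontology_edges.tsv", sep="\t")
            term_to_genes: dict[str, set] = {}
            for g, terms in annotations.items():
                for t in terms:
                    term_to_genes.setdefault(t, set()).add(g)

            for direction, nodes in sub_nodes.items():
                if nodes:
                    tab = enr.ora(nodes, term_to_genes, background, alpha=cfg.alpha_enrich)
                    tab.to_csv(out / f"ora_{direction}.tsv", sep="\t", index=False)
                    result[f"{direction}_ora_top_term"] = tab.iloc[0]["term"] if len(tab) else ""
                    result[f"{direction}_ora_top_padj"] = (
                        float(tab.iloc[0]["padj"]) if len(tab) else 1.0
                    )

            # node-level similarity: pro vs anti subnetwork, or vs a random
            # background sample when one side is degenerate (< 2 nodes)
            group_a = sorted(sub_nodes["pro"])
            group_b = sorted(sub_nodes["anti"])
            versus = "anti"
            if len(group_a) >= 2 and len(group_b) < 2:
                rng = np.random.default_rng(derive_seed(cfg.seed, "enrich"))
                pool = sorted(background - set(group_a))
                group_b = sorted(rng.choice(pool, size=len(group_a), replace=False))
                versus = "random_background"
            if len(group_a) >= 2 and len(group_b) >= 2:
                both = sorted(set(group_a) | set(group_b))
                sims = enr.semantic_similarity(
                    both, annotations, list(onto.itertuples(index=False, name=None))
                )
                cmp = enr.compare_similarity_distributions(group_a, group_b, sims)
                cmp["versus"] = versus
                result["similarity_comparison"] = cmp
            io.write_json(result, out / "enrichment.json")
            self._log("enrich", "enrichment statistics written",
                      keys=sorted(result))
            return result

        return self._stage("enrich", _run)

    # -- orchestration ----------------------------------------------------
    def run_all(self) -> Path:
        cfg = self.cfg
        if cfg.synthetic:
            self.stage_synth()
        elif not (self.run_dir / "inputs").exists():
            raise FileNotFoundError(
                f"no inputs under {self.run_dir} and synthetic generation is disabled"
            )
        summary = {
            "regions": self.stage_regions(),
            "screen": self.stage_screen(),
            "aggregate": self.stage_aggregate(),
            "propagate": self.stage_propagate(),
            "enrich": self.stage_enrich(),
        }
        io.write_json(summary, self.run_dir / "summary.json")
        self._write_manifest()
        return self.run_dir

    def _write_manifest(self) -> None:
        files = sorted(
            p for p in self.run_dir.rglob("*")
            if p.is_file() and p.name not in ("manifest.json", "run_log.jsonl")
        )
        manifest = {
            "config": self.cfg.to_dict(),
            "stage_seeds": {
                s: derive_seed(self.cfg.seed, s)
                for s in ("synth", "screen", "aggregate.pro", "aggregate.anti",
                          "propagate.pro", "propagate.anti")
            },
            "checksums": {str(p.relative_to(self.run_dir)): _sha256(p) for p in files},
        }
        io.write_json(manifest, self.run_dir / "manifest.json")


def run_all(config: RunConfig, run_dir: str | Path | None = None) -> Path:
    """Run the whole pipeline; returns the run directory."""
    return Runner(config, run_dir).run_all()
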