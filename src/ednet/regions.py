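"""Epigenomic region integration and the DEG/TF candidate funnel.

Replicate peak sets (ATAC or ChIP) are reduced to consensus regions by a
base-pair coverage vote, conditions are intersected by a containment rule
(a region counts as shared only when one peak lies entirely within the
other), ChIP evidence is re-centred onto open-chromatin ATAC intervals,
peaks are annotated to genomic features, and differentially expressed
genes are filtered down to a panel supported both by a peak assignment and
by a curated TF->target regulon.

Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_ORDER = ["promoter/TSS", "5'UTR", "3'UTR", "exon", "intron", "intergenic"]


@dataclass
class PeakSet:
    """A set of genomic intervals for one condition/replicate.

    ``intervals`` holds columns ``chrom, start, end`` (extra columns pass
    through); rows are kept sorted by (chrom, start).
    """

    intervals: pd.DataFrame
    label: str = ""

    def __post_init__(self):
        df = self.intervals
        if df.empty and "chrom" not in df.columns:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
        if (df["end"] <= df["start"]).any():
            raise ValueError("intervals must satisfy start < end")
        if (df["start"] < 0).any():
            raise ValueError("intervals must satisfy start >= 0")
        self.intervals = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_tuples(cls, tuples, label: str = "") -> "PeakSet":
        df = pd.DataFrame(tuples, columns=["chrom", "start", "end"])
        return cls(df, label)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneModel:
    """Simplified gene annotation used for peak-to-feature assignment."""

    gene: str
    chrom: str
    strand: str
    tss: int
    gene_span: tuple[int, int]
    exons: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    def __post_init__(self):
        lo, hi = self.gene_span
        if not lo <= self.tss <= hi:
            raise ValueError(f"TSS of {self.gene} outside gene span")


def _merge_intervals(df: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Union of possibly-overlapping intervals, per chromosome."""
    merged = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return merged


def consensus_peaks(replicates: list[PeakSet], min_support: int) -> PeakSet:
    """Coverage-vote consensus across replicate peak sets.

    Returns the maximal regions covered by peaks from at least
    ``min_support`` replicates (each replicate counts once per base pair,
    however many of its peaks overlap it). ``min_support=1`` is the
    interval union; ``min_support=len(replicates)`` the n-way
    intersection.
    """
    if not replicates:
        raise ValueError("replicate list is empty")
    n = len(replicates)
    if not 1 <= min_support <= n:
        raise ValueError(f"min_support must be in [1, {n}], got {min_support}")

    events: dict[str, list[tuple[int, int]]] = {}
    for rep in replicates:
        for chrom, s, e in _merge_intervals(rep.intervals):
            events.setdefault(chrom, []).append((s, +1))
            events[chrom].append((e, -1))

    out = []
    for chrom in sorted(events):
        # coalesce deltas per coordinate so an end meeting a start at the
        # same base keeps coverage contiguous (half-open intervals)
        net: dict[int, int] = {}
        for pos, delta in events[chrom]:
            net[pos] = net.get(pos, 0) + delta
        cov = 0
        region_start = None
        for pos in sorted(net):
            new_cov = cov + net[pos]
            if cov < min_support <= new_cov:
                region_start = pos
            elif new_cov < min_support <= cov:
                out.append((chrom, region_start, pos))
                region_start = None
            cov = new_cov
    return PeakSet.from_tuples(out, label=f"consensus>={min_support}")


def _containment_matches(iv: tuple[str, int, int], peaks: PeakSet, either: bool):
    """Intervals of ``peaks`` related to ``iv`` by containment."""
    chrom, s, e = iv
    sub = peaks.intervals[peaks.intervals["chrom"] == chrom]
    hits = []
    for os, oe in zip(sub["start"], sub["end"]):
        contained_in_other = os <= s and e <= oe
        contains_other = s <= os and oe <= e
        if contained_in_other or (either and contains_other):
            hits.append((chrom, int(os), int(oe)))
    return hits


def common_regions(per_condition: list[PeakSet], either_direction: bool = True) -> PeakSet:
    """Regions shared by every condition under the containment rule.

    A region is retained when, for every other condition, some peak pair
    with it satisfies containment (one interval entirely within the
    other). The smaller (contained) interval of each match chain is
    reported. Scanning is anchored on every condition in turn and the
    results deduplicated, so the output does not depend on condition
    order.
    """
    if len(per_condition) < 2:
        raise ValueError("common_regions needs at least two conditions")
    retained: set[tuple[str, int, int]] = set()
    for anchor_idx, anchor in enumerate(per_condition):
        others = [p for i, p in enumerate(per_condition) if i != anchor_idx]
        for chrom, s, e in anchor.intervals[["chrom", "start", "end"]].itertuples(index=False):
            smallest = (chrom, int(s), int(e))
            ok = True
            for other in others:
                hits = _containment_matches((chrom, s, e), other, either=either_direction)
                if not hits:
                    ok = False
                    break
                for h in hits:
                    if h[2] - h[1] < smallest[2] - smallest[1]:
                        smallest = h
            if ok:
                retained.add(smallest)
    return PeakSet.from_tuples(sorted(retained), label="common")


def center_on_atac(chip: PeakSet, atac: PeakSet, either_direction: bool = True) -> PeakSet:
    """Keep ATAC intervals supported by a ChIP peak via containment.

    The open-chromatin (ATAC) coordinates are reported; the supporting
    ChIP interval is recorded in ``support_start``/``support_end``. With
    ``either_direction`` (default) the containment may go either way;
    strict mode requires the ATAC peak to lie within the ChIP peak.
    """
    if len(chip) == 0 or len(atac) == 0:
        raise ValueError("center_on_atac requires non-empty peak sets")
    rows = []
    for chrom, s, e in atac.intervals[["chrom", "start", "end"]].itertuples(index=False):
        hits = _containment_matches((chrom, s, e), chip, either=either_direction)
        if hits:
            hc, hs, he = hits[0]
            rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                         "support_start": hs, "support_end": he})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "support_start", "support_end"])
    if df.empty:
        df = df.astype({"start": int, "end": int})
    return PeakSet(df, label="atac_centred")


def _in_blocks(pos: int, blocks) -> bool:
    return any(lo <= pos < hi for lo, hi in blocks)


def annotate_peaks(
    peaks: PeakSet,
    genes: list[GeneModel],
    promoter_window: int = 3000,
    assignment_window: int = 100_000,
) -> pd.DataFrame:
    """Assign each peak one genomic feature and (where possible) a gene.

    The feature is decided at the peak midpoint with precedence
    promoter/TSS > 5'UTR > 3'UTR > exon > intron > intergenic; the
    promoter is TSS +/- ``promoter_window`` on either strand. Non-promoter
    peaks are assigned to the nearest TSS within ``assignment_window`` bp.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    known_chroms = set(by_chrom)
    rows = []
    for chrom, s, e in peaks.intervals[["chrom", "start", "end"]].itertuples(index=False):
        mid = (int(s) + int(e)) // 2
        if chrom not in known_chroms:
            if genes:
                warnings.warn(f"peak chromosome {chrom!r} absent from gene models", stacklevel=2)
            rows.append({"chrom": chrom, "start": s, "end": e, "feature": "intergenic",
                         "gene": "", "distance_to_tss": np.nan})
            continue
        feature = "intergenic"
        assigned = ""
        distance = np.nan
        best = (len(FEATURE_ORDER) - 1, np.inf)  # (precedence rank, |distance to TSS|)
        nearest_gene, nearest_dist = None, None
        for g in by_chrom[chrom]:
            signed = mid - g.tss if g.strand == "+" else g.tss - mid
            if nearest_dist is None or abs(signed) < abs(nearest_dist):
                nearest_gene, nearest_dist = g, signed
            if abs(mid - g.tss) <= promoter_window:
                cand = "promoter/TSS"
            elif _in_blocks(mid, g.utr5):
                cand = "5'UTR"
            elif _in_blocks(mid, g.utr3):
                cand = "3'UTR"
            elif _in_blocks(mid, g.exons):
                cand = "exon"
            elif g.gene_span[0] <= mid < g.gene_span[1]:
                cand = "intron"
            else:
                continue
            key = (FEATURE_ORDER.index(cand), abs(signed))
            if key < best or assigned == "":
                best = key
                feature = cand
                assigned = g.gene
                distance = signed
        if feature == "intergenic" and nearest_gene is not None:
            if abs(nearest_dist) <= assignment_window:
                assigned = nearest_gene.gene
                distance = nearest_dist
        rows.append({"chrom": chrom, "start": s, "end": e, "feature": feature,
                     "gene": assigned, "distance_to_tss": distance})
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "feature", "gene", "distance_to_tss"]
    )


def filter_degs(de: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 1.5) -> pd.DataFrame:
    """Differentially expressed genes at adjusted p <= ``padj_max`` and |log2FC| >= ``lfc_min``."""
    for col in ("gene", "log2fc", "padj"):
        if col not in de.columns:
            raise ValueError(f"DE table missing column {col!r}")
    kept = de[(de["padj"] <= padj_max) & (de["log2fc"].abs() >= lfc_min)].copy()
    kept["direction"] = np.where(kept["log2fc"] > 0, "up", "down")
    return kept[["gene", "log2fc", "padj", "direction"]].reset_index(drop=True)


def genes_under_peaks(deg_sets: dict[str, set], annotated: pd.DataFrame) -> set:
    """DEGs (union across conditions) that carry a peak assignment."""
    peak_genes = set(annotated.loc[annotated["gene"] != "", "gene"])
    degs = set().union(*deg_sets.values()) if deg_sets else set()
    return degs & peak_genes


def filter_by_regulon(genes: set, tfs: list[str], regulon: pd.DataFrame):
    """Keep regulon rows with a candidate TF and a candidate target gene.

    Returns ``(kept_rows, panel, counts)`` where the panel is the union of
    the retained TFs and targets and ``counts`` reports TF / non-TF
    membership.
    """
    if not {"tf", "target"} <= set(regulon.columns):
        raise ValueError("regulon table needs 'tf' and 'target' columns")
    reg = regulon.drop_duplicates(subset=["tf", "target"])
    kept = reg[reg["tf"].isin(tfs) & reg["target"].isin(genes)].reset_index(drop=True)
    panel = set(kept["tf"]) | set(kept["target"])
    tf_members = panel & set(kept["tf"])
    counts = {"tf": len(tf_members), "non_tf": len(panel - tf_members)}
    return kept, panel, counts
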