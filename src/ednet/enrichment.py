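"""Gene-set overlap, over-representation and semantic-similarity statistics.

Overlap between a gene set and a network's nodes within a stated
background universe is scored with the upper-tail hypergeometric
probability; term over-representation analysis applies the same tail per
term with BH adjustment; gene-to-gene functional similarity uses
information content over a term DAG (Lin term similarity, best-match
average between genes), and two networks' node-level similarity
distributions are compared by the rank-sum test.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def hypergeom_overlap(set_a: set, network_nodes: set, background: set) -> dict:
    """Upper-tail hypergeometric overlap within an explicit background.

    Returns the 2x2 table, P(X >= k), per-cell Pearson residuals
    (obs - exp)/sqrt(exp) and the odds ratio.
    """
    set_a, network_nodes, background = set(set_a), set(network_nodes), set(background)
    if not set_a <= background or not network_nodes <= background:
        raise ValueError("both gene sets must be subsets of the background")
    n_bg = len(background)
    k = len(set_a & network_nodes)
    big_k, n = len(set_a), len(network_nodes)
    p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n)) if big_k and n else 1.0

    obs = np.array(
        [[k, big_k - k], [n - k, n_bg - big_k - n + k]], dtype=float
    )  # rows: in/out set_a; cols: in/out network
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / n_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        residuals = np.where(exp > 0, (obs - exp) / np.sqrt(exp), 0.0)
        odds = (obs[0, 0] * obs[1, 1]) / (obs[0, 1] * obs[1, 0]) if obs[0, 1] * obs[1, 0] else np.inf
    return {
        "table": obs.astype(int),
        "overlap": k,
        "pvalue": p,
        "residuals": residuals,
        "odds_ratio": float(odds),
    }


def ora(
    gene_set: set,
    term_to_genes: dict[str, set],
    background: set,
    alpha: float = 0.05,
    depletion: bool = False,
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation with BH adjustment.

    Columns: term, k (overlap), K (term size in background), p,
    adjusted p, significant (adjusted p <= alpha).
    """
    from statsmodels.stats.multitest import multipletests

    gene_set = set(gene_set) & set(background)
    n_bg, n_query = len(background), len(gene_set)
    rows = []
    for term, members in term_to_genes.items():
        members = set(members) & set(background)
        k = len(gene_set & members)
        if depletion:
            p = float(stats.hypergeom.cdf(k, n_bg, len(members), n_query))
        else:
            p = float(stats.hypergeom.sf(k - 1, n_bg, len(members), n_query)) if members else 1.0
        rows.append({"term": term, "k": k, "K": len(members), "pvalue": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["padj"] = []
        df["significant"] = []
        return df
    df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    df["significant"] = df["padj"] <= alpha
    return df.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# semantic similarity

def _build_dag(ontology_edges) -> nx.DiGraph:
    dag = nx.DiGraph()
    dag.add_edges_from(ontology_edges)  # child -> parent
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology edges contain a cycle")
    roots = [n for n in dag if dag.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(f"ontology must have a single root, found {len(roots)}")
    return dag


def _ancestors_with_self(dag: nx.DiGraph, term: str) -> set:
    return {term} | nx.descendants(dag, term)  # edges point child -> parent


def semantic_similarity(
    genes: list[str],
    annotations: dict[str, set],
    ontology_edges,
    method: str = "lin_bma",
) -> pd.DataFrame:
    """Gene x gene similarity matrix from term annotations over a DAG.

    Term information content is IC(t) = -log(freq(t)) with annotation
    frequency propagated to ancestors; term similarity is Lin,
    2*IC(MICA)/(IC(t1)+IC(t2)); gene similarity is the best-match
    average of their term sets. Genes with no annotation are dropped
    with a warning.
    """
    if method != "lin_bma":
        raise ValueError(f"unknown method {method!r}")
    dag = _build_dag(ontology_edges)
    annotated = [g for g in genes if annotations.get(g)]
    dropped = sorted(set(genes) - set(annotated))
    if dropped:
        warnings.warn(f"dropping unannotated genes: {dropped}", stacklevel=2)
    if not annotated:
        raise ValueError("no annotated genes")

    anc_cache = {t: _ancestors_with_self(dag, t) for t in dag}
    counts: dict[str, int] = {t: 0 for t in dag}
    for g in annotated:
        hit = set()
        for t in annotations[g]:
            if t not in dag:
                raise ValueError(f"term {t!r} not in ontology")
            hit |= anc_cache[t]
        for t in hit:
            counts[t] += 1
    n_ann = len(annotated)
    ic = {t: -np.log(c / n_ann) if c else np.inf for t, c in counts.items()}

    def term_sim(t1: str, t2: str) -> float:
        common = anc_cache[t1] & anc_cache[t2]
        mica = max((ic[t] for t in common if np.isfinite(ic[t])), default=0.0)
        denom = ic[t1] + ic[t2]
        if not np.isfinite(denom) or denom == 0:
            return 0.0
        return 2.0 * mica / denom

    term_lists = {g: sorted(annotations[g]) for g in annotated}
    mat = np.eye(len(annotated))
    for i, g1 in enumerate(annotated):
        for j in range(i + 1, len(annotated)):
            g2 = annotated[j]
            s = np.array([[term_sim(a, b) for b in term_lists[g2]] for a in term_lists[g1]])
            bma = (s.max(axis=1).mean() + s.max(axis=0).mean()) / 2.0
            mat[i, j] = mat[j, i] = bma
    return pd.DataFrame(mat, index=annotated, columns=annotated)


def compare_similarity_distributions(
    net_a_nodes, net_b_nodes, sims: pd.DataFrame
) -> dict:
    """Rank-sum comparison of within-network node-level mean similarities.

    Each node's statistic is its mean pairwise similarity to the other
    nodes of its own network; distributions for the two networks are
    compared with the two-sided rank-sum test.
    """
    def node_means(nodes):
        nodes = [n for n in nodes if n in sims.index]
        if len(nodes) < 2:
            raise ValueError("need at least two annotated nodes per network")
        block = sims.loc[nodes, nodes].to_numpy(dtype=float, copy=True)
        np.fill_diagonal(block, np.nan)
        return np.nanmean(block, axis=1)

    a, b = node_means(net_a_nodes), node_means(net_b_nodes)
    stat, p = stats.ranksums(a, b)
    return {
        "statistic": float(stat),
        "pvalue": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": len(a),
        "n_b": len(b),
    }
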