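"""Direction-aware robust rank aggregation of the four screen readouts.

Genes are ranked within each readout by their median Z-score — for the
pro-dysfunction direction ICAM1 and ROS descending (high inflammation /
oxidative stress first) and VE-cadherin and nuclei counts ascending
(junction loss and cell loss first); the anti direction reverses all
four. The order-statistic consensus score rho for a gene with normalized
ranks r_(1) <= ... <= r_(n) is

    rho = min_k P(at least k of n uniform ranks <= r_(k))
        = min_k [1 - BinomCDF(k-1; n, r_(k))],

i.e. how surprisingly well-ranked the gene is under the null that every
list orders genes at random. Significance comes from a permutation null
that randomly reassigns measurements to genes within each list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ASCENDING_PRO = {"ICAM1": False, "ROS": False, "VECAD": True, "NUCLEI": True}


def build_rank_matrix(
    z_summary: pd.DataFrame, direction: str, ascending_pro: dict | None = None
) -> pd.DataFrame:
    """Normalized rank matrix (genes x readouts) for one direction.

    ``z_summary`` is indexed by gene with one column per readout. Ties
    get mid-ranks; ranks are divided by the number of genes so each
    column lies in (0, 1].
    """
    if direction not in ("pro", "anti"):
        raise ValueError(f"direction must be 'pro' or 'anti', got {direction!r}")
    ascending_pro = ascending_pro or ASCENDING_PRO
    missing = set(ascending_pro) - set(z_summary.columns)
    if missing:
        raise ValueError(f"z summary missing readouts: {sorted(missing)}")
    n = len(z_summary)
    cols = {}
    for readout, asc in ascending_pro.items():
        if direction == "anti":
            asc = not asc
        cols[readout] = z_summary[readout].rank(ascending=asc, method="average") / n
    return pd.DataFrame(cols, index=z_summary.index)


def rra_rho(r: np.ndarray) -> float:
    """Order-statistic consensus score for one gene's normalized ranks."""
    return float(_rho_rows(np.asarray(r, dtype=float)[None, :])[0])


def _rho_rows(r: np.ndarray) -> np.ndarray:
    """rho for each row of a (genes x n_lists) normalized-rank matrix."""
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    srt = np.sort(r, axis=1)
    n = r.shape[1]
    k = np.arange(1, n + 1)
    # P(at least k of n uniforms <= r_(k)) = survival of Binomial(n, r_(k)) at k-1
    beta = stats.binom.sf(k - 1, n, srt)
    return beta.min(axis=1)


def rra_pvalues(
    matrix: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    joint_rows: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for the consensus scores of a rank matrix.

    The null permutes the measurement-to-gene assignment independently in
    each list (``joint_rows=True`` instead permutes whole rows jointly)
    ``n_perm`` times; a gene's p is (1 + #{null rho <= observed rho}) /
    (1 + n_perm) over its own null scores. ``bound`` is the analytic
    Bonferroni-style bound min(1, n_lists * rho).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    vals = matrix.to_numpy(dtype=float)
    n_genes, n_lists = vals.shape
    rho_obs = _rho_rows(vals)

    exceed = np.zeros(n_genes)
    for _ in range(n_perm):
        if joint_rows:
            null = vals[rng.permutation(n_genes), :]
        else:
            null = np.column_stack([vals[rng.permutation(n_genes), j] for j in range(n_lists)])
        exceed += _rho_rows(null) <= rho_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    bound = np.minimum(1.0, n_lists * rho_obs)
    return pd.DataFrame(
        {"rho": rho_obs, "pvalue": pvals, "bound": bound}, index=matrix.index
    )


def aggregate_direction(
    z_summary: pd.DataFrame, direction: str, n_perm: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Rank matrix + rho + permutation p for one direction."""
    res = rra_pvalues(build_rank_matrix(z_summary, direction), n_perm=n_perm, seed=seed)
    res["direction"] = direction
    return res


def classify_genes(
    pro: pd.DataFrame, anti: pd.DataFrame, alpha: float = 0.05
) -> dict[str, list]:
    """Split genes into pro / anti / neutral by permutation p at ``alpha``.

    A gene significant in both directions is reported as inconsistent and
    assigned to neither list.
    """
    genes = pro.index
    pro_sig = set(genes[pro["pvalue"] < alpha])
    anti_sig = set(anti.index[anti["pvalue"] < alpha])
    inconsistent = pro_sig & anti_sig
    pro_only = pro_sig - inconsistent
    anti_only = anti_sig - inconsistent
    neutral = set(genes) - pro_only - anti_only - inconsistent
    return {
        "pro": sorted(pro_only),
        "anti": sorted(anti_only),
        "neutral": sorted(neutral),
        "inconsistent": sorted(inconsistent),
    }


def seed_importance(result: pd.DataFrame, genes: list[str] | None = None) -> dict[str, float]:
    """Propagation seed weights from aggregation p-values: -log10(p), floored at 0."""
    sub = result if genes is None else result.loc[result.index.intersection(genes)]
    return {g: max(0.0, -np.log10(p)) for g, p in sub["pvalue"].items()}
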