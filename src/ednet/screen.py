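"""Plate normalisation and hit calling for multi-plate high-content screens.

Each plate carries a block of control wells (siRNA scramble under the
dysfunction stimulus) and one well per perturbed gene. Raw per-well
medians are divided by the mean of the plate's control wells, converted
to Z-scores to absorb plate-to-plate variation, cleaned of |Z| > 3
outliers, and each condition is tested against the controls with a
bootstrap Wilcoxon rank-sum scheme: because the design is unbalanced
(8x more control wells), controls are resampled (size 8, with
replacement) 1,000 times, the two-sided rank-sum test is run each time
(optionally BH-adjusted across conditions within the iteration), and the
median p over iterations is the condition's p-value. Hits are median
p < 0.05.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

DEFAULT_READOUTS = ["ICAM1", "ROS", "VECAD", "NUCLEI"]


# ---------------------------------------------------------------------------
# rank-sum machinery (vectorised over bootstrap draws)

@lru_cache(maxsize=64)
def _mwu_cdf(n1: int, n2: int) -> np.ndarray:
    """Exact CDF of the Mann-Whitney U statistic for tie-free samples.

    Built from the count recurrence f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u),
    the number of rank arrangements of i group-1 and j group-2
    observations with statistic u.
    """
    maxu = n1 * n2
    prev = np.zeros((n2 + 1, maxu + 1))
    prev[:, 0] = 1.0
    for _i in range(1, n1 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for j in range(1, n2 + 1):
            cur[j] = cur[j - 1]
            cur[j, j:] = cur[j, j:] + prev[j, : maxu + 1 - j]
        prev = cur
    pmf = prev[n2] / comb(n1 + n2, n1)
    return np.cumsum(pmf)


def _ranksum_p(x: np.ndarray, draws: np.ndarray, exact_max_n: int = 25) -> np.ndarray:
    """Two-sided rank-sum p of ``x`` against each row of ``draws``.

    Mid-ranks handle ties; p is exact (enumeration) for tie-free rows
    with both group sizes <= ``exact_max_n``, else a tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    n1, n2 = x.size, draws.shape[1]
    b = draws.shape[0]
    combined = np.concatenate([np.broadcast_to(x, (b, n1)), draws], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0

    srt = np.sort(combined, axis=1)
    tied = srt[:, 1:] == srt[:, :-1]
    has_ties = tied.any(axis=1)

    p = np.empty(b)
    exact = (~has_ties) & (max(n1, n2) <= exact_max_n)
    if exact.any():
        cdf = _mwu_cdf(n1, n2)
        u_int = np.rint(u1[exact]).astype(int)
        p_le = cdf[u_int]
        p_ge = 1.0 - np.where(u_int > 0, cdf[u_int - 1], 0.0)
        p[exact] = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))
    if (~exact).any():
        idx = ~exact
        n = n1 + n2
        tie_term = np.zeros(idx.sum())
        sub = srt[idx]
        for k, row in enumerate(sub):
            _, counts = np.unique(row, return_counts=True)
            tie_term[k] = float((counts**3 - counts).sum())
        mu = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        num = u1[idx] - mu
        num = num - 0.5 * np.sign(num)  # continuity correction
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, num / np.sqrt(var), 0.0)
        p[idx] = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    return p


def bh_adjust(p: np.ndarray, axis: int = 0) -> np.ndarray:
    """Benjamini-Hochberg adjustment along ``axis`` (vectorised)."""
    p = np.asarray(p, dtype=float)
    p = np.moveaxis(p, axis, -1)
    m = p.shape[-1]
    order = np.argsort(p, axis=-1)
    ranked = np.take_along_axis(p, order, axis=-1)
    scaled = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[..., ::-1], axis=-1)[..., ::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=-1)
    return np.moveaxis(out, -1, axis)


# ---------------------------------------------------------------------------
# normalisation

def normalize_plate(values: np.ndarray, control_values: np.ndarray, plate: str = "?") -> np.ndarray:
    """Divide each well value by the mean of the plate's control wells."""
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValueError(f"plate {plate!r} has no control wells")
    mean = control_values.mean()
    if mean == 0:
        raise ValueError(f"plate {plate!r} control mean is zero")
    return np.asarray(values, dtype=float) / mean


def normalize_screen(
    table: pd.DataFrame, control_label: str, readouts: list[str] | None = None
) -> pd.DataFrame:
    """Per-plate control normalisation of every readout (adds ``<readout>_norm``)."""
    readouts = readouts or [c for c in table.columns if c not in ("plate", "well", "condition")]
    out = table.copy()
    for r in readouts:
        out[f"{r}_norm"] = np.nan
    for plate, idx in table.groupby("plate").groups.items():
        sub = table.loc[idx]
        ctrl = sub["condition"] == control_label
        if not ctrl.any():
            raise ValueError(f"plate {plate!r} has no control wells ({control_label!r})")
        for r in readouts:
            out.loc[idx, f"{r}_norm"] = normalize_plate(
                sub[r].to_numpy(), sub.loc[ctrl, r].to_numpy(), plate=str(plate)
            )
    return out


def zscore(values: np.ndarray) -> np.ndarray:
    """Standard scores with the sample SD (ddof=1)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot Z-score a constant group")
    return (values - values.mean()) / sd


def zscore_screen(
    table: pd.DataFrame, readouts: list[str] | None = None, scope: str = "plate"
) -> pd.DataFrame:
    """Z-score the normalised readouts, per plate (default) or globally."""
    readouts = readouts or DEFAULT_READOUTS
    out = table.copy()
    for r in readouts:
        col = f"{r}_norm"
        if scope == "plate":
            out[f"{r}_z"] = out.groupby("plate")[col].transform(lambda v: zscore(v.to_numpy()))
        elif scope == "global":
            out[f"{r}_z"] = zscore(out[col].to_numpy())
        else:
            raise ValueError(f"unknown z-scope {scope!r}")
    return out


def remove_outliers(table: pd.DataFrame, readouts: list[str] | None = None, cutoff: float = 3.0):
    """Flag wells with |Z| > cutoff per readout; returns (table, removal log).

    The table gains boolean ``<readout>_keep`` columns; the log lists one
    row per removed (well, readout).
    """
    readouts = readouts or DEFAULT_READOUTS
    out = table.copy()
    log_rows = []
    for r in readouts:
        z = out[f"{r}_z"]
        keep = z.abs() <= cutoff
        out[f"{r}_keep"] = keep
        for _, row in out.loc[~keep].iterrows():
            log_rows.append({"plate": row["plate"], "well": row["well"],
                             "condition": row["condition"], "readout": r, "z": row[f"{r}_z"]})
    log = pd.DataFrame(log_rows, columns=["plate", "well", "condition", "readout", "z"])
    return out, log


# ---------------------------------------------------------------------------
# testing

def bootstrap_wilcoxon(
    test_values,
    control_values,
    n_boot: int = 1000,
    resample_size: int = 8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Median p of ``n_boot`` rank-sum tests against control resamples.

    Each iteration draws ``resample_size`` control values with
    replacement and runs the two-sided rank-sum test against
    ``test_values``. Returns ``{"median_p", "pvalues"}``.
    """
    test_values = np.asarray(test_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if test_values.size == 0:
        raise ValueError("empty test group")
    if control_values.size == 0:
        raise ValueError("empty control pool")
    rng = rng if rng is not None else np.random.default_rng(seed)
    draws = rng.choice(control_values, size=(n_boot, resample_size), replace=True)
    p = _ranksum_p(test_values, draws)
    return {"median_p": float(np.median(p)), "pvalues": p}


def screen_test(
    table: pd.DataFrame,
    control_label: str,
    readouts: list[str] | None = None,
    n_boot: int = 1000,
    resample_size: int = 8,
    seed: int | None = None,
    z_scope: str = "plate",
    outlier_cutoff: float = 3.0,
    bh_within_iteration: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full screen analysis: normalise, Z-score, de-outlier, bootstrap-test.

    One control resample per iteration is shared across all conditions of
    a readout, the rank-sum p-values are BH-adjusted across conditions
    within the iteration (disable with ``bh_within_iteration=False``),
    and the median over iterations is reported per (condition, readout).
    """
    readouts = readouts or DEFAULT_READOUTS
    rng = np.random.default_rng(seed)
    norm = normalize_screen(table, control_label, readouts)
    zed = zscore_screen(norm, readouts, scope=z_scope)
    clean, _removals = remove_outliers(zed, readouts, cutoff=outlier_cutoff)

    conditions = [c for c in clean["condition"].unique() if c != control_label]
    rows = []
    for r in readouts:
        kept = clean[clean[f"{r}_keep"]]
        ctrl_pool = kept.loc[kept["condition"] == control_label, f"{r}_z"].to_numpy()
        if ctrl_pool.size == 0:
            raise ValueError(f"no control wells survive outlier removal for {r}")
        draws = rng.choice(ctrl_pool, size=(n_boot, resample_size), replace=True)
        pmat = np.empty((len(conditions), n_boot))
        med_z = {}
        n_wells = {}
        for i, cond in enumerate(conditions):
            vals = kept.loc[kept["condition"] == cond, f"{r}_z"].to_numpy()
            if vals.size == 0:
                pmat[i] = 1.0
                med_z[cond] = np.nan
                n_wells[cond] = 0
                continue
            pmat[i] = _ranksum_p(vals, draws)
            med_z[cond] = float(np.median(vals))
            n_wells[cond] = int(vals.size)
        if bh_within_iteration and len(conditions) > 1:
            pmat = bh_adjust(pmat, axis=0)
        med_p = np.median(pmat, axis=1)
        for i, cond in enumerate(conditions):
            rows.append({"condition": cond, "readout": r, "median_z": med_z[cond],
                         "median_p": float(med_p[i]),
                         "significant": bool(med_p[i] < alpha), "n_wells": n_wells[cond]})
    return pd.DataFrame(rows)


def death_index(positive_count: int, total_count: int) -> float:
    """Percentage of dead (stain-positive) cells among all nuclei."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if positive_count > total_count or positive_count < 0:
        raise ValueError("positive_count must be in [0, total_count]")
    return 100.0 * positive_count / total_count
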