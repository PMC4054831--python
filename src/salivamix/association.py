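"""Paired epigenome-wide testing and the study's supporting statistics.

The workhorse is an exact Wilcoxon signed-rank test: for n nonzero
paired differences the null distribution of the positive-rank sum W+ is
built by dynamic programming over all 2**n sign assignments, which
remains correct in the presence of ties (midranks make the distribution
data-dependent, so it is recomputed whenever ties occur). The two-sided
P-value doubles the smaller tail, giving the familiar floor of 2·2⁻ⁿ
for n untied same-sign differences. Above n = 25 nonzero pairs a
tie-corrected normal approximation takes over (mode "auto").

Also here: MVP (methylation variable position) calling by intersecting
significance and effect-size filters across analyses, the exact
Freeman–Halton r×c test, the paired t-test, noncentral-t power for the
paired design, and birth-weight discordance arithmetic.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import AssociationTable, BetaMatrix, TwinDesign

__all__ = [
    "wilcoxon_signed_rank_paired",
    "paired_ewas",
    "mean_difference",
    "call_mvps",
    "fisher_exact_rxc",
    "paired_t_test",
    "power_paired_t",
    "relative_discordance",
    "volcano_export",
]

_EXACT_LIMIT = 25  # max nonzero pairs for exact enumeration in mode "auto"


# --------------------------------------------------------------------------
# exact signed-rank machinery
# --------------------------------------------------------------------------

def _signed_rank_counts(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all sign assignments.

    ``ranks2`` are doubled ranks (so midranks like 1.5 become integers).
    Returns ``counts`` where ``counts[w]`` is the number of the 2**n
    sign assignments with doubled positive-rank sum w. Counts are exact
    in float64 up to n = 25 (max count 2**25 << 2**53).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    return counts


@lru_cache(maxsize=64)
def _untied_null(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative and survival tail counts of W+ for untied ranks 1..n.

    Returns (cdf_counts, sf_counts) over W+ = 0..n(n+1)/2 (plain, not
    doubled, ranks: with no ties all ranks are integers).
    """
    ranks2 = 2 * np.arange(1, n + 1)
    counts = _signed_rank_counts(ranks2)
    counts = counts[::2]  # doubled sums are even for integer ranks
    return np.cumsum(counts), np.cumsum(counts[::-1])[::-1]


def _exact_two_sided(ranks2: np.ndarray, w2: float) -> float:
    counts = _signed_rank_counts(ranks2)
    n = len(ranks2)
    total = 2.0 ** n
    w = int(round(w2))
    cdf = counts[: w + 1].sum() / total
    sf = counts[w:].sum() / total
    return min(1.0, 2.0 * min(cdf, sf))


def _approx_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie-corrected variance (no continuity
    correction; ranks may be midranks)."""
    mu = ranks.sum() / 2.0
    sigma = np.sqrt((ranks ** 2).sum() / 4.0)
    if sigma == 0:
        return 1.0
    z = (w_plus - mu) / sigma
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank_paired(
    values_heavy: Sequence[float],
    values_light: Sequence[float],
    mode: str = "auto",
    zero_method: str = "wilcox",
) -> float:
    """Two-sided Wilcoxon signed-rank P for paired measurements.

    Parameters
    ----------
    values_heavy, values_light
        Equal-length paired measurements; the test is on the
        differences heavy − light.
    mode
        "exact" enumerates the null over all sign assignments (valid
        with ties via midranks); "approx" uses the tie-corrected normal
        approximation; "auto" picks exact for ≤ 25 nonzero differences.
    zero_method
        "wilcox" discards zero differences before ranking (classical
        treatment); "pratt" ranks them but drops their ranks from the
        statistic.
    """
    heavy = np.asarray(values_heavy, dtype=float)
    light = np.asarray(values_light, dtype=float)
    if heavy.shape != light.shape or heavy.ndim != 1 or heavy.size < 1:
        raise ValueError("need two equal-length vectors with at least one pair")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")

    d = heavy - light
    if np.isnan(d).any():
        raise ValueError("missing values in paired differences")
    nonzero = d != 0
    if not nonzero.any():
        warnings.warn("all paired differences are zero; P = 1", stacklevel=2)
        return 1.0

    if zero_method == "wilcox":
        d_use = d[nonzero]
        ranks = stats.rankdata(np.abs(d_use))
    else:  # pratt: rank zeros too, then drop their ranks
        ranks_all = stats.rankdata(np.abs(d))
        d_use = d[nonzero]
        ranks = ranks_all[nonzero]

    n = d_use.size
    w_plus = ranks[d_use > 0].sum()
    use_exact = mode == "exact" or (mode == "auto" and n <= _EXACT_LIMIT)
    if not use_exact:
        return _approx_two_sided(ranks, w_plus)

    ranks2 = np.round(2 * ranks).astype(int)
    return _exact_two_sided(ranks2, 2 * w_plus)


def _ewas_pvalues(diffs: np.ndarray, mode: str) -> np.ndarray:
    """Vectorized per-row Wilcoxon P-values for a CpG × pair difference
    matrix. Rows without zeros or ties share the cached untied null
    distribution; other rows fall back to the general routine."""
    n_rows, n = diffs.shape
    pvals = np.full(n_rows, np.nan)
    ok = ~np.isnan(diffs).any(axis=1)
    if not ok.any():
        return pvals

    exact_ok = mode in ("auto", "exact") and n <= _EXACT_LIMIT
    absd = np.abs(diffs[ok])
    has_zero = (absd == 0).any(axis=1)
    sorted_abs = np.sort(absd, axis=1)
    has_tie = (np.diff(sorted_abs, axis=1) == 0).any(axis=1)
    fast = ~has_zero & ~has_tie

    rows = np.flatnonzero(ok)
    if exact_ok and fast.any():
        cdf_counts, sf_counts = _untied_null(n)
        total = 2.0 ** n
        sub = absd[fast]
        order = np.argsort(sub, axis=1)
        ranks = np.empty_like(sub)
        np.put_along_axis(ranks, order, np.arange(1, n + 1)[None, :].astype(float), axis=1)
        w = (ranks * (diffs[ok][fast] > 0)).sum(axis=1).astype(int)
        p_fast = np.minimum(1.0, 2.0 * np.minimum(cdf_counts[w], sf_counts[w]) / total)
        pvals[rows[fast]] = p_fast
        remaining = rows[~fast]
        remaining_d = diffs[ok][~fast]
    else:
        remaining = rows
        remaining_d = diffs[ok]

    for i, row in zip(remaining, remaining_d):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[i] = wilcoxon_signed_rank_paired(row, np.zeros(n), mode=mode)
    return pvals


def paired_ewas(
    matrix: BetaMatrix,
    design: TwinDesign,
    mode: str = "auto",
    p_threshold: float = 0.01,
    d_threshold: float = 0.05,
    label: str = "",
) -> AssociationTable:
    """Per-CpG paired Wilcoxon test of heavy vs light co-twins.

    CpGs with any missing β among the design samples are reported with
    NaN P (complete-case analysis). The returned table flags CpGs
    passing ``p_threshold`` and, as ``mvp``, those additionally passing
    the ``d_threshold`` effect-size filter.
    """
    missing = [s for s in design.sample_ids if s not in matrix.sample_ids]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing[:5]}")
    heavy = matrix.beta[design.heavy].to_numpy()
    light = matrix.beta[design.light].to_numpy()
    diffs = heavy - light
    mean_diff = diffs.mean(axis=1)
    pvals = _ewas_pvalues(diffs, mode)
    table = pd.DataFrame(
        {
            "pvalue": pvals,
            "mean_diff": mean_diff,
            "significant": pvals < p_threshold,
        },
        index=matrix.cpg_ids,
    )
    return AssociationTable(
        table=table,
        p_threshold=p_threshold,
        d_threshold=d_threshold,
        n_pairs=design.n_pairs,
        label=label,
    )


def mean_difference(values_heavy: Sequence[float], values_light: Sequence[float]) -> float:
    """Arithmetic mean of the paired differences heavy − light."""
    heavy = np.asarray(values_heavy, dtype=float)
    light = np.asarray(values_light, dtype=float)
    if heavy.shape != light.shape or heavy.size < 1:
        raise ValueError("need two equal-length nonempty vectors")
    return float(np.mean(heavy - light))


def call_mvps(
    tables: Sequence[AssociationTable],
    p_threshold: float = 0.01,
    d_threshold: float = 0.05,
) -> Tuple[pd.Index, dict]:
    """Intersect analyses into a final MVP set with per-stage counts.

    An MVP must have P < ``p_threshold`` in every analysis and an
    absolute mean β difference > ``d_threshold`` in every analysis.
    Returned counts: per-table P-pass counts, the P-intersection count,
    and the final MVP count.
    """
    if not tables:
        raise ValueError("need at least one association table")
    index = tables[0].cpg_ids
    for t in tables[1:]:
        if not index.equals(t.cpg_ids):
            raise ValueError("association tables cover different CpG sets")

    p_pass = [t.table["pvalue"] < p_threshold for t in tables]
    d_pass = [t.table["mean_diff"].abs() > d_threshold for t in tables]
    p_inter = np.logical_and.reduce(p_pass)
    mvp = p_inter & np.logical_and.reduce(d_pass)
    counts = {
        "p_pass_per_table": {
            t.label or f"analysis_{i + 1}": int(p.sum())
            for i, (t, p) in enumerate(zip(tables, p_pass))
        },
        "p_intersection": int(p_inter.sum()),
        "mvps": int(mvp.sum()),
    }
    return index[mvp], counts


# --------------------------------------------------------------------------
# exact r×c test (Freeman–Halton)
# --------------------------------------------------------------------------

def fisher_exact_rxc(table: Sequence[Sequence[int]], tol: float = 1e-9) -> float:
    """Two-sided exact P for an r×c contingency table.

    Sums the conditional (hypergeometric) probabilities of every table
    with the observed margins whose probability does not exceed the
    observed table's (within a relative float guard ``tol``). This is
    Freeman and Halton's extension of Fisher's 2×2 test; enumeration is
    exact and intended for totals up to a few hundred.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r×c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    total = int(obs.sum())
    if total < 1:
        raise ValueError("table total must be >= 1")

    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    const = (
        special.gammaln(row_sums + 1).sum()
        + special.gammaln(col_sums + 1).sum()
        - special.gammaln(total + 1)
    )

    def logp(cells: np.ndarray) -> float:
        return const - special.gammaln(cells + 1).sum()

    lp_obs = logp(obs)
    cutoff = lp_obs + tol
    n_rows, n_cols = obs.shape
    p_sum = 0.0

    def fill_row(row_idx: int, col_rem: np.ndarray, lg_acc: float) -> None:
        nonlocal p_sum
        if row_idx == n_rows - 1:
            # last row forced by the column margins
            lp = const + lg_acc - special.gammaln(col_rem + 1).sum()
            if lp <= cutoff:
                p_sum += np.exp(lp)
            return
        r = int(row_sums[row_idx])
        cells = np.zeros(n_cols, dtype=int)

        def fill_cell(c: int, rem: int, lg_row: float) -> None:
            if c == n_cols - 1:
                if rem > col_rem[n_cols - 1]:
                    return
                cells[c] = rem
                new_rem = col_rem - cells
                fill_row(
                    row_idx + 1,
                    new_rem,
                    lg_acc + lg_row - special.gammaln(rem + 1),
                )
                return
            for v in range(min(rem, int(col_rem[c])) + 1):
                cells[c] = v
                fill_cell(c + 1, rem - v, lg_row - special.gammaln(v + 1))

        fill_cell(0, r, 0.0)

    fill_row(0, col_sums.copy(), 0.0)
    return min(1.0, p_sum)


# --------------------------------------------------------------------------
# parametric support
# --------------------------------------------------------------------------

def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> Tuple[float, float]:
    """Paired t-test on the differences a − b; returns (t, two-sided P)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need at least 2 equal-length pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def power_paired_t(
    n_pairs: int, delta: float, sd_diff: float, alpha: float = 0.01
) -> float:
    """Power of the two-sided paired t-test.

    Computed from the noncentral t distribution with df = n − 1 and
    noncentrality δ√n / sd, the standard closed form for a paired
    design. ``sd_diff`` is the standard deviation of the within-pair
    differences.
    """
    if n_pairs < 2:
        raise ValueError("need n_pairs >= 2")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    df = n_pairs - 1
    nc = delta * np.sqrt(n_pairs) / sd_diff
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(t_crit, df, nc)
    lower = stats.nct.cdf(-t_crit, df, nc)
    # far-tail probabilities can underflow to NaN at large noncentrality;
    # they are then numerically zero
    upper = 0.0 if np.isnan(upper) else upper
    lower = 0.0 if np.isnan(lower) else lower
    return float(min(1.0, upper + lower))


def relative_discordance(heavier_bw: float, lighter_bw: float) -> float:
    """Relative birth-weight difference (heavier − lighter) / heavier."""
    if lighter_bw <= 0:
        raise ValueError("birth weights must be positive")
    if lighter_bw > heavier_bw:
        raise ValueError("lighter birth weight exceeds heavier")
    return (heavier_bw - lighter_bw) / heavier_bw


def volcano_export(table: AssociationTable, path) -> None:
    """Write (CpG, mean Δβ, −log10 P, MVP flag) TSV for volcano plots."""
    with np.errstate(divide="ignore"):
        out = pd.DataFrame(
            {
                "mean_diff": table.table["mean_diff"],
                "neg_log10_p": -np.log10(table.table["pvalue"]),
                "mvp": table.table["mvp"].astype(bool),
            },
            index=table.cpg_ids,
        )
    out.index.name = "cpg_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
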