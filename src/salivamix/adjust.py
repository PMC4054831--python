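"""Marker-based adjustment for cell-type heterogeneity.

Saliva is a variable mixture of buccal epithelium and leukocytes, so a
bulk β value confounds true methylation with cell composition. The
strategy implemented here:

1. screen a cell-type reference panel for CpGs near-binary between the
   two types (``screen_discriminative``);
2. among the top candidates, select as the composition marker the CpG
   whose measured β explains the largest number of other CpGs linearly
   (``select_marker``), since under the mixture model every
   composition-driven CpG is a linear function of any other;
3. estimate per-sample mixing proportions by inverting the convex
   combination at the marker (``estimate_proportion``);
4. regress every CpG on the marker β (``fit_marker_models``) and
   subtract the fitted composition component only at CpGs whose
   regression is significant (``adjust_for_composition``) — all other
   CpGs pass through bit-identical. After adjustment an affected CpG is
   linearly independent of the marker (OLS residual orthogonality).

Samples with extreme composition break the linearity assumption and
distort every slope; ``detect_outlier_samples`` flags them (whole pairs
at a time) so they can be excluded from fitting and adjustment.
The same machinery accepts several markers at once (e.g. leukocyte
subtype markers) through an ordinary multiple regression.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import AdjustedMatrix, BetaMatrix, MarkerFit, ReferencePanel, TwinDesign

__all__ = [
    "screen_discriminative",
    "estimate_proportion",
    "fit_marker_models",
    "select_marker",
    "classify_marker_correlation",
    "detect_outlier_samples",
    "adjust_for_composition",
]


def screen_discriminative(
    panel: ReferencePanel, type_a: str, type_b: str, k: int = 10
) -> pd.DataFrame:
    """Top-k CpGs by absolute reference difference |β_a − β_b|.

    Returns a frame (index = CpG, columns beta_a, beta_b, abs_diff)
    sorted by descending |Δ|; ties keep panel input order (stable sort)
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(panel.cpg_ids):
        raise ValueError(f"k={k} exceeds panel size {len(panel.cpg_ids)}")
    a = panel.profile(type_a)
    b = panel.profile(type_b)
    diff = (a - b).abs()
    ranked = pd.DataFrame({"beta_a": a, "beta_b": b, "abs_diff": diff}).sort_values(
        "abs_diff", ascending=False, kind="stable"
    )
    top = ranked.head(k)
    if k < len(ranked) and top["abs_diff"].iloc[-1] == ranked["abs_diff"].iloc[k]:
        warnings.warn(
            "tie at the top-k boundary; kept panel input order", stacklevel=2
        )
    return top


def estimate_proportion(
    matrix: BetaMatrix,
    marker: str,
    panel: ReferencePanel,
    type_a: str,
    type_b: str,
    min_separation: float = 0.3,
) -> pd.Series:
    """Per-sample fraction of ``type_a`` from the marker CpG.

    Inverts the mixture model at the marker:
    p = (β_obs − β_b) / (β_a − β_b), truncated to [0,1]. Requires the
    marker's reference separation to exceed ``min_separation``,
    otherwise the marker is uninformative.
    """
    if marker not in matrix.cpg_ids:
        raise KeyError(f"marker {marker!r} not in matrix")
    if marker not in panel.cpg_ids:
        raise KeyError(f"marker {marker!r} not in panel")
    beta_a = float(panel.profile(type_a).loc[marker])
    beta_b = float(panel.profile(type_b).loc[marker])
    sep = beta_a - beta_b
    if abs(sep) < min_separation:
        raise ValueError(
            f"marker separation |{beta_a:.3f} - {beta_b:.3f}| = {abs(sep):.3f} "
            f"below minimum {min_separation}; marker uninformative"
        )
    obs = matrix.beta.loc[marker]
    return ((obs - beta_b) / sep).clip(0.0, 1.0).rename("proportion")


def _resolve_samples(
    matrix: BetaMatrix, exclude_samples: Sequence[str]
) -> pd.Index:
    excluded = set(exclude_samples)
    unknown = excluded - set(matrix.sample_ids)
    if unknown:
        raise KeyError(f"excluded samples not in matrix: {sorted(unknown)}")
    return pd.Index([s for s in matrix.sample_ids if s not in excluded])


def fit_marker_models(
    matrix: BetaMatrix,
    markers: Sequence[str] | str,
    exclude_samples: Sequence[str] = (),
    affected_p: float = 0.01,
) -> MarkerFit:
    """OLS fit of every non-marker CpG's β on the marker β value(s).

    Per CpG returns intercept, one slope per marker, R², and the
    overall regression F-test P-value; a CpG is flagged ``affected``
    when that P is below ``affected_p`` (per-CpG, unadjusted for
    multiplicity). CpGs with any missing β among the fitted samples get
    NaN statistics and are never flagged. A constant CpG has slope 0,
    R² = 0 and P = 1. A rank-deficient multi-marker design drops later
    markers (input order) with a warning.
    """
    if isinstance(markers, str):
        markers = [markers]
    markers = list(markers)
    if not markers:
        raise ValueError("need at least one marker")
    for m in markers:
        if m not in matrix.cpg_ids:
            raise KeyError(f"marker {m!r} not in matrix")
    samples = _resolve_samples(matrix, exclude_samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 non-excluded samples")

    X_marker = matrix.beta.loc[markers, samples].to_numpy().T  # samples × markers
    if np.isnan(X_marker).any():
        raise ValueError("marker CpGs have missing values in the fitted samples")
    for j, m in enumerate(markers):
        if np.var(X_marker[:, j]) == 0:
            raise ValueError(f"marker {m!r} has zero variance across fitted samples")

    # drop collinear later markers until full column rank
    kept = list(range(len(markers)))
    while len(kept) > 1:
        X = np.column_stack([np.ones(len(samples)), X_marker[:, kept]])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        dropped = kept.pop()
        warnings.warn(
            f"marker {markers[dropped]!r} collinear with earlier markers; dropped",
            stacklevel=2,
        )
    used_markers = [markers[i] for i in kept]
    X = np.column_stack([np.ones(len(samples)), X_marker[:, kept]])
    n, p = X.shape
    m_terms = p - 1

    fit_cpgs = matrix.cpg_ids[~matrix.cpg_ids.isin(markers)]
    Y = matrix.beta.loc[fit_cpgs, samples].to_numpy().T  # samples × CpGs
    complete = ~np.isnan(Y).any(axis=0)

    coefs = np.full((p, len(fit_cpgs)), np.nan)
    r2 = np.full(len(fit_cpgs), np.nan)
    pval = np.full(len(fit_cpgs), np.nan)
    if complete.any():
        Yc = Y[:, complete]
        beta_hat, *_ = np.linalg.lstsq(X, Yc, rcond=None)
        resid = Yc - X @ beta_hat
        ssr = (resid ** 2).sum(axis=0)
        sst = ((Yc - Yc.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_c = np.where(sst > 0, 1.0 - ssr / sst, 0.0)
            r2_c = np.clip(r2_c, 0.0, 1.0)
            df_resid = n - p
            f_stat = ((sst - ssr) / m_terms) / np.where(ssr > 0, ssr / df_resid, np.nan)
            p_c = np.where(
                sst > 0,
                np.where(
                    ssr > 1e-300 * np.maximum(sst, 1.0),
                    stats.f.sf(f_stat, m_terms, df_resid),
                    0.0,  # numerically perfect fit
                ),
                1.0,  # constant CpG: no variance to explain
            )
        coefs[:, complete] = beta_hat
        # constant CpGs: define slope 0, intercept = mean
        const = complete.copy()
        const[complete] = sst == 0
        if const.any():
            coefs[1:, const] = 0.0
            coefs[0, const] = Y[:, const].mean(axis=0)
        r2[complete] = r2_c
        pval[complete] = p_c

    table = pd.DataFrame({"intercept": coefs[0]}, index=fit_cpgs)
    for j, m in enumerate(used_markers):
        table[f"slope:{m}"] = coefs[1 + j]
    for m in markers:
        if m not in used_markers:
            table[f"slope:{m}"] = 0.0
    table["r2"] = r2
    table["pvalue"] = pval
    table["affected"] = pd.Series(pval < affected_p, index=fit_cpgs).fillna(False)

    return MarkerFit(
        markers=markers,
        table=table,
        exclude_samples=list(exclude_samples),
        affected_p=affected_p,
        fitted_samples=list(samples),
    )


def select_marker(
    matrix: BetaMatrix,
    candidates: Sequence[str],
    affected_p: float = 0.01,
    exclude_samples: Sequence[str] = (),
) -> Tuple[str, dict]:
    """Pick the candidate whose linear model fits the most CpGs.

    Each candidate's score is the number of CpGs whose single-marker
    regression passes the ``affected_p`` fit rule; the highest score
    wins, ties resolve to the first candidate in input order (with a
    warning).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate marker")
    scores = {}
    for cand in candidates:
        fit = fit_marker_models(
            matrix, cand, exclude_samples=exclude_samples, affected_p=affected_p
        )
        scores[cand] = int(fit.table["affected"].sum())
    best = max(scores.values())
    winners = [c for c in candidates if scores[c] == best]
    if len(winners) > 1:
        warnings.warn(
            f"marker-selection tie among {winners}; kept first in input order",
            stacklevel=2,
        )
    return winners[0], scores


def classify_marker_correlation(
    matrix: BetaMatrix, marker: str, exclude_samples: Sequence[str] = ()
) -> Tuple[pd.Series, dict]:
    """Pearson r of every CpG against the marker, with class counts.

    strong: |r| > 0.8; moderate: 0.4 ≤ |r| ≤ 0.8; weak: |r| < 0.4.
    The marker itself is excluded; zero-variance CpGs get undefined r
    and are counted separately.
    """
    if marker not in matrix.cpg_ids:
        raise KeyError(f"marker {marker!r} not in matrix")
    samples = _resolve_samples(matrix, exclude_samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    others = matrix.cpg_ids[matrix.cpg_ids != marker]
    Y = matrix.beta.loc[others, samples]
    x = matrix.beta.loc[marker, samples].astype(float)
    if x.var() == 0:
        raise ValueError("marker has zero variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = Y.T.corrwith(x)  # NaN where CpG variance is 0
    abs_r = r.abs()
    counts = {
        "strong": int((abs_r > 0.8).sum()),
        "moderate": int(((abs_r >= 0.4) & (abs_r <= 0.8)).sum()),
        "weak": int((abs_r < 0.4).sum()),
        "undefined": int(abs_r.isna().sum()),
    }
    return r.rename("r"), counts


def detect_outlier_samples(
    matrix: BetaMatrix,
    marker: str,
    n_mad: float = 3.0,
    design: Optional[TwinDesign] = None,
    enabled: bool = True,
) -> list:
    """Flag samples with extreme composition (marker β outliers).

    A sample is flagged when its marker β lies outside
    median ± ``n_mad``·MAD over all samples. When a design is given and
    a flagged sample belongs to a pair, the whole pair is excluded
    (paired analyses cannot use half a pair). Returns sample ids.
    """
    if not enabled:
        return []
    if marker not in matrix.cpg_ids:
        raise KeyError(f"marker {marker!r} not in matrix")
    x = matrix.beta.loc[marker].astype(float)
    med = x.median()
    mad = (x - med).abs().median()
    flagged = set(x.index[(x - med).abs() > n_mad * mad])
    if design is not None and flagged:
        for _, row in design.pairs.iterrows():
            if row["heavy_sample"] in flagged or row["light_sample"] in flagged:
                flagged.update([row["heavy_sample"], row["light_sample"]])
    return [s for s in matrix.sample_ids if s in flagged]


def adjust_for_composition(
    matrix: BetaMatrix,
    fit: MarkerFit,
    anchors: Optional[dict] = None,
) -> AdjustedMatrix:
    """Remove the fitted composition component at affected CpGs.

    For each affected CpG j:
    β_adj = β − Σ_k slope_jk · (marker_k − anchor_k), truncated to
    [0,1] (truncation events are counted). Anchor defaults to the mean
    marker β over the fitted (non-excluded) samples, keeping adjusted
    values on the β scale near observed levels. Non-affected CpGs and
    the marker CpGs themselves are copied bit-identically. Samples
    excluded during fitting are dropped from the output.
    """
    for m in fit.markers:
        if m not in matrix.cpg_ids:
            raise KeyError(f"marker {m!r} not in matrix")
    samples = pd.Index(fit.fitted_samples)
    missing = samples.difference(matrix.sample_ids)
    if len(missing):
        raise KeyError(f"fitted samples absent from matrix: {list(missing)}")

    marker_vals = matrix.beta.loc[fit.markers, samples]  # markers × samples
    if anchors is None:
        anchors = {m: float(marker_vals.loc[m].mean()) for m in fit.markers}
    for m, a in anchors.items():
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"anchor {a} for marker {m!r} outside [0,1]")

    sub = matrix.subset_samples(samples)
    beta = sub.beta.copy()
    affected = fit.affected_cpgs
    affected = affected[affected.isin(beta.index)]

    if len(affected):
        slopes = fit.table.loc[affected, [f"slope:{m}" for m in fit.markers]].to_numpy()
        centered = marker_vals.to_numpy() - np.array(
            [anchors[m] for m in fit.markers]
        )[:, None]  # markers × samples
        correction = slopes @ centered  # affected CpGs × samples
        raw = beta.loc[affected].to_numpy() - correction
        n_trunc = int(((raw < 0) | (raw > 1)).sum())
        beta.loc[affected] = np.clip(raw, 0.0, 1.0)
    else:
        n_trunc = 0

    mask = pd.Series(False, index=beta.index)
    mask.loc[affected] = True
    adjusted = BetaMatrix(
        beta=beta,
        detection_p=sub.detection_p,
        annotation=sub.annotation,
    )
    return AdjustedMatrix(
        matrix=adjusted,
        adjusted_mask=mask,
        markers=list(fit.markers),
        anchors=anchors,
        excluded_samples=list(fit.exclude_samples),
        n_truncated=n_trunc,
    )
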