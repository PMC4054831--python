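"""Methylation-index quantification from primer-extension peak areas.

A SNuPE/SIRPH assay extends a primer next to a CpG with either ddCTP
(site was methylated, hence protected from bisulfite conversion) or
ddTTP (unmethylated, converted). HPLC separates the products and the
methylation index is the area ratio MI = AC / (AC + AT) — a peak-area
analogue of the array β value, used here for repetitive elements
(LINE1, HERVK) that arrays do not cover. The paired association of MIs
between heavy and light co-twins reuses the exact Wilcoxon test, and
the optional composition adjustment reuses the marker-regression code
path of the array pipeline, applied per element CpG.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .adjust import adjust_for_composition, fit_marker_models
from .association import wilcoxon_signed_rank_paired
from .types import BetaMatrix, FormatError, SirphAssay, TwinDesign

__all__ = [
    "methylation_index",
    "assays_to_frame",
    "load_sirph_tsv",
    "write_sirph_tsv",
    "sirph_association",
]

_MARKER_ROW = "__composition_marker__"


def methylation_index(area_c: float, area_t: float) -> float:
    """MI = AC / (AC + AT) from the two peak areas; scale-invariant."""
    if area_c < 0 or area_t < 0:
        raise ValueError("peak areas must be nonnegative")
    total = area_c + area_t
    if total == 0:
        raise ValueError("both peak areas zero; MI undefined")
    return float(area_c / total)


def assays_to_frame(assays: Iterable[SirphAssay]) -> pd.DataFrame:
    """Flatten assay records into a long frame with an ``mi`` column."""
    rows = [
        {
            "element": a.element,
            "cpg_index": a.cpg_index,
            "sample_id": a.sample_id,
            "area_c": a.area_c,
            "area_t": a.area_t,
            "mi": a.mi,
        }
        for a in assays
    ]
    if not rows:
        raise ValueError("no assays given")
    return pd.DataFrame(rows)


def load_sirph_tsv(path) -> pd.DataFrame:
    """Read raw peak areas (element, cpg_index, sample_id, area_c,
    area_t) and compute MI on load, so the area ratio is exercised on
    every input path."""
    raw = pd.read_csv(path, sep="\t")
    required = {"element", "cpg_index", "sample_id", "area_c", "area_t"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    raw["mi"] = [
        methylation_index(c, t) for c, t in zip(raw["area_c"], raw["area_t"])
    ]
    return raw


def write_sirph_tsv(frame: pd.DataFrame, path) -> None:
    cols = ["element", "cpg_index", "sample_id", "area_c", "area_t"]
    frame[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def sirph_association(
    assays: pd.DataFrame,
    design: TwinDesign,
    marker_values: Optional[pd.Series] = None,
    affected_p: float = 0.01,
    mode: str = "auto",
) -> pd.DataFrame:
    """Paired heavy-vs-light test of MIs per element CpG.

    With ``marker_values`` (per-sample composition-marker β) given,
    each element CpG's MIs are first residual-adjusted on the marker
    through the same fit/adjust code path used for arrays (adjusted
    only when the marker regression P < ``affected_p``). Returns one
    row per (element, cpg_index) with group means, mean heavy − light
    difference, exact Wilcoxon P and whether adjustment was applied.
    """
    if "mi" not in assays.columns:
        assays = assays.assign(
            mi=[methylation_index(c, t) for c, t in zip(assays["area_c"], assays["area_t"])]
        )
    wide = assays.pivot_table(
        index=["element", "cpg_index"], columns="sample_id", values="mi"
    )
    missing_samples = [s for s in design.sample_ids if s not in wide.columns]
    if missing_samples:
        raise ValueError(f"samples without MI values: {missing_samples[:5]}")
    incomplete = wide[design.sample_ids].isna()
    if incomplete.any().any():
        where = incomplete.stack()
        bad = where[where].index[0]
        raise ValueError(f"missing MI for element CpG {bad[0]}/sample {bad[-1]}")

    wide = wide[design.sample_ids]
    adjusted_flags = pd.Series(False, index=wide.index)
    if marker_values is not None:
        marker_values = marker_values.reindex(design.sample_ids)
        if marker_values.isna().any():
            raise ValueError("marker values missing for some design samples")
        beta = wide.copy()
        beta.index = [f"{e}:{c}" for e, c in beta.index]
        beta.loc[_MARKER_ROW] = marker_values
        matrix = BetaMatrix(beta=beta)
        fit = fit_marker_models(matrix, _MARKER_ROW, affected_p=affected_p)
        adj = adjust_for_composition(matrix, fit)
        flat = adj.matrix.beta.drop(index=_MARKER_ROW)
        flat.index = wide.index
        adjusted_flags[:] = adj.adjusted_mask.drop(index=_MARKER_ROW).to_numpy()
        wide = flat[design.sample_ids]

    records = []
    for (element, cpg_index), row in wide.iterrows():
        heavy = row[design.heavy].to_numpy(dtype=float)
        light = row[design.light].to_numpy(dtype=float)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            p = wilcoxon_signed_rank_paired(heavy, light, mode=mode)
        records.append(
            {
                "element": element,
                "cpg_index": cpg_index,
                "mean_heavy": float(np.mean(heavy)),
                "mean_light": float(np.mean(light)),
                "mean_diff": float(np.mean(heavy - light)),
                "pvalue": p,
                "adjusted": bool(adjusted_flags.loc[(element, cpg_index)]),
            }
        )
    return pd.DataFrame(records)
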