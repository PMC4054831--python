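"""Tabular input/output for β matrices, reference panels and designs.

The β-matrix dialect mirrors a GenomeStudio-style export without any
binary IDAT handling: one tab-separated header line, CpG identifiers in
the first column (``cpg_id``), optional annotation columns (``chrom``,
``pos``, ``gene``), one column per sample, and optional detection
P-value columns named ``<sample>.detP``. Empty cells are missing values.
Values outside [0,1] are rejected with the offending CpG and column
named — never silently clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .types import BetaMatrix, FormatError, ReferencePanel, TwinDesign

__all__ = [
    "load_beta_table",
    "save_beta_table",
    "load_reference_panel",
    "save_reference_panel",
    "load_design",
    "save_design",
    "filter_probes",
    "FilterResult",
    "intersect_with_panel",
    "sample_correlation_matrix",
    "export_bed",
]

_ANNOTATION_COLS = ("chrom", "pos", "gene")
_DETP_SUFFIX = ".detP"


def load_beta_table(path) -> BetaMatrix:
    """Read a β-value TSV into a validated :class:`BetaMatrix`."""
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.columns[0] != "cpg_id":
        raise FormatError(
            f"{path}: first column must be 'cpg_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("cpg_id")
    ann_cols = [c for c in _ANNOTATION_COLS if c in raw.columns]
    detp_cols = [c for c in raw.columns if c.endswith(_DETP_SUFFIX)]
    sample_cols = [c for c in raw.columns if c not in ann_cols and c not in detp_cols]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")

    annotation = None
    if ann_cols:
        annotation = raw[ann_cols].copy()
        if "chrom" in annotation:
            annotation["chrom"] = annotation["chrom"].astype(str)
        if "pos" in annotation:
            annotation["pos"] = annotation["pos"].astype(int)

    detection = None
    if detp_cols:
        expected = [s + _DETP_SUFFIX for s in sample_cols]
        if sorted(detp_cols) != sorted(expected):
            raise FormatError(
                f"{path}: detection-P columns {detp_cols} do not match samples"
            )
        detection = raw[expected].copy()
        detection.columns = sample_cols

    try:
        return BetaMatrix(
            beta=raw[sample_cols].astype(float),
            detection_p=detection,
            annotation=annotation,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_beta_table(matrix: BetaMatrix, path, float_format: str = "%.10g") -> None:
    out = pd.DataFrame(index=matrix.cpg_ids)
    out.index.name = "cpg_id"
    if matrix.annotation is not None:
        for c in _ANNOTATION_COLS:
            if c in matrix.annotation.columns:
                out[c] = matrix.annotation[c]
    for s in matrix.sample_ids:
        out[s] = matrix.beta[s]
    if matrix.detection_p is not None:
        for s in matrix.sample_ids:
            out[s + _DETP_SUFFIX] = matrix.detection_p[s]
    out.to_csv(path, sep="\t", float_format=float_format)


def load_reference_panel(path) -> ReferencePanel:
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.columns[0] != "cpg_id":
        raise FormatError(
            f"{path}: first column must be 'cpg_id', got {raw.columns[0]!r}"
        )
    try:
        return ReferencePanel(raw.set_index("cpg_id").astype(float))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_reference_panel(panel: ReferencePanel, path, float_format: str = "%.10g") -> None:
    out = panel.means.copy()
    out.index.name = "cpg_id"
    out.to_csv(path, sep="\t", float_format=float_format)


def load_design(path) -> TwinDesign:
    return TwinDesign(pd.read_csv(path, sep="\t", dtype=str))


def save_design(design: TwinDesign, path) -> None:
    design.pairs.to_csv(path, sep="\t", index=False)


@dataclass
class FilterResult:
    """Probe-filter output with per-criterion removal counts."""

    matrix: BetaMatrix
    n_input: int
    n_detection_removed: int
    n_chromosome_removed: int

    @property
    def n_kept(self) -> int:
        return self.matrix.n_cpgs

    def report(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_detection_removed": self.n_detection_removed,
            "n_chromosome_removed": self.n_chromosome_removed,
            "n_kept": self.n_kept,
        }


def filter_probes(
    matrix: BetaMatrix,
    detection_threshold: Optional[float] = None,
    drop_chromosomes: Iterable[str] = (),
) -> FilterResult:
    """Drop unreliable probes and unwanted chromosomes.

    A CpG is kept only if its detection P-value is below
    ``detection_threshold`` in *every* sample (when a threshold is
    given) and its chromosome is not in ``drop_chromosomes``.
    Removal counts per criterion are reported; a CpG failing both is
    counted under detection (the first criterion applied).
    """
    drop_chromosomes = {str(c) for c in drop_chromosomes}
    keep = pd.Series(True, index=matrix.cpg_ids)

    n_det = 0
    if detection_threshold is not None:
        if matrix.detection_p is None:
            raise FormatError(
                "detection threshold given but matrix carries no detection P-values"
            )
        det_ok = (matrix.detection_p < detection_threshold).all(axis=1)
        n_det = int((~det_ok).sum())
        keep &= det_ok

    n_chrom = 0
    if drop_chromosomes:
        if matrix.annotation is None or "chrom" not in matrix.annotation.columns:
            raise FormatError("chromosome filter requested but matrix has no annotation")
        on_bad = matrix.annotation["chrom"].astype(str).isin(drop_chromosomes)
        n_chrom = int((on_bad & keep).sum())
        keep &= ~on_bad

    return FilterResult(
        matrix=matrix.subset_cpgs(matrix.cpg_ids[keep]),
        n_input=matrix.n_cpgs,
        n_detection_removed=n_det,
        n_chromosome_removed=n_chrom,
    )


def intersect_with_panel(
    matrix: BetaMatrix, panel: ReferencePanel
) -> Tuple[BetaMatrix, ReferencePanel]:
    """Restrict matrix and panel to their common CpGs, order-aligned."""
    common = matrix.cpg_ids.intersection(panel.cpg_ids)
    if len(common) == 0:
        raise FormatError("matrix and reference panel share no CpGs")
    common = matrix.cpg_ids[matrix.cpg_ids.isin(common)]  # keep matrix order
    return matrix.subset_cpgs(common), ReferencePanel(panel.means.loc[common])


def sample_correlation_matrix(matrix: BetaMatrix) -> pd.DataFrame:
    """Array-wide pairwise Pearson correlations between samples.

    Missing β values are excluded pairwise. A zero-variance sample
    yields undefined (NaN) coefficients for its pairs, with a warning;
    the diagonal is 1 by convention.
    """
    if matrix.n_samples < 2 or matrix.n_cpgs < 2:
        raise ValueError("need at least 2 samples and 2 CpGs")
    variances = matrix.beta.var(axis=0, skipna=True)
    flat = variances[variances == 0].index.tolist()
    if flat:
        warnings.warn(
            f"zero-variance sample(s) {flat}: correlations undefined", stacklevel=2
        )
    corr = matrix.beta.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def export_bed(matrix: BetaMatrix, path) -> None:
    """Write CpG coordinates as BED (0-based, half-open)."""
    if matrix.annotation is None or not {"chrom", "pos"} <= set(matrix.annotation.columns):
        raise FormatError("BED export needs chrom/pos annotation")
    ann = matrix.annotation
    bed = pd.DataFrame(
        {
            "chrom": ann["chrom"].astype(str),
            "start": ann["pos"].astype(int) - 1,
            "end": ann["pos"].astype(int),
            "name": matrix.cpg_ids,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
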