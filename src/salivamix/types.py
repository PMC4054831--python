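"""Core data containers exchanged between pipeline stages.

The central object is :class:`BetaMatrix`, a CpG-by-sample table of
methylation fractions (β values) with optional per-probe detection
P-values and CpG annotation. Reference cell-type profiles, twin-pair
designs, marker-model fits and read-level bisulfite data get their own
lightweight containers. Validation happens at construction: invalid
values are rejected, never clamped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "BetaMatrix",
    "ReferencePanel",
    "TwinDesign",
    "SimulationTruth",
    "MarkerFit",
    "AdjustedMatrix",
    "AssociationTable",
    "AmpliconReadSet",
    "SirphAssay",
]


class FormatError(ValueError):
    """A data table violates its declared format or invariants."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} identifiers: {dupes[:5]}")


def _check_unit_interval(frame: pd.DataFrame, what: str) -> None:
    values = frame.to_numpy(dtype=float)
    bad = ~np.isnan(values) & ((values < 0.0) | (values > 1.0) | ~np.isfinite(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{what} value {values[i, j]!r} outside [0,1] at "
            f"CpG {frame.index[i]!r}, sample {frame.columns[j]!r}"
        )


@dataclass
class BetaMatrix:
    """Methylation β values: rows are CpGs, columns are samples.

    Parameters
    ----------
    beta
        CpG × sample matrix of methylation fractions in [0, 1].
        Missing measurements are NaN and are excluded pairwise from
        correlations; CpGs with any missing value are excluded from
        marker fitting and association (complete-case analysis).
    detection_p
        Optional per-probe detection P-values, same shape as ``beta``.
    annotation
        Optional per-CpG frame with columns ``chrom`` (plain string,
        "1".."22","X","Y"), ``pos`` (1-based) and optionally ``gene``.
    """

    beta: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    annotation: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        _check_unique(self.beta.index, "CpG")
        _check_unique(self.beta.columns, "sample")
        _check_unit_interval(self.beta, "beta")
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise FormatError(
                    f"detection-P shape {self.detection_p.shape} does not match "
                    f"beta shape {self.beta.shape}"
                )
            self.detection_p = self.detection_p.astype(float)
            self.detection_p.index = self.beta.index
            self.detection_p.columns = self.beta.columns
            _check_unit_interval(self.detection_p, "detection P")
        if self.annotation is not None:
            missing = self.beta.index.difference(self.annotation.index)
            if len(missing) > 0:
                raise FormatError(f"annotation missing for CpGs: {list(missing[:5])}")
            self.annotation = self.annotation.loc[self.beta.index]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        idx = pd.Index(cpg_ids)
        return BetaMatrix(
            beta=self.beta.loc[idx],
            detection_p=None if self.detection_p is None else self.detection_p.loc[idx],
            annotation=None if self.annotation is None else self.annotation.loc[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        cols = pd.Index(sample_ids)
        return BetaMatrix(
            beta=self.beta[cols],
            detection_p=None if self.detection_p is None else self.detection_p[cols],
            annotation=self.annotation,
        )


@dataclass
class ReferencePanel:
    """Per-cell-type mean β per CpG (CpG rows × cell-type columns)."""

    means: pd.DataFrame

    def __post_init__(self) -> None:
        self.means = self.means.astype(float)
        _check_unique(self.means.index, "CpG")
        _check_unique(self.means.columns, "cell type")
        if self.means.isna().any().any():
            raise FormatError("reference panel has missing cell-type means")
        _check_unit_interval(self.means, "reference β")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.means.index

    @property
    def cell_types(self) -> pd.Index:
        return self.means.columns

    def profile(self, cell_type: str) -> pd.Series:
        if cell_type not in self.means.columns:
            raise KeyError(f"cell type {cell_type!r} not in panel {list(self.means.columns)}")
        return self.means[cell_type]


@dataclass
class TwinDesign:
    """Paired design: one heavy-at-birth and one light-at-birth member per pair."""

    pairs: pd.DataFrame  # columns: pair_id, heavy_sample, light_sample

    REQUIRED = ("pair_id", "heavy_sample", "light_sample")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.pairs.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        self.pairs = self.pairs[list(self.REQUIRED)].reset_index(drop=True)
        _check_unique(pd.Index(self.pairs["pair_id"]), "pair")
        same = self.pairs["heavy_sample"] == self.pairs["light_sample"]
        if same.any():
            raise FormatError(
                f"heavy and light member identical in pair(s) "
                f"{self.pairs.loc[same, 'pair_id'].tolist()}"
            )
        all_samples = pd.Index(
            pd.concat([self.pairs["heavy_sample"], self.pairs["light_sample"]])
        )
        _check_unique(all_samples, "sample (each sample must be in exactly one pair)")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def heavy(self) -> list:
        return self.pairs["heavy_sample"].tolist()

    @property
    def light(self) -> list:
        return self.pairs["light_sample"].tolist()

    @property
    def sample_ids(self) -> list:
        return self.heavy + self.light

    def drop_pairs(self, pair_ids: Sequence) -> "TwinDesign":
        keep = ~self.pairs["pair_id"].isin(set(pair_ids))
        return TwinDesign(self.pairs[keep].reset_index(drop=True))

    def pair_of(self, sample_id: str):
        """Return the pair_id containing ``sample_id`` (None if absent)."""
        hit = self.pairs[
            (self.pairs["heavy_sample"] == sample_id)
            | (self.pairs["light_sample"] == sample_id)
        ]
        return None if hit.empty else hit["pair_id"].iloc[0]


@dataclass
class SimulationTruth:
    """Ground truth recorded by the synthetic-data generator.

    All stochastic outputs are reproducible bit-for-bit from ``seed``
    plus the generator's parameters.
    """

    seed: int
    noise_sd: float = 0.0
    proportions: Optional[dict] = None  # sample id -> true buccal fraction
    cell_type_means: Optional[dict] = None  # cpg id -> {cell type: β}
    discriminative_cpgs: Optional[list] = None
    marker_cpg: Optional[str] = None
    effects: Optional[dict] = None  # cpg id -> signed β effect (heavy − light)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.proportions:
            vals = np.array(list(self.proportions.values()), dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError("true proportions must lie in [0,1]")
        if self.cell_type_means:
            for cpg, means in self.cell_type_means.items():
                for ct, b in means.items():
                    if not 0.0 <= b <= 1.0:
                        raise ValueError(f"cell-type β {b} for {cpg}/{ct} outside [0,1]")
        if self.effects and self.cell_type_means is not None:
            unknown = set(self.effects) - set(self.cell_type_means)
            if unknown:
                raise ValueError(f"effect CpGs not in panel: {sorted(unknown)[:5]}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


@dataclass
class MarkerFit:
    """Per-CpG OLS fit of β on one or more marker CpGs.

    ``table`` has one row per fitted (non-marker) CpG with columns
    ``intercept``, one ``slope:<marker>`` per marker, ``r2``, ``pvalue``
    (overall regression F-test) and ``affected`` (pvalue < affected_p).
    """

    markers: list
    table: pd.DataFrame
    exclude_samples: list
    affected_p: float
    fitted_samples: list

    def __post_init__(self) -> None:
        required = {"intercept", "r2", "pvalue", "affected"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker-fit table missing columns {sorted(missing)}")
        for m in self.markers:
            if f"slope:{m}" not in self.table.columns:
                raise ValueError(f"marker-fit table missing slope column for {m!r}")

    @property
    def affected_cpgs(self) -> pd.Index:
        return self.table.index[self.table["affected"].fillna(False).astype(bool)]

    def slopes(self) -> pd.DataFrame:
        return self.table[[f"slope:{m}" for m in self.markers]]


@dataclass
class AdjustedMatrix:
    """Selectively composition-adjusted β matrix with provenance."""

    matrix: BetaMatrix
    adjusted_mask: pd.Series  # bool per CpG: True where values were changed
    markers: list
    anchors: dict  # marker id -> anchor β at which adjustment is pinned
    excluded_samples: list
    n_truncated: int = 0

    def __post_init__(self) -> None:
        self.adjusted_mask = self.adjusted_mask.reindex(self.matrix.cpg_ids).fillna(False)

    @property
    def n_adjusted(self) -> int:
        return int(self.adjusted_mask.sum())

    @property
    def n_unchanged(self) -> int:
        return int((~self.adjusted_mask).sum())


@dataclass
class AssociationTable:
    """Per-CpG paired-test results.

    ``table`` columns: ``pvalue`` (two-sided, in (0,1]), ``mean_diff``
    (mean heavy − light β difference), ``significant``, ``mvp``.
    """

    table: pd.DataFrame
    p_threshold: float
    d_threshold: float
    n_pairs: int
    label: str = ""

    def __post_init__(self) -> None:
        required = {"pvalue", "mean_diff", "significant"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"association table missing columns {sorted(missing)}")
        if "mvp" not in self.table.columns:
            self.table["mvp"] = self.table["significant"] & (
                self.table["mean_diff"].abs() > self.d_threshold
            )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.table.index

    @property
    def mvps(self) -> pd.Index:
        return self.table.index[self.table["mvp"].fillna(False).astype(bool)]


@dataclass
class AmpliconReadSet:
    """Per-read binary methylation calls for one amplicon in one sample.

    ``calls`` is an int8 matrix (reads × CpGs): 1 methylated,
    0 unmethylated, -1 missing. ``conversion`` holds the per-read
    bisulfite conversion-rate estimate.
    """

    amplicon_id: str
    sample_id: str
    calls: np.ndarray
    conversion: np.ndarray
    cpg_ids: list = field(default_factory=list)
    read_ids: list = field(default_factory=list)
    alleles: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a reads × CpGs matrix")
        self.conversion = np.asarray(self.conversion, dtype=float)
        if self.conversion.shape[0] != self.calls.shape[0]:
            raise ValueError("one conversion-rate estimate per read required")
        if ((self.conversion < 0) | (self.conversion > 1)).any():
            raise ValueError("conversion rates must lie in [0,1]")
        if not self.cpg_ids:
            self.cpg_ids = [f"cpg_{i + 1}" for i in range(self.calls.shape[1])]
        if len(self.cpg_ids) != self.calls.shape[1]:
            raise ValueError("cpg_ids length must match call-vector width")
        if not self.read_ids:
            self.read_ids = [f"read_{i + 1}" for i in range(self.calls.shape[0])]
        if self.alleles is not None:
            self.alleles = np.asarray(self.alleles, dtype=object)
            if self.alleles.shape[0] != self.calls.shape[0]:
                raise ValueError("one allele call per read required")

    @property
    def n_reads(self) -> int:
        return self.calls.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.calls.shape[1]

    def subset_reads(self, index: np.ndarray) -> "AmpliconReadSet":
        return AmpliconReadSet(
            amplicon_id=self.amplicon_id,
            sample_id=self.sample_id,
            calls=self.calls[index],
            conversion=self.conversion[index],
            cpg_ids=list(self.cpg_ids),
            read_ids=[self.read_ids[i] for i in np.flatnonzero(index)]
            if np.asarray(index).dtype == bool
            else [self.read_ids[i] for i in index],
            alleles=None if self.alleles is None else self.alleles[index],
        )


@dataclass
class SirphAssay:
    """One primer-extension (SNuPE/SIRPH) measurement.

    The methylation index MI = AC/(AC+AT) is the fraction of the summed
    peak area contributed by the ddCTP-extended (methylated) primer.
    """

    element: str
    cpg_index: int
    sample_id: str
    area_c: float
    area_t: float

    def __post_init__(self) -> None:
        if self.area_c < 0 or self.area_t < 0:
            raise ValueError("peak areas must be nonnegative")

    @property
    def mi(self) -> float:
        from .sirph import methylation_index

        return methylation_index(self.area_c, self.area_t)
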