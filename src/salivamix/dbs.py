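"""Deep-bisulfite-sequencing validation of array methylation calls.

Amplicon reads arrive as per-read binary methylation calls over the
amplicon's CpGs ('1' methylated, '0' unmethylated, '.' missing) plus a
per-read bisulfite conversion-rate estimate. Low-quality reads are
removed (incomplete conversion inflates apparent methylation), per-CpG
methylation fractions are computed from the retained calls, and
cross-platform concordance with the array quantifies whether an array
signal replicates. A SNP inside an amplicon gives a technical-noise
floor: in genetically identical twins the within-pair difference in
read-level allele fractions is pure assay noise, against which any
claimed methylation difference can be judged.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .types import AmpliconReadSet, FormatError, TwinDesign

__all__ = [
    "write_reads_tsv",
    "load_reads_tsv",
    "filter_reads",
    "amplicon_methylation",
    "cross_platform_concordance",
    "snp_allele_balance",
    "paired_allele_noise",
]

_CALL_CHARS = {1: "1", 0: "0", -1: "."}
_CHAR_CALLS = {"1": 1, "0": 0, ".": -1}


def write_reads_tsv(readsets: Iterable[AmpliconReadSet], path) -> None:
    """Write read sets as TSV: amplicon_id, sample_id, read_id, calls
    (string over CpGs), conversion, allele (may be empty)."""
    rows = []
    for rs in readsets:
        for i in range(rs.n_reads):
            rows.append(
                {
                    "amplicon_id": rs.amplicon_id,
                    "sample_id": rs.sample_id,
                    "read_id": rs.read_ids[i],
                    "calls": "".join(_CALL_CHARS[int(c)] for c in rs.calls[i]),
                    "conversion": rs.conversion[i],
                    "allele": "" if rs.alleles is None else (rs.alleles[i] or ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_reads_tsv(path) -> Dict[Tuple[str, str], AmpliconReadSet]:
    """Load a read-call TSV, grouped by (amplicon_id, sample_id)."""
    raw = pd.read_csv(
        path, sep="\t", dtype={"calls": str, "allele": str}, keep_default_na=False
    )
    required = {"amplicon_id", "sample_id", "read_id", "calls", "conversion"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: Dict[Tuple[str, str], AmpliconReadSet] = {}
    for (amp, samp), grp in raw.groupby(["amplicon_id", "sample_id"], sort=False):
        call_strings = grp["calls"].astype(str).tolist()
        widths = {len(s) for s in call_strings}
        if len(widths) != 1:
            raise FormatError(
                f"{path}: unequal call-vector lengths for amplicon {amp!r}, "
                f"sample {samp!r}"
            )
        try:
            calls = np.array(
                [[_CHAR_CALLS[ch] for ch in s] for s in call_strings], dtype=np.int8
            )
        except KeyError as exc:
            raise FormatError(f"{path}: invalid call character {exc}") from exc
        alleles = None
        if "allele" in grp.columns and (grp["allele"] != "").any():
            alleles = grp["allele"].replace("", None).to_numpy(dtype=object)
        out[(amp, samp)] = AmpliconReadSet(
            amplicon_id=str(amp),
            sample_id=str(samp),
            calls=calls,
            conversion=grp["conversion"].astype(float).to_numpy(),
            read_ids=grp["read_id"].astype(str).tolist(),
            alleles=alleles,
        )
    return out


def filter_reads(
    reads: AmpliconReadSet,
    min_conversion: float = 0.95,
    max_missing_fraction: float = 0.2,
) -> Tuple[AmpliconReadSet, dict]:
    """Drop low-quality reads; report counts removed per criterion.

    A read is kept when its conversion-rate estimate is at least
    ``min_conversion`` and its fraction of missing CpG calls is at most
    ``max_missing_fraction``. The operation is idempotent.
    """
    if not 0 <= min_conversion <= 1 or not 0 <= max_missing_fraction <= 1:
        raise ValueError("thresholds must lie in [0,1]")
    conv_ok = reads.conversion >= min_conversion
    missing_frac = (reads.calls == -1).mean(axis=1) if reads.n_cpgs else np.zeros(
        reads.n_reads
    )
    miss_ok = missing_frac <= max_missing_fraction
    keep = conv_ok & miss_ok
    report = {
        "n_input": reads.n_reads,
        "n_low_conversion": int((~conv_ok).sum()),
        "n_high_missing": int((~miss_ok).sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    return reads.subset_reads(keep), report


def amplicon_methylation(reads: AmpliconReadSet) -> pd.DataFrame:
    """Per-CpG methylation fraction and coverage from read calls.

    fraction = methylated calls / non-missing calls; a CpG with zero
    non-missing calls gets NaN and is flagged in the ``defined``
    column.
    """
    if reads.n_reads < 1:
        raise ValueError("no reads retained; cannot compute methylation")
    meth = (reads.calls == 1).sum(axis=0)
    covered = (reads.calls != -1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(covered > 0, meth / np.maximum(covered, 1), np.nan)
    if (covered == 0).any():
        warnings.warn("CpG(s) with zero coverage; fraction undefined", stacklevel=2)
    return pd.DataFrame(
        {"fraction": frac, "coverage": covered, "defined": covered > 0},
        index=pd.Index(reads.cpg_ids, name="cpg_id"),
    )


def cross_platform_concordance(
    array_values: pd.DataFrame,
    dbs_values: pd.DataFrame,
    axis: str = "per-sample",
) -> Tuple[pd.Series, float]:
    """Pearson concordance between array and DBS methylation values.

    Both inputs are CpG × sample frames over the validated loci.
    ``axis='per-sample'`` correlates the two platforms across CpGs
    within each sample; ``'per-CpG'`` correlates across samples within
    each CpG. Items with fewer than 3 complete pairs or zero variance
    on either side get NaN (flagged by warning). Returns the per-item
    series and its median.
    """
    if axis not in ("per-sample", "per-CpG"):
        raise ValueError("axis must be 'per-sample' or 'per-CpG'")
    common_cpgs = array_values.index.intersection(dbs_values.index)
    common_samples = array_values.columns.intersection(dbs_values.columns)
    a = array_values.loc[common_cpgs, common_samples]
    d = dbs_values.loc[common_cpgs, common_samples]
    if axis == "per-sample":
        items = common_samples
        get = lambda frame, item: frame[item]
    else:
        items = common_cpgs
        get = lambda frame, item: frame.loc[item]
    r_values = {}
    for item in items:
        x = get(a, item).astype(float)
        y = get(d, item).astype(float)
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            r_values[item] = np.nan
            continue
        r_values[item] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    r = pd.Series(r_values, name="r")
    if r.isna().any():
        warnings.warn(
            f"concordance undefined for {r.index[r.isna()].tolist()}", stacklevel=2
        )
    return r, float(r.median(skipna=True))


def snp_allele_balance(
    reads: AmpliconReadSet, ref_allele: Optional[str] = None
) -> float:
    """Fraction of reads carrying the reference allele.

    With ``ref_allele`` unset, the lexicographically first observed
    allele is taken as reference. A sample showing only one allele
    (effectively homozygous) triggers a warning: the balance is then
    uninformative as a noise measure.
    """
    if reads.alleles is None:
        raise ValueError("read set carries no allele calls")
    called = np.array([a for a in reads.alleles if a], dtype=object)
    if called.size == 0:
        raise ValueError("no non-missing allele calls")
    observed = sorted(set(called.tolist()))
    if len(observed) < 2:
        warnings.warn(
            f"sample {reads.sample_id!r} shows a single allele; "
            "not informative as heterozygous noise floor",
            stacklevel=2,
        )
    if ref_allele is None:
        ref_allele = observed[0]
    return float((called == ref_allele).mean())


def paired_allele_noise(design: TwinDesign, fractions: pd.Series) -> float:
    """Mean absolute within-pair allele-fraction difference.

    In monozygotic twins both members share the genotype, so the true
    allele fraction is identical within a pair and the observed mean
    |Δ| across pairs estimates the technical noise floor of the assay.
    """
    missing = [s for s in design.sample_ids if s not in fractions.index]
    if missing:
        raise ValueError(f"allele fractions missing for samples: {missing[:5]}")
    heavy = fractions.loc[design.heavy].to_numpy(dtype=float)
    light = fractions.loc[design.light].to_numpy(dtype=float)
    return float(np.mean(np.abs(heavy - light)))
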