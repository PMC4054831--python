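"""Seeded synthetic data with the structure the analysis assumes.

Saliva DNA is a two-cell-type mixture (buccal epithelium + leukocytes),
so a sample's β at CpG j is modeled as the convex combination
``p·β_buccal,j + (1−p)·β_blood,j`` of the two cell-type profiles, where
p is the sample's buccal fraction, plus additive Gaussian technical
noise on the β scale truncated to [0,1]. The generator covers:

* a two-cell-type reference panel with a configurable number of
  discriminatively methylated CpGs (the planted top marker carries the
  buccal/blood values 0.82/0.05 typical of a near-binary marker);
* paired cohorts (heavy/light co-twins) with controllable within-pair
  composition correlation, an optional systematic composition offset
  in the heavy member (the confounding scenario), and injected
  heavy−light β effects at chosen CpGs;
* in-vitro-style mixture dilution series;
* read-level bisulfite amplicon data with imperfect conversion;
* primer-extension (SIRPH) peak-area measurements.

Every function takes an integer seed and is bit-reproducible.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    AmpliconReadSet,
    BetaMatrix,
    ReferencePanel,
    SimulationTruth,
    SirphAssay,
    TwinDesign,
)

__all__ = [
    "simulate_reference_panel",
    "simulate_cohort",
    "simulate_mixture_series",
    "simulate_dbs_reads",
    "simulate_sirph_assay",
]

_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y"]

# planted near-binary marker: methylated in buccal epithelium,
# unmethylated in blood
_MARKER_BUCCAL = 0.82
_MARKER_BLOOD = 0.05


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def simulate_reference_panel(
    n_cpgs: int,
    n_discriminative: int,
    separation: float = 0.7,
    seed: int = 0,
    cell_types: Tuple[str, str] = ("buccal", "blood"),
    plant_marker: bool = True,
    max_separation: float = 0.75,
) -> Tuple[ReferencePanel, SimulationTruth]:
    """Two cell-type profiles with a controlled discriminative subset.

    Exactly ``n_discriminative`` CpGs get an absolute cell-type
    difference of at least ``separation``; the remainder differ by at
    most 0.05 (safely below the MVP effect threshold). When
    ``plant_marker`` is true the first discriminative CpG carries the
    exact values (0.82 buccal, 0.05 blood) and the other discriminative
    differences are capped at ``max_separation`` < 0.77, so the planted
    marker is deterministically the top-ranked screen hit.
    """
    if n_cpgs <= 0:
        raise ValueError("n_cpgs must be positive")
    if not 0 <= n_discriminative <= n_cpgs:
        raise ValueError("need 0 <= n_discriminative <= n_cpgs")
    if not 0 < separation <= 1:
        raise ValueError("separation must be in (0,1]")

    rng = np.random.default_rng(seed)
    ids = [f"cg{i:08d}" for i in range(1, n_cpgs + 1)]
    type_a, type_b = cell_types

    a = np.empty(n_cpgs)
    b = np.empty(n_cpgs)

    # non-discriminative background: small differences, uniform base
    base = rng.uniform(0.02, 0.98, size=n_cpgs)
    small_delta = rng.uniform(0.0, 0.05, size=n_cpgs) * rng.choice([-1, 1], size=n_cpgs)
    a[:] = _clip01(base + small_delta / 2)
    b[:] = _clip01(base - small_delta / 2)

    disc = list(range(n_discriminative))
    hi = min(max_separation, 1.0) if plant_marker else 1.0
    lo = min(separation, hi)
    for i in disc:
        if plant_marker and i == 0:
            a[i], b[i] = _MARKER_BUCCAL, _MARKER_BLOOD
            continue
        delta = rng.uniform(lo, hi)
        low_val = rng.uniform(0.01, 0.99 - delta)
        if rng.random() < 0.5:
            a[i], b[i] = low_val + delta, low_val
        else:
            a[i], b[i] = low_val, low_val + delta

    means = pd.DataFrame({type_a: a, type_b: b}, index=pd.Index(ids, name="cpg_id"))
    panel = ReferencePanel(means)
    truth = SimulationTruth(
        seed=seed,
        cell_type_means={cid: {type_a: float(x), type_b: float(y)}
                         for cid, x, y in zip(ids, a, b)},
        discriminative_cpgs=[ids[i] for i in disc],
        marker_cpg=ids[0] if (plant_marker and n_discriminative > 0) else None,
        extra={"separation": separation, "n_cpgs": n_cpgs},
    )
    return panel, truth


def _sample_pair_proportions(
    rng: np.random.Generator,
    n_pairs: int,
    low: float,
    high: float,
    pair_corr: float,
    heavy_offset: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Buccal fractions for (heavy, light) members of each pair.

    ``pair_corr`` in [0,1] controls within-pair similarity: the pair
    shares a latent level drawn from a shrunken range and members
    scatter around it; 0 gives independent uniforms on [low, high],
    1 gives identical members. ``heavy_offset`` adds a systematic extra
    buccal fraction to the heavy member (the confounding scenario seen
    when deviating samples are predominantly heavy co-twins).
    """
    if not 0 <= pair_corr <= 1:
        raise ValueError("pair_corr must be in [0,1]")
    half = (high - low) / 2.0
    spread = (1.0 - pair_corr) * half
    center = rng.uniform(low + spread, high - spread, size=n_pairs)
    heavy = center + rng.uniform(-spread, spread, size=n_pairs)
    light = center + rng.uniform(-spread, spread, size=n_pairs)
    heavy = heavy + heavy_offset
    return _clip01(heavy), _clip01(light)


def simulate_cohort(
    panel: ReferencePanel,
    n_pairs: int,
    proportion_sampler: Optional[dict] = None,
    effect_spec: Optional[Sequence[Tuple[str, float]]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_types: Tuple[str, str] = ("buccal", "blood"),
    effect_target: str = "heavy",
    proportions: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
    detection_fail_rate: float = 0.0,
    n_snp_probes: int = 0,
) -> Tuple[BetaMatrix, TwinDesign, SimulationTruth]:
    """Paired saliva-like cohort as per-sample two-cell-type mixtures.

    Parameters
    ----------
    proportion_sampler
        Dict spec with keys ``low``, ``high`` (uniform range, default
        [0.1, 0.9]), ``pair_corr`` (within-pair composition similarity,
        default 0) and ``heavy_offset`` (systematic extra buccal
        fraction in the heavy member, default 0).
    effect_spec
        (CpG id, signed β effect) pairs; the effect is added to the
        ``effect_target`` member so the heavy − light mean difference
        equals +effect (target "heavy") or −effect (target "light").
    proportions
        Explicit (heavy, light) buccal fractions per pair; overrides
        the sampler (useful for exact-recovery tests).
    detection_fail_rate
        Fraction of CpGs given a detection P of 0.002 in one random
        sample (fails the conventional <0.001-in-all-samples filter).
    n_snp_probes
        Extra SNP-probe-like loci appended (ids ``rs...``) whose β is a
        genotype level {0, 0.5, 1} shared within each twin pair plus
        noise — a technical-noise floor, not a mixture signal.
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if effect_target not in ("heavy", "light"):
        raise ValueError("effect_target must be 'heavy' or 'light'")
    type_a, type_b = cell_types
    prof_a = panel.profile(type_a).to_numpy()
    prof_b = panel.profile(type_b).to_numpy()

    rng = np.random.default_rng(seed)
    sampler = dict(low=0.1, high=0.9, pair_corr=0.0, heavy_offset=0.0)
    sampler.update(proportion_sampler or {})
    if proportions is not None:
        p_heavy = np.asarray(proportions[0], dtype=float)
        p_light = np.asarray(proportions[1], dtype=float)
        if p_heavy.size != n_pairs or p_light.size != n_pairs:
            raise ValueError("explicit proportions must have one value per pair")
        if ((p_heavy < 0) | (p_heavy > 1) | (p_light < 0) | (p_light > 1)).any():
            raise ValueError("proportions must lie in [0,1]")
    else:
        p_heavy, p_light = _sample_pair_proportions(
            rng, n_pairs, sampler["low"], sampler["high"],
            sampler["pair_corr"], sampler["heavy_offset"],
        )

    heavy_ids = [f"pair{i + 1}_H" for i in range(n_pairs)]
    light_ids = [f"pair{i + 1}_L" for i in range(n_pairs)]
    sample_ids = heavy_ids + light_ids
    p_all = np.concatenate([p_heavy, p_light])

    base = np.outer(prof_a, p_all) + np.outer(prof_b, 1.0 - p_all)  # CpG × sample

    effects = {}
    if effect_spec:
        cpg_pos = {cid: i for i, cid in enumerate(panel.cpg_ids)}
        for cid, delta in effect_spec:
            if cid not in cpg_pos:
                raise ValueError(f"effect CpG {cid!r} not in panel")
            j = cpg_pos[cid]
            if effect_target == "heavy":
                base[j, :n_pairs] += delta
            else:
                base[j, n_pairs:] += delta
            effects[cid] = float(delta) if effect_target == "heavy" else -float(delta)

    noise = rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else 0.0
    beta = _clip01(base + noise)
    beta = pd.DataFrame(beta, index=panel.cpg_ids.copy(), columns=sample_ids)

    if n_snp_probes > 0:
        genotypes = rng.choice([0.0, 0.5, 1.0], size=(n_snp_probes, n_pairs))
        snp = np.repeat(genotypes, 2, axis=1)  # identical within a pair
        snp_cols = [s for pair in zip(heavy_ids, light_ids) for s in pair]
        snp_noise = rng.normal(0.0, max(noise_sd, 0.01), size=snp.shape)
        snp_beta = pd.DataFrame(
            _clip01(snp + snp_noise),
            index=[f"rs{i + 1:06d}" for i in range(n_snp_probes)],
            columns=snp_cols,
        )[sample_ids]
        beta = pd.concat([beta, snp_beta])

    n_total = beta.shape[0]
    detp = pd.DataFrame(
        rng.uniform(0.0, 5e-4, size=(n_total, len(sample_ids))),
        index=beta.index, columns=sample_ids,
    )
    if detection_fail_rate > 0:
        n_fail = int(round(detection_fail_rate * n_total))
        fail_rows = rng.choice(n_total, size=n_fail, replace=False)
        fail_cols = rng.integers(0, len(sample_ids), size=n_fail)
        for r, c in zip(fail_rows, fail_cols):
            detp.iat[r, c] = 0.002

    annotation = pd.DataFrame(
        {
            "chrom": [_CHROMS[i % len(_CHROMS)] for i in range(n_total)],
            "pos": np.arange(1, n_total + 1) * 1000,
        },
        index=beta.index,
    )

    matrix = BetaMatrix(beta=beta, detection_p=detp, annotation=annotation)
    design = TwinDesign(
        pd.DataFrame(
            {
                "pair_id": [f"pair{i + 1}" for i in range(n_pairs)],
                "heavy_sample": heavy_ids,
                "light_sample": light_ids,
            }
        )
    )
    truth = SimulationTruth(
        seed=seed,
        noise_sd=noise_sd,
        proportions={s: float(p) for s, p in zip(sample_ids, p_all)},
        effects=effects or None,
        extra={"sampler": sampler, "effect_target": effect_target,
               "n_snp_probes": n_snp_probes},
    )
    return matrix, design, truth


def simulate_mixture_series(
    panel: ReferencePanel,
    fractions: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_types: Tuple[str, str] = ("buccal", "blood"),
) -> Tuple[BetaMatrix, SimulationTruth]:
    """In-vitro-style dilution series: one sample per mixing fraction."""
    fractions = np.asarray(list(fractions), dtype=float)
    if fractions.size == 0:
        raise ValueError("fraction list must not be empty")
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("fractions must lie in [0,1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    type_a, type_b = cell_types
    prof_a = panel.profile(type_a).to_numpy()
    prof_b = panel.profile(type_b).to_numpy()
    rng = np.random.default_rng(seed)

    sample_ids = [f"mix_{i + 1:02d}" for i in range(fractions.size)]
    base = np.outer(prof_a, fractions) + np.outer(prof_b, 1.0 - fractions)
    noise = rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else 0.0
    beta = pd.DataFrame(
        _clip01(base + noise), index=panel.cpg_ids.copy(), columns=sample_ids
    )
    matrix = BetaMatrix(beta=beta)
    truth = SimulationTruth(
        seed=seed,
        noise_sd=noise_sd,
        proportions={s: float(f) for s, f in zip(sample_ids, fractions)},
    )
    return matrix, truth


def simulate_dbs_reads(
    true_beta: Sequence[float],
    n_reads: int,
    conversion_rate: float = 0.995,
    seed: int = 0,
    amplicon_id: str = "amplicon",
    sample_id: str = "sample",
    cpg_ids: Optional[Sequence[str]] = None,
    missing_rate: float = 0.0,
    allele_freq: Optional[float] = None,
    alleles: Tuple[str, str] = ("A", "B"),
    n_conversion_sites: int = 25,
) -> AmpliconReadSet:
    """Read-level bisulfite calls for one amplicon in one sample.

    Each read draws an independent methylation state per CpG with
    probability ``true_beta``; an unmethylated cytosine escapes
    bisulfite conversion (and therefore reads as methylated) with
    probability 1 − ``conversion_rate``. The per-read conversion-rate
    estimate is a binomial draw over ``n_conversion_sites`` non-CpG
    cytosines, as a read filter would compute it. With ``allele_freq``
    set, each read also carries an allele call (reference-allele
    probability ``allele_freq``) to emulate an amplicon SNP.
    """
    beta = np.asarray(list(true_beta), dtype=float)
    if ((beta < 0) | (beta > 1)).any():
        raise ValueError("true_beta values must lie in [0,1]")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 < conversion_rate <= 1:
        raise ValueError("conversion_rate must be in (0,1]")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0,1)")

    rng = np.random.default_rng(seed)
    n_cpgs = beta.size
    methylated = rng.random((n_reads, n_cpgs)) < beta[None, :]
    conv_fail = rng.random((n_reads, n_cpgs)) < (1.0 - conversion_rate)
    calls = (methylated | (~methylated & conv_fail)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n_reads, n_cpgs)) < missing_rate] = -1

    conv_est = rng.binomial(n_conversion_sites, conversion_rate, size=n_reads) / float(
        n_conversion_sites
    )
    allele_calls = None
    if allele_freq is not None:
        if not 0 <= allele_freq <= 1:
            raise ValueError("allele_freq must be in [0,1]")
        ref = rng.random(n_reads) < allele_freq
        allele_calls = np.where(ref, alleles[0], alleles[1]).astype(object)

    return AmpliconReadSet(
        amplicon_id=amplicon_id,
        sample_id=sample_id,
        calls=calls,
        conversion=conv_est,
        cpg_ids=list(cpg_ids) if cpg_ids is not None else [],
        alleles=allele_calls,
    )


def simulate_sirph_assay(
    true_beta: float,
    total_area: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    element: str = "element",
    cpg_index: int = 1,
    sample_id: str = "sample",
) -> SirphAssay:
    """Primer-extension peak areas for one CpG in one sample.

    AC = β·A + ε₁ and AT = (1−β)·A + ε₂ with independent Gaussian
    noise, both truncated at zero, so that with zero noise
    MI = AC/(AC+AT) equals ``true_beta`` exactly.
    """
    if not 0 <= true_beta <= 1:
        raise ValueError("true_beta must lie in [0,1]")
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 else np.zeros(2)
    area_c = max(0.0, true_beta * total_area + noise[0])
    area_t = max(0.0, (1.0 - true_beta) * total_area + noise[1])
    return SirphAssay(
        element=element,
        cpg_index=cpg_index,
        sample_id=sample_id,
        area_c=area_c,
        area_t=area_t,
    )
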