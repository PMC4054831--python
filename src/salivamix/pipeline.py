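"""End-to-end study pipeline over synthetic (or user-supplied) data.

``run_study`` sequences the full analysis: simulate a two-cell-type
reference panel and a paired cohort → detection/chromosome probe
filtering → discriminative-marker screening and model-based marker
selection → composition-outlier exclusion → single- and multi-marker
adjustment → paired exact-Wilcoxon association on unadjusted and both
adjusted variants → MVP intersection → deep-bisulfite-sequencing
simulation and cross-platform concordance on a subset of candidate
loci → SIRPH repetitive-element stage. Every stage writes its
artifacts and counts into the run directory; given the same config and
seed the whole run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import adjust as adj
from . import association as assoc
from . import dbs as dbsmod
from . import io as mio
from . import simulate as sim
from . import sirph as sirphmod
from .types import TwinDesign

__all__ = ["PipelineConfig", "load_config", "run_study", "generate_report", "ConfigError"]

log = logging.getLogger("salivamix")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; every stochastic step derives its
    stream from ``seed``."""

    seed: int = 0
    out_dir: str = "salivamix_run"
    # simulation
    n_cpgs: int = 2000
    n_discriminative: int = 200
    separation: float = 0.5
    n_pairs: int = 16
    noise_sd: float = 0.02
    pair_corr: float = 0.5
    heavy_offset: float = 0.0
    effects: list = field(default_factory=list)  # [cpg_id or int offset, delta]
    n_snp_probes: int = 64
    detection_fail_rate: float = 0.005
    # filtering
    detection_threshold: Optional[float] = 0.001
    drop_chromosomes: list = field(default_factory=lambda: ["Y"])
    # adjustment
    k_candidates: int = 10
    affected_p: float = 0.01
    outlier_rule: str = "auto"  # auto | none
    n_mad: float = 3.0
    n_multi_markers: int = 3
    # association
    p_threshold: float = 0.01
    d_threshold: float = 0.05
    test_mode: str = "auto"
    # DBS
    dbs_n_loci: int = 8
    dbs_n_reads: int = 1000
    dbs_conversion: float = 0.995
    dbs_min_conversion: float = 0.95
    dbs_max_missing: float = 0.2
    # SIRPH
    sirph_total_area: float = 1000.0
    sirph_noise_sd: float = 20.0

    def __post_init__(self) -> None:
        checks = [
            (self.n_cpgs > 0, "n_cpgs must be positive"),
            (0 <= self.n_discriminative <= self.n_cpgs, "n_discriminative out of range"),
            (0 < self.separation <= 1, "separation must be in (0,1]"),
            (self.n_pairs >= 2, "need at least 2 pairs"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (0 <= self.pair_corr <= 1, "pair_corr must be in [0,1]"),
            (0 < self.p_threshold <= 1, "p_threshold must be in (0,1]"),
            (0 <= self.d_threshold < 1, "d_threshold must be in [0,1)"),
            (self.outlier_rule in ("auto", "none"), "outlier_rule must be auto|none"),
            (self.test_mode in ("auto", "exact", "approx"), "bad test_mode"),
            (
                self.detection_threshold is None or 0 < self.detection_threshold <= 1,
                "detection_threshold must be in (0,1]",
            ),
            (0 < self.dbs_conversion <= 1, "dbs_conversion must be in (0,1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


def load_config(path) -> PipelineConfig:
    """Load YAML/JSON config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _child_seeds(seed: int, n: int) -> list:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_study(config: PipelineConfig) -> dict:
    """Execute the full study; returns (and writes) the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"config": asdict(config)}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    try:
        seeds = _child_seeds(config.seed, 6)

        # --- stage 1: simulation -----------------------------------------
        log.info("stage simulate: panel %d CpGs (%d discriminative)",
                 config.n_cpgs, config.n_discriminative)
        panel, panel_truth = sim.simulate_reference_panel(
            config.n_cpgs, config.n_discriminative, config.separation, seed=seeds[0]
        )
        effect_spec = []
        for cpg, delta in config.effects:
            cpg_id = panel.cpg_ids[int(cpg)] if isinstance(cpg, int) else cpg
            effect_spec.append((cpg_id, float(delta)))
        matrix, design, cohort_truth = sim.simulate_cohort(
            panel,
            config.n_pairs,
            proportion_sampler={
                "pair_corr": config.pair_corr,
                "heavy_offset": config.heavy_offset,
            },
            effect_spec=effect_spec,
            noise_sd=config.noise_sd,
            seed=seeds[1],
            detection_fail_rate=config.detection_fail_rate,
            n_snp_probes=config.n_snp_probes,
        )
        mio.save_beta_table(matrix, out / "beta_raw.tsv")
        mio.save_reference_panel(panel, out / "reference_panel.tsv")
        mio.save_design(design, out / "design.tsv")
        panel_truth.to_json(out / "truth_panel.json")
        cohort_truth.to_json(out / "truth_cohort.json")

        # --- stage 2: probe filtering ------------------------------------
        filt = mio.filter_probes(
            matrix, config.detection_threshold, config.drop_chromosomes
        )
        report["filter"] = filt.report()
        log.info("stage filter: %s", report["filter"])
        matrix = filt.matrix

        # --- stage 3: marker screening and selection ---------------------
        matrix_panel, panel_common = mio.intersect_with_panel(matrix, panel)
        top = adj.screen_discriminative(panel_common, "buccal", "blood",
                                        k=config.k_candidates)
        candidates = [c for c in top.index if c in matrix.cpg_ids]
        marker, scores = adj.select_marker(matrix, candidates,
                                           affected_p=config.affected_p)
        report["marker"] = {
            "candidates": list(top.index),
            "selected": marker,
            "scores": scores,
        }
        log.info("stage marker: selected %s (score %d)", marker, scores[marker])

        # --- stage 4: outlier exclusion ----------------------------------
        excluded = adj.detect_outlier_samples(
            matrix, marker, n_mad=config.n_mad, design=design,
            enabled=config.outlier_rule == "auto",
        )
        design_used = design
        if excluded:
            dropped_pairs = sorted({design.pair_of(s) for s in excluded})
            design_used = design.drop_pairs(dropped_pairs)
            log.info("stage outliers: excluded samples %s (pairs %s)",
                     excluded, dropped_pairs)
        report["outliers"] = {"excluded_samples": excluded}

        # --- stage 5: adjustment (single- and multi-marker) --------------
        fit_single = adj.fit_marker_models(
            matrix, marker, exclude_samples=excluded, affected_p=config.affected_p
        )
        adjusted_single = adj.adjust_for_composition(matrix, fit_single)
        multi_markers = [marker] + [
            c for c in candidates if c != marker
        ][: max(0, config.n_multi_markers - 1)]
        fit_multi = adj.fit_marker_models(
            matrix, multi_markers, exclude_samples=excluded,
            affected_p=config.affected_p,
        )
        adjusted_multi = adj.adjust_for_composition(matrix, fit_multi)
        report["adjustment"] = {
            "single": {
                "markers": adjusted_single.markers,
                "n_adjusted": adjusted_single.n_adjusted,
                "n_unchanged": adjusted_single.n_unchanged,
                "n_truncated": adjusted_single.n_truncated,
            },
            "multi": {
                "markers": adjusted_multi.markers,
                "n_adjusted": adjusted_multi.n_adjusted,
                "n_unchanged": adjusted_multi.n_unchanged,
                "n_truncated": adjusted_multi.n_truncated,
            },
        }
        log.info("stage adjust: %s", report["adjustment"])
        mio.save_beta_table(adjusted_single.matrix, out / "beta_adjusted.tsv")
        with open(out / "adjustment.json", "w") as fh:
            json.dump(report["adjustment"], fh, indent=1)

        # --- stage 6: paired association + MVP calling -------------------
        unadj = matrix.subset_samples(design_used.sample_ids)
        tables = {
            "unadjusted": assoc.paired_ewas(
                unadj, design_used, mode=config.test_mode,
                p_threshold=config.p_threshold, d_threshold=config.d_threshold,
                label="unadjusted",
            ),
            "adjusted_single": assoc.paired_ewas(
                adjusted_single.matrix, design_used, mode=config.test_mode,
                p_threshold=config.p_threshold, d_threshold=config.d_threshold,
                label="adjusted_single",
            ),
            "adjusted_multi": assoc.paired_ewas(
                adjusted_multi.matrix, design_used, mode=config.test_mode,
                p_threshold=config.p_threshold, d_threshold=config.d_threshold,
                label="adjusted_multi",
            ),
        }
        for name, table in tables.items():
            assoc.volcano_export(table, out / f"volcano_{name}.tsv")
        mvps, mvp_counts = assoc.call_mvps(
            [tables["adjusted_single"], tables["adjusted_multi"]],
            p_threshold=config.p_threshold, d_threshold=config.d_threshold,
        )
        report["association"] = {
            "mvp_count_per_table": {
                name: int(t.table["mvp"].sum()) for name, t in tables.items()
            },
            "intersection": mvp_counts,
            "mvps": list(mvps),
        }
        log.info("stage associate: %s", report["association"]["mvp_count_per_table"])

        # --- stage 7: DBS validation -------------------------------------
        loci = list(mvps[: config.dbs_n_loci])
        if len(loci) < config.dbs_n_loci:
            # top up with the most significant adjusted CpGs
            ranked = tables["adjusted_single"].table.sort_values("pvalue").index
            loci += [c for c in ranked if c not in loci][: config.dbs_n_loci - len(loci)]
        dbs_rng = np.random.default_rng(seeds[2])
        readsets = []
        dbs_frames = {}
        for cpg in loci:
            per_sample = {}
            for s in design_used.sample_ids:
                true_b = float(matrix.beta.loc[cpg, s])
                rs = sim.simulate_dbs_reads(
                    [true_b], config.dbs_n_reads,
                    conversion_rate=config.dbs_conversion,
                    seed=int(dbs_rng.integers(2**31)),
                    amplicon_id=cpg, sample_id=s, cpg_ids=[cpg],
                )
                rs, _ = dbsmod.filter_reads(
                    rs, config.dbs_min_conversion, config.dbs_max_missing
                )
                readsets.append(rs)
                per_sample[s] = dbsmod.amplicon_methylation(rs)["fraction"].iloc[0]
            dbs_frames[cpg] = per_sample
        dbs_values = pd.DataFrame(dbs_frames).T  # CpG × sample
        dbsmod.write_reads_tsv(readsets, out / "dbs_reads.tsv")
        array_values = matrix.beta.loc[loci, design_used.sample_ids]
        r_sample, median_r = dbsmod.cross_platform_concordance(
            array_values, dbs_values, axis="per-sample"
        )
        retest = {
            cpg: assoc.wilcoxon_signed_rank_paired(
                dbs_values.loc[cpg, design_used.heavy],
                dbs_values.loc[cpg, design_used.light],
                mode=config.test_mode,
            )
            for cpg in loci
        }
        report["dbs"] = {
            "loci": loci,
            "median_sample_concordance": median_r,
            "retest_pvalues": retest,
            "n_confirmed": int(sum(p < config.p_threshold for p in retest.values())),
        }
        log.info("stage dbs: median concordance %.3f", median_r)

        # --- stage 8: SIRPH repetitive elements --------------------------
        sirph_rng = np.random.default_rng(seeds[3])
        marker_values = matrix.beta.loc[marker, design_used.sample_ids]
        proportions = pd.Series(cohort_truth.proportions)[design_used.sample_ids]
        assays = []
        element_levels = {("HERVK", 1): 0.61, ("HERVK", 2): 0.36,
                          ("LINE1", 1): 0.58, ("LINE1", 2): 0.37}
        for (element, cpg_index), level in element_levels.items():
            # repetitive-element methylation is lower in buccal epithelium
            slope = -0.1 if cpg_index == 1 else 0.0
            for s in design_used.sample_ids:
                true_mi = float(np.clip(level + slope * (proportions[s] - 0.5), 0, 1))
                assays.append(
                    sim.simulate_sirph_assay(
                        true_mi, total_area=config.sirph_total_area,
                        noise_sd=config.sirph_noise_sd,
                        seed=int(sirph_rng.integers(2**31)),
                        element=element, cpg_index=cpg_index, sample_id=s,
                    )
                )
        sirph_frame = sirphmod.assays_to_frame(assays)
        sirphmod.write_sirph_tsv(sirph_frame, out / "sirph_areas.tsv")
        sirph_unadj = sirphmod.sirph_association(sirph_frame, design_used)
        sirph_adj = sirphmod.sirph_association(
            sirph_frame, design_used, marker_values=marker_values,
            affected_p=config.affected_p,
        )
        report["sirph"] = {
            "unadjusted": sirph_unadj.to_dict("records"),
            "adjusted": sirph_adj.to_dict("records"),
        }
        log.info("stage sirph: done")

        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        generate_report(out)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def generate_report(run_dir) -> str:
    """Render a human-readable stage-count summary from a finished run."""
    run_dir = Path(run_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"incomplete run: missing {report_path}")
    with open(report_path) as fh:
        report = json.load(fh)

    lines = ["salivamix study report", "=" * 23, ""]
    filt = report.get("filter", {})
    lines += [
        f"CpGs input:                {filt.get('n_input')}",
        f"  removed (detection P):   {filt.get('n_detection_removed')}",
        f"  removed (chromosome):    {filt.get('n_chromosome_removed')}",
        f"  kept:                    {filt.get('n_kept')}",
        "",
    ]
    marker = report.get("marker", {})
    lines += [
        f"marker candidates:         {len(marker.get('candidates', []))}",
        f"selected marker:           {marker.get('selected')}",
        f"excluded samples:          {report.get('outliers', {}).get('excluded_samples')}",
        "",
    ]
    adj_rep = report.get("adjustment", {}).get("single", {})
    lines += [
        f"CpGs adjusted:             {adj_rep.get('n_adjusted')}",
        f"CpGs unchanged:            {adj_rep.get('n_unchanged')}",
        f"  (total:                  "
        f"{(adj_rep.get('n_adjusted') or 0) + (adj_rep.get('n_unchanged') or 0)})",
        "",
    ]
    assoc_rep = report.get("association", {})
    for name, count in assoc_rep.get("mvp_count_per_table", {}).items():
        lines.append(f"MVPs ({name}):".ljust(27) + str(count))
    inter = assoc_rep.get("intersection", {})
    lines += [
        f"P-intersection count:      {inter.get('p_intersection')}",
        f"final MVPs:                {inter.get('mvps')}",
        "",
    ]
    dbs_rep = report.get("dbs", {})
    lines += [
        f"DBS loci validated:        {len(dbs_rep.get('loci', []))}",
        f"median concordance r:      {dbs_rep.get('median_sample_concordance')}",
        f"DBS-confirmed loci:        {dbs_rep.get('n_confirmed')}",
    ]
    text = "\n".join(lines) + "\n"
    with open(run_dir / "report.txt", "w") as fh:
        fh.write(text)
    return text
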