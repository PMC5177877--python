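"""End-to-end orchestration: simulate -> scan -> build panel -> validate.

Stages communicate only through files in the documented formats, so each is
independently runnable and replaceable; a manifest lists every output with
a content hash, and rerunning the same config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import fst, haplotyping, markers, sim, structure
from .classify import assignments_table, blind_trial
from .io import (
    read_phased_vcf,
    write_frequency_workbook,
    write_panel_bed,
    write_panel_table,
)

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValueError("config must set an explicit top-level seed")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _tier_structure(cfg: dict) -> fst.TierStructure:
    raw = cfg.get("tier_structure")
    if raw is None:
        return [(t, list(m)) for t, m in sim.DEFAULT_TIERS]
    return [(t, list(m)) for t, m in raw]


def run_full_pipeline(config: dict[str, Any] | str | Path, outdir: str | Path) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the manifest.

    An empty panel (e.g. under starvation-level screening thresholds) is not
    an error: validation stages are skipped with a notice in the manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    tier_structure = _tier_structure(config)
    manifest: dict[str, Any] = {"seed": seed, "stages": {}, "files": {}, "notes": []}

    def record(stage: str, *paths: Path, **info) -> None:
        manifest["stages"][stage] = {"outputs": [p.name for p in paths], **info}
        for p in paths:
            manifest["files"][p.name] = _sha256(p)

    # --- simulate -----------------------------------------------------------
    sim_cfg = sim.SimConfig(seed=seed, tier_structure=tier_structure, **config.get("simulate", {}))
    cohort = sim.simulate_tiered_cohort(sim_cfg)
    vcf_path = outdir / "cohort.vcf"
    map_path = outdir / "cohort.samples.tsv"
    sim.emit_vcf(cohort, vcf_path, map_path)
    record("simulate", vcf_path, map_path, n_loci=cohort.n_loci, n_samples=cohort.n_samples)
    logger.info("simulate: %d loci, %d samples", cohort.n_loci, cohort.n_samples)

    # --- scan ---------------------------------------------------------------
    cohort = read_phased_vcf(vcf_path, map_path)
    scan_cfg = config.get("scan", {})
    results = fst.pairwise_theta_matrices(cohort, tier_structure)
    passing = fst.screen_loci(
        results,
        t_continental=scan_cfg.get("t_continental", fst.DEFAULT_T_CONTINENTAL),
        t_sub=scan_cfg.get("t_sub", fst.DEFAULT_T_SUB),
    )
    screen_path = outdir / "theta_screen.tsv"
    fst.screen_table(results).to_csv(screen_path, sep="\t", index=False)
    record("scan", screen_path, n_loci=len(results), n_passing=len(passing))
    logger.info("scan: %d of %d loci pass", len(passing), len(results))

    # --- build panel --------------------------------------------------------
    bp_cfg = config.get("build_panel", {})
    panel = markers.build_panel(
        cohort,
        results,
        max_gap=bp_cfg.get("max_gap", markers.DEFAULT_MAX_GAP),
        max_amplicon=bp_cfg.get("max_amplicon", markers.DEFAULT_MAX_AMPLICON),
        flank_padding=bp_cfg.get("flank_padding", markers.DEFAULT_FLANK_PADDING),
    )
    panel_path = outdir / "panel.tsv"
    bed_path = outdir / "panel.bed"
    size_path = outdir / "size_maps.json"
    write_panel_table(panel, panel_path)
    write_panel_bed(panel, bed_path)
    with open(size_path, "w") as fh:
        json.dump(
            {
                m.marker_id: {
                    "base_amplicon_size": m.base_amplicon_size,
                    "sizes": {"".join(map(str, h)): s for h, s in sorted(m.size_map.items())},
                }
                for m in panel
            },
            fh, indent=1, sort_keys=True,
        )
    record("build_panel", panel_path, bed_path, size_path, n_markers=len(panel))
    logger.info("build_panel: %d markers", len(panel))

    if len(panel) == 0:
        manifest["notes"].append("empty panel: validation stages skipped")
        _write_manifest(manifest, outdir)
        return manifest

    # --- frequencies --------------------------------------------------------
    genotypes = haplotyping.marker_genotypes_from_phase(cohort, panel, key="size")
    labels = dict(zip(cohort.sample_ids, cohort.populations))
    freq = haplotyping.count_haplotype_frequencies(genotypes, labels)
    geno_path = outdir / "genotypes.tsv"
    haplotyping.write_genotype_table(genotypes, geno_path)
    freq_dir = outdir / "frequencies"
    write_frequency_workbook(freq, freq_dir)
    freq_files = sorted(freq_dir.glob("marker_*.csv"))
    record("frequencies", geno_path, *freq_files, n_markers=len(freq))

    # --- validation cohort --------------------------------------------------
    val_cfg = config.get("validate", {})
    val_pops = val_cfg.get("populations")
    if val_pops is None:
        multi = [m for _, m in tier_structure if len(m) > 1]
        val_pops = multi[0][:2] if multi else list(dict.fromkeys(cohort.populations))[:2]
    val_samples = [s for s, p in labels.items() if p in val_pops]
    val_geno = genotypes[genotypes["sample_id"].isin(val_samples)]
    val_labels = {s: labels[s] for s in val_samples}
    manifest["stages"]["validate"] = {"populations": val_pops, "n_samples": len(val_samples)}

    # --- blind trials -------------------------------------------------------
    accuracy, trial_results = blind_trial(
        val_geno, val_labels,
        n_holdout=val_cfg.get("n_holdout", 10),
        seed=seed,
        alpha=val_cfg.get("alpha", 1.0),
    )
    assign_path = outdir / "assignments.tsv"
    assignments_table(trial_results).to_csv(assign_path, sep="\t", index=False)
    record("blind_trial", assign_path, accuracy=accuracy)
    logger.info("blind_trial: accuracy %.2f", accuracy)

    # --- structure + delta-K ------------------------------------------------
    runs, selection = structure.structure_scan(
        val_geno,
        k_min=val_cfg.get("k_min", 1),
        k_max=val_cfg.get("k_max", 4),
        replicates=val_cfg.get("replicates", 3),
        burn_in=val_cfg.get("burn_in", 500),
        kept=val_cfg.get("kept", 500),
        seed=seed,
    )
    dk_path = outdir / "delta_k.tsv"
    selection.table().to_csv(dk_path, sep="\t", index=False)
    q_path = outdir / "q_matrix.tsv"
    opt_runs = runs.get(max(selection.optimum, 2), runs[max(runs)])
    q = structure.align_replicates(opt_runs)
    pd.DataFrame(
        q, index=opt_runs[0].sample_ids,
        columns=[f"cluster_{i + 1}" for i in range(q.shape[1])],
    ).rename_axis("sample_id").reset_index().to_csv(q_path, sep="\t", index=False, float_format="%.6f")
    record("structure", dk_path, q_path, optimum_K=selection.optimum, method=selection.method)
    logger.info("structure: optimum K = %d (%s)", selection.optimum, selection.method)

    # --- PCA ----------------------------------------------------------------
    ids, coords, ev = structure.pca_genotypes(val_geno)
    pca_path = outdir / "pca.tsv"
    n_show = min(5, coords.shape[1])
    df = pd.DataFrame(coords[:, :n_show], columns=[f"PC{i + 1}" for i in range(n_show)])
    df.insert(0, "sample_id", ids)
    df.insert(1, "population", [val_labels[s] for s in ids])
    df.to_csv(pca_path, sep="\t", index=False, float_format="%.6f")
    record("pca", pca_path, explained_variance=[round(float(v), 6) for v in ev[:n_show]])

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict[str, Any], outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
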