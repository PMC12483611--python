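"""End-to-end orchestration: simulate -> QC/demux -> repertoire -> proportions
-> serology -> association, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import group_compare, ols_fit
from .config import PipelineConfig
from .proportions import proportion_test
from .qc_demux import demux_hashtags, filter_cells
from .repertoire import (
    assign_clones,
    clone_size_bins,
    diversity_profile,
    filter_contigs,
    gene_usage,
    isotype_fractions,
    mutation_table,
)
from .reference import reference_gene_frequencies
from .serology import fit_ec50_table, score_avidity_table
from .synthetic import gen_hto_qc, gen_repertoire, gen_serology_cohort, gen_subject_table

log = logging.getLogger("gcoutput")

STAGES = ("simulate", "qc", "repertoire", "proportions", "serology", "association")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _dose_of(timepoint: str) -> int | None:
    m = re.search(r"(\d+)", str(timepoint))
    return int(m.group(1)) if m else None


def subject_summary(records: pd.DataFrame, shm: pd.DataFrame,
                    avidity: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """One row per subject x timepoint: mean heavy-chain SHM frequency + TRAI."""
    heavy = shm[shm["chain"] == "heavy"] if "chain" in shm.columns else shm
    mean_shm = (heavy.groupby(["subject", "timepoint"])["frequency"]
                .mean().rename("mean_shm").reset_index())
    mean_shm["dose"] = mean_shm["timepoint"].map(_dose_of)
    out = mean_shm.merge(avidity[["subject", "dose", "trai"]],
                         on=["subject", "dose"], how="left")
    return out.merge(subjects, on="subject", how="left")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage in dependency order, writing all intermediate tables.

    Returns the manifest (also written to ``manifest.json``).  Identical
    configs reproduce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.cohort.seed,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    def record_stage(name: str, **counts):
        manifest["stages"][name] = counts
        log.info("stage %s: %s", name, counts)

    def save(df: pd.DataFrame, name: str, sep: str = ","):
        df.to_csv(out / name, sep=sep, index=False)

    stage = "simulate"
    try:
        records = gen_repertoire(config.cohort, config.repertoire)
        plates = gen_serology_cohort(config.cohort, config.serology)
        subjects = gen_subject_table(config.cohort)
        qc_table, hto = gen_hto_qc(config.cohort, config.qc_cells,
                                   config.doublet_rate, config.cohort.seed)
        save(records, "repertoire.tsv", sep="\t")
        save(plates, "plates.csv")
        save(subjects, "subjects.csv")
        save(qc_table, "cell_qc.csv")
        hto.reset_index().to_csv(out / "hto_counts.csv", index=False)
        record_stage(stage, records=len(records), plate_rows=len(plates),
                     qc_cells=len(qc_table))

        stage = "qc"
        filt = filter_cells(qc_table, config.qc)
        demux = demux_hashtags(hto, margin=config.qc.hto_margin)
        save(filt.retained, "qc_retained.csv")
        pd.DataFrame([filt.tally]).to_csv(out / "qc_tally.csv", index=False)
        demux.reset_index().to_csv(out / "demux.csv", index=False)
        record_stage(stage, retained=len(filt.retained),
                     demux_assigned=int((demux["assignment"] != "excluded").sum()))

        stage = "repertoire"
        filtered, contig_tally = filter_contigs(records)
        heavy = filtered[filtered["chain"] == "heavy"]
        clones = assign_clones(heavy, config.clone_threshold)
        shm = mutation_table(filtered, config.repertoire.region_layout)
        save(clones.assignments, "clones.csv")
        save(shm, "shm.csv")
        div_frames = []
        for group in config.cohort.groups:
            sub = clones.assignments[clones.assignments["group"] == group]
            if sub.empty:
                continue
            prof = diversity_profile(
                sub.drop_duplicates("cell_id")["clone_id"], config.q_grid,
                n_boot=config.n_boot, seed=config.cohort.seed, label=group)
            div_frames.append(prof.to_frame())
        save(pd.concat(div_frames, ignore_index=True), "diversity.csv")
        usage, pairs = gene_usage(filtered, reference_gene_frequencies())
        save(usage, "gene_usage.csv")
        save(pairs, "gene_pairs.csv")
        save(clone_size_bins(clones), "clone_bins.csv")
        save(isotype_fractions(heavy, group_by=("group",)), "isotypes.csv")
        record_stage(stage, **contig_tally, clones=int(clones.sizes().size))

        stage = "proportions"
        cell_meta = heavy.drop_duplicates("cell_id")[
            ["cell_id", "subject", "group", "subset"]
        ].rename(columns={"subset": "cluster"})
        prop_frames = []
        for ga, gb in itertools.combinations(config.cohort.groups, 2):
            res = proportion_test(cell_meta, ga, gb, n_perm=config.n_perm,
                                  n_boot=config.n_boot, seed=config.cohort.seed)
            res.insert(0, "comparison", f"{gb} vs {ga}")
            prop_frames.append(res)
        save(pd.concat(prop_frames, ignore_index=True), "proportion_tests.csv")
        record_stage(stage, comparisons=len(prop_frames))

        stage = "serology"
        avidity = score_avidity_table(plates)
        ec50 = fit_ec50_table(plates)
        save(avidity, "avidity.csv")
        save(ec50, "ec50.csv")
        record_stage(stage, avidity_samples=len(avidity), ec50_fits=len(ec50))

        stage = "association"
        summary = subject_summary(filtered, shm, avidity, subjects)
        save(summary, "subject_summary.csv")
        fit = ols_fit(summary.dropna(subset=["trai"]), "trai",
                      ["mean_shm", "age", "sex", "bmi", "vaccine"])
        save(fit, "association_trai_shm.csv")
        shm_by_group = {
            g: shm[(shm["group"] == g) & (shm["chain"] == "heavy")]["frequency"].to_numpy()
            for g in config.cohort.groups
        }
        cmp_res = group_compare(shm_by_group)
        pd.DataFrame([
            {"test": cmp_res.test, "statistic": cmp_res.statistic, "p": cmp_res.p_value}
        ]).to_csv(out / "shm_group_test.csv", index=False)
        if cmp_res.pairwise is not None:
            save(cmp_res.pairwise, "shm_dunn.csv")
        record_stage(stage, summary_rows=len(summary))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
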