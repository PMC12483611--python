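"""BCR repertoire statistics: clones, SHM, diversity, gene usage, isotypes.

Clonal assignment partitions heavy chains by (V gene, J gene, junction
length) and then single-linkage clusters junctions on normalized Hamming
distance.  SHM is counted per IMGT-like region against the germline
alignment, with replacement/silent calls made in germline codon context.
Diversity is the Hill family D(q) with a cell-bootstrap confidence band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .reference import DEFAULT_REGION_LAYOUT, REGION_NAMES

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

SWITCHED_ISOTYPES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1")

#: Clone-size bins; upper bounds inclusive.
CLONE_BINS = (("rare", 1, 1), ("small", 2, 2), ("medium", 3, 5),
              ("large", 6, 10), ("larger", 11, np.inf))


class RecordError(ValueError):
    """A malformed or missing-field BCR record."""


def strip_allele(call: str) -> str:
    """Gene-level name: text before the first '*'."""
    return call.split("*")[0]


def filter_contigs(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop nonproductive records and cells without exactly one heavy chain.

    Returns the retained records plus a tally of removals per rule.
    """
    df = records.copy()
    n0 = len(df)
    if "productive" in df.columns:
        df = df[df["productive"].astype(bool)]
    n_nonproductive = n0 - len(df)
    heavy_per_cell = (
        df[df["chain"] == "heavy"].groupby("cell_id")["sequence_id"].size()
    )
    good_cells = set(heavy_per_cell[heavy_per_cell == 1].index)
    multi = set(heavy_per_cell[heavy_per_cell > 1].index)
    before = len(df)
    df = df[df["cell_id"].isin(good_cells)]
    tally = {
        "nonproductive": int(n_nonproductive),
        "cells_multiple_heavy": len(multi),
        "records_removed_heavy_rule": int(before - len(df)),
        "retained_records": int(len(df)),
    }
    return df.reset_index(drop=True), tally


# ---------------------------------------------------------------------------
# clonal assignment
# ---------------------------------------------------------------------------

def normalized_hamming(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("junctions differ in length")
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    return float((arr_a != arr_b).mean())


@dataclass
class CloneSet:
    """A clonal partition of cells with the metadata that defined it."""

    assignments: pd.DataFrame  # sequence_id, cell_id, clone_id + carry-through labels
    threshold: float
    clone_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def sizes(self) -> pd.Series:
        return self.assignments.groupby("clone_id")["cell_id"].nunique()


def assign_clones(records: pd.DataFrame, distance_threshold: float = 0.15) -> CloneSet:
    """Partition heavy chains into clones.

    Cells are first grouped by allele-stripped V gene, J gene, and junction
    length; within each group, junctions are single-linkage clustered on
    normalized Hamming distance and the dendrogram is cut at
    ``distance_threshold``.  Clone ids are stable under input reordering
    (groups and members ordered lexicographically by sequence_id).
    """
    heavy = records[records["chain"] == "heavy"] if "chain" in records else records
    missing = heavy["v_call"].isna() | (heavy["v_call"] == "") \
        | heavy["j_call"].isna() | (heavy["j_call"] == "")
    if missing.any():
        bad = heavy.loc[missing, "sequence_id"].tolist()
        raise RecordError(f"records missing v_call/j_call: {bad[:5]}")
    if (heavy["junction"].fillna("") == "").any():
        raise RecordError("records with empty junction")

    heavy = heavy.sort_values("sequence_id", kind="mergesort").reset_index(drop=True)
    v_gene = heavy["v_call"].map(strip_allele)
    j_gene = heavy["j_call"].map(strip_allele)
    jlen = heavy["junction"].str.len()

    out_rows = []
    clone_meta = []
    clone_no = 0
    keys = pd.DataFrame({"v": v_gene, "j": j_gene, "l": jlen})
    for (v, j, length), idx in sorted(keys.groupby(["v", "j", "l"]).groups.items()):
        sub = heavy.loc[idx]
        junctions = sub["junction"].tolist()
        n = len(junctions)
        if n == 1:
            labels = np.array([1])
        else:
            mat = np.frombuffer("".join(junctions).encode(), dtype="S1")
            mat = mat.reshape(n, int(length))
            dist = pdist(mat.view(np.uint8), metric="hamming")
            labels = fcluster(linkage(dist, method="single"),
                              t=distance_threshold, criterion="distance")
        # deterministic clone numbering: by first (lexicographic) member
        order = {}
        for seq_id, lab in zip(sub["sequence_id"], labels):
            if lab not in order:
                order[lab] = seq_id
        for lab in sorted(order, key=lambda k: order[k]):
            clone_no += 1
            clone_meta.append({
                "clone_id": f"C{clone_no:05d}", "v_gene": v, "j_gene": j,
                "junction_length": int(length),
            })
        relabel = {lab: f"C{i:05d}" for i, lab in enumerate(
            sorted(order, key=lambda k: order[k]), start=clone_no - len(order) + 1)}
        for row, lab in zip(sub.itertuples(index=False), labels):
            out_rows.append({
                "sequence_id": row.sequence_id,
                "cell_id": row.cell_id,
                "clone_id": relabel[lab],
                **{k: getattr(row, k) for k in
                   ("subject", "group", "timepoint", "subset")
                   if hasattr(row, k)},
            })
    assignments = pd.DataFrame(out_rows).sort_values("sequence_id").reset_index(drop=True)
    return CloneSet(assignments=assignments, threshold=distance_threshold,
                    clone_meta=pd.DataFrame(clone_meta))


# ---------------------------------------------------------------------------
# somatic hypermutation
# ---------------------------------------------------------------------------

@dataclass
class MutationProfile:
    """Replacement/silent mutation counts per region for one chain."""

    sequence_id: str
    r_counts: dict
    s_counts: dict
    denominator: int
    frequency: float

    @property
    def total(self) -> int:
        return sum(self.r_counts.values()) + sum(self.s_counts.values())


def _translate(codon: str) -> str | None:
    return _CODON_TABLE.get(codon)


def mutation_profile(record: Mapping, region_layout: Mapping[str, tuple[int, int]] | None = None,
                     include_cdr3: bool = True) -> MutationProfile:
    """Count R/S mutations per region for one observed/germline alignment pair.

    A position contributes a mutation when both bases are unambiguous
    A/C/G/T and differ; it is Replacement when translating the observed base
    in germline codon context changes the amino acid, else Silent.  The
    denominator counts positions where both bases are unambiguous A/C/G/T.
    """
    obs = record["sequence_alignment"]
    germ = record["germline_alignment"]
    if len(obs) != len(germ):
        raise RecordError(
            f"alignment length mismatch for {record.get('sequence_id', '?')}: "
            f"{len(obs)} vs {len(germ)}"
        )
    layout = dict(region_layout or DEFAULT_REGION_LAYOUT)
    if not include_cdr3:
        layout.pop("CDR3")

    obs_a = np.frombuffer(obs.encode(), dtype="S1")
    germ_a = np.frombuffer(germ.encode(), dtype="S1")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    valid = np.isin(obs_a, acgt) & np.isin(germ_a, acgt)
    region_mask = np.zeros(len(obs), dtype=bool)
    for name, (lo, hi) in layout.items():
        region_mask[lo:min(hi, len(obs))] = True
    comparable = valid & region_mask
    denominator = int(comparable.sum())
    if denominator == 0:
        raise RecordError("zero comparable positions")

    r_counts = {name: 0 for name in layout}
    s_counts = {name: 0 for name in layout}
    mismatch = comparable & (obs_a != germ_a)
    for pos in np.flatnonzero(mismatch):
        pos = int(pos)
        region = next(name for name, (lo, hi) in layout.items() if lo <= pos < hi)
        c0 = 3 * (pos // 3)
        germ_codon = germ[c0:c0 + 3]
        obs_codon = germ_codon[: pos - c0] + obs[pos] + germ_codon[pos - c0 + 1:]
        aa_g = _translate(germ_codon) if len(germ_codon) == 3 else None
        aa_o = _translate(obs_codon) if len(obs_codon) == 3 else None
        if aa_g is None or aa_o is None:
            # undetermined codon context (gap/N/truncated codon): count as R
            r_counts[region] += 1
        elif aa_g == aa_o:
            s_counts[region] += 1
        else:
            r_counts[region] += 1

    total = int(mismatch.sum())
    return MutationProfile(
        sequence_id=str(record.get("sequence_id", "")),
        r_counts=r_counts,
        s_counts=s_counts,
        denominator=denominator,
        frequency=total / denominator,
    )


def mutation_table(records: pd.DataFrame,
                   region_layout: Mapping[str, tuple[int, int]] | None = None,
                   include_cdr3: bool = True) -> pd.DataFrame:
    """Per-record SHM summary: R/S per region, denominator, frequency."""
    rows = []
    for rec in records.to_dict("records"):
        prof = mutation_profile(rec, region_layout, include_cdr3)
        row = {
            "sequence_id": prof.sequence_id,
            **{k: rec[k] for k in ("cell_id", "subject", "group", "timepoint",
                                   "subset", "chain") if k in rec},
            "denominator": prof.denominator,
            "frequency": prof.frequency,
            "total_mutations": prof.total,
        }
        for name in prof.r_counts:
            row[f"R_{name}"] = prof.r_counts[name]
            row[f"S_{name}"] = prof.s_counts[name]
        row["R_total"] = sum(prof.r_counts.values())
        row["S_total"] = sum(prof.s_counts.values())
        cdr_r = sum(prof.r_counts.get(n, 0) for n in ("CDR1", "CDR2", "CDR3"))
        row["R_CDR_frequency"] = cdr_r / prof.denominator
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def hill_diversity(proportions: np.ndarray, q: float) -> float:
    """Hill number D(q); D(1) is the exponential of Shannon entropy."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("empty distribution")
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


@dataclass
class DiversityProfile:
    label: str
    q_grid: np.ndarray
    d: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.label, "q": self.q_grid, "D": self.d,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def diversity_profile(clones: CloneSet | pd.Series, q_grid: Sequence[float],
                      n_boot: int = 200, seed: int = 0,
                      label: str = "") -> DiversityProfile:
    """Hill diversity profile over ``q_grid`` with a bootstrap percentile band.

    Accepts a CloneSet (cells resampled with replacement) or a precomputed
    per-cell clone-label Series.
    """
    if isinstance(clones, CloneSet):
        cell_clones = clones.assignments.drop_duplicates("cell_id")["clone_id"]
    else:
        cell_clones = pd.Series(clones)
    cells = cell_clones.to_numpy()
    if cells.size == 0:
        raise ValueError("no cells for diversity computation")
    q_grid = np.asarray(list(q_grid), dtype=float)

    def profile(labels: np.ndarray) -> np.ndarray:
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        return np.array([hill_diversity(p, q) for q in q_grid])

    d = profile(cells)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, q_grid.size))
        for b in range(n_boot):
            boot[b] = profile(rng.choice(cells, cells.size, replace=True))
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    else:
        lo = hi = d.copy()
    return DiversityProfile(label=label, q_grid=q_grid, d=d, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# gene usage / clone bins / isotypes
# ---------------------------------------------------------------------------

def gene_usage(records: pd.DataFrame, reference: pd.DataFrame | None = None,
               min_freq: float = 0.03) -> tuple[pd.DataFrame, pd.DataFrame]:
    """V-gene usage per group and chain, joined to a reference distribution.

    Returns ``(usage, pairs)``: usage rows are filtered to genes reaching
    ``min_freq`` in at least one group (or the reference); ``pairs`` counts
    paired heavy/light V-gene combinations per group.
    """
    df = records.copy()
    if df.empty:
        raise ValueError("no records for gene usage")
    df["gene"] = df["v_call"].map(strip_allele)
    rows = []
    for (group, chain), sub in df.groupby(["group", "chain"]):
        freqs = sub["gene"].value_counts(normalize=True)
        for gene, f in freqs.items():
            rows.append({"group": group, "chain": chain, "gene": gene, "frequency": f})
    usage = pd.DataFrame(rows)
    if reference is not None:
        ref = reference.copy()
        ref["gene"] = ref["gene"].map(strip_allele)
        chain_of = usage.drop_duplicates("gene").set_index("gene")["chain"]
        ref["chain"] = ref["gene"].map(chain_of)
        ref["group"] = "reference"
        usage = pd.concat([usage, ref[["group", "chain", "gene", "frequency"]]],
                          ignore_index=True)
    keep = usage.groupby("gene")["frequency"].max()
    usage = usage[usage["gene"].map(keep) >= min_freq].reset_index(drop=True)

    heavy = df[df["chain"] == "heavy"][["cell_id", "group", "gene"]]
    light = df[df["chain"] != "heavy"][["cell_id", "gene"]]
    paired = heavy.merge(light, on="cell_id", suffixes=("_heavy", "_light"))
    pairs = (paired.groupby(["group", "gene_heavy", "gene_light"])
             .size().rename("n_cells").reset_index())
    return usage, pairs


def shared_gene_pairs(pairs: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    """Heavy/light V-gene pairs detected in every listed group."""
    present = pairs.groupby(["gene_heavy", "gene_light"])["group"].apply(set)
    shared = present[present.apply(lambda s: set(groups) <= s)]
    return shared.reset_index()[["gene_heavy", "gene_light"]]


def clone_size_bins(clones: CloneSet, by: Sequence[str] = ("subject", "timepoint")) -> pd.DataFrame:
    """Cell-weighted clone-size bin fractions per grouping.

    Bins: rare (1 cell), small (2), medium (3-5), large (6-10); clones above
    10 cells are reported as "larger".
    """
    cells = clones.assignments.drop_duplicates("cell_id")
    rows = []
    group_cols = [c for c in by if c in cells.columns]
    grouped = cells.groupby(group_cols) if group_cols else [((), cells)]
    for key, sub in grouped:
        sizes = sub.groupby("clone_id").size()
        total = sizes.sum()
        per_cell_bin = {}
        for name, lo, hi in CLONE_BINS:
            mask = (sizes >= lo) & (sizes <= hi)
            per_cell_bin[name] = sizes[mask].sum() / total
        if not isinstance(key, tuple):
            key = (key,)
        rows.append({**dict(zip(group_cols, key)), **per_cell_bin,
                     "n_cells": int(total)})
    return pd.DataFrame(rows)


def isotype_fractions(records: pd.DataFrame,
                      group_by: Sequence[str] = ("group",),
                      known_isotypes: Sequence[str] = ("IGHM", "IGHD") + SWITCHED_ISOTYPES,
                      ) -> pd.DataFrame:
    """Per-grouping isotype fractions plus the class-switched aggregate.

    Unknown labels are pooled under "other" with a warning.  Groupings with
    no cells are absent from the output rather than reported as zero.
    """
    heavy = records[records["chain"] == "heavy"] if "chain" in records else records
    if heavy.empty:
        return pd.DataFrame()
    labels = heavy["c_call"].fillna("other")
    unknown = ~labels.isin(known_isotypes)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} records with unknown isotype counted as 'other'",
            stacklevel=2,
        )
    heavy = heavy.assign(_iso=labels.where(~unknown, "other"))
    rows = []
    for key, sub in heavy.groupby(list(group_by)):
        fr = sub["_iso"].value_counts(normalize=True)
        if not isinstance(key, tuple):
            key = (key,)
        row = dict(zip(group_by, key))
        for iso, f in fr.items():
            row[iso] = f
        row["switched"] = float(sum(fr.get(i, 0.0) for i in SWITCHED_ISOTYPES))
        row["n_cells"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)
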