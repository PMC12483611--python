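"""Synthetic vaccinated-cohort generators with retained ground truth.

Every generator is a pure function of its configuration and seed: the same
inputs produce byte-identical tables.  Ground-truth fields (true clone id,
true mutation count, true hashtag, true TRAI, ...) are carried alongside the
observables so that downstream estimators can be tested for parameter
recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import (
    CohortConfig,
    ConfigurationError,
    RepertoireConfig,
    SerologyConfig,
    SUBSETS,
)
from .reference import GERMLINE_300NT

_BASES = np.array(list("ACGT"))

#: AIRR-style column order for repertoire tables.
AIRR_COLUMNS = [
    "sequence_id", "cell_id", "subject", "group", "timepoint", "subset",
    "chain", "v_call", "j_call", "junction", "junction_length",
    "sequence_alignment", "germline_alignment", "c_call", "productive",
    "true_clone_id", "true_mutation_count",
]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """i.i.d. per-position substitution to one of the 3 alternative bases."""
    n = seq.size
    hit = rng.random(n) < rate
    out = seq.copy()
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift by 1..3 in base space guarantees a different base
        cur = np.searchsorted(_BASES, seq[idx])
        out[idx] = _BASES[(cur + rng.integers(1, 4, idx.size)) % 4]
    return out, int(idx.size)


def _clone_sizes(rng: np.random.Generator, n_cells: int, exponent: float,
                 max_size: int = 10) -> list[int]:
    """Clone sizes from a discrete power law P(k) ~ k^-exponent truncated at max_size."""
    k = np.arange(1, max_size + 1)
    p = k.astype(float) ** -exponent
    p /= p.sum()
    sizes: list[int] = []
    total = 0
    while total < n_cells:
        s = int(rng.choice(k, p=p))
        s = min(s, n_cells - total)
        sizes.append(s)
        total += s
    return sizes


def gen_repertoire(cohort: CohortConfig, rep: RepertoireConfig) -> pd.DataFrame:
    """Generate an annotated BCR table for every subject x timepoint.

    Each cell carries one heavy chain (and, by default, one light chain)
    derived from the packaged 300-nt germline: a clone-founder junction is
    substituted into the CDR3 interval, then i.i.d. substitutions are applied
    at the cell's group/subset SHM rate.  True clone ids and true mutation
    counts are retained.
    """
    rng = np.random.default_rng(cohort.seed)
    shm = rep.shm_rates(cohort.groups)
    subset_probs = rep.subset_probs(cohort.groups)
    germ = np.array(list(GERMLINE_300NT[: rep.germline_length]))
    if germ.size != rep.germline_length:
        raise ConfigurationError(
            f"germline_length {rep.germline_length} exceeds packaged germline "
            f"({len(GERMLINE_300NT)} nt)"
        )
    cdr3_lo, cdr3_hi = rep.region_layout["CDR3"]
    jlen = cdr3_hi - cdr3_lo

    usage = rep.vj_usage
    heavy_v = usage[(usage["chain"] == "heavy") & (usage["segment"] == "V")]
    heavy_j = usage[(usage["chain"] == "heavy") & (usage["segment"] == "J")]
    light_v = usage[(usage["chain"] != "heavy") & (usage["segment"] == "V")].copy()
    light_v["frequency"] = light_v["frequency"] / light_v["frequency"].sum()
    light_j = {
        ch: usage[(usage["chain"] == ch) & (usage["segment"] == "J")]
        for ch in ("kappa", "lambda")
    }

    rows: list[dict] = []
    clone_counter = 0
    for subject, group in cohort.subjects():
        for timepoint in cohort.timepoints:
            sizes = _clone_sizes(rng, rep.cells_per_subject, rep.clone_size_exponent)
            cell_no = 0
            for size in sizes:
                clone_counter += 1
                clone_id = f"clone-{clone_counter:05d}"
                v = heavy_v["gene"].iloc[
                    rng.choice(len(heavy_v), p=heavy_v["frequency"].to_numpy())
                ]
                j = heavy_j["gene"].iloc[
                    rng.choice(len(heavy_j), p=heavy_j["frequency"].to_numpy())
                ]
                founder_junction = rng.choice(_BASES, jlen)
                clone_germ = germ.copy()
                clone_germ[cdr3_lo:cdr3_hi] = founder_junction
                for _ in range(size):
                    cell_no += 1
                    cell_id = f"{subject}_{timepoint}_c{cell_no:04d}"
                    subset = SUBSETS[
                        rng.choice(
                            len(SUBSETS),
                            p=[subset_probs[group][s] for s in SUBSETS],
                        )
                    ]
                    isotypes = rep.isotype_probs[subset]
                    c_call = list(isotypes)[
                        rng.choice(len(isotypes), p=list(isotypes.values()))
                    ]
                    rate = shm[group][subset]
                    seq, nmut = _mutate(rng, clone_germ, rate)
                    rows.append({
                        "sequence_id": f"{cell_id}_H",
                        "cell_id": cell_id,
                        "subject": subject,
                        "group": group,
                        "timepoint": timepoint,
                        "subset": subset,
                        "chain": "heavy",
                        "v_call": f"{v}*01",
                        "j_call": f"{j}*01",
                        "junction": "".join(seq[cdr3_lo:cdr3_hi]),
                        "junction_length": jlen,
                        "sequence_alignment": "".join(seq),
                        "germline_alignment": "".join(clone_germ),
                        "c_call": c_call,
                        "productive": True,
                        "true_clone_id": clone_id,
                        "true_mutation_count": nmut,
                    })
                    if rep.multi_heavy_rate > 0 and rng.random() < rep.multi_heavy_rate:
                        seq2, nmut2 = _mutate(rng, clone_germ, rate)
                        extra = dict(rows[-1])
                        extra.update({
                            "sequence_id": f"{cell_id}_H2",
                            "junction": "".join(seq2[cdr3_lo:cdr3_hi]),
                            "sequence_alignment": "".join(seq2),
                            "true_mutation_count": nmut2,
                        })
                        rows.append(extra)
                    if rep.include_light_chain:
                        lv_i = rng.choice(len(light_v), p=light_v["frequency"].to_numpy())
                        lv = light_v.iloc[lv_i]
                        lj_tab = light_j[lv["chain"]]
                        lj = lj_tab["gene"].iloc[
                            rng.choice(len(lj_tab), p=lj_tab["frequency"].to_numpy())
                        ]
                        lgerm = germ.copy()
                        lgerm[cdr3_lo:cdr3_hi] = rng.choice(_BASES, jlen)
                        lseq, lnmut = _mutate(rng, lgerm, rate)
                        rows.append({
                            "sequence_id": f"{cell_id}_L",
                            "cell_id": cell_id,
                            "subject": subject,
                            "group": group,
                            "timepoint": timepoint,
                            "subset": subset,
                            "chain": lv["chain"],
                            "v_call": f"{lv['gene']}*01",
                            "j_call": f"{lj}*01",
                            "junction": "".join(lseq[cdr3_lo:cdr3_hi]),
                            "junction_length": jlen,
                            "sequence_alignment": "".join(lseq),
                            "germline_alignment": "".join(lgerm),
                            "c_call": "IGKC" if lv["chain"] == "kappa" else "IGLC",
                            "productive": True,
                            "true_clone_id": f"{clone_id}-L",
                            "true_mutation_count": lnmut,
                        })
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


# ---------------------------------------------------------------------------
# serology
# ---------------------------------------------------------------------------

def four_pl(d, blank: float, top: float, ec50: float, hill: float):
    """4-parameter logistic response on the concentration scale."""
    d = np.asarray(d, dtype=float)
    return blank + (top - blank) / (1.0 + (ec50 / d) ** hill)


def gen_dilution_series(ec50_true: float, top_od: float, hill: float,
                        blank_od: float, dilutions, noise_sd: float,
                        seed: int) -> pd.DataFrame:
    """One 4PL dilution series; lognormal multiplicative noise on OD.

    ``dilutions`` are plasma concentrations (1/dilution factor), strictly
    positive.  The truth is recorded in ``DataFrame.attrs``.
    """
    d = np.asarray(dilutions, dtype=float)
    if np.any(d <= 0):
        raise ConfigurationError("dilutions must be strictly positive")
    rng = np.random.default_rng(seed)
    od = four_pl(d, blank_od, top_od, ec50_true, hill)
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, od.size))
    out = pd.DataFrame({"dilution": d, "od": od})
    out.attrs.update(
        ec50_true=ec50_true, top_od=top_od, hill=hill, blank_od=blank_od
    )
    return out


def _decay_rate_for_trai(trai: float, concs: np.ndarray) -> float:
    """Exponential elution rate k with 100 * sum(exp(-k c)) == trai."""
    nonzero = concs[concs > 0]
    t_max = 100.0 * nonzero.size
    if trai >= t_max:
        return 0.0
    if trai <= 0:
        return np.inf

    def f(k):
        return 100.0 * np.exp(-k * nonzero).sum() - trai

    return float(brentq(f, 0.0, 1e4))


def gen_serology_cohort(cohort: CohortConfig, ser: SerologyConfig) -> pd.DataFrame:
    """Tidy plate table: EC50 series, avidity dilution series, chaotrope wells.

    Per subject x dose the chaotrope triplicates are constructed so the true
    TRAI equals ``baseline + dose * increment - deficit(group)`` and the mean
    OD is non-increasing in chaotrope concentration before noise.
    """
    rng = np.random.default_rng(cohort.seed + 104729)  # distinct stream from repertoire
    concs = np.asarray(ser.chaotrope_concs, dtype=float)
    ec50_dil = 1.0 / (5.0 * 4.0 ** np.arange(10))       # 10-point, 4-fold from 1:5
    avidity_dil = 1.0 / (100.0 * 3.0 ** np.arange(7))   # 7-point, 3-fold from 1:100

    rows: list[dict] = []
    for subject, group in cohort.subjects():
        ec50_subj = ser.ec50_true * float(np.exp(rng.normal(0.0, 0.25)))
        for dose in ser.doses:
            sample = f"{subject}-d{dose}"

            def emit(assay, dilution, conc, replicate, mean_od):
                od = mean_od
                if ser.od_noise_sd > 0:
                    od = od * float(np.exp(rng.normal(0.0, ser.od_noise_sd)))
                rows.append({
                    "sample_id": sample, "subject": subject, "group": group,
                    "dose": dose, "assay": assay, "replicate": replicate,
                    "chaotrope_M": conc, "dilution": dilution, "od": od,
                })

            for d in ec50_dil:
                emit("ec50", d, 0.0, 1,
                     float(four_pl(d, ser.blank_od, ser.top_od, ec50_subj, ser.hill)))
            for d in avidity_dil:
                emit("avidity_dilution", d, 0.0, 1,
                     float(four_pl(d, ser.blank_od, ser.top_od, ec50_subj, ser.hill)))

            trai = ser.true_trai(group, dose)
            k = _decay_rate_for_trai(trai, concs)
            d_score = float(avidity_dil[np.argmin(np.abs(np.log(avidity_dil / ec50_subj)))])
            a0 = float(four_pl(d_score, ser.blank_od, ser.top_od, ec50_subj, ser.hill))
            for c in concs:
                retention = 0.0 if np.isinf(k) and c > 0 else float(np.exp(-k * c))
                for r in range(1, ser.n_replicates + 1):
                    emit("chaotrope", d_score, float(c), r, a0 * retention)

    df = pd.DataFrame(rows)
    truth = {
        (f"{s}-d{d}"): ser.true_trai(g, d)
        for s, g in cohort.subjects() for d in ser.doses
    }
    df.attrs["true_trai"] = truth
    return df


def gen_subject_table(cohort: CohortConfig, ser: SerologyConfig | None = None) -> pd.DataFrame:
    """Per-subject covariates (age, sex, BMI, vaccine type) for regressions."""
    rng = np.random.default_rng(cohort.seed + 7919)
    rows = []
    for subject, group in cohort.subjects():
        rows.append({
            "subject": subject,
            "group": group,
            "age": float(np.round(rng.uniform(22, 70), 1)),
            "sex": ("F", "M")[int(rng.integers(0, 2))],
            "bmi": float(np.round(rng.normal(26, 4), 1)),
            "vaccine": ("mRNA-A", "mRNA-B")[int(rng.integers(0, 2))],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC / HTO
# ---------------------------------------------------------------------------

def gen_hto_qc(cohort: CohortConfig, n_cells: int, doublet_rate: float,
               seed: int, dominant_mean: float = 200.0,
               background_mean: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell QC table plus an HTO count matrix with injected doublets.

    Singlets get one dominant hashtag (Poisson around ``dominant_mean``) over
    a low Poisson background; doublets get two comparable hashtags.  True
    hashtag labels (or ``doublet``) are retained in the QC table.
    """
    if not 0 <= doublet_rate < 1:
        raise ConfigurationError("doublet_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hashtags = [
        f"HTO-{subject}-{tp}"
        for subject, _ in cohort.subjects()
        for tp in cohort.timepoints
    ]
    n_h = len(hashtags)
    counts = rng.poisson(background_mean, size=(n_cells, n_h))
    is_doublet = rng.random(n_cells) < doublet_rate
    true_label = []
    for i in range(n_cells):
        if is_doublet[i]:
            a, b = rng.choice(n_h, 2, replace=False)
            counts[i, a] += rng.poisson(dominant_mean * 0.6)
            counts[i, b] += rng.poisson(dominant_mean * 0.6)
            true_label.append("doublet")
        else:
            a = int(rng.integers(0, n_h))
            counts[i, a] += rng.poisson(dominant_mean)
            true_label.append(hashtags[a])

    cell_ids = [f"cell-{i:05d}" for i in range(n_cells)]
    mito = rng.gamma(shape=4.0, scale=1.25, size=n_cells)  # mean 5%, tail past 10%
    n_feat = np.clip(
        np.round(np.exp(rng.normal(np.log(2500), 0.45, n_cells))).astype(int), 1, None
    )
    qc = pd.DataFrame({
        "cell_id": cell_ids,
        "mito_pct": mito,
        "n_features": n_feat,
        "true_hashtag": true_label,
        "true_doublet": is_doublet,
    })
    hto = pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell_id"), columns=hashtags)
    return qc, hto
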