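"""Configuration objects for cohort simulation and the pipeline.

All generators are driven by three validated dataclasses (cohort,
repertoire, serology) plus the cell-QC parameter block.  A YAML file with
matching top-level keys drives the CLI; the seed is mandatory whenever a
synthetic block is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .reference import DEFAULT_REGION_LAYOUT, REGION_NAMES, default_vj_usage


class ConfigurationError(ValueError):
    """Raised when a configuration block fails validation."""


_PROB_TOL = 1e-9

DEFAULT_GROUPS = ("healthy", "anti-IL-12/23", "anti-TNF")
DEFAULT_TIMEPOINTS = ("post-dose-2", "post-dose-3")
SUBSETS = ("cMBC", "MZ-like", "aMBC")
ISOTYPES = ("IGHM", "IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1")


def _check_probs(vec: Mapping[str, float], what: str) -> None:
    total = float(sum(vec.values()))
    if abs(total - 1.0) > _PROB_TOL:
        raise ConfigurationError(f"{what} must sum to 1 (got {total!r})")
    if any(p < 0 for p in vec.values()):
        raise ConfigurationError(f"{what} contains negative probabilities")


@dataclass(frozen=True)
class CohortConfig:
    """Study-arm layout: groups x subjects x timepoints plus the master seed."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    subjects_per_group: int = 4
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ConfigurationError("need at least 2 groups")
        if self.subjects_per_group < 1:
            raise ConfigurationError("subjects_per_group must be >= 1")
        if not self.timepoints:
            raise ConfigurationError("need at least one timepoint")

    def subjects(self) -> list[tuple[str, str]]:
        """(subject_id, group) pairs, deterministic order."""
        out = []
        for g in self.groups:
            for i in range(self.subjects_per_group):
                out.append((f"{_slug(g)}-{i + 1:02d}", g))
        return out


def _slug(label: str) -> str:
    return label.replace("/", "").replace(" ", "-")


def _per_group(value, groups: Sequence[str], subsets: Sequence[str]) -> dict:
    """Broadcast a scalar / per-group / per-group-per-subset spec to nested dict."""
    if isinstance(value, (int, float)):
        return {g: {s: float(value) for s in subsets} for g in groups}
    out = {}
    for g in groups:
        v = value[g]
        if isinstance(v, (int, float)):
            out[g] = {s: float(v) for s in subsets}
        else:
            out[g] = {s: float(v[s]) for s in subsets}
    return out


@dataclass
class RepertoireConfig:
    """Generative parameters for synthetic BCR repertoires."""

    cells_per_subject: int = 40
    subset_props: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    shm_rate: object = 0.04  # scalar, per-group, or per-group-per-subset
    isotype_probs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    clone_size_exponent: float = 2.5
    vj_usage: pd.DataFrame | None = None
    germline_length: int = 300
    region_layout: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LAYOUT)
    )
    junction_length: int = 12
    multi_heavy_rate: float = 0.0  # cells flagged with >1 heavy chain (filter tests)
    include_light_chain: bool = True

    def __post_init__(self) -> None:
        if self.cells_per_subject < 1:
            raise ConfigurationError("cells_per_subject must be >= 1")
        if self.clone_size_exponent <= 1:
            raise ConfigurationError("clone_size_exponent must be > 1")
        for g, vec in self.subset_props.items():
            _check_probs(vec, f"subset_props[{g}]")
        if not self.isotype_probs:
            self.isotype_probs = {
                "cMBC": {"IGHM": 0.10, "IGHG1": 0.45, "IGHG2": 0.15,
                         "IGHG3": 0.12, "IGHG4": 0.03, "IGHA1": 0.15},
                "MZ-like": {"IGHM": 0.60, "IGHG1": 0.15, "IGHG2": 0.08,
                            "IGHG3": 0.07, "IGHG4": 0.02, "IGHA1": 0.08},
                "aMBC": {"IGHM": 0.25, "IGHG1": 0.35, "IGHG2": 0.15,
                         "IGHG3": 0.10, "IGHG4": 0.05, "IGHA1": 0.10},
            }
        for s, vec in self.isotype_probs.items():
            _check_probs(vec, f"isotype_probs[{s}]")
        if self.vj_usage is None:
            self.vj_usage = default_vj_usage()
        self._validate_layout()

    def _validate_layout(self) -> None:
        layout = self.region_layout
        if tuple(layout) != REGION_NAMES:
            raise ConfigurationError(f"region_layout must have regions {REGION_NAMES}")
        prev = 0
        for name in REGION_NAMES:
            lo, hi = layout[name]
            if lo != prev or hi <= lo:
                raise ConfigurationError(
                    "region boundaries must be contiguous, non-overlapping "
                    f"and increasing (bad interval {name}={layout[name]})"
                )
            prev = hi
        if prev != self.germline_length:
            raise ConfigurationError(
                f"region layout covers [0,{prev}) but germline_length={self.germline_length}"
            )

    def subset_probs(self, groups: Sequence[str]) -> dict:
        """Per-group subset probability vectors, defaulting groups not listed."""
        default = dict(zip(SUBSETS, (0.6, 0.3, 0.1)))
        out = {}
        for g in groups:
            vec = dict(self.subset_props.get(g, default))
            _check_probs(vec, f"subset_props[{g}]")
            out[g] = vec
        return out

    def shm_rates(self, groups: Sequence[str]) -> dict:
        rates = _per_group(self.shm_rate, groups, SUBSETS)
        for g, per_subset in rates.items():
            for s, r in per_subset.items():
                if not 0.0 <= r <= 0.25:
                    raise ConfigurationError(
                        f"shm_rate[{g}][{s}]={r} outside [0, 0.25]"
                    )
        return rates


@dataclass
class SerologyConfig:
    """Generative parameters for synthetic ELISA / chaotrope-avidity plates."""

    doses: tuple[int, ...] = (1, 2, 3, 4)
    baseline_trai: float = 80.0
    dose_increment: float = 40.0
    group_deficit: Mapping[str, float] = field(default_factory=dict)
    od_noise_sd: float = 0.0  # lognormal sigma applied multiplicatively to OD
    ec50_true: float = 1e-3   # plasma-concentration scale of the half response
    chaotrope_concs: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    top_od: float = 2.0
    blank_od: float = 0.05
    hill: float = 1.5
    n_replicates: int = 3

    def __post_init__(self) -> None:
        cc = tuple(self.chaotrope_concs)
        if cc[0] != 0 or any(b <= a for a, b in zip(cc, cc[1:])):
            raise ConfigurationError(
                "chaotrope_concs must start at 0 and be strictly increasing"
            )
        if self.od_noise_sd < 0:
            raise ConfigurationError("od_noise_sd must be >= 0")
        if not self.group_deficit:
            self.group_deficit = {"anti-TNF": 0.0}

    def true_trai(self, group: str, dose: int) -> float:
        t = self.baseline_trai + dose * self.dose_increment - self.group_deficit.get(group, 0.0)
        n_nonzero = len(self.chaotrope_concs) - 1
        return float(min(max(t, 0.0), 100.0 * n_nonzero))


@dataclass(frozen=True)
class CellQCParams:
    """Cell-level QC thresholds and the hashtag demultiplexing margin."""

    mito_max: float = 10.0
    feat_min: int = 200
    feat_max: int = 6500
    hto_margin: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.mito_max <= 100:
            raise ConfigurationError("mito_max must be in (0, 100]")
        if self.feat_min >= self.feat_max:
            raise ConfigurationError("feat_min must be < feat_max")


@dataclass
class PipelineConfig:
    """Full-pipeline configuration (synthetic block + module parameters)."""

    cohort: CohortConfig
    repertoire: RepertoireConfig
    serology: SerologyConfig
    qc: CellQCParams = field(default_factory=CellQCParams)
    clone_threshold: float = 0.15
    q_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    n_boot: int = 200
    n_perm: int = 1000
    doublet_rate: float = 0.05
    qc_cells: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        synth = raw.get("synthetic", raw)
        cohort_raw = dict(synth.get("cohort", {}))
        if "seed" not in cohort_raw:
            raise ConfigurationError("synthetic block requires an explicit seed")
        for key in ("groups", "timepoints"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        cohort = CohortConfig(**cohort_raw)
        repertoire = RepertoireConfig(**synth.get("repertoire", {}))
        ser_raw = dict(synth.get("serology", {}))
        for key in ("doses", "chaotrope_concs"):
            if key in ser_raw:
                ser_raw[key] = tuple(ser_raw[key])
        serology = SerologyConfig(**ser_raw)
        qc = CellQCParams(**raw.get("qc", {}))
        extra = {
            k: raw[k]
            for k in ("clone_threshold", "n_boot", "n_perm", "doublet_rate", "qc_cells")
            if k in raw
        }
        if "q_grid" in raw:
            extra["q_grid"] = tuple(raw["q_grid"])
        return cls(cohort=cohort, repertoire=repertoire, serology=serology, qc=qc, **extra)

    def to_dict(self) -> dict:
        d = {
            "synthetic": {
                "cohort": asdict(self.cohort),
                "serology": asdict(self.serology),
            },
            "qc": asdict(self.qc),
            "clone_threshold": self.clone_threshold,
            "q_grid": list(self.q_grid),
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "doublet_rate": self.doublet_rate,
            "qc_cells": self.qc_cells,
        }
        rep = asdict(self.repertoire)
        rep["vj_usage"] = None  # table serialized separately if customized
        d["synthetic"]["repertoire"] = rep
        return d
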