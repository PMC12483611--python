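"""Cell-level QC filtering and hashtag (HTO) demultiplexing.

Filtering follows the printed strict-inequality semantics: a cell is
excluded when mitochondrial percentage > 10, features < 200 or features
> 6500, so cells sitting exactly on a threshold are retained.  Hashtag
assignment takes the CLR-normalized argmax, excluding cells whose margin
(max minus second max on the CLR scale) falls below 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CellQCParams


@dataclass
class FilterResult:
    retained: pd.DataFrame
    tally: dict  # rule -> number of cells violating it (cells may hit several)
    excluded_ids: list


def filter_cells(qc_table: pd.DataFrame, params: CellQCParams | None = None) -> FilterResult:
    """Retain cells with mito_pct <= mito_max and feat_min <= n_features <= feat_max.

    The exclusion tally attributes each dropped cell to every rule it
    violates.  Idempotent: filtering a retained set changes nothing.
    """
    params = params or CellQCParams()
    for col in ("mito_pct", "n_features"):
        if col not in qc_table.columns:
            raise KeyError(f"qc table missing required column {col!r}")
    mito_bad = qc_table["mito_pct"] > params.mito_max
    feat_low = qc_table["n_features"] < params.feat_min
    feat_high = qc_table["n_features"] > params.feat_max
    bad = mito_bad | feat_low | feat_high
    tally = {
        "mito_pct": int(mito_bad.sum()),
        "feat_min": int(feat_low.sum()),
        "feat_max": int(feat_high.sum()),
        "excluded_total": int(bad.sum()),
    }
    id_col = "cell_id" if "cell_id" in qc_table.columns else None
    excluded = qc_table.loc[bad, id_col].tolist() if id_col else list(qc_table.index[bad])
    return FilterResult(
        retained=qc_table.loc[~bad].copy(),
        tally=tally,
        excluded_ids=excluded,
    )


def clr_normalize(counts: np.ndarray, pseudo_count: float = 1.0) -> np.ndarray:
    """Per-cell centered log-ratio across hashtags: ln(x+1) minus the row mean."""
    y = np.log(np.asarray(counts, dtype=float) + pseudo_count)
    return y - y.mean(axis=1, keepdims=True)


def demux_hashtags(hto: pd.DataFrame, margin: float = 2.0,
                   pseudo_count: float = 1.0) -> pd.DataFrame:
    """Assign each cell to its max-CLR hashtag, or exclude it.

    Exclusion reasons: ``no signal`` (all-zero row), ``tie`` (max not
    unique), ``low margin`` (max minus second max below ``margin`` on the
    CLR scale).  Returns assignment, margin and reason per cell.
    """
    if hto.shape[1] < 2:
        raise ValueError("demultiplexing needs at least 2 hashtags")
    counts = hto.to_numpy(dtype=float)
    y = clr_normalize(counts, pseudo_count)
    order = np.argsort(y, axis=1)
    top = order[:, -1]
    second = order[:, -2]
    margins = y[np.arange(len(y)), top] - y[np.arange(len(y)), second]

    labels = np.asarray(hto.columns)
    assignment = labels[top].astype(object)
    reason = np.full(len(y), "", dtype=object)

    no_signal = counts.sum(axis=1) == 0
    tie = y[np.arange(len(y)), top] == y[np.arange(len(y)), second]
    low = margins < margin

    excluded = no_signal | tie | low
    reason[low] = "low margin"
    reason[tie & ~no_signal] = "tie"
    reason[no_signal] = "no signal"
    assignment[excluded] = "excluded"

    return pd.DataFrame({
        "cell_id": hto.index,
        "assignment": assignment,
        "clr_margin": margins,
        "reason": reason,
    }).set_index("cell_id")
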