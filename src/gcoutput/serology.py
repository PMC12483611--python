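"""EC50 estimation and chaotrope-displacement avidity scoring.

EC50 is the concentration giving a response halfway between the blank mean
and the fitted top of a 4-parameter logistic whose lower asymptote is
anchored at the blank.  Avidity scoring converts replicate-mean ODs across
chaotrope concentrations (0, 0.5, 1, 2 M) into relative avidity indices
(RAI, % of the 0 M signal), their fractional decomposition into four
elution categories, and a total relative avidity index (TRAI, AU) defined
as the sum of the three nonzero-concentration RAIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CATEGORY_NAMES = ("very_low", "low", "medium", "high")


@dataclass
class Ec50Fit:
    ec50: float
    top: float
    hill: float
    blank: float
    residual_norm: float
    converged: bool
    status: str  # "ok" | "no signal" | "non-convergent"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def fit_ec50(series: pd.DataFrame, blank: float | None = None) -> Ec50Fit:
    """Fit a blank-anchored 4PL in log-dilution and report the half response.

    ``series`` needs columns ``dilution`` (plasma concentration scale,
    strictly positive and ordered) and ``od``; ``blank`` defaults to the
    mean of a ``blank`` column if present, else the minimum OD.  Scale
    invariance: multiplying every OD (blank included) by k leaves the EC50
    unchanged.
    """
    d = series["dilution"].to_numpy(dtype=float)
    od = series["od"].to_numpy(dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 dilution points for a fit")
    if np.any(d <= 0) or np.any(np.diff(d) == 0):
        raise ValueError("dilutions must be strictly positive and distinct")
    if blank is None:
        blank = float(series["blank"].mean()) if "blank" in series else float(od.min())

    span = od.max() - blank
    if span <= 1e-12 or span <= 0.02 * max(abs(blank), od.max(), 1e-12):
        return Ec50Fit(np.nan, np.nan, np.nan, blank, np.nan, False, "no signal")

    logd = np.log(d)

    def model(x, log_ec50, top, hill):
        return blank + (top - blank) / (1.0 + np.exp(-hill * (x - log_ec50)))

    p0 = [float(np.median(logd)), float(od.max()), 1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, logd, od, p0=p0, maxfev=20000,
                bounds=([logd.min() - 10, blank + 1e-12, 0.05],
                        [logd.max() + 10, 10 * od.max() + 1, 50.0]),
            )
    except RuntimeError:
        return Ec50Fit(np.nan, np.nan, np.nan, blank, np.nan, False, "non-convergent")
    resid = od - model(logd, *popt)
    return Ec50Fit(
        ec50=float(np.exp(popt[0])),
        top=float(popt[1]),
        hill=float(popt[2]),
        blank=blank,
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
        status="ok",
    )


@dataclass
class AvidityResult:
    """RAI per nonzero chaotrope concentration, categories, and TRAI."""

    sample_id: str
    rai: dict                      # conc (M) -> RAI (%)
    fractional_rai: dict           # category -> % of 0 M signal
    trai: float                    # AU
    repaired: bool = False         # monotonicity repair applied
    warnings: list = field(default_factory=list)

    @property
    def categories(self) -> dict:
        return self.fractional_rai

    def to_row(self) -> dict:
        row = {"sample_id": self.sample_id, "trai": self.trai,
               "repaired": self.repaired}
        row.update({f"rai_{c}M": v for c, v in self.rai.items()})
        row.update(self.fractional_rai)
        return row


def score_avidity(series: pd.DataFrame, sample_id: str | None = None) -> AvidityResult:
    """Score one chaotrope series (columns ``chaotrope_M``, ``od``).

    Replicate-mean ODs are made non-increasing in concentration by a running
    minimum, then: RAI(c) = 100 m(c)/m(0); the four category fractions are
    the successive drops (very_low, low, medium) and the final residual
    (high), summing to 100; TRAI is the sum of the nonzero-concentration
    RAIs (0 to 100*(K-1) AU).
    """
    warns: list[str] = []
    df = series.copy()
    if (df["od"] < 0).any():
        warns.append("negative ODs clipped to 0")
        df["od"] = df["od"].clip(lower=0)
    means = df.groupby("chaotrope_M")["od"].mean().sort_index()
    concs = means.index.to_numpy(dtype=float)
    if concs[0] != 0:
        raise ValueError("chaotrope series must include the 0 M reference")
    m = means.to_numpy(dtype=float)
    if m[0] <= 0:
        raise ValueError("0 M reference mean OD must be positive")

    if len(m) != len(CATEGORY_NAMES):
        raise ValueError(
            f"expected {len(CATEGORY_NAMES)} chaotrope concentrations, got {len(m)}"
        )
    repaired = bool(np.any(np.diff(m) > 0))
    m = np.minimum.accumulate(m)

    rai = 100.0 * m / m[0]
    frac = {name: rai[i] - rai[i + 1]
            for i, name in enumerate(CATEGORY_NAMES[:-1])}
    frac[CATEGORY_NAMES[-1]] = rai[-1]
    trai = float(rai[1:].sum())

    if sample_id is None and "sample_id" in df:
        sample_id = str(df["sample_id"].iloc[0])
    return AvidityResult(
        sample_id=sample_id or "",
        rai={float(c): float(r) for c, r in zip(concs[1:], rai[1:])},
        fractional_rai={k: float(v) for k, v in frac.items()},
        trai=trai,
        repaired=repaired,
        warnings=warns,
    )


def choose_scoring_dilution(dilution_series: pd.DataFrame,
                            blank: float = 0.0) -> float:
    """Dilution whose 0 M OD is nearest the half-maximal response."""
    d = dilution_series["dilution"].to_numpy(dtype=float)
    od = dilution_series["od"].to_numpy(dtype=float)
    half = blank + (od.max() - blank) / 2.0
    return float(d[np.argmin(np.abs(od - half))])


def score_avidity_table(plates: pd.DataFrame) -> pd.DataFrame:
    """Score every sample's chaotrope series in a tidy plate table."""
    chao = plates[plates["assay"] == "chaotrope"] if "assay" in plates else plates
    rows = []
    for sample, sub in chao.groupby("sample_id"):
        res = score_avidity(sub, sample_id=sample)
        row = res.to_row()
        for col in ("subject", "group", "dose"):
            if col in sub.columns:
                row[col] = sub[col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def fit_ec50_table(plates: pd.DataFrame) -> pd.DataFrame:
    """Fit EC50 for every sample's dilution series in a tidy plate table."""
    ser = plates[plates["assay"] == "ec50"] if "assay" in plates else plates
    rows = []
    for sample, sub in ser.groupby("sample_id"):
        fit = fit_ec50(sub.sort_values("dilution"))
        row = {"sample_id": sample, "ec50": fit.ec50, "top": fit.top,
               "hill": fit.hill, "status": fit.status,
               "residual_norm": fit.residual_norm}
        for col in ("subject", "group", "dose"):
            if col in sub.columns:
                row[col] = sub[col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
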