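"""Screening and assay triage arithmetic.

Covers the numerical bookkeeping around a radioligand-displacement screen:
docking-score ranking with per-cluster diversity picks, the inhibition
percentage of a filtration binding assay,

    inhibition % = 100 · (total − test) / (total − nonspecific),

threshold hit counting ("over X % inhibition" is a strict inequality — it
matches every printed count), and IC50 determination by four-parameter
logistic (4PL) fits of concentration–response curves:

    y = bottom + (top − bottom) / (1 + 10^((log10 IC50 − log10 x) · hill)).

A 27-row transcription of the screen's assay table ships with the package
(``load_reference_table``) so the counting arithmetic has a frozen worked
example.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FourPLFit",
    "FitError",
    "inhibition_percent",
    "count_hits",
    "lowest_ic50s",
    "four_pl",
    "fit_4pl",
    "rank_and_pick",
    "load_reference_table",
]


class FitError(RuntimeError):
    """Raised when a dose-response curve cannot be fit."""


@dataclass
class FourPLFit:
    bottom: float
    top: float
    log_ic50: float  # log10 of µM
    hill: float
    residual_norm: float

    @property
    def ic50(self) -> float:
        return float(10.0 ** self.log_ic50)

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return four_pl(np.asarray(conc, dtype=float), self.bottom, self.top,
                       self.log_ic50, self.hill)


def inhibition_percent(total: float, test: float, nonspecific: float) -> float:
    """Percent inhibition of specific binding from raw assay counts."""
    if total <= nonspecific:
        raise ValueError("total binding must exceed non-specific binding")
    return 100.0 * (total - test) / (total - nonspecific)


def count_hits(records: pd.DataFrame, threshold_pct: float,
               column: str = "inhibition_pct") -> int:
    """Number of compounds with inhibition strictly above the threshold."""
    values = pd.to_numeric(records[column], errors="coerce").dropna()
    return int((values > threshold_pct).sum())


def lowest_ic50s(records: pd.DataFrame, n: int = 5,
                 column: str = "ic50_uM") -> list[float]:
    """The n smallest measured IC50 values, ascending (µM)."""
    values = pd.to_numeric(records[column], errors="coerce").dropna()
    return sorted(values)[:n]


def four_pl(x: np.ndarray, bottom: float, top: float, log_ic50: float,
            hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - np.log10(x)) * hill))


def fit_4pl(concentrations: np.ndarray, responses: np.ndarray) -> FourPLFit:
    """Least-squares 4PL fit in log-concentration space.

    Requires >= 4 distinct positive concentrations and a non-flat response
    (otherwise the IC50 is unidentifiable).  Bottom/top are bounded to
    [-10, 110] %; the Hill slope to (0.05, 20).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be matching 1-D arrays")
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations for a 4PL fit")
    span = float(np.max(y) - np.min(y))
    if span < 1.0:
        raise FitError(f"flat response (span {span:.3g}%): IC50 unidentifiable")
    # midpoint-response initial guess for log IC50
    mid = (np.max(y) + np.min(y)) / 2.0
    bounds = ([-10.0, -10.0, np.log10(x.min()) - 3.0, 0.05],
              [110.0, 110.0, np.log10(x.max()) + 3.0, 20.0])
    p0 = np.clip(
        [float(np.min(y)), float(np.max(y)),
         float(np.log10(x[np.argmin(np.abs(y - mid))])), 1.0],
        bounds[0], bounds[1])
    try:
        popt, _ = curve_fit(four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        resid = float(np.linalg.norm(y - four_pl(x, *p0)))
        raise FitError(f"4PL fit did not converge (residual norm {resid:.3g})") from exc
    resid = float(np.linalg.norm(y - four_pl(x, *popt)))
    return FourPLFit(*popt, residual_norm=resid)


def rank_and_pick(records: pd.DataFrame, cluster_labels: dict[str, int],
                  top_n: int = 300,
                  score_column: str = "vina_score",
                  id_column: str = "compound_id") -> pd.DataFrame:
    """Diversity selection: top-N by ascending docking score, then the
    best-scoring compound of each cluster.

    ``cluster_labels`` maps compound id -> cluster id and must cover every
    top-N compound.  Returns the picked rows, score-ascending.
    """
    ranked = records.sort_values(
        [score_column, id_column], kind="stable").head(top_n).copy()
    missing = [c for c in ranked[id_column] if c not in cluster_labels]
    if missing:
        raise ValueError(f"no cluster label for top-ranked compounds: {missing[:5]}")
    ranked["_cluster"] = [cluster_labels[c] for c in ranked[id_column]]
    picks = (ranked.sort_values([score_column, id_column], kind="stable")
             .groupby("_cluster", as_index=False).first())
    return (picks.drop(columns="_cluster")
            .sort_values([score_column, id_column], kind="stable")
            .reset_index(drop=True))


def load_reference_table() -> pd.DataFrame:
    """The packaged 27-row D3R screening assay table.

    Columns: compound_id, vina_score (kcal/mol), inhibition_pct (% at
    10 µM), ic50_uM (µM, only where measured).  Transcribed verbatim from
    the published screen, including its duplicate 74.8 % entry.
    """
    ref = importlib.resources.files("poseval.data") / "assay_table.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
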