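"""Agreement statistics and the ROI-dimension optimization sweep.

Validation of an automated TI selector against human readers treats each
selection as a categorical rating (the chosen grid TI) and quantifies
agreement three ways:

* **Fleiss' kappa** — chance-corrected complete agreement between raters;
  computed pairwise and averaged into an overall kappa per grouping.
* **Partial agreement** — mean absolute TI difference (kappa ignores how
  far apart two selections are) and the percentage of exactly matched TIs.
* **ROI sweep** — mean absolute TI difference against a reference
  selection for every ROI shape and shim-divisor, over divisors 1.0 to 4.0
  in steps of 0.1 (31 dimensions per shape).

Kappa strength follows the conventional bands: Poor (<= 0.2), Fair
(<= 0.4), Moderate (<= 0.6), Good (<= 0.8), Excellent (<= 1.0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .core import RoiSpec, select_ti, DegenerateRoiError
from .scout_io import ScoutSeries

__all__ = [
    "RatingTable",
    "PairAgreement",
    "AgreementReport",
    "UndefinedKappaError",
    "fleiss_kappa",
    "kappa_strength",
    "partial_agreement",
    "agreement_report",
    "sweep_divisors",
    "roi_sweep",
]


class UndefinedKappaError(ValueError):
    """Chance agreement is 1 (a single category used throughout): kappa is 0/0."""


@dataclass(frozen=True)
class RatingTable:
    """Complete cases x raters table of categorical TI selections.

    ``selections`` is a wide DataFrame indexed by case identifier with one
    column per rater/method label, every cell a TI in ms.  The category
    set is the union of TIs observed in the table.
    """

    selections: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.selections
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValueError("rating table needs >= 1 case and >= 2 raters")
        if df.isna().any().any():
            raise ValueError("rating table must be complete (every case rated by every rater)")
        object.__setattr__(self, "selections", df.astype(float))

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "RatingTable":
        """Build from a tidy frame with columns case_id, rater, ti_ms."""
        for col in ("case_id", "rater", "ti_ms"):
            if col not in df.columns:
                raise ValueError(f"tidy ratings need a {col!r} column")
        wide = df.pivot(index="case_id", columns="rater", values="ti_ms")
        return cls(wide)

    @property
    def cases(self) -> list:
        return list(self.selections.index)

    @property
    def raters(self) -> list[str]:
        return [str(c) for c in self.selections.columns]

    @property
    def categories(self) -> np.ndarray:
        return np.unique(self.selections.to_numpy())


def _counts_matrix(table: RatingTable, raters: Sequence[str]) -> np.ndarray:
    """Cases x categories matrix of rating counts for the chosen raters."""
    sub = table.selections[list(raters)].to_numpy()
    cats = np.unique(sub)
    counts = np.zeros((sub.shape[0], cats.size), dtype=np.int64)
    for j, cat in enumerate(cats):
        counts[:, j] = (sub == cat).sum(axis=1)
    return counts


def fleiss_kappa(table: RatingTable, raters: Sequence[str] | None = None) -> float:
    """Fleiss' kappa over the categorical TI selections of the given raters.

    Uses the standard formulation kappa = (P_bar - Pe_bar) / (1 - Pe_bar)
    with per-case observed agreement and chance agreement from marginal
    category proportions.  Perfect observed agreement returns exactly 1.0;
    a table where every rating falls in one single category has chance
    agreement 1 and raises :class:`UndefinedKappaError`.
    """
    raters = list(raters) if raters is not None else table.raters
    if len(raters) < 2:
        raise ValueError("kappa needs at least 2 raters")
    missing = set(raters) - set(table.raters)
    if missing:
        raise ValueError(f"unknown raters: {sorted(missing)}")
    counts = _counts_matrix(table, raters)
    if counts.shape[1] == 1:
        raise UndefinedKappaError(
            "all raters used a single category for every case; kappa is undefined"
        )
    # perfect agreement: every case unanimous
    if (counts.max(axis=1) == counts.sum(axis=1)).all():
        return 1.0
    return float(_sm_fleiss_kappa(counts, method="fleiss"))


def kappa_strength(kappa: float) -> str:
    """Conventional verbal strength band for a kappa value."""
    if kappa <= 0.2:
        return "Poor"
    if kappa <= 0.4:
        return "Fair"
    if kappa <= 0.6:
        return "Moderate"
    if kappa <= 0.8:
        return "Good"
    return "Excellent"


@dataclass(frozen=True)
class PairAgreement:
    """Partial agreement between two raters."""

    mean_abs_diff_ms: float
    sd_abs_diff_ms: float
    percent_matched: float


def partial_agreement(table: RatingTable, rater_a: str, rater_b: str) -> PairAgreement:
    """Mean absolute TI difference (with SD) and percent of matched TIs."""
    a = table.selections[rater_a].to_numpy()
    b = table.selections[rater_b].to_numpy()
    diffs = np.abs(a - b)
    return PairAgreement(
        mean_abs_diff_ms=float(diffs.mean()),
        sd_abs_diff_ms=float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
        percent_matched=float((diffs == 0).mean() * 100.0),
    )


@dataclass(frozen=True)
class AgreementReport:
    """Pairwise kappa matrix plus partial agreement for every rater pair."""

    raters: tuple[str, ...]
    kappa_matrix: pd.DataFrame  # symmetric, unit diagonal
    overall_kappa: float  # arithmetic mean of pairwise kappas
    pairwise: dict[tuple[str, str], PairAgreement]
    strength: str

    def to_dict(self) -> dict:
        return {
            "raters": list(self.raters),
            "kappa_matrix": self.kappa_matrix.to_dict(),
            "overall_kappa": self.overall_kappa,
            "strength": self.strength,
            "pairwise": {
                f"{a}|{b}": {
                    "kappa": float(self.kappa_matrix.loc[a, b]),
                    "mean_abs_diff_ms": p.mean_abs_diff_ms,
                    "sd_abs_diff_ms": p.sd_abs_diff_ms,
                    "percent_matched": p.percent_matched,
                }
                for (a, b), p in self.pairwise.items()
            },
        }


def agreement_report(table: RatingTable, raters: Sequence[str] | None = None) -> AgreementReport:
    """Full pairwise agreement analysis over the chosen raters.

    The overall kappa is the arithmetic mean of the pairwise kappas, the
    aggregation used when summarizing one method against several readers.
    """
    raters = tuple(raters) if raters is not None else tuple(table.raters)
    mat = pd.DataFrame(np.eye(len(raters)), index=list(raters), columns=list(raters))
    pairwise: dict[tuple[str, str], PairAgreement] = {}
    kappas = []
    for a, b in itertools.combinations(raters, 2):
        k = fleiss_kappa(table, [a, b])
        mat.loc[a, b] = mat.loc[b, a] = k
        kappas.append(k)
        pairwise[(a, b)] = partial_agreement(table, a, b)
    overall = float(np.mean(kappas))
    return AgreementReport(
        raters=raters,
        kappa_matrix=mat,
        overall_kappa=overall,
        pairwise=pairwise,
        strength=kappa_strength(overall),
    )


def sweep_divisors(start: float = 1.0, stop: float = 4.0, step: float = 0.1) -> list[float]:
    """Arithmetic divisor sequence for the ROI sweep (default: 31 values)."""
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


def roi_sweep(
    series_set: Iterable[ScoutSeries],
    reference_ti_ms: Sequence[float],
    shapes: Sequence[str] = ("rectangle", "circle"),
    divisors: Sequence[float] | None = None,
    threshold_mode: str = "inclusive",
) -> pd.DataFrame:
    """Mean absolute TI difference versus a reference, per ROI configuration.

    Runs the selection on every series for each (shape, divisor) cell and
    compares against the per-series reference TI.  Cells where the ROI is
    degenerate for some series report the count of failures and NaN
    statistics when no series succeeded.

    Returns a DataFrame with columns shape, divisor, mean_abs_diff_ms,
    sd_abs_diff_ms, percent_matched, n, n_failed.
    """
    series_list = list(series_set)
    refs = [float(r) for r in reference_ti_ms]
    if len(series_list) != len(refs):
        raise ValueError("one reference TI per series is required")
    if divisors is None:
        divisors = sweep_divisors()
    rows = []
    for shape in shapes:
        for k in divisors:
            diffs = []
            n_failed = 0
            for series, ref in zip(series_list, refs):
                try:
                    res = select_ti(series, RoiSpec(shape, float(k)), threshold_mode)
                except DegenerateRoiError:
                    n_failed += 1
                    continue
                diffs.append(abs(res.selected_ti_ms - ref))
            arr = np.asarray(diffs, dtype=float)
            rows.append(
                {
                    "shape": shape,
                    "divisor": float(k),
                    "mean_abs_diff_ms": float(arr.mean()) if arr.size else np.nan,
                    "sd_abs_diff_ms": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                    "percent_matched": float((arr == 0).mean() * 100.0) if arr.size else np.nan,
                    "n": int(arr.size),
                    "n_failed": n_failed,
                }
            )
    return pd.DataFrame(rows)


def best_sweep_configuration(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-shape argmin of the sweep's mean absolute TI difference."""
    valid = sweep.dropna(subset=["mean_abs_diff_ms"])
    idx = valid.groupby("shape")["mean_abs_diff_ms"].idxmin()
    return valid.loc[idx].reset_index(drop=True)
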