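"""Poststratification of posterior stratum mortality to population excess.

For each posterior draw, population monthly mortality over a month window
is the census-weighted sum over (age bin, sex, education) strata of the
stratum's window-average monthly death probability; the excess is the
percent change of the pandemic window relative to the month-matched 2019
comparator, computed per draw and then summarized by quantiles (Monte
Carlo propagation of the full posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AGE_BIN_LABELS, N_AGE_BINS, N_EDU, N_MONTHS, N_SEX
from .model import PosteriorDraws


class AggregationError(ValueError):
    pass


@dataclass
class ExcessEstimate:
    """Population-aggregated excess mortality over one window."""

    window: tuple
    comparator: tuple
    mean: float
    ci50: tuple
    ci95: tuple
    baseline_annualized_per_1000: float
    pandemic_annualized_per_1000: float
    by_age_bin: dict = field(default_factory=dict)
    draws: np.ndarray | None = None
    baseline_rate_draws: np.ndarray | None = None   # monthly, per draw
    pandemic_rate_draws: np.ndarray | None = None

    def summary_row(self) -> dict:
        return {
            "window_start": self.window[0], "window_end": self.window[1],
            "mean_percent": self.mean,
            "ci50_low": self.ci50[0], "ci50_high": self.ci50[1],
            "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
            "baseline_annualized_per_1000":
                self.baseline_annualized_per_1000,
            "pandemic_annualized_per_1000":
                self.pandemic_annualized_per_1000,
        }


def _weight_array(weights: pd.DataFrame) -> np.ndarray:
    """Weights as a (age, sex, edu) array; error on missing triples."""
    need = {(a, s, e) for a in range(N_AGE_BINS)
            for s in range(N_SEX) for e in range(N_EDU)}
    have = set(zip(weights["age_bin_index"].astype(int),
                   weights["sex_index"].astype(int),
                   weights["education"].astype(int)))
    missing = sorted(need - have)
    if missing:
        raise AggregationError(
            f"weight table lacks strata: {missing[:6]}"
            + ("..." if len(missing) > 6 else ""))
    w = np.zeros((N_AGE_BINS, N_SEX, N_EDU))
    w[weights["age_bin_index"].astype(int),
      weights["sex_index"].astype(int),
      weights["education"].astype(int)] = weights["weight"].to_numpy()
    return w


def _p_grid(draws: PosteriorDraws) -> np.ndarray:
    n = draws.p.shape[0]
    expected = N_MONTHS * N_AGE_BINS * N_SEX * N_EDU
    if draws.p.shape[1] != expected:
        raise AggregationError(
            f"posterior covers {draws.p.shape[1]} cells, expected the "
            f"full {expected}-cell grid")
    return draws.p.reshape(n, N_MONTHS, N_AGE_BINS, N_SEX, N_EDU)


def _window_mean(p_grid: np.ndarray, window: tuple) -> np.ndarray:
    lo, hi = window
    if not 1 <= lo <= hi <= N_MONTHS:
        raise AggregationError(f"window {window} outside study months")
    return p_grid[:, lo - 1:hi, :, :, :].mean(axis=1)


def _summarize(excess_draws, window, comparator, base_draws, pand_draws,
               keep_draws) -> ExcessEstimate:
    q = np.percentile(excess_draws, [2.5, 25, 75, 97.5])
    return ExcessEstimate(
        window=tuple(window), comparator=tuple(comparator),
        mean=float(np.mean(excess_draws)),
        ci50=(float(q[1]), float(q[2])),
        ci95=(float(q[0]), float(q[3])),
        baseline_annualized_per_1000=float(base_draws.mean() * 12_000),
        pandemic_annualized_per_1000=float(pand_draws.mean() * 12_000),
        draws=np.asarray(excess_draws) if keep_draws else None,
        baseline_rate_draws=np.asarray(base_draws) if keep_draws else None,
        pandemic_rate_draws=np.asarray(pand_draws) if keep_draws else None)


def aggregate_excess(draws: PosteriorDraws, weights: pd.DataFrame,
                     window: tuple = None,
                     keep_draws: bool = True) -> ExcessEstimate:
    """Population excess mortality over ``window`` vs month-matched 2019.

    Per posterior draw: aggregate monthly mortality in a window is
    ``sum_(a,s,e) w_(a,s,e) * mean_(m in window) p[draw, cell]``; the
    excess percent is ``100 * (pandemic / comparator - 1)``.  Absolute
    rates are annualized as rate x 12 x 1000.
    """
    if window is None:
        window = (draws.config.onset_month, N_MONTHS)
    comparator = (window[0] - 12, window[1] - 12)
    if comparator[0] < 1:
        raise AggregationError(
            f"window {window} has no month-matched 2019 comparator")
    w = _weight_array(weights)
    grid = _p_grid(draws)
    pand = np.einsum("nase,ase->n", _window_mean(grid, window), w)
    base = np.einsum("nase,ase->n", _window_mean(grid, comparator), w)
    excess = 100.0 * (pand / base - 1.0)
    return _summarize(excess, window, comparator, base, pand, keep_draws)


def age_specific_excess(draws: PosteriorDraws, weights: pd.DataFrame,
                        window: tuple = None,
                        keep_draws: bool = False) -> dict:
    """Per-age-bin excess with weights renormalized within each bin.

    Bins with zero census weight are flagged absent (entry ``None``)
    rather than reported as zero.
    """
    if window is None:
        window = (draws.config.onset_month, N_MONTHS)
    comparator = (window[0] - 12, window[1] - 12)
    if comparator[0] < 1:
        raise AggregationError(
            f"window {window} has no month-matched 2019 comparator")
    w = _weight_array(weights)
    grid = _p_grid(draws)
    pand_m = _window_mean(grid, window)
    base_m = _window_mean(grid, comparator)
    out = {}
    for a, label in enumerate(AGE_BIN_LABELS):
        wa = w[a]
        tot = wa.sum()
        if tot == 0:
            out[label] = None
            continue
        wa = wa / tot
        pand = np.einsum("nse,se->n", pand_m[:, a], wa)
        base = np.einsum("nse,se->n", base_m[:, a], wa)
        excess = 100.0 * (pand / base - 1.0)
        out[label] = _summarize(excess, window, comparator, base, pand,
                                keep_draws)
    return out


def aggregate_excess_log_odds(draws: PosteriorDraws, weights: pd.DataFrame,
                              window: tuple = None) -> np.ndarray:
    """Per-draw census-weighted mean excess log-odds over the window.

    For each pandemic-window cell the excess log-odds is the logit of its
    posterior death probability minus the logit of its month-matched 2019
    counterpart (same month of year, so seasonal terms cancel); the
    population summary weights cells by census weight and averages over
    window months.  Under a uniform generator effect this recovers the
    injected excess log odds ratio.
    """
    if window is None:
        window = (draws.config.onset_month, N_MONTHS)
    comparator = (window[0] - 12, window[1] - 12)
    if comparator[0] < 1:
        raise AggregationError(
            f"window {window} has no month-matched 2019 comparator")
    w = _weight_array(weights)
    grid = _p_grid(draws)
    lo, hi = window
    with np.errstate(divide="ignore"):
        lp = np.log(grid) - np.log1p(-grid)
    diff = (lp[:, lo - 1:hi] - lp[:, comparator[0] - 1:comparator[1]]
            ).mean(axis=1)
    return np.einsum("nase,ase->n", diff, w)


def sensitivity_windows(draws_by_onset: dict, weights: pd.DataFrame
                        ) -> pd.DataFrame:
    """One aggregate ExcessEstimate row per onset month.

    ``draws_by_onset`` maps an onset study-month to a PosteriorDraws fit
    with that onset; every window ends in October 2020.  A missing fit
    (value ``None``) yields an explicit all-NaN gap row.
    """
    rows = []
    for onset in sorted(draws_by_onset):
        draws = draws_by_onset[onset]
        if draws is None:
            rows.append({"onset_month": onset, "window_start": onset,
                         "window_end": N_MONTHS, "mean_percent": np.nan,
                         "ci50_low": np.nan, "ci50_high": np.nan,
                         "ci95_low": np.nan, "ci95_high": np.nan,
                         "baseline_annualized_per_1000": np.nan,
                         "pandemic_annualized_per_1000": np.nan,
                         "missing": True})
            continue
        est = aggregate_excess(draws, weights, window=(onset, N_MONTHS),
                               keep_draws=False)
        row = {"onset_month": onset, **est.summary_row(), "missing": False}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Economic-impact summary
# ---------------------------------------------------------------------------

@dataclass
class EconSummary:
    income: pd.DataFrame         # per earner type: normal/May/Nov means
    food: pd.DataFrame           # per round: count, denominator, proportion
    excluded_zero_normal: int = 0


def economic_summary(econ: pd.DataFrame) -> EconSummary:
    """Mean incomes per earner type and food-unavailability proportions.

    Percent change is the change of the mean period income relative to the
    mean usual income (ratio of means).  Households reporting zero usual
    income are excluded from the income means and counted.
    """
    if "earner_type" not in econ.columns:
        raise AggregationError("econ table lacks earner_type")
    zero = econ["income_normal"] <= 0
    n_zero = int(econ.loc[zero, "household_id"].nunique())
    df = econ[~zero]

    rows = []
    for etype, grp in df.groupby("earner_type"):
        r1 = grp[grp["round"] == 1]
        r2 = grp[grp["round"] == 2]
        normal = grp.drop_duplicates("household_id")["income_normal"].mean()
        may = r1["income_current"].mean()
        nov = r2["income_current"].mean()
        rows.append({
            "earner_type": etype,
            "income_normal": normal,
            "income_may": may,
            "income_november": nov,
            "percent_change_may": 100.0 * (may / normal - 1.0),
            "percent_change_november": 100.0 * (nov / normal - 1.0),
        })
    income = pd.DataFrame(rows)

    food_rows = []
    for rnd, grp in econ.groupby("round"):
        n = len(grp)
        k = int(grp["food_unavailable"].astype(bool).sum())
        food_rows.append({
            "round": rnd, "count": k, "denominator": n,
            "proportion": k / n if n else 0.0,
            "percent_whole": round(100.0 * k / n) if n else 0,
            "percent_1dp": round(100.0 * k / n, 1) if n else 0.0,
        })
    food = pd.DataFrame(food_rows)
    return EconSummary(income=income, food=food,
                       excluded_zero_normal=n_zero)


# ---------------------------------------------------------------------------
# Tidy outputs
# ---------------------------------------------------------------------------

def excess_table(est: ExcessEstimate) -> pd.DataFrame:
    return pd.DataFrame([est.summary_row()])


def excess_by_age_table(by_age: dict) -> pd.DataFrame:
    rows = []
    for label, est in by_age.items():
        if est is None:
            rows.append({"age_bin": label, "present": False})
        else:
            rows.append({"age_bin": label, "present": True,
                         **est.summary_row()})
    return pd.DataFrame(rows)
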