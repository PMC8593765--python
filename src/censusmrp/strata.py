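"""Person-month tabulation into month x age-bin x sex x education cells.

Every included person contributes one person-month to the cell of their
current age bin, sex, and household education for each month in which
their household is under observation; a death increments the cell of its
month and ends exposure after that month (the death month itself counts a
full person-month, so cell deaths never exceed cell trials).

Observation coverage is household-level: round-1-only households are
covered through April 2020 (month 16), any round-2 respondent through the
end of the window, unreached households not at all.  Age advances on the
census-date anniversary.  Overlooked members count from the start of the
window (they were always present); joiners are excluded entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .census import ReferencePopulation
from .constants import (
    AGE_BIN_LABELS,
    CENSUS_MONTH,
    N_AGE_BINS,
    N_EDU,
    N_MONTHS,
    N_SEX,
    ROUND1_COVERS_THROUGH,
    ROUND2_COVERS_THROUGH,
)


class StrataError(ValueError):
    pass


def assign_age_bin(age):
    """10-year age bin index for an age in years; ages 80+ share one bin."""
    arr = np.asarray(age)
    if np.any(arr < 0):
        raise StrataError("age must be non-negative")
    return np.minimum(arr // 10, N_AGE_BINS - 1).astype(int)


def age_bin_label(age) -> str:
    return AGE_BIN_LABELS[int(assign_age_bin(age))]


def _cell_frame() -> pd.DataFrame:
    """The full 22 x 9 x 2 x 3 cell grid in canonical order."""
    month, age, sex, edu = np.meshgrid(
        np.arange(1, N_MONTHS + 1), np.arange(N_AGE_BINS),
        np.arange(N_SEX), np.arange(N_EDU), indexing="ij")
    return pd.DataFrame({
        "month": month.ravel(),
        "age_bin": np.array(AGE_BIN_LABELS)[age.ravel()],
        "age_bin_index": age.ravel(),
        "sex": np.where(sex.ravel() == 1, "male", "female"),
        "sex_index": sex.ravel(),
        "education": edu.ravel(),
    })


def cell_id(month, age_bin_index, sex_index, education):
    """Row position of a cell in the canonical grid of :func:`_cell_frame`."""
    return (((np.asarray(month) - 1) * N_AGE_BINS
             + np.asarray(age_bin_index)) * N_SEX
            + np.asarray(sex_index)) * N_EDU + np.asarray(education)


def build_strata(ref: ReferencePopulation,
                 window: tuple[int, int] = (1, N_MONTHS)) -> pd.DataFrame:
    """Tabulate deaths and person-month exposure over the cell grid.

    Returns one row per cell (zero cells included) with columns
    ``month, age_bin, sex, education, deaths, exposure`` plus index
    columns, and attaches a coverage report (quarantined persons with
    unknown education) as ``DataFrame.attrs['coverage']``.
    """
    lo, hi = window
    if not (1 <= lo <= hi <= N_MONTHS):
        raise StrataError(f"window must lie within 1..{N_MONTHS}")

    persons = ref.persons
    reach = ref.reach.set_index("household_id")
    cover = pd.Series(0, index=reach.index)
    cover[reach["reached_r1"]] = ROUND1_COVERS_THROUGH
    cover[reach["reached_r2"]] = ROUND2_COVERS_THROUGH

    p = persons[persons["in_reference"]].copy()
    unknown_edu = p["education"].isna()
    coverage_report = {
        "included": int((~unknown_edu).sum()),
        "quarantined_unknown_education": int(unknown_edu.sum()),
    }
    p = p[~unknown_edu]

    hh_cover = p["household_id"].map(cover).fillna(0).to_numpy(int)
    entry = np.maximum(p["entry_month"].to_numpy(int), lo)
    death = p["death_month"].to_numpy(float)
    own = p["own_household_reported"].to_numpy(bool)

    last = np.minimum(hh_cover, hi)
    has_death = ~np.isnan(death)
    last = np.where(has_death, np.minimum(last, np.where(
        has_death, death, N_MONTHS)), last).astype(int)

    age0 = p["age_at_census"].to_numpy(int)
    sex_i = (p["sex"] == "male").to_numpy().astype(int)
    edu_i = p["education"].to_numpy(float).astype(int)

    n_cells = N_MONTHS * N_AGE_BINS * N_SEX * N_EDU
    exposure = np.zeros(n_cells, dtype=np.int64)
    deaths = np.zeros(n_cells, dtype=np.int64)

    months = np.arange(1, N_MONTHS + 1)
    # person x month presence mask, then bincount into flat cell ids
    present = (months[None, :] >= entry[:, None]) & (
        months[None, :] <= last[:, None])
    age_m = age0[:, None] + (months[None, :] - CENSUS_MONTH) // 12
    bins = np.minimum(np.maximum(age_m, 0) // 10, N_AGE_BINS - 1)
    cells = cell_id(months[None, :], bins,
                    sex_i[:, None], edu_i[:, None])
    np.add.at(exposure, cells[present], 1)

    death_ok = (has_death & own
                & (death >= lo) & (death <= np.maximum(last, 0)))
    if death_ok.any():
        dm = death[death_ok].astype(int)
        d_age = age0[death_ok] + (dm - CENSUS_MONTH) // 12
        d_bins = np.minimum(np.maximum(d_age, 0) // 10, N_AGE_BINS - 1)
        d_cells = cell_id(dm, d_bins, sex_i[death_ok], edu_i[death_ok])
        np.add.at(deaths, d_cells, 1)

    out = _cell_frame()
    out["deaths"] = deaths
    out["exposure"] = exposure
    if (out["deaths"] > out["exposure"]).any():
        raise StrataError("cell deaths exceed exposure")
    out.attrs["coverage"] = coverage_report
    return out


def census_weights(census: pd.DataFrame) -> pd.DataFrame:
    """Poststratification weights from the January 2020 census.

    weight(age_bin, sex, education) = census count in that triple divided
    by the total census count; all 9 x 2 x 3 triples are present (zero
    weight where the census has nobody) and weights sum to 1.
    """
    if len(census) == 0:
        raise StrataError("census table is empty")
    bins = assign_age_bin(census["age"].astype(int).to_numpy())
    sex_i = (census["sex"].astype(str) == "male").to_numpy().astype(int)
    edu_i = census["education"].astype(float).astype(int).to_numpy()

    counts = np.zeros((N_AGE_BINS, N_SEX, N_EDU))
    np.add.at(counts, (bins, sex_i, edu_i), 1)
    weights = counts / counts.sum()

    age, sex, edu = np.meshgrid(np.arange(N_AGE_BINS), np.arange(N_SEX),
                                np.arange(N_EDU), indexing="ij")
    return pd.DataFrame({
        "age_bin": np.array(AGE_BIN_LABELS)[age.ravel()],
        "age_bin_index": age.ravel(),
        "sex": np.where(sex.ravel() == 1, "male", "female"),
        "sex_index": sex.ravel(),
        "education": edu.ravel(),
        "weight": weights.ravel(),
        "count": counts.ravel().astype(int),
    })
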