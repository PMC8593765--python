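"""Reference-population construction and death-report cleaning.

The reference population is the January 2020 in-person census roster of
consenting households, augmented with members recorded during the
telephone rounds who had been overlooked in person and with household
members who reportedly died in 2019 (and so could not be censused), and
excluding members who joined a household from elsewhere after the census.

Deaths arrive as name-keyed telephone reports and may be filed by more
than one household — typically for an elderly parent — so reports are
merged when the normalized name matches exactly, reported ages differ by
at most 2 years, and reported death months differ by at most 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CAUSE_LABELS, N_MONTHS, year_of_month


class ProcessingError(ValueError):
    pass


_PUNCT = re.compile(r"[^a-z0-9]+")


def normalize_name(name: str) -> str:
    """Deterministic decedent-name key: lowercase, strip punctuation/space."""
    return _PUNCT.sub("", str(name).lower())


# ---------------------------------------------------------------------------
# Round-table parsing
# ---------------------------------------------------------------------------

_DEATH_COLS = ["reporting_household", "name", "age", "sex", "death_month",
               "cause", "injury", "consulted_doctor", "died_in_hospital",
               "symptoms"]


def _to_bool(s: pd.Series) -> pd.Series:
    return s.astype(str).str.lower().isin(["true", "1", "1.0", "yes"])


def split_round(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a row-typed telephone-round table into reach / member / death."""
    df = df.copy()
    out = {}
    reach = df[df["record_type"] == "reach"]
    out["reach"] = pd.DataFrame({
        "household_id": reach["household_id"].astype(int).to_numpy(),
        "reached": reach["reached"].astype(float).astype(int).to_numpy(),
    })
    mem = df[df["record_type"] == "member"].copy()
    if len(mem):
        mem = pd.DataFrame({
            "household_id": mem["household_id"].astype(int).to_numpy(),
            "person_id": mem["person_id"].astype(float).astype(int).to_numpy(),
            "name": mem["name"].astype(str).to_numpy(),
            "age": mem["age"].astype(float).astype(int).to_numpy(),
            "sex": mem["sex"].astype(str).to_numpy(),
            "member_status": mem["member_status"].astype(str).to_numpy(),
            "entry_month": pd.to_numeric(
                mem["entry_month"], errors="coerce").to_numpy(),
        })
    else:
        mem = pd.DataFrame(columns=["household_id", "person_id", "name",
                                    "age", "sex", "member_status",
                                    "entry_month"])
    out["member"] = mem
    death = df[df["record_type"] == "death"].copy()
    if len(death):
        death = pd.DataFrame({
            "reporting_household": death["reporting_household"]
                .astype(float).astype(int).to_numpy(),
            "name": death["name"].astype(str).to_numpy(),
            "age": death["age"].astype(float).astype(int).to_numpy(),
            "sex": death["sex"].astype(str).to_numpy(),
            "death_month": death["death_month"]
                .astype(float).astype(int).to_numpy(),
            "cause": death["cause"].astype(str).to_numpy(),
            "injury": _to_bool(death["injury"]).to_numpy(),
            "consulted_doctor": _to_bool(
                death["consulted_doctor"]).to_numpy(),
            "died_in_hospital": _to_bool(
                death["died_in_hospital"]).to_numpy(),
            "symptoms": death["symptoms"].fillna("").astype(str).to_numpy(),
        })
    else:
        death = pd.DataFrame(columns=_DEATH_COLS)
    out["death"] = death
    return out


# ---------------------------------------------------------------------------
# Death-report deduplication
# ---------------------------------------------------------------------------

AGE_TOLERANCE = 2
MONTH_TOLERANCE = 1


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, i):
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.p[max(ri, rj)] = min(ri, rj)


def _modal(values, canonical):
    vals = pd.Series(list(values))
    counts = vals.value_counts()
    top = counts[counts == counts.iloc[0]].index
    return canonical if canonical in top else top[0]


def deduplicate_death_reports(
        reports: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge duplicate death reports into unique deaths.

    Two reports refer to the same death when their normalized names match
    exactly, |age difference| <= 2 years and |death-month difference| <= 1
    (merging is transitive within a name group).  The merged record takes
    its identity fields (name, age, death month) verbatim from a canonical
    member report — earliest death month, then lowest age, then input
    order — which makes deduplication idempotent; cause and the boolean
    context fields are modal across reports, with cause disagreements
    returned as a conflict log.

    Returns ``(unique_deaths, conflicts)``.
    """
    if len(reports) == 0:
        empty = reports.copy()
        empty["name_norm"] = pd.Series(dtype=str)
        empty["reporting_households"] = pd.Series(dtype=object)
        empty["n_reports"] = pd.Series(dtype=int)
        return empty, pd.DataFrame(columns=["name_norm", "causes"])

    df = reports.reset_index(drop=True).copy()
    df["name_norm"] = df["name"].map(normalize_name)
    uf = _UnionFind(len(df))
    for _, grp in df.groupby("name_norm"):
        idx = grp.index.to_numpy()
        ages = grp["age"].to_numpy()
        months = grp["death_month"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if (abs(int(ages[a]) - int(ages[b])) <= AGE_TOLERANCE
                        and abs(int(months[a]) - int(months[b]))
                        <= MONTH_TOLERANCE):
                    uf.union(idx[a], idx[b])

    df["_cluster"] = [uf.find(i) for i in range(len(df))]
    rows, conflicts = [], []
    for _, grp in df.groupby("_cluster"):
        grp = grp.sort_values(
            ["death_month", "age"], kind="stable")
        canon = grp.iloc[0]
        causes = grp["cause"].tolist()
        if len(set(causes)) > 1:
            conflicts.append({"name_norm": canon["name_norm"],
                              "causes": sorted(set(causes))})
        rows.append({
            "name": canon["name"],
            "name_norm": canon["name_norm"],
            "age": int(canon["age"]),
            "sex": canon["sex"],
            "death_month": int(canon["death_month"]),
            "cause": _modal(causes, canon["cause"]),
            "injury": bool(_modal(grp["injury"], canon["injury"])),
            "consulted_doctor": bool(
                _modal(grp["consulted_doctor"], canon["consulted_doctor"])),
            "died_in_hospital": bool(
                _modal(grp["died_in_hospital"], canon["died_in_hospital"])),
            "symptoms": canon["symptoms"],
            "reporting_households": tuple(
                sorted(set(grp["reporting_household"].astype(int)))),
            "n_reports": len(grp),
        })
    unique = pd.DataFrame(rows).reset_index(drop=True)
    return unique, pd.DataFrame(conflicts)


# ---------------------------------------------------------------------------
# Reference population
# ---------------------------------------------------------------------------

@dataclass
class ReferencePopulation:
    """Cleaned person roster plus reach outcomes and unique deaths."""

    persons: pd.DataFrame
    reach: pd.DataFrame                      # household_id, reached_r1/r2
    unique_deaths: pd.DataFrame
    counts: dict = field(default_factory=dict)
    quarantine: pd.DataFrame = field(default_factory=pd.DataFrame)
    conflicts: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_reference_population(census: pd.DataFrame,
                               round1: pd.DataFrame,
                               round2: pd.DataFrame) -> ReferencePopulation:
    """Assemble the reference population from the three survey tables.

    Census-listed members, overlooked members, and 2019 decedents are
    included; joiners are kept in the roster but flagged excluded.  Member
    updates whose household never appears in the census or reach records
    are quarantined rather than silently dropped.  Deaths are deduplicated
    and linked to roster persons by normalized name within the reporting
    households; an unlinked death becomes a new person record (a 2019
    decedent when the death month is pre-census).
    """
    r1 = split_round(round1)
    r2 = split_round(round2)

    reach = pd.merge(
        r1["reach"].rename(columns={"reached": "reached_r1"}),
        r2["reach"].rename(columns={"reached": "reached_r2"}),
        on="household_id", how="outer").fillna(0)
    reach["reached_r1"] = reach["reached_r1"].astype(bool)
    reach["reached_r2"] = reach["reached_r2"].astype(bool)
    known_households = set(census["household_id"].astype(int)) | set(
        reach["household_id"].astype(int))

    hh_edu = (census.groupby("household_id")["education"].first()
              .astype(float))

    persons = pd.DataFrame({
        "person_id": census["person_id"].astype(int).to_numpy(),
        "household_id": census["household_id"].astype(int).to_numpy(),
        "name": census["name"].astype(str).to_numpy(),
        "sex": census["sex"].astype(str).to_numpy(),
        "age_at_census": census["age"].astype(int).to_numpy(),
        "education": census["education"].astype(float).to_numpy(),
        "provenance": "census_listed",
        "entry_month": 1,
    })

    quarantined = []
    extras = []
    for mem, rnd in ((r1["member"], 1), (r2["member"], 2)):
        if not len(mem):
            continue
        known = mem["household_id"].astype(int).isin(known_households)
        for row in mem[~known].itertuples():
            quarantined.append({
                "reason": "unknown_household", "round": rnd,
                "household_id": row.household_id, "name": row.name})
        ok = mem[known]
        prov = np.where(ok["member_status"] == "joiner",
                        "joiner", "overlooked")
        entry = np.where(
            (prov == "joiner") & ok["entry_month"].notna(),
            ok["entry_month"].fillna(1), 1).astype(int)
        extras.append(pd.DataFrame({
            "person_id": ok["person_id"].astype(int).to_numpy(),
            "household_id": ok["household_id"].astype(int).to_numpy(),
            "name": ok["name"].to_numpy(),
            "sex": ok["sex"].to_numpy(),
            "age_at_census": ok["age"].astype(int).to_numpy(),
            "education": ok["household_id"].astype(int).map(hh_edu)
                .to_numpy(float),
            "provenance": prov,
            "entry_month": entry,
        }))
    if extras:
        persons = pd.concat([persons] + extras, ignore_index=True)
    # a member reported in both rounds enters once
    persons = persons.drop_duplicates("person_id", keep="first")

    reports = pd.concat([r1["death"], r2["death"]], ignore_index=True)
    unique_deaths, conflicts = deduplicate_death_reports(reports)

    persons = persons.reset_index(drop=True)
    persons["name_norm"] = persons["name"].map(normalize_name)
    persons["death_month"] = np.nan
    persons["reported_by"] = [() for _ in range(len(persons))]
    persons["own_household_reported"] = False

    roster = {(h, n): i for i, (h, n) in enumerate(
        zip(persons["household_id"], persons["name_norm"]))}
    next_pid = int(persons["person_id"].max()) + 1 if len(persons) else 0

    new_rows = []
    death_person = []
    for d in unique_deaths.itertuples():
        homes = d.reporting_households
        hit = None
        for h in homes:
            hit = roster.get((h, d.name_norm))
            if hit is not None:
                break
        if hit is not None:
            persons.at[hit, "death_month"] = d.death_month
            persons.at[hit, "reported_by"] = homes
            persons.at[hit, "own_household_reported"] = (
                persons.at[hit, "household_id"] in homes)
            death_person.append(persons.at[hit, "person_id"])
        else:
            prov = ("decedent_2019" if year_of_month(d.death_month) == 2019
                    else "overlooked")
            home = homes[0]
            # invert the census-anniversary age convention: the report
            # carries age at death, one year lower for pre-census deaths
            age_census = int(d.age) - (int(d.death_month) - 13) // 12
            new_rows.append({
                "person_id": next_pid,
                "household_id": home,
                "name": d.name,
                "sex": d.sex,
                "age_at_census": age_census,
                "education": float(hh_edu.get(home, np.nan)),
                "provenance": prov,
                "entry_month": 1,
                "name_norm": d.name_norm,
                "death_month": float(d.death_month),
                "reported_by": homes,
                "own_household_reported": True,
            })
            death_person.append(next_pid)
            next_pid += 1
    if new_rows:
        persons = pd.concat([persons, pd.DataFrame(new_rows)],
                            ignore_index=True)
    unique_deaths = unique_deaths.copy()
    unique_deaths["person_id"] = death_person

    persons["in_reference"] = persons["provenance"] != "joiner"
    counts = persons["provenance"].value_counts().to_dict()
    counts["reference_size"] = int(persons["in_reference"].sum())

    return ReferencePopulation(
        persons=persons, reach=reach, unique_deaths=unique_deaths,
        counts=counts,
        quarantine=pd.DataFrame(quarantined), conflicts=conflicts)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def annualized_mortality_rate(deaths: int, population: int,
                              months: int) -> float:
    """Deaths per 1000 individuals per year: deaths/pop * (12/months) * 1000."""
    if population <= 0:
        raise ProcessingError("annualized rate undefined for population <= 0")
    if months <= 0:
        raise ProcessingError("annualized rate undefined for months <= 0")
    return deaths / population * (12.0 / months) * 1000.0


def death_year(death_month: int) -> int:
    if not 1 <= death_month <= N_MONTHS:
        raise ProcessingError(
            f"death month {death_month} outside study window 1..{N_MONTHS}")
    return year_of_month(death_month)


def _pct_entry(count: int, denom: int) -> dict:
    pct = 100.0 * count / denom if denom else 0.0
    return {"count": int(count), "denominator": int(denom),
            "percent": pct, "percent_whole": round(pct),
            "percent_1dp": round(pct, 1)}


def tabulate_death_context(unique_deaths: pd.DataFrame, year: int) -> dict:
    """Counts and proportions of death circumstances for one calendar year.

    Reports doctor/nurse consultation, in-hospital death, injury, each
    cause category, and — among lung-disease deaths — the total number of
    pandemic-typical symptom mentions.  Denominator is the number of
    unique deaths in that year.
    """
    if year not in (2019, 2020):
        raise ProcessingError("year must be 2019 or 2020")
    d = unique_deaths[
        unique_deaths["death_month"].map(death_year) == year]
    n = len(d)
    out = {
        "year": year,
        "n_deaths": n,
        "consulted_doctor": _pct_entry(d["consulted_doctor"].sum(), n),
        "died_in_hospital": _pct_entry(d["died_in_hospital"].sum(), n),
        "injury": _pct_entry(d["injury"].sum(), n),
        "causes": {},
    }
    causes = list(CAUSE_LABELS) + sorted(
        set(d["cause"]) - set(CAUSE_LABELS))
    for cause in causes:
        out["causes"][cause] = _pct_entry((d["cause"] == cause).sum(), n)
    lung = d[d["cause"] == "lung"]
    mentions = int(sum(len([s for s in str(row).split(";") if s])
                       for row in lung["symptoms"]))
    out["lung_symptom_mentions"] = mentions
    return out
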