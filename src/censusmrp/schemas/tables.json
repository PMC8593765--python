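{
  "version": "1.0",
  "encoding": "UTF-8, RFC 4180 CSV",
  "tables": {
    "census.csv": {
      "description": "January 2020 in-person census roster, one row per listed member",
      "columns": {
        "household_id": "integer household identifier",
        "person_id": "integer person identifier, unique across tables",
        "name": "member name as recorded (free text)",
        "age": "age in completed years at the census",
        "sex": "male | female",
        "education": "household education band: 0 none, 1 primary, 2 secondary+"
      }
    },
    "round1.csv / round2.csv": {
      "description": "telephone round, row-typed via record_type",
      "columns": {
        "record_type": "reach | member | death",
        "household_id": "household the record refers to (reach/member rows)",
        "reached": "reach rows: 1 if the household responded, else 0",
        "person_id": "member rows: assigned person identifier",
        "name": "member or decedent name as reported",
        "age": "member age at census / decedent age at death",
        "sex": "male | female",
        "member_status": "member rows: overlooked | joiner",
        "entry_month": "member rows (joiners): study month 13..22 of arrival",
        "reporting_household": "death rows: household filing the report",
        "death_month": "death rows: study month 1..22 of the death",
        "cause": "stroke_heart | cancer | liver | lung | injury | other",
        "injury": "death rows: True if death resulted from injury",
        "consulted_doctor": "death rows: doctor/nurse consulted before death",
        "died_in_hospital": "death rows: death occurred at a hospital",
        "symptoms": "death rows: semicolon-separated symptom list"
      }
    },
    "econ.csv": {
      "description": "economic-impact module, one row per sampled household-round",
      "columns": {
        "household_id": "integer household identifier",
        "round": "1 (May 2020) | 2 (November 2020)",
        "earner_type": "salaried | self_employed (primary income earner)",
        "income_normal": "usual monthly income, BDT",
        "income_current": "income in the round's reference month, BDT",
        "food_unavailable": "could not obtain an essential food item"
      }
    },
    "strata.csv": {
      "description": "one row per month x age-bin x sex x education cell",
      "columns": {
        "month": "study month 1 (Jan 2019) .. 22 (Oct 2020)",
        "age_bin": "0-9 .. 70-79, 80+",
        "age_bin_index": "0..8",
        "sex": "male | female",
        "sex_index": "0 female, 1 male",
        "education": "0 | 1 | 2",
        "deaths": "deaths observed in the cell",
        "exposure": "person-months under observation in the cell"
      }
    },
    "weights.csv": {
      "description": "census poststratification weights per (age bin, sex, education)",
      "columns": {
        "age_bin": "0-9 .. 80+",
        "age_bin_index": "0..8",
        "sex": "male | female",
        "sex_index": "0 female, 1 male",
        "education": "0 | 1 | 2",
        "weight": "census share, sums to 1 over all 54 triples",
        "count": "census head count in the triple"
      }
    }
  }
}
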