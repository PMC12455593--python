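# Cohort column schema: names, types, units, level sets, and feature groups.
# All I/O validates against this file. CSV: RFC 4180, UTF-8, "." decimal,
# empty cell = missing.
schema_version: "1.0"
id_column: id
columns:
  id:
    type: string
    role: id
  school_type:
    type: categorical
    role: predictor
    group: demog
    levels: [primary, middle, high]
  parental_myopia:
    type: categorical
    role: predictor
    group: demog
    levels: [neither, either]
  sex:
    type: categorical
    role: predictor
    group: demog
    levels: [female, male]
  bmi:
    type: numeric
    role: predictor
    group: demog
    unit: kg/m^2
    min: 0.0
  sleep_duration:
    type: numeric
    role: predictor
    group: habit
    unit: hours/night
    min: 0.0
  homework_hour:
    type: numeric
    role: predictor
    group: habit
    unit: hours/day
    min: 0.0
  outdoor_hour:
    type: categorical
    role: predictor
    group: habit
    levels: ["<1", "1-2", "2-3", ">3"]
  rubbing:
    type: categorical
    role: predictor
    group: habit
    levels: [never, sometimes, frequent, always]
  ballgame:
    type: numeric
    role: predictor
    group: habit
    unit: kinds (0-5)
    min: 0.0
    max: 5.0
  reading_distance:
    type: categorical
    role: predictor
    group: habit
    levels: ["<1ft", ">=1ft"]
  green_frequency:
    type: categorical
    role: predictor
    group: habit
    levels: [never, few_per_year, monthly_plus, almost_daily]
  seat_row:
    type: categorical
    role: predictor
    group: habit
    levels: ["1-3", "4-6", "7-10"]
  transportation:
    type: categorical
    role: predictor
    group: habit
    levels: [nonmotorized, private_car, public_transport, residential]
  seafood_intake:
    type: categorical
    role: predictor
    group: habit
    levels: [hardly_ever, lt1_per_week, 2_3_per_week, 4_6_per_week, 1_per_day, 2plus_per_day]
  beverage_intake:
    type: categorical
    role: predictor
    group: habit
    levels: [hardly_ever, lt1_per_week, 2_3_per_week, 4_6_per_week, 1_per_day, 2plus_per_day]
  salt_intake:
    type: categorical
    role: predictor
    group: habit
    levels: ["<4g", "4-6g", ">6g"]
  nightlight:
    type: numeric
    role: predictor
    group: environ
    unit: nW cm^-2 sr^-1
    min: 0.0
  ndvi:
    type: numeric
    role: predictor
    group: environ
    unit: dimensionless
    min: -1.0
    max: 1.0
  no2:
    type: numeric
    role: predictor
    group: environ
    unit: ug/m^3
    min: 0.0
  pm25:
    type: numeric
    role: predictor
    group: environ
    unit: ug/m^3
    min: 0.0
  ucva:
    type: numeric
    role: outcome
    unit: 5-point logarithmic chart
    min: 3.0
    max: 5.3
  sphere:
    type: numeric
    role: outcome
    unit: diopters
  cylinder:
    type: numeric
    role: outcome
    unit: diopters
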