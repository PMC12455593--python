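n: 10000
seed: 20260925
base_ucva: 4.5
noise_sd: 0.3
categorical_marginals:
  school_type:
    primary: 0.700744
    middle: 0.211171
    high: 0.088085
  parental_myopia:
    neither: 0.355077
    either: 0.644923
  sex:
    female: 0.480531
    male: 0.519469
  outdoor_hour:
    <1: 0.266725
    1-2: 0.538887
    2-3: 0.146375
    '>3': 0.048013
  rubbing:
    never: 0.142538
    sometimes: 0.774982
    frequent: 0.075073
    always: 0.007407
  reading_distance:
    <1ft: 0.207134
    '>=1ft': 0.792866
  green_frequency:
    never: 0.043676
    few_per_year: 0.20353
    monthly_plus: 0.573988
    almost_daily: 0.178806
  seat_row:
    1-3: 0.437022
    4-6: 0.436489
    7-10: 0.126489
  transportation:
    nonmotorized: 0.573855
    private_car: 0.345734
    public_transport: 0.071636
    residential: 0.008775
  seafood_intake:
    hardly_ever: 0.120516
    lt1_per_week: 0.297721
    2_3_per_week: 0.479231
    4_6_per_week: 0.074472
    1_per_day: 0.019552
    2plus_per_day: 0.008508
  beverage_intake:
    hardly_ever: 0.371558
    lt1_per_week: 0.368156
    2_3_per_week: 0.2065
    4_6_per_week: 0.03073
    1_per_day: 0.015415
    2plus_per_day: 0.007641
  salt_intake:
    <4g: 0.157619
    4-6g: 0.788429
    '>6g': 0.053952
numeric_marginals:
  bmi:
    dist: normal
    mean: 17.8
    sd: 3.4
    meanlog: null
    sdlog: null
    a: null
    b: null
    low: null
    high: null
    min: 10.0
    max: 40.0
    values: null
    probs: null
  sleep_duration:
    dist: normal
    mean: 9.2
    sd: 0.75
    meanlog: null
    sdlog: null
    a: null
    b: null
    low: null
    high: null
    min: 5.0
    max: 12.0
    values: null
    probs: null
  homework_hour:
    dist: normal
    mean: 1.5
    sd: 0.8
    meanlog: null
    sdlog: null
    a: null
    b: null
    low: null
    high: null
    min: 0.0
    max: 6.0
    values: null
    probs: null
  ballgame:
    dist: discrete
    mean: null
    sd: null
    meanlog: null
    sdlog: null
    a: null
    b: null
    low: null
    high: null
    min: null
    max: null
    values:
    - 0.0
    - 1.0
    - 2.0
    - 3.0
    - 4.0
    - 5.0
    probs:
    - 0.285943
    - 0.461245
    - 0.184145
    - 0.05492
    - 0.011044
    - 0.002703
  nightlight:
    dist: lognormal
    mean: null
    sd: null
    meanlog: 3.963
    sdlog: 1.2
    a: null
    b: null
    low: null
    high: null
    min: 0.0
    max: 400.0
    values: null
    probs: null
  ndvi:
    dist: beta_scaled
    mean: null
    sd: null
    meanlog: null
    sdlog: null
    a: 2.0
    b: 3.0
    low: 0.15
    high: 0.4
    min: null
    max: null
    values: null
    probs: null
pollutants:
  no2:
    mean: 36.5
    sd: 1.8
  pm25:
    mean: 38.3
    sd: 1.2
pollutant_rho: 0.5
categorical_effects:
  school_type:
    primary: 0.11
    middle: -0.26
    high: -0.38
  parental_myopia:
    neither: 0.04
    either: -0.04
  sex:
    female: -0.03
    male: 0.03
  outdoor_hour:
    <1: -0.03
    1-2: 0.0
    2-3: 0.03
    '>3': 0.05
  rubbing:
    never: 0.02
    sometimes: 0.0
    frequent: -0.04
    always: -0.06
  reading_distance:
    <1ft: -0.04
    '>=1ft': 0.01
  green_frequency:
    never: -0.03
    few_per_year: -0.01
    monthly_plus: 0.01
    almost_daily: 0.03
  seat_row:
    1-3: 0.01
    4-6: 0.0
    7-10: -0.01
  transportation:
    nonmotorized: 0.0
    private_car: 0.0
    public_transport: 0.0
    residential: 0.0
  seafood_intake:
    hardly_ever: 0.0
    lt1_per_week: 0.0
    2_3_per_week: 0.0
    4_6_per_week: 0.0
    1_per_day: 0.0
    2plus_per_day: 0.0
  beverage_intake:
    hardly_ever: 0.01
    lt1_per_week: 0.0
    2_3_per_week: -0.01
    4_6_per_week: -0.02
    1_per_day: -0.02
    2plus_per_day: -0.03
  salt_intake:
    <4g: 0.0
    4-6g: 0.0
    '>6g': 0.0
numeric_effects:
  bmi:
    slope: -0.002
    center: 17.6
  sleep_duration:
    slope: 0.025
    center: 9.2
  homework_hour:
    slope: -0.035
    center: 1.5
  ballgame:
    slope: 0.01
    center: 1.0
  nightlight:
    slope: -0.0004
    center: 52.0
  ndvi:
    slope: 0.5
    center: 0.245
pollutant_effects:
  no2: -0.01
  pm25: -0.012
school_multiplier:
  primary: 1.25
  middle: 0.6
  high: 0.5
sphere_map:
  intercept: 0.83
  slope: 3.2
  quad: 8.0
  knot: 4.5
  noise_sd: 0.8
cylinder_sd: 0.4
missing_rates:
  bmi: 0.0377
  homework_hour: 0.039
  outdoor_hour: 0.048
  sleep_duration: 0.0324
  ndvi: 0.0015
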