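# Machine-readable schemas of the two CSV tables soiltrial exchanges.
# Encoding UTF-8, header row required, "." decimal separator.

yields:
  description: long format, one row per plot-year
  columns:
    plot_id: {type: string, description: opaque plot identifier}
    block: {type: integer, min: 1, description: replicate block index}
    treatment: {type: string, values: [CK, CF, M1, M2, M3]}
    year: {type: integer, description: calendar year of harvest}
    yield: {type: number, unit: kg/ha, min: 0, description: seed-cotton yield}
  key: [plot_id, year]

soil:
  description: wide format, one row per plot, final-year indicator panel
  columns:
    plot_id: {type: string}
    treatment: {type: string, values: [CK, CF, M1, M2, M3]}
    bulk_density: {type: number, unit: g/cm3, min_exclusive: 0, aliases: [BD, soil_bulk_density]}
    ph: {type: number, unit: unitless, range_exclusive: [0, 14], aliases: [pH, soil_ph]}
    organic_matter: {type: number, unit: g/kg, min: 0, aliases: [SOM, OM, soil_organic_matter]}
    total_n: {type: number, unit: g/kg, min: 0, aliases: [TN, total_nitrogen]}
    ammonium_n: {type: number, unit: mg/kg, min: 0, aliases: [NH4-N, ammonium_nitrogen]}
    nitrate_n: {type: number, unit: mg/kg, min: 0, aliases: [NO3-N, nitrate_nitrogen]}
    alkali_n: {type: number, unit: mg/kg, min: 0, aliases: [Alkali-N, alkali_hydrolyzable_n, AHN]}
    available_p: {type: number, unit: mg/kg, min: 0, aliases: [AP, available_phosphorus]}
    available_k: {type: number, unit: mg/kg, min: 0, aliases: [AK, available_potassium]}
    urease: {type: number, unit: activity, min: 0, aliases: [Ur]}
    catalase: {type: number, unit: activity, min: 0, aliases: [CAT]}
    alkaline_phosphatase: {type: number, unit: activity, min: 0, aliases: [ALP]}
  key: [plot_id]
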