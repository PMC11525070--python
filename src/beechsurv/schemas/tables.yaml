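# Column schemas for the three CSV interchange tables.

trees.csv:
  description: >
    Long form, one row per tree x measurement. Diameter gaps are empty
    cells, never zero. Status is absorbing for death. Extra columns (e.g.
    species) are tolerated and ignored: the analysis is single-species.
  columns:
    tree_id: {type: string, description: opaque tree identifier, unique within the table}
    plot_id: {type: string, description: plot the tree belongs to}
    subplot: {type: integer, range: [1, 16], description: 5 m x 5 m cell on the 4x4 plot grid, row-major}
    year: {type: integer, description: measurement year; must be a schedule year}
    diameter_mm: {type: float, unit: mm, description: diameter at 1.4 m; empty if not measured}
    status: {type: string, values: [alive, dead, not-yet-tagged]}

plots.csv:
  description: One row per 0.04 ha (20 m x 20 m) plot.
  columns:
    plot_id: {type: string}
    transect_id: {type: string}
    elevation_m: {type: float, unit: m, range: [640, 1417]}
    slope_deg: {type: float, unit: degrees}
    landform_index: {type: float, unit: degrees, description: terrain-shape index; low = exposed ridge, high = sheltered downslope}
    soil_avP_ug_g: {type: float, unit: ug/g, description: soil-available P, positive}
    epicentre_distance_km: {type: float, unit: km, description: distance from the earthquake epicentre, positive}

observations.csv:
  description: >
    One row per tree x survival interval, model-ready. Standardized
    covariates use the fixed study constants (basal area - 50 m2/ha,
    diameter - 164 mm, ln soil P - 2.7, landform - 20 deg,
    ln distance - 2.9, (elevation - 1000 m)/100 m); growth covariates are
    raw mm/yr.
  columns:
    tree_id: {type: string}
    plot_id: {type: string}
    start_year: {type: integer}
    end_year: {type: integer}
    delta_t_years: {type: float, unit: years}
    period_index: {type: integer, values: [1, 2, 3], description: 1 pre-earthquake, 2 = 0-5 yr post, 3 = 5+ yr post}
    outcome: {type: integer, values: [0, 1], description: 1 if alive at end_year}
    diameter_std: {type: float, description: diameter - 164 mm at interval start}
    diameter_sq_std: {type: float, description: diameter_std squared}
    local_ba_std: {type: float, description: local basal area (15 m x 15 m window) - 50 m2/ha}
    growth_prev: {type: float, unit: mm/yr, description: annual growth in the window ending at interval start; may be negative}
    growth_lag: {type: float, unit: mm/yr, description: annual growth in the window before previous}
    soil_p_std: {type: float}
    landform_std: {type: float}
    elevation_std: {type: float}
    distance_std: {type: float}
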