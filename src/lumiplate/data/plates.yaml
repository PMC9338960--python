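# Built-in plate registry.
#
# The 96-well entry (9 mm pitch, 6.38 mm well diameter) matches the
# device characterization; the other formats carry common ANSI/SLAS
# footprint catalogue dimensions and may be overridden by a user
# registry with the same layout.
plates:
  96-well:
    n_well_rows: 8
    n_well_cols: 12
    well_pitch_mm: 9.0
    well_diameter_mm: 6.38
    geometry_kind: circular_well
  48-well:
    n_well_rows: 6
    n_well_cols: 8
    well_pitch_mm: 13.0
    well_diameter_mm: 11.05
    geometry_kind: circular_well
  24-well:
    n_well_rows: 4
    n_well_cols: 6
    well_pitch_mm: 19.3
    well_diameter_mm: 15.6
    geometry_kind: circular_well
  12-well:
    n_well_rows: 3
    n_well_cols: 4
    well_pitch_mm: 26.01
    well_diameter_mm: 22.11
    geometry_kind: circular_well
  6-well:
    n_well_rows: 2
    n_well_cols: 3
    well_pitch_mm: 39.12
    well_diameter_mm: 34.8
    geometry_kind: circular_well
  dish-100mm:
    n_well_rows: 1
    n_well_cols: 1
    well_pitch_mm: 86.8
    well_diameter_mm: 86.8
    geometry_kind: dish
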