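# Penetration dataset — CSV column dictionary

UTF-8, comma-separated, one header row; an empty cell means missing.
One row is one penetration experiment.  Concentration must be reported
in a single declared unit per file (µg/mL in all shipped data); the
package does not convert units.

| column | type | unit / levels | notes |
|---|---|---|---|
| `source_id` | text | — | provenance tag, free text |
| `depth` | enum | Surface, SC, Epidermis, Dermis, Distant | layer where most NPs accumulated; follicular penetration counts as Dermis |
| `core_diameter_nm` | float > 0 | nm | bare-particle diameter |
| `shape` | enum | sphere, rod, other | `other` is treated as a sphere for geometry |
| `rod_length_nm` | float > 0 | nm | rods only, else empty |
| `surface_area_nm2` | float | nm² | derivable from diameter + shape |
| `volume_nm3` | float | nm³ | derivable |
| `sv_ratio_per_nm` | float | nm⁻¹ | surface-to-volume ratio; 6/d for spheres |
| `concentration_ug_ml` | float > 0 | µg/mL | may be missing |
| `medium` | enum | aqueous, oil, emulsion, other | dispersion medium |
| `np_class` | enum | inorganic, polymeric, other | material class |
| `hydrophobicity_value` | float | logKow or degrees | may be missing |
| `hydrophobicity_scale` | enum | logKow, contact_angle_deg | logKow for polymeric/other, contact angle for inorganic |
| `species` | enum | human, pig, rat, mouse, rabbit | |
| `region` | enum | face, abdomen, arm, back, breast, ear, other | body site |
| `sc_thickness_um` | float > 0 | µm | stratum corneum |
| `epidermis_thickness_um` | float > 0 | µm | viable epidermis |
| `dermis_thickness_um` | float > 0 | µm | |
| `hf_density_per_cm2` | float > 0 | cm⁻² | hair-follicle density |
| `hf_diameter_um` | float in [5, 500] | µm | follicular opening diameter |
| `lipid_lipophilicity` | float | — | mass-weighted mean over SC lipids |
| `lipid_polarity` | float | — | mass-weighted mean over SC lipids |
| `temperature_c` | float in [15, 45] | °C | may be missing |
| `contact_time_h` | float > 0 | hours | may be missing |
| `in_vivo` | bool | True/False | False = ex vivo |

The skin-reference table (`npskin.synth.builtin_skin_reference`) uses
the same skin columns keyed by (`species`, `region`) plus `n_sources`,
the number of literature values averaged per cell (≥ 3).
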