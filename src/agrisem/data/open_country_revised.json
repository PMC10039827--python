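{
  "name": "open_country",
  "nodes": [
    {"name": "cropland", "family": "gaussian"},
    {"name": "perennial_forages_grassland", "family": "gaussian"},
    {"name": "mean_field_size", "family": "gaussian"},
    {"name": "hedgerow", "family": "gaussian"},
    {"name": "forest_edge", "family": "gaussian"},
    {"name": "open_country_richness", "family": "poisson"}
  ],
  "links": [
    {"source": "cropland", "target": "mean_field_size", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "cropland", "target": "perennial_forages_grassland", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "mean_field_size", "target": "hedgerow", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "mean_field_size", "target": "open_country_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "perennial_forages_grassland", "target": "open_country_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "hedgerow", "target": "open_country_richness", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "forest_edge", "target": "open_country_richness", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "cropland", "target": "hedgerow", "form": "linear", "predicted_sign": "none", "provenance": "added"},
    {"source": "cropland", "target": "forest_edge", "form": "linear", "predicted_sign": "none", "provenance": "added"},
    {"source": "cropland", "target": "open_country_richness", "form": "linear", "predicted_sign": "none", "provenance": "added"}
  ]
}
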