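{
  "name": "forest",
  "nodes": [
    {"name": "cropland", "family": "gaussian"},
    {"name": "mean_field_size", "family": "gaussian"},
    {"name": "forest", "family": "gaussian"},
    {"name": "hedgerow", "family": "gaussian"},
    {"name": "forest_edge", "family": "gaussian"},
    {"name": "forest_richness", "family": "poisson"}
  ],
  "links": [
    {"source": "cropland", "target": "mean_field_size", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "cropland", "target": "forest", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "mean_field_size", "target": "hedgerow", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "forest", "target": "forest_edge", "form": "quadratic", "predicted_sign": "peaked", "provenance": "a_priori"},
    {"source": "forest", "target": "forest_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "hedgerow", "target": "forest_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "forest_edge", "target": "forest_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"}
  ]
}
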