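{
  "name": "shrub_edge",
  "nodes": [
    {"name": "cropland", "family": "gaussian"},
    {"name": "perennial_forages_grassland", "family": "gaussian"},
    {"name": "forest", "family": "gaussian"},
    {"name": "shrubland", "family": "gaussian"},
    {"name": "hedgerow", "family": "gaussian"},
    {"name": "forest_edge", "family": "gaussian"},
    {"name": "shrub_edge_richness", "family": "poisson"}
  ],
  "links": [
    {"source": "cropland", "target": "perennial_forages_grassland", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "cropland", "target": "forest", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "cropland", "target": "shrubland", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "perennial_forages_grassland", "target": "forest", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "perennial_forages_grassland", "target": "shrubland", "form": "linear", "predicted_sign": "-", "provenance": "a_priori"},
    {"source": "forest", "target": "forest_edge", "form": "quadratic", "predicted_sign": "peaked", "provenance": "a_priori"},
    {"source": "shrubland", "target": "shrub_edge_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "hedgerow", "target": "shrub_edge_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "forest_edge", "target": "shrub_edge_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "perennial_forages_grassland", "target": "shrub_edge_richness", "form": "linear", "predicted_sign": "+", "provenance": "a_priori"},
    {"source": "cropland", "target": "hedgerow", "form": "linear", "predicted_sign": "none", "provenance": "added"},
    {"source": "cropland", "target": "forest_edge", "form": "linear", "predicted_sign": "none", "provenance": "added"},
    {"source": "cropland", "target": "shrub_edge_richness", "form": "linear", "predicted_sign": "none", "provenance": "added"},
    {"source": "perennial_forages_grassland", "target": "hedgerow", "form": "linear", "predicted_sign": "none", "provenance": "added"},
    {"source": "perennial_forages_grassland", "target": "forest_edge", "form": "linear", "predicted_sign": "none", "provenance": "added"},
    {"source": "forest", "target": "shrubland", "form": "linear", "predicted_sign": "none", "provenance": "added"},
    {"source": "shrubland", "target": "forest_edge", "form": "linear", "predicted_sign": "none", "provenance": "added"}
  ]
}
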