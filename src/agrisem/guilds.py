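"""Shipped guild diagrams and the synthetic truth used with them.

Three path diagrams are bundled, one per breeding-habitat guild (forest,
shrub-edge, open country), each in an a-priori version (the hypothesised
links only) and a revised version (a-priori links plus the links added
after failed independence claims).  ``default_truth`` supplies the
structural coefficients the synthetic-data generator uses with the revised
diagrams: moderate effects (|β| 0.25–0.6) in the hypothesised directions,
with richness intercepts on the log scale chosen to give realistic
per-site counts (about 7 forest and shrub-edge species and 1–2 open
country species per site).
"""

from __future__ import annotations

from importlib import resources

from .dag import DagSpec, validate_dag

__all__ = ["GUILDS", "RICHNESS_NODES", "AGRICULTURE_VARS", "load_guild_dag", "default_truth"]

GUILDS = ("forest", "shrub_edge", "open_country")

RICHNESS_NODES = {
    "forest": "forest_richness",
    "shrub_edge": "shrub_edge_richness",
    "open_country": "open_country_richness",
}

#: Agriculture variables whose direct/indirect/total effects are summarised.
AGRICULTURE_VARS = ("cropland", "perennial_forages_grassland", "mean_field_size")


def load_guild_dag(guild: str, revised: bool = False) -> DagSpec:
    """Load a bundled guild diagram (validated)."""
    if guild not in GUILDS:
        raise KeyError(f"unknown guild {guild!r}; expected one of {GUILDS}")
    fname = f"{guild}_revised.json" if revised else f"{guild}.json"
    with resources.files("agrisem.data").joinpath(fname).open() as fh:
        import json

        spec = DagSpec.from_dict(json.load(fh))
    return validate_dag(spec)


_TRUTH = {
    "forest": {
        "coefficients": {
            ("cropland", "mean_field_size"): 0.5,
            ("cropland", "forest"): -0.6,
            ("mean_field_size", "hedgerow"): -0.4,
            ("forest", "forest_edge"): 0.3,
            ("forest", "forest_richness"): 0.45,
            ("hedgerow", "forest_richness"): 0.25,
            ("forest_edge", "forest_richness"): 0.25,
            ("cropland", "hedgerow"): 0.35,
            ("cropland", "forest_edge"): -0.45,
            ("cropland", "forest_richness"): -0.25,
        },
        "quad_coefficients": {("forest", "forest_edge"): -0.25},
        "intercepts": {"forest_richness": 1.95},
    },
    "shrub_edge": {
        "coefficients": {
            ("cropland", "perennial_forages_grassland"): -0.45,
            ("cropland", "forest"): -0.55,
            ("cropland", "shrubland"): -0.3,
            ("perennial_forages_grassland", "forest"): -0.3,
            ("perennial_forages_grassland", "shrubland"): -0.25,
            ("forest", "shrubland"): -0.3,
            ("forest", "forest_edge"): 0.3,
            ("shrubland", "forest_edge"): 0.3,
            ("cropland", "forest_edge"): -0.4,
            ("perennial_forages_grassland", "forest_edge"): -0.25,
            ("cropland", "hedgerow"): 0.4,
            ("perennial_forages_grassland", "hedgerow"): 0.3,
            ("shrubland", "shrub_edge_richness"): 0.3,
            ("hedgerow", "shrub_edge_richness"): 0.3,
            ("forest_edge", "shrub_edge_richness"): 0.35,
            ("perennial_forages_grassland", "shrub_edge_richness"): 0.25,
            ("cropland", "shrub_edge_richness"): 0.3,
        },
        "quad_coefficients": {("forest", "forest_edge"): -0.25},
        "intercepts": {"shrub_edge_richness": 1.95},
    },
    "open_country": {
        "coefficients": {
            ("cropland", "mean_field_size"): 0.5,
            ("cropland", "perennial_forages_grassland"): -0.45,
            ("mean_field_size", "hedgerow"): -0.4,
            ("cropland", "hedgerow"): 0.35,
            ("cropland", "forest_edge"): -0.45,
            ("mean_field_size", "open_country_richness"): 0.25,
            ("perennial_forages_grassland", "open_country_richness"): 0.35,
            ("hedgerow", "open_country_richness"): -0.25,
            ("forest_edge", "open_country_richness"): -0.25,
            ("cropland", "open_country_richness"): 0.35,
        },
        "quad_coefficients": {},
        "intercepts": {"open_country_richness": 0.3},
    },
}


def default_truth(guild: str) -> dict:
    """Structural truth for the revised diagram of one guild.

    Returns ``{"coefficients", "quad_coefficients", "intercepts"}``.  Links
    of the a-priori diagram form a subset, so the same dictionaries drive
    generation from either diagram version.
    """
    if guild not in _TRUTH:
        raise KeyError(f"unknown guild {guild!r}")
    t = _TRUTH[guild]
    return {
        "coefficients": dict(t["coefficients"]),
        "quad_coefficients": dict(t["quad_coefficients"]),
        "intercepts": dict(t["intercepts"]),
    }
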