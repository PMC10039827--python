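import hypothesis
import numpy as np
import pandas as pd
import pytest

from agrisem.dag import DagSpec, LinkSpec, NodeSpec
from agrisem.guilds import GUILDS, default_truth, load_guild_dag
from agrisem.synthetic import GeneratorConfig, generate_site_table

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def chain_dag():
    """A -> B -> C."""
    return DagSpec(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def diamond_dag():
    """A -> {B, C} -> D."""
    return DagSpec(["A", "B", "C", "D"], [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])


def guild_generator_config(guild: str, n_sites: int = 127, seed: int = 0,
                           revised: bool = True, layout: str = "random") -> GeneratorConfig:
    """Generator config using a guild's bundled diagram and default truth."""
    spec = load_guild_dag(guild, revised=revised)
    truth = default_truth(guild)
    coefs = {l.pair: truth["coefficients"][l.pair] for l in spec.links}
    quads = {l.pair: truth["quad_coefficients"][l.pair]
             for l in spec.links if l.form == "quadratic"}
    return GeneratorConfig(
        spec=spec,
        coefficients=coefs,
        quad_coefficients=quads,
        intercepts=truth["intercepts"],
        n_sites=n_sites,
        seed=seed,
        spatial_layout=layout,
    )


@pytest.fixture
def forest_table():
    """One synthetic forest-guild table at the study's sample size."""
    return generate_site_table(guild_generator_config("forest", seed=11)).table


def brute_force_paths(spec: DagSpec, source: str, sink: str):
    """Exhaustive DFS enumeration of simple directed paths (test oracle)."""
    children = {n: [] for n in spec.node_names}
    for l in spec.links:
        children[l.source].append(l.target)
    out = []

    def walk(node, path):
        if node == sink:
            out.append(list(path))
            return
        for c in children[node]:
            if c not in path:
                path.append(c)
                walk(c, path)
                path.pop()

    walk(source, [source])
    return sorted(out, key=lambda p: (len(p), p))
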