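"""End-to-end confirmatory path analysis per guild.

The chain per guild: standardise covariates → Moran's I screen on raw
richness → d-separation test of the a-priori diagram → add links for
failed claims and re-test → all-subsets AICc selection for every response
node of the revised diagram → direct/indirect/total effect decomposition
for each agriculture variable.  Reports are written as JSON (full detail)
and CSV (one row per guild × agriculture variable), plus a plain-text log
with one line per fitted model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dag import DagSpec, validate_dag
from .dsep import DSepResult, dsep_test, revise_dag
from .effects import EffectDecomposition, decompose, quadratic_link_effect
from .guilds import AGRICULTURE_VARS
from .regression import ModelSelectionResult, all_subsets_selection, standardize
from .spatial import MoranResult, morans_i

__all__ = ["RunConfig", "GuildReport", "prepare_frame", "link_coefficients",
           "analyse", "run_guild_analysis", "run_all"]


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    data_path: str
    dag_paths: dict[str, str]
    output_dir: str = "agrisem_out"
    column_roles: dict[str, str] = field(default_factory=dict)  # node/"x"/"y" -> column
    subset_columns: dict[str, dict[str, str]] = field(default_factory=dict)
    alpha: float = 0.05
    delta_window: float = 2.0
    revision: str = "single"  # or "iterate"
    seed: int = 0
    moran_permutations: int = 999
    moran_scheme: str = "inverse_distance"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.revision not in ("single", "iterate"):
            raise ValueError("revision must be 'single' or 'iterate'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**d)


@dataclass(frozen=True)
class GuildReport:
    """Everything the analysis of one guild produced."""

    guild: str
    dag_before: DagSpec
    dag_after: DagSpec
    dsep_before: DSepResult
    dsep_after: DSepResult
    selections: dict[str, ModelSelectionResult]
    coefficients: dict[tuple[str, str], float]
    decompositions: dict[str, EffectDecomposition]
    moran: MoranResult | None
    n_sites: int

    def to_dict(self) -> dict:
        return {
            "guild": self.guild,
            "n_sites": self.n_sites,
            "dag_after": self.dag_after.to_dict(),
            "dsep_before": self.dsep_before.to_dict(),
            "dsep_after": self.dsep_after.to_dict(),
            "moran": self.moran.to_dict() if self.moran else None,
            "selections": {
                resp: {
                    "support": sel.support,
                    "effect_coefficients": sel.effect_coefficients,
                    "top_terms": list(sel.top.terms),
                    "top_aicc": sel.candidates[0][1],
                }
                for resp, sel in self.selections.items()
            },
            "link_coefficients": {f"{s}->{t}": v for (s, t), v in self.coefficients.items()},
            "effects": {src: d.to_dict() for src, d in self.decompositions.items()},
        }

    def effects_frame(self) -> pd.DataFrame:
        rows = []
        for src, d in self.decompositions.items():
            rows.append(
                {
                    "guild": self.guild,
                    "agriculture_variable": src,
                    "n_indirect_paths": d.n_indirect_paths,
                    "direct": round(d.direct, 3),
                    "indirect": round(d.indirect, 3),
                    "total": round(d.total, 3),
                    "proportional_change": d.proportional_change,
                    "label": d.direction_label,
                }
            )
        return pd.DataFrame(rows)


def prepare_frame(table: pd.DataFrame, spec: DagSpec,
                  column_roles: dict[str, str] | None = None) -> pd.DataFrame:
    """Extract and standardise the analysis frame for one diagram.

    Covariates (Gaussian nodes) are standardised; richness counts are left
    raw.  ``column_roles`` maps node names (and ``"x"``/``"y"``) to table
    columns when they differ.
    """
    roles = column_roles or {}
    out = {}
    for node in spec.node_names:
        col = roles.get(node, node)
        if col not in table.columns:
            raise KeyError(f"column {col!r} for node {node!r} not in table")
        series = np.asarray(table[col], dtype=float)
        out[node] = standardize(series) if spec.family(node) == "gaussian" else series
    for axis in ("x", "y"):
        col = roles.get(axis, axis)
        if col in table.columns:
            out[axis] = np.asarray(table[col], dtype=float)
    return pd.DataFrame(out)


def link_coefficients(
    spec: DagSpec, selections: dict[str, ModelSelectionResult]
) -> dict[tuple[str, str], float]:
    """Path coefficient per link from the per-response selections.

    Quadratic links contribute the summed linear + quadratic estimate as a
    single path coefficient.
    """
    coefs: dict[tuple[str, str], float] = {}
    for l in spec.links:
        eff = selections[l.target].effect_coefficients
        if l.form == "quadratic":
            coefs[l.pair] = quadratic_link_effect(eff[l.source], eff[f"{l.source}^2"])
        else:
            coefs[l.pair] = eff[l.source]
    return coefs


def analyse(
    frame: pd.DataFrame,
    spec: DagSpec,
    guild: str = "",
    alpha: float = 0.05,
    delta_window: float = 2.0,
    iterate: bool = False,
    moran_permutations: int = 999,
    moran_scheme: str = "inverse_distance",
    seed: int = 0,
) -> GuildReport:
    """Run the full chain on a prepared (standardised) frame."""
    validate_dag(spec)
    poisson_nodes = [n.name for n in spec.nodes if n.family == "poisson"]
    if len(poisson_nodes) != 1:
        raise ValueError(f"diagram must contain exactly one richness node, got {poisson_nodes}")
    richness = poisson_nodes[0]

    moran = None
    if "x" in frame.columns and "y" in frame.columns:
        moran = morans_i(
            frame[richness],
            np.column_stack([frame["x"], frame["y"]]),
            scheme=moran_scheme,
            n_permutations=moran_permutations,
            seed=seed,
        )

    before = dsep_test(spec, frame)
    revised, after = revise_dag(spec, frame, alpha=alpha, iterate=iterate)

    selections: dict[str, ModelSelectionResult] = {}
    for node in revised.node_names:
        parents = revised.parents(node)
        if not parents:
            continue
        groups = [
            f"{p}+{p}^2" if revised.link(p, node).form == "quadratic" else p
            for p in parents
        ]
        selections[node] = all_subsets_selection(
            node, groups, frame, revised.family(node), delta_window=delta_window
        )

    coefs = link_coefficients(revised, selections)
    decomps: dict[str, EffectDecomposition] = {}
    for src in AGRICULTURE_VARS:
        if src in revised.node_names and src != richness:
            decomps[src] = decompose(revised, coefs, src, richness)

    return GuildReport(
        guild=guild,
        dag_before=spec,
        dag_after=revised,
        dsep_before=before,
        dsep_after=after,
        selections=selections,
        coefficients=coefs,
        decompositions=decomps,
        moran=moran,
        n_sites=len(frame),
    )


def _write_report(report: GuildReport, outdir: Path, tag: str, log_lines: list[str]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"report_{tag}.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    report.effects_frame().to_csv(outdir / f"effects_{tag}.csv", index=False)
    for resp, sel in sorted(report.selections.items()):
        fit, a, _ = sel.candidates[0]
        log_lines.append(
            f"[{tag}] response={resp} family={sel.family} "
            f"top_terms={','.join(fit.terms) or '(null)'} loglik={fit.loglik:.4f} aicc={a:.4f}"
        )
    log_lines.append(
        f"[{tag}] dsep C={report.dsep_after.C:.4f} df={report.dsep_after.df} "
        f"p={report.dsep_after.p_value:.4f}"
    )


def run_guild_analysis(config: RunConfig, guild: str,
                       table: pd.DataFrame | None = None) -> GuildReport:
    """Load data and diagram for one guild, run the chain, write reports."""
    if table is None:
        table = pd.read_csv(config.data_path)
    spec = validate_dag(DagSpec.from_json(config.dag_paths[guild]))
    frame = prepare_frame(table, spec, config.column_roles)
    report = analyse(
        frame,
        spec,
        guild=guild,
        alpha=config.alpha,
        delta_window=config.delta_window,
        iterate=config.revision == "iterate",
        moran_permutations=config.moran_permutations,
        moran_scheme=config.moran_scheme,
        seed=config.seed,
    )
    log: list[str] = []
    _write_report(report, Path(config.output_dir), guild, log)
    with open(Path(config.output_dir) / "run.log", "a") as fh:
        fh.write("\n".join(log) + "\n")
    return report


def run_all(config: RunConfig) -> list[GuildReport]:
    """Run every configured guild, then any species-subset richness columns.

    A failing guild is reported as a warning without aborting the others.
    A subset column that is missing or empty is skipped with a warning.
    """
    table = pd.read_csv(config.data_path)
    reports: list[GuildReport] = []
    for guild in config.dag_paths:
        jobs: list[tuple[str, dict[str, str]]] = [(guild, dict(config.column_roles))]
        spec = validate_dag(DagSpec.from_json(config.dag_paths[guild]))
        richness = next(n.name for n in spec.nodes if n.family == "poisson")
        for label, column in config.subset_columns.get(guild, {}).items():
            roles = dict(config.column_roles)
            roles[richness] = column
            jobs.append((f"{guild}_subset_{label}", roles))
        for tag, roles in jobs:
            col = roles.get(richness, richness)
            if col not in table.columns or table[col].dropna().empty:
                warnings.warn(f"richness column {col!r} missing or empty; skipping {tag}")
                continue
            try:
                frame = prepare_frame(table, spec, roles)
                report = analyse(
                    frame,
                    spec,
                    guild=tag,
                    alpha=config.alpha,
                    delta_window=config.delta_window,
                    iterate=config.revision == "iterate",
                    moran_permutations=config.moran_permutations,
                    moran_scheme=config.moran_scheme,
                    seed=config.seed,
                )
            except Exception as err:  # noqa: BLE001 - per-guild isolation
                warnings.warn(f"analysis of {tag} failed: {err}")
                continue
            log: list[str] = []
            _write_report(report, Path(config.output_dir), tag, log)
            with open(Path(config.output_dir) / "run.log", "a") as fh:
                fh.write("\n".join(log) + "\n")
            reports.append(report)
    return reports
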