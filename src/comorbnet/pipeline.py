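"""One-call orchestration: cohort in, tables + network + modules out.

The pipeline is a pure function of (input records, configuration): given
the same inputs it writes byte-identical outputs.  A JSON run manifest
records the configuration, seed, and package version so any bundle can be
regenerated exactly.

Stages (each also available separately through the library API):

1. ingest or simulate a cohort, filter to the index disease, normalize codes;
2. demographics, stratified prevalence with group-comparison p-values,
   per-stratum comorbidity-count distributions;
3. pairwise co-occurrence, relative risk, thresholded network (GEXF +
   GraphML + edge list);
4. community detection (seeded Louvain) and the module report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .community import ModularityUndefinedError, louvain, module_report
from .network import build_network, degree_table, export_network
from .records import (
    Cohort,
    demographics_table,
    filter_index_cohort,
    normalize_codes,
    read_records,
    stratify,
    write_records,
)
from .simulate import config_from_yaml, generate_cohort
from .stats import (
    comorbidity_count_distribution,
    pair_counts,
    prevalence_table,
    relative_risk,
    stratified_comparison_table,
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; serialized into the output manifest."""

    output_dir: str
    input_path: str | None = None          # delimited records file, or
    input_layout: str = "long"
    sim_config: str | None = None          # YAML generative config
    sim_n: int | None = None               # override simulated cohort size
    index_codes: tuple[str, ...] = ("C220",)
    code_level: str = "full"               # full | category3
    min_prevalence: float = 0.01
    rr_threshold: float = 1.0
    gamma: float = 1.0
    seed: int = 0
    write_stratified: bool = True

    def __post_init__(self) -> None:
        if self.min_prevalence < 0 or self.rr_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if (self.input_path is None) == (self.sim_config is None):
            raise ValueError("exactly one of input_path or sim_config is required")


def _write_csv(df, path: Path, seed: int) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# comorbnet {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)


def load_cohort(config: RunConfig) -> Cohort:
    if config.input_path is not None:
        cohort = read_records(
            config.input_path, layout=config.input_layout, index_codes=config.index_codes
        )
    else:
        sim = config_from_yaml(config.sim_config)
        if config.sim_n is not None:
            sim = dataclasses.replace(sim, n=config.sim_n)
        cohort, _ = generate_cohort(sim, seed=config.seed)
    cohort = filter_index_cohort(cohort, config.index_codes)
    return normalize_codes(cohort, level=config.code_level)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict[str, Path]:
    """Run every stage and return {artifact name: path}.

    ``cohort`` may be supplied directly (already filtered/normalized) to
    bypass ingestion — useful for programmatic use and testing.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    seed = config.seed

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in paths.values():
                        p.unlink(missing_ok=True)
                    raise PipelineError(name, exc) from exc

        return _Ctx()

    with stage("ingest"):
        if cohort is None:
            cohort = load_cohort(config)
        paths["cohort"] = out / "cohort.csv"
        write_records(cohort, paths["cohort"], layout="long")

    with stage("demographics"):
        paths["demographics"] = out / "demographics.csv"
        _write_csv(demographics_table(cohort), paths["demographics"], seed)

    with stage("prevalence"):
        prev = prevalence_table(cohort)
        paths["prevalence"] = out / "prevalence.csv"
        _write_csv(prev.table, paths["prevalence"], seed)
        dist = comorbidity_count_distribution(cohort)
        paths["comorbidity_counts"] = out / "comorbidity_counts.csv"
        _write_csv(dist, paths["comorbidity_counts"], seed)

    if config.write_stratified:
        with stage("stratified"):
            by_sex = stratify(cohort, "sex")
            if set(by_sex) == {"male", "female"}:
                cmp_df = stratified_comparison_table(
                    by_sex["male"], by_sex["female"], "male", "female"
                )
                paths["prevalence_by_sex"] = out / "prevalence_by_sex.csv"
                _write_csv(cmp_df, paths["prevalence_by_sex"], seed)
            for label, sub in stratify(cohort, "age_bin").items():
                safe = label.replace("<=", "le").replace(">=", "ge")
                key = f"prevalence_age_{safe}"
                paths[key] = out / f"{key}.csv"
                _write_csv(prevalence_table(sub).table, paths[key], seed)
                key = f"comorbidity_counts_age_{safe}"
                paths[key] = out / f"{key}.csv"
                _write_csv(comorbidity_count_distribution(sub), paths[key], seed)

    with stage("network"):
        pairs = relative_risk(pair_counts(cohort), prev)
        paths["pair_stats"] = out / "pair_stats.csv"
        _write_csv(pairs, paths["pair_stats"], seed)
        net = build_network(
            pairs, prev,
            min_prevalence=config.min_prevalence,
            rr_threshold=config.rr_threshold,
        )
        paths["network_gexf"] = out / "network.gexf"
        export_network(net, paths["network_gexf"], "gexf")
        paths["network_graphml"] = out / "network.graphml"
        export_network(net, paths["network_graphml"], "graphml")
        paths["edgelist"] = out / "network_edges.csv"
        export_network(net, paths["edgelist"], "edgelist")
        paths["degree_table"] = out / "degree_table.csv"
        _write_csv(degree_table(net), paths["degree_table"], seed)

    with stage("communities"):
        try:
            part = louvain(net, seed=seed, gamma=config.gamma)
        except ModularityUndefinedError:
            part = None
        if part is not None:
            paths["partition"] = out / "partition.csv"
            _write_csv(part.to_frame(), paths["partition"], seed)
            report = module_report(net, part)
            paths["module_report"] = out / "module_report.csv"
            _write_csv(report, paths["module_report"], seed)
            summary = _module_summary(report, part)
            paths["module_summary"] = out / "module_summary.txt"
            paths["module_summary"].write_text(summary, encoding="utf-8")

    with stage("manifest"):
        manifest = {
            "comorbnet_version": __version__,
            "config": dataclasses.asdict(config),
            "cohort_n": cohort.n,
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "modularity": None if part is None else part.modularity,
            "n_modules": None if part is None else part.n_communities,
        }
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return paths


def _module_summary(report, part) -> str:
    lines = [
        f"Comorbidity modules (Louvain, gamma={part.gamma}, seed={part.seed}): "
        f"{part.n_communities} modules, Q={part.modularity:.4f}",
        "",
    ]
    for module, group in report.groupby("module"):
        members = ", ".join(group["disease"])
        lines.append(f"Module {module} ({len(group)} nodes): {members}")
    return "\n".join(lines) + "\n"
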