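"""End-to-end pipeline orchestration.

``run_pipeline`` composes the stages — preprocess (normalize, average,
impute, outlier removal), network construction (soft threshold, TOM),
module detection, module statistics, hub ranking, and optional helper
selection — archiving every intermediate table in the output directory and
emitting a deterministic JSON run report. All randomness is funneled
through the single seed in the configuration, so identical configurations
produce bit-identical report bodies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from biofilmnet import graphstats, io, network, preprocessing
from biofilmnet import helpers as helpers_mod
from biofilmnet import hubs as hubs_mod
from biofilmnet import modules as modules_mod
from biofilmnet import synthetic as synthetic_mod

__version__ = "0.1.0"


class PipelineStageError(RuntimeError):
    """Stage failure carrying the stage name and the offending entity."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {error}")


@dataclass
class RunConfig:
    """All parameters of one pipeline run (JSON round-trippable).

    Either ``input_abundance`` points at a taxa x samples matrix or
    ``synthetic`` holds :class:`~biofilmnet.synthetic.SyntheticSpec` keyword
    arguments to simulate one.
    """

    # inputs
    input_abundance: str | None = None
    probe_map: str | None = None
    universal_row: str | None = None
    traits: str | None = None
    synthetic: dict | None = None
    # imputation
    q: int | None = None
    tol: float = 1e-6
    max_iter: int = 200
    # outlier detection
    detect_outliers: bool = True
    outlier_cut: float | None = None
    mad_factor: float = 12.0
    n_sample_clusters: int = 1
    # network
    beta: int | None = None
    candidate_betas: list[int] = field(default_factory=lambda: list(range(1, 21)))
    target_r2: float = 0.85
    n_bins: int = 10
    # modules
    min_module_size: int = 5
    cut_height: float | None = None
    # module graphs
    edge_threshold: float | None = None
    target_density: float = 0.3
    weight_source: str = "tom"
    # hubs
    k_mnc: int | None = None
    k_dmnc: int | None = None
    # helpers
    helper_target: str | None = None
    required_clusters: int = 1
    cultivability: str | None = None
    # run
    seed: int = 0
    outdir: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        synth = data.get("synthetic")
        if synth and "trait_loadings" in synth:
            # JSON stringifies integer dict keys
            synth["trait_loadings"] = {
                int(k): float(v) for k, v in synth["trait_loadings"].items()
            }
        return cls(**data)


@dataclass
class RunReport:
    """Summaries of every stage of one run; serializes deterministically."""

    version: str
    config: dict
    n_taxa: int
    n_samples: int
    n_missing_imputed: int
    outliers_removed: list[str]
    beta: int
    scale_free_r2: float | None
    module_sizes: dict[str, int]
    stats: list[dict]
    hubs: dict[str, list[str]]
    helper_candidates: list[dict]
    warnings: list[str]

    def body(self) -> str:
        """Deterministic JSON body (no timestamps)."""
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.body() + "\n")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as err:
                raise PipelineStageError(name, err) from err
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Stages: load/simulate -> normalize -> average probes -> BPCA impute ->
    outlier removal -> correlation + soft threshold + TOM -> module
    detection -> eigenspecies/membership (+ trait correlation) -> module
    graphs and statistics -> hub ranking -> optional helper selection.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    @_stage("load")
    def load():
        traits = None
        if config.synthetic is not None:
            spec = synthetic_mod.SyntheticSpec(
                **{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)}
            )
            matrix, truth = synthetic_mod.generate_community(spec)
            traits = truth.trait_matrix
        elif config.input_abundance is not None:
            matrix = io.read_abundance(config.input_abundance)
        else:
            raise ValueError("config needs input_abundance or synthetic")
        if config.traits is not None:
            traits = io.read_traits(config.traits)
        return matrix, traits

    matrix, traits = load()

    @_stage("normalize")
    def normalize(m):
        if config.universal_row is not None:
            m = preprocessing.normalize_by_universal_probe(m, config.universal_row)
        if config.probe_map is not None:
            m = preprocessing.average_probes(m, io.read_probe_map(config.probe_map))
        return m

    matrix = normalize(matrix)
    n_missing = int(matrix.isna().to_numpy().sum())

    @_stage("impute")
    def impute(m):
        if not m.isna().any().any():
            return m
        result = preprocessing.bpca_impute(
            m, q=config.q, tol=config.tol, max_iter=config.max_iter,
            seed=config.seed,
        )
        if not result.converged:
            warnings.append(
                f"BPCA did not converge within {config.max_iter} iterations"
            )
        if outdir:
            io.write_abundance(result.matrix, outdir / "imputed.tsv")
        return result.matrix

    matrix = impute(matrix)

    @_stage("outliers")
    def outliers(m):
        if not config.detect_outliers or m.shape[1] < 3:
            return m, []
        ids, labels = preprocessing.detect_outlier_samples(
            m, cut_height=config.outlier_cut, mad_factor=config.mad_factor,
            n_clusters=config.n_sample_clusters,
        )
        if outdir:
            labels.to_csv(outdir / "sample_clusters.csv")
        return m.drop(columns=ids), ids

    matrix, outlier_ids = outliers(matrix)
    if traits is not None:
        traits = traits.drop(index=[s for s in outlier_ids if s in traits.index])

    @_stage("network")
    def build_network(m):
        cor = network.correlation_matrix(m)
        r2 = None
        if config.beta is not None:
            beta = config.beta
        else:
            fit = network.pick_soft_threshold(
                cor, candidate_betas=config.candidate_betas,
                target_r2=config.target_r2, n_bins=config.n_bins,
            )
            beta, r2 = fit.beta, fit.r_squared
            if outdir:
                fit.table.to_csv(outdir / "scale_free_fit.csv", index=False)
        net = network.topological_overlap(
            network.soft_threshold_adjacency(cor, beta)
        )
        if outdir:
            io.write_square_matrix(cor, outdir / "correlation.tsv")
            io.write_square_matrix(net.tom_frame(), outdir / "tom.tsv")
        return net, beta, r2

    net, beta, r2 = build_network(matrix)

    @_stage("modules")
    def detect_modules(n):
        diss = pd.DataFrame(n.disstom, index=n.taxa, columns=n.taxa)
        link = modules_mod.cluster_taxa(diss)
        partition = modules_mod.cut_modules(
            link, n.taxa, min_module_size=config.min_module_size,
            cut_height=config.cut_height,
        )
        eig = modules_mod.module_eigenspecies(matrix, partition)
        membership = modules_mod.module_membership(matrix, eig)
        if outdir:
            out = pd.concat(
                [partition.colors.rename("module"), membership], axis=1
            )
            out.to_csv(outdir / "module_assignments.tsv", sep="\t")
            eig.profiles.to_csv(outdir / "eigenspecies.csv")
        if traits is not None and len(eig.profiles.columns):
            assoc = modules_mod.module_trait_correlation(eig, traits)
            if outdir:
                assoc.correlation.to_csv(outdir / "module_trait_r.csv")
                assoc.p_value.to_csv(outdir / "module_trait_p.csv")
        return partition

    partition = detect_modules(net)
    if (partition.colors == modules_mod.GREY).any():
        warnings.append(
            "grey contains unassigned taxa: only a subset of its nodes may "
            "be connected"
        )

    @_stage("stats")
    def module_stats(part):
        graphs = {}
        for color in part.module_colors(include_grey=True):
            if len(part.members(color)) < 2:
                continue
            graphs[color] = graphstats.binarize_module(
                net, part, color,
                threshold=config.edge_threshold,
                weight_source=config.weight_source,
                target_density=(
                    config.target_density if config.edge_threshold is None else None
                ),
            )
        table = graphstats.stats_table(list(graphs.values()))
        if outdir:
            table.to_csv(outdir / "module_stats.csv", index=False)
            for color, g in graphs.items():
                io.export_graph(g, outdir / f"module_{color}.sif")
        return graphs, table

    graphs, stats = module_stats(partition)

    @_stage("hubs")
    def rank_hubs(gs):
        rankings = {}
        for color, g in gs.items():
            if g.graph.number_of_nodes() < 2:
                continue
            rankings[color] = hubs_mod.dss_rank(
                g, k_mnc=config.k_mnc, k_dmnc=config.k_dmnc
            )
        if outdir and rankings:
            combined = pd.concat(
                {c: r.table for c, r in rankings.items()}, names=["module", "taxon"]
            )
            combined.to_csv(outdir / "hub_table.csv")
        return rankings

    rankings = rank_hubs(graphs)

    @_stage("helpers")
    def select_helpers(part, gs, ranks):
        if config.helper_target is None:
            return []
        cultiv = (
            io.read_probe_map(config.cultivability)
            if config.cultivability else {}
        )
        cultiv = {k: str(v).lower() in ("1", "true", "yes") for k, v in cultiv.items()}
        tcolor = part.colors.get(config.helper_target)
        mg = {"run": gs[tcolor]} if tcolor in gs else None
        hr = {"run": ranks[tcolor]} if tcolor in ranks else None
        cands = helpers_mod.candidate_helpers(
            {"run": part}, config.helper_target, cultiv,
            required_clusters=config.required_clusters,
            module_graphs=mg, hub_rankings=hr,
        )
        if outdir:
            pd.DataFrame([c.as_row() for c in cands]).to_csv(
                outdir / "helper_candidates.csv", index=False
            )
        return cands

    candidates = select_helpers(partition, graphs, rankings)

    report = RunReport(
        version=__version__,
        config=dataclasses.asdict(config),
        n_taxa=int(matrix.shape[0]),
        n_samples=int(matrix.shape[1]),
        n_missing_imputed=n_missing,
        outliers_removed=list(outlier_ids),
        beta=int(beta),
        scale_free_r2=(None if r2 is None else float(r2)),
        module_sizes={
            c: int(len(partition.members(c)))
            for c in partition.module_colors(include_grey=True)
        },
        stats=stats.to_dict(orient="records"),
        hubs={c: r.dss_hubs for c, r in rankings.items()},
        helper_candidates=[c.as_row() for c in candidates],
        warnings=warnings,
    )
    if outdir:
        report.write(outdir / "report.json")
        config.to_json(outdir / "config.json")
    return report
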