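"""End-to-end orchestration: ingest/simulate -> preprocess -> cluster ->
differential expression -> target enrichment -> imprinting -> report.

The report bundle is exactly the union of stage outputs; nothing is
recomputed in the report layer. Logging records the audit quantities: how
many wells were censored, how many miRNAs the detection filter removed,
each comparison's Bonferroni family size, and the null used per enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from . import clustering, diffexp, imprinting, io_formats, synthetic_data, target_integration
from .preprocess import CtMatrix, censor_cts, filter_low_detection, mean_normalize, to_relative_expression
from .synthetic_data import SimConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Inputs and parameters for one pipeline run.

    Either ``simulate`` is set (synthetic cohort) or the four input paths
    are given. All module-level parameters are surfaced here with the same
    defaults they have in their modules.
    """

    simulate: SimConfig | None = None
    ct_path: str | None = None
    cases_path: str | None = None
    methylation_path: str | None = None
    targets_path: str | None = None
    gene_de_path: str | None = None

    censor_threshold: float = 35.0
    min_detection: float = 0.20
    ctmax_scope: Literal["global", "feature"] = "global"
    min_overlap: int = 10
    ward_squared: bool = False
    alpha: float = 0.05
    null_kind: Literal["permutation", "hypergeometric"] = "permutation"
    n_permutations: int = 10_000
    expected_states: Mapping[str, str] = field(
        default_factory=lambda: {"A": imprinting.PATERNAL_LOSS, "B1": imprinting.MATERNAL_LOSS}
    )
    seed: int = 0
    outdir: str | None = None


@dataclass
class ReportBundle:
    labels: clustering.ClusterLabels
    labels_no_block: clustering.ClusterLabels | None
    dendrogram_newick: str
    split_drivers: set[str]
    de_tables: pd.DataFrame
    enrichment: pd.DataFrame
    concordance: pd.DataFrame
    cohort_summary: pd.DataFrame
    fish_rates: pd.DataFrame


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the stages in fixed order and return the report bundle."""
    # --- ingest ------------------------------------------------------------
    try:
        if cfg.simulate is not None:
            cohort = synthetic_data.simulate_cohort(cfg.simulate)
            ct, cases = cohort.ct, cohort.cases
            methylation, gene_de, targets = cohort.methylation, cohort.gene_de, cohort.targets
        else:
            if cfg.ct_path is None or cfg.cases_path is None:
                raise ValueError("either simulate or ct_path + cases_path must be set")
            ct = CtMatrix.from_records(io_formats.read_ct_table(cfg.ct_path))
            cases = io_formats.read_case_table(cfg.cases_path)
            methylation = (
                io_formats.read_methylation_calls(cfg.methylation_path)
                if cfg.methylation_path
                else []
            )
            gene_de = (
                io_formats.read_results(cfg.gene_de_path) if cfg.gene_de_path else None
            )
            targets = None  # read lazily in the mirmatch stage
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    # --- preprocess --------------------------------------------------------
    try:
        censored = censor_cts(ct, cfg.censor_threshold)
        n_censored = int(ct.values.notna().sum().sum() - censored.values.notna().sum().sum())
        filtered = filter_low_detection(censored, cfg.min_detection)
        logger.info(
            "preprocess: censored %d well(s) over Ct %.1f; %d of %d features retained",
            n_censored, cfg.censor_threshold, filtered.values.shape[0], ct.values.shape[0],
        )
        expr = to_relative_expression(mean_normalize(filtered), scope=cfg.ctmax_scope)
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    # --- clustering --------------------------------------------------------
    try:
        dist = clustering.spearman_dissimilarity(expr, cfg.min_overlap)
        tree = clustering.ward_hclust(dist, squared=cfg.ward_squared)
        top = clustering.cut_clusters(tree, 2)
        labels = _paper_style_labels(top, expr, cases, cfg)
        split_drivers = clustering.identify_split_drivers(expr, top, cfg.alpha)
        logger.info("clustering: top split drives %d miRNA(s)", len(split_drivers))
        labels_no_block = None
        if split_drivers and len(split_drivers) < len(expr.features):
            reduced = clustering.drop_feature_block(expr, split_drivers)
            tree2 = clustering.ward_hclust(
                clustering.spearman_dissimilarity(reduced, cfg.min_overlap),
                squared=cfg.ward_squared,
            )
            second = clustering.cut_clusters(tree2, 2)
            labels_no_block = clustering.ClusterLabels(
                {s: {"A": "C", "B": "D"}[v] for s, v in second.assignments.items()},
                scheme="re-clustered without the dominant block",
            )
        newick = clustering.to_newick(tree)
    except Exception as exc:
        raise PipelineError("cluster", exc) from exc

    # --- differential expression -------------------------------------------
    try:
        label_map = labels.assignments
        frames = []
        for spec in diffexp.enumerate_comparisons(cases, label_map):
            results = diffexp.compare_classes(expr, cases, spec, cfg.alpha, labels=label_map)
            logger.info(
                "diffexp %s: family size %d, %d significant",
                spec.name, len(results), sum(r.significant for r in results),
            )
            frames.append(diffexp.results_to_frame(results, spec.name))
        de_tables = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["comparison", "feature_id", "direction", "p_raw", "p_adjusted",
                     "significant", "n_a", "n_b"]
        )
    except Exception as exc:
        raise PipelineError("diffexp", exc) from exc

    # --- target enrichment --------------------------------------------------
    try:
        enrich_rows = []
        if targets is None and cfg.targets_path:
            pairs = io_formats.read_target_pairs(cfg.targets_path)
            targets = target_integration.TargetTable.from_pairs(pairs)
        if targets is not None and gene_de is not None:
            available = set(de_tables["comparison"]) & set(gene_de["comparison"])
            for scheme in target_integration.PAIRING_SCHEMES.values():
                if scheme.comparison not in available:
                    logger.info("mirmatch: scheme %s skipped (comparison missing)", scheme.name)
                    continue
                sets = target_integration.build_diametric_sets(de_tables, gene_de, scheme)
                result = target_integration.interaction_enrichment(
                    sets, targets, cfg.null_kind, cfg.n_permutations, seed=cfg.seed,
                )
                logger.info(
                    "mirmatch %s: observed %d expected %.2f p=%.4g (%s null)",
                    scheme.name, result.observed, result.expected, result.p_value,
                    result.null_kind,
                )
                enrich_rows.append(
                    dict(
                        scheme=scheme.name, comparison=scheme.comparison,
                        n_mirnas=len(sets.mirnas_down), n_genes=len(sets.genes_up),
                        observed=result.observed, expected=result.expected,
                        p_value=result.p_value, null_kind=result.null_kind,
                    )
                )
        enrichment = pd.DataFrame(
            enrich_rows,
            columns=["scheme", "comparison", "n_mirnas", "n_genes", "observed",
                     "expected", "p_value", "null_kind"],
        )
    except Exception as exc:
        raise PipelineError("mirmatch", exc) from exc

    # --- imprinting ---------------------------------------------------------
    try:
        states = [imprinting.classify_allelic_state(c) for c in methylation]
        summaries = imprinting.cluster_concordance(states, labels.assignments, cfg.expected_states)
        concordance = pd.DataFrame(
            [
                dict(cluster=s.cluster, n_tested=s.n_tested, n_matching=s.n_matching,
                     fraction=s.fraction)
                for s in summaries
            ]
        )
        fish_rows = []
        for cohort_name, pred in (
            ("adult_mutant", lambda c: c.cohort == "adult_mutant"),
            ("adult_wt", lambda c: c.cohort == "adult_wt"),
            ("pediatric_wt", lambda c: c.cohort == "pediatric_wt"),
        ):
            try:
                n_tested, n_loss, frac = imprinting.fish_loss_rate(cases, pred)
            except ValueError:
                continue
            fish_rows.append(dict(cohort=cohort_name, n_tested=n_tested, n_loss=n_loss,
                                  fraction=frac))
        fish_rates = pd.DataFrame(fish_rows, columns=["cohort", "n_tested", "n_loss", "fraction"])
        cohort_summary = imprinting.cohort_counts(cases)
    except Exception as exc:
        raise PipelineError("imprint", exc) from exc

    bundle = ReportBundle(
        labels=labels,
        labels_no_block=labels_no_block,
        dendrogram_newick=newick,
        split_drivers=split_drivers,
        de_tables=de_tables,
        enrichment=enrichment,
        concordance=concordance,
        cohort_summary=cohort_summary,
        fish_rates=fish_rates,
    )
    if cfg.outdir:
        _write_bundle(bundle, Path(cfg.outdir))
    return bundle


def _paper_style_labels(
    top: clustering.ClusterLabels,
    expr,
    cases,
    cfg: PipelineConfig,
) -> clustering.ClusterLabels:
    """Nested presentation labels A / B1 / B2a / B2b.

    "B" is the top-level cluster holding the majority of pediatric cases;
    its pediatric-majority child becomes B2, which is split once more into
    B2a/B2b. Any subdivision that is impossible (too few members) is skipped.
    """
    pediatric = {c.case_id for c in cases if c.age_class == "pediatric"}

    def pediatric_share(members: list[str]) -> float:
        return sum(1 for s in members if s in pediatric) / max(len(members), 1)

    groups = top.groups()
    name_b = max(groups, key=lambda g: (pediatric_share(groups[g]), g))
    name_a = next(g for g in groups if g != name_b)
    assignments = {
        s: ("A" if v == name_a else "B") for s, v in top.assignments.items()
    }
    labels = clustering.ClusterLabels(assignments, scheme="top cut k=2 (B = pediatric-rich)")
    try:
        labels = clustering.subdivide_cluster(
            labels, "B", expr, ("B1", "B2"),
            min_overlap=cfg.min_overlap, squared=cfg.ward_squared,
        )
        b_groups = labels.groups()
        share1 = pediatric_share(b_groups.get("B1", []))
        share2 = pediatric_share(b_groups.get("B2", []))
        if share1 > share2:  # keep B2 the pediatric-rich child
            swap = {"B1": "B2", "B2": "B1"}
            labels = clustering.ClusterLabels(
                {s: swap.get(v, v) for s, v in labels.assignments.items()}, labels.scheme
            )
        labels = clustering.subdivide_cluster(
            labels, "B2", expr, ("B2a", "B2b"),
            min_overlap=cfg.min_overlap, squared=cfg.ward_squared,
        )
    except ValueError as exc:
        logger.info("nested labelling stopped early: %s", exc)
    return labels


def split_driver_recovery(sim_cfg: SimConfig, alpha: float = 0.05) -> dict:
    """One replicate of the imprinted-block recovery experiment.

    Simulates a cohort, preprocesses it, clusters the SDHB-immunopositive
    adult samples (the subcohort whose two-way split the imprinted block
    drives; the pediatric-type samples are excluded so the SDHB signature
    cannot confound the contrast), cuts at k=2 and identifies the split
    drivers. Returns the recovered/expected set sizes and whether recovery
    was exact.
    """
    import dataclasses as _dc

    from . import preprocess

    cohort = synthetic_data.simulate_cohort(sim_cfg)
    expr = preprocess.preprocess_pipeline(cohort.ct)
    sdhb_pos_adult = [
        c.case_id
        for c in cohort.cases
        if c.age_class == "adult" and c.sdhb_ihc == "positive" and c.case_id in set(expr.samples)
    ]
    sub = _dc.replace(expr, values=expr.values[sdhb_pos_adult])
    tree = clustering.ward_hclust(clustering.spearman_dissimilarity(sub))
    labels = clustering.cut_clusters(tree, 2)
    drivers = clustering.identify_split_drivers(sub, labels, alpha)
    block = set(cohort.truth.block_members)
    return {
        "n_recovered": len(drivers & block),
        "n_extra": len(drivers - block),
        "n_block": len(block),
        "exact": drivers == block,
    }


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    labels_df = pd.DataFrame(
        sorted(bundle.labels.assignments.items()), columns=["sample_id", "cluster"]
    )
    io_formats.write_results(labels_df, outdir / "cluster_labels.csv")
    if bundle.labels_no_block is not None:
        df = pd.DataFrame(
            sorted(bundle.labels_no_block.assignments.items()),
            columns=["sample_id", "cluster"],
        )
        io_formats.write_results(df, outdir / "cluster_labels_no_block.csv")
    (outdir / "dendrogram.nwk").write_text(bundle.dendrogram_newick + "\n")
    io_formats.write_results(bundle.de_tables, outdir / "differential_expression.csv")
    io_formats.write_results(bundle.enrichment, outdir / "target_enrichment.csv")
    io_formats.write_results(bundle.concordance, outdir / "methylation_concordance.csv")
    io_formats.write_results(bundle.cohort_summary, outdir / "cohort_summary.csv")
    io_formats.write_results(bundle.fish_rates, outdir / "fish_loss_rates.csv")
    pd.DataFrame({"feature_id": sorted(bundle.split_drivers)}).to_csv(
        outdir / "split_drivers.csv", index=False
    )
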