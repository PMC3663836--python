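"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator emulates a TaqMan low-density-array study of 73 gastric/small
bowel GISTs profiled for 667 miRNAs on two card pools, with:

* three classes — adult mutant (KIT/PDGFRA/BRAF), adult wild-type split by
  SDHB immunohistochemistry, and pediatric wild-type;
* a 47-member co-regulated imprinted block (the 14q32 DLK1-DIO3 cluster)
  whose Ct level depends on a per-case allelic state: cases losing the
  expressed maternal allele — or pediatric-type cases silenced by some other
  mechanism — carry the block shifted ``block_shift_ct`` cycles later;
* a 16-miRNA SDHB signature shifted in SDHB-immunonegative cases (half the
  signature up, half down);
* optional planted differential expression for named class comparisons;
* Ct-dependent dropout: each well goes missing with logistic probability
  ``expit(slope * (ct - center))``, so late (low-abundance) wells drop out
  preferentially and some emitted Cts exceed the censoring threshold;
* methylation-specific-PCR band calls consistent with the allelic states,
  except for a ``contamination_rate`` of loss cases whose admixed stromal
  DNA produces a normal-pattern call;
* a predicted miRNA->gene target table with background pair density
  everywhere and an elevated density inside one designated diametric
  miRNA/gene set, plus the matching gene DE table.

Effect sizes are specified on the Ct scale, where the measurement (and its
dropout) lives; expression-scale effects follow from the ``2**`` transform.
One global seed drives a hierarchy of per-table independent generators, so
adding a table does not perturb earlier draws. Identical config + seed gives
bit-identical outputs.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io_formats
from .io_formats import CaseRecord, MethylationCallRecord, TargetPair
from .preprocess import CtMatrix
from .target_integration import TargetTable
from .imprinting import MATERNAL_LOSS, NORMAL_PATTERN, PATERNAL_LOSS

#: comparison the planted DE features and the enriched diametric sets refer to
PLANTED_COMPARISON = "all_wt_vs_all_mutant"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Class sizes, feature count, block size and signature size mirror the
    profiled study (30 adult mutant / 25 adult WT / 18 pediatric; 667
    miRNAs; 47-member 14q32 block; 16-miRNA SDHB signature). Shifts are in
    Ct cycles: 4 cycles is a 16-fold expression change, appropriate for
    near-complete allelic silencing of an imprinted cluster.
    """

    n_adult_mutant: int = 30
    n_adult_wt: int = 25
    n_pediatric: int = 18
    n_features: int = 667
    block_size: int = 47
    block_shift_ct: float = 4.0
    sdhb_signature_size: int = 16
    sdhb_shift_ct: float = 3.0
    planted_de: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {PLANTED_COMPARISON: (20, 3.0)}
    )
    baseline_ct_mean: float = 28.0
    baseline_ct_sd: float = 2.0
    noise_ct_sd: float = 1.0
    missingness_center: float = 34.0
    missingness_slope: float = 1.0
    #: adult-mutant-type allelic mix (paternal loss : maternal loss : normal)
    allelic_proportions: tuple[int, int, int] = (9, 5, 4)
    #: adult WT cases that are SDHB-immunonegative (pediatric-like)
    n_adult_wt_sdhb_negative: int = 11
    #: fraction of allelic-loss cases whose MS-PCR reads normal (stromal DNA)
    contamination_rate: float = 0.2
    n_genes: int = 400
    n_de_genes: int = 40
    target_density_background: float = 0.02
    target_density_planted: float = 0.10
    seed: int = 0

    def __post_init__(self):
        planted_total = sum(n for n, _ in self.planted_de.values())
        if self.block_size + self.sdhb_signature_size + planted_total > self.n_features:
            raise ValueError("block + signature + planted features exceed n_features")
        for name, value in (
            ("target_density_background", self.target_density_background),
            ("target_density_planted", self.target_density_planted),
            ("contamination_rate", self.contamination_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if min(self.n_adult_mutant, self.n_adult_wt, self.n_pediatric) < 2:
            raise ValueError("each class needs >= 2 cases")
        if self.n_adult_wt_sdhb_negative > self.n_adult_wt:
            raise ValueError("more SDHB-negative adult WT cases than adult WT cases")


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated cohort."""

    block_members: frozenset[str]
    sdhb_signature: frozenset[str]
    planted_de: dict[str, frozenset[str]]
    enriched_mirnas: frozenset[str]
    enriched_genes: frozenset[str]
    allelic_state: dict[str, str]
    other_mechanism: dict[str, bool]
    sdhb_negative: frozenset[str]
    ct_true: pd.DataFrame  # latent Ct before dropout


@dataclass
class SimulatedCohort:
    ct: CtMatrix
    cases: list[CaseRecord]
    methylation: list[MethylationCallRecord]
    gene_de: pd.DataFrame
    targets: TargetTable
    truth: SyntheticTruth

    def write_tables(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input table as CSV/TSV under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ct": outdir / "ct_table.csv",
            "cases": outdir / "cases.tsv",
            "methylation": outdir / "methylation_calls.tsv",
            "gene_de": outdir / "gene_de.tsv",
            "targets": outdir / "target_pairs.tsv",
        }
        io_formats.write_ct_table(self.ct.to_records(), paths["ct"])
        io_formats.write_case_table(self.cases, paths["cases"])
        io_formats.write_methylation_calls(self.methylation, paths["methylation"])
        io_formats.write_results(self.gene_de, paths["gene_de"], format="tsv")
        io_formats.write_target_pairs(sorted(
            self.targets.pairs, key=lambda p: (p.mirna_id, p.gene_id)
        ), paths["targets"])
        return paths


def _simulate_cases(cfg: SimConfig, rng: np.random.Generator) -> tuple[
    list[dict], list[str]
]:
    """Per-case latent attributes (class, SDHB, allelic state, metadata)."""
    cases = []
    ids = []
    locations_wt = ["stomach"] * 20 + ["jejunum", "jejunum", "ileum", "ileum", "retroperitoneum"]
    genotype_pool = ["KIT"] * 18 + ["PDGFRA"] * 11 + ["BRAF"]
    p_allelic = np.asarray(cfg.allelic_proportions, dtype=float)
    p_allelic /= p_allelic.sum()
    states = [PATERNAL_LOSS, MATERNAL_LOSS, NORMAL_PATTERN]

    sdhb_neg_wt = set(
        rng.choice(cfg.n_adult_wt, size=cfg.n_adult_wt_sdhb_negative, replace=False).tolist()
    )
    k = 0
    for cls, n in (
        ("adult_mutant", cfg.n_adult_mutant),
        ("adult_wt", cfg.n_adult_wt),
        ("pediatric_wt", cfg.n_pediatric),
    ):
        for i in range(n):
            k += 1
            case_id = f"GIST-{k:03d}"
            ids.append(case_id)
            if cls == "pediatric_wt":
                age = int(rng.integers(8, 20))
                age_class = "pediatric"
            else:
                age = int(rng.integers(20, 86))
                age_class = "adult"
            if cls == "adult_mutant":
                genotype = str(rng.choice(genotype_pool))
                sdhb = "positive"
                location = "stomach"
            elif cls == "adult_wt":
                genotype = "WT"
                sdhb = "negative" if i in sdhb_neg_wt else "positive"
                location = str(rng.choice(locations_wt))
            else:
                genotype = "WT"
                sdhb = "negative"
                location = "stomach"
            # pediatric-like tumors keep both alleles; the block is silenced
            # by some other mechanism instead
            pediatric_like = sdhb == "negative"
            if pediatric_like:
                state = NORMAL_PATTERN
                other_mech = True
            else:
                state = str(rng.choice(states, p=p_allelic))
                other_mech = False
            fish = "loss" if state in (PATERNAL_LOSS, MATERNAL_LOSS) else "diploid"
            risk = str(rng.choice(["L", "I", "H"])) if age_class == "adult" else "not_available"
            followup = (
                str(rng.choice(["WD", "AWD", "DOD"], p=[0.6, 0.25, 0.15]))
                if age_class == "adult"
                else "not_available"
            )
            cases.append(
                dict(
                    case_id=case_id,
                    cls=cls,
                    age=age,
                    age_class=age_class,
                    sex=str(rng.choice(["M", "F"], p=[0.4, 0.6])),
                    location=location,
                    genotype=genotype,
                    mutation="WT" if genotype == "WT" else "simulated",
                    sdhb=sdhb,
                    state=state,
                    other_mech=other_mech,
                    fish=fish,
                    risk=risk,
                    followup=followup,
                )
            )
    return cases, ids


def simulate_cohort(cfg: SimConfig | None = None) -> SimulatedCohort:
    """Draw one full synthetic study: Ct matrix, metadata, calls, targets.

    Deterministic in ``cfg.seed``: the seed is split into independent child
    streams for cases, Ct values, dropout, methylation, the gene DE table
    and the target pairs.
    """
    cfg = cfg or SimConfig()
    children = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_cases, rng_ct, rng_drop, rng_meth, rng_gene, rng_targets = (
        np.random.default_rng(s) for s in children
    )

    cases, sample_ids = _simulate_cases(cfg, rng_cases)

    # feature identities: a random permutation assigns block / signature /
    # planted roles so no test can rely on positional layout
    feature_ids = [f"miR-sim-{i + 1:04d}" for i in range(cfg.n_features)]
    order = rng_ct.permutation(cfg.n_features)
    cursor = 0
    block = [feature_ids[i] for i in order[cursor:cursor + cfg.block_size]]
    cursor += cfg.block_size
    signature = [feature_ids[i] for i in order[cursor:cursor + cfg.sdhb_signature_size]]
    cursor += cfg.sdhb_signature_size
    planted: dict[str, list[str]] = {}
    planted_shift: dict[str, float] = {}
    for comparison, (n, shift) in cfg.planted_de.items():
        planted[comparison] = [feature_ids[i] for i in order[cursor:cursor + n]]
        planted_shift[comparison] = shift
        cursor += n

    baselines = rng_ct.normal(cfg.baseline_ct_mean, cfg.baseline_ct_sd, size=cfg.n_features)
    n_samples = len(sample_ids)
    ct = baselines[:, None] + rng_ct.normal(0.0, cfg.noise_ct_sd, size=(cfg.n_features, n_samples))
    ct_df = pd.DataFrame(ct, index=feature_ids, columns=sample_ids)

    block_idx = ct_df.index.get_indexer(block)
    sig_up_idx = ct_df.index.get_indexer(signature[: len(signature) // 2])
    sig_down_idx = ct_df.index.get_indexer(signature[len(signature) // 2:])
    for j, case in enumerate(cases):
        silenced = case["state"] == MATERNAL_LOSS or case["other_mech"]
        if silenced:
            ct_df.iloc[block_idx, j] += cfg.block_shift_ct
        if case["sdhb"] == "negative":
            # half the signature is lower (later Ct), half higher in SDHB-
            ct_df.iloc[sig_up_idx, j] += cfg.sdhb_shift_ct
            ct_df.iloc[sig_down_idx, j] -= cfg.sdhb_shift_ct
    # planted DE: shift features later (lower expression) in the WT class
    wt_cols = [j for j, case in enumerate(cases) if case["genotype"] == "WT"]
    for comparison, features in planted.items():
        idx = ct_df.index.get_indexer(features)
        ct_df.iloc[idx, wt_cols] += planted_shift[comparison]

    ct_true = ct_df.copy()

    # logistic dropout on the true Ct
    p_drop = expit(cfg.missingness_slope * (ct_df.to_numpy() - cfg.missingness_center))
    dropped = rng_drop.random(ct_df.shape) < p_drop
    values = ct_df.mask(pd.DataFrame(dropped, index=ct_df.index, columns=ct_df.columns))

    # internal controls: stable early Cts, removed by the detection filter step
    controls = sorted(io_formats.CONTROL_FEATURES)
    control_values = pd.DataFrame(
        rng_ct.normal(22.0, 0.5, size=(len(controls), n_samples)),
        index=controls, columns=sample_ids,
    )
    values = pd.concat([values, control_values])
    is_control = pd.Series(
        [False] * cfg.n_features + [True] * len(controls), index=values.index
    )
    pools = pd.Series(
        ["A" if i < cfg.n_features // 2 else "B" for i in range(cfg.n_features)] + ["A"] * len(controls),
        index=values.index,
    )
    ct_matrix = CtMatrix(values, stage="raw", is_control=is_control, pools=pools)

    case_records = [
        CaseRecord(
            case_id=c["case_id"],
            age_class=c["age_class"],
            sex=c["sex"],
            age=c["age"],
            location=c["location"],
            genotype=c["genotype"],
            mutation=c["mutation"],
            fish_14q=c["fish"],
            sdhb_ihc=c["sdhb"],
            carney_triad=False,
            risk=c["risk"],
            followup=c["followup"],
            histology=None,
        )
        for c in cases
    ]

    # methylation-specific PCR band calls from the allelic states
    methylation = []
    for c in cases:
        state = c["state"]
        contaminated = state != NORMAL_PATTERN and rng_meth.random() < cfg.contamination_rate
        if state == NORMAL_PATTERN or contaminated:
            maternal, paternal = True, True
        elif state == PATERNAL_LOSS:
            maternal, paternal = True, False
        else:
            maternal, paternal = False, True
        methylation.append(MethylationCallRecord(c["case_id"], maternal, paternal, True))

    # gene DE table + target pairs with planted diametric enrichment:
    # genes higher in WT pair with the planted miRNAs lower in WT
    gene_ids = [f"GENE-{i + 1:04d}" for i in range(cfg.n_genes)]
    gene_order = rng_gene.permutation(cfg.n_genes)
    enriched_genes = [gene_ids[i] for i in gene_order[: cfg.n_de_genes]]
    decoy_down = [gene_ids[i] for i in gene_order[cfg.n_de_genes: cfg.n_de_genes + cfg.n_de_genes // 2]]
    rows = []
    for g in gene_ids:
        if g in set(enriched_genes):
            rows.append((PLANTED_COMPARISON, g, "higher_in_a", True))
        elif g in set(decoy_down):
            rows.append((PLANTED_COMPARISON, g, "higher_in_b", True))
        else:
            direction = "higher_in_a" if rng_gene.random() < 0.5 else "higher_in_b"
            rows.append((PLANTED_COMPARISON, g, direction, False))
    gene_de = pd.DataFrame(rows, columns=["comparison", "gene_id", "direction", "significant"])

    enriched_mirnas = planted.get(PLANTED_COMPARISON, [])
    enriched_m = set(enriched_mirnas)
    enriched_g = set(enriched_genes)
    density = np.full((cfg.n_features, cfg.n_genes), cfg.target_density_background)
    m_idx = [i for i, f in enumerate(feature_ids) if f in enriched_m]
    g_idx = [i for i, g in enumerate(gene_ids) if g in enriched_g]
    density[np.ix_(m_idx, g_idx)] = cfg.target_density_planted
    hits = rng_targets.random((cfg.n_features, cfg.n_genes)) < density
    pairs = frozenset(
        TargetPair(feature_ids[i], gene_ids[j]) for i, j in zip(*np.nonzero(hits))
    )
    targets = TargetTable(pairs, frozenset(feature_ids), frozenset(gene_ids))

    truth = SyntheticTruth(
        block_members=frozenset(block),
        sdhb_signature=frozenset(signature),
        planted_de={k: frozenset(v) for k, v in planted.items()},
        enriched_mirnas=frozenset(enriched_mirnas),
        enriched_genes=frozenset(enriched_genes),
        allelic_state={c["case_id"]: c["state"] for c in cases},
        other_mechanism={c["case_id"]: c["other_mech"] for c in cases},
        sdhb_negative=frozenset(c["case_id"] for c in cases if c["sdhb"] == "negative"),
        ct_true=ct_true,
    )
    return SimulatedCohort(ct_matrix, case_records, methylation, gene_de, targets, truth)


def expected_missing_fraction(cfg: SimConfig, truth: SyntheticTruth) -> float:
    """Closed-form expected dropout fraction given the latent Ct values."""
    p = expit(cfg.missingness_slope * (truth.ct_true.to_numpy() - cfg.missingness_center))
    return float(p.mean())


def emit_fixture_tables(outdir: str | Path) -> dict[str, Path]:
    """Write the packaged transcriptions of the published case/DE tables.

    Byte-identical on re-emission; row counts match the printed tables
    (73 cases; per-comparison DE miRNA lists).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in ("tables1_3_cases.tsv", "table4_de_mirnas.tsv"):
        src = io_formats.packaged_fixture_path(name)
        dst = outdir / name
        shutil.copyfile(src, dst)
        out[name] = dst
    return out


def study_methylation_calls() -> tuple[list[MethylationCallRecord], dict[str, str], dict[str, str]]:
    """Synthetic band-call reconstruction of the published cluster summaries.

    Per-case gel calls were never published; only the cluster-level counts
    are known: 9 of 12 tested cluster-A cases lost the paternal allele (the
    rest normal pattern), and 5 of 6 tested cluster-B1 cases lost the
    maternal allele (the last one normal). This constructs call records and
    cluster labels matching exactly those counts, plus the expected-state
    map, so the concordance arithmetic can be recomputed.
    """
    calls, labels = [], {}
    for i in range(12):
        case_id = f"A-{i + 1:02d}"
        labels[case_id] = "A"
        paternal_lost = i < 9
        calls.append(MethylationCallRecord(case_id, True, not paternal_lost, True))
    for i in range(6):
        case_id = f"B1-{i + 1:02d}"
        labels[case_id] = "B1"
        maternal_lost = i < 5
        calls.append(MethylationCallRecord(case_id, not maternal_lost, True, True))
    expected = {"A": PATERNAL_LOSS, "B1": MATERNAL_LOSS}
    return calls, labels, expected
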