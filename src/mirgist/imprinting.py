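"""14q32 (DLK1-DIO3) allelic-state classification and cohort summaries.

The 14q32 miRNA mega-cluster is imprinted: the miRNAs are transcribed only
from the maternal allele, the paternal copy being silenced by methylation of
the MEG3-promoter DMR. Methylation-specific PCR with maternal/paternal
primers therefore reads out which alleles are present:

* both bands            -> normal imprinted pattern (both alleles retained);
* maternal band only    -> loss of the *paternal* (silent) allele — no
  expression change despite genomic loss by FISH;
* paternal band only    -> loss of the *maternal* (expressed) allele — the
  cluster goes dark;
* no bands / failed bisulfite-conversion control -> uninterpretable.

A "normal pattern" call in a case with FISH-proven loss is a discordance
(typically stromal-DNA admixture); it is flagged, never reclassified. This
module also computes cluster-wise concordance fractions against an expected
state per cluster, FISH 14q32 loss rates, and cohort genotype/SDHB counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import CaseRecord, MethylationCallRecord

logger = logging.getLogger(__name__)

NORMAL_PATTERN = "normal_pattern"
PATERNAL_LOSS = "paternal_loss"
MATERNAL_LOSS = "maternal_loss"
UNINTERPRETABLE = "uninterpretable"

STATES = (NORMAL_PATTERN, PATERNAL_LOSS, MATERNAL_LOSS, UNINTERPRETABLE)


@dataclass(frozen=True)
class AllelicState:
    case_id: str
    state: str

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown allelic state {self.state!r}")


@dataclass(frozen=True)
class ConcordanceSummary:
    """Fraction of a cluster's interpretable cases matching the expectation."""

    cluster: str
    n_tested: int
    n_matching: int

    @property
    def fraction(self) -> float:
        return self.n_matching / self.n_tested if self.n_tested else math.nan

    @property
    def percent(self) -> int:
        """Display rounding to the nearest integer percent."""
        if self.n_tested == 0:
            raise ValueError(f"cluster {self.cluster!r}: no tested cases")
        return round(100 * self.fraction)


def classify_allelic_state(call: MethylationCallRecord) -> AllelicState:
    """Map one band-call record to an allelic state (total on the 2x2x2 space)."""
    if not call.conversion_control_ok or (not call.maternal_band and not call.paternal_band):
        state = UNINTERPRETABLE
    elif call.maternal_band and call.paternal_band:
        state = NORMAL_PATTERN
    elif call.maternal_band:
        state = PATERNAL_LOSS
    else:
        state = MATERNAL_LOSS
    return AllelicState(call.case_id, state)


def cluster_concordance(
    states: Sequence[AllelicState],
    labels: Mapping[str, str],
    expected: Mapping[str, str],
) -> list[ConcordanceSummary]:
    """Per cluster, how many interpretable tested cases show the expected state.

    ``expected`` maps cluster name -> allelic state (e.g. ``{"A":
    "paternal_loss", "B1": "maternal_loss"}``). Cases without a label are
    skipped with a log entry; a cluster with zero tested cases yields a
    summary with ``n_tested = 0`` and an undefined (NaN) fraction.
    """
    out = []
    for cluster, want in expected.items():
        if want not in STATES:
            raise ValueError(f"unknown expected state {want!r} for cluster {cluster!r}")
        tested = 0
        matching = 0
        for s in states:
            label = labels.get(s.case_id)
            if label is None:
                logger.info("case %s has no cluster label; skipped", s.case_id)
                continue
            if label != cluster or s.state == UNINTERPRETABLE:
                continue
            tested += 1
            if s.state == want:
                matching += 1
        if tested == 0:
            logger.warning("cluster %s: no interpretable tested cases", cluster)
        out.append(ConcordanceSummary(cluster, tested, matching))
    return out


def flag_discordant_normals(
    states: Sequence[AllelicState], cases: Sequence[CaseRecord]
) -> list[str]:
    """Cases called normal-pattern despite FISH-proven 14q32 loss.

    These typically reflect admixed non-tumor DNA retaining the normal
    imprinted arrangement; they are reported, never reclassified.
    """
    fish = {c.case_id: c.fish_14q for c in cases}
    return sorted(
        s.case_id
        for s in states
        if s.state == NORMAL_PATTERN and fish.get(s.case_id) == "loss"
    )


def fish_loss_rate(
    cases: Sequence[CaseRecord],
    subset: Callable[[CaseRecord], bool] = lambda c: True,
) -> tuple[int, int, float]:
    """(n_tested, n_loss, fraction) of 14q32 FISH loss in a case subset.

    Only FISH-tested cases count; an empty tested subset is an error. The
    fraction is kept at full precision (display rounding is the caller's
    concern, e.g. ``round(100 * fraction)``).
    """
    tested = [c for c in cases if subset(c) and c.fish_14q != "not_tested"]
    if not tested:
        raise ValueError("no FISH-tested cases match the subset")
    n_loss = sum(1 for c in tested if c.fish_14q == "loss")
    return len(tested), n_loss, n_loss / len(tested)


def cohort_counts(cases: Iterable[CaseRecord]) -> pd.DataFrame:
    """Cohort summary: genotype counts, SDHB IHC by class, class sizes.

    Returns a long table with columns (category, key, count). Genotype
    categories are mutually exclusive and exhaustive, so their counts sum to
    the number of cases.
    """
    cases = list(cases)
    rows: list[tuple[str, str, int]] = [("total", "cases", len(cases))]
    for genotype in ("KIT", "PDGFRA", "BRAF", "WT"):
        rows.append(("genotype", genotype, sum(1 for c in cases if c.genotype == genotype)))
    for cohort in ("adult_mutant", "adult_wt", "pediatric_wt"):
        rows.append(("class", cohort, sum(1 for c in cases if c.cohort == cohort)))
        for sdhb in ("positive", "negative", "not_tested"):
            rows.append(
                (
                    f"sdhb_{cohort}",
                    sdhb,
                    sum(1 for c in cases if c.cohort == cohort and c.sdhb_ihc == sdhb),
                )
            )
    rows.append(("carney_triad", "yes", sum(1 for c in cases if c.carney_triad)))
    return pd.DataFrame(rows, columns=["category", "key", "count"])
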