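"""Ct pre-processing: censor, detection-filter, mean-normalize, exponentiate.

The pipeline order is fixed and stage-checked:

    raw --censor--> censored --filter--> filtered --mean_normalize-->
    mean_normalized --to_relative_expression--> ExpressionMatrix

* Censoring: Ct values strictly over the threshold (default 35 cycles) are
  treated as amplification noise and set to missing.
* Detection filter: a miRNA detected in fewer than ``min_fraction`` of
  samples (default 20%) is dropped; internal-control assays are dropped
  unconditionally.
* Mean normalization: the per-sample mean Ct (over present values) is
  subtracted from each Ct of that sample.
* Relative expression: ``2 ** (ct_max - ct)`` with ``ct_max`` the maximum
  mean-normalized value. With a single global ``ct_max`` every expression
  value is >= 1 and the minimum is exactly 1; a per-feature ``ct_max`` is
  available via ``scope="feature"``.

Because Ct is a log2-scale inverse-abundance measure, lower Ct always means
strictly higher relative expression within a sample, and ranks are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io_formats import CtRecord

ATOL = 1e-9

Stage = Literal["raw", "censored", "filtered", "mean_normalized"]
_STAGES = ("raw", "censored", "filtered", "mean_normalized")


class StageError(ValueError):
    """An operation was applied out of pipeline order."""


@dataclass
class CtMatrix:
    """A features x samples grid of (possibly missing) Ct values.

    ``values`` is a float DataFrame indexed by feature id with sample-id
    columns; NaN encodes missing. ``is_control`` flags internal-control
    assays; ``pools`` records each feature's TLDA card (A/B).
    """

    values: pd.DataFrame
    stage: Stage = "raw"
    is_control: pd.Series | None = None
    pools: pd.Series | None = None

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.values = self.values.astype(float)
        if self.is_control is None:
            self.is_control = pd.Series(False, index=self.values.index)
        self.is_control = self.is_control.reindex(self.values.index, fill_value=False)
        if self.stage in ("raw", "censored"):
            present = self.values.to_numpy()
            if np.any(present[np.isfinite(present)] <= 0):
                raise ValueError("present Ct values must be > 0")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def _require_stage(self, expected: Stage, op: str) -> None:
        if self.stage != expected:
            raise StageError(f"{op} requires stage {expected!r}, got {self.stage!r}")

    @classmethod
    def from_records(cls, records: Iterable[CtRecord], stage: Stage = "raw") -> "CtMatrix":
        """Pivot long-format Ct records into a matrix (pools concatenated)."""
        records = list(records)
        if not records:
            raise ValueError("no Ct records")
        features, samples = [], []
        fseen, sseen = set(), set()
        control, pool = {}, {}
        for r in records:
            if r.feature_id not in fseen:
                fseen.add(r.feature_id)
                features.append(r.feature_id)
                control[r.feature_id] = r.is_control
                pool[r.feature_id] = r.pool
            if r.sample_id not in sseen:
                sseen.add(r.sample_id)
                samples.append(r.sample_id)
        values = pd.DataFrame(np.nan, index=features, columns=samples, dtype=float)
        for r in records:
            values.at[r.feature_id, r.sample_id] = np.nan if r.ct is None else r.ct
        return cls(
            values,
            stage=stage,
            is_control=pd.Series(control),
            pools=pd.Series(pool),
        )

    def to_records(self) -> list[CtRecord]:
        """Back to long format (one record per cell, missing kept)."""
        out = []
        pools = self.pools if self.pools is not None else pd.Series("A", index=self.values.index)
        for feature in self.values.index:
            for sample in self.values.columns:
                v = self.values.at[feature, sample]
                out.append(
                    CtRecord(
                        feature,
                        sample,
                        None if pd.isna(v) else float(v),
                        pools.get(feature, "A"),
                        bool(self.is_control.get(feature, False)),
                    )
                )
        return out


@dataclass
class ExpressionMatrix:
    """Normalized relative expression ``2 ** (ct_max - ct)``.

    With the global ``ct_max`` convention every present value is >= 1 and the
    matrix minimum equals 1 (attained at the cell holding ``ct_max``).
    ``removed_blocks`` annotates feature blocks dropped after the fact, in
    which case the minimum may exceed 1.
    """

    values: pd.DataFrame
    ct_max: float | pd.Series
    scope: Literal["global", "feature"] = "global"
    removed_blocks: list[str] = field(default_factory=list)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def censor_cts(m: CtMatrix, threshold: float = 35.0) -> CtMatrix:
    """Censor late-cycle noise: any Ct strictly over ``threshold`` -> missing.

    The boundary is strict ("over 35"): a Ct of exactly 35 is retained.
    Idempotent: censoring a censored matrix changes nothing.
    """
    if m.stage not in ("raw", "censored"):
        raise StageError(f"censor_cts requires stage 'raw' (or 'censored'), got {m.stage!r}")
    values = m.values.where(m.values <= threshold)
    return replace(m, values=values, stage="censored")


def filter_low_detection(m: CtMatrix, min_fraction: float = 0.20) -> CtMatrix:
    """Drop features detected in fewer than ``min_fraction`` of samples.

    The boundary is strict in the other direction ("less than 20% excluded"):
    a feature detected in exactly 20% of samples is retained. Internal
    controls are removed unconditionally — the analysis matrix is
    mean-normalized, not control-normalized.
    """
    m._require_stage("censored", "filter_low_detection")
    n_samples = m.values.shape[1]
    if n_samples == 0:
        raise ValueError("matrix has zero samples")
    detected = m.values.notna().sum(axis=1) / n_samples
    keep = (detected >= min_fraction - ATOL) & ~m.is_control.astype(bool)
    values = m.values.loc[keep]
    pools = m.pools.loc[keep] if m.pools is not None else None
    return CtMatrix(values, stage="filtered", is_control=m.is_control.loc[keep], pools=pools)


def mean_normalize(m: CtMatrix) -> CtMatrix:
    """Subtract each sample's mean Ct (over its present values).

    After normalization every sample's mean over present values is 0 (within
    1e-9). A sample with no present values is an error naming the sample.
    """
    m._require_stage("filtered", "mean_normalize")
    empty = m.values.columns[m.values.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"sample(s) with no detected miRNAs: {list(empty)}")
    values = m.values - m.values.mean(axis=0, skipna=True)
    return replace(m, values=values, stage="mean_normalized")


def to_relative_expression(
    m: CtMatrix, scope: Literal["global", "feature"] = "global"
) -> ExpressionMatrix:
    """Convert mean-normalized Cts to relative expression ``2**(ct_max - ct)``.

    ``scope="global"`` (default) uses one reference maximum over the whole
    matrix; ``scope="feature"`` re-references each miRNA to its own maximum.
    """
    m._require_stage("mean_normalized", "to_relative_expression")
    if m.values.notna().to_numpy().sum() == 0:
        raise ValueError("matrix has no present values")
    if scope == "global":
        ct_max: float | pd.Series = float(np.nanmax(m.values.to_numpy()))
        expr = np.power(2.0, ct_max - m.values)
    elif scope == "feature":
        ct_max = m.values.max(axis=1, skipna=True)
        expr = np.power(2.0, m.values.rsub(ct_max, axis=0))
    else:
        raise ValueError(f"scope must be 'global' or 'feature', got {scope!r}")
    return ExpressionMatrix(expr, ct_max=ct_max, scope=scope)


def preprocess_pipeline(
    m: CtMatrix,
    *,
    censor_threshold: float = 35.0,
    min_fraction: float = 0.20,
    scope: Literal["global", "feature"] = "global",
) -> ExpressionMatrix:
    """Run the four fixed steps in order and return the expression matrix."""
    return to_relative_expression(
        mean_normalize(filter_low_detection(censor_cts(m, censor_threshold), min_fraction)),
        scope=scope,
    )
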