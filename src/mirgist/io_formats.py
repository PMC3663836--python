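"""Readers and writers for every table the pipeline touches.

All formats are plain delimited text (CSV or TSV) with a header row, UTF-8.
Tables handled here:

* long-format Ct tables from TaqMan low-density arrays
  (feature, sample, Ct, card pool A/B, internal-control flag);
* case metadata (demographics, genotype, 14q32 FISH state, SDHB
  immunohistochemistry, risk, follow-up);
* predicted miRNA -> gene target pairs (two-column TSV);
* methylation-specific PCR band calls for the MEG3-promoter DMR;
* generic result tables (differential expression, enrichment, ...).

Validation is strict: files violating a declared invariant are rejected with
an error naming the offending row or column; there is no silent coercion.
Missing Ct values may be spelled "", "NA", "Undetermined" or "ND" — qPCR
exports vary.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: tokens accepted as a missing Ct (or missing value generally) on input
MISSING_TOKENS = frozenset({"", "NA", "Undetermined", "ND"})

#: sentinel written for missing values on output
NA_SENTINEL = "NA"

#: internal-control assays carried on the TLDA cards
CONTROL_FEATURES = frozenset({"MammU6", "RNU24", "RNU43", "RNU44", "RNU48", "RNU6B"})

POOLS = frozenset({"A", "B"})
AGE_CLASSES = frozenset({"adult", "pediatric"})
SEXES = frozenset({"M", "F"})
LOCATIONS = frozenset({"stomach", "jejunum", "ileum", "retroperitoneum"})
GENOTYPES = frozenset({"KIT", "PDGFRA", "BRAF", "WT"})
FISH_STATES = frozenset({"loss", "diploid", "trisomy", "not_tested"})
SDHB_STATES = frozenset({"positive", "negative", "not_tested"})
RISKS = frozenset({"L", "I", "H", "not_available"})
FOLLOWUPS = frozenset({"DOD", "WD", "AWD", "not_available"})


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class RowError(ValueError):
    """A row violates a declared invariant; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(frozen=True)
class CtRecord:
    """One well of a TaqMan array: a feature/sample Ct observation."""

    feature_id: str
    sample_id: str
    ct: float | None
    pool: str = "A"
    is_control: bool = False

    def __post_init__(self):
        if self.ct is not None and (not math.isfinite(self.ct) or self.ct <= 0):
            raise ValueError(
                f"Ct for ({self.feature_id}, {self.sample_id}) must be finite "
                f"and > 0, got {self.ct}"
            )
        if self.pool not in POOLS:
            raise ValueError(f"pool must be one of {sorted(POOLS)}, got {self.pool!r}")


@dataclass(frozen=True)
class CaseRecord:
    """Clinico-genomic metadata for one tumor case."""

    case_id: str
    age_class: str
    sex: str
    location: str
    genotype: str
    mutation: str | None = None
    fish_14q: str = "not_tested"
    sdhb_ihc: str = "not_tested"
    carney_triad: bool = False
    risk: str = "not_available"
    followup: str = "not_available"
    histology: str | None = None
    age: int | None = None

    def __post_init__(self):
        for field, value, allowed in (
            ("age_class", self.age_class, AGE_CLASSES),
            ("sex", self.sex, SEXES),
            ("location", self.location, LOCATIONS),
            ("genotype", self.genotype, GENOTYPES),
            ("fish_14q", self.fish_14q, FISH_STATES),
            ("sdhb_ihc", self.sdhb_ihc, SDHB_STATES),
            ("risk", self.risk, RISKS),
            ("followup", self.followup, FOLLOWUPS),
        ):
            if value not in allowed:
                raise ValueError(
                    f"case {self.case_id}: {field}={value!r} not in {sorted(allowed)}"
                )
        wt_mutation = self.mutation is None or self.mutation == "WT"
        if (self.genotype == "WT") != wt_mutation:
            raise ValueError(
                f"case {self.case_id}: genotype {self.genotype!r} inconsistent "
                f"with mutation {self.mutation!r}"
            )
        if self.age_class == "pediatric" and self.age is not None and self.age >= 20:
            raise ValueError(
                f"case {self.case_id}: pediatric cases must be < 20 years, got {self.age}"
            )

    @property
    def is_mutant(self) -> bool:
        """True for KIT/PDGFRA/BRAF-mutant tumors."""
        return self.genotype != "WT"

    @property
    def cohort(self) -> str:
        """One of 'adult_mutant', 'adult_wt', 'pediatric_wt'."""
        if self.age_class == "pediatric":
            return "pediatric_wt"
        return "adult_mutant" if self.is_mutant else "adult_wt"


@dataclass(frozen=True)
class TargetPair:
    """A predicted miRNA -> gene regulatory interaction."""

    mirna_id: str
    gene_id: str


@dataclass(frozen=True)
class MethylationCallRecord:
    """Band calls from the MEG3-promoter methylation-specific PCR.

    ``maternal_band`` / ``paternal_band`` record presence of the
    allele-specific products on the gel; ``conversion_control_ok`` flags a
    successful bisulfite conversion. A failed control renders the record
    uninterpretable downstream.
    """

    case_id: str
    maternal_band: bool
    paternal_band: bool
    conversion_control_ok: bool = True


# ---------------------------------------------------------------------------
# low-level helpers


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _read_rows(path: str | Path, delimiter: str | None) -> tuple[list[str], list[tuple[int, dict[str, str]]]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path, delimiter)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        rows = [(i, row) for i, row in enumerate(reader, start=2)]
    return list(header), rows


def _require_columns(header: Sequence[str], required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_bool(token: str, line: int, column: str) -> bool:
    t = token.strip().lower()
    if t in {"true", "yes", "1", "t", "y"}:
        return True
    if t in {"false", "no", "0", "f", "n"}:
        return False
    raise RowError(line, f"column {column!r}: cannot parse boolean from {token!r}")


# ---------------------------------------------------------------------------
# Ct tables

DEFAULT_CT_SCHEMA = {
    "feature_id": "feature_id",
    "sample_id": "sample_id",
    "ct": "ct",
    "pool": "pool",
    "is_control": "is_control",
}


def read_ct_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    strict_missing: bool = False,
    delimiter: str | None = None,
) -> list[CtRecord]:
    """Read a long-format Ct table into validated :class:`CtRecord` rows.

    ``schema`` maps canonical column names (``feature_id``, ``sample_id``,
    ``ct`` and optionally ``pool``, ``is_control``) to the file's actual
    headers. Non-numeric Ct tokens in :data:`MISSING_TOKENS` become missing
    values unless ``strict_missing`` is set, in which case they raise a
    :class:`RowError` with the line number. Duplicate (feature, sample) keys
    are always an error.
    """
    cols = dict(DEFAULT_CT_SCHEMA)
    if schema:
        cols.update(schema)
    header, rows = _read_rows(path, delimiter)
    _require_columns(header, [cols["feature_id"], cols["sample_id"], cols["ct"]], path)
    has_pool = cols["pool"] in header
    has_control = cols["is_control"] in header

    records: list[CtRecord] = []
    seen: set[tuple[str, str]] = set()
    for line, row in rows:
        feature = row[cols["feature_id"]].strip()
        sample = row[cols["sample_id"]].strip()
        key = (feature, sample)
        if key in seen:
            raise RowError(line, f"duplicate (feature, sample) key {key}")
        seen.add(key)
        token = (row[cols["ct"]] or "").strip()
        if token in MISSING_TOKENS:
            if strict_missing:
                raise RowError(line, f"non-numeric Ct {token!r} for {key}")
            ct: float | None = None
        else:
            try:
                ct = float(token)
            except ValueError as exc:
                raise RowError(line, f"cannot parse Ct {token!r} for {key}") from exc
        pool = row[cols["pool"]].strip() if has_pool else "A"
        if has_control:
            is_control = _parse_bool(row[cols["is_control"]], line, cols["is_control"])
        else:
            is_control = feature in CONTROL_FEATURES
        try:
            records.append(CtRecord(feature, sample, ct, pool, is_control))
        except ValueError as exc:
            raise RowError(line, str(exc)) from exc
    if not records:
        logger.warning("Ct table %s is empty", path)
    return records


def write_ct_table(records: Iterable[CtRecord], path: str | Path, *, delimiter: str = ",") -> None:
    """Write Ct records in the long format accepted by :func:`read_ct_table`."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["feature_id", "sample_id", "ct", "pool", "is_control"])
        for r in records:
            ct = NA_SENTINEL if r.ct is None else repr(r.ct)
            writer.writerow([r.feature_id, r.sample_id, ct, r.pool, str(r.is_control).lower()])


# ---------------------------------------------------------------------------
# case metadata

_FISH_MAP = {"loss": "loss", "diploid": "diploid", "trisomy": "trisomy", "na": "not_tested"}
_SDHB_MAP = {"positive": "positive", "negative": "negative", "na": "not_tested"}
_RISK_MAP = {"l": "L", "i": "I", "h": "H", "na": "not_available"}
_FOLLOWUP_MAP = {"dod": "DOD", "wd": "WD", "awd": "AWD", "na": "not_available"}
_LOCATION_MAP = {loc: loc for loc in LOCATIONS}

CASE_COLUMNS = [
    "case_id", "age_class", "sex", "age", "location", "genotype", "mutation",
    "fish_14q32", "sdhb_ihc", "followup", "risk", "histology", "carney_triad",
]


def _map_enum(token: str, mapping: Mapping[str, str], line: int, column: str) -> str:
    t = token.strip().lower()
    if t not in mapping:
        raise RowError(line, f"column {column!r}: unknown token {token!r}")
    return mapping[t]


def _parse_genotype(raw: str, line: int) -> tuple[str, str]:
    """Split a genotype cell like 'KIT ex 11' into (gene, raw spelling)."""
    gene = raw.strip().split()[0] if raw.strip() else ""
    if gene not in GENOTYPES:
        raise RowError(line, f"column 'genotype': unknown genotype {raw!r}")
    return gene, raw.strip()


def read_case_table(path: str | Path, *, delimiter: str | None = None) -> list[CaseRecord]:
    """Read a case-metadata table using the printed tables' spellings.

    Enum cells keep the tables' verbatim vocabulary ("DOD", "WD", "AWD",
    "Loss", "Diploid", "H/I/L", "E&S", ...) and are normalized through
    explicit maps; an unknown token is a validation error, never a guess.
    "NA" becomes ``not_tested`` / ``not_available`` depending on the field.
    """
    header, rows = _read_rows(path, delimiter)
    if not rows and not header:
        logger.warning("case table %s is empty", path)
        return []
    _require_columns(header, CASE_COLUMNS, path)

    records: list[CaseRecord] = []
    for line, row in rows:
        genotype, _raw = _parse_genotype(row["genotype"], line)
        mutation = row["mutation"].strip()
        mutation_val = None if mutation.upper() in {"NA", ""} else mutation
        histology = row["histology"].strip()
        age_token = row["age"].strip()
        try:
            record = CaseRecord(
                case_id=row["case_id"].strip(),
                age_class=row["age_class"].strip().lower(),
                sex=row["sex"].strip().upper(),
                age=None if age_token in MISSING_TOKENS else int(age_token),
                location=_map_enum(row["location"], _LOCATION_MAP, line, "location"),
                genotype=genotype,
                mutation=mutation_val,
                fish_14q=_map_enum(row["fish_14q32"], _FISH_MAP, line, "fish_14q32"),
                sdhb_ihc=_map_enum(row["sdhb_ihc"], _SDHB_MAP, line, "sdhb_ihc"),
                followup=_map_enum(row["followup"], _FOLLOWUP_MAP, line, "followup"),
                risk=_map_enum(row["risk"], _RISK_MAP, line, "risk"),
                histology=None if histology.upper() in {"NA", ""} else histology,
                carney_triad=_parse_bool(row["carney_triad"], line, "carney_triad"),
            )
        except ValueError as exc:
            if isinstance(exc, RowError):
                raise
            raise RowError(line, str(exc)) from exc
        records.append(record)
    if not records:
        logger.warning("case table %s has a header but no rows", path)
    ids = [r.case_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate case ids {dupes}")
    return records


def write_case_table(records: Iterable[CaseRecord], path: str | Path) -> None:
    """Write cases back out in the verbatim-spelling TSV schema."""
    inv_fish = {"loss": "Loss", "diploid": "Diploid", "trisomy": "Trisomy", "not_tested": "NA"}
    inv_na = lambda v: "NA" if v in {"not_tested", "not_available"} else v  # noqa: E731
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(CASE_COLUMNS)
        for r in records:
            writer.writerow([
                r.case_id, r.age_class, r.sex,
                NA_SENTINEL if r.age is None else r.age,
                r.location.capitalize(),
                r.genotype,
                r.mutation if r.mutation is not None else NA_SENTINEL,
                inv_fish[r.fish_14q], inv_na(r.sdhb_ihc), inv_na(r.followup),
                inv_na(r.risk),
                r.histology if r.histology is not None else NA_SENTINEL,
                "yes" if r.carney_triad else "no",
            ])


# ---------------------------------------------------------------------------
# target pairs, methylation calls, generic results


def read_target_pairs(path: str | Path, *, delimiter: str | None = None) -> list[TargetPair]:
    """Read a two-column (mirna_id, gene_id) predicted-target table."""
    header, rows = _read_rows(path, delimiter)
    _require_columns(header, ["mirna_id", "gene_id"], path)
    pairs: list[TargetPair] = []
    seen: set[tuple[str, str]] = set()
    for line, row in rows:
        key = (row["mirna_id"].strip(), row["gene_id"].strip())
        if key in seen:
            raise RowError(line, f"duplicate target pair {key}")
        seen.add(key)
        pairs.append(TargetPair(*key))
    return pairs


def write_target_pairs(pairs: Iterable[TargetPair], path: str | Path) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["mirna_id", "gene_id"])
        for p in pairs:
            writer.writerow([p.mirna_id, p.gene_id])


def read_methylation_calls(path: str | Path, *, delimiter: str | None = None) -> list[MethylationCallRecord]:
    """Read MEG3-DMR band calls (booleans per case)."""
    header, rows = _read_rows(path, delimiter)
    _require_columns(
        header, ["case_id", "maternal_band", "paternal_band", "conversion_control_ok"], path
    )
    out = []
    for line, row in rows:
        out.append(
            MethylationCallRecord(
                case_id=row["case_id"].strip(),
                maternal_band=_parse_bool(row["maternal_band"], line, "maternal_band"),
                paternal_band=_parse_bool(row["paternal_band"], line, "paternal_band"),
                conversion_control_ok=_parse_bool(
                    row["conversion_control_ok"], line, "conversion_control_ok"
                ),
            )
        )
    return out


def write_methylation_calls(records: Iterable[MethylationCallRecord], path: str | Path) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["case_id", "maternal_band", "paternal_band", "conversion_control_ok"])
        for r in records:
            writer.writerow([
                r.case_id,
                str(r.maternal_band).lower(),
                str(r.paternal_band).lower(),
                str(r.conversion_control_ok).lower(),
            ])


def write_results(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write any result DataFrame with the "NA" missing-value sentinel.

    Round-trips through :func:`read_results` field-for-field.
    """
    if table is None:
        raise ValueError("table must not be None")
    if format not in {"csv", "tsv"}:
        raise ValueError(f"format must be 'csv' or 'tsv', got {format!r}")
    sep = "," if format == "csv" else "\t"
    table.to_csv(path, sep=sep, index=False, na_rep=NA_SENTINEL)


def read_results(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() == ".tsv" else "csv"
    sep = "," if format == "csv" else "\t"
    return pd.read_csv(path, sep=sep, na_values=[NA_SENTINEL], keep_default_na=False)


# ---------------------------------------------------------------------------
# packaged fixtures


def packaged_fixture_path(name: str) -> Path:
    """Path to a data table shipped with the package (e.g. the case tables)."""
    from importlib.resources import files

    resource = files("mirgist.data").joinpath(name)
    return Path(str(resource))


def load_case_fixture() -> list[CaseRecord]:
    """The 73-case cohort metadata table shipped with the package."""
    return read_case_table(packaged_fixture_path("tables1_3_cases.tsv"))


def load_de_mirna_fixture() -> pd.DataFrame:
    """The published per-comparison differentially-expressed miRNA lists."""
    return read_results(packaged_fixture_path("table4_de_mirnas.tsv"), format="tsv")
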