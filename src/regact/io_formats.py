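"""On-disk formats and probe-level preprocessing.

Gene sets travel as GMT (one regulator per line: name, description, target
symbols), expression and clinical data as UTF-8 TSV with ``NA`` as the
missing-value token. Expression TSVs are genes-as-rows, samples-as-columns
with a leading ``gene`` column, mirroring GEO series-matrix layout without
binary dependencies.

Regulator sets emulate MSigDB C3 motif sets: the set name encodes the
regulator (``CART1_01`` -> gene symbol ``CART1``), and miRNA seed-match sets
are recognised by name pattern since the format itself carries no class tag.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TWO_CHANNEL = "two_channel_log_ratio"
SINGLE_CHANNEL = "single_channel_intensity"
DIALECTS = (TWO_CHANNEL, SINGLE_CHANNEL)

SUBSETS = ("fibroproliferative", "inflammatory", "limited", "normal_like")
CUTANEOUS_SUBTYPES = ("dcSSc", "lcSSc", "unknown")

#: default rule marking miRNA seed-match motif sets by name
MIRNA_NAME_PATTERN = r"(^MIR|_MIR|^LET7|miR)"

NA_TOKEN = "NA"


class FormatError(ValueError):
    """Malformed or invalid on-disk artifact."""


@dataclass(frozen=True)
class RegulatorSet:
    """A named regulator (TF or miRNA) with its target-gene symbol set."""

    name: str
    regulator_class: str  # "TF" | "miRNA"
    gene_symbol: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if not self.targets:
            raise FormatError(f"regulator set {self.name!r} has no targets")
        if self.regulator_class not in ("TF", "miRNA"):
            raise FormatError(
                f"regulator set {self.name!r}: bad class {self.regulator_class!r}"
            )


@dataclass
class ProbeMatrix:
    """Probe-level values (missing allowed) plus a probe->genes mapping.

    A probe may map to several genes; it is then assigned to all of them
    when collapsing.
    """

    values: pd.DataFrame  # probes x samples, NaN = missing
    probe_to_gene: Mapping[str, tuple[str, ...]]
    dialect: str = TWO_CHANNEL

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise FormatError(f"unknown dialect {self.dialect!r}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids in probe matrix")


@dataclass
class ExpressionMatrix:
    """Gene-level expression, no missing values, unique gene symbols."""

    values: pd.DataFrame  # genes x samples
    dialect: str = TWO_CHANNEL

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise FormatError(f"unknown dialect {self.dialect!r}")
        if self.values.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            raise FormatError("duplicate gene symbols in expression matrix")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates.

    ``fvc_percent_predicted`` holds per-sample lists of
    ``(months_from_baseline, value)`` pairs sorted by time; on disk they are
    encoded ``"0:95.0;42:88.5"``. ``ild`` is True/False/None (unknown).
    """

    data: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("sample_id", "patient_id", "mrss", "subset")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            raise FormatError("clinical table must be indexed by sample_id")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        mrss = df["mrss"].dropna()
        bad = mrss[(mrss < 0) | (mrss > 51)]
        if len(bad):
            raise FormatError(
                f"MRSS out of range 0-51 for samples {list(bad.index[:5])}"
            )
        bad_subset = set(df["subset"].dropna()) - set(SUBSETS)
        if bad_subset:
            raise FormatError(f"unknown intrinsic subsets {sorted(bad_subset)}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def mrss(self) -> pd.Series:
        return self.data["mrss"]

    def subset_samples(self, subset: str) -> pd.Index:
        return self.data.index[self.data["subset"] == subset]


@dataclass
class ActivityMatrix:
    """Normalized regulator activity scores (regulators x samples)."""

    scores: pd.DataFrame
    n_permutations: int = 0
    seed: int | None = None
    dialect: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise FormatError("activity scores must be finite")

    @property
    def regulators(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns


# ---------------------------------------------------------------------------
# regulator class / symbol rules


def classify_regulator(name: str, mirna_pattern: str = MIRNA_NAME_PATTERN) -> str:
    """TF or miRNA, decided by the set-name pattern rule."""
    return "miRNA" if re.search(mirna_pattern, name, re.IGNORECASE) else "TF"


def extract_symbol(
    name: str, aliases: Mapping[str, str] | None = None
) -> str | None:
    """Gene symbol for network use: token before the first underscore.

    Returns None when no symbol can be extracted (an "unclassified motif").
    An alias table resolves motif names to HGNC-style symbols (NMYC->MYCN).
    """
    token = name.split("_", 1)[0].strip().upper()
    if not token or not re.match(r"^[A-Z0-9-]+$", token):
        return None
    if aliases:
        token = aliases.get(token, token)
    return token


# ---------------------------------------------------------------------------
# GMT


def read_gmt(
    path: str | Path, mirna_pattern: str = MIRNA_NAME_PATTERN
) -> list[RegulatorSet]:
    """Parse a GMT file into regulator sets.

    Each line is ``name<TAB>description<TAB>symbol...``; duplicate target
    symbols are dropped. Regulator class comes from the name-pattern rule.
    """
    path = Path(path)
    sets: list[RegulatorSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            name = fields[0].strip()
            targets = frozenset(t.strip() for t in fields[2:] if t.strip())
            if not targets:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no targets")
            sets.append(
                RegulatorSet(
                    name=name,
                    regulator_class=classify_regulator(name, mirna_pattern),
                    gene_symbol=extract_symbol(name) or name.upper(),
                    targets=targets,
                )
            )
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Iterable[RegulatorSet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.regulator_class, *sorted(s.targets)]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# probe preprocessing


def preprocess_probes(pm: ProbeMatrix) -> ExpressionMatrix:
    """Impute missing values and collapse probes to genes.

    Missing entries are replaced by the probe's across-sample mean; probes
    missing in every sample cannot be imputed and are dropped with a warning.
    Genes measured by several probes are collapsed to the per-sample median.
    """
    vals = pm.values.astype(float)
    all_missing = vals.isna().all(axis=1)
    if all_missing.any():
        dropped = list(vals.index[all_missing])
        warnings.warn(
            f"dropping {len(dropped)} probe(s) with no observed values: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
        vals = vals.loc[~all_missing]
    row_means = vals.mean(axis=1)
    vals = vals.apply(lambda col: col.fillna(row_means))

    # expand probe -> (possibly several) genes, then median-collapse per gene
    records: list[tuple[str, str]] = []
    for probe in vals.index:
        for gene in pm.probe_to_gene.get(probe, ()):
            records.append((probe, gene))
    if not records:
        raise FormatError("no probe maps to any gene")
    mapping = pd.DataFrame(records, columns=["probe", "gene"])
    expanded = vals.loc[mapping["probe"]]
    expanded.index = pd.Index(mapping["gene"], name="gene")
    collapsed = expanded.groupby(level="gene").median()
    return ExpressionMatrix(values=collapsed, dialect=pm.dialect)


# ---------------------------------------------------------------------------
# TSV readers / writers


def read_expression(
    path: str | Path,
    dialect: str = TWO_CHANNEL,
    probe_to_gene: Mapping[str, Sequence[str]] | None = None,
) -> ProbeMatrix:
    """Read an expression TSV (first column ``gene`` or ``probe``).

    Without an explicit probe map each row id is taken to be its own gene
    symbol (already gene-level data).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no sample columns")
    mapping = (
        {p: tuple(gs) for p, gs in probe_to_gene.items()}
        if probe_to_gene
        else {p: (str(p),) for p in df.index}
    )
    return ProbeMatrix(values=df, probe_to_gene=mapping, dialect=dialect)


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene", na_rep=NA_TOKEN)


def _parse_fvc_series(cell: object) -> list[tuple[float, float]]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    series = []
    for chunk in str(cell).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            months, value = chunk.split(":")
            series.append((float(months), float(value)))
        except ValueError as exc:
            raise FormatError(f"bad FVC series element {chunk!r}") from exc
    return sorted(series)


def format_fvc_series(series: Sequence[tuple[float, float]]) -> str:
    return ";".join(f"{m:g}:{v:g}" for m, v in sorted(series))


def _parse_bool(cell: object) -> bool | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    if text in ("", "na", "unknown"):
        return None
    raise FormatError(f"bad boolean value {cell!r}")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN])
    missing = [c for c in ClinicalTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        df["mrss"] = pd.to_numeric(df["mrss"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric MRSS") from exc
    for col in ("disease_duration_months", "age_at_diagnosis"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "cutaneous_subtype" in df.columns:
        df["cutaneous_subtype"] = df["cutaneous_subtype"].fillna("unknown")
        bad = set(df["cutaneous_subtype"]) - set(CUTANEOUS_SUBTYPES)
        if bad:
            raise FormatError(f"{path}: unknown cutaneous subtype(s) {sorted(bad)}")
    else:
        df["cutaneous_subtype"] = "unknown"
    df["ild"] = pd.Series(
        [_parse_bool(v) for v in df["ild"]] if "ild" in df.columns else None,
        index=df.index,
        dtype=object,
    )
    df["fvc_percent_predicted"] = (
        df["fvc_percent_predicted"].map(_parse_fvc_series)
        if "fvc_percent_predicted" in df.columns
        else [[] for _ in range(len(df))]
    )
    if "early_stage" in df.columns:
        df["early_stage"] = df["early_stage"].map(_parse_bool)
    elif "disease_duration_months" in df.columns:
        df["early_stage"] = df["disease_duration_months"] < 18
    else:
        df["early_stage"] = None
    if "treatment" not in df.columns:
        df["treatment"] = "unknown"
    df = df.set_index("sample_id")
    return ClinicalTable(data=df)


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    out = ct.data.copy()
    out["fvc_percent_predicted"] = out["fvc_percent_predicted"].map(
        format_fvc_series
    )
    out["ild"] = out["ild"].map(
        lambda v: NA_TOKEN if v is None else str(bool(v)).lower()
    )
    out.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA_TOKEN)


def read_scores(path: str | Path) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    return ActivityMatrix(scores=df)


def write_scores(am: ActivityMatrix, path: str | Path) -> None:
    am.scores.to_csv(
        path, sep="\t", index_label="regulator", float_format="%.17g"
    )
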