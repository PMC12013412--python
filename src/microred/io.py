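"""Table readers/writers and the end-to-end compute pipeline.

Formats (UTF-8, tab- or comma-delimited, header row):

* abundances — wide (first column species, one column per sample) or long
  (``sample_id``, ``species_id``, ``abundance``); both parse to the same
  communities;
* fluxes — long (``sample_id``, ``species_id``, ``function_id``, ``flux``),
  positive = secretion; pass ``invert_sign=True`` for raw solver output;
* reference — two columns (``function_id``, ``species_id``);
* universe — single column of species ids;
* traits — species by trait, with a ``kind`` row (binary|quantitative)
  directly under the header.

Missing values in output tables are written as ``NA`` (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    Community,
    FunctionReference,
    FunctionalProfile,
    MissingReason,
    RedundancyResult,
    ValidationError,
    compute_all,
    global_interdependency,
    DEFAULT_ZERO_TOL,
)
from .preprocessing import (
    DEFAULT_MIN_NONMISSING,
    DEFAULT_MIN_SPECIES,
    DEFAULT_UPTAKE_TOL,
    STATUS_UPTAKE,
    FilterReport,
    FluxTable,
    apply_function_filter,
    apply_sample_filter,
    pair_missingness,
    reference_from_corpus,
    restrict_and_renormalise,
)
from .rao import TraitMatrix

logger = logging.getLogger("microred")

RESULT_COLUMNS = (
    "sample_id",
    "function_id",
    "n",
    "m",
    "k",
    "producer_abundance_sum",
    "sample_taxon_fr",
    "reference_taxon_fr",
    "abundance_fr",
    "interdependency",
    "missing_reason",
)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs in one place; unknown YAML keys are rejected."""

    delimiter: str | None = None
    invert_sign: bool = False
    min_species: int = DEFAULT_MIN_SPECIES
    min_nonmissing: float = DEFAULT_MIN_NONMISSING
    tolerance: float = DEFAULT_UPTAKE_TOL
    zero_tol: float = DEFAULT_ZERO_TOL
    na_string: str = "NA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_species < 1:
            raise ValidationError("min_species must be >= 1")
        if not 0.0 <= self.min_nonmissing <= 1.0:
            raise ValidationError("min_nonmissing must be in [0, 1]")
        if self.tolerance < 0 or self.zero_tol < 0:
            raise ValidationError("tolerances must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter), dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: empty table")
    return df


def read_abundances(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read an abundance table and return it in long form.

    A table whose header contains ``sample_id``/``species_id``/``abundance``
    is taken as long form; anything else is treated as wide with species in
    the first column and one sample per remaining column.
    """
    df = _read_table(path, delimiter)
    cols = set(df.columns)
    if {"sample_id", "species_id", "abundance"} <= cols:
        long = df[["sample_id", "species_id", "abundance"]].copy()
    else:
        species_col = df.columns[0]
        long = df.melt(
            id_vars=[species_col], var_name="sample_id", value_name="abundance"
        ).rename(columns={species_col: "species_id"})
    long["abundance"] = pd.to_numeric(long["abundance"], errors="raise")
    # wide tables encode absence as 0; drop here so both forms agree
    long = long[long["abundance"] > 0].reset_index(drop=True)
    logger.info("read %d abundance records from %s", len(long), path)
    return long


def read_flux_table(
    path: str | Path, delimiter: str | None = None, invert_sign: bool = False
) -> FluxTable:
    df = _read_table(path, delimiter)
    needed = {"sample_id", "species_id", "function_id", "flux"}
    if not needed <= set(df.columns):
        raise ValidationError(
            f"{path}: flux table needs columns {sorted(needed)}"
        )
    df["flux"] = pd.to_numeric(df["flux"], errors="raise")
    table = FluxTable(df)
    if invert_sign:
        table = table.invert_sign()
    logger.info("read %d flux records from %s", len(table.frame), path)
    return table


def read_reference(
    path: str | Path, delimiter: str | None = None
) -> dict[str, FunctionReference]:
    df = _read_table(path, delimiter)
    if not {"function_id", "species_id"} <= set(df.columns):
        raise ValidationError(f"{path}: reference needs function_id and species_id")
    refs = {}
    for function_id, group in df.groupby("function_id", sort=True):
        refs[str(function_id)] = FunctionReference(
            str(function_id), frozenset(group["species_id"].astype(str))
        )
    return refs


def read_universe(path: str | Path, delimiter: str | None = None) -> frozenset[str]:
    df = _read_table(path, delimiter)
    return frozenset(df.iloc[:, 0].astype(str))


def read_trait_matrix(path: str | Path, delimiter: str | None = None) -> TraitMatrix:
    """Read a species-by-trait table whose first data row declares trait kinds."""
    df = _read_table(path, delimiter)
    id_col = df.columns[0]
    kind_row = df[df[id_col] == "kind"]
    if kind_row.empty:
        raise ValidationError(f"{path}: trait table needs a 'kind' row")
    kinds = tuple(kind_row.iloc[0, 1:])
    body = df[df[id_col] != "kind"]
    return TraitMatrix(
        species_ids=tuple(body[id_col]),
        trait_names=tuple(df.columns[1:]),
        values=body.iloc[:, 1:].astype(float).to_numpy(),
        kinds=kinds,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComputeOutput:
    results: pd.DataFrame
    report: FilterReport
    global_interdependency: pd.DataFrame


def _profile_for(
    flux: pd.DataFrame, community: Community, function_id: str
) -> FunctionalProfile:
    by_species = dict(zip(flux["species_id"], flux["flux"]))
    contributions = np.array(
        [max(by_species.get(s, 0.0), 0.0) for s in community.species_ids]
    )
    return FunctionalProfile(function_id, contributions)


def run_compute(
    abundances: pd.DataFrame,
    flux: FluxTable,
    reference: Mapping[str, FunctionReference] | None = None,
    universe: frozenset[str] | None = None,
    config: RunConfig = RunConfig(),
) -> ComputeOutput:
    """Full pipeline: restrict, filter, compute all measures per pair.

    When no curated reference is supplied one is derived from the corpus
    (union of observed producers per function) and logged as such.
    """
    communities, report = restrict_and_renormalise(abundances, universe)
    communities, sample_report = apply_sample_filter(communities, config.min_species)
    report = report.merge(sample_report)
    for sid, reason in report.excluded_samples.items():
        logger.info(
            "excluded sample %s (%s, richness=%s)",
            sid,
            reason,
            report.sample_richness.get(sid),
        )
    if not communities:
        raise ValidationError("no samples remain after filtering")

    statuses, clipped = pair_missingness(
        flux, config.tolerance, samples=communities.keys()
    )
    kept_functions, function_report = apply_function_filter(
        statuses, n_samples=len(communities), min_nonmissing=config.min_nonmissing
    )
    report = report.merge(function_report)
    for fid, frac in report.excluded_functions.items():
        logger.info("excluded function %s (non-missing fraction %.3f)", fid, frac)
    if not kept_functions:
        raise ValidationError("no functions remain after filtering")

    if reference is None:
        logger.info("no reference supplied; deriving capable sets from the corpus")
        reference = reference_from_corpus(clipped, config.zero_tol)

    status_map = {
        (row["sample_id"], row["function_id"]): row["status"]
        for _, row in statuses.iterrows()
    }
    flux_groups = dict(tuple(clipped.frame.groupby(["sample_id", "function_id"])))

    rows = []
    interdependencies: dict[str, list[float | None]] = {s: [] for s in communities}
    for sample_id in sorted(communities):
        community = communities[sample_id]
        for function_id in kept_functions:
            status = status_map.get((sample_id, function_id), "no_record")
            if status == STATUS_UPTAKE:
                result = RedundancyResult(
                    function_id=function_id,
                    sample_id=sample_id,
                    sample_taxon_fr=None,
                    reference_taxon_fr=None,
                    abundance_fr=None,
                    interdependency=None,
                    n=community.n,
                    m=reference[function_id].m,
                    k=0,
                    producer_abundance_sum=0.0,
                    missing_reason=MissingReason.UPTAKE_DETECTED,
                )
            else:
                group = flux_groups.get(
                    (sample_id, function_id),
                    clipped.frame.iloc[0:0],
                )
                profile = _profile_for(group, community, function_id)
                result = compute_all(
                    profile,
                    community,
                    reference[function_id],
                    sample_id=sample_id,
                    zero_tol=config.zero_tol,
                )
            interdependencies[sample_id].append(result.interdependency)
            rows.append(
                {
                    "sample_id": result.sample_id,
                    "function_id": result.function_id,
                    "n": result.n,
                    "m": result.m,
                    "k": result.k,
                    "producer_abundance_sum": result.producer_abundance_sum,
                    "sample_taxon_fr": result.sample_taxon_fr,
                    "reference_taxon_fr": result.reference_taxon_fr,
                    "abundance_fr": result.abundance_fr,
                    "interdependency": result.interdependency,
                    "missing_reason": result.missing_reason.value,
                }
            )
    results = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))

    global_rows = [
        {
            "sample_id": sample_id,
            "global_interdependency": global_interdependency(values),
            "n_functions": sum(v is not None for v in values),
        }
        for sample_id, values in sorted(interdependencies.items())
    ]
    return ComputeOutput(results, report, pd.DataFrame(global_rows))


def write_outputs(
    output: ComputeOutput, out_dir: str | Path, na_string: str = "NA"
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out_dir / "results.tsv",
        "filter_report": out_dir / "filter_report.tsv",
        "global_interdependency": out_dir / "global_interdependency.tsv",
    }
    output.results.to_csv(paths["results"], sep="\t", index=False, na_rep=na_string)
    output.report.to_frame().to_csv(
        paths["filter_report"], sep="\t", index=False, na_rep=na_string
    )
    output.global_interdependency.to_csv(
        paths["global_interdependency"], sep="\t", index=False, na_rep=na_string
    )
    return paths
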