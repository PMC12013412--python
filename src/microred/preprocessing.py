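"""Turn raw abundance and flux tables into validated computation inputs.

Conventions applied here, each configurable:

* flux tables are long-form records of (sample, species, function, flux) with
  positive = secretion; absent records mean zero contribution;
* abundances are restricted to a species universe (e.g. the set of modelled
  reconstructions) and renormalised per sample;
* samples with fewer than 25 species are excluded ("fewer than" is strict);
* a (sample, function) pair is missing when any flux is negative beyond
  tolerance (uptake) or when no flux is positive (no producers); negatives
  within tolerance are clipped to zero;
* functions kept for analysis need strictly more than 80 % non-missing pairs
  across retained samples.

Every exclusion is recorded in a :class:`FilterReport` so the pipeline is
auditable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .core import Community, FunctionReference, ValidationError

FLUX_COLUMNS = ("sample_id", "species_id", "function_id", "flux")

DEFAULT_MIN_SPECIES = 25
DEFAULT_MIN_NONMISSING = 0.8
DEFAULT_UPTAKE_TOL = 1e-9

STATUS_OK = "ok"
STATUS_NO_PRODUCERS = "no_producers"
STATUS_UPTAKE = "uptake_detected"


@dataclass(frozen=True)
class FluxTable:
    """Long-form per-species function outputs with unique (sample, species,
    function) keys, positive = secretion."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in FLUX_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"flux table lacks columns {missing}")
        df = df.loc[:, list(FLUX_COLUMNS)].copy()
        df["flux"] = df["flux"].astype(float)
        if df["flux"].isna().any():
            raise ValidationError("flux table contains NaN flux values")
        keys = df[["sample_id", "species_id", "function_id"]]
        dup = keys.duplicated()
        if dup.any():
            first = keys[dup].iloc[0]
            raise ValidationError(
                "duplicate flux record for "
                f"(sample={first['sample_id']!r}, species={first['species_id']!r}, "
                f"function={first['function_id']!r})"
            )
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def invert_sign(self) -> "FluxTable":
        """Flip the sign convention (raw solver output -> positive = secretion)."""
        df = self.frame.copy()
        df["flux"] = -df["flux"]
        return FluxTable(df)

    def functions(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["function_id"].unique()))

    def samples(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["sample_id"].unique()))


@dataclass
class FilterReport:
    """Audit trail of everything removed by the preprocessing rules."""

    excluded_samples: dict[str, str] = field(default_factory=dict)
    sample_richness: dict[str, int] = field(default_factory=dict)
    excluded_functions: dict[str, float] = field(default_factory=dict)
    pair_reasons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "function_id", "status"]
        )
    )

    def merge(self, other: "FilterReport") -> "FilterReport":
        merged = FilterReport(
            excluded_samples={**self.excluded_samples, **other.excluded_samples},
            sample_richness={**self.sample_richness, **other.sample_richness},
            excluded_functions={
                **self.excluded_functions,
                **other.excluded_functions,
            },
            pair_reasons=pd.concat(
                [self.pair_reasons, other.pair_reasons], ignore_index=True
            ),
        )
        return merged

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a single tidy table (entity, identifier, reason, detail)."""
        rows: list[dict[str, object]] = []
        for sid, reason in self.excluded_samples.items():
            rows.append(
                {
                    "entity": "sample",
                    "identifier": sid,
                    "reason": reason,
                    "detail": self.sample_richness.get(sid, ""),
                }
            )
        for fid, frac in self.excluded_functions.items():
            rows.append(
                {
                    "entity": "function",
                    "identifier": fid,
                    "reason": "low_nonmissing_fraction",
                    "detail": f"{frac:.6g}",
                }
            )
        for _, row in self.pair_reasons.iterrows():
            if row["status"] != STATUS_OK:
                rows.append(
                    {
                        "entity": "pair",
                        "identifier": f"{row['sample_id']}::{row['function_id']}",
                        "reason": row["status"],
                        "detail": "",
                    }
                )
        return pd.DataFrame(rows, columns=["entity", "identifier", "reason", "detail"])


def restrict_and_renormalise(
    abundances: pd.DataFrame, universe: Iterable[str] | None = None
) -> tuple[dict[str, Community], FilterReport]:
    """Build one :class:`Community` per sample from a long abundance table.

    ``abundances`` needs columns sample_id, species_id, abundance.  Species
    outside ``universe`` (when given) and zero-abundance species are dropped;
    the remainder is renormalised to sum to one.  Samples left empty after
    restriction are recorded as excluded.  Idempotent on its own output.
    """
    required = {"sample_id", "species_id", "abundance"}
    missing = required - set(abundances.columns)
    if missing:
        raise ValidationError(f"abundance table lacks columns {sorted(missing)}")
    df = abundances.copy()
    df["abundance"] = df["abundance"].astype(float)
    if (df["abundance"] < 0).any():
        raise ValidationError("abundances must be non-negative")
    dup = df[["sample_id", "species_id"]].duplicated()
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate abundance record for (sample={first['sample_id']!r}, "
            f"species={first['species_id']!r})"
        )
    universe_set = None if universe is None else {str(s) for s in universe}

    communities: dict[str, Community] = {}
    report = FilterReport()
    for sample_id, group in df.groupby("sample_id", sort=True):
        sub = group
        if universe_set is not None:
            sub = sub[sub["species_id"].isin(universe_set)]
        sub = sub[sub["abundance"] > 0]
        if sub.empty:
            report.excluded_samples[str(sample_id)] = "no_species_in_universe"
            report.sample_richness[str(sample_id)] = 0
            continue
        sub = sub.sort_values("species_id")
        communities[str(sample_id)] = Community.from_raw(
            list(sub["species_id"]), sub["abundance"].to_numpy()
        )
    return communities, report


def apply_sample_filter(
    communities: Mapping[str, Community],
    min_species: int = DEFAULT_MIN_SPECIES,
) -> tuple[dict[str, Community], FilterReport]:
    """Drop samples whose community has fewer than ``min_species`` species."""
    kept: dict[str, Community] = {}
    report = FilterReport()
    for sample_id, community in communities.items():
        if community.n < min_species:
            report.excluded_samples[sample_id] = "too_few_species"
            report.sample_richness[sample_id] = community.n
        else:
            kept[sample_id] = community
    return kept, report


def pair_missingness(
    flux: FluxTable,
    tolerance: float = DEFAULT_UPTAKE_TOL,
    samples: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, FluxTable]:
    """Classify every (sample, function) pair and clip tolerable negatives.

    Status per pair: ``uptake_detected`` if any flux < -tolerance,
    ``no_producers`` if no flux exceeds tolerance, else ``ok``.  The returned
    flux table has fluxes in [-tolerance, 0] clipped to exactly zero.  When
    ``samples`` is given, pairs are classified for those samples only (the
    filter rules operate on retained samples).
    """
    df = flux.frame
    if samples is not None:
        wanted = {str(s) for s in samples}
        df = df[df["sample_id"].isin(wanted)]
    statuses = []
    for (sample_id, function_id), group in df.groupby(
        ["sample_id", "function_id"], sort=True
    ):
        values = group["flux"].to_numpy()
        if (values < -tolerance).any():
            status = STATUS_UPTAKE
        elif not (values > tolerance).any():
            status = STATUS_NO_PRODUCERS
        else:
            status = STATUS_OK
        statuses.append(
            {"sample_id": sample_id, "function_id": function_id, "status": status}
        )
    clipped = df.copy()
    small_negative = (clipped["flux"] < 0) & (clipped["flux"] >= -tolerance)
    clipped.loc[small_negative, "flux"] = 0.0
    status_df = pd.DataFrame(
        statuses, columns=["sample_id", "function_id", "status"]
    )
    return status_df, FluxTable(clipped)


def apply_function_filter(
    statuses: pd.DataFrame,
    n_samples: int,
    min_nonmissing: float = DEFAULT_MIN_NONMISSING,
) -> tuple[tuple[str, ...], FilterReport]:
    """Keep functions whose non-missing fraction strictly exceeds the threshold.

    The fraction is non-missing pairs over ``n_samples`` retained samples —
    a pair absent from ``statuses`` entirely counts as missing (no record means
    no producer anywhere in that sample).
    """
    if n_samples <= 0:
        raise ValidationError("need at least one retained sample")
    report = FilterReport(pair_reasons=statuses.copy())
    kept: list[str] = []
    for function_id, group in statuses.groupby("function_id", sort=True):
        ok = int((group["status"] == STATUS_OK).sum())
        fraction = ok / n_samples
        if fraction > min_nonmissing:
            kept.append(str(function_id))
        else:
            report.excluded_functions[str(function_id)] = fraction
    return tuple(kept), report


def reference_from_corpus(flux: FluxTable, zero_tol: float = 0.0) -> dict[str, FunctionReference]:
    """Derive per-function capable-species sets as the union of observed producers.

    A fallback when no curated reference is supplied; it underestimates the
    true reference size ``m`` because species never seen producing are absent.
    """
    refs: dict[str, FunctionReference] = {}
    df = flux.frame
    for function_id, group in df[df["flux"] > zero_tol].groupby(
        "function_id", sort=True
    ):
        refs[str(function_id)] = FunctionReference(
            str(function_id), frozenset(group["species_id"].astype(str))
        )
    return refs
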