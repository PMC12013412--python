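"""Programmatic scenario generators ("fixtures") for tests, demos and the CLI.

Four named scenarios:

``toy``
    Five sampled species of which four produce the function equally; the
    reference holds those four plus three species absent from the sample
    (m = 7).  The numeric abundances are artifact choices.
``keystone``
    A corpus of uniform-abundance communities of richness 1..n_max where a
    single species carries the whole function and the reference holds ``m``
    capable species.
``proportional``
    Each producer's output is exactly proportional to its abundance, so the
    interdependency index is zero and the abundance measure reduces to the log
    of the producers' total abundance.
``dirichlet``
    Random communities drawn through the simulation module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Community, FunctionReference, FunctionalProfile, ValidationError
from .simulation import draw_community

FIXTURE_KINDS = ("toy", "keystone", "proportional", "dirichlet")

TOY_ABUNDANCES = (0.30, 0.25, 0.20, 0.15, 0.10)
TOY_N_PRODUCERS = 4
TOY_REFERENCE_SIZE = 7


@dataclass(frozen=True)
class Scenario:
    """In-memory fixture: aligned domain objects plus the equivalent tables."""

    abundances: pd.DataFrame  # long form: sample_id, species_id, abundance
    fluxes: pd.DataFrame  # long form: sample_id, species_id, function_id, flux
    reference: pd.DataFrame  # function_id, species_id

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "abundances": out_dir / "abundances.tsv",
            "fluxes": out_dir / "fluxes.tsv",
            "reference": out_dir / "reference.tsv",
        }
        self.abundances.to_csv(paths["abundances"], sep="\t", index=False)
        self.fluxes.to_csv(paths["fluxes"], sep="\t", index=False)
        self.reference.to_csv(paths["reference"], sep="\t", index=False)
        return paths


def toy_objects() -> tuple[Community, FunctionalProfile, FunctionReference]:
    """The five-species toy community as ready-made domain objects."""
    ids = tuple(f"sp{i + 1}" for i in range(len(TOY_ABUNDANCES)))
    community = Community(ids, np.array(TOY_ABUNDANCES))
    contributions = np.array(
        [1.0 if i < TOY_N_PRODUCERS else 0.0 for i in range(len(ids))]
    )
    profile = FunctionalProfile("toy_function", contributions)
    extra = tuple(
        f"ref{i + 1}" for i in range(TOY_REFERENCE_SIZE - TOY_N_PRODUCERS)
    )
    reference = FunctionReference(
        "toy_function", frozenset(ids[:TOY_N_PRODUCERS]) | frozenset(extra)
    )
    return community, profile, reference


def toy_scenario() -> Scenario:
    community, profile, reference = toy_objects()
    abund = pd.DataFrame(
        {
            "sample_id": "toy_sample",
            "species_id": community.species_ids,
            "abundance": community.abundances,
        }
    )
    flux = pd.DataFrame(
        {
            "sample_id": "toy_sample",
            "species_id": community.species_ids,
            "function_id": profile.function_id,
            "flux": profile.contributions,
        }
    )
    flux = flux[flux["flux"] > 0].reset_index(drop=True)
    ref = pd.DataFrame(
        {
            "function_id": profile.function_id,
            "species_id": sorted(reference.capable_species),
        }
    )
    return Scenario(abund, flux, ref)


def keystone_scenario(n_max: int = 100, m: int = 100) -> Scenario:
    """One sample per richness 1..n_max, uniform abundances, single producer."""
    if not 1 <= n_max <= m:
        raise ValidationError("need 1 <= n_max <= m")
    abund_rows = []
    flux_rows = []
    for n in range(1, n_max + 1):
        sample = f"keystone_n{n:03d}"
        for i in range(n):
            abund_rows.append(
                {
                    "sample_id": sample,
                    "species_id": f"sp{i + 1:03d}",
                    "abundance": 1.0 / n,
                }
            )
        flux_rows.append(
            {
                "sample_id": sample,
                "species_id": "sp001",
                "function_id": "keystone_function",
                "flux": 1.0,
            }
        )
    ref_ids = ["sp001"] + [f"ref{i + 1:03d}" for i in range(1, m)]
    ref = pd.DataFrame(
        {"function_id": "keystone_function", "species_id": ref_ids}
    )
    return Scenario(pd.DataFrame(abund_rows), pd.DataFrame(flux_rows), ref)


def proportional_scenario(
    n: int = 30,
    n_producers: int = 10,
    scale: float = 2.0,
    seed: int = 0,
) -> Scenario:
    """Producers secrete exactly ``scale`` times their abundance."""
    if not 1 <= n_producers <= n:
        raise ValidationError("need 1 <= n_producers <= n")
    rng = np.random.default_rng(seed)
    abundances = rng.dirichlet(np.ones(n))
    ids = [f"sp{i + 1:03d}" for i in range(n)]
    producers = ids[:n_producers]
    abund = pd.DataFrame(
        {"sample_id": "prop_sample", "species_id": ids, "abundance": abundances}
    )
    flux = pd.DataFrame(
        {
            "sample_id": "prop_sample",
            "species_id": producers,
            "function_id": "prop_function",
            "flux": scale * abundances[:n_producers],
        }
    )
    ref = pd.DataFrame({"function_id": "prop_function", "species_id": producers})
    return Scenario(abund, flux, ref)


def dirichlet_scenario(
    n_species: int = 50,
    n_samples: int = 5,
    alpha: float = 1.0,
    seed: int = 0,
) -> Scenario:
    """Random communities with Dirichlet abundances and shares."""
    rng = np.random.default_rng(seed)
    ids = [f"sp{i + 1:03d}" for i in range(n_species)]
    abund_rows = []
    flux_rows = []
    for s in range(n_samples):
        sample = f"dirichlet_s{s + 1:03d}"
        shares, abundances = draw_community(n_species, alpha, rng)
        for sid, share, ab in zip(ids, shares, abundances):
            abund_rows.append(
                {"sample_id": sample, "species_id": sid, "abundance": ab}
            )
            flux_rows.append(
                {
                    "sample_id": sample,
                    "species_id": sid,
                    "function_id": "dirichlet_function",
                    "flux": share,
                }
            )
    ref = pd.DataFrame({"function_id": "dirichlet_function", "species_id": ids})
    return Scenario(pd.DataFrame(abund_rows), pd.DataFrame(flux_rows), ref)


def make_fixtures(kind: str, out_dir: str | Path, seed: int = 0, **params) -> dict[str, Path]:
    """Write the named scenario's tables to ``out_dir`` and return the paths."""
    if kind == "toy":
        scenario = toy_scenario()
    elif kind == "keystone":
        scenario = keystone_scenario(**params)
    elif kind == "proportional":
        scenario = proportional_scenario(seed=seed, **params)
    elif kind == "dirichlet":
        scenario = dirichlet_scenario(seed=seed, **params)
    else:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        )
    return scenario.write(out_dir)
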