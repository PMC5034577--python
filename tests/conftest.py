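"""Shared fixtures: hand-built tiny surveys and seeded synthetic surveys."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ethnosurvey.model import SurveyDataset, build_dataset
from ethnosurvey.synthetic import GeneratorConfig, generate_survey


def make_dataset(
    report_rows: list[tuple],
    informant_rows: list[tuple] | None = None,
) -> SurveyDataset:
    """Build a validated dataset from (informant, species, category[, origin]) rows.

    Informant and species tables are derived automatically unless explicit
    (informant_id, region, community, elevation_m, gender, age) rows are given.
    """
    rows = [(r + ("unknown",))[:4] for r in report_rows]
    reports = pd.DataFrame(rows, columns=["informant_id", "species_id", "use_category", "origin"])
    reports["use_detail"] = ""
    if informant_rows is None:
        ids = sorted(reports["informant_id"].unique())
        informant_rows = [(i, "SJ", "SJ_com0", 1500.0, "female", 50) for i in ids]
    informants = pd.DataFrame(
        informant_rows,
        columns=["informant_id", "region", "community", "elevation_m", "gender", "age"],
    )
    species_ids = sorted(reports["species_id"].unique())
    species = pd.DataFrame(
        {
            "species_id": species_ids,
            "scientific_name": [f"Genus000 {s}" for s in species_ids],
            "genus": "Genus000",
            "family": "FamiliaA",
            "growth_form": "herb",
        }
    )
    return build_dataset(reports, informants, species)


@pytest.fixture(scope="session")
def synth():
    """Default-condition synthetic survey (171 informants, 480-species pool)."""
    return generate_survey(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def synth_dataset(synth):
    return synth[0]


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down generator conditions for replicate-based tests."""
    return GeneratorConfig(
        seed=0,
        region_informants={"SJ": 12, "SR": 22, "TK": 26},
        n_species=120,
        mean_reports_per_informant=40.0,
    )


@pytest.fixture(scope="session")
def plant_ordination(synth_dataset):
    """Plant-space NMDS of the default synthetic survey (shared; ~20 s)."""
    from ethnosurvey.model import build_incidence_matrix
    from ethnosurvey.ordination import bray_curtis, nmds_embed

    inc = build_incidence_matrix(synth_dataset, "plant_space").drop_zero_rows()
    return nmds_embed(bray_curtis(inc), k=2, n_restarts=20, seed=7)


def brute_force_indices(dataset: SurveyDataset, region: str | None = None) -> dict:
    """Exhaustive per-row recomputation of FIC, CI, UD and UV.

    Independent of the package's groupby implementation: iterates over raw
    deduplicated report tuples with dict/set bookkeeping only.
    """
    in_scope = {
        row.informant_id
        for row in dataset.informants.itertuples()
        if region is None or row.region == region
    }
    triples = set()
    for row in dataset.reports.itertuples():
        if row.informant_id in in_scope:
            triples.add((row.informant_id, row.species_id, row.use_category))

    by_cat: dict[str, list] = {}
    by_species: dict[str, list] = {}
    for inf, sp, cat in triples:
        by_cat.setdefault(cat, []).append((inf, sp))
        by_species.setdefault(sp, []).append((inf, cat))

    fic = {}
    for cat, pairs in by_cat.items():
        nur = len(pairs)
        nt = len({sp for _, sp in pairs})
        fic[cat] = (nur - nt) / (nur - 1) if nur >= 2 else 0.0

    ci, ud, uv = {}, {}, {}
    for sp, pairs in by_species.items():
        informants_of_sp = {inf for inf, _ in pairs}
        cats = {}
        for inf, cat in pairs:
            cats.setdefault(cat, set()).add(inf)
        ci[sp] = sum(len(infs) / len(informants_of_sp) for infs in cats.values())
        total = len(pairs)
        ud[sp] = -sum(
            (len([1 for _, c in pairs if c == cat]) / total)
            * np.log(len([1 for _, c in pairs if c == cat]) / total)
            for cat in cats
        )
        uv[sp] = total / len(in_scope)
    return {"fic": fic, "ci": ci, "ud": ud, "uv": uv}
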