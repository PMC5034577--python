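"""Core survey data model: use-report tables, validation, incidence matrices.

An ethnobotanical survey is held as three tables:

* ``reports`` — one row per use report: an informant attributing one use
  (in a closed use-category vocabulary) to one plant species, with the
  source origin of the plant (home garden, wild, or unknown);
* ``informants`` — survey participants with region, community, community
  elevation, gender and (optional) age;
* ``species`` — the taxon inventory with scientific name, genus, family
  and growth form.

The atomic counting unit throughout the package is the distinct
(informant, species, use_category) triple: repeated mentions of the same
species-use by one informant count once, and garden/wild variants of the
same triple collapse for counting while origin is retained as a report
attribute for the provenance analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed use-category vocabulary. Unrecognised labels are coerced to "other".
USE_CATEGORIES: tuple[str, ...] = (
    "food",
    "medicinal",
    "utensils_tools",
    "construction",
    "cultural",
    "fodder",
    "fuel",
    "veterinary",
    "ornamental",
    "other",
)

#: The three broad geographic survey regions: Samtshke-Javakheti,
#: Svaneti-Racha, Tusheti-Khevsureti.
REGIONS: tuple[str, ...] = ("SJ", "SR", "TK")

ORIGINS: tuple[str, ...] = ("garden", "wild", "unknown")

REPORT_COLUMNS = ("informant_id", "species_id", "use_category", "use_detail", "origin")
INFORMANT_COLUMNS = ("informant_id", "region", "community", "elevation_m", "gender", "age")
SPECIES_COLUMNS = ("species_id", "scientific_name", "genus", "family", "growth_form")

_MANDATORY = {
    "reports": ("informant_id", "species_id", "use_category"),
    "informants": ("informant_id", "region", "community", "elevation_m", "gender"),
    "species": ("species_id", "scientific_name", "genus", "family"),
}


class SchemaError(ValueError):
    """A survey table is missing a mandatory column."""


class ValidationError(ValueError):
    """Referential integrity or domain constraints are violated."""


@dataclass
class SurveyDataset:
    """A validated three-table survey.

    ``reports`` is stored deduplicated on
    (informant_id, species_id, use_category, origin).
    """

    reports: pd.DataFrame
    informants: pd.DataFrame
    species: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def n_reports(self) -> int:
        """Number of counting-unit reports (distinct informant/species/category)."""
        return len(self.counting_reports())

    def counting_reports(self, region: str | None = None) -> pd.DataFrame:
        """The deduplicated (informant, species, use_category) counting view.

        ``region`` restricts to informants of one region; ``None`` means the
        pooled all-regions scope.
        """
        rep = self.reports.drop_duplicates(
            subset=["informant_id", "species_id", "use_category"]
        )
        if region is not None:
            ids = self.informants.loc[self.informants["region"] == region, "informant_id"]
            rep = rep[rep["informant_id"].isin(set(ids))]
        return rep.reset_index(drop=True)

    def origin_reports(self, region: str | None = None) -> pd.DataFrame:
        """Origin-known report rows (one per informant/species/category/origin)."""
        rep = self.reports[self.reports["origin"] != "unknown"]
        if region is not None:
            ids = self.informants.loc[self.informants["region"] == region, "informant_id"]
            rep = rep[rep["informant_id"].isin(set(ids))]
        return rep.reset_index(drop=True)

    def informants_in_scope(self, region: str | None = None) -> pd.DataFrame:
        if region is None:
            return self.informants
        return self.informants[self.informants["region"] == region]

    def regions_present(self) -> list[str]:
        return [r for r in REGIONS if r in set(self.informants["region"])]


@dataclass
class IncidenceMatrix:
    """Informant-by-item incidence, the input to ordination.

    ``mode='plant_space'`` columns are species; ``mode='use_space'`` columns
    are (species, use_category) pairs encoded ``"species|category"``.
    """

    informant_ids: list
    item_ids: list
    values: np.ndarray
    mode: Literal["plant_space", "use_space"]
    binarized: bool

    @property
    def zero_rows(self) -> list:
        """Informants with no reports in this matrix (retained but flagged)."""
        mask = self.values.sum(axis=1) == 0
        return [i for i, z in zip(self.informant_ids, mask) if z]

    def drop_zero_rows(self) -> "IncidenceMatrix":
        mask = self.values.sum(axis=1) > 0
        return IncidenceMatrix(
            informant_ids=[i for i, m in zip(self.informant_ids, mask) if m],
            item_ids=self.item_ids,
            values=self.values[mask],
            mode=self.mode,
            binarized=self.binarized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.informant_ids, columns=self.item_ids)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8", keep_default_na=False)


def _require_columns(df: pd.DataFrame, table: str) -> None:
    for col in _MANDATORY[table]:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing mandatory column '{col}'")


def load_survey(
    report_path: str | Path,
    informant_path: str | Path,
    species_path: str | Path,
) -> SurveyDataset:
    """Read and validate the three survey tables.

    Files are comma- or tab-separated (by extension), UTF-8, with a header
    row. Unknown use categories are coerced to ``"other"`` with a warning;
    exact duplicate (informant, species, category, origin) rows collapse to
    one report.

    Raises
    ------
    FileNotFoundError, SchemaError, ValidationError
    """
    reports = _read_table(report_path)
    informants = _read_table(informant_path)
    species = _read_table(species_path)
    return build_dataset(reports, informants, species)


def build_dataset(
    reports: pd.DataFrame, informants: pd.DataFrame, species: pd.DataFrame
) -> SurveyDataset:
    """Assemble and validate a :class:`SurveyDataset` from in-memory tables."""
    _require_columns(reports, "reports")
    _require_columns(informants, "informants")
    _require_columns(species, "species")

    reports = reports.copy()
    informants = informants.copy()
    species = species.copy()
    warnings: list[str] = []

    if "use_detail" not in reports.columns:
        reports["use_detail"] = ""
    if "origin" not in reports.columns:
        reports["origin"] = "unknown"
    reports["origin"] = reports["origin"].replace("", "unknown")
    bad_origin = ~reports["origin"].isin(ORIGINS)
    if bad_origin.any():
        warnings.append(
            f"{int(bad_origin.sum())} report(s) with unrecognised origin mapped to 'unknown'"
        )
        reports.loc[bad_origin, "origin"] = "unknown"

    unknown_cat = ~reports["use_category"].isin(USE_CATEGORIES)
    if unknown_cat.any():
        labels = sorted(reports.loc[unknown_cat, "use_category"].unique())
        warnings.append(
            f"{int(unknown_cat.sum())} report(s) with use categories outside the "
            f"vocabulary mapped to 'other': {labels}"
        )
        logger.warning(warnings[-1])
        reports.loc[unknown_cat, "use_category"] = "other"

    n_before = len(reports)
    reports = reports.drop_duplicates(
        subset=["informant_id", "species_id", "use_category", "origin"]
    ).reset_index(drop=True)
    if len(reports) < n_before:
        warnings.append(f"collapsed {n_before - len(reports)} duplicate report row(s)")
        logger.warning(warnings[-1])

    if species["species_id"].duplicated().any():
        dupes = sorted(species.loc[species["species_id"].duplicated(), "species_id"])
        raise ValidationError(f"duplicate species_id in species table: {dupes}")
    if informants["informant_id"].duplicated().any():
        dupes = sorted(informants.loc[informants["informant_id"].duplicated(), "informant_id"])
        raise ValidationError(f"duplicate informant_id in informant table: {dupes}")

    orphans_inf = sorted(set(reports["informant_id"]) - set(informants["informant_id"]))
    orphans_sp = sorted(set(reports["species_id"]) - set(species["species_id"]))
    if orphans_inf or orphans_sp:
        raise ValidationError(
            "reports reference ids absent from the metadata tables: "
            f"informants {orphans_inf}, species {orphans_sp}"
        )

    bad_region = ~informants["region"].isin(REGIONS)
    if bad_region.any():
        raise ValidationError(
            f"unknown region labels: {sorted(informants.loc[bad_region, 'region'].unique())}"
        )
    informants["elevation_m"] = pd.to_numeric(informants["elevation_m"], errors="raise")
    if not np.isfinite(informants["elevation_m"]).all():
        raise ValidationError("non-finite elevation_m values")
    if (informants["elevation_m"] < 0).any():
        raise ValidationError("negative elevation_m values")
    if "age" not in informants.columns:
        informants["age"] = np.nan
    informants["age"] = pd.to_numeric(informants["age"].replace("", np.nan), errors="coerce")
    bad_age = informants["age"].dropna()
    bad_age = bad_age[(bad_age < 10) | (bad_age > 110)]
    if len(bad_age):
        raise ValidationError(f"ages outside [10, 110]: {sorted(bad_age.unique())}")
    if "growth_form" not in species.columns:
        species["growth_form"] = ""
    if (species["genus"].astype(str) == "").any() or (species["family"].astype(str) == "").any():
        raise ValidationError("species with empty genus or family")

    no_reports = set(informants["informant_id"]) - set(reports["informant_id"])
    if no_reports:
        warnings.append(
            f"{len(no_reports)} informant(s) with zero reports (kept in metadata, "
            f"excluded from ordination): {sorted(no_reports)}"
        )
        logger.info(warnings[-1])

    return SurveyDataset(
        reports=reports, informants=informants, species=species, warnings=warnings
    )


def write_survey(dataset: SurveyDataset, directory: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write the three survey tables; inverse of :func:`load_survey`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if sep == "\t" else ".csv"
    paths = {
        "reports": directory / f"reports{ext}",
        "informants": directory / f"informants{ext}",
        "species": directory / f"species{ext}",
    }
    dataset.reports[list(REPORT_COLUMNS)].to_csv(paths["reports"], sep=sep, index=False)
    dataset.informants[list(INFORMANT_COLUMNS)].to_csv(paths["informants"], sep=sep, index=False)
    dataset.species[list(SPECIES_COLUMNS)].to_csv(paths["species"], sep=sep, index=False)
    return paths


def validation_report(dataset: SurveyDataset) -> dict:
    """Structured JSON-able summary of a loaded survey (counts + warnings)."""
    counting = dataset.counting_reports()
    return {
        "n_reports": int(len(counting)),
        "n_report_rows": int(len(dataset.reports)),
        "n_informants": int(len(dataset.informants)),
        "n_species": int(dataset.species["species_id"].nunique()),
        "n_species_reported": int(counting["species_id"].nunique()),
        "n_genera": int(dataset.species["genus"].nunique()),
        "n_families": int(dataset.species["family"].nunique()),
        "regions": {
            r: int((dataset.informants["region"] == r).sum())
            for r in dataset.regions_present()
        },
        "use_categories": counting["use_category"].value_counts().to_dict(),
        "origins": dataset.reports["origin"].value_counts().to_dict(),
        "warnings": list(dataset.warnings),
        "errors": [],
    }


def derive_species_origin(
    dataset: SurveyDataset, region: str | None = None
) -> dict[str, str]:
    """Classify each reported species by provenance within a scope.

    A species is ``exclusively_wild`` if every origin-known report of it (in
    scope) is wild, ``garden_only`` if every one is garden, ``both`` if it has
    at least one of each, and ``unknown`` if it has no origin-known report.
    The first three classes partition the origin-known species.
    """
    counting = dataset.counting_reports(region)
    if counting.empty:
        return {}
    known = dataset.origin_reports(region)
    grouped = known.groupby("species_id")["origin"].agg(set)
    out: dict[str, str] = {}
    for sp in counting["species_id"].unique():
        origins = grouped.get(sp, set())
        if not origins:
            out[sp] = "unknown"
        elif origins == {"wild"}:
            out[sp] = "exclusively_wild"
        elif origins == {"garden"}:
            out[sp] = "garden_only"
        else:
            out[sp] = "both"
    return out


def build_incidence_matrix(
    dataset: SurveyDataset,
    mode: Literal["plant_space", "use_space"] = "plant_space",
    binarize: bool = False,
    region: str | None = None,
) -> IncidenceMatrix:
    """Cross-tabulate informants against species or (species, category) pairs.

    In count mode the matrix total equals the number of counting-unit reports
    in scope (conservation). Informants with all-zero rows are retained and
    reported by :attr:`IncidenceMatrix.zero_rows`.
    """
    counting = dataset.counting_reports(region)
    informant_ids = list(dataset.informants_in_scope(region)["informant_id"])
    if mode == "plant_space":
        item = counting["species_id"]
    elif mode == "use_space":
        item = counting["species_id"] + "|" + counting["use_category"]
    else:
        raise ValueError(f"unknown incidence mode: {mode!r}")
    tab = pd.crosstab(counting["informant_id"], item)
    item_ids = sorted(tab.columns)
    tab = tab.reindex(index=informant_ids, columns=item_ids, fill_value=0)
    values = tab.to_numpy(dtype=float)
    if binarize:
        values = (values > 0).astype(float)
    m = IncidenceMatrix(
        informant_ids=informant_ids,
        item_ids=item_ids,
        values=values,
        mode=mode,
        binarized=binarize,
    )
    if m.zero_rows:
        logger.info("incidence matrix has %d all-zero informant row(s)", len(m.zero_rows))
    return m
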