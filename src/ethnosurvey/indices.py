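"""Consensus and importance indices over informant use-reports.

Four statistics, each computable per region or pooled over all regions:

* **FIC** (informant consensus factor), per use category:
  ``(Nur - Nt) / (Nur - 1)`` where ``Nur`` is the number of use reports in
  the category and ``Nt`` the number of distinct taxa reported. 1 means all
  reports concern a single taxon (full consensus); 0 means every report is
  a different taxon.
* **CI** (cultural importance), per species: the sum over use categories of
  the fraction of the species' reporting informants who report each
  category. CI >= 1 whenever the species is reported; CI = 1 iff it is
  single-category.
* **UD** (use diversity), per species: Shannon entropy (natural log) of the
  species' report distribution over use categories; 0 for a single-category
  species, ln m for m equally reported categories.
* **UV** (use value), per species: total use reports of the species divided
  by the number of informants interviewed in the scope (reporters or not).
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np
import pandas as pd

from .model import SurveyDataset, derive_species_origin

__all__ = [
    "compute_fic",
    "category_summary",
    "compute_ci",
    "compute_ud",
    "compute_uv",
    "compute_metrics_table",
    "top_percentile",
]


def compute_fic(nur: int, nt: int) -> float:
    """Informant consensus factor (Nur - Nt) / (Nur - 1).

    Degenerate categories with Nur <= 1 return 0.0 with a warning, so
    category tables never contain missing cells.
    """
    if nt > nur:
        raise ValueError(f"Nt ({nt}) cannot exceed Nur ({nur})")
    if nt < 0 or nur < 0:
        raise ValueError("Nur and Nt must be non-negative")
    if nur <= 1:
        _warnings.warn(
            f"FIC undefined for Nur={nur} (need >= 2 reports); returning 0.0",
            stacklevel=2,
        )
        return 0.0
    return (nur - nt) / (nur - 1)


def category_summary(dataset: SurveyDataset, region: str | None = None) -> pd.DataFrame:
    """Per-use-category report counts, taxon counts and FIC for one scope.

    Returns columns use_category, region_scope, nur, nt, fic, degenerate.
    Only categories with at least one report in scope appear.
    """
    counting = dataset.counting_reports(region)
    rows = []
    for cat, grp in counting.groupby("use_category", sort=True):
        nur = len(grp)
        nt = grp["species_id"].nunique()
        degenerate = nur <= 1
        with _warnings.catch_warnings():
            if degenerate:
                _warnings.simplefilter("ignore")
            fic = compute_fic(nur, nt)
        rows.append(
            {
                "use_category": cat,
                "region_scope": region or "all",
                "nur": nur,
                "nt": nt,
                "fic": fic,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(
        rows, columns=["use_category", "region_scope", "nur", "nt", "fic", "degenerate"]
    )


def _species_scope(dataset: SurveyDataset, species_id: str, region: str | None) -> pd.DataFrame:
    counting = dataset.counting_reports(region)
    rep = counting[counting["species_id"] == species_id]
    if rep.empty:
        raise KeyError(f"species {species_id!r} has no reports in scope {region or 'all'!r}")
    return rep


def compute_ci(dataset: SurveyDataset, species_id: str, region: str | None = None) -> float:
    """Cultural importance: sum over categories u of n_{s,u} / n_s."""
    rep = _species_scope(dataset, species_id, region)
    n_s = rep["informant_id"].nunique()
    n_su = rep.groupby("use_category")["informant_id"].nunique()
    return float((n_su / n_s).sum())


def compute_ud(dataset: SurveyDataset, species_id: str, region: str | None = None) -> float:
    """Use diversity: Shannon entropy (nats) of reports over use categories."""
    rep = _species_scope(dataset, species_id, region)
    counts = rep["use_category"].value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def compute_uv(dataset: SurveyDataset, species_id: str, region: str | None = None) -> float:
    """Use value: the species' reports over all informants asked in scope.

    The denominator includes informants who never mention the species, so UV
    is monotone decreasing in the scope's informant count.
    """
    n = len(dataset.informants_in_scope(region))
    if n == 0:
        raise ValueError(f"no informants in scope {region or 'all'!r}")
    counting = dataset.counting_reports(region)
    return float((counting["species_id"] == species_id).sum() / n)


def compute_metrics_table(dataset: SurveyDataset, region: str | None = None) -> pd.DataFrame:
    """One row of CI/UD/UV per species reported in scope.

    Sorted by CI descending then species_id ascending (deterministic).
    """
    counting = dataset.counting_reports(region)
    n_scope = len(dataset.informants_in_scope(region))
    origin_class = derive_species_origin(dataset, region)
    names = dataset.species.set_index("species_id")["scientific_name"]

    rows = []
    for sp, rep in counting.groupby("species_id", sort=True):
        n_s = rep["informant_id"].nunique()
        n_su = rep.groupby("use_category")["informant_id"].nunique()
        counts = rep["use_category"].value_counts().to_numpy(dtype=float)
        p = counts / counts.sum()
        rows.append(
            {
                "species_id": sp,
                "scientific_name": names.get(sp, ""),
                "region_scope": region or "all",
                "ci": float((n_su / n_s).sum()),
                "ud": float(-(p * np.log(p)).sum()),
                "uv": len(rep) / n_scope,
                "n_informants": int(n_s),
                "reports_total": int(len(rep)),
                "origin_class": origin_class.get(sp, "unknown"),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "scientific_name",
            "region_scope",
            "ci",
            "ud",
            "uv",
            "n_informants",
            "reports_total",
            "origin_class",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["ci", "species_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return table


def top_percentile(
    table: pd.DataFrame,
    metric: str = "ci",
    q: float = 95.0,
    regional_tables: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Species at or above the q-th percentile of a metric.

    The threshold is the linear-interpolation quantile of the metric over the
    whole table; ties at the threshold are all included. When
    ``regional_tables`` maps region labels to per-region metric tables, a
    ``regional_{metric}_95`` column annotates, for each species, which
    regional top-percentile lists it also appears on.
    """
    if metric not in {"ci", "ud", "uv"}:
        raise ValueError(f"unknown metric {metric!r}")
    if table.empty:
        return table.copy()
    threshold = float(np.percentile(table[metric].to_numpy(), q))
    out = (
        table[table[metric] >= threshold]
        .sort_values([metric, "species_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    if regional_tables is not None:
        membership = {}
        for region, rtab in regional_tables.items():
            if rtab.empty:
                continue
            rthr = float(np.percentile(rtab[metric].to_numpy(), q))
            membership[region] = set(rtab.loc[rtab[metric] >= rthr, "species_id"])
        out[f"regional_{metric}_{int(q)}"] = [
            ",".join(sorted(r for r, sps in membership.items() if sp in sps))
            for sp in out["species_id"]
        ]
    return out
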