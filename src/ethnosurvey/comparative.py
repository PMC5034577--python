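"""Regional comparisons: overlap partitions, consensus scatter, origin splits.

The three survey regions (SJ, SR, TK) are compared on their plant and use
inventories via exact three-set Venn partitions, on informant consensus per
use category (FIC plotted over report counts, optionally split by
home-garden vs wild-collected provenance), and on species-level origin
classes (exclusively wild / garden only / both).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import pandas as pd

from .indices import compute_fic
from .model import REGIONS, SurveyDataset, derive_species_origin

__all__ = [
    "OverlapPartition",
    "region_overlap",
    "consensus_by_category",
    "garden_wild_summary",
]

#: Fixed naming of the 7 exclusive Venn cells.
VENN_CELLS = ("sj_only", "sr_only", "tk_only", "sj_sr", "sj_tk", "sr_tk", "all")


@dataclass
class OverlapPartition:
    """Exclusive three-set partition of items over the survey regions."""

    item_kind: str  # "species" | "use"
    region_sets: dict[str, set]
    partition_counts: dict[str, int]

    def cell_items(self) -> dict[str, set]:
        a = self.region_sets.get("SJ", set())
        b = self.region_sets.get("SR", set())
        c = self.region_sets.get("TK", set())
        return {
            "sj_only": a - b - c,
            "sr_only": b - a - c,
            "tk_only": c - a - b,
            "sj_sr": (a & b) - c,
            "sj_tk": (a & c) - b,
            "sr_tk": (b & c) - a,
            "all": a & b & c,
        }

    def region_total(self, region: str) -> int:
        return len(self.region_sets.get(region, set()))


def region_overlap(
    dataset: SurveyDataset,
    item_kind: str = "species",
    origin_filter: str | None = None,
) -> OverlapPartition:
    """Partition reported items into the 7 exclusive regional Venn cells.

    ``item_kind='species'`` partitions species ids; ``'use'`` partitions
    (species, use_category) pairs. ``origin_filter='garden'`` restricts each
    region's set to items with at least one garden-origin report there
    (the home-garden variant of the partition).
    """
    if item_kind not in {"species", "use"}:
        raise ValueError(f"unknown item_kind {item_kind!r}")
    if origin_filter not in {None, "garden", "wild"}:
        raise ValueError(f"unknown origin_filter {origin_filter!r}")

    region_sets: dict[str, set] = {}
    for region in REGIONS:
        if region not in set(dataset.informants["region"]):
            continue
        if origin_filter is None:
            rep = dataset.counting_reports(region)
        else:
            rep = dataset.origin_reports(region)
            rep = rep[rep["origin"] == origin_filter]
        if item_kind == "species":
            items = set(rep["species_id"])
        else:
            items = set(zip(rep["species_id"], rep["use_category"]))
        region_sets[region] = items

    tmp = OverlapPartition(item_kind=item_kind, region_sets=region_sets, partition_counts={})
    cells = tmp.cell_items()
    tmp.partition_counts = {name: len(items) for name, items in cells.items()}
    return tmp


def consensus_by_category(
    dataset: SurveyDataset,
    split_by_origin: bool = False,
    include_overall: bool = True,
) -> pd.DataFrame:
    """FIC-over-Nur points per (region, use category[, origin]).

    With ``split_by_origin`` each point is additionally restricted to
    home-garden or wild-collected reports; the counting unit within an
    origin scope is a distinct (informant, species, category) triple having
    at least one report with that origin. Categories with Nur <= 1 carry
    the degenerate FIC convention (0.0) and are flagged.
    """
    scopes: list[str | None] = list(dataset.regions_present())
    if include_overall:
        scopes.append(None)
    origin_scopes = ["garden", "wild"] if split_by_origin else ["all"]

    rows = []
    for region in scopes:
        for origin in origin_scopes:
            if origin == "all":
                rep = dataset.counting_reports(region)
            else:
                rep = dataset.origin_reports(region)
                rep = rep[rep["origin"] == origin].drop_duplicates(
                    subset=["informant_id", "species_id", "use_category"]
                )
            for cat, grp in rep.groupby("use_category", sort=True):
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
                        "origin_scope": origin,
                        "nur": nur,
                        "nt": nt,
                        "fic": fic,
                        "degenerate": degenerate,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "use_category",
            "region_scope",
            "origin_scope",
            "nur",
            "nt",
            "fic",
            "degenerate",
        ],
    )


def garden_wild_summary(dataset: SurveyDataset) -> pd.DataFrame:
    """Species provenance-class counts per region and overall.

    Counts species that are exclusively wild-collected, grown only in home
    gardens, or both, from :func:`derive_species_origin`. Species with no
    origin-known report are reported as ``unknown`` and flagged when they
    keep the three named classes from summing to the species total.
    """
    scopes: list[str | None] = list(dataset.regions_present()) + [None]
    rows = []
    for region in scopes:
        classes = derive_species_origin(dataset, region)
        counts = pd.Series(classes).value_counts() if classes else pd.Series(dtype=int)
        wild = int(counts.get("exclusively_wild", 0))
        garden = int(counts.get("garden_only", 0))
        both = int(counts.get("both", 0))
        unknown = int(counts.get("unknown", 0))
        total = len(classes)
        rows.append(
            {
                "region_scope": region or "all",
                "species_total": total,
                "exclusively_wild": wild,
                "garden_only": garden,
                "both": both,
                "unknown_origin": unknown,
                "classes_sum_to_total": wild + garden + both == total,
            }
        )
    return pd.DataFrame(rows)
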