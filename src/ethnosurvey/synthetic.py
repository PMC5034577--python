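"""Synthetic survey generator with a truth manifest for recovery tests.

Emulates the statistical structure of a three-region ethnobotanical survey:

* informant counts per region default to SJ=34, SR=63, TK=74 (170 total,
  with a roughly balanced gender split), each informant belonging to a
  community with a fixed elevation;
* a species pool (default 480) partitioned over the 7 regional Venn cells
  with a large shared core, long-tailed log-normal species popularity, and
  a per-species elevation loading so that informants at similar elevations
  report similar inventories;
* per-species use-category profiles drawn from a sparse Dirichlet tilted
  toward food and medicinal uses; each informant-species inclusion yields
  1-3 distinct category reports;
* report-level provenance whose garden probability increases with the
  species' realised use value (UV) through a logistic model
  ``logit P(garden) = b0 + b1 * UV``, so the garden share rises with
  report frequency when ``b1 > 0``.

Every planted quantity is recorded in a :class:`TruthManifest` so the
analysis pipeline can be tested against known ground truth. Generation is
fully deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comparative import VENN_CELLS
from .model import REGIONS, USE_CATEGORIES, SurveyDataset, build_dataset, write_survey

__all__ = ["GeneratorConfig", "TruthManifest", "generate_survey", "write_fixture"]

_CELL_REGIONS = {
    "sj_only": ("SJ",),
    "sr_only": ("SR",),
    "tk_only": ("TK",),
    "sj_sr": ("SJ", "SR"),
    "sj_tk": ("SJ", "TK"),
    "sr_tk": ("SR", "TK"),
    "all": ("SJ", "SR", "TK"),
}

_FAMILIES = [f"Familia{c}" for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic survey."""

    seed: int = 0
    #: informants per region (study design: SJ=34, SR=63, TK=74)
    region_informants: dict = field(
        default_factory=lambda: {"SJ": 34, "SR": 63, "TK": 74}
    )
    communities_per_region: int = 4
    #: community elevation ranges in meters, per region
    elevation_ranges: dict = field(
        default_factory=lambda: {
            "SJ": (1100.0, 2100.0),
            "SR": (600.0, 2200.0),
            "TK": (1400.0, 2500.0),
        }
    )
    n_species: int = 480
    #: fractions of the species pool in each exclusive Venn cell (sum to 1);
    #: a large three-region core with TK carrying the most unique species
    venn_fractions: dict = field(
        default_factory=lambda: {
            "sj_only": 0.10,
            "sr_only": 0.05,
            "tk_only": 0.20,
            "sj_sr": 0.04,
            "sj_tk": 0.14,
            "sr_tk": 0.12,
            "all": 0.35,
        }
    )
    #: expected counting-unit reports per informant
    mean_reports_per_informant: float = 60.0
    #: Dirichlet concentration for per-species category profiles
    category_concentration: float = 0.5
    #: base category weights (food and medicinal dominate, as in the field)
    category_weights: dict = field(
        default_factory=lambda: {
            "food": 3.0,
            "medicinal": 2.2,
            "utensils_tools": 1.2,
            "construction": 1.0,
            "cultural": 0.8,
            "fodder": 0.8,
            "fuel": 0.8,
            "veterinary": 0.5,
            "ornamental": 0.5,
            "other": 0.7,
        }
    )
    #: scale of the per-species elevation loading in the inclusion logit
    elevation_effect: float = 2.0
    #: sd of log-popularity (log-normal popularity gives a few UV >> 1 species)
    popularity_sd: float = 1.0
    #: provenance model: logit P(garden) = intercept + uv_coef * UV
    garden_intercept: float = -2.0
    garden_uv_coef: float = 3.0
    #: fraction of reports with unrecorded origin
    unknown_origin_rate: float = 0.03
    #: probability an informant reports an age (exercises the coverage rule)
    age_coverage: float = 0.8
    #: distribution of distinct category reports per informant-species inclusion
    reports_per_inclusion_probs: tuple = (0.70, 0.25, 0.05)

    def validate(self) -> None:
        if any(n <= 0 for n in self.region_informants.values()):
            raise ValueError("informant counts must be positive")
        if set(self.region_informants) - set(REGIONS):
            raise ValueError(f"unknown regions: {set(self.region_informants) - set(REGIONS)}")
        frac = sum(self.venn_fractions.get(c, 0.0) for c in VENN_CELLS)
        if abs(frac - 1.0) > 1e-9:
            raise ValueError(f"venn_fractions must sum to 1 (got {frac})")
        if self.n_species < 7:
            raise ValueError("species pool too small for a 7-cell partition")
        if self.mean_reports_per_informant <= 0:
            raise ValueError("mean_reports_per_informant must be positive")
        mean_uses = self.expected_uses_per_inclusion()
        for region, n_inf in self.region_informants.items():
            pool = sum(
                self.venn_fractions[c]
                for c, regs in _CELL_REGIONS.items()
                if region in regs
            ) * self.n_species
            if self.mean_reports_per_informant / mean_uses > pool:
                raise ValueError(
                    f"infeasible config: region {region} pool (~{pool:.0f} species) "
                    f"smaller than the target inclusions per informant"
                )

    def expected_uses_per_inclusion(self) -> float:
        p = np.asarray(self.reports_per_inclusion_probs, dtype=float)
        return float((p * np.arange(1, len(p) + 1)).sum() / p.sum())


@dataclass
class TruthManifest:
    """Planted ground truth sufficient to recompute every generated effect."""

    config: dict
    species_truth: pd.DataFrame  # venn_cell, popularity, elevation_loading, p_garden, uv_realised
    informant_truth: pd.DataFrame
    category_profiles: np.ndarray  # n_species x 10
    garden_intercept: float
    garden_uv_coef: float
    elevation_effect: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "garden_intercept": self.garden_intercept,
                "garden_uv_coef": self.garden_uv_coef,
                "elevation_effect": self.elevation_effect,
                "species_truth": self.species_truth.to_dict(orient="list"),
                "informant_truth": self.informant_truth.to_dict(orient="list"),
                "category_profiles": self.category_profiles.tolist(),
            },
            indent=None,
            sort_keys=True,
        )


def _calibrate_intercept(logits: np.ndarray, target: float) -> float:
    """Solve sum(sigmoid(a + logits)) = target for a, by bisection."""
    target = min(target, len(logits) - 0.5)
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        total = float((1.0 / (1.0 + np.exp(-(mid + logits)))).sum())
        if total > target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def generate_survey(config: GeneratorConfig | None = None) -> tuple[SurveyDataset, TruthManifest]:
    """Draw a full synthetic survey; deterministic given ``config.seed``."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- species pool -----------------------------------------------------
    n_sp = config.n_species
    cells = rng.choice(
        VENN_CELLS,
        size=n_sp,
        p=[config.venn_fractions[c] for c in VENN_CELLS],
    )
    log_pop = rng.normal(0.0, config.popularity_sd, size=n_sp)
    loading = rng.normal(0.0, 1.0, size=n_sp)
    alpha = np.array([config.category_weights[c] for c in USE_CATEGORIES])
    profiles = rng.dirichlet(alpha * config.category_concentration * len(alpha), size=n_sp)

    species_ids = [f"S{i:03d}" for i in range(n_sp)]
    n_genera = max(10, n_sp // 3)
    genus_of = rng.integers(0, n_genera, size=n_sp)
    species = pd.DataFrame(
        {
            "species_id": species_ids,
            "scientific_name": [
                f"Genus{g:03d} taxon{i:03d}" for i, g in enumerate(genus_of)
            ],
            "genus": [f"Genus{g:03d}" for g in genus_of],
            "family": [_FAMILIES[g % len(_FAMILIES)] for g in genus_of],
            "growth_form": rng.choice(
                ["herb", "shrub", "tree", "vine", "fungus"], size=n_sp, p=[0.5, 0.2, 0.2, 0.07, 0.03]
            ),
        }
    )

    # --- informants and communities --------------------------------------
    inf_rows = []
    idx = 0
    for region in REGIONS:
        n_inf = config.region_informants.get(region, 0)
        lo, hi = config.elevation_ranges[region]
        elevs = np.linspace(lo, hi, config.communities_per_region)
        for _ in range(n_inf):
            com = int(rng.integers(0, config.communities_per_region))
            age = float(np.clip(rng.normal(62, 14), 16, 95))
            inf_rows.append(
                {
                    "informant_id": f"I{idx:03d}",
                    "region": region,
                    "community": f"{region}_com{com}",
                    "elevation_m": float(elevs[com]),
                    "gender": "female" if rng.random() < 80 / 170 else "male",
                    "age": round(age) if rng.random() < config.age_coverage else np.nan,
                }
            )
            idx += 1
    informants = pd.DataFrame(inf_rows)
    n_informants = len(informants)
    elev_z = (
        informants["elevation_m"] - informants["elevation_m"].mean()
    ) / informants["elevation_m"].std()

    # --- inclusion draws ---------------------------------------------------
    pop_z = (log_pop - log_pop.mean()) / log_pop.std()
    target_inclusions = config.mean_reports_per_informant / config.expected_uses_per_inclusion()
    region_pools = {
        r: np.array([i for i in range(n_sp) if r in _CELL_REGIONS[cells[i]]])
        for r in REGIONS
    }
    m_probs = np.asarray(config.reports_per_inclusion_probs, dtype=float)
    m_probs = m_probs / m_probs.sum()

    rep_rows: list[tuple[str, str, str]] = []
    for i, inf in informants.iterrows():
        pool = region_pools[inf["region"]]
        logits = pop_z[pool] + config.elevation_effect * loading[pool] * elev_z[i]
        a = _calibrate_intercept(logits, target_inclusions)
        probs = 1.0 / (1.0 + np.exp(-(a + logits)))
        included = pool[rng.random(len(pool)) < probs]
        for s in included:
            m = int(rng.choice(len(m_probs), p=m_probs)) + 1
            cats = rng.choice(len(USE_CATEGORIES), size=m, replace=False, p=profiles[s])
            for c in cats:
                rep_rows.append((inf["informant_id"], species_ids[s], USE_CATEGORIES[c]))

    reports = pd.DataFrame(rep_rows, columns=["informant_id", "species_id", "use_category"])
    reports["use_detail"] = ""

    # --- provenance: garden probability rises with realised UV -------------
    sp_counts = reports["species_id"].value_counts()
    uv_realised = np.array(
        [sp_counts.get(sid, 0) / n_informants for sid in species_ids]
    )
    p_garden = 1.0 / (
        1.0 + np.exp(-(config.garden_intercept + config.garden_uv_coef * uv_realised))
    )
    p_by_id = dict(zip(species_ids, p_garden))
    u = rng.random(len(reports))
    origin = np.where(
        u < reports["species_id"].map(p_by_id).to_numpy(), "garden", "wild"
    )
    unknown = rng.random(len(reports)) < config.unknown_origin_rate
    origin[unknown] = "unknown"
    reports["origin"] = origin

    dataset = build_dataset(reports, informants, species)

    species_truth = pd.DataFrame(
        {
            "species_id": species_ids,
            "venn_cell": cells,
            "log_popularity": log_pop,
            "elevation_loading": loading,
            "uv_realised": uv_realised,
            "p_garden": p_garden,
        }
    )
    cfg_dict = asdict(config)
    cfg_dict["reports_per_inclusion_probs"] = list(config.reports_per_inclusion_probs)
    manifest = TruthManifest(
        config=cfg_dict,
        species_truth=species_truth,
        informant_truth=informants.copy(),
        category_profiles=profiles,
        garden_intercept=config.garden_intercept,
        garden_uv_coef=config.garden_uv_coef,
        elevation_effect=config.elevation_effect,
    )
    return dataset, manifest


def write_fixture(
    dataset: SurveyDataset, manifest: TruthManifest, directory: str | Path
) -> dict[str, Path]:
    """Write the three survey files plus the truth manifest JSON."""
    directory = Path(directory)
    paths = write_survey(dataset, directory)
    manifest_path = directory / "truth_manifest.json"
    manifest_path.write_text(manifest.to_json(), encoding="utf-8")
    paths["manifest"] = manifest_path
    return paths
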