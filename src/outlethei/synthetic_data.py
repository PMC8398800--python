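"""NHANES-like 24-h recall microdata with known ground truth.

Generates item-level recall records grouped by respondent under a masked
two-PSU-per-stratum design, with outlet-specific true density profiles.
Per item, energy is lognormal and each component amount is

    energy / 1000 * true_density * gamma_noise(mean 1, cv)

(percent-of-energy components are back-converted through the fixed kcal
factors, the fatty-acid ratio through the saturated-fat amount).  Because
the noise is multiplicative with mean one and independent of energy, the
population-ratio estimator — weighted component total over weighted energy
total — is consistent for the configured density, so expected HEI scores
are available analytically by scoring the configured densities directly.

The generator does not attempt to model real food-item co-occurrence,
seasonality, or within-person day-to-day correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hei_engine import (
    HEIScoreSet,
    ScoringStandard,
    densities_for_scores,
    load_standards,
    score_component,
)
from .recall_io import CANONICAL_COMPONENTS, RESPONDENT_COLUMNS

__all__ = [
    "OutletProfile",
    "SyntheticConfig",
    "generate",
    "expected_scores",
    "write_tables",
    "demo_config",
    "config_series_with_trend",
    "DEMO_SCORE_TARGETS",
]

#: Representative raw source code per detailed outlet category.
SOURCE_CODE_FOR_OUTLET: Mapping[str, str] = {
    "store": "1",
    "school": "7",
    "full_service": "2",
    "quick_service": "3",
    "community_food_program": "10",
    "homegrown": "19",
    "other": "16",
}


@dataclass(frozen=True)
class OutletProfile:
    """Generative truth for one outlet.

    ``densities`` holds one true density per scoring component, in that
    component's scoring unit (cup/oz-eq per 1000 kcal, percent of energy,
    or the fatty-acid ratio); ``item_rate`` is the expected number of items
    a respondent reports from this outlet; ``noise_cv`` the coefficient of
    variation of the multiplicative item-level noise.
    """

    item_rate: float
    densities: Mapping[str, float]
    energy_mu: float = 5.0
    energy_sigma: float = 0.6
    noise_cv: float = 0.3


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and truth parameters governing one generated population."""

    outlets: Mapping[str, OutletProfile]
    n_respondents: int = 2000
    n_strata: int = 16
    cycles: tuple[str, ...] = ("2017-2018",)
    weight_mu: float = 9.0
    weight_sigma: float = 0.7
    age_low: int = 2
    age_high: int = 80
    #: optional age-bin -> outlet -> probability mixture; bins are
    #: (low, high) with high exclusive.  Defaults to item-rate proportions.
    outlet_probs: Mapping[tuple[float, float], Mapping[str, float]] | None = None
    p_unreliable: float = 0.0
    p_human_milk: float = 0.0
    seed: int = 0
    standards: tuple[ScoringStandard, ...] = field(default_factory=load_standards)

    def validate(self) -> None:
        if self.n_respondents < 2 * self.n_strata:
            raise ValueError("need at least two respondents per stratum (2 PSUs each)")
        if not self.outlets:
            raise ValueError("at least one outlet profile is required")
        for name, profile in self.outlets.items():
            if name not in SOURCE_CODE_FOR_OUTLET:
                raise ValueError(f"unknown outlet {name!r}")
            if profile.item_rate < 0 or profile.noise_cv < 0:
                raise ValueError(f"outlet {name!r}: rates and cv must be >= 0")
            for comp, d in profile.densities.items():
                if d < 0:
                    raise ValueError(f"outlet {name!r}: density {comp!r} < 0")
            missing = {s.component for s in self.standards} - set(profile.densities)
            if missing:
                raise ValueError(f"outlet {name!r} lacks densities for {sorted(missing)}")
        if self.outlet_probs is not None:
            for bin_, probs in self.outlet_probs.items():
                if set(probs) != set(self.outlets):
                    raise ValueError(f"age bin {bin_}: probabilities must cover all outlets")
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"age bin {bin_}: probabilities must sum to 1")
        if not (0 <= self.p_unreliable <= 1 and 0 <= self.p_human_milk <= 1):
            raise ValueError("exclusion fractions must be probabilities")


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    shape = 1.0 / cv**2
    return rng.gamma(shape, 1.0 / shape, size)


def _item_amounts(
    rng: np.random.Generator,
    energy: np.ndarray,
    profile: OutletProfile,
    standards: Sequence[ScoringStandard],
) -> dict[str, np.ndarray]:
    """Back-convert true densities into canonical item amounts."""
    n = energy.size
    amounts = {c: np.zeros(n) for c in CANONICAL_COMPONENTS}
    ratio_standard = None
    for s in standards:
        d = profile.densities[s.component]
        noise = _noise(rng, profile.noise_cv, n)
        if s.unit == "per_1000kcal":
            amounts[s.source] = energy / 1000.0 * d / s.scale * noise
        elif s.unit == "percent_energy":
            amounts[s.source] = energy * (d / 100.0) / s.kcal_per_unit * noise
        else:  # fat_ratio: resolved after saturated fat is drawn
            ratio_standard = (s, noise)
    if ratio_standard is not None:
        s, noise = ratio_standard
        mono_poly = amounts["sfa_g"] * profile.densities[s.component] * noise
        amounts["mufa_g"] = mono_poly / 2.0
        amounts["pufa_g"] = mono_poly / 2.0
    return amounts


def _bin_probs(
    config: SyntheticConfig, ages: np.ndarray, outlet_names: list[str]
) -> np.ndarray:
    """Per-respondent outlet mixture probabilities (n x n_outlets)."""
    rates = np.array([config.outlets[o].item_rate for o in outlet_names])
    default = rates / rates.sum()
    probs = np.tile(default, (ages.size, 1))
    if config.outlet_probs is not None:
        for (low, high), mix in config.outlet_probs.items():
            mask = (ages >= low) & (ages < high)
            probs[mask] = [mix[o] for o in outlet_names]
    return probs


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (respondents, items) tables, fully reproducible from the seed.

    Respondents are assigned round-robin to ``n_strata`` strata with two
    PSUs each; per respondent the item count is Poisson with mean equal to
    the summed outlet rates, and each item's outlet is drawn from the
    respondent's age-bin mixture.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outlet_names = list(config.outlets)
    total_rate = sum(p.item_rate for p in config.outlets.values())

    resp_frames, item_frames = [], []
    for ci, cycle in enumerate(config.cycles):
        n = config.n_respondents
        ids = np.array([f"c{ci}r{i:06d}" for i in range(n)])
        idx = np.arange(n)
        stratum = idx % config.n_strata
        psu = (idx // config.n_strata) % 2
        ages = rng.integers(config.age_low, config.age_high + 1, n).astype(float)
        weights = rng.lognormal(config.weight_mu, config.weight_sigma, n)
        unreliable = rng.random(n) < config.p_unreliable
        human_milk = rng.random(n) < config.p_human_milk
        resp_frames.append(
            pd.DataFrame(
                {
                    "respondent_id": ids,
                    "cycle": cycle,
                    "age_years": ages,
                    "day1_weight": weights,
                    "stratum": [f"c{ci}s{s:03d}" for s in stratum],
                    "psu": psu.astype(str),
                    "recall_reliable": ~unreliable,
                    "consumes_human_milk": human_milk,
                }
            )
        )

        counts = rng.poisson(total_rate, n)
        item_resp = np.repeat(idx, counts)
        probs = _bin_probs(config, ages, outlet_names)[item_resp]
        u = rng.random(item_resp.size)
        outlet_idx = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)

        parts = []
        for oi, outlet in enumerate(outlet_names):
            mask = outlet_idx == oi
            m = int(mask.sum())
            if m == 0:
                continue
            profile = config.outlets[outlet]
            energy = rng.lognormal(profile.energy_mu, profile.energy_sigma, m)
            amounts = _item_amounts(rng, energy, profile, config.standards)
            frame = pd.DataFrame(
                {
                    "respondent_id": ids[item_resp[mask]],
                    "source_code": SOURCE_CODE_FOR_OUTLET[outlet],
                    "energy_kcal": energy,
                    **amounts,
                }
            )
            frame["cycle"] = cycle
            parts.append(frame)
        if parts:
            items = pd.concat(parts, ignore_index=True)
            items = items.sort_values("respondent_id", kind="stable").reset_index(drop=True)
            item_frames.append(items)

    respondents = pd.concat(resp_frames, ignore_index=True)
    items = (
        pd.concat(item_frames, ignore_index=True)
        if item_frames
        else pd.DataFrame(
            columns=["respondent_id", "source_code", "energy_kcal", *CANONICAL_COMPONENTS, "cycle"]
        )
    )
    return respondents, items


def expected_scores(
    config: SyntheticConfig,
    standards: Sequence[ScoringStandard] | None = None,
) -> dict[str, HEIScoreSet]:
    """Analytic expected HEI score set per outlet (noise-free limit).

    Scores the configured true densities directly; the population-ratio
    estimate from :func:`generate` output converges to these as the sample
    grows, because the item-level noise has mean one.
    """
    standards = tuple(standards) if standards is not None else config.standards
    out = {}
    for outlet, profile in config.outlets.items():
        scores = {
            s.component: score_component(profile.densities[s.component], s)
            for s in standards
        }
        out[outlet] = HEIScoreSet(
            group=outlet, component_scores=scores, total=sum(scores.values())
        )
    return out


def write_tables(
    respondents: pd.DataFrame, items: pd.DataFrame, directory: str | Path
) -> tuple[Path, Path]:
    """Write the generated tables in the CSV dialect recall_io reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    resp_path = directory / "respondents.csv"
    item_path = directory / "items.csv"
    respondents.loc[:, list(RESPONDENT_COLUMNS)].to_csv(resp_path, index=False)
    items.to_csv(item_path, index=False)
    return resp_path, item_path


#: Component-score targets per outlet for the packaged demonstration
#: config, chosen to resemble recent published NHANES 2017–2018 estimates
#: of diet quality by food outlet (totals near schools 65, stores 62,
#: full-service 51, quick-service 39).  Demonstration only.
DEMO_SCORE_TARGETS: Mapping[str, Mapping[str, float]] = {
    "store": {
        "total_fruits": 3.52, "whole_fruits": 5.0, "total_vegetables": 3.05,
        "greens_and_beans": 3.10, "whole_grains": 3.50, "dairy": 5.85,
        "total_protein_foods": 5.0, "seafood_plant_proteins": 5.0,
        "fatty_acids": 3.95, "refined_grains": 7.02, "sodium": 5.59,
        "added_sugars": 5.50, "saturated_fats": 6.19,
    },
    "school": {
        "total_fruits": 5.0, "whole_fruits": 5.0, "total_vegetables": 2.17,
        "greens_and_beans": 1.43, "whole_grains": 7.24, "dairy": 10.0,
        "total_protein_foods": 3.57, "seafood_plant_proteins": 2.52,
        "fatty_acids": 2.10, "refined_grains": 5.79, "sodium": 5.76,
        "added_sugars": 8.43, "saturated_fats": 6.0,
    },
    "full_service": {
        "total_fruits": 0.47, "whole_fruits": 0.53, "total_vegetables": 4.61,
        "greens_and_beans": 4.25, "whole_grains": 0.82, "dairy": 3.83,
        "total_protein_foods": 5.0, "seafood_plant_proteins": 5.0,
        "fatty_acids": 6.21, "refined_grains": 5.63, "sodium": 0.0,
        "added_sugars": 5.11, "saturated_fats": 9.25,
    },
    "quick_service": {
        "total_fruits": 0.66, "whole_fruits": 0.84, "total_vegetables": 3.08,
        "greens_and_beans": 1.87, "whole_grains": 0.76, "dairy": 5.64,
        "total_protein_foods": 5.0, "seafood_plant_proteins": 2.32,
        "fatty_acids": 4.01, "refined_grains": 2.79, "sodium": 2.06,
        "added_sugars": 2.83, "saturated_fats": 7.55,
    },
}

#: Expected items per respondent by outlet in the demo config, loosely
#: matching observed calorie shares (stores dominate).
_DEMO_ITEM_RATES: Mapping[str, float] = {
    "store": 8.0,
    "quick_service": 2.0,
    "full_service": 1.2,
    "school": 0.8,
}


def demo_config(
    n_respondents: int = 2000,
    n_strata: int = 16,
    noise_cv: float = 0.3,
    seed: int = 0,
    cycles: tuple[str, ...] = ("2017-2018",),
) -> SyntheticConfig:
    """Packaged demonstration config with outlet-specific true densities."""
    standards = load_standards()
    outlets = {
        name: OutletProfile(
            item_rate=_DEMO_ITEM_RATES[name],
            densities=densities_for_scores(targets, standards),
            noise_cv=noise_cv,
        )
        for name, targets in DEMO_SCORE_TARGETS.items()
    }
    return SyntheticConfig(
        outlets=outlets,
        n_respondents=n_respondents,
        n_strata=n_strata,
        cycles=cycles,
        seed=seed,
        standards=standards,
    )


def config_series_with_trend(
    base_scores: Mapping[str, float],
    slope_per_cycle: float,
    n_cycles: int = 8,
    outlet: str = "school",
    n_respondents: int = 1000,
    n_strata: int = 16,
    noise_cv: float = 0.3,
    seed: int = 0,
) -> list[SyntheticConfig]:
    """One single-outlet config per cycle with a linear total-score trend.

    Cycle c's component-score targets equal *base_scores* plus an increment
    of ``slope_per_cycle * c`` distributed across components in proportion
    to their remaining headroom, so the expected total is exactly linear in
    the cycle index.
    """
    standards = load_standards()
    max_points = {s.component: s.max_points for s in standards}
    headroom = {c: max_points[c] - base_scores[c] for c in base_scores}
    total_headroom = sum(headroom.values())
    if slope_per_cycle * (n_cycles - 1) > total_headroom:
        raise ValueError("injected trend exceeds available score headroom")
    configs = []
    for c in range(n_cycles):
        bump = slope_per_cycle * c
        targets = {
            comp: base_scores[comp] + bump * headroom[comp] / total_headroom
            for comp in base_scores
        }
        profile = OutletProfile(
            item_rate=6.0,
            densities=densities_for_scores(targets, standards),
            noise_cv=noise_cv,
        )
        configs.append(
            SyntheticConfig(
                outlets={outlet: profile},
                n_respondents=n_respondents,
                n_strata=n_strata,
                cycles=(f"cycle{c}",),
                seed=seed + c,
                standards=standards,
            )
        )
    return configs
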