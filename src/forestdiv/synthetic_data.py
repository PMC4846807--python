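"""Synthetic two-belt stand surveys with known ground truth.

Emulates the reference design — two altitudinal belts (birch, pine-oak),
five stand types per belt, five 30 x 30 m plots per stand — with species
pools drawn from a packaged regional taxonomy, per-belt species relative
abundances generated from a configurable SAD model, and per-stem DBH >= 5 cm
from guild-specific log-normal distributions.

Defaults target the observed scale of the study system: roughly 2,900 stems
in ~43 species per belt, a flat dominance structure for the birch belt
(niche preemption, alpha = 0.10, most-abundant species ~10% of stems) and a
concentrated one for the pine-oak belt (alpha = 0.33, top-3 species ~70% of
stems), with 80% of the smaller pool shared between belts.

Every draw flows from one seeded generator, so a fixed seed reproduces the
survey byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import sad_fit
from .plot_data import (
    BIRCH,
    PINEOAK,
    STAND_BELT,
    PlotInfo,
    StemRecord,
    load_taxonomy,
    write_plots,
    write_stems,
)

__all__ = [
    "BeltSpec",
    "GroundTruth",
    "model_proportions",
    "gen_community",
    "gen_survey",
    "default_survey_specs",
    "write_survey",
]

_CONIFER_GENERA = {"Pinus", "Abies", "Tsuga", "Larix"}


@dataclass
class BeltSpec:
    """Design of one belt: stands, plots, species pool and SAD model."""

    name: str
    stand_codes: list[str]
    species_pool: list[str]
    sad_model: str = "niche-preemption"
    sad_params: dict = field(default_factory=dict)
    plots_per_stand: int = 5
    plot_area_m2: float = 900.0
    stems_per_plot: int = 116
    dbh_medians: dict = field(default_factory=lambda: {"conifer": 13.0, "broadleaf": 9.0})
    dbh_sdlog: float = 0.45
    elevation_range: tuple[float, float] = (1300.0, 2400.0)

    def __post_init__(self) -> None:
        if self.stems_per_plot <= 0:
            raise ValueError("stems_per_plot must be positive")

    @property
    def n_plots(self) -> int:
        return len(self.stand_codes) * self.plots_per_stand

    @property
    def total_stems(self) -> int:
        return self.n_plots * self.stems_per_plot


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream checks."""

    seed: int
    belts: dict
    shared_species: list[str]
    shared_fraction: float
    stems_per_belt: dict
    proportions: dict  # belt -> {species: true relative abundance}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def model_proportions(model: str, S: int, params: dict) -> np.ndarray:
    """True relative abundances implied by a SAD model, normalized over S ranks."""
    if model == "broken-stick":
        a = sad_fit.expected_broken_stick(1.0, S)
    elif model == "niche-preemption":
        a = sad_fit.expected_preemption(1.0, S, params["alpha"])
    elif model == "log-normal":
        a = sad_fit.expected_lognormal(S, params.get("mu", 10.0), params["sigma"])
    elif model == "zipf":
        a = sad_fit.expected_zipf(1.0, S, params.get("p1", 0.3), params["gamma"])
    elif model == "zipf-mandelbrot":
        a = sad_fit.expected_zm(1.0, S, params.get("c", 0.3), params["beta"], params["gamma"])
    else:
        raise ValueError(f"no closed-form proportions for model {model!r}")
    return a / a.sum()


def _neutral_community(N: int, theta: float, m: float, rng: np.random.Generator) -> np.ndarray:
    """Sequential urn assembly of a neutral local community of size N.

    Each new individual immigrates from an Ewens(theta) metacommunity urn
    with probability m, otherwise copies a random established individual.
    Returns species counts (variable richness).
    """
    meta_counts: list[int] = []
    meta_draws = 0
    local: list[int] = []
    counts: dict[int, int] = {}

    def draw_meta() -> int:
        nonlocal meta_draws
        if meta_draws == 0 or rng.random() < theta / (theta + meta_draws):
            meta_counts.append(1)
            sp = len(meta_counts) - 1
        else:
            tot = sum(meta_counts)
            pick = rng.integers(tot)
            acc = 0
            for sp, c in enumerate(meta_counts):
                acc += c
                if pick < acc:
                    break
            meta_counts[sp] += 1
        meta_draws += 1
        return sp

    for j in range(N):
        if j == 0 or rng.random() < m:
            sp = draw_meta()
        else:
            sp = local[rng.integers(len(local))]
        local.append(sp)
        counts[sp] = counts.get(sp, 0) + 1
    return np.array(sorted(counts.values(), reverse=True))


def gen_community(
    S: int,
    N: int,
    sad_model: str,
    params: dict,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one community: N individuals multinomially from the model's
    expected relative abundances (neutral: sequential urn with theta, m)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sad_model == "neutral":
        return _neutral_community(N, params["theta"], params["m"], rng)
    p = model_proportions(sad_model, S, params)
    return rng.multinomial(N, p)


_BIRCH_DOMINANTS = [
    "Betula albosinensis",
    "Pinus armandii",
    "Acer davidii",
    "Toxicodendron vernicifluum",
    "Tsuga chinensis",
    "Carpinus turczaninowii",
    "Abies fargesii",
    "Sorbus folgneri",
]
_PINEOAK_DOMINANTS = [
    "Quercus aliena var. acutiserrata",
    "Pinus tabuliformis",
    "Pinus armandii",
    "Toxicodendron vernicifluum",
    "Carpinus turczaninowii",
    "Lindera obtusiloba",
]


def _ordered_pool(priority: list[str], all_species: list[str], size: int) -> list[str]:
    tail = [sp for sp in all_species if sp not in priority]
    return (priority + tail)[:size]


def default_survey_specs(taxonomy=None) -> tuple[BeltSpec, BeltSpec]:
    """Reference-design belt specs (flat birch vs concentrated pine-oak).

    Abundance ranks follow pool order, so each belt's namesake dominants
    head its pool.
    """
    if taxonomy is None:
        taxonomy = load_taxonomy()
    species = list(taxonomy.index)
    birch_codes = [c for c, b in STAND_BELT.items() if b == BIRCH]
    pine_codes = [c for c, b in STAND_BELT.items() if b == PINEOAK]
    birch = BeltSpec(
        name=BIRCH,
        stand_codes=birch_codes,
        species_pool=_ordered_pool(_BIRCH_DOMINANTS, species, 43),
        sad_model="niche-preemption",
        sad_params={"alpha": 0.10},
        stems_per_plot=116,
        elevation_range=(1800.0, 2400.0),
    )
    pineoak = BeltSpec(
        name=PINEOAK,
        stand_codes=pine_codes,
        species_pool=_ordered_pool(_PINEOAK_DOMINANTS, species, 41),
        sad_model="zipf",
        sad_params={"gamma": -1.3},
        stems_per_plot=110,
        elevation_range=(1300.0, 2000.0),
    )
    return birch, pineoak


def _overlap_pools(
    birch: BeltSpec, pineoak: BeltSpec, shared_fraction: float, all_species: list[str]
) -> None:
    """Rebuild the two pools so they share the requested fraction of the
    smaller pool. Each belt keeps its own head of exclusive (dominant)
    species; the shared species form the common tail — belts resemble each
    other floristically but differ in dominance structure."""
    s1, s2 = len(birch.species_pool), len(pineoak.species_pool)
    n_shared = int(round(shared_fraction * min(s1, s2)))
    need1, need2 = s1 - n_shared, s2 - n_shared

    pool_all = list(dict.fromkeys(birch.species_pool + pineoak.species_pool + all_species))
    excl1 = birch.species_pool[:need1]
    excl2 = [sp for sp in pineoak.species_pool if sp not in excl1][:need2]
    spare = [sp for sp in pool_all if sp not in excl1 and sp not in excl2]
    while len(excl2) < need2:  # own pool exhausted by the overlap with belt 1
        if not spare:
            raise ValueError("taxonomy too small for requested pool sizes and overlap")
        excl2.append(spare.pop(0))
    used = set(excl1) | set(excl2)
    shared = [sp for sp in pool_all if sp not in used][:n_shared]
    if len(shared) < n_shared:
        raise ValueError("taxonomy too small for requested pool sizes and overlap")
    birch.species_pool = excl1 + shared
    pineoak.species_pool = excl2 + shared


def _dbh_for(species: str, spec: BeltSpec, genus: str, rng: np.random.Generator) -> float:
    guild = "conifer" if genus in _CONIFER_GENERA else "broadleaf"
    median = spec.dbh_medians[guild]
    return 5.0 + float(rng.lognormal(np.log(median - 5.0), spec.dbh_sdlog))


def gen_survey(
    birch: BeltSpec | None = None,
    pineoak: BeltSpec | None = None,
    shared_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[StemRecord], list[PlotInfo], GroundTruth]:
    """Generate a full two-belt survey: stems, plots, and ground truth.

    Belt communities are drawn once at belt scale from the belt's SAD model
    and individuals are scattered over the belt's plots multinomially, so
    plot totals fluctuate around ``stems_per_plot`` while belt totals are
    exact.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    taxonomy = load_taxonomy()
    if birch is None or pineoak is None:
        b, p = default_survey_specs(taxonomy)
        birch = birch if birch is not None else b
        pineoak = pineoak if pineoak is not None else p
    _overlap_pools(birch, pineoak, shared_fraction, list(taxonomy.index))

    rng = np.random.default_rng(seed)
    stems: list[StemRecord] = []
    plots: list[PlotInfo] = []
    truth_props: dict[str, dict[str, float]] = {}
    stems_per_belt: dict[str, int] = {}

    for spec in (birch, pineoak):
        pool = list(spec.species_pool)
        S = len(pool)
        N = spec.total_stems
        if spec.sad_model == "neutral":
            counts = _neutral_community(N, spec.sad_params["theta"], spec.sad_params["m"], rng)
            pool = pool[: counts.size]
            S = counts.size
            props = counts / counts.sum()
        else:
            props = model_proportions(spec.sad_model, S, spec.sad_params)
            counts = rng.multinomial(N, props)
        truth_props[spec.name] = {sp: float(pr) for sp, pr in zip(pool, props)}
        stems_per_belt[spec.name] = int(counts.sum())

        plot_ids = [
            f"{code}-{i + 1}"
            for code in spec.stand_codes
            for i in range(spec.plots_per_stand)
        ]
        lo, hi = spec.elevation_range
        for pid in plot_ids:
            code = pid.rsplit("-", 1)[0]
            plots.append(
                PlotInfo(pid, code, spec.plot_area_m2, float(np.round(rng.uniform(lo, hi), 0)))
            )
        # scatter each species' individuals over the belt's plots
        for sp, c in zip(pool, counts):
            if c == 0:
                continue
            genus = str(taxonomy.loc[sp, "genus"]) if sp in taxonomy.index else "unknown"
            alloc = rng.multinomial(int(c), np.full(len(plot_ids), 1.0 / len(plot_ids)))
            for pid, k in zip(plot_ids, alloc):
                code = pid.rsplit("-", 1)[0]
                for _ in range(int(k)):
                    dbh = round(_dbh_for(sp, spec, genus, rng), 1)
                    height = round(1.3 + 0.75 * dbh ** 0.9 * float(rng.lognormal(0.0, 0.15)), 1)
                    crown = round(0.25 * dbh * float(rng.lognormal(0.0, 0.2)), 1)
                    stems.append(StemRecord(pid, code, spec.name, sp, dbh, height, crown))

    truth = GroundTruth(
        seed=seed,
        belts={
            spec.name: {
                "sad_model": spec.sad_model,
                "sad_params": spec.sad_params,
                "S": len(truth_props[spec.name]),
                "N": stems_per_belt[spec.name],
            }
            for spec in (birch, pineoak)
        },
        shared_species=sorted(set(birch.species_pool) & set(pineoak.species_pool)),
        shared_fraction=shared_fraction,
        stems_per_belt=stems_per_belt,
        proportions=truth_props,
    )
    return stems, plots, truth


def write_survey(
    outdir: str | Path,
    birch: BeltSpec | None = None,
    pineoak: BeltSpec | None = None,
    shared_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[Path, Path, Path]:
    """Generate a survey and write stems/plots CSVs plus ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stems, plots, truth = gen_survey(birch, pineoak, shared_fraction, seed)
    stems_path = outdir / "stems.csv"
    plots_path = outdir / "plots.csv"
    truth_path = outdir / "ground_truth.json"
    write_stems(stems, stems_path)
    write_plots(plots, plots_path)
    truth.to_json(truth_path)
    return stems_path, plots_path, truth_path
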