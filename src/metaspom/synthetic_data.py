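"""Synthetic landscapes, weather, and ground-truth occupancy histories.

The generator emulates the structure of the Åland-type study system — a
large network of small dry-meadow patches surveyed yearly for a butterfly,
its parasitoid, and a powdery mildew — at configurable size:

* clustered patch coordinates in a 50 × 70 km extent with log-normal areas,
* zero-inflated log-normal yearly host-plant cover with a shared year
  factor (long-term mean near 8 m² per patch),
* an ordinal second-host-plant score concentrated in the western third of
  the extent, and ~30% of patches bordering roads,
* May–August monthly precipitation, log-normal with a year-level factor,
* occupancy histories produced by the same colonization/extinction process
  the pipeline fits (via the metacommunity simulator), with known
  intercepts, slopes, variance components, and optional co-occurrence
  (patch-state) contrasts.

Default rate parameters put colonization events near 4–8% and extinction
events near 40–60% of possible events, the range observed in the real
system, which keeps the downstream model fits well conditioned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from metaspom import landscape as lsc
from metaspom.simulator import CommunityRates, RatePredictor, simulate_trajectory

__all__ = [
    "TruthParams",
    "default_truth",
    "generate_landscape",
    "generate_covariates",
    "generate_history",
    "make_fixture",
    "PROFILES",
]

START_YEAR = 2000

#: Fixture profiles: (n_patches, n_years).  `tiny` runs the full pipeline
#: in seconds; `default` echoes the study scale at reduced size; `power`
#: is sized for detecting moderate interaction contrasts.
PROFILES = {"tiny": (20, 5), "default": (500, 19), "power": (2000, 15)}


@dataclass
class TruthParams:
    """Ground-truth rate models for the three species.

    ``predictors`` maps (species, response) to a :class:`RatePredictor`
    holding the intercept, covariate slopes (model scales: log m² cover,
    ordinal score, raw connectivity, 0/1 road, log mm precipitation),
    variance components, and optional additive log-odds contrasts per
    co-occurring species.  ``alpha`` is the dispersal-kernel scale (km⁻¹).
    """

    predictors: dict = field(default_factory=dict)
    alpha: float = 1.0
    init_occupancy: dict = field(
        default_factory=lambda: {"M": 0.18, "C": 0.35, "P": 0.10}
    )  # C is the fraction of butterfly-occupied patches

    def __post_init__(self):
        for pred in self.predictors.values():
            vals = [pred.beta0, *pred.slopes.values(), pred.sigma2_patch,
                    pred.sigma2_year, *pred.state_effects.values()]
            if not np.all(np.isfinite(vals)):
                raise ValueError("truth parameters must be finite")

    def community_rates(self, n_patches: int, rng: np.random.Generator) -> CommunityRates:
        """Rates with patch random intercepts drawn from N(0, sigma2_patch)."""
        preds = {}
        for key, p in self.predictors.items():
            u = (rng.normal(0.0, np.sqrt(p.sigma2_patch), n_patches)
                 if p.sigma2_patch > 0 else None)
            preds[key] = RatePredictor(
                species=p.species, response=p.response, beta0=p.beta0,
                slopes=dict(p.slopes), sigma2_patch=p.sigma2_patch,
                sigma2_year=p.sigma2_year, u_patch=u,
                state_effects=dict(p.state_effects),
            )
        return CommunityRates(predictors=preds,
                              params=lsc.KernelParams(self.alpha))

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "init_occupancy": self.init_occupancy,
            "predictors": {
                f"{sp}_{resp}": {
                    "beta0": p.beta0, "slopes": p.slopes,
                    "sigma2_patch": p.sigma2_patch, "sigma2_year": p.sigma2_year,
                    "state_effects": p.state_effects,
                }
                for (sp, resp), p in self.predictors.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthParams":
        with open(path) as fh:
            payload = json.load(fh)
        preds = {}
        for key, p in payload["predictors"].items():
            sp, resp = key.split("_", 1)
            preds[(sp, resp)] = RatePredictor(
                species=sp, response=resp, beta0=p["beta0"], slopes=p["slopes"],
                sigma2_patch=p["sigma2_patch"], sigma2_year=p["sigma2_year"],
                state_effects=p["state_effects"],
            )
        return cls(predictors=preds, alpha=payload["alpha"],
                   init_occupancy=payload["init_occupancy"])


def default_truth(interactions: dict | None = None) -> TruthParams:
    """The default ground-truth parameter set.

    Slope magnitudes follow the order of the effects estimated in the real
    system (strong host-plant cover and connectivity effects, moderate
    road and weather effects); intercepts are set so that, on the default
    landscape, colonization events occur in roughly 4–8% and extinctions
    in roughly 40–60% of possible patch-years.  ``interactions`` maps
    (species, response) to {other-species: log-odds contrast} and defaults
    to none (the independent-species null model).
    """
    interactions = interactions or {}

    def pred(sp, resp, beta0, slopes):
        return RatePredictor(
            species=sp, response=resp, beta0=beta0, slopes=slopes,
            sigma2_patch=0.25, sigma2_year=0.09,
            state_effects=dict(interactions.get((sp, resp), {})),
        )

    preds = {
        ("M", "colonization"): pred("M", "colonization", -6.4, {
            "log_cover": 0.6, "vs": 0.3, "conn": 0.012, "road": 0.35,
            "precip_may": 0.5}),
        ("M", "extinction"): pred("M", "extinction", 4.1, {
            "log_cover": -0.6, "vs": -0.3, "conn": -0.012, "road": -0.3,
            "precip_july": -0.5}),
        ("C", "colonization"): pred("C", "colonization", -5.1, {
            "log_cover": 0.25, "vs": 0.55, "conn": 0.02, "road": 0.2,
            "precip_may": 0.3}),
        ("C", "extinction"): pred("C", "extinction", 2.3, {
            "log_cover": -0.35, "vs": -0.4, "conn": -0.02, "road": 0.0}),
        ("P", "colonization"): pred("P", "colonization", -3.3, {
            "log_cover": 0.7, "conn": 0.012, "host_conn": -0.0015, "road": 0.6,
            "precip_august": -0.4}),
        ("P", "extinction"): pred("P", "extinction", 3.1, {
            "log_cover": -0.4, "conn": -0.012, "host_conn": 0.0008, "road": -0.15,
            "precip_july": -0.4}),
    }
    return TruthParams(predictors=preds)


def generate_landscape(
    n_patches: int = 500,
    extent_km: tuple[float, float] = (50.0, 70.0),
    years: range | list[int] | None = None,
    seed=0,
) -> lsc.Landscape:
    """A clustered patch network with areas, yearly cover, scores, roads.

    Patches are scattered around uniformly placed cluster centres (normal
    offsets, sd 0.8 km, clipped to the extent), which creates the
    connectivity contrasts the dispersal kernel responds to.
    """
    if n_patches < 2:
        raise ValueError("need at least 2 patches")
    ex, ey = extent_km
    if ex <= 0 or ey <= 0:
        raise ValueError("extent must be positive")
    years = list(years) if years is not None else list(range(START_YEAR, START_YEAR + 19))
    rng = np.random.default_rng(seed)
    n_clusters = max(3, n_patches // 15)
    centers = rng.uniform([0, 0], [ex, ey], size=(n_clusters, 2))
    assign = rng.integers(0, n_clusters, n_patches)
    xy = centers[assign] + rng.normal(0.0, 0.8, size=(n_patches, 2))
    xy = np.clip(xy, [0, 0], [ex, ey])
    areas = rng.lognormal(np.log(30.0), 1.0, n_patches)
    # zero-inflated log-normal cover: patch base x shared year factor x noise
    base = rng.lognormal(np.log(5.0), 1.0, n_patches)
    year_factor = rng.lognormal(0.0, 0.35, len(years))
    west = xy[:, 0] < ex / 3.0
    p_vs = np.where(west, 0.5, 0.1)
    vs = np.where(rng.random(n_patches) < p_vs, rng.integers(1, 4, n_patches), 0)
    table = pd.DataFrame({
        "patch_id": [f"p{i:04d}" for i in range(n_patches)],
        "x_km": xy[:, 0],
        "y_km": xy[:, 1],
        "area_m2": areas,
        "road": rng.random(n_patches) < 0.3,
        "vs_score": vs,
    })
    table["road"] = table["road"].astype(int)
    for j, year in enumerate(years):
        noise = rng.lognormal(0.0, 0.3, n_patches)
        cover = base * year_factor[j] * noise
        cover[rng.random(n_patches) < 0.08] = 0.0
        table[f"cover_pl_{year}"] = cover
    return lsc.Landscape(table)


def generate_covariates(years: int = 19, seed=0, start_year: int = START_YEAR) -> pd.DataFrame:
    """May–August monthly precipitation (mm), log-normal with a year factor."""
    if years < 2:
        raise ValueError("need at least 2 years")
    rng = np.random.default_rng(seed)
    month_mean = {"may_mm": 46.0, "june_mm": 50.0, "july_mm": 44.0, "august_mm": 70.0}
    year_factor = rng.normal(0.0, 0.25, years)
    out = {"year": list(range(start_year, start_year + years))}
    for col, m in month_mean.items():
        out[col] = np.exp(np.log(m) + year_factor + rng.normal(0.0, 0.35, years))
    return pd.DataFrame(out)


def generate_history(
    landscape: lsc.Landscape,
    precip: pd.DataFrame,
    truth: TruthParams,
    T: int,
    seed=0,
    start_year: int = START_YEAR,
    na_fraction: float = 0.0,
) -> lsc.OccupancyHistory:
    """A T-year occupancy history generated by the ground-truth process.

    Initial occupancy is seeded independently at the truth's initial
    prevalences (parasitoid only within butterfly-occupied patches); the
    remaining T−1 years follow the simulator under ``truth``.  With
    ``na_fraction`` > 0, that fraction of patch-years is marked unsurveyed
    (all three species at once), exercising the missing-data paths.
    """
    if T < 2:
        raise ValueError("need at least 2 years of history")
    rng = np.random.default_rng(seed)
    n = landscape.n_patches
    init = np.zeros((n, 3), dtype=np.int8)
    iM, iC, iP = (lsc.SPECIES.index(s) for s in ("M", "C", "P"))
    init[:, iM] = rng.random(n) < truth.init_occupancy["M"]
    init[:, iC] = (init[:, iM] == 1) & (rng.random(n) < truth.init_occupancy["C"])
    init[:, iP] = rng.random(n) < truth.init_occupancy["P"]
    rates = truth.community_rates(n, rng)
    traj = simulate_trajectory(init, rates, landscape, precip, T - 1,
                               rng.integers(2**31), start_year)
    values = traj.states.transpose(1, 0, 2).astype(float)  # (n, T, 3)
    if values[:, :, iM].sum() == 0 and values[:, :, iP].sum() == 0:
        import warnings
        warnings.warn("ground-truth process went extinct everywhere")
    if na_fraction > 0:
        mask = rng.random((n, T)) < na_fraction
        values[mask] = np.nan
    return lsc.OccupancyHistory(values, traj.years, landscape.patch_ids)


def make_fixture(profile: str, seed=0, outdir=None):
    """Generate a complete input bundle for one named profile.

    Returns (landscape, history, precip, truth); when ``outdir`` is given,
    also writes ``patches.csv``, ``occupancy.csv``, ``precipitation.csv``
    and ``truth.json`` there.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    n_patches, n_years = PROFILES[profile]
    ss = np.random.SeedSequence(seed).spawn(3)
    years = list(range(START_YEAR, START_YEAR + n_years))
    landscape = generate_landscape(n_patches, years=years, seed=ss[0])
    precip = generate_covariates(n_years, seed=ss[1])
    truth = default_truth()
    if profile == "tiny":
        # a 20-patch, 5-year network needs dense initial occupancy so every
        # species has eligible transitions for the smoke-test pipeline
        truth.init_occupancy = {"M": 0.6, "C": 0.5, "P": 0.4}
    history = generate_history(landscape, precip, truth, n_years, seed=ss[2])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lsc.write_patches(landscape, outdir / "patches.csv")
        lsc.write_occupancy(history, outdir / "occupancy.csv")
        lsc.write_precipitation(precip, outdir / "precipitation.csv")
        truth.to_json(outdir / "truth.json")
    return landscape, history, precip, truth
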