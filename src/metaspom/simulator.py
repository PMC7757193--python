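"""Closed-loop metacommunity simulation on the patch network.

Starting from an initial set of patch states, each simulated year:

1. recomputes species-specific connectivity from the previous simulated
   year's occupancy,
2. evaluates colonization and extinction probabilities from the fitted (or
   ground-truth) logit models,
3. draws the new binary states as Bernoulli trials, and
4. enforces the community constraints (a butterfly extinction removes the
   parasitoid; a butterfly colonization admits the parasitoid with its own
   estimated colonization probability).

States are propagated as 0/1 occupancy (not probabilities), so the yearly
connectivity recomputation always sees binary occupancy.  Year random
effects for simulated years are drawn fresh from N(0, sigma2_year) per
replicate; patch effects are held at their conditional modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from metaspom import landscape as lsc
from metaspom.occmodels import FitResult, precip_covariates

__all__ = [
    "RatePredictor",
    "CommunityRates",
    "Trajectory",
    "SimEnsemble",
    "constant_rates",
    "community_step",
    "simulate_trajectory",
    "simulate_ensemble",
    "state_distribution",
]

RESPONSES = ("colonization", "extinction")


@dataclass
class RatePredictor:
    """Logit-linear rate model for one species and response.

    ``slopes`` are keyed by covariate name (``log_cover``, ``vs``,
    ``conn``, ``host_conn``, ``road``, ``precip_<month>``); missing keys
    simply do not contribute.  ``state_effects`` add log-odds per
    co-occurring species present in the previous year (keyed by species
    code), which is how ground-truth interaction contrasts enter.
    ``u_patch`` (aligned with the landscape patch order) holds patch-level
    random intercepts; year effects are supplied at evaluation time.
    """

    species: str
    response: str
    beta0: float
    slopes: dict[str, float] = field(default_factory=dict)
    sigma2_patch: float = 0.0
    sigma2_year: float = 0.0
    u_patch: np.ndarray | None = None
    state_effects: dict[str, float] = field(default_factory=dict)

    def linpred(self, covariates: pd.DataFrame, prev_states: np.ndarray | None = None,
                year_effect: float = 0.0) -> np.ndarray:
        eta = np.full(len(covariates), self.beta0 + year_effect)
        for term, slope in self.slopes.items():
            eta += slope * covariates[term].to_numpy(float)
        if self.u_patch is not None:
            eta += self.u_patch
        if self.state_effects and prev_states is not None:
            for sp, effect in self.state_effects.items():
                eta += effect * prev_states[:, lsc.SPECIES.index(sp)]
        return eta

    def rate(self, covariates: pd.DataFrame, prev_states: np.ndarray | None = None,
             year_effect: float = 0.0) -> np.ndarray:
        return special.expit(self.linpred(covariates, prev_states, year_effect))

    @classmethod
    def from_fit(cls, fit: FitResult, landscape: lsc.Landscape) -> "RatePredictor":
        """Predictor using a fit's point estimates, patch modes aligned to
        the landscape (unseen patches get 0)."""
        beta = fit.beta
        slopes = {k: float(v) for k, v in beta.items()
                  if k != "intercept" and not k.startswith("state_")}
        u = fit.u_patch.reindex(landscape.patch_ids).fillna(0.0).to_numpy()
        return cls(
            species=fit.spec.species,
            response=fit.spec.response,
            beta0=float(beta["intercept"]),
            slopes=slopes,
            sigma2_patch=fit.sigma2_patch,
            sigma2_year=fit.sigma2_year,
            u_patch=u,
            state_effects={},
        )


@dataclass
class CommunityRates:
    """The six rate models (3 species × colonization/extinction) plus the
    dispersal kernel they assume."""

    predictors: dict[tuple[str, str], RatePredictor]
    params: lsc.KernelParams = lsc.KernelParams()

    def __post_init__(self):
        for sp in lsc.SPECIES:
            for resp in RESPONSES:
                if (sp, resp) not in self.predictors:
                    raise ValueError(f"missing rate model for {(sp, resp)}")

    @classmethod
    def from_fits(cls, fits: dict[tuple[str, str], FitResult],
                  landscape: lsc.Landscape,
                  params: lsc.KernelParams = lsc.KernelParams()) -> "CommunityRates":
        preds = {key: RatePredictor.from_fit(fit, landscape)
                 for key, fit in fits.items()}
        return cls(predictors=preds, params=params)


def constant_rates(c: float, e: float,
                   params: lsc.KernelParams = lsc.KernelParams()) -> CommunityRates:
    """Spatially decoupled dynamics with the same constant rates for every
    species and patch; useful as a two-state Markov-chain reference."""
    preds = {}
    for sp in lsc.SPECIES:
        preds[(sp, "colonization")] = RatePredictor(sp, "colonization", special.logit(c))
        preds[(sp, "extinction")] = RatePredictor(sp, "extinction", special.logit(e))
    return CommunityRates(predictors=preds, params=params)


def covariate_frame(
    landscape: lsc.Landscape,
    year: int,
    conn: np.ndarray,
    host_conn: np.ndarray | None,
    precip_row: pd.Series,
) -> pd.DataFrame:
    """Named covariate columns for one species and one target year."""
    frame = pd.DataFrame({
        "log_cover": np.log1p(landscape.cover(year)),
        "vs": landscape.vs_score,
        "conn": conn,
        "road": landscape.road,
    })
    if host_conn is not None:
        frame["host_conn"] = host_conn
    for term in ("precip_may", "precip_june", "precip_july", "precip_august"):
        frame[term] = float(precip_row[term])
    return frame


def community_step(
    prev: np.ndarray,
    rates: dict[tuple[str, str], np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """One constrained Bernoulli update of all patch states.

    ``prev`` is the (n, 3) previous-year state matrix in species order
    (M, C, P); ``rates`` maps (species, response) to per-patch
    probabilities.  The butterfly and mildew update independently; the
    parasitoid then follows its host: it dies with a butterfly extinction,
    enters jointly with a butterfly colonization with its estimated
    colonization probability, and otherwise persists/colonizes within the
    occupied host patch.
    """
    n = prev.shape[0]
    new = np.zeros_like(prev)
    iM, iC, iP = (lsc.SPECIES.index(s) for s in ("M", "C", "P"))
    for sp, idx in (("M", iM), ("P", iP)):
        u = rng.random(n)
        was = prev[:, idx] == 1
        new[:, idx] = np.where(was, u >= rates[(sp, "extinction")],
                               u < rates[(sp, "colonization")])
    uC = rng.random(n)
    host_now = new[:, iM] == 1
    had_c = prev[:, iC] == 1
    survive = had_c & host_now & (uC >= rates[("C", "extinction")])
    colonize = ~had_c & host_now & (uC < rates[("C", "colonization")])
    new[:, iC] = (survive | colonize).astype(prev.dtype)
    return new


@dataclass
class Trajectory:
    """One simulated time series of patch states.

    ``states`` has shape (T+1, n_patches, 3); year 0 is the supplied
    initial condition.  ``connectivity_log`` records the per-species
    connectivity used for each yearly transition.
    """

    states: np.ndarray
    years: list[int]
    connectivity_log: np.ndarray  # (T, n, 3), transition into years[1:]

    def occupied_fraction(self, species: str) -> np.ndarray:
        k = lsc.SPECIES.index(species)
        return self.states[:, :, k].mean(axis=1)


@dataclass
class SimEnsemble:
    """Replicate simulations with per-year summary quantiles."""

    trajectories: list[Trajectory]
    summaries: pd.DataFrame  # year, metric, median, lo95, hi95

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)


def _year_effects(rates: CommunityRates, rng: np.random.Generator) -> dict:
    return {
        key: rng.normal(0.0, np.sqrt(pred.sigma2_year)) if pred.sigma2_year > 0 else 0.0
        for key, pred in rates.predictors.items()
    }


def simulate_trajectory(
    initial: np.ndarray,
    rates: CommunityRates,
    landscape: lsc.Landscape,
    precip: pd.DataFrame,
    T: int,
    seed,
    start_year: int,
) -> Trajectory:
    """Simulate ``T`` years of metacommunity dynamics from ``initial``.

    ``initial`` is the (n, 3) state matrix for ``start_year``; covariates
    (host-plant cover, precipitation) must be available for every simulated
    calendar year — missing years raise rather than extrapolate.  The seed
    fully determines the trajectory.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    initial = np.asarray(initial)
    n = landscape.n_patches
    if initial.shape != (n, 3):
        raise ValueError(f"initial states must have shape ({n}, 3)")
    iM, iC = lsc.SPECIES.index("M"), lsc.SPECIES.index("C")
    if np.any((initial[:, iC] == 1) & (initial[:, iM] == 0)):
        raise lsc.InvalidStateError("initial states violate the host constraint")
    # rate models without covariate slopes (e.g. constant-rate references)
    # need no cover or weather tables
    needs_cov = any(p.slopes for p in rates.predictors.values())
    years = [start_year + k for k in range(T + 1)]
    if needs_cov:
        precip_cov = precip_covariates(precip)
        for year in years[1:]:
            if year not in precip_cov.index:
                raise ValueError(f"no precipitation covariates for simulated year {year}")
            if f"cover_pl_{year}" not in landscape.table.columns:
                raise ValueError(f"no host-plant cover for simulated year {year}")
    rng = np.random.default_rng(seed)
    host_conn = (lsc.compute_host_connectivity(landscape, rates.params)
                 if needs_cov else None)
    states = np.zeros((T + 1, n, 3), dtype=np.int8)
    states[0] = initial
    conn_log = np.zeros((T, n, 3))
    for t, year in enumerate(years[1:], start=1):
        prev = states[t - 1]
        year_eff = _year_effects(rates, rng)
        rate_arrays = {}
        for k, sp in enumerate(lsc.SPECIES):
            conn = lsc.connectivity_from_occupancy(prev[:, k].astype(float),
                                                   landscape, rates.params)
            conn_log[t - 1, :, k] = conn
            if needs_cov:
                frame = covariate_frame(landscape, year, conn,
                                        host_conn if sp == "P" else None,
                                        precip_cov.loc[year])
            else:
                frame = pd.DataFrame(index=np.arange(n))
            for resp in RESPONSES:
                pred = rates.predictors[(sp, resp)]
                rate_arrays[(sp, resp)] = pred.rate(frame, prev_states=prev,
                                                    year_effect=year_eff[(sp, resp)])
        states[t] = community_step(prev, rate_arrays, rng)
    return Trajectory(states=states, years=years, connectivity_log=conn_log)


def simulate_ensemble(
    initial: np.ndarray,
    rates: CommunityRates,
    landscape: lsc.Landscape,
    precip: pd.DataFrame,
    T: int,
    R: int,
    seed,
    start_year: int,
) -> SimEnsemble:
    """R independent replicate trajectories with per-year summaries.

    Replicate seeds are spawned deterministically from the master seed.
    Summaries report the 2.5/50/97.5 percentiles across replicates of the
    per-species occupied fraction and of the count of patches in each of
    the six community states.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(R)
    trajectories = [
        simulate_trajectory(initial, rates, landscape, precip, T, s, start_year)
        for s in seeds
    ]
    years = trajectories[0].years
    records = []
    occ = np.stack([
        [traj.occupied_fraction(sp) for sp in lsc.SPECIES] for traj in trajectories
    ])  # (R, 3, T+1)
    counts = np.stack([
        state_distribution(traj).to_numpy() for traj in trajectories
    ])  # (R, T+1, 6)
    for ti, year in enumerate(years):
        for k, sp in enumerate(lsc.SPECIES):
            lo, med, hi = np.percentile(occ[:, k, ti], [2.5, 50, 97.5])
            records.append({"year": year, "metric": f"occ_{sp}",
                            "median": med, "lo95": lo, "hi95": hi})
        for k, label in enumerate(lsc.STATE_LABELS):
            lo, med, hi = np.percentile(counts[:, ti, k], [2.5, 50, 97.5])
            records.append({"year": year, "metric": f"state_{label}",
                            "median": med, "lo95": lo, "hi95": hi})
    return SimEnsemble(trajectories=trajectories, summaries=pd.DataFrame(records))


def state_distribution(traj_or_states) -> pd.DataFrame:
    """Per-year counts of patches in each of the six community states.

    Accepts a :class:`Trajectory` or a (T, n, 3) state array; returns a
    DataFrame indexed by year (or step) with one column per state label.
    Counts sum to the number of patches in every row.
    """
    if isinstance(traj_or_states, Trajectory):
        states = traj_or_states.states
        index = traj_or_states.years
    else:
        states = np.asarray(traj_or_states)
        index = list(range(states.shape[0]))
    iM, iC, iP = (lsc.SPECIES.index(s) for s in ("M", "C", "P"))
    m, c, p = states[:, :, iM], states[:, :, iC], states[:, :, iP]
    if np.any((c == 1) & (m == 0)):
        raise lsc.InvalidStateError("parasitoid present without host in states")
    code = m * 4 + c * 2 + p  # valid codes: 0,1,4,5,6,7
    label_by_code = {0: "0", 1: "P", 4: "M", 5: "MP", 6: "MC", 7: "MCP"}
    out = {}
    for lab in lsc.STATE_LABELS:
        want = [k for k, v in label_by_code.items() if v == lab][0]
        out[lab] = (code == want).sum(axis=1)
    df = pd.DataFrame(out, index=index)[list(lsc.STATE_LABELS)]
    return df
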