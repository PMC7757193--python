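"""Colonization/extinction models with crossed patch and year random effects.

Each yearly transition of one species in one patch is a Bernoulli trial:
colonization (conditional on absence in the previous year) or extinction
(conditional on presence).  Rates are modelled on the logit scale with
environmental covariates as fixed effects and patch and year as crossed
random intercepts:

    logit c_it = b0 + sum_j b_j x_ijt + gamma_year[t] + gamma_patch[i]

Covariates (by species): log host-plant cover, the ordinal *V. spicata*
score, species-specific connectivity, host-plant connectivity (mildew
only), the road-border flag, and log monthly precipitation (May–August,
entering via AIC-based subset selection over all 2^4 candidate models).
A patch-state factor (the co-occurrence state in the previous year) can be
added as a fixed effect to test whether interacting species shift the
rates; support is screened by the AIC difference against the base model.

Covariate transforms: cover enters as log(cover + 1) (m²), precipitation
as log(mm); the *V. spicata* score and the road flag enter untransformed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from metaspom import landscape as lsc
from metaspom._glmm import FitError, GLMMResult, fit_glmm, fit_logistic_newton

__all__ = [
    "ModelSpec",
    "FitResult",
    "FitSummary",
    "FitError",
    "build_transition_table",
    "fit_occupancy_glmm",
    "fit_state_model",
    "select_weather_model",
    "r2_nakagawa",
    "fixed_effect_variance_share",
    "state_rates",
    "delta_aic",
    "default_spec",
    "state_levels_for",
]

PRECIP_TERMS = ("precip_may", "precip_june", "precip_july", "precip_august")
_PRECIP_SOURCE = {
    "precip_may": "may_mm",
    "precip_june": "june_mm",
    "precip_july": "july_mm",
    "precip_august": "august_mm",
}

#: Environmental covariates per species (before weather selection).
BASE_TERMS: dict[str, tuple[str, ...]] = {
    "M": ("log_cover", "vs", "conn", "road"),
    "C": ("log_cover", "vs", "conn", "road"),
    "P": ("log_cover", "conn", "host_conn", "road"),
}

#: Patch states (previous year) compatible with each response: a species
#: can only colonize states where it is absent and only go extinct from
#: states where it is present; parasitoid colonization additionally covers
#: joint host-parasitoid arrivals into host-free states.
_STATE_LEVELS: dict[tuple[str, str], tuple[str, ...]] = {
    ("M", "colonization"): ("0", "P"),
    ("M", "extinction"): ("M", "MC", "MCP", "MP"),
    ("C", "colonization"): ("0", "M", "MP", "P"),
    ("C", "extinction"): ("MC", "MCP"),
    ("P", "colonization"): ("0", "M", "MC"),
    ("P", "extinction"): ("MCP", "MP", "P"),
}


def state_levels_for(species: str, response: str) -> tuple[str, ...]:
    """Patch-state factor levels compatible with one species/response."""
    try:
        return _STATE_LEVELS[(species, response)]
    except KeyError:
        raise ValueError(f"unknown species/response {(species, response)}") from None


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one colonization or extinction model."""

    response: str  # "colonization" | "extinction"
    species: str  # "M" | "C" | "P"
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...] = ("patch", "year")
    state_levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.response not in ("colonization", "extinction"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.species not in lsc.SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.species == "P" and "vs" in self.fixed_terms:
            raise ValueError("the mildew model does not include the V. spicata term")
        if self.species != "P" and "host_conn" in self.fixed_terms:
            raise ValueError("host connectivity applies only to the mildew")
        if self.state_levels is not None:
            allowed = set(state_levels_for(self.species, self.response))
            if not set(self.state_levels) <= allowed:
                raise ValueError(
                    f"state levels {self.state_levels} incompatible with "
                    f"{self.species} {self.response}; allowed {sorted(allowed)}"
                )

    def with_state(self) -> "ModelSpec":
        """The same model plus the compatible patch-state factor."""
        return replace(self, state_levels=state_levels_for(self.species, self.response))


def default_spec(species: str, response: str,
                 precip: tuple[str, ...] = ()) -> ModelSpec:
    """Base environmental model for one species and response."""
    return ModelSpec(
        response=response,
        species=species,
        fixed_terms=BASE_TERMS[species] + tuple(precip),
    )


@dataclass
class FitResult:
    """One fitted colonization or extinction model.

    ``beta`` holds the intercept and slopes by term name, ``vcov`` their
    sampling covariance, ``sigma2_patch``/``sigma2_year`` the random-effect
    variances, and ``u_patch``/``u_year`` the conditional modes of the
    random intercepts keyed by level.  ``covariate_means`` are the means of
    the environmental covariate columns over the fitted rows, used when
    holding covariates constant in rate tables.
    """

    spec: ModelSpec
    beta: pd.Series
    vcov: pd.DataFrame
    sigma2_patch: float
    sigma2_year: float
    u_patch: pd.Series
    u_year: pd.Series
    loglik: float
    aic: float
    n: int
    converged: bool
    covariate_means: pd.Series
    design: pd.DataFrame | None = None
    ridge: float = 0.0
    row_index: pd.Index | None = None
    state_levels_used: tuple[str, ...] | None = None

    @property
    def terms(self) -> list[str]:
        return [t for t in self.beta.index if t != "intercept"]

    def to_json_dict(self) -> dict:
        return {
            "species": self.spec.species,
            "response": self.spec.response,
            "fixed_terms": list(self.spec.fixed_terms),
            "state_levels": list(self.spec.state_levels) if self.spec.state_levels else None,
            "beta": self.beta.to_dict(),
            "vcov": {"columns": list(self.vcov.columns),
                     "values": self.vcov.to_numpy().tolist()},
            "sigma2_patch": self.sigma2_patch,
            "sigma2_year": self.sigma2_year,
            "u_patch": {str(k): float(v) for k, v in self.u_patch.items()},
            "u_year": {str(k): float(v) for k, v in self.u_year.items()},
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
            "covariate_means": self.covariate_means.to_dict(),
        }


@dataclass
class FitSummary:
    """Variance-explained summary of one fit."""

    r2_marginal: float
    r2_conditional: float
    var_share: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def save_fits(fits: dict, path) -> None:
    """Serialise a {(species, response): FitResult} mapping to JSON."""
    payload = {f"{sp}_{resp}": fit.to_json_dict() for (sp, resp), fit in fits.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_fits(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    fits = {}
    for fit in payload.values():
        spec = ModelSpec(
            response=fit["response"],
            species=fit["species"],
            fixed_terms=tuple(fit["fixed_terms"]),
            state_levels=tuple(fit["state_levels"]) if fit["state_levels"] else None,
        )
        beta = pd.Series(fit["beta"])
        vcov = pd.DataFrame(
            np.asarray(fit["vcov"]["values"]),
            index=fit["vcov"]["columns"],
            columns=fit["vcov"]["columns"],
        )
        fits[(spec.species, spec.response)] = FitResult(
            spec=spec,
            beta=beta,
            vcov=vcov,
            sigma2_patch=fit["sigma2_patch"],
            sigma2_year=fit["sigma2_year"],
            u_patch=pd.Series(fit["u_patch"], dtype=float),
            u_year=pd.Series({int(k): v for k, v in fit["u_year"].items()}, dtype=float),
            loglik=fit["loglik"],
            aic=fit["aic"],
            n=fit["n"],
            converged=fit["converged"],
            covariate_means=pd.Series(fit["covariate_means"], dtype=float),
        )
    return fits


# ---------------------------------------------------------------------------
# Transition-table assembly
# ---------------------------------------------------------------------------

def precip_covariates(precip: pd.DataFrame) -> pd.DataFrame:
    """Log-transform the monthly totals; indexed by year."""
    out = pd.DataFrame({"year": precip["year"].astype(int)})
    for term, col in _PRECIP_SOURCE.items():
        out[term] = np.log(precip[col].to_numpy(float))
    return out.set_index("year")


def build_transition_table(
    history: lsc.OccupancyHistory,
    landscape: lsc.Landscape,
    precip: pd.DataFrame,
    species: str,
    response: str,
    params: lsc.KernelParams = lsc.KernelParams(),
) -> pd.DataFrame:
    """Assemble the per-transition modelling table for one species/response.

    One row per eligible patch-year transition (t−1 → t): ``outcome`` is 1
    when the event (colonization or extinction) happened, with the
    covariates evaluated in the transition's target year t (connectivity by
    definition uses occupancy at t−1).  ``state_prev`` is the patch state
    at t−1 (NA when any species was unsurveyed then).  Transitions with a
    missing focal-species survey at either end are excluded.

    For the parasitoid, colonization rows comprise host-occupied patches
    plus joint host–parasitoid arrivals, mirroring how possible events are
    counted.
    """
    sidx = history.species_index(species)
    vals = history.values[:, :, sidx]
    precip_cov = precip_covariates(precip)
    host = history.values[:, :, history.species_index("M")]
    sPL = lsc.compute_host_connectivity(landscape, params) if species == "P" else None

    rows = []
    for t in range(1, len(history.years)):
        year = history.years[t]
        if year not in precip_cov.index:
            raise ValueError(f"precipitation table does not cover year {year}")
        prev, cur = vals[:, t - 1], vals[:, t]
        ok = ~np.isnan(prev) & ~np.isnan(cur)
        if response == "colonization":
            if species == "C":
                hprev, hcur = host[:, t - 1], host[:, t]
                hok = ~np.isnan(hprev) & ~np.isnan(hcur)
                eligible = ok & hok & (prev == 0) & ((hprev == 1) | (hcur == 1))
            else:
                eligible = ok & (prev == 0)
            outcome = cur
        else:
            eligible = ok & (prev == 1)
            outcome = 1.0 - cur
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            continue
        conn = lsc.compute_connectivity(history, landscape, params, species, year)
        cover = landscape.cover(year)
        pr = precip_cov.loc[year]
        state_prev = np.array([
            _state_label_or_na(history.values[i, t - 1, :]) for i in idx
        ], dtype=object)
        block = pd.DataFrame({
            "patch_id": history.patch_ids[idx],
            "year": year,
            "outcome": outcome[idx].astype(int),
            "log_cover": np.log1p(cover[idx]),
            "vs": landscape.vs_score[idx],
            "conn": conn[idx],
            "road": landscape.road[idx],
            "state_prev": state_prev,
        })
        if sPL is not None:
            block["host_conn"] = sPL[idx]
        for term in PRECIP_TERMS:
            block[term] = pr[term]
        rows.append(block)
    if not rows:
        raise ValueError("no eligible transitions found")
    return pd.concat(rows, ignore_index=True)


def _state_label_or_na(flags: np.ndarray):
    if np.isnan(flags).any():
        return np.nan
    return lsc.encode_patch_state(*flags.astype(int)).label


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _design_matrix(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[str, ...] | None]:
    """Build the fixed-effect design; returns (X, filtered data, state levels)."""
    cols = list(spec.fixed_terms)
    data = data.dropna(subset=cols + ["outcome"]).copy()
    present = None
    if spec.state_levels is not None:
        data = data.dropna(subset=["state_prev"])
        data = data[data["state_prev"].isin(spec.state_levels)]
        present = tuple(lv for lv in spec.state_levels if (data["state_prev"] == lv).any())
        dropped = set(spec.state_levels) - set(present)
        if dropped:
            warnings.warn(f"patch-state level(s) {sorted(dropped)} absent from the "
                          "data; dropped from the factor")
    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for c in cols:
        X[c] = data[c].to_numpy(float)
    if present is not None and len(present) > 1:
        for lv in present[1:]:  # first observed level is the reference
            X[f"state_{lv}"] = (data["state_prev"] == lv).astype(float).to_numpy()
    return X, data, present


def fit_occupancy_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    fix_sigma2_patch: float | None = None,
    fix_sigma2_year: float | None = None,
    keep_design: bool = True,
) -> FitResult:
    """Fit one colonization/extinction GLMM by Laplace maximum likelihood.

    ``data`` is a transition table from :func:`build_transition_table`
    (columns ``outcome``, ``patch_id``, ``year`` and the covariates named
    in the spec).  Variance components may be fixed (0 removes the factor,
    yielding an exact logistic fit).  Fitting is deterministic.
    """
    X, data, state_present = _design_matrix(spec, data)
    y = data["outcome"].to_numpy(float)
    patch_cat = pd.Categorical(data["patch_id"])
    year_cat = pd.Categorical(data["year"])
    if fix_sigma2_patch is None and len(patch_cat.categories) < 2:
        raise ValueError("need >= 2 patch levels to estimate the patch variance")
    if fix_sigma2_year is None and len(year_cat.categories) < 2:
        raise ValueError("need >= 2 year levels to estimate the year variance")
    res: GLMMResult = fit_glmm(
        y,
        X.to_numpy(float),
        patch_cat.codes.astype(int),
        year_cat.codes.astype(int),
        len(patch_cat.categories),
        len(year_cat.categories),
        fix_sigma2_patch=fix_sigma2_patch,
        fix_sigma2_year=fix_sigma2_year,
    )
    env_terms = [t for t in spec.fixed_terms]
    return FitResult(
        spec=spec,
        beta=pd.Series(res.beta, index=X.columns),
        vcov=pd.DataFrame(res.vcov, index=X.columns, columns=X.columns),
        sigma2_patch=res.sigma2_patch,
        sigma2_year=res.sigma2_year,
        u_patch=pd.Series(res.u_patch, index=patch_cat.categories),
        u_year=pd.Series(res.u_year, index=year_cat.categories),
        loglik=res.loglik,
        aic=res.aic,
        n=res.n,
        converged=res.converged,
        covariate_means=data[env_terms].mean(),
        design=X if keep_design else None,
        ridge=res.ridge,
        row_index=data.index,
        state_levels_used=state_present,
    )


def fit_state_model(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> FitResult:
    """Fit the model including the previous-year patch-state factor.

    Rows are restricted to the response-compatible states; the
    environmental covariates of the base spec are retained.
    """
    if spec.state_levels is None:
        spec = spec.with_state()
    return fit_occupancy_glmm(spec, data, **kwargs)


def select_weather_model(
    spec_base: ModelSpec,
    data: pd.DataFrame,
    precip_terms: tuple[str, ...] = PRECIP_TERMS,
    **kwargs,
) -> tuple[pd.DataFrame, FitResult]:
    """AIC selection over all subsets of the monthly precipitation terms.

    Fits the base covariates plus every subset of ``precip_terms`` (2^m
    candidates), ranks by AIC ascending with ties broken by fewer
    parameters and then by subset enumeration order, and returns the
    ranking table together with the winning fit.  A failing candidate is
    flagged and excluded from the ranking with a warning.
    """
    candidates = []
    for r in range(len(precip_terms) + 1):
        candidates.extend(itertools.combinations(precip_terms, r))
    records = []
    fits = {}
    for order, subset in enumerate(candidates):
        spec = replace(spec_base, fixed_terms=tuple(spec_base.fixed_terms) + subset)
        try:
            fit = fit_occupancy_glmm(spec, data, keep_design=False, **kwargs)
            records.append({
                "subset": "+".join(subset) if subset else "(none)",
                "n_precip": len(subset),
                "aic": fit.aic,
                "loglik": fit.loglik,
                "n_params": len(fit.beta) + 2,
                "order": order,
                "failed": False,
            })
            fits[order] = fit
        except (FitError, ValueError) as err:
            warnings.warn(f"candidate {subset} failed to fit: {err}")
            records.append({
                "subset": "+".join(subset) if subset else "(none)",
                "n_precip": len(subset), "aic": np.nan, "loglik": np.nan,
                "n_params": np.nan, "order": order, "failed": True,
            })
    table = pd.DataFrame(records)
    ok = table[~table["failed"]]
    if ok.empty:
        raise FitError("every weather candidate model failed to fit")
    ranked = ok.sort_values(["aic", "n_params", "order"], kind="stable")
    table = pd.concat([ranked, table[table["failed"]]], ignore_index=True)
    winner = fits[int(ranked.iloc[0]["order"])]
    # refit the winner keeping its design matrix for downstream summaries
    winner = fit_occupancy_glmm(winner.spec, data, **kwargs)
    return table, winner


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def r2_nakagawa(fit: FitResult, design: pd.DataFrame | None = None) -> FitSummary:
    """Marginal and conditional r² on the logit link scale.

    The fixed-effect variance is the variance of the linear predictor over
    the fitted observations; the residual variance of the logit link is
    π²/3.  r²_M is the fixed-effect share of the total; r²_C adds the
    patch and year variance components to the numerator.
    """
    X = design if design is not None else fit.design
    if X is None:
        raise ValueError("no design matrix available; pass `design`")
    eta = X.to_numpy(float) @ fit.beta.to_numpy()
    sigma_f2 = float(np.var(eta))
    if sigma_f2 == 0.0:
        warnings.warn("fixed-effect predictor has zero variance; r2_marginal = 0")
    denom = sigma_f2 + fit.sigma2_patch + fit.sigma2_year + np.pi**2 / 3.0
    return FitSummary(
        r2_marginal=sigma_f2 / denom,
        r2_conditional=(sigma_f2 + fit.sigma2_patch + fit.sigma2_year) / denom,
    )


def fixed_effect_variance_share(fit: FitResult, design: pd.DataFrame | None = None) -> pd.Series:
    """Per-covariate share (%) of the explained fixed-effect variation.

    Each slope contributes beta_j² · Var(x_j); shares are those
    contributions normalised by their sum (covariances between terms are
    not apportioned).
    """
    X = design if design is not None else fit.design
    if X is None:
        raise ValueError("no design matrix available; pass `design`")
    terms = [c for c in X.columns if c != "intercept"]
    if not terms:
        raise ValueError("model has no slopes")
    contrib = pd.Series({
        t: fit.beta[t] ** 2 * float(np.var(X[t].to_numpy(float))) for t in terms
    })
    total = contrib.sum()
    if total == 0:
        raise ValueError("all fixed-effect variance contributions are zero")
    return 100.0 * contrib / total


def state_rates(fit: FitResult, covariate_means: pd.Series | None = None,
                level: float = 0.95) -> pd.DataFrame:
    """Per-state rates (%) with confidence intervals from a state-model fit.

    The linear predictor is evaluated for each patch-state level while
    holding every environmental covariate at its mean over the fitted
    rows; a normal interval on the logit scale is inverse-logit
    transformed, so the bounds always bracket the point estimate.
    """
    if fit.spec.state_levels is None:
        raise ValueError("fit does not include a patch-state factor")
    means = covariate_means if covariate_means is not None else fit.covariate_means
    z = stats.norm.ppf(0.5 + level / 2.0)
    names = list(fit.beta.index)
    V = fit.vcov.to_numpy()
    levels = (fit.state_levels_used if fit.state_levels_used is not None
              else fit.spec.state_levels)
    rows = {}
    for lv in levels:
        a = np.zeros(len(names))
        for j, name in enumerate(names):
            if name == "intercept":
                a[j] = 1.0
            elif name.startswith("state_"):
                a[j] = 1.0 if name == f"state_{lv}" else 0.0
            else:
                a[j] = means[name]
        eta = float(a @ fit.beta.to_numpy())
        se = float(np.sqrt(a @ V @ a))
        rows[lv] = {
            "rate": 100.0 * special.expit(eta),
            "lo": 100.0 * special.expit(eta - z * se),
            "hi": 100.0 * special.expit(eta + z * se),
        }
    return pd.DataFrame(rows).T[["rate", "lo", "hi"]]


def delta_aic(full: FitResult, reduced: FitResult) -> float:
    """AIC(full) − AIC(reduced); negative values support the full model.

    Both models must have been fitted to the identical transition rows.
    """
    if full.n != reduced.n:
        raise ValueError(
            f"models fitted to different row counts ({full.n} vs {reduced.n}); "
            "the AIC comparison requires identical data"
        )
    return full.aic - reduced.aic


def plain_logistic_oracle(spec: ModelSpec, data: pd.DataFrame) -> tuple[pd.Series, float]:
    """Independent Newton–Raphson logistic fit on the same design (no random
    effects); used as a cross-check of the mixed model's zero-variance limit."""
    X, data, _ = _design_matrix(spec, data)
    beta, ll = fit_logistic_newton(data["outcome"].to_numpy(float), X.to_numpy(float))
    return pd.Series(beta, index=X.columns), ll
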