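"""One-step-ahead occupancy forecasts with parametric-bootstrap intervals.

For each yearly transition the predicted occurrence probability of species
Y in patch i is

    p_it = o_{t-1} (1 - e_it) + (1 - o_{t-1}) c_it,

with o_{t-1} the *observed* previous-year occupancy and c, e the fitted
colonization/extinction rates.  Parameter uncertainty is propagated by
resampling the fixed effects from their multivariate-normal sampling
distribution (default 1,000 draws); observation uncertainty by one
Bernoulli realisation of every patch-year per draw.  Community-level
draws respect the host-dependence constraint via the same constrained
update as the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from metaspom import landscape as lsc
from metaspom.occmodels import FitResult, precip_covariates
from metaspom.simulator import RatePredictor, community_step, covariate_frame

__all__ = [
    "ForecastEnsemble",
    "one_step_probability",
    "bootstrap_predictions",
    "assemble_community",
    "summarize_forecast",
]

_NA = np.int8(-1)  # sentinel for undefined draws (unobserved predecessor)


def one_step_probability(o_prev, c, e):
    """p = o_prev (1 - e) + (1 - o_prev) c, elementwise.

    ``o_prev`` may contain NaN (unsurveyed), which propagates to the
    result; rates outside [0, 1] raise.
    """
    c = np.asarray(c, float)
    e = np.asarray(e, float)
    for name, r in (("colonization", c), ("extinction", e)):
        if np.any((r < 0) | (r > 1)):
            raise ValueError(f"{name} rate outside [0, 1]")
    o = np.asarray(o_prev, float)
    return o * (1.0 - e) + (1.0 - o) * c


def _nearest_psd(v: np.ndarray) -> np.ndarray:
    w, q = np.linalg.eigh(0.5 * (v + v.T))
    if w.min() >= 0:
        return v
    warnings.warn("non-positive-semidefinite covariance; clipping negative "
                  "eigenvalues to zero")
    return (q * np.clip(w, 0.0, None)) @ q.T


@dataclass
class ForecastEnsemble:
    """Bootstrap draws of one-step-ahead patch states.

    ``draws`` has shape (B, n_patches, n_transition_years, 3) with entries
    0/1 and −1 where the previous-year state was unobserved.  Every draw
    satisfies the host-dependence constraint.
    """

    draws: np.ndarray
    years: list[int]  # transition target years
    patch_ids: np.ndarray

    @property
    def B(self) -> int:
        return self.draws.shape[0]

    def occupied_fraction(self, species: str) -> np.ndarray:
        """(B, n_years) fraction of (observed) patches occupied."""
        k = lsc.SPECIES.index(species)
        d = self.draws[:, :, :, k].astype(float)
        d[d < 0] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=1)


def _sample_betas(fit: FitResult, B: int, rng: np.random.Generator) -> np.ndarray:
    """(B, p) fixed-effect draws from N(beta_hat, vcov)."""
    v = _nearest_psd(fit.vcov.to_numpy())
    return rng.multivariate_normal(fit.beta.to_numpy(), v, size=B,
                                   method="eigh")


def bootstrap_predictions(
    fits: dict[tuple[str, str], FitResult],
    history: lsc.OccupancyHistory,
    landscape: lsc.Landscape,
    precip: pd.DataFrame,
    B: int = 1000,
    seed=0,
    params: lsc.KernelParams = lsc.KernelParams(),
) -> ForecastEnsemble:
    """Parametric-bootstrap one-step forecasts for every observed transition.

    Per draw, the fixed effects of all six models are resampled from their
    sampling distributions; random-effect modes are held at their
    estimates.  Rates are recomputed per patch-year, occupancy is drawn
    Bernoulli(p), and community constraints are applied.  The seed fully
    determines the output.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    precip_cov = precip_covariates(precip)
    n = landscape.n_patches
    years = history.years[1:]

    betas = {key: _sample_betas(fit, B, rng) for key, fit in fits.items()}
    preds = {key: RatePredictor.from_fit(fit, landscape) for key, fit in fits.items()}
    host_conn = lsc.compute_host_connectivity(landscape, params)

    draws = np.full((B, n, len(years), 3), _NA, dtype=np.int8)
    for ti, year in enumerate(years):
        prev = np.stack(
            [history.occupancy(sp, year - 1) for sp in lsc.SPECIES], axis=1
        )  # (n, 3) float with NaN
        prev_bin = np.nan_to_num(prev, nan=0.0).astype(np.int8)
        observed = ~np.isnan(prev).any(axis=1)
        # per-model design rows for this transition year
        etas = {}
        for k, sp in enumerate(lsc.SPECIES):
            conn = lsc.compute_connectivity(history, landscape, params, sp, year)
            frame = covariate_frame(landscape, year, conn,
                                    host_conn if sp == "P" else None,
                                    precip_cov.loc[year])
            for resp in ("colonization", "extinction"):
                fit = fits[(sp, resp)]
                pred = preds[(sp, resp)]
                cols = [c for c in fit.beta.index
                        if c != "intercept" and not c.startswith("state_")]
                Xrow = np.column_stack(
                    [np.ones(n)] + [frame[c].to_numpy(float) for c in cols]
                )
                keep = [list(fit.beta.index).index("intercept")] + [
                    list(fit.beta.index).index(c) for c in cols
                ]
                offs = np.zeros(n)
                if pred.u_patch is not None:
                    offs += pred.u_patch
                uy = fit.u_year.get(year, 0.0)
                offs += float(uy) * (fit.sigma2_year > 0)
                # (B, n) linear predictors for all draws at once
                etas[(sp, resp)] = betas[(sp, resp)][:, keep] @ Xrow.T + offs
        for b in range(B):
            rate_arrays = {key: expit(eta[b]) for key, eta in etas.items()}
            new = community_step(prev_bin, rate_arrays, rng)
            new[~observed] = _NA
            draws[b, :, ti, :] = new
    return ForecastEnsemble(draws=draws, years=list(years),
                            patch_ids=landscape.patch_ids)


def assemble_community(
    m_draw: np.ndarray,
    prev: np.ndarray,
    parasitoid_col_prob: np.ndarray,
    parasitoid_ext_prob: np.ndarray,
    seed=0,
) -> np.ndarray:
    """Resolve parasitoid presence given a butterfly draw and previous states.

    A butterfly extinction forces parasitoid absence; a butterfly
    colonization admits the parasitoid as a Bernoulli draw with its
    estimated colonization probability; a persisting host lets an absent
    parasitoid colonize and a present one survive with 1 − e.
    """
    for name, prob in (("colonization", parasitoid_col_prob),
                       ("extinction", parasitoid_ext_prob)):
        if np.any((np.asarray(prob) < 0) | (np.asarray(prob) > 1)):
            raise ValueError(f"parasitoid {name} probability outside [0, 1]")
    rng = np.random.default_rng(seed)
    iC = lsc.SPECIES.index("C")
    n = prev.shape[0]
    u = rng.random(n)
    host_now = np.asarray(m_draw) == 1
    had_c = prev[:, iC] == 1
    survive = had_c & host_now & (u >= parasitoid_ext_prob)
    colonize = ~had_c & host_now & (u < parasitoid_col_prob)
    return (survive | colonize).astype(np.int8)


def summarize_forecast(
    ensemble: ForecastEnsemble,
    grouping: str = "year",
    landscape: lsc.Landscape | None = None,
    k_classes: int = 15,
) -> pd.DataFrame:
    """Median and 95% percentile interval of occupancy/state shares.

    ``grouping="year"``: per transition year, the fraction of patches
    occupied by each species and the share of patches in each of the six
    community states, summarised across bootstrap draws.
    ``grouping="cover_class"``: patches are split into ``k_classes``
    equal-count classes of time-averaged host-plant cover; per class the
    occupied fractions are first averaged across years, then summarised
    across draws.
    """
    d = ensemble.draws
    valid = d[:, :, :, 0] >= 0  # (B, n, T); NA pattern identical across species
    records = []
    if grouping == "year":
        for ti, year in enumerate(ensemble.years):
            records.extend(_group_records(d[:, :, ti, :], valid[:, :, ti], str(year)))
    elif grouping == "cover_class":
        if landscape is None:
            raise ValueError("cover-class grouping needs the landscape")
        classes = lsc.bin_cover_classes(landscape.mean_cover(), k_classes)
        for cls in range(k_classes):
            sel = classes == cls
            if not sel.any():
                warnings.warn(f"empty cover class {cls}")
                for metric in [f"occ_{sp}" for sp in lsc.SPECIES]:
                    records.append({"group": f"class_{cls}", "species_or_state": metric,
                                    "median": np.nan, "lo95": np.nan, "hi95": np.nan})
                continue
            # average across years within each draw, then summarise over draws
            sub = d[:, sel, :, :]
            vsub = valid[:, sel, :]
            records.extend(_group_records(sub, vsub, f"class_{cls}", mean_axis=(1, 2)))
    else:
        raise ValueError("grouping must be 'year' or 'cover_class'")
    return pd.DataFrame(records)


def _group_records(block, valid, group, mean_axis=1):
    """Summary rows for one group: block (B, n[, T], 3), valid (B, n[, T])."""
    out = []
    vb = np.where(valid, 1.0, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for ksp, sp in enumerate(lsc.SPECIES):
            occ = np.nanmean(block[..., ksp] * vb, axis=mean_axis)
            out.append(_quantile_row(group, f"occ_{sp}", occ))
        m, c, p = (block[..., lsc.SPECIES.index(s)] for s in ("M", "C", "P"))
        code = m * 4 + c * 2 + p
        for label, want in (("0", 0), ("M", 4), ("MC", 6), ("P", 1),
                            ("MP", 5), ("MCP", 7)):
            share = np.nanmean(np.where(valid, code == want, np.nan), axis=mean_axis)
            out.append(_quantile_row(group, f"state_{label}", share))
    return out


def _quantile_row(group, metric, values):
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return {"group": group, "species_or_state": metric,
                "median": np.nan, "lo95": np.nan, "hi95": np.nan}
    lo, med, hi = np.percentile(values, [2.5, 50, 97.5])
    return {"group": group, "species_or_state": metric,
            "median": med, "lo95": lo, "hi95": hi}
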