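"""End-to-end validation metrics: oracles, recovery, calibration, coverage.

These routines re-run the pipeline against known ground truth or against
independent oracles and reduce the outcome to scalar metrics.  They back
the acceptance checks and the reproduction script; each takes explicit
seeds and returns plain numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from metaspom import forecast as fc
from metaspom import landscape as lsc
from metaspom import occmodels as om
from metaspom import simulator as sim
from metaspom import synthetic_data as sd
from metaspom._glmm import fit_glmm, fit_logistic_newton

#: Precipitation terms that actually enter the default ground truth, per
#: model; recovery fits use the correctly specified covariate set.
TRUE_PRECIP = {
    ("M", "colonization"): ("precip_may",),
    ("M", "extinction"): ("precip_july",),
    ("C", "colonization"): ("precip_may",),
    ("C", "extinction"): (),
    ("P", "colonization"): ("precip_august",),
    ("P", "extinction"): ("precip_july",),
}


def patch_state_enumeration() -> tuple[int, set[str]]:
    """Enumerate presence/absence triples under the host constraint."""
    labels = set()
    for m in (0, 1):
        for c in (0, 1):
            for p in (0, 1):
                try:
                    labels.add(lsc.encode_patch_state(m, c, p).label)
                except lsc.InvalidStateError:
                    pass
    return len(labels), labels


def weather_model_space(seed: int = 0) -> int:
    """Number of candidate models enumerated by the weather selection."""
    rng = np.random.default_rng(seed)
    n = 400
    years = rng.integers(0, 8, n)
    precip = sd.generate_covariates(8, seed=seed)
    pc = om.precip_covariates(precip)
    data = pd.DataFrame({
        "outcome": rng.integers(0, 2, n),
        "patch_id": np.arange(n) % 50,
        "year": 2000 + years,
        "log_cover": rng.normal(size=n),
    })
    for term in om.PRECIP_TERMS:
        data[term] = pc[term].to_numpy()[years]
    table, _ = om.select_weather_model(
        om.ModelSpec("colonization", "M", ("log_cover",)), data,
        fix_sigma2_patch=0.0, fix_sigma2_year=0.0)
    return len(table)


def connectivity_oracle_max_rel_err(n_networks: int = 100, seed: int = 0) -> float:
    """Largest relative deviation of the vectorised connectivity from a
    naive double-loop summation over random small networks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        n = int(rng.integers(2, 11))
        xy = rng.uniform(0, 10, (n, 2))
        areas = rng.lognormal(2, 1, n)
        occ = rng.integers(0, 2, n).astype(float)
        alpha = float(rng.uniform(0.2, 3.0))
        table = pd.DataFrame({
            "patch_id": [f"p{i}" for i in range(n)],
            "x_km": xy[:, 0], "y_km": xy[:, 1], "area_m2": areas,
            "road": 0, "vs_score": 0, "cover_pl_2000": 1.0,
        })
        s = lsc.connectivity_from_occupancy(occ, lsc.Landscape(table),
                                            lsc.KernelParams(alpha))
        oracle = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i != j:
                    d = np.hypot(*(xy[i] - xy[j]))
                    oracle[i] += np.exp(-alpha * d) * areas[j] * occ[j]
        denom = np.where(oracle == 0, 1.0, np.abs(oracle))
        worst = max(worst, float(np.max(np.abs(s - oracle) / denom)))
    return worst


def logistic_limit_max_coef_diff(seed: int = 0) -> float:
    """Max |beta| difference between the mixed fit on zero-variance data
    (every patch and year its own level, so the variances are pushed to the
    boundary) and an independent Newton-Raphson logistic oracle."""
    rng = np.random.default_rng(seed)
    n = 2000
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    beta_true = np.array([-1.0, 0.7, -0.4])
    y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
    res = fit_glmm(y, X, np.arange(n), np.arange(n), n, n)
    beta_oracle, _ = fit_logistic_newton(y, X)
    return float(np.max(np.abs(res.beta - beta_oracle)))


def _fit_all(hist, land, precip):
    fits = {}
    for key, pr in TRUE_PRECIP.items():
        tab = om.build_transition_table(hist, land, precip, key[0], key[1])
        fits[key] = om.fit_occupancy_glmm(
            om.default_spec(key[0], key[1], precip=pr), tab, keep_design=False)
    return fits


def recovery_and_forecast_metrics(
    n_seeds: int = 20,
    seed: int = 0,
    n_patches: int = 500,
    n_years: int = 19,
    B: int = 1000,
) -> dict:
    """Generate → refit → forecast over replicate landscapes.

    Returns the mean absolute relative bias (%) of the refitted butterfly
    and mildew coefficients with |beta| >= 0.3, their mean 95% CI coverage,
    the fraction of seed-years whose observed occupied count falls inside
    the 95% bootstrap prediction interval (all three species), and the
    total count of host-constraint violations across all forecast draws.

    Recovery excludes the parasitoid models: their transition rows conflate
    joint host events with the parasitoid's own process, so the generating
    parameters are not their estimand (the parasitoid still participates in
    the community forecast).
    """
    truth = sd.default_truth()
    bias_rows, cover_hits, cover_tot = [], 0, 0
    fc_inside = fc_total = 0
    violations = 0
    seeds = np.random.SeedSequence(seed).spawn(n_seeds)
    for srep in seeds:
        s0, s1, s2, s3 = srep.spawn(4)
        land = sd.generate_landscape(n_patches,
                                     years=range(2000, 2000 + n_years), seed=s0)
        precip = sd.generate_covariates(n_years, seed=s1)
        hist = sd.generate_history(land, precip, truth, n_years, seed=s2)
        fits = _fit_all(hist, land, precip)
        for key, fit in fits.items():
            tp = truth.predictors[key]
            true = {"intercept": tp.beta0, **tp.slopes}
            se = np.sqrt(np.diag(fit.vcov.to_numpy()))
            for name, s_ in zip(fit.beta.index, se):
                est, tr = float(fit.beta[name]), true[name]
                if key[0] in ("M", "P"):
                    cover_hits += int(abs(est - tr) <= 1.96 * s_)
                    cover_tot += 1
                    if abs(tr) >= 0.3:
                        bias_rows.append((key, name, tr, est))
        ens = fc.bootstrap_predictions(fits, hist, land, precip, B=B,
                                       seed=int(s3.generate_state(1)[0] % 2**31))
        d = ens.draws
        violations += int(np.sum((d[:, :, :, lsc.SPECIES.index("C")] == 1)
                                 & (d[:, :, :, lsc.SPECIES.index("M")] == 0)))
        for k, sp in enumerate(lsc.SPECIES):
            frac = ens.occupied_fraction(sp)
            lo, hi = np.percentile(frac, [2.5, 97.5], axis=0)
            for ti, year in enumerate(ens.years):
                obs = np.nanmean(hist.occupancy(sp, year))
                fc_total += 1
                fc_inside += int(lo[ti] - 1e-12 <= obs <= hi[ti] + 1e-12)
    # average the estimate over seeds per coefficient, then take the
    # relative bias of that average
    df = pd.DataFrame(bias_rows, columns=["model", "coef", "true", "est"])
    per_coef = df.groupby(["model", "coef"]).agg(true=("true", "first"),
                                                 mean_est=("est", "mean"))
    rel_bias = 100.0 * (per_coef.mean_est - per_coef.true) / per_coef.true.abs()
    return {
        "bias_pct_mean_abs": float(rel_bias.abs().mean()),
        "ci_coverage": cover_hits / cover_tot,
        "forecast_coverage_pct": 100.0 * fc_inside / fc_total,
        "constraint_violations": violations,
        "n_coefficients": int(len(per_coef)),
    }


def stationary_occupancy(c: float = 0.2, e: float = 0.3, n: int = 200,
                         T: int = 500, burn: int = 100, seed: int = 11) -> dict:
    """Long-run occupied fraction of decoupled constant-rate dynamics.

    The per-patch chain has stationary occupancy c/(c+e); the Monte-Carlo
    standard error accounts for the lag-1 autocorrelation 1 - c - e.
    """
    side = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    table = pd.DataFrame({
        "patch_id": [f"g{i}" for i in idx],
        "x_km": (idx % side) * 50.0, "y_km": (idx // side) * 50.0,
        "area_m2": 10.0, "road": 0, "vs_score": 0, "cover_pl_2000": 1.0,
    })
    land = lsc.Landscape(table)
    traj = sim.simulate_trajectory(np.zeros((n, 3), dtype=np.int8),
                                   sim.constant_rates(c, e), land, None,
                                   T=T, seed=seed, start_year=2000)
    occ = traj.occupied_fraction("M")[burn:]
    target = c / (c + e)
    rho = 1 - c - e
    n_eff = n * (T - burn) * (1 - rho) / (1 + rho)
    se = float(np.sqrt(target * (1 - target) / n_eff))
    return {"occupancy": float(occ.mean()), "target": target, "mc_se": se}


def state_screen_rates(
    n_seeds: int = 20,
    seed: int = 0,
    contrast: float = 0.7,
    null_size: tuple[int, int] = (500, 19),
    power_size: tuple[int, int] = (2000, 15),
) -> dict:
    """Delta-AIC support rates for the patch-state term under null and
    interaction truths (butterfly colonization screened for a mildew
    contrast)."""

    def one(seed_seq, n_patches, n_years, inter):
        s0, s1, s2 = seed_seq.spawn(3)
        land = sd.generate_landscape(n_patches,
                                     years=range(2000, 2000 + n_years), seed=s0)
        precip = sd.generate_covariates(n_years, seed=s1)
        truth = sd.default_truth(interactions=inter)
        hist = sd.generate_history(land, precip, truth, n_years, seed=s2)
        tab = om.build_transition_table(hist, land, precip, "M", "colonization")
        spec = om.default_spec("M", "colonization", precip=("precip_may",))
        sfit = om.fit_state_model(spec.with_state(), tab, keep_design=False)
        base = om.fit_occupancy_glmm(spec, tab.loc[sfit.row_index],
                                     keep_design=False)
        return om.delta_aic(sfit, base)

    root = np.random.SeedSequence(seed)
    null_seeds, power_seeds = root.spawn(2)
    null_support = sum(
        one(s, *null_size, None) < -2.0 for s in null_seeds.spawn(n_seeds))
    power_support = sum(
        one(s, *power_size, {("M", "colonization"): {"P": contrast}}) < -2.0
        for s in power_seeds.spawn(n_seeds))
    return {
        "null_support_pct": 100.0 * null_support / n_seeds,
        "power_support_pct": 100.0 * power_support / n_seeds,
        "n_seeds": n_seeds,
    }


def simulation_constraint_violations(seed: int = 0, n_patches: int = 300,
                                     n_years: int = 12, R: int = 100) -> dict:
    """Host-constraint violations across a full simulated ensemble."""
    s0, s1, s2, s3 = np.random.SeedSequence(seed).spawn(4)
    land = sd.generate_landscape(n_patches, years=range(2000, 2000 + n_years),
                                 seed=s0)
    precip = sd.generate_covariates(n_years, seed=s1)
    truth = sd.default_truth()
    hist = sd.generate_history(land, precip, truth, n_years, seed=s2)
    fits = _fit_all(hist, land, precip)
    init = np.nan_to_num(hist.values[:, 0, :], nan=0.0).astype(np.int8)
    ens = sim.simulate_ensemble(init, sim.CommunityRates.from_fits(fits, land),
                                land, precip, T=n_years - 1, R=R,
                                seed=int(s3.generate_state(1)[0] % 2**31),
                                start_year=2000)
    viol = 0
    iM, iC = lsc.SPECIES.index("M"), lsc.SPECIES.index("C")
    for traj in ens.trajectories:
        viol += int(np.sum((traj.states[:, :, iC] == 1)
                           & (traj.states[:, :, iM] == 0)))
    return {"violations": viol, "n_state_years": R * n_years * n_patches}
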