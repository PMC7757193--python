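"""Patch-network data model, connectivity, turnover events, and patch states.

The landscape is a static network of habitat patches with centroid
coordinates (km), areas (m²), yearly host-plant (*Plantago lanceolata*)
cover (m²), an ordinal *Veronica spicata* abundance score (0–3), and a
road-border flag.  Occupancy histories record yearly presence/absence of
the three focal species — the butterfly (M), its parasitoid wasp (C), and
the powdery mildew (P) — with missing surveys stored as NaN.

Connectivity of patch *i* for species *Y* in year *t* is the
kernel-weighted sum of occupied neighbour areas

    S_it = sum_{j != i} exp(-alpha * d_ij) * A_j * O_{j,t-1}

with a negative-exponential dispersal kernel of scale ``alpha`` (km⁻¹);
1/alpha is the mean dispersal distance.  Host connectivity replaces the
occupancy-weighted area by the time-averaged host-plant cover and is
time-invariant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Focal species codes: butterfly (M), parasitoid (C), mildew (P).
SPECIES: tuple[str, ...] = ("M", "C", "P")

#: The six valid patch states under the host-dependence constraint
#: (the parasitoid C cannot be present without the butterfly M).
STATE_LABELS: tuple[str, ...] = ("0", "M", "MC", "P", "MP", "MCP")

_FLAGS_TO_LABEL = {
    (0, 0, 0): "0",
    (1, 0, 0): "M",
    (1, 1, 0): "MC",
    (0, 0, 1): "P",
    (1, 0, 1): "MP",
    (1, 1, 1): "MCP",
}
_LABEL_TO_FLAGS = {v: k for k, v in _FLAGS_TO_LABEL.items()}


class InvalidStateError(ValueError):
    """A presence/absence combination violating the host-dependence constraint."""


@dataclass(frozen=True)
class KernelParams:
    """Negative-exponential dispersal kernel scale.

    Parameters
    ----------
    alpha
        Kernel decay rate in km⁻¹.  The default of 1.0 corresponds to a
        mean dispersal distance of 1 km, a value supported by
        mark–recapture estimates for all three focal species.
    """

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"kernel scale alpha must be positive, got {self.alpha}")

    @property
    def mean_dispersal(self) -> float:
        """Mean dispersal distance 1/alpha in km."""
        return 1.0 / self.alpha


@dataclass(frozen=True)
class PatchState:
    """Categorical patch state: which focal species are present.

    ``label`` is one of ``STATE_LABELS``; ``flags`` is the (M, C, P)
    presence triple.  The two are bijective under the constraint C ⇒ M.
    """

    label: str
    flags: tuple[int, int, int]


def encode_patch_state(m: int, c: int, p: int) -> PatchState:
    """Encode a presence/absence triple as one of the six patch states.

    Raises
    ------
    InvalidStateError
        If the parasitoid is marked present without its butterfly host.
    """
    key = (int(m), int(c), int(p))
    if any(v not in (0, 1) for v in key):
        raise ValueError(f"presence flags must be 0/1, got {key}")
    if key not in _FLAGS_TO_LABEL:
        raise InvalidStateError(
            f"invalid patch state {key}: the parasitoid cannot be present "
            "without its butterfly host"
        )
    return PatchState(label=_FLAGS_TO_LABEL[key], flags=key)


def decode_patch_state(label: str) -> PatchState:
    """Inverse of :func:`encode_patch_state`."""
    if label not in _LABEL_TO_FLAGS:
        raise ValueError(f"unknown patch state label {label!r}")
    return PatchState(label=label, flags=_LABEL_TO_FLAGS[label])


class Landscape:
    """A static patch network.

    Wraps a patch attribute table with columns ``patch_id``, ``x_km``,
    ``y_km``, ``area_m2``, ``road``, ``vs_score`` and one ``cover_pl_<year>``
    column per survey year (NaN marks unsurveyed cover years).

    Distances between patches are Euclidean on the km coordinates
    (centroid-to-centroid).  Duplicate coordinates are allowed; the
    self-term is always excluded from connectivity sums.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"patch_id", "x_km", "y_km", "area_m2", "road", "vs_score"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"patch table missing columns: {sorted(missing)}")
        if table["patch_id"].duplicated().any():
            raise ValueError("duplicate patch ids in patch table")
        areas = table["area_m2"].to_numpy(float)
        if not np.all(areas > 0):
            raise ValueError("patch areas must be positive")
        xy = table[["x_km", "y_km"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("patch coordinates must be finite")
        vs = table["vs_score"].to_numpy()
        if not np.isin(vs, [0, 1, 2, 3]).all():
            raise ValueError("vs_score must be an integer in 0..3")
        self.table = table.reset_index(drop=True)
        self._kernels: dict[float, np.ndarray] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_patches(self) -> int:
        return len(self.table)

    @property
    def patch_ids(self) -> np.ndarray:
        return self.table["patch_id"].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self.table["area_m2"].to_numpy(float)

    @property
    def road(self) -> np.ndarray:
        return self.table["road"].to_numpy(float)

    @property
    def vs_score(self) -> np.ndarray:
        return self.table["vs_score"].to_numpy(float)

    @property
    def cover_years(self) -> list[int]:
        return sorted(
            int(c.split("_")[-1]) for c in self.table.columns if c.startswith("cover_pl_")
        )

    def cover(self, year: int, impute: bool = True) -> np.ndarray:
        """Host-plant cover (m²) per patch for one year.

        Missing cover years are imputed with the patch mean over recorded
        years, so downstream covariates stay defined on partially surveyed
        patches.
        """
        col = f"cover_pl_{year}"
        if col not in self.table.columns:
            raise KeyError(f"no cover column for year {year}")
        values = self.table[col].to_numpy(float)
        if impute:
            values = np.where(np.isnan(values), self.mean_cover(), values)
        return values

    def mean_cover(self) -> np.ndarray:
        """Per-patch cover averaged across recorded years (NaN years dropped)."""
        cols = [c for c in self.table.columns if c.startswith("cover_pl_")]
        if not cols:
            raise ValueError("patch table has no cover_pl_<year> columns")
        cover = self.table[cols].to_numpy(float)
        all_na = np.isnan(cover).all(axis=1)
        if all_na.any():
            bad = self.patch_ids[all_na]
            raise ValueError(f"all-NA host-plant cover for patch(es): {list(bad[:5])}")
        with np.errstate(invalid="ignore"):
            return np.nanmean(cover, axis=1)

    # -- geometry ----------------------------------------------------------

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances (km)."""
        xy = self.table[["x_km", "y_km"]].to_numpy(float)
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def kernel(self, params: KernelParams) -> np.ndarray:
        """exp(-alpha d_ij) with zero diagonal (self-term excluded), cached."""
        if params.alpha not in self._kernels:
            k = np.exp(-params.alpha * self.distance_matrix())
            np.fill_diagonal(k, 0.0)
            self._kernels[params.alpha] = k
        return self._kernels[params.alpha]


class OccupancyHistory:
    """Patch × year × species presence/absence with missing-survey support.

    ``values`` is a float array with entries 0, 1, or NaN (not surveyed).
    Years must be strictly increasing and contiguous.  Wherever both the
    butterfly and parasitoid entries are observed, parasitoid presence
    implies butterfly presence.
    """

    def __init__(
        self,
        values: np.ndarray,
        years: list[int] | np.ndarray,
        patch_ids: np.ndarray | list,
        species: tuple[str, ...] = SPECIES,
    ):
        values = np.asarray(values, float)
        years = [int(y) for y in years]
        if values.ndim != 3 or values.shape[1] != len(years) or values.shape[2] != len(species):
            raise ValueError(f"values shape {values.shape} inconsistent with labels")
        if len(patch_ids) != values.shape[0]:
            raise ValueError("patch_ids length mismatch")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing and contiguous")
        obs = values[~np.isnan(values)]
        if not np.isin(obs, [0.0, 1.0]).all():
            raise ValueError("occupancy entries must be 0, 1 or NaN")
        if "M" in species and "C" in species:
            m = values[:, :, species.index("M")]
            c = values[:, :, species.index("C")]
            both = ~np.isnan(m) & ~np.isnan(c)
            if np.any((c == 1) & (m == 0) & both):
                raise InvalidStateError("parasitoid present without butterfly host")
        self.values = values
        self.years = years
        self.patch_ids = np.asarray(patch_ids)
        self.species = tuple(species)

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]

    def species_index(self, species: str) -> int:
        if species not in self.species:
            raise KeyError(f"unknown species label {species!r}; have {self.species}")
        return self.species.index(species)

    def year_index(self, year: int) -> int:
        if year not in self.years:
            raise KeyError(f"year {year} not in history ({self.years[0]}..{self.years[-1]})")
        return self.years.index(year)

    def occupancy(self, species: str, year: int) -> np.ndarray:
        """Presence vector (with NaN) for one species and year."""
        return self.values[:, self.year_index(year), self.species_index(species)]

    def occupied_count(self, species: str, year: int) -> int:
        return int(np.nansum(self.occupancy(species, year)))


@dataclass
class TurnoverEvents:
    """Colonization/extinction events and their possible-event denominators.

    ``rate`` properties divide event counts by the number of patch-years in
    which the event was possible (absent at t−1 for colonization, present
    at t−1 for extinction); transitions touching a missing survey are
    excluded from both counts and denominators.  For the parasitoid,
    ``joint_col``/``joint_ext`` flag events coinciding with a butterfly
    colonization/extinction in the same year.
    """

    species: str
    colonizations: list[tuple] = field(default_factory=list)
    extinctions: list[tuple] = field(default_factory=list)
    n_possible_col: int = 0
    n_possible_ext: int = 0
    joint_col: list[tuple] = field(default_factory=list)
    joint_ext: list[tuple] = field(default_factory=list)

    @property
    def col_rate(self) -> float:
        return len(self.colonizations) / self.n_possible_col if self.n_possible_col else np.nan

    @property
    def ext_rate(self) -> float:
        return len(self.extinctions) / self.n_possible_ext if self.n_possible_ext else np.nan


def compute_connectivity(
    history: OccupancyHistory,
    landscape: Landscape,
    params: KernelParams,
    species: str,
    year: int,
) -> np.ndarray:
    """Species-specific connectivity S_it from the previous year's occupancy.

    S_it = sum_{j != i} exp(-alpha d_ij) A_j O_{j,t-1}.  Missing occupancy
    at t−1 contributes zero to neighbour sums (unsurveyed patches are
    treated as unoccupied neighbours).

    Raises
    ------
    KeyError
        If the species is unknown or ``year - 1`` is not in the history.
    """
    occ = history.occupancy(species, year - 1)
    occ = np.nan_to_num(occ, nan=0.0)
    return connectivity_from_occupancy(occ, landscape, params)


def connectivity_from_occupancy(
    occupancy: np.ndarray, landscape: Landscape, params: KernelParams
) -> np.ndarray:
    """Connectivity from an explicit 0/1 occupancy vector (previous year)."""
    occupancy = np.asarray(occupancy, float)
    if occupancy.shape != (landscape.n_patches,):
        raise ValueError("occupancy vector length must equal the number of patches")
    return landscape.kernel(params) @ (landscape.areas * occupancy)


def compute_host_connectivity(landscape: Landscape, params: KernelParams) -> np.ndarray:
    """Time-invariant host-plant connectivity S_i^PL.

    S_i^PL = sum_{j != i} exp(-alpha d_ij) * mean-over-years cover of
    *P. lanceolata* in patch j.
    """
    return landscape.kernel(params) @ landscape.mean_cover()


def assign_turnover_events(history: OccupancyHistory, species: str) -> TurnoverEvents:
    """Assign yearly colonization and extinction events for one species.

    A colonization at (i, t) is presence at t following absence at t−1; an
    extinction is absence at t following presence at t−1.  Denominators
    count the patch-years in which each transition was possible.  For the
    parasitoid, events whose host transitioned the same way in the same
    year are additionally flagged as joint events, and joint colonizations
    (host and parasitoid arriving together) enter the possible-colonization
    denominator even though the host was absent at t−1.
    """
    if len(history.years) < 2:
        raise ValueError("need at least 2 years of data to assign turnover events")
    s = history.species_index(species)
    vals = history.values[:, :, s]
    ev = TurnoverEvents(species=species)
    host = history.values[:, :, history.species_index("M")] if species == "C" else None
    for t in range(1, len(history.years)):
        year = history.years[t]
        prev, cur = vals[:, t - 1], vals[:, t]
        ok = ~np.isnan(prev) & ~np.isnan(cur)
        if species == "C":
            hprev, hcur = host[:, t - 1], host[:, t]
            hok = ~np.isnan(hprev) & ~np.isnan(hcur)
            # Parasitoid colonization is possible into an existing host
            # population, or jointly with a host arrival.
            possible_col = ok & hok & (prev == 0) & ((hprev == 1) | (hcur == 1))
        else:
            possible_col = ok & (prev == 0)
        possible_ext = ok & (prev == 1)
        ev.n_possible_col += int(possible_col.sum())
        ev.n_possible_ext += int(possible_ext.sum())
        for i in np.flatnonzero(possible_col & (cur == 1)):
            event = (history.patch_ids[i], year)
            ev.colonizations.append(event)
            if species == "C" and host[i, t - 1] == 0 and host[i, t] == 1:
                ev.joint_col.append(event)
        for i in np.flatnonzero(possible_ext & (cur == 0)):
            event = (history.patch_ids[i], year)
            ev.extinctions.append(event)
            if species == "C" and host[i, t - 1] == 1 and host[i, t] == 0:
                ev.joint_ext.append(event)
    return ev


def bin_cover_classes(values: np.ndarray, k: int = 15) -> np.ndarray:
    """Assign patches to ``k`` equal-count cover classes (0-based indices).

    Classes are quantile bins: patches are sorted by cover (stable order on
    ties) and split into ``k`` contiguous chunks whose sizes differ by at
    most one, so class boundaries are monotone in cover.  The default of 15
    classes matches the cover-gradient summaries used throughout.
    """
    values = np.asarray(values, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cover values must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > values.size:
        raise ValueError(f"k={k} exceeds the number of patches ({values.size})")
    order = np.argsort(values, kind="stable")
    classes = np.empty(values.size, dtype=int)
    for c, chunk in enumerate(np.array_split(order, k)):
        classes[chunk] = c
    return classes


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
#
# patches.csv       patch_id,x_km,y_km,area_m2,road,vs_score,cover_pl_<year>...
# occupancy.csv     patch_id,year,species,present     (long; present in 0/1/NA)
# precipitation.csv year,may_mm,june_mm,july_mm,august_mm
#
# All writers use a fixed column order and '.' decimal separator; NA cells
# are the literal string "NA".

PRECIP_COLUMNS = ["year", "may_mm", "june_mm", "july_mm", "august_mm"]


def read_patches(path) -> Landscape:
    """Read a patch attribute table into a :class:`Landscape`."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    return Landscape(df)


def write_patches(landscape: Landscape, path) -> None:
    fixed = ["patch_id", "x_km", "y_km", "area_m2", "road", "vs_score"]
    cover = [f"cover_pl_{y}" for y in landscape.cover_years]
    landscape.table[fixed + cover].to_csv(path, index=False, na_rep="NA")


def read_occupancy(path, patch_ids=None) -> OccupancyHistory:
    """Read a long-format occupancy table into an :class:`OccupancyHistory`.

    Patch order follows ``patch_ids`` when given (e.g. from the landscape),
    otherwise first appearance in the file.
    """
    df = pd.read_csv(path, na_values=["NA"], dtype={"present": float})
    if patch_ids is None:
        patch_ids = df["patch_id"].drop_duplicates().to_numpy()
    patch_ids = np.asarray(patch_ids)
    years = sorted(df["year"].unique())
    pidx = {p: i for i, p in enumerate(patch_ids)}
    yidx = {y: j for j, y in enumerate(years)}
    values = np.full((len(patch_ids), len(years), len(SPECIES)), np.nan)
    sidx = {s: k for k, s in enumerate(SPECIES)}
    for row in df.itertuples(index=False):
        values[pidx[row.patch_id], yidx[row.year], sidx[row.species]] = row.present
    return OccupancyHistory(values, years, patch_ids)


def write_occupancy(history: OccupancyHistory, path) -> None:
    buf = io.StringIO()
    buf.write("patch_id,year,species,present\n")
    for i, pid in enumerate(history.patch_ids):
        for t, year in enumerate(history.years):
            for k, sp in enumerate(history.species):
                v = history.values[i, t, k]
                cell = "NA" if np.isnan(v) else str(int(v))
                buf.write(f"{pid},{year},{sp},{cell}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_precipitation(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    missing = set(PRECIP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"precipitation table missing columns: {sorted(missing)}")
    return df[PRECIP_COLUMNS]


def write_precipitation(precip: pd.DataFrame, path) -> None:
    precip[PRECIP_COLUMNS].to_csv(path, index=False, na_rep="NA")
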