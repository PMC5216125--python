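"""CD-monitored Fe/S-cluster synthesis kinetics and cluster stoichiometry.

De novo [2Fe-2S] cluster synthesis on the Isu1 scaffold is followed by the
circular-dichroism signal change at 431 nm after the reaction is started by
cysteine addition.  The initial rate is the ordinary least-squares slope of
ellipticity versus time over the first 4.5 min (window boundary inclusive,
free intercept); omission reactions and iron-free backgrounds are expressed
as a percentage of the standard reaction's rate rather than subtracted.

Times are seconds internally; slopes are reported in mdeg/min and windows
given in minutes, matching how the measurements are usually quoted.

Cluster stoichiometry is plain atom bookkeeping: a [2Fe-2S] cluster
contributes 2 Fe + 2 S, a [4Fe-4S] cluster 4 Fe + 4 S; two [4Fe-4S]
clusters per heterodimer give the expected 8 Fe and 8 S against which
measured Fe and acid-labile S per complex are compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CDTimeCourse",
    "InitialRate",
    "InitialRateModel",
    "ClusterInventory",
    "StoichiometryResult",
    "DEFAULT_RATE_WINDOW_MIN",
    "initial_rate",
    "relative_rate",
    "simulate_timecourse",
    "cluster_stoichiometry",
    "atoms_per_complex",
    "occupancy_from_cd",
]

#: Length (min) of the linear-fit window for initial rates.
DEFAULT_RATE_WINDOW_MIN = 4.5

#: Atom contributions (Fe, S) per cluster species.  Hyphen/en-dash spellings
#: are normalised on lookup.
CLUSTER_ATOMS = {
    "[2Fe-2S]": (2, 2),
    "[4Fe-4S]": (4, 4),
}


@dataclass(frozen=True)
class CDTimeCourse:
    """Ellipticity (mdeg, 431 nm) versus time (s) for one reaction.

    ``condition`` is free-form; conventional values are ``standard``,
    ``omission:<component>`` and ``no_iron``.  Times start at reaction
    initiation (cysteine addition) and must be strictly increasing.
    """

    times_s: np.ndarray
    signal_mdeg: np.ndarray
    reaction_id: str = "rx0"
    condition: str = "standard"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        s = np.asarray(self.signal_mdeg, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "signal_mdeg", s)


@dataclass(frozen=True)
class InitialRate:
    """OLS initial-rate fit over the rate window."""

    slope_mdeg_per_min: float
    intercept_mdeg: float
    window_min: float
    r_squared: float
    n_points: int


class InitialRateModel:
    """Model: linear initial-rate fit to a CD time course.

    ``fit()`` performs ordinary least squares on all samples with
    0 <= t <= window (inclusive) and returns an :class:`InitialRate`.
    """

    def __init__(self, timecourse: CDTimeCourse, window_min: float = DEFAULT_RATE_WINDOW_MIN):
        self.timecourse = timecourse
        self.window_min = float(window_min)

    @classmethod
    def from_dataframe(cls, df, window_min: float = DEFAULT_RATE_WINDOW_MIN,
                       reaction_id: str = "rx0", condition: str = "standard"):
        """Build from a table with ``t_s`` and ``cd_mdeg`` columns."""
        tc = CDTimeCourse(
            times_s=df["t_s"].to_numpy(),
            signal_mdeg=df["cd_mdeg"].to_numpy(),
            reaction_id=reaction_id,
            condition=condition,
        )
        return cls(tc, window_min=window_min)

    def fit(self) -> InitialRate:
        tc = self.timecourse
        mask = (tc.times_s >= 0.0) & (tc.times_s <= self.window_min * 60.0 + 1e-9)
        n = int(mask.sum())
        if n < 3:
            raise ValueError(
                f"need >= 3 samples within the {self.window_min} min window, got {n}"
            )
        t_min = tc.times_s[mask] / 60.0
        y = tc.signal_mdeg[mask]
        res = stats.linregress(t_min, y)
        return InitialRate(
            slope_mdeg_per_min=float(res.slope),
            intercept_mdeg=float(res.intercept),
            window_min=self.window_min,
            r_squared=float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
            n_points=n,
        )


def initial_rate(tc: CDTimeCourse, window_min: float = DEFAULT_RATE_WINDOW_MIN) -> InitialRate:
    """OLS slope (mdeg/min) over the first ``window_min`` minutes."""
    return InitialRateModel(tc, window_min).fit()


def relative_rate(rate: InitialRate | float, standard_rate: InitialRate | float) -> float:
    """Rate as a percentage of the standard reaction's rate."""
    r = rate.slope_mdeg_per_min if isinstance(rate, InitialRate) else float(rate)
    s = (
        standard_rate.slope_mdeg_per_min
        if isinstance(standard_rate, InitialRate)
        else float(standard_rate)
    )
    if s == 0:
        raise ValueError("standard rate is zero; relative rate undefined")
    return 100.0 * r / s


def simulate_timecourse(
    amplitude_mdeg: float,
    rate_constant_per_min: float,
    noise_sd_mdeg: float = 0.0,
    window_min: float = 15.0,
    dt_s: float = 1.0,
    seed: int = 0,
    reaction_id: str = "sim",
    condition: str = "standard",
) -> CDTimeCourse:
    """Saturating-rise trace theta(t) = A*(1 - exp(-k*t)) + Gaussian noise.

    A synthetic stand-in for recorded reaction traces; ``rate_constant`` is
    per minute, sampling every ``dt_s`` seconds from t = 0.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    t = np.arange(0.0, window_min * 60.0 + 0.5 * dt_s, dt_s)
    theta = amplitude_mdeg * (1.0 - np.exp(-rate_constant_per_min * t / 60.0))
    if noise_sd_mdeg > 0:
        theta = theta + np.random.default_rng(seed).normal(0.0, noise_sd_mdeg, size=len(t))
    return CDTimeCourse(t, theta, reaction_id=reaction_id, condition=condition)


@dataclass(frozen=True)
class ClusterInventory:
    """Multiset of Fe/S cluster species bound by a complex."""

    clusters: tuple[tuple[str, int], ...]  # (species, multiplicity)

    @classmethod
    def of(cls, *species: str) -> "ClusterInventory":
        counts: dict[str, int] = {}
        for s in species:
            counts[s] = counts.get(s, 0) + 1
        return cls(tuple(sorted(counts.items())))


@dataclass(frozen=True)
class StoichiometryResult:
    fe_per_complex: float
    s_per_complex: float


def _normalise_species(name: str) -> str:
    return name.replace("–", "-").replace("—", "-")


def cluster_stoichiometry(inventory: ClusterInventory) -> StoichiometryResult:
    """Total Fe and S atoms contributed by an inventory of clusters."""
    fe = s = 0
    for species, mult in inventory.clusters:
        if mult < 0:
            raise ValueError("multiplicities must be >= 0")
        key = _normalise_species(species)
        if key not in CLUSTER_ATOMS:
            raise ValueError(f"unknown cluster species {species!r}")
        dfe, ds = CLUSTER_ATOMS[key]
        fe += dfe * mult
        s += ds * mult
    return StoichiometryResult(fe_per_complex=float(fe), s_per_complex=float(s))


def atoms_per_complex(fe_conc_uM: float, s_conc_uM: float, complex_conc_uM: float) -> tuple[float, float]:
    """Measured Fe and acid-labile S atoms per complex from concentrations."""
    if complex_conc_uM <= 0:
        raise ValueError("complex concentration must be > 0")
    return fe_conc_uM / complex_conc_uM, s_conc_uM / complex_conc_uM


def occupancy_from_cd(sample_cd: float, reference_cd: float, reference_occupancy: float = 1.0) -> float:
    """Cluster occupancy by CD intensity ratio against a reference of known
    occupancy (e.g. chemically reconstituted scaffold with one [2Fe-2S] per
    dimer)."""
    if reference_cd == 0:
        raise ValueError("reference CD intensity is zero")
    return reference_occupancy * sample_cd / reference_cd
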