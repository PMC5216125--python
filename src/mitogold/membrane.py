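"""Membrane-distance statistics for immunogold localization.

The localization question — are gold particles for a protein concentrated
toward the matrix side of the inner mitosomal membrane? — is answered by
comparing the signed distances of gold particles to the inner aspect of the
inner membrane with the distances of an equal number of random points
placed uniformly over the same mitosome profiles.  The comparison bundles:

* two-sample Kolmogorov–Smirnov and Mann–Whitney tests on the raw signed
  distances,
* a chi-squared test of the binned gold counts against the proportions
  observed for the random points,
* the *band fraction*: the proportion of distances falling in a fixed-width
  band just inside the matrix (default 20 nm), with its complement covering
  both d < 0 and d beyond the band,
* per-bin gold/random count ratios and pooled cumulative-fraction (ECDF)
  curves.

All tests are two-sided.  Exact p-values are used on small samples
(KS: total n <= 16; Mann–Whitney: min(n) <= 8 without ties) and standard
large-sample approximations otherwise (asymptotic Kolmogorov distribution;
normal approximation with tie and continuity correction).  Multiple labels
are tested without multiplicity correction by default, matching per-protein
reporting; a Bonferroni option is available.

The model/results pair :class:`LocalizationComparison` /
:class:`LocalizationResults` packages the whole procedure; the module-level
functions expose the individual steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import MitosomeProfile, signed_distances

__all__ = [
    "DistanceSample",
    "BinnedDistribution",
    "BandStatistic",
    "NullComparison",
    "LocalizationComparison",
    "LocalizationResults",
    "DEFAULT_BIN_EDGES",
    "DEFAULT_BAND_WIDTH_NM",
    "measure_distances",
    "band_fraction",
    "bin_distances",
    "label_to_random_ratio",
    "cumulative_fraction",
    "ks_two_sample",
    "mann_whitney",
    "chi_squared_binned",
    "compare_to_null",
]

#: Default signed-distance bin edges (nm): -40 to +60 in 10-nm steps.
DEFAULT_BIN_EDGES = tuple(float(e) for e in range(-40, 61, 10))

#: Width (nm) of the matrix-side band used for the headline fraction.
DEFAULT_BAND_WIDTH_NM = 20.0


@dataclass(frozen=True)
class DistanceSample:
    """Signed distances (nm) of one point set to the inner aspect."""

    label: str
    kind: str  # gold | random
    distances: np.ndarray
    profile_ids: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class BandStatistic:
    """Proportion of distances within the matrix-side band [0, band_width]."""

    band_width: float
    fraction_inside: float
    n: int

    @property
    def fraction_outside(self) -> float:
        return 1.0 - self.fraction_inside

    def standard_error(self) -> float:
        """Binomial s.e. of the inside fraction."""
        f = self.fraction_inside
        return math.sqrt(f * (1.0 - f) / self.n) if self.n else float("nan")


@dataclass(frozen=True)
class BinnedDistribution:
    """Counts of signed distances in left-closed bins (last bin closed).

    ``counts`` has len(edges)+1 entries: an underflow bin (< edges[0]), the
    core bins, and an overflow bin (> edges[-1]); the end bins are flagged
    via ``underflow``/``overflow``.
    """

    bin_edges: tuple[float, ...]
    counts: np.ndarray  # core bins only
    underflow: int
    overflow: int

    @property
    def n(self) -> int:
        return int(self.counts.sum()) + self.underflow + self.overflow

    @property
    def frequencies(self) -> np.ndarray:
        """Relative frequencies over the core bins (sum to 1 together with
        the under/overflow fractions)."""
        total = self.n
        return self.counts / total if total > 0 else self.counts.astype(float)

    @property
    def all_counts(self) -> np.ndarray:
        """Underflow + core + overflow counts; sums to the sample size."""
        return np.concatenate([[self.underflow], self.counts, [self.overflow]])


@dataclass(frozen=True)
class NullComparison:
    """The three two-sample tests of gold against matched random points."""

    ks_statistic: float
    ks_p: float
    mw_statistic: float
    mw_p: float
    chi2_statistic: float
    chi2_df: int
    chi2_p: float


def measure_distances(points: pd.DataFrame, profiles: list[MitosomeProfile]) -> pd.DataFrame:
    """Signed distance to the inner aspect for every point in a point set.

    Every point must carry a ``profile_id`` matching one of ``profiles``.
    Returns the input table with a ``distance_nm`` column appended.
    """
    by_id = {p.profile_id: p for p in profiles}
    missing = set(points["profile_id"]) - set(by_id) - {""}
    if missing:
        raise ValueError(f"points reference unknown profiles: {sorted(missing)[:5]}")
    if (points["profile_id"] == "").any():
        raise ValueError("every point needs a profile assignment to measure distances")
    out = points.copy()
    dist = np.empty(len(out))
    for prof_id, grp in out.groupby("profile_id", sort=False):
        prof = by_id[prof_id]
        dist[grp.index.to_numpy()] = signed_distances(
            grp["x_nm"].to_numpy(), grp["y_nm"].to_numpy(), prof
        )
    out["distance_nm"] = dist
    return out


def distance_sample(measured: pd.DataFrame, label: str, kind: str) -> DistanceSample:
    """Extract one (label, kind) sample from a measured point table."""
    sel = measured[(measured["label"] == label) & (measured["kind"] == kind)]
    return DistanceSample(
        label=label,
        kind=kind,
        distances=sel["distance_nm"].to_numpy(),
        profile_ids=tuple(sel["profile_id"]),
    )


def band_fraction(sample: DistanceSample | np.ndarray, band_width: float = DEFAULT_BAND_WIDTH_NM) -> BandStatistic:
    """Fraction of distances with 0 <= d <= band_width (matrix-side band).

    The complement counts both d < 0 (membranes / outside) and d beyond the
    band, reproducing the binary inside/outside split.
    """
    d = sample.distances if isinstance(sample, DistanceSample) else np.asarray(sample, float)
    if len(d) == 0:
        raise ValueError("empty distance sample")
    inside = float(np.mean((d >= 0.0) & (d <= band_width)))
    return BandStatistic(band_width=band_width, fraction_inside=inside, n=len(d))


def bin_distances(
    sample: DistanceSample | np.ndarray, bin_edges=DEFAULT_BIN_EDGES
) -> BinnedDistribution:
    """Histogram of signed distances into left-closed, right-open bins.

    A value on an internal edge goes to the upper bin; the last bin is
    closed on the right.  Values beyond the edges land in flagged
    underflow/overflow bins.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending with >= 2 entries")
    d = sample.distances if isinstance(sample, DistanceSample) else np.asarray(sample, float)
    counts, _ = np.histogram(d, bins=edges)
    under = int(np.count_nonzero(d < edges[0]))
    over = int(np.count_nonzero(d > edges[-1]))
    return BinnedDistribution(
        bin_edges=tuple(edges), counts=counts, underflow=under, overflow=over
    )


def label_to_random_ratio(
    gold: BinnedDistribution, random: BinnedDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin gold/random count ratios over the core bins.

    Returns (ratios, defined): bins where the random count is zero are
    flagged undefined (NaN), never infinite.
    """
    if gold.bin_edges != random.bin_edges:
        raise ValueError("gold and random distributions must share bin edges")
    g = gold.counts.astype(float)
    r = random.counts.astype(float)
    defined = r > 0
    ratios = np.full_like(g, np.nan)
    ratios[defined] = g[defined] / r[defined]
    return ratios, defined


def cumulative_fraction(
    samples: DistanceSample | list[DistanceSample], pool: bool = True
):
    """Right-continuous ECDF(s) over signed distance.

    With ``pool=True`` (the pooled cumulative-fraction plot) all samples'
    distances are concatenated into a single curve and one ``(x, F)`` pair
    is returned; otherwise a list of per-sample pairs.
    """
    if isinstance(samples, DistanceSample):
        samples = [samples]
    if not samples or all(s.n == 0 for s in samples):
        raise ValueError("no distances to accumulate")

    def _ecdf(d: np.ndarray):
        x = np.sort(d)
        return x, np.arange(1, len(x) + 1) / len(x)

    if pool:
        return _ecdf(np.concatenate([s.distances for s in samples]))
    return [_ecdf(s.distances) for s in samples]


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    D = sup |ECDF_a - ECDF_b|.  The p-value is exact when
    n_a + n_b <= 16 and from the asymptotic Kolmogorov distribution
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    method = "exact" if len(a) + len(b) <= 16 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test with midrank ties.

    U is the statistic of the first sample.  Exact p by enumeration when
    min(n_a, n_b) <= 8 and there are no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _merge_small_expected(observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0):
    """Merge adjacent bins until every expected count is >= min_expected."""
    obs = list(observed.astype(float))
    exp = list(expected.astype(float))
    while len(exp) > 1 and min(exp) < min_expected:
        i = int(np.argmin(exp))
        # merge into the smaller adjacent neighbour
        if i == 0:
            j = 1
        elif i == len(exp) - 1:
            j = i - 1
        else:
            j = i - 1 if exp[i - 1] <= exp[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        obs[lo] += obs[hi]
        exp[lo] += exp[hi]
        del obs[hi], exp[hi]
    return np.array(obs), np.array(exp)


def chi_squared_binned(
    gold: BinnedDistribution,
    random: BinnedDistribution,
    homogeneity: bool = False,
) -> tuple[float, int, float]:
    """Chi-squared comparison of binned gold counts with the random null.

    Default: goodness-of-fit of the gold counts against expected
    proportions taken from the random sample, after merging adjacent bins
    (including the under/overflow bins) until every expected count is
    >= 5; df = merged bins - 1.  With ``homogeneity=True`` the alternative
    2 x k contingency (homogeneity) formulation is used instead.
    """
    if gold.bin_edges != random.bin_edges:
        raise ValueError("gold and random distributions must share bin edges")
    g = gold.all_counts.astype(float)
    r = random.all_counts.astype(float)
    if g.sum() == 0 or r.sum() == 0:
        raise ValueError("empty binned distribution")
    if homogeneity:
        table = np.vstack([g, r])
        keep = table.sum(axis=0) > 0
        chi2, p, df, _ = stats.chi2_contingency(table[:, keep])
        return float(chi2), int(df), float(p)
    expected = r / r.sum() * g.sum()
    keep = (g > 0) | (expected > 0)
    obs, exp = _merge_small_expected(g[keep], expected[keep])
    if len(exp) < 2:
        raise ValueError("fewer than 2 bins remain after merging; test undefined")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = len(exp) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def compare_to_null(
    gold: DistanceSample,
    random: DistanceSample,
    bin_edges=DEFAULT_BIN_EDGES,
    band_width: float = DEFAULT_BAND_WIDTH_NM,
) -> tuple[NullComparison, BandStatistic, BandStatistic]:
    """Full gold-vs-random comparison for one label (or the pool).

    Returns (tests, gold band statistic, random band statistic).  The
    matched design requires equal sample sizes.
    """
    if gold.n != random.n:
        raise ValueError(
            f"matched design requires equal sizes (gold {gold.n}, random {random.n})"
        )
    ks_d, ks_p = ks_two_sample(gold.distances, random.distances)
    mw_u, mw_p = mann_whitney(gold.distances, random.distances)
    chi2, df, chi2_p = chi_squared_binned(
        bin_distances(gold, bin_edges), bin_distances(random, bin_edges)
    )
    tests = NullComparison(
        ks_statistic=ks_d,
        ks_p=ks_p,
        mw_statistic=mw_u,
        mw_p=mw_p,
        chi2_statistic=chi2,
        chi2_df=df,
        chi2_p=chi2_p,
    )
    return tests, band_fraction(gold, band_width), band_fraction(random, band_width)


class LocalizationComparison:
    """Model: gold-vs-random membrane-distance comparison for a point set.

    Built from measured point tables (or raw points plus profiles); `fit()`
    runs the per-label and pooled comparisons and returns a
    :class:`LocalizationResults`.

    Parameters
    ----------
    gold, random : pandas.DataFrame
        Point tables with a ``distance_nm`` column (see
        :func:`measure_distances`); ``random`` must contain one matched
        random point per gold particle.
    bin_edges : sequence of float
        Signed-distance bin edges (nm) for the chi-squared test and the
        per-bin ratios.
    band_width : float
        Matrix-side band width (nm) for the headline fraction.
    bonferroni : bool
        Multiply per-label p-values by the number of labels (off by
        default; per-protein comparisons are reported uncorrected).
    """

    def __init__(
        self,
        gold: pd.DataFrame,
        random: pd.DataFrame,
        bin_edges=DEFAULT_BIN_EDGES,
        band_width: float = DEFAULT_BAND_WIDTH_NM,
        bonferroni: bool = False,
    ) -> None:
        for name, df in (("gold", gold), ("random", random)):
            if "distance_nm" not in df.columns:
                raise ValueError(f"{name} table lacks distance_nm; run measure_distances first")
        self.gold = gold
        self.random = random
        self.bin_edges = tuple(float(e) for e in bin_edges)
        self.band_width = float(band_width)
        self.bonferroni = bonferroni

    @classmethod
    def from_points(
        cls,
        gold_points: pd.DataFrame,
        random_points: pd.DataFrame,
        profiles: list[MitosomeProfile],
        **kwargs,
    ) -> "LocalizationComparison":
        """Construct from raw coordinates, measuring distances on the way."""
        return cls(
            measure_distances(gold_points, profiles),
            measure_distances(random_points, profiles),
            **kwargs,
        )

    def fit(self) -> "LocalizationResults":
        labels = sorted(self.gold["label"].unique())
        per_label: dict[str, dict] = {}
        for label in labels:
            g = distance_sample(self.gold, label, "gold")
            r_sel = self.random[self.random["label"].isin([label, "random"])]
            r = DistanceSample(
                label=label, kind="random", distances=r_sel["distance_nm"].to_numpy()
            )
            # a shared random table (label == 'random') is matched per label
            if r.n != g.n and (self.random["label"] == label).any():
                r = distance_sample(self.random, label, "random")
            tests, band_g, band_r = compare_to_null(
                g, r, self.bin_edges, self.band_width
            )
            ratios, defined = label_to_random_ratio(
                bin_distances(g, self.bin_edges), bin_distances(r, self.bin_edges)
            )
            per_label[label] = dict(
                tests=tests, band_gold=band_g, band_random=band_r,
                ratios=ratios, ratios_defined=defined, n=g.n,
            )
        pooled_gold = DistanceSample(
            "pooled", "gold", self.gold["distance_nm"].to_numpy()
        )
        pooled_random = DistanceSample(
            "pooled", "random", self.random["distance_nm"].to_numpy()
        )
        tests, band_g, band_r = compare_to_null(
            pooled_gold, pooled_random, self.bin_edges, self.band_width
        )
        return LocalizationResults(
            model=self,
            per_label=per_label,
            pooled_tests=tests,
            pooled_band_gold=band_g,
            pooled_band_random=band_r,
            pooled_gold=pooled_gold,
            pooled_random=pooled_random,
        )


@dataclass
class LocalizationResults:
    """Results of a :class:`LocalizationComparison` fit."""

    model: LocalizationComparison
    per_label: dict
    pooled_tests: NullComparison
    pooled_band_gold: BandStatistic
    pooled_band_random: BandStatistic
    pooled_gold: DistanceSample
    pooled_random: DistanceSample

    def _maybe_correct(self, p: float) -> float:
        if self.model.bonferroni:
            return min(1.0, p * max(1, len(self.per_label)))
        return p

    def summary(self) -> pd.DataFrame:
        """One row per label plus the pooled row."""
        rows = []
        for label, res in self.per_label.items():
            t: NullComparison = res["tests"]
            rows.append(
                dict(
                    label=label,
                    n=res["n"],
                    band_inside_gold=res["band_gold"].fraction_inside,
                    band_inside_random=res["band_random"].fraction_inside,
                    ks_D=t.ks_statistic,
                    ks_p=self._maybe_correct(t.ks_p),
                    mw_U=t.mw_statistic,
                    mw_p=self._maybe_correct(t.mw_p),
                    chi2=t.chi2_statistic,
                    chi2_df=t.chi2_df,
                    chi2_p=self._maybe_correct(t.chi2_p),
                )
            )
        t = self.pooled_tests
        rows.append(
            dict(
                label="pooled",
                n=self.pooled_gold.n,
                band_inside_gold=self.pooled_band_gold.fraction_inside,
                band_inside_random=self.pooled_band_random.fraction_inside,
                ks_D=t.ks_statistic,
                ks_p=t.ks_p,
                mw_U=t.mw_statistic,
                mw_p=t.mw_p,
                chi2=t.chi2_statistic,
                chi2_df=t.chi2_df,
                chi2_p=t.chi2_p,
            )
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-serialisable report."""
        def _tests(t: NullComparison) -> dict:
            return dict(
                ks=dict(D=t.ks_statistic, p=t.ks_p),
                mann_whitney=dict(U=t.mw_statistic, p=t.mw_p),
                chi2=dict(stat=t.chi2_statistic, df=t.chi2_df, p=t.chi2_p),
            )

        report = dict(
            band_width_nm=self.model.band_width,
            bin_edges_nm=list(self.model.bin_edges),
            pooled=dict(
                n=self.pooled_gold.n,
                tests=_tests(self.pooled_tests),
                band_inside_gold=self.pooled_band_gold.fraction_inside,
                band_inside_random=self.pooled_band_random.fraction_inside,
            ),
            per_label={},
        )
        for label, res in self.per_label.items():
            report["per_label"][label] = dict(
                n=res["n"],
                tests=_tests(res["tests"]),
                band_inside_gold=res["band_gold"].fraction_inside,
                band_inside_random=res["band_random"].fraction_inside,
                gold_per_random_ratio=[
                    None if not ok else float(v)
                    for v, ok in zip(res["ratios"], res["ratios_defined"])
                ],
            )
        return report

    def plot_cumulative(self, ax=None):
        """Pooled cumulative-fraction curves for gold and random points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sample, style, name in (
            (self.pooled_gold, "-", "ISC labelling"),
            (self.pooled_random, "--", "random"),
        ):
            x, f = cumulative_fraction(sample)
            ax.step(x, f, style, where="post", label=name)
        ax.set_xlabel("signed distance to inner membrane (nm)")
        ax.set_ylabel("cumulative fraction")
        ax.legend()
        return ax
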