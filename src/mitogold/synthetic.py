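"""Synthetic EM fields: mitosome profiles, compartment polygons, gold points.

The study's raw micrograph coordinates were never deposited, so this module
generates fields that emulate the published sampling universe: elliptical
double-membrane mitosome profiles with minor-axis diameters in 47-119 nm and
major-axis diameters in 78-267 nm (means 80 and 127 nm), embedded in a cell
with a nuclear profile, and immunogold point sets whose per-protein counts
default to the published ones (ThIsu1 79, ThNfs1 66, ThYah1 37, ThYfh1 63,
ThIsd11 50).

Axis diameters are drawn from scaled Beta distributions on the stated
ranges with shape parameters chosen so the means equal 80 and 127 nm (a
triangular law on the major-axis range cannot reach a mean of 127 nm, since
even the most left-skewed triangular distribution on [78, 267] has mean
141 nm).

Gold placement laws are a test harness, not a biological claim: the true
spatial law of ISC labelling is unknown.  Supported laws:

``matrix_uniform``
    uniform over the matrix (inside the inner-aspect ellipse);
``membrane_proximal``
    matrix points with density proportional to exp(-d/lambda) in the signed
    distance d >= 0 to the inner aspect (rejection sampling);
``profile_uniform``
    uniform over the whole profile up to the outer boundary;
``cytosol_uniform``
    uniform over the cytoplasm polygon, outside mitosomes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point as ShapelyPoint, Polygon

from .geometry import (
    MAJOR_DIAMETER_RANGE,
    MINOR_DIAMETER_RANGE,
    MitosomeProfile,
    Point2D,
    points_in_ellipse,
    signed_distances,
)

__all__ = [
    "FieldConfig",
    "GoldPlacementLaw",
    "DEFAULT_GOLD_COUNTS",
    "POINT_COLUMNS",
    "generate_field",
    "generate_fields",
    "generate_gold",
    "sample_random_points",
    "matched_random_points",
    "sample_fields_sur",
]

#: Published per-protein gold counts over mitosome profiles.
DEFAULT_GOLD_COUNTS: dict[str, int] = {
    "ThIsu1": 79,
    "ThNfs1": 66,
    "ThYah1": 37,
    "ThYfh1": 63,
    "ThIsd11": 50,
}

#: Canonical column order of a point-set table.
POINT_COLUMNS = [
    "point_id",
    "field_id",
    "profile_id",
    "label",
    "kind",
    "x_nm",
    "y_nm",
    "diameter_nm",
]

#: Colloidal gold marker diameter (protein-A gold), nm.  Metadata only;
#: positions always refer to the particle centre.
GOLD_DIAMETER_NM = 10.0

_MAX_REJECTION_PROPOSALS = 10_000_000

# Beta shapes for axis diameters, alpha fixed at 2, beta solved from the
# target mean position within the range.
_MINOR_MEAN = 80.0
_MAJOR_MEAN = 127.0


def _beta_shapes(lo: float, hi: float, mean: float, alpha: float = 2.0) -> tuple[float, float]:
    m = (mean - lo) / (hi - lo)
    if not 0.0 < m < 1.0:
        raise ValueError("target mean outside range")
    return alpha, alpha * (1.0 - m) / m


@dataclass(frozen=True)
class FieldConfig:
    """Parameters of a synthetic micrograph field.

    The cell is a circular plasma-membrane profile containing a circular
    nuclear profile; mitosome profiles are scattered uniformly over the
    cytoplasm without overlap.  Lengths in nm.
    """

    n_fields: int = 3
    profiles_per_field: int = 8
    membrane_inset: float = 15.0
    minor_diameter_range: tuple[float, float] = MINOR_DIAMETER_RANGE
    major_diameter_range: tuple[float, float] = MAJOR_DIAMETER_RANGE
    minor_diameter_mean: float = _MINOR_MEAN
    major_diameter_mean: float = _MAJOR_MEAN
    cell_radius: float = 900.0
    nucleus_radius: float = 280.0
    nucleus_offset: tuple[float, float] = (320.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 0 or self.profiles_per_field < 0:
            raise ValueError("counts must be >= 0")
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be smaller than cell_radius")


@dataclass(frozen=True)
class GoldPlacementLaw:
    """Spatial law and per-label counts for synthetic gold placement."""

    law: str = "matrix_uniform"
    scale_nm: float = 10.0  # lambda of the membrane_proximal exponential
    counts_per_label: dict[str, int] = dataclass_field(
        default_factory=lambda: dict(DEFAULT_GOLD_COUNTS)
    )
    contamination_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.law not in ("matrix_uniform", "membrane_proximal", "profile_uniform", "cytosol_uniform"):
            raise ValueError(f"unknown placement law {self.law!r}")
        if self.scale_nm <= 0:
            raise ValueError("scale_nm must be > 0")
        if any(c < 0 for c in self.counts_per_label.values()):
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be in [0, 1]")


def _sample_axes(cfg: FieldConfig, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (semi_minor, semi_major) pairs honouring ranges, means and ordering."""
    lo_b, hi_b = cfg.minor_diameter_range
    lo_a, hi_a = cfg.major_diameter_range
    ab_min, bb_min = _beta_shapes(lo_b, hi_b, cfg.minor_diameter_mean)
    ab_maj, bb_maj = _beta_shapes(lo_a, hi_a, cfg.major_diameter_mean)
    minor = lo_b + (hi_b - lo_b) * rng.beta(ab_min, bb_min, size=n)
    major = lo_a + (hi_a - lo_a) * rng.beta(ab_maj, bb_maj, size=n)
    # enforce major >= minor by redrawing the major axis where violated
    for _ in range(1000):
        bad = major < minor
        if not np.any(bad):
            break
        major[bad] = lo_a + (hi_a - lo_a) * rng.beta(ab_maj, bb_maj, size=int(bad.sum()))
    else:  # pragma: no cover - astronomically unlikely with defaults
        major = np.maximum(major, minor)
    return minor / 2.0, major / 2.0


def _circle_polygon(cx: float, cy: float, r: float, n: int = 256) -> Polygon:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def generate_field(
    config: FieldConfig,
    field_id: str = "F0",
    rng: np.random.Generator | None = None,
) -> tuple[list[MitosomeProfile], dict[str, Polygon]]:
    """Generate one field: non-overlapping mitosome profiles + compartments.

    Returns (profiles, compartments) where compartments maps
    ``cell`` / ``nucleus`` / ``cytoplasm`` to shapely polygons; the
    cytoplasm polygon is the cell minus the nucleus (mitosomes are excluded
    from cytoplasm area at measurement time by the stereology module).

    Raises ``RuntimeError`` when the requested number of profiles cannot be
    placed without overlap after bounded retries.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    cell = _circle_polygon(0.0, 0.0, config.cell_radius)
    nucleus = _circle_polygon(config.nucleus_offset[0], config.nucleus_offset[1], config.nucleus_radius)
    cytoplasm = cell.difference(nucleus)
    compartments = {"cell": cell, "nucleus": nucleus, "cytoplasm": cytoplasm}

    n = config.profiles_per_field
    profiles: list[MitosomeProfile] = []
    if n == 0:
        return profiles, compartments

    semi_minor, semi_major = _sample_axes(config, n, rng)
    placed: list[tuple[float, float, float]] = []  # (cx, cy, clearance radius)
    max_tries = 2000 * n
    tries = 0
    for i in range(n):
        r_clear = semi_major[i]
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"infeasible layout: placed {len(profiles)}/{n} profiles "
                    f"after {max_tries} proposals"
                )
            rr = config.cell_radius * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            cx, cy = rr * math.cos(th), rr * math.sin(th)
            # bounding circle inside the cell, clear of the nucleus
            if rr + r_clear > config.cell_radius:
                continue
            dn = math.hypot(cx - config.nucleus_offset[0], cy - config.nucleus_offset[1])
            if dn < config.nucleus_radius + r_clear:
                continue
            if any(math.hypot(cx - px, cy - py) < r_clear + pr for px, py, pr in placed):
                continue
            break
        theta = rng.uniform(0.0, math.pi)
        profiles.append(
            MitosomeProfile(
                profile_id=f"{field_id}_m{i}",
                field_id=field_id,
                center=Point2D(cx, cy),
                semi_major_outer=float(semi_major[i]),
                semi_minor_outer=float(semi_minor[i]),
                orientation=float(theta),
                membrane_inset=config.membrane_inset,
            )
        )
        placed.append((cx, cy, r_clear))
    return profiles, compartments


def generate_fields(
    config: FieldConfig,
) -> tuple[list[MitosomeProfile], dict[str, dict[str, Polygon]]]:
    """Generate ``config.n_fields`` independent fields from one seed."""
    rng = np.random.default_rng(config.rng_seed)
    all_profiles: list[MitosomeProfile] = []
    all_compartments: dict[str, dict[str, Polygon]] = {}
    for k in range(config.n_fields):
        fid = f"F{k}"
        profiles, comps = generate_field(config, field_id=fid, rng=rng)
        all_profiles.extend(profiles)
        all_compartments[fid] = comps
    return all_profiles, all_compartments


def _uniform_in_ellipse(profile: MitosomeProfile, boundary: str, n: int, rng: np.random.Generator):
    a, b = profile.semi_axes(boundary)
    if a <= 0 or b <= 0:
        raise ValueError("zero-area target region")
    r = np.sqrt(rng.uniform(size=n))
    t = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return profile.from_frame(a * r * np.cos(t), b * r * np.sin(t))


def _membrane_proximal(profile: MitosomeProfile, lam: float, n: int, rng: np.random.Generator):
    """Rejection sampler: matrix points with density ~ exp(-d/lam), d >= 0."""
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    proposals = 0
    while got < n:
        m = max(4 * (n - got), 256)
        proposals += m
        if proposals > _MAX_REJECTION_PROPOSALS:
            raise RuntimeError("rejection sampling budget exhausted")
        px, py = _uniform_in_ellipse(profile, "inner", m, rng)
        d = signed_distances(px, py, profile)
        acc = rng.uniform(size=m) < np.exp(-np.maximum(d, 0.0) / lam)
        k = min(int(acc.sum()), n - got)
        idx = np.flatnonzero(acc)[:k]
        xs[got : got + k] = px[idx]
        ys[got : got + k] = py[idx]
        got += k
    return xs, ys


def _points_frame(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=POINT_COLUMNS)
    df["x_nm"] = df["x_nm"].astype(float)
    df["y_nm"] = df["y_nm"].astype(float)
    return df


def generate_gold(
    profiles: list[MitosomeProfile],
    law: GoldPlacementLaw,
    seed: int,
    compartments: dict[str, Polygon] | None = None,
) -> pd.DataFrame:
    """Place synthetic gold particles according to ``law``.

    Each particle is assigned to a profile with probability proportional to
    the area of its target region; ``counts_per_label`` are honoured
    exactly.  ``contamination_fraction`` of each label's count is placed
    uniformly over the cytoplasm instead (requires ``compartments``).
    Returns a point-set table with :data:`POINT_COLUMNS`.
    """
    rng = np.random.default_rng(seed)
    total = sum(law.counts_per_label.values())
    needs_profiles = law.law != "cytosol_uniform" and law.contamination_fraction < 1.0
    if total > 0 and needs_profiles and not profiles:
        raise ValueError("at least one profile required for intra-mitosome placement")

    if profiles:
        boundary = "inner" if law.law in ("matrix_uniform", "membrane_proximal") else "outer"
        areas = np.array([math.pi * np.prod(p.semi_axes(boundary)) for p in profiles])
        weights = areas / areas.sum()

    records: list[dict] = []
    pid = 0
    for label in sorted(law.counts_per_label):
        count = law.counts_per_label[label]
        n_cyto = int(round(count * law.contamination_fraction))
        if law.law == "cytosol_uniform":
            n_cyto = count
        n_mito = count - n_cyto
        if n_mito > 0:
            assignment = rng.choice(len(profiles), size=n_mito, p=weights)
            for j in np.unique(assignment):
                prof = profiles[j]
                k = int(np.sum(assignment == j))
                if law.law == "membrane_proximal":
                    x, y = _membrane_proximal(prof, law.scale_nm, k, rng)
                elif law.law == "matrix_uniform":
                    x, y = _uniform_in_ellipse(prof, "inner", k, rng)
                else:
                    x, y = _uniform_in_ellipse(prof, "outer", k, rng)
                for xi, yi in zip(np.atleast_1d(x), np.atleast_1d(y)):
                    records.append(
                        dict(
                            point_id=f"g{pid}",
                            field_id=prof.field_id,
                            profile_id=prof.profile_id,
                            label=label,
                            kind="gold",
                            x_nm=float(xi),
                            y_nm=float(yi),
                            diameter_nm=GOLD_DIAMETER_NM,
                        )
                    )
                    pid += 1
        if n_cyto > 0:
            if compartments is None or "cytoplasm" not in compartments:
                raise ValueError("cytoplasm compartment required for cytosolic placement")
            cyto = compartments["cytoplasm"]
            minx, miny, maxx, maxy = cyto.bounds
            got = 0
            proposals = 0
            while got < n_cyto:
                proposals += 1
                if proposals > _MAX_REJECTION_PROPOSALS:
                    raise RuntimeError("rejection sampling budget exhausted")
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if not cyto.contains(ShapelyPoint(x, y)):
                    continue
                if any(points_in_ellipse(x, y, p, "outer") for p in profiles):
                    continue
                records.append(
                    dict(
                        point_id=f"g{pid}",
                        field_id=profiles[0].field_id if profiles else "F0",
                        profile_id="",
                        label=label,
                        kind="gold",
                        x_nm=x,
                        y_nm=y,
                        diameter_nm=GOLD_DIAMETER_NM,
                    )
                )
                pid += 1
                got += 1
    return _points_frame(records)


def sample_random_points(profile: MitosomeProfile, n: int, seed: int) -> pd.DataFrame:
    """Uniform random points over the whole profile (closed outer boundary).

    These are the null reference against which gold distributions are
    compared; each point carries the profile it was placed over.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    x, y = _uniform_in_ellipse(profile, "outer", n, rng)
    records = [
        dict(
            point_id=f"r{i}",
            field_id=profile.field_id,
            profile_id=profile.profile_id,
            label="random",
            kind="random",
            x_nm=float(x[i]),
            y_nm=float(y[i]),
            diameter_nm=0.0,
        )
        for i in range(n)
    ]
    return _points_frame(records)


def matched_random_points(
    gold: pd.DataFrame, profiles: list[MitosomeProfile], seed: int
) -> pd.DataFrame:
    """One random point per gold particle, over the same profile.

    Reproduces the matched-null design: for every labelled profile, as many
    uniform random points as gold particles, placed over that profile.
    """
    by_id = {p.profile_id: p for p in profiles}
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    offset = 0
    grouped = gold[gold["profile_id"] != ""].groupby(["label", "profile_id"], sort=True)
    for (label, prof_id), grp in grouped:
        prof = by_id[prof_id]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pts = sample_random_points(prof, len(grp), sub_seed)
        pts["label"] = label
        pts["point_id"] = [f"r{offset + i}" for i in range(len(pts))]
        offset += len(pts)
        frames.append(pts)
    if not frames:
        return _points_frame([])
    return pd.concat(frames, ignore_index=True)


def sample_fields_sur(fields: list, step: int, seed: int) -> list:
    """Systematic uniform random subsample: every ``step``-th field from a
    uniformly random start in [0, step)."""
    if not fields:
        raise ValueError("empty field list")
    if step < 1:
        raise ValueError("step must be >= 1")
    start = int(np.random.default_rng(seed).integers(0, step))
    return list(fields[start::step])
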