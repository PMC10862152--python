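"""Synthetic cohorts and geometric phantoms for the growth analysis.

Two generative modes are provided, with different jobs:

* **band-wise** (mode A): each sex × age-band group draws every variable
  from a log-normal whose parameters are moment-matched to a published
  summary table (mean/SD per group). Two refinements make the draws
  behave like growth data rather than iid group noise, while leaving
  the group-level moments at their calibration targets:

  - the log-mean is interpolated linearly in age between band midpoints
    (children keep growing inside a 2.5-year band), and the residual
    log-SD is shrunk by the variance the age trend now explains, so the
    band's total variance still matches the calibrated value;
  - within a participant the residual log-scale deviations share a
    common latent size factor (bigger children have uniformly bigger
    muscles and longer bones), giving the between-muscle correlations
    that volumetric data always show without touching any marginal
    mean or SD.

  Simulated group means and SDs converge to the calibration targets as
  n grows — this mode *looks like* the normative data and inherits its
  (asynchronous) between-band growth pattern.

* **allometric** (mode B): a structural model with a known truth,
  ``log V_m = a_m + b_m·log S + ε_m``, where the latent size ``S`` is
  tibia length (itself a monotone function of age plus noise) and
  ``ε_m ~ N(0, σ_m²)`` independently. The per-muscle exponents ``b_m``
  are the dial: all equal ⇒ muscles grow in synchrony (the isometric
  null holds); spread out ⇒ asynchronous growth with a recoverable
  exponent ratio ``b_k/b_j`` for every muscle pair. Used for size and
  power studies of the isometry test.

Log-normal moment matching: for a target mean μ > 0 and SD s > 0 the
log-scale parameters are σ² = ln(1 + s²/μ²) and m = ln μ − σ²/2, so the
log-normal's first two moments equal (μ, s²) exactly.

All randomness flows through one ``numpy.random.Generator`` created from
an explicit seed; a fixed seed gives a bitwise-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COLUMNS, empty_cohort, validate_cohort, volume_col
from .morphometry import LabelVolume
from .muscles import AGE_BANDS, MUSCLES, SEXES, validate_bands
from .reference import COVARIATES, GROUP_N, reference_summary

#: QC-exclusion rate: two motion-corrupted scans out of 210 recruits.
DEFAULT_ARTEFACT_PROB = 2.0 / 210.0

#: Anchor size (cm) at which mode-B intercepts reproduce the boys'
#: [5, 7.5) reference mean volumes, whatever the exponents.
_ANCHOR_TIBIA_CM = 26.1

#: Linear tibia growth curve, cm: ~10 cm at birth, ~40 cm at 15 y.
_TIBIA_BASE_CM = 9.9
_TIBIA_SLOPE_CM_PER_Y = 2.05
_TIBIA_NOISE_LOG_SD = 0.04

#: Age band 3 months - 5 years that normative cohorts typically cannot
#: scan; can be generated on request for exploration.
GAP_BAND: tuple[float, float] = (0.3, 5.0)


class ConfigError(ValueError):
    """Invalid generator configuration."""


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (log-mean, log-SD) for a log-normal.

    ``sd == 0`` degenerates to a point mass at ``mean`` (log-SD 0).
    """
    if mean <= 0 or sd < 0:
        raise ConfigError(f"invalid summary moments mean={mean}, sd={sd}")
    var_log = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - var_log / 2.0), float(np.sqrt(var_log))


@dataclass
class GrowthModelSpec:
    """Parameters of the synthetic growth model.

    ``mode`` selects band-wise ("bandwise") or structural allometric
    ("allometric") generation; only the matching parameter block is
    used. ``girl_volume_factor`` multiplies girls' volumes in mode B
    (girls run slightly smaller in normative data).
    """

    mode: str
    muscles: tuple[str, ...] = MUSCLES
    age_bands: tuple[tuple[float, float], ...] = AGE_BANDS
    artefact_prob: float = DEFAULT_ARTEFACT_PROB
    # mode A: {(sex, band_index, variable): (log_mean, log_sd)}
    band_params: dict[tuple[str, int, str], tuple[float, float]] = field(default_factory=dict)
    #: mode A: loading of the shared within-participant size factor on
    #: each variable's log-scale deviation; between-variable log
    #: correlation is the loading squared (0.85² ≈ 0.72, the order seen
    #: between muscle volumes in whole-limb morphometry)
    shared_factor_loading: float = 0.85
    #: mode A: interpolate log-means linearly in age between band
    #: midpoints (False falls back to constant-within-band draws)
    age_interpolation: bool = True
    #: mode A: per-(sex, band, variable) d(log-mean)/d(age), computed by
    #: calibrate_from_summary from neighbouring band midpoints
    band_slopes: dict[tuple[str, int, str], float] = field(default_factory=dict)
    # mode B
    exponents: dict[str, float] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    girl_volume_factor: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("bandwise", "allometric"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if len(set(self.muscles)) != len(self.muscles) or len(self.muscles) != 10:
            raise ConfigError("exactly 10 unique muscle codes required")
        validate_bands(self.age_bands)
        if not 0 <= self.artefact_prob <= 1:
            raise ConfigError("artefact_prob must be a probability")
        if not 0 <= self.shared_factor_loading < 1:
            raise ConfigError("shared_factor_loading must be in [0, 1)")
        if self.mode == "allometric":
            for m in self.muscles:
                if self.sigma.get(m, 0.0) <= 0:
                    raise ConfigError(f"sigma must be positive for muscle {m}")
                if m not in self.exponents or m not in self.intercepts:
                    raise ConfigError(f"missing allometric parameters for muscle {m}")

    @property
    def synchronous(self) -> bool:
        """True iff all allometric exponents are equal (isometric null)."""
        if self.mode != "allometric":
            return False
        b = [self.exponents[m] for m in self.muscles]
        return bool(np.allclose(b, b[0]))


def calibrate_from_summary(summary: pd.DataFrame | None = None) -> GrowthModelSpec:
    """Mode-A spec moment-matched to a group summary table.

    Parameters
    ----------
    summary
        Tidy table with columns ``sex, band_lo, band_hi, variable,
        mean, sd`` (one row per group × variable); defaults to the
        embedded normative reference. Means must be positive and SDs
        non-negative.
    """
    if summary is None:
        summary = reference_summary()
    required = {"sex", "band_lo", "band_hi", "variable", "mean", "sd"}
    if not required <= set(summary.columns):
        raise ConfigError(f"summary table needs columns {sorted(required)}")
    bands = sorted({(float(r.band_lo), float(r.band_hi)) for r in summary.itertuples()})
    spec = GrowthModelSpec(mode="bandwise", age_bands=tuple(bands))
    band_index = {b: i for i, b in enumerate(bands)}
    needed = set(MUSCLES) | {"tibia_length", "fibula_length"}
    for r in summary.itertuples():
        if r.variable in ("age", "TSURAE", "TOTAL"):
            continue  # age is drawn uniformly in-band; aggregates are derived
        i = band_index[(float(r.band_lo), float(r.band_hi))]
        spec.band_params[(r.sex, i, r.variable)] = lognormal_params(float(r.mean), float(r.sd))
    for sex in SEXES:
        for i in range(len(bands)):
            missing = {v for v in needed if (sex, i, v) not in spec.band_params}
            if missing:
                raise ConfigError(f"summary incomplete for {sex}, band {bands[i]}: {sorted(missing)}")
    # d(log-mean)/d(age) per band from the midpoints of *contiguous*
    # neighbouring bands only (central differences inside a contiguous
    # run, one-sided at its ends, zero for an isolated band): a slope
    # taken across the unscanned 0.3-5 y gap would ascribe the whole
    # infancy-to-childhood jump to within-band growth
    mids = [0.5 * (lo + hi) for lo, hi in bands]
    variables = {v for (_, _, v) in spec.band_params}
    contiguous = [
        [
            j
            for j in (i - 1, i + 1)
            if 0 <= j < len(bands)
            and (bands[i][0] == bands[j][1] or bands[i][1] == bands[j][0])
        ]
        for i in range(len(bands))
    ]
    for sex in SEXES:
        for var in variables:
            mu = [spec.band_params[(sex, i, var)][0] for i in range(len(bands))]
            for i, nbrs in enumerate(contiguous):
                if nbrs:
                    j_lo, j_hi = min(nbrs + [i]), max(nbrs + [i])
                    slope = (mu[j_hi] - mu[j_lo]) / (mids[j_hi] - mids[j_lo])
                else:
                    slope = 0.0
                spec.band_slopes[(sex, i, var)] = slope
    return spec


def _default_intercepts(exponents: dict[str, float]) -> dict[str, float]:
    """Intercepts anchoring mode-B volumes to reference means at the
    anchor tibia length, so simulated volumes stay physiological for
    any choice of exponents."""
    ref = reference_summary()
    anchor = ref[(ref.sex == "boy") & (ref.band_lo == 5.0)].set_index("variable")["mean"]
    log_t0 = np.log(_ANCHOR_TIBIA_CM)
    return {m: float(np.log(anchor[m]) - exponents[m] * log_t0) for m in MUSCLES}


def synchronous_spec(
    exponent: float = 1.0,
    sigma: float = 0.15,
    include_gap: bool = False,
) -> GrowthModelSpec:
    """Mode-B spec under the isometric null: one shared exponent.

    Residual log-SD is equal across muscles by design: with a shared
    exponent and homogeneous residuals the population covariance of the
    log volumes is ``b²σ_S²·11ᵀ + σ²I``, whose leading eigenvector is
    exactly the isometric direction — the null the joint test targets.
    """
    return allometric_spec({m: exponent for m in MUSCLES}, sigma=sigma, include_gap=include_gap)


def asynchronous_spec(
    spread: tuple[float, float] = (0.7, 1.3),
    sigma: float = 0.15,
    include_gap: bool = False,
) -> GrowthModelSpec:
    """Mode-B spec with exponents spread evenly over ``spread``."""
    lo, hi = spread
    b = np.linspace(lo, hi, len(MUSCLES))
    return allometric_spec(dict(zip(MUSCLES, map(float, b))), sigma=sigma, include_gap=include_gap)


def allometric_spec(
    exponents: dict[str, float],
    sigma: float | dict[str, float] = 0.15,
    include_gap: bool = False,
) -> GrowthModelSpec:
    """General mode-B spec from per-muscle exponents."""
    if isinstance(sigma, (int, float)):
        sigma = {m: float(sigma) for m in MUSCLES}
    bands = AGE_BANDS if not include_gap else tuple(sorted(AGE_BANDS + (GAP_BAND,)))
    return GrowthModelSpec(
        mode="allometric",
        age_bands=bands,
        exponents=dict(exponents),
        intercepts=_default_intercepts(dict(exponents)),
        sigma=dict(sigma),
    )


def reference_group_sizes() -> dict[str, tuple[int, ...]]:
    """Published per-band group sizes, per sex (bands in spec order)."""
    return {sex: tuple(GROUP_N[sex]) for sex in SEXES}


def simulate_cohort(
    spec: GrowthModelSpec,
    n_per_group: dict[str, tuple[int, ...]] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Parameters
    ----------
    spec
        Generative model (band-wise or allometric).
    n_per_group
        ``{sex: counts}`` with one count per band of ``spec.age_bands``;
        defaults to the published group sizes.
    seed
        Integer seed or a ``numpy.random.Generator``.

    Returns
    -------
    A validated cohort DataFrame; bitwise-reproducible for a fixed
    integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_per_group is None:
        n_per_group = reference_group_sizes()
    unknown = set(n_per_group) - set(SEXES)
    if unknown:
        raise ConfigError(f"unknown sex keys in n_per_group: {sorted(unknown)}")
    for sex, counts in n_per_group.items():
        if len(counts) != len(spec.age_bands):
            raise ConfigError(
                f"{sex}: {len(counts)} counts for {len(spec.age_bands)} age bands"
            )

    rows: list[dict] = []
    pid = 0
    for sex in SEXES:
        counts = n_per_group.get(sex, (0,) * len(spec.age_bands))
        for band_i, ((lo, hi), n) in enumerate(zip(spec.age_bands, counts)):
            for _ in range(int(n)):
                pid += 1
                age = float(rng.uniform(lo, hi))
                row: dict = {
                    "participant": f"P{pid:04d}",
                    "sex": sex,
                    "age": age,
                    "body_mass": np.nan,
                    "height": np.nan,
                }
                if spec.mode == "bandwise":
                    rho = spec.shared_factor_loading
                    resid_scale = float(np.sqrt(1.0 - rho * rho))
                    z_size = float(rng.normal())  # shared latent size factor
                    mid = 0.5 * (lo + hi)
                    age_var = (hi - lo) ** 2 / 12.0  # variance of U(lo, hi)

                    def _draw(var: str) -> float:
                        m, s = spec.band_params[(sex, band_i, var)]
                        slope = 0.0
                        if spec.age_interpolation:
                            slope = spec.band_slopes.get((sex, band_i, var), 0.0)
                        # keep the band's total log-variance at s²: the
                        # age trend explains slope²·age_var of it
                        s_res = np.sqrt(max(s * s - slope * slope * age_var, (0.2 * s) ** 2))
                        # exact-mean adjustment: E[e^{slope(a-mid)}] over
                        # a ~ U(lo, hi) is sinh(u)/u, and the residual
                        # log-variance changed from s² to s_res²
                        u = slope * (hi - lo) / 2.0
                        mean_corr = float(np.log(np.sinh(u) / u)) if u != 0.0 else 0.0
                        m_eff = m + (s * s - s_res * s_res) / 2.0 - mean_corr
                        dev = rho * z_size + resid_scale * float(rng.normal())
                        return float(np.exp(m_eff + slope * (age - mid) + s_res * dev))

                    for var in ("body_mass", "height", "tibia_length", "fibula_length"):
                        if (sex, band_i, var) in spec.band_params:
                            row[var] = _draw(var)
                    for mu in spec.muscles:
                        row[volume_col(mu)] = _draw(mu)
                else:
                    tibia = (_TIBIA_BASE_CM + _TIBIA_SLOPE_CM_PER_Y * age) * float(
                        np.exp(rng.normal(0.0, _TIBIA_NOISE_LOG_SD))
                    )
                    row["tibia_length"] = tibia
                    row["fibula_length"] = 0.97 * tibia
                    log_s = np.log(tibia)
                    sex_off = 0.0 if sex == "boy" else float(np.log(spec.girl_volume_factor))
                    for mu in spec.muscles:
                        log_v = (
                            spec.intercepts[mu]
                            + spec.exponents[mu] * log_s
                            + sex_off
                            + rng.normal(0.0, spec.sigma[mu])
                        )
                        row[volume_col(mu)] = float(np.exp(log_v))
                row["motion_artefact"] = bool(rng.random() < spec.artefact_prob)
                row["included"] = True
                rows.append(row)
    if not rows:
        return empty_cohort()
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df["participant"] = df["participant"].astype("string")
    df["sex"] = df["sex"].astype("string")
    return validate_cohort(df)


# ---------------------------------------------------------------------------
# Geometric phantoms
# ---------------------------------------------------------------------------


class OverlapError(ValueError):
    """Two phantom shapes with different labels claim the same voxel."""


@dataclass
class Shape:
    """One phantom shape in physical (mm) coordinates.

    ``size`` is kind-specific: cuboid — full edge lengths (3,);
    ellipsoid — semi-axes (3,); cylinder — (radius, length), axis along
    local z. ``angles`` are extrinsic xyz rotation angles in degrees.
    """

    kind: str
    label: int
    center: tuple[float, float, float]
    size: tuple[float, ...]
    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("cuboid", "ellipsoid", "cylinder"):
            raise ConfigError(f"unknown shape kind {self.kind!r}")
        n_expected = 2 if self.kind == "cylinder" else 3
        if len(self.size) != n_expected or any(s <= 0 for s in self.size):
            raise ConfigError(f"{self.kind} needs {n_expected} positive size parameters")
        if self.label <= 0:
            raise ConfigError("shape labels must be positive integers")

    @property
    def rotation(self) -> np.ndarray:
        """Extrinsic x-y-z rotation matrix (world = R @ local)."""
        ax, ay, az = np.deg2rad(self.angles)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def analytic_volume_cm3(self) -> float:
        if self.kind == "cuboid":
            v = float(np.prod(self.size))
        elif self.kind == "ellipsoid":
            a, b, c = self.size
            v = 4.0 / 3.0 * np.pi * a * b * c
        else:
            r, length = self.size
            v = np.pi * r * r * length
        return v / 1000.0

    def analytic_length_cm(self) -> float:
        """Extent along the shape's own principal (longest) axis."""
        if self.kind == "cuboid":
            ext = max(self.size)
        elif self.kind == "ellipsoid":
            ext = 2.0 * max(self.size)
        else:
            r, length = self.size
            ext = max(length, 2.0 * r)
        return ext / 10.0

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Boolean membership for an (n, 3) array of mm coordinates."""
        local = (points_mm - np.asarray(self.center)) @ self.rotation
        if self.kind == "cuboid":
            half = np.asarray(self.size) / 2.0
            return np.all(np.abs(local) <= half, axis=1)
        if self.kind == "ellipsoid":
            semi = np.asarray(self.size)
            return np.sum((local / semi) ** 2, axis=1) <= 1.0
        r, length = self.size
        radial = local[:, 0] ** 2 + local[:, 1] ** 2 <= r * r
        axial = np.abs(local[:, 2]) <= length / 2.0
        return radial & axial


@dataclass
class PhantomSpec:
    """Voxel grid plus the shapes to burn into it."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    structures: tuple[Shape, ...]

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.shape):
            raise ConfigError("grid dimensions must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError("voxel spacing must be positive")
        labels = [s.label for s in self.structures]
        if len(set(labels)) != len(labels):
            raise ConfigError("phantom shapes must carry distinct labels")


def make_phantom(
    spec: PhantomSpec,
    seed: int = 0,
    label_kinds: dict[int, tuple[str, str]] | None = None,
) -> LabelVolume:
    """Voxelize a phantom and record its analytic ground truth.

    Voxel i covers the slab ``[i, i+1) × spacing`` so its center sits at
    ``(i + ½) × spacing``; a voxel belongs to a shape if its center
    does (this keeps a grid-aligned cuboid's voxel count exact). Overlapping shapes (two labels claiming one
    voxel) raise :class:`OverlapError`. ``seed`` is accepted for
    interface symmetry with the cohort generator; clean phantoms are
    deterministic.
    """
    del seed  # phantoms are noise-free
    nx, ny, nz = (int(s) for s in spec.shape)
    sp = np.asarray(spec.spacing, float)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pts = np.stack(
        [(ii.ravel() + 0.5) * sp[0], (jj.ravel() + 0.5) * sp[1], (kk.ravel() + 0.5) * sp[2]],
        axis=1,
    )
    data = np.zeros(nx * ny * nz, dtype=np.int32)
    ground_truth: dict[int, dict[str, float]] = {}
    labels: dict[int, tuple[str, str]] = {}
    for shape in spec.structures:
        mask = shape.contains(pts)
        clash = mask & (data != 0)
        if clash.any():
            other = int(data[clash][0])
            raise OverlapError(f"shapes {other} and {shape.label} overlap")
        data[mask] = shape.label
        ground_truth[shape.label] = {
            "volume_cm3": shape.analytic_volume_cm3(),
            "length_cm": shape.analytic_length_cm(),
        }
        default = (f"S{shape.label}", "muscle")
        labels[shape.label] = (label_kinds or {}).get(shape.label, default)
    return LabelVolume(
        data=data.reshape(nx, ny, nz),
        spacing=tuple(map(float, sp)),
        labels=labels,
        ground_truth=ground_truth,
    )
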