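"""Synthetic study data with the statistical structure the analysis assumes.

Three generators stand in for the field data:

* :func:`gen_specimens` — two kangaroo populations differing in sample
  size, female proportion, age span and growth rate.  Ages are drawn
  uniformly on each population's range, the molar index is back-solved
  through the inverse of the aging curve, and each size trait follows a
  sex- and population-specific von Bertalanffy curve plus Gaussian noise.
* :func:`gen_landmarks` — bilaterally symmetric landmark "crania": a
  labelled symmetric point cloud (no anatomical realism intended) scaled
  to a centroid size that grows with age, deformed along a fixed
  allometric vector proportional to log centroid size, plus symmetric
  individual variation and optional mirrored-antisymmetric noise.
* :func:`gen_evi` — two-site 16-day vegetation-index series with a
  seasonal cycle, AR(1) noise and a south-minus-north offset.  The
  default baseline sits just above zero, as in arid rangeland, so the
  pipeline's zero-clamping floor truncates the drier (north) site much
  more often than the offset-lifted south.  That truncation is what
  makes a constant site offset visible to the anomaly analysis at all:
  standardizing each cell against its own calendar-month climatology
  would cancel a constant offset exactly if the series never touched
  the floor, whereas the clamped north months become left-censored and
  their anomaly medians skew negative.  ``offset_onset`` optionally
  delays the offset to a later date for step-change experiments.

All generators are fully reproducible from their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .core_io import (
    ConfigError,
    DAYS_PER_YEAR,
    LandmarkConfiguration,
    PairingMap,
)
from .demography import molar_index_from_age

TRAITS = ("cranial_size", "weight_kg", "pes_length_cm")


@dataclass
class PopulationSpec:
    """Generating parameters for one kangaroo population."""

    name: str
    n: int
    female_prop: float
    age_range_years: tuple[float, float]
    # vb_params[trait][sex] = (L_inf, k per year, t0 years)
    vb_params: dict[str, dict[str, tuple[float, float, float]]]
    noise_sd: dict[str, float]
    sex_counts: tuple[int, int] | None = None  # exact (n_female, n_male) override

    def __post_init__(self) -> None:
        lo, hi = self.age_range_years
        if not lo < hi:
            raise ConfigError(f"{self.name}: degenerate age range {self.age_range_years}")
        if not 0.0 < self.female_prop < 1.0:
            raise ConfigError(f"{self.name}: female_prop must lie in (0,1)")
        for trait, by_sex in self.vb_params.items():
            for sex, (L, k, _t0) in by_sex.items():
                if L <= 0 or k <= 0:
                    raise ConfigError(f"{self.name}/{trait}/{sex}: need L_inf > 0 and k > 0")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigError(f"{self.name}: noise_sd must be >= 0")
        if self.sex_counts is not None and sum(self.sex_counts) != self.n:
            raise ConfigError(f"{self.name}: sex_counts must sum to n={self.n}")


def _vb(age, L, k, t0):
    return L * (1.0 - np.exp(-k * (np.asarray(age, dtype=float) - t0)))


def default_population_specs(
    k_ratio_common: float = 1.3,
    exact_sex_counts: bool = False,
) -> dict[str, PopulationSpec]:
    """The two-population study conditions the analysis emulates.

    The dingoes-rare population is larger (n=115), female-biased (67.8%)
    and spans a wider age range; the dingoes-common population (n=51,
    39.2% female) grows faster (growth coefficients scaled by
    ``k_ratio_common``) toward the same adult asymptotes, so young
    animals are larger for a given age and the curves converge with age.
    """
    base_vb = {
        "cranial_size": {"female": (600.0, 0.45, -0.6), "male": (720.0, 0.40, -0.6)},
        "weight_kg": {"female": (26.0, 0.55, -0.1), "male": (55.0, 0.35, -0.1)},
        "pes_length_cm": {"female": (47.0, 0.60, -0.5), "male": (56.0, 0.50, -0.5)},
    }
    noise = {"cranial_size": 18.0, "weight_kg": 2.5, "pes_length_cm": 1.8}
    fast_vb = {
        trait: {sex: (L, k * k_ratio_common, t0) for sex, (L, k, t0) in by_sex.items()}
        for trait, by_sex in base_vb.items()
    }
    return {
        "dingoes_rare": PopulationSpec(
            name="dingoes_rare",
            n=115,
            female_prop=78 / 115,
            age_range_years=(0.25, 12.0),
            vb_params=base_vb,
            noise_sd=dict(noise),
            sex_counts=(78, 37) if exact_sex_counts else None,
        ),
        "dingoes_common": PopulationSpec(
            name="dingoes_common",
            n=51,
            female_prop=20 / 51,
            age_range_years=(1.1, 9.5),
            vb_params=fast_vb,
            noise_sd=dict(noise),
            sex_counts=(20, 31) if exact_sex_counts else None,
        ),
    }


def gen_specimens(
    specs: dict[str, PopulationSpec],
    seed: int,
    age_scale: float = 1.0,
) -> pd.DataFrame:
    """Draw a specimen table from two (or more) population specifications.

    Sexes are Bernoulli(female_prop) unless a spec pins exact counts;
    ages are uniform on the population's range; the molar index is the
    exact inverse image of the age under the aging curve; each trait is
    its von Bertalanffy curve value plus Gaussian(0, noise_sd) noise.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for pop_name, spec in specs.items():
        n = spec.n
        if spec.sex_counts is not None:
            sexes = np.array(["female"] * spec.sex_counts[0] + ["male"] * spec.sex_counts[1])
            rng.shuffle(sexes)
        else:
            sexes = np.where(rng.random(n) < spec.female_prop, "female", "male")
        ages = rng.uniform(*spec.age_range_years, size=n)
        df = pd.DataFrame(
            {
                "specimen_id": [f"{pop_name}_{i:03d}" for i in range(n)],
                "property": pop_name,
                "sex": sexes,
                "age_years": ages,
            }
        )
        df["age_days"] = ages * DAYS_PER_YEAR
        df["molar_index"] = molar_index_from_age(df["age_days"].to_numpy(), scale=age_scale)
        for trait in TRAITS:
            vals = np.empty(n)
            for sex in ("female", "male"):
                mask = sexes == sex
                L, k, t0 = spec.vb_params[trait][sex]
                vals[mask] = _vb(ages[mask], L, k, t0)
            sd = spec.noise_sd.get(trait, 0.0)
            if sd > 0:
                vals = vals + rng.normal(0.0, sd, size=n)
            df[trait] = vals
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if out["specimen_id"].duplicated().any():
        raise ConfigError("population names must yield unique specimen ids")
    out["weight_kg"] = out["weight_kg"].clip(lower=0.1)
    out["pes_length_cm"] = out["pes_length_cm"].clip(lower=0.1)
    out["cranial_size"] = out["cranial_size"].clip(lower=1.0)
    out["landmark_ref"] = out["specimen_id"]
    return out


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def symmetric_template(k: int) -> tuple[np.ndarray, PairingMap]:
    """A deterministic bilaterally symmetric point cloud with k landmarks.

    Midline points sit on the x=0 plane; each left point at x<0 has its
    mirror partner at x>0.  ``k`` must be >= 8; an odd count gets one
    extra midline point.
    """
    if k < 8:
        raise ConfigError(f"template needs k >= 8 landmarks, got {k}")
    n_mid = 4 if k % 2 == 0 else 5
    n_pairs = (k - n_mid) // 2
    rng = np.random.default_rng(97531 + k)  # fixed template per k
    mid = np.column_stack([np.zeros(n_mid), rng.uniform(-1, 1, n_mid), np.linspace(-1, 1, n_mid)])
    left = np.column_stack(
        [-rng.uniform(0.4, 1.2, n_pairs), rng.uniform(-1, 1, n_pairs), rng.uniform(-1, 1, n_pairs)]
    )
    right = left * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right, mid])
    pairs = tuple((i, n_pairs + i) for i in range(n_pairs))
    midline = tuple(range(2 * n_pairs, k))
    pairing = PairingMap(pairs=pairs, midline=midline)
    pairing.validate(k)
    coords -= coords.mean(axis=0)
    coords /= np.sqrt(np.sum(coords**2))
    return coords, pairing


def _symmetrize(field_arr: np.ndarray, pairing: PairingMap) -> np.ndarray:
    """Project a per-landmark 3-vector field onto its mirror-symmetric part."""
    out = field_arr.copy()
    refl = field_arr * np.array([-1.0, 1.0, 1.0])
    for left, right in pairing.pairs:
        sym_l = 0.5 * (field_arr[left] + refl[right])
        out[left] = sym_l
        out[right] = sym_l * np.array([-1.0, 1.0, 1.0])
    for m in pairing.midline:
        out[m] = np.array([0.0, field_arr[m][1], field_arr[m][2]])
    return out


def _antisymmetric_field(rng: np.random.Generator, k: int, pairing: PairingMap,
                         sd: float) -> np.ndarray:
    """Noise whose mirrored-relabeled image is its own negation."""
    out = np.zeros((k, 3))
    for left, right in pairing.pairs:
        v = rng.normal(0.0, sd, 3)
        out[left] = v
        out[right] = -(v * np.array([-1.0, 1.0, 1.0]))
    for m in pairing.midline:
        out[m] = np.array([rng.normal(0.0, sd), 0.0, 0.0])
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_landmarks(
    records: pd.DataFrame,
    template_k: int = 12,
    allometric_vector_scale: float = 0.15,
    asym_sd: float = 0.002,
    ind_sd: float = 0.005,
    seed: int = 0,
) -> list[LandmarkConfiguration]:
    """Landmark configurations for every specimen row.

    Each configuration is the symmetric template deformed along a fixed
    allometric vector by ``allometric_vector_scale * (log CS - mean log
    CS)``, plus symmetric individual variation (``ind_sd``, unit-shape
    scale) and antisymmetric noise (``asym_sd``), scaled to the
    specimen's cranial centroid size and arbitrarily rotated/translated.
    """
    if asym_sd < 0:
        raise ConfigError("asym_sd must be >= 0")
    template, pairing = symmetric_template(template_k)
    k = template_k
    # fixed unit allometric direction, mirror-symmetric, orthogonal to template
    vec_rng = np.random.default_rng(86420 + k)
    allo = _symmetrize(vec_rng.normal(size=(k, 3)), pairing)
    allo -= allo.mean(axis=0)
    allo /= np.sqrt(np.sum(allo**2))

    sizes = records["cranial_size"].to_numpy(dtype=float)
    log_cs = np.log(sizes)
    log_cs_centered = log_cs - log_cs.mean()

    rng = np.random.default_rng(seed)
    configs = []
    for i, (_, row) in enumerate(records.iterrows()):
        shape = template + allometric_vector_scale * log_cs_centered[i] * allo
        if ind_sd > 0:
            shape = shape + _symmetrize(rng.normal(0.0, ind_sd, (k, 3)), pairing)
        if asym_sd > 0:
            shape = shape + _antisymmetric_field(rng, k, pairing, asym_sd)
        shape -= shape.mean(axis=0)
        shape /= np.sqrt(np.sum(shape**2))
        coords = sizes[i] * shape @ _random_rotation(rng) + rng.uniform(-50, 50, 3)
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]), coordinates=coords, pairing=pairing
            )
        )
    return configs


# ---------------------------------------------------------------------------
# vegetation index
# ---------------------------------------------------------------------------

SITE_CENTERS = {"north": (-30.362, 140.696), "south": (-31.433, 140.797)}


@dataclass
class EviSimSpec:
    """Generating parameters for the two-site vegetation-index series."""

    n_cells_per_site: int = 4
    baseline: float = 0.03
    site_offset: float = 0.0  # south minus north, index units
    seasonal_amplitude: float = 0.05
    noise_sd: float = 0.04
    ar_coefficient: float = 0.5
    start: date = field(default_factory=lambda: date(2011, 1, 1))
    end: date = field(default_factory=lambda: date(2022, 1, 1))
    cadence_days: int = 16
    offset_onset: date | None = None  # None: offset applies to the whole record

    def __post_init__(self) -> None:
        if self.n_cells_per_site < 1:
            raise ConfigError("need at least one cell per site")
        if self.end <= self.start:
            raise ConfigError(f"end {self.end} must follow start {self.start}")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ConfigError("ar_coefficient must lie in [0, 1)")

    @property
    def marginal_noise_sd(self) -> float:
        """Stationary sd of the AR(1) noise (the 'within-cell sd')."""
        return self.noise_sd / np.sqrt(1.0 - self.ar_coefficient**2)

    def dates(self) -> list[date]:
        out = []
        d = self.start
        step = timedelta(days=self.cadence_days)
        while d < self.end:
            out.append(d)
            d += step
        return out


def gen_evi(spec: EviSimSpec, seed: int) -> pd.DataFrame:
    """Simulate the two-site vegetation-index table.

    evi(t) = baseline + offset * I(south) * I(t >= onset)
             + amplitude * sin(2*pi*doy/365.25) + AR(1) noise.

    Negative values are retained (clamping is the analysis pipeline's
    first step, not the generator's).
    """
    rng = np.random.default_rng(seed)
    dates = spec.dates()
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal = spec.seasonal_amplitude * np.sin(2.0 * np.pi * doy / 365.25)
    onset = spec.offset_onset or spec.start
    offset_on = np.array([d >= onset for d in dates], dtype=float)

    frames = []
    for site in ("north", "south"):
        lat0, lon0 = SITE_CENTERS[site]
        for c in range(spec.n_cells_per_site):
            noise = np.empty(len(dates))
            x = rng.normal(0.0, spec.marginal_noise_sd)
            for t in range(len(dates)):
                x = spec.ar_coefficient * x + rng.normal(0.0, spec.noise_sd)
                noise[t] = x
            evi = spec.baseline + seasonal + noise
            if site == "south":
                evi = evi + spec.site_offset * offset_on
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": f"{site}_{c:02d}",
                        "lat": lat0 + 0.0025 * c,
                        "lon": lon0 + 0.0025 * c,
                        "date": pd.to_datetime(dates),
                        "evi": evi,
                        "site": site,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
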