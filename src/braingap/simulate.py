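"""Synthetic two-cohort study generator.

Builds the world the downstream analyses assume: a smooth brain-like
template, a planted age-related gray-matter-loss signal, a training cohort
of cognitively normal subjects and an older target cohort whose volumes are
generated at an *effective* age (chronological age + a subject-level true
brain-age gap), phenotypes and mortality with site-specific administrative
censoring and CNS vs non-CNS causes, and a SOMAscan-scale protein panel in
which a designated analyte subset is linearly associated with the true gap.

Everything is driven by :class:`~braingap.config.SimConfig` and a seed;
identical inputs reproduce every output bit-identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import SimConfig
from .volumes import GMVolumeSet

__all__ = [
    "Template",
    "GroundTruth",
    "SimulatedStudy",
    "derive_seed",
    "make_template",
    "make_signal_map",
    "simulate_gm_cohort",
    "simulate_phenotypes",
    "simulate_proteins",
    "simulate_study",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

BRAIN_THRESHOLD = 0.1

_CENTER_RACE_LEVELS = ["Forsyth-AA", "Forsyth-W", "Jackson-AA", "Minn-W", "Wash-W"]
_CENTER_RACE_PROBS = [0.05, 0.17, 0.25, 0.30, 0.23]
_SITE_OF_CENTER_RACE = {
    "Forsyth-AA": "Forsyth", "Forsyth-W": "Forsyth", "Jackson-AA": "Jackson",
    "Minn-W": "Minneapolis", "Wash-W": "Washington",
}
_SMOKING_LEVELS = ["current", "former", "never"]
_SMOKING_PROBS = [0.053, 0.477, 0.470]
_EDU_LEVELS = ["basic", "intermediate", "advanced"]
_EDU_PROBS = [0.144, 0.407, 0.449]
# target marginal class mix for cognitive status (CN / MCI / dementia)
_COG_MIX = (0.63, 0.32, 0.05)


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from a global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class Template:
    """Smooth GM-probability template with a contiguous brain region."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def n_brain_voxels(self) -> int:
        return int((self.data > BRAIN_THRESHOLD).sum())

    @property
    def brain_fraction(self) -> float:
        return self.n_brain_voxels / self.data.size


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery tests."""

    weight_map: np.ndarray            # GM units per year, zero outside clusters
    true_bag: np.ndarray              # years, target cohort
    true_protein_ids: list[str]
    protein_gammas: dict[str, float]  # analyte SD units per BAG-year
    true_log_hrs: dict[int, float]    # tertile -> log hazard ratio vs highest


def make_template(grid_shape, seed: int) -> Template:
    """Generate a smooth [0, 1] template whose >0.1 region covers 30-70% of voxels.

    An ellipsoidal soft blob (semi-axes 0.45 of each dimension) provides the
    "brain"; a smoothed Gaussian field adds realistic spatial texture.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or any(g < 8 for g in grid_shape):
        raise ValueError(f"grid_shape must be 3-D with every dim >= 8, got {grid_shape}")
    rng = np.random.default_rng(seed)
    axes = [
        (np.arange(n) - (n - 1) / 2.0) / (0.45 * n)
        for n in grid_shape
    ]
    r2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
          + axes[2][None, None, :] ** 2)
    blob = np.clip(1.0 - r2, 0.0, 1.0) ** 0.7
    noise = gaussian_filter(rng.standard_normal(grid_shape),
                            sigma=max(min(grid_shape) / 10.0, 1.0))
    noise /= max(noise.std(), 1e-12)
    data = np.clip(0.85 * blob + 0.04 * noise * (blob > 0), 0.0, 1.0)
    return Template(data=data)


def make_signal_map(template: Template, n_clusters: int, effect_scale: float,
                    seed: int) -> np.ndarray:
    """Plant ``n_clusters`` non-overlapping spherical atrophy clusters.

    Cluster voxels carry negative values (GM loss per year of effective age)
    with peak magnitude ``effect_scale`` and a parabolic falloff.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    data = template.data
    weight_map = np.zeros_like(data)
    if effect_scale == 0:
        return weight_map
    rng = np.random.default_rng(seed)
    radius = max(2, min(data.shape) // 10)
    # centers deep enough that the whole sphere stays inside the brain region
    from scipy.ndimage import distance_transform_edt
    depth = distance_transform_edt(data > BRAIN_THRESHOLD)
    candidates = np.argwhere(depth > radius)
    if candidates.size == 0:
        raise ValueError("template brain region too small to place any cluster")
    min_sep = 2 * radius + 2
    centers: list[np.ndarray] = []
    for _ in range(50):  # greedy placement with random restarts
        order = rng.permutation(len(candidates))
        trial: list[np.ndarray] = []
        for i in order:
            c = candidates[i]
            if all(np.linalg.norm(c - prev) >= min_sep for prev in trial):
                trial.append(c)
                if len(trial) == n_clusters:
                    break
        if len(trial) > len(centers):
            centers = trial
        if len(centers) == n_clusters:
            break
    if len(centers) < n_clusters:
        raise ValueError(
            f"requested {n_clusters} clusters but only {len(centers)} "
            f"non-overlapping spheres of radius {radius} fit in the brain region"
        )
    grids = np.indices(data.shape)
    for c in centers:
        d2 = sum((grids[k] - c[k]) ** 2 for k in range(3))
        inside = d2 <= radius**2
        weight_map[inside] -= abs(effect_scale) * (1.0 - d2[inside] / (radius**2 + 1))
    return weight_map


def simulate_gm_cohort(template: Template, weight_map: np.ndarray, n: int,
                       age_range, noise_sd: float, smooth_fwhm: float,
                       age_ref: float, seed: int, bag: np.ndarray | None = None,
                       cohort: str = "", id_prefix: str = "sub") -> GMVolumeSet:
    """Simulate per-subject GM volumes.

    volume_i = clip(template + weight_map * (age_i + bag_i - age_ref) + eps_i, 0, 1)
    with eps_i white Gaussian noise (SD ``noise_sd`` before smoothing) smoothed
    to ``smooth_fwhm`` voxels FWHM, and ages uniform on ``age_range``.
    ``bag`` (default zero) is the subject-level true brain-age gap in years.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = float(age_range[0]), float(age_range[1])
    if not hi > lo:
        raise ValueError("age_range must be nondegenerate")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n)
    if bag is None:
        bag = np.zeros(n)
    bag = np.asarray(bag, dtype=float)
    if bag.shape != (n,):
        raise ValueError("bag must have length n")
    sigma = smooth_fwhm / _FWHM_TO_SIGMA if smooth_fwhm > 0 else 0.0
    data = np.empty((n,) + template.data.shape)
    for i in range(n):
        vol = template.data + weight_map * (ages[i] + bag[i] - age_ref)
        if noise_sd > 0:
            eps = rng.standard_normal(template.data.shape) * noise_sd
            if sigma > 0:
                eps = gaussian_filter(eps, sigma=sigma)
            vol = vol + eps
        data[i] = np.clip(vol, 0.0, 1.0)
    ids = [f"{id_prefix}{i:05d}" for i in range(n)]
    return GMVolumeSet(data=data, subject_ids=ids, ages=ages,
                       affine=template.affine, cohort=cohort)


def _bag_tertile(true_bag: np.ndarray) -> np.ndarray:
    """Tertile of the true gap (1 lowest, 3 highest), boundary convention <=q1 / >=q2."""
    q1, q2 = np.quantile(true_bag, [1 / 3, 2 / 3])
    labels = np.full(true_bag.shape, 2, dtype=int)
    labels[true_bag <= q1] = 1
    labels[true_bag >= q2] = 3
    return labels


def simulate_phenotypes(true_bag: np.ndarray, config: SimConfig, seed: int,
                        ages: np.ndarray | None = None,
                        subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Simulate the phenotype/outcome table for the target cohort.

    Covariates are drawn independently of the gap; cognitive status,
    physical function, disease indicators and mortality all load on
    ``true_bag``. Survival is exponential with tertile-of-true-gap log
    hazard ratios from the config, administratively censored at the
    site-specific calendar date.
    """
    true_bag = np.asarray(true_bag, dtype=float)
    if not np.all(np.isfinite(true_bag)):
        raise ValueError("true_bag must be finite")
    n = true_bag.size
    rng = np.random.default_rng(seed)
    if ages is None:
        ages = rng.uniform(*config.target_age_range, size=n)
    ages = np.asarray(ages, dtype=float)
    if ages.size != n:
        raise ValueError(f"ages length {ages.size} does not match true_bag length {n}")
    if subject_ids is None:
        subject_ids = [f"tgt{i:05d}" for i in range(n)]
    if len(subject_ids) != n:
        raise ValueError("subject_ids length mismatch")

    sex = np.where(rng.random(n) < 0.605, "female", "male")
    center_race = rng.choice(_CENTER_RACE_LEVELS, size=n, p=_CENTER_RACE_PROBS)
    site = np.array([_SITE_OF_CENTER_RACE[c] for c in center_race])
    smoking = rng.choice(_SMOKING_LEVELS, size=n, p=_SMOKING_PROBS)
    education = rng.choice(_EDU_LEVELS, size=n, p=_EDU_PROBS)
    hypertension = (rng.random(n) < 0.754).astype(int)
    diabetes = (rng.random(n) < 0.30).astype(int)
    bmi = rng.normal(28.5, 5.7, size=n)
    icv = rng.normal(1400.0, 130.0, size=n)  # cm^3

    # ordinal cognitive status: logistic latent with a gap effect; thresholds at
    # the latent's empirical quantiles so the marginal mix matches _COG_MIX
    latent = 0.35 * true_bag + rng.logistic(0.0, 1.0, size=n)
    c1, c2 = np.quantile(latent, [_COG_MIX[0], _COG_MIX[0] + _COG_MIX[1]])
    cognitive_status = np.where(latent <= c1, "CN",
                                np.where(latent <= c2, "MCI", "DEM"))

    walk4m = (4.5 + 0.10 * (ages - config.age_ref) / 5.0 + 0.15 * true_bag
              + rng.normal(0.0, 1.0, size=n))
    low_grip = (rng.random(n) < _sigmoid(-1.4 + 0.20 * true_bag)).astype(int)
    disease = {}
    for name, base_logit, slope in (("chd", -2.0, 0.12), ("stroke", -2.7, 0.15),
                                    ("afib", -2.4, 0.12), ("hf", -2.6, 0.10)):
        disease[name] = (rng.random(n) < _sigmoid(base_logit + slope * true_bag)).astype(int)

    tertile_true = _bag_tertile(true_bag)
    log_hr = np.where(tertile_true == 1, np.log(config.hr_lowest),
                      np.where(tertile_true == 2, np.log(config.hr_middle), 0.0))
    rate = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / rate)

    base_start = pd.Timestamp("2011-06-01")
    baseline_date = base_start + pd.to_timedelta(rng.integers(0, 731, size=n), unit="D")
    censor_dates = pd.to_datetime(
        [config.censor_date_by_site[s] for s in site])
    censor_years = (censor_dates - baseline_date).days / 365.25
    event = (t_event <= censor_years).astype(int)
    time = np.minimum(t_event, censor_years)
    cause = np.where(event == 1,
                     np.where(rng.random(n) < config.p_cns_death, "CNS", "nonCNS"),
                     None)

    return pd.DataFrame({
        "subject_id": subject_ids,
        "age": ages,
        "sex": sex,
        "center_race": center_race,
        "site": site,
        "smoking": smoking,
        "education": education,
        "hypertension": hypertension,
        "diabetes": diabetes,
        "bmi": bmi,
        "icv": icv,
        "cognitive_status": cognitive_status,
        "walk4m": walk4m,
        "low_grip": low_grip,
        "chd": disease["chd"],
        "stroke": disease["stroke"],
        "afib": disease["afib"],
        "hf": disease["hf"],
        "baseline_date": baseline_date,
        "time": time,
        "event": event,
        "cause": cause,
    })


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_proteins(true_bag: np.ndarray, covariates: pd.DataFrame | None,
                      config: SimConfig, seed: int,
                      subject_ids: list[str] | None = None):
    """Simulate the analyte panel.

    Analyte j = gamma_j * true_bag + covariate effects + N(0, 1) noise, with
    gamma_j = +/- ``protein_effect_sd`` for the ``n_true_proteins`` designated
    analytes and 0 otherwise. A ``qc_fail_fraction`` of analytes is flagged
    as failing quality control. Returns (ProteomicsMatrix, gammas dict).
    """
    from .pwas import ProteomicsMatrix

    true_bag = np.asarray(true_bag, dtype=float)
    n = true_bag.size
    m = config.n_proteins
    rng = np.random.default_rng(seed)
    analyte_ids = [f"prot_{j:05d}" for j in range(m)]
    if subject_ids is None:
        subject_ids = [f"tgt{i:05d}" for i in range(n)]

    true_idx = np.sort(rng.choice(m, size=config.n_true_proteins, replace=False))
    gammas = np.zeros(m)
    gammas[true_idx] = config.protein_effect_sd * rng.choice([-1.0, 1.0],
                                                             size=true_idx.size)
    values = gammas[None, :] * true_bag[:, None]
    if covariates is not None and len(covariates) == n:
        if "age" in covariates:
            age_load = rng.normal(0.0, 0.01, size=m)
            age_c = covariates["age"].to_numpy(dtype=float)
            values = values + np.outer(age_c - age_c.mean(), age_load)
        if "sex" in covariates:
            sex_load = rng.normal(0.0, 0.05, size=m)
            female = (covariates["sex"].to_numpy() == "female").astype(float)
            values = values + np.outer(female - female.mean(), sex_load)
    values = values + rng.standard_normal((n, m))

    n_fail = int(round(config.qc_fail_fraction * m))
    fail_idx = rng.choice(m, size=n_fail, replace=False)
    qc_pass = np.ones(m, dtype=bool)
    qc_pass[fail_idx] = False

    matrix = ProteomicsMatrix(
        values=pd.DataFrame(values, index=list(subject_ids), columns=analyte_ids),
        qc_pass=pd.Series(qc_pass, index=analyte_ids),
    )
    gamma_map = {analyte_ids[j]: float(gammas[j]) for j in true_idx}
    return matrix, gamma_map


@dataclass
class SimulatedStudy:
    """Everything one seeded run of the generator produced."""

    config: SimConfig
    template: Template
    truth: GroundTruth
    train_volumes: GMVolumeSet
    target_volumes: GMVolumeSet
    phenotypes: pd.DataFrame
    proteins: "object"                # ProteomicsMatrix


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the whole generator: template, signal, both cohorts, phenotypes, panel."""
    seed = config.seed
    template = make_template(config.grid_shape, derive_seed(seed, "template"))
    weight_map = make_signal_map(template, config.n_signal_clusters,
                                 config.effect_scale, derive_seed(seed, "signal"))
    train = simulate_gm_cohort(
        template, weight_map, config.n_train, config.train_age_range,
        config.noise_sd, config.smooth_fwhm, config.age_ref,
        derive_seed(seed, "train"), cohort="train", id_prefix="trn",
    )
    rng = np.random.default_rng(derive_seed(seed, "bag"))
    true_bag = rng.normal(0.0, config.bag_sd, size=config.n_target)
    true_bag = true_bag - true_bag.mean()  # centered by construction
    target = simulate_gm_cohort(
        template, weight_map, config.n_target, config.target_age_range,
        config.noise_sd, config.smooth_fwhm, config.age_ref,
        derive_seed(seed, "target"), bag=true_bag, cohort="target",
        id_prefix="tgt",
    )
    phenotypes = simulate_phenotypes(
        true_bag, config, derive_seed(seed, "phenotypes"),
        ages=target.ages, subject_ids=target.subject_ids,
    )
    proteins, gamma_map = simulate_proteins(
        true_bag, phenotypes, config, derive_seed(seed, "proteins"),
        subject_ids=target.subject_ids,
    )
    truth = GroundTruth(
        weight_map=weight_map,
        true_bag=true_bag,
        true_protein_ids=sorted(gamma_map),
        protein_gammas=gamma_map,
        true_log_hrs={1: float(np.log(config.hr_lowest)),
                      2: float(np.log(config.hr_middle)), 3: 0.0},
    )
    return SimulatedStudy(config=config, template=template, truth=truth,
                          train_volumes=train, target_volumes=target,
                          phenotypes=phenotypes, proteins=proteins)
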