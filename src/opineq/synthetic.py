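"""Synthetic inpatient-record generator with known opportunity-inequality ground truth.

Real medical-insurance settlement records of the kind analysed by ex-ante
opportunity-inequality studies are confidential, so every downstream stage of
this package is exercised on synthetic tables whose *marginal* structure
matches the descriptive statistics of a provincial inpatient sample of
middle-aged and older cardiovascular/cerebrovascular patients (age truncated
at 45, four-category ordinal discharge diagnosis, thirteen environmental
covariates) and whose data-generating process has a *configurable, known*
share of latent-health variance attributable to environment.

Latent structure
----------------
A latent health score is built from the circumstance covariates ``E``:

    h* = sqrt(env_share) * standardize(s(E)) + sqrt(1 - env_share) * eps,

with ``eps ~ N(0,1)`` a single effort/luck noise term and ``s`` a linear,
interaction or threshold score (``nonlinearity``).  ``h*`` is discretised by
three increasing cutpoints into the ordinal discharge diagnosis
(1 = cured ... 4 = death; high ``h*`` = category 1).  Because the conditional
distribution of the diagnosis given ``E`` is known in closed form,
:func:`oracle_iop` can integrate out the noise and return the true relative
opportunity inequality under the same RINT + reversal + shift convention the
preprocessing stage uses.

Clustered macro covariates
--------------------------
Hospital-bed density, doctor density, rail-transit and old-revolutionary-area
status are properties of the treatment city, not the patient: they are drawn
once per synthetic city (default 11) and shared by that city's patients, then
calibrated so the *patient-weighted* moments still match the configured
marginal targets (continuous values by an affine rescale, binary flags by a
best subset-sum assignment over city sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .inequality import mld
from .preprocess import rint_fit

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "TABLE_MARGINALS",
    "PATIENT_COLUMNS",
    "generate",
    "oracle_iop",
    "write_patients_csv",
    "read_patients_csv",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


#: marginal targets (mean, sd, min, max) for the emulated descriptive table
TABLE_MARGINALS = {
    "age": {"mean": 66.202, "sd": 10.769, "min": 45.0, "max": 87.0},
    "gender": {"mean": 0.502},
    "ethnicity": {"mean": 0.971},
    "marital_status": {"mean": 0.866},
    "occupational_risk": {"mean": 0.528, "sd": 0.872,
                          "probs": {0: 0.7276, 1: 0.0168, 2: 0.2556}},
    "beds_per_1000": {"mean": 6.767, "sd": 1.348, "min": 5.13, "max": 10.05},
    "doctors_per_1000": {"mean": 2.609, "sd": 0.643, "min": 1.43, "max": 3.83},
    "rail_transit": {"mean": 0.11},
    "old_area": {"mean": 0.606},
    "surgical_level": {"mean": 0.789, "sd": 0.874,
                       "probs": {0: 0.5095, 1: 0.192, 2: 0.2985}},
    "emergency_admission": {"mean": 0.2},
    "admission_condition": {"mean": 1.127, "sd": 0.466,
                            "probs": {1: 0.921, 2: 0.036, 3: 0.038, 4: 0.005}},
}

#: column order of the generated patient table
PATIENT_COLUMNS = [
    "age", "gender", "ethnicity", "marital_status", "occupational_risk",
    "beds_per_1000", "doctors_per_1000", "rail_transit", "old_area",
    "surgical_level", "emergency_admission", "admission_condition",
    "total_expenses", "icd10_group", "city", "primary_dx", "secondary_dx",
]

_CITY_COLUMNS = ("beds_per_1000", "doctors_per_1000", "rail_transit", "old_area")

#: weights of the linear circumstance score on standardized covariates; the
#: loadings put surgical level and regional resource density first, matching
#: the ranking such studies report for these diseases
_LINEAR_WEIGHTS = {
    "surgical_level": 1.0,
    "beds_per_1000": 0.8,
    "doctors_per_1000": 0.6,
    "rail_transit": 0.35,
    "age": -0.35,
    "admission_condition": -0.45,
    "emergency_admission": -0.2,
    "old_area": -0.15,
    "occupational_risk": -0.15,
    "marital_status": 0.1,
    "gender": 0.08,
    "ethnicity": 0.05,
}

#: default cutpoints give discharge-category frequencies ~(0.35, 0.50, 0.12, 0.03)
_DEFAULT_CUTPOINTS = (-1.8808, -1.0364, 0.3853)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic data-generating process."""

    n: int = 10_000
    seed: int = 0
    env_share: float = 0.3
    nonlinearity: str = "linear"  # linear | interaction | threshold
    cutpoints: tuple[float, float, float] = _DEFAULT_CUTPOINTS
    marginals: dict = field(default_factory=lambda: dict(TABLE_MARGINALS))
    n_diagnosis_groups: int = 25
    secondary_dx_rate: float = 0.35
    n_cities: int = 11
    copula_corr: np.ndarray | None = None  # optional corr matrix, patient-level covariates
    shift: float = 5.0  # positivity shift convention shared with preprocessing

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not 0.0 <= self.env_share <= 1.0:
            raise ConfigError("env_share must lie in [0, 1]")
        c = tuple(self.cutpoints)
        if len(c) != 3 or not (c[0] < c[1] < c[2]):
            raise ConfigError("cutpoints must be 3 strictly increasing reals")
        if self.nonlinearity not in ("linear", "interaction", "threshold"):
            raise ConfigError(f"unknown nonlinearity {self.nonlinearity!r}")
        if not 0.0 <= self.secondary_dx_rate <= 1.0:
            raise ConfigError("secondary_dx_rate must lie in [0, 1]")
        if self.n_diagnosis_groups < 1 or self.n_cities < 1:
            raise ConfigError("n_diagnosis_groups and n_cities must be >= 1")


# ---------------------------------------------------------------------------
# marginal samplers
# ---------------------------------------------------------------------------

_PATIENT_LEVEL = ["age", "gender", "ethnicity", "marital_status",
                  "occupational_risk", "surgical_level", "emergency_admission",
                  "admission_condition"]


def _solve_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Parent (loc, scale) of a truncated normal with given truncated moments."""

    def moments(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        d = stats.truncnorm(a, b, loc=loc, scale=scale)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.fsolve(moments, x0=[mean, np.log(sd)], full_output=False)
    loc, scale = sol[0], float(np.exp(sol[1]))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return a, b, loc, scale


_TRUNCNORM_CACHE: dict[tuple, tuple] = {}


def _truncnorm_params(spec: dict) -> tuple:
    key = (spec["mean"], spec["sd"], spec["min"], spec["max"])
    if key not in _TRUNCNORM_CACHE:
        _TRUNCNORM_CACHE[key] = _solve_truncnorm(*key)
    return _TRUNCNORM_CACHE[key]


def _marginal_ppf(col: str, spec: dict, u: np.ndarray) -> np.ndarray:
    """Quantile function of one covariate's marginal, for uniform draws u."""
    if "probs" in spec:
        levels = np.array(sorted(spec["probs"]))
        cum = np.cumsum([spec["probs"][k] for k in levels])
        cum[-1] = 1.0
        return levels[np.searchsorted(cum, u, side="left")].astype(float)
    if "sd" in spec:  # continuous truncated normal
        a, b, loc, scale = _truncnorm_params(spec)
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)
    return (u < spec["mean"]).astype(float)  # Bernoulli


def _draw_patient_covariates(cfg: GeneratorConfig, rng: np.random.Generator,
                             n: int) -> dict[str, np.ndarray]:
    cols = _PATIENT_LEVEL
    if cfg.copula_corr is not None:
        corr = np.asarray(cfg.copula_corr, dtype=float)
        if corr.shape != (len(cols), len(cols)):
            raise ConfigError(
                f"copula_corr must be {len(cols)}x{len(cols)} over {cols}")
        z = rng.multivariate_normal(np.zeros(len(cols)), corr, size=n,
                                    method="cholesky")
        u = stats.norm.cdf(z)
    else:
        u = rng.random((n, len(cols)))
    return {c: _marginal_ppf(c, cfg.marginals[c], u[:, j])
            for j, c in enumerate(cols)}


# ---------------------------------------------------------------------------
# city-level covariates with patient-weighted calibration
# ---------------------------------------------------------------------------

def _best_subset_assignment(shares: np.ndarray, target: float) -> np.ndarray:
    """0/1 assignment over cities whose patient-share total is closest to target."""
    m = len(shares)
    if m <= 16:
        best, best_err = 0, np.inf
        for mask in range(2 ** m):
            tot = sum(shares[i] for i in range(m) if mask >> i & 1)
            err = abs(tot - target)
            if err < best_err:
                best, best_err = mask, err
        return np.array([(best >> i) & 1 for i in range(m)], dtype=float)
    order = np.argsort(-shares)  # greedy for many cities
    flags = np.zeros(m)
    tot = 0.0
    for i in order:
        if abs(tot + shares[i] - target) < abs(tot - target):
            flags[i] = 1.0
            tot += shares[i]
    return flags


def _draw_city_covariates(cfg: GeneratorConfig, rng: np.random.Generator,
                          city: np.ndarray) -> dict[str, np.ndarray]:
    m = cfg.n_cities
    counts = np.bincount(city, minlength=m).astype(float)
    shares = counts / counts.sum()
    out = {}
    for col in ("beds_per_1000", "doctors_per_1000"):
        spec = cfg.marginals[col]
        vals = rng.normal(spec["mean"], spec["sd"], size=m)
        # affine calibration of patient-weighted moments, then clamp to range
        for _ in range(5):
            mu = float(shares @ vals)
            sd = float(np.sqrt(shares @ (vals - mu) ** 2))
            if sd > 0:
                vals = spec["mean"] + (vals - mu) * (spec["sd"] / sd)
            clipped = np.clip(vals, spec["min"], spec["max"])
            if np.allclose(clipped, vals):
                vals = clipped
                break
            vals = clipped
        vals += spec["mean"] - float(shares @ vals)  # recentre the mean
        vals = np.clip(vals, spec["min"], spec["max"])
        out[col] = vals[city]
    for col in ("rail_transit", "old_area"):
        flags = _best_subset_assignment(shares, cfg.marginals[col]["mean"])
        out[col] = flags[city]
    return out


# ---------------------------------------------------------------------------
# latent health score
# ---------------------------------------------------------------------------

def _standardized(col: str, values: np.ndarray, marg: dict) -> np.ndarray:
    spec = marg[col]
    mean = spec["mean"]
    if "sd" in spec:
        sd = spec["sd"]
    else:
        sd = float(np.sqrt(spec["mean"] * (1 - spec["mean"])))
    return (values - mean) / sd


def _circumstance_score(cfg: GeneratorConfig, cov: dict[str, np.ndarray]) -> np.ndarray:
    marg = cfg.marginals
    z = {c: _standardized(c, cov[c], marg) for c in _LINEAR_WEIGHTS}
    s_lin = sum(w * z[c] for c, w in _LINEAR_WEIGHTS.items())
    if cfg.nonlinearity == "linear":
        return s_lin
    if cfg.nonlinearity == "interaction":
        return (0.6 * s_lin
                + 1.4 * z["beds_per_1000"] * z["doctors_per_1000"]
                + 1.0 * z["surgical_level"] * z["age"])
    # threshold
    return (1.0 * (cov["beds_per_1000"] > marg["beds_per_1000"]["mean"])
            + 1.0 * (cov["surgical_level"] == 2)
            + 0.6 * (cov["doctors_per_1000"] > marg["doctors_per_1000"]["mean"])
            - 0.5 * (cov["admission_condition"] >= 2)
            + 0.3 * (cov["age"] < 60)).astype(float)


def _latent_inputs(cfg: GeneratorConfig, rng: np.random.Generator,
                   n: int) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Draw covariates and the standardized circumstance score for n patients."""
    city_shares = rng.dirichlet(np.full(cfg.n_cities, 5.0))
    city = rng.choice(cfg.n_cities, size=n, p=city_shares)
    cov = _draw_patient_covariates(cfg, rng, n)
    cov.update(_draw_city_covariates(cfg, rng, city))
    cov["city"] = city
    s = _circumstance_score(cfg, cov)
    sd = s.std()
    zs = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    return cov, zs


def _discretize(h: np.ndarray, cutpoints) -> np.ndarray:
    # h above the top cutpoint -> category 1 (cured); below the bottom -> 4 (death)
    return (4 - np.searchsorted(np.asarray(cutpoints), h, side="left")).astype(int)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a patient table (one row per admission).

    Reproducible given ``config.seed``; covariate sample moments converge to
    the configured marginal targets as ``n`` grows.  Columns are
    :data:`PATIENT_COLUMNS`; ``secondary_dx`` holds (possibly empty) lists of
    ordinal codes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    cov, zs = _latent_inputs(cfg, rng, n)

    eps = rng.standard_normal(n)
    h = np.sqrt(cfg.env_share) * zs + np.sqrt(1.0 - cfg.env_share) * eps
    primary = _discretize(h, cfg.cutpoints)

    # secondary diagnoses: noisy copies of the primary category
    has_sec = rng.random(n) < cfg.secondary_dx_rate
    n_sec = np.where(has_sec, 1 + rng.binomial(2, 0.3, size=n), 0)
    noise_pool = rng.choice([-1, 0, 1], size=int(n_sec.sum()), p=[0.2, 0.6, 0.2])
    secondary, pos = [], 0
    for i in range(n):
        k = int(n_sec[i])
        codes = np.clip(primary[i] + noise_pool[pos:pos + k], 1, 4).tolist()
        secondary.append(codes)
        pos += k

    # diagnosis groups (ICD-10 circulatory chapter, 4-character codes)
    g = cfg.n_diagnosis_groups
    code_nums = np.linspace(100, 700, g).astype(int)
    codes = np.array([f"I{v:03d}" for v in code_nums])
    group_p = np.sort(rng.dirichlet(np.full(g, 2.0)))[::-1]
    group_idx = rng.choice(g, size=n, p=group_p)

    # expenses: lognormal with group-specific location and dispersion, plus
    # mild loading on surgery and admission severity
    base = rng.normal(9.2, 0.25, size=g)
    sigma = rng.uniform(0.3, 0.9, size=g)
    log_exp = (base[group_idx] + 0.35 * cov["surgical_level"]
               + 0.15 * (cov["admission_condition"] - 1)
               + sigma[group_idx] * rng.standard_normal(n))
    expenses = np.exp(log_exp)

    df = pd.DataFrame({
        **{c: cov[c] for c in _PATIENT_LEVEL},
        **{c: cov[c] for c in _CITY_COLUMNS},
        "city": cov["city"],
        "total_expenses": expenses,
        "icd10_group": codes[group_idx],
        "primary_dx": primary,
        "secondary_dx": secondary,
    })
    return df[PATIENT_COLUMNS]


def oracle_iop(config: GeneratorConfig, n_mc: int = 200_000, *,
               shift: float | None = None) -> float:
    """Ground-truth relative opportunity inequality of the configured process.

    Monte-Carlo over the circumstance draw only: the effort-noise dimension is
    integrated out in closed form (the conditional category distribution given
    the circumstance score is known), so the returned value is the MLD of the
    exact conditional-mean transformed health divided by the MLD of the
    marginal transformed health, under the same RINT + reversal + shift
    convention as the preprocessing stage.
    """
    if n_mc < 1:
        raise ConfigError("n_mc must be >= 1")
    cfg = config
    shift = cfg.shift if shift is None else shift
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 982451653]))
    _, zs = _latent_inputs(cfg, rng, n_mc)
    mu = np.sqrt(cfg.env_share) * zs
    sigma = np.sqrt(1.0 - cfg.env_share)
    cut = np.asarray(cfg.cutpoints)
    if sigma > 0:
        cdf = stats.norm.cdf((cut[None, :] - mu[:, None]) / sigma)
    else:
        cdf = (cut[None, :] >= mu[:, None]).astype(float)
    # P(category k), columns ordered dx = 4, 3, 2, 1
    probs = np.diff(np.concatenate(
        [np.zeros((n_mc, 1)), cdf, np.ones((n_mc, 1))], axis=1), axis=1)
    freqs = probs.mean(axis=0)
    present = freqs > 0
    rmap = rint_fit({dx: f for dx, f in zip((4, 3, 2, 1), freqs) if f > 0})
    t_by_dx = {int(c): -z + shift for c, z in zip(rmap.categories, rmap.z)}
    t = np.array([t_by_dx.get(dx, 0.0) for dx in (4, 3, 2, 1)])
    h_bar = probs @ t  # conditional-mean transformed health given circumstances
    total = float(np.log(freqs @ t) - freqs[present] @ np.log(t[present]))
    if total == 0.0:
        return 0.0
    return mld(h_bar) / total


# ---------------------------------------------------------------------------
# CSV round-trip (secondary diagnoses serialised as ';'-joined codes)
# ---------------------------------------------------------------------------

def write_patients_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["secondary_dx"] = [";".join(str(int(c)) for c in codes)
                           for codes in out["secondary_dx"]]
    out.to_csv(path, index=False)


def read_patients_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"icd10_group": str})
    sec = df["secondary_dx"].fillna("")
    df["secondary_dx"] = [[int(c) for c in s.split(";") if c] for s in sec]
    return df
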