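"""Synthetic discovery and validation cohorts for the exposure-transcriptome pipeline.

The generator emulates two middle-aged general-population cohorts (a microarray
discovery cohort and an independent qPCR validation cohort) with the statistical
structure the downstream analysis assumes:

* long-term PM10/PM2.5 exposures drawn from a correlated bivariate log-normal,
  calibrated to the printed cohort descriptives (mean ~26 ug/m3 with a 5-95th
  range of roughly 21.5-30.4 ug/m3 for discovery PM10);
* covariates (age, BMI, 3-level socioeconomic status, smoking, season and
  4-bin daytime of blood sampling, white-blood-cell counts) with realistic
  marginal distributions;
* gene expression following the analysis model in reverse:
  ``log2 x_gi = mu_g + (log2fc_per_5ug / 5) * pm_i * [sex match] + sum_c beta_c z_ci + eps``,
  so that fitted slopes can be compared against the embedded truth;
* season shifts both exposure and expression (mild confounding), so covariate
  adjustment in the regression stage is actually exercised;
* probe-level microarray intensities (replicate spots, background, bad-spot
  flags) constructed so that preprocessing is exactly invertible when all noise
  terms are switched off: ``foreground = background + 2**log2_value``;
* triplicate qPCR Cq tables with three reference genes, per-assay amplification
  efficiencies, replicate noise and occasional discordant replicates to
  exercise the triplicate-concordance filter.

Smokers exist only in the validation cohort; the discovery cohort is generated
smoke-free, and cell counts are only available for validation participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from . import io

SES_LEVELS = ("low", "medium", "high")
SMOKING_LEVELS = ("never", "former", "current")
SEASON_LEVELS = ("cold", "warm")
DAYTIME_LEVELS = ("<1200", "1200-1500", "1500-1800", ">2000")

#: default categorical frequencies per cohort kind (sex-averaged descriptives)
_CATEGORICAL_DEFAULTS = {
    "discovery": {
        "ses": (0.49, 0.22, 0.29),
        "smoking": (1.0, 0.0, 0.0),
        "season": (0.82, 0.18),
        "daytime": (0.87, 0.13, 0.0, 0.0),
    },
    "validation": {
        "ses": (0.22, 0.25, 0.53),
        "smoking": (0.43, 0.44, 0.13),
        "season": (0.40, 0.60),
        "daytime": (0.04, 0.27, 0.44, 0.25),
    },
}

#: covariate channels that effect maps may reference (encoded per participant)
COVARIATE_CHANNELS = (
    "age",
    "bmi",
    "season_cold",
    "smoking_former",
    "smoking_current",
    "leukocytes",
    "neutrophils",
    "ses_medium",
    "ses_high",
    "daytime_1200_1500",
    "daytime_1500_1800",
    "daytime_gt2000",
)


@dataclass(frozen=True)
class EffectSpec:
    """One embedded exposure effect: gene, sex stratum and log2 FC per 5 ug/m3."""

    gene_id: str
    sex: str
    log2fc_per_5ug: float
    exposure: str = "pm10"


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Exposure means/SDs are arithmetic (ug/m3); the generator matches them with
    a bivariate log-normal. ``effect_table`` genes must appear in ``probe_map``
    (or be auto-added when the probe map is left empty, together with
    ``n_null_genes`` unaffected genes).
    """

    n_men: int = 48
    n_women: int = 50
    cohort_kind: str = "discovery"
    pm10_mean: float = 25.9
    pm10_sd: float = 2.8
    pm25_mean: float = 17.8
    pm25_sd: float = 1.7
    pm_correlation: float = 0.85
    effect_table: tuple = ()
    covariate_effects: dict = field(
        default_factory=lambda: {"season_cold": 0.10, "age": 0.004, "bmi": 0.008}
    )
    residual_sd: float = 0.4
    probe_map: dict = field(default_factory=dict)
    probe_sd: float = 0.05
    flag_probability: float = 0.01
    n_null_genes: int = 0
    baseline_range: tuple = (6.0, 12.0)
    background_range: tuple = (20.0, 80.0)
    #: latent-scale shift (in units of the log-normal sigma) added to exposure
    #: in the cold season; makes season a genuine confounder.
    season_exposure_shift: float = 0.3
    reference_genes: tuple = ("HPRT", "IPO8", "YWHAZ")
    efficiencies: dict = field(default_factory=dict)
    cq_replicate_sd: float = 0.1
    cq_outlier_probability: float = 0.02
    seed: int = 0

    def __post_init__(self):
        self.effect_table = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(*e) for e in self.effect_table
        )

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_men <= 0:
            raise ConfigurationError("n_men must be > 0")
        if self.n_women <= 0:
            raise ConfigurationError("n_women must be > 0")
        if self.cohort_kind not in ("discovery", "validation"):
            raise ConfigurationError("cohort_kind must be 'discovery' or 'validation'")
        for name in ("pm10_sd", "pm25_sd", "residual_sd", "probe_sd", "cq_replicate_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("pm10_mean", "pm25_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not -1.0 < self.pm_correlation < 1.0:
            raise ConfigurationError("pm_correlation must lie strictly inside (-1, 1)")
        if not 0.0 <= self.flag_probability < 1.0:
            raise ConfigurationError("flag_probability must lie in [0, 1)")
        if not 0.0 <= self.cq_outlier_probability < 1.0:
            raise ConfigurationError("cq_outlier_probability must lie in [0, 1)")
        if self.n_null_genes < 0:
            raise ConfigurationError("n_null_genes must be >= 0")
        for assay, eff in self.efficiencies.items():
            if not 1.9 <= eff <= 2.1:
                raise ConfigurationError(
                    f"efficiencies[{assay!r}] = {eff} outside [1.9, 2.1] "
                    "(amplification efficiency must be 90-110%)"
                )
        for spec in self.effect_table:
            if spec.sex not in ("M", "F"):
                raise ConfigurationError(f"effect_table sex {spec.sex!r} not in {{M, F}}")
            if spec.exposure not in ("pm10", "pm25"):
                raise ConfigurationError(f"effect_table exposure {spec.exposure!r} unknown")
        if self.probe_map:
            missing = [e.gene_id for e in self.effect_table if e.gene_id not in self.probe_map]
            if missing:
                raise ConfigurationError(
                    f"effect_table genes missing from probe_map: {missing}"
                )
        unknown = set(self.covariate_effects) - set(COVARIATE_CHANNELS)
        if unknown:
            raise ConfigurationError(f"covariate_effects keys unknown: {sorted(unknown)}")

    # -- derived ------------------------------------------------------------
    def gene_ids(self) -> list:
        """All simulated genes, in deterministic order."""
        if self.probe_map:
            return list(self.probe_map)
        genes = [e.gene_id for e in self.effect_table]
        seen = dict.fromkeys(genes)
        genes = list(seen)
        genes += [f"NULL{i:04d}" for i in range(self.n_null_genes)]
        return genes

    def resolved_probe_map(self) -> dict:
        if self.probe_map:
            return {g: tuple(p) for g, p in self.probe_map.items()}
        return {g: (f"{g}|p1|s1",) for g in self.gene_ids()}


def make_probe_map(genes, max_probes: int = 2, max_spots: int = 2) -> dict:
    """Deterministic probe map: genes cycle through (probes, spots) patterns.

    Spot ids are ``<gene>|p<j>|s<k>`` so that the probe id (``<gene>|p<j>``)
    and the gene id can be recovered by splitting on ``|``.
    """
    patterns = [(p, s) for p in range(1, max_probes + 1) for s in range(1, max_spots + 1)]
    out = {}
    for i, g in enumerate(genes):
        n_probes, n_spots = patterns[i % len(patterns)]
        out[g] = tuple(
            f"{g}|p{j}|s{k}" for j in range(1, n_probes + 1) for k in range(1, n_spots + 1)
        )
    return out


def annotation_frame(probe_map: dict) -> pd.DataFrame:
    """Spot -> probe -> gene annotation table derived from a probe map."""
    rows = []
    for gene, spots in probe_map.items():
        for spot in spots:
            probe = spot.rsplit("|", 1)[0] if "|" in spot else spot
            rows.append((spot, probe, gene))
    return pd.DataFrame(rows, columns=["spot_id", "probe_id", "gene_id"])


@dataclass
class ProbeIntensityMatrix:
    """Probe x sample foreground/background intensities with a bad-spot flag channel."""

    foreground: pd.DataFrame
    background: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self):
        if not (
            self.foreground.shape == self.background.shape == self.flags.shape
            and self.foreground.index.equals(self.background.index)
            and self.foreground.columns.equals(self.flags.columns)
        ):
            raise ConfigurationError("probe matrix channels have inconsistent dimensions")

    def write(self, path) -> None:
        """Write three wide TSVs: <path>, <stem>.background.tsv, <stem>.flags.tsv."""
        import pathlib

        p = pathlib.Path(path)
        io.write_matrix(self.foreground, p)
        io.write_matrix(self.background, p.with_suffix(".background.tsv"))
        io.write_matrix(self.flags.astype(int), p.with_suffix(".flags.tsv"))

    @classmethod
    def read(cls, path) -> "ProbeIntensityMatrix":
        import pathlib

        p = pathlib.Path(path)
        return cls(
            foreground=io.read_matrix(p),
            background=io.read_matrix(p.with_suffix(".background.tsv")),
            flags=io.read_matrix(p.with_suffix(".flags.tsv")).astype(bool),
        )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float):
    """Latent normal (mu, sigma) matching an arithmetic mean/SD."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _latent_correlation(rho: float, s1: float, s2: float) -> float:
    """Latent normal correlation reproducing a log-normal scale correlation."""
    if s1 == 0 or s2 == 0:
        return 0.0
    arg = 1.0 + rho * np.sqrt(np.expm1(s1 ** 2) * np.expm1(s2 ** 2))
    return float(np.clip(np.log(arg) / (s1 * s2), -0.999999, 0.999999))


def generate_cohort(config: SimulationConfig, rng_seed=None) -> pd.DataFrame:
    """Draw one cohort table (one row per participant), deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    n = config.n_men + config.n_women
    kind = config.cohort_kind
    freq = _CATEGORICAL_DEFAULTS[kind]

    sex = np.array(["M"] * config.n_men + ["F"] * config.n_women)
    sample_id = np.array([f"{'D' if kind == 'discovery' else 'V'}{i + 1:04d}" for i in range(n)])

    a, b = (50 - 58.0) / 4.2, (65 - 58.0) / 4.2
    age = stats.truncnorm.rvs(a, b, loc=58.0, scale=4.2, size=n, random_state=rng)
    bmi = np.clip(rng.normal(26.2, 3.9, size=n), 16.0, 45.0)
    ses = rng.choice(SES_LEVELS, size=n, p=freq["ses"])
    smoking = (
        np.array(["never"] * n)
        if kind == "discovery"
        else rng.choice(SMOKING_LEVELS, size=n, p=freq["smoking"])
    )
    season = rng.choice(SEASON_LEVELS, size=n, p=freq["season"])
    daytime = rng.choice(DAYTIME_LEVELS, size=n, p=freq["daytime"])
    if kind == "validation":
        leukocytes = np.clip(rng.normal(6981.5, 1632.1, size=n), 2000.0, 15000.0)
        neutrophils = np.clip(rng.normal(56.8, 8.1, size=n), 25.0, 90.0)
    else:
        leukocytes = np.full(n, np.nan)
        neutrophils = np.full(n, np.nan)

    # correlated bivariate log-normal exposures with a centred season shift
    mu1, s1 = _lognormal_params(config.pm10_mean, config.pm10_sd)
    mu2, s2 = _lognormal_params(config.pm25_mean, config.pm25_sd)
    rho_lat = _latent_correlation(config.pm_correlation, s1, s2)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho_lat], [rho_lat, 1.0]], size=n)
    cold = (season == "cold").astype(float)
    shift = config.season_exposure_shift * (cold - freq["season"][0])
    pm10 = np.exp(mu1 + s1 * (z[:, 0] + shift))
    pm25 = np.exp(mu2 + s2 * (z[:, 1] + shift))

    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "ses": ses,
            "smoking": smoking,
            "season": season,
            "daytime": daytime,
            "leukocytes": leukocytes,
            "neutrophils": neutrophils,
            "pm10": pm10,
            "pm25": pm25,
        }
    )


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

def covariate_channels(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate encodings used by the generative model.

    Continuous channels are centred at their typical values so that covariate
    effects do not shift the overall expression level.
    """
    ch = pd.DataFrame(index=cohort.index)
    ch["age"] = cohort["age"] - 58.0
    ch["bmi"] = cohort["bmi"] - 26.0
    ch["season_cold"] = (cohort["season"] == "cold").astype(float)
    ch["smoking_former"] = (cohort["smoking"] == "former").astype(float)
    ch["smoking_current"] = (cohort["smoking"] == "current").astype(float)
    ch["leukocytes"] = (cohort["leukocytes"].fillna(7000.0) - 7000.0) / 1000.0
    ch["neutrophils"] = cohort["neutrophils"].fillna(57.0) - 57.0
    ch["ses_medium"] = (cohort["ses"] == "medium").astype(float)
    ch["ses_high"] = (cohort["ses"] == "high").astype(float)
    ch["daytime_1200_1500"] = (cohort["daytime"] == "1200-1500").astype(float)
    ch["daytime_1500_1800"] = (cohort["daytime"] == "1500-1800").astype(float)
    ch["daytime_gt2000"] = (cohort["daytime"] == ">2000").astype(float)
    return ch


def _effect_matrix(cohort: pd.DataFrame, config: SimulationConfig, genes) -> np.ndarray:
    """Gene x sample matrix of embedded exposure effects (log2 units)."""
    n = len(cohort)
    eff = np.zeros((len(genes), n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for spec in config.effect_table:
        if spec.gene_id not in gene_pos:
            raise ConfigurationError(f"effect_table gene {spec.gene_id!r} not simulated")
        mask = (cohort["sex"] == spec.sex).to_numpy(float)
        pm = cohort[spec.exposure].to_numpy(float)
        eff[gene_pos[spec.gene_id]] += (spec.log2fc_per_5ug / 5.0) * pm * mask
    return eff


def simulate_gene_matrix(
    cohort: pd.DataFrame, config: SimulationConfig, rng_seed=None
) -> pd.DataFrame:
    """Gene x sample log2 expression drawn from the generative linear model.

    This is the gene-level truth that probe-level intensities are built from;
    it can also be fed straight into the regression stage for calibration
    studies that do not involve the microarray preprocessing chain.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    genes = config.gene_ids()
    n = len(cohort)
    baselines = rng.uniform(*config.baseline_range, size=len(genes))
    values = baselines[:, None] + _effect_matrix(cohort, config, genes)
    ch = covariate_channels(cohort)
    cov_shift = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        cov_shift += beta * ch[name].to_numpy(float)
    values += cov_shift[None, :]
    if config.residual_sd > 0:
        values += rng.normal(0.0, config.residual_sd, size=values.shape)
    return pd.DataFrame(values, index=pd.Index(genes, name="id"), columns=cohort["sample_id"])


def generate_expression(
    cohort: pd.DataFrame, config: SimulationConfig, rng_seed=None
) -> ProbeIntensityMatrix:
    """Probe-level intensities: replicate spots, background, bad-spot flags.

    ``foreground = background + 2**log2_value`` makes background subtraction
    exactly invertible, so the preprocessing chain can recover the simulated
    log2 values when noise terms are zero.
    """
    config.validate()
    seed = config.seed if rng_seed is None else rng_seed
    ss = np.random.SeedSequence(seed)
    s_gene, s_probe, s_bg, s_flag = ss.spawn(4)

    gene_values = simulate_gene_matrix(cohort, config, rng_seed=s_gene)
    probe_map = config.resolved_probe_map()
    rng_probe = np.random.default_rng(s_probe)
    rng_bg = np.random.default_rng(s_bg)
    rng_flag = np.random.default_rng(s_flag)

    spot_ids, rows = [], []
    for gene in gene_values.index:
        gvals = gene_values.loc[gene].to_numpy(float)
        for spot in probe_map[gene]:
            offset = rng_probe.normal(0.0, config.probe_sd) if config.probe_sd > 0 else 0.0
            noise = (
                rng_probe.normal(0.0, config.probe_sd, size=gvals.shape)
                if config.probe_sd > 0
                else 0.0
            )
            spot_ids.append(spot)
            rows.append(gvals + offset + noise)
    values = np.asarray(rows)
    background = rng_bg.uniform(*config.background_range, size=values.shape)
    foreground = background + np.exp2(values)
    flags = rng_flag.random(size=values.shape) < config.flag_probability

    idx = pd.Index(spot_ids, name="id")
    cols = gene_values.columns
    return ProbeIntensityMatrix(
        foreground=pd.DataFrame(foreground, index=idx, columns=cols),
        background=pd.DataFrame(background, index=idx, columns=cols),
        flags=pd.DataFrame(flags, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# qPCR generation
# ---------------------------------------------------------------------------

def generate_cq(
    cohort: pd.DataFrame, config: SimulationConfig, rng_seed=None, assays=None
) -> pd.DataFrame:
    """Triplicate Cq table for the validation assays plus reference genes.

    The quantity model is ``Cq = c_g - log_E(Q)`` with ``log2 Q`` following the
    same linear model as the expression generator (baseline 0; reference genes
    carry no exposure effect). Replicates get Normal(0, cq_replicate_sd) noise;
    with probability ``cq_outlier_probability`` one replicate is displaced by
    more than half a cycle so the triplicate-concordance filter has work to do.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    targets = list(
        dict.fromkeys(e.gene_id for e in config.effect_table)
        if assays is None
        else [a for a in assays if a not in config.reference_genes]
    )
    bad_refs = set(e.gene_id for e in config.effect_table) & set(config.reference_genes)
    if bad_refs:
        raise ConfigurationError(
            f"reference genes must carry no exposure effect: {sorted(bad_refs)}"
        )
    all_assays = targets + list(config.reference_genes)

    n = len(cohort)
    kept = tuple(e for e in config.effect_table if e.gene_id in set(all_assays))
    eff_cfg = dataclasses.replace(
        config, effect_table=kept, probe_map={}, n_null_genes=0
    )
    log2q = _effect_matrix(cohort, eff_cfg, all_assays)
    ch = covariate_channels(cohort)
    cov_shift = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        cov_shift += beta * ch[name].to_numpy(float)
    log2q += cov_shift[None, :]
    if config.residual_sd > 0:
        log2q += rng.normal(0.0, config.residual_sd, size=log2q.shape)

    records = []
    for j, assay in enumerate(all_assays):
        e_fold = config.efficiencies.get(assay, 2.0)
        c_g = rng.uniform(22.0, 30.0)
        cq_centre = c_g - log2q[j] / np.log2(e_fold)
        reps = cq_centre[:, None] + rng.normal(0.0, config.cq_replicate_sd, size=(n, 3))
        outlier = rng.random(n) < config.cq_outlier_probability
        which = rng.integers(0, 3, size=n)
        magnitude = rng.uniform(0.8, 1.6, size=n) * rng.choice([-1.0, 1.0], size=n)
        reps[np.arange(n), which] += np.where(outlier, magnitude, 0.0)
        for i, sid in enumerate(cohort["sample_id"]):
            records.append(
                (
                    sid,
                    assay,
                    reps[i, 0],
                    reps[i, 1],
                    reps[i, 2],
                    round((e_fold - 1.0) * 100.0, 6),
                )
            )
    return pd.DataFrame(
        records,
        columns=["sample_id", "assay_id", "rep1", "rep2", "rep3", "efficiency_percent"],
    )
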