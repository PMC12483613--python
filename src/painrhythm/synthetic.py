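"""Seeded synthetic cohorts with known ground truth.

Every downstream stage of the pipeline gets a recovery test from this module:

* ``gen_diaries`` — 7-day, 3-slot integer NRS diaries drawn from four
  phenotype archetypes (constant-low, constant-high, rhythmic-increasing,
  rhythmic-decreasing, mixed) with slot-wise missingness and timestamp
  jitter.  The rhythmic archetypes are multiplicative: the expected evening
  score is morning x (1 + slope), so the >=30 % relative-change rule is
  directly targetable.  Default group sizes mirror the main study cohort
  (17 / 14 / 10 / 2 / 19).
* ``gen_covariates`` — PROMIS-style t-scores ~ Normal(50, 10) with
  configurable phenotype shifts, plus demographics and medication
  indicators; the opioid-use probability is exactly 0 in the
  rhythmic-increasing group and 0.44 elsewhere by default.
* ``gen_counts`` — paired day/night negative-binomial count matrices
  (Var = mu + alpha mu^2) with multiplicative batch, sex and time effects
  and one planted coexpression module: its genes share a latent factor whose
  per-sample score is shifted *down* in rhythmic-increasing participants by
  the configured module effect.
* ``gen_replication`` — a two-visit cohort (45 opioid users / 52 nonusers by
  default) with a positive opioid x time interaction planted in a designated
  "degranulation" gene set and a chronicity outcome generated at a
  configurable odds ratio for opioid use (2.6 by default).

All generators are deterministic given their config seed; independent
substreams are derived per product so regenerating one table never perturbs
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExprMatrix

PHENOS = ("constant_low", "constant_high", "rhythmic_up", "rhythmic_down", "mixed")

SLOT_HOURS = (8, 14, 20)
N_DAYS = 7


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class ArchetypeParams:
    """One phenotype's diary model: NRS units throughout."""

    baseline_mean: float  # expected 08:00 score
    diurnal_slope: float  # evening = morning * (1 + slope)
    day_noise_sd: float  # shared within a day
    within_day_noise_sd: float  # per slot


DEFAULT_ARCHETYPES: dict[str, ArchetypeParams] = {
    "constant_low": ArchetypeParams(2.5, 0.0, 0.4, 0.5),
    "constant_high": ArchetypeParams(7.0, 0.0, 0.4, 0.5),
    "rhythmic_up": ArchetypeParams(3.5, 0.6, 0.3, 0.4),
    "rhythmic_down": ArchetypeParams(5.5, -0.45, 0.3, 0.4),
    "mixed": ArchetypeParams(5.0, 0.0, 2.2, 1.3),
}

def low_noise_archetypes() -> dict[str, ArchetypeParams]:
    """Archetypes with damped noise for the structured phenotypes.

    The mixed archetype keeps its defining day-to-day and within-day
    variability (a noiseless 'unpredictable' pattern is a contradiction);
    the four structured archetypes get day/within-day SDs of 0.2/0.3 NRS
    units, the regime used for classifier-recovery benchmarks.
    """
    out = dict(DEFAULT_ARCHETYPES)
    for ph in ("constant_low", "constant_high", "rhythmic_up", "rhythmic_down"):
        a = out[ph]
        out[ph] = ArchetypeParams(a.baseline_mean, a.diurnal_slope, 0.2, 0.3)
    return out


#: group sizes of the main study cohort
DEFAULT_N = {
    "constant_low": 17,
    "constant_high": 14,
    "rhythmic_up": 10,
    "rhythmic_down": 2,
    "mixed": 19,
}


@dataclass
class CohortConfig:
    seed: int
    n_per_phenotype: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N))
    archetypes: dict[str, ArchetypeParams] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    missing_rate: float = 0.10
    timestamp_jitter_sd: float = 10.0  # minutes, truncated at +/-55
    start_date: str = "2019-03-04"

    def __post_init__(self) -> None:
        for ph, n in self.n_per_phenotype.items():
            if ph not in PHENOS:
                raise ConfigError(f"n_per_phenotype: unknown phenotype {ph!r}")
            if n < 0:
                raise ConfigError(f"n_per_phenotype[{ph}] must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ConfigError("missing_rate must be in [0, 1]")
        if self.timestamp_jitter_sd < 0:
            raise ConfigError("timestamp_jitter_sd must be >= 0")
        for ph, a in self.archetypes.items():
            if a.day_noise_sd < 0 or a.within_day_noise_sd < 0:
                raise ConfigError(f"archetypes[{ph}]: noise SDs must be >= 0")


@dataclass
class GroundTruth:
    """What the generators planted, keyed for downstream recovery tests."""

    phenotype: dict[str, str] = field(default_factory=dict)
    module_genes: list[str] = field(default_factory=list)
    interaction_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "module_genes": self.module_genes,
            "interaction_genes": self.interaction_genes,
        }


def gen_diaries(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate 7-day, 3-slot NRS diaries for pain, mood and fatigue.

    One row per non-missing entry: participant_id, timestamp (jittered around
    08:00 / 14:00 / 20:00), scale, score.  Pain follows the participant's
    archetype; mood and fatigue track the day's pain level with extra noise
    (inducing the positive rank correlations seen between symptom scales)
    without carrying the diurnal signature.  Scores are rounded
    half-away-from-zero and clipped to 0-10.
    """
    rng = _substream(config.seed, 1)
    truth = GroundTruth()
    start = pd.Timestamp(config.start_date)
    slot_mult = {0: 0.0, 1: 0.5, 2: 1.0}
    rows = []
    pid_counter = 0
    for ph in PHENOS:
        n = config.n_per_phenotype.get(ph, 0)
        arch = config.archetypes[ph]
        for _ in range(n):
            pid = f"P{pid_counter:03d}"
            pid_counter += 1
            truth.phenotype[pid] = ph
            for day in range(N_DAYS):
                day_off = rng.normal(0.0, arch.day_noise_sd)
                day_pain_mean = arch.baseline_mean * (1 + 0.5 * arch.diurnal_slope) + day_off
                mood_base = 0.8 * day_pain_mean + rng.normal(0, 1.2)
                fatigue_base = 0.9 * day_pain_mean + rng.normal(0, 1.0)
                for slot, hour in enumerate(SLOT_HOURS):
                    expected = arch.baseline_mean * (
                        1 + slot_mult[slot] * arch.diurnal_slope
                    )
                    pain = expected + day_off + rng.normal(0, arch.within_day_noise_sd)
                    mood = mood_base + rng.normal(0, 0.8)
                    fatigue = fatigue_base + rng.normal(0, 0.8)
                    jitter = float(
                        np.clip(rng.normal(0, config.timestamp_jitter_sd), -55, 55)
                    )
                    ts = start + pd.Timedelta(days=day, hours=hour, minutes=jitter)
                    for scale, val in (("pain", pain), ("mood", mood), ("fatigue", fatigue)):
                        if rng.random() < config.missing_rate:
                            continue
                        score = int(np.clip(_round_half_away(np.array(val)), 0, 10))
                        rows.append(
                            {
                                "participant_id": pid,
                                "timestamp": ts.isoformat(),
                                "scale": scale,
                                "score": score,
                            }
                        )
    return pd.DataFrame(rows, columns=["participant_id", "timestamp", "scale", "score"]), truth


@dataclass
class CovariateConfig:
    seed: int
    promis_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    # phenotype -> probability of opioid use; rhythmic_up forced to 0
    opioid_prob: dict[str, float] = field(
        default_factory=lambda: {ph: (0.0 if ph == "rhythmic_up" else 0.44) for ph in PHENOS}
    )
    antidepressant_prob: dict[str, float] = field(
        default_factory=lambda: {
            "rhythmic_up": 0.10,
            "constant_low": 0.118,
            "mixed": 0.421,
            "constant_high": 0.571,
            "rhythmic_down": 0.20,
        }
    )

    def __post_init__(self) -> None:
        if self.opioid_prob.get("rhythmic_up", 0.0) != 0.0:
            raise ConfigError("opioid_prob[rhythmic_up] must be 0")
        for d, nm in ((self.opioid_prob, "opioid_prob"), (self.antidepressant_prob, "antidepressant_prob")):
            for ph, p in d.items():
                if not 0 <= p <= 1:
                    raise ConfigError(f"{nm}[{ph}] must be a probability")


PROMIS_SCALES = ("depression", "sleep_disturbance", "pain_interference", "physical_function")


def gen_covariates(truth: GroundTruth, config: CovariateConfig) -> pd.DataFrame:
    """Per-participant questionnaire covariates tied to the true phenotypes.

    PROMIS-style t-scores are Normal(50, 10) plus any configured per-scale
    phenotype shift; pain catastrophizing (PCS-6, 0-24) is generated on its
    own scale.  The opioid indicator is Bernoulli with probability exactly 0
    for the rhythmic-increasing group.
    """
    if not truth.phenotype:
        raise ConfigError("ground truth is empty")
    rng = _substream(config.seed, 2)
    rows = []
    for pid, ph in truth.phenotype.items():
        row = {"participant_id": pid, "phenotype": ph}
        for scale_name in PROMIS_SCALES:
            shift = config.promis_shifts.get(scale_name, {}).get(ph, 0.0)
            row[scale_name] = float(rng.normal(50 + shift, 10))
        row["pcs6"] = float(np.clip(rng.normal(10, 4), 0, 24))
        row["age"] = float(np.clip(rng.normal(51.8, 14.4), 18, 90))
        row["sex"] = "female" if rng.random() < 35 / 62 else "male"
        row["smoking"] = bool(rng.random() < 0.2)
        row["opioid"] = bool(rng.random() < config.opioid_prob.get(ph, 0.0))
        row["antidepressant"] = bool(rng.random() < config.antidepressant_prob.get(ph, 0.0))
        row["n_pain_meds"] = int(rng.poisson(2.0 if ph in ("constant_high", "mixed") else 1.2))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CountsConfig:
    seed: int
    n_transcripts: int = 600
    planted_module_size: int = 50
    module_effect: float = 1.0  # latent-factor downshift in rhythmic_up samples
    module_loading_mean: float = 0.8  # log-scale factor loading of member genes
    module_loading_sd: float = 0.20
    batch_effect_sd: float = 0.30  # per gene x batch, log scale
    sex_effect_sd: float = 0.10
    time_effect_sd: float = 0.20
    nb_dispersion: float = 0.15
    lib_size_range: tuple[float, float] = (8e4, 1.6e5)
    base_logmean_range: tuple[float, float] = (np.log(20.0), np.log(500.0))

    def __post_init__(self) -> None:
        if self.planted_module_size > self.n_transcripts:
            raise ConfigError("planted_module_size exceeds n_transcripts")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise ConfigError("lib_size_range must be positive and ordered")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def gen_counts(
    truth: GroundTruth, config: CountsConfig
) -> tuple[ExprMatrix, ExprMatrix, pd.DataFrame]:
    """Paired day/night NB count matrices with one planted coexpression module.

    Each participant contributes a day (08:00) and a night (20:00) sample.
    log-mean model per gene g and sample s:
    ``log mu = log lib_s + base_g + b[g, batch_s] + sex_g * female_s +
    time_g * night_s + load_g * f_s`` where the latent factor
    ``f_s ~ N(-effect * rhythmic_up_s, 1)`` is shared by the planted module's
    genes only.  Counts are NB with Var = mu + alpha mu^2.  Returns the day
    matrix, night matrix and combined sample sheet; the planted member ids
    land in the ground truth.
    """
    if not truth.phenotype:
        raise ConfigError("ground truth is empty")
    rng = _substream(config.seed, 3)
    pids = list(truth.phenotype)
    genes = [f"T{i:05d}" for i in range(config.n_transcripts)]
    module = genes[: config.planted_module_size]
    truth.module_genes = list(module)

    n_p = len(pids)
    batches = np.array(["b1" if i % 2 == 0 else "b2" for i in range(n_p)])
    sexes = np.array(["female" if rng.random() < 35 / 62 else "male" for _ in range(n_p)])

    base = rng.uniform(*config.base_logmean_range, size=config.n_transcripts)
    rel = base - np.log(np.sum(np.exp(base)))  # relative log abundance
    batch_eff = rng.normal(0, config.batch_effect_sd, size=(config.n_transcripts, 2))
    sex_eff = rng.normal(0, config.sex_effect_sd, size=config.n_transcripts)
    time_eff = rng.normal(0, config.time_effect_sd, size=config.n_transcripts)
    loadings = np.zeros(config.n_transcripts)
    loadings[: config.planted_module_size] = rng.normal(
        config.module_loading_mean, config.module_loading_sd, size=config.planted_module_size
    )

    mats = {}
    sheets = []
    for t_idx, tp in enumerate(("day", "night")):
        sample_ids = [f"{pid}_{tp}" for pid in pids]
        lib = rng.uniform(*config.lib_size_range, size=n_p)
        shift = np.array(
            [-config.module_effect if truth.phenotype[p] == "rhythmic_up" else 0.0 for p in pids]
        )
        factor = rng.normal(shift, 1.0)
        log_mu = (
            np.log(lib)[None, :]
            + rel[:, None]
            + batch_eff[:, [0 if b == "b1" else 1 for b in batches]]
            + sex_eff[:, None] * (sexes == "female")[None, :]
            + time_eff[:, None] * float(t_idx)
            + loadings[:, None] * factor[None, :]
        )
        counts = _nb_draw(rng, np.exp(log_mu), config.nb_dispersion)
        mats[tp] = pd.DataFrame(counts, index=genes, columns=sample_ids)
        sheets.append(
            pd.DataFrame(
                {
                    "participant": pids,
                    "time": tp,
                    "batch": batches,
                    "sex": sexes,
                    "phenotype": [truth.phenotype[p] for p in pids],
                },
                index=sample_ids,
            )
        )
    sheet = pd.concat(sheets)
    day = ExprMatrix(mats["day"], sheet.loc[mats["day"].columns])
    night = ExprMatrix(mats["night"], sheet.loc[mats["night"].columns])
    return day, night, sheet


@dataclass
class ReplicationConfig:
    seed: int
    n_users: int = 45
    n_nonusers: int = 52
    n_genes: int = 400
    set_size: int = 40
    interaction_log_fc: float = 0.5  # planted opioid x time log effect
    chronicity_or: float = 2.6
    baseline_chronicity: float = 0.35
    nb_dispersion: float = 0.15
    lib_size_range: tuple[float, float] = (8e4, 1.6e5)

    def __post_init__(self) -> None:
        if self.n_users + self.n_nonusers <= 6:
            raise ConfigError("cohort too small for the covariate model")
        if self.set_size > self.n_genes:
            raise ConfigError("set_size exceeds n_genes")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")


def gen_replication(
    config: ReplicationConfig, truth: GroundTruth | None = None
) -> tuple[ExprMatrix, pd.DataFrame]:
    """Two-visit replication cohort with a planted opioid x time gene set.

    Participants (opioid users and nonusers) are sampled at baseline and a
    follow-up visit.  Genes in the designated set get an opioid x time
    interaction of ``interaction_log_fc`` (positive: expression in users
    lingers or rises over time); all genes share small age / sex / RIN /
    smoking nuisance effects.  The chronicity outcome (``resolved`` False)
    is Bernoulli from a logistic model whose opioid coefficient is
    log(chronicity_or).  Returns the combined two-visit count matrix (with
    its sample sheet) and the per-participant design table.
    """
    rng = _substream(config.seed, 4)
    truth = truth if truth is not None else GroundTruth()
    n = config.n_users + config.n_nonusers
    pids = [f"R{i:03d}" for i in range(n)]
    opioid = np.array([True] * config.n_users + [False] * config.n_nonusers)
    age = np.clip(rng.normal(48, 13, n), 18, 85)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    smoker = rng.random(n) < 0.25
    rin = np.clip(rng.normal(8.5, 0.5, n), 7.5, 10.0)
    b0 = np.log(config.baseline_chronicity / (1 - config.baseline_chronicity))
    lin = b0 + np.log(config.chronicity_or) * opioid + 0.01 * (age - 48) - 0.1 * (sex == "female")
    chronic = rng.random(n) < 1.0 / (1.0 + np.exp(-lin))
    design = pd.DataFrame(
        {
            "participant": pids,
            "opioids": opioid,
            "age": age,
            "sex": sex,
            "smoker": smoker,
            "rin": rin,
            "chronic": chronic,
            "resolved": ~chronic,
        }
    )

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    in_set = np.zeros(config.n_genes, dtype=bool)
    in_set[: config.set_size] = True
    truth.interaction_genes = [g for g, s in zip(genes, in_set) if s]
    base = rng.uniform(np.log(20.0), np.log(500.0), config.n_genes)
    rel = base - np.log(np.sum(np.exp(base)))
    age_eff = rng.normal(0, 0.002, config.n_genes)
    sex_eff = rng.normal(0, 0.08, config.n_genes)
    rin_eff = rng.normal(0, 0.05, config.n_genes)
    smoke_eff = rng.normal(0, 0.08, config.n_genes)
    time_drift = rng.normal(0, 0.15, config.n_genes)
    opioid_main = rng.normal(0, 0.08, config.n_genes)
    interact = np.where(in_set, config.interaction_log_fc, 0.0)

    cols, meta = [], []
    counts = np.zeros((config.n_genes, 2 * n), dtype=int)
    j = 0
    for t_idx, visit in enumerate(("t0", "t1")):
        lib = rng.uniform(*config.lib_size_range, size=n)
        for i, pid in enumerate(pids):
            log_mu = (
                np.log(lib[i])
                + rel
                + age_eff * (age[i] - 48)
                + sex_eff * (sex[i] == "female")
                + rin_eff * (rin[i] - 8.5)
                + smoke_eff * smoker[i]
                + time_drift * t_idx
                + opioid_main * opioid[i]
                + interact * opioid[i] * t_idx
            )
            counts[:, j] = _nb_draw(rng, np.exp(log_mu), config.nb_dispersion)
            cols.append(f"{pid}_{visit}")
            meta.append(
                {
                    "participant": pid,
                    "time": t_idx,
                    "opioids": bool(opioid[i]),
                    "age": float(age[i]),
                    "sex": sex[i],
                    "smoker": bool(smoker[i]),
                    "rin": float(rin[i]),
                    "resolved": bool(~chronic[i]),
                }
            )
            j += 1
    sheet = pd.DataFrame(meta, index=cols)
    expr = ExprMatrix(pd.DataFrame(counts, index=genes, columns=cols), sheet)
    return expr, design
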