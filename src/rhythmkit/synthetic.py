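"""Seeded in-silico cohorts of minute-level step / heart-rate recordings.

The generator emulates 7-day wrist-wearable recordings of community-dwelling
older adults.  Each group (robust / prefrail / frail) has a
:class:`GroupProfile` whose defaults are centred on the cohort-level values
the pipeline is meant to reproduce: group mean daily steps around
9080 / 7809 / 6005, heart-rate circadian parameters around
(min 58.7, amp 21.7, alpha -0.41, beta 17.6, acrophase 14.0), and a frail
group with a blunted activity-rest heart-rate contrast, lower interdaily
stability and higher intradaily CV than the robust group.

Mechanics per participant:

* a two-state (rest/active) minute-resolution Markov chain whose stationary
  active probability follows a sigmoid-squashed 24-h cosine, shifted by the
  group phase shift and modulated day-by-day by a log-normal level
  multiplier and a Gaussian phase jitter whose spread scales with the
  group's ``fragmentation`` rate (day-to-day irregularity is what raises the
  across-day hourly CV and lowers IS; burst length itself is geometric with
  mean 1/fragmentation);
* steps are overdispersed (negative binomial) counts in active minutes,
  zero at rest;
* heart rate = extended-cosinor curve + coupling x (recent 5-min step rate)
  + AR(1) noise (lag-1 coefficient 0.7, innovation SD ``noise_sd``);
* non-wear: Poisson-placed blocks of geometric length (mean 45 min) masking
  both streams at ``nonwear_rate`` expected hours/day.

One RNG stream per participant, derived from (master seed, participant
index), so cohorts are reproducible regardless of generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .cosinor import evaluate_model
from .io import (
    QUESTIONNAIRE_COLUMNS,
    QUESTIONNAIRE_ITEMS,
    ParticipantSeries,
    write_minute_table,
)
from .nonparametric import intradaily_cv
from .preprocessing import PreprocessConfig, preprocess

logger = logging.getLogger(__name__)

GROUPS = ("robust", "prefrail", "frail")

# activity waveform constants (shared shape; group differences enter through
# intensity, phase shift and fragmentation)
_ACT_ALPHA = -0.1
_ACT_BETA = 6.0
_ACT_PHASE = 13.0   # clock hour of peak activity propensity
_P_ACTIVE_MAX = 0.8
_AR1 = 0.7
_NB_DISPERSION = 0.5
_STEP_RATE_WINDOW = 5      # minutes for the HR-coupling step rate
_NONWEAR_BLOCK_MEAN = 45.0  # minutes
_NONWEAR_DAY_CAP = 210      # max non-wear minutes per day (< the 4 h margin)
_DAY_SIGMA_PER_FRAG = 6.0   # log-normal daily level sigma per unit fragmentation
_JITTER_H_PER_FRAG = 8.0    # daily phase jitter SD (h) per unit fragmentation
# hour-block activity modulation: real step recordings are far lumpier than a
# smooth diurnal curve, so each clock-hour block gets a log-normal level
# multiplier whose spread also grows with fragmentation
_BLOCK_SIGMA_BASE = 0.45
_BLOCK_SIGMA_PER_FRAG = 6.0


@dataclass
class GroupProfile:
    """Ground-truth generating parameters for one frailty group."""

    group: str
    cosinor_truth: tuple[float, float, float, float, float]  # min, amp, alpha, beta, phi
    activity_intensity: float  # mean steps/min while active
    activity_coupling: float   # bpm per (steps/min) of recent step rate
    fragmentation: float       # per-minute burst exit probability
    phase_shift: float         # hours added to activity onset
    noise_sd: float            # AR(1) innovation SD, bpm
    nonwear_rate: float        # expected missing hours/day
    score_probs: tuple[float, ...]  # P(social frailty score = 0..5)
    age_mean: float = 77.0
    female_prob: float = 0.9

    def __post_init__(self) -> None:
        if min(self.activity_intensity, self.fragmentation, self.noise_sd,
               self.nonwear_rate, self.activity_coupling) < 0:
            raise ValueError("group profile rates must be >= 0")


DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "robust": GroupProfile(
        group="robust",
        cosinor_truth=(58.79, 21.88, -0.48, 21.0, 14.12),
        activity_intensity=18.0,
        activity_coupling=0.30,
        fragmentation=0.030,
        phase_shift=0.0,
        noise_sd=2.5,
        nonwear_rate=1.5,
        score_probs=(0.92, 0.06, 0.02, 0.0, 0.0, 0.0),
        age_mean=76.3,
        female_prob=0.93,
    ),
    "prefrail": GroupProfile(
        group="prefrail",
        cosinor_truth=(57.19, 23.57, -0.35, 13.51, 13.70),
        activity_intensity=15.5,
        activity_coupling=0.20,
        fragmentation=0.045,
        phase_shift=-0.3,
        noise_sd=2.5,
        nonwear_rate=1.5,
        score_probs=(0.04, 0.92, 0.04, 0.0, 0.0, 0.0),
        age_mean=77.2,
        female_prob=0.87,
    ),
    "frail": GroupProfile(
        group="frail",
        cosinor_truth=(61.72, 17.52, -0.41, 20.96, 14.50),
        activity_intensity=15.0,
        activity_coupling=0.10,
        fragmentation=0.080,
        phase_shift=0.5,
        noise_sd=2.5,
        nonwear_rate=2.0,
        score_probs=(0.02, 0.04, 0.47, 0.28, 0.14, 0.05),
        age_mean=78.3,
        female_prob=0.95,
    ),
}

# questionnaire score distributions per group: (mean, sd) by column
_QUESTIONNAIRE_NORMS = {
    "robust": {"grip_strength": (23.8, 4.4), "walking_speed": (1.34, 0.29),
               "tmt_a": (1.31, 0.39), "tmt_b": (3.04, 2.0), "dsst": (47.0, 15.8)},
    "prefrail": {"grip_strength": (24.6, 5.9), "walking_speed": (1.38, 0.30),
                 "tmt_a": (1.30, 0.29), "tmt_b": (3.42, 2.5), "dsst": (45.6, 12.9)},
    "frail": {"grip_strength": (22.1, 5.6), "walking_speed": (1.33, 0.30),
              "tmt_a": (1.40, 0.37), "tmt_b": (3.09, 1.1), "dsst": (39.6, 10.4)},
}

_DEFAULT_WLM = (28.3, 0.15, 0.04)  # a0, a1 (age), a2 (ICV x 100)
_WLM_NOISE_SD = 2.8


def activity_probability(
    minutes: np.ndarray,
    profile: GroupProfile,
    day_level: np.ndarray | None = None,
    day_jitter: np.ndarray | None = None,
) -> np.ndarray:
    """Stationary per-minute active probability for given minute indexes."""
    day = minutes // 1440
    tod = (minutes % 1440) / 60.0
    jitter = 0.0 if day_jitter is None else day_jitter[day]
    level = 1.0 if day_level is None else day_level[day]
    c = np.cos((tod - _ACT_PHASE - profile.phase_shift - jitter) * np.pi / 12.0)
    l = expit(_ACT_BETA * (c - _ACT_ALPHA))
    return np.clip(_P_ACTIVE_MAX * level * l, 0.0, 0.95)


def expected_daily_steps(profile: GroupProfile) -> float:
    """Expected daily steps under the stationary activity process.

    Integrates the clipped log-normal day/block modulation numerically
    (quantile grid), so the value is an honest expectation of the generator,
    not of the smooth waveform alone.
    """
    base = activity_probability(np.arange(1440), profile)  # already clipped
    frag = profile.fragmentation
    sigma = float(
        np.hypot(_DAY_SIGMA_PER_FRAG * frag,
                 (_BLOCK_SIGMA_BASE + _BLOCK_SIGMA_PER_FRAG * frag) if frag > 0 else 0.0)
    )
    if sigma == 0:
        return float(profile.activity_intensity * base.sum())
    from scipy import stats

    qs = (np.arange(2000) + 0.5) / 2000
    mult = stats.lognorm.ppf(qs, s=sigma, scale=np.exp(-0.5 * sigma**2))
    p = np.minimum(base[:, None] * mult[None, :], 0.95).mean(axis=1)
    return float(profile.activity_intensity * p.sum())


def _simulate_states(p: np.ndarray, q: float, u: np.ndarray) -> np.ndarray:
    """Two-state chain with stationary active prob p(t) and exit rate q."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_on = np.minimum(1.0, q * p / np.maximum(1.0 - p, 1e-12))
    stay_active = (u >= q).tolist()  # precomputed comparisons keep the loop cheap
    turn_on = (u < p_on).tolist()
    state = np.empty(len(p), dtype=bool)
    s = bool(u[0] < p[0])
    state[0] = s
    for i in range(1, len(p)):
        s = stay_active[i] if s else turn_on[i]
        state[i] = s
    return state


def simulate_participant(
    profile: GroupProfile,
    days: int = 7,
    seed: int | np.random.Generator = 0,
    participant_id: str = "P001",
    start: str = "2024-03-04",
    quantize: bool = True,
) -> tuple[ParticipantSeries, dict]:
    """Simulate one participant; returns the canonical series and its truth."""
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = days * 1440
    minutes = np.arange(T)
    tod = (minutes % 1440) / 60.0

    sigma = _DAY_SIGMA_PER_FRAG * profile.fragmentation
    day_level = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=days)) if sigma > 0 \
        else np.ones(days)
    jitter_sd = _JITTER_H_PER_FRAG * profile.fragmentation
    day_jitter = rng.normal(0.0, jitter_sd, size=days) if jitter_sd > 0 else np.zeros(days)
    block_sigma = (_BLOCK_SIGMA_BASE + _BLOCK_SIGMA_PER_FRAG * profile.fragmentation) \
        if profile.fragmentation > 0 else 0.0
    if block_sigma > 0:
        block_level = np.exp(
            rng.normal(-0.5 * block_sigma**2, block_sigma, size=days * 24)
        )
    else:
        block_level = np.ones(days * 24)

    p = activity_probability(minutes, profile, day_level, day_jitter)
    p = np.clip(p * block_level[minutes // 60], 0.0, 0.95)
    u = rng.random(T)
    if profile.fragmentation > 0:
        state = _simulate_states(p, profile.fragmentation, u)
    else:
        state = np.zeros(T, dtype=bool)  # degenerate chain: permanently at rest

    mu = profile.activity_intensity
    if mu > 0:
        r = _NB_DISPERSION
        counts = rng.negative_binomial(r, r / (r + mu), size=T).astype(float)
        steps = counts * state
    else:
        steps = np.zeros(T)

    kernel = np.ones(_STEP_RATE_WINDOW) / _STEP_RATE_WINDOW
    step_rate = lfilter(kernel, [1.0], steps)  # causal 5-min mean

    innov = rng.normal(0.0, profile.noise_sd, size=T) if profile.noise_sd > 0 else np.zeros(T)
    ar_noise = lfilter([1.0], [1.0, -_AR1], innov)
    hr = evaluate_model(tod, *profile.cosinor_truth)
    hr = hr + profile.activity_coupling * step_rate + ar_noise
    hr = np.clip(hr, 30.0, 190.0)
    if quantize:
        hr = np.round(hr)
        steps = np.round(steps)

    wear_mask = np.zeros(T, dtype=bool)  # True = non-wear
    if profile.nonwear_rate > 0:
        lam = profile.nonwear_rate * 60.0 / (1440.0 * _NONWEAR_BLOCK_MEAN)
        starts = np.flatnonzero(rng.random(T) < lam)
        if len(starts):
            lengths = rng.geometric(1.0 / _NONWEAR_BLOCK_MEAN, size=len(starts))
            for s0, ln in zip(starts, lengths):
                wear_mask[s0 : s0 + ln] = True
        # compliant wearers: cap non-wear below the valid-day margin (4 h)
        # so day validity is governed by the recording length, not by chance
        for d in range(days):
            day_slice = wear_mask[d * 1440 : (d + 1) * 1440]
            masked = np.flatnonzero(day_slice)
            if len(masked) > _NONWEAR_DAY_CAP:
                day_slice[masked[_NONWEAR_DAY_CAP:]] = False

    index = pd.date_range(pd.Timestamp(start), periods=T, freq="min")
    df = pd.DataFrame(
        {
            "steps": np.where(wear_mask, np.nan, steps),
            "heart_rate": np.where(wear_mask, np.nan, hr),
        },
        index=index,
    )
    df["valid"] = df["steps"].notna() & df["heart_rate"].notna()
    series = ParticipantSeries(participant_id=participant_id, data=df)
    mn, amp, alpha, beta, phi = profile.cosinor_truth
    truth = {
        "participant_id": participant_id,
        "group": profile.group,
        "minimum_true": mn,
        "amplitude_true": amp,
        "alpha_true": alpha,
        "beta_true": beta,
        "acrophase_true": phi,
        "activity_intensity": profile.activity_intensity,
        "activity_coupling": profile.activity_coupling,
        "fragmentation": profile.fragmentation,
        "phase_shift": profile.phase_shift,
        "noise_sd": profile.noise_sd,
        "nonwear_rate": profile.nonwear_rate,
        "expected_daily_steps": expected_daily_steps(profile),
        "days": days,
    }
    return series, truth


def _fast_step_icv(
    series: ParticipantSeries, config: PreprocessConfig | None = None
) -> float:
    """Step ICV via an aligned-day reshape shortcut.

    Generator output is exactly midnight-aligned whole days, so the hourly
    aggregation (same 20 h / 30-minute rules as :mod:`.preprocessing`)
    reduces to array reshapes; used to keep the WLM-generation loop cheap.
    Agreement with the general pipeline is asserted in the test suite.
    """
    config = config or PreprocessConfig()
    df = series.data
    T = len(df)
    if T % 1440 != 0 or df.index[0] != df.index[0].normalize():
        day_set = preprocess(series, config)
        hourly = day_set.valid_hourly("steps")
    else:
        days = T // 1440
        valid = df["valid"].to_numpy().reshape(days, 24, 60)
        steps = np.nan_to_num(df["steps"].to_numpy()).reshape(days, 24, 60)
        counts = valid.sum(axis=2)
        day_valid = counts.sum(axis=1) / 60.0 >= config.valid_day_hours
        sums = np.where(valid, steps, 0.0).sum(axis=2)
        scale = 60.0 / np.maximum(counts, 1) if config.rescale_partial_hours else 1.0
        hourly = np.where(counts >= config.hour_min_minutes, sums * scale, np.nan)
        hourly = hourly[day_valid]
    if hourly.shape[0] < 2:
        return np.nan
    return intradaily_cv(hourly)


@dataclass
class SyntheticCohort:
    series: dict[str, ParticipantSeries]
    questionnaire: pd.DataFrame
    truth: pd.DataFrame
    seed: int

    def write(self, outdir) -> None:
        """Emit the long minute CSV, questionnaire CSV and truth CSV."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_minute_table(self.series, out / "minutes.csv")
        self.questionnaire.to_csv(out / "questionnaire.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _draw_questionnaire(
    rng: np.random.Generator, pid: str, profile: GroupProfile
) -> tuple[dict, int]:
    age = float(np.round(np.clip(rng.normal(profile.age_mean, 5.7), 65, 92)))
    sex = "female" if rng.random() < profile.female_prob else "male"
    score = int(rng.choice(6, p=np.asarray(profile.score_probs) / np.sum(profile.score_probs)))
    positive = rng.permutation(5)[:score]
    items = {name: float(i in positive) for i, name in enumerate(QUESTIONNAIRE_ITEMS)}
    norms = _QUESTIONNAIRE_NORMS[profile.group]
    row = {"participant_id": pid, "age": age, "sex": sex, **items}
    for colname, (m, s) in norms.items():
        row[colname] = float(np.round(max(rng.normal(m, s), 0.1), 2))
    return row, score


def simulate_cohort(
    n_per_group: tuple[int, int, int] = (28, 39, 19),
    days: int = 7,
    seed: int = 0,
    n_low_wear: int = 0,
    low_wear_days: int = 4,
    profiles: dict[str, GroupProfile] | None = None,
    wlm_coefs: tuple[float, float, float] = _DEFAULT_WLM,
    wlm_noise_sd: float = _WLM_NOISE_SD,
    quantize: bool = True,
    compute_icv: bool = True,
    preprocess_config: PreprocessConfig | None = None,
) -> SyntheticCohort:
    """Simulate a full cohort with group-dependent ground truth.

    ``n_low_wear`` participants (spread over the groups by largest
    remainder) receive only ``low_wear_days`` days of recording, so they
    fail the 5-valid-day inclusion rule downstream.  WLM is generated as
    ``a0 - a1*age - a2*(step ICV x 100) + noise`` from the participant's own
    realized ICV, so regression recovery against extracted features is
    well-posed.
    """
    profiles = profiles or DEFAULT_PROFILES
    if any(n < 1 for n in n_per_group):
        raise ValueError("need at least one participant per group")
    n_total = sum(n_per_group)
    if n_low_wear > n_total:
        raise ValueError("n_low_wear exceeds cohort size")

    # largest-remainder split of low-wear participants across groups
    quota = [n_low_wear * n / n_total for n in n_per_group]
    low = [int(q) for q in quota]
    rem = sorted(range(3), key=lambda g: quota[g] - low[g], reverse=True)
    for g in rem:
        if sum(low) >= n_low_wear:
            break
        low[g] += 1

    a0, a1, a2 = wlm_coefs
    series_map: dict[str, ParticipantSeries] = {}
    q_rows, t_rows = [], []
    idx = 0
    for g, group in enumerate(GROUPS):
        profile = profiles[group]
        for j in range(n_per_group[g]):
            pid = f"P{idx + 1:03d}"
            is_low = j >= n_per_group[g] - low[g]
            p_days = low_wear_days if is_low else days
            rng_series = np.random.default_rng([seed, idx])
            series, truth = simulate_participant(
                profile, days=p_days, seed=rng_series,
                participant_id=pid, quantize=quantize,
            )
            rng_q = np.random.default_rng([seed, idx, 1])
            row, score = _draw_questionnaire(rng_q, pid, profile)

            icv = np.nan
            if compute_icv:
                icv = _fast_step_icv(series, preprocess_config)
            icv_term = icv * 100.0 if not np.isnan(icv) else 110.0
            wlm = a0 - a1 * row["age"] - a2 * icv_term + rng_q.normal(0.0, wlm_noise_sd)
            row["wlm"] = float(np.round(np.clip(wlm, 0, 20), 1))
            # column order per the documented questionnaire schema
            q_rows.append({c: row[c] for c in QUESTIONNAIRE_COLUMNS})
            truth.update(
                {
                    "score_true": score,
                    "icv_true": icv,
                    "low_wear": is_low,
                    "wlm_a0": a0,
                    "wlm_a1": a1,
                    "wlm_a2": a2,
                }
            )
            t_rows.append(truth)
            series_map[pid] = series
            idx += 1
    return SyntheticCohort(
        series=series_map,
        questionnaire=pd.DataFrame(q_rows),
        truth=pd.DataFrame(t_rows),
        seed=seed,
    )


def simulate_frailty_feature_table(
    n: int = 300,
    seed: int = 0,
    log_or_frail_per_icv100: float = 0.04,
    log_or_prefrail_per_icv100: float = 0.0,
    icv100_mean: float = 112.0,
    icv100_sd: float = 15.0,
) -> pd.DataFrame:
    """Tabular simulator for effect-recovery harnesses.

    Draws an ICV x 100 covariate and assigns the frailty group from a
    multinomial logit with the planted per-unit log-odds (robust reference),
    intercepts chosen so group shares resemble the 33/45/22% cohort split.
    Returns columns ``participant_id``, ``ICV.st`` (unscaled) and ``group``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(icv100_mean, icv100_sd, size=n)
    b0_pre = 0.4 - log_or_prefrail_per_icv100 * icv100_mean
    b0_frail = -0.4 - log_or_frail_per_icv100 * icv100_mean
    eta = np.column_stack(
        [
            np.zeros(n),
            b0_pre + log_or_prefrail_per_icv100 * x,
            b0_frail + log_or_frail_per_icv100 * x,
        ]
    )
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    cum = prob.cumsum(axis=1)
    draws = rng.random(n)
    codes = (draws[:, None] > cum).sum(axis=1)
    return pd.DataFrame(
        {
            "participant_id": [f"S{i + 1:04d}" for i in range(n)],
            "ICV.st": x / 100.0,
            "group": pd.Categorical.from_codes(codes, categories=list(GROUPS)),
        }
    )
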