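"""Synthetic grey-seal colony simulator.

No field recordings are distributed with the study, so this module generates
audio and annotation tables with the statistical structure the analysis
assumes: tonal harmonic pup calls emitted in short sequences over ages 0-19
days, where the probability that a sequence is "planted" as a match to a
playback template follows a condition-specific developmental trajectory:

* control pups produce chance matches to any template, declining from about
  20% of calls at ages 0-4 days to about 2% at weaning;
* playback pups increasingly match their own template, doubling from birth
  to weaning, with varied-context pups reaching about 35% of calls at
  weaning and matching 1.5x more often than feeding-context pups overall;
* for varied-context pups, planted sequences also become more similar to
  the template with age (the configured Mantel-r gain from birth to
  weaning).

Trajectories are linear on the log-odds scale; the two anchor values of
each trajectory are interpreted as means over the first (0-4 days) and last
(15-19 days) age bins, which is the form in which the study reports them.

A second, purely tabular generator draws call-level match outcomes directly
from a logistic random-intercept model at specified odds ratios, for
parameter-recovery experiments on the inference stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .synth import synthesize_call
from .waveform import Waveform

CONDITIONS = ("control", "feeding", "varied")
SEXES = ("M", "F")
AGE_BIN_EDGES = (0, 5, 10, 15, 20)  # ages 0-4, 5-9, 10-14, 15-19
DEFAULT_SEED = 20211025

#: Odds ratios of the call-level logistic mixed model (intercept, age,
#: condition contrasts vs control, age x condition), with age coded as the
#: four 5-day bins (0-3). Used by :func:`simulate_match_table_from_effects`.
DEFAULT_MATCH_EFFECTS = {
    "intercept": 1.116,
    "age": 1.031,
    "condition_feed": 1.243,
    "condition_varied": 1.651,
    "age_x_feed": 1.544,
    "age_x_varied": 1.981,
}


def age_bin(age_days) -> np.ndarray:
    """Map age in days to the ordinal age bin 0-3 (5-day bins)."""
    return np.clip(np.asarray(age_days) // 5, 0, 3)


@dataclass(frozen=True)
class PupRecord:
    """One study animal."""

    pup_id: str
    sex: str
    condition: str
    stimulus_id: str  # 'a', 'b', 'ab' or 'none'
    birth_day: int = 0
    wean_day: int = 19

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if (self.condition == "control") != (self.stimulus_id == "none"):
            raise ValueError("control pups and only control pups have stimulus 'none'")
        if self.condition != "control" and self.stimulus_id not in ("a", "b", "ab"):
            raise ValueError("playback pups need stimulus 'a', 'b' or 'ab'")
        if not 0 <= self.birth_day < self.wean_day <= 19:
            raise ValueError("need 0 <= birth_day < wean_day <= 19")


@dataclass(frozen=True)
class DevelopmentalConfig:
    """Generator defaults encoding the study's reported trajectories.

    Probabilities are planted-match fractions of calls; ``*_start`` refers
    to the 0-4 day bin and ``*_end`` to the 15-19 day (weaning) bin.
    ``feed_vs_varied_ratio`` is the ratio of varied- to feeding-condition
    match probabilities, and ``birth_to_wean_match_ratio`` the within-
    condition rise of playback pups from the first to the last bin.
    """

    p_match_control_start: float = 0.20
    p_match_control_end: float = 0.02
    p_match_playback_end_varied: float = 0.35
    feed_vs_varied_ratio: float = 1.5
    birth_to_wean_match_ratio: float = 2.0
    similarity_gain_varied: float = 0.25
    calls_per_day: float = 25.0
    f0_base: float = 250.0
    f0_sd: float = 40.0
    rate: float = 96_000.0
    n_harmonics: int = 6
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in (
            "p_match_control_start",
            "p_match_control_end",
            "p_match_playback_end_varied",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.feed_vs_varied_ratio <= 0 or self.birth_to_wean_match_ratio <= 0:
            raise ValueError("ratios must be positive")
        if self.calls_per_day <= 0:
            raise ValueError("calls_per_day must be positive")
        if self.rate <= 0 or self.f0_base <= 0 or self.f0_sd < 0:
            raise ValueError("rate and F0 parameters must be positive")


def logit_linear_through_bins(
    p_early: float, p_late: float, wean_day: int = 19
) -> tuple[float, float]:
    """Intercept and slope of a log-odds-linear age trajectory whose mean
    probability over ages 0-4 equals ``p_early`` and over the last bin
    (``wean_day - 4 .. wean_day``) equals ``p_late``."""
    early = np.arange(0, 5)
    late = np.arange(wean_day - 4, wean_day + 1)

    def intercept_for(slope: float) -> float:
        lo, hi = -50.0, 50.0
        f = lambda a: np.mean(expit(a + slope * early)) - p_early
        return brentq(f, lo, hi, xtol=1e-12)

    def late_gap(slope: float) -> float:
        a = intercept_for(slope)
        return np.mean(expit(a + slope * late)) - p_late

    if np.isclose(p_early, p_late):
        return float(logit(p_early)), 0.0
    slope = brentq(late_gap, -5.0, 5.0, xtol=1e-12)
    return intercept_for(slope), slope


class MatchTrajectories:
    """Per-condition planted-match probability as a function of age."""

    def __init__(self, config: DevelopmentalConfig, wean_day: int = 19):
        c = config
        v_end = c.p_match_playback_end_varied
        v_start = v_end / c.birth_to_wean_match_ratio
        f_end = v_end / c.feed_vs_varied_ratio
        f_start = f_end / c.birth_to_wean_match_ratio
        self._params = {
            "control": logit_linear_through_bins(
                c.p_match_control_start, c.p_match_control_end, wean_day
            ),
            "varied": logit_linear_through_bins(v_start, v_end, wean_day),
            "feeding": logit_linear_through_bins(f_start, f_end, wean_day),
        }

    def p_match(self, condition: str, age_days: float) -> float:
        a, b = self._params[condition]
        return float(expit(a + b * age_days))


# ---------------------------------------------------------------------------
# audio colony

# sequence timing (seconds)
_CALL_DUR_MEAN = 0.7
_CALL_DUR_SD = 0.08  # scatter of call durations at full sloppiness
_DUR_CLIP = (0.5, 0.85)
_INTRA_GAP_BASE = 0.04  # minimum silent gap between calls of one sequence
_INTRA_GAP_JITTER = 0.08  # extra gap at full sloppiness (onset gaps stay < 1 s)
_INTER_GAP = (1.2, 2.0)  # silent gap between sequences (onset gaps > 1 s)
_MATCH_STEP_MEAN = 155.0  # |F0 step| of planted matches
_MATCH_STEP_JITTER = 40.0  # step scatter at full sloppiness (always > 100 Hz rule)
_NONMATCH_STEP = 80.0  # |F0 step| bound of non-match sequences
_BASE_SD_MULT = 2.0  # sequence base-F0 scatter = mult x f0_sd at full sloppiness
_F0_LIMITS = (120.0, 620.0)
# feature-noise schedule realizing the similarity gain for varied pups: the
# planted-call scatter shrinks linearly with age by LAMBDA_PER_GAIN x gain
# (calibrated by simulation under the default feature set).
_LAMBDA_PER_GAIN = 3.8


def _sequence_f0s(
    rng: np.random.Generator,
    template_id: str,
    is_match: bool,
    f0_base: float,
    f0_sd: float,
    tightness: float,
) -> np.ndarray:
    """Fundamental frequencies of one call sequence.

    Planted matches walk the template's direction pattern with steps of at
    least 120 Hz; non-matches take steps below 80 Hz so they never satisfy
    the 100 Hz rule. ``tightness`` in [0, 1] shrinks the random scatter
    (used to make varied pups' matches more stereotyped with age).
    """
    n_calls = 3 if template_id == "ab" else 2
    scale = 1.0 - tightness
    base = f0_base + scale * rng.normal(0.0, _BASE_SD_MULT * f0_sd)
    if is_match:
        pattern = {"a": (1,), "b": (-1,), "ab": (1, -1)}[template_id]
        steps = np.array(
            [
                s * (_MATCH_STEP_MEAN + scale * rng.uniform(-_MATCH_STEP_JITTER, _MATCH_STEP_JITTER))
                for s in pattern
            ]
        )
    else:
        steps = rng.uniform(-_NONMATCH_STEP, _NONMATCH_STEP, n_calls - 1)
    f0s = base + np.concatenate(([0.0], np.cumsum(steps)))
    # shift the whole walk into the admissible band rather than clipping,
    # which would destroy planted step sizes
    lo, hi = _F0_LIMITS
    f0s = f0s + max(0.0, lo - f0s.min()) - max(0.0, f0s.max() - hi)
    return f0s


@dataclass
class ColonySessions:
    """Output of :func:`simulate_colony`."""

    waveforms: dict[tuple[str, int], Waveform]
    annotations: pd.DataFrame
    pups: list[PupRecord]
    config: DevelopmentalConfig


def simulate_colony(
    pups: list[PupRecord],
    config: DevelopmentalConfig | None = None,
    days: list[int] | None = None,
    synthesize: bool = True,
) -> ColonySessions:
    """Generate per-pup daily recording sessions.

    Parameters
    ----------
    pups
        Study animals; must be non-empty.
    config
        Generator parameters (defaults encode the study trajectories).
    days
        Subset of ages (days) to simulate; default all days from birth to
        weaning of each pup. Restricting days leaves the retained sessions
        identical to a full run with the same seed.
    synthesize
        If False, only the annotation table is produced (waveforms empty);
        the planted F0s and timings are identical either way.

    Returns
    -------
    ColonySessions
        ``waveforms[(pup_id, age)]`` is the session audio; ``annotations``
        has one row per call with columns (pup_id, age_days, onset_s,
        offset_s, sequence_id, is_planted_match, condition, stimulus_id,
        sex, template_id, position, f0_hz).
    """
    if not pups:
        raise ValueError("need at least one pup")
    if len({p.pup_id for p in pups}) != len(pups):
        raise ValueError("duplicate pup ids")
    config = config or DevelopmentalConfig()
    traj = MatchTrajectories(config, wean_day=max(p.wean_day for p in pups))

    waveforms: dict[tuple[str, int], Waveform] = {}
    rows: list[dict] = []
    for pup_index, pup in enumerate(pups):
        pup_days = range(pup.birth_day, pup.wean_day + 1)
        for age in pup_days:
            if days is not None and age not in days:
                continue
            rng = np.random.default_rng([config.seed, pup_index, age])
            p = traj.p_match(pup.condition, age)
            if pup.condition == "varied":
                tight = (
                    _LAMBDA_PER_GAIN
                    * config.similarity_gain_varied
                    * age
                    / pup.wean_day
                )
                tight = min(tight, 0.95)
            else:
                tight = 0.0
            target_calls = max(int(rng.poisson(config.calls_per_day)), 1)
            # choose sequence templates until the call budget is covered
            templates: list[str] = []
            budget = 0
            while budget < target_calls:
                template_id = (
                    pup.stimulus_id
                    if pup.condition != "control"
                    else str(rng.choice(["a", "b", "ab"]))
                )
                templates.append(template_id)
                budget += 3 if template_id == "ab" else 2
            # plant matches by randomized rounding of the expected count:
            # the realized session match rate concentrates on the
            # trajectory value instead of fluctuating binomially
            n_seq = len(templates)
            expected = n_seq * p
            n_match = int(np.floor(expected)) + int(rng.random() < expected % 1.0)
            match_flags = np.zeros(n_seq, dtype=bool)
            match_flags[rng.choice(n_seq, size=min(n_match, n_seq), replace=False)] = True

            t = float(rng.uniform(0.3, 0.8))
            calls: list[tuple[float, float, float, int, bool, int]] = []
            for g, (template_id, is_match) in enumerate(zip(templates, match_flags)):
                is_match = bool(is_match)
                f0s = _sequence_f0s(
                    rng, template_id, is_match, config.f0_base, config.f0_sd, tight
                )
                # session-local id, stable under day subsetting
                seq_counter = (pup_index * 20 + age) * 10_000 + g
                scale = 1.0 - tight
                for pos, f0 in enumerate(f0s):
                    dur = float(
                        np.clip(
                            _CALL_DUR_MEAN + scale * rng.normal(0.0, _CALL_DUR_SD),
                            *_DUR_CLIP,
                        )
                    )
                    calls.append((t, dur, float(f0), seq_counter, is_match, pos))
                    intra = _INTRA_GAP_BASE + scale * rng.uniform(0.0, _INTRA_GAP_JITTER)
                    t += dur + (intra if pos < len(f0s) - 1 else rng.uniform(*_INTER_GAP))
            session_len = calls[-1][0] + calls[-1][1] + 0.5
            if synthesize:
                x = np.zeros(int(round(session_len * config.rate)))
                for onset, dur, f0, _, _, _ in calls:
                    c = synthesize_call(
                        f0, dur, n_harmonics=config.n_harmonics, rate=config.rate
                    )
                    i = int(round(onset * config.rate))
                    x[i : i + len(c)] += c.samples
                waveforms[(pup.pup_id, age)] = Waveform(x, config.rate)
            for onset, dur, f0, seq, is_match, pos in calls:
                rows.append(
                    {
                        "pup_id": pup.pup_id,
                        "age_days": age,
                        "onset_s": onset,
                        "offset_s": onset + dur,
                        "sequence_id": seq,
                        "is_planted_match": is_match,
                        "condition": pup.condition,
                        "stimulus_id": pup.stimulus_id,
                        "sex": pup.sex,
                        "template_id": (
                            pup.stimulus_id if pup.condition != "control" else "any"
                        ),
                        "position": pos,
                        "f0_hz": f0,
                    }
                )
    annotations = pd.DataFrame(rows)
    return ColonySessions(waveforms, annotations, list(pups), config)


def default_colony_pups() -> list[PupRecord]:
    """The 12-animal design of the study: 4 controls plus 4 feeding/varied
    pairs hearing stimuli a, a, b and ab."""
    return [
        PupRecord("A", "M", "control", "none"),
        PupRecord("B", "M", "control", "none"),
        PupRecord("C", "F", "control", "none"),
        PupRecord("D", "F", "control", "none"),
        PupRecord("E", "F", "feeding", "a"),
        PupRecord("F", "M", "varied", "a"),
        PupRecord("G", "F", "feeding", "b"),
        PupRecord("H", "F", "varied", "b"),
        PupRecord("I", "F", "feeding", "a"),
        PupRecord("J", "M", "varied", "a"),
        PupRecord("K", "M", "feeding", "ab"),
        PupRecord("L", "M", "varied", "ab"),
    ]


# ---------------------------------------------------------------------------
# tabular generators for the inference stage


def simulate_match_table_from_effects(
    effects: dict[str, float] | None = None,
    n_pups_per_condition: int = 4,
    calls_per_pup: int = 400,
    random_intercept_sd: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a call-level match table directly from the logistic mixed model.

    ``effects`` are odds ratios (see :data:`DEFAULT_MATCH_EFFECTS`); age is
    the ordinal 5-day bin (0-3), drawn uniformly per call. Used to test
    that the GLMM stage recovers known effect sizes.
    """
    eff = dict(DEFAULT_MATCH_EFFECTS)
    if effects:
        eff.update(effects)
    beta = {k: np.log(v) for k, v in eff.items()}
    rng = np.random.default_rng(seed)
    rows = []
    for cond in CONDITIONS:
        for i in range(n_pups_per_condition):
            pup_id = f"{cond[:4]}{i}"
            b = rng.normal(0.0, random_intercept_sd)
            ages = rng.integers(0, 4, calls_per_pup)
            eta = beta["intercept"] + beta["age"] * ages + b
            if cond == "feeding":
                eta = eta + beta["condition_feed"] + beta["age_x_feed"] * ages
            elif cond == "varied":
                eta = eta + beta["condition_varied"] + beta["age_x_varied"] * ages
            y = rng.random(calls_per_pup) < expit(eta)
            rows.append(
                pd.DataFrame(
                    {
                        "pup_id": pup_id,
                        "age": ages,
                        "condition": cond,
                        "is_match": y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_mantel_rows(
    n_pups_per_condition: int = 4,
    baseline_r: float = 0.55,
    similarity_gain_varied: float = 0.25,
    pup_sd: float = 0.04,
    residual_sd: float = 0.045,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per pup x age-bin Mantel r values for LMM power experiments.

    Varied-condition pups gain ``similarity_gain_varied x baseline_r`` in
    expectation from the first to the last bin; other conditions are flat.
    """
    rng = np.random.default_rng(seed)
    slope = similarity_gain_varied * baseline_r / 3.0
    rows = []
    for cond in CONDITIONS:
        for i in range(n_pups_per_condition):
            b = rng.normal(0.0, pup_sd)
            sex = SEXES[i % 2]
            for age_bin_ in range(4):
                mu = baseline_r + b
                if cond == "varied":
                    mu += slope * age_bin_
                rows.append(
                    {
                        "pup_id": f"{cond[:4]}{i}",
                        "sex": sex,
                        "age_bin": age_bin_,
                        "condition": cond,
                        "r": float(np.clip(mu + rng.normal(0, residual_sd), -1, 1)),
                    }
                )
    return pd.DataFrame(rows)
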