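"""Synthetic masked-priming study generator.

Emulates the statistical structure of a 16-subject MEG masked-priming
lexical-decision experiment on English past-tense verbs: four word
conditions (identity, regular, irregular, pseudo-irregular) of 50 targets
each plus nonword fillers, two counterbalanced experiment versions that
swap which targets get related vs. unrelated primes, reaction times with
crossed subject/item random intercepts, and dSPM-like source-space time
courses with priming effects injected in configurable latency windows on
top of AR(1)-colored noise.

Every draw is deterministic given ``SimulationSpec.seed``; independent
substreams are spawned per component so adding one component never
perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import (
    CONDITIONS,
    WORD_CONDITIONS,
    EpochSet,
    SourceEpochSet,
    validate_trial_table,
)

__all__ = [
    "EffectWindow",
    "SimulationSpec",
    "generate_design",
    "simulate_rts",
    "simulate_roi_timecourses",
    "simulate_source_grid",
    "evoked_template",
]

# Per-condition target covariate moments (word length, log surface
# frequency): means/SDs of the stimulus set being emulated.
_COVARIATE_MOMENTS = {
    "identity": dict(length=(5.68, 1.04), freq=(2.60, 0.51)),
    "regular": dict(length=(4.14, 0.45), freq=(3.06, 0.55)),
    "irregular": dict(length=(4.20, 0.76), freq=(2.80, 0.72)),
    "pseudo_irregular": dict(length=(3.88, 0.66), freq=(2.50, 1.00)),
    "nonword": dict(length=(4.48, 1.03), freq=(2.54, 0.68)),
}


@dataclasses.dataclass(frozen=True)
class EffectWindow:
    """A condition x prime-type effect injected into simulated epochs.

    ``amplitude`` is the peak unrelated-minus-related difference produced
    in the window; ``direction`` +1 injects a facilitatory reduction for
    related trials (relative to the local response sign), -1 the opposite.
    ``shape`` is "gaussian" (smooth bump, FWHM = half the window) or
    "boxcar" (exact rectangle, useful for oracle tests).
    """

    start_ms: float
    end_ms: float
    amplitude: float
    direction: int = 1
    shape: str = "gaussian"

    def profile(self, time_ms: np.ndarray) -> np.ndarray:
        """Temporal profile (0..1 scaled) of the effect on a time grid."""
        if self.shape == "boxcar":
            return ((time_ms >= self.start_ms) & (time_ms <= self.end_ms)).astype(float)
        center = 0.5 * (self.start_ms + self.end_ms)
        width = self.end_ms - self.start_ms
        sigma = (width / 2.0) / 2.3548200450309493  # FWHM = width/2
        return np.exp(-0.5 * ((time_ms - center) / sigma) ** 2)


def _default_priming_effects() -> dict[str, float]:
    return {
        "identity": 33.3,
        "regular": 22.5,
        "irregular": 14.2,
        "pseudo_irregular": 14.6,
        "nonword": 0.0,
    }


def _default_effect_windows() -> dict[str, tuple[EffectWindow, ...]]:
    # Facilitatory priming around the M170 (window centered at 183 ms) for
    # the three conditions that show it, plus a late lexical-access effect;
    # amplitudes are calibration choices (single-trial SNR is not an
    # observable of the emulated study), sized for moderate pointwise
    # evidence at 800 trials/condition with unit noise.
    m170 = (158.0, 208.0)
    late = (385.0, 493.0)
    return {
        "identity": (EffectWindow(*m170, 0.35), EffectWindow(*late, 0.30)),
        "regular": (EffectWindow(*m170, 0.30), EffectWindow(*late, 0.30)),
        "irregular": (EffectWindow(*m170, 0.25), EffectWindow(*late, 0.25)),
    }


def _default_source_masks() -> dict[str, int]:
    return {"fusiform": 10, "inferior_temporal": 10, "middle_temporal": 10}


@dataclasses.dataclass
class SimulationSpec:
    """Parameters of the synthetic study; defaults emulate the target design.

    RT parameters (ms): grand mean 620.7 and a variance decomposition
    subject 140 / item 50 / residual 100 whose total (~179) matches the
    observed overall RT SD while the residual reproduces the observed
    scale of the priming t-values at ~800 trials per condition.
    """

    n_subjects: int = 16
    trials_per_condition: int = 50
    n_nonword_trials: int = 200
    grand_mean_rt_ms: float = 620.7
    priming_effects_ms: Mapping[str, float] = dataclasses.field(
        default_factory=_default_priming_effects
    )
    subject_sd: float = 140.0
    item_sd: float = 50.0
    residual_sd: float = 100.0
    accuracy_rate: float = 0.944
    # epochs
    sampling_rate_hz: float = 1000.0
    epoch_window_ms: tuple[float, float] = (-150.0, 500.0)
    effect_windows: Mapping[str, Sequence[EffectWindow]] = dataclasses.field(
        default_factory=_default_effect_windows
    )
    noise_sd: float = 1.0
    ar1_rho: float = 0.95
    epoch_subject_gain_sd: float = 0.2
    epoch_item_gain_sd: float = 0.1
    scale_effect_by_albright: bool = False
    # item covariates
    albright_irregular_moments: tuple[float, float] = (0.514, 0.228)
    albright_regular_moments: tuple[float, float] = (0.975, 0.025)
    albright_freq_correlation: float = 0.29
    # source grid
    source_masks: Mapping[str, int] = dataclasses.field(
        default_factory=_default_source_masks
    )
    mask_signs: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {
            "fusiform": 1, "inferior_temporal": -1, "middle_temporal": -1,
        }
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("subject_sd", "item_sd", "residual_sd", "noise_sd",
                     "epoch_subject_gain_sd", "epoch_item_gain_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in (-1, 1)")
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValueError("n_subjects and trials_per_condition must be >= 1")
        start, end = self.epoch_window_ms
        if end <= start:
            raise ValueError("epoch window must be non-empty")
        self.effect_windows = {
            cond: tuple(
                w if isinstance(w, EffectWindow) else EffectWindow(*w)
                for w in wins
            )
            for cond, wins in dict(self.effect_windows).items()
        }
        for cond, wins in self.effect_windows.items():
            for w in wins:
                if w.start_ms < start or w.end_ms > end or w.end_ms <= w.start_ms:
                    raise ValueError(
                        f"effect window {w} for {cond!r} outside epoch window"
                    )

    @property
    def time_ms(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate_hz
        start, end = self.epoch_window_ms
        n = int(round((end - start) / step)) + 1
        return start + step * np.arange(n)

    # -- config round-trip -----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["priming_effects_ms"] = dict(self.priming_effects_ms)
        d["effect_windows"] = {
            cond: [dataclasses.asdict(w) for w in wins]
            for cond, wins in self.effect_windows.items()
        }
        d["source_masks"] = dict(self.source_masks)
        d["mask_signs"] = dict(self.mask_signs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationSpec":
        d = dict(d)
        if "effect_windows" in d:
            d["effect_windows"] = {
                cond: tuple(
                    EffectWindow(**w) if isinstance(w, Mapping) else EffectWindow(*w)
                    for w in wins
                )
                for cond, wins in d["effect_windows"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimulationSpec fields: {sorted(unknown)}")
        # tuples arrive as lists from JSON/YAML
        for name in ("epoch_window_ms", "albright_irregular_moments",
                     "albright_regular_moments"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SimulationSpec":
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent substream, deterministic given the seed."""
        streams = (
            "design", "subject_effects", "item_effects", "rt_residual",
            "accuracy", "covariates", "epoch_gains", "epoch_noise",
            "source_geometry", "source_noise",
        )
        child = streams.index(stream)
        ss = np.random.SeedSequence(self.seed, spawn_key=(child,))
        return np.random.default_rng(ss)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError("Beta moments infeasible")
    return mean * nu, (1 - mean) * nu


def _item_covariates(spec: SimulationSpec, items: pd.DataFrame) -> pd.DataFrame:
    """Per-item word length, log surface frequency and Albright score.

    Albright scores: irregulars from a Beta matched to mean/SD
    (0.514/0.228 by default), regulars from a tight Beta near 1; the
    score-frequency correlation is induced through a Gaussian copula.
    """
    rng = spec.rng("covariates")
    rows = []
    rho = spec.albright_freq_correlation
    for cond, grp in items.groupby("condition", sort=True):
        k = len(grp)
        mom = _COVARIATE_MOMENTS[cond]
        z1 = rng.standard_normal(k)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(k)
        freq = mom["freq"][0] + mom["freq"][1] * z1
        length = np.clip(
            np.round(mom["length"][0] + mom["length"][1] * rng.standard_normal(k)),
            2, None,
        ).astype(int)
        if cond == "irregular":
            a, b = _beta_params(*spec.albright_irregular_moments)
            score = stats.beta.ppf(stats.norm.cdf(z2), a, b)
        elif cond == "regular":
            a, b = _beta_params(*spec.albright_regular_moments)
            score = stats.beta.ppf(stats.norm.cdf(z2), a, b)
        else:
            score = np.full(k, np.nan)
        rows.append(
            pd.DataFrame(
                dict(
                    item_id=grp["item_id"].to_numpy(),
                    word_length=length,
                    log_surface_freq=freq,
                    albright_score=score,
                )
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_design(spec: SimulationSpec) -> pd.DataFrame:
    """Counterbalanced trial table (no outcomes yet).

    Per subject: ``trials_per_condition`` trials in each word condition,
    half preceded by related and half by unrelated primes, with the
    related/unrelated assignment of each target swapped between versions
    A and B; versions alternate across subjects.  Nonword fillers get 75
    related / 125 unrelated primes (scaled to ``n_nonword_trials``) and
    are identical across versions.
    """
    m = spec.trials_per_condition
    if m % 2 != 0:
        raise ValueError(
            "trials_per_condition must be even to split related/unrelated equally"
        )
    subjects = [f"S{j + 1:02d}" for j in range(spec.n_subjects)]
    word_items = pd.DataFrame(
        [
            dict(item_id=f"{cond[:4]}_{k:03d}", condition=cond)
            for cond in WORD_CONDITIONS
            for k in range(m)
        ]
    )
    n_nw = spec.n_nonword_trials
    nw_related = int(round(n_nw * 75.0 / 200.0))
    nonword_items = pd.DataFrame(
        [dict(item_id=f"nonw_{k:03d}", condition="nonword") for k in range(n_nw)],
        columns=["item_id", "condition"],
    )
    rows = []
    for j, subj in enumerate(subjects):
        version = "A" if j % 2 == 0 else "B"
        for cond in WORD_CONDITIONS:
            cond_items = word_items[word_items["condition"] == cond]["item_id"].to_numpy()
            half = m // 2
            related_first = version == "A"
            for k, item in enumerate(cond_items):
                related = (k < half) if related_first else (k >= half)
                rows.append(
                    dict(
                        subject_id=subj,
                        item_id=item,
                        condition=cond,
                        prime_type="related" if related else "unrelated",
                        version=version,
                    )
                )
        for k, item in enumerate(nonword_items["item_id"]):
            rows.append(
                dict(
                    subject_id=subj,
                    item_id=item,
                    condition="nonword",
                    prime_type="related" if k < nw_related else "unrelated",
                    version=version,
                )
            )
    design = pd.DataFrame(rows)
    items = pd.concat([word_items, nonword_items], ignore_index=True)
    design = design.merge(_item_covariates(spec, items), on="item_id", how="left")
    design.index.name = "trial"
    return validate_trial_table(design)


def simulate_rts(design: pd.DataFrame, spec: SimulationSpec) -> pd.DataFrame:
    """Add rt_ms and accuracy columns to a design.

    rt = grand mean + subject intercept + item intercept
         - priming_effect(condition) * 1[related] + residual noise.
    Accuracy is Bernoulli(accuracy_rate), used only to exercise filters.
    """
    if "rt_ms" in design.columns and design["rt_ms"].notna().any():
        raise ValueError("design already carries rt_ms")
    out = design.copy()
    subj_levels = np.sort(out["subject_id"].unique())
    item_levels = np.sort(out["item_id"].unique())
    u_s = dict(
        zip(subj_levels,
            spec.rng("subject_effects").normal(0.0, spec.subject_sd, len(subj_levels)))
    )
    u_i = dict(
        zip(item_levels,
            spec.rng("item_effects").normal(0.0, spec.item_sd, len(item_levels)))
    )
    effect = out["condition"].map(lambda c: spec.priming_effects_ms.get(c, 0.0))
    related = (out["prime_type"] == "related").to_numpy()
    rt = (
        spec.grand_mean_rt_ms
        + out["subject_id"].map(u_s).to_numpy()
        + out["item_id"].map(u_i).to_numpy()
        - effect.to_numpy() * related
        + spec.rng("rt_residual").normal(0.0, spec.residual_sd, len(out))
    )
    out["rt_ms"] = np.clip(rt, 1.0, None)
    out["accuracy"] = (
        spec.rng("accuracy").random(len(out)) < spec.accuracy_rate
    ).astype(int)
    return validate_trial_table(out)


def evoked_template(time_ms: np.ndarray) -> np.ndarray:
    """Smooth evoked response: visual (M100-like), letter-string
    (M170-like) and late lexical (M350/N400m-like) components."""
    t = np.asarray(time_ms, dtype=float)
    bump = lambda c, s, a: a * np.exp(-0.5 * ((t - c) / s) ** 2)
    wave = bump(100.0, 15.0, 0.8) + bump(170.0, 25.0, 2.0) + bump(400.0, 60.0, 1.2)
    wave[t < 0] = 0.0
    return wave


def _ar1_noise(rng, shape, sd, rho):
    """Stationary AR(1) rows: x_t = rho x_{t-1} + sqrt(1-rho^2) sd e_t."""
    if sd == 0:
        return np.zeros(shape)
    w = rng.standard_normal(shape) * (sd * np.sqrt(1.0 - rho**2))
    w[..., 0] = rng.standard_normal(shape[:-1]) * sd
    return signal.lfilter([1.0], [1.0, -rho], w, axis=-1)


def _trial_gains(design, spec):
    rng = spec.rng("epoch_gains")
    subj_levels = np.sort(design["subject_id"].unique())
    item_levels = np.sort(design["item_id"].unique())
    g_s = dict(zip(subj_levels,
                   rng.normal(0.0, spec.epoch_subject_gain_sd, len(subj_levels))))
    g_i = dict(zip(item_levels,
                   rng.normal(0.0, spec.epoch_item_gain_sd, len(item_levels))))
    return (
        1.0
        + design["subject_id"].map(g_s).to_numpy()
        + design["item_id"].map(g_i).to_numpy()
    )


def _effect_matrix(design: pd.DataFrame, spec: SimulationSpec,
                   time_ms: np.ndarray) -> np.ndarray:
    """Per-trial additive effect (applied to related trials only).

    Returns the amount *subtracted* from related trials, i.e. the injected
    unrelated-minus-related difference, per trial and time point.
    """
    eff = np.zeros((len(design), len(time_ms)))
    related = (design["prime_type"] == "related").to_numpy()
    if spec.scale_effect_by_albright:
        scale = design["albright_score"].fillna(1.0).to_numpy()
    else:
        scale = np.ones(len(design))
    for cond, wins in spec.effect_windows.items():
        sel = related & (design["condition"] == cond).to_numpy()
        if not sel.any():
            continue
        prof = np.zeros_like(time_ms)
        for w in wins:
            prof = prof + w.direction * w.amplitude * w.profile(time_ms)
        eff[sel] = scale[sel, None] * prof[None, :]
    return eff


def simulate_roi_timecourses(design: pd.DataFrame, spec: SimulationSpec) -> EpochSet:
    """Single-ROI dSPM-like time courses for every trial of the design.

    Each trial is (1 + subject gain + item gain) * evoked template, minus
    the condition's injected priming effect on related trials, plus
    AR(1)-colored noise.
    """
    time_ms = spec.time_ms
    template = evoked_template(time_ms)
    gains = _trial_gains(design, spec)
    eff = _effect_matrix(design, spec, time_ms)
    noise = _ar1_noise(
        spec.rng("epoch_noise"), (len(design), len(time_ms)), spec.noise_sd, spec.ar1_rho
    )
    data = gains[:, None] * template[None, :] - eff + noise
    return EpochSet(data, time_ms, design.index.to_numpy(), spec.sampling_rate_hz)


def simulate_source_grid(
    design: pd.DataFrame,
    spec: SimulationSpec,
    patch: Sequence[int],
) -> SourceEpochSet:
    """Source-space simulation on a shared 1-D grid of labeled sources.

    Every source carries the shared evoked template with a random gain and
    a per-mask response sign (free-orientation signed estimates point
    coherently within an anatomical patch but may flip between patches);
    only sources in ``patch`` carry the condition x prime-type effect,
    injected as a reduction of |activity| for related trials.  Sources
    outside the patch are effect-free.
    """
    masks = dict(spec.source_masks)
    n_sources = int(sum(masks.values()))
    if n_sources < 1:
        raise ValueError("empty source set")
    patch = np.asarray(sorted(set(int(s) for s in patch)), dtype=int)
    if patch.size == 0:
        raise ValueError("empty patch")
    if patch.min() < 0 or patch.max() >= n_sources:
        raise ValueError("patch contains sources outside the grid")
    labels = [name for name, k in masks.items() for _ in range(int(k))]

    time_ms = spec.time_ms
    template = evoked_template(time_ms)
    geom = spec.rng("source_geometry")
    gains_src = geom.uniform(0.6, 1.4, n_sources)
    signs = np.array([float(spec.mask_signs.get(lab, 1)) for lab in labels])
    trial_gain = _trial_gains(design, spec)
    eff = _effect_matrix(design, spec, time_ms)

    n = len(design)
    data = np.empty((n, n_sources, len(time_ms)))
    noise_rng = spec.rng("source_noise")
    in_patch = np.zeros(n_sources, dtype=bool)
    in_patch[patch] = True
    for s in range(n_sources):
        base = (gains_src[s] * trial_gain)[:, None] * template[None, :]
        if in_patch[s]:
            base = base - eff
        noise = _ar1_noise(noise_rng, (n, len(time_ms)), spec.noise_sd, spec.ar1_rho)
        data[:, s, :] = signs[s] * base + noise
    return SourceEpochSet(
        data, time_ms, design.index.to_numpy(), labels, spec.sampling_rate_hz
    )
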