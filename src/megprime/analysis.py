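"""End-to-end analyses: behavioral priming, windowed MEG cluster tests,
fROI localization/testing, and the rule-support interaction.

Each runner returns a plain JSON-serializable dict ("report").  Reports
are deterministic given the configuration seed: rerunning with the same
inputs yields byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clusterperm import permutation_test
from .containers import EpochSet, SourceEpochSet, WORD_CONDITIONS
from .covariates import add_orthogonalized_score, bin_albright, interaction_analysis
from .mixedmodel import build_design, fit_lmm, lrt_nested, mc_pvalue_fixed_effect
from .roi import centered_window, find_peak_latency, localize_froi, \
    extract_froi_timecourses, mean_timecourse
from .roi import _facilitation_map

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_behavioral", "run_meg_analysis",
           "report_to_json", "report_to_text"]

ANALYSES = ("m100", "m170_anatomical", "late", "froi", "albright")


@dataclasses.dataclass
class AnalysisConfig:
    """Window rules, permutation settings and condition sets.

    Early-response windows are 50 ms wide: the visual (M100) window is
    fixed around 100 ms; the letter-string (M170) window is centered at a
    *detected* peak (grand-mean activity for the anatomical analysis, the
    localizer priming effect for the fROI analysis); the late
    lexical-access window is the fixed interval (300, 500) ms.
    """

    threshold: float = 1.96
    n_perm: int = 10000
    seed: int = 0
    window_width_ms: float = 50.0
    m100_center_ms: float = 100.0
    late_window_ms: tuple[float, float] = (300.0, 500.0)
    peak_search_ms: tuple[float, float] = (100.0, 250.0)
    m100_conditions: Sequence[str] = WORD_CONDITIONS
    anatomical_conditions: Sequence[str] = WORD_CONDITIONS
    late_conditions: Sequence[str] = WORD_CONDITIONS
    froi_localizer_conditions: Sequence[str] = ("identity", "regular")
    froi_test_conditions: Sequence[str] = ("irregular", "pseudo_irregular")
    froi_masks: Sequence[str] = ("fusiform", "inferior_temporal")
    froi_extent_rule: float = 0.5
    permutation_scheme: str = "within_subject"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.window_width_ms <= 0:
            raise ValueError("window width must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown AnalysisConfig fields: {sorted(unknown)}")
        # sequence-valued fields are stored as tuples; YAML/JSON give lists
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def report_to_json(report: dict, path=None) -> str:
    text = json.dumps(_jsonable(report), sort_keys=True, indent=2)
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def report_to_text(report: dict, indent: int = 0) -> str:
    """Human-readable rendering of a (nested) report dict."""
    lines = []
    pad = "  " * indent
    for key in sorted(report):
        val = report[key]
        if isinstance(val, Mapping):
            lines.append(f"{pad}{key}:")
            lines.append(report_to_text(val, indent + 1))
        elif isinstance(val, list) and val and isinstance(val[0], Mapping):
            lines.append(f"{pad}{key}:")
            for item in val:
                lines.append(report_to_text(item, indent + 1))
                lines.append(f"{pad}  -")
        else:
            if isinstance(val, float):
                val = f"{val:.6g}"
            lines.append(f"{pad}{key}: {val}")
    return "\n".join(line for line in lines if line)


def _cluster_block(result) -> dict:
    d = result.to_dict()
    d["significant"] = bool(result.clusters) and result.p_value <= 0.05
    return d


# --------------------------------------------------------------------------
# behavioral
# --------------------------------------------------------------------------

def run_behavioral(trials: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Per-condition RT priming (LMM t + Monte-Carlo p) and the
    prime-type x pseudo-irregularity interaction LRT.

    Expects a preprocessed table (subject exclusion and RT trimming
    already applied); nonword trials are ignored.
    """
    words = trials[(trials["condition"] != "nonword") & trials["rt_ms"].notna()]
    if "accuracy" in words.columns:
        words = words[words["accuracy"] == 1]
    report: dict = {"analysis": "behavioral", "conditions": {},
                    "n_trials": int(len(words)), "n_perm": config.n_perm,
                    "seed": config.seed}
    for cond in sorted(words["condition"].unique()):
        sub = words[words["condition"] == cond]
        counts = sub["prime_type"].value_counts()
        if counts.reindex(["related", "unrelated"]).fillna(0).min() < 2:
            logger.warning("condition %s has < 2 trials per prime type; skipped", cond)
            continue
        X, names = build_design(sub, terms=("prime_type",))
        fit = fit_lmm(sub["rt_ms"], X, sub["subject_id"], sub["item_id"],
                      method="REML", term_names=names)
        # the model coefficient (unrelated - related, adjusted for subject
        # and item intercepts) is the priming estimate; the raw marginal
        # difference is reported alongside but is confounded by item
        # effects once exclusions unbalance the counterbalancing
        marginal = float(
            sub.loc[sub["prime_type"] == "unrelated", "rt_ms"].mean()
            - sub.loc[sub["prime_type"] == "related", "rt_ms"].mean()
        )
        p = mc_pvalue_fixed_effect(sub, term="prime_type", response="rt_ms",
                                   n_iter=config.n_perm, seed=config.seed)
        report["conditions"][cond] = dict(
            priming_ms=float(fit.coefficients[names[1]]),
            priming_marginal_ms=marginal,
            t=float(fit.t_values[names[1]]),
            mc_p=float(p),
            n_trials=int(len(sub)),
        )
    # interaction on the irregular-family subset only
    pair = words[words["condition"].isin(["irregular", "pseudo_irregular"])].copy()
    if pair["condition"].nunique() == 2:
        pair["pseudo_irregularity"] = (
            pair["condition"] == "pseudo_irregular"
        ).astype(float)
        Xr, nr = build_design(pair, terms=("prime_type", "pseudo_irregularity"))
        Xf, nf = build_design(
            pair, terms=("prime_type", "pseudo_irregularity"),
            interactions=(("prime_type", "pseudo_irregularity"),),
        )
        chi2, df, p = lrt_nested(pair["rt_ms"], Xr, Xf, pair["subject_id"],
                                 pair["item_id"], names_reduced=nr, names_full=nf)
        report["primetype_x_pseudoirregularity"] = dict(chi2=float(chi2), df=int(df),
                                                        p=float(p))
    return report


# --------------------------------------------------------------------------
# MEG analyses
# --------------------------------------------------------------------------

def _prime_test(epochs, trials, window_ms, config, seed_offset=0):
    return permutation_test(
        epochs, trials, term="prime_type", window_ms=window_ms,
        threshold=config.threshold, n_perm=config.n_perm,
        seed=config.seed + seed_offset, scheme=config.permutation_scheme,
    )


def run_meg_analysis(data, trials: pd.DataFrame, analysis_name: str,
                     config: AnalysisConfig) -> dict:
    """Execute one named MEG analysis chain and return its report.

    ``data`` is an :class:`EpochSet` of ROI time courses for "m100",
    "m170_anatomical" and "late", or a :class:`SourceEpochSet` for "froi"
    and "albright".
    """
    if analysis_name not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis_name!r}; choose from {ANALYSES}")
    words = trials[trials["condition"] != "nonword"]
    report: dict = {"analysis": analysis_name, "n_perm": config.n_perm,
                    "seed": config.seed, "threshold": config.threshold}

    if analysis_name == "m100":
        _require_conditions(words, config.m100_conditions)
        sub = words[words["condition"].isin(config.m100_conditions)]
        window = centered_window(config.m100_center_ms, config.window_width_ms)
        report["window_ms"] = list(window)
        report["window_provenance"] = "fixed center 100 ms"
        report["result"] = _cluster_block(_prime_test(data, sub, window, config))
        return report

    if analysis_name == "m170_anatomical":
        _require_conditions(words, config.anatomical_conditions)
        sub = words[words["condition"].isin(config.anatomical_conditions)]
        grand = mean_timecourse(data.subset(sub.index))
        peak = find_peak_latency(grand, data.time_ms, config.peak_search_ms,
                                 direction="absmax")
        window = centered_window(peak, config.window_width_ms)
        report["peak_latency_ms"] = peak
        report["window_ms"] = list(window)
        report["window_provenance"] = "detected grand-mean peak"
        report["result"] = _cluster_block(_prime_test(data, sub, window, config))
        return report

    if analysis_name == "late":
        _require_conditions(words, config.late_conditions)
        window = tuple(config.late_window_ms)
        report["window_ms"] = list(window)
        report["window_provenance"] = "fixed late interval"
        report["conditions"] = {}
        for k, cond in enumerate(sorted(set(config.late_conditions))):
            sub = words[words["condition"] == cond]
            report["conditions"][cond] = _cluster_block(
                _prime_test(data, sub, window, config, seed_offset=k)
            )
        return report

    # source-space chains
    if not isinstance(data, SourceEpochSet):
        raise TypeError("froi/albright analyses need a SourceEpochSet")
    _require_conditions(words, config.froi_localizer_conditions)
    loc = words[words["condition"].isin(config.froi_localizer_conditions)]
    # localizer window: peak of the facilitatory priming difference
    # (sign-aligned per source, averaged over the mask sources), searched
    # in the early-response range
    mask_idx = data.sources_in_masks(config.froi_masks)
    full_range = (data.time_ms[0], data.time_ms[-1])
    _, facil_t, _ = _facilitation_map(
        data, words, config.froi_localizer_conditions, full_range
    )
    facil = facil_t[mask_idx].mean(axis=0)
    peak = find_peak_latency(facil, data.time_ms, config.peak_search_ms,
                             direction="max")
    window = centered_window(peak, config.window_width_ms)
    froi = localize_froi(
        data, words, conditions=config.froi_localizer_conditions,
        masks=config.froi_masks, window_ms=window,
        extent_rule=config.froi_extent_rule,
    )
    froi_epochs = extract_froi_timecourses(data, froi)
    report["peak_latency_ms"] = peak
    report["window_ms"] = list(window)
    report["window_provenance"] = "detected localizer priming peak"
    report["froi"] = dict(
        sources=[int(s) for s in froi.sources],
        peak_source=int(froi.peak_source),
        peak_latency_ms=float(froi.peak_latency_ms),
    )

    if analysis_name == "froi":
        _require_conditions(words, config.froi_test_conditions)
        report["tests"] = {}
        for k, cond in enumerate(sorted(set(config.froi_test_conditions))):
            sub = words[words["condition"] == cond]
            report["tests"][cond] = _cluster_block(
                _prime_test(froi_epochs, sub, window, config, seed_offset=k)
            )
        return report

    # albright: score x prime-type interaction for irregulars, plus the
    # high/low score split
    irr = words[words["condition"] == "irregular"]
    if irr.empty:
        raise ValueError("albright analysis requires irregular trials")
    scored = add_orthogonalized_score(words)
    result = interaction_analysis(
        froi_epochs, scored, score_term="albright_score_o", factor="prime_type",
        condition="irregular", window_ms=window, threshold=config.threshold,
        n_perm=config.n_perm, seed=config.seed,
    )
    report["interaction"] = _cluster_block(result)
    labels = bin_albright(irr["albright_score"].to_numpy())
    report["bins"] = {}
    for k, level in enumerate(("high", "low")):
        sub = irr[labels == level]
        if sub["prime_type"].nunique() < 2:
            logger.warning("albright bin %s lacks both prime types; skipped", level)
            continue
        report["bins"][level] = _cluster_block(
            _prime_test(froi_epochs, sub, window, config, seed_offset=k + 1)
        )
        report["bins"][level]["n_trials"] = int(len(sub))
    return report


def _require_conditions(words: pd.DataFrame, conditions) -> None:
    present = set(words["condition"].unique())
    missing = set(conditions) - present
    if missing:
        raise ValueError(f"required conditions missing from trials: {sorted(missing)}")
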