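"""Build scenario-labelled training points from dated record sets.

Sub-samples are admitted to a training set only when their death-date
distribution matches one duration scenario unambiguously:

* at least ``min_size`` individuals (default 15 — below that the sample SD is
  noticeably biased low, see :func:`mortwear.stats.sd_vs_n_bias`);
* a date window consistent with the scenario (A <= 92 days, B 120–365 days);
* for A/B, deaths spread evenly over the window, without long blank periods
  or strong concentrations (the max-gap / max-bin rules below).

Scenario-C sub-samples are assembled from two groups of deaths in opposite
seasons; because real collections rarely cover both seasons evenly, the
relative frequencies are varied by replicating one group's densities over a
grid of warm-season proportions, yielding up to nine points per group pair.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from . import config
from ._calendar import YEAR_DAYS, month_day, season_of, seasons_consecutive
from .simulate import (
    Scenario,
    SeasonalDietModel,
    Window,
    default_model,
    simulate_event,
    simulate_scenario,
)
from .stats import VariabilityPoint, densities_from_records, variability_point

__all__ = [
    "SubsampleSpec",
    "extract_subsamples",
    "build_scenario_c",
    "synthetic_training_points",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsampleSpec:
    """Admissibility rules for training sub-samples.

    ``relax`` disables the evenness checks (mirroring the occasional need to
    relax them when real collections do not cover every month) but never the
    size check.
    """

    scenario: Scenario | str
    min_size: int = config.DEFAULT_MIN_SIZE
    max_gap_frac: float = config.EVENNESS["max_gap_frac"]
    n_bins: int = config.EVENNESS["n_bins"]
    max_bin_frac: float = config.EVENNESS["max_bin_frac"]
    c_proportions: tuple = config.C_PROPORTIONS
    relax: bool = False

    def __post_init__(self):
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if any(not 0.0 < p < 1.0 for p in self.c_proportions):
            raise ValueError("proportions must be strictly between 0 and 1")


def _window_offsets(records, window: Window):
    """Offsets (days from window start) of records falling inside the window."""
    inside, offsets = [], []
    for rec in records:
        off = (rec.day_of_year - window.start) % YEAR_DAYS
        if off < window.length:
            inside.append(rec)
            offsets.append(off)
    return inside, offsets


def _evenness_violation(offsets, window: Window, spec: SubsampleSpec) -> str | None:
    offs = np.sort(np.asarray(offsets, dtype=float))
    gaps = np.diff(offs)
    if gaps.size and gaps.max() > spec.max_gap_frac * window.length:
        return (
            f"blank period of {gaps.max():.0f} days exceeds "
            f"{spec.max_gap_frac:.2f} of the {window.length}-day window"
        )
    bins = np.floor(offs / window.length * spec.n_bins).clip(max=spec.n_bins - 1)
    top = Counter(bins).most_common(1)[0][1]
    if top > spec.max_bin_frac * offs.size:
        return (
            f"{top}/{offs.size} deaths concentrated in one "
            f"1/{spec.n_bins} of the window"
        )
    return None


def extract_subsamples(records, spec: SubsampleSpec, windows) -> list[VariabilityPoint]:
    """Extract admissible scenario-labelled points from dated records.

    Parameters
    ----------
    records : list of IndividualRecord
        Dated at least to month resolution.
    windows : list of Window, or list of (Window, Window) for scenario C
        User-declared candidate windows; there is no automated window search.

    Returns the points that pass every rule (possibly empty).  Discarded
    candidates are logged with the violated rule.
    """
    scenario = Scenario(spec.scenario)
    points: list[VariabilityPoint] = []
    for i, win in enumerate(windows):
        sid = f"{scenario.value}-{i}"
        if scenario is Scenario.C:
            w1, w2 = win
            hemi = records[0].hemisphere if records else "north"
            if seasons_consecutive(w1.season(hemi), w2.season(hemi)):
                logger.info("discarded %s: windows in consecutive seasons", sid)
                continue
            g1, _ = _window_offsets(records, w1)
            g2, _ = _window_offsets(records, w2)
            inside = g1 + g2
            if len(inside) < spec.min_size:
                logger.info("discarded %s: n=%d below min_size=%d", sid, len(inside), spec.min_size)
                continue
            points.append(
                variability_point(densities_from_records(inside), sid, label=scenario.value)
            )
            continue

        if scenario is Scenario.A and win.length > 92:
            logger.info("discarded %s: %d-day window too long for scenario A", sid, win.length)
            continue
        if scenario is Scenario.B and not 120 <= win.length <= 365:
            logger.info("discarded %s: %d-day window inconsistent with scenario B", sid, win.length)
            continue
        inside, offsets = _window_offsets(records, win)
        if len(inside) < spec.min_size:
            logger.info("discarded %s: n=%d below min_size=%d", sid, len(inside), spec.min_size)
            continue
        if not spec.relax:
            why = _evenness_violation(offsets, win, spec)
            if why is not None:
                logger.info("discarded %s: %s", sid, why)
                continue
        points.append(variability_point(densities_from_records(inside), sid, label=scenario.value))
    return points


def _season_of_group(records) -> str:
    seasons = Counter(season_of(r.death_month, r.hemisphere) for r in records)
    return seasons.most_common(1)[0][0]


def build_scenario_c(
    group_warm,
    group_cold,
    proportions=None,
    min_size: int = config.DEFAULT_MIN_SIZE,
    sample_id_prefix: str = "C",
) -> list[VariabilityPoint]:
    """Assemble scenario-C points from two opposite-season death groups.

    For each target warm-season proportion the minority group's densities are
    replicated (cyclically, so no new values are introduced) until the warm
    fraction matches the target; the pooled sample's (SD, CV) becomes one
    labelled point.  Proportions whose pooled size falls below ``min_size``
    are skipped.
    """
    if not group_warm or not group_cold:
        raise ValueError("both season groups must be non-empty")
    s_w, s_c = _season_of_group(group_warm), _season_of_group(group_cold)
    if seasons_consecutive(s_w, s_c):
        raise ValueError(f"seasons {s_w!r} and {s_c!r} are not non-consecutive")
    proportions = config.C_PROPORTIONS if proportions is None else proportions
    d_warm = densities_from_records(group_warm)
    d_cold = densities_from_records(group_cold)

    def tile(values: np.ndarray, m: int) -> np.ndarray:
        reps = int(np.ceil(m / values.size))
        return np.tile(values, reps)[:m]

    points = []
    for p in proportions:
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must be strictly between 0 and 1")
        if p >= d_warm.size / (d_warm.size + d_cold.size):
            # replicate the warm group against the fixed cold group
            m = max(1, round(p / (1.0 - p) * d_cold.size))
            pooled = np.concatenate([tile(d_warm, m), d_cold])
        else:
            m = max(1, round((1.0 - p) / p * d_warm.size))
            pooled = np.concatenate([d_warm, tile(d_cold, m)])
        if pooled.size < min_size:
            logger.info(
                "skipped proportion %.2f: pooled n=%d below min_size=%d",
                p, pooled.size, min_size,
            )
            continue
        points.append(
            variability_point(pooled, f"{sample_id_prefix}-p{p:.2f}", label=Scenario.C.value)
        )
    return points


def synthetic_training_points(
    model: SeasonalDietModel | None = None,
    seed: int = 0,
    n_per_subsample: int = config.TRAINING_N_PER_SUBSAMPLE,
) -> list[VariabilityPoint]:
    """The default calibrated training set, generated from the simulator.

    Scenario A and B points come from one simulated event per configured
    window (:data:`mortwear.config.TRAINING_WINDOWS_A` / ``_B``); scenario C
    points from two simulated opposite-season short events combined over the
    default warm-season proportion grid.
    """
    model = model or default_model()
    rng = np.random.default_rng(seed)
    points: list[VariabilityPoint] = []
    isds = config.TRAINING_INDIVIDUAL_SDS

    for label, window_list in ((Scenario.A, config.TRAINING_WINDOWS_A),
                               (Scenario.B, config.TRAINING_WINDOWS_B)):
        for i, (start, length) in enumerate(window_list):
            # cycle the within-date heterogeneity so each class reflects
            # between-population differences in individual spread
            m_i = replace(model, individual_sd=isds[i % len(isds)])
            recs = simulate_scenario(
                label, n_per_subsample, m_i, Window(start, length), rng,
                sample_id=f"train-{label.value}{i}",
            )
            points.append(
                variability_point(
                    densities_from_records(recs), f"train-{label.value}{i}", label=label.value
                )
            )

    warm = Window(*config.TRAINING_WINDOWS_C["warm"])
    cold = Window(*config.TRAINING_WINDOWS_C["cold"])
    half = max(config.DEFAULT_MIN_SIZE, n_per_subsample // 2)

    def event(win, sid):
        dates = [month_day(doy) for doy in win.days(half)]
        return simulate_event(dates, 1, model, rng, sample_id=sid)

    g_warm = event(warm, "train-C-warm")
    g_cold = event(cold, "train-C-cold")
    points += build_scenario_c(g_warm, g_cold, sample_id_prefix="train-C")
    return points
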