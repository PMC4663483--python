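"""Per-individual scratch densities and per-sample variability coordinates.

Each specimen contributes one density: the mean of its (up to two) area
counts.  Each sample of n >= 2 specimens is summarised by the pair
(SD, CV) — standard deviation and coefficient of variation of the individual
densities — which are the x and y coordinates of the classifier's plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariabilityPoint",
    "individual_density",
    "densities_from_records",
    "variability_point",
    "points_by_sample",
    "sd_vs_n_bias",
]


@dataclass(frozen=True)
class VariabilityPoint:
    """A sample's coordinates in the SD-CV plane.

    ``sd`` is in scratches per 0.16 mm^2; ``cv = sd / mean`` is dimensionless.
    ``label`` is the duration scenario ("A", "B" or "C") when known.
    """

    sample_id: str
    n: int
    mean: float
    sd: float
    cv: float
    label: str | None = None


def individual_density(count_area1: float, count_area2: float | None = None) -> float:
    """Scratch density of one specimen: mean of the available area counts.

    Two standard areas are counted per tooth when possible; a specimen with a
    single countable area contributes that single count.
    """
    if count_area1 is None:
        raise ValueError("count_area1 is mandatory")
    if count_area1 < 0 or (count_area2 is not None and count_area2 < 0):
        raise ValueError("scratch counts must be >= 0")
    if count_area2 is None:
        return float(count_area1)
    return (float(count_area1) + float(count_area2)) / 2.0


def densities_from_records(records) -> np.ndarray:
    """Per-individual densities for a list of :class:`IndividualRecord`."""
    return np.array([individual_density(r.count_area1, r.count_area2) for r in records])


def variability_point(
    densities, sample_id: str, label: str | None = None, ddof: int = 1
) -> VariabilityPoint:
    """Summarise a sample of individual densities as a (SD, CV) point.

    Parameters
    ----------
    densities : array-like
        Individual scratch densities, length >= 2.
    ddof : int
        Delta degrees of freedom for the SD (1 = sample SD, the default).
    """
    x = np.asarray(densities, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"sd undefined: need at least 2 individuals, got {n}")
    mean = float(x.mean())
    if mean <= 0:
        raise ValueError("cv undefined: mean density must be > 0")
    sd = float(x.std(ddof=ddof))
    return VariabilityPoint(sample_id=sample_id, n=int(n), mean=mean, sd=sd, cv=sd / mean, label=label)


def points_by_sample(records, ddof: int = 1) -> list[VariabilityPoint]:
    """Group records by ``sample_id`` and compute one variability point each.

    Samples with fewer than 2 specimens are dropped (SD undefined).
    """
    by_id: dict[str, list] = {}
    for rec in records:
        by_id.setdefault(rec.sample_id, []).append(rec)
    out = []
    for sid in sorted(by_id):
        recs = by_id[sid]
        if len(recs) < 2:
            continue
        out.append(variability_point(densities_from_records(recs), sid, ddof=ddof))
    return out


def sd_vs_n_bias(population, sizes, reps: int, seed: int) -> pd.DataFrame:
    """Small-sample behaviour of the sample SD under random sub-sampling.

    For each size ``n`` draws ``reps`` random subsets (without replacement)
    from ``population`` and averages their sample SDs.  The mean SD has a
    negative correlation with subset size at small n — the rationale for
    the minimum-size filter applied when building classifier training sets.

    Returns a DataFrame with columns ``n`` and ``mean_sd``.
    """
    pop = np.asarray(population, dtype=float)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        n = int(n)
        if n < 2:
            raise ValueError("subset size must be >= 2")
        if n > pop.size:
            raise ValueError(f"subset size {n} exceeds population size {pop.size}")
        if n == pop.size:
            # every subset is the whole population
            rows.append((n, float(pop.std(ddof=1))))
            continue
        sds = [rng.choice(pop, size=n, replace=False).std(ddof=1) for _ in range(reps)]
        rows.append((n, float(np.mean(sds))))
    return pd.DataFrame(rows, columns=["n", "mean_sd"])
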