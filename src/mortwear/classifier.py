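"""Three-class Gaussian naive-Bayes model over the SD-CV plane.

The model assigns to each duration scenario k in {A, B, C} a weighted,
axis-aligned bivariate Gaussian

    G_k(x, y) = P_k * N(x; mu_xk, sigma_xk) * N(y; mu_yk, sigma_yk),

where x = SD and y = CV of a sample's scratch densities and the priors P_k
default to 1/3 (no a-priori information on real case frequencies).  The
naive independence assumption between SD and CV means only per-axis means
and standard deviations need estimating, so very small training sets
suffice.  The plane is partitioned into three regions by which G_k is
largest; boundaries are the loci G_i = G_j.  The total mixture
G = G_A + G_B + G_C supports probability isolines (level curves enclosing a
stated probability mass) and an expected total classification error.

Usage follows the model/results idiom::

    model = DurationClassifier.from_points(points)
    res = model.fit()
    res.classify(4.134, 0.242)          # -> ClassificationResult
    res.isolines([0.68, 0.95])
    print(res.summary())
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import config

__all__ = [
    "CLASS_ORDER",
    "ClassGaussian",
    "GridSpec",
    "ClassificationResult",
    "Isoline",
    "ExpectedTotalError",
    "DurationClassifier",
    "DurationClassifierResults",
]

#: Fixed class order; also the deterministic tie-break order for argmax.
CLASS_ORDER = ("A", "B", "C")

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ClassGaussian:
    """Fitted parameters of one class: axis-aligned bivariate Gaussian + prior."""

    label: str
    mu_x: float
    sigma_x: float
    mu_y: float
    sigma_y: float
    prior: float

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError(f"class {self.label}: sigmas must be > 0")
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"class {self.label}: prior must be in (0, 1)")


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grid over the SD-CV plane (cell-centre quadrature)."""

    x_min: float = config.DEFAULT_GRID["x_min"]
    x_max: float = config.DEFAULT_GRID["x_max"]
    y_min: float = config.DEFAULT_GRID["y_min"]
    y_max: float = config.DEFAULT_GRID["y_max"]
    nx: int = config.DEFAULT_GRID["nx"]
    ny: int = config.DEFAULT_GRID["ny"]

    def __post_init__(self):
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid bounds must be increasing")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid resolution must be >= 2")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.nx

    @property
    def dy(self) -> float:
        return (self.y_max - self.y_min) / self.ny

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.ny) + 0.5) * self.dy

    def mesh(self):
        """(X, Y) cell-centre meshgrid, shape (ny, nx)."""
        return np.meshgrid(self.x_centers, self.y_centers)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of classifying one (SD, CV) point."""

    sd: float
    cv: float
    region: str
    posterior: dict
    error_prob: float
    inside_isoline: float | None = None


@dataclass(frozen=True)
class Isoline:
    """A level curve of the total mixture enclosing probability ``mass``."""

    mass: float
    level: float
    paths: tuple  # tuple of (k, 2) vertex arrays


@dataclass(frozen=True)
class ExpectedTotalError:
    """Total expected misclassification mass and its decomposition.

    ``by_class[k]`` is the mass of G_k outside region k; ``ac_overlap`` is
    the (expected-negligible) cross term between the two non-adjacent
    classes: mass of G_A in region C plus mass of G_C in region A.
    """

    total: float
    by_class: dict
    ac_overlap: float


def _norm_pdf(v, mu, sigma):
    z = (np.asarray(v, dtype=float) - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))


class DurationClassifier:
    """Model: labelled (SD, CV) training points awaiting a fit.

    Parameters
    ----------
    sd, cv : array-like of float
        Training coordinates.
    labels : array-like of str
        Scenario labels; every point must be labelled "A", "B" or "C" and
        each class needs at least two points.
    """

    def __init__(self, sd, cv, labels):
        self.sd = np.asarray(sd, dtype=float)
        self.cv = np.asarray(cv, dtype=float)
        self.labels = np.asarray([str(l) for l in labels])
        if not (self.sd.shape == self.cv.shape == self.labels.shape):
            raise ValueError("sd, cv and labels must have equal length")
        unknown = set(self.labels) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")

    @classmethod
    def from_points(cls, points) -> "DurationClassifier":
        """Build from an iterable of labelled :class:`VariabilityPoint`."""
        pts = list(points)
        if any(p.label is None for p in pts):
            raise ValueError("every training point needs a scenario label")
        return cls([p.sd for p in pts], [p.cv for p in pts], [p.label for p in pts])

    @classmethod
    def from_dataframe(cls, df, sd="sd", cv="cv", label="label") -> "DurationClassifier":
        return cls(df[sd].to_numpy(), df[cv].to_numpy(), df[label].to_numpy())

    def fit(self, priors=None, ddof: int = 1, grid: GridSpec | None = None) -> "DurationClassifierResults":
        """Estimate per-class means/SDs on both axes; return a results object.

        Parameters
        ----------
        priors : sequence of three floats or mapping label -> float, optional
            Class weights (normalised to sum to 1).  Default: equal (1/3).
        ddof : int
            Degrees-of-freedom correction for the class SDs (1 = sample SD).
        grid : GridSpec, optional
            Evaluation grid for boundaries, maps and integrals.
        """
        if priors is None:
            pri = {k: 1.0 / 3.0 for k in CLASS_ORDER}
        elif isinstance(priors, dict):
            pri = {k: float(priors[k]) for k in CLASS_ORDER}
        else:
            pri = dict(zip(CLASS_ORDER, map(float, priors)))
        tot = sum(pri.values())
        if tot <= 0 or any(v <= 0 for v in pri.values()):
            raise ValueError("priors must be positive")
        pri = {k: v / tot for k, v in pri.items()}

        classes = {}
        for k in CLASS_ORDER:
            mask = self.labels == k
            n_k = int(mask.sum())
            if n_k < 2:
                raise ValueError(f"class {k} needs at least 2 training points, got {n_k}")
            xs, ys = self.sd[mask], self.cv[mask]
            sx = float(xs.std(ddof=ddof))
            sy = float(ys.std(ddof=ddof))
            if sx == 0.0 or sy == 0.0:
                raise ValueError(
                    f"class {k} has zero within-class variance on one axis; "
                    "add training sub-samples with distinct (SD, CV) values"
                )
            classes[k] = ClassGaussian(
                label=k, mu_x=float(xs.mean()), sigma_x=sx,
                mu_y=float(ys.mean()), sigma_y=sy, prior=pri[k],
            )
        return DurationClassifierResults(classes, grid or GridSpec(), model=self)


class DurationClassifierResults:
    """Fitted three-class naive-Bayes map over the SD-CV plane."""

    def __init__(self, classes: dict, grid: GridSpec, model: DurationClassifier | None = None):
        if set(classes) != set(CLASS_ORDER):
            raise ValueError(f"need exactly the classes {CLASS_ORDER}")
        self.classes = {k: classes[k] for k in CLASS_ORDER}
        self.grid = grid
        self.model = model
        self._grid_cache = None
        self._level_cache: dict[float, float] = {}

    # --- densities -----------------------------------------------------

    def class_density(self, label: str, x, y):
        """Weighted class density G_k(x, y) = prior * N(x) * N(y)."""
        g = self.classes[label]
        return g.prior * _norm_pdf(x, g.mu_x, g.sigma_x) * _norm_pdf(y, g.mu_y, g.sigma_y)

    def densities(self, x, y) -> np.ndarray:
        """Stack of the three class densities, shape (3, ...) in A,B,C order."""
        return np.stack([self.class_density(k, x, y) for k in CLASS_ORDER])

    def total_density(self, x, y):
        """The mixture G(x, y) = G_A + G_B + G_C."""
        return self.densities(x, y).sum(axis=0)

    def posteriors(self, x, y) -> np.ndarray:
        """Posterior class probabilities, shape (3, ...); sums to 1.

        Where all three densities underflow to zero (far tails) the posterior
        is taken as uniform, matching the equal-priors limit.
        """
        d = self.densities(x, y)
        return self._normalise(d)

    @staticmethod
    def _normalise(d: np.ndarray) -> np.ndarray:
        s = d.sum(axis=0)
        zero = s == 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            post = d / np.where(zero, 1.0, s)
        if np.any(zero):
            post = np.where(zero, 1.0 / len(CLASS_ORDER), post)
        return post

    # --- classification ------------------------------------------------

    def classify(self, sd: float, cv: float, isolines: bool = True) -> ClassificationResult:
        """Classify one point; ties broken in fixed A < B < C order.

        ``error_prob`` is 1 - max posterior: the probability that the point
        does not belong to the region it falls in.
        """
        if not (math.isfinite(sd) and math.isfinite(cv)):
            raise ValueError(f"non-finite input point ({sd}, {cv})")
        post = self.posteriors(sd, cv)
        idx = int(np.argmax(post))  # first max -> A < B < C tie-break
        inside = None
        if isolines:
            g = float(self.total_density(sd, cv))
            for m in sorted(config.DEFAULT_ISOLINE_MASSES):
                if g >= self.isoline_level(m):
                    inside = m
                    break
        return ClassificationResult(
            sd=float(sd),
            cv=float(cv),
            region=CLASS_ORDER[idx],
            posterior={k: float(p) for k, p in zip(CLASS_ORDER, post)},
            error_prob=float(1.0 - post[idx]),
            inside_isoline=inside,
        )

    def classify_points(self, points, isolines: bool = True):
        """Classify an iterable of points; returns a :class:`pandas.DataFrame`.

        Accepts (sd, cv) pairs, objects with ``sd``/``cv`` attributes, or a
        DataFrame with ``sd``/``cv`` columns.
        """
        import pandas as pd

        rows = []
        if isinstance(points, pd.DataFrame):
            items = [(r.get("sample_id", i), r["sd"], r["cv"]) for i, r in points.iterrows()]
        else:
            items = []
            for i, p in enumerate(points):
                if hasattr(p, "sd"):
                    items.append((getattr(p, "sample_id", i), p.sd, p.cv))
                else:
                    s, c = p
                    items.append((i, s, c))
        for sid, s, c in items:
            r = self.classify(s, c, isolines=isolines)
            rows.append(
                {
                    "sample_id": sid,
                    "sd": r.sd,
                    "cv": r.cv,
                    "region": r.region,
                    **{f"p_{k}": r.posterior[k] for k in CLASS_ORDER},
                    "error_prob": r.error_prob,
                    "inside_isoline": r.inside_isoline,
                }
            )
        return pd.DataFrame(rows)

    # --- grid machinery ------------------------------------------------

    def _grid_densities(self) -> np.ndarray:
        """Cached class densities on the grid, shape (3, ny, nx)."""
        if self._grid_cache is None:
            X, Y = self.grid.mesh()
            self._grid_cache = self.densities(X, Y)
        return self._grid_cache

    def region_map(self) -> np.ndarray:
        """Region index (0=A, 1=B, 2=C) at each grid node, shape (ny, nx)."""
        return np.argmax(self._grid_densities(), axis=0)

    def error_map(self, kind: str = "one_minus_max") -> np.ndarray:
        """Classification-uncertainty heat map on the grid, shape (ny, nx).

        ``one_minus_max`` (default): 1 - max posterior, the probability that
        a case at that position does not belong to the region containing it.
        ``margin``: difference between the top two posteriors (an alternative
        proximity-to-boundary measure; small near boundaries).
        """
        post = self._normalise(self._grid_densities())
        srt = np.sort(post, axis=0)
        if kind == "one_minus_max":
            return 1.0 - srt[-1]
        if kind == "margin":
            return srt[-1] - srt[-2]
        raise ValueError(f"unknown error-map kind {kind!r}")

    def boundary_curve(self, pair) -> list[np.ndarray]:
        """Zero contour of log G_i - log G_j: the decision boundary.

        The two boundaries the map actually uses are (A, B) and (B, C); the
        (A, C) pair is computed on request with a warning, since the overlap
        of G_A and G_C is negligible and that boundary plays no role in the
        three-region partition.
        Returns a list of (k, 2) polyline vertex arrays in (SD, CV) space.
        """
        i, j = pair
        if {i, j} == {"A", "C"}:
            warnings.warn(
                "the A-C boundary is not used by the three-region map "
                "(A and C barely overlap); computing it anyway",
                stacklevel=2,
            )
        if i not in CLASS_ORDER or j not in CLASS_ORDER or i == j:
            raise ValueError(f"invalid class pair {pair!r}")
        from contourpy import contour_generator

        X, Y = self.grid.mesh()
        gi = np.log(np.maximum(self.class_density(i, X, Y), 1e-300))
        gj = np.log(np.maximum(self.class_density(j, X, Y), 1e-300))
        gen = contour_generator(x=X, y=Y, z=gi - gj)
        return [np.asarray(line) for line in gen.lines(0.0)]

    # --- isolines of the total mixture ----------------------------------

    def _grid_mass(self, level: float) -> float:
        G = self._grid_densities().sum(axis=0)
        return float(G[G >= level].sum() * self.grid.cell_area)

    def isoline_level(self, mass: float, tol: float = 1e-10) -> float:
        """Density level c with ∫_{G >= c} G = mass, by bisection on c."""
        if not 0.0 < mass < 1.0:
            raise ValueError("mass must be in (0, 1)")
        if mass in self._level_cache:
            return self._level_cache[mass]
        G = self._grid_densities().sum(axis=0)
        total = float(G.sum() * self.grid.cell_area)
        if total < mass:
            raise ValueError(
                f"grid captures only {total:.4f} probability mass; enlarge the "
                f"grid bounds to resolve the {mass:.3f} isoline"
            )
        lo, hi = 0.0, float(G.max())
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if self._grid_mass(mid) >= mass:
                lo = mid
            else:
                hi = mid
            if hi - lo <= tol * max(1.0, hi):
                break
        level = 0.5 * (lo + hi)
        self._level_cache[mass] = level
        return level

    def isolines(self, masses=config.DEFAULT_ISOLINE_MASSES) -> list[Isoline]:
        """Level curves of G enclosing the given probability masses."""
        from contourpy import contour_generator

        X, Y = self.grid.mesh()
        G = self._grid_densities().sum(axis=0)
        gen = contour_generator(x=X, y=Y, z=G)
        out = []
        for m in masses:
            level = self.isoline_level(m)
            paths = tuple(np.asarray(line) for line in gen.lines(level))
            out.append(Isoline(mass=float(m), level=level, paths=paths))
        return out

    def sample_mixture(self, n: int, seed) -> np.ndarray:
        """Draw n points from the fitted mixture G; shape (n, 2)."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        priors = np.array([self.classes[k].prior for k in CLASS_ORDER])
        counts = rng.multinomial(n, priors)
        chunks = []
        for k, m in zip(CLASS_ORDER, counts):
            g = self.classes[k]
            xs = rng.normal(g.mu_x, g.sigma_x, size=m)
            ys = rng.normal(g.mu_y, g.sigma_y, size=m)
            chunks.append(np.column_stack([xs, ys]))
        pts = np.concatenate(chunks)
        rng.shuffle(pts)
        return pts

    # --- expected error --------------------------------------------------

    def expected_total_error(self) -> ExpectedTotalError:
        """Sum over classes of the class mass lying outside its own region.

        Computed by cell-centre quadrature on the grid; algebraically equal
        to 1 - ∫ max_k G_k.  The A-C cross term is reported separately so
        its negligibility can be checked.
        """
        d = self._grid_densities()
        region = np.argmax(d, axis=0)
        area = self.grid.cell_area
        by_class = {}
        for idx, k in enumerate(CLASS_ORDER):
            by_class[k] = float(d[idx][region != idx].sum() * area)
        ac = float(d[0][region == 2].sum() * area + d[2][region == 0].sum() * area)
        return ExpectedTotalError(
            total=float(sum(by_class.values())), by_class=by_class, ac_overlap=ac
        )

    # --- presentation ----------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary in the statsmodels spirit."""
        lines = [
            "Mortality-duration naive-Bayes classifier (SD-CV plane)",
            "=" * 60,
            f"{'class':>6} {'prior':>7} {'mu_SD':>8} {'sd_SD':>8} {'mu_CV':>8} {'sd_CV':>8} {'n':>5}",
        ]
        for k in CLASS_ORDER:
            g = self.classes[k]
            n_k = int((self.model.labels == k).sum()) if self.model is not None else -1
            lines.append(
                f"{k:>6} {g.prior:7.3f} {g.mu_x:8.3f} {g.sigma_x:8.3f} "
                f"{g.mu_y:8.3f} {g.sigma_y:8.3f} {n_k:5d}"
            )
        err = self.expected_total_error()
        lines += [
            "-" * 60,
            f"expected total error: {err.total:.4f}   (A-C overlap term: {err.ac_overlap:.2e})",
            f"grid: {self.grid.nx}x{self.grid.ny} over "
            f"SD [{self.grid.x_min}, {self.grid.x_max}], CV [{self.grid.y_min}, {self.grid.y_max}]",
        ]
        return "\n".join(lines)

    # --- persistence ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "classes": {k: asdict(g) for k, g in self.classes.items()},
            "grid": asdict(self.grid),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DurationClassifierResults":
        """Rebuild a fitted map from :meth:`to_json` output (text or path)."""
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source, encoding="utf-8") as fh:
                payload = json.load(fh)
        classes = {k: ClassGaussian(**v) for k, v in payload["classes"].items()}
        return cls(classes, GridSpec(**payload["grid"]))

    # --- plotting ---------------------------------------------------------

    def plot_map(self, points=None, masses=config.DEFAULT_ISOLINE_MASSES, ax=None):
        """SD-CV map: uncertainty heat map, boundaries, isolines, points.

        ``points`` may be anything :meth:`classify_points` accepts; they are
        drawn with their sample ids.  Returns the matplotlib Axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        X, Y = self.grid.mesh()
        im = ax.pcolormesh(X, Y, self.error_map(), cmap="YlOrRd", vmin=0.0, vmax=0.5, shading="auto")
        plt.colorbar(im, ax=ax, label="P(not in assigned region)")
        for pair in (("A", "B"), ("B", "C")):
            for line in self.boundary_curve(pair):
                ax.plot(line[:, 0], line[:, 1], "k-", lw=1.2)
        for iso in self.isolines(masses):
            for line in iso.paths:
                ax.plot(line[:, 0], line[:, 1], "b--", lw=0.8, alpha=0.7)
        for k in CLASS_ORDER:
            g = self.classes[k]
            ax.annotate(k, (g.mu_x, g.mu_y), fontsize=14, weight="bold", ha="center")
        if points is not None:
            df = self.classify_points(points, isolines=False)
            ax.scatter(df["sd"], df["cv"], c="k", s=18, zorder=5)
            for _, row in df.iterrows():
                ax.annotate(str(row["sample_id"]), (row["sd"], row["cv"]),
                            fontsize=7, xytext=(3, 3), textcoords="offset points")
        ax.set_xlim(0.0, self.grid.x_max * 0.85)
        ax.set_ylim(0.0, self.grid.y_max * 0.85)
        ax.set_xlabel("SD (scratches / 0.16 mm$^2$)")
        ax.set_ylabel("CV")
        return ax
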