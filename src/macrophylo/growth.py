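"""Stage-binned lineage richness and exponential-vs-logistic growth tests.

A family-level range table (raw or ghost-range adjusted) is binned on a
geological timescale: a family counts toward a stage when its
[FAD, LAD] interval overlaps the stage, originations fall in the stage
containing the FAD and extinctions (extinct families only) in the stage
containing the LAD.  The resulting lineage-through-time series, indexed by
stage midpoints, is interpolated to equal spacing with an Akima spline and
log(richness + 1) is regressed on time with an AR(1) residual structure by
generalized least squares.  Exponential growth predicts a linear trend in
log richness; a significantly *decelerating* quadratic term (negative, with
time running toward the present) is the signature of logistic saturation.

The GLS machinery is exposed statsmodels-style: ``GrowthCurveModel`` holds
the data and design, ``fit()`` returns a ``GrowthFit`` results object with
estimates, standard errors, the AR(1) coefficient and a ``summary()``.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.interpolate import Akima1DInterpolator
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .ghosts import FossilRangeTable

__all__ = [
    "Stage",
    "Timescale",
    "load_timescale",
    "RichnessSeries",
    "lineage_series",
    "akima_resample",
    "durbin_watson",
    "GrowthCurveModel",
    "GrowthFit",
    "fit_gls_ar1",
    "classify_growth",
    "plot_ltt",
]


# ---------------------------------------------------------------------------
# timescale


@dataclass(frozen=True)
class Stage:
    name: str
    period: str
    base: float   # older boundary, Ma
    top: float    # younger boundary, Ma

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.base + self.top)

    @property
    def duration(self) -> float:
        return self.base - self.top


@dataclass(frozen=True)
class Timescale:
    """Ordered (oldest first), contiguous geological stages."""

    stages: tuple[Stage, ...]

    def __post_init__(self):
        if not self.stages:
            raise ValueError("empty timescale")
        for a, b in zip(self.stages, self.stages[1:]):
            if a.base <= a.top:
                raise ValueError(f"stage {a.name}: base must exceed top")
            if abs(a.top - b.base) > 1e-9:
                raise ValueError(
                    f"stages {a.name} and {b.name} are not contiguous")
        last = self.stages[-1]
        if last.base <= last.top:
            raise ValueError(f"stage {last.name}: base must exceed top")

    @property
    def span(self) -> tuple[float, float]:
        return self.stages[0].base, self.stages[-1].top

    def stage_of(self, age: float) -> int:
        """Index of the stage containing ``age`` (base >= age > top; the
        oldest base and the youngest top are included)."""
        oldest, youngest = self.span
        if age > oldest or age < youngest:
            raise ValueError(f"age {age} Ma outside timescale "
                             f"[{youngest}, {oldest}]")
        for i, s in enumerate(self.stages):
            if s.base >= age > s.top:
                return i
        return len(self.stages) - 1  # age == youngest top (e.g. 0 Ma)

    def __len__(self) -> int:
        return len(self.stages)


def load_timescale(path: str | Path | None = None) -> Timescale:
    """Read a stage table (stage, period, base_ma, top_ma).  With no path,
    the packaged Carboniferous→Quaternary table is used."""
    if path is None:
        ref = importlib.resources.files("macrophylo.data") / \
            "geological_stages.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    stages: list[Stage] = []
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#") or row[0].lower() == "stage":
            continue
        stages.append(Stage(row[0].strip(), row[1].strip(),
                            float(row[2]), float(row[3])))
    return Timescale(tuple(stages))


# ---------------------------------------------------------------------------
# lineage-through-time series


@dataclass
class RichnessSeries:
    """Lineage counts against time (Ma, oldest first)."""

    times_ma: np.ndarray
    richness: np.ndarray
    source: str = "fossil_only"
    originations: np.ndarray | None = None   # per stage, aligned with times
    extinctions: np.ndarray | None = None
    stage_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.times_ma = np.asarray(self.times_ma, dtype=float)
        self.richness = np.asarray(self.richness, dtype=float)
        if self.times_ma.shape != self.richness.shape:
            raise ValueError("times and richness differ in length")
        if np.any(self.richness < 0):
            raise ValueError("negative richness")

    @property
    def n(self) -> int:
        return len(self.times_ma)

    def drop_last(self) -> "RichnessSeries":
        """Variant excluding the final (extant) point."""
        return RichnessSeries(self.times_ma[:-1], self.richness[:-1],
                              source=self.source + "_no_extant")

    def since_first_appearance(self) -> "RichnessSeries":
        """Subseries from the first stage with positive richness — growth
        models only make sense once the clade exists."""
        nz = np.nonzero(self.richness > 0)[0]
        if len(nz) == 0:
            raise ValueError("series is identically zero")
        i = nz[0]
        return RichnessSeries(self.times_ma[i:], self.richness[i:],
                              source=self.source)

    def equally_spaced(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.times_ma)
        return bool(len(d) == 0 or
                    np.allclose(d, d.mean(), rtol=rtol,
                                atol=1e-9 * abs(d.mean() or 1.0)))


def lineage_series(ranges: FossilRangeTable, scale: Timescale,
                   source: str = "fossil_only") -> RichnessSeries:
    """Bin a range table into per-stage lineage counts.

    A family is present in a stage when its stratigraphic interval strictly
    overlaps the stage interior, so a FAD sitting exactly on a stage base
    counts from that stage onward, not before.
    """
    oldest, youngest = scale.span
    nstage = len(scale)
    rich = np.zeros(nstage)
    orig = np.zeros(nstage)
    ext = np.zeros(nstage)
    for fam, r in ranges.items():
        if r.fad > oldest or r.lad < youngest:
            raise ValueError(
                f"family {fam!r}: range [{r.lad}, {r.fad}] outside "
                f"timescale [{youngest}, {oldest}]")
        orig[scale.stage_of(r.fad)] += 1
        if not r.extant:
            ext[scale.stage_of(r.lad)] += 1
        for i, s in enumerate(scale.stages):
            if r.fad > s.top and r.lad < s.base:
                rich[i] += 1
    mids = np.array([s.midpoint for s in scale.stages])
    return RichnessSeries(mids, rich, source=source, originations=orig,
                          extinctions=ext,
                          stage_names=tuple(s.name for s in scale.stages))


def akima_resample(series: RichnessSeries) -> RichnessSeries:
    """Interpolate to the same number of equally spaced points with an
    Akima (1970) piecewise cubic; endpoints are reproduced exactly.

    Akima splines can undershoot slightly between knots, so interpolated
    richness is floored at zero before the log transform downstream.
    """
    if series.n < 5:
        raise ValueError("Akima interpolation needs at least 5 points")
    # work on a forward-running axis (-Ma) so x is strictly increasing
    x = -series.times_ma
    order = np.argsort(x)
    x, y = x[order], series.richness[order]
    if np.any(np.diff(x) <= 0):
        raise ValueError("duplicate time points")
    interp = Akima1DInterpolator(x, y)
    x_new = np.linspace(x[0], x[-1], series.n)
    y_new = np.clip(interp(x_new), 0.0, None)
    return RichnessSeries(-x_new, y_new, source=series.source + "_akima")


# ---------------------------------------------------------------------------
# Durbin–Watson


def durbin_watson(residuals: Sequence[float]) -> float:
    """d = Σ(e_t − e_{t−1})² / Σ e_t², in [0, 4]; 2 means no lag-1
    autocorrelation."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(np.sum(e ** 2))
    if denom == 0:
        raise ValueError("all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


# ---------------------------------------------------------------------------
# AR(1) GLS growth model


@dataclass
class GrowthFit:
    """Results of an AR(1)-GLS polynomial fit to log(richness + 1)."""

    model: Literal["linear", "quadratic"]
    coefficients: np.ndarray
    stderrs: np.ndarray
    phi: float
    df: int
    dw: float
    loglik: float
    n: int

    @property
    def tvalues(self) -> np.ndarray:
        return self.coefficients / self.stderrs

    @property
    def quad_t(self) -> float | None:
        return float(self.tvalues[2]) if self.model == "quadratic" else None

    @property
    def quad_coef(self) -> float | None:
        return (float(self.coefficients[2]) if self.model == "quadratic"
                else None)

    @property
    def p(self) -> float:
        """Two-sided p of the highest-order coefficient."""
        t = self.tvalues[-1]
        return float(2 * t_dist.sf(abs(t), self.df))

    def summary(self) -> str:
        names = ["intercept", "time", "time^2"][:len(self.coefficients)]
        lines = [
            f"AR(1)-GLS {self.model} fit of log(richness+1) on time",
            f"  n = {self.n}, residual df = {self.df}, "
            f"phi = {self.phi:.4f}, DW(linear OLS) = {self.dw:.3f}",
            f"  log-likelihood = {self.loglik:.3f}",
            f"  {'term':<10}{'coef':>12}{'se':>12}{'t':>9}",
        ]
        for name, c, s, t in zip(names, self.coefficients, self.stderrs,
                                 self.tvalues):
            lines.append(f"  {name:<10}{c:>12.5g}{s:>12.5g}{t:>9.3f}")
        lines.append(f"  p(highest-order term) = {self.p:.4g}")
        return "\n".join(lines)


class GrowthCurveModel:
    """Polynomial trend in log lineage richness with AR(1) errors.

        log(N_t + 1) = b0 + b1*t (+ b2*t^2) + e_t,   e_t = phi*e_{t-1} + u_t

    ``t`` runs *forward* (t = −Ma), so deceleration toward the present is a
    negative quadratic coefficient.  The series must be equally spaced
    (apply :func:`akima_resample` first); phi is estimated by profiled
    restricted maximum likelihood (REML, the default — it debiases phi and
    keeps the t-test close to nominal size at these series lengths) or
    plain ML, with exact (Prais–Winsten) whitening in either case.
    """

    def __init__(self, series: RichnessSeries,
                 order: Literal["linear", "quadratic"] = "linear"):
        if order not in ("linear", "quadratic"):
            raise ValueError(f"unknown order {order!r}")
        if series.n < 10:
            raise ValueError("need at least 10 points")
        if not series.equally_spaced():
            raise ValueError(
                "series is not equally spaced; resample with "
                "akima_resample first")
        self.series = series
        self.order = order
        t = -series.times_ma.astype(float)
        self._t0 = t.mean()          # centred internally for conditioning
        tc = t - self._t0
        cols = [np.ones_like(tc), tc]
        if order == "quadratic":
            cols.append(tc ** 2)
        self.exog = np.column_stack(cols)
        self.endog = np.log1p(np.clip(series.richness, 0.0, None))

    # -- internals ----------------------------------------------------

    def _whiten(self, phi: float) -> tuple[np.ndarray, np.ndarray]:
        y, X = self.endog, self.exog
        c = np.sqrt(1.0 - phi ** 2)
        yw = np.concatenate([[y[0] * c], y[1:] - phi * y[:-1]])
        Xw = np.vstack([X[0] * c, X[1:] - phi * X[:-1]])
        return yw, Xw

    def _profile_rss(self, phi: float) -> float:
        yw, Xw = self._whiten(phi)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        return float(r @ r)

    def _negloglik(self, phi: float) -> float:
        n = len(self.endog)
        rss = self._profile_rss(phi)
        if rss <= 0:
            rss = 1e-300
        return 0.5 * n * np.log(rss / n) - 0.5 * np.log(1.0 - phi ** 2)

    def _negremllik(self, phi: float) -> float:
        n, k = self.exog.shape
        yw, Xw = self._whiten(phi)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        rss = max(float(r @ r), 1e-300)
        _, logdet = np.linalg.slogdet(Xw.T @ Xw)
        return 0.5 * ((n - k) * np.log(rss / (n - k))
                      - np.log(1.0 - phi ** 2) + logdet)

    def fit(self, phi: float | None = None,
            method: Literal["reml", "ml"] = "reml") -> GrowthFit:
        """Estimate the model; pass ``phi`` to fix the AR(1) coefficient
        (``phi=0`` reproduces ordinary least squares)."""
        if phi is None:
            objective = (self._negremllik if method == "reml"
                         else self._negloglik)
            res = minimize_scalar(objective, bounds=(-0.999, 0.999),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            if not res.success:
                raise RuntimeError(
                    f"AR(1) profile likelihood failed: {res.message}")
            phi_hat = float(res.x)
        else:
            if not -1 < phi < 1:
                raise ValueError("|phi| must be < 1")
            phi_hat = float(phi)
        n, k = self.exog.shape
        yw, Xw = self._whiten(phi_hat)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        df = n - k
        sigma2 = rss / df
        cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
        se = np.sqrt(np.diag(cov))
        loglik = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1) + \
            0.5 * np.log(1.0 - phi_hat ** 2)
        # de-centre: report coefficients on the raw t = -Ma scale
        beta_raw, se_raw = self._decentre(beta, cov)
        dw = self._linear_ols_dw()
        return GrowthFit(model=self.order, coefficients=beta_raw,
                         stderrs=se_raw, phi=phi_hat, df=df, dw=dw,
                         loglik=loglik, n=n)

    def _decentre(self, beta: np.ndarray, cov: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Transform coefficients from the centred design tc = t - t0 back
        to raw t, propagating the covariance."""
        t0 = self._t0
        if self.order == "linear":
            A = np.array([[1.0, -t0], [0.0, 1.0]])
        else:
            A = np.array([[1.0, -t0, t0 ** 2],
                          [0.0, 1.0, -2 * t0],
                          [0.0, 0.0, 1.0]])
        beta_raw = A @ beta
        cov_raw = A @ cov @ A.T
        return beta_raw, np.sqrt(np.diag(cov_raw))

    def _linear_ols_dw(self) -> float:
        """Durbin–Watson of the uncorrected ordinary-least-squares *linear*
        fit — the diagnostic that motivates the AR(1) structure."""
        X = self.exog[:, :2]
        beta, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        resid = self.endog - X @ beta
        if np.allclose(resid, 0):
            return 2.0  # perfect fit: no autocorrelation signal
        return durbin_watson(resid)


def fit_gls_ar1(series: RichnessSeries,
                order: Literal["linear", "quadratic"] = "linear",
                phi: float | None = None,
                method: Literal["reml", "ml"] = "reml") -> GrowthFit:
    """Convenience wrapper: build a :class:`GrowthCurveModel` and fit it."""
    return GrowthCurveModel(series, order=order).fit(phi=phi, method=method)


def classify_growth(linear: GrowthFit, quadratic: GrowthFit,
                    alpha: float = 0.05
                    ) -> Literal["exponential_consistent",
                                 "logistic_consistent"]:
    """Logistic growth requires a significant *decelerating* quadratic term
    (negative coefficient on forward-running time); anything else is
    consistent with exponential increase."""
    if linear.model != "linear" or quadratic.model != "quadratic":
        raise ValueError("pass one linear and one quadratic fit")
    if linear.n != quadratic.n:
        raise ValueError("fits are on different series")
    if quadratic.p < alpha and quadratic.quad_coef < 0:
        return "logistic_consistent"
    return "exponential_consistent"


# ---------------------------------------------------------------------------
# plotting


def plot_ltt(series_list: Sequence[RichnessSeries], path: str | Path,
             log_scale: bool = False) -> None:
    """Render lineage-through-time curves (one per series) to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for s in series_list:
        ax.step(s.times_ma, s.richness, where="post", label=s.source)
    ax.set_xlabel("Time (Ma)")
    ax.set_ylabel("Family lineages")
    if log_scale:
        ax.set_yscale("log")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
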