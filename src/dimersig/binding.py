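"""AlphaScreen, dose-response and fluorescence-polarization analytics.

AlphaScreen titrations show a bell-shaped "hook" when two proteins interact
(bead saturation kills the signal at high analyte); the curve maximum I is
normalized against a reference interacting pair via the binding index
``BI = (I - Ineg) / (Iref - Ineg) * 100``.  Inhibitor titrations are summarized
as percent interaction ``(I_cpd / I_DMSO) * 100`` and fitted with a
three-parameter log-logistic model (top fixed at 100, Hill slope 1) for the
IC50.  Fluorescence-polarization series are fitted to the Hill equation
``mP = mp_free + (mp_bound - mp_free) c^n / (kd^n + c^n)``; the fitted
amplitude (mp_bound - mp_free) is proportional to probe occupancy, so the
amplitude ratio of two probes compares how much protein each accommodates.

The fits follow the statsmodels convention: a Model object built from data
whose ``fit()`` returns a Results object with estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from dimersig.simulate import hill_mp, inhibition_percent


@dataclass
class TitrationCurve:
    """Concentration/dilution-indexed AlphaScreen signals with replicates."""

    dilutions: np.ndarray
    signals: np.ndarray  # shape (n_points, n_replicates)

    def __post_init__(self) -> None:
        self.dilutions = np.asarray(self.dilutions, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != self.dilutions.size:
            self.signals = self.signals.T
        if self.dilutions.size < 4:
            raise ValueError("a titration needs at least 4 points")
        if np.any(self.signals < 0):
            raise ValueError("signals must be >= 0")

    @property
    def mean(self) -> np.ndarray:
        return self.signals.mean(axis=1)

    @property
    def sem(self) -> np.ndarray:
        n = self.signals.shape[1]
        if n == 1:
            return np.zeros(self.dilutions.size)
        return self.signals.std(axis=1, ddof=1) / math.sqrt(n)

    @property
    def n_replicates(self) -> int:
        return self.signals.shape[1]

    def to_plate(self, condition: str = "titration") -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.dilutions):
            for r in range(self.n_replicates):
                rows.append({"condition": condition, "conc": d,
                             "signal": self.signals[i, r], "replicate": r + 1})
        return pd.DataFrame(rows)

    @classmethod
    def from_plate(cls, df: pd.DataFrame, condition: str | None = None
                   ) -> "TitrationCurve":
        if condition is not None:
            df = df[df["condition"] == condition]
        wide = df.pivot_table(index="conc", columns="replicate", values="signal")
        return cls(wide.index.to_numpy(), wide.to_numpy())


@dataclass
class DoseResponse:
    """Percent-interaction readouts over strictly increasing doses."""

    doses: np.ndarray
    percent: np.ndarray  # shape (n_doses, n_replicates)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.percent = np.atleast_2d(np.asarray(self.percent, dtype=float))
        if self.percent.shape[0] != self.doses.size:
            self.percent = self.percent.T
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if not np.all(np.isfinite(self.percent)):
            raise ValueError("percent values must be finite")

    @property
    def mean(self) -> np.ndarray:
        return self.percent.mean(axis=1)


@dataclass
class FPSeries:
    """Fluorescence-polarization readings (mP) over protein concentrations.

    ``controls`` may carry the three plate controls: ``free_dna`` (no
    protein, low mP), ``protein`` (saturating protein, high mP) and
    ``competition`` (excess unlabelled probe, low mP).
    """

    concs: np.ndarray
    mp: np.ndarray
    controls: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        self.mp = np.asarray(self.mp, dtype=float)
        if self.concs.shape != self.mp.shape:
            raise ValueError("concs and mp must have the same shape")


# ---------------------------------------------------------------------------
# Hook-curve characterization

def find_hook_maximum(curve: TitrationCurve) -> tuple[float, float]:
    """Locate the top of the hook: (I, dilution at the maximum mean signal).

    Ties across dilutions resolve to the lowest dilution with a warning.  A
    maximum at the final (highest-concentration) point means the descending
    limb of the hook was never reached; a "no hook detected" warning is
    issued and the maximum returned as-is.
    """
    means = curve.mean
    i_max = int(np.argmax(means))
    ties = np.flatnonzero(means == means[i_max])
    if ties.size > 1:
        warnings.warn(f"maximum signal tied across {ties.size} dilutions; "
                      "returning the lowest", stacklevel=2)
        i_max = int(ties[0])
    if i_max == means.size - 1:
        warnings.warn("maximum at the highest concentration: no hook detected",
                      stacklevel=2)
    return float(means[i_max]), float(curve.dilutions[i_max])


def binding_index(I: float, Ineg: float, Iref: float) -> float:
    """BI = (I - Ineg) / (Iref - Ineg) * 100; 100 at the reference pair, 0 at
    background.  May exceed 100 if the pair outsignals the reference."""
    if Iref <= Ineg:
        raise ValueError("degenerate reference: Iref must exceed Ineg")
    return (I - Ineg) / (Iref - Ineg) * 100.0


def classify_interaction(curve: TitrationCurve, fold_threshold: float = 3.0,
                         drop_fraction: float = 0.2) -> str:
    """Call a titration positive (bell-shaped hook) or negative (flat).

    Positive requires both a peak at least ``fold_threshold`` times the
    minimum mean signal and a descent: the mean at the highest concentration
    no more than ``(1 - drop_fraction)`` of the peak.  A monotone rise (no
    descending limb) is negative.
    """
    means = curve.mean
    I = float(means.max())
    Ineg = float(means.min())
    rises = Ineg > 0 and I >= fold_threshold * Ineg
    falls = means[-1] <= (1.0 - drop_fraction) * I
    return "positive" if (rises and falls) else "negative"


def percent_interaction(i_cpd: float, i_dmso: float) -> float:
    """Percent of the vehicle-control signal retained: (I_cpd / I_DMSO) * 100."""
    if i_dmso <= 0:
        raise ValueError("I_DMSO must be positive")
    return i_cpd / i_dmso * 100.0


# ---------------------------------------------------------------------------
# IC50 dose-response model

class IC50Model:
    """Three-parameter log-logistic inhibition model.

    Default parameterization fixes top = 100% and Hill slope = 1, fitting
    {ic50, bottom}: ``y = bottom + (100 - bottom) / (1 + dose/ic50)``.  The
    alternative ``variant="slope"`` fixes bottom = 0 and fits {ic50, slope}:
    ``y = 100 / (1 + (dose/ic50)^slope)``.
    """

    def __init__(self, dr: DoseResponse, variant: str = "three_parameter"):
        if variant not in ("three_parameter", "slope"):
            raise ValueError("variant must be 'three_parameter' or 'slope'")
        self.data = dr
        self.variant = variant
        if dr.doses.size < 5:
            warnings.warn("fewer than 5 doses; IC50 poorly constrained",
                          stacklevel=2)
        span = math.log10(dr.doses.max() / dr.doses.min())
        if span < 2:
            warnings.warn(f"doses span only {span:.1f} decades (< 2); IC50 "
                          "poorly constrained", stacklevel=2)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col: str = "conc",
                       value_col: str = "signal", **kw) -> "IC50Model":
        wide = df.pivot_table(index=dose_col, columns=df.get("replicate", 1),
                              values=value_col)
        return cls(DoseResponse(wide.index.to_numpy(), wide.to_numpy()), **kw)

    def predict(self, params, doses=None) -> np.ndarray:
        d = self.data.doses if doses is None else np.asarray(doses, float)
        log_ic50, other = params
        ic50 = 10.0 ** log_ic50
        if self.variant == "three_parameter":
            return inhibition_percent(d, ic50, other)
        return 100.0 / (1.0 + (d / ic50) ** other)

    def fit(self) -> "IC50Results":
        y = self.data.mean
        if y.max() - y.min() < 1.0:
            raise ValueError("no dose dependence: response is flat")
        d = self.data.doses
        # initial ic50: dose whose mean is nearest the half-span
        half = 0.5 * (y.max() + y.min())
        ic50_0 = float(d[np.argmin(np.abs(y - half))])
        other_0 = max(0.0, min(99.0, float(y.min()))) \
            if self.variant == "three_parameter" else 1.0
        bounds = ((math.log10(d.min()) - 3, 0.0),
                  (math.log10(d.max()) + 3,
                   100.0 if self.variant == "three_parameter" else 10.0))
        sol = least_squares(lambda p: self.predict(p) - y,
                            (math.log10(ic50_0), other_0),
                            bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise RuntimeError(f"IC50 fit failed: {sol.message}")
        log_ic50, other = sol.x
        resid = sol.fun
        n, p = y.size, 2
        rss = float(np.sum(resid ** 2))
        if n > p and rss > 0:
            ci = self._profile_ci(y, float(log_ic50), rss, n, p)
        else:
            ci = (10.0 ** log_ic50, 10.0 ** log_ic50)
        fitted_amp = 100.0 - other if self.variant == "three_parameter" else 100.0
        if fitted_amp < 1.0:
            raise ValueError("no dose dependence: fitted amplitude is flat")
        return IC50Results(
            ic50=float(10.0 ** log_ic50), top=100.0,
            bottom=float(other) if self.variant == "three_parameter" else 0.0,
            slope=1.0 if self.variant == "three_parameter" else float(other),
            ic50_ci=ci, rss=rss, n_obs=n, variant=self.variant, model=self)

    def _profile_ci(self, y, log_ic50_hat: float, rss_min: float, n: int,
                    p: int, level: float = 0.95) -> tuple[float, float]:
        """Profile-likelihood CI for IC50 via an F-test threshold on the SSR."""
        crit = rss_min * (1.0 + stats.f.ppf(level, 1, n - p) / (n - p))

        def profile_rss(log_ic50: float) -> float:
            sol = least_squares(
                lambda q: self.predict((log_ic50, q[0])) - y,
                [0.0 if self.variant == "three_parameter" else 1.0],
                bounds=([0.0], [100.0 if self.variant == "three_parameter" else 10.0]))
            return float(np.sum(sol.fun ** 2))

        grid = np.union1d(np.linspace(log_ic50_hat - 2, log_ic50_hat + 2, 161),
                          [log_ic50_hat])
        rss_profile = np.array([profile_rss(g) for g in grid])
        inside = grid[rss_profile <= crit]
        if inside.size == 0:
            return (10.0 ** log_ic50_hat, 10.0 ** log_ic50_hat)
        return (float(10.0 ** inside.min()), float(10.0 ** inside.max()))


@dataclass
class IC50Results:
    """Fitted IC50 with profile confidence interval and goodness-of-fit."""

    ic50: float
    top: float
    bottom: float
    slope: float
    ic50_ci: tuple[float, float]
    rss: float
    n_obs: int
    variant: str
    model: IC50Model | None = field(default=None, repr=False)

    def predict(self, doses) -> np.ndarray:
        if self.variant == "three_parameter":
            return inhibition_percent(doses, self.ic50, self.bottom)
        return 100.0 / (1.0 + (np.asarray(doses, float) / self.ic50) ** self.slope)

    def summary(self) -> str:
        lo, hi = self.ic50_ci
        return "\n".join([
            f"IC50 dose-response fit ({self.variant}; top fixed at 100%)",
            f"  IC50:    {self.ic50:.4g}   95% CI [{lo:.4g}, {hi:.4g}]",
            f"  bottom:  {self.bottom:.3f} %    Hill slope: {self.slope:.3f}",
            f"  RSS: {self.rss:.4g} over {self.n_obs} dose points",
        ])

    def plot(self, ax=None):  # pragma: no cover - plotting convenience
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        d = self.model.data.doses
        ax.semilogx(d, self.model.data.mean, "o", label="data")
        grid = np.geomspace(d.min(), d.max(), 200)
        ax.semilogx(grid, self.predict(grid), "-",
                    label=f"fit (IC50 = {self.ic50:.3g})")
        ax.set_xlabel("dose")
        ax.set_ylabel("% interaction")
        ax.legend()
        return ax


def fit_ic50(dr: DoseResponse, variant: str = "three_parameter") -> IC50Results:
    """Fit the three-parameter inhibition model to a dose-response."""
    return IC50Model(dr, variant=variant).fit()


# ---------------------------------------------------------------------------
# Hill fluorescence-polarization model

class HillBindingModel:
    """Hill binding isotherm for fluorescence-polarization series.

    ``mP(c) = mp_free + (mp_bound - mp_free) c^n / (kd^n + c^n)``.  The free
    mP is initialized from the free-DNA control when present; the competition
    control serves as a sanity floor (a fitted mp_free far below it triggers
    a warning).
    """

    def __init__(self, series: FPSeries, noise_tolerance_mp: float = 10.0):
        self.data = series
        self.noise_tolerance_mp = noise_tolerance_mp
        if series.concs.size < 5:
            warnings.warn("fewer than 5 concentrations; Hill fit poorly "
                          "constrained", stacklevel=2)
        drops = np.diff(series.mp)
        if np.any(drops < -noise_tolerance_mp):
            warnings.warn("mP series is non-monotone beyond noise tolerance",
                          stacklevel=2)

    def fit(self) -> "HillBindingResults":
        c, y = self.data.concs, self.data.mp
        span = float(y.max() - y.min())
        if span < 1.0:
            raise ValueError("no binding amplitude: mP span below 1 mP")
        free0 = float(self.data.controls.get("free_dna", y.min()))
        bound0 = float(self.data.controls.get("protein", y.max()))
        pos = c[c > 0]
        half = free0 + 0.5 * (bound0 - free0)
        kd0 = float(pos[np.argmin(np.abs(y[c > 0] - half))]) if pos.size else 1.0

        def resid(p):
            log_kd, n, mp_free, mp_bound = p
            return hill_mp(c, 10.0 ** log_kd, n, mp_free, mp_bound) - y

        lb = [math.log10(max(pos.min(), 1e-12)) - 4, 0.2,
              y.min() - 5 * span, y.min() - 5 * span]
        ub = [math.log10(pos.max()) + 4, 6.0, y.max() + 5 * span, y.max() + 5 * span]
        sol = least_squares(resid, [math.log10(kd0), 1.0, free0, bound0],
                            bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise RuntimeError(f"Hill fit failed: {sol.message}")
        log_kd, n, mp_free, mp_bound = sol.x
        if mp_bound <= mp_free:
            raise ValueError("no binding amplitude: fitted mp_bound <= mp_free")
        comp = self.data.controls.get("competition")
        if comp is not None and mp_free < comp - 3 * self.noise_tolerance_mp:
            warnings.warn("fitted mp_free far below the competition control",
                          stacklevel=2)
        # asymptotic standard errors from the Jacobian
        dof = max(c.size - 4, 1)
        s2 = float(np.sum(sol.fun ** 2)) / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            perr = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            perr = np.full(4, float("nan"))
        return HillBindingResults(
            kd=float(10.0 ** log_kd), hill_n=float(n), mp_free=float(mp_free),
            mp_bound=float(mp_bound),
            kd_se=float(10.0 ** log_kd * math.log(10) * perr[0]),
            hill_n_se=float(perr[1]), mp_free_se=float(perr[2]),
            mp_bound_se=float(perr[3]), rss=float(np.sum(sol.fun ** 2)),
            n_obs=int(c.size), model=self)


@dataclass
class HillBindingResults:
    """Fitted Hill binding parameters with asymptotic standard errors."""

    kd: float
    hill_n: float
    mp_free: float
    mp_bound: float
    kd_se: float
    hill_n_se: float
    mp_free_se: float
    mp_bound_se: float
    rss: float
    n_obs: int
    model: HillBindingModel | None = field(default=None, repr=False)

    @property
    def amplitude(self) -> float:
        """Binding amplitude mp_bound - mp_free, proportional to occupancy."""
        return self.mp_bound - self.mp_free

    @property
    def amplitude_se(self) -> float:
        return math.hypot(self.mp_free_se, self.mp_bound_se)

    def predict(self, concs) -> np.ndarray:
        return hill_mp(concs, self.kd, self.hill_n, self.mp_free, self.mp_bound)

    def summary(self) -> str:
        return "\n".join([
            "Hill binding fit (fluorescence polarization)",
            f"  Kd:       {self.kd:.4g} ± {self.kd_se:.2g}",
            f"  Hill n:   {self.hill_n:.3f} ± {self.hill_n_se:.2g}",
            f"  mp_free:  {self.mp_free:.2f} ± {self.mp_free_se:.2g} mP",
            f"  mp_bound: {self.mp_bound:.2f} ± {self.mp_bound_se:.2g} mP",
            f"  amplitude (occupancy): {self.amplitude:.2f} mP",
            f"  RSS: {self.rss:.4g} over {self.n_obs} points",
        ])

    def plot(self, ax=None):  # pragma: no cover - plotting convenience
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        c = self.model.data.concs
        ax.plot(c, self.model.data.mp, "o", label="data")
        grid = np.linspace(0, c.max(), 200)
        ax.plot(grid, self.predict(grid), "-",
                label=f"Hill fit (Kd = {self.kd:.3g})")
        ax.set_xlabel("protein concentration")
        ax.set_ylabel("mP")
        ax.legend()
        return ax


def fit_hill_fp(series: FPSeries) -> HillBindingResults:
    """Fit the Hill binding model to a fluorescence-polarization series."""
    return HillBindingModel(series).fit()


def compare_occupancy(fit_a: HillBindingResults,
                      fit_b: HillBindingResults) -> tuple[float, float]:
    """Amplitude ratio of two FP fits with propagated uncertainty.

    Returns (ratio, se) where ratio = amplitude_a / amplitude_b.  A ratio of
    ~2 means probe A accommodates roughly twice the protein of probe B.
    """
    if fit_b.amplitude == 0:
        raise ValueError("denominator fit has zero binding amplitude")
    ratio = fit_a.amplitude / fit_b.amplitude
    se = abs(ratio) * math.hypot(
        fit_a.amplitude_se / fit_a.amplitude if fit_a.amplitude else 0.0,
        fit_b.amplitude_se / fit_b.amplitude)
    return ratio, se
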