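"""Multi-component Gaussian decomposition of O-D stretch FTIR spectra.

An O-D stretch band of dilute HDO is modelled as a sum of 3-4 Gaussian
components plus a low-order polynomial baseline, fitted by bounded
trust-region nonlinear least squares (lmfit).  The pure-water band at low
temperature resolves into one dominant narrow peak flanked by two weak
sidebands of similar width; DMSO mixtures show an additional broad
(~120 cm^-1 FWHM) high-frequency component whose area grows with DMSO
content.  The temperature series utilities track component parameters
across a melting transition and score its sharpness.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lmfit import Parameters, minimize

FOUR_LN2 = 4.0 * math.log(2.0)
#: area of a unit-amplitude Gaussian of unit FWHM
AREA_FACTOR = math.sqrt(math.pi / FOUR_LN2)

DEFAULT_WINDOW = (2300.0, 2700.0)
#: CO2 rovibrational artifact band, excludable from the fit window
CO2_BAND = (2330.0, 2370.0)


@dataclass
class Spectrum:
    """Wavenumber/absorbance series with free-form metadata
    (``temperature_C``, ``wt_dmso``, ...)."""

    wavenumber: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumber.shape != self.absorbance.shape:
            raise ValueError("wavenumber and absorbance must have equal length")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    def window(self, lo: float, hi: float, exclude: tuple[float, float] | None = None) -> "Spectrum":
        mask = (self.wavenumber >= lo) & (self.wavenumber <= hi)
        if exclude is not None:
            mask &= ~((self.wavenumber >= exclude[0]) & (self.wavenumber <= exclude[1]))
        return Spectrum(self.wavenumber[mask], self.absorbance[mask], dict(self.metadata))


@dataclass
class GaussianComponent:
    center: float
    fwhm: float
    amplitude: float

    @property
    def area(self) -> float:
        return self.amplitude * self.fwhm * AREA_FACTOR

    def __call__(self, nu: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-FOUR_LN2 * (nu - self.center) ** 2 / self.fwhm**2)


@dataclass
class GaussianFit:
    """Converged sum-of-Gaussians decomposition, components sorted by center."""

    components: list[GaussianComponent]
    baseline: np.ndarray  # polynomial coefficients, ascending order
    residual_rms: float
    window: tuple[float, float]

    def model(self, nu: np.ndarray) -> np.ndarray:
        out = np.polynomial.polynomial.polyval(nu, self.baseline)
        for comp in self.components:
            out = out + comp(nu)
        return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Two-column CSV (wavenumber, absorbance); ``# key=value`` header lines
    become metadata (numeric values parsed)."""
    meta: dict = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                try:
                    meta[k.strip()] = float(v)
                except ValueError:
                    meta[k.strip()] = v.strip()
            continue
        parts = line.replace(",", " ").split()
        if parts[0].lower() in ("wavenumber", "wavenumber_cm1"):
            continue
        rows.append((float(parts[0]), float(parts[1])))
    rows.sort()
    nu, ab = zip(*rows)
    return Spectrum(np.array(nu), np.array(ab), meta)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in spectrum.metadata.items():
            fh.write(f"# {k}={v}\n")
        fh.write("wavenumber,absorbance\n")
        for nu, ab in zip(spectrum.wavenumber, spectrum.absorbance):
            fh.write(f"{nu:.6g},{ab:.8g}\n")
    return path


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _default_init(nu: np.ndarray, ab: np.ndarray, n_components: int) -> list[tuple[float, float, float]]:
    """Dominant peak at the global maximum, sidebands at -/+ 40 and 80 cm^-1
    (narrow), and for 4 components a broad band near 2470 cm^-1."""
    base = float(np.percentile(ab, 5))
    peak = float(nu[int(np.argmax(ab))])
    amp = float(ab.max() - base)
    comps = [
        (peak, 30.0, amp),
        (peak - 60.0, 30.0, 0.25 * amp),
        (peak + 60.0, 30.0, 0.25 * amp),
    ]
    if n_components == 4:
        comps.append((2470.0 if nu.min() < 2470.0 < nu.max() else peak + 40.0, 120.0, 0.3 * amp))
    return comps


def _residual(params: Parameters, nu: np.ndarray, ab: np.ndarray, n: int, nbase: int) -> np.ndarray:
    model = np.zeros_like(nu)
    for k in range(n):
        model += params[f"a{k}"].value * np.exp(
            -FOUR_LN2 * (nu - params[f"c{k}"].value) ** 2 / params[f"w{k}"].value ** 2
        )
    coeffs = [params[f"b{j}"].value for j in range(nbase)]
    model += np.polynomial.polynomial.polyval(nu, np.array(coeffs))
    return model - ab


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the best attempt found."""

    def __init__(self, message: str, best: GaussianFit | None = None):
        super().__init__(message)
        self.best = best


def fit_gaussians(
    spectrum: Spectrum,
    n_components: int = 4,
    window: tuple[float, float] = DEFAULT_WINDOW,
    init: list[tuple[float, float, float]] | None = None,
    baseline: str = "linear",
    exclude_co2: bool = False,
    fwhm_bounds: tuple[float, float] = (2.0, 400.0),
    max_restarts: int = 5,
    seed: int = 0,
) -> GaussianFit:
    """Fit ``n_components`` Gaussians plus a polynomial baseline to the
    windowed spectrum.

    Bounds keep amplitudes non-negative, FWHM within ``fwhm_bounds`` and
    centers inside the window.  Deterministic given ``init``; otherwise the
    default initialization is refined by up to ``max_restarts`` jittered
    restarts under a fixed seed, keeping the best residual.
    """
    if n_components not in (3, 4):
        raise ValueError("n_components must be 3 or 4")
    sub = spectrum.window(*window, exclude=CO2_BAND if exclude_co2 else None)
    if len(sub.wavenumber) < 3 * n_components + 3:
        raise ValueError("window contains too few points for the model")
    nbase = {"constant": 1, "linear": 2, "quadratic": 3}[baseline]
    start = init if init is not None else _default_init(sub.wavenumber, sub.absorbance, n_components)
    if len(start) != n_components:
        raise ValueError("init length must equal n_components")

    rng = np.random.default_rng(seed)
    best_result = None
    attempts = [start] + [
        [
            (
                c + rng.normal(0, 10.0),
                float(np.clip(w * rng.lognormal(0, 0.2), *fwhm_bounds)),
                a * rng.lognormal(0, 0.2),
            )
            for c, w, a in start
        ]
        for _ in range(max_restarts)
    ]
    for guess in attempts:
        params = Parameters()
        for k, (c, w, a) in enumerate(guess):
            params.add(f"c{k}", value=float(np.clip(c, *window)), min=window[0], max=window[1])
            params.add(f"w{k}", value=float(np.clip(w, *fwhm_bounds)), min=fwhm_bounds[0], max=fwhm_bounds[1])
            params.add(f"a{k}", value=max(a, 1e-12), min=0.0)
        for j in range(nbase):
            params.add(f"b{j}", value=0.0)
        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                result = minimize(
                    _residual, params, args=(sub.wavenumber, sub.absorbance, n_components, nbase),
                    method="least_squares", calc_covar=False,
                )
        except Exception:
            continue
        if best_result is None or result.chisqr < best_result.chisqr:
            best_result = result
        if init is not None:
            break  # deterministic single-shot when the caller supplies init
    if best_result is None:
        raise FitError("all fit attempts failed")

    p = best_result.params
    comps = sorted(
        (
            GaussianComponent(
                center=p[f"c{k}"].value, fwhm=p[f"w{k}"].value, amplitude=p[f"a{k}"].value
            )
            for k in range(n_components)
        ),
        key=lambda c: c.center,
    )
    coeffs = np.array([p[f"b{j}"].value for j in range(nbase)])
    rms = float(np.sqrt(np.mean(best_result.residual**2)))
    fit = GaussianFit(components=comps, baseline=coeffs, residual_rms=rms, window=window)
    if not best_result.success:
        raise FitError("fit did not converge", best=fit)
    return fit


def peak_metrics(fit: GaussianFit) -> list[dict]:
    """Per-component center, FWHM, amplitude, area and area fraction
    (baseline excluded; fractions sum to 1)."""
    total = sum(c.area for c in fit.components)
    return [
        {
            "center": c.center,
            "fwhm": c.fwhm,
            "amplitude": c.amplitude,
            "area": c.area,
            "area_fraction": c.area / total if total > 0 else float("nan"),
        }
        for c in fit.components
    ]


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------

def temperature_series(
    spectra: list[Spectrum],
    n_components: int = 4,
    window: tuple[float, float] = DEFAULT_WINDOW,
    link: bool = True,
    **fit_kwargs,
) -> tuple[list[GaussianFit | None], "pd.DataFrame"]:
    """Fit every spectrum of a temperature series (sorted by the
    ``temperature_C`` metadata, auto-sorting with a warning if needed) and
    tabulate component center/FWHM/area against temperature.

    With ``link`` the previous temperature's solution warm-starts the next
    fit, which keeps component identity stable across the series.  A fit
    failure at one temperature is recorded as None and the series continues.
    """
    import warnings

    import pandas as pd

    temps = [s.metadata.get("temperature_C") for s in spectra]
    if any(t is None for t in temps):
        raise ValueError("every spectrum needs temperature_C metadata")
    if list(temps) != sorted(temps):
        warnings.warn("spectra not sorted by temperature; sorting", stacklevel=2)
        spectra = sorted(spectra, key=lambda s: s.metadata["temperature_C"])
        temps = [s.metadata["temperature_C"] for s in spectra]

    fits: list[GaussianFit | None] = []
    rows = []
    prev: GaussianFit | None = None
    for spec in spectra:
        init = None
        if link and prev is not None:
            init = [(c.center, c.fwhm, c.amplitude) for c in prev.components]
        try:
            fit = fit_gaussians(spec, n_components=n_components, window=window, init=init, **fit_kwargs)
        except FitError as exc:
            fit = exc.best  # may be None
        fits.append(fit)
        if fit is not None:
            prev = fit
            for k, c in enumerate(fit.components):
                rows.append(
                    {
                        "temperature_C": spec.metadata["temperature_C"],
                        "component": k,
                        "center": c.center,
                        "fwhm": c.fwhm,
                        "amplitude": c.amplitude,
                        "area": c.area,
                    }
                )
    return fits, pd.DataFrame(rows)


def transition_sharpness(temperatures: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Locate a phase transition in a parameter-vs-temperature trend and
    score its sharpness.

    The transition temperature is the midpoint of the step with the largest
    absolute first difference; the sharpness score is that difference
    divided by the median absolute difference of the remaining steps, so a
    clean step function scores high and a uniform ramp scores ~1.
    """
    t = np.asarray(temperatures, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 temperatures")
    order = np.argsort(t)
    t, v = t[order], v[order]
    diffs = np.abs(np.diff(v))
    if np.allclose(diffs, 0):
        return float("nan"), float("nan")
    k = int(np.argmax(diffs))
    rest = np.delete(diffs, k)
    med = float(np.median(rest))
    sharpness = float(diffs[k] / med) if med > 0 else float("inf")
    return float(0.5 * (t[k] + t[k + 1])), sharpness
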