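"""Common spatial patterns with a rhythm filter bank.

CSP finds spatial filters w maximizing the variance ratio
J(w) = w' C1 w / w' C2 w between two movement classes, solved as a
generalized eigenproblem: whiten the joint covariance C1 + C2, then
eigendecompose the whitened C1. Filters are normalized so that
w' (C1 + C2) w = 1; the generalized eigenvalue lambda = w' C1 w lies in
(0, 1), with lambda near 1 favouring class 1 and near 0 class 2. The
model keeps the 6 filters with the largest and the 6 with the smallest
eigenvalues (12 components), in that frozen order — the downstream CNN
is not permutation invariant.

Features: each window is projected through the 12 spatial filters, each
component trace is band-passed into the 6 canonical rhythms (delta,
alpha, beta, gamma, high gamma, super high gamma), and each
(component, rhythm) trace is reduced to its log centered mean power,
giving a 12 x 6 feature map per window. By default one broadband CSP is
fitted and the filter bank is applied to the component traces; the
classic per-band variant (a separate CSP per rhythm) is available with
``band_first=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .core import Montage
from .exceptions import InvalidArgumentError, NumericalError
from .preprocess import WindowSet

__all__ = [
    "BandSpec",
    "CSPModel",
    "FeatureMap",
    "FBCSPModel",
    "class_covariance",
    "fit_csp",
    "apply_filter_bank",
    "log_power",
    "featurize",
    "export_patterns_csv",
]

LOG_POWER_EPS = 1e-12
RIDGE_SCALE = 1e-6

DEFAULT_BANDS = (
    ("delta", (1.0, 4.0)),
    ("alpha", (8.0, 12.0)),
    ("beta", (12.0, 30.0)),
    ("gamma", (30.0, 50.0)),
    ("high_gamma", (75.0, 115.0)),
    ("super_high_gamma", (125.0, 150.0)),
)


@dataclass(frozen=True)
class BandSpec:
    """Named rhythm bands and the Butterworth order of the filter bank."""

    bands: tuple = DEFAULT_BANDS
    filter_order: int = 4

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def edges(self):
        return [edges for _, edges in self.bands]

    @property
    def names(self):
        return [name for name, _ in self.bands]

    def validate(self, fs: float) -> None:
        for name, (lo, hi) in self.bands:
            if not 0 < lo < hi:
                raise InvalidArgumentError(f"band {name!r}: need 0 < low < high")
            if hi >= fs / 2:
                raise InvalidArgumentError(
                    f"band {name!r} upper edge {hi} Hz >= Nyquist {fs / 2} Hz"
                )


@dataclass
class CSPModel:
    """Fitted CSP spatial filters for one class pair.

    W is channels x C (filters in columns); patterns is C x channels
    (rows are the corresponding activation patterns, the pseudo-inverse
    of the selected filters); eigenvalues is length C ordered
    [largest..., smallest...].
    """

    W: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    class_pair: tuple
    n_components: int


@dataclass
class FeatureMap:
    """windows x components x rhythms log-power tensor with labels."""

    values: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    run_ids: np.ndarray
    band_names: list = field(default_factory=list)


def class_covariance(windows: WindowSet, label) -> np.ndarray:
    """Average trace-normalized spatial covariance of one class's windows.

    Each window's channel covariance is normalized to unit trace before
    averaging (scale invariance across windows), and a small ridge
    proportional to the mean diagonal is added for conditioning.
    """
    mask = windows.labels == label
    if not np.any(mask):
        raise InvalidArgumentError(f"no windows with label {label!r}")
    x = windows.data[mask]
    xc = x - x.mean(axis=2, keepdims=True)
    covs = np.einsum("wct,wdt->wcd", xc, xc) / (x.shape[2] - 1 if x.shape[2] > 1 else 1)
    traces = np.trace(covs, axis1=1, axis2=2)
    traces[traces == 0] = 1.0
    c = (covs / traces[:, None, None]).mean(axis=0)
    ridge = RIDGE_SCALE * np.mean(np.diag(c))
    return c + ridge * np.eye(c.shape[0])


def fit_csp(c1: np.ndarray, c2: np.ndarray, n_components: int = 12,
            class_pair=(1, 2)) -> CSPModel:
    """Solve the CSP generalized eigenproblem for a class pair.

    Whitens C1 + C2 and eigendecomposes the whitened C1; returned filters
    satisfy w' (C1 + C2) w = 1. Keeps ceil(n/2) filters with the largest
    and floor(n/2) with the smallest generalized eigenvalues.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 2 or c1.shape[0] != c1.shape[1]:
        raise InvalidArgumentError("C1 and C2 must be square matrices of equal shape")
    n_ch = c1.shape[0]
    if not 1 <= n_components <= n_ch:
        raise InvalidArgumentError("n_components must be in 1..n_channels")
    joint = c1 + c2
    evals, evecs = sla.eigh(joint)
    if np.any(evals <= 0):
        raise NumericalError("joint covariance C1 + C2 is not positive definite")
    whitener = evecs @ np.diag(evals ** -0.5) @ evecs.T
    s1 = whitener @ c1 @ whitener
    lam, v = sla.eigh((s1 + s1.T) / 2.0)
    order = np.argsort(lam)[::-1]  # descending: class-1-favouring first
    lam, v = lam[order], v[:, order]
    w_full = whitener @ v

    n_hi = (n_components + 1) // 2
    n_lo = n_components - n_hi
    sel = list(range(n_hi)) + list(range(n_ch - n_lo, n_ch))
    w = w_full[:, sel]
    lam_sel = lam[sel]
    # sign convention: make the largest-magnitude coefficient positive
    signs = np.sign(w[np.argmax(np.abs(w), axis=0), np.arange(w.shape[1])])
    signs[signs == 0] = 1.0
    w = w * signs
    patterns = np.linalg.pinv(w)
    return CSPModel(w, patterns, lam_sel, tuple(class_pair), n_components)


def apply_filter_bank(component_signals: np.ndarray, bands: BandSpec,
                      fs: float) -> np.ndarray:
    """Zero-phase band-pass each component trace into every rhythm band.

    Input windows x components x samples; output windows x components x
    n_bands x samples.
    """
    bands.validate(fs)
    x = np.asarray(component_signals, dtype=float)
    out = np.empty(x.shape[:2] + (bands.n_bands,) + x.shape[2:])
    for r, (lo, hi) in enumerate(bands.edges):
        sos = sps.butter(bands.filter_order, [lo, hi], btype="bandpass",
                         fs=fs, output="sos")
        out[:, :, r] = sps.sosfiltfilt(sos, x, axis=-1)
    return out


def log_power(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Log centered mean power: log(mean((x - mean(x))^2) + eps)."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=axis, keepdims=True)
    return np.log(np.mean(centered ** 2, axis=axis) + LOG_POWER_EPS)


def featurize(windows: WindowSet, csp: CSPModel, bands: BandSpec,
              fs: float) -> FeatureMap:
    """Project windows through the CSP filters, band-filter the component
    traces, and reduce each trace to its log power: windows x C x R."""
    comp = np.einsum("nct,ck->nkt", windows.data, csp.W)
    banded = apply_filter_bank(comp, bands, fs)
    values = log_power(banded, axis=-1)
    return FeatureMap(values, windows.labels.copy(), windows.trial_ids.copy(),
                      windows.run_ids.copy(), bands.names)


@dataclass
class FBCSPModel:
    """Fitted FBCSP featurizer for one class pair.

    ``band_first=False`` (default): one broadband CSP, then the filter
    bank on the component traces. ``band_first=True``: classic FBCSP —
    band-pass the raw windows first and fit one CSP per rhythm; column r
    of the feature map then comes from band r's own CSP.
    """

    bands: BandSpec
    fs: float
    n_components: int = 12
    band_first: bool = False
    csp: CSPModel | None = None
    per_band_csp: list | None = None
    class_pair: tuple | None = None

    def fit(self, windows_train: WindowSet, class_pair) -> "FBCSPModel":
        a, b = class_pair
        self.class_pair = (a, b)
        if not self.band_first:
            c1 = class_covariance(windows_train, a)
            c2 = class_covariance(windows_train, b)
            self.csp = fit_csp(c1, c2, self.n_components, (a, b))
            return self
        self.per_band_csp = []
        banded = apply_filter_bank(windows_train.data, self.bands, self.fs)
        for r in range(self.bands.n_bands):
            ws = WindowSet(banded[:, :, r], windows_train.labels,
                           windows_train.trial_ids, windows_train.run_ids,
                           windows_train.window_len, windows_train.step)
            c1 = class_covariance(ws, a)
            c2 = class_covariance(ws, b)
            self.per_band_csp.append(fit_csp(c1, c2, self.n_components, (a, b)))
        return self

    def transform(self, windows: WindowSet) -> FeatureMap:
        if not self.band_first:
            if self.csp is None:
                raise InvalidArgumentError("model is not fitted")
            return featurize(windows, self.csp, self.bands, self.fs)
        if self.per_band_csp is None:
            raise InvalidArgumentError("model is not fitted")
        banded = apply_filter_bank(windows.data, self.bands, self.fs)
        cols = []
        for r, csp in enumerate(self.per_band_csp):
            comp = np.einsum("nct,ck->nkt", banded[:, :, r], csp.W)
            cols.append(log_power(comp, axis=-1))
        values = np.stack(cols, axis=2)
        return FeatureMap(values, windows.labels.copy(), windows.trial_ids.copy(),
                          windows.run_ids.copy(), self.bands.names)


def export_patterns_csv(csp: CSPModel, montage: Montage, path,
                        component: int = 0) -> None:
    """Write one CSP activation pattern as (x_mm, y_mm, weight) rows for
    topography plotting."""
    import pandas as pd

    if not 0 <= component < csp.patterns.shape[0]:
        raise InvalidArgumentError("component index out of range")
    pd.DataFrame({
        "x_mm": montage.coords[:, 0],
        "y_mm": montage.coords[:, 1],
        "weight": csp.patterns[component],
    }).to_csv(path, index=False)
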