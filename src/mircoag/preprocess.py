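"""Scatter corrections and WinISI-coded derivative/smoothing treatments.

Every operation is exposed both as a scikit-learn transformer (composable in a
``sklearn.pipeline.Pipeline``) and as a thin function over :class:`Spectra`.

Scatter corrections
-------------------
SNV
    Standard normal variate: each spectrum is centred and scaled to unit
    sample standard deviation (``ddof=1``), suppressing particle-size effects.
Detrend
    Residual of an ordinary least-squares fit of each spectrum on
    ``{1, w, w^2}`` where ``w`` is the wavenumber axis; removes linear and
    quadratic baseline curvature.
SNV+D
    SNV followed by detrending.
MSC
    Multiplicative scatter correction: each spectrum ``x`` is regressed on a
    reference spectrum (``x ~ a + b*ref``, the reference being the calibration
    mean unless supplied) and corrected to ``(x - a)/b``.

Math treatments
---------------
A 4-tuple code ``(d, gap, s1, s2)``: running-mean smoothing over ``s1``
points, then a gap difference applied ``d`` times (the derivative at a point
is the difference of the series across a gap of ``gap`` points, which after
the first smoothing equals the difference of segment averages), then a second
running-mean smoothing over ``s2`` points.  ``(0,0,1,1)`` is the identity.
Only indices where every window fits are kept -- no padding or extrapolation
-- and the wavenumber axis is trimmed consistently (window-centre
wavenumbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

from .data_model import Spectra, WavenumberAxis

__all__ = [
    "PreprocessSpec",
    "SNV",
    "Detrend",
    "SNVDetrend",
    "MSC",
    "GapSegmentDerivative",
    "make_preprocess_pipeline",
    "snv",
    "detrend",
    "snv_detrend",
    "msc",
    "math_treatment",
    "apply_preprocess",
]

SCATTER_CHOICES = ("none", "snv", "detrend", "snv+d", "msc")
#: Math-treatment grid exercised in the model sweep: (derivative, gap, smooth1, smooth2).
MATH_GRID = ((0, 0, 1, 1), (1, 4, 4, 1), (1, 8, 8, 1), (2, 5, 5, 1), (2, 10, 10, 1))

_SCATTER_ALIASES = {
    "none": "none",
    "snv": "snv",
    "d": "detrend",
    "detrend": "detrend",
    "snv+d": "snv+d",
    "snvd": "snv+d",
    "msc": "msc",
}


@dataclass(frozen=True)
class PreprocessSpec:
    """A scatter-correction name plus a ``(d, gap, s1, s2)`` treatment code."""

    scatter: str = "none"
    math: tuple[int, int, int, int] = (0, 0, 1, 1)

    def __post_init__(self) -> None:
        name = _SCATTER_ALIASES.get(str(self.scatter).strip().lower())
        if name is None:
            raise ValueError(f"unknown scatter correction {self.scatter!r}; one of {SCATTER_CHOICES}")
        object.__setattr__(self, "scatter", name)
        math = tuple(int(v) for v in self.math)
        if len(math) != 4:
            raise ValueError(f"math treatment must be a 4-tuple, got {math}")
        d, gap, s1, s2 = math
        if d not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {d}")
        if gap < 0 or s1 < 1 or s2 < 1:
            raise ValueError(f"invalid math code {math}: gap >= 0 and smoothing windows >= 1")
        if d == 0 and gap != 0:
            raise ValueError(f"math code {math}: zero derivative requires gap = 0")
        if d > 0 and gap < 1:
            raise ValueError(f"math code {math}: derivative requires gap >= 1")
        object.__setattr__(self, "math", math)

    @property
    def math_code(self) -> str:
        return ",".join(str(v) for v in self.math)

    @classmethod
    def parse(cls, scatter: str, math_code: str) -> "PreprocessSpec":
        parts = [int(v) for v in str(math_code).split(",")]
        return cls(scatter=scatter, math=tuple(parts))

    def __str__(self) -> str:
        return f"{self.scatter}/{self.math_code}"


# ---------------------------------------------------------------------------
# scatter-correction transformers
# ---------------------------------------------------------------------------

def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a 2-D spectral matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("spectral matrix contains non-finite values")
    return X


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: per-row centring and scaling to sample SD 1."""

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if X.shape[1] < 2:
            raise ValueError("SNV needs at least 2 points per spectrum")
        sd = X.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"SNV undefined for constant spectrum at row {int(bad[0])}")
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class Detrend(TransformerMixin, BaseEstimator):
    """Remove per-row linear and quadratic curvature against the wavenumber axis.

    The regressors are the wavenumbers (centred and scaled for conditioning);
    with ``wavenumbers=None`` the point index is used, which yields identical
    residuals on a uniform grid.
    """

    def __init__(self, wavenumbers=None):
        self.wavenumbers = wavenumbers

    def _basis(self, n_points: int) -> np.ndarray:
        if self.wavenumbers is not None:
            w = np.asarray(self.wavenumbers, dtype=float)
            if w.size != n_points:
                raise ValueError(f"{w.size} wavenumbers for {n_points} spectral columns")
        else:
            w = np.arange(n_points, dtype=float)
        ws = (w - w.mean()) / (w.std() if w.std() > 0 else 1.0)
        basis = np.column_stack([np.ones_like(ws), ws, ws**2])
        q, _ = np.linalg.qr(basis)
        return q

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[1] < 3:
            raise ValueError("detrending needs at least 3 points per spectrum")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if X.shape[1] < 3:
            raise ValueError("detrending needs at least 3 points per spectrum")
        q = self._basis(X.shape[1])
        return X - (X @ q) @ q.T

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class SNVDetrend(TransformerMixin, BaseEstimator):
    """SNV followed by detrending (the WinISI ``SNV+D`` option)."""

    def __init__(self, wavenumbers=None):
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return Detrend(self.wavenumbers).fit_transform(SNV().fit_transform(X))

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a (learned) reference spectrum.

    ``fit`` stores the column mean of the calibration matrix unless an explicit
    ``reference`` is supplied.
    """

    def __init__(self, reference=None, min_slope: float = 1e-8):
        self.reference = reference
        self.min_slope = min_slope

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.size != X.shape[1]:
                raise ValueError(f"reference length {ref.size} != {X.shape[1]} columns")
            if not np.all(np.isfinite(ref)):
                raise ValueError("MSC reference contains non-finite values")
            self.reference_ = ref.copy()
        else:
            self.reference_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise ValueError("MSC transformer is not fitted (no reference spectrum)")
        X = _as_matrix(X)
        ref = self.reference_
        refc = ref - ref.mean()
        denom = float(refc @ refc)
        if denom == 0:
            raise ValueError("MSC reference spectrum is constant")
        # closed-form simple linear regression of each row on the reference
        b = (X - X.mean(axis=1, keepdims=True)) @ refc / denom
        a = X.mean(axis=1) - b * ref.mean()
        bad = np.flatnonzero(np.abs(b) < self.min_slope)
        if bad.size:
            raise ValueError(f"MSC slope ~ 0 for spectrum at row {int(bad[0])}")
        return (X - a[:, None]) / b[:, None]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# gap-segment derivative / running-mean smoothing
# ---------------------------------------------------------------------------

def _running_mean(X: np.ndarray, window: int) -> np.ndarray:
    """Valid-mode running mean along the last axis (output shrinks by window-1)."""
    if window == 1:
        return X
    n = X.shape[-1]
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds spectrum length {n}")
    # cumulative-sum running mean: exact and fast
    cs = np.cumsum(np.concatenate([np.zeros(X.shape[:-1] + (1,)), X], axis=-1), axis=-1)
    return (cs[..., window:] - cs[..., :-window]) / window


def _gap_difference(X: np.ndarray, gap: int) -> np.ndarray:
    n = X.shape[-1]
    if gap >= n:
        raise ValueError(f"derivative gap {gap} exceeds spectrum length {n}")
    return X[..., gap:] - X[..., :-gap]


class GapSegmentDerivative(TransformerMixin, BaseEstimator):
    """WinISI math treatment ``(derivative, gap, smooth1, smooth2)``.

    Pipeline: running-mean smooth over ``smooth1`` points, ``derivative``
    applications of a gap difference across ``gap`` points, running-mean smooth
    over ``smooth2`` points.  After the first smoothing, the gap difference is
    exactly the segment-average difference of two ``smooth1``-point segments
    whose starts are ``gap`` points apart.  Output (and axis) keep only the
    indices where every window fits.
    """

    def __init__(self, derivative=0, gap=0, smooth1=1, smooth2=1, wavenumbers=None):
        self.derivative = derivative
        self.gap = gap
        self.smooth1 = smooth1
        self.smooth2 = smooth2
        self.wavenumbers = wavenumbers

    def _spec(self) -> PreprocessSpec:
        # reuse PreprocessSpec validation of the 4-tuple
        return PreprocessSpec(math=(self.derivative, self.gap, self.smooth1, self.smooth2))

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self._spec()
        self.n_features_in_ = X.shape[1]
        if self.wavenumbers is not None:
            w = np.asarray(self.wavenumbers, dtype=float)
            if w.size != X.shape[1]:
                raise ValueError(f"{w.size} wavenumbers for {X.shape[1]} spectral columns")
            self.wavenumbers_out_ = self._transform(w[None, :], as_axis=True)[0]
        return self

    def _transform(self, X: np.ndarray, as_axis: bool = False) -> np.ndarray:
        d, gap, s1, s2 = self._spec().math
        Z = _running_mean(X, s1)
        for _ in range(d):
            if as_axis:
                # the axis value of a difference is the midpoint of its two windows
                Z = 0.5 * (Z[..., gap:] + Z[..., :-gap])
            else:
                Z = _gap_difference(Z, gap)
        Z = _running_mean(Z, s2)
        if Z.shape[-1] < 1:
            raise ValueError("math-treatment windows leave no spectral points")
        return Z

    def transform(self, X):
        X = _as_matrix(X)
        return self._transform(X)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)

    def output_axis(self, axis: np.ndarray) -> np.ndarray:
        """Wavenumber axis after trimming (window-centre wavenumbers)."""
        axis = np.asarray(axis, dtype=float)
        return self._transform(axis[None, :], as_axis=True)[0]


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _scatter_transformer(spec: PreprocessSpec, wavenumbers, msc_reference):
    if spec.scatter == "none":
        return None
    if spec.scatter == "snv":
        return SNV()
    if spec.scatter == "detrend":
        return Detrend(wavenumbers=wavenumbers)
    if spec.scatter == "snv+d":
        return SNVDetrend(wavenumbers=wavenumbers)
    if spec.scatter == "msc":
        return MSC(reference=msc_reference)
    raise ValueError(f"unknown scatter correction {spec.scatter!r}")


def make_preprocess_pipeline(
    spec: PreprocessSpec,
    wavenumbers=None,
    msc_reference=None,
) -> Pipeline:
    """sklearn Pipeline applying the scatter correction then the math treatment.

    Scatter correction precedes the derivative/smoothing pass (WinISI
    convention).  Fit the pipeline on calibration rows only so the MSC
    reference is learned from the calibration set.
    """
    steps = []
    scatter = _scatter_transformer(spec, wavenumbers, msc_reference)
    if scatter is not None:
        steps.append(("scatter", scatter))
    d, gap, s1, s2 = spec.math
    steps.append(
        ("math", GapSegmentDerivative(d, gap, s1, s2, wavenumbers=wavenumbers))
    )
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# Spectra-level functional wrappers
# ---------------------------------------------------------------------------

def snv(spectra: Spectra) -> Spectra:
    return spectra.with_matrix(SNV().fit_transform(spectra.absorbance))


def detrend(spectra: Spectra) -> Spectra:
    t = Detrend(wavenumbers=spectra.axis.values)
    return spectra.with_matrix(t.fit_transform(spectra.absorbance))


def snv_detrend(spectra: Spectra) -> Spectra:
    return detrend(snv(spectra))


def msc(spectra: Spectra, reference: np.ndarray | None = None) -> Spectra:
    t = MSC(reference=reference)
    return spectra.with_matrix(t.fit_transform(spectra.absorbance))


def math_treatment(spectra: Spectra, math: tuple[int, int, int, int]) -> Spectra:
    d, gap, s1, s2 = PreprocessSpec(math=tuple(math)).math
    t = GapSegmentDerivative(d, gap, s1, s2, wavenumbers=spectra.axis.values)
    matrix = t.fit_transform(spectra.absorbance)
    return Spectra(WavenumberAxis(t.wavenumbers_out_), matrix, list(spectra.sample_ids))


def apply_preprocess(
    spectra: Spectra,
    spec: PreprocessSpec,
    msc_reference: np.ndarray | None = None,
) -> Spectra:
    """Scatter correction followed by the math treatment, axis trimmed to match."""
    if spec.scatter == "msc" and msc_reference is None:
        raise ValueError("MSC requires a reference spectrum from the calibration set")
    pipeline = make_preprocess_pipeline(
        spec, wavenumbers=spectra.axis.values, msc_reference=msc_reference
    )
    matrix = pipeline.fit_transform(spectra.absorbance)
    axis_out = pipeline.named_steps["math"].wavenumbers_out_
    return Spectra(WavenumberAxis(axis_out), matrix, list(spectra.sample_ids))
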