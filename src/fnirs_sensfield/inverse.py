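"""Regularized cortical reconstruction (minimum-norm estimate).

The inverse problem — mapping ~10^2 channel optical-density measurements
onto ~10^3-10^4 cortical vertices — is ill-posed and solved with a
Tikhonov/minimum-norm estimator whose two hyperparameters weight a
channel-space noise covariance C1 against a source-space prior
covariance C2. The hyperparameters are estimated by restricted maximum
likelihood under the two-component variance model
cov(y) = (1/h1) C1 + (1/h2) A C2 A'. Per-vertex absorption changes at
the two wavelengths are unmixed into oxy-/deoxy-hemoglobin with the
molar extinction matrix (concentration outputs carry an arbitrary
scale: no absolute pathlength calibration is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .montage import Parcellation
from .recording import extinction_matrix


@dataclass
class InverseModel:
    A: np.ndarray  # (I, J) sensitivity matrix
    C1: np.ndarray  # (I, I) channel noise covariance, SPD
    C2: np.ndarray | None = None  # (J, J) source prior; None = identity
    h1: float = 1.0
    h2: float = 1.0

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.C1 = np.asarray(self.C1, dtype=float)
        if self.C2 is not None:
            self.C2 = np.asarray(self.C2, dtype=float)
        if self.h1 <= 0 or self.h2 <= 0:
            raise ValueError("hyperparameters must be > 0")
        _assert_spd(self.C1, "C1")

    @property
    def signal_gram(self) -> np.ndarray:
        """A C2 A' (I x I)."""
        if self.C2 is None:
            return self.A @ self.A.T
        return self.A @ self.C2 @ self.A.T


def _assert_spd(M: np.ndarray, name: str) -> None:
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    try:
        linalg.cholesky(M)
    except linalg.LinAlgError as err:
        raise ValueError(f"{name} must be positive definite") from err


def restricted_loglik(log_s1: float, log_s2: float, C1: np.ndarray,
                      M: np.ndarray, S: np.ndarray, n_samples: int) -> float:
    """Log-likelihood of zero-mean Gaussian samples with covariance
    s1*C1 + s2*M, where S is the sample second-moment matrix."""
    V = np.exp(log_s1) * C1 + np.exp(log_s2) * M
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Vinv_S = linalg.cho_solve((L, True), S)
    return -0.5 * n_samples * (logdet + np.trace(Vinv_S))


def reml_hyperparameters(y: np.ndarray, A: np.ndarray, C1: np.ndarray,
                         C2: np.ndarray | None = None,
                         grid: int = 15) -> tuple[float, float]:
    """Estimate (h1, h2) from data samples by restricted maximum likelihood.

    ``y`` holds zero-mean channel samples, shape (I, n_samples). The
    variance components s1 = 1/h1 (noise) and s2 = 1/h2 (signal) are
    found by a coarse log-grid search refined with Nelder-Mead;
    deterministic given the inputs. A boundary solution (signal variance
    collapsing to zero) is clipped to a tiny positive value.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != A.shape[0]:
        raise ValueError("y rows must match channel count")
    n = y.shape[1]
    S = y @ y.T / n
    M = A @ (C2 @ A.T if C2 is not None else A.T)
    _assert_spd(C1, "C1")
    # scale-aware grid around the data variance
    scale = np.trace(S) / np.trace(C1)
    scale_m = np.trace(S) / max(np.trace(M), 1e-300)
    g1 = np.log(scale) + np.linspace(-6, 3, grid)
    g2 = np.log(max(scale_m, 1e-300)) + np.linspace(-8, 3, grid)
    best, best_ll = None, -np.inf
    for a in g1:
        for b in g2:
            ll = restricted_loglik(a, b, C1, M, S, n)
            if ll > best_ll:
                best, best_ll = (a, b), ll
    res = optimize.minimize(
        lambda p: -restricted_loglik(p[0], p[1], C1, M, S, n),
        x0=np.array(best), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500})
    s1, s2 = np.exp(res.x)
    s1 = max(s1, 1e-12 * scale)
    s2 = max(s2, 1e-12 * scale)
    return 1.0 / s1, 1.0 / s2


def mne_solve(y: np.ndarray, model: InverseModel) -> np.ndarray:
    """Minimum-norm estimate x = C2 A' (A C2 A' + (h2/h1) C1)^-1 y.

    The channel-space form of the Tikhonov solution: numerically stable
    because only an I x I system is factorized. ``y`` may be a vector or
    an (I, T) series; the estimate is applied columnwise.
    """
    A, C1, C2 = model.A, model.C1, model.C2
    lam = model.h2 / model.h1
    K = model.signal_gram + lam * C1
    try:
        L = linalg.cholesky(K, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(
            "singular channel-space matrix: A C2 A' + (h2/h1) C1 is not "
            "positive definite (check conditioning / hyperparameters)") from err
    w = linalg.cho_solve((L, True), np.atleast_2d(y.T).T.reshape(A.shape[0], -1))
    At = A.T if C2 is None else C2 @ A.T
    x = At @ w
    return x[:, 0] if np.ndim(y) == 1 else x


@dataclass
class CorticalActivation:
    dmua: dict[int, np.ndarray]  # wavelength -> (J, T) absorption changes
    hbo: np.ndarray  # (J, T)
    hbr: np.ndarray  # (J, T)
    extinction: np.ndarray  # (2, 2) rows wavelengths, cols (HbO2, HbR)
    arbitrary_scale: bool = True


def unmix_hemoglobin(dmua_by_wl: dict[int, np.ndarray],
                     ext: np.ndarray | None = None) -> CorticalActivation:
    """Per-vertex 2x2 solve from two-wavelength absorption changes to
    (dHbO2, dHbR). Raises on a near-singular extinction matrix."""
    wavelengths = tuple(sorted(dmua_by_wl))
    if len(wavelengths) != 2:
        raise ValueError("exactly two wavelengths are required to unmix")
    if ext is None:
        ext = extinction_matrix(wavelengths) * 0.1  # 1/(mM mm)
    ext = np.asarray(ext, dtype=float)
    if np.linalg.cond(ext) > 1e8:
        raise ValueError("extinction matrix is near-singular")
    stacked = np.stack([np.atleast_2d(dmua_by_wl[w]) for w in wavelengths])
    inv = np.linalg.inv(ext)
    conc = np.einsum("cw,wjt->cjt", inv, stacked)
    return CorticalActivation(dmua={w: stacked[k] for k, w in enumerate(wavelengths)},
                              hbo=conc[0], hbr=conc[1], extinction=ext)


def area_timecourse(values: np.ndarray, parc: Parcellation, area_id: int
                    ) -> dict[str, np.ndarray | float]:
    """Vertexwise mean trace over one area, with peak value and latency
    (in samples). ``values`` is (J,) or (J, T)."""
    j = parc.vertex_indices(area_id)
    if j.size == 0:
        raise ValueError(f"area {area_id} is empty")
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[0] == 1 and np.ndim(values) == 1:
        v = v.T
    trace = v[j].mean(axis=0)
    ipk = int(np.argmax(np.abs(trace)))
    return {"trace": trace, "peak_value": float(trace[ipk]), "peak_sample": ipk}
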