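"""Tissue optical properties for the five-layer head model.

Absorption and scattering are full (not reduced) coefficients in 1/mm;
the Henyey-Greenstein anisotropy factor g and the refractive index n are
dimensionless. The default table covers continuous-wave fNIRS wavelengths
760 and 850 nm for scalp, skull, CSF, grey matter and white matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: voxel label codes shared across the package
BACKGROUND, SCALP, SKULL, CSF, GM, WM = 0, 1, 2, 3, 4, 5

TISSUE_NAMES = {SCALP: "scalp", SKULL: "skull", CSF: "csf", GM: "gm", WM: "wm"}

WAVELENGTHS_NM = (760, 850)

# per-tissue (mua, mus) in 1/mm at each wavelength; g and n shared
_DEFAULTS = {
    760: {
        SCALP: (0.017, 6.727),
        SKULL: (0.0116, 8.545),
        CSF: (0.004, 2.727),
        GM: (0.018, 7.599),
        WM: (0.0167, 10.825),
    },
    850: {
        SCALP: (0.019, 5.818),
        SKULL: (0.0139, 7.636),
        CSF: (0.004, 2.727),
        GM: (0.0192, 6.165),
        WM: (0.0208, 9.188),
    },
}
_DEFAULT_G = 0.89
_DEFAULT_N = 1.37


@dataclass
class OpticalProperties:
    """Per-label optical coefficients on a single wavelength.

    Arrays are indexed by voxel label (0..5); label 0 is the ambient
    medium (air) with zero interaction and refractive index
    ``n_ambient``. Defaults reproduce the standard five-layer table.
    """

    wavelength_nm: int
    mua: np.ndarray = field(default=None)  # 1/mm, shape (6,)
    mus: np.ndarray = field(default=None)  # 1/mm, shape (6,)
    g: np.ndarray = field(default=None)  # anisotropy, shape (6,)
    n: np.ndarray = field(default=None)  # refractive index, shape (6,)
    n_ambient: float = 1.0

    def __post_init__(self):
        if self.wavelength_nm not in _DEFAULTS:
            raise ValueError(f"no default optical table at {self.wavelength_nm} nm")
        table = _DEFAULTS[self.wavelength_nm]
        if self.mua is None:
            self.mua = np.array([0.0] + [table[k][0] for k in range(1, 6)])
        if self.mus is None:
            self.mus = np.array([0.0] + [table[k][1] for k in range(1, 6)])
        if self.g is None:
            self.g = np.array([0.0] + [_DEFAULT_G] * 5)
        if self.n is None:
            self.n = np.array([1.0] + [_DEFAULT_N] * 5)
        self.mua = np.asarray(self.mua, dtype=float).copy()
        self.mus = np.asarray(self.mus, dtype=float).copy()
        self.g = np.asarray(self.g, dtype=float)
        self.n = np.asarray(self.n, dtype=float).copy()
        self.n[BACKGROUND] = self.n_ambient
        self._validate()

    def _validate(self) -> None:
        for name, arr in (("mua", self.mua), ("mus", self.mus),
                          ("g", self.g), ("n", self.n)):
            if np.asarray(arr).ndim != 1 or len(arr) < 6:
                raise ValueError(f"{name} must have one entry per label (>= 6)")
        if np.any(self.mua < 0):
            raise ValueError("mua must be >= 0")
        if np.any(self.mus[1:] <= 0):
            raise ValueError("tissue mus must be > 0")
        if np.any((self.g < 0) | (self.g >= 1)):
            raise ValueError("g must be in [0, 1)")
        if np.any(self.n < 1):
            raise ValueError("n must be >= 1")

    @classmethod
    def homogeneous(cls, wavelength_nm: int, tissue: int = GM,
                    n_ambient: float | None = None) -> "OpticalProperties":
        """All tissue labels share one tissue's coefficients.

        With ``n_ambient=None`` the boundary is index-matched to the
        tissue (photons leave without Fresnel reflection), the natural
        setting for infinite-medium validation runs.
        """
        props = cls(wavelength_nm)
        for arr in (props.mua, props.mus):
            arr[1:] = arr[tissue]
        if n_ambient is None:
            n_ambient = float(props.n[tissue])
        props.n_ambient = n_ambient
        props.n[BACKGROUND] = n_ambient
        return props


def default_properties(wavelength_nm: int) -> OpticalProperties:
    return OpticalProperties(wavelength_nm)


def with_perturbed_voxel(head_labels: np.ndarray, props: OpticalProperties,
                         voxel: tuple[int, int, int], dmua: float
                         ) -> tuple[np.ndarray, OpticalProperties]:
    """Single-voxel absorption perturbation via an extra label.

    Returns a label grid where ``voxel`` carries a new label whose
    coefficients copy the voxel's tissue except mua += dmua — the
    brute-force counterpart of a first-order sensitivity prediction.
    """
    labels = head_labels.copy()
    base = int(labels[voxel])
    if base == BACKGROUND:
        raise ValueError("cannot perturb a background voxel")
    new = len(props.mua)
    out = OpticalProperties(
        props.wavelength_nm,
        mua=np.append(props.mua, props.mua[base] + dmua),
        mus=np.append(props.mus, props.mus[base]),
        g=np.append(props.g, props.g[base]),
        n=np.append(props.n, props.n[base]),
        n_ambient=props.n_ambient)
    labels[voxel] = new
    return labels, out
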