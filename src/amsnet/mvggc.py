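"""Multi-view generation by gamma correction (MVGGC).

A grayscale ultrasound image is expanded into several brightness "views" by
the power-law transform

    x_hat = C * ((x + eps) / C) ** gamma

and the views are stacked as the input channels of the network.  A gamma
below 1 stretches the dark range (brightening), a gamma above 1 stretches
the bright range (darkening); feeding the original together with one
brightened and one darkened view lets the first convolution see the
hyperechoic substantia-nigra signal at three contrast settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GammaSpec", "MultiViewImage", "gamma_correct", "build_multiview"]


@dataclass
class GammaSpec:
    """Gamma-view configuration.

    gammas : ordered exponents, one per view.  The default triplet is the
        identity view plus the standard display-gamma pair 1/2.2 and 2.2.
    c : intensity ceiling C; 1.0 for [0,1]-normalized images.
    epsilon : small offset added before exponentiation so the transform has
        a finite derivative at zero intensity.
    """

    gammas: tuple[float, ...] = (1.0, 1.0 / 2.2, 2.2)
    c: float = 1.0
    epsilon: float = 1e-6

    def __post_init__(self):
        self.gammas = tuple(float(g) for g in self.gammas)
        if len(self.gammas) == 0:
            raise ValueError("gammas must be non-empty")
        if any(g <= 0 for g in self.gammas):
            raise ValueError("all gammas must be > 0")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @property
    def n_views(self) -> int:
        return len(self.gammas)


@dataclass
class MultiViewImage:
    """Stack of gamma-corrected views, shaped (n_views, H, W)."""

    views: np.ndarray
    gamma_spec: GammaSpec = field(default_factory=GammaSpec)

    def __post_init__(self):
        self.views = np.asarray(self.views, dtype=np.float64)
        if self.views.ndim != 3:
            raise ValueError("views must be (n_views, H, W)")
        if self.views.shape[0] != self.gamma_spec.n_views:
            raise ValueError("view count does not match gamma spec")


def gamma_correct(image: np.ndarray, gamma: float,
                  spec: GammaSpec | None = None) -> np.ndarray:
    """Apply ``C * ((x + eps)/C) ** gamma`` elementwise."""
    spec = spec or GammaSpec()
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    x = np.asarray(image, dtype=np.float64)
    if x.size and (x.min() < 0 or x.max() > spec.c):
        raise ValueError(f"image values must lie in [0, {spec.c}]")
    return spec.c * ((x + spec.epsilon) / spec.c) ** gamma


def build_multiview(image: np.ndarray,
                    spec: GammaSpec | None = None) -> MultiViewImage:
    """Stack one gamma-corrected view per exponent in ``spec.gammas``."""
    spec = spec or GammaSpec()
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    views = np.stack([gamma_correct(x, g, spec) for g in spec.gammas])
    return MultiViewImage(views=views, gamma_spec=spec)
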