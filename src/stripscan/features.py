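"""Scalar texture features of an averaged co-occurrence matrix.

Twenty-two Haralick-style statistics are computed from a normalised
co-occurrence matrix p(i, j) with gray-level indices i, j = 1..Ng:
autocorrelation, contrast, two correlation forms, cluster prominence and
shade, dissimilarity, energy, entropy, two homogeneity forms, maximum
probability, variance about the marginal mean, sum average / variance /
entropy, difference variance / entropy, the two information measures of
correlation, and the normalised inverse-difference pair.

Logs are base 2 with a small constant eps = 2**-52 added inside every log
to guard zero probabilities.  Correlation returns 0 for degenerate matrices
with zero marginal variance, so every feature is finite for any valid input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .glcm import AHMOMatrix, ahmo_batch

__all__ = [
    "FEATURE_NAMES",
    "EPS",
    "MarginalStats",
    "marginals",
    "compute_features",
    "features_for_patches",
    "AHMOFeatures",
]

EPS = 2.0 ** -52

#: Fixed export order of the 22 features.
FEATURE_NAMES: tuple[str, ...] = (
    "autoc", "contr", "corrm", "corrp", "cprom", "cshad", "dissi", "energ",
    "entro", "homom", "homop", "maxpr", "sosvh", "savgh", "svarh", "senth",
    "dvarh", "denth", "inf1h", "inf2h", "indnc", "idmnc",
)


def _log2e(x: np.ndarray | float) -> np.ndarray | float:
    return np.log2(x + EPS)


@dataclass
class MarginalStats:
    """Marginal distributions and moments of a normalised p(i, j).

    Indices run 1..Ng, so the sum distribution pXplusY is supported on
    k = 2..2Ng and the absolute-difference distribution pXminusY on
    k = 0..Ng-1.
    """

    px: np.ndarray
    py: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_xplusy: np.ndarray   # index 0 <-> k=2
    p_xminusy: np.ndarray  # index 0 <-> k=0
    Ng: int

    @property
    def k_sum(self) -> np.ndarray:
        return np.arange(2, 2 * self.Ng + 1, dtype=np.float64)

    @property
    def k_diff(self) -> np.ndarray:
        return np.arange(0, self.Ng, dtype=np.float64)


def _as_matrix(p) -> np.ndarray:
    m = p.p if isinstance(p, AHMOMatrix) else np.asarray(p, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if abs(m.sum() - 1.0) > 1e-8:
        raise ValueError(f"matrix must be normalised to sum 1, got {m.sum()}")
    return m


def marginals(p) -> MarginalStats:
    """Row/column marginals, their moments, and the sum/difference distributions."""
    m = _as_matrix(p)
    Ng = m.shape[0]
    idx = np.arange(1, Ng + 1, dtype=np.float64)
    px = m.sum(axis=1)
    py = m.sum(axis=0)
    mu_x = float(px @ idx)
    mu_y = float(py @ idx)
    sigma_x = float(np.sqrt(max(px @ idx**2 - mu_x**2, 0.0)))
    sigma_y = float(np.sqrt(max(py @ idx**2 - mu_y**2, 0.0)))

    ii = idx[:, None] + idx[None, :]          # i + j in 2..2Ng
    dd = np.abs(idx[:, None] - idx[None, :])  # |i - j| in 0..Ng-1
    p_sum = np.bincount((ii.ravel() - 2).astype(np.intp), weights=m.ravel(),
                        minlength=2 * Ng - 1)
    p_diff = np.bincount(dd.ravel().astype(np.intp), weights=m.ravel(), minlength=Ng)
    return MarginalStats(px=px, py=py, mu_x=mu_x, mu_y=mu_y,
                         sigma_x=sigma_x, sigma_y=sigma_y,
                         p_xplusy=p_sum, p_xminusy=p_diff, Ng=Ng)


def compute_features(p, strict_printed_formulas: bool = True) -> dict[str, float]:
    """Compute the 22 named texture features of one normalised matrix.

    ``strict_printed_formulas`` keeps the inverse-difference-normalised
    feature (indnc) in its unnormalised form sum p / (1 + (i-j)^2); setting
    it False divides the difference term by Ng as in the conventional
    normalised definition.
    """
    m = _as_matrix(p)
    Ng = m.shape[0]
    st = marginals(m)
    idx = np.arange(1, Ng + 1, dtype=np.float64)
    I = idx[:, None]
    J = idx[None, :]
    D = I - J
    S = I + J

    f: dict[str, float] = {}
    f["autoc"] = float(np.sum(I * J * m))
    f["contr"] = float(np.sum(D**2 * m))
    cov = float(np.sum((I - st.mu_x) * (J - st.mu_y) * m))
    sxsy = st.sigma_x * st.sigma_y
    f["corrm"] = cov / sxsy if sxsy > 0 else 0.0
    f["corrp"] = (f["autoc"] - st.mu_x * st.mu_y) / sxsy if sxsy > 0 else 0.0
    f["cprom"] = float(np.sum((S - st.mu_x - st.mu_y) ** 4 * m))
    f["cshad"] = float(np.sum((S - st.mu_x - st.mu_y) ** 3 * m))
    f["dissi"] = float(np.sum(np.abs(D) * m))
    f["energ"] = float(np.sum(m**2))
    f["entro"] = float(-np.sum(m * _log2e(m)))
    f["homom"] = float(np.sum(m / (1.0 + np.abs(D))))
    f["homop"] = float(np.sum(m / (1.0 + D**2)))
    f["maxpr"] = float(m.max())
    f["sosvh"] = float(np.sum((I - st.mu_x) ** 2 * m))

    ks, kd = st.k_sum, st.k_diff
    f["savgh"] = float(ks @ st.p_xplusy)
    f["senth"] = float(-np.sum(st.p_xplusy * _log2e(st.p_xplusy)))
    f["svarh"] = float(np.sum((ks - f["senth"]) ** 2 * st.p_xplusy))
    mu_d = float(kd @ st.p_xminusy)
    f["dvarh"] = float(np.sum((kd - mu_d) ** 2 * st.p_xminusy))
    f["denth"] = float(-np.sum(st.p_xminusy * _log2e(st.p_xminusy)))

    hxy = f["entro"]
    hx = float(-np.sum(st.px * _log2e(st.px)))
    hy = float(-np.sum(st.py * _log2e(st.py)))
    pxpy = st.px[:, None] * st.py[None, :]
    hxy1 = float(-np.sum(m * _log2e(pxpy)))
    hxy2 = float(-np.sum(pxpy * _log2e(pxpy)))
    denom = max(hx, hy)
    f["inf1h"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    f["inf2h"] = float(np.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - hxy)))))

    if strict_printed_formulas:
        f["indnc"] = float(np.sum(m / (1.0 + D**2)))
    else:
        f["indnc"] = float(np.sum(m / (1.0 + np.abs(D) / Ng)))
    f["idmnc"] = float(np.sum(m / (1.0 + D**2 / Ng**2)))

    for name, v in f.items():
        if not np.isfinite(v):
            raise ArithmeticError(f"feature {name} is not finite: {v}")
    return {name: f[name] for name in FEATURE_NAMES}


class AHMOFeatures(BaseEstimator, TransformerMixin):
    """Stateless transformer: patch stack -> 22-column texture feature matrix.

    Composes the whole texture operator — grayscale conversion is assumed
    done, patches are quantised to ``levels`` gray levels, horizontal
    co-occurrence matrices at offsets 1..d_max are averaged, and the 22
    scalar features are evaluated.

    Parameters follow the operator defaults: ``levels=64``, ``d_max=25``,
    non-symmetric pairs, per-image gray range.
    """

    def __init__(self, levels: int = 64, d_max: int = 25, symmetric: bool = False,
                 range_mode: str = "per_image", strict_printed_formulas: bool = True):
        self.levels = levels
        self.d_max = d_max
        self.symmetric = symmetric
        self.range_mode = range_mode
        self.strict_printed_formulas = strict_printed_formulas

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        P = ahmo_batch(X, Ng=self.levels, d_max=self.d_max,
                       symmetric=self.symmetric, range_mode=self.range_mode)
        rows = [
            list(compute_features(P[k], self.strict_printed_formulas).values())
            for k in range(P.shape[0])
        ]
        return np.asarray(rows, dtype=np.float64)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)

    @staticmethod
    def _validate(X) -> np.ndarray:
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected (n, rows, cols) patch stack, got shape {arr.shape}")
        return arr


def features_for_patches(patches, levels: int = 64, d_max: int = 25,
                         symmetric: bool = False, range_mode: str = "per_image",
                         strict_printed_formulas: bool = True) -> pd.DataFrame:
    """Feature table for a list of :class:`~stripscan.patches.Patch`.

    One row per patch in input order: the 22 feature columns plus ``label``,
    ``source_image``, ``side`` and ``patch_index`` provenance columns.
    """
    if not patches:
        raise ValueError("patch list is empty")
    stack = np.stack([p.pixels for p in patches])
    ext = AHMOFeatures(levels=levels, d_max=d_max, symmetric=symmetric,
                       range_mode=range_mode,
                       strict_printed_formulas=strict_printed_formulas)
    vals = ext.transform(stack)
    df = pd.DataFrame(vals, columns=list(FEATURE_NAMES))
    df["label"] = [p.label for p in patches]
    df["source_image"] = [p.source_image for p in patches]
    df["side"] = [p.source_side for p in patches]
    df["patch_index"] = [p.patch_index for p in patches]
    return df
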