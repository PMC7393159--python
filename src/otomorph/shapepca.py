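"""Principal component analysis of normalized EFD coefficients.

Shape variation is reduced per species by an eigendecomposition of the
variance-covariance matrix of the normalized harmonic coefficients.  The
entries fixed by normalization (a1 = 1, b1 = c1 = 0) carry no variance and
are excluded; d1 is kept because it carries the aspect-ratio (height)
signal.  The number of biologically meaningful components is chosen by the
broken-stick null model: the expected eigenvalue proportions when total
variance is split at random are

    b_k = (1/p) * sum_{i=k..p} 1/i,

and leading components are retained up to (excluding) the first k where the
observed proportion falls to or below b_k (first-crossover rule, matching
scree-plot practice).

PC sign convention: eigenvectors are signed so that moving in the +PC1
direction increases the reconstructed dorsoventral extent (otolith height)
and +PC2 deepens the anterior notch; remaining components get the largest
absolute loading positive.  This pins down the sign-flip ambiguity so
planted-effect directions are stable across seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efd import Contour, EFDCoefficients, reconstruct_contour

logger = logging.getLogger(__name__)

__all__ = [
    "ShapePCA",
    "BrokenStick",
    "coefficient_matrix",
    "fit_shape_pca",
    "broken_stick",
    "first_crossover",
    "select_pcs",
    "pc_extreme_contour",
]

# indices of the normalization-fixed entries in the flattened (a,b,c,d) row
_FIXED = (0, 1, 2)


@dataclass
class ShapePCA:
    """Reduced shape space for one species.

    ``mean`` is the full mean coefficient row (including fixed entries, for
    reconstruction); eigenvectors are columns over the variable entries.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    proportions: np.ndarray
    scores: pd.DataFrame
    n_harmonics: int
    variable_idx: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, float)
        if np.any(lam < -1e-10):
            raise ValueError("eigenvalues must be >= 0")
        if np.any(np.diff(lam) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("variance proportions must sum to 1")

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass
class BrokenStick:
    """Broken-stick expected eigenvalue proportions for p components."""

    p: int
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        inv = 1.0 / np.arange(1, self.p + 1)
        # b_k = (1/p) sum_{i=k..p} 1/i  — strictly decreasing, sums to 1
        self.proportions = inv[::-1].cumsum()[::-1] / self.p


def coefficient_matrix(efds: list[EFDCoefficients]) -> pd.DataFrame:
    """Stack normalized EFDs into a (specimens x coefficients) table.

    Columns are a1,b1,c1,d1,a2,...; the index is specimen_id.  All inputs
    must be normalized and share the same harmonic count.
    """
    if not efds:
        raise ValueError("no coefficients given")
    N = efds[0].n_harmonics
    rows, ids = [], []
    for e in efds:
        if not e.normalized:
            raise ValueError(f"{e.specimen_id}: coefficients are not normalized")
        if e.n_harmonics != N:
            raise ValueError("all specimens must share the same harmonic count")
        rows.append(e.flattened())
        ids.append(e.specimen_id)
    cols = [f"{l}{n}" for n in range(1, N + 1) for l in "abcd"]
    return pd.DataFrame(rows, index=pd.Index(ids, name="specimen_id"), columns=cols)


def _reconstruction_metrics(vec: np.ndarray, n_harmonics: int) -> tuple[float, float]:
    """(height ratio, notch depth) of the contour a coefficient row encodes."""
    coeffs = vec.reshape(n_harmonics, 4).copy()
    coeffs[0, :3] = (1.0, 0.0, 0.0)
    e = EFDCoefficients(coeffs=coeffs, normalized=True)
    pts = reconstruct_contour(e, 256).points
    width = pts[:, 0].max() - pts[:, 0].min()
    height = pts[:, 1].max() - pts[:, 1].min()
    # notch depth: max radial deficit of the full shape vs. its
    # first-harmonic ellipse, relative to the ellipse radius
    e1 = EFDCoefficients(coeffs=coeffs[:1].copy(), normalized=True)
    pts1 = reconstruct_contour(e1, 256).points
    r = np.hypot(pts[:, 0] - pts[:, 0].mean(), pts[:, 1] - pts[:, 1].mean())
    r1 = np.hypot(pts1[:, 0] - pts1[:, 0].mean(), pts1[:, 1] - pts1[:, 1].mean())
    notch = float(np.max((r1 - r) / r1))
    return height / width, notch


def fit_shape_pca(coeff_matrix: pd.DataFrame) -> ShapePCA:
    """Covariance PCA of normalized coefficients for one species.

    Excludes the normalization-fixed entries (zero variance), eigendecomposes
    the sample covariance matrix, centers scores, and applies the sign
    convention described in the module docstring.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 otoliths for PCA")
    n_harmonics = X.shape[1] // 4
    var_idx = np.array([j for j in range(X.shape[1]) if j not in _FIXED])
    mean = X.mean(axis=0)
    Xc = X[:, var_idx] - mean[var_idx]
    cov = np.cov(Xc, rowvar=False, ddof=1)
    total_var = np.trace(cov)
    if total_var <= 0.0:
        raise ValueError("zero shape variance: all specimens identical")
    lam, vecs = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vecs = vecs[:, order]
    scores = Xc @ vecs
    scores -= scores.mean(axis=0)  # exact centering

    # sign convention
    for k in range(vecs.shape[1]):
        if k < 2 and lam[k] > 0:
            step = 2.0 * np.sqrt(lam[k])
            plus = mean.copy()
            plus[var_idx] += step * vecs[:, k]
            minus = mean.copy()
            minus[var_idx] -= step * vecs[:, k]
            hp, np_ = _reconstruction_metrics(plus, n_harmonics)
            hm, nm = _reconstruction_metrics(minus, n_harmonics)
            flip = (hp < hm) if k == 0 else (np_ < nm)
        else:
            j = np.argmax(np.abs(vecs[:, k]))
            flip = vecs[j, k] < 0
        if flip:
            vecs[:, k] *= -1.0
            scores[:, k] *= -1.0

    props = lam / lam.sum()
    score_df = pd.DataFrame(
        scores,
        index=coeff_matrix.index,
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )
    return ShapePCA(
        mean=mean,
        eigenvectors=vecs,
        eigenvalues=lam,
        proportions=props,
        scores=score_df,
        n_harmonics=n_harmonics,
        variable_idx=var_idx,
    )


def broken_stick(p: int) -> BrokenStick:
    """Broken-stick proportions b_k for p components (closed form)."""
    return BrokenStick(p=p)


def first_crossover(proportions: np.ndarray) -> int:
    """Count of leading proportions strictly above their broken-stick
    expectation, stopping at the first crossover."""
    proportions = np.asarray(proportions, dtype=float)
    b = broken_stick(proportions.shape[0]).proportions
    n = 0
    for pi_k, b_k in zip(proportions, b):
        if pi_k <= b_k:
            break
        n += 1
    return n


def select_pcs(pca: ShapePCA) -> int:
    """Number of leading PCs before the first broken-stick crossover."""
    return first_crossover(pca.proportions)


def pc_extreme_contour(
    pca: ShapePCA, pc: int, sd_multiple: float, K: int = 256
) -> Contour:
    """Reconstruct the contour at mean + sd_multiple * sqrt(lambda_pc) * v.

    ``pc`` is 1-based.  sd_multiple = 0 gives the mean shape; +/-2 SD pairs
    visualize the shape change each component captures.
    """
    if not np.isfinite(sd_multiple):
        raise ValueError("sd_multiple must be finite")
    if not (1 <= pc <= pca.n_components):
        raise ValueError(f"pc must lie in 1..{pca.n_components}")
    vec = pca.mean.copy()
    vec[pca.variable_idx] += (
        sd_multiple * np.sqrt(pca.eigenvalues[pc - 1]) * pca.eigenvectors[:, pc - 1]
    )
    coeffs = vec.reshape(pca.n_harmonics, 4)
    coeffs[0, :3] = (1.0, 0.0, 0.0)  # restore normalization-fixed entries
    e = EFDCoefficients(coeffs=coeffs, normalized=True,
                        specimen_id=f"PC{pc}_{sd_multiple:+g}SD")
    return reconstruct_contour(e, K)
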