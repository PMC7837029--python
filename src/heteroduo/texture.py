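"""Co-occurrence matrices and the scalar texture features computed from them.

The same normalized level-pair matrix underlies both the slide-level
heterogeneity descriptors (10 stained-ratio ranks) and the PET gray-level
co-occurrence features (64 SUV bins), so the container and the feature
formulas live here and are shared by :mod:`heteroduo.ihc` and
:mod:`heteroduo.pet`.

All entropies are base 2. Features that are undefined on a degenerate
matrix (e.g. correlation when a marginal has zero variance) are returned
as ``nan``, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CooccurrenceMatrix",
    "haralick_features",
    "glcm_matrix_features",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric pair-frequency matrix over ``levels`` discrete levels.

    Parameters
    ----------
    entries
        ``(levels, levels)`` nonnegative array. If ``normalized`` is true the
        entries sum to 1 (within 1e-9).
    levels
        Number of discrete levels L (10 for stained-ratio ranks, 64 for
        SUV bins).
    normalized
        Whether ``entries`` are frequencies (sum 1) rather than raw counts.
    """

    entries: np.ndarray
    levels: int
    normalized: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (self.levels, self.levels):
            raise ValueError(
                f"entries shape {e.shape} does not match levels={self.levels}"
            )
        if (e < 0).any():
            raise ValueError("co-occurrence entries must be nonnegative")
        if self.normalized and abs(e.sum() - 1.0) > _NORM_TOL:
            raise ValueError("normalized matrix must sum to 1 within 1e-9")
        object.__setattr__(self, "entries", e)

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.entries, self.entries.T, atol=_NORM_TOL))

    def normalize(self) -> "CooccurrenceMatrix":
        """Return the frequency-normalized version of this matrix."""
        total = self.entries.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty co-occurrence matrix")
        return CooccurrenceMatrix(self.entries / total, self.levels, normalized=True)


def _marginal_stats(p: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Row-marginal distribution, its mean and standard deviation."""
    i = np.arange(p.shape[0], dtype=float)
    px = p.sum(axis=1)
    mu = float(np.dot(i, px))
    sigma = float(np.sqrt(np.dot((i - mu) ** 2, px)))
    return px, mu, sigma


def _require_normalized(m: CooccurrenceMatrix) -> np.ndarray:
    if not m.normalized:
        raise ValueError("features require a normalized co-occurrence matrix")
    return m.entries


def entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits of a (possibly sparse) probability array."""
    q = np.asarray(p, dtype=float).ravel()
    q = q[q > 0]
    return float(-(q * np.log2(q)).sum())


def haralick_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """Classical Haralick summaries of a normalized co-occurrence matrix.

    Returns ``contrast``, ``homogeneity``, ``dissimilarity``, ``entropy``,
    ``energy`` and ``correlation``. With :math:`p(i,j)` the entries:

    - contrast       = sum (i-j)^2 p
    - dissimilarity  = sum |i-j| p
    - homogeneity    = sum p / (1 + (i-j)^2)
    - energy         = sum p^2
    - entropy        = -sum_{p>0} p log2 p
    - correlation    = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j)

    ``correlation`` is ``nan`` when either marginal is degenerate.
    """
    p = _require_normalized(m)
    i, j = np.indices(p.shape)
    d = (i - j).astype(float)
    _, mu_i, sig_i = _marginal_stats(p)
    _, mu_j, sig_j = _marginal_stats(p.T)
    if sig_i * sig_j > 0:
        correlation = float(((i - mu_i) * (j - mu_j) * p).sum() / (sig_i * sig_j))
    else:
        correlation = float("nan")
    return {
        "contrast": float((d**2 * p).sum()),
        "homogeneity": float((p / (1.0 + d**2)).sum()),
        "dissimilarity": float((np.abs(d) * p).sum()),
        "entropy": entropy_bits(p),
        "energy": float((p**2).sum()),
        "correlation": correlation,
    }


def glcm_matrix_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """PET-style GLCM features of a single normalized direction matrix.

    Returns ``inverse_difference``, ``angular_second_moment``, ``variance``,
    ``correlation``, ``entropy`` and ``dissimilarity``. ``variance`` is
    :math:`\\sum_{ij} (i-\\mu)^2 p(i,j)` with :math:`\\mu` the mean of the
    (symmetric) marginal.
    """
    p = _require_normalized(m)
    i, j = np.indices(p.shape)
    d = np.abs(i - j).astype(float)
    _, mu, _ = _marginal_stats(p)
    har = haralick_features(m)
    return {
        "inverse_difference": float((p / (1.0 + d)).sum()),
        "angular_second_moment": har["energy"],
        "variance": float((((i - mu) ** 2) * p).sum()),
        "correlation": har["correlation"],
        "entropy": har["entropy"],
        "dissimilarity": har["dissimilarity"],
    }


def pairs_to_matrix(
    a: np.ndarray, b: np.ndarray, levels: int, symmetric: bool = True
) -> CooccurrenceMatrix:
    """Accumulate level pairs ``(a_k, b_k)`` into a normalized matrix.

    ``a`` and ``b`` are integer level arrays of equal length (each ordered
    pair counted once). With ``symmetric`` the transpose is added before
    normalizing, so (i,j) and (j,i) carry equal mass.
    """
    if a.size == 0:
        raise ValueError("no level pairs to accumulate")
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (np.asarray(a, dtype=int), np.asarray(b, dtype=int)), 1.0)
    if symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(counts, levels).normalize()
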