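"""Similarity-matrix assembly and every similarity-side statistic.

The analysis chain mirrors the elicitation protocol: repeated bounded pairwise
ratings are averaged into a square similarity matrix; for pitch ladders the
matrix is smoothed over its sub-diagonals (separations |i-j| on the semitone
grid) and summarised as an interval profile, whose local contrast locates the
octave-equivalence spike at 12 semitones. Structure recovery uses classical
(Torgerson) multidimensional scaling of a min-max normalised dissimilarity
transform. Agreement statistics are Pearson correlations over the strictly
upper triangle (the matrices are symmetric; self-pairs were never elicited),
with percentile bootstrap confidence intervals, and split-half inter-rater
reliability with the Spearman-Brown correction 2r/(1+r).
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "RatingRecord",
    "SimilarityMatrix",
    "ConfusionMatrix",
    "IntervalProfile",
    "EmbeddingResult",
    "CorrelationResult",
    "ReliabilityResult",
    "QualityAssessment",
    "OctavePeak",
    "assemble_matrix",
    "confusion_to_similarity",
    "symmetrize",
    "smooth_toeplitz",
    "interval_profile",
    "octave_peak",
    "correlate_upper_triangles",
    "bootstrap_correlation",
    "split_half_reliability",
    "spearman_brown",
    "quality_bonus",
    "classical_mds",
    "procrustes_distance_correlation",
    "term_frequencies",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingRecord:
    """One repeated pairwise similarity rating from one rater."""

    rater_id: str
    stim_a: str
    stim_b: str
    rating: float
    repetition: int = 0


@dataclass(frozen=True)
class SimilarityMatrix:
    """Aggregated square similarity matrix over an ordered stimulus set.

    Missing cells are NaN. ``counts`` records how many ratings entered each
    cell; ``n_parse_failures`` how many responses were excluded upstream.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    scale: tuple[float, float] | None = None
    symmetric: bool = False
    counts: np.ndarray | None = None
    n_parse_failures: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix dimension")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", v)
        if self.symmetric and not np.array_equal(v, v.T, equal_nan=True):
            raise ValueError("symmetric flag set but values are not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-stochastic confusion probabilities p[x, y] = P(respond y | shown x)."""

    ids: tuple[str, ...]
    probs: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] != len(self.ids):
            raise ValueError("confusion matrix must be square and match ids")
        if (p < 0).any():
            raise ValueError("confusion probabilities must be nonnegative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion matrix rows must sum to 1")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "probs", p)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class IntervalProfile:
    """Mean similarity per semitone separation on an equally spaced ladder."""

    separations: tuple[int, ...]
    mean_similarity: tuple[float, ...]
    pair_counts: tuple[int, ...]


@dataclass(frozen=True)
class EmbeddingResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # k, nonincreasing

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9):
            raise ValueError("eigenvalues must be nonincreasing")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_boot: int


@dataclass(frozen=True)
class ReliabilityResult:
    split_half_r: float
    corrected_r: float
    n_boot: int
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class QualityAssessment:
    consistency_spearman: float
    bonus: float  # USD


class OctavePeak(NamedTuple):
    separation: int
    contrast: float


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def assemble_matrix(
    records: Iterable[RatingRecord],
    ids: Sequence[str],
    scale: tuple[float, float] | None = None,
    n_parse_failures: int = 0,
) -> SimilarityMatrix:
    """Average repeated ratings into a square matrix; cell (i, j) is the mean
    of all ratings for the unordered pair {i, j}. Unrated cells are NaN."""
    ids = tuple(ids)
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for rec in records:
        if rec.stim_a not in index or rec.stim_b not in index:
            raise KeyError(f"unknown stimulus id in record: {rec.stim_a!r}/{rec.stim_b!r}")
        i, j = index[rec.stim_a], index[rec.stim_b]
        total[i, j] += rec.rating
        counts[i, j] += 1
        if i != j:
            total[j, i] += rec.rating
            counts[j, i] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return SimilarityMatrix(
        ids=ids,
        values=values,
        scale=scale,
        symmetric=bool(np.array_equal(values, values.T, equal_nan=True)),
        counts=counts,
        n_parse_failures=n_parse_failures,
    )


def confusion_to_similarity(C: ConfusionMatrix) -> SimilarityMatrix:
    """Similarity from confusion probabilities: s_xy = sqrt(p_xy p_yx / (p_xx p_yy)).

    Symmetric by construction with unit diagonal. Requires a strictly positive
    diagonal; smooth the counts upstream if any p_xx is zero.
    """
    p = C.probs
    d = np.diag(p)
    if (d <= 0).any():
        raise ValueError(
            "confusion matrix has a zero diagonal entry; apply count smoothing upstream"
        )
    s = np.sqrt((p * p.T) / np.outer(d, d))
    s = 0.5 * (s + s.T)  # remove fp asymmetry only
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(ids=C.ids, values=s, scale=None, symmetric=True)


def symmetrize(M: SimilarityMatrix) -> SimilarityMatrix:
    v = 0.5 * (M.values + M.values.T)
    return SimilarityMatrix(ids=M.ids, values=v, scale=M.scale, symmetric=True,
                            counts=M.counts, n_parse_failures=M.n_parse_failures)


# ---------------------------------------------------------------------------
# Sub-diagonal smoothing and interval profile (pitch ladders)
# ---------------------------------------------------------------------------

def _separation_means(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and pair count per separation s = 0..n-1, NaN-aware."""
    n = values.shape[0]
    means = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for s in range(n):
        diag = np.diagonal(values, offset=s)
        good = ~np.isnan(diag)
        counts[s] = int(good.sum())
        if counts[s]:
            means[s] = float(diag[good].mean())
    return means, counts


def smooth_toeplitz(M: SimilarityMatrix) -> SimilarityMatrix:
    """Replace every cell at separation s = |i-j| with the mean over that
    sub-diagonal (after symmetrization); the result is symmetric Toeplitz.

    Only meaningful when the stimuli sit on an equally spaced 1-d grid, e.g.
    a one-semitone pitch ladder in matrix order.
    """
    sym = symmetrize(M)
    means, _ = _separation_means(sym.values)
    n = sym.n
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    values = means[idx]
    return SimilarityMatrix(ids=sym.ids, values=values, scale=sym.scale, symmetric=True)


def interval_profile(M: SimilarityMatrix) -> IntervalProfile:
    """Mean similarity and pair count per separation s = 1..n-1 of a ladder matrix."""
    sym = symmetrize(M)
    means, counts = _separation_means(sym.values)
    seps = tuple(range(1, sym.n))
    return IntervalProfile(
        separations=seps,
        mean_similarity=tuple(float(means[s]) for s in seps),
        pair_counts=tuple(int(counts[s]) for s in seps),
    )


def octave_peak(profile: IntervalProfile) -> OctavePeak:
    """Separation with the strongest local spike in the interval profile.

    The contrast at separation s is c(s) = mean(s) - (mean(s-1) + mean(s+1))/2,
    evaluated for interior separations; the argmax (smallest separation on
    ties) and its contrast are returned, so callers can additionally require
    c > 0 to assert a genuine spike. On the two-octave one-semitone ladder
    with octave-equivalent raters the peak falls at 12 semitones.
    """
    seps = profile.separations
    if len(seps) < 3:
        raise ValueError("need at least 3 separations to compute contrasts")
    if list(seps) != list(range(seps[0], seps[0] + len(seps))):
        raise ValueError("separations must be contiguous")
    m = np.asarray(profile.mean_similarity)
    contrasts = m[1:-1] - 0.5 * (m[:-2] + m[2:])
    best = int(np.nanargmax(contrasts))
    return OctavePeak(separation=seps[1 + best], contrast=float(contrasts[best]))


# ---------------------------------------------------------------------------
# Correlation and bootstrap
# ---------------------------------------------------------------------------

def _upper_pairs(A: SimilarityMatrix, B: SimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    if A.ids != B.ids:
        raise ValueError("matrices must share the same ids in the same order")
    iu = np.triu_indices(A.n, k=1)
    a, b = A.values[iu], B.values[iu]
    good = ~(np.isnan(a) | np.isnan(b))
    return a[good], b[good]


def correlate_upper_triangles(A: SimilarityMatrix, B: SimilarityMatrix) -> CorrelationResult:
    """Pearson r over the strictly upper triangles (diagonal excluded), using
    pairwise-complete cells only."""
    a, b = _upper_pairs(symmetrize(A), symmetrize(B))
    if a.size < 3:
        raise ValueError(f"need at least 3 common cells, got {a.size}")
    r = float(stats.pearsonr(a, b).statistic)
    return CorrelationResult(r=r, ci_low=math.nan, ci_high=math.nan,
                             n_pairs=int(a.size), n_boot=0)


def _group_by_pair(records: Iterable[RatingRecord]) -> dict[tuple[str, str], list[float]]:
    groups: dict[tuple[str, str], list[float]] = defaultdict(list)
    for rec in records:
        key = tuple(sorted((rec.stim_a, rec.stim_b)))
        groups[key].append(rec.rating)
    return groups


def bootstrap_correlation(
    ratings_a: Sequence[RatingRecord],
    B: SimilarityMatrix,
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Upper-triangle correlation with a percentile bootstrap CI.

    Each bootstrap round resamples every pair's repeated ratings with
    replacement, rebuilds the mean matrix, and correlates it against ``B``;
    the 2.5/97.5 percentiles of the resulting r distribution form the 95% CI.
    The point estimate uses the unresampled data.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point_M = assemble_matrix(ratings_a, B.ids, scale=None)
    point = correlate_upper_triangles(point_M, B)
    # recompute the point r along the bootstrap code path so that noiseless
    # data collapses to a CI of exactly zero width
    ap, bp = _upper_pairs(symmetrize(point_M), symmetrize(B))
    point_r = float(np.corrcoef(ap, bp)[0, 1])

    groups = _group_by_pair(ratings_a)
    pairs = list(groups)
    index = {s: i for i, s in enumerate(B.ids)}
    rows = np.array([index[p[0]] for p in pairs])
    cols = np.array([index[p[1]] for p in pairs])
    # Ragged -> padded matrix of ratings per pair for vectorised resampling.
    lens = np.array([len(groups[p]) for p in pairs])
    maxlen = lens.max()
    padded = np.zeros((len(pairs), maxlen))
    for i, p in enumerate(pairs):
        padded[i, : lens[i]] = groups[p]

    bsym = symmetrize(B)
    iu = np.triu_indices(B.n, k=1)
    bvec = bsym.values[iu]

    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    n = B.n
    uniform = bool((lens == lens[0]).all())
    row_idx = np.arange(len(pairs))[:, None]
    for it in range(n_boot):
        draws = rng.integers(0, lens[:, None], size=(len(pairs), maxlen))
        sampled = padded[row_idx, draws]
        if uniform:
            means = sampled.mean(axis=1)
        else:  # only the first len(p) draws of each row are real resamples
            means = np.array([sampled[i, : lens[i]].mean() for i in range(len(pairs))])
        m = np.full((n, n), np.nan)
        m[rows, cols] = means
        m[cols, rows] = means
        a, b = m[iu], bvec
        good = ~(np.isnan(a) | np.isnan(b))
        rs[it] = np.corrcoef(a[good], b[good])[0, 1]
    lo, hi = np.percentile(rs, [2.5, 97.5])
    # Resampling repeated ratings inflates the per-pair noise relative to the
    # unresampled mean, so the whole bootstrap distribution can sit slightly
    # below the point estimate (attenuation). The interval is widened to
    # cover the point, which then lies exactly at the interval edge.
    lo, hi = min(float(lo), point_r), max(float(hi), point_r)
    return CorrelationResult(r=point_r, ci_low=lo, ci_high=hi,
                             n_pairs=point.n_pairs, n_boot=n_boot)


def spearman_brown(r: float) -> float:
    """Spearman-Brown prophecy correction for a half-split: 2r/(1+r)."""
    if r <= -1.0:
        raise ValueError("correction undefined for r <= -1")
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    records: Sequence[RatingRecord],
    ids: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> ReliabilityResult:
    """Split-half inter-rater reliability, bootstrapped over raters.

    Each round randomly halves the rater pool, averages each half's ratings
    into a matrix, correlates the upper triangles over pairwise-complete
    cells, and applies the Spearman-Brown correction. Returns the mean
    corrected value with a 2.5/97.5 percentile CI.
    """
    ids = tuple(ids)
    raters = sorted({rec.rater_id for rec in records})
    if len(raters) < 2:
        raise ValueError("need at least 2 raters")
    by_rater: dict[str, list[RatingRecord]] = defaultdict(list)
    for rec in records:
        by_rater[rec.rater_id].append(rec)

    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(max(1, n_boot)):
        perm = rng.permutation(len(raters))
        half = len(raters) // 2
        g1 = [raters[i] for i in perm[:half]]
        g2 = [raters[i] for i in perm[half:]]
        m1 = assemble_matrix([r for rid in g1 for r in by_rater[rid]], ids)
        m2 = assemble_matrix([r for rid in g2 for r in by_rater[rid]], ids)
        try:
            r = correlate_upper_triangles(m1, m2).r
        except ValueError:
            continue
        vals.append(spearman_brown(r))
    if not vals:
        raise ValueError("no bootstrap round had enough common cells")
    vals = np.asarray(vals)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    # invert 2r/(1+r) to report the mean uncorrected half-split r as well
    return ReliabilityResult(
        split_half_r=float(np.mean([v / (2.0 - v) for v in vals])),
        corrected_r=float(vals.mean()),
        n_boot=len(vals),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def quality_bonus(original: Sequence[float], repeated: Sequence[float]) -> QualityAssessment:
    """Consistency bonus from repeated catch trials.

    s is the Spearman rank correlation between the original responses and
    their repetitions; the bonus (USD) is min(max(0.0, 0.1·s), 0.1).
    """
    if len(original) != len(repeated):
        raise ValueError("original and repeated response lists must have equal length")
    if len(original) < 2:
        raise ValueError("need at least 2 repeated trials")
    s = float(stats.spearmanr(original, repeated).statistic)
    bonus = min(max(0.0, 0.1 * s), 0.1)
    return QualityAssessment(consistency_spearman=s, bonus=bonus)


# ---------------------------------------------------------------------------
# Classical MDS and structure recovery
# ---------------------------------------------------------------------------

def classical_mds(M: SimilarityMatrix, k: int) -> EmbeddingResult:
    """Classical (Torgerson) MDS of a similarity matrix.

    Similarities are converted to dissimilarities by min-max normalisation of
    the observed range, d = (s_max - s)/(s_max - s_min), with zero diagonal;
    the squared dissimilarities are double-centered, B = -1/2 J D^2 J, and the
    top-k eigenvectors scaled by the square roots of the (nonnegative-clipped)
    eigenvalues give the coordinates.
    """
    if k < 1 or k >= M.n:
        raise ValueError("k must satisfy 1 <= k <= n-1")
    sym = symmetrize(M)
    s = sym.values.copy()
    off = ~np.eye(sym.n, dtype=bool)
    if np.isnan(s[off]).any():
        raise ValueError("classical MDS requires all off-diagonal cells")
    smax, smin = float(np.nanmax(s)), float(np.nanmin(s))
    if smax == smin:
        D = np.zeros_like(s)
    else:
        D = (smax - s) / (smax - smin)
    # self-dissimilarity is zero by definition (self-pairs are never elicited)
    np.fill_diagonal(D, 0.0)
    n = sym.n
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(0.5 * (B + B.T))
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    return EmbeddingResult(ids=sym.ids, coordinates=coords, eigenvalues=lam)


def procrustes_distance_correlation(E: EmbeddingResult, truth) -> float:
    """Pearson correlation between embedded and true pairwise distances.

    Distance profiles are invariant to rotation, reflection and translation,
    and Pearson r to uniform scaling, so no explicit Procrustes alignment is
    needed. ``truth`` is a LatentSpace (or any object with ``coordinates``
    mapping ids to points).
    """
    truth_coords = truth.coordinates if hasattr(truth, "coordinates") else dict(truth)
    if set(E.ids) != set(truth_coords):
        raise ValueError("embedding and latent space must cover the same ids")
    X = np.asarray(E.coordinates, dtype=float)
    Y = np.asarray([truth_coords[i] for i in E.ids], dtype=float)
    de = pdist(X)
    dt = pdist(Y)
    return float(stats.pearsonr(de, dt).statistic)


# ---------------------------------------------------------------------------
# Explanation term frequencies
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def term_frequencies(
    texts: Sequence[str], exclude: Iterable[str] = ()
) -> dict[str, float]:
    """Fraction of texts containing each token at least once, sorted descending.

    Texts are lowercased and tokenized on non-letter characters; tokens in
    ``exclude`` (e.g. prompt terms, or generic words like "similar") are
    dropped. Mirrors reporting like "blue appeared in 49% of explanations".
    """
    excl = {t.lower() for t in exclude}
    counts: dict[str, int] = defaultdict(int)
    for text in texts:
        for tok in {t.lower() for t in _TOKEN_RE.findall(text)}:
            if tok not in excl:
                counts[tok] += 1
    n = len(texts)
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {t: c / n for t, c in items}
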