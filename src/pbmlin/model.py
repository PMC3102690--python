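"""Fitting and applying linear K-mer affinity models.

The measured, log-transformed and mean-subtracted probe intensities p are
modelled as p = H alpha + eps, where H is the binary K-mer containment
matrix (with intercept column) and alpha the vector of K-mer affinity
contributions.  The system is solved by running the conjugate gradient
method on the normal equations H'H alpha = H'p from a zero start; the
default of 10 iterations acts as an implicit regularizer and is part of
the method.  Affinities are not sign-constrained.

A heteroscedastic probe-noise model sigma(mu) = sigma0 + beta * mu can be
estimated from technical replicates and used for weighted least squares
(implemented by row-scaling, so constant sigma reduces exactly to OLS).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

from .exceptions import DomainError
from .kmers import DesignMatrix, KmerSet, build_design_matrix, canonicalize

SIGMA_FLOOR = 1e-6


@dataclass
class AffinityModel:
    """A fitted K-mer affinity vector and the bookkeeping needed to predict.

    ``alpha[j]`` is the log-intensity contribution of feature j of
    ``kmer_set``; ``intercept`` is the coefficient of the all-ones column
    and ``training_mean`` the mean subtracted from the training log
    intensities (added back at prediction time).
    """

    kmer_set: KmerSet
    alpha: np.ndarray
    intercept: float
    training_mean: float
    cg_iterations: int = 10
    variant: str = "joint"
    log_base: float | None = None
    training_probe_length: int | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (len(self.kmer_set),):
            raise ValueError(
                f"alpha length {self.alpha.shape} does not match "
                f"{len(self.kmer_set)} features")

    def coefficients(self) -> np.ndarray:
        """alpha with the intercept appended, aligned to design columns."""
        return np.concatenate([self.alpha, [self.intercept]])

    def top_kmers(self, n: int = 20):
        """The n highest-affinity features as (pattern, gap_offset, alpha)."""
        order = np.argsort(-self.alpha)[:n]
        return [(self.kmer_set.features[j].pattern,
                 self.kmer_set.features[j].gap_offset,
                 float(self.alpha[j])) for j in order]


@dataclass
class NoiseModel:
    """Affine probe-noise model sigma(mu) = sigma0 + beta * mu."""

    sigma0: float
    beta: float
    source_replicates: list[str] = field(default_factory=list)

    def sigma(self, mu: np.ndarray) -> np.ndarray:
        return np.maximum(self.sigma0 + self.beta * np.asarray(mu, float),
                          SIGMA_FLOOR)


def center_intensities(p: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the mean of p; returns (centered p, mean)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("cannot center an empty intensity vector")
    if np.isnan(p).any():
        raise DomainError("missing intensities must be excluded before "
                          "centering")
    m = float(p.mean())
    return p - m, m


def solve_normal_equations(
    H: sparse.spmatrix,
    p: np.ndarray,
    iterations: int = 10,
    tol: float = 0.0,
) -> np.ndarray:
    """Conjugate gradient on H'H x = H'p from a zero start.

    Runs exactly ``iterations`` CG steps unless the relative residual of
    the normal equations drops below ``tol`` first (tol=0 disables the
    stopping rule, reproducing a fixed truncated-iteration solve).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    p = np.asarray(p, dtype=float)
    if H.shape[0] != p.shape[0]:
        raise ValueError(f"H has {H.shape[0]} rows but p has {p.shape[0]}")
    H = H.tocsr()
    b = H.T @ p
    x = np.zeros(H.shape[1])
    r = b.copy()
    d = r.copy()
    rs = float(r @ r)
    b_norm = math.sqrt(rs)
    if b_norm == 0.0:
        return x
    for _ in range(iterations):
        if tol > 0.0 and math.sqrt(rs) <= tol * b_norm:
            break
        Ad = H.T @ (H @ d)
        dAd = float(d @ Ad)
        if dAd <= 0.0:  # exact convergence / null-space direction
            break
        a = rs / dAd
        x += a * d
        r -= a * Ad
        rs_new = float(r @ r)
        d = r + (rs_new / rs) * d
        rs = rs_new
    return x


def _identifiable_columns(H: sparse.spmatrix) -> np.ndarray:
    """Mask of feature columns that vary across probes.

    A feature present in every probe (e.g. a K-mer inside the shared
    flank) or in none is exactly collinear with the intercept / carries no
    signal; any affinity assigned to it would be arbitrary, so such
    columns are excluded from the solve and get affinity zero.  The final
    (intercept) column is always kept.
    """
    n = H.shape[0]
    support = np.asarray(H.sum(axis=0)).ravel()
    keep = (support > 0) & (support < n)
    keep[-1] = True
    return keep


def _weighted_system(H: sparse.spmatrix, p: np.ndarray,
                     noise_model: NoiseModel | None,
                     training_mean: float) -> tuple[sparse.spmatrix, np.ndarray]:
    if noise_model is None:
        return H, p
    sig = noise_model.sigma(p + training_mean)
    if np.all(sig == sig[0]):  # Sigma proportional to I: exactly OLS
        return H, p
    w = 1.0 / sig
    w /= w.mean()  # scale-free weights (only ratios matter)
    Hw = H.multiply(w[:, None]).tocsr()
    return Hw, p * w


def fit_affinities(
    design: DesignMatrix,
    p: np.ndarray,
    iterations: int = 10,
    tol: float = 0.0,
    noise_model: NoiseModel | None = None,
    training_mean: float = 0.0,
    log_base: float | None = None,
    training_probe_length: int | None = None,
) -> AffinityModel:
    """Fit alpha from centered log intensities p by (weighted) truncated CG.

    With a noise model, rows of H and p are scaled by 1/sigma(p + mean),
    i.e. the weighted normal equations H'S^-1 H alpha = H'S^-1 p are
    solved; a constant sigma therefore gives exactly the OLS solution.
    """
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise DomainError("probes with missing intensities must be dropped "
                          "before fitting")
    Hs, ps = _weighted_system(design.matrix, p, noise_model, training_mean)
    keep = _identifiable_columns(design.matrix)
    x = np.zeros(Hs.shape[1])
    x[keep] = solve_normal_equations(Hs.tocsc()[:, keep].tocsr(), ps,
                                     iterations=iterations, tol=tol)
    return AffinityModel(
        kmer_set=design.kmer_set,
        alpha=x[:-1],
        intercept=float(x[-1]),
        training_mean=training_mean,
        cg_iterations=iterations,
        variant="joint",
        log_base=log_base,
        training_probe_length=training_probe_length,
    )


def fit_stepwise(
    design: DesignMatrix,
    p: np.ndarray,
    iterations: int = 10,
    tol: float = 0.0,
    noise_model: NoiseModel | None = None,
    training_mean: float = 0.0,
    log_base: float | None = None,
    training_probe_length: int | None = None,
) -> AffinityModel:
    """Stepwise-residual variant: fit each K-length block in ascending
    order of K on the residual of the previous blocks.

    Yields unique (per-block least squares) affinities at the cost of a
    training residual that is never smaller than the joint fit's.  The
    intercept column is attached to the first block.
    """
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise DomainError("probes with missing intensities must be dropped "
                          "before fitting")
    Hs, ps = _weighted_system(design.matrix, p, noise_model, training_mean)
    Hs = Hs.tocsc()
    keep = _identifiable_columns(design.matrix)
    n_feat = len(design.kmer_set)
    alpha = np.zeros(n_feat)
    intercept = 0.0
    residual = ps.copy()
    partitions = design.kmer_set.partition_by_k()
    for step, (_, cols) in enumerate(partitions):
        block_cols = [c for c in cols if keep[c]]
        if step == 0:
            block_cols = block_cols + [n_feat]
        Hb = Hs[:, block_cols].tocsr()
        x = solve_normal_equations(Hb, residual, iterations=iterations, tol=tol)
        residual = residual - Hb @ x
        if step == 0:
            intercept = float(x[-1])
            for j, c in enumerate(block_cols[:-1]):
                alpha[c] = x[j]
        else:
            for j, c in enumerate(block_cols):
                alpha[c] = x[j]
    return AffinityModel(
        kmer_set=design.kmer_set,
        alpha=alpha,
        intercept=intercept,
        training_mean=training_mean,
        cg_iterations=iterations,
        variant="stepwise",
        log_base=log_base,
        training_probe_length=training_probe_length,
    )


def tie_reverse_complements(
    kmer_set: KmerSet, design: DesignMatrix
) -> tuple[KmerSet, DesignMatrix]:
    """Collapse reverse-complement column pairs into canonical columns.

    Each pair of strand-specific columns is merged by logical OR;
    palindromic K-mers map to themselves.  The result constrains reverse
    complements to share one affinity contribution.
    """
    canon_index: dict[tuple[str, int], int] = {}
    canon_feats = []
    col_map = np.empty(len(kmer_set) + 1, dtype=np.int64)
    for j, f in enumerate(kmer_set.features):
        cf = canonicalize(f)
        key = cf.key()
        if key not in canon_index:
            canon_index[key] = len(canon_feats)
            canon_feats.append(cf)
        col_map[j] = canon_index[key]
    n_canon = len(canon_feats)
    col_map[len(kmer_set)] = n_canon  # intercept -> intercept

    transfer = sparse.csr_matrix(
        (np.ones(len(col_map)), (np.arange(len(col_map)), col_map)),
        shape=(len(col_map), n_canon + 1))
    merged = (design.matrix @ transfer).tocsr()
    merged.data = np.minimum(merged.data, 1.0)  # OR of binary columns
    tied_set = KmerSet(canon_feats, strand_tied=True)
    return tied_set, DesignMatrix(merged, design.row_ids, tied_set)


def predict(model: AffinityModel, sequences: list[str]) -> np.ndarray:
    """Predicted log intensities p' = H' alpha + training mean for new
    sequences (intercept included in H' alpha)."""
    if (model.training_probe_length is not None and sequences
            and len(sequences[0]) != model.training_probe_length):
        warnings.warn(
            f"prediction sequences have length {len(sequences[0])} but the "
            f"model was trained on length {model.training_probe_length}; "
            "predictions are most reliable for matching lengths",
            stacklevel=2)
    design = build_design_matrix(sequences, model.kmer_set)
    return design.matrix @ model.coefficients() + model.training_mean


# expected value of the sample sd of n normal draws is c4(n) * sigma
def _c4(n: int) -> float:
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


def fit_noise_model(replicates: list) -> NoiseModel:
    """Estimate sigma(mu) = sigma0 + beta * mu from technical replicates.

    Per probe, the mean and standard deviation of the log intensity across
    replicates are computed (probes missing in any replicate are dropped)
    and an affine curve is fitted to the sd-vs-mean data.  Two small-sample
    corrections keep the fit consistent: the sample sd is unbiased by the
    normal-theory c4 factor, and the slope is disattenuated for the
    sampling noise of the per-probe mean (the regressor is the mean of
    n_rep noisy replicates, which would otherwise bias the slope toward
    zero); mean(sd^2) / n_rep estimates that error variance.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicate samples")
    ids0 = list(replicates[0].probes["probe_id"])
    mats = []
    for rep in replicates:
        if list(rep.probes["probe_id"]) != ids0:
            raise ValueError("replicates must share an identical probe set")
        mats.append(rep.intensities())
    X = np.vstack(mats)  # replicates x probes
    ok = ~np.isnan(X).any(axis=0)
    if ok.sum() < 3:
        raise ValueError("too few probes with complete replicate data")
    X = X[:, ok]
    n_rep = X.shape[0]
    mu = X.mean(axis=0)
    s_raw = X.std(axis=0, ddof=1)
    names = [getattr(r, "name", "") for r in replicates]
    if np.allclose(s_raw, 0.0):
        return NoiseModel(0.0, 0.0, names)
    s = s_raw / _c4(n_rep)
    w = np.ones_like(s)
    sigma0 = beta = 0.0
    # one OLS pass, then a GLS pass reweighted by 1/sigma^2 (Var(s) scales
    # with sigma^2, so bright probes are noisier points on the curve)
    for _ in range(2):
        wm_mu = float(np.average(mu, weights=w))
        wm_s = float(np.average(s, weights=w))
        var_mu = float(np.average((mu - wm_mu) ** 2, weights=w))
        var_true = var_mu - float(np.average(s_raw ** 2, weights=w)) / n_rep
        if var_true <= 1e-12:  # no real intensity spread: sd is a constant
            return NoiseModel(wm_s, 0.0, names)
        cov = float(np.average((mu - wm_mu) * (s - wm_s), weights=w))
        beta = cov / var_true
        sigma0 = wm_s - beta * wm_mu
        w = 1.0 / np.maximum(sigma0 + beta * mu, SIGMA_FLOOR) ** 2
    return NoiseModel(sigma0, beta, names)


def evaluate(predicted: np.ndarray, measured: np.ndarray) -> tuple[float, float]:
    """Pearson and Spearman correlation between predictions and
    measurements, excluding missing pairs (Spearman uses average ranks)."""
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured vectors differ in length")
    ok = ~(np.isnan(predicted) | np.isnan(measured))
    x, y = predicted[ok], measured[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DomainError("zero variance in one of the vectors")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman
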