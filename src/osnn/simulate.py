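"""Synthetic ordinal gene-environment (G-E) interaction data.

This module generates datasets with the statistical structure used throughout the
package's simulation experiments: ``p`` gene-expression (or imaging) features drawn
from a multivariate normal with autoregressive correlation, ``q`` environmental
variables (a mix of continuous and dichotomized normals), a sparse set of important
main effects and G-E interactions obeying *strong hierarchy* (an interaction is
active only if its parent main effect is), and an ordinal response obtained by
discretizing a partially nonlinear latent variable at quantile thresholds.

All indices are 0-based.  The latent response is

    u = eta_lin + sin(eta_lin) + eps,    eps ~ Logistic(0, 1),

with ``eta_lin`` a linear predictor combining main effects, interactions with the
first environmental variable, and environmental main effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "OrdinalDataset",
    "ar_covariance",
    "generate_covariates",
    "build_interactions",
    "nonlinear_latent",
    "discretize_latent",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulated scenario.

    Parameters
    ----------
    n_train, n_val, n_test
        Split sizes.  ``n_val=None`` means a validation set the same size as the
        training set; the test set defaults to 1000 for a stable estimate.
    p, q
        Number of G (or I) variables and environmental variables.
    rho_ar
        AR(rho) correlation of the G variables: corr(X_s, X_t) = rho**|s-t|.
    rho_e
        AR correlation of the latent normals behind the E variables.
    n_important
        Number of important main effects; the same number of interactions (all
        with the first E variable) is active, giving strong hierarchy by design.
    coef_low, coef_high
        Uniform bounds for the main-effect (omega) and E-variable (s) coefficients.
    inter_low, inter_high
        Uniform bounds for the interaction coefficients (c); lower them, e.g. to
        (0.4, 0.7), for a weak-interaction-signal variant.
    proportions
        Target class fractions; (1/3, 1/3, 1/3) balanced or (0.25, 0.5, 0.25)
        imbalanced for K = 3.
    """

    n_train: int = 300
    n_val: int | None = None
    n_test: int = 1000
    p: int = 100
    q: int = 5
    rho_ar: float = 0.25
    rho_e: float = 0.5
    n_important: int = 15
    coef_low: float = 0.6
    coef_high: float = 0.9
    inter_low: float = 0.6
    inter_high: float = 0.9
    proportions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    K: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_ar < 1.0):
            raise ValueError(f"rho_ar must be in [0, 1), got {self.rho_ar}")
        if self.n_important > self.p:
            raise ValueError("n_important cannot exceed p")
        if self.K < 2:
            raise ValueError("K must be at least 2")
        props = np.asarray(self.proportions, dtype=float)
        if len(props) != self.K:
            raise ValueError("proportions must have length K")
        if np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be strictly positive and sum to 1")

    @property
    def n_val_effective(self) -> int:
        return self.n_train if self.n_val is None else self.n_val


@dataclass(frozen=True)
class GroundTruth:
    """The data-generating coefficients and thresholds of one replicate.

    ``main_coefs`` / ``inter_coefs`` are dense (length p / shape p x q) with zeros
    outside the important sets, so the latent predictor is a plain matrix product.
    """

    important_main: np.ndarray          # sorted indices, size n_important
    important_inter: tuple[tuple[int, int], ...]  # (j, d) pairs, 0-based
    main_coefs: np.ndarray              # omega, length p
    inter_coefs: np.ndarray             # c, shape (p, q)
    e_coefs: np.ndarray                 # s, length q
    thresholds: np.ndarray              # K-1 increasing reals (a_0/a_K implicit)

    def __post_init__(self) -> None:
        mains = set(int(j) for j in self.important_main)
        for j, _d in self.important_inter:
            if j not in mains:
                raise ValueError(
                    f"strong hierarchy violated in truth: interaction parent {j} "
                    "is not an important main effect"
                )
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")


@dataclass(frozen=True)
class OrdinalDataset:
    """Covariates, derived interactions and ordinal labels for one split."""

    X: np.ndarray  # (n, p)
    Z: np.ndarray  # (n, q)
    R: np.ndarray  # (n, p*q), R[:, j*q + d] = X[:, j] * Z[:, d]
    y: np.ndarray  # (n,) integer labels in {1..K}

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (self.Z.shape[0] == n and self.R.shape[0] == n and self.y.shape[0] == n):
            raise ValueError("X, Z, R, y must have equal row counts")
        if self.R.shape[1] != self.X.shape[1] * self.Z.shape[1]:
            raise ValueError("R must have p*q columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def features(self) -> np.ndarray:
        """Network input (x, r, z) concatenated per row, shape (n, p + p*q + q)."""
        return np.hstack([self.X, self.R, self.Z])

    def subset(self, idx: np.ndarray) -> "OrdinalDataset":
        return OrdinalDataset(self.X[idx], self.Z[idx], self.R[idx], self.y[idx])


def ar_covariance(dim: int, rho: float) -> np.ndarray:
    """AR(rho) covariance: entry (s, t) = rho**|s-t|, unit diagonal.

    Symmetric positive definite for |rho| < 1.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not np.isfinite(rho) or abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1 and finite, got {rho}")
    idx = np.arange(dim)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def generate_covariates(
    config: SimulationConfig, rng: np.random.Generator, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, Z) for ``n`` samples (default: pooled train+val+test size).

    X is multivariate normal with AR(rho_ar) covariance.  Z starts from q
    correlated normals with AR(rho_e) covariance; the last two columns are
    dichotomized at 0 into {0, 1} indicators, leaving q-2 continuous and two
    discrete environmental variables.
    """
    if n is None:
        n = config.n_train + config.n_val_effective + config.n_test
    cov_x = ar_covariance(config.p, config.rho_ar)
    cov_z = ar_covariance(config.q, config.rho_e)
    try:
        chol_x = np.linalg.cholesky(cov_x)
        chol_z = np.linalg.cholesky(cov_z)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - SPD by construction
        raise np.linalg.LinAlgError(
            f"AR covariance factorization failed: {exc}"
        ) from exc
    X = rng.standard_normal((n, config.p)) @ chol_x.T
    Z = rng.standard_normal((n, config.q)) @ chol_z.T
    # dichotomize the last two E variables at 0 -> {0,1}
    n_binary = min(2, config.q)
    if n_binary:
        Z[:, -n_binary:] = (Z[:, -n_binary:] > 0).astype(float)
    return X, Z


def build_interactions(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """All pairwise products x_j * z_d, j-major d-minor column order.

    Column j*q + d holds X[:, j] * Z[:, d].
    """
    if X.shape[0] != Z.shape[0]:
        raise ValueError(
            f"X and Z must have equal row counts, got {X.shape[0]} vs {Z.shape[0]}"
        )
    return (X[:, :, None] * Z[:, None, :]).reshape(X.shape[0], -1)


def nonlinear_latent(
    X: np.ndarray,
    Z: np.ndarray,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent response u = eta + sin(eta) + eps with standard logistic noise.

    eta = X @ omega + sum_jd c_jd * x_j * z_d + Z @ s.  Pass ``rng=None`` to
    suppress the noise term (useful for exact checks).
    """
    p, q = X.shape[1], Z.shape[1]
    if truth.main_coefs.shape != (p,) or truth.inter_coefs.shape != (p, q):
        raise ValueError("truth coefficient shapes do not match the covariates")
    eta = X @ truth.main_coefs
    eta += np.einsum("ij,jd,id->i", X, truth.inter_coefs, Z)
    eta += Z @ truth.e_coefs
    u = eta + np.sin(eta)
    if rng is not None:
        # standard logistic noise, variance pi^2 / 3
        u = u + rng.logistic(loc=0.0, scale=1.0, size=X.shape[0])
    return u


def discretize_latent(
    u: np.ndarray, proportions: tuple[float, ...] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cut ``u`` at its empirical quantiles into ordered classes.

    Thresholds a_k are the empirical quantiles of ``u`` at the cumulative
    proportions; labels follow y_i = k iff a_{k-1} < u_i <= a_k (half-open
    intervals, a_0 = -inf, a_K = +inf).  If heavy ties at a threshold would empty
    a class (impossible for continuous u), labels fall back to a stable
    rank-based assignment that realizes the requested counts.
    """
    u = np.asarray(u, dtype=float)
    props = np.asarray(proportions, dtype=float)
    K = len(props)
    if np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-12:
        raise ValueError("proportions must be strictly positive and sum to 1")
    cum = np.cumsum(props)[:-1]
    thresholds = np.quantile(u, cum)
    # y = 1 + #{k : a_k < u}; side='left' keeps u == a_k in the lower class
    y = 1 + np.searchsorted(thresholds, u, side="left")
    if len(u) >= K and len(np.unique(y)) < K:
        # tie degeneracy: assign by stable rank so every class is realized
        order = np.argsort(u, kind="stable")
        counts = np.diff(np.round(np.concatenate([[0.0], cum, [1.0]]) * len(u))).astype(int)
        y = np.empty(len(u), dtype=int)
        y[order] = np.repeat(np.arange(1, K + 1), counts)
    return y.astype(int), thresholds


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Coefficients of one replicate; thresholds filled in later."""
    important = np.arange(config.n_important)
    omega = np.zeros(config.p)
    omega[important] = rng.uniform(config.coef_low, config.coef_high, config.n_important)
    c = np.zeros((config.p, config.q))
    c[important, 0] = rng.uniform(config.inter_low, config.inter_high, config.n_important)
    s = rng.uniform(config.coef_low, config.coef_high, config.q)
    inter_pairs = tuple((int(j), 0) for j in important)
    return GroundTruth(
        important_main=important,
        important_inter=inter_pairs,
        main_coefs=omega,
        inter_coefs=c,
        e_coefs=s,
        thresholds=np.arange(1.0, config.K),  # placeholder, replaced after pooling
    )


def generate_dataset(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[OrdinalDataset, OrdinalDataset, OrdinalDataset, GroundTruth]:
    """One full replicate: (train, val, test, truth).

    Coefficients are drawn once; covariates and noise for all three splits are
    drawn jointly, and the class thresholds are empirical quantiles of the pooled
    latent sample, so the splits share a single ground truth.  Sub-streams for
    coefficients, covariates and noise are derived deterministically from the
    given seed.
    """
    if rng is None:
        rng = config.seed
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence(int(rng)))
    rng_coef, rng_cov, rng_noise = (
        np.random.default_rng(s) for s in rng.bit_generator.seed_seq.spawn(3)
    )
    truth = _draw_truth(config, rng_coef)
    n_total = config.n_train + config.n_val_effective + config.n_test
    X, Z = generate_covariates(config, rng_cov, n=n_total)
    u = nonlinear_latent(X, Z, truth, rng_noise)
    y, thresholds = discretize_latent(u, config.proportions)
    truth = replace(truth, thresholds=thresholds)
    R = build_interactions(X, Z)
    pooled = OrdinalDataset(X, Z, R, y)
    i1 = config.n_train
    i2 = i1 + config.n_val_effective
    train = pooled.subset(np.arange(0, i1))
    val = pooled.subset(np.arange(i1, i2))
    test = pooled.subset(np.arange(i2, n_total))
    return train, val, test, truth
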