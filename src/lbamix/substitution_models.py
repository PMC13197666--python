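"""Rate-matrix algebra shared by simulation, ML fitting and MCMC.

All models are built from the same three elements: a symmetric exchangeability
matrix, one or more stationary amino-acid frequency profiles, and a discrete
Gamma distribution of site rates.  A single-component mixture is exactly a
homogeneous model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees_io import AA_ALPHABET

N_STATES = 20
SIMPLEX_TOL = 1e-10
_FREQ_FLOOR = 1e-6

__all__ = [
    "ExchangeabilityMatrix",
    "FrequencyProfile",
    "ProfileMixture",
    "RatesAcrossSites",
    "SubstitutionModel",
    "build_rate_matrix",
    "SpectralDecomposition",
    "transition_probabilities",
    "discrete_gamma_rates",
    "sample_profile_mixture",
    "get_exchangeability",
    "get_default_frequencies",
    "get_cxx_mixture",
    "available_matrices",
    "smooth_profile",
]


def _load_json(name: str) -> dict:
    with resources.files("lbamix.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ExchangeabilityMatrix:
    """Symmetric 20x20 non-negative exchangeabilities with zero diagonal."""

    name: str
    entries: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", m)
        if m.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(m, m.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if (m < 0).any() or not m.any():
            raise ValueError("exchangeabilities must be non-negative and not all zero")
        if np.diag(m).any():
            raise ValueError("exchangeability diagonal must be zero")


def smooth_profile(freqs: np.ndarray) -> np.ndarray:
    """Floor zero frequencies at 1e-6 and renormalize (keeps Q irreducible)."""
    f = np.asarray(freqs, dtype=float)
    f = np.where(f < _FREQ_FLOOR, _FREQ_FLOOR, f)
    return f / f.sum()


@dataclass(frozen=True)
class FrequencyProfile:
    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.shape != (N_STATES,):
            raise ValueError("frequency profile must have 20 entries")
        if (f < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")

    def smoothed(self) -> "FrequencyProfile":
        return FrequencyProfile(smooth_profile(self.freqs))

    @property
    def entropy(self) -> float:
        f = smooth_profile(self.freqs)
        return float(-(f * np.log(f)).sum())


@dataclass(frozen=True)
class ProfileMixture:
    """Profiles with simplex weights; one component means a homogeneous model."""

    profiles: tuple[FrequencyProfile, ...]
    weights: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if len(self.profiles) != len(w):
            raise ValueError("profiles and weights must have equal length")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be a simplex vector")
        if self.labels is not None and len(self.labels) != len(w):
            raise ValueError("labels length mismatch")

    @property
    def k(self) -> int:
        return len(self.profiles)

    def profile_matrix(self) -> np.ndarray:
        return np.stack([p.freqs for p in self.profiles])

    @staticmethod
    def single(profile: FrequencyProfile, label: str | None = None) -> "ProfileMixture":
        return ProfileMixture((profile,), np.array([1.0]), (label,) if label else None)

    def reweighted(self, weights: np.ndarray) -> "ProfileMixture":
        return ProfileMixture(self.profiles, np.asarray(weights, float), self.labels)


@dataclass(frozen=True)
class RatesAcrossSites:
    alpha: float
    ncat: int
    rates: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, float)
        p = np.asarray(self.probs, float)
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "probs", p)
        if abs(float(r @ p) - 1.0) > 1e-8:
            raise ValueError("mean rate must be 1")


def discrete_gamma_rates(alpha: float, ncat: int) -> RatesAcrossSites:
    """Equal-probability discrete Gamma (category means), renormalized to mean 1."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return RatesAcrossSites(alpha, 1, np.array([1.0]), np.array([1.0]))
    # X ~ Gamma(shape=alpha, rate=alpha); category mean over equal-probability bins:
    # ncat * [I(alpha+1, alpha*b_hi) - I(alpha+1, alpha*b_lo)]
    bounds = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, alpha * bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, alpha * bounds)])
    rates = ncat * (upper - lower)
    probs = np.full(ncat, 1.0 / ncat)
    rates = rates / (rates @ probs)
    return RatesAcrossSites(alpha, ncat, rates, probs)


@dataclass(frozen=True)
class SubstitutionModel:
    """Exchangeabilities + profile mixture + discrete Gamma rates."""

    exchangeabilities: ExchangeabilityMatrix
    mixture: ProfileMixture
    rates: RatesAcrossSites
    name: str = ""

    @property
    def is_homogeneous(self) -> bool:
        return self.mixture.k == 1

    @staticmethod
    def homogeneous(
        matrix: str | ExchangeabilityMatrix,
        freqs: np.ndarray | None = None,
        alpha: float = 0.6,
        ncat: int = 4,
        name: str = "",
    ) -> "SubstitutionModel":
        exch = get_exchangeability(matrix) if isinstance(matrix, str) else matrix
        if freqs is None:
            freqs = get_default_frequencies(exch.name)
        prof = FrequencyProfile(smooth_profile(freqs))
        return SubstitutionModel(
            exch,
            ProfileMixture.single(prof),
            discrete_gamma_rates(alpha, ncat),
            name=name or f"{exch.name}+G",
        )


# ---------------------------------------------------------------------------
# Generator construction and CTMC transition probabilities


def build_rate_matrix(R: ExchangeabilityMatrix, pi: FrequencyProfile) -> np.ndarray:
    """Reversible generator Q_ij = R_ij pi_j, normalized to one expected
    substitution per unit branch length; rows sum to zero."""
    f = pi.freqs
    if (f <= 0).any():
        raise ValueError("profile has zero entries; smooth it first")
    Q = R.entries * f[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(f * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / scale


class SpectralDecomposition:
    """Symmetrized eigendecomposition of a reversible Q for fast expm(Q t).

    With D = diag(pi), B = D^1/2 Q D^-1/2 is symmetric; P(t) =
    D^-1/2 V exp(L t) V' D^1/2 row-stochastic for every t >= 0.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self.lam = lam
        self.left = V / sqrt_pi[:, None]  # D^-1/2 V
        self.right = (V * sqrt_pi[:, None]).T  # V' D^1/2
        self.pi = pi

    def transition(self, t) -> np.ndarray:
        """P(t) for scalar or array t; shape (*t.shape, 20, 20)."""
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            raise ValueError("branch length must be non-negative")
        ex = np.exp(np.multiply.outer(t, self.lam))
        P = np.einsum("ik,...k,kj->...ij", self.left, ex, self.right)
        return np.clip(P, 0.0, 1.0)


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """Stochastic matrix expm(Q t); uses the reversible spectral form."""
    if pi is None:
        # stationary distribution of a normalized reversible Q: solve pi Q = 0
        w, vl = np.linalg.eig(Q.T)
        idx = int(np.argmin(np.abs(w)))
        pi = np.abs(np.real(vl[:, idx]))
        pi = pi / pi.sum()
    P = SpectralDecomposition(Q, np.asarray(pi, float)).transition(float(t))
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Synthetic profile mixtures


def sample_profile_mixture(
    K: int,
    base: FrequencyProfile,
    sharpness: float,
    weight_conc: float,
    rng: np.random.Generator,
) -> ProfileMixture:
    """K profiles ~ Dirichlet(sharpness * base), weights ~ Dirichlet(weight_conc).

    Small ``sharpness`` gives sharp, compositionally distinct profiles; the
    sentinel ``K=1, sharpness=inf`` returns the base profile exactly.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    if K == 1 and np.isinf(sharpness):
        return ProfileMixture.single(base, label="base")
    conc = sharpness * smooth_profile(base.freqs)
    profiles = tuple(
        FrequencyProfile(smooth_profile(rng.dirichlet(conc))) for _ in range(K)
    )
    weights = rng.dirichlet(np.full(K, weight_conc)) if K > 1 else np.array([1.0])
    return ProfileMixture(profiles, weights)


# ---------------------------------------------------------------------------
# Bundled empirical constants

_EXCH_CACHE: dict[str, dict] = {}
_CXX_CACHE: dict[str, ProfileMixture] = {}


def _exch_data() -> dict:
    if not _EXCH_CACHE:
        _EXCH_CACHE.update(_load_json("exchangeabilities.json"))
    return _EXCH_CACHE


def available_matrices() -> list[str]:
    return sorted(_exch_data()) + ["POISSON"]


def get_exchangeability(name: str) -> ExchangeabilityMatrix:
    if name.upper() == "POISSON":
        m = np.ones((N_STATES, N_STATES))
        np.fill_diagonal(m, 0.0)
        return ExchangeabilityMatrix("POISSON", m)
    data = _exch_data()
    key = {k.upper(): k for k in data}.get(name.upper())
    if key is None:
        raise KeyError(f"no bundled exchangeability matrix named {name!r}")
    return ExchangeabilityMatrix(key, np.array(data[key]["exchangeabilities"]))


def get_default_frequencies(name: str) -> np.ndarray:
    if name.upper() == "POISSON":
        return np.full(N_STATES, 1.0 / N_STATES)
    data = _exch_data()
    key = {k.upper(): k for k in data}.get(name.upper())
    if key is None:
        raise KeyError(f"no bundled frequencies for matrix {name!r}")
    return np.array(data[key]["frequencies"])


def get_cxx_mixture(name: str, extra_profile: FrequencyProfile | None = None) -> ProfileMixture:
    """Published C10..C60 profile sets with their published weights.

    ``extra_profile`` prepends a '+F'-style component (weights renormalized
    uniformly), as in 'WAG+F+G+CXX' specifications.
    """
    key = name.upper()
    if key not in _CXX_CACHE:
        data = _load_json("cxx_profiles.json")
        if key not in data:
            raise KeyError(f"no bundled profile set named {name!r}")
        profs = tuple(
            FrequencyProfile(smooth_profile(np.array(p))) for p in data[key]["profiles"]
        )
        w = np.array(data[key]["weights"], float)
        _CXX_CACHE[key] = ProfileMixture(
            profs, w / w.sum(), tuple(f"{key}pi{i+1}" for i in range(len(profs)))
        )
    mix = _CXX_CACHE[key]
    if extra_profile is None:
        return mix
    profs = (extra_profile,) + mix.profiles
    k = len(profs)
    labels = ("F",) + (mix.labels or ())
    return ProfileMixture(profs, np.full(k, 1.0 / k), labels)
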