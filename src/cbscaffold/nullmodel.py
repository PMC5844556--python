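"""Score-to-p-value calibration via a random-barcode null.

For a contig barcode of m pixels, R random barcodes with the same length
and short-range correlation are matched against the reference; the maximum
score of each gives a sample from the null distribution of the best match
score. A parametric family is fitted by maximum likelihood:

    F(c) = G(c; nu_eff) ** n_eff,

where G is the null CDF of a single Pearson correlation computed from
nu_eff effective samples (density proportional to (1-c^2)^((nu_eff-4)/2) on
[-1, 1], i.e. (1+c)/2 ~ Beta(a, a) with a = (nu_eff-2)/2), raised to an
effective number n_eff of independent comparisons. Pixels along a barcode
are correlated, so both parameters are effective quantities recovered from
the fit rather than the literal pixel counts. A Gumbel fit is retained as
a baseline for comparison. p-values are the upper tail p = 1 - F(c).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, signal, special, stats

__all__ = [
    "NullFit",
    "PValueTable",
    "estimate_autocorrelation",
    "generate_random_barcodes",
    "fit_null",
    "score_to_pvalue",
    "score_to_logpvalue",
    "length_filter",
    "NullModelCache",
    "child_seed",
]


def child_seed(seed: int, *tokens) -> int:
    """Deterministic substream seed derived from a master seed and tokens."""
    h = hashlib.sha256(repr((int(seed),) + tuple(tokens)).encode())
    return int.from_bytes(h.digest()[:4], "big")


@dataclass(frozen=True)
class NullFit:
    """Fitted null distribution of the maximum match score for one contig
    length."""

    contig_len_px: int
    nu_eff: float
    n_eff: float
    fit_loglik: float
    r_used: int
    gumbel_loglik: float = float("nan")

    def __post_init__(self):
        if not self.nu_eff > 3:
            raise ValueError("nu_eff must exceed 3")
        if not self.n_eff >= 1:
            raise ValueError("n_eff must be >= 1")

    @property
    def beta_a(self) -> float:
        return (self.nu_eff - 2.0) / 2.0

    def cdf(self, c):
        """F(c) = G(c; nu_eff)^n_eff, closed form via the regularized
        incomplete beta function."""
        c = np.clip(np.asarray(c, dtype=float), -1.0, 1.0)
        G = special.betainc(self.beta_a, self.beta_a, (1.0 + c) / 2.0)
        return G**self.n_eff

    def quantile(self, q: float) -> float:
        u = special.betaincinv(self.beta_a, self.beta_a, q ** (1.0 / self.n_eff))
        return float(2.0 * u - 1.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PValueTable:
    """Per-position p-values p[n, x] of one contig (length 2*x_max)."""

    contig_id: str
    pvals: np.ndarray
    log_pvals: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.pvals, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        object.__setattr__(self, "pvals", p)


def estimate_autocorrelation(values: np.ndarray) -> float:
    """Lag-1 autocorrelation of a mean-removed barcode, clipped to
    [0, 0.999]."""
    x = np.asarray(getattr(values, "values", values), dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pixels to estimate autocorrelation")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("zero-variance barcode has no defined autocorrelation")
    rho = float(x[:-1] @ x[1:]) / denom
    return float(np.clip(rho, 0.0, 0.999))


def generate_random_barcodes(
    length_px: int,
    corr_param: float,
    R: int,
    seed: int,
    generator: str = "ar1",
) -> np.ndarray:
    """R stationary Gaussian random barcodes with the given lag-1
    autocorrelation, z-normalized per row.

    ``generator='ar1'`` uses a first-order autoregressive process;
    ``generator='gaussian_filtered'`` convolves white noise with a Gaussian
    kernel whose width reproduces the same lag-1 autocorrelation (the
    natural model for PSF-smoothed barcodes).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not 0 <= corr_param < 1:
        raise ValueError("corr_param must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if generator == "ar1":
        a = corr_param
        eps = rng.standard_normal((R, length_px))
        drive = eps * math.sqrt(max(1.0 - a * a, 1e-12))
        drive[:, 0] = eps[:, 0]  # stationary start
        out = signal.lfilter([1.0], [1.0, -a], drive, axis=1)
    elif generator == "gaussian_filtered":
        if corr_param == 0:
            out = rng.standard_normal((R, length_px))
        else:
            # white noise * Gaussian kernel: acf(k) = exp(-k^2 / (4 s^2))
            s = math.sqrt(-1.0 / (4.0 * math.log(corr_param)))
            half = max(1, int(math.ceil(5 * s)))
            t = np.arange(-half, half + 1, dtype=float)
            kern = np.exp(-0.5 * (t / s) ** 2)
            eps = rng.standard_normal((R, length_px + 2 * half))
            out = signal.fftconvolve(eps, kern[None, :], mode="valid")
    else:
        raise ValueError(f"unknown generator {generator!r}")
    mu = out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    return (out - mu) / sd


def _nll(params, c):
    """Negative log-likelihood of max-score samples under F = G^n."""
    log_a, log_n = params
    a = 0.5 + math.exp(log_a)
    n = 1.0 + math.exp(log_n)
    u = (1.0 + c) / 2.0
    G = special.betainc(a, a, u)
    if (G <= 0).any():
        return 1e12
    # density of a single correlation: g(c) = (1-c^2)^(a-1) / B(a, 1/2)
    log_g = (a - 1.0) * np.log1p(-c * c) - special.betaln(a, 0.5)
    ll = np.log(n) + (n - 1.0) * np.log(G) + log_g
    total = ll.sum()
    if not np.isfinite(total):
        return 1e12
    return -total


def fit_null(max_scores: np.ndarray, contig_len_px: int = 0) -> NullFit:
    """Maximum-likelihood fit of F(c) = G(c; nu_eff)^n_eff to a sample of
    maximum match scores, with a Gumbel baseline for comparison."""
    c = np.asarray(max_scores, dtype=float)
    if len(c) < 10:
        raise ValueError("need at least 10 max scores to fit the null")
    if c.std() == 0:
        raise ValueError("degenerate max-score sample (all equal)")
    if (np.abs(c) >= 1).any():
        c = np.clip(c, -1 + 1e-12, 1 - 1e-12)

    # coarse grid start, then simplex refinement
    best = None
    for a0 in (2.0, 5.0, 15.0, 40.0, 100.0):
        for n0 in (5.0, 30.0, 150.0, 800.0, 4000.0):
            p0 = (math.log(a0 - 0.5), math.log(n0 - 1.0))
            v = _nll(p0, c)
            if best is None or v < best[0]:
                best = (v, p0)
    res = optimize.minimize(
        _nll, best[1], args=(c,), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise RuntimeError(f"null-model fit failed: {res.message}")
    a = 0.5 + math.exp(res.x[0])
    n = 1.0 + math.exp(res.x[1])
    gl = stats.gumbel_r.fit(c)
    gumbel_ll = float(stats.gumbel_r.logpdf(c, *gl).sum())
    return NullFit(
        contig_len_px=int(contig_len_px),
        nu_eff=2.0 * a + 2.0,
        n_eff=n,
        fit_loglik=float(-res.fun),
        r_used=len(c),
        gumbel_loglik=gumbel_ll,
    )


def score_to_pvalue(c, fit: NullFit):
    """Upper-tail p-value p = 1 - F(c) of a match score (vectorized)."""
    c = np.clip(np.asarray(c, dtype=float), -1.0, 1.0)
    G = special.betainc(fit.beta_a, fit.beta_a, (1.0 + c) / 2.0)
    with np.errstate(divide="ignore"):
        t = fit.n_eff * np.log(G)
    return -np.expm1(t)


def score_to_logpvalue(c, fit: NullFit):
    """log p, stable far into the tail (p below 1e-12)."""
    c = np.clip(np.asarray(c, dtype=float), -1.0, 1.0)
    G = special.betainc(fit.beta_a, fit.beta_a, (1.0 + c) / 2.0)
    with np.errstate(divide="ignore"):
        t = fit.n_eff * np.log(G)
    p = -np.expm1(t)
    with np.errstate(divide="ignore"):
        out = np.where(p > 1e-12, np.log(np.maximum(p, 1e-300)), np.log(np.maximum(-t, 1e-300)))
    return out


def length_filter(contigs, l_thresh_bp: float):
    """Partition contigs into (kept, discarded) by sequence length;
    contigs at least l_thresh_bp long are kept."""
    if l_thresh_bp < 0:
        raise ValueError("l_thresh_bp must be non-negative")
    kept = [c for c in contigs if len(c) >= l_thresh_bp]
    discarded = [c for c in contigs if len(c) < l_thresh_bp]
    return kept, discarded


class NullModelCache:
    """One NullFit per (contig length in px, lag-1 autocorrelation rounded
    to 2 decimals), fitted on demand from R random barcodes matched against
    the reference."""

    def __init__(self, matcher, R: int = 1000, seed: int = 0,
                 generator: str = "ar1"):
        self.matcher = matcher
        self.R = R
        self.seed = seed
        self.generator = generator
        self._cache: dict[tuple[int, float], NullFit] = {}

    def get(self, length_px: int, corr_param: float) -> NullFit:
        key = (int(length_px), round(float(corr_param), 2))
        if key not in self._cache:
            sub = child_seed(self.seed, "null", key[0], key[1])
            barcodes = generate_random_barcodes(
                key[0], key[1], self.R, sub, generator=self.generator
            )
            maxima = self.matcher.max_scores(barcodes)
            self._cache[key] = fit_null(maxima, contig_len_px=key[0])
        return self._cache[key]

    def to_json(self, path) -> None:
        payload = {
            f"{k[0]}:{k[1]:.2f}": fit.to_dict() for k, fit in self._cache.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def load_json(self, path) -> None:
        with open(path) as fh:
            payload = json.load(fh)
        for key, d in payload.items():
            length_px, corr = key.split(":")
            self._cache[(int(length_px), float(corr))] = NullFit(**d)
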