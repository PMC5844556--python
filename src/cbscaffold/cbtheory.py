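"""Competitive-binding barcode theory.

Converts a DNA sequence into a theoretical optical barcode. A fluorescent
intercalator (YOYO-1) and a non-fluorescent AT-specific minor-groove binder
(netropsin) compete at equilibrium for sites on the DNA lattice; the
fluorescence profile is the per-basepair probability that YOYO covers the
basepair, blurred by the microscope point spread function and resampled at
camera pixel resolution.

The equilibrium is the standard grand-canonical two-species lattice model:
each bound ligand of species s occupies ``footprint_s`` consecutive
basepairs and carries statistical weight ``K_s(site) * c_free_s``; there is
no ligand-ligand cooperativity. YOYO has a single sequence-independent
binding constant, netropsin's constant is looked up per 4-mer (strand
symmetrized: a 4-mer and its reverse complement share a constant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal

from . import _tm

__all__ = [
    "SequenceRecord",
    "LigandParams",
    "BindingProfile",
    "Barcode",
    "ConvergenceError",
    "free_concentrations",
    "yoyo_binding_profile",
    "apply_psf",
    "to_pixel_resolution",
    "sequence_to_barcode",
    "znorm",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ConvergenceError(RuntimeError):
    """Raised when the free-ligand self-consistency solve does not converge."""


def reverse_complement(bases: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(bases))


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence with identity and topology."""

    id: str
    bases: str
    circular: bool = False

    def __post_init__(self):
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if set(self.bases) - set("ACGT"):
            bad = sorted(set(self.bases) - set("ACGT"))
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGT symbols {bad}; "
                "resolve ambiguity codes before building barcodes"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, bases=reverse_complement(self.bases))


def encode_bases(bases: str) -> np.ndarray:
    return np.frombuffer(
        bases.translate(str.maketrans("ACGT", "\x00\x01\x02\x03")).encode("latin1"),
        dtype=np.uint8,
    ).copy()


def symmetrize_table(table: dict[str, float]) -> np.ndarray:
    """Netropsin constants as a length-256 array indexed by the 4-mer code,
    averaging each 4-mer with its reverse complement."""
    arr = np.zeros(256)
    for kmer, k in table.items():
        if len(kmer) != 4 or set(kmer) - set("ACGT"):
            raise ValueError(f"bad 4-mer {kmer!r} in binding-constant table")
        if k < 0:
            raise ValueError(f"negative binding constant for {kmer!r}")
        code = 0
        for b in kmer:
            code = code * 4 + _BASE_CODE[b]
        arr[code] = k
    out = np.empty(256)
    for code in range(256):
        digits = [(code >> (2 * (3 - i))) & 3 for i in range(4)]
        rc = 0
        for d in reversed(digits):
            rc = rc * 4 + (3 - d)
        out[code] = 0.5 * (arr[code] + arr[rc])
    return out


@dataclass(frozen=True)
class LigandParams:
    """Ligand binding constants, footprints and total concentrations.

    Concentrations are in uM; ``conc_dna`` is in uM basepairs. Binding
    constants are in 1/uM. ``netropsin_constants`` maps each 4-mer to its
    constant; it is strand-symmetrized on construction.
    """

    K_yoyo: float = 26.0
    netropsin_constants: dict[str, float] = field(default_factory=dict)
    footprint_yoyo: int = 4
    footprint_netropsin: int = 4
    conc_yoyo_total: float = 0.02
    conc_netropsin_total: float = 6.0
    conc_dna: float = 0.2

    def __post_init__(self):
        if self.K_yoyo < 0:
            raise ValueError("K_yoyo must be non-negative")
        if min(self.footprint_yoyo, self.footprint_netropsin) < 1:
            raise ValueError("footprints must be >= 1")
        for name in ("conc_yoyo_total", "conc_netropsin_total", "conc_dna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        object.__setattr__(
            self, "_net_table", symmetrize_table(self.netropsin_constants)
        )

    @property
    def netropsin_table(self) -> np.ndarray:
        """Symmetrized constants indexed by 4-mer code (A=0..T=3, base 4)."""
        return self._net_table


@dataclass(frozen=True)
class BindingProfile:
    """Per-basepair probability that a YOYO molecule covers the basepair."""

    p_bound: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p_bound, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("p_bound must be a non-empty 1-D vector")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("binding probabilities must lie in [0, 1]")
        object.__setattr__(self, "p_bound", np.clip(p, 0.0, 1.0))

    def __len__(self) -> int:
        return len(self.p_bound)


@dataclass(frozen=True)
class Barcode:
    """A 1-D pixel intensity profile with its physical metadata."""

    values: np.ndarray
    bp_per_px: float
    psf_sigma_bp: float
    circular: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("barcode must be a non-empty 1-D vector")
        if self.bp_per_px <= 0:
            raise ValueError("bp_per_px must be positive")
        if self.psf_sigma_bp < 0:
            raise ValueError("psf_sigma_bp must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_px(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def znormed(self) -> "Barcode":
        return replace(self, values=znorm(self.values))


def znorm(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd (population) copy of a vector."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-normalize a constant vector")
    return (v - v.mean()) / sd


def _site_weights(
    seq: SequenceRecord, params: LigandParams, c_yoyo: float, c_net: float
):
    """Statistical weights per start site (circular indexing; the linear
    solver zeroes the starts that do not fit)."""
    L = len(seq)
    mn = params.footprint_netropsin
    codes = encode_bases(seq.bases)
    if L >= mn:
        ext = np.concatenate([codes, codes[: mn - 1]])
        kmer = np.zeros(L, dtype=np.int64)
        for i in range(mn):
            kmer = kmer * 4 + ext[i : i + L]
        wn = params.netropsin_table[kmer] * c_net
    else:
        wn = np.zeros(L)
    wy = np.full(L, params.K_yoyo * c_yoyo)
    return wy, wn


def _equilibrium(seq, params, c_yoyo, c_net):
    """Coverage vectors and expected bound-ligand counts at given free
    concentrations."""
    L = len(seq)
    my, mn = params.footprint_yoyo, params.footprint_netropsin
    if L < max(my, mn) and not seq.circular:
        raise ValueError(
            f"linear sequence of {L} bp is shorter than the largest ligand "
            f"footprint ({max(my, mn)} bp)"
        )
    wy, wn = _site_weights(seq, params, c_yoyo, c_net)
    if seq.circular:
        if L < max(my, mn):
            raise ValueError("circular sequence shorter than a footprint")
        return _tm.circular_coverage(wy, wn, my, mn)
    wy = wy.copy()
    wn = wn.copy()
    wy[max(0, L - my + 1) :] = 0.0
    wn[max(0, L - mn + 1) :] = 0.0
    return _tm.linear_coverage(wy, wn, my, mn)


def free_concentrations(
    params: LigandParams,
    seq: SequenceRecord,
    rtol: float = 1e-9,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Solve the two-ligand mass balance for the free concentrations.

    For each ligand, total = free + bound(free), where the bound
    concentration is the equilibrium ligand count per basepair on ``seq``
    scaled by the DNA concentration. Solved as a bounded least-squares
    problem on the relative mass-balance residuals.
    """
    tot = np.array([params.conc_yoyo_total, params.conc_netropsin_total])
    if params.conc_dna == 0 or (params.K_yoyo == 0 and params.netropsin_table.max() == 0):
        return float(tot[0]), float(tot[1])
    L = len(seq)
    scale = np.maximum(tot, 1e-12)

    def bound_conc(c):
        _, _, n_y, n_n = _equilibrium(seq, params, c[0], c[1])
        return params.conc_dna * np.array([n_y, n_n]) / L

    def residuals(c):
        return (tot - c - bound_conc(c)) / scale

    # damped fixed point c <- tot - bound(c); contraction is strong when
    # the bound fraction is modest, the damping handles the rest
    c = tot / 2.0
    damp = 1.0
    last = np.inf
    for _ in range(max_iter):
        r = residuals(c)
        worst = np.abs(r).max()
        if worst < rtol:
            return float(c[0]), float(c[1])
        if worst > last:
            damp = max(damp * 0.5, 0.05)
        last = worst
        c = np.clip(c + damp * r * scale, 0.0, tot)

    res = optimize.least_squares(
        residuals,
        x0=np.maximum(c, 1e-12),
        bounds=(np.zeros(2), np.maximum(tot, 1e-12)),
        xtol=1e-14,
        ftol=1e-14,
        gtol=None,
        max_nfev=max_iter,
    )
    final = residuals(res.x)
    if np.abs(final).max() > rtol:
        raise ConvergenceError(
            f"free-concentration solve did not reach relative tolerance {rtol}; "
            f"residuals={final.tolist()}"
        )
    return float(res.x[0]), float(res.x[1])


def yoyo_binding_profile(
    seq: SequenceRecord,
    params: LigandParams,
    c_free_yoyo: float,
    c_free_netropsin: float,
) -> BindingProfile:
    """Per-basepair probability that a YOYO molecule covers the basepair at
    the given free ligand concentrations (exact transfer-matrix marginals).

    Circular sequences use periodic boundary conditions; linear sequences
    use free ends (no ligand may protrude).
    """
    cov_y, _, _, _ = _equilibrium(seq, params, c_free_yoyo, c_free_netropsin)
    return BindingProfile(cov_y)


def apply_psf(profile, sigma_bp: float, circular: bool) -> np.ndarray:
    """Convolve a per-basepair signal with the Gaussian point spread function.

    Circular signals wrap; linear signals renormalize the kernel at the
    edges so the kernel mass in use always sums to one (no dimming at the
    molecule ends).
    """
    x = np.asarray(getattr(profile, "p_bound", profile), dtype=float)
    if sigma_bp < 0:
        raise ValueError("sigma_bp must be non-negative")
    if sigma_bp == 0:
        return x.copy()
    L = len(x)
    if circular:
        # periodic kernel: sample the Gaussian at circular distances
        d = np.arange(L, dtype=float)
        d = np.minimum(d, L - d)
        kern = np.exp(-0.5 * (d / sigma_bp) ** 2)
        kern /= kern.sum()
        return np.fft.irfft(np.fft.rfft(x) * np.fft.rfft(kern), n=L)
    half = min(L - 1, int(math.ceil(5 * sigma_bp)))
    t = np.arange(-half, half + 1, dtype=float)
    kern = np.exp(-0.5 * (t / sigma_bp) ** 2)
    kern /= kern.sum()
    num = signal.fftconvolve(x, kern, mode="same")
    den = signal.fftconvolve(np.ones(L), kern, mode="same")
    return num / den


def to_pixel_resolution(
    smoothed: np.ndarray,
    bp_per_px: float,
    *,
    psf_sigma_bp: float = 0.0,
    circular: bool = False,
    method: str = "interp",
) -> Barcode:
    """Resample a basepair-resolution signal to camera pixels.

    ``method='interp'`` (default) linearly interpolates the signal at pixel
    centers; ``method='block'`` averages the signal over each pixel's
    basepair extent.
    """
    x = np.asarray(smoothed, dtype=float)
    L = len(x)
    if bp_per_px < 1:
        raise ValueError("bp_per_px must be >= 1")
    n_px = int(round(L / bp_per_px))
    if n_px < 1:
        raise ValueError(
            f"signal of {L} bp is shorter than one pixel at {bp_per_px} bp/px"
        )
    if method == "interp":
        step = L / n_px
        centers = (np.arange(n_px) + 0.5) * step - 0.5
        if circular:
            idx = np.arange(L + 1, dtype=float)
            ext = np.concatenate([x, x[:1]])
            vals = np.interp(np.mod(centers, L), idx, ext)
        else:
            vals = np.interp(np.clip(centers, 0, L - 1), np.arange(L, dtype=float), x)
    elif method == "block":
        edges = np.arange(n_px + 1) * (L / n_px)
        integral = np.concatenate([[0.0], np.cumsum(x)])
        iv = np.interp(edges, np.arange(L + 1, dtype=float), integral)
        vals = np.diff(iv) / np.diff(edges)
    else:
        raise ValueError(f"unknown downsampling method {method!r}")
    return Barcode(
        values=vals,
        bp_per_px=bp_per_px,
        psf_sigma_bp=psf_sigma_bp,
        circular=circular,
    )


def sequence_to_barcode(
    seq: SequenceRecord,
    params: LigandParams,
    sigma_bp: float = 1000.0,
    bp_per_px: float = 500.0,
    *,
    method: str = "interp",
) -> Barcode:
    """Full theory pipeline: free-ligand solve -> binding profile -> PSF ->
    pixel resampling."""
    c_y, c_n = free_concentrations(params, seq)
    profile = yoyo_binding_profile(seq, params, c_y, c_n)
    smoothed = apply_psf(profile, sigma_bp, seq.circular)
    return to_pixel_resolution(
        smoothed,
        bp_per_px,
        psf_sigma_bp=sigma_bp,
        circular=seq.circular,
        method=method,
    )
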