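"""Synthetic inputs for the scaffolding pipeline.

Everything the pipeline consumes can be generated here without external
data: random genomes standing in for the sequenced plasmids and
chromosomes, contig cut plans with truncated-exponential fragment lengths,
pseudo-experimental reference barcodes (theory barcode plus correlated
noise, emulating a consensus of averaged single-molecule measurements),
and mixed plasmid/chromosomal contig sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cbtheory import (
    Barcode,
    LigandParams,
    SequenceRecord,
    sequence_to_barcode,
    znorm,
)
from .nullmodel import child_seed, generate_random_barcodes

__all__ = [
    "TruthEntry",
    "CutPlan",
    "random_genome",
    "truncated_exponential",
    "cut_contigs",
    "sample_contigs",
    "pseudo_experimental_barcode",
    "mixed_sample",
]

# Mean Illumina contig size observed in plasmid/chromosome mixtures; used
# as the default mean fragment length for synthetic cutting.
DEFAULT_MEAN_CONTIG_BP = 24_500.0


@dataclass(frozen=True)
class TruthEntry:
    """Ground-truth placement of one synthetic contig."""

    start_bp: int
    start_px: int | None
    orientation: str  # 'forward' | 'flipped'
    provenance: str = "plasmid"
    length_bp: int = 0


@dataclass
class CutPlan:
    """A tiling of a genome into contigs with its ground truth."""

    genome_id: str
    cut_positions: list[int]
    contigs: list[SequenceRecord]
    truth: dict[str, TruthEntry] = field(default_factory=dict)


def random_genome(
    length_bp: int, gc_content: float = 0.5, circular: bool = True,
    seed: int = 0, id: str = "genome",
) -> SequenceRecord:
    """An i.i.d. random genome with the requested GC content."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if not 0 <= gc_content <= 1:
        raise ValueError("gc_content must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length_bp, p=p)
    return SequenceRecord(id=id, bases=bases.tobytes().decode(), circular=circular)


def truncated_exponential(
    rng: np.random.Generator, mean: float, upper: float, size: int = 1
) -> np.ndarray:
    """Exponential(mean) samples conditioned on not exceeding ``upper``
    (inverse-CDF sampling)."""
    if mean <= 0 or upper <= 0:
        raise ValueError("mean and upper must be positive")
    u = rng.random(size)
    return -mean * np.log1p(-u * (1.0 - np.exp(-upper / mean)))


def cut_contigs(
    genome: SequenceRecord,
    mean_len_bp: float = DEFAULT_MEAN_CONTIG_BP,
    seed: int = 0,
    bp_per_px: float = 500.0,
    provenance: str = "plasmid",
) -> CutPlan:
    """Cut a genome into contigs; inter-cut distances are exponential with
    the given mean, truncated (censored) at the genome length — a draw at
    or past the end simply produces no further cut, so a mean comparable
    to the genome length frequently leaves the genome in one piece. The
    contigs tile the genome. Circular genomes receive a uniform random
    origin cut first. Each contig's orientation is randomized (reverse
    complement with probability 1/2) and recorded in the truth table.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    origin = int(rng.integers(L)) if genome.circular else 0
    cuts = [origin]
    total = 0
    while True:
        d = max(1, int(round(min(rng.exponential(mean_len_bp), float(L)))))
        if total + d >= L:
            break
        total += d
        cuts.append((origin + total) % L)
    x_max = int(round(L / bp_per_px))
    doubled = genome.bases + genome.bases
    starts = [origin + s for s in np.sort([(c - origin) % L for c in cuts])]
    contigs: list[SequenceRecord] = []
    truth: dict[str, TruthEntry] = {}
    for k, s in enumerate(starts):
        e = starts[k + 1] if k + 1 < len(starts) else origin + L
        bases = doubled[s:e]
        cid = f"{genome.id}_c{k:04d}"
        flip = bool(rng.random() < 0.5)
        rec = SequenceRecord(id=cid, bases=bases, circular=False)
        if flip:
            rec = rec.reverse_complement()
        start_bp = s % L
        start_px = int(round(start_bp / bp_per_px)) % max(x_max, 1) + 1
        contigs.append(rec)
        truth[cid] = TruthEntry(
            start_bp=start_bp,
            start_px=start_px,
            orientation="flipped" if flip else "forward",
            provenance=provenance,
            length_bp=len(bases),
        )
    return CutPlan(
        genome_id=genome.id,
        cut_positions=[s % L for s in starts],
        contigs=contigs,
        truth=truth,
    )


def sample_contigs(
    genome: SequenceRecord,
    length_bp: int,
    n: int,
    seed: int = 0,
    bp_per_px: float = 500.0,
    provenance: str = "plasmid",
) -> CutPlan:
    """n equal-length contigs excised at independent uniform positions
    (they do not tile the genome); used for per-length calibration
    studies."""
    rng = np.random.default_rng(seed)
    L = len(genome)
    if length_bp > L:
        raise ValueError("contig longer than the genome")
    x_max = int(round(L / bp_per_px))
    doubled = genome.bases + genome.bases
    hi = L if genome.circular else L - length_bp + 1
    contigs, truth = [], {}
    for k in range(n):
        s = int(rng.integers(hi))
        cid = f"{genome.id}_s{k:04d}"
        rec = SequenceRecord(id=cid, bases=doubled[s : s + length_bp], circular=False)
        flip = bool(rng.random() < 0.5)
        if flip:
            rec = rec.reverse_complement()
        contigs.append(rec)
        truth[cid] = TruthEntry(
            start_bp=s,
            start_px=int(round(s / bp_per_px)) % max(x_max, 1) + 1,
            orientation="flipped" if flip else "forward",
            provenance=provenance,
            length_bp=length_bp,
        )
    return CutPlan(genome_id=genome.id, cut_positions=[], contigs=contigs, truth=truth)


def pseudo_experimental_barcode(
    genome: SequenceRecord,
    ligand_params: LigandParams,
    sigma_bp: float = 1000.0,
    bp_per_px: float = 500.0,
    noise_sd: float = 0.3,
    noise_corr_px: float = 0.9,
    seed: int = 0,
) -> Barcode:
    """Stand-in for an experimental consensus barcode: the theory barcode
    of the genome plus additive stationary correlated Gaussian noise.

    ``noise_sd`` is in units of the z-normalized theory barcode;
    ``noise_corr_px`` is the lag-1 autocorrelation of the noise (the PSF
    smooths optical noise to roughly its own width). The result is
    z-normalized; noise_sd = 0 returns the pure normalized theory barcode.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    theory = sequence_to_barcode(genome, ligand_params, sigma_bp, bp_per_px)
    clean = znorm(theory.values)
    if noise_sd == 0:
        values = clean
    else:
        noise = generate_random_barcodes(
            len(clean), noise_corr_px, 1, child_seed(seed, "refnoise", genome.id)
        )[0]
        values = znorm(clean + noise_sd * noise)
    return Barcode(
        values=values,
        bp_per_px=bp_per_px,
        psf_sigma_bp=sigma_bp,
        circular=genome.circular,
    )


def mixed_sample(
    plasmid_genome: SequenceRecord,
    foreign_genome: SequenceRecord | None,
    mean_len_bp: float = DEFAULT_MEAN_CONTIG_BP,
    seed: int = 0,
    bp_per_px: float = 500.0,
) -> CutPlan:
    """Union of cut plans from a plasmid and an unrelated (foreign) genome,
    with provenance labels in the truth table. Foreign contigs carry no
    true position on the plasmid reference (start_px None)."""
    plan = cut_contigs(
        plasmid_genome, mean_len_bp, child_seed(seed, "plasmid"), bp_per_px,
        provenance="plasmid",
    )
    if foreign_genome is None or len(foreign_genome) == 0:
        return plan
    fplan = cut_contigs(
        foreign_genome, mean_len_bp, child_seed(seed, "foreign"), bp_per_px,
        provenance="foreign",
    )
    for cid, entry in fplan.truth.items():
        plan.truth[cid] = TruthEntry(
            start_bp=entry.start_bp,
            start_px=None,
            orientation=entry.orientation,
            provenance="foreign",
            length_bp=entry.length_bp,
        )
    plan.contigs.extend(fplan.contigs)
    plan.genome_id = f"{plasmid_genome.id}+{foreign_genome.id}"
    return plan
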