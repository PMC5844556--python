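"""Calibration simulation studies.

These protocols validate the pipeline end to end on synthetic data and are
what ``scripts/acceptance.py`` and the acceptance tests run:

* p-value calibration — contigs cut from a reference genome, placed
  independently (no auction); the misallocation fraction among placements
  should track the 1 - (1 - p_thresh) contract, i.e. about 1%.
* pure-sample scaffolding — truncated-exponential cut plans pushed through
  the full pipeline including the auction; correct/placed should be about
  99%.
* foreign rejection — contigs from an unrelated genome attempted against
  the reference; the placed fraction among length-passing contigs should
  be about p_thresh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cbtheory import LigandParams, sequence_to_barcode, znorm
from .io import default_netropsin_table
from .matching import MatchTable, ReferenceMatcher, best_match
from .nullmodel import (
    NullModelCache,
    child_seed,
    estimate_autocorrelation,
    length_filter,
    score_to_pvalue,
)
from .pipeline import ScaffoldConfig, circular_distance_px, run_scaffold
from .synthdata import (
    cut_contigs,
    pseudo_experimental_barcode,
    random_genome,
    sample_contigs,
)

__all__ = [
    "default_params",
    "IndependentPlacement",
    "independent_placements",
    "pvalue_calibration_study",
    "pure_sample_study",
    "foreign_rejection_study",
]


def default_params() -> LigandParams:
    return LigandParams(netropsin_constants=default_netropsin_table())


@dataclass(frozen=True)
class IndependentPlacement:
    """Outcome of placing one contig on its own (steps 1-3, no auction)."""

    contig_id: str
    length_px: int
    c_hat: float
    x_star: int
    orientation: str
    p_hat: float
    placed: bool


def independent_placements(
    contigs,
    matcher: ReferenceMatcher,
    cache: NullModelCache,
    config: ScaffoldConfig,
    params: LigandParams,
) -> list[IndependentPlacement]:
    """Steps 1-3 for each contig separately: theory barcode, sliding
    Pearson, null fit, p-value at the maximum score. A contig is placed
    when p(C_hat) < p_thresh; the non-overlap auction is not involved."""
    out = []
    for rec in contigs:
        barcode = sequence_to_barcode(
            rec, params, config.sigma_bp, config.bp_per_px, method=config.downsample
        )
        values = znorm(barcode.values)
        m = barcode.n_px
        table = MatchTable(contig_id=rec.id, scores=matcher.match(values),
                           contig_len_px=m)
        fit = cache.get(m, estimate_autocorrelation(values))
        bm = best_match(table)
        p_hat = float(score_to_pvalue(bm.c_hat, fit))
        out.append(
            IndependentPlacement(
                contig_id=rec.id,
                length_px=m,
                c_hat=bm.c_hat,
                x_star=bm.x_star,
                orientation=bm.orientation,
                p_hat=p_hat,
                placed=p_hat < config.p_thresh,
            )
        )
    return out


def pvalue_calibration_study(
    seed: int,
    genome_len: int = 138_000,
    contig_lengths=(20_000, 30_000, 40_000),
    n_per_length: int = 250,
    noise_sd: float = 0.3,
    config: ScaffoldConfig | None = None,
    params: LigandParams | None = None,
) -> dict:
    """Independent-placement calibration on a synthetic reference
    (pEC005B-scale stand-in genome by default).

    Contigs are excised from the genome at random positions and placed one
    at a time; a placement is misallocated when its best-match position or
    orientation disagrees with the truth. Returns counts and the
    misallocation percentage among placements.
    """
    config = config or ScaffoldConfig(seed=seed)
    params = params or default_params()
    genome = random_genome(genome_len, circular=True,
                           seed=child_seed(seed, "cal-genome"), id="calref")
    reference = pseudo_experimental_barcode(
        genome, params, config.sigma_bp, config.bp_per_px,
        noise_sd=noise_sd, seed=child_seed(seed, "cal-noise"),
    )
    matcher = ReferenceMatcher(reference)
    cache = NullModelCache(matcher, R=config.R, seed=config.seed,
                           generator=config.null_generator)
    x_max = matcher.x_max
    n_placed = n_wrong = n_attempted = 0
    per_length = {}
    for length in contig_lengths:
        plan = sample_contigs(
            genome, length, n_per_length,
            seed=child_seed(seed, "cal-cut", length), bp_per_px=config.bp_per_px,
        )
        kept, _ = length_filter(plan.contigs, config.l_thresh_bp)
        placements = independent_placements(kept, matcher, cache, config, params)
        stats = {"attempted": len(placements), "placed": 0, "misallocated": 0}
        for pl in placements:
            if not pl.placed:
                continue
            entry = plan.truth[pl.contig_id]
            ok = (
                pl.orientation == entry.orientation
                and circular_distance_px(pl.x_star, entry.start_px, x_max)
                <= config.tol_px
            )
            stats["placed"] += 1
            stats["misallocated"] += 0 if ok else 1
        per_length[length] = stats
        n_attempted += stats["attempted"]
        n_placed += stats["placed"]
        n_wrong += stats["misallocated"]
    return {
        "n_attempted": n_attempted,
        "n_placed": n_placed,
        "n_misallocated": n_wrong,
        "misallocation_pct": 100.0 * n_wrong / n_placed if n_placed else 0.0,
        "per_length": per_length,
    }


def pure_sample_study(
    seed: int,
    genome_len: int = 220_000,
    mean_lens=(10_000, 24_500, 40_000, 80_000),
    n_rep: int = 30,
    noise_sd: float = 0.3,
    config: ScaffoldConfig | None = None,
    params: LigandParams | None = None,
) -> dict:
    """Full-pipeline scaffolding of truncated-exponential cut plans from a
    single synthetic plasmid-scale genome (pUUH-scale stand-in by
    default); placements are pooled over replicates and mean contig
    sizes."""
    config = config or ScaffoldConfig(seed=seed)
    params = params or default_params()
    genome = random_genome(genome_len, circular=True,
                           seed=child_seed(seed, "pure-genome"), id="pureref")
    reference = pseudo_experimental_barcode(
        genome, params, config.sigma_bp, config.bp_per_px,
        noise_sd=noise_sd, seed=child_seed(seed, "pure-noise"),
    )
    n_placed = n_correct = 0
    per_mean = {}
    fill = {}
    for mean_len in mean_lens:
        stats = {"placed": 0, "correct": 0, "attempted": 0}
        fills = []
        for rep in range(n_rep):
            plan = cut_contigs(
                genome, mean_len, seed=child_seed(seed, "pure-cut", mean_len, rep),
                bp_per_px=config.bp_per_px,
            )
            report = run_scaffold(plan.contigs, reference, config, params,
                                  truth=plan.truth)
            stats["placed"] += report.ratios["n_placed"]
            stats["correct"] += report.ratios["n_correct"]
            stats["attempted"] += report.ratios["n_attempted"]
            fills.append(report.filling_fraction)
        per_mean[mean_len] = stats
        fill[mean_len] = (float(np.mean(fills)), float(np.std(fills)))
        n_placed += stats["placed"]
        n_correct += stats["correct"]
    return {
        "n_placed": n_placed,
        "n_correct": n_correct,
        "correct_pct": 100.0 * n_correct / n_placed if n_placed else 0.0,
        "per_mean": per_mean,
        "filling_fraction": fill,
    }


def foreign_rejection_study(
    seed: int,
    plasmid_len: int = 220_000,
    foreign_len: int = 2_000_000,
    mean_lens=(10_000, 17_500, 25_000, 32_500, 45_000),
    reps_per_mean: int = 6,
    noise_sd: float = 0.3,
    config: ScaffoldConfig | None = None,
    params: LigandParams | None = None,
) -> dict:
    """Foreign-contig rejection: contigs cut from an unrelated genome are
    attempted (steps 1-3) on the plasmid stand-in reference; reports the
    placed fraction among length-passing contigs, expected to sit near
    p_thresh."""
    config = config or ScaffoldConfig(seed=seed)
    params = params or default_params()
    plasmid = random_genome(plasmid_len, circular=True,
                            seed=child_seed(seed, "fr-plasmid"), id="frref")
    foreign = random_genome(foreign_len, circular=True,
                            seed=child_seed(seed, "fr-foreign"), id="chrom")
    reference = pseudo_experimental_barcode(
        plasmid, params, config.sigma_bp, config.bp_per_px,
        noise_sd=noise_sd, seed=child_seed(seed, "fr-noise"),
    )
    matcher = ReferenceMatcher(reference)
    cache = NullModelCache(matcher, R=config.R, seed=config.seed,
                           generator=config.null_generator)
    n_attempted = n_placed = 0
    for mean_len in mean_lens:
        for rep in range(reps_per_mean):
            plan = cut_contigs(
                foreign, mean_len, seed=child_seed(seed, "fr-cut", mean_len, rep),
                bp_per_px=config.bp_per_px, provenance="foreign",
            )
            kept, _ = length_filter(plan.contigs, config.l_thresh_bp)
            kept = [c for c in kept
                    if round(len(c) / config.bp_per_px) <= matcher.x_max]
            placements = independent_placements(kept, matcher, cache, config, params)
            n_attempted += len(placements)
            n_placed += sum(p.placed for p in placements)
    return {
        "n_attempted": n_attempted,
        "n_placed": n_placed,
        "placed_fraction": n_placed / n_attempted if n_attempted else 0.0,
    }
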