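"""End-to-end pipelines: the virtual-genome experiment and the decision run.

The virtual-genome experiment is the model-building procedure: mutate a
genome over a series of substitution rates (Ts/Tv preserved), map one
fixed read set against every mutated genome while sweeping the allowed
mismatch count, record each genome's optimal mismatch rate, and fit the
linear model of optimal rate on mutation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .distances import genetic_distance, ortholog_set_distance
from .fixtures import random_genome
from .formats_io import ambiguous_fraction
from .mapping import MismatchProfile, optimal_mismatch_search
from .model_decision import (Decision, DecisionThresholds, DEFAULT_THRESHOLDS,
                             LinearModel, decide, fit_linear)
from .mutagenesis import DEFAULT_RATES, DEFAULT_TSTV, make_virtual_series
from .readsim import SimSpec, simulate_reads

logger = logging.getLogger(__name__)


@dataclass
class VirtualExperimentResult:
    """Per-rate optima plus the fitted linear model.

    ``points`` rows are (mutation_rate, N_star, optimal_mismatch_rate_%).
    The model is fitted with x = mutation rate (fraction) and
    y = optimal mismatch rate (%).
    """

    points: list[tuple[float, int, float]]
    model: LinearModel
    profiles: list[MismatchProfile] = field(default_factory=list, repr=False)
    seeds: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["# mutation_rate\tN_star\toptimal_mismatch_rate_pct"]
        for rate, n_star, opt in self.points:
            lines.append(f"{rate:g}\t{n_star}\t{opt:.6g}")
        m = self.model
        lines.append(f"# model slope={m.slope:.8g} intercept={m.intercept:.8g} "
                     f"r2={m.r2:.8g} rmse={m.rmse:.8g}")
        return "\n".join(lines) + "\n"


def virtual_experiment(seed: int = 1, genome_length: int = 200_000,
                       rates=DEFAULT_RATES, tstv: float = DEFAULT_TSTV,
                       n_reads: int = 20_000, read_length: int = 100,
                       n_max: int = 30, k: int = 12,
                       keep_profiles: bool = False) -> VirtualExperimentResult:
    """Run the virtual-genome series and fit the linear model.

    Seeds are derived deterministically: the genome uses ``seed``, the read
    simulation ``seed + 6``, and the mutated-genome series ``seed + 100 + i``
    for the i-th rate (i from 1).
    """
    genome = random_genome(genome_length, seed)
    spec = SimSpec(n_reads=n_reads, read_length=read_length,
                   error_rate=0.0, paired=False, seed=seed + 6)
    reads, _truth = simulate_reads([genome], spec)
    series = make_virtual_series(genome, rates=rates, tstv=tstv,
                                 base_seed=seed + 99)
    grid = list(range(0, n_max + 1))
    points = []
    profiles = []
    for mut in series:
        profile = optimal_mismatch_search(reads, mut.genome, N_grid=grid, k=k)
        points.append((mut.spec.rate, profile.N_star,
                       profile.optimal_mismatch_rate))
        if keep_profiles:
            profiles.append(profile)
        logger.info("rate %.2f: N*=%d (%.2f%%)", mut.spec.rate,
                    profile.N_star, profile.optimal_mismatch_rate)
    model = fit_linear([(rate, opt) for rate, _n, opt in points])
    return VirtualExperimentResult(
        points=points, model=model, profiles=profiles,
        seeds={"genome": seed, "reads": seed + 6,
               "mutations": [seed + 100 + i for i in range(len(points))]},
    )


def odd_even_holdout(result: VirtualExperimentResult):
    """Train on the odd-indexed rates (1st, 3rd, ...) and report the RMSE of
    predictions on the even-indexed rates — the held-out generalization
    check of the virtual experiment."""
    pts = [(rate, opt) for rate, _n, opt in result.points]
    train = pts[0::2]
    test = pts[1::2]
    from .model_decision import holdout_rmse
    return holdout_rmse(train, test), train, test


def full_decision(ref_available: bool = False,
                  marker_pairs: dict | None = None,
                  numeric_distances: dict | None = None,
                  reads=None, model: LinearModel | None = None,
                  thresholds: DecisionThresholds = DEFAULT_THRESHOLDS,
                  read_length: int | None = None):
    """Distance measurement + decision flow in one call.

    ``marker_pairs`` maps marker name → list of (seq_a, seq_b) pairs; the
    ortholog marker takes the median over pairs, single-sequence markers
    the pairwise distance of their first pair.  ``numeric_distances`` are
    used as-is (taking precedence).  Returns (Decision, distances dict).
    """
    distances = dict(numeric_distances or {})
    for marker, pairs in (marker_pairs or {}).items():
        if marker in distances:
            continue
        pairs = list(pairs)
        if not pairs:
            continue
        if marker == "ortholog" and len(pairs) > 1:
            distances[marker] = ortholog_set_distance(pairs)
        else:
            distances[marker] = genetic_distance(*pairs[0]).distance
    amb = ambiguous_fraction(reads) if reads else None
    decision = decide(ref_available, distances, model=model,
                      thresholds=thresholds, ambiguous_fraction=amb,
                      read_length=read_length)
    return decision, distances
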