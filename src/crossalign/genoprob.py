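"""Multipoint genotype probabilities for an F2 intercross via a hidden Markov model.

The hidden state at each autosomal position is the true genotype, one of
(BB, BR, RR); the chain starts from the F2 Hardy–Weinberg prior (1/4, 1/2, 1/4)
and moves between adjacent grid positions with the two-meioses transition
matrix implied by the interval's recombination fraction (obtained from the cM
gap through the configured map function).  Observed marker calls enter through
a symmetric genotyping-error emission model with error rate ``epsilon``:
the true genotype is observed with probability 1 - epsilon and each of the two
wrong codominant calls with probability epsilon / 2; a missing call is
uninformative (emits 1 for every state).

The forward–backward recursions are scaled per position, so chromosomes with
many thousands of grid positions do not underflow.  The X chromosome is
excluded here: hemizygous males make its state space different, and all
downstream eQTL work uses autosomal probes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import NA, GeneticMap, GenotypeTable
from .genmap import PositionGrid, inverse_map_r

N_STATES = 3  # BB, BR, RR

F2_PRIOR = np.array([0.25, 0.5, 0.25])


def f2_transition(r: float) -> np.ndarray:
    """3x3 genotype transition matrix for two independent meioses.

    Rows/columns ordered (BB, BR, RR).  Each parental meiosis recombines with
    probability ``r``, independently, giving e.g.
    BB -> ((1-r)^2, 2r(1-r), r^2).
    """
    if not 0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def emission(observed: int, true_state: int, epsilon: float = 0.002) -> float:
    """P(observed call | true genotype) under the symmetric error model."""
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"error rate must be in [0, 0.5), got {epsilon}")
    if observed == NA:
        return 1.0
    return 1.0 - epsilon if observed == true_state else epsilon / 2.0


def _emission_table(epsilon: float) -> np.ndarray:
    """Rows: observed call code (0..2); columns: true state."""
    e = np.full((N_STATES, N_STATES), epsilon / 2.0)
    np.fill_diagonal(e, 1.0 - epsilon)
    return e


@dataclass
class GenoProbArray:
    """Posterior genotype probabilities on the evaluation grid, per autosome.

    ``probs[chrom]`` has shape (n_samples, n_positions, 3) over states
    (BB, BR, RR); every triple sums to 1.
    """

    sample_ids: list[str]
    grid: PositionGrid
    probs: dict[str, np.ndarray]
    epsilon: float
    map_function: str

    def chromosomes(self) -> list[str]:
        return list(self.probs)


def calc_genoprob(
    gt: GenotypeTable,
    gmap: GeneticMap,
    grid: PositionGrid,
    epsilon: float = 0.002,
    map_function: str = "carter_falconer",
) -> GenoProbArray:
    """Scaled forward–backward posteriors at every autosomal grid position.

    A sample with no informative calls on a chromosome gets the prior at every
    position (not an error).
    """
    gt.check_against_map(gmap)
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"error rate must be in [0, 0.5), got {epsilon}")
    emit = _emission_table(epsilon)
    marker_col = {m: j for j, m in enumerate(gt.markers)}
    n = gt.n_samples
    probs: dict[str, np.ndarray] = {}

    for chrom in gmap.autosomes():
        pos = grid.positions[chrom]
        midx = grid.marker_index[chrom]
        n_pos = len(pos)

        # emission probabilities per sample x position x state
        e = np.ones((n, n_pos, N_STATES))
        for k in range(n_pos):
            if midx[k] >= 0:
                obs = gt.calls[:, marker_col[gmap.markers[midx[k]]]]
                typed = obs != NA
                e[typed, k, :] = emit[obs[typed]]

        # transition matrices per interval
        trans = [
            f2_transition(inverse_map_r(float(pos[k + 1] - pos[k]), map_function))
            for k in range(n_pos - 1)
        ]

        # scaled forward
        alpha = np.empty((n, n_pos, N_STATES))
        scale = np.empty((n, n_pos))
        a = F2_PRIOR[None, :] * e[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0, None]
        for k in range(1, n_pos):
            a = (alpha[:, k - 1, :] @ trans[k - 1]) * e[:, k, :]
            scale[:, k] = a.sum(axis=1)
            alpha[:, k, :] = a / scale[:, k, None]

        # scaled backward
        beta = np.empty((n, n_pos, N_STATES))
        beta[:, -1, :] = 1.0
        for k in range(n_pos - 2, -1, -1):
            b = (beta[:, k + 1, :] * e[:, k + 1, :]) @ trans[k].T
            beta[:, k, :] = b / scale[:, k + 1, None]

        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        probs[chrom] = post

    return GenoProbArray(
        sample_ids=list(gt.sample_ids),
        grid=grid,
        probs=probs,
        epsilon=float(epsilon),
        map_function=map_function,
    )


def call_genotype(p: GenoProbArray, threshold: float = 0.99) -> dict[str, np.ndarray]:
    """Argmax genotype where the maximal posterior exceeds ``threshold``, else NA.

    Returns, per chromosome, an int8 (samples x positions) array with codes
    {0, 1, 2, -1}.  The threshold is strict: a posterior of exactly
    ``threshold`` is treated as missing.
    """
    calls: dict[str, np.ndarray] = {}
    for chrom, post in p.probs.items():
        arg = post.argmax(axis=2).astype(np.int8)
        arg[post.max(axis=2) <= threshold] = NA
        calls[chrom] = arg
    return calls
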