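"""Synthetic dyadic block-series generator with known ground truth.

Two coupled agents (patient and therapist) each follow a latent k-state
Markov chain whose transition kernel mixes two ingredients:

* a *frequency attraction*: the propensity of moving i -> j grows with the
  product f_i * f_j of the states' target frequencies ("composite frequency",
  the random-walk-like regime), and
* a *distance penalty*: the propensity decays as exp(-d_ij / lambda) in the
  Euclidean distance between state centroids (the attractor-like regime),

added with weights (w_freq, w_dist) and row-normalized.  Each visited state
emits the three linguistic features of its centroid plus Gaussian noise, and
the standardized emissions are mapped back onto the bounded [0, 1] frequency
scale.  Because the generating states, kernel and coupling are known, every
downstream stage (clustering, transition matrices, transition-law regression,
drift tests) has a parameter-recovery test without any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .coding import FEATURE_COLUMNS, WordBlockSeries
from .states import StateSequence


class SimulationError(ValueError):
    pass


#: occupancy-shaped default target frequencies for k = 8 (descending, sums to 1)
DEFAULT_TARGET_FREQS = np.array([0.28, 0.19, 0.15, 0.12, 0.10, 0.08, 0.05, 0.03])

#: raw-scale location/spread used to map standardized emissions into [0, 1]
DEFAULT_FEATURE_MEANS = np.array([0.10, 0.10, 0.12])
DEFAULT_FEATURE_SDS = np.array([0.03, 0.03, 0.03])


def cube_centroids(k: int, scale: float = 1.0) -> np.ndarray:
    """Well-separated default centroids in standardized 3-D feature space.

    The first eight are the corners of the cube {-scale, +scale}^3 (pairwise
    distance >= 2*scale); six face centers extend the layout up to k = 14.
    """
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    faces = np.array(
        [[2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 2], [0, 0, -2]],
        dtype=float,
    )
    pool = np.vstack([corners, faces]) * scale
    if k > len(pool):
        raise SimulationError(f"default centroid layout supports k <= {len(pool)}")
    return pool[:k].copy()


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of one agent's latent state dynamic.

    ``w_freq`` and ``w_dist`` weight the composite-frequency and
    distance-kernel terms of the transition law; ``length_scale`` is the
    e-folding distance of the kernel; ``emission_sd`` the Gaussian noise SD
    around centroids in standardized units.
    """

    k: int = 8
    centroids: np.ndarray | None = None
    target_freqs: np.ndarray | None = None
    w_dist: float = 0.01
    w_freq: float = 1.0
    length_scale: float = 1.5
    emission_sd: float = 0.7
    n_blocks: int = 5000
    coupling: float = 0.3
    seed: int = 0
    feature_means: np.ndarray = field(default_factory=lambda: DEFAULT_FEATURE_MEANS.copy())
    feature_sds: np.ndarray = field(default_factory=lambda: DEFAULT_FEATURE_SDS.copy())

    def __post_init__(self) -> None:
        if self.centroids is None:
            self.centroids = cube_centroids(self.k)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.target_freqs is None:
            if self.k == 8:
                self.target_freqs = DEFAULT_TARGET_FREQS.copy()
            else:
                self.target_freqs = np.full(self.k, 1.0 / self.k)
        self.target_freqs = np.asarray(self.target_freqs, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise SimulationError("centroids must have k rows")
        if self.target_freqs.shape != (self.k,) or np.any(self.target_freqs < 0):
            raise SimulationError("target_freqs must be a length-k non-negative vector")
        if abs(self.target_freqs.sum() - 1.0) > 1e-9:
            raise SimulationError("target_freqs must sum to 1")
        if self.w_dist < 0 or self.w_freq < 0 or self.w_dist + self.w_freq <= 0:
            raise SimulationError("need w_dist >= 0, w_freq >= 0, w_dist + w_freq > 0")
        if self.length_scale <= 0:
            raise SimulationError("length_scale must be positive")
        if self.emission_sd < 0:
            raise SimulationError("emission_sd must be non-negative")
        if not 0.0 <= self.coupling <= 1.0:
            raise SimulationError("coupling must lie in [0, 1]")
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        dist = np.sqrt((d**2).sum(axis=2))
        if np.any(dist[~np.eye(self.k, dtype=bool)] == 0):
            raise SimulationError("centroids must be pairwise distinct")


def build_generator_matrix(config: GeneratorConfig) -> np.ndarray:
    """Row-stochastic transition kernel of the configured transition law.

    T_ij is proportional to ``w_freq * f_i * f_j + w_dist * exp(-d_ij /
    length_scale)`` with each row normalized to sum to one.
    """
    f = config.target_freqs
    diff = config.centroids[:, None, :] - config.centroids[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    raw = config.w_freq * np.outer(f, f) + config.w_dist * np.exp(-d / config.length_scale)
    totals = raw.sum(axis=1)
    if np.any(totals <= 0):
        raise SimulationError("transition kernel has an all-zero row; check weights")
    return raw / totals[:, None]


def simulate_states(
    T: np.ndarray,
    n_blocks: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    init_dist: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a 1-based Markov chain path of length ``n_blocks``."""
    T = np.asarray(T, dtype=float)
    k = T.shape[0]
    if n_blocks < 2:
        raise SimulationError("n_blocks must be >= 2")
    if T.shape != (k, k) or np.any(T < 0):
        raise SimulationError("T must be a square non-negative matrix")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise SimulationError("T rows must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if init_dist is None:
        init_dist = np.full(k, 1.0 / k)
    init_dist = np.asarray(init_dist, dtype=float)
    states = np.empty(n_blocks, dtype=int)
    # inverse-CDF sampling against precomputed cumulative rows
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_blocks)
    states[0] = np.searchsorted(np.cumsum(init_dist), u[0], side="right")
    for t in range(1, n_blocks):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    return states + 1


def emit_blocks(
    pat_states: np.ndarray,
    ther_states: np.ndarray,
    config_pat: GeneratorConfig,
    config_ther: GeneratorConfig | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> tuple[WordBlockSeries, dict]:
    """Emit the six-feature block series of a labeled dyad.

    Each block's standardized features are the state centroid plus
    N(0, emission_sd^2) noise, mapped back to the raw [0, 1] frequency scale
    via the per-feature means/SDs and clipped into the valid range.  The
    fraction of clipped cells is reported and a warning is raised above 5%.
    """
    config_ther = config_ther or config_pat
    pat_states = np.asarray(pat_states, dtype=int)
    ther_states = np.asarray(ther_states, dtype=int)
    if len(pat_states) != len(ther_states):
        raise SimulationError("patient and therapist state sequences differ in length")
    if seed is None:
        seed = np.random.SeedSequence(config_pat.seed).spawn(1)[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(pat_states)

    def emit(states, cfg):
        z = cfg.centroids[states - 1] + rng.normal(0.0, cfg.emission_sd, size=(n, 3))
        raw = cfg.feature_means + cfg.feature_sds * z
        clipped = np.clip(raw, 0.0, 1.0)
        return clipped, int((clipped != raw).sum())

    pat_feats, pat_clip = emit(pat_states, config_pat)
    ther_feats, ther_clip = emit(ther_states, config_ther)
    # POS+NEG+AB per speaker must stay <= 1: rescale the rare offending rows
    for feats in (pat_feats, ther_feats):
        tot = feats.sum(axis=1)
        over = tot > 1.0
        if over.any():
            feats[over] /= tot[over, None]
    clip_rate = (pat_clip + ther_clip) / (6 * n)
    if clip_rate > 0.05:
        warnings.warn(
            f"{clip_rate:.1%} of emitted feature cells were clipped into [0, 1]; "
            "consider smaller feature_sds or emission_sd",
            stacklevel=2,
        )
    frame = pd.DataFrame(
        np.hstack([pat_feats, ther_feats]), columns=FEATURE_COLUMNS
    )
    frame.insert(0, "t", np.arange(n))
    return WordBlockSeries(frame), {"clip_rate": clip_rate, "clipped_cells": pat_clip + ther_clip}


@dataclass
class DyadSimulation:
    """Ground truth and emitted data of one simulated dyad."""

    pat_seq: StateSequence
    ther_seq: StateSequence
    series: WordBlockSeries
    T_pat: np.ndarray
    T_ther: np.ndarray
    stationary_pat: np.ndarray
    clip_info: dict
    subject_id: str = ""


def simulate_dyad(
    config_pat: GeneratorConfig,
    config_ther: GeneratorConfig | None = None,
    coupling: float | None = None,
    seed: int | None = None,
    state_map: Callable[[int], int] | None = None,
    subject_id: str = "",
) -> DyadSimulation:
    """Simulate a coupled patient/therapist dyad.

    At each block the therapist copies ``state_map`` of the patient's current
    state with probability ``coupling``; otherwise it advances from its own
    previous state by its own chain.  ``coupling=0`` gives independent chains,
    ``coupling=1`` a fully driven therapist.  Sub-streams (patient chain,
    therapist chain, coupling coin, emission noise) are split deterministically
    from ``seed`` via numpy's SeedSequence spawning.
    """
    config_ther = config_ther or config_pat
    if config_pat.n_blocks != config_ther.n_blocks:
        raise SimulationError("patient and therapist configs must share n_blocks")
    kappa = config_pat.coupling if coupling is None else coupling
    if not 0.0 <= kappa <= 1.0:
        raise SimulationError("coupling must lie in [0, 1]")
    if seed is None:
        seed = config_pat.seed
    ss = np.random.SeedSequence(seed)
    s_pat, s_ther, s_coin, s_emit = ss.spawn(4)
    n = config_pat.n_blocks

    T_pat = build_generator_matrix(config_pat)
    T_ther = build_generator_matrix(config_ther)
    pat = simulate_states(T_pat, n, seed=s_pat, init_dist=config_pat.target_freqs)

    mapper = state_map or (lambda s: s)
    rng_ther = np.random.default_rng(s_ther)
    rng_coin = np.random.default_rng(s_coin)
    cum = np.cumsum(T_ther, axis=1)
    cum[:, -1] = 1.0
    init_cum = np.cumsum(config_ther.target_freqs)
    ther = np.empty(n, dtype=int)
    copy = rng_coin.random(n) < kappa
    u = rng_ther.random(n)
    prev = int(np.searchsorted(init_cum, u[0], side="right")) + 1
    for t in range(n):
        if copy[t]:
            ther[t] = mapper(int(pat[t]))
        elif t == 0:
            ther[t] = prev
        else:
            ther[t] = int(np.searchsorted(cum[ther[t - 1] - 1], u[t], side="right")) + 1
    series, clip_info = emit_blocks(pat, ther, config_pat, config_ther, seed=s_emit)

    from .markov import stationary_distribution

    return DyadSimulation(
        pat_seq=StateSequence(pat, role="patient", subject_id=subject_id),
        ther_seq=StateSequence(ther, role="therapist", subject_id=subject_id),
        series=series,
        T_pat=T_pat,
        T_ther=T_ther,
        stationary_pat=stationary_distribution(T_pat),
        clip_info=clip_info,
        subject_id=subject_id,
    )


def perturb_freqs(
    f: np.ndarray, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal multiplicative jitter of a frequency vector, renormalized."""
    f = np.asarray(f, dtype=float)
    if jitter <= 0:
        return f.copy()
    g = f * np.exp(rng.normal(0.0, jitter, size=f.shape))
    return g / g.sum()


#: therapist response map used by the cohort builder: responses stay inside
#: the therapist's own frequent repertoire (states 1..5)
def cohort_state_map(s: int) -> int:
    return (s - 1) % 5 + 1


@dataclass
class CohortDyad:
    subject_id: str
    outcome: str  # "good" | "poor"
    sim: DyadSimulation


def simulate_cohort(
    n_good: int = 4,
    n_poor: int = 4,
    n_blocks: int = 5000,
    seed: int = 0,
    emission_sd: float = 0.7,
    pat_jitter: float = 0.15,
    ther_jitter_good: float = 0.05,
    ther_jitter_poor: float = 0.5,
    coupling: float = 0.3,
    pat_target_freqs: np.ndarray | None = None,
    ther_target_freqs: np.ndarray | None = None,
    state_map: Callable[[int], int] | None = cohort_state_map,
    outlier_scale: float = 5.0,
    pat_w_dist: float = 0.005,
    ther_w_dist: float = 0.0,
) -> list[CohortDyad]:
    """Simulate a study-shaped cohort of good- and poor-outcome dyads.

    All subjects of a role share one centroid layout and one baseline
    transition law (patients carry a small distance penalty, therapists a
    pure frequency attraction); per-subject heterogeneity enters through
    multiplicative jitter of the target frequencies.  Poor-outcome therapists
    are given markedly more jitter than good-outcome ones, emulating the more
    variable linguistic behavior of therapists in difficult treatments.

    Two patient states and three therapist states are kept rare (sub-1%
    stationary occupancy) and their centroids pushed far from the frequent
    ones (``outlier_scale``): rare states are simultaneously scarce and
    remote, so pooled clustering isolates them and occupancy pruning
    reproduces the 6-active / 5-active state structure.  Note that a nonzero
    ``w_dist`` places a floor of about ``w_dist / (6 * mean row total)`` under
    every state's occupancy (the kernel's self-term makes scarce states
    sticky), which is why the patient weight is kept small.
    """
    if pat_target_freqs is None:
        pat_target_freqs = np.array([0.285, 0.22, 0.18, 0.14, 0.10, 0.073, 0.001, 0.001])
    if ther_target_freqs is None:
        ther_target_freqs = np.array([0.30, 0.24, 0.18, 0.16, 0.111, 0.003, 0.003, 0.003])

    def layout(base_freqs: np.ndarray) -> np.ndarray:
        c = cube_centroids(len(base_freqs))
        c[base_freqs < 0.01] *= outlier_scale
        return c

    ss = np.random.SeedSequence(seed)
    dyads: list[CohortDyad] = []
    classes = ["good"] * n_good + ["poor"] * n_poor
    for idx, outcome in enumerate(classes):
        sub_ss = ss.spawn(1)[0]
        rng = np.random.default_rng(sub_ss)
        ther_jitter = ther_jitter_good if outcome == "good" else ther_jitter_poor
        cfg_pat = GeneratorConfig(
            centroids=layout(pat_target_freqs),
            target_freqs=perturb_freqs(pat_target_freqs, pat_jitter, rng),
            w_dist=pat_w_dist,
            w_freq=1.0,
            emission_sd=emission_sd,
            n_blocks=n_blocks,
            coupling=coupling,
        )
        cfg_ther = GeneratorConfig(
            centroids=layout(ther_target_freqs),
            target_freqs=perturb_freqs(ther_target_freqs, ther_jitter, rng),
            w_dist=ther_w_dist,
            w_freq=1.0,
            emission_sd=emission_sd,
            n_blocks=n_blocks,
            coupling=coupling,
        )
        subject_id = f"{outcome}{idx + 1}"
        sim = simulate_dyad(
            cfg_pat,
            cfg_ther,
            coupling=coupling,
            seed=int(rng.integers(0, 2**31 - 1)),
            state_map=state_map,
            subject_id=subject_id,
        )
        dyads.append(CohortDyad(subject_id=subject_id, outcome=outcome, sim=sim))
    return dyads
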